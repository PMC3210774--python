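# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `rcflex`, at the level of detail a maintainer or careful
user needs. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Quasi-harmonic analysis

The atomic fluctuation matrix is the mass-weighted covariance of Cartesian
coordinates over all frames, `F_ab = sqrt(m_a m_b) ⟨Δx_a Δx_b⟩`, with the
population average (divide by T, not T−1) so that in-sample identities are
exact: the population variance of a mode's projected amplitudes equals its
eigenvalue, and the full-basis mode-restricted RMSF equals the direct
per-residue RMSF to machine precision.

Conventions and choices:

- **Superposition.** Frames are least-squares fitted (SVD Kabsch with
  determinant correction) onto the iterated mean structure (fit → new mean →
  refit, tolerance 1e-6 Å, max 10 iterations), the standard essential-dynamics
  protocol. The fit uses the analysis selection by default; fluctuations
  entering F are then internal rather than rigid-body. An independent
  quaternion (Horn) formulation serves as the test oracle for the rotation.
- **Selections.** Default analysis selection is "non-solvent" (water residues
  HOH/WAT/SPC excluded); Cα-only is a built-in alternative. Masses come from
  standard atomic weights by element, never from PDB B/occupancy columns.
  Coordinates are Å; atom and residue indices are 0-based internally.
- **Mode order and signs.** Eigenvalues are sorted descending; the *slowest*
  mode is the largest-eigenvalue mode (frequency ∝ 1/sqrt(λ)). Frequencies are
  relative (no k_B·T factor; no absolute cm⁻¹ conversion). Each eigenvector's
  largest-magnitude component is made positive, which fixes the arbitrary sign
  reproducibly; zero-eigenvalue modes get a NaN frequency sentinel
  ("rigid/null"). Eigenvalues within −1e-8·trace/3N of zero are clipped to 0;
  anything more negative is rejected as not a covariance.
- **Window weighting.** All frames are weighted equally regardless of which
  reaction window they came from (pooled-ensemble convention).

## Reaction coupling

- **Dihedral (isomerization) score.** Δω is evaluated by realizing the mode at
  21 evenly spaced amplitudes between the extremes of its projection on the
  ensemble and cumulatively unwrapping ω (period 360°) along the sweep; this
  resolves the ±180° branch-cut ambiguity for large sweeps. The default
  amplitude range is min/max of the projections; a percentile option (default
  1st/99th) guards against single-frame outliers and is recorded in the
  output metadata.
- **Transfer score.** |δ_H · r̂| · A with δ_H the mode's *Cartesian*
  displacement direction at the transferred atom (v_H/√m_H), r̂ the unit
  donor→acceptor vector at the mean structure, and A the mode's amplitude
  range — making dihedral and transfer couplings both per-full-mode-excursion
  quantities, so the slowest-50 normalization is well defined for either.
- **Signs.** Couplings are absolute values: eigenvector sign is arbitrary.
- **Normalization and ranks.** Raw couplings over the slowest 50 modes are
  divided by their mean (so normalized couplings average to exactly 1 over the
  reference set); ranks are by descending normalized coupling with mode-index
  tie-break, independent of input order. "Top-k reaction-coupled modes"
  (default k = 10) are the k best-ranked.

## Cross-homolog comparison

Eigenvectors of different-length proteins are compared on the only well-defined
common space: the alignment-mapped Cα coordinates. Each mode is restricted to
the mapped Cα 3-vectors (alignment-column order) and the restricted set is
re-orthonormalized by ordered Gram–Schmidt, so the best-coupled modes are least
perturbed and γ stays in [0, 1]. The Hess overlap is the normalized sum of
squared inner products, which is symmetric and invariant to rotations within
either span. Alignments (aligned FASTA/Clustal) are consumed, never computed;
equal-length synthetic pairs may use a trivial identity mapping. RMSF profiles
are compared by Pearson correlation over mapped residues plus a region report
(contiguous runs of normalized RMSF > 1.5, minimum length 3). Per-window
interaction series of unequal window counts are linearly interpolated onto a
common reaction-progress grid before correlating.

## Dynamics and networks

- **DCCM.** `C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)` over Cα displacement
  vectors. Zero-fluctuation residues get zero off-diagonals (never NaN) and are
  reported.
- **Dynamic clustering.** The published clustering procedure this emulates is
  not fully specified anywhere we could implement from, so the package uses a
  declared, documented stand-in: per-residue features = the residue's DCCM row
  concatenated with its Cα displacement magnitude in the top-10 coupled modes,
  standardized; agglomerative clustering with average linkage on
  1 − Pearson(features); cluster count chosen from a k-range (default 2–10) by
  maximum silhouette. The construction is deterministic and label-equivariant
  under residue permutation, and is isolated behind `dynamic_cluster` so it can
  be swapped.
- **Hydrogen bonds.** Geometric criteria (3.5 Å heavy-atom distance, D–H–A
  angle ≥ 120° when hydrogens are available, occupancy ≥ 50% of frames) are
  standard MD-analysis defaults, all exposed as parameters. Without hydrogens
  the angle criterion is skipped and pairs are reported once (symmetric mode).
  Disulphide-style permanent bridges can be supplied and enter the graph with
  weight 1.
- **Network identification.** Graph edges: persistent H-bonds (weight =
  occupancy), permanent bridges, and high-|DCCM| pairs (|C| ≥ 0.5, sequence
  separation ≥ 4 to suppress trivial backbone-neighbor correlations — both
  parameters). Endpoints: any residue in a flexible region (normalized RMSF
  > 1.5) to any residue within 4.5 Å of the reaction-coordinate atoms at the
  mean structure. Candidate paths are found with Yen's k-shortest-paths on
  additive −log(weight) costs and ranked by the product of edge weights. We
  deliberately rank by the product rather than by mean × min: the mean rewards
  padding a path with extra strong edges, whereas the product always penalizes
  additional links, so the tightest strong chain ranks first. An empty
  candidate list is a *result* (reported with a diagnostic), mirroring
  homologs with a genuinely truncated network.

## The synthetic generator

The generator emulates the sampling design of a windowed reaction study, not
protein physics. Geometry is a Cα-trace toy: a serpentine grid (default 8 rows
× 15 residues, 3.8 Å within rows, 5.4 Å between rows) rather than a straight
extended trace, because the planted interaction chain needs spatially proximal
non-neighbor residues; a 4-atom dihedral probe group and a 3-atom
donor/acceptor/hydride group are attached near the chain end. Bonded terms,
sterics and solvent are deliberately absent — every analysis under test is
geometric/statistical, and the toy makes all planted features exactly
controllable and recoverable from the truth manifest.

Study conditions (defaults): 120 residues, 37 windows × 500 frames (18,500
conformations) with the reaction dihedral ω driven from 180° to 0° in ~5°
decrements (targets clipped to [2°, 178°] because the probe geometry is
asymptotic at exactly 0°/180°; the planted sweep is therefore 176°); the
two-state variant uses 2 × 10,000 frames with the coupled mode realized as the
inter-state mean shift. Five planted modes with amplitude sds 1.5, 1.2, 1.0,
0.8, 0.6 Å (at the shape peak); the coupled mode is index 2, i.e.
variance-rank 3. Isotropic positional noise is 0.3 Å on the backbone and
0.02 Å on the probe atoms — the probe emulates an umbrella-restrained
active site; with full backbone noise the arctangent geometry of the probe
dihedral would be dominated by noise rather than by the planted drive.

Construction details that matter for interpreting results:

- **Block structure.** Residues fall into 6 contiguous blocks. Each mode's
  displacement field uses one positive tapered envelope per block
  (sqrt-half-sine) so any linear combination keeps blocks sign-coherent and
  internally correlated; per-mode, per-block directions come from the six
  icosahedral axes (pairwise |cos| = 1/√5 ≈ 0.447), keeping inter-block DCCM
  below the 0.5 network-edge threshold by construction. Mode 0 lives on block
  0 alone (the flexible surface block, moving along one fixed axis — which
  also keeps the planted H-bond chain's first link perpendicular to the
  block's motion); each further mode drives a primary and a secondary block.
  Additional coherent per-block motions (blocks 1–5, distinct amplitudes so
  their eigenvalues stay non-degenerate and each keeps its identity across
  seeds) complete the planted carrier set.
- **Residual gears.** Every non-coupled slow carrier has a small deterministic
  component on the probe atom, giving it a weak but nonzero reaction coupling,
  as real enzymes' slow modes do. This makes the top-10 coupled set
  deterministic across seeds — the basis of the cross-seed conservation
  analogue — instead of letting estimation noise pick arbitrary modes beyond
  rank 1.
- **Orthogonalization.** All carriers are mass-weighted, stripped of
  rigid-body content over the backbone, and Gram–Schmidt orthonormalized in a
  fixed order; the truth manifest stores the final orthonormal vectors
  (Gram off-diagonals < 1e-10). Coherent block profiles have the planted
  envelope projected out analytically so orthogonalization cannot cancel
  their probe gears.
- **Coupled-mode drive.** Per-window mean amplitudes are computed from the ω
  targets through the final (post-orthogonalization) probe component, so the
  window-mean structures hit the ω schedule exactly; the within-window spread
  completes the mode's designed total variance. Mid-window per-frame ω is
  intentionally noisy (the arctangent is steep there); the pinned quantities
  are the window-mean structures at the pathway ends and the mode-swept Δω.
- **Planted network.** A 5-residue chain (4 links ≈ 2.7 Å, modulated by
  +0.1 Å across the pathway) runs from the flexible block to the probe;
  chain interior residues are motion-quiet scaffold (block label −1 in the
  truth), so no correlation shortcut can bypass a truncated link. Truncation
  holds one link at 6 Å. A separate monitored pair carries a linear
  distance trend along the pathway (default 0.5 Å total; set
  `monitor_drift=2.0` for a 3→5 Å trend). Window-driven geometry is
  deliberately kept small because any such drift is mutually correlated
  through the reaction coordinate and would otherwise create spurious
  collective modes.
- **Disjoint-subspace variant.** `subspace_variant=1` shifts the block
  partition, rotates the direction motifs, and applies an alternating
  per-residue sign to all profiles, making the planted subspace rigorously
  orthogonal to the base variant's — the "unrelated fold" control.
- **Randomness.** All stochastic draws flow from one `numpy` Generator seeded
  by the single run seed; structural motifs depend only on the spec, so two
  seeds share identical planted structure. Same seed ⇒ bit-identical output.

What passing tests on this generator do and do not show: they validate the
estimators (QHA recovery, coupling ranking, subspace overlap, clustering,
network logic) under realistic sampling noise and window structure; they do
not validate force fields, sampling convergence of real MD, solvent effects,
or anharmonicity beyond the planted Gaussian/driven model.

## Problem sizes used in validation

The acceptance checks run the full study design (18,500 frames) where a single
run suffices (planted-subspace recovery), and a documented reduced design —
10 windows × 100 frames, 120 residues — for the 100-seed batteries (coupling
rank, clustering, network recovery/ablation) and 37 × 200 frames for the
cross-seed conservation pairs. These sizes were chosen so multi-seed batteries
remain cheap while keeping every per-run signal (eigenvalue gaps, occupancy
estimates, Δω) comfortably above its estimation noise.

## Known limitations

- QHA assumes the pooled ensemble's fluctuations are meaningfully summarized
  by a single covariance; strongly multi-basin ensembles mix basins into the
  slow modes (the two-state variant is the qualitative limit of this).
- Δω-based coupling saturates near 180° and is most sensitive where the
  dihedral's lever geometry is steep; couplings between modes beyond the top
  few ranks should be read as order-of-magnitude, not precise.
- The dynamic clustering stand-in is one reasonable construction among
  several; silhouette-based k selection can split weakly-driven blocks.
- Cross-homolog γ has no significance model here; judge values against the
  self (≈1) and disjoint (≈0) controls.
- Full eigendecomposition is used up to 3N ≈ 3,000; beyond that request a
  partial decomposition (`n_modes`) of the slowest modes.
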