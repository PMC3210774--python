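# rcflex — reaction-coupled protein flexibility

`rcflex` analyzes how the slow, collective motions of an enzyme–substrate
complex couple to its chemical step. It is aimed at computational biophysicists
who have conformational ensembles sampled along a reaction pathway (e.g.
umbrella-style windows mapping a cis/trans isomerization, or reactant/product
end-state ensembles for a hydrolysis) and want to know *which* collective modes
move the reaction coordinate, whether those modes are conserved across
homologs, and whether a chain of persistent interactions links flexible surface
regions to the active site.

## The method

**Quasi-harmonic analysis (QHA).** From an ensemble of superposed structures,
build the mass-weighted atomic fluctuation matrix

    F_ab = sqrt(m_a m_b) ⟨ (x_a − ⟨x_a⟩)(x_b − ⟨x_b⟩) ⟩ ,    a, b = 1 … 3N,

and diagonalize it. Eigenvectors are collective displacement modes; the
quasi-harmonic frequency of a mode scales as λ^(−1/2), so the *slowest* modes
are those with the largest fluctuation eigenvalues. Water is excluded.

**Reaction coupling.** Each of the slowest 50 modes is scored against a
reaction coordinate. For an isomerization, the score is Δω = ω⁺ − ω⁻: the
change in the reaction dihedral between the two extreme ends of the mode's
excursion, with the excursion taken from projecting the mode on every snapshot
and ω tracked along a dense amplitude sweep (so a 180° sweep is not aliased by
the branch cut). For a transfer reaction, the score is |δ_H · r̂(C_D→C_A)| · A:
the transferred atom's mode displacement projected on the donor→acceptor axis,
scaled by the mode's amplitude range. Raw scores are normalized by their mean
over the slowest 50 modes; the top-10 by normalized coupling are the
*reaction-coupled modes*.

**Cross-homolog comparison.** Two proteins' top-10 coupled modes are compared
with the Hess subspace overlap

    γ = (1/k) Σ_i Σ_j (v_i^A · v_j^B)² ,

computed on alignment-mapped Cα coordinates after re-orthonormalization;
γ = 1 means identical subspaces, γ = 0 orthogonal ones.

**Networks of coupled motions.** Dynamical cross-correlation maps (DCCM),
residue clustering by dynamical similarity, and persistent hydrogen-bond
detection feed a residue interaction graph; the package reports the
highest-scoring paths from flexible surface regions (normalized RMSF > 1.5)
to residues in contact with the reaction-coordinate atoms.

Because real microsecond MD ensembles of enzymes are not shippable, the
package includes a first-class synthetic generator
(`rcflex.synthetic`) that emulates the sampling design of such a study —
37 windows × 500 frames ≈ 18,500 conformations along a 180°→0° dihedral sweep,
or 2 × 10,000-frame end states — with planted slow modes, exactly one planted
reaction-coupled mode, planted residue blocks, and a planted surface-to-active
interaction chain, plus a machine-readable truth manifest for validation.

## Worked example

```bash
python examples/02_reaction_coupling_ranking.py
```

```
top 5 reaction-coupled modes (Δω in degrees):
 mode_index  lambda_rank  raw_coupling  normalized_coupling
          2            3        178.16                 3.90
          3            4        171.82                 3.76
          0            1        168.01                 3.68
          5            6        167.19                 3.66
          6            7        159.31                 3.49

normalization constant (mean Δω over slowest 50): 45.69°
```

Mode 2 — the planted coupled mode — ranks first by coupling while being only
the third-largest by variance (`lambda_rank 3`): the mode that drives the
chemistry is *not* the overall-largest motion, which is exactly the situation
the coupling score is designed to expose. Its Δω ≈ 178° recovers the planted
180°-sweep of the reaction dihedral. The other examples demonstrate QHA
recovery of the planted slow subspace (`01`), conservation of the coupled
subspace across independently sampled ensembles (γ = 0.995 same motifs vs.
0.004 disjoint, `03`), and recovery/ablation of the planted interaction
network (`04`).

A thin CLI wraps the same pipeline for shell use:

```bash
rcflex simulate --seed 5 --out sim --windows 10 --frames 100
rcflex report --config run.yaml        # QHA + coupling + RMSF + networks
```

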