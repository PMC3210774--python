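"""Synthetic reaction-pathway ensembles with planted ground truth.

The generator emulates the sampling design of a windowed enzyme-reaction study: a
reaction pathway discretized into ``n_windows`` umbrella-style windows (default 37,
mapping a dihedral reaction coordinate from 180° to 0° in ~5° decrements) with
``frames_per_window`` snapshots each (default 500, i.e. 18,500 conformations), or a
two-end-state variant (reactant/product only, default 10,000 frames per state).

Planted structure, all recoverable from the emitted :class:`TruthManifest`:

* a small set of slow collective modes of decreasing amplitude (block-enveloped
  sinusoid harmonics over residue index, mutually orthogonalized);
* exactly one mode coupled to the reaction coordinate: its per-window mean
  amplitude drives a 4-atom probe dihedral ω from ~180° to ~0° (or a transfer
  probe's hydride along the donor→acceptor axis).  All other slow modes carry a
  small residual gear on the probe, so every slow mode has weak but nonzero
  coupling, as in real enzymes, while only the planted mode sweeps the full range;
* residue blocks with distinct correlated dynamics: per-mode, per-block
  displacement directions are drawn from the six icosahedral axes (pairwise
  |cos| = 1/sqrt(5) ≈ 0.447), plus a small coherent per-block motion, so
  intra-block correlations are strong and inter-block correlations stay below
  typical network-edge thresholds;
* a chain of "hydrogen-bond" distance pairs linking the flexible surface block
  (block 0) to the reaction-coordinate probe, with link distances modulated in
  phase with the reaction window, plus a separate monitored pair with a linear
  distance trend along the pathway.

The geometry is a deliberately non-physical Cα-trace toy (serpentine grid with
probe groups attached): the analyses under test are geometric/statistical, and
the toy makes every planted feature exactly controllable.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from .io import AtomRecord, ConformationalEnsemble

__all__ = [
    "SyntheticSpec",
    "TruthManifest",
    "generate_pathway_ensemble",
    "generate_two_state_ensemble",
    "perturb_truncate_network",
]

_CA_MASS = 12.011
_H_MASS = 1.008


class SyntheticError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-truth generator (defaults = the study conditions)."""

    n_residues: int = 120
    n_windows: int = 37
    frames_per_window: int = 500
    mode_sds: tuple[float, ...] = (1.5, 1.2, 1.0, 0.8, 0.6)  # Å at shape peak
    coupled_mode_index: int = 2
    coupling: str = "dihedral"  # "dihedral" | "transfer"
    n_blocks: int = 6
    block_motion_sd: float = 0.3  # Å, coherent per-block motion
    noise_sd: float = 0.3  # Å, isotropic per-atom
    probe_noise_sd: float = 0.02  # Å, probe atoms (restrained active site)
    plant_network: bool = True
    truncated_link: int | None = None
    coupling_strength: float = 1.0
    within_window_fraction: float = 0.35  # fraction of coupled-mode sd within a window
    clip_deg: float = 2.0  # ω targets clipped to [clip, 180-clip]
    dihedral_offset: float = 0.03  # Å, probe out-of-plane offset δ
    transfer_shift: float = 1.4  # Å, total hydride travel along donor→acceptor
    planted_gear_deg: float = 160.0  # residual Δω of non-coupled planted modes
    block_gear_deg: float = 120.0  # residual Δω of geared block-coherent modes
    subspace_variant: int = 0  # nonzero = disjoint planted subspace
    row_length: int = 15
    spacing_x: float = 3.8
    spacing_y: float = 5.4
    chain_link_base: float = 2.7
    chain_link_drift: float = 0.1
    chain_link_broken: float = 6.0
    monitor_base: float = 3.0
    monitor_drift: float = 0.5
    seed: int | None = None

    def validate(self) -> None:
        if self.n_windows < 2:
            raise SyntheticError("need at least 2 windows")
        if not 0 <= self.coupled_mode_index < len(self.mode_sds):
            raise SyntheticError("coupled_mode_index must address a planted mode")
        if self.coupling not in ("dihedral", "transfer"):
            raise SyntheticError(f"unknown coupling kind {self.coupling!r}")
        if self.n_blocks < 2 or self.n_blocks > 6:
            raise SyntheticError("n_blocks must be in [2, 6] (six motif axes available)")
        if self.n_residues < 2 * self.n_blocks:
            raise SyntheticError("need at least 2 residues per block")
        if self.plant_network:
            n_rows = math.ceil(self.n_residues / self.row_length)
            if n_rows < 5 or self.row_length < 8:
                raise SyntheticError(
                    "planted network needs >= 5 serpentine rows and row_length >= 8; "
                    "use plant_network=False for small systems"
                )
        if any(s <= 0 for s in self.mode_sds):
            raise SyntheticError("mode sds must be positive")


@dataclasses.dataclass
class TruthManifest:
    """Everything needed to score recovery without re-reading the generator source."""

    spec: dict
    seed: int
    carrier_vectors: np.ndarray  # 3N x K orthonormal planted motion carriers
    amplitude_sds: np.ndarray  # K, in sqrt(amu) Å (QHA amplitude units)
    planted_count: int  # first `planted_count` carriers are the slow planted modes
    coupled_mode_index: int
    planted_delta_omega: float | None
    planted_transfer_shift: float | None
    planted_state_shift: float | None  # QHA units, two-state only
    window_targets: np.ndarray  # ω targets (deg) or hydride offsets (Å) per window
    block_labels: np.ndarray  # per-residue truth labels, -1 = quiet scaffold residue
    chain_residues: tuple[int, ...]
    chain_pairs: tuple[tuple[int, int], ...]
    truncated_link: int | None
    monitor_pair: tuple[int, int]
    monitor_slope_per_window: float
    reaction_coordinate: dict
    active_atoms: tuple[int, ...]
    probe_atoms: tuple[int, ...]
    flexible_block: int

    def planted_mode_vectors(self) -> np.ndarray:
        return self.carrier_vectors[:, : self.planted_count]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("carrier_vectors", "amplitude_sds", "window_targets", "block_labels"):
            d[key] = np.asarray(d[key]).tolist()
        return json.dumps(d, indent=1)


# ---------------------------------------------------------------------------
# deterministic motif construction (depends on the spec only, never on the seed)
# ---------------------------------------------------------------------------

_PHI = (1.0 + math.sqrt(5.0)) / 2.0


def _icosahedral_axes(variant: int) -> np.ndarray:
    """Six axes with pairwise |cos| = 1/sqrt(5), axis 0 rotated onto +x."""
    raw = np.array(
        [
            (1.0, _PHI, 0.0),
            (0.0, 1.0, _PHI),
            (_PHI, 0.0, 1.0),
            (-1.0, _PHI, 0.0),
            (0.0, 1.0, -_PHI),
            (_PHI, 0.0, -1.0),
        ]
    )
    axes = raw / np.linalg.norm(raw, axis=1)[:, None]
    # rotate axes[0] onto x̂ (Rodrigues)
    a = axes[0]
    b = np.array([1.0, 0.0, 0.0])
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(a @ b)
    if s > 1e-12:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
        axes = axes @ R.T
    if variant:
        rng = np.random.default_rng(97561 + variant)
        M = rng.normal(size=(3, 3))
        Q, r = np.linalg.qr(M)
        Q *= np.sign(np.diag(r))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        axes = axes @ Q.T
    return axes


def _grid_position(i: int, spec: SyntheticSpec) -> np.ndarray:
    row, col = divmod(i, spec.row_length)
    if row % 2 == 1:
        col = spec.row_length - 1 - col
    return np.array([col * spec.spacing_x, row * spec.spacing_y, 0.0])


def _residue_at(row: int, col: int, spec: SyntheticSpec) -> int:
    c = col if row % 2 == 0 else spec.row_length - 1 - col
    return row * spec.row_length + c


@dataclasses.dataclass
class _Motifs:
    atoms: list[AtomRecord]
    base: np.ndarray  # N x 3
    block_of: np.ndarray  # per-residue block id
    quiet: set[int]
    chain: tuple[int, ...]
    monitor: tuple[int, int]
    probe_dihedral: tuple[int, int, int, int]
    probe_transfer: tuple[int, int, int]
    carriers: np.ndarray  # 3N x K orthonormal (mass-weighted)
    amp_sds: np.ndarray
    window_targets: np.ndarray
    window_means: np.ndarray  # per-window mean amplitude of the coupled carrier (QHA units)
    within_sd: float
    coupled_idx: int
    n_planted: int
    probe_dof: int  # flat 3N index of the driven probe coordinate


def _build_motifs(spec: SyntheticSpec) -> _Motifs:
    spec.validate()
    n_res = spec.n_residues
    L = spec.row_length

    # --- blocks --------------------------------------------------------------
    size = n_res // spec.n_blocks
    shift = 10 * spec.subspace_variant
    block_of = np.minimum(((np.arange(n_res) + shift) % n_res) // size, spec.n_blocks - 1)

    # --- scaffold: chain + monitor pair -------------------------------------
    chain: tuple[int, ...] = ()
    quiet: set[int] = set()
    if spec.plant_network:
        chain_col = min(9, spec.row_length - 2)
        chain = tuple(_residue_at(r, chain_col, spec) for r in range(5))
        quiet.update(chain[1:])
    n_rows = math.ceil(n_res / L)
    monitor = (_residue_at(n_rows - 1, 5, spec), _residue_at(n_rows - 1, 2, spec))
    monitor = (min(monitor), max(monitor))
    if monitor[1] >= n_res:
        monitor = (n_res - 6, n_res - 2)
    # monitor residues keep their block's collective motion; only their base
    # positions are overridden so the pair distance tracks the reaction window

    # --- base geometry -------------------------------------------------------
    base_ca = np.stack([_grid_position(i, spec) for i in range(n_res)])
    if spec.plant_network:
        x_chain = base_ca[chain[0], 0]
        z = 1.5
        # link 0 spans the z lift; later links run along +y
        pos = [base_ca[chain[0]].copy()]
        dy0 = math.sqrt(max(spec.chain_link_base**2 - z**2, 0.25))
        pos.append(np.array([x_chain, dy0, z]))
        for k in range(2, 5):
            pos.append(pos[-1] + np.array([0.0, spec.chain_link_base, 0.0]))
        for k, r in enumerate(chain[1:], start=1):
            base_ca[r] = pos[k]
        anchor = pos[4]
        # 3.8 Å lift: only the chain end is within active-site reach (4.5 Å)
        probe_origin = anchor + np.array([0.0, 0.0, 3.8])
    else:
        # anchor over a weakly flexible block so a no-network ensemble offers
        # no correlation shortcut from a flexible region to the active site
        anchor_res = _residue_at(min(5, n_rows - 1), min(7, L - 1), spec)
        anchor = base_ca[anchor_res]
        probe_origin = anchor + np.array([0.0, 0.0, 4.0])
    # monitor pair lifted out of plane; distance driven along x per window
    m1, m2 = monitor
    base_ca[m1] = base_ca[m1] + np.array([0.0, 0.0, 4.0])
    base_ca[m2] = base_ca[m1] + np.array([spec.monitor_base, 0.0, 0.0])

    # probe groups: 4-atom dihedral (PA-PB-PC-PD) and donor/acceptor/hydride
    B = probe_origin
    A = B + np.array([0.0, 1.5, 0.0])
    C = B + np.array([1.5, 0.0, 0.0])
    D = C + np.array([0.0, 0.0, spec.dihedral_offset])
    CD = B + np.array([-1.2, 0.0, 0.0])
    CA_ = CD + np.array([3.5, 0.0, 0.0])
    HT = CD + np.array([1.2, 0.0, 0.0])
    probe_coords = np.stack([A, B, C, D, CD, CA_, HT])

    atoms: list[AtomRecord] = [
        AtomRecord(
            index=i,
            name="CA",
            element="C",
            mass=_CA_MASS,
            residue_index=i,
            residue_name="GLY",
            chain_id="A",
        )
        for i in range(n_res)
    ]
    probe_names = ["PA", "PB", "PC", "PD", "CD", "CAC", "HT"]
    probe_elements = ["C", "C", "C", "C", "C", "C", "H"]
    probe_masses = [_CA_MASS] * 6 + [_H_MASS]
    for k, (nm, el, ms) in enumerate(zip(probe_names, probe_elements, probe_masses)):
        atoms.append(
            AtomRecord(
                index=n_res + k,
                name=nm,
                element=el,
                mass=ms,
                residue_index=n_res + (0 if k < 4 else 1),
                residue_name="PRB",
                chain_id="X",
            )
        )
    base = np.vstack([base_ca, probe_coords])
    n_atoms = base.shape[0]
    masses = np.array([a.mass for a in atoms])

    dih = (n_res, n_res + 1, n_res + 2, n_res + 3)  # PA PB PC PD
    trf = (n_res + 4, n_res + 5, n_res + 6)  # donor, acceptor, hydride

    # --- window schedule ------------------------------------------------------
    W = spec.n_windows
    if spec.coupling == "dihedral":
        omega = np.clip(np.linspace(180.0, 0.0, W), spec.clip_deg, 180.0 - spec.clip_deg)
        tbar = spec.dihedral_offset / np.tan(np.radians(omega))
        window_targets = omega
        probe_dof = 3 * dih[3] + 1  # PD moves along global y
        probe_dir = np.array([0.0, 1.0, 0.0])
        probe_atom = dih[3]
    else:
        tbar = np.linspace(-spec.transfer_shift / 2.0, spec.transfer_shift / 2.0, W)
        window_targets = tbar.copy()
        probe_dof = 3 * trf[2] + 0  # hydride moves along donor→acceptor (x)
        probe_dir = np.array([1.0, 0.0, 0.0])
        probe_atom = trf[2]
    tbar = spec.coupling_strength * tbar
    sd_tbar = float(tbar.std())

    # --- planted mode displacement fields ------------------------------------
    axes = _icosahedral_axes(spec.subspace_variant)
    sds = spec.mode_sds
    n_modes = len(sds)
    f = spec.within_window_fraction
    sigma_c = sds[spec.coupled_mode_index]
    # gear of the coupled mode (probe Å per shape-unit amplitude) chosen so the
    # window-mean drive plus within-window spread reproduce the mode's total sd
    gear_c = sd_tbar / (math.sqrt(max(1.0 - f * f, 1e-9)) * sigma_c) if sd_tbar > 0 else 0.0

    def secondary_gear(sd: float, half_deg: float) -> float:
        if sd <= 0:
            return 0.0
        if spec.coupling == "dihedral":
            t_half = spec.dihedral_offset * math.tan(math.radians(half_deg) / 2.0)
        else:
            t_half = 0.05 * spec.transfer_shift / 2.0
        return t_half / (3.3 * sd)

    block_len = np.array([(block_of == b).sum() for b in range(spec.n_blocks)])
    pos_in_block = np.zeros(n_res, dtype=int)
    counters = [0] * spec.n_blocks
    for i in range(n_res):
        b = block_of[i]
        pos_in_block[i] = counters[b]
        counters[b] += 1

    # Per-block spatial envelope: one positive tapered profile (half-sine), so any
    # linear combination of modes keeps every block sign-coherent and blocks stay
    # internally correlated.  Mode 0 lives on block 0 alone (the flexible surface
    # block, moving along a single fixed axis); each further mode drives a primary
    # and a secondary block with mode-specific icosahedral directions.
    nb = spec.n_blocks
    weightmat = np.zeros((n_modes, nb))
    weightmat[0, 0] = 1.0
    for n in range(1, n_modes):
        primary = 1 + ((2 * (n - 1)) % (nb - 1))
        secondary = 1 + ((2 * (n - 1) + 1) % (nb - 1))
        weightmat[n, primary] = 1.0
        weightmat[n, secondary] = 0.45

    fields: list[np.ndarray] = []
    for n in range(n_modes):
        U = np.zeros((n_atoms, 3))
        for i in range(n_res):
            if i in quiet:
                continue
            b = int(block_of[i])
            w = weightmat[n, b]
            if w == 0.0:
                continue
            xt = (pos_in_block[i] + 1) / (block_len[b] + 1)
            profile = math.sqrt(math.sin(math.pi * xt))
            if spec.subspace_variant:
                # alternating per-residue sign makes the variant's planted
                # subspace rigorously orthogonal to the smooth base fields
                profile *= (-1.0) ** i
            if b == 0:
                direction = axes[0]
            else:
                direction = axes[1 + ((b - 1 + 2 * n) % (nb - 1))]
            U[i] = w * profile * direction
        if n == spec.coupled_mode_index:
            U[probe_atom] += gear_c * probe_dir
        else:
            U[probe_atom] += secondary_gear(sds[n], spec.planted_gear_deg) * probe_dir
        fields.append(U)
    # block-coherent motions for blocks 1..n-1 (block 0's correlation is carried by
    # its dedicated planted mode; a coherent field there would be nearly parallel
    # to it and degenerate under orthogonalization).  Distinct amplitudes keep the
    # block eigenvalues non-degenerate so each block mode keeps its identity.
    block_sds: list[float] = []
    for b in range(1, spec.n_blocks):
        U = np.zeros((n_atoms, 3))
        # coherent profile with the planted envelope projected out, so the block
        # mode is orthogonal to every planted mode by construction and its
        # residual probe gear survives orthogonalization intact
        prof = np.zeros(n_res)
        env = np.zeros(n_res)
        for i in range(n_res):
            if i in quiet or block_of[i] != b:
                continue
            xt = (pos_in_block[i] + 1) / (block_len[b] + 1)
            env[i] = math.sqrt(math.sin(math.pi * xt))
            if spec.subspace_variant:
                env[i] *= (-1.0) ** i
            prof[i] = 1.0 if not spec.subspace_variant else (-1.0) ** i
        denom = float(env @ env)
        if denom > 0:
            prof -= (float(prof @ env) / denom) * env
        for i in range(n_res):
            if prof[i] != 0.0:
                U[i] = prof[i] * axes[b]
        sd_b = spec.block_motion_sd * (1.25 - 0.1 * (b - 1))
        U[probe_atom] += secondary_gear(sd_b, spec.block_gear_deg) * probe_dir
        fields.append(U)
        block_sds.append(sd_b)

    shape_sds = np.array(list(sds) + block_sds)

    # --- mass-weight, remove rigid-body content, orthonormalize ---------------
    sqrt_m = np.repeat(np.sqrt(masses), 3)
    raw = np.stack([(U.ravel() * sqrt_m) for U in fields], axis=1)  # 3N x K
    raw_norms = np.linalg.norm(raw, axis=0)
    keep = (shape_sds > 0) & (raw_norms > 1e-12)
    keep[: n_modes] = True  # planted modes are validated non-degenerate
    raw = raw[:, keep]
    shape_sds = shape_sds[keep]
    raw_norms = raw_norms[keep]
    amp_sds = shape_sds * raw_norms  # QHA amplitude units
    # block-coherent carriers: fix the amplitude scale to the block size rather
    # than the (small) norm of the contrast profile, so their eigenvalues stay
    # clear of the noise bulk and keep distinct identities
    mean_len = float(block_len.mean())
    for k in range(n_modes, raw.shape[1]):
        amp_sds[k] = shape_sds[k] * math.sqrt(_CA_MASS * mean_len * 0.5)

    # rigid-body content is removed over the backbone only (probe rows stay
    # untouched so the planted reaction-coordinate gears are exact)
    bb = np.zeros(n_atoms)
    bb[:n_res] = 1.0
    bb3 = np.repeat(bb, 3)
    com = (masses[:n_res, None] * base[:n_res]).sum(axis=0) / masses[:n_res].sum()
    rigid = []
    for ax in np.eye(3):
        rigid.append(np.tile(ax, n_atoms) * sqrt_m * bb3)
    rel = base - com
    for ax in np.eye(3):
        rigid.append((np.cross(np.tile(ax, (n_atoms, 1)), rel)).ravel() * sqrt_m * bb3)
    basis = []
    for v in rigid:
        w = v.copy()
        for u in basis:
            w -= (u @ w) * u
        nv = np.linalg.norm(w)
        if nv > 1e-9:
            basis.append(w / nv)
    carriers = np.zeros_like(raw)
    for k in range(raw.shape[1]):
        v = raw[:, k].copy()
        for u in basis:
            v -= (u @ v) * u
        for j in range(k):
            v -= (carriers[:, j] @ v) * carriers[:, j]
        nv = np.linalg.norm(v)
        if nv < 1e-9:
            raise SyntheticError(f"planted carrier {k} degenerate after orthogonalization")
        carriers[:, k] = v / nv

    # --- coupled-mode window schedule in QHA amplitude units ------------------
    ci = spec.coupled_mode_index
    comp = carriers[probe_dof, ci]  # mass-weighted probe component
    disp_per_amp = comp / math.sqrt(masses[probe_atom])
    if abs(disp_per_amp) < 1e-12:
        window_means = np.zeros(W)
    else:
        window_means = tbar / disp_per_amp
    # within-window spread completes the mode's designed total variance
    target_var = float(amp_sds[ci] ** 2)
    resid = target_var - float(window_means.var())
    within_sd = math.sqrt(max(resid, (0.05 * amp_sds[ci]) ** 2))

    return _Motifs(
        atoms=atoms,
        base=base,
        block_of=block_of,
        quiet=quiet,
        chain=chain,
        monitor=monitor,
        probe_dihedral=dih,
        probe_transfer=trf,
        carriers=carriers,
        amp_sds=amp_sds,
        window_targets=window_targets,
        window_means=window_means,
        within_sd=within_sd,
        coupled_idx=ci,
        n_planted=n_modes,
        probe_dof=probe_dof,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _window_bases(spec: SyntheticSpec, motifs: _Motifs) -> np.ndarray:
    """Per-window base structures: chain link gaps and the monitored pair distance
    are modulated in phase with the reaction window."""
    W = spec.n_windows
    bases = np.tile(motifs.base, (W, 1, 1))
    frac = np.linspace(0.0, 1.0, W) if W > 1 else np.zeros(1)
    m1, m2 = motifs.monitor
    for w in range(W):
        d_mon = spec.monitor_base + spec.monitor_drift * frac[w]
        bases[w, m2] = bases[w, m1] + np.array([d_mon, 0.0, 0.0])
        if spec.plant_network and motifs.chain:
            chain = motifs.chain
            d_w = spec.chain_link_base + spec.chain_link_drift * frac[w]
            gaps = [d_w] * 4
            if spec.truncated_link is not None:
                if not 0 <= spec.truncated_link < 4:
                    raise SyntheticError("truncated_link must be in [0, 4)")
                gaps[spec.truncated_link] = spec.chain_link_broken
            x_chain = motifs.base[chain[0], 0]
            z = 1.5
            dy0 = math.sqrt(max(gaps[0] ** 2 - z**2, 0.25))
            pos = motifs.base[chain[0]] + np.array([0.0, dy0, z])
            bases[w, chain[1]] = pos
            for k in range(2, 5):
                pos = pos + np.array([0.0, gaps[k - 1], 0.0])
                bases[w, chain[k]] = pos
            # probe group rides with the chain end, keeping its base offset
            shift = pos - motifs.base[chain[4]]
            for pa in (*motifs.probe_dihedral, *motifs.probe_transfer):
                bases[w, pa] = motifs.base[pa] + shift
    return bases


def _generate(spec: SyntheticSpec, seed: int) -> tuple[ConformationalEnsemble, TruthManifest]:
    motifs = _build_motifs(spec)
    rng = np.random.default_rng(seed)
    W, fpw = spec.n_windows, spec.frames_per_window
    T = W * fpw
    n_atoms = len(motifs.atoms)
    labels = np.repeat(np.arange(W), fpw)

    K = motifs.carriers.shape[1]
    amps = rng.normal(size=(T, K)) * motifs.amp_sds
    ci = motifs.coupled_idx
    amps[:, ci] = motifs.window_means[labels] + rng.normal(size=T) * motifs.within_sd

    masses = np.array([a.mass for a in motifs.atoms])
    disp_dirs = (motifs.carriers / np.repeat(np.sqrt(masses), 3)[:, None]).T  # K x 3N

    bases = _window_bases(spec, motifs)
    coords = bases[labels].reshape(T, -1)
    coords += amps @ disp_dirs
    noise_sd = np.full(n_atoms, spec.noise_sd)
    noise_sd[spec.n_residues :] = spec.probe_noise_sd
    coords += rng.normal(size=(T, 3 * n_atoms)) * np.repeat(noise_sd, 3)
    coords = coords.reshape(T, n_atoms, 3)

    ensemble = ConformationalEnsemble(
        atoms=motifs.atoms,
        coordinates=coords,
        window_labels=labels,
        window_values=np.asarray(motifs.window_targets, dtype=float),
    )

    block_labels = motifs.block_of.copy()
    for q in motifs.quiet:
        block_labels[q] = -1
    if spec.coupling == "dihedral":
        rc = {"kind": "dihedral", "atoms": list(motifs.probe_dihedral)}
        active = motifs.probe_dihedral
        planted_dw = 180.0 - 2.0 * spec.clip_deg
        planted_shift = None
    else:
        rc = {"kind": "transfer", "atoms": list(motifs.probe_transfer)}
        active = motifs.probe_transfer
        planted_dw = None
        planted_shift = spec.transfer_shift * spec.coupling_strength
    state_shift = None
    if W == 2:
        state_shift = float(motifs.window_means[1] - motifs.window_means[0])
    chain_pairs = tuple(zip(motifs.chain, motifs.chain[1:])) if motifs.chain else ()
    manifest = TruthManifest(
        spec=dataclasses.asdict(spec),
        seed=seed,
        carrier_vectors=motifs.carriers,
        amplitude_sds=motifs.amp_sds,
        planted_count=motifs.n_planted,
        coupled_mode_index=ci,
        planted_delta_omega=planted_dw,
        planted_transfer_shift=planted_shift,
        planted_state_shift=state_shift,
        window_targets=np.asarray(motifs.window_targets, dtype=float),
        block_labels=block_labels,
        chain_residues=motifs.chain,
        chain_pairs=chain_pairs,
        truncated_link=spec.truncated_link,
        monitor_pair=motifs.monitor,
        monitor_slope_per_window=(
            spec.monitor_drift / (W - 1) if W > 1 else 0.0
        ),
        reaction_coordinate=rc,
        active_atoms=tuple(int(a) for a in active),
        probe_atoms=tuple(range(spec.n_residues, n_atoms)),
        flexible_block=0,
    )
    return ensemble, manifest


def generate_pathway_ensemble(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ConformationalEnsemble, TruthManifest]:
    """Windowed reaction-pathway ensemble (default 37 windows x 500 frames)."""
    if seed is None:
        seed = spec.seed
    if seed is None:
        raise SyntheticError("a seed is required (spec.seed or the seed argument)")
    return _generate(spec, int(seed))


def generate_two_state_ensemble(
    spec: SyntheticSpec, seed: int | None = None, frames_per_state: int = 10_000
) -> tuple[ConformationalEnsemble, TruthManifest]:
    """Two-end-state ensemble (reactant/product only, default 10,000 frames each).

    The coupled mode is realized as the inter-state mean shift; end-state-only
    sampling gives the qualitative version of reaction-coupled flexibility.
    """
    two = dataclasses.replace(spec, n_windows=2, frames_per_window=frames_per_state)
    return generate_pathway_ensemble(two, seed)


def perturb_truncate_network(
    ensemble: ConformationalEnsemble, manifest: TruthManifest, link_index: int
) -> tuple[ConformationalEnsemble, TruthManifest]:
    """Regenerate the ensemble with one chain link held at a non-bonding distance.

    The chosen link's distance is decoupled from the reaction coordinate (fixed at
    ``chain_link_broken`` Å); everything else, including the seed, is unchanged.
    """
    if not manifest.chain_pairs:
        raise SyntheticError("manifest has no planted network to truncate")
    if not 0 <= link_index < len(manifest.chain_pairs):
        raise SyntheticError(f"link_index {link_index} outside planted chain")
    spec = SyntheticSpec(**manifest.spec)
    spec = dataclasses.replace(spec, truncated_link=link_index)
    return generate_pathway_ensemble(spec, manifest.seed)
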