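"""Quasi-harmonic analysis of conformational ensembles.

The atomic fluctuation matrix is the mass-weighted covariance of the Cartesian
coordinates over the ensemble,

    F_ab = sqrt(m_a m_b) < (x_a - <x_a>) (x_b - <x_b>) >,

where a, b run over the 3N selected degrees of freedom and <.> averages over all
frames.  Its eigenvectors are collective displacement modes; eigenvalues (amu Å²)
measure the mass-weighted variance along each mode, and quasi-harmonic frequencies
scale as 1/sqrt(lambda).  The slowest mode is the one with the largest eigenvalue.

Water/solvent atoms are excluded whenever the default (non-solvent) selection is
used, since solvent fluctuations would otherwise dominate the slow end of the
spectrum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .io import AtomSelection, ConformationalEnsemble, calpha

__all__ = [
    "FluctuationMatrix",
    "QHAResult",
    "ModeProjection",
    "build_fluctuation_matrix",
    "qha_decompose",
    "project_mode",
    "project_modes",
    "displace_along_mode",
    "rmsf_from_modes",
]


class QHAError(ValueError):
    pass


@dataclasses.dataclass
class FluctuationMatrix:
    """3N x 3N mass-weighted atomic fluctuation matrix (amu Å²)."""

    matrix: np.ndarray
    selection: AtomSelection
    mean_coordinates: np.ndarray  # N x 3, Å
    masses: np.ndarray  # length N, amu
    frame_count: int

    def __post_init__(self) -> None:
        M = self.matrix
        if M.shape[0] != M.shape[1] or M.shape[0] != 3 * len(self.selection):
            raise QHAError("fluctuation matrix must be 3N x 3N for the selection")
        scale = max(np.abs(M).max(), 1e-300)
        if np.abs(M - M.T).max() > 1e-10 * scale:
            raise QHAError("fluctuation matrix is not symmetric")

    @property
    def n_dof(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass
class QHAResult:
    """Eigen-decomposition of a fluctuation matrix.

    ``eigenvalues`` are sorted descending (mode 0 = slowest = largest fluctuation);
    ``eigenvectors`` holds orthonormal modes as columns; ``frequencies`` are the
    relative quasi-harmonic frequencies 1/sqrt(lambda) (NaN sentinel marks
    rigid/null modes with zero eigenvalue).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # 3N x n_modes, columns orthonormal
    frequencies: np.ndarray
    mean_coordinates: np.ndarray
    masses: np.ndarray
    selection: AtomSelection

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def n_atoms(self) -> int:
        return len(self.selection)

    def mode_vectors(self, mode_index: int) -> np.ndarray:
        """Mode as an N x 3 array of mass-weighted displacement components."""
        return self.eigenvectors[:, mode_index].reshape(-1, 3)

    def mode_displacements(self, mode_index: int) -> np.ndarray:
        """Per-atom Cartesian displacement direction v / sqrt(m) (N x 3, Å per unit amplitude)."""
        return self.mode_vectors(mode_index) / np.sqrt(self.masses)[:, None]


@dataclasses.dataclass
class ModeProjection:
    """Per-frame scalar amplitude of one mode (mass-weighted projection, sqrt(amu) Å)."""

    mode_index: int
    amplitudes: np.ndarray

    @property
    def amplitude_min(self) -> float:
        return float(self.amplitudes.min())

    @property
    def amplitude_max(self) -> float:
        return float(self.amplitudes.max())

    def amplitude_range(self, percentile: float | None = None) -> tuple[float, float]:
        """Amplitude extremes: min/max, or symmetric percentiles (p, 100-p)."""
        if percentile is None:
            return self.amplitude_min, self.amplitude_max
        lo, hi = np.percentile(self.amplitudes, [percentile, 100.0 - percentile])
        return float(lo), float(hi)

    @property
    def variance(self) -> float:
        """Population variance of the amplitudes (equals the mode eigenvalue in-sample)."""
        return float(self.amplitudes.var())


def _displacement_matrix(
    ensemble: ConformationalEnsemble, selection: AtomSelection
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = selection.array
    coords = ensemble.coordinates[:, idx, :]
    mean = coords.mean(axis=0)
    disp = (coords - mean).reshape(ensemble.n_frames, -1)
    masses = ensemble.masses[idx]
    return disp, mean, masses


def build_fluctuation_matrix(
    ensemble: ConformationalEnsemble, selection: AtomSelection
) -> FluctuationMatrix:
    """Build F_ab = sqrt(m_a m_b) <dx_a dx_b> over all frames of the ensemble.

    The ensemble must already be superposed (rigid-body motion removed); a single
    frame is rejected because the zero fluctuation matrix is degenerate.
    """
    if ensemble.n_frames < 2:
        raise QHAError("at least 2 frames are required to build a fluctuation matrix")
    disp, mean, masses = _displacement_matrix(ensemble, selection)
    sqrt_m = np.repeat(np.sqrt(masses), 3)
    weighted = disp * sqrt_m
    F = weighted.T @ weighted / ensemble.n_frames
    return FluctuationMatrix(
        matrix=F,
        selection=selection,
        mean_coordinates=mean,
        masses=masses,
        frame_count=ensemble.n_frames,
    )


def qha_decompose(F: FluctuationMatrix, n_modes: int | None = None) -> QHAResult:
    """Diagonalize the fluctuation matrix into quasi-harmonic modes.

    Eigenvalues within -1e-8 * trace/3N of zero are clipped at 0; anything more
    negative means the matrix is not a covariance and is an error.  A partial
    decomposition (``n_modes``) of the slowest modes is allowed for large systems.

    Degenerate-eigenvalue tie-break: each eigenvector's largest-magnitude component
    is made positive, so mode signs are reproducible across runs and platforms.
    """
    M = F.matrix
    n = F.n_dof
    tol = 1e-8 * max(np.trace(M) / n, 1e-300)
    if n_modes is not None and n_modes < n:
        vals, vecs = scipy.linalg.eigh(M, subset_by_index=[n - n_modes, n - 1])
    else:
        vals, vecs = scipy.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    if vals.min() < -tol:
        raise QHAError(
            f"matrix is not positive semi-definite (eigenvalue {vals.min():.3e})"
        )
    vals = np.clip(vals, 0.0, None)
    # sign convention for reproducibility
    peak = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[peak, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    with np.errstate(divide="ignore"):
        freqs = np.where(vals > 0, 1.0 / np.sqrt(np.where(vals > 0, vals, 1.0)), np.nan)
    return QHAResult(
        eigenvalues=vals,
        eigenvectors=vecs,
        frequencies=freqs,
        mean_coordinates=F.mean_coordinates,
        masses=F.masses,
        selection=F.selection,
    )


def project_modes(
    qha: QHAResult, ensemble: ConformationalEnsemble, mode_indices
) -> np.ndarray:
    """Amplitudes of several modes at once: frames x len(mode_indices)."""
    disp, mean, masses = _displacement_matrix(ensemble, qha.selection)
    if disp.shape[1] != qha.eigenvectors.shape[0]:
        raise QHAError("ensemble selection does not match the QHA selection")
    sqrt_m = np.repeat(np.sqrt(masses), 3)
    return (disp * sqrt_m) @ qha.eigenvectors[:, list(mode_indices)]


def project_mode(
    qha: QHAResult, ensemble: ConformationalEnsemble, mode_index: int
) -> ModeProjection:
    """Project one mode on every snapshot: a_t = sum_a sqrt(m_a) dx_a,t v_a.

    The amplitude range observed over the whole ensemble defines the extent of the
    mode's excursion, used downstream for reaction-coupling scores.
    """
    amps = project_modes(qha, ensemble, [mode_index])[:, 0]
    return ModeProjection(mode_index=mode_index, amplitudes=amps)


def displace_along_mode(
    qha: QHAResult, mode_index: int, amplitude: float
) -> np.ndarray:
    """Structure (N x 3, Å) at a given mode amplitude: <x> + a v / sqrt(m)."""
    if not np.isfinite(amplitude):
        raise QHAError("amplitude must be finite")
    return qha.mean_coordinates + amplitude * qha.mode_displacements(mode_index)


def rmsf_from_modes(
    qha: QHAResult,
    mode_indices,
    ensemble: ConformationalEnsemble,
) -> "ModeRMSF":
    """Per-residue Cα RMSF restricted to a mode subset, plus the normalized profile.

    RMSF_i = sqrt( sum_n var(a_n) |v_{i,n}|^2 / m_i ) over the requested modes,
    with var(a_n) the population variance of the mode's projected amplitudes.  The
    normalized profile divides by the mean over residues (so its mean is exactly 1),
    mirroring the convention of normalizing by the average Cα flexibility.

    Only residues with a Cα inside the QHA selection contribute; others are
    omitted and counted in ``omitted_residues``.
    """
    mode_indices = list(mode_indices)
    if not mode_indices:
        raise QHAError("mode_indices must be non-empty")
    amps = project_modes(qha, ensemble, mode_indices)
    variances = amps.var(axis=0)

    sel_idx = qha.selection.array
    atoms = ensemble.atoms
    ca_rows = [k for k, i in enumerate(sel_idx) if calpha(atoms[i])]
    all_residues = {atoms[i].residue_index for i in range(len(atoms)) if not atoms[i].is_solvent}
    omitted = len(all_residues) - len(ca_rows)
    if not ca_rows:
        raise QHAError("no Cα atoms inside the QHA selection")

    residues = np.array([atoms[sel_idx[k]].residue_index for k in ca_rows])
    masses = qha.masses[ca_rows]
    msf = np.zeros(len(ca_rows))
    for n, var in zip(mode_indices, variances):
        d = qha.mode_vectors(n)[ca_rows]  # mass-weighted components
        msf += var * (d**2).sum(axis=1) / masses
    rmsf = np.sqrt(msf)
    return ModeRMSF(
        residue_indices=residues,
        rmsf=rmsf,
        normalized=rmsf / rmsf.mean(),
        mode_indices=tuple(mode_indices),
        omitted_residues=omitted,
    )


@dataclasses.dataclass
class ModeRMSF:
    """Per-residue Cα RMSF profile (Å) restricted to a mode subset."""

    residue_indices: np.ndarray
    rmsf: np.ndarray
    normalized: np.ndarray
    mode_indices: tuple[int, ...]
    omitted_residues: int = 0
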