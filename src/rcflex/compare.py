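"""Cross-homolog comparison of reaction-coupled flexibility.

Eigenmodes of different proteins live in different 3N-dimensional spaces, so all
comparisons are made after restricting each mode to the alignment-mapped Cα
coordinates (the only well-defined common space) and re-orthonormalizing the
restricted set, ordered so the best-coupled modes are least perturbed.

Similarity of two k-mode sets uses the Hess subspace overlap

    gamma = (1/k) * sum_i sum_j (v_i^A . v_j^B)^2,

which is 1 for identical spans, 0 for orthogonal spans, is symmetric, and is
invariant to rotations of either basis within its own span.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ResidueMapping, calpha
from .qha import QHAResult

__all__ = [
    "RestrictedModeSet",
    "SubspaceOverlap",
    "restrict_modes",
    "subspace_overlap",
    "mode_fluctuation_correlation",
    "compare_rmsf_profiles",
    "interaction_profile_correlation",
]


class CompareError(ValueError):
    pass


@dataclasses.dataclass
class RestrictedModeSet:
    """k orthonormal modes restricted to M mapped Cα positions (3M components each)."""

    vectors: np.ndarray  # 3M x k, orthonormal columns
    provenance: str
    source_modes: tuple[int, ...]
    mapping_id: str = ""

    def __post_init__(self) -> None:
        M3, k = self.vectors.shape
        if M3 < k:
            raise CompareError(f"cannot hold {k} orthonormal modes in {M3} dimensions")
        gram = self.vectors.T @ self.vectors
        if np.abs(gram - np.eye(k)).max() > 1e-8:
            raise CompareError("restricted mode set is not orthonormal")

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


@dataclasses.dataclass(frozen=True)
class SubspaceOverlap:
    gamma: float
    k: int
    provenance: tuple[str, str]

    def __post_init__(self) -> None:
        if not -1e-9 <= self.gamma <= 1.0 + 1e-9:
            raise CompareError(f"gamma out of range: {self.gamma}")


def _ca_rows_by_residue(qha: QHAResult, atoms) -> dict[int, int]:
    """Map residue index -> row within the QHA selection for Cα atoms."""
    rows = {}
    for k, i in enumerate(qha.selection.array):
        a = atoms[i]
        if calpha(a):
            rows[a.residue_index] = k
    return rows


def restrict_modes(
    qha: QHAResult,
    top_modes,
    atoms,
    mapping: ResidueMapping,
    mapping_side: str = "a",
    provenance: str = "",
) -> RestrictedModeSet:
    """Restrict modes to mapped Cα coordinates and re-orthonormalize.

    ``mapping_side`` says whether this structure is the "a" or "b" side of the
    mapping.  Cα 3-vectors of each mode are extracted in alignment-column order,
    then orthonormalized by ordered Gram-Schmidt so earlier (better-coupled)
    modes are preserved exactly.
    """
    top_modes = list(top_modes)
    if not top_modes:
        raise CompareError("top_modes must be non-empty")
    res_indices = mapping.a_indices if mapping_side == "a" else mapping.b_indices
    if len(res_indices) == 0:
        raise CompareError("mapping is empty; nothing to compare")
    ca_rows = _ca_rows_by_residue(qha, atoms)
    missing = [int(r) for r in res_indices if r not in ca_rows]
    if missing:
        raise CompareError(f"mapped residues without Cα in the selection: {missing}")
    M = len(res_indices)
    if len(top_modes) > 3 * M:
        raise CompareError(f"{len(top_modes)} modes requested but only {3*M} mapped dimensions")
    rows = np.array([ca_rows[int(r)] for r in res_indices])
    cols = np.stack(
        [qha.mode_vectors(m)[rows].ravel() for m in top_modes], axis=1
    )
    # ordered Gram-Schmidt: mode precedence preserved
    Q = np.zeros_like(cols)
    for j in range(cols.shape[1]):
        v = cols[:, j].copy()
        for i in range(j):
            v -= (Q[:, i] @ v) * Q[:, i]
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise CompareError(f"mode {top_modes[j]} vanishes on the mapped residues")
        Q[:, j] = v / norm
    return RestrictedModeSet(
        vectors=Q,
        provenance=provenance,
        source_modes=tuple(top_modes),
        mapping_id=mapping.source,
    )


def subspace_overlap(set_a: RestrictedModeSet, set_b: RestrictedModeSet) -> SubspaceOverlap:
    """Hess subspace overlap gamma of two restricted mode sets (same mapping, same k)."""
    if set_a.vectors.shape != set_b.vectors.shape:
        raise CompareError(
            f"dimension mismatch: {set_a.vectors.shape} vs {set_b.vectors.shape}"
        )
    k = set_a.k
    inner = set_a.vectors.T @ set_b.vectors
    gamma = float((inner**2).sum() / k)
    return SubspaceOverlap(
        gamma=min(gamma, 1.0), k=k, provenance=(set_a.provenance, set_b.provenance)
    )


def _mode_magnitudes(qha: QHAResult, atoms, mode: int, res_indices) -> np.ndarray:
    ca_rows = _ca_rows_by_residue(qha, atoms)
    rows = np.array([ca_rows[int(r)] for r in res_indices])
    d = qha.mode_vectors(mode)[rows]
    return np.linalg.norm(d, axis=1)


def mode_fluctuation_correlation(
    qha_a: QHAResult,
    atoms_a,
    mode_a: int,
    qha_b: QHAResult,
    atoms_b,
    mode_b: int,
    mapping: ResidueMapping,
) -> float:
    """Pearson correlation of per-residue Cα displacement magnitudes of two modes.

    Magnitudes only, so the result is invariant to eigenvector sign flips.
    """
    if len(mapping) < 3:
        raise CompareError("need at least 3 mapped residues for a correlation")
    mag_a = _mode_magnitudes(qha_a, atoms_a, mode_a, mapping.a_indices)
    mag_b = _mode_magnitudes(qha_b, atoms_b, mode_b, mapping.b_indices)
    return float(np.corrcoef(mag_a, mag_b)[0, 1])


def flexible_regions(
    residue_indices: np.ndarray,
    normalized_profile: np.ndarray,
    threshold: float = 1.5,
    min_run: int = 3,
) -> list[tuple[int, int]]:
    """Contiguous residue runs with normalized RMSF above ``threshold`` (inclusive ends)."""
    order = np.argsort(residue_indices)
    res = np.asarray(residue_indices)[order]
    prof = np.asarray(normalized_profile)[order]
    regions: list[tuple[int, int]] = []
    start = prev = None
    for r, v in zip(res, prof):
        if v > threshold and (prev is None or r == prev + 1):
            if start is None:
                start = r
            prev = r
        elif v > threshold:
            if start is not None and prev - start + 1 >= min_run:
                regions.append((int(start), int(prev)))
            start = prev = r
        else:
            if start is not None and prev - start + 1 >= min_run:
                regions.append((int(start), int(prev)))
            start = prev = None
    if start is not None and prev - start + 1 >= min_run:
        regions.append((int(start), int(prev)))
    return regions


def compare_rmsf_profiles(
    residues_a: np.ndarray,
    profile_a: np.ndarray,
    residues_b: np.ndarray,
    profile_b: np.ndarray,
    mapping: ResidueMapping,
    threshold: float = 1.5,
    min_run: int = 3,
) -> tuple[float, pd.DataFrame]:
    """Pearson r of two normalized RMSF profiles over mapped residues, plus regions.

    The region table lists contiguous runs of normalized RMSF > ``threshold``
    (minimum length ``min_run``) in each profile — the flexible surface segments.
    """
    if len(mapping) == 0:
        raise CompareError("mapping is empty")
    pos_a = {int(r): i for i, r in enumerate(residues_a)}
    pos_b = {int(r): i for i, r in enumerate(residues_b)}
    rows = [
        (profile_a[pos_a[int(a)]], profile_b[pos_b[int(b)]])
        for a, b in mapping.pairs
        if int(a) in pos_a and int(b) in pos_b
    ]
    if len(rows) < 3:
        raise CompareError("fewer than 3 mapped residues with profile values")
    arr = np.asarray(rows)
    r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
    records = []
    for label, res, prof in (("A", residues_a, profile_a), ("B", residues_b, profile_b)):
        for start, end in flexible_regions(res, prof, threshold, min_run):
            records.append({"profile": label, "start": start, "end": end})
    return r, pd.DataFrame(records, columns=["profile", "start", "end"])


def interaction_profile_correlation(
    series_a: np.ndarray, series_b: np.ndarray
) -> float:
    """Pearson cc of two per-window interaction series along reaction progress.

    Series of unequal window counts are resampled by linear interpolation onto a
    common normalized progress grid (the finer of the two).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise CompareError("need at least 3 windows per series")
    if a.size != b.size:
        n = max(a.size, b.size)
        grid = np.linspace(0.0, 1.0, n)
        a = np.interp(grid, np.linspace(0.0, 1.0, a.size), a)
        b = np.interp(grid, np.linspace(0.0, 1.0, b.size), b)
    return float(np.corrcoef(a, b)[0, 1])
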