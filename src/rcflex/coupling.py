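"""Scoring quasi-harmonic modes by their coupling to the chemical step.

Two reaction-coordinate flavours are supported:

* ``dihedral`` — a 4-atom torsion ω (e.g. the amide bond of a cis/trans
  isomerization).  A mode's coupling is Δω, the change in ω between the two
  extreme ends of the mode's excursion, with the excursion taken from the range
  of the mode's projected amplitudes over the whole ensemble.  ω is tracked along
  a dense amplitude sweep and cumulatively unwrapped, so a 180° isomerization is
  not aliased by the ±180° branch cut.

* ``transfer`` — a donor/acceptor/transferred-atom triple (e.g. hydride
  transfer).  The coupling is the magnitude of the dot product between the
  transferred atom's displacement direction in the mode and the unit
  donor→acceptor vector at the mean structure, scaled by the mode's amplitude
  range, so dihedral and transfer couplings are both per-full-mode-excursion
  quantities.

Raw couplings over the slowest ``reference_count`` (default 50) modes are
normalized by their mean, and modes are ranked by descending normalized
coupling; the top-k (default 10) are the reaction-coupled modes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ConformationalEnsemble
from .qha import QHAResult, displace_along_mode, project_mode

__all__ = [
    "ReactionCoordinate",
    "CouplingTable",
    "dihedral_angle",
    "dihedral_coupling",
    "transfer_coupling",
    "mode_coupling",
    "couple_modes",
    "normalize_and_rank",
]


class CouplingError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ReactionCoordinate:
    """Either a 4-atom dihedral ω or a donor/acceptor/transferred-atom triple.

    Atom indices refer to positions within the analyzed (QHA) selection, i.e. rows
    of the mean-coordinate array.
    """

    kind: str  # "dihedral" | "transfer"
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("dihedral", "transfer"):
            raise CouplingError(f"unknown reaction-coordinate kind {self.kind!r}")
        expected = 4 if self.kind == "dihedral" else 3
        if len(self.atoms) != expected:
            raise CouplingError(f"{self.kind} coordinate needs {expected} atoms")
        if len(set(self.atoms)) != expected:
            raise CouplingError("reaction-coordinate atom indices must be distinct")

    @staticmethod
    def dihedral(a: int, b: int, c: int, d: int) -> "ReactionCoordinate":
        return ReactionCoordinate(kind="dihedral", atoms=(a, b, c, d))

    @staticmethod
    def transfer(donor: int, acceptor: int, transferred: int) -> "ReactionCoordinate":
        return ReactionCoordinate(kind="transfer", atoms=(donor, acceptor, transferred))


def dihedral_angle(coords: np.ndarray, four_atoms) -> float:
    """Signed IUPAC dihedral in (-180°, 180°] from an N x 3 coordinate array.

    trans (anti-periplanar) = 180°, cis = 0°; sign by the right-hand rule about
    the central bond.
    """
    i, j, k, l = four_atoms
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n2 = np.linalg.norm(b2)
    if n2 < 1e-12:
        raise CouplingError("central bond atoms coincide; dihedral undefined")
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    if np.linalg.norm(c12) < 1e-12 or np.linalg.norm(c23) < 1e-12:
        raise CouplingError("collinear atoms; dihedral undefined")
    x = np.dot(c12, c23)
    y = np.dot(np.cross(c12, c23), b2) / n2
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 for the (-180, 180] convention
    return float(ang if ang > -180.0 else 180.0)


def _check_rc_in_selection(rc: ReactionCoordinate, qha: QHAResult) -> None:
    n = qha.n_atoms
    for a in rc.atoms:
        if not 0 <= a < n:
            raise CouplingError(
                f"reaction-coordinate atom {a} is outside the analyzed selection (N={n})"
            )


def dihedral_coupling(
    qha: QHAResult,
    ensemble: ConformationalEnsemble,
    rc: ReactionCoordinate,
    mode_index: int,
    range_method: str = "minmax",
    percentile: float = 1.0,
    n_sweep: int = 21,
    amplitude_range: tuple[float, float] | None = None,
) -> float:
    """Δω (degrees): unwrapped dihedral change across the mode's amplitude range.

    The mode is realized at ``n_sweep`` (≥ 21) evenly spaced amplitudes between the
    extremes of its projection on the ensemble; ω is computed at each and
    cumulatively unwrapped before taking |ω(end) − ω(start)|.  ``range_method``
    is ``"minmax"`` (default) or ``"percentile"`` (uses ``percentile`` /
    ``100-percentile`` to guard against single-frame outliers).  A precomputed
    ``amplitude_range`` skips the projection.
    """
    if rc.kind != "dihedral":
        raise CouplingError("dihedral_coupling requires a dihedral reaction coordinate")
    _check_rc_in_selection(rc, qha)
    n_sweep = max(int(n_sweep), 21)
    if amplitude_range is None:
        proj = project_mode(qha, ensemble, mode_index)
        amplitude_range = proj.amplitude_range(
            percentile if range_method == "percentile" else None
        )
    lo, hi = amplitude_range
    amps = np.linspace(lo, hi, n_sweep)
    # only the four dihedral atoms matter; displace just those rows
    mean = qha.mean_coordinates[list(rc.atoms)]
    direction = qha.mode_displacements(mode_index)[list(rc.atoms)]
    angles = np.empty(n_sweep)
    for s, a in enumerate(amps):
        angles[s] = dihedral_angle(mean + a * direction, (0, 1, 2, 3))
    unwrapped = np.unwrap(angles, period=360.0)
    return float(abs(unwrapped[-1] - unwrapped[0]))


def transfer_coupling(
    qha: QHAResult,
    ensemble: ConformationalEnsemble,
    rc: ReactionCoordinate,
    mode_index: int,
    range_method: str = "minmax",
    percentile: float = 1.0,
    amplitude_range: tuple[float, float] | None = None,
) -> float:
    """|δ_H · r̂(C_D→C_A)| · A — transferred-atom displacement along the donor→acceptor axis.

    δ_H is the mode's Cartesian displacement direction at the transferred atom
    (v_H / sqrt(m_H)); r̂ is the unit donor→acceptor vector at the mean structure;
    A is the mode's amplitude range from projection, making the score the
    transferred atom's total excursion (Å) along the transfer axis over the mode.
    """
    if rc.kind != "transfer":
        raise CouplingError("transfer_coupling requires a transfer reaction coordinate")
    _check_rc_in_selection(rc, qha)
    donor, acceptor, hydride = rc.atoms
    r = qha.mean_coordinates[acceptor] - qha.mean_coordinates[donor]
    norm = np.linalg.norm(r)
    if norm < 1e-9:
        raise CouplingError("donor and acceptor coincide at the mean structure")
    r_hat = r / norm
    delta_h = qha.mode_displacements(mode_index)[hydride]
    if amplitude_range is None:
        proj = project_mode(qha, ensemble, mode_index)
        amplitude_range = proj.amplitude_range(
            percentile if range_method == "percentile" else None
        )
    lo, hi = amplitude_range
    return float(abs(np.dot(delta_h, r_hat)) * (hi - lo))


def mode_coupling(
    qha: QHAResult,
    ensemble: ConformationalEnsemble,
    rc: ReactionCoordinate,
    mode_index: int,
    **kwargs,
) -> float:
    if rc.kind == "dihedral":
        return dihedral_coupling(qha, ensemble, rc, mode_index, **kwargs)
    return transfer_coupling(qha, ensemble, rc, mode_index, **kwargs)


@dataclasses.dataclass
class CouplingTable:
    """Per-mode raw and normalized reaction-coupling scores with ranks.

    ``table`` columns: mode_index, lambda_rank (1 = slowest/largest eigenvalue),
    eigenvalue, raw_coupling, normalized_coupling, coupling_rank (1 = best).
    The normalization constant is the mean raw coupling over the slowest
    ``reference_count`` modes, so normalized couplings average to 1 over that set.
    """

    table: pd.DataFrame
    normalization_constant: float
    reference_count: int
    range_method: str = "minmax"

    def top_modes(self, k: int = 10) -> list[int]:
        """Mode indices of the k best-coupled modes, by ascending coupling rank."""
        ordered = self.table.sort_values("coupling_rank")
        return [int(m) for m in ordered["mode_index"].head(k)]

    @property
    def coupled_rank_of(self) -> dict[int, int]:
        return dict(zip(self.table["mode_index"].astype(int), self.table["coupling_rank"].astype(int)))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def normalize_and_rank(
    couplings: dict[int, float],
    eigenvalues: np.ndarray,
    reference_count: int = 50,
    range_method: str = "minmax",
) -> CouplingTable:
    """Normalize raw couplings by their mean over the slowest reference modes and rank.

    ``couplings`` maps mode index -> raw coupling for the slowest ``reference_count``
    modes.  All-zero couplings are an error ("no reaction-coupled flexibility
    detected").  Ranking is by descending normalized coupling, ties broken by mode
    index, and is independent of the input dict order.
    """
    if len(couplings) != reference_count:
        raise CouplingError(
            f"expected couplings for the slowest {reference_count} modes, got {len(couplings)}"
        )
    modes = sorted(couplings)
    raw = np.array([couplings[m] for m in modes], dtype=float)
    norm_const = raw.mean()
    if norm_const <= 0:
        raise CouplingError(
            "no reaction-coupled flexibility detected (all couplings are zero)"
        )
    normalized = raw / norm_const
    order = np.lexsort((modes, -normalized))
    ranks = np.empty(len(modes), dtype=int)
    ranks[order] = np.arange(1, len(modes) + 1)
    df = pd.DataFrame(
        {
            "mode_index": modes,
            "lambda_rank": [m + 1 for m in modes],
            "eigenvalue": [float(eigenvalues[m]) for m in modes],
            "raw_coupling": raw,
            "normalized_coupling": normalized,
            "coupling_rank": ranks,
        }
    )
    return CouplingTable(
        table=df,
        normalization_constant=float(norm_const),
        reference_count=reference_count,
        range_method=range_method,
    )


def couple_modes(
    qha: QHAResult,
    ensemble: ConformationalEnsemble,
    rc: ReactionCoordinate,
    reference_count: int = 50,
    range_method: str = "minmax",
    percentile: float = 1.0,
) -> CouplingTable:
    """Score the slowest ``reference_count`` modes against the reaction coordinate."""
    from .qha import project_modes

    reference_count = min(reference_count, qha.n_modes)
    amps = project_modes(qha, ensemble, range(reference_count))
    if range_method == "percentile":
        lows = np.percentile(amps, percentile, axis=0)
        highs = np.percentile(amps, 100.0 - percentile, axis=0)
    else:
        lows = amps.min(axis=0)
        highs = amps.max(axis=0)
    couplings = {
        n: mode_coupling(
            qha,
            ensemble,
            rc,
            n,
            range_method=range_method,
            percentile=percentile,
            amplitude_range=(float(lows[n]), float(highs[n])),
        )
        for n in range(reference_count)
    }
    return normalize_and_rank(
        couplings, qha.eigenvalues, reference_count=reference_count, range_method=range_method
    )
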