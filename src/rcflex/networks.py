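"""Dynamical cross-correlation, dynamic clustering, H-bond persistence and
coupled-motion networks.

The network picture: flexible surface regions identified from reaction-coupled
RMSF are linked to active-site (reaction-coordinate-contacting) residues through
chains of persistent interactions — hydrogen bonds, permanent bridges
(disulphides), and strongly correlated residue pairs.  Candidate networks are
paths in a residue graph whose edges carry occupancy / |correlation| weights.
"""

from __future__ import annotations

import dataclasses
import json
import math

import networkx as nx
import numpy as np
import scipy.cluster.hierarchy as sch
from sklearn.metrics import silhouette_score

from .io import AtomSelection, ConformationalEnsemble, calpha, select_atoms
from .qha import QHAResult

__all__ = [
    "DCCM",
    "ClusterAssignment",
    "HBond",
    "NetworkCandidate",
    "compute_dccm",
    "dynamic_cluster",
    "detect_hbonds",
    "distance_profile",
    "identify_network",
]


class NetworkError(ValueError):
    pass


@dataclasses.dataclass
class DCCM:
    """Residue x residue normalized Cα cross-correlation matrix."""

    matrix: np.ndarray
    residue_indices: np.ndarray
    zero_fluctuation_residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        M = self.matrix
        if np.abs(M - M.T).max() > 1e-9:
            raise NetworkError("DCCM must be symmetric")
        if np.abs(np.diag(M) - 1.0).max() > 1e-9:
            raise NetworkError("DCCM diagonal must be 1")
        if M.min() < -1 - 1e-9 or M.max() > 1 + 1e-9:
            raise NetworkError("DCCM entries must lie in [-1, 1]")


def compute_dccm(
    ensemble: ConformationalEnsemble, selection: AtomSelection | None = None
) -> DCCM:
    """C_ij = <Δr_i · Δr_j> / sqrt(<Δr_i²><Δr_j²>) over Cα displacement vectors.

    The ensemble must be superposed.  A residue with zero fluctuation gets zero
    off-diagonal entries (with its index recorded) rather than NaN.
    """
    if ensemble.n_frames < 2:
        raise NetworkError("at least 2 frames required")
    if selection is None:
        selection = select_atoms(ensemble, calpha, label="calpha")
    idx = selection.array
    res = np.array([ensemble.atoms[i].residue_index for i in idx])
    coords = ensemble.coordinates[:, idx, :]
    disp = coords - coords.mean(axis=0)
    # covariance of 3-vectors: sum over x,y,z components
    T = disp.shape[0]
    flat = disp.transpose(1, 0, 2)  # R x T x 3
    cov = np.einsum("itk,jtk->ij", flat, flat) / T
    var = np.diag(cov).copy()
    zero = var <= 1e-300
    safe = np.where(zero, 1.0, var)
    C = cov / np.sqrt(np.outer(safe, safe))
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    C = (C + C.T) / 2.0
    return DCCM(
        matrix=C,
        residue_indices=res,
        zero_fluctuation_residues=tuple(int(r) for r in res[zero]),
    )


@dataclasses.dataclass
class ClusterAssignment:
    """Per-residue dynamical-cluster labels (contiguous 0..k-1)."""

    labels: np.ndarray
    residue_indices: np.ndarray
    n_clusters: int
    silhouette: float
    linkage: str = "average"
    criterion: str = "silhouette over k_range"


def dynamic_cluster(
    ensemble: ConformationalEnsemble,
    qha: QHAResult,
    k_range=range(2, 11),
    top_coupled_modes=None,
    selection: AtomSelection | None = None,
) -> ClusterAssignment:
    """Cluster residues into regions of similar dynamics.

    Feature vector per residue: its DCCM row concatenated with its Cα displacement
    magnitude in each of the top coupled modes (default: the 10 slowest modes),
    standardized.  Agglomerative clustering with average linkage on the distance
    1 - Pearson(features); k is chosen from ``k_range`` by maximum silhouette.
    Deterministic given its inputs.
    """
    dccm = compute_dccm(ensemble, selection)
    R = dccm.matrix.shape[0]
    k_range = [int(k) for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > R - 1:
        raise NetworkError(f"k_range must lie within [2, {R - 1}]")
    if top_coupled_modes is None:
        top_coupled_modes = list(range(min(10, qha.n_modes)))
    # map DCCM residues to rows of the QHA selection (Cα only)
    qha_rows = {}
    for k, i in enumerate(qha.selection.array):
        a = ensemble.atoms[i]
        if calpha(a):
            qha_rows[a.residue_index] = k
    mags = np.zeros((R, len(top_coupled_modes)))
    for c, m in enumerate(top_coupled_modes):
        vec = qha.mode_vectors(m)
        for r, res in enumerate(dccm.residue_indices):
            if int(res) in qha_rows:
                mags[r, c] = np.linalg.norm(vec[qha_rows[int(res)]])
    features = np.hstack([dccm.matrix, mags])
    std = features.std(axis=0)
    std[std == 0] = 1.0
    features = (features - features.mean(axis=0)) / std

    corr = np.corrcoef(features)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(R, 1)]
    Z = sch.linkage(condensed, method="average")
    best = None
    for k in k_range:
        labels = sch.fcluster(Z, t=k, criterion="maxclust") - 1
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dist, labels, metric="precomputed")
        if best is None or score > best[0]:
            best = (score, k, labels)
    if best is None:
        raise NetworkError("clustering degenerate: no k produced >= 2 clusters")
    score, k, labels = best
    # relabel contiguously by first appearance
    remap = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return ClusterAssignment(
        labels=out,
        residue_indices=dccm.residue_indices,
        n_clusters=len(remap),
        silhouette=float(score),
    )


@dataclasses.dataclass(frozen=True)
class HBond:
    """A persistent donor-acceptor contact with its occupancy over frames."""

    donor: int  # atom index
    acceptor: int
    occupancy: float
    mean_distance: float
    hydrogen: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise NetworkError("occupancy must be in [0, 1]")


def detect_hbonds(
    ensemble: ConformationalEnsemble,
    donors,
    acceptors,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    occupancy_min: float = 0.5,
    hydrogens: dict[int, int] | None = None,
) -> list[HBond]:
    """Find donor-acceptor pairs satisfying geometry in >= ``occupancy_min`` of frames.

    Criteria: heavy-atom distance <= ``d_max`` Å and, when a hydrogen is supplied
    for the donor (``hydrogens`` maps donor -> H atom index), D-H-A angle >=
    ``angle_min`` degrees.  Without hydrogens the angle criterion is skipped
    (distance-only mode).  Occupancy is the fraction of frames passing.
    """
    donors = list(donors)
    acceptors = list(acceptors)
    if not donors or not acceptors:
        raise NetworkError("donor and acceptor lists must be non-empty")
    coords = ensemble.coordinates
    out: list[HBond] = []
    seen: set[tuple[int, int]] = set()
    for d in donors:
        for a in acceptors:
            if d == a:
                continue
            if hydrogens is None:
                # distance-only mode is symmetric; report each pair once
                key = (min(d, a), max(d, a))
                if key in seen:
                    continue
                seen.add(key)
            delta = coords[:, a] - coords[:, d]
            dist = np.linalg.norm(delta, axis=1)
            ok = dist <= d_max
            h = hydrogens.get(d) if hydrogens else None
            if h is not None:
                hd = coords[:, d] - coords[:, h]
                ha = coords[:, a] - coords[:, h]
                cosang = np.einsum("ij,ij->i", hd, ha) / (
                    np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                ok &= ang >= angle_min
            occ = float(ok.mean())
            if occ >= occupancy_min:
                out.append(
                    HBond(
                        donor=int(d),
                        acceptor=int(a),
                        occupancy=occ,
                        mean_distance=float(dist[ok].mean()),
                        hydrogen=h,
                    )
                )
    return out


def distance_profile(
    ensemble: ConformationalEnsemble, atom_pair: tuple[int, int]
):
    """Per-window mean ± sd of a pair distance, ordered by window (reaction progress).

    Returns a DataFrame with columns window, value (reaction-coordinate value when
    available), mean, sd, n_frames.
    """
    import pandas as pd

    if ensemble.window_labels is None:
        raise NetworkError(
            "ensemble has no window labels; use a two-state ensemble or label frames"
        )
    i, j = atom_pair
    dist = np.linalg.norm(
        ensemble.coordinates[:, i] - ensemble.coordinates[:, j], axis=1
    )
    rows = []
    for w in range(ensemble.n_windows):
        mask = ensemble.window_labels == w
        value = (
            float(ensemble.window_values[w])
            if ensemble.window_values is not None
            else float(w)
        )
        rows.append(
            {
                "window": w,
                "value": value,
                "mean": float(dist[mask].mean()),
                "sd": float(dist[mask].std()),
                "n_frames": int(mask.sum()),
            }
        )
    df = pd.DataFrame(rows).sort_values("value", ignore_index=True)
    return df


@dataclasses.dataclass
class NetworkCandidate:
    """An ordered chain of residue-pair links joining a flexible region to the active site."""

    residues: tuple[int, ...]
    links: tuple[dict, ...]  # each: {pair, evidence, score}
    score: float

    def to_report_line(self, atoms=None) -> str:
        def name(r):
            return f"R{r}"

        parts = []
        for link in self.links:
            i, j = link["pair"]
            parts.append(f"{name(i)}-{name(j)}[{link['evidence']}:{link['score']:.2f}]")
        return " -> ".join(parts) + f"  (path score {self.score:.3f})"


def identify_network(
    ensemble: ConformationalEnsemble,
    dccm: DCCM,
    hbonds: list[HBond],
    flexible_residues,
    active_atoms,
    dccm_threshold: float = 0.5,
    min_sequence_separation: int = 4,
    active_distance: float = 4.5,
    permanent_bridges=None,
    max_candidates: int = 5,
) -> tuple[list[NetworkCandidate], str]:
    """Rank candidate coupled-motion networks from flexible regions to the active site.

    The residue graph has edges for persistent hydrogen bonds (weight = occupancy),
    permanent bridges such as disulphides (weight 1.0), and high-|DCCM| pairs
    (|C| >= ``dccm_threshold`` with sequence separation >= ``min_sequence_separation``;
    weight = |C|).  Up to ``max_candidates`` highest-scoring simple paths from any
    flexible-region residue to any residue within ``active_distance`` Å of the
    active atoms (at the mean structure) are returned, ranked by the product of
    their edge weights (so padding a path with extra edges never helps).  An
    empty candidate list comes with a diagnostic string (a genuinely missing
    network is a result, not a failure).
    """
    atoms = ensemble.atoms
    flexible_residues = {int(r) for r in flexible_residues}
    if not flexible_residues:
        raise NetworkError("flexible region is empty; no network endpoints")

    mean_coords = ensemble.coordinates.mean(axis=0)
    # residues within reach of the active atoms
    active_set: set[int] = set()
    ca_pos = {}
    for a in atoms:
        if calpha(a):
            ca_pos[a.residue_index] = mean_coords[a.index]
    for r, pos in ca_pos.items():
        for aa in active_atoms:
            if np.linalg.norm(pos - mean_coords[aa]) <= active_distance:
                active_set.add(r)
                break
    if not active_set:
        return [], "no residues within reach of the active atoms"

    G = nx.Graph()
    res_of_atom = {a.index: a.residue_index for a in atoms}
    for hb in hbonds:
        ri, rj = res_of_atom[hb.donor], res_of_atom[hb.acceptor]
        if ri == rj:
            continue
        w = hb.occupancy
        if not G.has_edge(ri, rj) or G[ri][rj]["weight"] < w:
            G.add_edge(ri, rj, weight=w, evidence="hbond")
    if permanent_bridges:
        for ri, rj in permanent_bridges:
            G.add_edge(int(ri), int(rj), weight=1.0, evidence="bridge")
    R = dccm.matrix.shape[0]
    res = dccm.residue_indices
    for i in range(R):
        for j in range(i + 1, R):
            if abs(int(res[i]) - int(res[j])) < min_sequence_separation:
                continue
            c = abs(dccm.matrix[i, j])
            if c >= dccm_threshold:
                ri, rj = int(res[i]), int(res[j])
                if not G.has_edge(ri, rj) or G[ri][rj]["weight"] < c:
                    G.add_edge(ri, rj, weight=c, evidence="correlation")

    sources = sorted(flexible_residues & set(G.nodes))
    targets = sorted(active_set & set(G.nodes))
    if not sources or not targets:
        return [], "flexible region and/or active-site residues have no interactions"

    # k-best simple paths by product of edge weights (additive -log costs).
    # The product penalizes padding a path with extra strong edges, so the
    # tightest strong chain ranks first; mean*min is reported alongside.
    H = G.copy()
    for u, v, d in H.edges(data=True):
        d["cost"] = -math.log(max(d["weight"], 1e-12))
    raw_paths: list[tuple[float, list[int]]] = []
    seen = set()
    for s in sources:
        for t in targets:
            if s == t or not nx.has_path(H, s, t):
                continue
            gen = nx.shortest_simple_paths(H, s, t, weight="cost")
            for _, path in zip(range(5), gen):
                key = tuple(path)
                if key in seen:
                    continue
                seen.add(key)
                weights = [G[a][b]["weight"] for a, b in zip(path, path[1:])]
                score = float(np.prod(weights))
                raw_paths.append((score, path))
    if not raw_paths:
        return [], "no connected path from the flexible region to the active site"
    raw_paths.sort(key=lambda sp: (-sp[0], sp[1]))
    candidates = []
    for score, path in raw_paths[:max_candidates]:
        links = tuple(
            {
                "pair": (a, b),
                "evidence": G[a][b]["evidence"],
                "score": float(G[a][b]["weight"]),
            }
            for a, b in zip(path, path[1:])
        )
        candidates.append(
            NetworkCandidate(residues=tuple(path), links=links, score=score)
        )
    return candidates, ""


def network_to_json(candidates: list[NetworkCandidate]) -> str:
    return json.dumps(
        [
            {
                "residues": list(c.residues),
                "links": [
                    {"pair": list(l["pair"]), "evidence": l["evidence"], "score": l["score"]}
                    for l in c.links
                ],
                "score": c.score,
            }
            for c in candidates
        ],
        indent=1,
    )
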