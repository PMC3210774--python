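"""Conformational-ensemble I/O, atom selection, superposition and residue mapping.

The central container is :class:`ConformationalEnsemble`: a ``frames x atoms x 3``
coordinate array (Å) with per-atom metadata and optional per-frame reaction-pathway
window labels.  Two interchange formats are supported: multi-model PDB (the canonical
dialect, parsed with biotite) and a plain per-frame XYZ trajectory whose comment line
may carry a ``window=<id>`` tag.  Sequence alignments (aligned FASTA / Clustal) are
consumed to map residues across homologous structures; alignments are never computed
here.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Callable, Sequence
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Data.IUPACData import atom_weights

__all__ = [
    "AtomRecord",
    "ConformationalEnsemble",
    "AtomSelection",
    "ResidueMapping",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "select_atoms",
    "non_solvent",
    "calpha",
    "superpose",
    "kabsch_rotation",
    "read_alignment",
]

DEFAULT_SOLVENT_NAMES = frozenset({"HOH", "WAT", "SPC"})

#: Standard atomic weights (amu), keyed by capitalised element symbol.
_ATOM_WEIGHTS = {k.upper(): v for k, v in atom_weights.items()}


class EnsembleError(ValueError):
    """Raised for malformed ensembles or inconsistent trajectory files."""


def mass_of_element(element: str) -> float:
    try:
        return float(_ATOM_WEIGHTS[element.strip().upper()])
    except KeyError:
        raise EnsembleError(f"unknown element {element!r}: no standard atomic weight")


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """Metadata for one atom; ``mass`` in amu, indices 0-based."""

    index: int
    name: str
    element: str
    mass: float
    residue_index: int
    residue_name: str
    chain_id: str = "A"
    is_solvent: bool = False

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise EnsembleError(f"atom {self.index} ({self.name}): mass must be > 0")


@dataclasses.dataclass
class ConformationalEnsemble:
    """Frames x atoms x 3 Cartesian coordinates (Å) plus atom metadata.

    ``window_labels`` (optional) assigns each frame to a reaction-pathway window
    (a contiguous ``0..W-1`` integer set); ``window_values`` optionally carries the
    per-window reaction-coordinate value (degrees or Å).
    """

    atoms: list[AtomRecord]
    coordinates: np.ndarray
    window_labels: np.ndarray | None = None
    window_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise EnsembleError(
                f"coordinates must be frames x atoms x 3, got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != len(self.atoms):
            raise EnsembleError(
                f"{len(self.atoms)} atom records but coordinate array has "
                f"{self.coordinates.shape[1]} atoms per frame"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise EnsembleError("coordinates contain non-finite values")
        if [a.index for a in self.atoms] != list(range(len(self.atoms))):
            raise EnsembleError("atom indices must be 0-based and contiguous")
        if self.window_labels is not None:
            self.window_labels = np.asarray(self.window_labels, dtype=int)
            if self.window_labels.shape != (self.n_frames,):
                raise EnsembleError("window_labels must have one entry per frame")
            uniq = np.unique(self.window_labels)
            if not np.array_equal(uniq, np.arange(uniq.size)):
                raise EnsembleError("window labels must form a contiguous 0..W-1 set")
        if self.window_values is not None:
            self.window_values = np.asarray(self.window_values, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_windows(self) -> int:
        if self.window_labels is None:
            raise EnsembleError("ensemble has no window labels")
        return int(self.window_labels.max()) + 1

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def mean_coordinates(self, indices: np.ndarray | None = None) -> np.ndarray:
        coords = self.coordinates if indices is None else self.coordinates[:, indices]
        return coords.mean(axis=0)

    def with_coordinates(self, coordinates: np.ndarray) -> "ConformationalEnsemble":
        return ConformationalEnsemble(
            atoms=self.atoms,
            coordinates=coordinates,
            window_labels=self.window_labels,
            window_values=self.window_values,
        )


@dataclasses.dataclass(frozen=True)
class AtomSelection:
    """A sorted, duplicate-free subset of ensemble atom indices."""

    indices: tuple[int, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        idx = tuple(self.indices)
        if len(idx) == 0:
            raise EnsembleError(f"selection {self.label!r} matched no atoms")
        if list(idx) != sorted(set(idx)):
            raise EnsembleError("selection indices must be sorted and duplicate-free")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


def non_solvent(atom: AtomRecord) -> bool:
    return not atom.is_solvent


def calpha(atom: AtomRecord) -> bool:
    return atom.name == "CA" and not atom.is_solvent


def select_atoms(
    ensemble: ConformationalEnsemble,
    predicate: Callable[[AtomRecord], bool],
    label: str = "custom",
) -> AtomSelection:
    """Resolve a predicate over atom records into a deterministic sorted index list.

    Empty selections are an error: all downstream analysis is undefined on zero atoms.
    """
    indices = tuple(a.index for a in ensemble.atoms if predicate(a))
    return AtomSelection(indices=indices, label=label)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal least-squares rotation of centred ``mobile`` onto centred ``reference``.

    Returns ``(R, mobile_centroid, reference_centroid)`` with proper rotation ``R``
    (SVD construction, determinant corrected).
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, cm, cr


def _fit_frames(coords: np.ndarray, fit_idx: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` (fit on ``fit_idx``, transform all atoms)."""
    out = np.empty_like(coords)
    cr = reference.mean(axis=0)
    ref_c = reference - cr
    for t in range(coords.shape[0]):
        mob = coords[t, fit_idx]
        cm = mob.mean(axis=0)
        H = (mob - cm).T @ ref_c
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        U[:, 2] *= d
        R = U @ Vt
        out[t] = (coords[t] - cm) @ R + cr
    return out


def superpose(
    ensemble: ConformationalEnsemble,
    selection: AtomSelection,
    reference: str | int = "mean",
    tol: float = 1e-6,
    max_iter: int = 10,
) -> ConformationalEnsemble:
    """Remove rigid-body motion by least-squares superposition.

    Each frame is optimally rotated/translated onto the reference using the
    selection atoms only; all atoms are transformed.  With ``reference="mean"``
    the fit iterates (superpose -> recompute mean) until the mean structure moves
    by less than ``tol`` Å or ``max_iter`` iterations — the standard essential-
    dynamics convention.
    """
    fit_idx = selection.array
    if len(fit_idx) < 3:
        raise EnsembleError("superposition requires at least 3 selection atoms")
    sub = ensemble.coordinates[0, fit_idx]
    # collinearity check on the reference frame's selected atoms
    centred = sub - sub.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise EnsembleError("selection atoms are collinear; superposition is ill-posed")

    coords = ensemble.coordinates
    if reference == "mean":
        ref = coords[:, fit_idx].mean(axis=0)
        for _ in range(max_iter):
            coords = _fit_frames(coords, fit_idx, ref)
            new_ref = coords[:, fit_idx].mean(axis=0)
            shift = np.sqrt(((new_ref - ref) ** 2).sum(axis=1).mean())
            ref = new_ref
            if shift < tol:
                break
    else:
        ref = coords[int(reference), fit_idx]
        coords = _fit_frames(coords, fit_idx, ref)
    return ensemble.with_coordinates(coords)


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def _scan_pdb_models(lines: list[str]) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (whole file = one block if no MODEL)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not saw_model:
        counts = [current]
    elif in_model:  # MODEL without ENDMDL
        counts.append(current)
    return counts


def read_multimodel_pdb(
    path: str | Path,
    solvent_names: frozenset[str] | set[str] = DEFAULT_SOLVENT_NAMES,
) -> ConformationalEnsemble:
    """Read a multi-model PDB file into an ensemble (one frame per MODEL).

    Masses come from standard atomic weights by element; residues whose name is in
    ``solvent_names`` are flagged ``is_solvent`` (so the default QHA selection can
    exclude water, as the analysis requires).
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    lines = path.read_text().splitlines()
    counts = _scan_pdb_models(lines)
    if len(counts) == 0 or all(c == 0 for c in counts):
        raise EnsembleError(f"{path}: no ATOM/HETATM records found")
    if len(set(counts)) > 1:
        bad = next(i + 1 for i, c in enumerate(counts) if c != counts[0])
        raise EnsembleError(
            f"{path}: inconsistent atom count across MODELs "
            f"(model {bad} has {counts[bad - 1]} atoms, model 1 has {counts[0]})"
        )

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    arr0 = stack[0]
    atoms: list[AtomRecord] = []
    res_key_to_index: dict[tuple, int] = {}
    for i in range(stack.array_length()):
        res_key = (arr0.chain_id[i], int(arr0.res_id[i]), arr0.ins_code[i])
        if res_key not in res_key_to_index:
            res_key_to_index[res_key] = len(res_key_to_index)
        element = str(arr0.element[i])
        if not element:
            raise EnsembleError(
                f"{path}: atom {i} ({arr0.atom_name[i]}) has no element symbol"
            )
        res_name = str(arr0.res_name[i])
        atoms.append(
            AtomRecord(
                index=i,
                name=str(arr0.atom_name[i]),
                element=element,
                mass=mass_of_element(element),
                residue_index=res_key_to_index[res_key],
                residue_name=res_name,
                chain_id=str(arr0.chain_id[i]),
                is_solvent=res_name in solvent_names,
            )
        )
    return ConformationalEnsemble(atoms=atoms, coordinates=np.asarray(stack.coord, dtype=float))


def write_multimodel_pdb(path: str | Path, ensemble: ConformationalEnsemble) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ensemble.n_atoms
    arr = struc.AtomArray(n)
    for a in ensemble.atoms:
        arr.atom_name[a.index] = a.name
        arr.element[a.index] = a.element.upper()
        arr.res_id[a.index] = a.residue_index + 1
        arr.res_name[a.index] = a.residue_name
        arr.chain_id[a.index] = a.chain_id
        arr.hetero[a.index] = a.is_solvent
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = ensemble.coordinates.astype(np.float32)
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Plain XYZ trajectory + topology
# ---------------------------------------------------------------------------

def topology_to_json(atoms: Sequence[AtomRecord]) -> str:
    return json.dumps([dataclasses.asdict(a) for a in atoms], indent=1)


def topology_from_json(text: str) -> list[AtomRecord]:
    return [AtomRecord(**d) for d in json.loads(text)]


def write_xyz_trajectory(path: str | Path, ensemble: ConformationalEnsemble) -> None:
    """Write the plain per-frame trajectory format.

    Per frame: a line with the atom count N, a comment line (``window=<id>`` when
    window labels are present), then N lines ``name x y z``.
    """
    with open(path, "w") as fh:
        for t in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\n")
            if ensemble.window_labels is not None:
                fh.write(f"window={int(ensemble.window_labels[t])}\n")
            else:
                fh.write(f"frame {t}\n")
            for a, (x, y, z) in zip(ensemble.atoms, ensemble.coordinates[t]):
                fh.write(f"{a.name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_trajectory(
    path: str | Path, topology: Sequence[AtomRecord]
) -> ConformationalEnsemble:
    """Read the plain per-frame trajectory format; topology supplies atom metadata."""
    topology = list(topology)
    n = len(topology)
    frames: list[np.ndarray] = []
    labels: list[int] = []
    any_label = False
    with open(path) as fh:
        frame_no = 0
        while True:
            header = fh.readline()
            if not header.strip():
                break
            frame_no += 1
            try:
                count = int(header)
            except ValueError:
                raise EnsembleError(f"frame {frame_no}: malformed atom-count line {header!r}")
            if count != n:
                raise EnsembleError(
                    f"frame {frame_no}: file declares {count} atoms but topology has {n}"
                )
            comment = fh.readline().strip()
            if comment.startswith("window="):
                labels.append(int(comment.split("=", 1)[1]))
                any_label = True
            else:
                labels.append(-1)
            xyz = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise EnsembleError(f"frame {frame_no}: truncated atom line {i}")
                xyz[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append(xyz)
    if not frames:
        raise EnsembleError(f"{path}: no frames found")
    window_labels = np.asarray(labels) if any_label else None
    if window_labels is not None and np.any(window_labels < 0):
        raise EnsembleError("some frames carry window labels and some do not")
    return ConformationalEnsemble(
        atoms=topology, coordinates=np.stack(frames), window_labels=window_labels
    )


# ---------------------------------------------------------------------------
# Alignment-derived residue mappings
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ResidueMapping:
    """Ordered (residue_index_A, residue_index_B) pairs for non-gap alignment columns."""

    pairs: tuple[tuple[int, int], ...]
    source: str = ""

    def __post_init__(self) -> None:
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise EnsembleError("a residue index appears more than once in the mapping")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    def inverse(self) -> "ResidueMapping":
        return ResidueMapping(
            pairs=tuple((b, a) for a, b in self.pairs), source=self.source
        )

    @staticmethod
    def identity(n: int, source: str = "identity") -> "ResidueMapping":
        return ResidueMapping(pairs=tuple((i, i) for i in range(n)), source=source)


def mapping_from_aligned(seq_a: str, seq_b: str, source: str = "") -> ResidueMapping:
    """Build a mapping from two equal-length aligned sequences ('-' or '.' = gap)."""
    if len(seq_a) != len(seq_b):
        raise EnsembleError("aligned sequences have unequal lengths")
    pairs = []
    ia = ib = 0
    gaps = "-."
    for ca, cb in zip(seq_a, seq_b):
        if ca not in gaps and cb not in gaps:
            pairs.append((ia, ib))
        if ca not in gaps:
            ia += 1
        if cb not in gaps:
            ib += 1
    return ResidueMapping(pairs=tuple(pairs), source=source)


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], ResidueMapping]:
    """Read an aligned FASTA or Clustal file and derive per-pair residue mappings.

    ``pairs`` selects (id_A, id_B) sequence pairs; default is all ordered pairs of
    the first two sequences.  For each pair, the non-gap columns shared by both
    sequences are converted to 0-based per-sequence residue indices.
    """
    aln = AlignIO.read(str(path), "clustal" if format == "clustal" else "fasta")
    if len(aln) < 2:
        raise EnsembleError(f"{path}: alignment must contain at least 2 sequences")
    seqs = {rec.id: str(rec.seq) for rec in aln}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise EnsembleError(f"{path}: aligned sequences have unequal lengths")
    if pairs is None:
        ids = [rec.id for rec in aln]
        pairs = [(ids[0], ids[1])]
    out: dict[tuple[str, str], ResidueMapping] = {}
    for id_a, id_b in pairs:
        for sid in (id_a, id_b):
            if sid not in seqs:
                raise EnsembleError(f"{path}: sequence id {sid!r} not in alignment")
        out[(id_a, id_b)] = mapping_from_aligned(
            seqs[id_a], seqs[id_b], source=f"{Path(path).name}:{id_a}/{id_b}"
        )
    return out
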