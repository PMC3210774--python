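"""End-to-end orchestration: config loading/validation and composed analyses.

Every function here is a pure composition of module operations — no analysis
math of its own.  Outputs are deterministic for a fixed config + seed (reports
carry no timestamps), so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as eio
from . import qha as q
from .compare import compare_rmsf_profiles, flexible_regions, restrict_modes, subspace_overlap
from .coupling import ReactionCoordinate, couple_modes
from .networks import (
    compute_dccm,
    detect_hbonds,
    dynamic_cluster,
    identify_network,
    network_to_json,
)

logger = logging.getLogger("rcflex")


class ConfigError(ValueError):
    pass


class HBondParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d_max: float = 3.5
    angle_min: float = 120.0
    occupancy_min: float = 0.5


class AnalysisParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    top_k: int = 10
    reference_count: int = 50
    rmsf_threshold: float = 1.5
    rmsf_min_run: int = 3
    range_method: str = "minmax"
    percentile: float = 1.0
    dccm_threshold: float = 0.5
    min_sequence_separation: int = 4
    active_distance: float = 4.5
    cluster_k_range: tuple[int, int] = (2, 10)
    hbond: HBondParams = Field(default_factory=HBondParams)


class ReactionCoordinateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str
    atoms: list[int]


class InputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trajectory: str | None = None
    topology: str | None = None
    pdb: str | None = None


class RunConfig(BaseModel):
    """Validated pipeline configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")
    input: InputConfig
    selection: str = "non_solvent"
    reaction_coordinate: ReactionCoordinateConfig | None = None
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)
    output_dir: str = "rcflex_out"
    seed: int = 0
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except Exception as exc:  # malformed YAML
            raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        try:
            return RunConfig(**data)
        except Exception as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @staticmethod
    def json_schema() -> dict:
        return RunConfig.model_json_schema()


def load_ensemble(config: RunConfig) -> eio.ConformationalEnsemble:
    inp = config.input
    if inp.pdb:
        return eio.read_multimodel_pdb(inp.pdb)
    if inp.trajectory and inp.topology:
        topo = eio.topology_from_json(Path(inp.topology).read_text())
        return eio.read_xyz_trajectory(inp.trajectory, topo)
    raise ConfigError("input requires either 'pdb' or 'trajectory'+'topology'")


def resolve_selection(
    ensemble: eio.ConformationalEnsemble, name: str
) -> eio.AtomSelection:
    if name == "non_solvent":
        return eio.select_atoms(ensemble, eio.non_solvent, label="non_solvent")
    if name == "calpha":
        return eio.select_atoms(ensemble, eio.calpha, label="calpha")
    raise ConfigError(f"unknown selection {name!r} (use 'non_solvent' or 'calpha')")


def run_qha(config: RunConfig):
    """Load, superpose, build the fluctuation matrix and decompose."""
    ensemble = load_ensemble(config)
    selection = resolve_selection(ensemble, config.selection)
    logger.info("superposing %d frames on the iterated mean", ensemble.n_frames)
    ensemble = eio.superpose(ensemble, selection)
    F = q.build_fluctuation_matrix(ensemble, selection)
    result = q.qha_decompose(F)
    logger.info(
        "QHA: %d dof, slowest eigenvalue %.3f amu Å^2", F.n_dof, result.eigenvalues[0]
    )
    return ensemble, selection, result


def run_coupling(config: RunConfig):
    if config.reaction_coordinate is None:
        raise ConfigError("coupling analysis requires a reaction_coordinate block")
    ensemble, selection, result = run_qha(config)
    rc = ReactionCoordinate(
        kind=config.reaction_coordinate.kind,
        atoms=tuple(config.reaction_coordinate.atoms),
    )
    a = config.analysis
    table = couple_modes(
        result,
        ensemble,
        rc,
        reference_count=a.reference_count,
        range_method=a.range_method,
        percentile=a.percentile,
    )
    return ensemble, selection, result, table


def run_network(config: RunConfig):
    ensemble, selection, result, table = run_coupling(config)
    a = config.analysis
    top = table.top_modes(a.top_k)
    rmsf = q.rmsf_from_modes(result, top, ensemble)
    regions = flexible_regions(
        rmsf.residue_indices, rmsf.normalized, a.rmsf_threshold, a.rmsf_min_run
    )
    flexible = [r for start, end in regions for r in range(start, end + 1)]
    dccm = compute_dccm(ensemble)
    ca = [i for i in selection.array if eio.calpha(ensemble.atoms[i])]
    hb = a.hbond
    hbonds = detect_hbonds(
        ensemble, ca, ca, d_max=hb.d_max, angle_min=hb.angle_min,
        occupancy_min=hb.occupancy_min,
    )
    lo, hi = config.analysis.cluster_k_range
    clusters = dynamic_cluster(
        ensemble, result, k_range=range(lo, hi + 1), top_coupled_modes=top
    )
    rc_atoms = [selection.array[i] for i in config.reaction_coordinate.atoms]
    candidates, diagnostic = identify_network(
        ensemble,
        dccm,
        hbonds,
        flexible,
        rc_atoms,
        dccm_threshold=a.dccm_threshold,
        min_sequence_separation=a.min_sequence_separation,
        active_distance=a.active_distance,
    )
    return {
        "ensemble": ensemble,
        "selection": selection,
        "qha": result,
        "coupling": table,
        "rmsf": rmsf,
        "regions": regions,
        "dccm": dccm,
        "hbonds": hbonds,
        "clusters": clusters,
        "candidates": candidates,
        "diagnostic": diagnostic,
    }


def run_compare(config_a: RunConfig, config_b: RunConfig, alignment: str | None = None,
                alignment_format: str = "fasta", pair: tuple[str, str] | None = None):
    """Cross-structure comparison: top-k coupled-mode subspace overlap + RMSF correlation."""
    ens_a, sel_a, qha_a, tab_a = run_coupling(config_a)
    ens_b, sel_b, qha_b, tab_b = run_coupling(config_b)
    k = config_a.analysis.top_k
    top_a = tab_a.top_modes(k)
    top_b = tab_b.top_modes(k)
    if alignment:
        mappings = eio.read_alignment(alignment, alignment_format,
                                      pairs=[pair] if pair else None)
        mapping = next(iter(mappings.values()))
    else:
        n_res = min(
            len({ens_a.atoms[i].residue_index for i in sel_a.array if eio.calpha(ens_a.atoms[i])}),
            len({ens_b.atoms[i].residue_index for i in sel_b.array if eio.calpha(ens_b.atoms[i])}),
        )
        mapping = eio.ResidueMapping.identity(n_res)
    set_a = restrict_modes(qha_a, top_a, ens_a.atoms, mapping, "a", provenance="A")
    set_b = restrict_modes(qha_b, top_b, ens_b.atoms, mapping, "b", provenance="B")
    overlap = subspace_overlap(set_a, set_b)
    rmsf_a = q.rmsf_from_modes(qha_a, top_a, ens_a)
    rmsf_b = q.rmsf_from_modes(qha_b, top_b, ens_b)
    r, region_table = compare_rmsf_profiles(
        rmsf_a.residue_indices, rmsf_a.normalized,
        rmsf_b.residue_indices, rmsf_b.normalized,
        mapping,
        threshold=config_a.analysis.rmsf_threshold,
        min_run=config_a.analysis.rmsf_min_run,
    )
    return {"overlap": overlap, "rmsf_correlation": r, "regions": region_table,
            "top_modes": (top_a, top_b)}


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def build_report(config: RunConfig) -> dict:
    """Full deterministic run report (JSON-serializable, no timestamps)."""
    out = run_network(config)
    table: pd.DataFrame = out["coupling"].table
    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "selection": config.selection,
            "parameters": config.analysis.model_dump(),
        },
        "coupling_table": table.sort_values("coupling_rank").to_dict(orient="records"),
        "normalization_constant": out["coupling"].normalization_constant,
        "top_modes": out["coupling"].top_modes(config.analysis.top_k),
        "rmsf": {
            "residues": out["rmsf"].residue_indices.tolist(),
            "normalized": [round(float(v), 9) for v in out["rmsf"].normalized],
        },
        "flexible_regions": [list(r) for r in out["regions"]],
        "clusters": {
            "n_clusters": out["clusters"].n_clusters,
            "silhouette": round(float(out["clusters"].silhouette), 9),
            "labels": out["clusters"].labels.tolist(),
        },
        "hbonds": [
            {
                "donor": hb.donor,
                "acceptor": hb.acceptor,
                "occupancy": round(hb.occupancy, 6),
                "mean_distance": round(hb.mean_distance, 6),
            }
            for hb in out["hbonds"]
        ],
        "network_candidates": json.loads(network_to_json(out["candidates"])),
        "network_diagnostic": out["diagnostic"],
        "warnings": (
            [f"{out['rmsf'].omitted_residues} residues without Cα omitted from RMSF"]
            if out["rmsf"].omitted_residues
            else []
        ),
    }
    return report


def write_report(config: RunConfig, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = build_report(config)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    lines = ["reaction-coupled flexibility report", "=" * 36]
    lines.append(f"config hash: {report['provenance']['config_hash']}")
    lines.append(f"normalization constant: {report['normalization_constant']:.6g}")
    lines.append("top coupled modes (mode, lambda_rank, normalized coupling):")
    for rec in report["coupling_table"][: len(report["top_modes"])]:
        lines.append(
            f"  mode {rec['mode_index']:>3}  λ-rank {rec['lambda_rank']:>3}  "
            f"coupling {rec['normalized_coupling']:.3f}"
        )
    lines.append(f"flexible regions: {report['flexible_regions']}")
    lines.append(f"persistent hbonds: {len(report['hbonds'])}")
    if report["network_candidates"]:
        best = report["network_candidates"][0]
        lines.append(f"best network path: {best['residues']} (score {best['score']:.3f})")
    else:
        lines.append(f"no network found: {report['network_diagnostic']}")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return path
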