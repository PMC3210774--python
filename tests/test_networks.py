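import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rcflex.coupling import ReactionCoordinate, couple_modes
from rcflex.compare import flexible_regions
from rcflex.io import non_solvent, select_atoms, superpose
from rcflex.networks import (
    NetworkError,
    compute_dccm,
    detect_hbonds,
    distance_profile,
    dynamic_cluster,
    identify_network,
)
from rcflex.qha import build_fluctuation_matrix, qha_decompose, rmsf_from_modes
from rcflex.synthetic import SyntheticSpec, generate_pathway_ensemble, perturb_truncate_network

from conftest import make_ensemble


class TestDCCM:
    def test_unit_diagonal_symmetry_bounds(self, reduced_run):
        d = compute_dccm(reduced_run["ensemble"])
        C = d.matrix
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)
        np.testing.assert_allclose(C, C.T, atol=1e-9)
        assert C.min() >= -1 - 1e-9 and C.max() <= 1 + 1e-9

    def test_planted_comoving_pair(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=0.02, size=(500, 6, 3))
        drive = rng.normal(size=500)
        coords[:, 2, 0] += drive
        coords[:, 4, 0] += drive
        d = compute_dccm(make_ensemble(coords))
        assert d.matrix[2, 4] >= 0.99

    def test_anticorrelated_pair(self):
        rng = np.random.default_rng(1)
        coords = np.zeros((200, 4, 3))
        drive = rng.normal(size=200)
        coords[:, 0, 0] = drive
        coords[:, 3, 0] = -drive
        d = compute_dccm(make_ensemble(coords))
        assert d.matrix[0, 3] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_fluctuation_residue_zeroed_not_nan(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(50, 4, 3))
        coords[:, 1] = 0.0  # frozen residue
        d = compute_dccm(make_ensemble(coords))
        assert 1 in d.zero_fluctuation_residues
        assert d.matrix[1, 1] == 1.0
        assert np.all(np.isfinite(d.matrix))
        assert np.abs(np.delete(d.matrix[1], 1)).max() == 0.0


class TestHBonds:
    def _pair_ensemble(self, dists):
        T = len(dists)
        coords = np.zeros((T, 3, 3))
        coords[:, 1, 0] = dists
        coords[:, 2, 1] = 30.0  # far spectator
        return make_ensemble(coords)

    def test_constant_contact_full_occupancy(self):
        ens = self._pair_ensemble([2.9] * 50)
        bonds = detect_hbonds(ens, [0], [1])
        assert len(bonds) == 1
        assert bonds[0].occupancy == 1.0
        assert bonds[0].mean_distance == pytest.approx(2.9)

    def test_sub_threshold_occupancy_excluded(self):
        dists = [2.9] * 40 + [6.0] * 60
        ens = self._pair_ensemble(dists)
        assert detect_hbonds(ens, [0], [1], occupancy_min=0.5) == []

    def test_raising_occupancy_min_is_monotone(self):
        rng = np.random.default_rng(0)
        dists = np.where(rng.uniform(size=200) < 0.7, 2.9, 6.0)
        ens = self._pair_ensemble(dists)
        counts = [
            len(detect_hbonds(ens, [0], [1], occupancy_min=o))
            for o in (0.1, 0.5, 0.69, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_angle_criterion_with_hydrogen(self):
        # donor-H pointing away from acceptor: angle fails even at short distance
        coords = np.zeros((10, 3, 3))
        coords[:, 1, 0] = 3.0  # acceptor
        coords[:, 2, 0] = -1.0  # hydrogen on the far side
        ens = make_ensemble(coords)
        assert detect_hbonds(ens, [0], [1], hydrogens={0: 2}) == []
        coords[:, 2, 0] = 1.0  # hydrogen toward the acceptor
        ens2 = make_ensemble(coords)
        assert len(detect_hbonds(ens2, [0], [1], hydrogens={0: 2})) == 1

    def test_planted_chain_detected_exactly(self, reduced_run):
        truth = reduced_run["truth"]
        n_res = truth.spec["n_residues"]
        bonds = detect_hbonds(reduced_run["ensemble"], range(n_res), range(n_res))
        found = {tuple(sorted((b.donor, b.acceptor))) for b in bonds}
        planted = {tuple(sorted(p)) for p in truth.chain_pairs}
        monitor = {tuple(sorted(truth.monitor_pair))}
        assert planted <= found
        assert found - planted - monitor == set()

    def test_empty_lists_rejected(self, reduced_run):
        with pytest.raises(NetworkError):
            detect_hbonds(reduced_run["ensemble"], [], [0])


class TestDistanceProfile:
    def test_constant_distance_flat_profile(self):
        coords = np.zeros((40, 2, 3))
        coords[:, 1, 0] = 3.0
        ens = make_ensemble(coords, window_labels=np.repeat(np.arange(4), 10))
        df = distance_profile(ens, (0, 1))
        np.testing.assert_allclose(df["mean"], 3.0, atol=1e-12)
        np.testing.assert_allclose(df["sd"], 0.0, atol=1e-12)
        assert len(df) == 4

    def test_planted_linear_trend_slope(self):
        spec = SyntheticSpec(n_windows=37, frames_per_window=100,
                             plant_network=False, monitor_drift=2.0)
        ens, truth = generate_pathway_ensemble(spec, seed=5)
        df = distance_profile(ens, truth.monitor_pair)
        slope = np.polyfit(df["window"], df["mean"], 1)[0]
        assert slope == pytest.approx(truth.monitor_slope_per_window, rel=0.05)

    def test_missing_labels_rejected(self):
        ens = make_ensemble(np.zeros((5, 2, 3)))
        with pytest.raises(NetworkError, match="window labels"):
            distance_profile(ens, (0, 1))


class TestDynamicClustering:
    def test_two_anticorrelated_blocks(self):
        rng = np.random.default_rng(0)
        T, R = 400, 30
        drive = rng.normal(size=T)
        coords = rng.normal(scale=0.05, size=(T, R, 3))
        coords[:, :15, 0] += drive[:, None]
        coords[:, 15:, 0] -= drive[:, None]
        ens = make_ensemble(coords)
        sel = select_atoms(ens, non_solvent)
        q = qha_decompose(build_fluctuation_matrix(ens, sel))
        ca = dynamic_cluster(ens, q, k_range=range(2, 6))
        assert ca.n_clusters == 2
        truth = np.array([0] * 15 + [1] * 15)
        assert adjusted_rand_score(truth, ca.labels) == 1.0

    def test_six_block_partition_recovered(self):
        spec = SyntheticSpec(n_windows=10, frames_per_window=100, plant_network=False)
        ens, truth = generate_pathway_ensemble(spec, seed=3)
        sel = select_atoms(ens, non_solvent)
        sup = superpose(ens, sel)
        q = qha_decompose(build_fluctuation_matrix(sup, sel))
        ca = dynamic_cluster(sup, q, k_range=range(2, 11))
        mask = truth.block_labels >= 0
        assert adjusted_rand_score(truth.block_labels[mask], ca.labels[mask]) >= 0.9

    def test_label_equivariance_under_residue_permutation(self):
        rng = np.random.default_rng(1)
        T, R = 300, 20
        drive = rng.normal(size=(T, 2))
        coords = rng.normal(scale=0.05, size=(T, R, 3))
        coords[:, :10, 0] += drive[:, :1]
        coords[:, 10:, 1] += drive[:, 1:]
        ens = make_ensemble(coords)
        sel = select_atoms(ens, non_solvent)
        q = qha_decompose(build_fluctuation_matrix(ens, sel))
        ca = dynamic_cluster(ens, q, k_range=range(2, 5))
        perm = rng.permutation(R)
        ens_p = make_ensemble(coords[:, perm])
        sel_p = select_atoms(ens_p, non_solvent)
        q_p = qha_decompose(build_fluctuation_matrix(ens_p, sel_p))
        ca_p = dynamic_cluster(ens_p, q_p, k_range=range(2, 5))
        assert adjusted_rand_score(ca.labels[perm], ca_p.labels) == 1.0

    def test_bad_k_range_rejected(self, reduced_run):
        with pytest.raises(NetworkError):
            dynamic_cluster(reduced_run["ensemble"], reduced_run["qha"], k_range=[1])


def run_network(ens, truth):
    sel = select_atoms(ens, non_solvent)
    sup = superpose(ens, sel)
    q = qha_decompose(build_fluctuation_matrix(sup, sel))
    rc = ReactionCoordinate(
        kind=truth.reaction_coordinate["kind"],
        atoms=tuple(truth.reaction_coordinate["atoms"]),
    )
    table = couple_modes(q, sup, rc, reference_count=50)
    rmsf = rmsf_from_modes(q, table.top_modes(10), sup)
    regions = flexible_regions(rmsf.residue_indices, rmsf.normalized)
    flex = [r for a, b in regions for r in range(a, b + 1)]
    n_res = truth.spec["n_residues"]
    dccm = compute_dccm(sup)
    hbonds = detect_hbonds(sup, range(n_res), range(n_res))
    return identify_network(sup, dccm, hbonds, flex, list(truth.active_atoms))


class TestIdentifyNetwork:
    def test_planted_chain_is_top_candidate(self, reduced_spec):
        ens, truth = generate_pathway_ensemble(reduced_spec, seed=17)
        candidates, diag = run_network(ens, truth)
        assert candidates, diag
        assert candidates[0].residues == truth.chain_residues
        assert all(l["evidence"] == "hbond" for l in candidates[0].links)

    def test_truncated_middle_link_breaks_path(self, reduced_spec):
        ens, truth = generate_pathway_ensemble(reduced_spec, seed=17)
        t_ens, t_truth = perturb_truncate_network(ens, truth, 1)
        candidates, diag = run_network(t_ens, t_truth)
        assert candidates == []
        assert diag  # diagnostic emitted

    def test_empty_flexible_region_rejected(self, reduced_run):
        truth = reduced_run["truth"]
        n_res = truth.spec["n_residues"]
        dccm = compute_dccm(reduced_run["ensemble"])
        hbonds = detect_hbonds(reduced_run["ensemble"], range(n_res), range(n_res))
        with pytest.raises(NetworkError, match="flexible region is empty"):
            identify_network(
                reduced_run["ensemble"], dccm, hbonds, [], list(truth.active_atoms)
            )

    def test_permanent_bridges_join_paths(self, reduced_spec):
        # breaking a link but supplying it as a disulphide-style bridge restores the path
        ens, truth = generate_pathway_ensemble(reduced_spec, seed=17)
        t_ens, t_truth = perturb_truncate_network(ens, truth, 1)
        sel = select_atoms(t_ens, non_solvent)
        sup = superpose(t_ens, sel)
        q = qha_decompose(build_fluctuation_matrix(sup, sel))
        rc = ReactionCoordinate(kind="dihedral", atoms=tuple(t_truth.reaction_coordinate["atoms"]))
        table = couple_modes(q, sup, rc, reference_count=50)
        rmsf = rmsf_from_modes(q, table.top_modes(10), sup)
        regions = flexible_regions(rmsf.residue_indices, rmsf.normalized)
        flex = [r for a, b in regions for r in range(a, b + 1)]
        n_res = t_truth.spec["n_residues"]
        dccm = compute_dccm(sup)
        hbonds = detect_hbonds(sup, range(n_res), range(n_res))
        broken = t_truth.chain_pairs[1]
        candidates, _ = identify_network(
            sup, dccm, hbonds, flex, list(t_truth.active_atoms),
            permanent_bridges=[broken],
        )
        assert candidates and candidates[0].residues == t_truth.chain_residues
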