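import numpy as np
import pytest

from rcflex.coupling import (
    CouplingError,
    ReactionCoordinate,
    couple_modes,
    dihedral_angle,
    dihedral_coupling,
    mode_coupling,
    normalize_and_rank,
    transfer_coupling,
)
from rcflex.io import non_solvent, select_atoms, superpose
from rcflex.qha import build_fluctuation_matrix, qha_decompose
from rcflex.synthetic import SyntheticSpec, generate_pathway_ensemble

from conftest import make_ensemble


class TestDihedralAngle:
    def test_trans_is_180(self):
        coords = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], dtype=float)
        assert dihedral_angle(coords, (0, 1, 2, 3)) == pytest.approx(180.0)

    def test_cis_is_0(self):
        coords = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        assert dihedral_angle(coords, (0, 1, 2, 3)) == pytest.approx(0.0)

    def test_right_handed_plus_90(self):
        coords = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1]], dtype=float)
        assert dihedral_angle(coords, (0, 1, 2, 3)) == pytest.approx(90.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_vector_oracle(self, seed):
        # oracle: angle between plane normals with sign from the central bond
        rng = np.random.default_rng(seed)
        c = rng.normal(size=(4, 3))
        b1, b2, b3 = c[1] - c[0], c[2] - c[1], c[3] - c[2]
        n1 = np.cross(b1, b2) / np.linalg.norm(np.cross(b1, b2))
        n2 = np.cross(b2, b3) / np.linalg.norm(np.cross(b2, b3))
        cosang = np.clip(n1 @ n2, -1, 1)
        sign = np.sign(np.cross(n1, n2) @ b2)
        oracle = np.degrees(np.arccos(cosang)) * (sign if sign != 0 else 1.0)
        got = dihedral_angle(c, (0, 1, 2, 3))
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_collinear_rejected(self):
        c = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], dtype=float)
        with pytest.raises(CouplingError, match="collinear"):
            dihedral_angle(c, (0, 1, 2, 3))


class TestReactionCoordinate:
    def test_kinds_and_arity(self):
        ReactionCoordinate.dihedral(0, 1, 2, 3)
        ReactionCoordinate.transfer(0, 1, 2)
        with pytest.raises(CouplingError):
            ReactionCoordinate(kind="dihedral", atoms=(0, 1, 2))
        with pytest.raises(CouplingError):
            ReactionCoordinate(kind="transfer", atoms=(0, 1, 1))
        with pytest.raises(CouplingError):
            ReactionCoordinate(kind="bend", atoms=(0, 1, 2))


@pytest.fixture(scope="module")
def coupled_system(reduced_run):
    run = reduced_run
    rc = ReactionCoordinate(
        kind="dihedral", atoms=tuple(run["truth"].reaction_coordinate["atoms"])
    )
    table = couple_modes(run["qha"], run["ensemble"], rc, reference_count=50)
    return run, rc, table


class TestDihedralCoupling:
    def test_zero_mode_components_give_zero(self, reduced_run):
        q = reduced_run["qha"]
        rc = ReactionCoordinate(
            kind="dihedral", atoms=tuple(reduced_run["truth"].reaction_coordinate["atoms"])
        )
        # a mode with no weight on the dihedral atoms
        v = q.eigenvectors[:, 0].copy()
        for a in rc.atoms:
            v[3 * a : 3 * a + 3] = 0.0
        v /= np.linalg.norm(v)
        q2 = q.__class__(
            eigenvalues=q.eigenvalues,
            eigenvectors=np.where(
                np.arange(q.n_modes)[None] == 0, v[:, None], q.eigenvectors
            ),
            frequencies=q.frequencies,
            mean_coordinates=q.mean_coordinates,
            masses=q.masses,
            selection=q.selection,
        )
        dw = dihedral_coupling(q2, reduced_run["ensemble"], rc, 0)
        assert dw == pytest.approx(0.0, abs=1e-9)

    def test_planted_sweep_near_180(self, coupled_system):
        run, rc, table = coupled_system
        planted = run["truth"].carrier_vectors[:, run["truth"].coupled_mode_index]
        mode = int(np.argmax((run["qha"].eigenvectors.T @ planted) ** 2))
        dw = dihedral_coupling(run["qha"], run["ensemble"], rc, mode)
        assert dw == pytest.approx(run["truth"].planted_delta_omega, rel=0.05)

    def test_sign_flip_invariance(self, coupled_system):
        run, rc, _ = coupled_system
        q = run["qha"]
        dw1 = dihedral_coupling(q, run["ensemble"], rc, 1)
        q.eigenvectors[:, 1] *= -1
        try:
            dw2 = dihedral_coupling(q, run["ensemble"], rc, 1)
        finally:
            q.eigenvectors[:, 1] *= -1
        assert dw2 == pytest.approx(dw1, abs=1e-9)

    def test_outside_selection_rejected(self, coupled_system):
        run, _, _ = coupled_system
        rc = ReactionCoordinate(kind="dihedral", atoms=(0, 1, 2, 10_000))
        with pytest.raises(CouplingError, match="outside"):
            dihedral_coupling(run["qha"], run["ensemble"], rc, 0)


class TestTransferCoupling:
    def _simple_system(self, h_direction):
        # donor at origin, acceptor on +x, hydride between; one mode moving H
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=0.01, size=(20, 4, 3))
        coords[:, :2] = 0.0  # donor/acceptor fixed so the mean axis is exact
        coords[:, 1, 0] += 3.5
        coords[:, 2, 0] += 1.2
        coords[:, 3, 1] += 8.0
        ens = make_ensemble(coords)
        sel = select_atoms(ens, non_solvent)
        q = qha_decompose(build_fluctuation_matrix(ens, sel))
        v = np.zeros(12)
        v[6:9] = h_direction / np.linalg.norm(h_direction)
        q.eigenvectors[:, 0] = v
        return ens, q

    def test_perpendicular_displacement_scores_zero(self):
        ens, q = self._simple_system(np.array([0.0, 1.0, 0.0]))
        rc = ReactionCoordinate.transfer(0, 1, 2)
        assert transfer_coupling(q, ens, rc, 0) == pytest.approx(0.0, abs=1e-9)

    def test_parallel_displacement_matches_definition(self):
        ens, q = self._simple_system(np.array([1.0, 0.0, 0.0]))
        rc = ReactionCoordinate.transfer(0, 1, 2)
        from rcflex.qha import project_mode

        proj = project_mode(q, ens, 0)
        lo, hi = proj.amplitude_range()
        expected = abs(q.mode_displacements(0)[2, 0]) * (hi - lo)
        assert transfer_coupling(q, ens, rc, 0) == pytest.approx(expected, rel=1e-9)

    def test_planted_transfer_mode_dominates_noise(self):
        spec = SyntheticSpec(n_windows=10, frames_per_window=100, coupling="transfer")
        ens, truth = generate_pathway_ensemble(spec, seed=11)
        sel = select_atoms(ens, non_solvent)
        sup = superpose(ens, sel)
        q = qha_decompose(build_fluctuation_matrix(sup, sel))
        rc = ReactionCoordinate(kind="transfer", atoms=tuple(truth.reaction_coordinate["atoms"]))
        table = couple_modes(q, sup, rc, reference_count=50)
        t = table.table.sort_values("coupling_rank")
        top = t.iloc[0]
        planted = truth.carrier_vectors[:, truth.coupled_mode_index]
        assert int(top.mode_index) == int(np.argmax((q.eigenvectors.T @ planted) ** 2))
        noise = t[t.mode_index >= 12].raw_coupling.max()  # beyond all planted carriers
        assert top.raw_coupling >= 3 * noise

    def test_coincident_donor_acceptor_rejected(self):
        ens, q = self._simple_system(np.array([1.0, 0.0, 0.0]))
        q.mean_coordinates[1] = q.mean_coordinates[0]
        rc = ReactionCoordinate.transfer(0, 1, 2)
        with pytest.raises(CouplingError, match="coincide"):
            transfer_coupling(q, ens, rc, 0)


class TestNormalizeAndRank:
    def test_equal_couplings_normalize_to_one(self):
        c = {m: 0.7 for m in range(50)}
        table = normalize_and_rank(c, np.linspace(50, 1, 50))
        np.testing.assert_allclose(table.table["normalized_coupling"], 1.0)

    def test_single_dominant_mode_value(self):
        c = {m: (5.0 if m == 0 else 1.0) for m in range(50)}
        table = normalize_and_rank(c, np.linspace(50, 1, 50))
        top = table.table.sort_values("coupling_rank").iloc[0]
        assert top.normalized_coupling == pytest.approx(5.0 / 1.08, rel=1e-9)
        assert int(top.mode_index) == 0

    def test_rank_map_is_order_independent(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.1, 3.0, size=50)
        eigs = np.linspace(50, 1, 50)
        c1 = {m: vals[m] for m in range(50)}
        c2 = dict(reversed(list(c1.items())))
        t1 = normalize_and_rank(c1, eigs)
        t2 = normalize_and_rank(c2, eigs)
        assert t1.coupled_rank_of == t2.coupled_rank_of

    def test_normalized_mean_is_exactly_one(self):
        rng = np.random.default_rng(1)
        c = {m: rng.uniform(0, 2) for m in range(50)}
        table = normalize_and_rank(c, np.linspace(50, 1, 50))
        assert table.table["normalized_coupling"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_is_flagged_error(self):
        with pytest.raises(CouplingError, match="no reaction-coupled flexibility"):
            normalize_and_rank({m: 0.0 for m in range(50)}, np.linspace(50, 1, 50))


class TestPlantedRanking:
    def test_planted_mode_is_coupling_rank_one_but_not_eigen_rank_one(self, coupled_system):
        run, rc, table = coupled_system
        truth = run["truth"]
        planted = truth.carrier_vectors[:, truth.coupled_mode_index]
        best = int(np.argmax((run["qha"].eigenvectors.T @ planted) ** 2))
        top = table.top_modes(1)[0]
        assert top == best
        # the coupled mode is the 3rd-largest-variance mode, not the slowest
        row = table.table[table.table.mode_index == top].iloc[0]
        assert int(row.lambda_rank) == 3
        assert int(row.coupling_rank) == 1
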