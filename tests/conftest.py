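import numpy as np
import pytest

from rcflex.io import AtomRecord, ConformationalEnsemble, select_atoms, non_solvent, superpose
from rcflex.qha import build_fluctuation_matrix, qha_decompose
from rcflex.synthetic import SyntheticSpec, generate_pathway_ensemble

CA_MASS = 12.011


def make_atoms(n, name="CA", element="C", mass=CA_MASS, solvent_from=None):
    """n single-atom residues; atoms at index >= solvent_from are flagged solvent."""
    return [
        AtomRecord(
            index=i,
            name=name,
            element=element,
            mass=mass,
            residue_index=i,
            residue_name="HOH" if solvent_from is not None and i >= solvent_from else "GLY",
            chain_id="A",
            is_solvent=solvent_from is not None and i >= solvent_from,
        )
        for i in range(n)
    ]


def make_ensemble(coords, atoms=None, **kw):
    coords = np.asarray(coords, dtype=float)
    if atoms is None:
        atoms = make_atoms(coords.shape[1])
    return ConformationalEnsemble(atoms=atoms, coordinates=coords, **kw)


@pytest.fixture(scope="session")
def reduced_spec():
    """Reduced-size pathway generator settings used throughout the suite."""
    return SyntheticSpec(n_windows=10, frames_per_window=100)


@pytest.fixture(scope="session")
def reduced_run(reduced_spec):
    """One generated + superposed + decomposed reduced-size pathway ensemble."""
    ens, truth = generate_pathway_ensemble(reduced_spec, seed=42)
    sel = select_atoms(ens, non_solvent, label="non_solvent")
    sup = superpose(ens, sel)
    qha = qha_decompose(build_fluctuation_matrix(sup, sel))
    return {"raw": ens, "ensemble": sup, "selection": sel, "qha": qha, "truth": truth}
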