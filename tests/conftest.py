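import numpy as np
import pytest

from chesel.pdbqt_io import BindingMode, DockedLigand, LigandAtom


def make_ligand(
    ligand_id="lig",
    energies=(-9.0, -8.5, -8.0),
    rmsds=None,
    atoms=None,
    torsdof=None,
):
    """Hand-build a DockedLigand from an energy list."""
    modes = []
    for i, e in enumerate(energies):
        if i == 0:
            lb = ub = 0.0
        elif rmsds is not None:
            lb, ub = rmsds[i]
        else:
            lb, ub = 1.0 + 0.1 * i, 2.0 + 0.2 * i
        modes.append(BindingMode(rank=i + 1, affinity=float(e), rmsd_lb=lb, rmsd_ub=ub))
    return DockedLigand(
        ligand_id=ligand_id, modes=modes,
        mode1_atoms=list(atoms) if atoms else [], torsdof=torsdof,
    )


def make_atom(serial, element, xyz, charge=0.0, ad_type=None):
    default_types = {"C": "C", "N": "N", "O": "OA", "H": "HD"}
    return LigandAtom(
        serial=serial, name=f"{element}{serial}", element=element,
        x=float(xyz[0]), y=float(xyz[1]), z=float(xyz[2]),
        partial_charge=charge, ad_type=ad_type or default_types.get(element, "C"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240516)
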