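import numpy as np
import pytest

from edgepore.builder import Strand
from edgepore.defects import build_slice_grid
from edgepore.roles import Role, Subrole
from edgepore.synth import SyntheticSpec, make_bilayer_system, make_ideal_sheet
from edgepore.trajectory import AtomRecord, FrameSnapshot, Topology


@pytest.fixture(scope="session")
def grid():
    return build_slice_grid(2.8, 0.1)


@pytest.fixture(scope="session")
def bilayer():
    return make_bilayer_system(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def tetramer_sheet():
    return make_ideal_sheet(6)


def atom(
    i,
    name="OW",
    resname="SOL",
    resnum=1,
    chain="W",
    role=Role.WATER,
    subrole=Subrole.WATER_O,
    element=None,
):
    return AtomRecord(
        atom_index=i,
        name=name,
        element=element or name[0],
        residue_number=resnum,
        residue_name=resname,
        chain_id=chain,
        role=role,
        subrole=subrole,
    )


def water_topology(n):
    return Topology([atom(i, resnum=i + 1) for i in range(n)])


def frame(coords, box=(5.0, 5.0, 9.0), time=0.0):
    return FrameSnapshot(np.asarray(coords, dtype=float), np.asarray(box), time)


@pytest.fixture
def make_water_frame():
    def _make(coords, box=(5.0, 5.0, 9.0)):
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return water_topology(len(coords)), frame(coords, box)

    return _make
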