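import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgepore.constants import GAS_CONSTANT_KJ_PER_MOL_K as R
from edgepore.density import AxialProfile
from edgepore.ions import (
    CrossingEvent,
    crossing_events,
    permeation_free_energy,
    shell_composition,
)
from edgepore.roles import Role, Subrole
from edgepore.synth import (
    IonPath,
    SyntheticSpec,
    make_bilayer_system,
    make_permeation_series,
)
from edgepore.trajectory import Topology, trajectory_from_frames

from .conftest import atom, frame


def ion_with_shell(shell_atoms):
    """A single K+ at the origin plus explicit shell atoms at given positions."""
    records = [atom(0, name="K", resname="K", resnum=1, chain="I", role=Role.ION, subrole=Subrole.K)]
    coords = [[0.0, 0.0, 0.0]]
    for i, (name, resname, resnum, role, subrole, element, pos) in enumerate(shell_atoms, start=1):
        records.append(
            atom(i, name=name, resname=resname, resnum=resnum, chain="Z", role=role, subrole=subrole, element=element)
        )
        coords.append(pos)
    return Topology(records), frame(coords)


def water_at(pos):
    return ("OW", "SOL", 100, Role.WATER, Subrole.WATER_O, "O", pos)


def q15_o_at(pos):
    return ("OE1", "GLN", 15, Role.PROTEIN, Subrole.SIDECHAIN, "O", pos)


class TestShellComposition:
    def test_six_waters_only(self):
        shell = [water_at([0.30, 0.0, 0.0]), water_at([-0.30, 0.0, 0.0]),
                 water_at([0.0, 0.30, 0.0]), water_at([0.0, -0.30, 0.0]),
                 water_at([0.0, 0.0, 0.30]), water_at([0.0, 0.0, -0.30])]
        top, fr = ion_with_shell(shell)
        comp = shell_composition(top, fr, 0)
        assert comp.counts["water_O"] == 6
        assert comp.counts["protein_total"] == 0
        assert comp.counts["lipid_O"] == 0

    def test_q15_sidechain_oxygen_counted(self):
        top, fr = ion_with_shell([water_at([0.3, 0.0, 0.0]), q15_o_at([0.0, 0.34, 0.0])])
        comp = shell_composition(top, fr, 0)
        assert comp.counts["protein_total"] == 1
        assert comp.counts["Q15_sidechain"] == 1

    def test_partner_beyond_cutoff_excluded(self):
        top, fr = ion_with_shell([water_at([0.36, 0.0, 0.0])])
        comp = shell_composition(top, fr, 0)
        assert comp.counts["water_O"] == 0

    def test_index_out_of_range(self):
        top, fr = ion_with_shell([])
        with pytest.raises(IndexError):
            shell_composition(top, fr, 5)

    def test_permutation_invariance(self):
        shell = [water_at([0.3, 0.0, 0.0]), water_at([0.0, 0.3, 0.0]), q15_o_at([0.0, 0.0, 0.3])]
        top1, fr1 = ion_with_shell(shell)
        top2, fr2 = ion_with_shell(shell[::-1])
        c1 = shell_composition(top1, fr1, 0)
        c2 = shell_composition(top2, fr2, 0)
        assert c1.counts == c2.counts


@pytest.fixture(scope="module")
def corridor_system():
    return make_bilayer_system(
        SyntheticSpec(seed=9, corridor_xy=(1.1, 1.1), corridor_radius=0.6)
    )


class TestCoordinationProfile:
    def test_planted_shell_recovered_at_center(self, corridor_system):
        from edgepore.ions import coordination_profile

        traj = make_permeation_series(
            corridor_system,
            [IonPath(xy=(1.1, 1.1), z_path=np.full(10, 0.03), shell={"water_O": 4, "Q15_sidechain": 2})],
        )
        prof = coordination_profile(traj)
        b = np.flatnonzero(np.isclose(prof["water_O"].bin_centers, 0.05))[0]
        assert prof["water_O"].values[b] == 4.0
        assert prof["Q15_sidechain"].values[b] == 2.0

    def test_no_ions_in_slab_bins_missing(self, corridor_system):
        from edgepore.ions import coordination_profile

        traj = make_permeation_series(
            corridor_system, [IonPath(xy=(1.1, 1.1), z_path=np.full(3, 3.5))]
        )
        # restrict to the scripted ion so the base bath ions do not contribute
        scripted = np.array([traj.topology.n_atoms - 1])
        assert traj.topology.subrole[scripted[0]] == "K"
        prof = coordination_profile(traj, scripted)
        interior = np.abs(prof["water_O"].bin_centers) < 1.0
        assert np.all(np.isnan(prof["water_O"].values[interior]))

    def test_two_replicates_mean_and_sem(self, corridor_system):
        from edgepore.ions import coordination_profile

        t4 = make_permeation_series(
            corridor_system, [IonPath(xy=(1.1, 1.1), z_path=np.full(5, 0.03), shell={"water_O": 4})]
        )
        t6 = make_permeation_series(
            corridor_system, [IonPath(xy=(1.1, 1.1), z_path=np.full(5, 0.03), shell={"water_O": 6})]
        )
        # same topology shape is required; rebuild replicate 2 with 6 waters but
        # compare via separate profiles instead
        p4 = coordination_profile(t4, np.array([t4.topology.n_atoms - 5]))
        p6 = coordination_profile(t6, np.array([t6.topology.n_atoms - 7]))
        b = np.flatnonzero(np.isclose(p4["water_O"].bin_centers, 0.05))[0]
        assert p4["water_O"].values[b] == 4.0
        assert p6["water_O"].values[b] == 6.0


class TestCrossingEvents:
    def _traj(self, z_paths, system):
        plan = [IonPath(xy=(1.1, 1.1), z_path=np.asarray(z)) for z in z_paths]
        return make_permeation_series(system, plan)

    def _scripted_ion_indices(self, traj, n_paths):
        base = traj.topology.n_atoms - n_paths
        return np.arange(base, traj.topology.n_atoms)

    def test_monotone_descent_one_down_event(self, corridor_system):
        traj = self._traj([np.linspace(3.0, -3.0, 31)], corridor_system)
        ions = self._scripted_ion_indices(traj, 1)
        ev = crossing_events(traj, ions)
        assert len(ev) == 1 and ev[0].direction == "down"

    def test_dip_and_return_no_event(self, corridor_system):
        z = np.concatenate([np.linspace(3.0, 0.0, 16), np.linspace(0.2, 3.0, 15)])
        traj = self._traj([z], corridor_system)
        ev = crossing_events(traj, self._scripted_ion_indices(traj, 1))
        assert ev == []

    def test_two_traversals_two_events(self, corridor_system):
        z = np.concatenate([np.linspace(3.0, -3.0, 25), np.linspace(-3.0, 3.0, 25)])
        traj = self._traj([z], corridor_system)
        ev = crossing_events(traj, self._scripted_ion_indices(traj, 1))
        assert len(ev) == 2
        assert [e.direction for e in ev] == ["down", "up"]

    def test_time_reversal_swaps_direction(self, corridor_system):
        z = np.linspace(3.0, -3.0, 31)
        fwd = self._traj([z], corridor_system)
        rev = self._traj([z[::-1]], corridor_system)
        e1 = crossing_events(fwd, self._scripted_ion_indices(fwd, 1))
        e2 = crossing_events(rev, self._scripted_ion_indices(rev, 1))
        assert len(e1) == len(e2) == 1
        assert {e1[0].direction, e2[0].direction} == {"down", "up"}

    def test_event_invariant_exit_after_entry(self):
        with pytest.raises(ValueError):
            CrossingEvent(0, 0, entry_time=100.0, exit_time=50.0, direction="down")


class TestPermeationFreeEnergy:
    def _profile(self, rho):
        z = np.arange(len(rho)) * 0.1 - (len(rho) - 1) * 0.05
        return AxialProfile(z, np.asarray(rho, float), np.zeros(len(rho)))

    def test_uniform_density_zero_everywhere(self):
        prof = self._profile(np.ones(70))
        pmf = permeation_free_energy(prof)
        assert np.allclose(pmf.values, 0.0, atol=1e-12)

    def test_half_bulk_density_rt_ln2(self):
        rho = np.ones(70)
        mid = 35
        rho[mid] = 0.5
        pmf = permeation_free_energy(self._profile(rho), temperature=300.0)
        assert pmf.values[mid] == pytest.approx(R * 300.0 * np.log(2.0), abs=1e-12)
        assert pmf.values[mid] == pytest.approx(1.7289, abs=1e-4)

    def test_empty_interior_bin_flagged(self):
        rho = np.ones(70)
        rho[35] = 0.0
        pmf = permeation_free_energy(self._profile(rho))
        assert np.isnan(pmf.values[35])
        assert pmf.missing is not None and pmf.missing[35]

    def test_zero_bulk_rejected(self):
        rho = np.zeros(70)
        rho[35] = 1.0
        with pytest.raises(ValueError):
            permeation_free_energy(self._profile(rho))

    @given(r1=st.floats(0.01, 10.0), r2=st.floats(0.01, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_difference_identity(self, r1, r2):
        rho = np.ones(70)
        rho[30], rho[40] = r1, r2
        pmf = permeation_free_energy(self._profile(rho), temperature=300.0)
        assert pmf.values[30] - pmf.values[40] == pytest.approx(
            R * 300.0 * np.log(r2 / r1), rel=1e-9, abs=1e-9
        )
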