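import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgepore.constants import GAS_CONSTANT_KJ_PER_MOL_K as R
from edgepore.defects import (
    ConfigurationError,
    EdgeDefinition,
    build_slice_grid,
    edge_xi,
    frame_xi,
    occupied_slices,
    xi_distribution,
    xi_free_energy,
)
from edgepore.synth import SyntheticSpec, make_bilayer_system, plant_polar_column

from .conftest import frame, water_topology


def brute_force_xi(z_values, center, grid):
    """Independent oracle: per slice, scan all polar atoms by direct z comparison."""
    occupied = 0
    z0 = center - grid.slab_thickness / 2
    for k in range(grid.n_slices):
        lo = z0 + k * grid.increment
        hi = lo + grid.increment
        for z in z_values:
            inside = (lo < z <= hi) or (k == 0 and z == lo)
            if inside:
                occupied += 1
                break
    return occupied / grid.n_slices


class TestSliceGrid:
    def test_default_28_slices(self):
        assert build_slice_grid(2.8, 0.1).n_slices == 28

    def test_two_slices(self):
        assert build_slice_grid(1.0, 0.5).n_slices == 2

    def test_non_commensurate_rejected(self):
        with pytest.raises(ConfigurationError):
            build_slice_grid(2.8, 0.3)

    def test_invariant_enforced_on_type(self):
        with pytest.raises(ConfigurationError):
            from edgepore.defects import SliceGrid

            SliceGrid(slab_thickness=2.8, increment=0.1, n_slices=27)


class TestFrameXi:
    def test_full_occupancy_is_one(self, grid, make_water_frame):
        z = grid.slice_centers(0.0)
        top, fr = make_water_frame([[0.0, 0.0, zi] for zi in z])
        assert frame_xi(top, fr, grid, center=0.0) == 1.0

    def test_dry_slab_is_zero(self, grid, make_water_frame):
        top, fr = make_water_frame([[0.0, 0.0, 3.0]])
        assert frame_xi(top, fr, grid, center=0.0) == 0.0

    def test_seven_slices_is_quarter(self, grid, make_water_frame):
        z = grid.slice_centers(0.0)[:7]
        top, fr = make_water_frame([[0.0, 0.0, zi] for zi in z])
        assert frame_xi(top, fr, grid, center=0.0) == 0.25

    def test_empty_polar_selection_is_error(self, grid, make_water_frame):
        top, fr = make_water_frame([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="polar selection is empty"):
            frame_xi(top, fr, grid, polar=np.array([], dtype=int), center=0.0)

    def test_boundary_assigned_to_lower_slice(self):
        # use a grid whose boundaries are exactly representable in binary
        g = build_slice_grid(2.0, 0.25)
        occ = occupied_slices(np.array([-1.0 + 0.25]), center=0.0, grid=g)
        assert occ[0] and not occ[1]

    def test_translation_invariance_in_plane(self, grid, make_water_frame):
        rng = np.random.default_rng(3)
        coords = rng.uniform([-2, -2, -1.4], [2, 2, 1.4], size=(30, 3))
        top, fr = make_water_frame(coords)
        base = frame_xi(top, fr, grid, center=0.0)
        top2, fr2 = make_water_frame(coords + np.array([1.3, -0.7, 0.0]))
        assert frame_xi(top2, fr2, grid, center=0.0) == base

    def test_relabeling_invariance(self, grid, make_water_frame):
        rng = np.random.default_rng(4)
        coords = rng.uniform([-2, -2, -1.4], [2, 2, 1.4], size=(25, 3))
        top, fr = make_water_frame(coords)
        top2, fr2 = make_water_frame(coords[rng.permutation(25)])
        assert frame_xi(top, fr, grid, center=0.0) == frame_xi(top2, fr2, grid, center=0.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, grid, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 200)
        coords = rng.uniform([-2.5, -2.5, -2.2], [2.5, 2.5, 2.2], size=(n, 3))
        top, fr = water_topology(n), frame(coords)
        assert frame_xi(top, fr, grid, center=0.0) == brute_force_xi(
            coords[:, 2], 0.0, grid
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_under_added_polar_atom(self, grid, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform([-2, -2, -2.0], [2, 2, 2.0], size=(10, 3))
        extra = rng.uniform([-2, -2, -2.0], [2, 2, 2.0], size=(1, 3))
        top, fr = water_topology(10), frame(coords)
        all_c = np.vstack([coords, extra])
        top2, fr2 = water_topology(11), frame(all_c)
        assert frame_xi(top2, fr2, grid, center=0.0) >= frame_xi(top, fr, grid, center=0.0)


class TestEdgeXi:
    def _edge(self, x, y, n=5):
        # a vertical pseudo-strand of heavy atoms used only as edge anchors
        coords = [[x, y, z] for z in np.linspace(-1.5, 1.5, n)]
        return coords

    def test_column_near_one_edge_only(self, grid):
        edge_a = self._edge(-1.0, 0.0)
        edge_b = self._edge(1.5, 0.0)
        zc = grid.slice_centers(0.0)
        column = [[-0.7, 0.0, z] for z in zc]
        coords = np.array(edge_a + edge_b + column)
        top = water_topology(len(coords))
        fr = frame(coords)
        polar = np.arange(10, 10 + len(zc))
        ea = EdgeDefinition("A", tuple(range(5)))
        eb = EdgeDefinition("B", tuple(range(5, 10)))
        assert edge_xi(top, fr, grid, ea, polar=polar, center=0.0) == 1.0
        assert edge_xi(top, fr, grid, eb, polar=polar, center=0.0) == 0.0

    def test_cutoff_excludes_far_column(self, grid):
        edge_a = self._edge(-1.6, 0.0)
        edge_b = self._edge(1.6, 0.0)
        zc = grid.slice_centers(0.0)
        column = [[0.0, 2.4, z] for z in zc]  # 2.8 nm from both edges in-plane
        coords = np.array(edge_a + edge_b + column)
        top = water_topology(len(coords))
        fr = frame(coords, box=(9.0, 9.0, 9.0))
        polar = np.arange(10, 10 + len(zc))
        ea = EdgeDefinition("A", tuple(range(5)), lateral_cutoff=1.0)
        eb = EdgeDefinition("B", tuple(range(5, 10)), lateral_cutoff=1.0)
        assert edge_xi(top, fr, grid, ea, polar=polar, center=0.0) == 0.0
        assert edge_xi(top, fr, grid, eb, polar=polar, center=0.0) == 0.0
        assert frame_xi(top, fr, grid, polar=polar, center=0.0) == 1.0

    def test_equidistant_column_counts_for_both(self, grid):
        edge_a = self._edge(-0.5, 0.0)
        edge_b = self._edge(0.5, 0.0)
        zc = grid.slice_centers(0.0)
        column = [[0.0, 0.0, z] for z in zc]
        coords = np.array(edge_a + edge_b + column)
        top = water_topology(len(coords))
        fr = frame(coords)
        polar = np.arange(10, 10 + len(zc))
        for idx in (range(5), range(5, 10)):
            e = EdgeDefinition("e", tuple(idx))
            assert edge_xi(top, fr, grid, e, polar=polar, center=0.0) == 1.0

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=25, deadline=None)
    def test_edge_xi_never_exceeds_total(self, grid, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform([-2.4, -2.4, -2.0], [2.4, 2.4, 2.0], size=(40, 3))
        top = water_topology(len(coords))
        fr = frame(coords)
        polar = np.arange(10, 40)
        e = EdgeDefinition("e", tuple(range(10)), lateral_cutoff=rng.uniform(0.2, 2.0))
        assert edge_xi(top, fr, grid, e, polar=polar, center=0.0) <= frame_xi(
            top, fr, grid, polar=polar, center=0.0
        )


class TestDistribution:
    def test_two_point_distribution(self, grid):
        dist = xi_distribution([np.array([1.0, 1.0, 0.0, 0.0])], grid.n_slices)
        assert dist.p[0] == 0.5
        assert dist.p[-1] == 0.5
        assert dist.p.sum() == 1.0

    def test_single_frame_degenerate(self, grid):
        dist = xi_distribution([np.array([0.25])], grid.n_slices)
        k = round(0.25 * grid.n_slices)
        assert dist.p[k] == 1.0

    def test_planted_three_point_counts_exactly(self, grid):
        # oracle: direct counting of a planted 3-point distribution
        rng = np.random.default_rng(11)
        values = np.array([0.0, 7 / 28, 1.0])
        draws = rng.choice(3, size=1000, p=[0.2, 0.5, 0.3])
        xi = values[draws]
        expected = np.bincount(draws, minlength=3) / 1000
        dist = xi_distribution([xi], grid.n_slices)
        assert dist.p[0] == expected[0]
        assert dist.p[7] == expected[1]
        assert dist.p[28] == expected[2]

    def test_replicate_sem_zero_for_identical(self, grid):
        xi = np.array([0.0, 1.0])
        dist = xi_distribution([xi, xi.copy()], grid.n_slices)
        assert np.all(dist.sem == 0.0)

    def test_empty_input_rejected(self, grid):
        with pytest.raises(ValueError):
            xi_distribution([np.array([])], grid.n_slices)


class TestFreeEnergy:
    def test_p_one_gives_zero(self):
        dg, defined = xi_free_energy(np.array([1.0]))
        assert dg[0] == 0.0 and defined[0]

    def test_p_inverse_e_gives_rt(self):
        dg, _ = xi_free_energy(np.array([np.exp(-1.0)]), temperature=300.0)
        assert dg[0] == pytest.approx(R * 300.0, abs=1e-12)
        assert dg[0] == pytest.approx(2.4944, abs=1e-4)

    def test_p_zero_flagged_undefined(self):
        dg, defined = xi_free_energy(np.array([0.0, 0.5]))
        assert not defined[0] and np.isnan(dg[0])
        assert defined[1] and np.isfinite(dg[1])

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            xi_free_energy(np.array([-0.1]))

    @given(
        p1=st.floats(1e-6, 1.0),
        p2=st.floats(1e-6, 1.0),
        t=st.floats(10.0, 1000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_difference_identity(self, p1, p2, t):
        dg, _ = xi_free_energy(np.array([p1, p2]), temperature=t)
        assert dg[0] - dg[1] == pytest.approx(R * t * np.log(p2 / p1), rel=1e-9, abs=1e-9)


class TestPlantedClosedLoop:
    def test_planted_column_recovered(self, grid):
        system = make_bilayer_system(SyntheticSpec(seed=5))
        filled = [0, 3, 4, 10, 27]
        planted = plant_polar_column(system, grid, filled, xy=(0.7, -0.9))
        xi = frame_xi(planted.topology, planted.frame, grid)
        assert xi == len(filled) / grid.n_slices
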