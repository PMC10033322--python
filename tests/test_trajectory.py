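import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgepore.roles import Role, Subrole, assign_role, validate_role
from edgepore.trajectory import (
    EmptyReplicateError,
    FormatError,
    FrameSnapshot,
    RoleSelection,
    Topology,
    TopologyMismatchError,
    intersect_indices,
    read_frame_table,
    read_pdb,
    read_structure,
    read_trajectory,
    select_atoms,
    subsample_frames,
    union_indices,
    write_frame_table,
    write_pdb,
)

from .conftest import atom, frame, water_topology


class TestRoles:
    def test_water_oxygen(self):
        assert assign_role("OW", "HOH") == (Role.WATER, Subrole.WATER_O)

    def test_lipid_phosphate(self):
        assert assign_role("P", "POPC") == (Role.LIPID, Subrole.PHOSPHATE)

    def test_protein_backbone_vs_sidechain(self):
        assert assign_role("CA", "HIS") == (Role.PROTEIN, Subrole.BACKBONE)
        assert assign_role("ND1", "HIS") == (Role.PROTEIN, Subrole.SIDECHAIN)

    def test_unknown_tagged_other(self, caplog):
        with caplog.at_level("WARNING"):
            role, subrole = assign_role("XX", "XYZ")
        assert (role, subrole) == (Role.OTHER, Subrole.OTHER)
        assert "tagged role=other" in caplog.text

    def test_compat_table_rejects_illegal_pair(self):
        with pytest.raises(ValueError):
            validate_role(Role.WATER, Subrole.PHOSPHATE)

    def test_duplicate_atom_index_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Topology([atom(0), atom(0)])


class TestPDB:
    def test_single_water_unit_conversion(self, tmp_path):
        # 10 A on x must come back as 1.0 nm
        p = tmp_path / "w.pdb"
        p.write_text(
            "CRYST1   50.000   50.000   90.000  90.00  90.00  90.00 P 1\n"
            "ATOM      1  OW  HOH W   1      10.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        top, fr = read_structure(p, dialect="pdb")
        assert top.n_atoms == 1
        assert top.subrole[0] == "water_O"
        assert fr.coordinates[0, 0] == pytest.approx(1.0)

    def test_two_models_read_as_two_frames(self, tmp_path):
        p = tmp_path / "t.pdb"
        rec = "ATOM      1  OW  HOH W   1      10.000   0.000   0.000  1.00  0.00           O\n"
        p.write_text("MODEL        1\n" + rec + "ENDMDL\nMODEL        2\n" + rec + "ENDMDL\n")
        traj = read_trajectory([p], stride=100.0, discard=0.0)
        assert len(traj.replicates[0]) == 2

    def test_unparseable_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  OW  HOH W   X      10.0\n")
        with pytest.raises(FormatError, match=r"bad\.pdb:1"):
            read_pdb(p)

    def test_write_read_roundtrip_roles(self, tmp_path, bilayer):
        p = tmp_path / "sys.pdb"
        write_pdb(p, bilayer.topology, [bilayer.frame])
        top, frames = read_pdb(p)
        assert list(top.role) == list(bilayer.topology.role)
        assert list(top.subrole) == list(bilayer.topology.subrole)
        assert np.abs(frames[0].coordinates - bilayer.frame.coordinates).max() < 1e-3


class TestFrameTable:
    def test_roundtrip_bit_exact(self, tmp_path, bilayer):
        p = tmp_path / "r.ftb"
        rng = np.random.default_rng(0)
        f2 = FrameSnapshot(
            bilayer.frame.coordinates + rng.normal(0, 0.37, bilayer.frame.coordinates.shape),
            bilayer.frame.box,
            time=100.0,
        )
        write_frame_table(p, bilayer.topology, [bilayer.frame, f2])
        top, frames = read_frame_table(p)
        assert top == bilayer.topology
        assert np.array_equal(frames[0].coordinates, bilayer.frame.coordinates)
        assert np.array_equal(frames[1].coordinates, f2.coordinates)

    def test_row_maps_role_fields(self, tmp_path):
        p = tmp_path / "row.ftb"
        p.write_text(
            "#FRAME t=0.0 box=5.0 5.0 9.0\n"
            "5\tP\tPOPC\t12\tL\tlipid\tphosphate\t1.0\t2.0\t3.0\n"
        )
        top, frames = read_frame_table(p)
        rec = top.record(0)
        assert rec.role is Role.LIPID and rec.subrole is Subrole.PHOSPHATE
        assert frames[0].coordinates[0].tolist() == [1.0, 2.0, 3.0]

    def test_bad_field_count_names_line(self, tmp_path):
        p = tmp_path / "bad.ftb"
        p.write_text("#FRAME t=0.0 box=5.0 5.0 9.0\n1\tOW\tSOL\n")
        with pytest.raises(FormatError, match=r"bad\.ftb:2"):
            read_frame_table(p)


class TestReadTrajectory:
    def _write(self, path, n_frames, spacing=100.0):
        top = water_topology(1)
        frames = [frame([[0.0, 0.0, 2.5]], time=i * spacing) for i in range(n_frames)]
        write_frame_table(path, top, frames)

    def test_discard_and_stride(self, tmp_path):
        p = tmp_path / "a.ftb"
        self._write(p, 10)
        traj = read_trajectory([p], stride=100.0, discard=500.0)
        assert len(traj.replicates[0]) == 5

    def test_identity_when_no_discard(self, tmp_path):
        p = tmp_path / "a.ftb"
        self._write(p, 10)
        traj = read_trajectory([p], stride=100.0, discard=0.0)
        assert len(traj.replicates[0]) == 10

    def test_discard_beyond_span_errors(self, tmp_path):
        p = tmp_path / "a.ftb"
        self._write(p, 10)
        with pytest.raises(EmptyReplicateError):
            read_trajectory([p], stride=100.0, discard=5000.0)

    def test_topology_mismatch_names_atom(self, tmp_path):
        pa, pb = tmp_path / "a.ftb", tmp_path / "b.ftb"
        self._write(pa, 2)
        top = Topology([atom(0, name="P", resname="POPC", chain="L", role=Role.LIPID, subrole=Subrole.PHOSPHATE)])
        write_frame_table(pb, top, [frame([[0.0, 0.0, 2.0]])])
        with pytest.raises(TopologyMismatchError, match="atom 0"):
            read_trajectory([pa, pb], stride=100.0, discard=0.0)

    @given(
        n=st.integers(min_value=1, max_value=40),
        k_discard=st.integers(min_value=0, max_value=10),
        k_stride=st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=40, deadline=None)
    def test_retained_count_formula(self, n, k_discard, k_stride):
        spacing = 100.0
        frames = [frame([[0.0, 0.0, 2.5]], time=i * spacing) for i in range(n)]
        discard = k_discard * spacing
        stride = k_stride * spacing
        kept = subsample_frames(frames, stride=stride, discard=discard)
        span = (n - 1) * spacing
        expected = 0 if discard > span else int((span - discard) // stride) + 1
        assert len(kept) == expected


class TestSelection:
    def test_water_oxygens_only(self, bilayer):
        idx = select_atoms(bilayer.topology, RoleSelection(role=Role.WATER, subrole=Subrole.WATER_O))
        assert len(idx) == bilayer.spec.n_waters
        assert set(bilayer.topology.subrole[idx]) == {"water_O"}

    def test_indices_strictly_increasing(self, bilayer):
        idx = select_atoms(bilayer.topology, RoleSelection(role=Role.LIPID))
        assert np.all(np.diff(idx) > 0)

    def test_hhqk_domain_residues_13_16(self, tetramer_sheet):
        _, top, _ = tetramer_sheet
        idx = select_atoms(
            top, RoleSelection(role=Role.PROTEIN, residue_min=13, residue_max=16)
        )
        assert set(top.residue_number[idx]) == {13, 14, 15, 16}
        assert set(top.residue_name[idx]) == {"HIS", "GLN", "LYS"}

    def test_beta1_backbone_carbonyls(self, tetramer_sheet):
        # intersection: protein x residues 9-21 x backbone O
        _, top, _ = tetramer_sheet
        a = select_atoms(top, RoleSelection(role=Role.PROTEIN, residue_min=9, residue_max=21))
        b = select_atoms(
            top, RoleSelection(subrole=Subrole.BACKBONE, names=frozenset({"O"}))
        )
        both = intersect_indices(a, b)
        assert len(both) > 0
        assert all(top.name[i] == "O" and 9 <= top.residue_number[i] <= 21 for i in both)

    def test_empty_selection_is_legal(self, bilayer):
        idx = select_atoms(bilayer.topology, RoleSelection(role=Role.PROTEIN))
        assert idx.size == 0

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_union_intersection_cardinality(self, bilayer, data):
        roles = [None, Role.WATER, Role.LIPID, Role.ION]
        subs = [None, Subrole.WATER_O, Subrole.PHOSPHATE, Subrole.K]
        sel_a = RoleSelection(role=data.draw(st.sampled_from(roles)), subrole=data.draw(st.sampled_from(subs)))
        sel_b = RoleSelection(role=data.draw(st.sampled_from(roles)), subrole=data.draw(st.sampled_from(subs)))
        try:
            a = select_atoms(bilayer.topology, sel_a)
            b = select_atoms(bilayer.topology, sel_b)
        except ValueError:
            return
        assert len(union_indices(a, b)) + len(intersect_indices(a, b)) == len(a) + len(b)
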