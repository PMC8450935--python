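"""Reading/writing structures and trajectories, parameters, selections."""

import numpy as np
import pytest

from afpshell import (ParameterTable, Trajectory, assign_parameters,
                      default_parameter_table, load_selection, read_structure,
                      read_trajectory, write_structure, write_trajectory)
from afpshell.structure_io import Frame, Topology, minimum_image
from conftest import water_atoms

TOY_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  OW  SOL W   1      10.000  10.000  10.000  1.00  0.00           O
ATOM      2  HW1 SOL W   1      10.800  10.000  10.000  1.00  0.00           H
ATOM      3  HW2 SOL W   1       9.700  10.900  10.000  1.00  0.00           H
END
"""

TOY_GRO = """\
toy water
    3
    1SOL     OW    1   1.000   1.000   1.000
    1SOL    HW1    2   1.080   1.000   1.000
    1SOL    HW2    3   0.970   1.090   1.000
   5.0   5.0   5.0
"""


def test_read_toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    traj = read_structure(p)
    assert traj.n_atoms == 3 and traj.n_frames == 1
    assert traj.topology[0].is_water and traj.topology[0].element == "O"
    # Angstrom -> nm conversion
    assert np.allclose(traj.frames[0].coordinates[0], [1.0, 1.0, 1.0])
    assert np.allclose(traj.frames[0].box, [5.0, 5.0, 5.0])


def test_read_gro_box_line(tmp_path):
    p = tmp_path / "toy.gro"
    p.write_text(TOY_GRO)
    traj = read_structure(p)
    assert np.allclose(traj.frames[0].box, [5.0, 5.0, 5.0])
    assert traj.n_atoms == 3
    assert np.allclose(traj.frames[0].coordinates[0], [1.0, 1.0, 1.0], atol=1e-6)


@pytest.mark.parametrize("ext", ["pdb", "gro"])
def test_structure_roundtrip_precision(tmp_path, ext):
    rng = np.random.default_rng(0)
    topo = Topology(water_atoms(5))
    coords = rng.uniform(0.5, 4.5, (15, 3))
    traj = Trajectory(topo, [Frame(coords, np.array([5.0, 5.0, 5.0]))])
    p = tmp_path / f"w.{ext}"
    write_structure(traj, p)
    back = read_structure(p)
    assert np.abs(back.frames[0].coordinates - coords).max() <= 1e-3


def test_trajectory_roundtrip_and_order(tmp_path):
    rng = np.random.default_rng(1)
    topo = Topology(water_atoms(4))
    box = np.array([5.0, 5.0, 5.0])
    frames = [Frame(rng.uniform(0.5, 4.5, (12, 3)), box, time=float(t))
              for t in range(10)]
    traj = Trajectory(topo, frames)
    p = tmp_path / "traj.pdb"
    write_trajectory(traj, p)
    back = read_trajectory(p)
    assert back.n_frames == 10
    times = [fr.time for fr in back.frames]
    assert times == sorted(times)
    for fr, orig in zip(back.frames, frames):
        assert np.abs(fr.coordinates - orig.coordinates).max() <= 1e-3


def test_truncated_trajectory_errors(tmp_path):
    # protein atoms differ between models -> must fail, not silently load
    text = TOY_PDB.replace("SOL W", "ALA A")
    lines = text.splitlines()
    body = "\n".join(["MODEL     1"] + lines[1:4] + ["ENDMDL", "MODEL     2"]
                     + lines[1:3] + ["ENDMDL", "END"])
    p = tmp_path / "trunc.pdb"
    p.write_text(lines[0] + "\n" + body + "\n")
    with pytest.raises(ValueError, match="cannot reconcile"):
        read_trajectory(p)


def test_atom_count_mismatch_reported(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    wrong_topo = Topology(water_atoms(2))
    with pytest.raises(ValueError, match="atom count mismatch"):
        read_trajectory(p, Trajectory(wrong_topo, []))


def test_triclinic_box_rejected(tmp_path):
    p = tmp_path / "tri.pdb"
    p.write_text(TOY_PDB.replace("90.00  90.00  90.00", "90.00  90.00  60.00"))
    with pytest.raises(ValueError, match="triclinic"):
        read_structure(p)


class TestParameters:
    def test_water_neutrality(self):
        topo = Topology(water_atoms(1))
        for a in topo:
            a.vdw_radius = a.partial_charge = None
        traj = Trajectory(topo, [Frame(np.zeros((3, 3)) + 1.0, np.ones(3) * 5)])
        assign_parameters(traj, default_parameter_table())
        q = traj.topology.partial_charges
        assert q.sum() == pytest.approx(0.0, abs=1e-12)

    def test_missing_entry_names_atom(self):
        from afpshell.structure_io import AtomRecord
        topo = Topology([AtomRecord(0, "CG1", "X", 7, "VAL", "A")])
        traj = Trajectory(topo, [Frame(np.ones((1, 3)), np.ones(3) * 5)])
        with pytest.raises(ValueError, match="VAL7:CG1"):
            assign_parameters(traj, default_parameter_table())

    def test_pair_lookup_beats_element_fallback(self):
        table = ParameterTable(pairs={("SOL", "OW"): (0.2, -1.0)},
                               elements={"O": (0.1, 0.5)})
        assert table.lookup("SOL", "OW", "O") == (0.2, -1.0)
        assert table.lookup("HOH", "O", "O") == (0.1, 0.5)
        assert table.lookup("ALA", "CA", "C") is None

    def test_yaml_roundtrip(self, tmp_path):
        t = ParameterTable(pairs={("PRT", "C1"): (0.17, 0.35)},
                           elements={"O": (0.152, -0.1)})
        p = tmp_path / "params.yaml"
        t.to_yaml(p)
        back = ParameterTable.from_yaml(p)
        assert back.pairs == t.pairs and back.elements == t.elements


class TestSelections:
    def make_topology(self, n_res=10):
        from afpshell.structure_io import AtomRecord
        return Topology([AtomRecord(i, "CA", "C", i + 1, "ALA", "A")
                         for i in range(n_res)])

    def test_complement(self):
        topo = self.make_topology()
        ibs, nibs = load_selection({"ibs_residues": ["A:1-5"]}, topo)
        assert ibs.residues == frozenset(("A", r) for r in range(1, 6))
        assert nibs.residues == frozenset(("A", r) for r in range(6, 11))
        assert not (ibs.residues & nibs.residues)

    def test_empty_ibs_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            load_selection({"ibs_residues": []}, self.make_topology())

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="99"):
            load_selection({"ibs_residues": ["A:99"]}, self.make_topology())

    def test_duplicates_deduplicated(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="afpshell"):
            ibs, _ = load_selection({"ibs_residues": ["A:1", "A:1", "A:2"]},
                                    self.make_topology())
        assert ibs.residues == frozenset({("A", 1), ("A", 2)})
        assert "duplicate" in caplog.text


def test_minimum_image_convention():
    box = np.array([5.0, 5.0, 5.0])
    v = np.array([[4.9, 0.0, -4.9]])
    assert np.allclose(minimum_image(v, box), [[-0.1, 0.0, 0.1]])
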