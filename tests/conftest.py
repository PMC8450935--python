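"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from afpshell import (EllipsoidModel, Frame, SyntheticSpec, Topology,
                      Trajectory, generate_hydrated_frames)
from afpshell.structure_io import AtomRecord


def water_atoms(n_mols: int, start_id: int = 0, chain: str = "W") -> list:
    atoms = []
    aid = start_id
    for m in range(n_mols):
        for name, el, r, q in (("OW", "O", 0.152, -0.82),
                               ("HW1", "H", 0.04, 0.41),
                               ("HW2", "H", 0.04, 0.41)):
            atoms.append(AtomRecord(
                atom_id=aid, atom_name=name, element=el, residue_id=m + 1,
                residue_name="SOL", chain_id=chain, vdw_radius=r,
                partial_charge=q, is_water=True))
            aid += 1
    return atoms


def oxygen_only_trajectory(ox_per_frame: list, box, radii_q=(0.152, -0.82)) -> Trajectory:
    """Trajectory of water oxygens only (1-atom waters), one list per frame."""
    n_max = max(len(o) for o in ox_per_frame)
    atoms = [AtomRecord(atom_id=i, atom_name="OW", element="O", residue_id=i + 1,
                        residue_name="SOL", chain_id="W", vdw_radius=radii_q[0],
                        partial_charge=radii_q[1], is_water=True)
             for i in range(n_max)]
    topo = Topology(atoms)
    frames = []
    for t, ox in enumerate(ox_per_frame):
        idx = np.arange(len(ox))
        frames.append(Frame(coordinates=np.asarray(ox, float).reshape(-1, 3),
                            box=box, time=float(t),
                            atom_index=idx if len(ox) != n_max else None))
    return Trajectory(topology=topo, frames=frames)


@pytest.fixture(scope="session")
def unit_sphere_model():
    return EllipsoidModel(center=np.zeros(3), axes=np.eye(3),
                          semi_axes=np.array([2.0, 2.0, 2.0]))


@pytest.fixture(scope="session")
def triaxial_model():
    return EllipsoidModel(center=np.zeros(3), axes=np.eye(3),
                          semi_axes=np.array([3.0, 2.0, 1.0]))


@pytest.fixture(scope="session")
def small_hydrated():
    """30-frame pseudo-protein system with a 10% step enhancement."""
    spec = SyntheticSpec(box=(4.6, 4.6, 4.6), n_protein_atoms=120,
                         enhancement=0.10, seed=42)
    traj, mimic = generate_hydrated_frames(spec, 30)
    return spec, traj, mimic
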