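"""Structure/trajectory I/O and the internal data model.

All coordinates are stored in nm (PDB Angstroms are converted on read).
PDB files — including multi-model trajectories whose models may contain
different numbers of water molecules, as the fictitious bulk-overlay
construction produces — are handled through gemmi; GRO and XTC/DCD go
through MDAnalysis.  Only orthorhombic boxes are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("afpshell")

__all__ = [
    "AtomRecord", "Topology", "Frame", "Trajectory", "SurfaceSelection",
    "ParameterTable", "default_parameter_table",
    "read_structure", "read_trajectory", "write_structure", "write_trajectory",
    "assign_parameters", "load_selection", "minimum_image",
    "WATER_RESNAMES",
]

#: residue names recognised as water (configurable per call where relevant)
WATER_RESNAMES = frozenset({"SOL", "HOH", "WAT", "TIP3", "SPC"})

_TWO_LETTER_ELEMENTS = {"CL", "NA", "MG", "ZN", "CA", "FE", "BR", "MN", "CU"}


def element_from_name(atom_name: str, residue_name: str = "") -> str:
    """Infer the chemical element from an atom name (PDB/GRO conventions)."""
    stripped = "".join(ch for ch in atom_name if ch.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    # calcium/CA ambiguity: within amino-acid residues CA is the alpha carbon
    if stripped[:2] in _TWO_LETTER_ELEMENTS and not (
        stripped[:2] == "CA" and residue_name not in ("CA", "")
    ):
        return stripped[:2].capitalize()
    return stripped[0]


@dataclass
class AtomRecord:
    """One atom of the system topology (lengths nm, charges e)."""

    atom_id: int
    atom_name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str
    vdw_radius: float | None = None
    partial_charge: float | None = None
    is_water: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_water_oxygen(self) -> bool:
        return self.is_water and self.element.upper() == "O"


class Topology:
    """Ordered atom list with cached numpy views used by the analyses."""

    def __init__(self, atoms: list[AtomRecord]):
        self.atoms = list(atoms)
        self._invalidate()

    def _invalidate(self) -> None:
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i):
        return self.atoms[i]

    def _arr(self, key: str, fn, dtype) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.array([fn(a) for a in self.atoms], dtype=dtype)
        return self._cache[key]

    @property
    def is_water(self) -> np.ndarray:
        return self._arr("is_water", lambda a: a.is_water, bool)

    @property
    def is_heavy(self) -> np.ndarray:
        return self._arr("is_heavy", lambda a: a.is_heavy, bool)

    @property
    def is_water_oxygen(self) -> np.ndarray:
        return self._arr("is_wo", lambda a: a.is_water_oxygen, bool)

    @property
    def is_protein(self) -> np.ndarray:
        return self._arr("is_protein", lambda a: not a.is_water, bool)

    @property
    def vdw_radii(self) -> np.ndarray:
        return self._arr("radii",
                         lambda a: np.nan if a.vdw_radius is None else a.vdw_radius,
                         float)

    @property
    def partial_charges(self) -> np.ndarray:
        return self._arr("charges",
                         lambda a: np.nan if a.partial_charge is None else a.partial_charge,
                         float)

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return [(a.chain_id, a.residue_id) for a in self.atoms]


@dataclass
class Frame:
    """One configuration: coordinates (nm), orthorhombic box lengths (nm), time (ps).

    ``atom_index`` maps coordinate rows onto topology atoms; ``None`` means
    the frame covers the full topology in order.  Frames produced by the
    fictitious bulk-overlay construction use it to drop removed waters.
    """

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0
    atom_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in frame")
        if not np.all(self.box > 0):
            raise ValueError(f"box lengths must be positive, got {self.box}")
        if self.atom_index is not None:
            self.atom_index = np.asarray(self.atom_index, dtype=int)
            if len(self.atom_index) != len(self.coordinates):
                raise ValueError("atom_index length must match coordinates")

    def indices(self, n_topology: int) -> np.ndarray:
        if self.atom_index is None:
            return np.arange(n_topology)
        return self.atom_index


@dataclass
class Trajectory:
    """Topology plus an ordered list of frames."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.topology, Topology):
            self.topology = Topology(list(self.topology))
        for i, fr in enumerate(self.frames):
            if fr.atom_index is None and len(fr.coordinates) != len(self.topology):
                raise ValueError(
                    f"frame {i} has {len(fr.coordinates)} coordinates for "
                    f"{len(self.topology)} topology atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_mask(self, frame: Frame, topo_mask: np.ndarray) -> np.ndarray:
        """Positions of `frame` rows whose topology atoms satisfy `topo_mask`."""
        idx = frame.indices(len(self.topology))
        return frame.coordinates[topo_mask[idx]]


@dataclass(frozen=True)
class SurfaceSelection:
    """A set of residues defining a protein surface (IBS, NIBS, or WHOLE)."""

    label: str
    residues: frozenset

    def atom_indices(self, topology: Topology, heavy_only: bool = True) -> np.ndarray:
        res = self.residues
        out = [
            i for i, a in enumerate(topology)
            if not a.is_water and (a.chain_id, a.residue_id) in res
            and (a.is_heavy or not heavy_only)
        ]
        return np.array(out, dtype=int)


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors in an orthorhombic box."""
    vectors = np.asarray(vectors, dtype=float)
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


# ---------------------------------------------------------------------------
# parameter table
# ---------------------------------------------------------------------------

class ParameterTable:
    """Maps atoms to (vdW radius nm, partial charge e).

    Lookup order: exact (residue_name, atom_name) pair first, element
    fallback second.  The table is explicit input — analyses refuse to run
    on atoms it does not cover.
    """

    def __init__(self,
                 pairs: dict[tuple[str, str], tuple[float, float]] | None = None,
                 elements: dict[str, tuple[float, float]] | None = None):
        self.pairs = {(r.upper(), a.upper()): (float(v[0]), float(v[1]))
                      for (r, a), v in (pairs or {}).items()}
        self.elements = {e.upper(): (float(v[0]), float(v[1]))
                         for e, v in (elements or {}).items()}

    def lookup(self, residue_name: str, atom_name: str,
               element: str) -> tuple[float, float] | None:
        hit = self.pairs.get((residue_name.upper(), atom_name.upper()))
        if hit is not None:
            return hit
        return self.elements.get(element.upper())

    def to_yaml(self, path) -> None:
        d = {
            "pairs": {f"{r}:{a}": {"radius": v[0], "charge": v[1]}
                      for (r, a), v in self.pairs.items()},
            "elements": {e: {"radius": v[0], "charge": v[1]}
                         for e, v in self.elements.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ParameterTable":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        pairs = {}
        for key, v in (d.get("pairs") or {}).items():
            resname, atomname = key.split(":")
            pairs[(resname, atomname)] = (v["radius"], v["charge"])
        elements = {e: (v["radius"], v["charge"])
                    for e, v in (d.get("elements") or {}).items()}
        return cls(pairs=pairs, elements=elements)


def default_parameter_table() -> ParameterTable:
    """Element radii following common OPLS-AA-like conventions and SPC water.

    The radii/charges here are convenience defaults for synthetic systems
    and quick looks; production analyses of real force-field output should
    supply the matching table explicitly.
    """
    return ParameterTable(
        pairs={
            ("SOL", "OW"): (0.158, -0.82),
            ("SOL", "HW1"): (0.040, 0.41),
            ("SOL", "HW2"): (0.040, 0.41),
        },
        elements={
            "H": (0.110, 0.0),
            "C": (0.170, 0.0),
            "N": (0.155, 0.0),
            "O": (0.152, 0.0),
            "S": (0.180, 0.0),
        },
    )


def assign_parameters(traj: Trajectory, params: ParameterTable,
                      water_resnames=WATER_RESNAMES) -> Trajectory:
    """Assign vdW radii and partial charges to every atom, in place.

    Raises a single error listing *all* unparameterised atoms — no silent
    defaults.  Water atoms are (re-)flagged by residue name.
    """
    missing = []
    for a in traj.topology:
        a.is_water = a.residue_name.upper() in water_resnames
        hit = params.lookup(a.residue_name, a.atom_name, a.element)
        if hit is None:
            missing.append(f"{a.chain_id}:{a.residue_name}{a.residue_id}:{a.atom_name}")
        else:
            a.vdw_radius, a.partial_charge = hit
    if missing:
        raise ValueError(
            f"{len(missing)} atom(s) without parameters: " + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else "")
        )
    traj.topology._invalidate()
    return traj


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def _parse_residue_spec(item) -> list[tuple[str, int]]:
    """Accept 'A:12', 'A:1-5', ['A', 12] forms."""
    if isinstance(item, (list, tuple)) and len(item) == 2:
        return [(str(item[0]), int(item[1]))]
    s = str(item)
    chain, _, respart = s.partition(":")
    if not respart:
        chain, respart = "A", chain
    import re

    m = re.fullmatch(r"(\d+)-(\d+)", respart)
    if m:
        return [(chain, r) for r in range(int(m.group(1)), int(m.group(2)) + 1)]
    return [(chain, int(respart))]


def load_selection(config, topology: Topology) -> tuple[SurfaceSelection, SurfaceSelection]:
    """Build the (IBS, NIBS) residue partition from a config mapping or YAML path.

    The config lists ``ibs_residues``; NIBS is the complement over all
    protein residues, so the two are disjoint and jointly exhaustive.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    raw = config.get("ibs_residues") if isinstance(config, dict) else config
    if raw is None:
        raise ValueError("config has no 'ibs_residues' entry")
    listed: list[tuple[str, int]] = []
    for item in raw:
        listed.extend(_parse_residue_spec(item))
    if not listed:
        raise ValueError("empty IBS residue list: an AFP analysis requires a nonempty IBS")
    seen = set()
    ibs_res = []
    for key in listed:
        if key in seen:
            logger.warning("duplicate IBS residue %s:%s ignored", *key)
            continue
        seen.add(key)
        ibs_res.append(key)
    all_protein = {(a.chain_id, a.residue_id) for a in topology if not a.is_water}
    unknown = [k for k in ibs_res if k not in all_protein]
    if unknown:
        raise ValueError(f"IBS residues not found in topology: {unknown}")
    ibs = SurfaceSelection("IBS", frozenset(ibs_res))
    nibs = SurfaceSelection("NIBS", frozenset(all_protein - set(ibs_res)))
    return ibs, nibs


# ---------------------------------------------------------------------------
# file readers/writers
# ---------------------------------------------------------------------------

def _check_orthorhombic(angles, path) -> None:
    if angles is not None and not np.allclose(angles, 90.0, atol=1e-3):
        raise ValueError(f"{path}: triclinic boxes are unsupported (angles {angles})")


def _topology_from_gemmi(model, path) -> tuple[Topology, np.ndarray]:
    import gemmi

    atoms, coords = [], []
    i = 0
    for chain in model:
        for res in chain:
            is_w = res.name.upper() in WATER_RESNAMES
            for at in res:
                el = at.element.name if at.element != gemmi.Element("X") else ""
                if not el:
                    el = element_from_name(at.name, res.name)
                atoms.append(AtomRecord(
                    atom_id=i, atom_name=at.name, element=el,
                    residue_id=res.seqid.num, residue_name=res.name,
                    chain_id=chain.name, is_water=is_w,
                ))
                coords.append([at.pos.x, at.pos.y, at.pos.z])
                i += 1
    return Topology(atoms), np.asarray(coords) / 10.0  # A -> nm


def _read_pdb(path) -> Trajectory:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    cell = st.cell
    if cell.a > 1.0:
        _check_orthorhombic([cell.alpha, cell.beta, cell.gamma], path)
        box = np.array([cell.a, cell.b, cell.c]) / 10.0
    else:
        box = None
    parsed = [_topology_from_gemmi(st[m], path) for m in range(len(st))]
    if box is None:
        # fallback: bounding box + margin, flagged to the user
        span = parsed[0][1].max(axis=0) - parsed[0][1].min(axis=0)
        box = span + 2.0
        logger.warning("%s has no CRYST1 record; using bounding box + 2 nm", path)

    # union topology = the largest model (waters are interchangeable, so a
    # smaller model maps onto the first k water molecules of the union)
    ref = int(np.argmax([len(t) for t, _ in parsed]))
    topo = parsed[ref][0]
    n_protein = int((~topo.is_water).sum())
    water_mol_size = None
    if topo.is_water.any():
        w_res: dict[tuple, int] = {}
        for a in topo:
            if a.is_water:
                w_res[(a.chain_id, a.residue_id)] = w_res.get(
                    (a.chain_id, a.residue_id), 0) + 1
        sizes = set(w_res.values())
        water_mol_size = sizes.pop() if len(sizes) == 1 else None

    frames = []
    for m, (topo_m, coords_m) in enumerate(parsed):
        if len(topo_m) == len(topo):
            frames.append(Frame(coordinates=coords_m, box=box, time=float(m)))
            continue
        n_protein_m = int((~topo_m.is_water).sum())
        n_wat_m = len(topo_m) - n_protein_m
        if (n_protein_m != n_protein or water_mol_size is None
                or n_wat_m % water_mol_size or n_wat_m > int(topo.is_water.sum())):
            raise ValueError(
                f"{path}: model {m + 1} has {len(topo_m)} atoms, topology has "
                f"{len(topo)}; cannot reconcile"
            )
        idx = np.concatenate([
            np.flatnonzero(~topo.is_water)[:n_protein],
            np.flatnonzero(topo.is_water)[:n_wat_m],
        ])
        frames.append(Frame(coordinates=coords_m, box=box, time=float(m), atom_index=idx))
    return Trajectory(topology=topo, frames=frames)


def _read_gro(path) -> Trajectory:
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse GRO file {path}: {exc}") from exc
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise ValueError(f"{path}: missing or invalid box line")
    _check_orthorhombic(dims[3:6], path)
    atoms = []
    for i, at in enumerate(u.atoms):
        resname = str(at.resname)
        el = element_from_name(str(at.name), resname)
        atoms.append(AtomRecord(
            atom_id=i, atom_name=str(at.name), element=el,
            residue_id=int(at.resid), residue_name=resname,
            chain_id=str(getattr(at, "chainID", "") or "A"),
            is_water=resname.upper() in WATER_RESNAMES,
        ))
    coords = u.atoms.positions.astype(float) / 10.0
    box = dims[:3].astype(float) / 10.0
    return Trajectory(topology=Topology(atoms),
                      frames=[Frame(coordinates=coords, box=box, time=0.0)])


def read_structure(path, fmt: str | None = None) -> Trajectory:
    """Read a single-structure file (PDB or GRO) into a one-frame Trajectory.

    Coordinates are converted to nm regardless of the source units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        traj = _read_pdb(path)
        traj.frames = traj.frames[:1]
        return traj
    if fmt == "gro":
        return _read_gro(path)
    raise ValueError(f"unsupported structure format {fmt!r} (expected pdb or gro)")


def read_trajectory(path, topology: Trajectory | Topology | None = None) -> Trajectory:
    """Read a trajectory: multi-model PDB (self-describing) or XTC/DCD
    (requires `topology` from a matching structure file)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        traj = _read_pdb(path)
        if topology is not None:
            ref = topology.topology if isinstance(topology, Trajectory) else topology
            if len(ref) != len(traj.topology):
                raise ValueError(
                    f"atom count mismatch: topology has {len(ref)}, "
                    f"trajectory {path} has {len(traj.topology)}"
                )
        logger.info("read %d frames from %s", traj.n_frames, path)
        return traj
    if fmt in ("xtc", "dcd"):
        import MDAnalysis as mda

        if topology is None:
            raise ValueError(f"{fmt} trajectories need an explicit topology")
        base = topology if isinstance(topology, Trajectory) else Trajectory(topology, [])
        topo = base.topology
        u = mda.Universe.empty(len(topo), trajectory=True)
        try:
            u.load_new(str(path))
        except Exception as exc:
            raise ValueError(f"cannot read trajectory {path}: {exc}") from exc
        if u.atoms.n_atoms != len(topo):
            raise ValueError(
                f"atom count mismatch: topology has {len(topo)}, "
                f"trajectory {path} has {u.atoms.n_atoms}"
            )
        frames = []
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                raise ValueError(f"{path}: frame {ts.frame} lacks box information")
            _check_orthorhombic(dims[3:6], path)
            frames.append(Frame(
                coordinates=ts.positions.astype(float) / 10.0,
                box=dims[:3].astype(float) / 10.0,
                time=float(ts.time),
            ))
        logger.info("read %d frames from %s", len(frames), path)
        return Trajectory(topology=topo, frames=frames)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _gemmi_structure(traj: Trajectory, frames: list[Frame]):
    import gemmi

    st = gemmi.Structure()
    st.name = "afpshell"
    box = frames[0].box * 10.0
    st.cell = gemmi.UnitCell(box[0], box[1], box[2], 90, 90, 90)
    st.spacegroup_hm = "P 1"
    topo = traj.topology
    for mi, fr in enumerate(frames):
        model = gemmi.Model(mi + 1)
        idx = fr.indices(len(topo))
        chains: dict[str, "gemmi.Chain"] = {}
        res_key = None
        res = None
        for row, ti in enumerate(idx):
            a = topo[int(ti)]
            ch = chains.get(a.chain_id)
            if ch is None:
                ch = gemmi.Chain(a.chain_id)
                chains[a.chain_id] = ch
                model.add_chain(ch)
                ch = model[len(model) - 1]
                chains[a.chain_id] = ch
                res_key = None
            key = (a.chain_id, a.residue_id, a.residue_name)
            if key != res_key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_id, " ")
                ch.add_residue(res)
                res = ch[len(ch) - 1]
                res_key = key
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            x, y, z = fr.coordinates[row] * 10.0
            at.pos = gemmi.Position(x, y, z)
            res.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(traj: Trajectory, path) -> None:
    """Write the first frame to PDB (gemmi) or GRO (MDAnalysis)."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        st = _gemmi_structure(traj, traj.frames[:1])
        st.write_pdb(str(path))
        return
    if fmt == "gro":
        import MDAnalysis as mda

        topo = traj.topology
        fr = traj.frames[0]
        resmap: dict[tuple, int] = {}
        resindex = []
        resnames, resids = [], []
        for a in topo:
            key = (a.chain_id, a.residue_id, a.residue_name)
            if key not in resmap:
                resmap[key] = len(resmap)
                resnames.append(a.residue_name)
                resids.append(a.residue_id)
            resindex.append(resmap[key])
        u = mda.Universe.empty(len(topo), n_residues=len(resmap),
                               atom_resindex=np.array(resindex), trajectory=True)
        u.add_TopologyAttr("names", [a.atom_name for a in topo])
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)
        u.atoms.positions = fr.coordinates * 10.0
        u.dimensions = np.array([*(fr.box * 10.0), 90.0, 90.0, 90.0])
        u.atoms.write(str(path))
        return
    raise ValueError(f"unsupported structure format {fmt!r}")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write all frames as a multi-model PDB (models may differ in waters)."""
    path = Path(path)
    if path.suffix.lower() != ".pdb":
        raise ValueError("trajectories are written as multi-model PDB")
    st = _gemmi_structure(traj, traj.frames)
    st.write_pdb(str(path))
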