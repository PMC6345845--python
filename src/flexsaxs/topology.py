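"""Coarse-grained bead representation of multi-domain protein complexes.

A complex is modelled at one bead per residue, placed at the Calpha
position.  Crystallised portions are grouped into rigid bodies whose
internal geometry never changes; disordered linkers are chains of beads
with a fixed bond length (3.8 A, the consecutive-Calpha spacing) that may
be anchored to rigid bodies at one or both ends.

All coordinates are in Angstrom, all energies in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: formal charges at pH 7; His neutral by default (see :func:`residue_charge`)
FORMAL_CHARGES = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}

CA_BOND_LENGTH = 3.8


def residue_charge(residue_type: str, his_charge: float = 0.0) -> float:
    """Formal charge of a residue type in elementary charges.

    Asp/Glu carry -1, Lys/Arg +1; histidine is neutral by default but its
    charge is configurable (protonation is pH dependent); all others 0.
    """
    if residue_type == "H":
        return his_charge
    return FORMAL_CHARGES.get(residue_type, 0.0)


@dataclass
class Bead:
    """One residue of the coarse-grained model."""

    index: int
    residue_type: str
    position: np.ndarray
    charge: float
    member_of: str

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"bead {self.index}: position must be a finite 3-vector")
        if self.residue_type not in AMINO_ACIDS:
            raise ValueError(f"bead {self.index}: unknown residue type {self.residue_type!r}")


@dataclass
class RigidBody:
    """A crystallised portion treated as one rigid unit.

    ``reference_coords`` store the internal frame (centred on the body
    centroid); the instantaneous placement is ``R(q) @ ref + t`` where the
    pose is a unit quaternion ``q`` (scalar first) and a translation ``t``.
    """

    id: str
    bead_indices: np.ndarray
    reference_coords: np.ndarray
    pose_rotation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    pose_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.bead_indices = np.asarray(self.bead_indices, dtype=np.int64)
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        self.pose_rotation = np.asarray(self.pose_rotation, dtype=float)
        self.pose_translation = np.asarray(self.pose_translation, dtype=float)
        if abs(np.linalg.norm(self.pose_rotation) - 1.0) > 1e-9:
            raise ValueError(f"rigid body {self.id}: pose quaternion must have unit norm")

    @property
    def n_beads(self) -> int:
        return len(self.bead_indices)

    def coords(self) -> np.ndarray:
        """Instantaneous bead coordinates under the current pose."""
        return self.reference_coords @ quat_to_matrix(self.pose_rotation).T + self.pose_translation


@dataclass
class LinkerChain:
    """A flexible chain of amino-acid beads.

    ``anchor_start`` / ``anchor_end`` are bead indices on rigid bodies the
    chain ends are bonded to, or ``None`` for a free terminus.
    """

    id: str
    bead_indices: np.ndarray
    bond_length: float = CA_BOND_LENGTH
    anchor_start: int | None = None
    anchor_end: int | None = None

    def __post_init__(self):
        self.bead_indices = np.asarray(self.bead_indices, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return len(self.bead_indices)


@dataclass
class ComplexTopology:
    """Rigid bodies + linkers + restraints: the simulated object.

    membrane_restraints are ``(bead_index, target_z, spring_k)`` triples in
    A and kcal/mol/A^2 — soft harmonic tethers standing in for lipidated
    anchors (e.g. geranylgeranylated cysteines) or membrane-binding sites.
    """

    beads: list[Bead]
    rigid_bodies: list[RigidBody]
    linkers: list[LinkerChain]
    membrane_restraints: list[tuple[int, float, float]] = field(default_factory=list)
    stoichiometry: str = ""

    def __post_init__(self):
        n = len(self.beads)
        owners = np.full(n, -2, dtype=int)
        for bi, body in enumerate(self.rigid_bodies):
            for idx in body.bead_indices:
                if owners[idx] != -2:
                    raise ValueError(f"bead {idx} assigned to more than one segment")
                owners[idx] = bi
        for linker in self.linkers:
            for idx in linker.bead_indices:
                if owners[idx] != -2:
                    raise ValueError(f"bead {idx} assigned to more than one segment")
                owners[idx] = -1
        if np.any(owners == -2):
            orphan = int(np.where(owners == -2)[0][0])
            raise ValueError(f"bead {orphan} belongs to no rigid body or linker")
        for idx, _z, _k in self.membrane_restraints:
            if not 0 <= idx < n:
                raise ValueError(f"membrane restraint references unknown bead {idx}")
        for linker in self.linkers:
            for anchor in (linker.anchor_start, linker.anchor_end):
                if anchor is not None and not 0 <= anchor < n:
                    raise ValueError(f"linker {linker.id}: anchor bead {anchor} does not exist")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    @property
    def residue_types(self) -> list[str]:
        return [b.residue_type for b in self.beads]

    def type_indices(self) -> np.ndarray:
        """Index of each bead's residue type into :data:`AMINO_ACIDS`."""
        return np.array([AMINO_ACIDS.index(t) for t in self.residue_types], dtype=np.int64)

    def body_of(self) -> np.ndarray:
        """Per-bead rigid-body index, -1 for linker beads."""
        owners = np.full(self.n_beads, -1, dtype=np.int64)
        for bi, body in enumerate(self.rigid_bodies):
            owners[body.bead_indices] = bi
        return owners

    def initial_coords(self) -> np.ndarray:
        return np.array([b.position for b in self.beads])

    def locate(self, segment_id: str, position: int) -> int:
        """Bead index of residue number ``position`` (1-based within its
        segment) on a named rigid body or linker."""
        for body in self.rigid_bodies:
            if body.id == segment_id:
                return int(body.bead_indices[position - 1])
        for linker in self.linkers:
            if linker.id == segment_id:
                return int(linker.bead_indices[position - 1])
        raise KeyError(f"no segment named {segment_id!r}")


@dataclass
class Conformation:
    """One full set of bead coordinates with energy and provenance."""

    coords: np.ndarray
    energy: float = np.nan
    run_id: int = 0
    replica_temperature: float = np.nan
    sweep_index: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (scalar-first convention)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def rotvec_to_quat(v: np.ndarray) -> np.ndarray:
    """Quaternion of a rotation by |v| radians about axis v/|v|."""
    angle = np.linalg.norm(v)
    if angle < 1e-15:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = v / angle
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def _coords_of(conformation) -> np.ndarray:
    if isinstance(conformation, Conformation):
        return conformation.coords
    return np.asarray(conformation, dtype=float)


def radius_of_gyration(conformation) -> float:
    """Root-mean-square distance of beads from their centroid (unit masses)."""
    coords = _coords_of(conformation)
    if len(coords) < 1:
        raise ValueError("radius_of_gyration requires at least one bead")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def maximum_extension(conformation) -> float:
    """Largest bead-pair distance, Dmax."""
    coords = _coords_of(conformation)
    if len(coords) < 1:
        raise ValueError("maximum_extension requires at least one bead")
    if len(coords) == 1:
        warnings.warn("maximum_extension of a single bead is 0", stacklevel=2)
        return 0.0
    return float(pdist(coords).max())


def build_topology(structure_files: dict, topology_spec: dict) -> ComplexTopology:
    """Assemble a :class:`ComplexTopology` from atomic structures and a spec.

    Parameters
    ----------
    structure_files
        Mapping from logical structure name to PDB path.  Each rigid-body
        entry of the spec names one of these.
    topology_spec
        Dict (typically loaded from YAML) with keys:

        ``rigid_bodies``
            list of ``{id, structure, chain (optional), residues:
            [[first, last], ...] (optional, default all)}``
        ``linkers``
            list of ``{id, sequence, anchor_start, anchor_end}`` where each
            anchor is ``[segment_id, residue_position]`` (1-based within the
            segment) or null for a free terminus
        ``restraints``
            optional list of ``{bead: [segment_id, residue_position],
            z, k}`` harmonic z-tethers
        ``stoichiometry``
            optional label, e.g. ``"2:1:1"``

    Rigid bodies get one bead per residue at the Calpha position with the
    crystal coordinates as internal reference frame.  Linkers are laid out
    in extended geometry starting from their start anchor (or from the
    origin if free), with consecutive beads at the bond length.
    """
    from .io import read_pdb  # local import: io depends on topology types

    beads: list[Bead] = []
    bodies: list[RigidBody] = []
    linkers: list[LinkerChain] = []
    his_charge = float(topology_spec.get("his_charge", 0.0))

    for body_spec in topology_spec.get("rigid_bodies", []):
        name = body_spec["id"]
        structure = body_spec["structure"]
        if structure not in structure_files:
            raise KeyError(f"rigid body {name!r}: no structure file named {structure!r}")
        models = read_pdb(structure_files[structure])
        model = models[0]
        chain = body_spec.get("chain")
        mask = np.ones(len(model.res_ids), dtype=bool)
        if chain is not None:
            mask &= model.chain_ids == chain
        ranges = body_spec.get("residues")
        if ranges is not None:
            in_range = np.zeros(len(model.res_ids), dtype=bool)
            for first, last in ranges:
                in_range |= (model.res_ids >= first) & (model.res_ids <= last)
            mask &= in_range
            declared = set()
            for first, last in ranges:
                declared.update(range(first, last + 1))
            present = set(int(r) for r in model.res_ids[mask])
            missing = sorted(declared - present)
            if missing:
                raise ValueError(
                    f"rigid body {name!r}: declared residues missing from "
                    f"{structure!r}: {missing[:10]}"
                )
        if not mask.any():
            raise ValueError(f"rigid body {name!r}: no residues selected from {structure!r}")
        coords = model.coords[mask]
        res_types = [model.res_types[i] for i in np.where(mask)[0]]
        start = len(beads)
        indices = np.arange(start, start + len(coords))
        for idx, rtype, pos in zip(indices, res_types, coords):
            beads.append(Bead(int(idx), rtype, pos, residue_charge(rtype, his_charge), name))
        centroid = coords.mean(axis=0)
        bodies.append(RigidBody(name, indices, coords - centroid,
                                pose_translation=centroid.copy()))

    def _resolve(anchor):
        if anchor is None:
            return None
        seg, pos = anchor
        for body in bodies:
            if body.id == seg:
                return int(body.bead_indices[pos - 1])
        for linker in linkers:
            if linker.id == seg:
                return int(linker.bead_indices[pos - 1])
        raise ValueError(f"anchor segment {seg!r} not found")

    for linker_spec in topology_spec.get("linkers", []):
        name = linker_spec["id"]
        sequence = linker_spec["sequence"]
        bond = float(linker_spec.get("bond_length", CA_BOND_LENGTH))
        anchor_start = _resolve(linker_spec.get("anchor_start"))
        anchor_end = _resolve(linker_spec.get("anchor_end"))
        if anchor_start is not None:
            origin = beads[anchor_start].position
        else:
            origin = np.zeros(3)
        start = len(beads)
        indices = np.arange(start, start + len(sequence))
        for k, (idx, rtype) in enumerate(zip(indices, sequence)):
            pos = origin + np.array([bond * (k + 1), 0.0, 0.0])
            beads.append(Bead(int(idx), rtype, pos, residue_charge(rtype, his_charge), name))
        linkers.append(LinkerChain(name, indices, bond, anchor_start, anchor_end))

    restraints = []
    for r in topology_spec.get("restraints", []):
        topo_tmp = ComplexTopology(beads, bodies, linkers, [], "")
        seg, pos = r["bead"]
        restraints.append((topo_tmp.locate(seg, pos), float(r["z"]), float(r["k"])))

    return ComplexTopology(beads, bodies, linkers, restraints,
                           topology_spec.get("stoichiometry", ""))
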