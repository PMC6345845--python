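"""Coarse-grained potential energy.

Four contributions:

* bonded terms for linker chains — harmonic stretching between consecutive
  beads (and between chain ends and their anchor beads), harmonic bending,
  and a cosine torsion term;
* nonbonded residue-pair contacts — a square well of residue-type-dependent
  depth inside the contact range, with harmonic excluded-volume repulsion;
* screened Debye-Hueckel electrostatics between formal charges;
* membrane terms (membrane mode only) — harmonic z-restraints on anchored
  beads, a per-residue-type attraction ramp near the membrane plane, and a
  steep half-space repulsion below it.

The contact well depths derive from an established class of statistical
(knowledge-based) residue-residue potentials; since no single parameter set
is canonical at this resolution, the default matrix is a simple documented
hydrophobicity rule (deep wells for hydrophobic pairs, shallow for polar
pairs) and is fully user-replaceable from a 20x20 text table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _kernels
from ._kernels import COULOMB_KCAL
from .topology import AMINO_ACIDS, ComplexTopology, Conformation

#: Boltzmann constant, kcal/mol/K
KB_KCAL = 0.0019872041

# Kyte-Doolittle hydropathy, used only to build the default contact matrix
# and membrane well depths.
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def _hydrophobicity01() -> np.ndarray:
    """Kyte-Doolittle scale rescaled to [0, 1] over the 20 amino acids."""
    v = np.array([_KD[a] for a in AMINO_ACIDS])
    return (v - v.min()) / (v.max() - v.min())


def default_contact_matrix(eps0: float = 0.6) -> np.ndarray:
    """Symmetric 20x20 contact well depths (kcal/mol).

    eps_ij = eps0 * h_i * h_j with h the [0,1]-rescaled hydropathy, so
    hydrophobic-hydrophobic pairs get the deepest wells (eps0) and polar
    pairs approach zero.  A crude but transparent default; replace it from
    a text table for production work.
    """
    h = _hydrophobicity01()
    return eps0 * np.outer(h, h)


def default_membrane_depths(w0: float = 0.8) -> np.ndarray:
    """Per-residue-type membrane well depths (kcal/mol).

    Hydrophobic residues and the aromatic/basic residues common at membrane
    interfaces (Trp, Tyr, Arg, Lys) get the larger depths.
    """
    h = _hydrophobicity01()
    depths = w0 * h
    for aa in "WYRK":
        depths[AMINO_ACIDS.index(aa)] = 0.6 * w0
    return depths


def load_contact_matrix(path) -> np.ndarray:
    """Read a 20x20 whitespace-delimited well-depth table (kcal/mol),
    rows/columns in the order ACDEFGHIKLMNPQRSTVWY."""
    m = np.loadtxt(path)
    if m.shape != (20, 20):
        raise ValueError(f"contact matrix must be 20x20, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("contact matrix must be symmetric")
    return m


@dataclass
class EnergyModel:
    """Parameters of the coarse-grained force field (A, kcal/mol, rad)."""

    bond_k: float = 10.0
    bond_length: float = 3.8
    angle_k: float = 2.0
    angle_0: float = 2.094  # ~120 deg, typical Calpha pseudo-angle
    torsion_amp: float = 0.5
    contact_matrix: np.ndarray = field(default_factory=default_contact_matrix)
    contact_range: float = 6.5
    excluded_radius: float = 4.0
    repulsion_k: float = 10.0
    debye_length: float = 10.0  # ~150 mM monovalent salt
    dielectric: float = 80.0
    membrane_z: float = 20.0  # membrane surface plane, A
    membrane_depths: np.ndarray = field(default_factory=default_membrane_depths)
    membrane_range: float = 6.0
    wall_k: float = 100.0
    external: Optional[Callable[[np.ndarray], float]] = None

    def __post_init__(self):
        self.contact_matrix = np.asarray(self.contact_matrix, dtype=float)
        self.membrane_depths = np.asarray(self.membrane_depths, dtype=float)
        if self.contact_matrix.shape != (20, 20):
            raise ValueError("contact matrix must be 20x20")
        if not np.allclose(self.contact_matrix, self.contact_matrix.T, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        for name in ("contact_range", "excluded_radius", "debye_length",
                     "membrane_range"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class EnergyCalculator:
    """Precomputed tables tying an :class:`EnergyModel` to one topology.

    Holds the per-pair well depth and scaled charge-product matrices, the
    nonbonded exclusion mask (same rigid body, bonded neighbours), and the
    bonded index arrays — everything the sampler needs for fast full and
    incremental energy evaluation.
    """

    def __init__(self, topology: ComplexTopology, model: EnergyModel,
                 membrane: bool = False):
        self.topology = topology
        self.model = model
        self.membrane = membrane
        n = topology.n_beads

        tidx = topology.type_indices()
        self.eps_mat = model.contact_matrix[np.ix_(tidx, tidx)].copy()
        q = topology.charges
        self.qq_mat = np.outer(q, q) * (COULOMB_KCAL / model.dielectric)
        self.bead_depths = model.membrane_depths[tidx].copy()

        allowed = np.ones((n, n), dtype=bool)
        np.fill_diagonal(allowed, False)
        body = topology.body_of()
        same_body = (body[:, None] == body[None, :]) & (body[:, None] >= 0)
        allowed &= ~same_body

        bonds = []
        angles = []
        torsions = []
        for linker in topology.linkers:
            chain = list(linker.bead_indices)
            full = ([linker.anchor_start] if linker.anchor_start is not None else []) \
                + chain + ([linker.anchor_end] if linker.anchor_end is not None else [])
            for a, b in zip(full[:-1], full[1:]):
                bonds.append((a, b))
                allowed[a, b] = allowed[b, a] = False
            for a, b, c in zip(full[:-2], full[1:-1], full[2:]):
                angles.append((a, b, c))
            for quad in zip(full[:-3], full[1:-2], full[2:-1], full[3:]):
                torsions.append(quad)
        self.allowed = allowed
        self.bond_pairs = np.array(bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_b0 = np.full(len(bonds), model.bond_length)
        self.angle_triples = np.array(angles, dtype=np.int64).reshape(-1, 3)
        self.torsion_quads = np.array(torsions, dtype=np.int64).reshape(-1, 4)

        r = topology.membrane_restraints
        self.restraint_idx = np.array([x[0] for x in r], dtype=np.int64)
        self.restraint_z = np.array([x[1] for x in r], dtype=float)
        self.restraint_k = np.array([x[2] for x in r], dtype=float)

    # ---- full evaluations ------------------------------------------------
    def bonded(self, coords: np.ndarray) -> float:
        m = self.model
        return float(_kernels.bonded_total(
            coords, self.bond_pairs, self.bond_b0, m.bond_k,
            self.angle_triples, m.angle_0, m.angle_k,
            self.torsion_quads, m.torsion_amp))

    def nonbonded(self, coords: np.ndarray) -> float:
        m = self.model
        return float(_kernels.nonbonded_total(
            coords, self.eps_mat, self.qq_mat, self.allowed,
            m.excluded_radius, m.contact_range, m.repulsion_k, m.debye_length))

    def membrane_energy(self, coords: np.ndarray) -> float:
        m = self.model
        z = np.ascontiguousarray(coords[:, 2])
        e = _kernels.membrane_terms(z, self.bead_depths, m.membrane_z,
                                    m.membrane_range, m.wall_k)
        e += _kernels.restraint_terms(z, self.restraint_idx, self.restraint_z,
                                      self.restraint_k)
        return float(e)

    def total(self, coords: np.ndarray) -> float:
        e = self.bonded(coords) + self.nonbonded(coords)
        if self.membrane:
            e += self.membrane_energy(coords)
        if self.model.external is not None:
            e += self.model.external(coords)
        return e

    # ---- incremental evaluation for MC moves -----------------------------
    def fast_delta(self, coords: np.ndarray, trial: np.ndarray,
                   moved_idx: np.ndarray, new_moved: np.ndarray,
                   is_moved: np.ndarray) -> float:
        """Single-kernel energy change for one move; leaves the trial
        coordinates in the scratch buffer ``trial``."""
        m = self.model
        d = float(_kernels.total_delta(
            coords, trial, new_moved, moved_idx, is_moved,
            self.eps_mat, self.qq_mat, self.allowed,
            m.excluded_radius, m.contact_range, m.repulsion_k, m.debye_length,
            self.bond_pairs, self.bond_b0, m.bond_k,
            self.angle_triples, m.angle_0, m.angle_k,
            self.torsion_quads, m.torsion_amp,
            self.membrane, self.bead_depths, m.membrane_z, m.membrane_range,
            m.wall_k, self.restraint_idx, self.restraint_z, self.restraint_k))
        if m.external is not None:
            d += m.external(trial) - m.external(coords)
        return d

    def delta(self, coords: np.ndarray, moved_idx: np.ndarray,
              new_moved: np.ndarray, is_moved: np.ndarray) -> float:
        """Energy change if beads moved_idx take coordinates new_moved.

        Valid for single-bead and rigid-set moves (intra-set distances
        unchanged).  coords is the current full coordinate array.
        """
        m = self.model
        d = _kernels.nonbonded_delta(
            coords, new_moved, moved_idx, is_moved, self.eps_mat, self.qq_mat,
            self.allowed, m.excluded_radius, m.contact_range, m.repulsion_k,
            m.debye_length)
        # bonded set is tiny; recompute in full rather than tracking deltas
        if len(self.bond_pairs):
            old_b = self.bonded(coords)
            trial = coords.copy()
            trial[moved_idx] = new_moved
            d += self.bonded(trial) - old_b
        if self.membrane:
            z_old = np.ascontiguousarray(coords[moved_idx, 2])
            z_new = np.ascontiguousarray(new_moved[:, 2])
            depths = np.ascontiguousarray(self.bead_depths[moved_idx])
            d += _kernels.membrane_terms(z_new, depths, m.membrane_z,
                                         m.membrane_range, m.wall_k)
            d -= _kernels.membrane_terms(z_old, depths, m.membrane_z,
                                         m.membrane_range, m.wall_k)
            if len(self.restraint_idx):
                moved_set = is_moved[self.restraint_idx]
                if moved_set.any():
                    trial_z = coords[:, 2].copy()
                    trial_z[moved_idx] = new_moved[:, 2]
                    d += _kernels.restraint_terms(
                        np.ascontiguousarray(trial_z), self.restraint_idx,
                        self.restraint_z, self.restraint_k)
                    d -= _kernels.restraint_terms(
                        np.ascontiguousarray(coords[:, 2]), self.restraint_idx,
                        self.restraint_z, self.restraint_k)
        if self.model.external is not None:
            trial = coords.copy()
            trial[moved_idx] = new_moved
            d += self.model.external(trial) - self.model.external(coords)
        return float(d)


def _coords_of(conformation) -> np.ndarray:
    if isinstance(conformation, Conformation):
        return np.ascontiguousarray(conformation.coords)
    return np.ascontiguousarray(conformation, dtype=float)


def bonded_energy(conformation, topology: ComplexTopology,
                  model: EnergyModel) -> float:
    """Linker stretching + bending + torsion energy (kcal/mol)."""
    return EnergyCalculator(topology, model).bonded(_coords_of(conformation))


def nonbonded_energy(conformation, topology: ComplexTopology,
                     model: EnergyModel) -> float:
    """Contact wells + excluded volume + screened electrostatics (kcal/mol).

    Pairs within one rigid body and bonded neighbours are excluded.
    """
    return EnergyCalculator(topology, model).nonbonded(_coords_of(conformation))


def membrane_energy(conformation, topology: ComplexTopology,
                    model: EnergyModel) -> float:
    """Anchor restraints + membrane attraction + impenetrability (kcal/mol)."""
    calc = EnergyCalculator(topology, model, membrane=True)
    return calc.membrane_energy(_coords_of(conformation))


def total_energy(conformation, topology: ComplexTopology, model: EnergyModel,
                 membrane: bool = False) -> float:
    calc = EnergyCalculator(topology, model, membrane=membrane)
    return calc.total(_coords_of(conformation))
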