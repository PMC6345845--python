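"""Readers and writers: PDB structures, 3-column SAXS curves, TSV tables,
YAML configs, and JSON run manifests."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .saxs import SAXSProfile
from .topology import (ONE_TO_THREE, THREE_TO_ONE, ComplexTopology,
                       Conformation)


@dataclass
class PDBModel:
    """Per-residue Calpha records of one MODEL."""

    coords: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    res_types: list[str]


def read_pdb(path, model_policy: str = "all") -> list[PDBModel]:
    """Read Calpha coordinates per residue from a (possibly multi-MODEL) PDB.

    model_policy "all" returns one PDBModel per MODEL record; "first"
    returns only the first.  Residues without a CA record are skipped;
    a file with no CA records at all is an error.
    """
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite reports the offending line
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    ca = stack[:, stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"{path}: no CA records found")
    models = []
    n_models = 1 if model_policy == "first" else ca.stack_depth()
    for m in range(n_models):
        frame = ca[m]
        res_types = []
        for name in frame.res_name:
            res_types.append(THREE_TO_ONE.get(name, "G"))
        models.append(PDBModel(
            coords=np.asarray(frame.coord, dtype=float),
            res_ids=np.asarray(frame.res_id, dtype=int),
            chain_ids=np.asarray(frame.chain_id),
            res_types=res_types,
        ))
    return models


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_pdb(path, topology: ComplexTopology, conformations) -> None:
    """Write conformations as a multi-MODEL Calpha-only PDB.

    One chain per rigid body / linker, residues numbered 1.. within each
    chain, coordinates at PDB precision (3 decimals).
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(conformations, Conformation):
        conformations = [conformations]
    n = topology.n_beads
    segments = [b.id for b in topology.rigid_bodies] + [l.id for l in topology.linkers]
    chain_of_segment = {seg: _CHAIN_IDS[k % len(_CHAIN_IDS)]
                        for k, seg in enumerate(segments)}

    template = struc.AtomArray(n)
    res_counter: dict[str, int] = {}
    for i, bead in enumerate(topology.beads):
        res_counter[bead.member_of] = res_counter.get(bead.member_of, 0) + 1
        template.chain_id[i] = chain_of_segment[bead.member_of]
        template.res_id[i] = res_counter[bead.member_of]
        template.res_name[i] = ONE_TO_THREE[bead.residue_type]
        template.atom_name[i] = "CA"
        template.element[i] = "C"
        template.hetero[i] = False

    coords = np.array([np.asarray(c.coords if isinstance(c, Conformation) else c,
                                  dtype=float) for c in conformations])
    stack = struc.from_template(template, coords)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    _atomic_write(path, "".join(line + "\n" for line in pdb_file.lines))


def read_saxs_dat(path) -> SAXSProfile:
    """Read an ATSAS-style whitespace-delimited (q, I[, sigma]) file."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSProfile(data[:, 0], data[:, 1], sigma)


def write_saxs_dat(path, profile: SAXSProfile, header: str = "") -> None:
    """Write a 3-column (or 2-column, if no sigma) SAXS .dat file."""
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    lines.append("# q[1/A]  I(q)  sigma" if profile.sigma is not None
                 else "# q[1/A]  I(q)")
    for i in range(len(profile)):
        if profile.sigma is not None:
            lines.append(f"{profile.q[i]:.6e} {profile.intensity[i]:.6e} "
                         f"{profile.sigma[i]:.6e}")
        else:
            lines.append(f"{profile.q[i]:.6e} {profile.intensity[i]:.6e}")
    _atomic_write(path, "\n".join(lines) + "\n")


def write_tsv(path, header: list[str], rows) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    _atomic_write(path, "\n".join(lines) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _atomic_write(path, text: str) -> None:
    """Write text then rename, so readers never see partial files."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, seed, stage records."""

    config: dict
    seed: int
    version: str = "0.1.0"
    stages: list[dict] = field(default_factory=list)

    def record_stage(self, name: str, outputs: list[str]) -> None:
        self.stages.append({
            "stage": name,
            "outputs": {str(p): file_digest(p) for p in outputs},
        })

    def save(self, path) -> None:
        _atomic_write(path, json.dumps({
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
        }, indent=2, default=str))
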