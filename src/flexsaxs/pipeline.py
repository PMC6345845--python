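"""End-to-end orchestration: simulate -> profile -> select -> cluster
(solution mode) or simulate -> membrane-analyze (membrane mode)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .clustering import cluster_medoids, default_pair_set, drms_matrix, qt_cluster
from .energy import EnergyModel
from .io import (RunManifest, read_saxs_dat, write_pdb, write_saxs_dat,
                 write_tsv)
from .membrane_analysis import contact_probability, extension_stats
from .sampler import REMCConfig, run_remc
from .saxs import debye_intensity
from .selection import minimum_ensemble, rank_structures, select_top_n
from .topology import maximum_extension, radius_of_gyration


def run_pipeline(topology, config: dict, out_dir, seed: int = 0,
                 target=None) -> dict:
    """Run the full analysis described by a config dict.

    config keys: ``mode`` ("solution" | "membrane"), ``remc`` (REMCConfig
    fields), ``energy`` (EnergyModel fields, optional), ``selection``
    (top_n, max_size, chi2_accept, prune), ``clustering`` (cutoff),
    ``q_grid`` (n, q_max), ``z0`` (membrane thresholds, A).  ``target``
    may be a SAXSProfile or a path to a .dat file.

    Writes TSVs, PDBs and a manifest under out_dir and returns a dict of
    in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode", "solution")
    manifest = RunManifest(config=config, seed=seed)
    results: dict = {}

    energy_cfg = dict(config.get("energy", {}))
    model = EnergyModel(**energy_cfg)
    remc_cfg = dict(config.get("remc", {}))
    remc_cfg.setdefault("seed", seed)
    remc_cfg["membrane"] = mode == "membrane"
    if mode == "membrane":
        remc_cfg.setdefault("n_replicas", 8)
        remc_cfg.setdefault("save_policy", "lowest")
    remc = REMCConfig(**remc_cfg)

    pool = run_remc(topology, model, remc)
    results["pool"] = pool
    sidecar = out / "pool.tsv"
    write_tsv(sidecar,
              ["index", "run", "temperature", "sweep", "energy", "rg", "dmax"],
              [(i, c.run_id, f"{c.replica_temperature:.2f}", c.sweep_index,
                f"{c.energy:.4f}", f"{radius_of_gyration(c):.3f}",
                f"{maximum_extension(c):.3f}")
               for i, c in enumerate(pool.conformations)])
    pdb_path = out / "pool.pdb"
    write_pdb(pdb_path, topology, pool.conformations)
    manifest.record_stage("simulate", [sidecar, pdb_path])

    if mode == "membrane":
        thresholds = config.get("z0", [20.0, 22.5, 25.0])
        rows = []
        profiles = {z0: contact_probability(pool, z0) for z0 in thresholds}
        for i, bead in enumerate(topology.beads):
            rows.append([bead.member_of, i]
                        + [f"{profiles[z0].probabilities[i]:.4f}"
                           for z0 in thresholds])
        contact_path = out / "contacts.tsv"
        write_tsv(contact_path,
                  ["segment", "bead"] + [f"p(z<{z0}A)" for z0 in thresholds],
                  rows)
        stats = extension_stats(pool)
        hist_path = out / "extension_hist.tsv"
        write_tsv(hist_path, ["dmax_bin_lo", "dmax_count", "rg_bin_lo", "rg_count"],
                  [(f"{stats['dmax']['bin_edges'][k]:.2f}",
                    stats["dmax"]["histogram"][k],
                    f"{stats['rg']['bin_edges'][k]:.2f}",
                    stats["rg"]["histogram"][k])
                   for k in range(len(stats["dmax"]["histogram"]))])
        manifest.record_stage("membrane-analyze", [contact_path, hist_path])
        results["contacts"] = profiles
        results["extension"] = stats
    else:
        if target is None:
            raise ValueError("solution mode requires a target SAXS profile")
        if isinstance(target, (str, Path)):
            target = read_saxs_dat(target)
        q_cfg = config.get("q_grid", {})
        profiles = [debye_intensity(c, target.q) for c in pool.conformations]
        ranked = rank_structures(profiles, target)
        sel_cfg = config.get("selection", {})
        top_n = min(sel_cfg.get("top_n", 100), len(ranked))
        top_ids = select_top_n(ranked, top_n)
        rank_path = out / "ranked.tsv"
        write_tsv(rank_path, ["id", "chi2"],
                  [(i, f"{c:.6f}") for i, c in ranked])
        ens = minimum_ensemble(profiles, target,
                               max_size=sel_cfg.get("max_size", 2),
                               chi2_accept=sel_cfg.get("chi2_accept", 1.5),
                               prune=sel_cfg.get("prune", 200))
        kratky_path = out / "kratky.tsv"
        write_tsv(kratky_path, ["q", "q2I_exp"],
                  [(f"{q:.5f}", f"{q * q * i_exp:.6e}")
                   for q, i_exp in zip(target.q, target.intensity)])
        top_pdb = out / "top.pdb"
        write_pdb(top_pdb, topology, [pool.conformations[i] for i in top_ids])
        manifest.record_stage("select", [rank_path, kratky_path, top_pdb])

        cutoff = config.get("clustering", {}).get("cutoff", 5.0)
        pair_set = default_pair_set(topology, seed=seed)
        top_confs = [pool.conformations[i] for i in top_ids]
        mat = drms_matrix(top_confs, pair_set)
        clusters = qt_cluster(top_ids, mat, cutoff)
        medoids = cluster_medoids(clusters, top_ids, mat)
        member_of = clusters.membership()
        cluster_path = out / "clusters.tsv"
        write_tsv(cluster_path, ["id", "cluster"],
                  [(i, member_of[i]) for i in top_ids])
        manifest.record_stage("cluster", [cluster_path])
        results.update(ranked=ranked, top_ids=top_ids, ensemble=ens,
                       clusters=clusters, medoids=medoids)

    manifest.save(out / "manifest.json")
    return results
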