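"""Analysis of membrane-mode trajectory pools.

Membrane contact is defined geometrically: a residue bead is in contact
when its z coordinate lies below a threshold z0, conventionally scanned
between 20 and 25 A (2-2.5 nm) above the bilayer midplane convention used
by the sampling model (membrane surface at z = 20 A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sampler import TrajectoryPool
from .topology import maximum_extension, radius_of_gyration


@dataclass
class ContactProfile:
    """Per-bead membrane contact probability at one threshold."""

    probabilities: np.ndarray
    z0: float
    pool_size: int

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0) or np.any(self.probabilities > 1):
            raise ValueError("contact probabilities must lie in [0, 1]")


def _pool_coords(pool) -> np.ndarray:
    if isinstance(pool, TrajectoryPool):
        return pool.coords_array()
    arr = np.asarray([c.coords if hasattr(c, "coords") else c for c in pool],
                     dtype=float)
    return arr


def contact_probability(pool, z0: float) -> ContactProfile:
    """Fraction of pool conformations in which each bead has z < z0."""
    coords = _pool_coords(pool)
    if coords.size == 0:
        raise ValueError("empty pool")
    if not 20.0 <= z0 <= 25.0:
        warnings.warn(f"z0 = {z0} A is outside the conventional 20-25 A "
                      "(2-2.5 nm) scan range", stacklevel=2)
    probs = np.mean(coords[:, :, 2] < z0, axis=0)
    return ContactProfile(probs, z0, len(coords))


def extension_stats(pool, n_bins: int = 20) -> dict:
    """Order statistics and histograms of per-conformation Dmax and Rg."""
    coords = _pool_coords(pool)
    if coords.size == 0:
        raise ValueError("empty pool")
    dmax = np.array([maximum_extension(c) for c in coords])
    rg = np.array([radius_of_gyration(c) for c in coords])
    out = {}
    for name, values in (("dmax", dmax), ("rg", rg)):
        hist, edges = np.histogram(values, bins=n_bins)
        out[name] = {
            "min": float(values.min()),
            "max": float(values.max()),
            "mean": float(values.mean()),
            "std": float(values.std()),
            "values": values,
            "histogram": hist,
            "bin_edges": edges,
        }
    return out
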