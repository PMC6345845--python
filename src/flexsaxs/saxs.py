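"""Theoretical scattering, Guinier analysis, and chi-square fitting.

The model intensity of a bead conformation is the orientation-averaged
Debye double sum

    I(q) = sum_ij f_i(q) f_j(q) sin(q r_ij) / (q r_ij),

with the q -> 0 and r -> 0 limits taken as 1.  By default every residue
carries the same constant effective form factor; a per-residue-type table
may be supplied.  Excluded-volume/solvent-contrast corrections are not
applied (documented limitation).

Discrepancy against a measured curve I_exp(q) with per-point errors
sigma(q) is the chi-square

    chi2_k = sum_i (I_exp(q_i) - a I_k(q_i))^2 / sigma^2(q_i),

where the scale a is set by d(chi2)/da = 0, giving the closed form
a = sum(I_exp I_k / sigma^2) / sum(I_k^2 / sigma^2).  The headline value
reported everywhere is the reduced statistic chi2 / N_q; the raw sum is
kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import _kernels
from .topology import Conformation


@dataclass
class SAXSProfile:
    """A scattering curve on a strictly increasing q grid (1/A).

    sigma is present for measured/synthetic data and None for theoretical
    model profiles.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if len(self.q) and (np.any(np.diff(self.q) <= 0) or self.q[0] < 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be strictly positive")

    def __len__(self):
        return len(self.q)


@dataclass
class FitResult:
    """Scale and chi-square of one model profile against a target."""

    scale: float
    chi2: float  # reduced: raw sum / n_points
    chi2_raw: float
    n_points: int


@dataclass
class GuinierResult:
    rg: float
    i0: float
    window: tuple[int, int]  # [start, stop) indices into the profile
    qmax_rg: float


def _form_factor_vector(residue_types: Sequence[str] | None, n: int,
                        form_factors) -> np.ndarray:
    if form_factors is None:
        return np.ones(n)
    if np.isscalar(form_factors):
        return np.full(n, float(form_factors))
    if isinstance(form_factors, Mapping):
        if residue_types is None:
            raise ValueError("per-type form factors require residue types")
        return np.array([form_factors[t] for t in residue_types], dtype=float)
    ff = np.asarray(form_factors, dtype=float)
    if ff.shape != (n,):
        raise ValueError("form factor array must have one entry per bead")
    return ff


def debye_intensity(conformation, q_grid, form_factors=None,
                    residue_types: Sequence[str] | None = None) -> SAXSProfile:
    """Debye-formula intensity of a bead conformation.

    form_factors may be None (all 1), a scalar, a per-bead array, or a
    mapping residue_type -> f (then residue_types must be given).
    """
    coords = conformation.coords if isinstance(conformation, Conformation) \
        else np.asarray(conformation, dtype=float)
    if coords.size == 0:
        raise ValueError("cannot compute scattering of an empty conformation")
    q_grid = np.ascontiguousarray(q_grid, dtype=float)
    f = _form_factor_vector(residue_types, len(coords), form_factors)
    if len(coords) == 1:
        return SAXSProfile(q_grid, np.full(len(q_grid), f[0] ** 2))
    dists = np.ascontiguousarray(pdist(coords))
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    ff_prod = np.ascontiguousarray(f[iu] * f[ju])
    self_term = float(np.sum(f**2))
    intensity = _kernels.debye_sum(dists, ff_prod, q_grid, self_term)
    return SAXSProfile(q_grid, intensity)


def ensemble_intensity(profiles: Sequence[SAXSProfile], weights) -> SAXSProfile:
    """Pointwise weighted mean intensity of profiles on a common q grid."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(profiles):
        raise ValueError("one weight per profile required")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    q = profiles[0].q
    for p in profiles[1:]:
        if len(p.q) != len(q) or not np.allclose(p.q, q):
            raise ValueError("profiles must share a common q grid")
    mix = np.einsum("k,kq->q", weights, np.array([p.intensity for p in profiles]))
    return SAXSProfile(q.copy(), mix)


def interpolate_to(profile: SAXSProfile, q_grid: np.ndarray) -> SAXSProfile:
    """Linear interpolation of a model profile onto a target q grid.

    Extrapolation outside the model's q range is refused.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid[0] < profile.q[0] - 1e-12 or q_grid[-1] > profile.q[-1] + 1e-12:
        raise ValueError("target q grid extends beyond the model profile "
                         "(extrapolation forbidden)")
    return SAXSProfile(q_grid, np.interp(q_grid, profile.q, profile.intensity))


def optimal_scale(target_i: np.ndarray, model_i: np.ndarray,
                  sigma: np.ndarray) -> float:
    """Closed-form least-squares intensity scale from d(chi2)/da = 0."""
    w = 1.0 / sigma**2
    denom = float(np.sum(w * model_i**2))
    if denom == 0:
        raise ValueError("model profile is identically zero")
    return float(np.sum(w * target_i * model_i)) / denom


def chi2_fit(target: SAXSProfile, model: SAXSProfile) -> FitResult:
    """Fit a model profile to a target curve with a free intensity scale.

    The model is interpolated onto the target grid if the grids differ.
    Returns the optimal scale, the reduced chi-square (raw / N_q) and the
    raw sum.
    """
    if target.sigma is None:
        raise ValueError("target profile must carry error estimates")
    if len(model.q) != len(target.q) or not np.allclose(model.q, target.q):
        model = interpolate_to(model, target.q)
    a = optimal_scale(target.intensity, model.intensity, target.sigma)
    resid = (target.intensity - a * model.intensity) / target.sigma
    raw = float(np.sum(resid**2))
    n = len(target)
    return FitResult(scale=a, chi2=raw / n, chi2_raw=raw, n_points=n)


def guinier_fit(profile: SAXSProfile, qrg_limit: float = 1.3,
                min_points: int = 5) -> GuinierResult:
    """Estimate Rg and I(0) from the low-q Guinier region.

    Fits ln I = ln I0 - q^2 Rg^2 / 3 by (sigma-weighted, when available)
    linear regression, starting from the widest window and shrinking it
    until qmax * Rg <= qrg_limit holds at a fixed point.
    """
    import warnings

    q = profile.q
    intensity = profile.intensity
    usable = intensity > 0
    if np.any(~usable):
        warnings.warn("dropping non-positive intensities from Guinier window",
                      stacklevel=2)
    if profile.sigma is not None:
        weight_full = (intensity / profile.sigma) ** 2  # var of ln I = (sigma/I)^2
    else:
        weight_full = np.ones_like(intensity)

    idx = np.where(usable)[0]
    if len(idx) < min_points:
        raise ValueError("too few usable low-q points for a Guinier fit")
    stop = len(idx)

    def _fit(active):
        x = q[active] ** 2
        y = np.log(intensity[active])
        w = weight_full[active]
        coeffs = np.polyfit(x, y, 1, w=np.sqrt(w))
        slope, icpt = coeffs[0], coeffs[1]
        if slope >= 0:
            return None
        return float(np.sqrt(-3.0 * slope)), float(np.exp(icpt))

    prev_stop = None
    rg = i0 = None
    while stop >= min_points:
        active = idx[:stop]
        result = _fit(active)
        if result is None:
            stop -= 1
            continue
        rg, i0 = result
        qmax = q[active[-1]]
        if qmax * rg <= qrg_limit:
            break
        new_stop = int(np.searchsorted(q[idx], qrg_limit / rg, side="right"))
        if new_stop >= stop:
            new_stop = stop - 1
        if new_stop == prev_stop:
            break
        prev_stop = stop
        stop = new_stop
    else:
        raise ValueError("no stable Guinier window: qmin * Rg exceeds the "
                         f"validity limit {qrg_limit}")
    if rg is None:
        raise ValueError("Guinier fit failed: intensity does not decay")
    active = idx[:stop]
    return GuinierResult(rg=rg, i0=i0,
                         window=(int(active[0]), int(active[-1]) + 1),
                         qmax_rg=float(q[active[-1]] * rg))
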