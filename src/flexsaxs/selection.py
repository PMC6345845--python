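"""Ranking pool structures against a target curve and minimum-ensemble search.

A pool of simulated conformations rarely contains a single structure that
explains the scattering of a flexible complex; the minimum-ensemble method
looks for the smallest set of structures whose (equal-weight) average
intensity, jointly rescaled, fits the data below an acceptance chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .saxs import SAXSProfile, chi2_fit, ensemble_intensity, interpolate_to


@dataclass
class Ensemble:
    """A minimal set of pool members explaining the target profile."""

    member_ids: tuple[int, ...]
    weights: np.ndarray
    chi2: float
    scale: float
    accepted: bool  # True if chi2 <= the acceptance threshold

    @property
    def size(self) -> int:
        return len(self.member_ids)


def rank_structures(pool_profiles: Sequence[SAXSProfile],
                    target: SAXSProfile,
                    ids: Sequence[int] | None = None) -> list[tuple[int, float]]:
    """Reduced chi-square of every pool profile against the target,
    ascending; ties broken by pool id."""
    if len(pool_profiles) == 0:
        raise ValueError("empty pool")
    if ids is None:
        ids = range(len(pool_profiles))
    scored = [(int(i), chi2_fit(target, p).chi2)
              for i, p in zip(ids, pool_profiles)]
    return sorted(scored, key=lambda t: (t[1], t[0]))


def select_top_n(ranked: Sequence[tuple[int, float]], n: int) -> list[int]:
    """Ids of the n best-fitting structures."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(ranked):
        raise ValueError(f"cannot select {n} from a pool of {len(ranked)}")
    return [i for i, _ in ranked[:n]]


def minimum_ensemble(pool_profiles: Sequence[SAXSProfile],
                     target: SAXSProfile,
                     max_size: int = 2,
                     chi2_accept: float = 1.5,
                     prune: int = 200,
                     ids: Sequence[int] | None = None) -> Ensemble:
    """Smallest equal-weight ensemble fitting the target.

    Sizes s = 1, 2, ..., max_size are tried in order; for each size every
    equal-weight combination over the pruned candidate pool (the `prune`
    best single structures) is evaluated with the joint closed-form scale.
    The first size whose best reduced chi-square reaches chi2_accept wins;
    if no size does, the overall best combination is returned with
    ``accepted=False``.

    For an equal-weight mixture M = mean_k I_k with fitted scale a, the
    weighted residual sum is  S_yy - (sum w I_exp M)^2 / (sum w M^2), so
    the exhaustive search only needs the cross vector u_k and the Gram
    matrix V_kl of the candidate profiles — exact, no per-combination
    refitting.
    """
    if max_size < 1:
        raise ValueError("max_size must be at least 1")
    if target.sigma is None:
        raise ValueError("target profile must carry error estimates")
    if ids is None:
        ids = list(range(len(pool_profiles)))
    ranked = rank_structures(pool_profiles, target, ids)
    id_to_profile = dict(zip(ids, pool_profiles))
    candidates = [i for i, _ in ranked[:prune]]

    w = 1.0 / target.sigma**2
    mat = np.array([
        interpolate_to(id_to_profile[i], target.q).intensity
        if not np.array_equal(id_to_profile[i].q, target.q)
        else id_to_profile[i].intensity
        for i in candidates
    ])
    s_yy = float(np.sum(w * target.intensity**2))
    u = mat @ (w * target.intensity)  # cross terms, per candidate
    gram = (mat * w) @ mat.T
    n_q = len(target)

    def _combo_fit(combo_idx: tuple[int, ...]):
        sel = list(combo_idx)
        num = float(u[sel].mean())
        den = float(gram[np.ix_(sel, sel)].mean())
        if den <= 0:
            raise ValueError("degenerate (all-zero) model combination")
        scale = num / den
        chi2_raw = s_yy - num * num / den
        return max(chi2_raw, 0.0) / n_q, scale

    best_overall = None
    for size in range(1, max_size + 1):
        if size > len(candidates):
            break
        best_for_size = None
        for combo in combinations(range(len(candidates)), size):
            chi2, scale = _combo_fit(combo)
            member_ids = tuple(candidates[c] for c in combo)
            key = (chi2, member_ids)
            if best_for_size is None or key < best_for_size[0]:
                best_for_size = (key, member_ids, scale)
        (chi2, _), member_ids, scale = best_for_size
        if best_overall is None or chi2 < best_overall[0]:
            best_overall = (chi2, member_ids, scale)
        if chi2 <= chi2_accept:
            return Ensemble(member_ids, np.full(size, 1.0 / size),
                            chi2, scale, accepted=True)
    chi2, member_ids, scale = best_overall
    return Ensemble(member_ids, np.full(len(member_ids), 1.0 / len(member_ids)),
                    chi2, scale, accepted=False)


def ensemble_profile(ensemble: Ensemble,
                     pool_profiles: Sequence[SAXSProfile],
                     ids: Sequence[int] | None = None) -> SAXSProfile:
    """Weighted mean profile of an ensemble's members."""
    if ids is None:
        ids = list(range(len(pool_profiles)))
    lookup = dict(zip(ids, pool_profiles))
    return ensemble_intensity([lookup[i] for i in ensemble.member_ids],
                              ensemble.weights)
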