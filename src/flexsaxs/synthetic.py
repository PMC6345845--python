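"""Synthetic fixtures: toy complexes, conformation pools, noisy SAXS data.

No public SAXS curve accompanies the complexes this package targets, so
end-to-end testing relies on fully synthetic experiments in which the
generating structure or ensemble is known: a "dumbbell" of two rigid
globular bead clusters joined by a flexible linker stands in for a
two-domain complex, and noisy target curves are drawn from its known
mixture intensity with a truthful per-point error model

    sigma(q) = alpha + beta * I(q),   alpha, beta >= 0.

Everything is bit-reproducible from the generator seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .saxs import SAXSProfile, debye_intensity, ensemble_intensity
from .topology import (AMINO_ACIDS, Bead, ComplexTopology, Conformation,
                       LinkerChain, RigidBody, residue_charge)

#: residue volume used to size globular bodies (A^3 per residue)
_RESIDUE_VOLUME = 110.0


@dataclass
class SyntheticSpec:
    """Recipe for a toy rigid-bodies-plus-linker complex.

    geometry presets: "compact" places the two bodies nearly in contact,
    "extended" separates them by the full linker contour length.
    """

    n_bodies: int = 2
    beads_per_body: int = 30
    linker_length: int = 15
    geometry: str = "compact"  # "compact" | "extended"
    noise_alpha: float = 0.0
    noise_beta: float = 0.01
    anchored: bool = False  # add membrane z-restraints on each body
    seed: int = 0

    def __post_init__(self):
        if self.n_bodies < 1 or self.beads_per_body < 1:
            raise ValueError("bodies must contain at least one bead")
        if self.geometry not in ("compact", "extended"):
            raise ValueError("geometry must be 'compact' or 'extended'")
        if self.noise_alpha < 0 or self.noise_beta < 0:
            raise ValueError("noise parameters must be non-negative")


def _globular_cluster(n: int, rng: np.random.Generator) -> np.ndarray:
    """n bead positions roughly uniform in a sphere of protein-like density."""
    radius = (3.0 * n * _RESIDUE_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius * rng.random(n)[:, None] ** (1.0 / 3.0)
    return pts


def make_toy_complex(spec: SyntheticSpec) -> tuple[ComplexTopology, Conformation]:
    """Deterministic toy topology plus its reference conformation.

    Bodies are globular bead clusters laid out along x, joined in series
    by flexible linkers; body separation follows the geometry preset.
    With ``anchored=True`` each body grows a short flexible tail whose
    terminal bead is tethered to z = 20 A by a soft spring
    (k = 0.1 kcal/mol/A^2) — lipid anchors (e.g. geranylgeranylated
    cysteines) sit on disordered termini, so the tether acts on a mobile
    bead rather than dragging a whole rigid body.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    contour = spec.linker_length * 3.8
    body_radius = (3.0 * spec.beads_per_body * _RESIDUE_VOLUME / (4 * np.pi)) ** (1 / 3)
    if spec.geometry == "extended":
        gap = contour + 2 * body_radius
    else:
        gap = 2.2 * body_radius

    beads: list[Bead] = []
    bodies: list[RigidBody] = []
    linkers: list[LinkerChain] = []
    aa = np.array(list(AMINO_ACIDS))

    def _add_body(b: int) -> RigidBody:
        centre = np.array([b * gap, 0.0, 20.0 if spec.anchored else 0.0])
        local = _globular_cluster(spec.beads_per_body, rng)
        local -= local.mean(axis=0)
        start = len(beads)
        idx = np.arange(start, start + spec.beads_per_body)
        types = aa[rng.integers(0, 20, spec.beads_per_body)]
        for i, t, p in zip(idx, types, local + centre):
            beads.append(Bead(int(i), str(t), p, residue_charge(str(t)), f"body{b}"))
        body = RigidBody(f"body{b}", idx, local, pose_translation=centre)
        bodies.append(body)
        return body

    prev = _add_body(0)
    for b in range(1, spec.n_bodies):
        nxt = _add_body(b)
        if spec.linker_length:
            anchor_a = int(prev.bead_indices[-1])
            anchor_b = int(nxt.bead_indices[0])
            start = len(beads)
            idx = np.arange(start, start + spec.linker_length)
            types = aa[rng.integers(0, 20, spec.linker_length)]
            pa, pb = beads[anchor_a].position, beads[anchor_b].position
            ts = np.arange(1, spec.linker_length + 1) / (spec.linker_length + 1)
            for i, t, s in zip(idx, types, ts):
                pos = pa + s * (pb - pa)
                beads.append(Bead(int(i), str(t), pos, residue_charge(str(t)),
                                  f"linker{b - 1}"))
            linkers.append(LinkerChain(f"linker{b - 1}", idx,
                                       anchor_start=anchor_a, anchor_end=anchor_b))
        prev = nxt

    restraints = []
    if spec.anchored:
        tail_len = 5
        for b, body in enumerate(bodies):
            root = int(body.bead_indices[0])
            start = len(beads)
            idx = np.arange(start, start + tail_len)
            types = aa[rng.integers(0, 20, tail_len)]
            root_pos = beads[root].position
            for j, (i, t) in enumerate(zip(idx, types)):
                pos = root_pos + np.array([0.0, 0.0, -3.8 * (j + 1)])
                pos[2] = max(pos[2], 20.5)  # stay above the membrane plane
                beads.append(Bead(int(i), str(t), pos, residue_charge(str(t)),
                                  f"tail{b}"))
            linkers.append(LinkerChain(f"tail{b}", idx, anchor_start=root))
            restraints.append((int(idx[-1]), 20.0, 0.1))

    topo = ComplexTopology(beads, bodies, linkers, restraints,
                           stoichiometry=f"{spec.n_bodies} bodies")
    return topo, Conformation(topo.initial_coords())


def synthesize_saxs(conformations, weights, q_grid, noise_alpha: float = 0.0,
                    noise_beta: float = 0.01, seed: int = 0,
                    form_factors=None) -> SAXSProfile:
    """Noisy synthetic target curve from a known generating ensemble.

    The noiseless ensemble intensity receives Gaussian noise of standard
    deviation sigma(q) = alpha + beta * I(q); the sigma column records the
    generating standard deviation truthfully (zero noise yields a profile
    without a sigma column).
    """
    if noise_alpha < 0 or noise_beta < 0:
        raise ValueError("noise parameters must be non-negative")
    weights = np.asarray(weights, dtype=float)
    profiles = [debye_intensity(c, q_grid, form_factors) for c in conformations]
    clean = ensemble_intensity(profiles, weights)
    sd = noise_alpha + noise_beta * clean.intensity
    if np.all(sd == 0):
        return clean
    if np.any(sd <= 0):
        raise ValueError("noise model gives non-positive sigma at some q")
    rng = np.random.Generator(np.random.PCG64(seed))
    noisy = clean.intensity + sd * rng.standard_normal(len(sd))
    return SAXSProfile(clean.q, noisy, sd)


def perturbed_pool(topology: ComplexTopology, reference: Conformation,
                   n: int, rng: np.random.Generator,
                   translation_sd: float = 6.0, rotation_sd: float = 0.3,
                   min_translation: float = 2.0,
                   linker_sd: float = 1.0) -> list[Conformation]:
    """Decoy conformations from seeded Gaussian kicks of rigid-body poses.

    Each body is rotated about its centroid and displaced; displacement
    magnitudes get a floor of min_translation so every decoy is a
    structurally distinct individual rather than a near-copy of the
    reference.  Linker beads are re-laid between the moved anchors with
    small jitter.
    """
    from .topology import quat_to_matrix, rotvec_to_quat

    out = []
    for _ in range(n):
        coords = reference.coords.copy()
        for body in topology.rigid_bodies:
            idx = body.bead_indices
            rotvec = rotation_sd * rng.standard_normal(3)
            rot = quat_to_matrix(rotvec_to_quat(rotvec))
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            magnitude = min_translation + abs(translation_sd * rng.standard_normal())
            centroid = coords[idx].mean(axis=0)
            coords[idx] = (coords[idx] - centroid) @ rot.T + centroid \
                + magnitude * direction
        for linker in topology.linkers:
            chain = linker.bead_indices
            pa = coords[linker.anchor_start] if linker.anchor_start is not None \
                else coords[chain[0]]
            pb = coords[linker.anchor_end] if linker.anchor_end is not None \
                else coords[chain[-1]]
            ts = np.arange(1, len(chain) + 1) / (len(chain) + 1)
            coords[chain] = pa + ts[:, None] * (pb - pa) \
                + linker_sd * rng.standard_normal((len(chain), 3))
        out.append(Conformation(coords))
    return out


def two_state_fixture(seed: int = 0, pool_size: int = 200,
                      n_q: int = 60, q_max: float = 0.25,
                      noise_beta: float = 0.01):
    """Pool + noisy target + ground truth for ensemble-recovery experiments.

    Builds a dumbbell complex, designates one compact and one extended
    conformation as the generating pair, surrounds them with pose-kick
    decoys (half around each parent), and synthesises the target as the
    50/50 mixture intensity with 1% multiplicative Gaussian noise.

    Rigid-body pose kicks can be almost scattering-invariant (rotations
    about the inter-body axis, transverse translations), so raw decoys may
    be profile-degenerate with their parent even when structurally
    distinct.  To keep the recovery question well posed, candidate decoys
    are rejection-sampled: a decoy is kept only if substituting it for its
    parent in the generating mixture shifts the reduced chi-square against
    the noiseless target by at least min_bias at the generating noise
    level, i.e. every decoy is a structure the experiment could actually
    distinguish from the truth.

    Returns (pool, target, truth_ids, topology) where truth_ids are the
    pool indices of the two generating structures.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 47])))
    spec_c = SyntheticSpec(geometry="compact", seed=seed)
    spec_e = SyntheticSpec(geometry="extended", seed=seed)
    topo, compact = make_toy_complex(spec_c)
    _, extended = make_toy_complex(spec_e)

    q_grid = np.linspace(0.005, q_max, n_q)
    from .saxs import SAXSProfile, chi2_fit

    prof_c = debye_intensity(compact, q_grid)
    prof_e = debye_intensity(extended, q_grid)
    clean = ensemble_intensity([prof_c, prof_e], [0.5, 0.5])
    nominal = SAXSProfile(q_grid, clean.intensity,
                          np.maximum(noise_beta, 1e-6) * clean.intensity)

    def _resolvable(parent_profile, other_profile, n, min_bias=3.0):
        parent = compact if parent_profile is prof_c else extended
        kept: list[Conformation] = []
        while len(kept) < n:
            for cand in perturbed_pool(topo, parent, n - len(kept), rng):
                sub = ensemble_intensity(
                    [debye_intensity(cand, q_grid), other_profile], [0.5, 0.5])
                if chi2_fit(nominal, sub).chi2 >= min_bias:
                    kept.append(cand)
        return kept

    n_decoys = pool_size - 2
    decoys = _resolvable(prof_c, prof_e, n_decoys // 2)
    decoys += _resolvable(prof_e, prof_c, n_decoys - n_decoys // 2)
    pool = [compact, extended] + decoys
    order = rng.permutation(pool_size)
    pool = [pool[k] for k in order]
    position = {int(orig): new for new, orig in enumerate(order)}
    truth_ids = (position[0], position[1])

    target = synthesize_saxs([compact, extended], [0.5, 0.5], q_grid,
                             noise_alpha=0.0, noise_beta=noise_beta,
                             seed=seed + 1)
    return pool, target, truth_ids, topo
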