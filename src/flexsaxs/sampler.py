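"""Replica-exchange Metropolis Monte Carlo over rigid bodies and linkers.

One MC sweep attempts one move per mobile degree of freedom: each rigid
body gets a random translation or rotation about its centroid, each linker
bead a local displacement or a pivot of the downstream chain segment.
Moves are accepted with probability min(1, exp(-dE/kT)).  Replicas at a
geometric temperature ladder exchange configurations between adjacent
temperatures with the standard acceptance min(1, exp((b_i-b_j)(E_i-E_j))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import KB_KCAL, EnergyCalculator, EnergyModel
from .topology import (ComplexTopology, Conformation, quat_multiply,
                       quat_to_matrix, rotvec_to_quat)


@dataclass
class REMCConfig:
    """Protocol of a replica-exchange run.

    The solution-mode defaults reflect the study protocol for complexes in
    solution (16 replicas over 300-500 K, structures saved every 1000
    sweeps at all temperatures); membrane runs conventionally use 8
    replicas and save at the lowest temperature only.
    """

    n_runs: int = 2
    n_replicas: int = 16
    t_min: float = 300.0
    t_max: float = 500.0
    n_sweeps: int = 5_000_000
    save_interval: int = 1000
    save_policy: str = "all"  # "all" | "lowest"
    seed: int = 0
    translation_amp: float = 1.0  # A
    rotation_amp: float = 0.1  # rad
    linker_amp: float = 1.5  # A
    pivot_amp: float = 0.2  # rad
    swap_period: int = 10  # sweeps between swap attempts
    membrane: bool = False

    def __post_init__(self):
        if self.t_min > self.t_max:
            raise ValueError("t_min must not exceed t_max")
        if self.n_sweeps % self.save_interval:
            raise ValueError("n_sweeps must be a multiple of save_interval")
        if self.save_policy not in ("all", "lowest"):
            raise ValueError("save_policy must be 'all' or 'lowest'")

    def temperature_ladder(self) -> np.ndarray:
        """Geometric ladder from t_min to t_max."""
        if self.n_replicas == 1:
            return np.array([self.t_min])
        ratio = self.t_max / self.t_min
        return self.t_min * ratio ** (np.arange(self.n_replicas) / (self.n_replicas - 1))


@dataclass
class TrajectoryPool:
    """Recorded conformations plus the protocol and acceptance bookkeeping."""

    conformations: list[Conformation]
    config: REMCConfig
    acceptance: dict = field(default_factory=dict)
    ladder: np.ndarray | None = None

    def __len__(self):
        return len(self.conformations)

    def coords_array(self) -> np.ndarray:
        return np.array([c.coords for c in self.conformations])


def plan_pool_size(config: REMCConfig) -> int:
    """Number of conformations a run of this protocol records.

    n_runs x (replicas saved) x (n_sweeps / save_interval).
    """
    per_replica = config.n_sweeps // config.save_interval
    replicas_saved = config.n_replicas if config.save_policy == "all" else 1
    return config.n_runs * replicas_saved * per_replica


class MCState:
    """One replica's mutable state: poses, coordinates, cached energy."""

    def __init__(self, topology: ComplexTopology, calc: EnergyCalculator):
        self.topology = topology
        self.calc = calc
        self.coords = np.ascontiguousarray(topology.initial_coords())
        self.quats = np.array([b.pose_rotation for b in topology.rigid_bodies],
                              dtype=float).reshape(-1, 4)
        self.is_moved = np.zeros(topology.n_beads, dtype=bool)
        self._trial = np.empty_like(self.coords)
        self._scratch = np.empty(topology.n_beads, dtype=np.int64)
        # per-linker index arrays reused by pivot moves
        self._linker_chains = [np.asarray(l.bead_indices) for l in topology.linkers]
        # flattened segment layout for the compiled sweep kernel
        bodies = topology.rigid_bodies
        self._body_indices = (np.concatenate([b.bead_indices for b in bodies])
                              if bodies else np.empty(0, dtype=np.int64))
        self._body_offsets = np.cumsum([0] + [b.n_beads for b in bodies]).astype(np.int64)
        self._body_refs = (np.concatenate([b.reference_coords for b in bodies])
                           if bodies else np.empty((0, 3)))
        chains = self._linker_chains
        self._chain_indices = (np.concatenate(chains) if chains
                               else np.empty(0, dtype=np.int64))
        self._chain_offsets = np.cumsum([0] + [len(c) for c in chains]).astype(np.int64)
        self.energy = calc.total(self.coords)
        self.n_accepted = 0
        self.n_attempted = 0

    def copy(self) -> "MCState":
        new = object.__new__(MCState)
        new.__dict__.update(self.__dict__)
        new.coords = self.coords.copy()
        new.quats = self.quats.copy()
        new.is_moved = np.zeros(self.topology.n_beads, dtype=bool)
        new._trial = np.empty_like(self.coords)
        new._scratch = np.empty(self.topology.n_beads, dtype=np.int64)
        new.n_accepted = 0
        new.n_attempted = 0
        return new

    # -- proposal helpers --------------------------------------------------
    def _attempt(self, moved_idx, new_moved, beta, u_accept, on_accept=None):
        self.n_attempted += 1
        self.is_moved[moved_idx] = True
        d_e = self.calc.fast_delta(self.coords, self._trial, moved_idx,
                                   new_moved, self.is_moved)
        self.is_moved[moved_idx] = False
        if not np.isfinite(d_e):
            raise RuntimeError("non-finite energy change during MC move")
        if d_e <= 0 or u_accept < math.exp(-beta * d_e):
            self.coords[moved_idx] = new_moved
            self.energy += d_e
            self.n_accepted += 1
            if on_accept is not None:
                on_accept()


def mc_sweep(state: MCState, temperature: float, rng: np.random.Generator,
             config: REMCConfig) -> MCState:
    """Advance one sweep: one attempted move per rigid body and linker bead.

    Returns the (mutated) state.  Zero-amplitude moves leave coordinates
    untouched and are always accepted.

    Dispatches to a compiled kernel unless the energy model carries a
    Python external potential, in which case an equivalent (but not
    stream-identical) Python path is used.
    """
    from . import _kernels

    beta = 1.0 / (KB_KCAL * temperature) if np.isfinite(temperature) else 0.0
    topo = state.topology
    calc = state.calc
    m = calc.model
    if m.external is None:
        energy, att, acc = _kernels.sweep_kernel(
            state.coords, state.quats, state._body_indices,
            state._body_offsets, state._body_refs,
            state._chain_indices, state._chain_offsets,
            calc.eps_mat, calc.qq_mat, calc.allowed,
            m.excluded_radius, m.contact_range, m.repulsion_k, m.debye_length,
            calc.bond_pairs, calc.bond_b0, m.bond_k,
            calc.angle_triples, m.angle_0, m.angle_k,
            calc.torsion_quads, m.torsion_amp,
            calc.membrane, calc.bead_depths, m.membrane_z, m.membrane_range,
            m.wall_k, calc.restraint_idx, calc.restraint_z, calc.restraint_k,
            beta, config.translation_amp, config.rotation_amp,
            config.linker_amp, config.pivot_amp,
            state.energy, rng, state._trial, state.is_moved, state._scratch)
        if not np.isfinite(energy):
            raise RuntimeError("non-finite energy change during MC move")
        state.energy = float(energy)
        state.n_attempted += att
        state.n_accepted += acc
        return state
    n_moves = len(topo.rigid_bodies) + sum(len(c) for c in state._linker_chains)
    kicks = rng.standard_normal((n_moves, 3))
    choices = rng.random(n_moves)
    u_accepts = rng.random(n_moves)
    m = 0

    for bi, body in enumerate(topo.rigid_bodies):
        idx = body.bead_indices
        if choices[m] < 0.5:
            shift = config.translation_amp * kicks[m]
            new_moved = state.coords[idx] + shift
            state._attempt(idx, new_moved, beta, u_accepts[m])
        else:
            rotvec = config.rotation_amp * kicks[m]
            dq = rotvec_to_quat(rotvec)
            new_q = quat_multiply(dq, state.quats[bi])
            new_q /= np.linalg.norm(new_q)
            # rotate about the instantaneous centroid, reconstructing from
            # the reference frame so rigidity never drifts
            centroid = state.coords[idx].mean(axis=0)
            new_moved = body.reference_coords @ quat_to_matrix(new_q).T
            new_moved += centroid - new_moved.mean(axis=0)

            def _keep(bi=bi, q=new_q):
                state.quats[bi] = q

            state._attempt(idx, new_moved, beta, u_accepts[m], on_accept=_keep)
        m += 1

    for chain in state._linker_chains:
        n = len(chain)
        for k in range(n):
            bead = chain[k]
            if n == 1 or choices[m] < 0.5:
                shift = config.linker_amp * kicks[m]
                moved_idx = chain[k:k + 1]
                new_moved = state.coords[moved_idx] + shift
                state._attempt(moved_idx, new_moved, beta, u_accepts[m])
            else:
                # pivot: rotate the shorter arm of the chain about this bead
                if k >= n // 2:
                    moved_idx = chain[k + 1:]
                else:
                    moved_idx = chain[:k]
                if len(moved_idx):
                    rotvec = config.pivot_amp * kicks[m]
                    rot = quat_to_matrix(rotvec_to_quat(rotvec))
                    pivot_point = state.coords[bead]
                    new_moved = (state.coords[moved_idx] - pivot_point) @ rot.T \
                        + pivot_point
                    state._attempt(moved_idx, new_moved, beta, u_accepts[m])
            m += 1
    return state


def _randomize_state(state: MCState, rng: np.random.Generator,
                     config: REMCConfig) -> None:
    """Scatter rigid-body poses so independent runs start from different
    conformations; linker beads are re-laid between their anchors."""
    topo = state.topology
    for bi, body in enumerate(topo.rigid_bodies):
        idx = body.bead_indices
        rotvec = rng.uniform(0, np.pi, 3) * rng.choice([-1.0, 1.0], 3)
        q = rotvec_to_quat(rotvec)
        q = quat_multiply(q, state.quats[bi])
        q /= np.linalg.norm(q)
        centroid = state.coords[idx].mean(axis=0)
        shift = 10.0 * rng.standard_normal(3)
        if config.membrane:
            shift[2] = abs(shift[2]) * 0.2  # keep bodies above the plane
        new = body.reference_coords @ quat_to_matrix(q).T
        new += centroid + shift - new.mean(axis=0)
        state.coords[idx] = new
        state.quats[bi] = q
    for linker in topo.linkers:
        chain = linker.bead_indices
        start = (state.coords[linker.anchor_start]
                 if linker.anchor_start is not None else state.coords[chain[0]])
        if linker.anchor_end is not None:
            end = state.coords[linker.anchor_end]
            ts = (np.arange(1, len(chain) + 1)) / (len(chain) + 1)
            base = start + ts[:, None] * (end - start)
        else:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            base = start + np.outer(np.arange(1, len(chain) + 1),
                                    direction * linker.bond_length)
        state.coords[chain] = base + 0.5 * rng.standard_normal((len(chain), 3))
    state.energy = state.calc.total(state.coords)


def run_remc(topology: ComplexTopology, model: EnergyModel,
             config: REMCConfig) -> TrajectoryPool:
    """Run n_runs independent REMC simulations and pool the saved structures.

    Fully reproducible from config.seed: each run draws its own RNG stream
    from a spawned seed sequence.  Raises on non-finite energies.
    """
    calc = EnergyCalculator(topology, model, membrane=config.membrane)
    ladder = config.temperature_ladder()
    pool: list[Conformation] = []
    acceptance: dict = {}
    root = np.random.SeedSequence(config.seed)
    run_seeds = root.spawn(config.n_runs)

    for run_id in range(config.n_runs):
        rng = np.random.Generator(np.random.PCG64(run_seeds[run_id]))
        base = MCState(topology, calc)
        _randomize_state(base, rng, config)
        # states[i] is the configuration currently at ladder temperature i
        states = [base.copy() for _ in range(config.n_replicas)]
        for st in states[1:]:
            _randomize_state(st, rng, config)
        swap_attempts = 0
        swap_accepts = 0

        for sweep in range(1, config.n_sweeps + 1):
            for i, temp in enumerate(ladder):
                mc_sweep(states[i], temp, rng, config)
            if config.swap_period and sweep % config.swap_period == 0 \
                    and config.n_replicas > 1:
                i = int(rng.integers(config.n_replicas - 1))
                j = i + 1
                beta_i = 1.0 / (KB_KCAL * ladder[i])
                beta_j = 1.0 / (KB_KCAL * ladder[j])
                arg = (beta_i - beta_j) * (states[i].energy - states[j].energy)
                swap_attempts += 1
                if arg >= 0 or rng.random() < math.exp(arg):
                    states[i], states[j] = states[j], states[i]
                    swap_accepts += 1
            if sweep % config.save_interval == 0:
                save_from = (range(config.n_replicas)
                             if config.save_policy == "all" else (0,))
                for i in save_from:
                    st = states[i]
                    if not np.isfinite(st.energy):
                        raise RuntimeError(
                            f"non-finite energy at run {run_id}, sweep {sweep}")
                    pool.append(Conformation(st.coords.copy(), st.energy,
                                             run_id, float(ladder[i]), sweep))
        move_acc = {
            i: (states[i].n_accepted / max(states[i].n_attempted, 1))
            for i in range(config.n_replicas)
        }
        acceptance[run_id] = {
            "moves": move_acc,
            "swap": swap_accepts / max(swap_attempts, 1),
        }

    result = TrajectoryPool(pool, config, acceptance, ladder)
    expected = plan_pool_size(config)
    assert len(result) == expected, (len(result), expected)
    return result


def swap_acceptance_probability(e_i: float, e_j: float, t_i: float,
                                t_j: float) -> float:
    """Metropolis probability of exchanging configurations between two
    temperatures; equals 1 when the temperatures coincide."""
    beta_i = 1.0 / (KB_KCAL * t_i)
    beta_j = 1.0 / (KB_KCAL * t_j)
    return min(1.0, math.exp((beta_i - beta_j) * (e_i - e_j)))
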