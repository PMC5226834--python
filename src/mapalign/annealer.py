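"""Stochastic energy minimization of the wiring configuration.

The optimizer is a simulated-annealing variant without a cooling
schedule: every step proposes one contact addition (uniform over all
site pairs) and one contact removal (uniform over existing contacts,
i.e. count-weighted), and accepts each sub-move independently with the
sigmoid probability ``P = 1 / (1 + exp(gain * dE))`` at a fixed gain of
4.  The run length is expressed per neuron (default 15,000 steps per
lattice site, i.e. 150,000,000 steps on the full 100x100 grid) and
snapshots of the connection-density profile are recorded every
``snapshot_interval`` steps (default 500,000).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from .omega_core import ConnectivityState, ModelParams
from .energies import delta_energy, make_energy_tables, total_energy

__all__ = [
    "Move",
    "AnnealSchedule",
    "Trajectory",
    "acceptance_probability",
    "propose_move",
    "step",
    "anneal",
]

SIGMOID_GAIN = 4.0


@dataclass(frozen=True)
class Move:
    """One proposed elementary change: an optional addition and an
    optional removal, each a (SC site, V1 site) index pair."""

    add_pair: Optional[Tuple[int, int]] = None
    remove_pair: Optional[Tuple[int, int]] = None


def acceptance_probability(delta_E: float, gain: float = SIGMOID_GAIN) -> float:
    """Sigmoid acceptance ``1 / (1 + exp(gain * delta_E))``.

    Equal to 1/2 at zero energy change, strictly decreasing, and
    symmetric: ``P(x) + P(-x) == 1``.
    """
    if not math.isfinite(delta_E):
        raise ValueError(f"delta_E must be finite, got {delta_E}")
    z = gain * delta_E
    if z > 700.0:
        return 0.0
    if z < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def propose_move(state: ConnectivityState, rng: np.random.Generator) -> Move:
    """Draw the two halves of a move from the current state.

    The addition target is uniform over all (SC, V1) site pairs; the
    removal target is uniform over existing contacts (count-weighted).
    On an empty state the move is addition-only.
    """
    m = state.grid.n_sites
    add_pair = (int(rng.integers(m)), int(rng.integers(m)))
    total = state.total_connections
    if total == 0:
        return Move(add_pair=add_pair)
    flat = np.cumsum(state.counts.ravel(), dtype=np.int64)
    k = int(rng.integers(total))
    idx = int(np.searchsorted(flat, k, side="right"))
    remove_pair = (idx // m, idx % m)
    return Move(add_pair=add_pair, remove_pair=remove_pair)


def step(state: ConnectivityState, params: ModelParams,
         rng: np.random.Generator, tables: Optional[dict] = None,
         gain: float = SIGMOID_GAIN) -> Tuple[bool, bool]:
    """One annealing step on the pure-Python path (reference/testing).

    The addition and the removal are evaluated and accepted
    independently; the state is mutated in place for accepted sub-moves.
    Returns (addition accepted, removal accepted).
    """
    move = propose_move(state, rng)
    accepted_add = False
    if move.add_pair is not None:
        dE = delta_energy(state, Move(add_pair=move.add_pair), params, tables)
        if rng.random() < acceptance_probability(dE, gain):
            state.add_contact(*move.add_pair)
            accepted_add = True
    accepted_rem = False
    if move.remove_pair is not None:
        dE = delta_energy(state, Move(remove_pair=move.remove_pair), params, tables)
        if rng.random() < acceptance_probability(dE, gain):
            state.remove_contact(*move.remove_pair)
            accepted_rem = True
    return accepted_add, accepted_rem


@dataclass(frozen=True)
class AnnealSchedule:
    """Run-length and bookkeeping parameters of one annealing run."""

    steps_per_neuron: int = 15_000
    snapshot_interval: int = 500_000
    seed: int = 0
    gain: float = SIGMOID_GAIN
    store_states: bool = False

    def total_steps(self, n_sites: int) -> int:
        return self.steps_per_neuron * n_sites

    def __post_init__(self) -> None:
        if self.steps_per_neuron < 1 or self.snapshot_interval < 1:
            raise ValueError("steps_per_neuron and snapshot_interval must be >= 1")


@dataclass
class Trajectory:
    """Snapshots and diagnostics of one annealing run.

    ``profile_vectors[i]`` is the concatenated, max-normalized SC-azimuth
    density sampled at five V1 azimuth bands (the convergence summary);
    ``energy_trace`` holds the exactly recomputed total energy at each
    snapshot.
    """

    params: ModelParams
    schedule: AnnealSchedule
    grid_size: int
    snapshot_steps: List[int] = field(default_factory=list)
    energy_trace: List[float] = field(default_factory=list)
    accumulated_energy: List[float] = field(default_factory=list)
    accepted_adds: List[int] = field(default_factory=list)
    accepted_removals: List[int] = field(default_factory=list)
    profile_vectors: List[np.ndarray] = field(default_factory=list)
    states: List[ConnectivityState] = field(default_factory=list)
    final_state: Optional[ConnectivityState] = None

    @property
    def profile_matrix(self) -> np.ndarray:
        return np.asarray(self.profile_vectors, dtype=float)


def _chunk_seed(base_seed: int, counter: int) -> int:
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, counter])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def anneal(state: ConnectivityState, params: ModelParams,
           schedule: AnnealSchedule, tables: Optional[dict] = None) -> Trajectory:
    """Run the full annealing schedule on ``state`` (mutated in place).

    The run is deterministic given (state, params, schedule): all
    randomness derives from ``schedule.seed``.  Returns the trajectory;
    ``trajectory.final_state`` is the optimized state.
    """
    from .analysis import snapshot_profile_vector  # local: avoids cycle

    grid = state.grid
    m = grid.n_sites
    if tables is None:
        tables = make_energy_tables(grid, params)
    total_steps = schedule.total_steps(m)

    con_s, con_l = state.contact_list()
    ncon = con_s.shape[0]
    cap = max(2 * ncon + 1024, 64 * m)
    con_s = np.resize(con_s, cap)
    con_l = np.resize(con_l, cap)

    integ = params.model_kind == "integrational"
    if integ:
        D, K = tables["D"], tables["K"]
        C = np.zeros((m, m), dtype=np.float64)
        SD = np.zeros(m, dtype=np.float64)
        act_list = np.zeros((m, m), dtype=np.int32)
        act_n = np.zeros(m, dtype=np.int32)
        act_pos = np.full((m, m), -1, dtype=np.int32)
        _kernels.rebuild_integrational_cache(state.counts, D, K, C, SD,
                                             act_list, act_n, act_pos)

    traj = Trajectory(params=params, schedule=schedule, grid_size=grid.n_per_axis)
    e0 = total_energy(state, params)
    e_acc = e0.E_total
    traj.snapshot_steps.append(0)
    traj.energy_trace.append(e0.E_total)
    traj.accumulated_energy.append(e_acc)
    traj.accepted_adds.append(0)
    traj.accepted_removals.append(0)
    traj.profile_vectors.append(snapshot_profile_vector(state))
    if schedule.store_states:
        traj.states.append(state.copy())

    done = 0
    chunk_counter = 0
    while done < total_steps:
        target = min(done + schedule.snapshot_interval, total_steps)
        while done < target:
            nsteps = target - done
            seed = _chunk_seed(schedule.seed, chunk_counter)
            chunk_counter += 1
            if integ:
                out = _kernels.run_chunk_integrational(
                    state.counts, state.n_A, state.n_D, con_s, con_l, ncon,
                    tables["L"], D, K, C, SD, act_list, act_n, act_pos,
                    params.beta_c, params.alpha_c, params.gamma_c,
                    params.gamma_u, schedule.gain, nsteps, seed)
            else:
                out = _kernels.run_chunk_correlational(
                    state.counts, state.n_A, state.n_D, con_s, con_l, ncon,
                    tables["L"], params.beta_c, params.alpha_c,
                    params.gamma_c, schedule.gain, nsteps, seed)
            dE, ncon, acc_add, acc_rem, steps_done = out
            e_acc += dE
            done += steps_done
            if steps_done < nsteps:  # contact list full: grow and resume
                cap *= 2
                con_s = np.resize(con_s, cap)
                con_l = np.resize(con_l, cap)
            # counters for the interval ending at the next snapshot
            traj.accepted_adds[-1] += acc_add
            traj.accepted_removals[-1] += acc_rem
        # snapshot
        if integ:
            _kernels.rebuild_integrational_cache(state.counts, D, K, C, SD,
                                                 act_list, act_n, act_pos)
        eb = total_energy(state, params)
        traj.snapshot_steps.append(done)
        traj.energy_trace.append(eb.E_total)
        traj.accumulated_energy.append(e_acc)
        traj.profile_vectors.append(snapshot_profile_vector(state))
        traj.accepted_adds.append(0)
        traj.accepted_removals.append(0)
        if schedule.store_states:
            traj.states.append(state.copy())
    # the trailing zero counters correspond to "after the last snapshot"
    traj.accepted_adds.pop()
    traj.accepted_removals.pop()
    traj.final_state = state
    return traj
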