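"""Parallel stochastic spin dynamics and the recall protocols.

All N neurons update simultaneously each time step (Little-model updating).
Given the local fields h_i = sum_j J_ij sigma_j + theta_i, each new spin is
+1 with probability

    P(sigma_i = +1) = exp(+beta h_i) / (2 cosh(beta h_i)) = (1 + tanh(beta h_i)) / 2,

independently across neurons, with beta = 1/T.  At T = 0 the update is the
deterministic map sigma_i <- sign(h_i), with the tie-break sign(0) = +1.

Two recall protocols measure what the network stores:

* associative memory (AM): start 10% away from a stored pattern, relax for
  a transient, and read the overlap with that same pattern;
* sequential pattern recognition (SPR): start 10% away from a sequence
  pattern, wait three putative periods, then traverse one full period and
  average the overlap with the sequence advanced one pattern per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import NetworkState, PatternSet, corrupt, generate_random_patterns, overlap
from .synapses import SynapticMatrix, dilute, mixed_matrix

__all__ = [
    "DynamicsConfig",
    "Trajectory",
    "AttractorReport",
    "local_fields",
    "step",
    "run",
    "run_am_protocol",
    "run_spr_protocol",
    "detect_attractor",
    "sweep_nu",
]


@dataclass
class DynamicsConfig:
    """Temperature, optional external fields theta_i, and the random seed."""

    temperature: float = 0.0
    external_field: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Trajectory:
    """Time-ordered list of network states plus the config that produced it."""

    states: list
    config: DynamicsConfig

    def __post_init__(self) -> None:
        lengths = {s.n_neurons for s in self.states}
        if len(lengths) > 1:
            raise ValueError("all states in a trajectory must have equal length")


@dataclass
class AttractorReport:
    """Outcome of exact recurrence detection on the T=0 deterministic map."""

    kind: str           # "fixed_point" | "cycle" | "none"
    period: int = 0     # 1 for a fixed point, >= 2 for a cycle
    entry_time: int = 0


def local_fields(J: SynapticMatrix, state, external_field=None) -> np.ndarray:
    """h_i = sum_j J_ij sigma_j + theta_i."""
    s = state.spins if isinstance(state, NetworkState) else np.asarray(state)
    h = J.weights @ s.astype(np.float64)
    if external_field is not None:
        h = h + np.asarray(external_field, dtype=np.float64)
    return h


def step(state: NetworkState, J: SynapticMatrix, config: DynamicsConfig,
         rng: np.random.Generator | None = None) -> NetworkState:
    """One synchronous update of all spins.

    The new state depends only on the previous state.  For T > 0 a
    generator must carry the randomness across steps; if none is given a
    fresh one is derived from ``config.seed`` (so isolated calls are
    reproducible but repeat the same draw).
    """
    h = local_fields(J, state, config.external_field)
    if config.temperature == 0.0:
        spins = np.where(h >= 0.0, 1, -1).astype(np.int8)  # sign(0) = +1
    else:
        if rng is None:
            rng = config.rng()
        beta = 1.0 / config.temperature
        p_up = 0.5 * (1.0 + np.tanh(beta * h))
        spins = np.where(rng.random(h.size) < p_up, 1, -1).astype(np.int8)
    return NetworkState(spins=spins, time_index=state.time_index + 1)


def run(state: NetworkState, J: SynapticMatrix, config: DynamicsConfig,
        n_steps: int, rng: np.random.Generator | None = None,
        record: bool = False) -> NetworkState | Trajectory:
    """Iterate ``step`` n_steps times; optionally record the whole trajectory."""
    if rng is None:
        rng = config.rng()
    states = [state]
    for _ in range(n_steps):
        state = step(state, J, config, rng)
        if record:
            states.append(state)
    return Trajectory(states=states, config=config) if record else state


def run_am_protocol(J: SynapticMatrix, pattern_set: PatternSet,
                    flip_fraction: float = 0.1, transient: int = 35,
                    config: DynamicsConfig | None = None) -> float:
    """Mean retrieval overlap over all patterns of the AM set.

    Each pattern is corrupted by ``flip_fraction`` spin flips, the network
    relaxes for ``transient`` synchronous steps, and the overlap with the
    original pattern is recorded; the average over patterns is returned.
    """
    if pattern_set.n_patterns < 1:
        raise ValueError("empty pattern set")
    config = config or DynamicsConfig()
    rng = config.rng()
    overlaps = []
    for mu in range(pattern_set.n_patterns):
        state = corrupt(pattern_set[mu], flip_fraction,
                        seed=int(rng.integers(2 ** 31)))
        state = run(state, J, config, transient, rng)
        overlaps.append(overlap(state, pattern_set[mu]))
    return float(np.mean(overlaps))


def run_spr_protocol(J: SynapticMatrix, sequence_set: PatternSet,
                     flip_fraction: float = 0.1, transient: int | None = None,
                     config: DynamicsConfig | None = None) -> float:
    """Mean cyclic overlap along one period of the stored sequence.

    The network starts 10% away from the first sequence pattern and runs
    for ``transient`` steps (default three periods, 3P).  The cycle phase
    is then aligned to the best-matching sequence index, and over the next
    P steps the overlap with the sequence advanced one pattern per step is
    averaged.  Overlaps are signed; retrieval of the anti-cycle shows up
    as a mean near -1, not +1.
    """
    p = sequence_set.n_patterns
    if p < 1:
        raise ValueError("empty sequence set")
    if transient is None:
        transient = 3 * p
    config = config or DynamicsConfig()
    rng = config.rng()
    state = corrupt(sequence_set[0], flip_fraction, seed=int(rng.integers(2 ** 31)))
    state = run(state, J, config, transient, rng)
    # phase alignment: which sequence pattern does the state match best now?
    start = int(np.argmax([abs(overlap(state, sequence_set[mu])) for mu in range(p)]))
    overlaps = []
    for tau in range(p):
        state = step(state, J, config, rng)
        overlaps.append(overlap(state, sequence_set[(start + 1 + tau) % p]))
    return float(np.mean(overlaps))


def detect_attractor(J: SynapticMatrix, state: NetworkState,
                     config: DynamicsConfig, horizon: int = 1000) -> AttractorReport:
    """Iterate the T=0 deterministic map until an exact state recurrence.

    Rejects T > 0 (stochastic trajectories have no exact recurrences).
    On a finite state space the map is eventually periodic, so a large
    enough horizon always finds the attractor.
    """
    if config.temperature != 0.0:
        raise ValueError("attractor detection requires temperature = 0")
    seen: dict[bytes, int] = {state.spins.tobytes(): 0}
    current = state
    for t in range(1, horizon + 1):
        current = step(current, J, config)
        key = current.spins.tobytes()
        if key in seen:
            entry = seen[key]
            period = t - entry
            kind = "fixed_point" if period == 1 else "cycle"
            return AttractorReport(kind=kind, period=period, entry_time=entry)
        seen[key] = t
    return AttractorReport(kind="none", period=0, entry_time=horizon)


def sweep_nu(variant: str, nus, n_neurons: int = 2000, p_am: int = 10,
             p_spr: int = 10, in_degree: int | None = 500,
             flip_fraction: float = 0.1, transient_am: int = 35,
             temperature: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Both recall protocols across a grid of mixture values nu.

    For the two-set variant the AM and SPR protocols address independent
    pattern sets; for the one-set variant a single set plays both roles.
    Returns a table with columns nu, overlap_am, overlap_spr, seed.
    """
    if variant not in ("one_set", "two_set"):
        raise ValueError(f"unknown variant {variant!r}")
    am = generate_random_patterns(n_neurons, p_am, role="AM", seed=seed)
    if variant == "two_set":
        spr = generate_random_patterns(n_neurons, p_spr, role="SPR", seed=seed + 1)
    else:
        spr = PatternSet(entries=am.entries.copy(), role="SPR", seed=seed)
    rows = []
    for k, nu in enumerate(nus):
        J = mixed_matrix(am, float(nu), spr_set=spr if variant == "two_set" else None)
        if in_degree is not None:
            J = dilute(J, in_degree, seed=seed + 1000 + k)
        cfg_am = DynamicsConfig(temperature=temperature, seed=seed + 2)
        cfg_spr = DynamicsConfig(temperature=temperature, seed=seed + 3)
        rows.append({
            "nu": float(nu),
            "overlap_am": run_am_protocol(J, am, flip_fraction, transient_am, cfg_am),
            "overlap_spr": run_spr_protocol(J, spr, flip_fraction, None, cfg_spr),
            "seed": seed,
        })
    return pd.DataFrame(rows)
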