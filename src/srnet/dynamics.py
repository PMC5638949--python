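"""Synchronous excitable Boolean dynamics on a weighted network.

Each node is either quiescent (0) or excited (1).  At every time step, all
nodes are updated synchronously from the previous state:

* a quiescent node becomes excited spontaneously with probability ``p_qe``
  (the noise), or deterministically when its weighted input
  ``alpha_i = sum_j w_ij s_j(t)`` reaches the threshold ``T``;
* an excited node that is still stimulated (spontaneously with probability
  ``p_qe``, or because ``alpha_i >= T``) stays excited with probability
  ``p_ee``, otherwise it returns to quiescence.

There is no refractory state: nodes stand for whole regions comprising many
units, not single excitable cells.  A periodic input signal can be injected
by clamping one node (the "seeder") to a square wave; the clamped node keeps
driving its neighbours but its own update is overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "SignalProtocol",
    "Trajectory",
    "local_input",
    "step_update",
    "simulate",
    "simulate_ensemble",
    "order_parameter",
    "square_wave",
]


@dataclass
class ModelParams:
    """The three model parameters plus run-length controls.

    Parameters
    ----------
    p_qe:
        Probability per step that a quiescent node activates spontaneously;
        plays the role of the noise level.  In [0, 1].
    p_ee:
        Probability per step that an excited, still-stimulated node remains
        excited.  In [0, 1].
    threshold:
        Minimum weighted input ``alpha_i`` required for stimulus-driven
        activation, in the same units as summed edge weights.
    transient:
        Equilibration steps discarded before recording.
    steps:
        Recorded steps.
    """

    p_qe: float
    p_ee: float
    threshold: float
    transient: int = 1000
    steps: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_qe <= 1.0:
            raise ValueError(f"p_qe must be in [0,1], got {self.p_qe}")
        if not 0.0 <= self.p_ee <= 1.0:
            raise ValueError(f"p_ee must be in [0,1], got {self.p_ee}")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.transient < 0 or self.steps < 1:
            raise ValueError("transient must be >= 0 and steps >= 1")


@dataclass
class SignalProtocol:
    """Square-wave input clamped at one node.

    The seeder is held excited for ``period // 2`` steps, then quiescent for
    the same number of steps, repeating for the whole run (a frequency of
    ``1/period`` cycles per step).
    """

    seeder: int
    period: int = 50
    phase: int = 0

    def __post_init__(self) -> None:
        if self.period < 2 or self.period % 2:
            raise ValueError("period must be a positive even integer")
        if self.seeder < 0:
            raise ValueError("seeder index must be non-negative")
        if self.phase < 0:
            raise ValueError("phase must be non-negative")


def square_wave(t: np.ndarray | int, period: int, phase: int = 0) -> np.ndarray:
    """The clamped input signal: 1 during the first half-period, 0 during the second."""
    return (((np.asarray(t) + phase) % period) < period // 2).astype(np.uint8)


@dataclass
class Trajectory:
    """Recorded binary states (steps x nodes) and the active-density series S(t)."""

    states: np.ndarray
    density: np.ndarray
    params: ModelParams
    protocol: SignalProtocol | None = None

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]


def local_input(c, state: np.ndarray, i: int) -> float:
    """Weighted input alpha_i = sum_j w_ij s_j(t) received by node ``i``.

    The diagonal of the weight matrix is zero, so a node never drives itself.
    """
    w = c.weights
    if not 0 <= i < w.shape[0]:
        raise IndexError(f"node index {i} out of range for {w.shape[0]} nodes")
    return float(w[i] @ np.asarray(state, dtype=float))


def step_update(c, state: np.ndarray, params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """One synchronous update of all nodes from the frozen previous state.

    For each node, with independent uniform draws ``r1, r2`` in [0, 1):
    the stimulation factor is 1 iff ``r1 < p_qe`` or ``alpha_i >= T``; the
    persistence factor is 1 for a quiescent node and, for an excited one,
    1 iff ``r2 < p_ee``.  The new state is the product of the two factors.

    The strict comparison ``r < p`` makes ``p = 0`` exactly never fire and
    ``p = 1`` always fire; for uniform draws it is probabilistically
    identical to the threshold form with ``>=``.
    """
    state = np.asarray(state, dtype=float)
    alpha = c.weights @ state
    r = rng.random((2, state.size))
    stimulated = (r[0] < params.p_qe) | (alpha >= params.threshold)
    persists = (state == 0) | (r[1] < params.p_ee)
    return (stimulated & persists).astype(np.uint8)


def _evolve(
    weights: np.ndarray,
    p_qe: np.ndarray,
    p_ee: float,
    threshold: float,
    transient: int,
    steps: int,
    rng: np.random.Generator,
    seeders: np.ndarray | None = None,
    period: int = 50,
    phase: int = 0,
    record_states: bool = True,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Run ``R`` independent replicas synchronously (vectorized over replicas).

    ``p_qe`` is broadcast per replica, so one call can sweep a noise grid.
    ``seeders`` gives the clamped node of each replica (or None for free
    runs).  Returns ``(states, density)`` with states of shape
    ``(steps, R, N)`` (or None when not recorded) and density ``(steps, R)``.

    All replicas start from the all-quiescent state; ``transient`` steps are
    discarded.
    """
    n = weights.shape[0]
    p_qe = np.atleast_1d(np.asarray(p_qe, dtype=float))
    reps = p_qe.size if seeders is None else max(p_qe.size, len(seeders))
    p_qe = np.broadcast_to(p_qe, (reps,))[:, None]
    state = np.zeros((reps, n))
    rows = np.arange(reps)
    if seeders is not None:
        seeders = np.asarray(seeders)
        state[rows, seeders] = square_wave(phase - 1, period)
    states = np.empty((steps, reps, n), dtype=np.uint8) if record_states else None
    density = np.empty((steps, reps))
    total = transient + steps
    for t in range(1, total + 1):
        alpha = state @ weights
        r = rng.random((2, reps, n))
        stimulated = (r[0] < p_qe) | (alpha >= threshold)
        persists = (state == 0) | (r[1] < p_ee)
        new = stimulated & persists
        if seeders is not None:
            # the state produced at loop step t is recorded at index
            # t - transient - 1, so its wave clock reads t - 1
            new[rows, seeders] = bool(square_wave(t - 1 + phase, period))
        state = new.astype(float)
        if t > transient:
            k = t - transient - 1
            if record_states:
                states[k] = new
            density[k] = state.mean(axis=1)
    return states, density


def simulate(
    c,
    params: ModelParams,
    protocol: SignalProtocol | None = None,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Simulate the dynamics on a connectome, optionally with a clamped signal.

    Runs ``params.transient`` discarded steps from the all-quiescent initial
    state, then records ``params.steps`` steps.  When ``protocol`` is given,
    the seeder node is clamped to the square wave at every step (transient
    included); it still contributes to its neighbours' inputs.
    """
    rng = np.random.default_rng(rng)
    if protocol is not None and protocol.seeder >= c.n_nodes:
        raise IndexError("seeder index out of range")
    seeders = None if protocol is None else np.array([protocol.seeder])
    period = protocol.period if protocol else 50
    phase = protocol.phase if protocol else 0
    states, density = _evolve(
        c.weights, params.p_qe, params.p_ee, params.threshold,
        params.transient, params.steps, rng,
        seeders=seeders, period=period, phase=phase,
    )
    return Trajectory(states[:, 0, :], density[:, 0], params, protocol)


def simulate_ensemble(
    c,
    params: ModelParams,
    p_qe_values: Sequence[float] | None = None,
    seeders: Sequence[int] | None = None,
    protocol_template: SignalProtocol | None = None,
    rng: np.random.Generator | int | None = None,
    record_states: bool = True,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Run a batch of independent replicas in one vectorized sweep.

    Either ``p_qe_values`` (one replica per noise level, no signal) or
    ``seeders`` (one replica per clamped seeder node, all at ``params.p_qe``)
    is given.  Returns ``(states, density)`` as in the shapes documented on
    the core loop: states ``(steps, R, N)``, density ``(steps, R)``.
    """
    rng = np.random.default_rng(rng)
    if seeders is not None:
        period = protocol_template.period if protocol_template else 50
        phase = protocol_template.phase if protocol_template else 0
        return _evolve(
            c.weights, params.p_qe, params.p_ee, params.threshold,
            params.transient, params.steps, rng,
            seeders=np.asarray(seeders), period=period, phase=phase,
            record_states=record_states,
        )
    p = params.p_qe if p_qe_values is None else np.asarray(p_qe_values)
    return _evolve(
        c.weights, p, params.p_ee, params.threshold,
        params.transient, params.steps, rng, record_states=record_states,
    )


def order_parameter(traj: Trajectory) -> float:
    """Time average of the instantaneous active-node density S(t)."""
    if traj.density.size == 0:
        raise ValueError("empty trajectory")
    return float(traj.density.mean())
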