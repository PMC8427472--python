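"""Toy replica exchange with solute tempering (REST) on 1-D potentials.

A ladder of replicas differs in both the alchemical parameter lambda and an
effective-temperature ``scale`` applied, REST2-style, to the *solute* term
of the reduced potential:

    u(x; lambda, scale) = scale * [(1-lambda) u_A(x) + lambda u_B(x)]
                          + u_env(x)

with u_A a double well (or harmonic), u_B a harmonic well and u_env an
optional unscaled environment term.  Replicas evolve by Gaussian
random-walk Metropolis and periodically attempt configuration swaps with
their neighbours using the standard criterion

    p_acc = min(1, exp(-Delta)),
    Delta = [u_i(x_j) + u_j(x_i)] - [u_i(x_i) + u_j(x_j)],

in each replica's own reduced potential.  Neighbour pairs alternate between
odd and even sweeps.  A small discrete variant (three sites, two replicas)
admits exact enumeration of the stationary distribution and is used to
verify detailed balance of the composite move set.

Energies are in reduced units (kT = 1 for the base replica).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ToyPotentialSpec",
    "ReplicaState",
    "RestResult",
    "reduced_energy",
    "exchange_acceptance",
    "run_toy_rest",
    "run_discrete_rest",
    "discrete_rest_exact_stationary",
]


@dataclass(frozen=True)
class ToyPotentialSpec:
    """1-D model potential with a solute/environment split.

    ``barrier_height`` is the double-well barrier in reduced units (kT of
    the base replica); ``well_separation`` the distance between minima.
    The solute term is what the REST scale multiplies; the optional
    harmonic environment term (force constant ``env_force_constant``) is
    never scaled.
    """

    form: Literal["double_well", "harmonic"] = "double_well"
    barrier_height: float = 14.0
    well_separation: float = 4.0
    env_force_constant: float = 0.0

    def __post_init__(self) -> None:
        if self.barrier_height < 0 or self.well_separation <= 0:
            raise ValueError("barrier_height >= 0 and well_separation > 0 required")
        if self.env_force_constant < 0:
            raise ValueError("env_force_constant must be >= 0")

    def solute_energy(self, x: float | np.ndarray, lam: float = 0.0) -> float | np.ndarray:
        """(1-lambda) * end-state-A + lambda * end-state-B solute energy."""
        x = np.asarray(x, dtype=float)
        if self.form == "double_well":
            a = self.well_separation / 2.0
            u_a = self.barrier_height * ((x / a) ** 2 - 1.0) ** 2
        else:
            u_a = 0.5 * x**2
        u_b = 0.5 * x**2  # end state B: single harmonic well
        return ((1.0 - lam) * u_a + lam * u_b)[()]

    def environment_energy(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        return (0.5 * self.env_force_constant * x**2)[()]


def reduced_energy(
    spec: ToyPotentialSpec, lam: float, scale: float, x: float | np.ndarray
) -> float | np.ndarray:
    """Reduced energy of configuration x in replica (lambda, scale)."""
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    return scale * spec.solute_energy(x, lam) + spec.environment_energy(x)


@dataclass
class ReplicaState:
    """Instantaneous state of one replica on the ladder."""

    index: int
    lam: float
    scale: float
    position: float
    energy: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError("replica energy must be finite")


def exchange_acceptance(
    spec: ToyPotentialSpec, state_i: ReplicaState, state_j: ReplicaState
) -> float:
    """Metropolis probability of swapping the two replicas' configurations."""
    uii = reduced_energy(spec, state_i.lam, state_i.scale, state_i.position)
    ujj = reduced_energy(spec, state_j.lam, state_j.scale, state_j.position)
    uij = reduced_energy(spec, state_i.lam, state_i.scale, state_j.position)
    uji = reduced_energy(spec, state_j.lam, state_j.scale, state_i.position)
    if not all(math.isfinite(u) for u in (uii, ujj, uij, uji)):
        raise ValueError("non-finite reduced energies in exchange attempt")
    delta = (uij + uji) - (uii + ujj)
    return min(1.0, math.exp(-delta))


@dataclass
class RestResult:
    """Trajectories and exchange statistics from a toy REST run."""

    positions: np.ndarray  # (n_replicas, n_steps)
    ladder: tuple[tuple[float, float], ...]
    pair_attempts: np.ndarray  # per neighbour pair (len R-1)
    pair_accepts: np.ndarray
    move_acceptance: np.ndarray  # per replica
    step_sizes: np.ndarray
    n_exchange_rounds: int

    @property
    def pair_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.pair_attempts > 0, self.pair_accepts / self.pair_attempts, np.nan
            )


def _tune_step_size(
    spec: ToyPotentialSpec, lam: float, scale: float, x0: float,
    rng: np.random.Generator, target: float = 0.4, n_tune: int = 500,
) -> float:
    """Crude step-size tuning toward a 30-50% move acceptance."""
    step = 0.5
    x = x0
    for block in range(5):
        acc = 0
        for _ in range(n_tune // 5):
            prop = x + rng.normal(0.0, step)
            du = reduced_energy(spec, lam, scale, prop) - reduced_energy(spec, lam, scale, x)
            if du <= 0 or rng.random() < math.exp(-du):
                x = prop
                acc += 1
        rate = acc / (n_tune // 5)
        if rate > target + 0.1:
            step *= 1.5
        elif rate < target - 0.1:
            step /= 1.5
    return step


def run_toy_rest(
    spec: ToyPotentialSpec,
    ladder: Sequence[tuple[float, float]],
    n_steps: int,
    exchange_interval: int = 10,
    seed: int = 0,
    step_size: float | None = None,
    start_position: float | None = None,
) -> RestResult:
    """Run the toy REST sampler.

    ``ladder`` is the ordered list of (lambda, scale) rungs; replica 0 is
    the base (physical) replica.  All replicas start at ``start_position``
    (default: the left-well minimum for a double well, 0 otherwise).
    Exchanges are attempted every ``exchange_interval`` steps, alternating
    odd/even neighbour-pair sweeps.  Fully deterministic under ``seed``.
    """
    if len(ladder) < 1:
        raise ValueError("ladder must have at least 1 rung")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if exchange_interval < 1:
        raise ValueError("exchange_interval must be >= 1")
    n_rep = len(ladder)
    lams = np.array([l for l, _ in ladder])
    scales = np.array([s for _, s in ladder])
    if np.any((scales <= 0) | (scales > 1)):
        raise ValueError("ladder scales must lie in (0, 1]")

    if start_position is None:
        start_position = (
            -spec.well_separation / 2.0 if spec.form == "double_well" else 0.0
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    tune_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    if step_size is None:
        steps = np.array(
            [
                _tune_step_size(spec, lams[r], scales[r], start_position, tune_rng)
                for r in range(n_rep)
            ]
        )
    else:
        steps = np.full(n_rep, float(step_size))

    x = np.full(n_rep, float(start_position))
    u = np.array([reduced_energy(spec, lams[r], scales[r], x[r]) for r in range(n_rep)])

    positions = np.empty((n_rep, n_steps))
    move_acc = np.zeros(n_rep)
    pair_attempts = np.zeros(max(n_rep - 1, 0), dtype=int)
    pair_accepts = np.zeros(max(n_rep - 1, 0), dtype=int)
    n_rounds = 0

    for t in range(n_steps):
        # Metropolis displacement moves, all replicas
        prop = x + rng.normal(0.0, 1.0, size=n_rep) * steps
        u_prop = np.array(
            [reduced_energy(spec, lams[r], scales[r], prop[r]) for r in range(n_rep)]
        )
        accept = rng.random(n_rep) < np.exp(np.minimum(0.0, -(u_prop - u)))
        x = np.where(accept, prop, x)
        u = np.where(accept, u_prop, u)
        move_acc += accept

        # neighbour exchanges, alternating parity sweeps
        if n_rep > 1 and (t + 1) % exchange_interval == 0:
            first = n_rounds % 2
            n_rounds += 1
            for i in range(first, n_rep - 1, 2):
                j = i + 1
                uij = reduced_energy(spec, lams[i], scales[i], x[j])
                uji = reduced_energy(spec, lams[j], scales[j], x[i])
                delta = (uij + uji) - (u[i] + u[j])
                pair_attempts[i] += 1
                if delta <= 0 or rng.random() < math.exp(-delta):
                    x[i], x[j] = x[j], x[i]
                    # replica i now holds the old x_j, evaluated in its own
                    # reduced potential (and vice versa)
                    u[i], u[j] = uij, uji
                    pair_accepts[i] += 1
        positions[:, t] = x

    return RestResult(
        positions=positions,
        ladder=tuple((float(l), float(s)) for l, s in ladder),
        pair_attempts=pair_attempts,
        pair_accepts=pair_accepts,
        move_acceptance=move_acc / n_steps,
        step_sizes=steps,
        n_exchange_rounds=n_rounds,
    )


# ---------------------------------------------------------------------------
# discrete variant with an exact stationary-distribution oracle
# ---------------------------------------------------------------------------

def _discrete_boltzmann(site_energies: np.ndarray, scale: float) -> np.ndarray:
    w = np.exp(-scale * site_energies)
    return w / w.sum()


def _discrete_transition_matrix(
    site_energies: np.ndarray, scales: tuple[float, float]
) -> np.ndarray:
    """Exact transition matrix of the composite two-replica discrete chain.

    State space: (s1, s2) pairs over S sites (flattened index s1 * S + s2).
    Each step picks one of three moves uniformly — update replica 1, update
    replica 2, or attempt a configuration exchange — each a Metropolis move,
    so the product of the two scaled Boltzmann distributions is stationary.
    Site-update proposals are uniform over the other S-1 sites.
    """
    e = np.asarray(site_energies, dtype=float)
    s = e.size
    p = np.zeros((s * s, s * s))

    def acc(du: float) -> float:
        return min(1.0, math.exp(-du))

    for s1 in range(s):
        for s2 in range(s):
            i = s1 * s + s2
            # move replica 1
            for t1 in range(s):
                if t1 == s1:
                    continue
                a = acc(scales[0] * (e[t1] - e[s1])) / (s - 1) / 3.0
                p[i, t1 * s + s2] += a
            # move replica 2
            for t2 in range(s):
                if t2 == s2:
                    continue
                a = acc(scales[1] * (e[t2] - e[s2])) / (s - 1) / 3.0
                p[i, s1 * s + t2] += a
            # exchange configurations
            du = (scales[0] * e[s2] + scales[1] * e[s1]) - (
                scales[0] * e[s1] + scales[1] * e[s2]
            )
            p[i, s2 * s + s1] += acc(du) / 3.0
            p[i, i] += 1.0 - p[i].sum()
    return p


def discrete_rest_exact_stationary(
    site_energies: Sequence[float], scales: tuple[float, float]
) -> np.ndarray:
    """Stationary distribution of the discrete chain by eigen-decomposition."""
    p = _discrete_transition_matrix(np.asarray(site_energies, float), scales)
    vals, vecs = np.linalg.eig(p.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def run_discrete_rest(
    site_energies: Sequence[float],
    scales: tuple[float, float],
    n_steps: int,
    seed: int = 0,
    start: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Simulate the discrete two-replica chain; return the empirical joint
    occupancy over (site of replica 1, site of replica 2)."""
    e = np.asarray(site_energies, dtype=float)
    s = e.size
    if s < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    moves = rng.integers(0, 3, size=n_steps)
    props = rng.integers(0, s - 1, size=n_steps)
    us = rng.random(n_steps)

    s1, s2 = start
    occ = np.zeros((s, s))
    for t in range(n_steps):
        m = moves[t]
        if m == 0:
            t1 = props[t] + (props[t] >= s1)  # uniform over other sites
            if us[t] < math.exp(-min(max(scales[0] * (e[t1] - e[s1]), 0.0), 700.0)):
                s1 = t1
        elif m == 1:
            t2 = props[t] + (props[t] >= s2)
            if us[t] < math.exp(-min(max(scales[1] * (e[t2] - e[s2]), 0.0), 700.0)):
                s2 = t2
        else:
            du = (scales[0] * e[s2] + scales[1] * e[s1]) - (
                scales[0] * e[s1] + scales[1] * e[s2]
            )
            if du <= 0 or us[t] < math.exp(-du):
                s1, s2 = s2, s1
        occ[s1, s2] += 1
    return occ / n_steps
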