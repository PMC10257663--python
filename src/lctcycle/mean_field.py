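"""Mean-field ODE model of the two-phase cell cycle.

The linear chain trick replaces the gamma-distributed G1 and S-G2
transit times with chains of exponential subphases, so the expected
subphase occupancies follow a linear ODE system d(state)/dt = A state.
Cells leaving the last S-G2 subphase divide into two newborn G1 cells;
death removes cells from any subphase at its part's death rate.

Propagation uses one matrix exponential per step size, applied
repeatedly on the uniform time grid.  Dead cells are tracked exactly
through absorbing per-phase compartments; a discrete-sum accounting
mode over per-part occupancies is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .structure import DEFAULT_STRUCTURE, PhaseStructure, RateSet

__all__ = [
    "PopulationTrajectory",
    "build_generator",
    "initial_state",
    "simulate_mean_field",
    "accumulate_dead_discrete",
    "average_phase_durations",
    "simulate_exponential_baseline",
    "default_times",
]


def default_times(t_max: float = 96.0, dt: float = 0.5) -> np.ndarray:
    """Uniform grid in hours, default the 30-minute cadence over 96 H."""
    n = int(round(t_max / dt))
    return np.linspace(0.0, n * dt, n + 1)


def build_generator(
    rates: RateSet,
    structure: Optional[PhaseStructure] = None,
    division_factor: float = 2.0,
    include_dead_compartments: bool = False,
) -> np.ndarray:
    """Generator matrix A of the linear mean-field system.

    State ordering: G1 subphases (part-major), then S-G2 subphases, then
    optionally two absorbing dead compartments (G1 deaths, S-G2 deaths).
    Each subphase loses mass at its part's progression + death rate;
    progression feeds the next subphase; the last S-G2 subphase feeds
    the first G1 subphase multiplied by ``division_factor`` (two
    daughters per division by default).
    """
    structure = structure or rates.structure
    if structure != rates.structure:
        raise ValueError("structure does not match the RateSet's structure")
    n = structure.n_states
    prog = rates.progression_per_subphase()
    death = rates.death_per_subphase()

    size = n + 2 if include_dead_compartments else n
    A = np.zeros((size, size))
    for j in range(n):
        A[j, j] -= prog[j] + death[j]
        if j < n - 1:
            A[j + 1, j] += prog[j]
        else:  # division: last S-G2 subphase -> first G1 subphase
            A[0, j] += division_factor * prog[j]
    if include_dead_compartments:
        n1 = structure.n_g1
        A[n, :n1] = death[:n1]
        A[n + 1, n1:n] = death[n1:]
    return A


def initial_state(
    structure: PhaseStructure,
    initial_g1_fraction: float,
    init_spread: str = "uniform",
    division_factor: float = 2.0,
    rates: Optional[RateSet] = None,
) -> np.ndarray:
    """Unit total mass split initial_g1_fraction : 1-fraction between phases.

    ``init_spread`` controls the within-phase distribution:
      - "uniform": equal mass in every subphase of a phase (default),
      - "first_subphase": all phase mass in the first subphase,
      - "stationary": proportional to the dominant right-eigenvector of
        the generator, renormalized per phase (requires ``rates``).
    """
    f = float(initial_g1_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"initial_g1_fraction must be in [0, 1], got {f}")
    n1, n2 = structure.n_g1, structure.n_sg2
    x = np.zeros(n1 + n2)
    if init_spread == "uniform":
        x[:n1] = f / n1
        x[n1:] = (1.0 - f) / n2
    elif init_spread == "first_subphase":
        x[0] = f
        x[n1] = 1.0 - f
    elif init_spread == "stationary":
        if rates is None:
            raise ValueError("init_spread='stationary' requires rates")
        A = build_generator(rates, structure, division_factor=division_factor)
        vals, vecs = np.linalg.eig(A)
        v = np.real(vecs[:, np.argmax(np.real(vals))])
        v = np.abs(v)
        g1 = v[:n1] / v[:n1].sum() if v[:n1].sum() > 0 else np.full(n1, 1.0 / n1)
        sg2 = v[n1:] / v[n1:].sum() if v[n1:].sum() > 0 else np.full(n2, 1.0 / n2)
        x[:n1] = f * g1
        x[n1:] = (1.0 - f) * sg2
    else:
        raise ValueError(f"unknown init_spread {init_spread!r}")
    return x


@dataclass
class PopulationTrajectory:
    """Expected per-subphase occupancies and dead-cell accumulation over time."""

    times: np.ndarray
    g1_states: np.ndarray        # (n_times, n_g1)
    sg2_states: np.ndarray       # (n_times, n_sg2)
    dead_g1: np.ndarray          # accumulated expected G1 deaths
    dead_sg2: np.ndarray
    structure: PhaseStructure
    rates: Optional[RateSet] = field(default=None, repr=False)

    @property
    def g1_total(self) -> np.ndarray:
        return self.g1_states.sum(axis=1)

    @property
    def sg2_total(self) -> np.ndarray:
        return self.sg2_states.sum(axis=1)

    @property
    def total(self) -> np.ndarray:
        return self.g1_total + self.sg2_total

    @property
    def dead_cumulative(self) -> np.ndarray:
        return self.dead_g1 + self.dead_sg2

    @property
    def frac_g1(self) -> np.ndarray:
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.g1_total / tot, np.nan)

    @property
    def death_rate_series(self) -> np.ndarray:
        """Instantaneous expected death count n(t) = sum_parts G_part(t) * gamma_part."""
        if self.rates is None:
            raise ValueError("trajectory carries no RateSet; death rate series unavailable")
        d = self.rates.death_per_subphase()
        n1 = self.structure.n_g1
        return self.g1_states @ d[:n1] + self.sg2_states @ d[n1:]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, g1, sg2, total, dead_cum."""
        return pd.DataFrame({
            "time_h": self.times,
            "g1": self.g1_total,
            "sg2": self.sg2_total,
            "total": self.total,
            "dead_cum": self.dead_cumulative,
        })


def _check_uniform(times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least 2 points")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValueError("times must be strictly increasing")
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-8, atol=1e-12):
        raise ValueError("times must be uniformly spaced (a single matrix exponential "
                         "is precomputed per step size)")
    return dt


def _propagate(A: np.ndarray, x0: np.ndarray, n_steps: int, dt: float) -> np.ndarray:
    T = expm(A * dt)
    out = np.empty((n_steps + 1, x0.size))
    out[0] = x0
    x = x0
    for i in range(n_steps):
        x = T @ x
        out[i + 1] = x
    return out


def simulate_mean_field(
    rates: RateSet,
    initial_g1_fraction: float,
    times: Optional[np.ndarray] = None,
    init_spread: str = "uniform",
    division_factor: float = 2.0,
) -> PopulationTrajectory:
    """Propagate the expected population from one starting cell.

    The state is augmented with absorbing dead compartments so
    ``dead_cumulative`` is the exact integral of the death flux.
    """
    times = default_times() if times is None else np.asarray(times, dtype=float)
    dt = _check_uniform(times)
    structure = rates.structure
    A = build_generator(rates, structure, division_factor=division_factor,
                        include_dead_compartments=True)
    x0_live = initial_state(structure, initial_g1_fraction, init_spread,
                            division_factor=division_factor, rates=rates)
    x0 = np.concatenate([x0_live, [0.0, 0.0]])
    states = _propagate(A, x0, times.size - 1, dt)
    n1 = structure.n_g1
    n = structure.n_states
    return PopulationTrajectory(
        times=times,
        g1_states=states[:, :n1],
        sg2_states=states[:, n1:n],
        dead_g1=states[:, n],
        dead_sg2=states[:, n + 1],
        structure=structure,
        rates=rates,
    )


def accumulate_dead_discrete(
    trajectory: PopulationTrajectory,
    rates: Optional[RateSet] = None,
    weight: str = "dt",
) -> np.ndarray:
    """Discrete-sum dead-cell accumulation N(T) = sum_{t<=T} n(t) [* dt].

    ``weight="dt"`` (default) weights the instantaneous death counts by
    the grid step (trapezoidal quadrature of the death flux), which
    converges to the exact absorbing-compartment value as dt -> 0.
    ``weight="unit"`` reproduces the bare running sum of n(t).
    """
    rates = rates or trajectory.rates
    if rates is None:
        raise ValueError("a RateSet is required for per-part death accounting")
    if trajectory.g1_states.shape[1] != trajectory.structure.n_g1:
        raise ValueError("per-subphase occupancies are required")
    d = rates.death_per_subphase()
    n1 = trajectory.structure.n_g1
    n_t = trajectory.g1_states @ d[:n1] + trajectory.sg2_states @ d[n1:]
    dt = _check_uniform(trajectory.times)
    if weight == "dt":
        out = np.concatenate([[0.0], np.cumsum((n_t[1:] + n_t[:-1]) / 2.0) * dt])
    elif weight == "unit":
        out = np.cumsum(n_t)
    else:
        raise ValueError(f"unknown weight {weight!r}")
    return out


def average_phase_durations(rates: RateSet,
                            structure: Optional[PhaseStructure] = None) -> tuple[float, float]:
    """Mean G1 and S-G2 durations (hours) implied by the progression rates.

    Transit time through part j is Erlang with shape = subphases per
    part and rate = the part's progression rate, so the phase mean is
    sum_j subphases_per_part / rate_j.  Death rates do not enter.
    """
    structure = structure or rates.structure
    if np.any(rates.alpha <= 0) or np.any(rates.beta <= 0):
        raise ValueError("average phase durations are infinite: all progression "
                         "rates must be strictly positive")
    g1 = float(np.sum(structure.g1_subphases_per_part / rates.alpha))
    sg2 = float(np.sum(structure.sg2_subphases_per_part / rates.beta))
    return g1, sg2


def simulate_exponential_baseline(
    alpha: float,
    beta: float,
    gamma1: float,
    gamma2: float,
    initial_g1_fraction: float,
    times: Optional[np.ndarray] = None,
    strict_paper_gamma: bool = False,
) -> PopulationTrajectory:
    """Two-state exponential model: one memoryless compartment per phase.

        dG1/dt = 2 beta G2 - (alpha + gamma1) G1
        dG2/dt = alpha G1 - (beta + gamma2) G2

    This is the chain model with a single subphase per phase; it cannot
    produce sustained oscillations in the G1 fraction.  With
    ``strict_paper_gamma`` the S-G2 loss term uses gamma1 instead of
    gamma2 (the uncorrected printed form).
    """
    times = default_times() if times is None else np.asarray(times, dtype=float)
    structure = PhaseStructure(1, 1, 1, 1)
    rates = RateSet(alpha=alpha, beta=beta, gamma1=gamma1, gamma2=gamma2,
                    structure=structure)
    if not strict_paper_gamma:
        return simulate_mean_field(rates, initial_g1_fraction, times)

    dt = _check_uniform(times)
    rates = rates.replace(gamma2=gamma1)  # printed form: gamma1 in both loss terms
    # 2x2 live block plus absorbing dead rows
    A = np.zeros((4, 4))
    A[0, 0] = -(alpha + gamma1)
    A[0, 1] = 2.0 * beta
    A[1, 0] = alpha
    A[1, 1] = -(beta + gamma1)
    A[2, 0] = gamma1
    A[3, 1] = gamma1
    f = float(initial_g1_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"initial_g1_fraction must be in [0, 1], got {f}")
    x0 = np.array([f, 1.0 - f, 0.0, 0.0])
    states = _propagate(A, x0, times.size - 1, dt)
    return PopulationTrajectory(
        times=times,
        g1_states=states[:, :1],
        sg2_states=states[:, 1:2],
        dead_g1=states[:, 2],
        dead_sg2=states[:, 3],
        structure=structure,
        rates=rates,
    )
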