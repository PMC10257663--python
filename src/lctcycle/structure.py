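"""Chain layout and rate containers for the two-phase cell-cycle model.

The cell cycle is reduced to two observable phases, G1 and the combined
S-G2 (a live-cell reporter typically cannot separate S from G2).  Each
phase is subdivided into *parts* (drug effects can differ between the
beginning, middle and end of a phase) and each part into *subphases*
(the linear chain trick: a chain of exponential stages yields an
Erlang-distributed phase transit time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhaseStructure", "RateSet", "DEFAULT_STRUCTURE"]


@dataclass(frozen=True)
class PhaseStructure:
    """Number of parts per phase and subphases per part.

    Defaults give 4 x 2 = 8 G1 subphases and 4 x 5 = 20 S-G2 subphases,
    the layout selected by gamma-shape estimation on untreated
    single-cell phase durations.
    """

    g1_parts: int = 4
    g1_subphases_per_part: int = 2
    sg2_parts: int = 4
    sg2_subphases_per_part: int = 5

    def __post_init__(self) -> None:
        for name in ("g1_parts", "g1_subphases_per_part", "sg2_parts", "sg2_subphases_per_part"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")

    @property
    def n_g1(self) -> int:
        """Total number of G1 subphases."""
        return self.g1_parts * self.g1_subphases_per_part

    @property
    def n_sg2(self) -> int:
        """Total number of S-G2 subphases."""
        return self.sg2_parts * self.sg2_subphases_per_part

    @property
    def n_states(self) -> int:
        """Total number of live-cell states."""
        return self.n_g1 + self.n_sg2

    def g1_part_of(self, subphase: int) -> int:
        """Part index (0-based) of a G1 subphase index."""
        return subphase // self.g1_subphases_per_part

    def sg2_part_of(self, subphase: int) -> int:
        return subphase // self.sg2_subphases_per_part


DEFAULT_STRUCTURE = PhaseStructure()


def _as_rates(x, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1 and n > 1:
        arr = np.full(n, float(arr[0]))
    if arr.shape != (n,):
        raise ValueError(f"{name} must have {n} per-part entries, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        bad = int(np.argmin(arr)) if np.any(arr < 0) else int(np.argmax(~np.isfinite(arr)))
        raise ValueError(f"{name}[{bad}] = {arr[bad]} is invalid: rates must be finite and >= 0")
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class RateSet:
    """Per-part progression and death rates (1/hour) at one condition.

    alpha  : G1 progression rate per part
    beta   : S-G2 progression rate per part
    gamma1 : G1 death rate per part
    gamma2 : S-G2 death rate per part

    Scalars broadcast to all parts of the phase.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma1: np.ndarray = 0.0
    gamma2: np.ndarray = 0.0
    structure: PhaseStructure = field(default=DEFAULT_STRUCTURE)

    def __post_init__(self) -> None:
        s = self.structure
        object.__setattr__(self, "alpha", _as_rates(self.alpha, s.g1_parts, "alpha"))
        object.__setattr__(self, "beta", _as_rates(self.beta, s.sg2_parts, "beta"))
        object.__setattr__(self, "gamma1", _as_rates(self.gamma1, s.g1_parts, "gamma1"))
        object.__setattr__(self, "gamma2", _as_rates(self.gamma2, s.sg2_parts, "gamma2"))

    # -- per-subphase expansions -------------------------------------------
    def progression_per_subphase(self) -> np.ndarray:
        """Progression rate of each of the n_g1 + n_sg2 subphases."""
        s = self.structure
        return np.concatenate([
            np.repeat(self.alpha, s.g1_subphases_per_part),
            np.repeat(self.beta, s.sg2_subphases_per_part),
        ])

    def death_per_subphase(self) -> np.ndarray:
        s = self.structure
        return np.concatenate([
            np.repeat(self.gamma1, s.g1_subphases_per_part),
            np.repeat(self.gamma2, s.sg2_subphases_per_part),
        ])

    def replace(self, **kw) -> "RateSet":
        d = dict(alpha=self.alpha, beta=self.beta, gamma1=self.gamma1,
                 gamma2=self.gamma2, structure=self.structure)
        d.update(kw)
        return RateSet(**d)

    def allclose(self, other: "RateSet", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        return (
            self.structure == other.structure
            and np.allclose(self.alpha, other.alpha, rtol=rtol, atol=atol)
            and np.allclose(self.beta, other.beta, rtol=rtol, atol=atol)
            and np.allclose(self.gamma1, other.gamma1, rtol=rtol, atol=atol)
            and np.allclose(self.gamma2, other.gamma2, rtol=rtol, atol=atol)
        )
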