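"""Hill dose-response mapping from drug concentration to cell-cycle rates.

Every progression and death rate in the chain model responds to drug
concentration C (nM) through a Hill function

    Hill(C) = E_min + (E_max - E_min) / (1 + (EC50 / C)^k)

with E_min the rate without drug, E_max the rate at saturating drug,
EC50 the half-maximal concentration and k the steepness.  A
DrugResponseProfile bundles one Hill curve per rate slot for one drug,
with the drug-free rates (all E_min values) shared across drugs and a
shared EC50/steepness per drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structure import RateSet

__all__ = ["HillParams", "DrugResponseProfile", "hill", "rates_at_concentration"]


@dataclass(frozen=True)
class HillParams:
    """Hill curve for a single rate slot (rates in 1/hour, EC50 in nM)."""

    e_min: float
    e_max: float
    ec50: float
    steepness: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.steepness <= 0:
            raise ValueError(f"steepness must be > 0, got {self.steepness}")
        if self.e_min < 0 or self.e_max < 0:
            raise ValueError("e_min and e_max must be >= 0")


def hill(concentration, params: HillParams):
    """Evaluate the Hill dose-response at a concentration (nM).

    C = 0 is the drug-free limit E_min (not evaluated through the power
    law).  Accepts scalars or arrays.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0 nM")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, params.ec50 / np.where(c > 0, c, 1.0), np.inf)
        # overflow of ratio**k is benign: the Hill term tends to e_min
        val = params.e_min + (params.e_max - params.e_min) / (1.0 + ratio ** params.steepness)
    val = np.where(c == 0, params.e_min, val)
    return float(val) if np.isscalar(concentration) or np.ndim(concentration) == 0 else val


_FAMILIES = ("alpha", "beta", "gamma1", "gamma2")


@dataclass(frozen=True)
class DrugResponseProfile:
    """Hill parameters for every rate slot of one drug.

    ``control_rates`` holds the shared drug-free RateSet (the E_min of
    every slot; death rates default to 0 in untreated control).
    ``e_max`` maps each rate family to its per-part saturating values;
    families absent from ``e_max`` are unaffected by the drug
    (E_max = E_min, e.g. a pure-G1 drug masks beta and gamma2).
    EC50 and steepness are shared across all slots of the drug.
    """

    drug_name: str
    control_rates: RateSet
    ec50: float
    steepness: float
    e_max: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.steepness <= 0:
            raise ValueError("ec50 and steepness must be > 0")
        s = self.control_rates.structure
        sizes = {"alpha": s.g1_parts, "beta": s.sg2_parts,
                 "gamma1": s.g1_parts, "gamma2": s.sg2_parts}
        checked = {}
        for fam, vals in self.e_max.items():
            if fam not in _FAMILIES:
                raise ValueError(f"unknown rate family {fam!r}")
            arr = np.atleast_1d(np.asarray(vals, dtype=float))
            if arr.size == 1:
                arr = np.full(sizes[fam], float(arr[0]))
            if arr.shape != (sizes[fam],):
                raise ValueError(f"e_max[{fam!r}] must have {sizes[fam]} entries")
            if np.any(arr < 0):
                raise ValueError(f"e_max[{fam!r}] must be >= 0")
            arr.setflags(write=False)
            checked[fam] = arr
        object.__setattr__(self, "e_max", checked)

    def slot_params(self, family: str, part: int) -> HillParams:
        e_min = float(getattr(self.control_rates, family)[part])
        if family in self.e_max:
            e_max = float(self.e_max[family][part])
        else:
            e_max = e_min
        return HillParams(e_min=e_min, e_max=e_max, ec50=self.ec50,
                          steepness=self.steepness)


def rates_at_concentration(profile: DrugResponseProfile, concentration: float) -> RateSet:
    """RateSet at one drug concentration via the per-slot Hill curves.

    At concentration 0 this returns exactly the shared control rates.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0 nM")
    if concentration == 0:
        return profile.control_rates
    s = profile.control_rates.structure
    out = {}
    for fam, n in (("alpha", s.g1_parts), ("beta", s.sg2_parts),
                   ("gamma1", s.g1_parts), ("gamma2", s.sg2_parts)):
        out[fam] = np.array([
            hill(concentration, profile.slot_params(fam, p)) for p in range(n)
        ])
    return RateSet(structure=s, **out)
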