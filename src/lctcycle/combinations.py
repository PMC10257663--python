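"""Bliss-independence prediction of two-drug responses.

The model-based route applies Bliss additivity to the drugs' effects on
cell-cycle progression rates: each drug's fractional reduction of a
progression rate relative to control, E = (rate_control - rate)/
rate_control, lies in [0, 1] (progression is saturable), and two drugs
combine as E_ab = E_a + E_b - E_a * E_b per rate slot.  Death is not
saturable, so added death rates combine by plain addition,
D_ab = D_a + D_b.  The combined RateSet is then simulated with the
mean-field model.

The baseline route applies the same Bliss formula directly to
normalized cell numbers per timepoint, the conventional reference that
ignores cell-cycle structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dose_response import DrugResponseProfile, rates_at_concentration
from .mean_field import PopulationTrajectory, simulate_mean_field
from .structure import RateSet

__all__ = ["ScaledEffect", "scale_effect", "unscale_effect", "drug_effects",
           "bliss_combine_rates", "predict_combination_trajectory",
           "bliss_combine_cell_numbers"]


def scale_effect(rate: float, control_rate: float) -> float:
    """Fractional reduction of a progression rate: (control - rate)/control."""
    if control_rate <= 0:
        raise ValueError("control_rate must be > 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate > control_rate:
        raise ValueError(
            f"rate {rate} exceeds control {control_rate}: progression effects "
            "must lie in [0, 1] (a rate increase has no Bliss representation)")
    return (control_rate - rate) / control_rate


def unscale_effect(effect: float, control_rate: float) -> float:
    """Inverse of :func:`scale_effect`: effect -> rate on the original scale."""
    return control_rate * (1.0 - effect)


@dataclass(frozen=True)
class ScaledEffect:
    """One drug's per-slot effects against a shared control RateSet.

    ``alpha``/``beta``: fractional progression reductions in [0, 1];
    ``dgamma1``/``dgamma2``: absolute added death rates (>= 0, 1/hour).
    """

    alpha: np.ndarray
    beta: np.ndarray
    dgamma1: np.ndarray
    dgamma2: np.ndarray
    control: RateSet

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"progression effect {name} must lie in [0, 1]")
            object.__setattr__(self, name, v)
        for name in ("dgamma1", "dgamma2"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0):
                raise ValueError(f"death effect {name} must be >= 0")
            object.__setattr__(self, name, v)


def drug_effects(profile: DrugResponseProfile, concentration: float,
                 control: Optional[RateSet] = None) -> ScaledEffect:
    """Scaled per-slot effects of one drug at one dose, relative to control."""
    control = control or profile.control_rates
    rates = rates_at_concentration(profile, concentration)
    alpha = np.array([scale_effect(r, c) for r, c in zip(rates.alpha, control.alpha)])
    beta = np.array([scale_effect(r, c) for r, c in zip(rates.beta, control.beta)])
    return ScaledEffect(alpha=alpha, beta=beta,
                        dgamma1=rates.gamma1 - control.gamma1,
                        dgamma2=rates.gamma2 - control.gamma2,
                        control=control)


def _bliss(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    return ea + eb - ea * eb


def bliss_combine_rates(effects_a: ScaledEffect, effects_b: ScaledEffect) -> RateSet:
    """Combined RateSet: Bliss on progression effects, addition on death rates."""
    if not effects_a.control.allclose(effects_b.control):
        raise ValueError("effects were computed against different controls")
    c = effects_a.control
    return RateSet(
        alpha=c.alpha * (1.0 - _bliss(effects_a.alpha, effects_b.alpha)),
        beta=c.beta * (1.0 - _bliss(effects_a.beta, effects_b.beta)),
        gamma1=c.gamma1 + effects_a.dgamma1 + effects_b.dgamma1,
        gamma2=c.gamma2 + effects_a.dgamma2 + effects_b.dgamma2,
        structure=c.structure,
    )


def predict_combination_trajectory(
    profile_a: DrugResponseProfile,
    profile_b: DrugResponseProfile,
    dose_a: float,
    dose_b: float,
    initial_g1_fraction: float = 0.75,
    times: Optional[np.ndarray] = None,
    init_spread: str = "uniform",
) -> PopulationTrajectory:
    """Simulate the rate-Bliss prediction for a two-drug treatment."""
    if not profile_a.control_rates.allclose(profile_b.control_rates):
        raise ValueError("profiles must share the same control rates")
    ea = drug_effects(profile_a, dose_a)
    eb = drug_effects(profile_b, dose_b)
    combined = bliss_combine_rates(ea, eb)
    return simulate_mean_field(combined, initial_g1_fraction, times,
                               init_spread=init_spread)


def bliss_combine_cell_numbers(count_a, count_b, count_control):
    """Baseline Bliss on normalized cell numbers, per timepoint.

    Counts are scaled by the untreated control, X_hat = (X_ctrl - X)/
    X_ctrl, combined with the Bliss formula, and scaled back.
    """
    a = np.asarray(count_a, dtype=float)
    b = np.asarray(count_b, dtype=float)
    ctrl = np.asarray(count_control, dtype=float)
    if a.shape != b.shape or a.shape != ctrl.shape:
        raise ValueError("count series must share one time grid")
    if np.any(ctrl <= 0):
        raise ValueError("control counts must be > 0 at every timepoint")
    ea = (ctrl - a) / ctrl
    eb = (ctrl - b) / ctrl
    return ctrl * (1.0 - _bliss(ea, eb))
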