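"""Simultaneous fitting of the chain model across drugs and doses.

The cost is the sum of squared errors between model-predicted and
observed G1 and S-G2 cell numbers over all timepoints, concentrations
and drugs.  Drug-free rates and the initial G1 fraction are shared
across drugs; each drug contributes one EC50, one steepness and the
saturating values (E_max) of its unmasked rate slots.  The cost is
minimized with a seeded differential-evolution global optimizer under
box bounds, searching rates on a log scale and the initial G1 fraction
on a logit scale.  Identifiability is assessed by a local sensitivity
profile: the cost as each fitted parameter is scaled across
[0.1, 10] x optimum while the others are held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .dose_response import DrugResponseProfile, rates_at_concentration
from .mean_field import simulate_mean_field
from .structure import DEFAULT_STRUCTURE, PhaseStructure, RateSet

__all__ = ["FitSpec", "FitResult", "sse_cost", "fit", "sensitivity_profile",
           "DEFAULT_FACTORS"]

DEFAULT_FACTORS = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)

_PENALTY = 1e12


@dataclass(frozen=True)
class _Param:
    name: str
    transform: str          # "log" | "logit"
    lo: float               # bounds in internal (transformed) space
    hi: float


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


@dataclass
class FitSpec:
    """Layout of the free parameter vector and optimizer settings.

    ``free_emax`` maps drug -> rate family -> per-part boolean mask of
    which E_max slots are free; families absent from the mapping are
    unaffected by that drug.  ``drug_doses`` maps drug -> dose list
    (nM); EC50 bounds default to [min positive dose / 10, max dose x 10].
    The two-state exponential baseline is the same layout with a
    1-part / 1-subphase structure.
    """

    drug_doses: dict
    free_emax: dict
    times: np.ndarray
    structure: PhaseStructure = DEFAULT_STRUCTURE
    initial_spread: str = "uniform"
    rate_bounds: tuple = (1e-4, 10.0)
    death_emax_bounds: tuple = (1e-4, 2.0)
    steepness_bounds: tuple = (0.1, 10.0)
    ec50_bounds: Optional[dict] = None
    g1_frac_bounds: tuple = (0.01, 0.99)
    optimizer: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        defaults = dict(popsize=15, maxiter=200, tol=1e-8, seed=0,
                        mutation=(0.5, 1.0), recombination=0.7,
                        polish=True, init="latinhypercube")
        defaults.update(self.optimizer)
        self.optimizer = defaults

    # ------------------------------------------------------------------
    def _ec50_bounds_for(self, drug: str) -> tuple[float, float]:
        if self.ec50_bounds and drug in self.ec50_bounds:
            return self.ec50_bounds[drug]
        doses = [d for d in self.drug_doses[drug] if d > 0]
        if not doses:
            raise ValueError(f"drug {drug!r} has no positive dose; supply ec50_bounds")
        return (min(doses) / 10.0, max(doses) * 10.0)

    def params(self) -> list[_Param]:
        s = self.structure
        lo, hi = np.log(self.rate_bounds[0]), np.log(self.rate_bounds[1])
        dlo, dhi = np.log(self.death_emax_bounds[0]), np.log(self.death_emax_bounds[1])
        out = [
            *(_Param(f"alpha_ctrl_{j+1}", "log", lo, hi) for j in range(s.g1_parts)),
            *(_Param(f"beta_ctrl_{j+1}", "log", lo, hi) for j in range(s.sg2_parts)),
            _Param("initial_g1_fraction", "logit",
                   _logit(self.g1_frac_bounds[0]), _logit(self.g1_frac_bounds[1])),
        ]
        sizes = {"alpha": s.g1_parts, "beta": s.sg2_parts,
                 "gamma1": s.g1_parts, "gamma2": s.sg2_parts}
        for drug in self.drug_doses:
            e_lo, e_hi = self._ec50_bounds_for(drug)
            out.append(_Param(f"ec50_{drug}", "log", np.log(e_lo), np.log(e_hi)))
            out.append(_Param(f"steepness_{drug}", "log",
                              np.log(self.steepness_bounds[0]),
                              np.log(self.steepness_bounds[1])))
            for fam, mask in self.free_emax.get(drug, {}).items():
                mask = list(mask)
                if len(mask) != sizes[fam]:
                    raise ValueError(f"free_emax[{drug!r}][{fam!r}] needs "
                                     f"{sizes[fam]} entries")
                b = (lo, hi) if fam in ("alpha", "beta") else (dlo, dhi)
                out.extend(
                    _Param(f"emax_{drug}_{fam}_{j+1}", "log", b[0], b[1])
                    for j in range(sizes[fam]) if mask[j]
                )
        return out

    def bounds(self) -> list[tuple[float, float]]:
        return [(p.lo, p.hi) for p in self.params()]

    def unpack(self, x: np.ndarray) -> tuple[RateSet, float, dict]:
        """Internal vector -> (control RateSet, initial G1 fraction, profiles)."""
        s = self.structure
        x = np.asarray(x, dtype=float)
        i = 0
        alpha = np.exp(x[i:i + s.g1_parts]); i += s.g1_parts
        beta = np.exp(x[i:i + s.sg2_parts]); i += s.sg2_parts
        f = _sigmoid(x[i]); i += 1
        control = RateSet(alpha=alpha, beta=beta, gamma1=0.0, gamma2=0.0, structure=s)
        sizes = {"alpha": s.g1_parts, "beta": s.sg2_parts,
                 "gamma1": s.g1_parts, "gamma2": s.sg2_parts}
        profiles = {}
        for drug in self.drug_doses:
            ec50 = float(np.exp(x[i])); i += 1
            k = float(np.exp(x[i])); i += 1
            e_max = {}
            for fam, mask in self.free_emax.get(drug, {}).items():
                vals = np.array(getattr(control, fam), dtype=float)
                for j in range(sizes[fam]):
                    if mask[j]:
                        vals[j] = np.exp(x[i]); i += 1
                e_max[fam] = vals
            profiles[drug] = DrugResponseProfile(
                drug_name=drug, control_rates=control, ec50=ec50,
                steepness=k, e_max=e_max)
        if i != x.size:
            raise ValueError(f"parameter vector length {x.size} != layout {i}")
        return control, f, profiles

    def pack(self, control: RateSet, f: float, profiles: dict) -> np.ndarray:
        """Inverse of :meth:`unpack` (lossless layout round-trip)."""
        s = self.structure
        vals = [*np.log(control.alpha), *np.log(control.beta), _logit(f)]
        sizes = {"alpha": s.g1_parts, "beta": s.sg2_parts,
                 "gamma1": s.g1_parts, "gamma2": s.sg2_parts}
        for drug in self.drug_doses:
            pr = profiles[drug]
            vals.extend([np.log(pr.ec50), np.log(pr.steepness)])
            for fam, mask in self.free_emax.get(drug, {}).items():
                for j in range(sizes[fam]):
                    if mask[j]:
                        vals.append(np.log(pr.e_max[fam][j]))
        return np.array(vals)


@dataclass
class FitResult:
    """Best parameters, final cost and optimizer diagnostics."""

    x: np.ndarray
    control_rates: RateSet
    initial_g1_fraction: float
    profiles: dict
    sse: float
    sse_per_drug: dict
    converged: bool
    n_iterations: int
    n_evaluations: int
    seed: Optional[int]
    trace: list = field(default_factory=list)
    message: str = ""


def _model_series(profile: DrugResponseProfile, conc: float, f: float,
                  times: np.ndarray, init_spread: str) -> tuple[np.ndarray, np.ndarray]:
    rates = rates_at_concentration(profile, conc)
    traj = simulate_mean_field(rates, f, times, init_spread=init_spread)
    return traj.g1_total, traj.sg2_total


def _series_of(entry) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(entry, "g1"):
        return np.asarray(entry.g1, float), np.asarray(entry.sg2, float)
    g1, sg2 = entry
    return np.asarray(g1, float), np.asarray(sg2, float)


def sse_cost(x: np.ndarray, spec: FitSpec, datasets: dict,
             per_drug: bool = False):
    """Sum of squared G1 + S-G2 residuals over all drugs x doses x times.

    ``datasets`` maps (drug, concentration_nM) to a ProcessedSeries or
    a (g1, sg2) array pair on ``spec.times``.  Invalid parameter
    vectors return a large finite penalty.
    """
    try:
        with np.errstate(over="ignore"):  # far-out DE trial vectors
            _, f, profiles = spec.unpack(x)
    except (ValueError, FloatingPointError, OverflowError):
        return (_PENALTY, {}) if per_drug else _PENALTY
    total = 0.0
    by_drug: dict[str, float] = {}
    for drug, doses in spec.drug_doses.items():
        acc = 0.0
        for conc in doses:
            g1_obs, sg2_obs = _series_of(datasets[(drug, float(conc))])
            try:
                g1_mod, sg2_mod = _model_series(profiles[drug], float(conc), f,
                                                spec.times, spec.initial_spread)
            except (ValueError, np.linalg.LinAlgError):
                return (_PENALTY, {}) if per_drug else _PENALTY
            acc += float(np.sum((g1_mod - g1_obs) ** 2)
                         + np.sum((sg2_mod - sg2_obs) ** 2))
        by_drug[drug] = acc
        total += acc
    if not np.isfinite(total):
        total = _PENALTY
    return (total, by_drug) if per_drug else total


def fit(spec: FitSpec, datasets: dict) -> FitResult:
    """Global fit of all free parameters by seeded differential evolution."""
    if not datasets:
        raise ValueError("no datasets supplied")
    for drug, doses in spec.drug_doses.items():
        for conc in doses:
            if (drug, float(conc)) not in datasets:
                raise ValueError(f"dataset missing for {drug} @ {conc} nM")
    opt = spec.optimizer
    trace: list[float] = []

    def cb(xk, convergence=0.0):
        trace.append(float(sse_cost(xk, spec, datasets)))

    res = differential_evolution(
        sse_cost, spec.bounds(), args=(spec, datasets),
        seed=opt["seed"], popsize=opt["popsize"], maxiter=opt["maxiter"],
        tol=opt["tol"], mutation=opt["mutation"],
        recombination=opt["recombination"], polish=False,
        init=opt["init"], callback=cb, updating="immediate",
    )
    x_best, converged, message = res.x, bool(res.success), str(res.message)
    n_evals = int(res.nfev)
    if opt["polish"]:
        # explicit local refinement; its gradient-convergence flag is the
        # fit's convergence diagnostic
        local = minimize(sse_cost, res.x, args=(spec, datasets),
                         method="L-BFGS-B", bounds=spec.bounds())
        n_evals += int(local.nfev)
        if local.fun <= res.fun:
            x_best = local.x
        converged = converged or bool(local.success)
        message = f"{message}; polish: {local.message}"
    sse, by_drug = sse_cost(x_best, spec, datasets, per_drug=True)
    control, f, profiles = spec.unpack(x_best)
    return FitResult(
        x=np.asarray(x_best), control_rates=control, initial_g1_fraction=f,
        profiles=profiles, sse=sse, sse_per_drug=by_drug,
        converged=converged, n_iterations=int(res.nit),
        n_evaluations=n_evals, seed=opt["seed"], trace=trace,
        message=message,
    )


def sensitivity_profile(
    result: FitResult,
    spec: FitSpec,
    datasets: dict,
    factors=DEFAULT_FACTORS,
    identifiability_threshold: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Local sensitivity: cost as each parameter is scaled across ``factors``.

    Each fitted parameter is multiplied (on its natural scale) by every
    factor while the others stay at the optimum.  A parameter is
    flagged identifiable when the cost rises by more than
    ``identifiability_threshold`` (fractional) at both factor 0.5 and
    factor 2.0.
    """
    factors = np.asarray(sorted(set(float(f) for f in factors)))
    for needed in (0.5, 1.0, 2.0):
        if not np.any(np.isclose(factors, needed)):
            raise ValueError(f"factor grid must contain {needed}")
    params = spec.params()
    base_cost = float(sse_cost(result.x, spec, datasets))
    rows = []
    ident = {}
    for i, p in enumerate(params):
        costs = {}
        for fac in factors:
            x = result.x.copy()
            if p.transform == "log":
                x[i] = x[i] + np.log(fac)
            else:  # logit-scale parameter: scale the natural fraction
                val = np.clip(_sigmoid(x[i]) * fac, 1e-3, 1.0 - 1e-3)
                x[i] = _logit(val)
            c = float(sse_cost(x, spec, datasets))
            costs[float(fac)] = c
            rows.append({"parameter": p.name, "factor": float(fac), "cost": c})
        floor = max(base_cost, 1e-12)
        ident[p.name] = bool(
            costs[0.5] > floor * (1.0 + identifiability_threshold)
            and costs[2.0] > floor * (1.0 + identifiability_threshold)
        )
    return pd.DataFrame(rows), ident
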