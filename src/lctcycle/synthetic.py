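"""Stochastic single-cell branching-process simulator and data generator.

Each cell traverses the subphase chain with independent exponential
dwell times at its part's progression rate, in competition with that
part's exponential death hazard.  Exit from the last S-G2 subphase is a
division spawning two newborn G1 cells.  This process is the exact
stochastic counterpart of the mean-field ODE system: ensemble means of
the subphase occupancies satisfy the linear system, which makes the
simulator a brute-force oracle for the deterministic model (and vice
versa).

The module also emulates a live-imaging dose-response experiment:
populations simulated per concentration on a fixed cadence, counts with
multiplicative lognormal noise, G1 fractions with binomial sampling
noise, and counts normalized to the mean of the first three timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dose_response import DrugResponseProfile, rates_at_concentration
from .mean_field import simulate_mean_field
from .structure import PhaseStructure, RateSet

__all__ = [
    "SingleCellRecord",
    "SyntheticDataset",
    "LINEAGE_COLUMNS",
    "simulate_cells",
    "population_counts",
    "ensemble_mean",
    "complete_phase_durations",
    "fate_summary",
    "generate_dose_response_dataset",
    "mean_field_dose_response",
]

LINEAGE_COLUMNS = [
    "cell_id", "parent_id", "root_id", "birth_time", "g1s_time",
    "end_time", "fate", "phase_at_end", "start_subphase",
]

FATE_DIVIDED = "divided"
FATE_DIED_G1 = "died_g1"
FATE_DIED_SG2 = "died_sg2"
FATE_CENSORED = "censored"


@dataclass(frozen=True)
class SingleCellRecord:
    """One row of the lineage table (times in hours)."""

    cell_id: int
    parent_id: int          # -1 for founder cells
    root_id: int            # founder ancestor, for per-lineage statistics
    birth_time: float
    g1s_time: Optional[float]
    end_time: float
    fate: str
    phase_at_end: str
    start_subphase: int     # global subphase index at birth (founders may start mid-cycle)


def _draw_exponential(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, n)


def simulate_cells(
    rates: RateSet,
    structure: Optional[PhaseStructure] = None,
    n0: int = 100,
    initial_g1_fraction: float = 0.75,
    t_max: float = 96.0,
    seed=None,
    init_spread: str = "uniform",
    max_cells: int = 50_000,
) -> pd.DataFrame:
    """Simulate a branching cell population; returns the lineage table.

    Founder cells are assigned to G1 with probability
    ``initial_g1_fraction`` and start at a subphase chosen per
    ``init_spread`` ("uniform" across the phase's subphases or
    "first_subphase").  Cells still alive at ``t_max`` are censored
    there.  Fully reproducible from ``seed``.

    If the total number of simulated cells would exceed ``max_cells``,
    newborn cohorts are uniformly subsampled (runtime guard; flagged in
    ``df.attrs["capped"]`` — population counts are biased downward
    after the cap triggers).
    """
    structure = structure or rates.structure
    if structure != rates.structure:
        raise ValueError("structure does not match the RateSet's structure")
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if not 0.0 <= initial_g1_fraction <= 1.0:
        raise ValueError("initial_g1_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n1, m = structure.n_g1, structure.n_states
    prog = rates.progression_per_subphase()
    death = rates.death_per_subphase()

    # founders: phase, then starting subphase within the phase
    in_g1 = rng.random(n0) < initial_g1_fraction
    if init_spread == "uniform":
        start = np.where(in_g1,
                         rng.integers(0, n1, n0),
                         n1 + rng.integers(0, m - n1, n0))
    elif init_spread == "first_subphase":
        start = np.where(in_g1, 0, n1)
    else:
        raise ValueError(f"unknown init_spread {init_spread!r}")

    cols: dict[str, list] = {c: [] for c in
                             ("cell_id", "parent_id", "root_id", "birth_time",
                              "g1s_time", "end_time", "fate", "start_subphase")}
    capped = False
    next_id = 0
    total = 0

    # current wave
    birth = np.zeros(n0)
    pos0 = start.astype(int)
    parent = np.full(n0, -1, dtype=int)
    root = np.arange(n0)

    while birth.size > 0:
        nw = birth.size
        if total + nw > max_cells:
            keep = max_cells - total
            capped = True
            if keep <= 0:
                break
            sel = rng.choice(nw, size=keep, replace=False)
            birth, pos0, parent, root = birth[sel], pos0[sel], parent[sel], root[sel]
            nw = keep
        ids = np.arange(next_id, next_id + nw)
        next_id += nw
        total += nw

        t = birth.copy()
        g1s = np.full(nw, np.nan)
        end = np.full(nw, np.nan)
        fate = np.empty(nw, dtype=object)
        alive = np.ones(nw, dtype=bool)
        for j in range(m):
            mask = alive & (pos0 <= j)
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            tp = _draw_exponential(rng, prog[j], idx.size)
            td = _draw_exponential(rng, death[j], idx.size)
            dies = td < tp
            t[idx] += np.minimum(tp, td)
            died_idx = idx[dies]
            if died_idx.size:
                alive[died_idx] = False
                end[died_idx] = t[died_idx]
                fate[died_idx] = FATE_DIED_G1 if j < n1 else FATE_DIED_SG2
            if j == n1 - 1:
                surv = idx[~dies]
                g1s[surv] = t[surv]  # G1 -> S transition time
        div_idx = np.flatnonzero(alive)
        end[div_idx] = t[div_idx]
        fate[div_idx] = FATE_DIVIDED

        cols["cell_id"].append(ids)
        cols["parent_id"].append(parent)
        cols["root_id"].append(root)
        cols["birth_time"].append(birth)
        cols["g1s_time"].append(g1s)
        cols["end_time"].append(end)
        cols["fate"].append(fate)
        cols["start_subphase"].append(pos0)

        # spawn two children per division occurring before the horizon
        moms = div_idx[end[div_idx] < t_max]
        nb = moms.size * 2
        birth = np.repeat(end[moms], 2)
        pos0 = np.zeros(nb, dtype=int)
        parent = np.repeat(ids[moms], 2)
        root = np.repeat(root[moms], 2)

    df = pd.DataFrame({c: np.concatenate(v) if v else np.array([], dtype=float)
                       for c, v in cols.items()})
    df["fate"] = df["fate"].astype(str) if len(df) else df["fate"]

    # censor at the observation horizon
    late = df["end_time"] >= t_max
    df.loc[late, "fate"] = FATE_CENSORED
    df.loc[late, "end_time"] = t_max
    df.loc[df["g1s_time"] >= t_max, "g1s_time"] = np.nan
    started_g1 = df["start_subphase"] < n1
    in_g1_at_end = (df["g1s_time"].isna() & started_g1) | (df["g1s_time"] > df["end_time"])
    df["phase_at_end"] = np.where(in_g1_at_end, "G1", "SG2")
    df.loc[df["fate"] == FATE_DIED_G1, "phase_at_end"] = "G1"
    df.loc[df["fate"] == FATE_DIED_SG2, "phase_at_end"] = "SG2"
    df = df[LINEAGE_COLUMNS[:6] + ["fate", "phase_at_end", "start_subphase"]]
    df.attrs["capped"] = capped
    df.attrs["seed"] = seed
    df.attrs["t_max"] = t_max
    df.attrs["n_g1_subphases"] = n1
    return df


def _phase_masks(records: pd.DataFrame, times: np.ndarray, n_g1: int):
    """Boolean (n_cells, n_times) alive/in-G1/dead masks at each grid time."""
    birth = records["birth_time"].to_numpy()[:, None]
    end = records["end_time"].to_numpy().copy()
    fate = records["fate"].to_numpy()
    censored = fate == FATE_CENSORED
    end_eff = np.where(censored, np.inf, end)[:, None]
    g1s = records["g1s_time"].to_numpy()
    started_g1 = (records["start_subphase"].to_numpy() < n_g1)
    t = times[None, :]
    alive = (birth <= t) & (t < end_eff)
    g1_boundary = np.where(np.isnan(g1s), np.where(started_g1, np.inf, -np.inf), g1s)
    in_g1 = alive & (t < g1_boundary[:, None])
    died = np.isin(fate, [FATE_DIED_G1, FATE_DIED_SG2])
    dead = died[:, None] & (end[:, None] <= t)
    dead_g1 = dead & (fate == FATE_DIED_G1)[:, None]
    return alive, in_g1, dead, dead_g1


def population_counts(records: pd.DataFrame, times: np.ndarray,
                      n_g1: Optional[int] = None) -> pd.DataFrame:
    """Alive / G1 / S-G2 / cumulative-dead counts on a time grid."""
    if len(records) == 0:
        raise ValueError("empty lineage table")
    n_g1 = n_g1 if n_g1 is not None else records.attrs.get("n_g1_subphases", 8)
    times = np.asarray(times, dtype=float)
    alive = np.zeros(times.size)
    g1 = np.zeros(times.size)
    dead = np.zeros(times.size)
    for lo in range(0, len(records), 20_000):
        chunk = records.iloc[lo:lo + 20_000]
        a, ig1, d, _ = _phase_masks(chunk, times, n_g1)
        alive += a.sum(axis=0)
        g1 += ig1.sum(axis=0)
        dead += d.sum(axis=0)
    return pd.DataFrame({"time_h": times, "count": alive, "g1": g1,
                         "sg2": alive - g1, "dead_cum": dead})


def ensemble_mean(records: pd.DataFrame, times: np.ndarray,
                  n0: int, n_g1: Optional[int] = None) -> pd.DataFrame:
    """Per-founder means and standard errors of G1/S-G2/dead counts.

    Founder lineages are i.i.d., so the per-founder mean is an unbiased
    estimate of the mean-field trajectory from one starting cell and
    the SE is the across-founder standard deviation / sqrt(n0).
    """
    if len(records) == 0:
        raise ValueError("empty lineage table")
    n_g1 = n_g1 if n_g1 is not None else records.attrs.get("n_g1_subphases", 8)
    times = np.asarray(times, dtype=float)
    roots = records["root_id"].to_numpy()
    sums = {k: np.zeros((n0, times.size)) for k in ("g1", "sg2", "dead")}
    for lo in range(0, len(records), 20_000):
        chunk = records.iloc[lo:lo + 20_000]
        a, ig1, d, _ = _phase_masks(chunk, times, n_g1)
        r = roots[lo:lo + 20_000]
        np.add.at(sums["g1"], r, ig1)
        np.add.at(sums["sg2"], r, a & ~ig1)
        np.add.at(sums["dead"], r, d)
    out = {"time_h": times}
    for k, mat in sums.items():
        out[f"{k}_mean"] = mat.mean(axis=0)
        out[f"{k}_se"] = mat.std(axis=0, ddof=1) / np.sqrt(n0)
    return pd.DataFrame(out)


def complete_phase_durations(records: pd.DataFrame, phase: str,
                             n_g1: Optional[int] = None) -> np.ndarray:
    """Fully observed phase durations (hours) from a lineage table.

    G1: cells that entered G1 at its first subphase (newborns or
    founders placed there) and reached the G1->S transition.
    S-G2: cells with an observed G1->S transition that went on to divide.
    Founders starting mid-phase and censored intervals are excluded.
    """
    n_g1 = n_g1 if n_g1 is not None else records.attrs.get("n_g1_subphases", 8)
    if phase == "G1":
        ok = (records["start_subphase"] == 0) & records["g1s_time"].notna()
        return (records.loc[ok, "g1s_time"] - records.loc[ok, "birth_time"]).to_numpy()
    if phase == "SG2":
        ok = records["g1s_time"].notna() & (records["fate"] == FATE_DIVIDED)
        return (records.loc[ok, "end_time"] - records.loc[ok, "g1s_time"]).to_numpy()
    raise ValueError(f"phase must be 'G1' or 'SG2', got {phase!r}")


def fate_summary(records: pd.DataFrame) -> dict:
    """Fate fractions of founder cells and relative cell-death count.

    Returns the fraction of founders that divided / died / were
    censored, the fraction of their daughters that divided again, and
    the relative death count (all deaths / number of founders), the
    population-level cytotoxicity readout.
    """
    if records is None or len(records) == 0:
        raise ValueError("empty lineage table")
    founders = records[records["parent_id"] == -1]
    n0 = len(founders)
    frac = {f: float((founders["fate"] == f).mean())
            for f in (FATE_DIVIDED, FATE_DIED_G1, FATE_DIED_SG2, FATE_CENSORED)}
    div_ids = founders.loc[founders["fate"] == FATE_DIVIDED, "cell_id"]
    daughters = records[records["parent_id"].isin(div_ids)]
    second = float((daughters["fate"] == FATE_DIVIDED).mean()) if len(daughters) else np.nan
    deaths = int(records["fate"].isin([FATE_DIED_G1, FATE_DIED_SG2]).sum())
    return {
        "n_initial": n0,
        "divided_fraction": frac[FATE_DIVIDED],
        "died_fraction": frac[FATE_DIED_G1] + frac[FATE_DIED_SG2],
        "censored_fraction": frac[FATE_CENSORED],
        "second_division_fraction": second,
        "relative_death_count": deaths / n0,
    }


@dataclass
class SyntheticDataset:
    """Emulated dose-response experiment with stored ground truth.

    ``population``: tidy table with columns drug, concentration_nM,
    replicate, time_h, count_norm (normalized to the mean of the first
    three timepoints), frac_g1.  ``lineages`` optionally maps
    (concentration, replicate) to lineage tables.  ``metadata`` records
    the seed, noise model and the generating DrugResponseProfile.
    """

    population: pd.DataFrame
    lineages: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def condition(self, concentration: float, replicate: Optional[int] = None) -> pd.DataFrame:
        df = self.population[np.isclose(self.population["concentration_nM"], concentration)]
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        return df.reset_index(drop=True)


def _noisy_observation(count: np.ndarray, frac_g1: np.ndarray, noise_cv: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        count = count * rng.lognormal(-0.5 * sigma ** 2, sigma, count.size)
    n = np.maximum(np.round(count).astype(int), 0)
    p = np.clip(frac_g1, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        obs_frac = np.where(n > 0, rng.binomial(np.maximum(n, 1), p) / np.maximum(n, 1), 0.0)
    return count, obs_frac


def normalize_first_three(counts: np.ndarray) -> np.ndarray:
    """Normalize a count series to the mean of its first three entries."""
    counts = np.asarray(counts, dtype=float)
    ref = counts[:3].mean()
    if ref <= 0:
        raise ValueError("cannot normalize: mean of the first three counts is <= 0")
    return counts / ref


def generate_dose_response_dataset(
    profile: DrugResponseProfile,
    concentrations,
    replicates: int = 3,
    cadence: float = 0.5,
    t_max: float = 96.0,
    n0: int = 1000,
    noise_cv: float = 0.05,
    seed=None,
    initial_g1_fraction: float = 0.75,
    keep_lineages: bool = False,
) -> SyntheticDataset:
    """Simulate a full single-drug dose-response experiment.

    Per concentration and replicate, a population of ``n0`` founder
    cells is simulated under the profile's rates at that concentration,
    binned on the cadence grid, observed with multiplicative lognormal
    counting noise (coefficient of variation ``noise_cv``) and binomial
    G1-fraction sampling, then normalized to the mean of the first
    three timepoints.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if n0 < 100:
        import warnings
        warnings.warn(f"n0={n0} is small; G1 fractions will be unstable", stacklevel=2)
    concentrations = [float(c) for c in concentrations]
    times = np.arange(0.0, t_max + cadence / 2, cadence)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(concentrations) * replicates)
    rows = []
    lineages = {}
    capped = False
    k = 0
    for conc in concentrations:
        rates = rates_at_concentration(profile, float(conc))
        for rep in range(replicates):
            child = children[k]; k += 1
            rng = np.random.default_rng(child)
            recs = simulate_cells(rates, n0=n0,
                                  initial_g1_fraction=initial_g1_fraction,
                                  t_max=t_max, seed=rng)
            capped = capped or recs.attrs.get("capped", False)
            pop = population_counts(recs, times)
            count = pop["count"].to_numpy().astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(count > 0, pop["g1"].to_numpy() / count, 0.0)
            count_obs, frac_obs = _noisy_observation(count, frac, noise_cv, rng)
            rows.append(pd.DataFrame({
                "drug": profile.drug_name,
                "concentration_nM": float(conc),
                "replicate": rep,
                "time_h": times,
                "count_norm": normalize_first_three(count_obs),
                "frac_g1": frac_obs,
            }))
            if keep_lineages:
                lineages[(float(conc), rep)] = recs
    return SyntheticDataset(
        population=pd.concat(rows, ignore_index=True),
        lineages=lineages,
        metadata={
            "seed": seed, "noise_cv": noise_cv, "n0": n0,
            "cadence_h": cadence, "t_max_h": t_max,
            "initial_g1_fraction": initial_g1_fraction,
            "noise_model": "lognormal counts, binomial G1 fraction",
            "true_profile": profile,
            "capped": capped,
        },
    )


def mean_field_dose_response(
    profile: DrugResponseProfile,
    concentrations,
    times: Optional[np.ndarray] = None,
    initial_g1_fraction: float = 0.75,
) -> dict:
    """Noiseless expected G1/S-G2 series per concentration (model units,
    one starting cell) — the n0 -> infinity limit of the experiment."""
    from .mean_field import default_times
    times = default_times() if times is None else np.asarray(times, dtype=float)
    out = {}
    for conc in concentrations:
        rates = rates_at_concentration(profile, float(conc))
        traj = simulate_mean_field(rates, initial_g1_fraction, times)
        out[float(conc)] = (traj.g1_total, traj.sg2_total)
    return out
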