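"""Turn raw population tables into model-ready G1/S-G2 count series.

Pipeline order is fixed: normalize -> smooth (Savitzky-Golay, per
replicate) -> average replicates -> split into phase counts.  Smoothing
before averaging is the default; the alternative ordering is available
via ``smooth_each_replicate=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = ["ProcessedSeries", "split_phase_counts", "smooth_series",
           "average_replicates", "process_condition", "process_dataset"]

log = logging.getLogger(__name__)


@dataclass
class ProcessedSeries:
    """Normalized, smoothed, replicate-averaged G1 and S-G2 counts."""

    times: np.ndarray
    g1: np.ndarray
    sg2: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.g1 + self.sg2


def split_phase_counts(total_norm, frac_g1) -> tuple[np.ndarray, np.ndarray]:
    """Split a total-count series into G1 and S-G2 counts.

    g1 = total * frac_g1, sg2 = total * (1 - frac_g1).
    """
    total = np.asarray(total_norm, dtype=float)
    frac = np.asarray(frac_g1, dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("frac_g1 must lie in [0, 1]")
    return total * frac, total * (1.0 - frac)


def smooth_series(series, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Endpoints are handled by polynomial extrapolation within the edge
    windows; length is preserved.  Negative smoothed values are clamped
    to 0 (logged).
    """
    y = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if y.size < window:
        raise ValueError(f"series of length {y.size} is too short: need at least "
                         f"{window} samples for window={window}")
    out = savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")
    neg = out < 0
    if np.any(neg):
        log.warning("smoothing produced %d negative values; clamped to 0", int(neg.sum()))
        out = np.where(neg, 0.0, out)
    return out


def average_replicates(series_list: Sequence, times_list: Optional[Sequence] = None) -> np.ndarray:
    """Pointwise arithmetic mean of replicate series on a shared grid."""
    if len(series_list) == 0:
        raise ValueError("no replicate series given")
    arrs = [np.asarray(s, dtype=float) for s in series_list]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("replicate series must share one time grid (equal lengths)")
    if times_list is not None:
        t0 = np.asarray(times_list[0], dtype=float)
        for t in times_list[1:]:
            if not np.allclose(np.asarray(t, dtype=float), t0):
                raise ValueError("replicate time grids do not match")
    return np.mean(arrs, axis=0)


def process_condition(
    times: np.ndarray,
    totals: Sequence[np.ndarray],
    fracs: Sequence[np.ndarray],
    window: int = 11,
    polyorder: int = 3,
    smooth_each_replicate: bool = True,
    provenance: Optional[dict] = None,
) -> ProcessedSeries:
    """Smooth, average and phase-split replicate series of one condition.

    ``totals`` are already-normalized total counts and ``fracs`` the G1
    fractions, one array per replicate on the shared ``times`` grid.
    """
    times = np.asarray(times, dtype=float)
    if smooth_each_replicate:
        totals_s = [smooth_series(t, window, polyorder) for t in totals]
        fracs_s = [np.clip(smooth_series(f, window, polyorder), 0.0, 1.0) for f in fracs]
        total = average_replicates(totals_s)
        frac = average_replicates(fracs_s)
    else:
        total = smooth_series(average_replicates(totals), window, polyorder)
        frac = np.clip(smooth_series(average_replicates(fracs), window, polyorder), 0.0, 1.0)
    g1, sg2 = split_phase_counts(total, frac)
    prov = dict(provenance or {})
    prov.update({
        "pipeline": "normalize->smooth->average->split",
        "smooth_each_replicate": smooth_each_replicate,
        "window": window, "polyorder": polyorder,
    })
    return ProcessedSeries(times=times, g1=g1, sg2=sg2, provenance=prov)


def process_dataset(population: pd.DataFrame, window: int = 11, polyorder: int = 3,
                    smooth_each_replicate: bool = True) -> dict:
    """Process a tidy population table into {(drug, concentration): ProcessedSeries}."""
    out = {}
    for (drug, conc), grp in population.groupby(["drug", "concentration_nM"], sort=True):
        reps = sorted(grp["replicate"].unique())
        times = np.sort(grp[grp["replicate"] == reps[0]]["time_h"].to_numpy())
        totals, fracs = [], []
        for r in reps:
            sub = grp[grp["replicate"] == r].sort_values("time_h")
            if not np.allclose(sub["time_h"].to_numpy(), times):
                raise ValueError(f"replicate time grids differ for {drug} @ {conc} nM")
            totals.append(sub["count_norm"].to_numpy())
            fracs.append(sub["frac_g1"].to_numpy())
        out[(drug, float(conc))] = process_condition(
            times, totals, fracs, window=window, polyorder=polyorder,
            smooth_each_replicate=smooth_each_replicate,
            provenance={"drug": drug, "concentration_nM": float(conc),
                        "replicates": list(reps)},
        )
    return out
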