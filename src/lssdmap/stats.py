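"""Histogram statistics over LSSD maps and training-session trajectories.

A map's quality summary is the mean and standard deviation of its valid
cells (LSSD_AVG, LSSD_SD).  The training effect of one session is
``delta_sd = LSSD_SD(initial) - LSSD_SD(final)``, tested for significance
with a two-tailed F test on the two cell-value variances at the 95%
confidence level.  Map cells are treated as independent observations in
that test — a simplification inherited from the feedback protocol itself
(see the methods note) rather than a statistically rigorous model of
spatially correlated contour errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metric import LSSDMap


@dataclass(frozen=True)
class LSSDStats:
    """Summary of one LSSD map's valid-cell distribution (all mm)."""

    mean: float
    sd: float
    min: float
    max: float
    n_cells: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray


@dataclass(frozen=True)
class DeltaResult:
    """Initial-vs-final spread comparison for one session."""

    delta_sd: float
    f_statistic: float
    p_value: float
    significant_95: bool
    df: tuple[int, int]
    degenerate: bool = False


@dataclass
class SessionRecord:
    """Ordered (sequence index, map, stats) triples of one training session."""

    entries: list[tuple[int, LSSDMap, LSSDStats]] = field(default_factory=list)

    def append(self, lssd_map: LSSDMap, bin_width: float = 0.5) -> None:
        seq = lssd_map.sequence_index
        if self.entries and seq <= self.entries[-1][0]:
            raise ValueError("sequence indices must be strictly increasing")
        self.entries.append((seq, lssd_map, map_stats(lssd_map, bin_width)))

    @property
    def initial(self) -> tuple[int, LSSDMap, LSSDStats]:
        return self.entries[0]

    @property
    def final(self) -> tuple[int, LSSDMap, LSSDStats]:
        return self.entries[-1]

    def delta(self) -> DeltaResult:
        return delta_lssd(self.initial[1], self.final[1])


def _values(source: LSSDMap | np.ndarray) -> np.ndarray:
    if isinstance(source, LSSDMap):
        return source.valid_values()
    return np.asarray(source, dtype=float).ravel()


def map_stats(lssd_map: LSSDMap | np.ndarray, bin_width: float = 0.5) -> LSSDStats:
    """Mean/SD/min/max and a zero-centred histogram of a map's valid cells.

    The standard deviation uses the n-1 (sample) denominator.  Histogram
    bins have the given width with one bin centred on 0; the histogram is
    descriptive only, statistics are computed from the raw values.
    """
    v = _values(lssd_map)
    if v.size == 0:
        raise ValueError("map has no valid cells")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    half = bin_width / 2.0
    kmin = math.floor((float(v.min()) + half) / bin_width) - 1
    kmax = math.ceil((float(v.max()) - half) / bin_width) + 1
    edges = (np.arange(kmin, kmax + 2) - 0.5) * bin_width
    counts, _ = np.histogram(v, bins=edges)
    return LSSDStats(
        mean=mean,
        sd=sd,
        min=float(v.min()),
        max=float(v.max()),
        n_cells=int(v.size),
        hist_edges=edges,
        hist_counts=counts,
    )


def delta_lssd(initial: LSSDMap | np.ndarray, final: LSSDMap | np.ndarray) -> DeltaResult:
    """SD reduction between two maps plus a two-tailed variance F test.

    ``delta_sd = sd(initial) - sd(final)``.  The F statistic is the larger
    sample variance over the smaller with the matching (n-1, n-1) degrees of
    freedom; the two-tailed p-value is ``2 * min(CDF, 1 - CDF)``.
    """
    vi = _values(initial)
    vf = _values(final)
    if vi.size < 2 or vf.size < 2:
        raise ValueError("both maps need at least 2 valid cells")
    si2 = float(np.var(vi, ddof=1))
    sf2 = float(np.var(vf, ddof=1))
    delta_sd = math.sqrt(si2) - math.sqrt(sf2)
    if si2 == 0.0 or sf2 == 0.0:
        if si2 == sf2:
            return DeltaResult(delta_sd, 1.0, 1.0, False, (vi.size - 1, vf.size - 1),
                               degenerate=True)
        return DeltaResult(delta_sd, math.inf, math.nan, False,
                           (vi.size - 1, vf.size - 1), degenerate=True)
    if si2 >= sf2:
        f_stat, df = si2 / sf2, (vi.size - 1, vf.size - 1)
    else:
        f_stat, df = sf2 / si2, (vf.size - 1, vi.size - 1)
    cdf = float(sps.f.cdf(f_stat, *df))
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return DeltaResult(delta_sd, f_stat, p, p < 0.05, df)


def aggregate_maps(maps: list[LSSDMap], bin_width: float = 0.5) -> LSSDStats:
    """Pool the valid cells of several maps into one distribution summary."""
    if not maps:
        raise ValueError("aggregate_maps requires at least one map")
    pooled = np.concatenate([m.valid_values() for m in maps])
    if pooled.size == 0:
        raise ValueError("no valid cells across the supplied maps")
    return map_stats(pooled, bin_width)


def session_trajectory(record: SessionRecord) -> pd.DataFrame:
    """Per-update (sequence index, LSSD_AVG, LSSD_SD) series of a session."""
    if not record.entries:
        raise ValueError("empty session record")
    rows = [
        {
            "sequence_index": seq,
            "lssd_avg_mm": st.mean,
            "lssd_sd_mm": st.sd,
            "n_cells": st.n_cells,
            "is_final": i == len(record.entries) - 1,
        }
        for i, (seq, _m, st) in enumerate(record.entries)
    ]
    return pd.DataFrame(rows)
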