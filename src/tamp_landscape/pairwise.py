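"""Head-to-head competitions, doubling times, and aCGH population frequency.

Pairwise fitness against a GFP-marked neutral reference is the slope of
``ln(dark cells / GFP+ cells)`` versus generations, so it is reported in
natural-log units per generation; the pooled bar-seq assay measures slopes
in log2 units, and the two agree after dividing the pairwise slope by
``ln 2`` (exposed via ``per_generation_log2=True``).

The population frequency of an aneuploid subclone is inverted from a
mixture's mean copy number: if a region averages ``c_hat`` copies in a
population where the clone carries ``c`` copies over a ``c0``-copy
baseline, the clone's frequency is ``(c_hat - c0) / (c - c0)``.  When the
clonal copy number is unknown it is taken as the population copy number
rounded up to the next integer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "gfp_competition_fitness",
    "doubling_time",
    "AcghFrequency",
    "acgh_population_frequency",
]


def gfp_competition_fitness(trajectory: pd.DataFrame,
                            per_generation_log2: bool = False,
                            ) -> tuple[float, float]:
    """Relative fitness from a GFP competition trajectory.

    ``trajectory`` needs columns ``generations, dark, gfp``.  Timepoints
    with a zero count on either channel are dropped with a warning; fewer
    than three remaining timepoints is an error.  Returns ``(slope, se)``
    from the OLS regression of ``ln(dark/gfp)`` on generations, divided by
    ``ln 2`` if ``per_generation_log2`` (to match pooled-assay units).
    """
    t = trajectory[["generations", "dark", "gfp"]].astype(float)
    bad = (t["dark"] <= 0) | (t["gfp"] <= 0)
    if bad.any():
        logger.warning("dropping %d timepoint(s) with zero cell counts",
                       int(bad.sum()))
        t = t[~bad]
    if len(t) < 3:
        raise ValueError(f"only {len(t)} usable timepoints; need >= 3")
    y = np.log(t["dark"].to_numpy() / t["gfp"].to_numpy())
    res = stats.linregress(t["generations"].to_numpy(), y)
    slope, se = float(res.slope), float(res.stderr)
    if per_generation_log2:
        slope /= math.log(2.0)
        se /= math.log(2.0)
    return slope, se


def doubling_time(hours, density, window: tuple[float, float] | None = None,
                  ) -> tuple[float, float]:
    """Doubling time (hours) from a batch-culture growth curve.

    Regresses log2(density) on time over the exponential window (a
    ``(start, stop)`` time range; default all points).  The doubling time
    is 1/slope; its SE follows from the slope SE by the delta method.
    A non-positive slope raises ("no growth detected").
    """
    t = np.asarray(hours, dtype=float)
    d = np.asarray(density, dtype=float)
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, d = t[mask], d[mask]
    if len(t) < 3:
        raise ValueError("need >= 3 points in the exponential window")
    if np.any(d <= 0):
        raise ValueError("non-positive density")
    res = stats.linregress(t, np.log2(d))
    b = float(res.slope)
    if b <= 0:
        raise ValueError("no growth detected (non-positive slope)")
    se = float(res.stderr) / b ** 2 if res.stderr is not None else np.nan
    return 1.0 / b, se


@dataclass(frozen=True)
class AcghFrequency:
    """Population frequency of an aneuploid event from aCGH probes."""

    frequency: float
    below_detection: bool
    population_copy: float
    clonal_copy: int
    baseline_copy: int
    n_probes: int


def acgh_population_frequency(profile: pd.DataFrame,
                              region: tuple[str, float, float],
                              baseline_copy: int = 2,
                              clonal_copy: int | None = None,
                              ploidy: int = 2,
                              detection_limit: float = 0.06,
                              ) -> AcghFrequency:
    """Invert a mixture's mean copy number into a clone frequency.

    ``profile`` has columns ``chrom, position, log2ratio``; ``region`` is a
    ``(chrom, start, end)`` interval that must contain at least one probe.
    The population copy number is ``ploidy * 2**mean(log2ratio)`` over the
    region; when ``clonal_copy`` is None it defaults to the population copy
    number rounded up to the next integer (at least baseline + 1).
    Frequencies below ``detection_limit`` (default 6%) are flagged as below
    the detection limit.  An explicit clonal copy equal to the baseline is
    an error: the mixture fraction is then undefined.
    """
    chrom, lo, hi = region
    probes = profile[(profile["chrom"] == chrom)
                     & (profile["position"] >= lo)
                     & (profile["position"] < hi)]
    if probes.empty:
        raise ValueError(f"no probes in region {region}")
    mean_ratio = float(probes["log2ratio"].mean())
    c_hat = ploidy * 2.0 ** mean_ratio
    if clonal_copy is None:
        clonal = max(int(math.ceil(c_hat)), baseline_copy + 1)
    else:
        clonal = int(clonal_copy)
        if clonal == baseline_copy:
            raise ValueError("clonal copy equals baseline: mixture undefined")
    f = (c_hat - baseline_copy) / (clonal - baseline_copy)
    f = float(np.clip(f, 0.0, 1.0))
    return AcghFrequency(frequency=f,
                         below_detection=f < detection_limit,
                         population_copy=float(c_hat),
                         clonal_copy=clonal,
                         baseline_copy=int(baseline_copy),
                         n_probes=int(len(probes)))
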