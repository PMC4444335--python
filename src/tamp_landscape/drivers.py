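"""Cross-condition integration, driver-gene filtering, and the exact tests.

The per-condition segmentations are merged into a single partition of each
chromosome (the union of all breakpoint boundaries), so that every region
has a fitness in every condition; regions whose fitness exceeds a common
threshold in *all* conditions are the universally advantageous/detrimental
amplifications, everything else is condition-specific.

Downstep regions flag candidate driver genes.  Because each breakpoint
region spans several genes, the gene list is filtered against independent
evidence (up-regulation in evolved clones, single-gene amplification
fitness outliers, recurrent mutation); a gene in a Downstep region that
appears on at least one evidence list for that condition is a candidate.

Also here: the small-sample statistics used throughout — an exact
Wilcoxon rank-sum test by complete enumeration, Fisher's exact test by
hypergeometric summation with Holm–Bonferroni correction, between-condition
fitness variance as a pleiotropy measure, and the Downstep-vs-Upstep
single-gene fitness contrast.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel
from .landscape import Breakpoint, FitnessSegment

logger = logging.getLogger(__name__)

__all__ = [
    "union_regions",
    "common_effect_regions",
    "step_gene_contrast",
    "DriverCandidate",
    "filter_driver_candidates",
    "driver_coverage",
    "AmpliconPrediction",
    "predict_amplicon",
    "pleiotropy_variance",
    "rank_sum_exact",
    "fisher_exact",
    "holm_bonferroni",
    "fisher_exact_with_holm",
    "cen_threshold_genes",
]

# Printed single-gene amplification fitness cutoffs (mean +/- 2 SD of the
# low-copy-plasmid dataset) used for the "CEN mean + 2SD" evidence lists.
CEN_MEAN_2SD_THRESHOLDS: dict[str, tuple[float, float]] = {
    "phosphate": (-0.096, 0.097),
    "glucose": (-0.052, 0.050),
}
CEN_OUTLIER_THRESHOLDS: tuple[float, float] = (-0.10, 0.10)


# ---------------------------------------------------------------------------
# Region algebra across conditions
# ---------------------------------------------------------------------------

def _boundary_position(left: FitnessSegment, right: FitnessSegment) -> float:
    """Deterministic genomic position of a breakpoint: the midpoint of the
    gap between the flanking Tamps."""
    return (left.end_position + right.start_position) / 2.0


def union_regions(condition_segments: Mapping[str, Sequence[FitnessSegment]],
                  ) -> pd.DataFrame:
    """Partition each chromosome by the union of all conditions' breakpoints.

    Returns one row per region with columns ``chrom, start, end`` plus a
    fitness column per condition (the mean of the segment covering the
    region).  The region count is the minimum number of genomic intervals
    with a distinct fitness in at least one condition.
    """
    if not condition_segments:
        raise ValueError("need at least one condition")
    conditions = sorted(condition_segments)
    by_chrom: dict[str, dict[str, list[FitnessSegment]]] = {}
    for cond in conditions:
        for seg in condition_segments[cond]:
            by_chrom.setdefault(seg.chromosome, {}).setdefault(
                cond, []).append(seg)
    rows = []
    for chrom in sorted(by_chrom):
        segs_by_cond = {c: sorted(s, key=lambda x: x.start_index)
                        for c, s in by_chrom[chrom].items()}
        if set(segs_by_cond) != set(conditions):
            missing = set(conditions) - set(segs_by_cond)
            raise ValueError(f"chromosome {chrom} missing in conditions "
                             f"{sorted(missing)}")
        lo = min(s[0].start_position for s in segs_by_cond.values())
        hi = max(s[-1].end_position for s in segs_by_cond.values())
        cuts: set[float] = set()
        for segs in segs_by_cond.values():
            for left, right in zip(segs[:-1], segs[1:]):
                cuts.add(_boundary_position(left, right))
        edges = [lo] + sorted(cuts) + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            mid = (a + b) / 2.0
            rec = {"chrom": chrom, "start": a, "end": b}
            for cond, segs in segs_by_cond.items():
                rec[cond] = _covering_mean(segs, mid)
            rows.append(rec)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"] + conditions)


def _covering_mean(segments: Sequence[FitnessSegment], position: float,
                   ) -> float:
    """Mean fitness of the segment covering a position; positions beyond the
    profiled range take the nearest segment."""
    best = None
    for seg in segments:
        left, right = seg.start_position, seg.end_position
        if left <= position <= right:
            return seg.mean_fitness
        d = min(abs(position - left), abs(position - right))
        if best is None or d < best[0]:
            best = (d, seg.mean_fitness)
    assert best is not None
    return best[1]


def common_effect_regions(regions: pd.DataFrame,
                          conditions: Sequence[str],
                          threshold: float = 0.05) -> pd.Series:
    """Classify regions by the sign consistency of their fitness effects.

    ``universally_advantageous`` if fitness > threshold in all conditions,
    ``universally_detrimental`` if < -threshold in all, else
    ``condition_specific``.
    """
    vals = regions[list(conditions)].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("every region needs a fitness in every condition")
    adv = (vals > threshold).all(axis=1)
    det = (vals < -threshold).all(axis=1)
    out = np.where(adv, "universally_advantageous",
                   np.where(det, "universally_detrimental",
                            "condition_specific"))
    return pd.Series(out, index=regions.index, name="effect_class")


# ---------------------------------------------------------------------------
# Single-gene fitness at breakpoints
# ---------------------------------------------------------------------------

def step_gene_contrast(downstep_gene_sets: Sequence[Sequence[str]],
                       upstep_gene_sets: Sequence[Sequence[str]],
                       gene_fitness: Mapping[str, float],
                       equal_var: bool = True,
                       ) -> tuple[list[float], list[float], float, float]:
    """Compare mean single-gene amplification fitness at Downsteps vs Upsteps.

    For each breakpoint the mean single-gene fitness over its gene set is
    taken (breakpoints with no covered gene are skipped with a warning);
    the two groups of per-breakpoint means are compared by an unpaired
    two-tailed t test (pooled variance by default, Welch via
    ``equal_var=False``).  Returns (downstep means, upstep means, t, p).
    """

    def per_break(gene_sets: Sequence[Sequence[str]], label: str) -> list[float]:
        means = []
        for genes in gene_sets:
            vals = [gene_fitness[g] for g in genes if g in gene_fitness]
            if not vals:
                logger.warning("%s breakpoint with no gene in the fitness "
                               "table; skipped", label)
                continue
            means.append(float(np.mean(vals)))
        return means

    down = per_break(downstep_gene_sets, "Downstep")
    up = per_break(upstep_gene_sets, "Upstep")
    if len(down) < 2 or len(up) < 2:
        raise ValueError("need >= 2 breakpoints per class for the contrast")
    t, p = stats.ttest_ind(down, up, equal_var=equal_var)
    return down, up, float(t), float(p)


# ---------------------------------------------------------------------------
# Driver candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriverCandidate:
    """A Downstep gene supported by at least one line of evidence."""

    gene: str
    condition: str
    downstep: str
    evidence: tuple[str, ...]


EVIDENCE_KINDS = ("upregulated", "CEN_outlier", "CEN_mean_2SD", "mutated")


def cen_threshold_genes(gene_fitness: Mapping[str, float],
                        low: float, high: float) -> set[str]:
    """Genes with single-gene amplification fitness < low or > high."""
    return {g for g, f in gene_fitness.items() if f < low or f > high}


def filter_driver_candidates(
        downstep_genes: Mapping[str, Mapping[str, Sequence[str]]],
        evidence: Mapping[str, Mapping[str, set[str]]],
        ) -> list[DriverCandidate]:
    """Filter Downstep genes against per-condition evidence lists.

    ``downstep_genes[condition][downstep_id]`` is the gene list of one
    Downstep region; ``evidence[condition][kind]`` is a gene set for one of
    :data:`EVIDENCE_KINDS`.  A gene becomes a candidate iff it appears on
    at least one evidence list for its condition (evidence union, not
    intersection).  Missing evidence lists are skipped with a warning.
    """
    out: list[DriverCandidate] = []
    for cond in sorted(downstep_genes):
        cond_evidence = evidence.get(cond, {})
        for kind in EVIDENCE_KINDS:
            if kind not in cond_evidence:
                logger.warning("condition %s: evidence list %r missing; "
                               "flag skipped", cond, kind)
        for ds_id in sorted(downstep_genes[cond]):
            for gene in downstep_genes[cond][ds_id]:
                kinds = tuple(k for k in EVIDENCE_KINDS
                              if gene in cond_evidence.get(k, set()))
                if kinds:
                    out.append(DriverCandidate(gene=gene, condition=cond,
                                               downstep=ds_id,
                                               evidence=kinds))
    return out


def driver_coverage(downstep_ids: Sequence[str],
                    candidates: Sequence[DriverCandidate]) -> float:
    """Fraction of Downsteps with at least one candidate driver gene."""
    if not downstep_ids:
        raise ValueError("no Downsteps")
    covered = {c.downstep for c in candidates}
    return sum(d in covered for d in downstep_ids) / len(downstep_ids)


# ---------------------------------------------------------------------------
# Amplicon prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconPrediction:
    """Predicted fitness of an evolved telomeric amplicon in one condition."""

    chromosome: str
    interval: tuple[float, float]
    condition: str
    predicted_fitness: float
    n_downsteps: int


def predict_amplicon(chromosome: str, interval: tuple[float, float],
                     genome: GenomeModel,
                     segments: Mapping[str, Sequence[FitnessSegment]],
                     breakpoints: Mapping[str, Sequence[Breakpoint]],
                     ) -> list[AmpliconPrediction]:
    """Predict an evolved amplicon's fitness from the Tamp landscape.

    The amplicon must touch a chromosome end (it is Tamp-like); its
    predicted fitness per condition is the landscape value at its
    centromere-proximal boundary — the mean of the covering segment — and
    the number of driver genes along it is estimated as the number of
    Downsteps whose region lies within the amplicon.
    """
    lo, hi = interval
    length = genome.length_of(chromosome)
    touches_start = lo <= 0
    touches_end = hi >= length
    if not (touches_start ^ touches_end):
        raise ValueError("amplicon must touch exactly one chromosome end")
    init = hi if touches_start else lo  # centromere-proximal boundary
    out = []
    for cond in sorted(segments):
        segs = [s for s in segments[cond] if s.chromosome == chromosome]
        if not segs:
            raise ValueError(f"no segments on {chromosome} for {cond}")
        fitness = _covering_mean(segs, init)
        n_down = sum(
            1 for b in breakpoints.get(cond, [])
            if b.chromosome == chromosome and b.klass == "Downstep"
            and lo <= b.region[0] and b.region[1] <= hi)
        out.append(AmpliconPrediction(chromosome, (lo, hi), cond,
                                      float(fitness), n_down))
    return out


def group_means(values: Mapping[str, float],
                groups: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Mean of a per-entity value over named groups of entities.

    Used e.g. to average Tamp fitness over the Tamps containing a given
    driver gene, or aneuploid-event population frequencies over events.
    Entities missing from ``values`` raise, so silent partial means cannot
    occur.
    """
    out = {}
    for name, members in groups.items():
        missing = [m for m in members if m not in values]
        if missing:
            raise KeyError(f"group {name!r}: no value for {missing}")
        if not members:
            raise ValueError(f"group {name!r} is empty")
        out[name] = float(np.mean([values[m] for m in members]))
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def pleiotropy_variance(fitness_by_condition: Sequence[float]) -> float:
    """Between-condition sample variance of one entity's fitness (ddof=1)."""
    v = np.asarray(fitness_by_condition, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 conditions")
    return float(np.var(v, ddof=1))


def rank_sum_exact(a: Sequence[float], b: Sequence[float],
                   exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value, exact for small samples.

    With combined n <= ``exact_max_n`` every assignment of the (mid)ranks
    to the two groups is enumerated and the p-value is the fraction of
    assignments whose rank sum deviates from its mean at least as much as
    the observed one.  Larger samples use the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    na, nb = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_obs = float(ranks[:na].sum())
    n = na + nb
    if n <= exact_max_n:
        total = 0
        extreme = 0
        mu = na * (n + 1) / 2.0
        for combo in itertools.combinations(range(n), na):
            w = float(ranks[list(combo)].sum())
            total += 1
            if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                extreme += 1
        return extreme / total
    # normal approximation with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    mu = na * (n + 1) / 2.0
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return float(2.0 * stats.norm.sf(z))


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table, by hypergeometric
    summation of all tables at most as probable as the observed one."""
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)


def holm_bonferroni(pvalues: Sequence[float],
                    m: int | None = None) -> list[float]:
    """Holm step-down adjustment: sort ascending, multiply by (m - rank + 1),
    enforce monotonicity, cap at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValueError("m must be >= the number of p-values")
    order = np.argsort(p, kind="stable")
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(p[idx] * (m - rank), 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj.tolist()


def fisher_exact_with_holm(tables: Sequence[Sequence[Sequence[int]]],
                           m: int | None = None,
                           ) -> tuple[list[float], list[float]]:
    """Raw and Holm–Bonferroni-adjusted Fisher p-values for 2x2 tables."""
    raw = [fisher_exact(t) for t in tables]
    return raw, holm_bonferroni(raw, m=m)
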