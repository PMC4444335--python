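"""Genome-ordered fitness profiles, circular binary segmentation, and
Upstep/Downstep breakpoint classification.

The fitness landscape of telomeric amplicons is piecewise constant along
each chromosome: runs of adjacent Tamps share a fitness plateau, and the
boundaries between plateaus ("fitness breakpoints") mark genes whose gain
or loss from the amplicon changes fitness.  Plateaus are found by circular
binary segmentation (CBS): recursively, the arc of the ordered profile
maximizing the standardized difference in means between the arc and its
complement is tested against a within-segment permutation null; a
significant arc splits the segment, and recursion continues until no split
is accepted.

A breakpoint whose flanking points lie on the same chromosome arm is
classified by the sign of the fitness change *in the telomere direction of
that arm*: an increase toward the telomere is an Upstep (the gene lost from
the amplicon was deleterious when amplified — an anti-driver), a decrease
is a Downstep (the gene lost was a fitness driver).  Boundaries spanning
the centromere are left unclassified, since telomere direction is undefined
across it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genome import GeneRecord, GenomeModel, arm_of

__all__ = [
    "FitnessSegment",
    "Breakpoint",
    "build_profile",
    "cbs_segment",
    "segment_profile",
    "classify_breakpoints",
    "breakpoint_region_genes",
]

MERGE_TOL = 1e-12  # adjacent segments closer than this in mean are merged


@dataclass(frozen=True)
class FitnessSegment:
    """A fitness plateau: a run of adjacent profile points with one mean."""

    chromosome: str
    start_index: int          # first profile point (within-chromosome index)
    end_index: int            # one past the last point
    start_position: float     # init position of the first Tamp in the run
    end_position: float       # init position of the last Tamp in the run
    mean_fitness: float
    n_points: int


@dataclass(frozen=True)
class Breakpoint:
    """Boundary between two adjacent fitness plateaus."""

    chromosome: str
    arm: str                           # "L", "R", or "" when unclassified
    boundary_start: float              # init position of the last point of
    boundary_end: float                # the centromere-ward... see region
    delta: float                       # telomere-side mean - centromere-side
    klass: Literal["Upstep", "Downstep", "cross_centromere"]
    left_mean: float
    right_mean: float

    @property
    def region(self) -> tuple[float, float]:
        """Genomic interval between the flanking Tamps' init positions."""
        return (self.boundary_start, self.boundary_end)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def build_profile(tamp_fitness: pd.DataFrame, genome: GenomeModel,
                  condition: str | None = None,
                  init_at: str = "start") -> pd.DataFrame:
    """Order kept Tamp fitnesses along the genome.

    ``tamp_fitness`` needs columns ``tamp, fitness`` and optionally ``se``,
    ``condition`` and ``status`` (rows not marked ``kept`` are dropped).
    Tamp ids must resolve to genes of the genome; unresolvable ids raise
    with the full list of offenders.  Output columns:
    ``chromosome, position, tamp, fitness, se`` sorted by
    (chromosome, position).
    """
    table = tamp_fitness
    if condition is not None and "condition" in table.columns:
        table = table[table["condition"] == condition]
    if "status" in table.columns:
        table = table[table["status"] == "kept"]
    table = table.dropna(subset=["fitness"])
    missing = [t for t in table["tamp"] if t not in genome._by_id]
    if missing:
        raise ValueError(f"Tamp ids not in genome: {sorted(set(missing))}")
    rows = []
    for row in table.itertuples():
        tamp = genome.tamp_for_gene(row.tamp, init_at=init_at)
        rows.append((tamp.chromosome, float(tamp.init_position), row.tamp,
                     float(row.fitness),
                     float(getattr(row, "se", np.nan))))
    profile = pd.DataFrame(rows, columns=["chromosome", "position", "tamp",
                                          "fitness", "se"])
    return (profile.sort_values(["chromosome", "position", "tamp"])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

def _arc_mask(n: int, min_width: int) -> np.ndarray:
    """Validity mask over arcs (i, j), 0 <= i < j <= n.

    An accepted arc cuts the segment at i and j, leaving linear pieces
    [0,i), [i,j), [j,n); every nonempty piece must have >= min_width points,
    and (i, j) = (0, n) is no split at all.
    """
    idx = np.arange(n + 1)
    i = idx[:, None]
    j = idx[None, :]
    m = j - i
    ok = (m >= min_width) & (m <= n - min_width)
    ok &= (i == 0) | (i >= min_width)
    ok &= (j == n) | (n - j >= min_width)
    ok &= ~((i == 0) & (j == n))
    return ok


def _arc_tsq(batch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Squared two-sample t statistic for every arc, for a batch of rows.

    ``batch`` has shape (B, n); the result has shape (B, n+1, n+1) with
    invalid arcs set to -inf.  The statistic compares the arc [i, j) to its
    complement with pooled variance.
    """
    b, n = batch.shape
    S = np.zeros((b, n + 1))
    Q = np.zeros((b, n + 1))
    np.cumsum(batch, axis=1, out=S[:, 1:])
    np.cumsum(batch ** 2, axis=1, out=Q[:, 1:])
    total = S[:, -1][:, None, None]
    qtotal = Q[:, -1][:, None, None]
    sum_in = S[:, None, :] - S[:, :, None]
    q_in = Q[:, None, :] - Q[:, :, None]
    idx = np.arange(n + 1, dtype=float)
    m = idx[None, None, :] - idx[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        mo = n - m
        sum_out = total - sum_in
        mean_in = sum_in / m
        mean_out = sum_out / mo
        ss_in = q_in - sum_in ** 2 / m
        ss_out = (qtotal - q_in) - sum_out ** 2 / mo
        sp2 = (ss_in + ss_out) / max(n - 2, 1)
        denom = sp2 * (1.0 / m + 1.0 / mo)
        diff2 = (mean_in - mean_out) ** 2
        tsq = diff2 / denom
        # zero pooled variance: infinite statistic if the means differ,
        # zero otherwise
        tsq = np.where(denom <= 0, np.where(diff2 > 0, np.inf, 0.0), tsq)
    tsq = np.where(mask[None, :, :], tsq, -np.inf)
    return tsq


def _best_arc(x: np.ndarray, mask: np.ndarray) -> tuple[int, int, float]:
    """The arc maximizing the statistic; ties go to the smallest start
    index, then the smallest arc (row-major argmax order)."""
    tsq = _arc_tsq(x[None, :], mask)[0]
    flat = int(np.argmax(tsq))
    n1 = x.size + 1
    i, j = divmod(flat, n1)
    return i, j, float(tsq[i, j])


def _permutation_pvalue(x: np.ndarray, mask: np.ndarray, observed: float,
                        n_permutations: int, alpha: float,
                        rng: np.random.Generator) -> float:
    """Permutation p-value of the best-arc statistic, with early stopping
    once the split can no longer reach significance."""
    n = x.size
    count = 0
    done = 0
    # keep batch memory around a few hundred MB even for long profiles
    batch_size = max(1, int(4_000_000 / (n + 1) ** 2))
    stop_count = alpha * (n_permutations + 1)
    while done < n_permutations:
        b = min(batch_size, n_permutations - done)
        perms = np.empty((b, n))
        for k in range(b):
            perms[k] = rng.permutation(x)
        tsq = _arc_tsq(perms, mask)
        maxima = tsq.reshape(b, -1).max(axis=1)
        count += int(np.sum(maxima >= observed - 1e-12))
        done += b
        if count + 1 > stop_count:
            return 1.0  # cannot reach significance; reject the split
    return (count + 1) / (n_permutations + 1)


def cbs_segment(values: Sequence[float], alpha: float = 0.05,
                min_width: int = 2, n_permutations: int = 10_000,
                rng: np.random.Generator | int = 0,
                ) -> list[tuple[int, int, float]]:
    """Segment one ordered profile by circular binary segmentation.

    Returns ``(start, end, mean)`` index ranges partitioning the profile.
    At each stage the arc maximizing the pooled two-sample t statistic
    between arc and complement is tested by permuting the values within the
    current segment (``n_permutations`` shuffles, seeded); the split is
    accepted when p < ``alpha`` and every resulting piece has at least
    ``min_width`` points.  Adjacent segments whose means coincide to
    machine tolerance are merged afterwards.
    """
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points to segment")
    if np.any(np.isnan(x)):
        raise ValueError("profile contains missing fitness values")
    rng = np.random.default_rng(rng)

    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = seg.size
        if n < 2 * min_width or np.ptp(seg) == 0:
            return
        mask = _arc_mask(n, min_width)
        if not mask.any():
            return
        i, j, stat = _best_arc(seg, mask)
        if not np.isfinite(stat) and stat < 0:
            return
        p = _permutation_pvalue(seg, mask, stat, n_permutations, alpha, rng)
        if p >= alpha:
            return
        cuts = sorted({c for c in (i, j) if 0 < c < n})
        if not cuts:
            return
        for c in cuts:
            boundaries.append(lo + c)
        pieces = [lo] + [lo + c for c in cuts] + [hi]
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, x.size)
    cuts = sorted(set(boundaries))
    edges = [0] + cuts + [x.size]
    segments = [(a, b, float(x[a:b].mean()))
                for a, b in zip(edges[:-1], edges[1:])]
    # prune: merge neighbours indistinguishable in mean
    merged: list[tuple[int, int, float]] = []
    for seg in segments:
        if merged and abs(merged[-1][2] - seg[2]) < MERGE_TOL:
            a, _, _ = merged[-1]
            merged[-1] = (a, seg[1], float(x[a:seg[1]].mean()))
        else:
            merged.append(seg)
    return merged


def segment_profile(profile: pd.DataFrame, alpha: float = 0.05,
                    min_width: int = 2, n_permutations: int = 10_000,
                    rng: np.random.Generator | int = 0,
                    ) -> list[FitnessSegment]:
    """Run CBS per chromosome of a fitness profile.

    Chromosomes with a single point become a single one-point segment
    (they cannot host a breakpoint).
    """
    rng = np.random.default_rng(rng)
    segments: list[FitnessSegment] = []
    for chrom, sub in profile.groupby("chromosome", sort=True):
        sub = sub.sort_values("position").reset_index(drop=True)
        vals = sub["fitness"].to_numpy()
        pos = sub["position"].to_numpy()
        if len(sub) < 2:
            parts = [(0, len(sub), float(vals.mean()))]
        else:
            parts = cbs_segment(vals, alpha=alpha, min_width=min_width,
                                n_permutations=n_permutations, rng=rng)
        for a, b, mean in parts:
            segments.append(FitnessSegment(
                chromosome=str(chrom), start_index=a, end_index=b,
                start_position=float(pos[a]), end_position=float(pos[b - 1]),
                mean_fitness=mean, n_points=b - a))
    return segments


# ---------------------------------------------------------------------------
# Breakpoints
# ---------------------------------------------------------------------------

def classify_breakpoints(segments: Sequence[FitnessSegment],
                         genome: GenomeModel) -> list[Breakpoint]:
    """Classify every boundary between adjacent plateaus as Upstep/Downstep.

    The fitness change is evaluated in the telomere direction of the arm:
    on the right arm the telomere side is the higher-coordinate segment, on
    the left arm the lower-coordinate one.  ``delta`` is telomere-side mean
    minus centromere-side mean; positive delta is an Upstep, negative a
    Downstep.  Boundaries whose flanking points straddle the centromere are
    returned as ``cross_centromere`` with no arm.
    """
    out: list[Breakpoint] = []
    by_chrom: dict[str, list[FitnessSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom, segs in sorted(by_chrom.items()):
        segs = sorted(segs, key=lambda s: s.start_index)
        for left, right in zip(segs[:-1], segs[1:]):
            if right.start_index != left.end_index:
                raise ValueError(
                    f"segments do not partition chromosome {chrom}")
            lo = left.end_position      # last Tamp of the left plateau
            hi = right.start_position   # first Tamp of the right plateau
            arm_lo = arm_of(int(lo), chrom, genome)
            arm_hi = arm_of(int(hi), chrom, genome)
            if arm_lo != arm_hi:
                out.append(Breakpoint(chrom, "", lo, hi, np.nan,
                                      "cross_centromere",
                                      left.mean_fitness, right.mean_fitness))
                continue
            if arm_lo == "R":
                delta = right.mean_fitness - left.mean_fitness
            else:
                delta = left.mean_fitness - right.mean_fitness
            klass = "Upstep" if delta > 0 else "Downstep"
            out.append(Breakpoint(chrom, arm_lo, lo, hi, float(delta), klass,
                                  left.mean_fitness, right.mean_fitness))
    return out


def breakpoint_region_genes(breakpoint: Breakpoint, genome: GenomeModel,
                            extra_centromeric: int = 1) -> list[GeneRecord]:
    """Genes in a breakpoint region, plus extra genes on the centromere side.

    The region is the interval between the flanking Tamps' initiation
    points (any overlap counts).  ``extra_centromeric`` additional genes
    are taken just centromere-ward of the region's centromeric border, to
    compensate for segmentation insensitivity near the boundary.
    """
    if breakpoint.klass == "cross_centromere":
        raise ValueError("cannot collect genes for an unclassified "
                         "cross-centromere boundary")
    lo, hi = breakpoint.region
    chrom = breakpoint.chromosome
    # closed interval: both flanking initiation points belong to the region,
    # so the gene at which the telomere-side Tamp initiates is included
    genes = [g for g in genome.genes_on(chrom)
             if g.start <= hi and g.end > lo]
    have = {g.id for g in genes}
    all_genes = genome.genes_on(chrom)
    if breakpoint.arm == "R":
        # centromere side = lower coordinates
        centromeric = [g for g in all_genes
                       if g.end <= lo and g.id not in have]
        extra = sorted(centromeric, key=lambda g: g.end,
                       reverse=True)[:extra_centromeric]
    else:
        centromeric = [g for g in all_genes
                       if g.start >= hi and g.id not in have]
        extra = sorted(centromeric, key=lambda g: g.start)[:extra_centromeric]
    return sorted(genes + extra, key=lambda g: g.start)


def segments_to_frame(segments: Sequence[FitnessSegment]) -> pd.DataFrame:
    """Segments as a BED-like table (1-based inclusive positions)."""
    return pd.DataFrame(
        [(s.chromosome, int(s.start_position) + 1, int(s.end_position) + 1,
          s.mean_fitness, s.n_points) for s in segments],
        columns=["chrom", "start", "end", "mean_fitness", "n_points"])


def breakpoints_to_frame(breakpoints: Sequence[Breakpoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chromosome, int(b.boundary_start) + 1, int(b.boundary_end) + 1,
          b.klass, b.delta) for b in breakpoints],
        columns=["chrom", "boundary_start", "boundary_end", "class", "delta"])
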