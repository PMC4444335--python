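"""Barcode-sequencing I/O: demultiplexing, counting, and trajectory tables.

Reads from a pooled competition carry up to three barcodes:

* a short multiplex barcode (default 6 bp) identifying the sequencing sample
  (condition x technical replicate x timepoint);
* a strain-identifying barcode ("Tamp BC") naming the gene at which the
  amplicon initiates;
* a random replicate barcode (default 12 bp) unique to each independent
  transformant, i.e. each biological replicate of a Tamp.

Counts are stored in a long-format :class:`CountMatrix`; per-replicate
frequency trajectories are expressed as log2 ratios relative to the first
timepoint with a +1 pseudocount on every read count, the convention of the
raw-trajectory CSV schema (columns ``gene, mer, replicate, t1..t9, g1..g9``).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeScheme",
    "CountMatrix",
    "demultiplex",
    "count_barcodes",
    "to_trajectories",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_fastq_sequences",
]

SAMPLE_COLUMNS = ["sample", "condition", "technical_replicate",
                  "timepoint", "generations", "total_reads"]
COUNT_COLUMNS = ["tamp", "replicate_bc", "sample", "count"]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class BarcodeScheme:
    """Positions and lengths of the three barcodes within a read.

    ``*_offset`` is the 0-based position of the barcode in the read; the
    default layout concatenates multiplex, Tamp, and replicate barcodes with
    no spacers.  ``*_mismatches`` is the allowed Hamming radius for matching
    (default 0 everywhere).
    """

    multiplex_len: int = 6
    tamp_len: int = 20
    replicate_len: int = 12
    multiplex_offset: int = 0
    tamp_offset: int | None = None
    replicate_offset: int | None = None
    multiplex_mismatches: int = 0
    tamp_mismatches: int = 0
    replicate_mismatches: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tamp_offset",
                           self.tamp_offset if self.tamp_offset is not None
                           else self.multiplex_offset + self.multiplex_len)
        object.__setattr__(self, "replicate_offset",
                           self.replicate_offset if self.replicate_offset is not None
                           else self.tamp_offset + self.tamp_len)
        spans = sorted([
            (self.multiplex_offset, self.multiplex_offset + self.multiplex_len),
            (self.tamp_offset, self.tamp_offset + self.tamp_len),
            (self.replicate_offset, self.replicate_offset + self.replicate_len),
        ])
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("barcode fields overlap within the read layout")

    @property
    def read_length(self) -> int:
        return max(self.multiplex_offset + self.multiplex_len,
                   self.tamp_offset + self.tamp_len,
                   self.replicate_offset + self.replicate_len)

    def multiplex_bc(self, read: str) -> str:
        return read[self.multiplex_offset:self.multiplex_offset + self.multiplex_len]

    def tamp_bc(self, read: str) -> str:
        return read[self.tamp_offset:self.tamp_offset + self.tamp_len]

    def replicate_bc(self, read: str) -> str:
        return read[self.replicate_offset:self.replicate_offset + self.replicate_len]


class CountMatrix:
    """Read counts keyed by (Tamp, replicate barcode, sample).

    Attributes
    ----------
    counts
        Long-format frame with columns ``tamp, replicate_bc, sample, count``.
    samples
        Per-sample metadata with columns ``sample, condition,
        technical_replicate, timepoint, generations, total_reads``.
        ``total_reads`` is the total number of input reads for the sample
        (assigned + unassigned), so conservation can be checked.
    unassigned
        Reads per sample that matched no known barcode.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame,
                 unassigned: Mapping[str, int] | None = None) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
        if missing:
            raise ValueError(f"counts missing columns {missing}")
        missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing:
            raise ValueError(f"samples missing columns {missing}")
        if (counts["count"] < 0).any():
            raise ValueError("negative read count")
        self.counts = counts.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        self.unassigned = dict(unassigned or {})

    def sample_total(self, sample: str) -> int:
        """Total assigned reads in a sample."""
        return int(self.counts.loc[self.counts["sample"] == sample, "count"].sum())

    def to_csv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, index=False)
        self.samples.to_csv(samples_path, index=False)

    @classmethod
    def from_csv(cls, counts_path: str | Path,
                 samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path)
        samples = pd.read_csv(samples_path)
        return cls(counts, samples)


# ---------------------------------------------------------------------------
# FASTQ and demultiplexing
# ---------------------------------------------------------------------------

def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (plain or gzipped)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield str(record.seq)


def _check_barcode_table(barcodes: Iterable[str], radius: int, what: str) -> None:
    bcs = list(barcodes)
    if len(set(bcs)) != len(bcs):
        raise ValueError(f"duplicate {what} barcodes")
    if radius > 0:
        for i, a in enumerate(bcs):
            for b in bcs[i + 1:]:
                if hamming(a, b) <= 2 * radius:
                    raise ValueError(
                        f"ambiguous {what} barcode table: {a!r} and {b!r} "
                        f"are within mismatch radius {radius}")


def _match(bc: str, table: Mapping[str, str], radius: int) -> str | None:
    if bc in table:
        return table[bc]
    if radius > 0:
        for cand, label in table.items():
            if len(cand) == len(bc) and hamming(cand, bc) <= radius:
                return label
    return None


def demultiplex(reads: Iterable[str], scheme: BarcodeScheme,
                multiplex_table: Mapping[str, str],
                ) -> tuple[dict[str, list[str]], int]:
    """Group reads by sample via the multiplex barcode.

    ``multiplex_table`` maps barcode -> sample id.  Returns the per-sample
    read lists and the number of unassigned reads.  Every input read goes to
    exactly one sample or to the unassigned tally.
    """
    _check_barcode_table(multiplex_table.keys(), scheme.multiplex_mismatches,
                         "multiplex")
    by_sample: dict[str, list[str]] = {s: [] for s in multiplex_table.values()}
    unassigned = 0
    for read in reads:
        sample = _match(scheme.multiplex_bc(read), multiplex_table,
                        scheme.multiplex_mismatches)
        if sample is None:
            unassigned += 1
        else:
            by_sample[sample].append(read)
    return by_sample, unassigned


def count_barcodes(sample_reads: Iterable[str], scheme: BarcodeScheme,
                   tamp_table: Mapping[str, str],
                   min_reads: int = 0,
                   ) -> tuple[pd.DataFrame, int]:
    """Count reads per (Tamp, replicate barcode) within one sample.

    ``tamp_table`` maps Tamp barcode -> initiating-gene id.  Replicate
    barcodes seen fewer than ``min_reads`` times in total are dropped.
    Returns the count frame (columns ``tamp, replicate_bc, count``) and the
    number of reads with an unknown Tamp barcode.
    """
    _check_barcode_table(tamp_table.keys(), scheme.tamp_mismatches, "Tamp")
    tallies: dict[tuple[str, str], int] = {}
    unknown = 0
    for read in sample_reads:
        gene = _match(scheme.tamp_bc(read), tamp_table, scheme.tamp_mismatches)
        if gene is None:
            unknown += 1
            continue
        key = (gene, scheme.replicate_bc(read))
        tallies[key] = tallies.get(key, 0) + 1
    rows = [(t, r, c) for (t, r), c in sorted(tallies.items())
            if c >= min_reads]
    frame = pd.DataFrame(rows, columns=["tamp", "replicate_bc", "count"])
    return frame, unknown


def count_fastq(path: str | Path, scheme: BarcodeScheme,
                multiplex_table: Mapping[str, str],
                tamp_table: Mapping[str, str],
                sample_metadata: pd.DataFrame,
                min_reads: int = 0) -> CountMatrix:
    """Demultiplex and count a whole FASTQ file into a :class:`CountMatrix`.

    ``sample_metadata`` must carry one row per sample with the
    :data:`SAMPLE_COLUMNS` minus ``total_reads`` (which is filled in here).
    """
    by_sample, unassigned_total = demultiplex(
        read_fastq_sequences(path), scheme, multiplex_table)
    frames = []
    totals: dict[str, int] = {}
    unknown: dict[str, int] = {}
    for sample, reads in by_sample.items():
        frame, unk = count_barcodes(reads, scheme, tamp_table, min_reads)
        frame = frame.assign(sample=sample)
        frames.append(frame[COUNT_COLUMNS])
        totals[sample] = len(reads)
        unknown[sample] = unk
    counts = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=COUNT_COLUMNS))
    samples = sample_metadata.copy()
    samples["total_reads"] = samples["sample"].map(totals).fillna(0).astype(int)
    cm = CountMatrix(counts, samples, unassigned={"__demux__": unassigned_total})
    cm.unknown_tamp = unknown  # type: ignore[attr-defined]
    return cm


def pool_complexity(counts: CountMatrix, targeted: Iterable[str],
                    floor: float = 0.005e-2) -> float:
    """Fraction of targeted Tamps above a total read-fraction floor.

    A Tamp is "represented" when its reads across all samples exceed
    ``floor`` (default 0.005%) of all assigned reads; the returned value is
    the represented fraction of the targeted set.
    """
    targeted = list(targeted)
    if not targeted:
        raise ValueError("empty targeted set")
    per_tamp = counts.counts.groupby("tamp")["count"].sum()
    total = float(per_tamp.sum())
    if total <= 0:
        return 0.0
    represented = {t for t, c in per_tamp.items() if c / total > floor}
    return sum(t in represented for t in targeted) / len(targeted)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def to_trajectories(counts: CountMatrix, pseudocount: float = 1.0,
                    ) -> pd.DataFrame:
    """Convert counts to per-replicate log2 frequency-ratio trajectories.

    For each (Tamp, replicate barcode, condition, technical replicate) the
    value at timepoint ``t`` is::

        log2( ((c_t + 1) / N_t) / ((c_0 + 1) / N_0) )

    where ``N`` is the total *assigned* reads in the sample and the
    pseudocount (default 1) is applied to counts, never to frequencies.
    Output columns: ``gene, mer, replicate, t1..tK, g1..gK`` where K is the
    number of post-baseline timepoints.  A trajectory whose baseline (t0)
    sample is missing is emitted with all-missing values and logged.
    """
    samples = counts.samples.sort_values(["condition", "technical_replicate",
                                          "timepoint"])
    merged = counts.counts.merge(samples, on="sample", how="left")
    assigned = counts.counts.groupby("sample")["count"].sum().to_dict()

    timepoints = sorted(samples["timepoint"].unique())
    if not timepoints:
        raise ValueError("count matrix has no samples")
    t0 = timepoints[0]
    k = len(timepoints) - 1

    rows = []
    group_cols = ["condition", "technical_replicate"]
    for (cond, tech), sub in merged.groupby(group_cols, sort=True):
        meta = samples[(samples["condition"] == cond)
                       & (samples["technical_replicate"] == tech)]
        gens = dict(zip(meta["timepoint"], meta["generations"]))
        sample_of = dict(zip(meta["timepoint"], meta["sample"]))
        totals = {tp: assigned.get(s, 0) for tp, s in sample_of.items()}
        pivot = sub.pivot_table(index=["tamp", "replicate_bc"],
                                columns="timepoint", values="count",
                                aggfunc="sum", fill_value=0)
        has_t0 = t0 in pivot.columns and totals.get(t0, 0) > 0
        if not has_t0:
            logger.warning("no baseline (t0) sample for condition=%s "
                           "technical_replicate=%s; trajectories set to NA",
                           cond, tech)
        for (tamp, rep), row in pivot.iterrows():
            out = {"gene": tamp, "mer": rep, "replicate": tech,
                   "condition": cond}
            for i, tp in enumerate(timepoints[1:], start=1):
                g = gens.get(tp, np.nan)
                out[f"g{i}"] = g
                if (not has_t0 or tp not in sample_of
                        or totals.get(tp, 0) <= 0):
                    out[f"t{i}"] = np.nan
                    continue
                c0 = row.get(t0, 0)
                ct = row.get(tp, 0)
                f0 = (c0 + pseudocount) / totals[t0]
                ft = (ct + pseudocount) / totals[tp]
                out[f"t{i}"] = np.log2(ft / f0)
            rows.append(out)
    cols = (["gene", "mer", "replicate", "condition"]
            + [f"t{i}" for i in range(1, k + 1)]
            + [f"g{i}" for i in range(1, k + 1)])
    return pd.DataFrame(rows, columns=cols)


def _trajectory_columns(header: list[str]) -> tuple[list[str], list[str]]:
    t_cols = sorted((c for c in header if re.fullmatch(r"t\d+", c)),
                    key=lambda c: int(c[1:]))
    g_cols = sorted((c for c in header if re.fullmatch(r"g\d+", c)),
                    key=lambda c: int(c[1:]))
    if [int(c[1:]) for c in t_cols] != list(range(1, len(t_cols) + 1)):
        raise ValueError(f"non-contiguous t columns: {t_cols}")
    if [c[1:] for c in g_cols] != [c[1:] for c in t_cols]:
        raise ValueError("t and g columns do not pair up")
    return t_cols, g_cols


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw-trajectory CSV (``gene, mer, replicate, t1..tK, g1..gK``).

    ``NA`` cells are parsed as missing.  A malformed header or a non-numeric
    cell raises with its row/column position.
    """
    table = pd.read_csv(path, na_values=["NA"], dtype=str,
                        keep_default_na=True)
    for col in ("gene", "mer", "replicate"):
        if col not in table.columns:
            raise ValueError(f"malformed header: missing column {col!r}")
    t_cols, g_cols = _trajectory_columns(list(table.columns))
    if not t_cols:
        raise ValueError("malformed header: no t1..tK columns")
    for col in t_cols + g_cols:
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError):
            bad = table[pd.to_numeric(table[col], errors="coerce").isna()
                        & table[col].notna()]
            row = int(bad.index[0]) + 2  # 1-based, plus header line
            raise ValueError(
                f"non-numeric cell in column {col!r} at file row {row}")
    for _, row in table.iterrows():
        gens = row[g_cols].dropna().to_numpy(dtype=float)
        if len(gens) > 1 and not np.all(np.diff(gens) > 0):
            raise ValueError(
                f"generations not strictly increasing for gene={row['gene']} "
                f"mer={row['mer']} replicate={row['replicate']}")
    return table


def write_trajectory_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory table, representing missing values as ``NA``."""
    t_cols, g_cols = _trajectory_columns(list(table.columns))
    lead = [c for c in ("gene", "mer", "replicate") if c in table.columns]
    extra = [c for c in table.columns
             if c not in lead and c not in t_cols and c not in g_cols]
    table[lead + extra + t_cols + g_cols].to_csv(path, index=False,
                                                 na_rep="NA")
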