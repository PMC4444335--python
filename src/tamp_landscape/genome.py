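"""Genome coordinate system, gene geometry, and chromosome-arm conventions.

All coordinates are 0-based, half-open internally.  File readers and writers
translate to 1-based, inclusive coordinates, following the convention of most
annotation tables.

A telomeric amplicon ("Tamp") is a segmental amplification that starts at a
genomic position (its *initiation point*, the centromere-proximal boundary)
and extends to the nearest chromosome end.  Every downstream stage of the
pipeline relies on the arm/telomere conventions defined here:

* a position is on the left (``L``) arm iff it lies below the centromere;
* "telomere direction" is ``+1`` on the right arm (coordinates increase
  toward the telomere) and ``-1`` on the left arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Arm = Literal["L", "R"]

__all__ = [
    "GeneRecord",
    "GenomeModel",
    "TampDef",
    "arm_of",
    "telomere_direction",
    "genes_in_interval",
    "random_genome",
    "read_genome_tables",
    "write_genome_tables",
]


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval on a chromosome, 0-based half-open."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.id}: start must be < end "
                             f"({self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class GenomeModel:
    """Chromosome lengths, centromere positions, and gene intervals.

    Parameters
    ----------
    chromosomes
        Ordered list of ``(name, length_bp)`` pairs.
    centromeres
        Map chromosome name -> centromere position (bp), strictly inside
        ``(0, length)``.
    genes
        Gene records; identifiers must be unique and every interval must lie
        within its chromosome.
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, int]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if name not in self.centromeres:
                raise ValueError(f"chromosome {name!r} has no centromere")
            cen = self.centromeres[name]
            if not 0 < cen < length:
                raise ValueError(
                    f"centromere of {name!r} at {cen} not strictly inside "
                    f"(0, {length})")
        extra = set(self.centromeres) - set(lengths)
        if extra:
            raise ValueError(f"centromeres for unknown chromosomes: {sorted(extra)}")
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            if g.chromosome not in lengths:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chromosome!r}")
            if g.start < 0 or g.end > lengths[g.chromosome]:
                raise ValueError(
                    f"gene {g.id}: interval [{g.start}, {g.end}) outside "
                    f"chromosome {g.chromosome} of length {lengths[g.chromosome]}")
        self._length = lengths
        self._by_id = {g.id: g for g in self.genes}
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for g in sorted(self.genes, key=lambda g: (g.chromosome, g.start, g.end)):
            self._by_chrom.setdefault(g.chromosome, []).append(g)

    # -- lookups -----------------------------------------------------------
    def length_of(self, chromosome: str) -> int:
        try:
            return self._length[chromosome]
        except KeyError:
            raise KeyError(f"unknown chromosome {chromosome!r}") from None

    def centromere_of(self, chromosome: str) -> int:
        self.length_of(chromosome)
        return self.centromeres[chromosome]

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def genes_on(self, chromosome: str) -> list[GeneRecord]:
        """Genes on one chromosome, sorted by start coordinate."""
        self.length_of(chromosome)
        return list(self._by_chrom.get(chromosome, []))

    # -- arm geometry ------------------------------------------------------
    def arm_of_gene(self, gene_id: str) -> Arm:
        """Arm containing the gene midpoint (deterministic for genes that
        span the centromere)."""
        g = self.gene(gene_id)
        cen = self.centromere_of(g.chromosome)
        return "L" if g.midpoint < cen else "R"

    def tamp_for_gene(self, gene_id: str,
                      init_at: Literal["start", "end"] = "start") -> "TampDef":
        """The telomeric amplicon initiating at a deleted gene.

        ``init_at`` selects whether the amplicon boundary sits at the gene's
        start or end coordinate; the amplicon runs from that boundary to the
        telomere on the gene's arm.
        """
        g = self.gene(gene_id)
        if init_at not in ("start", "end"):
            raise ValueError("init_at must be 'start' or 'end'")
        pos = g.start if init_at == "start" else g.end
        arm = self.arm_of_gene(gene_id)
        if arm == "R":
            interval = (pos, self.length_of(g.chromosome))
        else:
            interval = (0, pos)
        return TampDef(id=gene_id, chromosome=g.chromosome,
                       init_position=pos, arm=arm, amplicon_interval=interval)


@dataclass(frozen=True)
class TampDef:
    """A telomeric amplicon: initiation point, arm, and genomic extent."""

    id: str
    chromosome: str
    init_position: int
    arm: Arm
    amplicon_interval: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.amplicon_interval
        if lo > hi:
            raise ValueError("amplicon interval reversed")

    @property
    def size(self) -> int:
        lo, hi = self.amplicon_interval
        return hi - lo

    def contains(self, position: float) -> bool:
        lo, hi = self.amplicon_interval
        return lo <= position < hi


def arm_of(position: int, chromosome: str, genome: GenomeModel) -> Arm:
    """Arm of a chromosomal position: ``L`` iff below the centromere."""
    length = genome.length_of(chromosome)
    if not 0 <= position < length:
        raise ValueError(
            f"position {position} outside [0, {length}) on {chromosome!r}")
    return "L" if position < genome.centromere_of(chromosome) else "R"


def telomere_direction(arm: Arm) -> int:
    """+1 if coordinates increase toward the telomere (right arm), else -1."""
    if arm == "R":
        return 1
    if arm == "L":
        return -1
    raise ValueError(f"invalid arm {arm!r}")


def genes_in_interval(interval: tuple[int, int], chromosome: str,
                      genome: GenomeModel,
                      mode: Literal["any_overlap", "contained"] = "any_overlap",
                      ) -> list[GeneRecord]:
    """Genes intersecting a half-open genomic interval, sorted by start.

    ``any_overlap`` keeps genes with at least 1 bp of overlap; ``contained``
    keeps genes entirely inside the interval.  An empty interval returns an
    empty list.
    """
    lo, hi = interval
    if mode not in ("any_overlap", "contained"):
        raise ValueError(f"unknown mode {mode!r}")
    if hi <= lo:
        return []  # empty interval overlaps nothing
    out = []
    for g in genome.genes_on(chromosome):
        if mode == "any_overlap":
            keep = g.start < hi and g.end > lo
        else:
            keep = g.start >= lo and g.end <= hi
        if keep:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Programmatic toy genomes
# ---------------------------------------------------------------------------

def random_genome(n_chromosomes: int = 3,
                  chrom_length: int = 600_000,
                  n_genes_per_chrom: int = 60,
                  gene_length: int = 1_500,
                  seed: int | np.random.Generator = 0) -> GenomeModel:
    """Generate a toy genome with evenly spread, non-overlapping genes.

    Centromeres are placed at a random interior position away from the
    chromosome ends; genes are laid on a jittered grid so that intervals
    never overlap.  Intended for tests and simulations; nothing about it is
    organism-specific.
    """
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1:02d}", int(chrom_length))
                   for i in range(n_chromosomes)]
    centromeres = {}
    genes: list[GeneRecord] = []
    for name, length in chromosomes:
        centromeres[name] = int(rng.integers(int(0.25 * length),
                                             int(0.75 * length)))
        pitch = length // n_genes_per_chrom
        if gene_length >= pitch:
            raise ValueError("gene_length must be smaller than the gene pitch")
        for k in range(n_genes_per_chrom):
            offset = int(rng.integers(0, pitch - gene_length))
            start = k * pitch + offset
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(id=f"{name}_g{k + 1:03d}",
                                    chromosome=name, start=start,
                                    end=start + gene_length, strand=strand))
    return GenomeModel(chromosomes=chromosomes, centromeres=centromeres,
                       genes=genes)


# ---------------------------------------------------------------------------
# File I/O (1-based inclusive on disk)
# ---------------------------------------------------------------------------

def write_genome_tables(genome: GenomeModel, gene_path: str | Path,
                        centromere_path: str | Path) -> None:
    """Write gene and centromere tables as tab-delimited text.

    The gene table has columns ``chrom  start  end  strand  id`` with 1-based
    inclusive coordinates; the centromere table has columns
    ``chrom  length  centromere`` (centromere as a 1-based position).
    """
    genes = pd.DataFrame(
        [(g.chromosome, g.start + 1, g.end, g.strand, g.id)
         for g in genome.genes],
        columns=["chrom", "start", "end", "strand", "id"])
    genes.to_csv(gene_path, sep="\t", index=False)
    cen = pd.DataFrame(
        [(name, length, genome.centromeres[name] + 1)
         for name, length in genome.chromosomes],
        columns=["chrom", "length", "centromere"])
    cen.to_csv(centromere_path, sep="\t", index=False)


def read_genome_tables(gene_path: str | Path,
                       centromere_path: str | Path) -> GenomeModel:
    """Read the tables written by :func:`write_genome_tables`."""
    cen = pd.read_csv(centromere_path, sep="\t")
    for col in ("chrom", "length", "centromere"):
        if col not in cen.columns:
            raise ValueError(f"centromere table missing column {col!r}")
    chromosomes = [(str(r.chrom), int(r.length)) for r in cen.itertuples()]
    centromeres = {str(r.chrom): int(r.centromere) - 1 for r in cen.itertuples()}
    gt = pd.read_csv(gene_path, sep="\t")
    for col in ("chrom", "start", "end", "strand", "id"):
        if col not in gt.columns:
            raise ValueError(f"gene table missing column {col!r}")
    genes = [GeneRecord(id=str(r.id), chromosome=str(r.chrom),
                        start=int(r.start) - 1, end=int(r.end),
                        strand=str(r.strand))
             for r in gt.itertuples()]
    return GenomeModel(chromosomes=chromosomes, centromeres=centromeres,
                       genes=genes)
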