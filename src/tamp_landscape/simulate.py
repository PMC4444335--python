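"""Synthetic pooled chemostat competitions with planted fitness landscapes.

The generator emulates a genome-wide telomeric-amplicon (Tamp) screen:

* a piecewise-constant *fitness landscape* per condition — the true
  per-generation selection coefficient of the Tamp initiating at each
  genomic position, with plateaus separated by planted breakpoints, a
  configurable fraction of which are shared between conditions;
* a pool of barcoded biological replicates per Tamp (Poisson-distributed
  count, mean 26) with a strain-construction error model: a configurable
  fraction of replicates carry *aberrant* amplicons that do not extend to
  the telomere and therefore realize the landscape value at a truncated
  extent rather than at the intended initiation point;
* deterministic exponential selection dynamics within each chemostat,
  ``f_i(g) ∝ f_i(0) · 2**(s_i · g)``, renormalized at every sampled
  generation, with all stochasticity entering through multinomial read
  sampling at the configured depth (sequencing noise dominates at these
  depths; within-chemostat drift is not modeled);
* pairwise GFP competition trajectories, ``ln(dark/GFP)`` drifting linearly
  with slope ``s·ln 2``;
* aCGH-like mixture profiles, per-probe ``log2((f·c + (1−f)·c0)/ploidy)``
  plus Gaussian noise, for population-frequency estimation.

Everything is driven by a single ``numpy`` generator so identical seeds and
configs give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .barseq import COUNT_COLUMNS, SAMPLE_COLUMNS, BarcodeScheme, CountMatrix
from .genome import GenomeModel, TampDef, telomere_direction

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "plant_landscape",
    "landscape_value",
    "assign_replicates",
    "corrupt_replicates",
    "build_truth",
    "simulate_pool",
    "simulate_pairwise",
    "simulate_acgh",
    "random_barcodes",
    "emit_fastq",
]

REFERENCE_ID = "REF0"
DEFAULT_CONDITIONS = ("glucose", "phosphate", "sulfate")


@dataclass
class SimulationConfig:
    """Study-design parameters of a pooled competition.

    Defaults reproduce the genome-wide screen design: ~26 biological
    replicates per Tamp, 3 technical-replicate chemostats, ~25 generations
    sampled at 10 timepoints, a 50% aberrant-karyotype rate (use 0.2 for a
    targeted pool), and a neutral-background fitness jitter spanning
    [-0.05, 0.04] (the fitness range of the deletion strains the pool is
    built from).  The dilution rate (0.17 h^-1) is informational only; the
    dynamics are parameterized in generations.
    """

    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    mean_replicates: float = 26.0
    technical_replicates: int = 3
    total_generations: float = 25.0
    n_timepoints: int = 10
    read_depth: int = 1_000_000
    aberrant_prob: float = 0.5
    other_event_prob: float = 0.05
    other_event_scale: float = 0.1
    background_jitter: tuple[float, float] = (-0.05, 0.04)
    dilution_rate_per_hour: float = 0.17
    include_reference: bool = True
    reference_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("aberrant_prob", "other_event_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.n_timepoints < 2:
            raise ValueError("need at least two timepoints")
        if self.total_generations <= 0:
            raise ValueError("total_generations must be positive")

    @property
    def timepoint_generations(self) -> np.ndarray:
        """Sampled generations, strictly increasing from 0."""
        return np.linspace(0.0, self.total_generations, self.n_timepoints)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        d["background_jitter"] = list(d["background_jitter"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["conditions"] = tuple(d["conditions"])
        d["background_jitter"] = tuple(d["background_jitter"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------

Landscape = list[tuple[str, float, float, float]]  # (chrom, start, end, s)


def plant_landscape(genome: GenomeModel,
                    tamps: Sequence[TampDef],
                    n_breakpoints_per_chromosome: int,
                    effect_size: Callable[[np.random.Generator], float] | float = 0.1,
                    sharing_fraction: float = 0.0,
                    conditions: Sequence[str] = DEFAULT_CONDITIONS,
                    rng: np.random.Generator | int = 0,
                    ) -> dict[str, Landscape]:
    """Plant piecewise-constant fitness landscapes, one per condition.

    Breakpoints are placed midway between adjacent Tamp initiation points so
    that every Tamp falls unambiguously inside one plateau.
    ``sharing_fraction`` of the breakpoints (rounded down) sit at identical
    positions in all conditions; the rest are condition-private.  Plateau
    values are drawn independently per condition: either from
    ``effect_size(rng)`` if callable, or ``Normal(0, effect_size)``.

    Raises if a chromosome has fewer candidate positions than requested
    breakpoints.
    """
    rng = np.random.default_rng(rng)
    if not 0.0 <= sharing_fraction <= 1.0:
        raise ValueError("sharing_fraction must be in [0, 1]")
    if n_breakpoints_per_chromosome < 0:
        raise ValueError("n_breakpoints_per_chromosome must be >= 0")

    def draw(r: np.random.Generator) -> float:
        if callable(effect_size):
            return float(effect_size(r))
        return float(r.normal(0.0, effect_size))

    positions: dict[str, np.ndarray] = {}
    for name, _length in genome.chromosomes:
        pos = np.sort(np.unique([t.init_position for t in tamps
                                 if t.chromosome == name]))
        mids = (pos[:-1] + pos[1:]) / 2.0
        positions[name] = mids
        if n_breakpoints_per_chromosome > len(mids):
            raise ValueError(
                f"chromosome {name}: requested {n_breakpoints_per_chromosome} "
                f"breakpoints but only {len(mids)} candidate positions")

    n_shared = int(np.floor(sharing_fraction * n_breakpoints_per_chromosome))
    landscapes: dict[str, Landscape] = {c: [] for c in conditions}
    for name, length in genome.chromosomes:
        mids = positions[name]
        shared = np.sort(rng.choice(mids, size=n_shared, replace=False)) \
            if n_shared else np.array([])
        remaining = np.setdiff1d(mids, shared)
        for cond in conditions:
            n_private = n_breakpoints_per_chromosome - n_shared
            private = (np.sort(rng.choice(remaining, size=n_private,
                                          replace=False))
                       if n_private else np.array([]))
            cuts = np.sort(np.concatenate([shared, private]))
            bounds = np.concatenate([[0.0], cuts, [float(length)]])
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                landscapes[cond].append((name, float(lo), float(hi), draw(rng)))
    return landscapes


def landscape_value(landscape: Landscape, chromosome: str,
                    position: float) -> float:
    """Landscape value at a genomic position (plateaus are half-open)."""
    for chrom, lo, hi, s in landscape:
        if chrom == chromosome and lo <= position < hi:
            return s
    raise KeyError(f"position {position} on {chromosome!r} not covered by "
                   "the landscape")


def landscape_breakpoints(landscape: Landscape) -> dict[str, list[float]]:
    """Interior plateau boundaries per chromosome (the planted breakpoints)."""
    out: dict[str, list[float]] = {}
    by_chrom: dict[str, list[tuple[float, float]]] = {}
    for chrom, lo, hi, _s in landscape:
        by_chrom.setdefault(chrom, []).append((lo, hi))
    for chrom, spans in by_chrom.items():
        spans.sort()
        out[chrom] = [lo for lo, _hi in spans[1:]]
    return out


# ---------------------------------------------------------------------------
# Replicates and the strain-construction error model
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Ground truth of a simulated screen.

    ``replicates`` has one row per biological replicate with columns
    ``tamp, replicate_bc, chromosome, init_position, arm, eval_position,
    aberrant, other_offset, background``.  ``eval_position`` is where the
    landscape is evaluated: the initiation point for correct karyotypes, a
    telomere-ward truncation point for aberrant ones.  ``background`` is a
    per-Tamp neutral-background fitness shared by all replicates of a Tamp.
    The realized per-condition selection coefficient of a replicate is
    ``landscape(eval_position) + other_offset + background``, except for the
    neutral reference strain which is exactly 0.
    """

    genome: GenomeModel
    tamps: dict[str, TampDef]
    landscapes: dict[str, Landscape]
    replicates: pd.DataFrame
    conditions: tuple[str, ...]

    def landscape_fitness(self, condition: str) -> np.ndarray:
        """Landscape value at each replicate's eval position (no offsets)."""
        landscape = self.landscapes[condition]
        out = np.empty(len(self.replicates))
        for i, row in enumerate(self.replicates.itertuples()):
            if row.tamp == REFERENCE_ID:
                out[i] = 0.0
            else:
                out[i] = landscape_value(landscape, row.chromosome,
                                         row.eval_position)
        return out

    def realized_fitness(self, condition: str) -> np.ndarray:
        """Full selection coefficient per replicate under one condition."""
        base = self.landscape_fitness(condition)
        extra = (self.replicates["other_offset"].to_numpy()
                 + self.replicates["background"].to_numpy())
        extra = np.where(self.replicates["tamp"].to_numpy() == REFERENCE_ID,
                         0.0, extra)
        return base + extra

    def write_tables(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.replicates.to_csv(directory / "truth_replicates.tsv",
                               sep="\t", index=False)
        rows = [(cond, chrom, lo, hi, s)
                for cond, landscape in self.landscapes.items()
                for chrom, lo, hi, s in landscape]
        pd.DataFrame(rows, columns=["condition", "chrom", "start", "end",
                                    "fitness"]).to_csv(
            directory / "truth_landscape.tsv", sep="\t", index=False)


def random_barcodes(n: int, length: int,
                    rng: np.random.Generator) -> list[str]:
    """n unique random DNA k-mers."""
    if n > 4 ** length:
        raise ValueError("barcode space too small")
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(alphabet, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def assign_replicates(genome: GenomeModel, tamps: Sequence[TampDef],
                      config: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw biological replicates per Tamp (Poisson, mean 26 by default).

    Tamps drawing zero replicates are simply absent from the pool, as
    happens for under-represented strains in a real transformation.  The
    per-Tamp neutral-background fitness is drawn uniformly from the
    configured jitter range.
    """
    lo, hi = config.background_jitter
    rows = []
    for tamp in tamps:
        n = int(rng.poisson(config.mean_replicates))
        background = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        for bc in random_barcodes(n, 12, rng):
            rows.append((tamp.id, bc, tamp.chromosome,
                         float(tamp.init_position), tamp.arm,
                         float(tamp.init_position), False, 0.0, background))
    if config.include_reference:
        for bc in random_barcodes(config.reference_replicates, 12, rng):
            rows.append((REFERENCE_ID, bc, "", 0.0, "R", 0.0, False, 0.0, 0.0))
    return pd.DataFrame(rows, columns=[
        "tamp", "replicate_bc", "chromosome", "init_position", "arm",
        "eval_position", "aberrant", "other_offset", "background"])


def corrupt_replicates(truth: SimulationTruth, aberrant_prob: float,
                       rng: np.random.Generator | int,
                       other_event_prob: float = 0.0,
                       other_event_scale: float = 0.1) -> SimulationTruth:
    """Apply the strain-construction error model.

    Each non-reference replicate is independently flagged aberrant with
    probability ``aberrant_prob``.  An aberrant replicate's amplicon stops
    short of the telomere: its landscape-evaluation point moves to a gene
    boundary chosen uniformly among boundaries telomere-ward of the
    initiation gene (so larger Tamps have more ways to be truncated, and
    truncation is naturally more consequential for them).  With probability
    ``other_event_prob`` a replicate instead carries an unrelated large
    aneuploid event, modeled as an additive fitness offset drawn from
    ``Normal(0, other_event_scale)``.
    """
    rng = np.random.default_rng(rng)
    if not 0.0 <= aberrant_prob <= 1.0:
        raise ValueError("aberrant_prob must be in [0, 1]")
    reps = truth.replicates.copy()
    eval_pos = reps["eval_position"].to_numpy(dtype=float).copy()
    aberrant = reps["aberrant"].to_numpy(dtype=bool).copy()
    other = reps["other_offset"].to_numpy(dtype=float).copy()
    for i, row in enumerate(reps.itertuples()):
        if row.tamp == REFERENCE_ID:
            continue
        if rng.random() >= aberrant_prob:
            continue
        if other_event_prob > 0 and rng.random() < other_event_prob:
            aberrant[i] = True
            other[i] = float(rng.normal(0.0, other_event_scale))
            continue
        tamp = truth.tamps[row.tamp]
        lo, hi = tamp.amplicon_interval
        # candidate truncation points: gene starts strictly inside the
        # amplicon and telomere-ward of the initiation point
        direction = telomere_direction(tamp.arm)
        candidates = [g.start for g in truth.genome.genes_on(tamp.chromosome)
                      if lo < g.start < hi
                      and (g.start - tamp.init_position) * direction > 0]
        if not candidates:
            continue  # nothing telomere-ward to truncate at
        aberrant[i] = True
        eval_pos[i] = float(rng.choice(candidates))
    reps["eval_position"] = eval_pos
    reps["aberrant"] = aberrant
    reps["other_offset"] = other
    return SimulationTruth(genome=truth.genome, tamps=truth.tamps,
                           landscapes=truth.landscapes, replicates=reps,
                           conditions=truth.conditions)


def build_truth(genome: GenomeModel, config: SimulationConfig,
                n_breakpoints_per_chromosome: int = 2,
                effect_size: Callable[[np.random.Generator], float] | float = 0.1,
                sharing_fraction: float = 0.0,
                init_at: str = "start",
                rng: np.random.Generator | None = None) -> SimulationTruth:
    """Plant landscapes, assign replicates, and apply the error model."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    tamps = [genome.tamp_for_gene(g.id, init_at=init_at)
             for g in genome.genes]
    landscapes = plant_landscape(genome, tamps,
                                 n_breakpoints_per_chromosome,
                                 effect_size=effect_size,
                                 sharing_fraction=sharing_fraction,
                                 conditions=config.conditions, rng=rng)
    replicates = assign_replicates(genome, tamps, config, rng)
    truth = SimulationTruth(genome=genome,
                            tamps={t.id: t for t in tamps},
                            landscapes=landscapes, replicates=replicates,
                            conditions=tuple(config.conditions))
    return corrupt_replicates(truth, config.aberrant_prob, rng,
                              other_event_prob=config.other_event_prob,
                              other_event_scale=config.other_event_scale)


# ---------------------------------------------------------------------------
# Pooled competition dynamics
# ---------------------------------------------------------------------------

def simulate_pool(truth: SimulationTruth, config: SimulationConfig,
                  rng: np.random.Generator | int | None = None,
                  initial_frequencies: np.ndarray | None = None,
                  ) -> CountMatrix:
    """Simulate the pooled competitions and bar-seq read sampling.

    Selection dynamics are deterministic: lineage frequencies follow
    ``f_i(g) ∝ f_i(0) · 2**(s_i g)``, renormalized at every sampled
    generation (so they sum to one before sampling); read counts per sample
    are a single multinomial draw at the configured depth.  Technical
    replicates share the deterministic trajectory and differ only in their
    sampling noise.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n = len(truth.replicates)
    if n == 0:
        raise ValueError("no replicates in truth")
    if initial_frequencies is None:
        f0 = np.full(n, 1.0 / n)
    else:
        f0 = np.asarray(initial_frequencies, dtype=float)
        if len(f0) != n:
            raise ValueError("initial_frequencies length mismatch")
        if np.any(f0 <= 0):
            raise ValueError("zero initial frequency for a lineage")
        f0 = f0 / f0.sum()
    gens = config.timepoint_generations

    count_frames = []
    sample_rows = []
    for cond in config.conditions:
        s = truth.realized_fitness(cond)
        for tech in range(1, config.technical_replicates + 1):
            for tp, g in enumerate(gens):
                # log-space renormalization avoids overflow for large s*g
                logw = np.log(f0) + s * g * np.log(2.0)
                logw -= logw.max()
                w = np.exp(logw)
                freqs = w / w.sum()
                counts = rng.multinomial(config.read_depth, freqs)
                sample = f"{cond}_r{tech}_t{tp}"
                frame = pd.DataFrame({
                    "tamp": truth.replicates["tamp"].to_numpy(),
                    "replicate_bc": truth.replicates["replicate_bc"].to_numpy(),
                    "sample": sample,
                    "count": counts,
                })
                count_frames.append(frame[frame["count"] > 0])
                sample_rows.append((sample, cond, tech, tp, float(g),
                                    int(config.read_depth)))
    counts = pd.concat(count_frames, ignore_index=True)[COUNT_COLUMNS]
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    return CountMatrix(counts, samples)


def expected_frequencies(truth: SimulationTruth, condition: str,
                         generations: float) -> np.ndarray:
    """Closed-form lineage frequencies at a sampled generation (no noise)."""
    s = truth.realized_fitness(condition)
    n = len(s)
    logw = s * generations * np.log(2.0)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Pairwise GFP competitions and aCGH mixtures
# ---------------------------------------------------------------------------

def simulate_pairwise(s: float, generations: Sequence[float],
                      n_cells: int = 100_000,
                      noise: bool = False,
                      rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """A head-to-head competition against a GFP-marked neutral reference.

    The mixture starts at 50/50; the expected log ratio is
    ``ln(dark/GFP) = s · ln 2 · g`` where ``s`` is the per-generation
    relative fitness in log2 units.  With ``noise=True`` the dark-cell count
    at each timepoint is a binomial draw over ``n_cells`` flow-cytometry
    events; otherwise the (real-valued) expected counts are returned.
    """
    rng = np.random.default_rng(rng)
    gens = np.asarray(generations, dtype=float)
    ratio = 2.0 ** (s * gens)          # dark / GFP
    p_dark = ratio / (1.0 + ratio)
    if noise:
        dark = rng.binomial(n_cells, p_dark).astype(float)
        gfp = n_cells - dark
    else:
        dark = n_cells * p_dark
        gfp = n_cells * (1.0 - p_dark)
    return pd.DataFrame({"generations": gens, "dark": dark, "gfp": gfp})


def simulate_acgh(genome: GenomeModel,
                  clone_karyotype: Sequence[tuple[str, float, float, int]],
                  mixing_fraction: float,
                  probe_spacing: int = 10_000,
                  noise_sd: float = 0.0,
                  ploidy: int = 2,
                  rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Probe-level log2 ratios for a population containing an aneuploid clone.

    ``clone_karyotype`` lists the clone's deviant regions as
    ``(chrom, start, end, copy_number)``; everywhere else the clone is at
    base ploidy.  The expected probe log2 ratio is
    ``log2((f·c_clone + (1−f)·ploidy) / ploidy)`` plus Gaussian noise.
    """
    rng = np.random.default_rng(rng)
    f = float(mixing_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("mixing_fraction must be in [0, 1]")
    rows = []
    for chrom, length in genome.chromosomes:
        for pos in range(probe_spacing // 2, length, probe_spacing):
            copy = ploidy
            for kchrom, lo, hi, c in clone_karyotype:
                if kchrom == chrom and lo <= pos < hi:
                    copy = c
                    break
            mean_copy = f * copy + (1.0 - f) * ploidy
            ratio = np.log2(mean_copy / ploidy)
            if noise_sd > 0:
                ratio += rng.normal(0.0, noise_sd)
            rows.append((chrom, pos, ratio))
    return pd.DataFrame(rows, columns=["chrom", "position", "log2ratio"])


# ---------------------------------------------------------------------------
# Synthetic reads
# ---------------------------------------------------------------------------

def emit_fastq(counts: CountMatrix, path: str | Path,
               scheme: BarcodeScheme,
               multiplex_table: Mapping[str, str],
               tamp_bc_table: Mapping[str, str],
               rng: np.random.Generator | int = 0) -> None:
    """Write synthetic reads with the three-barcode layout.

    ``multiplex_table`` maps sample id -> multiplex barcode and
    ``tamp_bc_table`` maps Tamp id -> Tamp barcode (inverses of the lookup
    tables the counting stage consumes).  One read is emitted per counted
    read; reads are shuffled so samples are interleaved as on a real lane.
    """
    rng = np.random.default_rng(rng)
    reads = []
    for row in counts.counts.itertuples():
        seq = (multiplex_table[row.sample] + tamp_bc_table[row.tamp]
               + row.replicate_bc)
        reads.extend([seq] * int(row.count))
    order = rng.permutation(len(reads))
    qual = "I" * (len(reads[0]) if reads else 0)
    with open(path, "w") as fh:
        for k, idx in enumerate(order):
            fh.write(f"@read{k}\n{reads[idx]}\n+\n{qual}\n")
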