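"""End-to-end orchestration: simulate/ingest -> fit -> segment -> analyze.

Stages communicate only through files in the run directory, so any stage
can be re-run or replaced; a manifest records the configuration hash and
seed so identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barseq import read_trajectory_csv, to_trajectories, \
    write_trajectory_csv
from .drivers import common_effect_regions, union_regions
from .fitness import aggregate_all, calibrate_variance_threshold, \
    combine_technical, normalize_to_reference, trajectories_to_slopes
from .genome import GenomeModel, random_genome, write_genome_tables
from .landscape import breakpoints_to_frame, build_profile, \
    classify_breakpoints, segment_profile, segments_to_frame
from .simulate import REFERENCE_ID, SimulationConfig, build_truth, \
    simulate_pool

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run, serializable to YAML.

    With ``trajectory_csvs`` set (a mapping condition -> path of a
    raw-trajectory CSV), the simulation and counting stages are skipped and
    fitness estimation starts from the supplied trajectories.
    """

    conditions: tuple[str, ...] = ("glucose", "phosphate", "sulfate")
    seed: int = 0
    # simulated inputs (used when trajectory_csvs is empty)
    n_chromosomes: int = 2
    chrom_length: int = 600_000
    genes_per_chromosome: int = 40
    n_breakpoints_per_chromosome: int = 2
    effect_sd: float = 0.1
    sharing_fraction: float = 0.0
    mean_replicates: float = 26.0
    technical_replicates: int = 3
    total_generations: float = 25.0
    n_timepoints: int = 10
    read_depth: int = 200_000
    aberrant_prob: float = 0.5
    trajectory_csvs: dict = field(default_factory=dict)
    # analysis parameters
    pseudocount: float = 1.0
    min_points: int = 3
    variance_sd_threshold: float | None = None   # None -> calibrate
    variance_target_fraction: float = 0.2
    mode_min_replicates: int = 15
    alpha: float = 0.05
    min_width: int = 2
    n_permutations: int = 10_000
    common_effect_threshold: float = 0.05
    detection_limit: float = 0.06
    reference: str = REFERENCE_ID

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["conditions"] = tuple(d["conditions"])
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str, manifest: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = round(dt, 3)
            if exc is not None:
                logger.error("stage %s failed after %.2fs: %s", name, dt, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False
    return _Timer()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write all outputs into ``outdir``.

    Returns the manifest (also written as ``manifest.json``).  Identical
    config + seed give byte-identical numeric outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": config.digest(), "stages": {}}
    config.to_yaml(outdir / "config.yaml")
    rng = np.random.default_rng(config.seed)

    genome: GenomeModel | None = None
    truth = None
    trajectories: dict[str, pd.DataFrame] = {}

    if config.trajectory_csvs:
        with _stage("ingest", manifest):
            for cond in config.conditions:
                path = config.trajectory_csvs.get(cond)
                if path is None:
                    raise ValueError(f"no trajectory CSV for {cond!r}")
                trajectories[cond] = read_trajectory_csv(path).assign(
                    condition=cond)
    else:
        with _stage("simulate", manifest):
            genome = random_genome(n_chromosomes=config.n_chromosomes,
                                   chrom_length=config.chrom_length,
                                   n_genes_per_chrom=config.genes_per_chromosome,
                                   seed=rng)
            sim = SimulationConfig(
                conditions=config.conditions,
                mean_replicates=config.mean_replicates,
                technical_replicates=config.technical_replicates,
                total_generations=config.total_generations,
                n_timepoints=config.n_timepoints,
                read_depth=config.read_depth,
                aberrant_prob=config.aberrant_prob,
                seed=config.seed)
            truth = build_truth(genome, sim,
                                n_breakpoints_per_chromosome=config.n_breakpoints_per_chromosome,
                                effect_size=config.effect_sd,
                                sharing_fraction=config.sharing_fraction,
                                rng=rng)
            counts = simulate_pool(truth, sim, rng=rng)
            write_genome_tables(genome, outdir / "genes.tsv",
                                outdir / "centromeres.tsv")
            truth.write_tables(outdir)
            counts.to_csv(outdir / "counts.csv", outdir / "samples.csv")
        with _stage("count", manifest):
            traj = to_trajectories(counts, pseudocount=config.pseudocount)
            for cond in config.conditions:
                sub = traj[traj["condition"] == cond].reset_index(drop=True)
                trajectories[cond] = sub
                write_trajectory_csv(sub, outdir / f"trajectories_{cond}.csv")

    with _stage("fit", manifest):
        all_traj = pd.concat(trajectories.values(), ignore_index=True)
        slopes = trajectories_to_slopes(all_traj,
                                        min_points=config.min_points)
        biological = combine_technical(slopes)
        try:
            biological = normalize_to_reference(biological, config.reference)
        except ValueError:
            logger.warning("reference %r absent; fitness left unnormalized",
                           config.reference)
        threshold = config.variance_sd_threshold
        if threshold is None:
            threshold = calibrate_variance_threshold(
                biological, target_fraction=config.variance_target_fraction)
        manifest["variance_sd_threshold"] = float(threshold)
        tamp_fitness = aggregate_all(
            biological, sd_threshold=threshold,
            mode_min_replicates=config.mode_min_replicates)
        tamp_fitness = tamp_fitness[tamp_fitness["tamp"] != config.reference]
        biological.to_csv(outdir / "replicate_fitness.tsv", sep="\t",
                          index=False)
        tamp_fitness.to_csv(outdir / "tamp_fitness.tsv", sep="\t",
                            index=False)

    segments_by_cond: dict = {}
    breakpoints_by_cond: dict = {}
    if genome is not None:
        with _stage("segment", manifest):
            for cond in config.conditions:
                profile = build_profile(tamp_fitness, genome, condition=cond)
                segs = segment_profile(
                    profile, alpha=config.alpha, min_width=config.min_width,
                    n_permutations=config.n_permutations, rng=rng)
                segments_by_cond[cond] = segs
                breakpoints_by_cond[cond] = classify_breakpoints(segs, genome)
                segments_to_frame(segs).to_csv(
                    outdir / f"segments_{cond}.tsv", sep="\t", index=False)
                breakpoints_to_frame(breakpoints_by_cond[cond]).to_csv(
                    outdir / f"breakpoints_{cond}.tsv", sep="\t", index=False)
        with _stage("analyze", manifest):
            regions = union_regions(segments_by_cond)
            regions["effect_class"] = common_effect_regions(
                regions, config.conditions,
                threshold=config.common_effect_threshold)
            regions.to_csv(outdir / "regions.tsv", sep="\t", index=False)
            manifest["n_regions"] = int(len(regions))
            manifest["n_segments"] = int(sum(len(s) for s
                                             in segments_by_cond.values()))
            counts_by_class = regions["effect_class"].value_counts().to_dict()
            manifest["region_classes"] = {str(k): int(v) for k, v
                                          in counts_by_class.items()}
    with _stage("report", manifest):
        lines = [f"tamp-landscape {__version__}",
                 f"seed: {config.seed}",
                 f"conditions: {', '.join(config.conditions)}",
                 f"tamps kept: "
                 f"{int((tamp_fitness['status'] == 'kept').sum())} of "
                 f"{len(tamp_fitness)} (per-condition rows)"]
        for key in ("n_segments", "n_regions"):
            if key in manifest:
                lines.append(f"{key.replace('_', ' ')}: {manifest[key]}")
        (outdir / "report.txt").write_text("\n".join(lines) + "\n")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
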