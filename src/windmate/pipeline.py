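"""End-to-end orchestration: simulate, genotype, assign, fitness, selection.

A single global seed spawns deterministic per-stage, per-population child
generators, so the same seed always reproduces the same tables and each
stage can be re-run independently. Populations are simulated and analysed
independently (they are far enough apart that pollen flow between them is
ignored), then pooled for the regression stage with population as a
covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitness as fit_mod
from . import mating, msatgen, paternity, selection, synthpop
from .io import write_table, save_config

__all__ = ["RunConfig", "seeds_to_sample", "subsample_seeds", "run_all", "estimate_allele_freqs"]

logger = logging.getLogger("windmate")

# seed-subsampling rule: (inclusive lower bound of the mother's total seed
# count, number of seeds to genotype); below 5 seeds, all are taken
_SAMPLING_BINS = [(501, 10), (401, 9), (301, 8), (201, 7), (101, 6), (5, 5)]


def seeds_to_sample(n_total_seeds: int) -> int:
    """Number of a mother's seeds to genotype given her total seed count.

    5, 6, 7, 8, 9 and 10 seeds for mothers with 5-100, 101-200, 201-300,
    301-400, 401-500 and more than 500 seeds respectively; mothers with
    fewer than five seeds have all of them genotyped.
    """
    if n_total_seeds < 0:
        raise ValueError("seed count must be non-negative")
    for lower, k in _SAMPLING_BINS:
        if n_total_seeds >= lower:
            return k
    return n_total_seeds


def subsample_seeds(seeds: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Apply the size-stratified subsampling rule per mother."""
    parts = []
    for _, grp in seeds.groupby("mother_id", sort=True):
        k = seeds_to_sample(len(grp))
        if k >= len(grp):
            parts.append(grp)
        else:
            parts.append(grp.iloc[np.sort(rng.choice(len(grp), size=k, replace=False))])
    if not parts:
        return seeds.iloc[:0]
    return pd.concat(parts, ignore_index=True)


def estimate_allele_freqs(
    parents: msatgen.GenotypeTable, pseudocount: float = 0.5
) -> list[msatgen.LocusModel]:
    """Allele frequencies re-estimated from the genotyped adults.

    Mirrors the usual parentage workflow, where the candidate-parent
    sample defines the background allele frequencies; a pseudocount keeps
    rare panel alleles at non-zero frequency.
    """
    out = []
    for loc in parents.loci:
        vals = parents.alleles(loc)
        vals = vals[vals != msatgen.MISSING]
        counts = np.array([(vals == a).sum() for a in loc.alleles], dtype=float)
        counts += pseudocount
        out.append(msatgen.LocusModel(loc.name, loc.alleles, counts / counts.sum()))
    return out


@dataclass
class RunConfig:
    """Configuration of a full replicate experiment."""

    population: synthpop.PopulationConfig = field(default_factory=synthpop.PopulationConfig)
    n_populations: int = 3
    deltas: tuple[float, ...] = (0.0, 1.0)
    n_loci: int = 9
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.02
    confidence: float = 0.80
    calibration_n_sim: int = 10_000
    min_loci: int = paternity.MIN_LOCI
    pop_interactions: str = "auto"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deltas"] = list(self.deltas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("population"), dict):
            d["population"] = synthpop.PopulationConfig.from_dict(d["population"])
        if "deltas" in d:
            d["deltas"] = tuple(d["deltas"])
        return cls(**d)


def _simulate_one_population(
    config: RunConfig,
    loci: list[msatgen.LocusModel],
    pop_id: str,
    ss: np.random.SeedSequence,
):
    """Simulate one population through mating, genotyping and assignment."""
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    plants = synthpop.simulate_population(config.population, streams[0], pop_id)
    plants, seeds = mating.simulate_mating(plants, config.population, streams[1])
    sampled = subsample_seeds(seeds, streams[2])
    parents_gt = msatgen.sample_parent_genotypes(plants["plant_id"], loci, streams[3])
    seeds_gt_true = msatgen.offspring_genotypes(sampled, parents_gt, streams[3])
    parents_obs = msatgen.apply_typing_error(
        parents_gt, config.genotyping_error_rate, config.missing_rate, streams[4]
    )
    seeds_obs = msatgen.apply_typing_error(
        seeds_gt_true, config.genotyping_error_rate, config.missing_rate, streams[4]
    )
    freqs = estimate_allele_freqs(parents_obs)
    parents_obs = msatgen.GenotypeTable(parents_obs.frame, freqs)
    seeds_obs = msatgen.GenotypeTable(seeds_obs.frame, freqs)
    calib = paternity.calibrate_delta(
        parents_obs,
        plants,
        config.genotyping_error_rate,
        confidence=config.confidence,
        n_sim=config.calibration_n_sim,
        rng=streams[5],
        missing_rate=config.missing_rate,
        min_loci=config.min_loci,
    )
    assignments = paternity.assign_population(
        seeds_obs,
        parents_obs,
        plants,
        config.genotyping_error_rate,
        calib.delta_critical,
        config.min_loci,
    )
    assignments.insert(1, "population_id", pop_id)
    logger.info(
        "population %s: plants=%d seeds=%d genotyped=%d assigned=%d confident=%d "
        "delta_crit=%.3f",
        pop_id,
        len(plants),
        int(plants["n_seeds"].sum()),
        len(sampled),
        int((assignments["status"] == "assigned").sum()),
        int(assignments["confident"].sum()),
        calib.delta_critical,
    )
    return {
        "plants": plants,
        "seeds": seeds,
        "sampled": sampled,
        "parents_obs": parents_obs,
        "seeds_obs": seeds_obs,
        "assignments": assignments,
        "calibration": calib,
    }


def run_all(config: RunConfig, seed: int, outdir=None) -> dict:
    """Run the full pipeline and return (optionally also write) all tables.

    Stages: simulate populations -> mass-action mating -> seed subsampling
    -> genotyping with error -> Delta calibration and paternity assignment
    -> per-mother selfing rates -> fitness per inbreeding-depression
    scenario -> pooled regressions and gradient extraction.
    """
    ss_root = np.random.SeedSequence(seed)
    pop_seeds = ss_root.spawn(config.n_populations + 1)
    loci = msatgen.default_loci(config.n_loci, np.random.default_rng(pop_seeds[-1]))
    per_pop = {}
    for i in range(config.n_populations):
        pop_id = f"P{i + 1}"
        try:
            per_pop[pop_id] = _simulate_one_population(config, loci, pop_id, pop_seeds[i])
        except Exception as exc:
            raise RuntimeError(f"stage failure in population {pop_id}: {exc}") from exc

    plants = pd.concat([p["plants"] for p in per_pop.values()], ignore_index=True)
    seeds = pd.concat([p["seeds"] for p in per_pop.values()], ignore_index=True)
    assignments = pd.concat([p["assignments"] for p in per_pop.values()], ignore_index=True)
    plants = fit_mod.add_gender(plants)
    selfing = paternity.selfing_rates(assignments)
    fitness = fit_mod.compute_fitness(plants, selfing, assignments, config.deltas)

    size_levels = selection.SizeLevels.from_sizes(plants["size_log"])
    tradeoff = selection.fit_tradeoff(plants)
    selfing_fit = selection.fit_selfing(selfing, plants)
    gradient_frames = []
    fits = {}
    for component in ("female", "male", "total"):
        sel = selection.fit_selection(
            fitness, component, pop_interactions=config.pop_interactions
        )
        fits[component] = sel
        gradient_frames.append(
            selection.extract_gradients(sel, size_levels, config.deltas)
        )
    gradients = pd.concat(gradient_frames, ignore_index=True)

    results = {
        "config": config,
        "loci": loci,
        "plants": plants,
        "seeds": seeds,
        "assignments": assignments,
        "selfing": selfing,
        "fitness": fitness,
        "size_levels": size_levels,
        "tradeoff_fit": tradeoff,
        "selfing_fit": selfing_fit,
        "selection_fits": fits,
        "gradients": gradients,
        "per_population": per_pop,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(plants, outdir / "plants.csv", seed)
        write_table(seeds, outdir / "seeds.csv", seed)
        write_table(assignments, outdir / "assignments.csv", seed)
        write_table(selfing, outdir / "selfing.csv", seed)
        write_table(fitness, outdir / "fitness.csv", seed)
        write_table(gradients, outdir / "gradients.csv", seed)
        save_config({"seed": seed, **config.to_dict()}, outdir / "config.yaml")
        for pop_id, p in per_pop.items():
            p["parents_obs"].frame.pipe(write_table, outdir / f"genotypes_parents_{pop_id}.csv", seed)
            p["seeds_obs"].frame.pipe(write_table, outdir / f"genotypes_seeds_{pop_id}.csv", seed)
        _write_report(results, outdir / "report.txt")
    return results


def _write_report(results: dict, path) -> None:
    plants = results["plants"]
    assignments = results["assignments"]
    selfing = results["selfing"]
    lines = [
        "windmate run report",
        f"populations: {plants['population_id'].nunique()}",
        f"plants: {len(plants)}",
        f"total seeds: {int(plants['n_seeds'].sum())}",
        f"genotyped seeds: {len(assignments)}",
        f"assigned (confident): {int(assignments['confident'].sum())}",
        f"mothers with selfing estimate: {len(selfing)}",
        f"mean selfing rate: {selfing['s_hat'].mean():.3f}" if len(selfing) else "",
        "",
        "gradients:",
        results["gradients"].to_string(index=False),
    ]
    Path(path).write_text("\n".join(lines) + "\n")
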