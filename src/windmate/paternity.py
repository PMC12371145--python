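"""Likelihood-based categorical paternity allocation and selfing rates.

Each seed of a known mother is scored against every candidate sire by a
multilocus LOD score: the log ratio of the probability of the seed's
observed genotype given the mother and the candidate as parents, to the
probability given the mother and a random population sire. Genotyping
error is modelled as frequency-weighted allele substitution applied to
the offspring observation, with the likelihood obtained by exact
marginalization over the seed's possible true genotypes; a single scalar
error rate thus absorbs Mendelian mismatches anywhere in the trio
without zeroing the likelihood. Assignments are declared confident when
the Delta statistic (LOD gap between the best and second-best candidate)
exceeds a threshold calibrated by simulation to a stated assignment
accuracy, and per-mother selfing rates are the fraction of confidently
assigned seeds sired by the mother herself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msatgen import MISSING, GenotypeTable, LocusModel

__all__ = [
    "InsufficientLociError",
    "error_matrix",
    "trio_locus_likelihood",
    "lod_score",
    "pairwise_lod",
    "calibrate_delta",
    "assign_population",
    "assign_all",
    "selfing_rates",
    "MIN_LOCI",
]

# a seed enters assignment only if typed (together with its mother) at
# more than five loci
MIN_LOCI = 6


class InsufficientLociError(ValueError):
    """Raised when a trio shares too few typed loci for a LOD score."""


def error_matrix(locus: LocusModel, error_rate: float) -> np.ndarray:
    """P(observed allele | true allele) under frequency-weighted substitution.

    E[x, a] = (1 - e) * 1[x == a] + e * p_x : with probability e the true
    allele is replaced by a draw from the locus allele frequencies (which
    may redraw the same allele).
    """
    k = len(locus.alleles)
    return (1.0 - error_rate) * np.eye(k) + error_rate * locus.freqs[:, None] * np.ones((1, k))


def _obs_given_true_vector(locus: LocusModel, off_idx, error_rate: float) -> np.ndarray:
    """v[a, b] summed over mother alleles is built by callers; here return M.

    M[a, b] = P(observed offspring genotype | true ordered genotype (a, b)).
    """
    E = error_matrix(locus, error_rate)
    x, y = off_idx
    if x == y:
        return np.outer(E[x], E[x])
    return np.outer(E[x], E[y]) + np.outer(E[y], E[x])


def trio_locus_likelihood(
    offspring_pair,
    mother_pair,
    candidate_pair,
    locus: LocusModel,
    error_rate: float,
) -> tuple[float, float]:
    """Single-locus likelihoods (L_father, L_random) for one trio.

    L_father = P(offspring observation | mother, candidate as parents);
    L_random = P(offspring observation | mother, paternal allele drawn from
    the population allele frequencies). Transmission is Mendelian (one
    allele uniformly from each parent); observation error follows
    :func:`error_matrix`. Missing offspring or mother genotypes are the
    caller's responsibility (the locus is skipped upstream).
    """
    off = locus.index_of(np.asarray(offspring_pair))
    mom = locus.index_of(np.asarray(mother_pair))
    cand = locus.index_of(np.asarray(candidate_pair))
    if np.any(off < 0) or np.any(mom < 0) or np.any(cand < 0):
        raise ValueError("trio_locus_likelihood requires non-missing genotypes")
    M = _obs_given_true_vector(locus, off, error_rate)
    v = 0.5 * (M[mom[0]] + M[mom[1]])  # true paternal allele -> likelihood
    l_father = 0.5 * (v[cand[0]] + v[cand[1]])
    l_random = float(v @ locus.freqs)
    return float(l_father), l_random


def lod_score(
    offspring_gt: dict[str, tuple[int, int]],
    mother_gt: dict[str, tuple[int, int]],
    candidate_gt: dict[str, tuple[int, int]],
    loci: list[LocusModel],
    error_rate: float,
    min_loci: int = 0,
) -> tuple[float, int]:
    """Multilocus LOD: sum of per-locus log likelihood ratios.

    Only loci typed in all three individuals contribute. Returns
    (lod, n_loci_compared); raises :class:`InsufficientLociError` when
    fewer than ``min_loci`` loci are comparable.
    """
    lod = 0.0
    n = 0
    for loc in loci:
        trio = [offspring_gt[loc.name], mother_gt[loc.name], candidate_gt[loc.name]]
        if any(MISSING in pair for pair in trio):
            continue
        lf, lr = trio_locus_likelihood(*trio, loc, error_rate)
        with np.errstate(divide="ignore"):
            lod += float(np.log(lf) - np.log(lr))
        n += 1
    if n < min_loci:
        raise InsufficientLociError(f"only {n} comparable loci (need >= {min_loci})")
    return lod, n


def pairwise_lod(
    seed_alleles: dict[str, np.ndarray],
    mother_rows: np.ndarray,
    parent_alleles: dict[str, np.ndarray],
    cand_rows: np.ndarray,
    loci: list[LocusModel],
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized LOD of every seed against every candidate.

    Parameters are per-locus allele-index arrays (missing = -1):
    ``seed_alleles[locus]`` is (n_seeds, 2), ``parent_alleles[locus]`` is
    (n_parents, 2); ``mother_rows`` maps each seed to its mother's row and
    ``cand_rows`` lists candidate rows. Returns (lod (n, C),
    n_loci (n, C), seed_typed (n,)) where ``seed_typed`` counts loci typed
    in both the seed and its mother.
    """
    n = len(mother_rows)
    C = len(cand_rows)
    lod = np.zeros((n, C))
    nloci = np.zeros((n, C), dtype=np.int64)
    seed_typed = np.zeros(n, dtype=np.int64)
    for loc in loci:
        off = seed_alleles[loc.name]
        par = parent_alleles[loc.name]
        mom = par[mother_rows]
        cand = par[cand_rows]
        valid_s = (off >= 0).all(axis=1) & (mom >= 0).all(axis=1)
        valid_c = (cand >= 0).all(axis=1)
        if not valid_s.any():
            continue
        seed_typed += valid_s
        E = error_matrix(loc, error_rate)
        x = np.clip(off[:, 0], 0, None)
        y = np.clip(off[:, 1], 0, None)
        m0 = np.clip(mom[:, 0], 0, None)
        m1 = np.clip(mom[:, 1], 0, None)
        Ex = E[x]  # (n, A): P(obs x | true allele)
        Ey = E[y]
        rows = np.arange(n)
        ex_m = Ex[rows, m0] + Ex[rows, m1]
        ey_m = Ey[rows, m0] + Ey[rows, m1]
        v = 0.5 * (ex_m[:, None] * Ey + ey_m[:, None] * Ex)
        v[x == y] *= 0.5  # homozygous observation counted once
        l_random = v @ loc.freqs
        l_father = 0.5 * (v[:, np.clip(cand[:, 0], 0, None)] + v[:, np.clip(cand[:, 1], 0, None)])
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.log(l_father) - np.log(l_random)[:, None]
        mask = valid_s[:, None] & valid_c[None, :]
        lod += np.where(mask, contrib, 0.0)
        nloci += mask
    return lod, nloci, seed_typed


def _best_and_delta(lod: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best candidate, Delta, and tie flag per row of a LOD matrix.

    Delta is the LOD gap to the second-best candidate; with a single
    candidate in the pool, Delta is the best LOD itself (gap to an empty
    field, taken as zero). Exact ties for the best score are flagged.
    """
    order = np.argsort(lod, axis=1)
    best = order[:, -1]
    lod_best = lod[np.arange(len(lod)), best]
    if lod.shape[1] >= 2:
        second = order[:, -2]
        lod_second = lod[np.arange(len(lod)), second]
        delta = lod_best - lod_second
        tied = delta == 0.0
    else:
        delta = lod_best.copy()
        tied = np.zeros(len(lod), dtype=bool)
    return best, delta, tied


def _index_tables(gt: GenotypeTable) -> dict[str, np.ndarray]:
    return {loc.name: loc.index_of(gt.alleles(loc)) for loc in gt.loci}


@dataclass
class DeltaCalibration:
    """Result of the simulation-based Delta threshold calibration."""

    delta_critical: float
    confidence: float
    n_sim: int
    precision_at_zero: float  # fraction correct among all simulated assignments


def calibrate_delta(
    parents: GenotypeTable,
    plants: pd.DataFrame,
    error_rate: float,
    confidence: float = 0.80,
    n_sim: int = 10_000,
    rng: np.random.Generator | None = None,
    missing_rate: float = 0.0,
    candidate_sampling: float = 1.0,
    min_loci: int = MIN_LOCI,
) -> DeltaCalibration:
    """Simulate known-sire offspring to find the Delta confidence threshold.

    Offspring are generated Mendelianly from genotyped dams and candidate
    sires of the focal population, observed through the same error and
    missingness process as the data, and re-assigned; the returned
    threshold is the smallest Delta such that at least ``confidence`` of
    simulated assignments with Delta at or above it recover the true sire.
    ``candidate_sampling`` < 1 drops the true sire from the scored pool
    with the complementary probability, mimicking incomplete sampling of
    candidate fathers.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    if n_sim < 500:
        import warnings

        warnings.warn(f"n_sim={n_sim} is small for Delta calibration", stacklevel=2)
    pid = parents.frame["individual_id"].to_numpy()
    nm = plants.set_index("plant_id")["nm"].reindex(pid).fillna(0).to_numpy()
    nf = plants.set_index("plant_id")["nf"].reindex(pid).fillna(0).to_numpy()
    dam_rows = np.nonzero(nf > 0)[0]
    sire_rows = np.nonzero(nm > 0)[0]
    if len(dam_rows) == 0 or len(sire_rows) == 0:
        raise ValueError("calibration requires at least one dam and one sire")
    par_idx = _index_tables(parents)
    mothers = rng.choice(dam_rows, size=n_sim)
    fathers = rng.choice(sire_rows, size=n_sim)
    # simulate offspring observations locus by locus
    seed_alleles: dict[str, np.ndarray] = {}
    for loc in parents.loci:
        par = par_idx[loc.name]
        mom = par[mothers]
        dad = par[fathers]
        a1 = mom[np.arange(n_sim), rng.integers(2, size=n_sim)]
        a2 = dad[np.arange(n_sim), rng.integers(2, size=n_sim)]
        obs = np.stack([a1, a2], axis=1)
        miss_parent = (mom < 0).any(axis=1) | (dad < 0).any(axis=1)
        err = rng.random(obs.shape) < error_rate
        redraw = rng.choice(len(loc.alleles), size=obs.shape, p=loc.freqs)
        obs = np.where(err & (obs >= 0), redraw, obs)
        drop = (rng.random(n_sim) < missing_rate) | miss_parent
        obs[drop] = -1
        seed_alleles[loc.name] = obs
    lod, _, seed_typed = pairwise_lod(
        seed_alleles, mothers, par_idx, sire_rows, parents.loci, error_rate
    )
    if candidate_sampling < 1.0:
        unsampled = rng.random(n_sim) >= candidate_sampling
        true_col = np.searchsorted(sire_rows, fathers)
        lod[unsampled, true_col[unsampled]] = -np.inf
    eligible = seed_typed >= min_loci
    best, delta, tied = _best_and_delta(lod)
    correct = (sire_rows[best] == fathers) & ~tied & eligible
    delta = np.where(eligible & ~tied, delta, -np.inf)
    keep = np.isfinite(delta)
    delta, correct = delta[keep], correct[keep]
    order = np.argsort(-delta)
    delta, correct = delta[order], correct[order]
    cum_prec = np.cumsum(correct) / np.arange(1, len(correct) + 1)
    qualifying = np.nonzero(cum_prec >= confidence)[0]
    if len(qualifying) == 0:
        crit = float("inf")
    elif qualifying[-1] == len(delta) - 1:
        crit = 0.0  # every simulated assignment qualifies: no restriction
    else:
        crit = max(0.0, float(delta[qualifying[-1]]))
    return DeltaCalibration(
        delta_critical=crit,
        confidence=confidence,
        n_sim=n_sim,
        precision_at_zero=float(correct.mean()) if len(correct) else float("nan"),
    )


def assign_population(
    seeds: GenotypeTable,
    parents: GenotypeTable,
    plants: pd.DataFrame,
    error_rate: float,
    delta_critical: float,
    min_loci: int = MIN_LOCI,
) -> pd.DataFrame:
    """Assign the most likely sire to every eligible seed of one population.

    Candidate sires are the genotyped adults with male flowers (the mother
    competes like any other candidate when she produces pollen, which is
    how selfing is detected). Seeds typed, together with their mother, at
    fewer than ``min_loci`` loci are excluded; exact LOD ties are left
    unassigned. ``confident`` marks assignments with Delta >=
    ``delta_critical``.
    """
    pid = parents.frame["individual_id"].to_numpy()
    row_of = {p: i for i, p in enumerate(pid)}
    nm = plants.set_index("plant_id")["nm"].reindex(pid).fillna(0).to_numpy()
    cand_rows = np.nonzero(nm > 0)[0]
    if len(cand_rows) == 0:
        raise ValueError("no candidate sires with male flowers")
    mother_ids = seeds.frame["mother_id"].to_numpy()
    mother_rows = np.array([row_of[m] for m in mother_ids])
    seed_alleles = _index_tables(seeds)
    par_idx = _index_tables(parents)
    lod, nloci, seed_typed = pairwise_lod(
        seed_alleles, mother_rows, par_idx, cand_rows, seeds.loci, error_rate
    )
    best, delta, tied = _best_and_delta(lod)
    eligible = seed_typed >= min_loci
    assigned = eligible & ~tied
    rows = np.arange(len(mother_rows))
    out = pd.DataFrame(
        {
            "seed_id": seeds.frame["individual_id"].to_numpy(),
            "mother_id": mother_ids,
            "best_father_id": np.where(assigned, pid[cand_rows[best]], None),
            "lod": np.where(eligible, lod[rows, best], np.nan),
            "delta": np.where(assigned, delta, np.nan),
            "confident": assigned & (delta >= delta_critical),
            "n_loci": seed_typed,
            "status": np.select(
                [~eligible, tied],
                ["insufficient_loci", "tied"],
                default="assigned",
            ),
        }
    )
    return out


def assign_all(
    seeds_by_pop: dict[str, GenotypeTable],
    parents_by_pop: dict[str, GenotypeTable],
    plants: pd.DataFrame,
    error_rate: float,
    delta_by_pop: dict[str, float],
    min_loci: int = MIN_LOCI,
) -> pd.DataFrame:
    """Run assignment independently for each population and concatenate."""
    frames = []
    for pop, seeds in seeds_by_pop.items():
        sub = plants[plants["population_id"] == pop]
        res = assign_population(
            seeds, parents_by_pop[pop], sub, error_rate, delta_by_pop[pop], min_loci
        )
        res.insert(1, "population_id", pop)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def selfing_rates(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-mother selfing rate from confident assignments.

    S = (confidently assigned seeds sired by the mother) / (confidently
    assigned seeds). Mothers without any confidently assigned seed do not
    appear in the output.
    """
    conf = assignments[assignments["confident"]].copy()
    if conf.empty:
        return pd.DataFrame(columns=["mother_id", "n_assigned", "n_selfed", "s_hat"])
    conf["selfed"] = conf["best_father_id"] == conf["mother_id"]
    g = conf.groupby("mother_id", sort=True)["selfed"].agg(["count", "sum"]).reset_index()
    g.columns = ["mother_id", "n_assigned", "n_selfed"]
    g["s_hat"] = g["n_selfed"] / g["n_assigned"]
    return g
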