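"""Paternity LOD scores, Delta calibration, assignment and selfing rates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_plants
from windmate import msatgen, paternity
from windmate.msatgen import MISSING, GenotypeTable, LocusModel, default_loci
from windmate.paternity import (
    InsufficientLociError,
    assign_population,
    calibrate_delta,
    lod_score,
    selfing_rates,
    trio_locus_likelihood,
)


def brute_force_likelihoods(off_pair, mom_pair, cand_pair, locus, e):
    """Exhaustive enumeration over transmission events and error configurations.

    Loops explicitly over the maternal and paternal transmitted alleles,
    over whether each of the two observed offspring allele slots suffered a
    substitution, and over the replacement allele drawn from the locus
    frequencies; completely independent of the matrix implementation.
    """
    alleles = list(locus.alleles)
    freqs = dict(zip(alleles, locus.freqs))

    def p_slot(obs, true):
        p = (1 - e) if obs == true else 0.0
        for c in alleles:  # substitution event drawing allele c
            if c == obs:
                p += e * freqs[c]
        return p

    def p_obs(true_a, true_b):
        x, y = off_pair
        if x == y:
            return p_slot(x, true_a) * p_slot(x, true_b)
        return p_slot(x, true_a) * p_slot(y, true_b) + p_slot(y, true_a) * p_slot(x, true_b)

    l_father = sum(
        0.25 * p_obs(a, b) for a in mom_pair for b in cand_pair
    )
    l_random = sum(
        0.5 * freqs[b] * p_obs(a, b) for a in mom_pair for b in alleles
    )
    return l_father, l_random


ORACLE_LOCI = [
    LocusModel("L2", [100, 102], [0.5, 0.5]),
    LocusModel("L2b", [100, 102], [0.7, 0.3]),
    LocusModel("L3", [100, 102, 104], [0.5, 0.3, 0.2]),
]


class TestTrioLikelihoodOracle:
    @pytest.mark.parametrize("locus", ORACLE_LOCI, ids=lambda l: l.name)
    @pytest.mark.parametrize("e", [0.0, 0.01, 0.3])
    def test_matches_exhaustive_enumeration(self, locus, e):
        genotypes = list(itertools.combinations_with_replacement(locus.alleles, 2))
        for off, mom, cand in itertools.product(genotypes, repeat=3):
            lf, lr = trio_locus_likelihood(off, mom, cand, locus, e)
            bf_lf, bf_lr = brute_force_likelihoods(off, mom, cand, locus, e)
            assert abs(lf - bf_lf) < 1e-12
            assert abs(lr - bf_lr) < 1e-12

    def test_hand_worked_example(self):
        # alleles A/B at 0.5 each, mother AA, offspring AA, candidate AA,
        # no error: paternal allele must be A; candidate transmits A with
        # certainty vs 0.5 at random -> locus LOD = ln 2
        loc = LocusModel("L", [100, 102], [0.5, 0.5])
        lf, lr = trio_locus_likelihood((100, 100), (100, 100), (100, 100), loc, 0.0)
        assert np.isclose(np.log(lf) - np.log(lr), np.log(2.0))

    def test_exclusion_without_error_zeroes_likelihood(self):
        # offspring paternal allele absent from the candidate
        loc = LocusModel("L", [100, 102], [0.5, 0.5])
        lf, _ = trio_locus_likelihood((100, 102), (100, 100), (100, 100), loc, 0.0)
        assert lf == 0.0

    def test_error_model_absorbs_exclusion(self):
        loc = LocusModel("L", [100, 102], [0.5, 0.5])
        lf, lr = trio_locus_likelihood((100, 102), (100, 100), (100, 100), loc, 0.01)
        lod = np.log(lf) - np.log(lr)
        assert np.isfinite(lod) and lod < 0


class TestLodScore:
    def _gts(self, pairs):
        return {f"L{i+1}": p for i, p in enumerate(pairs)}

    def test_uninformative_loci_give_zero(self):
        # candidate likelihood equals random likelihood when every allele
        # is equally frequent and the candidate is heterozygous like the pool
        loc = LocusModel("L1", [100, 102], [0.5, 0.5])
        off, mom, cand = (100, 102), (100, 102), (100, 102)
        lf, lr = trio_locus_likelihood(off, mom, cand, loc, 0.0)
        assert np.isclose(lf, lr)
        lod, n = lod_score({"L1": off}, {"L1": mom}, {"L1": cand}, [loc], 0.0)
        assert np.isclose(lod, 0.0) and n == 1

    def test_additivity_over_loci(self):
        loci = [
            LocusModel("L1", [100, 102], [0.6, 0.4]),
            LocusModel("L2", [200, 202, 204], [0.2, 0.3, 0.5]),
        ]
        off = self._gts([(100, 102), (200, 204)])
        mom = self._gts([(100, 100), (200, 202)])
        cand = self._gts([(102, 102), (204, 204)])
        lod_both, _ = lod_score(off, mom, cand, loci, 0.01)
        lod_1, _ = lod_score(off, mom, cand, loci[:1], 0.01)
        lod_2, _ = lod_score(off, mom, cand, loci[1:], 0.01)
        assert np.isclose(lod_both, lod_1 + lod_2)

    def test_missing_locus_skipped_and_min_loci_enforced(self):
        loci = [LocusModel("L1", [100, 102], [0.5, 0.5])]
        off = {"L1": (MISSING, MISSING)}
        mom = {"L1": (100, 100)}
        with pytest.raises(InsufficientLociError):
            lod_score(off, mom, mom, loci, 0.01, min_loci=1)

    def test_true_father_beats_unrelated_candidate(self, rng):
        # simulation oracle: with 9 informative loci the true sire outranks
        # an unrelated candidate in nearly every trio
        loci = default_loci(9, np.random.default_rng(10))
        parents = msatgen.sample_parent_genotypes(
            ["mom", "dad", "other"], loci, rng
        )
        wins = 0
        n = 1000
        seeds = pd.DataFrame(
            {"seed_id": [f"s{i}" for i in range(n)], "mother_id": "mom", "father_id": "dad"}
        )
        off = msatgen.offspring_genotypes(seeds, parents, rng)
        for i in range(n):
            child = {
                loc.name: tuple(off.alleles(loc)[i]) for loc in loci
            }
            gt = lambda who: {
                loc.name: tuple(
                    parents.alleles(loc)[list(parents.frame["individual_id"]).index(who)]
                )
                for loc in loci
            }
            lod_true, _ = lod_score(child, gt("mom"), gt("dad"), loci, 0.01)
            lod_other, _ = lod_score(child, gt("mom"), gt("other"), loci, 0.01)
            wins += lod_true > lod_other
        assert wins >= 0.99 * n


def _population_for_assignment(rng, n_parents=30, n_loci=9, n_seeds_per=6):
    loci = default_loci(n_loci, np.random.default_rng(20))
    ids = [f"p{i}" for i in range(n_parents)]
    xy = rng.uniform(0, 100, size=(n_parents, 2))
    plants = pd.DataFrame(
        {
            "plant_id": ids,
            "population_id": "P1",
            "x_cm": xy[:, 0],
            "y_cm": xy[:, 1],
            "nf": 10,
            "nm": 10,
            "size_log": 3.0,
        }
    )
    parents = msatgen.sample_parent_genotypes(ids, loci, rng)
    mothers = rng.choice(ids, size=n_parents * n_seeds_per)
    fathers = rng.choice(ids, size=n_parents * n_seeds_per)
    seeds = pd.DataFrame(
        {
            "seed_id": [f"s{i}" for i in range(len(mothers))],
            "mother_id": mothers,
            "father_id": fathers,
        }
    )
    seeds_gt = msatgen.offspring_genotypes(seeds, parents, rng)
    return loci, plants, parents, seeds, seeds_gt


class TestAssignment:
    def test_exclusion_consistency_without_error(self, rng):
        # with error rate 0, a candidate with a Mendelian incompatibility
        # at any locus is never the assigned sire
        loci, plants, parents, seeds, seeds_gt = _population_for_assignment(rng)
        res = assign_population(seeds_gt, parents, plants, 0.0, 0.0)
        assigned = res.dropna(subset=["best_father_id"])
        par_rows = {p: i for i, p in enumerate(parents.frame["individual_id"])}
        for _, row in assigned.iterrows():
            srow = list(seeds_gt.frame["individual_id"]).index(row["seed_id"])
            for loc in loci:
                off = seeds_gt.alleles(loc)[srow]
                mom = parents.alleles(loc)[par_rows[row["mother_id"]]]
                cand = parents.alleles(loc)[par_rows[row["best_father_id"]]]
                if MISSING in off or MISSING in mom or MISSING in cand:
                    continue
                # offspring must carry at least one allele from the candidate
                # consistent with the mother providing the other
                ok = any(
                    (a in mom) and (b in cand)
                    for a, b in (off, off[::-1])
                )
                assert ok

    def test_mother_only_compatible_candidate_assigned_selfed(self):
        # a selfed seed whose alleles exclude every other candidate is
        # assigned to its mother, scoring the seed as selfed
        loci = [LocusModel(f"L{i}", [100, 102], [0.5, 0.5]) for i in range(9)]
        rows = {"individual_id": ["mom", "other"], "role": "parent", "mother_id": ""}
        for loc in loci:
            rows[f"{loc.name}_a1"] = [100, 102]
            rows[f"{loc.name}_a2"] = [100, 102]
        parents = GenotypeTable(pd.DataFrame(rows), loci)
        srow = {"individual_id": ["s1"], "role": "seed", "mother_id": ["mom"]}
        for loc in loci:
            srow[f"{loc.name}_a1"] = [100]
            srow[f"{loc.name}_a2"] = [100]
        seeds_gt = GenotypeTable(pd.DataFrame(srow), loci)
        plants = make_plants([("mom", 0, 0, 5, 5), ("other", 20, 0, 5, 5)])
        res = assign_population(seeds_gt, parents, plants, 0.01, 0.0)
        assert res["best_father_id"].iloc[0] == "mom"
        assert res["confident"].iloc[0]

    def test_identical_candidate_genotypes_tie_unassigned(self, rng):
        loci = default_loci(9, np.random.default_rng(31))
        parents = msatgen.sample_parent_genotypes(["mom", "t1", "t2"], loci, rng)
        # make t2 an exact genetic copy of t1
        for loc in loci:
            for col in (f"{loc.name}_a1", f"{loc.name}_a2"):
                parents.frame.loc[2, col] = parents.frame.loc[1, col]
        plants = make_plants(
            [("mom", 0, 0, 5, 0), ("t1", 20, 0, 5, 5), ("t2", 40, 0, 5, 5)]
        )
        seeds = pd.DataFrame({"seed_id": ["s1"], "mother_id": ["mom"], "father_id": ["t1"]})
        seeds_gt = msatgen.offspring_genotypes(seeds, parents, rng)
        res = assign_population(seeds_gt, parents, plants, 0.01, 0.5)
        assert res["status"].iloc[0] == "tied"
        assert not res["confident"].iloc[0]

    def test_insufficient_loci_flagged(self, rng):
        loci, plants, parents, seeds, seeds_gt = _population_for_assignment(rng)
        frame = seeds_gt.frame.copy()
        for loc in loci[:5]:  # leave only 4 typed loci on the first seed
            frame.loc[0, [f"{loc.name}_a1", f"{loc.name}_a2"]] = MISSING
        res = assign_population(GenotypeTable(frame, loci), parents, plants, 0.01, 0.0)
        assert res["status"].iloc[0] == "insufficient_loci"
        assert not res["confident"].iloc[0]

    def test_confident_assignments_mostly_correct(self, default_run):
        assignments = default_run["assignments"]
        truth = default_run["seeds"].set_index("seed_id")["father_id"]
        conf = assignments[assignments["confident"]]
        acc = (conf["best_father_id"] == conf["seed_id"].map(truth)).mean()
        assert acc >= 0.90


class TestDeltaCalibration:
    def test_monotone_in_confidence(self, rng):
        loci, plants, parents, *_ = _population_for_assignment(rng)
        c80 = calibrate_delta(parents, plants, 0.01, 0.80, 2000, np.random.default_rng(5))
        c95 = calibrate_delta(parents, plants, 0.01, 0.95, 2000, np.random.default_rng(5))
        assert c95.delta_critical >= c80.delta_critical >= 0.0

    def test_vanishing_confidence_assigns_everything(self, rng):
        loci, plants, parents, *_ = _population_for_assignment(rng)
        c = calibrate_delta(parents, plants, 0.01, 1e-9, 1000, np.random.default_rng(5))
        assert c.delta_critical == 0.0

    def test_small_threshold_with_full_sampling(self, rng):
        # all candidates genotyped and polymorphic loci: threshold small
        loci, plants, parents, *_ = _population_for_assignment(rng)
        c = calibrate_delta(parents, plants, 0.01, 0.80, 2000, np.random.default_rng(6))
        assert 0.0 <= c.delta_critical < 5.0
        assert c.precision_at_zero > 0.5

    def test_warns_on_small_n_sim(self, rng):
        loci, plants, parents, *_ = _population_for_assignment(rng)
        with pytest.warns(UserWarning, match="small"):
            calibrate_delta(parents, plants, 0.01, 0.8, 200, np.random.default_rng(5))

    def test_invalid_confidence(self, rng):
        loci, plants, parents, *_ = _population_for_assignment(rng)
        with pytest.raises(ValueError):
            calibrate_delta(parents, plants, 0.01, 1.2, 1000, rng)


class TestSelfingRates:
    def _assignments(self, rows):
        return pd.DataFrame(
            rows, columns=["seed_id", "mother_id", "best_father_id", "confident"]
        )

    def test_no_selfed(self):
        rows = [(f"s{i}", "m1", "d1", True) for i in range(5)]
        out = selfing_rates(self._assignments(rows))
        assert out["s_hat"].iloc[0] == 0.0 and out["n_assigned"].iloc[0] == 5

    def test_quarter_selfed(self):
        rows = [(f"s{i}", "m1", "m1" if i < 2 else "d1", True) for i in range(8)]
        out = selfing_rates(self._assignments(rows))
        assert np.isclose(out["s_hat"].iloc[0], 0.25)

    def test_unconfident_excluded(self):
        rows = [("s1", "m1", "m1", False)]
        out = selfing_rates(self._assignments(rows))
        assert len(out) == 0

    def test_population_mean_recovery(self, default_run):
        # estimated per-mother mean selfing within 3 points of the truth
        est = default_run["selfing"]
        true_s = default_run["seeds"].groupby("mother_id")["selfed"].mean()
        common = true_s.index.intersection(est["mother_id"])
        err = est.set_index("mother_id").loc[common, "s_hat"].mean() - true_s.loc[common].mean()
        assert abs(err) <= 0.03
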