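"""Codominant multilocus microsatellite genotypes for parents and seeds.

Synthetic marker panels (by default nine loci, 5-15 alleles each) with
Hardy-Weinberg parental genotypes, Mendelian seed genotypes, and a
frequency-weighted allele-substitution error process plus per-locus
missingness. Allele labels are integer fragment lengths; 0 denotes a
missing call. The wide CSV layout (two columns per locus) follows the
GenAlEx convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LocusModel",
    "GenotypeTable",
    "default_loci",
    "sample_parent_genotypes",
    "mendelian_offspring",
    "offspring_genotypes",
    "apply_typing_error",
]

MISSING = 0


@dataclass
class LocusModel:
    """One microsatellite locus: allele fragment lengths and frequencies."""

    name: str
    alleles: np.ndarray  # integer fragment lengths, > 0
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name}: needs at least one allele")
        if np.any(self.freqs <= 0) or abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"locus {self.name}: frequencies must be positive and sum to 1")
        if np.any(self.alleles <= 0):
            raise ValueError(f"locus {self.name}: allele labels must be positive integers")

    def index_of(self, allele_values: np.ndarray) -> np.ndarray:
        """Map allele values to indices into the allele set; MISSING -> -1."""
        lookup = {int(a): i for i, a in enumerate(self.alleles)}
        lookup[MISSING] = -1
        try:
            return np.vectorize(lookup.__getitem__, otypes=[np.int64])(allele_values)
        except KeyError as exc:
            raise ValueError(f"locus {self.name}: allele {exc} not in allele set") from exc


def default_loci(
    n_loci: int = 9,
    rng: np.random.Generator | None = None,
    min_alleles: int = 5,
    max_alleles: int = 15,
    dirichlet_alpha: float = 1.0,
) -> list[LocusModel]:
    """Synthetic marker panel standing in for an empirical microsatellite set."""
    rng = np.random.default_rng(0) if rng is None else rng
    loci = []
    for i in range(n_loci):
        k = int(rng.integers(min_alleles, max_alleles + 1))
        # fragment lengths: dinucleotide ladder starting at a locus-specific offset
        start = 100 + 20 * i
        alleles = start + 2 * np.arange(k)
        freqs = rng.dirichlet(np.full(k, dirichlet_alpha))
        freqs = np.clip(freqs, 1e-4, None)
        freqs = freqs / freqs.sum()
        loci.append(LocusModel(f"L{i + 1:02d}", alleles, freqs))
    return loci


class GenotypeTable:
    """Genotypes of parents and seeds at a shared marker panel.

    Wraps a wide DataFrame: individual_id, role ('parent' | 'seed'),
    mother_id (empty for parents), then two columns per locus
    (``<locus>_a1``, ``<locus>_a2``) holding allele fragment lengths,
    0 = missing.
    """

    def __init__(self, frame: pd.DataFrame, loci: list[LocusModel]):
        self.frame = frame.reset_index(drop=True)
        self.loci = loci
        for loc in loci:
            for col in (f"{loc.name}_a1", f"{loc.name}_a2"):
                if col not in frame.columns:
                    raise ValueError(f"genotype table missing column {col}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def alleles(self, locus: str | LocusModel) -> np.ndarray:
        """(n, 2) array of allele values at one locus (0 = missing)."""
        name = locus.name if isinstance(locus, LocusModel) else locus
        return self.frame[[f"{name}_a1", f"{name}_a2"]].to_numpy(dtype=np.int64)

    def subset(self, mask) -> "GenotypeTable":
        return GenotypeTable(self.frame.loc[mask].reset_index(drop=True), self.loci)

    def validate(self) -> None:
        """Check every non-missing allele belongs to its locus's allele set."""
        for loc in self.loci:
            vals = self.alleles(loc)
            ok = np.isin(vals, np.concatenate(([MISSING], loc.alleles)))
            if not ok.all():
                bad = np.unique(vals[~ok])
                raise ValueError(f"locus {loc.name}: alleles {bad} outside allele set")

    def write_csv(self, path, seed: int | None = None) -> None:
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path, loci: list[LocusModel]) -> "GenotypeTable":
        frame = pd.read_csv(path, comment="#", dtype={"individual_id": str, "mother_id": str})
        frame["mother_id"] = frame["mother_id"].fillna("")
        table = cls(frame, loci)
        table.validate()
        return table


def _hw_draw(locus: LocusModel, n: int, rng: np.random.Generator) -> np.ndarray:
    return locus.alleles[rng.choice(len(locus.alleles), size=(n, 2), p=locus.freqs)]


def sample_parent_genotypes(
    plant_ids, loci: list[LocusModel], rng: np.random.Generator
) -> GenotypeTable:
    """Hardy-Weinberg genotypes for the adult plants."""
    plant_ids = list(plant_ids)
    data = {
        "individual_id": plant_ids,
        "role": "parent",
        "mother_id": "",
    }
    frame = pd.DataFrame(data)
    for loc in loci:
        pairs = _hw_draw(loc, len(plant_ids), rng)
        frame[f"{loc.name}_a1"] = pairs[:, 0]
        frame[f"{loc.name}_a2"] = pairs[:, 1]
    return GenotypeTable(frame, loci)


def mendelian_offspring(
    mother_gt: dict[str, tuple[int, int]],
    father_gt: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    """One offspring genotype: one allele drawn uniformly from each parent per locus.

    A locus missing in either parent is missing in the offspring.
    """
    child = {}
    for name, m_pair in mother_gt.items():
        f_pair = father_gt[name]
        if MISSING in m_pair or MISSING in f_pair:
            child[name] = (MISSING, MISSING)
            continue
        child[name] = (
            int(m_pair[rng.integers(2)]),
            int(f_pair[rng.integers(2)]),
        )
    return child


def offspring_genotypes(
    seeds: pd.DataFrame,
    parents: GenotypeTable,
    rng: np.random.Generator,
) -> GenotypeTable:
    """Mendelian genotypes for a seed table (columns seed_id, mother_id, father_id)."""
    idx = {pid: i for i, pid in enumerate(parents.frame["individual_id"])}
    mi = seeds["mother_id"].map(idx).to_numpy()
    fi = seeds["father_id"].map(idx).to_numpy()
    frame = pd.DataFrame(
        {
            "individual_id": seeds["seed_id"].to_numpy(),
            "role": "seed",
            "mother_id": seeds["mother_id"].to_numpy(),
        }
    )
    n = len(seeds)
    for loc in parents.loci:
        pv = parents.alleles(loc)
        m_pick = rng.integers(2, size=n)
        f_pick = rng.integers(2, size=n)
        a1 = pv[mi, m_pick]
        a2 = pv[fi, f_pick]
        miss = (pv[mi] == MISSING).any(axis=1) | (pv[fi] == MISSING).any(axis=1)
        a1 = np.where(miss, MISSING, a1)
        a2 = np.where(miss, MISSING, a2)
        frame[f"{loc.name}_a1"] = a1
        frame[f"{loc.name}_a2"] = a2
    return GenotypeTable(frame, parents.loci)


def apply_typing_error(
    gt: GenotypeTable,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> GenotypeTable:
    """Observed genotypes: allele substitution errors plus per-locus dropouts.

    Each allele call is independently replaced, with probability
    ``error_rate``, by an allele drawn from the locus's frequencies (the
    frequency-weighted 'class II' error model); each locus of each
    individual is independently set fully missing with probability
    ``missing_rate``. Replacement can redraw the true allele, so the
    realized changed-call rate per allele is error_rate * (1 - p_own).
    """
    if not (0 <= error_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    frame = gt.frame.copy()
    n = len(frame)
    for loc in gt.loci:
        vals = gt.alleles(loc).copy()
        present = vals != MISSING
        err = (rng.random(vals.shape) < error_rate) & present
        if err.any():
            vals[err] = loc.alleles[rng.choice(len(loc.alleles), size=int(err.sum()), p=loc.freqs)]
        drop = rng.random(n) < missing_rate
        vals[drop] = MISSING
        frame[f"{loc.name}_a1"] = vals[:, 0]
        frame[f"{loc.name}_a2"] = vals[:, 1]
    return GenotypeTable(frame, gt.loci)
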