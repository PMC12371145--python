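"""Mass-action wind pollination.

Each mother's ovules are fertilized from the pollen cloud around her
stigmas, to which every plant j (the mother included) contributes in
proportion to its male flower number weighted by a distance-decay kernel.
Paternity shares are the normalized contributions, so the selfing
probability is the mother's own share of her cloud — it rises with her
absolute male allocation, and for a given relative allocation it is larger
for larger plants. Inbreeding depression is *not* applied here: selfed
seeds are recorded as selfed and discounted downstream in the fitness
accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthpop import PopulationConfig

__all__ = [
    "PollenCloud",
    "dispersal_weight",
    "build_pollen_cloud",
    "selfing_probability",
    "seed_set",
    "sample_sires",
    "simulate_mating",
    "mean_outcross_distance",
]


def dispersal_weight(distance_cm, lambda_cm: float, kernel: str = "exponential"):
    """Pollen dispersal kernel, normalized to 1 at distance zero.

    exponential: exp(-d / lambda); gaussian: exp(-(d / lambda)^2).
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if lambda_cm <= 0:
        raise ValueError("lambda_cm must be positive")
    if kernel == "exponential":
        return np.exp(-d / lambda_cm)
    if kernel == "gaussian":
        return np.exp(-((d / lambda_cm) ** 2))
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class PollenCloud:
    """Pollen contributions of every candidate sire at one mother's stigmas."""

    mother_id: str
    contributions: dict[str, float]

    def total(self) -> float:
        return float(sum(self.contributions.values()))


def build_pollen_cloud(
    mother_id: str,
    plants: pd.DataFrame,
    lambda_cm: float,
    kernel: str = "exponential",
    self_weight: float = 1.0,
) -> PollenCloud:
    """Pollen cloud at one mother under mass action.

    Contribution of plant j is NM_j * k(d_ij); the mother's own pollen
    competes at distance zero (k = 1), optionally scaled by ``self_weight``
    to represent within-canopy proximity effects.
    """
    row = plants.loc[plants["plant_id"] == mother_id]
    if row.empty:
        raise ValueError(f"mother {mother_id!r} not among plants")
    mx, my = float(row["x_cm"].iloc[0]), float(row["y_cm"].iloc[0])
    d = np.hypot(plants["x_cm"].to_numpy() - mx, plants["y_cm"].to_numpy() - my)
    w = plants["nm"].to_numpy(dtype=float) * dispersal_weight(d, lambda_cm, kernel)
    is_self = (plants["plant_id"] == mother_id).to_numpy()
    w[is_self] *= self_weight
    return PollenCloud(mother_id, dict(zip(plants["plant_id"], w)))


def selfing_probability(cloud: PollenCloud) -> float:
    """Mother's own share of her pollen cloud (mass-action selfing rate)."""
    total = cloud.total()
    if total <= 0:
        raise ValueError("no pollen available: all cloud contributions are zero")
    return cloud.contributions[cloud.mother_id] / total


def seed_set(
    nf,
    seeds_per_flower_mean: float,
    rng: np.random.Generator,
    dispersion: float = 5.0,
):
    """Mature seed count: negative binomial with mean NF * seeds_per_flower."""
    nf = np.atleast_1d(np.asarray(nf))
    if np.any(nf < 0):
        raise ValueError("NF must be non-negative")
    mean = nf * seeds_per_flower_mean
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def sample_sires(cloud: PollenCloud, n_seeds: int, rng: np.random.Generator) -> list[str]:
    """Draw sires for n_seeds ovules, multinomially by cloud contribution."""
    if n_seeds == 0:
        return []
    ids = list(cloud.contributions)
    w = np.array([cloud.contributions[i] for i in ids], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("no pollen available: cannot sire seeds from an empty cloud")
    idx = rng.choice(len(ids), size=n_seeds, p=w / total)
    return [ids[i] for i in idx]


def _cloud_matrix(plants: pd.DataFrame, cfg: PopulationConfig) -> np.ndarray:
    """(mothers x sires) pollen contribution matrix for one population."""
    xy = plants[["x_cm", "y_cm"]].to_numpy()
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    w = plants["nm"].to_numpy(dtype=float)[None, :] * dispersal_weight(
        d, cfg.lambda_cm, cfg.kernel
    )
    w[np.diag_indices_from(w)] *= cfg.self_weight
    return w


def expected_selfing(plants: pd.DataFrame, cfg: PopulationConfig) -> np.ndarray:
    """Analytic mass-action selfing probability of every plant's ovules."""
    w = _cloud_matrix(plants, cfg)
    total = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, np.diag(w) / total, np.nan)
    return s


def simulate_mating(
    plants: pd.DataFrame,
    cfg: PopulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate seed set and true paternity for every seed of one population.

    Returns (plants with an ``n_seeds`` column appended, seeds table with
    seed_id, mother_id, father_id, selfed). Ovule number is driven by NF
    alone (no pollen limitation): whenever any pollen weight is positive,
    all ovules are fertilized.
    """
    plants = plants.reset_index(drop=True).copy()
    n_seeds = seed_set(
        plants["nf"].to_numpy(), cfg.seeds_per_flower, rng, cfg.seed_set_dispersion
    )
    plants["n_seeds"] = n_seeds
    w = _cloud_matrix(plants, cfg)
    ids = plants["plant_id"].to_numpy()
    rows = []
    for i in range(len(plants)):
        k = int(n_seeds[i])
        if k == 0:
            continue
        wi = w[i]
        total = wi.sum()
        if total <= 0:
            # no pollen anywhere: ovules stay unfertilized
            plants.loc[i, "n_seeds"] = 0
            continue
        counts = rng.multinomial(k, wi / total)
        for j in np.nonzero(counts)[0]:
            rows.append((ids[i], ids[j], int(counts[j])))
    seed_rows = []
    counter = 0
    for mother, father, cnt in rows:
        for _ in range(cnt):
            counter += 1
            seed_rows.append(
                {
                    "seed_id": f"{mother}-s{counter:05d}",
                    "mother_id": mother,
                    "father_id": father,
                    "selfed": int(mother == father),
                }
            )
    seeds = pd.DataFrame(
        seed_rows, columns=["seed_id", "mother_id", "father_id", "selfed"]
    )
    return plants, seeds


def mean_outcross_distance(seeds: pd.DataFrame, plants: pd.DataFrame) -> float:
    """Realized mean mother-father distance among outcrossed seeds (cm)."""
    pos = plants.set_index("plant_id")[["x_cm", "y_cm"]]
    out = seeds[seeds["selfed"] == 0]
    if out.empty:
        return float("nan")
    pm = pos.loc[out["mother_id"]].to_numpy()
    pf = pos.loc[out["father_id"]].to_numpy()
    return float(np.hypot(*(pm - pf).T).mean())
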