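"""Synthetic experimental populations of a wind-pollinated monoecious herb.

Generates replicate common-garden populations laid out on hexagonal plots,
with log-normal biomass variation, a U-shaped gender distribution spanning
pure females (gender 0) to pure males (gender 1), and integer female/male
flower counts scattered around a concave size-dependent trade-off frontier.

The generator's defaults emulate the study conditions of the experimental
populations the analysis modules are built for: 61 plants per plot, mean
female and male flower production near 238 and 316, and seed production
near 106 seeds per plant once the mating module has run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GenderMixture",
    "PopulationConfig",
    "centered_hexagonal_numbers",
    "make_hexagonal_layout",
    "sample_sizes",
    "sample_gender",
    "flower_capacities",
    "allocate_flowers",
    "simulate_population",
]


def centered_hexagonal_numbers(k_max: int = 20) -> list[int]:
    """Return the centered hexagonal numbers 1, 7, 19, 37, 61, ... up to ring k_max."""
    return [3 * k * (k + 1) + 1 for k in range(k_max + 1)]


def make_hexagonal_layout(n_plants: int, spacing_cm: float) -> np.ndarray:
    """Coordinates (cm) of a filled hexagon of pots on a triangular lattice.

    Parameters
    ----------
    n_plants : int
        Must be a centered hexagonal number (1, 7, 19, 37, 61, ...); the
        plot is a hexagon of concentric rings around a central plant.
    spacing_cm : float
        Nearest-neighbour distance between pots.

    Returns
    -------
    ndarray of shape (n_plants, 2)
        x, y coordinates in cm, centre plant at the origin.
    """
    if spacing_cm <= 0:
        raise ValueError("spacing_cm must be positive")
    hexnums = centered_hexagonal_numbers(40)
    if n_plants not in hexnums:
        lower = max([h for h in hexnums if h < n_plants], default=1)
        upper = min(h for h in hexnums if h > n_plants)
        raise ValueError(
            f"n_plants={n_plants} is not a centered hexagonal number; "
            f"nearest valid counts are {lower} and {upper}"
        )
    rings = hexnums.index(n_plants)
    pts = []
    # axial hex coordinates (q, r) with cube distance <= rings
    for q in range(-rings, rings + 1):
        for r in range(max(-rings, -q - rings), min(rings, -q + rings) + 1):
            x = spacing_cm * (q + r / 2.0)
            y = spacing_cm * (np.sqrt(3.0) / 2.0) * r
            pts.append((x, y))
    coords = np.array(pts, dtype=float)
    assert coords.shape[0] == n_plants
    return coords


def sample_sizes(n: int, size_mean: float, size_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw plant sizes (log-transformed aboveground biomass) from a normal.

    Biomass is log-normal, so size = ln(biomass) is normal; ``size_sd = 0``
    degenerates to all plants at ``size_mean``.
    """
    if size_sd < 0:
        raise ValueError("size_sd must be non-negative")
    return rng.normal(size_mean, size_sd, size=n)


@dataclass
class GenderMixture:
    """Mixture describing the population's target gender (maleness) distribution.

    Point masses at 0 (pure female) and 1 (pure male) plus a Beta-distributed
    hermaphroditic component on (0, 1). The U-shaped default mirrors a
    population spanning the full gender continuum with excess mass at the
    unisexual extremes.
    """

    weight_female: float = 0.25
    weight_male: float = 0.15
    beta_a: float = 0.7
    beta_b: float = 0.7

    def __post_init__(self) -> None:
        w_cont = 1.0 - self.weight_female - self.weight_male
        if self.weight_female < 0 or self.weight_male < 0 or w_cont < -1e-12:
            raise ValueError("gender mixture weights must be non-negative and sum to <= 1")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def weight_continuous(self) -> float:
        return 1.0 - self.weight_female - self.weight_male


def sample_gender(n: int, mixture: GenderMixture, rng: np.random.Generator) -> np.ndarray:
    """Draw target gender values in [0, 1] from the three-part mixture."""
    u = rng.random(n)
    g = np.empty(n)
    is_f = u < mixture.weight_female
    is_m = (u >= mixture.weight_female) & (u < mixture.weight_female + mixture.weight_male)
    is_c = ~(is_f | is_m)
    g[is_f] = 0.0
    g[is_m] = 1.0
    g[is_c] = rng.beta(mixture.beta_a, mixture.beta_b, size=int(is_c.sum()))
    return g


@dataclass
class PopulationConfig:
    """Parameters of one synthetic replicate population.

    Flower capacities are power laws of biomass: with size s = ln(biomass),
    K_f(s) = kf_coef * exp(kf_exp * (s - size_mean)) and likewise K_m. The
    trade-off frontier is (NF/K_f)^gamma + (NM/K_m)^gamma = 1: gamma < 1
    gives a concave fitness set (mixed strategies fall below the linear
    chord, penalizing intermediate allocation, as in the study system),
    gamma = 1 a linear trade-off, gamma > 1 an outward-bowed frontier that
    advantages hermaphrodites; gamma may depend on size through
    ``gamma_size_slope``.
    Defaults are calibrated so population means of NF, NM and seed set are
    of the order observed in the experimental plots (~238, ~316, ~106).
    """

    n_plants: int = 61
    spacing_cm: float = 23.0
    size_mean: float = 3.0
    size_sd: float = 0.6
    gender_mixture: GenderMixture = field(default_factory=GenderMixture)
    kf_coef: float = 305.0
    kf_exp: float = 1.5
    km_coef: float = 500.0
    km_exp: float = 1.5
    tradeoff_gamma: float = 0.8
    gamma_size_slope: float = 0.0
    interference: float = 0.0
    nb_dispersion: float = 5.0
    # mating-stage parameters carried in the same config for convenience
    lambda_cm: float = 10.5
    kernel: str = "exponential"
    self_weight: float = 1.0
    seeds_per_flower: float = 0.45
    seed_set_dispersion: float = 5.0

    def __post_init__(self) -> None:
        if self.tradeoff_gamma <= 0:
            raise ValueError("tradeoff_gamma must be positive")
        if self.kf_coef <= 0 or self.km_coef <= 0:
            raise ValueError("flower capacities must be positive")

    def gamma_at(self, size: np.ndarray | float) -> np.ndarray | float:
        """Concavity exponent at a given size; floored at a small positive value."""
        g = self.tradeoff_gamma + self.gamma_size_slope * (np.asarray(size) - self.size_mean)
        return np.maximum(g, 0.1)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        gm = d.get("gender_mixture")
        if isinstance(gm, dict):
            d["gender_mixture"] = GenderMixture(**gm)
        return cls(**d)


def flower_capacities(size, cfg: PopulationConfig):
    """Per-plant female and male flower capacities K_f, K_m (power laws of biomass)."""
    size = np.asarray(size, dtype=float)
    kf = cfg.kf_coef * np.exp(cfg.kf_exp * (size - cfg.size_mean))
    km = cfg.km_coef * np.exp(cfg.km_exp * (size - cfg.size_mean))
    return kf, km


def _negbin(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial draw with given mean and shape (dispersion) parameter."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def allocate_flowers(size, gender_target, cfg: PopulationConfig, rng: np.random.Generator):
    """Draw integer flower counts (NF, NM) around the concave trade-off frontier.

    The expected allocation for target maleness m sits on the frontier:
    E[NF] = K_f * (1 - m)^(1/gamma), E[NM] = K_m * m^(1/gamma), so that
    (E[NF]/K_f)^gamma + (E[NM]/K_m)^gamma = 1. With gamma < 1 mixed
    strategies fall below the linear chord (a concave fitness set: flower
    production is less efficient for intermediate allocation, an economy
    of specialization); gamma = 1 recovers the linear trade-off and
    gamma > 1 bows the frontier outward. Counts are negative binomial
    around the expectation; pure strategies (m exactly 0 or 1) produce
    exact zeros on the other side.
    """
    size = np.atleast_1d(np.asarray(size, dtype=float))
    m = np.atleast_1d(np.asarray(gender_target, dtype=float))
    if np.any((m < 0) | (m > 1)):
        raise ValueError("gender_target must lie in [0, 1]")
    kf, km = flower_capacities(size, cfg)
    gamma = np.asarray(cfg.gamma_at(size), dtype=float)
    mean_f = kf * np.power(1.0 - m, 1.0 / gamma)
    mean_m = km * np.power(m, 1.0 / gamma)
    # sexual interference: male allocation suppresses female output more
    # strongly in larger plants, steepening their trade-off; vanishes at the
    # mean size and when interference = 0
    mean_f = mean_f * np.exp(-cfg.interference * (size - cfg.size_mean) * m)
    nf = _negbin(rng, mean_f, cfg.nb_dispersion)
    nm = _negbin(rng, mean_m, cfg.nb_dispersion)
    nf[m >= 1.0] = 0
    nm[m <= 0.0] = 0
    # a reproductive plant carries at least one flower of its dominant sex
    dead = (nf + nm) == 0
    if np.any(dead):
        nf[dead & (m < 0.5)] = 1
        nm[dead & (m >= 0.5)] = 1
    return nf, nm


def simulate_population(
    cfg: PopulationConfig,
    rng: np.random.Generator,
    population_id: str = "P1",
) -> pd.DataFrame:
    """Simulate one population: layout, sizes, genders, flower counts.

    Returns a plants table with columns plant_id, population_id, x_cm, y_cm,
    biomass_g, size_log, nf, nm. Seed counts are appended by the mating
    module.
    """
    coords = make_hexagonal_layout(cfg.n_plants, cfg.spacing_cm)
    size = sample_sizes(cfg.n_plants, cfg.size_mean, cfg.size_sd, rng)
    gtar = sample_gender(cfg.n_plants, cfg.gender_mixture, rng)
    nf, nm = allocate_flowers(size, gtar, cfg, rng)
    return pd.DataFrame(
        {
            "plant_id": [f"{population_id}-{i + 1:03d}" for i in range(cfg.n_plants)],
            "population_id": population_id,
            "x_cm": coords[:, 0],
            "y_cm": coords[:, 1],
            "biomass_g": np.exp(size),
            "size_log": size,
            "gender_target": gtar,
            "nf": nf,
            "nm": nm,
        }
    )
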