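"""Functional gender and female/male/total fitness accounting.

Functional gender expresses an individual's maleness on [0, 1] from its
flower counts, scaled by the population equivalence factor E (total male
flowers over total female flowers). Fitness is seed-based: female fitness
is the mature seed number discounted for the selfed fraction under an
inbreeding-depression scenario delta; male fitness credits each sire its
paternity share of every dam's seed crop, with selfed shares discounted
by the same delta. Selfed progeny thus contribute (1 - delta) once
through each sexual function, and total fitness is the sum of the two
components. Relative fitness divides by the population mean per scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "equivalence_factor",
    "gender",
    "add_gender",
    "female_fitness",
    "male_fitness",
    "total_and_relative",
    "compute_fitness",
]


def equivalence_factor(plants: pd.DataFrame) -> float:
    """E = total male flowers / total female flowers of one population."""
    nf_total = plants["nf"].sum()
    nm_total = plants["nm"].sum()
    if nf_total <= 0:
        raise ValueError("equivalence factor undefined: population has no female flowers")
    return float(nm_total / nf_total)


def gender(nf, nm, E: float):
    """Functional gender G = NM / (E * NF + NM), in [0, 1].

    G = 0 for a pure female (NM = 0), G = 1 for a pure male (NF = 0);
    NaN for a plant with no flowers at all. Note that scaling by E makes
    gender unit-free, but the arithmetic mean of G is not exactly 0.5 for
    every flower-count configuration.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    nf = np.asarray(nf, dtype=float)
    nm = np.asarray(nm, dtype=float)
    denom = E * nf + nm
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(denom > 0, nm / denom, np.nan)
    return g


def add_gender(plants: pd.DataFrame) -> pd.DataFrame:
    """Append equivalence-scaled gender per population to a plants table."""
    plants = plants.copy()
    plants["gender"] = np.nan
    for pop, sub in plants.groupby("population_id"):
        E = equivalence_factor(sub)
        plants.loc[sub.index, "gender"] = gender(sub["nf"], sub["nm"], E)
    return plants


def female_fitness(n_seeds, s, delta: float):
    """W_F = N_T * (S * (1 - delta) + (1 - S)).

    With delta = 0 female fitness is simply the mature seed count; with
    delta = 1 only the outcrossed fraction survives. S may be NaN (no
    assigned seeds), propagating NaN unless N_T = 0.
    """
    n_seeds = np.asarray(n_seeds, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any((s < -1e-12) | (s > 1 + 1e-12)):
        raise ValueError("selfing rate S must lie in [0, 1]")
    if not 0 <= delta <= 1:
        raise ValueError("delta must lie in [0, 1]")
    wf = n_seeds * (s * (1.0 - delta) + (1.0 - s))
    return np.where(n_seeds == 0, 0.0, wf)


def male_fitness(
    plants: pd.DataFrame,
    assignments: pd.DataFrame,
    delta: float,
) -> pd.Series:
    """W_M per plant: sum over dams of (sired share) x (dam's seed crop).

    The share of sire i on dam j is n_ij / N_G,j, where n_ij counts
    confidently assigned seeds and N_G,j is the dam's number of assigned
    seeds; the share is scaled by the dam's total mature seed count N_T,j.
    Self-sired shares (i = j) are discounted by (1 - delta).
    """
    conf = assignments[assignments["confident"]]
    n_t = plants.set_index("plant_id")["n_seeds"]
    wm = pd.Series(0.0, index=plants["plant_id"])
    if conf.empty:
        return wm
    counts = conf.groupby(["mother_id", "best_father_id"]).size()
    n_g = conf.groupby("mother_id").size()
    for (mother, father), n_ij in counts.items():
        if n_g[mother] <= 0:
            raise ValueError(f"dam {mother} has assigned seeds but N_G = 0")
        share = n_ij / n_g[mother] * float(n_t[mother])
        if father == mother:
            share *= 1.0 - delta
        wm[father] += share
    return wm


def total_and_relative(records: pd.DataFrame) -> pd.DataFrame:
    """Append W_T = W_F + W_M and mean-scaled relative fitness columns.

    Relative fitness divides each component by its mean over the plants of
    the same population and delta scenario with defined (non-NaN) values,
    so each relative component averages 1 within population x scenario.
    """
    records = records.copy()
    records["w_t_abs"] = records["w_f_abs"] + records["w_m_abs"]
    for col in ("w_f_abs", "w_m_abs", "w_t_abs"):
        rel = col.replace("_abs", "_rel")
        records[rel] = np.nan
        for (pop, d), sub in records.groupby(["population_id", "delta"]):
            mean = sub[col].mean()
            if not np.isfinite(mean) or mean <= 0:
                raise ValueError(
                    f"population {pop}, delta={d}: mean {col} is not positive"
                )
            records.loc[sub.index, rel] = sub[col] / mean
    return records


def compute_fitness(
    plants: pd.DataFrame,
    selfing: pd.DataFrame,
    assignments: pd.DataFrame,
    deltas=(0.0, 1.0),
) -> pd.DataFrame:
    """Per plant x scenario fitness table for one or more populations.

    ``plants`` must carry n_seeds and gender columns; ``selfing`` the
    per-mother s_hat estimates; ``assignments`` the confident paternity
    calls. Mothers with seeds but no assigned seed get NaN female fitness
    (their selfing rate is unknown) while still accruing male fitness.
    """
    s_map = selfing.set_index("mother_id")["s_hat"]
    frames = []
    for delta in deltas:
        rec = plants[["plant_id", "population_id", "n_seeds", "gender", "size_log"]].copy()
        rec["delta"] = float(delta)
        s = rec["plant_id"].map(s_map)
        rec["s_hat"] = s
        rec["w_f_abs"] = female_fitness(rec["n_seeds"], s.to_numpy(), float(delta))
        wm_parts = []
        for pop, sub in plants.groupby("population_id"):
            wm = male_fitness(
                sub,
                assignments[assignments["mother_id"].isin(sub["plant_id"])],
                float(delta),
            )
            wm_parts.append(wm)
        rec["w_m_abs"] = rec["plant_id"].map(pd.concat(wm_parts))
        frames.append(rec)
    out = pd.concat(frames, ignore_index=True)
    return total_and_relative(out)
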