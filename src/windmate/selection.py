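"""Regression models: flower trade-off, selfing, and selection gradients.

Three fits mirror the analysis stages of the study design this package
simulates:

* a (zero-inflated) negative-binomial regression of female flower number
  on standardized male flower number, plant size and their interaction
  (the sex-allocation trade-off);
* a beta-binomial regression of per-mother selfed seed counts on gender,
  size and their interaction (mother-level overdispersion replacing an
  observation-level random effect);
* weighted least-squares regressions of relative fitness (female, male or
  total) on linear and quadratic gender terms interacting with size and
  the inbreeding-depression scenario delta, with variance taken
  proportional to plant size (weights 1/size) and cluster-robust standard
  errors by plant (the two delta scenarios reuse the same individuals).

Marginal linear and quadratic gender coefficients at chosen size levels
and delta values are exact linear combinations of the fitted
coefficients, with delta-method standard errors from the coefficient
covariance, and are classified into selection regimes (disruptive,
stabilizing, directional, none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, special
import statsmodels.api as sm
from statsmodels.base.model import GenericLikelihoodModel

__all__ = [
    "SizeLevels",
    "fit_tradeoff",
    "fit_selfing",
    "fit_selection",
    "extract_gradients",
    "classify_regime",
    "TradeoffFit",
    "SelfingFit",
    "SelectionFit",
]


@dataclass
class SizeLevels:
    """Small / medium / large plant sizes: mean -/+ one SD of log biomass."""

    small: float
    medium: float
    large: float

    def __post_init__(self) -> None:
        if not self.small < self.medium < self.large:
            raise ValueError("size levels must satisfy small < medium < large")

    @classmethod
    def from_sizes(cls, sizes) -> "SizeLevels":
        sizes = np.asarray(sizes, dtype=float)
        m, sd = sizes.mean(), sizes.std(ddof=1)
        return cls(m - sd, m, m + sd)

    def as_dict(self) -> dict[str, float]:
        return {"small": self.small, "medium": self.medium, "large": self.large}


# ---------------------------------------------------------------------------
# trade-off model


@dataclass
class TradeoffFit:
    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    zero_inflated: bool
    nm_scale: dict
    pop_shares: dict
    diagnostics: str = ""

    def slope_at(self, size: float, scale: str = "response") -> tuple[float, float]:
        """Marginal trade-off slope at a plant size, with delta-method SE.

        ``scale='link'``: change in log E[NF] per SD of male flowers.
        ``scale='response'`` (default): change in expected female flower
        number per SD of male flowers, evaluated at the population-mean
        male flower number (NM_std = 0) and averaged over populations —
        the flowers-per-flower cost read off the fitted trade-off lines
        at a common male-allocation level.
        """
        c = pd.Series(0.0, index=self.params.index)
        c["nm_std"] = 1.0
        if "nm_std:size" in c.index:
            c["nm_std:size"] = size
        if scale == "link":
            est = float(c @ self.params)
            se = float(np.sqrt(c @ self.cov @ c))
            return est, se
        x0 = pd.Series(0.0, index=self.params.index)
        x0["const"] = 1.0
        if "size" in x0.index:
            x0["size"] = size
        for name, share in self.pop_shares.items():
            if name in x0.index:
                x0[name] = share
        mu = float(np.exp(x0 @ self.params))
        lin = float(c @ self.params)
        est = mu * lin
        grad = mu * (x0 * lin + c)
        se = float(np.sqrt(grad @ self.cov @ grad))
        return est, se


def _pop_dummies(df: pd.DataFrame) -> pd.DataFrame:
    pops = sorted(df["population_id"].unique())
    out = pd.DataFrame(index=df.index)
    for p in pops[1:]:
        out[f"pop[{p}]"] = (df["population_id"] == p).astype(float)
    return out


def fit_tradeoff(plants: pd.DataFrame, zero_inflation: bool = True) -> TradeoffFit:
    """Count regression of female on standardized male flower number.

    NM is standardized to mean 0, SD 1 within each population. The
    response NF is negative binomial with an optional zero-inflation
    component (intercept only); non-convergence of the zero-inflated fit
    falls back to the plain negative binomial, flagged in the result.
    """
    if len(plants) < 30:
        raise ValueError("trade-off fit needs at least 30 plants")
    df = plants.copy()
    scale = {}
    df["nm_std"] = 0.0
    for pop, sub in df.groupby("population_id"):
        mu, sd = sub["nm"].mean(), sub["nm"].std(ddof=1)
        scale[pop] = (float(mu), float(sd))
        df.loc[sub.index, "nm_std"] = (sub["nm"] - mu) / sd
    X = pd.DataFrame(
        {
            "const": 1.0,
            "nm_std": df["nm_std"],
            "size": df["size_log"],
            "nm_std:size": df["nm_std"] * df["size_log"],
        }
    )
    X = pd.concat([X, _pop_dummies(df)], axis=1)
    y = df["nf"].to_numpy()

    names = list(X.columns)
    k = len(names)
    pop_shares = {c: float(X[c].mean()) for c in X.columns if c.startswith("pop[")}

    if zero_inflation:
        from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nb0 = sm.NegativeBinomial(y, X.to_numpy()).fit(disp=0, maxiter=200)
                start = np.concatenate([[-1.5], np.asarray(nb0.params)])
                zi_model = ZeroInflatedNegativeBinomialP(
                    y, X.to_numpy(), exog_infl=np.ones((len(y), 1)), p=2
                )
                res = zi_model.fit(start_params=start, method="bfgs", maxiter=1000, disp=0)
            cov_all = np.asarray(res.cov_params())
            if res.mle_retvals.get("converged", False) and np.all(np.isfinite(cov_all)):
                # param order: [inflate const, count coefficients..., alpha]
                params = pd.Series(np.asarray(res.params)[1 : 1 + k], index=names)
                cov = pd.DataFrame(cov_all[1 : 1 + k, 1 : 1 + k], index=names, columns=names)
                return TradeoffFit(params, cov, True, True, scale, pop_shares)
            note = "zero-inflated fit did not converge; plain negative binomial used"
        except Exception as exc:  # noqa: BLE001 - fit failure is data-dependent
            note = f"zero-inflated fit failed ({exc}); plain negative binomial used"
    else:
        note = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = sm.NegativeBinomial(y, X.to_numpy()).fit(disp=0, maxiter=200)
            cov_nb = np.asarray(nb.cov_params())
        if not np.all(np.isfinite(cov_nb)):
            raise ValueError("non-finite covariance")
        converged = bool(nb.mle_retvals.get("converged", True))
        return TradeoffFit(
            pd.Series(np.asarray(nb.params)[:k], index=names),
            pd.DataFrame(cov_nb[:k, :k], index=names, columns=names),
            converged,
            False,
            scale,
            pop_shares,
            note,
        )
    except Exception as exc:  # noqa: BLE001
        note = (note + "; " if note else "") + (
            f"NB maximum likelihood failed ({exc}); GLM quasi-NB used"
        )
    # last resort: NB GLM with fixed shape and Pearson-scaled covariance
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X.to_numpy(), family=sm.families.NegativeBinomial(alpha=1.0)).fit(
            scale="X2"
        )
    return TradeoffFit(
        pd.Series(np.asarray(glm.params), index=names),
        pd.DataFrame(np.asarray(glm.cov_params()), index=names, columns=names),
        True,
        False,
        scale,
        pop_shares,
        note,
    )


# ---------------------------------------------------------------------------
# selfing model (beta-binomial)


class _BetaBinomial(GenericLikelihoodModel):
    """Beta-binomial regression: logit-linear mean, common dispersion."""

    def __init__(self, counts, totals, exog, xnames, **kwargs):
        self._counts = np.asarray(counts, dtype=int)
        self._totals = np.asarray(totals, dtype=int)
        super().__init__(endog=self._counts, exog=np.asarray(exog), **kwargs)
        self.data.xnames = list(xnames) + ["log_theta"]
        self.k_extra = 1

    def loglike(self, params):
        beta = params[:-1]
        theta = np.exp(np.clip(params[-1], -20, 20))
        p = special.expit(self.exog @ beta)
        p = np.clip(p, 1e-10, 1 - 1e-10)
        a = p * theta
        b = (1 - p) * theta
        return float(stats.betabinom.logpmf(self._counts, self._totals, a, b).sum())


@dataclass
class SelfingFit:
    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    degenerate: bool
    message: str = ""

    def slope_at(self, size: float) -> tuple[float, float]:
        """Marginal logit-scale slope of selfing on gender at a given size."""
        if self.degenerate:
            raise ValueError(f"selfing fit degenerate: {self.message}")
        c = pd.Series(0.0, index=self.params.index)
        c["gender"] = 1.0
        c["gender:size"] = size
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov @ c))
        return est, se


def fit_selfing(selfing: pd.DataFrame, plants: pd.DataFrame) -> SelfingFit:
    """Beta-binomial fit of per-mother selfed counts on gender x size.

    ``selfing`` carries mother_id, n_assigned, n_selfed; gender, size and
    population come from the plants table. All-outcrossed (or
    all-selfed) data cannot identify the gender effect and returns a
    result flagged degenerate rather than raising inside the optimizer.
    """
    df = selfing.merge(
        plants[["plant_id", "population_id", "gender", "size_log"]],
        left_on="mother_id",
        right_on="plant_id",
        how="inner",
    )
    if df["n_assigned"].sum() < 2:
        return SelfingFit(pd.Series(dtype=float), pd.DataFrame(), False, True, "too few seeds")
    k = df["n_selfed"].to_numpy()
    n = df["n_assigned"].to_numpy()
    if k.sum() == 0 or (n - k).sum() == 0:
        return SelfingFit(
            pd.Series(dtype=float),
            pd.DataFrame(),
            False,
            True,
            "all seeds outcrossed or all selfed: gender slope unidentified",
        )
    X = pd.DataFrame(
        {
            "const": 1.0,
            "gender": df["gender"],
            "size": df["size_log"],
            "gender:size": df["gender"] * df["size_log"],
        }
    )
    X = pd.concat([X, _pop_dummies(df)], axis=1)
    # logistic GLM start values stabilize the beta-binomial optimizer
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(
            np.column_stack([k, n - k]), X.to_numpy(), family=sm.families.Binomial()
        ).fit()
        start = np.append(glm.params, 1.0)
        model = _BetaBinomial(k, n, X.to_numpy(), X.columns)
        res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
    names = list(X.columns) + ["log_theta"]
    cov = np.asarray(res.cov_params())
    converged = bool(res.mle_retvals.get("converged", True)) and np.all(np.isfinite(cov))
    if not np.all(np.isfinite(cov)):
        # fall back to the GLM covariance scaled by Pearson dispersion
        disp = glm.pearson_chi2 / glm.df_resid
        cov = np.zeros((len(names), len(names)))
        cov[:-1, :-1] = np.asarray(glm.cov_params()) * disp
        res_params = np.append(np.asarray(glm.params), 1.0)
    else:
        res_params = np.asarray(res.params)
    return SelfingFit(
        pd.Series(res_params, index=names),
        pd.DataFrame(cov, index=names, columns=names),
        converged,
        False,
    )


# ---------------------------------------------------------------------------
# selection-gradient model


def _selection_design(df: pd.DataFrame, pop_interactions: bool) -> pd.DataFrame:
    g = df["gender"].to_numpy(dtype=float)
    g2 = g * g
    s = df["size_log"].to_numpy(dtype=float)
    d = df["delta"].to_numpy(dtype=float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "G": g,
            "G2": g2,
            "size": s,
            "delta": d,
            "G:size": g * s,
            "G:delta": g * d,
            "G2:size": g2 * s,
            "G2:delta": g2 * d,
            "size:delta": s * d,
            "G:size:delta": g * s * d,
            "G2:size:delta": g2 * s * d,
        },
        index=df.index,
    )
    pops = _pop_dummies(df)
    X = pd.concat([X, pops], axis=1)
    if pop_interactions:
        for col in pops.columns:
            X[f"G:{col}"] = X["G"] * pops[col]
            X[f"G2:{col}"] = X["G2"] * pops[col]
    return X


@dataclass
class SelectionFit:
    component: str
    params: pd.Series
    cov: pd.DataFrame
    nobs: int
    weights_note: str
    pop_interactions: bool
    flags: list[str] = field(default_factory=list)
    weights: np.ndarray | None = field(default=None, repr=False)

    def _contrast(self, kind: str, size: float, delta: float) -> pd.Series:
        base = "G" if kind == "linear" else "G2"
        c = pd.Series(0.0, index=self.params.index)
        c[base] = 1.0
        for name, w in (
            (f"{base}:size", size),
            (f"{base}:delta", delta),
            (f"{base}:size:delta", size * delta),
        ):
            if name in c.index:
                c[name] = w
        return c

    def gradient(self, kind: str, size: float, delta: float) -> tuple[float, float]:
        """Marginal gender coefficient (linear or quadratic) and its SE."""
        c = self._contrast(kind, size, delta)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov @ c))
        return est, se

    def contrast_between_deltas(
        self, kind: str, size: float, delta_a: float, delta_b: float
    ) -> tuple[float, float, float]:
        """Difference of a marginal coefficient between two delta scenarios."""
        c = self._contrast(kind, size, delta_b) - self._contrast(kind, size, delta_a)
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov @ c))
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
        return est, se, float(p)


_COMPONENT_COLS = {"female": "w_f_rel", "male": "w_m_rel", "total": "w_t_rel"}


def fit_selection(
    fitness: pd.DataFrame,
    component: str = "total",
    pop_interactions: str = "auto",
    size_shift_floor: float = 0.5,
    weight_scale: float = 1.0,
    weights=None,
) -> SelectionFit:
    """Weighted regression of relative fitness on gender, size and delta.

    Residual variance is modelled proportional to plant size, i.e. weights
    1/size with size shifted to stay positive; standard errors are
    cluster-robust by plant (each plant contributes one row per delta
    scenario). ``pop_interactions`` in {'auto', 'always', 'never'}: 'auto'
    fits population x gender interactions and drops them when their joint
    Wald test is non-significant (alpha 0.05), mirroring a
    simplify-when-justified strategy.
    """
    col = _COMPONENT_COLS[component]
    df = fitness.dropna(subset=[col, "gender"]).copy()
    if df.empty:
        raise ValueError("no usable fitness records")
    if weights is not None:
        w = weight_scale * np.asarray(weights, dtype=float)
        note = "caller-supplied weights"
    else:
        size = df["size_log"].to_numpy(dtype=float)
        shift = 0.0
        if size.min() <= 0:
            shift = size_shift_floor - size.min()
        w = weight_scale / (size + shift)
        note = f"weights {weight_scale:g}/(size + {shift:.3g})"
    flags: list[str] = []

    multi_pop = df["population_id"].nunique() > 1

    def _fit(pop_int: bool):
        X = _selection_design(df, pop_int)
        groups = df["plant_id"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.WLS(df[col].to_numpy(), X.to_numpy(), weights=w).fit(
                cov_type="cluster", cov_kwds={"groups": groups}
            )
        params = pd.Series(np.asarray(res.params), index=X.columns)
        cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
        return res, params, cov, X

    use_int = pop_interactions == "always" and multi_pop
    if pop_interactions == "auto" and multi_pop:
        res, params, cov, X = _fit(True)
        int_cols = [c for c in X.columns if (":pop[" in c)]
        R = np.zeros((len(int_cols), len(X.columns)))
        for i, c in enumerate(int_cols):
            R[i, list(X.columns).index(c)] = 1.0
        try:
            wt = res.wald_test(R, scalar=True)
            if float(wt.pvalue) < 0.05:
                use_int = True
        except Exception:  # singular restriction: keep the simpler model
            flags.append("population-interaction Wald test failed; interactions dropped")
    res, params, cov, X = _fit(use_int)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        flags.append("singular design matrix")
    return SelectionFit(component, params, cov, len(df), note, use_int, flags, w)


def classify_regime(
    linear: float,
    se_linear: float,
    quad: float,
    se_quad: float,
    alpha: float = 0.05,
) -> str:
    """Selection regime from marginal coefficients and their SEs.

    disruptive: significantly positive quadratic term (fitness minimized
    at intermediate gender); stabilizing: significantly negative
    quadratic; directional: only the linear term significant; none
    otherwise. Wald z-tests at level alpha.
    """
    for v in (linear, se_linear, quad, se_quad):
        if not np.isfinite(v):
            raise ValueError("classify_regime requires finite inputs")
    p_quad = 2 * stats.norm.sf(abs(quad) / se_quad) if se_quad > 0 else 1.0
    p_lin = 2 * stats.norm.sf(abs(linear) / se_linear) if se_linear > 0 else 1.0
    if quad > 0 and p_quad < alpha:
        return "disruptive"
    if quad < 0 and p_quad < alpha:
        return "stabilizing"
    if p_lin < alpha:
        return "directional"
    return "none"


def extract_gradients(
    fit: SelectionFit,
    size_levels: SizeLevels,
    deltas=(0.0, 1.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Marginal gender coefficients per size level and delta scenario.

    One row per (size level, delta): linear and quadratic coefficients,
    delta-method SEs, Wald p-values, regime classification, and (when two
    or more scenarios are given) the p-value of the contrast between the
    first and last delta at the same size level.
    """
    deltas = list(deltas)
    rows = []
    for level_name, s in size_levels.as_dict().items():
        contrast = (np.nan, np.nan, np.nan)
        contrast_q = (np.nan, np.nan, np.nan)
        if len(deltas) >= 2:
            contrast = fit.contrast_between_deltas("linear", s, deltas[0], deltas[-1])
            contrast_q = fit.contrast_between_deltas("quad", s, deltas[0], deltas[-1])
        for d in deltas:
            lin, lin_se = fit.gradient("linear", s, d)
            quad, quad_se = fit.gradient("quad", s, d)
            p_lin = 2 * stats.norm.sf(abs(lin) / lin_se) if lin_se > 0 else np.nan
            p_quad = 2 * stats.norm.sf(abs(quad) / quad_se) if quad_se > 0 else np.nan
            rows.append(
                {
                    "fitness_component": fit.component,
                    "delta": d,
                    "size_level": level_name,
                    "size": s,
                    "linear_coef": lin,
                    "linear_se": lin_se,
                    "p_linear": p_lin,
                    "quad_coef": quad,
                    "quad_se": quad_se,
                    "p_quad": p_quad,
                    "regime": classify_regime(lin, lin_se, quad, quad_se, alpha),
                    "linear_contrast_p": contrast[2],
                    "quad_contrast_p": contrast_q[2],
                }
            )
    return pd.DataFrame(rows)
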