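"""Vigor scores, dyadic vigor, variance decomposition and the dyadic LMM.

Vigor quantifies how fast an individual (or a coupled dyad) moves relative
to the population.  From per-target movement durations T_i(A_k) and the
population means Tbar(A_k),

    v_i = sum_k Tbar(A_k)^2 / sum_k T_i(A_k) Tbar(A_k),

so a participant pacing exactly with the population has v = 1 and moving
twice as slowly gives v = 0.5.  Dyadic vigor applies the same score to the
per-target mean of the two partners' durations.  A one-way sum-of-squares
decomposition splits vigor (or duration) variance into inter- and
intra-entity parts, and a linear mixed model with a random intercept per
dyad regresses dyadic vigor on the two partners' solo vigors per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VigorScore", "VarianceDecomposition", "DyadicVigorModel",
    "vigor_score", "dyadic_vigor", "variance_decomposition",
    "fit_dyadic_vigor_lmm", "weighted_adaptation_prediction",
]


@dataclass(frozen=True)
class VigorScore:
    entity_id: str
    condition: str
    v: float

    def __post_init__(self):
        if not self.v > 0:
            raise ValueError("vigor must be positive")


@dataclass(frozen=True)
class VarianceDecomposition:
    ss_inter: float
    ss_intra: float
    pct_inter: float
    degenerate: bool = False


@dataclass
class DyadicVigorModel:
    """Per-condition fast/slow coefficients of the dyadic-vigor LMM."""

    coefficients: pd.DataFrame     # condition, predictor, estimate, se, p, p_holm
    with_intercept: bool
    converged: bool
    non_identifiable: bool = False
    details: dict = field(default_factory=dict)

    def gamma(self, condition: str, predictor: str) -> float:
        df = self.coefficients
        row = df[(df.condition == condition) & (df.predictor == predictor)]
        return float(row["estimate"].iloc[0])


def _as_duration_arrays(T_entity, T_bar):
    a = np.asarray(T_entity, float)
    b = np.asarray(T_bar, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("duration vectors must be 1-D and cover the same targets")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("durations must be positive")
    return a, b


def vigor_score(T_entity, T_bar, entity_id: str = "", condition: str = "") -> VigorScore:
    """Vigor of one entity against the population mean durations."""
    a, b = _as_duration_arrays(T_entity, T_bar)
    v = float(np.sum(b ** 2) / np.sum(a * b))
    return VigorScore(entity_id=entity_id, condition=condition, v=v)


def dyadic_vigor(T_f, T_s, T_bar, entity_id: str = "", condition: str = "") -> VigorScore:
    """Vigor of a coupled pair from the partners' per-target mean durations."""
    f = np.asarray(T_f, float)
    s = np.asarray(T_s, float)
    if f.shape != s.shape:
        raise ValueError("partner duration vectors must cover the same targets")
    return vigor_score(0.5 * (f + s), T_bar, entity_id=entity_id, condition=condition)


def weighted_adaptation_prediction(v_f, v_s, alpha: float):
    """Convex combination v_d = alpha v_f + (1 - alpha) v_s."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * np.asarray(v_f, float) + (1.0 - alpha) * np.asarray(v_s, float)


def variance_decomposition(values: pd.DataFrame, value_col: str = "value",
                           entity_col: str = "entity") -> VarianceDecomposition:
    """One-way sum-of-squares split of a metric by entity across conditions.

    ``ss_inter`` accumulates entity-mean deviations about the grand mean
    (weighted by entity counts); ``ss_intra`` is the residual within-entity
    sum of squares.  With no variance at all the split is reported as 0%
    with a degeneracy flag rather than NaN.
    """
    if values[entity_col].nunique() < 2:
        raise ValueError("need at least two entities")
    x = values[value_col].to_numpy(float)
    grand = x.mean()
    ss_inter = 0.0
    ss_intra = 0.0
    for _, grp in values.groupby(entity_col):
        g = grp[value_col].to_numpy(float)
        ss_inter += len(g) * (g.mean() - grand) ** 2
        ss_intra += float(np.sum((g - g.mean()) ** 2))
    total = ss_inter + ss_intra
    if total <= 0:
        return VarianceDecomposition(0.0, 0.0, 0.0, degenerate=True)
    return VarianceDecomposition(ss_inter, ss_intra, 100.0 * ss_inter / total)


def fit_dyadic_vigor_lmm(table: pd.DataFrame, with_intercept: bool = False,
                         holm_scope: str = "per_predictor") -> DyadicVigorModel:
    """Regress dyadic vigor on the partners' solo vigors, per condition.

    ``table`` needs columns (dyad, condition, v_d, v_f, v_s) with one row per
    dyad x condition.  A single mixed model is fitted by maximum likelihood
    with condition-specific fixed effects for v_f and v_s and a random
    intercept per dyad; Bonferroni-Holm adjusts the per-condition p-values
    (per predictor by default, or across all coefficients with
    ``holm_scope='all'``).  Collinear predictors (v_f identical to v_s) are
    reported as non-identifiable.
    """
    req = {"dyad", "condition", "v_d", "v_f", "v_s"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    if table["dyad"].nunique() < 5:
        raise ValueError("need at least five dyads")
    non_ident = bool(np.allclose(table["v_f"], table["v_s"]))
    if non_ident:
        warnings.warn("v_f and v_s are collinear; coefficients are not identifiable")
        coefs = pd.DataFrame([
            {"condition": c, "predictor": p, "estimate": np.nan,
             "se": np.nan, "p": np.nan, "p_holm": np.nan}
            for c in sorted(table["condition"].unique())
            for p in ("v_f", "v_s")])
        return DyadicVigorModel(coefficients=coefs, with_intercept=with_intercept,
                                converged=False, non_identifiable=True)
    base = "1" if with_intercept else "0"
    formula = f"v_d ~ {base} + C(condition):v_f + C(condition):v_s"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=table, groups=table["dyad"])
        fit = model.fit(reml=False)
    rows = []
    for name, est in fit.fe_params.items():
        if ":v_f" in name or ":v_s" in name:
            cond = name.split("[")[1].split("]")[0].lstrip("T.")
            pred = "v_f" if name.endswith("v_f") else "v_s"
            rows.append({
                "condition": cond, "predictor": pred, "estimate": float(est),
                "se": float(fit.bse[name]), "p": float(fit.pvalues[name]),
            })
    coefs = pd.DataFrame(rows)
    coefs["p_holm"] = np.nan
    if holm_scope == "all":
        coefs["p_holm"] = multipletests(coefs["p"], method="holm")[1]
    else:
        for pred in ("v_f", "v_s"):
            m = coefs.predictor == pred
            coefs.loc[m, "p_holm"] = multipletests(coefs.loc[m, "p"], method="holm")[1]
    return DyadicVigorModel(
        coefficients=coefs, with_intercept=with_intercept,
        converged=bool(getattr(fit, "converged", True)),
        non_identifiable=non_ident,
        details={"llf": float(fit.llf), "n_obs": int(fit.nobs)},
    )
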