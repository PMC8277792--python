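"""Trait models: general linear models of shift statistics on species traits.

Each response (median altitude, z_alt, z_range, z_VMR, z_skew) is modelled on
the three categorical traits — dispersal ability (sedentary/intermediate/
mobile), specialisation (euryocy: generalist/specialist) and endangerment
(threatened/least_concern) — with median altitude as a continuous covariate.
Effect sizes are partial eta^2 = SS_effect / (SS_effect + SS_error) from
Type II sums of squares (main effects only, no interactions), with the
parametric F-test p-value per predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

TRAIT_COLUMNS = ("dispersal", "euryocy", "endangerment")
REFERENCE_LEVELS = {
    "dispersal": "sedentary",
    "euryocy": "specialist",
    "endangerment": "threatened",
}


@dataclass
class GLMResult:
    """Per-predictor df, partial eta^2 and P(F), plus the model r^2."""

    response: str
    table: pd.DataFrame      # index = predictor; columns df, partial_eta2, p
    r2: float
    model: object = None


def _term(trait: str) -> str:
    ref = REFERENCE_LEVELS[trait]
    return f"C({trait}, Treatment(reference='{ref}'))"


def fit_trait_glm(
    data: pd.DataFrame,
    response: str,
    covariate: str | None = "median_alt",
) -> GLMResult:
    """Fit the trait GLM for one response and return Type II effect sizes.

    ``data`` needs one row per species with the response, the trait columns
    and the covariate.  Traits constant across species are aliased and
    dropped with a warning.  Rows with a missing response are excluded.
    """
    df = data.dropna(subset=[response]).copy()
    if len(df) < 10:
        raise ValueError("need at least 10 species with data")
    terms = []
    for trait in TRAIT_COLUMNS:
        if trait not in df.columns:
            continue
        if df[trait].nunique() < 2:
            warnings.warn(f"trait {trait!r} is constant; dropped from the model")
            continue
        if df[trait].value_counts().min() < 2:
            warnings.warn(f"trait {trait!r} has a singleton level")
        terms.append(_term(trait))
    if covariate is not None and covariate != response:
        terms.append(covariate)
    if not terms:
        raise ValueError("no usable predictors")
    formula = f"{response} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    ss_err = anova.loc["Residual", "sum_sq"]
    rows = []
    label_map = {_term(t): t for t in TRAIT_COLUMNS}
    for term in anova.index:
        if term == "Residual":
            continue
        ss = anova.loc[term, "sum_sq"]
        rows.append(
            {
                "predictor": label_map.get(term, term),
                "df": int(anova.loc[term, "df"]),
                "partial_eta2": float(ss / (ss + ss_err)),
                "p": float(anova.loc[term, "PR(>F)"]),
            }
        )
    table = pd.DataFrame(rows).set_index("predictor")
    return GLMResult(response=response, table=table, r2=float(fit.rsquared), model=fit)


def marginal_means(result: GLMResult, data: pd.DataFrame, trait: str) -> pd.Series:
    """Estimated marginal mean response per trait level (G-computation).

    Each level's mean is the average model prediction over the full species
    table with that trait set to the level — other predictors keep their
    observed joint distribution.
    """
    fit = result.model
    df = data.dropna(subset=[result.response])
    out = {}
    for level in sorted(df[trait].unique()):
        counterfactual = df.copy()
        counterfactual[trait] = level
        out[level] = float(fit.predict(counterfactual).mean())
    return pd.Series(out, name=result.response)


def ols_relation(x, y) -> tuple[float, float, float]:
    """OLS slope, r^2 and two-sided p of one per-species value on another."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x[ok]) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x[ok], y[ok])
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def trait_table(glm_results: list[GLMResult]) -> pd.DataFrame:
    """Wide table: rows = predictors, (partial eta^2, p) column pair per response."""
    if not glm_results:
        return pd.DataFrame()
    pieces = {}
    for res in glm_results:
        pieces[(res.response, "partial_eta2")] = res.table["partial_eta2"]
        pieces[(res.response, "p")] = res.table["p"]
    wide = pd.DataFrame(pieces)
    wide.loc["r2"] = np.nan
    for res in glm_results:
        wide.loc["r2", (res.response, "partial_eta2")] = res.r2
    return wide
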