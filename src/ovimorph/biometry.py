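"""Biometric layer: descriptive statistics, correlation, ANOVA and the
body-weight regressions.

Works on a *trait table*: one row per animal with ``animal_id``, ``sex``
(``male``/``female``), body weight ``BW`` (kg) and the eight body-size
traits (cm).  Weight prediction uses ordinary least squares and
bidirectional stepwise selection (forward entry by partial-F p-value with
backward removal of variables rendered non-significant), and a set of
published sex-specific reference equations is shipped for direct use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TRAITS",
    "REFERENCE_SUMMARY",
    "PUBLISHED_EQUATIONS",
    "RegressionModel",
    "filter_complete",
    "describe",
    "spearman",
    "significance_stars",
    "anova_by_sex",
    "ols_fit",
    "stepwise",
    "predict_weight",
]

TRAITS = ("BSL", "HW", "CD", "HH", "SW", "RW", "CC", "SC")

#: Published sex-stratified reference summary (mean, SD, max, min, n) of the
#: 332-head Ujumqin sheep survey that anchors the synthetic generator.
REFERENCE_SUMMARY = pd.DataFrame(
    [
        # trait, sex, mean, sd, max, min, n
        ("BW", "male", 54.09, 9.36, 77.0, 36.0, 113),
        ("BW", "female", 46.06, 9.85, 71.0, 24.1, 219),
        ("BW", "overall", 48.83, 10.41, 77.0, 24.1, 332),
        ("BSL", "male", 72.56, 4.40, 83.0, 60.0, 113),
        ("BSL", "female", 67.50, 5.14, 81.0, 54.0, 219),
        ("BSL", "overall", 69.22, 5.45, 83.0, 54.0, 332),
        ("HW", "male", 69.29, 3.85, 79.0, 59.0, 113),
        ("HW", "female", 63.70, 4.15, 74.0, 51.0, 219),
        ("HW", "overall", 65.63, 4.83, 79.0, 51.0, 332),
        ("CD", "male", 30.90, 2.68, 39.5, 25.0, 113),
        ("CD", "female", 29.18, 4.03, 39.0, 19.0, 219),
        ("CD", "overall", 29.81, 3.75, 39.5, 19.0, 332),
        ("HH", "male", 69.84, 3.71, 81.0, 61.0, 113),
        ("HH", "female", 66.33, 4.08, 74.0, 55.0, 219),
        ("HH", "overall", 67.55, 4.29, 81.0, 55.0, 332),
        ("SW", "male", 20.61, 2.48, 27.0, 15.0, 113),
        ("SW", "female", 20.21, 2.66, 27.0, 13.0, 219),
        ("SW", "overall", 20.37, 2.61, 27.0, 13.0, 332),
        ("RW", "male", 22.74, 2.81, 29.0, 18.0, 113),
        ("RW", "female", 22.12, 2.65, 28.0, 15.0, 219),
        ("RW", "overall", 22.34, 2.72, 29.0, 15.0, 332),
        ("CC", "male", 95.88, 7.84, 116.0, 80.0, 113),
        ("CC", "female", 101.31, 9.85, 125.0, 72.0, 219),
        ("CC", "overall", 99.47, 9.56, 125.0, 72.0, 332),
        ("SC", "male", 9.04, 0.84, 10.6, 6.5, 113),
        ("SC", "female", 9.01, 0.73, 11.2, 6.5, 219),
        ("SC", "overall", 9.03, 0.77, 11.2, 6.5, 332),
    ],
    columns=["trait", "sex", "mean", "sd", "max", "min", "n"],
)


@dataclass
class RegressionModel:
    """A fitted (or published) linear weight-prediction equation."""

    intercept: float
    coefficients: dict[str, float]
    se_estimate: float | None = None  # std. error of the estimate, kg
    r_squared: float | None = None
    adj_r_squared: float | None = None
    mse: float | None = None  # residual mean square, kg^2
    p_value: float | None = None  # overall F-test
    coef_pvalues: dict[str, float] = field(default_factory=dict)
    n: int | None = None
    notes: str = ""

    def predict(self, traits) -> float:
        row = traits if isinstance(traits, dict) else dict(traits)
        missing = [k for k in self.coefficients if k not in row or pd.isna(row[k])]
        if missing:
            raise ValueError(f"missing predictor(s): {', '.join(missing)}")
        return float(
            self.intercept
            + sum(c * float(row[k]) for k, c in self.coefficients.items())
        )

    def equation(self, response: str = "BW") -> str:
        terms = "".join(
            f" {'+' if c >= 0 else '-'} {abs(c):.2f}{k}"
            for k, c in self.coefficients.items()
        )
        return f"{response} = {self.intercept:.2f}{terms}"


def _published(intercept, coefs, se, r2, adj, mse, notes=""):
    return RegressionModel(
        intercept=intercept,
        coefficients=coefs,
        se_estimate=se,
        r_squared=r2,
        adj_r_squared=adj,
        mse=mse,
        p_value=0.001,  # reported only as < 0.001
        notes=notes,
    )


#: The published stepwise model sequences for ewes (3 steps) and rams
#: (6 steps).  The ram 5-variable row is labelled "... and HW" in the source
#: table while its printed equation uses SW; the printed equation is kept.
PUBLISHED_EQUATIONS: dict[str, RegressionModel] = {
    "ewe-1": _published(-53.71, {"BSL": 1.48}, 6.35, 0.589, 0.587, 40.357),
    "ewe-2": _published(-70.75, {"BSL": 1.05, "CC": 0.45}, 5.03, 0.744, 0.742, 25.276),
    "ewe-3": _published(
        -92.49, {"BSL": 0.82, "CC": 0.33, "HH": 0.75}, 4.49, 0.797, 0.794, 20.173
    ),
    "ram-1": _published(-39.21, {"CC": 0.97}, 5.48, 0.664, 0.661, 29.985),
    "ram-2": _published(-75.74, {"CC": 0.79, "BSL": 0.75}, 4.62, 0.763, 0.759, 21.318),
    "ram-3": _published(
        -65.74, {"CC": 0.51, "BSL": 0.63, "RW": 1.13}, 4.19, 0.807, 0.801, 17.556
    ),
    "ram-4": _published(
        -79.42,
        {"CC": 0.41, "BSL": 0.52, "RW": 0.96, "HH": 0.49},
        4.05, 0.821, 0.815, 16.377,
    ),
    "ram-5": _published(
        -74.30,
        {"CC": 0.44, "BSL": 0.66, "RW": 0.88, "HH": 0.78, "SW": -0.52},
        3.83, 0.842, 0.834, 14.648,
        notes="source row label says HW; printed equation uses SW",
    ),
    "ram-6": _published(
        -76.96,
        {"CC": 0.44, "BSL": 0.70, "RW": 1.29, "HH": 0.76, "HW": -0.46, "SW": -0.64},
        3.75, 0.849, 0.841, 14.087,
    ),
}


# ---------------------------------------------------------------------------
# completeness filtering


def filter_complete(manifest: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep only records with a weight and all eight body-size traits.

    ``manifest`` may carry a boolean ``recorded`` column (collection
    failures); missing values are NaN.  Returns the complete-case table and
    the per-reason removal counts: ``unrecorded``, ``missing_weight``,
    ``missing_body_size``, ``retained``.
    """
    df = manifest.copy()
    n0 = len(df)
    if "recorded" in df.columns:
        unrecorded = int((~df["recorded"].astype(bool)).sum())
        df = df[df["recorded"].astype(bool)].drop(columns=["recorded"])
    else:
        unrecorded = 0
    missing_w = df["BW"].isna()
    n_missing_w = int(missing_w.sum())
    df = df[~missing_w]
    trait_cols = [t for t in TRAITS if t in df.columns]
    missing_t = df[trait_cols].isna().any(axis=1)
    n_missing_t = int(missing_t.sum())
    df = df[~missing_t].reset_index(drop=True)
    if len(df) == 0:
        warnings.warn("no complete records remain after filtering", stacklevel=2)
    counts = {
        "total": n0,
        "unrecorded": unrecorded,
        "missing_weight": n_missing_w,
        "missing_body_size": n_missing_t,
        "retained": len(df),
    }
    return df, counts


# ---------------------------------------------------------------------------
# descriptive statistics


def describe(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Sex-stratified mean, SD, CV%, max, min and n per trait.

    Rows for ``male``, ``female`` and ``overall``; SD is the sample standard
    deviation and CV% = 100 * SD / mean.
    """
    traits = list(traits) if traits is not None else ["BW", *TRAITS]
    traits = [t for t in traits if t in table.columns]
    groups = {"male": table[table["sex"] == "male"],
              "female": table[table["sex"] == "female"],
              "overall": table}
    rows = []
    for trait in traits:
        for sex, sub in groups.items():
            v = sub[trait].dropna().astype(float)
            if len(v) == 0:
                continue
            mean = v.mean()
            sd = v.std(ddof=1) if len(v) > 1 else 0.0
            rows.append(
                {
                    "trait": trait,
                    "sex": sex,
                    "mean": mean,
                    "sd": sd,
                    "cv_pct": 0.0 if mean == 0 else 100.0 * sd / mean,
                    "max": v.max(),
                    "min": v.min(),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, percent: ``100 * SD / mean``."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


# ---------------------------------------------------------------------------
# correlation and ANOVA


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Rank correlation is robust to outliers and to non-normal marginals,
    which is why it is preferred over Pearson here.  The p-value uses the
    t-approximation.  A constant input has no defined rank correlation:
    (nan, nan) is returned with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def significance_stars(p: float) -> str:
    """Conventional significance marks: * 0.05, ** 0.01, *** 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_by_sex(table: pd.DataFrame, trait: str) -> tuple[float, float]:
    """One-way ANOVA of a trait between the two sexes: returns (F, p)."""
    groups = [
        table.loc[table["sex"] == s, trait].dropna().astype(float).to_numpy()
        for s in ("male", "female")
    ]
    if any(len(g) < 2 for g in groups):
        raise ValueError("both sex groups need at least 2 observations")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# regression


def _design(table: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    X = table[predictors].astype(float)
    return sm.add_constant(X, has_constant="add")


def ols_fit(table: pd.DataFrame, response: str, predictors) -> RegressionModel:
    """Ordinary least-squares fit of ``response`` on ``predictors``.

    Reports the standard error of the estimate, R², adjusted R², the
    residual mean square (MSE), per-coefficient t-test p-values and the
    overall F-test p-value.  Rank-deficient designs (e.g. a duplicated
    predictor) have the offending columns dropped with a warning.
    """
    predictors = list(predictors)
    sub = table[[response, *predictors]].dropna()
    y = sub[response].astype(float)
    X = sub[predictors].astype(float)
    # drop columns that add no rank (duplicates / exact collinearity)
    keep: list[str] = []
    for col in predictors:
        trial = X[keep + [col]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(trial)), trial])) == (
            len(keep) + 2
        ):
            keep.append(col)
        else:
            warnings.warn(f"dropping collinear predictor {col!r}", stacklevel=2)
    res = sm.OLS(y, _design(sub, keep)).fit()
    coefs = {k: float(res.params[k]) for k in keep}
    pvals = {k: float(res.pvalues[k]) for k in keep}
    return RegressionModel(
        intercept=float(res.params["const"]),
        coefficients=coefs,
        se_estimate=float(np.sqrt(res.mse_resid)),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        mse=float(res.mse_resid),
        p_value=float(res.f_pvalue) if len(keep) else float("nan"),
        coef_pvalues=pvals,
        n=int(res.nobs),
    )


def stepwise(
    table: pd.DataFrame,
    response: str,
    candidates,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
) -> list[RegressionModel]:
    """Bidirectional stepwise selection of a linear model.

    Forward step: among candidates not yet included, fit each one added to
    the current model and pick the smallest entry p-value (the t-test of the
    new coefficient, equivalent to the partial F-test); enter it if
    p <= ``alpha_enter``.  Backward step: after every entry, remove (worst
    first) any included variable whose p-value has risen above
    ``alpha_remove``.  Returns the model refitted after each forward step,
    mirroring how stepwise software reports the model sequence; an empty
    list means no candidate passed entry.
    """
    candidates = list(candidates)
    sub = table[[response, *candidates]].dropna()
    if len(sub) <= len(candidates) + 2:
        raise ValueError("too few complete rows for stepwise selection")
    included: list[str] = []
    sequence: list[RegressionModel] = []
    while True:
        remaining = [c for c in candidates if c not in included]
        if not remaining:
            break
        entry = []
        for cand in remaining:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = ols_fit(sub, response, included + [cand])
            p = m.coef_pvalues.get(cand, np.inf)
            entry.append((p, cand))
        entry.sort()
        best_p, best = entry[0]
        if best_p > alpha_enter:
            break
        included.append(best)
        # backward purge
        while True:
            m = ols_fit(sub, response, included)
            worst = max(m.coef_pvalues.items(), key=lambda kv: kv[1], default=None)
            if worst is None or worst[1] <= alpha_remove:
                break
            included.remove(worst[0])
        if not included:
            break
        sequence.append(ols_fit(sub, response, included))
    if not sequence:
        warnings.warn("no candidate passed the entry threshold", stacklevel=2)
    return sequence


def predict_weight(traits, model: RegressionModel | str) -> float:
    """Evaluate a weight equation (fitted, or published by fixture name).

    ``model`` may be a :class:`RegressionModel` or one of the
    :data:`PUBLISHED_EQUATIONS` keys (``"ewe-1"`` … ``"ram-6"``).
    """
    if isinstance(model, str):
        try:
            model = PUBLISHED_EQUATIONS[model]
        except KeyError:
            raise ValueError(
                f"unknown published equation {model!r}; "
                f"choose from {sorted(PUBLISHED_EQUATIONS)}"
            ) from None
    return model.predict(traits)


def models_report(models, component: str = "") -> pd.DataFrame:
    """Tabulate a model sequence with the standard report columns."""
    rows = []
    for m in models:
        rows.append(
            {
                "component": component or ", ".join(m.coefficients),
                "equation": m.equation(),
                "SE": m.se_estimate,
                "R2": m.r_squared,
                "adj_R2": m.adj_r_squared,
                "MSE": m.mse,
                "p": m.p_value,
            }
        )
    return pd.DataFrame(rows)
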