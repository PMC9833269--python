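"""Statistical analyses: score quantile stratification, LDL-C ~ score linear
regression, CAC quartile logistic model, and nonparametric group comparisons.

Conventions: empirical quantile cut points use linear interpolation of the
empirical CDF with ties going to the lower stratum; odds-ratio intervals are
Wald (symmetric on the log scale); 2x2 chi-square applies the Yates continuity
correction; all tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "QuantileAssignment",
    "LinearAssocResult",
    "LogisticQuartileResult",
    "GroupComparisonResult",
    "StratificationError",
    "FitError",
    "assign_quantiles",
    "quantile_labels",
    "linear_assoc",
    "logistic_quartile_or",
    "group_compare",
]

ALPHA = 0.05
_Z975 = 1.959963984540054


class StratificationError(ValueError):
    pass


class FitError(ValueError):
    pass


# -- quantile stratification -------------------------------------------------

@dataclass(frozen=True)
class QuantileAssignment:
    subject_id: str
    k: int
    label: int  # 1..k, 1 = lowest scores


def quantile_labels(scores: Sequence[float], k: int) -> np.ndarray:
    """1..k stratum labels from empirical quantile cut points.

    Cut points are the (1/k .. (k-1)/k) quantiles under the inclusive
    linear-interpolation definition; a score exactly on a cut point goes to
    the lower stratum.
    """
    scores = np.asarray(scores, dtype=float)
    if k < 2:
        raise StratificationError("k must be at least 2")
    if np.unique(scores).size < k:
        raise StratificationError(
            f"need at least {k} distinct score values, found {np.unique(scores).size}"
        )
    cuts = np.quantile(scores, np.arange(1, k) / k, method="linear")
    # strictly-greater comparison sends exact ties to the lower stratum
    return 1 + (scores[:, None] > cuts[None, :]).sum(axis=1)


def assign_quantiles(scores: Sequence[float], k: int,
                     subject_ids: Sequence[str] | None = None) -> list[QuantileAssignment]:
    labels = quantile_labels(scores, k)
    if subject_ids is None:
        subject_ids = [str(i) for i in range(len(labels))]
    if len(subject_ids) != len(labels):
        raise StratificationError("subject_ids and scores differ in length")
    return [QuantileAssignment(subject_id=str(s), k=k, label=int(l))
            for s, l in zip(subject_ids, labels)]


# -- linear association ------------------------------------------------------

@dataclass(frozen=True)
class LinearAssocResult:
    slope: float        # mg/dL per score unit
    intercept: float
    r2: float
    adjusted_r2: float
    n: int
    p_value: float      # two-sided, for the score slope
    slope_se: float
    slope_ci: tuple[float, float]  # 95%, t-based


def linear_assoc(response: Sequence[float], predictor: Sequence[float],
                 covariates: pd.DataFrame | None = None) -> LinearAssocResult:
    """Ordinary least squares of response (mg/dL) on the score, with optional
    covariates; reports the score slope and the model's (adjusted) R^2."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape:
        raise FitError("response and predictor differ in length")
    X = pd.DataFrame({"score": x})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise FitError(f"n = {n} too small for {p} predictor(s)")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise FitError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    ci_lo, ci_hi = fit.conf_int(alpha=ALPHA).loc["score"]
    return LinearAssocResult(
        slope=float(fit.params["score"]),
        intercept=float(fit.params["const"]),
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        n=n,
        p_value=float(fit.pvalues["score"]),
        slope_se=float(fit.bse["score"]),
        slope_ci=(float(ci_lo), float(ci_hi)),
    )


# -- quartile logistic model --------------------------------------------------

@dataclass(frozen=True)
class OddsRatio:
    or_: float
    ci_low: float
    ci_high: float
    p_value: float

    def covers(self, value: float = 1.0) -> bool:
        return self.ci_low <= value <= self.ci_high


@dataclass(frozen=True)
class LogisticQuartileResult:
    """Quartile odds ratios vs the lowest quartile, age/sex-adjusted."""

    quartile_or: Mapping[int, OddsRatio]  # keys 2..4; quartile 1 is the reference
    trend_or: OddsRatio                   # quartile entered as ordinal 1-4
    age_or: OddsRatio                     # per year
    sex_or: OddsRatio                     # male vs female
    intercept: float
    n: int


def _sex_to_male(sex: Sequence) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "ifb":
        return arr.astype(float)
    out = np.empty(len(arr))
    for i, s in enumerate(arr):
        s = str(s).strip().upper()
        if s in ("M", "MALE", "1"):
            out[i] = 1.0
        elif s in ("F", "FEMALE", "0"):
            out[i] = 0.0
        else:
            raise FitError(f"cannot code sex value {s!r}")
    return out


def _wald_or(fit, name: str) -> OddsRatio:
    b = float(fit.params[name])
    se = float(fit.bse[name])
    return OddsRatio(
        or_=float(np.exp(b)),
        ci_low=float(np.exp(b - _Z975 * se)),
        ci_high=float(np.exp(b + _Z975 * se)),
        p_value=float(fit.pvalues[name]),
    )


def _logit_fit(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge "
                       f"(|grad| = {np.abs(fit.score(fit.params)).max():.3g})")
    if not np.isfinite(fit.bse).all() or np.nanmax(fit.bse) > 1e3:
        raise FitError("unstable standard errors; data may be separated")
    return fit


def logistic_quartile_or(outcome: Sequence, quartile: Sequence[int],
                         age: Sequence[float], sex: Sequence) -> LogisticQuartileResult:
    """Age/sex-adjusted logistic regression of a binary outcome on score quartile.

    Quartiles are indicator-coded against quartile 1; a second fit with the
    quartile as an ordinal numeric term gives the per-quartile trend OR.
    95% intervals are Wald: exp(estimate +/- 1.96 SE).
    """
    y = np.asarray(outcome, dtype=float)
    q = np.asarray(quartile, dtype=int)
    if set(np.unique(q)) - {1, 2, 3, 4}:
        raise FitError("quartile labels must be 1..4")
    if y.min() == y.max():
        raise FitError("outcome has a single class; logistic model is undefined")
    male = _sex_to_male(sex)
    X = pd.DataFrame({
        "q2": (q == 2).astype(float),
        "q3": (q == 3).astype(float),
        "q4": (q == 4).astype(float),
        "age": np.asarray(age, dtype=float),
        "male": male,
    })
    fit = _logit_fit(y, X)
    Xt = pd.DataFrame({"quartile": q.astype(float), "age": X["age"], "male": male})
    trend = _logit_fit(y, Xt)
    return LogisticQuartileResult(
        quartile_or={k: _wald_or(fit, f"q{k}") for k in (2, 3, 4)},
        trend_or=_wald_or(trend, "quartile"),
        age_or=_wald_or(fit, "age"),
        sex_or=_wald_or(fit, "male"),
        intercept=float(fit.params["const"]),
        n=len(y),
    )


# -- group comparisons --------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonResult:
    test: Literal["chi-square", "mann-whitney", "kruskal-wallis"]
    statistic: float
    p_value: float
    summaries: dict = field(default_factory=dict)
    posthoc: dict | None = None  # pairwise Bonferroni-adjusted p-values


def _summaries_continuous(values: np.ndarray, labels: np.ndarray) -> dict:
    out = {}
    for g in pd.unique(labels):
        v = values[labels == g]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[str(g)] = {"n": int(v.size), "median": float(med),
                       "q1": float(q1), "q3": float(q3)}
    return out


def group_compare(values=None, groups=None, *, table=None,
                  test: Literal["auto", "chi2", "mannwhitney", "kruskal"] = "auto",
                  ) -> GroupComparisonResult:
    """Compare groups: chi-square for contingency counts, Mann-Whitney U for two
    continuous groups, Kruskal-Wallis (with Bonferroni pairwise post hoc) for
    three or more.

    Either pass a contingency ``table`` of nonnegative counts (rows = groups),
    or parallel ``values`` and ``groups`` sequences.  2x2 tables use the Yates
    continuity correction.
    """
    if table is not None:
        tab = np.asarray(table, dtype=float)
        if tab.ndim != 2 or (tab < 0).any():
            raise ValueError("contingency table must be 2-D with nonnegative counts")
        if test not in ("auto", "chi2"):
            raise ValueError(f"test {test!r} is not applicable to a contingency table")
        correction = tab.shape == (2, 2)
        chi2, p, dof, _ = stats.chi2_contingency(tab, correction=correction)
        row_tot = tab.sum(axis=1)
        summaries = {
            f"group{i+1}": {"counts": tab[i].tolist(),
                            "percents": (100 * tab[i] / row_tot[i]).tolist()}
            for i in range(tab.shape[0])
        }
        return GroupComparisonResult(test="chi-square", statistic=float(chi2),
                                     p_value=float(p), summaries=summaries)

    if values is None or groups is None:
        raise ValueError("pass either a contingency table or values + groups")
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups differ in length")
    levels = pd.unique(g)
    samples = [v[g == lev] for lev in levels]
    if len(levels) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need at least two nonempty groups")

    if test == "auto":
        test = "mannwhitney" if len(levels) == 2 else "kruskal"
    if test == "mannwhitney":
        if len(levels) != 2:
            raise ValueError("Mann-Whitney requires exactly two groups")
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupComparisonResult(test="mann-whitney", statistic=float(stat),
                                     p_value=float(p),
                                     summaries=_summaries_continuous(v, g))
    if test == "kruskal":
        stat, p = stats.kruskal(*samples)
        posthoc = None
        if p < ALPHA:
            pairs = list(itertools.combinations(range(len(levels)), 2))
            posthoc = {}
            for i, j in pairs:
                _, p_ij = stats.mannwhitneyu(samples[i], samples[j],
                                             alternative="two-sided")
                posthoc[f"{levels[i]} vs {levels[j]}"] = float(min(1.0, p_ij * len(pairs)))
        return GroupComparisonResult(test="kruskal-wallis", statistic=float(stat),
                                     p_value=float(p),
                                     summaries=_summaries_continuous(v, g),
                                     posthoc=posthoc)
    raise ValueError(f"unknown test {test!r} for continuous data")
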