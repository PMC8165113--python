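"""Propensity-score matching of male to female patients and balance diagnostics.

The propensity model is a maximum-likelihood logistic regression of male sex
on the chosen clinical covariates; matching is greedy 1:1 nearest-neighbour
without replacement under an optional caliper. Balance is summarised by
absolute standardized differences (continuous, binary, and multicategory
Mahalanobis forms). Matching is performed once, up front, and never refit
by downstream stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_sim import SMOKING_LEVELS

DEFAULT_COVARIATES = ("age", "cabg", "bmi", "diabetes", "smoking", "ckd")

#: covariate -> kind; anything absent is inferred from the data.
COVARIATE_KINDS = {
    "age": "continuous",
    "bmi": "continuous",
    "cabg": "binary",
    "diabetes": "binary",
    "ckd": "binary",
    "smoking": "multicategory",
}


class SeparationWarning(UserWarning):
    """Raised when the propensity covariates perfectly separate the sexes."""


@dataclass
class PropensityResult:
    scores: pd.Series  # patient_id -> P(male | covariates)
    coefficients: pd.Series
    separation: bool
    design_columns: list


@dataclass
class MatchResult:
    pairs: list  # (male_id, female_id)
    caliper: float | None
    unmatched_males: list = field(default_factory=list)
    unmatched_females: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_patients(self) -> list:
        return [p for pair in self.pairs for p in pair]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["male_id", "female_id"])


# ----------------------------------------------------------------------
# propensity model
# ----------------------------------------------------------------------


def _design_matrix(clinical: pd.DataFrame, covariates) -> pd.DataFrame:
    """One-hot encode categoricals (reference level dropped), keep the rest."""
    cols = {}
    for cov in covariates:
        if cov not in clinical.columns:
            raise KeyError(f"covariate {cov!r} not in clinical table")
        series = clinical[cov]
        if series.dtype == object or str(series.dtype) == "category":
            levels = SMOKING_LEVELS if cov == "smoking" else tuple(sorted(series.unique()))
            for level in levels[1:]:  # first level is the reference
                cols[f"{cov}[{level}]"] = (series == level).astype(float).to_numpy()
        else:
            cols[cov] = series.astype(float).to_numpy()
    return pd.DataFrame(cols, index=clinical.index)


def fit_propensity(clinical: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> PropensityResult:
    """Fit P(male | covariates) by maximum-likelihood logistic regression.

    Zero-variance design columns are dropped (they are collinear with the
    intercept). Perfect separation is detected, flagged and warned about;
    scores are still returned.
    """
    sexes = set(clinical["sex"].unique())
    if sexes != {"M", "F"} or (clinical["sex"] == "M").sum() < 2 or (clinical["sex"] == "F").sum() < 2:
        raise ValueError("need at least 2 patients of each sex")
    y = (clinical["sex"] == "M").astype(float).to_numpy()
    X = _design_matrix(clinical, covariates)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate column(s): {constant}", UserWarning)
        X = X.drop(columns=constant)
    design = sm.add_constant(X, has_constant="add")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = sm.Logit(y, design).fit(method="bfgs", maxiter=500, disp=0)
    scores = np.asarray(fit.predict(design))

    separation = any("separat" in str(w.message).lower() for w in caught)
    male_scores, female_scores = scores[y == 1], scores[y == 0]
    if male_scores.min() > female_scores.max() and male_scores.min() - female_scores.max() > 0.9:
        separation = True
    if separation:
        warnings.warn(
            "perfect separation: covariates fully predict sex; propensity scores are degenerate",
            SeparationWarning,
        )

    ids = clinical["patient_id"] if "patient_id" in clinical.columns else clinical.index
    return PropensityResult(
        scores=pd.Series(scores, index=pd.Index(ids, name="patient_id")),
        coefficients=pd.Series(np.asarray(fit.params), index=design.columns),
        separation=separation,
        design_columns=list(design.columns),
    )


# ----------------------------------------------------------------------
# greedy 1:1 matching
# ----------------------------------------------------------------------


def default_caliper(scores: pd.Series) -> float:
    """0.2 times the SD of the logit of the scores (a common convention)."""
    eps = 1e-12
    p = np.clip(scores.to_numpy(dtype=float), eps, 1 - eps)
    logit = np.log(p / (1 - p))
    return float(0.2 * np.std(logit, ddof=1))


def greedy_match(
    scores: pd.Series,
    sex: pd.Series,
    caliper: float | str | None = None,
    seed: int = 0,
) -> MatchResult:
    """Greedy nearest-neighbour 1:1 matching without replacement.

    Males are processed in descending propensity-score order; each takes the
    closest still-available female within the caliper. ``caliper=None``
    disables the caliper; ``caliper="auto"`` uses :func:`default_caliper`.
    The seed only breaks exact ties (equal scores / equal distances).
    """
    scores = scores.astype(float)
    sex = sex.reindex(scores.index)
    if sex.isna().any():
        raise ValueError("sex not provided for every scored patient")
    if caliper == "auto":
        caliper = default_caliper(scores)
    if caliper is not None and caliper < 0:
        raise ValueError("caliper must be >= 0")

    rng = np.random.default_rng(seed)
    males = [p for p in scores.index if sex[p] == "M"]
    females = [p for p in scores.index if sex[p] == "F"]
    # seeded tie-break ranks; deterministic otherwise
    tie_rank = {p: r for p, r in zip(scores.index, rng.permutation(len(scores.index)))}

    males.sort(key=lambda p: (-scores[p], tie_rank[p]))
    available = set(females)
    pairs = []
    for m in males:
        if not available:
            break
        best = min(available, key=lambda f: (abs(scores[m] - scores[f]), tie_rank[f]))
        dist = abs(scores[m] - scores[best])
        if caliper is None or dist <= caliper:
            pairs.append((m, best))
            available.remove(best)
    matched_f = {f for _, f in pairs}
    matched_m = {m for m, _ in pairs}
    return MatchResult(
        pairs=pairs,
        caliper=None if caliper is None else float(caliper),
        unmatched_males=[m for m in males if m not in matched_m],
        unmatched_females=[f for f in females if f not in matched_f],
    )


# ----------------------------------------------------------------------
# standardized differences
# ----------------------------------------------------------------------


def standardized_difference(summary_a, summary_b, kind: str) -> float:
    """Absolute standardized difference between two group summaries.

    kind = "continuous":    summaries are (mean, sd);
           d = |m_a - m_b| / sqrt((s_a^2 + s_b^2) / 2)
    kind = "binary":        summaries are proportions p_a, p_b;
           d = |p_a - p_b| / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2)
    kind = "multicategory": summaries are K-vectors of category proportions;
           d = sqrt(T' S^{-1} T) with T the difference of the first K-1
           proportions and S the average of the two multinomial covariance
           matrices (last category dropped).

    A zero numerator with a degenerate denominator yields d = 0; a nonzero
    numerator with a degenerate denominator is an error.
    """
    if kind == "continuous":
        (m_a, s_a), (m_b, s_b) = summary_a, summary_b
        num = abs(m_a - m_b)
        denom = np.sqrt((s_a**2 + s_b**2) / 2.0)
        if denom == 0:
            if num == 0:
                return 0.0
            raise ZeroDivisionError("both group SDs are 0 but means differ")
        return float(num / denom)

    if kind == "binary":
        p_a, p_b = float(summary_a), float(summary_b)
        num = abs(p_a - p_b)
        denom = np.sqrt((p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0)
        if denom == 0:
            if num == 0:
                return 0.0
            raise ZeroDivisionError("degenerate proportions with nonzero difference")
        return float(num / denom)

    if kind == "multicategory":
        p_a = np.asarray(summary_a, dtype=float)
        p_b = np.asarray(summary_b, dtype=float)
        if p_a.shape != p_b.shape or p_a.ndim != 1 or len(p_a) < 2:
            raise ValueError("multicategory summaries must be equal-length proportion vectors")
        # categories empty in both groups carry no difference and no variance
        occupied = (p_a + p_b) > 0
        p_a, p_b = p_a[occupied], p_b[occupied]
        if len(p_a) < 2:
            return 0.0
        t = (p_a - p_b)[:-1]
        if np.allclose(t, 0.0):
            return 0.0

        def mcov(p):
            q = p[:-1]
            return np.diag(q) - np.outer(q, q)

        s = (mcov(p_a) + mcov(p_b)) / 2.0
        try:
            sol = np.linalg.solve(s, t)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(s) @ t
            if not np.allclose(s @ sol, t, atol=1e-10):
                raise np.linalg.LinAlgError(
                    "degenerate covariance with difference outside its range"
                ) from None
        return float(np.sqrt(max(t @ sol, 0.0)))

    raise ValueError(f"unknown covariate kind {kind!r}")


def _infer_kind(series: pd.Series) -> str:
    if series.dtype == object or str(series.dtype) == "category":
        return "binary" if series.nunique() <= 2 else "multicategory"
    uniq = pd.unique(series.dropna())
    if len(uniq) <= 2 and set(np.asarray(uniq, dtype=float)) <= {0.0, 1.0}:
        return "binary"
    return "continuous"


def balance_table(
    clinical: pd.DataFrame,
    match: MatchResult,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-covariate group summaries and standardized differences on the
    matched patients only."""
    keep = set(match.matched_patients())
    sub = clinical[clinical["patient_id"].isin(keep)]
    males = sub[sub["sex"] == "M"]
    females = sub[sub["sex"] == "F"]
    rows = []
    for cov in covariates:
        if cov not in clinical.columns:
            raise KeyError(f"covariate {cov!r} not in clinical table")
        kind = COVARIATE_KINDS.get(cov, _infer_kind(clinical[cov]))
        if kind == "continuous":
            sa = (males[cov].mean(), males[cov].std(ddof=1))
            sb = (females[cov].mean(), females[cov].std(ddof=1))
            summary_m = f"{sa[0]:.2f} +/- {sa[1]:.2f}"
            summary_f = f"{sb[0]:.2f} +/- {sb[1]:.2f}"
        elif kind == "binary":
            sa = float(np.mean(males[cov].astype(float)))
            sb = float(np.mean(females[cov].astype(float)))
            summary_m = f"{sa:.2f}"
            summary_f = f"{sb:.2f}"
        else:
            levels = SMOKING_LEVELS if cov == "smoking" else sorted(clinical[cov].unique())
            sa = np.array([(males[cov] == lv).mean() for lv in levels])
            sb = np.array([(females[cov] == lv).mean() for lv in levels])
            summary_m = "/".join(f"{v:.2f}" for v in sa)
            summary_f = "/".join(f"{v:.2f}" for v in sb)
        d = standardized_difference(sa, sb, kind)
        rows.append(
            {
                "covariate": cov,
                "kind": kind,
                "male_summary": summary_m,
                "female_summary": summary_f,
                "std_diff": d,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
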