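"""Two-group risk-stratification statistics for phase-parameter cohorts.

Implements the study's statistical stage: normality-gated univariate
comparisons (Shapiro-Wilk gate; Welch t vs rank-sum), the Henze-Zirkler
multivariate normality check and Hotelling's T², two logistic models with
an ApEn x baseline-LVEF interaction, Mann-Whitney AUC, and repeated
stratified-CV Random Forest / Naive-Bayes classifiers.

Note: between independent groups of unequal size the paired signed-rank
test is undefined, so the non-parametric branch is the two-sample rank-sum
(Mann-Whitney) test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PHASE_FEATURES = ("apen", "synchrony", "entropy", "phase_sd")
FULL_PREDICTORS = ("apen", "baseline_lvef", "apen_x_lvef", "synchrony", "entropy", "phase_sd")
REDUCED_PREDICTORS = ("apen", "baseline_lvef", "apen_x_lvef")

POSITIVE_LABEL = "ctrcd"


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    test: str  # "welch-t" or "rank-sum"
    statistic: float
    p_value: float
    mean_sd: dict  # group -> (mean, sd)
    shapiro_p: dict  # group -> Shapiro-Wilk p


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float


@dataclass(frozen=True)
class LogisticModelResult:
    model: str  # "full" or "reduced"
    coefficients: dict  # predictor -> estimate (incl. "const")
    p_values: dict  # predictor -> Wald p
    std_errors: dict
    model_chi2_p: float
    auc: float  # in-sample
    n: int


@dataclass(frozen=True)
class ClassifierResult:
    method: str
    fold_aucs: tuple[float, ...]
    mean_auc: float
    n_valid_resamples: int
    n_skipped: int


def _split_groups(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if "group" not in cohort.columns:
        raise ValueError("cohort table has no 'group' column")
    stable = cohort[cohort["group"] == "stable"]
    ctrcd = cohort[cohort["group"] == POSITIVE_LABEL]
    if len(stable) == 0 or len(ctrcd) == 0:
        raise ValueError("both groups must be present in the cohort")
    return stable, ctrcd


def compare_feature(
    cohort: pd.DataFrame, feature: str, alpha: float = 0.05
) -> GroupComparison:
    """Two-group comparison of one feature with a normality gate.

    If Shapiro-Wilk finds no evidence against normality in either group
    (p >= alpha in both) an unpaired Welch t test is used, otherwise the
    two-sample rank-sum (Mann-Whitney) test.  Both are two-sided.
    """
    stable, ctrcd = _split_groups(cohort)
    x1 = stable[feature].to_numpy(dtype=float)
    x2 = ctrcd[feature].to_numpy(dtype=float)
    if len(x1) < 3 or len(x2) < 3:
        raise ValueError("both groups need at least 3 members")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValueError(
            f"feature {feature!r} has zero variance within a group; "
            "comparison is degenerate"
        )
    sw1 = stats.shapiro(x1).pvalue
    sw2 = stats.shapiro(x2).pvalue
    if sw1 >= alpha and sw2 >= alpha:
        res = stats.ttest_ind(x1, x2, equal_var=False)
        test = "welch-t"
    else:
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided")
        test = "rank-sum"
    return GroupComparison(
        feature=feature,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_sd={
            "stable": (float(x1.mean()), float(x1.std(ddof=1))),
            POSITIVE_LABEL: (float(x2.mean()), float(x2.std(ddof=1))),
        },
        shapiro_p={"stable": float(sw1), POSITIVE_LABEL: float(sw2)},
    )


def henze_zirkler(x: np.ndarray, alpha: float = 0.05):
    """Henze-Zirkler multivariate normality test (delegates to pingouin)."""
    import pingouin as pg

    return pg.multivariate_normality(np.asarray(x, dtype=float), alpha=alpha)


def hotelling_t2(x1: np.ndarray, x2: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling's T² with pooled covariance and F conversion.

    ``T² = (n1*n2/(n1+n2)) * (d)ᵀ S_pooled⁻¹ d`` with ``d`` the mean
    difference; ``F = T² * (n1+n2-p-1) / (p*(n1+n2-2))`` on
    ``(p, n1+n2-p-1)`` degrees of freedom.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.ndim != 2 or x2.ndim != 2 or x1.shape[1] != x2.shape[1]:
        raise ValueError("feature matrices must be 2-D with matching columns")
    n1, n2 = x1.shape[0], x2.shape[0]
    p = x1.shape[1]
    if n1 + n2 <= p + 2:
        raise ValueError(f"combined sample size {n1 + n2} too small for p={p}")
    d = x1.mean(axis=0) - x2.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(x1, rowvar=False, ddof=1)
                + (n2 - 1) * np.cov(x2, rowvar=False, ddof=1)) / (n1 + n2 - 2)
    s_pooled = np.atleast_2d(s_pooled)
    try:
        sol = np.linalg.solve(s_pooled, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; reduce or decorrelate the feature set"
        ) from exc
    if not np.all(np.isfinite(sol)) or np.linalg.cond(s_pooled) > 1e12:
        raise ValueError(
            "pooled covariance is numerically singular; reduce the feature set"
        )
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / (p * (n1 + n2 - 2))
    p_value = float(stats.f.sf(f_stat, p, df2))
    return HotellingResult(t2=t2, f_statistic=float(f_stat), df=(p, df2), p_value=p_value)


def _design_matrix(cohort: pd.DataFrame, predictors: tuple[str, ...]) -> pd.DataFrame:
    x = pd.DataFrame(index=cohort.index)
    for name in predictors:
        if name == "apen_x_lvef":
            x[name] = cohort["apen"].astype(float) * cohort["baseline_lvef"].astype(float)
        else:
            x[name] = cohort[name].astype(float)
    return x


def fit_logistic(cohort: pd.DataFrame, model: str = "full") -> LogisticModelResult:
    """Maximum-likelihood logistic regression for CTRCD.

    ``model="full"`` uses all four phase parameters, baseline LVEF, and the
    ApEn x LVEF interaction; ``model="reduced"`` keeps ApEn, baseline LVEF
    and the interaction.  Reports Wald p-values, the likelihood-ratio
    chi-squared p for the whole model, and the in-sample AUC.  Raises on
    non-convergence or (quasi-)separation, which small-event cohorts can
    produce.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    if model == "full":
        predictors = FULL_PREDICTORS
    elif model == "reduced":
        predictors = REDUCED_PREDICTORS
    else:
        raise ValueError(f"unknown model {model!r}")
    y = (cohort["group"] == POSITIVE_LABEL).astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome has a single class; cannot fit a logistic model")
    x = sm.add_constant(_design_matrix(cohort, predictors), has_constant="add")
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=PerfectSeparationWarning)
        warnings.filterwarnings("error", message=".*[Ss]eparation.*")
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # ill-conditioned Hessian (e.g. a near-constant predictor);
            # retry with a gradient method before giving up
            try:
                fit = sm.Logit(y, x).fit(disp=0, maxiter=500, method="bfgs")
            except Exception as exc:  # noqa: BLE001 - diagnose and re-raise
                raise ValueError(f"logistic fit failed ({model} model): {exc}") from exc
        except Exception as exc:  # noqa: BLE001 - diagnose and re-raise
            raise ValueError(f"logistic fit failed ({model} model): {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ValueError(f"logistic fit did not converge ({model} model)")
    if np.abs(fit.params).max() > 1e4 or not np.all(np.isfinite(fit.bse)):
        raise ValueError(
            f"logistic fit is degenerate ({model} model): separation suspected"
        )
    scores = np.asarray(fit.predict(x))
    return LogisticModelResult(
        model=model,
        coefficients=dict(fit.params),
        p_values=dict(fit.pvalues),
        std_errors=dict(fit.bse),
        model_chi2_p=float(fit.llr_pvalue),
        auc=auc(scores, y),
        n=len(y),
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def cv_classifiers(
    cohort: pd.DataFrame,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
    features: tuple[str, ...] = (*PHASE_FEATURES, "baseline_lvef"),
) -> dict[str, ClassifierResult]:
    """Random Forest and Naive-Bayes AUC under repeated stratified k-fold CV.

    Per-resample AUC is computed on held-out data; a fold whose test split
    (or training split) contains a single class is skipped with a warning
    and the count of valid resamples is reported.  Fold assignment is a
    pure function of ``seed``.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import RepeatedStratifiedKFold
    from sklearn.naive_bayes import GaussianNB

    x = _design_matrix(cohort, features).to_numpy()
    y = (cohort["group"] == POSITIVE_LABEL).astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    makers = {
        "random-forest": lambda: RandomForestClassifier(random_state=seed),
        "naive-bayes": lambda: GaussianNB(),
    }
    results: dict[str, ClassifierResult] = {}
    splits = list(cv.split(x, y))
    for method, make in makers.items():
        aucs: list[float] = []
        skipped = 0
        for train, test in splits:
            if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                skipped += 1
                continue
            clf = make()
            clf.fit(x[train], y[train])
            scores = clf.predict_proba(x[test])[:, 1]
            aucs.append(auc(scores, y[test]))
        if skipped:
            logger.warning(
                "%s: skipped %d of %d resamples with a single-class split",
                method, skipped, len(splits),
            )
        if not aucs:
            raise ValueError("every CV resample had a single-class split")
        results[method] = ClassifierResult(
            method=method,
            fold_aucs=tuple(aucs),
            mean_auc=float(np.mean(aucs)),
            n_valid_resamples=len(aucs),
            n_skipped=skipped,
        )
    return results


def exclude_baseline(
    cohort: pd.DataFrame,
    lvef_floor: float = 55.0,
    quality_flags: tuple[str, ...] = ("gating_problem", "poor_quality"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the baseline exclusion rules and account for every removal.

    Records are removed if any quality flag column is set or the baseline
    LVEF is below ``lvef_floor``.  Each removed record is counted once, in
    the first matching category (flag columns in the given order, then
    ``lvef``), mirroring a mutually exclusive exclusion accounting.
    """
    remaining = np.ones(len(cohort), dtype=bool)
    report: dict[str, int] = {}
    for flag in quality_flags:
        if flag in cohort.columns:
            hit = remaining & cohort[flag].fillna(False).astype(bool).to_numpy()
            report[flag] = int(hit.sum())
            remaining &= ~hit
        else:
            report[flag] = 0
    low = remaining & (cohort["baseline_lvef"].to_numpy(dtype=float) < lvef_floor)
    report["lvef"] = int(low.sum())
    remaining &= ~low
    report["excluded"] = int((~remaining).sum())
    report["remaining"] = int(remaining.sum())
    return cohort[remaining].copy(), report


def group_feature_matrices(
    cohort: pd.DataFrame, features: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group feature matrices (stable, ctrcd) for multivariate tests."""
    stable, ctrcd = _split_groups(cohort)
    return (
        stable[list(features)].to_numpy(dtype=float),
        ctrcd[list(features)].to_numpy(dtype=float),
    )
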