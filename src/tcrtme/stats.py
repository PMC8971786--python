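"""Inferential layer: paired/group nonparametric tests, correlation,
group-wise multiplicity control, ROC response prediction, and survival staging.

All tests are two-sided at the 5% significance level. Rank tests use the exact
null distribution where scipy provides it (no ties/zeros, moderate n) and the
tie- and continuity-corrected normal approximation otherwise. The false
discovery rate is controlled with the Benjamini-Hochberg step-up applied
group-wise for each biomarker, not across the whole result table at once.

Survival staging follows the two-stage convention: univariable proportional-
hazards fits for every candidate variable, then a multivariable fit restricted
to variables with univariable p <= 0.05, pruned by iterative backward
elimination using likelihood-ratio tests until every retained term has
LR p <= 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, UndefinedStatisticError

__all__ = [
    "ComparisonResult",
    "SurvivalFit",
    "paired_test",
    "group_test",
    "spearman",
    "bh_adjust",
    "roc_auc",
    "km_logrank",
    "cox_stage",
    "contingency_test",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """One hypothesis test on a contrast (pre-vs-post, responder-vs-non, ...)."""

    contrast: str
    n: int  # complete pairs, or total across groups
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    direction: int = 0  # sign of the median (paired) difference / location shift

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass
class SurvivalFit:
    """Hazard-ratio estimate for one variable at one model stage."""

    variable: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    stage: str  # "univariate" | "multivariate"
    n: int = 0
    events: int = 0
    converged: bool = True


def _clean_pairs(pre, post) -> tuple[np.ndarray, np.ndarray]:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post vectors must have equal length")
    ok = ~(np.isnan(pre) | np.isnan(post))
    return pre[ok], post[ok]


def paired_test(pre, post, contrast: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Incomplete pairs (NaN on either side) are dropped first; zero differences
    are dropped per the Wilcoxon convention. If every difference is zero the
    test is vacuous and p = 1 by convention. Requires >= 3 complete pairs.
    """
    pre, post = _clean_pairs(pre, post)
    if pre.size < 3:
        raise InsufficientDataError(
            f"paired test needs >= 3 complete pairs, got {pre.size}"
        )
    diff = post - pre
    direction = int(np.sign(np.median(diff)))
    if np.all(diff == 0):
        return ComparisonResult(contrast, int(pre.size), 0.0, 1.0, direction=0)
    res = sps.wilcoxon(
        post, pre, zero_method="wilcox", alternative="two-sided", method="auto"
    )
    return ComparisonResult(
        contrast, int(pre.size), float(res.statistic), float(res.pvalue), direction=direction
    )


def group_test(a, b, contrast: str = "") -> ComparisonResult:
    """Two-sided Mann-Whitney rank-sum test between two independent groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"group test needs >= 3 per group, got {a.size} and {b.size}"
        )
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and a.size <= 25 and b.size <= 25) else "auto"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(a) - np.median(b)))
    return ComparisonResult(
        contrast,
        int(a.size + b.size),
        float(res.statistic),
        float(res.pvalue),
        direction=direction,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise InsufficientDataError(f"spearman needs >= 4 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values, groups=None) -> np.ndarray:
    """Benjamini-Hochberg step-up, applied separately within each group.

    ``groups`` assigns each p-value to a biomarker family; ``None`` treats all
    inputs as one family. Output order matches input order; the step-up
    cumulative-minimum enforcement makes each adjusted value >= its raw value
    and invariant to within-group input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if groups is None:
        groups = np.zeros(p.size)
    groups = np.asarray(groups)
    if groups.size != p.size:
        raise ValueError("groups must match p_values in length")
    adjusted = np.empty_like(p)
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        adjusted[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return adjusted


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation with midranks for ties."""
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    ranks = sps.rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(
    scores, labels, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float, float]:
    """ROC area under the curve with a stratified percentile-bootstrap 95% CI.

    The point estimate is the Mann-Whitney rank statistic (midranks for tied
    scores), identical to the trapezoidal ROC integral. The CI resamples
    responders and non-responders separately so every bootstrap replicate
    keeps both classes; with ``n_boot=0`` the CI is (nan, nan).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise UndefinedStatisticError("AUC undefined with a single class")
    auc = _rank_auc(scores, labels)
    if n_boot <= 0:
        return auc, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        take = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        boots[i] = _rank_auc(scores[take], labels[take])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, float(lo), float(hi)


def km_logrank(time, event, group) -> tuple[float, float, dict]:
    """Kaplan-Meier estimates per group with a two-sided log-rank test.

    Returns (chi-square statistic, p, {group: median survival}). A group with
    no events still contributes to the test but its median may be infinite;
    a warning flags it. Requires >= 2 groups.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    frame = pd.DataFrame(
        {"time": np.asarray(time, float), "event": np.asarray(event, bool), "group": group}
    )
    levels = frame["group"].unique()
    if len(levels) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    medians = {}
    for g, sub in frame.groupby("group"):
        if sub["event"].sum() == 0:
            warnings.warn(f"group {g!r} has no events", UserWarning, stacklevel=2)
        km = KaplanMeierFitter().fit(sub["time"], sub["event"])
        medians[g] = float(km.median_survival_time_)
    res = multivariate_logrank_test(frame["time"], frame["group"], frame["event"])
    return float(res.test_statistic), float(res.p_value), medians


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str):
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def cox_stage(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str] | None = None,
    entry_p: float = ALPHA,
    stay_p: float = ALPHA,
) -> list[SurvivalFit]:
    """Two-stage Cox proportional-hazards screening.

    Stage 1 fits one univariable model per covariate. Stage 2 fits a
    multivariable model on the covariates whose univariable p <= ``entry_p``
    and prunes it by backward elimination: at each step the term whose removal
    has the largest likelihood-ratio p is dropped if that p > ``stay_p``,
    until all retained terms pass. Hazard ratios, 95% CIs and p-values are
    emitted for both stages; a covariate whose fit fails to converge is
    flagged (``converged=False``) rather than aborting the stage.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (duration_col, event_col)]
    n = len(data)
    n_events = int(np.asarray(data[event_col], bool).sum())
    for c in covariates:
        if data[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    if n_events < 10:
        warnings.warn(
            f"only {n_events} events; hazard-ratio estimates will be unstable",
            UserWarning,
            stacklevel=2,
        )

    fits: list[SurvivalFit] = []
    selected: list[str] = []
    for c in covariates:
        try:
            cph = _fit_cox(data[[duration_col, event_col, c]], duration_col, event_col)
            s = cph.summary.loc[c]
            fit = SurvivalFit(
                variable=c,
                hazard_ratio=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p_value=float(s["p"]),
                stage="univariate",
                n=n,
                events=n_events,
            )
            if fit.p_value <= entry_p:
                selected.append(c)
        except Exception as exc:  # noqa: BLE001 - per-variable convergence flag
            logger.warning("univariable Cox fit failed for %s: %s", c, exc)
            fit = SurvivalFit(c, float("nan"), float("nan"), float("nan"),
                              float("nan"), "univariate", n, n_events, converged=False)
        fits.append(fit)

    if not selected:
        return fits

    current = list(selected)
    while current:
        full = _fit_cox(data[[duration_col, event_col, *current]], duration_col, event_col)
        ll_full = full.log_likelihood_
        lr_p = {}
        for c in current:
            rest = [x for x in current if x != c]
            if rest:
                reduced = _fit_cox(
                    data[[duration_col, event_col, *rest]], duration_col, event_col
                )
                lr = 2.0 * (ll_full - reduced.log_likelihood_)
                lr_p[c] = float(sps.chi2.sf(max(lr, 0.0), df=1))
            else:
                lr_p[c] = float(full.log_likelihood_ratio_test().p_value)
        worst = max(lr_p, key=lr_p.get)
        if lr_p[worst] > stay_p:
            logger.info("backward elimination drops %s (LR p=%.3f)", worst, lr_p[worst])
            current.remove(worst)
        else:
            break

    if current:
        final = _fit_cox(data[[duration_col, event_col, *current]], duration_col, event_col)
        for c in current:
            s = final.summary.loc[c]
            fits.append(
                SurvivalFit(
                    variable=c,
                    hazard_ratio=float(s["exp(coef)"]),
                    ci_low=float(s["exp(coef) lower 95%"]),
                    ci_high=float(s["exp(coef) upper 95%"]),
                    p_value=float(s["p"]),
                    stage="multivariate",
                    n=n,
                    events=n_events,
                )
            )
    return fits


def contingency_test(table, strata=None) -> tuple[float, float, str]:
    """Contingency testing for categorical associations.

    A single 2x2 table uses Fisher's exact test (odds ratio as the statistic);
    larger unstratified tables use the chi-square test; a list of 2x2 tables
    (one per stratum) uses the Cochran-Mantel-Haenszel statistic. Returns
    (statistic, p, method-name).
    """
    if strata is not None:
        from statsmodels.stats.contingency_tables import StratifiedTable

        st = StratifiedTable(np.asarray(strata, dtype=float))
        res = st.test_null_odds(correction=True)
        return float(res.statistic), float(res.pvalue), "cmh"
    table = np.asarray(table)
    if table.shape == (2, 2):
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p), "fisher"
    chi2, p, _, _ = sps.chi2_contingency(table)
    return float(chi2), float(p), "chi2"
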