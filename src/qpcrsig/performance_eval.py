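"""Classifier evaluation: ROC/AUC, Youden cut-point, stratified bootstrap
confidence intervals, predictive values, and group-comparison statistics.

Orientation conventions follow the assay: scores are HIGHER in viral
samples, so the ROC is drawn with the viral class positive; a bacterial
call corresponds to a score below the cut-point.  The empirical trapezoid
AUC is identical to the tie-corrected Mann-Whitney probability
P(score_pos > score_neg) + P(tie)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
DEFAULT_N_BOOT = 2000


class EvaluationError(ValueError):
    pass


@dataclass
class RocCurve:
    """Empirical ROC points; index 0 is the (0, 0) corner."""

    thresholds: np.ndarray  # descending score cutoffs, thresholds[0] = +inf
    tpr: np.ndarray
    fpr: np.ndarray
    positive_label: str

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tpr

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


@dataclass
class BootstrapInterval:
    lo: float
    hi: float
    level: float
    n_boot: int
    seed: int | None

    def as_tuple(self) -> tuple[float, float]:
        return (self.lo, self.hi)


@dataclass
class GroupComparison:
    """Result of the assumption-driven test decision tree."""

    design: str
    test: str
    statistic: float
    p_value: float
    trace: dict
    posthoc: pd.DataFrame | None = None


@dataclass
class PerformanceReport:
    positive_label: str
    n_positive: int
    n_negative: int
    auc: float
    auc_ci: BootstrapInterval
    cutpoint: float
    sensitivity: float
    specificity: float
    sensitivity_ci: BootstrapInterval
    specificity_ci: BootstrapInterval
    ppv: float | None
    npv: float | None
    ppv_ci: BootstrapInterval | None
    npv_ci: BootstrapInterval | None
    n_boot: int
    seed: int | None

    def to_dict(self) -> dict:
        def ci(x):
            return None if x is None else [x.lo, x.hi]

        return {
            "positive_label": self.positive_label,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "auc": self.auc,
            "auc_ci": ci(self.auc_ci),
            "cutpoint": self.cutpoint,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_ci": ci(self.sensitivity_ci),
            "specificity_ci": ci(self.specificity_ci),
            "ppv": self.ppv,
            "npv": self.npv,
            "ppv_ci": ci(self.ppv_ci),
            "npv_ci": ci(self.npv_ci),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _split_scores(scores, labels, positive) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(pd.Series(scores), dtype=float)
    labels = np.asarray(pd.Series(labels))
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels differ in length")
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("both classes must be non-empty")
    return pos, neg


def roc_and_auc(scores, labels, positive: str = "viral") -> tuple[RocCurve, float]:
    """Empirical ROC (higher score = positive) and trapezoid AUC."""
    pos, neg = _split_scores(scores, labels, positive)
    all_scores = np.concatenate([pos, neg])
    is_pos = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])

    order = np.argsort(-all_scores, kind="mergesort")
    s = all_scores[order]
    y = is_pos[order]
    # indices of the last occurrence of each distinct score value
    last = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[last]
    fps = (last + 1) - tps
    tpr = np.r_[0.0, tps / len(pos)]
    fpr = np.r_[0.0, fps / len(neg)]
    thresholds = np.r_[np.inf, s[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr,
                    positive_label=positive), auc


def auc_score(scores, labels, positive: str = "viral") -> float:
    """Tie-corrected rank AUC (fast path; equals the trapezoid AUC)."""
    pos, neg = _split_scores(scores, labels, positive)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _candidate_cuts(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.r_[-np.inf, mids, np.inf]


def youden_cutpoint(
    scores, labels, positive: str = "viral"
) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores plus
    -inf/+inf sentinels; a sample is called positive when score >= threshold.
    Ties in J are broken toward higher sensitivity, then the lower threshold.
    Returns (threshold, sensitivity, specificity).
    """
    pos, neg = _split_scores(scores, labels, positive)
    best = None
    for cut in _candidate_cuts(np.concatenate([pos, neg])):
        sens = float(np.mean(pos >= cut))
        spec = float(np.mean(neg < cut))
        j = sens + spec - 1.0
        key = (j, sens, -cut)
        if best is None or key > best[0]:
            best = (key, (float(cut), sens, spec))
    return best[1]


def bootstrap_ci(
    metric_fn,
    scores,
    labels,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapInterval:
    """Percentile interval of metric_fn(scores, labels) under a stratified
    bootstrap: samples are resampled with replacement within each class, so
    every resample keeps both class sizes (a single-class resample cannot
    occur).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    scores = np.asarray(pd.Series(scores), dtype=float)
    labels = np.asarray(pd.Series(labels))
    rng = np.random.default_rng(seed)
    strata = [np.nonzero(labels == lab)[0] for lab in pd.unique(labels)]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(s, size=len(s), replace=True) for s in strata]
        )
        vals[b] = metric_fn(scores[idx], labels[idx])
    lo, hi = np.quantile(vals, [(1 - level) / 2, 1 - (1 - level) / 2])
    return BootstrapInterval(float(lo), float(hi), level, n_boot, seed)


def bootstrap_auc_ci(
    scores,
    labels,
    positive: str = "viral",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapInterval:
    """Stratified-bootstrap percentile CI of the AUC (vectorized fast path).

    Statistically identical to ``bootstrap_ci`` with the rank-AUC metric,
    but computes all replicates at once so coverage studies stay cheap.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    pos, neg = _split_scores(scores, labels, positive)
    rng = np.random.default_rng(seed)
    pos_rs = pos[rng.integers(0, len(pos), size=(n_boot, len(pos)))]
    neg_rs = neg[rng.integers(0, len(neg), size=(n_boot, len(neg)))]
    ranks = stats.rankdata(np.concatenate([pos_rs, neg_rs], axis=1), axis=1)
    r_pos = ranks[:, : len(pos)].sum(axis=1)
    aucs = (r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return BootstrapInterval(float(lo), float(hi), level, n_boot, seed)


def predictive_values(
    tp: int, fp: int, tn: int, fn: int
) -> tuple[float | None, float | None]:
    """PPV = TP/(TP+FP), NPV = TN/(TN+FN); None when a denominator is zero."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    return ppv, npv


def confusion_at_cut(
    scores, labels, cut: float, positive: str = "viral"
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) calling positive when score >= cut."""
    pos, neg = _split_scores(scores, labels, positive)
    tp = int(np.sum(pos >= cut))
    fn = len(pos) - tp
    fp = int(np.sum(neg >= cut))
    tn = len(neg) - fp
    return tp, fp, tn, fn


def evaluate_scores(
    scores,
    labels,
    positive: str = "viral",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[PerformanceReport, RocCurve]:
    """Full performance work-up at the Youden cut-point.

    AUC and its CI use refit resamples; sensitivity/specificity/PPV/NPV CIs
    are bootstrapped at the cut-point fixed from the original data.
    """
    roc, auc = roc_and_auc(scores, labels, positive=positive)
    cut, sens, spec = youden_cutpoint(scores, labels, positive=positive)
    tp, fp, tn, fn = confusion_at_cut(scores, labels, cut, positive=positive)
    ppv, npv = predictive_values(tp, fp, tn, fn)

    def metric(fn_):
        return bootstrap_ci(fn_, scores, labels, n_boot=n_boot, seed=seed,
                            level=level)

    auc_ci = bootstrap_auc_ci(scores, labels, positive=positive,
                              n_boot=n_boot, seed=seed, level=level)
    sens_ci = metric(lambda s, l: float(np.mean(s[l == positive] >= cut)))
    spec_ci = metric(lambda s, l: float(np.mean(s[l != positive] < cut)))

    def _pv(which):
        def f(s, l):
            tp_, fp_, tn_, fn_ = confusion_at_cut(s, l, cut, positive)
            pv = predictive_values(tp_, fp_, tn_, fn_)[which]
            return np.nan if pv is None else pv

        return f

    ppv_ci = metric(_pv(0)) if ppv is not None else None
    npv_ci = metric(_pv(1)) if npv is not None else None

    pos, neg = _split_scores(scores, labels, positive)
    report = PerformanceReport(
        positive_label=positive,
        n_positive=len(pos),
        n_negative=len(neg),
        auc=auc,
        auc_ci=auc_ci,
        cutpoint=cut,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        ppv=ppv,
        npv=npv,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        n_boot=n_boot,
        seed=seed,
    )
    return report, roc


# ---------------------------------------------------------------------------
# group-comparison decision tree
# ---------------------------------------------------------------------------

def _shapiro_all(groups: dict[str, np.ndarray], alpha: float) -> tuple[bool, dict]:
    ps = {}
    for name, vals in groups.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps[name] = float(stats.shapiro(vals)[1])
    return all(p > alpha for p in ps.values()), ps


def _f_test_variances(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided variance-ratio F test."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))


def _breusch_pagan(groups: dict[str, np.ndarray]) -> float:
    """Breusch-Pagan p-value for heteroscedasticity across group dummies."""
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    y = np.concatenate(list(groups.values()))
    labels = np.concatenate([[n] * len(v) for n, v in groups.items()])
    dummies = pd.get_dummies(pd.Series(labels), drop_first=True, dtype=float)
    exog = sm.add_constant(dummies.to_numpy())
    resid = sm.OLS(y, exog).fit().resid
    return float(het_breuschpagan(resid, exog)[1])


def _games_howell(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    import pingouin as pg

    df = pd.DataFrame(
        {
            "value": np.concatenate(list(groups.values())),
            "group": np.concatenate([[n] * len(v) for n, v in groups.items()]),
        }
    )
    return pg.pairwise_gameshowell(data=df, dv="value", between="group")


def _tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    res = stats.tukey_hsd(*groups.values())
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "A": names[i],
                    "B": names[j],
                    "statistic": float(res.statistic[i, j]),
                    "pval": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    groups: dict[str, "np.ndarray | list[float]"],
    design: str | None = None,
    alpha: float = ALPHA,
) -> GroupComparison:
    """Assumption-driven comparison of 2+ groups with a recorded trace.

    Two-group design: Shapiro-Wilk per group; if normal, a variance-ratio
    F test chooses Student vs Welch t; otherwise Mann-Whitney.  Multi-group:
    Shapiro-Wilk + Breusch-Pagan; normal & homoscedastic -> one-way ANOVA
    with Tukey post hoc; normal & heteroscedastic -> Welch ANOVA with
    Games-Howell; non-normal -> Kruskal-Wallis with Games-Howell.  Groups
    smaller than 3 force the nonparametric branch (normality untestable).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if design is None:
        design = "two_group" if len(groups) == 2 else "multi_group"
    if design == "two_group" and len(groups) != 2:
        raise ValueError("two_group design requires exactly two groups")

    trace: dict = {"design": design, "alpha": alpha}
    too_small = any(len(v) < 3 for v in groups.values())
    if too_small:
        trace["warning"] = "group with < 3 values: nonparametric fallback"
        normal, trace["shapiro_p"] = False, None
    else:
        normal, trace["shapiro_p"] = _shapiro_all(groups, alpha)
    trace["normal"] = normal

    vals = list(groups.values())
    if design == "two_group":
        if normal:
            fstat, fp = _f_test_variances(vals[0], vals[1])
            trace["f_test_p"] = fp
            equal_var = fp > alpha
            trace["equal_variances"] = equal_var
            t, p = stats.ttest_ind(vals[0], vals[1], equal_var=equal_var)
            test = "t_test" if equal_var else "welch_t_test"
            return GroupComparison(design, test, float(t), float(p), trace)
        u, p = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        return GroupComparison(design, "mann_whitney", float(u), float(p), trace)

    if normal:
        bp_p = _breusch_pagan(groups)
        trace["breusch_pagan_p"] = bp_p
        homoscedastic = bp_p > alpha
        trace["homoscedastic"] = homoscedastic
        if homoscedastic:
            f, p = stats.f_oneway(*vals)
            return GroupComparison(
                design, "anova", float(f), float(p), trace, posthoc=_tukey(groups)
            )
        import pingouin as pg

        df = pd.DataFrame(
            {
                "value": np.concatenate(vals),
                "group": np.concatenate([[n] * len(v) for n, v in groups.items()]),
            }
        )
        wa = pg.welch_anova(data=df, dv="value", between="group")
        p_col = "p_unc" if "p_unc" in wa.columns else "p-unc"
        return GroupComparison(
            design, "welch_anova", float(wa["F"].iloc[0]),
            float(wa[p_col].iloc[0]), trace, posthoc=_games_howell(groups),
        )
    h, p = stats.kruskal(*vals)
    return GroupComparison(
        design, "kruskal_wallis", float(h), float(p), trace,
        posthoc=_games_howell(groups),
    )


def drs_stability_matrix(
    drs_by_option: dict[str, pd.Series],
) -> tuple[pd.DataFrame, pd.DataFrame, GroupComparison]:
    """Cross-reference-option DRS agreement.

    Returns the Pearson r and r^2 matrices over per-sample score vectors
    (aligned on their common samples) plus a Kruskal-Wallis / Games-Howell
    comparison of the score distributions across options.
    """
    if len(drs_by_option) < 2:
        raise ValueError("need at least two reference options")
    df = pd.DataFrame(drs_by_option).dropna(axis=0)
    if df.empty:
        raise ValueError("no samples shared by all options")
    names = list(df.columns)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if df[a].std() == 0 or df[b].std() == 0:
                val = np.nan
            else:
                val = float(stats.pearsonr(df[a], df[b])[0])
            r.loc[a, b] = r.loc[b, a] = val

    groups = {name: df[name].to_numpy() for name in names}
    h, p = stats.kruskal(*groups.values())
    comparison = GroupComparison(
        design="multi_group",
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        trace={"design": "multi_group", "note": "reference-option comparison"},
        posthoc=_games_howell(groups),
    )
    return r, r**2, comparison
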