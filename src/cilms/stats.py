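"""Univariate and multivariate statistics for ratio feature tables.

Covers the full selection stack used in severity-biomarker discovery:
auto-scaling, fold change with Welch's t-test and Benjamini-Hochberg
q-values, one-way ANOVA with Tukey's HSD post-hoc test, PLS-DA with VIP
scores and permutation validation, temporal-pattern calling, and the
three-way Venn significance partition over grade-versus-control
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .align import FeatureTable


@dataclass(frozen=True)
class GroupComparison:
    metabolite: str
    fold_change: float  # ratio of group means, injured / control, linear scale
    p_value: float
    q_value: float | None = None


@dataclass(frozen=True)
class PlsdaModel:
    n_components: int
    scores: np.ndarray      # (n, A) X-scores T
    loadings: np.ndarray    # (p, A) X-loadings P
    weights: np.ndarray     # (p, A) X-weights W
    y_loadings: np.ndarray  # (m, A) Q
    r2: float
    q2: float
    vip: np.ndarray         # (p,)
    classes: tuple


@dataclass(frozen=True)
class PatternCall:
    metabolite: str
    pattern: str            # "pattern1" | "pattern2" | "other"
    deviations: tuple[float, float, float]


def autoscale(X) -> np.ndarray:
    """Mean-center and scale each column (feature) to unit sample variance."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples-by-features matrix")
    n = (~np.isnan(X)).sum(axis=0)
    if np.any(n < 2):
        raise ValueError(f"feature(s) {np.where(n < 2)[0].tolist()} have "
                         "fewer than 2 observations")
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance feature(s) at columns {zero.tolist()}")
    return (X - mu) / sd


def fold_change_test(values_g1, values_g2, *, equal_var: bool = False
                     ) -> tuple[float, float]:
    """Fold change and t-test p-value between two groups of ratios.

    The fold change is the ratio of linear-scale group means
    (group1 / group2); the p-value is a two-sided two-sample t-test on
    log2 ratios (Welch by default, pooled-variance with
    ``equal_var=True``).
    """
    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observed values")
    if np.any(g1 <= 0) or np.any(g2 <= 0):
        raise ValueError("ratios must be strictly positive")
    fc = float(np.mean(g1) / np.mean(g2))
    t = sps.ttest_ind(np.log2(g1), np.log2(g2), equal_var=equal_var)
    p = float(t.pvalue)
    if np.isnan(p):  # both groups constant and equal
        p = 1.0
    return fc, p


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_tukey(values_by_group: dict, alpha: float = 0.05):
    """One-way ANOVA across groups with Tukey's HSD post-hoc test.

    Returns ``(anova_p, pairwise)`` where ``pairwise`` maps each
    unordered group pair to ``(p_adj, significant)`` from the
    studentized-range distribution.
    """
    names = list(values_by_group)
    groups = []
    for g in names:
        v = np.asarray(values_by_group[g], dtype=float)
        v = v[~np.isnan(v)]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        groups.append(v)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    anova_p = float(sps.f_oneway(*groups).pvalue)
    hsd = sps.tukey_hsd(*groups)
    pairwise = {}
    for i, j in combinations(range(len(names)), 2):
        p_adj = float(hsd.pvalue[i, j])
        pairwise[frozenset((names[i], names[j]))] = (p_adj, p_adj < alpha)
    return anova_p, pairwise


def _rank(X: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(X))


def _indicator(y) -> tuple[np.ndarray, tuple]:
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    y = np.asarray(y)
    if len(classes) == 2:
        Y = (y == classes[1]).astype(float)[:, None]
    else:
        Y = np.column_stack([(y == c).astype(float) for c in classes])
    return Y, classes


def _vip(model: PLSRegression) -> np.ndarray:
    W = model.x_weights_            # (p, A)
    T = model.x_scores_             # (n, A)
    Q = model.y_loadings_           # (m, A)
    p = W.shape[0]
    ssy = np.einsum("na,na->a", T, T) * np.einsum("ma,ma->a", Q, Q)
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


def plsda_fit(X, y, n_components: int = 2, *, cv_folds: int = 7,
              seed: int = 0) -> PlsdaModel:
    """PLS-DA on an auto-scaled matrix with indicator-coded classes.

    Fits a NIPALS partial-least-squares regression of the class
    indicator matrix on X, and derives R² (explained class variance),
    Q² (by ``cv_folds``-fold cross-validation) and per-feature VIP
    scores, normalized so that the mean squared VIP equals 1.
    """
    X = np.asarray(X, dtype=float)
    Y, classes = _indicator(y)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > _rank(X):
        raise ValueError(f"n_components={n_components} exceeds rank(X)={_rank(X)}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    Yc = Y - Y.mean(axis=0)
    resid = Y - pls.predict(X)
    r2 = 1.0 - (resid ** 2).sum() / (Yc ** 2).sum()
    q2 = _q2_cv(X, Y, n_components, cv_folds, seed)
    return PlsdaModel(n_components=n_components, scores=pls.x_scores_,
                      loadings=pls.x_loadings_, weights=pls.x_weights_,
                      y_loadings=pls.y_loadings_, r2=float(r2), q2=float(q2),
                      vip=_vip(pls), classes=classes)


def _q2_cv(X, Y, n_components, folds, seed) -> float:
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = min(folds, n)
    press = 0.0
    for k in range(folds):
        test = idx[k::folds]
        train = np.setdiff1d(idx, test)
        a = min(n_components, _rank(X[train]))
        pls = PLSRegression(n_components=a, scale=False)
        pls.fit(X[train], Y[train])
        press += ((Y[test] - pls.predict(X[test])) ** 2).sum()
    tss = ((Y - Y.mean(axis=0)) ** 2).sum()
    return 1.0 - press / tss


def permutation_validate(X, y, n_components: int = 2, n_perm: int = 20,
                         *, seed: int = 0, cv_folds: int = 7):
    """Label-permutation validation of a PLS-DA model.

    Refits the model ``n_perm`` times with permuted class labels and
    regresses R² and Q² against the absolute correlation between the
    permuted and original indicator labels.  The model is declared valid
    when both regression slopes are positive and every permuted Q² lies
    below the original Q².
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y)
    base = plsda_fit(X, y, n_components, cv_folds=cv_folds, seed=seed)
    Y0, _ = _indicator(y)
    Y0c = Y0 - Y0.mean(axis=0)
    rng = np.random.default_rng(seed)
    corrs, r2s, q2s = [1.0], [base.r2], [base.q2]
    for _ in range(n_perm):
        yp = rng.permutation(y)
        m = plsda_fit(X, yp, n_components, cv_folds=cv_folds, seed=seed)
        Yp, _ = _indicator(yp)
        Ypc = Yp - Yp.mean(axis=0)
        num = np.abs((Y0c * Ypc).sum(axis=0))
        den = np.sqrt((Y0c ** 2).sum(axis=0) * (Ypc ** 2).sum(axis=0))
        corrs.append(float(np.mean(num / den)))
        r2s.append(m.r2)
        q2s.append(m.q2)
    slope_r2 = sps.linregress(corrs, r2s).slope
    slope_q2 = sps.linregress(corrs, q2s).slope
    valid = bool(slope_r2 > 0 and slope_q2 > 0
                 and all(q < base.q2 for q in q2s[1:]))
    return valid, np.array(r2s[1:]), np.array(q2s[1:])


def classify_temporal_pattern(metabolite: str, control_mean: float,
                              t_means, epsilon: float = 0.1) -> PatternCall:
    """Call the temporal trajectory of a metabolite relative to control.

    Pattern 1 is a gradual monotone drift away from the non-injured
    level (deviations non-decreasing over t1..t3, consistent sign,
    deviation established by t3); pattern 2 is an acute excursion in the
    first window followed by restoration toward the control level.  All
    quantities are log2 ratio units; ``epsilon`` is the slack/noise floor.
    Pattern 1 takes precedence if both rules fire.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    t1, t2, t3 = (float(v) for v in t_means)
    dev = (t1 - control_mean, t2 - control_mean, t3 - control_mean)
    d1, d2, d3 = (abs(v) for v in dev)
    signs = {np.sign(v) for v, d in zip(dev, (d1, d2, d3)) if d > epsilon}
    consistent = len(signs) <= 1
    pattern = "other"
    if consistent and d1 <= d2 + epsilon and d2 <= d3 + epsilon and d3 > epsilon:
        pattern = "pattern1"
    elif d1 > d2 - epsilon and d2 >= d3 - epsilon and d1 > epsilon and d3 < d1 - epsilon:
        pattern = "pattern2"
    return PatternCall(metabolite, pattern, (d1, d2, d3))


def venn_select(comparisons: dict[str, list[GroupComparison]],
                fc_threshold: float = 1.5, p_threshold: float = 0.05
                ) -> dict[frozenset, set]:
    """Partition significant metabolites into the 7 Venn regions over the
    per-grade versus-control comparisons.

    A metabolite is significant in a comparison when its fold change
    exceeds ``fc_threshold`` (or falls below its reciprocal) and its
    p-value is below ``p_threshold``.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    grades = list(comparisons)
    member: dict[str, set] = {}
    for g in grades:
        for c in comparisons[g]:
            sig = ((c.fold_change > fc_threshold
                    or c.fold_change < 1.0 / fc_threshold)
                   and c.p_value < p_threshold)
            if sig:
                member.setdefault(c.metabolite, set()).add(g)
    regions = {frozenset(r): set()
               for k in range(1, len(grades) + 1)
               for r in combinations(grades, k)}
    for met, gs in member.items():
        regions[frozenset(gs)].add(met)
    return regions


# ---------------------------------------------------------------------------
# Feature-table conveniences

def impute_half_min(values: pd.DataFrame) -> pd.DataFrame:
    """Fill missing ratios with half the feature's minimum observed ratio
    (for multivariate methods that cannot handle missing entries)."""
    fill = values.min(axis=1, skipna=True) / 2.0
    return values.apply(lambda row: row.fillna(fill[row.name]), axis=1)


def grade_vs_control(table: FeatureTable, grade: str, time_window: str = "t1",
                     *, equal_var: bool = False) -> list[GroupComparison]:
    """Compare one injury grade at one time window against non-injured
    controls, feature by feature (available values only), with BH
    q-values across features."""
    ids_g = [s.sample_id for s in table.samples
             if s.grade == grade and s.time_window == time_window and not s.is_qc]
    ids_n = [s.sample_id for s in table.samples
             if s.grade == "N" and not s.is_qc]
    if not ids_g or not ids_n:
        raise ValueError(f"missing samples for grade {grade!r} or controls")
    names = _feature_names(table)
    out = []
    for i in range(table.n_features):
        fc, p = fold_change_test(table.values[ids_g].iloc[i],
                                 table.values[ids_n].iloc[i],
                                 equal_var=equal_var)
        out.append((names[i], fc, p))
    qs = bh_qvalues([p for _, _, p in out])
    return [GroupComparison(n, fc, p, float(q))
            for (n, fc, p), q in zip(out, qs)]


def _feature_names(table: FeatureTable) -> list[str]:
    ids = table.features["feature_id"].tolist()
    idents = table.features["identity"].tolist()
    return [i if (i is not None and not pd.isna(i)) else f
            for f, i in zip(ids, idents)]
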