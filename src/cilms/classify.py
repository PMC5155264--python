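"""Biomarker-panel evaluation and the two-step severity cascade.

Implements binary logistic regression (IRLS with a ridge fallback for
separable small-n data), ROC analysis with the Hanley-McNeil confidence
interval, combined-probability panel scoring, greedy forward feature
ranking by leave-one-out accuracy, and the two-step cascade that
assigns AIS grades A/B/C: first A vs non-A on all samples, then C vs
non-C among the predicted non-A (the remainder is graded B), each step
evaluated by leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import FeatureTable
from .stats import anova_tukey, impute_half_min, _feature_names


@dataclass(frozen=True)
class LogisticModel:
    feature_names: tuple
    coefficients: np.ndarray
    intercept: float
    converged: bool
    n_iterations: int
    ridge: float = 0.0

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


@dataclass(frozen=True)
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    ci95: tuple[float, float]
    cutoff: float


@dataclass
class CascadeResult:
    step1_model: LogisticModel
    step2_model: LogisticModel
    step1_features: tuple
    step2_features: tuple
    confusion: pd.DataFrame          # true A/B/C x predicted A/B/C
    step1_accuracy: float            # printed percentage, one decimal
    step2_accuracy: float
    overall_accuracy: float
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)


def fit_logistic(X, y, feature_names=None, *, max_iter: int = 100,
                 tol: float = 1e-8, ridge_fallback: float = 1e-4
                 ) -> LogisticModel:
    """Maximum-likelihood binary logistic regression via IRLS.

    Newton/IRLS iterations stop when the log-likelihood improves by less
    than ``tol`` or after ``max_iter`` rounds.  When the fit diverges
    (quasi-complete separation, unbounded coefficients) it is retried
    with a small L2 penalty ``ridge_fallback`` and flagged via
    ``converged=False``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.any(np.all(X == 0, axis=0)):
        raise ValueError("constant-zero feature column")
    names = tuple(feature_names) if feature_names is not None \
        else tuple(f"x{j}" for j in range(X.shape[1]))

    beta, ok, n_it = _irls(X, y, 0.0, max_iter, tol)
    ridge = 0.0
    if not ok:
        beta, _, n_it = _irls(X, y, ridge_fallback, max_iter, tol)
        ridge = ridge_fallback
    return LogisticModel(names, beta[1:].copy(), float(beta[0]),
                         converged=ok, n_iterations=n_it, ridge=ridge)


def _irls(X, y, ridge, max_iter, tol):
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = ridge * np.eye(p + 1)
    pen[0, 0] = 0.0  # intercept unpenalized
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = np.clip(Xd @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta)))
                   - 0.5 * ridge * beta[1:] @ beta[1:])
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = Xd.T @ (y - mu) - pen @ beta
        H = (Xd * w[:, None]).T @ Xd + pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False, it
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
            return beta, False, it
        if abs(ll - ll_old) < tol:
            # a deviance collapsing to zero means the classes are
            # (quasi-)separated and the MLE does not exist
            return beta, ll < -1e-6, it
        ll_old = ll
    return beta, False, max_iter


def roc(scores, labels) -> RocResult:
    """ROC analysis of a score against binary labels.

    AUC is the tie-corrected Mann-Whitney statistic; the operating
    cutoff maximizes Youden's J (sensitivity + specificity - 1); the
    95% CI uses the Hanley-McNeil variance formula.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    n1 = int(lab.sum())
    n0 = len(lab) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    auc = (ranks[lab == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    # Youden-optimal cutoff over midpoints between adjacent distinct scores
    uniq = np.unique(s)
    cuts = np.concatenate([[uniq[0] - 1],
                           (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best = None
    for c in cuts:
        pred = s > c
        sens = (pred & (lab == 1)).sum() / n1
        spec = (~pred & (lab == 0)).sum() / n0
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), float(sens), float(spec))
    _, cutoff, sens, spec = best
    a = float(auc)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a)
           + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    se = np.sqrt(max(var, 0.0))
    ci = (max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se))
    return RocResult(auc=a, sensitivity=sens, specificity=spec,
                     ci95=ci, cutoff=cutoff)


def combined_probability(X_panel, y, feature_names=None) -> np.ndarray:
    """Panel score: fitted class-1 probabilities of a logistic model on
    the panel features."""
    model = fit_logistic(X_panel, y, feature_names)
    return model.predict_proba(np.atleast_2d(np.asarray(X_panel, dtype=float)))


def loocv_accuracy(X, y, threshold: float = 0.5) -> float:
    """Leave-one-out accuracy of a logistic model on the given features."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    return float(np.mean((loocv_probabilities(X, y) > threshold) == (y == 1)))


def loocv_probabilities(X, y) -> np.ndarray:
    """Held-out class-1 probability for each sample, from a model fit on
    all other samples."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    probs = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        if len(np.unique(y[mask])) < 2:
            probs[i] = float(np.mean(y[mask]))
            continue
        m = fit_logistic(X[mask], y[mask])
        probs[i] = float(m.predict_proba(X[i:i + 1])[0])
    return probs


def greedy_stepwise_rank(X, y, feature_names, *, max_features: int = 6,
                         anova_p=None, criterion=None) -> list[str]:
    """Forward greedy feature ranking.

    At each step the feature whose addition maximizes the criterion
    (default: LOOCV accuracy of the logistic panel) joins the panel;
    ties break toward the smaller ANOVA p-value when supplied, then
    input order.  Stops at ``max_features`` or when no candidate
    improves the criterion.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = list(feature_names)
    if X.shape[1] != len(names):
        raise ValueError("feature_names length must match X columns")
    if not names:
        raise ValueError("empty feature set")
    crit = criterion if criterion is not None else (
        lambda cols: loocv_accuracy(X[:, cols], y))
    pvals = (list(anova_p) if anova_p is not None
             else [np.inf] * len(names))
    selected: list[int] = []
    best_score = -np.inf
    while len(selected) < min(max_features, len(names)):
        candidates = []
        for j in range(len(names)):
            if j in selected:
                continue
            score = crit(selected + [j])
            candidates.append((score, -pvals[j], -j))
        candidates.sort(reverse=True)
        score, negp, negj = candidates[0]
        if score <= best_score:
            break
        best_score = score
        selected.append(-int(negj))
    return [names[j] for j in selected]


def accuracy_report(n_correct: int, n_total: int) -> float:
    """Prediction accuracy as a percentage rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    if n_correct < 0 or n_correct > n_total:
        raise ValueError("correct count out of range")
    return round(100.0 * n_correct / n_total, 1)


def cascade_loocv(table: FeatureTable, *, time_window: str = "t1",
                  max_features: int = 6, threshold: float = 0.5,
                  nested: bool = False) -> CascadeResult:
    """Two-step AIS-grade cascade with leave-one-out cross-validation.

    Step 1 predicts grade A vs non-A over every graded sample at the
    chosen time window; samples predicted non-A proceed to step 2, which
    predicts C vs non-C (non-C is assigned B).  Features for each step
    are ranked by the greedy stepwise procedure over the ANOVA-significant
    pool (p < 0.05 across A/B/C).  With ``nested=True`` the ranking is
    redone inside every leave-one-out fold (no selection optimism);
    otherwise selection is performed once on the full data before LOOCV.
    The reported models are refit on all samples involved in each step.
    """
    ids, grades = _cascade_samples(table, time_window)
    for g in ("A", "B", "C"):
        if (grades == g).sum() < 2:
            raise ValueError(f"need at least 2 samples of grade {g}")
    values = impute_half_min(table.values[ids])
    names = _feature_names(table)
    Xall = values.to_numpy().T  # samples x features

    pool_idx, pool_p = _anova_pool(Xall, grades, names)
    y1 = (grades == "A").astype(float)

    sel1 = _select(Xall, y1, names, pool_idx, pool_p, max_features)
    idx1 = [names.index(f) for f in sel1]
    if nested:
        p1 = _nested_loocv_probs(Xall, y1, names, pool_idx, pool_p, max_features)
    else:
        p1 = loocv_probabilities(Xall[:, idx1], y1)
    pred_A = p1 > threshold

    final = np.array(["B"] * len(ids), dtype=object)
    final[pred_A] = "A"
    step2_mask = ~pred_A
    X2 = Xall[step2_mask]
    g2 = grades[step2_mask]
    y2 = (g2 == "C").astype(float)
    if len(np.unique(y2)) < 2:
        raise ValueError("step 2 has a single class among predicted non-A")
    sel2 = _select(X2, y2, names, pool_idx, pool_p, max_features)
    idx2 = [names.index(f) for f in sel2]
    if nested:
        p2 = _nested_loocv_probs(X2, y2, names, pool_idx, pool_p, max_features)
    else:
        p2 = loocv_probabilities(X2[:, idx2], y2)
    final[np.flatnonzero(step2_mask)[p2 > threshold]] = "C"

    order = ["A", "B", "C"]
    conf = pd.DataFrame(0, index=order, columns=order)
    for t, p in zip(grades, final):
        conf.loc[t, p] += 1
    n = len(ids)
    step1_correct = int((pred_A == (grades == "A")).sum())
    step2_correct = int(((p2 > threshold) == (g2 == "C")).sum())
    overall_correct = int(np.trace(conf.to_numpy()))
    model1 = fit_logistic(Xall[:, idx1], y1, sel1)
    model2 = fit_logistic(X2[:, idx2], y2, sel2)
    preds = pd.DataFrame({"sample_id": ids, "true_grade": grades,
                          "p_step1": p1, "predicted": final})
    return CascadeResult(
        step1_model=model1, step2_model=model2,
        step1_features=tuple(sel1), step2_features=tuple(sel2),
        confusion=conf,
        step1_accuracy=accuracy_report(step1_correct, n),
        step2_accuracy=accuracy_report(step2_correct, len(g2)),
        overall_accuracy=accuracy_report(overall_correct, n),
        predictions=preds)


def _cascade_samples(table, time_window):
    ids, grades = [], []
    for s in table.samples:
        if s.grade in ("A", "B", "C") and s.time_window == time_window and not s.is_qc:
            ids.append(s.sample_id)
            grades.append(s.grade)
    if not ids:
        raise ValueError(f"no graded samples at {time_window!r}")
    return ids, np.array(grades, dtype=object)


def _anova_pool(X, grades, names, alpha: float = 0.05):
    """Features with ANOVA p < alpha across the three grades; returns
    (indices, p-values aligned with `names`)."""
    pvals = np.full(len(names), np.inf)
    for j in range(X.shape[1]):
        by_group = {g: X[grades == g, j] for g in ("A", "B", "C")}
        try:
            p, _ = anova_tukey(by_group)
        except ValueError:
            continue
        pvals[j] = p
    idx = [j for j in range(len(names)) if pvals[j] < alpha]
    if not idx:
        raise ValueError("no feature passes the ANOVA pre-filter")
    return idx, pvals


def _select(X, y, names, pool_idx, pool_p, max_features):
    pool_names = [names[j] for j in pool_idx]
    sub = X[:, pool_idx]
    return greedy_stepwise_rank(sub, y, pool_names, max_features=max_features,
                                anova_p=[pool_p[j] for j in pool_idx])


def _nested_loocv_probs(X, y, names, pool_idx, pool_p, max_features):
    n = len(y)
    probs = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        if len(np.unique(y[mask])) < 2:
            probs[i] = float(np.mean(y[mask]))
            continue
        sel = _select(X[mask], y[mask], names, pool_idx, pool_p, max_features)
        idx = [names.index(f) for f in sel]
        m = fit_logistic(X[mask][:, idx], y[mask], sel)
        probs[i] = float(m.predict_proba(X[i:i + 1, idx])[0])
    return probs
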