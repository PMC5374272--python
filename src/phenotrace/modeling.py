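"""Candidate logistic symptom models, cross-validated AUC selection, reporting.

For each binary symptom the three representative features span a fixed
candidate space of 10 logistic model forms — every single feature, every
feature pair with and without its interaction, and the full main-effects
model.  Each candidate is fit by maximum likelihood and scored by pooled
out-of-fold predictions from seeded, stratified 10-fold cross-validation;
the candidate with the highest cross-validated area under the ROC curve is
selected (ties favor the more parsimonious form).  Threshold metrics
(sensitivity, specificity, PPV, NPV, accuracy) are reported on the pooled
out-of-fold scores.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

SYMPTOMS = ("depressed_mood", "diminished_interest", "fatigue", "avoidance")


class ModelingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateModel:
    """A symbolic logistic model form over named features."""

    symptom: str
    terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.terms:
            raise ModelingError("candidate must have at least one main effect")
        if len(set(self.terms)) != len(self.terms):
            raise ModelingError("duplicate main-effect terms")
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ModelingError(f"interaction ({a},{b}) not covered by main effects")

    @property
    def n_coefficients(self) -> int:
        return 1 + len(self.terms) + len(self.interactions)

    def formula(self) -> str:
        parts = list(self.terms) + [f"{a}:{b}" for a, b in self.interactions]
        return "+".join(parts)


def enumerate_candidates(features: list[str], symptom: str) -> list[CandidateModel]:
    """The 10 candidate forms over exactly 3 representative features.

    3 single-feature + 3 two-feature main-effects + 3 two-feature with
    interaction + 1 three-feature main-effects, in deterministic order.
    """
    if len(features) != 3 or len(set(features)) != 3:
        raise ModelingError(
            f"the 10-candidate scheme is defined for exactly 3 distinct features, got {features}"
        )
    cands = [CandidateModel(symptom, (f,)) for f in features]
    pairs = list(itertools.combinations(features, 2))
    cands += [CandidateModel(symptom, p) for p in pairs]
    cands += [CandidateModel(symptom, p, (p,)) for p in pairs]
    cands.append(CandidateModel(symptom, tuple(features)))
    return cands


def enumerate_candidates_general(features: list[str], symptom: str) -> list[CandidateModel]:
    """Generalized candidate scheme for k != 3 surviving features.

    All single-feature models, all two-feature main-effect models, all
    two-feature models with interaction, and the full main-effects model
    (for 3 features this reproduces :func:`enumerate_candidates`).
    """
    if len(features) == 3:
        return enumerate_candidates(features, symptom)
    if not features or len(set(features)) != len(features):
        raise ModelingError(f"need distinct, nonempty features, got {features}")
    cands = [CandidateModel(symptom, (f,)) for f in features]
    pairs = list(itertools.combinations(features, 2))
    cands += [CandidateModel(symptom, p) for p in pairs]
    cands += [CandidateModel(symptom, p, (p,)) for p in pairs]
    if len(features) > 1:
        cands.append(CandidateModel(symptom, tuple(features)))
    return cands


# ---------------------------------------------------------------------------
# Maximum-likelihood logistic fitting (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    coefficients: dict[str, float]
    converged: bool
    n_used: int
    log_likelihood: float


def build_design(values: pd.DataFrame, candidate: CandidateModel) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) for a candidate; interactions on raw scale."""
    cols = [np.ones(len(values))]
    names = ["(Intercept)"]
    for term in candidate.terms:
        cols.append(values[term].to_numpy(dtype=float))
        names.append(term)
    for a, b in candidate.interactions:
        cols.append(values[a].to_numpy(dtype=float) * values[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def fit_logistic(
    design: np.ndarray,
    y: np.ndarray,
    term_names: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    separation_bound: float = 15.0,
) -> FittedModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence when the log-likelihood change falls below ``tol`` (or 100
    iterations).  Perfect/quasi-perfect separation is detected as any
    standardized-scale coefficient magnitude above ``separation_bound``;
    the fit is then flagged ``converged=False`` but its scores remain
    usable.  A rank-deficient design raises, naming an aliased term.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if term_names is None:
        term_names = [f"b{j}" for j in range(X.shape[1])]
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ModelingError("y must be binary with both classes present")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an aliased column via pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = term_names[int(np.argmin(diag))]
        raise ModelingError(f"rank-deficient design: term {aliased!r} is aliased")

    beta = np.zeros(X.shape[1])
    beta[0] = float(np.log(np.clip(y.mean(), 1e-9, 1 - 1e-9) / (1 - np.clip(y.mean(), 1e-9, 1 - 1e-9))))
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as exc:
            raise ModelingError(f"IRLS normal equations singular: {exc}") from exc

    # separation diagnostic on the standardized scale
    sds = X.std(axis=0, ddof=0)
    sds[0] = 1.0  # intercept
    std_beta = beta * np.where(sds > 0, sds, 1.0)
    if np.any(np.abs(std_beta[1:]) > separation_bound):
        converged = False

    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return FittedModel(
        coefficients={n: float(b) for n, b in zip(term_names, beta)},
        converged=converged,
        n_used=len(y),
        log_likelihood=ll,
    )


def predict_proba(fit: FittedModel, design: np.ndarray, term_names: list[str]) -> np.ndarray:
    beta = np.array([fit.coefficients[n] for n in term_names])
    return expit(np.asarray(design, dtype=float) @ beta)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Pooled ROC by descending-score threshold sweep (ties grouped) and its AUC.

    The trapezoidal AUC over the tie-grouped curve equals the Mann-Whitney
    pair statistic with ties counted one half.  The curve starts at (0,0)
    and ends at (1,1); points are (FPR, TPR).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = float((labels == 1).sum())
    n_neg = float((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ModelingError("labels must contain both classes")
    order = np.argsort(-scores, kind="mergesort")
    s, lab = scores[order], labels[order]
    # group tied scores
    boundary = np.nonzero(np.diff(s))[0]
    tp = np.cumsum(lab)
    fp = np.cumsum(1.0 - lab)
    idx = np.append(boundary, len(s) - 1)
    tpr = np.concatenate([[0.0], tp[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp[idx] / n_neg])
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return roc, auc


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    candidate: CandidateModel
    fold_assignment: dict[str, int]
    oof_scores: dict[str, float]
    roc: np.ndarray
    auc: float
    fold_aucs: list[float] = field(default_factory=list)


def _stratified_folds(
    y: np.ndarray, folds: int, seed: int, max_tries: int = 100
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified folds, re-drawn until every training set has both classes."""
    for attempt in range(max_tries):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        try:
            split = list(skf.split(np.zeros_like(y), y))
        except ValueError as exc:
            raise ModelingError(
                f"cannot form {folds} stratified folds: {exc}; try fewer folds"
            ) from exc
        if all(len(np.unique(y[tr])) == 2 for tr, _ in split):
            return split
    raise ModelingError(
        f"could not draw {folds} folds with both classes in every training set; try fewer folds"
    )


def cv_auc(
    candidate: CandidateModel,
    values: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Pooled out-of-fold ROC/AUC for one candidate under seeded stratified CV.

    ``values`` rows are participants (complete cases for the candidate's
    features); ``labels`` aligns with the rows.  Every participant is
    scored exactly once out-of-fold and a single pooled ROC is computed.
    """
    y = np.asarray(labels, dtype=float)
    ids = list(values.index)
    X, names = build_design(values, candidate)
    split = _stratified_folds(y, folds, seed)
    oof = np.full(len(y), np.nan)
    assignment: dict[str, int] = {}
    fold_aucs: list[float] = []
    for k, (tr, te) in enumerate(split, start=1):
        fit = fit_logistic(X[tr], y[tr], names)
        oof[te] = predict_proba(fit, X[te], names)
        for i in te:
            assignment[ids[i]] = k
        if len(np.unique(y[te])) == 2:
            _, fa = roc_and_auc(oof[te], y[te])
            fold_aucs.append(fa)
    roc, auc = roc_and_auc(oof, y)
    return CVResult(
        candidate=candidate,
        fold_assignment=assignment,
        oof_scores={pid: float(s) for pid, s in zip(ids, oof)},
        roc=roc,
        auc=auc,
        fold_aucs=fold_aucs,
    )


def select_best(cv_results: list[CVResult]) -> CVResult:
    """Highest pooled CV AUC; ties -> fewest coefficients, then input order."""
    if not cv_results:
        raise ModelingError("no candidates scored")
    best = cv_results[0]
    for res in cv_results[1:]:
        if res.auc > best.auc + 1e-12:
            best = res
        elif abs(res.auc - best.auc) <= 1e-12:
            if res.candidate.n_coefficients < best.candidate.n_coefficients:
                best = res
    return best


# ---------------------------------------------------------------------------
# Threshold metrics
# ---------------------------------------------------------------------------

def threshold_metrics(
    oof_scores: np.ndarray, labels: np.ndarray, thresholds: list[float]
) -> pd.DataFrame:
    """Sensitivity/specificity/PPV/NPV/accuracy at each threshold.

    Predict positive iff score >= threshold.  PPV/NPV are NaN when no
    participant is predicted positive/negative.
    """
    scores = np.asarray(oof_scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ModelingError("labels must contain both classes")
    rows = []
    for thr in thresholds:
        pred = scores >= thr
        tp = float(np.sum(pred & (y == 1)))
        fp = float(np.sum(pred & (y == 0)))
        fn = float(np.sum(~pred & (y == 1)))
        tn = float(np.sum(~pred & (y == 0)))
        rows.append(
            {
                "threshold": thr,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
                "ppv": tp / (tp + fp) if (tp + fp) > 0 else math.nan,
                "npv": tn / (tn + fn) if (tn + fn) > 0 else math.nan,
                "accuracy": (tp + tn) / len(y),
            }
        )
    return pd.DataFrame(rows)
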