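"""Feature reduction before modeling.

Two strategies, matching the two data sources:

* **Correlation clustering** for the trace catalogue — agglomerative
  (average linkage) clustering of features on the distance ``1 - |r|``
  (absolute Pearson correlation), cut at a fixed number of clusters
  (default 3), with one representative per cluster: the feature with the
  highest mean absolute correlation to its co-members.

* **LASSO-screened logistic regression** for the acoustic registry —
  an L1-penalized logistic path solved by coordinate descent over a
  geometric penalty grid from the analytic ``lambda_max`` down three
  decades, with the penalty chosen by 10-fold cross-validated binomial
  deviance.  Predictors are standardized internally; coefficients are
  reported on the original scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.model_selection import StratifiedKFold


class ReductionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Correlation clustering
# ---------------------------------------------------------------------------

@dataclass
class FeatureClusters:
    """Cluster assignment and per-cluster representative features."""

    assignments: dict[str, int]
    representatives: dict[int, str]
    linkage_heights: list[float]

    def representative_features(self) -> list[str]:
        return [self.representatives[c] for c in sorted(self.representatives)]


def correlation_cluster(
    values: pd.DataFrame, n_clusters: int = 3, min_pairwise: int = 3
) -> FeatureClusters:
    """Group correlated features and pick one representative per group.

    ``values`` is a participants x features frame (NaN = missing); Pearson
    correlations use pairwise-complete observations with at least
    ``min_pairwise`` pairs.  Distance is ``1 - |r|`` with average linkage;
    the dendrogram is cut to exactly ``n_clusters``.  Representative =
    feature maximizing mean |r| to its cluster co-members (singleton
    clusters represent themselves); ties break lexicographically.
    """
    names = list(values.columns)
    if n_clusters > len(names):
        raise ReductionError(
            f"n_clusters={n_clusters} exceeds the {len(names)} available features"
        )
    stds = values.std(ddof=1)
    constant = [n for n in names if not np.isfinite(stds[n]) or stds[n] == 0]
    if constant:
        raise ReductionError(f"constant feature(s): {', '.join(constant)}")

    corr = values.corr(method="pearson", min_periods=min_pairwise)
    if corr.isna().any().any():
        bad = [n for n in names if corr[n].isna().any()]
        raise ReductionError(
            f"insufficient pairwise-complete observations for: {', '.join(bad)}"
        )
    absr = corr.abs().to_numpy()
    dist = 1.0 - absr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    link = average(squareform(dist, checks=False))
    flat = fcluster(link, t=n_clusters, criterion="maxclust")

    assignments = {name: int(c) for name, c in zip(names, flat)}
    representatives: dict[int, str] = {}
    for cluster in sorted(set(flat)):
        members = sorted(n for n, c in assignments.items() if c == cluster)
        if len(members) == 1:
            representatives[cluster] = members[0]
            continue
        best_name, best_score = None, -np.inf
        for name in members:
            others = [m for m in members if m != name]
            score = float(np.mean([abs(corr.loc[name, o]) for o in others]))
            if score > best_score + 1e-12:
                best_name, best_score = name, score
        representatives[cluster] = best_name
    return FeatureClusters(
        assignments=assignments,
        representatives=representatives,
        linkage_heights=[float(h) for h in link[:, 2]],
    )


# ---------------------------------------------------------------------------
# LASSO-penalized logistic screening
# ---------------------------------------------------------------------------

@dataclass
class LassoPath:
    """An L1 logistic path with cross-validated deviance per penalty."""

    feature_names: list[str]
    lambdas: np.ndarray
    coefficients: np.ndarray  # (n_lambda, n_features), original scale
    coefficients_std: np.ndarray  # same, on the standardized scale
    intercepts: np.ndarray
    cv_deviance_mean: np.ndarray | None = None
    cv_deviance_se: np.ndarray | None = None
    monotonicity_violations: list[int] = field(default_factory=list)

    def coef_at(self, lam: float) -> tuple[float, np.ndarray]:
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return float(self.intercepts[i]), self.coefficients[i]


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _cd_logistic_l1(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta0: float,
    beta: np.ndarray,
    tol: float = 1e-8,
    max_outer: int = 200,
) -> tuple[float, np.ndarray]:
    """One penalized fit by IRLS-outer / coordinate-descent-inner.

    Minimizes ``-(1/n) loglik + lam * ||beta||_1`` on standardized X.
    Convergence: max absolute coefficient change below ``tol`` across an
    outer iteration.
    """
    n, p = X.shape
    beta = beta.copy()
    for _ in range(max_outer):
        eta = beta0 + X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        delta_max = 0.0
        for _sweep in range(100):
            sweep_delta = 0.0
            r = z - beta0 - X @ beta
            # intercept (unpenalized)
            new0 = beta0 + float(w @ r) / float(w.sum())
            r += beta0 - new0
            sweep_delta = max(sweep_delta, abs(new0 - beta0))
            beta0 = new0
            for j in range(p):
                xj = X[:, j]
                rho = float((w * xj) @ r) / n + float((w * xj) @ xj) / n * beta[j]
                denom = float((w * xj) @ xj) / n
                new = _soft_threshold(rho, lam) / denom
                if new != beta[j]:
                    r += xj * (beta[j] - new)
                    sweep_delta = max(sweep_delta, abs(new - beta[j]))
                    beta[j] = new
            delta_max = max(delta_max, sweep_delta)
            if sweep_delta < tol:
                break
        if delta_max < tol:
            break
    return beta0, beta


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every slope is exactly zero: max|X'(y-ybar)|/n."""
    n = len(y)
    return float(np.max(np.abs(X_std.T @ (y - y.mean()))) / n)


def lasso_logistic_path(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 50,
    folds: int = 10,
    seed: int = 0,
    cv: bool = True,
) -> LassoPath:
    """Fit the L1 logistic path and (optionally) 10-fold CV deviance.

    Predictors are standardized internally (mean 0, SD 1); reported
    coefficients are rescaled to the original feature units.  The default
    grid is geometric over three decades down from the analytic
    ``lambda_max``.  Folds are stratified by class and seeded.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xmat = X.to_numpy(dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xmat.shape[1])]
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ReductionError("y must be binary with both classes present")
    sd = Xmat.std(axis=0, ddof=0)
    zero_var = [names[j] for j in range(len(names)) if sd[j] == 0]
    if zero_var:
        raise ReductionError(f"zero-variance column(s): {', '.join(zero_var)}")
    mean = Xmat.mean(axis=0)
    Xs = (Xmat - mean) / sd

    if lambdas is None:
        lmax = lambda_max(Xs, y)
        lambdas = np.geomspace(lmax, lmax * 1e-3, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ReductionError("lambdas must be decreasing")

    def _fit_path(Xs_fit, y_fit):
        p = Xs_fit.shape[1]
        b0 = float(np.log(y_fit.mean() / (1.0 - y_fit.mean())))
        b = np.zeros(p)
        b0s, betas = [], []
        for lam in lambdas:
            b0, b = _cd_logistic_l1(Xs_fit, y_fit, lam, b0, b)
            b[np.abs(b) < 1e-12] = 0.0  # shed numerical dust at the KKT boundary
            b0s.append(b0)
            betas.append(b.copy())
        return np.array(b0s), np.array(betas)

    intercepts_std, betas_std = _fit_path(Xs, y)

    # Original-scale coefficients.
    coefs = betas_std / sd
    intercepts = intercepts_std - coefs @ mean

    violations = []
    active = (np.abs(betas_std) > 0).sum(axis=1)
    for i in range(1, len(lambdas)):
        if active[i] < active[i - 1]:
            violations.append(i)

    path = LassoPath(
        feature_names=names,
        lambdas=lambdas,
        coefficients=coefs,
        coefficients_std=betas_std,
        intercepts=intercepts,
        monotonicity_violations=violations,
    )

    if cv:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        dev = np.empty((folds, len(lambdas)))
        for k, (tr, te) in enumerate(skf.split(Xs, y)):
            mu_tr = Xmat[tr].mean(axis=0)
            sd_tr = Xmat[tr].std(axis=0, ddof=0)
            sd_tr[sd_tr == 0] = 1.0
            Xs_tr = (Xmat[tr] - mu_tr) / sd_tr
            Xs_te = (Xmat[te] - mu_tr) / sd_tr
            b0s, betas = _fit_path(Xs_tr, y[tr])
            for i in range(len(lambdas)):
                eta = b0s[i] + Xs_te @ betas[i]
                dev[k, i] = _binomial_deviance(y[te], expit(eta))
        path.cv_deviance_mean = dev.mean(axis=0)
        path.cv_deviance_se = dev.std(axis=0, ddof=1) / math.sqrt(folds)
    return path


def select_lambda(path: LassoPath) -> float:
    """Penalty minimizing mean CV deviance; ties go to the largest (sparsest)."""
    if path.cv_deviance_mean is None:
        raise ReductionError("path has no cross-validated deviance")
    dev = path.cv_deviance_mean
    best = dev.min()
    tied = np.nonzero(np.isclose(dev, best, rtol=0.0, atol=1e-12))[0]
    return float(path.lambdas[tied.min()])  # grid is decreasing: first index = largest


def surviving_features(path: LassoPath, lam: float) -> list[str]:
    """Features with nonzero coefficient at ``lam``, by decreasing standardized |coef|.

    Magnitudes are compared on the standardized scale so the ordering is
    unit-free.
    """
    i = int(np.argmin(np.abs(path.lambdas - lam)))
    coefs = path.coefficients_std[i]
    order = [
        (name, abs(coefs[j])) for j, name in enumerate(path.feature_names) if coefs[j] != 0.0
    ]
    return [name for name, _ in sorted(order, key=lambda kv: (-kv[1], kv[0]))]
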