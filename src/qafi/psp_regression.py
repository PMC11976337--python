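"""Protein-specific predictors: balanced multiple linear regression on the
14-feature vectors, position-grouped cross-validation, and Lasso feature
introspection.

DMS score distributions are typically bimodal and imbalanced (a functional
peak near 1 and a damaged peak well below it). Before fitting, a two-component
Gaussian mixture locates the boundary between the peaks and the larger group
is randomly undersampled to the size of the smaller one; balancing is applied
to training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

from .model_io import DMSDataset
from .structure_features import FEATURE_NAMES


class RegressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


@dataclass
class FeatureScaler:
    """Per-feature min/max from the training split; maps features to [0, 1].

    Test-time values outside the training range are clipped to [0, 1].
    Features that were constant in training map to 0.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise RegressionError("scaler max below min")

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        scaled = (X - self.mins) / safe
        scaled = np.where(span > 0, scaled, 0.0)
        return np.clip(scaled, 0.0, 1.0)


# ---------------------------------------------------------------------------
# models and reports
# ---------------------------------------------------------------------------


@dataclass
class PSPModel:
    """One protein-specific predictor: 14 OLS weights over scaled features."""

    protein_id: str
    weights: np.ndarray
    intercept: float
    scaler: FeatureScaler
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(FEATURE_NAMES),):
            raise RegressionError(
                f"expected {len(FEATURE_NAMES)} weights, got {self.weights.shape}"
            )
        if not (
            np.all(np.isfinite(self.weights)) and np.isfinite(self.intercept)
        ):
            raise RegressionError("non-finite model parameters")

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = _as_matrix(features)
        return self.scaler.transform(X) @ self.weights + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": "psp",
            "protein_id": self.protein_id,
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "scaler": {
                "mins": self.scaler.mins.tolist(),
                "maxs": self.scaler.maxs.tolist(),
            },
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PSPModel":
        return cls(
            protein_id=d["protein_id"],
            weights=np.array(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            scaler=FeatureScaler(
                mins=np.array(d["scaler"]["mins"]),
                maxs=np.array(d["scaler"]["maxs"]),
            ),
            metadata=d.get("metadata", {}),
        )


@dataclass
class ThresholdFit:
    """GMM-derived boundary between the two DMS score peaks."""

    value: float
    degenerate: bool
    means: tuple[float, float]
    sigmas: tuple[float, float]
    mix_weights: tuple[float, float]


@dataclass
class BalancedSplit:
    retained: np.ndarray
    gmm_threshold: float
    sizes_before: tuple[int, int]
    sizes_after: tuple[int, int]

    def __post_init__(self) -> None:
        if self.sizes_after[0] != self.sizes_after[1]:
            raise RegressionError("balanced groups unequal in size")


@dataclass
class CVResult:
    observed: np.ndarray
    predicted: np.ndarray
    positions: np.ndarray
    pearson: float
    mae: float
    unbalanced_folds: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _as_matrix(features: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[FEATURE_NAMES].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def fit_gmm_threshold(
    scores: Sequence[float] | np.ndarray, seed: int = 0
) -> ThresholdFit:
    """Boundary between the two score peaks of a bimodal DMS distribution.

    Fits a two-component univariate Gaussian mixture and returns the
    equal-posterior decision boundary between the component means (the real
    root of the equal-posterior equation closest to the midpoint of the
    means). Degenerate fits (collapsed components) fall back to the median,
    flagged.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 10:
        raise RegressionError("need at least 10 scores for a mixture fit")
    if np.ptp(scores) == 0:
        m = float(scores[0])
        return ThresholdFit(m, True, (m, m), (0.0, 0.0), (0.5, 0.5))
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(scores[:, None])
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sigmas[order]
    w1, w2 = weights[order]
    degenerate = (m2 - m1) < 1e-6 * max(1.0, np.ptp(scores)) or min(w1, w2) < 1e-3
    if degenerate:
        return ThresholdFit(
            float(np.median(scores)), True,
            (float(m1), float(m2)), (float(s1), float(s2)), (float(w1), float(w2)),
        )
    boundary = _equal_posterior_boundary(m1, s1, w1, m2, s2, w2)
    return ThresholdFit(
        float(boundary), False,
        (float(m1), float(m2)), (float(s1), float(s2)), (float(w1), float(w2)),
    )


def _equal_posterior_boundary(m1, s1, w1, m2, s2, w2) -> float:
    """Root of w1 N(x; m1, s1) = w2 N(x; m2, s2) nearest the mean midpoint."""
    mid = 0.5 * (m1 + m2)
    a = 0.5 * (1 / s2**2 - 1 / s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (
        0.5 * (m2**2 / s2**2 - m1**2 / s1**2)
        + np.log(w1 / w2)
        + np.log(s2 / s1)
    )
    if abs(a) < 1e-12:  # equal variances: linear equation
        return -c / b if b != 0 else mid
    disc = b**2 - 4 * a * c
    if disc < 0:
        return mid
    roots = np.array([(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)])
    between = roots[(roots > m1) & (roots < m2)]
    candidates = between if len(between) else roots
    return float(candidates[np.argmin(np.abs(candidates - mid))])


def balance_by_undersampling(
    dataset: DMSDataset, threshold: float, seed: int = 0
) -> BalancedSplit:
    """Equalize the two peak groups by undersampling the larger one."""
    low = np.flatnonzero(dataset.scores <= threshold)
    high = np.flatnonzero(dataset.scores > threshold)
    if len(low) == 0 or len(high) == 0:
        raise RegressionError("one score group is empty; cannot balance")
    rng = np.random.default_rng(seed)
    if len(low) > len(high):
        low = np.sort(rng.choice(low, size=len(high), replace=False))
    elif len(high) > len(low):
        high = np.sort(rng.choice(high, size=len(low), replace=False))
    retained = np.sort(np.concatenate([low, high]))
    return BalancedSplit(
        retained=retained,
        gmm_threshold=float(threshold),
        sizes_before=(
            int((dataset.scores <= threshold).sum()),
            int((dataset.scores > threshold).sum()),
        ),
        sizes_after=(len(low), len(high)),
    )


def _fit_ols(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    design = np.column_stack([np.ones(len(X)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    collinear = rank < design.shape[1]
    return coef[1:], float(coef[0]), collinear


def fit_psp(
    dataset: DMSDataset,
    features: pd.DataFrame,
    balance: bool = True,
    seed: int = 0,
    protein_id: str | None = None,
) -> PSPModel:
    """Ordinary least squares on min-max-scaled features.

    The scaler is fit on the (optionally balanced) training rows themselves.
    Rank-deficient designs are fit by pseudo-inverse and flagged.
    """
    X_raw = _as_matrix(features)
    y = dataset.scores
    if len(X_raw) != len(y):
        raise RegressionError("features and dataset length mismatch")
    idx = np.arange(len(y))
    threshold = None
    if balance:
        fit = fit_gmm_threshold(y, seed=seed)
        threshold = fit.value
        try:
            idx = balance_by_undersampling(dataset, fit.value, seed=seed).retained
        except RegressionError:
            threshold = None  # one-sided distribution: fit unbalanced
    if len(idx) < len(FEATURE_NAMES) + 1:
        raise RegressionError(
            f"only {len(idx)} training variants after balancing; "
            f"need more than {len(FEATURE_NAMES)}"
        )
    scaler = FeatureScaler.fit(X_raw[idx])
    weights, intercept, collinear = _fit_ols(scaler.transform(X_raw[idx]), y[idx])
    train_pred = scaler.transform(X_raw[idx]) @ weights + intercept
    return PSPModel(
        protein_id=protein_id or dataset.protein_id,
        weights=weights,
        intercept=intercept,
        scaler=scaler,
        metadata={
            "n_variants": int(len(idx)),
            "n_total": int(len(y)),
            "seed": int(seed),
            "balanced": bool(balance and threshold is not None),
            "gmm_threshold": threshold,
            "collinear": bool(collinear),
            "train_pearson": _safe_pearson(y[idx], train_pred),
        },
    )


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(stats.pearsonr(a, b)[0])


def loocv_by_position(
    dataset: DMSDataset,
    features: pd.DataFrame,
    balance: bool = True,
    seed: int = 0,
) -> CVResult:
    """Position-grouped leave-one-out cross-validation.

    One fold per distinct position: all variants at that position are held
    out, the model (with per-fold balancing and scaling) is fit on the rest,
    and every variant is predicted exactly once. Folds whose training set
    loses a score group entirely are fit unbalanced and flagged.
    """
    X = _as_matrix(features)
    y = dataset.scores
    positions = dataset.positions
    distinct = np.unique(positions)
    if len(distinct) < 2:
        raise RegressionError("need at least 2 distinct positions")
    predicted = np.full(len(y), np.nan)
    unbalanced: list[int] = []
    for pos in distinct:
        test = positions == pos
        train = ~test
        y_tr = y[train]
        idx_tr = np.flatnonzero(train)
        sel = idx_tr
        used_balance = False
        if balance:
            try:
                fit = fit_gmm_threshold(y_tr, seed=seed)
                low = idx_tr[y_tr <= fit.value]
                high = idx_tr[y_tr > fit.value]
                if len(low) and len(high):
                    rng = np.random.default_rng(seed)
                    if len(low) > len(high):
                        low = rng.choice(low, size=len(high), replace=False)
                    elif len(high) > len(low):
                        high = rng.choice(high, size=len(low), replace=False)
                    sel = np.sort(np.concatenate([low, high]))
                    used_balance = True
            except RegressionError:
                pass
        if balance and not used_balance:
            unbalanced.append(int(pos))
        scaler = FeatureScaler.fit(X[sel])
        weights, intercept, _ = _fit_ols(scaler.transform(X[sel]), y[sel])
        predicted[test] = scaler.transform(X[test]) @ weights + intercept
    pearson = _safe_pearson(y, predicted)
    return CVResult(
        observed=y,
        predicted=predicted,
        positions=positions,
        pearson=np.nan if pearson is None else pearson,
        mae=float(np.mean(np.abs(y - predicted))),
        unbalanced_folds=unbalanced,
    )


@dataclass
class LassoReport:
    alphas: np.ndarray
    cv_mae: np.ndarray
    best_alpha: float
    abs_weights: dict[str, float]
    all_zero: bool


def lasso_importance(
    dataset: DMSDataset,
    features: pd.DataFrame,
    alpha_grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
) -> LassoReport:
    """L1 feature-importance analysis.

    Grid-searches the L1 penalty (default 10^-5 .. 10^2), selects the alpha
    with the lowest mean cross-validated absolute error, and reports the
    absolute feature weights of the model refit at that alpha on min-max
    scaled features.
    """
    if alpha_grid is None:
        alpha_grid = np.logspace(-5, 2, 29)
    X = _as_matrix(features)
    y = dataset.scores
    if len(y) < folds:
        raise RegressionError(f"need at least {folds} variants for {folds}-fold CV")
    scaler = FeatureScaler.fit(X)
    Xs = scaler.transform(X)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_mae = np.zeros(len(alpha_grid))
    for i, alpha in enumerate(alpha_grid):
        errs = []
        for tr, te in kf.split(Xs):
            model = Lasso(alpha=alpha, max_iter=50_000)
            model.fit(Xs[tr], y[tr])
            errs.append(np.mean(np.abs(y[te] - model.predict(Xs[te]))))
        cv_mae[i] = np.mean(errs)
    best = int(np.argmin(cv_mae))
    final = Lasso(alpha=alpha_grid[best], max_iter=50_000)
    final.fit(Xs, y)
    abs_w = np.abs(final.coef_)
    return LassoReport(
        alphas=alpha_grid,
        cv_mae=cv_mae,
        best_alpha=float(alpha_grid[best]),
        abs_weights=dict(zip(FEATURE_NAMES, abs_w.tolist())),
        all_zero=bool(np.all(abs_w == 0)),
    )
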