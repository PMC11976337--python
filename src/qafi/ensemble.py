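"""The generalizing ensemble: cross-prediction, predictor selection, median
aggregation and the calibrated pathogenic/benign threshold.

A variant in any protein is scored as the median of the selected
protein-specific predictors' outputs (default ten members), excluding the
member trained on the very protein being queried. Lower scores mean lower
residual function; scores at or below the calibrated threshold (default 0.82)
are called pathogenic, and scores above 1 indicate gain of function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import matthews_corrcoef, roc_curve

from .model_io import DMSDataset
from .psp_regression import PSPModel, _safe_pearson
from .structure_features import FeatureConfig


class EnsembleError(ValueError):
    pass


PATHOGENIC = "pathogenic"
BENIGN = "benign"


# ---------------------------------------------------------------------------
# cross-prediction
# ---------------------------------------------------------------------------


@dataclass
class CrossPredictionMatrix:
    """pearson[model_protein][target_protein]; diagonal = auto-prediction."""

    table: pd.DataFrame

    def __getitem__(self, key: tuple[str, str]) -> float:
        model, target = key
        return float(self.table.loc[model, target])


def cross_predict(
    models: Sequence[PSPModel],
    datasets: Sequence[tuple[DMSDataset, pd.DataFrame]],
) -> CrossPredictionMatrix:
    """Pearson correlation of every model's predictions on every dataset.

    Entry (m, t) applies model m (its own scaler, clipped) to the features of
    protein t and correlates with t's observed scores; constant predictions
    yield a missing (NaN) entry.
    """
    model_ids = [m.protein_id for m in models]
    target_ids = [ds.protein_id for ds, _ in datasets]
    table = pd.DataFrame(np.nan, index=model_ids, columns=target_ids)
    for m in models:
        for ds, feats in datasets:
            pred = m.predict(feats)
            r = _safe_pearson(ds.scores, pred)
            table.loc[m.protein_id, ds.protein_id] = np.nan if r is None else r
    return CrossPredictionMatrix(table=table)


# ---------------------------------------------------------------------------
# predictor selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    rounds: dict[str, list[str]]  # left-out protein -> candidate ids best-first
    mean_rank: dict[str, float]
    overall_median: dict[str, float]
    chosen: list[str]
    skipped_rounds: list[str] = field(default_factory=list)


def select_top_k(
    models: Sequence[PSPModel],
    datasets: Sequence[tuple[DMSDataset, pd.DataFrame]],
    k: int = 10,
    exclusions: Mapping[str, Sequence[str]] | None = None,
    matrix: CrossPredictionMatrix | None = None,
) -> SelectionReport:
    """Choose the k predictors that generalize best across proteins.

    One validation round per protein left out: each remaining candidate is
    scored by the median of its cross-prediction Pearsons over the other
    remaining proteins (never its own training protein) and candidates are
    ranked best-first. The final selection is the k models with the best mean
    rank over the rounds in which they were candidates; ties break by higher
    overall median Pearson, then lexicographic protein id.
    """
    ids = [m.protein_id for m in models]
    if len(set(ids)) != len(ids):
        raise EnsembleError("duplicate model protein ids")
    if k < 1 or k > len(models):
        raise EnsembleError(f"k={k} outside 1..{len(models)}")
    if len(models) < k + 1:
        raise EnsembleError("need at least k+1 models for leave-one-out rounds")
    exclusions = dict(exclusions or {})
    if matrix is None:
        matrix = cross_predict(models, datasets)
    target_ids = list(matrix.table.columns)

    def median_over(model_id: str, targets: list[str]) -> float:
        usable = [
            t
            for t in targets
            if t != model_id and t not in exclusions.get(model_id, ())
        ]
        vals = matrix.table.loc[model_id, usable].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(np.median(vals)) if len(vals) else np.nan

    rounds: dict[str, list[str]] = {}
    skipped: list[str] = []
    rank_sums: dict[str, float] = {i: 0.0 for i in ids}
    rank_counts: dict[str, int] = {i: 0 for i in ids}
    for left_out in sorted(target_ids):
        remaining = [t for t in target_ids if t != left_out]
        candidates = [i for i in ids if i != left_out]
        scores = {c: median_over(c, remaining) for c in candidates}
        evaluable = {c: s for c, s in scores.items() if not np.isnan(s)}
        if len(remaining) < 2 or len(evaluable) < 2:
            skipped.append(left_out)
            continue
        # rank best-first; ties share the mean rank
        vals = np.array([evaluable[c] for c in evaluable])
        ranks = stats.rankdata(-vals, method="average")
        ordered = sorted(evaluable, key=lambda c: (-evaluable[c], c))
        rounds[left_out] = ordered
        for c, r in zip(evaluable, ranks):
            rank_sums[c] += float(r)
            rank_counts[c] += 1
    mean_rank = {
        i: rank_sums[i] / rank_counts[i] for i in ids if rank_counts[i] > 0
    }
    overall = {i: median_over(i, target_ids) for i in ids}
    chosen = sorted(
        mean_rank,
        key=lambda i: (mean_rank[i], -overall.get(i, -np.inf), i),
    )[:k]
    return SelectionReport(
        rounds=rounds,
        mean_rank=mean_rank,
        overall_median=overall,
        chosen=chosen,
        skipped_rounds=skipped,
    )


# ---------------------------------------------------------------------------
# the ensemble predictor
# ---------------------------------------------------------------------------


@dataclass
class EnsembleModel:
    """Ordered set of protein-specific predictors aggregated by the median."""

    members: list[PSPModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise EnsembleError("empty ensemble")
        ids = [m.protein_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise EnsembleError("duplicate member protein ids")

    @property
    def member_ids(self) -> list[str]:
        return [m.protein_id for m in self.members]

    def predict(
        self,
        features: pd.DataFrame | np.ndarray,
        target_protein_id: str | None = None,
    ) -> np.ndarray:
        return qafi_predict(self, features, target_protein_id)

    def to_dict(self) -> dict:
        return {
            "kind": "ensemble",
            "aggregation": "median",
            "members": [m.to_dict() for m in self.members],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(members=[PSPModel.from_dict(m) for m in d["members"]])


def qafi_predict(
    ensemble: EnsembleModel,
    features: pd.DataFrame | np.ndarray,
    target_protein_id: str | None = None,
) -> np.ndarray:
    """Median of the member predictions for each variant.

    When the target protein trained one of the members, that member is
    excluded from the median. Even member counts use the mean of the two
    central order statistics. Predictions are not clamped: values above 1 are
    meaningful gain-of-function signals.
    """
    members = [
        m for m in ensemble.members if m.protein_id != target_protein_id
    ]
    if not members:
        raise EnsembleError("no members left after excluding the target protein")
    preds = np.stack([m.predict(features) for m in members])
    return np.median(preds, axis=0)


# ---------------------------------------------------------------------------
# threshold calibration and classification
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    grid: np.ndarray
    mcc_by_protein: pd.DataFrame  # proteins x thresholds
    median_mcc: np.ndarray
    threshold: float
    skipped_proteins: list[str] = field(default_factory=list)


def default_grid(cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    lo, hi = cfg.threshold_grid
    n = int(round((hi - lo) / cfg.threshold_step))
    return np.round(np.linspace(lo, hi, n + 1), 10)


def calibrate_threshold(
    scores_by_protein: Mapping[str, np.ndarray],
    labels_by_protein: Mapping[str, np.ndarray],
    grid: np.ndarray | None = None,
) -> CalibrationResult:
    """Sweep the decision threshold and maximize the median per-protein MCC.

    Variants with score <= threshold are called pathogenic. Proteins with a
    single label class are skipped (flagged). Ties on the median-MCC curve
    resolve to the lowest threshold.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    rows = {}
    skipped = []
    for pid, scores in scores_by_protein.items():
        labels = np.asarray(labels_by_protein[pid], dtype=int)
        scores = np.asarray(scores, dtype=float)
        if len(np.unique(labels)) < 2:
            skipped.append(pid)
            continue
        rows[pid] = [
            matthews_corrcoef(labels, (scores <= t).astype(int)) for t in grid
        ]
    if not rows:
        raise EnsembleError("no protein with both label classes")
    mcc = pd.DataFrame.from_dict(rows, orient="index", columns=grid)
    median = mcc.median(axis=0).to_numpy()
    best = int(np.argmax(median))  # argmax returns the first (lowest) maximum
    return CalibrationResult(
        grid=grid,
        mcc_by_protein=mcc,
        median_mcc=median,
        threshold=float(grid[best]),
        skipped_proteins=skipped,
    )


def classify(score: float, cfg: FeatureConfig = FeatureConfig()) -> str:
    """Binary call: pathogenic iff score <= the calibrated threshold."""
    if not np.isfinite(score):
        raise EnsembleError("non-finite score")
    return PATHOGENIC if score <= cfg.classification_threshold else BENIGN


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def evaluate(
    scores: np.ndarray,
    observed: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    cfg: FeatureConfig = FeatureConfig(),
) -> dict:
    """Standard regression and classification metrics.

    ``observed`` (continuous) yields Pearson and MAE; ``labels``
    (1 = pathogenic) yields MCC at the default threshold plus the full ROC
    sweep and its trapezoid AUC, using the low-score-is-pathogenic
    orientation.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 2:
        raise EnsembleError("need at least 2 points")
    out: dict = {}
    if observed is not None:
        observed = np.asarray(observed, dtype=float)
        r = _safe_pearson(observed, scores)
        out["pearson"] = np.nan if r is None else r
        out["mae"] = float(np.mean(np.abs(observed - scores)))
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) < 2:
            raise EnsembleError("label metrics need both classes")
        calls = (scores <= cfg.classification_threshold).astype(int)
        out["mcc"] = float(matthews_corrcoef(labels, calls))
        fpr, tpr, _ = roc_curve(labels, -scores)
        out["roc"] = (fpr, tpr)
        out["auc"] = float(np.trapezoid(tpr, fpr))
    return out
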