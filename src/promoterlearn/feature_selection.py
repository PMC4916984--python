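"""Wrapper feature selection scored by cross-validated linear regression.

The wrapper scores a candidate feature subset by fitting ordinary least
squares on each training fold of a seeded k-fold partition, pooling the
held-out predictions, and taking the Pearson correlation between pooled
predictions and the measured activities. Greedy forward search adds the
best-scoring candidate until the improvement falls below a tolerance; the
"forward-backward" variant also attempts single removals after each
addition. ``window_scan`` repeats selection per promoter window to locate
the window that carries the predictive signal (for ribosomal-protein
promoters, the 100 bp immediately upstream of the translation start site).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .promoter_io import PromoterSet
from .sequence_features import FeatureConfig, FeatureMatrix, build_feature_matrix

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    folds: int = 10
    search: Literal["forward", "forward-backward"] = "forward"
    score: Literal["pearson", "neg_rmse"] = "pearson"
    improvement_tol: float = 1e-3
    max_features: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.improvement_tol <= 0:
            raise ValueError("improvement_tol must be > 0")
        if self.search not in ("forward", "forward-backward"):
            raise ValueError(f"unknown search {self.search!r}")


@dataclass
class SelectionResult:
    """Outcome of a wrapper search: the selected set and its trajectory."""

    selected: list[str]
    trajectory: list[tuple[str, str, float]]  # (action, feature, cv score after step)
    final_cv_score: float
    config: SelectionConfig | None = None

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "trajectory": [list(step) for step in self.trajectory],
            "final_cv_score": self.final_cv_score,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((xc * yc).sum() / denom)


def fold_partition(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of range(n) into ``folds`` near-equal groups."""
    if not 2 <= folds <= n:
        raise ValueError(f"need 2 <= folds <= n, got folds={folds}, n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def _cv_predictions(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    n = len(y)
    preds = np.empty(n)
    warned = False
    for test_idx in fold_partition(n, folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        A = np.column_stack([np.ones(mask.sum()), X[mask]])
        coef, _, rank, _ = np.linalg.lstsq(A, y[mask], rcond=None)
        if rank < A.shape[1] and not warned:
            logger.warning("singular design; using least-squares pseudo-solution")
            warned = True
        preds[test_idx] = np.column_stack([np.ones(len(test_idx)), X[test_idx]]) @ coef
    return preds


def cross_val_score(
    matrix: FeatureMatrix,
    activities: Sequence[float],
    features: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    score: str = "pearson",
) -> float:
    """Pooled-prediction CV score of an OLS fit on the given features.

    Predictions from all held-out folds are pooled and compared with the
    activities as one Pearson correlation ("pearson") or negative RMSE
    ("neg_rmse"). Constant activities are an error; if the pooled predictions
    come out constant the correlation is reported as 0 with a warning.
    """
    if not features:
        raise ValueError("features must be non-empty")
    y = np.asarray(activities, dtype=float)
    if len(y) != matrix.n_promoters:
        raise ValueError("activities length does not match matrix rows")
    if np.ptp(y) == 0:
        raise ValueError("activities are constant; CV score undefined")
    X = matrix.subset(features)
    preds = _cv_predictions(X, y, folds, seed)
    if score == "neg_rmse":
        return float(-np.sqrt(np.mean((preds - y) ** 2)))
    if np.ptp(preds) == 0:
        logger.warning("pooled CV predictions are constant; reporting r = 0")
        return 0.0
    return _pearson(preds, y)


def wrapper_select(
    matrix: FeatureMatrix,
    activities: Sequence[float],
    config: SelectionConfig | None = None,
    candidates: Sequence[str] | None = None,
) -> SelectionResult:
    """Greedy wrapper search over feature subsets.

    Forward search starts empty and at each step adds the candidate that
    maximizes the CV score of the augmented set, stopping once the best
    improvement is <= ``improvement_tol`` or ``max_features`` is reached; at
    least the best singleton is always returned. Ties break lexicographically
    on feature name, so runs are deterministic given the config seed.
    """
    config = config or SelectionConfig()
    pool = sorted(candidates if candidates is not None else matrix.feature_names)
    if not pool:
        raise ValueError("empty candidate feature set")

    def score_of(feats: list[str]) -> float:
        return cross_val_score(
            matrix, activities, feats, folds=config.folds,
            seed=config.seed, score=config.score,
        )

    selected: list[str] = []
    trajectory: list[tuple[str, str, float]] = []
    current = -np.inf
    remaining = list(pool)
    while remaining:
        if config.max_features is not None and len(selected) >= config.max_features:
            break
        best_feat, best_score = None, -np.inf
        for feat in remaining:  # lexicographic order; strict > keeps first on ties
            s = score_of(selected + [feat])
            if s > best_score:
                best_feat, best_score = feat, s
        assert best_feat is not None
        if selected and best_score <= current + config.improvement_tol:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        current = best_score
        trajectory.append(("add", best_feat, current))
        if config.search == "forward-backward" and len(selected) > 1:
            improved = True
            while improved and len(selected) > 1:
                improved = False
                for feat in sorted(selected):
                    trial = [f for f in selected if f != feat]
                    s = score_of(trial)
                    if s > current + config.improvement_tol:
                        selected = trial
                        remaining.append(feat)
                        current = s
                        trajectory.append(("remove", feat, current))
                        improved = True
                        break
    return SelectionResult(
        selected=selected, trajectory=trajectory,
        final_cv_score=current, config=config,
    )


@dataclass
class WindowScanRecord:
    window: str
    window_index: int | None  # None for the full-promoter window
    n_promoters: int
    n_features_selected: int
    selected: list[str]
    cv_r_5fold: float
    cv_r_10fold: float


@dataclass
class WindowScanResult:
    records: list[WindowScanRecord]
    best: WindowScanRecord

    def ranked(self) -> list[WindowScanRecord]:
        return sorted(self.records, key=lambda r: r.cv_r_10fold, reverse=True)


def window_scan(
    pset: PromoterSet,
    feat_config: FeatureConfig,
    sel_config: SelectionConfig | None = None,
    scales: Mapping | None = None,
    min_coverage: float = 0.8,
) -> WindowScanResult:
    """Run wrapper selection per promoter window and rank the windows.

    Fixed windows present in fewer than ``min_coverage`` of the promoters are
    skipped with a warning; the full-promoter window is always scanned. Each
    scanned window gets a selected feature set plus its pooled-CV Pearson r
    under both 5- and 10-fold partitions. The best window is the one with the
    highest 10-fold r.
    """
    sel_config = sel_config or SelectionConfig()
    with_act = pset.with_activities()
    if len(with_act) == 0:
        raise ValueError("no promoters with activities")
    width = feat_config.window_width
    n = len(with_act)
    counts = [len(rec) // width for rec in with_act]
    max_index = max(counts)
    selectors: list = []
    for i in range(1, max_index + 1):
        covered = sum(1 for c in counts if c >= i)
        if covered >= min_coverage * n and covered > sel_config.folds:
            selectors.append(("index", i))
        elif covered > 0:
            logger.warning(
                "window %d present in only %d/%d promoters; skipped", i, covered, n
            )
    selectors.append("full")
    if len(selectors) == 0:
        raise ValueError("no scannable window")
    records: list[WindowScanRecord] = []
    for selector in selectors:
        fmatrix = build_feature_matrix(with_act, selector, feat_config, scales)
        acts = [with_act[pid].activity for pid in fmatrix.promoter_ids]
        result = wrapper_select(fmatrix, acts, sel_config)
        r5 = cross_val_score(
            fmatrix, acts, result.selected, folds=5, seed=sel_config.seed,
            score=sel_config.score,
        )
        r10 = cross_val_score(
            fmatrix, acts, result.selected, folds=10, seed=sel_config.seed,
            score=sel_config.score,
        )
        records.append(
            WindowScanRecord(
                window=fmatrix.window,
                window_index=None if selector == "full" else selector[1],
                n_promoters=fmatrix.n_promoters,
                n_features_selected=len(result.selected),
                selected=result.selected,
                cv_r_5fold=r5,
                cv_r_10fold=r10,
            )
        )
    best = max(records, key=lambda r: r.cv_r_10fold)
    return WindowScanResult(records=records, best=best)
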