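"""Challenge-style scoring: four statistics with permutation-null p-values.

A submission (one predicted activity per promoter) is scored against the
observed activities with four statistics — Pearson correlation, Spearman
correlation, a chi-square distance, and a squared rank distance. Each
statistic gets a p-value from a permutation null built by resampling, for
every promoter independently, a predicted value from a pool of competing
submissions (a whole-vector resampling variant is available). The four
p-values are combined as their product and as the negative log10 of their
geometric mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

STATISTICS = ("pearson", "spearman", "chi2", "rank")
#: whether a larger value of the statistic is better
_HIGHER_IS_BETTER = {"pearson": True, "spearman": True, "chi2": False, "rank": False}


@dataclass
class PredictionSubmission:
    """One team's predicted activity per promoter."""

    team_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = [pid for pid, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"submission {self.team_id!r}: non-finite predictions for {bad}")

    def vector(self, promoter_ids: Sequence[str]) -> np.ndarray:
        missing = [pid for pid in promoter_ids if pid not in self.values]
        if missing:
            raise ValueError(f"submission {self.team_id!r}: missing promoters {missing}")
        return np.array([self.values[pid] for pid in promoter_ids], dtype=float)


def _validate_pair(pred: Sequence[float], obs: Sequence[float], min_n: int = 2):
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("pred and obs must be 1-d vectors of equal length")
    if len(p) < min_n:
        raise ValueError(f"need at least {min_n} promoters")
    return p, o


def pearson_score(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Sample Pearson correlation between predicted and observed activities."""
    p, o = _validate_pair(pred, obs, min_n=3)
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(p, o).statistic)


def spearman_score(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Spearman correlation (Pearson on average ranks; ties get average ranks)."""
    p, o = _validate_pair(pred, obs, min_n=3)
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(p, o).statistic)


def chi_square_distance(
    pred: Sequence[float],
    obs: Sequence[float],
    denom: Literal["observed", "uniform"] = "observed",
) -> float:
    """Sum of squared residuals, optionally scaled by the observed activity.

    denom="observed": sum_i (pred_i - obs_i)^2 / obs_i (requires obs > 0);
    denom="uniform": sum_i (pred_i - obs_i)^2.
    """
    p, o = _validate_pair(pred, obs, min_n=1)
    if denom == "observed":
        if np.any(o <= 0):
            raise ValueError('denom="observed" requires all observed activities > 0')
        return float(((p - o) ** 2 / o).sum())
    return float(((p - o) ** 2).sum())


def rank_distance(
    pred: Sequence[float],
    obs: Sequence[float],
    variant: Literal["mean", "sum"] = "mean",
) -> float:
    """Squared difference between predicted and observed ranks (average ranks
    for ties); "mean" divides by n, "sum" does not. A fully reversed ranking
    of n distinct items scores (n^2 - 1)/3 under the mean variant."""
    p, o = _validate_pair(pred, obs, min_n=2)
    d2 = (stats.rankdata(p) - stats.rankdata(o)) ** 2
    return float(d2.mean() if variant == "mean" else d2.sum())


def compute_statistic(name: str, pred, obs, **kwargs) -> float:
    if name == "pearson":
        return pearson_score(pred, obs)
    if name == "spearman":
        return spearman_score(pred, obs)
    if name == "chi2":
        return chi_square_distance(pred, obs, **kwargs)
    if name == "rank":
        return rank_distance(pred, obs, **kwargs)
    raise ValueError(f"unknown statistic {name!r}")


def _null_matrix(
    pool_values: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    scheme: str,
) -> np.ndarray:
    """n_perm x n matrix of null prediction vectors drawn from the pool."""
    n_teams, n = pool_values.shape
    if scheme == "per_promoter":
        idx = rng.integers(0, n_teams, size=(n_perm, n))
        return pool_values[idx, np.arange(n)]
    if scheme == "whole_vector":
        idx = rng.integers(0, n_teams, size=n_perm)
        return pool_values[idx]
    raise ValueError(f"unknown null scheme {scheme!r}")


def _null_statistics(null_preds: np.ndarray, obs: np.ndarray, statistic: str) -> np.ndarray:
    """Vectorized statistic per null replicate (row of null_preds)."""
    if statistic in ("pearson", "spearman"):
        P = null_preds if statistic == "pearson" else stats.rankdata(null_preds, axis=1)
        o = obs if statistic == "pearson" else stats.rankdata(obs)
        Pc = P - P.mean(axis=1, keepdims=True)
        oc = o - o.mean()
        denom = np.sqrt((Pc ** 2).sum(axis=1) * (oc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Pc @ oc) / denom
        # a constant null vector has undefined correlation: score it as 0
        return np.where(denom > 0, r, 0.0)
    if statistic == "chi2":
        return ((null_preds - obs) ** 2 / obs).sum(axis=1)
    if statistic == "rank":
        R = stats.rankdata(null_preds, axis=1)
        return ((R - stats.rankdata(obs)) ** 2).mean(axis=1)
    raise ValueError(f"unknown statistic {statistic!r}")


def _pvalue_from_null(observed: float, null: np.ndarray, statistic: str) -> float:
    # add-one correction: p can never be exactly 0
    if _HIGHER_IS_BETTER[statistic]:
        better = int(np.sum(null >= observed))
    else:
        better = int(np.sum(null <= observed))
    return (1 + better) / (1 + len(null))


def permutation_pvalue(
    submission: PredictionSubmission,
    pool: Sequence[PredictionSubmission],
    obs: Sequence[float],
    statistic: str,
    n_perm: int = 10_000,
    seed: int = 0,
    promoter_ids: Sequence[str] | None = None,
    scheme: Literal["per_promoter", "whole_vector"] = "per_promoter",
) -> float:
    """Permutation-null p-value for one statistic of one submission.

    p = (1 + #{null replicates at least as good}) / (1 + n_perm), where "as
    good" means >= for correlations and <= for distances.
    """
    if len(pool) < 1:
        raise ValueError("empty submission pool")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = list(promoter_ids) if promoter_ids is not None else sorted(submission.values)
    obs = np.asarray(obs, dtype=float)
    pred = submission.vector(ids)
    pool_values = np.stack([s.vector(ids) for s in pool if s.team_id != submission.team_id])
    if len(pool_values) < 1:
        raise ValueError("pool contains no submission other than the scored one")
    observed = compute_statistic(statistic, pred, obs)
    rng = np.random.default_rng(seed)
    null_preds = _null_matrix(pool_values, n_perm, rng, scheme)
    null = _null_statistics(null_preds, obs, statistic)
    return _pvalue_from_null(observed, null, statistic)


@dataclass
class EvaluationReport:
    """Four challenge statistics, their permutation p-values, combined scores."""

    pearson_r: float
    spearman_rho: float
    chi2_distance: float
    rank_distance: float
    p_pearson: float
    p_spearman: float
    p_chi2: float
    p_rank: float
    overall_product: float
    overall_score: float
    n_promoters: int
    n_permutations: int
    seed: int
    directions: dict = field(
        default_factory=lambda: {
            s: (">=" if _HIGHER_IS_BETTER[s] else "<=") for s in STATISTICS
        }
    )

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def combined_scores(p_values: Sequence[float]) -> tuple[float, float]:
    """(product of p-values, -log10 of their geometric mean)."""
    p = np.asarray(p_values, dtype=float)
    product = float(np.prod(p))
    score = float(-np.log10(product ** (1 / len(p))))
    return product, score


def evaluate_submission(
    submission: PredictionSubmission,
    pool: Sequence[PredictionSubmission],
    obs: dict[str, float] | Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    promoter_ids: Sequence[str] | None = None,
    scheme: Literal["per_promoter", "whole_vector"] = "per_promoter",
) -> EvaluationReport:
    """Full challenge report: all four statistics and their p-values.

    All four statistics share one set of null prediction vectors (one draw
    per replicate), as when a panel of submissions is scored jointly.
    """
    if isinstance(obs, dict):
        ids = list(promoter_ids) if promoter_ids is not None else sorted(obs)
        missing = [pid for pid in ids if pid not in obs]
        if missing:
            raise ValueError(f"observed activities missing promoters {missing}")
        obs_vec = np.array([obs[pid] for pid in ids], dtype=float)
    else:
        if promoter_ids is None:
            raise ValueError("promoter_ids required when obs is a plain vector")
        ids = list(promoter_ids)
        obs_vec = np.asarray(obs, dtype=float)
    sub_missing = [pid for pid in ids if pid not in submission.values]
    if sub_missing:
        raise ValueError(f"submission missing promoters {sub_missing}")
    pred = submission.vector(ids)
    pool_values = np.stack([s.vector(ids) for s in pool if s.team_id != submission.team_id])
    if len(pool_values) < 1:
        raise ValueError("pool contains no submission other than the scored one")
    observed = {name: compute_statistic(name, pred, obs_vec) for name in STATISTICS}
    rng = np.random.default_rng(seed)
    null_preds = _null_matrix(pool_values, n_perm, rng, scheme)
    p_values = {
        name: _pvalue_from_null(observed[name], _null_statistics(null_preds, obs_vec, name), name)
        for name in STATISTICS
    }
    product, score = combined_scores([p_values[s] for s in STATISTICS])
    return EvaluationReport(
        pearson_r=observed["pearson"],
        spearman_rho=observed["spearman"],
        chi2_distance=observed["chi2"],
        rank_distance=observed["rank"],
        p_pearson=p_values["pearson"],
        p_spearman=p_values["spearman"],
        p_chi2=p_values["chi2"],
        p_rank=p_values["rank"],
        overall_product=product,
        overall_score=score,
        n_promoters=len(ids),
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class ErrorProfile:
    """Per-promoter absolute error, group comparison, and error-activity link."""

    abs_error: np.ndarray
    group_mean_error: dict[str, float]
    group_t_statistic: float | None
    group_p_value: float | None
    error_activity_r: float | None


def error_profile(
    pred: Sequence[float],
    obs: Sequence[float],
    labels: Sequence[str],
) -> ErrorProfile:
    """Where does the model fail? Absolute error per promoter, Welch t-test of
    error between two label groups (e.g. natural vs mutated), and the Pearson
    correlation between observed activity and error (undefined quantities are
    reported as None)."""
    p, o = _validate_pair(pred, obs, min_n=2)
    labels = list(labels)
    if len(labels) != len(p):
        raise ValueError("labels must cover all promoters")
    errors = np.abs(p - o)
    groups = sorted(set(labels))
    arr = {
        g: errors[np.array([lab == g for lab in labels])] for g in groups
    }
    group_means = {g: float(v.mean()) for g, v in arr.items()}
    t_stat = p_val = None
    usable = [g for g in groups if len(arr[g]) >= 2]
    if len(usable) == 2:
        t, pv = stats.ttest_ind(arr[usable[0]], arr[usable[1]], equal_var=False)
        t_stat, p_val = float(t), float(pv)
    elif len(groups) >= 2:
        logger.warning("group test skipped: need exactly 2 groups of size >= 2, have %s",
                       {g: len(v) for g, v in arr.items()})
    corr = None
    if np.ptp(errors) > 0 and np.ptp(o) > 0:
        corr = float(stats.pearsonr(o, errors).statistic)
    return ErrorProfile(
        abs_error=errors,
        group_mean_error=group_means,
        group_t_statistic=t_stat,
        group_p_value=p_val,
        error_activity_r=corr,
    )
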