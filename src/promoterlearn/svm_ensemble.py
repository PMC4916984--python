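"""Averaged epsilon-SVM regression ensembles for promoter activity.

The production model is an ensemble of 501 support-vector regressors: 500
members each trained on a random 80% of the promoters (held-out Pearson r
recorded on the remaining 20%) plus one member trained on a 66/34 split.
Features are standardized per member on that member's own training split so
no test information leaks into the scaling. The ensemble prediction is the
arithmetic mean of the member predictions.

Members are fitted with scikit-learn's SVR but store their own coefficients
(weight vector for the linear kernel; support vectors and dual coefficients
for RBF), so saved models predict without scikit-learn and serialize to
plain JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.svm import SVR

from .sequence_features import FeatureMatrix

logger = logging.getLogger(__name__)

_SEED_CAP = 2**31 - 1


@dataclass
class TrainingProtocol:
    """How the ensemble is built; defaults give the 501-member protocol."""

    n_resampled_members: int = 500
    resample_train_frac: float = 0.8
    include_6634_member: bool = True
    member_6634_train_frac: float = 0.66
    kernel: Literal["linear", "rbf"] = "linear"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float | str = "scale"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resampled_members < 1:
            raise ValueError("n_resampled_members must be >= 1")
        for frac in (self.resample_train_frac, self.member_6634_train_frac):
            if not 0 < frac < 1:
                raise ValueError("train fractions must lie in (0, 1)")
        if self.C <= 0 or self.epsilon <= 0:
            raise ValueError("C and epsilon must be positive")

    @property
    def n_members(self) -> int:
        return self.n_resampled_members + (1 if self.include_6634_member else 0)


@dataclass
class EnsembleMember:
    """One fitted epsilon-SVR with its own standardization parameters."""

    kernel: str
    intercept: float
    mean: np.ndarray
    std: np.ndarray
    train_frac: float
    seed: int
    holdout_r: float
    coef: np.ndarray | None = None  # linear kernel weight vector
    support_vectors: np.ndarray | None = None  # rbf kernel
    dual_coef: np.ndarray | None = None
    gamma: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean) / self.std
        if self.kernel == "linear":
            return Z @ self.coef + self.intercept
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        out = {
            "kernel": self.kernel,
            "intercept": self.intercept,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "train_frac": self.train_frac,
            "seed": self.seed,
            "holdout_r": self.holdout_r,
        }
        if self.kernel == "linear":
            out["coef"] = self.coef.tolist()
        else:
            out["support_vectors"] = self.support_vectors.tolist()
            out["dual_coef"] = self.dual_coef.tolist()
            out["gamma"] = self.gamma
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleMember":
        return cls(
            kernel=d["kernel"],
            intercept=float(d["intercept"]),
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            train_frac=float(d["train_frac"]),
            seed=int(d["seed"]),
            holdout_r=float(d["holdout_r"]),
            coef=np.asarray(d["coef"], dtype=float) if "coef" in d else None,
            support_vectors=(
                np.asarray(d["support_vectors"], dtype=float)
                if "support_vectors" in d else None
            ),
            dual_coef=np.asarray(d["dual_coef"], dtype=float) if "dual_coef" in d else None,
            gamma=d.get("gamma"),
        )


@dataclass
class EnsembleModel:
    members: list[EnsembleMember]
    feature_names: list[str]
    protocol: TrainingProtocol

    @property
    def member_holdout_r(self) -> np.ndarray:
        return np.array([m.holdout_r for m in self.members])

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "protocol": asdict(self.protocol),
            "members": [m.to_dict() for m in self.members],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            members=[EnsembleMember.from_dict(d) for d in payload["members"]],
            feature_names=list(payload["feature_names"]),
            protocol=TrainingProtocol(**payload["protocol"]),
        )


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _split_indices(n: int, train_frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 2), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _fit_member(
    X: np.ndarray,
    y: np.ndarray,
    train_frac: float,
    seed: int,
    protocol: TrainingProtocol,
) -> EnsembleMember:
    train_idx, test_idx = _split_indices(len(y), train_frac, seed)
    Xtr, ytr = X[train_idx], y[train_idx]
    if protocol.standardize:
        mean = Xtr.mean(axis=0)
        std = Xtr.std(axis=0)
        zero_var = std == 0
        if zero_var.any():
            logger.warning(
                "member seed %d: %d zero-variance feature(s) in training split; scale set to 1",
                seed, int(zero_var.sum()),
            )
            std = np.where(zero_var, 1.0, std)
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    Ztr = (Xtr - mean) / std
    svr = SVR(kernel=protocol.kernel, C=protocol.C, epsilon=protocol.epsilon,
              gamma=protocol.gamma)
    svr.fit(Ztr, ytr)
    if protocol.kernel == "linear":
        member = EnsembleMember(
            kernel="linear", intercept=float(svr.intercept_[0]),
            mean=mean, std=std, train_frac=train_frac, seed=seed,
            holdout_r=float("nan"), coef=svr.coef_.ravel().copy(),
        )
    else:
        member = EnsembleMember(
            kernel="rbf", intercept=float(svr.intercept_[0]),
            mean=mean, std=std, train_frac=train_frac, seed=seed,
            holdout_r=float("nan"),
            support_vectors=svr.support_vectors_.copy(),
            dual_coef=svr.dual_coef_.ravel().copy(),
            gamma=float(svr._gamma),
        )
    member.holdout_r = _pearson_or_nan(member.predict(X[test_idx]), y[test_idx])
    return member


def _resolve_inputs(
    matrix: FeatureMatrix, activities: Sequence[float], features: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(activities, dtype=float)
    if len(y) != matrix.n_promoters:
        raise ValueError("activities length does not match matrix rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("activities must be finite")
    if np.ptp(y) == 0:
        raise ValueError("activities are constant; nothing to learn")
    return matrix.subset(features), y


def train_ensemble(
    matrix: FeatureMatrix,
    activities: Sequence[float],
    features: Sequence[str],
    protocol: TrainingProtocol | None = None,
) -> EnsembleModel:
    """Train the averaged SVR ensemble; reproducible from ``protocol.seed``."""
    protocol = protocol or TrainingProtocol()
    X, y = _resolve_inputs(matrix, activities, features)
    if len(y) < 10:
        raise ValueError("need at least 10 promoters to train the ensemble")
    rng = np.random.default_rng(protocol.seed)
    member_seeds = rng.integers(0, _SEED_CAP, size=protocol.n_members)
    members: list[EnsembleMember] = []
    pos = 0
    if protocol.include_6634_member:
        members.append(
            _fit_member(X, y, protocol.member_6634_train_frac, int(member_seeds[pos]), protocol)
        )
        pos += 1
    for i in range(protocol.n_resampled_members):
        members.append(
            _fit_member(X, y, protocol.resample_train_frac, int(member_seeds[pos + i]), protocol)
        )
    return EnsembleModel(members=members, feature_names=list(features), protocol=protocol)


def predict(model: EnsembleModel, matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Mean of member predictions, in matrix row order."""
    if isinstance(matrix, FeatureMatrix):
        if matrix.feature_names == model.feature_names:
            X = matrix.values  # avoid a copy: keeps member averaging bitwise exact
        else:
            X = matrix.subset(model.feature_names)  # KeyError names any missing feature
    else:
        X = np.asarray(matrix, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
            )
    preds = np.stack([m.predict(X) for m in model.members])
    return preds.mean(axis=0)


def holdout_performance(
    matrix: FeatureMatrix,
    activities: Sequence[float],
    features: Sequence[str],
    protocol: TrainingProtocol | None = None,
    n_repeats: int = 1000,
    train_frac: float = 0.66,
) -> dict:
    """Distribution of single-SVR held-out Pearson r over repeated random splits."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    protocol = protocol or TrainingProtocol()
    X, y = _resolve_inputs(matrix, activities, features)
    rng = np.random.default_rng(protocol.seed)
    seeds = rng.integers(0, _SEED_CAP, size=n_repeats)
    per_repeat = np.array([
        _fit_member(X, y, train_frac, int(s), protocol).holdout_r for s in seeds
    ])
    valid = per_repeat[np.isfinite(per_repeat)]
    return {
        "per_repeat": per_repeat,
        "mean_r": float(valid.mean()) if len(valid) else float("nan"),
        "sd_r": float(valid.std(ddof=1)) if len(valid) > 1 else float("nan"),
        "n_repeats": n_repeats,
    }
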