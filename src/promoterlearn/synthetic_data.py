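"""Synthetic promoter sets with planted feature-activity structure.

Sequences are drawn i.i.d. per base from a configurable composition (the
default is AT-rich, yeast-promoter-like). Activities are a noisy linear
function of designated window-1 features — mirroring the finding that the
100 bp immediately upstream of the translation start carries the predictive
signal — so selection, ensemble training, window scanning and scoring all
have a planted correct answer. A fraction of promoters can be copy-and-
mutated versions of natural ones, emulating a test panel that mixes natural
promoters with synthetically mutated variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .promoter_io import PromoterRecord, PromoterSet
from .sequence_features import (
    BASES,
    kmer_frequencies,
    max_alternating_tract,
    max_homopolymer_tract,
)

logger = logging.getLogger(__name__)

#: AT-rich base composition typical of yeast promoter regions (A, C, G, T)
YEAST_LIKE_COMPOSITION = (0.31, 0.19, 0.19, 0.31)

#: default planted window-1 effects: G content down-regulates, T/TA tracts up
DEFAULT_EFFECTS = (
    ("kmer1:G", -2.0),
    ("tract:T", 0.05),
    ("tract:TA", 0.03),
)


@dataclass
class SyntheticConfig:
    n_promoters: int = 90
    length_range: tuple[int, int] = (200, 1200)
    base_composition: tuple[float, float, float, float] = YEAST_LIKE_COMPOSITION
    effects: tuple[tuple[str, float], ...] = DEFAULT_EFFECTS
    baseline: float = 1.0  # intercept keeping typical activities positive
    noise_sd: float = 0.0
    mutated_fraction: float = 0.0
    mutation_rate: float = 0.02
    window_width: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be >= 1")
        lo, hi = self.length_range
        if lo > hi or lo < self.window_width:
            raise ValueError("length_range min must be <= max and >= window_width")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if not 0 <= self.mutated_fraction <= 1:
            raise ValueError("mutated_fraction must lie in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Per-promoter realized effect features, noiseless activity and noise draw.

    ``activity = baseline + sum(weight * feature) + noise`` holds exactly per
    record (``noiseless_activity`` includes the baseline).
    """

    table: pd.DataFrame  # indexed by promoter id
    effects: tuple[tuple[str, float], ...]

    def activity_identity_error(self, pset: PromoterSet) -> float:
        """Max |activity - (noiseless + noise)| over the set (should be 0)."""
        err = 0.0
        for rec in pset:
            row = self.table.loc[rec.id]
            err = max(err, abs(rec.activity - (row["noiseless_activity"] + row["noise"])))
        return err


def evaluate_feature(seq: str, name: str, scales: Mapping | None = None) -> float:
    """Evaluate one namespaced sequence feature on a window sequence."""
    namespace, _, rest = name.partition(":")
    if namespace.startswith("kmer"):
        k = int(namespace[4:])
        return kmer_frequencies(seq, k)[rest]
    if namespace == "tract":
        if len(rest) == 1:
            return float(max_homopolymer_tract(seq, rest))
        return float(max_alternating_tract(seq, rest))
    if namespace in ("mech", "nuc"):
        from .mechanical_profiles import load_scale, window_property_mean

        scale_name, _, stat = rest.rpartition("_")
        if namespace == "nuc":
            scale_name = "nucleosome_preference"
        if stat != "mean":
            raise ValueError(f"unsupported mechanical statistic in effect {name!r}")
        scale = (scales or {}).get(scale_name) or load_scale(scale_name)
        return window_property_mean(seq, scale)
    raise ValueError(f"unknown feature name {name!r}")


def _window1(seq: str, width: int) -> str:
    return seq[-width:]


def _random_sequence(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=list(probs)))


def mutate_promoter(
    record: PromoterRecord, rate: float, seed: int, new_id: str | None = None
) -> PromoterRecord:
    """Independently substitute each base (uniform over the 3 alternatives)
    with probability ``rate``; rate 1 changes every position."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = list(record.sequence)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        alternatives = [b for b in BASES if b != seq[i]]
        seq[i] = alternatives[rng.integers(0, 3)]
    return PromoterRecord(
        id=new_id or f"{record.id}_mut",
        sequence="".join(seq),
        label="mutated",
    )


def plant_tract(
    record: PromoterRecord, word: str, tract_len: int, offset: int
) -> PromoterRecord:
    """Overwrite [offset, offset + tract_len) with the periodic extension of
    ``word`` (offset is TrSS-relative and negative); length unchanged."""
    L = len(record)
    start = L + offset
    end = start + tract_len
    if offset >= 0 or start < 0 or end > L:
        raise ValueError(
            f"tract [{offset}, {offset + tract_len}) does not fit promoter of length {L}"
        )
    fill = (word * (tract_len // len(word) + 1))[:tract_len]
    seq = record.sequence[:start] + fill + record.sequence[end:]
    return replace(record, sequence=seq)


def generate_promoters(config: SyntheticConfig) -> tuple[PromoterSet, GroundTruth]:
    """Draw a promoter set and its ground truth, reproducibly from the seed.

    Sequence/mutation randomness and activity-noise randomness come from
    separate streams spawned off the seed, so regenerating with a different
    ``noise_sd`` keeps the sequences identical.
    """
    ss = np.random.SeedSequence(config.seed)
    seq_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    n_mut = int(round(config.mutated_fraction * config.n_promoters))
    n_nat = config.n_promoters - n_mut
    if n_nat < 1:
        raise ValueError("mutated_fraction leaves no natural promoter to copy from")
    lo, hi = config.length_range
    naturals: list[PromoterRecord] = []
    for i in range(n_nat):
        length = int(seq_rng.integers(lo, hi + 1))
        naturals.append(
            PromoterRecord(
                id=f"p{i + 1:04d}",
                sequence=_random_sequence(seq_rng, length, config.base_composition),
                label="natural",
            )
        )
    records = list(naturals)
    parents: dict[str, str] = {}
    for j in range(n_mut):
        parent = naturals[int(seq_rng.integers(0, n_nat))]
        mut_seed = int(seq_rng.integers(0, 2**31 - 1))
        mutated = mutate_promoter(
            parent, config.mutation_rate, mut_seed, new_id=f"{parent.id}_mut{j + 1}"
        )
        parents[mutated.id] = parent.id
        records.append(mutated)
    rows = []
    for rec in records:
        w1 = _window1(rec.sequence, config.window_width)
        feats = {name: evaluate_feature(w1, name) for name, _ in config.effects}
        noiseless = config.baseline + sum(
            weight * feats[name] for name, weight in config.effects
        )
        noise = float(noise_rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
        activity = noiseless + noise
        # synthetic activities may go negative; the measured-data >=0 check
        # only runs at record construction, so assign directly
        rec.activity = float(activity)
        rows.append(
            {
                "promoter_id": rec.id,
                **feats,
                "noiseless_activity": noiseless,
                "noise": noise,
                "activity": float(activity),
                "label": rec.label,
                "parent_id": parents.get(rec.id, ""),
                "length": len(rec),
            }
        )
    truth = GroundTruth(
        table=pd.DataFrame(rows).set_index("promoter_id"),
        effects=tuple(config.effects),
    )
    return PromoterSet(records, provenance={"synthetic_seed": config.seed}), truth


@dataclass
class PlantedStudy:
    """A synthetic analogue of the challenge design: 90 training promoters
    (all natural) and a 53-promoter test panel mixing natural and mutated
    variants, with activities planted on window 1."""

    train: PromoterSet
    test: PromoterSet
    train_truth: GroundTruth
    test_truth: GroundTruth
    noise_sd: float
    effects: tuple[tuple[str, float], ...]


def planted_study(
    seed: int,
    n_train: int = 90,
    n_test: int = 53,
    n_test_mutated: int = 33,
    effects: Sequence[tuple[str, float]] = DEFAULT_EFFECTS,
    relative_noise: float = 0.1,
    length_range: tuple[int, int] = (200, 1200),
    window_width: int = 100,
) -> PlantedStudy:
    """Generate the standard train/test design used throughout the package.

    The activity noise level is calibrated once per study: noise_sd =
    ``relative_noise`` times the SD of the noiseless training activities
    (a noiseless pass with the same seed fixes the sequences, then the noisy
    pass reuses them).
    """
    base = dict(
        length_range=length_range,
        effects=tuple(effects),
        window_width=window_width,
    )
    train_cfg = SyntheticConfig(n_promoters=n_train, seed=seed * 2 + 1, **base)
    _, truth0 = generate_promoters(train_cfg)
    noise_sd = float(relative_noise * truth0.table["noiseless_activity"].std(ddof=1))
    train_set, train_truth = generate_promoters(replace(train_cfg, noise_sd=noise_sd))
    test_cfg = SyntheticConfig(
        n_promoters=n_test,
        mutated_fraction=n_test_mutated / n_test,
        noise_sd=noise_sd,
        seed=seed * 2 + 2,
        **base,
    )
    test_set, test_truth = generate_promoters(test_cfg)
    return PlantedStudy(
        train=train_set,
        test=test_set,
        train_truth=train_truth,
        test_truth=test_truth,
        noise_sd=noise_sd,
        effects=tuple(effects),
    )
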