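"""Window segmentation and per-window DNA sequence features.

Promoters are tiled into fixed-width non-overlapping windows anchored at the
TrSS-proximal (3') end — window 1 is the last ``width`` bases — plus one
"full" window spanning the whole promoter. Per window the package computes
overlapping k-mer frequencies, homopolymer / alternating tract lengths, and
mean mechanical-property values from di/trinucleotide parameter scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .promoter_io import PromoterRecord, PromoterSet

logger = logging.getLogger(__name__)

BASES = "ACGT"

WindowSelector = tuple[str, int] | Literal["full"]


@dataclass(frozen=True)
class Window:
    """A TrSS-relative half-open interval [start_offset, end_offset).

    Position -1 is the last promoter base, so a fixed window of width 100
    with index 1 (TrSS-proximal) is [-100, 0). ``kind`` is "fixed" or "full";
    fixed windows carry a 1-based ``index`` counting upstream from the TrSS.
    """

    kind: Literal["fixed", "full"]
    start_offset: int
    end_offset: int
    index: int | None = None

    def __post_init__(self) -> None:
        if self.end_offset > 0 or self.start_offset >= self.end_offset:
            raise ValueError(
                f"invalid window [{self.start_offset}, {self.end_offset}): offsets must "
                "satisfy start < end <= 0"
            )
        if self.kind == "fixed" and (self.index is None or self.index < 1):
            raise ValueError("fixed windows need a positive 1-based index")

    @property
    def length(self) -> int:
        return self.end_offset - self.start_offset

    def describe(self) -> str:
        if self.kind == "full":
            return "full"
        return f"window {self.index} [{self.start_offset},{self.end_offset})"


@dataclass
class FeatureConfig:
    """Which features to extract per window.

    ``kmer_ks``: word sizes for overlapping k-mer frequencies (subset of 1..5).
    ``tract_words``: single bases (homopolymer tracts) or two distinct bases
    (alternating tracts, e.g. "TA"); the reported statistic is the maximum
    tract length in bases (``tract_statistic="coverage"`` instead reports the
    number of bases inside tracts of length >= 2).
    ``mech_scales``: names of mechanical-property scales, summarized per
    window by their mean (or sum). ``include_nucleosome`` adds the packaged
    nucleosome-preference scale mean.
    """

    kmer_ks: tuple[int, ...] = (1, 2, 3, 4, 5)
    tract_words: tuple[str, ...] = ("T", "TA")
    mech_scales: tuple[str, ...] = ("bendability", "deformability", "stiffness")
    include_nucleosome: bool = True
    window_width: int = 100
    tract_statistic: Literal["max", "coverage"] = "max"
    mech_statistic: Literal["mean", "sum"] = "mean"

    def __post_init__(self) -> None:
        self.kmer_ks = tuple(sorted(set(int(k) for k in self.kmer_ks)))
        if not self.kmer_ks:
            raise ValueError("kmer_ks must be non-empty")
        if any(k < 1 or k > 5 for k in self.kmer_ks):
            raise ValueError("kmer_ks must be a subset of {1..5}")
        if self.window_width < max(self.kmer_ks):
            raise ValueError("window_width must be >= the largest k requested")
        for word in self.tract_words:
            if len(word) not in (1, 2) or any(b not in BASES for b in word):
                raise ValueError(f"invalid tract word {word!r}")
            if len(word) == 2 and word[0] == word[1]:
                raise ValueError(f"tract word {word!r}: use a single base for homopolymers")

    def scale_names(self) -> tuple[str, ...]:
        names = tuple(self.mech_scales)
        if self.include_nucleosome:
            names = names + ("nucleosome_preference",)
        return names


def segment_windows(record: PromoterRecord, width: int) -> list[Window]:
    """Tile a promoter into fixed windows from the TrSS-proximal end plus "full".

    Returns floor(L/width) fixed windows indexed 1..n proceeding upstream and
    one full-promoter window; a distal fragment shorter than ``width`` is not
    tiled (it remains inside the full window). A promoter shorter than
    ``width`` yields the full window only.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    L = len(record)
    windows = [
        Window("fixed", start_offset=-i * width, end_offset=-(i - 1) * width, index=i)
        for i in range(1, L // width + 1)
    ]
    windows.append(Window("full", start_offset=-L, end_offset=0))
    return windows


def window_sequence(record: PromoterRecord, window: Window) -> str:
    """The bases of ``record`` covered by ``window`` (5'->3')."""
    L = len(record)
    if -window.start_offset > L:
        raise ValueError(
            f"promoter {record.id!r} (length {L}) does not contain {window.describe()}"
        )
    start = L + window.start_offset
    end = L + window.end_offset
    return record.sequence[start:end] if end < L else record.sequence[start:]


def _check_acgt(seq: str, context: str = "") -> None:
    if "N" in seq:
        raise ValueError(f"sequence contains N{'; ' + context if context else ''}")


def kmer_frequencies(seq: str, k: int) -> dict[str, float]:
    """Overlapping k-mer frequencies over all 4^k words (zeros included).

    frequency(w) = occurrences of w in seq / (len(seq) - k + 1); the values
    sum to 1. The given strand only; no reverse-complement collapsing.
    """
    if not 1 <= k <= len(seq):
        raise ValueError(f"k={k} out of range for sequence of length {len(seq)}")
    _check_acgt(seq)
    counts = {"".join(p): 0 for p in product(BASES, repeat=k)}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    denom = len(seq) - k + 1
    return {word: n / denom for word, n in counts.items()}


def max_homopolymer_tract(seq: str, base: str) -> int:
    """Length of the longest run of consecutive ``base`` characters (0 if absent)."""
    if base not in BASES:
        raise ValueError(f"base must be one of {BASES}, got {base!r}")
    best = run = 0
    for c in seq:
        run = run + 1 if c == base else 0
        best = max(best, run)
    return best


def max_alternating_tract(seq: str, word: str) -> int:
    """Longest perfect alternation of word[0]/word[1], in bases, phase-agnostic.

    "CTATATAG" with word "TA" -> 6; a lone matching base counts as length 1.
    """
    if len(word) != 2 or word[0] == word[1]:
        raise ValueError(
            f"word must be a dinucleotide with distinct bases, got {word!r} "
            "(use max_homopolymer_tract for repeated bases)"
        )
    pair = set(word)
    best = run = 0
    prev = ""
    for c in seq:
        if c in pair:
            run = run + 1 if (prev in pair and prev != c) else 1
        else:
            run = 0
        best = max(best, run)
        prev = c
    return best


def tract_coverage(seq: str, word: str) -> int:
    """Number of bases inside maximal tracts of length >= 2 for ``word``."""
    covered = 0
    i = 0
    n = len(seq)
    while i < n:
        j = i
        if len(word) == 1:
            while j < n and seq[j] == word:
                j += 1
        else:
            pair = set(word)
            prev = ""
            while j < n and seq[j] in pair and seq[j] != prev:
                prev = seq[j]
                j += 1
        if j - i >= 2:
            covered += j - i
        i = max(j, i + 1)
    return covered


def _tract_statistic(seq: str, word: str, statistic: str) -> float:
    if statistic == "coverage":
        return float(tract_coverage(seq, word))
    if len(word) == 1:
        return float(max_homopolymer_tract(seq, word))
    return float(max_alternating_tract(seq, word))


def extract_window_features(
    record: PromoterRecord,
    window: Window,
    config: FeatureConfig,
    scales: Mapping[str, "PropertyScale"] | None = None,
) -> dict[str, float]:
    """Namespaced feature vector for one window of one promoter.

    Names: ``kmer{k}:{word}``, ``tract:{word}``, ``mech:{scale}_{stat}`` and
    ``nuc:preference_{stat}``. Deterministic; a window containing N is an
    error (no imputation).
    """
    seq = window_sequence(record, window)
    if "N" in seq:
        raise ValueError(
            f"promoter {record.id!r}, {window.describe()}: window contains N"
        )
    if len(seq) < max(config.kmer_ks):
        raise ValueError(
            f"promoter {record.id!r}, {window.describe()}: shorter than max k"
        )
    if scales is None:
        scales = _load_config_scales(config)
    features: dict[str, float] = {}
    for k in config.kmer_ks:
        for word, freq in kmer_frequencies(seq, k).items():
            features[f"kmer{k}:{word}"] = freq
    for word in config.tract_words:
        features[f"tract:{word}"] = _tract_statistic(seq, word, config.tract_statistic)
    from .mechanical_profiles import window_property_mean, window_property_sum

    summarize = window_property_mean if config.mech_statistic == "mean" else window_property_sum
    for name in config.mech_scales:
        features[f"mech:{name}_{config.mech_statistic}"] = summarize(seq, scales[name])
    if config.include_nucleosome:
        features[f"nuc:preference_{config.mech_statistic}"] = summarize(
            seq, scales["nucleosome_preference"]
        )
    return features


def _load_config_scales(config: FeatureConfig) -> dict[str, "PropertyScale"]:
    from .mechanical_profiles import load_scales

    return load_scales(config.scale_names())


@dataclass
class FeatureMatrix:
    """Promoters x named numeric features for one window specification."""

    promoter_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    window: str = ""
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.promoter_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.promoter_ids)} promoters x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        self._col = {name: j for j, name in enumerate(self.feature_names)}

    @property
    def n_promoters(self) -> int:
        return len(self.promoter_ids)

    def column(self, name: str) -> np.ndarray:
        if name not in self._col:
            raise KeyError(f"feature {name!r} not in matrix")
        return self.values[:, self._col[name]]

    def subset(self, features: Sequence[str]) -> np.ndarray:
        missing = [f for f in features if f not in self._col]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return self.values[:, [self._col[f] for f in features]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.promoter_ids, name="promoter_id"),
            columns=self.feature_names,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, window: str = "") -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            promoter_ids=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            window=window,
        )


def build_feature_matrix(
    pset: PromoterSet,
    window_selector: WindowSelector,
    config: FeatureConfig,
    scales: Mapping[str, "PropertyScale"] | None = None,
) -> FeatureMatrix:
    """One feature row per promoter for the selected window.

    ``window_selector`` is ``("index", i)`` for the i-th fixed window or
    ``"full"``. Promoters too short to contain the selected fixed window are
    dropped with a warning and listed in ``FeatureMatrix.dropped``; dropping
    everything is an error.
    """
    if scales is None:
        scales = _load_config_scales(config)
    width = config.window_width
    rows: list[list[float]] = []
    kept: list[str] = []
    dropped: list[str] = []
    names: list[str] | None = None
    for rec in pset:
        if window_selector == "full":
            window = Window("full", -len(rec), 0)
        else:
            kind, idx = window_selector
            if kind != "index":
                raise ValueError(f"unknown window selector {window_selector!r}")
            if len(rec) < idx * width:
                dropped.append(rec.id)
                continue
            window = Window("fixed", -idx * width, -(idx - 1) * width, index=idx)
        feats = extract_window_features(rec, window, config, scales)
        if names is None:
            names = list(feats)
        rows.append([feats[n] for n in names])
        kept.append(rec.id)
    if dropped:
        logger.warning(
            "build_feature_matrix: dropped %d promoter(s) too short for %r: %s",
            len(dropped), window_selector, dropped,
        )
    if not rows:
        raise ValueError(f"no promoter contains the selected window {window_selector!r}")
    label = "full" if window_selector == "full" else f"index:{window_selector[1]}:width={width}"
    return FeatureMatrix(kept, names or [], np.array(rows), window=label, dropped=dropped)
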