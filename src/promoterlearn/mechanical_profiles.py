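"""Positional DNA physical-property profiles from di/trinucleotide scales.

A :class:`PropertyScale` maps every DNA word of a fixed length (2 or 3) to a
numeric parameter — bendability, protein-induced deformability, bending
stiffness, or nucleosome binding preference. Sliding the word along a
promoter gives a positional profile; averaging it over a window gives the
mechanical features used by the activity model, and averaging it over a
TrSS-relative region supports group comparisons such as high- vs low-activity
promoters (Welch t-test).

Scales are applied to the given strand only: the promoters are
orientation-defined. ``PropertyScale.symmetrize`` is available for scales
published strand-symmetrically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .promoter_io import PromoterRecord, PromoterSet

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: packaged scale name -> data file
PACKAGED_SCALES = {
    "bendability": "bendability.tsv",
    "deformability": "deformability.tsv",
    "stiffness": "stiffness.tsv",
    "nucleosome_preference": "nucleosome_preference_synthetic.tsv",
}


def _reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


@dataclass
class PropertyScale:
    """A named word -> parameter table (complete over all 4^word_length words)."""

    name: str
    word_length: int
    table: dict[str, float]
    unit: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.word_length not in (2, 3):
            raise ValueError(f"word_length must be 2 or 3, got {self.word_length}")
        expected = {"".join(p) for p in product(_BASES, repeat=self.word_length)}
        missing = sorted(expected - set(self.table))
        if missing:
            raise ValueError(f"scale {self.name!r}: missing words {missing}")
        extra = sorted(set(self.table) - expected)
        if extra:
            raise ValueError(f"scale {self.name!r}: unexpected words {extra}")
        bad = [w for w, v in self.table.items() if not math.isfinite(float(v))]
        if bad:
            raise ValueError(f"scale {self.name!r}: non-finite values for {bad}")
        self.table = {w: float(v) for w, v in self.table.items()}

    def symmetrize(self) -> "PropertyScale":
        """Average each word with its reverse complement (strand-symmetric view)."""
        table = {
            w: 0.5 * (v + self.table[_reverse_complement(w)])
            for w, v in self.table.items()
        }
        return replace(self, table=table, name=f"{self.name}_symmetrized")


def uniform_scale(name: str, word_length: int, value: float = 1.0) -> PropertyScale:
    """A toy scale assigning ``value`` to every word — handy in tests."""
    table = {"".join(p): value for p in product(_BASES, repeat=word_length)}
    return PropertyScale(name=name, word_length=word_length, table=table, unit="toy")


def available_scales() -> list[str]:
    return sorted(PACKAGED_SCALES)


def load_scale(name_or_path: str | Path) -> PropertyScale:
    """Load a packaged scale by name or a scale file by path.

    Scale files are TSV ``word<TAB>value`` with optional ``#name=``, ``#unit=``
    and ``#source=`` header lines. Completeness over all 4^word_length words
    is enforced; duplicates are errors.
    """
    key = str(name_or_path)
    if key in PACKAGED_SCALES:
        ref = resources.files("promoterlearn.data.scales") / PACKAGED_SCALES[key]
        text = ref.read_text()
        default_name = key
    else:
        text = Path(name_or_path).read_text()
        default_name = Path(name_or_path).stem
    meta = {"name": default_name, "unit": "", "source": ""}
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
            continue
        word, _, value = line.partition("\t")
        word = word.upper()
        if word in table:
            raise ValueError(f"scale {meta['name']!r}: duplicate word {word!r}")
        table[word] = float(value)
    if not table:
        raise ValueError(f"scale {meta['name']!r}: empty table")
    word_length = len(next(iter(table)))
    return PropertyScale(
        name=meta["name"], word_length=word_length, table=table,
        unit=meta["unit"], source=meta["source"],
    )


def load_scales(names: Iterable[str | Path]) -> dict[str, PropertyScale]:
    scales = {}
    for name in names:
        scale = load_scale(name)
        scales[scale.name] = scale
    return scales


@dataclass
class PropertyProfile:
    """Per-position property values for one promoter under one scale.

    ``positions[i]`` is the TrSS-relative offset of the first base of the
    word scored at ``values[i]``; for a promoter of length L the positions run
    -L .. -word_length.
    """

    promoter_id: str
    scale_name: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values differ in length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


def _as_sequence(seq_or_record: str | PromoterRecord) -> tuple[str, str]:
    if isinstance(seq_or_record, PromoterRecord):
        return seq_or_record.sequence, seq_or_record.id
    return seq_or_record, ""


def property_profile(seq_or_record: str | PromoterRecord, scale: PropertyScale) -> PropertyProfile:
    """Slide the scale's word along the sequence: values[i] = table[seq[i:i+k]]."""
    seq, pid = _as_sequence(seq_or_record)
    k = scale.word_length
    if len(seq) < k:
        raise ValueError(f"sequence shorter than word length {k}")
    if "N" in seq:
        raise ValueError(f"sequence{' ' + pid if pid else ''} contains N")
    L = len(seq)
    values = np.array([scale.table[seq[i : i + k]] for i in range(L - k + 1)])
    positions = np.arange(-L, -k + 1)
    return PropertyProfile(pid, scale.name, positions, values)


def window_property_mean(seq: str | PromoterRecord, scale: PropertyScale) -> float:
    """Arithmetic mean of the property profile over the whole (window) sequence."""
    return float(property_profile(seq, scale).values.mean())


def window_property_sum(seq: str | PromoterRecord, scale: PropertyScale) -> float:
    return float(property_profile(seq, scale).values.sum())


def smoothed_profile(profile: PropertyProfile, half_width: int) -> PropertyProfile:
    """Centered moving average with shrinking windows at the boundaries."""
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if half_width == 0:
        return PropertyProfile(
            profile.promoter_id, profile.scale_name,
            profile.positions.copy(), profile.values.copy(),
        )
    v = profile.values
    n = len(v)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_width)
        hi = min(n, i + half_width + 1)
        out[i] = v[lo:hi].mean()
    return PropertyProfile(
        profile.promoter_id, profile.scale_name, profile.positions.copy(), out
    )


@dataclass
class RegionComparison:
    """Welch t-test of per-promoter mean property over a TrSS-relative region."""

    mean_a: float
    mean_b: float
    difference: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    region: tuple[int, int]
    dropped: list[str] = field(default_factory=list)


def region_property_means(
    pset: PromoterSet, scale: PropertyScale, region: tuple[int, int]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-promoter mean of the profile restricted to [region[0], region[1]).

    A word contributes if its first-base offset lies in the region. Promoters
    not covering the region are dropped with a warning.
    Returns (means, kept_ids, dropped_ids).
    """
    start, end = region
    if start >= end or end > 0:
        raise ValueError(f"invalid region [{start}, {end}): need start < end <= 0")
    means: list[float] = []
    kept: list[str] = []
    dropped: list[str] = []
    for rec in pset:
        if len(rec) < -start:
            dropped.append(rec.id)
            continue
        profile = property_profile(rec, scale)
        mask = (profile.positions >= start) & (profile.positions < end)
        if not mask.any():
            dropped.append(rec.id)
            continue
        means.append(float(profile.values[mask].mean()))
        kept.append(rec.id)
    if dropped:
        logger.warning(
            "region [%d,%d): dropped promoters not covering it: %s", start, end, dropped
        )
    return np.array(means), kept, dropped


def region_group_comparison(
    group_a: PromoterSet,
    group_b: PromoterSet,
    scale: PropertyScale,
    region: tuple[int, int] = (-60, -40),
) -> RegionComparison:
    """Compare mean property over a region between two promoter groups.

    Each promoter is summarized by the mean profile value inside the region;
    the groups are compared with a Welch (unequal-variance) two-sample t-test.
    The default region [-60, -40) is the TrSS-proximal band where deformability
    separates high- from low-activity promoters.
    """
    means_a, _, dropped_a = region_property_means(group_a, scale, region)
    means_b, _, dropped_b = region_property_means(group_b, scale, region)
    if len(means_a) == 0 or len(means_b) == 0:
        raise ValueError("a group is empty after dropping promoters not covering the region")
    t_stat, p_value = stats.ttest_ind(means_a, means_b, equal_var=False)
    return RegionComparison(
        mean_a=float(means_a.mean()),
        mean_b=float(means_b.mean()),
        difference=float(means_a.mean() - means_b.mean()),
        t_statistic=float(t_stat),
        p_value=float(p_value),
        n_a=len(means_a),
        n_b=len(means_b),
        region=(int(region[0]), int(region[1])),
        dropped=dropped_a + dropped_b,
    )
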