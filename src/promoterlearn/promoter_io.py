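"""Reading and writing promoter sequences, activities, and prediction tables.

Promoter sequences are given 5'->3' with the last base sitting immediately
upstream of the translation start site (TrSS); all coordinates elsewhere in
the package are negative offsets relative to the TrSS, half-open, with
position -1 being the last promoter base.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


@dataclass
class PromoterRecord:
    """One promoter: id, sequence (stored uppercase), optional measured activity.

    ``activity`` is a non-negative real in arbitrary fluorescence-rate units
    (reporter protein produced per cell per second); ``label`` is an optional
    category tag such as ``"natural"`` or ``"mutated"``.
    """

    id: str
    sequence: str
    activity: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("promoter id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"promoter {self.id!r}: sequence must be non-empty")
        for offset, base in enumerate(seq):
            if base not in VALID_BASES:
                raise ValueError(
                    f"promoter {self.id!r}: invalid character {base!r} at offset {offset}"
                )
        self.sequence = seq
        if self.activity is not None:
            act = float(self.activity)
            if not math.isfinite(act) or act < 0:
                raise ValueError(
                    f"promoter {self.id!r}: activity must be finite and >= 0, got {self.activity!r}"
                )
            self.activity = act

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PromoterSet:
    """Ordered collection of :class:`PromoterRecord` with unique ids."""

    records: list[PromoterRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate promoter id {rec.id!r}")
            seen.add(rec.id)
        self._by_id = {rec.id: rec for rec in self.records}

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: int | str) -> PromoterRecord:
        if isinstance(key, str):
            return self._by_id[key]
        return self.records[key]

    def __contains__(self, promoter_id: str) -> bool:
        return promoter_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def with_activities(self) -> "PromoterSet":
        """Subset of records that carry a measured activity (order preserved)."""
        return PromoterSet(
            [rec for rec in self.records if rec.activity is not None],
            provenance=dict(self.provenance),
        )

    def activity_vector(self) -> list[float]:
        """Activities in record order; raises if any record lacks one."""
        missing = [rec.id for rec in self.records if rec.activity is None]
        if missing:
            raise ValueError(f"promoters without activity: {missing}")
        return [float(rec.activity) for rec in self.records]  # type: ignore[arg-type]


def read_activity_table(path: str | Path) -> dict[str, float]:
    """Read a 2+ column TSV of (promoter id, activity).

    A header row is auto-detected: if column 2 of the first row does not parse
    as a number the row is treated as a header. Extra columns are ignored with
    a warning.
    """
    path = Path(path)
    activities: dict[str, float] = {}
    with path.open() as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        return activities
    start = 0
    try:
        float(rows[0][1])
    except (ValueError, IndexError):
        start = 1
    warned_extra = False
    for row in rows[start:]:
        if len(row) < 2:
            raise ValueError(f"{path}: activity row with fewer than 2 columns: {row!r}")
        if len(row) > 2 and not warned_extra:
            logger.warning("%s: ignoring extra columns beyond the first two", path)
            warned_extra = True
        pid = row[0]
        try:
            value = float(row[1])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric activity for {pid!r}: {row[1]!r}") from exc
        if not math.isfinite(value) or value < 0:
            raise ValueError(f"{path}: activity for {pid!r} must be finite and >= 0, got {value}")
        if pid in activities:
            raise ValueError(f"{path}: duplicate activity row for {pid!r}")
        activities[pid] = value
    return activities


def read_promoters(fasta_path: str | Path, activity_path: str | Path | None = None) -> PromoterSet:
    """Read promoters from FASTA, optionally joining activities by id.

    Every FASTA record becomes a :class:`PromoterRecord` (sequence uppercased,
    validated over {A,C,G,T,N}); an activity row whose id is absent from the
    FASTA is an error. FASTA records without an activity row keep
    ``activity=None``.
    """
    fasta_path = Path(fasta_path)
    seen: set[str] = set()
    records: list[PromoterRecord] = []
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        if seqrec.id in seen:
            raise ValueError(f"{fasta_path}: duplicate FASTA id {seqrec.id!r}")
        seen.add(seqrec.id)
        records.append(PromoterRecord(id=seqrec.id, sequence=str(seqrec.seq)))
    provenance = {"fasta": str(fasta_path)}
    if activity_path is not None:
        activities = read_activity_table(activity_path)
        unknown = sorted(set(activities) - seen)
        if unknown:
            raise ValueError(
                f"{activity_path}: activity rows for ids absent from FASTA: {unknown}"
            )
        for rec in records:
            if rec.id in activities:
                rec.activity = activities[rec.id]
        provenance["activities"] = str(activity_path)
    return PromoterSet(records, provenance=provenance)


def write_promoters(
    pset: PromoterSet,
    fasta_path: str | Path,
    activity_path: str | Path | None = None,
    line_width: int = 60,
) -> None:
    """Write a promoter set as FASTA (wrapped) plus optional activity TSV."""
    with Path(fasta_path).open("w") as fh:
        for rec in pset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")
    if activity_path is not None:
        with Path(activity_path).open("w") as fh:
            fh.write("promoter_id\tactivity\n")
            for rec in pset:
                if rec.activity is not None:
                    fh.write(f"{rec.id}\t{rec.activity:.9g}\n")


def write_predictions(ids: Sequence[str], predictions: Sequence[float], path: str | Path) -> None:
    """Write a 2-column TSV of (promoter_id, predicted_activity), input order."""
    if len(ids) != len(predictions):
        raise ValueError(
            f"ids and predictions differ in length: {len(ids)} vs {len(predictions)}"
        )
    with Path(path).open("w") as fh:
        fh.write("promoter_id\tpredicted_activity\n")
        for pid, value in zip(ids, predictions):
            fh.write(f"{pid}\t{float(value):.9g}\n")


def read_predictions(path: str | Path) -> tuple[list[str], list[float]]:
    """Read a prediction TSV written by :func:`write_predictions`."""
    ids: list[str] = []
    values: list[float] = []
    with Path(path).open() as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    start = 0
    if rows:
        try:
            float(rows[0][1])
        except (ValueError, IndexError):
            start = 1
    for row in rows[start:]:
        ids.append(row[0])
        values.append(float(row[1]))
    return ids, values
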