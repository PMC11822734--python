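"""Timestamp parsing, processing-delay computation and SPREC delay coding.

Blood samples in centralized biobanks experience two room-temperature
delays that matter for metabolite concentrations: the *precentrifugation*
delay (collection to centrifugation, cells still in contact with
plasma/serum) and the *postcentrifugation* delay (end of centrifugation
to freezing). The Standard PREanalytical Code (SPREC) assigns a category
letter to each delay; this module computes both delays from the three
timestamps a laboratory information system records and assigns the
room-temperature SPREC delay letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Material",
    "Phase",
    "SampleRecord",
    "SPRECLadder",
    "PRE_LADDER",
    "POST_LADDER",
    "compute_delays",
    "classify_delay",
    "prepare_cohort",
    "read_cohort_table",
    "spre_distribution",
]


class Material(str, Enum):
    """Blood collection matrix."""

    EDTA = "EDTA"
    LiHep = "LiHep"
    Serum = "Serum"


class Phase(str, Enum):
    """Which processing delay a quantity refers to."""

    pre = "pre"
    post = "post"


@dataclass
class SampleRecord:
    """One biobank sample: identifiers, timestamps and derived delays.

    Delays are in hours. ``spre_code_pre`` / ``spre_code_post`` hold the
    SPREC delay letters once assigned. Records that cannot be validated
    (unparseable timestamps, negative delays) are flagged ``invalid``
    with a reason rather than silently dropped.
    """

    sample_id: str
    material: Material
    collection_dt: datetime | None = None
    centrifugation_dt: datetime | None = None
    freezing_dt: datetime | None = None
    centrifugation_duration_min: float | None = None
    pre_delay_h: float | None = None
    post_delay_h: float | None = None
    spre_code_pre: str | None = None
    spre_code_post: str | None = None
    invalid: bool = False
    invalid_reason: str | None = None


@dataclass(frozen=True)
class SPRECLadder:
    """Ordered delay bins mapping hours to SPREC category letters.

    Bins are left-closed, right-open ``[lo, hi)``, contiguous, and start
    at 0 h. Delays at or beyond the last bin's upper edge map to
    ``overflow_letter``. Ladders are plain data so that variants (e.g.
    cold-chain codes) can be supplied without code changes.
    """

    phase: Phase
    bins: tuple[tuple[str, float, float], ...]
    overflow_letter: str = "X"

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("ladder needs at least one bin")
        letters = [b[0] for b in self.bins]
        if len(set(letters)) != len(letters):
            raise ValueError("ladder letters must be unique")
        lo0 = self.bins[0][1]
        if lo0 != 0.0:
            raise ValueError("first bin must start at 0 h")
        prev_hi = 0.0
        for letter, lo, hi in self.bins:
            if lo != prev_hi:
                raise ValueError(f"bins not contiguous at letter {letter!r}")
            if hi <= lo:
                raise ValueError(f"empty bin {letter!r}")
            prev_hi = hi

    @property
    def letters(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bins) + (self.overflow_letter,)

    def classify(self, delay_h: float) -> str:
        return classify_delay(delay_h, self)


#: Room-temperature precentrifugation ladder: A1 < 30 min, A < 2 h,
#: C 2-4 h, E 4-8 h, G 8-12 h. A1 is carved out of A's range because the
#: two are reported as disjoint categories.
PRE_LADDER = SPRECLadder(
    phase=Phase.pre,
    bins=(
        ("A1", 0.0, 0.5),
        ("A", 0.5, 2.0),
        ("C", 2.0, 4.0),
        ("E", 4.0, 8.0),
        ("G", 8.0, 12.0),
    ),
)

#: Room-temperature postcentrifugation ladder: B < 1 h, D 1-2 h, F 2-8 h.
POST_LADDER = SPRECLadder(
    phase=Phase.post,
    bins=(
        ("B", 0.0, 1.0),
        ("D", 1.0, 2.0),
        ("F", 2.0, 8.0),
    ),
)


def classify_delay(delay_h: float, ladder: SPRECLadder) -> str:
    """Return the SPREC letter whose bin contains ``delay_h``.

    Bins are left-closed, right-open; delays beyond the last bin map to
    the ladder's overflow letter.
    """
    if delay_h < 0:
        raise ValueError(f"delay must be non-negative, got {delay_h}")
    for letter, lo, hi in ladder.bins:
        if lo <= delay_h < hi:
            return letter
    return ladder.overflow_letter


def _parse_dt(value) -> datetime | None:
    """Parse an ISO-8601-ish timestamp; None/NaN/empty → None."""
    if value is None:
        return None
    if isinstance(value, datetime):
        return None if pd.isna(value) else value
    if isinstance(value, float) and pd.isna(value):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"nan", "nat", "none", "na"}:
        return None
    ts = pd.to_datetime(s, errors="coerce")
    if pd.isna(ts):
        raise ValueError(f"unparseable timestamp: {value!r}")
    return ts.to_pydatetime()


def compute_delays(
    record: SampleRecord,
    default_centrifugation_min: float = 0.0,
    material_offset_min: float = 0.0,
) -> SampleRecord:
    """Fill in pre- and postcentrifugation delays (hours) for a record.

    ``pre_delay_h`` is collection→centrifugation; ``post_delay_h`` is
    centrifugation→freezing minus the centrifugation duration (spin time
    is not a room-temperature delay of the separated fraction). When the
    record carries no per-sample duration, ``default_centrifugation_min``
    is used — set it to the protocol spin time (commonly 10 min) if the
    recorded timestamp marks the *start* of centrifugation, or leave at 0
    if it marks the end.

    ``material_offset_min`` subtracts a per-material offset from the
    precentrifugation delay (e.g. a serum clotting time when time zero is
    defined after clotting); default 0.

    Invalid inputs (missing/unparseable timestamps, negative delays)
    flag the record rather than raising.
    """
    rec = replace(record)
    if rec.collection_dt is None or rec.centrifugation_dt is None or rec.freezing_dt is None:
        rec.invalid = True
        rec.invalid_reason = "missing timestamp"
        return rec
    duration_min = (
        rec.centrifugation_duration_min
        if rec.centrifugation_duration_min is not None
        else default_centrifugation_min
    )
    if duration_min < 0:
        rec.invalid = True
        rec.invalid_reason = "negative centrifugation duration"
        return rec
    pre_h = (rec.centrifugation_dt - rec.collection_dt).total_seconds() / 3600.0
    pre_h -= material_offset_min / 60.0
    post_h = (rec.freezing_dt - rec.centrifugation_dt).total_seconds() / 3600.0
    post_h -= duration_min / 60.0
    if pre_h < 0:
        rec.invalid = True
        rec.invalid_reason = "negative pre delay"
        return rec
    if post_h < 0:
        rec.invalid = True
        rec.invalid_reason = "negative post delay"
        return rec
    rec.centrifugation_duration_min = duration_min
    rec.pre_delay_h = pre_h
    rec.post_delay_h = post_h
    return rec


_REQUIRED_COLUMNS = ("sample_id", "material", "collection_dt", "centrifugation_dt", "freezing_dt")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort timestamp table (comma- or tab-delimited, auto-detected)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df


def prepare_cohort(
    rows: pd.DataFrame,
    max_delay_h: float = 6.0,
    default_centrifugation_min: float = 0.0,
    pre_ladder: SPRECLadder = PRE_LADDER,
    post_ladder: SPRECLadder = POST_LADDER,
    material_offsets_min: dict[str, float] | None = None,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Validate a raw cohort table into SampleRecords with SPREC letters.

    Returns ``(records, exclusion_log)``. A row is excluded — with a
    reason in the log — when a timestamp is missing or unparseable, a
    delay is negative, or either delay exceeds ``max_delay_h`` (extreme
    processing times; default 6 h). Retained records carry both delays
    and both SPREC letters.
    """
    records: list[SampleRecord] = []
    excluded: list[dict] = []
    if rows.empty:
        warnings.warn("empty cohort table", stacklevel=2)
        return records, pd.DataFrame(columns=["sample_id", "reason"])
    offsets = material_offsets_min or {}

    for _, row in rows.iterrows():
        sample_id = str(row.get("sample_id", ""))
        material_raw = row.get("material")
        try:
            material = Material(str(material_raw))
        except ValueError:
            excluded.append({"sample_id": sample_id, "reason": f"unknown material {material_raw!r}"})
            continue
        try:
            coll = _parse_dt(row.get("collection_dt"))
            cent = _parse_dt(row.get("centrifugation_dt"))
            frz = _parse_dt(row.get("freezing_dt"))
        except ValueError:
            excluded.append({"sample_id": sample_id, "reason": "unparseable timestamp"})
            continue
        dur_raw = row.get("centrifugation_duration_min")
        duration = None
        if dur_raw is not None and not pd.isna(dur_raw) and str(dur_raw).strip() != "":
            duration = float(dur_raw)
        rec = SampleRecord(
            sample_id=sample_id,
            material=material,
            collection_dt=coll,
            centrifugation_dt=cent,
            freezing_dt=frz,
            centrifugation_duration_min=duration,
        )
        rec = compute_delays(
            rec,
            default_centrifugation_min=default_centrifugation_min,
            material_offset_min=offsets.get(material.value, 0.0),
        )
        if rec.invalid:
            excluded.append({"sample_id": sample_id, "reason": rec.invalid_reason})
            continue
        if rec.pre_delay_h > max_delay_h or rec.post_delay_h > max_delay_h:
            excluded.append({"sample_id": sample_id, "reason": "delay > max"})
            continue
        rec.spre_code_pre = classify_delay(rec.pre_delay_h, pre_ladder)
        rec.spre_code_post = classify_delay(rec.post_delay_h, post_ladder)
        records.append(rec)

    log = pd.DataFrame(excluded, columns=["sample_id", "reason"])
    return records, log


def spre_distribution(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Per-phase SPREC letter counts and fractions over retained records.

    Returns a tidy frame with columns phase, letter, count, fraction;
    fractions sum to 1 within each phase (empty input → empty frame).
    """
    rows = []
    for phase, attr in ((Phase.pre, "spre_code_pre"), (Phase.post, "spre_code_post")):
        letters = [getattr(r, attr) for r in records if getattr(r, attr) is not None]
        n = len(letters)
        if n == 0:
            continue
        counts = pd.Series(letters).value_counts()
        for letter, count in counts.items():
            rows.append(
                {
                    "phase": phase.value,
                    "letter": letter,
                    "count": int(count),
                    "fraction": count / n,
                }
            )
    return pd.DataFrame(rows, columns=["phase", "letter", "count", "fraction"])


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame for delimited-text output."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "material": r.material.value,
                "collection_dt": r.collection_dt,
                "centrifugation_dt": r.centrifugation_dt,
                "freezing_dt": r.freezing_dt,
                "centrifugation_duration_min": r.centrifugation_duration_min,
                "pre_delay_h": r.pre_delay_h,
                "post_delay_h": r.post_delay_h,
                "spre_code_pre": r.spre_code_pre,
                "spre_code_post": r.spre_code_post,
            }
            for r in records
        ]
    )
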