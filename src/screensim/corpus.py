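"""Labeled bibliographic corpora: reading, validation, preprocessing, statistics.

A screening corpus is an ordered pool of candidate publications, each carrying
a binary relevance label recorded by the original review team.  Simulations
replay the screening of such a fully labeled pool, so the corpus is the single
source of truth for record identity, text, and the oracle labels.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LabeledRecord",
    "LabeledCorpus",
    "CorpusStats",
    "PreprocessReport",
    "CorpusError",
    "ConfigurationError",
    "DataError",
    "PreprocessingError",
    "read_labeled_csv",
    "write_labeled_csv",
    "read_ris",
    "preprocess",
    "corpus_stats",
    "round_half_away",
]


class CorpusError(Exception):
    """Base class for corpus-layer failures."""


class ConfigurationError(CorpusError):
    """The caller's configuration (column map, label source, ...) is unusable."""


class DataError(CorpusError):
    """The input data violate the format contract."""


class PreprocessingError(CorpusError):
    """Preprocessing left the corpus unusable for simulation."""


_TRUE_LABELS = {"1", "true", "yes", "y", "included", "include", "relevant"}
_FALSE_LABELS = {"0", "false", "no", "n", "excluded", "exclude", "irrelevant"}


@dataclass(frozen=True)
class LabeledRecord:
    """One candidate publication with its screening decision."""

    record_id: str
    title: str
    abstract: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise DataError(f"record {self.record_id!r}: label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class LabeledCorpus:
    """Ordered pool of labeled records; the unit every simulation runs on."""

    records: tuple[LabeledRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise DataError(f"duplicate record_id {rec.record_id!r} in corpus")
            seen.add(rec.record_id)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_relevant(self) -> int:
        return sum(rec.label for rec in self.records)

    @property
    def labels(self) -> list[int]:
        return [rec.label for rec in self.records]

    @property
    def record_ids(self) -> list[str]:
        return [rec.record_id for rec in self.records]

    def texts(self) -> list[str]:
        """Title and abstract concatenated, per record, in pool order."""
        return [f"{rec.title} {rec.abstract}".strip() for rec in self.records]

    def validate_for_simulation(self) -> None:
        """Both classes must be present and the pool must be non-trivial."""
        if self.n < 2:
            raise DataError(f"corpus has {self.n} records; at least 2 required")
        if not 1 <= self.n_relevant < self.n:
            raise DataError(
                f"corpus needs at least one record of each class "
                f"(N={self.n}, relevant={self.n_relevant})"
            )

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> LabeledRecord:
        return self.records[i]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    scale = 10**ndigits
    scaled = x * scale
    import math

    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / scale


@dataclass(frozen=True)
class CorpusStats:
    """Composition summary: pool size, relevant count, prevalence in percent."""

    n: int
    n_relevant: int
    proportion_relevant: float  # percent, 1 decimal


def corpus_stats(corpus: LabeledCorpus) -> CorpusStats:
    """Composition statistics of a corpus (prevalence as a 1-decimal percent)."""
    n, r = corpus.n, corpus.n_relevant
    if n == 0:
        raise DataError("empty corpus has no statistics")
    return CorpusStats(n=n, n_relevant=r, proportion_relevant=round_half_away(100.0 * r / n, 1))


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS: Mapping[str, str] = {
    "record_id": "record_id",
    "title": "title",
    "abstract": "abstract",
    "label": "label",
}


def _parse_label(raw: str, row_number: int) -> int:
    token = raw.strip().lower()
    if token in _TRUE_LABELS:
        return 1
    if token in _FALSE_LABELS:
        return 0
    raise DataError(f"row {row_number}: cannot parse label value {raw!r} as binary")


def read_labeled_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> LabeledCorpus:
    """Read a labeled corpus from CSV.

    ``column_map`` maps the roles ``record_id``/``title``/``abstract``/``label``
    to column names in the file; the id column is optional (ids are synthesized
    as zero-padded row indices when absent).  Labels accept 0/1, true/false and
    yes/no case-insensitively.  Row order is preserved.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataError(f"{path}: empty CSV, no header row")
        for role in ("title", "abstract", "label"):
            if colmap[role] not in reader.fieldnames:
                raise ConfigurationError(
                    f"{path}: required column {colmap[role]!r} (role {role!r}) not in header"
                )
        has_id = colmap["record_id"] in reader.fieldnames
        records = []
        for i, row in enumerate(reader):
            row_number = i + 2  # header is line 1
            rid = row[colmap["record_id"]] if has_id else f"{i:06d}"
            records.append(
                LabeledRecord(
                    record_id=str(rid),
                    title=(row[colmap["title"]] or ""),
                    abstract=(row[colmap["abstract"]] or ""),
                    label=_parse_label(row[colmap["label"]] or "", row_number),
                )
            )
    return LabeledCorpus(records=tuple(records))


def write_labeled_csv(corpus: LabeledCorpus, path: str | Path) -> None:
    """Write the canonical CSV dialect (UTF-8, RFC-4180 quoting)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "title", "abstract", "label"])
        for rec in corpus:
            writer.writerow([rec.record_id, rec.title, rec.abstract, rec.label])


# ---------------------------------------------------------------------------
# RIS input
# ---------------------------------------------------------------------------

_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def read_ris(
    path: str | Path,
    inclusion_ids: Iterable[str] | None = None,
    label_tag: str | None = None,
) -> LabeledCorpus:
    """Read records from a RIS file (TY/TI/AB/ER tags).

    RIS carries no inclusion decision, so labels come either from
    ``inclusion_ids`` (ids labeled 1, the rest 0) or from a custom per-record
    ``label_tag`` whose value parses as a binary label.  Record ids come from
    the ID tag when present, else zero-padded record indices.
    """
    if inclusion_ids is None and label_tag is None:
        raise ConfigurationError("RIS input needs a label source: inclusion_ids or label_tag")
    include = set(inclusion_ids) if inclusion_ids is not None else None

    path = Path(path)
    records: list[LabeledRecord] = []
    current: dict[str, str] | None = None
    index = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            m = _RIS_TAG.match(line)
            if not m:
                continue
            tag, value = m.group(1), m.group(2).strip()
            if tag == "TY":
                if current is not None:
                    raise DataError(f"line {lineno}: new record before ER terminator")
                current = {}
            elif current is None:
                continue
            elif tag == "ER":
                rid = current.get("ID", f"{index:06d}")
                if include is not None:
                    label = 1 if rid in include else 0
                else:
                    label = _parse_label(current.get(label_tag, ""), lineno)
                records.append(
                    LabeledRecord(
                        record_id=rid,
                        title=current.get("TI", ""),
                        abstract=current.get("AB", ""),
                        label=label,
                    )
                )
                current = None
                index += 1
            else:
                # later duplicate tags append (RIS continuation style)
                current[tag] = (current.get(tag, "") + " " + value).strip()
    if current is not None:
        raise DataError(f"{path}: last record not terminated by ER")
    return LabeledCorpus(records=tuple(records))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def _dedup_key(rec: LabeledRecord) -> str:
    # lowercased, whitespace-collapsed title+abstract
    return _WS.sub(" ", f"{rec.title} {rec.abstract}".lower()).strip()


@dataclass
class PreprocessReport:
    """Counts of records removed, by reason."""

    missing_abstract: int = 0
    duplicate: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"missing_abstract": self.missing_abstract, "duplicate": self.duplicate}


def preprocess(corpus: LabeledCorpus) -> tuple[LabeledCorpus, PreprocessReport]:
    """Drop records with missing abstracts, then deduplicate.

    A missing abstract is empty or whitespace-only after trimming.  Duplicates
    share an identical normalized title+abstract (lowercased, whitespace
    collapsed); the first occurrence wins.  Relative order is preserved.
    """
    report = PreprocessReport()
    kept: list[LabeledRecord] = []
    seen: set[str] = set()
    for rec in corpus:
        if not rec.abstract.strip():
            report.missing_abstract += 1
            continue
        key = _dedup_key(rec)
        if key in seen:
            report.duplicate += 1
            continue
        seen.add(key)
        kept.append(rec)
    result = LabeledCorpus(records=tuple(kept))
    try:
        result.validate_for_simulation()
    except DataError as exc:
        raise PreprocessingError(f"preprocessing left an unusable corpus: {exc}") from exc
    return result, report
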