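"""The 31-item screening instrument: data model, cohort CSV I/O, ordinal
encoding, and the answer → fuzzy-rating bridge feeding the ranking channel.

The instrument has four criterion groups — 11 physical items, the 10
Kessler K10 distress items, 5 social-phobia items and 5 body-image items.
The physical group drives the PCOS channel (alternatives P1 high / P2
normal / P3 moderate); the other three groups drive the mental-health
channel (M1/M2/M3).  Expert labels, when present, are one of the fused
categories A1–A4.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .fuzzy import TFN
from .topsis import RATING_SCALE

CATEGORIES = ("A1", "A2", "A3", "A4")
PHYSICAL_ALTERNATIVES = ("P1", "P2", "P3")
MENTAL_ALTERNATIVES = ("M1", "M2", "M3")
#: Alternative roles in declared order: high severity, normal, moderate.
ALTERNATIVE_ROLES = ("high", "normal", "moderate")
LABEL_COLUMN = "label"

_RATING_ORDER = ("VL", "L", "M", "H", "VH")


@dataclass(frozen=True)
class Criterion:
    """One questionnaire item with its ordered categorical answer levels."""

    id: str
    group: str
    text: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"criterion {self.id} needs at least two answer levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"criterion {self.id} has duplicate answer levels")


class Instrument:
    """Ordered collection of criteria with group/channel bookkeeping."""

    def __init__(self, criteria: Sequence[Criterion]):
        ids = [c.id for c in criteria]
        if len(set(ids)) != len(ids):
            raise ValueError("criterion ids must be unique")
        self.criteria: tuple[Criterion, ...] = tuple(criteria)
        self._by_id = {c.id: c for c in self.criteria}

    def __len__(self) -> int:
        return len(self.criteria)

    def __getitem__(self, cid: str) -> Criterion:
        return self._by_id[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def channel_criteria(self, channel: str) -> tuple[Criterion, ...]:
        """Criteria of one screening channel: physical or mental."""
        if channel == "physical":
            return tuple(c for c in self.criteria if c.group == "physical")
        if channel == "mental":
            return tuple(c for c in self.criteria if c.group != "physical")
        raise ValueError(f"unknown channel {channel!r}")

    @classmethod
    def default(cls) -> "Instrument":
        """The shipped 31-item instrument definition."""
        from .datasets import default_instrument_config

        return cls.from_config(default_instrument_config())

    @classmethod
    def from_config(cls, entries: Sequence[Mapping]) -> "Instrument":
        return cls([
            Criterion(
                id=str(e["id"]),
                group=str(e["group"]),
                text=str(e["text"]),
                levels=tuple(str(v) for v in e["levels"]),
            )
            for e in entries
        ])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Instrument":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh)["criteria"])


@dataclass(frozen=True)
class SubjectResponse:
    """One subject's answer sheet plus an optional expert category label."""

    subject_id: str
    answers: dict[str, str]
    expert_label: str | None = None

    def __post_init__(self) -> None:
        if self.expert_label is not None and self.expert_label not in CATEGORIES:
            raise ValueError(
                f"subject {self.subject_id}: label {self.expert_label!r} "
                f"is not one of {CATEGORIES}"
            )


def _validate_subject(subject: SubjectResponse, instrument: Instrument, where: str) -> None:
    for cid in instrument.ids:
        if cid not in subject.answers:
            raise ValueError(f"{where}: missing answer for {cid}")
        ans = subject.answers[cid]
        if ans not in instrument[cid].levels:
            raise ValueError(f"{where}: column {cid}: unknown answer {ans!r}")
    extra = set(subject.answers) - set(instrument.ids)
    if extra:
        raise ValueError(f"{where}: answers for unknown criteria {sorted(extra)}")


def read_cohort_csv(path: str | Path, instrument: Instrument | None = None) -> list[SubjectResponse]:
    """Read a cohort CSV (one row per subject, columns C11…C45, optional label).

    Every cell is validated against the instrument's declared answer levels;
    missing or unknown values raise with the offending row and column named.
    """
    instrument = instrument or Instrument.default()
    subjects = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        known = set(instrument.ids) | {LABEL_COLUMN, "subject_id"}
        unknown_cols = [c for c in header if c not in known]
        if unknown_cols:
            raise ValueError(f"unknown columns in {path}: {unknown_cols}")
        missing_cols = [c for c in instrument.ids if c not in header]
        if missing_cols:
            raise ValueError(f"missing criterion columns in {path}: {missing_cols}")
        for rownum, row in enumerate(reader, start=2):
            sid = row.get("subject_id") or f"S{rownum - 1:04d}"
            label = row.get(LABEL_COLUMN) or None
            answers = {cid: (row.get(cid) or "") for cid in instrument.ids}
            subject = SubjectResponse(sid, answers, label)
            _validate_subject(subject, instrument, f"{path}: row {rownum}")
            subjects.append(subject)
    return subjects


def write_cohort_csv(
    subjects: Sequence[SubjectResponse], path: str | Path, instrument: Instrument | None = None
) -> None:
    """Write subjects in canonical column order; label column only if any subject has one."""
    if not subjects:
        raise ValueError("cannot write an empty cohort")
    instrument = instrument or Instrument.default()
    has_labels = any(s.expert_label is not None for s in subjects)
    header = ["subject_id", *instrument.ids] + ([LABEL_COLUMN] if has_labels else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in subjects:
            _validate_subject(s, instrument, f"subject {s.subject_id}")
            row = [s.subject_id] + [s.answers[cid] for cid in instrument.ids]
            if has_labels:
                row.append(s.expert_label or "")
            w.writerow(row)


def encode_ordinal(
    subjects: Sequence[SubjectResponse], instrument: Instrument | None = None
):
    """Encode answers as 0-based ordinal indices in declared level order.

    Returns ``(matrix, labels)`` where matrix is ``n_subjects × n_criteria``
    int array and labels is an int array with A1→0 … A4→3 (−1 when a
    subject is unlabelled).
    """
    import numpy as np

    instrument = instrument or Instrument.default()
    level_index = {c.id: {lv: k for k, lv in enumerate(c.levels)} for c in instrument.criteria}
    matrix = np.empty((len(subjects), len(instrument)), dtype=np.int64)
    labels = np.empty(len(subjects), dtype=np.int64)
    for i, s in enumerate(subjects):
        _validate_subject(s, instrument, f"subject {s.subject_id}")
        for j, cid in enumerate(instrument.ids):
            matrix[i, j] = level_index[cid][s.answers[cid]]
        labels[i] = CATEGORIES.index(s.expert_label) if s.expert_label else -1
    return matrix, labels


def decode_ordinal(matrix, labels, instrument: Instrument | None = None) -> list[SubjectResponse]:
    """Inverse of :func:`encode_ordinal` (subject ids regenerated)."""
    instrument = instrument or Instrument.default()
    out = []
    for i, row in enumerate(matrix):
        answers = {
            cid: instrument[cid].levels[int(v)] for cid, v in zip(instrument.ids, row)
        }
        lab = CATEGORIES[int(labels[i])] if labels is not None and labels[i] >= 0 else None
        out.append(SubjectResponse(f"S{i + 1:04d}", answers, lab))
    return out


@dataclass(frozen=True)
class RatingMap:
    """Maps (criterion, answer level) to a linguistic rating per alternative role.

    ``table[criterion_id][answer_level]`` is a mapping from alternative role
    (``high`` / ``normal`` / ``moderate``) to a rating label of the VL…VH
    scale.  The default map is monotone: the most symptomatic answer rates
    the high-severity alternative VH and the normal alternative VL, with the
    moderate alternative peaking at mid levels — severe answer sheets are
    thereby pushed towards P1/M1 and benign sheets towards P2/M2.
    """

    table: dict[str, dict[str, dict[str, str]]] = field(repr=False)

    def rating(self, criterion_id: str, level: str, role: str) -> TFN:
        try:
            label = self.table[criterion_id][level][role]
        except KeyError:
            raise ValueError(
                f"rating map does not cover (criterion {criterion_id!r}, "
                f"level {level!r}, role {role!r})"
            ) from None
        return RATING_SCALE[label]

    @classmethod
    def monotone_default(cls, instrument: Instrument) -> "RatingMap":
        """Construct the shipped monotone map for any instrument definition.

        For a criterion with L levels, answer index i is projected onto the
        five-point rating scale at position round(4·i/(L−1)); the high role
        reads the scale forwards, normal backwards, and moderate through a
        tent peaking at the middle.
        """
        high = _RATING_ORDER
        normal = tuple(reversed(_RATING_ORDER))
        moderate = ("VL", "M", "VH", "M", "VL")
        table: dict[str, dict[str, dict[str, str]]] = {}
        for c in instrument.criteria:
            per_level: dict[str, dict[str, str]] = {}
            span = len(c.levels) - 1
            for i, lv in enumerate(c.levels):
                k = round(4 * i / span)
                per_level[lv] = {"high": high[k], "normal": normal[k], "moderate": moderate[k]}
            table[c.id] = per_level
        return cls(table)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RatingMap":
        with open(path) as fh:
            return cls(yaml.safe_load(fh)["ratings"])

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"ratings": self.table}, fh, sort_keys=True)


def responses_to_ratings(
    subject: SubjectResponse,
    channel: str,
    rating_map: RatingMap,
    instrument: Instrument | None = None,
) -> tuple[tuple[str, ...], tuple[str, ...], list[list[TFN]]]:
    """Resolve a subject's answers into a 3 × n fuzzy rating grid for one channel.

    Returns ``(alternatives, criterion_ids, grid)`` where ``grid[a][j]`` is
    the TFN rating of alternative ``a`` on criterion ``j``.
    """
    instrument = instrument or Instrument.default()
    _validate_subject(subject, instrument, f"subject {subject.subject_id}")
    alternatives = PHYSICAL_ALTERNATIVES if channel == "physical" else MENTAL_ALTERNATIVES
    criteria = instrument.channel_criteria(channel)
    grid = [
        [
            rating_map.rating(c.id, subject.answers[c.id], role)
            for c in criteria
        ]
        for role in ALTERNATIVE_ROLES
    ]
    return alternatives, tuple(c.id for c in criteria), grid
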