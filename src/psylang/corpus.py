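"""Interview/cohort data model and transcript / feature-table I/O.

The unit of analysis is one clinical interview: an ordered sequence of
speaker-labelled turns (interviewer vs patient), subject metadata
(group, demographics, PANSS symptom scores) and, optionally, a voiced
speech timeline recovered from audio.

Two transcript dialects are supported:

``structured-transcript``
    JSON-lines: one record per turn with keys ``speaker``, ``text`` and
    optionally ``start_s``, ``end_s``, ``is_question``.  A record
    containing ``subject_id`` (no ``speaker``) is interview metadata.

``plain-text-two-speaker``
    UTF-8 text, one turn per line, prefixed ``E:``/``I:`` for the
    interviewer and ``P:`` for the patient.

Feature tables are CSV files with one extra leading header line that
tags every column with its category (fluency / productivity /
coherence / demographic / clinical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "Speaker",
    "Group",
    "Conversion",
    "Turn",
    "SubjectMeta",
    "Interview",
    "FeatureTable",
    "LANGUAGE_FEATURES",
    "FEATURE_CATEGORIES",
    "read_interview",
    "write_feature_table",
    "read_feature_table",
]


class Speaker(str, Enum):
    INTERVIEWER = "interviewer"
    PATIENT = "patient"


class Group(str, Enum):
    HC = "HC"
    FEP = "FEP"
    SZ = "SZ"


class Conversion(str, Enum):
    C_SZ = "C-SZ"
    NC_SZ = "NC-SZ"


class TranscriptParseError(ValueError):
    """Malformed transcript file; message names the offending line."""


class ValidationError(ValueError):
    """A domain invariant is violated."""


@dataclass(frozen=True)
class Turn:
    """One uninterrupted utterance by a single speaker."""

    speaker: Speaker
    text: str
    is_question: bool = False
    start_s: Optional[float] = None
    end_s: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValidationError("turn text is empty after trimming")
        if self.start_s is not None and self.end_s is not None and self.end_s < self.start_s:
            raise ValidationError(f"turn end_s {self.end_s} < start_s {self.start_s}")


@dataclass(frozen=True)
class SubjectMeta:
    """Subject-level demographics and clinical scores (PANSS)."""

    subject_id: str
    group: Group
    conversion: Optional[Conversion] = None
    gender: Optional[str] = None  # "M" / "F"
    age_years: Optional[float] = None
    education_years: Optional[float] = None
    illness_duration_years: Optional[float] = None
    first_degree_relative: Optional[bool] = None
    panss_pos: Optional[float] = None
    panss_neg: Optional[float] = None
    panss_gen: Optional[float] = None
    panss_total: Optional[float] = None

    def __post_init__(self) -> None:
        if self.conversion is not None and self.group is not Group.FEP:
            raise ValidationError("conversion label only valid for FEP subjects")
        subscales = [s for s in (self.panss_pos, self.panss_neg, self.panss_gen) if s is not None]
        if self.panss_total is not None and any(s > self.panss_total for s in subscales):
            raise ValidationError("panss_total must be >= every subscale")
        if self.group is Group.HC and any(
            v is not None for v in (self.panss_pos, self.panss_neg, self.panss_gen, self.panss_total)
        ):
            raise ValidationError("HC subjects carry no PANSS scores")


@dataclass
class Interview:
    """One interview: metadata, ordered turns, duration, optional timeline."""

    meta: SubjectMeta
    turns: Sequence[Turn]
    duration_s: float
    timeline: Optional[object] = None  # pauses.SpeechTimeline
    audio_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if not any(t.speaker is Speaker.PATIENT for t in self.turns):
            raise ValidationError("interview has no patient turns")
        stamped = [t for t in self.turns if t.start_s is not None]
        starts = [t.start_s for t in stamped]
        if starts != sorted(starts):
            raise ValidationError("turns not ordered by start_s")

    def patient_turns(self) -> list[Turn]:
        return [t for t in self.turns if t.speaker is Speaker.PATIENT]

    def qa_pairs(self) -> list[tuple[Turn, Turn]]:
        """Interviewer question turns paired with the next patient turn."""
        pairs = []
        for i, t in enumerate(self.turns):
            if t.speaker is Speaker.INTERVIEWER and t.is_question:
                for follow in self.turns[i + 1 :]:
                    if follow.speaker is Speaker.PATIENT:
                        pairs.append((t, follow))
                        break
                    if follow.speaker is Speaker.INTERVIEWER:
                        break
        return pairs


# Canonical 30-column language feature schema: 4 fluency, 20 productivity,
# 6 semantic coherence.
_FLUENCY = [
    "pause_count_gt2s",
    "qa_pairs_per_hour",
    "total_words_per_hour",
    "different_words_per_hour",
]
_PRONOUN_SUBCATS = ["personal", "possessive", "demonstrative", "indefinite", "interrogative", "relative"]
_DETERMINER_SUBCATS = [
    "definite_article",
    "indefinite",
    "possessive",
    "demonstrative",
    "interrogative",
    "numeral",
    "relative",
]
_PRODUCTIVITY = (
    [
        "total_words_per_answer_mean",
        "different_words_per_answer_mean",
        "mean_word_length_syllables",
        "ttr250",
        "ttr500",
        "ttr750",
        "ttr1000",
    ]
    + [f"pron_{s}_per_answer" for s in _PRONOUN_SUBCATS]
    + [f"det_{s}_per_answer" for s in _DETERMINER_SUBCATS]
)
_COHERENCE = [
    "qa_cos_mean",
    "qa_cos_min",
    "win5_cos_mean",
    "win5_cos_min",
    "win6_cos_mean",
    "win6_cos_min",
]

LANGUAGE_FEATURES: list[str] = _FLUENCY + _PRODUCTIVITY + _COHERENCE

FEATURE_CATEGORIES: dict[str, str] = (
    {f: "fluency" for f in _FLUENCY}
    | {f: "productivity" for f in _PRODUCTIVITY}
    | {f: "coherence" for f in _COHERENCE}
)

assert len(LANGUAGE_FEATURES) == 30


@dataclass
class FeatureTable:
    """Per-subject feature matrix with a category tag on every column.

    ``data`` is indexed by subject_id.  Language columns follow the
    canonical 30-column schema; demographic/clinical columns are tagged
    ``demographic`` / ``clinical``.
    """

    data: pd.DataFrame
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicated column names in feature table")
        for col in self.data.columns:
            self.categories.setdefault(col, FEATURE_CATEGORIES.get(col, "clinical"))

    def validate_schema(self) -> None:
        missing = [c for c in LANGUAGE_FEATURES if c not in self.data.columns]
        if missing:
            raise ValidationError(f"feature table missing language columns: {missing}")

    def language_columns(self) -> list[str]:
        return [c for c in LANGUAGE_FEATURES if c in self.data.columns]

    def columns_of(self, category: str) -> list[str]:
        return [c for c in self.data.columns if self.categories.get(c) == category]


def _parse_structured(lines: list[str], path: str) -> tuple[dict, list[Turn]]:
    meta_rec: dict = {}
    turns: list[Turn] = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        try:
            rec = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise TranscriptParseError(f"{path}:{lineno}: invalid JSON record ({exc.msg})") from exc
        if "speaker" not in rec:
            if "subject_id" in rec or "duration_s" in rec:
                meta_rec.update(rec)
                continue
            raise TranscriptParseError(f"{path}:{lineno}: record has neither 'speaker' nor metadata keys")
        try:
            speaker = Speaker(rec["speaker"])
        except ValueError as exc:
            raise TranscriptParseError(f"{path}:{lineno}: unknown speaker {rec['speaker']!r}") from exc
        text = rec.get("text", "")
        if not str(text).strip():
            raise TranscriptParseError(f"{path}:{lineno}: empty turn text")
        is_q = rec.get("is_question")
        if is_q is None:
            is_q = _infer_question(str(text))
        turns.append(
            Turn(
                speaker=speaker,
                text=str(text),
                is_question=bool(is_q),
                start_s=rec.get("start_s"),
                end_s=rec.get("end_s"),
            )
        )
    return meta_rec, turns


def _infer_question(text: str) -> bool:
    stripped = text.strip()
    return stripped.endswith("?") or "¿" in stripped


def _parse_plain(lines: list[str], path: str) -> list[Turn]:
    turns: list[Turn] = []
    prefixes = {"E": Speaker.INTERVIEWER, "I": Speaker.INTERVIEWER, "P": Speaker.PATIENT}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if len(line) < 2 or line[1] != ":" or line[0].upper() not in prefixes:
            raise TranscriptParseError(f"{path}:{lineno}: expected 'E:'/'I:'/'P:' speaker prefix")
        speaker = prefixes[line[0].upper()]
        text = line[2:].strip()
        if not text:
            raise TranscriptParseError(f"{path}:{lineno}: empty turn text")
        turns.append(Turn(speaker=speaker, text=text, is_question=_infer_question(text)))
    return turns


def read_interview(
    path: str | Path,
    dialect: str = "structured-transcript",
    meta: Optional[SubjectMeta] = None,
    duration_s: Optional[float] = None,
) -> Interview:
    """Parse a transcript file into a validated :class:`Interview`.

    Duration resolution order: explicit ``duration_s`` argument, then a
    metadata record in the file, then the maximum turn end time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if dialect == "structured-transcript":
        meta_rec, turns = _parse_structured(lines, str(path))
    elif dialect == "plain-text-two-speaker":
        meta_rec, turns = {}, _parse_plain(lines, str(path))
    else:
        raise ValueError(f"unknown transcript dialect {dialect!r}")
    if not turns:
        raise TranscriptParseError(f"{path}: no turns found")
    if meta is None:
        meta = SubjectMeta(
            subject_id=str(meta_rec.get("subject_id", path.stem)),
            group=Group(meta_rec.get("group", "HC")),
        )
    if duration_s is None:
        duration_s = meta_rec.get("duration_s")
    if duration_s is None:
        ends = [t.end_s for t in turns if t.end_s is not None]
        if not ends:
            raise ValidationError(f"{path}: no duration_s and no turn timestamps to infer it from")
        duration_s = max(ends)
    return Interview(meta=meta, turns=turns, duration_s=float(duration_s))


_CATEGORY_PREFIX = "#categories"


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with a leading category-tag header line."""
    path = Path(path)
    cats = ",".join([_CATEGORY_PREFIX] + [table.categories[c] for c in table.data.columns])
    body = table.data.to_csv(index=True, index_label="subject_id", float_format="%.12g")
    path.write_text(cats + "\n" + body, encoding="utf-8")


def read_feature_table(path: str | Path, require_language_schema: bool = False) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(_CATEGORY_PREFIX):
            raise TranscriptParseError(f"{path}:1: missing '{_CATEGORY_PREFIX}' header line")
        cat_values = first.split(",")[1:]
        data = pd.read_csv(fh, index_col="subject_id")
    if len(cat_values) != len(data.columns):
        raise ValidationError(
            f"{path}: {len(cat_values)} category tags for {len(data.columns)} columns"
        )
    table = FeatureTable(data=data, categories=dict(zip(data.columns, cat_values)))
    if require_language_schema:
        table.validate_schema()
    return table
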