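"""The 30-feature language vector for one interview.

Verbal fluency (4): count of pauses > 2 s; question-answer pairs,
total content words and different content lemmas per hour.

Verbal productivity (20): mean total and different content words per
answer; mean word length in syllables; moving-average type-token ratio
over spans of 250/500/750/1000 lemmas; and 13 closed-class usage rates
(6 pronoun + 7 determiner subcategories) per answer.

Semantic coherence (6): mean and minimum of three cosine-similarity
series — question-answer pairs, and 5- and 6-word windows.

Word counts are taken over *patient* speech only; interviewer turns
contribute only question-answer pairing and question vectors.
"different words" are unique lemmas.  Features whose inputs are absent
(no speech timeline, stream shorter than a TTR span, empty coherence
series) are missing (NaN), never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from psylang.corpus import FEATURE_CATEGORIES, LANGUAGE_FEATURES, FeatureTable, Interview, Speaker
from psylang.embeddings import CoherenceSeries, EmbeddingModel, UndefinedSimilarityError, cosine, sentence_vector
from psylang.pauses import extract_pauses
from psylang.textproc import (
    DETERMINER_SUBCATEGORIES,
    PRONOUN_SUBCATEGORIES,
    Preprocessor,
    Token,
    content_tokens,
)

__all__ = [
    "ttr_windowed",
    "fluency_features",
    "productivity_features",
    "coherence_features",
    "extract_all",
    "extract_table",
    "TTR_SPANS",
]

TTR_SPANS = (250, 500, 750, 1000)


class FeatureExtractionError(RuntimeError):
    pass


def ttr_windowed(lemmas: Sequence[str], span: int) -> Optional[float]:
    """Moving-average type-token ratio (MATTR).

    Mean, over every window of exactly ``span`` consecutive lemmas
    (step 1), of unique-lemmas / ``span``.  Streams shorter than the
    span give ``None`` (missing), never an extrapolation.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    n = len(lemmas)
    if n < span:
        return None
    _, codes = np.unique(np.asarray(lemmas, dtype=object), return_inverse=True)
    return _mattr_from_codes(codes.astype(np.int64), span)


def _mattr_from_codes(codes: np.ndarray, span: int) -> float:
    """O(n) MATTR: token j is a new type in window [i, i+span) iff its
    previous occurrence lies before i; accumulate each token's interval
    of window starts with a difference array."""
    n = codes.size
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    prev = np.full(n, -1, dtype=np.int64)
    same = np.flatnonzero(sorted_codes[1:] == sorted_codes[:-1]) + 1
    prev[order[same]] = order[same - 1]
    n_windows = n - span + 1
    j = np.arange(n)
    lo = np.maximum(prev + 1, j - span + 1)
    hi = np.minimum(j, n_windows - 1)
    lo = np.clip(lo, 0, None)
    keep = lo <= hi
    diff = np.zeros(n_windows + 1, dtype=np.int64)
    np.add.at(diff, lo[keep], 1)
    np.add.at(diff, hi[keep] + 1, -1)
    counts = np.cumsum(diff[:-1])
    return float(counts.mean() / span)


@dataclass
class _Prepared:
    """Tokenized patient answers plus derived streams, computed once."""

    answer_tokens: list[list[Token]]  # all tokens, per patient turn
    answer_content: list[list[Token]]  # content view, per patient turn
    content_stream: list[Token]  # concatenated content tokens
    qa_pairs: list[tuple[list[str], list[str]]]  # (question lemmas, answer lemmas), content view


def _prepare(interview: Interview, preprocessor: Preprocessor) -> _Prepared:
    answer_tokens = [preprocessor.process(t.text) for t in interview.patient_turns()]
    answer_content = [content_tokens(toks) for toks in answer_tokens]
    stream = [t for toks in answer_content for t in toks]
    qa = []
    for question, answer in interview.qa_pairs():
        q = [t.lemma for t in content_tokens(preprocessor.process(question.text))]
        a = [t.lemma for t in content_tokens(preprocessor.process(answer.text))]
        qa.append((q, a))
    return _Prepared(answer_tokens, answer_content, stream, qa)


def fluency_features(
    interview: Interview,
    preprocessor: Preprocessor | None = None,
    pause_threshold_s: float = 2.0,
    _prepared: _Prepared | None = None,
) -> dict[str, float]:
    """Pause count (raw, per the > 2 s criterion) and per-hour rates of
    question-answer pairs, total content words and different lemmas."""
    if interview.duration_s <= 0:
        raise FeatureExtractionError("zero interview duration")
    if preprocessor is None:
        preprocessor = Preprocessor.default()
    prep = _prepared or _prepare(interview, preprocessor)
    hours = interview.duration_s / 3600.0
    if interview.timeline is not None:
        pause_count: float = float(len(extract_pauses(interview.timeline, pause_threshold_s)))
    else:
        pause_count = float("nan")
    total_words = len(prep.content_stream)
    different = len({t.lemma for t in prep.content_stream})
    return {
        "pause_count_gt2s": pause_count,
        "qa_pairs_per_hour": len(interview.qa_pairs()) / hours,
        "total_words_per_hour": total_words / hours,
        "different_words_per_hour": different / hours,
    }


def productivity_features(
    interview: Interview,
    preprocessor: Preprocessor | None = None,
    _prepared: _Prepared | None = None,
) -> dict[str, float]:
    """Per-answer lexical volume, mean word length, the four windowed
    TTRs and the 13 closed-class subcategory rates per answer.

    Closed-class words are counted on the pre-filter token stream (stop
    words included) since most Spanish pronouns are standard stop
    words; the rate is total occurrences per answer.  A non-repeated
    (unique-form) variant is available from
    :func:`closed_class_variants`.
    """
    if preprocessor is None:
        preprocessor = Preprocessor.default()
    prep = _prepared or _prepare(interview, preprocessor)
    n_answers = len(prep.answer_tokens)
    if n_answers == 0:
        raise FeatureExtractionError("interview has no patient answers")
    totals = [len(toks) for toks in prep.answer_content]
    uniques = [len({t.lemma for t in toks}) for toks in prep.answer_content]
    out: dict[str, float] = {
        "total_words_per_answer_mean": float(np.mean(totals)),
        "different_words_per_answer_mean": float(np.mean(uniques)),
    }
    syl = [t.syllables for t in prep.content_stream]
    out["mean_word_length_syllables"] = float(np.mean(syl)) if syl else float("nan")
    lemmas = [t.lemma for t in prep.content_stream]
    for span in TTR_SPANS:
        v = ttr_windowed(lemmas, span)
        out[f"ttr{span}"] = float("nan") if v is None else v
    counts = {("pronoun", s): 0 for s in PRONOUN_SUBCATEGORIES}
    counts.update({("determiner", s): 0 for s in DETERMINER_SUBCATEGORIES})
    for toks in prep.answer_tokens:
        for t in toks:
            if t.closed_class is not None:
                counts[t.closed_class] += 1
    for s in PRONOUN_SUBCATEGORIES:
        out[f"pron_{s}_per_answer"] = counts[("pronoun", s)] / n_answers
    for s in DETERMINER_SUBCATEGORIES:
        out[f"det_{s}_per_answer"] = counts[("determiner", s)] / n_answers
    return out


def closed_class_variants(
    interview: Interview, preprocessor: Preprocessor | None = None
) -> dict[str, float]:
    """Extended schema: both closed-class variants per subcategory —
    total occurrences and non-repeated (unique surface forms), each per
    answer."""
    if preprocessor is None:
        preprocessor = Preprocessor.default()
    prep = _prepare(interview, preprocessor)
    n_answers = len(prep.answer_tokens)
    total: dict[tuple[str, str], int] = {}
    forms: dict[tuple[str, str], set] = {}
    for toks in prep.answer_tokens:
        for t in toks:
            if t.closed_class is not None:
                total[t.closed_class] = total.get(t.closed_class, 0) + 1
                forms.setdefault(t.closed_class, set()).add(t.surface.lower())
    out = {}
    for cls, subs in (("pron", PRONOUN_SUBCATEGORIES), ("det", DETERMINER_SUBCATEGORIES)):
        full = "pronoun" if cls == "pron" else "determiner"
        for s in subs:
            key = (full, s)
            out[f"{cls}_{s}_per_answer"] = total.get(key, 0) / n_answers
            out[f"{cls}_{s}_unique_per_answer"] = len(forms.get(key, ())) / n_answers
    return out


def _windowed_series_fast(lemmas: list[str], window_size: int, model: EmbeddingModel) -> CoherenceSeries:
    from psylang.embeddings import windowed_coherence

    return windowed_coherence(lemmas, window_size, model)


def coherence_features(
    interview: Interview,
    model: EmbeddingModel,
    preprocessor: Preprocessor | None = None,
    _prepared: _Prepared | None = None,
) -> dict[str, float]:
    """Mean and minimum of the three coherence series.  Empty series
    (no QA pairs, or stream shorter than two windows) give NaN."""
    if preprocessor is None:
        preprocessor = Preprocessor.default()
    prep = _prepared or _prepare(interview, preprocessor)
    qa_values = []
    for q, a in prep.qa_pairs:
        try:
            qa_values.append(cosine(sentence_vector(q, model), sentence_vector(a, model)))
        except UndefinedSimilarityError:
            continue
    qa = CoherenceSeries(values=tuple(qa_values), unit="qa-pair")
    lemmas = [t.lemma for t in prep.content_stream]
    win5 = _windowed_series_fast(lemmas, 5, model)
    win6 = _windowed_series_fast(lemmas, 6, model)
    return {
        "qa_cos_mean": qa.mean(),
        "qa_cos_min": qa.min(),
        "win5_cos_mean": win5.mean(),
        "win5_cos_min": win5.min(),
        "win6_cos_mean": win6.mean(),
        "win6_cos_min": win6.min(),
    }


def extract_all(
    interview: Interview,
    model: EmbeddingModel,
    preprocessor: Preprocessor | None = None,
    pause_threshold_s: float = 2.0,
) -> dict[str, float]:
    """Assemble the canonical 30-value feature vector (NaN = missing).

    Deterministic given its inputs; sub-extractor failures are re-raised
    with the feature block named.
    """
    if preprocessor is None:
        preprocessor = Preprocessor.default()
    prep = _prepare(interview, preprocessor)
    out: dict[str, float] = {}
    for name, fn in (
        ("fluency", lambda: fluency_features(interview, preprocessor, pause_threshold_s, _prepared=prep)),
        ("productivity", lambda: productivity_features(interview, preprocessor, _prepared=prep)),
        ("coherence", lambda: coherence_features(interview, model, preprocessor, _prepared=prep)),
    ):
        try:
            out.update(fn())
        except Exception as exc:
            raise FeatureExtractionError(f"{name} features failed for {interview.meta.subject_id}: {exc}") from exc
    assert list(out) == LANGUAGE_FEATURES
    return out


def extract_table(
    interviews: Sequence[Interview],
    model: EmbeddingModel,
    preprocessor: Preprocessor | None = None,
    include_metadata: bool = True,
) -> FeatureTable:
    """Extract all interviews into a :class:`FeatureTable`, appending
    demographic and clinical covariate columns from subject metadata."""
    import pandas as pd

    if preprocessor is None:
        preprocessor = Preprocessor.default()
    rows = {}
    for itv in interviews:
        row = extract_all(itv, model, preprocessor)
        if include_metadata:
            m = itv.meta
            row["gender_male"] = float("nan") if m.gender is None else float(m.gender.upper() == "M")
            row["age_years"] = np.nan if m.age_years is None else m.age_years
            row["education_years"] = np.nan if m.education_years is None else m.education_years
            row["first_degree_relative"] = (
                np.nan if m.first_degree_relative is None else float(m.first_degree_relative)
            )
            row["illness_duration_years"] = (
                np.nan if m.illness_duration_years is None else m.illness_duration_years
            )
            for k in ("panss_pos", "panss_neg", "panss_gen", "panss_total"):
                v = getattr(m, k)
                row[k] = np.nan if v is None else v
        rows[itv.meta.subject_id] = row
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "subject_id"
    categories = dict(FEATURE_CATEGORIES)
    for c in ("gender_male", "age_years", "education_years", "first_degree_relative"):
        categories[c] = "demographic"
    for c in ("illness_duration_years", "panss_pos", "panss_neg", "panss_gen", "panss_total"):
        categories[c] = "clinical"
    table = FeatureTable(data=data, categories={c: categories[c] for c in data.columns})
    table.validate_schema()
    return table
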