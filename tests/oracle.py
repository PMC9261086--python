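"""Independent brute-force recomputation of the 30 language features.

Deliberately shares no computation code with the package: transcripts
are re-tokenized with a fresh regex, the closed-class tagging rule is
re-implemented as a naive loop, windowed TTR uses per-window ``set()``
construction, and coherence sums word vectors in plain Python floats.
Only the shipped lexicon *data files* and the planted embedding table
are shared, since they define the inputs.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import psylang

_DATA = Path(psylang.__file__).parent / "data"

_FILLERS = set(
    """eh ehh ehm em mm mmm hm hmm ah aah oh ohh uh uf uff uy ay
    ja jaja jajaja je jeje jejeje ji jiji ejem pff pfff psh tsk shh
    brr puf bah guau miau pum zas toc tictac achís achis""".split()
)

_PRON_SUBCATS = ["personal", "possessive", "demonstrative", "indefinite", "interrogative", "relative"]
_DET_SUBCATS = [
    "definite_article", "indefinite", "possessive", "demonstrative",
    "interrogative", "numeral", "relative",
]


def _read_wordlist(name):
    out = set()
    for line in (_DATA / name).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.lower())
    return out


def load_lexicons():
    stop = _read_wordlist("stopwords_es.txt") | _read_wordlist("stopwords_chilean_ext.txt")
    closed = {}
    for line in (_DATA / "closed_class_es.tsv").read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        w, cls, sub = line.split("\t")
        closed.setdefault(w.lower(), {})
        closed[w.lower()].setdefault(cls, sub)
    lemmas = {}
    for line in (_DATA / "lemmas_es.tsv").read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")
        lemmas[a.lower()] = b.lower()
    return stop, closed, lemmas


_WORD_RE = re.compile(r"[a-záéíóúüñ]+", re.IGNORECASE)
_BRACKET_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)|<[^>]*>|\{[^}]*\}")


def tokenize(text):
    words = []
    for w in _WORD_RE.findall(_BRACKET_RE.sub(" ", text)):
        w = w.lower()
        if w not in _FILLERS:
            words.append(w)
    return words


def tag_tokens(words, stop, closed, lemma_map):
    """Return per-token (is_stop, tag) where tag is (cls, sub) or None."""

    def noun_like(w):
        lem = lemma_map.get(w, w)
        verbish = lem != w and (lem.endswith("ar") or lem.endswith("er") or lem.endswith("ir"))
        return w not in stop and w not in closed and not verbish

    out = []
    for i, w in enumerate(words):
        is_stop = w in stop
        classes = closed.get(w)
        tag = None
        if classes:
            if w == "que":
                if i > 0 and noun_like(words[i - 1]):
                    tag = ("pronoun", classes["pronoun"])
            elif len(classes) == 1:
                tag = next(iter(classes.items()))
            else:
                if i + 1 < len(words) and noun_like(words[i + 1]):
                    tag = ("determiner", classes["determiner"])
                else:
                    tag = ("pronoun", classes["pronoun"])
        out.append((is_stop, tag))
    return out


def mattr(lemmas, span):
    if len(lemmas) < span:
        return float("nan")
    vals = []
    for i in range(len(lemmas) - span + 1):
        vals.append(len(set(lemmas[i : i + span])) / span)
    return sum(vals) / len(vals)


def _vec_sum(words, table):
    total = None
    for w in words:
        v = table.get(w)
        if v is None:
            continue
        total = list(v) if total is None else [a + b for a, b in zip(total, v)]
    return total


def _cos(u, v):
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    if nu == 0 or nv == 0:
        return None
    return max(-1.0, min(1.0, dot / (nu * nv)))


def _series_stats(values):
    if not values:
        return float("nan"), float("nan")
    return sum(values) / len(values), min(values)


def recompute_features(interview, vector_table, syllable_table):
    """All 30 features for one interview by naive loops."""
    stop, closed, lemma_map = load_lexicons()

    patient_turns = [t for t in interview.turns if t.speaker.value == "patient"]
    per_answer = []
    for t in patient_turns:
        words = tokenize(t.text)
        tags = tag_tokens(words, stop, closed, lemma_map)
        per_answer.append((words, tags))

    def lemma(w):
        return lemma_map.get(w, w)

    content_stream = []
    for words, tags in per_answer:
        for w, (is_stop, tag) in zip(words, tags):
            if not is_stop and tag is None:
                content_stream.append(lemma(w))

    # --- fluency
    hours = interview.duration_s / 3600.0
    pauses = float("nan")
    if interview.timeline is not None:
        segs = interview.timeline.segments
        pauses = 0
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            if a2 - b1 > 2.0:
                pauses += 1
    qa = []
    turns = list(interview.turns)
    for i, t in enumerate(turns):
        if t.speaker.value == "interviewer" and t.is_question:
            for nxt in turns[i + 1 :]:
                if nxt.speaker.value == "patient":
                    qa.append((t, nxt))
                    break
                if nxt.speaker.value == "interviewer":
                    break
    out = {
        "pause_count_gt2s": pauses,
        "qa_pairs_per_hour": len(qa) / hours,
        "total_words_per_hour": len(content_stream) / hours,
        "different_words_per_hour": len(set(content_stream)) / hours,
    }

    # --- productivity
    n_ans = len(per_answer)
    tot, uniq = [], []
    for words, tags in per_answer:
        c = [lemma(w) for w, (s, tag) in zip(words, tags) if not s and tag is None]
        tot.append(len(c))
        uniq.append(len(set(c)))
    out["total_words_per_answer_mean"] = sum(tot) / n_ans
    out["different_words_per_answer_mean"] = sum(uniq) / n_ans
    syls = []
    for words, tags in per_answer:
        for w, (s, tag) in zip(words, tags):
            if not s and tag is None:
                syls.append(syllable_table[w])
    out["mean_word_length_syllables"] = sum(syls) / len(syls) if syls else float("nan")
    for span in (250, 500, 750, 1000):
        out[f"ttr{span}"] = mattr(content_stream, span)
    counts = {("pronoun", s): 0 for s in _PRON_SUBCATS}
    counts.update({("determiner", s): 0 for s in _DET_SUBCATS})
    for words, tags in per_answer:
        for _, tag in tags:
            if tag is not None:
                counts[tag] += 1
    for s in _PRON_SUBCATS:
        out[f"pron_{s}_per_answer"] = counts[("pronoun", s)] / n_ans
    for s in _DET_SUBCATS:
        out[f"det_{s}_per_answer"] = counts[("determiner", s)] / n_ans

    # --- coherence
    def content_of(text):
        words = tokenize(text)
        tags = tag_tokens(words, stop, closed, lemma_map)
        return [lemma(w) for w, (s, tag) in zip(words, tags) if not s and tag is None]

    qa_vals = []
    for q, a in qa:
        qv = _vec_sum(content_of(q.text), vector_table)
        av = _vec_sum(content_of(a.text), vector_table)
        if qv is None or av is None:
            continue
        c = _cos(qv, av)
        if c is not None:
            qa_vals.append(c)
    out["qa_cos_mean"], out["qa_cos_min"] = _series_stats(qa_vals)
    for ws in (5, 6):
        vals = []
        n_win = len(content_stream) // ws
        sums = []
        for k in range(n_win):
            chunk = content_stream[k * ws : (k + 1) * ws]
            sums.append(_vec_sum(chunk, vector_table))
        for s1, s2 in zip(sums, sums[1:]):
            if s1 is None or s2 is None:
                continue
            c = _cos(s1, s2)
            if c is not None:
                vals.append(c)
        out[f"win{ws}_cos_mean"], out[f"win{ws}_cos_min"] = _series_stats(vals)
    return out
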