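"""Synthetic interview cohorts with planted, recoverable group effects.

The generator emulates the *statistical structure* of a three-group
clinical interview corpus (healthy controls HC, first-episode psychosis
FEP, chronic schizophrenia SZ; FEP split into converters C-SZ and
non-converters NC-SZ) without any natural-language content:

* a synthetic content lexicon whose words sit on a circle in embedding
  space; patient speech is a topic random walk on that circle, so the
  topic-step scale sigma directly controls semantic coherence;
* word choice around the topic follows a truncated Zipf law, so the
  Zipf exponent controls type-token ratio, and a long-word bias
  controls mean word length in syllables (lexicon words carry planted
  syllable counts);
* real Spanish function words (stop words, pronouns, determiners) are
  injected at planted per-answer rates, so closed-class features are
  recoverable through the ordinary tagger;
* the speech timeline interleaves voiced segments with short gaps and
  lognormal pause events, so the > 2 s pause count is plantable; a
  guard band around the 2 s criterion keeps boundary quantization from
  flipping counts in end-to-end audio tests;
* demographics and PANSS scores are independent truncated normals with
  configurable per-group moments.

Everything is deterministic given one master seed.  Default group
sizes, interview-duration laws and demographic/clinical moments follow
the published cohort description (133 interviews: 49 HC / 40 FEP / 44
SZ, FEP split 28/12); language-effect magnitudes are tuned for
testability and documented as such, not as estimates of any real
corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.signal import butter, lfilter

from psylang.corpus import Conversion, Group, Interview, Speaker, SubjectMeta, Turn
from psylang.embeddings import EmbeddingModel
from psylang.pauses import SpeechTimeline
from psylang.textproc import (
    FILLERS,
    Preprocessor,
    load_closed_class_lexicon,
    load_lemma_table,
    load_stopwords,
)

__all__ = [
    "SyntheticLexicon",
    "build_lexicon",
    "GroupEffectProfile",
    "CohortSpec",
    "CohortSample",
    "default_profiles",
    "null_profiles",
    "conversion_profiles",
    "sample_interview",
    "sample_cohort",
    "render_audio",
]

# ---------------------------------------------------------------------------
# synthetic content lexicon

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"


def _planted_syllables(i: int) -> int:
    # every 4th circle position holds a long word (3-5 syllables);
    # the rest are short (1-2) -> baseline mean word length ~2.1
    if i % 4 == 0:
        return 3 + (i // 4) % 3
    return 1 if i % 4 == 1 else 2


@dataclass
class SyntheticLexicon:
    """Content words on an embedding circle with planted syllable counts."""

    words: list[str]
    syllables: np.ndarray  # (V,)
    vectors: np.ndarray  # (V, d)
    seed: int

    @property
    def size(self) -> int:
        return len(self.words)

    def embedding_model(self) -> EmbeddingModel:
        return EmbeddingModel(
            words=list(self.words),
            vectors=self.vectors.copy(),
            metadata={"algorithm": "planted-circle", "seed": self.seed},
        )

    def syllable_overrides(self) -> dict[str, int]:
        return {w: int(s) for w, s in zip(self.words, self.syllables)}

    def preprocessor(self) -> Preprocessor:
        """Standard Spanish lexicons plus this lexicon's syllable counts."""
        return Preprocessor(
            stopwords=load_stopwords(),
            lemma_table=load_lemma_table(),
            closed_class=load_closed_class_lexicon(),
            syllable_overrides=self.syllable_overrides(),
        )


def build_lexicon(n_words: int = 1200, d: int = 16, seed: int = 777) -> SyntheticLexicon:
    if n_words < 8 or d < 3:
        raise ValueError("need n_words >= 8 and d >= 3")
    rng = np.random.default_rng(seed)
    stop = load_stopwords()
    closed = load_closed_class_lexicon()
    lemmas = load_lemma_table()
    reserved = set(stop.base) | set(stop.extension) | set(closed.entries) | set(lemmas) | set(FILLERS)
    words: list[str] = []
    seen = set(reserved)
    syllables = np.array([_planted_syllables(i) for i in range(n_words)])
    for i in range(n_words):
        s = int(syllables[i])
        for attempt in range(1000):
            w = "".join(rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS)) for _ in range(s))
            if attempt >= 20:  # small syllable spaces: close with a coda consonant
                w += rng.choice(list(_CONSONANTS))
            if w not in seen:
                seen.add(w)
                words.append(w)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not generate a unique lexicon word")
    theta = 2 * np.pi * np.arange(n_words) / n_words
    vectors = np.zeros((n_words, d))
    vectors[:, 0] = np.cos(theta)
    vectors[:, 1] = np.sin(theta)
    vectors[:, 2:] = 0.35 * rng.standard_normal((n_words, d - 2)) / np.sqrt(d - 2)
    return SyntheticLexicon(words=words, syllables=syllables, vectors=vectors, seed=seed)


# ---------------------------------------------------------------------------
# group effect profiles

# real Spanish forms injected per subcategory; chosen so the shipped
# tagger recovers the planted subcategory deterministically in context
_PRONOUN_FORMS = {
    "personal": ["yo", "él", "ella", "usted", "nosotros", "ellos", "ellas"],
    "possessive": ["mío", "mía", "tuyo", "suyo", "suya"],
    "demonstrative": ["esto", "eso", "aquello"],
    "indefinite": ["alguien", "nadie", "algo", "nada"],
    "interrogative": ["quién", "quiénes"],
    "relative": ["quien", "quienes"],
}
_DETERMINER_FORMS = {
    "definite_article": ["el", "al", "del"],
    "indefinite": ["un", "una", "unas", "algún", "cualquier"],
    "possessive": ["mi", "mis", "tu", "su", "sus"],
    "demonstrative": ["este", "esa", "aquellos"],
    "interrogative": ["qué", "cuántos", "cuántas"],
    "numeral": ["dos", "tres", "cinco", "siete", "diez"],
    "relative": ["cuyo", "cuya", "cuyos"],
}
_FILLER_STOPWORDS = [
    "y", "pero", "entonces", "porque", "cuando", "muy", "también",
    "ya", "no", "bien", "después", "siempre", "aquí", "ahora",
]
_QUESTION_TEMPLATES = [
    "¿Qué me dice de {w}?",
    "¿Cómo fue eso de {w}?",
    "¿Y entonces qué pasó con {w}?",
    "¿Me puede contar más de {w}?",
]

_DEFAULT_PRONOUN_RATES = {
    "personal": 2.2,
    "possessive": 0.35,
    "demonstrative": 0.6,
    "indefinite": 0.8,
    "interrogative": 0.06,
    "relative": 0.7,
}
_DEFAULT_DETERMINER_RATES = {
    "definite_article": 2.8,
    "indefinite": 1.1,
    "possessive": 0.7,
    "demonstrative": 0.5,
    "interrogative": 0.05,
    "numeral": 0.35,
    "relative": 0.05,
}


@dataclass(frozen=True)
class GroupEffectProfile:
    """Per-group language generation parameters.

    Rates are per minute (pauses, question-answer pairs), per answer
    (closed-class injections) or per content word (stop-word fillers);
    pause durations are lognormal in seconds; answer lengths are
    negative binomial in content words; ``topic_sigma`` is the topic
    random-walk step in radians per content word (larger = less
    coherent speech); ``zipf_s`` > 1 is the truncated Zipf exponent of
    word choice around the topic (larger = fewer distinct words);
    ``long_word_prob`` biases choice toward the long-word sublattice;
    ``repeat_prob`` is a perseveration probability — the chance that a
    content word is copied from one of the last ``repeat_memory``
    emitted words, which lowers type-token ratio independently of how
    fast the topic drifts.
    """

    pause_rate_per_min: float = 2.2
    pause_logmean: float = -0.5
    pause_logsd: float = 0.7
    answer_words_mean: float = 45.0
    answer_words_dispersion: float = 3.0
    qa_rate_per_min: float = 1.2
    zipf_s: float = 1.3
    zipf_cutoff: int = 60
    repeat_prob: float = 0.15
    repeat_memory: int = 20
    long_word_prob: float = 0.24
    topic_sigma: float = 0.10
    pronoun_rates: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_PRONOUN_RATES))
    determiner_rates: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DETERMINER_RATES))
    stopword_rate: float = 0.45
    duration_mean_min: float = 28.6
    duration_sd_min: float = 16.5
    duration_range_min: tuple[float, float] = (5.0, 102.0)
    subject_jitter: float = 0.15
    pause_guard_band_s: float = 0.3

    def __post_init__(self) -> None:
        if self.zipf_s <= 1.0:
            raise ValueError("zipf_s must be > 1")
        for name in ("pause_rate_per_min", "answer_words_mean", "qa_rate_per_min", "stopword_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.long_word_prob <= 1:
            raise ValueError("long_word_prob must be a probability")


def default_profiles() -> dict[str, GroupEffectProfile]:
    """Strong-effect study conditions: group orderings mirror the
    qualitative clinical contrasts (patients pause more, say less,
    repeat more, use longer/rarer words, drift more in topic, and use
    fewer possessive pronouns); magnitudes are chosen for testability."""
    hc = GroupEffectProfile(
        pause_rate_per_min=2.0,
        pause_logmean=-0.7,
        pause_logsd=0.6,
        answer_words_mean=60.0,
        answer_words_dispersion=4.0,
        qa_rate_per_min=1.0,
        zipf_s=1.15,
        repeat_prob=0.05,
        long_word_prob=0.20,
        topic_sigma=0.04,
        pronoun_rates={**_DEFAULT_PRONOUN_RATES, "possessive": 0.5},
        duration_mean_min=53.5,
        duration_sd_min=10.2,
        duration_range_min=(32.0, 83.0),
    )
    fep = GroupEffectProfile(
        pause_rate_per_min=2.5,
        pause_logmean=-0.3,
        pause_logsd=0.7,
        answer_words_mean=40.0,
        answer_words_dispersion=3.0,
        qa_rate_per_min=1.3,
        zipf_s=1.30,
        repeat_prob=0.18,
        long_word_prob=0.24,
        topic_sigma=0.11,
        pronoun_rates={**_DEFAULT_PRONOUN_RATES, "possessive": 0.3},
    )
    sz = GroupEffectProfile(
        pause_rate_per_min=3.0,
        pause_logmean=0.0,
        pause_logsd=0.8,
        answer_words_mean=28.0,
        answer_words_dispersion=2.5,
        qa_rate_per_min=1.5,
        zipf_s=1.50,
        repeat_prob=0.32,
        long_word_prob=0.30,
        topic_sigma=0.22,
        pronoun_rates={**_DEFAULT_PRONOUN_RATES, "personal": 1.8, "possessive": 0.18},
        determiner_rates={**_DEFAULT_DETERMINER_RATES, "demonstrative": 0.8},
    )
    return {"HC": hc, "FEP": fep, "SZ": sz}


def null_profiles() -> dict[str, GroupEffectProfile]:
    """Zero-effect condition: one shared parameter set for all groups
    (including the interview-duration law), so every apparent group
    difference is sampling noise.  Durations are kept moderate so that
    calibration experiments over many replicate cohorts stay cheap."""
    shared = GroupEffectProfile(
        answer_words_mean=50.0,
        qa_rate_per_min=1.3,
        duration_mean_min=16.0,
        duration_sd_min=4.0,
        duration_range_min=(7.0, 35.0),
    )
    return {"HC": shared, "FEP": shared, "SZ": shared}


def conversion_profiles(language_only: bool = True) -> dict[str, GroupEffectProfile]:
    """FEP-subgroup profiles for the longitudinal task: converters
    (C-SZ) drift toward SZ-like language, non-converters (NC-SZ) stay
    FEP-like.  With ``language_only`` the two subgroups share all
    demographic/clinical moments, so only language carries signal."""
    base = default_profiles()["FEP"]
    c_sz = replace(
        base,
        topic_sigma=0.18,
        zipf_s=1.42,
        repeat_prob=0.28,
        long_word_prob=0.28,
        pause_logmean=-0.1,
        answer_words_mean=32.0,
        pronoun_rates={**_DEFAULT_PRONOUN_RATES, "possessive": 0.2},
    )
    nc_sz = replace(base, topic_sigma=0.09)
    del language_only  # demographic moments are handled by CohortSpec
    return {"C-SZ": c_sz, "NC-SZ": nc_sz}


# ---------------------------------------------------------------------------
# cohort specification (published moments as defaults)


def _norm(mean: float, sd: float, lo: float, hi: float) -> dict:
    return {"mean": mean, "sd": sd, "lo": lo, "hi": hi}


@dataclass
class CohortSpec:
    """Group sizes and demographic/clinical sampling moments.

    Defaults reproduce the published cohort description: sizes
    49/40/44 with the FEP group split 28 converters / 12
    non-converters; interview-duration moments per group; age,
    education, illness duration, family history, gender mix and PANSS
    subscale moments per group (and per FEP subgroup).  PANSS total is
    the sum of the three subscales, which keeps it >= each subscale.
    """

    sizes: dict = field(default_factory=lambda: {"HC": 49, "FEP": 40, "SZ": 44})
    fep_split: dict = field(default_factory=lambda: {"C-SZ": 28, "NC-SZ": 12})
    male_fraction: dict = field(
        default_factory=lambda: {"HC": 0.49, "FEP": 0.63, "SZ": 0.57, "C-SZ": 0.50, "NC-SZ": 0.68}
    )
    age: dict = field(
        default_factory=lambda: {
            "HC": _norm(38.6, 15.0, 18, 75),
            "FEP": _norm(18.1, 2.5, 14, 30),
            "SZ": _norm(35.5, 9.3, 20, 60),
            "C-SZ": _norm(17.8, 2.4, 14, 30),
            "NC-SZ": _norm(18.2, 2.5, 14, 30),
        }
    )
    education: dict = field(
        default_factory=lambda: {
            "HC": _norm(15.2, 2.6, 8, 22),
            "FEP": _norm(10.8, 1.7, 6, 18),
            "SZ": _norm(12.7, 2.4, 6, 20),
            "C-SZ": _norm(10.7, 2.1, 6, 18),
            "NC-SZ": _norm(10.9, 1.6, 6, 18),
        }
    )
    illness_duration: dict = field(
        default_factory=lambda: {
            "FEP": _norm(0.7, 0.8, 0.0, 2.0),
            "SZ": _norm(17.5, 8.8, 2.0, 45.0),
            "C-SZ": _norm(0.6, 0.8, 0.0, 2.0),
            "NC-SZ": _norm(0.7, 0.8, 0.0, 2.0),
        }
    )
    family_history: dict = field(
        default_factory=lambda: {"FEP": 0.50, "SZ": 0.52, "C-SZ": 0.58, "NC-SZ": 0.46}
    )
    panss: dict = field(
        default_factory=lambda: {
            "FEP": {"pos": _norm(26.0, 4.9, 7, 49), "neg": _norm(29.4, 5.4, 7, 49), "gen": _norm(62.4, 7.2, 16, 112)},
            "SZ": {"pos": _norm(32.8, 4.8, 7, 49), "neg": _norm(37.9, 4.5, 7, 49), "gen": _norm(74.4, 8.0, 16, 112)},
            "C-SZ": {"pos": _norm(24.1, 6.7, 7, 49), "neg": _norm(27.9, 5.7, 7, 49), "gen": _norm(62.5, 9.5, 16, 112)},
            "NC-SZ": {"pos": _norm(26.8, 3.7, 7, 49), "neg": _norm(30.0, 5.2, 7, 49), "gen": _norm(62.3, 6.2, 16, 112)},
        }
    )
    subgroup_moments: bool = True  # use C-SZ / NC-SZ moments for FEP subjects

    def total(self) -> int:
        return sum(self.sizes.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if sum(self.fep_split.values()) != self.sizes.get("FEP", 0):
            raise ValueError("FEP split does not sum to the FEP group size")


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size=size)
    for _ in range(200):
        bad = (out < lo) | (out > hi)
        if not np.any(bad):
            break
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)
    return np.clip(out, lo, hi)


# ---------------------------------------------------------------------------
# single-interview sampling


def _jitter(rng: np.random.Generator, value: float, rel_sd: float) -> float:
    return float(value * np.exp(rng.normal(0.0, rel_sd)))


def _sample_timeline(
    rng: np.random.Generator, profile: GroupEffectProfile, params: dict, duration_s: float
) -> tuple[SpeechTimeline, int]:
    dur_min = duration_s / 60.0
    n_pause = rng.poisson(params["pause_rate_per_min"] * dur_min)
    pause_durs = rng.lognormal(profile.pause_logmean, profile.pause_logsd, size=n_pause)
    g = profile.pause_guard_band_s
    if g > 0 and n_pause:
        # keep planted gaps away from the 2 s criterion so that frame
        # quantization in the audio path cannot flip the count
        lo_band, hi_band = 2.0 - g, 2.0 + g
        in_band = (pause_durs > lo_band) & (pause_durs < hi_band)
        pause_durs[in_band & (pause_durs <= 2.0)] = lo_band
        pause_durs[in_band & (pause_durs > 2.0)] = hi_band
    n_short = max(1, int(round(duration_s / 9.0)) - n_pause)
    short_durs = rng.uniform(0.2, 1.4, size=n_short)
    gaps = np.concatenate([pause_durs, short_durs])
    rng.shuffle(gaps)
    # leave at least 40% of the interview voiced
    total_gap = gaps.sum()
    if total_gap > 0.6 * duration_s:
        gaps = gaps * (0.6 * duration_s / total_gap)
    voiced_total = duration_s - gaps.sum()
    n_seg = gaps.size + 1
    seg = rng.gamma(2.0, 1.0, size=n_seg)
    seg = np.maximum(seg / seg.sum() * voiced_total, 0.5)
    segments = []
    t = 0.0
    for i in range(n_seg):
        segments.append((t, t + seg[i]))
        t += seg[i]
        if i < gaps.size:
            t += gaps[i]
    timeline = SpeechTimeline.from_pairs(segments)
    ends = np.array([s for s, _ in segments[1:]])
    starts_prev = np.array([e for _, e in segments[:-1]])
    planted_gt2 = int(np.sum((ends - starts_prev) > 2.0)) if segments[1:] else 0
    return timeline, planted_gt2


def _sample_answer_words(
    rng: np.random.Generator,
    lexicon: SyntheticLexicon,
    topic_pos: float,
    n_words: int,
    sigma_pos: float,
    zipf_s: float,
    zipf_cutoff: int,
    long_word_prob: float,
    repeat_prob: float,
    repeat_memory: int,
) -> tuple[list[int], float]:
    V = lexicon.size
    steps = rng.normal(0.0, sigma_pos, size=n_words)
    pos = topic_pos + np.cumsum(steps)
    offs = np.minimum(rng.zipf(zipf_s, size=n_words) - 1, zipf_cutoff)
    sign = rng.choice([-1, 1], size=n_words)
    idx = np.rint(pos + sign * offs).astype(np.int64) % V
    to_long = rng.random(n_words) < long_word_prob
    idx[to_long] = (np.rint(idx[to_long] / 4).astype(np.int64) * 4) % V
    # perseveration: copy a recently emitted word
    if repeat_prob > 0:
        rep = np.flatnonzero(rng.random(n_words) < repeat_prob)
        rep = rep[rep > 0]
        lags = rng.integers(1, repeat_memory + 1, size=rep.size)
        for j, lag in zip(rep, lags):
            idx[j] = idx[max(0, j - int(lag))]
    return idx.tolist(), float(pos[-1]) if n_words else topic_pos


def sample_interview(
    profile: GroupEffectProfile,
    meta: SubjectMeta,
    lexicon: SyntheticLexicon,
    seed: int | np.random.SeedSequence,
    duration_s: Optional[float] = None,
) -> tuple[Interview, dict]:
    """Generate one interview plus its planted-parameter record."""
    rng = np.random.default_rng(seed)
    if duration_s is None:
        lo, hi = profile.duration_range_min
        duration_s = 60.0 * float(
            _trunc_normal(rng, profile.duration_mean_min, profile.duration_sd_min, lo, hi)
        )
    j = profile.subject_jitter
    params = {
        "pause_rate_per_min": _jitter(rng, profile.pause_rate_per_min, j) if profile.pause_rate_per_min else 0.0,
        "answer_words_mean": _jitter(rng, profile.answer_words_mean, j),
        "qa_rate_per_min": _jitter(rng, profile.qa_rate_per_min, j / 2),
        "zipf_s": max(1.01, profile.zipf_s + rng.normal(0.0, 0.04)),
        "long_word_prob": float(np.clip(profile.long_word_prob + rng.normal(0.0, 0.02), 0.0, 1.0)),
        "topic_sigma": _jitter(rng, profile.topic_sigma, j) if profile.topic_sigma else 0.0,
        "repeat_prob": float(np.clip(profile.repeat_prob + rng.normal(0.0, 0.03), 0.0, 0.95)),
    }
    timeline, planted_gt2 = _sample_timeline(rng, profile, params, duration_s)
    # analytic expected count of > 2 s pauses (lognormal upper tail)
    from scipy.stats import norm as _norm_dist

    p_gt2 = float(1.0 - _norm_dist.cdf((np.log(2.0) - profile.pause_logmean) / profile.pause_logsd))
    pause_gt2_expected = params["pause_rate_per_min"] * (duration_s / 60.0) * p_gt2

    dur_min = duration_s / 60.0
    n_pairs = max(1, int(rng.poisson(params["qa_rate_per_min"] * dur_min)))
    V = lexicon.size
    sigma_pos = params["topic_sigma"] * V / (2 * np.pi)
    r = profile.answer_words_dispersion
    mean_w = params["answer_words_mean"]
    p_nb = r / (r + mean_w)
    turns: list[Turn] = []
    topic = float(rng.uniform(0, V))
    n_content_total = 0
    for _ in range(n_pairs):
        topic = float(rng.uniform(0, V))  # fresh topic per question
        q_word = lexicon.words[int(np.rint(topic)) % V]
        template = _QUESTION_TEMPLATES[int(rng.integers(len(_QUESTION_TEMPLATES)))]
        turns.append(Turn(speaker=Speaker.INTERVIEWER, text=template.format(w=q_word), is_question=True))
        n_words = max(1, int(rng.negative_binomial(r, p_nb)))
        idx, topic = _sample_answer_words(
            rng, lexicon, topic, n_words, sigma_pos,
            params["zipf_s"], profile.zipf_cutoff, params["long_word_prob"],
            params["repeat_prob"], profile.repeat_memory,
        )
        n_content_total += len(idx)
        units: list[list[str]] = [[lexicon.words[i]] for i in idx]
        # determiners prefix a content word (at most one each, so the
        # tagger always sees determiner + noun-like); pronouns/fillers
        # are standalone units
        free = list(range(len(units)))
        rng.shuffle(free)
        for sub, rate in profile.determiner_rates.items():
            for _ in range(rng.poisson(rate)):
                if not free:
                    break
                forms = _DETERMINER_FORMS[sub]
                units[free.pop()].insert(0, forms[int(rng.integers(len(forms)))])
        standalone: list[str] = []
        for sub, rate in profile.pronoun_rates.items():
            forms = _PRONOUN_FORMS[sub]
            standalone += [forms[int(rng.integers(len(forms)))] for _ in range(rng.poisson(rate))]
        n_fill = rng.poisson(profile.stopword_rate * n_words)
        standalone += [
            _FILLER_STOPWORDS[int(rng.integers(len(_FILLER_STOPWORDS)))] for _ in range(n_fill)
        ]
        for w in standalone:
            units.insert(int(rng.integers(len(units) + 1)), [w])
        text = " ".join(w for unit in units for w in unit)
        turns.append(Turn(speaker=Speaker.PATIENT, text=text, is_question=False))

    interview = Interview(meta=meta, turns=turns, duration_s=duration_s, timeline=timeline)
    planted = dict(params)
    planted.update(
        {
            "duration_s": duration_s,
            "n_qa_pairs": n_pairs,
            "n_content_words": n_content_total,
            "planted_pause_count_gt2s": planted_gt2,
            "pause_gt2_expected": pause_gt2_expected,
        }
    )
    return interview, planted


# ---------------------------------------------------------------------------
# cohort sampling


@dataclass
class CohortSample:
    interviews: list[Interview]
    planted: "object"  # pandas DataFrame indexed by subject_id
    lexicon: SyntheticLexicon
    spec: CohortSpec
    seed: int

    def labels(self, by: str = "group") -> np.ndarray:
        if by == "group":
            return np.array([i.meta.group.value for i in self.interviews], dtype=object)
        if by == "conversion":
            return np.array(
                [None if i.meta.conversion is None else i.meta.conversion.value for i in self.interviews],
                dtype=object,
            )
        raise ValueError(by)

    def embedding_model(self) -> EmbeddingModel:
        return self.lexicon.embedding_model()

    def preprocessor(self) -> Preprocessor:
        return self.lexicon.preprocessor()


def _sample_meta(rng: np.random.Generator, spec: CohortSpec, group: str, conv: Optional[str], sid: str) -> SubjectMeta:
    key = conv if (conv is not None and spec.subgroup_moments) else group
    gender = "M" if rng.random() < spec.male_fraction[key] else "F"
    age = float(_trunc_normal(rng, **spec.age[key]))
    edu = float(_trunc_normal(rng, **spec.education[key]))
    if group == "HC":
        return SubjectMeta(
            subject_id=sid, group=Group.HC, gender=gender, age_years=age, education_years=edu
        )
    dur = float(_trunc_normal(rng, **spec.illness_duration[key]))
    fam = bool(rng.random() < spec.family_history[key])
    moments = spec.panss[key]
    pos = float(np.rint(_trunc_normal(rng, **moments["pos"])))
    neg = float(np.rint(_trunc_normal(rng, **moments["neg"])))
    gen = float(np.rint(_trunc_normal(rng, **moments["gen"])))
    return SubjectMeta(
        subject_id=sid,
        group=Group(group),
        conversion=None if conv is None else Conversion(conv),
        gender=gender,
        age_years=age,
        education_years=edu,
        illness_duration_years=dur,
        first_degree_relative=fam,
        panss_pos=pos,
        panss_neg=neg,
        panss_gen=gen,
        panss_total=pos + neg + gen,
    )


def sample_cohort(
    spec: CohortSpec | None = None,
    profiles: Mapping[str, GroupEffectProfile] | None = None,
    seed: int = 0,
    lexicon: SyntheticLexicon | None = None,
) -> CohortSample:
    """Sample a full cohort of interviews, deterministic given ``seed``.

    ``profiles`` maps group names (and optionally FEP-subgroup names
    ``C-SZ`` / ``NC-SZ``) to :class:`GroupEffectProfile`; FEP subjects
    use their subgroup profile when present, else the FEP profile.
    """
    import pandas as pd

    spec = spec or CohortSpec()
    spec.validate()
    if profiles is None:
        profiles = {**default_profiles(), **conversion_profiles()}
    if lexicon is None:
        lexicon = build_lexicon()
    root = np.random.SeedSequence([int(seed) % (2**31), 0x5EED])
    interviews: list[Interview] = []
    planted_rows = {}
    plan: list[tuple[str, Optional[str]]] = []
    for group in ("HC", "FEP", "SZ"):
        n = spec.sizes.get(group, 0)
        if group == "FEP":
            plan += [("FEP", "C-SZ")] * spec.fep_split.get("C-SZ", 0)
            plan += [("FEP", "NC-SZ")] * spec.fep_split.get("NC-SZ", 0)
        else:
            plan += [(group, None)] * n
    children = root.spawn(len(plan))
    counters: dict[str, int] = {}
    for (group, conv), child in zip(plan, children):
        counters[group] = counters.get(group, 0) + 1
        sid = f"{group}{counters[group]:03d}"
        rng = np.random.default_rng(child)
        meta = _sample_meta(rng, spec, group, conv, sid)
        profile = profiles.get(conv, profiles.get(group)) if conv else profiles[group]
        if profile is None:
            raise ValueError(f"no profile for group {group}")
        itv, planted = sample_interview(profile, meta, lexicon, child.spawn(1)[0])
        interviews.append(itv)
        planted["group"] = group
        planted["conversion"] = conv
        planted_rows[sid] = planted
    planted_df = pd.DataFrame.from_dict(planted_rows, orient="index")
    planted_df.index.name = "subject_id"
    return CohortSample(interviews=interviews, planted=planted_df, lexicon=lexicon, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# audio rendering for the pause-detection path


def render_audio(
    timeline: SpeechTimeline,
    sample_rate: int = 8000,
    snr_db: float = 20.0,
    seed: int = 0,
    tail_s: float = 0.5,
) -> np.ndarray:
    """Render a timeline as band-limited noise bursts (300-3400 Hz) on
    voiced intervals over a white noise floor at the requested SNR."""
    rng = np.random.default_rng(seed)
    end = timeline.segments[-1][1] + tail_s if timeline.segments else tail_s
    n = int(np.ceil(end * sample_rate))
    speech_amp = 0.3
    floor_amp = speech_amp * 10 ** (-snr_db / 20.0)
    signal = floor_amp * rng.standard_normal(n)
    if timeline.segments:
        b, a = butter(4, [300 / (sample_rate / 2), 3400 / (sample_rate / 2)], btype="band")
        burst_src = lfilter(b, a, rng.standard_normal(n))
        burst_src *= speech_amp / max(1e-12, burst_src.std())
        mask = np.zeros(n, dtype=bool)
        for s, e in timeline.segments:
            mask[int(s * sample_rate) : int(e * sample_rate)] = True
        signal[mask] += burst_src[mask]
    return signal
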