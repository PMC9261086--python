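"""Spanish transcript preprocessing.

Tokenization drops punctuation, bracketed transcription annotations and
onomatopoeia/filler markers; stop words are *flagged*, not removed, so
that closed-class (pronoun/determiner) counting still sees them — the
"content token" view filters them out downstream.  Lemmatization is a
lookup table by default (pluggable); syllables are counted with
rule-based Spanish syllabification; pronouns and determiners are tagged
against a shipped lexicon with a positional rule for forms that are
ambiguous between the two classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

__all__ = [
    "Token",
    "StopwordLexicon",
    "ClosedClassLexicon",
    "Preprocessor",
    "load_stopwords",
    "load_closed_class_lexicon",
    "load_lemma_table",
    "tokenize_and_clean",
    "lemmatize",
    "count_syllables",
    "tag_closed_class",
    "content_tokens",
    "PRONOUN_SUBCATEGORIES",
    "DETERMINER_SUBCATEGORIES",
]

PRONOUN_SUBCATEGORIES = ["personal", "possessive", "demonstrative", "indefinite", "interrogative", "relative"]
DETERMINER_SUBCATEGORIES = [
    "definite_article",
    "indefinite",
    "possessive",
    "demonstrative",
    "interrogative",
    "numeral",
    "relative",
]

# Fillers / expression sounds / onomatopoeias removed outright.
FILLERS = frozenset(
    """eh ehh ehm em mm mmm hm hmm ah aah oh ohh uh uf uff uy ay
    ja jaja jajaja je jeje jejeje ji jiji ejem pff pfff psh tsk shh
    brr puf bah guau miau pum zas toc tictac achís achis""".split()
)


class Token(NamedTuple):
    """One word token with its analysis."""

    surface: str
    lemma: str
    is_stopword: bool
    closed_class: Optional[tuple[str, str]]  # (class, subcategory)
    syllables: int


@dataclass(frozen=True)
class StopwordLexicon:
    """Standard Spanish base list plus a dialectal extension.

    Membership is case-insensitive; the extension is kept disjoint from
    the base at load time.
    """

    base: frozenset[str]
    extension: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "extension", frozenset(self.extension) - self.base)

    def __contains__(self, word: str) -> bool:
        w = word.lower()
        return w in self.base or w in self.extension


@dataclass(frozen=True)
class ClosedClassLexicon:
    """word -> {class: subcategory} table for pronouns and determiners."""

    entries: Mapping[str, Mapping[str, str]]

    def classes_of(self, word: str) -> Mapping[str, str]:
        return self.entries.get(word.lower(), {})

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def subcategories(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {"pronoun": set(), "determiner": set()}
        for classes in self.entries.values():
            for cls, sub in classes.items():
                out[cls].add(sub)
        return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("psylang").joinpath("data", name)))


def _read_list(path: Path) -> list[str]:
    out = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.lower())
    return out


def load_stopwords(extension_path: str | Path | None = "default") -> StopwordLexicon:
    """Load the shipped base list; ``extension_path`` may point to a
    custom dialect list, be ``"default"`` (shipped Chilean placeholder)
    or ``None`` (no extension)."""
    base = frozenset(_read_list(_data_path("stopwords_es.txt")))
    if extension_path is None:
        ext: frozenset[str] = frozenset()
    elif extension_path == "default":
        ext = frozenset(_read_list(_data_path("stopwords_chilean_ext.txt")))
    else:
        ext = frozenset(_read_list(Path(extension_path)))
    return StopwordLexicon(base=base, extension=ext)


def load_closed_class_lexicon(path: str | Path | None = None) -> ClosedClassLexicon:
    path = _data_path("closed_class_es.tsv") if path is None else Path(path)
    entries: dict[str, dict[str, str]] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        word, cls, sub = line.split("\t")
        # first row per (word, class) defines the subcategory (priority rule)
        entries.setdefault(word.lower(), {}).setdefault(cls, sub)
    return ClosedClassLexicon(entries=entries)


def load_lemma_table(path: str | Path | None = None) -> dict[str, str]:
    path = _data_path("lemmas_es.tsv") if path is None else Path(path)
    table: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        surface, lemma = line.split("\t")
        table[surface.lower()] = lemma.lower()
    return table


_BRACKETED = re.compile(r"\[[^\]]*\]|\([^)]*\)|<[^>]*>|\{[^}]*\}")
_WORD = re.compile(r"[a-záéíóúüñ]+", re.IGNORECASE)

_STRONG = set("aeoáéó")
_ACCENTED_WEAK = set("íú")
_VOWELS = _STRONG | _ACCENTED_WEAK | set("iuü") | set("AEOÁÉÓÍÚIUÜ".lower())


def count_syllables(word: str) -> int:
    """Rule-based Spanish syllable count.

    Syllable nuclei are maximal vowel groups split at hiatus: two
    adjacent strong vowels (a/e/o, accented or not), or an accented
    weak vowel (í/ú) next to any vowel.  Weak+strong, strong+weak and
    weak+weak pairs form diphthongs (one nucleus).  The silent ``u`` of
    ``qu``/``gu`` + e/i is ignored; ``y`` counts as a vowel when not
    followed by one.
    """
    w = word.lower()
    if not w or not all(c.isalpha() for c in w):
        raise ValueError(f"count_syllables expects a single alphabetic word, got {word!r}")
    # silent u in que/qui/gue/gui (but not güe/güi)
    w = re.sub(r"([qg])u([eéií])", r"\1\2", w)
    # y: vowel /i/ unless it opens a syllable before a vowel
    chars = list(w)
    is_vowel = []
    for i, c in enumerate(chars):
        if c == "y":
            nxt = chars[i + 1] if i + 1 < len(chars) else ""
            is_vowel.append(nxt not in _VOWELS)
        else:
            is_vowel.append(c in _VOWELS)
    if not any(is_vowel):
        raise ValueError(f"no vowel nucleus in {word!r}")
    count = 0
    prev_vowel: Optional[str] = None
    for c, v in zip(chars, is_vowel):
        if not v:
            prev_vowel = None
            continue
        c_eff = "i" if c == "y" else c
        if prev_vowel is None:
            count += 1
        else:
            hiatus = (
                (prev_vowel in _STRONG and c_eff in _STRONG)
                or prev_vowel in _ACCENTED_WEAK
                or c_eff in _ACCENTED_WEAK
            )
            if hiatus:
                count += 1
        prev_vowel = c_eff
    return count


def _safe_syllables(surface: str, overrides: Mapping[str, int] | None) -> int:
    w = surface.lower()
    if overrides is not None and w in overrides:
        return int(overrides[w])
    try:
        return count_syllables(w)
    except ValueError:
        return 1


def tokenize_and_clean(
    text: str,
    stopwords: StopwordLexicon | None = None,
    syllable_overrides: Mapping[str, int] | None = None,
) -> list[Token]:
    """Tokenize Spanish text: strip punctuation and bracketed
    annotations, drop filler/onomatopoeia markers, flag stop words.

    Lemmas are initialised to the lowercased surface; run
    :func:`lemmatize` to fill them from a lemma table.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    cleaned = _BRACKETED.sub(" ", text)
    tokens: list[Token] = []
    for match in _WORD.finditer(cleaned):
        surface = match.group(0)
        low = surface.lower()
        if low in FILLERS:
            continue
        tokens.append(
            Token(
                surface=surface,
                lemma=low,
                is_stopword=surface in stopwords,
                closed_class=None,
                syllables=_safe_syllables(surface, syllable_overrides),
            )
        )
    return tokens


def lemmatize(tokens: Sequence[Token], table: Mapping[str, str] | None = None) -> list[Token]:
    """Fill lemmas from a lookup table; unknown surfaces keep their
    lowercased form."""
    if table is None:
        table = load_lemma_table()
    return [t._replace(lemma=table.get(t.surface.lower(), t.surface.lower())) for t in tokens]


def _verb_like(token: Token) -> bool:
    # the lemma table maps conjugated verbs to their infinitive; a token
    # whose lemma was rewritten to an -ar/-er/-ir form is verb-like
    return token.lemma != token.surface.lower() and token.lemma.endswith(("ar", "er", "ir"))


def _noun_like(token: Token, lexicon: ClosedClassLexicon) -> bool:
    return not token.is_stopword and token.surface.lower() not in lexicon and not _verb_like(token)


def tag_closed_class(tokens: Sequence[Token], lexicon: ClosedClassLexicon | None = None) -> list[Token]:
    """Tag pronoun/determiner tokens.

    For forms ambiguous between the two classes, a candidate determiner
    immediately preceding a noun-like token (neither closed-class nor a
    stop word) is tagged determiner, otherwise pronoun.  ``que`` is
    tagged relative pronoun only when it follows a noun-like token
    (an approximation of the relative-clause context; elsewhere it is
    treated as a conjunction and left untagged).
    """
    if lexicon is None:
        lexicon = load_closed_class_lexicon()
    out: list[Token] = []
    for i, tok in enumerate(tokens):
        classes = lexicon.classes_of(tok.surface)
        if not classes:
            out.append(tok)
            continue
        low = tok.surface.lower()
        if low == "que":
            prev = tokens[i - 1] if i > 0 else None
            if prev is not None and _noun_like(prev, lexicon):
                out.append(tok._replace(closed_class=("pronoun", classes["pronoun"])))
            else:
                out.append(tok)
            continue
        if len(classes) == 1:
            ((cls, sub),) = classes.items()
            out.append(tok._replace(closed_class=(cls, sub)))
            continue
        nxt = tokens[i + 1] if i + 1 < len(tokens) else None
        if nxt is not None and _noun_like(nxt, lexicon):
            out.append(tok._replace(closed_class=("determiner", classes["determiner"])))
        else:
            out.append(tok._replace(closed_class=("pronoun", classes["pronoun"])))
    return out


def content_tokens(tokens: Iterable[Token]) -> list[Token]:
    """Content view: stop words and closed-class function words removed."""
    return [t for t in tokens if not t.is_stopword and t.closed_class is None]


@dataclass
class Preprocessor:
    """Bundle of lexicons applied in one pass: tokenize -> lemmatize ->
    closed-class tagging.

    ``syllable_overrides`` lets a controlled (synthetic) lexicon supply
    authoritative syllable counts for its own words.
    """

    stopwords: StopwordLexicon
    lemma_table: Mapping[str, str]
    closed_class: ClosedClassLexicon
    syllable_overrides: Optional[Mapping[str, int]] = None

    @classmethod
    def default(cls, extension_path: str | Path | None = "default") -> "Preprocessor":
        return cls(
            stopwords=load_stopwords(extension_path),
            lemma_table=load_lemma_table(),
            closed_class=load_closed_class_lexicon(),
        )

    def process(self, text: str) -> list[Token]:
        """Single fused pass equivalent to tokenize_and_clean ->
        lemmatize -> tag_closed_class (the staged functions remain the
        reference implementation; equivalence is under test)."""
        overrides = self.syllable_overrides
        lemma_table = self.lemma_table
        stop = self.stopwords
        entries = self.closed_class.entries
        lows: list[str] = []
        surfaces: list[str] = []
        for match in _WORD.finditer(_BRACKETED.sub(" ", text)):
            s = match.group(0)
            low = s.lower()
            if low in FILLERS:
                continue
            surfaces.append(s)
            lows.append(low)
        n = len(lows)
        lemmas = [lemma_table.get(w, w) for w in lows]
        stops = [w in stop for w in lows]

        def verbish(i: int) -> bool:
            return lemmas[i] != lows[i] and lemmas[i].endswith(("ar", "er", "ir"))

        def nounish(i: int) -> bool:
            return not stops[i] and lows[i] not in entries and not verbish(i)

        out: list[Token] = []
        for i in range(n):
            classes = entries.get(lows[i])
            tag: Optional[tuple[str, str]] = None
            if classes:
                if lows[i] == "que":
                    if i > 0 and nounish(i - 1):
                        tag = ("pronoun", classes["pronoun"])
                elif len(classes) == 1:
                    tag = next(iter(classes.items()))
                elif i + 1 < n and nounish(i + 1):
                    tag = ("determiner", classes["determiner"])
                else:
                    tag = ("pronoun", classes["pronoun"])
            if overrides is not None and lows[i] in overrides:
                syl = int(overrides[lows[i]])
            else:
                syl = _safe_syllables(lows[i], None)
            out.append(Token(surfaces[i], lemmas[i], stops[i], tag, syl))
        return out

    def process_staged(self, text: str) -> list[Token]:
        toks = tokenize_and_clean(text, self.stopwords, self.syllable_overrides)
        toks = lemmatize(toks, self.lemma_table)
        return tag_closed_class(toks, self.closed_class)
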