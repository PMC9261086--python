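"""Word embeddings and cosine-based semantic-coherence series.

Word meaning is represented by a dense vector learned from context
(skip-gram with negative sampling, SGNS); a sentence or word-window is
represented by the *sum* of its word vectors, and coherence between two
adjacent discourse units is the cosine similarity of their sum vectors.
Three series are produced per interview: question-answer pairs, and
non-overlapping windows of 5 and of 6 content words.

The trainer here is a compact, single-threaded, fully deterministic
numpy implementation — adequate for the modest corpora this package
trains on.  Pre-trained vectors in the standard word2vec text format
can be loaded instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "EmbeddingModel",
    "CoherenceSeries",
    "train_embeddings",
    "sentence_vector",
    "cosine",
    "windowed_coherence",
    "qa_coherence",
]


class UndefinedSimilarityError(ValueError):
    """Cosine similarity is undefined for a null/zero vector."""


@dataclass
class EmbeddingModel:
    """Vocabulary -> fixed-dimension vector table.

    Out-of-vocabulary lookups return ``None`` (never raise).
    """

    words: list[str]
    vectors: np.ndarray  # (V, d)
    metadata: dict = field(default_factory=dict)
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or len(self.words) != self.vectors.shape[0]:
            raise ValueError("vectors must be (len(words), d)")
        self._index = {w: i for i, w in enumerate(self.words)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> Optional[np.ndarray]:
        i = self._index.get(word)
        return None if i is None else self.vectors[i]

    def indices(self, words: Sequence[str]) -> np.ndarray:
        """Vocabulary indices, -1 for out-of-vocabulary words."""
        idx = self._index
        return np.fromiter((idx.get(w, -1) for w in words), dtype=np.int64, count=len(words))

    def save(self, path: str | Path) -> None:
        """Standard word2vec text format plus a JSON metadata sidecar."""
        path = Path(path)
        lines = [f"{len(self.words)} {self.dimension}"]
        for w, v in zip(self.words, self.vectors):
            lines.append(w + " " + " ".join(f"{x:.8g}" for x in v))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.metadata, sort_keys=True, indent=1), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        path = Path(path)
        lines = path.read_text(encoding="utf-8").splitlines()
        n, d = (int(x) for x in lines[0].split())
        words, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split(" ")
            words.append(parts[0])
            rows.append([float(x) for x in parts[1 : d + 1]])
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
        return cls(words=words, vectors=np.array(rows), metadata=meta)


@dataclass(frozen=True)
class CoherenceSeries:
    """Ordered cosine values with the unit that produced them."""

    values: tuple[float, ...]
    unit: str  # "qa-pair" | "5-word" | "6-word" | ...
    window_size: Optional[int] = None
    n_undefined: int = 0  # pairs skipped because a sum vector was null/zero

    def __post_init__(self) -> None:
        if any(not (-1.0 - 1e-9 <= v <= 1.0 + 1e-9) for v in self.values):
            raise ValueError("coherence values must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")

    def min(self) -> float:
        return float(np.min(self.values)) if self.values else float("nan")


def train_embeddings(
    corpus_tokens: Sequence[Sequence[str]],
    d: int = 50,
    window: int = 5,
    epochs: int = 20,
    seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.05,
    min_count: int = 1,
    min_vocab: int = 2,
    batch_size: int = 256,
) -> EmbeddingModel:
    """Train SGNS embeddings on a corpus of token sequences.

    Deterministic given ``seed`` (single worker, fixed pair order per
    epoch up to a seeded shuffle).  Negative samples are drawn from the
    unigram distribution raised to 3/4.
    """
    if d < 2:
        raise ValueError("embedding dimension d must be >= 2")
    counts: dict[str, int] = {}
    for sent in corpus_tokens:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if len(vocab) < min_vocab:
        raise ValueError(f"vocabulary size {len(vocab)} below minimum {min_vocab}")
    index = {w: i for i, w in enumerate(vocab)}
    sents = [np.array([index[w] for w in s if w in index], dtype=np.int64) for s in corpus_tokens]
    sents = [s for s in sents if s.size >= 2]
    if not sents:
        raise ValueError("corpus has no sentence with >= 2 in-vocabulary tokens")

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W = (rng.random((V, d)) - 0.5) / d  # input vectors
    C = np.zeros((V, d))  # output (context) vectors
    freq = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    noise = freq / freq.sum()

    # enumerate skip-gram pairs once with dynamic window radii per epoch
    total_steps = None
    step = 0
    for epoch in range(epochs):
        centers_all, contexts_all = [], []
        for s in sents:
            n = s.size
            radii = rng.integers(1, window + 1, size=n)
            for i in range(n):
                lo, hi = max(0, i - radii[i]), min(n, i + radii[i] + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers_all.append(s[i])
                        contexts_all.append(s[j])
        centers = np.array(centers_all, dtype=np.int64)
        contexts = np.array(contexts_all, dtype=np.int64)
        order = rng.permutation(centers.size)
        centers, contexts = centers[order], contexts[order]
        if total_steps is None:
            total_steps = max(1, epochs * centers.size)
        # keep each word's accumulated per-batch update small: the
        # minibatch gradient is evaluated at stale parameters, which
        # destabilizes training when the vocabulary is tiny
        eff_batch = int(max(8, min(batch_size, 2 * V)))
        for start in range(0, centers.size, eff_batch):
            c_idx = centers[start : start + eff_batch]
            o_idx = contexts[start : start + eff_batch]
            b = c_idx.size
            lr = learning_rate * max(1e-4, 1.0 - step / total_steps)
            step += b
            neg = rng.choice(V, size=(b, negative), p=noise)
            w = W[c_idx]  # (b, d)
            # positive pair
            co = C[o_idx]
            s_pos = expit(np.einsum("bd,bd->b", w, co))
            g_pos = (s_pos - 1.0)[:, None]  # d L / d score
            # negatives
            cn = C[neg]  # (b, k, d)
            s_neg = expit(np.einsum("bd,bkd->bk", w, cn))
            g_neg = s_neg[:, :, None]
            grad_w = g_pos * co + np.einsum("bk,bkd->bd", s_neg, cn)
            # clip exploding updates (rare; tiny corpora)
            gn = np.linalg.norm(grad_w, axis=1, keepdims=True)
            grad_w = grad_w * np.minimum(1.0, 5.0 / np.maximum(gn, 1e-12))
            np.add.at(W, c_idx, -lr * grad_w)
            np.add.at(C, o_idx, -lr * (g_pos * w))
            np.add.at(C, neg.ravel(), -lr * (g_neg * w[:, None, :]).reshape(-1, d))
    meta = {
        "algorithm": "sgns",
        "dimension": d,
        "window": window,
        "epochs": epochs,
        "seed": seed,
        "negative": negative,
        "vocab_size": V,
    }
    return EmbeddingModel(words=vocab, vectors=W, metadata=meta)


def sentence_vector(tokens: Sequence[str], model: EmbeddingModel) -> Optional[np.ndarray]:
    """Sum of in-vocabulary word vectors; ``None`` when the input is
    empty or entirely out-of-vocabulary."""
    idx = model.indices(tokens)
    idx = idx[idx >= 0]
    if idx.size == 0:
        return None
    return model.vectors[idx].sum(axis=0)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; raises on null/zero vectors."""
    if u is None or v is None:
        raise UndefinedSimilarityError("null vector")
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedSimilarityError("zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _pairwise_series(sums: np.ndarray, valid: np.ndarray, unit: str, window_size: Optional[int]) -> CoherenceSeries:
    norms = np.linalg.norm(sums, axis=1)
    ok = valid & (norms > 0)
    values = []
    undefined = 0
    for a, b in zip(range(len(sums) - 1), range(1, len(sums))):
        if ok[a] and ok[b]:
            values.append(float(np.clip(np.dot(sums[a], sums[b]) / (norms[a] * norms[b]), -1.0, 1.0)))
        else:
            undefined += 1
    return CoherenceSeries(values=tuple(values), unit=unit, window_size=window_size, n_undefined=undefined)


def windowed_coherence(tokens: Sequence[str], window_size: int, model: EmbeddingModel) -> CoherenceSeries:
    """Cosine between adjacent non-overlapping ``window_size``-word
    windows of a content-token stream; the trailing partial window is
    dropped.  Fewer than two full windows gives an empty series."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    unit = f"{window_size}-word"
    n_windows = len(tokens) // window_size
    if n_windows < 2:
        return CoherenceSeries(values=(), unit=unit, window_size=window_size)
    idx = model.indices(list(tokens[: n_windows * window_size])).reshape(n_windows, window_size)
    padded = np.vstack([model.vectors, np.zeros((1, model.dimension))])
    sums = padded[idx].sum(axis=1)  # OOV rows hit the zero pad
    valid = (idx >= 0).any(axis=1)
    return _pairwise_series(sums, valid, unit, window_size)


def qa_coherence(interview, model: EmbeddingModel, preprocessor=None) -> CoherenceSeries:
    """One cosine per question-answer pair, between the question's and
    the answer's content-token sum vectors, in interview order."""
    from psylang.textproc import Preprocessor, content_tokens

    if preprocessor is None:
        preprocessor = Preprocessor.default()
    values = []
    undefined = 0
    for question, answer in interview.qa_pairs():
        q_tokens = [t.lemma for t in content_tokens(preprocessor.process(question.text))]
        a_tokens = [t.lemma for t in content_tokens(preprocessor.process(answer.text))]
        qv = sentence_vector(q_tokens, model)
        av = sentence_vector(a_tokens, model)
        try:
            values.append(cosine(qv, av))
        except UndefinedSimilarityError:
            undefined += 1
    return CoherenceSeries(values=tuple(values), unit="qa-pair", n_undefined=undefined)
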