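import numpy as np
import pytest

from psylang.corpus import Group, Interview, SubjectMeta, Turn, Speaker
from psylang.embeddings import EmbeddingModel
from psylang.synthetic import CohortSpec, build_lexicon, conversion_profiles, default_profiles, sample_cohort
from psylang.textproc import Preprocessor


@pytest.fixture(scope="session")
def lexicon():
    return build_lexicon(n_words=800, d=12, seed=321)


@pytest.fixture(scope="session")
def preproc():
    return Preprocessor.default()


@pytest.fixture(scope="session")
def toy_model():
    """Hand-built 3-dimensional embedding table for exact-value tests."""
    words = ["sol", "luna", "mar", "montaña", "perro"]
    vectors = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, 2.0, 2.0],
            [2.0, 1.0, 2.0],
        ]
    )
    return EmbeddingModel(words=words, vectors=vectors)


@pytest.fixture(scope="session")
def small_cohort(lexicon):
    """Strong-effect cohort, reduced sizes, shared across tests."""
    spec = CohortSpec(sizes={"HC": 8, "FEP": 8, "SZ": 8}, fep_split={"C-SZ": 5, "NC-SZ": 3})
    profiles = {**default_profiles(), **conversion_profiles()}
    return sample_cohort(spec, profiles, seed=20260919, lexicon=lexicon)


def make_interview(turn_specs, duration_s=600.0, group=Group.HC, timeline=None, subject_id="S1"):
    """Helper: build an interview from (speaker, text[, is_question]) tuples."""
    turns = []
    for spec in turn_specs:
        speaker, text = spec[0], spec[1]
        is_q = spec[2] if len(spec) > 2 else text.strip().endswith("?")
        turns.append(Turn(speaker=Speaker(speaker), text=text, is_question=is_q))
    meta = SubjectMeta(subject_id=subject_id, group=group)
    return Interview(meta=meta, turns=turns, duration_s=duration_s, timeline=timeline)
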