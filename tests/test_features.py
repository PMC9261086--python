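import numpy as np
import pytest

from conftest import make_interview
from oracle import recompute_features
from psylang.corpus import Group, SubjectMeta
from psylang.features import (
    coherence_features,
    extract_all,
    extract_table,
    fluency_features,
    productivity_features,
    ttr_windowed,
)
from psylang.pauses import SpeechTimeline
from psylang.synthetic import default_profiles, sample_interview


class TestTtrWindowed:
    def test_single_window_one_type(self):
        assert ttr_windowed(["casa"] * 250, 250) == pytest.approx(1 / 250)

    def test_all_distinct(self):
        assert ttr_windowed([f"w{i}" for i in range(250)], 250) == pytest.approx(1.0)

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(11)
        stream = [f"w{i}" for i in rng.integers(0, 50, 300)]
        got = ttr_windowed(stream, 250)
        expected = np.mean(
            [len(set(stream[i : i + 250])) / 250 for i in range(51)]
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_short_stream_is_missing(self):
        assert ttr_windowed(["a"] * 10, 250) is None

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            ttr_windowed(["a"], 0)

    def test_non_increasing_in_span_on_zipf_streams(self):
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(10):
            stream = [f"w{i}" for i in np.minimum(rng.zipf(1.3, 1200), 500)]
            vals = [ttr_windowed(stream, n) for n in (250, 500, 750, 1000)]
            diffs.append(all(a >= b for a, b in zip(vals, vals[1:])))
        # larger spans accumulate more repetition on average
        assert np.mean(diffs) >= 0.8


class TestFluency:
    def test_qa_rate_arithmetic(self, toy_model, preproc):
        turns = []
        for _ in range(30):
            turns += [("interviewer", "¿sol?", True), ("patient", "luna mar")]
        itv = make_interview(turns, duration_s=1800.0)  # half an hour
        f = fluency_features(itv, preproc)
        assert f["qa_pairs_per_hour"] == pytest.approx(60.0)

    def test_single_word_counts(self, preproc):
        itv = make_interview([("interviewer", "¿sí?", True), ("patient", "perro")], duration_s=3600.0)
        f = fluency_features(itv, preproc)
        assert f["total_words_per_hour"] == pytest.approx(1.0)
        assert f["different_words_per_hour"] == pytest.approx(1.0)

    def test_word_rates_use_unique_lemmas(self, preproc):
        # 1800 content words, 600 unique lemmas, 40 minutes
        vocab = [f"k{chr(97 + i // 26)}x{chr(97 + i % 26)}" for i in range(600)]
        words = [vocab[i % 600] for i in range(1800)]
        turns = [("patient", " ".join(words))]
        itv = make_interview(turns, duration_s=2400.0)
        f = fluency_features(itv, preproc)
        assert f["total_words_per_hour"] == pytest.approx(2700.0)
        assert f["different_words_per_hour"] == pytest.approx(900.0)

    def test_pause_count_from_timeline(self, preproc):
        tl = SpeechTimeline.from_pairs([(0, 10), (13, 20), (21, 30)])
        itv = make_interview([("patient", "sol luna")], duration_s=30.0, timeline=tl)
        assert fluency_features(itv, preproc)["pause_count_gt2s"] == 1.0

    def test_no_timeline_is_missing(self, preproc):
        itv = make_interview([("patient", "sol")], duration_s=30.0)
        assert np.isnan(fluency_features(itv, preproc)["pause_count_gt2s"])


class TestProductivity:
    def test_per_answer_means(self, preproc):
        itv = make_interview(
            [("patient", "uvas peras kiwis melones fresas"),
             ("patient", "lago río cerro valle bosque playa cueva")],
            duration_s=60.0,
        )
        f = productivity_features(itv, preproc)
        assert f["total_words_per_answer_mean"] == pytest.approx(6.0)

    def test_possessive_determiner_rate(self, preproc):
        itv = make_interview([("patient", "mi casa es mi casa")], duration_s=60.0)
        f = productivity_features(itv, preproc)
        assert f["det_possessive_per_answer"] == pytest.approx(2.0)

    def test_six_turn_fixture_hand_count(self, preproc):
        itv = make_interview(
            [
                ("interviewer", "¿Cómo está?", True),
                ("patient", "yo vivo en mi casa grande"),
                ("interviewer", "¿Y su familia?", True),
                ("patient", "ellos tienen dos perros y un gato"),
                ("interviewer", "¿Algo más?", True),
                ("patient", "nada más eso"),
            ],
            duration_s=120.0,
        )
        f = productivity_features(itv, preproc)
        # content words: vivo(->vivir), casa, grande / perros(->perro), gato / (none)
        assert f["total_words_per_answer_mean"] == pytest.approx(5 / 3)
        assert f["pron_personal_per_answer"] == pytest.approx(2 / 3)  # yo, ellos
        assert f["pron_indefinite_per_answer"] == pytest.approx(1 / 3)  # nada
        assert f["det_possessive_per_answer"] == pytest.approx(1 / 3)  # mi
        assert f["det_numeral_per_answer"] == pytest.approx(1 / 3)  # dos
        assert f["det_indefinite_per_answer"] == pytest.approx(1 / 3)  # un
        # word lengths: vi-vir? surfaces: vivo(2), casa(2), grande(2), perros(2), gato(2)
        assert f["mean_word_length_syllables"] == pytest.approx(2.0)

    def test_zero_answers_rejected(self, preproc):
        from psylang.corpus import Interview, ValidationError

        with pytest.raises(ValidationError):
            make_interview([("interviewer", "¿sí?", True)], duration_s=10.0)


class TestCoherenceFeatures:
    def test_repeated_word_all_ones(self, toy_model, preproc):
        turns = [("interviewer", "¿mar?", True), ("patient", " ".join(["mar"] * 60))]
        itv = make_interview(turns, duration_s=60.0)
        f = coherence_features(itv, toy_model, preproc)
        for k in ("qa_cos_mean", "qa_cos_min", "win5_cos_mean", "win5_cos_min", "win6_cos_mean", "win6_cos_min"):
            assert f[k] == pytest.approx(1.0)

    def test_orthogonal_single_pair(self, toy_model, preproc):
        itv = make_interview([("interviewer", "¿sol?", True), ("patient", "luna")], duration_s=60.0)
        f = coherence_features(itv, toy_model, preproc)
        assert f["qa_cos_mean"] == pytest.approx(0.0)
        assert f["qa_cos_min"] == pytest.approx(0.0)

    def test_toy_windows_match_hand_computation(self, toy_model, preproc):
        # two 5-word windows with known sum vectors
        text = "sol sol sol sol sol luna luna luna luna luna"
        itv = make_interview([("interviewer", "¿sol?", True), ("patient", text)], duration_s=60.0)
        f = coherence_features(itv, toy_model, preproc)
        assert f["win5_cos_mean"] == pytest.approx(0.0)  # orthogonal block sums
        assert np.isnan(f["win6_cos_mean"])  # only one full 6-window


class TestExtractAll:
    def test_full_synthetic_interview_no_missing(self, lexicon):
        prof = default_profiles()["HC"]
        meta = SubjectMeta(subject_id="h", group=Group.HC)
        itv, _ = sample_interview(prof, meta, lexicon, seed=3, duration_s=2400.0)
        vec = extract_all(itv, lexicon.embedding_model(), lexicon.preprocessor())
        assert len(vec) == 30
        assert not any(np.isnan(v) for v in vec.values())

    def test_missing_pause_feature_without_timeline(self, lexicon):
        prof = default_profiles()["HC"]
        meta = SubjectMeta(subject_id="h", group=Group.HC)
        itv, _ = sample_interview(prof, meta, lexicon, seed=4, duration_s=2400.0)
        itv.timeline = None
        vec = extract_all(itv, lexicon.embedding_model(), lexicon.preprocessor())
        assert np.isnan(vec["pause_count_gt2s"])
        assert sum(np.isnan(v) for v in vec.values()) == 1

    def test_identical_interviews_identical_vectors(self, lexicon):
        prof = default_profiles()["SZ"]
        meta = SubjectMeta(subject_id="s", group=Group.SZ)
        a, _ = sample_interview(prof, meta, lexicon, seed=9, duration_s=1200.0)
        b, _ = sample_interview(prof, meta, lexicon, seed=9, duration_s=1200.0)
        va = extract_all(a, lexicon.embedding_model(), lexicon.preprocessor())
        vb = extract_all(b, lexicon.embedding_model(), lexicon.preprocessor())
        assert list(va) == list(vb)
        np.testing.assert_array_equal(list(va.values()), list(vb.values()))

    def test_answer_duplication_scales_rates_not_means(self, lexicon, preproc):
        """Duplicating each answer's text doubles per-answer closed-class
        rates but leaves per-word means (word length) unchanged."""
        from psylang.corpus import Interview, Turn, Speaker

        prof = default_profiles()["FEP"]
        meta = SubjectMeta(subject_id="f", group=Group.FEP)
        itv, _ = sample_interview(prof, meta, lexicon, seed=12, duration_s=600.0)
        doubled_turns = [
            Turn(speaker=t.speaker, text=t.text + " " + t.text, is_question=t.is_question)
            if t.speaker is Speaker.PATIENT
            else t
            for t in itv.turns
        ]
        doubled = Interview(meta=meta, turns=doubled_turns, duration_s=itv.duration_s, timeline=itv.timeline)
        pre = lexicon.preprocessor()
        f1 = productivity_features(itv, pre)
        f2 = productivity_features(doubled, pre)
        assert f2["mean_word_length_syllables"] == pytest.approx(f1["mean_word_length_syllables"])
        assert f2["total_words_per_answer_mean"] == pytest.approx(2 * f1["total_words_per_answer_mean"])
        for key in ("pron_personal_per_answer", "det_definite_article_per_answer"):
            assert f2[key] == pytest.approx(2 * f1[key], abs=1e-9)


class TestBruteForceEquivalence:
    def test_pipeline_matches_oracle_on_random_interviews(self, lexicon):
        """Every feature equals an independent naive recomputation."""
        model = lexicon.embedding_model()
        pre = lexicon.preprocessor()
        table = {w: v.tolist() for w, v in zip(model.words, model.vectors)}
        syl = lexicon.syllable_overrides()
        profiles = list(default_profiles().values())
        rng = np.random.default_rng(2024)
        for seed in range(8):
            prof = profiles[seed % 3]
            dur = float(rng.uniform(300, 900))
            meta = SubjectMeta(subject_id=f"s{seed}", group=Group.HC)
            itv, _ = sample_interview(prof, meta, lexicon, seed=seed, duration_s=dur)
            got = extract_all(itv, model, pre)
            want = recompute_features(itv, table, syl)
            for k in got:
                if np.isnan(got[k]) and np.isnan(want[k]):
                    continue
                assert got[k] == pytest.approx(want[k], rel=1e-9, abs=1e-9), k


class TestExtractTable:
    def test_metadata_columns_and_categories(self, small_cohort):
        table = extract_table(
            small_cohort.interviews[:6],
            small_cohort.embedding_model(),
            small_cohort.preprocessor(),
        )
        assert len(table.language_columns()) == 30
        assert "age_years" in table.columns_of("demographic")
        assert "panss_total" in table.columns_of("clinical")
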