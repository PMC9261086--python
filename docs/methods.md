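# Methods

This note documents the models, defaults and design decisions behind
`psylang`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Unit of analysis and data model

One **interview** = subject metadata + an ordered list of
speaker-labelled turns (interviewer / patient) + a duration + an
optional voiced-speech timeline.  A **question–answer (QA) pair** is an
interviewer turn flagged as a question followed by the next patient
turn with no intervening interviewer turn.  Question flags are taken
from the transcript when present, else inferred from terminal `?` /
`¿…?` punctuation (the supported transcripts are manually punctuated).
Durations come, in order of precedence, from an explicit value, from
transcript metadata, or from the maximum turn end time; fluency
features are per-time, so an interview with none of these is rejected.

Two transcript dialects are read: a JSON-lines structured format (one
record per turn) and a permissive `E:`/`P:`-prefixed plain-text
format.  Unmappable bracketed annotations are discarded.

## 2. Pause detection

A **pause** is a silence between two consecutive voiced segments whose
duration is *strictly* greater than 2 s ("longer than 2 s" read
strictly; the threshold is a parameter).  Pauses are interview-global:
no diarization is attempted, so interviewer and patient silences are
not distinguished.

The audio path is spectral-gating noise reduction followed by a
short-time-energy VAD.  The noise profile is the per-frequency mean
magnitude of the quietest 10% of STFT frames; a bin is attenuated
(×0.05) only if it is below 2× that profile *and* below 0.35 of its
own frequency bin's temporal peak.  The second condition keeps steady
tonal components intact when a recording contains no silence from
which to estimate noise — without it, a constant tone is its own noise
estimate and would be gated away.  VAD defaults: 25 ms frames, 10 ms
hop, voicing threshold 3× the noise-floor RMS (10th percentile of
frame RMS) capped at 0.3× the peak RMS (so uninterrupted speech is
still detected), 200 ms minimum segment, 150 ms gap bridging.  These
are conventional speech-processing values — the methodological
criterion (the 2 s rule) is fixed; the segmentation front-end is this
package's documented choice and fully configurable.

## 3. Text preprocessing (Spanish)

Tokenization strips punctuation and bracketed annotations and drops a
fixed list of fillers/onomatopoeias.  Stop words are **flagged, not
removed**: most Spanish pronouns and determiners are standard stop
words, and closed-class counting must still see them.  The stop-word
lexicon is a standard Spanish base list plus a user-editable dialectal
extension (shipped: a placeholder set of Chilean colloquialisms; the
mechanism, not the particular list, is the reproducible content).  The
"content token" view used for word counts, TTR and coherence excludes
stop words and closed-class words.

Lemmatization is a pluggable lookup table (shipped: frequent verb
conjugations → infinitive, frequent plurals → singular; unknown
surfaces pass through lowercased).  "Different words" always means
unique lemmas.

Syllables are counted by rule: nuclei are maximal vowel groups, split
at hiatus (two strong vowels a/e/o, or an accented weak vowel í/ú next
to any vowel); weak+strong, strong+weak and unaccented weak+weak pairs
are diphthongs; the silent `u` of `qu`/`gu`+e/i is ignored; `y` counts
as a vowel when not opening a syllable.  A controlled lexicon (e.g.
the synthetic generator's) may override counts per word.

Closed-class tagging matches tokens case-insensitively against a
shipped pronoun/determiner lexicon with 6 pronoun and 7 determiner
subcategories.  Forms ambiguous between the classes (e.g. *esta*,
*muchos*) are resolved positionally: a candidate immediately preceding
a noun-like token (not a stop word, not closed-class, not a
lemma-table verb) is a determiner, otherwise a pronoun.  *que* is
tagged relative pronoun only after a noun-like token, else treated as
a conjunction and left untagged — documented as approximate.  Counting
happens on the pre-filter stream (before stop-word removal); the
alternative is exposed as a switch.

## 4. Embeddings and coherence

Default embeddings are trained by a compact deterministic numpy SGNS
(skip-gram with negative sampling) implementation: d = 50, window 5,
20 epochs, 5 negatives from the unigram^0.75 distribution, linearly
decaying learning rate, single worker, fixed seed.  Minibatches are
capped at 2× the vocabulary size and gradient updates norm-clipped at
5 — with a tiny vocabulary, large stale-gradient minibatches otherwise
diverge.  Pre-trained vectors load from the standard word2vec text
format; for synthetic cohorts the generator's planted vector table is
used directly (it *is* the corpus's semantic ground truth, and avoids
retraining embeddings inside every calibration replicate).

A discourse unit's vector is the **sum** of its in-vocabulary content
word vectors; out-of-vocabulary words are skipped silently and
per-interview OOV is countable.  Coherence series: one cosine per QA
pair, and one per adjacent pair of consecutive **non-overlapping**
windows of 5 (and of 6) content words, trailing partial window
dropped ("every 5 or 6 words" read as a partition; an overlapping
variant exists but is off by default).  Pairs involving a null/zero
sum vector are excluded and counted.  Feature values are the mean and
min of each of the three series; an empty series yields a missing
value.

## 5. The 30-feature schema

4 fluency + 20 productivity + 6 coherence (see README table).  The
composition of the 20 productivity features is: 2 lexical-volume
per-answer means + 1 word length + 4 windowed TTRs + 13 closed-class
subcategory rates (total occurrences per answer).  The non-repeated
(unique-form) closed-class variant is computed and available under an
extended schema but is not part of the default 30 columns — the
default respects the 4/20/6 split while keeping both variants
honoured; the schema is configuration, not code.  Other defaults with
an exposed switch: words are counted on patient turns only; "different
words" uses lemmas; the pause count is raw (not per-hour); TTR-N is
the *moving-average* TTR (MATTR, step 1), and streams shorter than N
give a missing value, never an extrapolation.  Missing inputs (no
timeline → no pause count) propagate as NaN with per-feature
missingness semantics; imputation happens only inside classification
folds.

MATTR is computed in O(n): token j is a new type in window [i, i+N)
iff its previous occurrence precedes i, so each token contributes an
interval of window starts, accumulated with a difference array.  The
test suite checks this against per-window `set()` brute force.

## 6. Group statistics

Shapiro–Wilk screens normality (constant samples are rejected as
degenerate input).  Group comparisons are two-sided Mann–Whitney U
(pairs) and Kruskal–Wallis (three groups) with mid-ranks and tie
correction.  For combined n ≤ 12 p-values are exact by full
enumeration of label assignments (two-sided MW p = doubled smaller
tail, clamped at 1; KW p = upper tail of H); beyond that, the
tie-corrected normal / chi-square approximations.  Feature–symptom
associations are Pearson r with Bonferroni correction at a stated
family size (default k = 30, the number of language features).
Redundancy structure is reported as connected components of the
feature graph with edges |r| ≥ τ; τ defaults to 0.7 — the number of
resulting clusters is data-dependent, so correctness is defined by
planted-block recovery tests, not by any particular count.

## 7. Classification

Variable ranking: 500-tree random forest, mean impurity-decrease
importances, ties broken by column order (deterministic given seed).
Ranking is per-contrast by default; a three-class ranking mode exists.
Selection: greedy scan of the ranking keeping features whose |r| with
all kept features is < r_max (default 0.7, deliberately equal to the
clustering τ — one coherent redundancy threshold).

Accuracy: repeated stratified k-fold CV, default 10 folds × 12
repeats, a fresh forest per fold, missing values imputed with the
*training-fold* median.  The default scheme is an inference from the
granularity of accuracies such a study reports (multiples of 1/120
suggest 120 fold-level evaluations); it is fully configurable, and
calibration/ordering experiments in the test suite use fewer repeats
and smaller forests to keep replicate counts high at fixed compute.
Reports carry per-fold accuracies, per-subject majority-vote
predictions (ties broken alphabetically), mean accuracy, and balanced
accuracy as a secondary honesty column for the imbalanced (28 vs 12)
conversion contrast.  The case matrix lays out per-subject predictions
per feature set against the reference diagnosis.  Interpretability
export: a single depth-≤3 decision tree fit on the full table (text
and DOT formats) — an illustration, not an accuracy estimate.

Feature-set ladder for the longitudinal analysis: `demographics`
(gender, age, education, first-degree relative), `panss` (the four
PANSS scores plus illness duration — the clinical block),
`demographics+panss`, `language` (all 30), `top10-all`, plus
per-category sets.

## 8. Synthetic cohort generator

The generator emulates the *statistical structure* of a clinical
interview corpus, not natural Spanish.  Content words live on a circle
in embedding space (unit circle in the first two of d = 16 dimensions
plus small noise dimensions); patient speech is a topic random walk on
the circle with per-word step σ (radians), so σ directly controls
coherence.  Word choice around the topic follows a truncated Zipf law
(exponent s), a perseveration probability ρ copies a recently emitted
word (clinically motivated; lowers TTR independently of drift speed),
and a long-word bias moves choice onto a sublattice of 3–5-syllable
words (lexicon words carry planted syllable counts, so word length is
controlled).  Real Spanish function words are injected: determiners
prefix a content word (one each, so the tagger's positional rule
resolves them deterministically), pronouns and stop-word fillers stand
alone.  Timelines interleave gamma-length voiced segments with short
gaps (0.2–1.4 s) and Poisson-count lognormal pause events; a ±0.3 s
guard band around the 2 s criterion keeps frame quantization in the
audio path from flipping planted counts.  Per-subject parameters are
jittered around group values (lognormal, 15%) so planted parameters
are recoverable by rank correlation across subjects.

Cohort defaults follow the published study description: sizes 49 HC /
40 FEP / 44 SZ with the FEP group split 28 C-SZ / 12 NC-SZ; interview
durations HC 53.5 ± 10.2 min (range 32–83), patients 28.6 ± 16.5 min
(range 5–102); per-group age, education, illness duration, family
history, gender mix and PANSS subscale moments, with PANSS total = sum
of subscales (which enforces total ≥ each subscale).  Demographic and
clinical draws are independent truncated normals — the source reports
moments only, so no covariance structure is modelled.

Three profile sets are provided.  **Strong-effect** (default): group
orderings mirror the qualitative clinical contrasts (patients pause
more: pause rate 2.0/2.5/3.0 per min with lognormal location −0.7/−0.3
/0.0; say less: 60/40/28 words per answer; repeat more: ρ = 0.05/0.18
/0.32; use rarer and longer words: s = 1.15/1.30/1.50, long-word bias
0.20/0.24/0.30; drift more: σ = 0.04/0.11/0.22 rad; fewer possessive
pronouns: 0.5/0.3/0.18 per answer).  Magnitudes are tuned for
testability and are labelled as such — they are **not** estimates of
any real corpus.  **Null**: one shared parameter set for all groups
(moderate 16 ± 4 min durations keep 100-replicate calibration cheap),
so every apparent group difference is sampling noise.  **Conversion**:
C-SZ drifts toward SZ-like language; with shared demographic/PANSS
moments the conversion signal is purely linguistic, which underpins
the language-beats-demographics ordering test.

What passing tests on synthetic data do and do not show: they verify
the *pipeline* — feature definitions, exact statistics, selection and
CV mechanics, determinism and calibration — under known ground truth.
They do not validate clinical effect sizes, natural-language
tokenization edge cases beyond the fixture set, ASR/transcription
noise, or generalization to real patients.

## 9. Problem sizes and numerical choices

Calibration and ordering experiments run at: 20 brute-force oracle
interviews (5–15 min each); 50 audio cases of 60 s at 8 kHz, 20 dB
SNR; exact-test enumeration up to combined n = 12; 100 null cohorts of
133 interviews for test calibration and one for CV chance bands (10
folds × 3 repeats, 200 trees); one strong cohort for contrast
accuracies (10 × 3, 300 trees); 20 seeds for ranking recovery and for
the longitudinal ordering (5 × 2, 150 trees, n = 40).  These replicate
counts and forest sizes are the package's chosen experiment scales;
`scripts/acceptance.py` uses 10 folds × 6 repeats with 300 trees.
Tolerances: oracle equivalence 1e-9 (relative and absolute); exact
p-value equivalence 1e-12; enumeration tail comparisons use a 1e-12
epsilon so floating-point H/U ties count as ≥.  All randomness flows
from one master seed through `numpy.random.SeedSequence` spawning;
scikit-learn estimators get derived 31-bit seeds; reports are written
with fixed float formatting so identical seeds give byte-identical
files.

## 10. Known limitations

- The lemmatizer is a lookup table; unseen inflections pass through,
  so "different words" slightly overcounts on real text.
- Closed-class disambiguation is positional, not syntactic; *que* and
  determiner/pronoun splits are approximations without a parser.
- Pauses are interview-global; no speaker attribution or pause-timing
  analysis.
- The VAD is energy-based and mono; overlapping speech, music or
  non-stationary noise will degrade segmentation.
- Synthetic text is not natural Spanish; effect magnitudes are
  testability choices, and classification accuracies on synthetic
  cohorts are not comparable to clinical results.
- Exact tests are limited to combined n ≤ 12 by enumeration cost.
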