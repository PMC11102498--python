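# Methods

This note documents the models, conventions and numerical choices behind
`szspeech`, in the order the pipeline runs.

## Frame model and segmentation

Input is a fixed-rate sequence of 10-ms analysis frames per response,
each carrying a fundamental frequency (F0, Hz; 0 encodes unvoiced) and
optionally intensity. A frame is classified as speech when its F0 lies
strictly inside the (75, 250) Hz band: the band captures male voiced
speech while rejecting high-frequency noise, and both bounds are treated
as strict (75 Hz exactly is non-speech). The bounds are configurable.

Segmentation is a run-length partition of the classified mask:

* **utterance** — maximal speech run of ≥ 50 frames (500 ms);
* **sub-threshold run** — maximal speech run of < 50 frames. These are
  deliberately a third class: they are speech, so they cannot be part of
  a gap, but they are too short to count as utterances;
* **gap** — maximal run with no speech frames. Runs at the start or end
  of a response count as gaps: a maximal no-speech interval has no
  interior restriction, and responses typically begin with silence.

The three classes partition the frame range exactly; this is enforced by
a property test against an independent run-length oracle.

"Seconds of speech" for the response filter counts every
speech-classified frame (including sub-threshold runs) × 10 ms — the
most inclusive reading; the filter keeps responses with ≥ 10.0 s
(boundary inclusive, since "less than 10 s" is what is excluded).

## Prosodic features

Durations are reported in seconds; ratios are dimensionless in [0, 1];
pitch statistics in Hz. A response that cannot define a feature (no
utterances for MUD, no gaps for MGD, < 2 speech frames for PS, …) yields
NaN — an explicit undefined marker, never a fabricated 0. Downstream,
classification imputes NaN cells with the training-fold mean and the
statistics drop them pairwise.

* **PS** uses the sample standard deviation (denominator n − 1).
* **FPC** is the Pearson correlation between the speech-pitch sequence
  and its one-step shift. By default both FPC and jitter index the
  *concatenated* sequence of speech frames, so a pitch pair or jitter
  window may bridge an interior silence; this matches the indexing of
  the jitter definition, where v counts speech frames, not time.
  `bridge_gaps=False` gives the gap-respecting alternative (pairs and
  windows confined to contiguous speech runs).
* **Jitter** is implemented exactly as defined: the numerator is the
  signed deviation of p(v) from its local K-frame mean and the
  denominator is the local window **sum**. Two consequences are worth
  knowing. First, dividing by the window sum rather than the window mean
  scales the statistic down by a factor of K; a
  `denominator="mean"` option is provided for sensitivity analysis
  (exactly K× the default, which the tests verify). Second, because the
  deviations are signed, they largely cancel for symmetric pitch noise
  and the statistic concentrates near 0 with group differences carried
  by its dispersion; an absolute-deviation variant would measure the
  same concept on a strictly positive scale but is not part of the
  definition implemented here. Jitter is invariant under rescaling all
  pitches by a positive constant, and zero for constant pitch; a window
  summing to zero raises an error (impossible for speech frames, whose
  pitch is positive by construction).
* **PR** has two normalizations: by the mean pitch (default) and by the
  minimum pitch (`mode="min"`), both reported.

## Textual features

All text operations work at the lemma level, on annotated transcripts
(CoNLL-U) — the package never runs a tagger or parser. Content words
are NOUN, VERB, ADJ, ADV. Tokens without an embedding are dropped
before windowing (logged per response), since a plain lookup table,
unlike subword-capable embeddings, can miss.

**Derailment(k)**: for each content word i, the mean cosine similarity
to its following content words j = i+1 … min(i+k, n); the response
score is the mean over words with at least one follower (the final word
contributes nothing; tail windows shrink rather than pad). Scores for
k = 1..6 are separate features.

**Incoherence**: noun–adjective pairs are tokens linked by the `amod`
relation whose head is a NOUN. The reference profile maps each noun
lemma to the document frequencies of its modifying adjective lemmas in
an external corpus (each document counts a distinct pair once). Per
response pair, the profile's adjectives for that noun are aggregated as
a weighted element-wise mean of their embedding vectors with weights
idf(a) = ln(N / df(a)), renormalized to sum to 1 so the aggregate is a
convex combination; the pair scores the cosine between the response
adjective's vector and this aggregate, and the response score is the
mean over scoreable pairs. Unique adjective *types* (lemmas) are
weighted, not token instances. Two degenerate cases are defined
explicitly: a noun absent from the profile skips the pair (counted in a
coverage diagnostic), and if every profile adjective for a noun has
df = N (all idf weights 0), the weights fall back to uniform so the
aggregate — and the score — remain defined.

## Cohort assembly and statistics

Responses with < 10 s of speech are dropped, then participants with
< 500 surface tokens across their interview are excluded with all their
responses (the two filters commute; a test checks this). Group
comparisons use Welch's unequal-variance two-sided t-test — group SDs
differ visibly, and Welch is the safe default — with the convention
t > 0 meaning control mean > patient mean. Both analysis levels are
exposed: `level="response"` tests response-level values;
`level="participant"` first aggregates each participant's retained
responses by the unweighted mean. (The two levels answer different
questions, and published tables of this kind are often a mixture of the
two; exposing both makes either reproducible.) A Shapiro–Wilk report
per feature and group is provided as an advisory diagnostic only; it
gates nothing. Feature correlations are pairwise-complete Pearson with
a minimum of 3 paired observations; constant features yield NaN
entries.

## Classification protocol

Each response is an instance labelled by its participant's group; the
patient label is the positive class. The protocol runs E evaluations
(default 5), each a stratified N-fold (default 5) cross-validation with
its own seed; the same seed list is shared across classifier families
and feature sets, so fold assignments are identical everywhere (fold
assignment depends only on the labels, the seed and the fold count).
Folds are stratified at the response level — responses of one
participant may land in different folds, matching the apparent original
protocol; `group_folds=True` switches to speaker-disjoint stratified
group folds for honest generalization estimates.

Within each fold: NaN cells are imputed with training-fold column means
(applied to both partitions — no test-fold leakage); the linear SVM
additionally standardizes features with training-fold statistics; tree
models consume raw features. Classifier hyperparameters are library
defaults (XGBoost, scikit-learn random forest, LinearSVC) — no
hyperparameters are tuned. Fold predictions are pooled per evaluation
before computing metrics (accuracy, patient precision/recall/F1, percent
scale); a `pool_folds=False` option averages per-fold metrics instead.
Reported mean (SD) are across the E evaluation-level values. A zero
denominator in precision or recall yields 0 with a warning, keeping
aggregation total. The ablation study reruns the identical protocol 16
times on the combined set, removing one feature at a time.

## Clinical statistics

**Regressions.** Each participant-aggregated feature is regressed on
age, years of education and a group indicator, all z-scored (including
the binary indicator, so the group coefficient is a standardized beta;
raw-scale coefficients are reported alongside — the t statistics are
identical under any affine rescaling, which a test verifies). Requires
≥ 10 complete records and a full-rank design; collinear predictors
raise a named error.

**Cluster–symptom mutual information.** Patients only. Features are
z-scored (population SD; constant features pass through unscaled), then
k-means with k ∈ {2, 3, 8} runs from fresh random centroids (one
initialization per run, no restarts — the 50 outer runs provide the
spread). The association with the PANSS-6 total (0–36, integer) uses
the plug-in (maximum-likelihood) mutual information of the discrete
joint distribution, in natural log (nats). Plug-in MI on 23 patients is
biased upward and grows with k; that is a property of the estimator and
the reported mean (SD) over runs should be read with it in mind.

## The synthetic cohort generator

The generator emulates the *measured structure* of interview speech,
not its physics: no waveforms, no phonetics, no Hebrew morphology
(tokens are abstract strings — the pipeline is language-agnostic once
annotations exist), no intensity modelling.

Defaults mirror the study conditions: 25 controls and 23 patients, 18
responses each, male-band pitch. Acoustically, each response draws
latent parameters from between-response distributions — mean gap
duration, utterance excess, sub-threshold-run probability, mean pitch,
within-response pitch SD, and an AR(1) coefficient — then alternates
speech runs and lognormal gaps until a target amount of speech is
reached. Speech runs are a mixture of sub-threshold bursts (uniform
below 500 ms) and utterance runs of 500 ms plus an exponential excess;
speech-frame pitch follows the AR(1) process around the response's mean,
truncated to the interior of the band so generated speech classifies as
speech.

The group defaults were calibrated analytically, once, to the published
response-level group profile: writing m_u, m_sub, m_g for the mean
utterance run, sub-run and gap durations and q for the sub-run
probability, the four duration-feature means satisfy MUD = m_u,
MGD = m_g, MSRS = m_s/(m_s+m_g) with m_s = (1−q)·m_u + q·m_sub, and
MSR = MSRS · (1−q)m_u/m_s; solving these against the published means
gives the per-group mixtures. Two corrections were applied on top of
the algebra. First, heterogeneous gap means make E[m_s/(m_s+g)] exceed
m_s/(m_s+E[g]) (Jensen), so the patient mixture was re-solved
numerically under the gap distribution. Second, the published patient
MUD (0.470 s) lies *below* the 500 ms utterance floor and is therefore
unattainable under the utterance definition (it is consistent with
zero-utterance responses having been counted as 0 rather than excluded);
the generator targets ≈ 0.51 s, inside a ±20% band of the published
value, and consequently compresses the patient MUD spread relative to
the published SD. AR(1) coefficients are set to the published lag-1
pitch correlations (0.581 / 0.483) with the published between-response
spread. Because the generator's jitter noise is symmetric, the signed
jitter statistic centres on 0 for both groups (see the jitter note
above); the generator does not attempt to reproduce the published J
magnitudes.

Text: embeddings are unit vectors composed of a shared anisotropy
component (magnitude c = 0.5 — real static-embedding spaces have a
positive baseline cosine), a topic-cluster component (s = 0.8) and a
word-specific component (n = 1.55), giving expected cosines
c²/(c²+s²+n²) ≈ 0.07 across topics, (c²+s²)/(c²+s²+n²) ≈ 0.26 within a
topic, and √((c²+s²)/(c²+s²+n²)) ≈ 0.52 between a typical adjective and
its noun's aggregated profile vector — the observed magnitudes of the
derailment and incoherence scales. A response is a topic-respecting
random walk switching topics with probability 0.05 (control) / 0.12
(patient); noun tokens take an `amod` adjective with probability 0.35,
drawn from a foreign topic at rate 0.05 / 0.25. A 40-document reference
corpus of typical pairs is generated alongside and digested into the
profile.

Metadata: ages, education years and patient PANSS-6 totals are clipped
normals matching the published demographic means/SDs.

All randomness flows from one seed through spawned generator streams;
identical spec + seed reproduces the cohort bit-for-bit.

**What passing tests on synthetic cohorts do and do not show.** They
show the estimators recover programmed effects at realistic effect
sizes, that the protocol is leakage-free and seed-deterministic, and
that null cohorts produce chance-level classification and nominal
false-positive rates. They do not show performance on real speech:
synthetic responses are conditionally independent given the group —
there are no participant-level random effects — so response-level and
speaker-disjoint cross-validation coincide here, whereas on real data
speaker effects make response-level CV optimistic (use
`group_folds=True` there). Real pitch trackers also produce artefacts
(octave errors, creak) that the AR(1) model does not emulate.

## Problem sizes

The test suite exercises small cohorts (6–12 participants per group,
4–6 responses) for speed, and the default 25/23 × 18 cohort where the
study-scale behaviour matters: generator calibration, effect-detection
power (12 replicate cohorts), and the classification ordering checks.
`scripts/acceptance.py` runs one full default cohort end to end (about
half a minute on one CPU).

## Known limitations

* The pipeline starts at frame tables; pitch extraction from WAV is out
  of scope (an external Praat step produces the inputs).
* The jitter statistic, as defined, is signed (see above); comparisons
  with absolute-deviation jitter variants used elsewhere in speech
  science require the caveat.
* Plug-in MI over 23 patients is strongly positively biased, increasing
  in k; values are comparable across feature sets at fixed k, not
  across k.
* The supplementary-style reader maps common column aliases but cannot
  anticipate every layout; unknown columns are warned about and
  ignored.
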