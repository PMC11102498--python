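# szspeech

Prosodic and semantic speech biomarkers for schizophrenia, as a tested,
end-to-end pipeline.

Disorganized speech is a core symptom of schizophrenia: patients pause
more, speak in shorter stretches, drift between topics (derailment) and
use atypical word combinations (incoherence). `szspeech` implements a
response-level analysis of interview speech that quantifies these
phenomena from two modalities and asks how well each separates patients
from controls:

* **Acoustic prosody** — from 10-ms pitch-frame tables (e.g. Praat
  `Sound: To Pitch` exports), nine features per response.
* **Semantics** — from dependency-annotated transcripts (CoNLL-U) plus a
  static word-embedding table, seven features per response.

The package is aimed at computational-psychiatry and speech-lab
researchers who have per-response frame tables and annotated
transcripts, and at anyone who wants to study the method itself: a
synthetic cohort generator produces frame sequences, transcripts,
embeddings, reference profiles and participant metadata with
controllable group effects, so every stage runs and is testable without
any clinical data.

## The features

A frame is **speech** when its fundamental frequency F0 satisfies
75 Hz < F0 < 250 Hz; an **utterance** is a maximal run of ≥ 50
consecutive speech frames (500 ms); a **gap** is a maximal run with no
speech. Per response:

| Feature | Definition |
|---|---|
| MUD | mean utterance duration (s) |
| MGD | mean gap duration (s) |
| MSR | total utterance time / total response time |
| MSRS | speech frames / total frames |
| MP | mean pitch of speech frames (Hz) |
| PR | (max − min) speech pitch, normalized by MP |
| PS | SD of speech-frame pitch (Hz) |
| FPC | lag-1 Pearson autocorrelation of the speech-pitch sequence |
| J | jitter — local deviation of pitch from stationarity |

With R speech frames of pitch p(v) and locality parameter K (default 5):

```
J = 1/(R−K) · Σ_{v=(K−1)/2}^{R−(K−1)/2−1}  [ p(v) − (1/K)·Σ_k p(v+k) ] / [ Σ_k p(v+k) ]
```

where k runs over the K-frame window centred on v.

**Derailment** (k = 1..6): for each content word (noun/verb/adjective/
adverb), the mean cosine similarity between its embedding and those of
its k following content words, averaged over the response — lower means
faster topical drift. **Incoherence**: for each noun–adjective pair
(`amod` dependency), the cosine between the response adjective's
embedding and the idf-weighted mean embedding of the adjectives that
modify the same noun in a reference corpus — lower means more atypical
adjective use.

Downstream, responses with under 10 s of speech and participants with
under 500 transcribed words are excluded; the retained response × 16
feature table feeds Welch group t-tests, a feature-correlation matrix,
a 5-seed × 5-fold stratified cross-validated classification protocol
(gradient-boosted trees, random forest, linear SVM; patient-label F1),
a leave-one-feature-out ablation, participant-level regressions on age,
education and group, and a k-means / mutual-information analysis
against PANSS-6 symptom totals.

## Worked example

```python
from szspeech import (CohortSpec, generate_cohort, filter_responses,
                      group_ttests, run_cv, EvaluationProtocol)
from szspeech.pipeline import (extract_prosodic_features,
                               extract_text_features, assemble_feature_table)

cohort = generate_cohort(CohortSpec(), seed=7)     # 25 controls, 23 patients
prosodic, seconds = extract_prosodic_features(cohort.frame_sequences)
textual, words = extract_text_features(cohort.responses,
                                       cohort.embeddings, cohort.profile)
groups = {r.participant_id: r.group for r in cohort.metadata}
table = filter_responses(assemble_feature_table(prosodic, textual, groups),
                         seconds)
print("retained:", table.group_counts())

stats = group_ttests(table, "acoustic", level="response").table
print(stats.loc[["MUD", "MGD", "MSR", "MSRS"],
                ["control_mean", "patient_mean", "t", "p"]].round(3))

res = run_cv(table, EvaluationProtocol(seeds=(0, 1, 2, 3, 4),
                                       classifier="xgb",
                                       feature_set="acoustic"))
print(f"acoustic XGBoost: accuracy {res.mean('accuracy'):.1f}"
      f" ({res.sd('accuracy'):.1f}), patient F1 {res.mean('f1'):.1f}"
      f" ({res.sd('f1'):.1f})")
```

Output:

```
retained: {'control': 448, 'patient': 407}
      control_mean  patient_mean       t    p
MUD          0.552         0.506   5.631  0.0
MGD          0.238         0.962 -13.001  0.0
MSR          0.445         0.214  27.826  0.0
MSRS         0.565         0.307  25.594  0.0
acoustic XGBoost: accuracy 91.2 (0.5), patient F1 90.6 (0.6)
```

Reading: after the 10-s speech filter, 448 control and 407 patient
responses remain. Controls speak in longer utterances (0.552 vs
0.506 s) with far shorter pauses (0.238 vs 0.962 s), and spend twice
the fraction of the response in substantive speech (MSR 0.445 vs
0.214) — all strongly significant. The nine prosodic features alone
separate the groups at ~91% cross-validated accuracy.

## Command line

```bash
szspeech simulate   --out data/ --seed 1           # write a synthetic cohort
szspeech run-all    --data-dir data/ --out out/    # full pipeline + manifest
szspeech stats      --table out/feature_table.csv --features acoustic
szspeech classify   --table out/feature_table.csv --features combined --model xgb
szspeech ablate     --table out/feature_table.csv --plot ablation.png
szspeech regress    --table ... --metadata data/metadata.csv --feature MUD
szspeech cluster-mi --table ... --metadata data/metadata.csv --k 2,3,8
```

`classify`/`stats`/`ablate` accept any per-response feature table in a
tolerant column layout (aliases such as "Derailment 1" or "Jitter" are
mapped to the canonical names), so an externally supplied feature table
can be analyzed directly.

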