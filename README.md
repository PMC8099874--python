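# tremordx

Two-stage differential classification of Parkinsonian (PD) vs essential
tremor (ET) from 3-axis hand accelerometry, with saliency-based
explainability and a synthetic tremor cohort generator.

The pipeline:

1. **Preprocessing** — each 20 s single-axis recording is downsampled to
   100 Hz (anti-aliased, zero-phase), demeaned, and turned into a 129 x 191
   spectrotemporal power grid (Hamming window of 100 samples, 90-sample
   overlap, 256-point FFT; frequency of bin *k* is *k* · 100/256 Hz).
2. **Stage 1** — a small CNN (2 conv + 3 dense layers, implemented in pure
   numpy with Adam and softmax cross-entropy) votes PD/ET per signal. A
   6-bit one-hot *task hint* (Rest-1/2, Posture-1/2, Load-1/2; the
   finger-to-nose task is excluded) is concatenated into the second dense
   layer.
3. **Stage 2** — the 54 votes of one *tremor assessment*
   (6 tasks x 3 trials x 3 axes for one patient-visit-hand) form a feature
   vector classified by a QDA likelihood ratio (or a diagonal naive-Bayes
   variant); patients are fused by a logical AND over their assessments.
4. **Evaluation** — strictly patient-wise splits, Monte-Carlo repeats over
   test fractions, ROC/AUC, first-visit-only scoring, and wrapper
   single-feature ranking.
5. **Explainability** — gradient-weighted class-activation maps per signal,
   aggregated into a population pixel-wise two-sample z grid with
   normal-CDF significance masks (alpha = 0.02), plus an advisory
   per-pixel normality gate.

The clinical dataset behind the original study is private, so the
`synthetic` module generates labeled cohorts with the statistical structure
the classifier assumes (class-specific tremor bands, pseudo-rhythmic
frequency random walks, task-amplitude profiles, laterality, visits); all
tests and the acceptance report run on synthetic data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (spectrogram
geometry, cohort bookkeeping, oracle equivalences, synthetic label
recovery, explainability direction, leakage audit); the heavy fixtures are
session-scoped so the suite stays desk-scale.

## CLI

```sh
tremordx simulate --out cohort/ --n-pd 8 --n-et 8 --separation easy --seed 0
tremordx train --manifest cohort/manifest.csv --config config.yaml --seed 0 --out model/
tremordx predict --manifest cohort/manifest.csv --model model/ --out decisions.csv
tremordx evaluate --manifest cohort/manifest.csv --test-fraction 0.25 --repeats 30 --out report.csv
tremordx rank-features --manifest cohort/manifest.csv --model model/ --out ranking.csv
tremordx explain --manifest cohort/manifest.csv --model model/ --out explain.npz --plot
```

Configuration is YAML mirroring `tremordx.config.PipelineConfig`; defaults
are the reference settings (learning rate 1e-4, 44 epochs, leaky-ReLU 0.1,
QDA + probabilistic features, 30 Monte-Carlo repeats, alpha 0.02). A config
hash and the master seed are stamped into every artifact; one master seed
reproduces every output bit-identically.

Cohorts on disk are a `manifest.csv`
(`patient_id,group,visit,hand,task,trial,axis,fs,file_path`) plus one
plain-text signal file per recording (one sample per line).

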