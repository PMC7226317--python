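# surprisalx

Surprisal analysis of bulk transcriptomes: decompose log-expression into a
balanced steady state plus "unbalanced processes", decide how many processes
are real, and reduce every sample to a ternary transcriptional signature
("barcode") that can be catalogued and compared across a cohort.

## The problem

Cohorts of expression profiles — for example postmortem brain samples from
demented and non-demented subjects — are molecularly heterogeneous: samples
with similar levels of a classical biomarker can differ completely in *which*
coordinated transcriptional deviations produced those levels.  Surprisal
analysis addresses this by modelling each sample's transcriptome as a common
homeostatic steady state perturbed by a small number of constraints, each of
which drags a subset of transcripts away from balance in a coordinated way.

## The model

For transcript *i* in sample *k* with measured expression X<sub>i</sub>(k):

```
ln X_i(k) = ln X_i^0(k) − Σ_{α≥1} G_iα λ_α(k)
```

* **ln X<sub>i</sub><sup>0</sup>(k) = −G<sub>i0</sub>·λ<sub>0</sub>(k)** — the
  steady state (component α = 0).  Its amplitude λ<sub>0</sub>(k) should be
  near-invariant across samples; the package reports its coefficient of
  variation as a health check.
* **G<sub>iα</sub>** — weight of transcript *i* in unbalanced process α
  (independent of the sample); sign encodes correlation vs anti-correlation
  inside the process, |G<sub>iα</sub>| above a cutoff (default 0.01) defines
  process membership.
* **λ<sub>α</sub>(k)** — amplitude of process α in sample *k*; |λ| above a
  noise-derived threshold means the process is active in that sample.
* **G<sub>iα</sub>·λ<sub>α</sub>(k)** — contribution of process α to the
  deviation of transcript *i* in sample *k* (reported both as the raw model
  term and as the deviation of ln X, where positive = upregulation).

Both parameter sets come from the SVD of the log-expression matrix, with a
deterministic sign convention so runs are reproducible.  The number of
significant processes *n* is chosen by two criteria: amplitudes must exceed a
Monte-Carlo noise threshold derived from the 100 most stable transcripts
(contiguously from α = 1), and the per-sample R² of the reconstruction must
plateau once the *n* processes are included.  Each sample's amplitudes over
the significant processes are then discretised to digits in {−1, 0, +1}
(strict threshold, default 24 in fixed mode), giving its barcode; unique
barcodes are catalogued with per-pathology-group counts, specificity classes
(AD-only / normal-only / mixed / null), rarity flags, per-region enrichment
ratios and per-subject heterogeneity summaries.

A fully parameterised synthetic-data generator plants a known factor
structure (exactly orthonormal weights, exactly orthogonal amplitude rows,
0–3 active processes per sample, Gaussian log-scale noise) so that every
stage of the pipeline is testable without any download.

## Worked example

```python
import surprisalx as sx

truth = sx.generate_truth(n_transcripts=2000, n_samples=300, K=7, seed=42)
sim = sx.simulate_dataset(truth, noise_sd=0.2, seed=43)

logx = sx.log_transform(sim.dataset)
dec = sx.decompose(logx)

steady = sx.steady_state_summary(dec)
print(f"steady-state CV: {steady.cv:.4f}  invariant: {steady.invariant}")

baseline = sx.stable_transcripts(logx, m=100)
thr = sx.amplitude_thresholds(dec, baseline, replicates=100, seed=0)
n = sx.count_significant(dec, thr)
print(f"noise sigma: {baseline.summary_sigma:.4f}  "
      f"threshold: {thr.thresholds[0]:.2f}  significant processes: {n}")

barcodes = sx.barcode_table(dec, n, thr)
catalog = sx.build_catalog(barcodes, sim.dataset.samples)
t = catalog.table
print(f"unique barcodes: {len(t)}  null carriers: {t.loc[1, 'n_total']}")
print(f"AD-only: {(t.specificity == 'AD-only').sum()}  rare: {t.rare.sum()}")
```

prints

```
steady-state CV: 0.0102  invariant: True
noise sigma: 0.1908  threshold: 2.83  significant processes: 7
unique barcodes: 55  null carriers: 108
AD-only: 41  rare: 33
```

Reading the output: the steady state is invariant (CV ≈ the generator's 1%
jitter); the noise level estimated from the most stable transcripts gives an
amplitude threshold of 2.83, above which exactly the 7 planted processes
survive; discretising the 300 samples' amplitudes yields 55 distinct
barcodes, 108 samples carry the null barcode (no active process), 41 barcodes
occur only in AD-labelled samples and 33 of those in at most two of them.

The same pipeline runs from the shell on TSV inputs:

```bash
surprisalx simulate --transcripts 2000 --samples 300 --k 7 --noise-sd 0.2 \
    --seed 7 --out sim/
surprisalx run --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --threshold-mode monte_carlo --out run/
surprisalx validate --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --modes subjects,half_samples --n 7 --seed 17
```

Real data enter through `read_expression` (transcripts × samples, positive
intensities) and `read_metadata` (sample, subject, brain region, pathology);
see `docs/methods.md` for the input contracts and all tunable parameters.

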