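# Methods

## Model and decomposition

The package models a transcripts × samples matrix of positive expression
intensities as

    ln X_i(k) = ln X_i^0(k) − Σ_{α≥1} G_iα λ_α(k),      ln X_i^0(k) = −G_i0 λ_0(k)

so that in matrix form `lnX = −G Λ`.  `G` (transcripts × components) has
orthonormal columns; `Λ` (components × samples) carries the per-sample
amplitudes.  Both are obtained from the dense SVD of `lnX`: with
`lnX = U S Vᵀ`, we set `G = U` and `Λ = −S Vᵀ`, so components are ordered by
decreasing singular value and component 0 — which absorbs the large common
term of log-expression — is the steady state.  The assumptions are those of
the decomposition itself: deviations from balance are low-rank (few
processes explain the cohort), process weights are sample-independent, and
measurement noise is approximately i.i.d. Gaussian on the natural-log scale.

SVD leaves a sign per component undefined.  The convention used everywhere:
component 0 is flipped so λ₀(k) ≥ 0 for a majority of samples (exact tie:
sample 1 positive); for α ≥ 1 the G entry of largest magnitude is made
positive.  This makes repeated runs bit-identical and lets independent runs
be compared directly.  Exactly tied singular values would make the
decomposition of the tied subspace non-unique; ties are left in SVD output
order and no attempt is made to resolve them.

Because the model carries a minus sign, the raw product `G_iα·λ_α(k)` is the
*negative* of that process's contribution to ln X.  Reporting functions
(`expression_deviation`, `attribute_deviation`) therefore return both
columns, labelled `product` (the raw model term) and `deviation` (its
negative, the change of ln X with positive = upregulation), so either
convention can be read off without re-deriving signs.

## Steady-state check

`steady_state_summary` reports λ₀(k) and its coefficient of variation across
samples.  The decomposition's premise is that the balanced state is shared by
the whole cohort; the summary flags "invariant" when CV < 0.05 (configurable).
A sample whose overall intensity scale is off (e.g. a normalisation failure)
shows up directly as a λ₀ outlier.

## Number of significant processes

**Noise baseline.**  The m = 100 transcripts with the smallest population SD
of log-expression across samples (ties by input order) define baseline
fluctuation; their mean SD is the representative noise level σ̂.  Because
taking the *smallest* m of N sample SDs biases the estimate low under
homoscedastic noise, σ̂ is divided by a selection-bias factor — the expected
value of that same statistic under i.i.d. Gaussian noise, estimated from
chi-square order statistics with a fixed internal seed.  The correction is
exact for homoscedastic noise and mildly conservative when the stable
transcripts are genuinely quieter than the rest; it can be disabled
(`bias_correction=False`).

**Amplitude thresholds.**  `amplitude_thresholds` builds a Monte-Carlo null:
each replicate draws an i.i.d. Gaussian(σ̂) matrix of the data's shape,
decomposes it the same way the data are decomposed, and records the largest
per-sample amplitude of its leading noise component.  The threshold is the
97.5th percentile (configurable) of that maximum over replicates (default
100), applied to every process — a parallel-analysis style null.  The
rationale for decomposing the null matrices rather than projecting noise
onto the data's weight vectors: amplitudes of the data's own components are
maxima of an *adaptive* fit, whose leading values concentrate near
σ̂(√n + √m) rather than at the σ̂ scale of a fixed projection, so only a null
that goes through the same SVD is comparable.  A per-component mode
(rank-matched null thresholds) and a fixed-threshold mode (a single constant,
default 24, the operational value used for barcoding when amplitudes are on
the original cohort scale) are also provided.  Thresholds scale linearly
with σ̂ by construction.

**Counting.**  `count_significant` counts contiguously from α = 1: a process
is significant when at least one sample's |λ_α(k)| exceeds its threshold, and
the first insignificant process terminates the count.  With the global
threshold this is calibrated: on structure-free data the count is 0 with
probability ≈ the percentile (measured ≥ 95% of 100 seeds), and planted
processes well above threshold are counted exactly.

**R² cross-check.**  `r2_curve` computes, per sample, 1 − SS_res/SS_tot of
the reconstruction with the steady state plus processes 1..n.  Each added
component reduces that sample's SS_res by exactly λ_α(k)², so the curve is
non-decreasing and reaches 1 with all components.  `plateau_n` returns the
smallest n after which every supplied curve's gains stay below ε (default
0.01); all supplied samples must plateau, and a curve still improving at the
end of the range is reported with a warning rather than silently truncated.

## Barcodes and catalog

Amplitudes of the significant processes are discretised per sample:
digit = +1 if λ_α(k) > T_α, −1 if λ_α(k) < −T_α, else 0.  The inequalities
are strict — an amplitude exactly at the threshold is inactive — because the
three-case rule is defined on open intervals and the conservative reading
assigns the boundary to "no call".  Thresholds may be the constant 24 or the
per-process `ThresholdSet` from the significance stage.

The catalog indexes unique barcodes: the all-zero (null) barcode is #1 when
present, the rest follow by descending carrier count with lexicographic
digit order breaking ties; when no sample carries the null barcode the
indices simply start at 1 by count.  Specificity: a barcode carried only by
possible/probable/definite samples is "AD-only", only by non-demented
samples "normal-only", otherwise "mixed"; the null barcode is classed "null"
regardless of carriers.  "Rare" means AD-only with at most two AD carriers —
rarity qualifies disease-specific signatures, so a normal-only barcode with
zero AD carriers is not flagged.  Region enrichment reports, per region, the
AD : non-demented carrier ratio of every barcode covering at least 10%
(configurable) of that region's AD or non-demented samples; a zero
non-demented denominator is reported as "AD-exclusive in region" rather than
as a number.  Per-subject summaries give the distinct barcodes of each
subject's samples and the union of processes active in any of them.
Group-wise barcode frequencies are relative to group size; an empty group is
NaN (undefined), never 0.

## Robustness validation

`validation_report` re-decomposes four kinds of subsets — all samples of a
random half of the subjects, a random half of the samples, a random half of
the transcripts, and the AD-only samples — and matches processes 1..n
against the full-data run.  Matching is an optimal one-to-one assignment
(Hungarian algorithm) on the n × n table of |Pearson r| between G columns
over the shared transcripts (λ rows over shared samples when no transcripts
are shared); Spearman is available as an option.  Signs are aligned so
matched correlations are positive, mirroring the convention that an
anti-correlated amplitude is the same process.  Matching A→B and inverting
equals matching B→A on the same table.

## Synthetic data

`generate_truth`/`simulate_dataset` emulate the structure the analysis
assumes.  Defaults (2,000 transcripts × 300 samples, K = 7) run in seconds.

* **Steady state** — per-transcript baseline log levels drawn N(5.5, 1.0)
  (clipped at 0.5): intensities around e^5.5 ≈ 250 spanning roughly a
  decade, as in quantified array data.  The steady amplitude has 1% Gaussian
  jitter across samples, so the planted steady state is invariant at the
  default CV limit.
* **Processes** — K sparse weight columns (5% support, disjoint supports,
  entries projected orthogonal to the steady column within each support), so
  the planted `G*` is exactly orthonormal.
* **Activity** — samples are grouped in blocks of 4 (8 if more than 3
  processes may be co-active); each block draws an active set, and the
  processes active in a block take distinct zero-sum Hadamard sign rows
  across the block's samples.  Rows of `Λ*` are then exactly pairwise
  orthogonal while keeping a clean 0/±A activity pattern, and the steady row
  is orthogonalised against them (a relative correction of order 1e-4).
  With exact orthogonality on both sides, the SVD of the noiseless matrix
  *is* the planted structure, which is what makes the zero-noise recovery
  tests exact rather than approximate.
* **Prevalence and amplitude ladders** — a scalar activation probability
  (default mean 0.12) is spread geometrically over processes
  (`prevalence_decay = 0.78`), emulating cohorts where a few processes are
  common and the rest rare, and per-process amplitudes decrease geometrically
  (`amplitude_spacing = 0.08`, leading amplitude default 120).  Both ladders
  keep the planted singular values separated; without them two processes
  active in equally many samples would have exactly tied singular values and
  be unrecoverable in principle.  Adjacent-strength processes are not
  co-activated in the same block, because their residual overlap after
  random sample subsetting is what mixes nearly-tied components in
  split-half reruns.  Active counts per process are fixed
  (round(p_α · blocks)) rather than binomial for the same reason.
* **Noise** — i.i.d. Gaussian on the log scale (the scale the model lives
  on); no count-model or probe-level artefacts.  Expression is
  `exp(−G*Λ* + ε)`.
* **Metadata** — consecutive samples share a subject (9 per subject),
  regions cycle through the 17-region vocabulary within a subject, subjects
  cycle through pathology groups with every 5th subject non-demented
  (≈ 20% control samples).  Assignments are deterministic so subject-,
  region- and group-level operations are exercisable.

What passing tests on this generator do *not* show: robustness to
heteroscedastic or correlated noise, probe/batch effects, non-log-linear
saturation, or real biological overlap between process memberships beyond
the planted sparsity pattern.  The generator is a fidelity check of the
*pipeline*, not of the biology.

## Problem sizes and numerical choices

Recovery and noiseless-identifiability checks run at 2,000 × 300 (K = 7);
robustness reruns at 2,000 × 600 so that even the rarest planted process
keeps enough carriers in every half; calibration of the significance count
runs 100 seeds at 500 × 120 with 60 null replicates.  Orthonormality and
full-reconstruction invariants are enforced at 1e-8 (measured ≈ 1e-14);
noiseless matched correlations at 1 − 1e-6.  Degenerate inputs: an
all-columns-identical matrix decomposes to a pure steady state (zero process
amplitudes, not an error); zero noise SD produces zero thresholds; a zero
singular-value tie keeps SVD output order.  Pearson correlation against a
zero-variance vector is defined as 0 in matching.

## Known limitations

* The amplitude-threshold null assumes exchangeable Gaussian noise; strong
  heteroscedasticity across transcripts will misestimate σ̂ (conservative
  direction when the stable transcripts are genuinely the quietest).
* The contiguous counting rule cannot detect a significant process hiding
  behind an insignificant one of larger rank.
* Barcode indices are stable only within a cohort; comparing catalogs across
  cohorts requires matching processes first (`match_processes`).
* With fewer than ~8 samples per planted process the subset reruns can lose
  a process entirely; the generator's prevalence floor is chosen to avoid
  this at the default sizes.
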