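"""Model-order selection: noise baseline, amplitude thresholds, R2 plateau.

How many unbalanced processes are real?  Two complementary criteria are
implemented:

1. *Amplitude criterion* - estimate the measurement-noise level from the most
   stable transcripts, derive a threshold for process amplitudes from a
   Monte-Carlo noise null, and count how many leading processes have at least
   one sample whose amplitude exceeds it (stopping at the first that does
   not).
2. *R2 plateau* - reconstruct each sample's log-expression with an increasing
   number of processes and find where adding further processes stops
   improving the fit.

The Monte-Carlo null draws i.i.d. Gaussian matrices at the estimated noise SD
and decomposes them exactly as the data are decomposed, so the threshold is
the upper percentile of the largest per-sample amplitude a pure-noise
component of this data shape can produce (a parallel-analysis style null).
A fixed threshold mode (default 24, the operational constant used for
barcoding) is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import SurprisalDecomposition, reconstruct


@dataclass
class NoiseBaseline:
    """The m most stable transcripts and the noise SD they imply."""

    stable_ids: pd.Index
    sds: pd.Series          # SD of log-expression for the selected transcripts
    summary_sigma: float    # representative noise SD (mean of the selected SDs)
    n_transcripts: int      # total transcripts the selection was drawn from
    n_samples: int


def stable_transcripts(logx: pd.DataFrame, m: int = 100) -> NoiseBaseline:
    """Select the ``m`` transcripts with the smallest SD of log-expression.

    SDs are population SDs across samples; ties are broken by input row
    order.  Their mean is the representative baseline-fluctuation sigma.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if m > logx.shape[0]:
        raise ValueError(f"m={m} exceeds the transcript count {logx.shape[0]}")
    sds = logx.std(axis=1, ddof=0)
    order = np.argsort(sds.to_numpy(), kind="stable")[:m]
    chosen = sds.iloc[order]
    return NoiseBaseline(
        stable_ids=chosen.index,
        sds=chosen,
        summary_sigma=float(chosen.mean()),
        n_transcripts=logx.shape[0],
        n_samples=logx.shape[1],
    )


@dataclass
class ThresholdSet:
    """Per-process amplitude thresholds T_alpha (alpha = 1..len(thresholds))."""

    thresholds: np.ndarray
    method: str                     # "monte_carlo" | "fixed"
    replicates: int | None = None
    percentile: float | None = None
    seed: int | None = None
    sigma: float | None = None      # noise SD the Monte-Carlo null used

    def threshold_for(self, alpha: int) -> float:
        if alpha < 1:
            raise ValueError("process indices start at 1")
        idx = min(alpha, len(self.thresholds)) - 1
        return float(self.thresholds[idx])

    @property
    def n_processes(self) -> int:
        return len(self.thresholds)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "method": self.method,
                "replicates": self.replicates,
                "percentile": self.percentile,
                "seed": self.seed,
            },
            index=pd.RangeIndex(1, len(self.thresholds) + 1, name="process"),
        )


def fixed_thresholds(n_processes: int, value: float = 24.0) -> ThresholdSet:
    """A constant amplitude threshold for every process (default 24)."""
    if value <= 0:
        raise ValueError("threshold value must be positive")
    return ThresholdSet(np.full(n_processes, float(value)), method="fixed")


def _selection_bias_factor(
    n_transcripts: int, m: int, n_samples: int, rng: np.random.Generator, n_rep: int = 40
) -> float:
    """Expected (mean of the m smallest of N sample SDs) / (true sigma).

    Selecting the most stable transcripts biases the SD estimate low under
    homoscedastic Gaussian noise; this factor, estimated from chi-square order
    statistics, removes that bias.
    """
    df = max(n_samples - 1, 1)
    sims = np.sqrt(rng.chisquare(df, size=(n_rep, n_transcripts)) / n_samples)
    part = np.partition(sims, m - 1, axis=1)[:, :m]
    return float(part.mean())


def amplitude_thresholds(
    dec: SurprisalDecomposition,
    baseline: NoiseBaseline,
    replicates: int = 100,
    percentile: float = 0.975,
    seed: int = 0,
    per_component: bool = False,
    bias_correction: bool = True,
) -> ThresholdSet:
    """Monte-Carlo amplitude thresholds from a pure-noise null.

    Each replicate draws an i.i.d. Gaussian matrix with SD ``sigma`` of the
    same shape as the log-expression matrix, decomposes it, and records the
    largest per-sample amplitude of each noise component.  The threshold is
    the requested percentile of the leading noise component's maximum
    (applied globally to every process); with ``per_component=True`` each
    process alpha is instead compared against the rank-matched noise
    component.  Deterministic for a fixed ``seed``.
    """
    if replicates < 10:
        raise ValueError("replicates must be at least 10")
    if not 0 < percentile < 1:
        raise ValueError("percentile must be a fraction in (0, 1)")
    n_t = len(dec.transcript_ids)
    n_s = len(dec.sample_ids)
    n_proc = dec.n_processes
    rng = np.random.default_rng(seed)

    sigma = baseline.summary_sigma
    if bias_correction and sigma > 0:
        factor = _selection_bias_factor(
            baseline.n_transcripts, len(baseline.stable_ids), baseline.n_samples, rng
        )
        sigma = sigma / factor

    if sigma == 0:
        return ThresholdSet(
            np.zeros(n_proc), "monte_carlo", replicates, percentile, seed, 0.0
        )

    n_rank = n_proc if per_component else 1
    maxima = np.empty((replicates, n_rank))
    for r in range(replicates):
        noise = rng.normal(0.0, sigma, size=(n_t, n_s))
        s, vt = np.linalg.svd(noise, full_matrices=False)[1:]
        amps = s[:n_rank, None] * vt[:n_rank]
        maxima[r] = np.abs(amps).max(axis=1)
    if per_component:
        # data component alpha is compared against the null's rank alpha-1
        # (under the global null, data component 1 is the top noise component)
        quant = np.quantile(maxima, percentile, axis=0)
        thresholds = quant[np.minimum(np.arange(n_proc), n_rank - 1)]
    else:
        thresholds = np.full(n_proc, np.quantile(maxima[:, 0], percentile))
    return ThresholdSet(thresholds, "monte_carlo", replicates, percentile, seed, sigma)


def count_significant(dec: SurprisalDecomposition, thresholds: ThresholdSet) -> int:
    """Number of significant unbalanced processes by the amplitude criterion.

    Counts contiguously from alpha = 1: the first process whose amplitudes
    never exceed its threshold in any sample terminates the count.
    """
    lam = dec.lam_values()
    n_max = min(dec.n_processes, thresholds.n_processes)
    n = 0
    for alpha in range(1, n_max + 1):
        if np.abs(lam[alpha]).max() > thresholds.threshold_for(alpha):
            n = alpha
        else:
            break
    return n


@dataclass
class R2Curve:
    """Goodness of reconstruction for one sample as processes are added.

    ``r2[n]`` is 1 - SS_res/SS_tot for the reconstruction using the steady
    state plus processes 1..n; it is non-decreasing in n and reaches 1 when
    all components are included.
    """

    sample_id: object
    r2: np.ndarray


def r2_curve(
    dec: SurprisalDecomposition, logx: pd.DataFrame, sample, n_max: int | None = None
) -> R2Curve:
    """R2 of reconstructed vs observed log-expression for one sample, n = 0..n_max."""
    if sample not in logx.columns:
        raise KeyError(f"unknown sample id {sample!r}")
    if n_max is None:
        n_max = dec.n_components - 1
    if not 0 <= n_max < dec.n_components:
        raise ValueError(f"n_max must be in [0, {dec.n_components - 1}]")
    col = logx[sample].to_numpy(dtype=float)
    ss_tot = float(((col - col.mean()) ** 2).sum())
    if ss_tot == 0:
        return R2Curve(sample, np.ones(n_max + 1))
    G = dec.g_values()
    lam_k = dec.lam[sample].to_numpy()
    resid = col.copy()
    r2 = np.empty(n_max + 1)
    for alpha in range(n_max + 1):
        resid = resid + G[:, alpha] * lam_k[alpha]
        r2[alpha] = 1.0 - float((resid**2).sum()) / ss_tot
    return R2Curve(sample, r2)


def plateau_n(curves, epsilon: float = 0.01) -> tuple[int, bool]:
    """Smallest n after which every curve's R2 gains stay below ``epsilon``.

    Returns ``(n_star, plateaued)``; when some curve is still improving at its
    last step, ``n_star`` is the largest n available and ``plateaued`` is
    False (a warning is emitted).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("at least one R2 curve is required")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n_star = 0
    plateaued = True
    for curve in curves:
        r2 = np.asarray(curve.r2 if isinstance(curve, R2Curve) else curve, dtype=float)
        gains = np.diff(r2)
        big = np.nonzero(gains >= epsilon)[0]
        n_c = int(big[-1]) + 1 if len(big) else 0
        if len(big) and big[-1] == len(gains) - 1:
            plateaued = False
        n_star = max(n_star, n_c)
    if not plateaued:
        warnings.warn("R2 curves did not plateau within the supplied range", stacklevel=2)
    return n_star, plateaued
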