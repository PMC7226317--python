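"""Surprisal decomposition of log-expression via singular value decomposition.

The model writes the natural log of each measured expression level as a
balanced steady-state term minus a sum of deviations contributed by
"unbalanced processes" (constraints):

    ln X_i(k) = ln X_i^0(k) - sum_{alpha>=1} G_{i,alpha} * lambda_alpha(k)

with the steady-state term itself expressed as -G_{i,0} * lambda_0(k), so the
full matrix identity is ``lnX = -G @ Lambda``.  ``G`` (transcripts x
components) has orthonormal columns and holds the per-transcript weights of
each process; ``Lambda`` (components x samples) holds the per-sample
amplitudes.  Both are obtained from the SVD of the log-expression matrix,
with components ordered by decreasing singular value (component 0 is the
steady state) and a deterministic sign convention:

* component 0 is flipped so that ``lambda_0(k) >= 0`` for a majority of
  samples (ties resolved by making sample 1 positive);
* for components alpha >= 1 the G entry of largest magnitude is made
  positive.

Because the raw product ``G_{i,alpha} * lambda_alpha(k)`` enters the model
with a minus sign, the *deviation of ln X* contributed by process alpha is
``-G_{i,alpha} * lambda_alpha(k)`` (positive = upregulation).  Reporting
functions return both values, labelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionDataset


def log_transform(dataset) -> pd.DataFrame:
    """Natural-log transform of an expression matrix (or ExpressionDataset).

    All values must be strictly positive; applying a pseudo-count belongs to
    the reader, not here.
    """
    expr = dataset.expression if isinstance(dataset, ExpressionDataset) else dataset
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values <= 0).any():
        raise ValueError("expression values must be strictly positive before log transform")
    return pd.DataFrame(np.log(values), index=expr.index, columns=expr.columns)


def _canonicalize_signs(G: np.ndarray, lam: np.ndarray) -> None:
    """Apply the deterministic sign convention in place (flips G column and
    matching Lambda row together, preserving the product)."""
    n_pos = int((lam[0] > 0).sum())
    n_neg = int((lam[0] < 0).sum())
    flip0 = n_neg > n_pos or (n_neg == n_pos and lam[0, 0] < 0)
    if flip0:
        G[:, 0] *= -1.0
        lam[0] *= -1.0
    for a in range(1, G.shape[1]):
        j = int(np.argmax(np.abs(G[:, a])))
        if G[j, a] < 0:
            G[:, a] *= -1.0
            lam[a] *= -1.0


class SurprisalAnalysis(TransformerMixin, BaseEstimator):
    """Scikit-learn style estimator for the surprisal decomposition.

    Follows the sklearn orientation convention: ``X`` is (n_samples,
    n_transcripts) and must already be on the natural-log scale.

    Parameters
    ----------
    n_components : int or None
        Number of components to retain (steady state included).  ``None``
        keeps all ``min(n_samples, n_transcripts)`` components.

    Attributes
    ----------
    weights_ : ndarray (n_transcripts, n_components)
        Transcript weights G, orthonormal columns; column 0 is the steady state.
    amplitudes_ : ndarray (n_components, n_samples)
        Per-sample amplitudes Lambda satisfying ``lnX.T == -(weights_ @ amplitudes_)``
        when all components are kept.
    singular_values_ : ndarray (n_components,)
        Decreasing singular values of the log-expression matrix.
    components_ : ndarray (n_components, n_transcripts)
        sklearn-style alias, ``weights_.T``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("X must be a 2-D matrix with at least 2 rows and 2 columns")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        lnx = X.T  # transcripts x samples
        try:
            U, s, Vt = np.linalg.svd(lnx, full_matrices=False)
        except np.linalg.LinAlgError as err:  # pragma: no cover - numerical edge
            raise RuntimeError(f"SVD did not converge: {err}") from err
        G = U
        lam = -(s[:, None] * Vt)
        _canonicalize_signs(G, lam)
        k = min(self.n_components or len(s), len(s))
        self.weights_ = G[:, :k]
        self.amplitudes_ = lam[:k]
        self.singular_values_ = s[:k]
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def components_(self):
        return self.weights_.T

    def transform(self, X):
        """Amplitude coordinates of (possibly new) samples: ``-X @ weights_``."""
        X = np.asarray(X, dtype=float)
        return -(X @ self.weights_)

    def inverse_transform(self, A):
        """Reconstruct log-expression from amplitude coordinates."""
        A = np.asarray(A, dtype=float)
        return -(A @ self.weights_.T)


class SurprisalDecomposition:
    """Domain wrapper over a fitted :class:`SurprisalAnalysis`.

    Holds G and Lambda as labelled DataFrames: ``G`` is transcripts x
    components (columns ``G0..Gn``), ``lam`` is components x samples.
    """

    def __init__(self, G: pd.DataFrame, lam: pd.DataFrame, singular_values: np.ndarray):
        self.G = G
        self.lam = lam
        self.singular_values = np.asarray(singular_values, dtype=float)

    @property
    def n_components(self) -> int:
        return self.G.shape[1]

    @property
    def n_processes(self) -> int:
        return self.n_components - 1

    @property
    def transcript_ids(self) -> pd.Index:
        return self.G.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.lam.columns

    def g_values(self) -> np.ndarray:
        return self.G.to_numpy()

    def lam_values(self) -> np.ndarray:
        return self.lam.to_numpy()

    @classmethod
    def from_arrays(cls, G, lam, singular_values, transcript_ids, sample_ids):
        G = pd.DataFrame(
            np.asarray(G, dtype=float),
            index=pd.Index(transcript_ids),
            columns=[f"G{a}" for a in range(np.asarray(G).shape[1])],
        )
        lam = pd.DataFrame(
            np.asarray(lam, dtype=float),
            index=pd.RangeIndex(np.asarray(lam).shape[0], name="component"),
            columns=pd.Index(sample_ids),
        )
        return cls(G, lam, singular_values)


def decompose(logx: pd.DataFrame) -> SurprisalDecomposition:
    """Full surprisal decomposition of a transcripts x samples log matrix."""
    est = SurprisalAnalysis().fit(logx.to_numpy().T)
    return SurprisalDecomposition.from_arrays(
        est.weights_, est.amplitudes_, est.singular_values_, logx.index, logx.columns
    )


def reconstruct(dec: SurprisalDecomposition, n: int) -> pd.DataFrame:
    """Log-expression reconstructed from the steady state plus processes 1..n.

    ``n`` counts unbalanced processes, so ``n = 0`` is the steady state alone
    and ``n = n_components - 1`` reproduces the input exactly.
    """
    if not 0 <= n < dec.n_components:
        raise ValueError(f"n must be in [0, {dec.n_components - 1}], got {n}")
    G = dec.g_values()[:, : n + 1]
    lam = dec.lam_values()[: n + 1]
    return pd.DataFrame(-(G @ lam), index=dec.transcript_ids, columns=dec.sample_ids)


class DeviationReport(NamedTuple):
    per_process: pd.DataFrame  # index alpha; columns product, deviation
    total_product: float
    total_deviation: float


def expression_deviation(
    dec: SurprisalDecomposition, transcript, sample, processes
) -> DeviationReport:
    """Per-process contribution of the requested processes to one cell.

    ``product`` is the raw model term ``G_{i,alpha} * lambda_alpha(k)``;
    ``deviation`` is the resulting change of ln X (its negative), with
    positive meaning upregulation.
    """
    if transcript not in dec.G.index:
        raise KeyError(f"unknown transcript id {transcript!r}")
    if sample not in dec.lam.columns:
        raise KeyError(f"unknown sample id {sample!r}")
    processes = sorted(int(a) for a in processes)
    for a in processes:
        if not 1 <= a < dec.n_components:
            raise ValueError(f"process index {a} out of range 1..{dec.n_components - 1}")
    g_row = dec.G.loc[transcript].to_numpy()
    lam_col = dec.lam[sample].to_numpy()
    prod = np.array([g_row[a] * lam_col[a] for a in processes])
    table = pd.DataFrame(
        {"product": prod, "deviation": -prod},
        index=pd.Index(processes, name="process"),
    )
    return DeviationReport(table, float(prod.sum()), float(-prod.sum()))


class SteadyStateSummary(NamedTuple):
    lambda0: pd.Series
    cv: float
    invariant: bool


def steady_state_summary(
    dec: SurprisalDecomposition, cv_limit: float = 0.05
) -> SteadyStateSummary:
    """Per-sample steady-state amplitude and its coefficient of variation.

    The steady state is expected to be invariant across samples; the summary
    flags it as such when CV(lambda_0) falls below ``cv_limit``.
    """
    lam0 = dec.lam.iloc[0]
    mean = float(lam0.mean())
    cv = float(lam0.std(ddof=0) / abs(mean)) if mean != 0 else float("inf")
    return SteadyStateSummary(lam0.copy(), cv, cv < cv_limit)
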