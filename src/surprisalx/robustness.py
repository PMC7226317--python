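"""Robustness validation: re-run the decomposition on data subsets and match
the recovered processes against the full-data run.

A process found in two independent runs is "the same" when its transcript
weights are highly correlated over the shared transcripts (sign flips are an
SVD ambiguity, so matching works on |Pearson r| and aligns signs afterwards).
The matching is an optimal one-to-one assignment on the n x n absolute
correlation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr

from .decomposition import SurprisalDecomposition, decompose, log_transform
from .io import AD_LEVELS, ExpressionDataset


def subset_subjects(
    dataset: ExpressionDataset, n_subjects: int, seed: int = 0
) -> ExpressionDataset:
    """Keep all samples of ``n_subjects`` randomly chosen subjects."""
    subjects = list(dict.fromkeys(dataset.samples["subject_id"]))
    if n_subjects <= 1:
        raise ValueError("n_subjects must be at least 2")
    if n_subjects > len(subjects):
        raise ValueError(f"n_subjects={n_subjects} exceeds subject count {len(subjects)}")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(subjects, size=n_subjects, replace=False))
    keep = [s for s in dataset.sample_ids if dataset.samples.loc[s, "subject_id"] in chosen]
    return dataset.subset_samples(keep)


def split_half(
    dataset: ExpressionDataset, axis: str = "samples", seed: int = 0
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Random disjoint halves along samples or transcripts (sizes differ by <= 1)."""
    rng = np.random.default_rng(seed)
    if axis == "samples":
        ids = list(dataset.sample_ids)
    elif axis == "transcripts":
        ids = list(dataset.transcript_ids)
    else:
        raise ValueError("axis must be 'samples' or 'transcripts'")
    if len(ids) < 4:
        raise ValueError(f"need at least 4 {axis} to split")
    perm = rng.permutation(len(ids))
    cut = (len(ids) + 1) // 2
    first = sorted(perm[:cut])
    second = sorted(perm[cut:])
    take = dataset.subset_samples if axis == "samples" else dataset.subset_transcripts
    return take([ids[i] for i in first]), take([ids[i] for i in second])


@dataclass
class ProcessMatch:
    """One-to-one matching of processes between two decompositions."""

    mapping: dict                 # process alpha in run A -> matched alpha in run B
    g_corr: pd.Series             # |corr| of G columns over shared transcripts
    lam_corr: pd.Series           # |corr| of lambda rows over shared samples (NaN if none)
    signs: pd.Series              # sign aligning B's component with A's
    matched_on: str = "G"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "matched_index": pd.Series(self.mapping),
                "g_corr": self.g_corr,
                "lam_corr": self.lam_corr,
                "sign": self.signs,
            }
        ).rename_axis("process")


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        r = spearmanr(x, y).statistic
        return float(r) if np.isfinite(r) else 0.0
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def match_processes(
    decA: SurprisalDecomposition,
    decB: SurprisalDecomposition,
    n: int,
    method: str = "pearson",
) -> ProcessMatch:
    """Match processes 1..n of two runs by maximal total |correlation|.

    Matching uses G columns over the shared transcripts when any exist,
    otherwise lambda rows over the shared samples.  Signs are aligned so the
    matched correlations are positive.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    n = min(n, decA.n_processes, decB.n_processes)
    shared_t = [t for t in decA.transcript_ids if t in set(decB.transcript_ids)]
    shared_s = [s for s in decA.sample_ids if s in set(decB.sample_ids)]
    if not shared_t and not shared_s:
        raise ValueError("runs share no transcripts and no samples; cannot match")

    if shared_t:
        A = decA.G.loc[shared_t].to_numpy()[:, 1 : n + 1]
        B = decB.G.loc[shared_t].to_numpy()[:, 1 : n + 1]
        matched_on = "G"
    else:
        A = decA.lam.loc[1:n, shared_s].to_numpy().T
        B = decB.lam.loc[1:n, shared_s].to_numpy().T
        matched_on = "lambda"
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = _corr(A[:, i], B[:, j], method)
    rows, cols = linear_sum_assignment(-np.abs(C))
    mapping = {int(i) + 1: int(j) + 1 for i, j in zip(rows, cols)}
    signs = {int(i) + 1: float(np.sign(C[i, j]) or 1.0) for i, j in zip(rows, cols)}

    proc_index = pd.RangeIndex(1, n + 1, name="process")
    g_corr = pd.Series(np.nan, index=proc_index)
    lam_corr = pd.Series(np.nan, index=proc_index)
    for a, b in mapping.items():
        if shared_t:
            g_corr.loc[a] = abs(
                _corr(
                    decA.G.loc[shared_t, f"G{a}"].to_numpy(),
                    decB.G.loc[shared_t, f"G{b}"].to_numpy(),
                    method,
                )
            )
        if shared_s:
            lam_corr.loc[a] = abs(
                _corr(
                    decA.lam.loc[a, shared_s].to_numpy(),
                    decB.lam.loc[b, shared_s].to_numpy(),
                    method,
                )
            )
    return ProcessMatch(mapping, g_corr, lam_corr, pd.Series(signs), matched_on)


VALIDATION_MODES = ("subjects", "half_samples", "half_transcripts", "AD_only")


def validation_report(
    dataset: ExpressionDataset,
    modes=VALIDATION_MODES,
    n: int = 7,
    seed: int = 0,
    subject_fraction: float = 0.5,
) -> pd.DataFrame:
    """Decompose subsets of the data and tabulate matched correlations.

    Modes: ``subjects`` (all samples of a random subject subset),
    ``half_samples`` / ``half_transcripts`` (one random half), and
    ``AD_only`` (pathology != non-demented).  Each subset's processes are
    matched against the full-data run.
    """
    full = decompose(log_transform(dataset))
    rows = []
    for mode in modes:
        if mode == "subjects":
            n_subj = len(set(dataset.samples["subject_id"]))
            sub = subset_subjects(dataset, max(2, round(subject_fraction * n_subj)), seed)
        elif mode == "half_samples":
            sub = split_half(dataset, "samples", seed)[0]
        elif mode == "half_transcripts":
            sub = split_half(dataset, "transcripts", seed)[0]
        elif mode == "AD_only":
            if "pathology" not in dataset.samples.columns:
                raise ValueError("mode 'AD_only' requires pathology labels")
            keep = [
                s for s in dataset.sample_ids
                if dataset.samples.loc[s, "pathology"] in AD_LEVELS
            ]
            if len(keep) < 2:
                raise ValueError("mode 'AD_only': fewer than 2 AD samples")
            sub = dataset.subset_samples(keep)
        else:
            raise ValueError(f"unsupported validation mode {mode!r}")
        match = match_processes(full, decompose(log_transform(sub)), n)
        frame = match.as_frame().reset_index()
        frame.insert(0, "mode", mode)
        frame["seed"] = seed
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
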