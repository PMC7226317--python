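"""Biomarker-level views: fold change, tail flags, process membership and
attribution of a transcript's deviation to the processes active in a sample."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .decomposition import SurprisalDecomposition
from .io import AD_LEVELS, PATHOLOGY_LEVELS


def fold_change_vs_median(logx: pd.DataFrame, gene) -> pd.Series:
    """Per-sample log fold change of one transcript vs its cohort median:
    ln X_i(k) - median_k ln X_i(.)."""
    if gene not in logx.index:
        raise KeyError(f"unknown gene id {gene!r}")
    row = logx.loc[gene]
    return row - row.median()


def process_membership(
    dec: SurprisalDecomposition, gene, cutoff: float = 0.01
) -> pd.Series:
    """Signed process membership of one transcript.

    For each process alpha >= 1: ``+1`` when G_{i,alpha} > cutoff, ``-1``
    when G_{i,alpha} < -cutoff, else 0 (strict inequalities: a weight exactly
    at the cutoff is a non-member).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if gene not in dec.G.index:
        raise KeyError(f"unknown gene id {gene!r}")
    g = dec.G.loc[gene].to_numpy()[1:]
    signs = (g > cutoff).astype(int) - (g < -cutoff).astype(int)
    return pd.Series(
        signs, index=pd.RangeIndex(1, len(g) + 1, name="process"), name=str(gene)
    )


class Attribution(NamedTuple):
    per_process: pd.DataFrame  # index = active process; product & deviation
    total_product: float
    total_deviation: float


def attribute_deviation(
    dec: SurprisalDecomposition, barcode, gene, sample
) -> Attribution:
    """Contributions of a sample's *active* processes to one transcript.

    ``barcode`` is the sample's digit vector over processes 1..n; only
    processes with digit != 0 contribute.  The null barcode yields an empty
    attribution with total 0.  ``product`` is the raw term
    G_{i,alpha}*lambda_alpha(k); ``deviation`` (its negative) is the change of
    ln X with positive = upregulation.
    """
    if gene not in dec.G.index:
        raise KeyError(f"unknown gene id {gene!r}")
    if sample not in dec.lam.columns:
        raise KeyError(f"unknown sample id {sample!r}")
    digits = np.asarray(barcode, dtype=int)
    active = [a + 1 for a, d in enumerate(digits) if d != 0]
    g_row = dec.G.loc[gene].to_numpy()
    lam_col = dec.lam[sample].to_numpy()
    prod = np.array([g_row[a] * lam_col[a] for a in active])
    table = pd.DataFrame(
        {"product": prod, "deviation": -prod}, index=pd.Index(active, name="process")
    )
    return Attribution(table, float(prod.sum()), float(-prod.sum()))


@dataclass
class TailRule:
    """Definition of "significant" up/down regulation for tail flagging.

    ``kind="sd"``: beyond ``k`` SDs of the non-demented group mean (the SD is
    the non-demented group's SD).  ``kind="quantile"``: outside the q / 1-q
    quantiles of the full cohort.
    """

    kind: str = "sd"
    k: float = 2.0
    q: float = 0.05
    reference: str = "non-demented"


def tail_flags(
    logx: pd.DataFrame, gene, meta: pd.DataFrame, rule: TailRule | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag samples whose expression of ``gene`` falls in a distribution tail.

    Returns (per-sample flags in {"up", "down", "none"}, per-pathology-group
    summary with counts and fractions flagged up/down).
    """
    rule = rule or TailRule()
    if gene not in logx.index:
        raise KeyError(f"unknown gene id {gene!r}")
    x = logx.loc[gene]
    meta = meta.loc[x.index]
    if rule.kind == "sd":
        ref = x[meta["pathology"] == rule.reference]
        if len(ref) == 0:
            raise ValueError(f"no samples in reference group {rule.reference!r}")
        mu, sd = float(ref.mean()), float(ref.std(ddof=0))
        hi, lo = mu + rule.k * sd, mu - rule.k * sd
    elif rule.kind == "quantile":
        lo, hi = float(x.quantile(rule.q)), float(x.quantile(1 - rule.q))
    else:
        raise ValueError(f"unknown tail rule kind {rule.kind!r}")
    flags = pd.Series("none", index=x.index, name="flag")
    flags[x > hi] = "up"
    flags[x < lo] = "down"
    rows = []
    for g in PATHOLOGY_LEVELS:
        grp = flags[meta["pathology"] == g]
        n = len(grp)
        up, down = int((grp == "up").sum()), int((grp == "down").sum())
        rows.append(
            {
                "pathology": g,
                "n": n,
                "n_up": up,
                "n_down": down,
                "frac_up": up / n if n else np.nan,
                "frac_down": down / n if n else np.nan,
            }
        )
    return flags, pd.DataFrame(rows).set_index("pathology")


def biomarker_report(
    dec: SurprisalDecomposition,
    logx: pd.DataFrame,
    barcodes: pd.DataFrame,
    genes,
    cutoff: float = 0.01,
) -> pd.DataFrame:
    """Long-format report over genes x samples: log fold change vs the cohort
    median, the sample's active processes, and the per-process attribution."""
    rows = []
    for gene in genes:
        fc = fold_change_vs_median(logx, gene)
        for sample in logx.columns:
            digits = barcodes.loc[sample].to_numpy()
            att = attribute_deviation(dec, digits, gene, sample)
            active = ",".join(str(a) for a in att.per_process.index)
            rows.append(
                {
                    "gene": gene,
                    "sample_id": sample,
                    "log_fc": float(fc.loc[sample]),
                    "active_processes": active,
                    "total_deviation": att.total_deviation,
                }
            )
    return pd.DataFrame(rows)
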