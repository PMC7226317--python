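"""Ternary sample barcodes and the population-level barcode catalog.

Each sample's amplitudes over the significant processes are discretised to
digits in {-1, 0, +1}: +1 when lambda_alpha(k) > T_alpha, -1 when
lambda_alpha(k) < -T_alpha, 0 otherwise (strict inequalities; an amplitude
exactly at the threshold is inactive).  The resulting per-sample digit vector
is the sample's transcriptional signature ("barcode"); unique barcodes are
catalogued across the cohort and classified by disease specificity, rarity,
and regional enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .decomposition import SurprisalDecomposition
from .io import AD_LEVELS, PATHOLOGY_LEVELS
from .significance import ThresholdSet


class TernaryBarcoder(TransformerMixin, BaseEstimator):
    """Discretise process amplitudes to ternary digits, sklearn-style.

    Parameters
    ----------
    threshold : float or array-like
        Activity threshold; a scalar applies to every process, an array gives
        one threshold per process.  Must be positive.
    """

    def __init__(self, threshold=24.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        t = np.asarray(self.threshold, dtype=float)
        if (t <= 0).any():
            raise ValueError("threshold must be positive")
        if t.ndim > 1 or (t.ndim == 1 and len(t) != X.shape[1]):
            raise ValueError("threshold must be a scalar or one value per process")
        self.threshold_ = np.broadcast_to(t, (X.shape[1],)).copy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Map amplitudes (n_samples, n_processes) to digits in {-1, 0, 1}."""
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("amplitudes contain non-finite values")
        t = self.threshold_
        return ((X > t).astype(int) - (X < -t).astype(int))


def make_barcode(lambdas, threshold=24.0) -> np.ndarray:
    """Ternary barcode of one sample's amplitude vector."""
    lambdas = np.asarray(lambdas, dtype=float)
    return TernaryBarcoder(threshold).fit(lambdas[None, :]).transform(lambdas[None, :])[0]


def barcode_table(
    dec: SurprisalDecomposition, n: int, thresholds: ThresholdSet | float = 24.0
) -> pd.DataFrame:
    """Barcodes for every sample over processes 1..n (columns digit_1..digit_n)."""
    if not 0 <= n <= dec.n_processes:
        raise ValueError(f"n must be in [0, {dec.n_processes}]")
    if isinstance(thresholds, ThresholdSet):
        t = np.array([thresholds.threshold_for(a) for a in range(1, n + 1)])
    else:
        t = np.full(n, float(thresholds))
    amps = dec.lam_values()[1 : n + 1].T  # samples x processes
    digits = (
        TernaryBarcoder(t).fit(amps).transform(amps)
        if n > 0
        else np.zeros((len(dec.sample_ids), 0), dtype=int)
    )
    return pd.DataFrame(
        digits,
        index=pd.Index(dec.sample_ids, name="sample_id"),
        columns=[f"digit_{a}" for a in range(1, n + 1)],
    )


@dataclass
class BarcodeCatalog:
    """Catalog of the unique barcodes found in a cohort.

    ``table`` is indexed by barcode index and holds the digit string, total
    and per-pathology-group counts, specificity class and rarity flag;
    ``assignment`` maps every sample to its barcode index; ``members`` maps a
    barcode index to its carrier sample ids.
    """

    table: pd.DataFrame
    assignment: pd.Series
    members: dict
    digits: dict  # barcode index -> tuple of digits

    @property
    def n_samples(self) -> int:
        return int(len(self.assignment))

    def barcode_of(self, sample_id) -> tuple:
        return self.digits[self.assignment.loc[sample_id]]


def _digit_string(digits) -> str:
    return ",".join(str(int(d)) for d in digits)


def build_catalog(barcodes: pd.DataFrame, meta: pd.DataFrame) -> BarcodeCatalog:
    """Catalog the unique barcodes and count carriers per pathology group.

    Indexing rule: the null (all-zero) barcode gets index 1 when present;
    the remaining barcodes are ordered by descending total count, ties by
    lexicographic digits.
    """
    missing = [s for s in barcodes.index if s not in meta.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing[:5]}")
    digit_cols = list(barcodes.columns)
    tuples = [tuple(int(v) for v in row) for row in barcodes[digit_cols].to_numpy()]
    sample_ids = list(barcodes.index)
    null = tuple([0] * len(digit_cols))

    counts: dict[tuple, int] = {}
    for t in tuples:
        counts[t] = counts.get(t, 0) + 1
    others = sorted(
        (t for t in counts if t != null), key=lambda t: (-counts[t], t)
    )
    ordered = ([null] if null in counts else []) + others
    index_of = {t: i + 1 for i, t in enumerate(ordered)}

    assignment = pd.Series(
        [index_of[t] for t in tuples], index=pd.Index(sample_ids, name="sample_id"),
        name="barcode_index",
    )
    members: dict[int, list] = {i: [] for i in index_of.values()}
    for sid, t in zip(sample_ids, tuples):
        members[index_of[t]].append(sid)

    pathology = meta.loc[sample_ids, "pathology"]
    rows = []
    for t in ordered:
        idx = index_of[t]
        carrier_path = pathology.loc[members[idx]]
        group_counts = {g: int((carrier_path == g).sum()) for g in PATHOLOGY_LEVELS}
        rows.append(
            {
                "barcode_index": idx,
                "digits": _digit_string(t),
                "n_total": counts[t],
                **{f"n_{g}": c for g, c in group_counts.items()},
            }
        )
    table = pd.DataFrame(rows).set_index("barcode_index")
    catalog = BarcodeCatalog(
        table=table,
        assignment=assignment,
        members=members,
        digits={index_of[t]: t for t in ordered},
    )
    return classify_specificity(catalog)


def classify_specificity(catalog: BarcodeCatalog) -> BarcodeCatalog:
    """Assign specificity classes and the rarity flag.

    AD-only: carried exclusively by possible/probable/definite samples;
    normal-only: exclusively non-demented; mixed otherwise.  The all-zero
    barcode is classed "null" regardless of its carriers.  Rare = AD-only and
    carried by at most 2 AD samples.
    """
    t = catalog.table
    n_ad = sum(t[f"n_{g}"] for g in AD_LEVELS)
    n_nd = t["n_non-demented"]
    classes = []
    for idx in t.index:
        if all(d == 0 for d in catalog.digits[idx]):
            classes.append("null")
        elif n_nd.loc[idx] == 0:
            classes.append("AD-only")
        elif n_ad.loc[idx] == 0:
            classes.append("normal-only")
        else:
            classes.append("mixed")
    t = t.assign(n_AD=n_ad, specificity=classes)
    t["rare"] = (t["specificity"] == "AD-only") & (t["n_AD"] <= 2)
    catalog.table = t
    return catalog


def region_enrichment(
    catalog: BarcodeCatalog,
    meta: pd.DataFrame,
    min_frac: float = 0.10,
    regions=None,
) -> pd.DataFrame:
    """AD : non-demented carrier ratios per region for the common barcodes.

    Within each region, a barcode is included when its carriers cover at
    least ``min_frac`` of that region's AD samples or of its non-demented
    samples.  A barcode with non-demented carrier count 0 gets an infinite
    ratio and the note "AD-exclusive in region".
    """
    if not 0 < min_frac < 1:
        raise ValueError("min_frac must be in (0, 1)")
    meta = meta.loc[catalog.assignment.index]
    available = list(dict.fromkeys(meta["region"]))
    if regions is None:
        regions = available
    rows = []
    for region in regions:
        if region not in available:
            warnings.warn(f"region {region!r} absent from metadata; skipped", stacklevel=2)
            continue
        in_region = meta["region"] == region
        is_ad = meta["pathology"].isin(AD_LEVELS)
        n_ad_total = int((in_region & is_ad).sum())
        n_nd_total = int((in_region & ~is_ad).sum())
        assign = catalog.assignment[in_region]
        for idx in sorted(assign.unique()):
            carriers = assign.index[assign == idx]
            n_ad = int(is_ad.loc[carriers].sum())
            n_nd = len(carriers) - n_ad
            ok_ad = n_ad_total > 0 and n_ad >= min_frac * n_ad_total
            ok_nd = n_nd_total > 0 and n_nd >= min_frac * n_nd_total
            if not (ok_ad or ok_nd):
                continue
            if n_nd == 0:
                ratio, note = np.inf, "AD-exclusive in region"
            else:
                ratio, note = n_ad / n_nd, ""
            rows.append(
                {"region": region, "barcode_index": idx, "n_AD": n_ad,
                 "n_ND": n_nd, "ratio": ratio, "note": note}
            )
    return pd.DataFrame(rows, columns=["region", "barcode_index", "n_AD", "n_ND", "ratio", "note"])


def subject_summary(catalog: BarcodeCatalog, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-subject barcode heterogeneity.

    For each subject: the number of samples, the distinct barcodes its
    samples carry, and the union of processes active (digit != 0) in any of
    them (1-based process indices).
    """
    meta = meta.loc[catalog.assignment.index]
    rows = []
    for subject, sub in meta.groupby("subject_id", sort=False):
        indices = sorted(set(catalog.assignment.loc[sub.index]))
        union: set[int] = set()
        for idx in indices:
            union |= {a + 1 for a, d in enumerate(catalog.digits[idx]) if d != 0}
        rows.append(
            {
                "subject_id": subject,
                "n_samples": len(sub),
                "n_distinct_barcodes": len(indices),
                "barcode_indices": ",".join(str(i) for i in indices),
                "active_process_union": ",".join(str(a) for a in sorted(union)),
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def frequency_map(catalog: BarcodeCatalog) -> pd.DataFrame:
    """Relative frequency of each barcode within each pathology group.

    A group with zero samples gets NaN (undefined), not 0.
    """
    t = catalog.table
    out = {}
    for g in PATHOLOGY_LEVELS:
        total = int(t[f"n_{g}"].sum())
        out[g] = t[f"n_{g}"] / total if total > 0 else np.full(len(t), np.nan)
    return pd.DataFrame(out, index=t.index)
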