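"""Readers, writers and validation for expression matrices and sample metadata.

The pipeline's carrier formats are plain delimited text: an expression matrix
with transcript identifiers in the first column and sample identifiers in the
header, and a metadata table with one row per sample.  All writers emit TSV
with a single leading ``#`` comment line recording the package version and any
parameters relevant to provenance, so every output round-trips through the
corresponding reader.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

#: The 17 brain-region codes sampled in the cohort this pipeline was designed
#: around (frontal pole ... putamen).
REGIONS: tuple[str, ...] = (
    "FP", "OVC", "ITG", "MTG", "STG", "PCC", "AC", "PG", "TP",
    "PrG", "IFG", "DPC", "SPL", "PC", "CN", "Hi", "Pu",
)

#: Neuropathology severity vocabulary, from unaffected to definite disease.
PATHOLOGY_LEVELS: tuple[str, ...] = ("non-demented", "possible", "probable", "definite")

#: Levels pooled as "AD" when contrasting diseased vs non-demented samples.
AD_LEVELS: tuple[str, ...] = ("possible", "probable", "definite")

METADATA_COLUMNS = ("sample_id", "subject_id", "region", "pathology")


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_header(path) -> tuple[str, str]:
    """Return (header line, separator), skipping leading comment lines."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return line.rstrip("\n"), _detect_sep(line)
    raise ValueError(f"{path}: file contains no header line")


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()].tolist()))
        raise ValueError(f"duplicate {what}: {dups}")


def read_expression(path, pseudo_count: float = 0.0) -> pd.DataFrame:
    """Read a transcripts x samples expression matrix from delimited text.

    The first column holds transcript ids, the header row holds sample ids.
    If any raw entry is <= 0 and ``pseudo_count`` is positive, the pseudo-count
    is added to *every* entry (and recorded in ``df.attrs['pseudo_count']``);
    a non-positive entry with ``pseudo_count == 0`` is an error.
    """
    path = pathlib.Path(path)
    header, sep = _read_header(path)
    sample_ids = [tok.strip() for tok in header.split(sep)][1:]
    _check_unique(sample_ids, "sample ids")

    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = [str(c).strip() for c in df.columns]
    _check_unique(df.index, "transcript ids")

    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric expression value at transcript {row!r}, sample {col!r}"
            )
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing entries")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("expression matrix must be at least 2 transcripts x 2 samples")

    values = df.to_numpy(dtype=float)
    applied = 0.0
    if (values <= 0).any():
        if pseudo_count > 0:
            df = df + pseudo_count
            applied = float(pseudo_count)
        else:
            n_bad = int((values <= 0).sum())
            raise ValueError(
                f"{n_bad} non-positive expression values and pseudo_count is 0"
            )
    df = df.astype(float)
    df.attrs["pseudo_count"] = applied
    return df


def read_metadata(path, strict: bool = True) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, subject_id, region, pathology[, age]).

    With ``strict=True`` (default) region and pathology tokens must come from
    the closed vocabularies; pass ``strict=False`` to accept extensions.
    """
    path = pathlib.Path(path)
    _, sep = _read_header(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    _check_unique(df["sample_id"], "sample ids")
    if strict:
        bad_region = sorted(set(df["region"]) - set(REGIONS))
        if bad_region:
            raise ValueError(f"unknown region codes {bad_region}; pass strict=False to allow")
        bad_path = sorted(set(df["pathology"]) - set(PATHOLOGY_LEVELS))
        if bad_path:
            raise ValueError(f"unknown pathology levels {bad_path}; pass strict=False to allow")
    return df.set_index("sample_id", drop=False)


@dataclass
class ExpressionDataset:
    """A positive expression matrix joined with aligned sample metadata.

    ``expression`` is transcripts x samples; ``samples`` is indexed by
    sample_id and ordered exactly as the expression columns.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.expression.columns) != list(self.samples.index):
            raise ValueError("expression columns and metadata rows are not aligned")

    @property
    def transcript_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        sample_ids = list(sample_ids)
        return ExpressionDataset(
            self.expression.loc[:, sample_ids], self.samples.loc[sample_ids]
        )

    def subset_transcripts(self, transcript_ids) -> "ExpressionDataset":
        return ExpressionDataset(self.expression.loc[list(transcript_ids)], self.samples)


def assemble_dataset(
    expr: pd.DataFrame, meta: pd.DataFrame, intersect: bool = False
) -> ExpressionDataset:
    """Join an expression matrix with metadata into an aligned dataset.

    With ``intersect=True`` samples missing from either side are dropped;
    otherwise any mismatch is an error.
    """
    shared = [s for s in expr.columns if s in meta.index]
    if len(shared) == 0:
        raise ValueError("no samples shared between expression matrix and metadata")
    if not intersect:
        extra_expr = sorted(set(expr.columns) - set(meta.index))
        extra_meta = sorted(set(meta.index) - set(expr.columns))
        if extra_expr or extra_meta:
            raise ValueError(
                "sample mismatch between expression and metadata "
                f"(expression-only: {extra_expr[:5]}, metadata-only: {extra_meta[:5]}); "
                "pass intersect=True to keep the shared samples"
            )
    if len(shared) < 2:
        raise ValueError("fewer than 2 samples shared between expression and metadata")
    return ExpressionDataset(expr.loc[:, shared], meta.loc[shared])


# ---------------------------------------------------------------------------
# writers

def _header_comment(params: dict | None) -> str:
    extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# surprisalx v{__version__}{extra}\n"


def write_table(obj, path, params: dict | None = None) -> None:
    """Write any of the pipeline's tabular results as commented TSV.

    DataFrames/Series are written directly.  A ``SurprisalDecomposition`` is
    written as two files, ``<stem>.G.tsv`` and ``<stem>.lambda.tsv``.
    """
    path = pathlib.Path(path)
    # local import: decomposition depends on io for nothing, keep io light
    from .decomposition import SurprisalDecomposition

    if isinstance(obj, SurprisalDecomposition):
        write_table(obj.G, path.with_name(path.stem + ".G.tsv"), params)
        write_table(obj.lam, path.with_name(path.stem + ".lambda.tsv"), params)
        return
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        obj.to_csv(fh, sep="\t")


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col, float_precision="round_trip"
    )
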