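"""End-to-end pipeline orchestration with a flat key-value configuration.

``run_pipeline`` chains: log transform -> decomposition -> noise baseline ->
thresholds -> significant-process count (cross-checked by the R2 plateau) ->
barcodes -> catalog -> specificity, region enrichment, subject summary and
frequency map.  Every stage output is written as commented TSV and listed,
with a content hash, in ``manifest.json``; reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .barcodes import (
    barcode_table,
    build_catalog,
    frequency_map,
    region_enrichment,
    subject_summary,
)
from .decomposition import decompose, log_transform, steady_state_summary
from .significance import (
    amplitude_thresholds,
    count_significant,
    fixed_thresholds,
    plateau_n,
    r2_curve,
    stable_transcripts,
)


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters; unknown keys are rejected when read from file."""

    expression: str = ""
    metadata: str = ""
    out_dir: str = "surprisalx_run"
    pseudo_count: float = 0.0
    values_are_log: bool = False
    stable_m: int = 100
    threshold_mode: str = "fixed"       # "fixed" | "monte_carlo"
    threshold_value: float = 24.0
    replicates: int = 100
    percentile: float = 0.975
    seed: int = 0
    n_override: int | None = None
    r2_epsilon: float = 0.01
    r2_samples: int = 6
    membership_cutoff: float = 0.01
    min_frac: float = 0.10

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> pathlib.Path:
    """Run every stage and write outputs plus a manifest; returns the run dir."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {"seed": config.seed}

    expr = io.read_expression(config.expression, pseudo_count=config.pseudo_count)
    meta = io.read_metadata(config.metadata)
    dataset = io.assemble_dataset(expr, meta, intersect=True)

    if config.values_are_log:
        logx = dataset.expression
    else:
        logx = log_transform(dataset)
    dec = decompose(logx)
    io.write_table(dec, out / "decomposition.tsv", params)

    steady = steady_state_summary(dec)
    io.write_table(
        steady.lambda0.rename("lambda0").to_frame().assign(cv=steady.cv, invariant=steady.invariant),
        out / "steady_state.tsv",
        params,
    )

    baseline = stable_transcripts(logx, m=min(config.stable_m, logx.shape[0]))
    if config.threshold_mode == "fixed":
        thresholds = fixed_thresholds(dec.n_processes, config.threshold_value)
    elif config.threshold_mode == "monte_carlo":
        thresholds = amplitude_thresholds(
            dec, baseline,
            replicates=config.replicates,
            percentile=config.percentile,
            seed=config.seed,
        )
    else:
        raise ValueError(f"unknown threshold_mode {config.threshold_mode!r}")
    io.write_table(thresholds.as_frame(), out / "thresholds.tsv", params)

    n_amp = count_significant(dec, thresholds)
    n_max = min(max(2 * max(n_amp, 1), 10), dec.n_components - 1)
    chosen = list(logx.columns[: config.r2_samples])
    curves = [r2_curve(dec, logx, s, n_max) for s in chosen]
    r2_frame = pd.concat(
        {c.sample_id: pd.Series(c.r2) for c in curves}, axis=1
    ).rename_axis("n")
    io.write_table(r2_frame, out / "r2_curves.tsv", params)
    n_plateau, plateaued = plateau_n(curves, epsilon=config.r2_epsilon)

    n = config.n_override if config.n_override is not None else n_amp
    barcodes = barcode_table(dec, n, thresholds)
    io.write_table(barcodes, out / "barcodes.tsv", params)

    catalog = build_catalog(barcodes, dataset.samples)
    io.write_table(catalog.table, out / "catalog.tsv", params)
    io.write_table(
        catalog.assignment.to_frame(), out / "barcode_assignment.tsv", params
    )
    io.write_table(
        region_enrichment(catalog, dataset.samples, min_frac=config.min_frac),
        out / "region_enrichment.tsv",
        params,
    )
    io.write_table(subject_summary(catalog, dataset.samples), out / "subject_summary.tsv", params)
    io.write_table(frequency_map(catalog), out / "frequency_map.tsv", params)

    summary = {
        "version": __version__,
        "config": config.as_dict(),
        "n_significant_amplitude": int(n_amp),
        "n_plateau": int(n_plateau),
        "r2_plateaued": bool(plateaued),
        "n_used_for_barcodes": int(n),
        "steady_state_cv": float(steady.cv),
        "steady_state_invariant": bool(steady.invariant),
        "n_unique_barcodes": int(len(catalog.table)),
        "thresholds": [float(t) for t in thresholds.thresholds[:n]] if n else [],
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    manifest = {
        "version": __version__,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
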