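"""Batch orchestration: simulate → morphometry → quantify → stats.

A run is described by a single serializable :class:`RunConfig`; executing
it produces per-cell and per-field tables, ANOVA / pairwise tables per
metric, and a JSON report whose provenance block (config hash, seed,
package version) is sufficient to reproduce the run bit-for-bit.  Each
stage writes its table as soon as it finishes, so a failed run keeps
earlier outputs and can be resumed: with ``resume=True`` a stage whose
output file already exists is skipped and its table reloaded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image_core import despeckle, max_projection, read_stack
from .morphometry import MorphometryConfig, analyze_projection, records_to_frame
from .quantification import (QuantificationConfig, aggregates_to_frame,
                             measurements_to_frame, summarize_field)
from .group_stats import two_way_anova
from .synthetic import DEFAULT_PRESETS, iter_stage_series, load_ground_truth

__all__ = ["RunConfig", "RunReport", "run_pipeline", "TABLE_SCHEMA_VERSION"]

log = logging.getLogger("retquant")

TABLE_SCHEMA_VERSION = 1

#: Field-level metrics compared across the design in the stats stage.
DEFAULT_METRICS = ("microglia_density_mm3", "caspase_pct", "gfap_fraction")
DEFAULT_CELL_METRICS = ("morphological_index", "n_branches", "n_endpoints",
                        "n_junctions", "n_triple_junctions")


@dataclass
class RunConfig:
    """Complete description of one pipeline run.

    Either ``input_dir`` points at an existing dataset (TIFF fields plus
    ``*.truth.json`` sidecars and a ``manifest.csv``) or ``simulate=True``
    generates the default stage × genotype series in memory.
    """

    out_dir: str = "runs/out"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    n_fields: int = 16
    channel_map: dict = field(default_factory=dict)  # real-data channel renames
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    quantification: QuantificationConfig | None = None
    metrics: tuple[str, ...] = DEFAULT_METRICS
    cell_metrics: tuple[str, ...] = DEFAULT_CELL_METRICS
    resume: bool = False

    def __post_init__(self) -> None:
        if self.quantification is None:
            self.quantification = QuantificationConfig(morphometry=self.morphometry)
        if not self.simulate:
            if self.input_dir is None:
                raise ValueError("a real-data run requires input_dir")
            if not self.channel_map:
                raise ValueError("a real-data run requires a channel map")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        d["cell_metrics"] = list(self.cell_metrics)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("morphometry"), dict):
            d["morphometry"] = MorphometryConfig(**d["morphometry"])
        if isinstance(d.get("quantification"), dict):
            q = dict(d["quantification"])
            if isinstance(q.get("morphometry"), dict):
                q["morphometry"] = MorphometryConfig(**q["morphometry"])
            if isinstance(q.get("aggregate_channels"), list):
                q["aggregate_channels"] = tuple(q["aggregate_channels"])
            d["quantification"] = QuantificationConfig(**q)
        for key in ("metrics", "cell_metrics"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunReport:
    """Outcome of one run: stage status, table paths and provenance."""

    provenance: dict
    stages: dict
    tables: dict

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, "stages": self.stages,
                "tables": self.tables}

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _hash_csv(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema_version={TABLE_SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _iter_fields(config: RunConfig):
    """Yield (meta, stack, truth) for simulated or on-disk datasets."""
    if config.simulate:
        yield from iter_stage_series(DEFAULT_PRESETS, config.n_fields, config.seed)
        return
    input_dir = Path(config.input_dir)
    manifest = pd.read_csv(input_dir / "manifest.csv")
    for _, row in manifest.iterrows():
        stack = read_stack(input_dir / row["tiff"])
        if config.channel_map:
            stack.channels = tuple(config.channel_map.get(c, c) for c in stack.channels)
        truth = None
        gt = row.get("ground_truth")
        if isinstance(gt, str) and (input_dir / gt).exists():
            truth = load_ground_truth(input_dir / gt)
        meta = {"field_id": row["field_id"], "genotype": row.get("genotype"),
                "stage": row.get("stage")}
        yield meta, stack, truth


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages of a run and write the report.

    Measurement (morphometry + quantification) streams over the fields one
    at a time so the full series never sits in memory; the stats stage
    consumes only the tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    stages: dict[str, str] = {}
    tables: dict[str, str] = {}

    log.info("run %s: seed=%d simulate=%s", config.config_hash[:12],
             config.seed, config.simulate)
    for name, val in sorted(dataclasses.asdict(config.morphometry).items()):
        log.info("morphometry parameter %s = %r", name, val)
    for name, val in sorted(dataclasses.asdict(config.quantification).items()):
        log.info("quantification parameter %s = %r", name, val)

    cells_path = out / "cells.csv"
    fields_path = out / "fields.csv"
    aggregates_path = out / "aggregates.csv"

    # -- measurement stage (per field, streaming) -------------------------
    if config.resume and cells_path.exists() and fields_path.exists() \
            and aggregates_path.exists():
        stages["measure"] = "skipped (resume)"
        cells_df = _read_table(cells_path)
        fields_df = _read_table(fields_path)
    else:
        try:
            cell_rows = []
            measurements = []
            for meta, stack, truth in _iter_fields(config):
                proj = despeckle(max_projection(
                    stack, config.quantification.microglia_channel))
                recs = analyze_projection(proj, config.morphometry)
                df = records_to_frame(recs)
                df.insert(0, "field_id", meta["field_id"])
                df.insert(1, "genotype", meta.get("genotype"))
                df.insert(2, "stage", meta.get("stage"))
                cell_rows.append(df)
                measurements.append(summarize_field(
                    stack, truth, config.quantification,
                    field_id=meta["field_id"], genotype=meta.get("genotype"),
                    stage=meta.get("stage"),
                ))
            cells_df = pd.concat(cell_rows, ignore_index=True) if cell_rows \
                else records_to_frame([])
            fields_df = measurements_to_frame(measurements)
            _write_table(cells_df, cells_path)
            _write_table(fields_df, fields_path)
            _write_table(aggregates_to_frame(measurements), aggregates_path)
            stages["measure"] = "ok"
        except Exception as exc:  # keep earlier outputs, mark stage failed
            stages["measure"] = f"failed: {exc}"
            report = _finalize(config, out, stages, tables)
            return report
    tables["cells"] = cells_path.name
    tables["fields"] = fields_path.name
    tables["aggregates"] = aggregates_path.name

    # -- stats stage ------------------------------------------------------
    try:
        stat_sources = [(fields_df, config.metrics)]
        if not cells_df.empty:
            per_field = cells_df.groupby(
                ["field_id", "genotype", "stage"], as_index=False
            )[list(config.cell_metrics)].mean()
            stat_sources.append((per_field, config.cell_metrics))
        for df, metrics in stat_sources:
            for metric in metrics:
                if metric not in df.columns or df[metric].nunique() < 2:
                    continue
                sub = df.rename(columns={metric: "value"})[
                    ["value", "genotype", "stage"]].dropna()
                try:
                    res = two_way_anova(sub)
                except ValueError as exc:
                    log.warning("stats for %s skipped: %s", metric, exc)
                    continue
                apath = out / f"anova_{metric}.csv"
                _write_table(res.anova.reset_index(), apath)
                tables[f"anova_{metric}"] = apath.name
                ppath = out / f"pairwise_{metric}.csv"
                _write_table(res.pairwise, ppath)
                tables[f"pairwise_{metric}"] = ppath.name
        stages["stats"] = "ok"
    except Exception as exc:
        stages["stats"] = f"failed: {exc}"

    return _finalize(config, out, stages, tables)


def _finalize(config: RunConfig, out: Path, stages: dict, tables: dict) -> RunReport:
    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "table_hashes": {k: _hash_csv(out / v) for k, v in tables.items()
                         if (out / v).exists()},
    }
    report = RunReport(provenance=provenance, stages=stages, tables=tables)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report
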