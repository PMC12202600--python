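"""Tidy-CSV, BED and config I/O for observations, chains and summaries.

The ingestion boundary is a documented pair of tidy tables rather than any
image-analysis tool's native output:

* cells CSV — ``cell_id, gene, condition, time_h, total_count, n_ts_total,
  n_ts_active`` (one row per cell),
* TS CSV — ``cell_id, gene, condition, time_h, intensity`` (one row per
  detected active transcription site),

plus a gene-model config (YAML or JSON) with keys ``gene_length_bp``,
``elongation_bp_per_s``, ``introns`` (list of [start, end)), ``exon_probes``
and ``intron_probes``; probe positions may alternatively come from BED
(0-based half-open; the interval start is the probe position).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .likelihood import Dataset, TSObservation
from .mcmc import Chain, MCMCConfig
from .nascent import GeneModel
from .telegraph import CellObservation

__all__ = [
    "CELL_COLUMNS",
    "TS_COLUMNS",
    "load_gene_model",
    "save_gene_model",
    "read_probe_bed",
    "read_observations",
    "write_observations",
    "write_chain",
    "read_chain",
    "write_summary",
]

CELL_COLUMNS = ["cell_id", "gene", "condition", "time_h", "total_count", "n_ts_total", "n_ts_active"]
TS_COLUMNS = ["cell_id", "gene", "condition", "time_h", "intensity"]


def load_gene_model(path: str | Path) -> GeneModel:
    """Gene model from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return GeneModel.from_config(cfg)


def save_gene_model(gene: GeneModel, path: str | Path) -> None:
    path = Path(path)
    cfg = gene.to_config()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_probe_bed(path: str | Path) -> tuple[int, ...]:
    """Probe positions from BED (0-based, half-open): the interval start is used."""
    positions = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {ln}: BED needs at least 3 columns")
        positions.append(int(fields[1]))
    return tuple(sorted(positions))


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def _int_column(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() | (vals != vals.round()) | (vals < 0)]
    if len(bad):
        raise ValueError(f"{what}: rows {list(bad[:5])}: column {col!r} must be a non-negative integer")
    return vals.astype(int)


def read_observations(
    cells_csv: str | Path,
    ts_csv: str | Path,
    gene_config: str | Path | GeneModel,
) -> dict[tuple, Dataset]:
    """Validated datasets keyed by (gene, condition, time_h).

    Rejects schema violations, orphan TS rows, non-integer counts, active-TS
    counts exceeding totals and non-positive intensities with row-level error
    messages.
    """
    gene = gene_config if isinstance(gene_config, GeneModel) else load_gene_model(gene_config)
    cells = pd.read_csv(cells_csv, float_precision="round_trip")
    ts = pd.read_csv(ts_csv, float_precision="round_trip")
    _require_columns(cells, CELL_COLUMNS, "cells CSV")
    _require_columns(ts, TS_COLUMNS, "TS CSV")
    cells = cells.copy()
    for col in ("total_count", "n_ts_total", "n_ts_active"):
        cells[col] = _int_column(cells, col, "cells CSV")
    over = cells.index[cells["n_ts_active"] > cells["n_ts_total"]]
    if len(over):
        raise ValueError(f"cells CSV: rows {list(over[:5])}: n_ts_active exceeds n_ts_total")
    bad_z = ts.index[~(pd.to_numeric(ts["intensity"], errors="coerce") > 0)]
    if len(bad_z):
        raise ValueError(f"TS CSV: rows {list(bad_z[:5])}: intensity must be > 0")

    keys = ["gene", "condition", "time_h"]
    out: dict[tuple, Dataset] = {}
    ts_groups = dict(tuple(ts.groupby(keys)))
    for key, grp in cells.groupby(keys):
        cell_objs = tuple(
            CellObservation(
                cell_id=str(r.cell_id), K=int(r.n_ts_total), k=int(r.n_ts_active), m=int(r.total_count)
            )
            for r in grp.itertuples()
        )
        known = {c.cell_id for c in cell_objs}
        ts_grp = ts_groups.get(key)
        ts_objs: list[TSObservation] = []
        if ts_grp is not None:
            for r in ts_grp.itertuples():
                if str(r.cell_id) not in known:
                    raise ValueError(
                        f"TS CSV row {r.Index}: cell_id {r.cell_id!r} not present in cells CSV "
                        f"for group {key}"
                    )
                ts_objs.append(TSObservation(cell_id=str(r.cell_id), z=float(r.intensity)))
        out[key] = Dataset(
            cells=cell_objs,
            active_ts=tuple(ts_objs),
            gene=gene,
            metadata=dict(zip(keys, key)),
        )
    orphans = set(ts_groups) - set(out)
    if orphans:
        raise ValueError(f"TS CSV contains groups with no cells: {sorted(orphans)}")
    return out


def write_observations(
    dataset: Dataset, cells_csv: str | Path, ts_csv: str | Path
) -> None:
    """Write one dataset in the same tidy dialects `read_observations` accepts."""
    meta = dataset.metadata
    gene = meta.get("gene", "unknown")
    condition = meta.get("condition", "unknown")
    time_h = meta.get("time_h", 0.0)
    cells = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in dataset.cells],
            "gene": gene,
            "condition": condition,
            "time_h": time_h,
            "total_count": [c.m for c in dataset.cells],
            "n_ts_total": [c.K for c in dataset.cells],
            "n_ts_active": [c.k for c in dataset.cells],
        }
    )
    ts = pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in dataset.active_ts],
            "gene": gene,
            "condition": condition,
            "time_h": time_h,
            "intensity": [t.z for t in dataset.active_ts],
        }
    )
    # %.17g keeps the write->read round trip bit-exact for float intensities
    cells.to_csv(cells_csv, index=False)
    ts.to_csv(ts_csv, index=False, float_format="%.17g")


def write_chain(chain: Chain, path: str | Path) -> None:
    """Chain CSV: iteration, log_lambda..log_beta, log_post, accepted."""
    chain.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_chain(path: str | Path, config: MCMCConfig | None = None) -> Chain:
    return Chain.from_frame(pd.read_csv(path, float_precision="round_trip"), config=config)


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Posterior-summary CSV: parameter, mean, q025, q975."""
    summary.to_csv(path, index=False)
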