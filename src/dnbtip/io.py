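"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are TSV/CSV with genes in rows (the dominant
transcriptome-matrix dialect; ``transpose=True`` flips on read), sample
sheets are TSV with columns ``sample_id / group / time``, gene sets are
standard GMT, and interaction networks are 2-3 column edge lists.  All
readers validate and reject structural violations rather than repairing
them; malformed lines are reported with their line number.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from .datamodel import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger("dnbtip")

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_edgelist",
    "write_edgelist",
    "write_report",
    "read_report",
]


def _sep_for(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(
    path: str | Path,
    sample_sheet_path: str | Path | None = None,
    *,
    scale: str = "log2",
    transpose: bool = False,
) -> tuple[ExpressionDataset, SampleSheet | None]:
    """Read an expression matrix (and optionally its sample sheet).

    The first column holds gene ids, the header row sample ids.  When a
    sample sheet is given, every matrix sample must be annotated in it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transpose:
        df = df.T
    dataset = ExpressionDataset(df, scale=scale)
    sheet = None
    if sample_sheet_path is not None:
        sheet = read_sample_sheet(sample_sheet_path)
        sheet.check_matches(dataset)
    return dataset, sheet


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    path = Path(path)
    dataset.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``set_id TAB description TAB member...`` per line."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line needs id, description "
                    f"and at least one member (got {len(parts)} fields)"
                )
            genes = tuple(g for g in parts[2:] if g)
            if not genes:
                raise ValidationError(f"{path}: line {lineno}: gene set has no members")
            sets.append(GeneSet(parts[0], parts[1], genes))
    return GeneSetCollection(sets, name=name or Path(path).stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


def read_edgelist(path: str | Path) -> InteractionNetwork:
    """Read a 2-3 column edge list; self-loops are dropped with a warning."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}: line {lineno}: edge needs two gene ids"
                )
            edges.append(tuple(parts[:3]))
    net = InteractionNetwork(edges)
    if net.n_dropped_self_loops:
        logger.warning(
            "%s: dropped %d self-loop edge(s)", path, net.n_dropped_self_loops
        )
    return net


def write_edgelist(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(network.edges()):
            fh.write(f"{u}\t{v}\n")


def _jsonable(obj: Any) -> Any:
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an analysis report (CI table, DNB members, tipping call,
    rankings, seeds, config hash) as indented JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
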