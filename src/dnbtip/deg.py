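"""Differential-expression stand-in stage and DEG/DNB intersection.

The stage applies a Welch two-sample t-test per gene on log2 values, with
Benjamini-Hochberg FDR control and the conventional pass rule
``|log2FC| > 1 AND q < 0.05`` (fold change > 2 or < 0.5).  It is plumbing
feeding the ranking stage, not a reimplementation of a count-based
NB-GLM; an externally produced DEG table can be imported via
:func:`read_deg_table` and used everywhere a computed one is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset, SampleSheet, ValidationError

__all__ = [
    "differential",
    "differential_around_tipping",
    "intersect_dnb_deg",
    "read_deg_table",
    "write_deg_table",
]

DEG_COLUMNS = ["gene", "log2fc", "p", "q", "passed"]


def differential(
    dataset: ExpressionDataset,
    sheet: SampleSheet,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test of sample groups A vs B on log2 values.

    ``log2fc = mean(A) - mean(B)``; q is BH-adjusted over all tested
    genes; ``passed`` requires both the fold-change and FDR thresholds.
    Genes with zero variance in both groups and equal means get p = 1.
    """
    ds = dataset.to_log2()
    for name, grp in (("A", group_a), ("B", group_b)):
        missing = [s for s in grp if s not in ds.values.columns]
        if missing:
            raise ValidationError(f"group {name}: unknown sample(s) {missing[:5]}")
        if len(grp) < 2:
            raise ValidationError(f"group {name} selects fewer than 2 samples")
    a = ds.values[list(group_a)].to_numpy()
    b = ds.values[list(group_b)].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    passed = (np.abs(lfc) > lfc_threshold) & (q < fdr_threshold)
    return pd.DataFrame(
        {
            "gene": ds.gene_ids,
            "log2fc": lfc,
            "p": p,
            "q": q,
            "passed": passed,
        }
    )


def differential_around_tipping(
    dataset: ExpressionDataset,
    sheet: SampleSheet,
    tipping_time: int,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Treated samples after the tipping point vs before it.

    The tipping timepoint itself is excluded from both pools so the
    unstable critical state contaminates neither side; positive log2fc
    means up-regulated after the transition.
    """
    after = [
        s
        for t in sheet.treated_times
        if t > tipping_time
        for s in sheet.samples_at("treated", t)
    ]
    before = [
        s
        for t in sheet.treated_times
        if t < tipping_time
        for s in sheet.samples_at("treated", t)
    ]
    if len(after) < 2 or len(before) < 2:
        raise ValidationError(
            f"tipping time {tipping_time} leaves fewer than 2 samples on one side"
        )
    return differential(dataset, sheet, after, before, lfc_threshold, fdr_threshold)


def intersect_dnb_deg(
    deg_table: pd.DataFrame, dnb_genes: Iterable[str]
) -> tuple[list[str], dict[str, int]]:
    """Passing DEGs that are also DNB members.

    Returns the sorted intersection plus counts of the DEG set, the DNB
    set and their overlap.
    """
    degs = set(deg_table.loc[deg_table["passed"], "gene"])
    dnbs = set(dnb_genes)
    common = sorted(degs & dnbs)
    return common, {
        "n_deg": len(degs),
        "n_dnb": len(dnbs),
        "n_intersection": len(common),
    }


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table[DEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Import an externally produced DEG table (gene, log2fc, p, q, passed)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"DEG table missing columns: {sorted(missing)}")
    df["gene"] = df["gene"].astype(str)
    df["passed"] = df["passed"].astype(bool)
    return df[DEG_COLUMNS]
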