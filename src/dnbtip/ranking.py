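"""Network mapping, gene-set over-representation and DNB gene ranking.

Candidate DNB genes are prioritised the way the liver-fibrosis study that
motivates this package did: by the total number of fibrosis-associated
pathways (across the supplied gene-set collections) containing each gene,
with the number of differentially expressed neighbours in a gene-gene
interaction network as tie-break, and the post-tipping expression
direction annotated.  Over-representation uses the one-sided
hypergeometric (Fisher) upper tail, the standard test behind both KEGG and
IPA-style enrichment.

The module also carries, as data, the published per-gene
fibrosis-pathway membership counts for the twelve key genes of the mouse
TAA liver-fibrosis model (KEGG- and IPA-derived lists; paralog conversions
Cxcl2->Cxcl1 and Ces1->Ces1d applied as printed), from which GMT-style
fixtures can be rebuilt at run time.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    ValidationError,
)

logger = logging.getLogger("dnbtip")

__all__ = [
    "subnetwork",
    "linked_deg_count",
    "enrich",
    "enrich_collection",
    "rank_dnbs",
    "apply_aliases",
    "KEGG_FIBROSIS_PATHWAY_COUNTS",
    "IPA_FIBROSIS_PATHWAY_COUNTS",
    "key_fibrosis_genes",
    "published_count_collections",
]

# Published fibrosis-associated pathway membership counts per key gene in
# the mouse TAA liver-fibrosis model (paralog conversions applied as
# printed: Cxcl2 reported as Cxcl1, Ces1 as Ces1d).
KEGG_FIBROSIS_PATHWAY_COUNTS: dict[str, int] = {
    "Mmp7": 1,
    "Tgfb3": 4,
    "Id1": 2,
    "Hsd17b6": 1,
    "Cyp1a1": 1,
    "Fst": 1,
    "Cxcl1": 2,
    "Retsat": 1,
    "Il1r2": 2,
    "Itgb21": 2,
}

IPA_FIBROSIS_PATHWAY_COUNTS: dict[str, int] = {
    "Mmp7": 5,
    "Tgfb3": 5,
    "Cxcl1": 2,
    "Mmp13": 5,
    "Ces1d": 1,
    "Il1r2": 6,
}


def key_fibrosis_genes() -> list[str]:
    """Union of the two published key-DNB gene lists."""
    return sorted(set(KEGG_FIBROSIS_PATHWAY_COUNTS) | set(IPA_FIBROSIS_PATHWAY_COUNTS))


def _counts_to_collection(counts: Mapping[str, int], name: str) -> GeneSetCollection:
    """Rebuild a gene-set collection realising given membership counts:
    a gene with count k is placed in the first k sets."""
    n_sets = max(counts.values())
    sets = []
    for i in range(n_sets):
        members = tuple(g for g, k in sorted(counts.items()) if k > i)
        sets.append(GeneSet(f"{name}_pw{i + 1:02d}", f"{name} pathway {i + 1}", members))
    return GeneSetCollection(sets, name=name)


def published_count_collections() -> list[GeneSetCollection]:
    """GMT-style fixtures realising the published KEGG and IPA per-gene
    fibrosis-pathway counts."""
    return [
        _counts_to_collection(KEGG_FIBROSIS_PATHWAY_COUNTS, "KEGG"),
        _counts_to_collection(IPA_FIBROSIS_PATHWAY_COUNTS, "IPA"),
    ]


# ---------------------------------------------------------------------------
# network operations


def subnetwork(network: InteractionNetwork, genes: Iterable[str]) -> InteractionNetwork:
    """Induced subgraph on ``genes``."""
    keep = set(genes)
    edges = [(u, v) for u, v in network.edges() if u in keep and v in keep]
    return InteractionNetwork(edges)


def linked_deg_count(
    network: InteractionNetwork, dnb_gene: str, deg_genes: Iterable[str]
) -> int:
    """Number of distinct differentially expressed neighbours of one gene
    (the gene itself never counted)."""
    if dnb_gene not in network:
        logger.warning("gene %s absent from network; linked-DEG count 0", dnb_gene)
        return 0
    degs = set(deg_genes) - {dnb_gene}
    return len(network.neighbors(dnb_gene) & degs)


# ---------------------------------------------------------------------------
# over-representation


def enrich(
    query_genes: Iterable[str], gene_set: GeneSet | Iterable[str], universe: Iterable[str]
) -> float:
    """One-sided hypergeometric upper-tail p for the query/set overlap.

    With universe size M, set size K and query size n, the p-value is
    P(overlap >= k_observed) under sampling without replacement.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    query = set(query_genes)
    if not query <= uni:
        raise ValidationError("query genes must be a subset of the universe")
    members &= uni
    k = len(query & members)
    return float(hypergeom.sf(k - 1, len(uni), len(members), len(query)))


def enrich_collection(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric p per set, BH-adjusted across the collection."""
    query = set(query_genes)
    uni = set(universe)
    rows = []
    for s in collection:
        members = set(s.genes) & uni
        rows.append(
            {
                "set_id": s.set_id,
                "set_size": len(members),
                "overlap": len(query & members),
                "p": enrich(query, s, uni),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
        df["significant"] = df["p"] < alpha
    return df


# ---------------------------------------------------------------------------
# ranking


def apply_aliases(genes: Iterable[str], alias: Mapping[str, str] | None) -> list[str]:
    """Optional user-supplied identifier conversion (e.g. paralog mapping);
    no mapping is ever applied implicitly."""
    if not alias:
        return list(genes)
    return [alias.get(g, g) for g in genes]


def rank_dnbs(
    dnb_genes: Sequence[str],
    collections: Sequence[GeneSetCollection],
    network: InteractionNetwork | None = None,
    deg_genes: Iterable[str] = (),
    expression_delta: Mapping[str, float] | None = None,
    count_mode: str = "sum",
) -> pd.DataFrame:
    """Rank candidate DNB genes by pathway involvement.

    pathway_count is, per gene, the total number of supplied sets
    containing it summed over the collections (``count_mode="sum"``, the
    default, which reproduces the published ordering) or the number of
    unique set ids across collections (``"union"``).  Ties break by
    linked-DEG count (descending) and then gene id.  ``direction`` is the
    sign of the post-minus-pre tipping mean adjusted expression, when
    supplied.
    """
    if count_mode not in ("sum", "union"):
        raise ValidationError(f"unknown count_mode {count_mode!r}")
    deg_set = set(deg_genes)
    rows = []
    for g in dict.fromkeys(dnb_genes):  # de-duplicate, keep order
        if count_mode == "sum":
            pc = sum(c.membership_count(g) for c in collections)
        else:
            pc = len(
                {f"{c.name}:{s.set_id}" for c in collections for s in c if g in s.genes}
            )
        ldc = linked_deg_count(network, g, deg_set) if network is not None else 0
        delta = expression_delta.get(g) if expression_delta else None
        direction = None
        if delta is not None:
            direction = "up" if delta > 0 else "down"
        rows.append(
            {
                "gene": g,
                "pathway_count": pc,
                "linked_deg_count": ldc,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["pathway_count", "linked_deg_count", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
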