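"""Core domain types shared by every analysis stage.

The pipeline's universal input is an :class:`ExpressionDataset` (a genes x
samples matrix, either raw counts or log2 values) together with a
:class:`SampleSheet` assigning each sample to a treatment group and an
ordered time label.  Gene identifiers are treated as opaque, case-sensitive
strings throughout: no symbol/alias mapping is ever applied silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SampleSheet",
    "GeneSet",
    "GeneSetCollection",
    "InteractionNetwork",
    "PipelineConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant.

    Readers and constructors reject rather than silently repair broken
    inputs (duplicate ids, NaN cells, unannotated samples, ...).
    """


GROUPS = ("treated", "control")


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with an explicit scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  No
        missing entries are allowed.
    scale
        ``"counts"`` (non-negative raw counts) or ``"log2"``.  All DNB and
        differential statistics operate on the log2 scale; counts are
        converted with ``log2(count + 1)`` via :meth:`to_log2`.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.size == 0:
            raise ValidationError("expression matrix is empty")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.scale not in ("counts", "log2"):
            raise ValidationError(f"scale must be 'counts' or 'log2', got {self.scale!r}")
        if self.scale == "counts" and (self.values.values < 0).any():
            raise ValidationError("counts mode requires non-negative values")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_log2(self) -> "ExpressionDataset":
        """Return a log2-scale dataset; counts become log2(count + 1)."""
        if self.scale == "log2":
            return self
        return ExpressionDataset(np.log2(self.values + 1.0), scale="log2")


@dataclass
class SampleSheet:
    """Sample annotation: group membership and ordered time labels.

    Invariants: one row per sample, groups limited to treated/control,
    every treated timepoint carries at least three replicates (the SD and
    correlation statistics are degenerate below that), and the treated
    timepoints form a strictly increasing sequence of length >= 3.
    """

    table: pd.DataFrame  # columns: sample_id, group, time

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "group", "time"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        t = t.copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["group"] = t["group"].astype(str)
        try:
            t["time"] = t["time"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"time labels must be integers: {exc}") from exc
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        bad = sorted(set(t["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group labels: {bad}")
        self.table = t.reset_index(drop=True)
        times = self.treated_times
        if len(times) < 3:
            raise ValidationError("need at least 3 treated timepoints")
        for tp in times:
            if len(self.samples_at("treated", tp)) < 3:
                raise ValidationError(
                    f"treated timepoint {tp} has fewer than 3 replicates"
                )

    @property
    def treated_times(self) -> list[int]:
        ts = sorted(set(self.table.loc[self.table["group"] == "treated", "time"]))
        return [int(t) for t in ts]

    @property
    def control_times(self) -> list[int]:
        ts = sorted(set(self.table.loc[self.table["group"] == "control", "time"]))
        return [int(t) for t in ts]

    def samples_at(self, group: str, time: int | None = None) -> list[str]:
        mask = self.table["group"] == group
        if time is not None:
            mask &= self.table["time"] == int(time)
        return self.table.loc[mask, "sample_id"].tolist()

    def check_matches(self, dataset: ExpressionDataset) -> None:
        """Every matrix sample must be annotated exactly once."""
        annotated = set(self.table["sample_id"])
        unannotated = [s for s in dataset.sample_ids if s not in annotated]
        if unannotated:
            raise ValidationError(f"unannotated sample(s): {unannotated[:5]}")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate set ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def membership_count(self, gene: str) -> int:
        """Number of sets in this collection containing ``gene``."""
        return sum(1 for s in self.sets if gene in s.genes)


class InteractionNetwork:
    """Undirected simple gene-gene interaction graph.

    Thin wrapper over :class:`networkx.Graph` enforcing no self-loops and
    no duplicate edges; edges may carry an optional ``source`` tag.
    """

    def __init__(self, edges: Iterable[tuple] = ()):  # (u, v[, source])
        import networkx as nx

        self.graph = nx.Graph()
        self.n_dropped_self_loops = 0
        for edge in edges:
            u, v = str(edge[0]), str(edge[1])
            source = str(edge[2]) if len(edge) > 2 else None
            if u == v:
                self.n_dropped_self_loops += 1
                continue
            self.graph.add_edge(u, v, source=source)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges()]

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Every tunable of every stage, with defaults that reproduce the
    documented reference behaviour.  Round-trips losslessly through
    ``to_dict``/``from_dict``; unknown keys are errors, not warnings."""

    seed: int = 0
    # synthetic design
    n_genes: int = 500
    module_size: int = 20
    treated_times: tuple[int, ...] = (3, 5, 9, 14, 17)
    reps_treated: int = 5
    control_times: tuple[int, ...] = (3, 9, 17)
    reps_control: int = 3
    tipping_time: int = 9
    rho_in: float = 0.9
    var_fold: float = 3.0
    rho_bg: float = 0.0
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    noise_sd: float = 0.5
    count_mode: bool = False
    dispersion: float = 0.05
    # dnb stage
    min_module_size: int | None = None  # None -> 3x replicate count
    cut_height: float = 0.5
    linkage_method: str = "average"
    n_permutations: int = 200
    alpha_tip: float = 0.05
    pcc_o_eps: float = 1e-6
    control_adjust: str = "pooled"  # pooled | time_matched | none
    # deg stage
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    # toggle stage
    alpha1: float = 3.0
    alpha2: float = 3.0
    beta1: float = 2.0
    beta2: float = 2.0

    def __post_init__(self) -> None:
        self.treated_times = tuple(int(t) for t in self.treated_times)
        self.control_times = tuple(int(t) for t in self.control_times)
        if self.n_permutations < 1:
            raise ValidationError("permutations must be >= 1")
        if not (0 < self.alpha_tip < 1):
            raise ValidationError("alpha_tip must be in (0, 1)")
        if self.control_adjust not in ("pooled", "time_matched", "none"):
            raise ValidationError(f"unknown control_adjust {self.control_adjust!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treated_times"] = list(d["treated_times"])
        d["control_times"] = list(d["control_times"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**dict(d))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
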