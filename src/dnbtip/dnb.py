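"""Dynamic-network-biomarker (DNB) analysis of a treated time series.

A DNB is a dominant group of genes satisfying, at one timepoint, three
criteria relative to the other timepoints: (a) the mean absolute pairwise
Pearson correlation within the group (PCC_i) rises sharply; (b) the mean
absolute correlation between group members and all outside genes (PCC_o)
falls; and (c) the mean replicate standard deviation of the group members
(SD_i) rises sharply.  The three are combined into the composite index

    CI = PCC_i * SD_i / PCC_o

evaluated per timepoint for the dominant candidate module; the timepoint
maximising CI is the tipping-point call, guarded by a permutation test.

Before any statistic is computed, treated samples are centred gene-wise on
the pooled mean of all normal-control samples, so that developmental drift
shared with controls does not masquerade as signal.

The original DNB literature leaves the grouping algorithm open.  Here the
dominant group at each timepoint is found by average-linkage hierarchical
clustering on the dissimilarity 1 - |PCC|, scoring every tree node in a
replicate-scaled size window by CI, and refining the best seeds under the
rank-1 collective-fluctuation model (see :func:`select_dnb`); a classical
fixed-height tree cut remains available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datamodel import ExpressionDataset, SampleSheet, ValidationError

logger = logging.getLogger("dnbtip")

__all__ = [
    "AdjustedMatrix",
    "DnbParams",
    "DnbScore",
    "ModuleCandidate",
    "DnbResult",
    "adjust_to_control",
    "per_time_stats",
    "candidate_modules",
    "composite_index",
    "select_dnb",
    "sample_dispersion",
]


@dataclass
class AdjustedMatrix:
    """Treated-sample log2 expression after gene-wise control centering.

    Adding ``control_means`` back restores the input exactly, so the
    adjustment is lossless.
    """

    values: pd.DataFrame  # genes x treated samples
    control_means: pd.Series  # per-gene mean over all control samples
    sheet: SampleSheet

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    def unadjust(self) -> pd.DataFrame:
        return self.values.add(self.control_means, axis=0)


@dataclass(frozen=True)
class ModuleCandidate:
    genes: tuple[str, ...]
    time: int

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class DnbScore:
    pcc_in: float
    pcc_out: float
    sd_in: float
    ci: float

    def as_dict(self) -> dict:
        return {
            "PCC_i": self.pcc_in,
            "PCC_o": self.pcc_out,
            "SD_i": self.sd_in,
            "CI": self.ci,
        }


@dataclass
class DnbParams:
    """Tunables of the DNB stage (defaults = reference behaviour).

    ``cut_rule`` controls dominant-group discovery: ``"scan"`` (default)
    evaluates the composite index at every node of the clustering tree
    with ``min_size <= size <= max_frac * n_genes`` and picks the CI
    maximiser, which is insensitive to any fixed cut height; ``"height"``
    restricts candidates to the clusters obtained by cutting the tree at
    ``cut_height``.
    """

    min_size: int | None = None  # None -> 3 * replicate count (>= 5)
    cut_rule: str = "scan"
    cut_height: float = 0.5
    max_frac: float = 0.5
    n_seeds: int = 8
    refine: bool = True
    loading_z: float = 2.5
    linkage_method: str = "average"
    n_permutations: int = 200
    alpha_tip: float = 0.05
    eps: float = 1e-6
    seed: int = 0
    early_stop: bool = True
    universe: tuple[str, ...] | None = None  # optional gene-universe restriction

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("permutations must be >= 1")
        if self.min_size is not None and self.min_size < 2:
            raise ValidationError("min_size must be >= 2")
        if self.cut_rule not in ("scan", "height"):
            raise ValidationError(f"unknown cut_rule {self.cut_rule!r}")
        if not 0 < self.max_frac < 1:
            raise ValidationError("max_frac must be in (0, 1)")
        if self.n_seeds < 1:
            raise ValidationError("n_seeds must be >= 1")

    def effective_min_size(self, n_replicates: int) -> int:
        """Default minimum dominant-group size scales with replicates:
        with r-sample correlation estimates, near-perfect |PCC| clusters
        of up to ~3r genes arise purely from selection noise, so smaller
        groups carry no evidential weight."""
        if self.min_size is not None:
            return self.min_size
        return max(5, 3 * n_replicates)


@dataclass
class DnbResult:
    """Per-timepoint dominant module, scores, and the tipping call."""

    times: list[int]
    dominant: dict[int, ModuleCandidate | None]
    scores: dict[int, DnbScore | None]
    tipping_time: int | None
    p_value: float
    permutations_used: int
    criteria_flags: dict[int, dict[str, bool]]
    params: DnbParams

    @property
    def dnb_genes(self) -> tuple[str, ...]:
        """The DNB set: dominant cluster at the called tipping point."""
        if self.tipping_time is None:
            return ()
        cand = self.dominant.get(self.tipping_time)
        return cand.genes if cand is not None else ()

    def ci_table(self) -> pd.DataFrame:
        rows = []
        for t in self.times:
            s = self.scores[t]
            rows.append(
                {
                    "time": t,
                    "PCC_i": s.pcc_in if s else np.nan,
                    "PCC_o": s.pcc_out if s else np.nan,
                    "SD_i": s.sd_in if s else np.nan,
                    "CI": s.ci if s else np.nan,
                    "module_size": self.dominant[t].size if self.dominant[t] else 0,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# control adjustment


def adjust_to_control(
    dataset: ExpressionDataset,
    sheet: SampleSheet,
    mode: str = "pooled",
) -> AdjustedMatrix:
    """Centre treated samples gene-wise on the control mean.

    ``mode="pooled"`` (default) subtracts the per-gene mean over ALL
    control samples, pooled across their timepoints.  ``"time_matched"``
    subtracts the control mean of the nearest control timepoint instead.
    ``"none"`` must be requested explicitly and performs no centering.
    """
    ds = dataset.to_log2()
    sheet.check_matches(ds)
    treated = sheet.samples_at("treated")
    treated = [s for s in treated if s in ds.values.columns]
    controls = [s for s in sheet.samples_at("control") if s in ds.values.columns]
    if mode == "none":
        zero = pd.Series(0.0, index=ds.values.index)
        return AdjustedMatrix(ds.values[treated].copy(), zero, sheet)
    if not controls:
        raise ValidationError(
            "no control samples; request mode='none' explicitly to skip adjustment"
        )
    if mode == "pooled":
        means = ds.values[controls].mean(axis=1)
        adj = ds.values[treated].sub(means, axis=0)
        return AdjustedMatrix(adj, means, sheet)
    if mode == "time_matched":
        ctimes = np.array(sheet.control_times)
        adj = ds.values[treated].copy()
        pooled = ds.values[controls].mean(axis=1)
        for s in treated:
            t = int(sheet.table.set_index("sample_id").loc[s, "time"])
            nearest = int(ctimes[np.argmin(np.abs(ctimes - t))])
            csamp = [c for c in sheet.samples_at("control", nearest) if c in ds.values.columns]
            adj[s] = ds.values[s] - ds.values[csamp].mean(axis=1)
        return AdjustedMatrix(adj, pooled, sheet)
    raise ValidationError(f"unknown adjustment mode {mode!r}")


# ---------------------------------------------------------------------------
# per-timepoint statistics (array core + labelled wrapper)


def _stats_arrays(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SD (ddof=1) per row and |Pearson| matrix across columns of ``block``.

    Constant rows get sd 0 and all their correlations mapped to 0.
    """
    n = block.shape[1]
    if n < 3:
        raise ValidationError(f"need >= 3 replicates, got {n}")
    mean = block.mean(axis=1, keepdims=True)
    centred = block - mean
    ss = np.einsum("ij,ij->i", centred, centred)
    sd = np.sqrt(ss / (n - 1))
    norm = np.sqrt(ss)
    safe = norm.copy()
    constant = norm == 0
    safe[constant] = 1.0
    z = centred / safe[:, None]
    corr = np.abs(z @ z.T)
    np.clip(corr, 0.0, 1.0, out=corr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    if constant.any():
        logger.debug("%d constant gene(s): correlations set to 0", int(constant.sum()))
    return sd, corr


def per_time_stats(
    adj: AdjustedMatrix, sheet: SampleSheet, time: int
) -> tuple[pd.Series, pd.DataFrame]:
    """Replicate SD per gene and absolute Pearson correlation matrix at
    one treated timepoint."""
    samples = [s for s in sheet.samples_at("treated", time) if s in adj.values.columns]
    if len(samples) < 3:
        raise ValidationError(f"timepoint {time}: fewer than 3 treated replicates")
    block = adj.values[samples].to_numpy()
    sd, corr = _stats_arrays(block)
    genes = adj.values.index
    return pd.Series(sd, index=genes), pd.DataFrame(corr, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# module discovery


def _cluster_indices(
    corr: np.ndarray, min_size: int, cut_height: float, method: str
) -> list[np.ndarray]:
    """Index sets of clusters of size >= min_size under the tree cut."""
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    labels = fcluster(linkage(condensed, method=method), t=cut_height, criterion="distance")
    out = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size >= min_size:
            out.append(idx)
    return out


def candidate_modules(
    adj: AdjustedMatrix,
    sheet: SampleSheet,
    time: int,
    min_size: int = 5,
    linkage_method: str = "average",
    cut_height: float = 0.5,
) -> list[ModuleCandidate]:
    """Candidate dominant groups at one timepoint.

    Average-linkage hierarchical clustering on 1 - |PCC|, tree cut at
    ``cut_height``; clusters of at least ``min_size`` genes are returned,
    ordered (and internally sorted) lexicographically so the output is
    deterministic regardless of input order.
    """
    _, corr = per_time_stats(adj, sheet, time)
    genes = np.asarray(adj.values.index, dtype=object)
    clusters = _cluster_indices(corr.to_numpy(), min_size, cut_height, linkage_method)
    cands = [
        ModuleCandidate(tuple(sorted(str(g) for g in genes[idx])), int(time))
        for idx in clusters
    ]
    return sorted(cands, key=lambda c: c.genes)


# ---------------------------------------------------------------------------
# composite index


def _score_from_arrays(
    sd: np.ndarray, corr: np.ndarray, idx: np.ndarray, eps: float
) -> DnbScore:
    m = idx.size
    n = corr.shape[0]
    if m < 2:
        raise ValidationError("module needs >= 2 genes")
    if m >= n:
        raise ValidationError("module covers all genes; PCC_o undefined")
    sub = corr[np.ix_(idx, idx)]
    within_sum = sub.sum() - np.trace(sub)
    pcc_in = within_sum / (m * (m - 1))
    row_tot = corr[idx].sum()
    pcc_out = (row_tot - sub.sum()) / (m * (n - m))
    sd_in = float(sd[idx].mean())
    ci = pcc_in * sd_in / max(pcc_out, eps)
    return DnbScore(float(pcc_in), float(pcc_out), sd_in, float(ci))


def composite_index(
    adj: AdjustedMatrix,
    sheet: SampleSheet,
    module: tuple[str, ...] | list[str] | ModuleCandidate,
    time: int,
    eps: float = 1e-6,
) -> DnbScore:
    """CI = PCC_i * SD_i / max(PCC_o, eps) for one module at one timepoint.

    PCC_i averages |PCC| over unordered within-module pairs, PCC_o over all
    module x outside pairs, SD_i averages the replicate SD over module
    genes.
    """
    genes = module.genes if isinstance(module, ModuleCandidate) else tuple(module)
    sd, corr = per_time_stats(adj, sheet, time)
    pos = {g: i for i, g in enumerate(adj.values.index)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValidationError(f"module gene(s) not in dataset: {missing[:5]}")
    idx = np.array([pos[g] for g in genes])
    return _score_from_arrays(sd.to_numpy(), corr.to_numpy(), idx, eps)


# ---------------------------------------------------------------------------
# full selection with permutation guard


def _scan_tree(
    sd: np.ndarray, corr: np.ndarray, params: DnbParams, min_size: int
) -> list[np.ndarray]:
    """Top candidate nodes (by CI) among all clustering-tree nodes in the
    size window.

    Walks the average-linkage merge tree once, maintaining per-cluster
    row-sum vectors so that every node's PCC_i, PCC_o and SD_i are
    available in O(n) per merge (O(n^2) total).  Returns up to
    ``params.n_seeds`` member-index arrays ordered by decreasing CI.
    """
    n = corr.shape[0]
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=params.linkage_method)
    max_size = max(min_size, int(params.max_frac * n))
    rowsum: dict[int, np.ndarray] = {i: corr[i] for i in range(n)}
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    within = np.zeros(2 * n - 1)  # sum of off-diagonal entries, both orders
    sumsd = np.zeros(2 * n - 1)
    sumsd[:n] = sd
    sizes = np.ones(2 * n - 1, dtype=int)
    scored: list[tuple[float, np.ndarray]] = []
    for k in range(Z.shape[0]):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        nid = n + k
        cross = float(rowsum[a][members[b]].sum())
        within[nid] = within[a] + within[b] + 2.0 * cross
        rowsum[nid] = rowsum[a] + rowsum[b]
        members[nid] = np.concatenate([members[a], members[b]])
        sizes[nid] = sizes[a] + sizes[b]
        sumsd[nid] = sumsd[a] + sumsd[b]
        del rowsum[a], rowsum[b], members[a], members[b]
        m = int(sizes[nid])
        if min_size <= m <= max_size:
            pcc_in = within[nid] / (m * (m - 1))
            out_sum = rowsum[nid].sum() - within[nid] - m  # minus diagonal
            pcc_out = out_sum / (m * (n - m))
            sd_in = sumsd[nid] / m
            ci = pcc_in * sd_in / max(pcc_out, params.eps)
            scored.append((float(ci), members[nid]))
    scored.sort(key=lambda t: -t[0])
    return [mem for _, mem in scored[: params.n_seeds]]


def _factor_refine(
    centred: np.ndarray, seed_idx: np.ndarray, params: DnbParams, min_size: int,
    max_iter: int = 15,
) -> np.ndarray:
    """Refine a seed cluster under the collective-fluctuation model.

    A DNB module is a rank-1 co-fluctuation: members share one latent
    factor, so membership evidence per gene is its loading (projection of
    the centred replicate profile onto the module's dominant factor) --
    the product of correlation and standard deviation, exactly what
    separates true members from genes that merely chance-correlate with
    the factor at this replicate count.  Iterates: estimate the factor
    from current members (top right singular vector), score all genes,
    keep genes whose |loading| exceeds ``loading_z`` robust (MAD-based)
    standard scores of the all-gene loading distribution; the size window
    is enforced by truncation at the loading order statistic.
    """
    n = centred.shape[0]
    cap = max(min_size, int(params.max_frac * n))
    current = np.sort(np.asarray(seed_idx))
    seen: set[tuple[int, ...]] = set()
    for _ in range(max_iter):
        _, _, vt = np.linalg.svd(centred[current], full_matrices=False)
        loading = centred @ vt[0]
        scale = np.median(np.abs(loading)) / 0.6745
        if scale <= 0:
            break
        new = np.flatnonzero(np.abs(loading) >= params.loading_z * scale)
        if new.size < min_size:
            new = np.argsort(-np.abs(loading))[:min_size]
        elif new.size > cap:
            new = np.argsort(-np.abs(loading))[:cap]
        new = np.sort(new)
        key = tuple(new)
        if key == tuple(current) or key in seen:
            current = new
            break
        seen.add(tuple(current))
        current = new
    return current


def _dominant_ci(
    block: np.ndarray, params: DnbParams
) -> tuple[float, np.ndarray | None, DnbScore | None]:
    """Max-CI dominant group at one timepoint from its replicate block."""
    sd, corr = _stats_arrays(block)
    min_size = params.effective_min_size(block.shape[1])
    n = block.shape[0]
    if params.cut_rule == "scan":
        seeds = _scan_tree(sd, corr, params, min_size)
        if not seeds:
            return 0.0, None, None
        if params.refine:
            centred = block - block.mean(axis=1, keepdims=True)
            candidates = {tuple(_factor_refine(centred, s, params, min_size)) for s in seeds}
            candidates |= {tuple(s) for s in seeds[:1]}  # keep the raw best node
        else:
            candidates = {tuple(s) for s in seeds}
        best_ci, best_idx, best_score = -np.inf, None, None
        for cand in candidates:
            idx = np.asarray(cand)
            if not (2 <= idx.size < n):
                continue
            score = _score_from_arrays(sd, corr, idx, params.eps)
            if score.ci > best_ci:
                best_ci, best_idx, best_score = score.ci, idx, score
        if best_idx is None:
            return 0.0, None, None
        return best_ci, best_idx, best_score
    clusters = _cluster_indices(
        corr, min_size, params.cut_height, params.linkage_method
    )
    best_ci, best_idx, best_score = -np.inf, None, None
    for idx in clusters:
        if idx.size >= n:
            continue
        score = _score_from_arrays(sd, corr, idx, params.eps)
        if score.ci > best_ci:
            best_ci, best_idx, best_score = score.ci, idx, score
    if best_idx is None:
        return 0.0, None, None
    return best_ci, best_idx, best_score


def select_dnb(
    adj: AdjustedMatrix, sheet: SampleSheet, params: DnbParams | None = None
) -> DnbResult:
    """Full DNB selection: dominant module and CI per timepoint, tipping
    call at the CI argmax guarded by a permutation test.

    The permutation null re-runs the entire discovery (clustering and
    refinement included) after independently permuting each gene's
    replicate values across all treated samples.  The permutation is
    block-constrained when the design is balanced: each gene's
    per-timepoint replicate blocks are shuffled across timepoints and the
    replicate order inside each relocated block is re-shuffled.  This
    destroys all cross-gene, time-localised co-fluctuation while
    preserving each gene's marginal distribution AND its multiset of
    per-timepoint variances (an unconstrained per-gene shuffle would
    scatter heavy values across timepoints and manufacture spurious
    outlier-coincidence correlations, inflating the null).
    p = (1 + #{null max-CI >= observed max-CI}) / (N + 1); the tipping
    time is reported only when p < alpha_tip.  Ties in CI across
    timepoints break toward the earliest timepoint (conservative early
    warning).
    """
    params = params or DnbParams()
    times = sheet.treated_times
    if len(times) < 3:
        raise ValidationError("need >= 3 treated timepoints")

    values = adj.values
    if params.universe is not None:
        keep = [g for g in values.index if g in set(params.universe)]
        if len(keep) < params.min_size + 1:
            raise ValidationError("universe restriction leaves too few genes")
        values = values.loc[keep]
    genes = np.asarray(values.index, dtype=object)

    sample_cols: dict[int, list[int]] = {}
    col_pos = {s: i for i, s in enumerate(values.columns)}
    for t in times:
        cols = [col_pos[s] for s in sheet.samples_at("treated", t) if s in col_pos]
        if len(cols) < 3:
            raise ValidationError(f"timepoint {t}: fewer than 3 treated replicates")
        sample_cols[t] = cols
    mat = values.to_numpy()

    dominant: dict[int, ModuleCandidate | None] = {}
    scores: dict[int, DnbScore | None] = {}
    module_idx: dict[int, np.ndarray | None] = {}
    for t in times:
        ci, idx, score = _dominant_ci(mat[:, sample_cols[t]], params)
        module_idx[t] = idx
        dominant[t] = (
            ModuleCandidate(tuple(sorted(str(g) for g in genes[idx])), int(t))
            if idx is not None
            else None
        )
        scores[t] = score

    ci_by_time = np.array([scores[t].ci if scores[t] else 0.0 for t in times])
    best_pos = int(np.argmax(ci_by_time))  # argmax; ties -> earliest
    t_star = times[best_pos]
    observed = float(ci_by_time[best_pos])

    # permutation null on the max-over-timepoints statistic
    rng = np.random.default_rng(params.seed)
    n_perm = params.n_permutations
    fail_at = math.ceil(params.alpha_tip * (n_perm + 1))  # p >= alpha once reached
    exceed = 0
    used = 0
    n_eff = mat.shape[0]
    cols_by_time = [np.asarray(sample_cols[t]) for t in times]
    rep_counts = {c.size for c in cols_by_time}
    balanced = len(rep_counts) == 1
    if balanced:
        n_rep = cols_by_time[0].size
        colmat = np.stack(cols_by_time)  # timepoints x replicates
    gene_rows = np.arange(n_eff)[:, None, None]
    for _ in range(n_perm):
        if balanced:
            block_perm = np.argsort(rng.random((n_eff, len(times))), axis=1)
            within = np.argsort(rng.random((n_eff, len(times), n_rep)), axis=2)
            src = colmat[block_perm[:, :, None], within]
            perm_vals = mat[gene_rows, src]  # genes x timepoints x replicates
            null_max = max(
                _dominant_ci(perm_vals[:, ti, :], params)[0]
                for ti in range(len(times))
            )
        else:  # unbalanced designs: unconstrained per-gene shuffle
            order = np.argsort(rng.random(mat.shape), axis=1)
            perm = np.take_along_axis(mat, order, axis=1)
            null_max = max(
                _dominant_ci(perm[:, sample_cols[t]], params)[0] for t in times
            )
        used += 1
        if null_max >= observed:
            exceed += 1
            if params.early_stop and exceed >= fail_at:
                break
    p_value = (1 + exceed) / (used + 1)
    tipping = t_star if (p_value < params.alpha_tip and scores[t_star]) else None

    # three DNB criteria per timepoint: the timepoint's dominant module,
    # compared against the mean of the same module's stats elsewhere
    stats_cache = {t: _stats_arrays(mat[:, sample_cols[t]]) for t in times}
    flags: dict[int, dict[str, bool]] = {}
    for t in times:
        idx = module_idx[t]
        if idx is None:
            flags[t] = {"pcc_in_up": False, "pcc_out_down": False, "sd_up": False}
            continue
        per_t = {
            u: _score_from_arrays(*stats_cache[u], idx, params.eps) for u in times
        }
        others = [u for u in times if u != t]
        mean_in = float(np.mean([per_t[u].pcc_in for u in others]))
        mean_out = float(np.mean([per_t[u].pcc_out for u in others]))
        mean_sd = float(np.mean([per_t[u].sd_in for u in others]))
        flags[t] = {
            "pcc_in_up": per_t[t].pcc_in > mean_in,
            "pcc_out_down": per_t[t].pcc_out < mean_out,
            "sd_up": per_t[t].sd_in > mean_sd,
        }

    return DnbResult(
        times=list(times),
        dominant=dominant,
        scores=scores,
        tipping_time=tipping,
        p_value=float(p_value),
        permutations_used=used,
        criteria_flags=flags,
        params=params,
    )


# ---------------------------------------------------------------------------
# QC: replicate dispersion per timepoint


def sample_dispersion(adj: AdjustedMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Mean pairwise Euclidean distance between replicate profiles, per
    treated timepoint.  Dispersed (non-clustering) replicates at a single
    timepoint are the sample-level signature of a critical state."""
    rows = []
    for t in sheet.treated_times:
        samples = [s for s in sheet.samples_at("treated", t) if s in adj.values.columns]
        if len(samples) < 2:
            raise ValidationError(f"timepoint {t}: need >= 2 replicates")
        block = adj.values[samples].to_numpy().T  # samples x genes
        dists = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                dists.append(float(np.linalg.norm(block[i] - block[j])))
        rows.append({"time": t, "mean_pairwise_distance": float(np.mean(dists))})
    return pd.DataFrame(rows)
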