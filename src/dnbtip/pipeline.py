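"""End-to-end orchestration: simulate -> DNB -> DEG -> rank -> toggle.

One :class:`~dnbtip.datamodel.PipelineConfig` plus a single seed drives a
fully reproducible run; the top-level seed is expanded deterministically
into independent per-stage seeds, every active tunable is logged, and the
consolidated JSON report embeds the CI table, the DNB member list, the DEG
summary, the ranking and the toggle analysis together with the config hash
and seeds so a run is auditable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as dio
from .datamodel import PipelineConfig, ValidationError
from .deg import differential_around_tipping, intersect_dnb_deg, write_deg_table
from .dnb import DnbParams, adjust_to_control, sample_dispersion, select_dnb
from .ranking import published_count_collections, rank_dnbs
from .simulate import SimulationDesign, simulate_expression, simulate_network
from .toggle import ToggleParams, bifurcation_scan, fixed_points, is_bistable

logger = logging.getLogger("dnbtip")

__all__ = ["RunManifest", "run_pipeline", "stage_seeds"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)
    wall_time: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "outputs": self.outputs,
            "wall_time_s": {k: round(v, 3) for k, v in self.wall_time.items()},
        }


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "dnb", "network"]
    states = ss.generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, states)}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> tuple[RunManifest, dict]:
    """Execute all stages in dependency order on a simulated dataset.

    Any stage failure aborts with the failing stage named.  When
    ``outdir`` is given, per-stage TSV outputs and the consolidated JSON
    report are written there.
    """
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(config.config_hash(), config.seed, seeds)
    report: dict = {
        "schema_version": 1,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
    }
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _run(stage: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise ValidationError(f"stage '{stage}' failed: {exc}") from exc
        manifest.wall_time[stage] = time.perf_counter() - t0
        return result

    # -- simulate ----------------------------------------------------------
    def _simulate():
        design = SimulationDesign(
            n_genes=config.n_genes,
            module_size=config.module_size,
            treated_times=config.treated_times,
            reps_treated=config.reps_treated,
            control_times=config.control_times,
            reps_control=config.reps_control,
            tipping_time=config.tipping_time,
            rho_in=config.rho_in,
            var_fold=config.var_fold,
            rho_bg=config.rho_bg,
            de_fraction=config.de_fraction,
            de_log2fc=config.de_log2fc,
            noise_sd=config.noise_sd,
            count_mode=config.count_mode,
            dispersion=config.dispersion,
            seed=seeds["simulate"],
        )
        return simulate_expression(design)

    dataset, sheet, truth = _run("simulate", _simulate)
    report["truth"] = truth.to_dict()

    # -- dnb ---------------------------------------------------------------
    def _dnb():
        adj = adjust_to_control(dataset, sheet, mode=config.control_adjust)
        params = DnbParams(
            min_size=config.min_module_size,
            cut_height=config.cut_height,
            linkage_method=config.linkage_method,
            n_permutations=config.n_permutations,
            alpha_tip=config.alpha_tip,
            eps=config.pcc_o_eps,
            seed=seeds["dnb"],
        )
        logger.info(
            "dnb stage: min_size=%d cut=%.3g linkage=%s perms=%d alpha=%.3g eps=%.1e adjust=%s",
            params.min_size, params.cut_height, params.linkage_method,
            params.n_permutations, params.alpha_tip, params.eps,
            config.control_adjust,
        )
        return adj, select_dnb(adj, sheet, params)

    adj, dnb_result = _run("dnb", _dnb)
    report["dnb"] = {
        "ci_table": dnb_result.ci_table().to_dict(orient="records"),
        "tipping_time": dnb_result.tipping_time,
        "p_value": dnb_result.p_value,
        "permutations_used": dnb_result.permutations_used,
        "dnb_genes": list(dnb_result.dnb_genes),
        "criteria_flags": {str(t): f for t, f in dnb_result.criteria_flags.items()},
        "dispersion": sample_dispersion(adj, sheet).to_dict(orient="records"),
    }

    # -- deg ---------------------------------------------------------------
    t_ref = dnb_result.tipping_time if dnb_result.tipping_time is not None else truth.tipping_time
    deg_table = _run(
        "deg",
        lambda: differential_around_tipping(
            dataset, sheet, t_ref, config.lfc_threshold, config.fdr_threshold
        ),
    )
    common, counts = intersect_dnb_deg(deg_table, dnb_result.dnb_genes)
    report["deg"] = {
        "reference_time": t_ref,
        "n_passing": int(deg_table["passed"].sum()),
        "intersection_with_dnb": common,
        "counts": counts,
    }

    # -- rank --------------------------------------------------------------
    def _rank():
        deg_genes = set(deg_table.loc[deg_table["passed"], "gene"])
        link_spec = {g: min(3, max(1, len(truth.de_genes) - 1)) for g in truth.module_genes}
        network = simulate_network(
            truth, n_extra_edges=5 * config.n_genes, seed=seeds["network"],
            link_spec=link_spec,
        )
        collections = published_count_collections()
        after = [s for t in sheet.treated_times if t > t_ref for s in sheet.samples_at("treated", t)]
        before = [s for t in sheet.treated_times if t < t_ref for s in sheet.samples_at("treated", t)]
        delta = (adj.values[after].mean(axis=1) - adj.values[before].mean(axis=1)).to_dict()
        genes = list(dnb_result.dnb_genes) or list(truth.module_genes)
        return rank_dnbs(genes, collections, network, deg_genes, delta)

    ranking = _run("rank", _rank)
    report["ranking"] = ranking.to_dict(orient="records")

    # -- toggle ------------------------------------------------------------
    def _toggle():
        params = ToggleParams(config.alpha1, config.alpha2, config.beta1, config.beta2)
        fps = fixed_points(params)
        out = {
            "params": {"alpha1": params.alpha1, "alpha2": params.alpha2,
                       "beta1": params.beta1, "beta2": params.beta2},
            "fixed_points": [
                {"x": fp.x, "y": fp.y, "stability": fp.stability,
                 "eigenvalues_real": [fp.eigenvalues[0].real, fp.eigenvalues[1].real]}
                for fp in fps
            ],
            "bistable": is_bistable(params),
        }
        if params.alpha1 == params.alpha2 and params.beta1 == params.beta2:
            out["critical_alpha"] = bifurcation_scan(params.beta1)
        return out

    report["toggle"] = _run("toggle", _toggle)

    # -- outputs -----------------------------------------------------------
    if outdir is not None:
        dio.write_expression(dataset, outdir / "expression.tsv")
        dio.write_sample_sheet(sheet, outdir / "samples.tsv")
        dnb_result.ci_table().to_csv(outdir / "ci_table.tsv", sep="\t", index=False)
        write_deg_table(deg_table, outdir / "deg_table.tsv")
        ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
        dio.write_report(report, outdir / "report.json")
        manifest.outputs = {
            "expression": str(outdir / "expression.tsv"),
            "samples": str(outdir / "samples.tsv"),
            "ci_table": str(outdir / "ci_table.tsv"),
            "deg_table": str(outdir / "deg_table.tsv"),
            "ranking": str(outdir / "ranking.tsv"),
            "report": str(outdir / "report.json"),
        }
        dio.write_report(manifest.to_dict(), outdir / "manifest.json")
    return manifest, report
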