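import numpy as np
import pandas as pd
import pytest

from dnbtip.datamodel import ExpressionDataset, ValidationError
from dnbtip.dnb import (
    DnbParams,
    adjust_to_control,
    candidate_modules,
    composite_index,
    per_time_stats,
    sample_dispersion,
    select_dnb,
)
from dnbtip.simulate import SimulationDesign, simulate_expression

TIMES3 = [1, 2, 3]


def brute_force_ci(values, module_idx, eps=1e-6):
    """Independent oracle: enumerate all gene pairs explicitly."""
    n = values.shape[0]
    sds = [np.std(values[i], ddof=1) for i in range(n)]
    inside = list(module_idx)
    outside = [i for i in range(n) if i not in module_idx]

    def abs_corr(i, j):
        r = np.corrcoef(values[i], values[j])[0, 1]
        return 0.0 if np.isnan(r) else abs(r)

    in_pairs = [abs_corr(a, b) for k, a in enumerate(inside) for b in inside[k + 1:]]
    out_pairs = [abs_corr(a, b) for a in inside for b in outside]
    pcc_i = float(np.mean(in_pairs))
    pcc_o = float(np.mean(out_pairs))
    sd_i = float(np.mean([sds[i] for i in inside]))
    return pcc_i, pcc_o, sd_i, pcc_i * sd_i / max(pcc_o, eps)


class TestAdjustToControl:
    def _dataset(self, treated, controls, sheet_factory):
        sheet = sheet_factory(TIMES3, 3, control_times=[1, 3], reps_control=3)
        tcols = [f"T{t:02d}_r{r + 1}" for t in TIMES3 for r in range(3)]
        ccols = [f"C{t:02d}_r{r + 1}" for t in [1, 3] for r in range(3)]
        values = pd.DataFrame(
            np.hstack([treated, controls]),
            index=[f"g{i}" for i in range(treated.shape[0])],
            columns=tcols + ccols,
        )
        return ExpressionDataset(values), sheet

    def test_treated_equal_to_control_mean_gives_zero(self, sheet_factory):
        treated = np.full((2, 9), 5.0)
        controls = np.full((2, 6), 5.0)
        ds, sheet = self._dataset(treated, controls, sheet_factory)
        adj = adjust_to_control(ds, sheet)
        assert np.allclose(adj.values.values, 0.0)

    def test_pooled_mean_arithmetic(self, sheet_factory):
        # controls {2, 4} -> mean 3; treated 5 -> adjusted 2
        treated = np.full((1, 9), 5.0)
        controls = np.array([[2.0, 2.0, 2.0, 4.0, 4.0, 4.0]])
        ds, sheet = self._dataset(treated, controls, sheet_factory)
        adj = adjust_to_control(ds, sheet)
        assert np.allclose(adj.values.values, 2.0)

    def test_round_trip_restores_input(self, sheet_factory):
        rng = np.random.default_rng(3)
        ds, sheet = self._dataset(
            rng.normal(6, 1, (10, 9)), rng.normal(6, 1, (10, 6)), sheet_factory
        )
        adj = adjust_to_control(ds, sheet)
        treated_cols = [s for s in sheet.samples_at("treated") if s in ds.values.columns]
        restored = adj.unadjust()
        assert np.max(np.abs(restored.values - ds.values[treated_cols].values)) < 1e-12

    def test_no_controls_requires_explicit_none_mode(self, sheet_factory):
        sheet = sheet_factory(TIMES3, 3)
        cols = [f"T{t:02d}_r{r + 1}" for t in TIMES3 for r in range(3)]
        ds = ExpressionDataset(
            pd.DataFrame(np.ones((2, 9)), index=["g1", "g2"], columns=cols)
        )
        with pytest.raises(ValidationError, match="control"):
            adjust_to_control(ds, sheet)
        adj = adjust_to_control(ds, sheet, mode="none")
        assert np.allclose(adj.values.values, 1.0)


class TestPerTimeStats:
    def test_sd_and_pcc_arithmetic(self, adjusted_factory):
        # g1=(1,2,3) -> sd 1; g2=2*g1 -> |PCC|=1; g3=(1,1,2) vs g1 -> 0.8660
        rows = np.array(
            [
                [1, 2, 3, 0, 0, 0, 0, 0, 0],
                [2, 4, 6, 0, 0, 0, 0, 0, 0],
                [1, 1, 2, 0, 0, 0, 0, 0, 0],
            ],
            dtype=float,
        )
        rows[:, 3:] = np.random.default_rng(0).normal(size=(3, 6))
        adj = adjusted_factory(rows, TIMES3, 3)
        sd, corr = per_time_stats(adj, adj.sheet, 1)
        assert sd.iloc[0] == pytest.approx(1.0)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(0.8660, abs=1e-4)

    def test_constant_gene_maps_to_zero(self, adjusted_factory):
        rows = np.vstack([np.arange(9, dtype=float), np.full(9, 7.0)])
        adj = adjusted_factory(rows, TIMES3, 3)
        sd, corr = per_time_stats(adj, adj.sheet, 2)
        assert sd.iloc[1] == 0.0
        assert corr.iloc[0, 1] == 0.0

    def test_too_few_replicates_rejected(self, adjusted_factory):
        adj = adjusted_factory(np.ones((2, 9)), TIMES3, 3)
        with pytest.raises(ValidationError):
            per_time_stats(adj, adj.sheet, 99)


class TestCompositeIndex:
    def test_worked_example(self, adjusted_factory):
        # module {g1=(1,2,3), g2=(2,4,6)}, outside {g3=(1,1,2)}:
        # PCC_i=1, SD_i=1.5, PCC_o=0.8660, CI=1.7321
        rows = np.zeros((3, 9))
        rows[0, :3] = [1, 2, 3]
        rows[1, :3] = [2, 4, 6]
        rows[2, :3] = [1, 1, 2]
        rows[:, 3:] = np.random.default_rng(1).normal(size=(3, 6))
        adj = adjusted_factory(rows, TIMES3, 3)
        score = composite_index(adj, adj.sheet, ["g001", "g002"], 1)
        assert score.pcc_in == pytest.approx(1.0)
        assert score.sd_in == pytest.approx(1.5)
        assert score.pcc_out == pytest.approx(0.8660, abs=1e-4)
        assert score.ci == pytest.approx(1.7321, abs=1e-4)

    def test_constant_module_ci_zero(self, adjusted_factory):
        rows = np.vstack([np.full(9, 2.0), np.full(9, 3.0), np.arange(9, dtype=float)])
        adj = adjusted_factory(rows, TIMES3, 3)
        score = composite_index(adj, adj.sheet, ["g001", "g002"], 1)
        assert score.sd_in == 0.0
        assert score.ci == 0.0

    def test_eps_guard_when_outside_uncorrelated(self, adjusted_factory):
        rows = np.zeros((3, 9))
        rows[0, :3] = [1, 2, 3]
        rows[1, :3] = [2, 4, 6]
        rows[2, :3] = [5, 5, 5]  # constant outside gene -> |PCC| mapped to 0
        rows[:, 3:] = np.random.default_rng(2).normal(size=(3, 6))
        adj = adjusted_factory(rows, TIMES3, 3)
        score = composite_index(adj, adj.sheet, ["g001", "g002"], 1, eps=1e-6)
        assert np.isfinite(score.ci)
        assert score.ci == pytest.approx(score.pcc_in * score.sd_in / 1e-6)

    def test_module_covering_all_genes_rejected(self, adjusted_factory):
        adj = adjusted_factory(np.random.default_rng(0).normal(size=(3, 9)), TIMES3, 3)
        with pytest.raises(ValidationError):
            composite_index(adj, adj.sheet, ["g001", "g002", "g003"], 1)

    def test_matches_brute_force_on_random_fixtures(self, adjusted_factory):
        """CI exactness: pair-enumeration oracle agreement to 1e-10 on
        random 20-gene fixtures."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            rows = rng.normal(size=(20, 15))
            adj = adjusted_factory(rows, TIMES3, 5)
            module = [f"g{i + 1:03d}" for i in rng.choice(20, size=6, replace=False)]
            idx = [int(m[1:]) - 1 for m in module]
            score = composite_index(adj, adj.sheet, module, 2)
            cols = adj.sheet.samples_at("treated", 2)
            exp = brute_force_ci(adj.values[cols].to_numpy(), idx)
            assert score.pcc_in == pytest.approx(exp[0], abs=1e-10)
            assert score.pcc_out == pytest.approx(exp[1], abs=1e-10)
            assert score.sd_in == pytest.approx(exp[2], abs=1e-10)
            assert score.ci == pytest.approx(exp[3], abs=1e-10)

    def test_scale_equivariance(self, adjusted_factory):
        """Multiplying expression by c scales SD_i and CI by c and leaves
        the correlations unchanged."""
        rng = np.random.default_rng(11)
        rows = rng.normal(size=(12, 9))
        module = ["g001", "g002", "g003"]
        a = composite_index(adjusted_factory(rows, TIMES3, 3),
                            adjusted_factory(rows, TIMES3, 3).sheet, module, 1)
        c = 3.7
        b = composite_index(adjusted_factory(c * rows, TIMES3, 3),
                            adjusted_factory(c * rows, TIMES3, 3).sheet, module, 1)
        assert b.pcc_in == pytest.approx(a.pcc_in, abs=1e-10)
        assert b.pcc_out == pytest.approx(a.pcc_out, abs=1e-10)
        assert b.sd_in == pytest.approx(c * a.sd_in, rel=1e-10)
        assert b.ci == pytest.approx(c * a.ci, rel=1e-10)


class TestCandidateModules:
    def _two_block_fixture(self, adjusted_factory):
        """Two perfectly co-fluctuating blocks of 10 genes, 30 noise
        genes, 15 replicates (so chance |PCC| stays far from 1)."""
        rng = np.random.default_rng(5)
        n_noise, reps = 30, 15
        base1 = rng.normal(size=reps)
        base2 = rng.normal(size=reps)
        rows = []
        for k in range(10):
            rows.append(2.0 * base1 + k)  # identical profile, shifted
        for k in range(10):
            rows.append(-1.5 * base2 + k)
        rows.extend(rng.normal(size=(n_noise, reps)))
        full = np.hstack([np.asarray(rows), rng.normal(size=(50, 2 * reps))])
        return adjusted_factory(full, TIMES3, reps)

    def test_two_blocks_recovered(self, adjusted_factory):
        adj = self._two_block_fixture(adjusted_factory)
        cands = candidate_modules(adj, adj.sheet, 1, min_size=5, cut_height=0.3)
        sets = [set(c.genes) for c in cands]
        block1 = {f"g{i + 1:03d}" for i in range(10)}
        block2 = {f"g{i + 1:03d}" for i in range(10, 20)}
        assert block1 in sets
        assert block2 in sets
        assert len(cands) == 2

    def test_min_size_two_keeps_blocks(self, adjusted_factory):
        adj = self._two_block_fixture(adjusted_factory)
        cands = candidate_modules(adj, adj.sheet, 1, min_size=2, cut_height=0.3)
        sets = [set(c.genes) for c in cands]
        assert {f"g{i + 1:03d}" for i in range(10)} in sets
        assert {f"g{i + 1:03d}" for i in range(10, 20)} in sets

    def test_iid_noise_large_min_size_empty(self, adjusted_factory):
        rng = np.random.default_rng(9)
        adj = adjusted_factory(rng.normal(size=(20, 9)), TIMES3, 3)
        assert candidate_modules(adj, adj.sheet, 1, min_size=20) == []


class TestSelectDnb:
    def test_hand_computed_fixture_tips_at_second_time(self, adjusted_factory):
        """One co-fluctuating, variance-inflated module at t2 of 3; CI by
        direct arithmetic is maximal there, and the permutation test
        confirms it."""
        rng = np.random.default_rng(21)
        n, reps = 60, 5
        rows = rng.normal(0, 0.3, size=(n, 3 * reps))
        factor = rng.normal(size=reps)
        for g in range(12):
            rows[g, reps:2 * reps] = 2.0 * factor + 0.1 * rng.normal(size=reps)
        adj = adjusted_factory(rows, TIMES3, reps)
        params = DnbParams(min_size=5, n_permutations=99, seed=0)
        res = select_dnb(adj, adj.sheet, params)
        cis = {t: res.scores[t].ci for t in res.times if res.scores[t]}
        assert max(cis, key=cis.get) == 2
        assert res.tipping_time == 2
        assert res.p_value < 0.05
        found = set(res.dnb_genes)
        planted = {f"g{i + 1:03d}" for i in range(12)}
        assert len(found & planted) / len(found | planted) >= 0.6

    def test_criteria_flags_at_tipping(self, adjusted_factory):
        rng = np.random.default_rng(22)
        rows = rng.normal(0, 0.3, size=(50, 15))
        factor = rng.normal(size=5)
        for g in range(10):
            rows[g, 5:10] = 1.5 * factor + 0.1 * rng.normal(size=5)
        adj = adjusted_factory(rows, TIMES3, 5)
        res = select_dnb(adj, adj.sheet, DnbParams(n_permutations=50, seed=1))
        flags = res.criteria_flags[2]
        assert flags["pcc_in_up"] and flags["sd_up"]

    def test_too_few_timepoints_rejected(self, adjusted_factory):
        with pytest.raises(ValidationError):
            adjusted_factory(np.ones((5, 6)), [1, 2], 3)

    def test_deterministic_given_seed(self, adjusted_factory):
        rng = np.random.default_rng(30)
        rows = rng.normal(size=(30, 15))
        adj = adjusted_factory(rows, TIMES3, 5)
        r1 = select_dnb(adj, adj.sheet, DnbParams(n_permutations=30, seed=5))
        r2 = select_dnb(adj, adj.sheet, DnbParams(n_permutations=30, seed=5))
        assert r1.p_value == r2.p_value
        assert r1.dnb_genes == r2.dnb_genes


class TestCiMonotonicity:
    @staticmethod
    def _mean_true_module_ci(rho_in, var_fold, n_seeds=100):
        cis = []
        for seed in range(n_seeds):
            d = SimulationDesign(
                n_genes=80, module_size=12, rho_in=rho_in, var_fold=var_fold,
                de_fraction=0.0, seed=seed,
            )
            ds, sheet, truth = simulate_expression(d)
            adj = adjust_to_control(ds, sheet)
            cis.append(
                composite_index(adj, sheet, truth.module_genes, truth.tipping_time).ci
            )
        return float(np.mean(cis))

    def test_ci_increases_with_correlation_and_variance(self):
        """Expected CI of the planted module at the tipping time is
        non-decreasing in the within-module correlation and in the
        variance inflation (paired over 100 seeds)."""
        base = self._mean_true_module_ci(0.5, 2.0)
        assert self._mean_true_module_ci(0.9, 2.0) > base
        assert self._mean_true_module_ci(0.5, 4.0) > base


class TestCriteriaConcordance:
    def test_three_criteria_hold_when_tipping_called(self):
        """Strong effect with background correlation suppressed inside the
        module at the tipping time: whenever tipping is called, all three
        DNB criteria (PCC_i up, SD_i up, PCC_o down) hold at the call."""
        calls = concordant = 0
        for seed in range(10):
            d = SimulationDesign(
                n_genes=150, module_size=25, rho_in=0.98, var_fold=8.0,
                rho_bg=0.8, de_fraction=0.0, seed=seed,
            )
            ds, sheet, truth = simulate_expression(d)
            adj = adjust_to_control(ds, sheet)
            res = select_dnb(adj, sheet, DnbParams(n_permutations=60, seed=seed))
            if res.tipping_time is None:
                continue
            calls += 1
            concordant += all(res.criteria_flags[res.tipping_time].values())
        assert calls >= 5
        assert concordant >= 0.95 * calls


class TestSampleDispersion:
    def test_identical_replicates_zero(self, adjusted_factory):
        rows = np.tile(np.arange(3.0)[:, None], (1, 9))
        adj = adjusted_factory(rows, TIMES3, 3)
        table = sample_dispersion(adj, adj.sheet)
        assert np.allclose(table["mean_pairwise_distance"], 0.0)

    def test_single_gene_difference_distance(self, adjusted_factory):
        rows = np.zeros((4, 9))
        rows[0, 1] = 3.0  # second replicate of t1 differs by 3 in one gene
        adj = adjusted_factory(rows, TIMES3, 3)
        table = sample_dispersion(adj, adj.sheet)
        # pairs (r1,r2)=3, (r1,r3)=0, (r2,r3)=3 -> mean 2
        assert table.loc[table["time"] == 1, "mean_pairwise_distance"].iloc[0] == (
            pytest.approx(2.0)
        )

    def test_dispersion_peaks_at_tipping_in_strong_designs(self):
        """Replicate spread is maximal at the planted tipping time in at
        least 80% of seeds under a strong effect."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            d = SimulationDesign(
                n_genes=100, module_size=30, rho_in=0.9, var_fold=6.0,
                de_fraction=0.0, seed=seed,
            )
            ds, sheet, truth = simulate_expression(d)
            adj = adjust_to_control(ds, sheet)
            table = sample_dispersion(adj, sheet)
            t_max = table.loc[table["mean_pairwise_distance"].idxmax(), "time"]
            hits += t_max == truth.tipping_time
        assert hits >= 0.8 * n_seeds
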