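import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pathscan.association import ModelSpec
from pathscan.cohort.types import PathwayDef
from pathscan.settest import (
    DEFAULT_GRID,
    ScoreEngine,
    SetTestParams,
    WaldRefitEngine,
    bonferroni_cutoff,
    format_cutoff,
    greedy_select,
    greedy_select_idx,
    pairwise_r2,
    r2_matrix,
    run_level,
    sensitivity_grid,
    set_based_test,
)
from pathscan.simulate import SimulationSpec, simulate_cohort, simulate_genotypes

from conftest import build_matrix, build_samples


class TestPairwiseR2:
    def test_self_is_one(self):
        d = np.array([0, 1, 2, 1, 0], float)
        assert pairwise_r2(d, d) == pytest.approx(1.0)

    def test_perfect_negative(self):
        d1 = np.array([0, 1, 2, 1, 0], float)
        d2 = np.array([2, 1, 0, 1, 2], float)
        assert pairwise_r2(d1, d2) == pytest.approx(1.0)

    def test_matches_brute_force(self):
        d1 = np.array([0, 1, 2, 1], float)
        d2 = np.array([0, 1, 2, 2], float)
        expected = np.corrcoef(d1, d2)[0, 1] ** 2
        assert pairwise_r2(d1, d2) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_zero(self):
        assert pairwise_r2(np.ones(5), np.array([0, 1, 2, 1, 0.0])) == 0.0

    def test_pairwise_complete(self):
        d1 = np.array([0, 1, 2, 1, np.nan], float)
        d2 = np.array([0, 1, 2, np.nan, 1], float)
        expected = np.corrcoef(d1[:3], d2[:3])[0, 1] ** 2
        assert pairwise_r2(d1, d2) == pytest.approx(expected, abs=1e-12)

    def test_r2_matrix_matches_pairwise(self):
        rng = np.random.default_rng(2)
        D = rng.binomial(2, 0.3, size=(50, 6)).astype(float)
        D[rng.random(D.shape) < 0.1] = np.nan
        M = r2_matrix(D)
        for i, j in itertools.combinations(range(6), 2):
            assert M[i, j] == pytest.approx(pairwise_r2(D[:, i], D[:, j]), abs=1e-10)


class TestGreedySelect:
    def test_none_pass_cutoff(self):
        stats_vec = np.array([1.0, 2.0, 3.0])
        crit = sps.chi2.isf(0.05, 1)  # 3.84
        assert greedy_select_idx(stats_vec, np.eye(3), crit, 0.5) == []

    def test_perfect_ld_pair_keeps_one(self):
        stats_vec = np.array([5.0, 7.0])
        r2 = np.array([[1.0, 1.0], [1.0, 1.0]])
        crit = sps.chi2.isf(0.05, 1)
        assert greedy_select_idx(stats_vec, r2, crit, 0.5) == [1]

    def test_five_snp_hand_trace(self):
        # hand-traced loop: pick s2 (max stat), prune s0 (r2 .9); pick s4,
        # prune s3 (r2 .8); pick s1 (passes cutoff); stop.
        stats_vec = np.array([6.0, 4.5, 9.0, 5.0, 8.0])
        r2 = np.array([
            [1.0, 0.1, 0.9, 0.2, 0.1],
            [0.1, 1.0, 0.3, 0.1, 0.2],
            [0.9, 0.3, 1.0, 0.4, 0.3],
            [0.2, 0.1, 0.4, 1.0, 0.8],
            [0.1, 0.2, 0.3, 0.8, 1.0],
        ])
        crit = sps.chi2.isf(0.05, 1)
        assert greedy_select_idx(stats_vec, r2, crit, 0.5) == [2, 4, 1]

    def test_tie_broken_by_order(self):
        stats_vec = np.array([5.0, 5.0])
        assert greedy_select_idx(stats_vec, np.eye(2), 3.84, 0.5) == [0, 1]

    def test_public_wrapper(self):
        rng = np.random.default_rng(8)
        D = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        g = build_matrix(D)
        pvals = np.array([0.001, 0.5, 0.01])
        stats_vec = sps.chi2.isf(pvals, 1)
        params = SetTestParams(seed=1)
        out = greedy_select(["s1", "s2", "s3"], pvals, stats_vec, g, params)
        assert out[0] == "s1" and "s2" not in out


def _oracle_exhaustive(D, case_idx_sets, y_obs, p_cutoff, r2_threshold):
    """Independent brute-force pipeline: plain-python greedy over plain
    corrcoef statistics for every case labeling."""
    n, m = D.shape
    df = n - 2

    def stat_vec(y):
        out = []
        for j in range(m):
            r = np.corrcoef(D[:, j], y)[0, 1]
            out.append(df * r * r / (1 - r * r))
        return out

    r2 = np.corrcoef(D.T) ** 2
    crit = sps.chi2.isf(p_cutoff, 1)

    def set_stat(y):
        stats_v = stat_vec(y)
        chosen = []
        avail = set(range(m))
        while avail:
            best = max(sorted(avail), key=lambda j: (stats_v[j], -j))
            if stats_v[best] < crit:
                break
            chosen.append(best)
            avail = {j for j in avail if j != best and r2[best, j] <= r2_threshold}
        return float(np.mean([stats_v[j] for j in chosen])) if chosen else 0.0

    obs = set_stat(y_obs)
    count = total = 0
    for cases in case_idx_sets:
        y = np.zeros(n)
        y[list(cases)] = 1.0
        total += 1
        if set_stat(y) >= obs - max(1e-12, 1e-9 * abs(obs)):
            count += 1
    return count / total


class TestSetBasedTest:
    def test_empty_selection_convention(self):
        # every per-SNP p > cutoff  ->  N Sig 0, emp p 1.00, no permutations
        rng = np.random.default_rng(6)
        n = 60
        D = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        g = build_matrix(D)
        s = build_samples(htn=rng.random(n) < 0.5)
        spec = ModelSpec("HTN", covariates=())
        params = SetTestParams(p_cutoff=1e-12, n_perm=100, seed=3)
        res = set_based_test(list(g.variant_ids), g, s, spec, params)
        assert res.n_sig == 0 and res.emp_p == 1.0 and res.n_perm == 0

    def test_zero_snp_set(self):
        g = build_matrix([[0.0], [1.0]])
        s = build_samples(htn=[True, False])
        res = set_based_test([], g, s, ModelSpec("HTN", covariates=()),
                             SetTestParams(seed=1))
        assert res.emp_p == 1.0 and res.n_snps == 0

    def test_exhaustive_singleton_matches_oracle(self):
        D = np.array([0, 1, 2, 1, 0, 2, 1, 0], float)[:, None]
        g = build_matrix(D)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        s = build_samples(htn=y.astype(bool))
        spec = ModelSpec("HTN", covariates=())
        params = SetTestParams(p_cutoff=1.0, seed=1, stat_mode="score_fast")
        res = set_based_test(["s1"], g, s, spec, params, exhaustive=True)
        oracle = _oracle_exhaustive(D, itertools.combinations(range(8), 4), y,
                                    p_cutoff=1.0, r2_threshold=0.5)
        assert res.n_perm == 70
        assert res.emp_p == pytest.approx(oracle, abs=1e-12)

    def test_exhaustive_multi_snp_matches_oracle(self):
        rng = np.random.default_rng(14)
        D = rng.binomial(2, 0.4, size=(8, 3)).astype(float)
        while min(np.ptp(D, axis=0)) == 0:
            D = rng.binomial(2, 0.4, size=(8, 3)).astype(float)
        g = build_matrix(D)
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0], float)
        s = build_samples(htn=y.astype(bool))
        spec = ModelSpec("HTN", covariates=())
        params = SetTestParams(p_cutoff=0.5, r2_threshold=0.5, seed=1,
                               stat_mode="score_fast")
        res = set_based_test(list(g.variant_ids), g, s, spec, params,
                             exhaustive=True)
        oracle = _oracle_exhaustive(D, itertools.combinations(range(8), 4), y,
                                    p_cutoff=0.5, r2_threshold=0.5)
        assert res.emp_p == pytest.approx(oracle, abs=1e-12)

    def test_emp_p_bounds(self, small_null_cohort):
        g, _, _, pws, samples, _ = small_null_cohort
        params = SetTestParams(n_perm=99, seed=5, stat_mode="score_fast")
        for pw in pws:
            res = set_based_test(pw, g, samples, ModelSpec("DBP"), params)
            assert 1 / (params.n_perm + 1) <= res.emp_p <= 1.0
            if res.n_sig == 0:
                assert res.emp_p == 1.0

    def test_selected_pairwise_r2_bound(self, small_null_cohort):
        g, _, _, pws, samples, _ = small_null_cohort
        params = SetTestParams(n_perm=20, seed=5, p_cutoff=0.8, r2_threshold=0.3,
                               stat_mode="score_fast")
        for pw in pws:
            res = set_based_test(pw, g, samples, ModelSpec("SBP"), params)
            idx = g.index_of(res.selected) if res.selected else []
            for a, b in itertools.combinations(idx, 2):
                assert pairwise_r2(g.dosages[:, a], g.dosages[:, b]) <= params.r2_threshold

    def test_causal_ranks_below_matched_null(self):
        wins = 0
        for rep in range(20):
            spec = SimulationSpec(
                seed=3000 + rep, n_samples=600,
                pathways=[("CAUSAL", 2, 8), ("NULL", 2, 8)],
                causal_pathway="CAUSAL", causal_snp_fraction=0.4,
                effect_or_range=(1.7, 2.0), random_effect_sign=False)
            g, _, _, pws, samples, _ = simulate_cohort(spec)
            params = SetTestParams(n_perm=200, seed=77, stat_mode="score_fast")
            res = run_level(pws, g, samples, [ModelSpec("HTN")], params)
            by_name = {r.set_name: r.emp_p for r in res}
            if by_name["CAUSAL"] < by_name["NULL"]:
                wins += 1
        assert wins >= 18

    def test_run_level_deterministic(self, small_null_cohort):
        g, _, _, pws, samples, _ = small_null_cohort
        params = SetTestParams(n_perm=50, seed=9, stat_mode="score_fast")
        r1 = run_level(pws, g, samples, [ModelSpec("HTN"), ModelSpec("DBP")], params)
        r2 = run_level(pws, g, samples, [ModelSpec("HTN"), ModelSpec("DBP")], params)
        assert r1 == r2

    def test_run_level_matches_set_based_test(self, small_null_cohort):
        # shared-permutation batch path equals the single-set path, same seed
        g, _, _, pws, samples, _ = small_null_cohort
        params = SetTestParams(n_perm=80, seed=123, stat_mode="score_fast")
        single = set_based_test(pws[0], g, samples, ModelSpec("DBP"), params)
        batch = run_level([pws[0]], g, samples, [ModelSpec("DBP")], params)[0]
        assert batch.emp_p == pytest.approx(single.emp_p)
        assert batch.selected == single.selected


class TestStatModes:
    def test_wald_engine_matches_snp_association(self, small_null_cohort):
        from pathscan.association import snp_association
        g, _, _, _, samples, _ = small_null_cohort
        spec = ModelSpec("HTN")
        eng = WaldRefitEngine(g.dosages, samples, spec, list(g.variant_ids))
        stats_vec, _ = eng.observed()
        for j in range(0, g.n_variants, 5):
            ref = snp_association(g.dosages[:, j], samples, spec, "x")
            assert stats_vec[j] == pytest.approx(ref.statistic, rel=1e-6, abs=1e-8)

    def test_score_equals_wald_for_linear_complete_data(self):
        rng = np.random.default_rng(21)
        n = 120
        D = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        g = build_matrix(D)
        s = build_samples(sbp=rng.normal(130, 15, n),
                          age=rng.normal(50, 10, n), bmi=rng.normal(24, 4, n),
                          sex=np.where(rng.random(n) < 0.5, "male", "female"))
        spec = ModelSpec("SBP")
        from pathscan.association import covariate_matrix, outcome_vector
        y = outcome_vector(s, spec)
        X = covariate_matrix(s, spec)
        fast = ScoreEngine(D, y, X).observed()[0]
        wald = WaldRefitEngine(D, s, spec, list(g.variant_ids)).observed()[0]
        np.testing.assert_allclose(fast, wald, rtol=1e-8)

    def test_mode_ranking_agreement(self):
        # 20 sets with ramped planted effects; engine rankings must agree
        rng = np.random.default_rng(31)
        spec_sim = SimulationSpec(seed=55, n_samples=250,
                                  pathways=[(f"S{k:02d}", 1, 6) for k in range(20)],
                                  ld_block_size=3)
        g, variants, genes, pws = simulate_genotypes(spec_sim)
        n = g.n_samples
        eta = np.zeros(n)
        for k, pw in enumerate(pws):
            d = g.dosages[:, g.index_of([pw.snp_ids[0]])[0]]
            eta += (0.05 * k) * (d - np.nanmean(d))
        htn = rng.random(n) < 1 / (1 + np.exp(-eta))
        s = build_samples(htn=htn, ids=list(g.sample_ids),
                          age=rng.normal(50, 10, n), bmi=rng.normal(24, 4, n),
                          sex=np.where(rng.random(n) < 0.5, "male", "female"))
        spec = ModelSpec("HTN")
        fast = run_level(pws, g, s, [spec],
                         SetTestParams(n_perm=200, seed=7, stat_mode="score_fast"))
        wald = run_level(pws, g, s, [spec],
                         SetTestParams(n_perm=200, seed=7, stat_mode="wald_refit"))
        rho = sps.spearmanr([r.emp_p for r in fast], [r.emp_p for r in wald]).statistic
        assert rho >= 0.95


class TestFreedmanLane:
    def test_coincides_with_label_scheme_without_covariates(self, small_null_cohort):
        g, _, _, pws, samples, _ = small_null_cohort
        spec = ModelSpec("SBP", covariates=())
        kw = dict(n_perm=60, seed=4, stat_mode="score_fast")
        label = set_based_test(pws[0], g, samples, spec,
                               SetTestParams(perm_scheme="label", **kw))
        fl = set_based_test(pws[0], g, samples, spec,
                            SetTestParams(perm_scheme="freedman_lane", **kw))
        assert label.emp_p == pytest.approx(fl.emp_p)
        assert label.selected == fl.selected

    def test_runs_with_covariates(self, small_null_cohort):
        g, _, _, pws, samples, _ = small_null_cohort
        params = SetTestParams(n_perm=60, seed=4, stat_mode="score_fast",
                               perm_scheme="freedman_lane")
        res = set_based_test(pws[0], g, samples, ModelSpec("DBP"), params)
        assert 1 / 61 <= res.emp_p <= 1.0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="perm_scheme"):
            SetTestParams(seed=1, perm_scheme="bootstrap")


class TestNullCalibration:
    def test_uniformity_of_null_set_pvalues(self):
        # >= 200 null sets over independent seeds; the empirical p-values
        # must not be anti-conservative (one-sided KS; the atom at 1.00 from
        # empty selections makes them conservative by construction) and the
        # lower tail must be calibrated.
        emp = []
        for cohort_seed in (101, 202, 303, 404):
            spec_sim = SimulationSpec(seed=cohort_seed, n_samples=300,
                                      pathways=[(f"N{k:02d}", 1, 5) for k in range(50)],
                                      ld_block_size=2)
            g, _, _, pws, samples, _ = simulate_cohort(spec_sim)
            params = SetTestParams(n_perm=500, seed=cohort_seed + 1,
                                   stat_mode="score_fast")
            res = run_level(pws, g, samples, [ModelSpec("HTN")], params)
            emp.extend(r.emp_p for r in res)
        emp = np.asarray(emp)
        assert len(emp) == 200
        ks_p = sps.kstest(emp, "uniform", alternative="greater").pvalue
        assert ks_p > 0.01
        frac05 = (emp <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(emp))
        assert frac05 <= 0.05 + 3 * se + 0.02


class TestBonferroni:
    def test_pathway_cutoff(self):
        v = bonferroni_cutoff(0.05, 28)
        assert v == pytest.approx(0.05 / 28)
        assert format_cutoff(v, 1) == "0.002"

    def test_gene_cutoff(self):
        assert format_cutoff(bonferroni_cutoff(0.05, 101), 1) == "0.0005"

    def test_snp_cutoff(self):
        assert format_cutoff(bonferroni_cutoff(0.05, 4349), 3) == "1.15e-05"

    def test_identity(self):
        assert bonferroni_cutoff(0.05, 1) == 0.05

    def test_zero_tests_error(self):
        with pytest.raises(ValueError):
            bonferroni_cutoff(0.05, 0)


class TestSensitivityGrid:
    def test_grid_labels_and_values(self, small_null_cohort):
        g, _, _, pws, samples, _ = small_null_cohort
        params = SetTestParams(n_perm=50, seed=2, stat_mode="score_fast")
        tab = sensitivity_grid(pws[0], g, samples, [ModelSpec("HTN")], params)
        assert list(tab["condition"]) == ["Default", "Strict", "Loose"]
        assert list(tab["r2"]) == [0.5, 0.1, 0.8]
        assert list(tab["p_cutoff"]) == [0.05, 0.01, 0.05]

    def test_empty_grid(self, small_null_cohort):
        g, _, _, pws, samples, _ = small_null_cohort
        params = SetTestParams(n_perm=10, seed=2, stat_mode="score_fast")
        tab = sensitivity_grid(pws[0], g, samples, [ModelSpec("HTN")], params, grid=[])
        assert tab.empty

    def test_strict_selection_subset_on_ld_free_toy(self):
        # no LD pruning possible (independent SNPs): tightening the p cutoff
        # can only shrink the selection
        spec_sim = SimulationSpec(seed=61, n_samples=400,
                                  pathways=[("A", 2, 10)], ld_block_size=1,
                                  causal_pathway="A", causal_snp_fraction=0.5,
                                  effect_or_range=(1.5, 1.8))
        g, _, _, pws, samples, _ = simulate_cohort(spec_sim)
        base = SetTestParams(n_perm=10, seed=3, stat_mode="score_fast")
        spec = ModelSpec("HTN")
        default = set_based_test(pws[0], g, samples, spec,
                                 SetTestParams(n_perm=10, seed=3, p_cutoff=0.05,
                                               r2_threshold=0.5, stat_mode="score_fast"))
        strict = set_based_test(pws[0], g, samples, spec,
                                SetTestParams(n_perm=10, seed=3, p_cutoff=0.01,
                                              r2_threshold=0.1, stat_mode="score_fast"))
        assert set(strict.selected) <= set(default.selected)
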