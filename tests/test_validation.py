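"""Validation stage: per-CpG screen, burden score test, FDR, meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dmrscan as ds


class TestPerCpgTest:
    def test_identical_groups_give_p_one(self):
        rates = np.array([[0.1, 0.2, 0.3, 0.1, 0.2, 0.3]])
        p = ds.per_cpg_test(rates, np.array([False, False, False, True, True, True]))
        assert p[0] == pytest.approx(1.0)

    def test_matches_welch_closed_form(self):
        a = np.array([0.2, 0.3, 0.45])
        b = np.array([0.5, 0.62, 0.7])
        rates = np.concatenate([a, b])[None, :]
        groups = np.array([False] * 3 + [True] * 3)
        p = ds.per_cpg_test(rates, groups)[0]
        # Welch t and Satterthwaite df evaluated directly
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (b.mean() - a.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_bonferroni_threshold_printed_expression(self):
        # alpha=0.05 over 1251 CpGs -> threshold ~3.997e-5
        assert ds.bonferroni_flag(3.9e-5, 0.05, 1251)
        assert not ds.bonferroni_flag(4.1e-5, 0.05, 1251)
        assert 0.05 / 1251 == pytest.approx(3.997e-5, rel=1e-3)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ds.per_cpg_test(np.array([[0.1, 0.2]]), np.array([False, True]))


class TestBurdenTest:
    def test_constant_rates_give_p_one(self):
        rates = np.full((30, 5), 0.4)
        y = np.repeat([0, 1], 15)
        res = ds.burden_test(rates, y)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_scale_invariance_of_weights(self):
        rng = np.random.default_rng(0)
        rates = rng.beta(2, 2, (24, 4))
        y = np.repeat([0, 1], 12)
        p1 = ds.burden_test(rates, y, weights=np.ones(4)).p_value
        p2 = ds.burden_test(rates, y, weights=np.full(4, 7.5)).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_covariate_free_exact_p_matches_permutation_sampler(self):
        rng = np.random.default_rng(3)
        n = 18
        y = np.zeros(n)
        y[:9] = 1
        rng.shuffle(y)
        rates = rng.beta(2, 2, (n, 3))
        res = ds.burden_test(rates, y)
        assert res.exact
        B = rates.sum(axis=1)
        u = abs(np.sum((y - y.mean()) * B))
        idx = np.argsort(rng.random((40_000, n)), axis=1)[:, :9]
        perm = np.abs(B[idx].sum(axis=1) - 9 * B.mean())
        p_perm = float((perm >= u - 1e-12).mean())
        se = np.sqrt(p_perm * (1 - p_perm) / 40_000)
        assert abs(res.p_value - p_perm) <= 3.5 * se

    def test_covariate_adjustment_removes_age_confounding(self):
        rng = np.random.default_rng(4)
        unadj, adj = [], []
        for _ in range(150):
            age = np.concatenate([rng.normal(68, 3, 48), rng.normal(74, 3, 48)])
            y = np.repeat([0, 1], 48)
            rates = np.clip(0.5 + 0.01 * (age[:, None] - 71) + rng.normal(0, 0.07, (96, 10)), 0, 1)
            unadj.append(ds.burden_test(rates, y).p_value)
            adj.append(ds.burden_test(rates, y, covariates=age[:, None]).p_value)
        assert np.mean(np.asarray(unadj) < 0.05) > 0.5  # confounded: massive inflation
        assert np.mean(np.asarray(adj) < 0.05) < 0.12   # adjusted: near nominal

    def test_non_binary_phenotype_rejected(self):
        with pytest.raises(ValueError):
            ds.burden_test(np.zeros((4, 2)), [0, 1, 2, 1])

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(0)
        cov = np.column_stack([np.arange(10.0), np.arange(10.0) * 2])
        with pytest.raises(ValueError, match="rank"):
            ds.burden_test(rng.beta(2, 2, (10, 2)), np.repeat([0, 1], 5), covariates=cov)


class TestBhFdr:
    def test_step_up_formula_example(self):
        q = ds.bh_fdr([0.01, 0.04, 0.03])
        assert q == pytest.approx([0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert ds.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_p_unchanged(self):
        assert ds.bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_monotone_in_p_order_and_discovery_count_matches_step_up(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200) ** 2
        q = ds.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        # classic step-up count at alpha
        alpha = 0.1
        ps = np.sort(p)
        k = max([i + 1 for i in range(len(ps)) if ps[i] <= alpha * (i + 1) / len(ps)], default=0)
        assert (q <= alpha).sum() == k

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ds.bh_fdr([0.1, np.nan])


class TestMetaAnalyze:
    def test_two_same_direction_p05_closed_form(self):
        # z_k = Phi^-1(1 - 0.05/2) = 1.95996, combined z = 2*1.95996/sqrt(2)
        res = ds.meta_analyze([0.05, 0.05], [-0.1, -0.1], [96, 96])
        z = 2 * stats.norm.isf(0.025) / np.sqrt(2)
        assert res.meta_z == pytest.approx(-z)
        assert res.meta_p == pytest.approx(2 * stats.norm.sf(z), rel=1e-9)
        assert res.meta_p == pytest.approx(0.005574, abs=2e-6)

    def test_antagonistic_evidence_weakens_the_minimum(self):
        res = ds.meta_analyze([1e-6, 1.0], [0.2, -0.2], [96, 96])
        assert res.meta_p > 1e-6

    def test_duplicated_cohort_strengthens_evidence(self):
        single = 0.04
        res = ds.meta_analyze([single, single], [0.1, 0.1], [96, 96])
        assert res.meta_p < single

    def test_identical_one_sided_evidence_scales_z_by_sqrt_k(self):
        z1 = stats.norm.isf(0.05 / 2)
        for k in (2, 3, 4):
            res = ds.meta_analyze([0.05] * k, [0.1] * k, [96] * k)
            assert res.meta_z == pytest.approx(np.sqrt(k) * z1, rel=1e-9)

    def test_single_cohort_passthrough_warns(self):
        with pytest.warns(UserWarning, match="single cohort"):
            res = ds.meta_analyze([0.2], [0.1], [96])
        assert res.meta_p == 0.2


def _two_cohorts(delta, seed, n_dmrs=4):
    regions = pd.DataFrame(
        [{"chrom": "chr1", "start": 1000 + i * 4000, "end": 1240 + i * 4000, "name": f"DMR{i+1}", "n_cpgs": 7}
         for i in range(n_dmrs)]
    )
    specs = tuple(
        ds.TrueDMRSpec(r["chrom"], r["start"], r["end"], 7, delta) for _, r in regions.iterrows()
    ) if delta else ()
    cfg = ds.SyntheticConfig(
        n_cn=48, n_ad=48, n_cpgs=0, seed=seed, rho=0.02, coverage=ds.AMPLICON_COVERAGE,
        dmr_specs=specs, baseline=ds.BaselineMixture(weights=(0.0, 1.0, 0.0)),
    )
    m2, s2 = ds.simulate_amplicon_cohort(cfg, regions, seed=seed)
    m3, s3 = ds.simulate_amplicon_cohort(cfg, regions, seed=seed + 10_000)
    return (
        ds.validate_cohort(m2, s2, regions, label="2nd"),
        ds.validate_cohort(m3, s3, regions, label="3rd"),
        regions,
    )


class TestConfirmDmrs:
    def test_rule_chain_thresholds(self):
        # hand-built cohort results exercising each rule step
        per_cpg = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": range(10),
                "dmr": ["A"] * 5 + ["B"] * 5,
                "delta_beta": -0.05,
                "p_raw": [1e-9] * 5 + [1e-9, 1e-9, 0.5, 0.5, 0.5],
                "significant_bonferroni": [True] * 5 + [True, True, False, False, False],
                "m_tests": 10,
            }
        )
        burden = pd.DataFrame(
            {"dmr": ["A", "B"], "statistic": [30.0, 30.0], "p_value": [1e-4, 1e-4],
             "n_cpgs_used": 5, "delta_beta": -0.05, "fdr_q": [0.01, 0.06]}
        )
        c2 = ds.CohortValidation("2nd", per_cpg, burden, 96)
        c3 = ds.CohortValidation("3rd", per_cpg.copy(), burden.assign(fdr_q=[0.2, 0.2]), 96)
        out = ds.confirm_dmrs(c2, c3).set_index("dmr")
        assert bool(out.loc["A", "confirmed"])
        assert not bool(out.loc["B", "eligible"])  # only 2 significant CpGs
        assert not bool(out.loc["B", "confirmed"])

    def test_implanted_effect_confirmed_null_not(self):
        c2, c3, _ = _two_cohorts(-0.05, seed=42)
        confirmed = ds.confirm_dmrs(c2, c3)
        assert confirmed["confirmed"].mean() > 0.5
        n2, n3, _ = _two_cohorts(0.0, seed=43)
        assert ds.confirm_dmrs(n2, n3)["confirmed"].sum() == 0

    def test_untestable_dmr_excluded_with_warning(self):
        c2, c3, regions = _two_cohorts(-0.05, seed=44, n_dmrs=2)
        c3.burden.loc[c3.burden["dmr"] == "DMR2", "p_value"] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            out = ds.confirm_dmrs(c2, c3)
        assert list(out["dmr"]) == ["DMR1"]


class TestValidateCohort:
    def test_burden_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for i in range(300):
            age = np.concatenate([rng.normal(70.3, 2.4, 48), rng.normal(71.2, 4.0, 48)])
            y = np.repeat([0, 1], 48)
            sex = rng.integers(0, 2, 96).astype(float)
            rates = np.clip(0.5 + 0.01 * (age[:, None] - 70.7) + rng.normal(0, 0.07, (96, 10)), 0, 1)
            pvals.append(ds.burden_test(rates, y, covariates=np.column_stack([sex, age])).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_table_shape_one_row_per_dmr(self):
        c2, _, regions = _two_cohorts(-0.05, seed=45)
        assert list(c2.burden["dmr"]) == list(regions["name"])
        assert c2.per_cpg["m_tests"].iloc[0] == len(c2.per_cpg)
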