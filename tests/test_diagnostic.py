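"""Marker selection, data splitting, model search, AUC and DeLong CI."""

import numpy as np
import pandas as pd
import pytest

import dmrscan as ds
from dmrscan.diagnostic import mann_whitney_auc


def _validation(per_cpg_rows, label="2nd"):
    per_cpg = pd.DataFrame(per_cpg_rows)
    per_cpg["m_tests"] = len(per_cpg)
    per_cpg["significant_bonferroni"] = per_cpg["p_raw"] <= 0.05 / len(per_cpg)
    burden = pd.DataFrame({"dmr": per_cpg["dmr"].unique()})
    return ds.CohortValidation(label, per_cpg, burden, 96)


class TestSelectMarkers:
    def _rows(self, p2, p3, d2=-0.1, d3=-0.1):
        base = [{"chrom": "chr1", "pos": 100 + i, "dmr": "A", "beta_cn": 0.5, "beta_ad": 0.4} for i in range(3)]
        rows2 = [dict(r, p_raw=p2, delta_beta=d2) for r in base]
        rows3 = [dict(r, p_raw=p3, delta_beta=d3) for r in base]
        return _validation(rows2), _validation(rows3, "3rd")

    def test_significant_concordant_sites_selected(self):
        c2, c3 = self._rows(1e-8, 1e-8)
        ms = ds.select_marker_cpgs(c2, c3)
        assert len(ms) == 3 and ms.dmrs == ["A"]

    def test_opposite_direction_excluded(self):
        c2, c3 = self._rows(1e-8, 1e-8, d2=-0.1, d3=0.1)
        assert len(ds.select_marker_cpgs(c2, c3)) == 0

    def test_null_cohort3_gives_empty_marker_set(self):
        c2, c3 = self._rows(1e-8, 0.9)
        assert len(ds.select_marker_cpgs(c2, c3)) == 0

    def test_site_in_one_cohort_only_warned_ineligible(self):
        c2, c3 = self._rows(1e-8, 1e-8)
        c3.per_cpg = c3.per_cpg.iloc[:2]
        with pytest.warns(UserWarning, match="only one cohort"):
            ms = ds.select_marker_cpgs(c2, c3)
        assert len(ms) == 2


class TestSplit:
    def _data(self, n=192):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.normal(size=n)})
        y = np.tile([0, 1], n // 2)
        return X, y

    def test_four_fifths_split_sizes(self):
        X, y = self._data(192)
        Xd, Xv, yd, yv = ds.split_discovery_validation(X, y, 0.8, seed=1)
        assert len(Xd) == 153 and len(Xv) == 39
        assert {*np.unique(yd)} == {0, 1} and {*np.unique(yv)} == {0, 1}

    def test_half_split_balanced(self):
        X, y = self._data(100)
        Xd, Xv, _, _ = ds.split_discovery_validation(X, y, 0.5, seed=2)
        assert len(Xd) == len(Xv) == 50

    def test_same_seed_identical_split(self):
        X, y = self._data()
        a = ds.split_discovery_validation(X, y, 0.8, seed=7)
        b = ds.split_discovery_validation(X, y, 0.8, seed=7)
        assert list(a[0].index) == list(b[0].index)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ds.split_discovery_validation(X, [1, 1], 0.5, 0)


class TestAuc:
    def test_perfect_separation(self):
        assert mann_whitney_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_is_half(self):
        assert mann_whitney_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_three_of_four_concordant_pairs(self):
        assert mann_whitney_auc([0, 0, 1, 1], [0.3, 0.6, 0.5, 0.9]) == 0.75

    def test_matches_exhaustive_pair_count_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(6, 200))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert mann_whitney_auc(y, s) == pytest.approx(pairs / (len(pos) * len(neg)))

    def test_delong_ci_contains_point_estimate_and_shrinks_with_n(self):
        rng = np.random.default_rng(1)
        widths = []
        for n in (40, 400):
            y = np.tile([0, 1], n // 2)
            s = rng.normal(size=n) + 0.8 * y
            auc, lo, hi = ds.delong_ci(y, s)
            assert lo <= auc <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_single_class_validation_rejected(self):
        class Dummy:
            def predict_proba(self, X):
                return np.column_stack([np.zeros(len(X)), np.ones(len(X))])

        with pytest.raises(ValueError):
            ds.evaluate_auc(Dummy(), np.zeros((3, 1)), [1, 1, 1])


def _marker_set(n_dmrs=5, cpgs=2):
    rows = []
    for i in range(n_dmrs):
        for j in range(cpgs):
            rows.append({"dmr": f"D{i+1}", "chrom": "chr1", "pos": 1000 * (i + 1) + j, "direction": "hyper"})
    return ds.MarkerSet(pd.DataFrame(rows))


def _feature_frame(ms, n=120, signal_dmrs=(), effect=0.8, seed=0):
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    cols = {}
    for _, row in ms.sites.iterrows():
        col = rng.normal(size=n)
        if row["dmr"] in signal_dmrs:
            col = col + effect * y
        cols[f"{row['dmr']}|{row['chrom']}:{row['pos']}"] = col
    X = pd.DataFrame(cols)
    X["age"] = rng.normal(70, 3, n)
    X["sex_male"] = rng.integers(0, 2, n).astype(float)
    X["apoe_e4"] = rng.integers(0, 3, n).astype(float)
    return X, y


class TestSearchModels:
    def test_d5_evaluates_31_subsets_plus_base(self):
        ms = _marker_set(5, 1)
        X, y = _feature_frame(ms, n=60)
        ranked = ds.search_models(ms, X, y, penalty_grid=(1.0,), seed=0)
        assert len(ranked) == 32
        assert sum(r.is_base for r in ranked) == 1

    def test_combinatorial_guard(self):
        ms = _marker_set(21, 1)
        X, y = _feature_frame(ms, n=60)
        with pytest.raises(ValueError, match="exhaustive"):
            ds.search_models(ms, X, y)

    def test_informative_dmrs_selected(self):
        ms = _marker_set(4, 2)
        hits = 0
        for seed in range(6):
            X, y = _feature_frame(ms, n=160, signal_dmrs=("D1",), effect=0.9, seed=seed)
            ranked = ds.search_models(ms, X, y, penalty_grid=(1.0, 10.0), seed=seed)
            hits += "D1" in ranked[0].dmrs
        assert hits >= 5

    def test_deterministic_given_seed(self):
        ms = _marker_set(3, 1)
        X, y = _feature_frame(ms, n=80, signal_dmrs=("D2",), seed=3)
        a = ds.search_models(ms, X, y, penalty_grid=(1.0,), seed=5)
        b = ds.search_models(ms, X, y, penalty_grid=(1.0,), seed=5)
        assert [(r.dmrs, r.cv_auc) for r in a] == [(r.dmrs, r.cv_auc) for r in b]

    def test_noise_dmrs_do_not_help_beyond_fold_noise(self):
        ms = _marker_set(4, 2)
        deltas = []
        for seed in range(4):
            X, y = _feature_frame(ms, n=160, signal_dmrs=("D1",), effect=1.0, seed=10 + seed)
            ranked = ds.search_models(ms, X, y, penalty_grid=(1.0,), seed=seed)
            by_subset = {r.dmrs: r.cv_auc for r in ranked}
            deltas.append(by_subset[("D1", "D2", "D3", "D4")] - by_subset[("D1",)])
        assert np.mean(deltas) < 0.05

    def test_sensitivity_table_rows_per_fold_count(self):
        ms = _marker_set(2, 1)
        X, y = _feature_frame(ms, n=120, signal_dmrs=("D1",), seed=2)
        Xd, Xv, yd, yv = ds.split_discovery_validation(X, y, 0.8, 0)
        table = ds.sensitivity_analysis(ms, Xd, yd, Xv, yv, fold_counts=(3, 5), penalty_grid=(1.0,), seed=0)
        assert list(table["cv_folds"]) == [3, 5]
        assert not table["subset_changed"].iloc[0]


class TestApoeBaseModel:
    def test_base_auc_concentrates_at_analytic_genotype_auc(self):
        # pooled cohort-2+3 genotype frequencies; the covariate-only model's
        # AUC equals the Mann-Whitney AUC of the e4 count distribution
        cn = np.array([79, 15, 2]) / 96.0   # counts 0,1,2
        adp = np.array([36, 49, 11]) / 96.0
        analytic = 0.0
        for i, pc in enumerate(cn):
            for j, pa in enumerate(adp):
                analytic += pc * pa * (1.0 if j > i else 0.5 if j == i else 0.0)
        demo = ds.DemographicParams(
            70.3, 2.4, 70.3, 2.4, 0.5, 0.5, (2 / 96, 15 / 96, 79 / 96), (11 / 96, 49 / 96, 36 / 96)
        )
        table = ds.sample_covariates(1500, 1500, demo, seed=9)
        y = (table["group"] == "AD").astype(int).to_numpy()
        auc = mann_whitney_auc(y, table["apoe_e4"].to_numpy(dtype=float))
        assert auc == pytest.approx(analytic, abs=0.02)
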