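"""Group-level voxel-wise tests, cluster-extent thresholding, ROI regressions."""

import numpy as np
import pandas as pd
import pytest

import chp_elastic as ce
from chp_elastic.errors import InvalidArgumentError

from oracles import covariate_regression, flood_fill_label, one_sample_t, slope_t


def maps_from_stack(stack, mask=None):
    if mask is None:
        mask = np.ones(stack.shape[1:], bool)
    return [ce.CVRMap(v, "r.u.", mask) for v in stack]


class TestOneSampleT:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        stack = rng.standard_normal((12, 5, 5, 3)) - 0.4
        res = ce.one_sample_t_map(maps_from_stack(stack), direction="negative",
                                  p_threshold=0.05, cluster_min=0)
        for idx in [(0, 0, 0), (2, 3, 1), (4, 4, 2)]:
            t, _ = one_sample_t(stack[(slice(None),) + idx], "negative")
            assert res.t_map[idx] == pytest.approx(t, rel=1e-8)

    def test_all_zero_maps_no_clusters(self):
        stack = np.zeros((5, 4, 4, 2))
        res = ce.one_sample_t_map(maps_from_stack(stack))
        assert res.clusters == []
        assert res.zero_variance_mask.all()

    def test_small_blob_removed_by_extent_rule(self):
        """A strongly negative blob below the size threshold does not survive."""
        rng = np.random.default_rng(1)
        stack = 0.01 * rng.standard_normal((10, 12, 12, 6))
        blob = np.zeros((12, 12, 6), bool)
        blob[2:7, 2:6, 1:3] = True  # 5*4*2 = 40 voxels
        stack[:, blob] -= 1.0
        res40 = ce.one_sample_t_map(maps_from_stack(stack), cluster_min=50)
        assert res40.surviving_mask.sum() == 0
        res_small = ce.one_sample_t_map(maps_from_stack(stack), cluster_min=30)
        assert res_small.surviving_mask.sum() >= 40

    def test_cluster_labels_match_flood_fill(self):
        rng = np.random.default_rng(2)
        stack = 0.05 * rng.standard_normal((15, 10, 10, 5))
        effect = np.zeros((10, 10, 5), bool)
        effect[1:4, 1:4, 1:4] = True
        effect[6:9, 6:9, 1:4] = True
        stack[:, effect] -= 1.0
        for conn in (6, 26):
            res = ce.one_sample_t_map(maps_from_stack(stack), cluster_min=5,
                                      connectivity=conn)
            supra = res.t_map < 0
            # rebuild the supra-threshold set the implementation used
            from scipy import stats as sstats

            p = sstats.t.cdf(res.t_map, stack.shape[0] - 1)
            supra = (p < res.p_threshold) & (res.t_map != 0)
            comps = [c for c in flood_fill_label(supra, conn) if len(c) > 5]
            assert sorted(len(c) for c in comps) == sorted(c.size for c in res.clusters)
            union = set().union(*comps) if comps else set()
            assert union == set(map(tuple, np.argwhere(res.surviving_mask)))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        stack = rng.standard_normal((10, 8, 8, 4)) - 0.5
        maps = maps_from_stack(stack)
        res_lo = ce.one_sample_t_map(maps, cluster_min=5)
        res_hi = ce.one_sample_t_map(maps, cluster_min=20)
        assert len(res_hi.clusters) <= len(res_lo.clusters)
        assert not (res_hi.surviving_mask & ~res_lo.surviving_mask).any()
        strict = ce.one_sample_t_map(maps, p_threshold=0.0005, cluster_min=5)
        loose = ce.one_sample_t_map(maps, p_threshold=0.005, cluster_min=5)
        assert not (strict.surviving_mask & ~loose.surviving_mask).any()

    def test_needs_three_subjects(self):
        stack = np.zeros((2, 4, 4, 2))
        with pytest.raises(InvalidArgumentError):
            ce.one_sample_t_map(maps_from_stack(stack))


class TestRegressionMap:
    def test_slope_t_matches_linregress(self):
        rng = np.random.default_rng(4)
        n = 14
        age = np.linspace(22, 80, n)
        stack = 0.002 * age[:, None, None, None] + 0.05 * rng.standard_normal((n, 4, 4, 3))
        res = ce.regression_map(maps_from_stack(stack), age, p_threshold=0.05, cluster_min=0)
        for idx in [(0, 0, 0), (3, 2, 1)]:
            t, _ = slope_t(age, stack[(slice(None),) + idx], "positive")
            assert res.t_map[idx] == pytest.approx(t, rel=1e-8)

    def test_null_covariate_rarely_survives(self):
        """With no true covariate effect, surviving clusters are rare."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            stack = rng.standard_normal((12, 8, 8, 4))
            age = rng.uniform(20, 80, 12)
            res = ce.regression_map(maps_from_stack(stack), age, cluster_min=50)
            hits += bool(res.clusters)
        assert hits <= 2

    def test_constant_covariate_rejected(self):
        stack = np.zeros((5, 4, 4, 2))
        with pytest.raises(InvalidArgumentError, match="constant"):
            ce.regression_map(maps_from_stack(stack), np.full(5, 50.0))


class TestRoiRegression:
    @staticmethod
    def _table(n=24, slope=0.001, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(20, 85, n)
        sex = np.where(np.arange(n) % 2 == 0, "M", "F")
        roi = -0.08 + slope * age + noise * rng.standard_normal(n)
        return pd.DataFrame({"roi_value": roi, "age": age, "sex": sex})

    def test_exact_linear_recovery(self):
        t = self._table(slope=0.00068)
        res = ce.roi_regression(t, "age")
        assert res.beta == pytest.approx(0.00068, rel=1e-9)
        assert res.p < 1e-12

    def test_matches_normal_equation_oracle(self):
        t = self._table(slope=0.0005, noise=0.02, seed=2)
        res = ce.roi_regression(t, "age")
        beta, p, ci = covariate_regression(t.roi_value, t.age, t.sex)
        assert res.beta == pytest.approx(beta, rel=1e-8)
        assert res.p == pytest.approx(p, rel=1e-6)
        assert res.ci95 == pytest.approx(ci, rel=1e-6)

    def test_permuted_ages_give_uniform_p(self):
        """Null calibration: over 200 permutations, ~5% of p-values fall below 0.05."""
        t = self._table(slope=0.0, noise=0.05, seed=3)
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(200):
            perm = t.copy()
            perm["age"] = rng.permutation(perm["age"].to_numpy())
            hits += ce.roi_regression(perm, "age").p < 0.05
        assert 0.01 <= hits / 200 <= 0.10

    def test_group_contrast(self):
        rng = np.random.default_rng(7)
        n_y, n_o = 17, 10
        table = pd.DataFrame(
            {
                "roi_value": np.r_[-0.46 + 0.26 * rng.standard_normal(n_y),
                                   -0.15 + 0.26 * rng.standard_normal(n_o)],
                "group": ["young"] * n_y + ["old"] * n_o,
                "sex": np.where(np.arange(n_y + n_o) % 2 == 0, "M", "F"),
            }
        )
        res = ce.roi_regression(table, "group")
        assert res.beta > 0  # old minus young: less negative in the old group

    def test_single_sex_rejected(self):
        t = self._table()
        t["sex"] = "F"
        with pytest.raises(InvalidArgumentError, match="sex"):
            ce.roi_regression(t, "age")


class TestRoiExtract:
    def test_uniform_map(self):
        m = ce.CVRMap(np.full((4, 4, 2), -0.3), "r.u.", np.ones((4, 4, 2), bool))
        roi = np.zeros((4, 4, 2), bool)
        roi[1:3, 1:3, :] = True
        assert ce.roi_extract(m, roi) == pytest.approx(-0.3)

    def test_disjoint_roi_rejected(self):
        mask = np.zeros((4, 4, 2), bool)
        mask[0, 0, 0] = True
        m = ce.CVRMap(np.zeros((4, 4, 2)), "r.u.", mask)
        roi = np.zeros((4, 4, 2), bool)
        roi[3, 3, 1] = True
        with pytest.raises(InvalidArgumentError):
            ce.roi_extract(m, roi)
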