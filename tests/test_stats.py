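"""Effect sizes, group comparisons, z-score matrices, Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from flimcyte.exceptions import (
    ConfigError,
    DataError,
    InsufficientDataError,
    InvalidParameterError,
)
from flimcyte.features import OMI_PARAMETERS
from flimcyte.stats import (
    compare_groups,
    glass_delta,
    mann_whitney_p,
    ward_cluster,
    zscore_matrix,
)


class TestGlassDelta:
    def test_arithmetic(self):
        exp = np.array([3.0, 3.0, 3.0])
        ctrl = np.array([-1.0, 1.0, 3.0])  # mean 1, sd 2
        assert glass_delta(exp, ctrl) == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        x = np.arange(10.0)
        assert glass_delta(x, x) == 0.0

    def test_matches_direct_formula_oracle(self, rng):
        x = rng.normal(2.0, 1.3, 200)
        c = rng.normal(0.5, 0.8, 200)
        direct = abs(x.mean() - c.mean()) / np.std(c, ddof=1)
        assert glass_delta(x, c) == pytest.approx(direct, abs=1e-12)

    def test_zero_control_sd_degenerate(self):
        with pytest.raises(InvalidParameterError):
            glass_delta(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
        with pytest.raises(InsufficientDataError):
            glass_delta(np.array([1.0]), np.array([5.0]))

    def test_documented_asymmetry(self, rng):
        a = rng.normal(0, 1.0, 300)
        b = rng.normal(1, 3.0, 300)
        assert glass_delta(a, b) != pytest.approx(glass_delta(b, a))

    def test_affine_invariance(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(2, 1, 100)
        d0 = glass_delta(a, b)
        assert glass_delta(3.5 * a + 7, 3.5 * b + 7) == pytest.approx(d0, rel=1e-12)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = np.arange(30.0)
        assert mann_whitney_p(x, x) == 1.0

    def test_exact_branch_matches_scipy_exact(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 9)
        from scipy.stats import mannwhitneyu
        expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mann_whitney_p(x, y) == pytest.approx(expected)


def _two_group_table(rng, n=500, shift=2.0):
    rows = []
    for tissue, mu in (("spleen", 0.0), ("tumor", shift)):
        for i in range(n // 2):
            row = {"tissue": tissue, "cell_id": i, "fov_id": tissue}
            for p in OMI_PARAMETERS:
                row[p] = rng.normal(mu if p == "fad_tau_m" else 0.0, 1.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups(self, rng):
        tab = _two_group_table(rng, n=100, shift=0.0)
        tab.loc[tab.tissue == "tumor", list(OMI_PARAMETERS)] = (
            tab.loc[tab.tissue == "spleen", list(OMI_PARAMETERS)].to_numpy()
        )
        comps = compare_groups(tab, "tissue", "spleen")
        for c in comps:
            assert c.glass_delta_abs == pytest.approx(0.0)
            assert c.mw_p == pytest.approx(1.0)

    def test_known_shift_recovered(self, rng):
        tab = _two_group_table(rng, n=500, shift=2.0)
        comps = {c.parameter: c for c in compare_groups(tab, "tissue", "spleen")}
        c = comps["fad_tau_m"]
        assert c.glass_delta_abs == pytest.approx(2.0, abs=0.3)
        assert c.mw_p < 1e-6
        assert c.significant_effect

    def test_missing_control_label(self, rng):
        with pytest.raises(ConfigError):
            compare_groups(_two_group_table(rng, 50), "tissue", "liver")


class TestZScoreMatrix:
    def _table(self, values, param="fad_tau_m"):
        df = pd.DataFrame({p: np.zeros(len(values)) + np.arange(len(values))
                           for p in OMI_PARAMETERS})
        df[param] = values
        df["tissue"] = "spleen"
        return df

    def test_simple_standardisation(self):
        z = zscore_matrix(self._table([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.values["fad_tau_m"], [-1.0, 0.0, 1.0])

    def test_preclip_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({p: rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 200)
                           for p in OMI_PARAMETERS})
        z = zscore_matrix(df)
        for col in z.values:
            assert abs(z.values[col].mean()) < 1e-9
            assert z.values[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_clipping_at_four_sd(self):
        vals = np.zeros(101)
        vals[-1] = 1000.0  # extreme outlier, raw z >> 4
        z = zscore_matrix(self._table(vals))
        assert z.values["fad_tau_m"].max() == pytest.approx(4.0)
        assert (z.values.abs() <= 4.0).all().all()

    def test_constant_column_zeros_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            z = zscore_matrix(self._table(np.full(5, 3.0)))
        assert (z.values["fad_tau_m"] == 0).all()
        assert any("constant" in r.message for r in caplog.records)

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            zscore_matrix(self._table([1.0]))

    def test_metadata_carried_not_standardised(self, rng):
        tab = _two_group_table(rng, n=40)
        z = zscore_matrix(tab)
        assert "tissue" in z.meta.columns
        assert "tissue" not in z.values.columns


class TestWardCluster:
    def test_duplicate_rows_merge_at_zero(self):
        mat = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        res = ward_cluster(mat)
        assert res.merge_heights[0] == pytest.approx(0.0)

    def test_three_points_on_line_closest_pair_first(self):
        # Ward cost of merging singletons {a},{b} is |a-b|^2/2: brute force
        # over the three pairs of (0, 1, 10) says {0,1} merges first
        pts = np.array([[0.0], [1.0], [10.0]])
        costs = {(i, j): (pts[i, 0] - pts[j, 0]) ** 2 / 2
                 for i in range(3) for j in range(i + 1, 3)}
        assert min(costs, key=costs.get) == (0, 1)
        res = ward_cluster(pts)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_heights_monotone_and_leaf_count(self, rng):
        mat = rng.normal(size=(30, 12))
        res = ward_cluster(mat)
        assert res.n_leaves == 30
        assert len(res.leaf_order) == 30
        assert (np.diff(res.merge_heights) >= -1e-12).all()

    def test_nan_rejected(self):
        mat = np.ones((4, 3))
        mat[0, 0] = np.nan
        with pytest.raises(DataError):
            ward_cluster(mat)

    def test_two_tissues_four_sd_apart_recovered(self, rng):
        # tissue mean vectors 4 within-group SD apart in every parameter:
        # the 2-cluster cut recovers the labels
        n = 100
        a = rng.normal(0.0, 1.0, size=(n, 12))
        b = rng.normal(4.0, 1.0, size=(n, 12))
        df = pd.DataFrame(np.vstack([a, b]), columns=list(OMI_PARAMETERS))
        z = zscore_matrix(df)
        res = ward_cluster(z)
        labels = res.cut(2)
        truth = np.repeat([0, 1], n)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_dropping_constant_column_changes_nothing(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 12)), columns=list(OMI_PARAMETERS))
        df["redox_ratio"] = 5.0  # constant -> z-scores all zero
        z12 = zscore_matrix(df)
        params11 = tuple(p for p in OMI_PARAMETERS if p != "redox_ratio")
        z11 = zscore_matrix(df, parameters=params11)
        np.testing.assert_allclose(
            ward_cluster(z12).linkage, ward_cluster(z11).linkage
        )
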