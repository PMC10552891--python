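"""Normalization, filtering, PCA and batch-adjustment behavior."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oxynet import preprocess as pp
from oxynet.containers import ExpressionMatrix, OxynetError


def _em(arr, layer="miRNA", scale="log2", features=None, samples=None,
        detection=None):
    arr = np.asarray(arr, float)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    det = None
    if detection is not None:
        det = pd.DataFrame(np.asarray(detection, bool), index=features,
                           columns=samples)
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples),
                            layer=layer, scale=scale, detection=det)


class TestQuantileNormalize:
    def test_two_column_rank_means(self):
        m = _em([[1, 2], [3, 4]])
        out = pp.quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self):
        m = _em([[1, 1, 1], [5, 5, 5], [2, 2, 2]])
        out = pp.quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_tie_gets_mean_of_spanned_rank_means(self):
        # col0 has a tie at value 2 spanning positions 0 and 1
        m = _em([[2, 1], [2, 5], [7, 9]])
        out = pp.quantile_normalize(m).values.to_numpy()
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)  # [1.5, 3.5, 8]
        np.testing.assert_allclose(out[:, 0],
                                   [(ref[0] + ref[1]) / 2, (ref[0] + ref[1]) / 2, ref[2]])
        np.testing.assert_allclose(out[:, 1], ref)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_idempotent_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(6, 3))  # continuous: ties have measure zero
        m = _em(arr)
        once = pp.quantile_normalize(m)
        twice = pp.quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy(), atol=1e-12)

    def test_columns_share_sorted_values(self, rng):
        m = _em(rng.normal(size=(20, 5)))
        out = pp.quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)


class TestLog2AndTPM:
    @pytest.mark.parametrize("value,offset,expected",
                             [(8, 0, 3), (0, 1, 0), (3, 1, 2)])
    def test_log2_values(self, value, offset, expected):
        m = _em([[value]], scale="counts", layer="mRNA")
        out = pp.log2_transform(m, offset=offset)
        assert out.values.iloc[0, 0] == expected
        assert out.scale == "log2"

    def test_log2_nonpositive_lists_offenders(self):
        m = _em([[4], [0]], scale="log2")
        with pytest.raises(OxynetError, match="f1"):
            pp.log2_transform(m, offset=0)

    def test_tpm_single_feature(self):
        m = _em([[17]], layer="mRNA", scale="counts")
        out = pp.counts_to_tpm(m, pd.Series([2.0], index=["f0"]))
        assert out.values.iloc[0, 0] == pytest.approx(1e6)

    def test_tpm_length_normalization(self):
        m = _em([[10], [10]], layer="mRNA", scale="counts")
        out = pp.counts_to_tpm(m, pd.Series([1.0, 2.0], index=["f0", "f1"]))
        np.testing.assert_allclose(out.values.to_numpy().ravel(),
                                   [666666.666667, 333333.333333], rtol=1e-9)

    def test_tpm_depth_invariance_and_column_sum(self, rng):
        arr = rng.integers(1, 100, size=(10, 3)).astype(float)
        lengths = pd.Series(rng.uniform(0.5, 5, 10), index=[f"f{i}" for i in range(10)])
        m = _em(arr, layer="mRNA", scale="counts")
        m2 = _em(arr * 2, layer="mRNA", scale="counts")
        t1 = pp.counts_to_tpm(m, lengths).values.to_numpy()
        t2 = pp.counts_to_tpm(m2, lengths).values.to_numpy()
        np.testing.assert_allclose(t1, t2, rtol=1e-9)
        np.testing.assert_allclose(t1.sum(axis=0), 1e6, rtol=1e-6)


class TestFilters:
    def test_extremes_of_signal_filter(self, rng):
        arr = rng.normal(8, 1, size=(10, 8))
        arr[0] = arr.max() + 1          # constant at matrix max -> retained
        arr[1] = arr.min() - 5          # constant below pooled 20th pct -> removed
        m = _em(arr)
        out, report = pp.filter_by_signal_percentile(m, 20, min_fraction=0.5)
        assert "f0" in out.feature_ids
        assert "f1" not in out.feature_ids
        assert report.features_before - report.features_after == len(report.removed_ids)

    def test_signal_filter_matches_brute_force(self, rng):
        # 10 features spanning deciles; exhaustive check at min_fraction=1.0
        arr = np.linspace(1, 10, 10)[:, None] + rng.normal(0, 0.1, size=(10, 5))
        m = _em(arr)
        out, _ = pp.filter_by_signal_percentile(m, 20, min_fraction=1.0)
        thr = np.percentile(arr, 20)
        expected = [f"f{i}" for i in range(10) if (arr[i] >= thr).all()]
        assert out.feature_ids == expected

    def test_detection_threshold_inclusive(self):
        det = np.zeros((3, 8), bool)
        det[0, :2] = True     # 25% exactly -> retained
        det[1, :1] = True     # 12.5% -> removed
        det[2, :] = True
        m = _em(np.ones((3, 8)) * 8, detection=det)
        out, report = pp.filter_by_detection_rate(m, min_rate=0.25)
        assert out.feature_ids == ["f0", "f2"]
        assert report.removed_ids == ("f1",)

    def test_all_detected_identity(self):
        m = _em(np.ones((4, 4)) * 8 + np.eye(4), detection=np.ones((4, 4)))
        out, _ = pp.filter_by_detection_rate(m)
        assert out.feature_ids == m.feature_ids

    def test_detection_filter_requires_flags(self, small_matrix):
        with pytest.raises(OxynetError, match="detection"):
            pp.filter_by_detection_rate(small_matrix)

    def test_filter_order_commutes_when_criteria_independent(self, rng):
        """Percentile-then-detection equals detection-then-percentile when
        detection flags are independent of the retained value range."""
        # low block kept below 20% of features so the pooled threshold
        # stays inside the expressed bulk in either filter order
        arr = rng.normal(8, 0.1, size=(20, 8))
        arr[:2] -= 12         # far-below-floor block
        det = np.ones((20, 8), bool)
        det[10:14, :] = False  # undetected block, signal untouched
        m = _em(arr, detection=det)
        a, _ = pp.filter_by_signal_percentile(m, 20, min_fraction=0.5)
        a, _ = pp.filter_by_detection_rate(a)
        b, _ = pp.filter_by_detection_rate(m)
        b, _ = pp.filter_by_signal_percentile(b, 20, min_fraction=0.5)
        # same pooled threshold regime in both orders for this fixture
        assert set(a.feature_ids) == set(b.feature_ids)


class TestPCA:
    def test_rank_one_matrix_single_component(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=6)
        m = _em(np.outer(u, v))
        _, _, frac = pp.pca(m, n_components=3)
        assert frac[0] == pytest.approx(1.0)

    def test_orthogonal_two_factor_fixture(self, rng):
        # samples x 2 scores with known variances, orthogonal loadings
        n = 40
        s1 = np.sqrt(9.0) * rng.standard_normal(n)
        s2 = np.sqrt(4.0) * rng.standard_normal(n)
        load = np.array([[1, 0], [0, 1], [0, 0]])
        X = (np.column_stack([s1, s2]) @ load.T).T  # features x samples
        m = _em(X)
        _, _, frac = pp.pca(m, n_components=2)
        # independent eigen-decomposition oracle on the sample covariance
        Xc = X.T - X.T.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        expected = eig[:2] / eig.sum()
        np.testing.assert_allclose(frac, expected, rtol=1e-8)

    def test_sample_permutation_equivariance(self, rng):
        arr = rng.normal(size=(8, 10))
        m = _em(arr)
        perm = rng.permutation(10)
        m2 = _em(arr[:, perm])
        s1, _, _ = pp.pca(m, 2)
        s2, _, _ = pp.pca(m2, 2)
        np.testing.assert_allclose(s2.to_numpy(), s1.to_numpy()[perm], atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(OxynetError, match="constant"):
            pp.pca(_em(np.full((3, 5), 2.0)))


class TestPCAOutliers:
    def test_displaced_sample_flagged(self):
        """The displaced sample is always caught; bystander flags stay at
        the null rate (the chi-distributed distance tail at k=3)."""
        caught = 0
        extras = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            arr = rng.normal(size=(30, 50))
            arr[:, 0] += 10 * arr.std() * rng.choice([-1, 1])
            m = _em(arr)
            flags = pp.pca_outlier_flags(m, n_components=3, k_sd=3)
            caught += "S0" in flags
            extras.append(len([f for f in flags if f != "S0"]))
        assert caught >= 38  # >=95% of seeds
        assert np.mean(extras) / 49 <= 0.02  # bystanders at the null rate

    def test_null_false_positive_rate(self):
        rates = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            m = _em(rng.normal(size=(30, 50)))
            rates.append(len(pp.pca_outlier_flags(m)) / 50)
        assert np.mean(rates) <= 0.02

    def test_duplicate_sample_not_flagged(self, rng):
        arr = rng.normal(size=(20, 30))
        arr[:, 1] = arr[:, 0]
        flags = pp.pca_outlier_flags(_em(arr))
        assert "S0" not in flags and "S1" not in flags


class TestComBat:
    # per-probe log2 noise SD 0.5: typical for array intensities, and small
    # enough that batch-mean sampling noise does not swamp the planted shift
    def _batched(self, rng, shift=0.0, scale=1.0, n_feat=200, n_per=60,
                 noise_sd=0.5):
        arr = rng.normal(8, noise_sd, size=(n_feat, 2 * n_per))
        arr[:, n_per:] = 8 + (arr[:, n_per:] - 8) * scale + shift
        m = _em(arr, samples=[f"S{j}" for j in range(2 * n_per)])
        batches = pd.Series(["B1"] * n_per + ["B2"] * n_per, index=m.sample_ids)
        return m, batches

    def test_single_batch_identity(self, rng):
        m = _em(rng.normal(8, 1, size=(10, 6)))
        batches = pd.Series(["B1"] * 6, index=m.sample_ids)
        out, model = pp.combat_adjust(m, batches)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())
        assert model.batches == ["B1"]

    @pytest.mark.parametrize("mode", ["parametric", "nonparametric"])
    def test_planted_location_shift_removed(self, rng, mode):
        m, batches = self._batched(rng, shift=2.0)
        out, _ = pp.combat_adjust(m, batches, mode=mode)
        X0, X1 = m.values.to_numpy(), out.values.to_numpy()
        before = np.abs(X0[:, 60:].mean(1) - X0[:, :60].mean(1))
        after = np.abs(X1[:, 60:].mean(1) - X1[:, :60].mean(1))
        assert np.mean(after <= 0.1 * before) >= 0.95

    def test_planted_scale_inflation_removed(self, rng):
        m, batches = self._batched(rng, scale=np.sqrt(3.0), n_per=100)
        out, _ = pp.combat_adjust(m, batches)
        X1 = out.values.to_numpy()
        ratio = X1[:, 100:].var(axis=1) / X1[:, :100].var(axis=1)
        assert np.mean((ratio >= 0.8) & (ratio <= 1.25)) >= 0.9

    def test_grand_mean_preserved(self, rng):
        m, batches = self._batched(rng, shift=1.0)
        out, _ = pp.combat_adjust(m, batches, mode="parametric")
        np.testing.assert_allclose(out.values.to_numpy().mean(axis=1),
                                   m.values.to_numpy().mean(axis=1), atol=1e-8)

    def test_single_sample_batch_rejected(self, rng):
        m = _em(rng.normal(size=(5, 5)))
        batches = pd.Series(["B1"] * 4 + ["B2"], index=m.sample_ids)
        with pytest.raises(OxynetError, match="<2 samples"):
            pp.combat_adjust(m, batches)

    def test_missing_batch_label_rejected(self, rng):
        m = _em(rng.normal(size=(5, 4)))
        batches = pd.Series(["B1", "B1"], index=m.sample_ids[:2])
        with pytest.raises(OxynetError, match="no batch label"):
            pp.combat_adjust(m, batches)


class TestDichotomize:
    def test_median_split_ge_rule(self):
        labels, mode = pp.dichotomize_expression(
            pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert mode == "median-split"
        assert set(labels[labels == "high"].index) == {"c", "d"}

    def test_any_vs_none_when_median_zero(self):
        labels, mode = pp.dichotomize_expression(
            pd.Series([0, 0, 0, 5], index=list("abcd")))
        assert mode == "any-vs-none"
        assert list(labels[labels == "high"].index) == ["d"]

    def test_constant_rejected(self):
        with pytest.raises(OxynetError, match="identical"):
            pp.dichotomize_expression(pd.Series([2, 2, 2, 2]))
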