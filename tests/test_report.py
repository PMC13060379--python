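"""Composite prediction, agreement, symmetry and edge classification."""

import numpy as np
import pandas as pd
import pytest

from netcog.connectome import EdgeMask
from netcog.report import (
    agreement,
    classify_edges,
    composite_predict,
    hemispheric_symmetry,
    pct,
    spatial_map_correlation,
)


class TestCompositePredict:
    def test_all_zero_weights_give_zero_scores(self):
        rng = np.random.default_rng(0)
        E = rng.random((50, 10))
        scores = composite_predict(E, np.zeros(10))
        assert np.allclose(scores, 0.0)

    def test_single_weight_reproduces_edge_zscore(self):
        rng = np.random.default_rng(1)
        E = rng.random((100, 5))
        w = np.zeros(5)
        w[2] = 1.0
        scores = composite_predict(E, w)
        z = (E[:, 2] - E[:, 2].mean()) / E[:, 2].std()
        assert np.allclose(scores, z)

    def test_invariant_to_affine_rescaling_of_columns(self):
        rng = np.random.default_rng(2)
        E = rng.random((80, 6))
        w = rng.normal(size=6)
        s1 = composite_predict(E, w)
        E2 = E * np.array([1, 5, 0.1, 2, 3, 7]) + np.arange(6)
        assert np.allclose(composite_predict(E2, w), s1)

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(3)
        E = rng.random((50, 4))
        E[:, 1] = 2.0
        w = np.ones(4)
        scores = composite_predict(E, w)
        expect = composite_predict(E[:, [0, 2, 3]], np.ones(3))
        assert np.allclose(scores, expect)

    def test_train_statistics_mode(self):
        rng = np.random.default_rng(4)
        train = rng.random((60, 3))
        test = rng.random((40, 3))
        w = np.array([1.0, -0.5, 0.2])
        s = composite_predict(test, w, means=train.mean(0),
                              sds=train.std(0))
        expect = ((test - train.mean(0)) / train.std(0)) @ w
        assert np.allclose(s, expect)


class TestAgreement:
    def test_identical_and_negated(self):
        v = np.array([0.1, -0.2, 0.4, 0.05])
        assert agreement(v, v) == pytest.approx(1.0)
        assert agreement(v, -v) == pytest.approx(-1.0)

    def test_arithmetic_oracle(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 4, 5, 9])
        # direct formula: cov / (sd_a sd_b)
        num = ((a - a.mean()) * (b - b.mean())).mean()
        expect = num / (a.std() * b.std())
        assert agreement(a, b) == pytest.approx(expect)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            agreement([1, 1, 1], [1, 2, 3])


class TestHemisphericSymmetry:
    def test_mirrored_betas(self, atlas):
        rng = np.random.default_rng(5)
        v = np.zeros(85)
        for l, r in atlas.bilateral_pairs:
            v[l] = v[r] = rng.normal()
        assert hemispheric_symmetry(v, atlas) == pytest.approx(1.0)

    def test_antimirrored_betas(self, atlas):
        rng = np.random.default_rng(6)
        v = np.zeros(85)
        for l, r in atlas.bilateral_pairs:
            x = rng.normal()
            v[l], v[r] = x, -x
        assert hemispheric_symmetry(v, atlas) == pytest.approx(-1.0)

    def test_matches_direct_paired_computation(self, atlas):
        rng = np.random.default_rng(7)
        v = rng.normal(size=85)
        pairs = np.array(atlas.bilateral_pairs)
        expect = np.corrcoef(v[pairs[:, 0]], v[pairs[:, 1]])[0, 1]
        assert hemispheric_symmetry(v, atlas) == pytest.approx(expect)


class TestClassifyEdges:
    def test_pure_left_mask(self, atlas):
        left = [i for i in range(85) if atlas.hemispheres[i] == "left"]
        mask = EdgeMask.from_pairs([(left[0], left[1]), (left[2], left[3]),
                                    (left[4], left[10])])
        cls = classify_edges(mask, atlas)
        hs = cls.hemisphere_summary.set_index("category")
        assert hs.loc["intra_left", "count"] == 3
        assert hs.loc["intra_left", "pct"] == 100.0

    def test_hand_labelled_mixed_mask(self, atlas):
        bs = atlas.midline_index
        # two intra-left, one intra-right, one inter, one brainstem edge
        mask = EdgeMask.from_pairs([(0, 1), (2, 3), (34, 35), (0, 34), (0, bs)])
        cls = classify_edges(mask, atlas)
        hs = cls.hemisphere_summary.set_index("category")["count"]
        assert hs["intra_left"] == 2
        assert hs["intra_right"] == 1
        assert hs["inter"] == 1
        assert hs["brainstem_involved"] == 1

    def test_categories_partition_the_mask(self, small_cohort, atlas):
        from netcog.thresholding import consistency_threshold

        mask = consistency_threshold(small_cohort.edge_weights["SC"], 0.30)
        cls = classify_edges(mask, atlas)
        assert cls.hemisphere_summary["count"].sum() == len(mask)
        assert cls.lobe_summary["count"].sum() == len(mask)
        # lobe-pair matrix diagonal counts intra-lobe edges
        intra = cls.lobe_summary.set_index("category")["count"].get("intra_lobe", 0)
        assert np.diag(cls.lobe_pair_counts).sum() == intra

    def test_reference_network_percentage_arithmetic(self):
        # hemispheric split of an 818-edge reference network
        assert pct(647, 818) == 79.1
        assert pct(166, 818) == 20.3
        assert pct(818, 1071) == 76.4
        assert pct(818, 3570) == 22.9
        assert pct(943, 1071) == 88.0
        assert pct(391, 818) == 47.8


class TestSpatialMapCorrelation:
    def test_identical_map(self, atlas):
        names = [atlas.names[i] for i in atlas.cortical_indices()]
        rng = np.random.default_rng(8)
        v = pd.Series(rng.normal(size=len(names)), index=names)
        r, unmatched = spatial_map_correlation(v, v.copy())
        assert r == pytest.approx(1.0)
        assert unmatched == []

    def test_permutation_null_centered_on_zero(self, atlas):
        names = [atlas.names[i] for i in atlas.cortical_indices()]
        rng = np.random.default_rng(9)
        v = pd.Series(rng.normal(size=68), index=names)
        ext = rng.normal(size=68)
        rs = []
        for _ in range(500):
            perm = rng.permutation(ext)
            rs.append(spatial_map_correlation(
                v, pd.Series(perm, index=names))[0])
        assert abs(np.mean(rs)) < 0.02

    def test_known_covariance_oracle(self, atlas):
        names = [atlas.names[i] for i in atlas.cortical_indices()]
        rng = np.random.default_rng(10)
        a = rng.normal(size=68)
        b = 0.5 * a + rng.normal(size=68)
        r, _ = spatial_map_correlation(pd.Series(a, index=names),
                                       pd.Series(b, index=names))
        assert r == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_too_few_matches_error(self, atlas):
        v = pd.Series([1.0] * 85, index=atlas.names)
        with pytest.raises(ValueError, match="matched"):
            spatial_map_correlation(v, pd.Series([1.0, 2.0],
                                                 index=["x", "y"]))
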