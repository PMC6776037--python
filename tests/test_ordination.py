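"""Feature building, Bray-Curtis, nMDS and post hoc vector fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from phagediv.ordination import (
    FeatureMatrix,
    OrdinationResult,
    bray_curtis,
    build_features,
    fit_vectors,
    nmds,
)
from phagediv.uss import USSProfile


def _profile(rid, gc, hin=0.0, apl=0.0):
    return USSProfile(record_id=rid, length_acgt=10_000, gc_percent=gc,
                      hin_per_mb=hin, apl_per_mb=apl,
                      hin_per_mb_1mm=hin, apl_per_mb_1mm=apl)


class TestBuildFeatures:
    def test_two_point_delta_gc(self):
        fm = build_features(
            [_profile("a", 40.0, hin=10), _profile("b", 50.0, hin=10)],
            {"a": "A", "b": "B"},
        )
        assert fm.values.loc["A", "delta_gc"] == 0.0
        assert fm.values.loc["B", "delta_gc"] == 100.0

    def test_hin_standardized_by_maximum(self):
        fm = build_features(
            [_profile("a", 40.0, hin=750.0), _profile("b", 42.0, hin=375.0)],
            {"a": "A", "b": "B"},
        )
        assert fm.values.loc["A", "hin_per_mb"] == pytest.approx(100.0)
        assert fm.values.loc["B", "hin_per_mb"] == pytest.approx(50.0)

    def test_degenerate_column_flagged_all_zero(self):
        fm = build_features(
            [_profile("a", 40.0, hin=10), _profile("b", 42.0, hin=20)],
            {"a": "A", "b": "B"},
        )
        assert "apl_per_mb" in fm.degenerate_columns
        assert (fm.values["apl_per_mb"] == 0.0).all()

    def test_members_averaged_per_entity(self):
        fm = build_features(
            [_profile("a1", 40.0, hin=100), _profile("a2", 44.0, hin=300),
             _profile("b", 38.0, hin=400)],
            {"a1": "A", "a2": "A", "b": "B"},
        )
        # entity A mean GC 42 vs B 38 -> delta {4, 0} -> scaled {100, 0}
        assert fm.values.loc["A", "delta_gc"] == pytest.approx(100.0)
        assert fm.values.loc["B", "delta_gc"] == pytest.approx(0.0)
        assert fm.values.loc["A", "hin_per_mb"] == pytest.approx(50.0)

    def test_standardization_idempotent(self):
        fm = build_features(
            [_profile("a", 40.0, hin=750.0, apl=5.0), _profile("b", 50.0, hin=375.0)],
            {"a": "A", "b": "B"},
        )
        vals = fm.values
        rescaled = 100.0 * vals / vals.max()
        pd.testing.assert_frame_equal(vals, rescaled)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        df = pd.DataFrame([[5.0, 3.0], [5.0, 3.0]], index=["a", "b"])
        assert bray_curtis(df).loc["a", "b"] == 0.0

    def test_disjoint_rows_one(self):
        df = pd.DataFrame([[100.0, 0, 0], [0, 100.0, 0]], index=["a", "b"])
        assert bray_curtis(df).loc["a", "b"] == pytest.approx(1.0)

    def test_half_magnitude_third(self):
        df = pd.DataFrame([[100.0, 0, 0], [50.0, 0, 0]], index=["a", "b"])
        assert bray_curtis(df).loc["a", "b"] == pytest.approx(1 / 3)

    def test_all_zero_pair_zero_by_convention(self):
        df = pd.DataFrame([[0.0, 0.0], [0.0, 0.0]], index=["a", "b"])
        assert bray_curtis(df).loc["a", "b"] == 0.0

    def test_properties_on_random_matrices(self, rng):
        for _ in range(10):
            df = pd.DataFrame(rng.uniform(0, 100, size=(6, 3)))
            d = bray_curtis(df).to_numpy()
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_negative_features_rejected(self):
        df = pd.DataFrame([[1.0, -0.5], [0.5, 1.0]])
        with pytest.raises(ValueError):
            bray_curtis(df)


class TestNMDS:
    def _planar(self, seed, n=6):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        labels = [f"p{i}" for i in range(n)]
        return pts, pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)

    def test_exact_planar_embedding_recovered(self):
        pts, D = self._planar(seed=3)
        res = nmds(D, n_restarts=10, seed=5)
        assert res.stress < 0.01
        emb = pdist(res.coordinates.to_numpy())
        assert np.array_equal(np.argsort(emb), np.argsort(pdist(pts)))

    def test_equidistant_four_points(self):
        D = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=list("wxyz"), columns=list("wxyz"))
        res = nmds(D, n_restarts=10, seed=1)
        assert res.stress < 0.05

    def test_determinism_and_restart_monotonicity(self):
        _, D = self._planar(seed=8, n=7)
        r1 = nmds(D, n_restarts=3, seed=9)
        r2 = nmds(D, n_restarts=3, seed=9)
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)
        r_more = nmds(D, n_restarts=12, seed=9)
        assert r_more.stress <= r1.stress + 1e-12

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(12)
        mat = rng.uniform(0.2, 1.0, size=(8, 8))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        D = pd.DataFrame(mat)
        res = nmds(D, n_restarts=4, seed=2)
        assert np.all(np.diff(res.stress_trace) <= 1e-9)

    def test_comparable_to_sklearn_nonmetric_mds(self):
        """Independent route: sklearn's nonmetric SMACOF reaches similar stress."""
        from sklearn.manifold import MDS

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 3))
        D = pd.DataFrame(squareform(pdist(pts)))
        ours = nmds(D, n_restarts=8, seed=3)
        ref = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                  normalized_stress=True, n_init=8, random_state=0,
                  max_iter=300, eps=1e-9)
        ref.fit(D.to_numpy())
        assert abs(ours.stress - ref.stress_) < 0.05
        assert ours.stress <= ref.stress_ + 0.02

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0, 1.0, 2], [1.1, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nmds(D, seed=0)

    def test_too_few_entities_rejected(self):
        D = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="at least"):
            nmds(D, dims=2, seed=0)


class TestFitVectors:
    def _result(self, coords):
        return OrdinationResult(
            coordinates=coords, stress=0.0, n_restarts=1, seed=0,
            stress_trace=np.array([0.0]),
        )

    def _square_coords(self):
        return pd.DataFrame(
            [[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]],
            index=list("abcd"), columns=["axis1", "axis2"],
        )

    def _features(self, values):
        df = pd.DataFrame({"delta_gc": values}, index=list("abcd"))
        return FeatureMatrix(values=df, degenerate_columns=[])

    def test_variable_equal_to_axis1(self):
        coords = self._square_coords()
        feats = self._features(coords["axis1"].to_numpy())
        vec = fit_vectors(self._result(coords), feats)
        assert vec.loc["delta_gc", "r_axis1"] == pytest.approx(1.0)
        assert vec.loc["delta_gc", "r_axis2"] == pytest.approx(0.0, abs=1e-12)
        assert vec.loc["delta_gc", "multiple_r"] == pytest.approx(1.0)

    def test_orthogonal_variable_r_zero(self):
        coords = self._square_coords()
        # +1,-1,-1,+1 is orthogonal to both axes on the square
        feats = self._features(np.array([1.0, -1.0, -1.0, 1.0]))
        vec = fit_vectors(self._result(coords), feats)
        assert vec.loc["delta_gc", "multiple_r"] == pytest.approx(0.0, abs=1e-6)

    def test_diagonal_variable_direction(self):
        coords = self._square_coords()
        feats = self._features(
            (coords["axis1"] + coords["axis2"]).to_numpy()
        )
        vec = fit_vectors(self._result(coords), feats)
        assert vec.loc["delta_gc", "r_axis1"] == pytest.approx(1 / np.sqrt(2))
        assert vec.loc["delta_gc", "r_axis2"] == pytest.approx(1 / np.sqrt(2))
        assert vec.loc["delta_gc", "multiple_r"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        coords = self._square_coords()
        feats = self._features(np.zeros(4))
        vec = fit_vectors(self._result(coords), feats)
        assert bool(vec.loc["delta_gc", "defined"]) is False
        assert np.isnan(vec.loc["delta_gc", "multiple_r"])
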