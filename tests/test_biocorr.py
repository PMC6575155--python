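"""Lasso biomarker-activation framework: targets, fitting, clamping,
MSE, segment matching, and importance elimination."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from enteronet.biocorr import (
    ActivationTargetMatrix,
    build_activation_targets,
    cross_validate_lasso,
    evaluate_activation_mse,
    fit_lasso_set,
    importance_elimination_curve,
    match_segments,
    predict_activations,
)
from enteronet.synthgen import BiomarkerTable
from enteronet.traceviz import SegmentRecord
from enteronet.probes import make_probe_model


def _targets(values: np.ndarray, case_ids=None) -> ActivationTargetMatrix:
    case_ids = case_ids or [f"c{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(
        values, index=case_ids,
        columns=[f"map_{j}" for j in range(values.shape[1])],
    )
    return ActivationTargetMatrix(values=frame)


def _markers(values: np.ndarray, names=None, case_ids=None) -> BiomarkerTable:
    names = names or [f"m{i}" for i in range(values.shape[1])]
    case_ids = case_ids or [f"c{i}" for i in range(values.shape[0])]
    return BiomarkerTable(pd.DataFrame(values, index=case_ids, columns=names))


class TestActivationTargets:
    def test_case_maximum_is_elementwise_over_images(self):
        model = make_probe_model(input_size=200)
        # build a 200x200 cohort on the fly
        from enteronet.synthgen import SyntheticCohortSpec, generate_cohort
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            spec = SyntheticCohortSpec(
                n_cases_per_class=1, images_per_case=2,
                image_height=200, image_width=200, seed=2,
            )
            manifest = generate_cohort(spec, td)
            targets = build_activation_targets(model, manifest)
            assert targets.values.shape == (3, 2)
            # recompute independently from per-image maxima
            from enteronet.cnn import layer_activations
            from enteronet.imgprep import RgbImage

            for rec in manifest.records:
                maxima = []
                for rel in rec.image_paths:
                    img = RgbImage.load(manifest.resolve(rel))
                    grid = layer_activations(model, img, "conv4")
                    maxima.append(grid.max(axis=(0, 1)))
                np.testing.assert_allclose(
                    targets.values.loc[rec.case_id].to_numpy(),
                    np.max(maxima, axis=0),
                    rtol=1e-6,
                )
                for j in range(2):
                    assert (rec.case_id, j) in targets.segments


class TestLassoFit:
    def test_model_count_matches_maps(self):
        rng = np.random.default_rng(0)
        x = rng.random((20, 4))
        y = rng.random((20, 6))
        models = fit_lasso_set(_markers(x), _targets(y), seed=0)
        assert models.n_maps == 6
        assert models.coefficients.shape == (6, 4)

    def test_huge_penalty_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        x = rng.random((15, 3))
        y = rng.random((15, 2))
        models = fit_lasso_set(_markers(x), _targets(y), alpha=1e6)
        np.testing.assert_allclose(models.coefficients, 0.0)
        np.testing.assert_allclose(models.intercepts, y.mean(axis=0), rtol=1e-10)

    def test_recovers_single_marker_coefficient(self):
        """Noiseless target = 2 * marker_0: tiny penalty recovers the
        coefficient within 5% and zeros elsewhere."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40, 3))
        y = (2.0 * x[:, [0]]) + 1.0
        models = fit_lasso_set(_markers(x), _targets(y), alpha=1e-4)
        # coefficient is on standardized markers: scale back
        coef = models.coefficients[0] / models.marker_scale
        assert coef[0] == pytest.approx(2.0, rel=0.05)
        assert abs(coef[1]) < 0.05 and abs(coef[2]) < 0.05

    def test_zero_penalty_matches_least_squares(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((30, 3))
        beta = np.array([1.5, -2.0, 0.7])
        y = (x @ beta)[:, None] + 0.3
        models = fit_lasso_set(_markers(x), _targets(y), alpha=1e-9)
        xs = (x - models.marker_mean) / models.marker_scale
        ls_coef, *_ = np.linalg.lstsq(
            np.column_stack([xs, np.ones(len(xs))]), y[:, 0], rcond=None
        )
        np.testing.assert_allclose(models.coefficients[0], ls_coef[:3], atol=1e-5)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_lasso_set(_markers(np.ones((2, 2))), _targets(np.ones((2, 2))))

    def test_disjoint_case_ids_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            fit_lasso_set(
                _markers(np.ones((4, 2)), case_ids=list("abcd")),
                _targets(np.ones((4, 2)), case_ids=list("wxyz")),
            )

    def test_missing_values_flagged_not_dropped(self):
        x = np.ones((5, 2))
        x[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            fit_lasso_set(_markers(x), _targets(np.ones((5, 2))))


class TestPredict:
    def _models(self, coefs, intercepts, names):
        from enteronet.biocorr import LassoModelSet

        coefs = np.asarray(coefs, float)
        return LassoModelSet(
            marker_names=list(names),
            coefficients=coefs,
            intercepts=np.asarray(intercepts, float),
            penalties=np.zeros(len(intercepts)),
            marker_mean=np.zeros(coefs.shape[1]),
            marker_scale=np.ones(coefs.shape[1]),
        )

    def test_dot_product_arithmetic(self):
        models = self._models([[1.0, -1.0]], [0.5], ["a", "b"])
        est = predict_activations(models, {"a": 2.0, "b": 1.0})
        assert est[0] == pytest.approx(1.5)

    def test_negative_estimates_clamped(self):
        models = self._models([[1.0]], [-0.3], ["a"])
        assert predict_activations(models, {"a": 0.0})[0] == 0.0
        raw = predict_activations(models, {"a": 0.0}, clamp_negative=False)
        assert raw[0] == pytest.approx(-0.3)

    def test_zero_coefficients_return_intercepts(self):
        models = self._models(np.zeros((3, 2)), [0.1, 0.2, 0.3], ["a", "b"])
        np.testing.assert_allclose(
            predict_activations(models, {"a": 9.0, "b": -4.0}), [0.1, 0.2, 0.3]
        )

    def test_missing_marker_named(self):
        models = self._models([[1.0, 1.0]], [0.0], ["a", "b"])
        with pytest.raises(ValueError, match="b"):
            predict_activations(models, {"a": 1.0})

    def test_clamping_never_hurts_nonnegative_truth(self):
        """MSE(clamped) <= MSE(raw) whenever actual values are >= 0."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            raw = rng.normal(0, 2, (4, 8))
            actual = np.abs(rng.normal(0, 2, (4, 8)))
            _, mse_raw = evaluate_activation_mse(raw, actual)
            _, mse_clamped = evaluate_activation_mse(np.maximum(raw, 0), actual)
            assert mse_clamped <= mse_raw + 1e-12


class TestMse:
    def test_perfect_prediction(self):
        a = np.random.default_rng(0).random((3, 32))
        _, mse = evaluate_activation_mse(a, a)
        assert mse == 0.0

    def test_single_entry_difference(self):
        a = np.zeros((1, 32))
        b = np.zeros((1, 32))
        b[0, 7] = 1.0
        per_case, mse = evaluate_activation_mse(a, b)
        assert mse == pytest.approx(1 / 32)
        assert per_case[0] == pytest.approx(1 / 32)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        est = rng.random((6, 5))
        act = rng.random((6, 5))
        per_case, mse = evaluate_activation_mse(est, act)
        for i in range(6):
            acc = 0.0
            for j in range(5):
                acc += (est[i, j] - act[i, j]) ** 2
            assert per_case[i] == pytest.approx(acc / 5, rel=1e-12)
        assert mse == pytest.approx(np.mean(per_case), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_activation_mse(np.ones((2, 3)), np.ones((2, 4)))


def _segment(value, tag):
    return SegmentRecord(
        pixels=np.zeros((4, 4, 3), np.uint8),
        source_id=tag, center=(0, 0), value=value,
        feature_map_index=0, box=(0, 0, 4, 4),
    )


class TestMatchSegments:
    def test_exact_match_zero_difference(self):
        lib = {("a", 0): _segment(0.7, "a")}
        res = match_segments([0.7], lib)
        assert res.differences[0] == 0.0
        assert res.matched[0].source_id == "a"

    def test_nearest_value_selected(self):
        lib = {("a", 0): _segment(0.2, "a"), ("b", 0): _segment(0.6, "b")}
        res = match_segments([0.5], lib)
        assert res.matched[0].source_id == "b"
        assert res.differences[0] == pytest.approx(0.1)

    def test_all_maps_returned_sorted(self):
        rng = np.random.default_rng(1)
        lib = {}
        for j in range(32):
            for c in "abc":
                lib[(c, j)] = _segment(float(rng.random()), f"{c}{j}")
        res = match_segments(rng.random(32), lib)
        assert len(res.matched) == 32
        diffs_sorted = res.differences[res.order]
        assert np.all(np.diff(diffs_sorted) >= 0)

    def test_empty_library_map_named(self):
        with pytest.raises(ValueError, match="map 1"):
            match_segments([0.5, 0.5], {("a", 0): _segment(0.1, "a")})


class TestEliminationAndRecovery:
    def test_curve_length_equals_marker_count(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((24, 4))
        y = x[:, [0]] * 2 + rng.normal(0, 0.05, (24, 1))
        curve = importance_elimination_curve(
            _markers(x), _targets(y), k=4, n_trees=30, seed=0
        )
        assert len(curve["mse_curve"]) == 4
        assert curve["subset_sizes"] == [4, 3, 2, 1]
        assert all(v >= 0 for v in curve["mse_curve"])

    def test_three_signal_markers_recovered(self):
        """Six markers, exactly three informative: the argmin subset of the
        elimination curve contains the three signal markers."""
        rng = np.random.default_rng(5)
        n = 36
        x = rng.standard_normal((n, 6))
        b = np.zeros((6, 4))
        b[0, 0], b[1, 1], b[2, 2] = 2.0, -1.5, 1.0
        b[0, 3] = 1.0
        y = x @ b + rng.normal(0, 0.05, (n, 4))
        names = [f"m{i}" for i in range(6)]
        curve = importance_elimination_curve(
            _markers(x, names=names), _targets(y), k=4, n_trees=60, seed=1
        )
        assert {"m0", "m1", "m2"} <= set(curve["best_subset"])

    def test_heldout_correlation_on_linear_chain(self):
        """Noiseless linear marker -> activation chain: held-out predicted
        activations correlate with actual at r >= 0.9."""
        rng = np.random.default_rng(6)
        n, n_maps = 30, 4
        act = np.abs(rng.standard_normal((n, n_maps))) + 0.2
        mix = rng.standard_normal((n_maps, 6))
        markers = act @ mix  # markers are exact linear images of activations
        table = _markers(markers)
        targets = _targets(act)
        from sklearn.model_selection import KFold

        from enteronet.biocorr import fit_lasso_set, predict_activations

        preds, actus = [], []
        for tr, te in KFold(5, shuffle=True, random_state=0).split(np.arange(n)):
            sub_t = _targets(act[tr], case_ids=[f"c{i}" for i in tr])
            sub_m = _markers(markers[tr], case_ids=[f"c{i}" for i in tr])
            models = fit_lasso_set(sub_m, sub_t, seed=0)
            for i in te:
                row = pd.Series(markers[i], index=table.marker_names)
                preds.append(predict_activations(models, row))
                actus.append(act[i])
        r = np.corrcoef(np.ravel(preds), np.ravel(actus))[0, 1]
        assert r >= 0.9

    def test_cross_validate_reports_mean_and_variance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((25, 3))
        y = np.abs(x[:, [0]]) + rng.normal(0, 0.1, (25, 2))
        cv = cross_validate_lasso(_markers(x), _targets(y), k=5, seed=0)
        assert cv["mean_mse"] >= 0
        assert cv["fold_mse_variance"] >= 0
        assert len(cv["fold_mses"]) == 5
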