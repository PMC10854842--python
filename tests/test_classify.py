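"""From-scratch LDA against hand-computed and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alkanediet import (
    DegenerateModelError,
    DietClassifier,
    SimConfig,
    ValidationError,
    confusion_matrix,
    lda_fit,
    lda_predict,
    per_marker_report,
    simulate_flock,
)


def _two_clouds(rng, n=20, p=5, sep=5.0):
    a = rng.normal(0.0, 1.0, size=(n, p))
    b = rng.normal(sep, 1.0, size=(n, p))
    X = np.vstack([a, b])
    y = ["ctrl"] * n + ["mix"] * n
    return X, y


class TestFit:
    def test_one_dimensional_hand_computed_case(self):
        # class A = {1,2,3}, class B = {7,8,9}: pooled var 1, LD1 coef 1
        X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        y = ["A", "A", "A", "B", "B", "B"]
        model = lda_fit(X, y)
        assert model.classes == ("A", "B")
        assert model.class_means[:, 0] == pytest.approx([2.0, 8.0])
        assert model.pooled_cov[0, 0] == pytest.approx(1.0)
        assert model.ld_coefficients[0, 0] == pytest.approx(1.0)
        assert model.priors == pytest.approx([0.5, 0.5])

    def test_scores_have_unit_pooled_within_class_variance(self):
        rng = np.random.default_rng(4)
        X, y = _two_clouds(rng)
        model = lda_fit(X, y)
        scores = model.scores(X)[:, 0]
        pooled = 0.0
        for c in model.classes:
            sel = [yi == c for yi in y]
            pooled += (np.count_nonzero(sel) - 1) * scores[sel].var(ddof=1)
        pooled /= len(y) - len(model.classes)
        assert pooled == pytest.approx(1.0)

    def test_sign_convention_first_nonzero_coefficient_positive(self):
        rng = np.random.default_rng(5)
        X, y = _two_clouds(rng)
        model = lda_fit(X, y)
        first_nonzero = model.ld_coefficients[:, 0][
            np.flatnonzero(np.abs(model.ld_coefficients[:, 0]) > 1e-10)[0]
        ]
        assert first_nonzero > 0

    def test_coincident_class_means_are_degenerate(self):
        X = np.array([[1.0], [3.0], [1.0], [3.0]])
        with pytest.raises(DegenerateModelError, match="separation"):
            lda_fit(X, ["A", "A", "B", "B"])

    def test_zero_variance_marker_makes_covariance_singular(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [7.0, 5.0], [8.0, 5.0]])
        with pytest.raises(DegenerateModelError, match="ridge"):
            lda_fit(X, ["A", "A", "B", "B"])

    def test_class_needs_at_least_two_animals(self):
        with pytest.raises(ValidationError):
            lda_fit(np.array([[1.0], [2.0], [3.0]]), ["A", "A", "B"])

    def test_bad_priors_rejected(self):
        X = np.array([[1.0], [2.0], [7.0], [8.0]])
        with pytest.raises(ValidationError, match="priors"):
            lda_fit(X, ["A", "A", "B", "B"], priors={"A": 0.8, "B": 0.4})


class TestPredict:
    def test_training_point_at_a_class_mean_goes_to_that_class(self):
        rng = np.random.default_rng(6)
        X, y = _two_clouds(rng)
        model = lda_fit(X, y)
        assert lda_predict(model, model.class_means) == list(model.classes)

    def test_midpoint_tie_goes_to_first_class_with_warning(self):
        X = np.array([[1.0], [3.0], [7.0], [9.0]])
        model = lda_fit(X, ["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="tied"):
            assert lda_predict(model, np.array([[5.0]])) == ["A"]

    def test_dimension_mismatch_rejected(self):
        X = np.array([[1.0], [2.0], [7.0], [8.0]])
        model = lda_fit(X, ["A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            lda_predict(model, np.array([[1.0, 2.0]]))

    def test_separable_clouds_classify_perfectly(self):
        rng = np.random.default_rng(7)
        X, y = _two_clouds(rng, sep=8.0)
        model = lda_fit(X, y)
        cm = confusion_matrix(y, lda_predict(model, X), model.classes)
        assert np.all(cm == np.diag(np.diag(cm)))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.01, 100.0))
    def test_affine_invariance_of_predictions(self, seed, scale):
        rng = np.random.default_rng(seed)
        X, y = _two_clouds(rng, n=10, p=3, sep=2.0)
        model = lda_fit(X, y)
        scaled = X.copy()
        scaled[:, 1] *= scale
        model_s = lda_fit(scaled, y)
        assert lda_predict(model, X) == lda_predict(model_s, scaled)
        # coefficients rescale inversely on the scaled column
        assert model_s.ld_coefficients[1, 0] * scale == pytest.approx(
            model.ld_coefficients[1, 0], rel=1e-6
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_density_ratio_oracle(self, seed):
        """Two-class prediction equals thresholding the Gaussian log-density
        ratio with pooled covariance and log-prior offset."""
        rng = np.random.default_rng(seed)
        X, y = _two_clouds(rng, n=8, p=3, sep=1.5)
        model = lda_fit(X, y)
        Sinv = np.linalg.inv(model.pooled_cov)
        mu_a, mu_b = model.class_means

        def oracle(x):
            def logd(mu, prior):
                d = x - mu
                return -0.5 * d @ Sinv @ d + np.log(prior)

            return (
                model.classes[0]
                if logd(mu_a, model.priors[0]) >= logd(mu_b, model.priors[1])
                else model.classes[1]
            )

        probe = rng.normal(0.75, 2.0, size=(20, 3))
        assert lda_predict(model, probe) == [oracle(x) for x in probe]

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(12)
        X, y = _two_clouds(rng, n=15, p=4, sep=1.0)
        model = lda_fit(X, y)
        ref = sklearn.LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        probe = rng.normal(0.5, 2.0, size=(50, 4))
        assert lda_predict(model, probe) == list(ref.predict(probe))


class TestPerMarkerReport:
    def test_degenerate_marker_recorded_without_breaking_others(self):
        rng = np.random.default_rng(8)
        X, y = _two_clouds(rng, p=2, sep=4.0)
        X = np.column_stack([X, np.full(len(y), 3.0)])  # constant third marker
        rows = per_marker_report(X, y, ["C25", "C29", "C31"])
        by_name = {r.model_name: r for r in rows}
        assert by_name["C31"].error is not None
        assert by_name["C25"].confusion is not None
        assert by_name["C29"].confusion is not None

    def test_zero_within_class_variance_resubstitutes_perfectly(self):
        X = np.array([[0.0, 1.0]] * 5 + [[4.0, 3.0]] * 5)
        y = ["ctrl"] * 5 + ["mix"] * 5
        # exact zero within-class variance is singular; nudge one coordinate
        X = X + np.arange(10)[:, None] * 1e-6
        rows = per_marker_report(X, y, ["C29", "C31"])
        for r in rows:
            if r.confusion is not None:
                assert np.trace(r.confusion) == 10

    def test_strong_markers_beat_weak_ones_on_a_synthetic_flock(
        self, components
    ):
        """C29/C31 (large alfalfa signal) misclassify fewer hens than C25."""
        animals, _ = simulate_flock(SimConfig(seed=21, noise_cv=0.10))
        results = DietClassifier(animals).fit()
        frame = results.frame().set_index("model")
        correct = lambda m: (
            frame.loc[m, "n_commercial_as_commercial"]
            + frame.loc[m, "n_mixed_as_mixed"]
        )
        assert correct("C29") >= correct("C25")
        assert correct("C31") >= correct("C25")
        assert correct("all") == 48  # full panel separates the diets

    def test_leave_one_out_confusion_shape(self):
        rng = np.random.default_rng(9)
        X, y = _two_clouds(rng, n=6, p=2, sep=6.0)
        rows = per_marker_report(X, y, ["C29", "C31"], leave_one_out=True)
        assert rows[0].confusion.sum() == 12
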