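"""CSP, mean/slope features and shrinkage LDA against closed-form and
eigendecomposition oracles."""

import numpy as np
import pytest
from scipy import linalg

from bifuse.baselines import (
    csp_features,
    csp_fit,
    csp_slda_featurizer,
    mean_slope_featurizer,
    mean_slope_features,
    slda_fit,
    slda_predict,
    sliding_window_eval,
    _window_starts,
)
from bifuse.containers import Epoch


def epochs_with_cov(cov, n_epochs, n_samples, rng):
    """Epochs whose expected spatial covariance is ``cov``."""
    chol = np.linalg.cholesky(cov)
    return [chol @ rng.standard_normal((cov.shape[0], n_samples))
            for _ in range(n_epochs)]


from tests_support import whitening_oracle


class TestCsp:
    def test_identical_covariances_are_uninformative(self, rng):
        eps = epochs_with_cov(np.eye(3), 40, 4000, rng)
        model = csp_fit(eps[:20], eps[20:], n_components=2)
        np.testing.assert_allclose(model.eigenvalue_ratios, 0.5, atol=0.05)

    def test_two_channel_toy_ratio(self, rng):
        """Class covariances diag(4,1) vs diag(1,4): after trace
        normalization the extreme eigenvalue ratio is 4/5 and filters align
        with the coordinate axes."""
        c0 = epochs_with_cov(np.diag([4.0, 1.0]), 30, 8000, rng)
        c1 = epochs_with_cov(np.diag([1.0, 4.0]), 30, 8000, rng)
        model = csp_fit(c0, c1, n_components=2)
        assert model.eigenvalue_ratios[0] == pytest.approx(0.8, abs=0.02)
        assert model.eigenvalue_ratios[-1] == pytest.approx(0.2, abs=0.02)
        top = np.abs(model.filters[0] / np.linalg.norm(model.filters[0]))
        assert top[0] > 0.99  # aligned with the first axis

    def test_paired_ratios_sum_to_one(self, rng):
        c0 = epochs_with_cov(np.diag([3.0, 1.0, 1.0, 0.5]), 30, 4000, rng)
        c1 = epochs_with_cov(np.diag([0.5, 1.0, 1.0, 3.0]), 30, 4000, rng)
        model = csp_fit(c0, c1, n_components=4)
        assert np.all(model.eigenvalue_ratios > 0)
        assert np.all(model.eigenvalue_ratios < 1)
        s = model.eigenvalue_ratios[0] + model.eigenvalue_ratios[-1]
        assert s == pytest.approx(1.0, abs=0.05)

    def test_filters_match_whitening_oracle(self, rng):
        """On random SPD pairs the fitted filters span the same directions
        as an independently-constructed whitening + rotation solution."""
        for _ in range(20):
            a = rng.standard_normal((4, 4))
            b = rng.standard_normal((4, 4))
            c0 = a @ a.T + 0.1 * np.eye(4)
            c1 = b @ b.T + 0.1 * np.eye(4)
            c0 /= np.trace(c0)
            c1 /= np.trace(c1)
            w_or, lam = whitening_oracle(c0, c1)
            evals, evecs = linalg.eigh(c0, c0 + c1)
            order = np.argsort(evals)[::-1]
            got, want = evecs[:, order].T, w_or
            np.testing.assert_allclose(np.sort(evals), np.sort(lam), atol=1e-8)
            for gf, wf in zip(got, want):
                cos = abs(gf @ wf) / (np.linalg.norm(gf) * np.linalg.norm(wf))
                assert cos == pytest.approx(1.0, abs=1e-8)

    def test_too_few_epochs_rejected(self, rng):
        eps = epochs_with_cov(np.eye(2), 2, 100, rng)
        with pytest.raises(ValueError, match="2 epochs"):
            csp_fit(eps[:1], eps[1:], 2)


class TestCspFeatures:
    def test_scaling_invariance(self, rng):
        eps = epochs_with_cov(np.diag([2.0, 1.0]), 20, 1000, rng)
        model = csp_fit(eps[:10], eps[10:], 2)
        x = rng.standard_normal((2, 500))
        np.testing.assert_allclose(
            csp_features(model, x), csp_features(model, 7.5 * x), atol=1e-10)

    def test_matches_direct_projection_oracle(self, rng):
        eps = epochs_with_cov(np.diag([2.0, 1.0, 0.5]), 20, 1000, rng)
        model = csp_fit(eps[:10], eps[10:], 2)
        x = rng.standard_normal((3, 400))
        proj = model.filters @ x
        var = proj.var(axis=1)
        np.testing.assert_allclose(
            csp_features(model, x), np.log(var / var.sum()), atol=1e-12)

    def test_zero_variance_component_rejected(self, rng):
        eps = epochs_with_cov(np.eye(2), 10, 500, rng)
        model = csp_fit(eps[:5], eps[5:], 2)
        with pytest.raises(ValueError, match="variance"):
            csp_features(model, np.zeros((2, 100)))


class TestMeanSlope:
    def test_constant_channel(self):
        out = mean_slope_features(np.full((1, 50), 3.0))
        np.testing.assert_allclose(out, [3.0, 0.0], atol=1e-12)

    def test_pure_ramp(self):
        t = np.arange(100, dtype=float)
        out = mean_slope_features((2.5 * t)[None, :])
        assert out[1] == pytest.approx(2.5)

    def test_noisy_line_matches_normal_equations(self, rng):
        t = np.arange(200, dtype=float)
        y = 1.5 * t + 4.0 + rng.standard_normal(200)
        slope_oracle = np.polyfit(t, y, 1)[0]
        out = mean_slope_features(y[None, :])
        assert out[1] == pytest.approx(slope_oracle, rel=1e-10)

    def test_epoch_slope_is_per_second(self):
        t = np.arange(0, 128) / 128.0
        e = Epoch("hbo", (3.0 * t)[None, :], 128.0, 0.0, "left", "t")
        out = mean_slope_features(e)
        assert out[1] == pytest.approx(3.0)


class TestSlda:
    def test_separated_clouds(self, rng):
        X = np.vstack([rng.standard_normal((30, 4)) - 5,
                       rng.standard_normal((30, 4)) + 5])
        y = np.repeat([0, 1], 30)
        clf = slda_fit(X, y)
        assert (slda_predict(clf, X) == y).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            slda_fit(rng.standard_normal((10, 3)), np.zeros(10))


class TestSlidingWindow:
    def test_23_windows_for_full_range(self):
        starts = _window_starts((-5.0, 20.0), 3.0, 1.0)
        assert len(starts) == 23
        assert starts[0] == -5.0 and starts[-1] == 17.0

    def _trials(self, rng, effect_window=(5.0, 8.0), n=24):
        """Mean-shift effect confined to one window of an otherwise flat
        signal (context [-5, 20] s at 10 Hz)."""
        trials = []
        for i in range(n):
            lab = "left" if i % 2 else "right"
            x = 0.3 * rng.standard_normal((2, 250))
            if lab == "left":
                i0 = int((effect_window[0] + 5.0) * 10)
                i1 = int((effect_window[1] + 5.0) * 10)
                x[:, i0:i1] += 3.0
            e = Epoch("hbo", x, 10.0, -5.0, lab, f"t{i}")
            trials.append((e, lab))
        return trials

    def test_max_over_windows_finds_the_effect(self, rng):
        trials = self._trials(rng)
        starts, accs, best = sliding_window_eval(
            trials, mean_slope_featurizer(), n_repeats=2, seed=0)
        assert best > 0.9
        best_start = starts[int(np.argmax(accs))]
        assert 2.0 <= best_start <= 8.0  # windows overlapping the effect

    def test_folds_are_seeded(self, rng):
        trials = self._trials(rng, n=12)
        _, a, _ = sliding_window_eval(trials, mean_slope_featurizer(),
                                      n_repeats=1, seed=3)
        _, b, _ = sliding_window_eval(trials, mean_slope_featurizer(),
                                      n_repeats=1, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_insufficient_context_rejected(self, rng):
        e = Epoch("hbo", rng.standard_normal((2, 100)), 10.0, 0.0, "left", "t")
        with pytest.raises(ValueError, match="cover"):
            sliding_window_eval([(e, "left")], mean_slope_featurizer())


class TestOnSyntheticData:
    def test_csp_slda_monotone_in_erd_depth(self):
        """CSP + sLDA cross-validated accuracy is non-decreasing in the ERD
        depth (averaged over 5 seeds), and beats chance at depth 0.8."""
        from sklearn.model_selection import StratifiedKFold

        from bifuse.pipeline import preprocess_pair
        from bifuse.synthetic import SyntheticSpec, generate_dataset

        def accuracy(erd, seed):
            spec = SyntheticSpec(n_trials_per_class=8, erd_depth=erd,
                                 hemo_amplitude=0.0, seed=seed)
            pairs = preprocess_pair(*generate_dataset(spec))
            X = [e.data for e, _ in pairs]
            y = np.array([0 if e.label == "left" else 1 for e, _ in pairs])
            accs = []
            for tr, te in StratifiedKFold(4, shuffle=True, random_state=0).split(X, y):
                model = csp_fit([X[i] for i in tr if y[i] == 0],
                                [X[i] for i in tr if y[i] == 1], 4)
                Xtr = np.stack([csp_features(model, X[i]) for i in tr])
                Xte = np.stack([csp_features(model, X[i]) for i in te])
                clf = slda_fit(Xtr, y[tr])
                accs.append((slda_predict(clf, Xte) == y[te]).mean())
            return float(np.mean(accs))

        means = {erd: np.mean([accuracy(erd, s) for s in range(5)])
                 for erd in (0.0, 0.4, 0.8)}
        assert means[0.4] >= means[0.0] - 0.02
        assert means[0.8] >= means[0.4] - 0.02
        assert means[0.8] > 0.8
        assert 0.3 <= means[0.0] <= 0.7
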