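"""VBGMM fitting, label assignment, CNV-component selection, and baselines."""

import warnings

import numpy as np
import pytest
from sklearn.mixture import BayesianGaussianMixture

from knncnv.labeling import (
    assign_labels,
    baseline_labelers,
    boxplot_flags,
    fit_vbgmm,
    select_cnv_component,
)
from knncnv.simulate import simulate_scores


def _two_cluster(seed=0, mu=(0.0, 10.0), sigma=0.5, n=(100, 100)):
    rng = np.random.default_rng(seed)
    s = np.concatenate([rng.normal(mu[0], sigma, n[0]), rng.normal(mu[1], sigma, n[1])])
    labels = np.concatenate([np.zeros(n[0], bool), np.ones(n[1], bool)])
    return s, labels


class TestFitVBGMM:
    def test_recovers_separated_components(self):
        s, truth = _two_cluster(seed=1)
        fit = fit_vbgmm(s, seed=1)
        means = np.sort(fit.means)
        assert abs(means[0] - 0.0) < 0.5
        assert abs(means[1] - 10.0) < 0.5
        lab = assign_labels(fit, s)
        assert (lab.is_cnv == truth).mean() >= 0.99

    def test_normalization_identities(self):
        s, _ = _two_cluster(seed=2)
        fit = fit_vbgmm(s, seed=2)
        assert fit.alphas.sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)
        assert (fit.variances > 0).all()

    def test_elbo_nondecreasing(self):
        s, _ = _two_cluster(seed=3)
        fit = fit_vbgmm(s, seed=3)
        d = np.diff(fit.elbo_trace)
        assert (d >= -1e-8).all()

    def test_constant_scores_no_crash(self):
        fit = fit_vbgmm(np.full(50, 2.5), seed=4)
        assert fit.alphas.max() > 0.9
        lab = np.argmax(fit.responsibilities, axis=1)
        assert len(set(lab)) == 1

    def test_deterministic_for_seed(self):
        s, _ = _two_cluster(seed=5)
        f1 = fit_vbgmm(s, seed=9)
        f2 = fit_vbgmm(s, seed=9)
        np.testing.assert_array_equal(f1.responsibilities, f2.responsibilities)
        assert f1.elbo_trace == f2.elbo_trace

    def test_label_affine_invariance(self):
        s, _ = _two_cluster(seed=6)
        base = assign_labels(fit_vbgmm(s, seed=0), s)
        trans = assign_labels(fit_vbgmm(3.5 * s + 11.0, seed=0), 3.5 * s + 11.0)
        np.testing.assert_array_equal(base.is_cnv, trans.is_cnv)

    def test_agrees_with_ml_gmm_when_separated(self):
        s, _ = _two_cluster(seed=7)
        vb = assign_labels(fit_vbgmm(s, seed=0), s)
        ml = baseline_labelers(s, "gmm", seed=0)
        assert (vb.is_cnv == ml.is_cnv).mean() >= 0.99

    def test_agrees_with_sklearn_variational_fit(self):
        # independent variational implementation as cross-check
        s, _ = _two_cluster(seed=8)
        vb = assign_labels(fit_vbgmm(s, seed=0), s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bg = BayesianGaussianMixture(n_components=2, n_init=3, random_state=0).fit(
                s[:, None]
            )
        ref = bg.predict(s[:, None]) == int(np.argmax(bg.means_.ravel()))
        assert (vb.is_cnv == ref).mean() >= 0.99

    def test_too_few_scores_fatal(self):
        with pytest.raises(ValueError):
            fit_vbgmm(np.array([1.0]))

    def test_nonfinite_fatal(self):
        with pytest.raises(ValueError):
            fit_vbgmm(np.array([1.0, np.inf, 2.0]))


class TestAssignAndSelect:
    def test_argmax_and_tie_rule(self):
        s, _ = _two_cluster(seed=10)
        fit = fit_vbgmm(s, seed=0)
        fit.responsibilities = np.array([[0.9, 0.1], [0.5, 0.5], [0.1, 0.9]])
        lab = np.argmax(fit.responsibilities, axis=1)
        assert lab.tolist() == [0, 0, 1]  # tie breaks to lower index

    def test_monotone_separation_in_1d(self):
        s, _ = _two_cluster(seed=11)
        fit = fit_vbgmm(s, seed=0)
        lab = assign_labels(fit, s)
        order = np.argsort(s)
        flags = lab.is_cnv[order].astype(int)
        assert (np.diff(flags) >= 0).all()  # single threshold in s

    def test_select_larger_mean_component(self):
        s, truth = _two_cluster(seed=12)
        fit = fit_vbgmm(s, seed=0)
        comp = select_cnv_component(fit, s)
        members = np.argmax(fit.responsibilities, axis=1) == comp
        assert s[members].mean() > s[~members].mean()

    def test_planted_outliers_recovered(self):
        s, truth = simulate_scores(950, 50, shift=8.0, sigma=1.0, seed=13)
        fit = fit_vbgmm(s, seed=0)
        lab = assign_labels(fit, s)
        assert lab.is_cnv[truth].mean() >= 0.95


class TestBaselines:
    def test_top_n_flags_largest(self):
        s = np.arange(1, 21, dtype=float)
        lab = baseline_labelers(s, "top_n", n=int(np.floor(0.25 * 20)))
        assert set(s[lab.is_cnv]) == {16, 17, 18, 19, 20}

    def test_top_n_frac(self):
        s = np.arange(100, dtype=float)
        lab = baseline_labelers(s, "top_n", frac=0.05)
        assert lab.is_cnv.sum() == 5

    def test_boxplot_extreme_point(self):
        s = np.array([0, 0, 0, 0, 100.0])
        lab = baseline_labelers(s, "boxplot")
        assert lab.is_cnv.tolist() == [False, False, False, False, True]

    def test_boxplot_matches_quantile_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            s = rng.gamma(2, 1, int(rng.integers(10, 200)))
            flags = boxplot_flags(s, 0.75)
            q1, q3 = np.percentile(s, [25, 75])
            np.testing.assert_array_equal(flags, s > q3 + 0.75 * (q3 - q1))

    def test_invalid_strategy_fatal(self):
        with pytest.raises(ValueError):
            baseline_labelers(np.ones(5), "magic")
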