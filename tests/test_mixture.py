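"""Finite-mixture decomposition: EM recovery, class assignment, QC."""

import numpy as np
import pytest

from iseseg import (
    FluorescenceSample,
    GsClassEstimate,
    MixtureComponent,
    MixtureFit,
    SegParams,
    assign_components_to_classes,
    class_positions,
    fit_finite_mixture,
    qc_cv,
    renormalize_classes,
    simulate_clone_sample,
)
from iseseg.mixture import _em_fit

from conftest import make_sim_config


def _make_fit(components, family="skew_normal"):
    comps = tuple(MixtureComponent(*c) for c in components)
    return MixtureFit(
        components=comps, g=len(comps), bic=0.0, loglik=0.0,
        converged=True, family=family, n_iter=1, n_events=1000,
    )


class TestFitFiniteMixture:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(0)
        s = FluorescenceSample(events=rng.normal(1000, 30, 10_000))
        fit = fit_finite_mixture(s, g_min=1, g_max=3, family="normal")
        assert fit.g == 1
        assert fit.components[0].location == pytest.approx(1000, rel=0.01)

    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(1)
        ev = np.concatenate(
            [rng.normal(800, 24, 5000), rng.normal(1200, 36, 5000)]
        )
        s = FluorescenceSample(events=ev)
        fit = fit_finite_mixture(s, g_min=1, g_max=4, seed=1)
        means = np.array([c.mean() for c in fit.components])
        weights = fit.weights()
        low = np.abs(means - 800) / 800 <= 0.02
        high = np.abs(means - 1200) / 1200 <= 0.02
        assert low.any() and high.any()
        assert abs(weights[low].sum() - 0.5) <= 0.05
        assert abs(weights[high].sum() - 0.5) <= 0.05

    def test_deterministic_for_identical_input(self):
        rng = np.random.default_rng(2)
        ev = np.concatenate([rng.normal(700, 20, 2000), rng.normal(1000, 25, 2000)])
        a = fit_finite_mixture(FluorescenceSample(events=ev), g_min=2, g_max=3, seed=5)
        b = fit_finite_mixture(FluorescenceSample(events=ev), g_min=2, g_max=3, seed=5)
        assert a.bic == b.bic
        assert all(
            (x.weight, x.location, x.scale, x.skewness)
            == (y.weight, y.location, y.scale, y.skewness)
            for x, y in zip(a.components, b.components)
        )

    def test_loglik_never_drops_with_an_extra_component(self):
        # true at the global optimum; EM finds local optima, so allow a
        # small relative slack
        rng = np.random.default_rng(3)
        ev = np.concatenate([rng.normal(800, 20, 3000), rng.normal(1100, 25, 3000)])
        lls = [
            _em_fit(ev, g, "skew_normal", 1e-6, 500,
                    np.random.default_rng(0)).loglik
            for g in (2, 3, 4)
        ]
        assert lls[1] >= lls[0] - 1e-4 * abs(lls[0])
        assert lls[2] >= lls[1] - 1e-4 * abs(lls[1])

    def test_normal_family_agrees_with_sklearn(self):
        # independent oracle: sklearn's Gaussian mixture EM on the same data
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(4)
        ev = np.concatenate([rng.normal(600, 15, 4000), rng.normal(900, 20, 6000)])
        fit = fit_finite_mixture(
            FluorescenceSample(events=ev), g_min=2, g_max=2, family="normal"
        )
        gm = sklearn.GaussianMixture(2, n_init=3, random_state=0).fit(ev[:, None])
        ref_means = np.sort(gm.means_.ravel())
        ref_w = gm.weights_[np.argsort(gm.means_.ravel())]
        np.testing.assert_allclose(fit.locations(), ref_means, rtol=0.01)
        np.testing.assert_allclose(fit.weights(), ref_w, atol=0.01)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least 200"):
            fit_finite_mixture(FluorescenceSample(events=np.ones(50) * 500))

    def test_skew_t_family_not_available(self):
        with pytest.raises(NotImplementedError, match="skew-t"):
            fit_finite_mixture(
                FluorescenceSample(events=np.full(300, 1.0)), family="skew_t"
            )


class TestAssignComponents:
    def test_components_on_one_class_merge(self):
        fit = _make_fit([(0.4, 995.0, 10.0, 0.0), (0.6, 1005.0, 10.0, 0.0)])
        est = assign_components_to_classes(fit, [1000.0])
        assert len(est) == 1
        e = est[0]
        assert e.class_k == 0
        assert e.proportion == pytest.approx(1.0)
        assert e.mean_fluorescence == pytest.approx(0.4 * 995 + 0.6 * 1005)
        assert e.member_component_ids == (0, 1)

    def test_out_of_window_component_is_background(self):
        fit = _make_fit([(0.2, 400.0, 10.0, 0.0), (0.8, 900.0, 10.0, 0.0)])
        est = assign_components_to_classes(fit, [900.0, 1100.0], window=0.05)
        kinds = {e.class_k: e for e in est}
        assert kinds[None].mean_fluorescence == pytest.approx(400.0)
        assert kinds[0].proportion == pytest.approx(0.8)

    def test_unresolvable_classes_raise(self):
        fit = _make_fit([(1.0, 1000.0, 10.0, 0.0)])
        with pytest.raises(ValueError, match="cannot be resolved"):
            assign_components_to_classes(fit, [980.0, 1020.0], window=0.05)

    def test_broad_low_weight_component_is_background(self):
        fit = _make_fit(
            [(0.985, 1000.0, 10.0, 0.0), (0.015, 1010.0, 80.0, 0.0)]
        )
        est = assign_components_to_classes(fit, [1000.0])
        by_kind = {e.class_k: e for e in est}
        assert by_kind[0].proportion == pytest.approx(0.985)
        assert by_kind[None].proportion == pytest.approx(0.015)


class TestRenormalize:
    def test_background_removed_and_rescaled(self):
        est = [
            GsClassEstimate(0, 0.2, 500.0, (0,)),
            GsClassEstimate(1, 0.4, 600.0, (1,)),
            GsClassEstimate(2, 0.2, 700.0, (2,)),
            GsClassEstimate(None, 0.2, 300.0, (3,)),
        ]
        out = renormalize_classes(est)
        assert [e.proportion for e in out] == pytest.approx([0.25, 0.5, 0.25])

    def test_identity_without_background(self):
        est = [GsClassEstimate(0, 0.5, 1.0, (0,)), GsClassEstimate(1, 0.5, 2.0, (1,))]
        out = renormalize_classes(est)
        assert [e.proportion for e in out] == pytest.approx([0.5, 0.5])

    def test_single_class_plus_background(self):
        est = [GsClassEstimate(0, 0.7, 1.0, (0,)), GsClassEstimate(None, 0.3, 2.0, (1,))]
        assert renormalize_classes(est)[0].proportion == pytest.approx(1.0)

    def test_all_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            renormalize_classes([GsClassEstimate(None, 1.0, 1.0, (0,))])


class TestQcCv:
    def test_clean_peaks_report_their_cv(self):
        rng = np.random.default_rng(8)
        tight = FluorescenceSample(events=rng.normal(1000, 20, 5000))
        broad = FluorescenceSample(events=rng.normal(1000, 40, 5000))
        assert qc_cv(tight, 1000.0) == pytest.approx(2.0, abs=0.3)
        assert qc_cv(broad, 1000.0) == pytest.approx(4.0, abs=0.4)
        assert qc_cv(tight, 1000.0) < 3.5 < qc_cv(broad, 1000.0)

    def test_constant_events_give_zero(self):
        s = FluorescenceSample(events=np.full(500, 1000.0))
        assert qc_cv(s, 1000.0) == 0.0

    def test_sparse_peak_rejected(self):
        s = FluorescenceSample(events=np.full(500, 300.0))
        with pytest.raises(ValueError, match="events within"):
            qc_cv(s, 1000.0)


class TestEndToEndDecomposition:
    def test_three_class_sample_recovered(self, two_ise_sample):
        estimates, truth = two_ise_sample
        freqs = np.zeros(3)
        for e in estimates:
            freqs[e.class_k] = e.proportion
        np.testing.assert_allclose(freqs, truth.freqs, atol=0.03)

    @pytest.fixture
    def two_ise_sample(self):
        from iseseg import IseKaryotype
        from iseseg.pipeline import decompose_sample

        kar = IseKaryotype(n_ise=2, female_2c_mb=450.0, core_1c_mb=200.0)
        config = make_sim_config(
            kar, SegParams(0.0, 0.0), seed=31, n_males=4000,
            n_events_per_male=3, female_events=2000, cv_percent=2.0,
        )
        sample, truth, _ = simulate_clone_sample(config)
        estimates, _, _ = decompose_sample(sample, kar, g_min=3, g_max=6, seed=1)
        return estimates, truth

    def test_recovery_across_observed_cv_range(self):
        # CVs spanning the empirically observed 1.7-3.95% female-peak
        # range; class proportions must come back within 0.05 (median
        # over seeds per CV).  The karyotype keeps adjacent classes
        # >= 4 CVs apart even for the broadest peaks, the regime in
        # which classes are resolvable at all.
        from iseseg import IseKaryotype
        from iseseg.pipeline import decompose_sample

        kar = IseKaryotype(n_ise=4, female_2c_mb=440.0, core_1c_mb=100.0)
        for cv in (1.7, 2.8, 3.9):
            max_errs = []
            for seed in range(3):
                config = make_sim_config(
                    kar, SegParams(0.1, -0.2), seed=40 + seed,
                    n_males=4000, n_events_per_male=3, female_events=2000,
                    cv_percent=cv,
                )
                sample, truth, _ = simulate_clone_sample(config)
                estimates, _, _ = decompose_sample(
                    sample, kar, g_min=3, g_max=7, seed=seed
                )
                freqs = np.zeros(5)
                for e in estimates:
                    freqs[e.class_k] = e.proportion
                freqs /= freqs.sum()
                max_errs.append(np.abs(freqs - truth.freqs).max())
            assert np.median(max_errs) <= 0.05
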