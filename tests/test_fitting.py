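"""Reconvolution fitting: self-consistency, recovery, diagnostics, selection."""

import numpy as np
import pytest
import scipy.stats

from flimfret import (
    AcquisitionConfig,
    DecayModel,
    ExponentialComponent,
    TCSPCHistogram,
    draw_cell,
    expected_counts,
    fit_biexp,
    fit_monoexp,
    residual_diagnostics,
    select_model,
    simulate_experiment,
    simulate_histogram,
)
from flimfret.errors import LowCountWarning, UnfittableHistogramError
from flimfret.fitting import runs_test
from conftest import make_design


def poisson_deviance(obs, exp):
    exp = np.clip(exp, 1e-300, None)
    term = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return 2.0 * np.sum(exp - obs + term)


def noiseless_hist(model, config, total):
    counts = np.round(expected_counts(model, config, total)).astype(int)
    return TCSPCHistogram(counts=counts, config=config, roi_id="noiseless")


def donor_only_hists(n, photons, seed, tau_sd=0.14, config=None):
    design = make_design(
        "donor_only", binding_mean=0.0, acceptor_intensity_logmean=None,
        tau_ud_sd=tau_sd, photons_per_cell=photons, n_cells=n,
    )
    return simulate_experiment([design], seed, config or AcquisitionConfig())


class TestFitMonoexp:
    def test_noiseless_self_consistency(self, config):
        model = DecayModel(
            (ExponentialComponent(1.0, 2.75),), background_fraction=0.01
        )
        hist = noiseless_hist(model, config, 1e6)
        fit = fit_monoexp(hist)
        assert fit.converged
        assert fit.tau_ud == pytest.approx(2.75, rel=0.005)

    def test_population_mean_lifetime(self, config):
        """Simulated donor-only cells recover the 2.75 ns population mean."""
        truths, hists = donor_only_hists(15, 100_000, seed=101)
        taus = [fit_monoexp(h).tau_ud for h in hists]
        se = np.std(taus, ddof=1) / np.sqrt(len(taus))
        assert np.mean(taus) == pytest.approx(2.75, abs=3 * se)

    def test_pure_background_flagged(self, config):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=config.n_channels)
        hist = TCSPCHistogram(counts=counts, config=config, roi_id="flat")
        fit = fit_monoexp(hist)
        assert (not fit.converged) or fit.at_bound or fit.runs_test_p < 0.05

    def test_all_zero_counts_unfittable(self, config):
        hist = TCSPCHistogram(
            counts=np.zeros(config.n_channels, dtype=int),
            config=config, roi_id="empty",
        )
        with pytest.raises(UnfittableHistogramError):
            fit_monoexp(hist)

    def test_low_count_warning(self, config):
        truths, hists = donor_only_hists(1, 500, seed=3)
        with pytest.warns(LowCountWarning):
            fit_monoexp(hists[0])

    def test_unbiased_at_scale(self):
        """200 cells at 1e5 photons, fixed true tau: mean within 0.01 ns."""
        truths, hists = donor_only_hists(200, 100_000, seed=11, tau_sd=0.0)
        taus = np.array([fit_monoexp(h).tau_ud for h in hists])
        assert 2.74 < taus.mean() < 2.76

    def test_fit_noise_shrinks_with_photons(self):
        """Fit-noise SD of tau strictly decreases from 1e4 to 1e6 photons."""
        sds = []
        for photons in (10_000, 100_000, 1_000_000):
            truths, hists = donor_only_hists(25, photons, seed=29, tau_sd=0.0)
            taus = [fit_monoexp(h).tau_ud for h in hists]
            sds.append(np.std(taus, ddof=1))
        assert sds[0] > sds[1] > sds[2]


@pytest.fixture(scope="module")
def mixture_fits():
    design = make_design(
        "wt", binding_mean=0.5, binding_sd=0.0, n_cells=25,
        tau_qd_mean=1.10, tau_qd_sd=0.20,
    )
    truths, hists = simulate_experiment([design], 201, AcquisitionConfig())
    return truths, [fit_biexp(h) for h in hists]


class TestFitBiexp:
    def test_recovers_quenched_lifetime(self, mixture_fits):
        _, fits = mixture_fits
        tqs = [f.tau_qd for f in fits]
        se = np.std(tqs, ddof=1) / np.sqrt(len(tqs))
        assert np.mean(tqs) == pytest.approx(1.10, abs=3 * se)

    def test_recovers_binding_fraction(self, mixture_fits):
        _, fits = mixture_fits
        fracs = np.array([f.a_qd / (f.a_uq + f.a_qd) for f in fits])
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert fracs.mean() == pytest.approx(0.5, abs=3 * se)

    def test_amplitudes_are_fractions(self, mixture_fits):
        _, fits = mixture_fits
        for f in fits:
            assert f.a_uq + f.a_qd == pytest.approx(1.0, abs=1e-9)
            assert f.tau_ud > f.tau_qd

    def test_pure_mono_input_degenerate_or_tiny_second(self, config):
        """With no second species present the bi-exponential split is not
        identifiable: either the fit collapses (degenerate flag), or the
        spurious species carries <5% amplitude, or model selection rejects
        the richer model; the amplitude-weighted lifetime always recovers
        the true mono-exponential lifetime."""
        truths, hists = donor_only_hists(3, 100_000, seed=55)
        for h, t in zip(hists, truths):
            fit = fit_biexp(h)
            spurious_small = min(fit.a_qd, fit.a_uq) < 0.05
            assert fit.degenerate or spurious_small or select_model(h) == 1
            weighted = fit.a_uq * fit.tau_ud + fit.a_qd * fit.tau_qd
            assert weighted == pytest.approx(t.true_tau_ud, rel=0.02)

    def test_fix_tau_ud_clamps(self, config):
        design = make_design("wt", binding_mean=0.5, n_cells=1)
        truths, hists = simulate_experiment([design], 77, config)
        fit = fit_biexp(hists[0], fix_tau_ud=2.75)
        assert fit.tau_ud == pytest.approx(2.75, abs=1e-12)


class TestGridSearchOracle:
    """The bounded optimizer lands within one grid cell of the exhaustive
    deviance-minimizing point on small instances."""

    def test_mono_lifetime(self, small_config):
        design = make_design(
            "d", binding_mean=0.0, acceptor_intensity_logmean=None,
            tau_ud_sd=0.0, photons_per_cell=10_000, n_cells=3,
        )
        truths, hists = simulate_experiment([design], 404, small_config)
        taus = np.arange(1.0, 5.0001, 0.05)
        for h in hists:
            fit = fit_monoexp(h, fix_background=0.01)
            dev = [
                poisson_deviance(
                    h.counts,
                    expected_counts(
                        DecayModel((ExponentialComponent(1.0, t),), 0.01),
                        small_config, h.total_counts,
                    ),
                )
                for t in taus
            ]
            assert abs(fit.tau_ud - taus[int(np.argmin(dev))]) <= 0.05 + 1e-9

    def test_biexp_lifetime_and_binding(self, small_config):
        design = make_design(
            "wt", binding_mean=0.5, binding_sd=0.0, tau_ud_sd=0.0,
            tau_qd_sd=0.0, photons_per_cell=10_000, n_cells=3,
        )
        truths, hists = simulate_experiment([design], 405, small_config)
        tau_grid = np.arange(0.5, 2.0001, 0.05)
        b_grid = np.arange(0.0, 1.0001, 0.02)
        for h in hists:
            fit = fit_biexp(h, fix_tau_ud=2.75, fix_background=0.01)
            best = None
            for tq in tau_grid:
                for b in b_grid:
                    if b == 0:
                        model = DecayModel((ExponentialComponent(1.0, 2.75),), 0.01)
                    else:
                        model = DecayModel(
                            (ExponentialComponent(1 - b, 2.75),
                             ExponentialComponent(b, tq)), 0.01,
                        )
                    d = poisson_deviance(
                        h.counts,
                        expected_counts(model, small_config, h.total_counts),
                    )
                    if best is None or d < best[0]:
                        best = (d, tq, b)
            _, tq_star, b_star = best
            assert abs(fit.tau_qd - tq_star) <= 0.05 + 1e-9
            assert abs(fit.a_qd - b_star) <= 0.02 + 1e-9


class TestDiagnostics:
    def test_reduced_chisq_near_one_for_correct_model(self):
        truths, hists = donor_only_hists(10, 100_000, seed=61)
        reds = [fit_monoexp(h).reduced_chisq for h in hists]
        assert np.mean(reds) == pytest.approx(1.0, abs=0.15)

    def test_single_run_residuals_give_tiny_p(self):
        assert runs_test(np.ones(50, dtype=bool)) < 1e-10

    def test_diagnostics_match_stored_fields(self):
        truths, hists = donor_only_hists(1, 50_000, seed=5)
        fit = fit_monoexp(hists[0])
        red, p = residual_diagnostics(fit)
        assert red == pytest.approx(fit.reduced_chisq)
        assert p == pytest.approx(fit.runs_test_p)

    def test_runs_p_uniform_under_correct_model(self):
        """Null calibration: runs-test p over repeated correct-model fits is
        approximately uniform (KS at alpha=0.01)."""
        truths, hists = donor_only_hists(120, 20_000, seed=71)
        ps = np.array([fit_monoexp(h).runs_test_p for h in hists])
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestSelectModel:
    def test_donor_only_selects_mono(self):
        truths, hists = donor_only_hists(5, 100_000, seed=81)
        assert all(select_model(h) == 1 for h in hists)

    def test_mixture_selects_biexp(self):
        design = make_design("wt", binding_mean=0.5, n_cells=5)
        truths, hists = simulate_experiment([design], 82, AcquisitionConfig())
        assert all(select_model(h) == 2 for h in hists)

    def test_low_count_defaults_to_mono(self, config):
        truths, hists = donor_only_hists(1, 500, seed=83)
        with pytest.warns(LowCountWarning):
            assert select_model(hists[0]) == 1
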