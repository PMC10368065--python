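"""Two-layer moments-based absorption-change fitting."""

import numpy as np
import pytest

from tdnirs import (
    BaselineState,
    DTOF,
    SensitivityFactors,
    TwoLayerScenario,
    baseline_error_study,
    chi2,
    compute_moments,
    fit_two_layer,
    linear_initial_guess,
    moment_changes,
    photon_noise,
    select_range,
    sensitivity_factors,
    simulate_dtof_pair,
)
from tdnirs.exceptions import DegenerateGeometryError, InvalidParameterError
from tdnirs.phantom_sim import add_poisson_noise
from tdnirs.two_layer_fit import MOMENT_ORDER, MomentsForward


@pytest.fixture(scope="module")
def fig2_baseline():
    """Landscape-study configuration: both layers 0.1 cm^-1 / 10 cm^-1,
    L = 12 mm."""
    return BaselineState(
        mua_sup=0.01, mua_deep=0.01, musp_sup=1.0, musp_deep=1.0,
        L=12.0, n=1.33, rho=30.0,
    )


@pytest.fixture(scope="module")
def fig2_sf(fig2_baseline, grid, irf):
    rng = _baseline_range(fig2_baseline, grid, irf)
    return sensitivity_factors(fig2_baseline, irf, grid, rng)


def _baseline_range(baseline, grid, irf):
    scen = TwoLayerScenario(baseline=baseline, dmua_sup=0.0, dmua_deep=0.0,
                            irf=irf, grid=grid)
    d, _ = simulate_dtof_pair(scen)
    return select_range(d, 0.25, 0.03)


class TestSensitivityFactors:
    def test_all_entries_positive(self, fig2_sf):
        """Absorption increase in either layer raises dA, dm1 and dV."""
        assert np.all(fig2_sf.matrix > 0)

    def test_depth_selectivity_ordering(self, fig2_sf):
        """Deep/superficial sensitivity ratio grows with moment order:
        smallest for dA, largest for dV."""
        ratios = fig2_sf.matrix[:, 1] / fig2_sf.matrix[:, 0]
        r = dict(zip(MOMENT_ORDER, ratios))
        assert r["dA"] < r["dm1"] < r["dV"]

    def test_local_linearity_of_perturbation(self, fig2_baseline, grid, irf):
        """Halving the probe perturbation moves each factor by < 1%."""
        rng = _baseline_range(fig2_baseline, grid, irf)
        sf2 = sensitivity_factors(fig2_baseline, irf, grid, rng, rel_perturbation=0.02)
        sf1 = sensitivity_factors(fig2_baseline, irf, grid, rng, rel_perturbation=0.01)
        np.testing.assert_allclose(sf1.matrix, sf2.matrix, rtol=0.01)


class TestLinearInitialGuess:
    def test_zero_changes_give_zero(self, fig2_sf):
        from tdnirs.moments import MomentChanges

        guess = linear_initial_guess(fig2_sf, MomentChanges(0.0, 0.0, 0.0))
        assert guess == (0.0, 0.0)

    def test_small_step_forward_consistency(self, fig2_baseline, grid, irf, fig2_sf):
        """For a small true step the linearized solution is within 5%."""
        truth = (0.0002, 0.0002)  # +0.002 cm^-1 in both layers
        scen = TwoLayerScenario(fig2_baseline, *truth, irf=irf, grid=grid)
        d0, d1 = simulate_dtof_pair(scen)
        rng = select_range(d0, 0.25, 0.03)
        measured = moment_changes(compute_moments(d0, rng), compute_moments(d1, rng))
        guess = linear_initial_guess(fig2_sf, measured)
        assert guess[0] == pytest.approx(truth[0], rel=0.05)
        assert guess[1] == pytest.approx(truth[1], rel=0.05)

    def test_matches_2x2_closed_form_inverse(self, fig2_sf):
        """The {dm1, dV} solution equals the hand-coded matrix inverse."""
        from tdnirs.moments import MomentChanges

        measured = MomentChanges(dA=0.0, dm1=5.0, dV=4000.0)
        guess = linear_initial_guess(fig2_sf, measured, ("dm1", "dV"))
        a = fig2_sf.rows(("dm1", "dV"))
        det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
        x = (a[1, 1] * 5.0 - a[0, 1] * 4000.0) / det
        y = (-a[1, 0] * 5.0 + a[0, 0] * 4000.0) / det
        assert guess[0] == pytest.approx(x, rel=1e-9)
        assert guess[1] == pytest.approx(y, rel=1e-9)

    def test_degenerate_matrix_raises(self, fig2_baseline):
        from tdnirs.moments import MomentChanges

        sf = SensitivityFactors(
            matrix=np.array([[1.0, 1.0], [1.0, 1.0 + 1e-12], [2.0, 2.0]]),
            baseline=fig2_baseline,
        )
        with pytest.raises(DegenerateGeometryError):
            linear_initial_guess(sf, MomentChanges(0.1, 1.0, 100.0), ("dm1", "dV"))


class TestChi2:
    def test_zero_at_truth_and_nonnegative(self, fig2_baseline, grid, irf):
        truth = (0.001, 0.003)
        scen = TwoLayerScenario(fig2_baseline, *truth, irf=irf, grid=grid)
        d0, d1 = simulate_dtof_pair(scen)
        rng = select_range(d0, 0.25, 0.03)
        base_m = compute_moments(d0, rng)
        measured = moment_changes(base_m, compute_moments(d1, rng))
        fw = MomentsForward(fig2_baseline, irf, grid, rng)
        at_truth = chi2(truth, measured, fig2_baseline, base_m, irf, rng, forward=fw)
        assert at_truth == pytest.approx(0.0, abs=1e-12)
        for cand in [(0.0, 0.0), (0.002, 0.001), (-0.001, 0.004)]:
            assert chi2(cand, measured, fig2_baseline, base_m, irf, rng, forward=fw) >= 0


class TestFitTwoLayer:
    def test_identical_dtofs_give_zero(self, fig3_scenario, fig3_dtof_pair):
        d0, _ = fig3_dtof_pair
        fit = fit_two_layer(d0, d0, fig3_scenario.baseline, fig3_scenario.irf)
        assert abs(fit.dmua_sup) < 1e-6
        assert abs(fit.dmua_deep) < 1e-6

    def test_deep_step_recovery(self, fig3_scenario, fig3_dtof_pair):
        """Correct assumed baseline: the deep step is recovered to < 2%
        of the step and the superficial change stays at zero."""
        d0, d1 = fig3_dtof_pair
        fit = fit_two_layer(d0, d1, fig3_scenario.baseline, fig3_scenario.irf)
        assert fit.converged
        assert fit.dmua_deep == pytest.approx(0.005, rel=0.02)
        assert abs(fit.dmua_sup) < 1e-4  # 0.001 cm^-1
        assert fit.mua_deep_abs == pytest.approx(0.015, rel=0.02)

    def test_random_truth_pairs_round_trip(self, fig2_baseline, grid, irf):
        """20 random noiseless truth pairs in [-0.05, +0.10] cm^-1 are
        each recovered to < 2% (or 0.001 cm^-1 for near-zero parts)."""
        rng_np = np.random.default_rng(123)
        truths = rng_np.uniform(-0.005, 0.010, size=(20, 2))
        for dsup, ddeep in truths:
            scen = TwoLayerScenario(fig2_baseline, dsup, ddeep, irf=irf, grid=grid)
            d0, d1 = simulate_dtof_pair(scen)
            fit = fit_two_layer(d0, d1, fig2_baseline, irf)
            for got, want in [(fit.dmua_sup, dsup), (fit.dmua_deep, ddeep)]:
                assert got == pytest.approx(want, rel=0.02, abs=1e-4)

    def test_init_independence(self, fig3_scenario, fig3_dtof_pair):
        """10 random initial guesses in [-0.1, 0.1] cm^-1 converge to the
        same solution within 1e-4 cm^-1."""
        d0, d1 = fig3_dtof_pair
        rng_np = np.random.default_rng(5)
        sols = []
        for _ in range(10):
            init = tuple(rng_np.uniform(-0.01, 0.01, 2))
            fit = fit_two_layer(
                d0, d1, fig3_scenario.baseline, fig3_scenario.irf, init=init
            )
            sols.append((fit.dmua_sup, fit.dmua_deep))
        sols = np.array(sols)
        assert np.ptp(sols, axis=0).max() < 1e-5  # 1e-4 cm^-1

    def test_nonlinearity_materiality(self, fig2_baseline, grid, irf):
        """For a large step (+0.10 cm^-1 deep) the linearized solution
        errs by > 5% while the iterative fit stays within 2%."""
        truth = (0.0, 0.010)
        scen = TwoLayerScenario(fig2_baseline, *truth, irf=irf, grid=grid)
        d0, d1 = simulate_dtof_pair(scen)
        rng = select_range(d0, 0.25, 0.03)
        base_m = compute_moments(d0, rng)
        measured = moment_changes(base_m, compute_moments(d1, rng))
        sf = sensitivity_factors(fig2_baseline, irf, grid, rng)
        lin = linear_initial_guess(sf, measured, ("dm1", "dV"), photon_noise(base_m))
        assert abs(lin[1] - truth[1]) / truth[1] > 0.05
        fit = fit_two_layer(d0, d1, fig2_baseline, irf)
        assert abs(fit.dmua_deep - truth[1]) / truth[1] < 0.02

    def test_poisson_robustness_bias(self, fig3_scenario, fig3_dtof_pair):
        """With Poisson noise at Ntot = 1e6 per DTOF (50 replicates) the
        recovered deep step has bias < 5% of the step."""
        d0, d1 = fig3_dtof_pair
        rng_np = np.random.default_rng(99)
        deeps = []
        for _ in range(50):
            n0 = add_poisson_noise(d0, 1e6, rng_np)
            n1 = add_poisson_noise(d1, 1e6, rng_np)
            fit = fit_two_layer(n0, n1, fig3_scenario.baseline, fig3_scenario.irf)
            deeps.append(fit.dmua_deep)
        bias = np.mean(deeps) - 0.005
        assert abs(bias) / 0.005 < 0.05

    def test_incompatible_grids_raise(self, fig3_scenario, fig3_dtof_pair):
        from tdnirs import TimeGrid

        d0, _ = fig3_dtof_pair
        other = DTOF(
            counts=np.ones(128), grid=TimeGrid(bin_width=5.0, n_bins=128)
        )
        with pytest.raises(InvalidParameterError):
            fit_two_layer(d0, other, fig3_scenario.baseline, fig3_scenario.irf)


class TestBaselineErrorStudy:
    def test_true_value_recovers_truth(self, fig3_scenario):
        table = baseline_error_study(fig3_scenario, "musp_sup", [1.0])
        assert table.dmua_sup[0] == pytest.approx(0.0, abs=1e-5)
        assert table.dmua_deep[0] == pytest.approx(0.005, rel=0.01)

    def test_musp_deep_has_little_effect(self, fig3_scenario):
        """+-20% error in the assumed deep musp barely moves the result."""
        table = baseline_error_study(fig3_scenario, "musp_deep", [0.8, 1.0, 1.2])
        dev = np.abs(table.dmua_deep - 0.005)
        assert dev.max() < 0.1 * 0.005

    def test_thickness_error_direction(self, fig3_scenario):
        """Underestimating L pulls the recovered deep change toward the
        superficial truth (0 here); overestimating pushes it away."""
        table = baseline_error_study(fig3_scenario, "L", [13.0, 15.0, 17.0])
        deep = table.dmua_deep.to_numpy()
        truth_deep, truth_sup = 0.005, 0.0
        assert abs(deep[0] - truth_sup) < abs(deep[1] - truth_sup)  # pulled toward
        assert abs(deep[2] - truth_sup) > abs(deep[1] - truth_sup)  # pushed away
        # the superficial recovery barely reacts to L
        assert np.abs(table.dmua_sup.to_numpy() - truth_sup).max() < 0.2 * truth_deep

    def test_unknown_parameter_raises(self, fig3_scenario):
        with pytest.raises(InvalidParameterError):
            baseline_error_study(fig3_scenario, "rho", [30.0])
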