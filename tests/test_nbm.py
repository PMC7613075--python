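"""Neural binding model: decode-error densities, simulator, exact likelihood
and model-based diagnostics."""

import numpy as np
import pytest

from swaplab import nbm, taskgen
from swaplab.circular import bessel_ratio, vm_pdf, wrap


@pytest.fixture(scope="module")
def params():
    return nbm.NBMParams(kappa_loc=10.0, kappa_feat=5.0, gain=40.0,
                         conjunction={"low": 0.3, "medium": 0.6, "high": 0.9})


@pytest.fixture(scope="module")
def medium_array():
    cfg = taskgen.exp1_config("location-report", n_trials_per_level=1, seed=3)
    return taskgen.generate_array(cfg, np.random.default_rng(7), level="medium")


class TestDecodeErrorDensity:
    def test_zero_samples_is_uniform(self):
        dens = nbm.decode_error_density(0, 5.0)
        assert np.allclose(dens, 1 / (2 * np.pi))

    def test_one_sample_is_von_mises(self):
        theta = nbm._theta_grid(720)
        np.testing.assert_allclose(nbm.decode_error_density(1, 3.0),
                                   vm_pdf(theta, 0.0, 3.0), rtol=1e-10)

    def test_matches_fresh_monte_carlo_oracle(self):
        # resultant direction of 4 vM(0, 2) samples, independent-seed oracle
        m, kappa = 4, 2.0
        dens = nbm.decode_error_density(m, kappa, 2880)
        theta = nbm._theta_grid(2880)
        draws = np.random.default_rng(991).vonmises(0.0, kappa, (2_000_000, m))
        dec = np.angle(np.exp(1j * draws).sum(axis=1))
        edges = np.linspace(-np.pi, np.pi, 101)
        hist, _ = np.histogram(dec, bins=edges, density=True)
        idx = np.digitize(theta, edges) - 1
        bin_avg = np.array([dens[idx == i].mean() for i in range(100)])
        center = 50  # bin containing zero error
        assert bin_avg[center] == pytest.approx(hist[center], rel=0.02)

    def test_normalization(self):
        for m, kappa in ((2, 1.0), (6, 8.0), (40, 3.0)):
            dens = nbm.decode_error_density(m, kappa, 720)
            assert dens.sum() * 2 * np.pi / 720 == pytest.approx(1.0, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nbm.decode_error_density(-1, 2.0)


class TestSimulator:
    def test_noiseless_limit_concentrates_on_target(self, medium_array):
        p = nbm.NBMParams(kappa_loc=200.0, kappa_feat=200.0, gain=2000.0,
                          conjunction={"medium": 1.0})
        sim = nbm._simulate_arrays([medium_array] * 2000, p,
                                   np.random.default_rng(0))
        assert sim["is_swap"].mean() < 0.001
        errs = wrap(sim["response"]
                    - medium_array.rep_feats[medium_array.target])
        assert np.abs(errs).max() < 0.1

    def test_zero_conjunction_with_feature_cue_gives_chance_selection(
            self, medium_array):
        # no cue-dimension information: uniform decodes, selection at chance
        p = nbm.NBMParams(kappa_loc=10.0, kappa_feat=5.0, gain=40.0,
                          conjunction={"medium": 0.0})
        n_trials = 5000
        sim = nbm._simulate_arrays([medium_array] * n_trials, p,
                                   np.random.default_rng(1))
        chance = 5 / 6
        se = np.sqrt(chance * (1 - chance) / n_trials)
        assert abs(sim["is_swap"].mean() - chance) < 3 * se

    def test_trial_api_diagnostics(self, medium_array, params):
        rec, diag = nbm.nbm_simulate_trial(medium_array, params,
                                           np.random.default_rng(2))
        assert diag.is_swap == (diag.selected_index != medium_array.target)
        assert diag.fisher_cue.shape == (6,)
        assert rec.ground_truth_selected == diag.selected_index


class TestResponseDensity:
    def test_integrates_to_one_and_selection_sums_to_one(self, medium_array,
                                                         params):
        theta, dens = nbm.nbm_response_density(medium_array, params)
        assert dens.sum() * 2 * np.pi / len(theta) == pytest.approx(1.0,
                                                                    abs=1e-6)
        selp = nbm.selection_probabilities(medium_array, params)
        assert selp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_swap_mass_matches_simulator(self, medium_array, params):
        selp = nbm.selection_probabilities(medium_array, params)
        model_swap = 1.0 - selp[medium_array.target]
        n_trials = 40_000
        sim = nbm._simulate_arrays([medium_array] * n_trials, params,
                                   np.random.default_rng(3))
        emp = sim["is_swap"].mean()
        se = np.sqrt(emp * (1 - emp) / n_trials)
        assert abs(model_swap - emp) < 3 * se + 1e-3

    def test_histogram_agrees_with_density(self, medium_array, params):
        theta, dens = nbm.nbm_response_density(medium_array, params)
        sim = nbm._simulate_arrays([medium_array] * 60_000, params,
                                   np.random.default_rng(4))
        edges = np.linspace(-np.pi, np.pi, 73)
        hist, _ = np.histogram(sim["response"], bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        model = np.interp(centers, theta, dens, period=2 * np.pi)
        tv = 0.5 * np.sum(np.abs(hist - model)) * (edges[1] - edges[0])
        assert tv < 0.02


@pytest.fixture(scope="module")
def records(params):
    cfg = taskgen.exp1_config("location-report", n_trials_per_level=150,
                              seed=5)
    trials = taskgen.generate_trials(cfg)
    return [r for r, _ in nbm.simulate_trials(trials, params,
                                              np.random.default_rng(5))]


class TestLoglik:
    def test_additivity_under_duplication(self, records, params):
        grid = nbm.NBMGrid(theta=360, t=64, delta=61)
        ll = nbm.nbm_loglik(records, params, grid)
        ll2 = nbm.nbm_loglik(records + records, params, grid)
        assert ll2 == pytest.approx(2 * ll, rel=1e-9)

    def test_deterministic(self, records, params):
        grid = nbm.NBMGrid(theta=360, t=64, delta=61)
        assert nbm.nbm_loglik(records, params, grid) == nbm.nbm_loglik(
            records, params, grid)

    def test_generating_parameters_beat_strong_perturbation(self, records,
                                                            params):
        grid = nbm.NBMGrid(theta=360, t=64, delta=61)
        bad = nbm.NBMParams(kappa_loc=params.kappa_loc,
                            kappa_feat=params.kappa_feat,
                            gain=params.gain * 10,
                            conjunction=params.conjunction)
        assert nbm.nbm_loglik(records, params, grid) > nbm.nbm_loglik(
            records, bad, grid)

    def test_missing_level_rejected(self, records):
        bad = nbm.NBMParams(kappa_loc=10.0, kappa_feat=5.0, gain=40.0,
                            conjunction={"other": 0.5})
        with pytest.raises(ValueError):
            nbm.nbm_loglik(records, bad)


class TestDiagnostics:
    def test_zero_spike_marginal_matches_analytic_thinning(self, medium_array):
        p = nbm.NBMParams(kappa_loc=10.0, kappa_feat=5.0, gain=24.0,
                          conjunction={"medium": 0.5})
        analytic = nbm.zero_spike_probability(p, "medium", 6)
        assert analytic == pytest.approx(np.exp(-24.0 * 0.5 / 6), rel=1e-12)
        out = nbm.zero_spike_conditionals(p, [medium_array] * 30_000,
                                          np.random.default_rng(6))
        emp = out["p_zero_marginal_empirical"]
        se = np.sqrt(analytic * (1 - analytic) / 30_000)
        assert abs(emp - analytic) < 3 * se

    def test_zero_conjunction_marginal_is_one(self, medium_array):
        p = nbm.NBMParams(kappa_loc=10.0, kappa_feat=5.0, gain=24.0,
                          conjunction={"medium": 0.0})
        assert nbm.zero_spike_probability(p, "medium", 6) == 1.0
        out = nbm.precision_by_outcome(p, [medium_array] * 2000,
                                       np.random.default_rng(7))
        assert out["unconditional_mean"] == 0.0

    def test_precision_ordering_and_unconditional_mean(self, medium_array,
                                                       params):
        out = nbm.precision_by_outcome(params, [medium_array] * 30_000,
                                       np.random.default_rng(8))
        # targets are retrieved more precisely on correct than on swap trials
        assert out["target_correct"] > out["target_swap"]
        c = params.conjunction["medium"]
        expected = (params.gain * c / 6) * params.kappa_feat \
            * bessel_ratio(params.kappa_feat)
        assert out["unconditional_mean"] == pytest.approx(expected, rel=0.05)
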