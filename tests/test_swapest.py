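"""Swap estimators: nearest-item rule, mixture EM, randomization corrections,
resultant-vector weights and the distance-binned MAD profile."""

import numpy as np
import pytest

from swaplab import swapest, taskgen
from swaplab.circular import wrap
from swaplab.taskgen import MixtureGenParams, ResponseRecord, TrialArray


def make_trial(rep, cue=None, target=0, level="low", cue_dim="orientation"):
    rep = np.asarray(rep, dtype=float)
    cue = rep.copy() if cue is None else np.asarray(cue, dtype=float)
    return TrialArray(cue_feats=cue, rep_feats=rep, target=target,
                      level=level, cue_dim=cue_dim)


class TestNearestItem:
    def test_response_at_target_and_at_nontarget(self):
        t = make_trial([0.0, 1.5, -2.0])
        at_target = ResponseRecord(trial=t, response=0.0)
        at_nontarget = ResponseRecord(trial=t, response=1.5)
        _, labels = swapest.nearest_item_swaps([at_target, at_nontarget])
        assert list(labels) == [False, True]

    def test_duplicate_report_features_rejected(self):
        t = make_trial([0.4, 0.4, 1.0])
        with pytest.raises(ValueError):
            swapest.nearest_item_swaps([ResponseRecord(trial=t, response=0.0)])

    def test_recovers_generating_nontarget_rate_at_low_noise(
            self, exp1_trials_location_report):
        trials = exp1_trials_location_report * 8
        params = MixtureGenParams(0.7, 0.3, 0.0, kappa=50.0)
        recs = taskgen.simulate_responses(trials, "mixture", params,
                                          np.random.default_rng(11))
        est, _ = swapest.nearest_item_swaps(recs)
        se = np.sqrt(0.3 * 0.7 / len(recs))
        assert abs(est.proportion - 0.3) < 3 * se


class TestMixtureEM:
    def test_pure_target_data(self, exp1_trials_location_report):
        trials = exp1_trials_location_report * 6
        recs = taskgen.simulate_responses(
            trials, "mixture", MixtureGenParams(1.0, 0.0, 0.0, kappa=8.0),
            np.random.default_rng(2))
        est = swapest.fit_mixture(recs, n_restarts=5)
        assert est.p_target >= 0.95
        assert est.converged

    def test_parameter_recovery(self, mixture_records,
                                exp1_trials_location_report):
        trials = exp1_trials_location_report * 6   # n = 3000
        recs = taskgen.simulate_responses(
            trials, "mixture", MixtureGenParams(0.6, 0.3, 0.1, kappa=8.0),
            np.random.default_rng(21))
        est = swapest.fit_mixture(recs, n_restarts=10,
                                  rng=np.random.default_rng(0))
        assert est.p_target == pytest.approx(0.6, abs=0.05)
        assert est.p_nontarget == pytest.approx(0.3, abs=0.05)
        assert est.p_uniform == pytest.approx(0.1, abs=0.05)
        assert est.kappa == pytest.approx(8.0, rel=0.20)
        assert est.p_target + est.p_nontarget + est.p_uniform == pytest.approx(1.0)

    def test_pure_uniform_degenerate_case(self, exp1_trials_location_report):
        # on uniform data the fit is degenerate: either the uniform weight
        # dominates or kappa collapses toward 0 (a uniform von Mises), and
        # the weights become arbitrary; the implied density must be uniform
        recs = taskgen.simulate_responses(
            exp1_trials_location_report * 4, "mixture",
            MixtureGenParams(0.0, 0.0, 1.0), np.random.default_rng(4))
        est = swapest.fit_mixture(recs, n_restarts=5)
        assert est.p_uniform > 0.75 or est.kappa < 0.5
        uniform_ll = -len(recs) * np.log(2 * np.pi)
        assert est.loglik == pytest.approx(uniform_ll, abs=0.005 * len(recs))


class TestExpectedProfile:
    def test_unconstrained_uniform_nontargets_flat_profile(self, rng):
        # no minimum separation: expected histogram ~ uniform, MAD ~ pi/2
        trials = []
        for _ in range(400):
            rep = rng.uniform(-np.pi, np.pi, 6)
            trials.append(make_trial(rep, target=0))
        recs = taskgen.simulate_responses(trials, "target_only", 8.0,
                                          np.random.default_rng(5))
        prof = swapest.expected_nontarget_profile(
            recs, swapest.GeneratorConstraints(0.0), n_iter=300, rng=rng)
        assert prof.expected_mad == pytest.approx(np.pi / 2, abs=0.02)
        assert np.allclose(prof.expected, 1 / (2 * np.pi), atol=0.012)

    def test_minimum_separation_produces_central_dip(
            self, exp1_trials_location_report):
        recs = taskgen.simulate_responses(
            exp1_trials_location_report * 2, "target_only", 20.0,
            np.random.default_rng(6))
        prof = swapest.expected_nontarget_profile(
            recs, swapest.GeneratorConstraints(np.pi / 6), n_iter=300,
            rng=np.random.default_rng(1))
        center = len(prof.expected) // 2
        assert prof.expected[center] < 0.6 * prof.expected.mean()

    def test_corrected_histogram_null_on_swap_free_data(
            self, exp1_trials_location_report):
        trials = exp1_trials_location_report * 4
        recs = taskgen.simulate_responses(trials, "target_only", 8.0,
                                          np.random.default_rng(8))
        prof = swapest.expected_nontarget_profile(
            recs, swapest.GeneratorConstraints(np.pi / 6), n_iter=500,
            rng=np.random.default_rng(2))
        n_dev = len(recs) * 5
        width = prof.bin_edges[1] - prof.bin_edges[0]
        # binomial MC error of the observed histogram dominates
        se = np.sqrt(np.clip(prof.expected, 1e-4, None) / (n_dev * width))
        assert np.all(np.abs(prof.corrected) < 3.5 * se + 1e-9)


class TestResultantVector:
    def test_no_swap_data_gives_near_zero_nontarget_weight(
            self, exp1_trials_location_report):
        trials = exp1_trials_location_report * 8
        recs = taskgen.simulate_responses(
            trials, "mixture",
            MixtureGenParams(0.8, 0.0, 0.2, error="wrapped_laplace"),
            np.random.default_rng(9))
        out = swapest.resultant_vector_estimate(recs)
        assert abs(out["p_nontarget"]) < 0.06
        assert not out["flagged"]
        total = out["p_target"] + out["p_nontarget"] + out["p_uniform"]
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_distribution_free_recovery(self, exp1_trials_location_report):
        trials = exp1_trials_location_report * 10   # 5000 pooled trials
        recs = taskgen.simulate_responses(
            trials, "mixture",
            MixtureGenParams(0.5, 0.3, 0.2, error="wrapped_laplace"),
            np.random.default_rng(10))
        out = swapest.resultant_vector_estimate(recs)
        assert out["p_target"] == pytest.approx(0.5, abs=0.07)
        assert out["p_nontarget"] == pytest.approx(0.3, abs=0.07)
        assert out["p_uniform"] == pytest.approx(0.2, abs=0.09)

    def test_degenerate_uniform_data_flagged(self, exp1_trials_location_report):
        recs = taskgen.simulate_responses(
            exp1_trials_location_report, "mixture",
            MixtureGenParams(0.0, 0.0, 1.0), np.random.default_rng(12))
        out = swapest.resultant_vector_estimate(recs)
        assert out["flagged"]


class TestMADByDistance:
    def test_no_swap_uniform_orientations_flat_at_half_pi(self, rng):
        cfg = taskgen.exp3_config("random", n_trials=1)
        trials = [taskgen.generate_array(cfg, rng) for _ in range(3000)]
        recs = taskgen.simulate_responses(trials, "target_only", 8.0,
                                          np.random.default_rng(13))
        prof = swapest.mad_by_distance(recs)
        assert prof.shape[0] == 7
        for _, row in prof.iterrows():
            se = (np.pi / np.sqrt(12)) / np.sqrt(row["n"])
            assert abs(row["mad"] - np.pi / 2) < 3.5 * se

    def test_fixed_configuration_occupies_three_distances(self, rng):
        cfg = taskgen.exp3_config("fixed", n_trials=1)
        trials = [taskgen.generate_array(cfg, rng) for _ in range(200)]
        recs = taskgen.simulate_responses(trials, "target_only", 8.0,
                                          np.random.default_rng(14))
        prof = swapest.mad_by_distance(recs, discrete=True)
        np.testing.assert_allclose(sorted(prof["center"]),
                                   np.deg2rad([60, 120, 180]), atol=1e-5)

    def test_swaps_to_nearest_nontarget_dip_only_nearest_bin(self, rng):
        cfg = taskgen.exp3_config("random", n_trials=1)
        trials = [taskgen.generate_array(cfg, rng) for _ in range(4000)]
        recs = []
        gen = np.random.default_rng(15)
        for t in trials:
            cue_val = t.cue_feats[t.target]
            nts = t.nontarget_indices
            d = np.abs(wrap(t.cue_feats[nts] - cue_val))
            # swap toward the spatially nearest non-target on half the trials
            src = nts[np.argmin(d)] if gen.random() < 0.5 else t.target
            resp = wrap(t.rep_feats[src] + gen.vonmises(0.0, 30.0))
            recs.append(ResponseRecord(trial=t, response=float(resp),
                                       ground_truth_selected=int(src)))
        prof = swapest.mad_by_distance(recs)
        mads = prof["mad"].to_numpy()
        assert mads[0] < np.pi / 2 - 0.05          # nearest bin dips
        assert np.all(mads[2:] > np.pi / 2 - 0.03)  # far bins stay flat
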