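import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sorsvf.thresholding import (
    DOMAIN,
    PsychometricModel,
    ZESTConfig,
    build_prior,
    p_seen,
    pmf_mean,
    pmf_sd,
    run_staircase,
    run_zest,
    seed_prior,
    simulate_response,
    zest_done,
    zest_estimate,
    zest_next_stimulus,
    zest_start,
    zest_step,
)


class TestPsychometric:
    def test_floor_at_unseeably_dim_stimulus(self):
        m = PsychometricModel(true_threshold=10, fp=0.05, fn=0.02)
        assert p_seen(m, 40.0) == pytest.approx(0.05)

    def test_midpoint_at_threshold(self):
        m = PsychometricModel(true_threshold=20, fp=0.03, fn=0.03)
        assert p_seen(m, 20.0) == pytest.approx(0.50)

    def test_linear_ramp_value(self):
        m = PsychometricModel(true_threshold=30, fp=0.0, fn=0.0, ramp_halfwidth=2.0)
        assert p_seen(m, 29.0) == pytest.approx(0.75)

    def test_monotone_non_increasing_in_stimulus(self):
        m = PsychometricModel(true_threshold=25, fp=0.1, fn=0.05, ramp_halfwidth=3.0)
        ps = [p_seen(m, s) for s in np.linspace(0, 40, 81)]
        assert np.all(np.diff(ps) <= 1e-12)
        assert min(ps) >= 0.1 - 1e-12 and max(ps) <= 0.95 + 1e-12

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            PsychometricModel(true_threshold=20, fp=0.6, fn=0.6)


class TestSimulateResponse:
    def test_degenerate_rates(self):
        rng = np.random.default_rng(0)
        never = PsychometricModel(true_threshold=10, fp=0.0, fn=0.0, ramp_halfwidth=0.0)
        assert not any(simulate_response(never, 39.0, rng) for _ in range(100))
        always = PsychometricModel(true_threshold=10, fp=1.0, fn=0.0, ramp_halfwidth=0.0)
        assert all(simulate_response(always, 39.0, rng) for _ in range(100))

    def test_midpoint_rate_matches_binomial(self):
        rng = np.random.default_rng(1)
        m = PsychometricModel(true_threshold=20, fp=0.03, fn=0.03)
        hits = sum(simulate_response(m, 20.0, rng) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.50, abs=0.02)


class TestPrior:
    def test_point_mass_with_zero_smoothing(self, grid24):
        X = np.full((54, 3), 30.0)
        p = build_prior(X, smoothing=0.0)
        assert p[30] == 1.0 and p.sum() == 1.0

    def test_uniform_training_gives_near_uniform_pmf(self):
        X = np.tile(DOMAIN, (5, 1))
        p = build_prior(X)
        assert p.max() / p.min() < 1.05

    def test_generated_mixture_is_bimodal(self, train200):
        p = build_prior(train200)
        # healthy mode spread over ~20-33 dB (the hill declines with
        # eccentricity, so pooling over locations broadens the peak),
        # damaged mass piled at the 0 dB floor, a trough in between
        assert p[20:34].sum() > 0.4
        assert p[0] > 3 * p[1:8].mean()
        assert p[8:16].mean() < p[24:32].mean()

    def test_seed_prior_identity_and_point_mass(self):
        p = np.zeros(len(DOMAIN))
        p[30] = 1.0
        assert np.array_equal(seed_prior(p, 30.0), p)
        shifted = seed_prior(p, 20.0)
        assert shifted[20] == 1.0

    def test_seed_prior_moves_mean_with_edge_effects(self, prior200):
        target = pmf_mean(DOMAIN, prior200) - 5.0
        shifted = seed_prior(prior200, target)
        assert shifted.sum() == pytest.approx(1.0)
        assert abs(pmf_mean(DOMAIN, shifted) - target) < 0.5


class TestZestUpdate:
    def test_not_seen_truncates_support_without_errors(self):
        cfg = ZESTConfig(fp=0.0, fn=0.0, ramp_halfwidth=2.0)
        state = zest_step(zest_start(cfg), cfg, stimulus=20.0, seen=False)
        # thresholds far above the stimulus would certainly have been seen
        assert np.all(state.pmf[np.where(DOMAIN >= 22.0)] == 0)
        assert state.pmf[np.where(DOMAIN < 18.0)].sum() > 0

    def test_updates_commute(self, prior200):
        cfg = ZESTConfig(prior=prior200)
        a = zest_step(zest_step(zest_start(cfg), cfg, 20.0, True), cfg, 28.0, False)
        b = zest_step(zest_step(zest_start(cfg), cfg, 28.0, False), cfg, 20.0, True)
        assert np.allclose(a.pmf, b.pmf, atol=1e-12)

    def test_five_bin_hand_oracle(self):
        domain = np.arange(5, dtype=float)
        cfg = ZESTConfig(
            prior=np.full(5, 0.2), domain=domain, fp=0.03, fn=0.03, ramp_halfwidth=2.0
        )
        state = zest_step(zest_start(cfg), cfg, stimulus=2.0, seen=True)
        # by hand: p_seen(t) for t=0..4 is .03, .265, .5, .735, .97; normalize
        like = np.array([0.03, 0.265, 0.5, 0.735, 0.97])
        expected = like / like.sum()
        assert np.allclose(state.pmf, expected, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        stimuli=st.lists(st.floats(0, 40), min_size=1, max_size=6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_pmf_stays_normalized_after_every_update(self, prior200, stimuli, seed):
        cfg = ZESTConfig(prior=prior200)
        rng = np.random.default_rng(seed)
        state = zest_start(cfg)
        for s in stimuli:
            state = zest_step(state, cfg, float(np.clip(round(s), 0, 40)), bool(rng.random() < 0.5))
            assert abs(state.pmf.sum() - 1.0) < 1e-9


class TestZestControl:
    def test_point_mass_done_immediately(self):
        p = np.zeros(len(DOMAIN))
        p[25] = 1.0
        cfg = ZESTConfig(prior=p)
        state = zest_start(cfg)
        assert zest_done(state, cfg)
        assert zest_estimate(state, cfg) == 25.0

    def test_uniform_pmf_not_done_sd_matches_formula(self):
        cfg = ZESTConfig()
        state = zest_start(cfg)
        # discrete uniform on 41 bins: sd = sqrt((41^2 - 1)/12)
        assert pmf_sd(DOMAIN, state.pmf) == pytest.approx(np.sqrt((41**2 - 1) / 12))
        assert not zest_done(state, cfg)

    def test_termination_threshold_is_strict_two_db(self):
        from sorsvf.thresholding import ZESTState

        cfg = ZESTConfig()
        for sd, done in ((1.99, True), (2.0, False), (2.01, False)):
            # three-point pmf at 20 +/- 2 with tail mass q^2/2 has sd = 2q
            q = sd / 2.0
            pmf = np.zeros(len(DOMAIN))
            pmf[18], pmf[20], pmf[22] = 0.5 * q * q, 1 - q * q, 0.5 * q * q
            state = ZESTState(pmf=pmf)
            assert pmf_sd(DOMAIN, pmf) == pytest.approx(sd, abs=1e-9)
            assert zest_done(state, cfg) is done

    def test_next_stimulus_is_rounded_posterior_mean(self, prior200):
        cfg = ZESTConfig(prior=prior200)
        state = zest_start(cfg)
        assert zest_next_stimulus(state, cfg) == round(pmf_mean(DOMAIN, prior200))


class TestRunZest:
    def test_determinized_responder_lands_within_two_db(self, prior200):
        cfg = ZESTConfig(prior=prior200)
        rng = np.random.default_rng(5)
        for t in (5.3, 12.7, 20.1, 27.6, 33.2):
            resp = PsychometricModel(true_threshold=t, fp=0, fn=0, ramp_halfwidth=0)
            est, n = run_zest(cfg, resp, rng)
            assert abs(est - t) <= 2.0
            assert n >= 1

    def test_point_mass_prior_terminates_with_zero_presentations(self):
        p = np.zeros(len(DOMAIN))
        p[30] = 1.0
        est, n = run_zest(
            ZESTConfig(prior=p),
            PsychometricModel(true_threshold=10),
            np.random.default_rng(0),
        )
        assert n == 0 and est == 30.0

    def test_bit_reproducible_under_seed(self, prior200):
        cfg = ZESTConfig(prior=prior200)
        resp = PsychometricModel(true_threshold=17.0)
        r1 = run_zest(cfg, resp, np.random.default_rng(77))
        r2 = run_zest(cfg, resp, np.random.default_rng(77))
        assert r1 == r2

    def test_trace_log_matches_run(self, prior200):
        from sorsvf import run_zest_trace

        cfg = ZESTConfig(prior=prior200)
        resp = PsychometricModel(true_threshold=24.0)
        est, n = run_zest(cfg, resp, np.random.default_rng(55))
        est2, log = run_zest_trace(cfg, resp, np.random.default_rng(55))
        assert est2 == est and len(log) == n
        assert log[-1]["posterior_sd"] < cfg.terminate_sd

    def test_presentations_non_increasing_in_terminate_sd(self, prior200):
        counts = []
        for sd in (1.0, 2.0, 4.0):
            tot = 0
            for rep in range(20):
                rng = np.random.default_rng([13, rep])
                cfg = ZESTConfig(prior=prior200, terminate_sd=sd)
                resp = PsychometricModel(true_threshold=22.0)
                tot += run_zest(cfg, resp, rng)[1]
            counts.append(tot)
        assert counts[0] >= counts[1] >= counts[2]

    def test_unbiased_with_reliable_responder(self, prior200):
        """Estimates are unbiased within +/-1 dB for interior thresholds."""
        cfg = ZESTConfig(prior=prior200)
        for t in (15.0, 25.0):
            errs = []
            for rep in range(300):
                rng = np.random.default_rng([21, int(t), rep])
                resp = PsychometricModel(true_threshold=t, fp=0.0, fn=0.0)
                errs.append(run_zest(cfg, resp, rng)[0] - t)
            assert abs(np.mean(errs)) <= 1.0


class TestStaircase:
    def test_hand_traced_example(self):
        """seen@30 -> 34 not seen (rev 1) -> 32 not seen -> 30 seen (rev 2)."""
        responses = iter([True, False, False, True])

        class FakeRng:
            def random(self):
                return 0.0 if next(responses) else 1.0

        resp = PsychometricModel(true_threshold=30, fp=0.5, fn=0.0, ramp_halfwidth=0)
        est, n = run_staircase(30.0, resp, FakeRng())
        assert est == 30.0 and n == 4

    def test_exhaustive_interior_thresholds_within_two_db(self):
        for t10 in range(30, 371):  # t = 3.0 .. 37.0 step 0.1
            t = t10 / 10
            resp = PsychometricModel(true_threshold=t, fp=0, fn=0, ramp_halfwidth=0)
            est, _ = run_staircase(30.0, resp, np.random.default_rng(0))
            assert abs(est - t) <= 2.0, t

    def test_never_seen_clamps_to_floor(self):
        resp = PsychometricModel(true_threshold=20, fp=0.0, fn=1.0)
        est, n = run_staircase(30.0, resp, np.random.default_rng(0))
        assert est == 0.0
        assert n <= 15
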