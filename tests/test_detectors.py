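import numpy as np
import pytest

from gaitevents.core import GaitEventSet, IMURecording
from gaitevents.detectors import (
    REGISTRY,
    EchoStateNetwork,
    detect,
    detect_auvinet,
    detect_fadillioglu,
    detect_lee_side,
    detect_purcell,
    enforce_alternation,
    list_methods,
    match_events,
    train_bach,
)
from gaitevents.simulate import SimTrialConfig, simulate_trial

ALL_METHODS = sorted(REGISTRY)
RECOMMENDED = ["purcell", "fadillioglu", "auvinet", "reenalda"]

EXPECTED_REGISTRY = {
    # method_id: (placement, events)
    "mizrahi": ("shank", {"IC"}),
    "mercer": ("shank", {"IC", "TC"}),
    "purcell": ("shank", {"IC", "TC"}),
    "greene_mcgrath": ("shank", {"IC", "TC"}),
    "greene_mcgrath_modified": ("shank", {"IC", "TC"}),
    "aminian_odonovan": ("shank", {"IC", "TC"}),
    "aminian_odonovan_modified": ("shank", {"IC", "TC"}),
    "sinclair": ("shank", {"IC", "TC"}),
    "whelan": ("shank", {"IC"}),
    "norris": ("shank", {"IC"}),
    "schmidt": ("shank", {"IC", "TC"}),
    "aubol": ("shank", {"IC"}),
    "fadillioglu": ("shank", {"IC", "TC"}),
    "bach": ("shank", {"IC", "TC"}),
    "bach_modified": ("shank", {"IC", "TC"}),
    "auvinet": ("sacrum", {"IC", "TC", "side"}),
    "lee": ("sacrum", {"IC", "TC", "side"}),
    "wixted": ("sacrum", {"IC", "TC"}),
    "bergamini": ("sacrum", {"IC", "TC"}),
    "benson": ("sacrum", {"IC", "TC", "side"}),
    "reenalda": ("sacrum", {"IC"}),
}


def _zero_rec(placement, n=3000, rate=1000.0):
    return IMURecording(time=np.arange(n) / rate, accel=np.zeros((3, n)),
                        gyro=np.zeros((3, n)), rate_hz=rate,
                        placement=placement)


def _shift_rec(rec, pad_frames):
    """Prepend the first frame pad_frames times (a +pad time shift)."""
    rep = lambda a: np.hstack([np.tile(a[:, :1], (1, pad_frames)), a])
    return IMURecording(
        time=np.arange(rec.n + pad_frames) / rec.rate_hz,
        accel=rep(rec.accel), gyro=rep(rec.gyro), rate_hz=rec.rate_hz,
        placement=rec.placement)


class TestRegistry:
    def test_full_registry_coverage(self):
        """All published methods plus the three modified variants exist."""
        assert set(REGISTRY) == set(EXPECTED_REGISTRY)

    @pytest.mark.parametrize("method_id", ALL_METHODS)
    def test_placement_and_events_declared(self, method_id):
        placement, events = EXPECTED_REGISTRY[method_id]
        spec = REGISTRY[method_id]
        assert spec.placement == placement
        assert set(spec.events_provided) == events
        assert spec.native_rate_hz > 0

    def test_list_methods_filters_by_placement(self):
        assert set(list_methods("shank")) | set(list_methods("sacrum")) == set(
            REGISTRY
        )

    def test_unknown_method_raises(self, shank_trial):
        with pytest.raises(KeyError):
            detect("nope", shank_trial[0])

    def test_wrong_placement_raises(self, shank_trial):
        with pytest.raises(ValueError, match="placement|expects"):
            detect("auvinet", shank_trial[0])

    def test_gyro_method_requires_gyro_channel(self, shank_trial):
        rec = shank_trial[0].copy_with()
        rec.meta["has_gyro"] = False
        with pytest.raises(ValueError, match="gyro"):
            detect("fadillioglu", rec)


class TestDispatcherContracts:
    @pytest.mark.parametrize("method_id", ALL_METHODS)
    def test_all_zero_signals_fail_gracefully(self, method_id):
        rec = _zero_rec(REGISTRY[method_id].placement)
        res = detect(method_id, rec)
        assert res.events.failed
        assert res.events.n_ic == res.events.n_tc == 0

    @pytest.mark.parametrize("method_id", ALL_METHODS)
    def test_determinism(self, method_id, shank_trial, sacrum_trial):
        rec = (shank_trial if REGISTRY[method_id].placement == "shank"
               else sacrum_trial)[0]
        r1 = detect(method_id, rec)
        r2 = detect(method_id, rec)
        assert np.array_equal(r1.events.ic_times, r2.events.ic_times)
        assert np.array_equal(r1.events.tc_times, r2.events.tc_times)

    @pytest.mark.parametrize("method_id", [m for m in ALL_METHODS
                                           if not m.startswith("bach")])
    def test_time_shift_equivariance(self, method_id, shank_trial, sacrum_trial):
        """Shifting the input by +100 ms shifts every event by +100 ms
        within one native-rate frame."""
        rec = (shank_trial if REGISTRY[method_id].placement == "shank"
               else sacrum_trial)[0]
        res = detect(method_id, rec)
        if res.events.failed:
            pytest.skip("method finds no events on this fixture")
        shifted = detect(method_id, _shift_rec(rec, 100))
        tol = 1.0 / REGISTRY[method_id].native_rate_hz + 1e-9
        for a, b in ((res.events.ic_times, shifted.events.ic_times),
                     (res.events.tc_times, shifted.events.tc_times)):
            assert len(a) == len(b)
            if len(a):
                assert np.max(np.abs((b - 0.1) - a)) <= tol

    def test_events_within_record_bounds(self, fixture_suite):
        for cfg, rec, _ in fixture_suite[::7]:
            for m in list_methods(cfg.placement):
                res = detect(m, rec)
                for arr in (res.events.ic_times, res.events.tc_times):
                    if arr.size:
                        assert arr.min() >= rec.time[0]
                        assert arr.max() <= rec.time[-1]


class TestRecommendedAccuracy:
    @pytest.mark.parametrize("method_id", RECOMMENDED)
    def test_median_error_and_zero_failures(self, method_id, fixture_suite):
        spec = REGISTRY[method_id]
        errs = []
        for cfg, rec, truth in fixture_suite:
            if cfg.placement != spec.placement:
                continue
            res = detect(method_id, rec)
            assert not res.events.failed, f"{method_id} failed at {cfg}"
            m = match_events(res.events, GaitEventSet(truth.ic_times,
                                                      truth.tc_times))
            errs.extend(m.ic_errors_ms)
            errs.extend(m.tc_errors_ms)
        assert np.median(np.abs(errs)) <= 50.0

    def test_purcell_single_stance(self):
        """One impact transient plus one push-off gives exactly 1 IC + 1 TC."""
        n, rate = 1500, 1000.0
        t = np.arange(n) / rate
        ay = 1.0 + 6.0 * np.exp(-0.5 * ((t - 0.5) / 0.01) ** 2)
        ay += 2.5 * np.exp(-0.5 * ((t - 0.75) / 0.02) ** 2)
        rec = IMURecording(time=t, accel=np.vstack([np.zeros(n), ay, np.zeros(n)]),
                           gyro=np.zeros((3, n)), rate_hz=rate, placement="shank")
        res = detect_purcell(rec)
        assert res.events.n_ic == 1 and res.events.n_tc == 1
        assert res.events.ic_times[0] < res.events.tc_times[0]
        assert res.events.ic_times[0] == pytest.approx(0.5, abs=0.02)
        assert res.events.tc_times[0] == pytest.approx(0.75, abs=0.02)

    def test_purcell_failure_free_across_speeds(self):
        for speed in (2.5, 3.5, 5.0, 6.5, 7.5):
            rec, _ = simulate_trial(SimTrialConfig(speed=speed, seed=0))
            assert not detect_purcell(rec).events.failed

    def test_fadillioglu_periodic_gyro_counts_strides(self):
        """Ten swing peaks with IC/TC troughs give ten ICs and ten TCs."""
        n, rate = 8000, 1500.0
        t = np.arange(n) / rate
        gz = np.zeros(n)
        stride, stance = 0.5, 0.2
        ics = 0.3 + np.arange(10) * stride
        tcs = ics + stance
        mids = tcs + (stride - stance) / 2
        for c, a, s in [(mids, 8.0, 0.04), (ics, -5.0, 0.015), (tcs, -4.0, 0.015)]:
            for cc in c:
                gz += a * np.exp(-0.5 * ((t - cc) / s) ** 2)
        rec = IMURecording(time=t, accel=np.tile([[0.0], [1.0], [0.0]], (1, n)),
                           gyro=np.vstack([np.zeros(n), np.zeros(n), gz]),
                           rate_hz=rate, placement="shank")
        res = detect_fadillioglu(rec)
        # each mid-swing peak anchors the following IC and the preceding TC;
        # the IC after the final peak lies beyond the last stride
        assert res.events.n_ic == 9
        assert res.events.n_tc == 10
        assert np.max(np.abs(res.events.ic_times - ics[1:])) < 0.01
        assert np.max(np.abs(res.events.tc_times - tcs)) < 0.01

    def test_fadillioglu_sign_flip_with_registry_flag(self, shank_trial):
        """A left-leg (sign-flipped) gyro with the flip flag gives identical
        event times."""
        rec, _ = shank_trial
        base = detect_fadillioglu(rec)
        flipped_rec = rec.copy_with(gyro=rec.gyro * np.array([[1], [1], [-1]]))
        flipped = detect("fadillioglu", flipped_rec, params={"flip_sign": True})
        assert np.array_equal(base.events.ic_times, flipped.events.ic_times)
        assert np.array_equal(base.events.tc_times, flipped.events.tc_times)

    def test_auvinet_event_count_and_alternating_sides(self, sacrum_trial):
        rec, truth = sacrum_trial
        res = detect_auvinet(rec)
        # one IC and one TC per simulated step
        assert res.events.n_ic == len(truth.ic_times)
        assert res.events.n_tc == len(truth.tc_times)
        labels = res.events.sides
        assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_auvinet_amplitude_scale_invariance(self, sacrum_trial):
        rec, _ = sacrum_trial
        base = detect_auvinet(rec)
        doubled = detect_auvinet(rec.copy_with(accel=rec.accel * 2.0))
        assert np.array_equal(base.events.ic_times, doubled.events.ic_times)
        assert np.array_equal(base.events.tc_times, doubled.events.tc_times)


@pytest.fixture(scope="module")
def noise_free():
    return simulate_trial(SimTrialConfig(placement="sacrum", speed=4.5,
                                         noise_sd=0.0, seed=9))


class TestLeeSide:

    def test_noise_free_sides_perfect(self, noise_free):
        rec, truth = noise_free
        sides = detect_lee_side(rec, GaitEventSet(truth.ic_times,
                                                  truth.tc_times))
        assert sides == truth.sides

    def test_empty_events_give_empty_list(self, noise_free):
        assert detect_lee_side(noise_free[0], GaitEventSet([], [])) == []

    def test_zeroed_ml_channel_all_unknown(self, noise_free):
        rec, truth = noise_free
        rec0 = rec.copy_with(accel=rec.accel * np.array([[1], [1], [0]]))
        sides = detect_lee_side(rec0, GaitEventSet(truth.ic_times, []))
        assert set(sides) == {"unknown"}

    def test_ml_sign_flip_flips_every_label(self, noise_free):
        rec, truth = noise_free
        ev = GaitEventSet(truth.ic_times, [])
        a = detect_lee_side(rec, ev)
        b = detect_lee_side(
            rec.copy_with(accel=rec.accel * np.array([[1], [1], [-1]])), ev
        )
        flip = {"left": "right", "right": "left", "unknown": "unknown"}
        assert b == [flip[s] for s in a]


class TestEnforceAlternation:
    def test_already_alternating_unchanged(self):
        s = ["left", "right", "left", "right"]
        assert enforce_alternation(s) == s

    def test_single_flip_corrected(self):
        s = ["left", "right", "right", "right", "left", "right"]
        assert enforce_alternation(s) == ["left", "right", "left", "right",
                                          "left", "right"]

    def test_majority_phase_wins_brute_force(self):
        """Exhaustive check against scoring both phases directly."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            s = [rng.choice(["left", "right", "unknown"]) for _ in range(n)]
            out = enforce_alternation(list(s))
            assert all(a != b for a, b in zip(out, out[1:]))
            # oracle: best achievable agreement over the two phases
            best = max(
                sum(1 for i, lab in enumerate(s)
                    if lab in ("left", "right")
                    and lab == ([p0, p1][i % 2]))
                for p0, p1 in (("left", "right"), ("right", "left"))
            )
            got = sum(1 for a, b in zip(out, s)
                      if b in ("left", "right") and a == b)
            assert got == best

    def test_tie_keeps_first_labeled_event(self):
        s = ["left", "left"]  # each phase matches exactly one label
        out = enforce_alternation(s)
        assert out == ["left", "right"]

    def test_unknown_only_input(self):
        out = enforce_alternation(["unknown", "unknown", "unknown"])
        assert all(a != b for a, b in zip(out, out[1:]))


class TestSchmidtDesignRange:
    def test_failures_concentrate_at_low_speed(self):
        """The sprint-calibrated threshold misses low-speed trials."""
        def rate(speeds):
            fails = 0
            for v in speeds:
                for seed in range(3):
                    rec, _ = simulate_trial(SimTrialConfig(
                        speed=v, footstrike_angle=0.1, seed=seed))
                    fails += detect("schmidt", rec).events.failed
            return fails / (3 * len(speeds))

        assert rate([2.5, 2.8, 3.0]) > rate([6.5, 7.0, 7.5])


class TestWalkingDerivedWindows:
    @pytest.mark.parametrize("orig,mod", [
        ("greene_mcgrath", "greene_mcgrath_modified"),
        ("aminian_odonovan", "aminian_odonovan_modified"),
    ])
    def test_modified_variants_recover_more_events(self, orig, mod,
                                                   fixture_suite):
        """Walking-cadence windows skip or mislabel events from neighbouring
        steps at running cadence; the running-rescaled variants recover
        strictly more of the true events."""
        def matched(method):
            total = 0
            for cfg, rec, truth in fixture_suite[:15]:
                if cfg.placement != "shank":
                    continue
                res = detect(method, rec)
                if res.events.failed:
                    continue
                m = match_events(res.events,
                                 GaitEventSet(truth.ic_times, truth.tc_times))
                total += len(m.ic_errors_ms) + len(m.tc_errors_ms)
            return total

        assert matched(mod) > matched(orig)


@pytest.fixture(scope="module")
def trained():
    trials = [simulate_trial(SimTrialConfig(speed=v, seed=s))
              for v, s in [(3.0, 0), (4.5, 1), (6.0, 2)]]
    return train_bach(trials)


class TestBach:

    def test_untrained_network_fails_cleanly(self, shank_trial):
        res = detect("bach", shank_trial[0])
        assert res.events.failed
        assert res.diagnostics.get("untrained")

    def test_trained_network_finds_events_on_held_out_trial(self, trained):
        rec, truth = simulate_trial(SimTrialConfig(speed=4.0, seed=77))
        res = detect("bach", rec, params={"model": trained})
        assert not res.events.failed
        m = match_events(res.events, GaitEventSet(truth.ic_times,
                                                  truth.tc_times))
        assert len(m.ic_errors_ms) >= len(truth.ic_times) - 1
        assert np.median(np.abs(m.ic_errors_ms)) < 60.0

    def test_modified_threshold_is_more_permissive(self, trained):
        rec, _ = simulate_trial(SimTrialConfig(speed=4.0, seed=78))
        base = detect("bach", rec, params={"model": trained})
        mod = detect("bach_modified", rec, params={"model": trained})
        total = lambda r: r.events.n_ic + r.events.n_tc
        assert total(mod) >= total(base)

    def test_reservoir_is_seed_deterministic(self):
        a, b = EchoStateNetwork(seed=3), EchoStateNetwork(seed=3)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.Win, b.Win)


class TestMatchEvents:
    def test_identical_sets_all_zero(self):
        ev = GaitEventSet([0.5, 1.1, 1.7], [0.7, 1.3, 1.9])
        m = match_events(ev, ev)
        assert np.allclose(m.ic_errors_ms, 0)
        assert np.allclose(m.tc_errors_ms, 0)
        assert m.unmatched_truth_ic == m.unmatched_truth_tc == 0

    def test_uniform_shift_reported(self):
        truth = GaitEventSet([0.5, 1.1, 1.7], [])
        det = GaitEventSet(truth.ic_times + 0.015, [])
        m = match_events(det, truth)
        assert np.allclose(m.ic_errors_ms, 15.0)

    def test_nearer_of_two_detections_pairs(self):
        truth = GaitEventSet([1.0], [])
        det = GaitEventSet([0.98, 1.10], [])
        m = match_events(det, truth)
        assert m.ic_errors_ms == pytest.approx([-20.0])
        assert m.extra_detected_ic == 1

    def test_outside_tolerance_unmatched(self):
        truth = GaitEventSet([1.0], [])
        det = GaitEventSet([1.5], [])
        m = match_events(det, truth)
        assert m.unmatched_truth_ic == 1 and len(m.ic_errors_ms) == 0

    def test_greedy_agrees_with_optimal_on_small_instances(self):
        """Brute-force optimal-assignment oracle on gait-like instances:
        truth events separated by at least a step time, detections jittered
        well below the matching tolerance, plus occasional spurious extras."""
        from scipy.optimize import linear_sum_assignment

        tol = 0.25
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 9))
            tru = np.cumsum(rng.uniform(0.3, 0.6, n)) + 0.5
            keep = rng.uniform(size=n) > 0.2
            det = tru[keep] + rng.normal(0, 0.03, int(keep.sum()))
            if rng.uniform() < 0.5:  # an extra detection far from any truth
                det = np.append(det, tru[-1] + 1.0)
            det = np.sort(np.unique(det))[:10]
            m = match_events(GaitEventSet(det, []), GaitEventSet(tru, []))
            big = 1e6
            cost = np.abs(det[:, None] - tru[None, :])
            cost[cost > tol] = big
            ri, ci = linear_sum_assignment(cost)
            n_opt = int(np.sum(cost[ri, ci] < big))
            assert len(m.ic_errors_ms) == n_opt
            assert m.unmatched_truth_ic == len(tru) - n_opt
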