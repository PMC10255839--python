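"""Synthetic running IMU signals with exact ground truth.

The waveform model is phenomenological: each trial is a sum of parameterized
components (a smooth stride-periodic base, an impact transient at each initial
contact, a push-off feature at each terminal contact, and sensor noise) whose
landmark timing is known by construction.  It is NOT a biomechanical
simulation; its contract is that every detector's landmark features exist at
the recorded truth times, that the sensor's orientation, angular velocity and
gravity signal are mutually consistent, and that a synthetic vertical ground
reaction force crosses 10 N exactly at each IC (upward) and TC (downward).

Sagittal-plane kinematics are generated first as an angular-velocity waveform
(swing peak, IC/TC troughs, stance-phase counter-rotation chosen so each
stride integrates to zero), integrated to a pitch angle, and the gravity
component of the accelerometer signal is rotated accordingly.  Specific-force
features are then added in the sensor frame.

Timing model (speed v in m/s):

* stride frequency  f = 1.25 + 0.07 v  (Hz)
* stance (contact) time  t_c = 0.35 - 0.03 v  (s), strictly decreasing in v
* steps alternate right/left every half stride (sacrum); a shank record
  carries only the instrumented (right) side's events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .calibration import invert_calibration
from .core import CalibrationModel, IMURecording, TrialRecord

SAT_G = 15.5  # primary accelerometer saturation threshold
PRIMARY_RANGE_G = 16.0  # primary accelerometer full scale
FORCE_THRESH_N = 10.0


@dataclass
class SimTrialConfig:
    """Conditions for one synthetic running trial.

    Speed and foot-strike-angle defaults sit inside the ranges the detectors
    are meant to cover (roughly 2.5-7.5 m/s and -0.25-0.75 rad).
    """

    placement: str = "shank"
    speed: float = 3.5
    footstrike_angle: float = 0.3
    surface: str = "track"
    n_strides: int = 6
    rate_hz: float = 1000.0
    noise_sd: float = 0.02  # g, accelerometer; gyro noise is noise_sd rad/s
    lead_in_s: float = 1.0  # quiet standing before running
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.n_strides < 1:
            raise ValueError("need at least one stride")
        if self.rate_hz <= 100:
            raise ValueError("rate_hz must exceed 100")


@dataclass
class SimTruth:
    """Ground truth stored alongside a simulated trial."""

    ic_times: np.ndarray
    tc_times: np.ndarray
    sides: list
    vertical_force: np.ndarray  # N, same grid as the recording
    gate_times: tuple
    specific_force: np.ndarray  # (3, N) g; accel minus sensor-frame gravity
    pitch: np.ndarray  # rad, sensor rotation about +z
    clipped_frames: int
    stance_time: float
    stride_time: float


def _stride_params(speed: float) -> tuple[float, float]:
    stride_t = 1.0 / (1.25 + 0.07 * speed)
    stance_t = max(0.08, 0.35 - 0.03 * speed)
    return stride_t, stance_t


def _add_bumps(y, t, centers, amp, sigma):
    """Add Gaussian bumps in place; supports scalar or per-center amplitude."""
    amps = np.broadcast_to(np.asarray(amp, float), np.shape(centers))
    for c, a in zip(np.asarray(centers, float).ravel(), amps.ravel()):
        lo = np.searchsorted(t, c - 5 * sigma)
        hi = np.searchsorted(t, c + 5 * sigma)
        y[lo:hi] += a * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)


def _smooth_box(t, start, end, edge=0.01):
    """Unit boxcar with sigmoid edges (0 outside [start, end])."""
    return 1.0 / (1.0 + np.exp(-(t - start) / edge)) - 1.0 / (
        1.0 + np.exp(-(t - end) / edge)
    )


def simulate_trial(cfg: SimTrialConfig) -> tuple[IMURecording, SimTruth]:
    """Generate one synthetic running trial with exact truth.

    Deterministic for a fixed config (seed included).  Shank records carry
    ipsilateral (right-side) events only; sacrum records carry bilateral
    events with alternating sides encoded in the medial-lateral acceleration.
    """
    rng = np.random.default_rng(cfg.seed)
    v, fsa = cfg.speed, cfg.footstrike_angle
    rate, dt = cfg.rate_hz, 1.0 / cfg.rate_hz
    stride_t, stance_t = _stride_params(v)
    lead = cfg.lead_in_s
    run_span = cfg.n_strides * stride_t
    dur = lead + run_span + 0.4
    n = int(round(dur * rate))
    t = np.arange(n) * dt

    def snap(x):
        return np.round(np.asarray(x) * rate) / rate

    # --- event schedule -----------------------------------------------------
    right_ic = snap(lead + np.arange(cfg.n_strides) * stride_t)
    right_tc = snap(right_ic + stance_t)
    if cfg.placement == "sacrum":
        left_ic = snap(right_ic + stride_t / 2)
        left_tc = snap(left_ic + stance_t)
        ic_all = np.concatenate([right_ic, left_ic])
        tc_all = np.concatenate([right_tc, left_tc])
        sides = ["right"] * len(right_ic) + ["left"] * len(left_ic)
        order = np.argsort(ic_all)
        ic_all, tc_all = ic_all[order], tc_all[order]
        sides = [sides[i] for i in order]
    else:
        ic_all, tc_all, sides = right_ic, right_tc, ["right"] * len(right_ic)

    # keep events whose features fit inside the record
    keep = tc_all < dur - 0.25
    ic_all, tc_all = ic_all[keep], tc_all[keep]
    sides = [s for s, k in zip(sides, keep) if k]

    surface_f = 1.05 if cfg.surface == "floor" else 1.0

    # --- sagittal angular velocity and pitch --------------------------------
    gz = np.zeros(n)
    if cfg.placement == "shank":
        mid_swing = snap(right_tc + (stride_t - stance_t) / 2)
        w_sw, s_sw = 3.0 + 1.1 * v, 0.040
        w_ic, s_ic = 3.0 + 0.6 * v, 0.015
        w_tc, s_tc = 2.0 + 0.4 * v, 0.015
        _add_bumps(gz, t, mid_swing, w_sw, s_sw)
        _add_bumps(gz, t, right_ic, -w_ic, s_ic)
        _add_bumps(gz, t, right_tc, -w_tc, s_tc)
        # stance-phase counter-rotation balances each stride's net rotation
        for t0, t1 in zip(right_ic, right_tc):
            box = _smooth_box(t, t0 + 0.02, t1 - 0.02)
            i0 = np.searchsorted(t, t0)
            i1 = np.searchsorted(t, min(t0 + stride_t, dur))
            area = gz[i0:i1].sum() * dt
            denom = box[i0:i1].sum() * dt
            if denom > 1e-6:
                gz -= (area / denom) * box
    else:
        # small pitch oscillation plus impact/push-off rotation blips
        f_step = 2.0 / stride_t
        run_box = _smooth_box(t, lead, lead + run_span, edge=0.05)
        gz += 0.06 * 2 * np.pi * f_step * np.cos(
            2 * np.pi * f_step * (t - lead)
        ) * run_box
        w_b = 1.2 + 0.2 * v
        for c, a in [(ic_all, w_b), (tc_all, 0.7 * w_b)]:
            _add_bumps(gz, t, c, a, 0.010)
            _add_bumps(gz, t, np.asarray(c) + 0.030, -a, 0.010)  # rotate back

    pitch = np.cumsum(gz) * dt
    grav = np.vstack([np.sin(pitch), np.cos(pitch), np.zeros(n)])

    # --- specific-force features (sensor frame, g) --------------------------
    feat = np.zeros((3, n))
    run_phase = _smooth_box(t, lead, lead + run_span, edge=0.05)
    if cfg.placement == "shank":
        a_ic = (2.0 + 1.9 * v) * (1.0 + 0.3 * fsa) * surface_f
        s_imp = max(0.006, 0.014 - 0.008 * np.clip(fsa, -0.25, 0.75))
        a_tc = 1.2 + 0.3 * v
        _add_bumps(feat[1], t, right_ic, a_ic, s_imp)  # axial impact
        _add_bumps(feat[1], t, right_tc, a_tc, 0.020)  # push-off
        _add_bumps(feat[0], t, right_ic, -(1.0 + 0.25 * v), 0.015)  # braking
        _add_bumps(feat[0], t, right_tc, 0.6 + 0.15 * v, 0.020)  # propulsion
        _add_bumps(feat[2], t, right_ic, 0.5 + 0.10 * v, 0.010)  # ML impact
        feat[1] += 0.3 * np.sin(2 * np.pi / stride_t * (t - lead)) * run_phase
    else:
        a_v = (1.5 + 0.35 * v) * surface_f
        _add_bumps(feat[1], t, ic_all, a_v, 0.025)  # vertical impact
        _add_bumps(feat[1], t, tc_all, -(0.8 + 0.10 * v), 0.020)  # unloading
        _add_bumps(feat[0], t, ic_all, 0.5 + 0.10 * v, 0.020)  # AP braking peak
        _add_bumps(feat[0], t, tc_all, -(0.4 + 0.08 * v), 0.020)
        ml_amp = (0.3 + 0.05 * v) * np.array(
            [1.0 if s == "right" else -1.0 for s in sides]
        )
        _add_bumps(feat[2], t, ic_all, ml_amp, 0.030)  # side-encoded ML
        feat[1] += 0.25 * np.sin(4 * np.pi / stride_t * (t - lead)) * run_phase

    # --- noise (running portion only; the quiet lead-in is still) -----------
    noise_a = rng.normal(0.0, cfg.noise_sd * surface_f, size=(3, n))
    noise_g = rng.normal(0.0, cfg.noise_sd, size=(3, n))
    quiet_mask = t >= lead - 0.1
    noise_a *= quiet_mask
    noise_g *= quiet_mask

    accel_full = grav + feat + noise_a
    gyro = np.vstack([np.zeros(n), np.zeros(n), gz]) + noise_g

    clipped = int(np.any(np.abs(accel_full) > SAT_G, axis=0).sum())
    accel_primary = np.clip(accel_full, -PRIMARY_RANGE_G, PRIMARY_RANGE_G)
    accel_secondary = accel_full + rng.normal(0.0, cfg.noise_sd, size=(3, n)) * (
        quiet_mask
    )

    rec = IMURecording(
        time=t,
        accel=accel_primary,
        gyro=gyro,
        rate_hz=rate,
        frame="WCS",
        placement=cfg.placement,
        accel_secondary=accel_secondary,
        meta={"sim_config": vars(cfg).copy()},
    )

    # --- vertical force: 10 N exactly at each IC/TC sample ------------------
    force = np.zeros(n)
    fmax = 1750.0 * (1.0 + 0.05 * (v - 3.5))
    for t0, t1 in zip(ic_all, tc_all):
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        s = np.clip((t[i0 : i1 + 1] - t0) / (t1 - t0), 0.0, 1.0)
        force[i0 : i1 + 1] = np.maximum(
            force[i0 : i1 + 1],
            FORCE_THRESH_N + (fmax - FORCE_THRESH_N) * np.sin(np.pi * s),
        )

    center = lead + run_span / 2
    half_gate = min(2.5 / v, run_span / 2)
    truth = SimTruth(
        ic_times=ic_all,
        tc_times=tc_all,
        sides=sides,
        vertical_force=force,
        gate_times=(center - half_gate, center + half_gate),
        specific_force=accel_full - grav,
        pitch=pitch,
        clipped_frames=clipped,
        stance_time=stance_t,
        stride_time=stride_t,
    )
    return rec, truth


def force_events(
    force: np.ndarray, rate_hz: float, thresh: float = FORCE_THRESH_N
) -> tuple[np.ndarray, np.ndarray]:
    """IC/TC times from a vertical force series via a threshold crossing.

    IC is the first sample at or above the threshold of each contiguous
    loaded interval; TC is the last.
    """
    above = force >= thresh
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(force) - 1]])
    return starts / rate_hz, ends / rate_hz


# ---------------------------------------------------------------------------
# Centrifuge-style calibration records
# ---------------------------------------------------------------------------


def simulate_centrifuge(
    model: CalibrationModel,
    orientations: int = 6,
    magnitudes: int = 16,
    max_val: float = 41.42,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(measured, known) pairs emulating a centrifuge calibration session.

    The known grid spans ``orientations`` axis-aligned unit directions
    (+/-x, +/-y, +/-z) times ``magnitudes`` evenly spaced magnitudes from 0 to
    ``max_val`` (41.42 g for the accelerometer design; use 78.54 for a
    rad/s gyro grid).  Measured data are the model's inverse image of the
    known values plus optional Gaussian noise.  Both arrays are (3, N).
    """
    rng = np.random.default_rng(seed)
    dirs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )[:orientations]
    mags = np.linspace(0.0, max_val, magnitudes)
    known = np.concatenate([np.outer(d, mags) for d in dirs], axis=1)
    measured = invert_calibration(model, known)
    if noise_sd > 0:
        measured = measured + rng.normal(0.0, noise_sd, size=measured.shape)
    return measured, known


# ---------------------------------------------------------------------------
# Linked-replicates error tables
# ---------------------------------------------------------------------------


def simulate_error_table(
    biases: dict,
    components: dict,
    n_participants: int = 100,
    n_trials: int = 10,
    covariate_effects: Optional[dict] = None,
    event_type: str = "IC",
    seed: int = 0,
) -> tuple[list[TrialRecord], dict]:
    """Draw an error table from the linked-replicates generative model.

    Every (method, participant, trial) error is::

        y = a_method + b_participant + c_participant_trial
            + d_method_participant + e_method_participant_trial
            [+ surface_shift * is_floor + speed_slope * speed
             + footstrike_slope * angle]

    with independent zero-mean normal components whose SDs come from
    ``components`` (keys ``sigma_b``, ``sigma_c``, ``sigma_d``, ``sigma_e``,
    ms).  All methods share the same b and c draws for a given participant and
    trial: that shared structure is what makes the replicates *linked*.

    ``covariate_effects`` optionally holds ``surface`` (ms shift on the floor
    condition), ``speed`` (ms per m/s) and ``footstrike`` (ms per rad) fixed
    effects applied identically to every method.

    Returns (records, truth) where truth echoes the generating parameters and
    the drawn covariates for recovery tests.
    """
    for k, vv in components.items():
        if vv < 0:
            raise ValueError(f"negative component {k}")
    rng = np.random.default_rng(seed)
    methods = list(biases)
    sb = components.get("sigma_b", 0.0)
    sc = components.get("sigma_c", 0.0)
    sd = components.get("sigma_d", 0.0)
    se = components.get("sigma_e", 0.0)
    eff = covariate_effects or {}
    records: list[TrialRecord] = []
    for p in range(n_participants):
        b = rng.normal(0.0, sb)
        d = {m: rng.normal(0.0, sd) for m in methods}
        for tr in range(n_trials):
            c = rng.normal(0.0, sc)
            speed = rng.uniform(2.5, 7.5)
            angle = rng.uniform(-0.25, 0.75)
            surface = "floor" if tr % 2 else "track"
            shift = (
                eff.get("surface", 0.0) * (surface == "floor")
                + eff.get("speed", 0.0) * speed
                + eff.get("footstrike", 0.0) * angle
            )
            for m in methods:
                y = biases[m] + b + c + d[m] + rng.normal(0.0, se) + shift
                records.append(
                    TrialRecord(
                        method_id=m,
                        participant_id=f"P{p:03d}",
                        trial_id=f"T{tr:03d}",
                        event_type=event_type,
                        error_ms=float(y),
                        surface=surface,
                        speed=float(speed),
                        footstrike_angle=float(angle),
                    )
                )
    truth = {
        "biases": dict(biases),
        "components": {"sigma_b": sb, "sigma_c": sc, "sigma_d": sd, "sigma_e": se},
        "covariate_effects": dict(eff),
    }
    return records, truth


def standard_fixture_suite(
    seeds: range | list = range(5), noise_sd: float = 0.02
) -> list[tuple[SimTrialConfig, IMURecording, SimTruth]]:
    """The standard test-bed: 3 speeds x 3 foot-strike classes x 2 placements.

    Trials are generated lazily by the caller's loop in tests; this helper
    returns the full list of (config, recording, truth) triples.
    """
    out = []
    for placement in ("shank", "sacrum"):
        for speed in (3.0, 4.5, 6.5):
            for fsa in (-0.15, 0.05, 0.45):
                for seed in seeds:
                    cfg = SimTrialConfig(
                        placement=placement,
                        speed=speed,
                        footstrike_angle=fsa,
                        noise_sd=noise_sd,
                        seed=seed,
                    )
                    rec, truth = simulate_trial(cfg)
                    out.append((cfg, rec, truth))
    return out
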