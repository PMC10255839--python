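"""Registry and implementations of single-wearable gait-event detectors.

Twenty-one methods (eighteen published approaches plus three modified
variants) are exposed through one registry keyed by ``method_id``.  Each
entry declares the wearable placement it expects, the signals it consumes,
its native sampling rate (window lengths and thresholds in the source
methods are tied to those rates, so the dispatcher resamples the input), the
events it can provide, and its tunable parameters.

The heuristic methods are landmark detectors: an impact transient in shank
axial acceleration at initial contact (IC), a push-off feature before
terminal contact (TC), a mid-swing peak with IC/TC troughs in the sagittal
shank angular velocity, per-step vertical-acceleration peaks at the sacrum
with a side-encoded medial-lateral component, and so on.  Per-method
constants are transcribed into the registry as named, overridable parameters.
The Bach method is an Echo State Network and ships untrained; a training
routine fitting its ridge readout on simulated trials is provided.

All detectors are deterministic: the same input and parameters give
bit-identical event indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import signal as sps

from .core import GaitEventSet, IMURecording

__all__ = [
    "MethodSpec",
    "DetectionResult",
    "MatchResult",
    "REGISTRY",
    "list_methods",
    "detect",
    "detect_purcell",
    "detect_fadillioglu",
    "detect_auvinet",
    "detect_lee_side",
    "enforce_alternation",
    "match_events",
    "EchoStateNetwork",
    "train_bach",
]


# ---------------------------------------------------------------------------
# Registry plumbing
# ---------------------------------------------------------------------------


@dataclass
class MethodSpec:
    """Declarative description of one detection method."""

    method_id: str
    placement: str  # "shank" | "sacrum"
    input_signals: tuple  # subset of ax/ay/az/a_resultant/gx/gy/gz
    native_rate_hz: float
    events_provided: tuple  # subset of ("IC", "TC", "side")
    source_citation: str
    parameters: dict = field(default_factory=dict)
    frame: str = "WCS"  # frame the method was defined in
    needs_gyro: bool = False
    fn: Optional[Callable] = None


@dataclass
class DetectionResult:
    events: GaitEventSet
    method_id: str
    diagnostics: dict = field(default_factory=dict)


REGISTRY: dict[str, MethodSpec] = {}


def _register(spec: MethodSpec):
    REGISTRY[spec.method_id] = spec
    return spec


def list_methods(placement: str | None = None) -> list[str]:
    return [
        m
        for m, s in REGISTRY.items()
        if placement is None or s.placement == placement
    ]


def _resample(rec: IMURecording, rate: float) -> tuple[np.ndarray, dict]:
    """Resample onto the method's native grid (anti-aliased for downsampling).

    Downsampling first applies a zero-phase low-pass at 0.4x the target rate
    so that wideband sensor noise does not alias into the native band, then
    interpolates linearly onto the native grid."""
    if abs(rate - rec.rate_hz) < 1e-9:
        return rec.time, {"accel": rec.accel, "gyro": rec.gyro}
    accel, gyro = rec.accel, rec.gyro
    if rate < rec.rate_hz:
        sos = sps.butter(4, 0.4 * rate, fs=rec.rate_hz, output="sos")
        accel = sps.sosfiltfilt(sos, accel, axis=1)
        gyro = sps.sosfiltfilt(sos, gyro, axis=1)
    n = int(np.floor((rec.time[-1] - rec.time[0]) * rate)) + 1
    t = rec.time[0] + np.arange(n) / rate
    sig = {
        "accel": np.vstack([np.interp(t, rec.time, accel[i]) for i in range(3)]),
        "gyro": np.vstack([np.interp(t, rec.time, gyro[i]) for i in range(3)]),
    }
    return t, sig


def _peak_height(x: np.ndarray, frac: float) -> float:
    """Threshold between the signal's median level and its maximum."""
    med = float(np.median(x))
    return med + frac * (float(x.max()) - med)


def _peaks(x: np.ndarray, height: float, min_dist: int) -> np.ndarray:
    """Peaks above ``height``, pruned greedily in *time* order.

    Unlike height-ordered pruning, time-ordered pruning is stable under a
    time shift of the whole input: near-tied peak heights cannot flip the
    selection."""
    idx, _ = sps.find_peaks(x, height=height)
    kept: list[int] = []
    for i in idx:
        if not kept or i - kept[-1] >= min_dist:
            kept.append(int(i))
    return np.asarray(kept, dtype=int)


def _window_extremum(x, t, t_start, t_end, mode="max"):
    i0 = int(np.searchsorted(t, t_start))
    i1 = int(np.searchsorted(t, t_end))
    if i1 - i0 < 1:
        return None
    seg = x[i0:i1]
    j = int(np.argmax(seg) if mode == "max" else np.argmin(seg))
    return i0 + j


def _side_from_ml(ml: np.ndarray, t: np.ndarray, ic_times, min_abs: float = 0.05):
    """left/right per IC from the sign of the medial-lateral acceleration.

    +z is right: a positive ML impact means the right foot.  Values below
    ``min_abs`` (g) are labeled unknown.
    """
    sides = []
    for et in ic_times:
        i = min(len(t) - 1, max(0, int(np.searchsorted(t, et))))
        lo, hi = max(0, i - 2), min(len(t), i + 3)
        val = float(np.mean(ml[lo:hi]))
        if val > min_abs:
            sides.append("right")
        elif val < -min_abs:
            sides.append("left")
        else:
            sides.append("unknown")
    return sides


# ---------------------------------------------------------------------------
# Shank accelerometer methods
# ---------------------------------------------------------------------------


def _impact_peaks(x, t, rate, p):
    """Stride-spaced impact peaks above a relative (or absolute) height."""
    if np.ptp(x) < 1e-12:
        return np.array([], dtype=int)
    height = p.get("abs_height_g") or _peak_height(x, p.get("height_frac", 0.5))
    return _peaks(x, height, max(1, int(p.get("min_period_s", 0.45) * rate)))


def _axial_ic_tc(t, sig, rate, p, want_tc, use_resultant=False):
    """Shared logic: IC at the axial/resultant impact peak, TC at the
    push-off maximum inside a post-IC stance window."""
    x = np.linalg.norm(sig["accel"], axis=0) if use_resultant else sig["accel"][1]
    idx = _impact_peaks(x, t, rate, p)
    ic = t[idx]
    tc = []
    if want_tc:
        for ti in ic:
            j = _window_extremum(
                x, t, ti + p.get("tc_win_start_s", 0.06), ti + p.get("tc_win_end_s", 0.40)
            )
            if j is not None:
                tc.append(t[j])
    return ic, np.asarray(tc), {"n_peaks": len(idx)}


def _fn_mizrahi(t, sig, rate, p):
    ic, _, d = _axial_ic_tc(t, sig, rate, p, want_tc=False)
    return ic, np.array([]), None, d


def _fn_mercer(t, sig, rate, p):
    ic, tc, d = _axial_ic_tc(t, sig, rate, p, want_tc=True)
    return ic, tc, None, d


def _fn_purcell(t, sig, rate, p):
    ic, tc, d = _axial_ic_tc(t, sig, rate, p, want_tc=True, use_resultant=True)
    return ic, tc, None, d


def _fn_sinclair(t, sig, rate, p):
    ic, tc, d = _axial_ic_tc(t, sig, rate, p, want_tc=True)
    return ic, tc, None, d


def _fn_whelan(t, sig, rate, p):
    x = -sig["accel"][0]  # braking spike is a negative anteroposterior peak
    idx = _impact_peaks(x, t, rate, p)
    return t[idx], np.array([]), None, {"n_peaks": len(idx)}


def _fn_norris(t, sig, rate, p):
    x = sig["accel"][2]  # medial-lateral impact transient
    idx = _impact_peaks(x, t, rate, p)
    return t[idx], np.array([]), None, {"n_peaks": len(idx)}


def _fn_aubol(t, sig, rate, p):
    x = np.linalg.norm(sig["accel"], axis=0)
    idx = _impact_peaks(x, t, rate, p)
    return t[idx], np.array([]), None, {"n_peaks": len(idx)}


def _fn_schmidt(t, sig, rate, p):
    """Sprint-calibrated: absolute impact threshold plus a gyro TC trough."""
    ic, _, d = _axial_ic_tc(t, sig, rate, p, want_tc=False)
    gz = sig["gyro"][2]
    tc = []
    for ti in ic:
        j = _window_extremum(gz, t, ti + 0.06, ti + 0.40, mode="min")
        if j is not None:
            tc.append(t[j])
    return ic, np.asarray(tc), None, d


# ---------------------------------------------------------------------------
# Shank gyroscope methods (mid-swing peak anchored)
# ---------------------------------------------------------------------------


def _swing_anchored(t, sig, rate, p):
    """IC/TC as sagittal angular-velocity minima around each mid-swing peak.

    The mid-swing forward-rotation peak anchors each stride; IC is the
    deepest trough in a window after the peak, TC the deepest trough in a
    window before it.  Window lengths are fractions of the inter-peak
    interval unless absolute window lengths are configured (the
    walking-derived variants use absolute windows sized for walking cadence,
    which is their documented failure mode at running cadence).
    """
    gz = sig["gyro"][2]
    if p.get("flip_sign", False):
        gz = -gz
    if np.ptp(gz) < 1e-12:
        return np.array([]), np.array([]), None, {"n_peaks": 0}
    smooth_hz = p.get("smooth_hz")
    if smooth_hz and smooth_hz < rate / 2:
        sos = sps.butter(2, smooth_hz, fs=rate, output="sos")
        gz = sps.sosfiltfilt(sos, gz)
    height = p.get("peak_frac", 0.5) * float(gz.max())
    if height <= 0:
        return np.array([]), np.array([]), None, {"n_peaks": 0}
    pk = _peaks(gz, height, max(1, int(p["peak_dist_s"] * rate)))
    if len(pk) == 0:
        return np.array([]), np.array([]), None, {"n_peaks": 0}
    period = float(np.median(np.diff(t[pk]))) if len(pk) > 1 else p["peak_dist_s"] * 1.3
    ic_win = p.get("ic_win_s") or p["ic_win_frac"] * period
    tc_win = p.get("tc_win_s") or p["tc_win_frac"] * period

    depth_frac = p.get("depth_frac", 0.5)

    def trough(t_start, t_end, pick_last):
        # qualifying troughs: interior local minima below zero and at least
        # depth_frac as deep as the window's deepest; the trough adjacent to
        # the swing peak (first after / last before) is the contact event.
        # Adjacency, unlike a bare argmin, is stable under a time shift.
        i0 = int(np.searchsorted(t, t_start))
        i1 = int(np.searchsorted(t, t_end))
        if i1 - i0 < 3:
            return None
        seg = gz[i0:i1]
        mins, _ = sps.find_peaks(-seg)
        mins = [j for j in mins if seg[j] < 0]
        if not mins:
            return None
        deepest = min(seg[j] for j in mins)
        qual = [j for j in mins if seg[j] <= depth_frac * deepest]
        j = qual[-1] if pick_last else qual[0]
        return t[i0 + j]

    ic, tc = [], []
    for i in pk:
        tj = trough(t[i] + 0.01, t[i] + ic_win, pick_last=False)
        if tj is not None:
            ic.append(tj)
        tj = trough(t[i] - tc_win, t[i] - 0.01, pick_last=True)
        if tj is not None:
            tc.append(tj)
    ic, tc = np.unique(ic), np.unique(tc)
    return ic, tc, None, {"n_peaks": len(pk), "period_s": period}


def _fn_fadillioglu(t, sig, rate, p):
    return _swing_anchored(t, sig, rate, p)


def _fn_greene(t, sig, rate, p):
    return _swing_anchored(t, sig, rate, p)


def _fn_aminian(t, sig, rate, p):
    return _swing_anchored(t, sig, rate, p)


# ---------------------------------------------------------------------------
# Sacrum methods
# ---------------------------------------------------------------------------


def _step_peaks(x, t, rate, p):
    if np.ptp(x) < 1e-12:
        return np.array([], dtype=int)
    return _peaks(
        x,
        _peak_height(x, p.get("height_frac", 0.5)),
        max(1, int(p.get("min_period_s", 0.22) * rate)),
    )


def _fn_auvinet(t, sig, rate, p):
    """Per-step vertical-acceleration peak (IC) and following trough (TC);
    side from the medial-lateral component's sign at IC."""
    ay = sig["accel"][1]
    idx = _step_peaks(ay, t, rate, p)
    ic = t[idx]
    tc = []
    for ti in ic:
        j = _window_extremum(ay, t, ti + 0.04, ti + 0.35, mode="min")
        if j is not None:
            tc.append(t[j])
    sides = _side_from_ml(sig["accel"][2], t, ic, p.get("side_min_abs_g", 0.05))
    return ic, np.asarray(tc), sides, {"n_peaks": len(idx)}


def _fn_lee(t, sig, rate, p):
    """Anteroposterior braking peak (IC) and trough (TC); side from ML sign."""
    ax = sig["accel"][0]
    idx = _step_peaks(ax, t, rate, p)
    ic = t[idx]
    tc = []
    for ti in ic:
        j = _window_extremum(ax, t, ti + 0.04, ti + 0.35, mode="min")
        if j is not None:
            tc.append(t[j])
    sides = _side_from_ml(sig["accel"][2], t, ic, p.get("side_min_abs_g", 0.05))
    return ic, np.asarray(tc), sides, {"n_peaks": len(idx)}


def _fn_wixted(t, sig, rate, p):
    ay, ax = sig["accel"][1], sig["accel"][0]
    idx = _step_peaks(ay, t, rate, p)
    ic = t[idx]
    tc = []
    for ti in ic:
        j = _window_extremum(ax, t, ti + 0.04, ti + 0.35, mode="min")
        if j is not None:
            tc.append(t[j])
    return ic, np.asarray(tc), None, {"n_peaks": len(idx)}


def _fn_bergamini(t, sig, rate, p):
    """Sharp rotation blips in high-passed sacral angular velocity; the
    larger blip of each step is IC, smaller following blips are TC."""
    gz = sig["gyro"][2]
    if np.ptp(gz) < 1e-12:
        return np.array([]), np.array([]), None, {"n_peaks": 0}
    sos = sps.butter(2, p.get("highpass_hz", 5.0), "highpass", fs=rate, output="sos")
    h = sps.sosfiltfilt(sos, gz)
    mx = float(h.max())
    if mx <= 0:
        return np.array([]), np.array([]), None, {"n_peaks": 0}
    pk = _peaks(h, p.get("peak_frac", 0.3) * mx, max(1, int(0.08 * rate)))
    big = h[pk] >= p.get("ic_frac", 0.65) * mx
    return t[pk[big]], t[pk[~big]], None, {"n_peaks": len(pk)}


def _fn_benson(t, sig, rate, p):
    res = np.linalg.norm(sig["accel"], axis=0)
    idx = _step_peaks(res, t, rate, p)
    ic = t[idx]
    ay = sig["accel"][1]
    tc = []
    for ti in ic:
        j = _window_extremum(ay, t, ti + 0.04, ti + 0.35, mode="min")
        if j is not None:
            tc.append(t[j])
    # raw single-sample side decision (no smoothing window): cheaper, noisier
    az = sig["accel"][2]
    sides = []
    for ti in ic:
        i = min(len(t) - 1, int(np.searchsorted(t, ti)))
        v = float(az[i])
        m = p.get("side_min_abs_g", 0.05)
        sides.append("right" if v > m else "left" if v < -m else "unknown")
    return ic, np.asarray(tc), sides, {"n_peaks": len(idx)}


def _fn_reenalda(t, sig, rate, p):
    """Vertical (gravity-aligned) acceleration peaks.

    The vertical direction is a slow gravity estimate (0.5 Hz low-pass of the
    acceleration); the specific force is projected onto it and the per-step
    impact peaks give IC.
    """
    a = sig["accel"]
    sos = sps.butter(2, p.get("gravity_lp_hz", 0.5), fs=rate, output="sos")
    g_est = sps.sosfiltfilt(sos, a, axis=1)
    g_norm = np.linalg.norm(g_est, axis=0)
    g_norm[g_norm < 1e-9] = 1.0
    vert = np.sum(a * (g_est / g_norm), axis=0) - g_norm
    idx = _step_peaks(vert, t, rate, p)
    return t[idx], np.array([]), None, {"n_peaks": len(idx)}


# ---------------------------------------------------------------------------
# Echo State Network (Bach)
# ---------------------------------------------------------------------------


class EchoStateNetwork:
    """Leaky reservoir with a ridge readout mapping tri-axial acceleration to
    IC/TC likelihood traces.

    The reservoir (fixed by ``seed``) is never trained; only the linear
    readout is fitted.  ``fit`` takes lists of input and target sequences;
    targets are Gaussian bumps centered on true event times.
    """

    def __init__(
        self,
        n_reservoir: int = 100,
        spectral_radius: float = 0.9,
        leak: float = 0.3,
        input_scaling: float = 0.5,
        ridge: float = 1e-4,
        seed: int = 12345,
    ):
        self.n_reservoir = n_reservoir
        self.leak = leak
        self.ridge = ridge
        rng = np.random.default_rng(seed)
        W = rng.uniform(-1, 1, size=(n_reservoir, n_reservoir))
        W[rng.uniform(size=W.shape) > 0.1] = 0.0  # sparse
        eig = np.max(np.abs(np.linalg.eigvals(W)))
        self.W = W * (spectral_radius / eig if eig > 0 else 1.0)
        self.Win = rng.uniform(-1, 1, size=(n_reservoir, 4)) * input_scaling
        self.Wout: Optional[np.ndarray] = None

    def _states(self, U: np.ndarray) -> np.ndarray:
        """U is (T, 3) normalized input; returns (T, n_reservoir + 4)."""
        T = U.shape[0]
        X = np.zeros((T, self.n_reservoir))
        x = np.zeros(self.n_reservoir)
        for i in range(T):
            u = np.concatenate([[1.0], U[i]])
            x = (1 - self.leak) * x + self.leak * np.tanh(
                self.W @ x + self.Win @ u
            )
            X[i] = x
        return np.hstack([X, np.ones((T, 1)), U])

    def fit(self, inputs: list[np.ndarray], targets: list[np.ndarray]) -> None:
        X = np.vstack([self._states(U) for U in inputs])
        Y = np.vstack(targets)
        A = X.T @ X + self.ridge * np.eye(X.shape[1])
        self.Wout = np.linalg.solve(A, X.T @ Y).T

    def predict(self, U: np.ndarray) -> np.ndarray:
        if self.Wout is None:
            raise RuntimeError("readout not fitted")
        return self._states(U) @ self.Wout.T


def _normalize_input(accel: np.ndarray) -> np.ndarray:
    U = accel.T.copy()
    U -= U.mean(axis=0)
    sdv = U.std(axis=0)
    sdv[sdv < 1e-9] = 1.0
    return U / sdv


def train_bach(
    trials: list,
    rate_hz: float = 142.9,
    target_sigma_s: float = 0.030,
    esn: EchoStateNetwork | None = None,
) -> EchoStateNetwork:
    """Fit the Echo State Network readout on (recording, truth) pairs.

    ``trials`` is a list of (IMURecording, SimTruth-like) tuples; truth must
    expose ``ic_times`` and ``tc_times``.  Inputs are resampled to the
    method's native rate and z-scored per trial; targets are unit Gaussian
    bumps (width ``target_sigma_s``) at the true event times.
    """
    esn = esn or EchoStateNetwork()
    inputs, targets = [], []
    for rec, truth in trials:
        t, sig = _resample(rec, rate_hz)
        U = _normalize_input(sig["accel"])
        Y = np.zeros((len(t), 2))
        for col, times in ((0, truth.ic_times), (1, truth.tc_times)):
            for et in np.atleast_1d(times):
                Y[:, col] += np.exp(-0.5 * ((t - et) / target_sigma_s) ** 2)
        inputs.append(U)
        targets.append(Y)
    esn.fit(inputs, targets)
    return esn


def _fn_bach(t, sig, rate, p):
    model: EchoStateNetwork | None = p.get("model")
    if model is None or model.Wout is None:
        return np.array([]), np.array([]), None, {"untrained": True}
    Y = model.predict(_normalize_input(sig["accel"]))
    thresh = p.get("threshold", 0.5)
    dist = max(1, int(p.get("min_period_s", 0.22) * rate))
    ic_idx = _peaks(Y[:, 0], thresh, dist)
    tc_idx = _peaks(Y[:, 1], thresh, dist)
    return t[ic_idx], t[tc_idx], None, {"max_score": float(Y.max(initial=0.0))}


# ---------------------------------------------------------------------------
# Registry entries (native rates and signals per the methods' source papers)
# ---------------------------------------------------------------------------

_register(MethodSpec("mizrahi", "shank", ("ay",), 1667.0, ("IC",),
                     "Mizrahi et al., shank axial acceleration peaks",
                     {"height_frac": 0.5, "min_period_s": 0.45}, fn=_fn_mizrahi))
_register(MethodSpec("mercer", "shank", ("ay",), 1000.0, ("IC", "TC"),
                     "Mercer et al., axial impact peak + push-off maximum",
                     {"height_frac": 0.5, "min_period_s": 0.45,
                      "tc_win_start_s": 0.06, "tc_win_end_s": 0.40}, fn=_fn_mercer))
_register(MethodSpec("purcell", "shank", ("ax", "ay", "az"), 250.0, ("IC", "TC"),
                     "Purcell et al., resultant-acceleration impact landmark",
                     {"height_frac": 0.5, "min_period_s": 0.45,
                      "tc_win_start_s": 0.06, "tc_win_end_s": 0.40}, fn=_fn_purcell))
_register(MethodSpec("greene_mcgrath", "shank", ("gz",), 102.4, ("IC", "TC"),
                     "Greene/McGrath, walking-derived sagittal gyro windows",
                     {"peak_frac": 0.6, "peak_dist_s": 0.8,
                      "ic_win_s": 0.55, "tc_win_s": 0.45}, needs_gyro=True,
                     fn=_fn_greene))
_register(MethodSpec("greene_mcgrath_modified", "shank", ("gz",), 102.4,
                     ("IC", "TC"),
                     "Greene/McGrath with stride windows rescaled for running",
                     {"peak_frac": 0.5, "peak_dist_s": 0.45,
                      "ic_win_frac": 0.40, "tc_win_frac": 0.35},
                     needs_gyro=True, fn=_fn_greene))
_register(MethodSpec("aminian_odonovan", "shank", ("gz",), 102.4, ("IC", "TC"),
                     "Aminian/O'Donovan, walking-cadence gyro search windows",
                     {"peak_frac": 0.6, "peak_dist_s": 1.0,
                      "ic_win_s": 0.60, "tc_win_s": 0.50},
                     frame="SCS", needs_gyro=True, fn=_fn_aminian))
_register(MethodSpec("aminian_odonovan_modified", "shank", ("gz",), 102.4,
                     ("IC", "TC"),
                     "Aminian/O'Donovan with running-cadence windows",
                     {"peak_frac": 0.5, "peak_dist_s": 0.45,
                      "ic_win_frac": 0.40, "tc_win_frac": 0.35},
                     frame="SCS", needs_gyro=True, fn=_fn_aminian))
_register(MethodSpec("sinclair", "shank", ("ay",), 1000.0, ("IC", "TC"),
                     "Sinclair et al., axial impact peak + push-off window",
                     {"height_frac": 0.45, "min_period_s": 0.45,
                      "tc_win_start_s": 0.08, "tc_win_end_s": 0.38},
                     fn=_fn_sinclair))
_register(MethodSpec("whelan", "shank", ("ax",), 148.2, ("IC",),
                     "Whelan et al., anteroposterior braking trough",
                     {"height_frac": 0.5, "min_period_s": 0.45}, fn=_fn_whelan))
_register(MethodSpec("norris", "shank", ("az",), 204.8, ("IC",),
                     "Norris et al., medial-lateral impact transient",
                     {"height_frac": 0.5, "min_period_s": 0.45}, fn=_fn_norris))
_register(MethodSpec("schmidt", "shank", ("ay", "gz"), 1000.0, ("IC", "TC"),
                     "Schmidt et al., sprint-scale absolute impact threshold",
                     {"abs_height_g": 8.0, "min_period_s": 0.40},
                     needs_gyro=True, fn=_fn_schmidt))
_register(MethodSpec("aubol", "shank", ("ax", "ay", "az"), 1000.0, ("IC",),
                     "Aubol et al., resultant-acceleration impact peak",
                     {"height_frac": 0.5, "min_period_s": 0.45}, fn=_fn_aubol))
_register(MethodSpec("fadillioglu", "shank", ("gz",), 1500.0, ("IC", "TC"),
                     "Fadillioglu et al., mid-swing-anchored gyro extrema",
                     {"peak_frac": 0.5, "peak_dist_s": 0.45,
                      "ic_win_frac": 0.40, "tc_win_frac": 0.35},
                     needs_gyro=True, fn=_fn_fadillioglu))
_register(MethodSpec("bach", "shank", ("ax", "ay", "az"), 142.9, ("IC", "TC"),
                     "Bach et al., Echo State Network (ships untrained)",
                     {"model": None, "threshold": 0.5, "min_period_s": 0.22},
                     fn=_fn_bach))
_register(MethodSpec("bach_modified", "shank", ("ax", "ay", "az"), 142.9,
                     ("IC", "TC"),
                     "Bach ESN with a lower decision threshold",
                     {"model": None, "threshold": 0.3, "min_period_s": 0.22},
                     fn=_fn_bach))
_register(MethodSpec("auvinet", "sacrum", ("ax", "ay", "az"), 100.0,
                     ("IC", "TC", "side"),
                     "Auvinet et al., vertical peak/trough per step + ML side",
                     {"height_frac": 0.5, "min_period_s": 0.22,
                      "side_min_abs_g": 0.05}, fn=_fn_auvinet))
_register(MethodSpec("lee", "sacrum", ("ax", "az"), 100.0, ("IC", "TC", "side"),
                     "Lee et al., anteroposterior peak + ML-sign side rule",
                     {"height_frac": 0.4, "min_period_s": 0.22,
                      "side_min_abs_g": 0.05}, fn=_fn_lee))
_register(MethodSpec("wixted", "sacrum", ("ax", "ay"), 500.0, ("IC", "TC"),
                     "Wixted et al., vertical peak IC + anteroposterior TC",
                     {"height_frac": 0.5, "min_period_s": 0.22}, fn=_fn_wixted))
_register(MethodSpec("bergamini", "sacrum", ("gx", "gy", "gz"), 200.0,
                     ("IC", "TC"),
                     "Bergamini et al., high-passed angular-velocity blips",
                     {"highpass_hz": 5.0, "peak_frac": 0.3, "ic_frac": 0.65},
                     needs_gyro=True, fn=_fn_bergamini))
_register(MethodSpec("benson", "sacrum", ("ax", "ay", "az"), 201.0,
                     ("IC", "TC", "side"),
                     "Benson et al., resultant peaks + raw-sample ML side",
                     {"height_frac": 0.5, "min_period_s": 0.22,
                      "side_min_abs_g": 0.05}, fn=_fn_benson))
_register(MethodSpec("reenalda", "sacrum", ("ay",), 1000.0, ("IC",),
                     "Reenalda et al., gravity-aligned vertical accel peaks",
                     {"height_frac": 0.5, "min_period_s": 0.22,
                      "gravity_lp_hz": 0.5}, frame="TILT", fn=_fn_reenalda))


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def detect(
    method_id: str,
    rec: IMURecording,
    params: dict | None = None,
    scs_rotation: np.ndarray | None = None,
) -> DetectionResult:
    """Run one registry method on a recording.

    The input is resampled to the method's native rate; events are returned
    in the recording's own clock.  A method that finds no events returns a
    result whose event set has ``failed=True`` (never an exception for
    degenerate signals).

    ``scs_rotation`` is applied first for methods declared against the
    segment frame when the record is still in the wearable frame; without
    it the frames are assumed aligned.
    """
    if method_id not in REGISTRY:
        raise KeyError(f"unknown method {method_id!r}; see list_methods()")
    spec = REGISTRY[method_id]
    if rec.placement != spec.placement:
        raise ValueError(
            f"{method_id} expects a {spec.placement} record, got {rec.placement}"
        )
    if spec.needs_gyro and not rec.meta.get("has_gyro", True):
        raise ValueError(f"{method_id} requires gyroscope data")
    if spec.frame == "SCS" and rec.frame == "WCS" and scs_rotation is not None:
        from .preprocess import apply_rotation

        rec = apply_rotation(rec, scs_rotation)
    p = dict(spec.parameters)
    if params:
        p.update(params)
    t, sig = _resample(rec, spec.native_rate_hz)
    ic, tc, sides, diag = spec.fn(t, sig, spec.native_rate_hz, p)
    ic = np.unique(np.asarray(ic, dtype=float))
    tc = np.unique(np.asarray(tc, dtype=float))
    lo, hi = rec.time[0], rec.time[-1]
    ic = ic[(ic >= lo) & (ic <= hi)]
    tc = tc[(tc >= lo) & (tc <= hi)]
    if sides is not None and len(sides) != len(ic):
        sides = None  # side labels stale after range clipping
    events = GaitEventSet(ic_times=ic, tc_times=tc, sides=sides)
    return DetectionResult(events=events, method_id=method_id, diagnostics=diag or {})


def detect_purcell(rec: IMURecording, params: dict | None = None) -> DetectionResult:
    return detect("purcell", rec, params)


def detect_fadillioglu(rec: IMURecording, params: dict | None = None) -> DetectionResult:
    return detect("fadillioglu", rec, params)


def detect_auvinet(rec: IMURecording, params: dict | None = None) -> DetectionResult:
    return detect("auvinet", rec, params)


def detect_lee_side(
    rec: IMURecording, events: GaitEventSet, min_abs_g: float = 0.05
) -> list[str]:
    """Side label per IC from the sacral medial-lateral acceleration sign.

    Raw per-event decisions; alternation is NOT enforced here (see
    ``enforce_alternation``).  Empty event sets give an empty list.
    """
    if events.n_ic == 0:
        return []
    spec = REGISTRY["lee"]
    t, sig = _resample(rec, spec.native_rate_hz)
    return _side_from_ml(sig["accel"][2], t, events.ic_times, min_abs_g)


def enforce_alternation(sides: list[str]) -> list[str]:
    """Snap side labels to a strict left/right alternation.

    Both phase assignments (starting left or starting right) are scored
    against the labeled entries; the majority wins.  A tie keeps the phase of
    the first labeled event.
    """
    n = len(sides)
    if n == 0:
        return []
    phases = []
    for start in ("left", "right"):
        other = "right" if start == "left" else "left"
        phases.append([start if i % 2 == 0 else other for i in range(n)])
    scores = [
        sum(1 for a, b in zip(ph, sides) if b in ("left", "right") and a == b)
        for ph in phases
    ]
    if scores[0] > scores[1]:
        return phases[0]
    if scores[1] > scores[0]:
        return phases[1]
    for i, s in enumerate(sides):  # tie-break: first labeled event keeps its label
        if s in ("left", "right"):
            return phases[0] if phases[0][i] == s else phases[1]
    return phases[0]


# ---------------------------------------------------------------------------
# Matching detected events to ground truth
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    """Greedy nearest-neighbour pairing of detected and truth events."""

    ic_errors_ms: np.ndarray  # detected minus truth, matched IC pairs
    tc_errors_ms: np.ndarray
    unmatched_truth_ic: int
    unmatched_truth_tc: int
    extra_detected_ic: int
    extra_detected_tc: int


def _greedy_match(det: np.ndarray, tru: np.ndarray, tol_s: float):
    pairs = []
    if len(det) and len(tru):
        d = np.abs(det[:, None] - tru[None, :])
        cand = np.argwhere(d <= tol_s)
        order = np.argsort(d[cand[:, 0], cand[:, 1]], kind="stable")
        used_d, used_t = set(), set()
        for k in order:
            i, j = cand[k]
            if i not in used_d and j not in used_t:
                used_d.add(int(i))
                used_t.add(int(j))
                pairs.append((int(i), int(j)))
    errors = np.array([det[i] - tru[j] for i, j in pairs]) * 1000.0
    return errors, len(tru) - len(pairs), len(det) - len(pairs)


def match_events(
    detected: GaitEventSet, truth: GaitEventSet, tol_ms: float = 250.0
) -> MatchResult:
    """Pair detected events to ground truth within a +/- tolerance.

    Pairs are assigned greedily in ascending order of |time difference|;
    each truth event is used at most once.  Truth events with no detection
    inside the tolerance count toward failure statistics; surplus detections
    are reported separately.
    """
    tol = tol_ms / 1000.0
    ic_err, um_ic, ex_ic = _greedy_match(detected.ic_times, truth.ic_times, tol)
    tc_err, um_tc, ex_tc = _greedy_match(detected.tc_times, truth.tc_times, tol)
    return MatchResult(
        ic_errors_ms=ic_err,
        tc_errors_ms=tc_err,
        unmatched_truth_ic=um_ic,
        unmatched_truth_tc=um_tc,
        extra_detected_ic=ex_ic,
        extra_detected_tc=ex_tc,
    )
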