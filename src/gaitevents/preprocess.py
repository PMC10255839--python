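"""Signal-conditioning chain for wearable running data.

Order of operations for a raw trial: quiet-period detection -> bias removal ->
saturation replacement -> low-pass filtering -> orientation estimation with
gravity removal -> segment-coordinate-system construction -> synchronization
and speed-gate segmentation.

All operations return new records; the input is never mutated.  Frame tags
change only where documented (``build_scs`` / ``apply_rotation``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import G_MS2, IMURecording


@dataclass(frozen=True)
class QuietPeriod:
    """A still interval used for bias estimation and orientation init."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def find_quiet_periods(
    rec: IMURecording,
    gyro_thresh: float = 0.5,
    jerk_thresh: float = 0.01,
    min_dur: float = 0.100,
    jerk_prefilter_hz: float | None = 5.0,
) -> list[QuietPeriod]:
    """Maximal still intervals: gyro magnitude and jerk both below threshold.

    Jerk is the first difference of (optionally 5 Hz low-pass pre-filtered)
    acceleration converted to m/s^2, divided by the sample period -> m/s^3.
    The default jerk threshold is strict, so the pre-filter matters: raw
    differentiation at 1000 Hz amplifies noise far beyond it.

    Returns periods of at least ``min_dur`` seconds (possibly none).
    """
    if rec.n < 2:
        raise ValueError("need at least 2 frames to estimate jerk")
    gyro_mag = np.linalg.norm(rec.gyro, axis=0)
    accel = rec.accel * G_MS2
    if jerk_prefilter_hz is not None and jerk_prefilter_hz < rec.rate_hz / 2:
        sos = sps.butter(2, jerk_prefilter_hz, fs=rec.rate_hz, output="sos")
        accel = sps.sosfiltfilt(sos, accel, axis=1)
    jerk = np.linalg.norm(np.diff(accel, axis=1), axis=0) * rec.rate_hz
    jerk = np.concatenate([jerk[:1], jerk])  # align to frames
    ok = (gyro_mag < gyro_thresh) & (jerk < jerk_thresh)
    out: list[QuietPeriod] = []
    n = rec.n
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            start, end = rec.time[i], rec.time[j]
            if end - start >= min_dur:
                out.append(QuietPeriod(float(start), float(end)))
            i = j + 1
        else:
            i += 1
    return out


def _quiet_slice(rec: IMURecording, quiet: QuietPeriod) -> slice:
    if quiet.start < rec.time[0] - 1e-9 or quiet.end > rec.time[-1] + 1e-9:
        raise ValueError("quiet period lies outside the record")
    i0 = int(np.searchsorted(rec.time, quiet.start - 1e-9))
    i1 = int(np.searchsorted(rec.time, quiet.end + 1e-9))
    return slice(i0, max(i1, i0 + 1))


def remove_bias(rec: IMURecording, quiet: QuietPeriod) -> IMURecording:
    """Subtract quiet-period sensor biases.

    Gyroscope: the mean over the quiet period (a still sensor should read 0).
    Accelerometer: a still sensor should read exactly 1 g along the gravity
    direction; the deviation of the quiet-period mean from a unit vector along
    its own direction is removed from every frame.
    """
    sl = _quiet_slice(rec, quiet)
    gyro_bias = rec.gyro[:, sl].mean(axis=1)
    a_mean = rec.accel[:, sl].mean(axis=1)
    norm = np.linalg.norm(a_mean)
    if norm < 1e-6:
        raise ValueError("quiet-period acceleration is ~0; cannot infer gravity")
    accel_bias = a_mean - a_mean / norm  # g units
    out = rec.copy_with(
        gyro=rec.gyro - gyro_bias[:, None], accel=rec.accel - accel_bias[:, None]
    )
    out.meta["bias_removed"] = {
        "gyro": gyro_bias.tolist(),
        "accel": accel_bias.tolist(),
    }
    return out


def replace_saturated(
    rec: IMURecording, sat_g: float = 15.5
) -> tuple[IMURecording, int]:
    """Swap frames saturating the primary accelerometer for wide-range frames.

    Any frame with a component beyond ``sat_g`` in magnitude is replaced whole
    by the secondary (wide-range) accelerometer frame.  Returns the new record
    and the number of frames replaced.
    """
    sat = np.any(np.abs(rec.accel) > sat_g, axis=0)
    count = int(sat.sum())
    if count == 0:
        return rec.copy_with(), 0
    if rec.accel_secondary is None:
        raise ValueError(
            f"{count} saturated frames but no secondary accelerometer channel"
        )
    accel = rec.accel.copy()
    accel[:, sat] = rec.accel_secondary[:, sat]
    out = rec.copy_with(accel=accel)
    out.meta["saturated_replaced"] = count
    return out, count


def lowpass_filter(
    rec: IMURecording, cutoff_hz: float = 50.0, order: int = 4, zero_phase: bool = True
) -> IMURecording:
    """Butterworth low-pass on all accelerometer and gyroscope channels.

    Zero-phase (forward-backward) by default so event timing is unbiased;
    ``zero_phase=False`` gives the causal single-pass filter.  Note the
    two-pass magnitude response is the square of the single-pass one.
    """
    if cutoff_hz >= rec.rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {rec.rate_hz / 2} Hz"
        )
    sos = sps.butter(order, cutoff_hz, fs=rec.rate_hz, output="sos")
    run = (lambda x: sps.sosfiltfilt(sos, x, axis=1)) if zero_phase else (
        lambda x: sps.sosfilt(sos, x, axis=1)
    )
    out = rec.copy_with(
        accel=run(rec.accel),
        gyro=run(rec.gyro),
        accel_secondary=run(rec.accel_secondary)
        if rec.accel_secondary is not None
        else None,
    )
    out.meta["lowpass_hz"] = cutoff_hz
    return out


# ---------------------------------------------------------------------------
# Orientation: gradient-descent complementary filter (gyro + gravity reference)
# ---------------------------------------------------------------------------


def _quat_mult(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _gravity_sensor_frame(q: np.ndarray) -> np.ndarray:
    """Unit gravity direction in the sensor frame for quaternion q (w,x,y,z)."""
    w, x, y, z = q
    return np.array(
        [2 * (x * z - w * y), 2 * (w * x + y * z), w * w - x * x - y * y + z * z]
    )


def _quat_from_two_vectors(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Shortest-arc quaternion rotating unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c < -1 + 1e-12:
        # 180 degrees: any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return np.array([0.0, *axis])
    axis = np.cross(u, v)
    q = np.array([1.0 + c, *axis])
    return q / np.linalg.norm(q)


def madgwick_step(
    q: np.ndarray, gyro: np.ndarray, accel: np.ndarray, dt: float, beta: float
) -> np.ndarray:
    """One update of the gradient-descent orientation filter (IMU variant).

    Fuses gyro integration with the accelerometer's gravity reference; beta
    weights the gravity correction (rad/s of assumed gyro error).
    """
    qdot = 0.5 * _quat_mult(q, np.array([0.0, *gyro]))
    a_norm = np.linalg.norm(accel)
    if a_norm > 1e-9:
        a = accel / a_norm
        w, x, y, z = q
        f = _gravity_sensor_frame(q) - a
        J = np.array(
            [
                [-2 * y, 2 * z, -2 * w, 2 * x],
                [2 * x, 2 * w, 2 * z, 2 * y],
                [2 * w, -2 * x, -2 * y, 2 * z],
            ]
        )
        grad = J.T @ f
        gnorm = np.linalg.norm(grad)
        if gnorm > 1e-12:
            qdot = qdot - beta * grad / gnorm
    q = q + qdot * dt
    return q / np.linalg.norm(q)


def orient_and_degravitate(
    rec: IMURecording,
    quiet: QuietPeriod,
    filter_gain: float = 0.033,
) -> tuple[IMURecording, np.ndarray]:
    """Estimate per-frame orientation and remove gravity from accelerations.

    The orientation filter is initialized from the quiet-period gravity
    direction, run forward over the record, and the world gravity vector is
    rotated into the sensor frame and subtracted frame by frame.  Returns the
    gravity-free record (tagged in metadata) and the (N, 4) quaternion series
    (w, x, y, z; sensor relative to a gravity-aligned world frame).
    """
    sl = _quiet_slice(rec, quiet)
    a0 = rec.accel[:, sl].mean(axis=1)
    n0 = np.linalg.norm(a0)
    if n0 < 1e-6:
        raise ValueError("quiet period has no gravity signal to initialize from")
    # q such that the estimated sensor-frame gravity matches the measured one
    q = _quat_from_two_vectors(np.array([0.0, 0.0, 1.0]), a0 / n0)
    if np.linalg.norm(_gravity_sensor_frame(q) - a0 / n0) > 1e-6:
        q = np.array([q[0], -q[1], -q[2], -q[3]])
    dt = 1.0 / rec.rate_hz
    quats = np.empty((rec.n, 4))
    grav = np.empty((3, rec.n))
    start = sl.start
    # run forward from the quiet period; frames before it get its orientation
    for i in range(start, rec.n):
        if i > start:
            q = madgwick_step(q, rec.gyro[:, i], rec.accel[:, i], dt, filter_gain)
        quats[i] = q
        grav[:, i] = _gravity_sensor_frame(q)
    quats[:start] = quats[start]
    grav[:, :start] = grav[:, start:start + 1]
    out = rec.copy_with(accel=rec.accel - grav)
    out.meta["gravity_removed"] = True
    return out, quats


# ---------------------------------------------------------------------------
# Segment coordinate system
# ---------------------------------------------------------------------------


def build_scs(
    rec_running: IMURecording,
    rec_standing: IMURecording,
    min_explained: float = 0.60,
) -> np.ndarray:
    """Rotation matrix taking input-frame vectors into the segment frame.

    The medial-lateral (+z) axis is the first principal axis of the running
    angular velocity; the proximal (+y) axis is the quiet-standing gravity
    direction (a still accelerometer reads +1 g along proximal),
    orthogonalized against z; +x = y x z completes a right-handed frame.

    The principal axis is sign-ambiguous; the sign is chosen so the skew of
    the projected angular velocity is positive (swing-phase rotation peaks
    positive, the convention the detector registry assumes), falling back to
    +z of the input frame when the skew is negligible.

    Returns a proper rotation R (det = +1, rows = segment axes in the input
    frame); warns if the first principal component explains less than
    ``min_explained`` of the angular-velocity variance.
    """
    from sklearn.decomposition import PCA

    pca = PCA(n_components=3)
    pca.fit(rec_running.gyro.T)
    if pca.explained_variance_ratio_[0] < min_explained:
        warnings.warn(
            "ambiguous medial-lateral axis: first principal component explains "
            f"only {pca.explained_variance_ratio_[0]:.1%} of angular-velocity "
            "variance",
            stacklevel=2,
        )
    z = pca.components_[0]
    proj = z @ rec_running.gyro
    resid = proj - proj.mean()
    m2 = np.mean(resid**2)
    skew = np.mean(resid**3) / m2**1.5 if m2 > 0 else 0.0
    if abs(skew) > 1e-3:
        z = z * np.sign(skew)
    elif z[2] < 0:
        z = -z
    g_dir = rec_standing.accel.mean(axis=1)
    norm = np.linalg.norm(g_dir)
    if norm < 1e-6:
        raise ValueError("standing record has no gravity direction")
    y = g_dir / norm
    y = y - (y @ z) * z
    yn = np.linalg.norm(y)
    if yn < 1e-6:
        raise ValueError("gravity direction parallel to medial-lateral axis")
    y /= yn
    x = np.cross(y, z)
    R = np.vstack([x, y, z])
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-9) and np.linalg.det(R) > 0
    return R


def apply_rotation(rec: IMURecording, R: np.ndarray, frame: str = "SCS") -> IMURecording:
    """Express all vector channels in a new frame; retags the record."""
    out = rec.copy_with(
        accel=R @ rec.accel,
        gyro=R @ rec.gyro,
        accel_secondary=R @ rec.accel_secondary
        if rec.accel_secondary is not None
        else None,
        frame=frame,
    )
    return out


# ---------------------------------------------------------------------------
# Synchronization and segmentation
# ---------------------------------------------------------------------------


def sync_offset(
    pulse_a: np.ndarray, pulse_b: np.ndarray, rate_hz: float = 1000.0
) -> float:
    """Lag (seconds) that best aligns pulse train b to pulse train a.

    Positive lag means b is delayed relative to a.  Cross-correlation over all
    lags; ties broken toward the smallest absolute lag.
    """
    a = np.asarray(pulse_a, dtype=float)
    b = np.asarray(pulse_b, dtype=float)
    if a.max(initial=0) == a.min(initial=0) or b.max(initial=0) == b.min(initial=0):
        raise ValueError("flat pulse train: cannot synchronize")
    a = a - a.mean()
    b = b - b.mean()
    xc = sps.correlate(b, a, mode="full")
    lags = sps.correlation_lags(len(b), len(a), mode="full")
    best = xc.max()
    cand = lags[xc >= best - 1e-12 * abs(best)]
    lag = cand[np.argmin(np.abs(cand))]
    return float(lag) / rate_hz


def segment_by_gates(
    rec: IMURecording, gate1_time: float, gate2_time: float
) -> IMURecording:
    """Cut the sub-record between two speed-gate crossings.

    Time is re-based to start at 0; the original origin is preserved in
    ``meta['time_origin']``.
    """
    if not (rec.time[0] - 1e-9 <= gate1_time < gate2_time <= rec.time[-1] + 1e-9):
        raise ValueError("gate times out of range or out of order")
    i0 = int(np.searchsorted(rec.time, gate1_time - 1e-9))
    i1 = int(np.searchsorted(rec.time, gate2_time + 1e-9))
    out = rec.copy_with(
        time=rec.time[i0:i1] - rec.time[i0],
        accel=rec.accel[:, i0:i1],
        gyro=rec.gyro[:, i0:i1],
        accel_secondary=rec.accel_secondary[:, i0:i1]
        if rec.accel_secondary is not None
        else None,
    )
    out.meta["time_origin"] = float(rec.time[i0]) + rec.meta.get("time_origin", 0.0)
    return out
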