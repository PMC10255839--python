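"""Shared domain types and coordinate-frame bookkeeping.

Axis convention (ISB-style, used everywhere in this package): +x anterior,
+y proximal (up when standing), +z medial-lateral with right positive.
Accelerations are stored in g (1 g = 9.8 m/s^2), angular velocities in rad/s,
time in seconds from record start.

Coordinate-frame tags:

* ``WCS``  -- wearable coordinate system, square to the sensor housing.
* ``SCS``  -- anatomical segment coordinate system built from a functional
  calibration (principal axis of angular velocity + standing gravity).
* ``TILT`` -- pseudo-global "tilt-corrected" frame (gravity-aligned vertical).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

G_MS2 = 9.8  # m/s^2 per g, the convention used throughout

FRAMES = ("WCS", "SCS", "TILT")
PLACEMENTS = ("shank", "sacrum")
SIDES = ("left", "right", "unknown")

# axis indices
AX, AY, AZ = 0, 1, 2


@dataclass
class IMURecording:
    """Uniformly sampled tri-axial accelerometer + gyroscope record.

    Parameters
    ----------
    time : (N,) array, seconds, uniform at 1/rate_hz
    accel : (3, N) array, g
    gyro : (3, N) array, rad/s
    rate_hz : sampling frequency
    frame : one of ``WCS``/``SCS``/``TILT``
    placement : ``shank`` or ``sacrum``
    accel_secondary : optional (3, N) wide-range accelerometer channel, g
    meta : free-form provenance dictionary (calibration applied, gravity
        removed, time origin, ...)
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    rate_hz: float
    frame: str = "WCS"
    placement: str = "shank"
    accel_secondary: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.accel_secondary is not None:
            self.accel_secondary = np.atleast_2d(
                np.asarray(self.accel_secondary, dtype=float)
            )

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n else 0.0

    def copy_with(self, **kw) -> "IMURecording":
        """Dataclass replace that never aliases the metadata dict."""
        kw.setdefault("meta", dict(self.meta))
        return replace(self, **kw)


def validate_recording(rec: IMURecording) -> list[str]:
    """Check IMURecording invariants; returns human-readable violations.

    Never raises: an empty list means the record is well formed.  Each
    descriptor names the offending field and, where meaningful, the first
    offending sample index.
    """
    out: list[str] = []
    n = rec.time.shape[0]
    if n < 1:
        out.append("time: empty record (N must be >= 1)")
        return out
    for name, arr in (("accel", rec.accel), ("gyro", rec.gyro)):
        if arr.shape != (3, n):
            out.append(f"{name}: length mismatch, expected (3, {n}), got {arr.shape}")
    if rec.accel_secondary is not None and rec.accel_secondary.shape != (3, n):
        out.append(
            f"accel_secondary: length mismatch, expected (3, {n}), "
            f"got {rec.accel_secondary.shape}"
        )
    if n >= 2:
        dt = np.diff(rec.time)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            out.append(f"time: not strictly increasing at index {bad[0] + 1}")
        else:
            step = 1.0 / rec.rate_hz
            off = np.flatnonzero(np.abs(dt - step) > 1e-9)
            if off.size:
                out.append(
                    f"time: non-uniform step at index {off[0] + 1} "
                    f"(expected {step:.9g} s)"
                )
    if rec.frame not in FRAMES:
        out.append(f"frame: unknown tag {rec.frame!r}")
    if rec.placement not in PLACEMENTS:
        out.append(f"placement: unknown tag {rec.placement!r}")
    if not np.all(np.isfinite(rec.accel)):
        out.append("accel: non-finite samples")
    if not np.all(np.isfinite(rec.gyro)):
        out.append("gyro: non-finite samples")
    return out


@dataclass
class GaitEventSet:
    """Ordered initial-contact / terminal-contact event times.

    ``failed`` is true iff the detector recognized no events at all in the
    segment.  ``sides`` labels each IC (``left``/``right``/``unknown``); shank
    detectors leave it None because the side is the instrumented leg.
    """

    ic_times: np.ndarray
    tc_times: np.ndarray
    sides: Optional[list[str]] = None
    failed: bool = False

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.tc_times = np.asarray(self.tc_times, dtype=float)
        self.failed = bool(
            self.failed or (self.ic_times.size == 0 and self.tc_times.size == 0)
        )

    @property
    def n_ic(self) -> int:
        return int(self.ic_times.size)

    @property
    def n_tc(self) -> int:
        return int(self.tc_times.size)

    def validate(self) -> list[str]:
        out = []
        for name, t in (("ic_times", self.ic_times), ("tc_times", self.tc_times)):
            if t.size >= 2 and np.any(np.diff(t) <= 0):
                out.append(f"{name}: not strictly ascending")
        if self.failed != (self.ic_times.size == 0 and self.tc_times.size == 0):
            out.append("failed flag inconsistent with event lists")
        if self.sides is not None and len(self.sides) != self.ic_times.size:
            out.append("sides: length differs from ic_times")
        return out


@dataclass
class CalibrationModel:
    """3x7 sensor calibration: 3 signed, 3 absolute-magnitude, 1 bias term per axis.

    Maps a measured vector m (after adding quiet-period bias B) to the known
    reference value::

        k = C @ [m + B, |m + B|, 1]

    An identity model has the signed block equal to I, the absolute block and
    the bias column zero, and B = 0.
    """

    C: np.ndarray
    B: np.ndarray
    units: str = "g"

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float).reshape(3, 7)
        self.B = np.asarray(self.B, dtype=float).reshape(3)

    @classmethod
    def identity(cls, units: str = "g") -> "CalibrationModel":
        C = np.hstack([np.eye(3), np.zeros((3, 3)), np.zeros((3, 1))])
        return cls(C=C, B=np.zeros(3), units=units)

    def apply(self, m: np.ndarray) -> np.ndarray:
        """Apply the model to (3,) or (3, N) measured data."""
        m = np.asarray(m, dtype=float)
        v = (m.T + self.B).T if m.ndim == 2 else m + self.B
        reg = np.vstack([np.atleast_2d(v.reshape(3, -1)),
                         np.abs(np.atleast_2d(v.reshape(3, -1))),
                         np.ones((1, v.reshape(3, -1).shape[1]))])
        out = self.C @ reg
        return out if m.ndim == 2 else out[:, 0]


@dataclass
class TrialRecord:
    """One trial's timing error and covariates for the agreement models."""

    method_id: str
    participant_id: str
    trial_id: str
    event_type: str  # "IC" or "TC"
    error_ms: float  # method time minus ground-truth time
    surface: str = "track"  # "track" or "floor"
    speed: float = np.nan  # m/s
    footstrike_angle: float = np.nan  # rad

    def __post_init__(self) -> None:
        if not np.isfinite(self.error_ms):
            raise ValueError("error_ms must be finite (failed trials carry no record)")


@dataclass
class AgreementSummary:
    """Per-method agreement with ground truth under the linked-replicates model.

    ``var_components`` holds the four variance components (ms^2):
    ``participant`` (between-participant), ``trial`` (participant-by-trial,
    shared across methods), ``method_participant`` (method-by-participant
    interaction), and ``residual``.
    """

    method_id: str
    event_type: str
    bias_ms: float
    var_components: dict
    within_sd_ms: float
    loa_ms: tuple
    failure_rate: float = np.nan
    side_accuracy: float = np.nan
    n_records: int = 0

    def validate(self) -> list[str]:
        out = []
        lo, hi = self.loa_ms
        sd = (hi - lo) / (2 * 1.96)
        if abs((self.bias_ms - lo) - 1.96 * sd) > 1e-6:
            out.append("loa not symmetric about bias")
        if any(v < 0 for v in self.var_components.values()):
            out.append("negative variance component")
        return out
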