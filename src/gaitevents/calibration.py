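"""Fit and apply the 3x7 sensor calibration model.

The model maps measured output M (plus a quiet-period bias B, estimated
separately and fixed before fitting) to known reference values K through a
3x7 matrix C with three signed-magnitude terms, three absolute-magnitude
terms, and one bias term per axis::

    C @ [M + B, |M + B|, 1] = K

The absolute-value regressors capture scale-factor asymmetry between positive
and negative accelerations; the bias column absorbs any offset the quiet-period
estimate missed.  Given the regressor the model is linear in C, so fitting is
ordinary least squares row by row.
"""

from __future__ import annotations

import itertools
import json

import numpy as np

from .core import CalibrationModel, IMURecording


def _regressor(v: np.ndarray) -> np.ndarray:
    """Stack [v; |v|; 1] for (3, N) bias-corrected measurements -> (7, N)."""
    v = np.atleast_2d(np.asarray(v, dtype=float).reshape(3, -1))
    return np.vstack([v, np.abs(v), np.ones((1, v.shape[1]))])


def fit_calibration(
    measured: np.ndarray,
    known: np.ndarray,
    quiet_bias: np.ndarray | None = None,
    units: str = "g",
    rcond_thresh: float = 1e-8,
) -> tuple[CalibrationModel, float]:
    """Least-squares fit of the 3x7 calibration matrix.

    Parameters
    ----------
    measured, known : (N, 3) or (3, N) paired sensor readings and reference
        values.  The orientation is inferred (samples along the long axis).
    quiet_bias : length-3 bias B observed during a quiet period, fixed before
        fitting (default zeros).
    units : unit tag stored on the model ("g" or "rad/s").

    Returns
    -------
    (model, residual_rms) where residual_rms is the RMS of ``C@reg - K`` over
    all samples and axes.

    Raises
    ------
    ValueError
        If the design is rank deficient (for example a single orientation),
        naming the deficient regressor columns.
    """
    M = _as_3xn(measured)
    K = _as_3xn(known)
    if M.shape != K.shape:
        raise ValueError(f"measured {M.shape} and known {K.shape} differ in shape")
    if M.shape[1] < 7:
        raise ValueError("underdetermined calibration: need >= 7 samples")
    B = np.zeros(3) if quiet_bias is None else np.asarray(quiet_bias, float).reshape(3)

    X = _regressor((M.T + B).T)  # (7, N)
    # rank check with named columns
    names = ["x", "y", "z", "|x|", "|y|", "|z|", "1"]
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < rcond_thresh * sv[0]:
        # identify columns not independently spanned
        deficient = []
        for i in range(7):
            others = np.delete(X, i, axis=0)
            resid = X[i] - others.T @ np.linalg.lstsq(others.T, X[i], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-6 * max(1.0, np.linalg.norm(X[i])):
                deficient.append(names[i])
        raise ValueError(
            "underdetermined calibration: rank-deficient design"
            + (f" (deficient columns: {', '.join(deficient)})" if deficient else "")
        )
    C, *_ = np.linalg.lstsq(X.T, K.T, rcond=None)
    model = CalibrationModel(C=C.T, B=B, units=units)
    resid = model.C @ X - K
    return model, float(np.sqrt(np.mean(resid**2)))


def apply_calibration(
    model: CalibrationModel,
    rec: IMURecording,
    gyro_model: CalibrationModel | None = None,
) -> IMURecording:
    """Apply a fitted accelerometer model (and optionally a gyro model).

    Every accelerometer frame m is replaced by ``C @ [m+B, |m+B|, 1]``; the
    gyroscope is transformed analogously when ``gyro_model`` is given.  The
    output record notes the calibration in its metadata.
    """
    if model.units != "g":
        raise ValueError(f"accelerometer model has units {model.units!r}, expected 'g'")
    accel = model.apply(rec.accel)
    accel2 = (
        model.apply(rec.accel_secondary) if rec.accel_secondary is not None else None
    )
    gyro = rec.gyro
    if gyro_model is not None:
        if gyro_model.units != "rad/s":
            raise ValueError(
                f"gyro model has units {gyro_model.units!r}, expected 'rad/s'"
            )
        gyro = gyro_model.apply(rec.gyro)
    out = rec.copy_with(accel=accel, gyro=gyro, accel_secondary=accel2)
    out.meta["calibrated"] = True
    return out


def invert_calibration(model: CalibrationModel, known: np.ndarray) -> np.ndarray:
    """Solve for the measured value that a model would map to ``known``.

    The absolute-value terms make the forward map piecewise linear, so each
    sample is solved by sign-consistent case analysis: for each of the eight
    sign patterns s of (m+B), solve the linear system
    ``(C_signed + C_abs @ diag(s)) v = k - c_bias`` and accept the solution
    whose signs match s.  Used by the centrifuge simulator.
    """
    K = _as_3xn(known)
    Cs, Ca, cb = model.C[:, :3], model.C[:, 3:6], model.C[:, 6]
    out = np.empty_like(K)
    patterns = list(itertools.product((1.0, -1.0), repeat=3))
    for j in range(K.shape[1]):
        k = K[:, j] - cb
        best, best_err = None, np.inf
        for s in patterns:
            A = Cs + Ca * np.asarray(s)  # column scaling = Ca @ diag(s)
            try:
                v = np.linalg.solve(A, k)
            except np.linalg.LinAlgError:
                continue
            # sign consistency (zeros compatible with either sign)
            err = np.max(np.maximum(0.0, -v * np.asarray(s)))
            if err < best_err:
                best, best_err = v, err
        if best is None:
            raise np.linalg.LinAlgError("calibration model not invertible at sample")
        out[:, j] = best - model.B
    return out if np.asarray(known).ndim == 2 and np.asarray(known).shape[0] == 3 else out.T


def to_json(model: CalibrationModel) -> str:
    return json.dumps(
        {"C": model.C.tolist(), "B": model.B.tolist(), "units": model.units}
    )


def from_json(text: str) -> CalibrationModel:
    d = json.loads(text)
    return CalibrationModel(C=np.array(d["C"]), B=np.array(d["B"]), units=d["units"])


def _as_3xn(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or 3 not in a.shape:
        raise ValueError(f"expected (3, N) or (N, 3) array, got {a.shape}")
    return a if a.shape[0] == 3 and a.shape[1] != 3 else (a.T if a.shape[0] != 3 else a)
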