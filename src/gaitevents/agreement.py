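"""Agreement statistics for event-timing errors: the linked-replicates model.

Every method is applied to the same trials, so method-vs-truth errors are
*linked replicates*: errors from different methods on one trial share the
participant and the trial.  The model for the error of method m on trial t of
participant p is::

    y[m,p,t] = a[m] + b[p] + c[p,t] + d[m,p] + e[m,p,t]

with fixed per-method biases a and independent zero-mean normal random
effects: b (between participants), c (participant-by-trial, shared by all
methods), d (method-by-participant interaction), e (residual).  Estimation is
restricted maximum likelihood via a mixed linear model with participant
groups, a random intercept (b), and variance components for trial within
participant (c) and method within participant (d).

From the fit, for each method:

* bias = a[m];
* 95 % limits of agreement = bias +/- 1.96 x SD of that method's errors,
  where the error SD is composed from the components that vary between a
  method's replicate measurements, sqrt(sigma_d^2 + sigma_e^2) by default
  (``include_trial``/``include_participant`` add sigma_c^2 / sigma_b^2);
* the within-method SD (repeatability) = sqrt(sigma_e^2).

Negative component estimates are truncated at zero with a warning (a REML
boundary artifact).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .core import AgreementSummary, TrialRecord


def _records_frame(records: list[TrialRecord], event_type: str) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "method": r.method_id,
                "participant": r.participant_id,
                "trial": r.trial_id,
                "error": r.error_ms,
                "surface": r.surface,
                "speed": r.speed,
                "footstrike": r.footstrike_angle,
            }
            for r in records
            if r.event_type == event_type
        ]
    )
    if df.empty:
        raise ValueError(f"no records with event_type {event_type!r}")
    return df


def _clip_component(name: str, value: float) -> float:
    if value < 0:
        warnings.warn(
            f"variance component {name} estimated negative ({value:.3g}); "
            "truncated at 0",
            stacklevel=3,
        )
        return 0.0
    return float(value)


def _robust_fit(model):
    """REML fit with an optimizer fallback for boundary cases."""
    fit = model.fit(reml=True)
    if not getattr(fit, "converged", True):
        fit = model.fit(reml=True, method="powell", maxiter=2000)
    return fit


def fit_linked_replicates(
    records: list[TrialRecord],
    event_type: str = "IC",
    include_trial: bool = False,
    include_participant: bool = False,
) -> dict[str, AgreementSummary]:
    """Fit the linked-replicates model and summarize agreement per method.

    Requires at least 2 participants; with 2+ methods the full crossed/nested
    random structure is identifiable.  With a single method the
    method-by-participant and participant effects are confounded, as are the
    trial and residual effects; the model collapses to a participant random
    intercept and the summary reduces to mean +/- 1.96 SD of the raw errors.

    Returns ``{method_id: AgreementSummary}``.
    """
    df = _records_frame(records, event_type)
    methods = sorted(df["method"].unique())
    n_participants = df["participant"].nunique()
    if n_participants < 2:
        raise ValueError(
            "degenerate grouping: participant random effect needs >= 2 "
            f"participants (got {n_participants})"
        )
    multi_method = len(methods) > 1
    multi_trial = df.groupby("participant")["trial"].nunique().min() > 1

    vc = {}
    if multi_method and multi_trial:
        vc["trial"] = "0 + C(trial)"
    if multi_method:
        vc["method"] = "0 + C(method)"
    model = smf.mixedlm(
        "error ~ 0 + C(method)",
        df,
        groups="participant",
        re_formula="1",
        vc_formula=vc or None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary/convergence chatter
        fit = _robust_fit(model)

    scale = float(fit.scale)  # sigma_e^2
    vc_names = list(getattr(fit.model.exog_vc, "names", []))
    sigma_b2 = _clip_component("participant", float(np.asarray(fit.cov_re)[0, 0]))
    sigma_c2 = (
        _clip_component("trial", float(fit.vcomp[vc_names.index("trial")]))
        if "trial" in vc_names
        else 0.0
    )
    sigma_d2 = (
        _clip_component("method_participant", float(fit.vcomp[vc_names.index("method")]))
        if "method" in vc_names
        else 0.0
    )
    if not multi_method:
        # single method: cov_re absorbs b+d, scale absorbs c+e
        sigma_d2, sigma_b2 = sigma_b2, 0.0

    comp = {
        "participant": sigma_b2,
        "trial": sigma_c2,
        "method_participant": sigma_d2,
        "residual": scale,
    }
    err_var = sigma_d2 + scale
    if include_trial:
        err_var += sigma_c2
    if include_participant:
        err_var += sigma_b2
    err_sd = float(np.sqrt(err_var))

    out: dict[str, AgreementSummary] = {}
    for m in methods:
        bias = float(fit.params[f"C(method)[{m}]"])
        out[m] = AgreementSummary(
            method_id=m,
            event_type=event_type,
            bias_ms=bias,
            var_components=dict(comp),
            within_sd_ms=float(np.sqrt(scale)),
            loa_ms=(bias - 1.96 * err_sd, bias + 1.96 * err_sd),
            n_records=int((df["method"] == m).sum()),
        )
    return out


def fit_explanatory(
    records: list[TrialRecord],
    event_type: str,
    method_id: str,
    alpha: float = 0.05,
) -> dict:
    """Per-method mixed model with surface, speed and foot-strike covariates.

    Model: error ~ surface + speed + footstrike with a participant random
    intercept and a trial variance component (the within-method reduction of
    the linked-replicates random structure).  The surface coefficient is the
    intercept shift for the floor condition relative to track; speed is in
    ms per m/s; foot strike in ms per rad.

    A covariate that is constant in the data is reported as undefined
    (coefficient NaN), not zero.  Returns a dict with ``coef``, ``se``,
    ``pvalue``, ``ci95`` and ``significant`` (p <= alpha) per covariate plus
    the fitted result under ``fit``.
    """
    df = _records_frame(records, event_type)
    df = df[df["method"] == method_id]
    if df.empty:
        raise ValueError(f"no records for method {method_id!r}")
    if df[["speed", "footstrike"]].isna().any().any():
        raise ValueError("covariates missing on some records")

    terms, dropped = [], []
    if df["surface"].nunique() > 1:
        terms.append("C(surface, Treatment('track'))")
    else:
        dropped.append("surface")
    for name in ("speed", "footstrike"):
        if df[name].nunique() > 1:
            terms.append(name)
        else:
            dropped.append(name)
    if not terms:
        raise ValueError("all covariates constant; nothing to fit")
    multi_trial = df.groupby("participant")["trial"].nunique().min() > 1
    model = smf.mixedlm(
        "error ~ " + " + ".join(terms),
        df,
        groups="participant",
        re_formula="1",
        vc_formula={"trial": "0 + C(trial)"} if multi_trial else None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = _robust_fit(model)

    key_map = {
        "surface": "C(surface, Treatment('track'))[T.floor]",
        "speed": "speed",
        "footstrike": "footstrike",
    }
    out = {"method_id": method_id, "event_type": event_type, "fit": fit,
           "intercept": float(fit.params["Intercept"])}
    ci = fit.conf_int(alpha=1 - 0.95)
    for name, key in key_map.items():
        if name in dropped or key not in fit.params.index:
            out[name] = {
                "coef": np.nan, "se": np.nan, "pvalue": np.nan,
                "ci95": (np.nan, np.nan), "significant": False,
                "undefined": True,
            }
            continue
        out[name] = {
            "coef": float(fit.params[key]),
            "se": float(fit.bse[key]),
            "pvalue": float(fit.pvalues[key]),
            "ci95": (float(ci.loc[key, 0]), float(ci.loc[key, 1])),
            "significant": bool(fit.pvalues[key] <= alpha),
            "undefined": False,
        }
    return out


def predict_mae_surface(
    explanatory: dict,
    speed_grid: np.ndarray,
    angle_grid: np.ndarray,
    surface: str = "track",
    speed_range: tuple = (2.5, 7.5),
    angle_range: tuple = (-0.25, 0.75),
) -> np.ndarray:
    """Model-predicted mean absolute error over a speed x foot-strike grid.

    Returns |intercept + surface shift + speed slope * v + strike slope * a|
    with undefined coefficients treated as zero contribution.  Grid points
    outside the default observed ranges trigger an extrapolation warning.
    The output is (len(angle_grid), len(speed_grid)): angles index rows.
    """
    speed_grid = np.atleast_1d(np.asarray(speed_grid, dtype=float))
    angle_grid = np.atleast_1d(np.asarray(angle_grid, dtype=float))
    if (
        speed_grid.min() < speed_range[0] - 1e-9
        or speed_grid.max() > speed_range[1] + 1e-9
        or angle_grid.min() < angle_range[0] - 1e-9
        or angle_grid.max() > angle_range[1] + 1e-9
    ):
        warnings.warn(
            "grid extends outside the fitted covariate ranges; predictions "
            "are extrapolations",
            stacklevel=2,
        )

    def coef(name):
        c = explanatory[name]["coef"]
        return 0.0 if not np.isfinite(c) else c

    base = explanatory["intercept"] + (coef("surface") if surface == "floor" else 0.0)
    pred = base + coef("speed") * speed_grid[None, :] + coef("footstrike") * angle_grid[:, None]
    return np.abs(pred)


def failure_rate(failed_by_participant: dict[str, list[bool]]) -> float:
    """Mean per-participant fraction of trials with no recognized events.

    Input maps participant id to a list of per-trial failure flags; the
    statistic is the mean across participants of each participant's failure
    fraction (participants weigh equally regardless of trial count).
    """
    if not failed_by_participant:
        raise ValueError("no trials")
    fracs = [float(np.mean(v)) for v in failed_by_participant.values() if len(v)]
    if not fracs:
        raise ValueError("no trials")
    return float(np.mean(fracs))


def side_accuracy(predicted: list[str], true: list[str]) -> float:
    """Fraction of events whose side label matches truth.

    ``unknown`` predictions count as incorrect."""
    if len(predicted) != len(true):
        raise ValueError("length mismatch between predicted and true sides")
    if not predicted:
        return np.nan
    return float(
        np.mean([p == t and p in ("left", "right") for p, t in zip(predicted, true)])
    )


def misid_probability(p_segment: float, n_segments: int) -> float:
    """Probability that the side is misidentified over n independent segments.

    With per-segment misidentification probability p and the strict
    left-right alternation of running, misidentifying *every* event over n
    segments requires an independent failure in each: p**n.
    """
    if not 0.0 <= p_segment <= 1.0:
        raise ValueError(f"p_segment must be in [0, 1], got {p_segment}")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    return float(p_segment**n_segments)


def diagnostics_tables(records: list[TrialRecord], event_type: str = "IC") -> dict:
    """Plain tables backing the model-assumption checks.

    Returns within-participant means and variances (per method) and the raw
    residuals about each method's mean, for plotting mean-variance
    relationships and residual histograms.
    """
    df = _records_frame(records, event_type)
    per = (
        df.groupby(["method", "participant"])["error"]
        .agg(["mean", "var", "count"])
        .reset_index()
    )
    resid = df.copy()
    resid["residual"] = df["error"] - df.groupby("method")["error"].transform("mean")
    return {"within_participant": per, "residuals": resid[["method", "participant", "residual"]]}
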