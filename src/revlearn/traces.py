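"""Ratiometric trace processing: raw two-channel fluorescence -> dR/R0 -> windowed metrics.

Processing order, applied independently to each trial's imaging segment
(local time 0 at imaging onset):

1. ratio        R(t) = G(t) / T(t)        (motion cancels here)
2. detrend      fit a double exponential to non-stimulus frames, subtract the
                trend, keep the initial level:  R_d = R - f(t) + f(t0)
3. normalize    R0 = mean R_d over the first 5 s (pre-odor); dRR = (R_d - R0)/R0
4. window       mean odor response  = mean dRR over [onset, onset+4) s
                mean shock response = mean dRR over [onset+4, onset+4.8) s

Windows are half-open in seconds; a frame belongs to a window when its
timestamp falls inside it.  The odor window deliberately stops before shock
onset and the shock window before odor offset, so neither metric is
contaminated by the other event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    ContractError,
    DegenerateReferenceError,
    InsufficientBaselineError,
    NonPositiveBaselineError,
    TruncatedWindowError,
)
from .schedule import TrialSchedule
from .simulate import TwoChannelTrace

__all__ = [
    "RatioTrace",
    "compute_ratio",
    "detrend_bleach",
    "compute_dff",
    "mean_odor_response",
    "mean_shock_response",
    "ratio_trace",
    "process_trace",
    "process_experiment",
]

#: seconds of pre-odor recording that define R0
BASELINE_WINDOW_S = 5.0
#: odor-response window length (ends at shock onset)
ODOR_WINDOW_S = 4.0
#: shock-response window (relative to odor onset)
SHOCK_WINDOW_S = (4.0, 4.8)
#: post-offset seconds also masked out of the bleach fit while the calcium
#: transients decay back to baseline; 6 s is four decay constants past the
#: shock response, below which its tail measurably biases the trend fit
MASK_DECAY_PAD_S = 6.0
#: minimum unmasked frames required to attempt the 5-parameter fit
MIN_FIT_FRAMES = 20

_WINDOW_TOL = 1e-6  # timestamp jitter tolerance, well under half a frame


@dataclass
class RatioTrace:
    """Processed ratio trace for one trial segment."""

    t: np.ndarray
    R_raw: np.ndarray
    R_detrended: np.ndarray
    dRR: np.ndarray
    R0: float
    fit_params: tuple[float, float, float, float, float]
    fit_ok: bool


def compute_ratio(G: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Frame-wise activity/reference ratio; the reference must stay positive."""
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    bad = np.flatnonzero(T <= 0)
    if bad.size:
        raise DegenerateReferenceError(
            f"reference channel non-positive at frame {int(bad[0])}"
        )
    return G / T


def _double_exp(t: np.ndarray, p: Sequence[float]) -> np.ndarray:
    a1, tau1, a2, tau2, c = p
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def _vp_amplitudes(t: np.ndarray, y: np.ndarray, tau1: float, tau2: float):
    """Solve the linear amplitudes (a1, a2, c) for fixed time constants."""
    X = np.column_stack([np.exp(-t / tau1), np.exp(-t / tau2), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def detrend_bleach(
    ratio: np.ndarray,
    t: np.ndarray,
    stimulus_mask: np.ndarray | None = None,
    tau_grid: Sequence[float] = (5.0, 30.0, 100.0, 300.0),
):
    """Remove a double-exponential photobleaching trend from a ratio trace.

    The trend ``f(t) = a1 e^{-t/tau1} + a2 e^{-t/tau2} + c`` is fitted to
    frames *outside* ``stimulus_mask`` (True = stimulus frame, excluded so
    evoked transients do not bias the trend).  The fit is deterministic:
    variable projection over the ``tau_grid`` start pairs (amplitudes solved
    linearly for each), then one bounded least-squares refinement from the
    best start.  The detrended trace preserves the initial level,
    ``R_d = R - f(t) + f(t[0])``, so a transient's amplitude is untouched.

    Returns ``(R_detrended, fit_params, fit_ok)``; on refinement failure the
    fallback is a linear detrend with ``fit_ok=False``.
    """
    ratio = np.asarray(ratio, dtype=float)
    t = np.asarray(t, dtype=float)
    if stimulus_mask is None:
        keep = np.ones(len(t), dtype=bool)
    else:
        keep = ~np.asarray(stimulus_mask, dtype=bool)
    if not keep.any():
        raise InsufficientBaselineError("all frames are stimulus-masked")
    if keep.sum() < MIN_FIT_FRAMES:
        raise InsufficientBaselineError(
            f"need >= {MIN_FIT_FRAMES} unmasked frames, got {int(keep.sum())}"
        )
    tf, yf = t[keep], ratio[keep]

    best = None
    for tau1 in tau_grid:
        for tau2 in tau_grid:
            if tau2 < tau1:
                continue
            (a1, a2, c), sse = _vp_amplitudes(tf, yf, tau1, tau2)
            if best is None or sse < best[1]:
                best = ((a1, tau1, a2, tau2, c), sse)
    p0 = np.asarray(best[0], dtype=float)

    # tau bounds: nothing faster than 1 s is bleaching (it would only chase
    # frame noise), nothing slower than 100x the record is identifiable
    span = max(tf[-1] - tf[0], 1.0)
    lo = [-np.inf, 1.0, -np.inf, 1.0, -np.inf]
    hi = [np.inf, 100.0 * span, np.inf, 100.0 * span, np.inf]
    p0[1] = np.clip(p0[1], lo[1], hi[1])
    p0[3] = np.clip(p0[3], lo[3], hi[3])
    def jac(p):
        a1, tau1, a2, tau2, _ = p
        e1 = np.exp(-tf / tau1)
        e2 = np.exp(-tf / tau2)
        return np.column_stack(
            [e1, a1 * tf / tau1 ** 2 * e1, e2, a2 * tf / tau2 ** 2 * e2, np.ones_like(tf)]
        )

    fit_ok = True
    try:
        sol = least_squares(
            lambda p: _double_exp(tf, p) - yf,
            p0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=30,  # identifiable trends converge in ~15 evals; flat
            # traces (nothing to remove) would otherwise wander indefinitely
        )
        # status 0 = evaluation cap reached: the iterate is still at least as
        # good as the grid start, so it is accepted (flat traces never meet
        # the gradient tolerance because the time constants are unidentifiable)
        if sol.status < 0 or not np.all(np.isfinite(sol.x)):
            raise RuntimeError("refinement failed")
        params = tuple(float(v) for v in sol.x)
    except Exception:
        slope, intercept = np.polyfit(tf, yf, 1)
        trend = slope * t + intercept
        detrended = ratio - trend + trend[0]
        return detrended, (0.0, 1.0, 0.0, 1.0, float(intercept)), False

    trend = _double_exp(t, params)
    detrended = ratio - trend + trend[0]
    return detrended, params, fit_ok


def compute_dff(
    R_detrended: np.ndarray,
    t: np.ndarray,
    baseline_window: float = BASELINE_WINDOW_S,
) -> tuple[np.ndarray, float]:
    """Baseline-normalize: R0 = mean over t in [0, baseline_window) s.

    At 5 fps the default 5-s baseline uses exactly 25 frames.
    """
    R_detrended = np.asarray(R_detrended, dtype=float)
    t = np.asarray(t, dtype=float)
    if t[-1] + 1.0 / max(len(t), 1) < baseline_window - _WINDOW_TOL:
        raise TruncatedWindowError(
            f"trace ends at {t[-1]:.2f} s; needs >= {baseline_window} s for R0"
        )
    sel = (t > -_WINDOW_TOL) & (t < baseline_window - _WINDOW_TOL)
    if not sel.any():
        raise TruncatedWindowError("no frames inside the baseline window")
    R0 = float(R_detrended[sel].mean())
    if R0 <= 0:
        raise NonPositiveBaselineError(f"baseline ratio R0 = {R0:.4g} <= 0")
    return (R_detrended - R0) / R0, R0


def _window_mean(
    x: np.ndarray, t: np.ndarray, lo: float, hi: float, what: str
) -> float:
    sel = (t > lo - _WINDOW_TOL) & (t < hi - _WINDOW_TOL)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    expected = int(round((hi - lo) / dt)) if dt > 0 else 0
    if int(sel.sum()) < expected:
        raise TruncatedWindowError(
            f"{what} window [{lo}, {hi}) s not fully covered "
            f"({int(sel.sum())}/{expected} frames)"
        )
    return float(np.asarray(x, dtype=float)[sel].mean())


def mean_odor_response(
    dRR: np.ndarray, t: np.ndarray, odor_onset: float, window: float = ODOR_WINDOW_S
) -> float:
    """Mean dR/R0 over the first ``window`` s after odor onset.

    The default 4-s window ends exactly at shock onset so the odor metric is
    never confounded by a shock response; the frame at ``onset + 4.0`` s is
    excluded (half-open window).
    """
    return _window_mean(dRR, t, odor_onset, odor_onset + window, "odor")


def mean_shock_response(
    dRR: np.ndarray,
    t: np.ndarray,
    odor_onset: float,
    shock: bool = True,
    window: tuple[float, float] = SHOCK_WINDOW_S,
) -> float:
    """Mean dR/R0 over the 800 ms after shock onset (4 frames at 5 fps).

    The window ends before odor offset at onset + 5 s, so the metric is not
    confounded by an odor-offset response.  Calling this for a no-shock trial
    is a contract violation.
    """
    if not shock:
        raise ContractError("mean_shock_response called on a no-shock trial")
    return _window_mean(
        dRR, t, odor_onset + window[0], odor_onset + window[1], "shock"
    )


def ratio_trace(
    trace: TwoChannelTrace, schedule: TrialSchedule, trial_index: int
) -> RatioTrace:
    """Full processed ratio trace for one trial (for inspection/plotting)."""
    trial = schedule.trial(trial_index)
    sel = trace.trial_index == trial.index
    if not sel.any():
        raise ContractError(f"trace has no frames for trial {trial_index}")
    t_loc = trace.t[sel]
    t_loc = t_loc - t_loc[0]
    R = compute_ratio(trace.G[sel], trace.T[sel])
    mask = (t_loc > trial.odor_onset - _WINDOW_TOL) & (
        t_loc < trial.odor_onset + trial.odor_duration + MASK_DECAY_PAD_S - _WINDOW_TOL
    )
    Rd, params, fit_ok = detrend_bleach(R, t_loc, stimulus_mask=mask)
    dRR, R0 = compute_dff(Rd, t_loc)
    return RatioTrace(
        t=t_loc, R_raw=R, R_detrended=Rd, dRR=dRR, R0=R0,
        fit_params=params, fit_ok=fit_ok,
    )


def process_trace(trace: TwoChannelTrace, schedule: TrialSchedule) -> pd.DataFrame:
    """Run the full per-trial pipeline for one fly; one output row per trial."""
    known = {tr.index for tr in schedule.trials}
    unknown = set(np.unique(trace.trial_index)) - known
    if unknown:
        raise ContractError(
            f"fly {trace.fly_id}: trace trial indices {sorted(unknown)} not in schedule"
        )
    rows = []
    for trial in schedule.trials:
        sel = trace.trial_index == trial.index
        if not sel.any():
            continue
        t_loc = trace.t[sel]
        t_loc = t_loc - t_loc[0]
        try:
            R = compute_ratio(trace.G[sel], trace.T[sel])
            mask = (t_loc > trial.odor_onset - _WINDOW_TOL) & (
                t_loc
                < trial.odor_onset + trial.odor_duration + MASK_DECAY_PAD_S - _WINDOW_TOL
            )
            Rd, params, fit_ok = detrend_bleach(R, t_loc, stimulus_mask=mask)
            dRR, R0 = compute_dff(Rd, t_loc)
            odor = mean_odor_response(dRR, t_loc, trial.odor_onset)
            shock = (
                mean_shock_response(dRR, t_loc, trial.odor_onset)
                if trial.shock
                else np.nan
            )
        except Exception as err:
            raise type(err)(
                f"fly {trace.fly_id}, trial {trial.index}: {err}"
            ) from err
        rows.append(
            {
                "fly_id": trace.fly_id,
                "neuron_class": trace.neuron_class,
                "trial_index": trial.index,
                "phase": trial.phase,
                "odor": trial.odor,
                "mean_odor_response": odor,
                "mean_shock_response": shock,
                "fit_ok": fit_ok,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fly_id", "neuron_class", "trial_index", "phase", "odor",
            "mean_odor_response", "mean_shock_response", "fit_ok",
        ],
    )


def process_experiment(
    traces: Iterable[TwoChannelTrace], schedule: TrialSchedule
) -> pd.DataFrame:
    """Response table over a cohort: ratio -> detrend -> dR/R0 -> window metrics.

    Deterministic; returns one row per (fly, trial) with the windowed odor
    and shock metrics (shock is NaN on no-shock trials).
    """
    frames = [process_trace(tr, schedule) for tr in traces]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=[
                "fly_id", "neuron_class", "trial_index", "phase", "odor",
                "mean_odor_response", "mean_shock_response", "fit_ok",
            ]
        )
    return pd.concat(frames, ignore_index=True)
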