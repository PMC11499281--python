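"""Attractor-characterization metrics for fitted latent dynamics.

Time constants come from the eigenvalues of the per-frame dynamics matrix,
``tau_a = |1 / log|lambda_a||`` (natural log; per-frame eigenvalues give tau in
frames, converted to seconds by the frame rate).  The line-attractor score is
``log2`` of the ratio of the largest to second-largest time constant: a system
with one dominant slow mode — a 1-D continuum of slowly-decaying states —
scores high.  Single-cell timescales are summarized by the autocorrelation
half-width (ACHW), the lag at which the autocorrelation function decays to
half its zero-lag value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TimeConstantSet",
    "AutocorrFunction",
    "FlowField",
    "HalfWidth",
    "RampDecay",
    "time_constants",
    "params_time_constants",
    "line_attractor_score",
    "autocorrelation",
    "autocorr_half_width",
    "flow_field",
    "ramp_and_decay_metrics",
]


@dataclass
class TimeConstantSet:
    """Eigenvalues and per-dimension time constants of one dynamics matrix."""

    eigenvalues: np.ndarray     # complex, per latent dimension
    tau_frames: np.ndarray      # |1/log|lambda||, np.inf where |lambda| == 1
    tau_s: np.ndarray
    frame_rate: float
    state: int = 0
    infinite: np.ndarray | None = None   # |lambda| == 1 flags
    zero: np.ndarray | None = None       # lambda == 0 flags


@dataclass
class AutocorrFunction:
    lags: np.ndarray
    values: np.ndarray          # r_k = c_k / c_0
    c: np.ndarray               # biased (1/T) autocovariances c_k
    c0: float
    T: int
    mean: float


class HalfWidth(NamedTuple):
    seconds: float
    censored: bool


@dataclass
class FlowField:
    points: np.ndarray          # (M, 2) latent grid points
    velocity: np.ndarray        # (M, 2) one-frame displacement at each point
    states: np.ndarray          # (M,) most-probable discrete state
    input_level: float | np.ndarray | None = None

    @property
    def speed(self) -> np.ndarray:
        """Scalar flow-speed map ||v(x)|| over the grid (the simplified
        velocity-landscape readout)."""
        return np.linalg.norm(self.velocity, axis=1)


class RampDecay(NamedTuple):
    ramp_rate: float            # signal units per second
    decay_tau_s: float
    degenerate: bool


def time_constants(A: np.ndarray, frame_rate: float, state: int = 0) -> TimeConstantSet:
    """Per-dimension time constants from the eigenvalues of ``A``.

    ``|lambda| = 1`` gives an infinite tau (marginally stable / attractor
    direction), flagged; ``lambda = 0`` gives zero tau, flagged.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("dynamics matrix must be square")
    if not np.all(np.isfinite(A)):
        raise ValueError("dynamics matrix must be finite")
    lam = np.linalg.eigvals(A)
    mod = np.abs(lam)
    tau = np.empty_like(mod)
    inf_mask = np.isclose(mod, 1.0, atol=1e-12)
    zero_mask = mod == 0.0
    with np.errstate(divide="ignore"):
        safe = ~(inf_mask | zero_mask)
        tau[safe] = np.abs(1.0 / np.log(mod[safe]))
        tau[inf_mask] = np.inf
        tau[zero_mask] = 0.0
    return TimeConstantSet(
        eigenvalues=lam,
        tau_frames=tau,
        tau_s=tau / frame_rate,
        frame_rate=frame_rate,
        state=state,
        infinite=inf_mask,
        zero=zero_mask,
    )


def params_time_constants(params, frame_rate: float) -> list[TimeConstantSet]:
    """Time constants for every discrete state of an rSLDS, ordered so the
    attractor-expressing state (largest leading tau) comes first."""
    sets = [time_constants(params.As[k], frame_rate, state=k)
            for k in range(params.K)]
    sets.sort(key=lambda s: -np.max(s.tau_frames))
    return sets


def line_attractor_score(taus) -> float:
    """log2 ratio of the largest to second-largest time constant.

    Accepts a TimeConstantSet or any sequence of taus (any time unit — the
    score is scale-free).  Requires at least two finite positive taus.
    """
    if isinstance(taus, TimeConstantSet):
        t = np.asarray(taus.tau_frames, dtype=float)
    else:
        t = np.asarray(taus, dtype=float).ravel()
    t = t[np.isfinite(t) & (t > 0)]
    if t.size < 2:
        raise ValueError("need at least two finite positive time constants")
    t = np.sort(t)
    return float(np.log2(t[-1] / t[-2]))


def autocorrelation(y: np.ndarray, max_lag: int) -> AutocorrFunction:
    """Sample autocorrelation with the biased (1/T) covariance estimator:
    ``c_k = (1/T) sum_{t=1}^{T-k} (y_t - ybar)(y_{t+k} - ybar)``, r_k = c_k/c_0.
    """
    y = np.asarray(y, dtype=float).ravel()
    T = len(y)
    if max_lag >= T:
        raise ValueError("max_lag must be smaller than the series length")
    if not np.all(np.isfinite(y)):
        raise ValueError("series must be finite")
    ybar = y.mean()
    dev = y - ybar
    c0 = float(np.dot(dev, dev) / T)
    if c0 == 0.0:
        raise ValueError("zero-variance series has no autocorrelation")
    full = np.correlate(dev, dev, mode="full")[T - 1:T + max_lag] / T
    r = full / c0
    return AutocorrFunction(lags=np.arange(max_lag + 1), values=r, c=full,
                            c0=c0, T=T, mean=float(ybar))


def autocorr_half_width(acf: AutocorrFunction, frame_rate: float) -> HalfWidth:
    """First lag at which r_k falls to 0.5, linearly interpolated, in seconds.

    If r never reaches 0.5 within the computed lags the value is censored at
    the maximum lag (flagged).
    """
    r = np.asarray(acf.values, dtype=float)
    if not np.isclose(r[0], 1.0):
        raise ValueError("autocorrelation must be normalized (r_0 = 1)")
    below = np.flatnonzero(r <= 0.5)
    if len(below) == 0:
        return HalfWidth(seconds=float(acf.lags[-1] / frame_rate), censored=True)
    i = int(below[0])
    if i == 0:
        return HalfWidth(seconds=0.0, censored=False)
    # linear interpolation between lag i-1 (r > 0.5) and lag i (r <= 0.5)
    frac = (r[i - 1] - 0.5) / (r[i - 1] - r[i])
    lag = (i - 1) + frac
    return HalfWidth(seconds=float(lag / frame_rate), censored=False)


def flow_field(params, grid, input_level=None) -> FlowField:
    """One-frame velocity ``v(x) = A_k x + b_k + B_k u - x`` over a 2-D grid,
    where k is the most-probable discrete state at x under the recurrent
    softmax (averaged over the previous state)."""
    if params.D != 2:
        raise ValueError("flow fields are defined for 2-D latent spaces")
    if isinstance(grid, (tuple, list)) and len(grid) == 2:
        X, Y = np.meshgrid(np.asarray(grid[0]), np.asarray(grid[1]))
        pts = np.column_stack([X.ravel(), Y.ravel()])
    else:
        pts = np.atleast_2d(np.asarray(grid, dtype=float))
        if pts.shape[1] != 2:
            raise ValueError("grid points must be 2-D")
    M = pts.shape[0]
    K = params.K
    # next-state logits averaged over the previous discrete state
    logits = np.einsum("kjd,md->mkj", params.Rs, pts) + params.rs[None]
    mean_logits = logits.mean(axis=1)                       # (M, K)
    states = np.argmax(mean_logits, axis=1)
    u = None
    if input_level is not None:
        u = np.atleast_1d(np.asarray(input_level, dtype=float))
    vel = np.empty_like(pts)
    for k in range(K):
        m = states == k
        if not m.any():
            continue
        drift = pts[m] @ params.As[k].T + params.bs[k]
        if u is not None and params.Bs is not None:
            drift = drift + params.Bs[k] @ u
        vel[m] = drift - pts[m]
    if not np.all(np.isfinite(vel)):
        raise ValueError("non-finite velocity on grid")
    return FlowField(points=pts, velocity=vel, states=states,
                     input_level=input_level)


def ramp_and_decay_metrics(
    x1: np.ndarray,
    events,
    frame_rate: float = 10.0,
    ramp_window_s: float = 10.0,
) -> RampDecay:
    """Ramp rate at intruder entry and decay time constant after removal.

    ``events`` is a list of (start_s, stop_s) bout boundaries or a BoutTable.
    The ramp rate is the least-squares slope of x1 over a fixed window after
    each entry (averaged over events); the decay tau is an exponential fit
    ``a exp(-t/tau) + c`` from each removal to the next event or series end.
    A flat decay segment is flagged degenerate.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    T = len(x1)
    if hasattr(events, "intervals"):
        events = events.intervals()
    events = sorted(events)
    if not events:
        raise ValueError("at least one event is required")
    win = int(round(ramp_window_s * frame_rate))
    slopes = []
    taus = []
    degenerate = False
    for i, (start_s, stop_s) in enumerate(events):
        s0 = int(round(start_s * frame_rate))
        s1 = int(round(stop_s * frame_rate))
        if s0 < 0 or s1 > T:
            raise ValueError("event window exceeds the series")
        hi = s0 + win
        if hi > T:
            raise ValueError("ramp window exceeds the series")
        tt = np.arange(win) / frame_rate
        seg = x1[s0:hi]
        slopes.append(float(np.polyfit(tt, seg, 1)[0]))
        # decay segment: removal to next entry (or series end)
        d1 = int(round(events[i + 1][0] * frame_rate)) if i + 1 < len(events) else T
        dseg = x1[s1:d1]
        if len(dseg) < 5:
            continue
        td = np.arange(len(dseg)) / frame_rate
        amp = dseg[0] - dseg[-1]
        if np.std(dseg) < 1e-12 or abs(amp) < 1e-12:
            degenerate = True
            continue
        p0 = (amp, max(td[-1] / 3.0, 1.0 / frame_rate), dseg[-1])
        try:
            popt, _ = curve_fit(
                lambda t, a, tau, c: a * np.exp(-t / tau) + c,
                td, dseg, p0=p0,
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
            taus.append(float(popt[1]))
        except RuntimeError:
            degenerate = True
    ramp = float(np.mean(slopes)) if slopes else 0.0
    tau = float(np.mean(taus)) if taus else np.nan
    if not taus:
        degenerate = True
    return RampDecay(ramp_rate=ramp, decay_tau_s=tau, degenerate=degenerate)
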