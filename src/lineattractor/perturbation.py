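"""Quantification of targeted-photostimulation experiments in state space.

Simulated holographic activation of selected neurons injects a pulse-shaped
drive into the latent dynamics of a synthetic session (through the transpose
of the emission matrix, so stimulating x1-weighted neurons pushes the slow
latent).  Analyses mirror the in-vivo quantifications: projection of activity
onto a latent dimension, per-ISI means/peaks with integration and saturation
flags, Euclidean displacement in state space relative to baseline, pairwise
influence scores from unitary stimulation, the connectivity fraction, and the
across-session correlation between attractor stability and functional
connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .rslds import LatentTrajectory, ObservedActivity, RSLDSParams, infer_latents

__all__ = [
    "StimProtocol",
    "DisplacementMetrics",
    "InfluenceMatrix",
    "ISITable",
    "simulate_targeted_stim",
    "project_onto_dimension",
    "isi_peak_table",
    "evoked_projection",
    "state_space_displacement",
    "influence_scores",
    "connectivity_fraction",
    "stability_connectivity_correlation",
]


@dataclass
class StimProtocol:
    """Pulse-train photostimulation description.

    Onsets/offsets in seconds; ``isi_s`` is the inter-stimulus interval
    (pulse offset to next onset).  ``targets`` are stimulated cell indices.
    The 50 um exclusion radius conservatively removes potential off-target
    cells from follower analyses; the 15 um off-target radius is the optical
    spillover zone (reporting only).
    """

    onsets_s: np.ndarray
    offsets_s: np.ndarray
    isi_s: float
    pulse_rate_hz: float
    targets: np.ndarray
    gain: float = 1.0
    exclusion_radius_um: float = 50.0
    off_target_radius_um: float = 15.0

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.offsets_s = np.asarray(self.offsets_s, dtype=float)
        self.targets = np.asarray(self.targets, dtype=int)
        if np.any(self.offsets_s < self.onsets_s):
            raise ValueError("pulse offsets must follow onsets")
        if np.any(self.onsets_s[1:] < self.offsets_s[:-1]):
            raise ValueError("pulses must not overlap")
        if self.exclusion_radius_um < 0 or self.off_target_radius_um < 0:
            raise ValueError("radii must be non-negative")

    @property
    def n_pulses(self) -> int:
        return len(self.onsets_s)

    @property
    def isi_windows(self) -> list[tuple[float, float]]:
        """(pulse offset, next onset) per pulse; the last window spans one ISI."""
        wins = []
        for i, off in enumerate(self.offsets_s):
            end = self.onsets_s[i + 1] if i + 1 < self.n_pulses else off + self.isi_s
            wins.append((float(off), float(end)))
        return wins

    def pulse_mask(self, n_frames: int, frame_rate: float) -> np.ndarray:
        m = np.zeros(n_frames, dtype=bool)
        for a, b in zip(self.onsets_s, self.offsets_s):
            m[int(np.floor(a * frame_rate)):int(np.ceil(b * frame_rate))] = True
        return m


@dataclass
class DisplacementMetrics:
    """Per-pulse Euclidean distances in latent space from the baseline point
    to the end of each stimulation (``t_stim_end``) and to the end of the
    following ISI (``t_post_stim``)."""

    d_stim_end: np.ndarray
    d_post_stim: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.d_stim_end < 0) or np.any(self.d_post_stim < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class ISITable:
    """Baseline and per-ISI summary of a projected activity series."""

    baseline_mean: float
    isi_means: np.ndarray
    isi_peaks: np.ndarray
    integration: bool           # strictly increasing ISI means, pulses 1..3
    saturation_pulse: int | None  # first pulse with relative increment < 10%


@dataclass
class InfluenceMatrix:
    """Pairwise influence scores: average evoked z-scored activity of each
    non-targeted follower after unitary stimulation of each target."""

    score: np.ndarray           # (n_targets_idx, n_cells), NaN where masked
    target_ids: np.ndarray
    labels: np.ndarray          # per-cell group label ('x1' / 'x2' / ...)
    masked: np.ndarray          # bool, True where pair excluded
    exclusion_radius_um: float = 50.0

    def pair_scores(self, src: str, dst: str) -> np.ndarray:
        """Unmasked scores for src-group targets onto dst-group followers."""
        rows = np.isin(self.target_ids, np.flatnonzero(self.labels == src))
        cols = self.labels == dst
        block = self.score[np.ix_(rows, cols)]
        mask = self.masked[np.ix_(rows, cols)]
        return block[~mask & np.isfinite(block)]


# ---------------------------------------------------------------------------
# simulated targeted stimulation
# ---------------------------------------------------------------------------

def simulate_targeted_stim(
    session,
    protocol: StimProtocol,
    latent_bound: float | None = 2.5,
    direct_response: float = 1.0,
    drive_scale: float = 0.06,
) -> ObservedActivity:
    """Inject targeted-stimulation drive into a synthetic session.

    The pulse drive enters the latent update through the normalized sum of
    the targeted neurons' emission rows (C^T weighting): stimulating
    x1-weighted cells pushes the slow latent, x2-weighted cells the fast one.
    The line attractor occupies a finite extent of state space, so the drive
    effectiveness shrinks linearly as the stimulation-driven displacement of
    the slow dimension approaches ``latent_bound`` — this is what makes
    integration saturate after a few pulses while leaving the decay time
    constant untouched.  Because the planted dynamics share one dynamics
    matrix across discrete states, the perturbation superposes exactly on the
    unperturbed latents; a zero-gain protocol therefore returns the session's
    activity unchanged.  Targeted cells additionally receive a direct somatic
    response of ``direct_response`` (in units of their activity SD) during
    pulses.
    """
    act = session.activity
    params = session.ground_truth
    N, T = act.y.shape
    fr = act.frame_rate
    if np.any(protocol.targets < 0) or np.any(protocol.targets >= N):
        raise ValueError("unknown target indices")
    if protocol.offsets_s[-1] > T / fr:
        raise ValueError("protocol extends past the session")

    pulse = protocol.pulse_mask(T, fr).astype(float)
    rows = params.C[protocol.targets]
    direction = rows.sum(axis=0)
    nrm = np.linalg.norm(direction)
    if nrm > 0:
        direction = direction / nrm
    A = params.As[0]
    slow_dim = int(np.argmax(np.abs(np.diag(A))))
    dx = np.zeros((params.D, T))
    prev = np.zeros(params.D)
    for t in range(T):
        sat = 1.0
        if latent_bound is not None:
            sat = max(0.0, 1.0 - prev[slow_dim] / latent_bound)
        cur = A @ prev + drive_scale * protocol.gain * direction * pulse[t] * sat
        dx[:, t] = cur
        prev = cur
    y = act.y + params.C @ dx
    if direct_response and protocol.gain != 0:
        sd = act.y[protocol.targets].std(axis=1, keepdims=True)
        y[protocol.targets] += direct_response * sd * pulse[None, :]
    return ObservedActivity(y=y, frame_rate=fr,
                            baseline_window=act.baseline_window)


def evoked_projection(session, protocol: StimProtocol, dim: int,
                      method: str = "posterior", **stim_kwargs) -> np.ndarray:
    """Stimulation-evoked component of the projected activity.

    Projection of the perturbed session minus that of the unperturbed
    session: the evoked-response correction that removes slow background
    drift of the latent state (in vivo the same role is played by averaging
    across sessions)."""
    pert = simulate_targeted_stim(session, protocol, **stim_kwargs)
    p1 = project_onto_dimension(pert, session.ground_truth, dim, method=method)
    p0 = project_onto_dimension(session.activity, session.ground_truth, dim,
                                method=method)
    return p1 - p0


def project_onto_dimension(
    y: ObservedActivity,
    params: RSLDSParams,
    dim: int,
    method: str = "posterior",
    inputs=None,
) -> np.ndarray:
    """Scalar series of activity projected onto latent dimension ``dim``
    (1-based).  ``posterior`` uses smoothed latents under the model;
    ``pinv`` uses the pseudo-inverse emission readout (faster)."""
    if not 1 <= dim <= params.D:
        raise ValueError(f"invalid dimension id {dim}")
    if method == "posterior":
        lat = infer_latents(params, y, inputs=inputs)
        return lat.x[dim - 1]
    if method == "pinv":
        ydat = y.y if isinstance(y, ObservedActivity) else np.asarray(y)
        x = np.linalg.pinv(params.C) @ (ydat - params.d[:, None])
        return x[dim - 1]
    raise ValueError("method must be 'posterior' or 'pinv'")


def isi_peak_table(
    proj: np.ndarray,
    protocol: StimProtocol,
    frame_rate: float = 10.0,
    exclude_s: float = 1.0,
    saturation_frac: float = 0.10,
) -> ISITable:
    """Baseline and per-ISI mean/peak of a projected series.

    The first ``exclude_s`` seconds of each ISI are dropped to avoid
    stimulation transients.  The integration flag requires strictly
    increasing ISI means over the first three pulses; the saturation pulse is
    the first whose ISI-mean increment, relative to the accumulated level
    above baseline, falls below ``saturation_frac``.
    """
    proj = np.asarray(proj, dtype=float).ravel()
    T = len(proj)
    b_end = int(np.floor(protocol.onsets_s[0] * frame_rate))
    baseline = float(proj[:b_end].mean()) if b_end > 0 else float(proj[0])
    means, peaks = [], []
    for (a, b) in protocol.isi_windows:
        lo = int(np.ceil((a + exclude_s) * frame_rate))
        hi = min(int(np.floor(b * frame_rate)), T)
        if hi <= lo:
            raise ValueError("ISI window outside the series")
        seg = proj[lo:hi]
        means.append(float(seg.mean()))
        peaks.append(float(seg.max()))
    means = np.asarray(means)
    peaks = np.asarray(peaks)
    n3 = min(3, len(means))
    levels = np.concatenate([[baseline], means])
    integration = bool(np.all(np.diff(levels[: n3 + 1]) > 0))
    saturation_pulse = None
    for p in range(1, len(means)):
        accumulated = means[p - 1] - baseline
        if accumulated <= 0:
            continue
        if (means[p] - means[p - 1]) / accumulated < saturation_frac:
            saturation_pulse = p + 1
            break
    return ISITable(baseline_mean=baseline, isi_means=means, isi_peaks=peaks,
                    integration=integration, saturation_pulse=saturation_pulse)


def state_space_displacement(
    latents: LatentTrajectory,
    protocol: StimProtocol,
    frame_rate: float = 10.0,
) -> DisplacementMetrics:
    """Euclidean distances from the pre-stimulation baseline point to each
    pulse's stimulation-end and ISI-end points in latent space."""
    x = latents.x
    T = x.shape[1]
    if protocol.isi_windows[-1][1] * frame_rate > T + 1:
        raise ValueError("latents do not cover the protocol")
    t0 = max(int(np.floor(protocol.onsets_s[0] * frame_rate)) - 1, 0)
    base = x[:, t0]
    d_stim, d_post = [], []
    for (on, off), (_, isi_end) in zip(
            zip(protocol.onsets_s, protocol.offsets_s), protocol.isi_windows):
        i_off = min(int(np.floor(off * frame_rate)), T - 1)
        i_end = min(int(np.floor(isi_end * frame_rate)) - 1, T - 1)
        d_stim.append(float(np.linalg.norm(x[:, i_off] - base)))
        d_post.append(float(np.linalg.norm(x[:, i_end] - base)))
    return DisplacementMetrics(d_stim_end=np.asarray(d_stim),
                               d_post_stim=np.asarray(d_post))


# ---------------------------------------------------------------------------
# pairwise influence and connectivity
# ---------------------------------------------------------------------------

def influence_scores(
    y,
    protocol,
    positions,
    labels,
    baseline_window: tuple[int, int] | None = None,
    exclude_s: float = 1.0,
) -> InfluenceMatrix:
    """Pairwise influence scores from unitary-stimulation sessions.

    ``y`` and ``protocol`` may each be a single object or parallel sequences
    (one session per stimulated target; each protocol must have exactly one
    target).  Per neuron, activity is z-scored against the baseline window;
    the score for (target, follower) is the mean z-scored activity of the
    follower over the ISI windows after each pulse.  Self pairs, other
    targeted cells and followers within the exclusion radius of the target
    are masked.  ``positions`` is a PositionTable or DataFrame with
    (x_um, y_um); ``labels`` maps each cell to its dimension group.
    """
    ys = [y] if isinstance(y, ObservedActivity) else list(y)
    prots = [protocol] if isinstance(protocol, StimProtocol) else list(protocol)
    if len(ys) != len(prots):
        raise ValueError("need one protocol per session")
    if positions is None:
        raise ValueError("cell positions are required for the exclusion mask")
    df = positions.table if hasattr(positions, "table") else positions
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    labels = np.asarray(labels)
    N = ys[0].y.shape[0]
    target_ids = []
    scores = np.full((len(prots), N), np.nan)
    masked = np.ones((len(prots), N), dtype=bool)
    for s, (act, prot) in enumerate(zip(ys, prots)):
        if len(prot.targets) != 1:
            raise ValueError("influence scores require unitary (single-target) "
                             "stimulation protocols")
        tgt = int(prot.targets[0])
        target_ids.append(tgt)
        fr = act.frame_rate
        bw = baseline_window or act.baseline_window
        if bw is None:
            bw = (0, int(np.floor(prot.onsets_s[0] * fr)))
        mu = act.y[:, bw[0]:bw[1]].mean(axis=1)
        sd = act.y[:, bw[0]:bw[1]].std(axis=1)
        z = (act.y - mu[:, None]) / np.maximum(sd[:, None], 1e-9)
        cols = []
        for (a, b) in prot.isi_windows:
            lo = int(np.ceil((a + exclude_s) * fr))
            hi = min(int(np.floor(b * fr)), act.y.shape[1])
            if hi > lo:
                cols.append(np.arange(lo, hi))
        idx = np.concatenate(cols)
        sc = z[:, idx].mean(axis=1)
        dist = np.linalg.norm(xy - xy[tgt], axis=1)
        ok = (dist > prot.exclusion_radius_um) & (np.arange(N) != tgt)
        scores[s, ok] = sc[ok]
        masked[s] = ~ok
    return InfluenceMatrix(score=scores, target_ids=np.asarray(target_ids),
                           labels=labels, masked=masked,
                           exclusion_radius_um=prots[0].exclusion_radius_um)


def connectivity_fraction(infl: InfluenceMatrix,
                          src: str = "x1", other: str = "x2") -> float:
    """Fraction of x1->x1 influence scores strictly above the largest
    x1->x2 score (the functional-coupling density estimate)."""
    within = infl.pair_scores(src, src)
    across = infl.pair_scores(src, other)
    if len(within) == 0 or len(across) == 0:
        raise ValueError("both pair classes must be non-empty")
    threshold = float(np.max(across))
    return float(np.mean(within > threshold))


def stability_connectivity_correlation(per_session_tau, per_session_connectivity):
    """OLS relation between per-session attractor time constants and a
    functional-connectivity metric; returns (r_squared, slope, p_value)."""
    tau = np.asarray(per_session_tau, dtype=float)
    conn = np.asarray(per_session_connectivity, dtype=float)
    if tau.shape != conn.shape or tau.size < 3:
        raise ValueError("need equal-length lists with n >= 3")
    if np.std(tau) == 0 or np.std(conn) == 0:
        raise ValueError("degenerate variance")
    res = sps.linregress(tau, conn)
    return float(res.rvalue ** 2), float(res.slope), float(res.pvalue)
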