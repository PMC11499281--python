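"""Synthetic line-attractor sessions and every other pipeline input.

The generator samples population calcium activity from a planted 2-D rSLDS
whose slow (integration) dimension has a time constant in the hundred-second
range and whose fast dimension relaxes within a second — the latent structure
of an approximate line attractor.  A binary intruder-presence input drives the
slow dimension, producing ramps on intruder entry and slow decay after
removal; behavior bouts are derived from the same input schedule, so behavior
annotations and dynamics are consistent by construction.  Cell positions,
pulse-train stimulation protocols, motion-feature regressors, and a
unitary-stimulation cohort with planted pairwise coupling are generated here
as well, so every analysis stage is testable without recordings.

All randomness flows from a single session seed split into named substreams
(latents, emission noise, positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .decoders import BoutTable
from .perturbation import StimProtocol
from .rslds import LatentTrajectory, ObservedActivity, RSLDSParams, sample_rslds

__all__ = [
    "GeneratorConfig",
    "SyntheticSession",
    "PositionTable",
    "generate_line_attractor_session",
    "generate_stim_protocol",
    "generate_cell_positions",
    "generate_motion_features",
    "generate_unitary_stim_cohort",
]


@dataclass
class GeneratorConfig:
    """Conditions of a synthetic line-attractor session.

    Defaults emulate the imaging regime the pipeline targets: 10 Hz calcium
    imaging of 50-150 neurons, a slow integration dimension with a time
    constant of ~100 s and a fast dimension of ~1 s, and emission noise at
    20% of each neuron's signal SD (SNR 5).
    """

    n_neurons: int = 60
    n_frames: int = 3000
    frame_rate: float = 10.0
    slow_tau_s: float = 100.0
    fast_tau_s: float = 1.0
    emission_noise_frac: float = 0.2
    input_schedule: np.ndarray | None = None
    seed: int = 0
    frac_x1: float = 0.4
    frac_x2: float = 0.4
    bout_label: str = "attack"

    def __post_init__(self) -> None:
        vals = (self.n_neurons, self.n_frames, self.frame_rate,
                self.slow_tau_s, self.fast_tau_s, self.emission_noise_frac)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("config values must be finite")
        if self.n_neurons < 2:
            raise ValueError("need at least two neurons")
        if not self.slow_tau_s > self.fast_tau_s > 0:
            raise ValueError("require slow_tau_s > fast_tau_s > 0")
        if self.emission_noise_frac < 0:
            raise ValueError("emission_noise_frac must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class PositionTable:
    """Per-cell (x, y) coordinates in um within a rectangular FOV, with the
    dimension label (x1 / x2 / neither) of each cell."""

    table: pd.DataFrame
    fov_um: tuple[float, float] = (500.0, 500.0)

    def __post_init__(self) -> None:
        req = {"cell_id", "x_um", "y_um", "dim_label"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"position table needs columns {sorted(req)}")
        allowed = {"x1", "x2", "neither"}
        if not set(self.table["dim_label"]).issubset(allowed):
            raise ValueError(f"labels must be in {sorted(allowed)}")
        x, y = self.table["x_um"], self.table["y_um"]
        if (x < 0).any() or (x > self.fov_um[0]).any() \
                or (y < 0).any() or (y > self.fov_um[1]).any():
            raise ValueError("coordinates must lie within the FOV")

    @property
    def labels(self) -> np.ndarray:
        return self.table["dim_label"].to_numpy()


@dataclass
class SyntheticSession:
    """A generated session: activity, ground-truth model, latents, bouts,
    cell positions and the seed that produced them."""

    activity: ObservedActivity
    ground_truth: RSLDSParams
    latents: LatentTrajectory
    bouts: BoutTable
    positions: PositionTable
    config: GeneratorConfig
    seed: int
    input_schedule: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.activity.y.shape[0] != self.ground_truth.C.shape[0]:
            raise ValueError("activity and emission matrix disagree on N")
        if self.latents.n_frames != self.activity.n_frames:
            raise ValueError("latents must cover every frame")


def _default_schedule(n_frames: int) -> np.ndarray:
    """Two intruder-presence bouts at fixed session fractions."""
    u = np.zeros(n_frames)
    u[int(0.20 * n_frames):int(0.45 * n_frames)] = 1.0
    u[int(0.60 * n_frames):int(0.80 * n_frames)] = 1.0
    return u


def _bouts_from_schedule(u: np.ndarray, frame_rate: float,
                         label: str) -> BoutTable:
    edges = np.diff(np.concatenate([[0.0], u, [0.0]]))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    rows = [(s / frame_rate, e / frame_rate) for s, e in zip(starts, stops)]
    return BoutTable.from_intervals(rows, label=label)


def generate_line_attractor_session(config: GeneratorConfig) -> SyntheticSession:
    """Sample a session from a planted line-attractor rSLDS.

    The ground-truth dynamics matrix is diagonal in latent coordinates with
    per-frame eigenvalues ``exp(-1/(tau * frame_rate))`` for the slow and
    fast taus.  Two discrete states (intruder-absent / intruder-present
    ramping) share those dynamics but differ in their recurrent transition
    map, which switches on the slow latent.  The intruder input drives the
    slow dimension with a magnitude calibrated so the slow latent spans about
    three of its stationary SDs over the first bout.  Emission rows have
    disjoint dominant-weight groups for the two dimensions plus a small
    'neither' group, and additive Gaussian emission noise at the configured
    fraction of each neuron's signal SD.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    ss_lat, ss_noise, ss_pos, ss_emit = ss.spawn(4)
    rate = cfg.frame_rate
    lam_slow = np.exp(-1.0 / (cfg.slow_tau_s * rate))
    lam_fast = np.exp(-1.0 / (cfg.fast_tau_s * rate))
    A = np.diag([lam_slow, lam_fast])
    D, K = 2, 2

    u = cfg.input_schedule
    u = _default_schedule(cfg.n_frames) if u is None else np.asarray(u, float)
    if len(u) != cfg.n_frames:
        raise ValueError("input schedule must cover every frame")

    # innovation scales: near-deterministic slow dimension, noisier fast one
    sig_q_slow = 0.015
    sig_q_fast = 0.10
    Q = np.diag([sig_q_slow ** 2, sig_q_fast ** 2])
    stat_sd_slow = sig_q_slow / np.sqrt(1.0 - lam_slow ** 2)

    # input gain: slow latent rises ~3 stationary SDs over the first bout
    edges = np.diff(np.concatenate([[0.0], u]))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(np.diff(np.concatenate([u, [0.0]])) == -1)
    bout_len = int(stops[0] - starts[0] + 1) if len(starts) else cfg.n_frames // 4
    rise_frac = 1.0 - lam_slow ** bout_len
    b_in = 3.0 * stat_sd_slow * (1.0 - lam_slow) / max(rise_frac, 1e-9)
    Bs = np.tile(np.array([[b_in], [0.0]]), (K, 1, 1))

    # recurrent transition map: state 2 when the slow latent is high
    x_half = 1.5 * stat_sd_slow
    Rs = np.tile(np.array([[0.0, 0.0], [4.0 / max(x_half, 1e-9), 0.0]]),
                 (K, 1, 1))
    rs = np.tile(np.array([0.0, -4.0]), (K, 1))

    rng_emit = np.random.default_rng(ss_emit)
    n1 = int(round(cfg.frac_x1 * cfg.n_neurons))
    n2 = int(round(cfg.frac_x2 * cfg.n_neurons))
    C = np.zeros((cfg.n_neurons, D))
    C[:n1, 0] = rng_emit.uniform(0.5, 1.5, n1)
    C[n1:n1 + n2, 1] = rng_emit.uniform(0.5, 1.5, n2)
    n_rest = cfg.n_neurons - n1 - n2
    if n_rest > 0:
        C[n1 + n2:] = rng_emit.uniform(0.0, 0.05, (n_rest, D))
    d = rng_emit.normal(0.0, 0.1, cfg.n_neurons)
    cell_labels = np.array(["x1"] * n1 + ["x2"] * n2 + ["neither"] * n_rest)

    params0 = RSLDSParams(
        As=np.tile(A, (K, 1, 1)), bs=np.zeros((K, D)),
        Qs=np.tile(Q, (K, 1, 1)), Rs=Rs, rs=rs,
        C=C, d=d, S=np.zeros(cfg.n_neurons), Bs=Bs,
    )
    latents, _ = sample_rslds(params0, cfg.n_frames, inputs=u[None, :],
                              seed=ss_lat)
    signal = C @ latents.x
    sig_sd = signal.std(axis=1)
    noise_sd = cfg.emission_noise_frac * sig_sd
    rng_noise = np.random.default_rng(ss_noise)
    y = signal + d[:, None]
    if cfg.emission_noise_frac > 0:
        y = y + noise_sd[:, None] * rng_noise.standard_normal(y.shape)
    params0.S = np.maximum(noise_sd ** 2, 0.0)

    activity = ObservedActivity(y=y, frame_rate=rate)
    bouts = _bouts_from_schedule(u, rate, cfg.bout_label)
    positions = generate_cell_positions(cfg.n_neurons, clustered=False,
                                        seed=ss_pos, labels=cell_labels)
    return SyntheticSession(activity=activity, ground_truth=params0,
                            latents=latents, bouts=bouts, positions=positions,
                            config=cfg, seed=cfg.seed, input_schedule=u)


def generate_stim_protocol(
    n_pulses: int,
    isi_s: float,
    pulse_dur_s: float,
    pulse_rate_hz: float,
    targets,
    start_s: float = 0.0,
    gain: float = 1.0,
) -> StimProtocol:
    """Pulse-train protocol with onsets spaced ``pulse_dur_s + isi_s`` apart
    (e.g. 2 s pulses at 20 Hz with a 20 s interstimulus interval)."""
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    if not isi_s > pulse_dur_s >= 0:
        raise ValueError("require isi_s > pulse_dur_s >= 0 (non-overlapping "
                         "pulses)")
    period = pulse_dur_s + isi_s
    onsets = start_s + period * np.arange(n_pulses)
    return StimProtocol(onsets_s=onsets, offsets_s=onsets + pulse_dur_s,
                        isi_s=isi_s, pulse_rate_hz=pulse_rate_hz,
                        targets=np.asarray(targets, dtype=int), gain=gain)


def generate_cell_positions(
    n: int,
    fov_um: tuple[float, float] = (500.0, 500.0),
    clustered: bool = False,
    seed=0,
    labels=None,
    cluster_sd_um: float = 30.0,
) -> PositionTable:
    """Cell centroids in a rectangular FOV.

    Uniform scatter by default (positions independent of dimension labels,
    matching the absence of spatial clustering in the data the pipeline
    emulates); with ``clustered=True`` the x1 and x2 groups are drawn from
    two well-separated Gaussian clusters.
    """
    if n < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    if labels is None:
        half = n // 2
        labels = np.array(["x1"] * half + ["x2"] * (n - half))
    labels = np.asarray(labels)
    if clustered:
        centers = {"x1": np.array([0.25 * fov_um[0], 0.5 * fov_um[1]]),
                   "x2": np.array([0.75 * fov_um[0], 0.5 * fov_um[1]])}
        xy = np.empty((n, 2))
        for i, lab in enumerate(labels):
            c = centers.get(lab)
            if c is None:
                xy[i] = rng.uniform([0, 0], fov_um)
            else:
                pt = rng.normal(c, cluster_sd_um)
                xy[i] = np.clip(pt, 0, fov_um)
    else:
        xy = rng.uniform([0, 0], fov_um, size=(n, 2))
    df = pd.DataFrame({"cell_id": np.arange(n), "x_um": xy[:, 0],
                       "y_um": xy[:, 1], "dim_label": labels})
    return PositionTable(table=df, fov_um=fov_um)


def generate_motion_features(
    n_frames: int,
    n_dims: int = 10,
    seed=0,
    frame_rate: float = 10.0,
    smooth_s: float = 0.5,
) -> np.ndarray:
    """Smooth stochastic motion regressors: low-pass-filtered Gaussian noise,
    unit variance per dimension; (n_dims, n_frames).  Synthetic stand-ins for
    the leading principal components of video-motion SVDs."""
    if n_dims < 1:
        raise ValueError("need at least one dimension")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_dims, n_frames))
    z = gaussian_filter1d(z, sigma=smooth_s * frame_rate, axis=1)
    z = z - z.mean(axis=1, keepdims=True)
    z = z / np.maximum(z.std(axis=1, keepdims=True), 1e-12)
    return z


def generate_unitary_stim_cohort(
    n_x1: int = 15,
    n_x2: int = 10,
    coupling_density: float = 0.36,
    coupled_amp_z: float = 3.0,
    cross_amp_z: float = 0.25,
    baseline_s: float = 60.0,
    n_pulses: int = 4,
    isi_s: float = 20.0,
    frame_rate: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Unitary-stimulation cohort with planted pairwise functional coupling.

    For each x1 target a separate session is synthesized: a baseline period
    followed by a pulse train.  Directed x1->x1 pairs are coupled with
    probability ``coupling_density``; coupled followers respond during ISIs
    with a slowly-decaying transient of ``coupled_amp_z`` baseline-SD units,
    x2 followers with at most ``cross_amp_z`` units, and uncoupled pairs with
    noise only.  Returns ``(sessions, protocols, positions, labels)`` ready
    for :func:`lineattractor.perturbation.influence_scores`.
    """
    if not 0.0 <= coupling_density <= 1.0:
        raise ValueError("coupling density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_x1 + n_x2
    labels = np.array(["x1"] * n_x1 + ["x2"] * n_x2)
    positions = generate_cell_positions(
        n, fov_um=(1000.0, 1000.0), clustered=False,
        seed=np.random.SeedSequence([seed, 1]), labels=labels)
    # spread cells out so exclusion radii leave most pairs analyzable
    coupled = rng.random((n_x1, n_x1)) < coupling_density
    np.fill_diagonal(coupled, False)

    dur_s = baseline_s + n_pulses * (isi_s + 2.0) + 5.0
    T = int(round(dur_s * frame_rate))
    sessions, protocols = [], []
    kernel_tau_s = 8.0  # slow decay of evoked activity within the ISI
    tt = np.arange(T) / frame_rate
    for ti in range(n_x1):
        prot = generate_stim_protocol(n_pulses, isi_s, 2.0, 20.0, [ti],
                                      start_s=baseline_s)
        resp = np.zeros(T)
        for on, off in zip(prot.onsets_s, prot.offsets_s):
            m = tt >= off
            resp[m] += np.exp(-(tt[m] - off) / kernel_tau_s)
        resp = np.clip(resp, 0.0, 1.5)
        y = noise_sd * rng.standard_normal((n, T))
        for j in range(n_x1):
            if j == ti:
                y[j] += 4.0 * noise_sd * resp
            elif coupled[ti, j]:
                y[j] += coupled_amp_z * noise_sd * resp
        for j in range(n_x1, n):
            amp = rng.uniform(0.0, cross_amp_z)
            y[j] += amp * noise_sd * resp
        act = ObservedActivity(y=y, frame_rate=frame_rate,
                               baseline_window=(0, int(baseline_s * frame_rate)))
        sessions.append(act)
        protocols.append(prot)
    return sessions, protocols, positions, labels
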