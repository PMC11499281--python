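"""Mechanistic spiking model: excitatory LIF networks with an integration
subnetwork.

A population of current-based leaky integrate-and-fire neurons (membrane time
constant tau_m = 20 ms, threshold theta = 0.1, reset to zero) is recurrently
coupled through synaptic currents p_i with conductance time constant tau_s.
A designated subnetwork (N_p = 200 of N = 1000 neurons) carries denser random
connectivity of density sigma; its weights are U(0, 1/sqrt(N_p)) while
background weights are U(0, 1/sqrt(N)).  For the linearized rate network the
slowest decay mode has time constant

    tau_n = tau_s / |1 - lambda_max|

where lambda_max is the largest eigenvalue modulus of the weight matrix;
lambda_max >= 1 means runaway excitation.  Fast feedback inhibition is a
single graded unit driven by the population-mean rate (tau_I = 50 ms) that
subtracts g_inh * I_inh from every membrane.  Firing rates are convolved with
an exponential calcium kernel for comparison with imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "LIFNetworkConfig",
    "WeightMatrix",
    "NetworkSimResult",
    "PhaseDiagram",
    "build_weight_matrix",
    "analytic_network_tau",
    "NetworkTau",
    "simulate_lif",
    "simulate_lif_inhibition",
    "make_pulse_input",
    "phase_diagram",
    "rate_to_calcium",
]


@dataclass
class LIFNetworkConfig:
    """Parameters of the excitatory LIF network with integration subnetwork.

    Times in seconds.  ``sigma`` is the subnetwork connection density;
    ``background_density`` the density everywhere else (the network outside
    the subnetwork contributes only weakly to the spectrum at the 1% default,
    so the subnetwork dominates the slow mode).
    """

    N: int = 1000
    N_p: int = 200
    sigma: float = 0.10
    background_density: float = 0.01
    tau_m: float = 0.020
    theta: float = 0.1
    g: float = 1.0
    tau_s: float = 20.0
    g_inh: float = 0.0
    tau_I: float = 0.050
    dt: float = 0.001
    noise_scale: float = 0.2        # eta ~ N(0,1)/5 added to the membrane each step

    def __post_init__(self) -> None:
        if self.N_p > self.N:
            raise ValueError("subnetwork cannot exceed the network size")
        for name in ("tau_m", "tau_s", "tau_I", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sigma", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dt >= min(self.tau_m, self.tau_I):
            raise ValueError("dt must be smaller than the fastest time constant")


@dataclass
class WeightMatrix:
    """Non-negative synaptic weights with subnetwork index set and the
    largest eigenvalue modulus."""

    W: sparse.csr_matrix
    sub_idx: np.ndarray
    lam_max: float

    def __post_init__(self) -> None:
        if (self.W.diagonal() != 0).any():
            raise ValueError("self-connections are not allowed")


class NetworkTau(NamedTuple):
    tau_n: float        # seconds; inf when unstable
    lam_max: float
    unstable: bool


@dataclass
class PhaseDiagram:
    """Mean analytic network time constant over a density x kinetics grid."""

    sigma_grid: np.ndarray
    tau_s_grid: np.ndarray
    tau_n: np.ndarray           # (n_tau_s, n_sigma), mean over seeds
    unstable: np.ndarray        # bool mask, True where any seed had lam >= 1
    lam_max: np.ndarray         # (n_sigma, n_seeds)


@dataclass
class NetworkSimResult:
    """Spiking simulation output.

    Spikes are stored as event lists; ``binned_rates`` are per-neuron firing
    rates (spikes/s) binned at ``bin_rate`` Hz, convenient for calcium
    convolution.  ``p_sub``/``p_bg`` are mean synaptic currents of the
    subnetwork and background populations at every step.
    """

    spike_times_s: np.ndarray
    spike_neurons: np.ndarray
    pop_rate: np.ndarray            # population-mean instantaneous rate per step
    binned_rates: np.ndarray        # (N, n_bins), spikes/s
    bin_rate: float
    p_sub: np.ndarray
    p_bg: np.ndarray
    I_inh: np.ndarray
    dt: float
    duration: float
    n_neurons: int
    sub_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def raster(self) -> sparse.csr_matrix:
        """Binary spike raster (N x timesteps) as a sparse matrix."""
        steps = int(round(self.duration / self.dt))
        t_idx = np.clip((self.spike_times_s / self.dt).round().astype(int),
                        0, steps - 1)
        data = np.ones(len(t_idx), dtype=np.uint8)
        return sparse.csr_matrix(
            (data, (self.spike_neurons, t_idx)),
            shape=(self.n_neurons, steps),
        )


# ---------------------------------------------------------------------------
# connectivity and the analytic time constant
# ---------------------------------------------------------------------------

def build_weight_matrix(cfg: LIFNetworkConfig, seed: int = 0,
                        lam_mode: str = "full") -> WeightMatrix:
    """Sample the synaptic weight matrix and compute lambda_max.

    Subnetwork block entries (first N_p indices) are nonzero with probability
    ``sigma`` and drawn U(0, 1/sqrt(N_p)); all other entries are nonzero with
    probability ``background_density`` and drawn U(0, 1/sqrt(N)).  The
    diagonal is zero.  ``lam_mode`` selects whether lambda_max is computed on
    the full matrix (default) or the subnetwork block alone.
    """
    rng = np.random.default_rng(seed)
    N, Np = cfg.N, cfg.N_p
    sub_idx = np.arange(Np)

    def _sample_block(n_rows, n_cols, density, scale):
        if density == 0.0:
            return sparse.csr_matrix((n_rows, n_cols))
        mask = rng.random((n_rows, n_cols)) < density
        vals = rng.uniform(0.0, scale, size=(n_rows, n_cols))
        return sparse.csr_matrix(np.where(mask, vals, 0.0))

    bg = _sample_block(N, N, cfg.background_density, 1.0 / np.sqrt(N))
    sub = _sample_block(Np, Np, cfg.sigma, 1.0 / np.sqrt(Np))
    W = sparse.lil_matrix(bg)
    W[:Np, :Np] = sub.toarray()
    W = W.tocsr()
    W.setdiag(0.0)
    W.eliminate_zeros()

    if lam_mode == "full":
        target = W
    elif lam_mode == "subnetwork":
        target = W[:Np, :Np]
    else:
        raise ValueError("lam_mode must be 'full' or 'subnetwork'")
    lam = _leading_eigenvalue(target)
    return WeightMatrix(W=W, sub_idx=sub_idx, lam_max=lam)


def _leading_eigenvalue(W, tol: float = 1e-8, max_iter: int = 5000) -> float:
    """Largest eigenvalue modulus by power iteration (non-negative matrix,
    so the leading eigenvalue is real and the iteration converges), with a
    dense eigensolver fallback."""
    n = W.shape[0]
    if W.nnz == 0:
        return 0.0
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(max_iter):
        w = W @ v
        nw = np.linalg.norm(w)
        if nw == 0.0:
            return 0.0
        w /= nw
        lam_new = float(w @ (W @ w))
        if abs(lam_new - lam) < tol * max(1.0, abs(lam_new)):
            return lam_new
        lam, v = lam_new, w
    return float(np.max(np.abs(np.linalg.eigvals(W.toarray()))))


def analytic_network_tau(W: WeightMatrix | float, tau_s: float) -> NetworkTau:
    """Network time constant tau_n = tau_s / |1 - lambda_max|.

    Accepts a WeightMatrix or a bare lambda_max.  lambda_max >= 1 is flagged
    unstable (runaway excitation, no finite time constant).
    """
    lam = W.lam_max if isinstance(W, WeightMatrix) else float(W)
    if lam >= 1.0:
        return NetworkTau(tau_n=np.inf, lam_max=lam, unstable=True)
    return NetworkTau(tau_n=tau_s / abs(1.0 - lam), lam_max=lam, unstable=False)


# ---------------------------------------------------------------------------
# spiking simulation
# ---------------------------------------------------------------------------

def make_pulse_input(
    n_pulses: int = 4,
    isi_s: float = 20.0,
    frac_driven: float = 0.25,
    seed: int = 0,
    pulse_dur_s: float = 2.0,
    amplitude: float = 0.3,
    pre_s: float = 10.0,
    dt: float = 0.001,
    N: int = 1000,
    smooth_s: float = 0.1,
):
    """Smoothed step-pulse input train and per-neuron input weights.

    Returns ``(s, w, duration)`` where ``s`` is the input series over all
    timesteps, ``w`` the input weight vector (1 for the randomly driven
    ``frac_driven`` subset, 0 elsewhere) and ``duration`` the covered time.
    The step train is smoothed with a 100 ms Gaussian; the amplitude default
    is set so driven neurons spike during pulses (steady-state membrane
    drive amplitude > threshold).
    """
    if not 0.0 < frac_driven <= 1.0:
        raise ValueError("frac_driven must lie in (0, 1]")
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    duration = pre_s + n_pulses * (pulse_dur_s + isi_s)
    steps = int(round(duration / dt))
    s = np.zeros(steps)
    for p in range(n_pulses):
        on = pre_s + p * (pulse_dur_s + isi_s)
        a, b = int(round(on / dt)), int(round((on + pulse_dur_s) / dt))
        s[a:b] = amplitude
    s = gaussian_filter1d(s, sigma=smooth_s / dt)
    rng = np.random.default_rng(seed)
    w = np.zeros(N)
    driven = rng.choice(N, size=max(int(round(frac_driven * N)), 1),
                        replace=False)
    w[driven] = 1.0
    return s, w, duration


def _simulate(cfg: LIFNetworkConfig, W: WeightMatrix, duration: float,
              seed: int, inputs, g_inh: float,
              bin_rate: float = 10.0) -> NetworkSimResult:
    N = cfg.N
    dt = cfg.dt
    steps = int(round(duration / dt))
    if steps < 1:
        raise ValueError("duration must cover at least one timestep")
    if inputs is None:
        s = np.zeros(steps)
        w_in = np.zeros(N)
    else:
        s, w_in = inputs
        s = np.asarray(s, dtype=float)
        w_in = np.asarray(w_in, dtype=float)
        if len(s) < steps:
            s = np.pad(s, (0, steps - len(s)))
    rng = np.random.default_rng(seed)
    Wc = W.W.tocsr()
    sub = W.sub_idx
    bg_mask = np.ones(N, dtype=bool)
    bg_mask[sub] = False

    x = np.zeros(N)
    p = np.zeros(N)
    r = np.zeros(N)
    I_inh = 0.0
    am, asn, aI = dt / cfg.tau_m, dt / cfg.tau_s, dt / cfg.tau_I

    n_bins = int(np.ceil(steps * dt * bin_rate))
    counts = np.zeros((N, n_bins))
    pop_rate = np.empty(steps)
    p_sub = np.empty(steps)
    p_bg = np.empty(steps)
    I_tr = np.empty(steps)
    spk_t: list[np.ndarray] = []
    spk_i: list[np.ndarray] = []

    for t in range(steps):
        # eta ~ N(0,1)/5 added to the membrane at every step: this sets the
        # spontaneous spiking regime on which recurrence operates
        eta = cfg.noise_scale * rng.standard_normal(N)
        drive = cfg.g * (Wc @ p - g_inh * I_inh) + w_in * s[t]
        x += am * (-x + drive) + eta
        spk = x > cfg.theta
        x[spk] = 0.0
        r[:] = 0.0
        r[spk] = 1.0
        if np.any(~np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite membrane state at t = {t * dt:.3f} s")
        p += asn * (-p + r)
        I_inh += aI * (-I_inh + r.mean())
        pop_rate[t] = r.mean()
        p_sub[t] = p[sub].mean() if len(sub) else 0.0
        p_bg[t] = p[bg_mask].mean() if bg_mask.any() else 0.0
        I_tr[t] = I_inh
        if spk.any():
            ids = np.flatnonzero(spk)
            spk_i.append(ids)
            spk_t.append(np.full(len(ids), t * dt))
            counts[ids, min(int(t * dt * bin_rate), n_bins - 1)] += 1.0
    rates = counts * bin_rate
    return NetworkSimResult(
        spike_times_s=np.concatenate(spk_t) if spk_t else np.empty(0),
        spike_neurons=np.concatenate(spk_i) if spk_i else np.empty(0, dtype=int),
        pop_rate=pop_rate, binned_rates=rates, bin_rate=bin_rate,
        p_sub=p_sub, p_bg=p_bg, I_inh=I_tr, dt=dt, duration=duration,
        n_neurons=N, sub_idx=sub,
    )


def simulate_lif(cfg: LIFNetworkConfig, W: WeightMatrix, duration: float,
                 seed: int = 0, inputs=None, bin_rate: float = 10.0
                 ) -> NetworkSimResult:
    """Euler simulation of the purely excitatory LIF network.

    ``inputs`` is an optional ``(s, w)`` pair of input series and per-neuron
    input weights (see make_pulse_input).  Gaussian noise scaled by the
    configured factor is added directly to every membrane at every step,
    which sets the spontaneous firing regime.
    """
    return _simulate(cfg, W, duration, seed, inputs, g_inh=0.0,
                     bin_rate=bin_rate)


def simulate_lif_inhibition(cfg: LIFNetworkConfig, W: WeightMatrix,
                            duration: float, seed: int = 0, inputs=None,
                            bin_rate: float = 10.0) -> NetworkSimResult:
    """LIF simulation with fast feedback inhibition: a single graded unit
    integrates the population-mean rate (tau_I) and subtracts
    ``g_inh * I_inh`` from every membrane.  With ``g_inh = 0`` the trajectory
    is identical to :func:`simulate_lif` under a shared seed."""
    if cfg.g_inh < 0:
        raise ValueError("g_inh must be non-negative")
    return _simulate(cfg, W, duration, seed, inputs, g_inh=cfg.g_inh,
                     bin_rate=bin_rate)


def phase_diagram(sigma_grid, tau_s_grid, cfg: LIFNetworkConfig | None = None,
                  seeds: int = 20, seed0: int = 0,
                  lam_mode: str = "full") -> PhaseDiagram:
    """Analytic tau_n over a subnetwork-density x synaptic-kinetics grid.

    lambda_max depends only on the connectivity, so it is sampled once per
    (density, seed) and reused across the tau_s rows.  A cell is masked
    unstable when any seed reaches lambda_max >= 1 (mean tau_n diverges).
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    tau_s_grid = np.asarray(tau_s_grid, dtype=float)
    if sigma_grid.size == 0 or tau_s_grid.size == 0:
        raise ValueError("grids must be non-empty")
    base = cfg or LIFNetworkConfig()
    lam = np.empty((len(sigma_grid), seeds))
    for i, sg in enumerate(sigma_grid):
        c = LIFNetworkConfig(N=base.N, N_p=base.N_p, sigma=float(sg),
                             background_density=base.background_density,
                             tau_s=base.tau_s)
        for s in range(seeds):
            lam[i, s] = build_weight_matrix(c, seed=seed0 + s,
                                            lam_mode=lam_mode).lam_max
    unstable_sigma = (lam >= 1.0).any(axis=1)
    tau_n = np.empty((len(tau_s_grid), len(sigma_grid)))
    for j, ts in enumerate(tau_s_grid):
        with np.errstate(divide="ignore"):
            tn = ts / np.abs(1.0 - lam)
        tn[lam >= 1.0] = np.inf
        tau_n[j] = tn.mean(axis=1)
    unstable = np.broadcast_to(unstable_sigma[None, :], tau_n.shape).copy()
    return PhaseDiagram(sigma_grid=sigma_grid, tau_s_grid=tau_s_grid,
                        tau_n=tau_n, unstable=unstable, lam_max=lam)


def rate_to_calcium(rates: np.ndarray, kernel_tau: float = 1.5,
                    frame_rate: float = 10.0, dt: float | None = None,
                    normalize: bool = False) -> np.ndarray:
    """Causal exponential-kernel convolution of firing rates, downsampled to
    the imaging frame rate.

    ``rates`` is (N, T) or (T,) in spikes/s sampled at interval ``dt``
    (defaults to 1/frame_rate, i.e. rates already binned at the frame rate).
    The kernel is exp(-t/tau): a leaky integrator of rate, so a constant rate
    rho plateaus at rho * kernel_tau and a unit spike decays by e^-1 after
    one tau.  ``normalize=True`` divides by kernel_tau (unit-integral kernel,
    plateau rho).
    """
    if kernel_tau <= 0:
        raise ValueError("kernel_tau must be positive")
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if dt is None:
        dt = 1.0 / frame_rate
    decay = np.exp(-dt / kernel_tau)
    # recursive exponential filter: c_t = decay * c_{t-1} + dt * rate_t
    from scipy.signal import lfilter
    ca = lfilter([dt], [1.0, -decay], rates, axis=1)
    stride = max(int(round(1.0 / (frame_rate * dt))), 1)
    ca = ca[:, stride - 1::stride]
    if normalize:
        ca = ca / kernel_tau
    return ca if ca.shape[0] > 1 else ca[0]
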