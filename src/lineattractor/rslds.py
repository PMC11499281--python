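"""Recurrent switching linear dynamical systems (rSLDS) for neural population data.

The generative model couples three sets of variables:

* discrete states ``z_t in {1..K}`` whose transitions depend recurrently on the
  continuous latent position through a softmax link,
  ``p(z_{t+1} | z_t = k, x_t) = softmax(R_k x_t + r_k)``;
* continuous latents ``x_t = A_{z_t} x_{t-1} + b_{z_t} + B_{z_t} u_t + eps_t``
  with state-specific linear-Gaussian dynamics, ``eps_t ~ N(0, Q_{z_t})``;
* linear-Gaussian emissions ``y_t = C x_t + d + delta_t``, ``delta_t ~ N(0, S)``
  with diagonal observation covariance ``S``.

Fitting uses structured variational EM: the posterior is factorized as
``q(z) q(x)`` where ``q(x)`` is a Gaussian with block-tridiagonal precision
(chain-structured, smoothed exactly given the discrete-state marginals) and
``q(z)`` is a Markov chain obtained by forward-backward given the continuous
posterior means.  M-steps are closed-form weighted regressions, except the
recurrent softmax parameters which are refit by multinomial logistic
regression.  The emission matrix is initialized by factor analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import subspace_angles
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.decomposition import FactorAnalysis
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ObservedActivity",
    "RSLDSParams",
    "LatentTrajectory",
    "FitDiagnostics",
    "sample_rslds",
    "fit_rslds",
    "infer_latents",
    "cross_validated_r2",
    "forward_simulate",
    "dimension_weights",
    "select_top_neurons",
    "subspace_angle",
]

_QFLOOR = 1e-8  # innovation-variance floor keeps smoother precisions finite
_SFLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ObservedActivity:
    """Population calcium activity, neurons x frames (dF/F or z-scored).

    Parameters
    ----------
    y : ndarray, shape (N, T)
    frame_rate : float
        Acquisition rate in Hz.
    baseline_window : (int, int) or None
        Frame interval treated as pre-stimulation baseline for z-scoring.
    """

    y: np.ndarray
    frame_rate: float = 10.0
    baseline_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("activity must be a 2-D (neurons x frames) array")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("activity contains non-finite entries")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_neurons(self) -> int:
        return self.y.shape[0]

    @property
    def n_frames(self) -> int:
        return self.y.shape[1]


@dataclass
class RSLDSParams:
    """Full rSLDS parameter set theta = {A_k, b_k, Q_k, R_k, r_k, C, d, S, B_k}.

    Shapes: ``As (K,D,D)``, ``bs (K,D)``, ``Qs (K,D,D)``, ``Rs (K,K,D)``,
    ``rs (K,K)``, ``C (N,D)``, ``d (N,)``, ``S (N,)`` (diagonal observation
    variances), optional ``Bs (K,D,U)``.  ``Rs[k]``/``rs[k]`` parameterize the
    next-state softmax conditioned on the current state being ``k``.
    """

    As: np.ndarray
    bs: np.ndarray
    Qs: np.ndarray
    Rs: np.ndarray
    rs: np.ndarray
    C: np.ndarray
    d: np.ndarray
    S: np.ndarray
    Bs: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("As", "bs", "Qs", "Rs", "rs", "C", "d", "S"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.Bs is not None:
            self.Bs = np.asarray(self.Bs, dtype=float)
        K, D, _ = self.As.shape
        if self.K < 1 or self.D < 1:
            raise ValueError("K and D must be >= 1")
        for k in range(K):
            if not _is_psd(self.Qs[k]):
                raise ValueError(f"Q[{k}] must be symmetric positive semi-definite")
        if np.any(self.S < 0):
            raise ValueError("observation variances must be non-negative")

    @property
    def K(self) -> int:
        return self.As.shape[0]

    @property
    def D(self) -> int:
        return self.As.shape[1]

    @property
    def N(self) -> int:
        return self.C.shape[0]

    @property
    def U(self) -> int:
        return 0 if self.Bs is None else self.Bs.shape[2]

    def transition_probs(self, k: int, x: np.ndarray) -> np.ndarray:
        """Next-state probabilities softmax(R_k x + r_k); rows sum to one."""
        logits = self.Rs[k] @ np.asarray(x, dtype=float) + self.rs[k]
        logits = logits - logits.max()
        p = np.exp(logits)
        return p / p.sum()


@dataclass
class LatentTrajectory:
    """Continuous latents x (D x T) and discrete states z (T,), z in 0..K-1."""

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.z = np.asarray(self.z, dtype=int)
        if self.x.shape[1] != self.z.shape[0]:
            raise ValueError("latents and discrete states must have equal length")

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]


@dataclass
class FitDiagnostics:
    """Optimization trace and model-quality summaries for one rSLDS fit."""

    elbo_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    n_iter: int = 0
    cv_r2: float | None = None          # percent
    forward_sim_r2: float | None = None  # percent
    fold_bounds: list[tuple[int, int]] | None = None


def _is_psd(M: np.ndarray, tol: float = 1e-8) -> bool:
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        return False
    w = np.linalg.eigvalsh((M + M.T) / 2.0)
    return bool(np.all(w >= -tol * max(1.0, abs(w).max())))


def _as_inputs(inputs, T: int) -> np.ndarray | None:
    if inputs is None:
        return None
    u = np.asarray(inputs, dtype=float)
    if u.ndim == 1:
        u = u[None, :]
    if u.shape[1] != T:
        raise ValueError("input series length must equal the number of frames")
    return u


# ---------------------------------------------------------------------------
# generative sampling
# ---------------------------------------------------------------------------

def sample_rslds(
    params: RSLDSParams,
    T: int,
    inputs=None,
    seed: int = 0,
    x0: np.ndarray | None = None,
    z0: int = 0,
) -> tuple[LatentTrajectory, ObservedActivity]:
    """Sample latents and observations from the generative model.

    ``x0`` is the pre-series latent state; the first returned frame is
    ``x_1 = A_{z_1} x0 + b_{z_1} + ...``.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = np.random.default_rng(seed)
    D, K, N = params.D, params.K, params.N
    u = _as_inputs(inputs, T)
    x_prev = np.zeros(D) if x0 is None else np.asarray(x0, dtype=float)
    z_prev = int(z0)

    # matrix square roots via eigendecomposition so exactly-zero innovation
    # covariances sample noise-free
    Qchol = []
    for k in range(K):
        wq, Vq = np.linalg.eigh((params.Qs[k] + params.Qs[k].T) / 2.0)
        Qchol.append(Vq * np.sqrt(np.maximum(wq, 0.0)))
    Qchol = np.stack(Qchol)
    s_sd = np.sqrt(params.S)

    x = np.empty((D, T))
    z = np.empty(T, dtype=int)
    for t in range(T):
        p = params.transition_probs(z_prev, x_prev)
        zt = int(rng.choice(K, p=p)) if K > 1 else 0
        mean = params.As[zt] @ x_prev + params.bs[zt]
        if u is not None and params.Bs is not None:
            mean = mean + params.Bs[zt] @ u[:, t]
        xt = mean + Qchol[zt] @ rng.standard_normal(D)
        x[:, t] = xt
        z[t] = zt
        x_prev, z_prev = xt, zt

    y = params.C @ x + params.d[:, None] + s_sd[:, None] * rng.standard_normal((N, T))
    lat = LatentTrajectory(x=x, z=z)
    return lat, ObservedActivity(y=y)


# ---------------------------------------------------------------------------
# structured variational E-step: Gaussian chain smoother (information form)
# ---------------------------------------------------------------------------

def _chain_smoother(y, u, params: RSLDSParams, w):
    """Smooth q(x) given discrete-state marginals w (T, K).

    Returns means ``mu (T,D)``, marginal covariances ``Sig (T,D,D)``,
    lag-one cross-covariances ``Cross (T-1,D,D)`` with
    ``Cross[t] = Cov(x_t, x_{t+1})``, and the Gaussian entropy of q(x).
    """
    N, T = y.shape
    D, K = params.D, params.K
    Qinv = np.stack([np.linalg.inv(params.Qs[k] + _QFLOOR * np.eye(D))
                     for k in range(K)])
    Sinv = 1.0 / np.maximum(params.S, _SFLOOR)
    CtSi = params.C.T * Sinv[None, :]           # (D, N)
    J_emis = CtSi @ params.C                    # (D, D)
    h_emis = CtSi @ (y - params.d[:, None])     # (D, T)

    # state-averaged dynamics blocks per transition t-1 -> t  (t = 1..T-1)
    AtQi = np.einsum("kji,kjl->kil", params.As, Qinv)       # A_k' Qinv_k
    AtQiA = np.einsum("kij,kjl->kil", AtQi, params.As)      # A_k' Qinv_k A_k
    wt = w[1:]                                              # (T-1, K)
    J11 = np.einsum("tk,kij->tij", wt, AtQiA)               # (T-1,D,D)
    J12 = -np.einsum("tk,kij->tij", wt, AtQi)               # coupling x_{t-1},x_t
    J22 = np.einsum("tk,kij->tij", wt, Qinv)
    m = np.repeat(params.bs[None, :, :], T, axis=0)         # (T,K,D)
    if u is not None and params.Bs is not None:
        m = m + np.einsum("kdu,ut->tkd", params.Bs, u)
    mw = m[1:]                                              # drive into frame t
    h1 = -np.einsum("tk,kij,tkj->ti", wt, AtQi, mw)
    h2 = np.einsum("tk,kij,tkj->ti", wt, Qinv, mw)

    # assemble diagonal/off-diagonal precision blocks and linear terms
    Lam = np.repeat(J_emis[None], T, axis=0)
    Lam[0] += 1e-4 * np.eye(D)                  # weak prior on the first frame
    Lam[:-1] += J11
    Lam[1:] += J22
    h = h_emis.T.copy()
    h[:-1] += h1
    h[1:] += h2
    Off = J12                                   # (T-1,D,D), block (t, t+1)

    mu, Sig, Cross, logdet = _block_tridiag_solve(Lam, Off, h)
    entropy = 0.5 * (T * D * np.log(2 * np.pi * np.e) - logdet)
    return mu, Sig, Cross, entropy


@njit(cache=False)
def _block_tridiag_solve(Lam, Off, h):
    """Gaussian chain inference: means, marginal and lag-one covariances, and
    log-determinant of the block-tridiagonal precision (Thomas algorithm)."""
    T, D, _ = Lam.shape
    P = np.empty((T, D, D))
    g = np.empty((T, D))
    Pinv = np.empty((T, D, D))
    P[0] = Lam[0]
    g[0] = h[0]
    for t in range(1, T):
        Pi = np.linalg.inv(P[t - 1])
        Pinv[t - 1] = Pi
        Mt = Off[t - 1]
        P[t] = Lam[t] - Mt.T @ Pi @ Mt
        g[t] = h[t] - Mt.T @ (Pi @ g[t - 1])
    Pinv[T - 1] = np.linalg.inv(P[T - 1])
    logdet = 0.0
    for t in range(T):
        sign, ld = np.linalg.slogdet(P[t])
        logdet += ld

    mu = np.empty((T, D))
    Sig = np.empty((T, D, D))
    Cross = np.empty((T - 1, D, D))
    mu[T - 1] = Pinv[T - 1] @ g[T - 1]
    Sig[T - 1] = Pinv[T - 1]
    for t in range(T - 2, -1, -1):
        Ut = Pinv[t] @ Off[t]
        mu[t] = Pinv[t] @ g[t] - Ut @ mu[t + 1]
        Sig[t] = Pinv[t] + Ut @ Sig[t + 1] @ Ut.T
        Cross[t] = -Ut @ Sig[t + 1]
    return mu, Sig, Cross, logdet


# ---------------------------------------------------------------------------
# discrete E-step: forward-backward over the recurrent chain
# ---------------------------------------------------------------------------

def _state_loglik(mu, Sig, Cross, u, params: RSLDSParams):
    """E_q(x)[log N(x_t; A_k x_{t-1} + b_k + B_k u_t, Q_k)] for t = 1..T-1."""
    T = mu.shape[0]
    D, K = params.D, params.K
    ll = np.empty((T - 1, K))
    m = np.repeat(params.bs[None, :, :], T, axis=0)
    if u is not None and params.Bs is not None:
        m = m + np.einsum("kdu,ut->tkd", params.Bs, u)
    for k in range(K):
        Q = params.Qs[k] + _QFLOOR * np.eye(D)
        Qi = np.linalg.inv(Q)
        A = params.As[k]
        resid = mu[1:] - mu[:-1] @ A.T - m[1:, k]           # (T-1, D)
        quad = np.einsum("ti,ij,tj->t", resid, Qi, resid)
        # second-order corrections from posterior covariance
        corr = (
            np.einsum("tij,ji->t", Sig[1:], Qi)
            + np.einsum("tij,ji->t", A @ Sig[:-1] @ A.T, Qi)
            - 2.0 * np.einsum("tij,ji->t", Cross @ Qi, A)
        )
        _, ld = np.linalg.slogdet(Q)
        ll[:, k] = -0.5 * (quad + corr + ld + D * np.log(2 * np.pi))
    return ll


def _transition_logprobs(mu, params: RSLDSParams):
    """log p(z_{t+1} = k' | z_t = k, x_t = mu_t): (T-1, K, K) array."""
    logits = np.einsum("kjd,td->tkj", params.Rs, mu[:-1]) + params.rs[None]
    return logits - logsumexp(logits, axis=2, keepdims=True)


@njit(cache=False)
def _fb_scan(ll, logP):
    Tm1, K = ll.shape
    T = Tm1 + 1
    alpha = np.empty((T, K))
    for k in range(K):
        alpha[0, k] = -np.log(K)
    tmp = np.empty(K)
    for t in range(1, T):
        for j in range(K):
            for k in range(K):
                tmp[k] = alpha[t - 1, k] + logP[t - 1, k, j]
            m = tmp.max()
            s = 0.0
            for k in range(K):
                s += np.exp(tmp[k] - m)
            alpha[t, j] = ll[t - 1, j] + m + np.log(s)
    m = alpha[T - 1].max()
    s = 0.0
    for k in range(K):
        s += np.exp(alpha[T - 1, k] - m)
    logZ = m + np.log(s)
    beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        for k in range(K):
            for j in range(K):
                tmp[j] = logP[t, k, j] + ll[t, j] + beta[t + 1, j]
            mm = tmp.max()
            ss = 0.0
            for j in range(K):
                ss += np.exp(tmp[j] - mm)
            beta[t, k] = mm + np.log(ss)
    return alpha, beta, logZ


def _forward_backward(ll, logP):
    """HMM smoothing with time-varying transitions.

    ll : (T-1, K) state log-likelihoods for frames 1..T-1
    logP : (T-1, K, K) transition log-probabilities (frame t -> t+1)
    Returns marginals w (T, K), pairwise xi (T-1, K, K), entropy, log-normalizer.
    """
    Tm1, K = ll.shape
    T = Tm1 + 1
    alpha, beta, logZ = _fb_scan(ll, logP)
    logw = alpha + beta - logZ
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    xi = np.exp(
        alpha[:-1, :, None] + logP + (ll + beta[1:])[:, None, :] - logZ
    )
    xi /= np.maximum(xi.sum(axis=(1, 2), keepdims=True), 1e-300)
    # chain entropy H(z_1) + sum_t H(z_{t+1} | z_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = -np.sum(w[0] * np.where(w[0] > 0, np.log(w[0]), 0.0))
        cond = np.where(xi > 0, xi * (np.log(xi) - np.log(np.maximum(w[:-1, :, None], 1e-300))), 0.0)
    entropy = h0 - float(cond.sum())
    return w, xi, entropy, float(logZ)


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------

def _dynamics_mstep(stats, D, U, ridge=1e-6):
    """Weighted regression of x_t on [x_{t-1}, u_t, 1] per state from moments."""
    As, bs, Bs, Qs = [], [], [], []
    for (Sxx, Sxy, Syy, wsum) in stats:
        P = D + U + 1
        reg = ridge * np.eye(P)
        reg[-1, -1] = 0.0
        W = np.linalg.solve(Sxx + reg, Sxy).T       # (D, P)
        A = W[:, :D]
        B = W[:, D:D + U] if U else None
        b = W[:, -1]
        Q = (Syy - W @ Sxy - Sxy.T @ W.T + W @ Sxx @ W.T) / max(wsum, 1e-12)
        Q = (Q + Q.T) / 2.0
        wq, Vq = np.linalg.eigh(Q)
        Q = (Vq * np.maximum(wq, _QFLOOR)) @ Vq.T
        As.append(A)
        bs.append(b)
        Bs.append(B)
        Qs.append(Q)
    Bs_arr = np.stack(Bs) if U else None
    return np.stack(As), np.stack(bs), Bs_arr, np.stack(Qs)


def _transition_mstep(params, mus, xis, ridge_C=1e3):
    """Multinomial logistic regression for (R_k, r_k) from pairwise marginals."""
    K, D = params.K, params.D
    Rs = params.Rs.copy()
    rs = params.rs.copy()
    X = np.concatenate([mu[:-1] for mu in mus], axis=0)         # (sumT-1, D)
    XI = np.concatenate(xis, axis=0)                            # (sumT-1, K, K)
    for k in range(K):
        Wk = XI[:, k, :]                                        # (n, K)
        tot = Wk.sum(axis=0)
        if tot.sum() < 1e-6:
            continue
        present = np.where(tot > 1e-4)[0]
        if len(present) < 2:
            # effectively deterministic next state; push logits hard that way
            rs[k] = -10.0
            rs[k, int(np.argmax(tot))] = 10.0
            Rs[k] = 0.0
            continue
        Xrep = np.repeat(X, len(present), axis=0)
        yrep = np.tile(present, X.shape[0])
        wrep = Wk[:, present].ravel()
        keep = wrep > 1e-8
        lr = LogisticRegression(C=ridge_C, max_iter=500, tol=1e-8)
        lr.fit(Xrep[keep], yrep[keep], sample_weight=wrep[keep])
        coef = np.zeros((K, D))
        intc = np.full(K, -15.0)
        if len(present) == 2:
            coef[present[1]] = lr.coef_[0]
            intc[present[1]] = lr.intercept_[0]
            coef[present[0]] = 0.0
            intc[present[0]] = 0.0
        else:
            coef[present] = lr.coef_
            intc[present] = lr.intercept_
        Rs[k] = coef
        rs[k] = intc
    return Rs, rs


def _emission_mstep(ys, mus, Sigs):
    D = mus[0].shape[1]
    Sxx = np.zeros((D + 1, D + 1))
    Sxy = np.zeros((D + 1, ys[0].shape[0]))
    Syy_diag = np.zeros(ys[0].shape[0])
    Ttot = 0
    for y, mu, Sig in zip(ys, mus, Sigs):
        T = mu.shape[0]
        Exx = Sig.sum(axis=0) + mu.T @ mu
        Sxx[:D, :D] += Exx
        Sxx[:D, -1] += mu.sum(axis=0)
        Sxx[-1, :D] += mu.sum(axis=0)
        Sxx[-1, -1] += T
        Sxy[:D] += mu.T @ y.T
        Sxy[-1] += y.sum(axis=1)
        Syy_diag += np.einsum("nt,nt->n", y, y)
        Ttot += T
    W = np.linalg.solve(Sxx + 1e-9 * np.eye(D + 1), Sxy).T      # (N, D+1)
    C, d = W[:, :D], W[:, -1]
    S = (Syy_diag - 2 * np.einsum("np,pn->n", W, Sxy)
         + np.einsum("np,pq,nq->n", W, Sxx, W)) / Ttot
    S = np.maximum(S, _SFLOOR)
    return C, d, S


# ---------------------------------------------------------------------------
# fitting driver
# ---------------------------------------------------------------------------

def _initialize(ys, us, D, K, seed):
    """Factor analysis for (C, d), k-means for states, LS for dynamics."""
    ycat = np.concatenate(ys, axis=1)
    if np.allclose(ycat.std(axis=1), 0.0):
        raise ValueError("degenerate data: zero variance in every neuron")
    fa = FactorAnalysis(n_components=D, random_state=seed)
    x_all = fa.fit_transform(ycat.T)                            # (T, D)
    C = fa.components_.T
    d = fa.mean_
    S = np.maximum(fa.noise_variance_, _SFLOOR)

    xs = []
    off = 0
    for y in ys:
        xs.append(x_all[off:off + y.shape[1]])
        off += y.shape[1]

    U = 0 if us[0] is None else us[0].shape[0]
    if K > 1:
        km = KMeans(n_clusters=K, n_init=5, random_state=seed)
        labels = km.fit_predict(x_all)
    else:
        labels = np.zeros(x_all.shape[0], dtype=int)

    stats = []
    for k in range(K):
        P = D + U + 1
        Sxx = 1e-6 * np.eye(P)
        Sxy = np.zeros((P, D))
        Syy = 1e-6 * np.eye(D)
        wsum = 1e-6
        stats.append([Sxx, Sxy, Syy, wsum])
    idx = 0
    for x, u in zip(xs, us):
        T = x.shape[0]
        seg_lab = labels[idx:idx + T]
        idx += T
        feats = [x[:-1]]
        if U:
            feats.append(u[:, 1:].T)
        feats.append(np.ones((T - 1, 1)))
        F = np.concatenate(feats, axis=1)
        tgt = x[1:]
        for k in range(K):
            mask = seg_lab[1:] == k
            if mask.sum() == 0:
                continue
            Fk, tk = F[mask], tgt[mask]
            stats[k][0] += Fk.T @ Fk
            stats[k][1] += Fk.T @ tk
            stats[k][2] += tk.T @ tk
            stats[k][3] += mask.sum()
    As, bs, Bs, Qs = _dynamics_mstep([tuple(s) for s in stats], D, U, ridge=1e-3)

    # transitions: empirical counts, no recurrent dependence yet
    rs = np.full((K, K), np.log(0.05 / max(K - 1, 1)))
    np.fill_diagonal(rs, np.log(0.95))
    Rs = np.zeros((K, K, D))
    return RSLDSParams(As=As, bs=bs, Qs=Qs, Rs=Rs, rs=rs, C=C, d=d, S=S,
                       Bs=Bs), xs


def _estep(ys, us, params, ws):
    mus, Sigs, Crosses, ent_x = [], [], [], 0.0
    for y, u, w in zip(ys, us, ws):
        mu, Sig, Cross, ent = _chain_smoother(y, u, params, w)
        mus.append(mu)
        Sigs.append(Sig)
        Crosses.append(Cross)
        ent_x += ent
    return mus, Sigs, Crosses, ent_x


def _discrete_estep(mus, Sigs, Crosses, us, params):
    ws, xis, ent_z, trans_ll = [], [], 0.0, 0.0
    for mu, Sig, Cross, u in zip(mus, Sigs, Crosses, us):
        if params.K == 1:
            T = mu.shape[0]
            ws.append(np.ones((T, 1)))
            xis.append(np.ones((T - 1, 1, 1)))
            continue
        ll = _state_loglik(mu, Sig, Cross, u, params)
        logP = _transition_logprobs(mu, params)
        w, xi, ent, _ = _forward_backward(ll, logP)
        ws.append(w)
        xis.append(xi)
        ent_z += ent
        trans_ll += float(np.sum(xi * logP))
    return ws, xis, ent_z, trans_ll


def _elbo(ys, us, params, mus, Sigs, Crosses, ws, xis, ent_x, ent_z):
    val = ent_x + ent_z
    Sinv = 1.0 / np.maximum(params.S, _SFLOOR)
    logS = np.log(np.maximum(params.S, _SFLOOR))
    for y, u, mu, Sig, Cross, w, xi in zip(ys, us, mus, Sigs, Crosses, ws, xis):
        T = mu.shape[0]
        resid = y - params.C @ mu.T - params.d[:, None]
        quad = np.einsum("nt,n->", resid ** 2, Sinv)
        tr = np.einsum("nd,tde,ne,n->", params.C, Sig, params.C, Sinv)
        val += -0.5 * (quad + tr + T * (logS.sum() + y.shape[0] * np.log(2 * np.pi)))
        ll = _state_loglik(mu, Sig, Cross, u, params)
        val += float(np.sum(w[1:] * ll))
        if params.K > 1:
            logP = _transition_logprobs(mu, params)
            val += float(np.sum(xi * logP))
            val += float(np.sum(w[0] * (-np.log(params.K))))
    return float(val)


def _fit_segments(ys, us, D, K, max_iter, tol, seed, n_discrete_init=1):
    params, xs0 = _initialize(ys, us, D, K, seed)
    Ttot = sum(y.shape[1] for y in ys)
    ws = [np.full((y.shape[1], K), 1.0 / K) for y in ys]
    trace = []
    converged = False
    prev = -np.inf
    for it in range(max_iter):
        mus, Sigs, Crosses, ent_x = _estep(ys, us, params, ws)
        ws, xis, ent_z, _ = _discrete_estep(mus, Sigs, Crosses, us, params)

        # M-step: dynamics moments per state
        U = 0 if us[0] is None else us[0].shape[0]
        stats = [[1e-9 * np.eye(D + U + 1), np.zeros((D + U + 1, D)),
                  1e-9 * np.eye(D), 1e-12] for _ in range(K)]
        for mu, Sig, Cross, u, w in zip(mus, Sigs, Crosses, us, ws):
            T = mu.shape[0]
            Exx_prev = Sig[:-1] + mu[:-1, :, None] * mu[:-1, None, :]
            Exx_next = Sig[1:] + mu[1:, :, None] * mu[1:, None, :]
            Exy = Cross + mu[:-1, :, None] * mu[1:, None, :]     # E[x_{t-1} x_t']
            uf = u[:, 1:].T if U else np.zeros((T - 1, 0))
            ones = np.ones((T - 1, 1))
            for k in range(K):
                wk = w[1:, k]
                swk = wk.sum()
                if swk < 1e-10:
                    continue
                Sxx = stats[k][0]
                Sxx[:D, :D] += np.einsum("t,tij->ij", wk, Exx_prev)
                fu = np.concatenate([uf, ones], axis=1)          # (T-1, U+1)
                wmu = wk[:, None] * mu[:-1]
                Sxx[:D, D:] += wmu.T @ fu
                Sxx[D:, :D] += fu.T @ wmu
                Sxx[D:, D:] += (wk[:, None] * fu).T @ fu
                stats[k][1][:D] += np.einsum("t,tij->ij", wk, Exy)
                stats[k][1][D:] += (wk[:, None] * fu).T @ mu[1:]
                stats[k][2] += np.einsum("t,tij->ij", wk, Exx_next)
                stats[k][3] += swk
        As, bs, Bs, Qs = _dynamics_mstep([tuple(s) for s in stats], D, U)
        C, d, S = _emission_mstep(ys, mus, Sigs)
        params = RSLDSParams(As=As, bs=bs, Qs=Qs, Rs=params.Rs, rs=params.rs,
                             C=C, d=d, S=S, Bs=Bs)
        if K > 1:
            Rs, rs = _transition_mstep(params, mus, xis)
            params.Rs, params.rs = Rs, rs

        obj = _elbo(ys, us, params, mus, Sigs, Crosses, ws, xis, ent_x, ent_z)
        trace.append(obj)
        if it > 0 and abs(obj - prev) < tol * (1.0 + abs(prev)):
            converged = True
            prev = obj
            break
        prev = obj
    diag = FitDiagnostics(elbo_trace=np.asarray(trace), converged=converged,
                          n_iter=len(trace))
    if not converged:
        warnings.warn("rSLDS fit did not converge within max_iter; "
                      "returning best parameters so far", RuntimeWarning)
    return params, diag, ws


def fit_rslds(
    y: ObservedActivity | np.ndarray,
    D: int = 2,
    K: int = 2,
    inputs=None,
    max_iter: int = 50,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[RSLDSParams, FitDiagnostics]:
    """Fit an rSLDS to population activity by structured variational EM.

    The emission matrix is initialized by factor analysis, discrete states by
    k-means on the factor-analysis latents, and dynamics by per-state ridge
    regression; EM then alternates chain smoothing of q(x), forward-backward
    over q(z), and closed-form M-steps.  The objective trace in the returned
    diagnostics is the structured-mean-field evidence lower bound with the
    recurrent softmax evaluated at the posterior latent means.
    """
    act = y if isinstance(y, ObservedActivity) else ObservedActivity(np.asarray(y))
    ydat = act.y
    if ydat.shape[1] <= D:
        raise ValueError("need more frames than latent dimensions")
    if np.allclose(ydat.std(axis=1).max(), 0.0):
        raise ValueError("degenerate data: zero variance")
    u = _as_inputs(inputs, ydat.shape[1])
    params, diag, _ = _fit_segments([ydat], [u], D, K, max_iter, tol, seed)
    return params, diag


def infer_latents(
    params: RSLDSParams,
    y: ObservedActivity | np.ndarray,
    inputs=None,
    n_iter: int = 4,
) -> LatentTrajectory:
    """Posterior inference: smoothed continuous latents and the most-probable
    discrete path (Viterbi over the recurrent chain at the latent means)."""
    act = y if isinstance(y, ObservedActivity) else ObservedActivity(np.asarray(y))
    ydat = act.y
    if ydat.shape[0] != params.N:
        raise ValueError("neuron count mismatch between params and data")
    T = ydat.shape[1]
    u = _as_inputs(inputs, T)
    K = params.K
    w = np.full((T, K), 1.0 / K)
    mu = Sig = Cross = None
    for _ in range(max(n_iter, 1)):
        mu, Sig, Cross, _ = _chain_smoother(ydat, u, params, w)
        if K == 1:
            break
        ll = _state_loglik(mu, Sig, Cross, u, params)
        logP = _transition_logprobs(mu, params)
        w, _, _, _ = _forward_backward(ll, logP)
    if K == 1:
        z = np.zeros(T, dtype=int)
    else:
        z = _viterbi(ll, logP)
    return LatentTrajectory(x=mu.T, z=z)


def _viterbi(ll, logP):
    Tm1, K = ll.shape
    T = Tm1 + 1
    delta = np.full((T, K), -np.log(K))
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[t - 1][:, None] + logP[t - 1] + ll[t - 1][None, :]
        back[t] = np.argmax(scores, axis=0)
        delta[t] = np.max(scores, axis=0)
    z = np.empty(T, dtype=int)
    z[T - 1] = int(np.argmax(delta[T - 1]))
    for t in range(T - 2, -1, -1):
        z[t] = back[t + 1][z[t + 1]]
    return z


def cross_validated_r2(
    y: ObservedActivity | np.ndarray,
    D: int = 2,
    K: int = 2,
    folds: int = 5,
    inputs=None,
    max_iter: int = 40,
    seed: int = 0,
) -> float:
    """Five-fold cross-validated variance explained (percent).

    Folds are contiguous time blocks; for each fold the model is fit on the
    remaining blocks (as separate segments, so no artificial discontinuity is
    spliced into the dynamics) and held-out activity is reconstructed from
    latents inferred under the train-fold parameters.
    """
    act = y if isinstance(y, ObservedActivity) else ObservedActivity(np.asarray(y))
    ydat = act.y
    T = ydat.shape[1]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if T < folds * (10 * D):
        raise ValueError("series too short for the requested fold count")
    u = _as_inputs(inputs, T)
    bounds = np.linspace(0, T, folds + 1).astype(int)
    ss_res = 0.0
    ss_tot = 0.0
    for f in range(folds):
        lo, hi = bounds[f], bounds[f + 1]
        train_ys, train_us = [], []
        for a, b in ((0, lo), (hi, T)):
            if b - a > 10 * D:
                train_ys.append(ydat[:, a:b])
                train_us.append(None if u is None else u[:, a:b])
        p, _, _ = _fit_segments(train_ys, train_us, D, K, max_iter, 1e-5,
                                seed + f)
        test_u = None if u is None else u[:, lo:hi]
        lat = infer_latents(p, ydat[:, lo:hi], inputs=test_u, n_iter=3)
        yhat = p.C @ lat.x + p.d[:, None]
        ytest = ydat[:, lo:hi]
        ss_res += float(((ytest - yhat) ** 2).sum())
        ss_tot += float(((ytest - ytest.mean(axis=1, keepdims=True)) ** 2).sum())
    return 100.0 * (1.0 - ss_res / ss_tot)


def forward_simulate(
    params: RSLDSParams,
    x0: np.ndarray,
    inputs=None,
    T: int = 100,
    z0: int = 0,
) -> LatentTrajectory:
    """Noise-free rollout of the mean dynamics from ``x0`` under given inputs.

    The discrete state follows the most-probable branch of the recurrent
    softmax at each step.
    """
    u = _as_inputs(inputs, T)
    x = np.empty((params.D, T))
    z = np.empty(T, dtype=int)
    x_prev = np.asarray(x0, dtype=float)
    z_prev = int(z0)
    for t in range(T):
        if params.K > 1:
            zt = int(np.argmax(params.transition_probs(z_prev, x_prev)))
        else:
            zt = 0
        mean = params.As[zt] @ x_prev + params.bs[zt]
        if u is not None and params.Bs is not None:
            mean = mean + params.Bs[zt] @ u[:, t]
        x[:, t] = mean
        z[t] = zt
        x_prev, z_prev = mean, zt
    return LatentTrajectory(x=x, z=z)


# ---------------------------------------------------------------------------
# neuron-to-dimension assignment via the emission matrix
# ---------------------------------------------------------------------------

def dimension_weights(params: RSLDSParams, min_weight: float = 0.0):
    """Per-neuron absolute emission weights for each latent dimension.

    Returns a pandas DataFrame with one row per neuron: the absolute weight on
    each dimension, the assigned dimension label (``x1``, ``x2``, ... by
    largest absolute weight; ``neither`` when every weight is <= min_weight),
    and the within-dimension rank (0 = strongest).
    """
    import pandas as pd

    absW = np.abs(params.C)
    labels = []
    for row in absW:
        if row.max() <= min_weight:
            labels.append("neither")
        else:
            labels.append(f"x{int(np.argmax(row)) + 1}")
    data = {"neuron": np.arange(params.N)}
    for d_ in range(params.D):
        data[f"weight_x{d_ + 1}"] = absW[:, d_]
        order = np.argsort(np.argsort(-absW[:, d_], kind="stable"), kind="stable")
        data[f"rank_x{d_ + 1}"] = order
    data["label"] = labels
    return pd.DataFrame(data)


def select_top_neurons(weights, dim: int, k: int = 5) -> np.ndarray:
    """Indices of the ``k`` neurons with largest absolute weight on ``dim``
    (1-based dimension id); ties broken toward the lower neuron index."""
    col = f"weight_x{dim}"
    if col not in weights.columns:
        raise ValueError(f"unknown dimension id {dim}")
    w = weights[col].to_numpy()
    if k > len(w):
        raise ValueError("k exceeds the number of neurons")
    order = np.argsort(-w, kind="stable")
    return weights["neuron"].to_numpy()[order[:k]]


def subspace_angle(C: np.ndarray) -> float:
    """Principal angle, in degrees, between the two emission columns of a
    2-D model; 90 for orthogonal dimensions, 0 for collinear ones."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] != 2:
        raise ValueError("subspace_angle expects an N x 2 emission matrix")
    if np.linalg.norm(C[:, 0]) == 0 or np.linalg.norm(C[:, 1]) == 0:
        raise ValueError("emission columns must be nonzero")
    ang = subspace_angles(C[:, [0]], C[:, [1]])[0]
    return float(np.degrees(ang))
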