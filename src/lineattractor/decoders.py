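"""Decoding and regression analyses on attractor latents.

Three analyses: (1) frame-wise decoding of attack bouts from the normalized
integration-dimension signal with a 1-D maximal-margin threshold and bout-label
shuffle nulls; (2) a linear SVM decoding x1 vs x2 identity from cell positions
in the field of view; (3) a lagged ridge GLM predicting single-neuron activity
from motion features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "BoutTable",
    "DecoderResult",
    "MotionGLMResult",
    "framewise_attack_decoder",
    "cross_condition_decode",
    "shuffle_null",
    "spatial_cluster_decoder",
    "motion_glm",
]


@dataclass
class BoutTable:
    """Behavior bout annotations: rows of (start_s, stop_s, label).

    Bouts separated by less than ``merge_gap_s`` are merged before decoding.
    """

    table: pd.DataFrame
    merge_gap_s: float = 5.0

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"start_s", "stop_s", "label"}
        if not required.issubset(t.columns):
            raise ValueError(f"bout table needs columns {sorted(required)}")
        if (t["start_s"] >= t["stop_s"]).any():
            raise ValueError("every bout must have start < stop")
        self.table = t.sort_values("start_s").reset_index(drop=True)

    @classmethod
    def from_intervals(cls, intervals, label: str = "attack",
                       merge_gap_s: float = 5.0) -> "BoutTable":
        df = pd.DataFrame(intervals, columns=["start_s", "stop_s"])
        df["label"] = label
        return cls(df, merge_gap_s=merge_gap_s)

    def merged(self, gap_s: float | None = None) -> "BoutTable":
        """Merge same-label bouts separated by less than the gap."""
        gap = self.merge_gap_s if gap_s is None else gap_s
        rows = []
        for label, sub in self.table.groupby("label", sort=False):
            sub = sub.sort_values("start_s")
            cur = None
            for _, r in sub.iterrows():
                if cur is None:
                    cur = [r.start_s, r.stop_s]
                elif r.start_s - cur[1] < gap:
                    cur[1] = max(cur[1], r.stop_s)
                else:
                    rows.append((cur[0], cur[1], label))
                    cur = [r.start_s, r.stop_s]
            if cur is not None:
                rows.append((cur[0], cur[1], label))
        df = pd.DataFrame(rows, columns=["start_s", "stop_s", "label"])
        return BoutTable(df, merge_gap_s=gap)

    def frame_mask(self, n_frames: int, frame_rate: float,
                   label: str | None = None) -> np.ndarray:
        mask = np.zeros(n_frames, dtype=bool)
        for _, r in self.table.iterrows():
            if label is not None and r.label != label:
                continue
            lo = int(np.floor(r.start_s * frame_rate))
            hi = int(np.ceil(r.stop_s * frame_rate))
            mask[max(lo, 0):min(hi, n_frames)] = True
        return mask

    def intervals(self, label: str | None = None) -> list[tuple[float, float]]:
        rows = self.table if label is None else self.table[self.table.label == label]
        return [(r.start_s, r.stop_s) for _, r in rows.iterrows()]


@dataclass
class DecoderResult:
    accuracy: float
    threshold: float
    direction: int = 1          # +1: values above threshold decode positive
    null_accuracies: list[float] = field(default_factory=list)
    n_shuffles: int = 0
    p_value: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class MotionGLMResult:
    betas: np.ndarray       # (n_neurons, n_lags, n_features)
    cv_r2: np.ndarray       # percent, per neuron
    ridge: float | np.ndarray
    folds: int
    lag_s: float


# ---------------------------------------------------------------------------
# 1-D threshold decoder (exhaustive search == linear SVM in one dimension)
# ---------------------------------------------------------------------------

def _fit_threshold(values: np.ndarray, labels: np.ndarray):
    """Deterministic maximal-accuracy threshold on a 1-D signal.

    Scans midpoints of the sorted values and both polarities; returns
    (threshold, direction, train_accuracy).
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    lab = labels[order].astype(int)
    n = len(v)
    npos = lab.sum()
    # candidate i: threshold between v[i-1] and v[i] (i = 0..n)
    pos_below = np.concatenate([[0], np.cumsum(lab)])
    idx = np.arange(n + 1)
    # direction +1: predict positive for value > thr
    correct_up = (npos - pos_below) + (idx - pos_below)
    correct_dn = pos_below + ((n - idx) - (npos - pos_below))
    acc_up = correct_up / n
    acc_dn = correct_dn / n
    if acc_up.max() >= acc_dn.max():
        i = int(np.argmax(acc_up))
        direction, acc = 1, float(acc_up[i])
    else:
        i = int(np.argmax(acc_dn))
        direction, acc = -1, float(acc_dn[i])
    if i == 0:
        thr = v[0] - 1e-12 if n else 0.0
    elif i == n:
        thr = v[-1] + 1e-12
    else:
        thr = 0.5 * (v[i - 1] + v[i])
    return float(thr), direction, acc


def _predict_threshold(values, thr, direction):
    return (values > thr) if direction > 0 else (values <= thr)


def _trial_frames(bouts: BoutTable, n_frames, frame_rate, label, rng):
    """Positive frame sets per merged bout plus duration-matched negative
    frame sets sampled outside all bouts (the balancing step)."""
    merged = bouts.merged()
    pos_mask = merged.frame_mask(n_frames, frame_rate, label=label)
    ivals = merged.intervals(label=label)
    if not ivals or pos_mask.all():
        raise ValueError("need both in-bout and out-of-bout frames")
    neg_pool = np.flatnonzero(~pos_mask)
    rng.shuffle(neg_pool)
    trials = []
    off = 0
    for (a, b) in ivals:
        lo = max(int(np.floor(a * frame_rate)), 0)
        hi = min(int(np.ceil(b * frame_rate)), n_frames)
        pos = np.arange(lo, hi)
        need = len(pos)
        if off + need > len(neg_pool):
            need = len(neg_pool) - off
            pos = pos[:need]
        neg = neg_pool[off:off + need]
        off += need
        if len(pos):
            trials.append((pos, neg))
    if not trials:
        raise ValueError("no usable trials after balancing")
    return trials


def framewise_attack_decoder(
    signal: np.ndarray,
    bouts: BoutTable,
    frame_rate: float = 10.0,
    label: str | None = None,
    seed: int = 0,
) -> DecoderResult:
    """Frame-wise attack decoding from the integration-dimension signal.

    Bouts closer than the merge gap are merged into trials, frames are
    balanced by sampling duration-matched out-of-bout negatives, and a
    maximal-margin 1-D threshold is fit.  Accuracy is the leave-one-trial-out
    average: for each trial the threshold is fit on all other trials and
    evaluated on the held-out trial's balanced frames.  The returned threshold
    is refit on all balanced frames (frozen for cross-condition testing).
    """
    signal = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(seed)
    trials = _trial_frames(bouts, len(signal), frame_rate, label, rng)
    if len(trials) < 2:
        # single trial: plain held-out split is impossible; train == test
        pos, neg = trials[0]
        v = np.concatenate([signal[pos], signal[neg]])
        lab = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        thr, direction, acc = _fit_threshold(v, lab)
        return DecoderResult(accuracy=acc, threshold=thr, direction=direction,
                             seed=seed)
    accs = []
    for i in range(len(trials)):
        tr_idx = [j for j in range(len(trials)) if j != i]
        vtr = np.concatenate([np.concatenate([signal[trials[j][0]],
                                              signal[trials[j][1]]])
                              for j in tr_idx])
        ltr = np.concatenate([np.concatenate([np.ones(len(trials[j][0])),
                                              np.zeros(len(trials[j][1]))])
                              for j in tr_idx])
        thr, direction, _ = _fit_threshold(vtr, ltr)
        pos, neg = trials[i]
        vte = np.concatenate([signal[pos], signal[neg]])
        lte = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        pred = _predict_threshold(vte, thr, direction)
        accs.append(float((pred == lte.astype(bool)).mean()))
    vall = np.concatenate([np.concatenate([signal[p], signal[n]])
                           for p, n in trials])
    lall = np.concatenate([np.concatenate([np.ones(len(p)), np.zeros(len(n))])
                           for p, n in trials])
    thr, direction, _ = _fit_threshold(vall, lall)
    return DecoderResult(accuracy=float(np.mean(accs)), threshold=thr,
                         direction=direction, seed=seed)


def cross_condition_decode(
    trained: DecoderResult,
    signal: np.ndarray,
    bouts: BoutTable,
    frame_rate: float = 10.0,
    label: str | None = None,
) -> float:
    """Apply a frozen decoding threshold to a second condition's signal and
    report accuracy on balanced frames."""
    signal = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(trained.seed)
    trials = _trial_frames(bouts, len(signal), frame_rate, label, rng)
    v = np.concatenate([np.concatenate([signal[p], signal[n]])
                        for p, n in trials])
    lab = np.concatenate([np.concatenate([np.ones(len(p)), np.zeros(len(n))])
                          for p, n in trials]).astype(bool)
    pred = _predict_threshold(v, trained.threshold, trained.direction)
    return float((pred == lab).mean())


def shuffle_null(
    signal: np.ndarray,
    bouts: BoutTable,
    n_shuffles: int = 1000,
    seed: int = 0,
    frame_rate: float = 10.0,
    label: str | None = None,
) -> np.ndarray:
    """Bout-label shuffle null for the frame-wise decoder.

    The trial structure (bout intervals plus duration-matched negative
    intervals) is kept fixed; each shuffle randomly reassigns which intervals
    carry the positive annotation, refits the threshold on a balanced half of
    the shuffled trials and records the accuracy on the held-out balanced
    half.  Because train and test labels are balanced and independent, the
    expected accuracy under the shuffle is exactly 0.5.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    signal = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(seed)
    trials = _trial_frames(bouts, len(signal), frame_rate, label, rng)
    segments = []
    for pos, neg in trials:
        segments.append(pos)
        segments.append(neg)
    n_seg = len(segments)
    accs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(n_seg)
        half = n_seg // 2
        tr_idx, te_idx = perm[:half], perm[half:]
        flags = np.zeros(n_seg, dtype=bool)
        # balanced random labels within each half, independently
        flags[rng.permutation(tr_idx)[: half // 2]] = True
        flags[rng.permutation(te_idx)[: len(te_idx) // 2]] = True
        vtr = np.concatenate([signal[segments[j]] for j in tr_idx])
        ltr = np.concatenate([np.full(len(segments[j]), flags[j])
                              for j in tr_idx]).astype(float)
        if ltr.min() == ltr.max():
            accs[s] = 0.5
            continue
        thr, direction, _ = _fit_threshold(vtr, ltr)
        vte = np.concatenate([signal[segments[j]] for j in te_idx])
        lte = np.concatenate([np.full(len(segments[j]), flags[j])
                              for j in te_idx])
        pred = _predict_threshold(vte, thr, direction)
        accs[s] = float((pred == lte).mean())
    return accs


# ---------------------------------------------------------------------------
# spatial cluster decoder
# ---------------------------------------------------------------------------

def spatial_cluster_decoder(
    positions,
    n_shuffles: int = 20,
    seed: int = 0,
    folds: int = 5,
) -> DecoderResult:
    """Linear SVM separating x1 from x2 cell positions in the FOV.

    Accuracy is stratified cross-validated; the null is the same procedure on
    identity-shuffled labels, averaged over ``n_shuffles`` repeats.
    ``positions`` is a PositionTable or DataFrame with columns
    (x_um, y_um, dim_label).
    """
    df = positions.table if hasattr(positions, "table") else positions
    sub = df[df["dim_label"].isin(["x1", "x2"])]
    labels = (sub["dim_label"] == "x1").to_numpy().astype(int)
    if len(labels) == 0 or labels.min() == labels.max():
        raise ValueError("both x1 and x2 labels must be present")
    X = sub[["x_um", "y_um"]].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-9)
    folds = min(folds, int(np.bincount(labels).min()))
    if folds < 2:
        raise ValueError("too few cells per class for cross-validation")

    def _cv_acc(y, random_state):
        cv = StratifiedKFold(n_splits=folds, shuffle=True,
                             random_state=random_state)
        clf = SVC(kernel="linear", C=1.0)
        return float(cross_val_score(clf, X, y, cv=cv).mean())

    acc = _cv_acc(labels, seed)
    rng = np.random.default_rng(seed)
    nulls = []
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        if perm.min() == perm.max():
            continue
        nulls.append(_cv_acc(perm, seed + 1 + s))
    p = float((np.sum(np.asarray(nulls) >= acc) + 1) / (len(nulls) + 1))
    return DecoderResult(accuracy=acc, threshold=np.nan, direction=1,
                         null_accuracies=list(nulls), n_shuffles=len(nulls),
                         p_value=p, seed=seed)


# ---------------------------------------------------------------------------
# motion GLM
# ---------------------------------------------------------------------------

def _lagged_design(features: np.ndarray, n_lags: int) -> np.ndarray:
    F, T = features.shape
    X = np.empty((T - n_lags, F * (n_lags + 1)))
    col = 0
    for lag in range(n_lags + 1):
        X[:, col:col + F] = features[:, n_lags - lag:T - lag].T
        col += F
    return X


def motion_glm(
    y: np.ndarray,
    features: np.ndarray,
    frame_rate: float = 10.0,
    lag_s: float = 10.0,
    folds: int = 10,
    ridge: float | None = None,
    seed: int = 0,
) -> MotionGLMResult:
    """Ridge GLM predicting neural activity from lagged motion features.

    ``y`` is one series (T,) or a matrix (N, T); ``features`` is (F, T).  Each
    neuron is predicted from the features at lags 0..lag_s (10 s default),
    with contiguous k-fold cross-validation.  When ``ridge`` is None the
    penalty is selected per fold by generalized cross-validation on the
    training data.  cvR^2 is reported in percent per neuron.
    """
    from sklearn.linear_model import Ridge, RidgeCV

    y = np.atleast_2d(np.asarray(y, dtype=float))
    features = np.asarray(features, dtype=float)
    F, T = features.shape
    if y.shape[1] != T:
        raise ValueError("features must cover the activity series")
    n_lags = int(round(lag_s * frame_rate))
    if n_lags >= T - folds:
        raise ValueError("lag window too long for the series")
    X = _lagged_design(features, n_lags)
    Yt = y[:, n_lags:]
    n = X.shape[0]
    bounds = np.linspace(0, n, folds + 1).astype(int)
    N = y.shape[0]
    ss_res = np.zeros(N)
    ss_tot = np.zeros(N)
    betas = np.zeros((N, X.shape[1]))
    alphas = np.logspace(-2, 4, 13)
    used_alpha = None
    for f in range(folds):
        lo, hi = bounds[f], bounds[f + 1]
        tr = np.concatenate([np.arange(0, lo), np.arange(hi, n)])
        if ridge is None:
            model = RidgeCV(alphas=alphas)
        else:
            model = Ridge(alpha=ridge)
        model.fit(X[tr], Yt[:, tr].T)
        used_alpha = getattr(model, "alpha_", ridge)
        pred = model.predict(X[lo:hi]).T
        ss_res += ((Yt[:, lo:hi] - pred) ** 2).sum(axis=1)
        mu = Yt[:, tr].mean(axis=1, keepdims=True)
        ss_tot += ((Yt[:, lo:hi] - mu) ** 2).sum(axis=1)
        betas += np.atleast_2d(model.coef_) / folds
    cv_r2 = 100.0 * (1.0 - ss_res / np.maximum(ss_tot, 1e-12))
    betas = betas.reshape(N, n_lags + 1, F)
    return MotionGLMResult(betas=betas, cv_r2=cv_r2,
                           ridge=used_alpha if used_alpha is not None else 0.0,
                           folds=folds, lag_s=lag_s)
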