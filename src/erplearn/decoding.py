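"""Time-resolved decoding of exposure day from single-trial differentials.

A regularized linear discriminant is trained independently at every epoch
timepoint on the three frontal-channel amplitudes of single-trial
deviant-minus-standard responses, labelled by exposure day.  Performance is
the cross-validated ROC AUC (stratified 5-fold, repeated with reshuffling),
and group inference on window-mean AUCs uses a one-tailed sign-flip
permutation t test against chance (AUC = 0.5) with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .erp import AnalysisWindow
from .preprocess import FRONTAL_CHANNELS


@dataclass
class FeatureTensor:
    """Single-trial features: trials x 3 frontal channels x timepoints."""

    data: np.ndarray
    labels: np.ndarray            # day identity per trial
    times_ms: np.ndarray
    participant: str = ""
    channels: tuple[str, ...] = FRONTAL_CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x features x timepoints")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(f"expected {len(self.channels)} feature channels")
        if len(np.unique(self.labels)) != 2:
            raise ValueError("exactly two classes (days) are required")
        if min(np.bincount(self._y())) == 0:
            raise ValueError("both classes must be non-empty")

    def _y(self) -> np.ndarray:
        classes = np.unique(self.labels)
        return (self.labels == classes[1]).astype(int)


@dataclass(frozen=True)
class LdaModel:
    """Fisher discriminant with covariance shrinkage toward scaled identity."""

    weights: np.ndarray
    bias: float
    shrinkage: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


@dataclass(frozen=True)
class DecodingCurve:
    """Per-timepoint cross-validated AUC for one day-pair comparison."""

    auc_per_timepoint: np.ndarray
    times_ms: np.ndarray
    participant: str
    comparison: tuple
    folds: int = 5
    repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.auc_per_timepoint)
        if a.min() < 0.0 or a.max() > 1.0:
            raise ValueError("AUC values must lie in [0, 1]")
        if len(a) != len(self.times_ms):
            raise ValueError("curve length must equal timepoint count")


@dataclass(frozen=True)
class WindowDecodingStat:
    """Group-level window statistic for one comparison x component."""

    component: str
    comparison: tuple
    participant_aucs: np.ndarray
    mean_auc: float
    t: float
    p: float
    p_adjusted: float
    n_permutations: int
    exhaustive: bool = False


def make_features(pairs_by_day: dict, target_fs: float = 50.0,
                  channels=FRONTAL_CHANNELS,
                  deviant_type: str | None = None) -> FeatureTensor:
    """Build the decoding tensor from two days' paired epochs.

    Each deviant trial contributes one single-trial differential (deviant
    epoch minus its paired preceding standard), restricted to the frontal
    channels and anti-alias downsampled to ``target_fs`` on the closed epoch
    grid (36 timepoints at 50 Hz for [-100, 600] ms epochs at 250 Hz).
    """
    if len(pairs_by_day) != 2:
        raise ValueError("exactly two days are compared at a time")
    blocks, labels, participant = [], [], ""
    for day, pairs in sorted(pairs_by_day.items()):
        if deviant_type is not None:
            pairs = pairs.select_type(deviant_type)
        diffs = pairs.differentials(channels=channels)
        blocks.append(diffs)
        labels.extend([day] * diffs.shape[0])
        participant = pairs.participant or participant
        src_fs = 1000.0 / float(np.median(np.diff(pairs.times_ms)))
        times = pairs.times_ms
    X = np.concatenate(blocks, axis=0)
    factor = int(round(src_fs / target_fs))
    if factor > 1:
        X = signal.resample_poly(X, 1, factor, axis=2)
        times = times[::factor][: X.shape[2]]
    return FeatureTensor(data=X, labels=np.array(labels), times_ms=times,
                         participant=participant, channels=tuple(channels))


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def _pooled_cov_and_means(X: np.ndarray, y: np.ndarray):
    X0, X1 = X[y == 0], X[y == 1]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    Xc = np.concatenate([X0 - m0, X1 - m1], axis=0)
    S = Xc.T @ Xc / len(Xc)
    return S, Xc, m0, m1


def ledoit_wolf_shrinkage(Xc: np.ndarray) -> float:
    """Analytic shrinkage intensity toward nu*I for class-centered data."""
    n, p = Xc.shape
    S = Xc.T @ Xc / n
    nu = np.trace(S) / p
    d2 = np.sum((S - nu * np.eye(p)) ** 2)
    if d2 <= 0:
        return 0.0
    b2 = sum(np.sum((np.outer(x, x) - S) ** 2) for x in Xc) / n**2
    return float(min(1.0, b2 / d2))


def lda_train(X: np.ndarray, y: np.ndarray, shrinkage: float | None = None) -> LdaModel:
    """Train a binary LDA with covariance shrinkage.

    The pooled within-class covariance S is shrunk toward nu*I (nu = mean
    eigenvalue): S_lam = (1 - lam) S + lam nu I, and the weights are
    S_lam^{-1} (m1 - m0).  ``shrinkage=None`` estimates lam analytically
    (Ledoit-Wolf); at lam = 1 the weights reduce to the class-mean
    difference.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2:
        raise ValueError("X must be trials x features")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 trials per class")
    S, Xc, m0, m1 = _pooled_cov_and_means(X, y)
    lam = ledoit_wolf_shrinkage(Xc) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    p = X.shape[1]
    nu = np.trace(S) / p
    S_lam = (1.0 - lam) * S + lam * nu * np.eye(p)
    try:
        w = np.linalg.solve(S_lam, m1 - m0)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; use shrinkage > 0") from err
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError(
            "non-finite LDA weights; use shrinkage > 0")
    bias = float(-w @ (m0 + m1) / 2.0)
    return LdaModel(weights=w, bias=bias, shrinkage=lam)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC: P(score_pos > score_neg), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1, n0 = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


# ---------------------------------------------------------------------------
# temporal decoding (vectorized over timepoints)
# ---------------------------------------------------------------------------

def _batched_lda_scores(Xtr, ytr, Xte, shrinkage):
    """Fit LDA per timepoint in one shot; return test scores (trials x T).

    Arrays are trials x features x timepoints.
    """
    T = Xtr.shape[2]
    p = Xtr.shape[1]
    X0, X1 = Xtr[ytr == 0], Xtr[ytr == 1]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)            # p x T
    Xc = np.concatenate([X0 - m0, X1 - m1], axis=0)       # n x p x T
    n = Xc.shape[0]
    S = np.einsum("npt,nqt->tpq", Xc, Xc) / n             # T x p x p
    if shrinkage is None:
        nu = np.trace(S, axis1=1, axis2=2) / p            # T
        eye = np.eye(p)
        d2 = np.sum((S - nu[:, None, None] * eye) ** 2, axis=(1, 2))
        outer = np.einsum("npt,nqt->ntpq", Xc, Xc)        # n x T x p x p
        b2 = np.sum((outer - S[None]) ** 2, axis=(0, 2, 3)) / n**2
        lam = np.clip(np.where(d2 > 0, b2 / np.maximum(d2, 1e-300), 0.0), 0.0, 1.0)
    else:
        lam = np.full(T, float(shrinkage))
        nu = np.trace(S, axis1=1, axis2=2) / p
    S_lam = ((1.0 - lam)[:, None, None] * S
             + (lam * nu)[:, None, None] * np.eye(p))
    md = (m1 - m0).T[:, :, None]                          # T x p x 1
    w = np.linalg.solve(S_lam, md)[:, :, 0]               # T x p
    return np.einsum("npt,tp->nt", Xte, w)


def _batched_auc(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank-based AUC per column of ``scores`` (trials x T), ties averaged."""
    ranks = stats.rankdata(scores, axis=0)
    n1 = int(np.sum(y == 1))
    n0 = scores.shape[0] - n1
    u = ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n0 * n1)


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Class-proportion-preserving folds, trials shuffled once per call."""
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for k, part in enumerate(np.array_split(idx, n_folds)):
            folds[k].extend(part.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def temporal_decoding(features: FeatureTensor, folds: int = 5,
                      repeats: int = 100, seed: int = 0,
                      shrinkage: float | None = None) -> DecodingCurve:
    """Repeated stratified k-fold temporal decoding; AUC per timepoint.

    Per repeat, trials are reshuffled into stratified folds; per fold and
    timepoint an LDA is trained on the remaining folds and scores the
    held-out fold; the AUC is averaged over folds, then over repeats.
    """
    X = features.data
    y = features._y()
    if min(np.bincount(y)) < folds:
        raise ValueError(
            f"cannot stratify: a class has fewer than {folds} trials")
    rng = np.random.default_rng(seed)
    T = X.shape[2]
    acc = np.zeros(T)
    for _ in range(repeats):
        fold_idx = _stratified_folds(y, folds, rng)
        rep = np.zeros(T)
        for k in range(folds):
            test = fold_idx[k]
            train = np.concatenate([fold_idx[j] for j in range(folds) if j != k])
            scores = _batched_lda_scores(X[train], y[train], X[test], shrinkage)
            rep += _batched_auc(scores, y[test])
        acc += rep / folds
    classes = np.unique(features.labels)
    return DecodingCurve(
        auc_per_timepoint=acc / repeats, times_ms=features.times_ms,
        participant=features.participant,
        comparison=(classes[0], classes[1]),
        folds=folds, repeats=repeats, seed=seed,
    )


def window_mean_auc(curve: DecodingCurve, window: AnalysisWindow) -> float:
    """Mean AUC over the timepoints falling inside a component window."""
    m = (curve.times_ms >= window.start_ms - 1e-9) & \
        (curve.times_ms <= window.end_ms + 1e-9)
    if not m.any():
        raise ValueError("window contains no decoding timepoints")
    return float(np.asarray(curve.auc_per_timepoint)[m].mean())


def group_permutation_ttest(values: np.ndarray, null: float = 0.5,
                            n_perm: int = 10_000, m_comparisons: int = 3,
                            seed: int = 0, component: str = "",
                            comparison: tuple = ()) -> WindowDecodingStat:
    """One-tailed (greater) sign-flip permutation t test against chance.

    The observed one-sample t is computed on ``values - null``; the null
    distribution flips the signs of the centred values.  All 2^n sign
    patterns are enumerated when feasible (2^n <= n_perm), giving an exact
    p; otherwise ``n_perm`` random flips with add-one smoothing.  Bonferroni:
    p_adj = min(1, m * p).
    """
    v = np.asarray(values, dtype=float) - null
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 participants")

    def tstat(x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1)
        sd = x.std(axis=-1, ddof=1)
        return mean / (sd / np.sqrt(n))

    t_obs = float(tstat(v))
    exhaustive = 2**n <= n_perm
    if exhaustive:
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n))).reshape(n, -1).T
        t_null = tstat(signs * v)
        p = float(np.mean(t_null >= t_obs - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        t_null = tstat(signs * v)
        p = float((1 + np.sum(t_null >= t_obs - 1e-12)) / (n_perm + 1))
    p_adj = min(1.0, m_comparisons * p)
    return WindowDecodingStat(
        component=component, comparison=tuple(comparison),
        participant_aucs=np.asarray(values, dtype=float),
        mean_auc=float(np.mean(values)), t=t_obs, p=p, p_adjusted=p_adj,
        n_permutations=n_perm, exhaustive=exhaustive,
    )
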