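"""Averaged-ERP, per-timepoint decoding with leave-one-out 3-fold CV.

The decoding unit is the averaged ERP, not the single trial: each iteration
randomly partitions every class's kept trials into ``n_folds`` equal bins
(trial counts equated across classes to avoid spurious accuracy), averages
each bin, trains on the averages of ``n_folds − 1`` bins per class and tests
on the held-out averages, rotating through the folds.  The whole process is
repeated (default 100 iterations) with fresh random assignments, and
accuracy at each timepoint is the proportion of correctly classified test
averages.  Chance is 1/M.

Classifiers: linear soft-margin SVM (binary), error-correcting output codes
over one-vs-one linear SVMs with hinge decoding (multiclass), and shrinkage
LDA with the pooled covariance shrunk toward its diagonal,
``Σ_γ = (1 − γ)·Σ + γ·diag(Σ)``.

Because 3-fold averaged-ERP CV makes every binary subproblem a 4-case
problem (2 training averages per class), the SVM is solved by a batched SMO
on the dual, vectorized across (timepoint × fold × class-pair) subproblems.
This is orders of magnitude faster than per-problem library calls at the
study's scale; a general-purpose library SVM serves as the correctness
oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .synth import EpochSet

__all__ = [
    "ClassifierSpec",
    "FoldAssignment",
    "DecodingRun",
    "DecodingInfeasibleError",
    "assign_folds",
    "average_folds",
    "normalize_fold",
    "fit_predict",
    "decode_timecourse",
    "window_mean",
]


class DecodingInfeasibleError(RuntimeError):
    """Too few kept trials in some class to form the requested folds."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Decoder choice and its regularization.

    ``box_constraint`` is the SVM's soft-margin C; ``gamma`` the LDA
    shrinkage weight in [0, 1] (required iff ``kind == "rlda"``);
    ``normalize`` z-scores each feature using training statistics within
    every fold.
    """

    kind: str = "svm"  # "svm" | "ecoc_svm" | "rlda"
    box_constraint: float = 1.0
    gamma: float | None = None
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "ecoc_svm", "rlda"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "rlda":
            if self.gamma is None or not 0.0 <= self.gamma <= 1.0:
                raise ValueError("rlda requires gamma in [0, 1]")
        elif self.gamma is not None:
            raise ValueError("gamma is only meaningful for rlda")


@dataclass
class FoldAssignment:
    """Per-class partition of kept trials into equal-size folds.

    ``folds[k, f]`` lists the epoch indices averaged into fold ``f`` of
    class ``k``; every (class, fold) bin holds exactly ``n_per_average``
    trials and bins are disjoint within a class.
    """

    folds: np.ndarray  # (M, n_folds, n_per_average) epoch indices

    @property
    def n_per_average(self) -> int:
        return self.folds.shape[2]

    @property
    def n_folds(self) -> int:
        return self.folds.shape[1]


@dataclass
class DecodingRun:
    """Per-iteration × per-timepoint accuracy with its provenance."""

    accuracy: np.ndarray  # (n_iterations, n_timepoints) in [0, 1]
    times: np.ndarray  # ms, the decoded timepoints
    spec: ClassifierSpec
    chance: float
    n_folds: int
    seed: int
    n_per_average: list[int] = field(default_factory=list)  # per iteration


# --------------------------------------------------------------------------
# Fold assignment and averaging
# --------------------------------------------------------------------------

def assign_folds(
    epochs: EpochSet, n_folds: int = 3, rng: np.random.Generator | int = 0
) -> FoldAssignment:
    """Randomly partition kept trials into folds with equated counts.

    ``n_per_average = floor(min_k kept_k / n_folds)``; per class,
    ``n_per_average·n_folds`` kept trials are sampled without replacement and
    split into folds.  Any class with fewer than ``n_folds`` kept trials
    makes decoding infeasible.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    per_class = [
        np.flatnonzero(epochs.keep & (epochs.labels == k)) for k in range(epochs.M)
    ]
    counts = [len(ix) for ix in per_class]
    if min(counts) < n_folds:
        raise DecodingInfeasibleError(
            f"class trial counts {counts} cannot fill {n_folds} folds"
        )
    n_per = min(counts) // n_folds
    folds = np.stack(
        [
            rng.choice(ix, size=n_per * n_folds, replace=False).reshape(n_folds, n_per)
            for ix in per_class
        ]
    )
    return FoldAssignment(folds=folds)


def average_folds(epochs: EpochSet, fa: FoldAssignment) -> np.ndarray:
    """Averaged ERPs, shape ``(M, n_folds, channels, samples)`` μV."""
    return epochs.data[fa.folds].mean(axis=2)


def normalize_fold(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both sets per feature using training mean/SD; zero-variance
    features map to 0 in both sets."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    ok = sd > 0
    tr = np.where(ok, (train - mu) / np.where(ok, sd, 1.0), 0.0)
    te = np.where(ok, (test - mu) / np.where(ok, sd, 1.0), 0.0)
    return tr, te


# --------------------------------------------------------------------------
# Batched linear soft-margin SVM (SMO on the dual)
# --------------------------------------------------------------------------

def _svm_fit_batch(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    max_sweeps: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve B independent linear SVM duals sharing one label vector.

    X: (B, n, F); y: (n,) in {−1, +1}.  Returns (w, b) with w: (B, F),
    b: (B,).  Pairwise SMO updates sweep all coordinate pairs until the
    largest multiplier change falls below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    B, n, _ = X.shape
    G = X @ X.transpose(0, 2, 1)  # (B, n, n)
    a = np.zeros((B, n))
    f = np.zeros((B, n))  # f_i = sum_j a_j y_j G_ij = w·x_i
    pairs = list(combinations(range(n), 2))
    for _ in range(max_sweeps):
        delta = 0.0
        for p, q in pairs:
            s = y[p] * y[q]
            eta = G[:, p, p] + G[:, q, q] - 2.0 * G[:, p, q]
            grad = (f[:, p] - y[p]) - (f[:, q] - y[q])
            step = y[q] * grad / np.where(eta > 1e-12, eta, np.inf)
            if s > 0:
                L = np.maximum(0.0, a[:, p] + a[:, q] - C)
                H = np.minimum(C, a[:, p] + a[:, q])
            else:
                L = np.maximum(0.0, a[:, q] - a[:, p])
                H = np.minimum(C, C + a[:, q] - a[:, p])
            aq = np.clip(a[:, q] + step, L, H)
            dq = aq - a[:, q]
            dp = -s * dq
            a[:, q] = aq
            a[:, p] += dp
            f += (dq * y[q])[:, None] * G[:, :, q] + (dp * y[p])[:, None] * G[:, :, p]
            delta = max(delta, float(np.abs(dq).max(initial=0.0)))
        if delta < tol * C:
            break
    w = np.einsum("bn,bnf->bf", a * y[None, :], X)
    eps = 1e-6 * C
    free = (a > eps) & (a < C - eps)
    resid = y[None, :] - f
    cnt = free.sum(axis=1)
    b_free = (resid * free).sum(axis=1) / np.maximum(cnt, 1)
    neg, pos = y < 0, y > 0
    b_fallback = -0.5 * (f[:, neg].max(axis=1) + f[:, pos].min(axis=1))
    b = np.where(cnt > 0, b_free, b_fallback)
    return w, b


def _ovo_pairs(M: int) -> list[tuple[int, int]]:
    return list(combinations(range(M), 2))


def _rlda_fit_batch(
    X: np.ndarray, y: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Shrinkage-LDA discriminants for B stacked problems.

    X: (B, n, F); y: (n,) ints 0..M−1 (equal priors).  Returns (W, c) with
    class scores ``X_test @ W + c``; W: (B, F, M), c: (B, M).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    M = int(y.max()) + 1
    B, n, F = X.shape
    mu = np.stack([X[:, y == k].mean(axis=1) for k in range(M)], axis=1)  # (B,M,F)
    centered = X - mu[:, y]
    dof = max(n - M, 1)
    S = np.einsum("bnf,bng->bfg", centered, centered) / dof
    d = np.einsum("bff->bf", S)
    Sg = (1.0 - gamma) * S
    ii = np.arange(F)
    Sg[:, ii, ii] = d
    Sinv = np.linalg.pinv(Sg, hermitian=True)
    W = np.einsum("bfg,bkg->bfk", Sinv, mu)
    c = -0.5 * np.einsum("bkf,bfk->bk", mu, W)
    return W, c


# --------------------------------------------------------------------------
# Public single-problem classifier
# --------------------------------------------------------------------------

def fit_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
) -> np.ndarray:
    """Train the specified classifier and predict labels for ``test_X``.

    Ties are broken toward the lowest class label throughout.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    classes = np.unique(train_y)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")

    if spec.kind == "svm":
        if len(classes) != 2:
            raise ValueError("kind='svm' is binary; use 'ecoc_svm' for multiclass")
        y = np.where(train_y == classes[1], 1.0, -1.0)
        w, b = _svm_fit_batch(train_X[None], y, C=spec.box_constraint)
        d = test_X @ w[0] + b[0]
        return np.where(d > 0, classes[1], classes[0])

    if spec.kind == "ecoc_svm":
        Mc = len(classes)
        pairs = _ovo_pairs(Mc)
        losses = np.zeros((test_X.shape[0], Mc))
        for i, j in pairs:
            sub = (train_y == classes[i]) | (train_y == classes[j])
            y = np.where(train_y[sub] == classes[i], 1.0, -1.0)
            w, b = _svm_fit_batch(train_X[sub][None], y, C=spec.box_constraint)
            d = test_X @ w[0] + b[0]
            losses[:, i] += np.maximum(0.0, 1.0 - d)
            losses[:, j] += np.maximum(0.0, 1.0 + d)
        return classes[np.argmin(losses, axis=1)]

    # rlda
    codes = np.searchsorted(classes, train_y)
    W, c = _rlda_fit_batch(train_X[None], codes, spec.gamma)
    scores = test_X @ W[0] + c[0]
    return classes[np.argmax(scores, axis=1)]


# --------------------------------------------------------------------------
# Time-resolved decoding
# --------------------------------------------------------------------------

def _normalize_batch(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature, per-timepoint z-scoring from training statistics.

    Xtr: (cases, F, Td); Xte: (cases_te, F, Td).
    """
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    ok = sd > 0
    safe = np.where(ok, sd, 1.0)
    return (
        np.where(ok, (Xtr - mu) / safe, 0.0),
        np.where(ok, (Xte - mu) / safe, 0.0),
    )


def decode_timecourse(
    epochs: EpochSet,
    spec: ClassifierSpec,
    n_iterations: int = 100,
    n_folds: int = 3,
    seed: int = 0,
    window: tuple[float, float] | None = None,
    decim: int = 1,
    channels=None,
) -> DecodingRun:
    """Run the full averaged-ERP decoding loop on one participant.

    ``window`` restricts decoding to timepoints inside the given ms range
    (inclusive; default: every sample), and ``decim`` keeps every
    ``decim``-th of those.  Features default to the scalp channels.
    Per-iteration randomness comes from streams derived from
    ``(seed, iteration)``, so the accuracy matrix is reproducible and
    iterations are independent.
    """
    feat = (
        np.asarray(channels, dtype=int)
        if channels is not None
        else epochs.montage.scalp_indices
    )
    times = epochs.times
    if window is not None:
        sel = np.flatnonzero((times >= window[0] - 1e-9) & (times <= window[1] + 1e-9))
        if sel.size == 0:
            raise ValueError("decoding window contains no samples")
    else:
        sel = np.arange(len(times))
    t_idx = sel[::decim]
    Td = len(t_idx)
    M = epochs.M

    pairs = _ovo_pairs(M)
    idx_i = np.array([p[0] for p in pairs])
    idx_j = np.array([p[1] for p in pairs])

    acc = np.zeros((n_iterations, Td))
    n_pers: list[int] = []
    for it in range(n_iterations):
        rng = np.random.default_rng([seed, it])
        fa = assign_folds(epochs, n_folds=n_folds, rng=rng)
        n_pers.append(fa.n_per_average)
        avg = average_folds(epochs, fa)  # (M, n_folds, C, T)
        A = avg[:, :, feat][:, :, :, t_idx]  # (M, n_folds, F, Td)
        correct = np.zeros(Td)
        for fold in range(n_folds):
            train_f = [f for f in range(n_folds) if f != fold]
            Xtr = A[:, train_f]  # (M, n_folds-1, F, Td)
            Xte = A[:, fold]  # (M, F, Td)
            if spec.normalize:
                flat_tr = Xtr.reshape(-1, *Xtr.shape[2:])
                flat_tr, Xte = _normalize_batch(flat_tr, Xte)
                Xtr = flat_tr.reshape(Xtr.shape)
            correct += _fold_correct(spec, Xtr, Xte, idx_i, idx_j)
        acc[it] = correct / (n_folds * M)
    return DecodingRun(
        accuracy=acc,
        times=times[t_idx],
        spec=spec,
        chance=1.0 / M,
        n_folds=n_folds,
        seed=seed,
        n_per_average=n_pers,
    )


def _fold_correct(
    spec: ClassifierSpec,
    Xtr: np.ndarray,
    Xte: np.ndarray,
    idx_i: np.ndarray,
    idx_j: np.ndarray,
) -> np.ndarray:
    """Correct-classification counts per timepoint for one fold.

    Xtr: (M, n_tr_folds, F, Td) training averages; Xte: (M, F, Td) test
    averages (true class = row index).
    """
    M, n_tr, F, Td = Xtr.shape
    C = spec.box_constraint

    if spec.kind == "rlda":
        Xp = Xtr.reshape(M * n_tr, F, Td).transpose(2, 0, 1)  # (Td, n, F)
        yy = np.repeat(np.arange(M), n_tr)
        W, c = _rlda_fit_batch(Xp, yy, spec.gamma)  # (Td,F,M), (Td,M)
        scores = np.einsum("mft,tfk->tmk", Xte, W) + c[:, None, :]
        pred = np.argmax(scores, axis=2)  # (Td, M)
        return (pred == np.arange(M)[None, :]).sum(axis=1).astype(float)

    if spec.kind == "svm" and M == 2:
        Xp = Xtr.reshape(2 * n_tr, F, Td).transpose(2, 0, 1)  # (Td, 2n, F)
        y = np.concatenate([-np.ones(n_tr), np.ones(n_tr)])  # class1 -> +1
        w, b = _svm_fit_batch(Xp, y, C=C)  # (Td, F), (Td,)
        d = np.einsum("mft,tf->tm", Xte, w) + b[:, None]  # (Td, 2)
        pred = (d > 0).astype(int)
        return (pred == np.arange(2)[None, :]).sum(axis=1).astype(float)

    # ECOC: one-vs-one linear SVMs, hinge decoding, lowest-index ties
    n_pairs = len(idx_i)
    Xi = Xtr[idx_i]  # (P, n_tr, F, Td)
    Xj = Xtr[idx_j]
    Xp = np.concatenate([Xi, Xj], axis=1)  # (P, 2n, F, Td)
    Xp = Xp.transpose(0, 3, 1, 2).reshape(n_pairs * Td, 2 * n_tr, F)
    y = np.concatenate([np.ones(n_tr), -np.ones(n_tr)])  # class i -> +1
    w, b = _svm_fit_batch(Xp, y, C=C)
    w = w.reshape(n_pairs, Td, F)
    b = b.reshape(n_pairs, Td)
    d = np.einsum("ptf,mft->ptm", w, Xte) + b[:, :, None]  # (P, Td, M_test)
    hinge_pos = np.maximum(0.0, 1.0 - d)
    hinge_neg = np.maximum(0.0, 1.0 + d)
    Ipos = np.zeros((n_pairs, Xte.shape[0]))
    Ineg = np.zeros_like(Ipos)
    Ipos[np.arange(n_pairs), idx_i] = 1.0
    Ineg[np.arange(n_pairs), idx_j] = 1.0
    losses = np.einsum("ptm,pk->tmk", hinge_pos, Ipos) + np.einsum(
        "ptm,pk->tmk", hinge_neg, Ineg
    )
    pred = np.argmin(losses, axis=2)  # (Td, M_test)
    return (pred == np.arange(Xte.shape[0])[None, :]).sum(axis=1).astype(float)


def window_mean(
    run: DecodingRun, window: tuple[float, float], times: np.ndarray | None = None
) -> float:
    """Iteration-averaged accuracy, averaged over the decoded timepoints
    falling inside ``window`` (ms, inclusive)."""
    t = np.asarray(times) if times is not None else run.times
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError("window does not overlap the decoded timepoints")
    return float(run.accuracy.mean(axis=0)[mask].mean())
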