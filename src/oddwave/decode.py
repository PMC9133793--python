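"""Time-resolved pairwise decoding with multivariate noise normalization.

The decoding scheme, applied per participant:

1. trials of the two conditions are randomly assigned to ``n_folds``
   stratified folds;
2. a noise covariance is estimated on the training folds only, with the
   "epoch" method: the across-trial sensor covariance of (trial - condition
   mean) is computed per time point within each condition, then averaged
   across time points and conditions, shrunk toward its diagonal with an
   analytically chosen intensity, and inverted (matrix inverse square root)
   into a whitener applied to training and test folds alike;
3. trials of the same condition within each fold are averaged into one
   pseudo-trial per condition per fold;
4. at every time point a linear C-SVM is trained on the 2(n_folds - 1)
   training pseudo-trials and tested on the 2 held-out pseudo-trials;
5. accuracy is averaged over folds and over ``n_repetitions`` random fold
   assignments, yielding one accuracy time series (chance = 50%).

Temporal generalization reuses the identical engine but tests every
classifier at every time point of a decimated grid; its diagonal equals the
time-resolved analysis run on the same grid with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._svm import svm_train_batch
from .containers import EpochsData

__all__ = [
    "DecodeConfig",
    "NoiseNormalizer",
    "DecodingResult",
    "TGResult",
    "estimate_epoch_noise_covariance",
    "decode_timecourse",
    "temporal_generalization",
    "subset_trials",
]


@dataclass(frozen=True)
class DecodeConfig:
    n_folds: int = 5
    n_repetitions: int = 100
    svm_c: float = 1.0  # regularization constant of the linear max-margin classifier
    shrinkage: str | float = "auto"  # analytic intensity, or a fixed gamma in [0, 1]
    tg_downsample: int = 4
    seed: int | None = None
    record_folds: bool = False  # keep per-repetition train/test index logs

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_repetitions < 1:
            raise ValueError("need at least 1 repetition")
        if self.tg_downsample < 1:
            raise ValueError("tg_downsample must be >= 1")
        if not isinstance(self.shrinkage, str) and not 0.0 <= float(self.shrinkage) <= 1.0:
            raise ValueError("fixed shrinkage gamma must lie in [0, 1]")


@dataclass
class NoiseNormalizer:
    covariance: np.ndarray  # shrunk sensor x sensor covariance
    shrinkage_gamma: float
    whitener: np.ndarray  # inverse matrix square root of the covariance


@dataclass
class DecodingResult:
    accuracy: np.ndarray  # (n_times,), proportion correct in [0, 1]
    times: np.ndarray  # ms
    condition_pair: tuple[str, str]
    n_trials_used: dict[str, int]
    config: DecodeConfig
    fold_log: list | None = None


@dataclass
class TGResult:
    matrix: np.ndarray  # (n_train_times, n_test_times) accuracy
    times: np.ndarray  # shared (decimated) ms grid
    condition_pair: tuple[str, str]
    n_trials_used: dict[str, int]
    config: DecodeConfig

    @property
    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.matrix).copy()


def _shrinkage_gamma(residuals: np.ndarray) -> float:
    """Ledoit-Wolf-style analytic intensity for shrinkage toward the diagonal.

    ``residuals`` is (N, p): demeaned observations pooled over conditions and
    time points.  gamma* = sum_offdiag Var(s_ij) / sum_offdiag s_ij^2, clipped
    to [0, 1].
    """
    N, _ = residuals.shape
    if N < 2:
        return 1.0
    Z = residuals
    Sm = Z.T @ Z / N  # raw second moments
    S2 = (Z**2).T @ (Z**2) / N
    var_s = (N / (N - 1.0) ** 3) * N * (S2 - Sm**2)
    s = Sm * (N / (N - 1.0))
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = float((s[off] ** 2).sum())
    if denom <= 0:
        return 1.0
    return float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))


def _inverse_sqrt(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)
    w = np.maximum(w, 1e-12 * w.max())
    return (v / np.sqrt(w)) @ v.T


def estimate_epoch_noise_covariance(
    X: np.ndarray, labels: np.ndarray, shrinkage: str | float = "auto"
) -> NoiseNormalizer:
    """Epoch-method noise covariance with shrinkage toward the diagonal.

    ``X`` is (n_trials, n_sensors, n_times); ``labels`` gives the condition of
    each trial.  The covariance is computed per time point separately within
    each condition, averaged across time points and then conditions, shrunk,
    and inverted into a whitener.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    covs = []
    resid = []
    for c in classes:
        Xc = X[labels == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"need >= 2 trials per condition, got {Xc.shape[0]} for {c!r}")
        R = Xc - Xc.mean(axis=0, keepdims=True)
        n_c, _, t = R.shape
        covs.append(np.einsum("npt,nqt->pq", R, R) / ((n_c - 1) * t))
        resid.append(R.transpose(0, 2, 1).reshape(-1, R.shape[1]))
    S = np.mean(covs, axis=0)
    gamma = _shrinkage_gamma(np.vstack(resid)) if shrinkage == "auto" else float(shrinkage)
    S_shrunk = (1.0 - gamma) * S + gamma * np.diag(np.diag(S))
    return NoiseNormalizer(
        covariance=S_shrunk, shrinkage_gamma=gamma, whitener=_inverse_sqrt(S_shrunk)
    )


def _as_binary(labels: Sequence) -> tuple[np.ndarray, tuple[str, str]]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 conditions, got {classes.size}")
    return (labels == classes[1]).astype(int), (str(classes[0]), str(classes[1]))


def _assign_folds(rng: np.random.Generator, y01: np.ndarray, n_folds: int) -> np.ndarray:
    """Stratified random fold assignment (round-robin within each condition)."""
    folds = np.empty(y01.size, dtype=int)
    for c in (0, 1):
        idx = np.flatnonzero(y01 == c)
        if idx.size < n_folds:
            raise ValueError(
                f"condition {c} has {idx.size} trials; cannot fill {n_folds} folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % n_folds
    return folds


def _decode_engine(
    X: np.ndarray,
    y01: np.ndarray,
    config: DecodeConfig,
    full_matrix: bool,
) -> tuple[np.ndarray, list | None]:
    n, p, t = X.shape
    k = config.n_folds
    rng = np.random.default_rng(config.seed)
    acc = np.zeros((t, t)) if full_matrix else np.zeros(t)
    y_sv = np.concatenate([-np.ones(k - 1), np.ones(k - 1)])
    fold_log: list | None = [] if config.record_folds else None

    for _ in range(config.n_repetitions):
        folds = _assign_folds(rng, y01, k)
        for f in range(k):
            train_mask = folds != f
            norm = estimate_epoch_noise_covariance(
                X[train_mask], y01[train_mask], config.shrinkage
            )
            if fold_log is not None:
                fold_log.append(
                    {
                        "test_trials": np.flatnonzero(~train_mask),
                        "normalizer_trials": np.flatnonzero(train_mask),
                    }
                )
            W = norm.whitener
            Xw = np.einsum("pq,nqt->npt", W, X)  # whitening is linear: apply once
            # pseudo-trials: one per condition per fold
            train_ps = np.empty((2 * (k - 1), p, t))
            pos = 0
            for c in (0, 1):
                for g in range(k):
                    if g == f:
                        continue
                    sel = (folds == g) & (y01 == c)
                    train_ps[pos] = Xw[sel].mean(axis=0)
                    pos += 1
            test_ps = np.stack(
                [Xw[(folds == f) & (y01 == c)].mean(axis=0) for c in (0, 1)]
            )  # (2, p, t)
            Xtr = train_ps.transpose(2, 0, 1)  # (t, m, p)
            K = np.einsum("tmp,tnp->tmn", Xtr, Xtr)
            alpha, b = svm_train_batch(K, y_sv, C=config.svm_c)
            wvec = np.einsum("tm,tmp->tp", alpha * y_sv[None, :], Xtr)  # primal weights
            Xte = test_ps.transpose(2, 0, 1)  # (t, 2, p)
            if full_matrix:
                dec = np.einsum("tp,ujp->tuj", wvec, Xte) + b[:, None, None]
                correct = (dec[:, :, 0] <= 0).astype(float) + (dec[:, :, 1] > 0)
                acc += correct / 2.0
            else:
                dec = np.einsum("tp,tjp->tj", wvec, Xte) + b[:, None]
                acc += ((dec[:, 0] <= 0).astype(float) + (dec[:, 1] > 0)) / 2.0
    acc /= k * config.n_repetitions
    return acc, fold_log


def decode_timecourse(
    epochs: EpochsData, condition_labels: Sequence, config: DecodeConfig | None = None
) -> DecodingResult:
    """One decoding-accuracy time series for a binary contrast.

    ``condition_labels`` has one entry per trial in ``epochs``; the full epoch
    grid is decoded and stored (inference later restricts to 0-550 ms).
    Deterministic given ``config.seed``.
    """
    config = config if config is not None else DecodeConfig()
    if epochs.normalization_state != "z-normalized":
        raise ValueError("decode expects baseline z-normalized epochs")
    y01, pair = _as_binary(condition_labels)
    acc, log = _decode_engine(epochs.data, y01, config, full_matrix=False)
    return DecodingResult(
        accuracy=acc,
        times=epochs.times.copy(),
        condition_pair=pair,
        n_trials_used={pair[0]: int((y01 == 0).sum()), pair[1]: int((y01 == 1).sum())},
        config=config,
        fold_log=log,
    )


def temporal_generalization(
    epochs: EpochsData, condition_labels: Sequence, config: DecodeConfig | None = None
) -> TGResult:
    """Train at each time point of a decimated grid, test at every time point.

    The matrix diagonal equals ``decode_timecourse`` run on the decimated
    epochs with the same seed (shared engine, shared fold draws).
    """
    config = config if config is not None else DecodeConfig()
    if epochs.normalization_state != "z-normalized":
        raise ValueError("decode expects baseline z-normalized epochs")
    dec = epochs.decimate(config.tg_downsample)
    y01, pair = _as_binary(condition_labels)
    acc, _ = _decode_engine(dec.data, y01, config, full_matrix=True)
    return TGResult(
        matrix=acc,
        times=dec.times.copy(),
        condition_pair=pair,
        n_trials_used={pair[0]: int((y01 == 0).sum()), pair[1]: int((y01 == 1).sum())},
        config=config,
    )


def subset_trials(
    trial_indices: dict[str, np.ndarray], target_count: int, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Uniform random subsets without replacement, one per condition.

    Used to match trial counts across repetition levels (e.g. subsetting 2nds
    through 5ths down to the number of usable 6ths) so that accuracies are
    comparable.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for key, idx in trial_indices.items():
        idx = np.asarray(idx)
        if target_count > idx.size:
            raise ValueError(
                f"target {target_count} exceeds the {idx.size} available trials for {key!r}"
            )
        if target_count == idx.size:
            out[key] = idx.copy()
        else:
            out[key] = np.sort(rng.choice(idx, size=target_count, replace=False))
    return out
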