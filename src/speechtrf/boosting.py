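"""Sparse TRF estimation by coordinate-descent boosting with early stopping.

The kernel starts at zero. Each iteration evaluates, for every
(feature, lag) weight, the training mean-squared-error change of adding
+step or -step, and applies the single best update (ties broken by the
lowest column index, + before -). After every update the validation MSE is
tracked; training stops once it has failed to improve for ``patience``
consecutive updates (or when no candidate reduces the training error), and
the kernel with the smallest validation MSE is returned.

All per-iteration work runs on sufficient statistics (Gram matrices and
correlations), so an update costs O(columns) regardless of the number of
samples; the hot loop is JIT-compiled with numba when available.

Cross-validation follows a rotating six-fold scheme: the segments are
partitioned in order into six contiguous groups (sizes as equal as
possible), and in fold f group f is the test set, group f+1 the validation
set, and the remaining four groups the training set — every segment trains
four times, validates once and tests once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import LAG_MS, LAG_SAMPLES, lagged_matrix
from .features import SpeechFeatureSet, ModelSpec

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


class BoostingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Cross-validation schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVSchedule:
    """Six-fold rotation over segment groups."""

    groups: tuple[tuple[int, ...], ...]
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]], ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_cv_schedule(
    segment_ids: Sequence[int], seed: int | None = None, n_folds: int = 6
) -> CVSchedule:
    """Partition segments into six contiguous groups and rotate them.

    Extra segments go to the earliest groups (25 segments -> sizes
    5,4,4,4,4,4). ``seed``, if given, shuffles the segment order before the
    contiguous partition; the default is the deterministic in-order rule.
    """
    ids = list(segment_ids)
    if len(ids) < n_folds:
        raise BoostingError(f"need >= {n_folds} segments, got {len(ids)}")
    if seed is not None:
        np.random.default_rng(seed).shuffle(ids)
    base, extra = divmod(len(ids), n_folds)
    groups: list[tuple[int, ...]] = []
    start = 0
    for g in range(n_folds):
        size = base + (1 if g < extra else 0)
        groups.append(tuple(ids[start : start + size]))
        start += size
    folds = []
    for f in range(n_folds):
        test = groups[f]
        val = groups[(f + 1) % n_folds]
        train = tuple(
            s for g in range(n_folds) if g not in (f, (f + 1) % n_folds) for s in groups[g]
        )
        folds.append((train, val, test))
    return CVSchedule(tuple(groups), tuple(folds))


# ---------------------------------------------------------------------------
# Boosting core
# ---------------------------------------------------------------------------


@njit(cache=True)
def _boost_loop(G, c, Gv, cv, val_sse, step, patience, max_iter):  # pragma: no cover
    P = G.shape[0]
    js = np.empty(max_iter, np.int64)
    ds = np.empty(max_iter, np.float64)
    best_sse = val_sse
    best_t = 0
    bad = 0
    t = 0
    while t < max_iter:
        best_v = 0.0
        best_j = -1
        best_d = 0.0
        for j in range(P):
            gjj = G[j, j]
            cj = c[j]
            vp = step * step * gjj - 2.0 * step * cj
            if vp < best_v:
                best_v = vp
                best_j = j
                best_d = step
            vm = step * step * gjj + 2.0 * step * cj
            if vm < best_v:
                best_v = vm
                best_j = j
                best_d = -step
        if best_j < 0:
            break
        val_sse = val_sse + best_d * best_d * Gv[best_j, best_j] - 2.0 * best_d * cv[best_j]
        for k in range(P):
            c[k] -= best_d * G[best_j, k]
            cv[k] -= best_d * Gv[best_j, k]
        js[t] = best_j
        ds[t] = best_d
        t += 1
        if val_sse < best_sse:
            best_sse = val_sse
            best_t = t
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    return js[:t], ds[:t], best_t, best_sse


@dataclass(frozen=True)
class BoostResult:
    kernel: np.ndarray  # flattened (features*lags,) weight vector
    n_steps: int  # accepted updates performed
    best_step: int  # iteration index of the returned (min-val-MSE) kernel
    val_mse: float  # validation MSE of the returned kernel
    updates: tuple[tuple[int, float], ...]  # (column, delta) per iteration


def _boost_from_stats(
    G: np.ndarray,
    b: np.ndarray,
    Gv: np.ndarray,
    bv: np.ndarray,
    val_sse0: float,
    n_val: int,
    *,
    step: float,
    patience: int,
    max_iter: int,
) -> BoostResult:
    c = b.astype(np.float64).copy()
    cv = bv.astype(np.float64).copy()
    js, ds, best_t, best_sse = _boost_loop(
        np.ascontiguousarray(G, dtype=np.float64),
        c,
        np.ascontiguousarray(Gv, dtype=np.float64),
        cv,
        float(val_sse0),
        float(step),
        int(patience),
        int(max_iter),
    )
    kernel = np.zeros(G.shape[0])
    for j, d in zip(js[:best_t], ds[:best_t]):
        kernel[j] += d
    return BoostResult(
        kernel=kernel,
        n_steps=int(len(js)),
        best_step=int(best_t),
        val_mse=float(best_sse) / max(n_val, 1),
        updates=tuple((int(j), float(d)) for j, d in zip(js, ds)),
    )


def boost_kernel(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    *,
    step: float = 0.005,
    patience: int = 32,
    max_iter: int = 10_000,
) -> BoostResult:
    """Boost one kernel for a single-electrode target.

    Designs and targets are expected z-scored (per channel, on training
    statistics) by the caller.
    """
    for arr in (X_train, y_train, X_val, y_val):
        if not np.all(np.isfinite(arr)):
            raise BoostingError("non-finite values in boosting inputs")
    G = X_train.T @ X_train
    b = X_train.T @ y_train
    Gv = X_val.T @ X_val
    bv = X_val.T @ y_val
    return _boost_from_stats(
        G, b, Gv, bv, float(y_val @ y_val), len(y_val),
        step=step, patience=patience, max_iter=max_iter,
    )


def predict_eeg(kernel: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Linear forward prediction: design @ flattened kernel."""
    kernel = np.asarray(kernel, dtype=float).ravel()
    if design.shape[1] != kernel.size:
        raise BoostingError(
            f"design has {design.shape[1]} columns, kernel {kernel.size} weights"
        )
    return design @ kernel


def encoding_accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson r between observed and predicted; NaN if either is constant."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 3:
        raise BoostingError("need equal-length series of >= 3 samples")
    so, sp = observed.std(), predicted.std()
    if so == 0 or sp == 0:
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1])


# ---------------------------------------------------------------------------
# Full mTRF fit
# ---------------------------------------------------------------------------


@dataclass
class TRFFit:
    """Fitted multivariate TRF for one participant and model."""

    model_name: str
    feature_names: tuple[str, ...]
    electrodes: tuple[str, ...]
    lag_ms: np.ndarray
    kernels: np.ndarray  # (features, lags, electrodes), fold-averaged
    per_fold_kernels: np.ndarray  # (folds, features, lags, electrodes)
    encoding_accuracy: np.ndarray  # (electrodes,), fold-averaged Pearson r
    meta: dict = field(default_factory=dict)

    @property
    def accuracy_mean(self) -> float:
        return float(np.nanmean(self.encoding_accuracy))

    def kernel(self, feature: str) -> np.ndarray:
        return self.kernels[self.feature_names.index(feature)]


class FoldStats:
    """Feature-side sufficient statistics per fold, shareable across
    participants (the stimulus features are identical for everyone)."""

    def __init__(
        self,
        channel_blocks: Sequence[np.ndarray],
        schedule: CVSchedule,
        lags: np.ndarray = LAG_SAMPLES,
    ) -> None:
        self.blocks = [np.atleast_2d(np.asarray(b, float)) for b in channel_blocks]
        self.schedule = schedule
        self.lags = lags
        self.per_fold = []
        for train, val, test in schedule.folds:
            concat = np.concatenate([self.blocks[s] for s in train], axis=1)
            mu = concat.mean(axis=1)
            sd = concat.std(axis=1)
            sd[sd == 0] = 1.0
            G = 0.0
            for s in train:
                D = self._design(s, mu, sd)
                G = G + D.T @ D
            Gv = 0.0
            for s in val:
                D = self._design(s, mu, sd)
                Gv = Gv + D.T @ D
            self.per_fold.append({"mu": mu, "sd": sd, "G": G, "Gv": Gv})

    def _design(self, s: int, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
        z = (self.blocks[s] - mu[:, None]) / sd[:, None]
        return lagged_matrix(z, self.lags)

    def design(self, fold: int, s: int) -> np.ndarray:
        f = self.per_fold[fold]
        return self._design(s, f["mu"], f["sd"])


def fit_mtrf(
    model_spec: ModelSpec,
    feature_sets: Sequence[SpeechFeatureSet],
    residual_eeg: np.ndarray,
    schedule: CVSchedule,
    *,
    electrodes: Sequence[str] | None = None,
    step: float = 0.005,
    patience: int = 32,
    max_iter: int = 10_000,
    truncate_s: float = 1.0,
    basis_width_ms: float = 1.0,
    _fold_stats: FoldStats | None = None,
) -> TRFFit:
    """Fit one mTRF model for one participant under the six-fold rotation.

    ``residual_eeg`` (segments x electrodes x samples) must already be
    residualized for this model's nuisance set. The first ``truncate_s``
    seconds of every segment are dropped from features and EEG before
    fitting; feature channels and targets are z-scored on training
    statistics per fold. Returned kernels are fold-averaged and expressed in
    target units per z-scored regressor unit.
    """
    eeg = np.asarray(residual_eeg, dtype=float)
    S, E, T = eeg.shape
    if S != len(feature_sets):
        raise BoostingError("segment count mismatch between EEG and features")
    sr = feature_sets[0].sample_rate
    skip = int(round(truncate_s * sr))
    names = model_spec.features_of_interest
    F = len(names)
    blocks = [fs.as_array(names)[:, skip:] for fs in feature_sets]
    eeg = eeg[:, :, skip:]
    if electrodes is None:
        electrodes = tuple(f"E{i}" for i in range(E))

    fs = _fold_stats or FoldStats(blocks, schedule)
    n_folds = schedule.n_folds
    L = len(fs.lags)
    per_fold_kernels = np.zeros((n_folds, F, L, E))
    acc = np.zeros((n_folds, E))
    n_steps = np.zeros((n_folds, E), dtype=int)

    seg_index = {s: i for i, s in enumerate(range(S))}
    for fi, (train, val, test) in enumerate(schedule.folds):
        stats = fs.per_fold[fi]
        # target z-scoring on training statistics, per electrode
        ytr = np.concatenate([eeg[seg_index[s]] for s in train], axis=1)  # (E, Ttr)
        ymu = ytr.mean(axis=1)
        ysd = ytr.std(axis=1)
        ysd[ysd == 0] = 1.0

        P = F * L
        b = np.zeros((P, E))
        for s in train:
            D = fs.design(fi, seg_index[s])
            Y = (eeg[seg_index[s]] - ymu[:, None]) / ysd[:, None]
            b += D.T @ Y.T
        bv = np.zeros((P, E))
        val_sse0 = np.zeros(E)
        n_val = 0
        for s in val:
            D = fs.design(fi, seg_index[s])
            Y = (eeg[seg_index[s]] - ymu[:, None]) / ysd[:, None]
            bv += D.T @ Y.T
            val_sse0 += (Y**2).sum(axis=1)
            n_val += Y.shape[1]

        test_designs = [fs.design(fi, seg_index[s]) for s in test]
        for e in range(E):
            res = _boost_from_stats(
                stats["G"], b[:, e], stats["Gv"], bv[:, e], val_sse0[e], n_val,
                step=step, patience=patience, max_iter=max_iter,
            )
            w = res.kernel
            n_steps[fi, e] = res.n_steps
            # back to target units per z-scored regressor unit
            per_fold_kernels[fi, :, :, e] = w.reshape(F, L) * ysd[e]
            obs = np.concatenate(
                [(eeg[seg_index[s]][e] - ymu[e]) / ysd[e] for s in test]
            )
            pred = np.concatenate([D @ w for D in test_designs])
            r = encoding_accuracy(obs, pred)
            # an all-zero kernel predicts a constant: no tracking, r = 0
            acc[fi, e] = 0.0 if np.isnan(r) else r

    kernels = per_fold_kernels.mean(axis=0)
    kernels = _basis_smooth(kernels, basis_width_ms, sr)
    return TRFFit(
        model_name=model_spec.model_name,
        feature_names=tuple(names),
        electrodes=tuple(electrodes),
        lag_ms=LAG_MS.copy(),
        kernels=kernels,
        per_fold_kernels=per_fold_kernels,
        encoding_accuracy=acc.mean(axis=0),
        meta={"n_steps": n_steps, "step": step, "patience": patience},
    )


def _basis_smooth(kernels: np.ndarray, width_ms: float, sr: int) -> np.ndarray:
    """Optional Hamming-window kernel smoothing; a no-op below one sample."""
    width = int(round(width_ms / 1000.0 * sr))
    if width <= 1:
        return kernels
    win = np.hamming(width)
    win /= win.sum()
    out = np.empty_like(kernels)
    for f in range(kernels.shape[0]):
        for e in range(kernels.shape[2]):
            out[f, :, e] = np.convolve(kernels[f, :, e], win, mode="same")
    return out
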