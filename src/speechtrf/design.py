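"""Time-lagged design matrices and nuisance residualization.

The encoding models operate on a fixed lag axis of -200..600 ms at 128 Hz.
That span is not integral in samples (-25.6..76.8), so the axis is realised
as integer sample lags -26..76 inclusive: exactly 103 lags covering
-203.1..593.8 ms.

Residualization removes, per electrode, the variance an ordinary least
squares fit on the lagged nuisance regressors (plus intercept) can explain,
pooling all segments of a participant; what remains is the target for the
model of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Integer sample lags realising the -200..600 ms axis at 128 Hz (103 lags).
LAG_SAMPLES = np.arange(-26, 77)
LAG_MS = LAG_SAMPLES / 128.0 * 1000.0
N_LAGS = len(LAG_SAMPLES)


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class LaggedDesign:
    """samples x (channels * lags) matrix with column labels."""

    matrix: np.ndarray
    channel_names: tuple[str, ...]
    lag_samples: np.ndarray

    @property
    def columns(self) -> list[tuple[str, int]]:
        return [(c, int(t)) for c in self.channel_names for t in self.lag_samples]


def lagged_matrix(channels: np.ndarray, lags: np.ndarray = LAG_SAMPLES) -> np.ndarray:
    """Build the (T, C*L) lag-expanded matrix of a (C, T) channel block.

    Column (c, tau) at row t holds channel c at sample t - tau; samples
    outside the segment are zero. Built per segment, never across segment
    boundaries.
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    C, T = channels.shape
    if C == 0:
        raise DesignError("empty channel set")
    L = len(lags)
    X = np.zeros((T, C * L))
    for c in range(C):
        x = channels[c]
        for li, tau in enumerate(lags):
            col = c * L + li
            if abs(tau) >= T:
                continue  # shift leaves the segment entirely; column is zero
            if tau >= 0:
                X[tau:, col] = x[: T - tau]
            elif tau < 0:
                X[:tau, col] = x[-tau:]
    return X


def lagged_design(
    channels: np.ndarray,
    channel_names: Sequence[str],
    lags: np.ndarray = LAG_SAMPLES,
) -> LaggedDesign:
    return LaggedDesign(lagged_matrix(channels, lags), tuple(channel_names), lags)


def _solve_normal(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve G beta = b; minimum-norm (pseudoinverse) fallback when singular."""
    from scipy.linalg import cho_factor, cho_solve

    try:
        return cho_solve(cho_factor(G), b)
    except np.linalg.LinAlgError:
        logger.warning("rank-deficient nuisance design; minimum-norm solution used")
        return np.linalg.pinv(G) @ b


class LaggedNuisance:
    """Pre-computed nuisance regression shared across participants.

    The nuisance channels (identical for every participant, being stimulus
    features) are z-scored over the pooled segments, lag-expanded, and their
    Gram matrix cached; :meth:`residualize` then only needs the per-electrode
    cross-products for each participant's EEG.
    """

    def __init__(
        self,
        channel_blocks: Sequence[np.ndarray],
        lags: np.ndarray = LAG_SAMPLES,
    ) -> None:
        blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in channel_blocks]
        if not blocks or blocks[0].shape[0] == 0:
            raise DesignError("empty channel set")
        concat = np.concatenate(blocks, axis=1)
        mu = concat.mean(axis=1)
        sd = concat.std(axis=1)
        sd[sd == 0] = 1.0
        self._z = [(b - mu[:, None]) / sd[:, None] for b in blocks]
        self.lags = lags
        self._designs = [lagged_matrix(z, lags) for z in self._z]
        P = self._designs[0].shape[1]
        # Gram of [design, intercept]
        G = np.zeros((P + 1, P + 1))
        for D in self._designs:
            G[:P, :P] += D.T @ D
            G[:P, P] += D.sum(axis=0)
        n = sum(D.shape[0] for D in self._designs)
        G[P, :P] = G[:P, P]
        G[P, P] = n
        self._G = G

    def residualize(self, eeg: np.ndarray) -> np.ndarray:
        """Residualize EEG of shape (segments, electrodes, samples)."""
        eeg = np.asarray(eeg, dtype=float)
        S, E, T = eeg.shape
        if S != len(self._designs) or any(D.shape[0] != T for D in self._designs):
            raise DesignError("EEG shape does not match the nuisance designs")
        P = self._designs[0].shape[1]
        b = np.zeros((P + 1, E))
        for s, D in enumerate(self._designs):
            Y = eeg[s].T  # (T, E)
            b[:P] += D.T @ Y
            b[P] += Y.sum(axis=0)
        beta = _solve_normal(self._G, b)  # (P+1, E)
        resid = np.empty_like(eeg)
        for s, D in enumerate(self._designs):
            fitted = D @ beta[:P] + beta[P]  # (T, E)
            resid[s] = (eeg[s].T - fitted).T
        return resid


def regress_out(
    eeg: np.ndarray,
    nuisance_blocks: Sequence[np.ndarray],
    lags: np.ndarray = LAG_SAMPLES,
) -> np.ndarray:
    """OLS-residualize (segments, electrodes, samples) EEG on lagged nuisance.

    The fit pools all segments of the participant; residuals are returned per
    segment with the input shape. ``lags`` may be ``np.array([0])`` for an
    instantaneous (lag-free) nuisance regression.
    """
    return LaggedNuisance(nuisance_blocks, lags).residualize(eeg)
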