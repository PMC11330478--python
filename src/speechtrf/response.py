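"""Derived measures of fitted response functions.

Reduces per-participant TRF kernels to the quantities the group statistics
operate on: RMS signal power over 0-500 ms lags, the two largest peaks of
each response (positive or negative, prominence-gated on a z-scored trace),
data-driven early/late temporal windows from 1-D K-means over pooled peak
latencies, three a-priori electrode clusters (frontal, central, parietal),
and the rule that a (feature, cluster, window) cell enters the group
comparison only if at least 75% of participants show a peak there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .boosting import TRFFit

#: A-priori midline electrode clusters.
ELECTRODE_CLUSTERS: dict[str, tuple[str, ...]] = {
    "F": ("F3", "Fz", "F4"),
    "C": ("C3", "Cz", "C4"),
    "P": ("P3", "Pz", "P4"),
}


class ResponseError(ValueError):
    pass


@dataclass(frozen=True)
class PeakRecord:
    participant_id: str
    feature: str
    cluster: str
    window: str  # "early" | "late"
    amplitude: float  # signed, original response units
    latency_ms: float


def response_rms(
    kernel: np.ndarray,
    lag_ms: np.ndarray,
    window_ms: tuple[float, float] = (0.0, 500.0),
) -> float:
    """Root mean square of the kernel over lags in [0, 500] ms inclusive."""
    lo, hi = window_ms
    if lo < lag_ms.min() or hi > lag_ms.max():
        raise ResponseError(f"window {window_ms} outside lag axis")
    sel = (lag_ms >= lo) & (lag_ms <= hi)
    return float(np.sqrt(np.mean(np.asarray(kernel, float)[sel] ** 2)))


def detect_peaks(
    response: np.ndarray,
    lag_ms: np.ndarray,
    *,
    search_ms: tuple[float, float] = (-50.0, 600.0),
    prominence: float = 0.5,
    max_peaks: int = 2,
    polarity: str = "both",
) -> list[tuple[float, float]]:
    """Find the largest response peaks as (latency_ms, signed amplitude).

    The trace is z-scored over the full lag axis; local maxima of the
    z-scored trace (and of its negation, for negative deflections such as
    N400-like responses) with topographic prominence >= ``prominence`` are
    pooled, candidates outside the search range or at negative latencies are
    discarded, and the ``max_peaks`` largest by absolute amplitude are
    returned with amplitudes on the original scale.
    """
    r = np.asarray(response, dtype=float)
    sd = r.std()
    if sd == 0:
        return []
    z = (r - r.mean()) / sd
    candidates: list[tuple[float, float, float]] = []  # (|z|, latency, amp)
    signs = (1.0, -1.0) if polarity == "both" else (1.0,)
    for sign in signs:
        idx, _ = find_peaks(sign * z, prominence=prominence)
        for i in idx:
            lat = lag_ms[i]
            if lat < max(0.0, search_ms[0]) or lat > search_ms[1]:
                continue
            candidates.append((abs(z[i]), float(lat), float(r[i])))
    candidates.sort(key=lambda c: -c[0])
    return [(lat, amp) for _, lat, amp in candidates[:max_peaks]]


def temporal_window_boundary(
    latencies: Sequence[float],
    *,
    k: int = 2,
    n_init: int = 100,
    seed: int | None = 0,
) -> float:
    """Early/late boundary: mean of the two 1-D K-means cluster centers."""
    lat = np.asarray(latencies, dtype=float)
    if len(np.unique(lat)) < k:
        raise ResponseError("need at least two distinct latencies")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(lat[:, None])
    return float(np.mean(km.cluster_centers_))


def temporal_windows(
    latencies_per_feature: Mapping[str, Sequence[float]],
    *,
    n_init: int = 100,
    seed: int | None = 0,
) -> dict[str, float]:
    """Per-feature boundary from peak latencies pooled over participants,
    electrodes and clusters."""
    return {
        f: temporal_window_boundary(lat, n_init=n_init, seed=seed)
        for f, lat in latencies_per_feature.items()
    }


def cluster_average_response(
    fit: TRFFit, feature: str, cluster_electrodes: Sequence[str]
) -> np.ndarray:
    """Average the feature's kernel over the cluster's electrodes."""
    missing = [e for e in cluster_electrodes if e not in fit.electrodes]
    if missing:
        raise ResponseError(f"electrodes {missing} not present in fit")
    idx = [fit.electrodes.index(e) for e in cluster_electrodes]
    return fit.kernel(feature)[:, idx].mean(axis=1)


def available_clusters(
    electrodes: Sequence[str],
    clusters: Mapping[str, Sequence[str]] = ELECTRODE_CLUSTERS,
) -> dict[str, tuple[str, ...]]:
    """Clusters whose electrodes are all present in the montage."""
    return {
        name: tuple(els)
        for name, els in clusters.items()
        if all(e in electrodes for e in els)
    }


def peak_table(
    fits: Mapping[str, Mapping[str, TRFFit]],
    *,
    clusters: Mapping[str, Sequence[str]] | None = None,
    boundaries: Mapping[str, float] | None = None,
    occurrence_threshold: float = 0.75,
    search_ms: tuple[float, float] = (-50.0, 600.0),
    prominence: float = 0.5,
    late_end_ms: float = 600.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level peaks per (feature, cluster, window) plus inclusion.

    ``fits`` maps participant_id -> model_name -> TRFFit. Per cell the three
    cluster electrodes are averaged, the two largest peaks detected, and the
    participant's largest-|amplitude| peak per temporal window recorded. If
    ``boundaries`` is None they are derived by K-means from the pooled peak
    latencies. A cell is included iff the fraction of participants with a
    peak is >= ``occurrence_threshold``.
    """
    any_fit = next(iter(next(iter(fits.values())).values()))
    electrodes = any_fit.electrodes
    if clusters is None:
        clusters = available_clusters(electrodes)
    features = sorted(
        {f for models in fits.values() for m in models.values() for f in m.feature_names}
    )
    feature_fit = {}  # feature -> model name carrying it
    for models in fits.values():
        for mname, fit in models.items():
            for f in fit.feature_names:
                feature_fit[f] = mname
        break

    # first pass: detect peaks per participant/feature/cluster
    detected: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    pooled: dict[str, list[float]] = {f: [] for f in features}
    for pid, models in fits.items():
        for f in features:
            fit = models[feature_fit[f]]
            for cname, els in clusters.items():
                resp = cluster_average_response(fit, f, els)
                peaks = detect_peaks(
                    resp, fit.lag_ms, search_ms=search_ms, prominence=prominence
                )
                detected[(pid, f, cname)] = peaks
                pooled[f].extend(lat for lat, _ in peaks)

    if boundaries is None:
        boundaries = {}
        for f in features:
            if len(np.unique(pooled[f])) >= 2:
                boundaries[f] = temporal_window_boundary(pooled[f])
            else:
                boundaries[f] = late_end_ms / 2.0

    records: list[PeakRecord] = []
    for (pid, f, cname), peaks in detected.items():
        for window in ("early", "late"):
            b = boundaries[f]
            in_win = [
                (lat, amp)
                for lat, amp in peaks
                if (lat < b) == (window == "early") and lat <= late_end_ms
            ]
            if not in_win:
                continue
            lat, amp = max(in_win, key=lambda p: abs(p[1]))
            records.append(PeakRecord(pid, f, cname, window, amp, lat))

    peaks_df = pd.DataFrame([r.__dict__ for r in records]) if records else pd.DataFrame(
        columns=["participant_id", "feature", "cluster", "window",
                 "amplitude", "latency_ms"]
    )
    n_participants = len(fits)
    rows = []
    for f in features:
        for cname in clusters:
            for window in ("early", "late"):
                if len(peaks_df):
                    n = len(
                        peaks_df[
                            (peaks_df.feature == f)
                            & (peaks_df.cluster == cname)
                            & (peaks_df.window == window)
                        ]
                    )
                else:
                    n = 0
                frac = n / n_participants
                rows.append(
                    {
                        "feature": f,
                        "cluster": cname,
                        "window": window,
                        "n_with_peak": n,
                        "fraction": frac,
                        "included": frac >= occurrence_threshold,
                        "boundary_ms": boundaries[f],
                    }
                )
    return peaks_df, pd.DataFrame(rows)


def rms_table(
    fits: Mapping[str, Mapping[str, TRFFit]],
    clusters: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Tidy per-electrode RMS: participant, model, feature, electrode, cluster."""
    rows = []
    for pid, models in fits.items():
        for mname, fit in models.items():
            cl = clusters or available_clusters(fit.electrodes)
            el_cluster = {e: c for c, els in cl.items() for e in els}
            for f in fit.feature_names:
                K = fit.kernel(f)
                for ei, e in enumerate(fit.electrodes):
                    rows.append(
                        {
                            "participant_id": pid,
                            "model": mname,
                            "feature": f,
                            "electrode": e,
                            "cluster": el_cluster.get(e, ""),
                            "rms": response_rms(K[:, ei], fit.lag_ms),
                        }
                    )
    return pd.DataFrame(rows)
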