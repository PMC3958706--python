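"""Ground-truth comparison utilities: spike matching, burst overlap, checksums."""

from __future__ import annotations

import hashlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "match_spike_times",
    "detection_scores",
    "interval_overlap_fraction",
    "table_checksum",
    "two_peak_bimodality",
]


def match_spike_times(true_times: np.ndarray, detected_times: np.ndarray, tol_s: float) -> int:
    """Count one-to-one matches between sorted time lists within +/- tol_s.

    Greedy two-pointer matching: each true spike pairs with the earliest
    unmatched detection within tolerance.  Both inputs must be sorted.
    """
    t = np.asarray(true_times, dtype=float)
    d = np.asarray(detected_times, dtype=float)
    i = j = matched = 0
    while i < t.size and j < d.size:
        if d[j] < t[i] - tol_s:
            j += 1
        elif d[j] > t[i] + tol_s:
            i += 1
        else:
            matched += 1
            i += 1
            j += 1
    return matched


def detection_scores(
    true_by_channel: Sequence[np.ndarray] | Mapping[int, np.ndarray],
    detected_by_channel: Mapping[int, np.ndarray],
    tol_s: float = 0.5e-3,
) -> tuple[float, float]:
    """(sensitivity, precision) of detections against ground truth.

    sensitivity = matched / n_true, precision = matched / n_detected,
    matching per channel within +/- tol_s.
    """
    if not isinstance(true_by_channel, Mapping):
        true_by_channel = dict(enumerate(true_by_channel))
    n_true = n_det = n_match = 0
    for c, t in true_by_channel.items():
        d = np.asarray(detected_by_channel.get(c, np.empty(0)))
        n_true += len(t)
        n_det += len(d)
        n_match += match_spike_times(np.sort(t), np.sort(d), tol_s)
    sensitivity = n_match / n_true if n_true else 1.0
    precision = n_match / n_det if n_det else 1.0
    return sensitivity, precision


def interval_overlap_fraction(true_iv: tuple[float, float], det_iv: tuple[float, float]) -> float:
    """|intersection| / |true interval|."""
    a0, a1 = true_iv
    b0, b1 = det_iv
    if a1 <= a0:
        raise ValueError("degenerate true interval")
    return max(0.0, min(a1, b1) - max(a0, b0)) / (a1 - a0)


def two_peak_bimodality(counts: np.ndarray, smooth: int = 3,
                        prominence_frac: float = 0.1, dip_ratio: float = 0.7) -> bool:
    """Two-peak criterion for a histogram (e.g. the pooled ISI distribution).

    True when the lightly smoothed histogram shows at least two prominent
    modes separated by a dip below ``dip_ratio`` of the lower mode — the
    signature of a bursting culture in the pooled ISI distribution (a fast
    intra-burst mode and a slow between-burst mode).
    """
    c = np.asarray(counts, dtype=float)
    if c.sum() == 0:
        return False
    sm = np.convolve(c, np.ones(smooth) / smooth, mode="same")
    peaks, _ = sps.find_peaks(sm, prominence=prominence_frac * sm.max())
    if len(peaks) < 2:
        return False
    top2 = np.sort(peaks[np.argsort(sm[peaks])[-2:]])
    lo, hi = int(top2[0]), int(top2[1])
    dip = sm[lo:hi + 1].min()
    return bool(dip < dip_ratio * min(sm[lo], sm[hi]))


def table_checksum(table: pd.DataFrame) -> str:
    """SHA-256 of the table's TSV serialization (the determinism fingerprint)."""
    payload = table.to_csv(sep="\t", index=False, float_format="%.9e").encode()
    return hashlib.sha256(payload).hexdigest()
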