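"""A-scan processing: distance extraction and stream synchronization.

Axial distances are read from 1D OCT intensity profiles. The initial
distance comes from a peak search for the most prominent interface; once
a reference A-scan with a known distance exists, subsequent distances are
the reference distance shifted by the lag maximizing the normalized
cross-correlation between the scans (assuming similar intensity-value
distributions), with parabolic sub-sample refinement.

OCT and robot-kinematics streams are synchronized by cross-correlating
both time series of a common physical motion after resampling to a
uniform rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "AScan",
    "DistanceEstimate",
    "SynchronizationError",
    "initial_peak_search",
    "template_match_distance",
    "synchronize_streams",
    "CORRELATION_FLOOR",
]

#: minimum normalized cross-correlation for a template match to be valid
CORRELATION_FLOOR = 0.3


class SynchronizationError(RuntimeError):
    """Stream synchronization failed (flat or ambiguous correlation)."""


@dataclass(frozen=True)
class AScan:
    """One axial intensity profile (pitch in mm/sample, t in seconds)."""

    intensities: np.ndarray
    pitch: float
    t: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 1 or arr.size < 64:
            raise ValueError("an A-scan needs at least 64 samples")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def imaging_range(self) -> float:
        return self.pitch * self.intensities.size


@dataclass(frozen=True)
class DistanceEstimate:
    distance: float
    method: str  # "peak" | "template"
    valid: bool
    correlation: float = np.nan


def _background_mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med))) or 1e-12


def initial_peak_search(scan: AScan, threshold: float | None = None) -> DistanceEstimate:
    """Distance of the most prominent interface peak.

    ``threshold`` is the minimum peak prominence; by default 5x the
    background median absolute deviation. Returns an invalid estimate if
    no peak qualifies.
    """
    x = scan.intensities
    if threshold is None:
        threshold = 5.0 * _background_mad(x)
    peaks, props = signal.find_peaks(x, prominence=threshold)
    if len(peaks) == 0:
        return DistanceEstimate(np.nan, "peak", False)
    idx = peaks[np.argmax(props["prominences"])]
    return DistanceEstimate(float(idx * scan.pitch), "peak", True)


def _parabolic_offset(y_m1: float, y_0: float, y_p1: float) -> float:
    denom = y_m1 - 2.0 * y_0 + y_p1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -1.0, 1.0))


def template_match_distance(scan: AScan, reference: AScan, reference_distance: float,
                            correlation_floor: float = CORRELATION_FLOOR) -> DistanceEstimate:
    """Distance from the cross-correlation lag against a reference A-scan.

    Both windows are zero-meaned and unit-normed; the lag maximizing the
    correlation, refined by parabolic interpolation, shifts the reference
    distance. The estimate is invalid below ``correlation_floor`` or when
    the implied distance leaves the imaging range.
    """
    if scan.pitch != reference.pitch:
        raise ValueError("scan and reference must share one pitch")
    a = scan.intensities - scan.intensities.mean()
    b = reference.intensities - reference.intensities.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return DistanceEstimate(np.nan, "template", False, 0.0)
    cc = signal.correlate(a, b, mode="full", method="auto") / (na * nb)
    lags = np.arange(-(len(b) - 1), len(a))
    k = int(np.argmax(cc))
    corr = float(cc[k])
    delta = 0.0
    if 0 < k < len(cc) - 1:
        delta = _parabolic_offset(cc[k - 1], cc[k], cc[k + 1])
    distance = reference_distance + scan.pitch * (lags[k] + delta)
    valid = corr >= correlation_floor and 0.0 <= distance <= scan.imaging_range
    return DistanceEstimate(float(distance), "template", bool(valid), corr)


def synchronize_streams(series_a, series_b, min_peak_correlation: float = 0.2) -> float:
    """Time offset tau (seconds) such that ``b(t + tau)`` aligns with ``a(t)``.

    Both (t, value) series are resampled to a common uniform rate (the
    higher of the two native rates), zero-meaned, and cross-correlated;
    the peak lag is refined parabolically. Raises
    :class:`SynchronizationError` when the correlation peak is too flat to
    be trusted.
    """
    ta, va = (np.asarray(x, dtype=float) for x in series_a)
    tb, vb = (np.asarray(x, dtype=float) for x in series_b)
    if len(ta) < 2 or len(tb) < 2:
        raise ValueError("series too short to synchronize")
    if min(ta[-1], tb[-1]) <= max(ta[0], tb[0]):
        raise ValueError("series have no overlapping time support")
    dt = min(float(np.median(np.diff(ta))), float(np.median(np.diff(tb))))
    t0 = min(ta[0], tb[0])
    t1 = max(ta[-1], tb[-1])
    grid = np.arange(t0, t1 + dt, dt)
    ya = np.interp(grid, ta, va, left=va.mean(), right=va.mean())
    yb = np.interp(grid, tb, vb, left=vb.mean(), right=vb.mean())
    ya -= ya.mean()
    yb -= yb.mean()
    norm = np.linalg.norm(ya) * np.linalg.norm(yb)
    if norm == 0:
        raise SynchronizationError("constant series cannot be synchronized")
    cc = signal.correlate(ya, yb, mode="full", method="fft") / norm
    k = int(np.argmax(cc))
    if cc[k] < min_peak_correlation:
        raise SynchronizationError("correlation peak too flat")
    delta = 0.0
    if 0 < k < len(cc) - 1:
        delta = _parabolic_offset(cc[k - 1], cc[k], cc[k + 1])
    lag = k - (len(yb) - 1) + delta
    # correlate(a, b) peaks at lag l when a(j) ~ b(j - l); if b lags a by
    # tau = m*dt then l = -m, and b(t + tau) ~ a(t) with tau = -l*dt
    return float(-lag * dt)
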