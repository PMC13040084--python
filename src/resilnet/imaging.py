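"""Calcium-imaging trace processing and transient detection.

Implements the mouse-arm event pipeline: ROI trace extraction from movie
stacks, ΔF/F against a quiescent 10-s baseline, windowed-median detrending,
repeated Gaussian smoothing with zero-phase high-pass filtering, and a
threshold/derivative transient detector with single-exponential decay fits.
Detected events are binarized into a neurons × frames activity raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal
from skimage.feature import peak_local_max
from skimage.filters import gaussian as _gaussian_blur


class MaskError(ValueError):
    """Raised for empty or out-of-frame ROI masks."""


class BaselineError(ValueError):
    """Raised when a valid positive fluorescence baseline cannot be formed."""


class FilterError(ValueError):
    """Raised for invalid smoothing/filter parameters."""


@dataclass
class FluorescenceTrace:
    """Raw fluorescence of one ROI, sampled at a fixed frame rate.

    Parameters
    ----------
    roi_id : int
        Identifier of the ROI within its field of view.
    samples : ndarray
        Mean fluorescence (a.u.) over the ROI pixels, one value per frame.
    fs : float
        Sampling (frame) rate in Hz.
    centroid : tuple of float, optional
        (row, col) pixel position of the ROI center, used for connectivity
        map node placement.
    """

    roi_id: int
    samples: np.ndarray
    fs: float
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class DffTrace:
    """Baseline-normalized fluorescence ΔF/F of one ROI."""

    roi_id: int
    dff: np.ndarray
    fs: float
    f0: float
    baseline_window: tuple[int, int] | None = None
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if not self.f0 > 0:
            raise BaselineError("baseline F0 must be positive")

    @property
    def n_frames(self) -> int:
        return self.dff.size


@dataclass
class CalciumEvent:
    """One detected calcium transient.

    ``amplitude`` is the ΔF/F amplitude estimated on the unsmoothed trace
    (exponential-fit amplitude at the refined peak); ``peak_value`` is the
    value of the analyzed (smoothed/filtered) trace at the detected peak,
    which by construction exceeds the detection threshold.  ``tau`` is NaN
    when the decay fit did not converge; such events are retained but must
    be excluded from decay-constant statistics.
    """

    peak: int
    onset: int
    offset: int
    amplitude: float
    tau: float
    peak_value: float
    fit_rms: float = np.nan

    def __post_init__(self) -> None:
        if not (self.onset <= self.peak <= self.offset):
            raise ValueError("event must satisfy onset <= peak <= offset")


@dataclass
class BinaryRaster:
    """0/1 activity matrix (neurons × frames); 1-runs are event spans."""

    matrix: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# ROI handling


def extract_traces(
    stack: np.ndarray,
    masks: Sequence[np.ndarray],
    fs: float,
) -> list[FluorescenceTrace]:
    """Average pixel intensities within each ROI mask, per frame.

    Parameters
    ----------
    stack : ndarray, shape (frames, rows, cols)
    masks : sequence of boolean ndarrays matching the frame shape
    fs : frame rate in Hz
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    flat = stack.reshape(stack.shape[0], -1)
    traces = []
    for i, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape[1:]:
            raise MaskError(f"mask {i} shape {mask.shape} != frame {stack.shape[1:]}")
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise MaskError(f"mask {i} is empty")
        rows, cols = np.nonzero(mask)
        centroid = (float(rows.mean()), float(cols.mean()))
        traces.append(
            FluorescenceTrace(
                roi_id=i,
                samples=flat[:, idx].mean(axis=1),
                fs=fs,
                centroid=centroid,
            )
        )
    return traces


def detect_rois(
    projection: np.ndarray,
    radius: float = 5.0,
    min_separation: float | None = None,
    smooth_sigma: float = 2.0,
    threshold_factor: float = 5.0,
) -> list[np.ndarray]:
    """Detect disc-shaped somata on an average-intensity projection.

    Local maxima of the smoothed projection that exceed the background
    (median + ``threshold_factor`` robust SDs) become ROI centers; each ROI
    is a disc of the given radius.  An empty list is a valid outcome.
    """
    projection = np.asarray(projection, dtype=float)
    if projection.ndim != 2:
        raise ValueError("projection must be 2-D")
    if min_separation is None:
        # peak suppression uses a square window; keep it just over one
        # radius so touching somata are still resolved
        min_separation = 1.2 * radius
    sm = _gaussian_blur(projection, sigma=smooth_sigma, preserve_range=True)
    med = np.median(sm)
    mad = np.median(np.abs(sm - med)) * 1.4826
    thr = med + threshold_factor * mad + 1e-12
    peaks = peak_local_max(
        sm, min_distance=max(int(round(min_separation)), 1), threshold_abs=thr
    )
    rr, cc = np.mgrid[: projection.shape[0], : projection.shape[1]]
    masks = []
    for r0, c0 in peaks:
        masks.append((rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2)
    return masks


# ---------------------------------------------------------------------------
# ΔF/F


def compute_dff(
    trace: FluorescenceTrace,
    baseline_window: tuple[int, int] | None = None,
    window_s: float = 10.0,
) -> DffTrace:
    """ΔF/F = (F − F0)/F0 with F0 the mean over a quiescent baseline window.

    When no window is given, the ``window_s``-long span with minimal
    variance is selected automatically — a transient-free stretch in
    sparsely active traces.
    """
    x = trace.samples
    w = int(round(window_s * trace.fs))
    w = min(max(w, 2), x.size)
    if baseline_window is None:
        c1 = np.cumsum(np.concatenate([[0.0], x]))
        c2 = np.cumsum(np.concatenate([[0.0], x * x]))
        n_starts = x.size - w + 1
        starts = np.arange(n_starts)
        s1 = c1[starts + w] - c1[starts]
        s2 = c2[starts + w] - c2[starts]
        var = s2 / w - (s1 / w) ** 2
        best = int(np.argmin(var))
        baseline_window = (best, best + w)
    a, b = baseline_window
    if not (0 <= a < b <= x.size):
        raise BaselineError("baseline window outside trace")
    f0 = float(x[a:b].mean())
    if f0 <= 0:
        raise BaselineError("baseline mean must be positive")
    return DffTrace(
        roi_id=trace.roi_id,
        dff=(x - f0) / f0,
        fs=trace.fs,
        f0=f0,
        baseline_window=(a, b),
        centroid=trace.centroid,
    )


def detrend_median(
    trace: FluorescenceTrace,
    long_window: int = 5401,
    short_window: int = 101,
) -> DffTrace:
    """Windowed-median detrending: ΔF/F = (median_short − median_long)/median_long.

    Rolling medians are centered; truncated windows are used at the edges.
    This variant feeds the refined-interval / connectivity path.
    """
    for w, name in ((long_window, "long"), (short_window, "short")):
        if w < 1 or w % 2 == 0:
            raise FilterError(f"{name} window must be odd and positive")
    if short_window > long_window:
        raise FilterError("short window must not exceed the long window")
    s = pd.Series(trace.samples)
    long_med = s.rolling(long_window, center=True, min_periods=1).median().to_numpy()
    short_med = s.rolling(short_window, center=True, min_periods=1).median().to_numpy()
    if np.any(long_med <= 0):
        raise BaselineError("long-window median must stay positive")
    dff = (short_med - long_med) / long_med
    return DffTrace(
        roi_id=trace.roi_id,
        dff=dff,
        fs=trace.fs,
        f0=float(long_med.mean()),
        centroid=trace.centroid,
    )


# ---------------------------------------------------------------------------
# Smoothing / filtering

_KERNEL3 = np.array([0.25, 0.5, 0.25])


def smooth_and_filter(
    dff: DffTrace,
    passes: int = 25,
    cutoff_hz: float = 0.12,
) -> DffTrace:
    """Repeated 3-point Gaussian smoothing, then zero-phase high-pass.

    ``passes`` applications of the binomial [1/4, 1/2, 1/4] kernel
    (equivalent to one Gaussian of σ ≈ sqrt(passes/2) frames) followed by a
    2nd-order Butterworth high-pass at ``cutoff_hz``, applied
    forward-backward so transient timing is preserved.
    """
    if passes < 1:
        raise FilterError("passes must be >= 1")
    nyq = dff.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise FilterError("cutoff must lie in (0, Nyquist)")
    x = dff.dff.copy()
    for _ in range(passes):
        x = np.convolve(np.pad(x, 1, mode="edge"), _KERNEL3, mode="valid")
    b, a = signal.butter(2, cutoff_hz / nyq, btype="high")
    x = signal.filtfilt(b, a, x)
    return DffTrace(
        roi_id=dff.roi_id,
        dff=x,
        fs=dff.fs,
        f0=dff.f0,
        baseline_window=dff.baseline_window,
        centroid=dff.centroid,
    )


# ---------------------------------------------------------------------------
# Transient detection


def _fit_exponential(
    t: np.ndarray, y: np.ndarray, tau0: float
) -> tuple[float, float, float]:
    """Least-squares fit of A·exp(−t/τ); returns (A, tau, rms)."""
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t,
            y,
            p0=[max(y[0], 1e-6), tau0],
            bounds=([0.0, 1e-3], [np.inf, 60.0]),
            maxfev=400,
        )
    except (RuntimeError, ValueError):
        return np.nan, np.nan, np.nan
    a, tau = float(popt[0]), float(popt[1])
    rms = float(np.sqrt(np.mean((y - a * np.exp(-t / tau)) ** 2)))
    return a, tau, rms


def detect_transients(
    dff: DffTrace,
    threshold_sd: float = 2.5,
    halfwidth_sd: float = 0.5,
    raw: DffTrace | None = None,
    tau0: float = 0.5,
    tail_s: float = 3.0,
) -> list[CalciumEvent]:
    """Detect calcium transients on a smoothed/filtered ΔF/F trace.

    Peaks are local maxima exceeding mean + ``threshold_sd``·SD whose first
    difference changes sign + → − and whose second difference is negative.
    For each peak a single-exponential decay A·exp(−t/τ) is fitted from the
    peak to the tail (next down-crossing of the threshold, or ``tail_s``
    seconds).  Onset is the last pre-peak frame below ``halfwidth_sd``·SD;
    offset is where the fitted curve falls below that level.  Overlapping
    events are merged into the earlier event's span.

    When ``raw`` (the unsmoothed ΔF/F) is supplied, amplitude and decay are
    estimated on it at a refined peak position, avoiding the amplitude
    attenuation of the repeated smoothing.
    """
    y = dff.dff
    sd = float(y.std())
    if sd == 0:
        return []  # perfectly flat trace: nothing exceeds any threshold
    mu = float(y.mean())
    thr = mu + threshold_sd * sd
    half = halfwidth_sd * sd
    fs = dff.fs

    d1 = np.diff(y)
    candidates = np.flatnonzero((y[1:-1] > thr) & (d1[:-1] > 0) & (d1[1:] <= 0)) + 1
    d2 = np.diff(y, 2)
    candidates = candidates[d2[candidates - 1] < 0]

    # half the composite smoothing kernel width, for raw-peak refinement
    refine_w = 8
    events: list[CalciumEvent] = []
    for p in candidates:
        # onset: last frame before the peak below the half-threshold
        before = np.flatnonzero(y[:p] < half)
        onset = int(before[-1]) if before.size else 0

        # tail for the decay fit on the analyzed trace
        below = np.flatnonzero(y[p:] < thr)
        tail_end = p + int(below[0]) if below.size else y.size
        tail_end = min(tail_end, p + int(round(tail_s * fs)), y.size)

        if raw is not None:
            seg0 = max(p - refine_w, 0)
            pr = seg0 + int(np.argmax(raw.dff[seg0 : p + 3]))
            fit_end = min(pr + int(round(tail_s * fs)), raw.dff.size)
            tt = (np.arange(pr, fit_end) - pr) / fs
            amp, tau, rms = _fit_exponential(tt, raw.dff[pr:fit_end], tau0)
            if np.isnan(amp):
                amp = float(raw.dff[pr])
            elif np.isfinite(tau) and tau > 0:
                # sampling-phase correction: with an instantaneous rise the
                # first sampled point has already decayed by
                # E[exp(-u/(tau*fs))], u ~ U(0,1) frames
                c = tau * fs * (1.0 - np.exp(-1.0 / (tau * fs)))
                amp /= c
        else:
            tt = (np.arange(p, max(tail_end, p + 3)) - p) / fs
            amp, tau, rms = _fit_exponential(tt, y[p : max(tail_end, p + 3)], tau0)
            if np.isnan(amp):
                amp = float(y[p])

        # offset: fitted decay dropping below the half-threshold
        if np.isfinite(tau) and amp > half > 0:
            off = p + int(np.ceil(tau * np.log(amp / half) * fs))
        else:
            after = np.flatnonzero(y[p:] < half)
            off = p + int(after[0]) if after.size else y.size - 1
        off = int(min(max(off, p), y.size - 1))

        events.append(
            CalciumEvent(
                peak=int(p),
                onset=onset,
                offset=off,
                amplitude=float(amp),
                tau=float(tau),
                peak_value=float(y[p]),
                fit_rms=rms,
            )
        )

    # merge overlapping events into the earlier event's span
    merged: list[CalciumEvent] = []
    for ev in events:
        if merged and ev.onset <= merged[-1].offset:
            prev = merged[-1]
            prev.offset = max(prev.offset, ev.offset)
        else:
            merged.append(ev)
    return merged


def binarize(
    event_lists: Sequence[Sequence[CalciumEvent]],
    n_frames: int,
    fs: float,
) -> BinaryRaster:
    """Encode event spans as a 0/1 neurons × frames raster."""
    mat = np.zeros((len(event_lists), n_frames), dtype=np.int8)
    for i, events in enumerate(event_lists):
        for ev in events:
            if not (0 <= ev.onset and ev.offset < n_frames):
                raise ValueError("event span outside raster")
            mat[i, ev.onset : ev.offset + 1] = 1
    return BinaryRaster(matrix=mat, fs=fs)


def refine_intervals(
    dff: DffTrace,
    peaks: Sequence[int],
) -> list[tuple[int, int]]:
    """Half-peak activity intervals for synchrony analysis.

    Each peak's interval runs from the first frame left/right of the peak
    whose ΔF/F drops below half the peak intensity.  Peaks falling inside
    an already-identified interval are absorbed into it; the returned
    intervals are pairwise disjoint and sorted.
    """
    y = dff.dff
    n = y.size
    intervals: list[list[int]] = []
    for p in sorted(int(p) for p in peaks):
        if not 0 <= p < n:
            raise ValueError("peak index outside trace")
        if intervals and intervals[-1][0] <= p <= intervals[-1][1]:
            continue  # absorbed into the existing activity interval
        halfpeak = 0.5 * y[p]
        left = np.flatnonzero(y[:p] < halfpeak)
        a = int(left[-1] + 1) if left.size else 0
        right = np.flatnonzero(y[p + 1 :] < halfpeak)
        b = p + int(right[0]) if right.size else n - 1
        if intervals and a <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], b)
        else:
            intervals.append([a, b])
    return [(a, b) for a, b in intervals]
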