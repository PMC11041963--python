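"""Remote photoplethysmography: POS pulse extraction and spectral heart rate.

Pipeline: per-ROI RGB traces -> blood volume pulse (BVP) via the
plane-orthogonal-to-skin (POS) projection -> heart rate per overlapping
6-s window from the most significant Fourier frequency -> a robust
aggregate over ROIs and the MAE/HR signal-quality index.

POS temporally normalizes each color channel by its short-window mean
and projects the normalized traces onto two axes orthogonal to the
skin-tone direction, ``S1 = G - B`` and ``S2 = -2R + G + B``; the pulse
is ``h = S1 + (sigma(S1)/sigma(S2)) * S2``, mean-centered per window and
overlap-added over a sliding window.  This makes the output invariant to
per-channel constant gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_HR_BAND_HZ = (0.65, 4.0)  # 39-240 BPM physiologic search band
DEFAULT_POS_WINDOW_S = 1.6
DEFAULT_HR_WIN_S = 6.0
DEFAULT_HR_HOP_S = 1.0
DEFAULT_HR_GRID_BPM = 0.25


@dataclass
class RoiTraceSet:
    """Per-ROI mean RGB intensities on a shared time base.

    ``rgb`` maps roi_id to an (n, 3) array of [R, G, B] mean intensities
    (arbitrary positive linear units); ``fps`` is the video frame rate.
    """

    fps: float
    rgb: dict[int, np.ndarray]
    time_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.rgb:
            raise ValueError("at least one ROI is required")
        lengths = {len(v) for v in self.rgb.values()}
        if len(lengths) != 1:
            raise ValueError("all ROI traces must have equal length")
        for roi, arr in self.rgb.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"ROI {roi}: trace must be (n, 3) RGB")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"ROI {roi}: intensities must be finite and > 0")
            self.rgb[roi] = arr
        if self.time_s is None:
            n = lengths.pop()
            self.time_s = np.arange(n) / self.fps

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.rgb.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fps


@dataclass
class BvpSignal:
    """Unitless blood-volume-pulse waveform for one ROI."""

    roi_id: int
    samples: np.ndarray
    fps: float


@dataclass
class HrSeries:
    """Heart-rate estimates on a regular window grid; NaN marks missing."""

    t_center_s: np.ndarray
    hr_bpm: np.ndarray
    win_s: float
    hop_s: float
    roi_id: int | None = None  # None = aggregate over ROIs
    band_hz: tuple[float, float] = DEFAULT_HR_BAND_HZ

    def __post_init__(self) -> None:
        self.t_center_s = np.asarray(self.t_center_s, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if len(self.t_center_s) != len(self.hr_bpm):
            raise ValueError("window centers and HR values must align")
        if len(self.t_center_s) > 1 and not np.all(np.diff(self.t_center_s) > 0):
            raise ValueError("window centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.hr_bpm)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.hr_bpm)


@dataclass
class QualityIndex:
    """MAE/HR signal-quality index.

    Mean absolute deviation of per-ROI window HR from the aggregate HR,
    divided by the mean aggregate HR.  Zero iff every ROI agrees with the
    aggregate in every window; large values flag inconsistent extraction.
    """

    mae_over_hr: float
    mae_bpm: float
    mean_hr_bpm: float
    n_rois: int
    n_windows: int


def pos_bvp(
    traces: RoiTraceSet, pos_window_s: float = DEFAULT_POS_WINDOW_S
) -> list[BvpSignal]:
    """Extract one BVP per ROI with the POS projection.

    Sliding windows of ``pos_window_s`` hop one sample; each window's
    mean-centered pulse estimate is overlap-added into the output, which
    has the same length as the input trace.  A window where sigma(S2) is
    zero (e.g. constant input) contributes S1 alone.
    """
    wlen = int(round(pos_window_s * traces.fps))
    if wlen < 2:
        raise ValueError("POS window shorter than 2 samples")
    n = traces.n_samples
    if n < wlen:
        raise ValueError("trace shorter than one POS window")

    out = []
    for roi, arr in sorted(traces.rgb.items()):
        # windows: (n_win, 3, wlen)
        win = sliding_window_view(arr.T, wlen, axis=1).transpose(1, 0, 2)
        cn = win / win.mean(axis=2, keepdims=True)
        s1 = cn[:, 1, :] - cn[:, 2, :]
        s2 = -2.0 * cn[:, 0, :] + cn[:, 1, :] + cn[:, 2, :]
        sd1 = s1.std(axis=1)
        sd2 = s2.std(axis=1)
        ratio = np.divide(sd1, sd2, out=np.zeros_like(sd1), where=sd2 > 0)
        h = s1 + ratio[:, None] * s2
        h -= h.mean(axis=1, keepdims=True)

        bvp = np.zeros(n)
        n_win = h.shape[0]
        for k in range(wlen):  # overlap-add, vectorized over windows
            bvp[k : k + n_win] += h[:, k]
        out.append(BvpSignal(roi_id=roi, samples=bvp, fps=traces.fps))
    return out


def windowed_hr(
    bvp: BvpSignal,
    win_s: float = DEFAULT_HR_WIN_S,
    hop_s: float = DEFAULT_HR_HOP_S,
    band_hz: tuple[float, float] = DEFAULT_HR_BAND_HZ,
    grid_bpm: float = DEFAULT_HR_GRID_BPM,
) -> HrSeries:
    """Heart rate per overlapping window from the Fourier magnitude peak.

    Each window is mean-removed and zero-padded so the frequency grid is
    at least as fine as ``grid_bpm``; HR is 60 times the in-band argmax
    frequency.  All-zero windows yield a missing (NaN) HR.
    """
    fps = bvp.fps
    wlen = int(round(win_s * fps))
    hop = max(1, int(round(hop_s * fps)))
    x = np.asarray(bvp.samples, dtype=float)
    if len(x) < wlen:
        raise ValueError("BVP shorter than one HR window")

    segs = sliding_window_view(x, wlen)[::hop]
    segs = segs - segs.mean(axis=1, keepdims=True)
    zero_windows = np.all(segs == 0.0, axis=1)
    # Hann taper keeps sidelobe leakage from a secondary tone from
    # skewing the location of the spectral peak
    segs = segs * np.hanning(wlen)

    # zero-pad to reach a <= grid_bpm BPM frequency grid
    nfft = int(2 ** np.ceil(np.log2(max(wlen, 60.0 * fps / grid_bpm))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not band.any():
        raise ValueError("search band contains no frequency bins")

    mag = np.abs(np.fft.rfft(segs, n=nfft, axis=1))[:, band]
    hr = 60.0 * freqs[band][np.argmax(mag, axis=1)]
    hr[zero_windows] = np.nan

    centers = (np.arange(len(segs)) * hop) / fps + win_s / 2.0
    return HrSeries(
        t_center_s=centers, hr_bpm=hr, win_s=win_s, hop_s=hop / fps,
        roi_id=bvp.roi_id, band_hz=band_hz,
    )


def _check_shared_grid(series: list[HrSeries]) -> None:
    ref = series[0]
    for s in series[1:]:
        if len(s) != len(ref) or not np.allclose(s.t_center_s, ref.t_center_s):
            raise ValueError("HR series do not share a window grid")


def aggregate_hr(per_roi: list[HrSeries]) -> HrSeries:
    """Median HR over ROIs per window; missing values are excluded.

    The median is robust to the occasional corrupted patch the quality
    index is designed to flag.
    """
    if not per_roi:
        raise ValueError("no HR series to aggregate")
    _check_shared_grid(per_roi)
    stack = np.vstack([s.hr_bpm for s in per_roi])
    with np.errstate(invalid="ignore"):
        agg = np.full(stack.shape[1], np.nan)
        any_valid = np.isfinite(stack).any(axis=0)
        agg[any_valid] = np.nanmedian(stack[:, any_valid], axis=0)
    ref = per_roi[0]
    return HrSeries(
        t_center_s=ref.t_center_s.copy(), hr_bpm=agg, win_s=ref.win_s,
        hop_s=ref.hop_s, roi_id=None, band_hz=ref.band_hz,
    )


def quality_mae_over_hr(per_roi: list[HrSeries], aggregate: HrSeries) -> QualityIndex:
    """MAE/HR quality index over all valid (ROI, window) pairs."""
    if not per_roi:
        raise ValueError("no per-ROI HR series")
    _check_shared_grid(per_roi + [aggregate])
    errs = []
    for s in per_roi:
        ok = np.isfinite(s.hr_bpm) & np.isfinite(aggregate.hr_bpm)
        errs.append(np.abs(s.hr_bpm[ok] - aggregate.hr_bpm[ok]))
    errs = np.concatenate(errs)
    if errs.size == 0:
        raise ValueError("no valid (ROI, window) pairs for the quality index")
    mean_hr = float(np.nanmean(aggregate.hr_bpm))
    mae = float(errs.mean())
    return QualityIndex(
        mae_over_hr=mae / mean_hr,
        mae_bpm=mae,
        mean_hr_bpm=mean_hr,
        n_rois=len(per_roi),
        n_windows=int(aggregate.valid.sum()),
    )


def extract_hr(
    traces: RoiTraceSet,
    pos_window_s: float = DEFAULT_POS_WINDOW_S,
    win_s: float = DEFAULT_HR_WIN_S,
    hop_s: float = DEFAULT_HR_HOP_S,
    band_hz: tuple[float, float] = DEFAULT_HR_BAND_HZ,
) -> tuple[list[HrSeries], HrSeries, QualityIndex]:
    """Convenience: traces -> per-ROI HR, aggregate HR, quality index."""
    bvps = pos_bvp(traces, pos_window_s=pos_window_s)
    per_roi = [windowed_hr(b, win_s=win_s, hop_s=hop_s, band_hz=band_hz) for b in bvps]
    agg = aggregate_hr(per_roi)
    qi = quality_mae_over_hr(per_roi, agg)
    return per_roi, agg, qi
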