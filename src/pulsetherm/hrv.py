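"""Heart-rate-variability measures from a windowed HR series or beat times.

The HR series is first cleaned with a jump rule: wherever consecutive
estimates differ by more than 25 BPM, the point farther from the median
of the full series is removed, sweeping until no violation remains.
Surviving HR values are converted to NN (beat-to-beat) intervals, from
which the standard time-domain measures (SDNN, rMSSD, pNN50) and the
log LF/HF band powers of the tachogram are computed, per 120-s segment.
ULF and VLF bands need recordings far longer than a 120-s segment and
are not computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

from .rppg import HrSeries

logger = logging.getLogger(__name__)

DEFAULT_MAX_JUMP_BPM = 25.0
DEFAULT_NN_BOUNDS_MS = (300.0, 2000.0)  # mirrors the 30-200 BPM plausibility range
LF_BAND_HZ = (0.04, 0.15)
HF_BAND_HZ = (0.15, 0.40)
DEFAULT_SEGMENT_S = 120.0
RESAMPLE_HZ = 4.0
WELCH_SEG_S = 64.0

#: Measure names reported per segment, in output order.
MEASURE_NAMES = ("hr_mean_bpm", "sdnn_ms", "rmssd_ms", "pnn50_pct", "ln_lf", "ln_hf")


@dataclass
class NnSeries:
    """Normal-to-normal (beat-to-beat) intervals in milliseconds.

    ``t_s`` carries one timestamp per interval (the time the interval is
    observed), used to place the tachogram on a real time axis.
    """

    nn_ms: np.ndarray
    t_s: np.ndarray

    def __post_init__(self) -> None:
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if len(self.nn_ms) != len(self.t_s):
            raise ValueError("nn_ms and timestamps must align")
        if len(self.nn_ms) < 2:
            raise ValueError("an NN series needs at least 2 intervals")

    def __len__(self) -> int:
        return len(self.nn_ms)

    @property
    def span_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


@dataclass
class HrvMeasures:
    """HR mean plus time- and frequency-domain HRV for one segment.

    NaN marks a measure that could not be computed (too few intervals,
    or vanishing band power before the log).
    """

    hr_mean_bpm: float = np.nan
    sdnn_ms: float = np.nan
    rmssd_ms: float = np.nan
    pnn50_pct: float = np.nan
    ln_lf: float = np.nan
    ln_hf: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in MEASURE_NAMES}


@dataclass
class SegmentChange:
    """Last-segment minus first-segment value of one measure."""

    measure: str
    first: float
    last: float

    @property
    def delta(self) -> float:
        return self.last - self.first


def filter_hr_jumps(hr: HrSeries, max_jump_bpm: float = DEFAULT_MAX_JUMP_BPM) -> HrSeries:
    """Remove HR points involved in implausible jumps.

    Scanning left to right, wherever successive points differ by more
    than ``max_jump_bpm`` the one farther from the median of the full
    input series is removed (ties remove the current point); the sweep
    repeats until no violation remains.  Output timestamps are those of
    the survivors, so the result is a subsequence of the input.
    """
    ok = hr.valid
    vals = list(hr.hr_bpm[ok])
    times = list(hr.t_center_s[ok])
    if not vals:
        raise ValueError("no valid HR points to filter; segment unusable")
    med = float(np.median(vals))

    i = 1
    while i < len(vals):
        if abs(vals[i] - vals[i - 1]) > max_jump_bpm:
            # drop whichever of the pair is farther from the input median
            drop = i if abs(vals[i] - med) >= abs(vals[i - 1] - med) else i - 1
            del vals[drop], times[drop]
            i = max(1, drop)  # re-examine the newly adjacent pair
        else:
            i += 1
    if not vals:
        raise ValueError("jump filter removed every HR point; segment unusable")
    return HrSeries(
        t_center_s=np.array(times), hr_bpm=np.array(vals), win_s=hr.win_s,
        hop_s=hr.hop_s, roi_id=hr.roi_id, band_hz=hr.band_hz,
    )


def hr_to_nn(
    hr: HrSeries, nn_bounds_ms: tuple[float, float] = DEFAULT_NN_BOUNDS_MS
) -> NnSeries:
    """Convert window HR estimates to NN intervals (``60000 / HR`` ms).

    Values falling outside ``nn_bounds_ms`` after conversion are treated
    as artifacts and dropped with a logged count.
    """
    ok = hr.valid
    nn = 60000.0 / hr.hr_bpm[ok]
    t = hr.t_center_s[ok]
    keep = (nn >= nn_bounds_ms[0]) & (nn <= nn_bounds_ms[1])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d NN values outside %s ms", n_dropped, nn_bounds_ms)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 NN intervals survive conversion")
    return NnSeries(nn_ms=nn[keep], t_s=t[keep])


def beats_to_nn(
    beat_times_s: np.ndarray, nn_bounds_ms: tuple[float, float] = DEFAULT_NN_BOUNDS_MS
) -> NnSeries:
    """NN intervals from explicit beat times (e.g. a reference beat series)."""
    bt = np.asarray(beat_times_s, dtype=float)
    if len(bt) < 3:
        raise ValueError("need at least 3 beats for 2 NN intervals")
    nn = np.diff(bt) * 1000.0
    t = bt[1:]
    keep = (nn >= nn_bounds_ms[0]) & (nn <= nn_bounds_ms[1])
    if keep.sum() < 2:
        raise ValueError("fewer than 2 NN intervals within bounds")
    return NnSeries(nn_ms=nn[keep], t_s=t[keep])


def time_domain(nn: NnSeries) -> tuple[float, float, float]:
    """SDNN, rMSSD and pNN50 of an NN series.

    SDNN is the sample standard deviation (n-1 denominator); rMSSD the
    root mean square of successive differences; pNN50 the percentage of
    successive differences strictly larger than 50 ms.  With fewer than
    3 intervals rMSSD and pNN50 are undefined (NaN) while SDNN is still
    computed for n >= 2.
    """
    x = nn.nn_ms
    sdnn = float(np.std(x, ddof=1)) if len(x) >= 2 else np.nan
    if len(x) < 3:
        return sdnn, np.nan, np.nan
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d**2)))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(d) > 50.0) / len(d))
    return sdnn, rmssd, pnn50


def freq_domain(
    nn: NnSeries,
    lf_band_hz: tuple[float, float] = LF_BAND_HZ,
    hf_band_hz: tuple[float, float] = HF_BAND_HZ,
    resample_hz: float = RESAMPLE_HZ,
    welch_seg_s: float = WELCH_SEG_S,
    min_span_s: float = DEFAULT_SEGMENT_S,
) -> tuple[float, float]:
    """Natural logs of the LF and HF band powers (ms^2) of the tachogram.

    The irregular NN series is resampled at ``resample_hz`` by cubic
    interpolation, mean-removed, and its Welch power spectral density is
    integrated over the LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) bands.
    A numerically nonpositive band power yields NaN with a warning.
    """
    if nn.span_s < min_span_s:
        raise ValueError(
            f"NN coverage of {nn.span_s:.1f} s is below the {min_span_s:.0f}-s minimum"
        )
    if len(nn) < 4:
        raise ValueError("cubic resampling needs at least 4 NN intervals")
    tg = np.arange(nn.t_s[0], nn.t_s[-1], 1.0 / resample_hz)
    x = interp1d(nn.t_s, nn.nn_ms, kind="cubic")(tg)
    x = x - x.mean()

    nperseg = min(len(x), int(welch_seg_s * resample_hz))
    f, pxx = sps.welch(x, fs=resample_hz, nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(lo: float, hi: float) -> float:
        m = (f >= lo) & (f <= hi)
        return float(np.trapezoid(pxx[m], f[m]))

    out = []
    for name, (lo, hi) in (("LF", lf_band_hz), ("HF", hf_band_hz)):
        p = band_power(lo, hi)
        # 1e-12 ms^2 is far below any physiologic band power; treat
        # anything at or under it (e.g. a constant tachogram) as zero
        if p <= 1e-12:
            warnings.warn(f"{name} band power is nonpositive; returning NaN", stacklevel=2)
            out.append(np.nan)
        else:
            out.append(float(np.log(p)))
    return out[0], out[1]


def nn_measures(nn: NnSeries, compute_freq: bool = True, **freq_kwargs) -> HrvMeasures:
    """All HRV measures for one NN series (frequency domain optional)."""
    sdnn, rmssd, pnn50 = time_domain(nn)
    ln_lf = ln_hf = np.nan
    if compute_freq:
        try:
            ln_lf, ln_hf = freq_domain(nn, **freq_kwargs)
        except ValueError:
            pass
    return HrvMeasures(
        hr_mean_bpm=float(np.mean(60000.0 / nn.nn_ms)),
        sdnn_ms=sdnn, rmssd_ms=rmssd, pnn50_pct=pnn50, ln_lf=ln_lf, ln_hf=ln_hf,
    )


def segment_measures(
    hr: HrSeries,
    segment_s: float = DEFAULT_SEGMENT_S,
    max_jump_bpm: float = DEFAULT_MAX_JUMP_BPM,
    nn_bounds_ms: tuple[float, float] = DEFAULT_NN_BOUNDS_MS,
) -> tuple[list[HrvMeasures], dict[str, SegmentChange]]:
    """HRV measures per non-overlapping segment, plus last-minus-first deltas.

    Each segment's HR points are jump-filtered and converted to NN
    intervals independently; a segment with unusable data yields missing
    measures, propagated into missing deltas.
    """
    duration = float(hr.t_center_s[-1]) + hr.win_s / 2.0
    n_seg = int(duration // segment_s)
    if n_seg < 2:
        raise ValueError(
            f"recording of {duration:.1f} s holds fewer than two {segment_s:.0f}-s segments"
        )

    per_segment: list[HrvMeasures] = []
    for k in range(n_seg):
        lo, hi = k * segment_s, (k + 1) * segment_s
        m = (hr.t_center_s >= lo) & (hr.t_center_s < hi)
        sub = HrSeries(
            t_center_s=hr.t_center_s[m], hr_bpm=hr.hr_bpm[m], win_s=hr.win_s,
            hop_s=hr.hop_s, roi_id=hr.roi_id, band_hz=hr.band_hz,
        )
        try:
            filt = filter_hr_jumps(sub, max_jump_bpm=max_jump_bpm)
            nn = hr_to_nn(filt, nn_bounds_ms=nn_bounds_ms)
            # within a single segment the spanned coverage is < segment_s;
            # require most of the segment rather than all of it
            meas = nn_measures(nn, min_span_s=0.75 * segment_s)
        except ValueError:
            meas = HrvMeasures()
        per_segment.append(meas)

    first, last = per_segment[0], per_segment[-1]
    deltas = {
        name: SegmentChange(measure=name, first=getattr(first, name), last=getattr(last, name))
        for name in MEASURE_NAMES
    }
    return per_segment, deltas
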