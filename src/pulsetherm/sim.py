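"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the pipeline assumes:

* beat series with sinusoidal LF/HF modulation of the beat-to-beat
  interval (band centers 0.095 and 0.275 Hz), built by direct NN-sequence
  construction so spectral power lands unambiguously inside the standard
  LF and HF bands;
* pulse-modulated RGB traces in which a unit pulse waveform (one
  asymmetric Gaussian per beat, fast rise / slow decay) is embedded with
  hemoglobin-like channel weighting (green strongest, red intermediate,
  blue weakest) on top of a common slow illumination drift and white
  sensor noise;
* thermal ROI traces with programmed group-wise segment effects (the
  last-120-s minus first-120-s mean change), a common linear drift,
  AR(1) sensor noise and randomly missing frames;

plus a labeled two-state study generator producing per-subject
baseline/stimulus feature records for the fusion stage.

Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rppg import RoiTraceSet
from .thermal import ROI_GROUP_OF, ROI_GROUPS, THERMAL_ROI_IDS, ThermalTraceSet

LF_MOD_HZ = 0.095  # center of the 0.04-0.15 Hz LF band
HF_MOD_HZ = 0.275  # center of the 0.15-0.40 Hz HF band

NN_RANGE_S = (0.3, 2.0)

#: Channel weights for embedding the pulse: hemoglobin absorbs green
#: light most strongly, so the pulse is largest in G, then R, then B.
RGB_PULSE_WEIGHTS = np.array([0.6, 1.0, 0.3])

RGB_BASELINES = np.array([120.0, 100.0, 80.0])


@dataclass
class BeatSeries:
    """Heartbeat times in seconds from recording start."""

    beat_times: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) < 2:
            raise ValueError("a beat series needs at least 2 beats")
        nn = np.diff(self.beat_times)
        if np.any(nn <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(nn < NN_RANGE_S[0]) or np.any(nn > NN_RANGE_S[1]):
            raise ValueError(f"NN intervals must lie in {NN_RANGE_S} s")

    @property
    def nn_s(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def mean_hr_bpm(self) -> float:
        return float(60.0 / self.nn_s.mean())


@dataclass
class SimGroundTruth:
    """Ground truth bundle written as a JSON sidecar next to simulated data."""

    beat_series: BeatSeries
    target_hr_bpm: float
    lf_amp_s: float
    hf_amp_s: float
    seed: int

    def __post_init__(self) -> None:
        if not 40.0 <= self.target_hr_bpm <= 180.0:
            raise ValueError("target_hr_bpm must be in [40, 180]")
        if self.lf_amp_s < 0 or self.hf_amp_s < 0:
            raise ValueError("modulation amplitudes must be >= 0")


@dataclass
class ThermalEffectSpec:
    """Programmed thermal study conditions, per ROI group.

    ``effects_c`` gives the last-minus-first 120-s mean temperature
    change per group; ``drift_slope_c_per_min`` a linear drift common to
    all ROIs; noise is AR(1) with stationary sd ``noise_sd_c``.
    """

    baselines_c: dict[str, float] = field(
        default_factory=lambda: {
            "eyebrow": 34.2, "forehead": 34.8, "nose": 33.0, "nostril": 33.5,
            "lip": 34.0, "cheek": 33.8, "chin": 33.6, "throat": 34.1,
        }
    )
    effects_c: dict[str, float] = field(default_factory=dict)
    drift_slope_c_per_min: float = 0.0
    noise_sd_c: float = 0.0
    ar_coef: float = 0.9
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_c < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        unknown = set(self.baselines_c) | set(self.effects_c)
        unknown -= set(ROI_GROUPS)
        if unknown:
            raise ValueError(f"unknown ROI groups {sorted(unknown)}")


def generate_beat_series(
    duration_s: float,
    mean_hr_bpm: float = 72.0,
    lf_amp_s: float = 0.0,
    hf_amp_s: float = 0.0,
    noise_sd_s: float = 0.0,
    seed: int = 0,
) -> BeatSeries:
    """Beat times whose NN intervals carry sinusoidal LF/HF modulation.

    ``NN(t) = 60/HR + lf_amp * sin(2 pi 0.095 t) + hf_amp * sin(2 pi 0.275 t)
    + N(0, noise_sd^2)`` evaluated at the previous beat time, laid down
    cumulatively from t = 0.  Parameter sets whose deterministic minimum
    NN would fall below 0.3 s are rejected; noise excursions are clipped
    to the physiologic NN range.
    """
    if duration_s < 30:
        raise ValueError("duration_s must be >= 30")
    if not 40.0 <= mean_hr_bpm <= 180.0:
        raise ValueError("mean_hr_bpm must be in [40, 180]")
    if lf_amp_s < 0 or hf_amp_s < 0 or noise_sd_s < 0:
        raise ValueError("amplitudes and noise sd must be >= 0")
    base = 60.0 / mean_hr_bpm
    if base - lf_amp_s - hf_amp_s < NN_RANGE_S[0]:
        raise ValueError(
            "modulation amplitudes allow NN below 0.3 s; reduce lf/hf amplitudes"
        )
    rng = np.random.default_rng(seed)
    beats = [0.0]
    t = 0.0
    while True:
        nn = (
            base
            + lf_amp_s * np.sin(2 * np.pi * LF_MOD_HZ * t)
            + hf_amp_s * np.sin(2 * np.pi * HF_MOD_HZ * t)
            + rng.normal(0.0, noise_sd_s)
        )
        nn = float(np.clip(nn, *NN_RANGE_S))
        t += nn
        if t >= duration_s:
            break
        beats.append(t)
    return BeatSeries(beat_times=np.array(beats), duration_s=float(duration_s))


def pulse_waveform(t: np.ndarray, beat_times: np.ndarray,
                   rise_s: float = 0.09, decay_s: float = 0.25) -> np.ndarray:
    """Unit-peak pulse train: one asymmetric Gaussian per beat."""
    p = np.zeros_like(t)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    half = int(np.ceil(4 * decay_s / dt))
    for b in beat_times:
        i0 = max(0, int((b - 4 * rise_s) / dt))
        i1 = min(len(t), int(b / dt) + half)
        seg = t[i0:i1] - b
        sig = np.where(seg < 0, rise_s, decay_s)
        p[i0:i1] += np.exp(-0.5 * (seg / sig) ** 2)
    return p


def synthesize_rgb_traces(
    beats: BeatSeries,
    fps: float = 30.0,
    n_rois: int = 8,
    pulse_amp: float = 0.01,
    noise_sd: float = 0.002,
    illum_drift_amp: float = 0.0,
    seed: int = 0,
    roi_ids: list[int] | None = None,
) -> RoiTraceSet:
    """Pulse-modulated multi-ROI RGB traces.

    Each ROI k gets ``C_k(t) = baseline_k * (1 + alpha_k p(t) + d(t) + eta(t))``
    with the channel-weighted pulse amplitude ``alpha_k`` jittered per
    ROI, a slow common illumination drift ``d(t)`` and white noise
    ``eta``.  The pulse waveform depends only on the beat series, never
    on the seed.
    """
    if fps < 10:
        raise ValueError("fps must be >= 10")
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if pulse_amp < 0 or noise_sd < 0:
        raise ValueError("pulse_amp and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(beats.duration_s * fps))
    t = np.arange(n) / fps
    p = pulse_waveform(t, beats.beat_times)
    drift = illum_drift_amp * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))

    if roi_ids is None:
        roi_ids = list(range(n_rois))
    rgb = {}
    for roi in roi_ids[:n_rois]:
        baseline = RGB_BASELINES * rng.uniform(0.9, 1.1, size=3)
        alpha = pulse_amp * RGB_PULSE_WEIGHTS * (1.0 + 0.2 * rng.standard_normal())
        eta = rng.normal(0.0, noise_sd, size=(n, 3))
        rgb[roi] = baseline * (1.0 + alpha * p[:, None] + drift[:, None] + eta)
    return RoiTraceSet(fps=fps, rgb=rgb, time_s=t)


def generate_thermal_traces(
    spec: ThermalEffectSpec,
    duration_s: float = 300.0,
    fps_thermal: float = 8.0,
    seed: int = 0,
    segment_s: float = 120.0,
) -> ThermalTraceSet:
    """Thermal ROI traces whose last-minus-first segment change equals the
    programmed group effect exactly (in the noise-free limit).

    The effect is realized as a linear ramp of slope
    ``effect / (duration - segment_s)``, whose first/last 120-s means
    differ by exactly the effect; the common drift adds
    ``drift_slope * (duration - segment_s)/60`` on top for every ROI.
    """
    if duration_s < 2 * segment_s:
        raise ValueError(f"duration_s must be >= {2 * segment_s:.0f}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps_thermal))
    t = np.arange(n) / fps_thermal
    drift = spec.drift_slope_c_per_min * t / 60.0

    parts = []
    for roi in THERMAL_ROI_IDS:
        grp = ROI_GROUP_OF[roi]
        base = spec.baselines_c.get(grp, 34.0)
        effect = spec.effects_c.get(grp, 0.0)
        ramp = effect / (duration_s - segment_s) * t
        noise = np.zeros(n)
        if spec.noise_sd_c > 0:
            eps = rng.normal(0.0, spec.noise_sd_c * np.sqrt(1 - spec.ar_coef**2), n)
            noise[0] = rng.normal(0.0, spec.noise_sd_c)
            for i in range(1, n):
                noise[i] = spec.ar_coef * noise[i - 1] + eps[i]
        temp = base + ramp + drift + noise
        keep = np.ones(n, dtype=bool)
        if spec.missing_fraction > 0:
            keep = rng.random(n) >= spec.missing_fraction
        parts.append(
            pd.DataFrame({"time_s": t[keep], "roi_id": roi, "temp_c": temp[keep]})
        )
    frames = pd.concat(parts, ignore_index=True)
    return ThermalTraceSet(frames=frames, fps=fps_thermal, duration_s=duration_s)


@dataclass
class StudyEffectProfile:
    """Programmed baseline -> stimulus shifts for the labeled study.

    The default direction mimics an arousal response: HR up, every HRV
    measure down, and warmer lip/cheek (stress) or nose-to-chin
    (elevation) regions.  Between-subject sds describe stable individual
    differences; within sds the per-record measurement noise.
    """

    hr_shift_bpm: float = 5.0
    sdnn_shift_ms: float = -10.0
    rmssd_shift_ms: float = -10.0
    pnn50_shift_pct: float = -8.0
    ln_lf_shift: float = -0.35
    ln_hf_shift: float = -0.35
    thermal_effects_c: dict[str, float] = field(
        default_factory=lambda: {"lip": 0.30, "cheek": 0.25}
    )
    between_sd_scale: float = 1.0
    within_sd_scale: float = 1.0

    @classmethod
    def for_condition(cls, condition: str) -> "StudyEffectProfile":
        if condition == "stress":
            return cls()
        if condition == "elevation":
            return cls(
                hr_shift_bpm=3.0, sdnn_shift_ms=-6.0, rmssd_shift_ms=-6.0,
                pnn50_shift_pct=-5.0, ln_lf_shift=-0.2, ln_hf_shift=-0.2,
                thermal_effects_c={
                    "nose": 0.2, "nostril": 0.2, "lip": 0.2, "cheek": 0.2, "chin": 0.2,
                },
            )
        raise ValueError(f"unknown condition {condition!r}")

    def null(self) -> "StudyEffectProfile":
        """Copy with every programmed effect set to zero."""
        return replace(
            self, hr_shift_bpm=0.0, sdnn_shift_ms=0.0, rmssd_shift_ms=0.0,
            pnn50_shift_pct=0.0, ln_lf_shift=0.0, ln_hf_shift=0.0,
            thermal_effects_c={},
        )


# population means and (between-subject sd, within-record sd) per measure
_HRV_POPULATION = {
    "hr_mean_bpm": (72.0, 7.0, 2.0),
    "sdnn_ms": (50.0, 12.0, 6.0),
    "rmssd_ms": (42.0, 12.0, 6.0),
    "pnn50_pct": (20.0, 8.0, 5.0),
    "ln_lf": (6.5, 0.6, 0.3),
    "ln_hf": (6.0, 0.7, 0.35),
}

_HRV_SHIFT_ATTR = {
    "hr_mean_bpm": "hr_shift_bpm",
    "sdnn_ms": "sdnn_shift_ms",
    "rmssd_ms": "rmssd_shift_ms",
    "pnn50_pct": "pnn50_shift_pct",
    "ln_lf": "ln_lf_shift",
    "ln_hf": "ln_hf_shift",
}

_THERMAL_BETWEEN_SD = 0.4
_THERMAL_WITHIN_SD = 0.12


def generate_labeled_study(
    n_subjects: int = 60,
    condition: str = "stress",
    effect_profile: StudyEffectProfile | None = None,
    seed: int = 0,
):
    """Labeled two-state study: one baseline and one stimulus record per
    subject, with programmed condition effects on both modalities.

    Records carry the six cardiac measures (HR mean, SDNN, rMSSD, pNN50,
    ln LF, ln HF) and the 22 per-ROI segment temperatures.  Subject
    random effects are shared between a subject's two records, so
    evaluation must keep subjects intact across folds.

    Returns a :class:`~pulsetherm.fusion.FusionDataset`.
    """
    from .fusion import FusionDataset  # local import avoids a cycle

    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    prof = effect_profile or StudyEffectProfile.for_condition(condition)
    rng = np.random.default_rng(seed)

    rppg_cols = list(_HRV_POPULATION)
    thermal_cols = [f"roi_{r}_temp_c" for r in THERMAL_ROI_IDS]
    base_spec = ThermalEffectSpec()

    rows, labels, subjects = [], [], []
    for s in range(n_subjects):
        subj_hrv = {
            m: mu + prof.between_sd_scale * bsd * rng.standard_normal()
            for m, (mu, bsd, _) in _HRV_POPULATION.items()
        }
        subj_thermal = {
            roi: base_spec.baselines_c[ROI_GROUP_OF[roi]]
            + prof.between_sd_scale * _THERMAL_BETWEEN_SD * rng.standard_normal()
            for roi in THERMAL_ROI_IDS
        }
        for label in (0, 1):  # 0 = baseline, 1 = stimulus
            rec = {}
            for m, (_, _, wsd) in _HRV_POPULATION.items():
                shift = getattr(prof, _HRV_SHIFT_ATTR[m]) if label else 0.0
                rec[m] = (
                    subj_hrv[m] + shift
                    + prof.within_sd_scale * wsd * rng.standard_normal()
                )
            for roi in THERMAL_ROI_IDS:
                eff = prof.thermal_effects_c.get(ROI_GROUP_OF[roi], 0.0) if label else 0.0
                rec[f"roi_{roi}_temp_c"] = (
                    subj_thermal[roi] + eff
                    + prof.within_sd_scale * _THERMAL_WITHIN_SD * rng.standard_normal()
                )
            rows.append(rec)
            labels.append(label)
            subjects.append(f"S{s:03d}")

    X = pd.DataFrame(rows, columns=rppg_cols + thermal_cols)
    modality = {c: "rppg" for c in rppg_cols} | {c: "thermal" for c in thermal_cols}
    return FusionDataset(
        X=X, y=np.array(labels), subjects=np.array(subjects), modality=modality
    )
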