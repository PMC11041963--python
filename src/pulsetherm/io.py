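"""CSV/JSON/YAML interchange and the pipeline configuration.

All tables are plain CSV with a header row, UTF-8, '.' decimal
separator, time in seconds from recording start, empty fields for
missing values.  Dialects:

* rgb:      time_s, roi_id, R, G, B
* thermal:  time_s, roi_id, temp_c
* beats:    beat_time_s
* hr:       t_center_s, roi_id ('agg' for the aggregate), hr_bpm
* bvp:      time_s, roi_id, bvp
* features: subject_id, <feature columns...>
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hrv as hrv_mod
from . import rppg as rppg_mod
from .rppg import BvpSignal, HrSeries, RoiTraceSet
from .sim import BeatSeries
from .thermal import THERMAL_ROI_IDS, ThermalTraceSet


class TraceFormatError(ValueError):
    """Malformed input table (bad header, row values, or ordering)."""


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their documented defaults."""

    fps_rgb: float = 30.0
    fps_thermal: float = 8.0
    pos_window_s: float = rppg_mod.DEFAULT_POS_WINDOW_S
    hr_win_s: float = rppg_mod.DEFAULT_HR_WIN_S
    hr_hop_s: float = rppg_mod.DEFAULT_HR_HOP_S
    hr_band_hz: tuple[float, float] = rppg_mod.DEFAULT_HR_BAND_HZ
    max_jump_bpm: float = hrv_mod.DEFAULT_MAX_JUMP_BPM
    segment_s: float = hrv_mod.DEFAULT_SEGMENT_S
    lf_band_hz: tuple[float, float] = hrv_mod.LF_BAND_HZ
    hf_band_hz: tuple[float, float] = hrv_mod.HF_BAND_HZ
    nn_bounds_ms: tuple[float, float] = hrv_mod.DEFAULT_NN_BOUNDS_MS
    min_coverage: float = 0.5
    cv_folds: int = 5
    seed: int = 0
    roi_include: list[int] = field(default_factory=list)  # empty = all

    def __post_init__(self) -> None:
        for name in ("hr_band_hz", "lf_band_hz", "hf_band_hz", "nn_bounds_ms"):
            setattr(self, name, tuple(float(v) for v in getattr(self, name)))
        if self.fps_rgb < 10 or self.fps_thermal <= 0:
            raise ValueError("invalid frame rates")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise TraceFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    if set(df.columns) != cols:
        raise TraceFormatError(
            f"{path}: expected columns {sorted(cols)}, found {sorted(df.columns)}"
        )


def read_trace_csv(path: str | Path, kind: str, fps: float | None = None):
    """Read and validate one of the documented CSV dialects.

    Returns the matching typed object (RoiTraceSet, ThermalTraceSet,
    BeatSeries, HrSeries, or a features DataFrame).  Malformed rows are
    reported with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise TraceFormatError(f"{path}: file not found")
    df = pd.read_csv(path)

    if kind == "rgb":
        _require_columns(df, {"time_s", "roi_id", "R", "G", "B"}, path)
        bad = df[(df[["R", "G", "B"]] <= 0).any(axis=1) | df[["R", "G", "B"]].isna().any(axis=1)]
        if len(bad):
            raise TraceFormatError(
                f"{path}: non-positive/missing intensities at rows {list(bad.index[:5] + 2)}"
            )
        rgb = {}
        t_ref = None
        for roi, g in df.groupby("roi_id"):
            t = g["time_s"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise TraceFormatError(f"{path}: non-monotone time for ROI {roi}")
            rgb[int(roi)] = g[["R", "G", "B"]].to_numpy(float)
            t_ref = t
        if fps is None:
            fps = 1.0 / float(np.median(np.diff(t_ref)))
        return RoiTraceSet(fps=fps, rgb=rgb, time_s=t_ref)

    if kind == "thermal":
        _require_columns(df, {"time_s", "roi_id", "temp_c"}, path)
        bad = df[~df["roi_id"].isin(THERMAL_ROI_IDS)]
        if len(bad):
            raise TraceFormatError(
                f"{path}: roi_id not in the 22-ROI set at rows {list(bad.index[:5] + 2)}"
            )
        if fps is None:
            dt = df.groupby("roi_id")["time_s"].diff().dropna()
            fps = 1.0 / float(dt.median())
        return ThermalTraceSet(frames=df, fps=fps)

    if kind == "beats":
        _require_columns(df, {"beat_time_s"}, path)
        t = df["beat_time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise TraceFormatError(f"{path}: beat times must be strictly increasing")
        return BeatSeries(beat_times=t, duration_s=float(t[-1]))

    if kind == "hr":
        _require_columns(df, {"t_center_s", "roi_id", "hr_bpm"}, path)
        series = []
        for roi, g in df.groupby("roi_id", sort=True):
            t = g["t_center_s"].to_numpy(float)
            if np.any(np.diff(t) <= 0):
                raise TraceFormatError(f"{path}: non-monotone window centers for {roi}")
            hop = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
            series.append(HrSeries(
                t_center_s=t, hr_bpm=g["hr_bpm"].to_numpy(float),
                win_s=rppg_mod.DEFAULT_HR_WIN_S, hop_s=hop,
                roi_id=None if str(roi) == "agg" else int(roi),
            ))
        return series

    if kind == "features":
        if "subject_id" not in df.columns:
            raise TraceFormatError(f"{path}: features CSV needs a subject_id column")
        return df.set_index("subject_id")

    raise ValueError(f"unknown kind {kind!r}")


def write_rgb_csv(traces: RoiTraceSet, path: str | Path) -> None:
    parts = []
    for roi, arr in sorted(traces.rgb.items()):
        parts.append(pd.DataFrame({
            "time_s": traces.time_s, "roi_id": roi,
            "R": arr[:, 0], "G": arr[:, 1], "B": arr[:, 2],
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def write_thermal_csv(traces: ThermalTraceSet, path: str | Path) -> None:
    traces.frames.to_csv(path, index=False)


def write_beats_csv(beats: BeatSeries, path: str | Path) -> None:
    pd.DataFrame({"beat_time_s": beats.beat_times}).to_csv(path, index=False)


def write_hr_csv(series: list[HrSeries], path: str | Path) -> None:
    parts = []
    for s in series:
        parts.append(pd.DataFrame({
            "t_center_s": s.t_center_s,
            "roi_id": "agg" if s.roi_id is None else s.roi_id,
            "hr_bpm": s.hr_bpm,
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def write_bvp_csv(bvps: list[BvpSignal], path: str | Path) -> None:
    parts = []
    for b in bvps:
        t = np.arange(len(b.samples)) / b.fps
        parts.append(pd.DataFrame({"time_s": t, "roi_id": b.roi_id, "bvp": b.samples}))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
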