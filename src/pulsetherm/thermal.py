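"""Facial thermal-imaging ROI features.

The thermal path works on per-ROI skin temperature time series for 22
facial regions (eyebrows, forehead, nose, nostrils, lips, cheeks, chin,
throat).  Features follow the segment-change design: the mean
temperature of the last 120-s window minus the mean of the first 120-s
window, per ROI; the same change referenced to the forehead (the most
thermally stable facial region, so common drifts cancel); and the full
antisymmetric matrix of pairwise change differences between ROIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ROI ids grouped by facial region.
ROI_GROUPS: dict[str, tuple[int, ...]] = {
    "eyebrow": (18, 21, 22, 25),
    "forehead": (58,),
    "nose": (28, 29, 30),
    "nostril": (32, 34),
    "lip": (48, 49, 50, 51, 52, 53),
    "cheek": (54, 55, 56, 57),
    "chin": (59,),
    "throat": (60,),
}

#: The 22 valid thermal ROI ids, ascending.
THERMAL_ROI_IDS: tuple[int, ...] = tuple(
    sorted(r for ids in ROI_GROUPS.values() for r in ids)
)

#: Reverse map roi_id -> group label.
ROI_GROUP_OF: dict[int, str] = {
    roi: grp for grp, ids in ROI_GROUPS.items() for roi in ids
}

FOREHEAD_ROI = 58

TEMP_RANGE_C = (20.0, 45.0)


@dataclass
class ThermalTraceSet:
    """Per-ROI facial temperature time series; missing frames allowed.

    Parameters
    ----------
    frames : DataFrame with columns ``time_s``, ``roi_id``, ``temp_c``.
    fps : nominal thermal frame rate (Hz), used for coverage checks.
    duration_s : recording length; inferred from the data if omitted.
    """

    frames: pd.DataFrame
    fps: float
    duration_s: float | None = None

    def __post_init__(self) -> None:
        req = {"time_s", "roi_id", "temp_c"}
        if not req.issubset(self.frames.columns):
            raise ValueError(f"thermal frames need columns {sorted(req)}")
        bad = set(self.frames["roi_id"].unique()) - set(THERMAL_ROI_IDS)
        if bad:
            raise ValueError(f"unknown thermal ROI ids {sorted(bad)}")
        temps = self.frames["temp_c"].to_numpy(float)
        if len(temps) and (
            np.nanmin(temps) < TEMP_RANGE_C[0] or np.nanmax(temps) > TEMP_RANGE_C[1]
        ):
            raise ValueError(
                f"temperatures outside plausible skin range {TEMP_RANGE_C} degC"
            )
        if self.duration_s is None:
            self.duration_s = float(self.frames["time_s"].max()) if len(temps) else 0.0

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.frames["roi_id"].unique())


@dataclass
class ThermalFeatureSet:
    """Segment-change features over the 22 thermal ROIs."""

    means: pd.DataFrame  # index roi_id; columns mean_first_c, mean_last_c
    abs_change_c: pd.Series  # last minus first, per ROI
    ref_change_c: pd.Series  # change minus forehead change
    diff_matrix: pd.DataFrame  # [i, j] = change_j - change_i
    segment_s: float = 120.0
    groups: dict[int, str] = field(default_factory=lambda: dict(ROI_GROUP_OF))


def segment_means(
    traces: ThermalTraceSet, segment_s: float = 120.0, min_coverage: float = 0.5
) -> pd.DataFrame:
    """Mean temperature of the first and last ``segment_s`` window per ROI.

    A window holding fewer than ``min_coverage`` of its nominally expected
    frames (``segment_s * fps``) yields a missing mean; a ROI missing in
    both windows is dropped with a warning.
    """
    T = float(traces.duration_s)
    if T < 2 * segment_s:
        raise ValueError(
            f"recording of {T:.1f} s cannot hold two {segment_s:.0f}-s segments"
        )
    expected = segment_s * traces.fps
    t = traces.frames["time_s"].to_numpy(float)
    first = traces.frames[(t >= 0) & (t < segment_s)]
    last = traces.frames[(t >= T - segment_s) & (t <= T)]

    rows = {}
    for roi in traces.roi_ids:
        out = {}
        for name, seg in (("mean_first_c", first), ("mean_last_c", last)):
            vals = seg.loc[seg["roi_id"] == roi, "temp_c"]
            out[name] = float(vals.mean()) if len(vals) >= min_coverage * expected else np.nan
        if np.isnan(out["mean_first_c"]) and np.isnan(out["mean_last_c"]):
            logger.warning("ROI %d has insufficient coverage in both segments; dropped", roi)
            continue
        rows[roi] = out
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("roi_id")


def absolute_changes(means: pd.DataFrame) -> pd.Series:
    """Temperature change per ROI: last-segment mean minus first-segment mean."""
    return (means["mean_last_c"] - means["mean_first_c"]).rename("abs_change_c")


def differential_matrix(abs_changes: pd.Series) -> pd.DataFrame:
    """Pairwise change differences, ``M[i, j] = change_j - change_i``.

    Antisymmetric with a zero diagonal; ROIs with a missing change get
    missing rows/columns.
    """
    if abs_changes.notna().sum() < 2:
        raise ValueError("differential matrix needs at least 2 ROIs with changes")
    c = abs_changes.to_numpy(float)
    m = c[None, :] - c[:, None]
    idx = abs_changes.index
    return pd.DataFrame(m, index=idx, columns=idx)


def forehead_referenced(abs_changes: pd.Series, ref_roi: int = FOREHEAD_ROI) -> pd.Series:
    """Changes referenced to the forehead ROI (common drift cancels)."""
    if ref_roi not in abs_changes.index or np.isnan(abs_changes[ref_roi]):
        raise ValueError(f"reference ROI {ref_roi} missing from changes")
    return (abs_changes - abs_changes[ref_roi]).rename("ref_change_c")


def compute_features(
    traces: ThermalTraceSet,
    segment_s: float = 120.0,
    min_coverage: float = 0.5,
    ref_roi: int = FOREHEAD_ROI,
) -> ThermalFeatureSet:
    """Full thermal feature set: segment means, changes, referenced changes,
    and the pairwise differential matrix."""
    means = segment_means(traces, segment_s=segment_s, min_coverage=min_coverage)
    changes = absolute_changes(means)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diff = differential_matrix(changes)
    ref = forehead_referenced(changes, ref_roi=ref_roi)
    return ThermalFeatureSet(
        means=means,
        abs_change_c=changes,
        ref_change_c=ref,
        diff_matrix=diff,
        segment_s=segment_s,
    )
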