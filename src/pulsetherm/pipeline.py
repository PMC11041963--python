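"""End-to-end composition of the pipeline stages with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, hrv, io, rppg, thermal

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: io.PipelineConfig,
    out_dir: str | Path,
    rgb_csv: str | Path | None = None,
    thermal_csv: str | Path | None = None,
    beats_csv: str | Path | None = None,
) -> dict:
    """Run rppg -> hrv -> thermal stages on whatever inputs are present.

    Writes per-stage artifacts plus a JSON run manifest (config, seed,
    version, per-stage record counts, output hashes) to ``out_dir`` and
    returns the manifest.  A stage error aborts with the stage name.
    """
    if rgb_csv is None and thermal_csv is None:
        raise ValueError("at least one modality's input must be provided")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }

    if rgb_csv is not None:
        try:
            traces = io.read_trace_csv(rgb_csv, "rgb", fps=config.fps_rgb)
            bvps = rppg.pos_bvp(traces, pos_window_s=config.pos_window_s)
            per_roi = [
                rppg.windowed_hr(b, win_s=config.hr_win_s, hop_s=config.hr_hop_s,
                                 band_hz=config.hr_band_hz)
                for b in bvps
            ]
            agg = rppg.aggregate_hr(per_roi)
            qi = rppg.quality_mae_over_hr(per_roi, agg)
            io.write_bvp_csv(bvps, out / "bvp.csv")
            io.write_hr_csv(per_roi + [agg], out / "hr.csv")
            (out / "quality.json").write_text(json.dumps({
                "mae_over_hr": qi.mae_over_hr, "mae_bpm": qi.mae_bpm,
                "mean_hr_bpm": qi.mean_hr_bpm, "n_rois": qi.n_rois,
                "n_windows": qi.n_windows,
            }, indent=2))
            manifest["stages"]["rppg"] = {
                "n_rois": len(bvps), "n_windows": len(agg),
                "mae_over_hr": qi.mae_over_hr,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("rppg", e) from e

        try:
            per_seg, deltas = hrv.segment_measures(
                agg, segment_s=config.segment_s, max_jump_bpm=config.max_jump_bpm,
                nn_bounds_ms=config.nn_bounds_ms,
            )
            seg_df = pd.DataFrame([m.as_dict() for m in per_seg])
            seg_df.insert(0, "segment", np.arange(len(per_seg)))
            seg_df.to_csv(out / "hrv_segments.csv", index=False)
            pd.DataFrame(
                [{"measure": k, "first": d.first, "last": d.last, "delta": d.delta}
                 for k, d in deltas.items()]
            ).to_csv(out / "hrv_deltas.csv", index=False)
            manifest["stages"]["hrv"] = {"n_segments": len(per_seg)}
        except Exception as e:  # noqa: BLE001
            raise StageError("hrv", e) from e
    else:
        manifest["stages"]["rppg"] = "skipped (no RGB input)"
        manifest["stages"]["hrv"] = "skipped (no RGB input)"

    if thermal_csv is not None:
        try:
            ttr = io.read_trace_csv(thermal_csv, "thermal", fps=config.fps_thermal)
            feats = thermal.compute_features(
                ttr, segment_s=config.segment_s, min_coverage=config.min_coverage
            )
            tbl = feats.means.copy()
            tbl["abs_change_c"] = feats.abs_change_c
            tbl["ref_change_c"] = feats.ref_change_c
            tbl.to_csv(out / "thermal_features.csv")
            feats.diff_matrix.to_csv(out / "thermal_diff_matrix.csv")
            manifest["stages"]["thermal"] = {"n_rois": len(feats.means)}
        except Exception as e:  # noqa: BLE001
            raise StageError("thermal", e) from e
    else:
        manifest["stages"]["thermal"] = "skipped (no thermal input)"

    if beats_csv is not None and rgb_csv is not None:
        try:
            beats = io.read_trace_csv(beats_csv, "beats")
            nn = hrv.beats_to_nn(beats.beat_times, nn_bounds_ms=config.nn_bounds_ms)
            ref = hrv.nn_measures(nn)
            (out / "reference_hrv.json").write_text(
                json.dumps(ref.as_dict(), indent=2)
            )
            manifest["stages"]["reference"] = {"n_beats": len(beats.beat_times)}
        except Exception as e:  # noqa: BLE001
            raise StageError("reference", e) from e

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
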