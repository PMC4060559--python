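"""File formats: trial/calibration CSV, NIfTI BOLD + masks, motion text, JSON.

All tabular formats go through pandas; volumetric data go through nibabel
(NIfTI-1).  A voxel-table CSV dialect mirrors the NIfTI content for
dependency-light round trips: one row per voxel with tissue probabilities,
an ROI label, and the time series in ``v0..v{T-1}`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .eye_movement import EyeMovementTrial
from .fmri_roi import BoldRun
from .timeline import DesignTimeline, IlluminationEvent, Phase


# -- eye movement -----------------------------------------------------------

def write_trials_csv(trials, path) -> None:
    """Write trials as long CSV: time_s, left_v, right_v, trial_id (+ metadata)."""
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": tr.time_s,
                    "left_v": tr.left,
                    "right_v": tr.right,
                    "trial_id": tr.trial_id,
                    "stim_onset_s": tr.stim_onset_s,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path, sample_rate: float | None = None) -> list[EyeMovementTrial]:
    df = pd.read_csv(path)
    trials = []
    for tid, g in df.groupby("trial_id", sort=False):
        t = g["time_s"].to_numpy()
        fs = sample_rate or 1.0 / np.median(np.diff(t))
        onset = float(g["stim_onset_s"].iloc[0]) if "stim_onset_s" in g else 0.0
        trials.append(
            EyeMovementTrial(
                t, g["left_v"].to_numpy(), g["right_v"].to_numpy(),
                float(fs), "volts", str(tid), onset,
            )
        )
    return trials


def write_calibration_csv(table: np.ndarray, path) -> None:
    pd.DataFrame(table, columns=["angle_deg", "left_v", "right_v"]).to_csv(
        path, index=False
    )


def read_calibration_csv(path) -> np.ndarray:
    return pd.read_csv(path)[["angle_deg", "left_v", "right_v"]].to_numpy()


# -- BOLD -------------------------------------------------------------------

def _grid_shape(coords: np.ndarray) -> tuple[int, int, int]:
    return tuple(int(c) + 1 for c in coords.max(axis=0))


def write_bold_nifti(run: BoldRun, path) -> None:
    """4D NIfTI-1 image laid out on the run's voxel grid coordinates."""
    if run.coords is None:
        raise ValueError("run has no voxel coordinates; use the CSV dialect")
    shape = _grid_shape(run.coords)
    vol = np.zeros(shape + (run.n_volumes,), dtype=np.float32)
    vol[tuple(run.coords.T)] = run.signal
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, str(path))


def write_mask_nifti(mask: np.ndarray, coords: np.ndarray, path) -> None:
    shape = _grid_shape(coords)
    vol = np.zeros(shape, dtype=np.uint8)
    vol[tuple(coords[mask].T)] = 1
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_tissue_niftis(run: BoldRun, out_dir) -> None:
    out_dir = Path(out_dir)
    shape = _grid_shape(run.coords)
    for i, name in enumerate(("gm", "wm", "csf")):
        vol = np.zeros(shape, dtype=np.float32)
        vol[tuple(run.coords.T)] = run.tissue_probs[:, i]
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(out_dir / f"{name}.nii"))


def read_bold_nifti(path, tissue_probs, motion) -> BoldRun:
    """Load a 4D NIfTI written by :func:`write_bold_nifti`.

    Only voxels with a nonzero time series are kept (the writer zero-fills
    the rest of the grid); their grid coordinates are preserved.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    nz = np.argwhere(np.abs(data).sum(axis=3) > 0)
    signal = data[tuple(nz.T)]
    return BoldRun(signal, tissue_probs, motion, tr, coords=nz)


def write_voxel_table_csv(
    run: BoldRun, masks: dict[str, np.ndarray], path
) -> None:
    roi_label = np.array(["" for _ in range(run.n_voxels)], dtype=object)
    for roi, m in masks.items():
        roi_label[m] = roi
    df = pd.DataFrame(
        {
            "gm_prob": run.tissue_probs[:, 0],
            "wm_prob": run.tissue_probs[:, 1],
            "csf_prob": run.tissue_probs[:, 2],
            "roi": roi_label,
        }
    )
    series = pd.DataFrame(
        run.signal, columns=[f"v{t}" for t in range(run.n_volumes)]
    )
    pd.concat([df, series], axis=1).to_csv(path, index=False)


def read_voxel_table_csv(path, motion, tr: float) -> tuple[BoldRun, dict]:
    df = pd.read_csv(path, keep_default_na=False)
    vcols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    vcols.sort(key=lambda c: int(c[1:]))
    signal = df[vcols].to_numpy(float)
    tissue = df[["gm_prob", "wm_prob", "csf_prob"]].to_numpy(float)
    run = BoldRun(signal, tissue, motion, tr)
    masks = {
        roi: (df["roi"] == roi).to_numpy()
        for roi in df["roi"].unique() if roi
    }
    return run, masks


def write_motion_par(motion: np.ndarray, path) -> None:
    """6-column whitespace-delimited motion parameters, one volume per row."""
    np.savetxt(path, np.asarray(motion, float), fmt="%.6f")


def read_motion_par(path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    return motion


# -- timeline / manifests ---------------------------------------------------

def write_timeline_json(timeline: DesignTimeline, path) -> None:
    payload = {
        "phases": [
            {"label": p.label, "start_s": p.start_s, "end_s": p.end_s}
            for p in timeline.phases
        ],
        "illuminations": [
            {
                "target": e.target, "demand_deg": e.demand_deg,
                "onset_s": e.onset_s, "duration_s": e.duration_s,
            }
            for e in timeline.illuminations
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_timeline_json(path) -> DesignTimeline:
    payload = json.loads(Path(path).read_text())
    return DesignTimeline(
        phases=[Phase(p["label"], p["start_s"], p["end_s"]) for p in payload["phases"]],
        illuminations=[
            IlluminationEvent(
                e["target"], e["demand_deg"], e["onset_s"], e["duration_s"]
            )
            for e in payload["illuminations"]
        ],
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dataclass_fields__"):
        return {k: getattr(o, k) for k in o.__dataclass_fields__}
    raise TypeError(f"cannot serialize {type(o)!r}")
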