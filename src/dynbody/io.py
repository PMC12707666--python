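"""Readers and writers for the pipeline's on-disk formats.

Events use the BIDS events TSV dialect (onset / duration / trial_type plus
stimulus_id and run); feature matrices are TSV with a header of feature
names; time series and trajectories use NumPy archives; statistical maps can
optionally round-trip through NIfTI (voxels flattened to a 1x1xV grid).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features.posture import FeatureSpace

__all__ = [
    "read_events",
    "write_events",
    "read_features",
    "write_features",
    "read_timeseries",
    "write_timeseries",
    "export_nifti_map",
    "import_nifti_map",
    "SchemaError",
]

_BIDS_COLUMNS = {"onset": "onset_s", "duration": "duration_s", "trial_type": "condition"}


class SchemaError(ValueError):
    """A file does not conform to its declared dialect."""


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    """Write an event table as BIDS-dialect TSV."""
    path = Path(path)
    out = pd.DataFrame(
        {
            "onset": events["onset_s"],
            "duration": events["duration_s"],
            "trial_type": events["condition"],
            "stimulus_id": events["stimulus_id"],
            "run": events["run"],
        }
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-dialect events TSV back into the internal schema."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type", "stimulus_id", "run"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required events column {col!r}")
    ev = pd.DataFrame(
        {
            "run": df["run"].astype(int),
            "onset_s": df["onset"].astype(float),
            "duration_s": df["duration"].astype(float),
            "stimulus_id": df["stimulus_id"].astype(str),
            "condition": df["trial_type"].astype(str),
        }
    )
    for r, grp in ev.groupby("run"):
        if not grp["onset_s"].is_monotonic_increasing:
            raise SchemaError(f"{path}: onsets not increasing within run {r}")
    return ev


def write_features(fs: FeatureSpace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(fs.X, index=fs.stimulus_ids, columns=fs.feature_names)
    df.index.name = "stimulus_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_features(path: str | Path, name: str | None = None) -> FeatureSpace:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "stimulus_id":
        raise SchemaError(f"{path}: first column must be 'stimulus_id'")
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no feature columns")
    return FeatureSpace(
        name=name or Path(path).stem,
        X=df.to_numpy(dtype=float),
        feature_names=list(df.columns),
        stimulus_ids=[str(i) for i in df.index],
    )


def write_timeseries(Y_runs: list[np.ndarray], path: str | Path, tr_s: float = 2.3) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"run{r:03d}": np.asarray(Y) for r, Y in enumerate(Y_runs)}
    np.savez_compressed(path, tr_s=np.array(tr_s), **arrays)
    return path


def read_timeseries(path: str | Path) -> tuple[list[np.ndarray], float]:
    with np.load(path) as z:
        keys = sorted(k for k in z.files if k.startswith("run"))
        if not keys:
            raise SchemaError(f"{path}: no run arrays found")
        runs = [z[k] for k in keys]
        tr_s = float(z["tr_s"]) if "tr_s" in z.files else 2.3
    v = {r.shape[1] for r in runs}
    if len(v) != 1:
        raise SchemaError(f"{path}: voxel count varies across runs")
    return runs, tr_s


def export_nifti_map(values: np.ndarray, path: str | Path) -> Path:
    """Write a per-voxel map as a 1x1xV float32 NIfTI volume."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = np.asarray(values, dtype=np.float32).reshape(1, 1, -1)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    return path


def import_nifti_map(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float32).ravel()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
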