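"""NIfTI / TSV / JSON input-output for subjects and derived maps."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .lagmap import LagMap
from .preprocess import BoldSeries, MotionTrace
from .synthetic import GroundTruth, SubjectBundle, SyntheticConfig

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_nifti(data: np.ndarray, voxel_size, path: Path, dtype=np.float32) -> Path:
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel_size


def save_motion_tsv(motion: MotionTrace, path: Path) -> Path:
    df = pd.DataFrame(np.hstack([motion.translations, motion.rotations]),
                      columns=MOTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


def load_motion_tsv(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV {path} is missing columns {missing}")
    return MotionTrace(df[MOTION_COLUMNS[:3]].to_numpy(),
                       df[MOTION_COLUMNS[3:]].to_numpy())


def save_subject(bundle: SubjectBundle, sub_dir: str | Path) -> dict[str, Path]:
    """Write one subject's images, motion trace and truth sidecar."""
    sub_dir = Path(sub_dir)
    sub_dir.mkdir(parents=True, exist_ok=True)
    vs = bundle.series.voxel_size
    t = bundle.truth
    paths = {
        "bold": save_nifti(bundle.series.data, vs, sub_dir / "bold.nii.gz"),
        "brain_mask": save_nifti(bundle.series.brain_mask, vs, sub_dir / "brain_mask.nii.gz", np.uint8),
        "sinus_mask": save_nifti(t.sinus_mask, vs, sub_dir / "sinus_mask.nii.gz", np.uint8),
        "dwi_mask": save_nifti(t.dwi_mask, vs, sub_dir / "dwi_mask.nii.gz", np.uint8),
        "lesion_mask": save_nifti(t.lesion_mask, vs, sub_dir / "true_lesion_mask.nii.gz", np.uint8),
        "territory_atlas": save_nifti(t.territory_atlas, vs, sub_dir / "territory_atlas.nii.gz", np.int16),
        "lag_field": save_nifti(t.lag_field, vs, sub_dir / "true_lag_field.nii.gz"),
        "motion": save_motion_tsv(bundle.motion, sub_dir / "motion.tsv"),
    }
    sidecar = {
        "subject_id": bundle.subject_id,
        "seed": bundle.seed,
        "tr": bundle.series.tr,
        "n_frames": bundle.series.n_frames,
        "voxel_size": list(vs),
        "territory_names": {str(k): v for k, v in t.territory_names.items()},
        "slfo_signal": [float(x) for x in t.slfo_signal],
    }
    sidecar_path = sub_dir / "truth.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    paths["sidecar"] = sidecar_path
    return paths


def load_subject(sub_dir: str | Path) -> SubjectBundle:
    """Re-assemble a subject bundle written by :func:`save_subject`."""
    sub_dir = Path(sub_dir)
    with open(sub_dir / "truth.json") as fh:
        sidecar = json.load(fh)
    data, vs = load_nifti(sub_dir / "bold.nii.gz")
    brain, _ = load_nifti(sub_dir / "brain_mask.nii.gz")
    series = BoldSeries(data=np.asarray(data, dtype=float), voxel_size=vs,
                        tr=float(sidecar["tr"]), brain_mask=brain > 0)
    truth = GroundTruth(
        lag_field=np.asarray(load_nifti(sub_dir / "true_lag_field.nii.gz")[0], dtype=float),
        lesion_mask=load_nifti(sub_dir / "true_lesion_mask.nii.gz")[0] > 0,
        sinus_mask=load_nifti(sub_dir / "sinus_mask.nii.gz")[0] > 0,
        territory_atlas=np.asarray(load_nifti(sub_dir / "territory_atlas.nii.gz")[0], dtype=np.int32),
        dwi_mask=load_nifti(sub_dir / "dwi_mask.nii.gz")[0] > 0,
        slfo_signal=np.asarray(sidecar["slfo_signal"], dtype=float),
        amplitude_field=np.zeros(series.spatial_shape),
        territory_names={int(k): v for k, v in sidecar["territory_names"].items()},
    )
    return SubjectBundle(series=series, truth=truth,
                         motion=load_motion_tsv(sub_dir / "motion.tsv"),
                         subject_id=sidecar["subject_id"], seed=int(sidecar["seed"]))


def save_lagmap(lagmap: LagMap, voxel_size, out_dir: str | Path, prefix: str = "bolddelay") -> dict[str, Path]:
    """Lag map as three NIfTI volumes: lags (s), peak r, validity."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {
        "lags": save_nifti(lagmap.lags, voxel_size, out_dir / f"{prefix}_lag_s.nii.gz"),
        "peak_r": save_nifti(lagmap.peak_r, voxel_size, out_dir / f"{prefix}_peak_r.nii.gz"),
        "valid": save_nifti(lagmap.valid, voxel_size, out_dir / f"{prefix}_valid.nii.gz", np.uint8),
    }


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a plain dict (YAML/JSON payload)."""
    fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown synthetic-config keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("grid_shape", "voxel_size", "slfo_band", "lag_range_normal", "lag_range_lesion"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticConfig(**kwargs)
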