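"""Readers/writers for calibrations, radiographs, pose series and volumes.

Formats: projection models as JSON/YAML; radiographs as 8-bit PNG with a
JSON sidecar (plane id, timestamp); pose series as CSV with the fixed
column order ``frame, t, x, y, z, alpha, beta, gamma``; voxel volumes as
NIfTI; shape models as compressed npz archives (see
:meth:`fluorokin.ssm.ShapeModel.save`).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .drr import RadiographImage, VoxelVolume
from .geometry import Pose6DOF, ProjectionModel

POSE_COLUMNS = ["frame", "t", "x", "y", "z", "alpha", "beta", "gamma"]


# ----------------------------------------------------------- calibrations

def projection_to_dict(model: ProjectionModel) -> dict:
    return {
        "source": model.source.tolist(),
        "detector_origin": model.detector_origin.tolist(),
        "u_axis": model.u_axis.tolist(),
        "v_axis": model.v_axis.tolist(),
        "pixel_spacing": model.pixel_spacing.tolist(),
        "resolution": list(model.resolution),
    }


def projection_from_dict(d: dict) -> ProjectionModel:
    return ProjectionModel(
        d["source"], d["detector_origin"], d["u_axis"], d["v_axis"],
        d["pixel_spacing"], tuple(d["resolution"]),
    )


def save_projection(model: ProjectionModel, path) -> None:
    path = Path(path)
    data = projection_to_dict(model)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=1, sort_keys=True))


def load_projection(path) -> ProjectionModel:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return projection_from_dict(data)


# ------------------------------------------------------------- radiographs

def save_radiograph(img: RadiographImage, path) -> None:
    """8-bit PNG plus `<name>.json` sidecar."""
    path = Path(path)
    pixels = img.pixels
    if pixels.dtype != np.uint8:
        pixels = img.to_uint8().pixels
    iio.imwrite(path, pixels)
    sidecar = {"plane_id": img.plane_id, "timestamp": img.timestamp}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_radiograph(path) -> RadiographImage:
    path = Path(path)
    pixels = iio.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return RadiographImage(pixels, meta.get("plane_id", "A"), meta.get("timestamp", 0.0))


# -------------------------------------------------------------- pose series

def save_pose_series(poses, times, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(POSE_COLUMNS)
        for i, (p, t) in enumerate(zip(poses, times)):
            w.writerow([i, repr(float(t))] + [repr(float(v)) for v in p.to_vector()])


def load_pose_series(path):
    poses, times = [], []
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header != POSE_COLUMNS:
            raise ValueError(f"unexpected pose CSV header: {header}")
        for row in r:
            times.append(float(row[1]))
            poses.append(Pose6DOF.from_vector([float(v) for v in row[2:8]]))
    return poses, times


# ------------------------------------------------------------------ volumes

def save_volume(volume: VoxelVolume, path) -> None:
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))


def load_volume(path) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    aff = img.affine
    return VoxelVolume(aff[:3, 3], np.diag(aff)[:3], np.asanyarray(img.dataobj))
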