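"""NIfTI and table I/O helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .data import VolumeChannelStack
from .phantom import TissuePhantom

__all__ = [
    "read_volume",
    "write_volume",
    "load_channel_stack",
    "write_lesion_records",
    "read_lesion_records",
    "write_phantom_lesions",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Load a 3D NIfTI-1 volume; returns (data, affine, voxel spacing in mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    spacing = tuple(float(s) for s in np.linalg.norm(affine[:3, :3], axis=0))
    return data, affine, spacing


def write_volume(volume: np.ndarray, affine: np.ndarray | None, path) -> None:
    """Write a 3D volume as NIfTI-1 (lossless for data and affine)."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    nib.save(nib.Nifti1Image(volume, affine), str(path))


def load_channel_stack(
    channel_paths: Sequence, mask_path, target_path=None, subject_id: str = ""
) -> VolumeChannelStack:
    """Load co-registered predictor channels (+ mask, optional target).

    All files of one subject must share shape and affine.
    """
    vols, affines = [], []
    for p in channel_paths:
        d, a, spacing = read_volume(p)
        vols.append(d.astype(np.float32))
        affines.append(a)
    mask, a, _ = read_volume(mask_path)
    affines.append(a)
    target = None
    if target_path is not None:
        target, a, _ = read_volume(target_path)
        target = target.astype(np.float32)
        affines.append(a)
    shapes = {v.shape for v in vols} | {mask.shape} | ({target.shape} if target is not None else set())
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ across subject files: {sorted(shapes)}")
    for a in affines[1:]:
        if not np.allclose(a, affines[0], atol=1e-6):
            raise ValueError("channel affines differ across subject files")
    _, _, spacing = read_volume(channel_paths[0])
    return VolumeChannelStack(
        predictors=np.stack(vols),
        target=target,
        spacing=spacing,
        mask=mask.astype(np.uint8),
        subject_id=subject_id,
        affine=affines[0],
    )


_LESION_COLUMNS = [
    "subject_id", "lesion_id", "type", "lobe",
    "centroid_x", "centroid_y", "centroid_z", "area_mm2", "source",
]


def write_lesion_records(records, path) -> None:
    rows = [
        dict(
            subject_id=r.subject_id,
            lesion_id=r.lesion_id,
            type=r.type,
            lobe=r.lobe,
            centroid_x=r.centroid[0],
            centroid_y=r.centroid[1],
            centroid_z=r.centroid[2],
            area_mm2=r.area_mm2,
            source=r.source,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_LESION_COLUMNS).to_csv(path, index=False)


def read_lesion_records(path):
    from .lesion_eval import LesionRecord

    df = pd.read_csv(path)
    return [
        LesionRecord(
            subject_id=str(row.subject_id),
            lesion_id=int(row.lesion_id),
            centroid=(float(row.centroid_x), float(row.centroid_y), float(row.centroid_z)),
            area_mm2=float(row.area_mm2),
            type=None if pd.isna(row.type) else str(row.type),
            lobe=None if pd.isna(row.lobe) else str(row.lobe),
            source=str(row.source),
        )
        for row in df.itertuples()
    ]


def write_phantom_lesions(phantom: TissuePhantom, path) -> None:
    """Ground-truth lesion table (CSV) plus a sidecar JSON naming the
    coordinate convention (0-based voxel index * spacing, mm)."""
    voxvol = float(np.prod(phantom.spacing))
    rows = []
    for lid, meta in sorted(phantom.lesion_meta.items()):
        rows.append(
            dict(
                lesion_id=lid,
                type=meta.type,
                lobe=meta.lobe,
                centroid_x=meta.center_mm[0],
                centroid_y=meta.center_mm[1],
                centroid_z=meta.center_mm[2],
                volume_mm3=float((phantom.lesion_mask == lid).sum()) * voxvol,
            )
        )
    pd.DataFrame(
        rows,
        columns=["lesion_id", "type", "lobe", "centroid_x", "centroid_y", "centroid_z", "volume_mm3"],
    ).to_csv(path, index=False)
    sidecar = Path(str(path)).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "coordinate_convention": "0-based voxel index times voxel spacing, mm",
                "spacing_mm": list(phantom.spacing),
            },
            indent=2,
        )
    )
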