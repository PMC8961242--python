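"""Intensity normalization and rigid resampling onto a common grid.

The intensity chain mirrors the standard preparation for adversarial
image-to-image translation: z-score over the brain mask, divide by four,
clip to [-1, 1].  Resampling applies an externally estimated rigid (or, when
flagged, 12-dof affine) transform with cubic spline interpolation; the
transform *search* (e.g. FLIRT) is deliberately out of scope -- phantoms are
born co-registered and clinical transforms arrive as 4x4 text matrices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

__all__ = ["RigidTransform", "NormalizedVolume", "apply_transform", "normalize_intensity"]


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous transform mapping target-grid mm to source-grid mm."""

    matrix: np.ndarray
    allow_affine: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-8):
            raise ValueError("last row must be [0, 0, 0, 1]")
        if not self.allow_affine:
            r = m[:3, :3]
            if not (np.allclose(r @ r.T, np.eye(3), atol=1e-6) and np.linalg.det(r) > 0):
                raise ValueError(
                    "upper-left 3x3 block is not a proper rotation; "
                    "set allow_affine=True for 12-dof transforms"
                )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_flirt(cls, path, allow_affine: bool = True) -> "RigidTransform":
        """Read a whitespace-delimited 4x4 text matrix (FLIRT .mat dialect)."""
        return cls(np.loadtxt(path), allow_affine=allow_affine)


@dataclasses.dataclass(frozen=True)
class NormalizedVolume:
    """Volume in [-1, 1] together with the statistics that produced it."""

    data: np.ndarray
    mask: np.ndarray
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.data.min() < -1.0 or self.data.max() > 1.0:
            raise ValueError("normalized data outside [-1, 1]")


def apply_transform(
    volume: np.ndarray,
    transform: RigidTransform,
    target_shape: tuple[int, ...] | None = None,
    order: int = 3,
    source_affine: np.ndarray | None = None,
    target_affine: np.ndarray | None = None,
) -> np.ndarray:
    """Resample ``volume`` onto the target grid under a rigid/affine transform.

    The voxel-to-voxel map is ``inv(source_affine) @ transform @
    target_affine`` (affines default to identity, i.e. mm == voxel indices).
    ``order`` 0 keeps discrete value sets intact (masks stay binary); order 3
    uses cubic spline interpolation.  Out-of-field voxels become 0.
    """
    if order not in (0, 3):
        raise ValueError("interpolation order must be 0 or 3")
    volume = np.asarray(volume)
    if target_shape is None:
        target_shape = volume.shape
    src_aff = np.eye(4) if source_affine is None else np.asarray(source_affine, float)
    tgt_aff = np.eye(4) if target_affine is None else np.asarray(target_affine, float)
    if abs(np.linalg.det(transform.matrix)) < 1e-12:
        raise np.linalg.LinAlgError("singular transform matrix")
    vox_map = np.linalg.inv(src_aff) @ transform.matrix @ tgt_aff
    return ndimage.affine_transform(
        volume.astype(np.float64, copy=False),
        vox_map[:3, :3],
        offset=vox_map[:3, 3],
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=True,
    )


def normalize_intensity(volume: np.ndarray, mask: np.ndarray) -> NormalizedVolume:
    """Z-score over the mask, divide by 4, clip to [-1, 1].

    Statistics (mu, sigma) are computed over mask voxels only -- background
    air would otherwise dominate them -- but the mapping is applied to every
    voxel.  A z-score of +-4 therefore lands exactly on the clip boundary.
    """
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape differs from volume")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = volume[mask]
    mu = float(vals.mean())
    sigma = float(vals.std())
    if sigma == 0.0:
        raise ValueError("zero variance inside mask (degenerate image)")
    data = np.clip((volume - mu) / sigma / 4.0, -1.0, 1.0)
    return NormalizedVolume(data=data, mask=mask, mu=mu, sigma=sigma)
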