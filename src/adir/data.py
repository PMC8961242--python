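"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["VolumeChannelStack", "PatchPair"]


@dataclasses.dataclass
class VolumeChannelStack:
    """Ordered multichannel 3D volume: predictor channels plus optional target.

    ``predictors`` is (C, D, H, W) -- by convention T1w, PDw, T2w -- and
    ``target`` the co-registered DIR volume (D, H, W), both normalized to
    [-1, 1].  ``mask`` is the binary brain mask on the same grid.
    """

    predictors: np.ndarray
    target: np.ndarray | None
    spacing: tuple[float, float, float]
    mask: np.ndarray
    subject_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.predictors.ndim != 4:
            raise ValueError("predictors must be (C, D, H, W)")
        spatial = self.predictors.shape[1:]
        if self.mask.shape != spatial:
            raise ValueError("mask shape differs from predictor channels")
        if self.target is not None and self.target.shape != spatial:
            raise ValueError("target shape differs from predictor channels")

    @property
    def n_channels(self) -> int:
        return self.predictors.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.predictors.shape[1:]


@dataclasses.dataclass
class PatchPair:
    """Co-located predictor patch stack and target patch around one center."""

    predictors: np.ndarray  # (C, S, S, S)
    target: np.ndarray | None  # (S, S, S)
    center: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.predictors.ndim != 4:
            raise ValueError("predictors must be (C, S, S, S)")
        s = self.predictors.shape[1:]
        if len(set(s)) != 1:
            raise ValueError("patches must be cubic")
        if self.target is not None and self.target.shape != s:
            raise ValueError("target patch shape differs from predictors")

    @property
    def size(self) -> int:
        return self.predictors.shape[1]
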