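"""Patch sampling and stochastic augmentation feeding adversarial training.

Patch centers are drawn uniformly (with replacement) from brain-mask voxels.
Each extracted predictor/target pair can then be augmented with the scheme
used for the DIR synthesis network:

* mirroring along each axis independently (p = 0.5 per axis);
* a combined rotation + scaling resampled with cubic splines (p = 0.5),
  angles uniform in [-90, 90] degrees, per-axis scale in [0.8, 1.2];
* predictor-only intensity operations: per-channel gamma in [0.8, 1.5]
  (p = 0.5), additive Gaussian noise with sd 0.05 (p = 0.3), a shared-sigma
  Gaussian blur with sigma in [0.2, 1.5] (p = 0.3), and zeroing one randomly
  chosen channel (p = 0.3, teaching the network to cope with a missing
  input sequence).

Because the intensity operations disturb the [-1, 1] calibration, predictors
are re-standardized afterwards (divide by the in-patch sd, divide by 4, clip)
before entering training.  Augmentation is split into a *plan* (all random
draws) and its *application*, so the draw statistics can be audited without
touching image data.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .data import PatchPair, VolumeChannelStack

__all__ = [
    "AugmentParams",
    "AugmentPlan",
    "sample_patch_centers",
    "extract_patch",
    "draw_augment_plan",
    "apply_augment_plan",
    "augment",
    "epoch_size",
]


@dataclasses.dataclass(frozen=True)
class AugmentParams:
    """Probabilities and ranges of the augmentation scheme."""

    p_mirror_per_axis: float = 0.5
    p_rotscale: float = 0.5
    angle_range: tuple[float, float] = (-90.0, 90.0)
    scale_range: tuple[float, float] = (0.8, 1.2)
    p_gamma: float = 0.5
    gamma_range: tuple[float, float] = (0.8, 1.5)
    p_degrade: float = 0.3
    noise_sd: float = 0.05
    blur_sigma_range: tuple[float, float] = (0.2, 1.5)
    p_channel_zero: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.p_mirror_per_axis, self.p_rotscale, self.p_gamma,
                  self.p_degrade, self.p_channel_zero):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.angle_range, self.scale_range, self.gamma_range,
                       self.blur_sigma_range):
            if lo > hi:
                raise ValueError("ranges must be ordered")


@dataclasses.dataclass(frozen=True)
class AugmentPlan:
    """One realization of all augmentation draws for a single patch."""

    mirror_axes: tuple[bool, bool, bool]
    angles_deg: tuple[float, float, float] | None  # None -> no rot/scale
    scales: tuple[float, float, float] | None
    gammas: tuple[float, ...] | None  # per predictor channel
    add_noise: bool
    noise_sd: float
    noise_seed: int
    blur_sigma: float | None
    zero_channel: int | None


def sample_patch_centers(
    brain_mask: np.ndarray, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` patch centers uniformly from true voxels of ``brain_mask``."""
    if n <= 0:
        raise ValueError("n must be positive")
    mask = np.asarray(brain_mask).astype(bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("brain mask is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=True)
    return np.stack(np.unravel_index(chosen, mask.shape), axis=1)


def extract_patch(volumes: VolumeChannelStack, center: Sequence[int], size: int) -> PatchPair:
    """Cut a cubic patch spanning ``center - size//2`` to ``center + size//2``
    (half-open), zero-padding wherever the window leaves the volume."""
    if size % 2 != 0 or size < 16:
        raise ValueError("patch size must be even and at least 16")
    center = tuple(int(c) for c in center)
    spatial = volumes.spatial_shape
    lo = [c - size // 2 for c in center]
    hi = [l + size for l in lo]

    def cut(vol: np.ndarray) -> np.ndarray:
        out = np.zeros(vol.shape[:-3] + (size, size, size), dtype=vol.dtype)
        src = tuple(slice(max(l, 0), min(h, s)) for l, h, s in zip(lo, hi, spatial))
        dst = tuple(
            slice(max(-l, 0), max(-l, 0) + (min(h, s) - max(l, 0)))
            for l, h, s in zip(lo, hi, spatial)
        )
        if all(sl.stop > sl.start for sl in src):
            out[(..., *dst)] = vol[(..., *src)]
        return out

    target = cut(volumes.target) if volumes.target is not None else None
    return PatchPair(predictors=cut(volumes.predictors), target=target, center=center)


def draw_augment_plan(
    params: AugmentParams, n_channels: int, seed: int | np.random.Generator | None = None
) -> AugmentPlan:
    """Sample every stochastic choice of one augmentation in a fixed order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mirror = tuple(bool(rng.random() < params.p_mirror_per_axis) for _ in range(3))
    if rng.random() < params.p_rotscale:
        angles = tuple(float(rng.uniform(*params.angle_range)) for _ in range(3))
        scales = tuple(float(rng.uniform(*params.scale_range)) for _ in range(3))
    else:
        angles = scales = None
    if rng.random() < params.p_gamma:
        gammas = tuple(float(rng.uniform(*params.gamma_range)) for _ in range(n_channels))
    else:
        gammas = None
    add_noise = bool(rng.random() < params.p_degrade)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    blur = float(rng.uniform(*params.blur_sigma_range)) if rng.random() < params.p_degrade else None
    zero = int(rng.integers(0, n_channels)) if rng.random() < params.p_channel_zero else None
    return AugmentPlan(
        mirror_axes=mirror,
        angles_deg=angles,
        scales=scales,
        gammas=gammas,
        add_noise=add_noise,
        noise_sd=params.noise_sd,
        noise_seed=noise_seed,
        blur_sigma=blur,
        zero_channel=zero,
    )


def _rotscale_matrix(angles_deg: Sequence[float], scales: Sequence[float]) -> np.ndarray:
    """Forward spatial transform: per-axis rotations composed with scaling."""
    rots = []
    for ax, a in enumerate(angles_deg):
        c, s = math.cos(math.radians(a)), math.sin(math.radians(a))
        r = np.eye(3)
        i, j = [k for k in range(3) if k != ax]
        r[i, i], r[i, j], r[j, i], r[j, j] = c, -s, s, c
        rots.append(r)
    return rots[0] @ rots[1] @ rots[2] @ np.diag(scales)


def _resample(vol: np.ndarray, fwd: np.ndarray, order: int) -> np.ndarray:
    center = (np.asarray(vol.shape, dtype=float) - 1.0) / 2.0
    inv = np.linalg.inv(fwd)
    offset = center - inv @ center
    return ndimage.affine_transform(
        vol, inv, offset=offset, order=order, mode="constant", cval=0.0, prefilter=order > 0
    )


def apply_augment_plan(pair: PatchPair, plan: AugmentPlan) -> PatchPair:
    """Apply a drawn plan: geometry to predictors *and* target, intensity to
    predictors only, then re-standardize predictors if intensity changed."""
    pred = np.asarray(pair.predictors, dtype=np.float64).copy()
    target = None if pair.target is None else np.asarray(pair.target, dtype=np.float64).copy()

    flips = tuple(ax + 1 for ax, f in enumerate(plan.mirror_axes) if f)
    if flips:
        pred = np.flip(pred, axis=flips)
        if target is not None:
            target = np.flip(target, axis=tuple(a - 1 for a in flips))

    if plan.angles_deg is not None:
        fwd = _rotscale_matrix(plan.angles_deg, plan.scales)
        pred = np.stack([_resample(ch, fwd, order=3) for ch in pred])
        if target is not None:
            target = _resample(target, fwd, order=3)
        pred = np.clip(pred, -1.0, 1.0)
        if target is not None:
            target = np.clip(target, -1.0, 1.0)

    intensity_touched = False
    if plan.gammas is not None:
        for c, g in enumerate(plan.gammas):
            if g == 1.0:
                continue  # exponent 1 is the identity; skip so no re-scaling
            intensity_touched = True
            # gamma on signed data is undefined; remap [-1,1] -> [0,1] first
            pred[c] = np.power(np.clip((pred[c] + 1.0) / 2.0, 0.0, 1.0), g) * 2.0 - 1.0
    if plan.add_noise:
        intensity_touched = True
        noise_rng = np.random.default_rng(plan.noise_seed)
        pred = pred + noise_rng.normal(0.0, plan.noise_sd, size=pred.shape)
    if plan.blur_sigma is not None:
        intensity_touched = True
        pred = np.stack([ndimage.gaussian_filter(ch, plan.blur_sigma) for ch in pred])
    if plan.zero_channel is not None:
        intensity_touched = True
        pred[plan.zero_channel] = 0.0

    if intensity_touched:
        for c in range(pred.shape[0]):
            sd = pred[c].std()
            if sd > 0:
                pred[c] = pred[c] / sd / 4.0
        pred = np.clip(pred, -1.0, 1.0)

    return PatchPair(
        predictors=np.ascontiguousarray(pred),
        target=None if target is None else np.ascontiguousarray(target),
        center=pair.center,
    )


def augment(
    pair: PatchPair,
    params: AugmentParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> PatchPair:
    """Draw a plan from ``params`` and apply it to ``pair`` (seeded)."""
    params = params or AugmentParams()
    plan = draw_augment_plan(params, pair.predictors.shape[0], seed)
    return apply_augment_plan(pair, plan)


def epoch_size(
    brain_masks: Sequence[np.ndarray], patch_edge: int = 128, multiplier: int = 8
) -> int:
    """Samples per epoch: floor(total brain voxels / patch_edge**3) * multiplier."""
    if not brain_masks:
        raise ValueError("need at least one brain mask")
    total = sum(int(np.asarray(m).astype(bool).sum()) for m in brain_masks)
    return (total // patch_edge**3) * multiplier
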