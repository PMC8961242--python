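"""Physics-based synthetic brain phantoms with embedded cortical lesions.

A phantom is a labeled 3D volume (background / CSF / grey-matter ribbon /
white-matter core, plus lesions) built from concentric, smoothly deformed
shells.  Per-tissue relaxation parameters (T1, T2, proton density) convert
the labels into realistic sequence contrasts through closed-form steady-state
signal equations for spin-echo, inversion-recovery and double inversion
recovery (DIR) readouts.  DIR uses two inversion pulses timed to null white
matter and CSF so that only cortical grey matter (and any hyperintense
lesion) retains signal -- the contrast that makes cortical lesions visible.

Every construction is deterministic given its seed, so phantoms double as
reproducible ground truth for the synthesis network and for the lesion
detection statistics downstream.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TissueParams",
    "SequenceParams",
    "LesionMeta",
    "TissuePhantom",
    "DEFAULT_TISSUES",
    "DEFAULT_SEQUENCES",
    "LABELS",
    "LESION_TYPES",
    "LOBES",
    "make_tissue_phantom",
    "longitudinal_dir",
    "solve_nulling_times",
    "simulate_sequence",
    "lobe_map",
]

# integer label codes used in TissuePhantom.labels
LABELS = {"background": 0, "csf": 1, "gm": 2, "wm": 3, "lesion": 4}

LESION_TYPES = ("intracortical", "juxtacortical", "mixed")
LOBES = ("frontal", "temporal", "parietal", "occipital")

# Cortical lesion type frequencies used when no explicit types are requested;
# intracortical lesions dominate in MS cohorts, mixed lesions are rare.
_TYPE_WEIGHTS = (0.72, 0.21, 0.07)


@dataclasses.dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue class.

    Parameters
    ----------
    name : tissue label (``WM``/``GM``/``CSF``/``lesion``/``background``).
    t1 : longitudinal relaxation time, ms.
    t2 : transverse relaxation time, ms (``t2 <= t1``).
    pd : proton density, arbitrary units in [0, 1].
    """

    name: str
    t1: float
    t2: float
    pd: float

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValueError("relaxation times must be positive")
        if self.t2 > self.t1:
            raise ValueError(f"{self.name}: t2 ({self.t2}) exceeds t1 ({self.t1})")
        if not 0.0 <= self.pd <= 1.0:
            raise ValueError("proton density must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SequenceParams:
    """Acquisition timing of one MR sequence (all times in ms).

    ``kind`` selects the signal equation: ``spin_echo`` (TR/TE),
    ``inversion_recovery`` (TR/TE/TI) or ``double_inversion_recovery``
    (TR/TE/TI1/TI2, with the first inversion at t=0, the second at t=TI1 and
    excitation at t=TI1+TI2).
    """

    kind: str
    tr: float
    te: float
    ti: float | None = None
    ti1: float | None = None
    ti2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("spin_echo", "inversion_recovery", "double_inversion_recovery"):
            raise ValueError(f"unknown sequence kind: {self.kind!r}")
        for v in (self.tr, self.te, self.ti, self.ti1, self.ti2):
            if v is not None and v <= 0:
                raise ValueError("sequence times must be positive")
        if self.kind == "inversion_recovery" and self.ti is None:
            raise ValueError("inversion_recovery requires ti")
        if self.kind == "double_inversion_recovery":
            if self.ti1 is None or self.ti2 is None:
                raise ValueError("double_inversion_recovery requires ti1 and ti2")
            if self.ti1 + self.ti2 >= self.tr:
                raise ValueError("DIR requires ti1 + ti2 < tr")


# Literature-typical 1.5 T relaxation values.  MS lesions are modelled with
# prolonged T1/T2 and slightly raised proton density relative to grey matter,
# which is what renders them hyperintense on DIR.
DEFAULT_TISSUES: Mapping[int, TissueParams] = {
    LABELS["background"]: TissueParams("background", t1=1.0, t2=1.0, pd=0.0),
    LABELS["csf"]: TissueParams("CSF", t1=4000.0, t2=2000.0, pd=1.0),
    LABELS["gm"]: TissueParams("GM", t1=950.0, t2=100.0, pd=0.85),
    LABELS["wm"]: TissueParams("WM", t1=600.0, t2=80.0, pd=0.7),
    LABELS["lesion"]: TissueParams("lesion", t1=1100.0, t2=120.0, pd=0.9),
}

# Acquisition timing of the emulated 1.5 T protocol: MPRAGE-like T1w,
# dual-echo TSE PD/T2, and a DIR at TR/TE = 6500/355 ms.  A DIR protocol
# chooses its two inversion delays to null white matter and CSF for the
# tissue T1s at hand; for the default table (WM 600 ms, CSF 4000 ms) the
# exact delays are the solve_nulling_times(600, 4000, 6500) root below
# (under the first-inversion-at-t0 convention: TI1 between the inversions,
# TI2 from second inversion to excitation).  They sit close to the
# interpreted acquisition pair (2350/350 ms); the residual magnetization of
# both nulled tissues is < 1e-12.
_DIR_TI1, _DIR_TI2 = 2349.381546794779, 403.8226807174598

DEFAULT_SEQUENCES: Mapping[str, SequenceParams] = {
    "t1w": SequenceParams("inversion_recovery", tr=2700.0, te=5.03, ti=950.0),
    "pdw": SequenceParams("spin_echo", tr=3130.0, te=24.0),
    "t2w": SequenceParams("spin_echo", tr=3130.0, te=85.0),
    "dir": SequenceParams(
        "double_inversion_recovery", tr=6500.0, te=355.0, ti1=_DIR_TI1, ti2=_DIR_TI2
    ),
}


@dataclasses.dataclass(frozen=True)
class LesionMeta:
    """Ground-truth annotation of one planted lesion."""

    lesion_id: int
    type: str
    lobe: str
    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclasses.dataclass
class TissuePhantom:
    """Labeled tissue volume plus lesion annotations and relaxation table."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    tissue_table: Mapping[int, TissueParams]
    lesion_mask: np.ndarray
    lesion_meta: dict[int, LesionMeta]
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.shape != self.lesion_mask.shape:
            raise ValueError("labels and lesion_mask shapes differ")
        if self.labels.shape != self.brain_mask.shape:
            raise ValueError("labels and brain_mask shapes differ")
        ids = set(np.unique(self.lesion_mask[self.lesion_mask > 0]).tolist())
        if ids - set(self.lesion_meta):
            raise ValueError("lesion ids missing from lesion_meta")
        if np.any(self.lesion_mask.astype(bool) & ~self.brain_mask.astype(bool)):
            raise ValueError("lesion voxels outside brain mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def gm_mask(self, include_lesions: bool = False) -> np.ndarray:
        m = self.labels == LABELS["gm"]
        if include_lesions:
            m = m | (self.labels == LABELS["lesion"])
        return m


# ---------------------------------------------------------------------------
# signal equations


def longitudinal_dir(t1: float, ti1: float, ti2: float, tr: float):
    """Longitudinal magnetization fraction at excitation for a DIR preparation.

    Two adiabatic inversions: the first at t=0, the second at t=ti1, with
    excitation at t=ti1+ti2.  Full relaxation between repetitions is not
    assumed; the ``exp(-tr/t1)`` term carries the steady-state correction.
    Returns ``1 - 2*exp(-ti2/t1) + 2*exp(-(ti1+ti2)/t1) - exp(-tr/t1)``,
    which is signed: nulled tissues cross zero.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0) or ti1 <= 0 or ti2 <= 0 or tr <= 0:
        raise ValueError("all times must be positive")
    out = (
        1.0
        - 2.0 * np.exp(-ti2 / t1)
        + 2.0 * np.exp(-(ti1 + ti2) / t1)
        - np.exp(-tr / t1)
    )
    return out if out.ndim else float(out)


def solve_nulling_times(t1_a: float, t1_b: float, tr: float) -> tuple[float, float]:
    """Inversion delays (ti1, ti2) that simultaneously null two tissues.

    Solves ``longitudinal_dir(t1_a) = longitudinal_dir(t1_b) = 0`` by nested
    bracketing: for a trial ti2 the unique ti1 nulling tissue *a* follows by
    1D root-finding (the magnetization is strictly decreasing in ti1), and a
    scan over ti2 brackets the zero of tissue *b*'s residual.  Residuals of
    the returned pair are below 1e-8.
    """
    if t1_a == t1_b:
        raise ValueError("tissues must have distinct t1 to be jointly nulled")
    if tr <= 1.05 * max(t1_a, t1_b):
        raise ValueError("tr must exceed both t1 values by a margin")

    def ti1_for(t1: float, ti2: float) -> float | None:
        # f(ti1) = 1 - 2 exp(-ti2/t1) + 2 exp(-(ti1+ti2)/t1) - exp(-tr/t1)
        # decreases from 1 - exp(-tr/t1) > 0 as ti1 grows; root exists iff
        # the ti1 -> tr - ti2 endpoint is negative.
        hi = tr - ti2 - 1e-9
        if hi <= 1e-9:
            return None
        f = lambda ti1: longitudinal_dir(t1, ti1, ti2, tr)
        if f(hi) > 0:
            return None
        return brentq(f, 1e-9, hi, xtol=1e-12, rtol=8.9e-16)

    def residual(ti2: float) -> float | None:
        ti1 = ti1_for(t1_a, ti2)
        if ti1 is None:
            return None
        return longitudinal_dir(t1_b, ti1, ti2, tr)

    # ti2 can at most reach t1_a * ln(2/(1+exp(-tr/t1_a))); scan below it.
    cap = t1_a * np.log(2.0 / (1.0 + np.exp(-tr / t1_a)))
    grid = np.linspace(cap * 1e-3, cap * 0.999, 512)
    vals = [residual(x) for x in grid]
    bracket = None
    for (x0, v0), (x1, v1) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if v0 is None or v1 is None:
            continue
        if v0 == 0.0:
            bracket = (x0, x0)
            break
        if v0 * v1 < 0:
            bracket = (x0, x1)
            break
    if bracket is None:
        raise ValueError("no nulling solution in (0, tr) for the given tissues")
    ti2 = bracket[0] if bracket[0] == bracket[1] else brentq(
        lambda x: residual(x), bracket[0], bracket[1], xtol=1e-12, rtol=8.9e-16
    )
    ti1 = ti1_for(t1_a, ti2)
    assert ti1 is not None and ti1 + ti2 < tr
    if abs(longitudinal_dir(t1_a, ti1, ti2, tr)) > 1e-8 or abs(
        longitudinal_dir(t1_b, ti1, ti2, tr)
    ) > 1e-8:
        raise ValueError("root finding failed to reach the 1e-8 tolerance")
    return float(ti1), float(ti2)


def _signal_equation(params: TissueParams, seq: SequenceParams) -> float:
    t1, t2, pd = params.t1, params.t2, params.pd
    if seq.kind == "spin_echo":
        return pd * (1.0 - np.exp(-seq.tr / t1)) * np.exp(-seq.te / t2)
    if seq.kind == "inversion_recovery":
        e = 1.0 - 2.0 * np.exp(-seq.ti / t1) + np.exp(-seq.tr / t1)
        return pd * abs(e) * np.exp(-seq.te / t2)
    if seq.kind == "double_inversion_recovery":
        e = longitudinal_dir(t1, seq.ti1, seq.ti2, seq.tr)
        return pd * abs(e) * np.exp(-seq.te / t2)
    raise ValueError(f"unknown sequence kind: {seq.kind!r}")


def simulate_sequence(
    phantom: TissuePhantom,
    seq: SequenceParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate one acquisition of the phantom as a 3D intensity volume.

    The magnitude signal of each tissue class follows the closed-form
    steady-state equation of ``seq.kind``; background voxels carry no signal.
    ``noise_sd`` is expressed as a fraction of the mean grey-matter signal and
    added as zero-mean Gaussian noise everywhere (background included).
    """
    labels = phantom.labels
    missing = set(np.unique(labels).tolist()) - set(phantom.tissue_table)
    if missing:
        raise ValueError(f"labels without tissue parameters: {sorted(missing)}")

    lut = np.zeros(max(phantom.tissue_table) + 1, dtype=np.float64)
    for code, params in phantom.tissue_table.items():
        if params.name.lower() == "background":
            lut[code] = 0.0
        else:
            lut[code] = _signal_equation(params, seq)
    vol = lut[labels]

    if noise_sd:
        gm = phantom.gm_mask()
        ref = float(vol[gm].mean()) if gm.any() else float(vol[phantom.brain_mask.astype(bool)].mean())
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd * ref, size=vol.shape)
    return vol


# ---------------------------------------------------------------------------
# phantom construction


def _shell_modulation(rng: np.random.Generator):
    """Smooth angular modulation of the shell radii (one function per phantom)."""
    a1, a2 = rng.uniform(0.02, 0.06, size=2)
    p1, p2 = rng.uniform(0.0, 2.0 * np.pi, size=2)

    def mod(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return 1.0 + a1 * np.cos(2.0 * theta + p1) + a2 * np.sin(theta) * np.cos(3.0 * phi + p2)

    return mod


def _lobe_of(phi: float) -> str:
    """Deterministic four-sector angular parcellation (azimuth quadrants)."""
    idx = int(np.floor((phi + np.pi) / (np.pi / 2.0))) % 4
    return ("occipital", "temporal", "frontal", "parietal")[idx]


def make_tissue_phantom(
    shape: Sequence[int] = (64, 64, 64),
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    n_lesions: int = 8,
    lesion_radius_range: tuple[float, float] = (1.0, 2.5),
    seed: int | None = None,
    lesion_types: Sequence[str] | None = None,
    tissue_table: Mapping[int, TissueParams] = DEFAULT_TISSUES,
) -> TissuePhantom:
    """Build a deformed-shell brain phantom with planted cortical lesions.

    The anatomy is background > CSF shell > grey-matter ribbon > white-matter
    core, with every shell boundary modulated by one smooth random angular
    function so that phantoms differ in shape across seeds.  Lesions are
    spheres placed relative to the grey-matter ribbon according to their
    type: ``intracortical`` entirely inside the ribbon, ``juxtacortical`` in
    white matter touching the ribbon, ``mixed`` straddling the WM/GM
    boundary.  Lobes come from a fixed four-sector azimuthal parcellation.
    """
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    if min(shape) < 32:
        raise ValueError("shape must be at least 32 voxels per axis")
    if n_lesions < 0:
        raise ValueError("n_lesions must be non-negative")
    r_lo, r_hi = map(float, lesion_radius_range)
    if not 0 < r_lo <= r_hi:
        raise ValueError("lesion_radius_range must be ordered and positive")
    if lesion_types is not None:
        if len(lesion_types) != n_lesions:
            raise ValueError("lesion_types length must equal n_lesions")
        for t in lesion_types:
            if t not in LESION_TYPES:
                raise ValueError(f"unknown lesion type {t!r}")

    rng = np.random.default_rng(seed)
    mod = _shell_modulation(rng)

    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0 * np.asarray(spacing)
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    dx, dy, dz = (g - c for g, c in zip(grids, center))
    rho = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(rho > 0, dz / np.maximum(rho, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(dy, dx)

    half = min(n * s for n, s in zip(shape, spacing)) / 2.0
    r_brain, r_gm_out, r_gm_in = 0.88 * half, 0.80 * half, 0.62 * half

    m = mod(theta, phi)
    rr = rho / m  # effective radius in the undeformed frame
    labels = np.zeros(shape, dtype=np.int16)
    labels[rr <= r_brain] = LABELS["csf"]
    labels[rr <= r_gm_out] = LABELS["gm"]
    labels[rr <= r_gm_in] = LABELS["wm"]
    brain_mask = (rr <= r_brain).astype(np.uint8)

    lesion_mask = np.zeros(shape, dtype=np.int32)
    lesion_meta: dict[int, LesionMeta] = {}
    ribbon = r_gm_out - r_gm_in  # undeformed ribbon thickness, mm

    positions: list[tuple[np.ndarray, float]] = []
    for i in range(n_lesions):
        lid = i + 1
        ltype = (
            lesion_types[i]
            if lesion_types is not None
            else rng.choice(LESION_TYPES, p=_TYPE_WEIGHTS)
        )
        radius = float(rng.uniform(r_lo, r_hi))
        if ltype == "intracortical":
            # shell modulation can thin the ribbon by up to ~12%
            fit_max = 0.5 * ribbon * 0.88
            if r_lo > fit_max:
                raise ValueError(
                    f"intracortical lesion radius >= {r_lo:.2f} mm exceeds the "
                    f"grey-matter ribbon thickness ({ribbon:.2f} mm)"
                )
            radius = min(radius, fit_max)
        placed = False
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            th = float(np.arccos(np.clip(u[2], -1, 1)))
            ph = float(np.arctan2(u[1], u[0]))
            mm = float(mod(np.array(th), np.array(ph)))
            if ltype == "intracortical":
                lo, hi = (r_gm_in * mm) + radius, (r_gm_out * mm) - radius
                if hi <= lo:
                    continue
                rc = float(rng.uniform(lo, hi))
            elif ltype == "juxtacortical":
                rc = r_gm_in * mm - radius
                if rc <= radius:
                    continue
            else:  # mixed
                rc = r_gm_in * mm
            c = center + u * rc
            if all(np.linalg.norm(c - pc) > radius + pr + 1.0 for pc, pr in positions):
                placed = True
                break
        if not placed and ltype == "intracortical":
            raise ValueError("could not place intracortical lesion inside the ribbon")
        sphere = (grids[0] - c[0]) ** 2 + (grids[1] - c[1]) ** 2 + (grids[2] - c[2]) ** 2 <= radius**2
        sphere &= brain_mask.astype(bool)
        if not sphere.any():
            # radius below voxel size at an off-grid center: keep the center voxel
            idx = tuple(int(round(ci / si)) for ci, si in zip(c, spacing))
            idx = tuple(np.clip(idx, 0, np.asarray(shape) - 1))
            if not brain_mask[idx]:
                continue
            sphere = np.zeros(shape, dtype=bool)
            sphere[idx] = True
        labels[sphere] = LABELS["lesion"]
        lesion_mask[sphere] = lid
        lesion_meta[lid] = LesionMeta(
            lesion_id=lid,
            type=str(ltype),
            lobe=_lobe_of(ph),
            center_mm=tuple(float(x) for x in c),
            radius_mm=radius,
        )
        positions.append((c, radius))

    # drop ids that were fully overwritten by later lesions
    live = set(np.unique(lesion_mask[lesion_mask > 0]).tolist())
    lesion_meta = {k: v for k, v in lesion_meta.items() if k in live}

    return TissuePhantom(
        labels=labels,
        spacing=spacing,
        tissue_table=dict(tissue_table),
        lesion_mask=lesion_mask,
        lesion_meta=lesion_meta,
        brain_mask=brain_mask,
    )


def lobe_map(phantom: TissuePhantom) -> np.ndarray:
    """Per-voxel lobe code (1..4 following LOBES order, 0 outside the brain).

    Uses the same azimuthal four-sector parcellation as lesion placement, so
    detected components can be assigned lobes consistently with the planted
    ground truth.
    """
    shape = phantom.shape
    spacing = phantom.spacing
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0 * np.asarray(spacing)
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    phi = np.arctan2(grids[1] - center[1], grids[0] - center[0])
    sector = (np.floor((phi + np.pi) / (np.pi / 2.0)).astype(int)) % 4
    names = ("occipital", "temporal", "frontal", "parietal")
    codes = np.array([LOBES.index(n) + 1 for n in names])
    out = codes[sector].astype(np.int16)
    out[~phantom.brain_mask.astype(bool)] = 0
    return out
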