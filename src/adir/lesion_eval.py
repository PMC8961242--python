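"""Lesion-level agreement statistics between two detection sets.

Given lesion records from an artificial (aDIR) and a conventional (cDIR)
reading of the same subjects, this module matches lesions by centroid
proximity, derives precision/recall with cDIR as reference, computes the
intraclass correlation of per-subject lesion counts (two-way mixed model,
absolute agreement, single measure) with its F test and 95% confidence
interval, and tabulates counts by lobe and lesion type in the
both-detected / aDIR-only / cDIR-only layout.

An automated detector (`detect_candidates`) stands in for the human rater:
it finds connected components hyperintense relative to normal-appearing
grey matter whose largest axial cross-section reaches the minimum area.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

log = logging.getLogger(__name__)

__all__ = [
    "LESION_TYPES",
    "LOBES",
    "LesionRecord",
    "MatchResult",
    "IccResult",
    "PrecisionRecall",
    "detect_candidates",
    "match_lesions",
    "precision_recall",
    "icc_two_way_mixed_absolute",
    "tabulate_lesions",
]

LESION_TYPES = ("intracortical", "juxtacortical", "mixed")
LOBES = ("frontal", "temporal", "parietal", "occipital")


@dataclasses.dataclass(frozen=True)
class LesionRecord:
    """One detected lesion."""

    subject_id: str
    lesion_id: int
    centroid: tuple[float, float, float]  # mm
    area_mm2: float  # largest axial cross-section
    type: str | None = None
    lobe: str | None = None
    source: str = "aDIR"

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("lesion area must be positive")
        if self.type is not None and self.type not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {self.type!r}")
        if self.lobe is not None and self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r}")


@dataclasses.dataclass
class MatchResult:
    """One-to-one matching between aDIR and cDIR records of one subject."""

    subject_id: str
    pairs: list[tuple[LesionRecord, LesionRecord]]
    tp: int
    fp: int
    fn: int


@dataclasses.dataclass(frozen=True)
class IccResult:
    """Single-measure absolute-agreement intraclass correlation."""

    icc: float
    ci_low: float
    ci_high: float
    f_stat: float
    p_value: float
    n: int
    k: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.icc <= 1.0:
            raise ValueError("icc out of [-1, 1]")


@dataclasses.dataclass(frozen=True)
class PrecisionRecall:
    per_subject: pd.DataFrame  # columns: subject_id, tp, fp, fn, precision, recall
    pooled_precision: float
    pooled_recall: float
    mean_precision: float
    sd_precision: float
    mean_recall: float
    sd_recall: float


# ---------------------------------------------------------------------------


def detect_candidates(
    dir_volume: np.ndarray,
    gm_mask: np.ndarray,
    spacing: Sequence[float],
    z_thresh: float = 3.0,
    min_area_mm2: float = 3.0,
    subject_id: str = "",
    source: str = "aDIR",
    lobe_map: np.ndarray | None = None,
) -> list[LesionRecord]:
    """Automated lesion candidates: GM-relative hyperintense components.

    Voxels exceeding ``mean + z_thresh * sd`` of the grey-matter intensity
    are grouped into 26-connected components; a component is kept if it
    overlaps the (1-voxel-dilated) grey-matter mask and its largest axial
    (in-plane, axes 0-1) cross-section reaches ``min_area_mm2``.  Type is
    inferred from the GM-overlap fraction (all inside -> intracortical, none
    -> juxtacortical, partial -> mixed); lobes come from an optional lobe
    code map (1..4 in LOBES order).
    """
    gm = np.asarray(gm_mask).astype(bool)
    if not gm.any():
        raise ValueError("grey-matter mask is empty")
    vol = np.asarray(dir_volume, dtype=np.float64)
    mu, sd = float(vol[gm].mean()), float(vol[gm].std())
    thr = mu + z_thresh * sd
    labels, n = ndimage.label(vol > thr, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return []
    gm_near = ndimage.binary_dilation(gm, structure=np.ones((3, 3, 3), dtype=bool))
    spacing = tuple(float(s) for s in spacing)
    pix_area = spacing[0] * spacing[1]
    records: list[LesionRecord] = []
    for comp in range(1, n + 1):
        mask = labels == comp
        if not (mask & gm_near).any():
            continue
        per_slice = mask.sum(axis=(0, 1))
        area = float(per_slice.max()) * pix_area
        if area < min_area_mm2:
            continue
        coords = np.argwhere(mask)
        centroid = tuple(float(c) for c in coords.mean(axis=0) * np.asarray(spacing))
        frac = float((mask & gm).sum()) / float(mask.sum())
        ltype = "intracortical" if frac >= 1.0 else ("juxtacortical" if frac == 0.0 else "mixed")
        lobe = None
        if lobe_map is not None:
            codes = np.asarray(lobe_map)[mask]
            codes = codes[codes > 0]
            if codes.size:
                lobe = LOBES[int(np.bincount(codes).argmax()) - 1]
        records.append(
            LesionRecord(
                subject_id=subject_id,
                lesion_id=len(records) + 1,
                centroid=centroid,
                area_mm2=area,
                type=ltype,
                lobe=lobe,
                source=source,
            )
        )
    return records


def match_lesions(
    a_records: Sequence[LesionRecord],
    c_records: Sequence[LesionRecord],
    tol_mm: float = 5.0,
) -> MatchResult:
    """Greedy one-to-one matching on ascending centroid distance.

    Candidate pairs within ``tol_mm`` are accepted closest-first; leftover
    aDIR records count as false positives, leftover cDIR as false negatives.
    """
    subjects = {r.subject_id for r in itertools.chain(a_records, c_records)}
    if len(subjects) > 1:
        raise ValueError(f"records from multiple subjects: {sorted(subjects)}")
    subject = subjects.pop() if subjects else ""
    dists = []
    for i, a in enumerate(a_records):
        for j, c in enumerate(c_records):
            d = float(np.linalg.norm(np.subtract(a.centroid, c.centroid)))
            if d <= tol_mm:
                dists.append((d, i, j))
    dists.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_c: set[int] = set()
    pairs: list[tuple[LesionRecord, LesionRecord]] = []
    for d, i, j in dists:
        if i in used_a or j in used_c:
            continue
        used_a.add(i)
        used_c.add(j)
        pairs.append((a_records[i], c_records[j]))
    tp = len(pairs)
    return MatchResult(
        subject_id=subject,
        pairs=pairs,
        tp=tp,
        fp=len(a_records) - tp,
        fn=len(c_records) - tp,
    )


def precision_recall(matches: Sequence[MatchResult]) -> PrecisionRecall:
    """Per-subject and pooled precision/recall with cDIR as reference.

    Pooled values come from summed counts; subject means exclude subjects
    with a zero denominator (logged).
    """
    if not matches:
        raise ValueError("need at least one subject")
    rows = []
    for m in matches:
        prec = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else np.nan
        rec = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else np.nan
        if np.isnan(prec):
            log.info("subject %s excluded from mean precision (no aDIR detections)", m.subject_id)
        if np.isnan(rec):
            log.info("subject %s excluded from mean recall (no cDIR detections)", m.subject_id)
        rows.append(dict(subject_id=m.subject_id, tp=m.tp, fp=m.fp, fn=m.fn,
                         precision=prec, recall=rec))
    df = pd.DataFrame(rows)
    tp, fp, fn = int(df.tp.sum()), int(df.fp.sum()), int(df.fn.sum())
    if tp + fp == 0 and tp + fn == 0:
        raise ValueError("no detections on either modality in any subject")
    pooled_p = tp / (tp + fp) if (tp + fp) else np.nan
    pooled_r = tp / (tp + fn) if (tp + fn) else np.nan
    return PrecisionRecall(
        per_subject=df,
        pooled_precision=float(pooled_p),
        pooled_recall=float(pooled_r),
        mean_precision=float(df.precision.mean()),
        sd_precision=float(df.precision.std(ddof=1)) if df.precision.notna().sum() > 1 else 0.0,
        mean_recall=float(df.recall.mean()),
        sd_recall=float(df.recall.std(ddof=1)) if df.recall.notna().sum() > 1 else 0.0,
    )


def icc_two_way_mixed_absolute(counts: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(A,1): two-way mixed model, absolute agreement, single measure.

    From the two-way ANOVA mean squares of the n-subjects x k-methods matrix:
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``, with the F test
    ``MSR/MSE`` on (n-1, (n-1)(k-1)) degrees of freedom and the F-based
    confidence bounds with Satterthwaite degrees of freedom.
    """
    x = np.asarray(counts, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("counts must be a 2D subjects x methods matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 methods")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance; ICC undefined")
    rowm = x.mean(axis=1, keepdims=True)
    colm = x.mean(axis=0, keepdims=True)
    msr = k * float(((rowm - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((colm - grand) ** 2).sum()) / (k - 1)
    mse = float(((x - rowm - colm + grand) ** 2).sum()) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom > 0 else 0.0
    icc = float(np.clip(icc, -1.0, 1.0))

    if mse == 0.0:
        # perfect within-subject agreement
        f = np.inf
        p = 0.0
        lo, hi = icc, icc
    else:
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        p = float(stats.f.sf(f, df1, df2))
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isfinite(a):
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den
            f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
            f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
            lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        else:
            lo = hi = icc
    lo, hi = float(np.clip(lo, -1.0, icc)), float(np.clip(hi, icc, 1.0))
    return IccResult(icc=icc, ci_low=lo, ci_high=hi, f_stat=float(f), p_value=p, n=n, k=k)


def _require_labels(rec: LesionRecord) -> tuple[str, str]:
    if rec.lobe not in LOBES:
        raise ValueError(f"record {rec.subject_id}/{rec.lesion_id}: unknown lobe {rec.lobe!r}")
    if rec.type not in LESION_TYPES:
        raise ValueError(f"record {rec.subject_id}/{rec.lesion_id}: unknown type {rec.type!r}")
    return rec.lobe, rec.type


def tabulate_lesions(
    a_records: Sequence[LesionRecord],
    c_records: Sequence[LesionRecord],
    matches: Sequence[MatchResult] | MatchResult,
) -> pd.DataFrame:
    """Lobe/type contingency table: both-detected, aDIR-only, cDIR-only.

    Matched pairs take lobe and type from their cDIR member.  Percentages
    are of each column total, rounded to 1 decimal.  Row ``n`` holds the
    column totals (equal to tp / fp / fn of the matching).
    """
    if isinstance(matches, MatchResult):
        matches = [matches]
    matched_a = {(a.subject_id, a.lesion_id) for m in matches for a, _ in m.pairs}
    matched_c = {(c.subject_id, c.lesion_id) for m in matches for _, c in m.pairs}

    groups = {
        "both": [_require_labels(c) for m in matches for _, c in m.pairs],
        "adir_only": [
            _require_labels(r) for r in a_records if (r.subject_id, r.lesion_id) not in matched_a
        ],
        "cdir_only": [
            _require_labels(r) for r in c_records if (r.subject_id, r.lesion_id) not in matched_c
        ],
    }

    rows = ["n", *LOBES, *LESION_TYPES]
    cols = pd.MultiIndex.from_product([groups.keys(), ("count", "pct")])
    df = pd.DataFrame(0.0, index=rows, columns=cols)
    for col, labels in groups.items():
        total = len(labels)
        df.loc["n", (col, "count")] = total
        df.loc["n", (col, "pct")] = 100.0
        for lobe in LOBES:
            c = sum(1 for lo, _ in labels if lo == lobe)
            df.loc[lobe, (col, "count")] = c
            df.loc[lobe, (col, "pct")] = round(100.0 * c / total, 1) if total else 0.0
        for t in LESION_TYPES:
            c = sum(1 for _, ty in labels if ty == t)
            df.loc[t, (col, "count")] = c
            df.loc[t, (col, "pct")] = round(100.0 * c / total, 1) if total else 0.0
    return df
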