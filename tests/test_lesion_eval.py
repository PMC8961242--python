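"""Lesion matching, precision/recall, ICC and the lobe/type table."""

import itertools

import numpy as np
import pytest

from adir import lesion_eval as le


def _rec(subject="s1", lid=1, centroid=(0.0, 0.0, 0.0), area=5.0,
         type="intracortical", lobe="frontal", source="aDIR"):
    return le.LesionRecord(subject_id=subject, lesion_id=lid, centroid=centroid,
                           area_mm2=area, type=type, lobe=lobe, source=source)


class TestDetectCandidates:
    def test_uniform_gm_yields_nothing(self, rng):
        vol = np.zeros((24, 24, 24))
        gm = np.zeros(vol.shape, bool)
        gm[8:16, 8:16, 8:16] = True
        vol[gm] = 1.0
        vol += rng.normal(0, 1e-6, vol.shape)
        assert le.detect_candidates(vol, gm, (1, 1, 1)) == []

    def test_single_bright_blob_detected(self):
        vol = np.zeros((24, 24, 24))
        gm = np.zeros(vol.shape, bool)
        gm[4:20, 4:20, 4:20] = True
        vol[gm] = 1.0
        vol[np.ix_(range(4, 20), range(4, 20), range(4, 20))] += np.random.default_rng(0).normal(
            0, 0.01, (16, 16, 16))
        # blob: one slice of >= 5 voxels at 1 mm spacing -> 5 mm^2 axial area
        vol[10:11, 10:15, 12] = 3.0
        recs = le.detect_candidates(vol, gm, (1, 1, 1), z_thresh=3.0, min_area_mm2=3.0,
                                    subject_id="s1")
        assert len(recs) == 1
        assert recs[0].area_mm2 >= 5.0
        assert recs[0].type in le.LESION_TYPES

    def test_small_axial_section_rejected(self):
        vol = np.zeros((24, 24, 24))
        gm = np.zeros(vol.shape, bool)
        gm[4:20, 4:20, 4:20] = True
        vol[gm] = 1.0
        vol += np.random.default_rng(1).normal(0, 0.01, vol.shape)
        # 2 voxels per axial slice, stacked through-plane: area 2 mm^2 < 3 mm^2
        vol[10:12, 10, 8:14] = 3.0
        recs = le.detect_candidates(vol, gm, (1, 1, 1), z_thresh=3.0, min_area_mm2=3.0)
        assert recs == []

    def test_area_uses_in_plane_spacing(self):
        vol = np.zeros((24, 24, 24))
        gm = np.zeros(vol.shape, bool)
        gm[4:20, 4:20, 4:20] = True
        vol[gm] = 1.0
        vol += np.random.default_rng(2).normal(0, 0.01, vol.shape)
        vol[10:12, 10, 10] = 3.0  # 2 voxels in one axial slice
        # at 1.3 x 1.3 mm in-plane, 2 voxels = 3.38 mm^2 >= 3
        recs = le.detect_candidates(vol, gm, (1.3, 1.3, 3.0), z_thresh=3.0)
        assert len(recs) == 1
        assert recs[0].area_mm2 == pytest.approx(2 * 1.3 * 1.3)


class TestMatchLesions:
    def test_identical_sets(self):
        a = [_rec(lid=i, centroid=(i * 10.0, 0, 0)) for i in range(4)]
        c = [_rec(lid=i, centroid=(i * 10.0, 0, 0), source="cDIR") for i in range(4)]
        m = le.match_lesions(a, c, tol_mm=5.0)
        assert (m.tp, m.fp, m.fn) == (4, 0, 0)

    def test_disjoint_sets(self):
        a = [_rec(lid=1, centroid=(0, 0, 0))]
        c = [_rec(lid=1, centroid=(100, 0, 0), source="cDIR"),
             _rec(lid=2, centroid=(0, 100, 0), source="cDIR")]
        m = le.match_lesions(a, c, tol_mm=5.0)
        assert (m.tp, m.fp, m.fn) == (0, 1, 2)

    def test_mixed_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            le.match_lesions([_rec(subject="s1")], [_rec(subject="s2", source="cDIR")])

    def test_counts_are_conserved(self):
        rng = np.random.default_rng(3)
        a = [_rec(lid=i, centroid=tuple(rng.uniform(0, 30, 3))) for i in range(7)]
        c = [_rec(lid=i, centroid=tuple(rng.uniform(0, 30, 3)), source="cDIR") for i in range(5)]
        m = le.match_lesions(a, c, tol_mm=8.0)
        assert m.tp + m.fp == 7 and m.tp + m.fn == 5
        matched_a = {id(p[0]) for p in m.pairs}
        matched_c = {id(p[1]) for p in m.pairs}
        assert len(matched_a) == len(matched_c) == m.tp  # one-to-one

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_assignment(self, seed):
        """On lesion-like instances (inter-lesion separation well above the
        matching radius) greedy matching attains the exhaustive optimum."""
        rng = np.random.default_rng(seed)
        tol = 5.0
        # cDIR lesions on a coarse jittered grid, >= 3*tol apart
        sites = np.array([[i * 18.0, j * 18.0, 0.0] for i in range(3) for j in range(2)])
        sites += rng.uniform(-1, 1, sites.shape)
        nc = int(rng.integers(2, 6))
        c = [_rec(lid=i, centroid=tuple(sites[i]), source="cDIR") for i in range(nc)]
        # aDIR: perturbed copies of a subset plus distant false positives
        a = []
        for i in range(nc):
            if rng.random() < 0.8:
                a.append(_rec(lid=i, centroid=tuple(sites[i] + rng.uniform(-3, 3, 3))))
        for j in range(int(rng.integers(0, 3))):
            a.append(_rec(lid=100 + j, centroid=tuple(rng.uniform(40, 80, 3))))
        m = le.match_lesions(a, c, tol_mm=tol)
        na = len(a)

        def dist(i, j):
            return float(np.linalg.norm(np.subtract(a[i].centroid, c[j].centroid)))

        best_tp = 0
        for k in range(min(na, nc), -1, -1):
            found = False
            for a_idx in itertools.permutations(range(na), k):
                for c_idx in itertools.permutations(range(nc), k):
                    if all(dist(i, j) <= tol for i, j in zip(a_idx, c_idx)):
                        found = True
                        break
                if found:
                    break
            if found:
                best_tp = k
                break
        assert m.tp == best_tp


class TestPrecisionRecall:
    def test_reference_prospective_counts(self):
        """Pooled precision/recall from the reference contingency counts."""
        m = le.MatchResult(subject_id="pooled", pairs=[], tp=528, fp=98, fn=168)
        pr = le.precision_recall([m])
        assert round(pr.pooled_precision, 2) == 0.84
        assert round(pr.pooled_recall, 2) == 0.76

    def test_degenerate_subject(self):
        m = le.MatchResult(subject_id="s", pairs=[], tp=0, fp=0, fn=5)
        pr = le.precision_recall([m])
        assert pr.pooled_recall == 0.0
        assert np.isnan(pr.per_subject.precision.iloc[0])

    def test_pooled_invariant_to_subject_order(self):
        ms = [le.MatchResult(f"s{i}", [], tp=t, fp=f, fn=n)
              for i, (t, f, n) in enumerate([(10, 2, 3), (5, 5, 0), (8, 1, 9)])]
        pr1 = le.precision_recall(ms)
        pr2 = le.precision_recall(ms[::-1])
        assert pr1.pooled_precision == pr2.pooled_precision
        assert pr1.pooled_recall == pr2.pooled_recall

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            le.precision_recall([le.MatchResult("s", [], tp=0, fp=0, fn=0)])


def _icc_bruteforce(x):
    """Direct two-way ANOVA decomposition, written independently."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ssr = sum((x[i].mean() - grand) ** 2 for i in range(n)) * k
    ssc = sum((x[:, j].mean() - grand) ** 2 for j in range(k)) * n
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIcc:
    def test_duplicated_column_gives_one(self):
        x = np.array([[1, 1], [4, 4], [9, 9], [2, 2]], float)
        res = le.icc_two_way_mixed_absolute(x)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_low == res.ci_high == 1.0

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, size=(200, 2))
        res = le.icc_two_way_mixed_absolute(x)
        se = 1.0 / np.sqrt(200 - 2)
        assert abs(res.icc) < 3 * se

    def test_matches_bruteforce_decomposition(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            x = rng.integers(0, 40, size=(6, 2)).astype(float)
            if np.allclose(x, x.mean()):
                continue
            res = le.icc_two_way_mixed_absolute(x)
            assert res.icc == pytest.approx(np.clip(_icc_bruteforce(x), -1, 1), abs=1e-10)

    def test_matches_pingouin(self):
        """Independent cross-check: pingouin's ICC2 (A,1) row."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        subj = rng.poisson(30, size=15)
        x = np.stack([subj + rng.poisson(3, 15), subj + rng.poisson(3, 15)], axis=1).astype(float)
        res = le.icc_two_way_mixed_absolute(x)
        df = pd.DataFrame(
            {"targets": np.repeat(np.arange(15), 2), "raters": np.tile([0, 1], 15),
             "scores": x.ravel()})
        out = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="scores").set_index("Type")
        icc2 = out.loc["ICC(A,1)"] if "ICC(A,1)" in out.index else out.loc["ICC2"]
        assert res.icc == pytest.approx(float(icc2["ICC"]), abs=1e-8)
        lo, hi = icc2["CI95"] if "CI95" in icc2 else icc2["CI95%"]
        assert res.ci_low == pytest.approx(lo, abs=0.02)
        assert res.ci_high == pytest.approx(hi, abs=0.02)
        assert res.f_stat == pytest.approx(float(icc2["F"]), rel=1e-6)

    def test_invariances(self):
        x = np.array([[3, 5], [8, 7], [1, 2], [9, 12], [4, 4]], float)
        base = le.icc_two_way_mixed_absolute(x).icc
        perm = le.icc_two_way_mixed_absolute(x[[3, 1, 4, 0, 2]]).icc
        assert perm == pytest.approx(base, abs=1e-12)
        shifted = le.icc_two_way_mixed_absolute(x + 7.0).icc
        assert shifted == pytest.approx(base, abs=1e-12)
        one_col = x.copy()
        one_col[:, 1] += 6.0  # systematic disagreement lowers absolute agreement
        assert le.icc_two_way_mixed_absolute(one_col).icc < base

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            le.icc_two_way_mixed_absolute(np.full((5, 2), 3.0))
        with pytest.raises(ValueError):
            le.icc_two_way_mixed_absolute(np.zeros((2, 2)))


class TestTabulate:
    def test_empty_inputs(self):
        table = le.tabulate_lesions([], [], [])
        assert (table.xs("count", axis=1, level=1).to_numpy() == 0).all()

    def test_unknown_label_rejected(self):
        bad = _rec(lobe=None)
        with pytest.raises(ValueError, match="lobe"):
            le.tabulate_lesions([bad], [], [le.MatchResult("s1", [], 0, 1, 0)])

    def test_conservation_and_cdir_labels(self):
        # matched pair with conflicting labels: the cDIR member's win
        a1 = _rec(lid=1, type="juxtacortical", lobe="parietal")
        c1 = _rec(lid=1, type="intracortical", lobe="frontal", source="cDIR")
        a2 = _rec(lid=2, type="mixed", lobe="occipital")
        c2 = _rec(lid=2, type="juxtacortical", lobe="temporal", source="cDIR")
        m = le.MatchResult("s1", [(a1, c1)], tp=1, fp=1, fn=1)
        table = le.tabulate_lesions([a1, a2], [c1, c2], m)
        assert table.loc["n", ("both", "count")] == m.tp
        assert table.loc["n", ("adir_only", "count")] == m.fp
        assert table.loc["n", ("cdir_only", "count")] == m.fn
        assert table.loc["frontal", ("both", "count")] == 1
        assert table.loc["intracortical", ("both", "count")] == 1
        assert table.loc["occipital", ("adir_only", "count")] == 1
        assert table.loc["temporal", ("cdir_only", "count")] == 1

    def test_reported_table_percentages(self):
        """Rebuild the reference lobe/type margins and check the percentages."""
        both_lobe = {"frontal": 245, "temporal": 181, "parietal": 97, "occipital": 5}
        both_type = {"intracortical": 393, "juxtacortical": 103, "mixed": 32}
        a_only_lobe = {"frontal": 42, "temporal": 34, "parietal": 20, "occipital": 2}
        a_only_type = {"intracortical": 81, "juxtacortical": 10, "mixed": 7}
        c_only_lobe = {"frontal": 80, "temporal": 60, "parietal": 22, "occipital": 6}
        c_only_type = {"intracortical": 121, "juxtacortical": 36, "mixed": 11}

        def build(lobes, types, source, start=0):
            lobe_seq = [l for l, n in lobes.items() for _ in range(n)]
            type_seq = [t for t, n in types.items() for _ in range(n)]
            return [
                _rec(lid=start + i, type=t, lobe=l, source=source)
                for i, (l, t) in enumerate(zip(lobe_seq, type_seq))
            ]

        both_a = build(both_lobe, both_type, "aDIR")
        both_c = build(both_lobe, both_type, "cDIR")
        a_only = build(a_only_lobe, a_only_type, "aDIR", start=1000)
        c_only = build(c_only_lobe, c_only_type, "cDIR", start=2000)
        m = le.MatchResult("s1", list(zip(both_a, both_c)), tp=528, fp=98, fn=168)
        table = le.tabulate_lesions(both_a + a_only, both_c + c_only, m)

        assert table.loc["frontal", ("both", "pct")] == 46.4
        assert table.loc["temporal", ("both", "pct")] == 34.3
        assert table.loc["parietal", ("both", "pct")] == 18.4
        assert table.loc["occipital", ("both", "pct")] == 0.9
        assert table.loc["intracortical", ("both", "pct")] == 74.4
        assert table.loc["juxtacortical", ("both", "pct")] == 19.5
        assert table.loc["mixed", ("both", "pct")] == 6.1
        assert table.loc["frontal", ("adir_only", "pct")] == 42.9
        assert table.loc["intracortical", ("adir_only", "pct")] == 82.7
        assert table.loc["frontal", ("cdir_only", "pct")] == 47.6
        assert table.loc["intracortical", ("cdir_only", "pct")] == 72.0
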