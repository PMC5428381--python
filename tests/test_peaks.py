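"""Peak processing: normalization arithmetic, IS QC, detection filter,
adduct annotation ppm logic, redundant-peak merging, cross-dataset
matching — each against a hand-computed or brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

import lifelipid as ll
from lifelipid.peaks import PRIMARY_ADDUCTS
from conftest import make_table


def _raw_table(values, is_col, **kw):
    """Raw-scale table whose first column is the internal standard."""
    vals = np.column_stack([is_col, values])
    n, m = vals.shape
    t = make_table(vals, peak_ids=["IS"] + [f"p{j}" for j in range(m - 1)],
                   log_scale=False, **kw)
    return t


class TestNormalization:
    def test_log_ratio_arithmetic(self):
        """intensity 1000 over IS 100 gives log(10)."""
        t = _raw_table(np.full((3, 1), 1000.0), np.full(3, 100.0))
        norm, dropped = ll.normalize_by_internal_standard(t, "IS")
        assert dropped == []
        assert np.allclose(norm.values.to_numpy(), np.log(10.0))
        assert "IS" not in norm.peak_ids

    def test_constant_is_is_a_constant_shift(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 1e5, size=(4, 6))
        t = _raw_table(x, np.full(4, 250.0))
        norm, _ = ll.normalize_by_internal_standard(t, "IS")
        assert np.allclose(norm.values.to_numpy(), np.log(x) - np.log(250.0))

    def test_five_sample_fixture_matches_hand_computation(self):
        """Spreadsheet-style recomputation of the log ratios."""
        x = np.array([[200.0, 30.0], [400.0, 80.0], [100.0, 10.0],
                      [900.0, 90.0], [50.0, 25.0]])
        is_lv = np.array([20.0, 40.0, 10.0, 90.0, 50.0])
        t = _raw_table(x, is_lv)
        norm, _ = ll.normalize_by_internal_standard(t, "IS")
        expected = np.log(x / is_lv[:, None])
        assert np.allclose(norm.values.to_numpy(), expected)

    def test_missing_is_flags_sample_for_removal(self):
        det = np.ones((3, 2), dtype=bool)
        det[1, 0] = False  # IS undetected in sample 1
        t = _raw_table(np.full((3, 1), 10.0), np.full(3, 5.0), detected=det)
        norm, dropped = ll.normalize_by_internal_standard(t, "IS")
        assert dropped == ["s1"]
        assert norm.n_samples == 2


class TestQC:
    def test_sample_at_mean_retained_and_outlier_removed(self):
        """One sample placed > 2.5 SD from the single-pass mean is the only
        removal (oracle: direct z-score)."""
        rng = np.random.default_rng(0)
        base = 100.0 + rng.normal(0, 2.0, size=19)
        is_levels = pd.Series(np.append(base, 200.0),
                              index=[f"s{i}" for i in range(20)])
        z = (is_levels - is_levels.mean()) / is_levels.std(ddof=1)
        assert (z.abs() > 2.5).sum() == 1
        keep = ll.qc_filter_samples(is_levels)  # default k_sd = 2.5
        assert set(is_levels.index) - set(keep) == {"s19"}

    def test_single_pass_mean(self):
        """Mean/SD are not re-estimated after removal: a second, milder
        outlier survives because the first one inflated the SD."""
        vals = pd.Series([10.0, 10, 10, 10, 10, 12.0, 40.0])
        keep = ll.qc_filter_samples(vals, k_sd=1.5)
        assert 5 in keep  # the 12.0 sample stays
        assert 6 not in keep

    def test_all_dropped_is_an_error(self):
        with pytest.raises(ValueError):
            ll.qc_filter_samples(pd.Series([1.0, 100.0]), k_sd=2.5)
        # also needs >= 3 samples
        with pytest.raises(ValueError):
            ll.qc_filter_samples(pd.Series([1.0, 1.0]))


class TestDetectionFilter:
    def _cohort_table(self, det):
        coh = ll.generate_cohort(
            n_species_per_clade={"rodent": 2, "primate": 2, "bat": 2},
            n_long={"rodent": 1, "primate": 1, "bat": 1},
            n_individuals=5, tissues=("liver",), seed=1)
        t = make_table(np.ones(det.shape), sample_ids=list(coh.samples.index),
                       detected=det)
        return coh, t

    def test_everywhere_detected_is_retained(self):
        coh, t = self._cohort_table(np.ones((30, 1), dtype=bool))
        assert ll.detection_filter(t, coh) == ["p0"]

    def test_three_of_five_in_one_species_is_retained(self):
        det = np.zeros((30, 1), dtype=bool)
        det[:3, 0] = True  # 3/5 individuals of the first species
        coh, t = self._cohort_table(det)
        assert ll.detection_filter(t, coh) == ["p0"]

    def test_two_of_five_everywhere_is_removed(self):
        det = np.zeros((30, 1), dtype=bool)
        det[::5, 0] = True
        det[1::5, 0] = True  # 2/5 in every species
        coh, t = self._cohort_table(det)
        assert ll.detection_filter(t, coh) == []


def _ref(rows):
    return pd.DataFrame(rows).set_index("compound_id")


class TestAnnotation:
    def _simple_ref(self, mass=500.0 - 1.007276):
        return _ref([{
            "compound_id": "C1", "monoisotopic_mass": mass,
            "lipid_class": "Sphingolipids", "sub_class": "Ceramides",
            "pathway": "Sphingolipid metabolism", "n_double_bonds": 2,
            "adducts": "[M+H]+:1.007276:pos;[M+Na]+:22.989218:pos",
        }])

    def test_exact_mass_matches_at_zero_ppm(self):
        t = make_table(np.ones((3, 1)), mz=[500.0], log_scale=True)
        ann = ll.annotate_adducts(t, self._simple_ref())
        assert len(ann) == 1 and ann["ppm"].iloc[0] < 1e-9
        assert ann["adduct"].iloc[0] == "[M+H]+"

    @pytest.mark.parametrize("obs,matched", [(500.0049, True), (500.0051, False)])
    def test_ppm_boundary(self, obs, matched):
        """9.8 ppm is inside the 10 ppm window, 10.2 ppm is outside."""
        t = make_table(np.ones((3, 1)), mz=[obs], log_scale=True)
        ann = ll.annotate_adducts(t, self._simple_ref())
        ppm = abs(obs - 500.0) / 500.0 * 1e6
        assert (ppm <= 10) == matched
        assert (len(ann) == 1) == matched

    def test_five_ppm_matches_are_a_subset_of_ten(self, small_lipidome):
        tables, reference, _ = small_lipidome
        t = tables["liver"]
        a5 = ll.annotate_adducts(t, reference, tol_ppm=5.0)
        a10 = ll.annotate_adducts(t, reference, tol_ppm=10.0)
        key = lambda df: set(zip(df["peak_id"], df["compound_id"], df["adduct"]))
        assert key(a5) <= key(a10)

    def test_mode_respected(self):
        t = make_table(np.ones((3, 1)), mz=[500.0], mode=["neg"], log_scale=True)
        ann = ll.annotate_adducts(t, self._simple_ref())  # pos-only adducts
        assert len(ann) == 0

    def test_ppm_is_scale_invariant(self):
        """Global m/z scaling within the tolerance arithmetic: scaling both
        observed and expected masses preserves the match set."""
        for scale in (1.0, 2.0):
            ref = self._simple_ref(mass=(500.0 - 1.007276) * scale
                                   + 1.007276 * (scale - 1) * 0)  # mass scaled
            ref["monoisotopic_mass"] = (500.0 - 1.007276) * scale
            obs = (500.0 - 1.007276) * scale + 1.007276
            obs *= 1 + 8e-6  # 8 ppm off
            t = make_table(np.ones((3, 1)), mz=[obs], log_scale=True)
            ann = ll.annotate_adducts(t, ref)
            assert len(ann) == 1

    def test_empty_reference_raises(self):
        t = make_table(np.ones((3, 1)), mz=[500.0], log_scale=True)
        with pytest.raises(ValueError):
            ll.annotate_adducts(t, self._simple_ref().iloc[:0])

    def test_primary_pass_before_rare_and_ambiguity_flag(self):
        ref = _ref([
            {"compound_id": "C1", "monoisotopic_mass": 498.992724,
             "lipid_class": "A", "sub_class": "a", "pathway": "p",
             "n_double_bonds": 0, "adducts": "[M+H]+:1.007276:pos"},
            {"compound_id": "C2", "monoisotopic_mass": 477.010782,
             "lipid_class": "B", "sub_class": "b", "pathway": "p",
             "n_double_bonds": 0, "adducts": "[M+Na]+:22.989218:pos"},
        ])
        t = make_table(np.ones((3, 1)), mz=[500.0], log_scale=True)
        ann = ll.annotate_adducts(t, ref)
        assert set(ann["compound_id"]) == {"C1", "C2"}
        assert ann["ambiguous"].all()
        assert list(ann["stage"]) == ["primary", "rare"]


class TestMerge:
    def _dup_table(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        vals = np.column_stack([x, x + 0.01, rng.normal(size=10)])
        t = make_table(vals, mz=[500.0, 500.001, 700.0], rt=[5.0, 5.01, 9.0],
                       compound_id=["C1", "C1", "C2"])
        ann = pd.DataFrame({
            "peak_id": ["p0", "p1", "p2"],
            "compound_id": ["C1", "C1", "C2"],
        })
        return t, ann

    def test_duplicate_pair_becomes_mean_composite(self):
        t, ann = self._dup_table()
        merged, comp = ll.merge_peaks(t, ann)
        assert merged.n_peaks == 2
        assert comp.loc["p0", "n_members"] == 2
        expected = (t.values["p0"] + t.values["p1"]) / 2.0
        assert np.allclose(merged.values["p0"], expected)

    def test_rt_window_prevents_merge(self):
        t, ann = self._dup_table()
        t.peak_meta.loc["p1", "rt"] = 5.2  # ΔRT 0.2 min >= 0.05
        merged, _ = ll.merge_peaks(t, ann)
        assert merged.n_peaks == 3

    def test_low_correlation_prevents_merge(self):
        t, ann = self._dup_table()
        rng = np.random.default_rng(5)
        t.values["p1"] = rng.normal(size=10)  # decorrelate
        merged, _ = ll.merge_peaks(t, ann)
        assert merged.n_peaks == 3

    def test_six_peak_fixture_matches_brute_force_closure(self):
        """Component structure equals the transitive closure of the pairwise
        rule, computed here by an independent hand-rolled union-find."""
        rng = np.random.default_rng(8)
        base = rng.normal(size=20)
        vals = np.column_stack([
            base, base + 0.01, base + 0.02,          # chain p0-p1-p2 (C1)
            rng.normal(size=20), rng.normal(size=20),  # p3, p4 (C2, uncorrelated)
            base * -1.0,                              # p5 (C3, alone)
        ])
        rt = [5.0, 5.01, 5.02, 7.0, 7.01, 9.0]
        comp = ["C1", "C1", "C1", "C2", "C2", "C3"]
        t = make_table(vals, rt=rt, compound_id=comp)
        ann = pd.DataFrame({"peak_id": [f"p{j}" for j in range(6)],
                            "compound_id": comp})
        merged, composites = ll.merge_peaks(t, ann)

        # oracle: pairwise rule + union-find
        parent = list(range(6))
        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i
        for i in range(6):
            for j in range(i + 1, 6):
                same = comp[i] == comp[j]
                close = abs(rt[i] - rt[j]) < 0.05
                r = np.corrcoef(vals[:, i], vals[:, j])[0, 1]
                if same and close and r > 0.7:
                    parent[find(j)] = find(i)
        groups = {}
        for i in range(6):
            groups.setdefault(find(i), set()).add(f"p{i}")
        expected = {frozenset(g) for g in groups.values()}
        got = {frozenset(m.split(";")) for m in composites["members"]}
        assert got == expected
        assert {frozenset({"p0", "p1", "p2"})} <= expected

    def test_member_counts_sum_to_premerge_width(self, processed_liver):
        merged, composites = processed_liver
        # composites frame from the fixture's merge covers every output peak
        assert composites["n_members"].sum() >= merged.n_peaks

    def test_merge_never_increases_columns(self, small_cohort, small_lipidome):
        tables, reference, _ = small_lipidome
        norm, _ = ll.normalize_by_internal_standard(tables["liver"], "IS_PC34_0")
        ann = ll.annotate_adducts(norm, reference)
        merged, composites = ll.merge_peaks(norm, ann)
        assert merged.n_peaks <= norm.n_peaks
        assert composites["n_members"].sum() == norm.n_peaks

    def test_too_few_shared_samples_gives_no_edge(self):
        t, ann = self._dup_table()
        det = np.ones((10, 3), dtype=bool)
        det[2:, 1] = False  # only 2 shared detected samples for p0/p1
        t2 = make_table(t.values.to_numpy(), mz=list(t.peak_meta["mz"]),
                        rt=list(t.peak_meta["rt"]),
                        compound_id=["C1", "C1", "C2"], detected=det)
        merged, _ = ll.merge_peaks(t2, ann)
        assert merged.n_peaks == 3


class TestCrossDatasetMatch:
    def _meta(self, mz, rt, mode=None):
        m = len(mz)
        return pd.DataFrame({"mz": mz, "rt": rt,
                             "mode": mode or ["pos"] * m},
                            index=[f"q{j}" for j in range(m)])

    def test_identical_peaks_match(self):
        a = self._meta([500.0, 600.0], [5.0, 6.0])
        b = self._meta([500.0, 600.0], [5.0, 6.0])
        pairs = ll.match_across_datasets(a, b)
        assert len(pairs) == 2

    def test_rt_apart_by_0p2_sec_not_matched(self):
        """Within 9 ppm but 0.2 s apart in RT fails the 0.1 s cutoff."""
        a = self._meta([500.0], [5.0])
        b = self._meta([500.0 * (1 + 9e-6)], [5.0 + 0.2 / 60.0])
        assert len(ll.match_across_datasets(a, b)) == 0
        # and passes once RT is within tolerance
        b2 = self._meta([500.0 * (1 + 9e-6)], [5.0 + 0.05 / 60.0])
        assert len(ll.match_across_datasets(a, b2)) == 1

    def test_one_to_one_by_nearest_mz(self):
        a = self._meta([500.0], [5.0])
        b = self._meta([500.0 * (1 + 5e-6), 500.0 * (1 + 2e-6)], [5.0, 5.0])
        pairs = ll.match_across_datasets(a, b)
        assert list(pairs["peak_b"]) == ["q1"]  # nearer in m/z

    def test_mode_mismatch_blocks_match(self):
        a = self._meta([500.0], [5.0], mode=["pos"])
        b = self._meta([500.0], [5.0], mode=["neg"])
        assert len(ll.match_across_datasets(a, b)) == 0
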