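import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mediatornet.cohort import SubgroupKey
from mediatornet.signatures import (CutoffSet, ZMatrix, classify_ratio,
                                    compute_zscores, covid_hc_ratio,
                                    derive_cutoffs, display_ratio,
                                    signature_heatmap, signature_proportions)
from mediatornet.simulate import generate_cohort, paperlike_config

from conftest import make_cohort


def zmatrix_from(values, groups, trimesters, analytes=("IL-6", "TNF-α")):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = [f"s{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=ids, columns=list(analytes))
    meta = pd.DataFrame({"subject_id": ids, "group": groups,
                         "trimester": trimesters}, index=ids)
    return ZMatrix(values=frame, meta=meta, reference="manual", transform="raw")


class TestZScores:
    def test_mean_case_is_zero(self, rng):
        data = rng.lognormal(size=(3, 27))
        data[:, 0] = [1.0, 2.0, 3.0]
        z = compute_zscores(make_cohort({("HC", 1): data}))
        assert z.values.iloc[1, 0] == pytest.approx(0.0)

    def test_shift_invariance(self, rng):
        data = rng.lognormal(size=(8, 27))
        z1 = compute_zscores(make_cohort({("HC", 1): data}))
        z2 = compute_zscores(make_cohort({("HC", 1): data + 7.5}))
        pd.testing.assert_frame_equal(z1.values, z2.values)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 1e4])
    def test_scale_invariance_per_analyte(self, rng, scale):
        data = rng.lognormal(size=(10, 27))
        scaled = data.copy()
        scaled[:, 5] *= scale
        z1 = compute_zscores(make_cohort({("HC", 1): data}))
        z2 = compute_zscores(make_cohort({("HC", 1): scaled}))
        pd.testing.assert_frame_equal(z1.values, z2.values)

    def test_right_skew_makes_median_z_negative(self, rng):
        data = rng.lognormal(sigma=1.0, size=(200, 27))
        z = compute_zscores(make_cohort({("HC", 1): data}))
        assert (z.values.median() < 0).all()

    def test_zero_sd_errors(self, rng):
        data = rng.lognormal(size=(5, 27))
        data[:, 3] = 2.0
        with pytest.raises(ValueError, match="zero reference standard deviation"):
            compute_zscores(make_cohort({("HC", 1): data}))

    def test_log10_transform_masks_nonpositive(self, rng):
        data = rng.lognormal(size=(5, 27))
        data[0, 0] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            z = compute_zscores(make_cohort({("HC", 1): data}), transform="log10")
        assert np.isnan(z.values.iloc[0, 0])


class TestCutoffs:
    def test_odd_count_median(self):
        z = zmatrix_from([[-1, -1], [0, 0], [2, 2]], ["HC"] * 3, [1, 2, 3])
        cuts = derive_cutoffs(z, mode="global_HC")
        assert cuts.values["IL-6"] == pytest.approx(0.0)

    def test_even_count_median(self):
        z = zmatrix_from([[0, 0], [1, 1]], ["HC"] * 2, [1, 2])
        cuts = derive_cutoffs(z, mode="global_HC")
        assert cuts.values["IL-6"] == pytest.approx(0.5)

    def test_trimester_mode_uses_only_that_trimester(self):
        z = zmatrix_from([[0, 0], [10, 10], [20, 20]], ["HC"] * 3, [1, 2, 2])
        cuts = derive_cutoffs(z, mode="trimester_HC", trimester=2)
        assert cuts.values["IL-6"] == pytest.approx(15.0)

    def test_sort_based_median_oracle_on_synthetic_cohort(self):
        cohort = generate_cohort(paperlike_config(seed=3))
        z = compute_zscores(cohort)
        cuts = derive_cutoffs(z, mode="global_HC")
        assert len(cuts.values) == 27
        hc_rows = z.subgroup_rows(SubgroupKey("HC", "ALL"))
        for analyte, cutoff in cuts.values.items():
            vals = sorted(z.values.loc[hc_rows, analyte].dropna())
            n = len(vals)
            oracle = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
            assert cutoff == pytest.approx(oracle)

    def test_covid_only_reference_errors(self):
        z = zmatrix_from([[0, 0]], ["COVID"], [1])
        with pytest.raises(ValueError, match="no HC samples"):
            derive_cutoffs(z, mode="global_HC")


class TestProportions:
    def test_saturation(self):
        z = zmatrix_from([[1, 1], [2, 2]], ["COVID"] * 2, [1, 1])
        cuts = CutoffSet(values={"IL-6": 0.0, "TNF-α": 0.0}, mode="manual")
        prof = signature_proportions(z, cuts, SubgroupKey("COVID", 1))
        assert (prof.table["proportion_above"] == 100.0).all()
        assert (prof.table["category"] == "increased").all()

    def test_boundary_equality_is_unaltered(self):
        z = zmatrix_from([[1, 1], [1, 1], [-1, -1], [-1, -1]],
                         ["COVID"] * 4, [1] * 4)
        cuts = CutoffSet(values={"IL-6": 0.0, "TNF-α": 0.0}, mode="manual")
        prof = signature_proportions(z, cuts, SubgroupKey("COVID", 1))
        assert (prof.table["proportion_above"] == 50.0).all()
        assert (prof.table["category"] == "unaltered").all()

    def test_brute_force_subject_loop_oracle(self, rng):
        cohort = make_cohort({("HC", 1): rng.lognormal(size=(13, 27)),
                              ("COVID", 1): rng.lognormal(size=(9, 27))})
        z = compute_zscores(cohort)
        cuts = derive_cutoffs(z, mode="global_HC")
        key = SubgroupKey("COVID", 1)
        prof = signature_proportions(z, cuts, key)
        rows = z.subgroup_rows(key)
        for analyte in z.values.columns:
            above = n_eval = 0
            for rid in rows:
                v = z.values.loc[rid, analyte]
                if not np.isnan(v):
                    n_eval += 1
                    above += v > cuts.values[analyte]
            assert prof.table.loc[analyte, "proportion_above"] == \
                pytest.approx(100.0 * above / n_eval)

    def test_all_missing_analyte_flagged(self):
        z = zmatrix_from([[np.nan, 1], [np.nan, 2]], ["HC"] * 2, [1, 1])
        cuts = CutoffSet(values={"IL-6": 0.0, "TNF-α": 0.0}, mode="manual")
        prof = signature_proportions(z, cuts, SubgroupKey("HC", 1))
        assert np.isnan(prof.table.loc["IL-6", "proportion_above"])
        assert prof.table.loc["IL-6", "category"] == "not_evaluable"
        assert prof.table.loc["IL-6", "n_evaluated"] == 0


class TestRatios:
    def make_profiles(self, pc, ph):
        analytes = ["IL-6", "TNF-α"]
        z_cv = zmatrix_from([[0, 0]], ["COVID"], [1], analytes)
        z_hc = zmatrix_from([[0, 0]], ["HC"], [1], analytes)
        cuts = CutoffSet(values={a: 0.0 for a in analytes}, mode="manual")
        prof_cv = signature_proportions(z_cv, cuts, SubgroupKey("COVID", 1))
        prof_hc = signature_proportions(z_hc, cuts, SubgroupKey("HC", 1))
        prof_cv.table["proportion_above"] = pc
        prof_hc.table["proportion_above"] = ph
        return prof_cv, prof_hc

    @pytest.mark.parametrize("ratio,display,cls", [
        (15.2, 15.0, "increased"),   # e.g. a 15x late-trimester growth factor
        (1.0, 1.0, "unaltered"),
        (0.3, 0.3, "decreased"),
        (0.34, 0.3, "decreased"),
        (0.35, 0.4, "unaltered"),
        (2.4, 2.0, "unaltered"),
        (2.5, 3.0, "increased"),
        (3.0, 3.0, "increased"),
    ])
    def test_display_rounding_and_bins(self, ratio, display, cls):
        assert display_ratio(ratio) == pytest.approx(display)
        assert classify_ratio(display_ratio(ratio)) == cls

    def test_ratio_profile_end_to_end(self):
        prof_cv, prof_hc = self.make_profiles(76.0, 5.0)
        ratios = covid_hc_ratio(prof_cv, prof_hc)
        assert ratios.table.loc["IL-6", "display_ratio"] == 15.0
        assert ratios.table.loc["IL-6", "class"] == "increased"

    def test_zero_hc_not_evaluable(self):
        prof_cv, prof_hc = self.make_profiles(40.0, 0.0)
        ratios = covid_hc_ratio(prof_cv, prof_hc)
        assert ratios.table.loc["IL-6", "class"] == "not_evaluable"

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_classification_total_and_consistent_with_display(self, ratio):
        disp = display_ratio(ratio)
        cls = classify_ratio(disp)
        assert cls in {"decreased", "unaltered", "increased"}
        assert (cls == "decreased") == (disp <= 0.3)
        assert (cls == "increased") == (disp >= 3)
        # display rounding: one decimal below 1, integer otherwise
        if ratio < 1:
            assert abs(disp - ratio) <= 0.05 + 1e-9
        else:
            assert disp == float(int(disp)) and abs(disp - ratio) <= 0.5

    def test_trimester_mismatch_errors(self):
        prof_cv, _ = self.make_profiles(40.0, 10.0)
        z_hc = zmatrix_from([[0, 0]], ["HC"], [2])
        cuts = CutoffSet(values={"IL-6": 0.0, "TNF-α": 0.0}, mode="manual")
        prof_hc2 = signature_proportions(z_hc, cuts, SubgroupKey("HC", 2))
        with pytest.raises(ValueError, match="trimester mismatch"):
            covid_hc_ratio(prof_cv, prof_hc2)


class TestHeatmap:
    def test_uniform_half_is_unaltered(self):
        z = zmatrix_from([[1, 1], [-1, -1]], ["HC"] * 2, [1, 1])
        cuts = CutoffSet(values={"IL-6": 0.0, "TNF-α": 0.0}, mode="manual")
        prof = signature_proportions(z, cuts, SubgroupKey("HC", 1))
        matrix = signature_heatmap([prof])
        assert (matrix["HC_t1"] == 50.0).all()
        assert (prof.table["category"] == "unaltered").all()

    def test_missing_row_stays_missing(self):
        z = zmatrix_from([[np.nan, 1], [np.nan, 0]], ["HC"] * 2, [1, 1])
        cuts = CutoffSet(values={"IL-6": 0.0, "TNF-α": 0.0}, mode="manual")
        prof = signature_proportions(z, cuts, SubgroupKey("HC", 1))
        matrix = signature_heatmap([prof])
        assert np.isnan(matrix.loc["IL-6", "HC_t1"])

    def test_paperlike_proinflammatory_trend_increased_in_covid_t3(
            self, paperlike_cohort):
        z = compute_zscores(paperlike_cohort)
        cuts = derive_cutoffs(z, mode="global_HC")
        prof = signature_proportions(z, cuts, SubgroupKey("COVID", 3))
        proc = paperlike_cohort.panel.members("PROc")
        increased = (prof.table.loc[list(proc), "category"] == "increased").sum()
        assert increased >= 5  # pro-inflammatory rows trend increased
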