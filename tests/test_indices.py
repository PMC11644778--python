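"""Index arithmetic, classification scales, and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_matrix
from mossrisk.indices import (
    CF_SCALE,
    ERI_SCALE,
    PERI_SCALE,
    assess_sites,
    classify_cf,
    classify_eri,
    classify_peri,
    classify_pli,
    contamination_factor,
    ecological_risk_index,
    peri,
    pollution_load_index,
    reports_to_frame,
)
from mossrisk.registry import DEFAULT_TRF, PLI_ELEMENTS
from mossrisk.survey import BackgroundTable, ToxicResponseTable

cf_values = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestContaminationFactor:
    def test_peak_mercury_over_background(self):
        assert contamination_factor(0.113, 0.033) == pytest.approx(3.4242, abs=1e-4)

    def test_identity_at_background(self):
        assert contamination_factor(5.0, 5.0) == 1.0

    def test_peak_lead_classifies_severe(self):
        cf = contamination_factor(42.32, 3.21)
        assert cf == pytest.approx(13.183, abs=0.001)
        assert classify_cf(cf) == "Severe"

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            contamination_factor(0.0, 1.0)
        with pytest.raises(ValueError):
            contamination_factor(1.0, 0.0)


class TestClassifications:
    @pytest.mark.parametrize(
        "cf, label",
        [
            (0.5, "No Contamination"),
            (1.0, "Suspected"),
            (2.0, "Slight"),
            (3.5, "Moderate"),  # left-closed boundary convention
            (13.18, "Severe"),
            (27.0, "Extreme"),
        ],
    )
    def test_cf_scale(self, cf, label):
        assert classify_cf(cf) == label

    @pytest.mark.parametrize(
        "pli, label",
        [
            (0.4, "no pollution"),
            (1.2, "minimal to moderate"),
            (2.22, "moderate"),
            (2.97, "moderate"),
            (3.06, "moderate to severe"),
            (3.21, "moderate to severe"),
            (9.5, "extremely high"),  # capped at class 6
        ],
    )
    def test_pli_scale(self, pli, label):
        assert classify_pli(pli) == label

    @pytest.mark.parametrize(
        "value, label",
        [
            (39.999, "low"),
            (40.0, "medium"),
            (89.0, "significant"),
            (99.0, "significant"),
            (112.0, "significant"),
            (125.0, "significant"),
            (160.0, "high"),
            (320.0, "extreme"),
        ],
    )
    def test_peri_scale(self, value, label):
        assert classify_peri(value) == label

    @pytest.mark.parametrize(
        "value, label",
        [
            (149.9, "low"),
            (150.0, "moderate"),
            (150.5, "moderate"),
            (254.7, "moderate"),
            (300.0, "moderate"),  # inclusive upper bound
            (600.0, "considerable"),  # inclusive upper bound
            (600.1, "high"),
        ],
    )
    def test_eri_scale(self, value, label):
        assert classify_eri(value) == label

    @pytest.mark.parametrize("scale", [CF_SCALE, PERI_SCALE, ERI_SCALE])
    def test_scales_are_monotone_step_functions(self, scale):
        grid = np.concatenate(
            [np.linspace(0, 700, 1401), [b for _, b, _, _ in scale.intervals[:-1]]]
        )
        labels = list(scale.labels)
        indices = [labels.index(scale.classify(v)) for v in sorted(grid)]
        assert indices == sorted(indices)


class TestPLI:
    def test_geometric_mean_identity_equal_cfs(self):
        cf = {e: 2.0 for e in PLI_ELEMENTS}
        assert pollution_load_index(cf) == pytest.approx(2.0)

    def test_ninth_root_of_product(self):
        cf = dict(zip(PLI_ELEMENTS, [512.0] + [1.0] * 8))
        assert pollution_load_index(cf) == pytest.approx(2.0)  # 512 = 2^9

    def test_missing_element_named_in_error(self):
        cf = {e: 1.0 for e in PLI_ELEMENTS if e != "Cd"}
        with pytest.raises(KeyError, match="Cd"):
            pollution_load_index(cf)

    @given(st.lists(cf_values, min_size=9, max_size=9))
    def test_permutation_symmetry_and_geometric_bound(self, values):
        cf = dict(zip(PLI_ELEMENTS, values))
        pli = pollution_load_index(cf)
        rotated = dict(zip(PLI_ELEMENTS, values[1:] + values[:1]))
        assert pollution_load_index(rotated) == pytest.approx(pli, rel=1e-9)
        assert min(values) * (1 - 1e-9) <= pli <= max(values) * (1 + 1e-9)


class TestPERIandERI:
    def test_mercury_worked_example(self):
        assert peri(3.4242, 40) == pytest.approx(136.97, abs=0.01)
        assert classify_peri(peri(3.4242, 40)) == "significant"

    def test_unit_cf_and_zero_cf(self):
        assert peri(1.0, 30) == 30.0
        assert peri(0.0, 40) == 0.0

    def test_eri_is_the_sum(self):
        assert ecological_risk_index({"Cd": 30.0, "Hg": 40.0}) == 70.0

    def test_eri_at_unit_cf_equals_trf_total(self):
        values = {e: peri(1.0, t) for e, t in DEFAULT_TRF.items()}
        assert ecological_risk_index(values) == 91.0  # 1+1+2+2+5+5+5+30+40

    def test_eri_with_unit_trfs_reduces_to_cf_sum(self):
        cf = {"Cd": 1.3, "Pb": 2.1, "Zn": 0.7}
        values = {e: peri(v, 1.0) for e, v in cf.items()}
        assert ecological_risk_index(values) == pytest.approx(sum(cf.values()))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ecological_risk_index({})


class TestAssessSites:
    def test_background_replicated_matrix_gives_all_unit_indices(self):
        background = {e: float(i + 1) for i, e in enumerate(PLI_ELEMENTS)}
        background["Hg"] = 0.033
        row = [background[e] for e in background]
        matrix = make_matrix([row, row], elements=list(background))
        reports = assess_sites(matrix, BackgroundTable(background))
        for report in reports:
            assert all(v == pytest.approx(1.0) for v in report.cf.values())
            assert report.pli == pytest.approx(1.0)
            # TRF elements present: Cd,Cr,Cu,Hg,Ni,Pb,V,Zn (no Mn) -> 90
            assert report.eri == pytest.approx(90.0)
            assert report.pli_class == "minimal to moderate"
            assert all(c == "Suspected" for c in report.cf_class.values())

    def test_doubling_a_site_doubles_cf_and_pli(self, georgia_survey):
        matrix, _ = georgia_survey
        background = BackgroundTable(
            {e: float(np.median(matrix.element_values(e))) for e in matrix.elements}
        )
        base = assess_sites(matrix, background)
        doubled_values = matrix.values.copy()
        doubled_values[3] *= 2.0
        doubled = assess_sites(
            make_matrix(
                doubled_values, elements=matrix.elements, site_ids=matrix.site_ids
            ),
            background,
        )
        assert doubled[3].pli == pytest.approx(2 * base[3].pli)
        assert doubled[3].eri == pytest.approx(2 * base[3].eri)
        for e in matrix.elements:
            assert doubled[3].cf[e] == pytest.approx(2 * base[3].cf[e])
        assert doubled[2].pli == pytest.approx(base[2].pli)

    def test_classes_consistent_with_values(self, georgia_survey):
        matrix, _ = georgia_survey
        background = BackgroundTable(
            {e: float(np.quantile(matrix.element_values(e), 0.1)) for e in matrix.elements}
        )
        for report in assess_sites(matrix, background):
            assert report.pli_class == classify_pli(report.pli)
            assert report.eri_class == classify_eri(report.eri)
            for e, v in report.cf.items():
                assert report.cf_class[e] == classify_cf(v)
            for e, v in report.peri.items():
                assert report.peri_class[e] == classify_peri(v)
                assert v == pytest.approx(report.cf[e] * DEFAULT_TRF[e])

    def test_missing_background_for_pli_element_rejected(self, tiny_survey):
        with pytest.raises(KeyError, match="Pb"):
            assess_sites(tiny_survey, BackgroundTable({"Al": 1.0}),
                         pli_elements=["Al", "Pb"])

    def test_report_frame_has_one_row_per_site(self, georgia_survey):
        matrix, _ = georgia_survey
        background = BackgroundTable(
            {e: float(np.median(matrix.element_values(e))) for e in matrix.elements}
        )
        frame = reports_to_frame(assess_sites(matrix, background))
        assert len(frame) == matrix.n_sites
        assert {"PLI", "PLI_class", "ERI", "ERI_class"} <= set(frame.columns)
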