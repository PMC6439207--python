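"""DI/ADI intake model: closed-form values, published-table regressions,
algebraic properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pahrisk import (
    ExposureScenario,
    ToxicityParameters,
    assess_intake_table,
    classify_intake,
    compute_adi,
    compute_di_ambient,
    compute_di_matrix,
    di_ratio,
    summarize_intake,
)
from pahrisk.rounding import round_sig

finite = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)
fractions = st.floats(min_value=1e-6, max_value=1.0, allow_nan=False)


class TestAdi:
    def test_low_potency_adi(self, defaults):
        _, tox, _ = defaults
        # maximum ADI, reached at the smallest TEF (0.001)
        adi = compute_adi(tox, 0.001)
        assert adi == pytest.approx(0.2564, abs=1e-4)
        assert round(adi, 2) == 0.26

    def test_bap_adi(self, defaults):
        _, tox, _ = defaults
        assert compute_adi(tox, 1.0) == pytest.approx(0.0003, abs=1e-4)

    def test_zero_tef_rejected(self, defaults):
        _, tox, _ = defaults
        with pytest.raises(ValueError):
            compute_adi(tox, 0.0)

    @given(tef=fractions, cr=st.floats(1e-8, 1e-3), ipf=st.floats(1e-6, 1.0))
    def test_cr_round_trip(self, tef, cr, ipf):
        tox = ToxicityParameters(cr=cr, cr_range=(cr, cr), ipf_bap=ipf)
        assert compute_adi(tox, tef) * tox.ipf_bap * tef == pytest.approx(
            cr, rel=1e-12
        )


class TestDiMatrix:
    def test_phenanthrene_w300(self, defaults):
        _, _, scenario = defaults
        di = compute_di_matrix(10000.0, 0.007541, scenario)
        assert di == pytest.approx(0.1056, abs=1e-4)

    def test_total_concentration_extreme(self, defaults):
        _, _, scenario = defaults
        assert compute_di_matrix(10000.0, 1.0, scenario) == pytest.approx(14.0)

    def test_zero_fraction(self, defaults):
        _, _, scenario = defaults
        assert compute_di_matrix(12345.0, 0.0, scenario) == 0.0

    def test_missing_particle_concentration_rejected(self):
        with pytest.raises(ValueError, match="c_particle"):
            compute_di_matrix(10000.0, 0.5, ExposureScenario())

    @given(
        q=finite,
        f=fractions,
        tr=fractions,
        c=finite,
        v=finite,
        bw=finite,
    )
    def test_matches_independent_product(self, q, f, tr, c, v, bw):
        """Brute-force oracle: same product evaluated in a different
        association order."""
        scenario = ExposureScenario(tr=tr, v_resp=v, bw=bw, c_particle=c)
        oracle = (1.0 / bw) * (v * (c * (tr * (f * q))))
        assert compute_di_matrix(q, f, scenario) == pytest.approx(oracle, rel=1e-12)

    @given(q=finite, f=fractions)
    def test_linear_in_each_factor(self, q, f):
        s = ExposureScenario(c_particle=5.6e-3)
        base = compute_di_matrix(q, f, s)
        assert compute_di_matrix(2 * q, f, s) == pytest.approx(2 * base, rel=1e-12)
        s2 = ExposureScenario(c_particle=2 * 5.6e-3)
        assert compute_di_matrix(q, f, s2) == pytest.approx(2 * base, rel=1e-12)
        s3 = ExposureScenario(c_particle=5.6e-3, bw=120.0)
        assert compute_di_matrix(q, f, s3) == pytest.approx(base / 2, rel=1e-12)


class TestDiAmbient:
    def test_phenanthrene_pm25(self, defaults):
        _, _, scenario = defaults
        assert compute_di_ambient(2.30, 0.2128, scenario) == pytest.approx(
            0.1224, abs=1e-4
        )

    def test_total_mode(self, defaults):
        _, _, scenario = defaults
        assert compute_di_ambient(2.30, 1.0, scenario) == pytest.approx(0.5750)

    def test_zero_concentration(self, defaults):
        _, _, scenario = defaults
        assert compute_di_ambient(0.0, 0.5, scenario) == 0.0

    @given(c=finite, f=fractions)
    def test_bioaccessible_scales_total(self, c, f):
        s = ExposureScenario()
        assert compute_di_ambient(c, f, s) == pytest.approx(
            f * compute_di_ambient(c, 1.0, s), rel=1e-12
        )


class TestClassification:
    @pytest.mark.parametrize(
        "di,adi,risky",
        [
            (0.5750, 0.2564, True),  # Phe, total mode
            (0.1072, 0.2564, False),  # Pyr, bioaccessible mode
            (0.2564, 0.2564, False),  # equality acceptable by convention
        ],
    )
    def test_boundary_convention(self, di, adi, risky):
        assert classify_intake(di, adi) is risky

    def test_strict_boundary_option(self):
        assert classify_intake(0.2564, 0.2564, tie_acceptable=False)

    @given(c=finite, f=fractions)
    def test_bioaccessible_risky_implies_total_risky(self, c, f, defaults):
        _, tox, _ = defaults
        s = ExposureScenario()
        adi = compute_adi(tox, 0.01)
        if classify_intake(compute_di_ambient(c, f, s), adi):
            assert classify_intake(compute_di_ambient(c, 1.0, s), adi)


class TestDiRatio:
    @pytest.mark.parametrize(
        "f,expected", [(0.0213, 46.9), (0.1958, 5.11), (1.0, 1.0)]
    )
    def test_ratio(self, f, expected):
        assert round_sig(di_ratio(f), 3) == pytest.approx(expected, abs=0.1)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            di_ratio(0.0)


def _flag(value) -> bool:
    return value == "Risky"


class TestPm25IntakeRegression:
    """Every printed DI cell and risk flag of the ambient assessment."""

    def test_all_rows_reproduced(self, defaults, pm25, pm25_maps):
        registry, tox, _ = defaults
        scenario = ExposureScenario()  # ambient route needs no particle conc
        tc_map, fbioa_map = pm25_maps
        results = assess_intake_table(
            registry, tc_map, fbioa_map, scenario, tox, mode="both"
        )
        by_key = {(r.analyte, r.mode): r for r in results}
        for row in pm25.itertuples():
            total = by_key[(row.analyte, "total")]
            assert total.di == pytest.approx(row.di_total_printed, abs=1e-4)
            assert total.adi == pytest.approx(row.adi_printed, abs=1e-4)
            assert total.risky == _flag(row.risk_di_total_printed)
            bioa = by_key[(row.analyte, "bioaccessible")]
            if pd.isna(row.fbioa):
                assert bioa.di is None and bioa.risky is None
                assert "not assessed" in bioa.note
            else:
                assert bioa.di == pytest.approx(row.di_bioa_printed, abs=1e-4)
                assert bioa.risky == _flag(row.risk_di_bioa_printed)

    def test_always_risky_set(self, defaults, pm25_maps):
        registry, tox, _ = defaults
        tc_map, fbioa_map = pm25_maps
        results = assess_intake_table(
            registry, tc_map, fbioa_map, ExposureScenario(), tox, mode="both"
        )
        risky = {
            m: {r.analyte for r in results if r.mode == m and r.risky}
            for m in ("total", "bioaccessible")
        }
        assert risky["bioaccessible"] == {
            "FA", "BaA", "Chr", "BbF + BkF", "BaP", "Ind", "DBahA", "BghiP",
        }
        # Phe and Pyr flip from risky to acceptable once bioaccessibility counts
        assert risky["total"] - risky["bioaccessible"] == {"Phe", "Pyr"}

    def test_overestimation_ratio_range(self, defaults, pm25_maps):
        registry, tox, _ = defaults
        tc_map, fbioa_map = pm25_maps
        results = assess_intake_table(
            registry, tc_map, fbioa_map, ExposureScenario(), tox, mode="both"
        )
        summary = summarize_intake(results)
        lo, hi = summary.di_ratio_range
        assert round_sig(lo, 3) == pytest.approx(5.11, abs=0.01)
        # quoted endpoint 47.0; full-precision ratio is 46.95
        assert 46.9 <= round_sig(hi, 3) <= 47.0

    def test_empty_table(self, defaults):
        registry, tox, scenario = defaults
        assert assess_intake_table(registry, {}, {}, scenario, tox) == []

    def test_unknown_analyte_rejected(self, defaults):
        registry, tox, scenario = defaults
        with pytest.raises(KeyError):
            assess_intake_table(registry, {"XYZ": 1.0}, {}, scenario, tox)


class TestBiocharRegression:
    """All 48 + 18 printed DI cells of the biochar tables."""

    def test_table1_di_cells(self, defaults, table1):
        _, _, scenario = defaults
        for row in table1.itertuples():
            di = compute_di_matrix(row.q_ng_g, row.fbioa, scenario)
            assert di == pytest.approx(row.di_printed_ng_kg_day, abs=1e-4), row

    def test_table2_di_cells(self, defaults, table2):
        _, _, scenario = defaults
        for row in table2.itertuples():
            di = compute_di_matrix(row.q_ng_g, row.fbioa, scenario)
            assert di == pytest.approx(row.di_printed_ng_kg_day, abs=1e-4), row

    def test_total_mode_loadings(self, defaults):
        _, _, scenario = defaults
        for q_ug_g, expected in [(10, 14.0), (50, 70.0), (100, 140.0)]:
            assert compute_di_matrix(q_ug_g * 1000.0, 1.0, scenario) == pytest.approx(
                expected
            )

    def test_table1_bioaccessible_di_range(self, defaults, table1):
        _, _, scenario = defaults
        dis = [
            compute_di_matrix(r.q_ng_g, r.fbioa, scenario) for r in table1.itertuples()
        ]
        assert round_sig(min(dis), 2) == pytest.approx(0.047)
        assert round_sig(max(dis), 2) == pytest.approx(0.21)
        adi_max = 0.2564
        assert all(di < adi_max for di in dis)

    def test_table2_bioaccessible_di_range(self, defaults, table2):
        _, _, scenario = defaults
        dis = [
            compute_di_matrix(r.q_ng_g, r.fbioa, scenario) for r in table2.itertuples()
        ]
        assert min(dis) == pytest.approx(0.084, abs=5e-4)
        assert max(dis) == pytest.approx(2.41, abs=5e-3)
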