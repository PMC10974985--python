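import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schooldust.datamodel import BackgroundTable, ConcentrationMatrix, PMSeries, ValidationError
from schooldust.indices import (
    CF_LABELS,
    EF_LABELS,
    MCD_LABELS,
    classify_cf,
    classify_ef,
    classify_igeo,
    classify_mcd,
    contamination_factor,
    enrichment_factor,
    geo_accumulation_index,
    modified_degree_of_contamination,
    pm_ratio_summary,
    pollution_load_index_site,
    pollution_load_index_zone,
    site_indices,
)


def _matrix(values: dict[str, list[float]], sites=None) -> ConcentrationMatrix:
    n = len(next(iter(values.values())))
    sites = sites or [f"S{i + 1}" for i in range(n)]
    return ConcentrationMatrix(pd.DataFrame(values, index=sites))


class TestGeoAccumulation:
    def test_known_values(self):
        bg = BackgroundTable({"X": 10.0})
        conc = _matrix({"X": [15.0, 30.0, 960.0]})  # 1.5B, 3B, 96B
        res = geo_accumulation_index(conc, bg)
        vals = res["value"].tolist()
        assert vals[0] == pytest.approx(0.0)
        assert vals[1] == pytest.approx(1.0)
        assert vals[2] == pytest.approx(6.0)  # log2(960/15) = log2(64)
        assert res["class"].tolist() == [
            "class 0: unpolluted",
            "class 1: unpolluted to moderately polluted",
            "class 6: extremely polluted",
        ]

    def test_zero_concentration_undefined_class_zero(self):
        bg = BackgroundTable({"X": 10.0})
        res = geo_accumulation_index(_matrix({"X": [0.0]}), bg)
        assert math.isnan(res["value"].iloc[0])
        assert res["class"].iloc[0].startswith("class 0")

    def test_missing_background_names_element(self):
        bg = BackgroundTable({"X": 10.0})
        with pytest.raises(ValidationError, match="Y"):
            geo_accumulation_index(_matrix({"X": [1.0], "Y": [1.0]}), bg)

    @given(
        c=st.floats(1e-6, 1e6),
        b=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_doubling_concentration_shifts_index_by_one(self, c, b):
        bg = BackgroundTable({"X": b})
        v1 = geo_accumulation_index(_matrix({"X": [c]}), bg)["value"].iloc[0]
        v2 = geo_accumulation_index(_matrix({"X": [2 * c]}), bg)["value"].iloc[0]
        assert v2 - v1 == pytest.approx(1.0, abs=1e-9)

    def test_class_boundaries_above_five(self):
        assert classify_igeo(5.0).startswith("class 5")
        assert classify_igeo(5.0001).startswith("class 6")


class TestContaminationFactor:
    def test_known_values_and_classes(self):
        bg = BackgroundTable({"X": 25.0})
        res = contamination_factor(_matrix({"X": [50.0, 25.0, 175.0]}), bg)
        assert res["value"].tolist() == pytest.approx([2.0, 1.0, 7.0])
        assert res["class"].tolist() == ["moderate", "moderate", "very high"]

    @given(
        c=st.floats(1e-3, 1e3),
        b=st.floats(1e-3, 1e3),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_covariance(self, c, b, k):
        """CF(kC, kB) == CF(C, B)."""
        r1 = contamination_factor(_matrix({"X": [c]}), BackgroundTable({"X": b}))
        r2 = contamination_factor(_matrix({"X": [k * c]}), BackgroundTable({"X": k * b}))
        assert r1["value"].iloc[0] == pytest.approx(r2["value"].iloc[0], rel=1e-9)

    def test_boundary_six_is_considerable(self):
        assert classify_cf(6.0) == "considerable"
        assert classify_cf(6.0000001) == "very high"


class TestCompositeIndices:
    def test_mcd_of_constant_cfs(self):
        val, label = modified_degree_of_contamination([3.3, 3.3, 3.3])
        assert val == pytest.approx(3.3)
        assert label == "moderate"

    def test_mcd_examples(self):
        assert modified_degree_of_contamination([1, 2, 3]) == (2.0, "low")
        assert modified_degree_of_contamination([4, 6]) == (5.0, "high")

    def test_pli_examples(self):
        val, _ = pollution_load_index_site([4.0, 1.0])
        assert val == pytest.approx(2.0)
        val, label = pollution_load_index_site([1.0, 1.0, 1.0])
        assert val == pytest.approx(1.0)
        assert label == "baseline"

    def test_pli_matches_direct_product(self, rng):
        """Log-space geometric mean equals the direct product oracle."""
        cfs = np.exp(rng.uniform(np.log(1e-3), np.log(1e3), size=50))
        val, _ = pollution_load_index_site(cfs)
        direct = float(np.prod(cfs) ** (1.0 / len(cfs)))
        assert val == pytest.approx(direct, rel=1e-12)

    def test_pli_rejects_zero_cf(self):
        with pytest.raises(ValidationError):
            pollution_load_index_site([1.0, 0.0])

    def test_mcd_between_min_and_max_and_pli_below_mcd(self, rng):
        """mCd in [min, max] of CFs; PLI <= mCd (AM-GM)."""
        for _ in range(1000):
            cfs = np.exp(rng.normal(0, 1, size=rng.integers(1, 12)))
            mcd, _ = modified_degree_of_contamination(cfs)
            pli, _ = pollution_load_index_site(cfs)
            assert cfs.min() - 1e-12 <= mcd <= cfs.max() + 1e-12
            assert pli <= mcd * (1 + 1e-12)

    def test_zone_pli(self):
        assert pollution_load_index_zone([2.0])[0] == pytest.approx(2.0)
        assert pollution_load_index_zone([1.0, 4.0])[0] == pytest.approx(2.0)
        a = pollution_load_index_zone([1.3, 2.7, 0.4])[0]
        b = pollution_load_index_zone([0.4, 1.3, 2.7])[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_site_indices_table(self, background, default_dataset):
        table = site_indices(default_dataset.conc, background)
        n = default_dataset.conc.shape[0]
        assert len(table) == 2 * n + 1  # mcd + pli per site, one zone row
        assert (table.loc[table["index"] == "pli", "value"] > 0).all()


class TestEnrichmentFactor:
    def test_reference_element_is_always_one(self, default_dataset, background):
        res = enrichment_factor(default_dataset.conc, background, "Fe")
        fe = res[res["element"] == "Fe"]["value"]
        assert np.allclose(fe, 1.0)

    def test_background_ratios_give_unit_ef(self):
        bg = BackgroundTable({"X": 5.0, "Fe": 100.0})
        conc = _matrix({"X": [10.0, 50.0], "Fe": [200.0, 1000.0]})  # 2x, 10x background
        res = enrichment_factor(conc, bg, "Fe")
        assert np.allclose(res["value"], 1.0)

    def test_extremely_severe_case(self):
        bg = BackgroundTable({"X": 2.0, "Fe": 1.0})
        conc = _matrix({"X": [120.0], "Fe": [1.0]})  # sample ratio 120, background 2
        res = enrichment_factor(conc, bg, "Fe")
        x = res[res["element"] == "X"].iloc[0]
        assert x["value"] == pytest.approx(60.0)
        assert x["class"] == "extremely severe enrichment"

    def test_site_scale_invariance(self, rng):
        """Multiplying all of a site's concentrations by a constant leaves EF."""
        bg = BackgroundTable({"X": 5.0, "Y": 7.0, "Fe": 100.0})
        vals = rng.uniform(1, 100, size=(1, 3))
        m1 = ConcentrationMatrix(pd.DataFrame(vals, index=["S1"], columns=["X", "Y", "Fe"]))
        m2 = ConcentrationMatrix(pd.DataFrame(vals * 7.3, index=["S1"], columns=["X", "Y", "Fe"]))
        r1 = enrichment_factor(m1, bg)["value"]
        r2 = enrichment_factor(m2, bg)["value"]
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_zero_reference_concentration_names_site(self):
        bg = BackgroundTable({"X": 5.0, "Fe": 100.0})
        conc = _matrix({"X": [1.0], "Fe": [0.0]})
        with pytest.raises(ValidationError, match="S1"):
            enrichment_factor(conc, bg, "Fe")


@given(st.floats(0, 1e6, allow_nan=False))
@settings(max_examples=200, deadline=None)
def test_classifications_are_total_with_closed_vocabulary(value):
    assert classify_cf(value) in CF_LABELS
    assert classify_mcd(value) in MCD_LABELS
    assert classify_ef(value) in EF_LABELS
    assert classify_igeo(math.log2(value) if value > 0 else float("nan")).startswith("class ")


class TestPMRatio:
    def _series(self, pm25, pm10):
        ts = pd.date_range("2022-01-01", periods=len(pm25), freq="D")
        return PMSeries(ts, np.asarray(pm25, float), np.asarray(pm10, float))

    def test_half_ratio_not_flagged(self):
        s = pm_ratio_summary(self._series([5.0], [10.0]))
        assert s.table["ratio"].iloc[0] == pytest.approx(0.5)
        assert not s.table["combustion_dominated"].iloc[0]

    def test_high_ratio_flagged(self):
        s = pm_ratio_summary(self._series([7.4], [10.0]))
        assert s.table["ratio"].iloc[0] == pytest.approx(0.74)
        assert s.table["combustion_dominated"].iloc[0]

    def test_constant_series_summary(self):
        s = pm_ratio_summary(self._series([6.0, 6.0, 6.0], [10.0, 10.0, 10.0]))
        assert s.mean == s.min == s.max == pytest.approx(0.6)

    def test_zero_pm10_excluded_from_summary(self):
        s = pm_ratio_summary(self._series([5.0, 5.0], [10.0, 0.0]))
        assert s.n_undefined == 1
        assert s.mean == pytest.approx(0.5)

    def test_inversion_flagged_not_dropped(self):
        s = pm_ratio_summary(self._series([12.0], [10.0]))
        assert s.n_inversions == 1
        assert s.max == pytest.approx(1.2)
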