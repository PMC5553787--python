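"""Episode assembly, covariate/outcome derivation and exclusion rules."""

import pandas as pd
import pytest

from stentminer import (
    GeneratorConfig,
    extract_corpus,
    generate_cohort,
    render_reports,
)
from stentminer.warehouse import (
    CohortTable,
    DataIntegrityError,
    WarehouseConfig,
    apply_exclusions,
    build_warehouse,
    derive_dapt,
    derive_diabetes,
    derive_hypertension,
    derive_tvr,
)


class TestDeriveTvr:
    def test_repeat_on_same_vessel_within_window_is_an_event(self):
        event, t = derive_tvr("2011-01-01", "LAD", ["2012-02-05"], None)
        assert event is True and t == 400

    def test_repeat_on_other_vessel_does_not_count(self):
        # the caller passes only same-vessel repeats; none here
        event, t = derive_tvr("2011-01-01", "LAD", [], "2011-12-31")
        assert event is False and t == 364

    def test_repeat_beyond_window_censors_at_window(self):
        event, t = derive_tvr("2011-01-01", "LAD", ["2013-03-11"], "2013-06-19")
        assert event is False and t == 730

    def test_repeat_before_index_is_a_data_error(self):
        with pytest.raises(DataIntegrityError):
            derive_tvr("2011-01-01", "LAD", ["2010-12-01"], None)

    def test_event_never_exceeds_window(self):
        for repeat in ("2011-01-10", "2012-06-01", "2013-12-31"):
            event, t = derive_tvr("2011-01-01", "LAD", [repeat], None)
            assert t <= 730
            if event:
                assert t == (pd.Timestamp(repeat) - pd.Timestamp("2011-01-01")).days


class TestDeriveDapt:
    @staticmethod
    def _rx(rows):
        return pd.DataFrame(rows, columns=["patient_id", "drug_class", "start", "end"])

    def test_full_overlap(self):
        rx = self._rx([
            ("p", "aspirin", "2011-01-01", "2012-02-05"),
            ("p", "clopidogrel", "2011-01-01", "2012-02-05"),
        ])
        days, flag = derive_dapt(rx, "2011-01-01")
        assert days == 400 and flag is True

    def test_overlap_limited_by_shorter_drug(self):
        rx = self._rx([
            ("p", "aspirin", "2011-01-01", "2012-02-05"),
            ("p", "ticagrelor", "2011-01-01", "2011-07-20"),
        ])
        days, flag = derive_dapt(rx, "2011-01-01")
        assert days == 200 and flag is False

    def test_no_p2y12_means_zero(self):
        rx = self._rx([("p", "aspirin", "2011-01-01", "2012-01-01")])
        assert derive_dapt(rx, "2011-01-01") == (0, False)

    def test_pre_index_exposure_does_not_count(self):
        rx = self._rx([
            ("p", "aspirin", "2010-01-01", "2011-03-02"),
            ("p", "clopidogrel", "2010-01-01", "2011-03-02"),
        ])
        days, _ = derive_dapt(rx, "2011-03-01")
        assert days == 1


class TestPhenotypes:
    @staticmethod
    def _tables(dx_rows, rx_rows):
        dx = pd.DataFrame(dx_rows, columns=["patient_id", "code", "date"])
        rx = pd.DataFrame(rx_rows, columns=["patient_id", "drug_class", "start", "end"])
        return dx, rx

    def test_code_only(self):
        dx, rx = self._tables([("p", "I10", "2010-06-01")], [])
        assert derive_hypertension(dx, rx, pd.Timestamp("2011-01-01")) is True

    def test_drug_only(self):
        dx, rx = self._tables([], [("p", "amlodipine", "2010-06-01", "2010-07-01")])
        assert derive_hypertension(dx, rx, pd.Timestamp("2011-01-01")) is True

    def test_neither(self):
        dx, rx = self._tables([], [("p", "metformin", "2010-06-01", "2010-07-01")])
        assert derive_hypertension(dx, rx, pd.Timestamp("2011-01-01")) is False

    def test_code_after_index_does_not_count(self):
        dx, rx = self._tables([("p", "I10", "2012-01-01")], [])
        assert derive_hypertension(dx, rx, pd.Timestamp("2011-01-01")) is False

    def test_diabetes_code_or_drug(self):
        dx, rx = self._tables([("p", "E11", "2010-01-01")], [])
        assert derive_diabetes(dx, rx, pd.Timestamp("2011-01-01")) is True
        dx2, rx2 = self._tables([], [("p", "insulin", "2010-01-01", "2010-02-01")])
        assert derive_diabetes(dx2, rx2, pd.Timestamp("2011-01-01")) is True


class TestBuildWarehouse:
    def test_toy_fixture_hand_checked(self, toy_extraction, toy_patients):
        table = build_warehouse(toy_extraction, toy_patients)
        df = table.df.set_index(["patient_id", "vessel"])
        assert len(df) == 3

        lad = df.loc[("P001", "LAD")]
        assert lad["n_stents"] == 2
        assert lad["total_length_mm"] == 38.0
        assert lad["mean_diameter_mm"] == 2.75
        assert bool(lad["balloon_used"]) is True
        assert bool(lad["tvr_event"]) is True and lad["followup_days"] == 400
        assert lad["age"] == 61
        assert bool(lad["hypertension"]) is True and bool(lad["diabetes"]) is False
        assert lad["dapt_days"] == 366 and bool(lad["dapt_over_12mo"]) is True
        assert lad["approach"] == "femoral"

        rca = df.loc[("P001", "RCA")]
        assert bool(rca["tvr_event"]) is False and rca["followup_days"] == 730
        assert rca["classes"] == "DES2-BP"

        lcx = df.loc[("P002", "LCx")]
        assert bool(lcx["tvr_event"]) is False and lcx["followup_days"] == 180
        assert lcx["age"] == 72
        assert bool(lcx["diabetes"]) is True and bool(lcx["hypertension"]) is False
        assert lcx["dapt_days"] == 0
        assert lcx["approach"] == "radial"

    def test_orphan_reports_are_dropped_and_counted(self, toy_extraction, toy_patients):
        ext = toy_extraction.copy()
        ext.loc[len(ext)] = ext.iloc[0]
        ext.loc[len(ext) - 1, "patient_id"] = "GHOST"
        ext.loc[len(ext) - 1, "report_id"] = "R999"
        table = build_warehouse(ext, toy_patients)
        assert table.provenance["n_orphan_rows"] == 1
        assert len(table.df) == 3

    def test_empty_extraction_yields_empty_table(self, toy_extraction, toy_patients):
        table = build_warehouse(toy_extraction.iloc[0:0], toy_patients)
        assert len(table.df) == 0

    def test_idempotent_byte_identical_output(self, tmp_path, toy_extraction, toy_patients):
        p1, p2 = tmp_path / "w1.csv", tmp_path / "w2.csv"
        build_warehouse(toy_extraction, toy_patients).write(p1)
        build_warehouse(toy_extraction, toy_patients).write(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_aggregation_conservation_on_synthetic_corpus(self, lexicon):
        """Total stents across episodes equals total extraction rows."""
        cohort = generate_cohort(GeneratorConfig(n_patients=80, seed=13))
        docs = render_reports(cohort, lexicon)
        frame, _ = extract_corpus(docs, lexicon)
        table = build_warehouse(frame, cohort.patient_tables)
        assert int(table.df["n_stents"].sum()) == len(frame)

    def test_reconstructs_generator_truth(self, lexicon, clean_cohort, clean_corpus):
        """On a clean corpus the warehouse reproduces the generator's
        episode truth: aggregates, covariates, follow-up and events."""
        _, frame, _ = clean_corpus
        table = build_warehouse(frame, clean_cohort.patient_tables)
        built = table.df.set_index(["patient_id", "vessel"]).sort_index()
        truth = clean_cohort.episodes.set_index(["patient_id", "vessel"]).sort_index()
        assert len(built) == len(truth)
        for col in (
            "n_stents", "total_length_mm", "mean_diameter_mm", "balloon_used",
            "followup_days", "tvr_event", "age", "hypertension", "diabetes",
            "dapt_days", "emergent",
        ):
            pd.testing.assert_series_equal(
                built[col], truth[col], check_dtype=False, check_names=False
            )


class TestExclusions:
    @staticmethod
    def _table(classes_brands):
        rows = []
        for i, (classes, brands) in enumerate(classes_brands):
            rows.append({
                "patient_id": f"p{i}", "vessel": "LAD", "index_date": "2011-01-01",
                "classes": classes, "brands": brands, "n_stents": 1,
                "total_length_mm": 28.0, "mean_diameter_mm": 3.0,
                "balloon_used": False, "approach": "femoral", "emergent": False,
                "age": 60, "sex": "M", "hypertension": False, "diabetes": False,
                "dapt_days": 400, "dapt_over_12mo": True, "followup_days": 730,
                "tvr_event": False, "excluded": False, "exclude_reason": "",
            })
        return CohortTable(df=pd.DataFrame(rows))

    def test_mixed_polymer_vessel_excluded_from_dp_vs_bp(self):
        table = self._table([("DES2-BP+DES2-DP", "Nobori+Xience")])
        out = apply_exclusions(table, "dp_vs_bp")
        assert out.df.loc[0, "excluded"] and out.df.loc[0, "exclude_reason"] == "mixed-category"

    def test_same_category_two_brands_retained_in_dp_vs_bp(self):
        table = self._table([("DES2-DP", "Promus+Xience")])
        out = apply_exclusions(table, "dp_vs_bp")
        assert not out.df.loc[0, "excluded"] and out.df.loc[0, "group"] == "DP"

    def test_cross_generation_vessel_excluded_from_gen_comparison(self):
        table = self._table([("DES1+DES2-DP", "Cypher+Xience")])
        out = apply_exclusions(table, "gen1_vs_gen2")
        assert out.df.loc[0, "exclude_reason"] == "mixed-category"

    def test_dp_plus_bp_is_single_category_at_generation_granularity(self):
        table = self._table([("DES2-BP+DES2-DP", "Nobori+Xience")])
        out = apply_exclusions(table, "gen1_vs_gen2")
        assert not out.df.loc[0, "excluded"] and out.df.loc[0, "group"] == "gen2"

    def test_bms_outside_des_comparisons(self):
        table = self._table([("BMS", "Vision")])
        for comparison in ("gen1_vs_gen2", "dp_vs_bp", "each_vs_rest"):
            out = apply_exclusions(table, comparison)
            assert out.df.loc[0, "exclude_reason"] == "not-in-comparison"

    def test_each_vs_rest_requires_single_brand(self):
        table = self._table([
            ("DES2-DP", "Promus+Xience"), ("DES2-DP", "Endeavor"),
        ])
        out = apply_exclusions(table, "each_vs_rest")
        assert out.df.loc[0, "exclude_reason"] == "mixed-category"
        assert out.df.loc[1, "group"] == "Endeavor"

    def test_excluded_rows_never_enter_analysis_exports(self):
        table = self._table([("DES2-BP+DES2-DP", "Nobori+Xience"), ("DES2-DP", "Xience")])
        out = apply_exclusions(table, "dp_vs_bp")
        assert len(out.analysis_frame()) == 1


def test_cohort_table_roundtrip(tmp_path, toy_extraction, toy_patients):
    table = build_warehouse(toy_extraction, toy_patients, WarehouseConfig())
    path = tmp_path / "warehouse.csv"
    table.write(path)
    loaded = CohortTable.read(path)
    assert len(loaded.df) == len(table.df)
    assert loaded.provenance["n_episodes"] == 3
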