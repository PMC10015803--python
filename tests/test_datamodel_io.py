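"""Domain types and CSV round trips: censoring at ingest, report writing."""

import math

import pytest

from vocmix import (
    ChemClass,
    ChemicalDescriptor,
    ClimateRecord,
    MeasurementSample,
    ReportingLimits,
    RunConfig,
    compute_tvoc,
    hazard_index,
    read_config,
    read_measurements,
    read_registry,
    read_report,
    write_measurements,
    write_report,
)
from vocmix.datamodel import format_sigfigs
from vocmix.errors import (
    DuplicateRecordError,
    FormatError,
    ParseError,
    ValidationError,
)

from conftest import chem, make_sample

MEAS_HEADER = "salon_id,worker_id,duration_min,chemical,cas,chem_class,concentration\n"


class TestDescriptor:
    def test_valid_cas_forms(self):
        chem("Formaldehyde", "59-00-0")
        chem("Xylene", "95-47-6; 108-38-3; 106-42-3")
        chem("Vertenex compound", "NA")

    @pytest.mark.parametrize("bad_cas", ["1-00-0", "59-0-0", "abc", "", "59-00-0;"])
    def test_invalid_cas_rejected(self, bad_cas):
        with pytest.raises(ValidationError):
            chem("X", bad_cas)

    def test_empty_name_rejected(self):
        with pytest.raises(ValidationError):
            chem("  ")

    def test_identity_is_name_and_cas(self):
        a = chem("Limonene", "5989-27-5", tvoc=True)
        b = chem("Limonene", "5989-27-5", tvoc=False)
        assert a == b and hash(a) == hash(b)
        assert a != chem("Limonene", "NA")


class TestSampleInvariants:
    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValidationError):
            make_sample({chem("A", "50-00-0"): 0.0})

    def test_censored_analyte_carries_no_value(self):
        a = chem("A", "50-00-0")
        with pytest.raises(ValidationError):
            MeasurementSample("s1", "h1", concentrations={a: 5.0}, censored={a})

    def test_climate_floor(self):
        with pytest.raises(ValidationError):
            ClimateRecord("s1", co2_ppm=250, temp_c=22, rh_pct=40)


class TestFormatSigfigs:
    @pytest.mark.parametrize(
        "value,expected",
        [(4.222, "4"), (0.7142857, "0.7"), (8.2857, "8"), (0.00242857, "0.002"), (12.5, "10")],
    )
    def test_one_sigfig_display(self, value, expected):
        assert format_sigfigs(value, 1) == expected


class TestReadMeasurements:
    def test_retains_value_at_or_above_limit(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MEAS_HEADER + "s1,h1,176,Formaldehyde,59-00-0,aldehyde,38\n")
        (sample,) = read_measurements(p, ReportingLimits())
        assert list(sample.concentrations.values()) == [38.0]

    def test_below_limit_numeric_is_censored_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.csv"
        p.write_text(MEAS_HEADER + "s1,h1,176,Limonene,5989-27-5,VOC,2.5\n")
        with caplog.at_level("WARNING", logger="vocmix.io"):
            (sample,) = read_measurements(p, ReportingLimits(voc_limit=3))
        assert not sample.concentrations
        assert {c.name for c in sample.censored} == {"Limonene"}
        assert any("reporting limit" in r.message for r in caplog.records)

    def test_rl_token_goes_to_censored_set(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MEAS_HEADER + "s1,h1,176,Nonane,111-84-2,VOC,<RL\n")
        (sample,) = read_measurements(p)
        assert {c.name for c in sample.censored} == {"Nonane"}

    def test_class_specific_limits(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            MEAS_HEADER
            + "s1,h1,176,Acetaldehyde,75-07-0,aldehyde,1.0\n"
            + "s1,h1,176,Toluene,108-88-3,VOC,1.0\n"
        )
        (sample,) = read_measurements(p)  # aldehyde limit 0.3, VOC limit 3
        assert {c.name for c in sample.concentrations} == {"Acetaldehyde"}
        assert {c.name for c in sample.censored} == {"Toluene"}

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MEAS_HEADER)
        assert read_measurements(p) == []

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("salon_id,worker_id,chemical,cas,chem_class,concentration\ns1,h1,A,50-00-0,VOC,5\n")
        with pytest.raises(FormatError, match="duration_min"):
            read_measurements(p)

    def test_bad_token_reports_row(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(MEAS_HEADER + "s1,h1,176,Toluene,108-88-3,VOC,oops\n")
        with pytest.raises(ParseError, match="row 2"):
            read_measurements(p)

    def test_duplicate_record_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            MEAS_HEADER
            + "s1,h1,176,Toluene,108-88-3,VOC,14\n"
            + "s1,h1,176,Toluene,108-88-3,VOC,31\n"
        )
        with pytest.raises(DuplicateRecordError):
            read_measurements(p)

    def test_groups_rows_into_one_sample_per_worker(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            MEAS_HEADER
            + "s1,h1,176,Toluene,108-88-3,VOC,14\n"
            + "s1,h1,176,Acetone,67-64-1,VOC,37\n"
            + "s1,h2,176,Acetone,67-64-1,VOC,11\n"
        )
        samples = read_measurements(p)
        assert {(s.salon_id, s.worker_id) for s in samples} == {("s1", "h1"), ("s1", "h2")}
        by_key = {s.key: s for s in samples}
        assert len(by_key[("s1", "h1")].concentrations) == 2


class TestReadRegistry:
    def test_rv_and_blank_tiers(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "chemical,cas,rv,oel_se,oel_nordic,oel_intl\n"
            "Formaldehyde,59-00-0,9,,,\n"
            "Hedione,24851-98-7; 2630-39-9,,,,\n"
        )
        reg = read_registry(p)
        assert reg.lookup(chem("Formaldehyde", "59-00-0")).rv == 9
        assert reg.lookup(chem("Hedione", "24851-98-7; 2630-39-9")).unresolvable

    def test_multivalue_tier_retained(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "chemical,cas,rv,oel_se,oel_nordic,oel_intl\nX,50-00-0,,,,1000;2100\n"
        )
        rec = read_registry(p).lookup(chem("X", "50-00-0"))
        assert sorted(v for v, _ in rec.oel_intl) == [1000, 2100]

    def test_nonpositive_limit_rejected(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("chemical,cas,rv,oel_se,oel_nordic,oel_intl\nX,50-00-0,-5,,,\n")
        with pytest.raises(ValidationError):
            read_registry(p)

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("chemical,cas,rv,oel_se,oel_nordic,oel_intl,bogus\nX,50-00-0,9,,,,y\n")
        with pytest.raises(FormatError, match="bogus"):
            read_registry(p)


class TestReportRoundTrip:
    def _result(self, mini_registry, formaldehyde, isopropanol):
        sample = make_sample({formaldehyde: 38.0, isopropanol: 58.0})
        return hazard_index(sample, mini_registry)

    def test_display_column_one_sigfig(self, tmp_path, mini_registry, formaldehyde):
        sample = make_sample({formaldehyde: 38.0})
        res = hazard_index(sample, mini_registry)  # HI = 38/9 = 4.222...
        out = tmp_path / "report.csv"
        write_report([res], out, RunConfig())
        main, _ = read_report(out)
        assert main.loc[0, "hi_display"] == 4
        assert math.isclose(main.loc[0, "hi"], 38 / 9, rel_tol=1e-12)

    def test_single_result_single_row(self, tmp_path, mini_registry, formaldehyde, isopropanol):
        out = tmp_path / "report.csv"
        write_report([self._result(mini_registry, formaldehyde, isopropanol)], out)
        main, hq = read_report(out)
        assert len(main) == 1
        assert len(hq) == 2  # one HQ row per contributing chemical

    def test_full_precision_round_trip(self, tmp_path, mini_registry, formaldehyde, isopropanol):
        res = self._result(mini_registry, formaldehyde, isopropanol)
        out = tmp_path / "report.csv"
        write_report([res], out)
        main, hq = read_report(out)
        assert math.isclose(main.loc[0, "hi"], res.hi, rel_tol=1e-12)
        assert math.isclose(main.loc[0, "mcr"], res.mcr, rel_tol=1e-12)
        hq_read = dict(zip(hq["chemical"], hq["hq"]))
        for c, v in res.hq_by_chemical.items():
            assert math.isclose(hq_read[c.name], v, rel_tol=1e-12)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_report([], tmp_path / "r.csv")


class TestMeasurementRoundTrip:
    def test_read_write_read_lossless(self, tmp_path):
        samples = [
            make_sample(
                {chem("Acetone", "67-64-1"): 37.123456789012, chem("Toluene", "108-88-3"): 14.0},
                censored={chem("Nonane", "111-84-2")},
            ),
            make_sample({chem("Acetone", "67-64-1"): 11.0}, salon="s2", worker="h1"),
        ]
        p = tmp_path / "m.csv"
        write_measurements(samples, p)
        back = {s.key: s for s in read_measurements(p)}
        for s in samples:
            assert back[s.key].concentrations == s.concentrations
            assert back[s.key].censored == s.censored


class TestRunConfigFile:
    def test_flat_key_value(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text(
            "# thresholds\nvoc_limit = 5\naldehyde_limit = 0.5\n"
            "risk_threshold = 1.0\nrisk_strict = true\nmcr_dominance_cutoff = 2.5\n"
        )
        cfg = read_config(p)
        assert cfg.reporting_limits.voc_limit == 5
        assert cfg.risk_strict and cfg.mcr_dominance_cutoff == 2.5

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("bogus = 1\n")
        with pytest.raises(FormatError, match="bogus"):
            read_config(p)


def test_censored_analytes_enter_no_numeric_computation(mini_registry, formaldehyde, isopropanol):
    """Adding censored analytes changes neither TVOC nor HI."""
    base = make_sample({formaldehyde: 38.0})
    with_censored = make_sample({formaldehyde: 38.0}, censored={isopropanol})
    assert compute_tvoc(base) == compute_tvoc(with_censored)
    r1 = hazard_index(base, mini_registry)
    r2 = hazard_index(with_censored, mini_registry)
    assert r1.hi == r2.hi and r1.n_contributing == r2.n_contributing
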