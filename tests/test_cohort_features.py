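"""Case-finding, exclusions, windowed features, labels, survival samples."""

import numpy as np
import pandas as pd
import pytest

import msprog.cohort_features as cf
from msprog.catalog import CodeLists
from msprog.synthetic_registry import class_at


def _tables(rx=None, adm=None, out=None, demo=None):
    empty_rx = pd.DataFrame(columns=["patient_id", "date", "drug_name"])
    empty_adm = pd.DataFrame(
        columns=["patient_id", "admit_date", "discharge_date", "icd9_codes", "emergency_flag"]
    )
    empty_out = pd.DataFrame(columns=["patient_id", "date", "service_category"])
    tabs = {
        "prescriptions": rx if rx is not None else empty_rx,
        "admissions": adm if adm is not None else empty_adm,
        "outpatients": out if out is not None else empty_out,
        "demographics": demo if demo is not None else pd.DataFrame(columns=["patient_id", "sex", "birth_year", "resident_flag"]),
    }
    for df, cols in ((tabs["prescriptions"], ["date"]), (tabs["admissions"], ["admit_date", "discharge_date"]), (tabs["outpatients"], ["date"])):
        for c in cols:
            df[c] = pd.to_datetime(df[c])
    return tabs


class TestFindCases:
    def test_single_prescription_suffices(self):
        t = _tables(rx=pd.DataFrame({"patient_id": ["A"], "date": ["2016-02-01"], "drug_name": ["natalizumab"]}))
        cases = cf.find_cases(t["prescriptions"], t["admissions"], t["outpatients"])
        assert list(cases["patient_id"]) == ["A"]
        assert cases["entry_date"].iloc[0] == pd.Timestamp("2016-02-01")

    def test_no_records_not_found(self):
        t = _tables()
        assert len(cf.find_cases(t["prescriptions"], t["admissions"], t["outpatients"])) == 0

    def test_secondary_diagnosis_position_is_irrelevant(self):
        adm = pd.DataFrame(
            {
                "patient_id": ["B"],
                "admit_date": ["2017-05-01"],
                "discharge_date": ["2017-05-04"],
                "icd9_codes": ["486;340"],  # MS code in second position
                "emergency_flag": [0],
            }
        )
        t = _tables(adm=adm)
        assert list(cf.find_cases(t["prescriptions"], t["admissions"], t["outpatients"])["patient_id"]) == ["B"]

    def test_non_ms_records_do_not_qualify(self):
        adm = pd.DataFrame(
            {
                "patient_id": ["C"],
                "admit_date": ["2017-05-01"],
                "discharge_date": ["2017-05-04"],
                "icd9_codes": ["486"],
                "emergency_flag": [0],
            }
        )
        out = pd.DataFrame({"patient_id": ["C"], "date": ["2017-06-01"], "service_category": ["laboratory"]})
        t = _tables(adm=adm, out=out)
        assert len(cf.find_cases(t["prescriptions"], t["admissions"], t["outpatients"])) == 0

    def test_order_independent_and_idempotent(self):
        rx = pd.DataFrame(
            {
                "patient_id": ["A", "B", "A"],
                "date": ["2016-03-01", "2016-01-01", "2016-02-01"],
                "drug_name": ["fingolimod"] * 3,
            }
        )
        t = _tables(rx=rx)
        a = cf.find_cases(t["prescriptions"], t["admissions"], t["outpatients"])
        b = cf.find_cases(t["prescriptions"].iloc[::-1], t["admissions"], t["outpatients"])
        pd.testing.assert_frame_equal(a, b)
        assert a.loc[a["patient_id"] == "A", "entry_date"].iloc[0] == pd.Timestamp("2016-02-01")


class TestExclusions:
    def test_reason_counting(self):
        cases = pd.DataFrame({"patient_id": list("ABCD"), "entry_date": pd.to_datetime(["2016-01-01"] * 4)})
        demo = pd.DataFrame(
            {
                "patient_id": list("ABCD"),
                "sex": ["F", "M", "", "F"],
                "birth_year": [1980, 1970, 1960, ""],
                "resident_flag": [1, 0, 1, 1],
            }
        )
        included, report = cf.apply_exclusions(cases, demo)
        assert list(included["patient_id"]) == ["A"]
        assert report["excluded_non_resident"] == 1
        assert report["excluded_missing_demographics"] == 2
        assert report["n_included"] == 1


class TestBuildFeatures:
    def _included(self):
        return pd.DataFrame(
            {
                "patient_id": ["A"],
                "entry_date": pd.to_datetime(["2016-01-01"]),
                "sex_female": [1],
                "birth_year": [1980],
            }
        )

    def test_window_is_half_open(self):
        adm = pd.DataFrame(
            {
                "patient_id": ["A", "A"],
                "admit_date": ["2016-06-30", "2016-07-01"],  # window end is 2016-07-01
                "discharge_date": ["2016-07-02", "2016-07-03"],
                "icd9_codes": ["340", "340"],
                "emergency_flag": [0, 0],
            }
        )
        feats = cf.build_features(self._included(), _tables(adm=adm))
        assert feats["n_admissions"].iloc[0] == 1

    def test_admission_sums(self):
        adm = pd.DataFrame(
            {
                "patient_id": ["A", "A"],
                "admit_date": ["2016-02-01", "2016-03-01"],
                "discharge_date": ["2016-02-04", "2016-03-05"],  # 3 and 4 days
                "icd9_codes": ["340", "486"],
                "emergency_flag": [1, 0],
            }
        )
        feats = cf.build_features(self._included(), _tables(adm=adm))
        row = feats.iloc[0]
        assert row["n_admissions"] == 2
        assert row["total_admission_length"] == 7
        assert row["n_ms_admissions"] == 1
        assert row["n_emergency_admissions"] == 1

    def test_platform_to_high_switch(self):
        rx = pd.DataFrame(
            {
                "patient_id": ["A", "A"],
                "date": ["2016-02-01", "2016-05-01"],
                "drug_name": ["glatiramer acetate", "fingolimod"],
            }
        )
        feats = cf.build_features(self._included(), _tables(rx=rx))
        assert feats["switch_platform_to_high"].iloc[0] == 1
        assert feats["n_rx_platform"].iloc[0] == 1
        assert feats["n_rx_high_efficacy"].iloc[0] == 1

    def test_high_before_platform_is_not_a_switch(self):
        rx = pd.DataFrame(
            {
                "patient_id": ["A", "A"],
                "date": ["2016-02-01", "2016-05-01"],
                "drug_name": ["fingolimod", "glatiramer acetate"],
            }
        )
        feats = cf.build_features(self._included(), _tables(rx=rx))
        assert feats["switch_platform_to_high"].iloc[0] == 0

    def test_unknown_drug_warns_and_is_counted(self):
        rx = pd.DataFrame({"patient_id": ["A"], "date": ["2016-02-01"], "drug_name": ["mystery-drug"]})
        with pytest.warns(UserWarning, match="uncategorized"):
            feats = cf.build_features(self._included(), _tables(rx=rx))
        assert feats["n_rx_other"].iloc[0] == 1

    def test_counts_match_bruteforce_on_simulated_registry(self, small_tables, small_cohort):
        feats = small_cohort["features"].set_index("patient_id")
        rng = np.random.default_rng(0)
        ids = rng.choice(feats.index.to_numpy(), size=min(100, len(feats)), replace=False)
        adm = small_tables["admissions"]
        out = small_tables["outpatients"]
        for pid in ids:
            w0, w1 = feats.loc[pid, "window_start"], feats.loc[pid, "window_end"]
            n_adm = ((adm["patient_id"] == pid) & (adm["admit_date"] >= w0) & (adm["admit_date"] < w1)).sum()
            assert feats.loc[pid, "n_admissions"] == n_adm
            n_rehab = (
                (out["patient_id"] == pid)
                & (out["date"] >= w0)
                & (out["date"] < w1)
                & (out["service_category"] == "rehabilitation")
            ).sum()
            assert feats.loc[pid, "n_out_rehabilitation"] == n_rehab


class TestLabels:
    def _features(self):
        return pd.DataFrame(
            {
                "patient_id": ["A"],
                "window_start": pd.to_datetime(["2016-01-01"]),
                "window_end": pd.to_datetime(["2016-07-01"]),
            }
        )

    @pytest.mark.parametrize("edss,expected", [(3.0, "C1"), (3.5, "C2"), (5.5, "C2"), (6.0, "C3")])
    def test_class_boundaries(self, edss, expected):
        clinical = pd.DataFrame(
            {"patient_id": ["A"], "visit_date": pd.to_datetime(["2016-06-15"]), "edss": [edss], "relapse_flag": [0]}
        )
        labels = cf.label_cohort(self._features(), clinical)
        assert labels["edss_class"].iloc[0] == expected

    def test_relapse_only_assessments_leave_patient_unlabelled(self):
        clinical = pd.DataFrame(
            {"patient_id": ["A"], "visit_date": pd.to_datetime(["2016-06-15"]), "edss": [4.0], "relapse_flag": [1]}
        )
        assert len(cf.label_cohort(self._features(), clinical)) == 0

    def test_equidistant_tie_takes_earlier_assessment(self):
        clinical = pd.DataFrame(
            {
                "patient_id": ["A", "A"],
                "visit_date": pd.to_datetime(["2016-06-21", "2016-07-11"]),  # both 10 days from window end
                "edss": [2.0, 6.5],
                "relapse_flag": [0, 0],
            }
        )
        labels = cf.label_cohort(self._features(), clinical)
        assert labels["edss"].iloc[0] == 2.0

    def test_invalid_edss_rejected(self):
        clinical = pd.DataFrame(
            {"patient_id": ["A"], "visit_date": pd.to_datetime(["2016-06-15"]), "edss": [4.25], "relapse_flag": [0]}
        )
        with pytest.raises(ValueError, match="0.5"):
            cf.label_cohort(self._features(), clinical)

    def test_labels_recover_latent_class_on_simulated_registry(self, small_registry, small_cohort):
        labels = small_cohort["labels"]
        pats = small_registry.patients.set_index("patient_id").loc[labels["patient_id"]].reset_index()
        latent = class_at(pats, labels["assessment_date"].to_numpy())
        assert (labels["edss_class"].to_numpy() == latent).all()


class TestSurvivalSamples:
    def test_transition_time_uses_interval_midpoint(self):
        included = pd.DataFrame({"patient_id": ["A"], "entry_date": pd.to_datetime(["2016-01-01"])})
        labels = pd.DataFrame(
            {
                "patient_id": ["A"],
                "assessment_date": pd.to_datetime(["2016-07-01"]),
                "edss": [2.0],
                "edss_class": ["C1"],
            }
        )
        clinical = pd.DataFrame(
            {
                "patient_id": ["A"] * 3,
                "visit_date": pd.to_datetime(["2016-07-01", "2017-01-01", "2017-07-01"]),
                "edss": [2.0, 2.5, 4.0],
                "relapse_flag": [0, 0, 0],
            }
        )
        samples = cf.build_survival_samples(included, labels, clinical)
        assert len(samples) == 1
        row = samples.iloc[0]
        assert row["event"] == 1
        # onset imputed midway between 2017-01-01 and 2017-07-01
        expected = (pd.Timestamp("2017-04-01") - pd.Timestamp("2016-01-01")).days / 30.4375
        assert row["time_months"] == pytest.approx(expected, abs=0.1)

    def test_no_transition_is_censored_at_last_visit(self):
        included = pd.DataFrame({"patient_id": ["A"], "entry_date": pd.to_datetime(["2016-01-01"])})
        labels = pd.DataFrame(
            {"patient_id": ["A"], "assessment_date": pd.to_datetime(["2016-07-01"]), "edss": [4.0], "edss_class": ["C2"]}
        )
        clinical = pd.DataFrame(
            {
                "patient_id": ["A", "A"],
                "visit_date": pd.to_datetime(["2016-07-01", "2018-01-01"]),
                "edss": [4.0, 5.0],
                "relapse_flag": [0, 0],
            }
        )
        samples = cf.build_survival_samples(included, labels, clinical)
        assert samples["event"].iloc[0] == 0
        assert samples["time_months"].iloc[0] == pytest.approx(731 / 30.4375, abs=0.05)

    def test_top_class_is_excluded_from_risk_set(self):
        included = pd.DataFrame({"patient_id": ["A"], "entry_date": pd.to_datetime(["2016-01-01"])})
        labels = pd.DataFrame(
            {"patient_id": ["A"], "assessment_date": pd.to_datetime(["2016-07-01"]), "edss": [7.0], "edss_class": ["C3"]}
        )
        clinical = pd.DataFrame(
            {"patient_id": ["A"], "visit_date": pd.to_datetime(["2016-07-01"]), "edss": [7.0], "relapse_flag": [0]}
        )
        assert len(cf.build_survival_samples(included, labels, clinical)) == 0


def test_loader_reports_row_of_bad_date(tmp_path, small_registry):
    small_registry.write_csv(tmp_path)
    bad = pd.read_csv(tmp_path / "prescriptions.csv")
    bad.loc[3, "date"] = "not-a-date"
    bad.to_csv(tmp_path / "prescriptions.csv", index=False)
    with pytest.raises(IOError, match="row 3"):
        cf.load_tables(tmp_path)
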