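"""Cohort construction from linked administrative tables.

Implements the case-finding rule used for regional MS surveillance (at least
one MS-specific record in any of the prescription, hospital-discharge or
outpatient databases), residency / missing-demographics exclusions, and the
aggregation of each patient's healthcare utilisation over a 6-month window
into a fixed-length feature vector.  Labels come from a clinical registry of
dated, relapse-free EDSS assessments.

Conventions (documented, since administrative extracts do not fix them):

* windows are half-open ``[start, start + 6 calendar months)`` with day
  clamping at month ends;
* a record contributes iff its (admission) date falls inside the window;
* the class label is the relapse-free assessment nearest to the window end,
  ties broken toward the earlier assessment;
* age is computed as window-start year minus birth year (administrative
  extracts rarely carry full birth dates).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from .catalog import CodeLists, DMTEntry
from .edss import edss_to_class, validate_edss

logger = logging.getLogger(__name__)

_DAYS_PER_MONTH = 30.4375
_RX_COVER_DAYS = 30  # assumed days of therapy covered by one dispensation

#: Numeric model-input columns of the feature matrix, in canonical order.
FEATURE_COLUMNS = [
    "age",
    "sex_female",
    "n_rx_mab",
    "n_rx_oral",
    "n_rx_injectable",
    "n_rx_platform",
    "n_rx_high_efficacy",
    "n_rx_other",
    "therapy_duration_days",
    "switch_platform_to_high",
    "n_admissions",
    "n_ms_admissions",
    "n_emergency_admissions",
    "total_admission_length",
    "n_out_consultation",
    "n_out_diagnostic",
    "n_out_laboratory",
    "n_out_procedure",
    "n_out_therapeutic",
    "n_out_rehabilitation",
    "severe_disability_flag",
]


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

def _parse_dates(df: pd.DataFrame, col: str, table: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise IOError(f"{table}: unparseable date {df[col].iloc[row]!r} in column {col!r} at row {row}")
    return parsed


def load_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the five linked CSVs, parse dates and check basic invariants."""
    indir = Path(indir)
    rx = pd.read_csv(indir / "prescriptions.csv", dtype={"patient_id": str})
    adm = pd.read_csv(indir / "admissions.csv", dtype={"patient_id": str})
    out = pd.read_csv(indir / "outpatients.csv", dtype={"patient_id": str})
    demo = pd.read_csv(indir / "demographics.csv", dtype={"patient_id": str}, keep_default_na=False)
    clinical = pd.read_csv(indir / "clinical_edss.csv", dtype={"patient_id": str})
    rx["date"] = _parse_dates(rx, "date", "prescriptions")
    adm["admit_date"] = _parse_dates(adm, "admit_date", "admissions")
    adm["discharge_date"] = _parse_dates(adm, "discharge_date", "admissions")
    out["date"] = _parse_dates(out, "date", "outpatients")
    clinical["visit_date"] = _parse_dates(clinical, "visit_date", "clinical_edss")
    for name, df, col in (
        ("prescriptions", rx, "patient_id"),
        ("admissions", adm, "patient_id"),
        ("outpatients", out, "patient_id"),
        ("demographics", demo, "patient_id"),
    ):
        empty = df[col].isna() | (df[col].astype(str).str.len() == 0)
        if empty.any():
            row = int(np.flatnonzero(empty.to_numpy())[0])
            raise IOError(f"{name}: empty patient_id at row {row}")
    bad = adm["discharge_date"] < adm["admit_date"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise IOError(f"admissions: discharge before admission at row {row}")
    return {
        "prescriptions": rx,
        "admissions": adm,
        "outpatients": out,
        "demographics": demo,
        "clinical_edss": clinical,
    }


def _codes_list(icd9_codes: pd.Series) -> pd.Series:
    return icd9_codes.fillna("").astype(str).str.split(";")


# ---------------------------------------------------------------------------
# Case-finding and exclusions
# ---------------------------------------------------------------------------

def find_cases(
    prescriptions: pd.DataFrame,
    admissions: pd.DataFrame,
    outpatients: pd.DataFrame,
    code_lists: CodeLists | None = None,
) -> pd.DataFrame:
    """Identify MS cases: at least one MS record in any of the three tables.

    Qualifying records are any DMT prescription, any admission carrying the
    MS diagnosis code among its discharge diagnoses, or any outpatient
    encounter in an MS-specific service category.  Returns one row per
    case-found patient with ``entry_date`` = earliest qualifying record date.
    """
    code_lists = code_lists or CodeLists()
    pieces = []
    if len(prescriptions):
        pieces.append(prescriptions[["patient_id", "date"]])
    if len(admissions):
        has_ms = _codes_list(admissions["icd9_codes"]).map(
            lambda codes: code_lists.ms_icd9_code in codes
        )
        pieces.append(
            admissions.loc[has_ms, ["patient_id", "admit_date"]].rename(columns={"admit_date": "date"})
        )
    if len(outpatients):
        ms_out = outpatients["service_category"].isin(code_lists.ms_outpatient_categories)
        pieces.append(outpatients.loc[ms_out, ["patient_id", "date"]])
    if not pieces:
        return pd.DataFrame({"patient_id": pd.Series(dtype=str), "entry_date": pd.Series(dtype="datetime64[ns]")})
    qualifying = pd.concat(pieces, ignore_index=True)
    cases = (
        qualifying.groupby("patient_id", as_index=False)["date"]
        .min()
        .rename(columns={"date": "entry_date"})
        .sort_values("patient_id", ignore_index=True)
    )
    return cases


def apply_exclusions(
    cases: pd.DataFrame, demographics: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop non-residents and patients with missing sex or birth year.

    Returns the included cases (joined with demographics) and a report
    counting each exclusion reason separately.
    """
    demo = demographics.copy()
    demo["sex"] = demo["sex"].astype(str).str.strip()
    year = pd.to_numeric(demo["birth_year"], errors="coerce")
    demo["birth_year_num"] = year
    merged = cases.merge(demo, on="patient_id", how="left")
    no_demo_row = merged["resident_flag"].isna()
    non_resident = ~no_demo_row & (merged["resident_flag"].astype(float) == 0)
    missing = ~non_resident & (
        no_demo_row
        | ~merged["sex"].isin(["F", "M"])
        | merged["birth_year_num"].isna()
    )
    included = merged[~non_resident & ~missing].copy()
    included["birth_year"] = included["birth_year_num"].astype(int)
    included["sex_female"] = (included["sex"] == "F").astype(int)
    report = {
        "n_case_found": int(len(cases)),
        "excluded_non_resident": int(non_resident.sum()),
        "excluded_missing_demographics": int(missing.sum()),
        "n_included": int(len(included)),
    }
    return included[["patient_id", "entry_date", "sex_female", "birth_year"]].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def _window_end(start: pd.Series, months: int = 6) -> pd.Series:
    return start + pd.DateOffset(months=months)


def _in_window(df, date_col, windows):
    """Inner-join records to per-patient windows and keep in-window rows."""
    merged = df.merge(windows, on="patient_id", how="inner")
    keep = (merged[date_col] >= merged["window_start"]) & (merged[date_col] < merged["window_end"])
    return merged[keep]


def _coverage_days(dates: np.ndarray, window_end: np.ndarray) -> float:
    """Days covered by the union of [date, date+30) intervals, clipped."""
    order = np.argsort(dates)
    d = dates[order]
    nxt = np.append(d[1:], window_end[order][-1:])
    span = np.minimum(np.minimum((nxt - d), _RX_COVER_DAYS), (window_end[order] - d))
    return float(np.maximum(span, 0).sum())


def build_features(
    included: pd.DataFrame,
    tables: dict[str, pd.DataFrame],
    dmt_catalog: dict[str, DMTEntry] | None = None,
    code_lists: CodeLists | None = None,
    window_start: pd.Series | None = None,
    window_months: int = 6,
) -> pd.DataFrame:
    """Aggregate each included patient's records over a 6-month window.

    ``included`` must carry patient_id, entry_date, sex_female, birth_year.
    By default the window opens at the patient's entry date; passing
    ``window_start`` (a per-patient Series aligned with ``included``) allows
    calendar-year windows for whole-population scoring.
    """
    dmt_catalog = dmt_catalog or cat.DEFAULT_DMT_CATALOG
    code_lists = code_lists or CodeLists()
    cat.validate_catalog(dmt_catalog)

    windows = included[["patient_id"]].copy()
    windows["window_start"] = (
        included["entry_date"] if window_start is None else pd.Series(window_start).reset_index(drop=True)
    )
    windows["window_end"] = _window_end(windows["window_start"], window_months)

    feats = included[["patient_id", "sex_female", "birth_year"]].copy().reset_index(drop=True)
    feats["window_start"] = windows["window_start"].to_numpy()
    feats["window_end"] = windows["window_end"].to_numpy()
    feats["age"] = feats["window_start"].dt.year - feats["birth_year"]
    for col in FEATURE_COLUMNS:
        if col not in feats.columns:
            feats[col] = 0
    feats = feats.set_index("patient_id")

    # prescriptions
    rx = _in_window(tables["prescriptions"], "date", windows)
    if len(rx):
        known = rx["drug_name"].isin(dmt_catalog)
        n_unknown = int((~known).sum())
        if n_unknown:
            warnings.warn(
                f"{n_unknown} prescription(s) with drug names absent from the DMT "
                "catalogue counted as uncategorized",
                stacklevel=2,
            )
        feats.loc[:, "n_rx_other"] = rx[~known].groupby("patient_id").size().reindex(feats.index, fill_value=0)
        rxk = rx[known].copy()
        rxk["route"] = rxk["drug_name"].map(lambda d: dmt_catalog[d].route_class)
        rxk["tier"] = rxk["drug_name"].map(lambda d: dmt_catalog[d].efficacy_tier)
        for route, col in ((cat.MAB, "n_rx_mab"), (cat.ORAL, "n_rx_oral"), (cat.INJECTABLE, "n_rx_injectable")):
            feats.loc[:, col] = (
                rxk[rxk["route"] == route].groupby("patient_id").size().reindex(feats.index, fill_value=0)
            )
        for tier, col in ((cat.PLATFORM, "n_rx_platform"), (cat.HIGH_EFFICACY, "n_rx_high_efficacy")):
            feats.loc[:, col] = (
                rxk[rxk["tier"] == tier].groupby("patient_id").size().reindex(feats.index, fill_value=0)
            )
        # platform-to-high switch: some platform dispensation strictly precedes
        # some high-efficacy dispensation within the window
        first_platform = rxk[rxk["tier"] == cat.PLATFORM].groupby("patient_id")["date"].min()
        last_high = rxk[rxk["tier"] == cat.HIGH_EFFICACY].groupby("patient_id")["date"].max()
        both = first_platform.index.intersection(last_high.index)
        switched = both[first_platform.loc[both] < last_high.loc[both]]
        feats.loc[switched, "switch_platform_to_high"] = 1
        # therapy coverage within window (union of 30-day dispensation intervals)
        rx_any = rx.sort_values(["patient_id", "date"])
        cover = rx_any.groupby("patient_id", sort=False).apply(
            lambda g: _coverage_days(
                g["date"].to_numpy().astype("datetime64[D]").astype(int),
                g["window_end"].to_numpy().astype("datetime64[D]").astype(int),
            ),
            include_groups=False,
        )
        feats.loc[:, "therapy_duration_days"] = cover.reindex(feats.index, fill_value=0.0)

    # admissions
    adm = _in_window(tables["admissions"], "admit_date", windows)
    if len(adm):
        adm = adm.copy()
        codes = _codes_list(adm["icd9_codes"])
        adm["ms_related"] = codes.map(lambda c: code_lists.ms_icd9_code in c)
        adm["severe"] = codes.map(lambda c: any(x in code_lists.severe_disability_codes for x in c))
        adm["length"] = (adm["discharge_date"] - adm["admit_date"]).dt.days
        g = adm.groupby("patient_id")
        feats.loc[:, "n_admissions"] = g.size().reindex(feats.index, fill_value=0)
        feats.loc[:, "n_ms_admissions"] = g["ms_related"].sum().reindex(feats.index, fill_value=0).astype(int)
        feats.loc[:, "n_emergency_admissions"] = (
            g["emergency_flag"].sum().reindex(feats.index, fill_value=0).astype(int)
        )
        feats.loc[:, "total_admission_length"] = g["length"].sum().reindex(feats.index, fill_value=0)
        feats.loc[:, "severe_disability_flag"] = (
            g["severe"].any().reindex(feats.index, fill_value=False).astype(int)
        )

    # outpatient encounters
    out = _in_window(tables["outpatients"], "date", windows)
    if len(out):
        counts = out.groupby(["patient_id", "service_category"]).size().unstack(fill_value=0)
        for category in cat.OUTPATIENT_CATEGORIES:
            if category in counts.columns:
                feats.loc[:, f"n_out_{category}"] = counts[category].reindex(feats.index, fill_value=0)

    feats = feats.reset_index()
    cols = ["patient_id", "window_start", "window_end"] + FEATURE_COLUMNS
    feats[FEATURE_COLUMNS] = feats[FEATURE_COLUMNS].astype(float)
    assert (feats["n_ms_admissions"] <= feats["n_admissions"]).all()
    assert (feats["n_emergency_admissions"] <= feats["n_admissions"]).all()
    return feats[cols]


# ---------------------------------------------------------------------------
# Labels and survival samples
# ---------------------------------------------------------------------------

def label_cohort(features: pd.DataFrame, clinical_edss: pd.DataFrame) -> pd.DataFrame:
    """Attach an EDSS class to every patient with a usable clinical assessment.

    Uses the relapse-free assessment nearest to the patient's window end
    (ties resolved toward the earlier assessment).  Patients without any
    eligible assessment are omitted.
    """
    validate_edss(clinical_edss["edss"])
    eligible = clinical_edss[clinical_edss["relapse_flag"].astype(int) == 0]
    merged = eligible.merge(features[["patient_id", "window_end"]], on="patient_id", how="inner")
    if not len(merged):
        return pd.DataFrame(columns=["patient_id", "assessment_date", "edss", "edss_class"])
    merged["gap"] = (merged["visit_date"] - merged["window_end"]).abs()
    merged = merged.sort_values(["patient_id", "gap", "visit_date"], kind="mergesort")
    best = merged.groupby("patient_id", as_index=False).first()
    best["edss_class"] = edss_to_class(best["edss"].to_numpy())
    return best[["patient_id", "visit_date", "edss", "edss_class"]].rename(
        columns={"visit_date": "assessment_date"}
    )


def build_survival_samples(
    included: pd.DataFrame,
    labels: pd.DataFrame,
    clinical_edss: pd.DataFrame,
) -> pd.DataFrame:
    """Time-to-progression samples for the labelled cohort.

    The event is the first transition to a higher EDSS class after the
    labelling assessment, detected from subsequent relapse-free assessments;
    interval-censored onsets are imputed at the midpoint between the last
    assessment in the lower class and the first in the higher class.
    Patients labelled C3 are excluded (absorbing top class); patients with no
    observed transition are censored at their last relapse-free assessment.
    Times are months from entry.
    """
    eligible = clinical_edss[clinical_edss["relapse_flag"].astype(int) == 0].copy()
    eligible["cls_idx"] = pd.Series(edss_to_class(eligible["edss"].to_numpy())).map(
        {"C1": 0, "C2": 1, "C3": 2}
    ).to_numpy()
    base = labels.merge(included[["patient_id", "entry_date"]], on="patient_id")
    base = base[base["edss_class"] != "C3"]
    base["base_idx"] = base["edss_class"].map({"C1": 0, "C2": 1})

    rows = []
    visits = eligible.sort_values(["patient_id", "visit_date"]).groupby("patient_id")
    for _, r in base.iterrows():
        try:
            v = visits.get_group(r["patient_id"])
        except KeyError:
            continue
        after = v[v["visit_date"] >= r["assessment_date"]]
        higher = after[after["cls_idx"] > r["base_idx"]]
        if len(higher):
            first_higher = higher["visit_date"].iloc[0]
            lower_before = after[(after["cls_idx"] <= r["base_idx"]) & (after["visit_date"] < first_higher)]
            last_lower = lower_before["visit_date"].iloc[-1] if len(lower_before) else r["assessment_date"]
            onset = last_lower + (first_higher - last_lower) / 2
            time = (onset - r["entry_date"]).days / _DAYS_PER_MONTH
            event = 1
        else:
            time = (after["visit_date"].iloc[-1] - r["entry_date"]).days / _DAYS_PER_MONTH if len(after) else 0.0
            event = 0
        if time > 0:
            rows.append((r["patient_id"], float(time), event, r["edss_class"]))
    return pd.DataFrame(rows, columns=["patient_id", "time_months", "event", "baseline_class"])
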