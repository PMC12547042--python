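"""Synthetic linked administrative registry for a regional MS population.

Generates the four administrative tables (drug prescriptions, hospital
discharge records, outpatient encounters, demographics) plus a clinical
EDSS sub-registry, all linked by an anonymised patient identifier, with the
statistical structure the downstream pipeline assumes:

* demographic marginals of a regional MS cohort (~64% female, age ~42.5 +- 13.5);
* three latent EDSS classes mixed ~9% / 62% / 29% at entry;
* progression-only class trajectories driven by a proportional-hazards model
  whose log hazard is linear in (standardised age, sex, current class);
* healthcare-utilisation intensities that increase with latent class, giving
  the classifier a learnable signal whose strength is a single dial
  (``signal_strength``; 0 removes all class dependence);
* a clinical sub-registry covering a configurable fraction of case-findable
  patients with 6-monthly EDSS assessments and relapse flags.

All randomness flows from one seed through per-table sub-streams, so a
configuration reproduces its tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from .edss import CLASSES, class_edss_values

_DAYS_PER_MONTH = 30.4375
_PERIOD_MONTHS = 6.0


@dataclass
class SimConfig:
    """Configuration of the synthetic registry.

    Hazard model: a patient currently in class ``c`` progresses to the next
    class with rate (events/month)

        lambda_i(c) = baseline_hazard_rate
                      * exp(w_age * age_std_i + w_sex * female_i + w_c2 * [c == C2])
                      * shape * t**(shape-1)        (shape = 1: exponential)

    where ``age_std = (age - age_mean)/age_sd``.  C3 is absorbing.  Defaults
    are calibrated so the five-year progression probability from C1 is ~0.68.
    """

    n_patients: int = 5000
    study_start: str = "2015-01-01"
    study_end: str = "2021-12-31"
    female_frac: float = 0.64
    age_mean: float = 42.5
    age_sd: float = 13.5
    class_mix: tuple[float, float, float] = (0.09, 0.62, 0.29)
    clinical_subset_frac: float = 0.22
    progression_log_hazard_weights: dict[str, float] = field(
        default_factory=lambda: {"age_std": 0.2, "sex_female": -0.1, "class_c2": -0.27}
    )
    baseline_hazard_rate: float = 0.0188  # events per month from class C1
    hazard_shape: float = 1.0  # Weibull shape; 1.0 = exponential
    dropout_hazard_rate: float = 0.002  # clinical follow-up loss, per month
    signal_strength: float = 1.0
    non_resident_frac: float = 0.03
    missing_demo_frac: float = 0.05
    zero_record_frac: float = 0.02
    untreated_frac: float = 0.10
    relapse_flag_prob: float = 0.10
    entry_spread_months: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (3,) or np.any(mix < 0):
            raise ValueError("class_mix must be 3 non-negative proportions")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1 within 1e-9")
        if not (0 < self.clinical_subset_frac <= 1):
            raise ValueError("clinical_subset_frac must be in (0, 1]")
        for name in ("female_frac", "non_resident_frac", "missing_demo_frac",
                     "zero_record_frac", "untreated_frac", "relapse_flag_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be positive")
        if self.hazard_shape <= 0:
            raise ValueError("hazard_shape must be positive")
        if self.dropout_hazard_rate < 0:
            raise ValueError("dropout_hazard_rate must be non-negative")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ValueError("study_start must precede study_end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "class_mix" in raw:
            raw["class_mix"] = tuple(raw["class_mix"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["class_mix"] = list(d["class_mix"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class Registry:
    """A full simulated registry: latent truth plus the five linked tables."""

    patients: pd.DataFrame  # latent truth, never shown to the pipeline
    prescriptions: pd.DataFrame
    admissions: pd.DataFrame
    outpatients: pd.DataFrame
    demographics: pd.DataFrame
    clinical_edss: pd.DataFrame
    config: SimConfig

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.prescriptions.to_csv(outdir / "prescriptions.csv", index=False)
        self.admissions.to_csv(outdir / "admissions.csv", index=False)
        self.outpatients.to_csv(outdir / "outpatients.csv", index=False)
        self.demographics.to_csv(outdir / "demographics.csv", index=False)
        self.clinical_edss.to_csv(outdir / "clinical_edss.csv", index=False)


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _hazard_multiplier(patients: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """exp(w . x) for the patient-level (class-independent) covariates."""
    w = config.progression_log_hazard_weights
    age_std = (patients["age_entry"].to_numpy() - config.age_mean) / config.age_sd
    female = (patients["sex"] == "F").to_numpy(dtype=float)
    return np.exp(w.get("age_std", 0.0) * age_std + w.get("sex_female", 0.0) * female)


def hazard_rate(patients: pd.DataFrame, config: SimConfig, cls: str) -> np.ndarray:
    """Per-patient progression rate (events/month) out of class ``cls``."""
    if cls == "C3":
        return np.zeros(len(patients))
    w_c2 = config.progression_log_hazard_weights.get("class_c2", 0.0)
    rate = config.baseline_hazard_rate * _hazard_multiplier(patients, config)
    if cls == "C2":
        rate = rate * np.exp(w_c2)
    return rate


def _draw_transition_time(rng: np.random.Generator, rate: np.ndarray, shape: float) -> np.ndarray:
    """Months to next transition under cumulative hazard H(t) = rate * t**shape."""
    e = rng.exponential(size=rate.shape)
    return (e / rate) ** (1.0 / shape)


def simulate_population(config: SimConfig) -> pd.DataFrame:
    """Draw the latent patient population.

    Returns one row per patient: demographics, entry date, entry class, and
    the latent months-from-entry transition times ``t_to_c2`` / ``t_to_c3``
    (``inf`` where not applicable; progression-only, C3 absorbing).
    """
    config.validate()
    rng, = _streams(config.seed, 1)[:1]
    n = config.n_patients
    start = pd.Timestamp(config.study_start)

    sex = np.where(rng.random(n) < config.female_frac, "F", "M")
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 90.0)
    entry_offset_days = rng.integers(0, int(config.entry_spread_months * _DAYS_PER_MONTH) + 1, n)
    entry_date = start + pd.to_timedelta(entry_offset_days, unit="D")
    birth_year = entry_date.year - np.round(age).astype(int)
    entry_class = rng.choice(CLASSES, size=n, p=np.asarray(config.class_mix, dtype=float))

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "birth_year": birth_year,
            "age_entry": age,
            "entry_date": entry_date,
            "entry_class": entry_class,
            "resident_flag": rng.random(n) >= config.non_resident_frac,
            "missing_demo": rng.random(n) < config.missing_demo_frac,
            "zero_record": rng.random(n) < config.zero_record_frac,
            "untreated": rng.random(n) < config.untreated_frac,
        }
    )

    # Latent progression times (months from entry), drawn sequentially so the
    # trajectory is monotone: C1 -> C2 -> C3.
    rate_c1 = hazard_rate(patients, config, "C1")
    rate_c2 = hazard_rate(patients, config, "C2")
    t_to_c2 = np.full(n, np.inf)
    t_to_c3 = np.full(n, np.inf)
    is_c1 = entry_class == "C1"
    is_c2 = entry_class == "C2"
    t_to_c2[is_c1] = _draw_transition_time(rng, rate_c1[is_c1], config.hazard_shape)
    t_to_c3[is_c1] = t_to_c2[is_c1] + _draw_transition_time(
        rng, rate_c2[is_c1], config.hazard_shape
    )
    t_to_c3[is_c2] = _draw_transition_time(rng, rate_c2[is_c2], config.hazard_shape)
    patients["t_to_c2"] = t_to_c2
    patients["t_to_c3"] = t_to_c3

    # Loss to clinical follow-up (months from entry); administrative tables
    # are unaffected — claims keep flowing even when clinic visits stop.
    if config.dropout_hazard_rate > 0:
        patients["dropout_months"] = rng.exponential(1.0 / config.dropout_hazard_rate, n)
    else:
        patients["dropout_months"] = np.inf
    return patients


def class_at(patients: pd.DataFrame, when) -> np.ndarray:
    """Latent EDSS class of each patient at calendar time ``when``.

    ``when`` may be a single timestamp or a per-patient array of timestamps.
    """
    when = pd.to_datetime(when)
    if np.ndim(when) == 0:
        months = (when - patients["entry_date"]).dt.days / _DAYS_PER_MONTH
    else:
        months = (pd.Series(when).to_numpy() - patients["entry_date"].to_numpy()) / np.timedelta64(1, "D") / _DAYS_PER_MONTH
    months = np.asarray(months, dtype=float)
    out = patients["entry_class"].to_numpy().copy()
    out = np.where(months >= patients["t_to_c2"].to_numpy(), "C2", out)
    out = np.where(months >= patients["t_to_c3"].to_numpy(), "C3", out)
    return out


def _period_table(patients: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """One row per (patient, 6-month period) from entry to study end, with the
    latent class at the period start."""
    end = pd.Timestamp(config.study_end)
    active = patients.loc[~patients["zero_record"]].reset_index(drop=True)
    months_follow = (
        (end - active["entry_date"]).dt.days / _DAYS_PER_MONTH
    ).clip(lower=0.0)
    n_periods = np.maximum(1, np.ceil(months_follow / _PERIOD_MONTHS).astype(int))
    idx = np.repeat(np.arange(len(active)), n_periods)
    period_no = np.concatenate([np.arange(k) for k in n_periods])
    tbl = active.iloc[idx].reset_index(drop=True)
    tbl["period_no"] = period_no
    tbl["period_start_months"] = period_no * _PERIOD_MONTHS
    tbl["period_start"] = tbl["entry_date"] + pd.to_timedelta(
        np.round(tbl["period_start_months"] * _DAYS_PER_MONTH).astype(int), unit="D"
    )
    tbl["period_days"] = np.minimum(
        (end - tbl["period_start"]).dt.days + 1, int(_PERIOD_MONTHS * _DAYS_PER_MONTH)
    ).clip(lower=1)
    m = tbl["period_start_months"].to_numpy()
    cls = tbl["entry_class"].to_numpy().copy()
    cls = np.where(m >= tbl["t_to_c2"].to_numpy(), "C2", cls)
    cls = np.where(m >= tbl["t_to_c3"].to_numpy(), "C3", cls)
    tbl["period_class"] = cls
    tbl["class_idx"] = pd.Series(cls).map({"C1": 0, "C2": 1, "C3": 2}).to_numpy()
    return tbl


def _scatter_dates(rng, period_start: pd.Series, period_days: np.ndarray, counts: np.ndarray):
    """Expand per-period counts into per-record uniform dates within the period."""
    idx = np.repeat(np.arange(len(counts)), counts)
    offsets = rng.integers(0, np.repeat(period_days, counts))
    dates = period_start.to_numpy()[idx] + offsets.astype("timedelta64[D]")
    return idx, pd.to_datetime(dates)


def simulate_utilization(
    patients: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the prescription, admission and outpatient tables.

    Intensities depend on the latent class at the start of each patient's
    6-month period, scaled by ``signal_strength`` (0 = class-blind null).
    """
    rng_rx, rng_adm, rng_out = _streams(config.seed + 1, 3)
    s = config.signal_strength
    tbl = _period_table(patients, config)
    cls_idx = tbl["class_idx"].to_numpy()

    # --- prescriptions -----------------------------------------------------
    treated = ~tbl["untreated"].to_numpy()
    # tier state: probability of being on a high-efficacy DMT starts low and
    # rises with the current class; escalation is one-way (platform -> high)
    pat = patients.loc[~patients["zero_record"], ["patient_id", "entry_class"]].reset_index(drop=True)
    entry_idx = pat["entry_class"].map({"C1": 0, "C2": 1, "C3": 2}).to_numpy()
    p_high0 = np.clip(0.05 + 0.40 * s * entry_idx, 0, 0.95)
    start_high = rng_rx.random(len(pat)) < p_high0

    platform_drugs = sorted(d for d, e in cat.DEFAULT_DMT_CATALOG.items() if e.efficacy_tier == cat.PLATFORM)
    high_drugs = sorted(
        d for d, e in cat.DEFAULT_DMT_CATALOG.items()
        if e.efficacy_tier == cat.HIGH_EFFICACY and d != "ofatumumab"  # not yet marketed in-window
    )
    pat_platform_drug = rng_rx.choice(platform_drugs, size=len(pat))
    pat_high_drug = rng_rx.choice(high_drugs, size=len(pat))

    # per-row escalation hazard driven by the current class
    p_switch = np.clip(0.02 + 0.12 * s * cls_idx, 0, 0.9)
    switch_draw = rng_rx.random(len(tbl)) < p_switch
    pat_pos = {pid: i for i, pid in enumerate(pat["patient_id"])}
    row_pat = tbl["patient_id"].map(pat_pos).to_numpy()
    ever_switched = pd.Series(switch_draw).groupby(row_pat).cumsum().to_numpy() > 0
    row_high = start_high[row_pat] | ever_switched

    n_rx = rng_rx.poisson(3.0 * tbl["period_days"].to_numpy() / 182.0) * treated
    idx, dates = _scatter_dates(rng_rx, tbl["period_start"], tbl["period_days"].to_numpy(), n_rx)
    rx_drug = np.where(row_high[idx], pat_high_drug[row_pat[idx]], pat_platform_drug[row_pat[idx]])
    prescriptions = pd.DataFrame(
        {"patient_id": tbl["patient_id"].to_numpy()[idx], "date": dates.strftime("%Y-%m-%d"), "drug_name": rx_drug}
    )

    # --- admissions --------------------------------------------------------
    # exponents capped so extreme signal_strength cannot explode volumes
    adm_rate = 0.25 * np.exp(np.minimum(1.2 * s * cls_idx, 3.0)) * tbl["period_days"].to_numpy() / 182.0
    n_adm = rng_adm.poisson(adm_rate)
    idx, admit = _scatter_dates(rng_adm, tbl["period_start"], tbl["period_days"].to_numpy(), n_adm)
    k = len(idx)
    length = 1 + rng_adm.poisson(1.5 * np.exp(np.minimum(0.6 * s * cls_idx[idx], 1.8)))
    ms_related = rng_adm.random(k) < np.clip(0.20 + 0.25 * s * cls_idx[idx], 0, 1)
    emergency = rng_adm.random(k) < np.clip(0.30 + 0.15 * s * cls_idx[idx], 0, 1)
    severe = rng_adm.random(k) < np.clip(0.01 + 0.70 * s * (cls_idx[idx] == 2), 0, 1)
    severe_codes = rng_adm.choice(sorted(cat.DEFAULT_SEVERE_DISABILITY_CODES), size=k)
    other_codes = rng_adm.choice(["486", "401.9", "250.00", "599.0"], size=k)
    codes = []
    for i in range(k):
        row = [other_codes[i]]
        if ms_related[i]:
            row.insert(rng_adm.integers(0, len(row) + 1), cat.MS_ICD9_CODE)
        if severe[i]:
            row.append(severe_codes[i])
        codes.append(";".join(row))
    admissions = pd.DataFrame(
        {
            "patient_id": tbl["patient_id"].to_numpy()[idx],
            "admit_date": admit.strftime("%Y-%m-%d"),
            "discharge_date": (admit + pd.to_timedelta(length, unit="D")).strftime("%Y-%m-%d"),
            "icd9_codes": codes,
            "emergency_flag": emergency.astype(int),
        }
    )

    # --- outpatient encounters --------------------------------------------
    out_rate = 3.0 * np.exp(np.minimum(0.45 * s * cls_idx, 1.4)) * tbl["period_days"].to_numpy() / 182.0
    n_out = rng_out.poisson(out_rate)
    idx, dates = _scatter_dates(rng_out, tbl["period_start"], tbl["period_days"].to_numpy(), n_out)
    base = np.array([0.09, 0.10, 0.78, 0.01, 0.005, 0.015])  # matches admin service mix
    probs = np.tile(base, (len(idx), 1))
    rehab_boost = 0.22 * s * cls_idx[idx]
    probs[:, 5] += rehab_boost
    probs[:, 2] -= rehab_boost  # reallocate from laboratory services
    cum = np.cumsum(probs, axis=1)
    u = rng_out.random(len(idx))[:, None]
    cat_idx = (u > cum[:, :-1]).sum(axis=1)
    outpatients = pd.DataFrame(
        {
            "patient_id": tbl["patient_id"].to_numpy()[idx],
            "date": dates.strftime("%Y-%m-%d"),
            "service_category": np.array(cat.OUTPATIENT_CATEGORIES)[cat_idx],
        }
    )

    for df in (prescriptions, admissions, outpatients):
        df.sort_values(df.columns.tolist(), inplace=True, kind="mergesort", ignore_index=True)
    return prescriptions, admissions, outpatients


def simulate_demographics(patients: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Demographics table; a configured fraction has sex or birth year blanked."""
    rng, = _streams(config.seed + 2, 1)
    demo = patients[["patient_id", "sex", "birth_year", "resident_flag"]].copy()
    demo["resident_flag"] = demo["resident_flag"].astype(int)
    demo["birth_year"] = demo["birth_year"].astype("object")
    missing = patients["missing_demo"].to_numpy()
    blank_sex = missing & (rng.random(len(demo)) < 0.5)
    blank_year = missing & ~blank_sex
    demo.loc[blank_sex, "sex"] = ""
    demo.loc[blank_year, "birth_year"] = ""
    return demo


def _case_findable_ids(prescriptions, admissions, outpatients) -> pd.Index:
    """MS-specific record holders under the default code lists (internal)."""
    rx = set(prescriptions["patient_id"])
    adm = set(
        admissions.loc[
            admissions["icd9_codes"].str.split(";").map(lambda c: cat.MS_ICD9_CODE in c),
            "patient_id",
        ]
    )
    out = set(
        outpatients.loc[
            outpatients["service_category"].isin(cat.DEFAULT_MS_OUTPATIENT_CATEGORIES),
            "patient_id",
        ]
    )
    return pd.Index(sorted(rx | adm | out))


def simulate_clinical_registry(
    patients: pd.DataFrame,
    config: SimConfig,
    case_findable_ids=None,
) -> pd.DataFrame:
    """Clinical EDSS table for a random sub-cohort of case-findable patients.

    Each enrolled patient gets an assessment every 6 months from entry until
    study end or loss to follow-up; the EDSS score is drawn uniformly from the
    half-point values of the patient's latent class at the visit date, and a
    fraction of visits carries a relapse flag.
    """
    rng, = _streams(config.seed + 3, 1)
    if case_findable_ids is None:
        case_findable_ids = patients.loc[~patients["zero_record"], "patient_id"]
    pool = patients[patients["patient_id"].isin(case_findable_ids)].reset_index(drop=True)
    enrolled = pool[rng.random(len(pool)) < config.clinical_subset_frac].reset_index(drop=True)

    end = pd.Timestamp(config.study_end)
    follow_months = np.minimum(
        (end - enrolled["entry_date"]).dt.days / _DAYS_PER_MONTH,
        enrolled["dropout_months"].to_numpy(),
    )
    n_visits = np.maximum(1, np.floor(follow_months / _PERIOD_MONTHS).astype(int) + 1)
    idx = np.repeat(np.arange(len(enrolled)), n_visits)
    visit_no = np.concatenate([np.arange(k) for k in n_visits])
    months = visit_no * _PERIOD_MONTHS
    visit_date = enrolled["entry_date"].to_numpy()[idx] + (
        np.round(months * _DAYS_PER_MONTH).astype(int).astype("timedelta64[D]")
    )
    cls = enrolled["entry_class"].to_numpy()[idx].copy()
    cls = np.where(months >= enrolled["t_to_c2"].to_numpy()[idx], "C2", cls)
    cls = np.where(months >= enrolled["t_to_c3"].to_numpy()[idx], "C3", cls)
    edss = np.empty(len(idx))
    for c in CLASSES:
        m = cls == c
        vals = class_edss_values(c)
        edss[m] = vals[rng.integers(0, len(vals), m.sum())]
    clinical = pd.DataFrame(
        {
            "patient_id": enrolled["patient_id"].to_numpy()[idx],
            "visit_date": pd.to_datetime(visit_date).strftime("%Y-%m-%d"),
            "edss": edss,
            "relapse_flag": (rng.random(len(idx)) < config.relapse_flag_prob).astype(int),
        }
    )
    clinical.sort_values(["patient_id", "visit_date"], inplace=True, kind="mergesort", ignore_index=True)
    return clinical


def simulate_registry(config: SimConfig) -> Registry:
    """Run the full generator: population, utilisation, demographics, clinic."""
    patients = simulate_population(config)
    rx, adm, out = simulate_utilization(patients, config)
    demo = simulate_demographics(patients, config)
    clinical = simulate_clinical_registry(
        patients, config, case_findable_ids=_case_findable_ids(rx, adm, out)
    )
    return Registry(patients, rx, adm, out, demo, clinical, config)


def analytic_transition_table(
    patients: pd.DataFrame,
    config: SimConfig,
    reference_date,
    horizon_months: float = 60.0,
    patient_ids=None,
) -> np.ndarray:
    """Ground-truth expected class-transition table over a horizon.

    For each patient, uses the latent class at ``reference_date`` and the true
    per-patient hazard to compute the probability of moving to the adjacent
    higher class within the horizon (adjacent-only, C3 absorbing) — the same
    flow rule the projection module applies, evaluated with the generator's
    own rates.  Only valid for the exponential model (hazard_shape == 1),
    where remaining time-to-transition is memoryless.

    Returns a 3x3 matrix of population proportions (rows: current class,
    columns: class at horizon) summing to 1.
    """
    if config.hazard_shape != 1.0:
        raise ValueError("analytic table requires the exponential model (hazard_shape=1)")
    sub = patients if patient_ids is None else patients[patients["patient_id"].isin(patient_ids)]
    sub = sub.reset_index(drop=True)
    cls = class_at(sub, pd.Timestamp(reference_date))
    table = np.zeros((3, 3))
    n = len(sub)
    for ci, c in enumerate(CLASSES):
        m = cls == c
        if not m.any():
            continue
        if c == "C3":
            table[2, 2] += m.sum() / n
            continue
        rate = hazard_rate(sub[m], config, c)
        p_move = 1.0 - np.exp(-rate * horizon_months)
        table[ci, ci + 1] += p_move.sum() / n
        table[ci, ci] += (1.0 - p_move).sum() / n
    return table


def simulate_proportional_hazards(
    n: int,
    beta,
    baseline_rate: float = 0.05,
    censor_time: float = 60.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain proportional-hazards data for oracle checks.

    Covariates X ~ N(0, I); event time ~ Exp(baseline_rate * exp(X beta)),
    administratively censored at ``censor_time``.  Returns (X, time, event).
    """
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = rng.standard_normal((n, beta.size))
    t = rng.exponential(1.0 / (baseline_rate * np.exp(X @ beta)))
    event = (t <= censor_time).astype(int)
    time = np.minimum(t, censor_time)
    # keep times strictly positive
    time = np.maximum(time, 1e-6)
    return X, time, event
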