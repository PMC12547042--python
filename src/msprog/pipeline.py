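"""End-to-end orchestration: registry -> cohort -> models -> projection.

Chains the package's stages exactly the way the standalone CLI commands do,
keeping every intermediate product available for inspection: case-finding
and exclusions, 6-month feature windows, EDSS labels, the class classifier,
the neural Cox progression model, the yearly class distribution, risk
stratification and the 2021 -> 2026 transition projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_features as cf
from . import eval_metrics as em
from . import neural_cox as nc
from . import risk_projection as rp
from .edss import CLASSES, edss_to_class
from .edss_net import ClassifierConfig, TrainedClassifier, predict_classes, train_classifier
from .synthetic_registry import Registry, SimConfig, simulate_registry


def registry_tables(reg: Registry) -> dict[str, pd.DataFrame]:
    """Simulator output with date columns parsed, as the loaders would emit."""
    tables = {
        "prescriptions": reg.prescriptions.copy(),
        "admissions": reg.admissions.copy(),
        "outpatients": reg.outpatients.copy(),
        "demographics": reg.demographics.copy(),
        "clinical_edss": reg.clinical_edss.copy(),
    }
    tables["prescriptions"]["date"] = pd.to_datetime(tables["prescriptions"]["date"])
    tables["admissions"]["admit_date"] = pd.to_datetime(tables["admissions"]["admit_date"])
    tables["admissions"]["discharge_date"] = pd.to_datetime(tables["admissions"]["discharge_date"])
    tables["outpatients"]["date"] = pd.to_datetime(tables["outpatients"]["date"])
    tables["clinical_edss"]["visit_date"] = pd.to_datetime(tables["clinical_edss"]["visit_date"])
    return tables


@dataclass
class PipelineResult:
    included: pd.DataFrame
    exclusion_report: dict
    features: pd.DataFrame
    labels: pd.DataFrame
    classifier: TrainedClassifier
    classification_metrics: dict
    survival_samples: pd.DataFrame
    risk_model: nc.RiskModel
    survival_metrics: dict
    yearly: pd.DataFrame
    profiles: pd.DataFrame
    risk_centroids: np.ndarray
    threshold: float
    transitions: rp.TransitionTable
    extras: dict = field(default_factory=dict)


def current_class_states(
    cohort: pd.DataFrame,
    tables: dict[str, pd.DataFrame],
    classifier: TrainedClassifier,
    reference_year: int,
    years_back: int = 2,
    max_gap_months: float = 12.0,
) -> pd.Series:
    """Class state per patient at mid-``reference_year``.

    The classifier scores 6-month windows opening each 1 January from
    ``reference_year - years_back`` through ``reference_year`` and the
    per-patient maximum class is taken — in a progression-only disease model
    the highest class seen is the current one, and pooling windows sharply
    reduces single-window misclassification.  Clinical EDSS (relapse-free
    assessment nearest the reference, within ``max_gap_months``) overrides
    the classifier wherever available.
    """
    idx_map = {c: i for i, c in enumerate(CLASSES)}
    max_idx = None
    for year in range(reference_year - years_back, reference_year + 1):
        feats = cf.build_features(
            cohort, tables, window_start=pd.Series([pd.Timestamp(f"{year}-01-01")] * len(cohort))
        )
        p = predict_classes(classifier, feats).set_index("patient_id")["predicted_class"].map(idx_map)
        max_idx = p if max_idx is None else np.maximum(max_idx, p)
    pred = max_idx.map({i: c for c, i in idx_map.items()})
    reference_end = pd.Timestamp(f"{reference_year}-01-01") + pd.DateOffset(months=6)
    clinical_edss = tables["clinical_edss"]
    eligible = clinical_edss[clinical_edss["relapse_flag"].astype(int) == 0].copy()
    eligible = eligible[eligible["patient_id"].isin(cohort["patient_id"])]
    eligible["gap"] = (eligible["visit_date"] - reference_end).abs()
    eligible = eligible[eligible["gap"] <= pd.Timedelta(days=max_gap_months * 30.4375)]
    eligible = eligible.sort_values(["patient_id", "gap", "visit_date"], kind="mergesort")
    best = eligible.groupby("patient_id").first()
    clinical_cls = pd.Series(edss_to_class(best["edss"].to_numpy()), index=best.index)
    out = pred.copy()
    out.loc[clinical_cls.index.intersection(out.index)] = clinical_cls
    return out.reindex(cohort["patient_id"]).rename("current_class")


def run_pipeline(
    sim_config: SimConfig,
    clf_config: ClassifierConfig | None = None,
    surv_config: nc.SurvivalModelConfig | None = None,
    horizon_months: float = 60.0,
    reference_year: int = 2021,
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020, 2021),
    n_boot: int = 200,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a freshly simulated registry."""
    reg = simulate_registry(sim_config)
    tables = registry_tables(reg)

    cases = cf.find_cases(tables["prescriptions"], tables["admissions"], tables["outpatients"])
    included, report = cf.apply_exclusions(cases, tables["demographics"])
    features = cf.build_features(included, tables)
    labels = cf.label_cohort(features, tables["clinical_edss"])

    labelled = labels.merge(features, on="patient_id")
    clf_config = clf_config or ClassifierConfig(seed=sim_config.seed)
    classifier = train_classifier(labelled[cf.FEATURE_COLUMNS], labelled["edss_class"], clf_config)
    val_idx = np.asarray(classifier.report["val_idx"])
    val_pred = predict_classes(classifier, labelled.iloc[val_idx][cf.FEATURE_COLUMNS])
    clf_metrics = em.classification_report(
        labelled["edss_class"].iloc[val_idx],
        val_pred["predicted_class"],
        n_boot=n_boot,
        seed=sim_config.seed,
    )

    samples = cf.build_survival_samples(included, labels, tables["clinical_edss"])
    samples = samples.merge(features, on="patient_id")
    surv_config = surv_config or nc.SurvivalModelConfig(seed=sim_config.seed)
    risk_model = nc.train_survival(
        samples[cf.FEATURE_COLUMNS], samples["time_months"], samples["event"], surv_config
    )
    folds = pd.DataFrame(risk_model.fold_reports)
    surv_metrics = {
        "c_index": float(folds["c_index"].mean()),
        "ibs": float(folds["ibs"].mean()),
        "per_fold": risk_model.fold_reports,
    }

    yearly = rp.yearly_distribution(classifier, included, tables, years)

    # projection cohort: patients active in the reference year
    ref_start = pd.Timestamp(f"{reference_year}-01-01")
    active = set()
    for name, col in (("prescriptions", "date"), ("admissions", "admit_date"), ("outpatients", "date")):
        df = tables[name]
        in_year = (df[col] >= ref_start) & (df[col] <= pd.Timestamp(f"{reference_year}-12-31"))
        active |= set(df.loc[in_year, "patient_id"])
    cohort = included[included["patient_id"].isin(active)].reset_index(drop=True)
    ref_features = cf.build_features(cohort, tables, window_start=pd.Series([ref_start] * len(cohort)))
    states = current_class_states(cohort, tables, classifier, reference_year)
    h5 = nc.predict_cumulative_hazard(risk_model, ref_features[cf.FEATURE_COLUMNS], horizon_months)
    profiles = pd.DataFrame(
        {
            "patient_id": ref_features["patient_id"].to_numpy(),
            "current_class": states.to_numpy(),
            "h5": h5,
            "p5": 1.0 - np.exp(-h5),
        }
    )
    # clusters calibrated on patients still able to progress (C3 is absorbing)
    at_risk = (profiles["current_class"] != "C3").to_numpy()
    risk_labels, centroids, threshold = rp.stratify_risk(profiles["h5"].to_numpy(), fit_mask=at_risk)
    profiles["risk_cluster"] = risk_labels
    transitions = rp.project_transitions(profiles, mode="expected")

    result = PipelineResult(
        included, report, features, labels, classifier, clf_metrics,
        samples, risk_model, surv_metrics, yearly, profiles,
        centroids, threshold, transitions,
        extras={"registry": reg, "tables": tables, "reference_year": reference_year},
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the pipeline products as deterministic CSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feats = result.features.copy()
    for col in ("window_start", "window_end"):
        feats[col] = feats[col].dt.strftime("%Y-%m-%d")
    feats.to_csv(outdir / "features.csv", index=False, float_format="%.10g")
    labels = result.labels.copy()
    labels["assessment_date"] = labels["assessment_date"].dt.strftime("%Y-%m-%d")
    labels.to_csv(outdir / "labels.csv", index=False, float_format="%.10g")
    result.yearly.to_csv(outdir / "yearly_distribution.csv", index=False, float_format="%.10g")
    result.profiles.to_csv(outdir / "risk_profiles.csv", index=False, float_format="%.10g")
    pd.DataFrame(result.transitions.matrix, index=CLASSES, columns=CLASSES).to_csv(
        outdir / "transition_table.csv", float_format="%.12g"
    )
    rp.sankey_export(result.transitions).to_csv(outdir / "sankey.csv", index=False, float_format="%.12g")
    metrics = {
        "exclusions": result.exclusion_report,
        "classification": {
            k: v
            for k, v in result.classification_metrics.items()
            if k in ("accuracy", "precision", "recall", "f1", "ci95", "per_class")
        },
        "survival": {"c_index": result.survival_metrics["c_index"], "ibs": result.survival_metrics["ibs"]},
        "risk_threshold": result.threshold,
        "risk_centroids": list(map(float, result.risk_centroids)),
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True, default=float) + "\n")
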