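"""msprog: MS disability estimation and progression forecasting from
routinely collected administrative healthcare data.

The package mirrors a population-level surveillance pipeline: case-finding
and feature construction from linked claims tables, a feed-forward EDSS
class classifier, a hybrid neural-network/Cox survival model with Breslow
baseline hazard, and whole-population risk stratification with a five-year
class-transition projection.  A synthetic registry generator makes every
stage runnable and testable without access to regional data.
"""

from .catalog import DEFAULT_DMT_CATALOG, CodeLists, DMTEntry
from .cohort_features import (
    FEATURE_COLUMNS,
    apply_exclusions,
    build_features,
    build_survival_samples,
    find_cases,
    label_cohort,
    load_tables,
)
from .edss import CLASSES, edss_to_class
from .edss_net import ClassifierConfig, TrainedClassifier, grid_search, predict_classes, train_classifier
from .eval_metrics import (
    classification_report,
    concordance_index,
    integrated_brier_score,
    kaplan_meier,
)
from .neural_cox import (
    RiskModel,
    SurvivalModelConfig,
    breslow_baseline,
    cox_loss,
    predict_cumulative_hazard,
    predict_survival,
    train_survival,
)
from .pipeline import PipelineResult, run_pipeline
from .risk_projection import (
    TransitionTable,
    kmeans_1d,
    project_transitions,
    risk_threshold,
    sankey_export,
    stratify_risk,
    yearly_distribution,
)
from .synthetic_registry import (
    Registry,
    SimConfig,
    simulate_clinical_registry,
    simulate_population,
    simulate_proportional_hazards,
    simulate_registry,
    simulate_utilization,
)

__version__ = "0.1.0"
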