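"""dscqc: automated quality control for DSC-MRI signal-time courses."""

from importlib.resources import files as _files

from .calibration import (
    ThresholdSet,
    apply_thresholds,
    calibrate_kfold,
    crossing_threshold,
    range_thresholds,
)
from .features import (
    GammaFit,
    QualityFeatures,
    extract_features,
    features_to_frame,
    fit_gamma_variate,
    fwhm,
    psr,
    sdnr,
    signal_drop,
)
from .io import DscVolume, QualityMap, load_dsc_volume, make_quality_map
from .metrics import (
    AgreementReport,
    ConfusionTable,
    MetricSet,
    agreement_report,
    binary_metrics,
    cohens_kappa,
    percent_disagreement,
    roc_auc,
)
from .ml import (
    ClassifierSpec,
    CvReport,
    FittedModel,
    compare_classifiers,
    predict_quality,
    train_classifier,
)
from .signal_model import (
    FirstPassSegmentation,
    SignalTimeCourse,
    detect_baseline_end,
    detect_postbolus_start,
    segment_first_pass,
)
from .synthetic import (
    Artifacts,
    CohortSpec,
    CourseParams,
    PhantomSpec,
    TruthRecord,
    TruthRule,
    simulate_cohort,
    simulate_timecourse,
    write_phantom,
)

__version__ = "0.1.0"


def default_thresholds() -> ThresholdSet:
    """The shipped (cohort-specific) default threshold configuration."""
    import yaml

    text = _files("dscqc.data").joinpath("default_thresholds.yaml").read_text()
    return ThresholdSet.from_dict(yaml.safe_load(text))
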