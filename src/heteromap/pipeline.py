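"""End-to-end orchestration: study → aligned → segmented → features → LOPO.

``process_case`` runs the per-case stages (registration if needed, ADC
fallback fit, K-means tumor segmentation, ADC-threshold labeling, ROI
extraction, per-pixel feature matrix).  ``lopo_evaluate`` then performs the
leave-one-patient-out experiment: for every held-out case the feature
selection and the classifier are fitted on the remaining cases only, the
held-out pixels are predicted block-wise, and the predictions are scored
against the ADC-derived labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierConfig, predict_blocks, train_classifier
from .evaluation import EvalReport, confusion, metrics
from .features.matrix import (
    FeatureConfig,
    FeatureMatrix,
    pixel_feature_matrix,
    remove_constant_features,
)
from .registration import RegistrationConfig, align_study
from .segmentation import (
    DEFAULT_ADC_CUTOFF,
    DEFAULT_UNCERTAIN_BAND,
    CellularityLabelMap,
    LABEL_BACKGROUND,
    LABEL_HIGH,
    LABEL_LOW,
    RoiExtraction,
    TumorMask,
    compute_adc,
    extract_roi,
    label_cellularity,
    segment_tumor_kmeans,
)
from .selection import SelectionResult, rfe_cv
from .volume import StudyCase

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ProcessedCase", "LopoResult", "process_case", "lopo_evaluate", "prediction_label_map"]


@dataclass
class PipelineConfig:
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    adc_cutoff: float = DEFAULT_ADC_CUTOFF
    uncertain_band: tuple[float, float] | None = DEFAULT_UNCERTAIN_BAND
    kmeans_k: int = 2
    kinds: tuple[str, ...] = ("svm", "sgd")
    rfe_step: float = 0.1
    rfe_folds: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        if "registration" in kw:
            kw["registration"] = RegistrationConfig(**kw["registration"])
        if "features" in kw:
            fkw = dict(kw["features"])
            if "filters" in fkw:
                from .features.filters import FilterBankConfig

                fkw["filters"] = FilterBankConfig(**fkw["filters"])
            kw["features"] = FeatureConfig(**fkw)
        if "classifier" in kw:
            kw["classifier"] = ClassifierConfig(**kw["classifier"])
        if "kinds" in kw:
            kw["kinds"] = tuple(kw["kinds"])
        if "uncertain_band" in kw and kw["uncertain_band"] is not None:
            kw["uncertain_band"] = tuple(kw["uncertain_band"])
        return cls(**kw)


@dataclass
class ProcessedCase:
    case: StudyCase
    tumor_mask: TumorMask
    labels: CellularityLabelMap       # on the full T2 grid
    roi: RoiExtraction
    feature_matrix: FeatureMatrix


def process_case(case: StudyCase, config: PipelineConfig | None = None) -> ProcessedCase:
    """All per-case stages, producing the case's feature matrix."""
    cfg = config or PipelineConfig()
    if case.alignment == "raw":
        case = align_study(case, cfg.registration)
    case.validate_geometry()
    if case.adc is None:
        logger.info("case %s: no ADC map supplied, fitting one from the DWI series", case.case_id)
        case.adc = compute_adc(case.dwi)
    mask = segment_tumor_kmeans(case.require_b(), k=cfg.kmeans_k, seed=cfg.seed)
    labels = label_cellularity(case.adc, mask, cfg.adc_cutoff, cfg.uncertain_band)
    roi = extract_roi(case.t2, mask)
    sl = tuple(
        slice(o, o + n) for o, n in zip(roi.offset, roi.mask.mask.shape)
    )
    labels_roi = CellularityLabelMap(
        labels.labels[sl], labels.cutoff, labels.uncertain_band
    )
    fm = pixel_feature_matrix(
        roi.t2, roi.mask, labels_roi, cfg.features, case_id=case.case_id
    )
    return ProcessedCase(case, mask, labels, roi, fm)


@dataclass
class LopoResult:
    report: EvalReport
    predictions: dict[str, dict[str, np.ndarray]]   # case -> kind -> labels
    selections: dict[str, dict[str, SelectionResult]]


def _concat(fms: list[FeatureMatrix]) -> FeatureMatrix:
    out = fms[0]
    for f in fms[1:]:
        out = out.concat(f)
    return out


def lopo_evaluate(
    fms: list[FeatureMatrix],
    config: PipelineConfig | None = None,
) -> LopoResult:
    """Leave-one-patient-out experiment over pre-built feature matrices.

    For each held-out case, constant-feature removal, RFE-CV and classifier
    training all see only the remaining cases; the held-out case's pixels
    are then predicted in blocks of 400 and scored against its ADC-derived
    labels.  Undefined metrics (a case with a single true class) are
    reported missing and excluded from the averages.
    """
    cfg = config or PipelineConfig()
    if len(fms) < 2:
        raise ValueError("LOPO needs at least 2 cases")
    ids = [fm.frame["case_id"].iloc[0] for fm in fms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids in cohort")
    rows = []
    predictions: dict[str, dict[str, np.ndarray]] = {}
    selections: dict[str, dict[str, SelectionResult]] = {}
    for i, held in enumerate(ids):
        train = _concat([f for j, f in enumerate(fms) if j != i])
        train = remove_constant_features(train)
        test = fms[i]
        row: dict = {"case_id": held}
        predictions[held] = {}
        selections[held] = {}
        for kind in cfg.kinds:
            sel = rfe_cv(
                train, kind, n_folds=cfg.rfe_folds, step=cfg.rfe_step, seed=cfg.seed
            )
            model = train_classifier(
                train, kind, config=cfg.classifier, seed=cfg.seed,
                feature_names=sel.selected,
            )
            pred = predict_blocks(model, test)
            m = metrics(confusion(pred, test.labels()))
            for name, value in m.as_dict().items():
                row[f"{kind}_{name}"] = np.nan if value is None else value
            predictions[held][kind] = pred
            selections[held][kind] = sel
        rows.append(row)
        logger.info("LOPO: finished case %s", held)
    report = EvalReport.from_rows(rows, cfg.kinds)
    return LopoResult(report, predictions, selections)


def prediction_label_map(
    fm: FeatureMatrix, pred: np.ndarray, roi: RoiExtraction
) -> CellularityLabelMap:
    """Fold block-wise predictions back onto the original T2 grid."""
    lab = np.full(roi.original_shape, LABEL_BACKGROUND, dtype=np.int8)
    z = fm.frame["slice"].to_numpy() + roi.offset[0]
    y = fm.frame["y"].to_numpy() + roi.offset[1]
    x = fm.frame["x"].to_numpy() + roi.offset[2]
    lab[z, y, x] = np.where(np.asarray(pred) == 1, LABEL_HIGH, LABEL_LOW)
    return CellularityLabelMap(lab, cutoff=0.0, uncertain_band=None)
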