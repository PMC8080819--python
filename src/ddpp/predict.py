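"""Linear PFS model on the selected DDPP scalar, plus leave-one-out validation."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_INTENSITY_BASE,
    build_feature_matrix,
    pearson_with_p,
    stepin_select,
    summate,
)
from .datamodel import (
    METHOD_ORDER,
    Channel,
    Cohort,
    DDPPModel,
    DegenerateDataError,
    FeatureMode,
    FoldResult,
    GenePanel,
    PatientRecord,
    SummationMethod,
    ValidationError,
    ValidationReport,
)

__all__ = [
    "RegressionFit",
    "fit_linear",
    "fit_model",
    "patient_scalar",
    "predict_pfs",
    "loo_validate",
]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares of PFS on the DDPP scalar."""

    slope: float
    intercept: float
    n: int
    r: float
    p: float

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


def fit_linear(x: Sequence[float], y_pfs: Sequence[float]) -> RegressionFit:
    """Closed-form OLS: slope = Sxy/Sxx, intercept = mean(y) - slope*mean(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_pfs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 observations to fit, got {n}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateDataError("constant predictor: cannot fit a line")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    r, p = pearson_with_p(x, y)
    return RegressionFit(slope=slope, intercept=intercept, n=n, r=r, p=p)


def fit_model(
    cohort: Cohort,
    panel: GenePanel,
    feature_mode: FeatureMode = FeatureMode.DUAL,
    methods: Sequence[SummationMethod] = METHOD_ORDER,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> DDPPModel:
    """Run the full selection pipeline and fit the linear predictor.

    Censored PFS values enter de-censored (at their censoring time); the
    censoring flag is kept on the patient records for reporting only.
    """
    selection = stepin_select(cohort, panel, feature_mode, methods, base=base)
    x = selection.scalars[(selection.best_k, selection.best_method)]
    fit = fit_linear(x, np.asarray(cohort.pfs, dtype=float))
    return DDPPModel(
        drug=cohort.drug,
        channel=selection.channel,
        feature_mode=selection.feature_mode,
        genes=selection.best_genes,
        method=selection.best_method,
        slope=fit.slope,
        intercept=fit.intercept,
        train_r=fit.r,
        train_p=fit.p,
        n_train=fit.n,
    )


def patient_scalar(
    model: DDPPModel,
    patient: PatientRecord,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> float:
    """Recompute the model's summation scalar X for one patient."""
    missing = patient.missing_genes(model.genes)
    if missing:
        raise ValidationError(
            f"patient {patient.patient_id!r} lacks model genes {missing}"
        )
    from .core import compute_feature  # local import avoids cycle at module load

    features = []
    for gene in model.genes:
        pe = patient.expression[gene]
        intensity = (
            pe.tumor_intensity
            if model.channel is Channel.TUMOR
            else pe.normal_intensity
        )
        features.append(
            compute_feature(
                pe.tumor_intensity,
                pe.normal_intensity,
                intensity,
                model.feature_mode,
                base=base,
            )
        )
    return summate(features, model.method)


def predict_pfs(
    model: DDPPModel,
    patient: PatientRecord,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> float:
    """Predicted PFS in months; negative predictions are returned with a warning."""
    x = patient_scalar(model, patient, base=base)
    predicted = model.slope * x + model.intercept
    if predicted < 0:
        warnings.warn(
            f"predicted PFS {predicted:.3g} months is negative for patient "
            f"{patient.patient_id!r}; reported as-is",
            stacklevel=2,
        )
    return predicted


def loo_validate(
    cohort: Cohort,
    panel: GenePanel,
    feature_mode: FeatureMode = FeatureMode.DUAL,
    methods: Sequence[SummationMethod] = METHOD_ORDER,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> ValidationReport:
    """Leave-one-out validation, refitting the full pipeline on each fold.

    Each fold repeats channel choice, ranking, prefix/method selection and
    regression on the retained patients only, then predicts the left-out
    patient. Degenerate folds are flagged, excluded from the summary, and
    counted. RMSE/MAE over the held-out predictions are the headline numbers;
    in-sample residual RMSE/MAE from the full fit are reported alongside.
    """
    if len(cohort) < 4:
        raise ValidationError(
            f"leave-one-out needs >= 4 patients (each fold keeps >= 3); "
            f"cohort {cohort.drug!r} has {len(cohort)}"
        )
    folds: list[FoldResult] = []
    for patient in cohort.patients:
        rest = cohort.without(patient.patient_id)
        try:
            model = fit_model(rest, panel, feature_mode, methods, base=base)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                predicted = predict_pfs(model, patient, base=base)
        except DegenerateDataError:
            folds.append(
                FoldResult(
                    left_out_id=patient.patient_id,
                    model=None,
                    predicted_pfs=None,
                    observed_pfs=patient.pfs_months,
                    degenerate=True,
                )
            )
            continue
        folds.append(
            FoldResult(
                left_out_id=patient.patient_id,
                model=model,
                predicted_pfs=predicted,
                observed_pfs=patient.pfs_months,
            )
        )

    live = [f for f in folds if not f.degenerate]
    if len(live) < 3:
        raise DegenerateDataError(
            f"only {len(live)} non-degenerate folds; cannot summarize concordance"
        )
    predicted = np.array([f.predicted_pfs for f in live])
    observed = np.array([f.observed_pfs for f in live])
    errors = predicted - observed
    rmse = float(np.sqrt(np.mean(errors**2)))
    mae = float(np.mean(np.abs(errors)))
    try:
        concordance_r, concordance_p = pearson_with_p(predicted, observed)
    except DegenerateDataError:
        concordance_r, concordance_p = math.nan, math.nan

    # in-sample residual errors from the single full-cohort fit
    full_model = fit_model(cohort, panel, feature_mode, methods, base=base)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        insample = np.array(
            [predict_pfs(full_model, p, base=base) for p in cohort.patients]
        )
    res = insample - np.asarray(cohort.pfs, dtype=float)
    return ValidationReport(
        folds=folds,
        concordance_r=concordance_r,
        concordance_p=concordance_p,
        rmse=rmse,
        mae=mae,
        n_degenerate=len(folds) - len(live),
        rmse_insample=float(np.sqrt(np.mean(res**2))),
        mae_insample=float(np.mean(np.abs(res))),
    )
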