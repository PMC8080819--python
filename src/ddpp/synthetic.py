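"""Synthetic paired tumor/normal cohorts with a planted summation signature.

The generator plants a K-gene signature whose summation scalar X is, by
construction, exactly the configured summation of the planted genes'
features, and couples PFS linearly to it: PFS = slope * X + intercept +
Gaussian noise (floored at 0.1 months, a generator artifact). Non-planted
genes get tumor/normal ratios centered at 1 so they carry no signal in
expectation. Every pipeline stage is therefore testable without external
data, and the ground-truth model is emitted alongside the cohort so tests
never reverse-engineer it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DEFAULT_INTENSITY_BASE, FeatureMatrix, pearson_with_p
from .datamodel import (
    Channel,
    Cohort,
    FeatureMode,
    PairedExpression,
    PatientRecord,
    SummationMethod,
    ValidationError,
)
from .panels import PublishedModel

__all__ = ["GeneratorConfig", "generate_cohort", "gaussian_feature_matrix",
           "pfs_only_cohort"]


@dataclass
class GeneratorConfig:
    n_patients: int = 6
    n_genes: int = 100
    planted_genes: Sequence[str] | None = None
    n_planted: int = 8
    planted_method: SummationMethod = SummationMethod.FOLD_ABS
    channel: Channel = Channel.TUMOR
    slope: float | None = None
    intercept: float = 3.0
    noise_sd: float = 0.0
    intensity_log_mean: float = 6.0
    intensity_log_sd: float = 1.0
    scalar_min: float | None = None
    scalar_max: float | None = None
    ratio_log2_sd: float = 0.5
    censor_longest: bool = False
    seed: int = 0
    planted: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.planted_method = SummationMethod(self.planted_method)
        self.channel = Channel(self.channel)
        # Product-type signatures need large scalars: the per-gene feature is
        # the K-th root of the scalar, and it must be big enough (relative to
        # log-base-1.1 intensities) to make realized fold changes, and hence
        # the tumor-vs-normal channel contrast, non-trivial.
        if self.scalar_min is None or self.scalar_max is None:
            if self.planted_method in (SummationMethod.FOLD,
                                       SummationMethod.FOLD_ABS):
                defaults = (5.0e17, 2.0e18)
            else:
                defaults = (2.0, 40.0)
            self.scalar_min = defaults[0] if self.scalar_min is None else self.scalar_min
            self.scalar_max = defaults[1] if self.scalar_max is None else self.scalar_max
        if self.slope is None:
            # keep PFS in a months-like range for the default scalar scale
            self.slope = 10.0 / self.scalar_max
        if self.planted_genes is not None:
            self.planted = list(self.planted_genes)
        else:
            self.planted = [f"SIG{i + 1}" for i in range(self.n_planted)]
        self.n_planted = len(self.planted)
        if self.n_patients < 3:
            raise ValidationError("n_patients must be >= 3")
        if self.n_planted < 1 or self.n_planted > self.n_genes:
            raise ValidationError("need 1 <= planted genes <= n_genes")
        if len(set(self.planted)) != self.n_planted:
            raise ValidationError("planted genes must be unique")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 < self.scalar_min < self.scalar_max:
            raise ValidationError("need 0 < scalar_min < scalar_max")
        # the intensity log floor must keep log_base(I) well away from zero,
        # otherwise planted log-ratios blow up when realizing the features
        if self.intensity_log_mean - 4 * self.intensity_log_sd < math.log(1.5):
            raise ValidationError(
                "intensity_log_mean - 4*intensity_log_sd must exceed log(1.5)"
            )


def _planted_features(
    rng: np.random.Generator, x: np.ndarray, k: int, method: SummationMethod
) -> np.ndarray:
    """(patients, k) feature block whose row-wise summation equals x exactly."""
    n = x.size
    if method in (SummationMethod.FOLD, SummationMethod.FOLD_ABS):
        scale = rng.uniform(0.8, 1.25, size=k)
        root = (x / np.prod(scale)) ** (1.0 / k)
        return scale[None, :] * root[:, None]
    if method is SummationMethod.SUM:
        offsets = rng.normal(0.0, 0.5, size=k)
        offsets -= offsets.mean()
        return x[:, None] / k + offsets[None, :]
    if method is SummationMethod.MEAN:
        offsets = rng.normal(0.0, 0.5, size=k)
        offsets -= offsets.mean()
        return x[:, None] + offsets[None, :]
    # MEDIAN: constant per-gene offsets with zero median keep the row median at x
    offsets = rng.normal(0.0, 0.5, size=k)
    offsets -= np.median(offsets)
    return x[:, None] + offsets[None, :]


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, PublishedModel]:
    """Draw a cohort with a planted signature; return it with its ground truth."""
    rng = np.random.default_rng(config.seed)
    k = config.n_planted
    base = DEFAULT_INTENSITY_BASE
    log_base = math.log(base)

    x = np.sort(rng.uniform(config.scalar_min, config.scalar_max, config.n_patients))
    features = _planted_features(rng, x, k, config.planted_method)

    # realize planted features: pick the channel intensity, back out the ratio
    floor = math.exp(config.intensity_log_mean - 4 * config.intensity_log_sd)
    channel_int = np.maximum(
        np.exp(rng.normal(config.intensity_log_mean, config.intensity_log_sd,
                          size=(config.n_patients, k))),
        floor,
    )
    log2_ratio = features / (np.log(channel_int) / log_base)
    if config.channel is Channel.TUMOR:
        tumor_p = channel_int
        normal_p = channel_int / np.exp2(log2_ratio)
    else:
        normal_p = channel_int
        tumor_p = channel_int * np.exp2(log2_ratio)

    n_noise = config.n_genes - k
    noise_tumor = np.exp(
        rng.normal(config.intensity_log_mean, config.intensity_log_sd,
                   size=(config.n_patients, n_noise))
    )
    noise_ratio = rng.normal(0.0, config.ratio_log2_sd,
                             size=(config.n_patients, n_noise))
    noise_normal = noise_tumor / np.exp2(noise_ratio)

    pfs = config.slope * x + config.intercept
    if config.noise_sd > 0:
        pfs = pfs + rng.normal(0.0, config.noise_sd, size=config.n_patients)
    pfs = np.maximum(pfs, 0.1)

    noise_genes = [f"G{i + 1:05d}" for i in range(n_noise)]
    genes = config.planted + noise_genes
    tumor = np.concatenate([tumor_p, noise_tumor], axis=1)
    normal = np.concatenate([normal_p, noise_normal], axis=1)
    if np.any(tumor <= 0) or np.any(normal <= 0) or not (
        np.all(np.isfinite(tumor)) and np.all(np.isfinite(normal))
    ):
        raise ValidationError("generator produced non-positive or non-finite "
                              "intensities; adjust the config")

    censor_index = int(np.argmax(pfs)) if config.censor_longest else -1
    patients = []
    for i in range(config.n_patients):
        record = PatientRecord(
            patient_id=f"P{i + 1:03d}",
            pfs_months=float(pfs[i]),
            censored=(i == censor_index),
        )
        for j, gene in enumerate(genes):
            record.add_expression(
                PairedExpression(
                    gene=gene,
                    tumor_intensity=float(tumor[i, j]),
                    normal_intensity=float(normal[i, j]),
                )
            )
        patients.append(record)
    cohort = Cohort(drug="synthetic", patients=patients)

    r, p = pearson_with_p(x, pfs)
    truth = PublishedModel(
        drug="synthetic",
        genes=tuple(config.planted),
        method=config.planted_method,
        channel=config.channel,
        slope=config.slope,
        intercept=config.intercept,
        r=r,
        p=p,
        n=config.n_patients,
    )
    return cohort, truth


def gaussian_feature_matrix(
    n_patients: int,
    n_genes: int,
    seed: int,
    *,
    patient_ids: Sequence[str] | None = None,
    channel: Channel = Channel.TUMOR,
) -> FeatureMatrix:
    """Independent standard-normal features — a pure null transcriptome."""
    rng = np.random.default_rng(seed)
    if patient_ids is None:
        patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    return FeatureMatrix(
        channel=channel,
        feature_mode=FeatureMode.DUAL,
        values=rng.standard_normal((n_patients, n_genes)),
        gene_order=[f"G{i + 1:05d}" for i in range(n_genes)],
        patient_order=list(patient_ids),
    )


def pfs_only_cohort(pfs: Sequence[float], drug: str = "synthetic") -> Cohort:
    """A cohort carrying PFS values only (for scans over feature matrices)."""
    patients = [
        PatientRecord(patient_id=f"P{i + 1:03d}", pfs_months=float(v), censored=False)
        for i, v in enumerate(pfs)
    ]
    return Cohort(drug=drug, patients=patients)
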