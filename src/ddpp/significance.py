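"""Random-gene-set null scans, cross-drug specificity tests, discovery scans."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_INTENSITY_BASE,
    FeatureMatrix,
    pearson_columns,
    pearson_with_p,
    _rank_order,
    summate_matrix,
)
from .datamodel import (
    Channel,
    Cohort,
    DDPPModel,
    GeneCorrelation,
    NullScanResult,
    SummationMethod,
    ValidationError,
)
from .predict import patient_scalar

__all__ = [
    "ThresholdSpec",
    "GENERIC_THRESHOLD",
    "match_predictor_threshold",
    "random_null_scan",
    "cross_drug_test",
    "transcriptome_scan",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Significance cut for a null scan: |r| >= min_abs_r AND p <= max_p."""

    min_abs_r: float
    max_p: float

    def __post_init__(self) -> None:
        if not 0 <= self.min_abs_r <= 1:
            raise ValidationError("min_abs_r must be in [0, 1]")
        if not 0 < self.max_p <= 1:
            raise ValidationError("max_p must be in (0, 1]")


#: Methods-style generic cut: |r| >= 0.9 and p <= 0.05.
GENERIC_THRESHOLD = ThresholdSpec(min_abs_r=0.9, max_p=0.05)


def match_predictor_threshold(model_or_r, p: float | None = None) -> ThresholdSpec:
    """Threshold matched to an observed predictor: |r| >= |r_obs|, p <= p_obs."""
    if p is None:
        model: DDPPModel = model_or_r
        return ThresholdSpec(min_abs_r=abs(model.train_r), max_p=model.train_p)
    return ThresholdSpec(min_abs_r=abs(float(model_or_r)), max_p=float(p))


def _distinct_draws(
    rng: np.random.Generator, n_genes: int, panel_size: int, iterations: int
) -> np.ndarray:
    """``iterations`` rows of ``panel_size`` distinct gene indices.

    Sampled with replacement across iterations; rows containing duplicate
    indices are redrawn (cheap for panel_size << n_genes).
    """
    draws = rng.integers(0, n_genes, size=(iterations, panel_size))
    while True:
        sorted_rows = np.sort(draws, axis=1)
        bad = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)
        if not bad.any():
            return draws
        draws[bad] = rng.integers(0, n_genes, size=(int(bad.sum()), panel_size))


def random_null_scan(
    cohort: Cohort,
    transcriptome: FeatureMatrix,
    panel_size: int,
    iterations: int,
    threshold: ThresholdSpec,
    method: SummationMethod,
    seed: int,
    *,
    chunk: int = 20_000,
) -> NullScanResult:
    """Fraction of random gene sets whose summation scalar beats a threshold.

    Each iteration draws ``panel_size`` distinct genes uniformly from the
    transcriptome, collapses their features per patient with ``method``,
    correlates the scalar with PFS and tests |r| >= min_abs_r and
    p <= max_p. Degenerate or overflowing draws count as not significant
    (the denominator stays ``iterations``) and are tallied separately.
    """
    n_genes = len(transcriptome.gene_order)
    if panel_size < 1 or panel_size > n_genes:
        raise ValidationError(
            f"panel_size must be in [1, {n_genes}], got {panel_size}"
        )
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if transcriptome.patient_order != cohort.patient_ids:
        raise ValidationError(
            "transcriptome patient order does not match the cohort"
        )
    method = SummationMethod(method)
    pfs = np.asarray(cohort.pfs, dtype=float)
    rng = np.random.default_rng(seed)

    n_significant = 0
    n_degenerate = 0
    done = 0
    while done < iterations:
        size = min(chunk, iterations - done)
        draws = _distinct_draws(rng, n_genes, panel_size, size)
        # (patients, size, panel_size) feature block -> (patients, size) scalars
        block = transcriptome.values[:, draws]
        if method is SummationMethod.SUM:
            scalars = block.sum(axis=2)
        elif method is SummationMethod.MEAN:
            scalars = block.mean(axis=2)
        elif method is SummationMethod.MEDIAN:
            scalars = np.median(block, axis=2)
        elif method is SummationMethod.FOLD:
            scalars = np.prod(block, axis=2)
        else:
            scalars = np.prod(np.abs(block), axis=2)
        with np.errstate(over="ignore", invalid="ignore"):
            r, p, degenerate = pearson_columns(scalars, pfs)
        overflow = ~np.isfinite(scalars).all(axis=0)
        degenerate = degenerate | overflow
        hits = (
            (np.abs(r) >= threshold.min_abs_r)
            & (p <= threshold.max_p)
            & ~degenerate
        )
        n_significant += int(hits.sum())
        n_degenerate += int(degenerate.sum())
        done += size

    return NullScanResult(
        panel_size=panel_size,
        iterations=iterations,
        min_abs_r=threshold.min_abs_r,
        max_p=threshold.max_p,
        n_significant=n_significant,
        n_degenerate=n_degenerate,
        proportion_significant=n_significant / iterations,
        seed=seed,
        method=method,
    )


def cross_drug_test(
    model: DDPPModel,
    other_cohort: Cohort,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> tuple[float, float]:
    """Apply a frozen model's scalar to another cohort; no refitting.

    Returns the Pearson (r, p) between the frozen scalar and the other
    cohort's PFS. The model is never mutated.
    """
    other_cohort.require_min_size()
    other_cohort.require_genes(model.genes)
    scalars = [patient_scalar(model, p, base=base) for p in other_cohort.patients]
    return pearson_with_p(scalars, np.asarray(other_cohort.pfs, dtype=float))


def transcriptome_scan(
    cohort: Cohort, transcriptome: FeatureMatrix
) -> list[GeneCorrelation]:
    """Univariate (r, p) for every transcriptome gene, ranked by |r|.

    Degenerate (zero-variance) genes are listed last with r = 0.
    """
    cohort.require_min_size()
    if transcriptome.patient_order != cohort.patient_ids:
        raise ValidationError("transcriptome patient order does not match the cohort")
    pfs = np.asarray(cohort.pfs, dtype=float)
    r, p, degenerate = pearson_columns(transcriptome.values, pfs)
    correlations = [
        GeneCorrelation(
            gene=g,
            r=float(r[j]),
            p=float(p[j]),
            channel=transcriptome.channel,
            degenerate=bool(degenerate[j]),
        )
        for j, g in enumerate(transcriptome.gene_order)
    ]
    return _rank_order(correlations)
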