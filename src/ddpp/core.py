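"""Core DDPP machinery.

The per-gene feature is the log2 tumor/normal fold change scaled by the
log base-1.1 intensity of one channel (tumor or normal):

    F = log2(T / N) * log_b(I),   b = 1.1 by default

or, in tumor-only mode, just ``log_b(T)``. Panel genes are ranked by the
absolute Pearson correlation of their feature with PFS; nested prefix subsets
of the ranking are collapsed into one scalar per patient with parameter-free
summations (sum, mean, median, signed product, absolute product), and the
(prefix length, method) cell whose scalar best correlates with PFS wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    METHOD_ORDER,
    MIN_PATIENTS,
    Channel,
    Cohort,
    DegenerateDataError,
    FeatureMode,
    GeneCorrelation,
    GenePanel,
    SummationMethod,
    ValidationError,
)

__all__ = [
    "DEFAULT_INTENSITY_BASE",
    "FeatureMatrix",
    "SelectionCell",
    "SelectionResult",
    "compute_feature",
    "build_feature_matrix",
    "pearson_with_p",
    "pearson_columns",
    "rank_genes",
    "summate",
    "summate_matrix",
    "stepin_select",
]

#: Base of the intensity logarithm in the feature transform.
DEFAULT_INTENSITY_BASE = 1.1


@dataclass
class FeatureMatrix:
    """Patients x genes grid of feature values with explicit orderings."""

    channel: Channel
    feature_mode: FeatureMode
    values: np.ndarray
    gene_order: list[str]
    patient_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_order), len(self.gene_order)):
            raise ValidationError(
                f"feature matrix shape {self.values.shape} inconsistent with "
                f"{len(self.patient_order)} patients x {len(self.gene_order)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix contains non-finite entries")

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_order.index(gene)]

    def select(self, genes: Sequence[str]) -> np.ndarray:
        index = {g: j for j, g in enumerate(self.gene_order)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes absent from feature matrix: {missing}")
        return self.values[:, [index[g] for g in genes]]


def compute_feature(
    tumor: float,
    normal: float,
    channel_intensity: float,
    feature_mode: FeatureMode = FeatureMode.DUAL,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> float:
    """Feature value for one gene of one patient.

    ``channel_intensity`` is the intensity of whichever channel (tumor or
    normal) the model multiplies into the fold change; it is ignored in
    tumor-only mode.
    """
    for label, v in (("tumor", tumor), ("normal", normal),
                     ("channel_intensity", channel_intensity)):
        if not math.isfinite(v) or v <= 0:
            raise ValidationError(f"{label} intensity must be > 0, got {v!r}")
    if FeatureMode(feature_mode) is FeatureMode.TUMOR_ONLY:
        return math.log(tumor) / math.log(base)
    return math.log2(tumor / normal) * (math.log(channel_intensity) / math.log(base))


def build_feature_matrix(
    cohort: Cohort,
    genes: Sequence[str] | GenePanel,
    channel: Channel,
    feature_mode: FeatureMode = FeatureMode.DUAL,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> FeatureMatrix:
    """Feature values for every cohort patient over an ordered gene list."""
    if isinstance(genes, GenePanel):
        gene_order = [genes.resolve(g) for g in genes.genes]
    else:
        gene_order = list(genes)
    channel = Channel(channel)
    feature_mode = FeatureMode(feature_mode)
    cohort.require_genes(gene_order)

    tumor = np.array(
        [[p.expression[g].tumor_intensity for g in gene_order] for p in cohort.patients]
    )
    normal = np.array(
        [[p.expression[g].normal_intensity for g in gene_order] for p in cohort.patients]
    )
    log_base = math.log(base)
    if feature_mode is FeatureMode.TUMOR_ONLY:
        values = np.log(tumor) / log_base
    else:
        intensity = tumor if channel is Channel.TUMOR else normal
        values = np.log2(tumor / normal) * (np.log(intensity) / log_base)
    return FeatureMatrix(
        channel=channel,
        feature_mode=feature_mode,
        values=values,
        gene_order=gene_order,
        patient_order=cohort.patient_ids,
    )


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"x and y must be equal-length vectors, got "
                              f"{x.shape} vs {y.shape}")
    n = x.size
    if n < MIN_PATIENTS:
        raise ValidationError(f"need at least {MIN_PATIENTS} observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateDataError("zero variance input to Pearson correlation")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    p = _t_two_sided(r, n)
    return r, p


def _t_two_sided(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def pearson_columns(
    matrix: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Pearson of each column of ``matrix`` against ``y``.

    Returns ``(r, p, degenerate)``; degenerate (zero-variance) columns get
    r = 0, p = 1. Constant ``y`` raises — a correlation against a constant
    outcome is meaningless everywhere, not just in one column.
    """
    matrix = np.asarray(matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if matrix.shape[0] != n:
        raise ValidationError("matrix rows must match outcome length")
    if n < MIN_PATIENTS:
        raise ValidationError(f"need at least {MIN_PATIENTS} observations, got {n}")
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0.0:
        raise DegenerateDataError("constant outcome (zero variance PFS)")
    xc = matrix - matrix.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    degenerate = ~(np.isfinite(sxx) & (sxx > 0) & np.isfinite(sxy))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    r = np.clip(r, -1.0, 1.0)
    r[degenerate] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.where(np.isfinite(t), t, 0), n - 2))
    p[degenerate] = 1.0
    return r, p, degenerate


def _rank_order(correlations: Iterable[GeneCorrelation]) -> list[GeneCorrelation]:
    # decreasing |r|; ties by ascending p, then symbol; degenerate genes last
    return sorted(
        correlations,
        key=lambda c: (c.degenerate, -abs(c.r), c.p, c.gene),
    )


def rank_genes(
    cohort: Cohort,
    panel: GenePanel,
    feature_mode: FeatureMode = FeatureMode.DUAL,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> tuple[Channel, list[GeneCorrelation]]:
    """Choose the intensity channel and rank panel genes by |r| with PFS.

    In dual mode, per-gene correlations are computed under both channels and
    the channel holding the single most-correlated gene (max |r|, ties by
    smaller p, tumor preferred on exact ties) is applied to all genes. In
    tumor-only mode there is no channel choice.
    """
    cohort.require_min_size()
    feature_mode = FeatureMode(feature_mode)
    pfs = np.asarray(cohort.pfs, dtype=float)

    if feature_mode is FeatureMode.TUMOR_ONLY:
        channels = [Channel.TUMOR]
    else:
        channels = [Channel.TUMOR, Channel.NORMAL]

    per_channel: dict[Channel, list[GeneCorrelation]] = {}
    for channel in channels:
        fm = build_feature_matrix(cohort, panel, channel, feature_mode, base=base)
        r, p, degenerate = pearson_columns(fm.values, pfs)
        per_channel[channel] = [
            GeneCorrelation(
                gene=g, r=float(r[j]), p=float(p[j]), channel=channel,
                degenerate=bool(degenerate[j]),
            )
            for j, g in enumerate(fm.gene_order)
        ]

    def best_of(channel: Channel) -> GeneCorrelation:
        return _rank_order(per_channel[channel])[0]

    chosen = channels[0]
    if len(channels) == 2:
        bt, bn = best_of(Channel.TUMOR), best_of(Channel.NORMAL)
        if (bn.degenerate, -abs(bn.r), bn.p) < (bt.degenerate, -abs(bt.r), bt.p):
            chosen = Channel.NORMAL
    ranking = _rank_order(per_channel[chosen])
    if all(c.degenerate for c in ranking):
        raise DegenerateDataError(
            f"every panel gene has a degenerate feature for cohort {cohort.drug!r}"
        )
    return chosen, ranking


def summate(features: Sequence[float], method: SummationMethod) -> float:
    """Collapse one patient's per-gene features into a scalar."""
    values = np.asarray(features, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot summate an empty feature vector")
    method = SummationMethod(method)
    with np.errstate(over="ignore"):
        if method is SummationMethod.SUM:
            out = float(values.sum())
        elif method is SummationMethod.MEAN:
            out = float(values.mean())
        elif method is SummationMethod.MEDIAN:
            out = float(np.median(values))
        elif method is SummationMethod.FOLD:
            out = float(np.prod(values))
        else:  # FOLD_ABS
            out = float(np.prod(np.abs(values)))
    if not math.isfinite(out):
        raise ValidationError(f"summation {method.value} overflowed to {out}")
    return out


def summate_matrix(features: np.ndarray, method: SummationMethod) -> np.ndarray:
    """Row-wise summation of a patients x genes feature block."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] == 0:
        raise ValidationError("feature block must be 2-D with >= 1 gene")
    method = SummationMethod(method)
    if method is SummationMethod.SUM:
        return features.sum(axis=1)
    if method is SummationMethod.MEAN:
        return features.mean(axis=1)
    if method is SummationMethod.MEDIAN:
        return np.median(features, axis=1)
    if method is SummationMethod.FOLD:
        return np.prod(features, axis=1)
    return np.prod(np.abs(features), axis=1)


@dataclass(frozen=True)
class SelectionCell:
    """One (prefix length, summation method) cell of the selection table."""

    k: int
    method: SummationMethod
    r: float
    p: float
    degenerate: bool = False


@dataclass
class SelectionResult:
    """Full step-in table plus the winning cell."""

    drug: str
    channel: Channel
    feature_mode: FeatureMode
    ranking: list[GeneCorrelation]
    cells: list[SelectionCell]
    best_k: int
    best_method: SummationMethod
    best_r: float
    best_p: float
    scalars: dict = field(default_factory=dict, repr=False)

    @property
    def best_genes(self) -> list[str]:
        return [c.gene for c in self.ranking[: self.best_k]]

    def cell(self, k: int, method: SummationMethod) -> SelectionCell:
        method = SummationMethod(method)
        for c in self.cells:
            if c.k == k and c.method is method:
                return c
        raise KeyError((k, method))

    def to_rows(self) -> list[tuple[int, str, float, float]]:
        return [(c.k, c.method.value, c.r, c.p) for c in self.cells]


def stepin_select(
    cohort: Cohort,
    panel: GenePanel,
    feature_mode: FeatureMode = FeatureMode.DUAL,
    methods: Sequence[SummationMethod] = METHOD_ORDER,
    *,
    base: float = DEFAULT_INTENSITY_BASE,
) -> SelectionResult:
    """Rank panel genes, then scan every (prefix, method) summation cell.

    For K = 1..len(panel) the top-K prefix of the ranking is collapsed per
    patient by each summation method and the scalar is correlated with PFS;
    the cell with the largest |r| wins (ties: smaller K, then the fixed
    method order sum, mean, median, fold, fold_abs).
    """
    cohort.require_min_size()
    methods = [SummationMethod(m) for m in methods]
    if not methods:
        raise ValidationError("at least one summation method is required")
    method_index = {m: i for i, m in enumerate(METHOD_ORDER)}

    channel, ranking = rank_genes(cohort, panel, feature_mode, base=base)
    ordered_genes = [c.gene for c in ranking]
    fm = build_feature_matrix(cohort, ordered_genes, channel, feature_mode, base=base)
    pfs = np.asarray(cohort.pfs, dtype=float)

    cells: list[SelectionCell] = []
    scalars: dict[tuple[int, SummationMethod], np.ndarray] = {}
    for k in range(1, len(ordered_genes) + 1):
        block = fm.values[:, :k]
        for method in methods:
            x = summate_matrix(block, method)
            if not np.all(np.isfinite(x)):
                cells.append(SelectionCell(k, method, 0.0, 1.0, degenerate=True))
                continue
            scalars[(k, method)] = x
            try:
                r, p = pearson_with_p(x, pfs)
            except DegenerateDataError:
                cells.append(SelectionCell(k, method, 0.0, 1.0, degenerate=True))
                continue
            cells.append(SelectionCell(k, method, r, p))

    live = [c for c in cells if not c.degenerate]
    if not live:
        raise DegenerateDataError(
            f"every (K, method) cell is degenerate for cohort {cohort.drug!r}"
        )
    best = min(live, key=lambda c: (-abs(c.r), c.k, method_index[c.method]))
    return SelectionResult(
        drug=cohort.drug,
        channel=channel,
        feature_mode=FeatureMode(feature_mode),
        ranking=ranking,
        cells=cells,
        best_k=best.k,
        best_method=best.method,
        best_r=best.r,
        best_p=best.p,
        scalars=scalars,
    )
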