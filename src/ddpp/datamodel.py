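"""Domain types for paired tumor/normal expression cohorts and fitted predictors.

All types are plain dataclasses with eager invariant checks: intensities must
be strictly positive (the feature transform takes logs), gene symbols are
case-sensitive and unique within a patient, and any cohort used for model
fitting must contain at least three patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Channel",
    "FeatureMode",
    "SummationMethod",
    "ValidationError",
    "DegenerateDataError",
    "PairedExpression",
    "PatientRecord",
    "Cohort",
    "GenePanel",
    "GeneCorrelation",
    "DDPPModel",
    "ValidationReport",
    "FoldResult",
    "NullScanResult",
    "MIN_PATIENTS",
]

#: Minimum cohort size for any model-fitting operation.
MIN_PATIENTS = 3


class ValidationError(ValueError):
    """Raised when domain invariants are violated."""


class DegenerateDataError(ValidationError):
    """Raised when a computation is undefined (zero variance, empty input)."""


class Channel(str, Enum):
    """Which intensity multiplies the log2 fold change in the feature."""

    TUMOR = "tumor"
    NORMAL = "normal"


class FeatureMode(str, Enum):
    """Dual-biopsy feature (fold change x intensity) or tumor-intensity-only."""

    DUAL = "dual"
    TUMOR_ONLY = "tumor_only"


class SummationMethod(str, Enum):
    """Parameter-free summations collapsing per-gene features into one scalar."""

    SUM = "sum"
    MEAN = "mean"
    MEDIAN = "median"
    FOLD = "fold"
    FOLD_ABS = "fold_abs"


#: Deterministic method order used to break best-cell ties.
METHOD_ORDER = (
    SummationMethod.SUM,
    SummationMethod.MEAN,
    SummationMethod.MEDIAN,
    SummationMethod.FOLD,
    SummationMethod.FOLD_ABS,
)


@dataclass(frozen=True)
class PairedExpression:
    """Measured tumor and matched-normal intensity (RFU) of one gene."""

    gene: str
    tumor_intensity: float
    normal_intensity: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")
        for label, value in (
            ("tumor_intensity", self.tumor_intensity),
            ("normal_intensity", self.normal_intensity),
        ):
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"{label} for gene {self.gene!r} must be finite and > 0, "
                    f"got {value!r}"
                )


@dataclass
class PatientRecord:
    """One patient: identifier, PFS in months, censoring flag, expression."""

    patient_id: str
    pfs_months: float
    censored: bool
    expression: dict[str, PairedExpression] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        if not math.isfinite(self.pfs_months) or self.pfs_months <= 0:
            raise ValidationError(
                f"pfs_months for patient {self.patient_id!r} must be finite "
                f"and > 0, got {self.pfs_months!r}"
            )
        if isinstance(self.expression, Iterable) and not isinstance(
            self.expression, dict
        ):
            items = list(self.expression)
            self.expression = {}
            for pe in items:
                self.add_expression(pe)

    def add_expression(self, pe: PairedExpression) -> None:
        if pe.gene in self.expression:
            raise ValidationError(
                f"duplicate gene {pe.gene!r} for patient {self.patient_id!r}"
            )
        self.expression[pe.gene] = pe

    def genes(self) -> set[str]:
        return set(self.expression)

    def missing_genes(self, genes: Iterable[str]) -> list[str]:
        return sorted(g for g in genes if g not in self.expression)


@dataclass
class Cohort:
    """Patients treated with one drug, sharing a gene universe."""

    drug: str
    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def pfs(self) -> list[float]:
        return [p.pfs_months for p in self.patients]

    def gene_universe(self) -> set[str]:
        """Genes present in every patient of the cohort."""
        if not self.patients:
            return set()
        universe = set(self.patients[0].expression)
        for p in self.patients[1:]:
            universe &= set(p.expression)
        return universe

    def require_min_size(self, minimum: int = MIN_PATIENTS) -> None:
        if len(self.patients) < minimum:
            raise ValidationError(
                f"cohort {self.drug!r} has {len(self.patients)} patients; "
                f"at least {minimum} are required for model fitting"
            )

    def require_genes(self, genes: Iterable[str]) -> None:
        missing: dict[str, list[str]] = {}
        for p in self.patients:
            m = p.missing_genes(genes)
            if m:
                missing[p.patient_id] = m
        if missing:
            detail = "; ".join(f"{pid}: {m}" for pid, m in sorted(missing.items()))
            raise ValidationError(f"cohort missing panel genes ({detail})")

    def without(self, patient_id: str) -> "Cohort":
        """Copy of the cohort with one patient removed (leave-one-out)."""
        kept = [p for p in self.patients if p.patient_id != patient_id]
        if len(kept) == len(self.patients):
            raise ValidationError(f"no patient {patient_id!r} in cohort")
        return Cohort(drug=self.drug, patients=kept)


@dataclass
class GenePanel:
    """Ordered drug-specific key-gene list with an explicit alias map.

    ``aliases`` maps alternative (e.g. protein) names onto the symbols used in
    the expression data; resolution is exact, never fuzzy.
    """

    drug: str
    genes: list[str]
    source: str = ""
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"panel for {self.drug!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"panel for {self.drug!r} has duplicate genes")
        if any(not g for g in self.genes):
            raise ValidationError("panel gene symbols must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)

    def resolve(self, symbol: str) -> str:
        """Map an alias onto the data symbol; unknown symbols pass through."""
        return self.aliases.get(symbol, symbol)


@dataclass(frozen=True)
class GeneCorrelation:
    """Univariate Pearson association of one gene's feature with PFS."""

    gene: str
    r: float
    p: float
    channel: Channel
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"|r| must be <= 1, got {self.r}")


@dataclass
class DDPPModel:
    """A fitted predictor: feature recipe, gene prefix, summation, and line."""

    drug: str
    channel: Channel
    feature_mode: FeatureMode
    genes: list[str]
    method: SummationMethod
    slope: float
    intercept: float
    train_r: float
    train_p: float
    n_train: int

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.feature_mode = FeatureMode(self.feature_mode)
        self.method = SummationMethod(self.method)
        if not self.genes:
            raise ValidationError("model must have at least one gene")
        if abs(self.train_r) > 1 + 1e-12:
            raise ValidationError(f"|train_r| must be <= 1, got {self.train_r}")
        if self.n_train < MIN_PATIENTS:
            raise ValidationError(
                f"n_train must be >= {MIN_PATIENTS}, got {self.n_train}"
            )


@dataclass
class FoldResult:
    """One leave-one-out fold: the refitted model and its held-out prediction."""

    left_out_id: str
    model: DDPPModel | None
    predicted_pfs: float | None
    observed_pfs: float
    degenerate: bool = False


@dataclass
class ValidationReport:
    """Leave-one-out summary: concordance, RMSE, MAE, per-fold details."""

    folds: list[FoldResult]
    concordance_r: float
    concordance_p: float
    rmse: float
    mae: float
    n_degenerate: int = 0
    rmse_insample: float | None = None
    mae_insample: float | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.mae < 0:
            raise ValidationError("rmse and mae must be non-negative")


@dataclass
class NullScanResult:
    """Outcome of a random-gene-set significance scan."""

    panel_size: int
    iterations: int
    min_abs_r: float
    max_p: float
    n_significant: int
    n_degenerate: int
    proportion_significant: float
    seed: int
    method: SummationMethod

    def __post_init__(self) -> None:
        if not 0 <= self.proportion_significant <= 1:
            raise ValidationError("proportion_significant must be in [0, 1]")


def as_patient_order(patients: Sequence[PatientRecord]) -> list[str]:
    return [p.patient_id for p in patients]


def expression_map(records: Iterable[PairedExpression]) -> Mapping[str, PairedExpression]:
    out: dict[str, PairedExpression] = {}
    for pe in records:
        if pe.gene in out:
            raise ValidationError(f"duplicate gene {pe.gene!r}")
        out[pe.gene] = pe
    return out
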