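from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ddpp.datamodel import Cohort, GenePanel, PairedExpression, PatientRecord
from ddpp.synthetic import GeneratorConfig, generate_cohort


def make_patient(pid: str, pfs: float, expr: dict[str, tuple[float, float]],
                 censored: bool = False) -> PatientRecord:
    record = PatientRecord(patient_id=pid, pfs_months=pfs, censored=censored)
    for gene, (t, n) in expr.items():
        record.add_expression(
            PairedExpression(gene=gene, tumor_intensity=t, normal_intensity=n)
        )
    return record


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Four patients x three genes with hand-picked intensities."""
    rows = {
        "A": (4.0, {"G1": (200.0, 100.0), "G2": (50.0, 100.0), "G3": (120.0, 120.0)}),
        "B": (8.0, {"G1": (400.0, 100.0), "G2": (60.0, 110.0), "G3": (90.0, 100.0)}),
        "C": (2.0, {"G1": (150.0, 100.0), "G2": (55.0, 95.0), "G3": (130.0, 110.0)}),
        "D": (6.0, {"G1": (300.0, 120.0), "G2": (70.0, 105.0), "G3": (100.0, 140.0)}),
    }
    return Cohort(
        drug="toy",
        patients=[make_patient(pid, pfs, expr) for pid, (pfs, expr) in rows.items()],
    )


@pytest.fixture
def tiny_panel() -> GenePanel:
    return GenePanel(drug="toy", genes=["G1", "G2", "G3"])


@pytest.fixture
def planted_cohort():
    """Noise-free fold_abs signature: cohort, ground truth, and full panel."""
    config = GeneratorConfig(seed=1, n_genes=40, noise_sd=0.0)
    cohort, truth = generate_cohort(config)
    panel = GenePanel(drug="synthetic", genes=sorted(cohort.gene_universe()))
    return cohort, truth, panel


# Per-gene Pearson correlations with PFS for the 17-gene mTOR panel, as
# printed in the source study's results (n = 6 everolimus patients).
EVEROLIMUS_PRINTED = [
    ("AKT2", 0.75, 0.087),
    ("TSC1", 0.74, 0.094),
    ("FKB-12", -0.67, 0.149),
    ("TSC2", 0.63, 0.178),
    ("RPTOR", 0.61, 0.198),
    ("RHEB", -0.49, 0.325),
    ("PIK3CA", 0.43, 0.4),
    ("PIK3CB", -0.41, 0.414),
    ("AKT1", -0.35, 0.496),
    ("MLST8", -0.34, 0.509),
    ("VEGFA", 0.27, 0.604),
    ("HIF1", 0.27, 0.606),
    ("PTEN", -0.16, 0.759),
    ("4EBP1", -0.16, 0.77),
    ("RICTOR", 0.14, 0.788),
    ("MTOR", 0.13, 0.807),
    ("S6K1", -0.04, 0.936),
]

# Printed per-gene correlations for the 12-gene immunotherapy panel (n = 3).
IO_PRINTED = [
    ("TLR-4", -0.99, 0.103),
    ("PDL-2", 0.97, 0.143),
    ("PDL-1", 0.90, 0.294),
    ("CD16", 0.77, 0.445),
    ("CTLA-4", 0.60, 0.588),
    ("CD28", -0.50, 0.665),
    ("CD80", -0.49, 0.67),
    ("CD86", -0.42, 0.721),
    ("LAG-3", 0.34, 0.776),
    ("CD8A", -0.30, 0.803),
    ("FOXP3", -0.21, 0.862),
    ("PD-1", -0.18, 0.882),
]
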