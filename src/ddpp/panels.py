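"""Packaged drug gene panels, published predictor equations, clinical fixture."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .datamodel import (
    Channel,
    Cohort,
    GenePanel,
    SummationMethod,
    ValidationError,
)
from . import io as ddpp_io

__all__ = [
    "PublishedModel",
    "available_drugs",
    "get_panel",
    "published_model",
    "clinical_cohorts",
]


@dataclass(frozen=True)
class PublishedModel:
    """A printed predictor equation: Y = slope * X + intercept."""

    drug: str
    genes: tuple[str, ...]
    method: SummationMethod
    channel: Channel
    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


def _load_json(name: str):
    ref = resources.files("ddpp").joinpath("data", name)
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _normalize(drug: str) -> str:
    return drug.strip().lower().replace("_", "-").replace(" ", "-")


_KEY_ALIASES = {
    "anti-pd-1": "anti-pd1",
    "anti-pd-1/pdl-1": "anti-pd1",
    "io": "anti-pd1",
    "fgfr-inhibitor": "fgfr",
    "fgfr-inhibitors": "fgfr",
}


def _resolve_key(drug: str, known: list[str]) -> str:
    key = _normalize(drug)
    key = _KEY_ALIASES.get(key, key)
    if key not in known:
        raise ValidationError(
            f"unknown drug {drug!r}; available: {sorted(known)}"
        )
    return key


def available_drugs() -> list[str]:
    return sorted(_load_json("panels.json"))


def get_panel(drug: str) -> GenePanel:
    """The full literature key-gene panel for one of the packaged drugs."""
    raw = _load_json("panels.json")
    key = _resolve_key(drug, list(raw))
    entry = raw[key]
    return GenePanel(
        drug=key,
        genes=list(entry["genes"]),
        source=entry.get("source", ""),
        aliases=dict(entry.get("aliases", {})),
    )


def published_model(drug: str) -> PublishedModel:
    """The printed equation (slope, intercept, genes, method, channel)."""
    raw = _load_json("published_models.json")
    key = _resolve_key(drug, list(raw))
    entry = raw[key]
    return PublishedModel(
        drug=key,
        genes=tuple(entry["genes"]),
        method=SummationMethod(entry["method"]),
        channel=Channel(entry["channel"]),
        slope=float(entry["slope"]),
        intercept=float(entry["intercept"]),
        r=float(entry["r"]),
        p=float(entry["p"]),
        n=int(entry["n"]),
    )


def clinical_cohorts() -> dict[str, Cohort]:
    """Per-drug cohorts from the packaged clinical table (no expression)."""
    ref = resources.files("ddpp").joinpath("data", "winther_clinical.csv")
    with resources.as_file(ref) as path:
        return ddpp_io.read_clinical_table(path)
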