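"""Gravimetric sorption analysis of hydrogels.

Four masses characterize a sample: the initial wet and dry (xerogel)
weights and the wet and re-dried weights after a swelling bath.  From
them follow the water content, swelling degree (SD), water absorption
capacity (WA) and hydrolytic degradation (HD), all as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass
class WeightRecord:
    """Gravimetric masses (g); fields a formula does not need may be None."""

    initial_wet: float | None = None
    initial_dry: float | None = None
    swollen_wet: float | None = None
    swollen_dry: float | None = None
    temperature_c: float | None = None
    hydrogel_type: str | None = None

    def __post_init__(self):
        for name in ("initial_wet", "initial_dry",
                     "swollen_wet", "swollen_dry"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DataError(f"{name} must be positive, got {v}")

    def _require(self, *names):
        for name in names:
            if getattr(self, name) is None:
                raise DataError(f"weight record is missing {name}")


def water_content(rec: WeightRecord) -> float:
    """Water content (%) = 100 · (W_initial,wet − W_initial,dry) / W_initial,wet."""
    rec._require("initial_wet", "initial_dry")
    if rec.initial_dry > rec.initial_wet:
        raise DataError("initial dry weight exceeds initial wet weight")
    return 100.0 * (rec.initial_wet - rec.initial_dry) / rec.initial_wet


def swelling_degree(rec: WeightRecord) -> float:
    """SD (%) = 100 · (W_swollen,wet − W_initial,dry) / W_initial,dry."""
    rec._require("swollen_wet", "initial_dry")
    return 100.0 * (rec.swollen_wet - rec.initial_dry) / rec.initial_dry


def water_absorption(rec: WeightRecord) -> float:
    """WA (%) = 100 · (W_swollen,wet − W_swollen,dry) / W_swollen,dry."""
    rec._require("swollen_wet", "swollen_dry")
    return 100.0 * (rec.swollen_wet - rec.swollen_dry) / rec.swollen_dry


def hydrolytic_degradation(rec: WeightRecord) -> float:
    """HD (%) = 100 · (W_initial,dry − W_swollen,dry) / W_initial,dry."""
    rec._require("initial_dry", "swollen_dry")
    return 100.0 * (rec.initial_dry - rec.swollen_dry) / rec.initial_dry


def replicate_stats(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n−1) standard deviation."""
    values = np.asarray(list(values), float)
    if len(values) < 2:
        raise DataError("replicate statistics need n >= 2 values")
    return float(values.mean()), float(values.std(ddof=1))
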