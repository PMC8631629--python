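"""Closed-form seed-lot sampling and contamination arithmetic.

Border inspection of seed for sowing draws a working sample (in New Zealand,
about 150,000 seeds regardless of lot size — five times the ISTA standard)
and searches it for regulated weed seeds.  These helpers convert shipment
masses to seed counts via thousand-seed weight (TSW), compute expected
contaminant loads at a given per-seed contamination rate, and give the
binomial zero-detection statistics that bound what a clean sample proves:
the probability a sample misses all contaminants, and the largest
contamination rate consistent with a clean sample at a stated confidence.

The with-replacement (binomial) approximation is used throughout; lot sizes
run to billions of seeds, so the hypergeometric correction is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "SeedLotSpec", "RYEGRASS", "CLOVER",
    "seeds_in_mass", "expected_contaminants", "contaminants_per_hectare",
    "prob_clean_sample", "max_rate_at_confidence",
]


@dataclass(frozen=True)
class SeedLotSpec:
    """Crop-specific constants for seed-lot arithmetic.

    Parameters
    ----------
    crop:
        Crop label, e.g. ``"ryegrass"``.
    thousand_seed_weight_g:
        Mass of 1000 seeds in grams (ryegrass ~2 g, white clover ~0.64 g).
    shipment_mass_kg:
        Reference shipment size in kg.
    sowing_rate_kg_per_ha:
        Typical pasture sowing rate in kg/ha.
    contaminant_rate:
        Contaminant seeds per crop seed (dimensionless, in [0, 1]).
    sample_size_seeds:
        Inspection working-sample size in seeds.
    """

    crop: str
    thousand_seed_weight_g: float
    shipment_mass_kg: float = 10_000.0
    sowing_rate_kg_per_ha: float = 20.0
    contaminant_rate: float = 1e-5
    sample_size_seeds: int = 150_000

    def __post_init__(self) -> None:
        if self.thousand_seed_weight_g <= 0:
            raise ValueError("thousand_seed_weight_g must be positive")
        if not 0.0 <= self.contaminant_rate <= 1.0:
            raise ValueError("contaminant_rate must be in [0, 1]")
        if self.sample_size_seeds < 1:
            raise ValueError("sample_size_seeds must be >= 1")


RYEGRASS = SeedLotSpec(crop="ryegrass", thousand_seed_weight_g=2.0,
                       sowing_rate_kg_per_ha=20.0)
CLOVER = SeedLotSpec(crop="clover", thousand_seed_weight_g=0.64,
                     sowing_rate_kg_per_ha=4.0)


def seeds_in_mass(mass_kg: float, tsw_g: float) -> float:
    """Number of seeds in ``mass_kg`` of seed with thousand-seed weight ``tsw_g``."""
    if mass_kg < 0:
        raise ValueError("mass_kg must be non-negative")
    if tsw_g <= 0:
        raise ValueError("tsw_g must be positive")
    return mass_kg * 1000.0 / tsw_g * 1000.0


def expected_contaminants(mass_kg: float, tsw_g: float, rate: float) -> float:
    """Expected contaminant seeds in a shipment at per-seed ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    return seeds_in_mass(mass_kg, tsw_g) * rate


class PerHectare(NamedTuple):
    exact: float
    whole: int  # floor, as conventionally reported


def contaminants_per_hectare(sowing_rate_kg_ha: float, tsw_g: float,
                             rate: float) -> PerHectare:
    """Contaminant seeds sown per hectare at a given sowing rate and rate.

    Returns both the exact value and its floor (whole seeds).
    """
    exact = expected_contaminants(sowing_rate_kg_ha, tsw_g, rate)
    return PerHectare(exact=exact, whole=math.floor(exact))


def prob_clean_sample(sample_size: int, rate: float) -> float:
    """Probability that a random sample of ``sample_size`` seeds contains no
    contaminant when the true per-seed contamination rate is ``rate``.

    Computed as (1 - rate)^n in log space, so tiny rates at large n do not
    lose precision.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 1.0:
        return 0.0
    return math.exp(sample_size * math.log1p(-rate))


def max_rate_at_confidence(sample_size: int, confidence: float) -> float:
    """Largest contamination rate consistent with a clean sample.

    The smallest rate r such that a clean draw of ``sample_size`` seeds has
    probability at most 1 - ``confidence``:  r = 1 - (1 - c)^(1/n).
    A clean inspection then supports "the rate is below r" at the stated
    confidence (e.g. n = 150,000 at 95% gives r of about 1 in 50,000).
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    return -math.expm1(math.log1p(-confidence) / sample_size)
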