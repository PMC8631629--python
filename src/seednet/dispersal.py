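"""From contamination event counts to a per-edge dispersal probability matrix.

The base rate is contamination events per tonne of exposure: events observed
over a window divided by (mean annual import tonnes x window years).  Two
event bases are used: border *detections* of quarantine weeds (events found
and stopped during inspection) and post-border *incursions* (regulated
contaminants discovered after release).  Detections are observed over the
inspection window (default 5 years); incursions over a longer response
record (default 20 years), so the incursion rate is roughly an order of
magnitude lower.

A trade edge carrying V tonnes per year transmits the contaminant with
probability p = 1 - (1 - r)^V under the default per-tonne Bernoulli
compounding model: each tonne is an independent chance to carry at least
one contamination event.  A literal linear form p = min(1, rV) is available
for sensitivity analysis; the two agree to first order when rV << 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .trade_network import TradeNetwork

logger = logging.getLogger(__name__)

__all__ = ["RateSpec", "ProbabilityMatrix", "estimate_rate",
           "edge_probability", "build_probability_matrix",
           "DETECTION_WINDOW_YEARS", "INCURSION_WINDOW_YEARS"]

DETECTION_WINDOW_YEARS = 5    # border inspection record window
INCURSION_WINDOW_YEARS = 20   # post-border incursion response record


@dataclass(frozen=True)
class RateSpec:
    """Contamination events per tonne of trade exposure."""

    basis: str                  # "detection" or "incursion"
    events: int
    exposure_tonnes: float      # mean annual tonnes x window years
    rate_per_tonne: float

    def __post_init__(self) -> None:
        if self.exposure_tonnes <= 0:
            raise ValueError("exposure_tonnes must be positive")
        if not 0.0 <= self.rate_per_tonne <= 1.0:
            raise ValueError("rate_per_tonne must be in [0, 1]")


def estimate_rate(events: int, mean_annual_tonnes: float, window_years: int,
                  basis: str = "detection") -> RateSpec:
    """Estimate the per-tonne contamination rate from observed events.

    ``rate = events / (mean_annual_tonnes x window_years)``.  A rate above 1
    (more events than tonnes of exposure) is capped at 1 with a warning.
    """
    if events < 0:
        raise ValueError("events must be non-negative")
    if mean_annual_tonnes <= 0:
        raise ValueError("mean_annual_tonnes must be positive")
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    exposure = mean_annual_tonnes * window_years
    rate = events / exposure
    if rate > 1.0:
        logger.warning("events (%d) exceed tonne-exposure (%.3g); "
                       "rate capped at 1", events, exposure)
        rate = 1.0
    return RateSpec(basis=basis, events=events, exposure_tonnes=exposure,
                    rate_per_tonne=rate)


def edge_probability(volume_tonnes: float, rate: RateSpec,
                     mode: Literal["compound", "linear"] = "compound") -> float:
    """Probability that at least one contaminant moves along an edge in one
    time-step, given its annual volume.

    compound (default): p = 1 - (1 - r)^V, evaluated in log space.
    linear: p = min(1, r V).
    """
    if volume_tonnes < 0:
        raise ValueError("volume_tonnes must be >= 0")
    r = rate.rate_per_tonne
    if volume_tonnes == 0 or r == 0.0:
        return 0.0
    if mode == "compound":
        if r >= 1.0:
            return 1.0
        return -math.expm1(volume_tonnes * math.log1p(-r))
    if mode == "linear":
        return min(1.0, r * volume_tonnes)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ProbabilityMatrix:
    """Dense per-edge dispersal probabilities with a fixed node ordering.

    ``P[i, j]`` is the one-step transmission probability along the directed
    edge from ``nodes[i]`` to ``nodes[j]``; zero wherever there is no trade.
    The diagonal is zero — state persistence is the simulator's concern.
    """

    nodes: tuple[str, ...]
    P: np.ndarray
    rate: RateSpec | None = None
    mode: str = "compound"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.nodes)
        if self.P.shape != (n, n):
            raise ValueError(f"P must be {n}x{n}, got {self.P.shape}")
        if (self.P < 0).any() or (self.P > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def index(self, node: str) -> int:
        return self.nodes.index(node)


def build_probability_matrix(net: TradeNetwork, rate: RateSpec,
                             mode: Literal["compound", "linear"] = "compound",
                             ) -> ProbabilityMatrix:
    """Evaluate the edge-probability model on every edge of the network.

    Node ordering is the sorted country list and is recorded on the result;
    the matrix has exactly the sparsity pattern of the trade network.
    """
    nodes = tuple(net.nodes)
    if not nodes:
        raise ValueError("network is empty")
    idx = {node: i for i, node in enumerate(nodes)}
    P = np.zeros((len(nodes), len(nodes)))
    for (origin, dest), volume in net.edges.items():
        P[idx[origin], idx[dest]] = edge_probability(volume, rate, mode=mode)
    return ProbabilityMatrix(nodes=nodes, P=P, rate=rate, mode=mode)
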