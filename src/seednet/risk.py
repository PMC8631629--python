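"""Risk metrics from simulation ensembles.

Three products:

* :func:`decile_compare` — does network-aware risk (simulated dispersal
  events per edge, summed over ensembles started from every exporter) rank
  edges differently from trade volume alone?  Both quantities are cut into
  equal-count deciles and the rank differences summarised.
* :func:`summarize_ensembles` — per start country, the distribution of
  countries contaminated per replicate (median, 10% and 90% quantiles) and
  the number of successful replicates.
* :func:`focal_risk_table` — per start country, mean direct and indirect
  contaminant arrivals per replicate at a focal country.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import ArrivalSummary, SimulationTrace

__all__ = ["ntile", "decile_compare", "summarize_ensembles",
           "focal_risk_table", "edge_dispersal_counts"]


def ntile(values: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Equal-count rank bins 1..n_bins, ties broken by stable input order.

    With heavy ties (e.g. many zero-dispersal edges) tied values fill the
    lowest occupied bins in input order, so the binning is deterministic and
    invariant to positive rescaling of ``values``.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} items for {n_bins} bins, "
                         f"got {n}; reduce the quantile count")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n + 1


def edge_dispersal_counts(traces: Sequence[SimulationTrace]) -> np.ndarray:
    """Total dispersal events per edge summed over ensembles (all starts)."""
    if not traces:
        raise ValueError("no traces")
    nodes = traces[0].nodes
    total = np.zeros((len(nodes), len(nodes)), dtype=np.int64)
    for tr in traces:
        if tr.nodes != nodes:
            raise ValueError("traces have inconsistent node orderings")
        total += tr.edge_counts
    return total


def decile_compare(volumes: Sequence[float], dispersal_counts: Sequence[float],
                   edges: Optional[Sequence[tuple[str, str]]] = None,
                   n_bins: int = 10) -> tuple[pd.DataFrame, dict]:
    """Compare dispersal-based and volume-based decile ranks per edge.

    Both inputs must cover the same edge set (edges that carry trade).
    Returns the per-edge table and a summary with the percentage of edges
    whose dispersal decile differs from the volume decile, split into
    higher and lower.
    """
    volumes = np.asarray(volumes, dtype=float)
    counts = np.asarray(dispersal_counts, dtype=float)
    if volumes.shape != counts.shape:
        raise ValueError("volumes and dispersal counts must align")
    vol_dec = ntile(volumes, n_bins)
    disp_dec = ntile(counts, n_bins)
    diff = disp_dec - vol_dec

    table = pd.DataFrame({
        "volume": volumes, "dispersal_events": counts,
        "volume_decile": vol_dec, "dispersal_decile": disp_dec,
        "decile_difference": diff,
    })
    if edges is not None:
        table.insert(0, "origin", [e[0] for e in edges])
        table.insert(1, "destination", [e[1] for e in edges])

    n = len(volumes)
    summary = {
        "n_edges": n,
        "percent_differing": 100.0 * np.count_nonzero(diff) / n,
        "percent_higher": 100.0 * np.count_nonzero(diff > 0) / n,
        "percent_lower": 100.0 * np.count_nonzero(diff < 0) / n,
        "max_difference": int(diff.max()),
        "min_difference": int(diff.min()),
    }
    return table, summary


def summarize_ensembles(traces: Mapping[str, SimulationTrace],
                        include_start: bool = False) -> pd.DataFrame:
    """Countries-contaminated quantiles and success counts per start country.

    Quantiles use linear interpolation (type 7).  ``include_start`` switches
    to counts that include the start country itself.
    """
    rows = []
    for start, tr in sorted(traces.items()):
        counts = (tr.contaminated_incl_start if include_start
                  else tr.contaminated)
        rows.append({
            "start": start,
            "median_contaminated": float(np.median(counts)),
            "q10_contaminated": float(np.quantile(counts, 0.10)),
            "q90_contaminated": float(np.quantile(counts, 0.90)),
            "n_success": tr.n_success,
            "n_reps": tr.n_reps,
        })
    return pd.DataFrame(rows)


def focal_risk_table(arrivals: Mapping[str, ArrivalSummary],
                     focal: str) -> pd.DataFrame:
    """Direct/indirect arrival risk at ``focal`` per start country.

    The focal country itself is excluded (no self-risk); rows are sorted by
    total arrivals per replicate, descending.
    """
    rows = []
    for start, arr in arrivals.items():
        if start == focal:
            continue
        rows.append({
            "start": start,
            "direct_per_rep": arr.direct_per_rep,
            "indirect_per_rep": arr.indirect_per_rep,
            "total_per_rep": arr.direct_per_rep + arr.indirect_per_rep,
            "direct_total": arr.direct_total,
            "indirect_total": arr.indirect_total,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["total_per_rep", "start"],
                            ascending=[False, True]).reset_index(drop=True)
    return df
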