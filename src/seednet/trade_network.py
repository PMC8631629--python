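"""Directed, volume-weighted trade networks from bilateral trade reports.

Comtrade-style records report each trade twice (the exporter's "export" row
and the importer's "import" row), frequently with discrepant masses.
:func:`resolve_duplicates` orients every report origin->destination and
resolves conflicts: reports by the focal country (the country whose border
data parameterises the dispersal model, e.g. New Zealand) win outright;
otherwise the higher reported quantity is kept.  :func:`build_network` sums
surviving flows over the study window, drops minor flows (total below a kg
threshold over the window), and weights edges by mean annual tonnes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TradeRecord", "TradeNetwork", "NetworkStats", "DegreeSummary",
    "TradeFormatError", "NON_COUNTRY_ENTITIES",
    "read_trade_csv", "resolve_duplicates", "build_network", "network_stats",
]

#: Comtrade partner/reporter labels that are aggregates, not countries.
NON_COUNTRY_ENTITIES = frozenset(s.casefold() for s in (
    "World",
    "Special Categories",
    "Areas, nes",
    "Other Asia, nes",
    "Other Europe, nes",
    "Other Africa, nes",
    "Free Zones",
    "Bunkers",
    "Neutral Zone",
))

#: Candidate CSV column names for each logical field, tried in order.
DEFAULT_COLUMN_CANDIDATES: Mapping[str, Sequence[str]] = {
    "reporter": ("reporter", "Reporter", "reporter_desc"),
    "partner": ("partner", "Partner", "partner_desc"),
    "year": ("year", "Year", "period"),
    "flow": ("flow", "trade_flow", "Trade Flow", "flow_desc"),
    "commodity": ("commodity", "Commodity", "crop", "commodity_desc"),
    "mass_kg": ("mass_kg", "netweight_kg", "Netweight (kg)", "net_weight_kg",
                "weight_kg", "kg"),
}


class TradeFormatError(ValueError):
    """Input CSV is missing a required column or is otherwise malformed."""


@dataclass(frozen=True)
class TradeRecord:
    """One reported bilateral flow.

    ``flow`` is ``"import"`` or ``"export"`` from the reporter's point of
    view; the oriented origin/destination pair is available via
    :meth:`oriented`.
    """

    reporter: str
    partner: str
    year: int
    flow: str
    commodity: str
    mass_kg: float

    def __post_init__(self) -> None:
        if self.mass_kg < 0:
            raise ValueError(f"mass_kg must be >= 0, got {self.mass_kg}")
        if self.reporter == self.partner:
            raise ValueError(f"self-trade record: {self.reporter}")
        if self.flow not in ("import", "export"):
            raise ValueError(f"flow must be 'import' or 'export', got {self.flow!r}")

    def oriented(self) -> tuple[str, str]:
        """(origin, destination) regardless of which side reported."""
        if self.flow == "export":
            return self.reporter, self.partner
        return self.partner, self.reporter


@dataclass
class TradeNetwork:
    """Directed trade network; edge weight is mean annual volume in tonnes."""

    graph: nx.DiGraph
    focal: Optional[str] = None
    window_years: int = 10

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        """Mapping (origin, destination) -> tonnes per year."""
        return {(u, v): d["tonnes_per_year"]
                for u, v, d in self.graph.edges(data=True)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_edgelist(self) -> pd.DataFrame:
        rows = [(u, v, w) for (u, v), w in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["origin", "destination",
                                           "tonnes_per_year"])


@dataclass(frozen=True)
class DegreeSummary:
    """Mean/sd of in- and out-degree over a node group (degrees taken on the
    full network, the group only selects which nodes are averaged)."""

    n: int
    mean_indegree: float
    sd_indegree: float
    mean_outdegree: float
    sd_outdegree: float


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    density: float
    diameter: int
    n_zero_outdegree: int
    n_exporters: int
    direct_partners: Optional[DegreeSummary] = None
    indirect_partners: Optional[DegreeSummary] = None
    metadata: dict = field(default_factory=dict)


def _resolve_columns(df: pd.DataFrame,
                     columns: Optional[Mapping[str, str]]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for logical, candidates in DEFAULT_COLUMN_CANDIDATES.items():
        if columns and logical in columns:
            if columns[logical] not in df.columns:
                raise TradeFormatError(
                    f"configured column {columns[logical]!r} for {logical!r} "
                    f"not in file")
            resolved[logical] = columns[logical]
            continue
        for cand in candidates:
            if cand in df.columns:
                resolved[logical] = cand
                break
        else:
            raise TradeFormatError(
                f"no column found for {logical!r}; tried {list(candidates)}")
    return resolved


def read_trade_csv(path: str | Path, commodity: str,
                   columns: Optional[Mapping[str, str]] = None,
                   aliases: Optional[Mapping[str, str]] = None,
                   ) -> list[TradeRecord]:
    """Read bilateral trade reports for one commodity from a CSV file.

    Rows naming aggregate entities ("World", "Special Categories", ...) as
    reporter or partner are dropped, as are self-trades and rows with
    negative mass (logged).  ``aliases`` maps raw country names to canonical
    ones (Comtrade naming variants); matching is exact after whitespace trim.
    """
    df = pd.read_csv(path)
    cols = _resolve_columns(df, columns)
    aliases = dict(aliases or {})

    def canon(name: object) -> str:
        s = str(name).strip()
        return aliases.get(s, s)

    records: list[TradeRecord] = []
    want = commodity.strip().casefold()
    for r in df.to_dict("records"):
        if str(r[cols["commodity"]]).strip().casefold() != want:
            continue
        reporter, partner = canon(r[cols["reporter"]]), canon(r[cols["partner"]])
        if (reporter.casefold() in NON_COUNTRY_ENTITIES
                or partner.casefold() in NON_COUNTRY_ENTITIES):
            continue
        if reporter == partner:
            logger.warning("dropping self-trade row for %s", reporter)
            continue
        mass = float(r[cols["mass_kg"]])
        if math.isnan(mass):
            logger.warning("dropping row with missing mass (%s-%s)", reporter, partner)
            continue
        if mass < 0:
            logger.warning("dropping negative-mass row (%s-%s, %s kg)",
                           reporter, partner, mass)
            continue
        flow = str(r[cols["flow"]]).strip().casefold()
        if flow not in ("import", "export"):
            raise TradeFormatError(f"unrecognised flow direction {flow!r}")
        records.append(TradeRecord(reporter=reporter, partner=partner,
                                   year=int(r[cols["year"]]), flow=flow,
                                   commodity=commodity, mass_kg=mass))
    return records


def resolve_duplicates(records: Sequence[TradeRecord],
                       focal: Optional[str] = None) -> list[TradeRecord]:
    """Resolve doubly-reported flows to one record per (origin, destination,
    year, commodity).

    If the focal country reported the flow (either side), its value is kept;
    among several non-focal reports the higher quantity wins.  Output records
    are normalised to the export orientation (reporter = origin) and sorted,
    so the operation is idempotent and order-invariant.
    """
    groups: dict[tuple[str, str, int, str], list[TradeRecord]] = {}
    for rec in records:
        origin, dest = rec.oriented()
        groups.setdefault((origin, dest, rec.year, rec.commodity), []).append(rec)

    resolved: list[TradeRecord] = []
    for (origin, dest, year, commodity), grp in sorted(groups.items()):
        focal_reports = [g for g in grp if focal is not None and g.reporter == focal]
        pool = focal_reports if focal_reports else grp
        mass = max(g.mass_kg for g in pool)
        resolved.append(TradeRecord(reporter=origin, partner=dest, year=year,
                                    flow="export", commodity=commodity,
                                    mass_kg=mass))
    return resolved


def build_network(records: Sequence[TradeRecord],
                  min_total_kg: float = 1000.0,
                  window_years: int = 10,
                  focal: Optional[str] = None) -> TradeNetwork:
    """Aggregate deduplicated records into the directed trade network.

    Edge weight is total kg over the window divided by ``window_years``,
    in tonnes per year.  Directed edges whose summed volume over the window
    falls below ``min_total_kg`` (default 1000 kg) are discarded as minor;
    nodes are the endpoints of surviving edges.
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    totals: dict[tuple[str, str], float] = {}
    for rec in records:
        origin, dest = rec.oriented()
        totals[(origin, dest)] = totals.get((origin, dest), 0.0) + rec.mass_kg

    g = nx.DiGraph()
    for (origin, dest), kg in sorted(totals.items()):
        if kg < min_total_kg:
            continue
        g.add_edge(origin, dest,
                   tonnes_per_year=kg / window_years / 1000.0)
    return TradeNetwork(graph=g, focal=focal, window_years=window_years)


def _degree_summary(g: nx.DiGraph, nodes: Sequence[str]) -> Optional[DegreeSummary]:
    if not nodes:
        return None
    indeg = np.array([g.in_degree(n) for n in nodes], dtype=float)
    outdeg = np.array([g.out_degree(n) for n in nodes], dtype=float)
    # sample sd (ddof=1), as conventional for reported group summaries
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return DegreeSummary(n=len(nodes),
                         mean_indegree=float(indeg.mean()), sd_indegree=sd(indeg),
                         mean_outdegree=float(outdeg.mean()), sd_outdegree=sd(outdeg))


def network_stats(net: TradeNetwork) -> NetworkStats:
    """Descriptive statistics of the trade network.

    Density is m / (n (n-1)) on the directed simple graph.  The diameter is
    the longest finite directed geodesic (unreachable pairs ignored).  When
    a focal country is set, degree summaries are reported separately for its
    direct partners (nodes sharing an edge with it, either direction) and
    for all remaining (indirect) nodes; degrees are always taken on the full
    network.
    """
    g = net.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("network is empty")
    density = m / (n * (n - 1)) if n > 1 else 0.0

    diameter = 0
    for _, lengths in nx.shortest_path_length(g):
        ecc = max(lengths.values())
        if ecc > diameter:
            diameter = ecc

    zero_out = sum(1 for node in g.nodes if g.out_degree(node) == 0)
    stats = NetworkStats(
        n_nodes=n, n_edges=m, density=density, diameter=diameter,
        n_zero_outdegree=zero_out, n_exporters=n - zero_out,
        metadata={"diameter_convention":
                  "directed geodesics, unreachable pairs ignored"},
    )

    focal = net.focal
    if focal is not None and focal in g:
        direct = sorted(set(g.successors(focal)) | set(g.predecessors(focal)))
        indirect = sorted(set(g.nodes) - set(direct) - {focal})
        stats.direct_partners = _degree_summary(g, direct)
        stats.indirect_partners = _degree_summary(g, indirect)
    return stats


def stats_to_dict(stats: NetworkStats) -> dict:
    """JSON-serialisable view of :class:`NetworkStats`."""
    out = {
        "n_nodes": stats.n_nodes, "n_edges": stats.n_edges,
        "density": stats.density, "diameter": stats.diameter,
        "n_zero_outdegree": stats.n_zero_outdegree,
        "n_exporters": stats.n_exporters,
        "metadata": stats.metadata,
    }
    for key in ("direct_partners", "indirect_partners"):
        summ = getattr(stats, key)
        out[key] = None if summ is None else {
            "n": summ.n,
            "mean_indegree": summ.mean_indegree, "sd_indegree": summ.sd_indegree,
            "mean_outdegree": summ.mean_outdegree, "sd_outdegree": summ.sd_outdegree,
        }
    return out
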