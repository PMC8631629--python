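"""Synthetic trade networks and inspection records with known ground truth.

The generators emulate the structural features the pipeline must cope with —
a small core of hub exporters with outdegree far above the mean, many
import-only leaf countries, heavy-tailed (log-normal) edge volumes,
mirrored duplicate trade reports with discrepant masses, sub-threshold minor
flows, and rare quarantine detections on top of country-level Bernoulli
contamination — without attempting to fit any real trade marginals.  Ground
truth is always returned alongside the raw records, so the builders can be
round-trip tested and the simulator's edge frequencies checked against the
analytic probabilities (parameter recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dispersal import RateSpec, build_probability_matrix
from .inspection import SeedLotRecord
from .simulate import step
from .trade_network import TradeNetwork, TradeRecord

__all__ = [
    "SyntheticNetworkSpec", "SyntheticInspectionSpec", "SyntheticNetwork",
    "RecoveryReport", "generate_network", "generate_inspections",
    "recovery_experiment", "write_trade_csv", "write_inspection_csv",
]


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of the synthetic trade network.

    Defaults mirror the shape of the ryegrass seed-trade network: 134
    countries, density 0.086, just under half import-only, a handful of hub
    exporters carrying most volume, log-normal annual volumes spanning
    roughly 0.1 to 10^4 tonnes/yr.
    """

    n_countries: int = 134
    n_hubs: int = 8
    density: float = 0.086
    volume_mu: float = 2.0          # log-tonnes/yr location
    volume_sigma: float = 2.0       # log-tonnes/yr scale
    hub_volume_factor: float = 20.0
    frac_import_only: float = 0.46
    focal: bool = True              # first country acts as the focal node
    window_years: int = 10
    commodity: str = "ryegrass"
    duplicate_fraction: float = 0.7
    partner_discrepancy: float = 0.2
    n_subthreshold: int = 8         # minor flows the builder must drop
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if not 0.0 <= self.frac_import_only < 1.0:
            raise ValueError("frac_import_only must be in [0, 1)")
        if self.n_countries < 2:
            raise ValueError("need at least 2 countries")
        n, n_exp = self.n_countries, self.n_exporters
        if round(self.density * n * (n - 1)) > n_exp * (n - 1):
            raise ValueError("density target infeasible for the number of "
                             "exporting countries")

    @property
    def n_exporters(self) -> int:
        return max(1, round(self.n_countries * (1.0 - self.frac_import_only)))

    @property
    def countries(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_countries)]

    @property
    def focal_country(self) -> Optional[str]:
        return self.countries[0] if self.focal else None


@dataclass
class SyntheticNetwork:
    """Ground-truth network plus the raw Comtrade-style reports that encode it."""

    truth: TradeNetwork
    records: list[TradeRecord]
    spec: SyntheticNetworkSpec


def generate_network(spec: SyntheticNetworkSpec) -> SyntheticNetwork:
    """Draw a trade network and emit mirrored, noisy bilateral reports.

    The raw records contain, for a fraction of edges, a mirrored duplicate
    report by the counterparty with a discrepant mass, constructed so the
    duplicate-resolution rules recover the truth exactly: the counterparty
    of a focal-country edge over-reports (the focal report wins), while on
    other edges the counterparty under-reports (the higher value wins).
    Sub-threshold flows (total below 1000 kg over the window) are added and
    must be dropped by the builder.
    """
    rng = np.random.default_rng(spec.rng_seed)
    countries = spec.countries
    n = spec.n_countries
    exporters = countries[:spec.n_exporters]
    hubs = exporters[:min(spec.n_hubs, len(exporters))]
    hub_set = set(hubs)

    m_target = max(1, round(spec.density * n * (n - 1)))

    edges: set[tuple[str, str]] = set()
    # every importer reachable, every exporter actually exports
    for d in countries:
        if d not in hub_set:
            edges.add((hubs[rng.integers(len(hubs))], d))
    for o in exporters:
        choices = [c for c in countries if c != o]
        edges.add((o, choices[rng.integers(len(choices))]))

    origin_weights = np.array(
        [8.0 if c in hub_set else 1.0 for c in exporters])
    origin_weights /= origin_weights.sum()
    while len(edges) < m_target:
        o = exporters[rng.choice(len(exporters), p=origin_weights)]
        d = countries[rng.integers(n)]
        if o != d:
            edges.add((o, d))

    # annual volumes (tonnes/yr), kept above the minor-flow threshold
    floor_tonnes = 1.05 * 1000.0 / (1000.0 * spec.window_years)
    g = nx.DiGraph()
    for (o, d) in sorted(edges):
        v = float(rng.lognormal(spec.volume_mu, spec.volume_sigma))
        if o in hub_set:
            v *= spec.hub_volume_factor
        v = max(v, floor_tonnes)
        g.add_edge(o, d, tonnes_per_year=v)
    truth = TradeNetwork(graph=g, focal=spec.focal_country,
                         window_years=spec.window_years)

    records: list[TradeRecord] = []
    years = list(range(2010, 2010 + spec.window_years))
    focal = spec.focal_country
    for (o, d), v in sorted(truth.edges.items()):
        total_kg = v * 1000.0 * spec.window_years
        weights = rng.random(len(years)) + 0.1
        weights /= weights.sum()
        for year, w in zip(years, weights):
            kg = total_kg * w
            if focal is not None and focal in (o, d):
                # the focal country reports its own trades
                if o == focal:
                    records.append(TradeRecord(o, d, year, "export",
                                               spec.commodity, kg))
                else:
                    records.append(TradeRecord(d, o, year, "import",
                                               spec.commodity, kg))
                if rng.random() < spec.duplicate_fraction:
                    # counterparty over-reports; focal's value must win
                    noisy = kg * (1.0 + spec.partner_discrepancy)
                    if o == focal:
                        records.append(TradeRecord(d, o, year, "import",
                                                   spec.commodity, noisy))
                    else:
                        records.append(TradeRecord(o, d, year, "export",
                                                   spec.commodity, noisy))
            else:
                records.append(TradeRecord(o, d, year, "export",
                                           spec.commodity, kg))
                if rng.random() < spec.duplicate_fraction:
                    # counterparty under-reports; the higher value must win
                    noisy = kg * (1.0 - spec.partner_discrepancy
                                  * rng.random())
                    records.append(TradeRecord(d, o, year, "import",
                                               spec.commodity, noisy))

    # minor flows on edges not in the truth network
    added = 0
    guard = 0
    while added < spec.n_subthreshold and guard < 1000:
        guard += 1
        o = exporters[rng.integers(len(exporters))]
        d = countries[rng.integers(n)]
        if o == d or (o, d) in edges:
            continue
        total_kg = float(rng.uniform(1.0, 900.0))
        year = years[rng.integers(len(years))]
        records.append(TradeRecord(o, d, year, "export", spec.commodity,
                                   total_kg))
        added += 1

    return SyntheticNetwork(truth=truth, records=records, spec=spec)


@dataclass(frozen=True)
class SyntheticInspectionSpec:
    """Parameters of the synthetic seed-lot inspection records.

    Defaults emulate the observed data shape for one crop: a few hundred
    lots spread unevenly over exporting countries, roughly one lot in six
    carrying unregulated contaminants, and quarantine hits rare enough that
    a five-year record yields only a handful of detection events.
    """

    crop: str = "ryegrass"
    lots_per_country: Mapping[str, int] = field(
        default_factory=lambda: {"C001": 120, "C002": 115, "C003": 110,
                                 "C004": 55, "C005": 50, "C006": 45,
                                 "C007": 35, "C008": 30})
    contamination_p: float | Mapping[str, float] = 0.16
    species_pool_size: int = 80
    mean_species_per_lot: float = 1.8
    n_quarantine_species: int = 5
    quarantine_p: float = 3.0 / 560.0
    years: tuple[int, int] = (2014, 2018)
    rng_seed: int = 0

    def prob_for(self, country: str) -> float:
        if isinstance(self.contamination_p, Mapping):
            return self.contamination_p[country]
        return float(self.contamination_p)


def generate_inspections(spec: SyntheticInspectionSpec) -> list[SeedLotRecord]:
    """Draw seed-lot records with lot-level Bernoulli contamination.

    Each lot is contaminated with its country's probability, in which case
    1 + Poisson(mean - 1) species are sampled from the pool; independently,
    with probability ``quarantine_p`` the lot also carries one regulated
    quarantine species (which marks it contaminated as well).
    """
    rng = np.random.default_rng(spec.rng_seed)
    pool = [f"Genus{i:03d} species{i:03d}"
            for i in range(spec.species_pool_size)]
    quarantine_pool = [f"Quarantinia weed{i:02d}"
                       for i in range(spec.n_quarantine_species)]
    y0, y1 = spec.years

    records: list[SeedLotRecord] = []
    for country in sorted(spec.lots_per_country):
        n_lots = spec.lots_per_country[country]
        p = spec.prob_for(country)
        for k in range(n_lots):
            contaminants: set[str] = set()
            quarantine: set[str] = set()
            if rng.random() < p:
                n_sp = 1 + rng.poisson(max(spec.mean_species_per_lot - 1.0,
                                           0.0))
                n_sp = min(n_sp, len(pool))
                contaminants.update(
                    pool[i] for i in rng.choice(len(pool), size=n_sp,
                                                replace=False))
            if spec.quarantine_p > 0 and rng.random() < spec.quarantine_p:
                q = quarantine_pool[rng.integers(len(quarantine_pool))]
                quarantine.add(q)
                contaminants.add(q)
            records.append(SeedLotRecord(
                lot_id=f"{spec.crop}-{country}-{k:04d}", crop=spec.crop,
                exporter=country, year=int(rng.integers(y0, y1 + 1)),
                contaminants=frozenset(contaminants),
                quarantine_hits=frozenset(quarantine)))
    return records


@dataclass
class RecoveryReport:
    """Empirical edge-transmission frequencies versus analytic probabilities."""

    nodes: tuple[str, ...]
    n_reps: int
    p_true: np.ndarray
    p_hat: np.ndarray
    max_abs_deviation: float
    n_edges: int
    n_edges_within_3se: int

    @property
    def all_within_3se(self) -> bool:
        return self.n_edges_within_3se == self.n_edges


def recovery_experiment(net: TradeNetwork, rate: RateSpec,
                        n_reps: int = 2000, rng_seed: int = 0,
                        mode: str = "compound") -> RecoveryReport:
    """End-to-end parameter recovery through the simulator.

    Builds P from the given rate, runs ``n_reps`` independent single-step
    replicates with every node infected (so every edge gets one Bernoulli
    trial per replicate), and compares the empirical per-edge event
    frequency with the analytic p_ij, flagging edges outside three binomial
    standard errors.
    """
    pm = build_probability_matrix(net, rate, mode=mode)
    n = len(pm.nodes)
    rng = np.random.default_rng(rng_seed)
    all_infected = np.ones(n, dtype=np.int8)
    counts = np.zeros((n, n), dtype=np.int64)
    for _ in range(n_reps):
        _, events = step(all_infected, pm, rng)
        if events.size:
            np.add.at(counts, (events[:, 0], events[:, 1]), 1)
    p_hat = counts / n_reps

    mask = pm.P > 0
    se = np.sqrt(pm.P * (1.0 - pm.P) / n_reps)
    dev = np.abs(p_hat - pm.P)
    within = dev <= 3.0 * se + 1e-12
    # off-pattern entries must be exactly zero
    off_ok = (p_hat[~mask] == 0).all()
    n_edges = int(mask.sum())
    n_within = int(within[mask].sum()) if off_ok else 0
    return RecoveryReport(nodes=pm.nodes, n_reps=n_reps, p_true=pm.P,
                          p_hat=p_hat,
                          max_abs_deviation=float(dev.max()),
                          n_edges=n_edges, n_edges_within_3se=n_within)


def write_trade_csv(records: Sequence[TradeRecord], path: str | Path) -> None:
    """Write records in the CSV dialect :func:`seednet.read_trade_csv` reads."""
    pd.DataFrame([{
        "reporter": r.reporter, "partner": r.partner, "year": r.year,
        "flow": r.flow, "commodity": r.commodity, "mass_kg": r.mass_kg,
    } for r in records]).to_csv(path, index=False)


def write_inspection_csv(records: Sequence[SeedLotRecord],
                         path: str | Path) -> None:
    """Write lot records in long form (one row per lot x species)."""
    rows = []
    for rec in records:
        if not rec.contaminants:
            rows.append({"lot_id": rec.lot_id, "crop": rec.crop,
                         "exporter": rec.exporter, "year": rec.year,
                         "species": "", "quarantine": ""})
            continue
        for sp in sorted(rec.contaminants):
            rows.append({"lot_id": rec.lot_id, "crop": rec.crop,
                         "exporter": rec.exporter, "year": rec.year,
                         "species": sp,
                         "quarantine": str(sp in rec.quarantine_hits).lower()})
    pd.DataFrame(rows).to_csv(path, index=False)
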