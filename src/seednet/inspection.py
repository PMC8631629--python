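"""Border-inspection records: contamination rates and quarantine detections.

Each inspected seed lot carries the set of weed-seed contaminant taxa found
in its working sample, a (usually empty) subset flagged as regulated
quarantine species, the exporting country and the inspection year.  The
summaries here feed the dispersal-rate estimation: the number of lots with a
quarantine hit (detection events) and externally supplied incursion counts
become contamination events per tonne-exposure.

Taxa determined only to genus (e.g. "Bromus sp.") still mark a lot as
contaminated but are excluded from distinct-species tallies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SeedLotRecord", "ContaminationSummary", "IncursionSpec",
    "read_inspection_csv", "summarize_contamination", "count_detection_events",
    "is_species_level",
]

KNOWN_CROPS = ("ryegrass", "clover")

_GENUS_ONLY = re.compile(r"^\S+\s+(sp|spp|sp\.|spp\.)$", re.IGNORECASE)


def is_species_level(name: str) -> bool:
    """True when a taxon determination reaches species level.

    Single-word names (genus or family) and explicit "Genus sp./spp." forms
    do not.
    """
    name = name.strip()
    if len(name.split()) < 2:
        return False
    return not _GENUS_ONLY.match(name)


def _normalize(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip())


@dataclass(frozen=True)
class SeedLotRecord:
    """One inspected seed lot and the contaminant taxa found in it."""

    lot_id: str
    crop: str
    exporter: str
    year: int
    contaminants: frozenset[str] = frozenset()
    quarantine_hits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.quarantine_hits <= self.contaminants:
            raise ValueError("quarantine_hits must be a subset of contaminants")

    @property
    def contaminated(self) -> bool:
        return bool(self.contaminants)


@dataclass(frozen=True)
class IncursionSpec:
    """Post-border incursion count, supplied externally (incursion responses
    are not part of the inspection file)."""

    events: int
    window_years: int

    def __post_init__(self) -> None:
        if self.window_years <= 0:
            raise ValueError("incursion window_years must be positive")
        if self.events < 0:
            raise ValueError("events must be non-negative")


@dataclass
class ContaminationSummary:
    per_country: pd.DataFrame           # crop, exporter, n_lots, n_contaminated, pct, n_species
    per_crop: dict                      # crop -> {n_lots, pct_contaminated, species set}
    total_species: int                  # species-level taxa across crops
    shared_species: frozenset[str]      # species seen in more than one crop
    detection_events: list              # (crop, species tuple, exporter, year)


_COLUMN_CANDIDATES: Mapping[str, Sequence[str]] = {
    "lot_id": ("lot_id", "lot", "seed_lot", "seedlot_id", "id"),
    "crop": ("crop", "commodity"),
    "exporter": ("exporter", "country", "exporting_country", "origin"),
    "year": ("year", "inspection_year"),
}


def read_inspection_csv(path: str | Path,
                        columns: Optional[Mapping[str, str]] = None,
                        ) -> list[SeedLotRecord]:
    """Read seed-lot inspection records.

    Two layouts are auto-detected from the header: long form, one row per
    lot x species with a ``species`` column (empty species = clean lot) and
    an optional boolean-ish ``quarantine`` column; and wide form, one row
    per lot with semicolon-separated ``contaminants`` and ``quarantine``
    columns.  Species strings are whitespace-normalised; matching is
    case-insensitive with the first-seen original casing preserved.
    Lots with an unknown crop label are rejected with a warning.
    """
    df = pd.read_csv(path)
    cols: dict[str, str] = {}
    for logical, candidates in _COLUMN_CANDIDATES.items():
        if columns and logical in columns:
            cols[logical] = columns[logical]
            continue
        for cand in candidates:
            if cand in df.columns:
                cols[logical] = cand
                break
        else:
            raise ValueError(f"no column found for {logical!r}")

    long_form = "species" in df.columns
    if not long_form and "contaminants" not in df.columns:
        raise ValueError("need a 'species' (long form) or 'contaminants' "
                         "(wide form) column")

    canonical: dict[str, str] = {}   # casefolded -> first-seen original

    def canon(raw: object) -> Optional[str]:
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            return None
        s = _normalize(str(raw))
        if not s:
            return None
        return canonical.setdefault(s.casefold(), s)

    def truthy(v: object) -> bool:
        return str(v).strip().casefold() in ("1", "true", "yes", "y", "t")

    lots: dict[str, dict] = {}
    for r in df.to_dict("records"):
        crop = str(r[cols["crop"]]).strip().casefold()
        if crop not in KNOWN_CROPS:
            logger.warning("rejecting lot %s with unknown crop %r",
                           r[cols["lot_id"]], crop)
            continue
        lot_id = str(r[cols["lot_id"]])
        entry = lots.setdefault(lot_id, {
            "crop": crop, "exporter": str(r[cols["exporter"]]).strip(),
            "year": int(r[cols["year"]]), "contaminants": set(),
            "quarantine": set()})
        if long_form:
            sp = canon(r.get("species"))
            if sp is not None:
                entry["contaminants"].add(sp)
                if "quarantine" in df.columns and truthy(r.get("quarantine")):
                    entry["quarantine"].add(sp)
        else:
            c_raw = r.get("contaminants")
            if c_raw is not None and not (isinstance(c_raw, float)
                                          and pd.isna(c_raw)):
                for sp_raw in str(c_raw).split(";"):
                    sp = canon(sp_raw)
                    if sp is not None:
                        entry["contaminants"].add(sp)
            q_raw = r.get("quarantine")
            if q_raw is not None and not (isinstance(q_raw, float) and pd.isna(q_raw)):
                for sp_raw in str(q_raw).split(";"):
                    sp = canon(sp_raw)
                    if sp is not None:
                        entry["contaminants"].add(sp)
                        entry["quarantine"].add(sp)

    return [SeedLotRecord(lot_id=lid, crop=e["crop"], exporter=e["exporter"],
                          year=e["year"],
                          contaminants=frozenset(e["contaminants"]),
                          quarantine_hits=frozenset(e["quarantine"]))
            for lid, e in sorted(lots.items())]


def summarize_contamination(records: Sequence[SeedLotRecord]) -> ContaminationSummary:
    """Per-country and per-crop contamination rates and species tallies.

    A lot is contaminated iff it has at least one contaminant taxon of any
    determination level; species tallies count only species-level taxa.
    Shared species are those identified in more than one crop.
    """
    if not records:
        raise ValueError("no inspection records")

    rows = []
    crop_species: dict[str, set[str]] = {}
    crop_lots: dict[str, list[SeedLotRecord]] = {}
    for rec in records:
        crop_lots.setdefault(rec.crop, []).append(rec)
        crop_species.setdefault(rec.crop, set()).update(
            s for s in rec.contaminants if is_species_level(s))

    for crop, lots in sorted(crop_lots.items()):
        by_country: dict[str, list[SeedLotRecord]] = {}
        for rec in lots:
            by_country.setdefault(rec.exporter, []).append(rec)
        for country, recs in sorted(by_country.items()):
            n = len(recs)
            n_cont = sum(r.contaminated for r in recs)
            species = set()
            for r in recs:
                species.update(s for s in r.contaminants if is_species_level(s))
            rows.append({"crop": crop, "exporter": country, "n_lots": n,
                         "n_contaminated": n_cont,
                         "pct_contaminated": 100.0 * n_cont / n,
                         "n_species": len(species)})

    per_crop = {}
    for crop, lots in sorted(crop_lots.items()):
        n_cont = sum(r.contaminated for r in lots)
        per_crop[crop] = {
            "n_lots": len(lots),
            "n_contaminated": n_cont,
            "pct_contaminated": 100.0 * n_cont / len(lots),
            "n_species": len(crop_species[crop]),
            "species": frozenset(crop_species[crop]),
        }

    all_species: set[str] = set()
    shared: set[str] = set()
    for crop, species in crop_species.items():
        for other, other_species in crop_species.items():
            if other != crop:
                shared |= species & other_species
        all_species |= species

    detections = [(rec.crop, tuple(sorted(rec.quarantine_hits)), rec.exporter,
                   rec.year)
                  for rec in records if rec.quarantine_hits]

    return ContaminationSummary(
        per_country=pd.DataFrame(rows),
        per_crop=per_crop,
        total_species=len(all_species),
        shared_species=frozenset(shared),
        detection_events=sorted(detections),
    )


def count_detection_events(records: Sequence[SeedLotRecord]) -> dict[str, int]:
    """Quarantine detection events per crop.

    One event per lot with at least one quarantine hit (an event is a
    shipment stopped, however many regulated species it contained).
    """
    counts: dict[str, int] = {}
    for rec in records:
        counts.setdefault(rec.crop, 0)
        if rec.quarantine_hits:
            counts[rec.crop] += 1
    return counts
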