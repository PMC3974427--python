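"""Museum collection records: sample-size categories, distances, KML export.

Collection coordinates are hill centroids, not exact collecting spots, so
distances are meaningful at the ~100 m scale and sympatry means "the same
limestone hill". Shell counts below 10 are stored exactly; larger samples
fall into four categories whose parenthetical ranges are authoritative:
">10" (10-24), ">25" (25-49), ">50" (50-100), ">100" (101+).

KML export follows the field mapping used for the revision's Google-Earth
workflow: one folder per species (folder name = species), one placemark per
georeferenced record (placemark name = collection reference, title =
species + reference, description = the collection-data paragraph).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from lxml import etree

__all__ = [
    "CollectionRecord",
    "SampleSizeCategory",
    "SAMPLE_SIZE_CATEGORIES",
    "categorize_sample_size",
    "haversine_km",
    "distribution_range",
    "load_records",
    "to_kml",
    "parse_kml",
    "parse_date",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # WGS84 mean radius

KML_NS = "http://www.opengis.net/kml/2.2"


@dataclass(frozen=True)
class SampleSizeCategory:
    """One of the four coarse shell-count categories for samples > 10 shells."""

    label: str  # ">10", ">25", ">50", ">100"
    low: int
    high: int | None  # inclusive; None = unbounded

    def __contains__(self, n: int) -> bool:
        return n >= self.low and (self.high is None or n <= self.high)

    def __str__(self) -> str:
        return self.label


SAMPLE_SIZE_CATEGORIES: tuple[SampleSizeCategory, ...] = (
    SampleSizeCategory(">10", 10, 24),
    SampleSizeCategory(">25", 25, 49),
    SampleSizeCategory(">50", 50, 100),
    SampleSizeCategory(">100", 101, None),
)


def categorize_sample_size(n: int) -> int | SampleSizeCategory:
    """Exact count below 10 shells, otherwise the matching category.

    The mapping is total and monotone: 10-24 -> ">10", 25-49 -> ">25",
    50-100 -> ">50", 101+ -> ">100" (100 belongs to ">50").
    """
    if n < 1:
        raise ValueError(f"shell count must be >= 1, got {n}")
    if n < 10:
        return n
    for cat in SAMPLE_SIZE_CATEGORIES:
        if n in cat:
            return cat
    raise AssertionError("unreachable: categories cover all n >= 10")


def parse_date(raw: str) -> tuple[str, bool]:
    """Lenient date normalisation: returns (stored text, parsed flag).

    Accepts ISO dates, year-month, or bare years; anything else is stored
    verbatim with parsed=False.
    """
    text = raw.strip()
    if re.fullmatch(r"\d{4}(-\d{2})?(-\d{2})?", text):
        return text, True
    return text, False


@dataclass(frozen=True)
class CollectionRecord:
    """One museum lot: voucher reference, species, hill coordinates, metadata."""

    reference: str
    species: str
    locality: str = ""
    lat: float | None = None
    lon: float | None = None
    date: str | None = None
    date_parsed: bool = True
    count: int | SampleSizeCategory | None = None
    accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValueError("collection reference must be non-empty")
        if (self.lat is None) != (self.lon is None):
            raise ValueError(f"{self.reference}: lat/lon must be given together")
        if self.lat is not None and not -90 <= self.lat <= 90:
            raise ValueError(f"{self.reference}: latitude {self.lat} out of range")
        if self.lon is not None and not -180 <= self.lon <= 180:
            raise ValueError(f"{self.reference}: longitude {self.lon} out of range")

    @property
    def georeferenced(self) -> bool:
        return self.lat is not None

    def description_paragraph(self) -> str:
        parts = [f"Reference: {self.reference}", f"Species: {self.species}"]
        if self.locality:
            parts.append(f"Locality: {self.locality}")
        if self.date:
            parts.append(f"Date: {self.date}")
        if self.count is not None:
            parts.append(f"Sample size: {self.count}")
        if self.accessions:
            parts.append("Accessions: " + ", ".join(self.accessions))
        return "; ".join(parts)


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float
) -> float:
    """Great-circle distance in km on the WGS84 mean-radius sphere."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def distribution_range(
    species: str, records: Iterable[CollectionRecord]
) -> float:
    """Maximum pairwise great-circle distance (km) among a species' sites.

    A species known from a single georeferenced site has range 0.
    """
    sites = [
        (r.lat, r.lon)
        for r in records
        if r.species == species and r.georeferenced
    ]
    if not sites:
        raise ValueError(f"no georeferenced records for {species!r}")
    best = 0.0
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            best = max(
                best, haversine_km(sites[i][0], sites[i][1], sites[j][0], sites[j][1])
            )
    return best


def load_records(path: str | Path) -> list[CollectionRecord]:
    """Read a TSV of collection records (reference, species, locality, lat,
    lon, optional date/count/accession columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"reference", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records table lacks columns {sorted(missing)}")
    records: list[CollectionRecord] = []
    for _, row in df.iterrows():
        lat = float(row["lat"]) if row.get("lat", "") else None
        lon = float(row["lon"]) if row.get("lon", "") else None
        date_raw = row.get("date", "")
        if date_raw:
            date, ok = parse_date(date_raw)
        else:
            date, ok = None, True
        count_raw = row.get("count", "")
        count = categorize_sample_size(int(count_raw)) if count_raw else None
        acc_raw = row.get("coi_accession", "") or row.get("accessions", "")
        accessions = tuple(a.strip() for a in acc_raw.split(",") if a.strip())
        records.append(
            CollectionRecord(
                reference=row["reference"],
                species=row["species"],
                locality=row.get("locality", ""),
                lat=lat,
                lon=lon,
                date=date,
                date_parsed=ok,
                count=count,
                accessions=accessions,
            )
        )
    return records


def _k(tag: str) -> str:
    return f"{{{KML_NS}}}{tag}"


def to_kml(records: Sequence[CollectionRecord]) -> bytes:
    """Serialise records as an OGC KML 2.2 document.

    One folder per species, one placemark per georeferenced record;
    placemark name = collection reference, the title (species + reference)
    goes in the address field of the description, coordinates in lon,lat
    order. Records without coordinates are skipped with a log message.
    """
    root = etree.Element(_k("kml"), nsmap={None: KML_NS})
    doc = etree.SubElement(root, _k("Document"))

    by_species: dict[str, list[CollectionRecord]] = {}
    for rec in records:
        if not rec.georeferenced:
            logger.warning("record %s has no coordinates; skipped", rec.reference)
            continue
        by_species.setdefault(rec.species, []).append(rec)

    for species in sorted(by_species):
        folder = etree.SubElement(doc, _k("Folder"))
        etree.SubElement(folder, _k("name")).text = species
        for rec in by_species[species]:
            pm = etree.SubElement(folder, _k("Placemark"))
            etree.SubElement(pm, _k("name")).text = rec.reference
            etree.SubElement(pm, _k("address")).text = f"{species} {rec.reference}"
            etree.SubElement(pm, _k("description")).text = rec.description_paragraph()
            point = etree.SubElement(pm, _k("Point"))
            etree.SubElement(point, _k("coordinates")).text = (
                f"{rec.lon:.6f},{rec.lat:.6f}"
            )
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def parse_kml(data: bytes | str) -> list[CollectionRecord]:
    """Recover (species, reference, coordinates) from a KML document
    produced by :func:`to_kml`."""
    if isinstance(data, str):
        data = data.encode()
    root = etree.fromstring(data)
    records: list[CollectionRecord] = []
    for folder in root.iter(_k("Folder")):
        species = folder.findtext(_k("name"))
        for pm in folder.iter(_k("Placemark")):
            reference = pm.findtext(_k("name"))
            coords = pm.findtext(f"{_k('Point')}/{_k('coordinates')}")
            lon_s, lat_s = coords.strip().split(",")[:2]
            records.append(
                CollectionRecord(
                    reference=reference,
                    species=species,
                    lat=float(lat_s),
                    lon=float(lon_s),
                )
            )
    return records
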