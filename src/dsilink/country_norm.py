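"""Resolve raw country strings to curated country entities and groups.

Geographic provenance in sequence records (the source-feature ``/country``
qualifier, conventionally ``"Country: region"``) and author affiliations
both use partly ambiguous names: common names ("Great Britain"), official
names, historic names ("Soviet Union"), marine sampling areas ("Bismarck
Sea"), and dependent territories.  This module resolves such strings against
a curated table of UN member states with ISO-3166-1 codes, synonyms and
continent assignments:

* marine-area names consolidate under a single "Ocean" pseudo-entry (a
  sampling-environment label, not a legal high-seas category);
* dependent territories and autonomous areas map to the responsible UN
  state party via explicit ``territory_mapped`` rows;
* historic countries resolve as ``obsolete`` — kept in the data, ignored by
  summary statistics;
* anything else is ``unresolved`` and reported for manual synonym curation.

Matching is exact after normalization (case/diacritics/punctuation folded);
there is deliberately no edit-distance guessing, so every resolution is
auditable back to a table row.

The shipped ``COUNTRY`` / ``COUNTRY2GRP`` / ``GEOLOCATION`` CSVs are dated
curation snapshots and can be replaced wholesale by the user.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CountryEntry",
    "CountryResolution",
    "CountryTable",
    "CountryGroup",
    "Geolocation",
    "OCEAN_ISO2",
    "default_table",
    "default_groups",
    "default_geolocation",
    "assign_groups",
    "affiliation_countries",
    "resolve_country",
]

OCEAN_ISO2 = "ZZ"

STATUSES = ("un_member", "ocean", "territory_mapped", "obsolete")


@dataclass(frozen=True)
class CountryEntry:
    iso2: str
    iso3: str
    numeric: int
    official_name: str
    short_name: str
    synonyms: frozenset[str]
    continent: str
    status: str = "un_member"
    maps_to: str = ""  # target iso2 for territory_mapped rows


@dataclass(frozen=True)
class CountryResolution:
    """Outcome of resolving one raw string."""

    input_raw: str
    matched_entry: CountryEntry | None
    region_suffix: str = ""
    outcome: str = "unresolved"  # resolved | ocean | obsolete | unresolved | empty

    @property
    def stats_eligible(self) -> bool:
        return self.outcome in ("resolved", "ocean")

    @property
    def iso2(self) -> str:
        return self.matched_entry.iso2 if self.matched_entry else ""


@dataclass(frozen=True)
class CountryGroup:
    group_code: str  # OECD | BRICS | G77
    members: frozenset[str]


@dataclass(frozen=True)
class Geolocation:
    iso2: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise ValueError(f"coordinates out of range for {self.iso2}")


def normalize_name(raw: str) -> str:
    """Fold case, diacritics and punctuation to a canonical lookup key."""
    s = unicodedata.normalize("NFKD", raw)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = "".join(ch if ch.isalnum() else " " for ch in s)
    return " ".join(s.casefold().split())


class CountryTable:
    """The curated COUNTRY table with its synonym index.

    Loading enforces the table invariants: ISO codes unique, every synonym
    resolving to exactly one entry, territory targets existing.
    """

    def __init__(self, entries: Iterable[CountryEntry]):
        self.entries: list[CountryEntry] = list(entries)
        self.by_iso2: dict[str, CountryEntry] = {}
        self._index: dict[str, CountryEntry] = {}
        seen_iso3: set[str] = set()
        seen_num: set[int] = set()
        for e in self.entries:
            if e.iso2 in self.by_iso2 or e.iso3 in seen_iso3 or e.numeric in seen_num:
                raise ValueError(f"duplicate ISO code for entry {e.iso2}/{e.iso3}")
            self.by_iso2[e.iso2] = e
            seen_iso3.add(e.iso3)
            seen_num.add(e.numeric)
            for name in {e.official_name, e.short_name, *e.synonyms}:
                key = normalize_name(name)
                if not key:
                    continue
                if key in self._index and self._index[key] is not e:
                    raise ValueError(
                        f"ambiguous synonym {name!r}: {self._index[key].iso2} vs {e.iso2}"
                    )
                self._index[key] = e
        for e in self.entries:
            if e.status == "territory_mapped" and e.maps_to not in self.by_iso2:
                raise ValueError(f"territory {e.iso2} maps to unknown target {e.maps_to!r}")

    def lookup(self, name: str) -> CountryEntry | None:
        return self._index.get(normalize_name(name))

    def resolve(self, raw: str) -> CountryResolution:
        """Resolve one raw country string (total function, never raises)."""
        if raw is None or not raw.strip():
            return CountryResolution(raw or "", None, outcome="empty")
        name, _, region = raw.partition(":")
        region = region.strip()
        entry = self.lookup(name)
        if entry is None:
            return CountryResolution(raw, None, region, "unresolved")
        if entry.status == "obsolete":
            return CountryResolution(raw, entry, region, "obsolete")
        if entry.status == "ocean":
            return CountryResolution(raw, entry, region, "ocean")
        if entry.status == "territory_mapped":
            entry = self.by_iso2[entry.maps_to]
        return CountryResolution(raw, entry, region, "resolved")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountryTable":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls(_entries_from_reader(csv.DictReader(fh)))

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {
                "iso2": e.iso2,
                "iso3": e.iso3,
                "numeric": e.numeric,
                "official_name": e.official_name,
                "short_name": e.short_name,
                "synonyms": "|".join(sorted(e.synonyms)),
                "continent": e.continent,
                "status": e.status,
                "maps_to": e.maps_to,
            }
            for e in self.entries
        ]


def _entries_from_reader(reader: Iterable[Mapping[str, str]]) -> list[CountryEntry]:
    entries = []
    for row in reader:
        if row["status"] not in STATUSES:
            raise ValueError(f"unknown status {row['status']!r} for {row['iso2']}")
        entries.append(
            CountryEntry(
                iso2=row["iso2"].strip(),
                iso3=row["iso3"].strip(),
                numeric=int(row["numeric"]),
                official_name=row["official_name"].strip(),
                short_name=row["short_name"].strip(),
                synonyms=frozenset(
                    s.strip() for s in row.get("synonyms", "").split("|") if s.strip()
                ),
                continent=row["continent"].strip(),
                status=row["status"].strip(),
                maps_to=row.get("maps_to", "").strip(),
            )
        )
    return entries


def resolve_country(raw: str, table: CountryTable) -> CountryResolution:
    """Functional alias for :meth:`CountryTable.resolve`."""
    return table.resolve(raw)


def assign_groups(iso2: str, groups: Iterable[CountryGroup]) -> set[str]:
    """Economic-group codes containing ``iso2`` (possibly empty)."""
    return {g.group_code for g in groups if iso2 in g.members}


def affiliation_countries(
    affiliation_strings: Iterable[str], table: CountryTable
) -> list[CountryResolution]:
    """Resolve author affiliations to countries.

    Affiliations conventionally end with the country, so each string is
    scanned from its last comma-segment backwards, trying the longest word
    suffix of each segment first.  Resolved countries are deduplicated
    (per article) preserving first-seen order; strings with no resolvable
    name yield an ``unresolved`` entry.
    """
    out: list[CountryResolution] = []
    seen: set[str] = set()
    for aff in affiliation_strings:
        res = _scan_affiliation(aff, table)
        if res.outcome == "resolved":
            if res.iso2 not in seen:
                seen.add(res.iso2)
                out.append(res)
        else:
            out.append(res)
    return out


def _scan_affiliation(aff: str, table: CountryTable) -> CountryResolution:
    segments = [s for s in aff.split(",") if s.strip()]
    for seg in reversed(segments):
        words = seg.split()
        for start in range(len(words)):
            candidate = " ".join(words[start:])
            entry = table.lookup(candidate)
            if entry is not None:
                res = table.resolve(candidate)
                if res.outcome in ("resolved", "ocean"):
                    return CountryResolution(aff, res.matched_entry, "", res.outcome)
    return CountryResolution(aff, None, "", "unresolved")


# ---------------------------------------------------------------------------
# shipped snapshot loaders

def _data_path(name: str):
    return resources.files("dsilink.data").joinpath(name)


def default_table() -> CountryTable:
    """The shipped COUNTRY snapshot (UN members + Ocean + territories + obsolete)."""
    with _data_path("country.csv").open(newline="", encoding="utf-8") as fh:
        return CountryTable(_entries_from_reader(csv.DictReader(fh)))


def default_groups() -> list[CountryGroup]:
    """The shipped OECD / BRICS / G77 membership snapshot."""
    members: dict[str, set[str]] = {}
    with _data_path("country_groups.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            members.setdefault(row["group_code"].strip(), set()).add(row["iso2"].strip())
    return [CountryGroup(code, frozenset(m)) for code, m in sorted(members.items())]


def default_geolocation() -> list[Geolocation]:
    """Approximate country centroids for map projection."""
    out = []
    with _data_path("geolocation.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Geolocation(row["iso2"].strip(), float(row["latitude"]), float(row["longitude"]))
            )
    return out
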