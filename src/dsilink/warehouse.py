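"""Assemble and check the six-table citation warehouse.

The warehouse links sequence records to articles in two directions:

* ``primary`` — the deposition's own paper, taken from the literature
  cross-references inside the ENA entry and matched to articles on any of
  DOI (case-insensitive), PMID or PMCID;
* ``secondary`` — articles whose full text cites the sequence, taken from
  extracted accession mentions intersected with the sequence table; a cited
  project accession links to every sequence carrying that project.

Tables: ENA_SEQUENCES, PMC_REFERENCES, SEQ2PUB_LINKS, plus the shipped
COUNTRY / COUNTRY2GRP / GEOLOCATION reference tables.  Sequences with
invalid or obsolete country tags are kept in the tables with an eligibility
flag rather than dropped, so summary statistics can exclude them without
the raw data ever being rewritten.

Storage is deliberately portable: plain pandas tables with documented keys,
exported as RFC-4180 CSV; nothing vendor-specific.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .accession_grammar import Kind
from .citation_extract import AccessionMention, ArticleDoc, PatternClass
from .country_norm import (
    CountryGroup,
    CountryTable,
    affiliation_countries,
    default_geolocation,
    default_groups,
    default_table,
)
from .embl_io import EnaRecord

__all__ = ["Warehouse", "QcReport", "BuildConfig", "build_warehouse", "integrity_check", "export_csv"]

COUNTRY_SNAPSHOT_DATE = "2021-06-30"

_SEQ_COLS = [
    "accession", "version", "project_accessions", "raw_country", "region",
    "country_iso2", "country_status", "stats_eligible", "taxon_name",
    "record_length", "doi", "pmid", "pmcid",
]
_ART_COLS = ["article_id", "pmcid", "pmid", "doi", "year", "author_countries", "n_affiliations"]
_LINK_COLS = ["accession", "article_id", "direction", "pattern_class", "id_kind"]


@dataclass
class QcReport:
    """Plausibility counters recomputable from the tables."""

    n_records_total: int = 0
    n_wgs_excluded: int = 0
    n_valid_country: int = 0
    n_invalid_country: int = 0
    n_no_primary_ref: int = 0
    n_primary_linked_records: int = 0
    n_primary_linked_articles: int = 0
    n_secondary_linked_records: int = 0
    n_secondary_linked_articles: int = 0
    n_unlinked_mentions: int = 0
    dangling_key_count: int = 0
    rejected_articles: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class BuildConfig:
    country_table: CountryTable | None = None
    groups: Sequence[CountryGroup] | None = None
    n_wgs_excluded: int = 0  # carried over from the parse report
    meta: dict = field(default_factory=dict)


@dataclass
class Warehouse:
    """The linked tables plus build metadata."""

    ena_sequences: pd.DataFrame
    pmc_references: pd.DataFrame
    seq2pub_links: pd.DataFrame
    country: pd.DataFrame
    country2grp: pd.DataFrame
    geolocation: pd.DataFrame
    build_meta: dict = field(default_factory=dict)

    def table_names(self) -> list[str]:
        return [
            "ena_sequences", "pmc_references", "seq2pub_links",
            "country", "country2grp", "geolocation",
        ]


def build_warehouse(
    records: Iterable[EnaRecord],
    articles: Iterable[ArticleDoc],
    mentions: Mapping[str, Iterable[AccessionMention]],
    config: BuildConfig | None = None,
) -> tuple[Warehouse, QcReport]:
    """Normalise inputs into the warehouse tables and report QC counters.

    ``mentions`` maps article ids (PMCID-preferred keys) to extracted
    mentions of that article's full text.  Duplicate primary accessions are
    a hard error; an article without any identifier is rejected with a
    report entry rather than aborting the build.
    """
    config = config or BuildConfig()
    table = config.country_table or default_table()
    groups = list(config.groups) if config.groups is not None else default_groups()
    report = QcReport(n_wgs_excluded=config.n_wgs_excluded)

    records = list(records)
    dup = _duplicates(r.accession for r in records)
    if dup:
        raise ValueError(f"duplicate primary accessions: {sorted(dup)[:10]}")

    seq_rows = []
    for r in records:
        res = table.resolve(r.raw_country)
        ref = r.primary_refs[0] if r.primary_refs else None
        seq_rows.append(
            {
                "accession": r.accession,
                "version": r.version,
                "project_accessions": ";".join(sorted(r.project_accessions)),
                "raw_country": r.raw_country,
                "region": res.region_suffix,
                "country_iso2": res.iso2 if res.stats_eligible else "",
                "country_status": res.outcome,
                "stats_eligible": res.stats_eligible,
                "taxon_name": r.taxon_name,
                "record_length": r.record_length,
                "doi": ref.doi if ref else "",
                "pmid": ref.pmid if ref else "",
                "pmcid": ref.pmcid if ref else "",
            }
        )
    seq_df = pd.DataFrame(seq_rows, columns=_SEQ_COLS).sort_values("accession", kind="mergesort")
    seq_df = seq_df.reset_index(drop=True)

    art_rows = []
    art_index: dict[str, ArticleDoc] = {}
    by_doi: dict[str, str] = {}
    by_pmid: dict[str, str] = {}
    by_pmcid: dict[str, str] = {}
    for doc in articles:
        try:
            aid = doc.article_id
        except Exception:
            aid = ""
        if not aid:
            report.rejected_articles.append("<article without identifier>")
            continue
        if aid in art_index:
            report.rejected_articles.append(f"duplicate article id {aid}")
            continue
        art_index[aid] = doc
        resolutions = affiliation_countries(doc.affiliation_strings, table)
        iso2s = [r.iso2 for r in resolutions if r.outcome == "resolved"]
        art_rows.append(
            {
                "article_id": aid,
                "pmcid": doc.pmcid,
                "pmid": doc.pmid,
                "doi": doc.doi,
                "year": doc.year,
                "author_countries": ";".join(iso2s),
                "n_affiliations": len(doc.affiliation_strings),
            }
        )
        if doc.doi:
            by_doi.setdefault(doc.doi.lower(), aid)
        if doc.pmid:
            by_pmid.setdefault(doc.pmid, aid)
        if doc.pmcid:
            by_pmcid.setdefault(doc.pmcid, aid)
    art_df = pd.DataFrame(art_rows, columns=_ART_COLS).sort_values("article_id", kind="mergesort")
    art_df = art_df.reset_index(drop=True)

    # primary direction: ENA entry cross-references -> article identifiers
    link_rows = []
    for r in records:
        matched: set[str] = set()
        for ref in r.primary_refs:
            aid = (
                by_pmcid.get(ref.pmcid)
                or by_pmid.get(ref.pmid)
                or (by_doi.get(ref.doi.lower()) if ref.doi else None)
            )
            if aid:
                matched.add(aid)
        for aid in sorted(matched):
            link_rows.append(
                {"accession": r.accession, "article_id": aid,
                 "direction": "primary", "pattern_class": "", "id_kind": ""}
            )

    # secondary direction: extracted mentions -> sequence table
    acc_set = set(seq_df["accession"])
    by_project: dict[str, list[str]] = {}
    for r in records:
        for prj in r.project_accessions:
            by_project.setdefault(prj, []).append(r.accession)
    for aid in sorted(art_index):
        seen: set[str] = set()
        for m in mentions.get(aid, ()):  # type: ignore[call-overload]
            for token in m.expanded:
                if m.id_kind is Kind.PROJECT or token.startswith("PRJ"):
                    targets = by_project.get(token, [])
                    if not targets:
                        report.n_unlinked_mentions += 1
                else:
                    targets = [token] if token in acc_set else []
                    if not targets:
                        report.n_unlinked_mentions += 1
                for acc in targets:
                    if acc in seen:
                        continue
                    seen.add(acc)
                    link_rows.append(
                        {"accession": acc, "article_id": aid, "direction": "secondary",
                         "pattern_class": m.pattern_class.value, "id_kind": m.id_kind.value}
                    )
    link_df = pd.DataFrame(link_rows, columns=_LINK_COLS).sort_values(
        ["direction", "accession", "article_id"], kind="mergesort"
    ).reset_index(drop=True)

    grp_rows = [
        {"group_code": g.group_code, "iso2": iso2}
        for g in sorted(groups, key=lambda g: g.group_code)
        for iso2 in sorted(g.members)
    ]
    geo_rows = [
        {"iso2": g.iso2, "latitude": g.latitude, "longitude": g.longitude}
        for g in default_geolocation()
    ]
    w = Warehouse(
        ena_sequences=seq_df,
        pmc_references=art_df,
        seq2pub_links=link_df,
        country=pd.DataFrame(table.to_rows()),
        country2grp=pd.DataFrame(grp_rows, columns=["group_code", "iso2"]),
        geolocation=pd.DataFrame(geo_rows, columns=["iso2", "latitude", "longitude"]),
        build_meta={
            "country_snapshot": COUNTRY_SNAPSHOT_DATE,
            "n_wgs_excluded": config.n_wgs_excluded,
            **config.meta,
        },
    )
    full = integrity_check(w)
    full.n_wgs_excluded = config.n_wgs_excluded
    full.n_unlinked_mentions = report.n_unlinked_mentions
    full.rejected_articles = report.rejected_articles
    return w, full


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def integrity_check(w: Warehouse) -> QcReport:
    """Recompute every QC counter from the tables alone (idempotent)."""
    seq = w.ena_sequences
    links = w.seq2pub_links
    report = QcReport(
        n_records_total=len(seq) + int(w.build_meta.get("n_wgs_excluded", 0)),
        n_wgs_excluded=int(w.build_meta.get("n_wgs_excluded", 0)),
        n_valid_country=int(seq["stats_eligible"].sum()) if len(seq) else 0,
        n_invalid_country=int((~seq["stats_eligible"].astype(bool)).sum()) if len(seq) else 0,
        n_no_primary_ref=int(
            ((seq["doi"] == "") & (seq["pmid"] == "") & (seq["pmcid"] == "")).sum()
        ) if len(seq) else 0,
    )
    for direction, rec_attr, art_attr in (
        ("primary", "n_primary_linked_records", "n_primary_linked_articles"),
        ("secondary", "n_secondary_linked_records", "n_secondary_linked_articles"),
    ):
        sub = links[links["direction"] == direction] if len(links) else links
        setattr(report, rec_attr, int(sub["accession"].nunique()) if len(sub) else 0)
        setattr(report, art_attr, int(sub["article_id"].nunique()) if len(sub) else 0)
    if len(links):
        dangling = (~links["accession"].isin(seq["accession"])).sum()
        dangling += (~links["article_id"].isin(w.pmc_references["article_id"])).sum()
        report.dangling_key_count = int(dangling)
    return report


def export_csv(w: Warehouse, directory: str | Path) -> dict:
    """Write one CSV per table plus a manifest of row counts and checksums.

    Exports are deterministic: identical warehouses produce byte-identical
    files (tables are written in stable order, UTF-8, RFC-4180 quoting).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for name in w.table_names():
        df: pd.DataFrame = getattr(w, name)
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest[name] = {"rows": int(len(df)), "sha256": digest}
    meta = {"tables": manifest, "build_meta": w.build_meta}
    (directory / "manifest.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta
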