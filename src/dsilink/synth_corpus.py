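"""Seeded synthetic corpus: ENA-style flat files and article texts with
planted ground-truth citations.

The generator emulates the statistical structure of the real inputs — a
sequence archive in which a configurable fraction of records carries a
valid, obsolete, empty or unresolvable country qualifier and a fraction
carries a primary literature reference, and an article corpus in which each
article cites a block of accessions in one of the citation pattern classes
(single accession, hyphenated range, in-text enumeration, or a list in
supplementary material).  Ranges are planted as blocks of consecutive
accessions that genuinely exist in the flat file, so range-aware extraction
can be scored against an exact ground truth.

Everything is driven by one explicitly-seeded ``random.Random``; equal
seeds produce byte-identical corpora.  The ground truth records every
planted link together with the counters a correct pipeline must reproduce,
and knows the closed-form single-token recall (ranges contribute only
their two endpoints to a plain token matcher).

What this corpus does *not* emulate: natural-language prose, citation
typos, accessions embedded in figure bitmaps, paywalled articles.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .citation_extract import ArticleDoc, PatternClass
from .country_norm import CountryTable, default_table
from .embl_io import EnaRecord, PubRef

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthCorpus",
    "generate",
    "make_range_undercount_passage",
]

_PREFIXES = ["AB", "AF", "AJ", "AM", "AY", "DQ", "EF", "EU", "HM", "KM", "KX", "LC", "MG", "MH", "MK"]
_WGS_PREFIXES = ["CAAB", "CABD", "JAAA", "JABX", "QXAA"]
_TAXA = [
    "Hordeum vulgare", "Arabidopsis thaliana", "Oryza sativa", "Danio rerio",
    "Escherichia coli", "Saccharomyces cerevisiae", "Drosophila melanogaster",
    "Triticum aestivum", "Mus musculus", "Zea mays",
]
_CITIES = [
    "Gatersleben", "Hinxton", "Braunschweig", "Leipzig", "Wernigerode",
    "Cambridge", "Heidelberg", "Uppsala", "Nairobi", "Kyoto",
]
_FILLERS = [
    "Total genomic DNA was extracted from field-collected specimens.",
    "Phylogenetic analyses were performed under maximum likelihood.",
    "Voucher specimens are stored at the institutional herbarium.",
    "Sampling permits were issued by the national authorities.",
    "Library preparation followed the standard protocol of the sequencing centre.",
]
_OBSOLETE_TAGS = ["Soviet Union", "USSR", "Yugoslavia", "Czechoslovakia"]
_UNRESOLVED_TAGS = ["Western Sahara", "Atlantis", "Unknown", "Borduria"]
_DEFAULT_AFFIL_POOL = (
    "DE", "GB", "US", "FR", "CN", "JP", "BR", "IN", "ZA", "KE",
    "AU", "CA", "ES", "IT", "NL", "SE", "KR", "MX", "AR", "RU",
)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus."""

    seed: int = 42
    n_records: int = 1000
    frac_valid_country: float = 0.15
    frac_obsolete_country: float = 0.01
    frac_empty_country: float = 0.83
    frac_with_primary_ref: float = 0.40
    frac_internal_primary_ref: float = 0.5
    n_articles: int = 200
    pattern_mix: dict = field(
        default_factory=lambda: {
            "single": 0.5, "range": 0.2, "enumeration": 0.2, "supplementary_list": 0.1,
        }
    )
    range_size_distribution: tuple[int, int] = (3, 10)
    enum_size_distribution: tuple[int, int] = (2, 4)
    supp_size_distribution: tuple[int, int] = (5, 10)
    affiliation_country_pool: Sequence[str] = _DEFAULT_AFFIL_POOL
    wgs_fraction: float = 0.05
    groups_per_article: int = 1
    ocean_share_of_valid: float = 0.1

    def validate(self) -> None:
        fracs = {
            "frac_valid_country": self.frac_valid_country,
            "frac_obsolete_country": self.frac_obsolete_country,
            "frac_empty_country": self.frac_empty_country,
            "frac_with_primary_ref": self.frac_with_primary_ref,
            "frac_internal_primary_ref": self.frac_internal_primary_ref,
            "wgs_fraction": self.wgs_fraction,
            "ocean_share_of_valid": self.ocean_share_of_valid,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        country_sum = (
            self.frac_valid_country + self.frac_obsolete_country + self.frac_empty_country
        )
        if country_sum > 1.0 + 1e-9:
            raise ValueError(f"country fractions sum to {country_sum} > 1")
        if abs(sum(self.pattern_mix.values()) - 1.0) > 1e-9:
            raise ValueError("pattern_mix must sum to 1")
        if set(self.pattern_mix) - {c.value for c in PatternClass}:
            raise ValueError(f"unknown pattern classes: {set(self.pattern_mix)}")
        if self.n_records < 0 or self.n_articles < 0 or self.groups_per_article < 1:
            raise ValueError("counts must be non-negative")
        for lo, hi in (
            self.range_size_distribution,
            self.enum_size_distribution,
            self.supp_size_distribution,
        ):
            if not (1 <= lo <= hi):
                raise ValueError("size distributions need 1 <= lo <= hi")


@dataclass(frozen=True)
class PlantedCitation:
    article_id: str
    pattern_class: str
    accessions: tuple[str, ...]

    @property
    def n_links(self) -> int:
        return len(self.accessions)

    @property
    def n_single_token_links(self) -> int:
        """Links a plain token matcher recovers: ranges yield endpoints only."""
        if self.pattern_class == "range":
            return min(2, len(self.accessions))
        return len(self.accessions)


@dataclass
class GroundTruth:
    """Everything a correct pipeline must recover from the corpus."""

    citations: list[PlantedCitation]
    record_country: dict[str, str]  # accession -> planted category
    expected: dict[str, int]  # QC / headline counters

    def link_pairs(self) -> set[tuple[str, str]]:
        return {
            (c.article_id, acc) for c in self.citations for acc in c.accessions
        }

    def expected_single_token_recall(self) -> float:
        """Closed-form recall of a plain token matcher on the planted links."""
        total = sum(c.n_links for c in self.citations)
        found = sum(c.n_single_token_links for c in self.citations)
        return found / total if total else 1.0

    def score(self, extracted: Mapping[str, Iterable[str]]) -> tuple[float, float]:
        """Precision and recall of ``{article_id: accessions}`` against the truth."""
        truth = self.link_pairs()
        got = {(aid, acc) for aid, accs in extracted.items() for acc in accs}
        if not got:
            return (1.0 if not truth else 0.0, 0.0 if truth else 1.0)
        tp = len(got & truth)
        return tp / len(got), tp / len(truth) if truth else 1.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "citations": [
                    {
                        "article_id": c.article_id,
                        "pattern_class": c.pattern_class,
                        "accessions": list(c.accessions),
                    }
                    for c in self.citations
                ],
                "record_country": self.record_country,
                "expected": self.expected,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SynthCorpus:
    config: SynthConfig
    records: list[EnaRecord]
    articles: list[ArticleDoc]
    truth: GroundTruth

    def write(self, directory: str | Path, jats_fraction: float = 0.5) -> None:
        """Write the corpus as text files: ``ena.dat`` flat file, one JATS or
        plain-text file per article, and ``ground_truth.json``."""
        from .embl_io import write_embl_flatfile

        directory = Path(directory)
        (directory / "articles").mkdir(parents=True, exist_ok=True)
        with open(directory / "ena.dat", "w", encoding="utf-8") as fh:
            write_embl_flatfile(self.records, fh)
        n_jats = int(round(jats_fraction * len(self.articles)))
        for i, doc in enumerate(self.articles):
            stem = directory / "articles" / f"article_{i:04d}"
            if i < n_jats:
                _write_jats(doc, stem.with_suffix(".xml"))
            else:
                stem.with_suffix(".txt").write_text(doc.body_text, encoding="utf-8")
                if doc.supplementary_texts:
                    Path(f"{stem}.supp.txt").write_text(
                        "\n".join(doc.supplementary_texts), encoding="utf-8"
                    )
                Path(f"{stem}.meta.json").write_text(
                    json.dumps(
                        {
                            "pmcid": doc.pmcid,
                            "pmid": doc.pmid,
                            "doi": doc.doi,
                            "year": doc.year,
                            "affiliations": doc.affiliation_strings,
                        },
                        indent=2,
                        sort_keys=True,
                    ),
                    encoding="utf-8",
                )
        (directory / "ground_truth.json").write_text(self.truth.to_json(), encoding="utf-8")


def _round_count(frac: float, n: int) -> int:
    return int(round(frac * n + 1e-9))


class _AccessionAllocator:
    """Collision-free accession allocation; ranges get consecutive blocks."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: dict[str, set[int]] = {p: set() for p in _PREFIXES}

    def block(self, size: int) -> list[str]:
        for _ in range(200):
            prefix = self.rng.choice(_PREFIXES)
            start = self.rng.randint(1, 999_999 - size)
            numbers = range(start, start + size)
            if not any(n in self.used[prefix] for n in numbers):
                self.used[prefix].update(numbers)
                return [f"{prefix}{n:06d}" for n in numbers]
        raise RuntimeError("accession space exhausted")

    def single(self) -> str:
        return self.block(1)[0]


def _largest_remainder(weights: Mapping[str, float], total: int) -> dict[str, int]:
    raw = {k: w * total for k, w in weights.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


def generate(config: SynthConfig | None = None, table: CountryTable | None = None) -> SynthCorpus:
    """Generate a corpus under ``config`` (deterministic for a fixed seed)."""
    config = config or SynthConfig()
    config.validate()
    rng = random.Random(config.seed)
    table = table or default_table()

    n_wgs = _round_count(config.wgs_fraction, config.n_records)
    n_seq = config.n_records - n_wgs

    # -- plan the planted citations -------------------------------------
    n_groups = config.n_articles * config.groups_per_article
    class_counts = _largest_remainder(config.pattern_mix, n_groups)
    classes = [c for c, k in sorted(class_counts.items()) for _ in range(k)]
    rng.shuffle(classes)

    sizes = []
    for cls in classes:
        if cls == "single":
            sizes.append(1)
        elif cls == "range":
            sizes.append(rng.randint(*config.range_size_distribution))
        elif cls == "enumeration":
            sizes.append(rng.randint(*config.enum_size_distribution))
        else:
            sizes.append(rng.randint(*config.supp_size_distribution))
    if sum(sizes) > n_seq:
        raise ValueError(
            f"infeasible config: planted citations need {sum(sizes)} accessions "
            f"but only {n_seq} non-WGS records are configured"
        )

    alloc = _AccessionAllocator(rng)
    plant_accessions: list[list[str]] = []
    for cls, size in zip(classes, sizes):
        if cls == "range":
            plant_accessions.append(alloc.block(size))
        else:
            plant_accessions.append(sorted(alloc.single() for _ in range(size)))

    cited = [a for block in plant_accessions for a in block]
    uncited = [alloc.single() for _ in range(n_seq - len(cited))]
    accessions = cited + uncited

    # -- articles ---------------------------------------------------------
    articles: list[ArticleDoc] = []
    citations: list[PlantedCitation] = []
    group_iter = iter(zip(classes, plant_accessions))
    for i in range(config.n_articles):
        pmcid = f"PMC{7_000_000 + i}"
        doc = ArticleDoc(
            pmcid=pmcid,
            pmid=str(30_000_000 + i),
            doi=f"10.5555/synth.{i:04d}",
            year=rng.randint(2005, 2021),
        )
        n_aff = rng.randint(1, 2)
        for _ in range(n_aff):
            iso2 = rng.choice(list(config.affiliation_country_pool))
            entry = table.by_iso2[iso2]
            doc.affiliation_strings.append(
                f"Department of Biology, University of {rng.choice(_CITIES)}, {entry.short_name}"
            )
        body = [rng.choice(_FILLERS)]
        for _ in range(config.groups_per_article):
            cls, accs = next(group_iter)
            body.append(_citation_sentence(rng, cls, accs, doc))
            citations.append(PlantedCitation(doc.article_id, cls, tuple(accs)))
        body.append(rng.choice(_FILLERS))
        doc.body_text = " ".join(s for s in body if s)
        articles.append(doc)

    # -- records ----------------------------------------------------------
    valid_entries = [e for e in table.entries if e.status == "un_member"]
    ocean_entry = next(e for e in table.entries if e.status == "ocean")
    # fractions are read against the total record count; categories are
    # assigned among the non-WGS records (WGS entries carry no country tag)
    n_valid = _round_count(config.frac_valid_country, config.n_records)
    n_obsolete = _round_count(config.frac_obsolete_country, config.n_records)
    n_empty = min(_round_count(config.frac_empty_country, config.n_records), n_seq - n_valid - n_obsolete)
    if n_valid + n_obsolete > n_seq or n_empty < 0:
        raise ValueError("infeasible config: country fractions exceed non-WGS record count")
    order = list(range(n_seq))
    rng.shuffle(order)
    category = {}
    for pos, idx in enumerate(order):
        if pos < n_valid:
            category[idx] = "valid"
        elif pos < n_valid + n_obsolete:
            category[idx] = "obsolete"
        elif pos < n_valid + n_obsolete + n_empty:
            category[idx] = "empty"
        else:
            category[idx] = "unresolved"

    n_ref = min(_round_count(config.frac_with_primary_ref, config.n_records), n_seq)
    ref_idx = set(rng.sample(range(n_seq), n_ref))
    n_internal = _round_count(config.frac_internal_primary_ref, n_ref)
    internal_idx = set(rng.sample(sorted(ref_idx), n_internal)) if articles else set()

    project_pool = [f"PRJEB{40_000 + k}" for k in range(max(1, n_seq // 50))]

    records: list[EnaRecord] = []
    primary_pairs: set[tuple[str, str]] = set()
    record_country: dict[str, str] = {}
    for idx, acc in enumerate(accessions):
        cat = category[idx]
        if cat == "valid":
            if rng.random() < config.ocean_share_of_valid:
                raw = rng.choice(sorted(ocean_entry.synonyms))
            else:
                entry = rng.choice(valid_entries)
                raw = entry.short_name
                if rng.random() < 0.3:
                    raw = f"{raw}: {rng.choice(_CITIES)}"
        elif cat == "obsolete":
            raw = rng.choice(_OBSOLETE_TAGS)
        elif cat == "unresolved":
            raw = rng.choice(_UNRESOLVED_TAGS)
        else:
            raw = ""
        refs: tuple[PubRef, ...] = ()
        if idx in ref_idx:
            if idx in internal_idx:
                art = rng.choice(articles)
                which = rng.randrange(3)
                if which == 0:
                    refs = (PubRef(pmcid=art.pmcid),)
                elif which == 1:
                    refs = (PubRef(pmid=art.pmid),)
                else:
                    refs = (PubRef(doi=art.doi),)
                primary_pairs.add((art.article_id, acc))
            else:
                refs = (PubRef(doi=f"10.9999/external.{idx:05d}"),)
        records.append(
            EnaRecord(
                accession=acc,
                version=rng.randint(1, 3),
                project_accessions=(
                    frozenset([rng.choice(project_pool)]) if rng.random() < 0.3 else frozenset()
                ),
                raw_country=raw,
                primary_refs=refs,
                taxon_name=rng.choice(_TAXA),
                record_length=rng.randint(300, 2500),
            )
        )
        record_country[acc] = cat
    for _ in range(n_wgs):
        prefix = rng.choice(_WGS_PREFIXES)
        records.append(
            EnaRecord(
                accession=f"{prefix}{rng.randint(1, 99_999_999):08d}",
                version=1,
                raw_country="",
                taxon_name=rng.choice(_TAXA),
                record_length=rng.randint(300, 2500),
            )
        )
    rng.shuffle(records)

    expected = {
        "n_records_total": config.n_records,
        "n_wgs_excluded": n_wgs,
        "n_valid_country": n_valid,
        "n_invalid_country": n_seq - n_valid,
        "n_no_primary_ref": n_seq - n_ref,
        "n_primary_linked_records": len({a for _, a in primary_pairs}),
        "n_primary_linked_articles": len({aid for aid, _ in primary_pairs}),
        "n_secondary_linked_records": len({a for c in citations for a in c.accessions}),
        "n_secondary_linked_articles": len({c.article_id for c in citations}),
        "dangling_key_count": 0,
    }
    truth = GroundTruth(citations=citations, record_country=record_country, expected=expected)
    return SynthCorpus(config=config, records=records, articles=articles, truth=truth)


def _citation_sentence(
    rng: random.Random, cls: str, accs: Sequence[str], doc: ArticleDoc
) -> str:
    if cls == "single":
        return (
            "The newly generated sequence was deposited in the European "
            f"Nucleotide Archive under accession {accs[0]}."
        )
    if cls == "range":
        dash = rng.choice(["-", "–", " to "])
        return f"All sequences are available under accessions {accs[0]}{dash}{accs[-1]}."
    if cls == "enumeration":
        listing = ", ".join(accs[:-1]) + " and " + accs[-1]
        return f"Accessions {listing} were analysed in this study."
    # supplementary_list: the body only points at the supplement
    doc.supplementary_texts.append(
        "Supplementary Table S1. ENA accessions of all analysed sequences: "
        + ", ".join(accs)
        + "."
    )
    return "Accession numbers of all analysed sequences are listed in Supplementary Table S1."


def _write_jats(doc: ArticleDoc, path: Path) -> None:
    from xml.sax.saxutils import escape

    paragraphs = "".join(f"<p>{escape(s)}</p>" for s in doc.body_text.split(". ") if s)
    affs = "".join(f"<aff>{escape(a)}</aff>" for a in doc.affiliation_strings)
    supp = "".join(
        f'<sec sec-type="supplementary-material"><p>{escape(s)}</p></sec>'
        for s in doc.supplementary_texts
    )
    xml = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        "<article>"
        "<front><article-meta>"
        f'<article-id pub-id-type="pmcid">{escape(doc.pmcid)}</article-id>'
        f'<article-id pub-id-type="pmid">{escape(doc.pmid)}</article-id>'
        f'<article-id pub-id-type="doi">{escape(doc.doi)}</article-id>'
        f"{affs}<pub-date><year>{doc.year}</year></pub-date>"
        "</article-meta></front>"
        f"<body>{paragraphs}</body>"
        f"<back>{supp}</back>"
        "</article>\n"
    )
    path.write_text(xml, encoding="utf-8")


def make_range_undercount_passage(
    total: int = 35, n_ranges: int = 4, prefix: str = "AB", start: int = 1
) -> tuple[str, list[str]]:
    """Build a synthetic passage citing ``total`` accessions via ``n_ranges``
    hyphenated ranges, and the full list of cited accessions.

    A plain token matcher sees only the ``2 * n_ranges`` endpoint tokens —
    the mechanism by which range notation makes text mining undercount
    cited sequences (e.g. 35 actual citations vs 8 matched tokens).
    """
    if not (1 <= n_ranges and 2 * n_ranges <= total):
        raise ValueError("need ranges of length >= 2 summing to total")
    base, extra = divmod(total, n_ranges)
    sizes = [base + (1 if i < extra else 0) for i in range(n_ranges)]
    spans = []
    n = start
    all_accs = []
    for s in sizes:
        first, last = n, n + s - 1
        spans.append(f"{prefix}{first:06d}–{prefix}{last:06d}")
        all_accs.extend(f"{prefix}{k:06d}" for k in range(first, last + 1))
        n = last + 1
    listing = ", ".join(spans[:-1]) + " and " + spans[-1]
    text = f"Sequence data are available from ENA under accessions {listing}."
    return text, all_accs
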