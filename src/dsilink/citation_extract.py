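"""Find accession citations in article full text.

Authors cite sequence records in several distinct textual patterns: a single
accession set off by word separators; a hyphenated range standing for a block
of consecutive accessions ("AB000001–AB000035"); an in-text enumeration
("AB000001, AB000002 and AB000004"); and plain lists in supplementary
material.  (A fifth pattern — accessions embedded in figure bitmaps — would
need OCR and is out of scope; the extractor has zero coverage for it.)

Two extraction modes are provided:

``single_token``
    emulates a plain token matcher: a candidate is any maximal run of ASCII
    letters/digits that classifies as a sequence or project accession.  A
    hyphenated range therefore contributes only its two endpoints — the
    systematic undercount this package quantifies.

``range_aware``
    additionally recognises endpoint pairs joined by a hyphen/en-dash/em-dash
    or the words "to"/"through", expanding them via the accession grammar,
    and groups comma/semicolon/"and" enumerations.

Both modes report half-open 0-based character spans, sorted by span start,
with overlaps resolved longest-match-first (a range or enumeration subsumes
its member tokens).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .accession_grammar import Grammar, Kind, RangeError, classify, expand_range

__all__ = [
    "PatternClass",
    "Mode",
    "AccessionMention",
    "ArticleDoc",
    "LinkResult",
    "extract_mentions",
    "link_article",
    "load_article_jats",
    "load_article_text",
    "load_articles",
]

log = logging.getLogger(__name__)


class PatternClass(str, Enum):
    SINGLE = "single"
    RANGE = "range"
    ENUMERATION = "enumeration"
    SUPPLEMENTARY_LIST = "supplementary_list"


class Mode(str, Enum):
    SINGLE_TOKEN = "single_token"
    RANGE_AWARE = "range_aware"


@dataclass(frozen=True)
class AccessionMention:
    """One recognised citation in a text."""

    matched_text: str
    span: tuple[int, int]
    pattern_class: PatternClass
    expanded: tuple[str, ...]
    id_kind: Kind
    source: str = "body"


@dataclass
class ArticleDoc:
    """A full-text article with minimal metadata."""

    pmcid: str = ""
    pmid: str = ""
    doi: str = ""
    body_text: str = ""
    supplementary_texts: list[str] = field(default_factory=list)
    affiliation_strings: list[str] = field(default_factory=list)
    year: int = 0

    def __post_init__(self) -> None:
        if not (self.pmcid or self.pmid or self.doi):
            raise ValueError("ArticleDoc needs at least one of pmcid/pmid/doi")
        if self.pmcid and not self.pmcid.startswith("PMC"):
            raise ValueError(f"pmcid must start with 'PMC': {self.pmcid!r}")

    @property
    def article_id(self) -> str:
        """Stable key: PMCID preferred, then PMID, then DOI."""
        return self.pmcid or self.pmid or self.doi.lower()


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_RANGE_GAP_RE = re.compile(r"\s*[-–—]\s*|\s+(?:to|through)\s+")
_ENUM_GAP_RE = re.compile(r"\s*[,;]\s*(?:and\s+)?|\s+and\s+")

_CUE_RE = re.compile(
    r"accession|ENA|GenBank|EMBL|DDBJ|deposited|BioProject|sequence", re.IGNORECASE
)


@dataclass(frozen=True)
class _Candidate:
    text: str
    start: int
    end: int
    shape: "object"


def _candidates(text: str, grammar: Grammar) -> list[_Candidate]:
    """Accession-shaped maximal alphanumeric runs, version suffix attached."""
    tokens = list(_TOKEN_RE.finditer(text))
    out: list[_Candidate] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        shape = classify(tok.group(), grammar)
        if shape.kind in (Kind.SEQUENCE, Kind.PROJECT):
            start, end = tok.span()
            # absorb an immediately following ".N" version suffix
            if (
                i + 1 < len(tokens)
                and tokens[i + 1].group().isdigit()
                and text[end : tokens[i + 1].start()] == "."
            ):
                end = tokens[i + 1].end()
                shape = classify(text[start:end], grammar)
                i += 1
            out.append(_Candidate(text[start:end], start, end, shape))
        i += 1
    return out


def extract_mentions(
    text: str,
    mode: Mode | str = Mode.RANGE_AWARE,
    grammar: Grammar | None = None,
    require_context_cue: bool = False,
    cue_window: int = 200,
) -> list[AccessionMention]:
    """Extract accession citations from ``text`` under the given mode.

    Range endpoints that fail expansion (prefix/width/order/cap violations)
    degrade to two single mentions with a logged warning — extraction never
    hard-fails on author notation.
    """
    mode = Mode(mode)
    grammar = grammar or Grammar()
    cands = _candidates(text, grammar)

    if mode is Mode.SINGLE_TOKEN:
        mentions = [_single(c) for c in cands]
    else:
        mentions = _range_aware(text, cands, grammar)

    if require_context_cue:
        mentions = [
            m
            for m in mentions
            if _CUE_RE.search(
                text[max(0, m.span[0] - cue_window) : m.span[1] + cue_window]
            )
        ]
    return mentions


def _single(c: _Candidate) -> AccessionMention:
    return AccessionMention(
        matched_text=c.text,
        span=(c.start, c.end),
        pattern_class=PatternClass.SINGLE,
        expanded=(c.shape.canonical,),
        id_kind=c.shape.kind,
    )


def _range_aware(
    text: str, cands: list[_Candidate], grammar: Grammar
) -> list[AccessionMention]:
    n = len(cands)
    mentions: list[AccessionMention] = []
    consumed = [False] * n
    forced_single = [False] * n

    # pass 1: adjacent sequence-accession pairs joined by a range connector
    i = 0
    while i < n - 1:
        a, b = cands[i], cands[i + 1]
        gap = text[a.end : b.start]
        if (
            a.shape.kind is Kind.SEQUENCE
            and b.shape.kind is Kind.SEQUENCE
            and _RANGE_GAP_RE.fullmatch(gap)
        ):
            try:
                expanded = expand_range(
                    a.shape.canonical, b.shape.canonical, cap=grammar.range_cap
                )
            except RangeError as exc:
                log.warning(
                    "range %s..%s not expandable (%s); keeping endpoints as singles",
                    a.text,
                    b.text,
                    exc.reason,
                )
                forced_single[i] = forced_single[i + 1] = True
                i += 2
                continue
            mentions.append(
                AccessionMention(
                    matched_text=text[a.start : b.end],
                    span=(a.start, b.end),
                    pattern_class=PatternClass.RANGE,
                    expanded=tuple(expanded),
                    id_kind=Kind.SEQUENCE,
                )
            )
            consumed[i] = consumed[i + 1] = True
            i += 2
            continue
        i += 1

    # pass 2: chains of remaining same-kind candidates joined by enumeration
    # separators become one enumeration mention; everything else is a single
    remaining = [k for k in range(n) if not consumed[k]]
    j = 0
    while j < len(remaining):
        chain = [remaining[j]]
        if not forced_single[remaining[j]]:
            while j + len(chain) < len(remaining):
                prev, nxt = chain[-1], remaining[j + len(chain)]
                if forced_single[nxt] or nxt != prev + 1:
                    break
                if cands[nxt].shape.kind is not cands[prev].shape.kind:
                    break
                gap = text[cands[prev].end : cands[nxt].start]
                if not _ENUM_GAP_RE.fullmatch(gap):
                    break
                chain.append(nxt)
        if len(chain) >= 2:
            first, last = cands[chain[0]], cands[chain[-1]]
            mentions.append(
                AccessionMention(
                    matched_text=text[first.start : last.end],
                    span=(first.start, last.end),
                    pattern_class=PatternClass.ENUMERATION,
                    expanded=tuple(cands[k].shape.canonical for k in chain),
                    id_kind=first.shape.kind,
                )
            )
        else:
            mentions.append(_single(cands[chain[0]]))
        j += len(chain)

    mentions.sort(key=lambda m: m.span)
    return mentions


@dataclass
class LinkResult:
    """Deduplicated accession links of one article, with provenance."""

    article_id: str
    links: set[tuple[Kind, str]]
    mentions: list[AccessionMention]
    counts_by_class: dict[PatternClass, int]


def link_article(
    doc: ArticleDoc,
    mode: Mode | str = Mode.RANGE_AWARE,
    grammar: Grammar | None = None,
    **kwargs,
) -> LinkResult:
    """Union of mentions over body and supplementary texts, deduplicated.

    Mentions found in supplementary texts are reclassified as
    ``supplementary_list`` regardless of their local shape.  An accession
    cited five times still yields one (kind, accession) link.
    """
    mentions: list[AccessionMention] = list(
        extract_mentions(doc.body_text, mode, grammar, **kwargs)
    )
    for k, supp in enumerate(doc.supplementary_texts):
        for m in extract_mentions(supp, mode, grammar, **kwargs):
            mentions.append(
                AccessionMention(
                    matched_text=m.matched_text,
                    span=m.span,
                    pattern_class=PatternClass.SUPPLEMENTARY_LIST,
                    expanded=m.expanded,
                    id_kind=m.id_kind,
                    source=f"supplementary[{k}]",
                )
            )
    links = {(m.id_kind, acc) for m in mentions for acc in m.expanded}
    counts: dict[PatternClass, int] = {c: 0 for c in PatternClass}
    for m in mentions:
        counts[m.pattern_class] += 1
    return LinkResult(doc.article_id, links, mentions, counts)


# ---------------------------------------------------------------------------
# article readers


def load_article_jats(path: str | Path) -> ArticleDoc:
    """Read a (minimal) JATS XML article.

    Body paragraphs are flattened to plain text; table rows are joined with
    tab separators; ``<sec sec-type="supplementary-material">`` sections and
    ``<supplementary-material>`` elements become supplementary texts.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()

    def first(xp: str) -> str:
        nodes = root.xpath(xp)
        return nodes[0].strip() if nodes else ""

    pmcid = first('.//article-id[@pub-id-type="pmcid"]/text()')
    if pmcid and not pmcid.startswith("PMC"):
        pmcid = "PMC" + pmcid
    doc = ArticleDoc(
        pmcid=pmcid,
        pmid=first('.//article-id[@pub-id-type="pmid"]/text()'),
        doi=first('.//article-id[@pub-id-type="doi"]/text()'),
        year=int(first(".//pub-date/year/text()") or 0),
        affiliation_strings=[
            _flatten(aff) for aff in root.xpath(".//aff")
        ],
    )
    supp_nodes = root.xpath(
        './/sec[@sec-type="supplementary-material"] | .//supplementary-material'
    )
    for node in supp_nodes:
        doc.supplementary_texts.append(_flatten(node))
    body = root.find("body")
    if body is not None:
        parts = []
        for p in body.iter():
            if p.tag in ("p", "title") and not _inside_supp(p):
                parts.append(_flatten(p))
            elif p.tag == "tr":
                cells = [_flatten(td) for td in p.iter() if td.tag in ("td", "th")]
                parts.append("\t".join(cells))
        doc.body_text = "\n".join(t for t in parts if t)
    return doc


def _inside_supp(node) -> bool:
    parent = node.getparent()
    while parent is not None:
        if parent.tag == "supplementary-material" or (
            parent.tag == "sec" and parent.get("sec-type") == "supplementary-material"
        ):
            return True
        parent = parent.getparent()
    return False


def _flatten(node) -> str:
    return " ".join("".join(node.itertext()).split())


def load_article_text(path: str | Path) -> ArticleDoc:
    """Read a plain-text article: ``X.txt`` body, optional ``X.supp.txt``
    supplementary block and ``X.meta.json`` identifier/affiliation sidecar."""
    import json

    path = Path(path)
    stem = path.with_suffix("")
    meta = {}
    meta_path = Path(str(stem) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    doc = ArticleDoc(
        pmcid=meta.get("pmcid", ""),
        pmid=meta.get("pmid", ""),
        doi=meta.get("doi", "") or (path.stem if not meta else ""),
        body_text=path.read_text(),
        affiliation_strings=list(meta.get("affiliations", [])),
        year=int(meta.get("year", 0)),
    )
    supp_path = Path(str(stem) + ".supp.txt")
    if supp_path.exists():
        doc.supplementary_texts.append(supp_path.read_text())
    return doc


def load_articles(directory: str | Path) -> list[ArticleDoc]:
    """Load every ``.xml`` (JATS) and ``.txt`` article in a directory."""
    directory = Path(directory)
    docs = [load_article_jats(p) for p in sorted(directory.glob("*.xml"))]
    docs += [
        load_article_text(p)
        for p in sorted(directory.glob("*.txt"))
        if not p.name.endswith(".supp.txt")
    ]
    return docs
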