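"""End-to-end orchestration: records + articles -> warehouse + QC report.

This is the extract-load-transform path in one call: extract accession
mentions from every article under the chosen mode, intersect them with the
parsed sequence records, normalise countries, and load the linked tables.
"""

from __future__ import annotations

from typing import Iterable

from .accession_grammar import Grammar
from .citation_extract import ArticleDoc, Mode, link_article
from .embl_io import EnaRecord
from .warehouse import BuildConfig, QcReport, Warehouse, build_warehouse

__all__ = ["run_pipeline", "extract_all"]


def extract_all(
    articles: Iterable[ArticleDoc],
    mode: Mode | str = Mode.RANGE_AWARE,
    grammar: Grammar | None = None,
):
    """Per-article link extraction; returns ``{article_id: LinkResult}``."""
    return {doc.article_id: link_article(doc, mode, grammar) for doc in articles}


def run_pipeline(
    records: Iterable[EnaRecord],
    articles: Iterable[ArticleDoc],
    mode: Mode | str = Mode.RANGE_AWARE,
    grammar: Grammar | None = None,
    config: BuildConfig | None = None,
) -> tuple[Warehouse, QcReport]:
    """Run extraction and warehouse construction in one pass."""
    articles = list(articles)
    results = extract_all(articles, mode, grammar)
    mentions = {aid: res.mentions for aid, res in results.items()}
    return build_warehouse(records, articles, mentions, config)
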