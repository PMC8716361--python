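import pytest

from dsilink.accession_grammar import Kind
from dsilink.citation_extract import (
    ArticleDoc,
    Mode,
    PatternClass,
    extract_mentions,
    link_article,
    load_article_jats,
    load_article_text,
    load_articles,
)
from dsilink.pipeline import extract_all
from dsilink.synth_corpus import make_range_undercount_passage


def _links(mentions):
    return {acc for m in mentions for acc in m.expanded}


def test_standalone_tokens_both_modes():
    text = "Sampling was approved (ENA accession HM034625) and KM654101."
    for mode in Mode:
        mentions = extract_mentions(text, mode)
        assert _links(mentions) == {"HM034625", "KM654101"}
        assert all(m.pattern_class is PatternClass.SINGLE for m in mentions)


def test_range_expansion_vs_endpoints():
    text = "accessions AB000001–AB000035 were deposited"
    aware = extract_mentions(text, Mode.RANGE_AWARE)
    assert len(aware) == 1
    assert aware[0].pattern_class is PatternClass.RANGE
    assert len(aware[0].expanded) == 35
    plain = extract_mentions(text, Mode.SINGLE_TOKEN)
    assert _links(plain) == {"AB000001", "AB000035"}
    assert len(plain) == 2


@pytest.mark.parametrize("connector", ["-", "–", "—", " to ", " through "])
def test_range_connectors(connector):
    text = f"accessions AB000001{connector}AB000004."
    (m,) = extract_mentions(text, Mode.RANGE_AWARE)
    assert m.pattern_class is PatternClass.RANGE
    assert len(m.expanded) == 4


def test_enumeration_groups_exactly_listed():
    text = "AB000001, AB000002 and AB000004 were deposited"
    mentions = extract_mentions(text, Mode.RANGE_AWARE)
    assert [m.pattern_class for m in mentions] == [PatternClass.ENUMERATION]
    assert mentions[0].expanded == ("AB000001", "AB000002", "AB000004")


def test_project_mention():
    mentions = extract_mentions("data under PRJEB1234 at ENA", Mode.RANGE_AWARE)
    assert len(mentions) == 1 and mentions[0].id_kind is Kind.PROJECT
    assert mentions[0].expanded == ("PRJEB1234",)


def test_span_matches_text_slice_and_sorted():
    text = "see AB000001–AB000003; also KM654101 and PRJEB7 (deposited)."
    for mode in Mode:
        mentions = extract_mentions(text, mode)
        assert all(text[m.span[0] : m.span[1]] == m.matched_text for m in mentions)
        assert [m.span for m in mentions] == sorted(m.span for m in mentions)


def test_tokens_inside_words_rejected():
    # catalogue-number style embeddings must not match
    text = "sample XAB000001, codeAY924392 and AY924392X were excluded"
    assert extract_mentions(text, Mode.SINGLE_TOKEN) == []


def test_version_suffix_stripped_for_linking():
    (m,) = extract_mentions("deposited as AB000001.2 in ENA", Mode.SINGLE_TOKEN)
    assert m.expanded == ("AB000001",)
    assert m.matched_text == "AB000001.2"


def test_invalid_range_degrades_to_singles():
    text = "range AB000001-CD000003 is a typo"
    mentions = extract_mentions(text, Mode.RANGE_AWARE)
    assert _links(mentions) == {"AB000001", "CD000003"}
    assert all(m.pattern_class is PatternClass.SINGLE for m in mentions)


def test_descending_range_degrades_to_singles():
    mentions = extract_mentions("AB000003-AB000001", Mode.RANGE_AWARE)
    assert _links(mentions) == {"AB000001", "AB000003"}


def test_context_cue_filter_optional():
    text = "An identifier AY924392 appears without any cue word nearby."
    assert _links(extract_mentions(text, Mode.SINGLE_TOKEN)) == {"AY924392"}
    filtered = extract_mentions(
        text, Mode.SINGLE_TOKEN, require_context_cue=True, cue_window=10
    )
    assert filtered == []


def test_link_article_deduplicates_and_counts():
    doc = ArticleDoc(
        pmcid="PMC1",
        body_text="AB000001 was used. AB000001 again; plus AB000010-AB000019 and KM654101.",
        supplementary_texts=["Table S1: AB000001, KM654101."],
    )
    aware = link_article(doc, Mode.RANGE_AWARE)
    assert len(aware.links) == 12  # 10-wide range + 2 singles, deduplicated
    plain = link_article(doc, Mode.SINGLE_TOKEN)
    assert len(plain.links) == 4  # endpoints only
    assert aware.counts_by_class[PatternClass.SUPPLEMENTARY_LIST] > 0


def test_mode_dominance_on_corpus(small_corpus):
    """links(single_token) is a subset of links(range_aware) per document."""
    aware = extract_all(small_corpus.articles, Mode.RANGE_AWARE)
    plain = extract_all(small_corpus.articles, Mode.SINGLE_TOKEN)
    for aid in aware:
        assert plain[aid].links <= aware[aid].links


def test_chunking_independence(small_corpus):
    """Splitting text at sentence boundaries does not change the link set."""
    for doc in small_corpus.articles[:20]:
        whole = _links(extract_mentions(doc.body_text, Mode.RANGE_AWARE))
        parts = doc.body_text.split(". ")
        chunked = set()
        for part in parts:
            chunked |= _links(extract_mentions(part, Mode.RANGE_AWARE))
        assert chunked == whole


def test_undercount_worked_example():
    text, accessions = make_range_undercount_passage(total=35, n_ranges=4)
    aware = extract_mentions(text, Mode.RANGE_AWARE)
    assert _links(aware) == set(accessions) and len(accessions) == 35
    plain = extract_mentions(text, Mode.SINGLE_TOKEN)
    assert len(plain) == 8  # only the standalone endpoint tokens


def test_jats_and_text_readers_agree(small_corpus, tmp_path):
    small_corpus.write(tmp_path, jats_fraction=0.5)
    docs = load_articles(tmp_path / "articles")
    assert len(docs) == len(small_corpus.articles)
    by_id = {d.article_id: d for d in small_corpus.articles}
    for doc in docs:
        ref = by_id[doc.article_id]
        assert doc.year == ref.year
        assert doc.affiliation_strings == ref.affiliation_strings
        assert link_article(doc, Mode.RANGE_AWARE).links == link_article(ref, Mode.RANGE_AWARE).links


def test_article_requires_identifier():
    with pytest.raises(ValueError):
        ArticleDoc(body_text="no ids")
    with pytest.raises(ValueError):
        ArticleDoc(pmcid="1234")  # PMCID must carry its prefix
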