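from dsilink.citation_extract import ArticleDoc, Mode
from dsilink.country_norm import OCEAN_ISO2
from dsilink.embl_io import EnaRecord, PubRef
from dsilink.pipeline import run_pipeline
from dsilink.stats import citation_network, group_matrix, headline_counts, per_country_stats
from dsilink.warehouse import build_warehouse

from bruteforce import recount_edges, recount_matrix, recount_per_country


def _article(pmcid, body, affs):
    return ArticleDoc(pmcid=pmcid, body_text=body, affiliation_strings=affs, year=2015)


def _fixture_warehouse():
    records = [
        EnaRecord("AB000001", raw_country="Germany"),
        EnaRecord("AB000002", raw_country="Germany: Jena"),
        EnaRecord("AB000003", raw_country="Soviet Union"),
        EnaRecord("AB000004", raw_country="Brazil"),
        EnaRecord("AB000005", raw_country="Coral Sea"),
    ]
    articles = [
        _article("PMC1", "We used AB000001 and AB000002.", ["Inst, Paris, France"]),
        _article("PMC2", "Based on AB000004 data.", ["Inst, Berlin, Germany"]),
        _article("PMC3", "Reusing AB000003 and AB000005.", ["Inst, Kyoto, Japan"]),
    ]
    return run_pipeline(records, articles, Mode.RANGE_AWARE)


def test_per_country_contribution_and_use():
    w, _ = _fixture_warehouse()
    stats = {s.iso2: s for s in per_country_stats(w)}
    assert stats["DE"].n_contributed_sequences == 2
    assert stats["FR"].n_used_sequences == 2 and stats["FR"].n_publications == 1
    # the obsolete-tag sequence appears in no statistic even though cited
    assert "SU" not in stats
    assert stats["BR"].n_used_sequences == 0 and stats["BR"].n_contributed_sequences == 1
    # ocean-tagged contribution appears under the Ocean label
    assert stats[OCEAN_ISO2].n_contributed_sequences == 1


def test_group_matrix_cells_and_ocean_margin(groups):
    w, _ = _fixture_warehouse()
    gm = group_matrix(w, groups)
    # BR-tagged sequence cited by a DE-affiliated article
    assert gm.matrix.loc["BRICS", "OECD"] == 1
    assert gm.matrix.loc["G77", "OECD"] == 1  # BR is also in G77
    # DE-tagged sequences cited by an FR-affiliated article: 2 pairs
    assert gm.matrix.loc["OECD", "OECD"] == 2
    # the Ocean-tagged cited sequence is excluded from the matrix
    assert gm.ocean_pairs == 1
    assert gm.counting_rule == "per-country"


def test_citation_network_edges():
    w, _ = _fixture_warehouse()
    edges = {(e.provider_iso2, e.user_iso2): e.weight for e in citation_network(w)}
    assert edges[("DE", "FR")] == 2
    assert edges[("BR", "DE")] == 1
    assert all(weight >= 1 for weight in edges.values())


def test_self_loop_for_domestic_use():
    records = [EnaRecord("AB000001", raw_country="Japan")]
    articles = [_article("PMC1", "Using AB000001.", ["Inst, Tokyo, Japan"])]
    w, _ = run_pipeline(records, articles, Mode.RANGE_AWARE)
    (edge,) = citation_network(w)
    assert (edge.provider_iso2, edge.user_iso2, edge.weight) == ("JP", "JP", 1)


def test_headline_counts_fixture():
    records = [
        EnaRecord("AB000001", primary_refs=(PubRef(doi="10.1/x"),)),
        EnaRecord("AB000002"),
        EnaRecord("AB000003"),
    ]
    w, _ = build_warehouse(records, [], {})
    counts = headline_counts(w)
    assert counts["records_without_primary_ref"] == 2
    assert counts["primary_linked_records"] == 0  # no matching article present


def test_empty_warehouse_stats():
    w, _ = build_warehouse([], [], {})
    assert per_country_stats(w) == []
    assert citation_network(w) == []
    gm = group_matrix(w)
    assert int(gm.matrix.to_numpy().sum()) == 0 and gm.ocean_pairs == 0
    assert headline_counts(w) == {
        "primary_linked_records": 0,
        "primary_linked_articles": 0,
        "secondary_linked_records": 0,
        "secondary_linked_articles": 0,
        "records_without_primary_ref": 0,
    }


def test_stats_equal_bruteforce_recount(small_corpus, groups):
    """Every stats output agrees with an independent plain-Python recount."""
    w, _ = run_pipeline(small_corpus.records, small_corpus.articles, Mode.RANGE_AWARE)

    contributed, used, pubs = recount_per_country(w)
    for s in per_country_stats(w):
        assert s.n_contributed_sequences == contributed.get(s.iso2, 0)
        assert s.n_used_sequences == len(used.get(s.iso2, set()))
        assert s.n_publications == len(pubs.get(s.iso2, set()))
    assert set(contributed) | set(used) == {s.iso2 for s in per_country_stats(w)}

    edge_weights = recount_edges(w)
    assert {
        (e.provider_iso2, e.user_iso2): e.weight for e in citation_network(w)
    } == dict(edge_weights)

    cells, ocean_pairs = recount_matrix(w, groups)
    gm = group_matrix(w, groups)
    assert gm.ocean_pairs == ocean_pairs
    for pg in gm.matrix.index:
        for ug in gm.matrix.columns:
            assert gm.matrix.loc[pg, ug] == cells.get((pg, ug), 0)


def test_contribution_conservation(small_corpus):
    """Summed contributions equal the number of stats-eligible sequences."""
    w, qc = run_pipeline(small_corpus.records, small_corpus.articles, Mode.RANGE_AWARE)
    total = sum(s.n_contributed_sequences for s in per_country_stats(w))
    assert total == qc.n_valid_country


def test_no_ineligible_country_in_any_output(small_corpus, groups):
    w, _ = run_pipeline(small_corpus.records, small_corpus.articles, Mode.RANGE_AWARE)
    eligible = set(w.ena_sequences[w.ena_sequences["stats_eligible"]]["country_iso2"])
    bad = {"", "SU", "YU", "CS", "DD", "AN"}
    for s in per_country_stats(w):
        assert s.iso2 not in bad
    for e in citation_network(w):
        assert e.provider_iso2 in eligible and e.provider_iso2 not in bad


def test_year_range_filter(small_corpus):
    w, _ = run_pipeline(small_corpus.records, small_corpus.articles, Mode.RANGE_AWARE)
    all_edges = sum(e.weight for e in citation_network(w))
    early = sum(e.weight for e in citation_network(w, year_range=(2005, 2012)))
    late = sum(e.weight for e in citation_network(w, year_range=(2013, 2021)))
    assert early + late == all_edges
    assert sum(e.weight for e in citation_network(w, year_range=(1990, 1991))) == 0
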