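"""Provider/user summary statistics over the citation warehouse.

The questions behind these queries: which countries contribute sequence
data (via the country qualifier of their deposited records), which
countries use it (via the author affiliations of articles citing those
records), and how use flows between economic groups (OECD / BRICS / G77).

Counting rules
--------------
All use-side statistics are computed over *secondary* links (articles whose
full text cites a sequence).  The atomic unit is the (sequence, article)
pair; an article with affiliations in several countries credits each of its
countries once per pair (the default, declared in output metadata), or
1/k per country under the optional fractional rule.  Sequences whose
country tag is obsolete, unresolved or empty are excluded from every
statistic here, although they remain in the warehouse tables.

Every output is simple enough to be re-derived by a brute-force recount
over the flat link table, which is how the test suite checks this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .country_norm import OCEAN_ISO2, CountryGroup
from .warehouse import Warehouse

__all__ = [
    "CountryStat",
    "GroupMatrix",
    "CitationEdge",
    "per_country_stats",
    "group_matrix",
    "citation_network",
    "headline_counts",
]


@dataclass(frozen=True)
class CountryStat:
    iso2: str
    n_contributed_sequences: int = 0
    n_used_sequences: int = 0
    n_publications: int = 0


@dataclass
class GroupMatrix:
    """Provider-group x user-group counts of (sequence, article) pairs."""

    matrix: pd.DataFrame  # rows: provider groups (+Other); cols: user groups (+Other)
    ocean_pairs: int = 0  # pairs with an Ocean-tagged provider, kept out of the matrix
    counting_rule: str = "per-country"
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CitationEdge:
    provider_iso2: str
    user_iso2: str
    weight: int


def _eligible_pairs(w: Warehouse, year_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Secondary (sequence, article) pairs joined to provider country and
    user (author) countries; only stats-eligible provider countries kept."""
    links = w.seq2pub_links
    links = links[links["direction"] == "secondary"] if len(links) else links
    seq = w.ena_sequences[w.ena_sequences["stats_eligible"].astype(bool)] if len(w.ena_sequences) else w.ena_sequences
    merged = links.merge(
        seq[["accession", "country_iso2"]], on="accession", how="inner"
    ).merge(
        w.pmc_references[["article_id", "author_countries", "year"]],
        on="article_id",
        how="inner",
    )
    if year_range is not None and len(merged):
        lo, hi = year_range
        merged = merged[(merged["year"] >= lo) & (merged["year"] <= hi)]
    return merged


def _explode_users(pairs: pd.DataFrame) -> pd.DataFrame:
    """One row per (sequence, article, user-country); articles without any
    resolved author country drop out (no valid user information)."""
    if not len(pairs):
        return pairs.assign(user_iso2=pd.Series(dtype=str))
    out = pairs.copy()
    out["user_iso2"] = out["author_countries"].str.split(";")
    out = out.explode("user_iso2")
    out = out[out["user_iso2"].astype(str) != ""]
    return out.drop_duplicates(["accession", "article_id", "user_iso2"])


def per_country_stats(
    w: Warehouse, year_range: tuple[int, int] | None = None
) -> list[CountryStat]:
    """Contribution and use counters per country (incl. the Ocean label).

    Contribution counts every stats-eligible country-tagged sequence;
    use counts distinct sequences cited by articles affiliated with the
    country; publications counts the distinct citing articles.
    """
    seq = w.ena_sequences
    contributed: dict[str, int] = {}
    if len(seq):
        eligible = seq[seq["stats_eligible"].astype(bool)]
        contributed = eligible.groupby("country_iso2")["accession"].nunique().to_dict()

    users = _explode_users(_eligible_pairs(w, year_range))
    used: dict[str, int] = {}
    pubs: dict[str, int] = {}
    if len(users):
        used = users.groupby("user_iso2")["accession"].nunique().to_dict()
        pubs = users.groupby("user_iso2")["article_id"].nunique().to_dict()

    out = [
        CountryStat(
            iso2=c,
            n_contributed_sequences=int(contributed.get(c, 0)),
            n_used_sequences=int(used.get(c, 0)),
            n_publications=int(pubs.get(c, 0)),
        )
        for c in sorted(set(contributed) | set(used))
    ]
    return out


def _group_of(iso2: str, groups: Sequence[CountryGroup]) -> list[str]:
    codes = [g.group_code for g in groups if iso2 in g.members]
    return codes or ["Other"]


def group_matrix(
    w: Warehouse,
    groups: Sequence[CountryGroup] | None = None,
    fractional: bool = False,
    year_range: tuple[int, int] | None = None,
) -> GroupMatrix:
    """Cross-tabulate (sequence, article) pairs by provider and user group.

    A country in several groups is counted once per group; countries in no
    group fall into "Other".  Ocean-tagged providers are excluded from the
    matrix and reported in ``ocean_pairs``.
    """
    if groups is None:
        from .country_norm import default_groups

        groups = default_groups()
    codes = sorted({g.group_code for g in groups}) + ["Other"]
    mat = pd.DataFrame(0.0, index=codes, columns=codes)
    users = _explode_users(_eligible_pairs(w, year_range))
    ocean_pairs = 0
    if len(users):
        ocean_mask = users["country_iso2"] == OCEAN_ISO2
        ocean_pairs = int(users[ocean_mask].drop_duplicates(["accession", "article_id"]).shape[0])
        users = users[~ocean_mask]
    for row in users.itertuples(index=False):
        provider_groups = _group_of(row.country_iso2, groups)
        user_groups = _group_of(row.user_iso2, groups)
        weight = 1.0
        if fractional:
            k = len(str(row.author_countries).split(";"))
            weight = 1.0 / k if k else 1.0
        for pg in provider_groups:
            for ug in user_groups:
                mat.loc[pg, ug] += weight
    if not fractional:
        mat = mat.astype(int)
    return GroupMatrix(
        matrix=mat,
        ocean_pairs=ocean_pairs,
        counting_rule="fractional" if fractional else "per-country",
        meta={"groups": codes[:-1]},
    )


def citation_network(
    w: Warehouse, year_range: tuple[int, int] | None = None
) -> list[CitationEdge]:
    """Provider-country -> user-country edges weighted by (sequence, article)
    pairs; self-loops represent domestic use."""
    users = _explode_users(_eligible_pairs(w, year_range))
    if not len(users):
        return []
    counts = (
        users.groupby(["country_iso2", "user_iso2"])
        .size()
        .reset_index(name="weight")
        .sort_values(["country_iso2", "user_iso2"], kind="mergesort")
    )
    return [
        CitationEdge(r.country_iso2, r.user_iso2, int(r.weight))
        for r in counts.itertuples(index=False)
    ]


def headline_counts(w: Warehouse) -> dict[str, int]:
    """Distinct linked sequences and articles per direction, plus the number
    of records lacking any primary literature reference."""
    links = w.seq2pub_links
    seq = w.ena_sequences
    out = {}
    for direction in ("primary", "secondary"):
        sub = links[links["direction"] == direction] if len(links) else links
        out[f"{direction}_linked_records"] = int(sub["accession"].nunique()) if len(sub) else 0
        out[f"{direction}_linked_articles"] = int(sub["article_id"].nunique()) if len(sub) else 0
    if len(seq):
        out["records_without_primary_ref"] = int(
            ((seq["doi"] == "") & (seq["pmid"] == "") & (seq["pmcid"] == "")).sum()
        )
    else:
        out["records_without_primary_ref"] = 0
    return out
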