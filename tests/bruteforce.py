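"""Independent brute-force recounts used as oracles for the stats module.

These deliberately use plain Python dict/set loops over the flat tables —
no pandas groupbys, no shared code with dsilink.stats — so that agreement
between the two routes is meaningful.
"""

from collections import Counter, defaultdict


def _rows(df):
    return df.to_dict("records")


def recount_per_country(w):
    seq = {r["accession"]: r for r in _rows(w.ena_sequences)}
    arts = {r["article_id"]: r for r in _rows(w.pmc_references)}
    contributed = Counter()
    for r in seq.values():
        if r["stats_eligible"]:
            contributed[r["country_iso2"]] += 1
    used = defaultdict(set)
    pubs = defaultdict(set)
    for l in _rows(w.seq2pub_links):
        if l["direction"] != "secondary":
            continue
        s = seq.get(l["accession"])
        a = arts.get(l["article_id"])
        if s is None or a is None or not s["stats_eligible"]:
            continue
        for c in str(a["author_countries"]).split(";"):
            if c:
                used[c].add(l["accession"])
                pubs[c].add(l["article_id"])
    return contributed, used, pubs


def recount_edges(w):
    seq = {r["accession"]: r for r in _rows(w.ena_sequences)}
    arts = {r["article_id"]: r for r in _rows(w.pmc_references)}
    weights = Counter()
    for l in _rows(w.seq2pub_links):
        if l["direction"] != "secondary":
            continue
        s = seq.get(l["accession"])
        a = arts.get(l["article_id"])
        if s is None or a is None or not s["stats_eligible"]:
            continue
        for c in set(str(a["author_countries"]).split(";")):
            if c:
                weights[(s["country_iso2"], c)] += 1
    return weights


def recount_matrix(w, groups, ocean_iso2="ZZ"):
    code_of = {}
    for g in groups:
        for m in g.members:
            code_of.setdefault(m, []).append(g.group_code)
    seq = {r["accession"]: r for r in _rows(w.ena_sequences)}
    arts = {r["article_id"]: r for r in _rows(w.pmc_references)}
    cells = Counter()
    ocean_pairs = set()
    for l in _rows(w.seq2pub_links):
        if l["direction"] != "secondary":
            continue
        s = seq.get(l["accession"])
        a = arts.get(l["article_id"])
        if s is None or a is None or not s["stats_eligible"]:
            continue
        provider = s["country_iso2"]
        user_countries = [c for c in set(str(a["author_countries"]).split(";")) if c]
        if not user_countries:
            continue
        if provider == ocean_iso2:
            ocean_pairs.add((l["accession"], l["article_id"]))
            continue
        for uc in user_countries:
            for pg in sorted(code_of.get(provider, ["Other"])) or ["Other"]:
                for ug in sorted(code_of.get(uc, ["Other"])) or ["Other"]:
                    cells[(pg, ug)] += 1
    return cells, len(ocean_pairs)


def recount_headline(w):
    out = {}
    for direction in ("primary", "secondary"):
        accs, arts = set(), set()
        for l in _rows(w.seq2pub_links):
            if l["direction"] == direction:
                accs.add(l["accession"])
                arts.add(l["article_id"])
        out[f"{direction}_linked_records"] = len(accs)
        out[f"{direction}_linked_articles"] = len(arts)
    out["records_without_primary_ref"] = sum(
        1
        for r in _rows(w.ena_sequences)
        if not (r["doi"] or r["pmid"] or r["pmcid"])
    )
    return out
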