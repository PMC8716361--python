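# Methods

## The linkage model

The pipeline connects a sequence archive and a literature corpus in two
directions. A *primary* link is declared inside the archive: a sequence
record carries literature cross-references (DOI, PubMed ID, PMC ID)
naming the paper that described the deposition. A *secondary* link is
declared inside the literature: an article's full text cites a sequence
accession or a BioProject accession. The two directions are independent
and a (sequence, article) pair may carry both; all counters report them
separately.

Provenance enters twice. On the provider side, the source feature of a
sequence record may carry a `/country` qualifier, conventionally
`"Country: region"`. On the user side, author affiliation strings end,
by convention, with a country name. Both are normalised against the same
curated country table, and all provider/user statistics are computed at
the (sequence, article) pair level over secondary links.

## Identifier grammar and range semantics

Sequence accessions follow the classic INSDC shapes (1 letter + 5 digits
or 2 letters + 6 digits); BioProject accessions are `PRJ{E,D,N}` + letter
+ digits; WGS accessions (4–6 letters + 8–9 digits) are recognised only
to be excluded, mirroring the archive-parsing scope. Study identifiers
(ERP/SRP), BioSample IDs and RefSeq underscore forms deliberately
classify as invalid: linking is on sequence and project accessions only.
Newer 8-digit sequence shapes are off by default but can be enabled via
`Grammar(extra_sequence_patterns=...)`.

Range expansion (`AB000001–AB000035`) requires identical prefix and digit
width and ordered endpoints, and is capped (default 1,000, configurable):
an uncapped expansion of a typo'd range such as `AB1–ZZ9` would flood the
link table. Failed expansions degrade to the two endpoint mentions with a
warning — author notation must never hard-fail extraction.

## Extraction modes and the undercount law

A candidate token is a maximal run of ASCII letters/digits; any other
character is a word separator. This is what makes `single_token` mode an
emulation of a plain token matcher: in `AB000001–AB000035` the dash
terminates both tokens, so only the endpoints match. The exact tokenizer
of the service being emulated is not published, so this mode is a
documented approximation of the mechanism, not a bit-reproduction of any
particular service.

`range_aware` mode additionally joins adjacent sequence-accession tokens
whose gap is a hyphen/en-dash/em-dash or the words "to"/"through"
(ranges), and chains tokens separated by comma/semicolon/"and"
(enumerations). Overlaps resolve longest-match-first; spans are 0-based
half-open. Mentions found in supplementary texts are reclassified as
`supplementary_list`. Version suffixes (`.2`) are displayed in the match
but stripped for linking.

On a corpus whose planted citations are known, single-token recall has a
closed form: each range of size *s* contributes *s* true links but only
min(2, *s*) recovered links, while singles, enumerations and
supplementary lists are fully recovered. The test suite asserts the
empirical recall equals this expectation to 1e-12, and that single-token
links are a per-article subset of range-aware links. Citations embedded
in figure bitmaps (a fifth pattern observed in real articles) would need
OCR; the extractor has zero coverage for them and this is a stated
limitation, as is PDF-only content.

An optional context-cue filter (require a word like "accession" or "ENA"
within a window) exists but is off by default, since the emulated matcher
used none.

## Country normalisation

Matching is exact after normalisation — NFKD-fold diacritics, casefold,
collapse punctuation — with no edit-distance guessing, so every
resolution is auditable to a table row. A `"Country: region"` string is
split at the first colon and the region preserved untouched; the raw
qualifier itself is never rewritten (parsing stores it byte-for-byte).

The shipped COUNTRY table is a curation snapshot (dated 2021-06-30 in the
build metadata): 193 UN member states with ISO-3166-1 alpha-2/alpha-3/
numeric codes, official and short names, and common synonyms; one "Ocean"
pseudo-entry aggregating marine sampling areas (a sampling-environment
label, explicitly not a legal high-seas category) whose pseudo-code `ZZ`
is user-assignable in ISO terms; territory rows (Taiwan, Hong Kong,
Greenland, Puerto Rico, …) carrying an explicit `maps_to` target state;
and obsolete historic entries (Soviet Union, Yugoslavia, Czechoslovakia,
East Germany, Netherlands Antilles) that resolve but are flagged
ineligible for statistics. "Western Sahara" is intentionally absent and
resolves as `unresolved`; users who want it mapped add a synonym row —
curation stays data, not code. Entities whose state assignment is itself
contested (e.g. Palestine, Kosovo) are likewise left to the unresolved
report rather than adjudicated in the default snapshot. Group membership
(OECD 38, BRICS 5, G77 133 — the snapshot lists G77 proper, without
China, whose BRICS membership covers it) and approximate country
centroids are separate CSV snapshots. Numeric codes and centroids are
curated by hand and validated for internal consistency (uniqueness,
coordinate bounds), not against a live registry.

Affiliation strings are scanned from the last comma-segment backwards,
longest word-suffix first, returning the last resolvable country name —
matching the convention that affiliations end with the country. Articles
with no resolvable affiliation country simply contribute no use-side
statistics.

## Warehouse and integrity

Records with obsolete/unresolved/empty country tags are kept in
ENA_SEQUENCES with `stats_eligible=False` and a status column rather than
dropped or nulled, which makes the "kept in the dataset but ignored for
summary statistics" rule directly queryable. Article records deduplicate
on a stable key with PMCID preferred over PMID over DOI; DOIs match
case-insensitively. Mentions of valid-shaped accessions that are not in
the sequence table are counted (`n_unlinked_mentions`), never linked.
`integrity_check` recomputes every counter from the tables alone and must
agree with the build-time report; a successful build has zero dangling
keys. CSV exports are sorted and therefore byte-deterministic for
identical inputs.

The QC report exposes the valid-country count against both denominators
(all physical entries including WGS-excluded ones, and parsed non-WGS
records), since "share of records with a valid country tag" is ambiguous
between the two in practice.

## Counting rules in statistics

The atomic unit is the (sequence, article) pair over secondary links.
An article affiliated with several countries credits each country once
per pair (default, declared in output metadata as `per-country`); a
fractional rule (1/k per country) is available behind a flag. Countries
in several economic groups count once per group; countries in none fall
into "Other". Ocean-tagged providers appear in per-country contribution
statistics under the Ocean label but are excluded from the group matrix
and reported as a margin count, since the pseudo-entry has no economy.
Year filtering is a query parameter on every statistic, not a separate
code path.

## Synthetic corpus

The generator emulates the statistical structure of the real inputs, not
their content. Defaults (chosen once as the study conditions):

| parameter | default | rationale |
|---|---|---|
| `n_records` / `n_articles` | 1000 / 200 | desk-scale corpus; every acceptance check runs in seconds |
| `wgs_fraction` | 0.05 | exercises the WGS-exclusion path without dominating |
| `frac_valid_country` | 0.15 | the share of country-tagged records in a real archive dump |
| `frac_obsolete_country` | 0.01 | obsolete tags are rare but must be exercised |
| `frac_empty_country` | 0.83 | most archive records carry no country qualifier |
| `frac_with_primary_ref` | 0.40 | roughly the archive-wide share of records with literature cross-references |
| `pattern_mix` | 0.5/0.2/0.2/0.1 | singles dominate real citation practice; ranges and enumerations are common; supplementary lists rarer |
| range / enum / supplement sizes | 3–10 / 2–4 / 5–10 | small blocks typical of deposition batches |

Fractions are read against the total record count with a deterministic
largest-remainder rounding, so `frac_valid_country=0.15` at 100 records
gives exactly 15 valid-country records. Ranges are planted as blocks of
consecutive accessions that genuinely exist in the flat file; all planted
accessions are globally unique, which makes per-article deduplication a
no-op and the ground-truth link set exact. One `random.Random(seed)`
threads through generation; equal seeds give byte-identical output trees.

What passing tests on this corpus show: the mechanics of parsing,
grammar, extraction, linking, normalisation and counting are correct and
self-consistent. What they do not show: robustness to real prose (typos,
unusual notations, figure-embedded citations), real affiliation noise, or
the exact recall of any particular production text-mining service.

## Numerical and design choices

- Range cap 1,000; versions stripped for linking, kept for provenance.
- Country matching has no fuzzy fallback by design (auditability).
- Empty inputs are total-function cases everywhere: empty corpus → empty
  warehouse → all-zero report and header-only CSV exports.
- The flat-file writer emits the same dialect subset the parser reads;
  unknown line codes on input are ignored for forward compatibility, and
  an independent EMBL parser (Biopython) is used in the test suite as a
  cross-check on a realistic entry.
- Full-archive validation (parsing an actual multi-hundred-GB release
  dump against its published corpus counts) requires the archive dump and
  the original curated country table and is outside the desk-scale scope
  of this package's checks.
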