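import io

import pytest

from dsilink.embl_io import (
    EnaRecord,
    ParseOptions,
    ParseReport,
    PubRef,
    parse_embl_flatfile,
    write_embl_flatfile,
)

# a realistic entry including the line codes the parser ignores (DT/DE/KW/
# RA/RT/RL/FH/SQ and the sequence block itself)
REALISTIC_ENTRY = """ID   HM034625; SV 1; linear; DNA; STD; PLN; 18 BP.
XX
AC   HM034625;
XX
PR   Project:PRJEB40001;
XX
DT   01-JAN-2011 (Rel. 107, Created)
DE   Example plant partial sequence.
KW   .
OS   Hordeum vulgare
OC   Eukaryota; Viridiplantae.
XX
RN   [1]
RP   1-18
RX   DOI; 10.1000/example.1.
RX   PUBMED; 21111111.
RA   Doe J.;
RT   "A deposited sequence";
RL   Submitted (01-JAN-2011) to the INSDC.
XX
FH   Key             Location/Qualifiers
FH
FT   source          1..18
FT                   /organism="Hordeum vulgare"
FT                   /country="Western Sahara"
FT                   /mol_type="genomic DNA"
XX
SQ   Sequence 18 BP; 5 A; 4 C; 4 G; 5 T; 0 other;
     acgtacgtac gtacgtac                                                     18
//
"""


def _records(corpus):
    return [r for r in corpus.records]


def test_realistic_entry_attributes():
    rec = next(parse_embl_flatfile(io.StringIO(REALISTIC_ENTRY)))
    assert rec.accession == "HM034625"
    assert rec.version == 1
    assert rec.raw_country == "Western Sahara"
    assert rec.taxon_name == "Hordeum vulgare"
    assert rec.project_accessions == {"PRJEB40001"}
    assert rec.primary_refs == (PubRef(doi="10.1000/example.1", pmid="21111111"),)
    assert rec.record_length == 18
    assert not rec.is_wgs


def test_agrees_with_biopython_oracle(tmp_path):
    """An independent EMBL parser extracts the same accession, country and
    organism from the same realistic entry."""
    pytest.importorskip("Bio")
    from Bio import SeqIO

    path = tmp_path / "entry.dat"
    path.write_text(REALISTIC_ENTRY)
    (bio_rec,) = SeqIO.parse(str(path), "embl")
    src = next(f for f in bio_rec.features if f.type == "source")
    (ours,) = parse_embl_flatfile(REALISTIC_ENTRY.splitlines(keepends=True))
    assert bio_rec.id.split(".")[0] == ours.accession
    assert src.qualifiers["country"] == [ours.raw_country]
    assert bio_rec.annotations["organism"] == ours.taxon_name


def test_country_qualifier_verbatim():
    entry = REALISTIC_ENTRY.replace("Western Sahara", "Germany: Gatersleben")
    rec = next(parse_embl_flatfile(io.StringIO(entry)))
    assert rec.raw_country == "Germany: Gatersleben"  # unsplit, byte-for-byte


def test_multiline_country_qualifier():
    entry = REALISTIC_ENTRY.replace(
        '/country="Western Sahara"',
        '/country="Germany: a very long\nFT                   collection locality"',
    )
    rec = next(parse_embl_flatfile(io.StringIO(entry)))
    assert rec.raw_country == "Germany: a very long collection locality"


def test_round_trip_identity(small_corpus):
    """parse(write(R)) == R field-by-field over generated records."""
    records = _records(small_corpus)
    buf = io.StringIO()
    assert write_embl_flatfile(records, buf) == len(records)
    buf.seek(0)
    parsed = list(parse_embl_flatfile(buf))
    assert len(parsed) == len(records)
    for orig, back in zip(records, parsed):
        assert orig == back


def test_wgs_exclusion_counts():
    wgs = EnaRecord("CAAB01000001")
    plain = [EnaRecord(f"AB00000{i}") for i in range(1, 4)]
    buf = io.StringIO()
    write_embl_flatfile([plain[0], wgs, plain[1], EnaRecord("CABD02000007"), plain[2]], buf)
    buf.seek(0)
    report = ParseReport()
    out = list(parse_embl_flatfile(buf, ParseOptions(exclude_wgs=True), report))
    assert [r.accession for r in out] == ["AB000001", "AB000002", "AB000003"]
    assert report.n_wgs_skipped == 2
    assert report.n_entries == report.n_yielded + report.n_wgs_skipped + len(report.malformed)


def test_malformed_id_reported_not_dropped_silently():
    bad = "ID   ???\nAC   AB000001;\n//\n" + REALISTIC_ENTRY
    report = ParseReport()
    out = list(parse_embl_flatfile(io.StringIO(bad), report=report))
    assert len(out) == 1 and out[0].accession == "HM034625"
    assert len(report.malformed) == 1
    assert report.n_entries == 2


def test_truncated_final_entry_discarded_with_warning():
    truncated = REALISTIC_ENTRY + "ID   AB000001; SV 1; linear; DNA; STD; PLN; 10 BP.\nAC   AB000001;\n"
    report = ParseReport()
    out = list(parse_embl_flatfile(io.StringIO(truncated), report=report))
    assert [r.accession for r in out] == ["HM034625"]
    assert report.truncated and report.warnings


def test_parser_is_lazy():
    """The parser yields entries before consuming the whole stream."""
    consumed = 0

    def counting_lines():
        nonlocal consumed
        for _ in range(50):
            for line in io.StringIO(REALISTIC_ENTRY):
                consumed += 1
                yield line

    gen = parse_embl_flatfile(counting_lines())
    next(gen)
    total = REALISTIC_ENTRY.count("\n") * 50
    assert consumed < total / 2


def test_writer_empty_and_invalid():
    buf = io.StringIO()
    assert write_embl_flatfile([], buf) == 0
    assert buf.getvalue() == ""
    rec = EnaRecord("AB000001")
    rec.accession = "ab000001"  # break the invariant after construction
    with pytest.raises(ValueError, match="record 1"):
        write_embl_flatfile([EnaRecord("AB000002"), rec], io.StringIO())


def test_record_without_country_writes_no_qualifier():
    buf = io.StringIO()
    write_embl_flatfile([EnaRecord("AB000001", raw_country="")], buf)
    assert "/country" not in buf.getvalue()
    buf.seek(0)
    assert next(parse_embl_flatfile(buf)).raw_country == ""


def test_pubref_invariants():
    with pytest.raises(ValueError):
        PubRef()
    with pytest.raises(ValueError):
        PubRef(pmcid="12345")
    assert PubRef(pmcid="PMC12345").pmcid == "PMC12345"
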