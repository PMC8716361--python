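"""Streaming reader/writer for the EMBL/ENA flat-file dialect subset.

The citation warehouse needs only a handful of attributes from each ENA
entry: the primary accession and version, BioProject cross-references, the
``/country`` qualifier of the feature-table source feature, literature
cross-references (DOI / PubMed / PMC) from the reference blocks, the
organism name and the record length.  This module parses exactly that
subset — line codes ``ID``, ``AC``, ``PR``, ``RN``/``RX``, ``OS``, ``FT``
and the ``//`` entry terminator — and ignores every other line code, so
files from a real ENA dump stream through unharmed.

The reader is single-pass and lazy: one :class:`EnaRecord` is materialised
at a time, which is what makes parsing a multi-hundred-GB release dump
feasible in bounded memory.  The writer emits the same dialect so that
synthetic corpora and round-trip tests use one format.

The raw country qualifier is stored byte-for-byte (only the qualifier's
surrounding quotes are removed); splitting the ENA ``"Country: region"``
convention is deliberately left to country normalization so that primary
data is never silently rewritten.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .accession_grammar import Kind, classify

__all__ = [
    "PubRef",
    "EnaRecord",
    "ParseOptions",
    "ParseReport",
    "parse_embl_flatfile",
    "write_embl_flatfile",
    "read_embl",
]


@dataclass(frozen=True)
class PubRef:
    """Identifiers of one literature cross-reference in an ENA entry."""

    doi: str = ""
    pmid: str = ""
    pmcid: str = ""

    def __post_init__(self) -> None:
        if not (self.doi or self.pmid or self.pmcid):
            raise ValueError("PubRef needs at least one of doi/pmid/pmcid")
        if self.pmcid and not self.pmcid.startswith("PMC"):
            raise ValueError(f"pmcid must start with 'PMC': {self.pmcid!r}")


@dataclass
class EnaRecord:
    """The warehouse-relevant attributes of one ENA sequence entry."""

    accession: str
    version: int = 0
    project_accessions: frozenset[str] = frozenset()
    raw_country: str = ""
    primary_refs: tuple[PubRef, ...] = ()
    taxon_name: str = ""
    record_length: int = 0
    secondary_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession or self.accession != self.accession.upper():
            raise ValueError(f"accession must be non-empty upper-case: {self.accession!r}")
        if self.version < 0 or self.record_length < 0:
            raise ValueError("version and record_length must be >= 0")
        self.project_accessions = frozenset(self.project_accessions)
        self.primary_refs = tuple(self.primary_refs)
        self.secondary_accessions = tuple(self.secondary_accessions)

    @property
    def is_wgs(self) -> bool:
        return classify(self.accession).kind is Kind.WGS


@dataclass
class ParseOptions:
    exclude_wgs: bool = False


@dataclass
class ParseReport:
    """Accounting of one parse pass.

    ``n_entries == n_yielded + n_wgs_skipped + len(malformed)`` always holds
    (plus one discarded partial record when ``truncated`` is set).
    """

    n_entries: int = 0
    n_yielded: int = 0
    n_wgs_skipped: int = 0
    malformed: list[str] = field(default_factory=list)
    truncated: bool = False
    warnings: list[str] = field(default_factory=list)


_ID_RE = re.compile(r"^([A-Z0-9]+)(?:\.(\d+))?;")
_ID_SV_RE = re.compile(r"SV\s+(\d+)")
_ID_BP_RE = re.compile(r"(\d+)\s+BP\.")
_QUAL_RE = re.compile(r'^/(\w+)(?:=(.*))?$')


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def parse_embl_flatfile(
    stream: IO[str] | Iterable[str],
    options: ParseOptions | None = None,
    report: ParseReport | None = None,
) -> Iterator[EnaRecord]:
    """Lazily parse EMBL-dialect entries from ``stream``.

    Yields one :class:`EnaRecord` per well-formed entry.  Entries with a
    malformed ``ID`` line are recorded in ``report.malformed`` and skipped;
    a final entry missing its ``//`` terminator is discarded with
    ``report.truncated`` set.  With ``options.exclude_wgs`` records whose
    accession has the WGS shape are counted but not yielded.
    """
    options = options or ParseOptions()
    report = report if report is not None else ParseReport()

    state = _EntryState()
    saw_lines = False
    for raw_line in stream:
        saw_lines = True
        line = raw_line.rstrip("\n")
        if line.startswith("//"):
            report.n_entries += 1
            rec, err = state.finish()
            state = _EntryState()
            if err is not None:
                report.malformed.append(err)
                continue
            assert rec is not None
            if options.exclude_wgs and rec.is_wgs:
                report.n_wgs_skipped += 1
                continue
            report.n_yielded += 1
            yield rec
            continue
        state.feed(line)
    if saw_lines and not state.empty:
        report.truncated = True
        report.warnings.append("truncated final entry discarded (missing '//' terminator)")


class _EntryState:
    """Mutable accumulator for the entry currently being parsed."""

    def __init__(self) -> None:
        self.empty = True
        self.id_acc: str | None = None
        self.id_error: str | None = None
        self.version = 0
        self.length = 0
        self.accessions: list[str] = []
        self.projects: list[str] = []
        self.taxon = ""
        self.country = ""
        self.refs: list[dict[str, str]] = []
        self._in_source = False
        self._pending_qualifier: list[str] | None = None
        self._lineno = 0

    def feed(self, line: str) -> None:
        self.empty = False
        self._lineno += 1
        code, _, rest = line[:2], line[2:5], line[5:]
        if code == "ID":
            m = _ID_RE.match(rest.strip())
            if not m:
                self.id_error = f"malformed ID line: {line!r}"
                return
            self.id_acc = m.group(1)
            sv = _ID_SV_RE.search(rest)
            if sv:
                self.version = int(sv.group(1))
            elif m.group(2):
                self.version = int(m.group(2))
            bp = _ID_BP_RE.search(rest)
            if bp:
                self.length = int(bp.group(1))
        elif code == "AC":
            for tok in rest.strip().split(";"):
                tok = tok.strip()
                if tok:
                    self.accessions.append(tok)
        elif code == "PR":
            for tok in rest.strip().split(";"):
                tok = tok.strip()
                if tok.startswith("Project:"):
                    self.projects.append(tok[len("Project:"):].strip())
        elif code == "OS":
            if not self.taxon:
                self.taxon = rest.strip()
        elif code == "RN":
            self.refs.append({})
        elif code == "RX":
            if not self.refs:
                self.refs.append({})
            body = rest.strip().rstrip(".")
            key, _, value = body.partition(";")
            self.refs[-1][key.strip().upper()] = value.strip()
        elif code == "FT":
            self._feed_feature(rest)

    def _feed_feature(self, rest: str) -> None:
        key = rest[:16].strip()
        body = rest[16:] if len(rest) > 16 else ""
        if key:  # a new feature starts
            self._flush_qualifier()
            self._in_source = key == "source"
            return
        if not self._in_source:
            return
        body = body.strip()
        if body.startswith("/"):
            self._flush_qualifier()
            self._pending_qualifier = [body]
            if _qualifier_complete(body):
                self._flush_qualifier()
        elif self._pending_qualifier is not None:
            self._pending_qualifier.append(body)
            if _qualifier_complete(" ".join(self._pending_qualifier)):
                self._flush_qualifier()

    def _flush_qualifier(self) -> None:
        if self._pending_qualifier is None:
            return
        text = " ".join(self._pending_qualifier)
        self._pending_qualifier = None
        m = _QUAL_RE.match(text)
        if not m or m.group(1) != "country" or m.group(2) is None:
            return
        value = m.group(2)
        if value.startswith('"') and value.endswith('"') and len(value) >= 2:
            value = value[1:-1]
        self.country = value

    def finish(self) -> tuple[EnaRecord | None, str | None]:
        self._flush_qualifier()
        if self.id_error:
            return None, self.id_error
        if self.id_acc is None:
            return None, "entry without ID line"
        primary = self.accessions[0] if self.accessions else self.id_acc
        refs = []
        for r in self.refs:
            doi, pmid, pmcid = r.get("DOI", ""), r.get("PUBMED", ""), r.get("PMC", "")
            if doi or pmid or pmcid:
                refs.append(PubRef(doi=doi, pmid=pmid, pmcid=pmcid))
        return (
            EnaRecord(
                accession=primary.upper(),
                version=self.version,
                project_accessions=frozenset(self.projects),
                raw_country=self.country,
                primary_refs=tuple(refs),
                taxon_name=self.taxon,
                record_length=self.length,
                secondary_accessions=tuple(a.upper() for a in self.accessions[1:]),
            ),
            None,
        )


def _qualifier_complete(text: str) -> bool:
    # a qualifier is complete when unquoted, or when its quoted value closes
    _, _, value = text.partition("=")
    if not value.startswith('"'):
        return True
    return len(value) >= 2 and value.endswith('"')


def write_embl_flatfile(records: Iterable[EnaRecord], sink: IO[str]) -> int:
    """Write ``records`` in the dialect :func:`parse_embl_flatfile` reads.

    Returns the number of entries written; raises ``ValueError`` naming the
    offending record index if a record violates its invariants.
    """
    n = 0
    for i, rec in enumerate(records):
        try:
            _write_entry(rec, sink)
        except ValueError as exc:
            raise ValueError(f"record {i} ({getattr(rec, 'accession', '?')}): {exc}") from exc
        n += 1
    return n


def _write_entry(rec: EnaRecord, sink: IO[str]) -> None:
    if not rec.accession or rec.accession != rec.accession.upper():
        raise ValueError("invalid accession")
    sink.write(
        f"ID   {rec.accession}; SV {rec.version}; linear; DNA; STD; XXX; "
        f"{rec.record_length} BP.\n"
    )
    acs = [rec.accession, *rec.secondary_accessions]
    sink.write("AC   " + " ".join(f"{a};" for a in acs) + "\n")
    for prj in sorted(rec.project_accessions):
        sink.write(f"PR   Project:{prj};\n")
    if rec.taxon_name:
        sink.write(f"OS   {rec.taxon_name}\n")
    for j, ref in enumerate(rec.primary_refs, start=1):
        sink.write(f"RN   [{j}]\n")
        if ref.doi:
            sink.write(f"RX   DOI; {ref.doi}.\n")
        if ref.pmid:
            sink.write(f"RX   PUBMED; {ref.pmid}.\n")
        if ref.pmcid:
            sink.write(f"RX   PMC; {ref.pmcid}.\n")
    sink.write(f"FT   source          1..{max(rec.record_length, 1)}\n")
    if rec.taxon_name:
        sink.write(f'FT                   /organism="{rec.taxon_name}"\n')
    if rec.raw_country:
        sink.write(f'FT                   /country="{rec.raw_country}"\n')
    sink.write("//\n")


def read_embl(
    path: str | Path,
    options: ParseOptions | None = None,
    report: ParseReport | None = None,
) -> Iterator[EnaRecord]:
    """Parse an EMBL flat file from disk (``.gz`` transparently supported)."""
    with _open_maybe_gzip(path) as fh:
        yield from parse_embl_flatfile(fh, options=options, report=report)
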