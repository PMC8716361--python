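"""INSDC identifier grammar: shape classification and range expansion.

Nucleotide records in the INSDC archives (ENA/GenBank/DDBJ) carry accession
numbers with a fixed letter+digit shape.  This module recognises the three
identifier families the citation pipeline links on:

* classic *sequence* accessions — 1 letter + 5 digits (``M12345``) or
  2 letters + 6 digits (``AY924392``);
* *WGS* (whole-genome shotgun) accessions — 4–6 letters + 8–9 digits,
  detected only so they can be excluded from parsing;
* BioProject (*project*) accessions — ``PRJ`` + one of ``E``/``D``/``N`` +
  a letter + digits (``PRJEB1234``).

Everything else — study identifiers (ERP/SRP), BioSample IDs, RefSeq
underscore forms, run accessions — classifies as ``invalid``: the pipeline
links on sequence and project accessions only.

Authors frequently cite blocks of consecutive accessions as a hyphenated
range ("AB000001–AB000035"); :func:`expand_range` enumerates such a range
under strict same-prefix / same-width / ordered-endpoint rules, with a cap
so that a typo'd range cannot flood downstream tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "Kind",
    "AccessionShape",
    "Grammar",
    "RangeError",
    "classify",
    "expand_range",
]


class Kind(str, Enum):
    """Identifier family of a classified token."""

    SEQUENCE = "sequence"
    WGS = "wgs"
    PROJECT = "project"
    INVALID = "invalid"


_SEQUENCE_RE = re.compile(r"([A-Z])(\d{5})$|([A-Z]{2})(\d{6})$")
_WGS_RE = re.compile(r"([A-Z]{4,6})(\d{8,9})$")
_PROJECT_RE = re.compile(r"(PRJ[EDN][A-Z])(\d+)$")
_VERSION_RE = re.compile(r"\.(\d+)$")


@dataclass(frozen=True)
class AccessionShape:
    """Result of classifying one token.

    ``canonical`` is the upper-case, version-stripped form used for linking;
    ``version`` is the numeric suffix that was stripped (0 when absent).
    """

    kind: Kind
    prefix: str = ""
    digits: str = ""
    width: int = 0
    canonical: str = ""
    version: int = 0

    @property
    def number(self) -> int:
        return int(self.digits) if self.digits else 0


@dataclass(frozen=True)
class Grammar:
    """Tunable grammar parameters.

    ``range_cap`` bounds :func:`expand_range`; ``extra_sequence_patterns``
    allows opting in to additional sequence shapes (e.g. 8-digit new-style
    accessions) without touching the defaults.
    """

    range_cap: int = 1000
    extra_sequence_patterns: Sequence[str] = field(default=())

    def sequence_regexes(self) -> list[re.Pattern[str]]:
        pats = [_SEQUENCE_RE]
        pats.extend(re.compile(p) for p in self.extra_sequence_patterns)
        return pats


def classify(token: str, grammar: Grammar | None = None) -> AccessionShape:
    """Classify ``token`` into one of the identifier families.

    Case-insensitive; a trailing ``.N`` version suffix is stripped before
    classification and recorded.  Never raises: unrecognised shapes return
    ``kind=Kind.INVALID``.
    """
    if not token:
        return AccessionShape(Kind.INVALID)
    tok = token.strip().upper()
    version = 0
    vm = _VERSION_RE.search(tok)
    if vm:
        version = int(vm.group(1))
        tok = tok[: vm.start()]

    m = _PROJECT_RE.fullmatch(tok)
    if m:
        return AccessionShape(
            Kind.PROJECT, m.group(1), m.group(2), len(m.group(2)), tok, version
        )
    for pat in (grammar or _DEFAULT_GRAMMAR).sequence_regexes():
        m = pat.fullmatch(tok)
        if m:
            groups = [g for g in m.groups() if g is not None]
            prefix, digits = groups[0], groups[1]
            return AccessionShape(
                Kind.SEQUENCE, prefix, digits, len(digits), tok, version
            )
    m = _WGS_RE.fullmatch(tok)
    if m:
        return AccessionShape(Kind.WGS, m.group(1), m.group(2), len(m.group(2)), tok, version)
    return AccessionShape(Kind.INVALID, canonical=tok, version=version)


_DEFAULT_GRAMMAR = Grammar()


class RangeError(ValueError):
    """A start–end accession pair that cannot be expanded.

    ``reason`` is one of ``"kind"`` (an endpoint is not a sequence
    accession), ``"prefix"``, ``"width"``, ``"order"``, or ``"cap"``
    (``length`` then carries the would-be expansion size).
    """

    def __init__(self, reason: str, message: str, length: int | None = None):
        super().__init__(message)
        self.reason = reason
        self.length = length


def expand_range(
    start: str, end: str, cap: int = 1000, grammar: Grammar | None = None
) -> list[str]:
    """Enumerate the inclusive accession range ``start``–``end``.

    Both endpoints must be sequence accessions sharing prefix and digit
    width, with ``end`` numerically >= ``start``; the result is zero-padded
    to the endpoints' width and has exactly ``number(end) - number(start) + 1``
    elements.  Raises :class:`RangeError` otherwise.
    """
    a = classify(start, grammar)
    b = classify(end, grammar)
    if a.kind is not Kind.SEQUENCE or b.kind is not Kind.SEQUENCE:
        raise RangeError("kind", f"range endpoints must be sequence accessions: {start!r}, {end!r}")
    if a.prefix != b.prefix:
        raise RangeError("prefix", f"range prefix mismatch: {a.prefix} vs {b.prefix}")
    if a.width != b.width:
        raise RangeError("width", f"range digit-width mismatch: {a.width} vs {b.width}")
    if b.number < a.number:
        raise RangeError("order", f"range end {end} precedes start {start}")
    length = b.number - a.number + 1
    if length > cap:
        raise RangeError("cap", f"range {start}-{end} expands to {length} > cap {cap}", length)
    return [f"{a.prefix}{n:0{a.width}d}" for n in range(a.number, a.number + length)]
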