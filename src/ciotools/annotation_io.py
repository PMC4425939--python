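"""Read and write annotation files into a common record model.

Two dialects are supported:

* **GAF** — the GO consortium's Gene Association File format 2.0
  (tab-separated, ``!`` comment lines, NOT qualifier in column 4,
  pipe-separated multi-values).  GAF has no standard confidence column, so
  this dialect appends the CIO term as an extra 18th column and a
  RAW/SUMMARY marker as a 19th; strict GAF consumers ignore both.  GO
  evidence codes in column 7 are mapped to ECO identifiers through a small
  built-in, user-extensible table.

* **Bgee similarity TSV** — the anatomical-similarity annotation dialect:
  seven tab-separated columns (entity name, qualifier, taxon name, line
  type, evidence term name, confidence term name, reference id), with a
  native RAW/SUMMARY line-type column.

Both readers are strict: a malformed line raises
:class:`AnnotationFormatError` carrying the 1-based line number; no
non-comment line is ever silently dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "Polarity",
    "LineKind",
    "AnnotationRecord",
    "AnnotationFormatError",
    "EVIDENCE_CODE_TO_ECO",
    "read_bgee_tsv",
    "write_bgee_tsv",
    "read_gaf",
    "write_gaf",
]


class Polarity(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class LineKind(enum.Enum):
    RAW = "RAW"
    SUMMARY = "SUMMARY"


class AnnotationFormatError(ValueError):
    """A malformed annotation line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotation line in the common model shared by both dialects.

    ``evidence`` and ``confidence`` hold ECO / CIO term ids or labels;
    SUMMARY lines may pipe-join several evidence values into one string, or
    leave the field empty.  ``references`` preserves input order.
    """

    subject: str
    object: str
    polarity: Polarity = Polarity.POSITIVE
    evidence: str | None = None
    confidence: str | None = None
    references: tuple[str, ...] = ()
    line_kind: LineKind = LineKind.RAW

    def evidence_list(self) -> tuple[str, ...]:
        """Individual evidence values (pipe-split), empty tuple if absent."""
        if not self.evidence:
            return ()
        return tuple(v for v in self.evidence.split("|") if v)

    def with_confidence(self, confidence: str) -> "AnnotationRecord":
        return replace(self, confidence=confidence)


# GO evidence codes printed with their ECO equivalents; extensible per call.
EVIDENCE_CODE_TO_ECO: dict[str, str] = {
    "ISA": "ECO:0000200",
    "IMP": "ECO:0000015",
    "TAS": "ECO:0000033",
    "IEA": "ECO:0000501",
}

_BGEE_HEADER = (
    "Entity name",
    "Qualifier",
    "Taxon name",
    "Line type",
    "Evidence term name",
    "Confidence term name",
    "Reference ID",
)

_EMPTY_MARKERS = {"", "-", "—"}


def _qualifier_to_polarity(q: str) -> Polarity:
    return Polarity.NEGATIVE if q.strip().upper() == "NOT" else Polarity.POSITIVE


def read_bgee_tsv(text: str, header_token: str = "entity name") -> list[AnnotationRecord]:
    """Parse a Bgee-style similarity TSV into annotation records.

    A first line whose first cell equals *header_token* (case-insensitive)
    is treated as a header and skipped.
    """
    records: list[AnnotationRecord] = []
    first_data_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.split("\t")
        if (
            not first_data_seen
            and cells[0].strip().lower() == header_token.strip().lower()
        ):
            first_data_seen = True
            continue
        first_data_seen = True
        if len(cells) != 7:
            raise AnnotationFormatError(
                lineno, f"expected 7 tab-separated columns, got {len(cells)}"
            )
        entity, qualifier, taxon, line_type, evidence, confidence, reference = (
            c.strip() for c in cells
        )
        try:
            kind = LineKind(line_type.upper())
        except ValueError:
            raise AnnotationFormatError(
                lineno, f"unknown line-type token {line_type!r}"
            ) from None
        refs = tuple(
            r for r in reference.split("|") if r and r not in _EMPTY_MARKERS
        )
        records.append(
            AnnotationRecord(
                subject=entity,
                object=taxon,
                polarity=_qualifier_to_polarity(qualifier),
                evidence=evidence if evidence not in _EMPTY_MARKERS else None,
                confidence=confidence if confidence not in _EMPTY_MARKERS else None,
                references=refs,
                line_kind=kind,
            )
        )
    return records


def write_bgee_tsv(records: Iterable[AnnotationRecord]) -> str:
    """Serialize records in the Bgee dialect (header line always emitted).

    SUMMARY rows leave the evidence and reference fields empty: in this
    dialect the supporting evidence of a summary is carried by the RAW rows
    of the same assertion.
    """
    lines = ["\t".join(_BGEE_HEADER)]
    for r in records:
        summary = r.line_kind is LineKind.SUMMARY
        lines.append(
            "\t".join(
                (
                    r.subject,
                    "NOT" if r.polarity is Polarity.NEGATIVE else "",
                    r.object,
                    r.line_kind.value,
                    "" if summary else (r.evidence or ""),
                    r.confidence or "",
                    "" if summary else "|".join(r.references),
                )
            )
        )
    return "\n".join(lines) + "\n"


def _split_subject(subject: str) -> tuple[str, str]:
    db, _, local = subject.partition(":")
    return (db, local) if local else ("", subject)


def read_gaf(
    text: str,
    code_map: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Parse a GAF 2.0 document (with the confidence-column extension).

    Column 7 evidence codes are mapped to ECO ids via *code_map* (defaults
    to the built-in table); tokens already containing ``:`` are taken as
    ECO ids verbatim.  An unmapped bare code raises
    :class:`AnnotationFormatError` listing the code.
    """
    codes = dict(EVIDENCE_CODE_TO_ECO)
    if code_map:
        codes.update(code_map)
    records: list[AnnotationRecord] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("!"):
            continue
        cells = raw.split("\t")
        if len(cells) < 15:
            raise AnnotationFormatError(
                lineno, f"GAF line has {len(cells)} columns, expected at least 15"
            )
        cells = [c.strip() for c in cells]
        db, obj_id, qualifier, go_id = cells[0], cells[1], cells[3], cells[4]
        refs = tuple(r for r in cells[5].split("|") if r)
        evidence_tokens = [t for t in cells[6].split("|") if t]
        mapped: list[str] = []
        for tok in evidence_tokens:
            if ":" in tok:
                mapped.append(tok)
            elif tok in codes:
                mapped.append(codes[tok])
            else:
                raise AnnotationFormatError(
                    lineno, f"unknown GO evidence code {tok!r}"
                )
        confidence = cells[17] if len(cells) > 17 and cells[17] else None
        kind = (
            LineKind.SUMMARY
            if len(cells) > 18 and cells[18].upper() == LineKind.SUMMARY.value
            else LineKind.RAW
        )
        polarity = (
            Polarity.NEGATIVE
            if "NOT" in [q.strip() for q in qualifier.split("|")]
            else Polarity.POSITIVE
        )
        records.append(
            AnnotationRecord(
                subject=f"{db}:{obj_id}" if db else obj_id,
                object=go_id,
                polarity=polarity,
                evidence="|".join(mapped) if mapped else None,
                confidence=confidence,
                references=refs,
                line_kind=kind,
            )
        )
    return records


_ECO_TO_CODE = {v: k for k, v in EVIDENCE_CODE_TO_ECO.items()}


def write_gaf(
    records: Iterable[AnnotationRecord],
    code_map: Mapping[str, str] | None = None,
) -> str:
    """Serialize records as GAF 2.0 plus the confidence extension columns.

    ECO ids with a known GO evidence code are written as the code; others
    are written as the ECO id itself.  Summary lines pipe-join their
    evidence codes and references and carry the SUMMARY marker.
    """
    eco_to_code = dict(_ECO_TO_CODE)
    if code_map:
        eco_to_code.update({v: k for k, v in code_map.items()})
    out = ["!gaf-version: 2.0"]
    for r in records:
        db, local = _split_subject(r.subject)
        codes = [eco_to_code.get(e, e) for e in r.evidence_list()]
        cols = [""] * 19
        cols[0] = db
        cols[1] = local
        cols[2] = local
        cols[3] = "NOT" if r.polarity is Polarity.NEGATIVE else ""
        cols[4] = r.object
        cols[5] = "|".join(r.references)
        cols[6] = "|".join(codes)
        cols[8] = ""
        cols[11] = "protein"
        cols[17] = r.confidence or ""
        cols[18] = r.line_kind.value if r.line_kind is LineKind.SUMMARY else ""
        out.append("\t".join(cols))
    return "\n".join(out) + "\n"
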