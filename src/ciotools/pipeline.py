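"""End-to-end workflow over annotation files: impute, summarize, validate.

The workflow mirrors how summary confidence rows are produced in practice:
single-evidence (RAW) annotation lines are grouped into assertions by
their (subject, object) key — gene product and GO term for GAF input,
anatomical entity and taxon for the Bgee dialect — and each group gains
exactly one auto-generated SUMMARY row carrying the aggregate confidence
statement.  Pre-existing SUMMARY rows in the input are dropped and
regenerated, so the re-evaluation of any single statement (e.g. a
retraction tagged ``rejected``) propagates to the summary.

Legacy inputs lacking per-line confidence can be integrated by imputing an
arbitrary single-evidence statement (medium by default) before
summarizing; the summaries then convey at least the multiplicity,
typality and concordance of the evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import cio_model
from .aggregation import (
    AggregationPolicy,
    EvidenceLine,
    NoAssessableEvidenceError,
    SummaryPolarity,
    aggregate,
)
from .annotation_io import AnnotationRecord, LineKind, Polarity
from .cio_model import (
    Arity,
    CioAxes,
    ConfidenceLevel,
    InvalidAxesError,
    term_for_axes,
)
from .evidence_typing import EvidenceTypePolicy, TypeMode
from .obo_io import Ontology, UnknownTermError

__all__ = [
    "Finding",
    "ValidationError",
    "impute_legacy_confidence",
    "summarize_file",
    "validate",
    "load_policy_file",
]


@dataclass(frozen=True)
class Finding:
    """One validation finding: 1-based record number, severity, message."""

    line: int
    severity: str  # "error" | "warning"
    message: str


class ValidationError(ValueError):
    """Raised by summarize_file when a record cannot be interpreted."""

    def __init__(self, line: int, message: str):
        super().__init__(f"record {line}: {message}")
        self.line = line


_LEVEL_LABEL = {
    ConfidenceLevel.LOW: "low confidence from single evidence",
    ConfidenceLevel.MEDIUM: "medium confidence from single evidence",
    ConfidenceLevel.HIGH: "high confidence from single evidence",
}


def impute_legacy_confidence(
    records: Sequence[AnnotationRecord],
    default_level: ConfidenceLevel = ConfidenceLevel.MEDIUM,
) -> list[AnnotationRecord]:
    """Give every RAW record lacking a confidence term the default level.

    Records already carrying a confidence value, and SUMMARY records, are
    returned untouched.
    """
    out = []
    for r in records:
        if r.line_kind is LineKind.RAW and not r.confidence:
            out.append(r.with_confidence(_LEVEL_LABEL[default_level]))
        else:
            out.append(r)
    return out


def _resolve_evidence(eco: Ontology, token: str) -> str:
    """Resolve an ECO id or label to an id in *eco*; raise if unknown."""
    if token in eco:
        return token
    by_name = eco.id_for_name(token)
    if by_name is not None:
        return by_name
    raise UnknownTermError(f"unknown evidence term {token!r}")


def _resolve_confidence(token: str, cio: Ontology | None) -> CioAxes:
    """Resolve a CIO label or id to statement axes.

    When a loaded CIO ontology is supplied, ids found in it are first
    translated to their labels, so official numeric ids resolve even where
    the built-in model does not carry them.
    """
    try:
        return cio_model.axes_for_term(token)
    except UnknownTermError:
        if cio is not None and token in cio:
            return cio_model.axes_for_term(cio[token].name)
        raise


def _to_evidence_line(
    r: AnnotationRecord, index: int, eco: Ontology, cio: Ontology | None
) -> EvidenceLine:
    if not r.confidence:
        raise ValidationError(
            index, "RAW record lacks a confidence term (impute legacy input first)"
        )
    if not r.evidence:
        raise ValidationError(
            index,
            "RAW record carries a confidence statement but no evidence term; "
            "confidence annotations must be accompanied by ECO terms",
        )
    try:
        axes = _resolve_confidence(r.confidence, cio)
    except (UnknownTermError, InvalidAxesError) as exc:
        raise ValidationError(index, str(exc)) from None
    if axes.arity is not Arity.SINGLE:
        raise ValidationError(
            index,
            f"RAW record carries the multiple-evidence statement "
            f"{r.confidence!r}; RAW lines take single-evidence statements",
        )
    evid = r.evidence_list()
    if len(evid) != 1:
        raise ValidationError(index, "RAW record must carry exactly one evidence term")
    try:
        eco_id = _resolve_evidence(eco, evid[0])
    except UnknownTermError as exc:
        raise ValidationError(index, str(exc)) from None
    return EvidenceLine(
        polarity="negative" if r.polarity is Polarity.NEGATIVE else "positive",
        evidence=eco_id,
        level=axes.level,
        rejected=axes.rejected,
    )


def _dedup(values) -> tuple:
    seen = []
    for v in values:
        if v and v not in seen:
            seen.append(v)
    return tuple(seen)


def summarize_file(
    records: Sequence[AnnotationRecord],
    eco: Ontology,
    cio: Ontology | None = None,
    type_policy: EvidenceTypePolicy = EvidenceTypePolicy(),
    policy: AggregationPolicy = AggregationPolicy(),
) -> list[AnnotationRecord]:
    """Append one SUMMARY record per assertion; regenerate existing ones.

    RAW records pass through unmodified, in input order; SUMMARY records
    present in the input are discarded.  For each distinct (subject,
    object) key among RAW records, one SUMMARY record is appended carrying
    the aggregate statement's canonical CIO label, the summary polarity
    (NOT only for a determined negative outcome), and the pipe-joined
    evidence terms and references of the contributing (non-rejected)
    lines.  Groups in which every line is rejected yield no summary row.
    """
    raws = [r for r in records if r.line_kind is LineKind.RAW]
    groups: dict[tuple[str, str], list[tuple[int, AnnotationRecord]]] = {}
    for i, r in enumerate(raws, start=1):
        groups.setdefault((r.subject, r.object), []).append((i, r))

    out: list[AnnotationRecord] = list(raws)
    for (subject, obj), members in groups.items():
        lines = [_to_evidence_line(r, i, eco, cio) for i, r in members]
        try:
            summary = aggregate(lines, eco, type_policy, policy)
        except NoAssessableEvidenceError:
            continue
        label = term_for_axes(summary.axes).label
        contributing = [
            r for (i, r), ln in zip(members, lines) if not ln.rejected
        ]
        out.append(
            AnnotationRecord(
                subject=subject,
                object=obj,
                polarity=(
                    Polarity.NEGATIVE
                    if summary.polarity is SummaryPolarity.NEGATIVE
                    else Polarity.POSITIVE
                ),
                evidence="|".join(_dedup(r.evidence for r in contributing)) or None,
                confidence=label,
                references=_dedup(
                    ref for r in contributing for ref in r.references
                ),
                line_kind=LineKind.SUMMARY,
            )
        )
    return out


def validate(
    records: Sequence[AnnotationRecord],
    eco: Ontology,
    cio: Ontology | None = None,
) -> list[Finding]:
    """Check records against the annotation guidelines; never raises on content.

    Errors: a RAW line pairing a confidence statement with no ECO term; an
    unknown or non-leaf (internal) CIO term; an unknown ECO term; a SUMMARY
    line tagged ``rejected`` (rejection applies to individual evidence,
    and rejected lines are excluded from aggregation).  Warning: a SUMMARY
    line carrying a single-evidence statement while listing several
    evidence terms.
    """
    findings: list[Finding] = []
    for i, r in enumerate(records, start=1):
        axes = None
        if r.confidence:
            try:
                axes = _resolve_confidence(r.confidence, cio)
            except UnknownTermError:
                findings.append(
                    Finding(i, "error", f"unknown CIO term {r.confidence!r}")
                )
            except InvalidAxesError as exc:
                findings.append(Finding(i, "error", str(exc)))
        for evid in r.evidence_list():
            try:
                _resolve_evidence(eco, evid)
            except UnknownTermError:
                findings.append(
                    Finding(i, "error", f"unknown evidence term {evid!r}")
                )
        if r.line_kind is LineKind.RAW:
            if r.confidence and not r.evidence:
                findings.append(
                    Finding(
                        i,
                        "error",
                        "confidence statement without an ECO evidence term; "
                        "annotations using confidence statements must also "
                        "carry evidence terms",
                    )
                )
        else:  # SUMMARY
            if axes is not None and axes.rejected:
                findings.append(
                    Finding(
                        i,
                        "error",
                        "'rejected' tags individual evidence and cannot "
                        "label a summary line",
                    )
                )
            elif (
                axes is not None
                and axes.arity is Arity.SINGLE
                and len(r.evidence_list()) > 1
            ):
                findings.append(
                    Finding(
                        i,
                        "warning",
                        "single-evidence statement on a summary line that "
                        "lists several evidence terms",
                    )
                )
    return findings


def load_policy_file(text: str) -> tuple[EvidenceTypePolicy, AggregationPolicy]:
    """Parse a flat key=value policy file.

    Recognized keys: ``type_mode`` (subsumption|exact), ``promote_count``,
    ``multitype_promotion``, ``weak_conflict_demotion``,
    ``legacy_default_level``.  Unknown keys raise ``ValueError``.
    """
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"policy line {lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        mapping[key.strip()] = value.strip()
    known = {
        "type_mode",
        "promote_count",
        "multitype_promotion",
        "weak_conflict_demotion",
        "legacy_default_level",
    }
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown policy keys: {sorted(unknown)}")
    type_policy = EvidenceTypePolicy(
        TypeMode(mapping.get("type_mode", "subsumption"))
    )
    agg_policy = AggregationPolicy.from_mapping(
        {k: v for k, v in mapping.items() if k != "type_mode"}
    )
    return type_policy, agg_policy


def drop_summaries(records: Sequence[AnnotationRecord]) -> list[AnnotationRecord]:
    """Input records without their SUMMARY rows."""
    return [r for r in records if r.line_kind is not LineKind.SUMMARY]


def regenerate(
    records: Sequence[AnnotationRecord],
    eco: Ontology,
    **kwargs,
) -> list[AnnotationRecord]:
    """Convenience: drop summaries and re-run :func:`summarize_file`."""
    return summarize_file(drop_summaries(records), eco, **kwargs)
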