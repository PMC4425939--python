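"""Typed model of the Confidence Information Ontology (CIO).

The CIO describes *confidence statements* about annotations along a small
set of semantic axes:

* **arity** — is the assertion supported by a single evidence line or by
  multiple evidence lines;
* **typality** — for multiple lines, whether they are all of the same
  evidence type (per the ECO hierarchy) or of multiple types;
* **concordance** — for multiple lines, whether they agree (congruent) or
  conflict, with conflicts split into weak (one side clearly better
  supported) and strong (both sides similarly supported);
* **level** — the confidence level reached, on the ordered scale
  low < medium < high.  Strongly conflicting statements carry no level,
  because the evidence does not allow a consensual conclusion;
* **rejected** — a special single-evidence statement tagging retracted or
  invalidated evidence, retained for traceability but never aggregated.

This module provides the axes as typed values, a builder for the ontology
itself (:func:`builtin_cio`, no download needed), and the bijection between
axes and canonical term labels (:func:`term_for_axes` /
:func:`axes_for_term`).  Numeric CIO ids are attached only for the two
statements whose ids are fixed in the published ontology release used here
(CIO:0000003 and CIO:0000012); every other term is keyed by its label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .obo_io import Ontology, OntologyTerm, UnknownTermError

__all__ = [
    "ConfidenceLevel",
    "Arity",
    "Typality",
    "Concordance",
    "CioAxes",
    "CioStatement",
    "InvalidAxesError",
    "builtin_cio",
    "term_for_axes",
    "axes_for_term",
    "leaf_statements",
    "ROOT_LABEL",
    "SINGLE_BRANCH_LABEL",
    "MULTIPLE_BRANCH_LABEL",
    "REJECTED_LABEL",
]


class ConfidenceLevel(enum.IntEnum):
    """Basic confidence rating: a strict total order low < medium < high."""

    LOW = 1
    MEDIUM = 2
    HIGH = 3

    def __str__(self) -> str:
        return self.name.lower()

    @classmethod
    def from_string(cls, s: str) -> "ConfidenceLevel":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"not a confidence level: {s!r}") from None


class Arity(enum.Enum):
    SINGLE = "single"
    MULTIPLE = "multiple"


class Typality(enum.Enum):
    SAME = "same"
    MULTIPLE = "multiple"
    UNSPECIFIED = "unspecified"


class Concordance(enum.Enum):
    CONGRUENT = "congruent"
    WEAKLY_CONFLICTING = "weakly_conflicting"
    STRONGLY_CONFLICTING = "strongly_conflicting"
    UNSPECIFIED = "unspecified"


class InvalidAxesError(ValueError):
    """Raised for axis combinations that name no CIO statement."""


@dataclass(frozen=True)
class CioAxes:
    """The semantic coordinates of one CIO confidence statement.

    Invariants (checked on construction):

    * ``rejected`` statements carry no other axes;
    * strongly conflicting statements carry no level;
    * non-rejected single-evidence statements carry a level and leave
      typality/concordance unspecified;
    * multiple-evidence statements fix a typality (same/multiple) and a
      concordance.
    """

    arity: Arity
    typality: Typality = Typality.UNSPECIFIED
    concordance: Concordance = Concordance.UNSPECIFIED
    level: ConfidenceLevel | None = None
    rejected: bool = False

    def __post_init__(self) -> None:
        if self.rejected:
            if (
                self.arity is not Arity.SINGLE
                or self.typality is not Typality.UNSPECIFIED
                or self.concordance is not Concordance.UNSPECIFIED
                or self.level is not None
            ):
                raise InvalidAxesError("rejected implies all other axes unspecified")
            return
        if self.arity is Arity.SINGLE:
            if self.typality is not Typality.UNSPECIFIED:
                raise InvalidAxesError("single evidence has no typality")
            if self.concordance is not Concordance.UNSPECIFIED:
                raise InvalidAxesError("single evidence has no concordance")
            if self.level is None:
                raise InvalidAxesError("single evidence requires a level")
            return
        # multiple evidence lines
        if self.typality not in (Typality.SAME, Typality.MULTIPLE):
            raise InvalidAxesError("multiple evidence lines require a typality")
        if self.concordance is Concordance.UNSPECIFIED:
            raise InvalidAxesError("multiple evidence lines require a concordance")
        if self.concordance is Concordance.STRONGLY_CONFLICTING:
            if self.level is not None:
                raise InvalidAxesError("strongly conflicting statements carry no level")
        elif self.level is None:
            raise InvalidAxesError(
                "congruent / weakly conflicting statements require an overall level"
            )


@dataclass(frozen=True)
class CioStatement:
    """A leaf CIO term: its axes, canonical label and (if fixed) numeric id."""

    axes: CioAxes
    label: str
    id: str | None = None


ROOT_LABEL = "confidence information statement"
SINGLE_BRANCH_LABEL = "confidence statement from single evidence"
MULTIPLE_BRANCH_LABEL = "confidence statement from multiple evidence lines"
REJECTED_LABEL = "rejected"

# The only numeric ids fixed here; all other terms are keyed by label.
KNOWN_IDS = {
    "high confidence from single evidence": "CIO:0000003",
    "confidence statement from congruent evidence lines of multiple types,"
    " overall confidence high": "CIO:0000012",
}

_TYPALITY_PHRASE = {Typality.SAME: "same type", Typality.MULTIPLE: "multiple types"}


def _single_label(level: ConfidenceLevel) -> str:
    return f"{level} confidence from single evidence"


def _multi_label(typality: Typality, concordance_phrase: str,
                 level: ConfidenceLevel | None) -> str:
    base = (
        f"confidence statement from {concordance_phrase} evidence lines of "
        f"{_TYPALITY_PHRASE[typality]}"
    )
    if level is None:
        return base
    return f"{base}, overall confidence {level}"


def _enumerate_leaves() -> list[CioStatement]:
    leaves: list[CioStatement] = []
    for level in ConfidenceLevel:
        label = _single_label(level)
        leaves.append(
            CioStatement(
                CioAxes(Arity.SINGLE, level=level), label, KNOWN_IDS.get(label)
            )
        )
    leaves.append(
        CioStatement(CioAxes(Arity.SINGLE, rejected=True), REJECTED_LABEL)
    )
    for typ in (Typality.SAME, Typality.MULTIPLE):
        for level in ConfidenceLevel:
            label = _multi_label(typ, "congruent", level)
            leaves.append(
                CioStatement(
                    CioAxes(Arity.MULTIPLE, typ, Concordance.CONGRUENT, level),
                    label,
                    KNOWN_IDS.get(label),
                )
            )
        for level in ConfidenceLevel:
            label = _multi_label(typ, "weakly conflicting", level)
            leaves.append(
                CioStatement(
                    CioAxes(
                        Arity.MULTIPLE, typ, Concordance.WEAKLY_CONFLICTING, level
                    ),
                    label,
                    KNOWN_IDS.get(label),
                )
            )
        label = _multi_label(typ, "strongly conflicting", None)
        leaves.append(
            CioStatement(
                CioAxes(Arity.MULTIPLE, typ, Concordance.STRONGLY_CONFLICTING),
                label,
                KNOWN_IDS.get(label),
            )
        )
    return leaves


_LEAVES = _enumerate_leaves()
_BY_AXES = {s.axes: s for s in _LEAVES}
_BY_KEY: dict[str, CioStatement] = {}
for _s in _LEAVES:
    _BY_KEY[_s.label.lower()] = _s
    if _s.id:
        _BY_KEY[_s.id.lower()] = _s


def leaf_statements() -> tuple[CioStatement, ...]:
    """All assignable (leaf) CIO statements: 4 single-evidence + 14 multi-line."""
    return tuple(_LEAVES)


def term_for_axes(axes: CioAxes) -> CioStatement:
    """The unique leaf statement with these axes.

    Raises :class:`InvalidAxesError` for axis combinations naming no
    statement (construction of :class:`CioAxes` already rejects most).
    """
    try:
        return _BY_AXES[axes]
    except KeyError:
        raise InvalidAxesError(f"no CIO statement for axes {axes!r}") from None


def axes_for_term(label_or_id: str) -> CioAxes:
    """The axes of the leaf statement with this label or numeric id.

    Labels match case-insensitively.  Internal (non-leaf) branch terms are
    not assignable as confidence statements and raise a dedicated error.
    """
    key = label_or_id.strip().lower()
    hit = _BY_KEY.get(key)
    if hit is not None:
        return hit.axes
    ont = builtin_cio()
    internal = ont.id_for_name(label_or_id)
    if internal is not None or key in {
        t.id.lower() for t in ont.terms.values()
    }:
        raise InvalidAxesError(
            f"{label_or_id!r} is an internal CIO term, not an assignable leaf"
        )
    raise UnknownTermError(f"unknown CIO term {label_or_id!r}")


def resolve_statement(label_or_id: str) -> CioStatement:
    """The leaf statement with this label or id (see :func:`axes_for_term`)."""
    return term_for_axes(axes_for_term(label_or_id))


def _term(label: str, *parents: str) -> OntologyTerm:
    return OntologyTerm(
        id=KNOWN_IDS.get(label, label),
        name=label,
        parents=frozenset(KNOWN_IDS.get(p, p) for p in parents),
    )


def builtin_cio() -> Ontology:
    """Build the CIO term hierarchy in memory.

    Structure: a root confidence-information-statement term with two
    branches.  The single-evidence branch holds the three level terms plus
    ``rejected``.  The multiple-evidence-lines branch splits by typality
    (same type / multiple types), each typality into congruent and
    conflicting, each conflicting into weakly and strongly conflicting;
    congruent and weakly conflicting nodes each carry three overall-level
    leaves, while strongly conflicting nodes are leaves themselves.
    """
    terms = [
        _term(ROOT_LABEL),
        _term(SINGLE_BRANCH_LABEL, ROOT_LABEL),
        _term(MULTIPLE_BRANCH_LABEL, ROOT_LABEL),
        _term(REJECTED_LABEL, SINGLE_BRANCH_LABEL),
    ]
    for level in ConfidenceLevel:
        terms.append(_term(_single_label(level), SINGLE_BRANCH_LABEL))
    for typ in (Typality.SAME, Typality.MULTIPLE):
        phrase = _TYPALITY_PHRASE[typ]
        typality_label = f"{MULTIPLE_BRANCH_LABEL} of {phrase}"
        congruent_label = _multi_label(typ, "congruent", None)
        conflicting_label = _multi_label(typ, "conflicting", None)
        weak_label = _multi_label(typ, "weakly conflicting", None)
        strong_label = _multi_label(typ, "strongly conflicting", None)
        terms.append(_term(typality_label, MULTIPLE_BRANCH_LABEL))
        terms.append(_term(congruent_label, typality_label))
        terms.append(_term(conflicting_label, typality_label))
        terms.append(_term(weak_label, conflicting_label))
        terms.append(_term(strong_label, conflicting_label))
        for level in ConfidenceLevel:
            terms.append(_term(_multi_label(typ, "congruent", level), congruent_label))
            terms.append(
                _term(_multi_label(typ, "weakly conflicting", level), weak_label)
            )
    return Ontology(terms)
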