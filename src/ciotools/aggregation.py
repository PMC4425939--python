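"""Derive one summary confidence statement from a group of evidence lines.

This is the rule engine at the heart of the package.  Given the
single-evidence annotations supporting one assertion — each carrying a
polarity (positive, or negative via the NOT qualifier), an ECO evidence
term, and a single-evidence confidence level or the ``rejected`` tag — it
produces the axes of the summary statement from the
multiple-evidence-lines branch of the CIO:

1. rejected lines are removed first: retracted evidence is kept for
   traceability but never contributes to a summary;
2. a single surviving line passes its own single-evidence statement
   through unchanged (the arity axis must reflect the evidence count);
3. otherwise the group's typality (same / multiple evidence types) is read
   off the ECO structure, its concordance from the polarity mix, and —
   when a consensual conclusion is reachable — an overall confidence
   level is computed.

Conflicts split by strength: a **strong** conflict has both sides equally
well supported (equal maximum levels) and yields no overall level and an
undetermined polarity; a **weak** conflict has a clearly better-supported
winning side, which determines the polarity and the overall level.

The overall level starts from the best level on the relevant side and may
be promoted one step when the evidence types are multiple (independent
methods corroborate) and one step when the line count reaches a threshold
(repeated confirmation), capped at high.  The promotion knobs, the conflict
predicate and the strength rule are deliberately configurable through
:class:`AggregationPolicy`: resources applying these guidelines are the
ones to define what a conflict is and how individual confidence values
combine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .cio_model import (
    Arity,
    CioAxes,
    Concordance,
    ConfidenceLevel,
    Typality,
)
from .evidence_typing import EvidenceTypePolicy, group_typality
from .obo_io import Ontology

__all__ = [
    "EvidenceLine",
    "AggregationPolicy",
    "SummaryStatement",
    "SummaryPolarity",
    "NoAssessableEvidenceError",
    "filter_rejected",
    "detect_concordance",
    "classify_conflict_strength",
    "overall_level",
    "aggregate",
]


import enum


class NoAssessableEvidenceError(ValueError):
    """All evidence lines of a group were rejected; no summary can be made."""


class SummaryPolarity(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class EvidenceLine:
    """One single-evidence annotation, reduced to what aggregation needs."""

    polarity: str  # "positive" | "negative"
    evidence: str  # ECO term id
    level: ConfidenceLevel | None = None
    rejected: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        if self.rejected != (self.level is None):
            raise ValueError(
                "a line carries a level exactly when it is not rejected"
            )


@dataclass(frozen=True)
class AggregationPolicy:
    """The configurable rules for combining single-evidence confidences.

    Attributes
    ----------
    promote_count
        Number of congruent lines on a side that earns one level of
        promotion (repeated confirmation); must be >= 2.  Default 3.
    multitype_promotion
        Whether congruent groups of multiple evidence types gain one level
        (independent corroboration).  Default True.
    weak_conflict_demotion
        Whether the winning side of a weak conflict is demoted one level.
        Default False: the ontology itself provides "weakly conflicting ...
        overall confidence high" as a reachable statement.
    legacy_default_level
        Level imputed to legacy lines lacking a confidence statement.
    conflict_predicate
        Hook deciding whether a group of non-rejected lines conflicts;
        defaults to mixed polarity.  Resources may substitute their own
        (e.g. incompatible-term conflicts).
    """

    promote_count: int = 3
    multitype_promotion: bool = True
    weak_conflict_demotion: bool = False
    legacy_default_level: ConfidenceLevel = ConfidenceLevel.MEDIUM
    conflict_predicate: Callable[[Sequence[EvidenceLine]], bool] | None = None

    def __post_init__(self) -> None:
        if self.promote_count < 2:
            raise ValueError("promote_count must be >= 2")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AggregationPolicy":
        kwargs = {}
        if "promote_count" in mapping:
            kwargs["promote_count"] = int(mapping["promote_count"])
        if "multitype_promotion" in mapping:
            kwargs["multitype_promotion"] = _to_bool(mapping["multitype_promotion"])
        if "weak_conflict_demotion" in mapping:
            kwargs["weak_conflict_demotion"] = _to_bool(
                mapping["weak_conflict_demotion"]
            )
        if "legacy_default_level" in mapping:
            kwargs["legacy_default_level"] = ConfidenceLevel.from_string(
                str(mapping["legacy_default_level"])
            )
        return cls(**kwargs)


def _to_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "on"):
        return True
    if s in ("false", "0", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


@dataclass(frozen=True)
class SummaryStatement:
    """The aggregate outcome: CIO axes, summary polarity, contributing count."""

    axes: CioAxes
    polarity: SummaryPolarity
    contributing: int

    def __post_init__(self) -> None:
        if self.axes.concordance is Concordance.STRONGLY_CONFLICTING:
            if self.polarity is not SummaryPolarity.UNDETERMINED:
                raise ValueError("a strong conflict has no determined polarity")
        if self.contributing < 1:
            raise ValueError("a summary needs at least one contributing line")


def filter_rejected(lines: Sequence[EvidenceLine]) -> list[EvidenceLine]:
    """Drop rejected lines, preserving order."""
    return [ln for ln in lines if not ln.rejected]


def detect_concordance(
    lines: Sequence[EvidenceLine],
    predicate: Callable[[Sequence[EvidenceLine]], bool] | None = None,
) -> str:
    """``"congruent"`` or ``"conflicting"`` for >= 2 non-rejected lines.

    The default conflict predicate is mixed polarity: a positive and a NOT
    annotation about the same assertion.  A custom *predicate* replaces it.
    """
    if len(lines) < 2:
        raise ValueError("concordance is defined for groups of >= 2 lines")
    if any(ln.rejected for ln in lines):
        raise ValueError("rejected lines must be filtered before aggregation")
    if predicate is None:
        conflicting = any(ln.polarity == "positive" for ln in lines) and any(
            ln.polarity == "negative" for ln in lines
        )
    else:
        conflicting = predicate(lines)
    return "conflicting" if conflicting else "congruent"


def _sides(
    lines: Sequence[EvidenceLine],
) -> tuple[list[EvidenceLine], list[EvidenceLine]]:
    pos = [ln for ln in lines if ln.polarity == "positive"]
    neg = [ln for ln in lines if ln.polarity == "negative"]
    return pos, neg


def classify_conflict_strength(
    lines: Sequence[EvidenceLine],
) -> tuple[str, list[EvidenceLine] | None]:
    """Classify a conflicting group as ("strong", None) or ("weak", winners).

    The conflict is strong when the best confidence level on each side is
    the same — both conclusions are similarly supported and no consensus is
    reachable.  Otherwise it is weak, and the side with the better maximum
    is the winning side.
    """
    pos, neg = _sides(lines)
    if not pos or not neg:
        raise ValueError("conflict strength is defined only for conflicting groups")
    max_pos = max(ln.level for ln in pos)
    max_neg = max(ln.level for ln in neg)
    if max_pos == max_neg:
        return "strong", None
    return "weak", (pos if max_pos > max_neg else neg)


def overall_level(
    side_lines: Sequence[EvidenceLine],
    typality: Typality,
    policy: AggregationPolicy = AggregationPolicy(),
) -> ConfidenceLevel:
    """Overall confidence for a congruent side of evidence lines.

    Best individual level, plus one step when the evidence types are
    multiple (if enabled) and one step when the side reaches the promotion
    count, capped at high.
    """
    if not side_lines:
        raise ValueError("overall level of an empty group is undefined")
    if any(ln.level is None for ln in side_lines):
        raise ValueError("every contributing line must carry a level")
    value = max(ln.level for ln in side_lines).value
    if typality is Typality.MULTIPLE and policy.multitype_promotion:
        value += 1
    if len(side_lines) >= policy.promote_count:
        value += 1
    return ConfidenceLevel(min(value, ConfidenceLevel.HIGH.value))


def _single_axes(line: EvidenceLine) -> CioAxes:
    return CioAxes(Arity.SINGLE, level=line.level)


def aggregate(
    lines: Sequence[EvidenceLine],
    eco: Ontology,
    type_policy: EvidenceTypePolicy = EvidenceTypePolicy(),
    policy: AggregationPolicy = AggregationPolicy(),
) -> SummaryStatement:
    """Summarize a group of evidence lines into one confidence statement.

    Raises :class:`NoAssessableEvidenceError` when every line is rejected,
    and ``ValueError`` on an empty group or missing levels (legacy lines
    must be imputed first).
    """
    if not lines:
        raise ValueError("cannot aggregate an empty group of evidence lines")
    kept = filter_rejected(lines)
    if not kept:
        raise NoAssessableEvidenceError(
            "all evidence lines of this group are rejected"
        )
    if len(kept) == 1:
        (line,) = kept
        return SummaryStatement(
            axes=_single_axes(line),
            polarity=SummaryPolarity(line.polarity),
            contributing=1,
        )
    typality = group_typality(eco, [ln.evidence for ln in kept], type_policy)
    concordance = detect_concordance(kept, policy.conflict_predicate)
    if concordance == "congruent":
        level = overall_level(kept, typality, policy)
        return SummaryStatement(
            axes=CioAxes(Arity.MULTIPLE, typality, Concordance.CONGRUENT, level),
            polarity=SummaryPolarity(kept[0].polarity),
            contributing=len(kept),
        )
    strength, winners = classify_conflict_strength(kept)
    if strength == "strong":
        return SummaryStatement(
            axes=CioAxes(
                Arity.MULTIPLE, typality, Concordance.STRONGLY_CONFLICTING
            ),
            polarity=SummaryPolarity.UNDETERMINED,
            contributing=len(kept),
        )
    level = overall_level(winners, typality, policy)
    if policy.weak_conflict_demotion:
        level = ConfidenceLevel(max(level.value - 1, ConfidenceLevel.LOW.value))
    return SummaryStatement(
        axes=CioAxes(
            Arity.MULTIPLE, typality, Concordance.WEAKLY_CONFLICTING, level
        ),
        polarity=SummaryPolarity(winners[0].polarity),
        contributing=len(kept),
    )
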