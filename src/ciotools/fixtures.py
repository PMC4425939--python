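"""Embedded worked examples, a toy ECO, a synthetic-annotation generator,
and an independent decision-table oracle for cross-validating the rule
engine.

The toy ECO is a 13-term miniature of the Evidence and Conclusion
Ontology, large enough to exercise every typality decision the aggregation
rules can take: unrelated branches (experimental vs. similarity vs. author
statement), parent/child pairs within a branch, and standalone types.
Real ECO identifiers are used only for the terms that carry them in common
curation practice (mutant phenotype ECO:0000015, microarray ECO:0000058,
sequence alignment ECO:0000200, protein BLAST ECO:0000208, traceable
author statement ECO:0000033, automatic assertion ECO:0000501); invented
grouping nodes carry a TOYECO: prefix so they cannot masquerade as real
ECO ids.

:func:`decision_table_oracle` restates the aggregation rules as a direct,
flat case analysis sharing no code with :mod:`ciotools.aggregation`; tests
check the two agree on the exhaustive enumeration of small groups.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .aggregation import (
    AggregationPolicy,
    EvidenceLine,
    SummaryPolarity,
    SummaryStatement,
)
from .annotation_io import AnnotationRecord, LineKind, Polarity
from .cio_model import (
    Arity,
    CioAxes,
    Concordance,
    ConfidenceLevel,
    Typality,
    term_for_axes,
)
from .evidence_typing import EvidenceTypePolicy, group_typality
from .obo_io import Ontology, parse_obo

__all__ = [
    "TOY_ECO_OBO",
    "toy_eco",
    "worked_example_bgee",
    "worked_example_gaf",
    "GroundTruthAnnotation",
    "generate_annotations",
    "decision_table_oracle",
]

# Term ids quoted where real; TOYECO: ids mark invented grouping nodes.
TOY_ECO_OBO = """\
format-version: 1.2
ontology: toy-eco

[Term]
id: TOYECO:0000000
name: evidence

[Term]
id: TOYECO:0000001
name: experimental evidence
is_a: TOYECO:0000000 ! evidence

[Term]
id: ECO:0000015
name: mutant phenotype evidence
is_a: TOYECO:0000001 ! experimental evidence

[Term]
id: ECO:0000058
name: microarray evidence
is_a: TOYECO:0000001 ! experimental evidence

[Term]
id: TOYECO:0000002
name: similarity evidence
is_a: TOYECO:0000000 ! evidence

[Term]
id: ECO:0000200
name: sequence alignment evidence
is_a: TOYECO:0000002 ! similarity evidence

[Term]
id: ECO:0000208
name: protein BLAST evidence
is_a: TOYECO:0000002 ! similarity evidence

[Term]
id: TOYECO:0000003
name: developmental similarity evidence
is_a: TOYECO:0000002 ! similarity evidence

[Term]
id: TOYECO:0000004
name: author statement evidence
is_a: TOYECO:0000000 ! evidence

[Term]
id: ECO:0000033
name: traceable author statement
is_a: TOYECO:0000004 ! author statement evidence

[Term]
id: TOYECO:0000005
name: non-traceable author statement
is_a: TOYECO:0000004 ! author statement evidence

[Term]
id: TOYECO:0000006
name: phylogenetic distribution evidence
is_a: TOYECO:0000000 ! evidence

[Term]
id: ECO:0000501
name: automatic assertion
is_a: TOYECO:0000000 ! evidence
"""


def toy_eco() -> Ontology:
    """Parse and return the embedded toy ECO."""
    return parse_obo(TOY_ECO_OBO)


def worked_example_bgee() -> list[AnnotationRecord]:
    """The two RAW rows of the autopod/Vertebrata homology example.

    Two traceable-author-statement lines of medium confidence, one positive
    and one NOT, about the homology of the autopod originating in
    Vertebrata — the conflicting-hypotheses case whose auto-generated
    summary is a strongly-conflicting same-type statement.
    """
    common = dict(
        subject="Autopod",
        object="Vertebrata",
        evidence="Traceable author statement",
        confidence="Medium confidence from single evidence",
        references=("PMID:23598338",),
        line_kind=LineKind.RAW,
    )
    return [
        AnnotationRecord(polarity=Polarity.POSITIVE, **common),
        AnnotationRecord(polarity=Polarity.NEGATIVE, **common),
    ]


# The source cited for the ERG9 annotations has no PMID printed alongside;
# a placeholder reference token is used.
ERG9_REFERENCE = "REF:ERG9-ref"


def worked_example_gaf() -> list[AnnotationRecord]:
    """The two GO annotations of Candida glabrata ERG9 (UniProtKB:Q9HGZ6).

    Both associate the gene product with GO:0051996 (squalene synthase
    activity) at high confidence from single evidence: one by sequence
    alignment evidence (ECO:0000200, code ISA), one by mutant phenotype
    evidence (ECO:0000015, code IMP).  Their summary is the
    congruent-multiple-types-overall-high statement, CIO:0000012.
    """
    common = dict(
        subject="UniProtKB:Q9HGZ6",
        object="GO:0051996",
        polarity=Polarity.POSITIVE,
        confidence="high confidence from single evidence",
        references=(ERG9_REFERENCE,),
        line_kind=LineKind.RAW,
    )
    return [
        AnnotationRecord(evidence="ECO:0000200", **common),
        AnnotationRecord(evidence="ECO:0000015", **common),
    ]


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """One synthetic assertion: its records, latent truth and intended summary."""

    subject: str
    object: str
    truth: bool
    records: tuple[AnnotationRecord, ...]
    intended_summary: SummaryStatement | None  # None when all lines rejected


_LEVEL_LABEL = {
    ConfidenceLevel.LOW: "low confidence from single evidence",
    ConfidenceLevel.MEDIUM: "medium confidence from single evidence",
    ConfidenceLevel.HIGH: "high confidence from single evidence",
}


def generate_annotations(
    seed: int,
    n_assertions: int = 20,
    lines_per: "int | tuple[int, int]" = (1, 4),
    p_negative: float = 0.2,
    level_weights: Sequence[float] = (0.25, 0.5, 0.25),
    p_rejected: float = 0.1,
    type_pool: Sequence[str] | None = None,
    type_policy: EvidenceTypePolicy = EvidenceTypePolicy(),
    policy: AggregationPolicy = AggregationPolicy(),
) -> list[GroundTruthAnnotation]:
    """Generate grouped single-evidence annotations with known ground truth.

    Deterministic for a fixed seed.  Each assertion draws a latent truth
    label, a line count from *lines_per* (an int, or an inclusive uniform
    range), and per line: a polarity (negative with probability
    *p_negative*), an evidence term from *type_pool* (default: the six
    real-id terms of the toy ECO), a confidence level from
    *level_weights* (low/medium/high), and a rejected flag with
    probability *p_rejected*.  The intended summary is computed with the
    decision-table oracle, or None when every line is rejected.
    """
    if not 0 <= p_negative <= 1 or not 0 <= p_rejected <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if len(level_weights) != 3 or any(w < 0 for w in level_weights) or not any(
        level_weights
    ):
        raise ValueError(
            "level_weights must be three non-negative weights, not all zero"
        )
    if isinstance(lines_per, int):
        lo = hi = lines_per
    else:
        try:
            lo, hi = lines_per
        except (TypeError, ValueError):
            raise ValueError(
                f"lines_per must be an int or a (min, max) pair, got {lines_per!r}"
            ) from None
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid line-count range ({lo}, {hi})")

    eco = toy_eco()
    if type_pool is None:
        type_pool = [
            "ECO:0000015",
            "ECO:0000058",
            "ECO:0000200",
            "ECO:0000208",
            "ECO:0000033",
            "ECO:0000501",
        ]
    for t in type_pool:
        eco[t]  # validate against the toy ECO

    rng = random.Random(seed)
    levels = list(ConfidenceLevel)
    out: list[GroundTruthAnnotation] = []
    for i in range(n_assertions):
        subject = f"SYN:entity{i:04d}"
        obj = f"SYN:term{i:04d}"
        truth = rng.random() < 0.5
        n_lines = rng.randint(lo, hi)
        lines: list[EvidenceLine] = []
        records: list[AnnotationRecord] = []
        for j in range(n_lines):
            negative = rng.random() < p_negative
            evid = rng.choice(list(type_pool))
            rejected = rng.random() < p_rejected
            level = None if rejected else rng.choices(levels, level_weights)[0]
            lines.append(
                EvidenceLine(
                    polarity="negative" if negative else "positive",
                    evidence=evid,
                    level=level,
                    rejected=rejected,
                )
            )
            records.append(
                AnnotationRecord(
                    subject=subject,
                    object=obj,
                    polarity=Polarity.NEGATIVE if negative else Polarity.POSITIVE,
                    evidence=evid,
                    confidence="rejected" if rejected else _LEVEL_LABEL[level],
                    references=(f"SYNREF:{i:04d}-{j}",),
                    line_kind=LineKind.RAW,
                )
            )
        kept_evidence = [ln.evidence for ln in lines if not ln.rejected]
        if not kept_evidence:
            intended = None
        else:
            typality = (
                group_typality(eco, kept_evidence, type_policy)
                if len(kept_evidence) > 1
                else Typality.SAME  # ignored by the oracle for one line
            )
            intended = decision_table_oracle(lines, typality, policy)
        out.append(
            GroundTruthAnnotation(
                subject=subject,
                object=obj,
                truth=truth,
                records=tuple(records),
                intended_summary=intended,
            )
        )
    return out


_ORDER = ["low", "medium", "high"]


def decision_table_oracle(
    lines: Sequence[EvidenceLine],
    typality: Typality,
    policy: AggregationPolicy = AggregationPolicy(),
) -> SummaryStatement:
    """Independent restatement of the aggregation rules as flat case analysis.

    Takes the group typality as a given (the caller decides it from the
    ECO by whatever independent means it trusts) and walks the decision
    table directly: drop rejected, pass a lone survivor through, split
    sides by polarity, compare side maxima for conflict strength, and count
    promotions explicitly.  Shares no logic with
    :func:`ciotools.aggregation.aggregate`.
    """
    kept = [ln for ln in lines if not ln.rejected]
    if len(kept) == 0:
        raise ValueError("no assessable evidence")
    if len(kept) == 1:
        only = kept[0]
        return SummaryStatement(
            axes=CioAxes(Arity.SINGLE, level=only.level),
            polarity=SummaryPolarity(only.polarity),
            contributing=1,
        )

    pos_levels = sorted(
        _ORDER.index(str(ln.level)) for ln in kept if ln.polarity == "positive"
    )
    neg_levels = sorted(
        _ORDER.index(str(ln.level)) for ln in kept if ln.polarity == "negative"
    )

    def promoted(best_index: int, n_on_side: int) -> ConfidenceLevel:
        steps = 0
        if typality is Typality.MULTIPLE and policy.multitype_promotion:
            steps = steps + 1
        if n_on_side >= policy.promote_count:
            steps = steps + 1
        idx = best_index + steps
        if idx > 2:
            idx = 2
        return ConfidenceLevel.from_string(_ORDER[idx])

    if not pos_levels or not neg_levels:
        # congruent: everyone on one side
        side = pos_levels or neg_levels
        pol = "positive" if pos_levels else "negative"
        return SummaryStatement(
            axes=CioAxes(
                Arity.MULTIPLE,
                typality,
                Concordance.CONGRUENT,
                promoted(side[-1], len(side)),
            ),
            polarity=SummaryPolarity(pol),
            contributing=len(kept),
        )

    if pos_levels[-1] == neg_levels[-1]:
        return SummaryStatement(
            axes=CioAxes(Arity.MULTIPLE, typality, Concordance.STRONGLY_CONFLICTING),
            polarity=SummaryPolarity.UNDETERMINED,
            contributing=len(kept),
        )

    if pos_levels[-1] > neg_levels[-1]:
        win_levels, win_pol = pos_levels, "positive"
    else:
        win_levels, win_pol = neg_levels, "negative"
    level = promoted(win_levels[-1], len(win_levels))
    if policy.weak_conflict_demotion:
        idx = _ORDER.index(str(level)) - 1
        if idx < 0:
            idx = 0
        level = ConfidenceLevel.from_string(_ORDER[idx])
    return SummaryStatement(
        axes=CioAxes(
            Arity.MULTIPLE, typality, Concordance.WEAKLY_CONFLICTING, level
        ),
        polarity=SummaryPolarity(win_pol),
        contributing=len(kept),
    )


def intended_summary_label(ann: GroundTruthAnnotation) -> str | None:
    """Canonical CIO label of the intended summary (None if unassessable)."""
    if ann.intended_summary is None:
        return None
    return term_for_axes(ann.intended_summary.axes).label
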