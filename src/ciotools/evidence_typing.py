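"""Decide whether evidence lines are of the same type, from the ECO structure.

Evidence type corresponds to any term of the Evidence and Conclusion
Ontology (ECO).  Two lines count as the *same type* when their ECO terms are
identical or stand in an ancestor/descendant relation (subsumption mode, the
default), or only when identical (exact mode, a stricter option).  A group
of lines is of the same type only if every pair is; one differing line makes
the whole group "multiple types".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .cio_model import Typality
from .obo_io import Ontology

__all__ = ["TypeMode", "EvidenceTypePolicy", "same_type", "group_typality"]


class TypeMode(enum.Enum):
    SUBSUMPTION = "subsumption"
    EXACT = "exact"


@dataclass(frozen=True)
class EvidenceTypePolicy:
    """How two ECO terms are compared: by hierarchy (default) or identity."""

    mode: TypeMode = TypeMode.SUBSUMPTION

    @classmethod
    def from_string(cls, s: str) -> "EvidenceTypePolicy":
        return cls(TypeMode(s.strip().lower()))


def same_type(
    eco: Ontology,
    a: str,
    b: str,
    policy: EvidenceTypePolicy = EvidenceTypePolicy(),
) -> bool:
    """True iff evidence terms *a* and *b* count as the same evidence type."""
    if policy.mode is TypeMode.EXACT:
        # still validate both ids
        eco[a], eco[b]
        return a == b
    return a == b or eco.subsumes(a, b) or eco.subsumes(b, a)


def group_typality(
    eco: Ontology,
    terms: Sequence[str],
    policy: EvidenceTypePolicy = EvidenceTypePolicy(),
) -> Typality:
    """Typality of a group of >= 2 evidence terms: SAME iff every pair matches."""
    if len(terms) < 2:
        raise ValueError(
            "typality is defined only for groups of at least two evidence lines"
        )
    for a, b in combinations(terms, 2):
        if not same_type(eco, a, b, policy):
            return Typality.MULTIPLE
    return Typality.SAME
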