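"""The aggregation rule engine, cross-validated against the decision-table
oracle on the exhaustive enumeration of small evidence groups."""

import itertools

import pytest

from ciotools.aggregation import (
    AggregationPolicy,
    EvidenceLine,
    NoAssessableEvidenceError,
    SummaryPolarity,
    aggregate,
    classify_conflict_strength,
    detect_concordance,
    filter_rejected,
    overall_level,
)
from ciotools.cio_model import (
    Arity,
    Concordance,
    ConfidenceLevel,
    Typality,
    term_for_axes,
)
from ciotools.evidence_typing import EvidenceTypePolicy, group_typality
from ciotools.fixtures import decision_table_oracle

from conftest import bfs_ancestors

LOW, MED, HIGH = ConfidenceLevel.LOW, ConfidenceLevel.MEDIUM, ConfidenceLevel.HIGH

TAS = "ECO:0000033"
AUTHOR = "TOYECO:0000004"  # parent of TAS in the toy ECO
IMP = "ECO:0000015"
ISA = "ECO:0000200"
PHYLO = "TOYECO:0000006"
DEVSIM = "TOYECO:0000003"


def line(level, polarity="positive", evidence=TAS, rejected=False):
    return EvidenceLine(
        polarity=polarity,
        evidence=evidence,
        level=None if rejected else level,
        rejected=rejected,
    )


REJECTED = line(None, rejected=True)


class TestFilterRejected:
    def test_drops_only_rejected(self):
        kept = filter_rejected([line(HIGH), REJECTED])
        assert kept == [line(HIGH)]

    def test_empty(self):
        assert filter_rejected([]) == []

    def test_all_rejected(self):
        assert filter_rejected([REJECTED, REJECTED]) == []


class TestConcordance:
    def test_mixed_polarity_conflicts(self):
        assert detect_concordance([line(MED), line(MED, "negative")]) == "conflicting"

    def test_all_positive_congruent(self):
        assert detect_concordance([line(HIGH), line(HIGH)]) == "congruent"

    def test_all_negative_congruent(self):
        assert (
            detect_concordance([line(LOW, "negative"), line(LOW, "negative")])
            == "congruent"
        )

    def test_single_line_contract_violation(self):
        with pytest.raises(ValueError):
            detect_concordance([line(HIGH)])

    def test_custom_conflict_predicate(self):
        always = lambda lines: True
        assert detect_concordance([line(HIGH), line(HIGH)], always) == "conflicting"


class TestConflictStrength:
    def test_equal_side_maxima_strong(self):
        s, winners = classify_conflict_strength([line(MED), line(MED, "negative")])
        assert s == "strong" and winners is None

    def test_low_dissent_against_high_consensus_weak(self):
        s, winners = classify_conflict_strength(
            [line(HIGH), line(HIGH), line(LOW, "negative")]
        )
        assert s == "weak"
        assert all(ln.polarity == "positive" for ln in winners)

    def test_equal_maxima_with_extra_low_line_still_strong(self):
        s, _ = classify_conflict_strength(
            [line(HIGH), line(HIGH, "negative"), line(LOW)]
        )
        assert s == "strong"

    def test_congruent_group_contract_violation(self):
        with pytest.raises(ValueError):
            classify_conflict_strength([line(HIGH), line(HIGH)])


class TestOverallLevel:
    def test_two_medium_same_type_unchanged(self):
        assert overall_level([line(MED), line(MED)], Typality.SAME) is MED

    def test_multitype_promotion_to_high(self):
        lines = [line(MED, evidence=PHYLO), line(MED, evidence=PHYLO),
                 line(MED, evidence=DEVSIM)]
        assert overall_level(lines, Typality.MULTIPLE) is HIGH

    def test_capped_at_high(self):
        assert overall_level([line(HIGH), line(HIGH)], Typality.MULTIPLE) is HIGH

    def test_many_low_lines_promote(self):
        four_low = [line(LOW)] * 4
        assert overall_level(four_low, Typality.SAME) is MED
        assert overall_level(four_low, Typality.MULTIPLE) is HIGH

    def test_empty_contract_violation(self):
        with pytest.raises(ValueError):
            overall_level([], Typality.SAME)


class TestAggregateWorkedExamples:
    def test_autopod_conflict_strongly_conflicting_same_type(self, eco):
        summary = aggregate([line(MED), line(MED, "negative")], eco)
        assert summary.axes.concordance is Concordance.STRONGLY_CONFLICTING
        assert summary.axes.typality is Typality.SAME
        assert summary.polarity is SummaryPolarity.UNDETERMINED
        assert term_for_axes(summary.axes).label == (
            "confidence statement from strongly conflicting evidence lines "
            "of same type"
        )

    def test_erg9_congruent_multiple_types_high(self, eco):
        summary = aggregate(
            [line(HIGH, evidence=ISA), line(HIGH, evidence=IMP)], eco
        )
        assert summary.axes.concordance is Concordance.CONGRUENT
        assert summary.axes.typality is Typality.MULTIPLE
        assert summary.axes.level is HIGH
        assert term_for_axes(summary.axes).id == "CIO:0000012"

    def test_rejected_line_leaves_single_evidence_passthrough(self, eco):
        summary = aggregate([line(HIGH), REJECTED], eco)
        assert summary.axes.arity is Arity.SINGLE
        assert summary.axes.level is HIGH
        assert summary.polarity is SummaryPolarity.POSITIVE
        assert summary.contributing == 1

    def test_all_rejected_error(self, eco):
        with pytest.raises(NoAssessableEvidenceError):
            aggregate([REJECTED, REJECTED], eco)

    def test_empty_group_error(self, eco):
        with pytest.raises(ValueError):
            aggregate([], eco)


# ---------------------------------------------------------------------------
# exhaustive cross-validation against the independent decision-table oracle

ALPHABET = [
    line(lvl, pol, ev)
    for lvl in (LOW, MED, HIGH)
    for pol in ("positive", "negative")
    for ev in (TAS, AUTHOR, IMP)
] + [REJECTED, line(None, "negative", IMP, rejected=True)]


def independent_typality(eco, lines):
    """Typality by brute-force BFS reachability, bypassing the library's
    subsumption code."""
    evs = [ln.evidence for ln in lines]
    for a, b in itertools.combinations(evs, 2):
        if not (a == b or a in bfs_ancestors(eco, b) or b in bfs_ancestors(eco, a)):
            return Typality.MULTIPLE
    return Typality.SAME


def all_multisets(max_size):
    for size in range(1, max_size + 1):
        yield from itertools.combinations_with_replacement(ALPHABET, size)


@pytest.mark.parametrize(
    "policy",
    [
        AggregationPolicy(),
        AggregationPolicy(promote_count=2),
        AggregationPolicy(multitype_promotion=False),
        AggregationPolicy(weak_conflict_demotion=True),
    ],
    ids=["default", "promote2", "no-multitype", "demote-weak"],
)
def test_engine_matches_oracle_on_all_groups_up_to_four_lines(eco, policy):
    checked = 0
    for group in all_multisets(4):
        kept = [ln for ln in group if not ln.rejected]
        if not kept:
            with pytest.raises(NoAssessableEvidenceError):
                aggregate(list(group), eco, policy=policy)
            continue
        typality = (
            independent_typality(eco, kept) if len(kept) > 1 else Typality.SAME
        )
        expected = decision_table_oracle(list(group), typality, policy)
        got = aggregate(list(group), eco, policy=policy)
        assert got == expected, f"group={group}"
        checked += 1
    assert checked > 3000  # the enumeration really is exhaustive


def test_two_line_level_polarity_enumeration_has_21_unordered_cases():
    symbols = [
        line(lvl, pol) for lvl in (LOW, MED, HIGH) for pol in ("positive", "negative")
    ]
    unordered = set(itertools.combinations_with_replacement(symbols, 2))
    ordered = list(itertools.product(symbols, repeat=2))
    assert len(unordered) == 21 and len(ordered) == 36


class TestInvariants:
    def test_permutation_invariance(self, eco):
        groups = [
            [line(HIGH, evidence=ISA), line(LOW, "negative", IMP), line(MED), REJECTED],
            [line(MED), line(MED, "negative"), line(HIGH)],
        ]
        for group in groups:
            outcomes = {
                aggregate(list(p), eco) for p in itertools.permutations(group)
            }
            assert len(outcomes) == 1

    def test_adding_rejected_line_is_noop(self, eco):
        for group in all_multisets(3):
            kept = [ln for ln in group if not ln.rejected]
            if not kept:
                continue
            base = aggregate(list(group), eco)
            assert aggregate(list(group) + [REJECTED], eco) == base

    def test_monotone_in_congruent_positive_lines(self, eco):
        positives = [ln for ln in ALPHABET if ln.polarity == "positive" and not ln.rejected]
        for group in itertools.combinations_with_replacement(positives, 2):
            before = aggregate(list(group), eco)
            for extra in positives:
                after = aggregate(list(group) + [extra], eco)
                assert after.axes.level >= before.axes.level

    def test_strong_conflicts_never_carry_level(self, eco):
        for group in all_multisets(4):
            kept = [ln for ln in group if not ln.rejected]
            if not kept:
                continue
            out = aggregate(list(group), eco)
            if out.axes.concordance is Concordance.STRONGLY_CONFLICTING:
                assert out.axes.level is None
                assert out.polarity is SummaryPolarity.UNDETERMINED
            else:
                assert out.axes.level is not None
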