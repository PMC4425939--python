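"""Structure of the built-in CIO and the axes<->term bijection."""

import pytest

from ciotools.cio_model import (
    MULTIPLE_BRANCH_LABEL,
    ROOT_LABEL,
    SINGLE_BRANCH_LABEL,
    Arity,
    CioAxes,
    Concordance,
    ConfidenceLevel,
    InvalidAxesError,
    Typality,
    axes_for_term,
    builtin_cio,
    leaf_statements,
    term_for_axes,
)
from ciotools.obo_io import UnknownTermError


class TestStructure:
    def test_root_has_two_branches(self, cio):
        assert cio.children(ROOT_LABEL) == {
            SINGLE_BRANCH_LABEL,
            MULTIPLE_BRANCH_LABEL,
        }

    def test_three_level_terms_under_single_evidence(self, cio):
        levelled = {
            c
            for c in cio.children(SINGLE_BRANCH_LABEL)
            if "confidence from single evidence" in cio[c].name
        }
        assert len(levelled) == 3

    def test_rejected_sits_under_single_evidence(self, cio):
        assert "rejected" in cio.children(SINGLE_BRANCH_LABEL)

    @pytest.mark.parametrize("phrase", ["same type", "multiple types"])
    def test_each_typality_node_has_congruent_and_conflicting(self, cio, phrase):
        node = f"{MULTIPLE_BRANCH_LABEL} of {phrase}"
        kids = {cio[c].name for c in cio.children(node)}
        assert kids == {
            f"confidence statement from congruent evidence lines of {phrase}",
            f"confidence statement from conflicting evidence lines of {phrase}",
        }

    @pytest.mark.parametrize("phrase", ["same type", "multiple types"])
    def test_conflicting_splits_weak_strong(self, cio, phrase):
        node = f"confidence statement from conflicting evidence lines of {phrase}"
        assert len(cio.children(node)) == 2

    @pytest.mark.parametrize("phrase", ["same type", "multiple types"])
    @pytest.mark.parametrize("kind", ["congruent", "weakly conflicting"])
    def test_three_overall_levels(self, cio, phrase, kind):
        node = f"confidence statement from {kind} evidence lines of {phrase}"
        assert len(cio.children(node)) == 3

    @pytest.mark.parametrize("phrase", ["same type", "multiple types"])
    def test_strongly_conflicting_is_leaf(self, cio, phrase):
        node = (
            f"confidence statement from strongly conflicting evidence lines of {phrase}"
        )
        assert cio.children(node) == set()

    def test_leaf_counts(self, cio):
        # 3 levels + rejected under single; 2 x (3 congruent + 3 weak + 1 strong)
        leaves = cio.leaves()
        assert len(leaves) == 18
        assert len(leaf_statements()) == 18

    def test_known_ids_attached(self, cio):
        assert cio["CIO:0000003"].name == "high confidence from single evidence"
        assert cio["CIO:0000012"].name == (
            "confidence statement from congruent evidence lines of multiple "
            "types, overall confidence high"
        )


class TestBijection:
    def test_roundtrip_over_every_leaf(self):
        for stmt in leaf_statements():
            assert term_for_axes(axes_for_term(stmt.label)).label == stmt.label
            assert term_for_axes(stmt.axes) == stmt

    def test_high_single(self):
        stmt = term_for_axes(CioAxes(Arity.SINGLE, level=ConfidenceLevel.HIGH))
        assert stmt.label == "high confidence from single evidence"
        assert stmt.id == "CIO:0000003"

    def test_congruent_multiple_high_has_fixed_id(self):
        stmt = term_for_axes(
            CioAxes(
                Arity.MULTIPLE,
                Typality.MULTIPLE,
                Concordance.CONGRUENT,
                ConfidenceLevel.HIGH,
            )
        )
        assert stmt.id == "CIO:0000012"

    def test_strongly_conflicting_same_type_label(self):
        stmt = term_for_axes(
            CioAxes(Arity.MULTIPLE, Typality.SAME, Concordance.STRONGLY_CONFLICTING)
        )
        assert (
            stmt.label
            == "confidence statement from strongly conflicting evidence lines of same type"
        )

    def test_rejected_axes(self):
        axes = axes_for_term("rejected")
        assert axes.rejected

    def test_low_single_from_label(self):
        axes = axes_for_term("low confidence from single evidence")
        assert axes.arity is Arity.SINGLE
        assert axes.level is ConfidenceLevel.LOW

    def test_labels_match_case_insensitively(self):
        axes = axes_for_term("Medium confidence from single evidence")
        assert axes.level is ConfidenceLevel.MEDIUM

    def test_id_lookup(self):
        assert axes_for_term("CIO:0000003").level is ConfidenceLevel.HIGH

    MOST_INFORMATIVE = [
        "high confidence from single evidence",
        "confidence statement from congruent evidence lines of same type, overall confidence high",
        "confidence statement from congruent evidence lines of same type, overall confidence medium",
        "confidence statement from congruent evidence lines of multiple types, overall confidence high",
        "confidence statement from congruent evidence lines of multiple types, overall confidence medium",
        "low confidence from single evidence",
        "confidence statement from strongly conflicting evidence lines of same type",
        "confidence statement from weakly conflicting evidence lines of same type, overall confidence low",
        "confidence statement from strongly conflicting evidence lines of multiple types",
        "confidence statement from weakly conflicting evidence lines of multiple types, overall confidence low",
    ]

    @pytest.mark.parametrize("label", MOST_INFORMATIVE)
    def test_most_informative_labels_resolve(self, label):
        axes_for_term(label)  # must not raise

    def test_internal_term_flagged_non_assignable(self):
        with pytest.raises(InvalidAxesError, match="internal"):
            axes_for_term(SINGLE_BRANCH_LABEL)

    def test_unknown_term_raises(self):
        with pytest.raises(UnknownTermError):
            axes_for_term("no such confidence statement")


class TestAxesInvariants:
    def test_level_order(self):
        assert ConfidenceLevel.LOW < ConfidenceLevel.MEDIUM < ConfidenceLevel.HIGH
        assert len(list(ConfidenceLevel)) == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(arity=Arity.SINGLE, rejected=True, level=ConfidenceLevel.LOW),
            dict(
                arity=Arity.MULTIPLE,
                typality=Typality.SAME,
                concordance=Concordance.STRONGLY_CONFLICTING,
                level=ConfidenceLevel.HIGH,
            ),
            dict(arity=Arity.SINGLE),  # no level, not rejected
            dict(arity=Arity.MULTIPLE, typality=Typality.UNSPECIFIED),
            dict(
                arity=Arity.MULTIPLE,
                typality=Typality.SAME,
                concordance=Concordance.UNSPECIFIED,
            ),
        ],
    )
    def test_inconsistent_axes_rejected(self, kwargs):
        with pytest.raises(InvalidAxesError):
            CioAxes(**kwargs)

    def test_builtin_cio_exports_and_reparses(self, cio):
        from ciotools.obo_io import parse_obo, write_obo

        assert parse_obo(write_obo(cio)).terms == cio.terms
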