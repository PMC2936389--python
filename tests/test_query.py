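"""Strategy parsing, serialization, matching and set-algebra execution."""

from __future__ import annotations

import numpy as np
import pytest

from hedgekit.medline_io import Corpus, MedlineRecord, MeshHeading
from hedgekit.query import (
    CorpusIndex,
    LineRef,
    MeshTree,
    OpNode,
    QueryParseError,
    TermNode,
    compile_single_line,
    execute,
    format_expression,
    format_strategy,
    match_mesh,
    match_tiab,
    parse_expression,
    parse_strategy,
)
from hedgekit.strategies import STRATEGY_TEXTS, builtin_strategy

from conftest import oracle_execute, random_strategy


class TestParseStrategy:
    @pytest.mark.parametrize(
        "name, n_lines", [("sensitive", 11), ("precise", 10), ("balanced", 8)]
    )
    def test_builtin_strategies_parse_with_expected_line_counts(self, name, n_lines):
        strategy = builtin_strategy(name)
        assert len(strategy.lines) == n_lines
        assert strategy.result_line == n_lines

    def test_balanced_line5_structure(self):
        # (nurse[tiab] OR nurses[tiab]) AND staffing[tiab]
        line5 = builtin_strategy("balanced").line(5)
        assert line5 == OpNode(
            "AND",
            (
                OpNode("OR", (TermNode("nurse"), TermNode("nurses"))),
                TermNode("staffing"),
            ),
        )

    def test_sensitive_line4_is_qualified_mesh_term(self):
        line4 = builtin_strategy("sensitive").line(4)
        assert line4 == TermNode(
            "Intensive Care Units", field="mh", subheading="manpower"
        )

    def test_lowercase_operators_accepted(self):
        expr = parse_expression("nurse[tiab] or nurses[tiab]")
        assert expr == OpNode("OR", (TermNode("nurse"), TermNode("nurses")))

    def test_unquoted_multiword_tiab_is_a_phrase(self):
        assert parse_expression("skill mix[tiab]") == TermNode("skill mix")

    def test_space_before_field_tag_accepted(self):
        expr = parse_expression('"Hospital Units" [mh]')
        assert expr == TermNode("Hospital Units", field="mh")

    def test_forward_reference_rejected(self):
        with pytest.raises(QueryParseError, match="line 1"):
            parse_strategy("1\t#9\n2\tnurse[tiab]\n3\t#1 OR #2\n")

    def test_self_reference_rejected(self):
        with pytest.raises(QueryParseError):
            parse_strategy("1\t#1\n")

    def test_unknown_field_tag_rejected(self):
        with pytest.raises(QueryParseError, match=r"\[majr\]"):
            parse_expression("nurse[majr]")

    @pytest.mark.parametrize("bad", ['"unterminated[mh]', "(nurse[tiab]", "nurse[tiab])"])
    def test_unbalanced_quotes_and_parens_rejected(self, bad):
        with pytest.raises(QueryParseError):
            parse_expression(bad)

    def test_non_consecutive_line_numbers_rejected(self):
        with pytest.raises(QueryParseError):
            parse_strategy("1\tnurse[tiab]\n3\tnurses[tiab]\n")

    def test_precedence_not_over_and_over_or(self):
        expr = parse_expression("a[tiab] OR b[tiab] AND c[tiab] NOT d[tiab]")
        assert expr == OpNode(
            "OR",
            (
                TermNode("a"),
                OpNode(
                    "AND",
                    (TermNode("b"), OpNode("NOT", (TermNode("c"), TermNode("d")))),
                ),
            ),
        )


class TestSerialization:
    @pytest.mark.parametrize("name", sorted(STRATEGY_TEXTS))
    def test_builtin_round_trip(self, name):
        strategy = builtin_strategy(name)
        assert parse_strategy(format_strategy(strategy), name=name) == strategy

    def test_random_expression_round_trip(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            strategy = random_strategy(rng)
            reparsed = parse_strategy(format_strategy(strategy), name=strategy.name)
            assert reparsed == strategy


class TestCompile:
    def test_single_line_strategy_unchanged(self):
        strategy = parse_strategy("1\tnurse[tiab] OR nurses[tiab]\n")
        assert compile_single_line(strategy) == strategy.line(1)

    def test_result_or_of_refs_substitutes_operands(self):
        strategy = parse_strategy("1\tnurse[tiab]\n2\tstaffing[tiab]\n3\t#1 OR #2\n")
        assert compile_single_line(strategy) == OpNode(
            "OR", (TermNode("nurse"), TermNode("staffing"))
        )

    def test_compiled_retrieval_equals_linewise(self, engine_corpus):
        rng = np.random.default_rng(7)
        for _ in range(100):
            strategy = random_strategy(rng)
            compiled = compile_single_line(strategy)
            assert execute(compiled, engine_corpus) == execute(strategy, engine_corpus)


class TestMatchTiab:
    def test_single_term_title_match(self, toy_corpus):
        assert match_tiab(toy_corpus[0], "staffing")

    def test_no_substring_or_stem_matching(self, toy_corpus):
        assert not match_tiab(toy_corpus[0], "mortal")  # token is "mortality"
        assert not match_tiab(toy_corpus[0], "staffin")  # token is "staffing"

    def test_case_insensitive(self, toy_corpus):
        assert match_tiab(toy_corpus[0], "NURSE")

    def test_phrase_requires_adjacency(self, toy_corpus):
        assert match_tiab(toy_corpus[0], "skill mix")  # "skill mix of staff"
        assert not match_tiab(toy_corpus[2], "skill mix")  # "skill and grade mix"

    def test_phrase_never_crosses_title_abstract_boundary(self):
        rec = MedlineRecord(pmid="1", title="Assessing skill", abstract="mix of staff")
        assert not match_tiab(rec, "skill mix")


class TestMatchMesh:
    def test_descriptor_equality_case_insensitive(self, toy_corpus):
        assert match_mesh(toy_corpus[0], "nursing staff, hospital")
        assert not match_mesh(toy_corpus[0], "Nursing Staff")

    def test_subheading_must_be_carried(self, toy_corpus):
        assert match_mesh(toy_corpus[1], "Intensive Care Units", subheading="manpower")
        assert not match_mesh(toy_corpus[0], "Hospital Units", subheading="manpower")

    def test_explode_requires_tree(self, toy_corpus):
        with pytest.raises(ValueError):
            match_mesh(toy_corpus[0], "Nursing Staff", explode=True)

    def test_explosion_matches_descendants_only_when_enabled(self, toy_corpus, mesh_tree):
        rec = toy_corpus[0]  # carries "Nursing Staff, Hospital"
        assert not match_mesh(rec, "Nursing Staff", explode=False, mesh_tree=mesh_tree)
        assert match_mesh(rec, "Nursing Staff", explode=True, mesh_tree=mesh_tree)

    def test_descendants_agree_with_tree_walk_oracle(self, mesh_tree):
        # brute-force: a descendant's tree number extends an ancestor's
        entries = [
            ("N02", "Health Personnel"),
            ("N02.360", "Nursing Staff"),
            ("N02.360.475", "Nursing Staff, Hospital"),
            ("N02.421", "Health Services Administration"),
            ("N02.421.143", "Personnel Staffing and Scheduling"),
            ("N02.421.143.150", "Nurse-Patient Ratio"),
            ("N05.715", "Hospital Units"),
            ("N05.715.360", "Intensive Care Units"),
        ]
        for tn, desc in entries:
            expected = {
                d.lower()
                for t, d in entries
                if t.startswith(tn + ".")
            }
            assert mesh_tree.descendants(desc) == expected


class TestExecute:
    def test_empty_corpus_retrieves_nothing(self):
        strategy = builtin_strategy("balanced")
        assert execute(strategy, Corpus()) == frozenset()

    def test_single_term_retrieves_matching_record(self, toy_corpus):
        assert execute(parse_expression("registered[tiab]"), toy_corpus) == {"2"}

    def test_not_is_set_difference(self, toy_corpus):
        expr = parse_expression("mix[tiab] NOT staffing[tiab]")
        assert execute(expr, toy_corpus) == {"3"}

    def test_year_range_limits_before_matching(self, toy_corpus):
        expr = parse_expression("mix[tiab]")
        assert execute(expr, toy_corpus, year_range=(2000, 2006)) == {"1", "3"}

    def test_or_idempotence_and_monotonicity(self, engine_corpus):
        a = parse_expression("nurse[tiab]")
        b = parse_expression("staffing[tiab]")
        set_a = execute(a, engine_corpus)
        assert execute(OpNode("OR", (a, a)), engine_corpus) == set_a
        assert execute(OpNode("AND", (a, a)), engine_corpus) == set_a
        assert execute(OpNode("OR", (a, b)), engine_corpus) >= set_a
        assert execute(OpNode("AND", (a, b)), engine_corpus) <= set_a

    def test_retrieved_ids_are_subset_of_corpus(self, engine_corpus):
        rng = np.random.default_rng(99)
        for _ in range(50):
            retrieved = execute(random_strategy(rng), engine_corpus)
            assert retrieved <= engine_corpus.ids

    def test_prebuilt_index_gives_identical_retrieval(self, engine_corpus):
        index = CorpusIndex(engine_corpus)
        rng = np.random.default_rng(3)
        for _ in range(20):
            strategy = random_strategy(rng)
            assert execute(strategy, index) == execute(strategy, engine_corpus)

    def test_index_refuses_year_range(self, engine_corpus):
        with pytest.raises(ValueError):
            execute(
                parse_expression("nurse[tiab]"),
                CorpusIndex(engine_corpus),
                year_range=(1982, 2006),
            )

    def test_agreement_with_truth_evaluation_oracle(self, engine_corpus):
        rng = np.random.default_rng(123)
        for _ in range(200):
            strategy = random_strategy(rng)
            assert execute(strategy, engine_corpus) == oracle_execute(
                strategy, engine_corpus
            )

    def test_exploded_execution_agrees_with_oracle(self, mesh_tree):
        corpus = Corpus(
            records=(
                MedlineRecord(pmid="1", mesh_headings=(MeshHeading("Intensive Care Units"),)),
                MedlineRecord(pmid="2", mesh_headings=(MeshHeading("Hospital Units"),)),
                MedlineRecord(pmid="3", mesh_headings=(MeshHeading("Nurse-Patient Ratio"),)),
            )
        )
        expr = parse_expression('"Hospital Units"[mh]')
        assert execute(expr, corpus, mesh_tree=mesh_tree, explode_default=True) == {"1", "2"}
        assert execute(expr, corpus, mesh_tree=mesh_tree, explode_default=False) == {"2"}
        noexp = parse_expression('"Hospital Units"[mh:noexp]')
        assert execute(noexp, corpus, mesh_tree=mesh_tree, explode_default=True) == {"2"}
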