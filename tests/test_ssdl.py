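"""Scheme parsing, expression evaluation, scoring, and the dual-route
check against an independently evaluated structural representation."""

import itertools
import json

import numpy as np
import pytest

from helpers import Leaf, StructuralEntry, Tree, oracle_scores, render_scheme
from varan.pipeline import default_scheme_path
from varan.ssdl import (
    Cutoffs,
    ExpressionError,
    SchemeError,
    ScoreResult,
    classify,
    compile_expression,
    eval_expr,
    list_controls,
    load_scheme,
    parse_scheme,
    scheme_to_json,
    score_variant,
)
from varan.variants import Variant, VariantRow

MINIMAL = {
    "name": "minimal",
    "version": "1",
    "categories": [
        {
            "name": "quality",
            "entries": [
                {
                    "id": "low_vaf",
                    "label": "low VAF",
                    "artifact_weight": 1.0,
                    "condition": {"expr": 'x("VAF") < th("minVAF")'},
                }
            ],
        }
    ],
    "thresholds": {"minVAF": {"default": 0.02, "min": 0.0, "max": 1.0}},
}


def _row(**kwargs):
    defaults = dict(variant=Variant("chr1", 10, "A", "G"))
    defaults.update(kwargs)
    return VariantRow(**defaults)


class TestParsing:
    def test_minimal_scheme_parses(self):
        s = parse_scheme(json.dumps(MINIMAL))
        assert len(s.entries) == 1
        assert s.thresholds["minVAF"].default == 0.02

    def test_zero_categories_rejected(self):
        with pytest.raises(SchemeError, match=r"\$\.categories"):
            parse_scheme({"categories": []})

    def test_empty_category_rejected(self):
        doc = dict(MINIMAL, categories=[{"name": "x", "entries": []}])
        with pytest.raises(SchemeError, match="at least one entry"):
            parse_scheme(doc)

    def test_duplicate_entry_id_rejected(self):
        doc = json.loads(json.dumps(MINIMAL))
        doc["categories"][0]["entries"].append(
            dict(doc["categories"][0]["entries"][0])
        )
        with pytest.raises(SchemeError, match="duplicate entry id"):
            parse_scheme(doc)

    def test_undeclared_threshold_rejected(self):
        doc = json.loads(json.dumps(MINIMAL))
        doc["thresholds"] = {}
        with pytest.raises(SchemeError, match="undeclared threshold"):
            parse_scheme(doc)

    def test_zero_weight_entry_rejected(self):
        doc = json.loads(json.dumps(MINIMAL))
        doc["categories"][0]["entries"][0]["artifact_weight"] = 0.0
        with pytest.raises(SchemeError, match="at least one score"):
            parse_scheme(doc)

    def test_expression_syntax_error_carries_location(self):
        doc = json.loads(json.dumps(MINIMAL))
        doc["categories"][0]["entries"][0]["condition"] = {"expr": 'x("VAF") <'}
        with pytest.raises(SchemeError, match=r"categories\[0\].entries\[0\]"):
            parse_scheme(doc)

    def test_default_scheme_round_trips(self):
        s1 = load_scheme(str(default_scheme_path()))
        s2 = parse_scheme(scheme_to_json(s1))
        assert scheme_to_json(s1) == scheme_to_json(s2)
        assert [e.id for e in s1.entries] == [e.id for e in s2.entries]
        assert s1.thresholds.keys() == s2.thresholds.keys()


class TestExpressions:
    def test_threshold_comparison(self):
        row = _row(vaf=0.01)
        assert eval_expr('x("VAF") < th("minVAF")', row, {"minVAF": 0.02})
        row2 = _row(vaf=0.05)
        assert not eval_expr('x("VAF") < th("minVAF")', row2, {"minVAF": 0.02})

    def test_is_empty_detects_missing_annotation(self):
        assert eval_expr('isEmpty(x("dbsnp_id"))', _row())
        assert not eval_expr(
            'isEmpty(x("dbsnp_id"))', _row(annotations={"dbsnp_id": "rs1"})
        )

    def test_missing_value_in_numeric_comparison_is_false(self):
        diags = []
        assert not eval_expr('x("popfreq.AF") > 0.5', _row(), diagnostics=diags)
        assert not eval_expr('x("popfreq.AF") < 0.5', _row(), diagnostics=diags)
        assert diags  # the unparseable value was recorded

    def test_string_and_boolean_combinators(self):
        row = _row(effect="frameshift_insertion", caller_flags={"a": True})
        expr = 'stringContains(x("effect"), "frameshift") or x("caller_count") >= 5'
        assert eval_expr(expr, row)
        row2 = _row(effect="missense", caller_flags={c: True for c in "abcde"})
        assert eval_expr(expr, row2)
        row3 = _row(effect="missense", caller_flags={"a": True})
        assert not eval_expr(expr, row3)

    def test_not_and_parentheses(self):
        row = _row(vaf=0.5)
        assert eval_expr('not (x("VAF") < 0.1)', row)

    def test_bad_syntax_reports_position(self):
        with pytest.raises(ExpressionError, match="position"):
            compile_expression('x("VAF") << 3')
        with pytest.raises(ExpressionError):
            compile_expression("while true")

    def test_state_function_rejected_outside_rules(self):
        with pytest.raises(ExpressionError, match="state"):
            compile_expression('state("NPM1") == "MUTATED"')

    def test_referenced_names_are_collected(self):
        c = compile_expression('x("VAF") < th("minVAF") and isEmpty(x("dbsnp.id"))')
        assert c.columns == {"VAF", "dbsnp.id"}
        assert c.thresholds == {"minVAF"}


class TestScoring:
    def test_single_firing_entry(self):
        s = parse_scheme(json.dumps(MINIMAL))
        r = score_variant(s, _row(vaf=0.001))
        assert (r.a_score, r.p_score) == (1.0, 0.0)
        assert r.fired_artifact == ["low_vaf"]

    def test_deactivated_entry_contributes_nothing(self):
        s = parse_scheme(json.dumps(MINIMAL))
        r = score_variant(s, _row(vaf=0.001), overrides={"entries": {"low_vaf": False}})
        assert (r.a_score, r.p_score) == (0.0, 0.0)

    def test_threshold_override_respected_and_range_checked(self):
        s = parse_scheme(json.dumps(MINIMAL))
        r = score_variant(
            s, _row(vaf=0.05), overrides={"thresholds": {"minVAF": 0.10}}
        )
        assert r.a_score == 1.0
        with pytest.raises(SchemeError, match="outside"):
            score_variant(s, _row(), overrides={"thresholds": {"minVAF": 5.0}})

    def test_truth_table_against_enumeration(self):
        """5 entries with mixed AND/OR trees over 3 boolean columns must
        match direct enumeration on all 8 assignments."""
        cols = ["f1", "f2", "f3"]
        L = lambda c: Leaf("cmp", c, "==", "1")
        entries = [
            StructuralEntry("e1", Tree("AND", [Tree(None, [L("f1")]), Tree(None, [L("f2")])]), 1.0, 0.0),
            StructuralEntry("e2", Tree("OR", [Tree(None, [L("f1")]), Tree(None, [L("f3")])]), 0.0, 1.0),
            StructuralEntry("e3", Tree("AND", [Tree("OR", [Tree(None, [L("f2")]), Tree(None, [L("f3")])]), Tree(None, [L("f1")])]), 2.0, 0.0),
            StructuralEntry("e4", Tree(None, [L("f3")]), 0.5, 0.5),
            StructuralEntry("e5", Tree("OR", [Tree(None, [L("f1")]), Tree(None, [L("f2")]), Tree(None, [L("f3")])]), 0.0, 3.0),
        ]
        scheme = parse_scheme(render_scheme(entries, {}))
        for bits in itertools.product("01", repeat=3):
            values = dict(zip(cols, bits))
            row = _row(annotations=dict(values))
            got = score_variant(scheme, row)
            want_a, want_p = oracle_scores(entries, values, {})
            assert (got.a_score, got.p_score) == (want_a, want_p), values

    def test_classification_boundaries(self):
        cut = Cutoffs(1.0, 1.0)
        assert classify(ScoreResult(2, 0), cut) == "artifact"
        assert classify(ScoreResult(0, 0), cut) == "pass"
        assert classify(ScoreResult(1.0, 0), cut) == "artifact"  # inclusive
        assert classify(ScoreResult(1, 1), cut) == "artifact_and_polymorphism"
        assert classify(ScoreResult(0, 3), cut) == "polymorphism"


class TestControls:
    def test_minimal_scheme_controls(self):
        s = parse_scheme(json.dumps(MINIMAL))
        controls = list_controls(s)
        assert len(controls) == 2
        kinds = {c["kind"] for c in controls}
        assert kinds == {"entry", "threshold"}

    def test_control_count_matches_entries_plus_thresholds(self):
        s = load_scheme(str(default_scheme_path()))
        assert len(list_controls(s)) == len(s.entries) + len(s.thresholds)

    def test_defaults_via_overrides_reproduce_plain_scoring(self):
        s = load_scheme(str(default_scheme_path()))
        controls = list_controls(s)
        overrides = {
            "entries": {c["id"]: c["active"] for c in controls if c["kind"] == "entry"},
            "thresholds": {
                c["name"]: c["default"] for c in controls if c["kind"] == "threshold"
            },
        }
        rng = np.random.default_rng(5)
        for _ in range(20):
            row = _row(
                vaf=float(rng.uniform(0, 0.3)),
                depth=int(rng.integers(0, 2000)),
                mean_base_quality=float(rng.uniform(0, 40)),
                caller_flags={f"c{i}": bool(rng.random() < 0.5) for i in range(8)},
                annotations={
                    "dbsnp.id": "rs1" if rng.random() < 0.5 else "",
                    "dbsnp.PM": "1" if rng.random() < 0.5 else "",
                    "popfreq.AF": f"{rng.uniform(0, 0.1):.4f}" if rng.random() < 0.7 else "",
                    "cosmic.occurrence": str(rng.integers(0, 50)) if rng.random() < 0.4 else "",
                    "clinsig.significance": str(rng.choice(["", "benign", "pathogenic"])),
                },
            )
            a = score_variant(s, row)
            b = score_variant(s, row, overrides)
            assert (a.a_score, a.p_score) == (b.a_score, b.p_score)


def _random_structural_scheme(rng):
    """Random scheme of <= 4 entries with trees of depth <= 3."""
    columns = ["colA", "colB", "colC", "colD"]
    th_names = ["t1", "t2"]
    thresholds = {n: float(rng.uniform(-5, 5)) for n in th_names}

    def leaf():
        col = str(rng.choice(columns))
        kind = rng.integers(0, 4)
        if kind == 0:
            return Leaf("empty", col)
        if kind == 1:
            return Leaf("contains", col, value=str(rng.choice(["a", "b", "1", "x"])))
        if kind == 2:
            return Leaf("th_cmp", col, str(rng.choice(["<", "<=", ">", ">="])), threshold=str(rng.choice(th_names)))
        op = str(rng.choice(["<", "<=", ">", ">=", "==", "!="]))
        value = (
            round(float(rng.uniform(-5, 5)), 2)
            if rng.random() < 0.7
            else str(rng.choice(["a", "b", "zz"]))
        )
        return Leaf("cmp", col, op, value)

    def tree(depth):
        if depth == 0 or rng.random() < 0.35:
            return Tree(None, [leaf()])
        op = str(rng.choice(["AND", "OR"]))
        return Tree(op, [tree(depth - 1) for _ in range(int(rng.integers(2, 4)))])

    entries = []
    for i in range(int(rng.integers(1, 5))):
        aw = float(rng.choice([0.0, 1.0, 2.5]))
        pw = float(rng.choice([0.0, 1.0, 0.5]))
        if aw + pw == 0:
            aw = 1.0
        entries.append(
            StructuralEntry(f"e{i}", tree(3), aw, pw, active=bool(rng.random() < 0.9))
        )
    return entries, thresholds, columns


def _random_row_values(rng, columns):
    values = {}
    for c in columns:
        kind = rng.integers(0, 4)
        if kind == 0:
            values[c] = ""
        elif kind == 1:
            values[c] = str(round(float(rng.uniform(-6, 6)), 2))
        elif kind == 2:
            values[c] = str(rng.choice(["a", "b", "ab", "xyz", "1a"]))
        else:
            values[c] = str(int(rng.integers(-5, 6)))
    return values


class TestOracleEquivalence:
    def test_random_schemes_match_independent_evaluation(self):
        """Production parser+evaluator vs direct structural evaluation on
        1,000 random scheme/row pairs."""
        rng = np.random.default_rng(42)
        for trial in range(1000):
            entries, thresholds, columns = _random_structural_scheme(rng)
            scheme = parse_scheme(render_scheme(entries, thresholds))
            values = _random_row_values(rng, columns)
            row = _row(annotations=dict(values))
            got = score_variant(scheme, row)
            want_a, want_p = oracle_scores(entries, values, thresholds)
            assert (got.a_score, got.p_score) == (want_a, want_p), (
                trial,
                [e.tree.render() for e in entries],
                values,
            )

    def test_deactivation_changes_score_by_exactly_the_weight(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            entries, thresholds, columns = _random_structural_scheme(rng)
            entries = [
                StructuralEntry(e.id, e.tree, e.artifact_weight, e.polymorphism_weight, True)
                for e in entries
            ]
            scheme = parse_scheme(render_scheme(entries, thresholds))
            row = _row(annotations=_random_row_values(rng, columns))
            base = score_variant(scheme, row)
            for e in entries:
                off = score_variant(scheme, row, {"entries": {e.id: False}})
                delta_a = base.a_score - off.a_score
                delta_p = base.p_score - off.p_score
                assert delta_a in (0.0, e.artifact_weight)
                assert delta_p in (0.0, e.polymorphism_weight)
                # monotone: deactivating never increases a score
                assert off.a_score <= base.a_score
                assert off.p_score <= base.p_score

    def test_de_morgan_on_generated_leaves(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            _entries, thresholds, columns = _random_structural_scheme(rng)
            a = Leaf("cmp", str(rng.choice(columns)), ">", round(float(rng.uniform(-3, 3)), 2))
            b = Leaf("empty", str(rng.choice(columns)))
            row = _row(annotations=_random_row_values(rng, columns))
            conj = eval_expr(f"{a.render()} and {b.render()}", row, thresholds)
            neg_disj = eval_expr(
                f"not (not ({a.render()}) or not ({b.render()}))", row, thresholds
            )
            assert conj == neg_disj

    def test_threshold_sweep_is_piecewise_constant(self):
        """Scores change only when the threshold crosses an observed value."""
        doc = json.loads(json.dumps(MINIMAL))
        doc["thresholds"]["minVAF"] = {"default": 0.02, "min": 0.0, "max": 1.0}
        scheme = parse_scheme(doc)
        row = _row(vaf=0.25)
        fired = [
            score_variant(scheme, row, {"thresholds": {"minVAF": th}}).a_score
            for th in [0.0, 0.1, 0.2, 0.25, 0.2500001, 0.3, 1.0]
        ]
        assert fired == [0, 0, 0, 0, 1, 1, 1]
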