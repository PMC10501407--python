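"""Karva decoding, tree evaluation, genetic operators, and the published
nonlinear equation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glioqsar.gep import (
    DEFAULT_FUNCTIONS,
    PUBLISHED_GEP_EQUATION,
    UNDEFINED,

    ExpressionTree,
    GepConfig,
    ParseError,
    decode_chromosome,
    decode_gene,
    evaluate_tree,
    evaluate_tree_rows,
    evolve,
    fitness,
    make_chromosome,
    parse_expression,
    published_gep_model,
    to_infix,
)


def oracle_eval(text: str, bindings: dict) -> float:
    """Independent evaluation path: Python's own parser/arithmetic on the
    infix string (conventional precedence)."""
    env = dict(bindings)
    env["sin"] = math.sin
    env["inv"] = lambda v: 1.0 / v
    return eval(text, {"__builtins__": {}}, env)  # noqa: S307 - test oracle


class TestDecode:
    def test_level_order_example(self):
        tree = decode_gene("+*aab")
        assert to_infix(tree) == "a * b + a"
        assert evaluate_tree(tree, {"a": 2.0, "b": 3.0}) == 8.0

    def test_root_terminal_is_identity(self):
        tree = decode_gene("abbaa")
        assert tree.is_terminal
        assert evaluate_tree(tree, {"a": 7.0, "b": 0.0}) == 7.0

    def test_tail_length_formula(self):
        c = make_chromosome(["+*aabbb"], head_length=3, terminals="ab")
        assert c.tail_length == 4  # h*(a_max-1)+1 with a_max=2
        assert len(c.genes[0]) == 7

    def test_unused_tail_ignored(self):
        a = decode_gene("+abbbbb")
        b = decode_gene("+abaaaa")
        assert a == b

    def test_tail_function_symbol_rejected(self):
        with pytest.raises(ValueError, match="tail"):
            make_chromosome(["+ab+abb"], head_length=3, terminals="ab")

    def test_wrong_gene_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            make_chromosome(["+ab"], head_length=3, terminals="ab")

    def test_multigene_joined_by_linker(self):
        c = make_chromosome(["aabbbbb", "babbbbb"], head_length=3,
                            terminals="ab", linker="+")
        tree = decode_chromosome(c)
        assert evaluate_tree(tree, {"a": 2.0, "b": 5.0}) == 7.0


class TestEvaluate:
    def test_division_guard_propagates(self):
        tree = parse_expression("1/(a - b) + a")
        assert evaluate_tree(tree, {"a": 1.0, "b": 1.0}) is UNDEFINED

    def test_unbound_terminal_errors(self):
        with pytest.raises(KeyError, match="b"):
            evaluate_tree(parse_expression("a + b"), {"a": 1.0})

    def test_vectorized_rows_match_scalar(self, rng):
        tree = parse_expression("sin(a) * b - inv(b)")
        a, b = rng.normal(size=20), rng.normal(size=20) + 3.0
        rows = evaluate_tree_rows(tree, {"a": a, "b": b})
        for i in range(20):
            assert rows[i] == pytest.approx(
                evaluate_tree(tree, {"a": a[i], "b": b[i]}), rel=1e-12
            )

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_matches_python_arithmetic(self, a, b):
        text = "a * b - sin(a) + a / (b * b + 1.5)"
        tree = parse_expression(text)
        got = evaluate_tree(tree, {"a": a, "b": b})
        assert got == pytest.approx(oracle_eval(text, {"a": a, "b": b}),
                                    rel=1e-12, abs=1e-12)


class TestPublishedEquation:
    def test_uses_exactly_the_six_descriptors(self):
        tree = published_gep_model()
        assert tree.terminals() == {"TEIZP", "NFA", "MECN", "MRCH", "MCIHN",
                                    "ZXS"}

    def test_agrees_with_independent_evaluator(self, rng):
        tree = published_gep_model()
        checked = 0
        for _ in range(100):
            b = {t: float(v) for t, v in zip(
                ("TEIZP", "NFA", "MECN", "MRCH", "MCIHN", "ZXS"),
                rng.uniform(0.5, 3.0, size=6),
            )}
            try:
                want = oracle_eval(PUBLISHED_GEP_EQUATION, b)
            except ZeroDivisionError:
                continue
            got = evaluate_tree(tree, b)
            assert got == pytest.approx(want, abs=1e-10)
            checked += 1
        assert checked >= 95

    def test_reference_point(self):
        # fixed before the build with the independent evaluator
        b = dict(TEIZP=2.0, NFA=1.0, MECN=5.0, MRCH=1.0, MCIHN=0.5, ZXS=1.0)
        assert evaluate_tree(published_gep_model(), b) == pytest.approx(
            2.9111314678, abs=1e-9
        )

    def test_self_cancelling_term_contributes_zero(self, rng):
        # MECN appears only inside (MECN - MECN): the whole equation is
        # constant in MECN
        tree = published_gep_model()
        b = {t: float(v) for t, v in zip(
            ("TEIZP", "NFA", "MECN", "MRCH", "MCIHN", "ZXS"),
            rng.uniform(0.5, 3.0, size=6),
        )}
        v1 = evaluate_tree(tree, b)
        v2 = evaluate_tree(tree, dict(b, MECN=b["MECN"] + 123.0))
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_equal_teizp_nfa_is_undefined(self):
        b = dict(TEIZP=1.7, NFA=1.7, MECN=1.0, MRCH=2.0, MCIHN=0.5, ZXS=1.0)
        assert evaluate_tree(published_gep_model(), b) is UNDEFINED


class TestParse:
    def test_roundtrip_print_parse(self, rng):
        for text in (
            PUBLISHED_GEP_EQUATION,
            "a - b - c",
            "a / b / c * (d + e)",
            "sin(inv(a)) * -(b)",
        ):
            tree = parse_expression(text)
            assert parse_expression(to_infix(tree)) == tree

    def test_left_associativity(self):
        tree = parse_expression("a / b * c")
        assert evaluate_tree(tree, {"a": 8.0, "b": 2.0, "c": 3.0}) == 12.0
        tree = parse_expression("a - b - c")
        assert evaluate_tree(tree, {"a": 10.0, "b": 3.0, "c": 2.0}) == 5.0

    def test_error_carries_position(self):
        with pytest.raises(ParseError, match="position"):
            parse_expression("a + (b * ")
        with pytest.raises(ParseError):
            parse_expression("foo(a)")  # unknown function


class TestFitness:
    def test_exact_expression_scores_one(self, rng):
        tree = parse_expression("a + sin(b)")
        a, b = rng.normal(size=30), rng.normal(size=30)
        y = a + np.sin(b)
        assert fitness(tree, {"a": a, "b": b}, y) == pytest.approx(1.0)

    def test_constant_tree_scores_zero(self, rng):
        tree = ExpressionTree(2.5)
        y = rng.normal(size=20)
        assert fitness(tree, {"a": rng.normal(size=20)}, y) == 0.0

    def test_sign_flip_scores_strictly_below_truth(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        y = a + np.sin(b)
        X = {"a": a, "b": b}
        good = fitness(parse_expression("a + sin(b)"), X, y)
        flipped = fitness(parse_expression("a - sin(b)"), X, y)
        assert flipped < good

    def test_undefined_prediction_scores_zero(self, rng):
        a = rng.normal(size=10)
        a[4] = 0.0
        tree = parse_expression("inv(a)")
        assert fitness(tree, {"a": a}, rng.normal(size=10)) == 0.0


def _random_genome_symbols(rng, h, terminals):
    fs = DEFAULT_FUNCTIONS
    t = h * (fs.max_arity - 1) + 1
    head_pool = fs.symbols + list(terminals)
    head = [head_pool[rng.integers(len(head_pool))] for _ in range(h)]
    tail = [terminals[rng.integers(len(terminals))] for _ in range(t)]
    return head + tail


class TestOperatorsPreserveValidity:
    """Every genetic operator must map valid chromosomes to valid
    chromosomes (tail purity, length)."""

    @given(st.integers(0, 500))
    def test_operator_closure(self, seed):
        from glioqsar.gep import (
            _Genome,
            _gene_recombine,
            _gene_transpose,
            _is_transpose,
            _mutate,
            _one_point_recombine,
            _ris_transpose,
            _two_point_recombine,
        )

        rng = np.random.default_rng(seed)
        cfg = GepConfig(population_size=4, n_genes=2, head_length=5,
                        mutation_rate=0.3, seed=seed)
        terminals = ["a", "b"]
        g1 = _Genome([_random_genome_symbols(rng, 5, terminals)
                      for _ in range(2)])
        g2 = _Genome([_random_genome_symbols(rng, 5, terminals)
                      for _ in range(2)])
        _mutate(g1, rng, cfg, terminals)
        _is_transpose(g1, rng, cfg)
        _ris_transpose(g1, rng, cfg)
        _gene_transpose(g1, rng)
        _one_point_recombine(g1, g2, rng)
        _two_point_recombine(g1, g2, rng)
        _gene_recombine(g1, g2, rng)
        for g in (g1, g2):
            # construction re-validates all invariants
            c = make_chromosome(g.genes, head_length=5, terminals=terminals)
            decode_chromosome(c)  # decoding total on valid chromosomes


class TestEvolve:
    def test_seeded_exact_solution_found_at_generation_zero(self, rng):
        a, b = rng.normal(size=25), rng.normal(size=25)
        y = a + np.sin(b)
        h, fs = 4, DEFAULT_FUNCTIONS
        t = h * (fs.max_arity - 1) + 1
        solution = make_chromosome(
            [["+", "a", "sin", "b"][:h] + ["a"] * t],
            head_length=h, terminals=["a", "b"],
        )
        res = evolve({"a": a, "b": b}, y,
                     GepConfig(population_size=10, generations=5, n_genes=1,
                               head_length=h, seed=0),
                     initial_population=[solution])
        assert res.best_fitness == pytest.approx(1.0)
        assert res.generations_run == 0

    def test_same_seed_identical_result(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        y = a * b
        cfg = GepConfig(population_size=30, generations=10, seed=5)
        r1 = evolve({"a": a, "b": b}, y, cfg)
        r2 = evolve({"a": a, "b": b}, y, cfg)
        assert r1.best_chromosome == r2.best_chromosome
        assert r1.history == r2.history

    def test_best_so_far_nondecreasing_under_elitism(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        y = a + np.sin(b) + 0.3 * rng.normal(size=20)
        res = evolve({"a": a, "b": b}, y,
                     GepConfig(population_size=40, generations=25, seed=3))
        hist = res.history
        assert all(later >= earlier for earlier, later in zip(hist, hist[1:]))

    def test_terminal_only_population_picks_best_terminal(self, rng):
        cols = {n: rng.normal(size=30) for n in ("a", "b", "c")}
        y = cols["b"] + 0.05 * rng.normal(size=30)
        h, t = 3, 3 * (2 - 1) + 1
        pop = [
            make_chromosome([[n] * (h + t)], head_length=h,
                            terminals=["a", "b", "c"])
            for n in ("a", "b", "c")
        ]
        res = evolve(cols, y,
                     GepConfig(population_size=3, generations=0, n_genes=1,
                               head_length=h, seed=0),
                     initial_population=pop)
        best_terminal = max("abc", key=lambda n: fitness(
            ExpressionTree(n), cols, y))
        assert res.best_tree == ExpressionTree(best_terminal)

    def test_recovers_additive_sine_law(self, rng):
        a = rng.uniform(-2, 2, 50)
        b = rng.uniform(-3, 3, 50)
        y = a + np.sin(b)
        res = evolve({"a": a, "b": b}, y,
                     GepConfig(population_size=500, generations=200,
                               n_genes=2, head_length=6, seed=1,
                               fitness_target=0.999))
        assert res.best_fitness >= 0.99


def test_config_validation():
    with pytest.raises(ValueError):
        GepConfig(population_size=1)
    with pytest.raises(ValueError):
        GepConfig(mutation_rate=1.5)
    with pytest.raises(ValueError):
        GepConfig(elitism=50, population_size=50)
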