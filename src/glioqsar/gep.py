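"""Gene expression programming (GEP) symbolic regression.

GEP evolves fixed-length linear genomes (Karva strings) that decode
breadth-first into expression trees.  Each gene has a function-bearing head
of length h and a terminal-only tail of length t = h·(a_max − 1) + 1, which
guarantees every genome decodes to a valid tree; multigenic chromosomes are
joined by a linking operator.  The population loop is: evaluate fitness,
check termination, copy elites, roulette-select, then apply mutation,
IS/RIS/gene transposition and one-point/two-point/gene recombination.

Arithmetic follows an explicit UNDEFINED contract: division (or ``inv``)
by a near-zero denominator is undefined and propagates to the root, and any
undefined prediction zeroes the fitness of the individual — pathological
denominators are never rewarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

DIV_EPS = 1e-12


class _Undefined:
    """Singleton result of arithmetic outside the defined domain."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"


UNDEFINED = _Undefined()


@dataclass(frozen=True)
class FunctionSet:
    """Mapping of operator symbol -> (arity, sampling weight)."""

    entries: Mapping[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "+": (2, 1.0),
            "-": (2, 1.0),
            "*": (2, 1.0),
            "/": (2, 1.0),
            "inv": (1, 1.0),
            "sin": (1, 1.0),
        }
    )

    def __post_init__(self) -> None:
        for sym, (arity, weight) in self.entries.items():
            if arity < 1:
                raise ValueError(f"arity of {sym!r} must be >= 1")
            if weight <= 0:
                raise ValueError(f"weight of {sym!r} must be > 0")

    @property
    def symbols(self) -> list[str]:
        return list(self.entries)

    @property
    def max_arity(self) -> int:
        return max(a for a, _ in self.entries.values())

    def arity(self, sym: str) -> int:
        return self.entries[sym][0]

    def weights(self) -> np.ndarray:
        w = np.array([wt for _, wt in self.entries.values()], dtype=float)
        return w / w.sum()


DEFAULT_FUNCTIONS = FunctionSet()

#: with natural log enabled behind the "Inx = ln" reading of the inverse slot
LN_FUNCTIONS = FunctionSet(
    entries={
        "+": (2, 1.0),
        "-": (2, 1.0),
        "*": (2, 1.0),
        "/": (2, 1.0),
        "ln": (1, 1.0),
        "sin": (1, 1.0),
    }
)


# ---------------------------------------------------------------------------
# Expression trees


@dataclass(frozen=True)
class ExpressionTree:
    """Operator/terminal tree; ``symbol`` is an operator name, a terminal
    (descriptor) name, or a float constant."""

    symbol: str | float
    children: tuple["ExpressionTree", ...] = ()

    @property
    def is_terminal(self) -> bool:
        return not self.children

    def terminals(self) -> set[str]:
        """Distinct variable terminals (constants excluded)."""
        if self.is_terminal:
            return {self.symbol} if isinstance(self.symbol, str) else set()
        out: set[str] = set()
        for c in self.children:
            out |= c.terminals()
        return out

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def __str__(self) -> str:
        return to_infix(self)


_UNARY_FUNCS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sin": np.sin,
    "cos": np.cos,
    "ln": np.log,
    "exp": np.exp,
    "sqrt": np.sqrt,
}


def _eval_array(tree: ExpressionTree, bindings: Mapping[str, np.ndarray]) -> np.ndarray:
    sym = tree.symbol
    if tree.is_terminal:
        if isinstance(sym, str):
            if sym not in bindings:
                raise KeyError(f"unbound terminal {sym!r}")
            return np.asarray(bindings[sym], dtype=float)
        return np.asarray(float(sym))
    with np.errstate(all="ignore"):
        if sym == "+":
            a = _eval_array(tree.children[0], bindings)
            b = _eval_array(tree.children[1], bindings)
            return a + b
        if sym == "-":
            a = _eval_array(tree.children[0], bindings)
            b = _eval_array(tree.children[1], bindings)
            return a - b
        if sym == "*":
            a = _eval_array(tree.children[0], bindings)
            b = _eval_array(tree.children[1], bindings)
            return a * b
        if sym == "/":
            a = _eval_array(tree.children[0], bindings)
            b = _eval_array(tree.children[1], bindings)
            return np.where(np.abs(b) < DIV_EPS, np.nan, a) / np.where(
                np.abs(b) < DIV_EPS, np.nan, b
            )
        if sym == "inv":
            b = _eval_array(tree.children[0], bindings)
            return 1.0 / np.where(np.abs(b) < DIV_EPS, np.nan, b)
        if sym == "neg":
            return -_eval_array(tree.children[0], bindings)
        if sym in _UNARY_FUNCS:
            return _UNARY_FUNCS[sym](_eval_array(tree.children[0], bindings))
    raise ValueError(f"unknown operator {sym!r}")


def evaluate_tree(tree: ExpressionTree, bindings: Mapping[str, float]):
    """Evaluate a tree at a single binding; returns a float or UNDEFINED.

    Division or ``inv`` with |denominator| < 1e-12 yields UNDEFINED, which
    propagates to the root (as do any non-finite intermediates).
    """
    out = _eval_array(tree, {k: np.asarray(v, dtype=float) for k, v in bindings.items()})
    val = float(out)
    return val if math.isfinite(val) else UNDEFINED


def evaluate_tree_rows(
    tree: ExpressionTree, columns: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Vectorized evaluation over sample rows; undefined rows come back NaN."""
    n = len(next(iter(columns.values())))
    out = _eval_array(tree, columns)
    out = np.asarray(out, dtype=float)
    if out.ndim == 0:
        out = np.full(n, float(out))
    out[~np.isfinite(out)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Karva genomes


@dataclass(frozen=True)
class Chromosome:
    """Fixed-length linear genome: one or more Karva genes.

    Each gene is a tuple of symbols of length ``head_length + tail_length``
    with terminals-only tails; genes are decoded independently and linked by
    ``linker``.
    """

    genes: tuple[tuple[str, ...], ...]
    head_length: int
    terminals: tuple[str, ...]
    function_set: FunctionSet = DEFAULT_FUNCTIONS
    linker: str = "+"

    def __post_init__(self) -> None:
        h = self.head_length
        t = self.tail_length
        fset = set(self.function_set.symbols)
        tset = set(self.terminals)
        for g, gene in enumerate(self.genes):
            if len(gene) != h + t:
                raise ValueError(
                    f"gene {g} length {len(gene)} != head+tail {h + t}"
                )
            for i, sym in enumerate(gene):
                if i < h:
                    if sym not in fset and sym not in tset:
                        raise ValueError(f"gene {g} head symbol {sym!r} unknown")
                elif sym not in tset:
                    raise ValueError(
                        f"gene {g} tail position {i} holds non-terminal {sym!r}"
                    )
        if len(self.genes) > 1 and self.function_set.arity(self.linker) != 2:
            raise ValueError("linker must be a binary operator")

    @property
    def tail_length(self) -> int:
        return self.head_length * (self.function_set.max_arity - 1) + 1

    def flat(self) -> tuple[str, ...]:
        return tuple(s for gene in self.genes for s in gene)


def _gene_from_str(gene: str | Sequence[str]) -> tuple[str, ...]:
    return tuple(gene) if not isinstance(gene, str) else tuple(gene)


def make_chromosome(
    genes: Sequence[str | Sequence[str]],
    head_length: int,
    terminals: Sequence[str],
    function_set: FunctionSet = DEFAULT_FUNCTIONS,
    linker: str = "+",
) -> Chromosome:
    """Build a chromosome from gene strings (one char per symbol) or symbol
    sequences."""
    return Chromosome(
        genes=tuple(_gene_from_str(g) for g in genes),
        head_length=head_length,
        terminals=tuple(terminals),
        function_set=function_set,
        linker=linker,
    )


def decode_gene(
    symbols: Sequence[str], function_set: FunctionSet = DEFAULT_FUNCTIONS
) -> ExpressionTree:
    """Breadth-first (Karva) decoding: symbols fill tree levels left to
    right; trailing unused symbols are ignored."""
    syms = list(symbols)
    if not syms:
        raise ValueError("empty gene")
    arities = function_set.entries

    def arity(s: str) -> int:
        return arities[s][0] if s in arities else 0

    pos = 1
    root_children: dict[int, list] = {}
    # build as nested lists first, then freeze
    nodes = [[syms[0], []]]
    level = [nodes[0]]
    while level:
        nxt = []
        for node in level:
            need = arity(node[0])
            for _ in range(need):
                if pos >= len(syms):
                    raise ValueError("gene exhausted before tree completed")
                child = [syms[pos], []]
                pos += 1
                node[1].append(child)
                nxt.append(child)
        level = nxt

    def freeze(nl) -> ExpressionTree:
        return ExpressionTree(nl[0], tuple(freeze(c) for c in nl[1]))

    return freeze(nodes[0])


def decode_chromosome(c: Chromosome) -> ExpressionTree:
    """Decode every gene and join multigene chromosomes with the linker."""
    trees = [decode_gene(g, c.function_set) for g in c.genes]
    out = trees[0]
    for t in trees[1:]:
        out = ExpressionTree(c.linker, (out, t))
    return out


# ---------------------------------------------------------------------------
# Fitness


def fitness(
    tree: ExpressionTree,
    X: Mapping[str, np.ndarray],
    y: np.ndarray,
) -> float:
    """Coefficient of determination of the tree's predictions vs y.

    ``max(0, 1 - RSS/TSS)``; any undefined prediction, or a degenerate
    (zero-variance) response, scores 0.  A correlation-based score is *not*
    used: a sign-flipped expression must score strictly below the true one.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    pred = evaluate_tree_rows(tree, X)
    if np.isnan(pred).any():
        return 0.0
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        return 0.0
    rss = float(np.sum((y - pred) ** 2))
    return max(0.0, 1.0 - rss / tss)


# ---------------------------------------------------------------------------
# Evolution loop


@dataclass(frozen=True)
class GepConfig:
    """Evolution settings.  Rate defaults follow common GEP practice;
    everything is configurable."""

    population_size: int = 50
    generations: int = 200
    fitness_target: float = 1.0 - 1e-9
    elitism: int = 1
    n_genes: int = 3
    head_length: int = 8
    linker: str = "+"
    mutation_rate: float = 0.044
    is_transposition_rate: float = 0.1
    ris_transposition_rate: float = 0.1
    gene_transposition_rate: float = 0.1
    one_point_recombination_rate: float = 0.3
    two_point_recombination_rate: float = 0.3
    gene_recombination_rate: float = 0.1
    max_transposon_length: int = 3
    function_set: FunctionSet = DEFAULT_FUNCTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must be in [0, population)")
        for nm in (
            "mutation_rate",
            "is_transposition_rate",
            "ris_transposition_rate",
            "gene_transposition_rate",
            "one_point_recombination_rate",
            "two_point_recombination_rate",
            "gene_recombination_rate",
        ):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ValueError(f"{nm} must be in [0,1], got {v}")


@dataclass
class GepResult:
    best_tree: ExpressionTree
    best_chromosome: Chromosome
    best_fitness: float
    history: list[float]  # best-so-far fitness per generation
    generations_run: int
    train_r2: float
    holdout_r2: float | None = None


class _Genome:
    """Mutable working copy of a chromosome during evolution."""

    __slots__ = ("genes",)

    def __init__(self, genes: list[list[str]]):
        self.genes = genes

    def copy(self) -> "_Genome":
        return _Genome([list(g) for g in self.genes])

    def key(self) -> tuple:
        return tuple(tuple(g) for g in self.genes)


def _random_genome(
    rng: np.random.Generator,
    cfg: GepConfig,
    terminals: Sequence[str],
) -> _Genome:
    fs = cfg.function_set
    h = cfg.head_length
    t = h * (fs.max_arity - 1) + 1
    fsyms = fs.symbols
    head_pool = fsyms + list(terminals)
    genes = []
    for _ in range(cfg.n_genes):
        head = [head_pool[rng.integers(len(head_pool))] for _ in range(h)]
        tail = [terminals[rng.integers(len(terminals))] for _ in range(t)]
        genes.append(head + tail)
    return _Genome(genes)


def _mutate(g: _Genome, rng, cfg: GepConfig, terminals: Sequence[str]) -> None:
    fs = cfg.function_set
    h = cfg.head_length
    head_pool = fs.symbols + list(terminals)
    for gene in g.genes:
        for i in range(len(gene)):
            if rng.random() < cfg.mutation_rate:
                pool = head_pool if i < h else terminals
                gene[i] = pool[int(rng.integers(len(pool)))]


def _is_transpose(g: _Genome, rng, cfg: GepConfig) -> None:
    # insertion-sequence transposition: copy a short fragment into the head
    # (never at the root); head is truncated back to length h
    h = cfg.head_length
    if h < 2:
        return
    flat = [s for gene in g.genes for s in gene]
    L = int(rng.integers(1, cfg.max_transposon_length + 1))
    start = int(rng.integers(0, len(flat) - L + 1))
    fragment = flat[start : start + L]
    gi = int(rng.integers(len(g.genes)))
    target = int(rng.integers(1, h))
    gene = g.genes[gi]
    new_head = gene[:target] + fragment + gene[target:h]
    g.genes[gi] = new_head[:h] + gene[h:]


def _ris_transpose(g: _Genome, rng, cfg: GepConfig) -> None:
    # root-insertion transposition: a fragment starting at a function symbol
    # in the head is copied to the gene's root
    fs = set(cfg.function_set.symbols)
    h = cfg.head_length
    gi = int(rng.integers(len(g.genes)))
    gene = g.genes[gi]
    starts = [i for i in range(h) if gene[i] in fs]
    if not starts:
        return
    start = starts[int(rng.integers(len(starts)))]
    L = int(rng.integers(1, min(cfg.max_transposon_length, h - start) + 1))
    fragment = gene[start : start + L]
    new_head = fragment + gene[:h]
    g.genes[gi] = new_head[:h] + gene[h:]


def _gene_transpose(g: _Genome, rng) -> None:
    if len(g.genes) < 2:
        return
    gi = int(rng.integers(1, len(g.genes)))
    gene = g.genes.pop(gi)
    g.genes.insert(0, gene)


def _one_point_recombine(a: _Genome, b: _Genome, rng) -> None:
    fa = [s for gene in a.genes for s in gene]
    fb = [s for gene in b.genes for s in gene]
    point = int(rng.integers(1, len(fa)))
    fa2 = fa[:point] + fb[point:]
    fb2 = fb[:point] + fa[point:]
    _unflatten(a, fa2)
    _unflatten(b, fb2)


def _two_point_recombine(a: _Genome, b: _Genome, rng) -> None:
    fa = [s for gene in a.genes for s in gene]
    fb = [s for gene in b.genes for s in gene]
    i, j = sorted(rng.choice(len(fa), size=2, replace=False).tolist())
    fa2 = fa[:i] + fb[i:j] + fa[j:]
    fb2 = fb[:i] + fa[i:j] + fb[j:]
    _unflatten(a, fa2)
    _unflatten(b, fb2)


def _gene_recombine(a: _Genome, b: _Genome, rng) -> None:
    gi = int(rng.integers(len(a.genes)))
    a.genes[gi], b.genes[gi] = b.genes[gi], a.genes[gi]


def _unflatten(g: _Genome, flat: list[str]) -> None:
    glen = len(g.genes[0])
    g.genes = [flat[i * glen : (i + 1) * glen] for i in range(len(g.genes))]


def _to_chromosome(g: _Genome, cfg: GepConfig, terminals: Sequence[str]) -> Chromosome:
    return Chromosome(
        genes=tuple(tuple(gene) for gene in g.genes),
        head_length=cfg.head_length,
        terminals=tuple(terminals),
        function_set=cfg.function_set,
        linker=cfg.linker,
    )


def evolve(
    X: Mapping[str, np.ndarray],
    y: np.ndarray,
    config: GepConfig,
    X_holdout: Mapping[str, np.ndarray] | None = None,
    y_holdout: np.ndarray | None = None,
    initial_population: Sequence[Chromosome] | None = None,
) -> GepResult:
    """Run the GEP loop and return the best individual found.

    ``X`` maps terminal (descriptor) names to value columns.  The loop is
    fully deterministic per ``config.seed``.  ``initial_population`` may seed
    the first generation (padded with random genomes if short).
    """
    terminals = sorted(X)
    if not terminals:
        raise ValueError("X must supply at least one descriptor column")
    y = np.asarray(y, dtype=float)
    cols = {k: np.asarray(v, dtype=float) for k, v in X.items()}
    rng = np.random.default_rng(config.seed)

    pop: list[_Genome] = []
    if initial_population:
        for c in initial_population[: config.population_size]:
            pop.append(_Genome([list(g) for g in c.genes]))
    while len(pop) < config.population_size:
        pop.append(_random_genome(rng, config, terminals))

    cache: dict[tuple, float] = {}

    def fit_of(g: _Genome) -> float:
        key = g.key()
        if key not in cache:
            tree = decode_chromosome(_to_chromosome(g, config, terminals))
            cache[key] = fitness(tree, cols, y)
        return cache[key]

    best_g: _Genome | None = None
    best_f = -1.0
    history: list[float] = []
    gen = 0
    for gen in range(config.generations + 1):
        fits = np.array([fit_of(g) for g in pop])
        top = int(np.argmax(fits))
        if fits[top] > best_f:
            best_f = float(fits[top])
            best_g = pop[top].copy()
        history.append(best_f)
        if best_f >= config.fitness_target or gen == config.generations:
            break
        # elite-preserving roulette selection
        order = np.argsort(-fits, kind="stable")
        elites = [pop[i].copy() for i in order[: config.elitism]]
        n_select = config.population_size - config.elitism
        total = fits.sum()
        probs = fits / total if total > 0 else np.full(len(pop), 1 / len(pop))
        chosen = rng.choice(len(pop), size=n_select, replace=True, p=probs)
        offspring = [pop[i].copy() for i in chosen]
        for g in offspring:
            _mutate(g, rng, config, terminals)
            if rng.random() < config.is_transposition_rate:
                _is_transpose(g, rng, config)
            if rng.random() < config.ris_transposition_rate:
                _ris_transpose(g, rng, config)
            if rng.random() < config.gene_transposition_rate:
                _gene_transpose(g, rng)
        for i in range(0, len(offspring) - 1, 2):
            a, b = offspring[i], offspring[i + 1]
            if rng.random() < config.one_point_recombination_rate:
                _one_point_recombine(a, b, rng)
            if rng.random() < config.two_point_recombination_rate:
                _two_point_recombine(a, b, rng)
            if rng.random() < config.gene_recombination_rate:
                _gene_recombine(a, b, rng)
        pop = elites + offspring

    assert best_g is not None
    best_chrom = _to_chromosome(best_g, config, terminals)
    best_tree = decode_chromosome(best_chrom)
    holdout_r2 = None
    if X_holdout is not None and y_holdout is not None:
        holdout_r2 = fitness(
            best_tree,
            {k: np.asarray(v, dtype=float) for k, v in X_holdout.items()},
            np.asarray(y_holdout, dtype=float),
        )
    return GepResult(
        best_tree=best_tree,
        best_chromosome=best_chrom,
        best_fitness=best_f,
        history=history,
        generations_run=gen,
        train_r2=best_f,
        holdout_r2=holdout_r2,
    )


# ---------------------------------------------------------------------------
# Infix parsing / printing


class ParseError(ValueError):
    def __init__(self, msg: str, pos: int):
        super().__init__(f"{msg} at position {pos}")
        self.pos = pos


_UNARY_NAMES = {"sin", "cos", "inv", "ln", "exp", "sqrt", "neg"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "+-*/()":
            tokens.append(("op", ch, i))
            i += 1
        elif ch.isdigit() or ch == ".":
            j = i
            while j < len(text) and (text[j].isdigit() or text[j] in ".eE" or
                                     (text[j] in "+-" and text[j - 1] in "eE")):
                j += 1
            tokens.append(("num", text[i:j], i))
            i = j
        elif ch.isalpha() or ch == "_":
            j = i
            while j < len(text) and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(("name", text[i:j], i))
            i = j
        else:
            raise ParseError(f"unexpected character {ch!r}", i)
    return tokens


def parse_expression(text: str) -> ExpressionTree:
    """Parse a parenthesized infix expression into an :class:`ExpressionTree`.

    Conventional precedence: unary functions bind tightest, then ``*``/``/``
    (left-associative), then ``+``/``-`` (left-associative).  Numeric
    literals become constant leaves.  Malformed text raises
    :class:`ParseError` carrying the character position.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None, len(text))

    def expect(val: str):
        nonlocal pos
        kind, v, at = peek()
        if v != val:
            raise ParseError(f"expected {val!r}, found {v!r}", at)
        pos += 1

    def parse_expr() -> ExpressionTree:
        nonlocal pos
        node = parse_term()
        while peek()[1] in ("+", "-"):
            op = peek()[1]
            pos += 1
            node = ExpressionTree(op, (node, parse_term()))
        return node

    def parse_term() -> ExpressionTree:
        nonlocal pos
        node = parse_factor()
        while peek()[1] in ("*", "/"):
            op = peek()[1]
            pos += 1
            node = ExpressionTree(op, (node, parse_factor()))
        return node

    def parse_factor() -> ExpressionTree:
        nonlocal pos
        kind, v, at = peek()
        if v == "-":
            pos += 1
            return ExpressionTree("neg", (parse_factor(),))
        if v == "(":
            pos += 1
            node = parse_expr()
            expect(")")
            return node
        if kind == "num":
            pos += 1
            return ExpressionTree(float(v))
        if kind == "name":
            pos += 1
            if peek()[1] == "(":
                if v not in _UNARY_NAMES:
                    raise ParseError(f"unknown function {v!r}", at)
                pos += 1
                arg = parse_expr()
                expect(")")
                return ExpressionTree(v, (arg,))
            return ExpressionTree(v)
        raise ParseError(f"unexpected token {v!r}", at)

    tree = parse_expr()
    if pos != len(tokens):
        raise ParseError(f"trailing input {tokens[pos][1]!r}", tokens[pos][2])
    return tree


_PREC = {"+": 1, "-": 1, "*": 2, "/": 2}


def to_infix(tree: ExpressionTree) -> str:
    """Render a tree as parenthesized infix; ``parse_expression`` of the
    output reproduces the tree exactly."""
    sym = tree.symbol
    if tree.is_terminal:
        return sym if isinstance(sym, str) else repr(float(sym))
    if sym in _PREC:
        lhs, rhs = tree.children
        lt = to_infix(lhs)
        rt = to_infix(rhs)
        if not lhs.is_terminal and lhs.symbol in _PREC and _PREC[lhs.symbol] < _PREC[sym]:
            lt = f"({lt})"
        if not rhs.is_terminal and rhs.symbol in _PREC and (
            _PREC[rhs.symbol] < _PREC[sym]
            or (_PREC[rhs.symbol] == _PREC[sym])  # -, / are not associative
        ):
            rt = f"({rt})"
        return f"{lt} {sym} {rt}"
    if sym == "neg":
        return f"-({to_infix(tree.children[0])})"
    return f"{sym}({to_infix(tree.children[0])})"


#: Transcription of the published GEP nonlinear activity model for the
#: dihydropteridone series, in the six selected descriptors.  The printed
#: self-cancelling (MECN - MECN) subterm is kept verbatim.
PUBLISHED_GEP_EQUATION = (
    "1/(TEIZP - NFA)"
    " + sin(sin(TEIZP) + (MECN - MECN))/(MRCH - MCIHN)*sin(MRCH)"
    " + ZXS*1/(MRCH*sin(ZXS)/ZXS + ZXS/TEIZP"
    " + sin(sin(sin(sin(MRCH)*sin(MCIHN)))))"
)


def published_gep_model() -> ExpressionTree:
    """Expression tree of the published nonlinear model (verbatim
    transcription; its reported train/test R² of 0.79/0.76 are metadata —
    the commercial descriptor values behind them are not available)."""
    return parse_expression(PUBLISHED_GEP_EQUATION)
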