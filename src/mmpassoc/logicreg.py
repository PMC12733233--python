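"""Logic regression for multi-locus SNP interactions.

Each SNP's 1/2/3 genotype code becomes two binary dummies: ``SNP_1`` (carries
at least one minor allele) and ``SNP_2`` (homozygous minor).  A logic tree --
a binary AND/OR tree over these dummies and their complements -- is fitted by
simulated annealing to minimise training misclassification, logicFS-style:
trees are fitted on bootstrap samples, each fitted tree is decomposed into
its prime implicants (the minimal Boolean conjunctions whose disjunction
reproduces the tree), and every prime implicant is an "interaction" scored by

* proportion: the fraction of bootstrap models whose tree contains it, and
* OOB importance: the mean drop in out-of-bag accuracy when it is removed
  from the models containing it.

Inference uses a permutation protocol: the whole bagging run is repeated on
the real labels and on freshly permuted labels, interactions are filtered by
mean proportion, and bootstrap percentile intervals of the OOB importance are
compared between the real and null arms.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeTable

# ---------------------------------------------------------------------------
# Dummy encoding
# ---------------------------------------------------------------------------

def binarize(g: GenotypeTable) -> tuple[np.ndarray, list[str], list[str]]:
    """Two binary dummies per SNP: code 1 -> (0,0), 2 -> (1,0), 3 -> (1,1).

    Rows with any missing code are excluded.  Returns (X, column names,
    retained sample ids); the encoding is a bijection on complete rows.
    """
    complete = ~np.isnan(g.codes).any(axis=1)
    codes = g.codes[complete].astype(int)
    samples = [s for s, keep in zip(g.samples, complete) if keep]
    cols, names = [], []
    for j, snp in enumerate(g.snps):
        cols.append(codes[:, j] >= 2)
        cols.append(codes[:, j] == 3)
        names.extend([f"{snp.id}_1", f"{snp.id}_2"])
    X = np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=bool)
    return X.astype(bool), names, samples


def decode(X: np.ndarray) -> np.ndarray:
    """Inverse of :func:`binarize`: dummy pairs back to 1/2/3 codes."""
    X = np.asarray(X, dtype=int)
    if X.shape[1] % 2:
        raise ValueError("dummy matrix must have an even number of columns")
    d1, d2 = X[:, 0::2], X[:, 1::2]
    if np.any((d2 == 1) & (d1 == 0)):
        raise ValueError("inconsistent dummy pair: SNP_2=1 with SNP_1=0")
    return 1 + d1 + d2


# ---------------------------------------------------------------------------
# Logic trees
# ---------------------------------------------------------------------------
# expr := ("leaf", var_index, complemented) | ("and"|"or", expr, expr)

def _eval_expr(expr, X: np.ndarray) -> np.ndarray:
    op = expr[0]
    if op == "leaf":
        col = X[:, expr[1]]
        return ~col if expr[2] else col
    left = _eval_expr(expr[1], X)
    right = _eval_expr(expr[2], X)
    return (left & right) if op == "and" else (left | right)


def _leaf_paths(expr, path=()):
    if expr[0] == "leaf":
        yield path
    else:
        yield from _leaf_paths(expr[1], path + (1,))
        yield from _leaf_paths(expr[2], path + (2,))


def _node_paths(expr, path=()):
    if expr[0] != "leaf":
        yield path
        yield from _node_paths(expr[1], path + (1,))
        yield from _node_paths(expr[2], path + (2,))


def _get(expr, path):
    for step in path:
        expr = expr[step]
    return expr


def _replace(expr, path, new):
    if not path:
        return new
    head, *rest = path
    parts = list(expr)
    parts[head] = _replace(parts[head], tuple(rest), new)
    return tuple(parts)


@dataclass(frozen=True)
class LogicTree:
    """An AND/OR tree over binary variables and their complements."""

    expr: tuple
    n_vars: int

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=bool)
        if X.shape[1] < self.n_vars:
            raise ValueError("row does not cover all tree variables")
        return _eval_expr(self.expr, X)

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in _leaf_paths(self.expr))

    def variables(self) -> list[int]:
        return sorted({_get(self.expr, p)[1] for p in _leaf_paths(self.expr)})

    def to_string(self, names: list[str] | None = None) -> str:
        def fmt(expr):
            if expr[0] == "leaf":
                name = names[expr[1]] if names else f"X{expr[1]}"
                return f"!{name}" if expr[2] else name
            sym = " & " if expr[0] == "and" else " | "
            return "(" + fmt(expr[1]) + sym + fmt(expr[2]) + ")"
        return fmt(self.expr)


# ---------------------------------------------------------------------------
# Prime implicants (Quine-McCluskey over the tree's support variables)
# ---------------------------------------------------------------------------

def prime_implicants(tree: LogicTree) -> list[tuple[tuple[int, bool], ...]]:
    """Prime implicants of the tree's Boolean function.

    Each implicant is a conjunction, returned as a sorted tuple of
    (variable index, complemented) literals.  A tautologous or contradictory
    tree yields no implicants.
    """
    support = tree.variables()
    k = len(support)
    assign = np.zeros((2 ** k, tree.n_vars), dtype=bool)
    for pos, var in enumerate(support):
        block = 2 ** (k - 1 - pos)
        assign[:, var] = (np.arange(2 ** k) // block) % 2 == 1
    truth = tree.evaluate(assign)
    minterms = [i for i in range(2 ** k) if truth[i]]
    if not minterms or len(minterms) == 2 ** k:
        return []

    # terms are (bits, care): variable fixed where the care bit is set
    full_care = (1 << k) - 1
    current = {(m, full_care) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        merged_away = set()
        nxt = set()
        terms = sorted(current)
        for i, (b1, c1) in enumerate(terms):
            for b2, c2 in terms[i + 1:]:
                if c1 != c2:
                    continue
                diff = b1 ^ b2
                if diff and not (diff & (diff - 1)):  # single differing bit
                    nxt.add((b1 & ~diff, c1 & ~diff))
                    merged_away.update({(b1, c1), (b2, c2)})
        primes |= current - merged_away
        current = nxt

    out = []
    for bits, care in primes:
        lits = []
        for pos, var in enumerate(support):
            bit = 1 << (k - 1 - pos)
            if care & bit:
                lits.append((var, not bool(bits & bit)))
        out.append(tuple(sorted(lits)))
    return sorted(set(out))


@dataclass(frozen=True)
class Interaction:
    """A Boolean conjunction over dummy variables (a prime implicant)."""

    literals: tuple[tuple[int, bool], ...]  # (variable index, complemented)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=bool)
        out = np.ones(len(X), dtype=bool)
        for var, neg in self.literals:
            out &= ~X[:, var] if neg else X[:, var]
        return out

    def to_string(self, names: list[str] | None = None) -> str:
        parts = []
        for var, neg in self.literals:
            name = names[var] if names else f"X{var}"
            parts.append(f"!{name}" if neg else name)
        return " & ".join(parts)

    @classmethod
    def from_string(cls, text: str, names: list[str]) -> "Interaction":
        lits = []
        for tok in re.split(r"\s*&\s*", text.strip()):
            neg = tok.startswith("!")
            name = tok[1:].strip() if neg else tok
            if name not in names:
                raise ValueError(f"unknown variable {name!r}")
            lits.append((names.index(name), neg))
        return cls(tuple(sorted(lits)))


# ---------------------------------------------------------------------------
# Simulated annealing fit
# ---------------------------------------------------------------------------

@dataclass
class LogicFSParams:
    """Bagging and annealing controls.

    The annealing schedule is geometric: ``moves_per_temp`` proposals at each
    temperature, cooled by ``cooling`` until the temperature has fallen by
    ``temp_span`` orders of magnitude.  The start temperature is calibrated so
    most uphill moves are accepted initially unless given explicitly.
    """

    n_bootstrap: int = 100
    max_leaves: int = 10
    start_temp: float | None = None
    cooling: float = 0.98
    moves_per_temp: int = 30
    temp_span: float = 4.0  # orders of magnitude from start to final temp
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")


def _random_leaf(rng, p):
    return ("leaf", int(rng.integers(p)), bool(rng.integers(2)))


def _propose(expr, rng, p, max_leaves):
    """One random structural move; returns a new expression tree."""
    leaves = list(_leaf_paths(expr))
    nodes = list(_node_paths(expr))
    moves = ["change_var", "toggle_neg"]
    if len(leaves) < max_leaves:
        moves.append("grow")
    if nodes:
        moves.extend(["prune", "change_op"])
    move = moves[int(rng.integers(len(moves)))]
    if move == "grow":
        path = leaves[int(rng.integers(len(leaves)))]
        op = "and" if rng.integers(2) else "or"
        return _replace(expr, path, (op, _get(expr, path), _random_leaf(rng, p)))
    if move == "prune":
        path = nodes[int(rng.integers(len(nodes)))]
        node = _get(expr, path)
        child = node[1 + int(rng.integers(2))]
        return _replace(expr, path, child)
    if move == "change_op":
        path = nodes[int(rng.integers(len(nodes)))]
        node = _get(expr, path)
        other = "or" if node[0] == "and" else "and"
        return _replace(expr, path, (other, node[1], node[2]))
    path = leaves[int(rng.integers(len(leaves)))]
    leaf = _get(expr, path)
    if move == "change_var":
        return _replace(expr, path, ("leaf", int(rng.integers(p)), leaf[2]))
    return _replace(expr, path, ("leaf", leaf[1], not leaf[2]))


def anneal_fit(
    X: np.ndarray,
    y: np.ndarray,
    params: LogicFSParams | None = None,
    seed: int | None = None,
) -> tuple[LogicTree, float]:
    """Fit one logic tree by simulated annealing.

    Minimises training misclassification of "predict class 1 where the tree
    is true".  Rows are collapsed to their distinct binary patterns first, so
    each proposal is scored on at most 2^p patterns.  Deterministic under a
    fixed seed.  Returns the best tree visited and its misclassification rate.
    """
    params = params or LogicFSParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    X = np.asarray(X, dtype=bool)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X and y must align")
    if y.min() == y.max():
        raise ValueError("outcome is constant")
    n, p = X.shape

    patterns, inverse = np.unique(X, axis=0, return_inverse=True)
    n1 = np.bincount(inverse[y == 1], minlength=len(patterns)).astype(float)
    n0 = np.bincount(inverse[y == 0], minlength=len(patterns)).astype(float)

    def errors(expr) -> float:
        pred = _eval_expr(expr, patterns)
        return float(n0[pred].sum() + n1[~pred].sum())

    # start from the best single literal
    best_expr, best_err = None, math.inf
    for var in range(p):
        for neg in (False, True):
            e = ("leaf", var, neg)
            err = errors(e)
            if err < best_err:
                best_expr, best_err = e, err
    expr, err = best_expr, best_err

    t0 = params.start_temp
    if t0 is None:
        # calibrate so a typical uphill move is accepted ~90% of the time
        deltas = []
        probe = expr
        for _ in range(30):
            cand = _propose(probe, rng, p, params.max_leaves)
            d = errors(cand) - errors(probe)
            if d > 0:
                deltas.append(d)
            probe = cand
        t0 = (float(np.median(deltas)) / math.log(1 / 0.9)) if deltas else 1.0
    n_temps = max(1, int(math.ceil(params.temp_span / -math.log10(params.cooling))))

    temp = t0
    for _ in range(n_temps):
        for _ in range(params.moves_per_temp):
            cand = _propose(expr, rng, p, params.max_leaves)
            cand_err = errors(cand)
            delta = cand_err - err
            if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-12)):
                expr, err = cand, cand_err
                if err < best_err:
                    best_expr, best_err = expr, err
        temp *= params.cooling
    return LogicTree(best_expr, p), best_err / n


# ---------------------------------------------------------------------------
# Bagged importance (logicFS)
# ---------------------------------------------------------------------------

def logic_fs(
    X: np.ndarray,
    y: np.ndarray,
    params: LogicFSParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """One bagging pass: bootstrap-fit trees and score their prime implicants.

    Returns a frame indexed by interaction (canonical literal tuple) with the
    proportion of bootstrap models containing it and its mean OOB importance
    (drop in out-of-bag accuracy when removed, over models containing it).
    """
    params = params or LogicFSParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    X = np.asarray(X, dtype=bool)
    y = np.asarray(y, dtype=int)
    n = len(y)

    counts: dict[tuple, int] = {}
    imp_sums: dict[tuple, float] = {}
    n_failed = 0
    for _ in range(params.n_bootstrap):
        idx = rng.integers(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        yb = y[idx]
        if yb.min() == yb.max() or not oob.any() or len(np.unique(y[oob])) < 1:
            n_failed += 1
            continue
        fit_seed = int(rng.integers(2 ** 31))
        try:
            tree, _ = anneal_fit(X[idx], yb, params, seed=fit_seed)
        except ValueError:
            n_failed += 1
            continue
        primes = prime_implicants(tree)
        if not primes:
            continue
        X_oob, y_oob = X[oob], y[oob]
        conj = {c: Interaction(c).evaluate(X_oob) for c in primes}
        full = np.zeros(len(X_oob), dtype=bool)
        for v in conj.values():
            full |= v
        acc_full = float((full == y_oob).mean())
        for c in primes:
            others = np.zeros(len(X_oob), dtype=bool)
            for c2, v in conj.items():
                if c2 != c:
                    others |= v
            acc_without = float((others == y_oob).mean())
            counts[c] = counts.get(c, 0) + 1
            imp_sums[c] = imp_sums.get(c, 0.0) + (acc_full - acc_without)
    if n_failed >= 0.8 * params.n_bootstrap:
        raise RuntimeError(
            f"{n_failed}/{params.n_bootstrap} bootstrap replicates failed"
        )
    n_models = params.n_bootstrap - n_failed
    # importance is normalised by the total model count (logicFS convention):
    # an interaction must appear often AND matter when present to score high
    rows = [
        {
            "interaction": c,
            "proportion": counts[c] / n_models,
            "importance": imp_sums[c] / n_models,
        }
        for c in counts
    ]
    df = pd.DataFrame(rows, columns=["interaction", "proportion", "importance"])
    return df.set_index("interaction")


@dataclass
class ImportanceComparison:
    """Real-vs-permuted-null importance summary for each candidate interaction."""

    table: pd.DataFrame  # per interaction: means, CIs, flagged
    n_iterations: int
    threshold: float
    params: LogicFSParams
    names: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> list[tuple]:
        return list(self.table.index[self.table["flagged"]])


def _percentile_ci(
    values: np.ndarray, rng, n_resamples: int = 2000, level: float = 0.95
) -> tuple[float, float]:
    """Bootstrap percentile interval for the mean of ``values``."""
    idx = rng.integers(0, len(values), (n_resamples, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def null_comparison(
    X: np.ndarray,
    y: np.ndarray,
    params: LogicFSParams | None = None,
    n_iter: int = 200,
    threshold: float = 0.15,
    seed: int | None = None,
    ci_resamples: int = 2000,
    names: list[str] | None = None,
) -> ImportanceComparison:
    """Permutation-null importance inference.

    The bagging run is repeated ``n_iter`` times on the real labels and
    ``n_iter`` times on labels freshly permuted each iteration, with identical
    settings.  Interactions with mean real proportion above ``threshold`` get
    bootstrap percentile CIs of their OOB importance in both arms.

    An interaction is flagged when its real CI lies entirely above both the
    range of its own per-permutation null importances and the median of the
    per-permutation maximum importance over all interactions.  Each
    permutation carries its own chance associations that persist between
    in-bag and out-of-bag samples, so per-iteration null values -- not a CI
    of their mean, which only reflects protocol RNG noise -- are the
    reference for what a no-signal dataset can produce; the median-of-maxima
    floor additionally guards against interactions that star in the fixed
    dataset but rarely recur across permutations, whose own null sample is
    spuriously narrow.
    """
    params = params or LogicFSParams()
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=int)

    def run_arm(labels_fn):
        props: dict[tuple, np.ndarray] = {}
        imps: dict[tuple, np.ndarray] = {}
        iter_max = np.zeros(n_iter)  # top importance per iteration, any interaction
        for it in range(n_iter):
            res = logic_fs(X, labels_fn(), params, seed=int(rng.integers(2 ** 31)))
            for c, row in res.iterrows():
                props.setdefault(c, np.zeros(n_iter))[it] = row["proportion"]
                imps.setdefault(c, np.zeros(n_iter))[it] = row["importance"]
            if len(res):
                iter_max[it] = float(res["importance"].max())
        return props, imps, iter_max

    real_props, real_imps, _ = run_arm(lambda: y)
    null_props, null_imps, null_iter_max = run_arm(lambda: rng.permutation(y))
    chance_floor = float(np.median(null_iter_max))

    zeros = np.zeros(n_iter)
    rows = []
    for c, prop in real_props.items():
        if prop.mean() <= threshold:
            continue
        r_imp = real_imps[c]
        n_imp = null_imps.get(c, zeros)
        r_lo, r_hi = _percentile_ci(r_imp, rng, ci_resamples)
        n_lo, n_hi = _percentile_ci(n_imp, rng, ci_resamples)
        rows.append({
            "interaction": c,
            "real_proportion": float(prop.mean()),
            "real_importance": float(r_imp.mean()),
            "real_ci_low": r_lo, "real_ci_high": r_hi,
            "null_proportion": float(null_props.get(c, zeros).mean()),
            "null_importance": float(n_imp.mean()),
            "null_ci_low": n_lo, "null_ci_high": n_hi,
            "null_imp_min": float(n_imp.min()),
            "null_imp_max": float(n_imp.max()),
            "chance_floor": chance_floor,
            "flagged": r_lo > max(float(n_imp.max()), chance_floor),
        })
    cols = [
        "interaction", "real_proportion", "real_importance", "real_ci_low",
        "real_ci_high", "null_proportion", "null_importance", "null_ci_low",
        "null_ci_high", "null_imp_min", "null_imp_max", "chance_floor",
        "flagged",
    ]
    table = pd.DataFrame(rows, columns=cols)
    table = table.set_index("interaction").sort_values(
        "real_importance", ascending=False
    )
    return ImportanceComparison(
        table=table, n_iterations=n_iter, threshold=threshold,
        params=params, names=names or [],
    )


def interaction_frequency_table(
    X: np.ndarray,
    y: np.ndarray,
    interaction: Interaction,
) -> tuple[pd.DataFrame, float]:
    """Carrier counts of a Boolean interaction by outcome level, with a
    two-sided Fisher exact p (degenerate margins give p = 1)."""
    carrier = interaction.evaluate(X)
    y = np.asarray(y, dtype=int)
    table = pd.DataFrame(
        {
            "carrier": [int((carrier & (y == lv)).sum()) for lv in (0, 1)],
            "non_carrier": [int((~carrier & (y == lv)).sum()) for lv in (0, 1)],
        },
        index=[0, 1],
    )
    m = table.to_numpy()
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("degenerate margin; Fisher p reported as 1")
        return table, 1.0
    return table, float(stats.fisher_exact(m)[1])
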