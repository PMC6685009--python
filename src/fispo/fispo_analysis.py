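"""Observability-identifiability rank tests and per-variable classification.

The observability-identifiability matrix stacks the Jacobians of the
extended Lie derivatives of the outputs with respect to the augmented state,

    OI = [ d g / dx_tilde;  d(L g)/dx_tilde;  ...;  d(L^m g)/dx_tilde ].

Full (generic) rank certifies that every state, unknown parameter and
unknown input is locally observable / structurally locally identifiable /
reconstructible.  When the rank is deficient, removing one column at a time
identifies the variables that cannot be determined: if deleting column i
leaves the rank unchanged, variable i is unobservable (resp. unidentifiable,
unreconstructible).

Generic rank is evaluated exactly, never with floating-point thresholds:
each symbol is specialized to a random positive rational (symbols used as
exponents get small positive integers so powers stay in the rational
field), the Jacobian entries are obtained at that point by forward-mode
differentiation in exact ``Fraction`` arithmetic, and the rank of the
resulting rational matrix is computed by modular Gaussian elimination over
a large random prime field (which can only underestimate the rational rank,
with negligible probability).  The maximum over several specialization
seeds is reported.  Logarithms arising from derivatives of symbolic powers
are treated as independent transcendentals.  A floating-point SVD rank at
independent points is available as a diagnostic cross-check.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy as sp

from .lie_engine import AugmentedModel, LieSeries, augment, lie_series
from .model_core import OdeModel

__all__ = [
    "OIMatrix",
    "FispoReport",
    "SweepResult",
    "InconclusiveRankError",
    "build_oi",
    "numeric_rank",
    "svd_rank",
    "classify",
    "analyze",
    "excitation_analysis",
    "multi_experiment",
    "fispo_sweep",
]

DEFAULT_SEEDS = (1, 2, 3)


class InconclusiveRankError(RuntimeError):
    """All numeric specializations hit singular expressions."""


class _SingularPoint(ArithmeticError):
    """Specialization point hit a pole; redraw."""


# ---------------------------------------------------------------------------
# random rational specialization
# ---------------------------------------------------------------------------

def _exponent_symbols(exprs) -> frozenset:
    """Symbols that occur inside an exponent (or a log argument) somewhere."""
    out: set[sp.Symbol] = set()
    for e in exprs:
        e = sp.sympify(e)
        for p in e.atoms(sp.Pow):
            out |= p.exp.free_symbols
        for l in e.atoms(sp.log):
            out |= l.args[0].free_symbols
    return frozenset(out)


def _draw_point(symbols, exponent_syms, rng: random.Random, as_float=False) -> dict:
    """Random positive value per symbol; small positive integers for exponents."""
    point = {}
    for s in symbols:
        if s in exponent_syms:
            point[s] = rng.randint(2, 4)
        else:
            point[s] = Fraction(rng.randint(50, 200), 100)
        if as_float:
            point[s] = float(point[s])
    return point


# ---------------------------------------------------------------------------
# exact forward-mode evaluation of values and gradients at a point
# ---------------------------------------------------------------------------

class _EvalContext:
    """Evaluate sympy expressions and their gradients at a fixed point.

    ``exact`` mode uses :class:`fractions.Fraction` throughout and assigns
    an independent random rational to each distinct logarithm value (the
    generic-transcendental treatment); ``float`` mode uses true IEEE
    arithmetic including real logarithms, providing an independent route
    for cross-checks.  Results are memoized per sub-expression, so repeated
    evaluation of a growing Lie series is incremental.
    """

    def __init__(self, point: dict, rng: random.Random, exact: bool = True):
        self.point = point
        self.rng = rng
        self.exact = exact
        self.memo: dict = {}
        self.logmap: dict = {}

    def _log(self, v):
        if not self.exact:
            if v <= 0:
                raise _SingularPoint("log of non-positive value")
            return math.log(v)
        if v <= 0:
            raise _SingularPoint("log of non-positive value")
        if v not in self.logmap:
            self.logmap[v] = Fraction(self.rng.randint(-150, 150) or 7, 100)
        return self.logmap[v]

    def grad(self, expr, wrt) -> list:
        """Gradient of ``expr`` with respect to the symbols in ``wrt``."""
        v, g = self._eval(sp.sympify(expr))
        return [g.get(s, 0) for s in wrt]

    def value(self, expr):
        return self._eval(sp.sympify(expr))[0]

    def _eval(self, expr):
        hit = self.memo.get(expr)
        if hit is not None:
            return hit
        res = self._eval_inner(expr)
        self.memo[expr] = res
        return res

    def _eval_inner(self, expr):
        zero = Fraction(0) if self.exact else 0.0
        if expr.is_Symbol:
            try:
                v = self.point[expr]
            except KeyError:
                raise _SingularPoint(f"symbol {expr} has no value") from None
            one = Fraction(1) if self.exact else 1.0
            return v, {expr: one}
        if expr.is_Number:
            if self.exact:
                r = sp.Rational(expr)
                return Fraction(int(r.p), int(r.q)), {}
            return float(expr), {}
        if expr.is_Add:
            v, g = zero, {}
            for a in expr.args:
                va, ga = self._eval(a)
                v = v + va
                for s, d in ga.items():
                    g[s] = g.get(s, zero) + d
            return v, g
        if expr.is_Mul:
            v, g = None, {}
            for a in expr.args:
                va, ga = self._eval(a)
                if v is None:
                    v, g = va, dict(ga)
                    continue
                ng = {s: d * va for s, d in g.items()}
                for s, d in ga.items():
                    ng[s] = ng.get(s, zero) + v * d
                v, g = v * va, ng
            return v, g
        if expr.is_Pow:
            b, e = expr.args
            vb, gb = self._eval(b)
            ve, ge = self._eval(e)
            if not ge:  # numeric exponent
                if self.exact:
                    fe = Fraction(ve)
                    if fe.denominator != 1:
                        raise NotImplementedError(
                            "non-integer numeric exponent in exact mode"
                        )
                    ve = int(fe)
                elif vb < 0 and ve != int(ve):
                    raise _SingularPoint("negative base, fractional power")
                if vb == 0:
                    if ve < 0:
                        raise _SingularPoint("pole")
                    if ve == 0:
                        return (Fraction(1) if self.exact else 1.0), {}
                    v = vb ** ve
                    dv = 1 if ve == 1 else 0
                else:
                    v = vb ** ve
                    dv = ve * vb ** (ve - 1)
                return v, {s: dv * d for s, d in gb.items()}
            # genuinely symbolic exponent: b^e, d = b^e (e' log b + e b'/b)
            if vb == 0:
                raise _SingularPoint("0 raised to symbolic power")
            if self.exact:
                fe = Fraction(ve)
                if fe.denominator != 1:
                    raise NotImplementedError(
                        "symbolic exponent evaluated to non-integer"
                    )
                v = vb ** int(fe)
            else:
                if vb < 0:
                    raise _SingularPoint("negative base with real exponent")
                v = vb ** ve
            L = self._log(vb)
            g = {}
            for s, d in ge.items():
                g[s] = g.get(s, zero) + v * L * d
            for s, d in gb.items():
                g[s] = g.get(s, zero) + v * ve / vb * d
            return v, g
        if isinstance(expr, sp.log):
            va, ga = self._eval(expr.args[0])
            if va == 0:
                raise _SingularPoint("log(0)")
            return self._log(va), {s: d / va for s, d in ga.items()}
        if not self.exact:
            fns = {sp.sin: math.sin, sp.cos: math.cos, sp.tan: math.tan,
                   sp.exp: math.exp}
            dfns = {sp.sin: math.cos, sp.cos: lambda x: -math.sin(x),
                    sp.tan: lambda x: 1.0 / math.cos(x) ** 2, sp.exp: math.exp}
            for cls, f in fns.items():
                if isinstance(expr, cls):
                    va, ga = self._eval(expr.args[0])
                    df = dfns[cls](va)
                    return f(va), {s: df * d for s, d in ga.items()}
        raise NotImplementedError(
            f"expression node {type(expr).__name__} not supported by the "
            "exact rank evaluator (powers, logs and rational operations only)"
        )


# ---------------------------------------------------------------------------
# exact rank of rational matrices (modular elimination)
# ---------------------------------------------------------------------------

_PRIME_LO, _PRIME_HI = 2 ** 50, 2 ** 52


def _rank_mod_p(rows: list, p: int, skip_col: int | None = None) -> int:
    """Rank over F_p of a matrix given as lists of Fractions/ints."""
    mat = []
    for row in rows:
        r = []
        for j, x in enumerate(row):
            if j == skip_col:
                continue
            f = Fraction(x)
            den = f.denominator % p
            if den == 0:
                raise _SingularPoint("denominator divisible by modulus")
            r.append((f.numerator % p) * pow(den, -1, p) % p)
        mat.append(r)
    if not mat or not mat[0]:
        return 0
    ncols = len(mat[0])
    rank = 0
    for col in range(ncols):
        piv = next((i for i in range(rank, len(mat)) if mat[i][col]), None)
        if piv is None:
            continue
        mat[rank], mat[piv] = mat[piv], mat[rank]
        inv = pow(mat[rank][col], -1, p)
        prow = [(x * inv) % p for x in mat[rank]]
        mat[rank] = prow
        for i in range(len(mat)):
            if i != rank and mat[i][col]:
                f = mat[i][col]
                mat[i] = [(a - f * b) % p for a, b in zip(mat[i], prow)]
        rank += 1
        if rank == len(mat):
            break
    return rank


def _rank_exact(rows: list, rng: random.Random, skip_col: int | None = None) -> int:
    """Rank over Q via two random prime moduli (max of the two)."""
    best = 0
    for _ in range(2):
        # derive the prime from the rng so results are reproducible
        p = sp.nextprime(rng.randrange(_PRIME_LO, _PRIME_HI))
        try:
            best = max(best, _rank_mod_p(rows, p, skip_col))
        except _SingularPoint:
            continue
    return best


# ---------------------------------------------------------------------------
# public rank helpers on arbitrary symbolic matrices
# ---------------------------------------------------------------------------

def _matrix_rows_at_point(M: sp.Matrix, ctx: _EvalContext) -> list:
    return [
        [ctx.value(M[i, j]) for j in range(M.cols)] for i in range(M.rows)
    ]


def numeric_rank(M: sp.Matrix, seeds=DEFAULT_SEEDS, exponent_syms=None) -> int:
    """Generic rank of a symbolic matrix: max exact rank over random points.

    Each seed draws one random positive rational point (with retries if a
    pole is hit); the matrix is evaluated there in exact arithmetic and its
    rank computed over random prime fields.  The maximum across seeds is a
    probability-one lower-and-exact estimate of the generic rank.
    """
    if M.rows == 0 or M.cols == 0:
        return 0
    if exponent_syms is None:
        exponent_syms = _exponent_symbols(list(M))
    symbols = sorted(M.free_symbols, key=lambda s: s.name)
    best = 0
    for seed in seeds:
        for attempt in range(5):
            rng = random.Random((seed + 1) * 10007 + attempt)
            point = _draw_point(symbols, exponent_syms, rng)
            ctx = _EvalContext(point, rng, exact=True)
            try:
                rows = _matrix_rows_at_point(M, ctx)
                best = max(best, _rank_exact(rows, rng))
            except _SingularPoint:
                continue
            break
        else:
            raise InconclusiveRankError(
                f"no non-singular rational specialization found (seed {seed})"
            )
        if best == min(M.rows, M.cols):
            break
    return best


def svd_rank(M: sp.Matrix, exponent_syms=None, seed: int = 0) -> int:
    """Floating-point SVD rank at a random point (diagnostic cross-check).

    Evaluates with true IEEE arithmetic (including real logarithms), so it
    is independent of the rational-field treatment in :func:`numeric_rank`.
    Tolerance: ``max(dims) * eps * sigma_max``.
    """
    if exponent_syms is None:
        exponent_syms = _exponent_symbols(list(M))
    symbols = sorted(M.free_symbols, key=lambda s: s.name)
    for attempt in range(5):
        rng = random.Random((seed + 1) * 7919 + attempt)
        point = _draw_point(symbols, exponent_syms, rng, as_float=True)
        ctx = _EvalContext(point, rng, exact=False)
        try:
            rows = _matrix_rows_at_point(M, ctx)
        except _SingularPoint:
            continue
        arr = np.array(rows, dtype=float)
        if not np.all(np.isfinite(arr)):
            continue
        if arr.size == 0:
            return 0
        s = np.linalg.svd(arr, compute_uv=False)
        tol = max(arr.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        return int(np.sum(s > tol))
    raise InconclusiveRankError("no non-singular floating specialization found")


# ---------------------------------------------------------------------------
# OI matrix
# ---------------------------------------------------------------------------

class OIMatrix:
    """Stacked Lie-derivative Jacobians with rank metadata.

    The numeric specializations (one exact rational matrix per seed, as
    nested ``Fraction`` lists) are kept for the column-removal
    classification; the symbolic matrix is assembled lazily on demand since
    it can be very large for high Lie orders.
    """

    def __init__(
        self,
        series: LieSeries,
        m: int,
        rank: int,
        effective_dim: int,
        column_labels,
        specialization_seeds,
        rank_history,
        exponent_syms,
        specialized,
        specialized_ranks,
        rank_rngs,
    ):
        self.series = series
        self.m = m
        self.rank = rank
        self.effective_dim = effective_dim
        self.column_labels = tuple(column_labels)
        self.specialization_seeds = tuple(specialization_seeds)
        self.rank_history = list(rank_history)
        self.exponent_syms = exponent_syms
        self.specialized = specialized
        self.specialized_ranks = specialized_ranks
        self._rank_rngs = rank_rngs
        self._entries = None

    @property
    def full_rank(self) -> bool:
        return self.rank == self.effective_dim

    @property
    def entries(self) -> sp.Matrix:
        """The symbolic OI matrix (assembled on first access)."""
        if self._entries is None:
            x = sp.Matrix(list(self.column_labels))
            blocks = [
                sp.Matrix(list(t)).jacobian(x)
                for t in self.series.terms[: self.m + 1]
            ]
            self._entries = sp.Matrix.vstack(*blocks)
        return self._entries


def build_oi(
    am: AugmentedModel,
    max_orders: int,
    seeds=DEFAULT_SEEDS,
    patience: int = 1,
) -> OIMatrix:
    """Build the OI matrix block-recursively with early termination.

    One Lie-derivative block is appended at a time; the build stops as soon
    as the rank reaches the (stage-dependent) augmented dimension, or when
    the rank has not increased for ``patience`` consecutive blocks, or at
    ``max_orders``.
    """
    if max_orders < 1:
        raise ValueError("max_orders must be >= 1")
    exps = _exponent_symbols((*am.f_aug, *am.outputs))
    series = lie_series(am, 0)
    wrt = list(am.x_aug)

    # one evaluation context per seed; memoization makes the growing series
    # incremental.  Retries on singular points restart that seed's context.
    ctxs: dict[int, _EvalContext] = {}
    rows_by_seed: dict[int, list] = {s: [] for s in seeds}
    rngs: dict[int, random.Random] = {}
    done_upto: dict[int, int] = {s: -1 for s in seeds}

    def _fresh(seed: int, attempt: int) -> None:
        rng = random.Random((seed + 1) * 10007 + attempt)
        all_syms = set()
        for f in am.f_aug:
            all_syms |= f.free_symbols
        for g in am.outputs:
            all_syms |= g.free_symbols
        all_syms |= set(am.x_aug)
        # include known-input derivative symbols up to the cap
        for u in am.base.known_inputs:
            for j in range(max_orders + 2):
                all_syms.add(sp.Symbol(f"{u.name}_d{j}") if j else u)
        point = _draw_point(sorted(all_syms, key=lambda s: s.name), exps, rng)
        ctxs[seed] = _EvalContext(point, rng, exact=True)
        rows_by_seed[seed] = []
        rngs[seed] = rng
        done_upto[seed] = -1

    def _extend_seed(seed: int, upto: int) -> None:
        for attempt in range(5):
            if seed not in ctxs:
                _fresh(seed, attempt)
            try:
                while done_upto[seed] < upto:
                    k = done_upto[seed] + 1
                    for comp in series.terms[k]:
                        rows_by_seed[seed].append(ctxs[seed].grad(comp, wrt))
                    done_upto[seed] = k
                return
            except _SingularPoint:
                del ctxs[seed]
                continue
        raise InconclusiveRankError(
            f"no non-singular rational specialization found (seed {seed})"
        )

    def _stage_rank(upto: int) -> int:
        best = 0
        for seed in seeds:
            _extend_seed(seed, upto)
            best = max(best, _rank_exact(rows_by_seed[seed], rngs[seed]))
            if best == am.effective_dim(upto):
                break
        return best

    m = 0
    rank = _stage_rank(0)
    rank_history = [rank]
    stall = 0
    while m < max_orders and rank < am.effective_dim(m):
        m += 1
        series.extend(m)
        new_rank = _stage_rank(m)
        rank_history.append(new_rank)
        if new_rank == rank and new_rank < am.effective_dim(m):
            stall += 1
            if stall >= patience:
                rank = new_rank
                break
        else:
            stall = 0
        rank = new_rank

    for seed in seeds:
        _extend_seed(seed, m)
    specialized = [rows_by_seed[s] for s in seeds]
    specialized_ranks = [
        _rank_exact(rows_by_seed[s], rngs[s]) for s in seeds
    ]
    return OIMatrix(
        series=series,
        m=m,
        rank=rank,
        effective_dim=am.effective_dim(m),
        column_labels=am.x_aug,
        specialization_seeds=seeds,
        rank_history=rank_history,
        exponent_syms=exps,
        specialized=specialized,
        specialized_ranks=specialized_ranks,
        rank_rngs=[rngs[s] for s in seeds],
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class FispoReport:
    """Per-variable observability / identifiability / reconstructibility."""

    model: str
    fispo: bool
    rank: int
    n_aug: int
    observable_states: tuple
    unobservable_states: tuple
    identifiable_params: tuple
    unidentifiable_params: tuple
    reconstructible_inputs: tuple
    unreconstructible_inputs: tuple
    lie_orders_used: int
    conclusive: bool
    assumptions: dict
    rank_history: list[int] = field(default_factory=list)
    seeds: tuple = ()

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for k in (
            "observable_states",
            "unobservable_states",
            "identifiable_params",
            "unidentifiable_params",
            "reconstructible_inputs",
            "unreconstructible_inputs",
        ):
            d[k] = [str(s) for s in d[k]]
        d["seeds"] = list(self.seeds)
        return d


def classify(am: AugmentedModel, oi: OIMatrix) -> FispoReport:
    """Column-removal classification of states, parameters and inputs.

    Only the columns for the original states, the parameters and the
    unknown inputs themselves (order-0 entries of the derivative chains) are
    user-facing; higher chain derivatives are bookkeeping of the
    augmentation.
    """
    base = am.base
    labels = list(oi.column_labels)
    conclusive = oi.full_rank or (
        len(oi.rank_history) >= 2 and oi.rank_history[-1] == oi.rank_history[-2]
    )

    def necessary(col: int) -> bool:
        for rows, r, rng in zip(
            oi.specialized, oi.specialized_ranks, oi._rank_rngs
        ):
            if r != oi.rank:
                continue  # unlucky point below generic rank; not informative
            if _rank_exact(rows, rng, skip_col=col) == oi.rank:
                return False
        return True

    def split(symbols):
        good, bad = [], []
        for s in symbols:
            col = labels.index(s)
            if oi.full_rank or necessary(col):
                good.append(s)
            else:
                bad.append(s)
        return tuple(good), tuple(bad)

    obs, unobs = split(base.states)
    ident, unident = split(base.params)
    w_syms = [w for w in base.unknown_inputs if w in labels]
    rec, unrec = split(w_syms)
    dropped_w = tuple(w for w in base.unknown_inputs if w not in labels)
    unrec = unrec + dropped_w  # w removed by truncation 0 cannot be assessed

    fispo = bool(oi.full_rank and not (unobs or unident or unrec))
    return FispoReport(
        model=base.name,
        fispo=fispo,
        rank=oi.rank,
        n_aug=oi.effective_dim,
        observable_states=obs,
        unobservable_states=unobs,
        identifiable_params=ident,
        unidentifiable_params=unident,
        reconstructible_inputs=rec,
        unreconstructible_inputs=unrec,
        lie_orders_used=oi.m,
        conclusive=conclusive,
        assumptions={
            "w_truncation": am.w_truncation,
            "u_truncation": am.u_truncation,
            "n_experiments": 1,
        },
        rank_history=list(oi.rank_history),
        seeds=oi.specialization_seeds,
    )


# ---------------------------------------------------------------------------
# high-level drivers
# ---------------------------------------------------------------------------

def _default_cap(m: OdeModel, w_truncation: int | None) -> int:
    chain = 1 if w_truncation is None else max(w_truncation, 1)
    n_aug = m.n_x + m.n_theta + m.n_w * chain
    # enough blocks for full rank plus slack to detect a stall
    return max(2, math.ceil(n_aug / max(m.n_y, 1)) + chain + 2)


def analyze(
    model: OdeModel,
    w_truncation: int | None = None,
    u_truncation: int | None = None,
    max_orders: int | None = None,
    seeds=DEFAULT_SEEDS,
    patience: int = 1,
    n_experiments: int = 1,
) -> FispoReport:
    """Run the full analysis pipeline on one model.

    ``w_truncation``/``u_truncation`` bound the non-zero derivatives of the
    unknown/known inputs (1 = constant input, ``None`` = generic smooth
    input).  ``n_experiments`` > 1 replicates the model first.
    """
    if n_experiments > 1:
        model = multi_experiment(model, n_experiments)
    cap = max_orders if max_orders is not None else _default_cap(model, w_truncation)
    am = augment(model, order=cap, w_truncation=w_truncation, u_truncation=u_truncation)
    oi = build_oi(am, cap, seeds=seeds, patience=patience)
    report = classify(am, oi)
    report.assumptions["n_experiments"] = n_experiments
    return report


def excitation_analysis(
    model: OdeModel,
    u_zero_above: int,
    **kwargs,
) -> FispoReport:
    """Rank analysis with known-input derivatives zeroed above an order.

    ``u_zero_above = 1`` models constant known inputs, 2 ramps, etc.  This
    probes how exciting the experiment's inputs must be for identifiability.
    """
    if not model.known_inputs:
        raise ValueError(f"{model.name} has no known inputs to analyse")
    return analyze(model, u_truncation=u_zero_above, **kwargs)


def multi_experiment(model: OdeModel, n_exp: int) -> OdeModel:
    """Replicate states, outputs and inputs per experiment, sharing theta.

    Every replicate gets its own copies of the states, inputs and outputs
    (suffixed ``_expK``); the unknown parameters are common to all
    replicates, which is what makes several experiments informative.  In
    the rank analysis the replicated input symbols receive independent
    random values, i.e. the experiments have generic, distinct input levels.
    """
    if n_exp < 2:
        raise ValueError("n_exp must be >= 2")

    states, odes, outputs, kin, win, init = [], [], [], [], [], {}
    for e in range(1, n_exp + 1):
        ren = {
            s: sp.Symbol(f"{s.name}_exp{e}")
            for s in (*model.states, *model.known_inputs, *model.unknown_inputs)
        }
        states += [ren[s] for s in model.states]
        odes += [expr.xreplace(ren) for expr in model.odes]
        outputs += [expr.xreplace(ren) for expr in model.outputs]
        kin += [ren[s] for s in model.known_inputs]
        win += [ren[s] for s in model.unknown_inputs]
        for s in model.states:
            init[ren[s]] = model.init.get(s, None)

    return OdeModel(
        name=f"{model.name}_x{n_exp}",
        states=tuple(states),
        odes=tuple(odes),
        outputs=tuple(outputs),
        known_inputs=tuple(kin),
        unknown_inputs=tuple(win),
        params=model.params,
        constants=dict(model.constants),
        init=init,
    )


@dataclass
class SweepResult:
    """Reports from a sweep over unknown-input truncation orders."""

    reports: list
    #: 'fispo_generic_smooth_input' | 'not_fispo' | 'inconclusive'
    suggestion: str

    def __iter__(self):
        return iter(self.reports)


def fispo_sweep(model: OdeModel, i_values, **kwargs) -> SweepResult:
    """Analyse under w^(j) = 0 for j >= i, for each i in ``i_values``.

    If the rank condition holds at every tested truncation order and the
    rank grows steadily (no stall before reaching full rank) as Lie blocks
    are added, the model is flagged as *suggested* fully observable for any
    generic smooth unknown input; if it fails at every order, the suggestion
    is that the model is not fully observable.  These are heuristics for the
    untestable infinite-chain limit, not theorems.
    """
    i_values = list(i_values)
    if not i_values:
        raise ValueError("i_values must be non-empty")
    reports = [analyze(model, w_truncation=i, **kwargs) for i in i_values]

    def uniform_growth(r: FispoReport) -> bool:
        h = r.rank_history
        return all(h[k + 1] > h[k] for k in range(len(h) - 1))

    if all(r.fispo for r in reports) and all(uniform_growth(r) for r in reports):
        suggestion = "fispo_generic_smooth_input"
    elif all(not r.fispo for r in reports):
        suggestion = "not_fispo"
    else:
        suggestion = "inconclusive"
    return SweepResult(reports=reports, suggestion=suggestion)
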