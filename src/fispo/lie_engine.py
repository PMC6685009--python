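"""Extended Lie derivatives on the augmented state.

To test observability jointly with identifiability and input
reconstructibility, the state vector is augmented with the unknown
parameters (zero dynamics) and with each unknown input together with a
chain of its time derivatives:

    x_tilde = [x, theta, w, w', w'', ..., w^(i)]
    f_tilde = [f, 0,     w', w'', ...,    w^(i+1)]

Successive outputs derivatives along the flow are computed with the
*extended* Lie derivative, which also carries the time derivatives of the
known inputs u:

    L^i g = d(L^{i-1} g)/dx_tilde . f_tilde  +  sum_j d(L^{i-1} g)/du^(j) . u^(j+1)

Derivatives of w (and optionally u) can be declared to vanish above a given
order ("truncation"), which restricts the admissible inputs to polynomials
in time of that degree — order 1 corresponds to constant unknown inputs.

No automatic simplification is applied to intermediate derivatives: the
downstream rank tests specialize the symbols numerically, where
simplification is unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy as sp

from .model_core import OdeModel

__all__ = [
    "deriv_symbol",
    "AugmentedModel",
    "LieSeries",
    "augment",
    "lie_derivative",
    "lie_series",
]


def deriv_symbol(base: sp.Symbol, order: int) -> sp.Symbol:
    """Symbol standing for the ``order``-th time derivative of ``base``."""
    if order == 0:
        return base
    return sp.Symbol(f"{base.name}_d{order}")


class ModelInconsistencyError(RuntimeError):
    """A Lie derivative produced a symbol outside the augmented state."""


@dataclass(frozen=True)
class AugmentedModel:
    """An :class:`OdeModel` recast with parameters and input chains as states.

    ``w_truncation = d`` means the d-th and higher derivatives of every
    unknown input are identically zero (d = 1: constant unknown inputs);
    ``None`` leaves the chain unbounded up to the requested ``order``.
    ``u_truncation`` plays the same role for the known inputs (1: constant
    known inputs; ``None``: generic smooth inputs); it may also be a mapping
    from input name to order so individual inputs can be held constant
    while others vary.
    """

    base: OdeModel
    order: int
    w_truncation: int | None = None
    u_truncation: int | None | dict = None
    x_aug: tuple[sp.Symbol, ...] = field(default=(), compare=False)
    f_aug: tuple[sp.Expr, ...] = field(default=(), compare=False)
    outputs: tuple[sp.Expr, ...] = field(default=(), compare=False)

    @property
    def n_aug(self) -> int:
        return len(self.x_aug)

    @property
    def chain_length(self) -> int:
        """Number of derivative orders kept per unknown input (incl. order 0)."""
        if self.w_truncation is None:
            return self.order + 1
        return self.w_truncation

    def effective_dim(self, m: int) -> int:
        """Augmented dimension relevant after m Lie derivatives.

        Per unknown input, only derivatives up to order m can enter the
        first m Lie derivatives, so trailing chain entries do not count yet.
        """
        b = self.base
        kept = min(m + 1, self.chain_length)
        return b.n_x + b.n_theta + b.n_w * kept

    def u_deriv(self, u: sp.Symbol, order: int) -> sp.Expr:
        """The ``order``-th derivative symbol of known input ``u`` (or 0)."""
        t = self.u_truncation
        if isinstance(t, dict):
            t = t.get(str(u), None)
        if t is not None and order >= t:
            return sp.Integer(0)
        return deriv_symbol(u, order)


def augment(
    m: OdeModel,
    order: int,
    w_truncation: int | None = None,
    u_truncation: int | None = None,
) -> AugmentedModel:
    """Build the augmented model with a w-derivative chain up to ``order``.

    Known numeric constants are substituted into the dynamics and outputs so
    the augmented expressions contain only augmented-state and known-input
    symbols.
    """
    if order < 0:
        raise ValueError("chain order must be non-negative")
    if w_truncation is not None and w_truncation < 0:
        raise ValueError("w_truncation must be non-negative or None")

    mc = m.with_constants_substituted()
    odes = list(mc.odes)
    outputs = list(mc.outputs)

    # truncation d: w^(j) = 0 for all j >= d.  d = 0 removes w entirely;
    # a truncated chain has length exactly d and is closed by a zero row,
    # an unbounded chain has length order+1 and its top row formally
    # carries w^(order+1), which never enters the first `order` Lie
    # derivatives (the chain is long enough by construction).
    kept = order + 1 if w_truncation is None else w_truncation
    if w_truncation == 0:
        zero = {w: sp.Integer(0) for w in mc.unknown_inputs}
        odes = [e.subs(zero) for e in odes]
        outputs = [e.subs(zero) for e in outputs]

    x_aug: list[sp.Symbol] = list(mc.states) + list(mc.params)
    f_aug: list[sp.Expr] = odes + [sp.Integer(0)] * mc.n_theta

    for w in mc.unknown_inputs:
        for j in range(kept):
            x_aug.append(deriv_symbol(w, j))
            nxt = j + 1
            if w_truncation is not None and nxt >= w_truncation:
                f_aug.append(sp.Integer(0))
            else:
                f_aug.append(deriv_symbol(w, nxt))

    return AugmentedModel(
        base=m,
        order=order,
        w_truncation=w_truncation,
        u_truncation=u_truncation,
        x_aug=tuple(x_aug),
        f_aug=tuple(f_aug),
        outputs=tuple(outputs),
    )


def _u_deriv_terms(expr: sp.Expr, am: AugmentedModel, max_order: int) -> sp.Expr:
    """Sum of d(expr)/du^(j) * u^(j+1) over known inputs and orders."""
    total = sp.Integer(0)
    for u in am.base.known_inputs:
        for j in range(max_order + 1):
            uj = deriv_symbol(u, j)
            if not expr.has(uj):
                continue
            nxt = am.u_deriv(u, j + 1)
            if nxt != 0:
                total += sp.diff(expr, uj) * nxt
    return total


def lie_derivative(prev: tuple[sp.Expr, ...], am: AugmentedModel, order: int) -> tuple[sp.Expr, ...]:
    """One step of the extended Lie derivative: from L^{order-1}g to L^{order}g."""
    if order < 1:
        raise ValueError("order must be >= 1 (order 0 is the output itself)")
    if am.w_truncation is None and order > am.order:
        raise ModelInconsistencyError(
            f"Lie order {order} exceeds the unbounded w-chain length "
            f"({am.order}); rebuild the augmentation with a longer chain"
        )
    out = []
    for comp in prev:
        nxt = sp.Integer(0)
        for xs, fs in zip(am.x_aug, am.f_aug):
            if comp.has(xs) and fs != 0:
                nxt += sp.diff(comp, xs) * fs
        nxt += _u_deriv_terms(comp, am, order - 1)
        out.append(nxt)
    return tuple(out)


@dataclass
class LieSeries:
    """The sequence [g, L g, L^2 g, ..., L^m g] for an augmented model."""

    am: AugmentedModel
    terms: list[tuple[sp.Expr, ...]]

    @property
    def order(self) -> int:
        return len(self.terms) - 1

    def extend(self, to_order: int) -> "LieSeries":
        """Extend in place up to ``to_order``; earlier terms are reused."""
        while self.order < to_order:
            self.terms.append(
                lie_derivative(self.terms[-1], self.am, self.order + 1)
            )
        return self


def lie_series(am: AugmentedModel, m: int) -> LieSeries:
    """Compute the extended Lie derivatives of the outputs up to order ``m``."""
    if m < 0:
        raise ValueError("m must be >= 0")
    series = LieSeries(am=am, terms=[am.outputs])
    return series.extend(m)
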