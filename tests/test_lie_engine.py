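"""Augmentation and extended Lie derivatives."""

import pytest
import sympy as sp

from fispo.lie_engine import augment, deriv_symbol, lie_derivative, lie_series
from fispo.model_core import loads_model


class TestAugment:
    def test_dimension_formula_unbounded(self, c2m_k1e_known):
        am = augment(c2m_k1e_known, order=2)
        assert am.n_aug == 2 + 2 + 1 * 3  # states + params + w chain

    def test_parameter_rows_have_zero_dynamics(self, hiv):
        am = augment(hiv, order=1)
        for s, f in zip(am.x_aug, am.f_aug):
            if s in hiv.params:
                assert f == 0

    def test_truncation_one_keeps_constant_input(self, c2m):
        am = augment(c2m, order=3, w_truncation=1)
        w = sp.Symbol("w")
        assert w in am.x_aug
        assert deriv_symbol(w, 1) not in am.x_aug
        # constant input: the w row itself has zero dynamics
        assert am.f_aug[am.x_aug.index(w)] == 0

    def test_truncation_zero_removes_input_entirely(self, c2m):
        am = augment(c2m, order=3, w_truncation=0)
        w = sp.Symbol("w")
        assert w not in am.x_aug
        assert all(not f.has(w) for f in am.f_aug)

    def test_chain_consistency(self, hiv):
        """d/dt of each w^(j) row is w^(j+1) (or 0 at a truncated top)."""
        am = augment(hiv, order=3)
        eta = sp.Symbol("eta")
        for j in range(3):
            idx = am.x_aug.index(deriv_symbol(eta, j))
            assert am.f_aug[idx] == deriv_symbol(eta, j + 1)
        amt = augment(hiv, order=3, w_truncation=2)
        idx = amt.x_aug.index(deriv_symbol(eta, 1))
        assert amt.f_aug[idx] == 0

    def test_negative_order_rejected(self, c2m):
        with pytest.raises(ValueError):
            augment(c2m, order=-1)


def _total_derivative_oracle(model, n):
    """d^n y/dt^n by explicit time-dependent substitution (independent route).

    States and unknown inputs become functions of t, the chain rule is
    applied by sympy's ``diff``, and state derivatives are replaced by the
    dynamics recursively.  Returns expressions in the same symbols as the
    Lie series (w derivatives as ``w_dj``).
    """
    t = sp.Symbol("t")
    mc = model.with_constants_substituted()
    funcs = {s: sp.Function(s.name)(t) for s in (*mc.states, *mc.unknown_inputs)}
    rhs = {funcs[s]: e.subs(funcs) for s, e in zip(mc.states, mc.odes)}
    exprs = [g.subs(funcs) for g in mc.outputs]
    for _ in range(n):
        exprs = [sp.diff(e, t) for e in exprs]
        # replace state derivatives by the dynamics until none remain
        changed = True
        while changed:
            changed = False
            for e_i, e in enumerate(exprs):
                for d in e.atoms(sp.Derivative):
                    if d.expr in rhs:
                        exprs[e_i] = exprs[e_i].xreplace(
                            {d: sp.diff(rhs[d.expr], t, d.derivative_count - 1)}
                        )
                        changed = True
                e = exprs[e_i]
    # map w-function derivatives and plain functions back to symbols
    back = {}
    for s, f in funcs.items():
        back[f] = s
        for j in range(1, n + 1):
            back[sp.Derivative(f, (t, j))] = deriv_symbol(s, j)
    return [e.subs(back) for e in exprs]


class TestLieDerivatives:
    def test_first_lie_derivative_of_c2m_is_first_dynamics_row(self, c2m):
        am = augment(c2m, order=2)
        series = lie_series(am, 1)
        # y = x1, so L^1 g is the x1 dynamics
        assert sp.simplify(series.terms[1][0] - am.f_aug[0]) == 0

    def test_order_zero_is_the_output(self, hiv):
        am = augment(hiv, order=0)
        series = lie_series(am, 0)
        assert series.terms[0] == am.outputs

    @pytest.mark.parametrize("name", ["c2m", "hiv"])
    def test_second_lie_derivative_matches_total_derivative_oracle(
        self, name, request
    ):
        model = request.getfixturevalue(name)
        am = augment(model, order=2)
        series = lie_series(am, 2)
        oracle = _total_derivative_oracle(model, 2)
        for lie, tot in zip(series.terms[2], oracle):
            assert sp.simplify(lie - tot) == 0

    def test_linearity_in_the_output(self):
        m = loads_model(
            """
name: tiny
states: [x1, x2]
odes: {x1: -a*x1 + x2*w, x2: x1 - b*x2}
outputs: [x1, x2, 3*x1 - 2*x2]
unknown_inputs: [w]
parameters: [a, b]
"""
        )
        am = augment(m, order=2)
        series = lie_series(am, 2)
        for i in range(3):
            g1, g2, combo = series.terms[i]
            assert sp.expand(combo - (3 * g1 - 2 * g2)) == 0

    def test_incremental_extension_preserves_earlier_terms(self, c2m):
        am = augment(c2m, order=4)
        series = lie_series(am, 2)
        frozen = [tuple(t) for t in series.terms]
        series.extend(4)
        assert [tuple(t) for t in series.terms[:3]] == frozen

    def test_known_input_derivatives_appear_with_the_gain(self, c2m_original):
        am = augment(c2m_original, order=2)
        series = lie_series(am, 2)
        u1 = deriv_symbol(sp.Symbol("u"), 1)
        b = sp.Symbol("b")
        assert sp.simplify(sp.diff(series.terms[2][0], u1) - b) == 0

    def test_u_truncation_removes_derivatives(self, c2m_original):
        am = augment(c2m_original, order=2, u_truncation=1)
        series = lie_series(am, 2)
        u1 = deriv_symbol(sp.Symbol("u"), 1)
        assert all(not e.has(u1) for term in series.terms for e in term)

    def test_order_must_be_positive(self, c2m):
        am = augment(c2m, order=1)
        with pytest.raises(ValueError):
            lie_derivative(am.outputs, am, 0)
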