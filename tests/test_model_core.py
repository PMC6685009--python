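"""Model definitions, file round-trips and model surgery."""

import pytest
import sympy as sp

from fispo.model_core import (
    DuplicateSymbolError,
    ModelError,
    UndeclaredSymbolError,
    dumps_model,
    fix_parameter,
    load_fixture,
    loads_model,
    model_library,
    reformulate_input,
)


def _syms(names):
    return sp.symbols(names)


class TestFixtures:
    def test_c2m_equations_match_canonical_form(self, c2m):
        x1, x2, k1e, k12, k21, w = _syms("x1 x2 k1e k12 k21 w")
        assert sp.expand(c2m.odes[0] - (-(k1e + k12) * x1 + k21 * x2 + w)) == 0
        assert sp.expand(c2m.odes[1] - (k12 * x1 - k21 * x2)) == 0
        assert c2m.outputs == (x1,)

    def test_hiv_equations_match_canonical_form(self, hiv):
        T_U, T_I, V, lam, rho, delta, N, c, eta = _syms(
            "T_U T_I V lam rho delta N c eta"
        )
        assert sp.expand(hiv.odes[0] - (lam - rho * T_U - eta * T_U * V)) == 0
        assert sp.expand(hiv.odes[1] - (eta * T_U * V - delta * T_I)) == 0
        assert sp.expand(hiv.odes[2] - (N * delta * T_I - c * V)) == 0
        assert sp.expand(hiv.outputs[1] - (T_U + T_I)) == 0

    def test_toggle_switch_reformulated_equations(self, toggle_switch_reformulated):
        m = toggle_switch_reformulated
        x1, x2, k01, k1, nT, w1 = _syms("x1 x2 k01 k1 n_TetR w1")
        expected = k01 + k1 / (1 + (x2 / (1 + w1)) ** nT) - x1
        assert sp.simplify(m.odes[0] - expected) == 0

    @pytest.mark.parametrize(
        "name,nx,nw,ntheta,ny",
        [
            ("c2m", 2, 1, 3, 1),
            ("c2m_k1e_known", 2, 1, 2, 1),
            ("toggle_switch", 2, 0, 10, 2),
            ("toggle_switch_reformulated", 2, 2, 6, 2),
            ("hiv", 3, 1, 5, 2),
        ],
    )
    def test_dimensions(self, name, nx, nw, ntheta, ny):
        m = load_fixture(name)
        assert (m.n_x, m.n_w, m.n_theta, m.n_y) == (nx, nw, ntheta, ny)

    def test_library_contains_all_fixtures(self):
        lib = model_library()
        assert {"c2m", "c2m_k1e_known", "toggle_switch",
                "toggle_switch_reformulated", "hiv"} <= set(lib)

    def test_unknown_initial_condition_marker(self, c2m):
        assert [str(s) for s in c2m.unknown_x0] == ["x2"]


class TestRoundTrip:
    @pytest.mark.parametrize(
        "name", ["c2m", "c2m_original", "toggle_switch", "hiv"]
    )
    def test_dump_load_identity(self, name):
        m = load_fixture(name)
        m2 = loads_model(dumps_model(m))
        assert m2.states == m.states
        assert all(sp.simplify(a - b) == 0 for a, b in zip(m2.odes, m.odes))
        assert all(sp.simplify(a - b) == 0 for a, b in zip(m2.outputs, m.outputs))
        assert m2.params == m.params
        assert m2.init == m.init

    def test_json_export_contains_all_sections(self, c2m):
        import json

        doc = json.loads(c2m.to_json())
        assert doc["states"] == ["x1", "x2"]
        assert doc["init"]["x2"] == "?"


class TestValidation:
    def test_undeclared_symbol_is_rejected_by_name(self):
        text = """
name: bad
states: [x1]
odes: {x1: -k*x1 + mystery}
outputs: [x1]
parameters: [k]
"""
        with pytest.raises(UndeclaredSymbolError, match="mystery"):
            loads_model(text)

    def test_duplicate_declaration_is_structural_error(self):
        text = """
name: bad
states: [x1]
odes: {x1: -x1}
outputs: [x1]
parameters: [x1]
"""
        with pytest.raises(DuplicateSymbolError):
            loads_model(text)


class TestFixParameter:
    def test_moves_parameter_to_constants(self, c2m):
        m = fix_parameter(c2m, "k1e", 1.0)
        assert [str(p) for p in m.params] == ["k12", "k21"]
        assert m.constants[sp.Symbol("k1e")] == 1.0
        assert m.n_theta == c2m.n_theta - 1

    def test_refixing_raises(self, c2m):
        m = fix_parameter(c2m, "k1e", 1.0)
        with pytest.raises(UndeclaredSymbolError):
            fix_parameter(m, "k1e", 2.0)


class TestReformulateInput:
    def test_c2m_gain_times_input_collapses_to_w(self, c2m_original, c2m):
        b, u = _syms("b u")
        m = reformulate_input(c2m_original, "w", b * u)
        assert [str(s) for s in m.unknown_inputs] == ["w"]
        assert "b" not in [str(p) for p in m.params]
        # resulting dynamics coincide with the shipped unknown-input variant
        assert all(sp.simplify(a - e) == 0 for a, e in zip(m.odes, c2m.odes))

    def test_toggle_switch_reformulation_matches_fixture(
        self, toggle_switch, toggle_switch_reformulated
    ):
        aTc, th_a, n_a = _syms("aTc theta_aTc n_aTc")
        IPTG, th_i, n_i = _syms("IPTG theta_IPTG n_IPTG")
        m = reformulate_input(toggle_switch, "w1", (aTc / th_a) ** n_a)
        m = reformulate_input(m, "w2", (IPTG / th_i) ** n_i)
        assert sorted(map(str, m.params)) == sorted(
            map(str, toggle_switch_reformulated.params)
        )
        ref = {str(s): e for s, e in zip(
            toggle_switch_reformulated.states, toggle_switch_reformulated.odes
        )}
        for s, e in zip(m.states, m.odes):
            assert sp.simplify(e - ref[str(s)]) == 0

    def test_absent_expression_raises(self, c2m):
        with pytest.raises(ModelError, match="does not occur"):
            reformulate_input(c2m, "v", sp.Symbol("k12") * sp.Symbol("k21") ** 7)
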