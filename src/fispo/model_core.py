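"""Symbolic ODE models with known/unknown inputs and parameters.

The central object is :class:`OdeModel`, a symbolic description of a system

    dx/dt = f(x, u, w, theta, k),    y = g(x, u, w, theta, k)

where ``x`` are states, ``u`` known (measured) inputs, ``w`` unknown inputs,
``theta`` unknown constant parameters and ``k`` known numeric constants.
Models are read from / written to a small YAML dialect with plain-text math
expressions, and a library of case-study fixtures (a two-compartment
pharmacokinetic model, a genetic toggle switch and an HIV infection model)
ships with the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import sympy as sp
import yaml
from sympy.parsing.sympy_parser import parse_expr, standard_transformations

__all__ = [
    "OdeModel",
    "UNKNOWN_X0",
    "ModelError",
    "UndeclaredSymbolError",
    "DuplicateSymbolError",
    "load_model",
    "loads_model",
    "save_model",
    "dumps_model",
    "fix_parameter",
    "reformulate_input",
    "model_library",
    "load_fixture",
    "FIXTURE_NAMES",
]

#: marker used in model files for an unknown initial condition
UNKNOWN_X0 = "?"

# functions allowed inside model expressions; everything else must be a
# declared symbol (this keeps sympy builtins like N, E, I from shadowing
# model quantities such as a burst size named "N")
_ALLOWED_FUNCS = {
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "exp": sp.exp,
    "log": sp.log,
    "sqrt": sp.sqrt,
    "pi": sp.pi,
    "Abs": sp.Abs,
    # needed by the tokenizer's number/name handling; undeclared names
    # become symbols here and are then rejected by the free-symbol check
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    "Symbol": sp.Symbol,
}


class ModelError(ValueError):
    """Structural problem in a model definition."""


class UndeclaredSymbolError(ModelError):
    """An expression uses a symbol that was not declared in any class."""


class DuplicateSymbolError(ModelError):
    """A symbol was declared in more than one class (or twice in one)."""


def _parse(expr_str: str, local: Mapping[str, sp.Symbol]) -> sp.Expr:
    d = dict(_ALLOWED_FUNCS)
    d.update(local)
    return parse_expr(
        str(expr_str),
        local_dict=d,
        global_dict={},
        transformations=standard_transformations,
        evaluate=True,
    )


@dataclass(frozen=True)
class OdeModel:
    """A nonlinear ODE model with declared symbol classes.

    Parameters
    ----------
    name
        Identifier for reports.
    states
        Ordered state symbols ``x``.
    odes
        Right-hand sides, one expression per state, same order as ``states``.
    outputs
        Output expressions ``g``.
    known_inputs, unknown_inputs
        Ordered input symbols ``u`` and ``w``.
    params
        Ordered unknown-parameter symbols ``theta``.
    constants
        Mapping of known-constant symbols ``k`` to numeric values.
    init
        Mapping state symbol -> numeric initial condition, or ``None`` for a
        declared-unknown initial condition (estimated alongside ``theta``).
    """

    name: str
    states: tuple[sp.Symbol, ...]
    odes: tuple[sp.Expr, ...]
    outputs: tuple[sp.Expr, ...]
    known_inputs: tuple[sp.Symbol, ...] = ()
    unknown_inputs: tuple[sp.Symbol, ...] = ()
    params: tuple[sp.Symbol, ...] = ()
    constants: dict[sp.Symbol, float] = field(default_factory=dict)
    init: dict[sp.Symbol, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- dimensions ------------------------------------------------------
    @property
    def n_x(self) -> int:
        return len(self.states)

    @property
    def n_u(self) -> int:
        return len(self.known_inputs)

    @property
    def n_w(self) -> int:
        return len(self.unknown_inputs)

    @property
    def n_theta(self) -> int:
        return len(self.params)

    @property
    def n_y(self) -> int:
        return len(self.outputs)

    @property
    def unknown_x0(self) -> tuple[sp.Symbol, ...]:
        """States whose initial condition is declared unknown."""
        return tuple(s for s in self.states if self.init.get(s, None) is None)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if len(self.odes) != len(self.states):
            raise ModelError(
                f"{self.name}: {len(self.odes)} equations for "
                f"{len(self.states)} states"
            )
        classes = [
            list(self.states),
            list(self.known_inputs),
            list(self.unknown_inputs),
            list(self.params),
            list(self.constants),
        ]
        seen: set[sp.Symbol] = set()
        for group in classes:
            for s in group:
                if s in seen:
                    raise DuplicateSymbolError(
                        f"{self.name}: symbol {s} declared more than once"
                    )
                seen.add(s)
        for expr in (*self.odes, *self.outputs):
            extra = sp.sympify(expr).free_symbols - seen
            if extra:
                raise UndeclaredSymbolError(
                    f"{self.name}: undeclared symbol(s) "
                    f"{sorted(map(str, extra))} in {expr}"
                )
        for s in self.init:
            if s not in self.states:
                raise ModelError(f"{self.name}: init given for non-state {s}")

    # -- convenience -----------------------------------------------------
    def with_constants_substituted(self) -> "OdeModel":
        """Return a copy with the numeric known constants substituted in."""
        sub = {k: sp.nsimplify(v, rational=True) for k, v in self.constants.items()}
        return replace(
            self,
            odes=tuple(e.subs(sub) for e in self.odes),
            outputs=tuple(e.subs(sub) for e in self.outputs),
            constants={},
        )

    def to_json(self) -> str:
        """Canonical JSON export of the parsed model (for reporting)."""
        return json.dumps(_model_dict(self), indent=2)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _model_dict(m: OdeModel) -> dict:
    return {
        "name": m.name,
        "states": [str(s) for s in m.states],
        "odes": {str(s): str(e) for s, e in zip(m.states, m.odes)},
        "outputs": [str(e) for e in m.outputs],
        "known_inputs": [str(s) for s in m.known_inputs],
        "unknown_inputs": [str(s) for s in m.unknown_inputs],
        "parameters": [str(s) for s in m.params],
        "constants": {str(s): float(v) for s, v in m.constants.items()},
        "init": {
            str(s): (UNKNOWN_X0 if v is None else float(v))
            for s, v in m.init.items()
        },
    }


def loads_model(text: str) -> OdeModel:
    """Parse a model from its YAML text representation."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ModelError("model file is not a mapping")

    def syms(key: str) -> tuple[sp.Symbol, ...]:
        names = doc.get(key) or []
        if len(set(names)) != len(names):
            raise DuplicateSymbolError(f"duplicate names in section '{key}'")
        return tuple(sp.Symbol(str(n)) for n in names)

    states = syms("states")
    known_inputs = syms("known_inputs")
    unknown_inputs = syms("unknown_inputs")
    params = syms("parameters")
    const_doc = doc.get("constants") or {}
    constants = {sp.Symbol(str(n)): float(v) for n, v in const_doc.items()}

    local = {
        str(s): s
        for s in (*states, *known_inputs, *unknown_inputs, *params, *constants)
    }
    odes_doc = doc.get("odes") or {}
    missing = [str(s) for s in states if str(s) not in odes_doc]
    if missing:
        raise ModelError(f"no ODE given for state(s) {missing}")
    odes = tuple(_parse(odes_doc[str(s)], local) for s in states)
    outputs = tuple(_parse(e, local) for e in (doc.get("outputs") or []))

    init_doc = doc.get("init") or {}
    init: dict[sp.Symbol, float | None] = {}
    for n, v in init_doc.items():
        s = sp.Symbol(str(n))
        init[s] = None if (isinstance(v, str) and v.strip() == UNKNOWN_X0) else float(v)

    return OdeModel(
        name=str(doc.get("name", "model")),
        states=states,
        odes=odes,
        outputs=outputs,
        known_inputs=known_inputs,
        unknown_inputs=unknown_inputs,
        params=params,
        constants=constants,
        init=init,
    )


def load_model(path) -> OdeModel:
    """Load a model from a YAML model file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_model(fh.read())


def dumps_model(m: OdeModel) -> str:
    """Serialize a model to canonical YAML text (round-trips with loads)."""
    return yaml.safe_dump(_model_dict(m), sort_keys=False, default_flow_style=None)


def save_model(m: OdeModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_model(m))


# ---------------------------------------------------------------------------
# model surgery
# ---------------------------------------------------------------------------

def fix_parameter(m: OdeModel, sym, value: float) -> OdeModel:
    """Move an unknown parameter into the known constants with a value.

    Used when the analysis finds a parameter combination unidentifiable and
    one member must be assumed known for the rest to become observable.
    """
    sym = sp.Symbol(str(sym))
    if sym not in m.params:
        raise UndeclaredSymbolError(f"{sym} is not an unknown parameter of {m.name}")
    constants = dict(m.constants)
    constants[sym] = float(value)
    return replace(
        m,
        params=tuple(p for p in m.params if p != sym),
        constants=constants,
        name=f"{m.name}_{sym}_known",
    )


def reformulate_input(
    m: OdeModel,
    new_input,
    replaced_expr,
    *,
    name: str | None = None,
) -> OdeModel:
    """Absorb an unidentifiable expression into a new unknown input.

    Every occurrence of ``replaced_expr`` in the dynamics and outputs is
    replaced by the fresh symbol ``new_input``; the parameters/inputs that
    appeared only inside the absorbed expression are dropped from their
    symbol classes.  A typical use is collapsing ``b*u(t)`` (unidentifiable
    gain times unknown signal) into a single unknown input ``w(t)``.
    """
    new_input = sp.Symbol(str(new_input))
    local = {
        str(s): s
        for s in (*m.states, *m.known_inputs, *m.unknown_inputs, *m.params, *m.constants)
    }
    expr = _parse(str(replaced_expr), local) if isinstance(replaced_expr, str) else sp.sympify(replaced_expr)

    occurs = any(e.has(expr) for e in (*m.odes, *m.outputs))
    if not occurs:
        raise ModelError(f"expression {expr} does not occur in {m.name}")

    odes = tuple(e.subs(expr, new_input) for e in m.odes)
    outputs = tuple(e.subs(expr, new_input) for e in m.outputs)

    absorbed = expr.free_symbols - set(m.states) - set(m.constants)
    still_free: set[sp.Symbol] = set()
    for e in (*odes, *outputs):
        still_free |= e.free_symbols & absorbed
    if still_free:
        raise ModelError(
            f"incomplete reformulation: {sorted(map(str, still_free))} "
            "remain free after substituting the new input"
        )

    return OdeModel(
        name=name or f"{m.name}_reformulated",
        states=m.states,
        odes=odes,
        outputs=outputs,
        known_inputs=tuple(s for s in m.known_inputs if s not in absorbed),
        unknown_inputs=tuple(s for s in m.unknown_inputs if s not in absorbed)
        + (new_input,),
        params=tuple(s for s in m.params if s not in absorbed),
        constants=dict(m.constants),
        init=dict(m.init),
    )


# ---------------------------------------------------------------------------
# fixture library
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "c2m_original": "c2m_original.yml",
    "c2m": "c2m.yml",
    "toggle_switch": "toggle_switch.yml",
    "toggle_switch_reformulated": "toggle_switch_reformulated.yml",
    "hiv": "hiv.yml",
}

#: default assumed-known degradation constant for the identifiable C2M variant
C2M_K1E_VALUE = 0.4

FIXTURE_NAMES: tuple[str, ...] = tuple(_FIXTURE_FILES) + ("c2m_k1e_known",)


def load_fixture(name: str) -> OdeModel:
    """Load one bundled case-study model by name."""
    if name == "c2m_k1e_known":
        return fix_parameter(load_fixture("c2m"), "k1e", C2M_K1E_VALUE)
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_NAMES)}"
        ) from None
    text = resources.files("fispo").joinpath("models", fname).read_text("utf-8")
    return loads_model(text)


def model_library() -> dict[str, OdeModel]:
    """All bundled case-study models keyed by name."""
    return {n: load_fixture(n) for n in FIXTURE_NAMES}
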