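"""Pseudo-experimental datasets for the three case studies.

Each scenario fixes the "true" system — nominal parameters, initial
conditions and a known shape for every unknown input (piecewise constant,
ramp or cosine) — simulates the model, samples the outputs on a regular
grid and optionally adds independent Gaussian noise with known standard
deviations (a fixed fraction of each output's range).  The generator also
emits a ground-truth record so that estimates can be scored against the
values that actually produced the data.

Six bundled scenarios cover the case studies: the two-compartment model
with a ramp input (noiseless single experiment, and a noisy six-experiment
scheme), the reformulated toggle switch with piecewise-constant inputs
(noiseless, and a noisy four-experiment scheme with constant inputs per
experiment), and the HIV model with a slowly varying cosine infection rate
(noiseless and noisy, one experiment each — one experiment corresponds to
one patient, and patient-specific parameters forbid pooling).

Nominal values are package defaults of order 0.1-10 (the HIV model uses
rescaled units); recovery is always scored relative to the recorded truth,
so conclusions do not hinge on the specific nominals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .estimation import (
    Experiment,
    PiecewiseInput,
    SolveBudget,
    TrackingProblem,
    TrackingResult,
    simulate,
)
from .model_core import OdeModel, load_fixture

__all__ = [
    "InputSignal",
    "ExperimentSpec",
    "ScenarioSpec",
    "generate",
    "make_tracking_problem",
    "score_recovery",
    "case_study_scenarios",
]


@dataclass(frozen=True)
class InputSignal:
    """A closed-form true input: constant, piecewise constant, ramp or cosine."""

    kind: str
    params: dict

    def __call__(self, t):
        p = self.params
        if self.kind == "constant":
            return np.full_like(np.asarray(t, dtype=float), p["value"]) if np.ndim(t) else p["value"]
        if self.kind == "ramp":
            return p["intercept"] + p["slope"] * np.asarray(t, dtype=float)
        if self.kind == "piecewise_constant":
            idx = np.searchsorted(np.asarray(p["switch_times"], dtype=float), t, side="right")
            return np.asarray(p["levels"], dtype=float)[idx]
        if self.kind == "cosine":
            return p["offset"] + p["amplitude"] * np.cos(
                2.0 * math.pi * np.asarray(t, dtype=float) / p["period"]
            )
        raise ValueError(f"unknown input kind {self.kind!r}")

    def derivative(self, t, order: int = 1):
        """Time derivative of the signal (piecewise kinds: away from jumps)."""
        p = self.params
        t = np.asarray(t, dtype=float)
        if self.kind in ("constant", "piecewise_constant"):
            return np.zeros_like(t)
        if self.kind == "ramp":
            return np.full_like(t, p["slope"]) if order == 1 else np.zeros_like(t)
        if self.kind == "cosine":
            om = 2.0 * math.pi / p["period"]
            return p["amplitude"] * om ** order * np.cos(
                om * t + order * math.pi / 2.0
            )
        raise ValueError(f"unknown input kind {self.kind!r}")


def constant(value):
    return InputSignal("constant", {"value": float(value)})


def ramp(intercept, slope):
    return InputSignal("ramp", {"intercept": float(intercept), "slope": float(slope)})


def piecewise_constant(levels, switch_times):
    return InputSignal(
        "piecewise_constant",
        {"levels": [float(v) for v in levels],
         "switch_times": [float(t) for t in switch_times]},
    )


def cosine(offset, amplitude, period):
    return InputSignal(
        "cosine",
        {"offset": float(offset), "amplitude": float(amplitude),
         "period": float(period)},
    )


@dataclass(frozen=True)
class ExperimentSpec:
    """True initial state and input signals for one experiment."""

    x0: dict                 # state name -> true initial value
    w: dict                  # unknown-input name -> InputSignal
    u: dict = field(default_factory=dict)  # known-input name -> InputSignal


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete pseudo-experimental study: truth, sampling and estimator."""

    name: str
    model_name: str
    theta: dict              # true parameter values
    experiments: tuple       # ExperimentSpec per experiment
    t0: float
    tf: float
    n_samples: int
    sigma_frac: float        # noise sd as fraction of output range; 0 = none
    seed: int
    estimator: dict          # basis/n_e/bounds/objective/refinements

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def noisy(self) -> bool:
        return self.sigma_frac > 0


def generate(spec: ScenarioSpec, seed: int | None = None):
    """Simulate a scenario and return ``(experiments, truth)``.

    With ``sigma_frac == 0`` the data equal the simulated outputs exactly
    (and unit sigmas are recorded for least-squares weighting); otherwise
    independent Gaussian noise N(0, sigma_ijk^2) is added, with sigma_ijk
    equal to ``sigma_frac`` times the range of output j in experiment k.
    Bit-reproducible for a given seed (default: the scenario's own).
    """
    model = load_fixture(spec.model_name)
    t = np.linspace(spec.t0, spec.tf, spec.n_samples)
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    experiments, truth_x0, truth_w = [], {}, {}
    for k, es in enumerate(spec.experiments):
        x0 = [es.x0[str(s)] for s in model.states]
        u = {name: sig for name, sig in es.u.items()}
        w = {name: sig for name, sig in es.w.items()}
        _, y = simulate(model, spec.theta, x0, u=u, w=w, t_grid=t)
        if spec.sigma_frac > 0:
            rng_k = np.random.default_rng(rng.integers(2**31 - 1))
            span = y.max(axis=0) - y.min(axis=0)
            sig = np.maximum(spec.sigma_frac * span, 1e-12)
            sigma = np.tile(sig, (len(t), 1))
            y = y + rng_k.normal(0.0, 1.0, size=y.shape) * sigma
        else:
            sigma = np.ones_like(y)
        eid = f"exp{k + 1}"
        experiments.append(
            Experiment(id=eid, t=t, y=y, sigma=sigma, u=u)
        )
        truth_x0[eid] = dict(es.x0)
        truth_w[eid] = dict(es.w)

    truth = {"theta": dict(spec.theta), "x0": truth_x0, "w": truth_w}
    return experiments, truth


def make_tracking_problem(spec: ScenarioSpec, experiments) -> TrackingProblem:
    """Assemble the tracking problem a user would pose for this scenario."""
    model = load_fixture(spec.model_name)
    est = spec.estimator
    pw = {
        wname: PiecewiseInput(
            kind=est.get("basis", "linear"),
            n_e=est.get("n_e", 1),
            t0=spec.t0,
            tf=spec.tf,
        )
        for wname in map(str, model.unknown_inputs)
    }
    return TrackingProblem(
        model=model,
        experiments=list(experiments),
        input_param=pw,
        theta_bounds=dict(est["theta_bounds"]),
        x0_bounds=dict(est.get("x0_bounds", {})),
        w_bounds={str(wn): tuple(est["w_bounds"]) for wn in model.unknown_inputs}
        if not isinstance(est["w_bounds"], dict)
        else {k: tuple(v) for k, v in est["w_bounds"].items()},
        objective="nll" if spec.noisy else "wls",
    )


def score_recovery(
    problem: TrackingProblem,
    result: TrackingResult,
    truth: dict,
    std: dict | None = None,
) -> dict:
    """Relative errors of every recovered unknown against the ground truth.

    Input trajectories are compared node-wise: the true signal is evaluated
    at the estimator's node times.  If ``std`` (from
    :func:`fispo.estimation.estimate_uncertainty`) is given, z-scores
    |error|/std are reported as well.
    """
    model = problem.model
    rel, z = {}, {}

    for name, true_v in truth["theta"].items():
        if name not in result.theta_hat:
            continue
        err = result.theta_hat[name] - true_v
        rel[name] = abs(err) / max(abs(true_v), 1e-12)
        if std and name in std and std[name] > 0:
            z[name] = abs(err) / std[name]

    unknown = {str(s) for s in model.unknown_x0}
    for eid, x0s in truth["x0"].items():
        for sname, true_v in x0s.items():
            if sname not in unknown:
                continue
            key = f"{eid}:{sname}0"
            est_v = result.x0_hat[eid][sname]
            rel[key] = abs(est_v - true_v) / max(abs(true_v), 1e-12)
            if std and key in std and std[key] > 0:
                z[key] = abs(est_v - true_v) / std[key]

    for eid, wsigs in truth["w"].items():
        for wname, sig in wsigs.items():
            pwi = problem.input_param[wname]
            tn = pwi.node_times
            true_nodes = np.asarray(sig(tn), dtype=float)
            est_nodes = np.asarray(result.w_nodes[eid][wname], dtype=float)
            for k, (tv, ev) in enumerate(zip(true_nodes, est_nodes)):
                key = f"{eid}:{wname}[{k}]"
                rel[key] = abs(ev - tv) / max(abs(tv), 1e-12)
                if std and key in std and std[key] > 0:
                    z[key] = abs(ev - tv) / std[key]

    out = {"rel_errors": rel, "max_rel_error": max(rel.values())}
    if z:
        out["z_scores"] = z
        out["max_z"] = max(z.values())
    return out


# ---------------------------------------------------------------------------
# bundled scenarios
# ---------------------------------------------------------------------------

_C2M_EST = {
    "basis": "linear",
    "n_e": 1,
    "theta_bounds": {"k12": (0.05, 5.0), "k21": (0.05, 5.0)},
    "x0_bounds": {"x2": (0.0, 5.0)},
    "w_bounds": (0.0, 5.0),
}

_TS_EST = {
    "basis": "constant",
    "n_e": 2,
    "theta_bounds": {
        "k01": (0.01, 2.0),
        "k1": (0.1, 10.0),
        "n_TetR": (1.0, 6.0),
        "k02": (0.01, 2.0),
        "k2": (0.1, 10.0),
        "n_LacI": (1.0, 6.0),
    },
    "w_bounds": (0.01, 5.0),
}

_HIV_EST = {
    "basis": "linear",
    "n_e": 1,            # refined 1 -> 2 -> 4 by element doubling
    "refinements": 2,
    "theta_bounds": {
        "lam": (0.1, 10.0),
        "rho": (0.01, 1.0),
        "delta": (0.05, 5.0),
        "N": (1.0, 100.0),
        "c": (0.3, 30.0),
    },
    "w_bounds": (0.001, 0.1),
}

_C2M_THETA = {"k12": 0.8, "k21": 0.6}
_TS_THETA = {
    "k01": 0.2, "k1": 2.5, "n_TetR": 2.0,
    "k02": 0.3, "k2": 2.0, "n_LacI": 3.0,
}
_HIV_THETA = {"lam": 1.0, "rho": 0.1, "delta": 0.5, "N": 10.0, "c": 3.0}
_HIV_X0 = {"T_U": 10.0, "T_I": 0.5, "V": 2.0}
_HIV_ETA = cosine(offset=0.02, amplitude=0.01, period=400.0)


def _c2m_exps(n: int) -> tuple:
    """Ramp-input experiments with distinct ramps and initial conditions."""
    out = []
    for k in range(n):
        out.append(
            ExperimentSpec(
                x0={"x1": 1.0, "x2": 0.3 + 0.1 * k},
                w={"w": ramp(0.4 + 0.1 * k, 0.10 + 0.02 * k)},
            )
        )
    return tuple(out)


#: distinct constant (w1, w2) levels for the four-experiment noisy scheme
_TS_LEVELS = [(0.3, 1.2), (1.5, 0.2), (0.6, 2.0), (2.5, 0.8)]


def case_study_scenarios() -> dict:
    """The six bundled scenarios keyed by name."""
    ts_x0 = {"x1": 1.2, "x2": 0.8}
    scenarios = [
        ScenarioSpec(
            name="c2m_noiseless",
            model_name="c2m_k1e_known",
            theta=_C2M_THETA,
            experiments=_c2m_exps(1),
            t0=0.0, tf=10.0, n_samples=20,
            sigma_frac=0.0, seed=101,
            estimator=_C2M_EST,
        ),
        ScenarioSpec(
            name="c2m_noisy",
            model_name="c2m_k1e_known",
            theta=_C2M_THETA,
            experiments=_c2m_exps(6),
            t0=0.0, tf=10.0, n_samples=20,
            sigma_frac=0.05, seed=102,
            estimator=_C2M_EST,
        ),
        ScenarioSpec(
            name="ts_noiseless",
            model_name="toggle_switch_reformulated",
            theta=_TS_THETA,
            experiments=(
                ExperimentSpec(
                    x0=ts_x0,
                    w={
                        "w1": piecewise_constant((0.3, 1.5), (5.0,)),
                        "w2": piecewise_constant((1.2, 0.4), (5.0,)),
                    },
                ),
            ),
            t0=0.0, tf=10.0, n_samples=20,
            sigma_frac=0.0, seed=103,
            estimator=_TS_EST,
        ),
        ScenarioSpec(
            name="ts_noisy",
            model_name="toggle_switch_reformulated",
            theta=_TS_THETA,
            experiments=tuple(
                ExperimentSpec(x0=ts_x0, w={"w1": constant(l1), "w2": constant(l2)})
                for l1, l2 in _TS_LEVELS
            ),
            t0=0.0, tf=10.0, n_samples=20,
            sigma_frac=0.05, seed=104,
            estimator={**_TS_EST, "n_e": 1},
        ),
        ScenarioSpec(
            name="hiv_noiseless",
            model_name="hiv",
            theta=_HIV_THETA,
            experiments=(ExperimentSpec(x0=_HIV_X0, w={"eta": _HIV_ETA}),),
            t0=0.0, tf=50.0, n_samples=25,
            sigma_frac=0.0, seed=105,
            estimator=_HIV_EST,
        ),
        ScenarioSpec(
            name="hiv_noisy",
            model_name="hiv",
            theta=_HIV_THETA,
            experiments=(ExperimentSpec(x0=_HIV_X0, w={"eta": _HIV_ETA}),),
            t0=0.0, tf=50.0, n_samples=25,
            sigma_frac=0.05, seed=106,
            estimator=_HIV_EST,
        ),
    ]
    return {s.name: s for s in scenarios}


def truth_to_json(truth: dict, problem: TrackingProblem | None = None) -> str:
    """Serialize a ground-truth record (inputs as node values if possible)."""
    doc = {"theta": truth["theta"], "x0": truth["x0"], "w": {}}
    for eid, wsigs in truth["w"].items():
        doc["w"][eid] = {}
        for wname, sig in wsigs.items():
            entry = {"kind": sig.kind, "params": sig.params}
            if problem is not None and wname in problem.input_param:
                tn = problem.input_param[wname].node_times
                entry["node_times"] = [float(x) for x in tn]
                entry["node_values"] = [float(v) for v in np.atleast_1d(sig(tn))]
            doc["w"][eid][wname] = entry
    return json.dumps(doc, indent=2)
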