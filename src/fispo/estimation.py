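"""Joint estimation of parameters, initial conditions and unknown inputs.

Once a model is known to be fully observable, the practical problem is to
recover its unknowns from output time series.  This is posed as an optimal
tracking problem: each unknown input w(t) is discretized as a piecewise
linear (or piecewise constant) function of a small number of node values,
and the node values are estimated *jointly* with the unknown constant
parameters and any unknown initial conditions by minimising either

* the negative Gaussian log-likelihood with known per-point standard
  deviations sigma (noisy data), or
* a weighted least-squares cost with unit weights (noiseless data),

subject to box bounds on every decision variable.  The decision vector is

    [ theta ; unknown x0 (per experiment) ; input nodes (per experiment) ]

with theta shared across all experiments.  The solver is a seeded hybrid:
a population-based global phase (differential evolution) followed by a
bounded derivative-based local polish (L-BFGS-B).  Input discretizations
can be refined by doubling the number of elements and warm-starting from
the interpolated coarse solution, which can never increase the cost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import ODEintWarning, odeint, solve_ivp

# integrator complaints at infeasible trial points are handled by penalties
warnings.filterwarnings("ignore", category=ODEintWarning)
from scipy.optimize import differential_evolution, least_squares

from .model_core import OdeModel

__all__ = [
    "PiecewiseInput",
    "Experiment",
    "TrackingProblem",
    "TrackingResult",
    "SolveBudget",
    "SimulationFailure",
    "parameterize_input",
    "simulate",
    "objective",
    "solve",
    "refine_elements",
    "estimate_uncertainty",
    "experiments_to_frame",
    "frame_to_experiments",
]

#: default integration tolerances (loose enough for speed, tight enough
#: that the discretization, not the integrator, limits accuracy)
RTOL, ATOL = 1e-8, 1e-10

#: finite cost assigned to decision vectors whose simulation fails
INFEASIBLE_COST = 1e10


class SimulationFailure(RuntimeError):
    """The ODE integrator did not reach the end of the horizon."""


# ---------------------------------------------------------------------------
# input discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiecewiseInput:
    """A piecewise-linear or piecewise-constant input discretization.

    ``linear``: ``n_e`` equidistant elements with ``n_e + 1`` node values;
    the input is the continuous piecewise-linear interpolant.
    ``constant``: ``n_e`` equidistant segments with one level each.
    """

    kind: str
    n_e: int
    t0: float
    tf: float

    def __post_init__(self):
        if self.kind not in ("linear", "constant"):
            raise ValueError(f"unknown input basis {self.kind!r}")
        if self.n_e < 1:
            raise ValueError("need at least one element")
        if not self.tf > self.t0:
            raise ValueError("tf must exceed t0")

    @property
    def n_nodes(self) -> int:
        return self.n_e + 1 if self.kind == "linear" else self.n_e

    @property
    def node_times(self) -> np.ndarray:
        if self.kind == "linear":
            return np.linspace(self.t0, self.tf, self.n_e + 1)
        edges = np.linspace(self.t0, self.tf, self.n_e + 1)
        return 0.5 * (edges[:-1] + edges[1:])  # segment midpoints

    def __call__(self, values, t):
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_nodes,):
            raise ValueError(
                f"expected {self.n_nodes} node values, got {values.shape}"
            )
        if self.kind == "linear":
            return np.interp(t, self.node_times, values)
        edges = np.linspace(self.t0, self.tf, self.n_e + 1)
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, self.n_e - 1)
        return values[idx]

    def refine(self) -> "PiecewiseInput":
        """The same family with twice the number of elements."""
        return replace(self, n_e=2 * self.n_e)

    def interpolate_to(self, fine: "PiecewiseInput", values) -> np.ndarray:
        """Node values in ``fine`` reproducing this input exactly.

        Piecewise-linear and piecewise-constant spaces are nested under
        element doubling, so the coarse solution is represented exactly.
        """
        if self.kind == "linear":
            return np.interp(fine.node_times, self.node_times, np.asarray(values, float))
        return self(values, fine.node_times)


def parameterize_input(
    n_e: int, t0: float, tf: float, bounds=None, kind: str = "linear"
) -> PiecewiseInput:
    """Equidistant piecewise input discretization over [t0, tf]."""
    del bounds  # bounds live on the tracking problem
    return PiecewiseInput(kind=kind, n_e=n_e, t0=t0, tf=tf)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_RHS_CACHE: dict = {}


def _compile(model: OdeModel):
    key = (model.name, tuple(str(e) for e in model.odes), tuple(str(e) for e in model.outputs))
    if key in _RHS_CACHE:
        return _RHS_CACHE[key]
    mc = model.with_constants_substituted()
    args = (
        list(mc.states)
        + list(mc.params)
        + list(mc.known_inputs)
        + list(mc.unknown_inputs)
    )
    f = sp.lambdify(args, list(mc.odes), modules="math")
    g = sp.lambdify(args, list(mc.outputs), modules="math")
    _RHS_CACHE[key] = (f, g)
    return f, g


def _as_func(v):
    if callable(v):
        return v
    return lambda t, _v=float(v): _v


def simulate(
    model: OdeModel,
    theta: dict,
    x0,
    u=None,
    w=None,
    t_grid=None,
    rtol: float = RTOL,
    atol: float = ATOL,
    dense: bool = False,
):
    """Integrate the model and return (states, outputs) on ``t_grid``.

    ``theta`` maps parameter names to values; ``u`` and ``w`` map input
    names to callables of time (or constants).  Raises
    :class:`SimulationFailure` if the integrator cannot reach the horizon.
    """
    f, g = _compile(model)
    t_grid = np.asarray(t_grid, dtype=float)
    th = [float(theta[str(p)]) for p in model.params]
    ufs = [_as_func((u or {})[str(s)]) for s in model.known_inputs]
    wfs = [_as_func((w or {})[str(s)]) for s in model.unknown_inputs]

    def rhs(t, x):
        vals = [*x, *th, *(uf(t) for uf in ufs), *(wf(t) for wf in wfs)]
        return f(*vals)

    if len(t_grid) == 1 or t_grid[-1] == t_grid[0]:
        # degenerate horizon: the state is the initial condition
        states = np.tile(np.asarray(x0, dtype=float), (len(t_grid), 1))
        outputs = np.array(
            [
                g(*states[i], *th, *(uf(t) for uf in ufs), *(wf(t) for wf in wfs))
                for i, t in enumerate(t_grid)
            ],
            dtype=float,
        )
        return states, outputs

    with np.errstate(all="ignore"):
        if dense:
            sol = solve_ivp(
                rhs,
                (t_grid[0], t_grid[-1]),
                np.asarray(x0, dtype=float),
                t_eval=t_grid,
                method="LSODA",
                rtol=rtol,
                atol=atol,
                dense_output=True,
            )
            if not sol.success or sol.y.shape[1] != len(t_grid):
                raise SimulationFailure(sol.message)
            states = sol.y.T
        else:
            # odeint (lsoda) has much lower per-call overhead than solve_ivp
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ODEintWarning)
                states, info = odeint(
                    rhs,
                    np.asarray(x0, dtype=float),
                    t_grid,
                    rtol=rtol,
                    atol=atol,
                    tfirst=True,
                    full_output=True,
                    mxstep=5000,
                    printmessg=False,
                )
            if info["message"] != "Integration successful." or not np.all(
                np.isfinite(states)
            ):
                raise SimulationFailure(info["message"])
    outputs = np.array(
        [
            g(*states[i], *th, *(uf(t) for uf in ufs), *(wf(t) for wf in wfs))
            for i, t in enumerate(t_grid)
        ],
        dtype=float,
    )
    return states, outputs


# ---------------------------------------------------------------------------
# problem definition
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    """One dataset: a time grid, measured outputs and their sigmas."""

    id: str
    t: np.ndarray
    y: np.ndarray          # shape (n_t, n_y)
    sigma: np.ndarray      # same shape; >0 where the likelihood is used
    u: dict = field(default_factory=dict)   # known-input trajectories
    x0_known: dict = field(default_factory=dict)  # state name -> value

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))


@dataclass
class TrackingProblem:
    """An optimal tracking instance: model, data, discretization, bounds."""

    model: OdeModel
    experiments: list
    input_param: dict               # w name -> PiecewiseInput
    theta_bounds: dict              # param name -> (lo, hi)
    x0_bounds: dict = field(default_factory=dict)   # state name -> (lo, hi)
    w_bounds: dict = field(default_factory=dict)    # w name -> (lo, hi)
    objective: str = "wls"          # 'wls' | 'nll'
    constraints: list = field(default_factory=list)  # penalty expressions
    constraint_weight: float = 1e6
    rtol: float = RTOL              # integration tolerances for this problem
    atol: float = ATOL

    def __post_init__(self):
        ny = self.model.n_y
        for e in self.experiments:
            if e.y.shape[1] != ny:
                raise ValueError(
                    f"experiment {e.id}: {e.y.shape[1]} output columns, "
                    f"model has {ny}"
                )
            if self.objective == "nll" and not np.all(e.sigma > 0):
                raise ValueError("likelihood objective requires sigma > 0")
        for lo, hi in {**self.theta_bounds, **self.x0_bounds, **self.w_bounds}.values():
            if not lo <= hi:
                raise ValueError("lower bound exceeds upper bound")

    # -- decision vector layout -----------------------------------------
    def decision_names(self) -> list[str]:
        names = [str(p) for p in self.model.params]
        for e in self.experiments:
            for s in self.model.unknown_x0:
                if str(s) not in e.x0_known:
                    names.append(f"{e.id}:{s}0")
        for e in self.experiments:
            for wname, pw in self.input_param.items():
                names += [f"{e.id}:{wname}[{k}]" for k in range(pw.n_nodes)]
        return names

    def decision_bounds(self) -> list[tuple[float, float]]:
        bounds = [self.theta_bounds[str(p)] for p in self.model.params]
        for e in self.experiments:
            for s in self.model.unknown_x0:
                if str(s) not in e.x0_known:
                    bounds.append(self.x0_bounds[str(s)])
        for e in self.experiments:
            for wname, pw in self.input_param.items():
                bounds += [self.w_bounds[wname]] * pw.n_nodes
        return bounds

    def unpack(self, x):
        """Split a decision vector into (theta, x0 per exp, w nodes per exp)."""
        x = np.asarray(x, dtype=float)
        i = self.model.n_theta
        theta = {str(p): x[k] for k, p in enumerate(self.model.params)}
        x0s, wnodes = {}, {}
        for e in self.experiments:
            x0 = []
            for s in self.model.states:
                v = self.model.init.get(s, None)
                if v is not None:
                    x0.append(v)
                elif str(s) in e.x0_known:
                    x0.append(e.x0_known[str(s)])
                else:
                    x0.append(x[i])
                    i += 1
            x0s[e.id] = np.array(x0)
        for e in self.experiments:
            wnodes[e.id] = {}
            for wname, pw in self.input_param.items():
                wnodes[e.id][wname] = x[i : i + pw.n_nodes].copy()
                i += pw.n_nodes
        if i != len(x):
            raise ValueError(f"decision vector length {len(x)}, expected {i}")
        return theta, x0s, wnodes

    def simulate_experiment(self, e: Experiment, theta, x0, wnodes, t_grid=None):
        w = {
            wname: (lambda t, _pw=pw, _v=wnodes[wname]: _pw(_v, t))
            for wname, pw in self.input_param.items()
        }
        grid = e.t if t_grid is None else t_grid
        return simulate(self.model, theta, x0, u=e.u, w=w, t_grid=grid,
                        rtol=self.rtol, atol=self.atol)


def residuals(problem: TrackingProblem, x) -> np.ndarray:
    """Sigma-scaled residual vector (large constants if simulation fails).

    Both objectives are monotone in the squared norm of this vector (the
    likelihood's normalizer does not depend on the decision variables), so
    it is the natural quantity for Gauss-Newton refinement.
    """
    n_res = sum(e.y.size for e in problem.experiments)
    try:
        theta, x0s, wnodes = problem.unpack(x)
        rs = []
        for e in problem.experiments:
            _, yhat = problem.simulate_experiment(e, theta, x0s[e.id], wnodes[e.id])
            rs.append(((yhat - e.y) / e.sigma).ravel())
        r = np.concatenate(rs)
        if not np.all(np.isfinite(r)):
            return np.full(n_res, 1e6)
        return r
    except SimulationFailure:
        return np.full(n_res, 1e6)


def objective(problem: TrackingProblem, x) -> float:
    """Cost of a decision vector (finite penalty on simulation failure)."""
    try:
        theta, x0s, wnodes = problem.unpack(x)
        total = 0.0
        for e in problem.experiments:
            _, yhat = problem.simulate_experiment(e, theta, x0s[e.id], wnodes[e.id])
            r = yhat - e.y
            if problem.objective == "nll":
                total += float(
                    np.sum(0.5 * (r / e.sigma) ** 2)
                    + np.sum(np.log(np.sqrt(2.0 * math.pi) * e.sigma))
                )
            else:
                total += float(np.sum(r ** 2))
        for c in problem.constraints:
            total += problem.constraint_weight * max(0.0, float(c(theta))) ** 2
        if not np.isfinite(total):
            return INFEASIBLE_COST
        return total
    except SimulationFailure:
        return INFEASIBLE_COST


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

@dataclass
class SolveBudget:
    """Evaluation budget for the hybrid global + local strategy.

    ``de_popsize`` is a per-dimension multiplier (scipy convention).  The
    local phase polishes the ``polish_starts`` best sufficiently distinct
    population members with L-BFGS-B; ``polish_eps`` is the finite
    difference step, chosen well above the ODE integration noise, and the
    winner gets a second pass with a 10x smaller step to sharpen the
    optimum.
    """

    de_popsize: int = 6
    de_maxiter: int = 40
    polish_maxiter: int = 400
    polish_starts: int = 3
    polish_eps: float = 1e-6


@dataclass
class TrackingResult:
    """Solution of a tracking problem."""

    theta_hat: dict
    x0_hat: dict                 # exp id -> {state name: value}
    w_nodes: dict                # exp id -> {w name: node values}
    cost: float
    x: np.ndarray                # raw decision vector
    n_evaluations: int
    seed: int
    trajectories: dict = field(default_factory=dict)  # exp id -> (x, y) arrays
    refinement_history: list = field(default_factory=list)  # (n_e, cost)
    problem: "TrackingProblem | None" = None  # problem the solution refers to


def solve(
    problem: TrackingProblem,
    budget: SolveBudget | None = None,
    seed: int = 0,
    warm_start=None,
) -> TrackingResult:
    """Hybrid seeded optimization of a tracking problem.

    A population global phase (differential evolution, optionally seeded
    with a warm-start member) is followed by a bounded L-BFGS-B polish.
    Re-running with the same seed reproduces the result.
    """
    budget = budget or SolveBudget()
    bounds = problem.decision_bounds()
    n = len(bounds)
    evals = [0]
    lo = np.array([l for l, _ in bounds])
    hi = np.array([h for _, h in bounds])

    # the global phase searches log-scale coordinates wherever the bounds
    # are strictly positive: decade-wide boxes around unknown magnitudes
    # are explored multiplicatively, which separates scaling ridges (e.g.
    # proportional inflation of a production/clearance pair) much better
    # than uniform linear sampling
    log_mask = lo > 0.0

    def to_external(z):
        x = np.asarray(z, dtype=float).copy()
        x[log_mask] = np.exp(x[log_mask])
        return x

    def to_internal(x):
        z = np.asarray(x, dtype=float).copy()
        z[log_mask] = np.log(np.maximum(z[log_mask], 1e-300))
        return z

    ilo, ihi = to_internal(lo), to_internal(hi)

    def fun(z):
        evals[0] += 1
        return objective(problem, to_external(z))

    rng = np.random.default_rng(seed)
    # population size scales with dimension, as is standard for DE
    n_members = max(budget.de_popsize * n, 15)
    init = rng.uniform(ilo, ihi, size=(n_members, n))
    if warm_start is not None:
        init[0] = to_internal(np.clip(warm_start, lo, hi))

    de = differential_evolution(
        fun,
        list(zip(ilo, ihi)),
        init=init,
        maxiter=budget.de_maxiter,
        seed=int(rng.integers(2**31 - 1)),
        tol=1e-10,
        polish=False,
    )

    # local phase: polish the best few distinct population members
    span = ihi - ilo
    order = np.argsort(de.population_energies)
    starts = []
    for idx in order:
        cand = de.population[idx]
        if any(np.max(np.abs(cand - s) / span) < 0.01 for s in starts):
            continue
        starts.append(cand)
        if len(starts) >= budget.polish_starts:
            break
    starts = [to_external(s) for s in starts]
    if warm_start is not None:
        starts.append(np.clip(warm_start, lo, hi))

    def res_fun(x):
        evals[0] += 1
        return residuals(problem, x)

    best, best_cost = to_external(de.x), float(de.fun)
    for s in starts:
        # strictly interior start (trf requires it)
        s = np.clip(s, lo + 1e-12 * (hi - lo), hi - 1e-12 * (hi - lo))
        ls = least_squares(
            res_fun,
            s,
            bounds=(lo, hi),
            method="trf",
            diff_step=budget.polish_eps,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=budget.polish_maxiter,
        )
        cand_cost = objective(problem, ls.x)
        if cand_cost < best_cost:
            best, best_cost = ls.x, float(cand_cost)

    # deep polish: re-refine the winner with a tighter integrator and a
    # finer difference step, to walk down the last stretch of the (often
    # very sloppy) valley that the standard-tolerance gradient noise hides
    deep = replace(problem, rtol=min(problem.rtol, 1e-10),
                   atol=min(problem.atol, 1e-12))
    ls = least_squares(
        lambda x: residuals(deep, x),
        np.clip(best, lo + 1e-12 * (hi - lo), hi - 1e-12 * (hi - lo)),
        bounds=(lo, hi),
        method="trf",
        diff_step=budget.polish_eps / 10.0,
        xtol=1e-15,
        ftol=1e-15,
        gtol=5e-16,
        max_nfev=budget.polish_maxiter,
    )
    evals[0] += ls.nfev
    cand_cost = objective(problem, ls.x)
    if cand_cost < best_cost:
        best, best_cost = ls.x, float(cand_cost)

    if objective(problem, best) >= INFEASIBLE_COST:
        raise RuntimeError(
            "optimization budget exhausted without a feasible simulation"
        )

    theta, x0s, wnodes = problem.unpack(best)
    traj = {}
    for e in problem.experiments:
        xs, ys = problem.simulate_experiment(e, theta, x0s[e.id], wnodes[e.id])
        traj[e.id] = (xs, ys)
    x0_hat = {
        e.id: {
            str(s): float(x0s[e.id][k])
            for k, s in enumerate(problem.model.states)
        }
        for e in problem.experiments
    }
    ne0 = {w: pw.n_e for w, pw in problem.input_param.items()}
    return TrackingResult(
        theta_hat={k: float(v) for k, v in theta.items()},
        x0_hat=x0_hat,
        w_nodes=wnodes,
        cost=best_cost,
        x=np.asarray(best, dtype=float),
        n_evaluations=evals[0],
        seed=seed,
        trajectories=traj,
        refinement_history=[(dict(ne0), best_cost)],
        problem=problem,
    )


def refine_elements(problem: TrackingProblem, result: TrackingResult):
    """Double the input elements and warm-start from the coarse solution.

    Returns ``(refined_problem, warm_start_vector)``.  Because element
    doubling nests the discretization spaces, the warm start reproduces the
    coarse input exactly and its cost equals the coarse cost.
    """
    fine_param = {w: pw.refine() for w, pw in problem.input_param.items()}
    refined = replace(problem, input_param=fine_param)

    theta, x0s, wnodes = problem.unpack(result.x)
    vec = [theta[str(p)] for p in problem.model.params]
    for e in problem.experiments:
        for k, s in enumerate(problem.model.states):
            if problem.model.init.get(s, None) is None and str(s) not in e.x0_known:
                vec.append(x0s[e.id][k])
    for e in problem.experiments:
        for wname, pw in problem.input_param.items():
            vec.extend(pw.interpolate_to(fine_param[wname], wnodes[e.id][wname]))
    return refined, np.array(vec, dtype=float)


def solve_with_refinement(
    problem: TrackingProblem,
    n_refinements: int,
    budget: SolveBudget | None = None,
    refine_budget: SolveBudget | None = None,
    seed: int = 0,
) -> TrackingResult:
    """Solve, then repeatedly double the input elements and re-optimize.

    The refinement stages warm-start from the interpolated previous
    solution, so the cost is non-increasing along the schedule.
    """
    result = solve(problem, budget=budget, seed=seed)
    history = list(result.refinement_history)
    for k in range(n_refinements):
        problem, warm = refine_elements(problem, result)
        nxt = solve(
            problem,
            budget=refine_budget or budget,
            seed=seed + k + 1,
            warm_start=warm,
        )
        if nxt.cost <= result.cost:
            result = nxt
        else:  # keep the warm-started coarse solution if re-opt regressed
            nxt.x = warm
            nxt.cost = objective(problem, warm)
            theta, x0s, wnodes = problem.unpack(warm)
            nxt.theta_hat = {k2: float(v) for k2, v in theta.items()}
            nxt.w_nodes = wnodes
            nxt.problem = problem
            result = nxt
        history.append((
            {w: pw.n_e for w, pw in problem.input_param.items()},
            result.cost,
        ))
    result.refinement_history = history
    return result


# ---------------------------------------------------------------------------
# uncertainty
# ---------------------------------------------------------------------------

def estimate_uncertainty(problem: TrackingProblem, result: TrackingResult) -> dict:
    """Linearized standard errors of every decision variable.

    Central finite differences of the sigma-scaled residual vector give the
    Jacobian J; the covariance is (J^T J)^{-1} evaluated at the optimum
    (the classical Gauss-Newton / Fisher-information approximation).
    """
    x = np.asarray(result.x, dtype=float)
    r0 = residuals(problem, x)
    J = np.empty((r0.size, x.size))
    for j in range(x.size):
        h = 1e-5 * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (residuals(problem, xp) - residuals(problem, xm)) / (2 * h)
    cov = np.linalg.pinv(J.T @ J)
    std = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return dict(zip(problem.decision_names(), std))


# ---------------------------------------------------------------------------
# delimited data tables
# ---------------------------------------------------------------------------

def experiments_to_frame(experiments) -> pd.DataFrame:
    """Long-format table (experiment_id, time, output_id, value, sigma)."""
    rows = []
    for e in experiments:
        for i, t in enumerate(e.t):
            for j in range(e.y.shape[1]):
                rows.append((e.id, float(t), j, float(e.y[i, j]), float(e.sigma[i, j])))
    return pd.DataFrame(
        rows, columns=["experiment_id", "time", "output_id", "value", "sigma"]
    )


def frame_to_experiments(df: pd.DataFrame, u=None, x0_known=None) -> list:
    """Rebuild :class:`Experiment` records from the long-format table."""
    out = []
    for eid, sub in df.groupby("experiment_id", sort=False):
        piv_v = sub.pivot_table(index="time", columns="output_id", values="value")
        piv_s = sub.pivot_table(index="time", columns="output_id", values="sigma")
        out.append(
            Experiment(
                id=str(eid),
                t=piv_v.index.to_numpy(),
                y=piv_v.to_numpy(),
                sigma=piv_s.to_numpy(),
                u=dict((u or {}).get(str(eid), {})),
                x0_known=dict((x0_known or {}).get(str(eid), {})),
            )
        )
    return out
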