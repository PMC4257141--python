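"""Derivative-free (Nelder-Mead simplex) optimization of transmission objectives.

Optimization happens in log10-parameter space (rate constants span many
decades), with per-parameter box bounds expressed as multiplier ranges
relative to the starting model.  The optimizer is seeded and fully
deterministic; restarts draw their initial points from the seeded RNG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .network import NetworkModel, ParameterVector, apply_parameters
from .objectives import (
    MAX_FAIL_FRAC,
    ObjectiveError,
    ObjectiveResult,
    SignalSet,
    evaluate_steady_objective,
    evaluate_transient_objective,
)
from .simulate import FAST_PROFILE, REFERENCE_PROFILE, SolverProfile

__all__ = [
    "OptimizationSpec",
    "OptimizationTrace",
    "simplex_optimize",
    "objective_adapter",
    "INVALID_SCORE",
]

INVALID_SCORE = -1e9   # scalar assigned to failed/invalid evaluations
RATE_BOUNDS = (0.2, 5.0)
CONC_BOUNDS = (0.1, 10.0)
INITIAL_STEP = 0.2     # log10 units, initial simplex edge
XATOL = 1e-3           # log10 units, simplex-size convergence


@dataclass(frozen=True)
class OptimizationSpec:
    """What to optimize, over which parameters, and with what budget.

    ``subset`` selects the free parameters (``rates_only``,
    ``concentrations_only``, ``both``, or an explicit key list);
    ``rate_bounds``/``conc_bounds`` are multiplier ranges relative to the
    starting values.  ``objective`` is one of ``R_only``, ``d_only``, ``f``,
    ``f_transient``.  The evaluation budget is shared across restarts.
    """

    subset: str | Sequence[tuple] = "both"
    objective: str = "f"
    max_evals: int = 2000
    restarts: int = 3
    seed: int = 0
    rate_bounds: tuple[float, float] = RATE_BOUNDS
    conc_bounds: tuple[float, float] = CONC_BOUNDS
    exclude_species: tuple[str, ...] = ()
    profile: SolverProfile = FAST_PROFILE

    def __post_init__(self) -> None:
        if self.max_evals < 1:
            raise ValueError("budget must be at least 1 evaluation")
        if self.restarts < 1:
            raise ValueError("need at least one start")
        for lo, hi in (self.rate_bounds, self.conc_bounds):
            if not (0 < lo <= 1 <= hi):
                raise ValueError("bounds must be positive and bracket 1")


@dataclass
class OptimizationTrace:
    """Best point found plus the full evaluation history."""

    best_params: ParameterVector
    best_model: NetworkModel
    best_scalar: float
    best_objective: ObjectiveResult | None
    history: list[tuple[int, float]] = field(default_factory=list)
    n_evals: int = 0
    converged: bool = False

    def best_so_far(self) -> np.ndarray:
        """Running maximum of the objective scalar (monotone by construction)."""
        return np.maximum.accumulate([h[1] for h in self.history])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history, columns=["eval", "scalar"])


def objective_adapter(
    kind: str,
    signals: SignalSet,
    ref: tuple[float, float] | None = None,
    profile: SolverProfile = FAST_PROFILE,
) -> Callable[[NetworkModel], tuple[float, ObjectiveResult | None]]:
    """Map an objective name to a maximization target over models.

    ``R_only`` maximizes the mean response coefficient, ``d_only`` minimizes
    the mean delay, ``f`` maximizes the equally weighted J = R/R_ref -
    d/d_ref, ``f_cost`` minimizes the cost form f (via -log10 f, which keeps
    recovering the response worthwhile even when it has collapsed toward
    zero), ``f_transient`` maximizes the peak-over-steady transient score.
    Invalid evaluations (too many failed pairs) score ``INVALID_SCORE``.
    """
    if kind not in ("R_only", "d_only", "f", "f_cost", "f_transient"):
        raise ValueError(f"unknown objective kind {kind!r}")
    if kind in ("f", "f_cost") and ref is None:
        raise ValueError(f"objective {kind!r} needs reference values (R_ref, d_ref)")

    def fn(model: NetworkModel) -> tuple[float, ObjectiveResult | None]:
        try:
            if kind == "f_transient":
                res = evaluate_transient_objective(model, signals, ref, profile)
            else:
                res = evaluate_steady_objective(model, signals, ref, profile)
        except Exception:  # solver blow-ups and failed ensembles score invalid
            return INVALID_SCORE, None
        if not res.valid:
            return INVALID_SCORE, res
        if kind == "R_only":
            return res.R_ss, res
        if kind == "d_only":
            return -res.d_ss, res
        if kind == "f":
            return (INVALID_SCORE if not np.isfinite(res.J) else res.J), res
        if kind == "f_cost":
            if not (np.isfinite(res.f) and res.f > 0):
                return INVALID_SCORE, res
            return -math.log10(res.f), res
        return (
            INVALID_SCORE if not np.isfinite(res.f_transient) else res.f_transient
        ), res

    return fn


def simplex_optimize(
    model: NetworkModel,
    signals: SignalSet,
    spec: OptimizationSpec,
    objective_fn: Callable[[NetworkModel], tuple[float, ObjectiveResult | None]] | None = None,
    ref: tuple[float, float] | None = None,
) -> OptimizationTrace:
    """Nelder-Mead over the selected parameters in log10 space.

    The search variable is the log10 multiplier relative to the starting
    model (0 = unchanged), clipped to the per-kind bounds.  The best-ever
    point is tracked across all evaluations and restarts, so the result is
    never worse than the starting point.  Fully deterministic given
    ``spec.seed``.
    """
    if ref is None and spec.objective in ("f", "f_cost"):
        start = evaluate_steady_objective(model, signals, profile=spec.profile)
        ref = (start.R_ss, start.d_ss)
    if objective_fn is None:
        objective_fn = objective_adapter(
            spec.objective, signals, ref=ref, profile=spec.profile
        )

    params0 = ParameterVector.from_model(
        model, spec.subset, exclude_species=spec.exclude_species
    )
    if len(params0) == 0:
        raise ValueError("no free parameters selected")
    kinds = [k[0] for k in params0.keys()]
    lo = np.array([
        math.log10(spec.rate_bounds[0] if k == "rate" else spec.conc_bounds[0])
        for k in kinds
    ])
    hi = np.array([
        math.log10(spec.rate_bounds[1] if k == "rate" else spec.conc_bounds[1])
        for k in kinds
    ])

    history: list[tuple[int, float]] = []
    best = {
        "x": np.zeros(len(params0)),
        "scalar": -math.inf,
        "objective": None,
    }
    n_evals = 0

    def model_at(x: np.ndarray) -> NetworkModel:
        return apply_parameters(model, params0.with_log10_values(
            params0.log10_values + np.clip(x, lo, hi)
        ))

    def neg_objective(x: np.ndarray) -> float:
        nonlocal n_evals
        if n_evals >= spec.max_evals:
            # budget exhausted: return a constant so NM terminates quickly
            return -INVALID_SCORE
        xc = np.clip(x, lo, hi)
        penalty = float(np.sum(np.abs(x - xc)))  # discourage leaving the box
        scalar, res = objective_fn(model_at(xc))
        n_evals += 1
        history.append((n_evals, scalar))
        if scalar > best["scalar"]:
            best.update(x=xc.copy(), scalar=scalar, objective=res)
        return -(scalar - penalty)

    # evaluate the start explicitly: the result must never be worse
    x0 = np.zeros(len(params0))
    start_scalar, start_res = objective_fn(model_at(x0))
    n_evals += 1
    history.append((n_evals, start_scalar))
    best.update(x=x0.copy(), scalar=start_scalar, objective=start_res)
    if start_scalar <= INVALID_SCORE:
        raise ObjectiveError("objective invalid at the starting point")

    rng = np.random.default_rng(spec.seed)
    per_restart = max(1, (spec.max_evals - 1) // spec.restarts)
    converged = False
    for r in range(spec.restarts):
        if n_evals >= spec.max_evals:
            break
        if r == 0:
            xs = x0
        else:
            xs = rng.uniform(np.maximum(lo, -2 * INITIAL_STEP),
                             np.minimum(hi, 2 * INITIAL_STEP))
        simplex = np.vstack([xs] + [
            np.clip(xs + INITIAL_STEP * np.eye(len(xs))[i], lo, hi)
            for i in range(len(xs))
        ])
        res = minimize(
            neg_objective,
            xs,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": min(per_restart, spec.max_evals - n_evals),
                "xatol": XATOL,
                "fatol": 1e-6,
                "adaptive": len(xs) > 20,
            },
        )
        converged = converged or bool(res.success)

    best_params = params0.with_log10_values(params0.log10_values + best["x"])
    return OptimizationTrace(
        best_params=best_params,
        best_model=apply_parameters(model, best_params),
        best_scalar=best["scalar"],
        best_objective=best["objective"],
        history=history,
        n_evals=n_evals,
        converged=converged,
    )
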