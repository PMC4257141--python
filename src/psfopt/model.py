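"""High-level Model/Results API.

:class:`TransmissionModel` bundles a reaction network with the signal
ensemble it must transmit and an objective; ``fit()`` runs the simplex
optimizer and returns :class:`TransmissionResults` with the tuned
parameters, before/after transmission metrics and a ``summary()`` table.

Example
-------
>>> from psfopt import load_default_model, make_signal_set, TransmissionModel
>>> net = load_default_model()
>>> signals = make_signal_set(10, 900)
>>> tm = TransmissionModel(net, signals, objective="R_only", subset="both")
>>> res = tm.fit(max_evals=200, seed=1)          # doctest: +SKIP
>>> print(res.summary())                         # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .network import NetworkModel, ParameterVector
from .objectives import (
    ObjectiveResult,
    SignalSet,
    evaluate_steady_objective,
    evaluate_transient_objective,
)
from .optimize import OptimizationSpec, OptimizationTrace, simplex_optimize
from .simulate import FAST_PROFILE, REFERENCE_PROFILE, SolverProfile
from .transfer import TransferFunction, compute_transfer_function

__all__ = ["TransmissionModel", "TransmissionResults"]


class TransmissionModel:
    """A reaction network paired with a signal-transmission task.

    Parameters
    ----------
    network : NetworkModel
        The mass-action reaction system.
    signals : SignalSet
        The ensemble of input steps to transmit.
    objective : str
        ``R_only`` | ``d_only`` | ``f`` | ``f_transient``.
    subset : str or list
        Free parameters for fitting: ``rates_only`` |
        ``concentrations_only`` | ``both`` | explicit key list.
    ref : (R_ref, d_ref), optional
        Normalization for the combined objective ``f``; computed from the
        unmodified network on ``signals`` when omitted.
    """

    def __init__(
        self,
        network: NetworkModel,
        signals: SignalSet,
        objective: str = "f",
        subset: str = "both",
        ref: tuple[float, float] | None = None,
        exclude_species: tuple[str, ...] = (),
        profile: SolverProfile = FAST_PROFILE,
    ):
        self.network = network
        self.signals = signals
        self.objective = objective
        self.subset = subset
        self.ref = ref
        self.exclude_species = tuple(exclude_species)
        self.profile = profile

    def evaluate(
        self,
        network: NetworkModel | None = None,
        profile: SolverProfile = REFERENCE_PROFILE,
        transient: bool | None = None,
    ) -> ObjectiveResult:
        """Transmission metrics of a network (default: the unfitted one)."""
        net = network if network is not None else self.network
        if transient is None:
            transient = self.objective == "f_transient"
        fn = evaluate_transient_objective if transient else evaluate_steady_objective
        return fn(net, self.signals, ref=self.ref, profile=profile)

    def fit(
        self,
        max_evals: int = 2000,
        restarts: int = 3,
        seed: int = 0,
        **spec_kwargs,
    ) -> "TransmissionResults":
        """Tune the free parameters by seeded Nelder-Mead; returns results."""
        if self.ref is None and self.objective in ("f", "f_cost"):
            start = evaluate_steady_objective(
                self.network, self.signals, profile=self.profile
            )
            self.ref = (start.R_ss, start.d_ss)
        spec = OptimizationSpec(
            subset=self.subset,
            objective=self.objective,
            max_evals=max_evals,
            restarts=restarts,
            seed=seed,
            exclude_species=self.exclude_species,
            profile=self.profile,
            **spec_kwargs,
        )
        trace = simplex_optimize(self.network, self.signals, spec, ref=self.ref)
        return TransmissionResults(self, trace)

    def transfer_function(
        self,
        grid: np.ndarray | None = None,
        network: NetworkModel | None = None,
        profile: SolverProfile = REFERENCE_PROFILE,
    ) -> TransferFunction:
        """Dose-response curve of the (or a fitted) network."""
        if grid is None:
            grid = np.geomspace(1.0, 1000.0, 16)
        return compute_transfer_function(
            network if network is not None else self.network, grid, profile=profile
        )


class TransmissionResults:
    """Outcome of a :meth:`TransmissionModel.fit` run."""

    def __init__(self, model: TransmissionModel, trace: OptimizationTrace):
        self.model = model
        self.trace = trace
        self.params: ParameterVector = trace.best_params
        self.fitted_network: NetworkModel = trace.best_model
        self.objective_at_optimum: ObjectiveResult | None = trace.best_objective
        self._ref_eval: ObjectiveResult | None = None

    @property
    def n_evals(self) -> int:
        return self.trace.n_evals

    def reevaluate(self, profile: SolverProfile = REFERENCE_PROFILE) -> ObjectiveResult:
        """Recompute the optimum's metrics under the reference solver profile."""
        self._ref_eval = self.model.evaluate(self.fitted_network, profile=profile)
        return self._ref_eval

    def multipliers(self) -> "np.ndarray":
        """Fitted values as fold changes relative to the starting model."""
        start = ParameterVector.from_model(
            self.model.network, self.model.subset,
            exclude_species=self.model.exclude_species,
        )
        return self.params.values / start.values

    def summary(self) -> str:
        """Plain-text summary: objective trajectory and largest shifts."""
        import pandas as pd

        start_scalar = self.trace.history[0][1]
        lines = [
            "Signal transmission optimization",
            "=" * 48,
            f"objective:        {self.model.objective}",
            f"free parameters:  {len(self.params)} ({self.model.subset})",
            f"signal pairs:     {len(self.model.signals)}",
            f"evaluations:      {self.trace.n_evals}",
            f"start scalar:     {start_scalar:.4g}",
            f"best scalar:      {self.trace.best_scalar:.4g}",
        ]
        obj = self._ref_eval or self.objective_at_optimum
        if obj is not None:
            lines += [
                f"R_ss at optimum:  {obj.R_ss:.4g}",
                f"d_ss at optimum:  {obj.d_ss:.4g} s",
            ]
            if np.isfinite(obj.f_transient):
                lines.append(f"f_transient:      {obj.f_transient:.4g}")
        mult = self.multipliers()
        labels = self.params.labels()
        order = np.argsort(np.abs(np.log10(mult)))[::-1][:10]
        tab = pd.DataFrame(
            {
                "parameter": [labels[i] for i in order],
                "fold_change": [round(float(mult[i]), 4) for i in order],
            }
        )
        lines += ["", "largest parameter shifts (fold change vs start):",
                  tab.to_string(index=False)]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<TransmissionResults: {self.model.objective}, "
            f"best={self.trace.best_scalar:.4g}, n_evals={self.trace.n_evals}>"
        )
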