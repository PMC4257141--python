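"""Dose-response transfer functions ("protein signaling functions").

A transfer function maps sustained input levels to steady-state output
concentrations.  On a logarithmic input axis these curves are sigmoids, so a
four-parameter logistic is fitted in log10-input space.  The response
coefficient

    R = (Ct/C0 - 1) / (St/S0 - 1)

quantifies transmission of a relative input change: 1 is perfect
transmission, < 1 signal loss, > 1 amplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .network import NetworkModel
from .simulate import (
    DelayError,
    REFERENCE_PROFILE,
    SimulationError,
    SolverProfile,
    delay_ec90,
    run_to_steady,
)

__all__ = [
    "TransferFunction",
    "SigmoidFit",
    "compute_transfer_function",
    "fit_sigmoid",
    "response_coefficient",
]

log = logging.getLogger(__name__)


def response_coefficient(C0: float, Ct: float, S0: float, St: float) -> float:
    """Response coefficient R = (Ct/C0 - 1)/(St/S0 - 1).

    Sign-preserving: inhibitory responses give negative R.  Invariant under
    common rescaling of the output pair and of the input pair.
    """
    if S0 <= 0:
        raise ValueError("baseline input S0 must be positive")
    if St == S0:
        raise ValueError("response undefined: St equals S0")
    if C0 == 0:
        raise ZeroDivisionError("undefined baseline: C0 is zero")
    return (Ct / C0 - 1.0) / (St / S0 - 1.0)


@dataclass
class SigmoidFit:
    """Four-parameter logistic in log10-input space.

    ``slope_s`` is the derivative of the 0-1 normalized curve at the
    half-maximal point (= hill * ln(10)/4 for an increasing curve).
    """

    bottom: float
    top: float
    log_ec50: float
    slope_s: float
    hill: float
    rss: float
    degenerate: bool = False


@dataclass
class TransferFunction:
    input_grid: np.ndarray       # nM, strictly increasing
    ss_outputs: np.ndarray       # nM
    delays: np.ndarray           # s (NaN where unavailable)
    converged: np.ndarray        # bool per grid point
    output_species: str = ""
    fitted: SigmoidFit | None = None

    def __post_init__(self) -> None:
        if not (len(self.input_grid) == len(self.ss_outputs) == len(self.delays)):
            raise ValueError("grid, outputs and delays must have equal length")
        if np.any(np.diff(self.input_grid) <= 0):
            raise ValueError("input grid must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "input_nM": self.input_grid,
                "ss_output_nM": self.ss_outputs,
                "delay_s": self.delays,
                "converged": self.converged,
            }
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.input_grid, self.ss_outputs, "o-", **kwargs)
        if self.fitted is not None and not self.fitted.degenerate:
            x = np.linspace(
                np.log10(self.input_grid[0]), np.log10(self.input_grid[-1]), 200
            )
            ax.semilogx(10 ** x, _logistic(x, self.fitted.bottom, self.fitted.top,
                                           self.fitted.log_ec50, self.fitted.hill),
                        "--", color="gray")
        ax.set_xlabel("input (nM)")
        ax.set_ylabel(f"{self.output_species} steady state (nM)")
        return ax


def compute_transfer_function(
    model: NetworkModel,
    grid: np.ndarray,
    profile: SolverProfile = REFERENCE_PROFILE,
    fit: bool = True,
) -> TransferFunction:
    """Steady-state output and EC90 delay for each input level.

    Protocol per grid point: equilibrate the system with the input clamped at
    0 (shared across points), then step the clamp to the grid level and run
    to steady state; the delay is measured on the post-step phase.
    Non-converged points are flagged and excluded from the sigmoid fit.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 1e6):
        raise ValueError("grid must lie within [0, 1e6] nM")
    base_traj, base_ss = run_to_steady(model, clamp=0.0, profile=profile)
    if not base_ss.converged:
        raise SimulationError("zero-input baseline did not reach steady state")
    out_i = model.species_index(model.output_species)
    C_base = float(base_ss.ss_values[out_i])
    outputs = np.full(len(grid), np.nan)
    delays = np.full(len(grid), np.nan)
    converged = np.zeros(len(grid), dtype=bool)
    for k, level in enumerate(grid):
        try:
            traj, ss = run_to_steady(
                model, clamp=float(level),
                from_state=base_traj.final_state, profile=profile,
            )
        except SimulationError as exc:
            log.warning("transfer point %g nM failed: %s", level, exc)
            continue
        if not ss.converged:
            log.warning("transfer point %g nM did not converge", level)
            continue
        converged[k] = True
        outputs[k] = ss.ss_values[out_i]
        if abs(outputs[k] - C_base) < 1e-12:
            delays[k] = 0.0
        else:
            try:
                delays[k] = delay_ec90(traj, model.output_species, C_base, outputs[k])
            except DelayError:
                delays[k] = np.nan
    tf = TransferFunction(
        grid, outputs, delays, converged, output_species=model.output_species
    )
    if fit and converged.sum() >= 4:
        tf.fitted = fit_sigmoid(tf)
    return tf


def _logistic(x, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - x)))


def fit_sigmoid(tf: TransferFunction) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit on log10(input).

    Flat data cannot constrain the midpoint: such fits are returned with
    ``slope_s = 0``, EC50 at the grid midpoint, and the ``degenerate`` flag.
    """
    ok = tf.converged & (tf.input_grid > 0) & np.isfinite(tf.ss_outputs)
    x = np.log10(tf.input_grid[ok])
    y = tf.ss_outputs[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 converged points to fit")
    span = y.max() - y.min()
    mid = 0.5 * (x[0] + x[-1])
    scale = max(abs(y).max(), 1.0)
    if span < 1e-9 * scale:
        return SigmoidFit(
            bottom=float(y.mean()), top=float(y.mean()), log_ec50=mid,
            slope_s=0.0, hill=0.0, rss=float(((y - y.mean()) ** 2).sum()),
            degenerate=True,
        )
    increasing = y[-1] >= y[0]
    h0 = 1.0 if increasing else -1.0
    # midpoint guess: where the curve crosses half its range
    yh = y.min() + 0.5 * span
    x0 = float(np.interp(yh, y, x)) if increasing else mid
    p0 = [float(y.min()), float(y.max()), x0, h0]
    try:
        popt, _ = curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        popt = p0
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    resid = y - _logistic(x, *popt)
    rss = float((resid ** 2).sum())
    degenerate = abs(top - bottom) < 1e-6 * scale
    # normalize: report the rising-branch parameterization
    if top < bottom:
        bottom, top, hill = top, bottom, -hill
    slope_s = hill * np.log(10.0) / 4.0
    return SigmoidFit(
        bottom=bottom, top=top, log_ec50=log_ec50,
        slope_s=float(slope_s), hill=float(hill), rss=rss,
        degenerate=degenerate,
    )
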