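"""Signal sets and the transmission objective functions.

A *signal set* is an ensemble of input steps ``(S0, St)`` representing the
distribution of extracellular signals the pathway must transmit.  For each
pair the system is equilibrated at the baseline ``S0``, the input is stepped
to ``St``, and two quantities are read off the output species: the response
coefficient ``R`` of the steady-state change, and the EC90 delay ``d``.

The steady-state objective combines the ensemble means, equally weighted and
normalized by a reference system (by default the unmodified model on the
same signal set):

    J = R/R_ref - d/d_ref          (maximization form, used by the optimizer)
    f = (d/d_ref) / (R/R_ref)      (cost form; the reference model has f = 1)

The transient score rewards a pronounced peak over the steady-state
response:

    f_transient = R_peak / max(R_ss, R_FLOOR)

with a floor on ``R_ss`` so that near-perfect steady-state suppression does
not diverge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .network import NetworkModel
from .simulate import (
    DelayError,
    REFERENCE_PROFILE,
    SimulationError,
    SolverProfile,
    delay_ec90,
    find_peak,
    run_to_steady,
)
from .transfer import response_coefficient

__all__ = [
    "SignalSet",
    "ObjectiveResult",
    "ObjectiveError",
    "ScalarizedObjective",
    "R_FLOOR",
    "MAX_FAIL_FRAC",
    "make_signal_set",
    "evaluate_steady_objective",
    "evaluate_transient_objective",
    "scalarize",
    "scalarize_transient",
]

R_FLOOR = 0.05        # floor on R_ss in the transient score
MAX_FAIL_FRAC = 0.5   # an evaluation with more failures is invalid
DEFAULT_CAP = 1000.0  # nM; input steps never exceed 1 uM


class ObjectiveError(RuntimeError):
    """Objective evaluation failed (e.g. every signal pair failed)."""


@dataclass(frozen=True)
class SignalSet:
    """Ensemble of (baseline, stepped) input pairs, in nM."""

    pairs: tuple[tuple[float, float], ...]
    description: str = ""

    def __post_init__(self) -> None:
        for S0, St in self.pairs:
            if S0 <= 0:
                raise ValueError(f"baseline must be positive, got {S0}")
            if St == S0:
                raise ValueError(f"step must differ from baseline ({S0})")

    def __len__(self) -> int:
        return len(self.pairs)

    def baselines(self) -> list[float]:
        seen: dict[float, None] = {}
        for S0, _ in self.pairs:
            seen.setdefault(S0)
        return list(seen)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.pairs, columns=["S0_nM", "St_nM"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, description: str = "") -> "SignalSet":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        pairs = tuple(
            (float(r["S0_nM"]), float(r["St_nM"])) for _, r in df.iterrows()
        )
        return cls(pairs, description=description or str(path))


def make_signal_set(
    lo: float,
    hi: float,
    folds: tuple[float, ...] = (1.1, 1.5, 2.0),
    n_baselines: int = 16,
    cap: float = DEFAULT_CAP,
) -> SignalSet:
    """Log-spaced baselines in [lo, hi] crossed with fold increases.

    Steps exceeding ``cap`` are clipped to it (pairs whose clipped step
    equals the baseline are dropped).  The default reproduces the task
    ensemble used throughout: baselines stepped to 110%, 150% and 200%, but
    never above 1 uM.
    """
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if n_baselines < 1:
        raise ValueError("need at least one baseline")
    baselines = np.geomspace(lo, hi, n_baselines)
    pairs = []
    for S0 in baselines:
        for fold in folds:
            St = min(S0 * fold, cap)
            if St != S0:
                pairs.append((float(S0), float(St)))
    if not pairs:
        raise ValueError("signal set is empty after clipping")
    return SignalSet(
        tuple(pairs),
        description=f"{n_baselines} baselines in [{lo:g}, {hi:g}] nM x folds {folds}, cap {cap:g} nM",
    )


class ScalarizedObjective(NamedTuple):
    J: float   # maximization form
    f: float   # cost form (reference system = 1)


def scalarize(R: float, d: float, ref: tuple[float, float]) -> ScalarizedObjective:
    """Equally weighted, reference-normalized combination of R and d.

    Returns both views: ``J = R/R_ref - d/d_ref`` (to maximize) and
    ``f = (d/d_ref)/(R/R_ref)`` (cost; smaller is better, 1 at the
    reference).  Nonpositive R carries no signal: f = +inf, J = -inf.
    """
    R_ref, d_ref = ref
    if R_ref <= 0 or d_ref <= 0:
        raise ValueError("reference values must be positive")
    if not np.isfinite(R) or R <= 0:
        return ScalarizedObjective(-math.inf, math.inf)
    return ScalarizedObjective(R / R_ref - d / d_ref, (d / d_ref) / (R / R_ref))


def scalarize_transient(R_peak: float, R_ss: float) -> float:
    """Transient propensity: fold-excess of the peak over the steady response."""
    if not np.isfinite(R_peak):
        return -math.inf
    return R_peak / max(R_ss, R_FLOOR)


@dataclass
class ObjectiveResult:
    """Ensemble-aggregated transmission metrics for one model.

    Means are over converged signal pairs only; ``n_failed`` counts pairs
    that failed to converge or had undefined responses.
    """

    R_ss: float
    d_ss: float
    f: float = math.nan
    J: float = math.nan
    R_peak: float = math.nan
    d_peak: float = math.nan
    f_transient: float = math.nan
    n_pairs: int = 0
    n_failed: int = 0
    per_pair: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        done = self.n_pairs - self.n_failed
        return done > 0 and self.n_failed <= MAX_FAIL_FRAC * self.n_pairs

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "R_ss", "d_ss", "f", "J", "R_peak", "d_peak",
                "f_transient", "n_pairs", "n_failed",
            )
        }


def _evaluate(
    model: NetworkModel,
    signals: SignalSet,
    ref: tuple[float, float] | None,
    profile: SolverProfile,
    transient: bool,
) -> ObjectiveResult:
    out_i = model.species_index(model.output_species)
    base_cache: dict[float, tuple[np.ndarray, float] | None] = {}
    rows = []
    n_failed = 0
    for S0, St in signals.pairs:
        if S0 not in base_cache:
            try:
                btraj, bss = run_to_steady(model, clamp=S0, profile=profile)
                base_cache[S0] = (
                    (btraj.final_state, float(bss.ss_values[out_i]))
                    if bss.converged else None
                )
            except SimulationError:
                base_cache[S0] = None
        base = base_cache[S0]
        if base is None:
            n_failed += 1
            continue
        state0, C0 = base
        if C0 <= 0:
            n_failed += 1
            continue
        try:
            traj, ss = run_to_steady(model, clamp=St, from_state=state0, profile=profile)
        except SimulationError:
            n_failed += 1
            continue
        if not ss.converged:
            n_failed += 1
            continue
        Ct = float(ss.ss_values[out_i])
        try:
            R = response_coefficient(C0, Ct, S0, St)
            if Ct == C0:
                d = 0.0
            else:
                d = delay_ec90(traj, model.output_species, C0, Ct)
        except (DelayError, ValueError, ZeroDivisionError):
            n_failed += 1
            continue
        row = {"S0": S0, "St": St, "C0": C0, "Ct": Ct, "R": R, "d": d}
        if transient:
            peak, t_peak, has_tr = find_peak(
                traj, model.output_species, Ct, baseline=C0
            )
            row["R_peak"] = response_coefficient(C0, peak, S0, St)
            row["d_peak"] = t_peak
            row["has_transient"] = has_tr
        rows.append(row)
    n_pairs = len(signals)
    if not rows:
        raise ObjectiveError("all signal pairs failed to evaluate")
    R_ss = float(np.mean([r["R"] for r in rows]))
    d_ss = float(np.mean([r["d"] for r in rows]))
    res = ObjectiveResult(
        R_ss=R_ss, d_ss=d_ss, n_pairs=n_pairs, n_failed=n_failed, per_pair=rows
    )
    if transient:
        res.R_peak = float(np.mean([r["R_peak"] for r in rows]))
        res.d_peak = float(np.mean([r["d_peak"] for r in rows]))
        res.f_transient = scalarize_transient(res.R_peak, res.R_ss)
    if ref is not None:
        res.J, res.f = scalarize(R_ss, d_ss, ref)
    return res


def evaluate_steady_objective(
    model: NetworkModel,
    signals: SignalSet,
    ref: tuple[float, float] | None = None,
    profile: SolverProfile = REFERENCE_PROFILE,
) -> ObjectiveResult:
    """Mean response coefficient and EC90 delay over a signal set.

    Per pair: equilibrate at ``S0`` (baselines are cached across folds),
    step the input to ``St``, run to steady state, and measure R and the
    EC90 delay on the output species.  ``ref=(R_ref, d_ref)`` additionally
    scalarizes into J and f.
    """
    return _evaluate(model, signals, ref, profile, transient=False)


def evaluate_transient_objective(
    model: NetworkModel,
    signals: SignalSet,
    ref: tuple[float, float] | None = None,
    profile: SolverProfile = REFERENCE_PROFILE,
) -> ObjectiveResult:
    """As :func:`evaluate_steady_objective`, plus peak metrics.

    Adds the mean peak response coefficient, mean delay-to-peak, and the
    transient propensity score ``f_transient = R_peak / max(R_ss, 0.05)``.
    Plateau systems (peak = steady state) score at the ratio floor.
    """
    return _evaluate(model, signals, ref, profile, transient=True)
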