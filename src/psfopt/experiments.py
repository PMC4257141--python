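"""The four computational experiments, as seeded, reproducible pipelines.

1. :func:`random_rate_scan` — sample kinetic-rate multipliers log-uniformly
   in [20%, 500%] and map the response-coefficient / delay landscape;
   :func:`classify_efficiency` splits the sampled systems into high
   (f < 2) / low (f > 5) transmission-efficiency classes and summarizes the
   spread ("sloppiness") of their Kd/KM constants.
2. :func:`concentration_robustness` — perturb concentrations by ±20% and
   check that the quality ranking of rate sets is preserved.
3. :func:`knockdown_adapt` / :func:`signal_shift_adapt` — reduce one protein
   to 10%, or move the extracellular signal range, then let all (other)
   concentrations re-adapt with rates frozen.
4. :func:`transient_training` — train concentrations for a transient
   (peaked) versus plateau response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import NetworkModel, ParameterVector, apply_parameters
from .objectives import (
    ObjectiveError,
    SignalSet,
    evaluate_steady_objective,
    evaluate_transient_objective,
    scalarize,
)
from .optimize import OptimizationSpec, simplex_optimize
from .simulate import FAST_PROFILE, SolverProfile

__all__ = [
    "ScanRecord",
    "AdaptationResult",
    "sample_rate_multipliers",
    "random_rate_scan",
    "classify_efficiency",
    "concentration_robustness",
    "knockdown_adapt",
    "signal_shift_adapt",
    "transient_training",
]

SCAN_LO, SCAN_HI = 0.2, 5.0     # 20% .. 500% of the original rates
F_HIGH_CUT, F_LOW_CUT = 2.0, 5.0
KNOCKDOWN_FACTOR = 0.1


@dataclass
class ScanRecord:
    """One randomly drawn rate set and its transmission metrics."""

    multipliers: np.ndarray       # per-rate factors, aligned to rate keys
    R_ss: float
    d_ss: float
    f: float
    cls: str = "unclassified"     # high | mid | low | invalid

    @property
    def valid(self) -> bool:
        return self.cls != "invalid" and np.isfinite(self.f)


@dataclass
class AdaptationResult:
    """Concentration re-adjustment after a perturbation.

    ``conc_changes`` maps species to (adapted / pre-perturbation)
    concentration ratios.  ``improved`` holds iff the cost-form f after
    adaptation beats the one right after the perturbation.
    """

    perturbed: tuple[str, float] | None
    conc_changes: dict[str, float]
    f_before: float
    f_after: float
    R_before: float
    d_before: float
    R_after: float
    d_after: float
    n_evals: int = 0

    @property
    def improved(self) -> bool:
        return self.f_after < self.f_before

    def mean_log_change(self, exclude: tuple[str, ...] = ()) -> float:
        """Mean log10 concentration change of non-perturbed species."""
        skip = set(exclude)
        if self.perturbed is not None:
            skip.add(self.perturbed[0])
        vals = [v for k, v in self.conc_changes.items() if k not in skip]
        return float(np.mean(np.log10(vals)))

    def to_series(self) -> pd.Series:
        return pd.Series(self.conc_changes, name=(
            self.perturbed[0] if self.perturbed else "shift"
        ))


def sample_rate_multipliers(
    n: int, n_rates: int, rng: np.random.Generator,
    lo: float = SCAN_LO, hi: float = SCAN_HI,
) -> np.ndarray:
    """Log-uniform multipliers in [lo, hi] (multiplicative noise on rates)."""
    return 10 ** rng.uniform(math.log10(lo), math.log10(hi), size=(n, n_rates))


def random_rate_scan(
    model: NetworkModel,
    signals: SignalSet,
    n: int,
    lo: float = SCAN_LO,
    hi: float = SCAN_HI,
    seed: int = 0,
    ref: tuple[float, float] | None = None,
    profile: SolverProfile = FAST_PROFILE,
) -> list[ScanRecord]:
    """Evaluate ``n`` random rate sets against a signal ensemble.

    Every kinetic rate (kon, koff, kcat) is multiplied by an independent
    log-uniform factor in [lo, hi].  ``ref`` normalizes the cost-form f
    (default: the unmodified model on ``signals``, so it sits at f = 1).
    """
    rates = ParameterVector.from_model(model, "rates_only")
    if ref is None:
        base = evaluate_steady_objective(model, signals, profile=profile)
        ref = (base.R_ss, base.d_ss)
    rng = np.random.default_rng(seed)
    mults = sample_rate_multipliers(n, len(rates), rng, lo, hi)
    records: list[ScanRecord] = []
    for i in range(n):
        perturbed = apply_parameters(model, rates.scaled(mults[i]))
        try:
            res = evaluate_steady_objective(perturbed, signals, ref=ref, profile=profile)
        except Exception:
            records.append(ScanRecord(mults[i], math.nan, math.nan, math.inf, "invalid"))
            continue
        if not res.valid:
            records.append(ScanRecord(mults[i], res.R_ss, res.d_ss, math.inf, "invalid"))
            continue
        records.append(ScanRecord(mults[i], res.R_ss, res.d_ss, res.f))
    return records


def classify_efficiency(
    records: list[ScanRecord],
    model: NetworkModel,
    f_high_cut: float = F_HIGH_CUT,
    f_low_cut: float = F_LOW_CUT,
) -> tuple[list[ScanRecord], pd.DataFrame, dict[str, pd.DataFrame]]:
    """Label records by transmission efficiency and summarize Kd/KM spread.

    Classes: ``high`` for f < f_high_cut, ``low`` for f > f_low_cut, else
    ``mid``.  Returns ``(records, summary, kd_corr)`` where ``summary`` has
    per-class mean and standard deviation of log10 Kd and log10 KM for every
    binding reaction (the "sloppiness" table) and ``kd_corr`` maps each
    class to the cross-correlation matrix of its log10 Kd values.
    """
    rates = ParameterVector.from_model(model, "rates_only")
    keys = rates.keys()
    base = rates.values
    kon_cols, koff_cols, kcat_cols, rxn_ids = {}, {}, {}, []
    for j, (kind, ridx, fld) in enumerate(keys):
        {"kon": kon_cols, "koff": koff_cols, "kcat": kcat_cols}[fld][ridx] = j
    rxn_ids = sorted(kon_cols)

    for rec in records:
        if rec.cls == "unclassified":
            rec.cls = (
                "high" if rec.f < f_high_cut
                else "low" if rec.f > f_low_cut
                else "mid"
            )

    rows = []
    corr: dict[str, pd.DataFrame] = {}
    labels = [f"r{ridx}" for ridx in rxn_ids]
    for cls in ("high", "mid", "low"):
        members = [r for r in records if r.cls == cls]
        if not members:
            continue
        M = np.vstack([r.multipliers for r in members]) * base
        log_kd = np.column_stack([
            np.log10(M[:, koff_cols[r]] / M[:, kon_cols[r]]) for r in rxn_ids
        ])
        log_km = np.column_stack([
            np.log10(
                (M[:, koff_cols[r]] + (M[:, kcat_cols[r]] if r in kcat_cols else 0.0))
                / M[:, kon_cols[r]]
            )
            for r in rxn_ids
        ])
        for k, ridx in enumerate(rxn_ids):
            rows.append(
                {
                    "class": cls,
                    "reaction_index": ridx,
                    "n": len(members),
                    "log10_Kd_mean": log_kd[:, k].mean(),
                    "log10_Kd_sd": log_kd[:, k].std(ddof=1) if len(members) > 1 else math.nan,
                    "log10_KM_mean": log_km[:, k].mean(),
                    "log10_KM_sd": log_km[:, k].std(ddof=1) if len(members) > 1 else math.nan,
                }
            )
        if len(members) > 2:
            corr[cls] = pd.DataFrame(
                np.corrcoef(log_kd, rowvar=False), index=labels, columns=labels
            )
    return records, pd.DataFrame(rows), corr


def concentration_robustness(
    model: NetworkModel,
    signals: SignalSet,
    records: list[ScanRecord],
    n_systems: int = 100,
    variation: float = 0.2,
    seed: int = 0,
    ref: tuple[float, float] | None = None,
    profile: SolverProfile = FAST_PROFILE,
) -> tuple[pd.DataFrame, float]:
    """Stability of rate-set quality under concentration noise.

    For up to ``n_systems`` valid records, every initial concentration is
    multiplied by an independent uniform factor in
    [1 - variation, 1 + variation] and f is re-evaluated.  Returns the
    per-system table and the Spearman rank correlation between original and
    perturbed f (high correlation = the quality of a rate set is robust to
    expression noise).
    """
    rates = ParameterVector.from_model(model, "rates_only")
    concs = ParameterVector.from_model(model, "concentrations_only")
    if ref is None:
        base = evaluate_steady_objective(model, signals, profile=profile)
        ref = (base.R_ss, base.d_ss)
    rng = np.random.default_rng(seed)
    chosen = [r for r in records if r.valid][:n_systems]
    rows = []
    for rec in chosen:
        noisy = concs.scaled(rng.uniform(1 - variation, 1 + variation, len(concs)))
        perturbed = apply_parameters(
            apply_parameters(model, rates.scaled(rec.multipliers)), noisy
        )
        try:
            res = evaluate_steady_objective(perturbed, signals, ref=ref, profile=profile)
            f_pert = res.f if res.valid else math.inf
        except Exception:
            f_pert = math.inf
        rows.append({"f_original": rec.f, "f_perturbed": f_pert})
    df = pd.DataFrame(rows)
    finite = df.replace(math.inf, math.nan).dropna()
    if len(finite) > 2 and finite["f_original"].nunique() > 1:
        rho = float(stats.spearmanr(finite["f_original"], finite["f_perturbed"])[0])
    else:
        rho = math.nan
    return df, rho


def _concentration_ratios(
    before: NetworkModel, after: NetworkModel
) -> dict[str, float]:
    out = {}
    for s in before.species:
        if s.initial_conc > 0 and not s.clamped:
            a = after.species[after.species_index(s.name)].initial_conc
            out[s.name] = a / s.initial_conc
    return out


def knockdown_adapt(
    model: NetworkModel,
    signals: SignalSet,
    target: str,
    factor: float = KNOCKDOWN_FACTOR,
    max_evals: int = 300,
    restarts: int = 1,
    seed: int = 0,
    profile: SolverProfile = FAST_PROFILE,
) -> AdaptationResult:
    """Reduce one protein, then let the other concentrations re-adapt.

    The target's initial concentration is multiplied by ``factor`` and held
    there (the perturbation is externally imposed); kinetic rates stay
    fixed; all other nonzero concentrations are free.  f is normalized to
    the unperturbed model on ``signals``, so the healthy system sits at
    f = 1.
    """
    t_idx = model.species_index(target)
    if model.species[t_idx].initial_conc <= 0:
        raise ValueError(f"knockdown target {target!r} has zero initial concentration")
    base = evaluate_steady_objective(model, signals, profile=profile)
    ref = (base.R_ss, base.d_ss)
    knocked = apply_parameters(
        model,
        ParameterVector({("conc", target, "conc0"): model.species[t_idx].initial_conc * factor}),
    )
    before = evaluate_steady_objective(knocked, signals, ref=ref, profile=profile)
    spec = OptimizationSpec(
        subset="concentrations_only",
        objective="f_cost",
        max_evals=max_evals,
        restarts=restarts,
        seed=seed,
        exclude_species=(target,),
        profile=profile,
    )
    trace = simplex_optimize(knocked, signals, spec, ref=ref)
    after = trace.best_objective
    changes = _concentration_ratios(model, trace.best_model)
    return AdaptationResult(
        perturbed=(target, factor),
        conc_changes=changes,
        f_before=before.f, f_after=after.f,
        R_before=before.R_ss, d_before=before.d_ss,
        R_after=after.R_ss, d_after=after.d_ss,
        n_evals=trace.n_evals,
    )


def signal_shift_adapt(
    model: NetworkModel,
    old_signals: SignalSet,
    new_signals: SignalSet,
    max_evals: int = 300,
    restarts: int = 1,
    seed: int = 0,
    profile: SolverProfile = FAST_PROFILE,
) -> AdaptationResult:
    """Re-adapt concentrations after the extracellular signal range moves.

    ``model`` is taken as adapted to ``old_signals``; concentrations (rates
    frozen) are re-optimized against ``new_signals``.  f is normalized to
    the starting model on the new ensemble, so f_before = 1 and adaptation
    shows up as f_after < 1.
    """
    before = evaluate_steady_objective(model, new_signals, profile=profile)
    ref = (before.R_ss, before.d_ss)
    spec = OptimizationSpec(
        subset="concentrations_only",
        objective="f_cost",
        max_evals=max_evals,
        restarts=restarts,
        seed=seed,
        profile=profile,
    )
    trace = simplex_optimize(model, new_signals, spec, ref=ref)
    after = trace.best_objective
    return AdaptationResult(
        perturbed=None,
        conc_changes=_concentration_ratios(model, trace.best_model),
        f_before=1.0, f_after=after.f,
        R_before=before.R_ss, d_before=before.d_ss,
        R_after=after.R_ss, d_after=after.d_ss,
        n_evals=trace.n_evals,
    )


def transient_training(
    model: NetworkModel,
    signals: SignalSet,
    n_random_starts: int = 10,
    max_evals: int = 150,
    seed: int = 0,
    start_spread: float = 10.0,
    profile: SolverProfile = FAST_PROFILE,
    plateau_cut: float = 3.0,
    transient_cut: float = 10.0,
) -> pd.DataFrame:
    """Train concentrations for a transient (peaked) response.

    Starting from the base model and ``n_random_starts`` seeded random
    concentration profiles (log-uniform within ``1/start_spread`` ..
    ``start_spread`` fold), each start is optimized for the transient score
    with rates frozen.  Returns one row per system, sorted by the achieved
    ``f_transient``, with its classification (< plateau_cut: plateau,
    > transient_cut: transient) and the concentration profile relative to
    the base model.
    """
    concs = ParameterVector.from_model(model, "concentrations_only")
    rng = np.random.default_rng(seed)
    starts = [np.ones(len(concs))]
    for _ in range(n_random_starts):
        starts.append(
            10 ** rng.uniform(
                -math.log10(start_spread), math.log10(start_spread), len(concs)
            )
        )
    rows = []
    for si, mult in enumerate(starts):
        start_model = apply_parameters(model, concs.scaled(mult))
        spec = OptimizationSpec(
            subset="concentrations_only",
            objective="f_transient",
            max_evals=max_evals,
            restarts=1,
            seed=seed + si,
            profile=profile,
        )
        try:
            trace = simplex_optimize(start_model, signals, spec)
            res = trace.best_objective
            tuned = trace.best_model
        except (ObjectiveError, ValueError):
            continue
        if res is None:
            continue
        row = {
            "system": si,
            "f_transient": res.f_transient,
            "R_peak": res.R_peak,
            "d_peak": res.d_peak,
            "R_ss": res.R_ss,
            "d_ss": res.d_ss,
            "class": (
                "plateau" if res.f_transient < plateau_cut
                else "transient" if res.f_transient > transient_cut
                else "mid"
            ),
        }
        row.update(_concentration_ratios(model, tuned))
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values("f_transient", ascending=True)
        .reset_index(drop=True)
    )
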