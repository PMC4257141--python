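# Methods

## The model

`psfopt` ships a mass-action ODE model of β2-adrenergic signaling in a
submembrane compartment of a mouse embryonic fibroblast.  The extracellular
agonist ISO (species `L`) activates the β2 receptor; the receptor catalyses
Gsα nucleotide exchange; GsαGTP binds and activates adenylyl cyclase AC6,
which converts ATP to cAMP; cAMP cooperatively dissociates the PKA
holoenzyme (R2C2 + 2 cAMP ↔ R2C2·cAMP2; + 2 cAMP ↔ R2C2·cAMP4 ↔ R2·cAMP4 +
2 C); free catalytic subunits phosphorylate VASP, and PP1 dephosphorylates
it.  Negative regulation enters through RGS-accelerated GTP hydrolysis on
both Gsα and Gi, Gi-mediated inhibition of AC6, receptor phosphorylation by
PKA followed by Gi coupling, β-arrestin sequestration of the active
receptor, and cAMP degradation by PDE4B.  The packaged tables define 23
reactions over 41 named species; 14 of these are transient Michaelis
complexes of two-step catalytic reactions (`A + E ↔ AE → P + E`), leaving 27
molecular species, 12 of which start at a nonzero concentration.

Units are nM and seconds throughout: `kon` in nM⁻¹ s⁻¹ for bimolecular
steps and nM⁻² s⁻¹ for the two termolecular cAMP-binding steps, `koff` and
`kcat` in s⁻¹.  The ligand is clamped (buffered extracellular signal, no
depletion by binding).  `AMP → ATP` and `pb2L → b2L` are first-order
conversions.

Every reaction is compiled to irreversible elementary steps with flux
`k·∏[Xᵢ]^sᵢ`; the state derivative is the stoichiometry matrix applied to
the flux vector, with clamped rows zeroed.  Conservation relations (total
receptor, total G-protein, total PKA catalytic subunit, total adenine
nucleotide, …) are computed exactly as the integer left null space of that
matrix restricted to non-clamped species, and serve as an independent
correctness oracle for the integrator: trajectories conserve every moiety
total to better than 1e-6 relative.

## Simulation and steady-state conventions

Integration uses LSODA (via `scipy.integrate.odeint`) with the analytic
Jacobian.  Mass-action fluxes are evaluated on the raw state without
clipping: when the stiff solver briefly drives a near-zero species slightly
negative, the consumption flux reverses sign and restores it, which keeps
trajectories nonnegative to solver noise without distorting the error
control.  Solver output more negative than 100× the absolute tolerance
aborts the run.

Steady state is operational, not asymptotic: the system is steady at the
earliest time `t` at which every non-clamped species stays within 2%
(relative, floored at 1e-6 nM) of its value at `t` over the whole window
`[t, t+100 s]`.  The whole-window comparison matters — endpoint-only checks
mistake oscillations whose period divides the window for steady states.
The watch set is the whole system rather than the output alone, so the
criterion certifies network-wide quiescence.  This pragmatic definition is
necessary because the model has an extremely slow relaxation mode: PKA
holoenzyme re-association (kon ≈ 8.5e-8 nM⁻² s⁻¹) equilibrates on a time
scale of days, so exact equilibrium is never reached in practice.
Steady-state values are read at `t_ss + 100 s`, making them independent of
how the integration was chunked.

Two solver profiles are used.  The reference profile (rtol 1e-8, atol 1e-6
nM, output every 1 s for the first 100 s after a step, phases capped at
10,000 s) produces every reported number; halving its tolerances moves
steady states by <0.1%.  A fast profile (rtol 1e-6, atol 1e-4, coarser
output) drives the inner loops of optimization and random scans; the best
point found is always re-evaluated under the reference profile before being
reported.

## Transmission metrics

A signal-transmission task is an ensemble of input steps `(S0, St)`.  The
default ensemble uses 16 log-spaced baselines in [10, 900] nM, each stepped
to 110%, 150% and 200%, with steps clipped at 1 µM (random-scan experiments
use baselines from 1 nM instead).  Per pair the protocol is: equilibrate
with the input clamped at `S0` (baselines are computed once per `S0` and
shared across folds), step the clamp to `St`, run to steady state again,
then read

* the response coefficient `R = (Ct/C0 − 1)/(St/S0 − 1)` on the output
  species (1 = perfect transmission of the relative change, <1 loss, >1
  amplification), and
* the EC90 delay: the first time the output crosses 90% of its eventual
  steady-state change, linearly interpolated between output points.

Ensemble metrics are arithmetic means over converged pairs; pairs that fail
to converge or have an undefined response are counted in `n_failed`, and an
evaluation with more than 50% failures is treated as invalid.

Both aggregates are sensitive to the ensemble discretization.  On the
packaged model the transfer curve has its half-maximal input near 20 nM, so
log-spaced baselines up to 900 nM place most pairs on the saturated
shoulder; the committed 16-baseline ensemble yields `R_ss ≈ 0.19` and
`d_ss ≈ 200 s`.  Coarser grids move `R_ss` up to ≈ 0.26 while the mean
delay stays near 200–250 s; no discretization of this curve yields a
qualitatively different pair of aggregates.  The acceptance script reports
the values of the committed ensemble.

## Objectives and scalarization

Transmission quality trades response against speed.  The optimizer works on
the maximization form `J = R/R_ref − d/d_ref`, the equally weighted,
reference-normalized combination; classification uses the cost form
`f = (d/d_ref)/(R/R_ref)`, which places the reference system exactly at
`f = 1` (smaller is better; `f < 2` marks high-efficiency systems, `f > 5`
low-efficiency ones).  The reference `(R_ref, d_ref)` is the unmodified
model evaluated on the active signal ensemble.  Nonpositive `R` means the
signal is lost entirely and scores `J = −∞`, `f = +∞`.

The transient score rewards peaked over sustained responses:
`f_transient = R_peak / max(R_ss, 0.05)`, where `R_peak` applies the
response-coefficient formula to the trajectory extremum and `R_ss` to the
steady state.  The floor of 0.05 keeps the fold-excess bounded when the
steady response is suppressed toward zero — exactly the regime transient
signaling aims for.  Scores below ≈3 indicate plateau responses, above ≈10
strongly transient ones.

## Optimization

Parameters are optimized in log10 space (rates span ten orders of
magnitude), as multipliers relative to the starting model, with box bounds
of 0.2–5× for kinetic rates and 0.1–10× for initial concentrations,
enforced by clipping plus a penalty on the distance clipped.  The optimizer
is Nelder–Mead with an explicit initial simplex of 0.2 log-unit edges,
simplex-size convergence at 1e-3 log units, and an evaluation budget shared
across restarts (default 2000 evaluations, 3 restarts; restart points are
drawn from the seeded RNG, so runs are bit-reproducible).  The starting
point is always evaluated first and the best-ever point is tracked across
all evaluations, so a fit can never end worse than it began.  Failed or
invalid evaluations receive a large penalty score rather than an exception.

Whole-model fits (rates + concentrations, 70 free parameters) improve
quickly and then crawl: the single-objective acceptance runs use budgets of
300–400 evaluations, by which point the simplex has long cleared the
qualitative outcomes of interest.  Adaptation experiments free only the 12
initial concentrations (rates frozen; a knocked-down species is held at its
imposed level) and use budgets of 150–300 evaluations.

## Experiments

*Rate-space scan.*  Each kinetic rate is multiplied by an independent
log-uniform factor in [0.2, 5] (multiplicative noise is the natural scale
for rate constants); each sampled system is evaluated against the 1 nM–1 µM
ensemble and classified by `f`.  Per-class spread of log10 Kd and log10 KM
per reaction quantifies parameter "sloppiness"; the cross-correlation
matrix of log10 Kd values exposes compensating parameter pairs.

*Concentration robustness.*  For sampled rate sets, every initial
concentration is multiplied by an independent uniform factor in
[0.8, 1.2] (a generic expression-noise magnitude) and `f` is re-evaluated;
the Spearman rank correlation between original and perturbed `f` measures
whether concentration noise reorders rate-set quality.

*Knockdown re-adaptation.*  One protein is reduced to 10% and frozen; the
remaining concentrations re-optimize against the unperturbed reference.
Adaptation minimizes the cost `f` directly (through `−log10 f`, i.e.
`log R − log d` up to a constant) rather than the additive `J`: after a
severe knockdown the response coefficient can collapse toward zero, where
`J` degenerates into pure delay minimization and can drive `f` further up,
while the log-cost keeps restoring the response worthwhile at any depth.
The result is the per-species ratio of adapted to pre-perturbation
concentration, plus `f` before and after adaptation.  Net up/down
regulation is judged over the mean log ratio of the protein concentrations
(the metabolite pools ATP and cAMP adjust too but are not
expression-regulated proteins).

*Signal-range shift.*  The model adapted to one input range re-optimizes
its concentrations against a shifted ensemble; the reference is the
starting model on the new ensemble, so `f_before = 1` by construction.

*Transient training.*  From the base model and seeded random concentration
profiles (log-uniform within 10-fold), concentrations are optimized for
`f_transient`; systems are reported sorted by the achieved score with their
concentration profiles, separating plateau from transient solutions.

All experiments are deterministic functions of (configuration, seed).

## Numerical choices and edge cases

* Sigmoid fits are 4-parameter logistics in log10-input space via
  least squares; flat curves return the grid midpoint as the (unidentified)
  midpoint with slope 0 and a `degenerate` flag; decreasing curves are
  normalized to the rising-branch parameterization.  The reported slope is
  the derivative of the 0–1 normalized curve at its midpoint
  (= hill·ln10/4).
* EC90 delays interpolate linearly between output points and are
  direction-aware; a response that never crosses its EC90 level raises a
  delay-specific error, distinct from convergence failure.
* Peaks are global extrema; a transient is flagged when the peak overshoots
  the steady state by more than 5% of the steady-state change.
* `Kd = koff/kon`, `KM = (koff + kcat)/kon`; reactions with `kon = 0` are
  skipped with a logged warning.

## Limitations

* Single well-mixed compartment, deterministic mass action: no space, no
  stochasticity, no pulse-train inputs.
* The steady-state criterion is operational; systems with day-scale
  relaxation report values on the slow manifold, not at true equilibrium.
  All comparisons use the same criterion, so they are internally
  consistent.
* Ensemble aggregates (`R_ss`, `d_ss`) depend on the assumed input
  distribution; only within-package comparisons at a fixed ensemble are
  meaningful.
* Nelder–Mead in 70 dimensions finds good local improvements, not global
  optima; adaptation outcomes (which species compensate) can depend on the
  seed and budget, which is why the experiment API exposes both.
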