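# Methods

This note documents the models the package implements, the choices made
where the published description leaves room, and what the synthetic-data
driven tests do and do not demonstrate.

## Structural models

The BUP/norBUP system is linear and time-invariant for a given subject, so
it is solved exactly by piecewise matrix-exponential propagation between
dose events (each sublingual dose is an impulse of F·amount into the first
transit compartment). For population simulations on a regular grid the
one-step propagator expm(A·dt) is computed once per subject and iterated,
which is exact for impulse inputs aligned to the grid. Naloxone uses the
closed-form Bateman superposition. Both routes are cross-checked in the
tests against a high-accuracy general-purpose ODE integrator (relative
error ≤ 1e−6) and against analytic identities (AUC·CL/F = F·Dose; mass
balance to 1e−6 with the elimination sink included).

Conventions that matter:

- **Transit chain length.** Only the mean transit time (MTT, 0.234 h) is
  published, not the number of transit compartments. The default is
  n = 3 with ktr = (n+1)/MTT, configurable 0–10. Because MTT is small
  relative to 1/ka, the profile is nearly insensitive to n; the choice is
  structural, not fitted.
- **Units.** Amounts in ng (doses converted at 1e6 ng/mg, no salt-to-base
  correction — the apparent F absorbs it), volumes in L, concentrations in
  ng/L internally. Pharmacodynamic thresholds quoted in ng/mL (3, 4.6,
  0.67) are converted ×1000 at module boundaries. LLOQs are 50 ng/L
  (BUP/norBUP) and 20 ng/L (NLX).
- **Metabolite scale.** Fm is fixed to 1 and the norBUP parameters are
  apparent ("/Fm"); the parent elimination flux transfers amount 1:1·Fm
  with no molar correction.
- **Fm dose tier.** The published results state a 16 mg tier Fm of
  "1.98 vs 1" while the linear-categorical covariate form implies a
  multiplier of 1 + 1.98 = 2.98. The default follows the covariate-form
  reading; `fm_absolute=True` selects the literal 1.98 multiplier. The
  choice only affects norBUP levels, not any of the BUP- or NLX-based
  optimization endpoints.
- **Swallowing covariate.** F = 1 + θ_NOS·(NOS − 2) with θ_NOS = −0.035 and
  the overall median (2) as the centering value, floored at 0.05 so linear
  extrapolation beyond the observed 0–12 range cannot produce a
  non-positive bioavailability.
- **Pre-dose convention.** When an output time coincides with a dose event
  the reported concentration is the trough (dose applied after sampling).
- **IIV reporting convention.** The published %CV values are interpreted as
  ω·100 (the SD of the log-normal η), not √(exp(ω²)−1); this is the common
  reporting convention for exponential random-effect models.

## Synthetic-trial generator

The generator reproduces the study design: arms 4/8/16 mg single dose
(n = 12/12/10, healthy volunteers) sampled pre-dose and at 0.25–72 h
(17 post-dose times), and 8 mg once daily × 8 days (n = 12, OUD subjects)
with troughs on days 6–8 plus nine post-dose times after the day-8 dose.
Number-of-swallows is drawn per arm from a shifted binomial calibrated to
the published median and range (4 mg: median 3.5 on 0–8; 8 mg: 2 on 0–3;
16 mg: 6.5 on 2–12); the multiple-dose arm, where NOS was not recorded, is
imputed with the single-dose 8 mg median (2). η is drawn once per subject
(no inter-occasion variability — none is modelled), residual error follows
the analyte's residual model, and values below the LLOQ are emitted as
censored records (pre-dose zeros therefore appear as BQL). Demographics are
drawn uniformly within the published per-arm ranges; they exist to exercise
the covariate-screening null path, as only NOS and dose enter the final
models.

What the generator does *not* emulate: assay drift, dropout or dosing
deviations, inter-occasion variability, and the exact censoring pattern of
the real study. In particular the simulated NLX arms censor more heavily
(≈70%) than the study observed (20.3% single / 56.2% repeat dose), because
the published one-compartment typical profile spends less time above
20 ng/L than the real data did. Passing tests therefore demonstrate
self-consistency of the pipeline under the published model, not fidelity of
that model to the unavailable raw data.

## Estimation

The marginal likelihood is approximated subject-by-subject with the Laplace
method: the joint −2 log-likelihood J(η) is minimized by a warm-started
damped Newton iteration (finite-difference gradient/Hessian, tolerance
1e−8), and −2 log L_i = J(η̂) − q·log 2π + log|J″(η̂)/2|. FOCE-I replaces J″
with the Gauss–Newton/expected-information form 2·f′f′ᵀ/V + V′V′ᵀ/V² +
2Ω⁻¹, which keeps the residual-variance dependence on η (the
"interaction") while dropping model second derivatives. On a one-η toy
model both objectives agree with adaptive-quadrature marginal likelihood to
better than 0.5% (Laplace: 0.05%). BQL handling follows the 10% rule: M1
(discard) below, M3 (censored-normal mass) at or above, with the estimation
method paired to it (FOCE-I/M1, Laplace/M3) unless overridden.

The outer problem optimizes fixed effects, ω and σ by Nelder–Mead on a log
scale (covariate coefficients unconstrained), with Ω diagonal. Structural
identifiability guardrails mirror the published model: Fm fixed, F_NLX
fixed at 0.01, no IIV on ka. Standard errors come from a finite-difference
Hessian of the marginal −2LL (condition number from its eigenvalue ratio);
shrinkage is 1 − SD(EBE)/ω and 1 − SD(IWRES). Sequential parent–metabolite
fitting (PPPD) runs parent-only → metabolite-with-parent-fixed → joint
refinement, and the tests verify stage self-consistency on noise-free data
and the OFV nesting property. Stepwise covariate modelling applies greedy
forward inclusion at ΔOFV ≥ 6.64 and backward elimination retaining
covariates whose deletion raises OFV ≥ 10.83; the thresholds are enforced
exactly and the univariate EBE prescreen (ANOVA / regression at p < 0.05)
is provided as a screening heuristic.

Deterministic least-squares refits (log-parameters, log-concentration
residuals, Levenberg–Marquardt) provide the structural self-consistency
checks: they recover the published clearances exactly from noise-free
profiles. The one-compartment Bateman model is invariant under swapping
absorption and elimination rates; recovered NLX parameters are
canonicalized to the absorption-limited branch (ka < CL/V), matching the
published flip-flop parameterization.

### Problem sizes used in the test suite

Full nine-η refits of the complete design are beyond what the
finite-difference Laplace implementation can do quickly, so the stochastic
parameter-recovery experiment runs the full 46-subject design but frees
only the clearance, its IIV and the residual SD, holding the remaining
structural parameters at the published values; the unmodelled IIV is
absorbed by the residual term. Under these conditions the recovered
CL_BUP/F and CL_NLX fall inside the published bootstrap 95% CIs. The SCM
power experiments are likewise scaled: threshold logic is verified exactly
against a synthetic OFV oracle, and end-to-end selection is demonstrated on
a small scenario with a strongly detectable covariate rather than by
re-running the full study-power simulation. Diagnostics tests use 150–500
simulation replicates instead of 1000.

## Diagnostics

VPC/pcVPC bin on the nominal protocol times (the design is rich and fixed,
avoiding data-driven binning ambiguity), merging bins with fewer than two
observations. Simulated replicates redraw η and residual error under the
original design and are censored at the same LLOQ before percentiles are
computed, so the observed and simulated summaries — including the
BQL-fraction-versus-time panels — are compared on equal footing.
Prediction correction scales each record by bin-median PRED over its own
PRED. The NPC tabulates observed versus simulated medians of
concentration, AUC and Cmax. GOF residual tables report PRED/IPRED, IWRES
and CWRES (first-order conditional linearization around the EBEs),
replacing CWRES with a simplified rank-based NPDE (inverse-normal of
simulation ranks, no decorrelation) whenever the fit used M3.

## Dose optimization

Eight days of dosing are simulated per virtual patient (terminal half-life
≈ 26 h, so day 8 is effectively steady state) with IIV but without residual
error — the targets concern true plasma concentration. The day-8 window is
evaluated on a 0.05 h grid with linear interpolation at threshold
crossings; halving the step changes %T>MSC by < 0.5 percentage points.
Doses follow the 08:00 clock (QD 24 h, BID 12 h, TID 8 h apart; mixed
regimens give the larger dose first with equal spacing). NOS per dose event
defaults to the dose-group median (4 mg → 3.5, 8 mg → 2, 16 mg → 6.5),
with an option to resample NOS per patient. The recommendation rule gates
on safety (≥95% of patients with day-8 NLX peak < 4.6 ng/mL) and efficacy
(median μORO ≥ 70% throughout day 8), then ranks passing regimens by total
daily dose with ties broken by the lower median NLX peak. Note that %T>MSC
is *not* monotone in labelled daily dose across the candidate list: the
16 mg tablets carry a higher median swallow count (F ≈ 0.84) and longer
dosing intervals erode troughs, which is precisely why 8 mg TID outperforms
nominally larger regimens.

## Known limitations

- The published typical parameters underpredict the observed mean
  dose-normalized Cmax for the 8 mg arm (simulated population mean
  ≈ 440 ng·L⁻¹·mg⁻¹ versus 583 ± 248 observed); the simulation-based
  plausibility check therefore uses a wide band. This is a property of the
  published model, not of the reimplementation.
- No inter-occasion variability, no covariate effects beyond NOS, dose
  tier and the NLX dose-on-F power term.
- The rank-based NPDE is not decorrelated across records within a subject.
- The outer optimizer is derivative-free; very high-dimensional fits (all
  thetas plus nine variance components) are possible but slow, and the
  bootstrap at its full 1000-replicate size is intended for batch use, not
  the test suite.
- The study cohort was all male; sex is not a covariate anywhere in the
  pipeline.
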