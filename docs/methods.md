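# Methods

## Pharmacokinetic model

Vancomycin disposition is modelled as a linear two-compartment system with
zero-order infusion input. The state is the amount pair (A₁, A₂) in mg;
concentration is A₁/V₁ in µg/mL (mg/L). Total clearance is piecewise
constant in time: the patient's physiological (body) clearance everywhere,
plus the extracorporeal clearance during haemodialysis sessions, gated on
the half-open interval [start, start + duration) so boundary values are
unambiguous. The model is linear in dose, so simulated AUCs scale exactly
with dose — a property the attainment sweep and several tests exploit.

Assumptions worth stating explicitly: drug input and elimination are
linear (no saturable binding or clearance); the dialyzer operates at
steady state with constant flows for the whole session; post-dialysis
rebound is represented only through redistribution from the peripheral
compartment, not as a separate process; "blood flow" is treated as the
flow available to the dialyzer without a haematocrit/plasma-water
correction (the convention in which membrane baseline clearances are
reported).

## Dialyzer clearance

A membrane is characterised by baseline clearances of creatinine and
vitamin B12 measured at reference flows (defaults 200/500 mL/min). The
mass-transfer–area coefficient KoA is recovered by inverting the
countercurrent relation

    CL = Q_b (e^z − 1) / (e^z − Q_b/Q_d),  z = (KoA/Q_b)(1 − Q_b/Q_d),

with the analytic limit CL = Q_b·KoA/(Q_b + KoA) at equal flows; the
inversion brackets the root and solves with Brent's method to ~1e-12
relative tolerance, and round-trips through the forward formula to better
than 1e-8. Vitamin B12 (1355 Da) is the vancomycin (1449 Da) surrogate by
default because the molecular weights are close; an optional mode instead
fits log KoA linearly in log molecular weight through the creatinine and
B12 baselines and evaluates at vancomycin's weight (off by default — it
extrapolates slightly beyond B12 and typically lowers CL_HD by a few
percent). Ultrafiltration adds Q_uf·(1 − CL_diff/Q_b), the convective
removal from blood already partially cleared by diffusion. User-facing
flows are mL/min and are converted to L/h once at ingestion.

Diffusive clearance is monotone non-decreasing in each flow and in the
baseline clearance, and bounded by min(Q_b, Q_d) + Q_uf; both properties
are tested.

## Integration

Profiles are integrated with the fixed-step fourth-order Runge–Kutta–Gill
scheme (stage coefficients a₂₁ = 1/2, a₃₁ = (√2−1)/2, a₃₂ = (2−√2)/2,
a₄₂ = −√2/2, a₄₃ = 1+√2/2; weights (1, 2−√2, 2+√2, 1)/6). Steps are
aligned so that every infusion start/stop and session start/stop falls on
a grid boundary; within each inter-event segment the nominal step is
shrunk to divide the segment evenly, so the right-hand side is smooth over
every step and the scheme retains its full order. The default step is
0.05 h: for this non-stiff system it resolves 1-h infusions and 3.5-h
sessions with errors orders of magnitude below assay noise (the suite
checks < 0.5% against an adaptive DOP853 reference with 1e-11 relative
tolerance; the observed deviation is ~1e-6%). Estimation uses a coarser
0.1-h step because the optimizer re-simulates per objective evaluation;
the accuracy loss is negligible relative to residual error. The inner loop
is JIT-compiled with numba for speed; the algorithm is identical to the
pure-Python statement of the scheme.

## Bayesian (MAP) estimation

Individual parameters are param_i = typical_i · exp(η_i). The estimator
minimises the penalised least-squares objective

    Σ_j (c_obs,j − c_pred,j)²/[(σ_prop c_pred,j)² + σ_add²] + Σ_i η_i²/ω_i²

over the η with ω_i > 0, i.e. a MAP point estimate under a log-normal
population prior and a combined proportional+additive residual model. The
± log-variance term of the full −2 log-likelihood is available behind
`include_variance_log` but off by default, matching the quadratic form
above. Optimisation starts at the prior mode η = 0 with Nelder–Mead and
refines with L-BFGS-B under |η_i| ≤ 5; an optional seeded multistart
(5 starts) exists for multimodal cases but single-start is the default.
Observations before the first dose are excluded with a warning;
non-convergence returns population-typical values with a flag.

With one pre-dialysis sample, clearance is the best-identified parameter:
the sample sits ~86 h into therapy after one dialysis session, so its
log-concentration is roughly proportional to cumulative clearance. On the
default synthetic cohort (n = 200, default residual noise) the median
absolute relative error of recovered clearance is ~11–13% and of the
second-term AUC ~6–7%; both are recomputed by `scripts/acceptance.py`.

## Term AUCs

Exposure windows are 24-h terms anchored at the END of the initial HD
session. The end-of-session anchor is a deliberate choice: it puts the
post-dialytic dose, its peak and the distribution phase into term 1 —
which is exactly why term 1 predicts poorly and term 2 (24–48 h after the
anchor) is the working PK/PD metric. The anchor is configurable to session
start. Each term AUC is the arithmetic mean of simulated concentrations at
grid points inside the window (inclusive start, exclusive end, so adjacent
terms never share a point) multiplied by 24 h. For dosing decisions the
inter-dialysis interval is fixed at 48 h regardless of the true schedule,
so events beyond the second session are ignored in that context. The
trapezoid rule appears only as a test oracle, never as the estimator. The
mean rule is first-order in step size; at the default steps its bias is
≤ 0.05% for realistic elimination rates (tested against the closed form at
0.2%).

## Regimen classification and target attainment

Regimens are classified on three axes in mg/kg — cumulative initial two
doses (low 24.75–31.5, standard 31.5–38.5, high 38.5–46.2), loading dose
(18–22.5 / 22.5–27.5 / 27.5–33.0) and maintenance dose (6.75–9.0 /
9.0–11.0 / 11.0–12.0) — with half-open [lo, hi) bands, the top band closed
at its upper bound, and "unclassified" outside all bands. The printed band
edges are taken literally; the clinical rounding that produced them is not
re-modelled.

Attainment simulation draws n virtual patients (weights, η's, HD settings,
session geometry), administers the loading dose at t = 0 and the
maintenance dose immediately at the end of the first session (1-h
infusions by default), and bins the second-term AUC into
<400 / [400,600) / [600,700) / ≥700 µg·h/mL; the target fraction is
[400,700). The same seed draws the same cohort, so regimens are compared
on fixed patients.

## Synthetic cohorts

The generator emulates the study population's structure: truncated-normal
draws (truncated at physical lower bounds) for elapsed time to the first
session (39.3 ± 4.0 h), session duration (3.5 ± 0.5 h), blood flow
(174.6 ± 36.7 mL/min), one high-flux polysulfone-like membrane class (B12
baseline 130 ± 15, creatinine 170 ± 15 mL/min at 200/500 reference flows —
typical bench values for this membrane class), ultrafiltration 10 ± 3
mL/min (~2.5 L removed per 3.5-h session), log-normal weights (60 kg, CV
20%), a thrice-weekly 48/48/72-h schedule with random phase, a regimen mix
matching the observed low/standard/high frequencies (9:68:42) with the
observed per-class dose means, MICs from {0.5, 1.0, 2.0} µg/mL at 2:28:1,
and one pre-dialysis sample 0.5 h before the second session with combined
proportional (15%) + additive (0.5 µg/mL) noise. The early-response flag
is Bernoulli with logit = −4.85 + 0.01·(AUC2nd/MIC) + 1.16·source-control
(prevalence 0.55), calibrated analytically so the marginal response rate
is near the observed 58%. A q12h non-HD control cohort (15 mg/kg q12h,
trough standardised to 11 h after the end of the fourth infusion, day-2
AUC over 24–48 h) supports the surrogate-marker comparisons.

What the generator does not emulate — and hence what passing tests do not
establish about real data: joint dependence among weight, flows and
membrane performance (all independent here); within-patient variability
over days; delayed or missed sessions; assay censoring at the dynamic
range edges; and any non-logistic exposure-response shape. Recovery and
calibration results on these cohorts validate the machinery, not the
clinical effect sizes.

## Statistics layer

Odds ratios are (a·d)/(b·c) with the Woolf interval
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); at the default α = 0.05 the
conventional two-decimal quantile z = 1.96 is used (this is what
reproduces published clinical factor tables to their printed precision;
other α use the exact quantile). Association p-values use Pearson's
chi-square without continuity correction, or the two-sided Fisher exact
test when any expected cell is below 5 — a rule that reproduces the
published table's printed p-values. Zero cells flag the OR undefined; no
continuity correction is applied.

Stepwise logistic regression screens candidates univariately at p < 0.2
(2×2 test for binary factors, likelihood-ratio test for continuous),
then runs forward-backward selection on likelihood-ratio p-values with
enter/stay thresholds of 0.05 (all three thresholds configurable; the
published analysis states only the 0.2 screen, so 0.05 is this package's
choice for the in-model criterion). Quasi-complete separation is flagged
via coefficient magnitude — small samples produce the same unstable, very
wide intervals the original analysis acknowledged. Perfectly collinear
duplicates never both enter: the second cannot improve the likelihood.

ROC analysis computes AUC as the Mann–Whitney concordance with mid-rank
ties (identical to the trapezoid over the empirical curve) and reports the
observed score value maximising Youden's J for the rule "positive if
score ≥ cut-off", ties broken toward the higher cut-off (higher
specificity). Correlations are compared with Fisher's z (two-sided normal
test); |r| = 1 is flagged as an infinite-z degenerate case. Group
comparisons are normality-gated: Student's t when both groups pass a
Shapiro–Wilk screen at α = 0.05, otherwise Mann–Whitney; paired
comparisons (e.g. term-1 vs term-2 AUCs within patients) use the Wilcoxon
signed-rank test. Groups below n = 3 are refused.

## Population parameter defaults

The two shipped priors are clearly-labelled placeholders, not any
published model's estimates, and are overridable via YAML:

| parameter | HD default | non-HD default | rationale |
|---|---|---|---|
| CL_body | 0.45 L/h | 3.3 L/h | anuric non-renal vs moderate-function vancomycin clearance |
| V₁ | 0.24 L/kg (weight-scaled) | 0.24 L/kg | typical central volume |
| Q | 6.5 L/h | 7.0 L/h | typical distribution clearance |
| V₂ | 38 L | 40 L | steady-state volume ≈ 0.85 L/kg total |
| ω (CL, V₁) | 0.30, 0.25 | same | literature-typical inter-individual CVs |
| σ_prop, σ_add | 0.15, 0.5 µg/mL | same | combined model; the assay floor (dynamic range 0.8–50 µg/mL) motivates the additive term |

ω for Q and V₂ defaults to 0 (fixed at typical values): a single sample
cannot inform them, and fixing them keeps the MAP problem well-posed.
Under these defaults a 60-kg typical patient on 30 + 10 mg/kg lands at an
AUC2nd of ~454 µg·h/mL with a pre-dialysis level of ~19 µg/mL — inside the
clinically reported range for this setting.

## Numerical choices and degenerate inputs

Tolerances: KoA inversion 1e-12 (round-trip verified at 1e-8); integrator
validated at < 0.5% vs the adaptive reference and at 0.1%/0.01% on the
closed-form AUC and mass-balance identities; MAP optimizer xatol 1e-4 on
η. Degenerate handling: zero blood flow turns the dialyzer off; equal
dialyzer flows use the analytic z → 0 limit; baseline clearance at or
above the smaller reference flow is an infeasible membrane (error);
observations before the first dose are excluded with a warning; an all-tied
score vector gives ROC AUC 0.5; identical groups give p = 1; omega = 0
pins a parameter to its typical value.

Problem sizes used by the default test run and the acceptance script —
n = 200 for MAP recovery, n = 300 per regimen for attainment, 100
replicates of n = 150 for null calibration — were chosen so each check's
Monte-Carlo error is small against the bound it tests while the whole
suite stays quick to run routinely.

## Known limitations

* Haemodiafiltration and continuous RRT are out of scope; intra-dialytic
  administration (with its 20–30% intra-session loss) is not modelled
  beyond what session-gated clearance produces.
* The 72-h-interval maintenance escalation rules are exposed only as a
  configuration hook, not implemented policy.
* The stepwise stay/enter criterion and the Shapiro gating threshold are
  conventions, not reproductions of an unstated original choice.
* Published cohort-level PK medians (term-AUC medians, the R² between
  pre-dialysis level and AUC2nd, ROC cut-offs, attainment percentages)
  depend on unpublished individual covariates and are not reproduction
  targets; synthetic analogues are computed and labelled as such.
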