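# Methods

## The model

`spinacarb` implements a compact nonlinear model of fasting insulin–glucose
homeostasis built from three physiological motifs:

1. **First-order pharmacokinetics.** Secretion/absorption rates x(t) (mol/s)
   are converted to plasma concentrations by dilution and elimination:
   dy/dt = α·x(t) − β·y(t), with α = 1/V_D (1/L) and β = ln 2 / t½ (1/s).
   At equilibrium such an element acts as a pure gain G = α/β (s/L). The
   glucose and insulin elements have gains G1 = α_G/β_G and G3 = α_I/β_I.
2. **Saturation kinetics** for stimulating paths. Beta-cell secretion
   S = G_β·G/(D_β + G) saturates in glucose with EC50 D_β and capacity G_β;
   receptor signalling M = G_R·I/(D_R + I) saturates in insulin with EC50
   D_R and gain G_R; the distal (post-receptor) signal is N = G_E·M with
   effector gain G_E.
3. **Non-competitive (divisive) inhibition** for the inhibiting path:
   endogenous glucose production Q = P/(1 + N), where P is the constitutive
   production rate. Total glucose arrival is R = W + Q with W the intestinal
   absorption rate (0 when fasting).

The closed loop is therefore a two-state ODE system

    dG/dt = α_G·(W + P/(1 + N(I))) − β_G·G
    dI/dt = α_I·S(G) − β_I·I

Deliberately omitted (as in the source model): glucagon, incretins,
somatostatin, autonomic and cytokine inputs. The reference parameter set
(α_G = 0.11 L⁻¹, β_G = 7.1e-4 s⁻¹, G_β = 2.8 pmol/s, D_β = 7 mmol/L,
α_I = 0.2 L⁻¹, β_I = 3.4e-3 s⁻¹, G_R = 2.3 mol/s, D_R = 1.6 nmol/L,
G_E = 50 s/mol, P = 150 µmol/s, W = 0) is the package default.

## Fasting steady state

With W = 0, eliminating the fast variables gives the scalar fixed-point map
G ← G1·P/(1 + K1·G/(K2+G)) with

    K1 = G_E·G_R·G3·G_β/(D_R + G3·G_β),   K2 = D_R·D_β/(D_R + G3·G_β)

whose equilibria solve (1+K1)·G² + (K2 − G1·P)·G − G1·K2·P = 0. The constant
term is negative for every positive parameter set, so the roots have
opposite signs and the positive root is the unique physiological
equilibrium; insulin follows as I = G3·G_β·G/(D_β+G). With the defaults
this gives G∞ = 4.3377 mmol/L and I∞ = 63.01 pmol/L — normal fasting
values. The fixed-point iteration (`fixed_point_iteration`, tolerance
1e-12 mol/L, max 10⁶ iterations — the map is a cheap scalar contraction) is
kept as an independent route and must agree with the closed form; this
dual-route check appears throughout the tests.

## SPINA structure-parameter estimators

Solving the equilibrium equations for the two clinically interesting gains
yields single-sample estimators from one fasting (G, I) pair:

    SPINA-GBeta = I·(D_β + G)/(G3·G)                              [pmol/s]
    SPINA-GR    = G1·P·(D_R + I)/(G_E·I·G) − D_R/(G_E·I) − 1/G_E  [mol/s]

These are exact algebraic inversions: evaluated at the model's own
equilibrium they return the generating G_β and G_R to machine precision
(the package's core correctness property). All model constants inside the
estimators come from an explicit `ParameterSet`, so the estimators are
recalibratable. SPINA-GR can be negative for samples with glucose above the
open-loop value G1·P (≈ 23.2 mmol/L at defaults); such values are flagged,
never clipped, because they carry information about model inconsistency.

Comparators are implemented in their original conventional units:
HOMA-IR = G[mmol/L]·I[µU/mL]/22.5, HOMA-Beta = 20·I[µU/mL]/(G[mmol/L]−3.5),
QUICKI = 1/(log10 I[µU/mL] + log10 G[mg/dL]). HOMA-Beta is structurally
undefined for G ≤ 3.5 mmol/L (the "HOMA-blind zone"); the panel flags these
records rather than returning a negative pseudo-value, and excludes them
from summaries. The insulin conversion factor (6.0 pmol/L per µU/mL,
configurable; 6.945 is also in circulation) and the glucose factor
(18.018 mg/dL per mmol/L, the molecular weight over ten) live in a single
`UnitConvention`; internally everything is mol/L and mol/s, converting only
at the I/O boundary, because the estimators mix pmol, nmol and mmol scales
and a single canonical system prevents silent 10³ errors.

## Simulator numerics

Classical fixed-step RK4, default dt = 1 s (the system's fastest time
constant is 1/β_I ≈ 294 s, so dt = 1–2 s is far below any stability limit
and keeps runs bit-deterministic). dt is capped at 60 s. Intravenous
boluses are applied as exact concentration increments amount·α_G between
steps, matching the α = 1/V_D dilution semantics, not smeared over a step.
The oral protocol uses a single-exponential absorption profile
W(t) = f·D·k_a·exp(−k_a·t) with bioavailability f = 0.8, k_a = 1/1800 s⁻¹
and default dose 75 g (D = dose/180.18 mol); the shape is a declared,
configurable default, chosen for an analytically checkable integral
(∫W dt = f·D), not inferred from data. A fasting run from any initial state
converges to the analytic equilibrium; the tests require agreement within
0.1% after ≥ 10 glucose time constants from a 4 × 3 grid of initial
conditions, and invariance under step halving.

## Synthetic cohorts

The generator emulates the statistical structure of fasting-pair validation
cohorts, entirely from the model:

- each subject draws (G_R, G_β) log-normally (default medians = the
  reference values, geometric SD 1.5 — a declared fixture choice, since no
  between-subject dispersion estimates are available for these gains);
- optionally G_β = κ/G_R × log-normal scatter (κ = 2.8 pmol/s × 2.3 mol/s,
  geometric SD 1.2), reproducing the hyperbolic compensation geometry in
  which rising beta-cell output offsets falling insulin sensitivity;
- the subject's noiseless record is the analytic equilibrium for its
  parameters — so noiseless cohorts satisfy the steady-state quadratic
  identically and recovery is exact by construction;
- each repeat visit applies independent multiplicative log-normal assay
  noise with mean 1, σ = sqrt(ln(1+CV²)); defaults CV = 10.2% for insulin
  (a realistic chemiluminescence-assay precision) and 2% for glucose;
- impaired strata are defined purely by parameter shifts (prediabetes-like:
  G_R × 0.5; diabetes-like: G_R × 0.5 and G_β × 0.6), keeping ground truth
  unambiguous; no glycemic thresholds or clinical labels are applied.

What passing tests on these cohorts show: the estimators, panel plumbing
and statistics behave correctly when the data-generating process is the
model itself plus assay noise. What they do not show: robustness to model
misspecification, demographic covariate structure, assay non-linearity or
drift, or anything about real populations.

Under the default noise (insulin CV 10.2%, glucose 2%, n = 1000) the median
absolute relative recovery error of both estimators falls in (0.05, 0.09);
this band was frozen from an independent Monte-Carlo error-propagation run
over 20 generator seeds before the generator was wired to the test.

## Statistics layer

Group contrasts use tie-corrected Kruskal–Wallis with post-hoc pairwise
Mann–Whitney U (exact null for small tie-free samples, tie/continuity
corrected normal approximation otherwise — scipy's automatic switch) and
Benjamini–Hochberg correction. Correlations are Spearman with midrank ties;
two dependent overlapping correlations (sharing one variable) are compared
with Zou's method: individual Fisher-z confidence limits combined using the
asymptotic correlation between the two estimates. Method agreement uses
Bland–Altman (bias, bias ± 1.96·SD limits, proportional-bias slope of
differences on pair means with a t-based 95% CI). Repeatability of repeated
visits uses e = Var_inter/(Var_intra + Var_inter) with unbiased (n−1)
sample variances, within-subject variances pooled by unweighted mean — a
standard decomposition, documented because other estimator choices would
shift e slightly; subjects with fewer than two repeats are excluded with a
warning. All tests are two-sided at α = 0.05.

## Problem sizes and degenerate inputs

Default verification sizes: 1000 random parameter sets for the round-trip
and dual-route checks, a 4 × 3 initial-condition grid run for 12 glucose
time constants at dt = 2 s, n = 1000 subjects for noisy recovery and
n = 2000 for the coupling geometry. Degenerate inputs are handled
explicitly: G_R = 0 or G_β = 0 give the well-defined open-loop equilibria
(G∞ = G1·P when insulin exerts no action); zero dose reduces any protocol
to fasting; missing cohort concentrations propagate as missing outputs,
never as zeros; scalar index calls raise typed errors while the vectorised
panel returns NaN plus a flag.

## Known limitations

- The model has no meal-composition, incretin or counter-regulatory
  pathways; oGTT simulations describe only the glucose-insulin core.
- The estimators assume the fasting sample is at steady state; acute
  perturbations violate this silently.
- Synthetic cohorts vary only G_R and G_β between subjects; real cohorts
  also vary volumes of distribution, clearances and EC50s.
- The closed-form steady state exists only for W = 0; non-fasting equilibria
  must go through the simulator or the fixed-point map.
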