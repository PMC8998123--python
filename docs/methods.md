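# Methods

This note documents the statistical machinery implemented in `mixtox`:
what is modeled, the conventions adopted where several are defensible,
the numerical choices, and what the synthetic-data experiments do and do
not demonstrate.

## Dose–response models and benchmark concentrations

Eight quantal model families are implemented in the standard U.S. EPA
BMDS parameterizations, mapping concentration *d* (µM) to an expected
affected fraction *p(d)*:

| family | p(d) | parameters |
|---|---|---|
| quantal linear | g + (1−g)(1−e^(−bd)) | g, b |
| multistage (degree 2) | g + (1−g)(1−e^(−b₁d−b₂d²)) | g, b₁, b₂ |
| weibull | g + (1−g)(1−e^(−bd^a)) | g, a, b |
| gamma | g + (1−g)·P(a, bd) | g, a, b |
| logistic | 1/(1+e^(−a−bd)) | a, b |
| probit | Φ(a+bd) | a, b |
| log-logistic | g + (1−g)/(1+e^(−a−b·ln d)) | g, a, b |
| log-probit | g + (1−g)Φ(a+b·ln d) | g, a, b |

P(a, x) is the regularized lower incomplete gamma function and Φ the
standard normal CDF. Background g lies in [0, 1); slopes are
non-negative; by default ("restricted" mode) the weibull/gamma shape and
the log-family slope are constrained to ≥ 1, which prevents supralinear
low-dose curvature; an unrestricted switch relaxes these to > 0. The
multistage degree is fixed at 2. Log-dose families return the background
g at d = 0.

The benchmark concentration BMC_q solves extra risk
(p(d) − p(0))/(1 − p(0)) = q. Inversion uses the closed form every
family admits, followed by a Brent refinement whenever the closed-form
residual exceeds 10⁻¹⁰ in response units; the returned BMC satisfies the
benchmark to < 10⁻⁸. A curve whose asymptote lies below the target (zero
slope, or a logistic/probit saturating early) raises a not-estimable
signal rather than returning a number.

### Continuous endpoints

Cell-viability data arrive as replicate fractions of the vehicle-control
mean. They are converted to an effect fraction e = 1 − response and the
same eight mean curves are fit by Gaussian likelihood with a constant
variance profiled out of the likelihood. This choice makes the
continuous BMC definition — relative deviation of viability from the
control mean by the benchmark fraction — coincide algebraically with
extra risk of the effect curve: v(d) = v₀(1 − q) iff
(p(d) − p(0))/(1 − p(0)) = q. One inversion path therefore serves both
data kinds, and a BMC₅₀ is literally the concentration at 50% viability
reduction.

## Fitting, adequacy and model selection

Each family is fit by bounded maximum likelihood (L-BFGS-B) from a
fixed, data-informed multi-start grid — characteristic concentration
scales spanning the tested range crossed with a small set of shape and
location values — so refits of the same table are bit-identical. Fewer
than four distinct concentrations (control included) is an error. The
convergence flag is `boundary` when every dose-effect slope sits at its
zero lower bound (a flat fitted curve); `failed` when no start converges.

A fit is **adequate** when all four conditions hold:

1. convergence flag `converged`;
2. Pearson χ² goodness-of-fit p ≥ 0.10 (the BMDS quantal default), with
   df = groups − model parameters and a saturated fit (df ≤ 0) counted
   as a pass;
3. the implied BMC₅₀ falls in (0, 10 × top tested concentration] — BMCs
   extrapolated further are scientifically meaningless for a screening
   grid and reported not-estimable;
4. the table shows a monotone dose-response trend: one-sided
   Cochran–Armitage z-test (quantal) or one-sided Spearman correlation
   of effect against concentration (continuous) at α = 0.05.

Condition 4 exists because a noisy-but-flat table otherwise admits
adequate steep curves positioned just beyond the tested grid: with no
real trend, a cliff at 3–7 × the top concentration fits the flat data
perfectly and passes GOF, yielding a spurious "estimable" BMC. A trend
pre-test is part of data-adequacy assessment in EPA practice and removes
the pathology at the data level rather than by tightening the
extrapolation window.

The **best model** is the adequate fit with the lowest AIC
(AIC = 2k − 2ℓ; k counts the variance parameter for continuous fits);
AIC ties (Δ < 0.01) break toward the smaller — more conservative —
BMC₅₀. When no family is adequate the chemical is *not modelable* and
every BMC is reported not-estimable. Note an inherent property of rule
2: the GOF p-value is uniform under the true model, so ~10% of tables
generated from a known curve are expected to be not modelable; this is
the intended behavior of the adequacy rule, not a fitting failure.

## Mixtures and the interaction index

Designs are *equimolar* (fractions 1/c) or *BMC-anchored* (fractions
E_i/ΣE_j, components in proportion to their individual benchmark
concentrations). All mixture totals are the summed component
concentration, so a 14-component equimolar mixture at 140 µM contains
each component at 10 µM.

The concentration-addition interaction index at the mixture's BMC is
I = Σ x_i/E_i, with x_i the component concentration implied by the
composition at the mixture BMC and E_i the component's own BMC₅₀.
Closed forms follow: (B_mix/c)·Σ(1/E_i) for equimolar and
c·B_mix/ΣE_i for anchored designs. I = 1 is additivity; I > 1
antagonism; I < 1 synergism. Because the index is reported at two
decimals and estimated from finite data, calls use a configurable
additivity band of ±0.05 around 1 — consistent with classifying 0.93 as
synergism and 1.17 as antagonism while not over-interpreting indices at
1.02. Anchoring values per design are configurable (anchored designs may
be built on BMC₁₀ or BMC₅₀ values as a study chooses); the index itself
always uses BMC₅₀ as E_i.

## Screening statistics

**Plate QC.** A plate passes when strictly more than 80% of
vehicle-control animals are normal (no mortality, no malformation) at
120 hpf.

**Incidence and "any effect".** Per-endpoint incidence is
affected/evaluable per concentration. Dead animals are excluded from
denominators of morphology endpoints that cannot be scored post-mortem
but count as affected for mortality and for the "any effect" union,
which counts each animal at most once regardless of how many endpoints
are flagged; any-effect incidence therefore dominates every
single-endpoint incidence.

**Fisher's exact and LEL.** Each concentration is compared to control
with a one-sided (greater incidence) Fisher's exact test at p < 0.05;
the test is one-sided because malformation screening is directional,
with a two-sided option exposed. The LEL is the lowest significant
tested concentration.

**In vitro statistics.** Well values are normalized to the
vehicle-control mean, then compared by one-way ANOVA, Dunnett's
many-to-one test and the Tukey–Kramer all-pairs test at α = 0.05
(standard multivariate-t and studentized-range implementations; the
Dunnett quadrature seed is fixed so identical inputs give identical
p-values).

**Behavior.** EPR traces are per-second movement indices over 50 s with
light pulses at 30 s and 40 s; the background/excitatory/refractory
periods are the nine seconds before the first pulse and after each
pulse. The per-subject summary is the mean movement index per period —
the movement-index scalar is deliberately simple; any per-subject
summary respecting the period structure would satisfy the same
contract. LPR traces are 6 s distance bins over four 3-min-light/
3-min-dark cycles; cycles 1–3 are acclimation and only cycle 4 is
tested, with the per-subject summary the area under the distance-time
curve per phase. Treatment and control summaries are compared per
period by the two-sample Kolmogorov–Smirnov test, Bonferroni-corrected
across the caller's comparison family (typically concentrations ×
periods within one chemical/assay); direction comes from the median
difference. Exclusions precede testing (EPR: dead/delayed; LPR:
dead/malformed); LPR groups additionally need ≥ 70% normal animals, and
any group with < 5 subjects after exclusion is not evaluable. A
chemical is **bioactive** when at least three consecutive
concentrations share the same non-normal verdict in the same period.

**Exposure correlations.** Concentrations are divided by deployment
time, correlated pairwise (Pearson, t-distribution p), reported at two
decimals and masked at p ≥ 0.01; constant columns are masked with a
warning.

## Synthetic data

Generators are pure functions of their seed. Defaults mirror the
screening design: the standard eight-point zebrafish grid with n = 36
animals per concentration (three plate replicates), six replicate wells
for viability with Gaussian noise (σ = 0.05 fraction-of-control, a
typical plate CV), 24–32 subjects per behavior group, and a 262-sample
log-normal exposure matrix with deployment times uniform on 5–10 days.

Concentration-addition mixtures are exact by construction: components
share one curve shape and differ only in potency ρ_i, so the mixture at
total T responds at effective reference dose T·Σρ_i f_i. This is the
regime where concentration addition is well defined (similarly acting
components); mixing different curve shapes is rejected. A deviation
factor k divides the effective dose, pushing the recovered index toward
k — above 1 for antagonism truth, below for synergy.

What the synthetic experiments show: the fitter recovers generating
BMC₅₀s (median relative error well under 25% at n = 36 and 10% at
n = 500), the end-to-end pipeline returns interaction indices near 1
under additive truth and directionally shifted ones under interaction
truth, and each test keeps its nominal type-I error under the null.
What they do not show: robustness to real-data features the generators
omit — plate effects and inter-plate drift, overdispersion beyond
binomial, correlated endpoints within animals, non-monotone responses,
solvent artifacts, or dosimetry differences between nominal and
internal concentration.

## Problem sizes and numerical details

Simulation-backed checks use 24–60 replicates per condition (60 per
family at n = 36 and 30 at n = 500 for recovery; 24 CA replicates;
400–2000 null replicates per calibration check), sizes at which the
medians and rates being asserted are stable. Optimization tolerances:
L-BFGS-B ftol 10⁻¹², inversion residual < 10⁻⁸, composition sums to the
total within 10⁻⁹, index closed forms verified to 10⁻¹². Likelihood
probabilities are clipped to [10⁻¹², 1 − 10⁻¹²]; the continuous GOF
floors the pooled variance at 10⁻¹⁰ so noiseless fixtures do not divide
by zero.

## Known limitations

- Point BMCs only: no BMCL/confidence limits, bootstrap or model
  averaging.
- Constant-variance Gaussian likelihood for continuous endpoints; no
  variance modeling.
- The multistage family is fixed at degree 2.
- Exact concentration-addition generation requires same-shape
  components; no independent-action or dose-surface alternatives.
- The LPR layer implements the AUC + KS comparison contract; no
  entropy-based modeling of the movement distribution.
- Indices recomputed from a rounded BMC table can differ in the second
  decimal from values computed on unrounded fits; full precision is
  retained internally and the two-decimal value is a reporting
  convention.
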