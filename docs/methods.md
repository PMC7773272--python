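# Methods

## The measurement model

`itcvar` models the blank-subtracted heat of injection *i* of an
incremental ITC titration as

    Q_i = r(V_inj,i; C_syr, C_cell, V_cell) · (1 + P_i) + Q_b,i

with three independent Gaussian error components:

| component | distribution | meaning | default |
|---|---|---|---|
| `V_ε` | `N(0, σ_v²)`, `V_inj = V_0 + V_ε` | injection-volume error, independent of the preset volume | σ_v = 0.0214 µL |
| `P` | `N(0, σ_p²)` | proportional error on the realized reaction heat | σ_p = 0.00309 |
| `Q_b` | `N(0, V_0·σ_b²)` | background noise; its variance scales with the *preset* volume, so σ_b carries units µJ·µL^-0.5 | σ_b = 0.1771 µJ·µL^-0.5 |

The defaults are literature-characterized error parameters of a NanoITC
Standard-Volume instrument, estimated from saturated CaCl₂/EDTA and
water-blank titrations; they are representative of modern
power-compensation calorimeters. Dilution and friction heats are treated
as exactly blank-subtracted (identically zero in simulation); whatever
randomness they contribute in practice is absorbed into σ_b and σ_p by
construction, which is how those parameters are estimated in the first
place.

Optional *additional* errors model solution handling: relative Gaussian
perturbations of `C_syr`, `K_a` and `ΔH` (default 1% when studying batch
effects), drawn once per titration (one prepared solution per fill) and
held fixed across its injections. In the 4-group estimation protocol they
are drawn once per *group*: one solution-preparation batch serves all of a
group's refills. This matters: resampling them at every refill would add
between-fill variance ≈ `Q²(rel_c² + rel_H²)` to a pooled 60-injection
sample variance, swamping the σ_p term and destroying the protocol's
shielding property, which our coverage simulations rule out.

## Binding and injection bookkeeping

The reaction heat comes from the 1:1 independent-binding equilibrium
`Ka = [ML]/([M][L])`, solved per injection as the smaller root of the
mass-action quadratic in the numerically stable form
`x = 2C/(B + √(B²−4AC))` (written for `n·M_tot`, so a stoichiometry
`n ≠ 1` is supported). The fixed-volume perfusion cell is advanced with
the instantaneous mix-then-overflow convention: the injected plug mixes
into the cell instantly (totals dilute by `V_cell/(V_cell+v)`, titrant
adds `C_syr·v/(V_cell+v)`), then an equal volume of *mixed* contents is
expelled. Heat is counted in the momentarily enlarged cell,
`Q = ΔH·[ML'·(V_cell+v) − ML·V_cell]`. The alternative
continuous/exponential dilution convention differs only at second order
in `v/V_cell` (~1% per 10 µL injection here) and is not implemented.

Units are fixed package-wide to µL / mM / M⁻¹ / kJ·mol⁻¹ / µJ; since
mM·µL = nmol and kJ/mol·nmol = µJ, heats need no conversion factors. The
mole-ratio axis is cumulative injected titrant moles over initial titrand
moles, uncorrected for overflow losses (the conventional ITC abscissa).

Heats keep the sign of ΔH throughout; standard deviations are
sign-invariant, and only plots take absolute values.

The first injection of a real titration is systematically low (stepper
backlash, syringe-tip leakage during equilibration). The anomaly itself is
not simulated; instead `drop_first` (default on) excludes injection 1 from
all summaries, mirroring standard practice.

## Monte-Carlo propagation

`propagate` draws `n_rep` independent titrations (default 1e5), each with
its own volume realizations, and reports per-injection mean, variance, SDR
(standard deviation of the heat residual) and an empirical 95% interval
taken as 2.5/97.5 percentiles of the simulated heats (assumption-free,
rather than ±1.96·SD). Statistics are accumulated chunk-wise with pairwise
mean/M2 combination; the heat matrix is kept only when percentiles are
requested (~20 MB at 1e5 replicates × 25 injections). Note that the chunk
size determines the order in which the random stream is consumed, so runs
are bit-reproducible for a fixed (seed, chunk_size) pair.

The propagation is vectorized across replicates; a 1e5-replicate,
25-injection run takes well under a second on one CPU.

## Variance functions and the deviation metric

Three literature forms are implemented (A, B, C; see `variance.py`); form
C, with the background term proportional to V, is the package baseline. In
the saturated constant-heat regime form C is *exact* for this measurement
model — term-by-term: `Var(Q_b) = σ_b²V`, `Var(rP) = σ_p²Q²`, and
`Var over V_inj of r = (σ_v·Q/V)²` because `r = (Q/V)·V_inj` there.

Outside that regime the comparison metric is

    max over effective injections of |SDR_mc − σ_vf| / σ_vf × 100,

with σ_vf evaluated at the noise-free heats and the first injection
dropped. The standard comparison series holds `C_cell = 1 mM`,
`C_syr = 6 mM`, 25 × 10 µL injections and varies `K_a = c·10³ M⁻¹` to set
the c-value; this keeps the heat scale constant across the series so that
only the isotherm shape changes. At low c the two approaches agree to a
few percent; at high c the volume error jitters the position of the steep
transition and the Monte-Carlo SDR develops a peak near mole ratio 1 that
the (monotone) variance function cannot follow — deviations of ~190% at
c = 1000 and ~260% at c = 5000. Without σ_v the SDR is exactly
`√(σ_b²V + σ_p²r²)` and decreases monotonically through the transition.

## Error-parameter estimation (4-group protocol)

Design: three saturated titrations (K_a ~ 1e9 M⁻¹, ΔH = −40 kJ/mol,
5 mM titrant into excess 5 mM titrand) at injection volumes 4, 10 and
16 µL, plus a 10 µL water blank; 60 effective injections per group,
pooling refills as needed (fresh cell per fill). Because the expected heat
per injection is the constant `ΔH·C_syr·V`, each group needs only its
sample mean and unbiased sample variance — no isotherm fit — and
batch-level concentration/parameter fluctuations merely rescale the
observed mean, leaving the variance at the basic-error level (the
shielding property; tested explicitly).

The four `(V, Q̄, s²)` points are fitted to form C, which is linear in
`β = (σ_b², σ_p², σ_v²)`, by weighted least squares with weights
`w = (n−1)/(2σ⁴)` — the inverse χ²-theory variance of `s²` — started at
the observed `s²` and refined twice at the fitted variance function.
Pure observed-s² weights correlate with the response and bias the
estimates low (≈ −2.6% on σ_p at these settings); fitted-value
reweighting, the standard practice in variance-function estimation,
removes most of that bias. Since the weights are absolute inverse
variances, the parameter covariance is `(XᵀWX)⁻¹` with no residual-MSE
rescaling (with one degree of freedom such a rescaling would be useless
anyway). Nonnegativity is enforced by an active set: negative components
are pinned at zero and the rest refitted; a pinned parameter reports an
infinite sd. Estimates are `σ̂ = √β̂` with first-order
`sd(σ̂) = sd(β̂)/(2σ̂)` and symmetric ±z·sd intervals on the σ scale.
For simulated blanks the design-matrix `Q̄` is entered as exactly 0 (known
by construction); for experimental files the sample mean is used
(CLI switch `--blank-qbar`).

`validate_protocol` closes the loop: at the default truth values with 1%
additional errors, 2000 simulated protocols give mean estimates
≈ (0.177, 0.0031, 0.021), WLS-reported sds matching the empirical spread
of the estimates within a few percent, and ±1/2/3·sd coverage
≈ (0.68, 0.95, 0.995) — the mild asymmetries from the √ transform are
reproduced, not corrected.

## Problem sizes and seeds

Default sizes are the reference conditions: 1e5 Monte-Carlo replicates for
SDR curves and variance-function comparisons; a full-scale protocol
validation uses 10,000 sets, and `scripts/acceptance.py` runs 2000 (binomial SE on a 95%
coverage ≈ 0.5%), which it reports alongside each value. All randomness
flows through `numpy.random.Generator` seeds; every CSV output embeds the
seed and a configuration hash.

## Synthetic data vs real data

The fixture generator emulates saturated CaCl₂/EDTA-style and water-blank
titrations with exactly the Gaussian error structure above. Real data
additionally contain a first-injection anomaly with structure (not just
lower weight), possible drifts in baseline integration, non-Gaussian
outliers from stirring events, and dilution/friction heats that are only
approximately removed by blank subtraction. Passing tests therefore
demonstrate correctness of the estimator and propagation machinery under
the stated error model, not robustness to those artefacts.

## Known limitations

* 1:1 independent binding only; no multi-site, sequential or displacement
  models, and no kinetic (power-curve) modelling.
* Raw thermogram acquisition and peak integration are out of scope; the
  package starts from integrated per-injection heats.
* The WLS covariance is first-order on the σ scale; intervals for
  parameters near zero (e.g. a clipped σ_v) are not meaningful.
* Vendor binary formats are not read; heats are exchanged as plain CSV.
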