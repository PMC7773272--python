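# itcvar

Heat-variance modelling and instrument error-parameter estimation for
isothermal titration calorimetry (ITC).

ITC measures the heat `Q_i` released by each injection of a titrant into a
reaction cell and fits the resulting binding isotherm for `K_a`, `ΔH` and
`n`. The heats are *heteroscedastic*: their variance depends on the heat
itself and on the injection volume, so weighted least-squares fitting and
model-selection statistics need a credible per-injection variance.
`itcvar` provides that in two complementary ways:

1. **A generative measurement model.** The blank-subtracted heat of
   injection *i* is

   `Q_i = r(V_inj,i) · (1 + P_i) + Q_b,i`

   where `r` is the reaction heat from a 1:1 independent-binding model
   with instantaneous mix-then-overflow injection bookkeeping,
   `V_inj = V_0 + V_ε` with `V_ε ~ N(0, σ_v²)` (injection-volume error),
   `P ~ N(0, σ_p²)` (proportional error) and `Q_b ~ N(0, V_0 σ_b²)`
   (background noise). Monte-Carlo propagation of this model yields the
   per-injection SD of the heat (the SDR) under any experimental design,
   including batch-level fluctuations of titrant concentration, `K_a` and
   `ΔH`.

2. **Closed-form variance functions** such as

   `σ_i² = σ_b² V_i + σ_p² Q_i² + σ_v² (Q_i/V_i)²`

   which are cheap and accurate at low Wiseman c-values
   (`c = K_a·C_cell`) but — being monotone in `|Q|` — miss the SDR peak
   the full model produces in the transition region of steep (high-c)
   isotherms.

The package also implements the optimized 4-group protocol for estimating
`(σ_b, σ_p, σ_v)` from data: three saturated titrations (constant expected
heat `ΔH·C_syr·V`) at 4/10/16 µL plus a 10 µL water blank, 60 effective
injections each, fitted by weighted least squares on the group sample
variances (weights from the χ² variance of `s²`, iterated at the fitted
variance function), with ±z·sd confidence intervals whose empirical
coverage is validated by simulation.

## Worked example

```python
import itcvar as iv

# SDR of a steep isotherm (c = 1000) vs the form-C variance function
config, rxn = iv.standard_comparison(1000)   # C_cell=1 mM, Ka=1e6 1/M
errs = iv.ErrorParams()                      # NanoITC: 0.1771, 0.00309, 0.0214
table, max_dev = iv.compare_to_variance_function(
    config, rxn, errs, n_rep=100_000, seed=1
)
print(f"max |SDR deviation| = {max_dev:.1f} %")
print(table.iloc[12:16].to_string(index=False, float_format="%.2f"))
```

prints

```
max |SDR deviation| = 187.8 %
 injection_index  mole_ratio  SDR_mc_uJ  sigma_vf_uJ  rel_dev_percent
              14        0.89       8.15         7.88             3.45
              15        0.95      10.02         4.94           103.08
              16        1.02       4.52         1.57           187.78
              17        1.08       1.21         0.73            66.29
```

The Monte-Carlo SDR peaks near mole ratio 1 — almost 3× the
variance-function prediction — because the injection-volume error jitters
the position of the steep transition, a mechanism no monotone variance
function can express.

Estimating error parameters from simulated 4-group protocol data:

```python
data = iv.simulate_protocol(iv.ErrorParams(), seed=2)
fit = iv.fit_error_params(iv.protocol_variance_points(data))
print(fit)
```

prints

```
sigma_b = 0.177(16) uJ*uL^-0.5, sigma_p = 0.00280(32), sigma_v = 0.0227(29) uL
```

i.e. the truth values (0.1771, 0.00309, 0.0214) recovered within one
reported standard deviation each.

The same workflows are available from the shell:

```sh
itcvar compare-vf --n-rep 100000 --seed 1 --out cmp.csv
itcvar estimate --saturated g4.csv --saturated g10.csv --saturated g16.csv \
    --blank blank.csv
itcvar validate-protocol --n-sets 2000 --seed 0
itcvar make-fixtures --seed 0 --outdir fixtures/
```

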