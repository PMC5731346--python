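# fluxcycle

Cell-cycle-phase-resolved metabolic flux analysis from pulse-chase
¹³C-tracing in synchronized cell populations.

## The problem

Metabolic demands change as a cell moves through G1, S and G2/M, but a
bulk LC-MS measurement of a "synchronized" culture is never a measurement
of one phase: the population is released as a tight cohort that advects
around the cell cycle and spreads out, so every sample is a mixture over
cell-cycle positions, with mixing weights that drift over release time.
`fluxcycle` is for researchers who run such experiments — pulse-chase
labeling with [U-¹³C]glucose- and [U-¹³C]glutamine-like tracers at a series
of release times after synchronization — and want phase-specific TCA-cycle
fluxes with honest confidence intervals out the other end.

The pipeline has three layers:

1. **Population model.** The density of cells over cycle position
   θ ∈ [0, 1) at time t after release is a wrapped Gaussian,
   ρ(θ|t) = N(θ0 + t/T, s0² + 2Dt) on the circle, division-weighted
   (cells past division count double). Its parameters are fitted to
   flow-cytometry phase fractions.
2. **Deconvolution.** Measurements mix position-bin signals through the
   bin masses w_rb: pools as meas_r = Σ_b w_rb P_b, MIDs abundance-weighted
   as meas_r(τ) = Σ_b w_rb P_b M_b(τ) / Σ_b w_rb P_b. Both stages are
   solved as non-negative least squares with circular Tikhonov smoothing
   across neighboring bins (MIDs constrained to the simplex).
3. **Flux fitting (isotopically non-stationary MFA).** Each EMU
   (elementary metabolite unit) MID X obeys
   C·dX/dt = Σ v_in·X_in − (Σ v_out)·X at metabolic steady state within a
   phase window. Free fluxes live on the null space of the stoichiometric
   matrix (every candidate is balanced), fitted by seeded multistart
   bounded least squares against both tracers simultaneously, with 95%
   profile-likelihood confidence intervals (SSR_min + χ²₁ = 3.841
   threshold). Derived outputs: NADH/FADH2 production, oxygen-equivalent
   OxPhos rate, and per-flux oscillation summaries (relative amplitude,
   peak phase).

A brute-force positional-isotopomer integrator (exponentially larger state,
built directly from the atom maps) serves as an independent oracle for the
EMU simulator; the two agree to < 1e-8 on the shipped network.

Since no public dataset accompanies the package, a first-class synthetic
module generates complete experiments with known ground truth, including an
`oscillating` design in which glucose oxidation peaks in G1 and
glutamine-derived oxidative + reductive fluxes peak in S while total NADH
production is constant across the cycle by construction.

## Worked example

Generate the three study designs and deconvolve the oscillating one:

```bash
$ python analysis/01_simulate.py
[oscillating] -> results/datasets/oscillating
  designed relative amplitudes: pdh=0.305, gls=0.414, idh_red=0.720
  per-bin NADH production: min=4.600000 max=4.600000
...

$ python analysis/02_deconvolve.py
population fit: T=19.946 h, theta0=0.9991, s0=0.0571, D=4.56e-04 (SSR 1.08e-03)
mixing matrix: 8 release times x 6 bins, condition number 8.9

recovery vs ground truth (written to results/deconvolution_recovery.csv):
  pool relative RMSE: 0.0471 (max 0.0896)
  bin-MID RMSE:       0.0096 (max 0.0116)
```

The fitted cycle length (19.95 h vs 20 h true), the near-zero release
position (0.999 ≈ 0 on the circle) and the dispersion rate are recovered
from noisy phase fractions alone; per-bin pools come back within ~5% and
bin MIDs within ~0.01 despite each measurement being a 6-bin mixture.

Fit phase-specific fluxes and summarize (about 4 minutes per dataset):

```bash
$ python analysis/03_fit_fluxes.py
[oscillating] analyzing results/datasets/oscillating -> results/analysis_oscillating
  glucose_oxidation          amplitude 0.267 peak G1
  glutamine_oxidative        amplitude 0.163 peak S
  reductive_carboxylation    amplitude 0.264 peak S
  nadh_production            amplitude 0.004 peak G1
[constant] analyzing results/datasets/constant -> results/analysis_constant
  glucose_oxidation          amplitude 0.096 peak S
  glutamine_oxidative        amplitude 0.045 peak G2M
  reductive_carboxylation    amplitude 0.348 peak G2M
  nadh_production            amplitude 0.032 peak G2M
$ python analysis/04_summarize.py   # collects these into results/*.csv
```

Reading: in the oscillating design the pipeline recovers the designed
complementarity — glucose oxidation (PDH flux) peaks in G1, glutamine entry
and reductive carboxylation peak in S — while the inferred total NADH
production varies by only 0.4% across phases (designed: exactly constant,
against designed flux oscillations of 30–72%; phase aggregation over six
bins shrinks the recovered flux amplitudes relative to the designed
bin-level ones). In the constant-design control the major-flux amplitudes
drop to the noise floor and the peak phases are arbitrary; reductive
carboxylation shows a larger relative amplitude there only because it is
the smallest flux (0.15 vs PDH's 1.0), so the same absolute error is a
much larger fraction of its mean. Equivalently through the CLI:
`fluxcycle simulate`, `fluxcycle analyze`, `fluxcycle report`,
`fluxcycle validate` (see `--help`).

## Network file format

```
[metabolites]
# name, n_carbons, pool_size, source|balanced|sink, dilution_fraction[, symmetric]
Pyr, 3, 2.0, balanced, 0.0
[reactions]
pdh: Pyr (abc) -> AcCoA (bc) + CO2 (a)
fh:  Fum (abcd) -> Mal (abcd) rev
```

Lowercase letters map each substrate carbon to a product carbon; `rev`
marks a reversible reaction (net + exchange flux parameterization);
`symmetric` declares two-fold rotational symmetry (succinate, fumarate).
The bundled default network is `src/fluxcycle/data/tca.network`; cofactor
yields used for NADH/FADH2 accounting are editable in
`src/fluxcycle/data/redox.yaml`.

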