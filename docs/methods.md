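# Methods

`fluxcycle` estimates how TCA-cycle fluxes change across the mammalian cell
cycle from pulse-chase isotope-tracing experiments in synchronized cell
populations. Because a synchronized culture desynchronizes as it progresses,
every measurement is a mixture over cell-cycle positions; the package first
deconvolves that mixture and then fits phase-specific fluxes by isotopically
non-stationary metabolic flux analysis (MFA). This note records the models,
the defaults and why they were chosen, and the numerical decisions.

## Network model

The metabolic network is an atom-mapped reaction list (text format, see
README). The default network is a single-compartment TCA cycle for a
proliferating cell: a glycolytic pyruvate source, PDH, pyruvate carboxylase,
citrate synthase, oxidative IDH (citrate → αKG), reductive carboxylation
(αKG → citrate, carried as a separate irreversible reaction so the two
directions are individually reportable), αKG dehydrogenase, SDH, fumarase,
MDH, glutamine → glutamate → αKG entry, ATP-citrate-lyase-style citrate
cleavage, and two biosynthetic effluxes (acetyl-CoA and OAA). CO2 is an
explicit 1-carbon species that is never balanced. Succinate and fumarate
carry a `symmetric` flag: every consuming reaction is expanded into two
half-weighted atom-map variants with reversed carbon order, which reproduces
the positional scrambling caused by their two-fold rotational symmetry.
Pool sizes are in arbitrary per-cell units; only the ratio flux/pool enters
the labeling kinetics, so units cancel wherever data and model meet.

Reversible reactions use the standard net + exchange parameterization
(forward = net + exchange, backward = exchange). The default network is
written fully irreversible — the net flux of each IDH direction is what the
study design resolves — but the machinery is exercised on toy networks in
the tests.

## Labeling kinetics

After the tracer switch at chase time τ = 0, the mass-isotopomer
distribution (MID) X of each EMU (elementary metabolite unit: a carbon
subset whose MID closes on itself) obeys

    C dX/dt = Σ_in v_in · X_in − (Σ_out v_out) · X,

with C the pool size, convolution of precursor MIDs for condensation EMUs,
and a per-metabolite `dilution_fraction` d replacing a fraction d of every
influx with unlabeled material. Fluxes and pools are constant within a
chase (metabolic steady state inside a cell-cycle window; chases of ≤ 4 h
are short against the 20 h cycle), so only the isotopic state is transient.

The EMU system is derived by backward tracing from the observed metabolites'
full-carbon MIDs and grouped by EMU size; the joint ODE is integrated with
LSODA at rtol 1e-8 / atol 1e-10 by default (the default network is only
mildly stiff; BDF with an analytic sparsity pattern is available for harder
cases, and the generator and oracle comparisons use tighter tolerances,
down to rtol 1e-11). Source-metabolite EMU MIDs are obtained from the
metabolite MID by hypergeometric marginalization, i.e. positional
exchangeability — exact for the uniformly labeled and unlabeled sources
used throughout.

A brute-force oracle integrates the full positional-isotopomer system
(2^n states per metabolite, production of a product isotopomer = flux ×
product of substrate isotopomer fractions) directly from the atom maps with
no EMU reduction. The two code paths share only the network definition and
agree to better than 1e-8 on the default network and random toy networks;
this equivalence is the core correctness guarantee of the simulator.

Natural-abundance correction inverts the binomial ¹³C-incorporation matrix
(default p13 = 0.0107), clips negatives and renormalizes. It is applied to
measurements only; simulations live in corrected space.

## Population model and deconvolution

Cell-cycle position θ lives on the unit circle. A synchronized cohort
released at θ0 advects at 1/T and broadens: ρ(θ|t) is a wrapped Gaussian
with mean θ0 + t/T and variance s0² + 2Dt. Division weighting doubles the
mass of lineages at every wrap of θ past 1, because a divided lineage
contributes two cells to a population-averaged signal. Defaults: T = 20 h,
θ0 = 0, s0 = 0.05 (±1 h initial spread), D = 5e-4 cycle²/h. D was set so
that σ ≈ 0.15 cycle units after one full cycle — synchronized cultures
remain scoreable through one cycle, and this keeps the default mixing
matrix (8 release times × 6 bins) well conditioned (condition number ≈ 9),
which the sampling design presumes. The model parameters (θ0, s0, D, and
optionally T) are fitted to flow-cytometry-style phase fractions by bounded
multistart least squares; phase fractions attribute each bin to G1/S/G2M
(default boundaries 0.4 and 0.75, configurable) by interval overlap.

Measurements mix bin-specific signals through the division-weighted bin
masses w_rb at each release time. Pools mix linearly; MIDs mix weighted by
abundance w_rb·P_b. Deconvolution is two-stage — pools first (they are
measurable without tracer and make the MID stage linear), then MIDs — each
a non-negative least-squares problem with circular Tikhonov smoothing
across neighboring bins. The smoothing weight λ is dimensionless: the
penalty rows are scaled by the mean data weight (and, for pools, the mean
measured level), so λ = 0.1 behaves comparably for metabolites whose pools
differ by orders of magnitude. λ = 0.1 is the default for both stages
(recovery quality is flat over roughly 0.03–0.3); an L-curve corner
selector is provided for data whose noise level is unknown. The MID stage
solves all mass channels of one chase time jointly with heavily weighted
sum-to-one rows per bin, then projects exactly onto the simplex — this
prevents weakly mixed bins from collapsing to zero. Bins with essentially
no mixing mass are flagged; with λ = 0 they raise instead.

Pool measurements from every chase sample and every tracer are treated as
technical replicates (pools are constant over a chase) and averaged before
deconvolution; with the default design that is 12 replicates of 10%
lognormal noise per release time.

## Flux estimation

Free fluxes are the net fluxes of a pivot reaction subset chosen by QR with
column pivoting on the null space of the balanced stoichiometric matrix;
every candidate flux vector is balanced by construction, and dependent-flux
non-negativity is enforced by penalty. Exchange fluxes of reversible
reactions are log10-scaled with an upper bound of 100× the flux upper
bound. The objective is the weighted SSR Σ((sim − meas)/σ)² over all
tracers simultaneously; optimization is bounded multistart least squares
(trust-region reflective), 20 seeded starts by default — the pipeline uses
4 because the default network's landscape has shown a single basin from
random starts — with pools fixed at their deconvolved values.

95% confidence intervals use the profile likelihood: the named flux is
pinned by a heavy quadratic penalty and walked away from the optimum with
doubling steps, re-optimizing all other parameters (warm-started), until
the SSR crosses SSR_min + 3.841 (χ², 1 df); the crossing is bisected to
1e-3 relative. Directions still below threshold at the walk limit are
reported open; a failed re-optimization flags the interval unreliable
rather than widening it.

Reducing-equivalent accounting is data, not code (`data/redox.yaml`):
NADH, NADPH and FADH2 yields per unit flux. NADH and NADPH are merged by
default (both feed the reducing-equivalent budget; `include_nadph=False`
separates them), and the oxygen-equivalent OxPhos rate is
(NADH + FADH2)/2. Oscillation summaries report relative amplitude
(max − min)/mean and peak phase (ties resolve to the earliest phase).

## Synthetic experiments

The generator emulates the full study: per-bin flux maps are circular
linear interpolations of three per-phase anchor flux maps (linearity
preserves both steady state and any linear design constraint), per-bin
pools follow a ±20% cosine modulation, and each release time mixes the
bin-specific labeling trajectories through the frozen population density.
Noise: additive Gaussian sd 0.01 on MID channels (clipped, renormalized),
multiplicative lognormal 10% on every pool sample, sd 0.01 on phase
fractions. Default design: 8 release times over one 20 h cycle, chase
times 0, 0.25, 0.5, 1, 2, 4 h, 6 bins, [U-¹³C]glucose-like (pyruvate M+3)
and [U-¹³C]glutamine-like (M+5) tracers, all nine balanced metabolites
observed.

The `oscillating` scenario sets PDH maximal at the G1 anchor and glutamine
entry plus reductive carboxylation maximal at the S anchor, and solves the
acetyl-CoA efflux per anchor so that total NADH production is identical in
every bin (with the default accounting, NADH = 4·pdh + 2·gls − 3·acc_out,
independent of the reductive flux): complementary substrate oscillations
with phase-constant reducing-equivalent output, the property the pipeline
is asked to detect. `constant` is the null design; `glucose_dominant` is a
phase-constant design with high glucose oxidation.

What the generator does not emulate: compartmentation (a single pool per
metabolite), natural-abundance contamination (data are generated in
corrected space), correlated or heteroscedastic instrument error,
chromatographic artifacts, apoptotic/quiescent subpopulations, and any
feedback of labeling on fluxes. Passing tests therefore demonstrate the
estimator inverts its own forward model under realistic noise and design
conditions — not that these biological complications are handled.

## Numerical choices and degenerate inputs

- MIDs are clipped at 0 and renormalized on output; validity tolerance 1e-6.
- Steady-state MIDs solve the per-size-class linear fixed point; a
  zero-turnover pool raises, naming the metabolite.
- Steady-state validation tolerance: 1e-9 × the largest flux.
- The λ → ∞ limit of MID deconvolution returns the abundance-weighted
  common signal; B = 1 is exact passthrough.
- All randomness (noise, multistarts) flows from explicit integer seeds;
  identical config + seed reproduces every output file byte-for-byte
  (floats serialized at 12 significant digits).
- Problem sizes used in the shipped verification runs (chosen to keep a
  single-CPU run comfortable): the default 9-metabolite network for
  simulate-then-refit, a 2-free-flux branch network × 50 replicates for CI
  coverage, and one full pipeline run per scenario.

## Known limitations

- Phase-level fluxes are abundance-weighted aggregates of bin-level truth;
  with 6 bins and 3 phases the G1 aggregate mixes part of the designed
  oscillation's shoulders, so recovered amplitudes are mildly shrunk
  relative to designed bin-level amplitudes.
- The deconvolution treats the fitted mixing matrix as known; population-
  fit uncertainty is not propagated into the flux CIs.
- Exchange fluxes of fast reversible reactions upstream of symmetric
  metabolites are weakly identifiable by construction; the profile
  likelihood reports them open rather than pretending precision.
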