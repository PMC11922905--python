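# Methods

## Models

All four families describe the light response of PSII photochemistry and
are linked across response kinds by the bridging identity
ETR(I) = α·β·Φ_PSII(I)·I, with α the PSII/PSI light-distribution
coefficient and β the leaf absorptance.  Both constants are assumptions
of the ETR calculation, not measurements, so they are injected everywhere
(`OpticalConstants`, defaults α = 0.5, β = 0.84) and never hard-coded.

**Mechanistic (`ye`).**  ETR(I) = α_e·I·(1 − β_e·I)/(1 + γ_e·I), with the
initial slope α_e [μmol electrons (μmol photons)⁻¹], the dynamic
down-regulation term β_e and the saturation term γ_e [both m² s (μmol
photons)⁻¹].  The aggregate parameters decompose into pigment photophysics
through D = ξ₃ + (ξ₁k_P + ξ₂k_D)τ and u = σ_ik·τ/D:

    α_e = α·β·N₀·σ_ik·φ/S,   β_e = (1 − g_i/g_k)·u,   γ_e = (1 + g_i/g_k)·u,

so γ_e − β_e = 2(g_i/g_k)u > 0 whenever 0 < g_i/g_k < 1 (enforced as an
invariant of `MicroscopicParams`).  Closed forms:
I_sat = (√((β_e+γ_e)/β_e) − 1)/γ_e and
ETR_max = α_e[(√(β_e+γ_e) − √β_e)/γ_e]².  Because the typography of the
ETR_max expression is easy to garble, the implementation validates it
against an independent numeric maximizer (grid scan plus bounded
golden-section refinement) rather than trusting transcription; agreement
is required to 1e-6 relative over 1000 random admissible draws.  With
β_e = 0 the curve is monotone: I_sat is flagged `not_finite` and ETR_max
reported as the supremum α_e/γ_e.  Values beyond I = 1/β_e are negative
and returned unclipped — the declining branch is the photoinhibition
regime the model exists to represent.

The same algebra yields the light-dependent pigment quantities: the
effective absorption cross-section σ′_ik(I) = σ_ik(1 − β_e I)/(1 + γ_e I),
the quantum-yield proportionality Φ_PSII = Φ_PSIImax·σ′_ik/σ_ik (asserted
pointwise equal to the direct Φ curve, to 1e-12), the excited-state
fraction N_k/N₀ = [1/(1 − g_i/g_k)]·β_e I/(1 + γ_e I), and the NPQ
response NPQ(I) = A·I/(1 + b·I) + NPQ₀.  The NPQ amplitude lumps
NPQ_max·a into a single A because the two factors enter the curve only as
a product and are not separately identifiable from an NPQ–I fit.  The
degeneracy ratio g_i/g_k defaults to 0.5 where one is needed (the N_k
curve); every N_k output is labelled with the ratio used, since published
N_k values rarely state it.  N₀'s unit convention (molecule count vs
amount) is carried as metadata and never converted implicitly.

**Negative exponential (`negexp`).**  Φ_PSII = Φ_PSIImax·e^(−k_w·I);
I_sat = 1/k_w and ETR_max = α·β·I_sat·Φ_PSIImax·e⁻¹ (the interior maximum
of the ETR form).

**Saturating exponential (`exp`).**  ETR = α·β·(F_v/F_m)·I_sat·(1 −
e^(−I/I_sat)).  The curve saturates only asymptotically, so its ETR_max
convention is the curve evaluated at I = I_sat — a factor (1 − 1/e) below
the asymptote.  The fitted I_sat of this family has no clean mechanistic
meaning for Φ-curve fits; it is reported verbatim, without
reinterpretation.

**Non-rectangular hyperbola (`nrh`).**  Strictly increasing and concave
towards the asymptote ETR_max; it therefore defines no saturation
intensity, and I_sat is flagged `not_defined_by_model` rather than
invented.  θ = 0 is handled analytically as the rectangular-hyperbola
limit; θ = 1 is the Blackman limit.

Singularities at I = 0 (the `exp` Φ form and the `nrh` Φ form divide by
I) are resolved by their analytic limits (F_v/F_m and α′/(α·β)), because
the measurement protocol includes a dark step and Φ_PSIImax is anchored
there.

## Fitting

Each replicate leaf is fitted independently; replicate parameters and
derived traits are then aggregated as mean ± SE (sd/√n), the convention
for five-leaf field measurements.  Fitting-to-the-mean-curve is
deliberately not done: averaging fits preserves between-leaf variance in
the reported SE.

The objective is unweighted SSR (no error model is assumed for the
instrument).  The global stage is multistart simulated annealing with
Metropolis acceptance: 20 Latin-hypercube starts within bounds, initial
temperature equal to the inter-quartile range of the starts' SSR values
(scale-free), geometric cooling 0.92 with 60 proposals per level and 50
levels, and a proposal scale that starts at 20 % of each bound width and
shrinks with the temperature.  The three best annealed points are
polished by bounded trust-region least squares (finite-difference
Jacobian, xtol = ftol = 1e-10).  These schedule constants are this
package's own documented defaults; the annealing literature fixes no
canonical schedule.  Ties between optima (SSR within 1e-12 relative) are
broken by the smallest β_e, then γ_e (lexicographic over the parameter
vector for the other families), so results are deterministic.  All
randomness flows from the single required seed; refitting with the same
seed is bit-reproducible, and the reported SSR never exceeds the best
multistart initial point's.

Default bounds span physically admissible ranges with an order of
magnitude to spare: α_e, α′ ∈ (0, 2]; β_e ∈ [0, 10⁻²]; γ_e ∈ (10⁻⁷,
10⁻¹]; Φ_PSIImax, F_v/F_m ∈ (0, 1]; k_w ∈ (10⁻⁶, 10⁻¹]; I_sat ∈ (1,
5000]; θ ∈ (0, 1]; ETR_max ∈ (0, 1000].  A fitted parameter within 10⁻⁶
of a bound (relative to the bound width) is flagged in the diagnostics.
A curve with fewer distinct intensities than parameters + 1 raises an
underdetermined error; an all-constant response raises a degenerate-data
error; a non-converged local stage is flagged, not raised.

`FitConfig.fast` (6 starts, 20 proposals × 20 levels, cooling 0.85) is
the documented configuration for Monte-Carlo batches.  Because the local
least-squares stage does the precision work on these smooth,
low-dimensional objectives, the light schedule recovers noiseless truths
to better than 1e-4 relative exactly as the full schedule does; the full
schedule is the default for one-off fits where robustness to odd data
matters more than throughput.

The two response kinds are fitted separately (matching how such data are
analysed in practice), so a mechanistic ETR fit and Φ fit each carry one
free leading coefficient.  With the default `linked=True` the other
kind's coefficient is implied through Φ_PSIImax = α_e/(α·β) for derived
reporting; `linked=False` suppresses that inference.

## Model comparison

R², MAE and AIC = 2k + n·ln(SSR/n).  k defaults to the number of free
fitted parameters, but the counting convention is configurable
(`k_convention`): `with_constants` counts every symbol in the fitted
equation including α and β where they appear explicitly — 3/4/4/3 for the
ETR equations of ye/negexp/exp/nrh and 3/2/2/5 for the Φ equations — which
is the convention used in published four-model comparisons of this kind.
The comparison table records which k each AIC used, flags non-estimable
cells (`NA(not_estimable)`) instead of printing numbers, and marks the
lowest-AIC model.  A perfect fit (SSR = 0) yields AIC = −∞, flagged
degenerate; zero-variance observations flag R² undefined.

The model-free observed summary takes Φ_PSIImax as the mean Φ_PSII at
I = 0, observed ETR_max as the mean of per-replicate curve maxima, and
observed I_sat as the mean of per-replicate argmax intensities over the
measured grid — no interpolation, since measured maxima sit on protocol
grid points.

## Synthetic data

The generator emulates the leaf-chamber fluorometer protocol: 16 actinic
steps (0, 25, 50, 100, 200, 300, 400, 600, 800, 1000, 1200, 1400, 1600,
1800, 1900, 2000 μmol photons m⁻² s⁻¹), five replicate leaves, additive
i.i.d. Gaussian noise with sd either absolute or relative to the curve
maximum (default: 2 % of maximum, roughly the replicate scatter of
healthy crop leaves).  Randomness derives from one seed via
`SeedSequence.spawn`, so replicates are independent streams yet every
curve's metadata suffices to regenerate it bit-identically.

The reference truths are chosen once to resemble a healthy C3 crop leaf:
mechanistic (α_e = 0.294, β_e = 2.2×10⁻⁴, γ_e = 4.2×10⁻⁴), giving
Φ_PSIImax = 0.70, I_sat ≈ 1680 and ETR_max ≈ 182.6 with the maximum
interior to the protocol grid; negexp (0.70, 1/1600); exp (0.72, 600);
nrh (0.3, 0.7, 180); NPQ (A = 1.5×10⁻³, b = 5×10⁻⁴, NPQ₀ = 0.05, so
NPQ ≈ 1.5 at 1800 μmol photons m⁻² s⁻¹).

What the generator does not emulate: autocorrelated drift within a
curve, heteroscedastic noise growing with signal, instrument
quantisation, or leaf-to-leaf parameter variation (replicates share one
truth and differ only in noise).  Passing recovery tests therefore show
the estimator is unbiased and precise under the stated noise model, not
that any particular field data set satisfies that model.

## Problem sizes and tolerances

The acceptance suite uses 1000 random draws per family for
closed-form-vs-oracle agreement (1e-6 relative), 50 Monte-Carlo repeats
of the 5-replicate protocol for recovery (median relative bias < 5 % at
2 % noise; < 1e-4 with zero noise) and for the directional model-ranking
checks, and 100 random cases for statistics-vs-brute-force (1e-12).  The
standalone script `scripts/acceptance.py` reports the same pipeline at 20
Monte-Carlo repeats and 200 oracle draws.  The numeric maximizer uses a
4001-point grid with golden-section refinement to xatol = 1e-8.

## Known limitations

- No weighting or heteroscedastic error model; SSR is unweighted.
- No joint hierarchical fitting across replicates or species; no Bayesian
  posteriors.
- Quenching partitioning (qP/qL/qN), PSI fluorescence and multiphase
  flash corrections are out of scope.
- The NPQ amplitude A cannot be split into NPQ_max and a without external
  information.
- Gas-exchange (A–I) light-response modelling, temperature and CO₂
  response surfaces are out of scope; the hyperbola here is the ETR
  sub-model only.
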