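# Methods

This note documents the models implemented in `febic`, the defaults and the
reasoning behind the open design choices. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Exposure calculus (`febic.beam_dose`)

A raster exposure is described by beam energy (keV), beam current *I* (pA),
pixel dwell time *DT* (ns), pass count *N* and point pitch *PP* (nm). The
pitch follows the beam-overlap convention `PP = d·(1 − overlap)` with
50 % overlap as the default, matching common patterning-engine settings
(e.g. a 20.8 nm beam at 50 % overlap → 10.4 nm pitch).

The areal dose is defined as charge-per-point over a square pitch cell,

    D = I·DT·N / PP²   (C/m²),

the standard electron-beam-lithography definition. No instrument prints
this formula; it is adopted because it makes doses comparable across dwell
times, currents and pitches and reproduces the ~1 C/m² scale of observed
conversion optima. The current density uses a nominal top-hat disc of the
stated beam diameter, `J = I/(π(d/2)²)` — an approximation, since real
beam profiles are instrument-specific and unknown here. Beam diameters per
(voltage, current) pair are instrument calibration data and must be
supplied in the configuration; none are built in.

## Conversion kinetics (`febic.kinetics`)

The two-step scheme TMSC → cellulose → ND with constant electron supply is
solved per dose as consecutive pseudo-first-order reactions (Bateman
closed form, see README). Back reactions are neglected: resilylation and
re-assembly of beam-damaged material do not occur under exposure. The
three-parameter residual function `a1·(f_TMSC + f_ND)` is a reconstruction
of the published fit function from the stated reaction scheme — the
original supplementary derivation is not available — and is exactly the
Bateman solution with equal height weighting of the two enzyme-surviving
species. That equal weighting rests on the density/volume compensation
argument for regenerated films (density rises 0.99 → 1.51 g/cm³ while the
thickness halves, so height per unit converted material is roughly
conserved); a per-species weighting `a1·(w_t·f_TMSC + w_nd·f_ND)` is
exposed for data where ND material sits at a genuinely shrunken height
(the synthetic generator's convention).

Numerical choices:

* The cellulose fraction is evaluated with a series branch for
  |(b₂−b₁)·D| ≤ 1e−4 (truncation error < 1e−14 relative), so the b₁ = b₂
  degenerate limit is continuous to machine precision; relative rate
  differences below 1e−9 are numerically exact ties.
* `optimal_dose` and `max_cellulose_fraction` use `log1p`-stable forms
  with the analytic degenerate limits 1/b₁ and e⁻¹.
* The OR band is defined as the dose interval where f_cell reaches at
  least 90 % of its maximum. The regimes have no sharp physical boundary;
  0.9 is an explicit, configurable convention, and the band edges are
  found by root bracketing on either side of D*.
* `ode_oracle` integrates the scheme with DOP853 at rtol 1e−11 purely as
  an independent verification path for the closed forms; it is not used in
  production code.

## Fitting (`febic.fitting`)

`ConversionKineticsModel` performs nonlinear least squares of the residual
function in log-parameter space (which enforces positivity without bound
constraints), Levenberg–Marquardt, with inverse-variance weights when the
curve carries uncertainties and equal weights otherwise — no error model
is invented for data that does not state one. The covariance is the
Gauss–Newton approximation from the Jacobian at the optimum, scaled by
RSS/(n−3) and mapped through the log-parameter chain rule; confidence
intervals are Wald intervals. Non-convergence is reported as a flag on the
results, not an exception. Note the covariance is trustworthy only when
the stated weights reflect the actual noise: on heteroscedastic
(multiplicative) noise an unweighted fit over-covers.

Starting values: a₁ from the lowest-dose response, D* from the location of
the response minimum, and a deterministic scan over rate ratios b₁/b₂
consistent with `ln(b₁/b₂)/(b₁−b₂) = D*`, keeping the lowest-RSS seed.
Curves whose minimum sits at the edge of the dose range (under-exposed,
ELR-only data) are fit with a warning — b₂ is then weakly identified.
No b₁ ≥ b₂ ordering is imposed; the model is not symmetric under swapping
the rates, so the data decide.

`rate_analysis` tabulates fitted rates against current density per beam
energy and fits the rectangular hyperbola `b(J) = b_sat·J/(J_half + J)`.
Saturation is only stated qualitatively by the data this emulates, so the
law and the "95 % of plateau" threshold (J = 19·J_half) are explicit
conventions; rates flat to within 5 % over the sampled densities, or
groups with fewer than three distinct densities, yield no threshold and a
flag. Curves are fitted independently per (voltage, current) condition —
no hierarchical sharing.

## Electron Monte Carlo (`febic.electron_mc`)

Single-scattering trajectory simulation with:

* screened-Rutherford elastic cross-sections, screening parameter
  α = 3.4e−3·Z^0.67/E, scattering element drawn per collision with
  probability ∝ nᵢσᵢ(E), polar angle from cos θ = 1 − 2αU/(1+α−U);
* continuous Bethe stopping with the Joy–Luo low-energy form (k = 0.85),
  J(Z) = 9.76 Z + 58.5 Z^−0.19 eV;
* steps split at layer boundaries (no scattering at the interface);
* termination at 50 eV with local deposition of the remainder; electrons
  crossing the top surface are booked as backscattered with their exit
  radius and residual energy.

This is the standard desk-implementable model (Mott cross-section tables,
as used by full-featured simulators, are deliberately out of scope); it is
adequate for per-layer energy bookkeeping, which is why film-fraction
comparisons carry a ±5 percentage-point tolerance. Secondary electrons are
not generated or transported — the chemistry they drive is outside the
computational scope — so "deposited energy" means primary energy loss.
The implementation advances all in-flight electrons simultaneously
(vectorized), is deterministic under a fixed seed, and conserves energy to
float accumulation error (checked to 0.1 %).

Materials: TMSC is read as degree of substitution 2.8 — formula unit
C₁₄.₄H₃₂.₄O₅Si₂.₈ at 0.99 g/cm³ (a *polymerisation* degree of 2.8 would be
a trimer, inconsistent with film formation); cellulose C₆H₁₀O₅ at
1.51 g/cm³; SiO₂ at 2.2 and Si at 2.33 g/cm³. All overridable in the
stack configuration.

Reported metrics: per-layer deposited-energy fractions; the absolute
in-film energy loss per electron; and that energy expressed relative to a
2 keV reference primary energy. The relative form is the headline
cross-energy comparison because the conversion chemistry scales with the
energy each electron leaves in the film — the dose required for optimal
conversion is inversely proportional to it — and at the 2 keV reference it
coincides with the plain deposited fraction. The plain per-primary
fraction at higher energies is necessarily small (a 100 nm film against
micron-scale ranges) and is available separately.

`electron_range_ko` (Kanaya–Okayama, mass-fraction-weighted Z and A) is a
closed-form cross-check: the MC's 95 %-energy depth sits within a factor
two of it over 2–30 keV. `recommend_min_energy` picks the smallest grid
energy whose 95 %-deposition depth in a semi-infinite film reaches the
film thickness — the "interaction volume must span the precursor layer"
criterion; by construction the recommendation is non-decreasing in
thickness. The x–z deposition map uses 2 nm bins by default with the beam
as a point source at normal incidence.

## Patterning (`febic.patterning`)

Exposure plans place one point per pitch cell inside the exposed bitmap
regions (serpentine or interlaced ordering; both expose identical point
sets). The stream-file dialect is deliberately minimal and round-trippable:
header `s16`, pass count, point count, then `dwell x y` per point with
dwell in 0.1 µs units — vendor dialects are proprietary and not modelled.

The dose map deposits each point's charge through the standard
double-Gaussian proximity PSF (primary amplitude 1, BSE amplitude η; total
kernel integral 1 + η), accumulated by FFT convolution on a 2 nm grid
(1 nm recommended for metrology) and normalized to C/m²; kernel truncation
at the grid edge is reported and kept below 0.5 %. σ_bse and η can be taken
directly from `bse_exit_profile` or supplied in configuration. In the
interior of a large exposed field the delivered dose is the nominal areal
dose times (1 + η).

`measure_fwhm` interpolates the half-maximum crossings linearly with the
baseline at the lower profile end; sides without a crossing are flagged
open-ended rather than guessed.

A note on proximity broadening: the converted-line FWHM grows with η
unconditionally, and with σ_bse while the BSE halo overlaps the line
(σ_bse up to roughly the line width — which is where the Monte Carlo puts
σ_bse at low keV, ~47 nm at 2 keV). For σ_bse much wider than an isolated
feature the halo dose dilutes over a large area and the width relaxes back
toward — but never below — the primary-only value. The tests assert
exactly this regime-resolved statement.

## Synthetic dose sweeps (`febic.synthetic_data`)

The generator emulates the structuring → AFM → incubation → AFM workflow
on a 7 × 7 dwell-time × pass-count matrix of 1 × 1 µm² fields on a 100 nm
film. Defaults, chosen once as the study conditions:

* base exposure 2 keV, 53 pA, 20.8 nm beam at 50 % overlap (10.4 nm pitch);
* dwell ladder 70–1930 ns (geometric, step ≈ 1.74) × passes 1–7, spanning
  ~0.05× to ~10× the default truth's optimal dose so ELR, OR and EER are
  all represented;
* truth b₁ = 2.5, b₂ = 0.8 m²/C (conversion ≈ 3× faster than damage, the
  experimentally observed balance), h₀ = 100 nm;
* height factors shrink = nd_shrink = 0.5 — conversion loses about half
  the film height through TMS loss, and no separate ND height is reported
  anywhere, so ND shares the factor (separately configurable);
* additive Gaussian AFM noise, σ = 1.5 nm, seeded.

Heights: `h_pre = h0·(f_t + shrink·(f_c + f_n))`,
`h_post = h0·(f_t + nd_shrink·f_n)`; the degraded fraction is recomputed
from the noisy heights exactly as an experimenter would, with clipping
into physical bounds flagged per field. Because ND height (0.5) and TMSC
height (1.0) enter `h_post` with different weights, the residual-height
minimum sits slightly above the cellulose-optimal dose (about 1.45× D* at
b₁ ≈ 3 b₂); fitting `h_post` with `species_weights=(1, nd_shrink)`
recovers the truth exactly, and the equal-weight normalized residual has
its minimum exactly at D*. Dwell × pass products can coincide in dose, so
curve construction averages duplicate doses.

What the generator does **not** emulate: AFM tip convolution, curtaining,
swelling, drift, spatially correlated roughness, or any dose-rate
dependence beyond what b₁ and b₂ absorb. Passing round-trip tests
therefore shows the estimator is correct under the stated noise model, not
that real AFM data meet that model.

## Problem sizes

Defaults were sized for laptop-scale runs: 50 000 trajectories for
headline film-energy numbers (sampling error ≪ 0.1 pp), a few thousand for
unit-level physics checks, 200 replicates for the noisy-recovery and
coverage studies, and 2 nm grids for dose maps. All are parameters.

## Known limitations

* The elastic model underestimates large-angle scattering relative to
  Mott tables; backscatter yields are accordingly low (e.g. ~0.18 vs
  ~0.35–0.40 for bulk Si at 10 keV). Layer-fraction bookkeeping tolerances
  absorb this; do not use the module for quantitative BSE yields.
* No secondary-electron transport, charging, or gas/curtaining effects.
* The kinetics absorbs all flux dependence into b₁, b₂; it cannot
  distinguish dose-rate effects from dose effects.
* Fitted covariances assume the stated weights match the true noise.
* Pattern prediction shares the film's kinetics parameters across the
  whole map; lateral inhomogeneity (film thickness, development) is not
  modelled, so predicted line/space widths are trends, not instrument
  measurements.
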