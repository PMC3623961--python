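# Methods

`fluorbind` implements the quantitative workflow used to characterise a
weakly emissive drug (tetracycline, TC) binding to proteins (the serum
albumins HSA and BSA, and *E. coli* alkaline phosphatase) through the
*drug's own* enhanced fluorescence, complemented by tryptophan-side FRET,
low-temperature phosphorescence, solvatochromism, and surface-area
accounting of docked poses. This note records the models, their
assumptions, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## TCSPC reconvolution fitting (`fluorbind.decay`)

**Model.** The measured histogram is
`M(t) = IRF_norm ⊛ Σ_i α_i exp(−t/τ_i) + B`, with the instrument response
function (IRF) normalized to unit sum, an optional channel shift `s`
(bounded to ±5 channels, fractional shifts by linear interpolation), a
constant background `B`, and 1–3 exponential components. Components are
reported sorted by descending lifetime, with amplitude fractions
`f_amp,i = α_i/Σα` and intensity fractions `f_int,i = α_iτ_i/Σα_jτ_j`.

**Discrete convolution.** The exponential kernel jumps from 0 to 1 at
t = 0. Rectangle-rule convolution of sampled kernels errs by tens of
percent on the rising edge; the t = 0 kernel sample therefore carries
trapezoid half-weight. With this correction the discrete model matches
the closed-form Gaussian ⊛ exponential (exponentially modified Gaussian)
to <0.5% per channel at 5 ps sampling, and a delta-function IRF still
yields an exact exponential in every channel after the excitation channel
(which itself carries half weight).

**Weighting.** Counting noise is Poisson. Weighting by the *observed*
counts (σ² = max(N, 1), the Neyman convention) over-weights channels
that fluctuated low and biased both recovered lifetimes by ≈ −3.6% at
10⁴ peak counts in our simulations. The fit therefore iterates: one pass
with observed-count weights, then two passes re-weighted by the fitted
*model* counts (σ² = max(M, 1)). This removes the bias (<0.1% remaining)
while keeping the simple weighted-least-squares machinery. Channels
before the IRF rise (IRF < 1% of its maximum, minus a 5-channel guard)
are excluded from the statistic. Goodness of fit is reported as reduced
χ² and the Durbin–Watson statistic of the weighted residuals.

**Optimiser.** Trust-region-reflective least squares (via lmfit).
Initial lifetimes come from the tail centroid of the decay, initial
amplitudes from non-negative least squares on the corresponding
convolution basis. Fits are deterministic given the data. If two
components collapse (τ ratio < 1.02) or an amplitude vanishes, the model
is refitted with one fewer component and a warning — the caller chooses
the component count (the study always used two); there is no automatic
model selection.

**Mean lifetime.** `<τ> = Σ f_i τ_i`. The instrument software's printed
percentage contributions are used as the fractions when reproducing
published tables; whether those percentages are amplitude or intensity
fractions is ambiguous in the source material, so fit results carry both
(`tau_mean_amplitude`, `tau_mean_intensity`) and record which one
`tau_mean` reports (amplitude by default, matching the synthetic
generator's convention).

## Time-resolved anisotropy (`fluorbind.decay`)

The polarized pair is modelled globally as
`I_VV = IRF ⊛ (1/3) I(t)[1 + 2r(t)]`, `I_VH = IRF ⊛ (1/(3G)) I(t)[1 − r(t)]`
with a single-rotor `r(t) = r₀ exp(−t/θ_c) + r_∞` (r_∞ = 0 unless
requested). The total decay `S = I_VV + 2G·I_VH` is fitted first for the
multi-exponential `I(t)`; its parameters are then held fixed while
(r₀, θ_c) are refined against both histograms simultaneously with the
same iterated Poisson weighting. θ_c is bounded to [0.05, 100] ns with a
warning on a bound hit; when r₀ is consistent with zero the correlation
time is flagged unidentifiable. The channel-wise estimator
`r(t) = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)` is also provided for display,
masked where the total intensity falls below a count threshold.

## Binding isotherms (`fluorbind.binding`)

All three estimators assume a single 1:1 site; concentrations are
converted to molar inside the fits and constants are reported in M⁻¹.

* **Benesi–Hildebrand (enhanced ligand emission).** Linear mode: OLS of
  `(F_∞−F_0)/(F_x−F_0)` on `1/[P]`; K = 1/slope, intercept ≈ 1 is a
  diagnostic. The saturation observable F_∞ is not measurable directly;
  the default mode fits the 1:1 hyperbola
  `F = F_0 + (F_∞−F_0)·K[P]/(1+K[P])` for (K, F_∞) jointly, and the
  linear mode defaults to the largest-concentration observable with both
  results labelled. `[P]` is the *added* protein concentration (ligand
  depletion ignored), mirroring the published analysis; an optional
  mass-balance mode solves the exact 1:1 quadratic instead.
* **Anisotropy titration.** OLS of `(r−r_f)/[R(r_b−r)]` on `[P]`, slope
  = K, where `R = Q_b/Q_f` is the bound/free quantum-yield ratio.
  Observations outside [r_f, r_b] are excluded with a warning: near
  saturation the linearization diverges and such points carry no usable
  information.
* **Stern–Volmer quenching.** `F₀/F = (1 + K_sv[L])·exp(K_static[L])`
  for combined dynamic + static quenching of the tryptophan emission
  (single site, f₁ = 1); with the static term disabled the classic
  linear slope is returned. The static constant is flagged unresolved
  when its 95% CI includes zero.

`ΔG = −RT ln K` with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, default T = 298 K.
Note: the published free-energy entries do not exactly equal −RT ln K of
any single printed constant; the package reports the formula value per
constant.

## FRET (`fluorbind.energy_transfer`)

Efficiency from donor quenching `E = 1 − F_DA/F_D`, from acceptor
enhancement `E = (ε_A/ε_AD)(F_AD/F_A − 1)` (the extinction ratio removes
direct acceptor excitation; this algebraic form is a reconstruction — the
source's printed equation is garbled), and from 77 K phosphorescence
areas `E = 1 − I_DA/I_D`. Rates: `k_ET = E/τ_D` and
`k_ET = 1/τ_DA − 1/τ_D`; the two are algebraically linked through
`E = 1 − τ_DA/τ_D` (property-tested). The Förster r⁻⁶ law gives the
two-system rate ratio `k₁/k₂ = (τ_D2/τ_D1)(r₂/r₁)⁶` under shared
overlap integral, refractive index, donor yield and κ²; donor lifetimes
are explicit inputs because the published absolute rates cannot be
reproduced without them. Absolute Förster radii are out of scope (no
absolute spectra for the overlap integral).

## Solvatochromism (`fluorbind.solvatochromism`)

`k_r = φ/τ`, `k_nr = (1−φ)/τ` with `k_r + k_nr = 1/τ` exact by
construction. The Kamlet–Taft regression
`response = c₀ + c_π·π* + c_α·α + c_β·β` is OLS (statsmodels) with a
rank check that names collinear columns; the response (φ or <τ>) is a
parameter because the source does not state which transform was
regressed. Monotone-trend claims are checked by Spearman rank
correlation. The published yield-vs-dielectric trend holds on the five
organic solvents the trend figures plot; water (high ε, yet the lowest
yield — hydrogen-bonding quenching dominates) breaks the global
monotonicity, so trend checks use the organic-solvent subset.

## Surface-area accounting (`fluorbind.structure_contacts`)

Per-residue loss = ASA_free − ASA_complex (positive when surface is
buried); reports negate to the published sign convention. A residue is
binding-involved when it loses *strictly more than* 10 Å². Totals are the
signed sum of (complex − free). Docked tryptophan-ligand distances are
consumed as tables; computing ASA from coordinates or docking itself is
out of scope. For residues whose free/complex pair was never published,
fixtures carry the change directly.

## Synthetic data (`fluorbind.simulate`)

Generator defaults are the study conditions: binding constant 4.72×10⁴
M⁻¹ at 25 µM ligand on the published concentration grid; biexponential
decay (2.62, 1.11 ns at 22.8/77.2% amplitude), Gaussian IRF of 0.6 ns
FWHM, 10⁴ peak counts over 1024 × 25 ps channels (a typical instrument
setting; channel count is not stated in the source); rotational
correlation times 0.5–6 ns with r₀ = 0.3; quenching constants 10⁴/5×10³
M⁻¹ on [0, 10⁻⁴] M; a 412.8 nm / 270 cm⁻¹ phosphorescence origin band.
Counting data get Poisson noise; analog steady-state data get
multiplicative Gaussian noise (2% titrations, 1% quenching) or additive
noise of 0.002 anisotropy units (typical polarizer reproducibility).
Every generator is deterministic given its seed, and changing the seed
changes only the noise realisation.

The generators emulate the *statistical structure* the fits assume —
ideal 1:1 isotherms, exactly biexponential decays, a noise-free measured
IRF, single-rotor anisotropy, Gaussian bands. Passing round-trip tests
therefore demonstrates estimator correctness and precision at realistic
counting statistics, not robustness to the ways real data depart from
the model (IRF drift and after-pulsing, scattered excitation, lifetime
distributions, associative anisotropy, inner-filter effects, baseline
structure). Those departures are deliberately out of scope.

## Problem sizes and tolerances

Recovery studies use 20 seeds per estimator (medians reported); decay
histograms 1024 channels at 10⁴ peak counts. Published-table arithmetic
is checked at the tables' printed precision, treating evident truncation
(1.454 printed as 1.4 in one table and 1.45 in another) as truncation.
The full test suite runs in well under a minute; the acceptance script
in a few seconds.

## Known limitations

* Component counts above 3, lifetime distributions, and global analysis
  across decays are unsupported.
* The acceptor-enhancement efficiency formula is a reconstruction (see
  FRET above) — flagged in its docstring.
* The anisotropy fit conditions on the total-decay fit; uncertainty in
  I(t) is not propagated into (r₀, θ_c) standard errors.
* Linearized binding estimators inherit the usual heteroscedasticity of
  reciprocal/ratio transforms; the nonlinear modes are preferred and are
  the defaults where applicable.
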