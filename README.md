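# fluorbind

Protein–drug binding analysis from fluorescence spectroscopy, built around
the case of a weakly emissive antibiotic (tetracycline, TC) whose emission
is strongly enhanced on binding to serum albumins (HSA, BSA) and alkaline
phosphatase. Instead of relying only on tryptophan quenching, the package
analyses the **ligand's own signal** — enhanced emission, steady-state and
time-resolved anisotropy — alongside FRET, 77 K phosphorescence,
solvatochromism and docking-derived surface-area tables.

It is intended for photophysics / biophysical-chemistry groups who run
titrations and time-correlated single-photon-counting (TCSPC) experiments
and want reproducible, scriptable versions of the standard analyses.

## What it computes

| Analysis | Model |
|---|---|
| TCSPC lifetime fit | I(t) = IRF ⊛ Σᵢ αᵢ e^(−t/τᵢ) + B, iterative reconvolution, Poisson weights; ⟨τ⟩ = Σ fᵢτᵢ |
| Anisotropy decay | global fit of I_VV, I_VH with r(t) = r₀ e^(−t/θ_c) + r_∞ |
| Binding constant | modified Benesi–Hildebrand (F_∞−F₀)/(F_x−F₀) = 1 + 1/(K[P]); anisotropy plot (r−r_f)/[R(r_b−r)] = K[P]; Stern–Volmer F₀/F = (1+K_sv[L])e^(K_static[L]); ΔG = −RT ln K |
| FRET | E = 1 − F_DA/F_D; E = (ε_A/ε_AD)(F_AD/F_A − 1); E = 1 − I_DA/I_D; k_ET = E/τ_D and 1/τ_DA − 1/τ_D; Förster ratio (τ_D2/τ_D1)(r₂/r₁)⁶ |
| Solvatochromism | k_r = φ/τ, k_nr = (1−φ)/τ; Kamlet–Taft OLS: response = c₀ + c_π π* + c_α α + c_β β |
| Surface area | ΔASAᵢ = ASAᵢ(free) − ASAᵢ(complex); binding residues lose > 10 Å² |

Every input class has a seeded synthetic generator (`fluorbind.simulate`)
with the statistical structure the fits assume, so the whole pipeline is
testable without instrument data; the published summary tables for the
TC–albumin system ship as CSV fixtures (`fluorbind.datasets`).

## Worked example

```python
from fluorbind.simulate import DecayConfig, gen_decay, TitrationConfig, gen_titration
from fluorbind import fit_decay, fit_benesi_hildebrand

# TCSPC decay at the BSA-complex study conditions
curve = gen_decay(DecayConfig(), seed=42)      # 2.62/1.11 ns, 1e4 peak counts
res = fit_decay(curve, n_components=2)
print(res.summary())

# enhanced-emission titration, 2% noise
series = gen_titration(TitrationConfig(noise_frac=0.02), seed=42)
fit = fit_benesi_hildebrand(series, f_inf_mode="fit")
print(fit.summary())
```

prints

```
Multi-exponential reconvolution fit
-------------------------------------------
tau1 =   2.6134 ns   f_amp =  0.230   f_int =  0.414
tau2 =   1.1048 ns   f_amp =  0.770   f_int =  0.586
<tau> (amplitude) = 1.4515 ns
<tau> (intensity) = 1.7290 ns
chi2_reduced = 0.938   DW = 1.971
shift = -0.006 ch   background = 0.00 counts

Binding fit (benesi_hildebrand)
K = 4.336e+04 +/- 1.49e+03 M^-1   R^2 = 0.99885
dG(298 K) = -6.322 kcal/mol
F0 = 0.2616   F_inf = 3.007
```

The fitted lifetimes land within 1% of the generating 2.62/1.11 ns and
the amplitude-weighted mean reproduces the 1.45 ns measured for the
TC–BSA complex; the titration fit recovers the generating association
constant 4.72×10⁴ M⁻¹ within the noise (±8% here at 2% noise), with the
free energy of about −6.3 kcal/mol that a 10⁴–10⁵ M⁻¹ constant implies
at 298 K.

A command-line interface mirrors the library
(`fluorbind fit-decay|fit-anisotropy|fit-binding|fit-quenching|fret|solvato|asa|simulate|report`);
`fluorbind simulate decay --seed 1 --out decay.csv` writes the same
delimited formats the readers consume, and `fluorbind report` runs the
full pipeline over the bundled tables.

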