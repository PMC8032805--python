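# Methods

## Scope and model

`saxsmw` estimates the molecular weight Mw and the squared mass-specific
excess scattering amplitude Δb² of monodisperse-to-moderately-polydisperse
nanoparticles from one 1D small-angle scattering curve I(q), assuming the
data are fully reduced (background-subtracted); instrument smearing is out
of scope. Two regimes are implemented.

**Concentrated regime (single-curve, two-point scheme).** A suspension with
repulsive interactions shows a low-q intensity downturn (S(q) < 1 there);
that downturn is a prerequisite and is checked. A form factor is fitted only
for q in [q_lo, q_hi] where S(q) ≈ 1 and extrapolated to q = 0 with
S ≡ 1, giving the zero-concentration curve. With the concentration-normalized
running invariant Z(q) = (1/2π²c)∫₀^q I q′² dq′, the two-point slope between
(c, Z_exp) and (0, Z_fit) estimates −dZ/dc = Δb², and
Mw = N_A·I_fit(0)/(Z_fit(q_m) − Z_exp(q_m)). Both I_fit(0) and ΔZ are linear
in the intensity scale, so the estimate is exactly scale-free; Δb² is
physical (cm²/g²) only for absolute-scale input and is flagged otherwise.

For a polydisperse ensemble the plateau value of ΔZ·c approaches the
sum-rule limit φ·n·⟨F(0)²⟩ (n the particle number density), which makes the
⟨V²⟩ weighting of I_fit(0) cancel: the estimator converges to the
**number-average** molecular weight N_A·⟨V⟩·d, i.e. the volume-based value
inflated by ⟨V⟩/V = 1 + 3σ_rel² for a Gaussian size distribution. This is
why the method degrades beyond σ_rel ≈ 0.2 (≈ +19% at σ_rel = 0.25) while
staying within 10% below σ_rel ≈ 0.15, as the acceptance sweep measures.

**Dilute regime.** When the structure factor is negligible and I(0) can be
estimated (here by iterative Guinier analysis, window shrunk until
q·Rg ≤ 1.3), Mw = 2π²·I₀·N_A·(1/V̄ − c)/∫₀^∞ I q² dq. The infinite integral
is closed below the first measured point by a flat I₀ extension and above
the last by a Porod C/q⁴ tail with C the median of I·q⁴ over the last
half-decade; the tail share is reported when it exceeds 5%. The default
partial specific volume V̄ = 0.708 mL/g is the customary protein average.

## Units and conventions

q in Å⁻¹, lengths in Å, scattering length densities in Å⁻², mass densities
and concentrations in g/cm³. Absolute intensities are cm⁻¹ with the
convention I(q) = φ·⟨|F(q)|²⟩/⟨V⟩·S(q)·10⁸, so a monodisperse sphere has
I(0) = φVΔρ²·10⁸ cm⁻¹. Invariant integrals over q[Å⁻¹] carry a 10²⁴ factor
(Å⁻³ → cm⁻³) where physical units are required; it cancels in the scale-free
estimators. Δb = (ρ₁−ρ₀)·10¹⁶/d₁ cm/g. N_A = 6.02214076·10²³ mol⁻¹.

## Form factors and structure factor

Sphere, core-shell sphere (per-layer SLDs) and ellipsoid of revolution
(64-point Gauss-Legendre orientation average) amplitudes use the standard
3(sin x − x cos x)/x³ kernel (series-protected below x = 0.01).
Polydispersity averages ⟨|F|²⟩ over a Gaussian or Schulz-Zimm radius
distribution on a 51-node trapezoid grid spanning mean ± 5σ truncated to
positive support (independent 31-node grid for the shell thickness when it
is polydisperse); the quadrature matches a 10⁶-sample Monte-Carlo average of
⟨V²⟩ to ≲0.1% up to σ_rel = 0.2 and widths ≥ 0.5 are rejected. The
Percus-Yevick hard-sphere S(q) is the analytic Wertheim/Thiele solution; for
q·2R_hs < 0.9 the cancellation-prone closed form is replaced by its Taylor
series (coefficients through 9th order, error < 10⁻⁹), and S(0) equals
(1−φ)⁴/(1+2φ)² to machine precision. P and S are combined as ⟨|F|²⟩·S with
R_hs the mean outer radius — the usual decoupling-free product, an
approximation for polydisperse systems.

## Fitting

Weighted least squares (lmfit/trust-region-reflective) of I₀·P̂(q) over the
window, residuals scaled by 1/σ where uncertainties exist and by
1/max(|I|, 10⁻⁵·max I) otherwise (relative residuals suit data spanning
several decades; the floor keeps exact form-factor zeros of noiseless
synthetic data from dominating). The radius is seeded from a 60-point
log-spaced coarse scan with the amplitude profiled out analytically; the
best local minima start up to five refinements, the lowest χ² (ties: the
smaller radius) wins, deterministically. Fitted contrasts are effective
parameters — only I_fit(0) and the curve shape enter the estimator. The
fitted model is evaluated on a 2000-point linear grid reaching q = 0 for the
extrapolation.

## Invariant numerics

Trapezoidal quadrature on the native grid (no resampling; re-gridding
changes Z by < 0.5% on the default grids). Below the first measured point
the fitted curve is integrated analytically and the experimental integrand
is represented by the fitted curve rescaled to match at q_min (< 0.5% effect
for the validation systems; can be disabled). The plateau search accepts the
smallest q beyond which the running difference changes by < 1% (relative)
over a sliding window of 15% of the covered q-range; if none exists, the
least-varying point is returned flagged `plateau_found=False`.

## Simulated validation systems

The presets emulate the validation study conditions: spheres of R = 90 Å
with Gaussian σ/R = 0.05 and a PY structure factor at φ = 0.2 for five
polymer/solvent pairs (polystyrene in water/ethanol/chloroform, PMMA and
polypropylene in water, SLDs and densities as tabulated in
`simulate.TWO_PHASE_SYSTEMS`), on a 400-point logarithmic grid from 0.002 to
0.35 Å⁻¹ (covers the plateau region for R ≈ 90 Å; the grid is configurable).
Concentrations follow c = ν·d₁ exactly. A core-shell Pluronic PE10500-like
micelle (R_core = 60 Å, shell 16.5 Å, PD 0.10/0.15, φ = 0.15) exercises the
three-phase case. Curves are ideal: no counting noise unless injected
(multiplicative Gaussian, seeded), no smearing, no background residuals —
so passing tests demonstrate correctness of the estimator and its stated
convergence behaviour, not robustness to real instrumental artefacts.

## Known limitations

* Multi-component (core-shell) particles near contrast match are at the
  method's edge: the S(q) principal-peak region overlaps where their form
  factor is still strong, the running invariant difference oscillates
  instead of plateauing cleanly, and the pipeline flags
  `plateau_found=False`. The Δb² obtained for such particles carries no
  simple physical meaning.
* Polydispersity ratios above ~0.2 bias Mw upward (number-average
  inflation plus I(0) extrapolation error) beyond 10%.
* Highly charged or strongly anisotropic particles violate the hard-sphere
  picture of the low-q downturn; aggregates or any other low-q upturn break
  the prerequisite and are rejected rather than silently estimated.
* The dilute-regime integral is noise-sensitive (it uses the whole curve);
  a smoothness gate warns on rough data.
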