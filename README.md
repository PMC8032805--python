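# saxsmw

Molecular weight of nanoparticles and proteins from a **single** small-angle
X-ray/neutron scattering curve — even when the intensity is only on a
**relative** scale.

## The problem

The classical route to the molar mass from SAXS/SANS,

    Mw = (N_A / c) · (dΣ/dΩ)(0) / Δb²,

needs the forward intensity on an absolute scale (cm⁻¹) and the contrast
factor Δb (mass-specific excess scattering amplitude, cm/g), both of which
are often unavailable or inaccurate. `saxsmw` implements an invariant-based
estimator that needs only one measured curve, its concentration *c*, and a
form-factor model, and is exactly invariant under any multiplicative
rescaling of the intensities.

## The method

For a concentrated suspension with repulsive interactions, intensities at
*q* above some limit *q_m* are unaffected by the structure factor, so a
form-factor model fitted there and extrapolated with S(q) ≡ 1 represents the
zero-concentration curve. Comparing the concentration-normalized cumulative
(Kratky/Porod) invariants

    Z(q) = (1 / 2π²c) ∫₀^q I(q′) q′² dq′

of the fit (Z₀, at c → 0) and of the experiment (Z₁, at c) gives a two-point
slope −dZ/dc = Δb² without any further measurements, and

    Mw = N_A · I_fit(0) / (Z_fit(q_m) − Z_exp(q_m)).

Any scale factor multiplies numerator and denominator alike and cancels.
*q_m* is chosen where the running difference Z_fit − Z_exp becomes constant
(the package detects the plateau automatically and exports the diagnostic
curve). For dilute systems (proteins) the same invariant idea with a Guinier
I(0) gives Mw = 2π² I₀ N_A (1/V̄ − c) / ∫₀^∞ I q² dq, with V̄ the partial
specific volume (0.708 mL/g default for proteins).

The package also contains the forward simulator used to validate the
estimator: sphere, core-shell and ellipsoid-of-revolution form factors with
Gaussian or Schulz-Zimm size distributions, the analytic Percus-Yevick
hard-sphere structure factor, and preset polymer/solvent scenarios
(polystyrene, PMMA, polypropylene in various solvents; a Pluronic micelle).

## Worked example

Simulate 20 vol% polystyrene spheres (R = 90 Å, σ/R = 0.05) in water with
hard-sphere interactions, then recover the molecular weight:

```sh
$ saxsmw simulate ps_h2o -o ps_h2o.dat
wrote ps_h2o.dat: 400 points, scale=absolute, c=0.208 g/cm3
$ saxsmw estimate ps_h2o.dat -c 0.208 --q-m 0.05
fitted_radius_A = 89.96
fitted_pd_ratio = 0.04835
chi2 = 0.0771033
method = single_curve
Mw_g_mol = 1.89496e+06
db2_cm2_g2 = 2.07301e+17
I0 = 0.135679
q_m_invA = 0.05
```

The recovered Mw = 1.89·10⁶ g/mol agrees with the ground truth
V·d·N_A = 1.91·10⁶ g/mol of the simulated spheres to 1%, and
Δb² = 2.07·10¹⁷ cm²/g² with the composition value (ρ₁−ρ₀)²/d₁² = 2.00·10¹⁷
to 4%. Multiplying the curve by an arbitrary factor
(`saxsmw simulate ps_h2o --scale-factor 50 ...`) changes Δb² but returns the
same Mw — the point of the method. Equivalent library calls:

```python
from saxsmw import fit_form_factor, mw_single_curve
from saxsmw.simulate import TWO_PHASE_SYSTEMS, simulate_system

curve = simulate_system(TWO_PHASE_SYSTEMS["ps_h2o"])
fit = fit_form_factor(curve, "sphere", q_lo=0.05)
est = mw_single_curve(fit, curve, c=0.208, q_m="auto")
print(est.report())
```

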