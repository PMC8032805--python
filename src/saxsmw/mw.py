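"""Molecular-weight and contrast estimators.

Three routes to Mw from small-angle scattering:

* the single-curve, concentrated-regime estimator
  Mw = N_A * I_fit(0) / [Z_fit(q_m) - Z_exp(q_m)], which needs no absolute
  intensity calibration because the unknown scale factor enters numerator
  and denominator alike;
* the dilute-regime estimator
  Mw = 2 pi^2 I0 N_A (1/Vbar - c) / integral_0^inf I q^2 dq, equally
  scale-free, requiring smooth data and a negligible structure factor;
* the classical absolute-scale relation Mw = I(0) N_A / (c * Delta b^2).

Throughout, q is in 1/A and the 1e24 factor converts the 1/A^3 of the
q-integrals to 1/cm^3 so that Mw comes out in g/mol when I is in 1/cm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import pi

import numpy as np

from .curve_io import ScatteringCurve
from .fitting import FitResult
from .invariant import UNIT_INVARIANT, delta_invariant, invariant_profile, select_qm
from .simulate import N_A

#: average partial specific volume of globular proteins, mL/g
DEFAULT_PROTEIN_VBAR = 0.708

#: median relative point-to-point intensity jump above which the dilute
#: estimator warns that the curve is too noisy for a full-range integral
SMOOTHNESS_THRESHOLD = 0.05


@dataclass
class MwEstimate:
    """Result of a molecular-weight determination."""

    Mw: float
    method: str
    db2: float | None = None
    db2_is_physical: bool = False
    I0_used: float | None = None
    q_m: float | None = None
    plateau_found: bool | None = None
    warnings: list = field(default_factory=list)

    def report(self) -> str:
        """Plain-text key=value block."""
        lines = [f"method = {self.method}", f"Mw_g_mol = {self.Mw:.6g}"]
        if self.db2 is not None:
            tag = "cm2_g2" if self.db2_is_physical else "working_units_relative_scale"
            lines.append(f"db2_{tag} = {self.db2:.6g}")
        if self.I0_used is not None:
            lines.append(f"I0 = {self.I0_used:.6g}")
        if self.q_m is not None:
            lines.append(f"q_m_invA = {self.q_m:.6g}")
        if self.plateau_found is not None:
            lines.append(f"plateau_found = {self.plateau_found}")
        for w in self.warnings:
            lines.append(f"warning = {w}")
        return "\n".join(lines)


@dataclass
class ContrastInputs:
    """Composition data for the theoretical excess amplitude."""

    rho1: float  # solute SLD, 1/A^2
    rho0: float  # solvent SLD, 1/A^2
    density: float  # solute mass density, g/cm^3
    vbar: float | None = None  # partial specific volume, cm^3/g; 1/density if None

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.vbar is None:
            self.vbar = 1.0 / self.density
        if self.vbar <= 0:
            raise ValueError("partial specific volume must be positive")


def contrast_from_composition(inp: ContrastInputs) -> float:
    """Squared mass-specific excess amplitude Delta b^2 [cm^2/g^2].

    Delta b = (rho1 - rho0) / d1 with the SLDs converted from 1/A^2 to
    1/cm^2 (factor 1e16).
    """
    db = (inp.rho1 - inp.rho0) * 1.0e16 / self_density(inp)
    return db * db


def self_density(inp: ContrastInputs) -> float:
    # the mass-specific amplitude divides by the solute density = 1/vbar
    return 1.0 / inp.vbar


def msf_density(nu: float, rho1: float, rho0: float) -> float:
    """Mean-square scattering-density fluctuation nu (1-nu) (rho1-rho0)^2 [1/cm^4].

    SLDs are given in 1/A^2; the result carries the 1e32 A^-4 -> cm^-4 factor.
    """
    if not 0.0 <= nu <= 1.0:
        raise ValueError("volume fraction must be in [0, 1]")
    return nu * (1.0 - nu) * ((rho1 - rho0) * 1.0e16) ** 2


def mw_classical(I0_abs: float, c: float, db2: float) -> MwEstimate:
    """Classical absolute-scale route: Mw = I(0) N_A / (c Delta b^2)."""
    if I0_abs < 0 or c <= 0 or db2 <= 0:
        raise ValueError("I0 must be >= 0 and c, db2 positive")
    return MwEstimate(Mw=I0_abs * N_A / (c * db2), method="classical",
                      db2=db2, db2_is_physical=True, I0_used=I0_abs)


def mw_single_curve(fit: FitResult, exp_curve: ScatteringCurve, c: float,
                    q_m: float | str = "auto",
                    extend_experimental: bool = True) -> MwEstimate:
    """Single-curve estimator for the concentrated regime.

    Fits must have been performed with S = 1 above the interaction region;
    the invariant difference between the fitted (zero-concentration) curve
    and the experiment up to q_m then plays the role of c * Delta b^2 and

        Mw = N_A I_fit(0) / (dZ(q_m) * 1e24).

    ``q_m="auto"`` selects the plateau of dZ(q); a warning is attached when
    no plateau is found.  Delta b^2 is flagged physical only for
    absolute-scale curves.
    """
    warn: list[str] = []
    plateau = None
    if q_m == "auto":
        profile = select_qm(invariant_profile(fit, exp_curve, c, extend_experimental))
        q_m = profile.q_m
        plateau = profile.plateau_found
        if not plateau:
            warn.append("no dZ plateau found; using the least-varying q_m")
    d = delta_invariant(fit, exp_curve, c, q_m, extend_experimental)
    Mw = N_A * fit.I0_fit / (d["dZ_at_qm"] * UNIT_INVARIANT)
    return MwEstimate(
        Mw=Mw,
        method="single_curve",
        db2=d["db2_working"],
        db2_is_physical=exp_curve.scale == "absolute",
        I0_used=fit.I0_fit,
        q_m=float(q_m),
        plateau_found=plateau,
        warnings=warn,
    )


def _porod_tail(curve: ScatteringCurve) -> tuple[float, float]:
    """Porod constant C = I q^4 from the last half-decade and the tail
    integral C / q_max of I q^2 beyond the data."""
    q, I = curve.q, curve.I
    m = q >= q[-1] / 10**0.5
    if np.count_nonzero(m) < 3:
        m = q >= q[-1] / 2
    C = float(np.median(I[m] * q[m] ** 4))
    C = max(C, 0.0)
    return C, C / q[-1]


def mw_low_concentration(I0: float, curve: ScatteringCurve, c: float,
                         vbar: float = DEFAULT_PROTEIN_VBAR,
                         extend_tail: bool = True) -> MwEstimate:
    """Dilute-regime estimator Mw = 2 pi^2 I0 N_A (1/Vbar - c) / integral I q^2 dq.

    I0 comes from a Guinier fit or a model fit on the same intensity scale
    as the curve; the full-range invariant integral is extended beyond the
    last measured point with a Porod q^-4 tail (contribution reported as a
    warning when it exceeds 5%).  Requires c < 1/Vbar.
    """
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    if c <= 0:
        raise ValueError("concentration must be positive")
    if vbar <= 0:
        raise ValueError("partial specific volume must be positive")
    if c >= 1.0 / vbar:
        raise ValueError("concentration must be below 1/Vbar (volume fraction < 1)")
    warn: list[str] = []
    jumps = np.abs(np.diff(curve.I)) / np.maximum(np.abs(curve.I[:-1]), np.finfo(float).tiny)
    if float(np.median(jumps)) > SMOOTHNESS_THRESHOLD:
        warn.append("curve fails the smoothness gate; the dilute estimator "
                    "integrates the full range and is noise-sensitive")
    q, I = curve.q, curve.I
    integral = float(np.trapezoid(I * q**2, q))
    # low-q closure: Guinier-flat extension I ~ I0 below q_min
    integral += I0 * q[0] ** 3 / 3.0
    if extend_tail:
        _, tail = _porod_tail(curve)
        if tail > 0.05 * integral:
            warn.append(f"Porod tail contributes {tail / (integral + tail):.1%} "
                        "of the invariant; extend the q-range if possible")
        integral += tail
    Mw = 2.0 * pi**2 * I0 * N_A * (1.0 / vbar - c) / (integral * UNIT_INVARIANT)
    return MwEstimate(Mw=Mw, method="low_concentration", I0_used=I0, warnings=warn)
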