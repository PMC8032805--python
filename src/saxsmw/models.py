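"""Analytic scattering models.

Form-factor amplitudes for spheres, core-shell spheres and ellipsoids of
revolution, size-distribution (polydispersity) averaging, the analytic
Percus-Yevick hard-sphere structure factor, and their assembly into an
absolute-scale intensity

    I(q) = phi * <|F(q)|^2> / <V> * S(q) * 1e8   [1/cm]

with F in Angstrom units (F(0) = V * delta_rho, V in A^3, SLD in 1/A^2); the
factor 1e8 converts A^3 * A^-4 = 1/A to 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import pi

import numpy as np
from scipy.special import gammaln

FAMILIES = ("sphere", "core_shell_sphere", "spheroid", "ellipsoid")
PD_KINDS = ("none", "gaussian", "schulz_zimm")

#: number of quadrature nodes over the size distribution (mean +/- 5 sigma)
N_SIZE_QUAD = 51
#: Gauss-Legendre order for the orientation average of spheroids/ellipsoids
N_ORIENT_QUAD = 64


class UnsupportedModelError(ValueError):
    """Raised for a form-factor family this package does not provide."""


@dataclass
class ParticleModel:
    """Geometry + contrast + polydispersity of a scattering particle.

    ``radius`` is the sphere radius, the core radius for core-shell, or the
    equatorial radius for spheroid/ellipsoid.  ``axis_ratio`` is
    polar/equatorial.  For core-shell particles the per-layer SLDs are given
    and ``contrast`` is ignored; for the homogeneous families ``contrast`` is
    the SLD difference particle - solvent in 1/A^2.
    """

    family: str
    radius: float
    contrast: float = 1.0
    shell_thickness: float = 0.0
    sld_core: float = 0.0
    sld_shell: float = 0.0
    sld_solvent: float = 0.0
    axis_ratio: float = 1.0
    pd_kind: str = "none"
    pd_ratio: float = 0.0
    pd_ratio_shell: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise UnsupportedModelError(f"unknown form-factor family {self.family!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")
        if self.axis_ratio <= 0:
            raise ValueError("axis_ratio must be positive")
        if self.pd_kind not in PD_KINDS:
            raise ValueError(f"pd_kind must be one of {PD_KINDS}")
        for r in (self.pd_ratio, self.pd_ratio_shell):
            if r < 0:
                raise ValueError("polydispersity ratio must be >= 0")
            if r >= 0.5:
                raise ValueError("polydispersity ratio must be < 0.5")
        if self.pd_kind == "none" and (self.pd_ratio or self.pd_ratio_shell):
            self.pd_kind = "gaussian"

    @property
    def is_polydisperse(self) -> bool:
        return self.pd_kind != "none" and (self.pd_ratio > 0 or self.pd_ratio_shell > 0)


@dataclass
class StructureFactorSpec:
    """Interparticle structure factor: none, or hard-sphere Percus-Yevick."""

    kind: str = "none"
    R_hs: float = 1.0
    phi: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "hard_sphere_py"):
            raise UnsupportedModelError(f"unknown structure factor {self.kind!r}")
        if not 0.0 <= self.phi < 0.74:
            raise ValueError("hard-sphere volume fraction must be in [0, 0.74)")
        if self.R_hs <= 0:
            raise ValueError("R_hs must be positive")


# --------------------------------------------------------------------------
# form-factor kernels

def _sphere_kernel(x):
    """3 (sin x - x cos x) / x^3, the normalized sphere amplitude."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-2
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def sphere_volume(R: float) -> float:
    return 4.0 / 3.0 * pi * R**3


def sphere_intensity_zero(R: float, contrast: float) -> float:
    """Forward-scattering intensity ((4/3) pi R^3 * contrast)^2 of a sphere.

    On the working scale where F(0) = V * delta_eta this is the fitted
    curve's extrapolated I(q -> 0).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    return (sphere_volume(R) * contrast) ** 2


# --------------------------------------------------------------------------
# size distributions

def size_distribution(mean: float, pd_ratio: float, kind: str, n: int = N_SIZE_QUAD):
    """Quadrature nodes and normalized weights over a size distribution.

    Gaussian or Schulz-Zimm in the radius, parameterized by the mean and the
    relative width sigma/mean; the grid spans mean +/- 5 sigma truncated to
    positive support and the weights are trapezoid-rule pdf weights,
    renormalized to sum to 1.
    """
    if pd_ratio < 1e-6 or kind == "none":
        return np.array([mean]), np.array([1.0])
    sigma = pd_ratio * mean
    lo = max(mean - 5.0 * sigma, 1e-6 * mean)
    hi = mean + 5.0 * sigma
    r = np.linspace(lo, hi, n)
    if kind == "gaussian":
        logpdf = -0.5 * ((r - mean) / sigma) ** 2
    elif kind == "schulz_zimm":
        z = 1.0 / pd_ratio**2 - 1.0
        logpdf = (z + 1) * np.log((z + 1) / mean) + z * np.log(r) - (z + 1) * r / mean - gammaln(z + 1)
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    pdf = np.exp(logpdf - logpdf.max())
    w = pdf.copy()
    # trapezoid end-point halving on the uniform grid
    w[0] *= 0.5
    w[-1] *= 0.5
    w /= w.sum()
    return r, w


# --------------------------------------------------------------------------
# amplitudes

def _amplitude_mono(model: ParticleModel, q: np.ndarray, radius: float,
                    shell: float | None = None) -> np.ndarray:
    """Single-size (orientation-averaged) amplitude F(q) in Angstrom."""
    q = np.asarray(q, dtype=float)
    if model.family == "sphere":
        return sphere_volume(radius) * model.contrast * _sphere_kernel(q * radius)
    if model.family == "core_shell_sphere":
        t = model.shell_thickness if shell is None else shell
        Rc, Rt = radius, radius + t
        Fc = sphere_volume(Rc) * (model.sld_core - model.sld_shell) * _sphere_kernel(q * Rc)
        Ft = sphere_volume(Rt) * (model.sld_shell - model.sld_solvent) * _sphere_kernel(q * Rt)
        return Fc + Ft
    if model.family in ("spheroid", "ellipsoid"):
        # orientation average of the amplitude of an ellipsoid of revolution
        mu, w = _orient_nodes()
        r_eff = radius * np.sqrt(1.0 + mu**2 * (model.axis_ratio**2 - 1.0))
        V = sphere_volume(radius) * model.axis_ratio
        F = V * model.contrast * _sphere_kernel(np.outer(q, r_eff))
        return F @ w
    raise UnsupportedModelError(model.family)


def _orient_nodes(n: int = N_ORIENT_QUAD):
    x, w = np.polynomial.legendre.leggauss(n)
    # map [-1, 1] -> cos(theta) in [0, 1]
    return 0.5 * (x + 1.0), 0.5 * w


def form_factor_amplitude(model: ParticleModel, q) -> np.ndarray:
    """Per-particle scattering amplitude F(q) [A], orientation-averaged.

    At q = 0 this equals V * delta_rho (summed per layer for core-shell).
    Polydispersity is deliberately not applied here; see
    :func:`polydisperse_intensity` for <|F|^2>.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    return _amplitude_mono(model, q, model.radius)


def _msq_mono(model: ParticleModel, q: np.ndarray, radius: float,
              shell: float | None = None) -> np.ndarray:
    """Orientation-averaged |F|^2 at a single size."""
    if model.family in ("spheroid", "ellipsoid"):
        mu, w = _orient_nodes()
        r_eff = radius * np.sqrt(1.0 + mu**2 * (model.axis_ratio**2 - 1.0))
        V = sphere_volume(radius) * model.axis_ratio
        F = V * model.contrast * _sphere_kernel(np.outer(q, r_eff))
        return (F**2) @ w
    F = _amplitude_mono(model, q, radius, shell)
    return F**2


def polydisperse_intensity(model: ParticleModel, q_grid) -> np.ndarray:
    """Size- and orientation-averaged squared amplitude <|F|^2>(q) [A^2].

    The size average runs over the radius (and, for core-shell particles
    with a non-zero shell polydispersity, independently over the shell
    thickness).  A zero polydispersity ratio reduces exactly to |F|^2.
    """
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if q.size > 1 and np.any(np.diff(q) <= 0):
        raise ValueError("q_grid must be strictly increasing")
    if not model.is_polydisperse:
        return _msq_mono(model, q, model.radius)
    r_nodes, r_w = size_distribution(model.radius, model.pd_ratio, model.pd_kind)
    if model.family == "core_shell_sphere" and model.pd_ratio_shell > 0:
        t_nodes, t_w = size_distribution(model.shell_thickness, model.pd_ratio_shell,
                                         model.pd_kind, n=31)
    else:
        t_nodes, t_w = np.array([model.shell_thickness]), np.array([1.0])
    if model.family == "core_shell_sphere":
        # broadcast over (core radius, shell thickness) node grids
        r = r_nodes[:, None]
        t = t_nodes[None, :]
        Rc = np.broadcast_to(r, (r_nodes.size, t_nodes.size)).ravel()
        Rt = (r + t).ravel()
        w = (r_w[:, None] * t_w[None, :]).ravel()
        Fc = (4.0 / 3.0 * pi) * Rc**3 * (model.sld_core - model.sld_shell) \
            * _sphere_kernel(np.outer(q, Rc))
        Ft = (4.0 / 3.0 * pi) * Rt**3 * (model.sld_shell - model.sld_solvent) \
            * _sphere_kernel(np.outer(q, Rt))
        return ((Fc + Ft) ** 2) @ w
    out = np.zeros_like(q)
    for r, wr in zip(r_nodes, r_w):
        out += wr * _msq_mono(model, q, r)
    return out


def mean_volume(model: ParticleModel) -> float:
    """Number-average particle volume <V> [A^3] over the size distribution."""
    r_nodes, r_w = size_distribution(model.radius, model.pd_ratio, model.pd_kind)
    if model.family == "sphere":
        return float(np.sum(r_w * sphere_volume(r_nodes)))
    if model.family == "core_shell_sphere":
        if model.pd_ratio_shell > 0:
            t_nodes, t_w = size_distribution(model.shell_thickness, model.pd_ratio_shell,
                                             model.pd_kind, n=31)
        else:
            t_nodes, t_w = np.array([model.shell_thickness]), np.array([1.0])
        tot = 0.0
        for t, wt in zip(t_nodes, t_w):
            tot += wt * np.sum(r_w * sphere_volume(r_nodes + t))
        return float(tot)
    if model.family in ("spheroid", "ellipsoid"):
        return float(np.sum(r_w * sphere_volume(r_nodes)) * model.axis_ratio)
    raise UnsupportedModelError(model.family)


# --------------------------------------------------------------------------
# Percus-Yevick hard-sphere structure factor

# small-argument Taylor coefficients of the three bracket functions
_B1 = (1 / 3, -1 / 30, 1 / 840, -1 / 45360, 1 / 3991680)
_B2 = (1 / 4, -1 / 36, 1 / 960, -1 / 50400, 1 / 4354560)
_B3 = (1 / 6, -1 / 48, 1 / 1200, -1 / 60480, 1 / 5080320)


def py_structure_factor(q_grid, spec: StructureFactorSpec) -> np.ndarray:
    """Analytic Percus-Yevick hard-sphere structure factor S(q).

    Standard Wertheim/Thiele solution; S(0) = (1-phi)^4 / (1+2phi)^2 and
    S(q) -> 1 at large q.  A Taylor series (error < 1e-9) replaces the
    cancellation-prone closed form at small q * R_hs.
    """
    if spec.kind != "hard_sphere_py":
        raise ValueError("py_structure_factor requires kind='hard_sphere_py'")
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    phi = spec.phi
    if phi == 0.0:
        return np.ones_like(q)
    A = 2.0 * q * spec.R_hs  # q times the hard-sphere diameter
    denom = (1.0 - phi) ** 4
    alpha = (1.0 + 2.0 * phi) ** 2 / denom
    beta = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / denom
    gamma = 0.5 * phi * alpha

    small = A < 0.9
    G_over_A = np.empty_like(A)

    As = A[small]
    # series form of b_i/A: even polynomial in A, finite at A = 0
    def _poly_even(x, coeffs):
        x2 = x * x
        out = np.zeros_like(x)
        for c in reversed(coeffs):
            out = out * x2 + c
        return out

    G_over_A[small] = (alpha * _poly_even(As, _B1) + beta * _poly_even(As, _B2)
                       + gamma * _poly_even(As, _B3))

    Al = A[~small]
    sa, ca = np.sin(Al), np.cos(Al)
    b1 = (sa - Al * ca) / Al**2
    b2 = (2.0 * Al * sa + (2.0 - Al**2) * ca - 2.0) / Al**3
    b3 = (-(Al**4) * ca + 4.0 * ((3.0 * Al**2 - 6.0) * ca + (Al**3 - 6.0 * Al) * sa + 6.0)) / Al**5
    G_over_A[~small] = (alpha * b1 + beta * b2 + gamma * b3) / Al

    return 1.0 / (1.0 + 24.0 * phi * G_over_A)


# --------------------------------------------------------------------------
# assembly

#: A^3 * A^-4 -> cm^-1
UNIT_A_TO_CM = 1.0e8


def assemble_intensity(model: ParticleModel, sf: StructureFactorSpec,
                       phi: float, q_grid) -> "np.ndarray":
    """Absolute-scale intensity I(q) = phi <|F|^2>/<V> S(q) * 1e8 [1/cm].

    For a monodisperse sphere this gives I(0) = phi * V[A^3] *
    delta_rho^2[A^-4] * 1e8 per cm; the structure factor multiplies the
    size-averaged form factor with no size-structure coupling (the common
    decoupling-free approximation, with R_hs the mean radius).
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError("volume fraction must be in [0, 1)")
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if phi == 0.0:
        return np.zeros_like(q)
    msq = polydisperse_intensity(model, q)
    S = py_structure_factor(q, sf) if sf.kind == "hard_sphere_py" else np.ones_like(q)
    return phi * msq / mean_volume(model) * S * UNIT_A_TO_CM
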