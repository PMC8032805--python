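"""Forward simulator for hard-sphere suspensions and micellar core-shell systems.

Generates synthetic scattering curves for two-phase polymer/solvent systems
(polydisperse spheres with a Percus-Yevick hard-sphere structure factor) and
a three-phase Pluronic-like core-shell scenario, with the ground truth
(molecular weight, squared excess amplitude) recorded in the curve metadata
so recovery can be tested downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi

import numpy as np

from .curve_io import ScatteringCurve
from .models import (
    ParticleModel,
    StructureFactorSpec,
    assemble_intensity,
    mean_volume,
    polydisperse_intensity,
    size_distribution,
    sphere_volume,
)

N_A = 6.02214076e23  # 1/mol


@dataclass
class TwoPhaseSystem:
    """Solute/solvent pair: mass densities [g/cm^3], SLDs [1/A^2], volume fraction."""

    name: str
    polymer_density: float
    solvent_density: float
    polymer_sld: float
    solvent_sld: float
    volume_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.volume_fraction < 1.0:
            raise ValueError("volume fraction must be in [0, 1)")

    @property
    def concentration(self) -> float:
        """c = nu * d1 in g/cm^3."""
        return self.volume_fraction * self.polymer_density

    @property
    def contrast(self) -> float:
        """SLD difference solute - solvent [1/A^2]."""
        return self.polymer_sld - self.solvent_sld


@dataclass
class CoreShellScenario:
    """Core-shell sphere suspension (a micellar three-phase system)."""

    name: str
    core_radius: float
    shell_thickness: float
    sld_core: float
    sld_shell: float
    sld_solvent: float
    pd_core: float
    pd_shell: float
    volume_fraction: float
    bulk_density: float

    @property
    def total_radius(self) -> float:
        return self.core_radius + self.shell_thickness

    @property
    def concentration(self) -> float:
        return self.volume_fraction * self.bulk_density


#: polymer/solvent two-phase systems simulated with R = 90 A spheres,
#: Gaussian size distribution sigma/mean = 0.05, PY hard spheres at phi = 0.2
TWO_PHASE_SYSTEMS = {
    "ps_h2o": TwoPhaseSystem("ps_h2o", 1.04, 1.0, 9.5156e-6, 9.4691e-6, 0.2),
    "ps_etoh": TwoPhaseSystem("ps_etoh", 1.04, 0.791, 9.5156e-6, 7.6022e-6, 0.2),
    "ps_chcl3": TwoPhaseSystem("ps_chcl3", 1.04, 1.486, 9.5156e-6, 12.4894e-6, 0.2),
    "pmma_h2o": TwoPhaseSystem("pmma_h2o", 1.171, 1.0, 10.749e-6, 9.4691e-6, 0.2),
    "pp_h2o": TwoPhaseSystem("pp_h2o", 0.855, 1.0, 8.2952e-6, 9.4691e-6, 0.2),
}

#: Pluronic PE10500 micelle: PPG core, hydrated PEG shell, in water
CORE_SHELL_SCENARIOS = {
    "pluronic_pe10500": CoreShellScenario(
        "pluronic_pe10500",
        core_radius=60.0,
        shell_thickness=16.5,
        sld_core=8.0592e-6,
        sld_shell=10.44e-6,
        sld_solvent=9.4691e-6,
        pd_core=0.10,
        pd_shell=0.15,
        volume_fraction=0.15,
        bulk_density=1.03,
    )
}

SCENARIOS = {**TWO_PHASE_SYSTEMS, **CORE_SHELL_SCENARIOS}

DEFAULT_RADIUS = 90.0
DEFAULT_PD = 0.05


@dataclass
class QGridSpec:
    """q-sampling for a simulated curve: 400 log-spaced points, 0.002-0.35 1/A."""

    q_min: float = 0.002
    q_max: float = 0.35
    n: int = 400
    spacing: str = "log"

    def build(self) -> np.ndarray:
        if self.q_min <= 0 or self.q_max <= self.q_min:
            raise ValueError("need 0 < q_min < q_max")
        if self.spacing == "log":
            return np.geomspace(self.q_min, self.q_max, self.n)
        if self.spacing == "linear":
            return np.linspace(self.q_min, self.q_max, self.n)
        raise ValueError("spacing must be 'log' or 'linear'")


def theoretical_mw(volume: float, density: float) -> float:
    """Molecular weight V * d * N_A [g/mol] of a dry particle (V in A^3)."""
    if volume < 0 or density <= 0:
        raise ValueError("volume must be >= 0 and density > 0")
    return volume * 1e-24 * density * N_A


def weight_average_volume(model: ParticleModel) -> float:
    """<V^2>/<V> [A^3] — the volume moment a scattering experiment weighs."""
    r, w = size_distribution(model.radius, model.pd_ratio, model.pd_kind)
    if model.family == "core_shell_sphere":
        r = r + model.shell_thickness
    V = sphere_volume(r) * (model.axis_ratio if model.family in ("spheroid", "ellipsoid") else 1.0)
    return float(np.sum(w * V**2) / np.sum(w * V))


def geometry_for(system) -> ParticleModel:
    """Default particle geometry for a named scenario."""
    if isinstance(system, TwoPhaseSystem):
        return ParticleModel("sphere", DEFAULT_RADIUS, contrast=system.contrast,
                             pd_kind="gaussian", pd_ratio=DEFAULT_PD)
    if isinstance(system, CoreShellScenario):
        return ParticleModel(
            "core_shell_sphere", system.core_radius,
            shell_thickness=system.shell_thickness,
            sld_core=system.sld_core, sld_shell=system.sld_shell,
            sld_solvent=system.sld_solvent,
            pd_kind="gaussian", pd_ratio=system.pd_core,
            pd_ratio_shell=system.pd_shell,
        )
    raise TypeError(f"unsupported system type {type(system).__name__}")


def simulate_system(system, geometry: ParticleModel | None = None,
                    q_grid_spec: QGridSpec | None = None) -> ScatteringCurve:
    """Simulate the absolute-scale scattering curve of a scenario.

    The hard-sphere radius of the structure factor is the mean outer radius
    of the particles.  Metadata records the concentration and the true
    molecular weights (number/volume-based and weight-average) and squared
    excess amplitude for later recovery checks.
    """
    if geometry is None:
        geometry = geometry_for(system)
    if isinstance(system, CoreShellScenario) and geometry.family != "core_shell_sphere":
        raise ValueError("core-shell scenario requires a core_shell_sphere geometry")
    spec = q_grid_spec or QGridSpec()
    q = spec.build()
    phi = system.volume_fraction
    if geometry.family == "core_shell_sphere":
        R_out = geometry.radius + geometry.shell_thickness
        density = system.bulk_density
    else:
        R_out = geometry.radius * max(1.0, geometry.axis_ratio) if geometry.family != "sphere" else geometry.radius
        density = system.polymer_density
    sf = StructureFactorSpec("hard_sphere_py", R_hs=R_out, phi=phi)
    I = assemble_intensity(geometry, sf, phi, q)

    V0 = mean_volume(ParticleModel(**{**geometry.__dict__, "pd_ratio": 0.0,
                                      "pd_ratio_shell": 0.0, "pd_kind": "none"}))
    c = system.concentration
    meta = {
        "scenario": system.name,
        "concentration_g_cm3": c,
        "volume_fraction": phi,
        "density_g_cm3": density,
        "true_mw_g_mol": theoretical_mw(V0, density),
        "true_mw_weight_avg_g_mol": theoretical_mw(weight_average_volume(geometry), density),
    }
    if isinstance(system, TwoPhaseSystem):
        # squared mass-specific excess amplitude, cm^2/g^2
        meta["true_db2_cm2_g2"] = (system.contrast * 1e16 / system.polymer_density) ** 2
    return ScatteringCurve(q, I, None, "absolute", meta)


def distort_scale(curve: ScatteringCurve, k: float) -> ScatteringCurve:
    """Multiply intensities by an arbitrary factor, losing the absolute scale."""
    if k <= 0:
        raise ValueError("scale factor must be positive")
    sigma = curve.sigma * k if curve.sigma is not None else None
    out = curve.with_intensity(curve.I * k, sigma=sigma, scale="relative")
    out.meta["scale_factor"] = out.meta.get("scale_factor", 1.0) * k
    return out


def add_noise(curve: ScatteringCurve, relative_sigma: float, seed: int) -> ScatteringCurve:
    """Apply multiplicative Gaussian noise and populate the sigma column."""
    if relative_sigma < 0:
        raise ValueError("relative_sigma must be >= 0")
    if relative_sigma == 0:
        return curve.with_intensity(curve.I.copy(), sigma=curve.sigma)
    rng = np.random.default_rng(seed)
    noisy = curve.I * (1.0 + relative_sigma * rng.standard_normal(curve.I.shape))
    sigma = relative_sigma * np.abs(curve.I)
    sigma = np.where(sigma > 0, sigma, np.finfo(float).tiny)
    return curve.with_intensity(noisy, sigma=sigma)
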