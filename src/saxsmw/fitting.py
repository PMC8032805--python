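"""Model fitting: form-factor fits in the structure-factor-free window, and
Guinier analysis.

The form-factor fit deliberately excludes the interaction-affected low-q
region: the model is fitted only for q above a user-chosen lower bound and
then extrapolated (with S(q) = 1) down to q = 0, supplying the
zero-concentration limit of the scattering curve that the invariant-based
molecular-weight estimator requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .curve_io import ScatteringCurve
from .models import ParticleModel, mean_volume, polydisperse_intensity


class FitError(RuntimeError):
    pass


class GuinierError(RuntimeError):
    pass


@dataclass
class FitResult:
    """A fitted particle model with its structure-factor-free extrapolation."""

    model: ParticleModel
    I0_fit: float
    chi2: float
    redchi: float
    q_fit_range: tuple
    n_points: int
    #: model curve on a dense grid reaching q = 0 (2000 linear points)
    fitted_curve: ScatteringCurve = field(repr=False, default=None)

    def evaluate(self, q) -> np.ndarray:
        """Model intensity (S = 1) on an arbitrary q grid, same scale as the data."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        shape = polydisperse_intensity(self.model, q) / self._msq0
        return self.I0_fit * shape

    def __post_init__(self):
        self._msq0 = float(polydisperse_intensity(self.model, np.array([0.0]))[0])


def _model_shape(q, model: ParticleModel) -> np.ndarray:
    msq = polydisperse_intensity(model, q)
    msq0 = polydisperse_intensity(model, np.array([0.0]))[0]
    return msq / msq0


def _make_model(family, params, template: ParticleModel | None,
                pd_kind: str = "schulz_zimm") -> ParticleModel:
    kw = dict(template.__dict__) if template is not None else {}
    kw.update(
        family=family,
        radius=params["radius"].value,
        pd_ratio=params["pd_ratio"].value,
        pd_kind=pd_kind if params["pd_ratio"].value > 0 else "none",
    )
    if family == "core_shell_sphere":
        kw["shell_thickness"] = params["shell_thickness"].value
    if family in ("spheroid", "ellipsoid"):
        kw["axis_ratio"] = params["axis_ratio"].value
    kw.setdefault("contrast", 1.0)
    return ParticleModel(**kw)


def fit_form_factor(
    curve: ScatteringCurve,
    family: str,
    q_lo: float,
    q_hi: float | None = None,
    init: ParticleModel | None = None,
    pd_kind: str = "schulz_zimm",
    vary_pd: bool = True,
    vary_axis_ratio: bool = False,
    vary_shell: bool = True,
    n_starts: int = 5,
) -> FitResult:
    """Weighted least-squares fit of a form-factor model over [q_lo, q_hi].

    Weights are 1/sigma^2 where uncertainties are present, else 1/I^2
    (relative residuals, appropriate for data spanning several decades).
    The radius is multi-started over ``n_starts`` log-spaced values; among
    converged starts the lowest chi-square wins, ties broken by the smaller
    radius.  The returned result carries the model evaluated with S = 1 on
    a dense grid extending to q = 0.
    """
    q_hi = q_hi if q_hi is not None else float(curve.q[-1])
    if q_lo < curve.q[0] - 1e-12:
        raise ValueError("q_lo below the measured range")
    mask = (curve.q >= q_lo) & (curve.q <= q_hi)
    q, I = curve.q[mask], curve.I[mask]
    if q.size < 10:
        raise FitError(f"only {q.size} points in the fit window; need >= 10")
    sigma = curve.sigma[mask] if curve.sigma is not None else None
    if sigma is None:
        # relative residuals; floor the weight so exact form-factor zeros in
        # noiseless synthetic data do not dominate the objective
        safe = np.maximum(np.abs(I), 1e-5 * np.max(np.abs(I)))
        weights = 1.0 / safe
    else:
        weights = 1.0 / sigma

    template = init
    if init is not None and init.family != family:
        raise ValueError("init model family does not match the requested family")

    def residual(params):
        model = _make_model(family, params, template, pd_kind)
        pred = params["I0"].value * _model_shape(q, model)
        return (pred - I) * weights

    # coarse scan over radius with the amplitude profiled out analytically
    # (I0 enters linearly), then the best local minima seed the refinements
    def _coarse_chi2(R0):
        model = _make_model(family, _seed_params(R0, init, family), template, pd_kind)
        shape = _model_shape(q, model)
        wsq = weights**2
        denom = float(np.sum(wsq * shape**2))
        I0_opt = float(np.sum(wsq * shape * I)) / denom if denom > 0 else 0.0
        return float(np.sum(((I0_opt * shape - I) * weights) ** 2))

    scan_radii = np.geomspace(max(1.0 / q_hi, 0.5), 15.0 / q_lo, 60)
    scan = np.array([_coarse_chi2(R0) for R0 in scan_radii])
    order = [i for i in np.argsort(scan)
             if i == 0 or i == scan.size - 1
             or (scan[i] <= scan[i - 1] and scan[i] <= scan[i + 1])]
    radii0 = [scan_radii[i] for i in order[:n_starts]]
    if init is not None:
        radii0 = [init.radius] + radii0[: max(0, n_starts - 1)]

    n_free = 2 + int(vary_pd) + int(family == "core_shell_sphere" and vary_shell) \
        + int(family in ("spheroid", "ellipsoid") and vary_axis_ratio)
    if q.size <= n_free:
        raise FitError("fewer points than free parameters")

    best = None
    for R0 in radii0:
        seed_model = _make_model(family, _seed_params(R0, init, family), template, pd_kind)
        shape_first = float(_model_shape(q[:1], seed_model)[0])
        params = lmfit.Parameters()
        params.add("I0", value=float(np.abs(I[0])) / max(shape_first, 1e-6), min=0.0)
        params.add("radius", value=R0, min=1e-2, max=20.0 / q_lo)
        params.add("pd_ratio", value=(init.pd_ratio if init is not None and init.pd_ratio else 0.08) if vary_pd else 0.0,
                   min=0.0, max=0.45, vary=vary_pd)
        if family == "core_shell_sphere":
            t0 = init.shell_thickness if init is not None else 0.3 * R0
            params.add("shell_thickness", value=t0, min=0.0, max=10.0 / q_lo, vary=vary_shell)
        if family in ("spheroid", "ellipsoid"):
            nu0 = init.axis_ratio if init is not None else 1.05
            params.add("axis_ratio", value=nu0, min=0.2, max=5.0, vary=vary_axis_ratio)
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        if not np.all(np.isfinite(res.residual)):
            continue
        chi2 = float(np.sum(res.residual**2))
        cand = (chi2, res.params["radius"].value, res)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise FitError("no fit start converged")
    chi2, _, res = best
    model = _make_model(family, res.params, template, pd_kind)
    I0_fit = float(res.params["I0"].value)
    if I0_fit <= 0:
        raise FitError("fit collapsed to non-positive forward intensity")
    result = FitResult(
        model=model,
        I0_fit=I0_fit,
        chi2=chi2,
        redchi=chi2 / max(1, q.size - n_free),
        q_fit_range=(float(q_lo), float(q_hi)),
        n_points=int(q.size),
    )
    q_dense = np.linspace(0.0, float(curve.q[-1]), 2000)
    I_dense = result.evaluate(q_dense)
    result.fitted_curve = ScatteringCurve(q_dense[1:], I_dense[1:], None, curve.scale,
                                          {"fitted_family": family})
    return result


def _seed_params(R0, init, family):
    p = lmfit.Parameters()
    p.add("radius", value=R0)
    p.add("pd_ratio", value=(init.pd_ratio if init is not None else 0.0))
    if family == "core_shell_sphere":
        p.add("shell_thickness", value=(init.shell_thickness if init is not None else 0.3 * R0))
    if family in ("spheroid", "ellipsoid"):
        p.add("axis_ratio", value=(init.axis_ratio if init is not None else 1.05))
    return p


@dataclass
class GuinierResult:
    """I(0) and radius of gyration from a Guinier fit ln I = ln I0 - (q Rg)^2/3."""

    I0: float
    Rg: float
    q_range: tuple
    qRg_max: float
    n_points: int


def guinier_fit(curve: ScatteringCurve, qRg_max: float = 1.3,
                min_points: int = 5) -> GuinierResult:
    """Iterative Guinier analysis of the low-q region.

    Fits ln I against q^2 on a window that is shrunk until q * Rg <= qRg_max
    for every point used, starting from the lowest decade of q.  Points with
    I <= 0 are excluded.
    """
    pos = curve.I > 0
    q, I = curve.q[pos], curve.I[pos]
    if q.size < min_points:
        raise GuinierError("not enough positive-intensity low-q points")
    n = max(min_points, min(q.size, int(0.3 * q.size)))
    for _ in range(200):
        qq, ll = q[:n] ** 2, np.log(I[:n])
        slope, intercept = np.polyfit(qq, ll, 1)
        if slope >= 0:
            raise GuinierError("no Guinier decay (non-negative slope)")
        Rg = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(q * Rg, qRg_max, side="right"))
        n_new = max(min_points, min(n_new, q.size))
        if n_new == n:
            break
        n = n_new
    return GuinierResult(
        I0=float(np.exp(intercept)),
        Rg=Rg,
        q_range=(float(q[0]), float(q[n - 1])),
        qRg_max=qRg_max,
        n_points=n,
    )
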