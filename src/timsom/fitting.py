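"""Viscoelastic model fitting on response spectra.

Least squares on the stacked relative residuals of G' and G'' (each
component normalized by its own measured value, since spectra span
several decades and measurement noise is relative), with points excluded
when G' <= 0, G'' <= 0 or their quality flag is set.
Exponents are bounded to [0, 1]; quasi-moduli are fitted in log10 space.
95% confidence half-widths come from the Jacobian covariance at the
optimum scaled by the residual variance (delta method back to the linear
scale for log-fitted parameters).  Multi-start initialization over an
exponent grid makes the optimum deterministic for multi-modal fractional
fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np

from .models import DerivedParams, ViscoModel, derived_params
from .spectra import ResponseSpectrum

__all__ = [
    "FitResult",
    "fit_model",
    "crossover_from_fit",
    "viscosity_from_loss",
]

_EXP_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class FitResult:
    """A fitted material with uncertainty and bookkeeping."""

    model: ViscoModel
    ci95: dict                    # parameter -> 95% CI half-width
    n_used: int
    n_excluded: int
    residual: float               # RMS relative error at the optimum
    derived: DerivedParams
    at_bounds: bool = False       # an exponent ended on the [0, 1] boundary

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "ci95": self.ci95,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "residual": self.residual,
            "at_bounds": self.at_bounds,
            "derived": {
                "tau_s": self.derived.tau,
                "omega_c_rad_s": self.derived.omega_c_rad_s,
                "omega_c_hz": self.derived.omega_c_hz,
                "plateau_pa": self.derived.plateau,
            },
        }


def _param_spec(family: str):
    """(log-scale names, exponent names) per family."""
    if family == "newtonian":
        return ["eta"], []
    if family == "springpot":
        return ["C_alpha"], ["alpha"]
    if family in ("maxwell", "kelvin_voigt"):
        return ["E", "eta"], []
    if family in ("fractional_kv", "fractional_maxwell"):
        return ["C_alpha", "C_beta"], ["alpha", "beta"]
    raise ValueError(f"unknown family {family!r}")


def _build_model(family: str, values: dict) -> ViscoModel:
    if family in ("fractional_kv", "fractional_maxwell"):
        # canonical order alpha <= beta (the two springpots are exchangeable)
        if values["alpha"] > values["beta"]:
            values = {
                "C_alpha": values["C_beta"], "alpha": values["beta"],
                "C_beta": values["C_alpha"], "beta": values["alpha"],
            }
    return ViscoModel(family=family, **values)


def _residuals(params, family, w, G, wre, wim):
    vals = {}
    for name in params:
        if name.startswith("log_"):
            vals[name[4:]] = 10.0 ** params[name].value
        else:
            vals[name] = params[name].value
    try:
        m = ViscoModel(family=family, **vals)
    except ValueError:
        return np.full(2 * len(w), 1e6)
    Gm = m.complex_modulus(w)
    return np.concatenate([(Gm.real - G.real) * wre,
                           (Gm.imag - G.imag) * wim])


def _starts(family: str, w, G):
    """Data-driven initial guesses over an exponent grid."""
    absG = np.abs(G)
    lo, hi = 0, len(w) - 1
    starts = []

    def c_for(exp, idx, part=None):
        # modulus scale making a springpot pass through the data at idx
        g = absG[idx] if part is None else max(part[idx], 1e-3 * absG[idx])
        return max(g / w[idx] ** exp, 1e-300)

    if family == "newtonian":
        starts.append({"log_eta": math.log10(np.median(G.imag / w))})
    elif family == "springpot":
        for a in _EXP_GRID + (0.99,):
            starts.append({"log_C_alpha": math.log10(c_for(a, hi)),
                           "alpha": a})
    elif family in ("maxwell", "kelvin_voigt"):
        eta0 = max(np.median(G.imag / w), 1e-300)
        if family == "maxwell":
            E0 = max(absG[hi], 1e-300)
        else:
            E0 = max(G.real[lo], 1e-3 * absG[lo])
        starts.append({"log_E": math.log10(E0), "log_eta": math.log10(eta0)})
    else:
        parallel = family == "fractional_kv"
        for a in _EXP_GRID:
            for b in _EXP_GRID:
                if a > b:
                    continue
                if parallel:
                    # low-frequency end ~ alpha element, high end ~ beta
                    ca, cb = c_for(a, lo), c_for(b, hi)
                else:
                    # series: low end ~ beta (softer), high end ~ alpha
                    ca, cb = c_for(a, hi), c_for(b, lo)
                starts.append({"log_C_alpha": math.log10(ca), "alpha": a,
                               "log_C_beta": math.log10(cb), "beta": b})
    return starts


def fit_model(spectrum: ResponseSpectrum, family: str,
              qc_exclude: bool = True,
              exclude_negative: bool = True,
              init: Optional[ViscoModel] = None) -> FitResult:
    """Fit a model family to a spectrum's complex modulus.

    Points with non-positive G' or G'' (and flagged points) are excluded
    before fitting, following the negative-data-point exclusion rule.
    ``exclude_negative=False`` disables the sign rule (used by the
    compensation's internal fit, where a purely viscous material puts the
    storage modulus at 0 +/- numerical noise on every frequency).
    ``init`` replaces the multi-start grid with a single warm start taken
    from a previously fitted model of the same family (used inside
    fixed-point loops where the optimum moves only slightly).

    Residuals are the relative errors of G' and G'', each component
    normalized by its own measured value (homoscedastic when measurement
    noise is relative, which makes the covariance-based CIs consistent);
    with ``exclude_negative=False`` the normalization falls back to
    1/|G| per point, which tolerates vanishing components.
    """
    log_names, exp_names = _param_spec(family)
    w_all = spectrum.omega
    G_all = spectrum.G
    mask = np.isfinite(G_all)
    if exclude_negative:
        mask &= (G_all.real > 0) & (G_all.imag > 0)
    if qc_exclude:
        mask &= ~spectrum.qc
    w, G = w_all[mask], G_all[mask]
    n_used, n_excluded = int(mask.sum()), int((~mask).sum())
    n_free = len(log_names) + len(exp_names)
    if n_used < max(4, 2 * n_free):
        raise ValueError(
            f"under-determined fit: {n_used} usable points "
            f"({n_excluded} excluded) for {n_free} free parameters")
    if exclude_negative:
        wre, wim = 1.0 / G.real, 1.0 / G.imag
    else:
        wre = wim = 1.0 / np.abs(G)

    if init is not None:
        if init.family != family:
            raise ValueError("init model must belong to the fitted family")
        start = {}
        for name in log_names:
            start[f"log_{name}"] = math.log10(getattr(init, name))
        for name in exp_names:
            start[name] = min(max(getattr(init, name), 1e-6), 1 - 1e-6)
        start_list = [start]
    else:
        start_list = _starts(family, w, G)

    best = None
    for start in start_list:
        params = lmfit.Parameters()
        for name in log_names:
            params.add(f"log_{name}", value=start[f"log_{name}"],
                       min=-15.0, max=15.0)
        for name in exp_names:
            params.add(name, value=start[name], min=0.0, max=1.0)
        try:
            res = lmfit.minimize(_residuals, params, method="leastsq",
                                 args=(family, w, G, wre, wim),
                                 nan_policy="omit")
        except Exception:
            continue
        cost = float(np.sum(res.residual ** 2))
        if best is None or cost < best[0] * (1.0 - 1e-12):
            best = (cost, res)
    if best is None:
        raise ValueError(f"all fits failed for family {family!r}")
    cost, res = best

    values, ci95 = {}, {}
    at_bounds = False
    var_names = list(res.params.keys())
    for i, name in enumerate(var_names):
        p = res.params[name]
        err = p.stderr if p.stderr is not None else float("nan")
        if name.startswith("log_"):
            raw = name[4:]
            values[raw] = 10.0 ** p.value
            ci95[raw] = 1.96 * math.log(10.0) * values[raw] * err
        else:
            values[name] = p.value
            ci95[name] = 1.96 * err
            if p.value < 1e-6 or p.value > 1.0 - 1e-6:
                at_bounds = True
    # exchange-symmetric families: swap CIs alongside parameters
    if family in ("fractional_kv", "fractional_maxwell") \
            and values["alpha"] > values["beta"]:
        ci95 = {"C_alpha": ci95["C_beta"], "alpha": ci95["beta"],
                "C_beta": ci95["C_alpha"], "beta": ci95["alpha"]}
    model = _build_model(family, values)
    rms = math.sqrt(cost / (2 * n_used))
    return FitResult(model=model, ci95=ci95, n_used=n_used,
                     n_excluded=n_excluded, residual=rms,
                     derived=derived_params(model), at_bounds=at_bounds)


def crossover_from_fit(fit: FitResult) -> Optional[float]:
    """Crossover frequency G' = G'' of the fitted model, in Hz.

    For a Maxwell material this is E/(2 pi eta); None when the fitted
    family has no crossover in the search band.
    """
    return fit.derived.omega_c_hz


@dataclass
class LossSlope:
    eta: float       # Pa s
    stderr: float    # Pa s
    n_used: int
    n_excluded: int


def viscosity_from_loss(spectrum: ResponseSpectrum) -> LossSlope:
    """Viscosity from the slope of the loss modulus, G'' = eta * w.

    Zero-intercept regression minimizing the relative residuals
    ((eta w - G'')/G'')^2 over points with positive G''.
    """
    w = spectrum.omega
    Gpp = spectrum.G_dprime
    mask = np.isfinite(Gpp) & (Gpp > 0) & ~spectrum.qc
    n_used = int(mask.sum())
    if n_used < 3:
        raise ValueError(f"need >= 3 positive loss-modulus points, "
                         f"have {n_used}")
    w, Gpp = w[mask], Gpp[mask]
    u = w / Gpp  # regressor of the relative-residual problem
    eta = float(np.sum(u) / np.sum(u * u))
    r = eta * u - 1.0
    se = math.sqrt(float(np.sum(r * r)) / (n_used - 1) / float(np.sum(u * u)))
    return LossSlope(eta=eta, stderr=se, n_used=n_used,
                     n_excluded=int((~mask).sum()))
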