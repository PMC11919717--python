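"""Non-oscillatory rheology estimators.

Creep compliance under a force clamp and its conversion to the complex
shear modulus; the spring--dashpot--dashpot (Jeffrey) indentation model;
viscosity from Stokes-drag ramps; trap stiffness and probe radius from
force scans.  Units follow the package convention pN--um--s (Pa = pN/um^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np

from .spectra import ResponseSpectrum

__all__ = [
    "CreepTrace",
    "CreepCompliance",
    "JeffreyFit",
    "DragSeries",
    "bead_position",
    "creep_compliance",
    "creep_to_G",
    "fit_jeffrey",
    "stokes_viscosity",
    "trap_stiffness_from_scan",
    "radius_from_scan",
]


@dataclass
class CreepTrace:
    """Force-clamp record: trap position and measured force over time."""

    t: np.ndarray        # s, strictly increasing from 0
    x_trap: np.ndarray   # um
    F: np.ndarray        # pN
    k: float             # pN/um
    F0: float            # clamp set-point, pN
    a: float             # bead radius, um

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x_trap = np.asarray(self.x_trap, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F0 <= 0:
            raise ValueError("clamp force F0 must be positive")
        if self.t[0] < 0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing from 0")


@dataclass
class CreepCompliance:
    t: np.ndarray        # s
    J: np.ndarray        # 1/Pa
    clamp_ok: np.ndarray  # per-sample clamp-tolerance flag
    a: float


@dataclass
class JeffreyFit:
    """x(t)/f_FC = (1/kappa)(1 - exp(-kappa t/gamma1)) + t/gamma2."""

    kappa: float    # pN/um
    gamma1: float   # pN s/um
    gamma2: float   # pN s/um
    f_FC: float     # pN
    ci95: dict
    residual: float


@dataclass
class DragSeries:
    """Plateau drag forces at a series of trap velocities."""

    v: np.ndarray          # um/s, positive and increasing
    F_plateau: np.ndarray  # pN
    R: float               # bead radius, um

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.F_plateau = np.asarray(self.F_plateau, dtype=float)
        if np.any(self.v <= 0) or np.any(np.diff(self.v) <= 0):
            raise ValueError("velocities must be positive and increasing")


def bead_position(x_trap, F, k: float):
    """Probe position from trap position and force: x_bead = x_trap - F/k."""
    if k <= 0:
        raise ValueError("trap stiffness must be positive")
    return np.asarray(x_trap, dtype=float) - np.asarray(F, dtype=float) / k


def creep_compliance(trace: CreepTrace,
                     clamp_tol: float = 0.05) -> CreepCompliance:
    """Creep compliance J(t) = 6 pi a x_bead(t) / F0.

    Samples where the measured force leaves the +/- ``clamp_tol`` band
    around the set-point are flagged (not dropped).
    """
    xb = bead_position(trace.x_trap, trace.F, trace.k)
    J = 6.0 * math.pi * trace.a * xb / trace.F0
    ok = np.abs(trace.F - trace.F0) <= clamp_tol * trace.F0
    return CreepCompliance(t=trace.t.copy(), J=J, clamp_ok=ok, a=trace.a)


def _local_powerlaw(t, J):
    """Fit J = c * t^p on (t, J) by log-log least squares."""
    m = (t > 0) & (J > 0)
    p, logc = np.polyfit(np.log(t[m]), np.log(J[m]), 1)
    return math.exp(logc), p


def creep_to_G(t, J=None, a: Optional[float] = None,
               k_trap: Optional[float] = None,
               omega_t: Optional[float] = None,
               n_freq: int = 30) -> ResponseSpectrum:
    """Convert a sampled creep compliance to G*(omega).

    Discrete transform of the piecewise-linear interpolant of J(t)
    (Evans-type):

        i w J~(w) = i w J(0) + (1 - e^{-i w t1}) (J1 - J(0)) / t1
                    + sum_n (dJ_n/dt_n)(e^{-i w t_{n-1}} - e^{-i w t_n})
                    + e^{-i w t_N} / eta_f ,
        G*(w) = 1 / (i w J~(w)) ,

    with the endpoints extrapolated by fitted local power laws: J(0) and
    the short-time behaviour from the first decade, the steady-flow
    viscosity eta_f from the last decade (a non-positive late slope means
    an arrested material, eta_f -> infinity).  The frequency grid spans
    [1/t_max, 1/(2 dt_min)], log-spaced.

    Accepts a :class:`CreepCompliance` as the single positional argument,
    or explicit (t, J) arrays plus the bead radius ``a``.
    """
    if isinstance(t, CreepCompliance):
        cc = t
        t, J, a = cc.t[cc.clamp_ok], cc.J[cc.clamp_ok], cc.a
    t = np.asarray(t, dtype=float)
    J = np.asarray(J, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 creep samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    if a is None:
        a = 0.5

    # short-time power law J ~ c t^p over the first decade; a clearly
    # positive exponent means J(0+) = 0, otherwise keep the first sample
    m_lo = (t <= t[0] * 10.0) if t[0] > 0 else np.zeros(len(t), dtype=bool)
    m_lo[:4] = True
    _, p_lo = _local_powerlaw(t[m_lo], np.maximum(J[m_lo], 1e-300))
    J0 = 0.0 if p_lo > 0.05 else float(J[0])

    # late-time slope -> steady-flow viscosity
    m_hi = t >= t[-1] / 10.0
    sl = np.polyfit(t[m_hi], J[m_hi], 1)[0]
    inv_eta = max(sl, 0.0)

    # top frequency: half the inverse of the finest time scale the record
    # constrains -- the smallest sampling interval, but never beyond the
    # first sample time (log-sampled records have dt_min << t[0], and
    # frequencies above 1/t[0] depend on the unobserved early response)
    dt_min = np.min(np.diff(t))
    t_fine = max(dt_min, t[0]) if t[0] > 0 else dt_min
    w = 2.0 * math.pi * np.logspace(
        math.log10(1.0 / t[-1]), math.log10(1.0 / (2.0 * t_fine)), n_freq)

    e = np.exp(-1j * np.outer(w, t))      # (n_freq, n_t)
    slopes = np.diff(J) / np.diff(t)
    core = np.sum(slopes * (e[:, :-1] - e[:, 1:]), axis=1)
    first = (1.0 - np.exp(-1j * w * t[0])) * (J[0] - J0) / t[0] \
        if t[0] > 0 else 0.0
    iwJ = 1j * w * J0 + first + core + e[:, -1] * inv_eta
    G = 1j * w / iwJ  # G* = 1/(i w J~), with iwJ = (i w)^2 J~ / (i w)
    if omega_t is None:
        omega_t = 4.0 * np.max(w)
    return ResponseSpectrum.from_G(
        w, G, k=k_trap if k_trap is not None else 0.0, a=a,
        omega_t=omega_t, stage="compensated")


def _jeffrey_y(t, kappa, g1, g2):
    return (1.0 - np.exp(-kappa * t / g1)) / kappa + t / g2


def fit_jeffrey(trace: CreepTrace, monotone_tol: float = 0.05) -> JeffreyFit:
    """Fit the Jeffrey (spring--dashpot--dashpot) creep model.

    The normalized displacement y = x_bead/F0 is fitted with
    y(t) = (1/kappa)(1 - e^{-kappa t/gamma1}) + t/gamma2; the initializer
    uses the closed-form slope relations (initial slope 1/gamma1 +
    1/gamma2, late slope 1/gamma2, late intercept 1/kappa).
    """
    t = trace.t
    y = bead_position(trace.x_trap, trace.F, trace.k) / trace.F0
    y = y - y[0]
    # reject decreasing trends while tolerating sample-level noise: check
    # monotonicity on coarse bin means rather than raw increments
    span = y[-1] - y[0]
    nb = min(15, max(3, len(y) // 10))
    bins = np.array_split(y, nb)
    means = np.array([b.mean() for b in bins])
    if span <= 0 or np.any(np.diff(means) < -monotone_tol * abs(span)):
        raise ValueError("normalized displacement must be increasing")

    n = len(t)
    tail = slice(max(2, int(0.8 * n)), n)
    s_inf, b_inf = np.polyfit(t[tail], y[tail], 1)
    s_inf = max(s_inf, 1e-12 * span / t[-1])
    g2_0 = 1.0 / s_inf
    kappa_0 = 1.0 / max(b_inf, 1e-3 * span)
    head = slice(0, max(3, n // 20))
    s_0 = max(np.polyfit(t[head], y[head], 1)[0], s_inf * (1 + 1e-9))
    g1_0 = 1.0 / max(s_0 - 1.0 / g2_0, 1e-12 * s_inf)

    params = lmfit.Parameters()
    params.add("log_kappa", value=math.log10(kappa_0), min=-12, max=12)
    params.add("log_gamma1", value=math.log10(g1_0), min=-12, max=12)
    params.add("log_gamma2", value=math.log10(g2_0), min=-12, max=12)

    scale = max(np.max(np.abs(y)), 1e-300)

    def resid(p):
        return (_jeffrey_y(t, 10.0 ** p["log_kappa"].value,
                           10.0 ** p["log_gamma1"].value,
                           10.0 ** p["log_gamma2"].value) - y) / scale

    res = lmfit.minimize(resid, params, method="leastsq")
    vals, ci = {}, {}
    for name in ("kappa", "gamma1", "gamma2"):
        p = res.params[f"log_{name}"]
        vals[name] = 10.0 ** p.value
        err = p.stderr if p.stderr is not None else float("nan")
        ci[name] = 1.96 * math.log(10.0) * vals[name] * err
    rms = math.sqrt(float(np.mean(res.residual ** 2)))
    return JeffreyFit(kappa=vals["kappa"], gamma1=vals["gamma1"],
                      gamma2=vals["gamma2"], f_FC=trace.F0, ci95=ci,
                      residual=rms)


def stokes_viscosity(series: DragSeries) -> tuple[float, float]:
    """Viscosity from F_drag = 6 pi eta R v: zero-intercept slope / (6 pi R).

    Returns (eta, standard error) in Pa s.
    """
    if len(series.v) < 3:
        raise ValueError("need at least 3 velocities")
    v, F = series.v, series.F_plateau
    slope = float(np.sum(F * v) / np.sum(v * v))
    r = F - slope * v
    se_slope = math.sqrt(float(np.sum(r * r)) / (len(v) - 1)
                         / float(np.sum(v * v)))
    c = 6.0 * math.pi * series.R
    return slope / c, se_slope / c


def trap_stiffness_from_scan(x, F, window: float = 0.2
                             ) -> tuple[float, dict]:
    """Trap stiffness from a force scan across the probe.

    Linear fit of force versus trap-probe offset restricted to
    |offset| <= ``window`` (um) around the force zero-crossing.  Returns
    (k, diagnostics) where the diagnostics report the crossing position,
    the number of points used and the RMS residual of the linear fit
    relative to the in-window force scale.
    """
    x = np.asarray(x, dtype=float)
    F = np.asarray(F, dtype=float)
    sgn = np.sign(F)
    cross = np.nonzero(np.diff(sgn) != 0)[0]
    if len(cross) == 0:
        raise ValueError("no force zero-crossing in the scan")
    # crossing closest to the scan centre
    i = cross[np.argmin(np.abs(x[cross] - 0.5 * (x[0] + x[-1])))]
    x0 = x[i] - F[i] * (x[i + 1] - x[i]) / (F[i + 1] - F[i])
    m = np.abs(x - x0) <= window
    if m.sum() < 3:
        raise ValueError("fewer than 3 scan points inside the linear window")
    if x0 - x[m].min() < 0.9 * window or x[m].max() - x0 < 0.9 * window:
        raise ValueError("scan does not cover the +/- window around the "
                         "force zero-crossing")
    k, c = np.polyfit(x[m] - x0, F[m], 1)
    r = F[m] - (k * (x[m] - x0) + c)
    scale = max(np.max(np.abs(F[m])), 1e-300)
    diag = {"x0": float(x0), "n_used": int(m.sum()),
            "rms_residual_rel": float(np.sqrt(np.mean(r * r)) / scale)}
    return float(k), diag


def radius_from_scan(x, F) -> float:
    """Probe radius as half the distance between the force extrema.

    A heuristic for sizing spherical probes (for example lipid droplets)
    from a trap scan across the whole particle: the restoring-force
    profile peaks near the particle edges.  Both extrema must lie strictly
    inside the scan.
    """
    x = np.asarray(x, dtype=float)
    F = np.asarray(F, dtype=float)
    i_max, i_min = int(np.argmax(F)), int(np.argmin(F))
    if {i_max, i_min} & {0, len(x) - 1}:
        raise ValueError("force extremum at the scan edge: the scan does "
                         "not cross the whole particle")
    return abs(x[i_max] - x[i_min]) / 2.0
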