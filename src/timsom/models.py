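"""Power-law (fractional) viscoelastic model family.

Every material handled by the package is built from at most two *springpots*,
the fractional element whose stress--strain law is ``sigma = C_a * D_t^a eps``
with ``0 <= a <= 1``.  A springpot interpolates between a spring (``a = 0``,
``C_a = E``) and a dashpot (``a = 1``, ``C_a = eta``).  Two springpots combine
either in parallel (fractional Kelvin--Voigt, a viscoelastic solid) or in
series (fractional Maxwell, a viscoelastic liquid); the classical Kelvin--Voigt
and Maxwell models are their ``(a, b) = (0, 1)`` limits.

Unit convention (fixed throughout the package): pN -- um -- s, under which
pN/um^2 is identical to Pa, so moduli carry no conversion factors.  The
complex convention is ``exp(+i w t)``; ``G = G' + i G''`` with both parts
non-negative for every family (passivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as _gamma, gammaln as _gammaln

__all__ = [
    "ViscoModel",
    "DerivedParams",
    "model_G",
    "model_chi",
    "model_relaxation",
    "model_creep",
    "derived_params",
    "mittag_leffler",
]

_FAMILIES = (
    "newtonian",
    "springpot",
    "kelvin_voigt",
    "maxwell",
    "fractional_kv",
    "fractional_maxwell",
)

# families whose springpots add stress (parallel) vs strain (series)
_PARALLEL = {"newtonian", "springpot", "kelvin_voigt", "fractional_kv"}
_SERIES = {"maxwell", "fractional_maxwell"}


# ---------------------------------------------------------------------------
# Mittag-Leffler function
# ---------------------------------------------------------------------------

def _ml_series(a: float, b: float, z: float, rtol: float = 1e-16):
    """Power series sum_k z^k / Gamma(a k + b) in extended precision.

    Returns (value, ok); ok is False when catastrophic cancellation is
    detected (alternating series with huge intermediate terms).
    """
    acc = np.longdouble(0.0)
    zl = np.longdouble(z)
    term = np.longdouble(1.0)
    max_term = np.longdouble(0.0)
    for k in range(0, 2000):
        g = _gamma(a * k + b)
        if not math.isfinite(g):
            contrib = np.longdouble(0.0)
        else:
            contrib = term / np.longdouble(g)
        acc += contrib
        max_term = max(max_term, abs(contrib))
        if abs(contrib) < rtol * max(abs(acc), np.longdouble(1e-300)) and k > 2:
            break
        term *= zl
    else:
        return float(acc), False
    if max_term > 1e15 * max(abs(acc), np.longdouble(1e-300)):
        return float(acc), False  # lost all significant digits
    return float(acc), True


def _ml_asymptotic(a: float, b: float, z: float):
    """Large negative-argument expansion, valid for 0 < a < 1, z << -1.

    E_{a,b}(z) ~ -sum_{k>=1} z^{-k} / Gamma(b - a k).
    """
    acc = 0.0
    prev = math.inf
    for k in range(1, 60):
        g = _gamma(b - a * k)
        if not math.isfinite(g) or g == 0.0:
            continue  # pole of gamma: the term vanishes exactly
        term = (z ** (-k)) / g
        if abs(term) > prev:  # divergent tail reached
            break
        acc -= term
        prev = abs(term)
        if abs(term) < 1e-12 * max(abs(acc), 1e-300):
            return acc, True
    return acc, prev < 1e-9 * max(abs(acc), 1e-300)


def _talbot(F, t: float, n: int = 48) -> float:
    """Fixed-Talbot inversion of a Laplace transform F(s) at time t > 0."""
    r = 2.0 * n / (5.0 * t)
    total = 0.5 * math.exp(r * t) * complex(F(r)).real
    for k in range(1, n):
        th = k * math.pi / n
        cot = 1.0 / math.tan(th)
        s = r * th * (cot + 1j)
        sigma = th + (th * cot - 1.0) * cot
        total += (np.exp(t * s) * complex(F(s)) * (1.0 + 1j * sigma)).real
    return float(total * r / n)


def mittag_leffler(a: float, b: float, z: float) -> float:
    """Two-parameter Mittag-Leffler function E_{a,b}(z) for real z <= 0.

    Series with adaptive truncation; asymptotic expansion and, as a last
    resort, Talbot inversion of the Laplace transform
    ``s^{a-b} / (s^a - z)`` when the series loses precision.
    """
    if a <= 0:
        raise ValueError("mittag_leffler requires a > 0")
    if z > 0:
        raise ValueError("implemented for z <= 0 only")
    if z == 0.0:
        return 1.0 / _gamma(b)
    # The alternating series cancels catastrophically for large |z|: its peak
    # term sits near k* = |z|^(1/a)/a.  Attempt it only when the peak is both
    # reachable and small enough to leave ~6 significant digits in 80-bit
    # arithmetic, otherwise go to the asymptotic expansion / Laplace fallback.
    log_k_peak = math.log(abs(z)) / a - math.log(a)
    if log_k_peak < math.log(900.0):
        k_peak = math.exp(log_k_peak)
        log10_peak = (k_peak * math.log10(abs(z))
                      - _gammaln(a * k_peak + b) / math.log(10.0))
        if log10_peak < 6.0:
            val, ok = _ml_series(a, b, z)
            if ok:
                return val
    val, ok = _ml_asymptotic(a, b, z)
    if ok:
        return val
    # E_{a,b}(-c t^a) has Laplace transform s^{a-b}/(s^a + c) at t=1 scaling;
    # invert at t=1 with c = -z.
    c = -z
    return _talbot(lambda s: s ** (a - b) / (s ** a + c), 1.0)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViscoModel:
    """A parametric viscoelastic material.

    Parameters
    ----------
    family:
        One of ``newtonian``, ``springpot``, ``kelvin_voigt``, ``maxwell``,
        ``fractional_kv``, ``fractional_maxwell``.
    C_alpha, alpha:
        Quasi-modulus (Pa s^alpha) and exponent of the first springpot.
    C_beta, beta:
        Quasi-modulus (Pa s^beta) and exponent of the second springpot
        (two-element families only).
    eta, E:
        Viscosity (Pa s) and elastic modulus (Pa) for the classical
        families; for ``newtonian`` only ``eta`` is active.
    """

    family: str
    C_alpha: Optional[float] = None
    alpha: Optional[float] = None
    C_beta: Optional[float] = None
    beta: Optional[float] = None
    eta: Optional[float] = None
    E: Optional[float] = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        pairs = self.springpots()
        for c, a in pairs:
            if not (c > 0):
                raise ValueError("moduli/viscosities must be strictly positive")
            if not (0.0 <= a <= 1.0):
                raise ValueError("exponents must lie in [0, 1]")
        if len(pairs) == 2 and pairs[0][1] > pairs[1][1]:
            raise ValueError("requires alpha <= beta")

    # -- springpot decomposition ------------------------------------------
    def springpots(self) -> list[tuple[float, float]]:
        """Return [(C, a), ...] springpot elements of this material."""
        f = self.family
        if f == "newtonian":
            return [(self._req("eta"), 1.0)]
        if f == "springpot":
            return [(self._req("C_alpha"), self._req("alpha"))]
        if f in ("kelvin_voigt", "maxwell"):
            return [(self._req("E"), 0.0), (self._req("eta"), 1.0)]
        return [
            (self._req("C_alpha"), self._req("alpha")),
            (self._req("C_beta"), self._req("beta")),
        ]

    def _req(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"{self.family} requires parameter {name}")
        return float(v)

    @property
    def is_series(self) -> bool:
        return self.family in _SERIES

    # -- frequency domain --------------------------------------------------
    def complex_modulus(self, omega):
        """G*(omega) in Pa for angular frequency omega > 0 (rad/s)."""
        w = np.asarray(omega, dtype=float)
        if np.any(w <= 0):
            raise ValueError("omega must be strictly positive")
        terms = [c * (1j * w) ** a for c, a in self.springpots()]
        if self.is_series:
            ga, gb = terms
            G = ga * gb / (ga + gb)
        else:
            G = sum(terms)
        return G if np.ndim(omega) else complex(G)

    def response(self, omega, a: float):
        """chi(omega) = 1/(6 pi a G) in um/pN for bead radius a in um."""
        if not a > 0:
            raise ValueError("bead radius must be positive")
        G = self.complex_modulus(omega)
        if np.any(np.abs(G) == 0):
            raise ZeroDivisionError("singular material: |G| = 0")
        return 1.0 / (6.0 * math.pi * a * G)

    # -- time domain --------------------------------------------------------
    def relaxation(self, t):
        """Relaxation modulus G(t) in Pa, where it is a regular function.

        Families containing a free dashpot contribution in parallel
        (newtonian, kelvin_voigt, fractional families with beta = 1 in
        parallel) have a delta-singular part and are rejected.
        """
        tt = np.asarray(t, dtype=float)
        if np.any(tt <= 0):
            raise ValueError("t must be strictly positive")
        pairs = self.springpots()
        if not self.is_series:
            if any(a >= 1.0 for _, a in pairs):
                raise ValueError(
                    f"relaxation modulus of {self.family} with a dashpot "
                    "element is delta-singular"
                )
            out = sum(c * tt ** (-a) / _gamma(1.0 - a) for c, a in pairs)
        else:
            (ca, a), (cb, b) = pairs
            if b - a < 1e-12:
                c = ca * cb / (ca + cb)
                out = c * tt ** (-a) / _gamma(1.0 - a)
            else:
                r = ca / cb
                ml = np.vectorize(
                    lambda x: mittag_leffler(b - a, 1.0 - a, -r * x ** (b - a))
                )
                out = ca * tt ** (-a) * ml(tt)
        return out if np.ndim(t) else float(out)

    def creep(self, t):
        """Creep compliance J(t) in 1/Pa for t > 0."""
        tt = np.asarray(t, dtype=float)
        if np.any(tt <= 0):
            raise ValueError("t must be strictly positive")
        pairs = self.springpots()

        def _sp_creep(c, a):
            return tt ** a / (c * _gamma(1.0 + a))

        if self.is_series:
            out = sum(_sp_creep(c, a) for c, a in pairs)
        elif len(pairs) == 1:
            out = _sp_creep(*pairs[0])
        else:
            (ca, a), (cb, b) = pairs
            if b - a < 1e-12:
                out = _sp_creep(ca + cb, a)
            else:
                r = ca / cb
                ml = np.vectorize(
                    lambda x: mittag_leffler(b - a, 1.0 + b, -r * x ** (b - a))
                )
                out = tt ** b / cb * ml(tt)
        return out if np.ndim(t) else float(out)

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        params = {
            k: getattr(self, k)
            for k in ("C_alpha", "alpha", "C_beta", "beta", "eta", "E")
            if getattr(self, k) is not None
        }
        return {"family": self.family, "params": params, "units": "pN-um-s"}

    @classmethod
    def from_dict(cls, d: dict) -> "ViscoModel":
        return cls(family=d["family"], **d.get("params", {}))


@dataclass(frozen=True)
class DerivedParams:
    """Quantities derived from a fitted material.

    ``tau`` is the relaxation time eta/E for the classical families and
    1/omega_c otherwise; ``omega_c`` solves G'(w) = G''(w).  ``plateau`` is
    the frequency-independent modulus of the elastic springpot when one is
    present (low-frequency plateau for solids, high-frequency for liquids).
    """

    tau: Optional[float] = None
    omega_c_rad_s: Optional[float] = None
    omega_c_hz: Optional[float] = None
    plateau: Optional[float] = None

    @property
    def has_crossover(self) -> bool:
        return self.omega_c_rad_s is not None


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def model_G(model: ViscoModel, omega):
    """Complex shear modulus G' + i G'' (Pa) at angular frequency omega."""
    return model.complex_modulus(omega)


def model_chi(model: ViscoModel, omega, a: float):
    """Complex response (compliance) chi = 1/(6 pi a G), um/pN."""
    return model.response(omega, a)


def model_relaxation(model: ViscoModel, t):
    return model.relaxation(t)


def model_creep(model: ViscoModel, t):
    return model.creep(t)


_W_LO, _W_HI = 1e-6, 1e9  # rad/s search bracket for the crossover


def _crossover(model: ViscoModel) -> Optional[float]:
    def h(logw):
        G = model.complex_modulus(10.0 ** logw)
        return G.real - G.imag

    grid = np.linspace(math.log10(_W_LO), math.log10(_W_HI), 301)
    vals = np.array([h(g) for g in grid])
    scale = np.array([abs(model.complex_modulus(10.0 ** g)) for g in grid])
    if np.all(np.abs(vals) <= 1e-12 * scale):
        return None  # G' == G'' identically (springpot with a = 1/2)
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    return 10.0 ** brentq(h, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14)


def derived_params(model: ViscoModel) -> DerivedParams:
    """Relaxation time, crossover frequency and plateau modulus."""
    pairs = model.springpots()
    plateau = None
    for c, a in pairs:
        if a == 0.0:
            plateau = c
    if model.family in ("maxwell", "kelvin_voigt"):
        tau = model._req("eta") / model._req("E")
        wc = 1.0 / tau
        return DerivedParams(tau=tau, omega_c_rad_s=wc,
                             omega_c_hz=wc / (2.0 * math.pi), plateau=plateau)
    wc = _crossover(model)
    if wc is None:
        return DerivedParams(plateau=plateau)
    return DerivedParams(tau=1.0 / wc, omega_c_rad_s=wc,
                         omega_c_hz=wc / (2.0 * math.pi), plateau=plateau)
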