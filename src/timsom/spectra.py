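"""Response-function extraction and first-harmonic compensation.

From interleaved slot signals the *deviated* response of the time-shared
measurement is

    chi_t(w) = -2 V2(w) / ( k [V1(w) + V2(w)] )

with V1, V2 the single-frequency Fourier amplitudes of the two streams and
``V`` the force exerted by the trap on the bead (in pN when the detector
conversion is unity).  The companion modulus is G = 1/(6 pi a chi).

Truncating the trap-occupancy waveform at its first harmonic gives the
closed-form map from the ideal material response chi to the deviated one:

    chi_t = [chi - chi1 + k (chi chi1 - chip chim)]
            / [1 + 2 k chi1 + k^2 chip chim]

with chip = chi(w_t + w), chim = chi*(w_t - w) = chi(-w_t + w) and
chi1 = (chip + chim)/2; w_t is the time-sharing angular frequency.  The map
is inverted per frequency by solving for chi algebraically, with the
shifted-frequency terms (which lie beyond the drive Nyquist) supplied by a
viscoelastic model fitted to the current estimate, iterated to a fixed
point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .tsim import InterleavedTrace

__all__ = [
    "ResponseSpectrum",
    "extract_fundamental",
    "chi_t_from_signals",
    "chi_active_passive",
    "fha_forward",
    "fha_compensate",
    "spectrum_from_traces",
    "peak_snr",
]

_HINTS = {
    "viscoelastic_solid": "fractional_kv",
    "viscoelastic_liquid": "fractional_maxwell",
    "springpot": "springpot",
}


@dataclass
class ResponseSpectrum:
    """Per-frequency complex response with provenance.

    ``chi`` is the complex compliance in um/pN; ``G = 1/(6 pi a chi)`` in
    Pa.  ``stage`` records whether the spectrum is the raw time-shared
    measurement ('deviated'), the inverted one ('compensated') or a model
    evaluation ('ideal').  ``qc`` flags frequencies that failed extraction
    or inversion; they are retained, and excluded downstream by the fitting
    rules.
    """

    omega: np.ndarray          # rad/s, strictly increasing
    chi: np.ndarray            # complex, um/pN
    k: float                   # pN/um
    a: float                   # um
    omega_t: float             # rad/s
    stage: str = "deviated"
    qc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.chi = np.asarray(self.chi, dtype=complex)
        if self.qc is None:
            self.qc = np.zeros(len(self.omega), dtype=bool)
        self.qc = np.asarray(self.qc, dtype=bool)
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")
        if np.any(self.omega > self.omega_t / 2.0 * (1.0 + 1e-9)):
            raise ValueError("omega must not exceed the drive Nyquist w_t/2")
        if self.stage not in ("deviated", "compensated", "ideal"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def freq_hz(self) -> np.ndarray:
        return self.omega / (2.0 * math.pi)

    @property
    def G(self) -> np.ndarray:
        """Complex shear modulus, Pa."""
        return 1.0 / (6.0 * math.pi * self.a * self.chi)

    @property
    def G_prime(self) -> np.ndarray:
        return self.G.real

    @property
    def G_dprime(self) -> np.ndarray:
        return self.G.imag

    @classmethod
    def from_G(cls, omega, G, k, a, omega_t, stage="ideal", qc=None):
        chi = 1.0 / (6.0 * math.pi * a * np.asarray(G, dtype=complex))
        return cls(omega=omega, chi=chi, k=k, a=a, omega_t=omega_t,
                   stage=stage, qc=qc)


# ---------------------------------------------------------------------------
# Extraction from interleaved traces
# ---------------------------------------------------------------------------

def _project(t: np.ndarray, v: np.ndarray, omega: float) -> complex:
    """Single-frequency discrete Fourier amplitude at the true timestamps."""
    return 2.0 / len(t) * np.sum(v * np.exp(-1j * omega * t))


def _project_ls(t: np.ndarray, v: np.ndarray, omega: float,
                n_harm: int = 4) -> complex:
    """Fundamental amplitude by harmonic regression at the true timestamps.

    The slot signals are periodic at the drive frequency but far from
    sinusoidal (the drive is a zero-order-hold staircase), so a plain
    single-bin projection leaks harmonic power into the fundamental when
    the sample spacing is incommensurate with the drive period.  Regressing
    the samples on {1, cos(h w t), sin(h w t), h = 1..n_harm} removes that
    leakage exactly.  Harmonics whose sampled (aliased) frequency collides
    with DC or with the fundamental are dropped; a rank-deficient design
    falls back to the plain projection.
    """
    fs = 1.0 / np.median(np.diff(t))
    f = omega / (2.0 * math.pi)
    span = t[-1] - t[0]
    cols = [np.ones_like(t)]
    idx_fund = 1
    cols += [np.cos(omega * t), np.sin(omega * t)]
    for h in range(2, n_harm + 1):
        fh = h * f
        folded = abs((fh + fs / 2.0) % fs - fs / 2.0)
        if min(folded, abs(folded - f)) < 0.5 / span:
            continue  # aliases onto DC or onto the fundamental
        cols += [np.cos(h * omega * t), np.sin(h * omega * t)]
    A = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(A, v, rcond=None)
    if rank < A.shape[1]:
        return _project(t, v, omega)
    a1, b1 = coef[idx_fund], coef[idx_fund + 1]
    return complex(a1, -b1)  # v ~ Re[(a1 - i b1) exp(i w t)]


def extract_fundamental(trace: InterleavedTrace,
                        n_discard_periods: int = 1,
                        trim: bool = True,
                        method: str = "regression"
                        ) -> tuple[complex, complex]:
    """Fundamental amplitudes (V1, V2) of the two slot streams.

    The first ``n_discard_periods`` drive periods are dropped (start-up
    transient) and the remainder is restricted to an integer number of
    drive periods (rectangular window, zero leakage at the known drive
    frequency).  With ``trim=False`` a non-integer residual raises instead
    of being trimmed.  ``method`` is 'regression' (harmonic least squares,
    default) or 'projection' (plain single-bin Fourier sum).
    """
    if method not in ("regression", "projection"):
        raise ValueError(f"unknown extraction method {method!r}")
    f = trace.drive_freq
    if f <= 0:
        raise ValueError("trace has no oscillatory drive")
    period = 1.0 / f
    t_start = n_discard_periods * period
    span = trace.t2[-1] + (trace.t1[1] - trace.t1[0]) - t_start
    m = int(math.floor(span / period + 1e-9))
    if m < 1:
        raise ValueError(
            "trace shorter than one drive period after transient removal")
    if not trim and abs(span / period - m) > 1e-9:
        raise ValueError(
            "trace does not span an integer period count; trim it to "
            f"{m} periods after the discarded transient")
    t_end = t_start + m * period
    omega = 2.0 * math.pi * f
    out = []
    proj = _project_ls if method == "regression" else _project
    for t, v in ((trace.t1, trace.V1), (trace.t2, trace.V2)):
        sel = (t >= t_start - 1e-12) & (t < t_end - 1e-12)
        if not np.any(sel):
            raise ValueError("no samples inside the analysis window")
        out.append(proj(t[sel], v[sel], omega))
    return out[0], out[1]


def chi_t_from_signals(V1: complex, V2: complex, k: float):
    """Deviated response chi_t = -2 V2 / (k (V1 + V2)), um/pN."""
    den = k * (np.asarray(V1) + np.asarray(V2))
    if np.any(np.abs(den) == 0):
        raise ZeroDivisionError("singular measurement: V1 + V2 = 0")
    return -2.0 * np.asarray(V2) / den


def spectrum_from_traces(traces: list[InterleavedTrace],
                         n_discard_periods: int = 1) -> ResponseSpectrum:
    """Deviated spectrum from a frequency sweep of interleaved traces."""
    if not traces:
        raise ValueError("empty sweep")
    cfg = traces[0].config
    order = np.argsort([tr.drive_freq for tr in traces])
    omega, chi, qc = [], [], []
    for i in order:
        tr = traces[i]
        w = 2.0 * math.pi * tr.drive_freq
        try:
            v1, v2 = extract_fundamental(tr, n_discard_periods)
            c = complex(chi_t_from_signals(v1, v2, cfg.k))
            flag = False
        except (ValueError, ZeroDivisionError):
            c, flag = complex("nan"), True
        omega.append(w)
        chi.append(c)
        qc.append(flag)
    return ResponseSpectrum(omega=np.array(omega), chi=np.array(chi),
                            k=cfg.k, a=cfg.a, omega_t=cfg.omega_t,
                            stage="deviated", qc=np.array(qc))


# ---------------------------------------------------------------------------
# First-harmonic map and its inversion
# ---------------------------------------------------------------------------

def chi_active_passive(chi, k: float):
    """Response of the bead held by the static trap: chi_a = chi/(1 + k chi)."""
    chi = np.asarray(chi, dtype=complex)
    den = 1.0 + k * chi
    if np.any(np.abs(den) == 0):
        raise ZeroDivisionError("resonant denominator 1 + k chi = 0")
    out = chi / den
    return out if out.ndim else complex(out)


def _shifted_terms(chi_fn: Callable, omega, omega_t: float):
    w = np.asarray(omega, dtype=float)
    chip = np.asarray(chi_fn(omega_t + w), dtype=complex)
    chim = np.conj(np.asarray(chi_fn(omega_t - w), dtype=complex))
    chi1 = 0.5 * (chip + chim)
    return chi1, chip * chim


def fha_forward(chi_fn: Callable, omega, omega_t: float, k: float,
                return_flags: bool = False):
    """Map the ideal response chi(w) to the deviated chi_t(w).

    ``chi_fn`` must be evaluable at w and w_t +/- w; the negative-frequency
    value chi(-(w_t - w)) is obtained by Hermitian symmetry (conjugation).
    Frequencies where the denominator vanishes are flagged, not raised.
    """
    w = np.asarray(omega, dtype=float)
    chi = np.asarray(chi_fn(w), dtype=complex)
    chi1, P = _shifted_terms(chi_fn, w, omega_t)
    num = chi - chi1 + k * (chi * chi1 - P)
    den = 1.0 + 2.0 * k * chi1 + k * k * P
    bad = np.abs(den) < 1e-300
    chit = np.where(bad, np.nan + 0j, num / np.where(bad, 1.0, den))
    if not np.ndim(omega):
        chit = complex(chit)
        bad = bool(bad)
    return (chit, bad) if return_flags else chit


def _invert_once(chi_t, chi1, P, k):
    """Solve the first-harmonic map for chi given the shifted terms."""
    return ((chi_t * (1.0 + 2.0 * k * chi1 + k * k * P) + chi1 + k * P)
            / (1.0 + k * chi1))


def fha_compensate(spectrum: ResponseSpectrum, family_hint: str,
                   k: Optional[float] = None,
                   omega_t: Optional[float] = None,
                   rtol: float = 1e-6, max_iter: int = 50
                   ) -> tuple[ResponseSpectrum, dict]:
    """Invert the first-harmonic map to recover the artefact-free response.

    The shifted-frequency terms lie beyond the drive Nyquist, so they are
    always evaluated from a model of the assumed material class
    (``family_hint``: 'viscoelastic_solid', 'viscoelastic_liquid',
    'springpot', or any concrete family name) fitted to the current
    estimate, and the inversion is iterated to a fixed point.

    Returns the compensated spectrum and a diagnostics dict with the number
    of iterations, convergence flag, relative-change history and the final
    fitted model.
    """
    from .fitting import fit_model  # deferred: fitting depends on spectra

    if spectrum.stage != "deviated":
        # the map chi_t -> chi applies to time-shared measurements only;
        # re-applying it to compensated (or model) spectra would corrupt
        # them, so compensation is idempotent by stage tracking
        out = ResponseSpectrum(omega=spectrum.omega.copy(),
                               chi=spectrum.chi.copy(), k=spectrum.k,
                               a=spectrum.a, omega_t=spectrum.omega_t,
                               stage="compensated", qc=spectrum.qc.copy())
        return out, {"n_iter": 0, "converged": True, "history": [],
                     "model": None,
                     "note": "input already compensated; nothing to do"}

    family = _HINTS.get(family_hint, family_hint)
    k = spectrum.k if k is None else k
    omega_t = spectrum.omega_t if omega_t is None else omega_t
    w = spectrum.omega
    chi_t = spectrum.chi
    good = ~spectrum.qc & np.isfinite(chi_t)
    chi_est = chi_t.copy()
    history: list[float] = []
    iterates: list[np.ndarray] = []
    converged = False
    fit = None
    warm = None
    for it in range(max_iter):
        est = ResponseSpectrum(omega=w[good], chi=chi_est[good], k=k,
                               a=spectrum.a, omega_t=omega_t,
                               stage="compensated")
        try:
            fit = fit_model(est, family, exclude_negative=False, init=warm)
        except ValueError as err:
            raise ValueError(
                f"compensation model fit failed for hint "
                f"{family_hint!r}: {err}") from err
        warm = fit.model
        chi1, P = _shifted_terms(
            lambda v: fit.model.response(v, spectrum.a), w, omega_t)
        chi_new = _invert_once(chi_t, chi1, P, k)
        delta = np.max(np.abs(chi_new[good] - chi_est[good])
                       / np.maximum(np.abs(chi_est[good]), 1e-300))
        history.append(float(delta))
        iterates.append(chi_new)
        if delta < rtol:
            chi_est = chi_new
            converged = True
            break
        # the plain map contracts slowly for strongly deviated (liquid)
        # spectra; Aitken delta^2 extrapolation of the iterate sequence
        # collapses the dominant geometric mode
        if it % 3 == 2 and len(iterates) >= 3:
            x0, x1, x2 = iterates[-3], iterates[-2], iterates[-1]
            den = x2 - 2.0 * x1 + x0
            safe = np.abs(den) > 1e-14 * np.maximum(np.abs(x2), 1e-300)
            acc = x0 - (x1 - x0) ** 2 / np.where(safe, den, 1.0)
            chi_new = np.where(safe, acc, x2)
        chi_est = chi_new
    qc = spectrum.qc | ~np.isfinite(chi_est)
    out = ResponseSpectrum(omega=w, chi=chi_est, k=k, a=spectrum.a,
                           omega_t=omega_t, stage="compensated", qc=qc)
    diag = {"n_iter": len(history), "converged": converged,
            "history": history, "model": fit.model if fit else None}
    return out, diag


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def peak_snr(trace: InterleavedTrace, omega: float,
             n_neighbours: int = 10) -> float:
    """Active-peak signal-to-noise ratio of the static-slot stream.

    Amplitude of the drive bin of |FFT(V2)| divided by (mean + 1 SD) of the
    neighbouring-bin amplitudes; the drive bin and its two immediate
    neighbours are excluded from the baseline.  QC passes when the ratio
    exceeds 1.
    """
    v = np.asarray(trace.V2, dtype=float)
    n = len(v)
    fs = 1.0 / (trace.t2[1] - trace.t2[0])
    amp = np.abs(np.fft.rfft(v - v.mean()))
    f = omega / (2.0 * math.pi)
    b = int(round(f * n / fs))
    if b < 1 or b >= len(amp):
        raise ValueError("drive frequency outside the sampled band")
    cand = [j for j in range(max(1, b - n_neighbours - 1),
                             min(len(amp), b + n_neighbours + 2))
            if abs(j - b) > 1]
    if len(cand) < 8:
        raise ValueError("trace too short: need >= 8 DFT bins around the "
                         "drive bin")
    base = amp[cand]
    floor = base.mean() + base.std(ddof=1)
    return float(amp[b] / max(floor, 1e-300))
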