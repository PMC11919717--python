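"""Forward simulation of a trapped probe under a time-shared trap waveform.

A single laser is alternated at the sharing rate between a driving trap
(oscillating as ``x1(t) = A sin(w t)``, held piecewise-constant over each
sharing cycle) and a static detection trap at the origin.  Within the linear
range of the traps, the optical force equals that of a single trap of full
stiffness ``k`` moving along a trapezoidal trajectory: a linear power ramp of
duration ``ramp`` into each trap position, a dwell, and the reverse ramp.

The acousto-optic deflector (AOD) receives its command at the *acoustic*
clock; the optical spot follows after the acoustic wave has filled the beam
cross-section (``fill_delay``).  Detector samples are taken ``sample_delay``
after each acoustic rising edge, which places them ``sample_delay -
fill_delay`` into the optical half-cycle -- at the centre of the dwell with
the default timing (33 us - 8 us = 25 us, dwell spanning 10-40 us).

The bead obeys overdamped force balance: the generalized Stokes resistance of
the medium, ``6 pi a`` times the material operator applied to ``x(t)``,
equals the instantaneous trap force ``k (x_l(t) - x(t))``.  No thermal noise
is generated here (detector noise can be added downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .models import ViscoModel

__all__ = [
    "TimeSharingConfig",
    "ProbeTrajectory",
    "InterleavedTrace",
    "drive_positions",
    "trap_trajectory",
    "simulate_probe",
    "sample_voltages",
    "run_sweep",
    "cycles_for",
]


@dataclass(frozen=True)
class TimeSharingConfig:
    """Instrument timing and trap parameters (units: s, pN/um, um)."""

    k: float = 50.0              # total trap stiffness, pN/um
    a: float = 0.5               # bead radius, um
    A: float = 0.1               # drive amplitude (= 2 x0), um
    cycle: float = 80e-6         # full sharing period, s
    ramp: float = 10e-6          # AOD power-transfer (rise) time, s
    dwell: float = 30e-6         # per-trap hold, s
    sample_delay: float = 33e-6  # sampling delay from the acoustic edge, s
    fill_delay: float = 8e-6     # acoustic transit to the beam centre, s
    dt: float = 0.5e-6           # integration step, s
    volt_per_pn: float = 1.0     # detector conversion (1 => signals in pN)
    linear_range: float = 0.2    # linear trap range bound on A, um

    def __post_init__(self):
        if abs(self.cycle - 2.0 * (self.ramp + self.dwell)) > 1e-12:
            raise ValueError("cycle must equal 2*(ramp + dwell)")
        off = self.sample_offset
        if not (self.ramp < off < self.ramp + self.dwell):
            raise ValueError(
                "sample_delay - fill_delay must fall inside the dwell")
        if not (0.0 <= self.A <= self.linear_range):
            raise ValueError(
                f"drive amplitude {self.A} um outside the linear range "
                f"[0, {self.linear_range}] um")
        if self.dt > self.ramp / 10.0:
            raise ValueError("dt must be <= ramp/10")
        if self.k <= 0 or self.a <= 0:
            raise ValueError("k and a must be positive")

    @property
    def per_trap_rate(self) -> float:
        """Per-trap sampling rate, Hz: each trap is visited once per cycle
        (the AOD itself is addressed twice per cycle, at 2/cycle)."""
        return 1.0 / self.cycle

    @property
    def nyquist(self) -> float:
        """Maximum drive frequency, Hz."""
        return self.per_trap_rate / 2.0

    @property
    def omega_t(self) -> float:
        """Time-sharing angular frequency, rad/s."""
        return 2.0 * math.pi * self.per_trap_rate

    @property
    def sample_offset(self) -> float:
        """Sample time within each optical half-cycle, s."""
        return self.sample_delay - self.fill_delay

    def to_dict(self) -> dict:
        return {
            "k": self.k, "a": self.a, "A": self.A, "cycle": self.cycle,
            "ramp": self.ramp, "dwell": self.dwell,
            "sample_delay": self.sample_delay, "fill_delay": self.fill_delay,
            "dt": self.dt, "volt_per_pn": self.volt_per_pn,
            "linear_range": self.linear_range,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimeSharingConfig":
        return cls(**d)


@dataclass
class ProbeTrajectory:
    """Probe and equivalent-trap trajectories on the integration grid."""

    t: np.ndarray    # s
    x: np.ndarray    # probe position, um
    x_l: np.ndarray  # equivalent trap position, um
    config: TimeSharingConfig
    drive_freq: float  # Hz

    @property
    def F(self) -> np.ndarray:
        """Instantaneous optical force k (x_l - x), pN."""
        return self.config.k * (self.x_l - self.x)


@dataclass
class InterleavedTrace:
    """Per-slot sampled detector signals of one frequency point."""

    drive_freq: float  # Hz
    t1: np.ndarray     # driving-slot sample times, s
    V1: np.ndarray     # driving-slot signals
    t2: np.ndarray     # static-slot sample times, s
    V2: np.ndarray     # static-slot signals
    config: TimeSharingConfig

    def __post_init__(self):
        for t in (self.t1, self.t2):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("sample times must be strictly increasing")


def drive_positions(omega: float, A: float, config: TimeSharingConfig,
                    n_cycles: int) -> np.ndarray:
    """Drive-trap command sequence x_{1,n} = A sin(w n / f_t)."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if omega / (2.0 * math.pi) > config.nyquist * (1.0 + 1e-9):
        raise ValueError(
            f"drive {omega / 2 / math.pi:.6g} Hz above the Nyquist bound "
            f"{config.nyquist:.6g} Hz")
    n = np.arange(n_cycles)
    seq = A * np.sin(omega * n / config.per_trap_rate)
    if omega > 0 and np.max(np.abs(seq)) < 1e-9 * A:
        raise ValueError(
            "sampled drive vanishes identically: a sine drive at a "
            "frequency commensurate with the sharing rate (e.g. exactly "
            "the Nyquist frequency) is zero at every command instant")
    return seq


def trap_trajectory(t, x1_seq: np.ndarray, config: TimeSharingConfig,
                    x2_seq: Optional[np.ndarray] = None) -> np.ndarray:
    """Equivalent single-trap position x_l(t) on the optical-cycle clock.

    Per cycle ``n``: ramp x2->x1 over [0, ramp), hold x1, ramp x1->x2,
    hold x2; continuous in t.  ``t`` beyond the command sequence holds the
    last cycle's values.
    """
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    x1 = np.asarray(x1_seq, dtype=float)
    x2 = np.zeros_like(x1) if x2_seq is None else np.asarray(x2_seq, float)
    T, r, d = config.cycle, config.ramp, config.dwell
    n = np.minimum((tt / T).astype(np.int64), len(x1) - 1)
    s = tt - n * T
    a1, a2 = x1[n], x2[n]
    out = np.empty_like(tt)
    m = s < r
    out[m] = a2[m] + (s[m] / r) * (a1[m] - a2[m])
    m = (s >= r) & (s < r + d)
    out[m] = a1[m]
    m = (s >= r + d) & (s < 2 * r + d)
    out[m] = a1[m] - ((s[m] - r - d) / r) * (a1[m] - a2[m])
    m = s >= 2 * r + d
    out[m] = a2[m]
    return out if np.ndim(t) else float(out[0])


def _steps_per_cycle(config: TimeSharingConfig) -> int:
    spc = config.cycle / config.dt
    if abs(spc - round(spc)) > 1e-9:
        raise ValueError("cycle must be an integer multiple of dt")
    return int(round(spc))


def cycles_for(freq: float, config: TimeSharingConfig,
               n_periods: int) -> int:
    """Sharing cycles covering ``n_periods`` full drive periods."""
    return max(1, math.ceil(n_periods / freq / config.cycle))


def simulate_probe(model: ViscoModel, omega: float,
                   config: TimeSharingConfig, n_cycles: int,
                   method: Optional[str] = None,
                   memory_window: Optional[int] = None) -> ProbeTrajectory:
    """Integrate the probe trajectory over ``n_cycles`` sharing cycles.

    ``method`` selects the solver for materials supported by both schemes
    ('gl' for the Grunwald-Letnikov fractional-derivative march, 'volterra'
    for the hereditary creep integral); by default stress-additive families
    use 'gl' and compliance-additive families 'volterra'.
    ``memory_window`` truncates the fractional memory (in steps) under the
    short-memory principle; default is full memory.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    spc = _steps_per_cycle(config)
    x1_seq = drive_positions(omega, config.A, config, n_cycles)
    n_steps = n_cycles * spc + 1
    t = np.arange(n_steps) * config.dt
    xl = trap_trajectory(t, x1_seq, config)
    six_pi_a = 6.0 * math.pi * config.a

    if method is None:
        method = "volterra" if model.is_series else "gl"
    if method == "gl":
        if model.is_series:
            raise ValueError(
                f"{model.family} is compliance-additive; the GL "
                "stress-operator march applies to parallel families only")
        pairs = model.springpots()
        coeffs = np.array([six_pi_a * c for c, _ in pairs])
        alphas = np.array([a for _, a in pairs])
        window = n_steps if memory_window is None else int(memory_window)
        window = min(window, n_steps)
        x = _kernels.gl_solve(xl, config.dt, config.k, coeffs, alphas, window)
    elif method == "volterra":
        x = _volterra(model, xl, t, config, six_pi_a)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(x)):
        bad = int(np.argmax(~np.isfinite(x)))
        raise ArithmeticError(
            f"solver diverged at step {bad} (t = {t[bad]:.3e} s)")
    return ProbeTrajectory(t=t, x=x, x_l=xl, config=config,
                           drive_freq=omega / (2.0 * math.pi))


def _volterra(model, xl, t, config, six_pi_a):
    pairs = model.springpots()
    # linear kernel J = J_el + t/eta: newtonian and classic Maxwell
    linear = all(a in (0.0, 1.0) for _, a in pairs)
    if linear:
        j_el = sum(1.0 / c for c, a in pairs if a == 0.0)
        inv_eta = sum(1.0 / c for c, a in pairs if a == 1.0)
        return _kernels.volterra_linear_solve(
            xl, config.dt, config.k, six_pi_a, j_el, inv_eta)
    tmid = (np.arange(len(xl)) + 0.5) * config.dt
    jmid = model.creep(tmid)
    return _kernels.volterra_solve(
        xl, config.dt, config.k, six_pi_a, np.asarray(jmid))


def sample_voltages(traj: ProbeTrajectory,
                    config: Optional[TimeSharingConfig] = None
                    ) -> InterleavedTrace:
    """Sample the instantaneous force in each slot at the detector times.

    V1 is taken ``sample_offset`` into each driving half-cycle, V2 the same
    offset into each static half-cycle (half a sharing period later), both
    divided by ``volt_per_pn``.
    """
    config = config or traj.config
    T = config.cycle
    n_cycles = int(round((traj.t[-1] - traj.t[0]) / T))
    if abs(n_cycles * T - (traj.t[-1] - traj.t[0])) > config.dt / 2:
        raise ValueError("trajectory must span an integer number of cycles")
    off = config.sample_offset
    n = np.arange(n_cycles)
    t1 = n * T + off
    t2 = n * T + T / 2.0 + off
    F = traj.F
    if t2[-1] > traj.t[-1] + 1e-12:
        raise ValueError("sample time outside the simulated trajectory")
    V1 = np.interp(t1, traj.t, F) / config.volt_per_pn
    V2 = np.interp(t2, traj.t, F) / config.volt_per_pn
    return InterleavedTrace(drive_freq=traj.drive_freq, t1=t1, V1=V1,
                            t2=t2, V2=V2, config=config)


def _default_periods(freq: float) -> int:
    """Drive periods per trace: one start-up transient to discard plus a
    measurement window of at least two periods and at least ~4 ms."""
    return 1 + max(2, math.ceil(0.004 * freq))


def run_sweep(model: ViscoModel, freq_list: Sequence[float],
              config: TimeSharingConfig,
              n_periods: Optional[int] = None,
              method: Optional[str] = None) -> list[InterleavedTrace]:
    """Simulate one interleaved trace per drive frequency (order kept)."""
    traces = []
    for f in freq_list:
        if f > config.nyquist * (1.0 + 1e-9):
            raise ValueError(f"{f} Hz above Nyquist {config.nyquist} Hz")
        periods = n_periods if n_periods is not None else _default_periods(f)
        nc = cycles_for(f, config, periods)
        traj = simulate_probe(model, 2.0 * math.pi * f, config, nc,
                              method=method)
        traj.drive_freq = f  # keep the requested value exactly
        traces.append(sample_voltages(traj, config))
    return traces
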