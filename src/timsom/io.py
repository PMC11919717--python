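"""File formats, frequency grids, fixture generation and the measurement
workflow.

Traces are tab-separated text with a commented YAML header (configuration
echo) and columns ``time_s``, ``slot`` (1|2), ``signal``.  Spectra are CSV
with columns ``omega_rad_s, freq_hz, chi_re, chi_im, G_prime_pa,
G_dprime_pa, stage, qc_flag``.  Fits are JSON.  All numeric output is
written at 12 significant digits so that write -> read round-trips are
exact at the 1e-12 level and fixture files are byte-stable for a fixed
seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import ViscoModel
from .spectra import (ResponseSpectrum, fha_compensate, fha_forward,
                      spectrum_from_traces)
from .tsim import InterleavedTrace, TimeSharingConfig, run_sweep

__all__ = [
    "SweepConfig",
    "default_frequency_grid",
    "write_trace", "read_trace",
    "write_spectrum", "read_spectrum",
    "write_fit",
    "generate_fixture",
    "workflow_run",
]

_FMT = "%.12g"


@dataclass
class SweepConfig:
    """A frequency sweep: grid, instrument timing, noise and seed."""

    fmin: float = 0.1
    fmax: float = 6250.0
    points_per_decade: int = 5
    timing: TimeSharingConfig = field(default_factory=TimeSharingConfig)
    noise: float = 0.0   # detector noise SD relative to the drive-slot RMS
    seed: int = 0

    def __post_init__(self):
        if self.fmax > self.timing.nyquist * (1.0 + 1e-9):
            raise ValueError(
                f"fmax {self.fmax} Hz exceeds the Nyquist bound "
                f"{self.timing.nyquist:.6g} Hz")

    @property
    def frequencies(self) -> np.ndarray:
        return default_frequency_grid(self.points_per_decade,
                                      self.fmin, self.fmax)

    def to_dict(self) -> dict:
        return {"fmin": self.fmin, "fmax": self.fmax,
                "points_per_decade": self.points_per_decade,
                "timing": self.timing.to_dict(),
                "noise": self.noise, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        d = dict(d)
        if "timing" in d:
            d["timing"] = TimeSharingConfig.from_dict(d["timing"])
        return cls(**d)


def default_frequency_grid(points_per_decade: int = 5,
                           fmin: float = 0.1,
                           fmax: float = 6250.0) -> np.ndarray:
    """Log-spaced drive frequencies, endpoints included.

    Points at fmin * 10^(j/points_per_decade); the first point above fmax
    is replaced by fmax itself, so the grid always ends at the cap.
    """
    if fmin <= 0 or fmax <= fmin:
        raise ValueError("need 0 < fmin < fmax")
    out = []
    j = 0
    while True:
        f = fmin * 10.0 ** (j / points_per_decade)
        if f >= fmax * (1.0 - 1e-12):
            break
        out.append(f)
        j += 1
    out.append(fmax)
    return np.array(out)


# ---------------------------------------------------------------------------
# Trace and spectrum files
# ---------------------------------------------------------------------------

def write_trace(trace: InterleavedTrace, path) -> None:
    path = Path(path)
    header = {"drive_freq_hz": float(trace.drive_freq),
              "config": trace.config.to_dict()}
    t = np.concatenate([trace.t1, trace.t2])
    slot = np.concatenate([np.ones(len(trace.t1), dtype=int),
                           np.full(len(trace.t2), 2, dtype=int)])
    v = np.concatenate([trace.V1, trace.V2])
    order = np.argsort(t, kind="stable")
    with path.open("w") as fh:
        for line in yaml.safe_dump(header, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        fh.write("time_s\tslot\tsignal\n")
        for ti, si, vi in zip(t[order], slot[order], v[order]):
            fh.write(f"{_FMT % ti}\t{si}\t{_FMT % vi}\n")


def _read_yaml_header(path) -> dict:
    lines = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("# "):
                lines.append(line[2:])
            elif line.startswith("#"):
                lines.append(line[1:])
            else:
                break
    return yaml.safe_load("".join(lines)) or {}


def read_trace(path) -> InterleavedTrace:
    header = _read_yaml_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    cfg = TimeSharingConfig.from_dict(header["config"])
    m1 = df["slot"] == 1
    m2 = df["slot"] == 2
    return InterleavedTrace(
        drive_freq=float(header["drive_freq_hz"]),
        t1=df.loc[m1, "time_s"].to_numpy(),
        V1=df.loc[m1, "signal"].to_numpy(),
        t2=df.loc[m2, "time_s"].to_numpy(),
        V2=df.loc[m2, "signal"].to_numpy(),
        config=cfg)


def write_spectrum(spec: ResponseSpectrum, path) -> None:
    path = Path(path)
    header = {"k": spec.k, "a": spec.a, "omega_t": spec.omega_t}
    with path.open("w") as fh:
        for line in yaml.safe_dump(header, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        fh.write("omega_rad_s,freq_hz,chi_re,chi_im,G_prime_pa,"
                 "G_dprime_pa,stage,qc_flag\n")
        G = spec.G
        for i in range(len(spec.omega)):
            fh.write(",".join([
                _FMT % spec.omega[i], _FMT % spec.freq_hz[i],
                _FMT % spec.chi[i].real, _FMT % spec.chi[i].imag,
                _FMT % G[i].real, _FMT % G[i].imag,
                spec.stage, str(int(spec.qc[i]))]) + "\n")


def read_spectrum(path) -> ResponseSpectrum:
    header = _read_yaml_header(path)
    df = pd.read_csv(path, comment="#")
    stage = str(df["stage"].iloc[0]) if len(df) else "deviated"
    return ResponseSpectrum(
        omega=df["omega_rad_s"].to_numpy(),
        chi=df["chi_re"].to_numpy() + 1j * df["chi_im"].to_numpy(),
        k=float(header["k"]), a=float(header["a"]),
        omega_t=float(header["omega_t"]), stage=stage,
        qc=df["qc_flag"].to_numpy().astype(bool))


def write_fit(fit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2,
                                     sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def generate_fixture(model: ViscoModel, sweep: SweepConfig, outdir,
                     n_periods: Optional[int] = None,
                     freqs: Optional[Sequence[float]] = None) -> dict:
    """Simulate a sweep, optionally add detector noise, write everything.

    Writes one trace file per frequency plus ``ground_truth.json`` holding
    the generating model, the ideal response and the first-harmonic
    prediction of the deviated response at each frequency.  Byte-stable
    for a fixed seed.  Returns {"traces": [paths], "ground_truth": path}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = sweep.timing
    freqs = list(sweep.frequencies if freqs is None else freqs)
    rng = np.random.default_rng(sweep.seed)
    traces = run_sweep(model, freqs, cfg, n_periods=n_periods)
    paths = []
    truth_rows = []
    for i, tr in enumerate(traces):
        if sweep.noise > 0:
            sd = sweep.noise * float(np.sqrt(np.mean(tr.V1 ** 2)))
            tr.V1 = tr.V1 + rng.normal(0.0, sd, len(tr.V1))
            tr.V2 = tr.V2 + rng.normal(0.0, sd, len(tr.V2))
        p = outdir / f"trace_{i:03d}_{tr.drive_freq:.6g}Hz.tsv"
        write_trace(tr, p)
        paths.append(p)
        w = 2.0 * math.pi * tr.drive_freq
        chi = model.response(w, cfg.a)
        chit = fha_forward(lambda v: model.response(v, cfg.a),
                           w, cfg.omega_t, cfg.k)
        truth_rows.append({
            "freq_hz": tr.drive_freq,
            "chi_ideal": [chi.real, chi.imag],
            "chi_t_fha": [chit.real, chit.imag],
        })
    truth = {"model": model.to_dict(), "sweep": sweep.to_dict(),
             "per_frequency": truth_rows}
    tp = outdir / "ground_truth.json"
    tp.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"traces": paths, "ground_truth": tp}


# ---------------------------------------------------------------------------
# The four-step measurement workflow
# ---------------------------------------------------------------------------

def workflow_run(trace_paths: Sequence, family_hint: str,
                 scan_path=None, fit_family: Optional[str] = None,
                 out_path=None) -> dict:
    """Run the four-step active-microrheology pipeline on files.

    1. probe centring (performed on the instrument; recorded as done),
    2. trap-rigidity advisory: warn when the trap is not softer than the
       material response at the top measured frequency (k |chi| >= 1),
    3. trap stiffness from a force scan (optional when the trace headers
       already carry a calibrated k),
    4. sweep extraction -> compensation -> model fit.

    Returns a machine-readable report with per-stage status and all
    intermediates; a failing stage stops the pipeline but earlier stages
    remain recorded.
    """
    from .auxrheo import trap_stiffness_from_scan
    from .fitting import fit_model, viscosity_from_loss

    report: dict = {"stages": []}

    def stage(name, status, **info):
        report["stages"].append({"stage": name, "status": status, **info})
        return status == "ok"

    stage("centering", "ok", note="assumed done on the instrument")

    try:
        traces = [read_trace(p) for p in trace_paths]
        if not traces:
            raise ValueError("no trace files given")
        spec = spectrum_from_traces(traces)
        k_hdr = traces[0].config.k
        good = ~spec.qc & np.isfinite(spec.chi)
        stiff = float(k_hdr * np.abs(spec.chi[good][np.argmax(
            spec.omega[good])])) if np.any(good) else float("inf")
        status = "warn" if stiff >= 1.0 else "ok"
        stage("stiffness_advisory", status, k_chi_top=stiff,
              note=("trap not softer than the material response at the top "
                    "measured frequency; the real part of a liquid-like "
                    "response may be unrecoverable" if status == "warn"
                    else "trap softer than the material"))
    except (OSError, ValueError, KeyError, ZeroDivisionError) as err:
        stage("stiffness_advisory", "error", message=str(err))
        return _finish(report, out_path)

    k = k_hdr
    if scan_path is not None:
        try:
            df = pd.read_csv(scan_path, comment="#")
            k_scan, diag = trap_stiffness_from_scan(
                df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
            stage("stiffness_from_scan", "ok", k=k_scan, **diag)
            k = k_scan
        except (OSError, ValueError) as err:
            stage("stiffness_from_scan", "error", message=str(err))
            return _finish(report, out_path)
    else:
        stage("stiffness_from_scan", "ok", k=k,
              note="taken from trace headers (no scan supplied)")

    try:
        comp, diag = fha_compensate(spec, family_hint, k=k)
        info: dict = {"compensation": {"n_iter": diag["n_iter"],
                                       "converged": diag["converged"]}}
        # model fit under the standard sign-exclusion rule; for nearly
        # purely viscous materials most storage points sit at 0 +/- noise
        # and are excluded, leaving the loss-slope viscosity as the result
        try:
            fit = fit_model(comp, fit_family
                            or getattr(diag["model"], "family", family_hint))
            report["fit"] = info["fit"] = fit.to_dict()
        except ValueError as err:
            report["fit"] = None
            info["fit_note"] = str(err)
        try:
            ls = viscosity_from_loss(comp)
            report["eta_loss_slope"] = info["eta_loss_slope"] = {
                "eta_pa_s": ls.eta, "stderr_pa_s": ls.stderr}
        except ValueError:
            pass
        if report.get("fit") is None and "eta_loss_slope" not in report:
            raise ValueError("neither a model fit nor a loss-slope "
                             "viscosity could be computed: "
                             + info.get("fit_note", ""))
        stage("sweep_analysis", "ok", **info)
        report["spectrum_deviated"] = _spec_rows(spec)
        report["spectrum_compensated"] = _spec_rows(comp)
    except (ValueError, ZeroDivisionError, ArithmeticError) as err:
        stage("sweep_analysis", "error", message=str(err))
    return _finish(report, out_path)


def _spec_rows(spec: ResponseSpectrum) -> list:
    G = spec.G
    return [{"freq_hz": float(f), "G_prime_pa": float(g.real),
             "G_dprime_pa": float(g.imag), "qc_flag": bool(q)}
            for f, g, q in zip(spec.freq_hz, G, spec.qc)]


def _finish(report: dict, out_path) -> dict:
    report["ok"] = all(s["status"] == "ok" for s in report["stages"])
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
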