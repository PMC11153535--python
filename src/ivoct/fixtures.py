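"""Analytic haematocrit-field fixtures and the top-level experiments.

The closed-form fields emulate the structures the flushing solver produces
— a clean saline front advancing down the lumen and the periodic arrival of
fresh erythrocyte slugs with each cardiac cycle — so the optics, scan and
imaging chain can be exercised quickly and deterministically without
running the CFD solver.  They are test scaffolding, not physics.

`run_scheme` and `run_comparison` are the real experiments: coupled
flushing plus pull-back scan for one injection scheme, and the
continuous-vs-intermittent comparison with dosage- and quality-reduction
percentages.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import Config
from .flush import FlushResult, solve_flushing
from .imaging import stack_longitudinal, write_image
from .optics import ALine, medium_profile, propagate
from .scan import (
    FrameQualitySeries,
    NoTriggerError,
    ScanSummary,
    run_scan,
    scan_summary,
)
from .schedules import InjectionScheme, blood_inflow_waveform, default_schemes

__all__ = [
    "SyntheticHaematocritField",
    "make_fixture",
    "SchemeRun",
    "ComparisonReport",
    "run_scheme",
    "run_comparison",
    "scan_alines",
]


@dataclass(frozen=True)
class SyntheticHaematocritField:
    """Closed-form haematocrit field ``X_e(r, z, t)`` (deterministic, seedless)."""

    kind: str
    fn: Callable[[np.ndarray, float, float], np.ndarray]

    def haematocrit(self, r, z: float, t: float):
        r = np.asarray(r, dtype=float)
        return np.clip(self.fn(r, float(z), float(t)), 0.0, 0.45)


def make_fixture(kind: str, **params) -> SyntheticHaematocritField:
    """Build a synthetic haematocrit field.

    Kinds:

    * ``uniform(value)`` — constant haematocrit everywhere.
    * ``axial_front(amplitude, z0_mm, speed_mm_s, width_mm)`` — blood ahead
      of a smooth front at ``z0 + speed t``, saline behind it (the advancing
      flush front).
    * ``cyclic_slugs(amplitude, duty, period_s, wavelength_mm)`` — periodic
      erythrocyte slugs sweeping through an otherwise clear lumen (the
      cyclic re-contamination each cardiac systole brings).
    """
    if kind == "uniform":
        value = float(params.pop("value", 0.0))
        if params:
            raise ValueError(f"unknown parameters {sorted(params)} for 'uniform'")
        if not 0.0 <= value <= 0.45:
            raise ValueError("uniform haematocrit must lie in [0, 0.45]")
        return SyntheticHaematocritField(
            "uniform", lambda r, z, t: np.full_like(r, value)
        )
    if kind == "axial_front":
        amplitude = float(params.pop("amplitude", 0.45))
        z0 = float(params.pop("z0_mm", 0.0))
        speed = float(params.pop("speed_mm_s", 20.0))
        width = float(params.pop("width_mm", 2.0))
        if params:
            raise ValueError(f"unknown parameters {sorted(params)} for 'axial_front'")

        def front(r, z, t):
            zf = z0 + speed * t
            return amplitude / (1.0 + np.exp(-(z - zf) / width)) * np.ones_like(r)

        return SyntheticHaematocritField("axial_front", front)
    if kind == "cyclic_slugs":
        amplitude = float(params.pop("amplitude", 0.15))
        duty = float(params.pop("duty", 0.5))
        period = float(params.pop("period_s", 0.8))
        wavelength = float(params.pop("wavelength_mm", 8.0))
        if params:
            raise ValueError(f"unknown parameters {sorted(params)} for 'cyclic_slugs'")
        if not 0.0 < duty < 1.0:
            raise ValueError("duty must lie in (0, 1)")

        def slugs(r, z, t):
            phase = np.mod(t / period + z / wavelength, 1.0)
            return np.where(phase < duty, amplitude, 0.0) * np.ones_like(r)

        return SyntheticHaematocritField("cyclic_slugs", slugs)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ----------------------------------------------------------------------
# coupled experiments
# ----------------------------------------------------------------------


@dataclass
class SchemeRun:
    """One coupled flushing + pull-back experiment for a single scheme."""

    scheme: InjectionScheme
    summary: ScanSummary
    series: FrameQualitySeries
    flush: FlushResult
    trigger_time: float


@dataclass
class ComparisonReport:
    """Continuous vs. intermittent injection, with reduction percentages."""

    continuous: ScanSummary
    intermittent: ScanSummary
    dosage_reduction_pct: float
    quality_reduction_pct: float
    cil_reduction_mm: float

    def to_dict(self) -> dict:
        return {
            "continuous": self.continuous.to_dict(),
            "intermittent": self.intermittent.to_dict(),
            "dosage_reduction_pct": self.dosage_reduction_pct,
            "quality_reduction_pct": self.quality_reduction_pct,
            "cil_reduction_mm": self.cil_reduction_mm,
        }


def comparison_report(
    continuous: ScanSummary, intermittent: ScanSummary
) -> ComparisonReport:
    """Reduction percentages for a continuous/intermittent summary pair."""
    return ComparisonReport(
        continuous=continuous,
        intermittent=intermittent,
        dosage_reduction_pct=(
            100.0 * (continuous.dosage_ml - intermittent.dosage_ml) / continuous.dosage_ml
            if continuous.dosage_ml > 0
            else 0.0
        ),
        quality_reduction_pct=(
            100.0 * (continuous.gamma - intermittent.gamma) / continuous.gamma
            if continuous.gamma > 0
            else 0.0
        ),
        cil_reduction_mm=continuous.cil_mm - intermittent.cil_mm,
    )


class _SolverField:
    """Adapter: live solver state as a HaematocritField."""

    def __init__(self, solver):
        self._solver = solver

    def haematocrit(self, r, z, t):
        return self._solver.haematocrit_column(r, z)


def run_scheme(
    config: Config,
    scheme: InjectionScheme,
    fidelity: str | None = None,
    nr: int | None = None,
    nz: int | None = None,
) -> SchemeRun:
    """Run flushing for one injection scheme, trigger and execute the scan.

    The pull-back starts automatically at the first frame whose ``M_w`` at
    the lens start position reaches the CIF threshold; the simulation is
    stopped once the scan horizon is covered.
    """
    from .scan import frame_mw  # local import to avoid cycle at module load

    protocol = config.scan
    geometry = config.geometry
    blood = blood_inflow_waveform(
        peak_rate=config.schedules.blood_peak_rate,
        period=config.clock.cycle_period,
        constants=config.constants,
    )
    state = {"trigger": None, "max_mw": -np.inf}

    def monitor(t, solver):
        if t < scheme.start_time - 1e-9 or state["trigger"] is not None:
            return None
        mw = frame_mw(_SolverField(solver), protocol.lens_start_z, geometry, t=t)
        state["max_mw"] = max(state["max_mw"], mw)
        if mw >= protocol.cif_threshold:
            state["trigger"] = t
            return t + protocol.scan_duration + 0.5 * config.clock.frame_dt
        return None

    result = solve_flushing(
        config,
        blood_waveform=blood,
        injection_waveform=scheme.waveform,
        fidelity=fidelity,
        nr=nr,
        nz=nz,
        monitor=monitor,
    )
    if state["trigger"] is None:
        raise NoTriggerError(protocol.cif_threshold, float(state["max_mw"]))
    trigger = float(state["trigger"])
    if trigger + protocol.scan_duration > result.times[-1] + 1e-9:
        raise RuntimeError(
            f"flushing horizon {result.times[-1]:.2f} s ends before the scan "
            f"triggered at {trigger:.2f} s completes "
            f"({protocol.scan_duration} s pull-back)"
        )
    series = run_scan(result, protocol, geometry, start_time=trigger)
    summary = scan_summary(
        series,
        scheme.waveform,
        horizon=config.clock.total_time,
        protocol=protocol,
        scheme=scheme.label or scheme.kind,
        trigger_time=trigger,
    )
    return SchemeRun(
        scheme=scheme, summary=summary, series=series, flush=result, trigger_time=trigger
    )


def scan_alines(
    run: SchemeRun, config: Config, dr_mm: float = 0.005
) -> list[ALine]:
    """Re-render the A-line of every scan frame (for imaging output)."""
    alines = []
    for z, t in zip(run.series.lens_z, run.series.times):
        profile = medium_profile(
            config.geometry,
            lumen_haematocrit=lambda r: run.flush.haematocrit(r, z, t),
            dr_mm=dr_mm,
        )
        alines.append(
            propagate(profile, wall_radius_mm=config.geometry.vessel_inner_radius)
        )
    return alines


def run_comparison(
    config: Config,
    fidelity: str | None = None,
    nr: int | None = None,
    nz: int | None = None,
    out_dir: str | None = None,
) -> ComparisonReport:
    """Continuous vs. intermittent injection at identical peak rate.

    Runs the coupled flushing + scan pipeline for both default schemes and
    reports dosage and image-quality reductions.  With ``out_dir`` set,
    writes a JSON report, per-scheme frame CSVs and longitudinal PNGs.
    """
    schemes = default_schemes(config)
    runs: dict[str, SchemeRun] = {}
    for name in ("continuous", "intermittent"):
        runs[name] = run_scheme(config, schemes[name], fidelity=fidelity, nr=nr, nz=nz)
    report = comparison_report(
        runs["continuous"].summary, runs["intermittent"].summary
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "comparison.json"), "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        for name, run in runs.items():
            run.series.to_csv(os.path.join(out_dir, f"{name}_frames.csv"))
            alines = scan_alines(run, config)
            image = stack_longitudinal(alines, lens_z_mm=run.series.lens_z)
            write_image(image, os.path.join(out_dir, f"{name}_longitudinal.png"))
    return report
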