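"""Pull-back scan kinematics, CIF trigger and quality indicators.

During a scan the lens retracts at constant speed (20 mm/s for 2.5 s at
defaults, i.e. a 50 mm pull-back with 251 frames spaced 0.2 mm).  For each
frame the residual irradiance ratio at the vessel inner wall, ``M_w``, is
obtained by propagating the beam through the local haematocrit column; a
frame with ``M_w`` at or above the clear-image-frame (CIF) threshold 0.75
counts toward the clear imaging length (CIL).  Overall quality is

    gamma = f1 * mean(M_w) + f2 * (1 - sigma / 0.25),

where ``sigma`` is the population variance of the per-frame ``M_w`` (0.25 is
the largest variance any [0, 1]-valued series can attain, so ``gamma`` stays
in [0, 1] whenever ``f1 + f2 = 1``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

from .config import GeometryConfig, ScanProtocolConfig
from .optics import medium_profile, propagate
from .schedules import FlowWaveform, dosage

__all__ = [
    "HaematocritField",
    "ScanProtocolConfig",
    "FrameQualitySeries",
    "ScanSummary",
    "NoTriggerError",
    "frame_mw",
    "pullback_trigger",
    "run_scan",
    "cil",
    "gamma",
    "scan_summary",
]


class HaematocritField(Protocol):
    """Anything that can report local haematocrit at ``(r mm, z mm, t s)``."""

    def haematocrit(self, r: np.ndarray, z: float, t: float) -> np.ndarray: ...


class NoTriggerError(RuntimeError):
    """The CIF threshold was never reached within the horizon."""

    def __init__(self, threshold: float, max_mw: float):
        super().__init__(
            f"M_w never reached the CIF threshold {threshold}; "
            f"maximum observed M_w = {max_mw:.4f}"
        )
        self.threshold = threshold
        self.max_mw = max_mw


@dataclass
class FrameQualitySeries:
    """Per-frame scan record: times, lens positions, M_w and CIF flags."""

    times: np.ndarray  # s
    lens_z: np.ndarray  # mm
    mw: np.ndarray
    cif: np.ndarray  # bool
    frame_spacing: float  # mm
    pullback_length: float  # mm

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "lens_z_mm": self.lens_z,
                "M_w": self.mw,
                "cif": self.cif,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ScanSummary:
    """Scan-level indicators: quality gamma, CIL and saline dosage."""

    scheme: str
    mean_mw: float
    variance: float
    gamma: float
    cil_mm: float
    dosage_ml: float
    n_frames: int
    trigger_time_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "mean_mw": self.mean_mw,
            "variance": self.variance,
            "gamma": self.gamma,
            "cil_mm": self.cil_mm,
            "dosage_ml": self.dosage_ml,
            "n_frames": self.n_frames,
            "trigger_time_s": self.trigger_time_s,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def frame_mw(
    field: HaematocritField,
    lens_z: float,
    geometry: GeometryConfig,
    t: float = 0.0,
    dr_mm: float = 0.005,
) -> float:
    """Residual irradiance ratio at the vessel inner wall for one frame.

    Builds the radial medium stack at ``z = lens_z`` from the local
    haematocrit column and propagates the beam through it.
    """
    if not geometry.blood_inlet_z <= lens_z <= geometry.domain_z_max:
        raise ValueError(
            f"lens position z = {lens_z} mm outside the domain "
            f"[{geometry.blood_inlet_z}, {geometry.domain_z_max}] mm"
        )
    profile = medium_profile(
        geometry,
        lumen_haematocrit=lambda r: field.haematocrit(r, lens_z, t),
        dr_mm=dr_mm,
    )
    aline = propagate(profile, wall_radius_mm=geometry.vessel_inner_radius)
    return aline.M_w


def pullback_trigger(
    times: np.ndarray, mw_values: np.ndarray, threshold: float
) -> float:
    """First sample time at which ``M_w`` reaches the CIF threshold.

    The pull-back then proceeds for the full scan duration regardless of
    later dips below the threshold.  Raises :class:`NoTriggerError` when the
    threshold is never reached.
    """
    times = np.asarray(times, float)
    mw_values = np.asarray(mw_values, float)
    hits = np.nonzero(mw_values >= threshold)[0]
    if hits.size == 0:
        raise NoTriggerError(threshold, float(mw_values.max(initial=-np.inf)))
    return float(times[hits[0]])


def run_scan(
    field: HaematocritField,
    protocol: ScanProtocolConfig,
    geometry: GeometryConfig,
    start_time: float = 0.0,
) -> FrameQualitySeries:
    """Execute one pull-back: lens moves toward -z, one frame per frame_dt."""
    protocol.validate()
    n = protocol.n_frames
    times = start_time + protocol.frame_dt * np.arange(n)
    lens_z = protocol.lens_start_z - protocol.pullback_speed * (times - start_time)
    mw = np.array(
        [frame_mw(field, z, geometry, t=t) for z, t in zip(lens_z, times)]
    )
    cif_flags = mw >= protocol.cif_threshold
    return FrameQualitySeries(
        times=times,
        lens_z=lens_z,
        mw=mw,
        cif=cif_flags,
        frame_spacing=protocol.frame_spacing,
        pullback_length=protocol.pullback_length,
    )


def cil(series: FrameQualitySeries, spacing: float | None = None) -> float:
    """Clear imaging length: CIF-frame count times frame spacing (mm).

    Non-contiguous clear segments all count (the length is cumulative); an
    all-clear scan is capped at the pull-back length.
    """
    d = series.frame_spacing if spacing is None else spacing
    return float(min(series.cif.sum() * d, series.pullback_length))


def gamma(
    series: FrameQualitySeries, f1: float = 0.7, f2: float = 0.3
) -> tuple[float, float, float]:
    """Composite quality indicator; returns ``(gamma, mean_mw, variance)``.

    The consistency term normalises the population variance by 0.25, its
    maximum for [0, 1]-valued data.
    """
    if abs(f1 + f2 - 1.0) > 1e-12:
        raise ValueError("weights must satisfy f1 + f2 = 1")
    if series.n_frames < 1:
        raise ValueError("empty frame series")
    mean_mw = float(np.mean(series.mw))
    variance = float(np.mean((series.mw - mean_mw) ** 2))
    g = f1 * mean_mw + f2 * (1.0 - variance / 0.25)
    return g, mean_mw, variance


def scan_summary(
    series: FrameQualitySeries,
    waveform: FlowWaveform | None,
    horizon: float,
    protocol: ScanProtocolConfig,
    scheme: str = "custom",
    trigger_time: float | None = None,
) -> ScanSummary:
    """Bundle gamma, CIL and saline dosage for one completed scan."""
    g, mean_mw, variance = gamma(series, protocol.f1, protocol.f2)
    volume = dosage(waveform, horizon) if waveform is not None else 0.0
    return ScanSummary(
        scheme=scheme,
        mean_mw=mean_mw,
        variance=variance,
        gamma=g,
        cil_mm=cil(series),
        dosage_ml=volume,
        n_frames=series.n_frames,
        trigger_time_s=trigger_time,
    )
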