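"""Lambert-Beer optical forward model: A-lines from a radial medium stack.

A collimated 1300 nm NIR beam leaves the OCT catheter's outer wall and
travels radially outward through the lumen (a blood/saline mixture), the
three-layer vessel wall and the extramural tissue.  The residual irradiance
follows Lambert-Beer attenuation with a position-dependent total attenuation
coefficient; the detected signal is the local backscatter of the round-trip
attenuated beam,

    E(r) = E0 exp(-int_0^r phi_t dx),      M(r) = E(r)/E0,
    I(r) = beta * phi_b(r) * E0 * exp(-2 int_0^r phi_t dx),

with ``phi_b = alpha * phi_t`` for fluids and tabulated values for solid
tissues.  Grayscale output normalises I by the whole-blood near-source
signal ``I_max = alpha beta E0 phi_t(X_e = 45%)``.

Lumen coefficients are haematocrit-dependent; solid-tissue coefficients are
fixed per layer.  Speckle, coherence gating and multiple scattering are out
of scope: the model is irradiance-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import GeometryConfig, radial_media_stack

__all__ = [
    "OpticalCoefficients",
    "MediumProfile",
    "ALine",
    "fluid_coefficients",
    "tissue_coefficients",
    "medium_profile",
    "propagate",
    "i_max",
    "grayscale",
    "WHOLE_BLOOD_HAEMATOCRIT",
]

WHOLE_BLOOD_HAEMATOCRIT = 0.45
# Reference whole-blood coefficients for the 1300 nm beam (per mm)
PHI_A_WHOLE_BLOOD = 0.19
PHI_S_WHOLE_BLOOD = 45.36
ANISOTROPY_BLOOD = 0.9779

# Solid-tissue coefficients (per mm): total attenuation and backscatter.
# Tissues tabulate phi_b directly; no alpha/delta decomposition is applied.
TISSUE_TABLE: dict[str, tuple[float, float]] = {
    "intima": (0.67, 0.73),
    "media": (0.48, 0.69),
    "adventitia": (0.53, 0.68),
    "extramural": (0.50, 0.50),
}

DEFAULT_RADIAL_STEP_MM = 0.005  # 5 um, below typical OCT axial resolution


@dataclass(frozen=True)
class OpticalCoefficients:
    """Absorption, scattering, anisotropy and derived coefficients (per mm)."""

    phi_a: float
    phi_s: float
    delta: float
    phi_t: float
    phi_b: float
    alpha: float = 1.0
    beta: float = 1.0


def fluid_coefficients(haematocrit, alpha: float = 1.0, beta: float = 1.0):
    """Haematocrit-dependent lumen coefficients.

    Absorption scales linearly with haematocrit; scattering carries an extra
    ``(1 - X_e)`` shielding factor so it vanishes both in pure saline and in
    a hypothetical pure-erythrocyte packing:

        phi_a = (X_e / 0.45) * 0.19
        phi_s = ((1 - X_e) / 0.55) * (X_e / 0.45) * 45.36
        phi_t = phi_a + phi_s * (1 - delta),  delta = 0.9779.

    Returns an :class:`OpticalCoefficients` for scalar input, or a tuple of
    arrays ``(phi_t, phi_b)`` for array input.
    """
    X = np.asarray(haematocrit, dtype=float)
    if np.any(X < 0) or np.any(X > 1):
        raise ValueError("haematocrit must lie in [0, 1]")
    phi_a = X / WHOLE_BLOOD_HAEMATOCRIT * PHI_A_WHOLE_BLOOD
    phi_s = (
        (1.0 - X)
        / (1.0 - WHOLE_BLOOD_HAEMATOCRIT)
        * (X / WHOLE_BLOOD_HAEMATOCRIT)
        * PHI_S_WHOLE_BLOOD
    )
    phi_t = phi_a + phi_s * (1.0 - ANISOTROPY_BLOOD)
    phi_b = alpha * phi_t
    if np.isscalar(haematocrit):
        return OpticalCoefficients(
            phi_a=float(phi_a),
            phi_s=float(phi_s),
            delta=ANISOTROPY_BLOOD,
            phi_t=float(phi_t),
            phi_b=float(phi_b),
            alpha=alpha,
            beta=beta,
        )
    return phi_t, phi_b


def tissue_coefficients(layer: str) -> OpticalCoefficients:
    """Tabulated coefficients of a solid-tissue layer."""
    try:
        phi_t, phi_b = TISSUE_TABLE[layer]
    except KeyError:
        raise KeyError(
            f"unknown tissue layer {layer!r}; expected one of {sorted(TISSUE_TABLE)}"
        ) from None
    return OpticalCoefficients(
        phi_a=np.nan, phi_s=np.nan, delta=np.nan, phi_t=phi_t, phi_b=phi_b
    )


@dataclass(frozen=True)
class MediumProfile:
    """Radial optical stack sampled on a fine grid (mm from the axis).

    ``labels`` maps each sample to its medium; lumen samples carry the local
    haematocrit and recomputed fluid coefficients, solid-tissue samples the
    tabulated values.
    """

    r: np.ndarray  # mm, ascending, from the OCT catheter wall outward
    phi_t: np.ndarray  # per mm
    phi_b: np.ndarray  # per mm
    labels: np.ndarray  # str per sample
    haematocrit: np.ndarray  # lumen haematocrit (0 outside the lumen)


def medium_profile(
    geometry: GeometryConfig,
    lumen_haematocrit: float | Callable[[np.ndarray], np.ndarray] = 0.0,
    dr_mm: float = DEFAULT_RADIAL_STEP_MM,
) -> MediumProfile:
    """Sample the radial media stack at ``dr_mm`` spacing.

    ``lumen_haematocrit`` is a constant or a function of radius (mm) giving
    the local haematocrit inside the lumen.
    """
    if dr_mm <= 0:
        raise ValueError("dr_mm must be positive")
    r0 = geometry.oct_catheter_radius
    r1 = geometry.extramural_outer_radius
    n = int(round((r1 - r0) / dr_mm)) + 1
    r = np.linspace(r0, r1, n)
    phi_t = np.zeros(n)
    phi_b = np.zeros(n)
    labels = np.empty(n, dtype=object)
    X = np.zeros(n)
    # a sample on a material interface takes the inner medium's coefficients,
    # so a homogeneous lumen attenuates by exactly exp(-phi_t * path)
    for label, (lo, hi) in radial_media_stack(geometry):
        sel = (r > lo + 1e-12) & (r <= hi + 1e-12)
        if label == "lumen":
            sel[0] = True
        if label == "lumen":
            if callable(lumen_haematocrit):
                X_loc = np.asarray(lumen_haematocrit(r[sel]), dtype=float)
            else:
                X_loc = np.full(sel.sum(), float(lumen_haematocrit))
            X_loc = np.clip(X_loc, 0.0, 1.0)
            ft, fb = fluid_coefficients(X_loc)
            phi_t[sel], phi_b[sel], X[sel] = ft, fb, X_loc
        else:
            coef = tissue_coefficients(label)
            phi_t[sel], phi_b[sel] = coef.phi_t, coef.phi_b
        labels[sel] = label
    # close the last half-open interval at the outer boundary
    labels[-1] = "extramural"
    phi_t[-1], phi_b[-1] = TISSUE_TABLE["extramural"]
    return MediumProfile(r=r, phi_t=phi_t, phi_b=phi_b, labels=labels, haematocrit=X)


@dataclass(frozen=True)
class ALine:
    """One radial OCT depth profile and its derived quantities."""

    r: np.ndarray  # mm
    E: np.ndarray  # residual irradiance, W/m^2
    M: np.ndarray  # residual irradiance ratio E/E0
    I: np.ndarray  # backscattered irradiance density, W/(m^2 mm)
    G: np.ndarray  # grayscale 0..255
    M_w: float  # residual ratio at the vessel inner wall
    I_max: float
    E0: float


def i_max(E0: float = 1.0, alpha: float = 1.0, beta: float = 1.0) -> float:
    """Normalisation constant: near-source signal in a whole-blood lumen."""
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    phi_t_wb = fluid_coefficients(WHOLE_BLOOD_HAEMATOCRIT).phi_t
    return alpha * beta * E0 * phi_t_wb


def grayscale(I: np.ndarray, I_max_value: float) -> np.ndarray:
    """Map signal to 8-bit grayscale, clipped, rounded half-to-even."""
    if I_max_value <= 0:
        raise ValueError("I_max must be positive")
    g = np.clip(255.0 * np.asarray(I, dtype=float) / I_max_value, 0.0, 255.0)
    return np.rint(g).astype(np.uint8)


def propagate(
    profile: MediumProfile,
    E0: float = 1.0,
    wall_radius_mm: float | None = None,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> ALine:
    """Propagate the beam through a radial profile and form the A-line.

    Cumulative optical depth is accumulated by trapezoidal integration from
    the source at ``profile.r[0]``; the signal uses the round-trip exponent.
    ``M_w`` is the single-pass residual ratio at ``wall_radius_mm``
    (default: 2.0 mm, the vessel inner wall of the base geometry).
    """
    if E0 <= 0:
        raise ValueError("E0 must be positive")
    r = profile.r
    if r.ndim != 1 or r.size < 2 or np.any(np.diff(r) <= 0):
        raise ValueError("radial grid must be 1-D and strictly increasing")
    dr = np.diff(r)
    tau = np.concatenate(
        [[0.0], np.cumsum(0.5 * (profile.phi_t[1:] + profile.phi_t[:-1]) * dr)]
    )
    M = np.exp(-tau)
    E = E0 * M
    I = beta * profile.phi_b * E0 * np.exp(-2.0 * tau)
    Imax = i_max(E0, alpha=alpha, beta=beta)
    G = grayscale(I, Imax)
    rw = 2.0 if wall_radius_mm is None else wall_radius_mm
    M_w = float(np.interp(rw, r, M))
    return ALine(r=r, E=E, M=M, I=I, G=G, M_w=M_w, I_max=Imax, E0=E0)
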