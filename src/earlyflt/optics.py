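"""Optical domain types and the closed-form fluorescence parameter
distribution function (FPDF).

The FPDF is the intermediate quantity reconstructed linearly by early-photon
time-domain fluorescence lifetime tomography before the fluorophore
absorption coefficient and lifetime are separated:

    f(r) = 4 D c γ μ_af(r) / (v² τ(r) + 4 D c)

where D is the photon diffusion coefficient of the background medium, c the
light speed in the medium, γ the fluorescence quantum yield, μ_af the
fluorophore absorption coefficient, τ the fluorescence lifetime and v the
average photon migration velocity |r_d − r_s| / t implied by a
source–detector distance and a time gate.

Unit system, fixed package-wide: lengths in mm, times in ps, rates in mm⁻¹,
velocities in mm/ps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Vacuum light speed in mm/ps.
C_VACUUM_MM_PS = 0.299792458


class InvalidMediumError(ValueError):
    """Optical medium parameters are physically inadmissible."""


class DomainError(ValueError):
    """Operation called outside its domain of validity."""


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous background optical properties.

    Parameters
    ----------
    mua : float
        Absorption coefficient (mm⁻¹), ``>= 0``.
    mus : float
        Scattering coefficient (mm⁻¹), ``> 0``.
    g : float
        Scattering anisotropy factor (mean cosine of the single-scattering
        deflection angle), ``0 <= g < 1``.
    n : float
        Refractive index, ``>= 1``.
    """

    mua: float
    mus: float
    g: float = 0.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not (self.mua >= 0.0):
            raise InvalidMediumError(f"mua must be >= 0, got {self.mua}")
        if not (self.mus > 0.0):
            raise InvalidMediumError(f"mus must be > 0, got {self.mus}")
        if not (0.0 <= self.g < 1.0):
            raise InvalidMediumError(f"g must be in [0, 1), got {self.g}")
        if not (self.n >= 1.0):
            raise InvalidMediumError(f"n must be >= 1, got {self.n}")
        if not (self.mus_reduced > 0.0):
            raise InvalidMediumError("reduced scattering mus*(1-g) must be > 0")

    @property
    def mus_reduced(self) -> float:
        """Reduced scattering coefficient μs′ = μs (1 − g), mm⁻¹."""
        return self.mus * (1.0 - self.g)


@dataclass(frozen=True)
class FluorophoreProps:
    """Fluorophore parameters: absorption μ_af (mm⁻¹), quantum yield γ
    (dimensionless, in [0, 1]) and lifetime τ (ps)."""

    muaf: float
    gamma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.muaf >= 0.0):
            raise DomainError(f"muaf must be >= 0, got {self.muaf}")
        if not (0.0 <= self.gamma <= 1.0):
            raise DomainError(f"gamma must be in [0, 1], got {self.gamma}")
        if not (self.tau >= 0.0):
            raise DomainError(f"tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class VelocitySet:
    """Average photon migration velocities (mm/ps), one per FPDF
    reconstruction.

    The velocities must be pairwise distinct: parameter separation solves a
    linear system whose rows differ only through v², so duplicate entries
    make it singular.
    """

    v: tuple[float, ...]

    def __post_init__(self) -> None:
        vv = tuple(float(x) for x in self.v)
        object.__setattr__(self, "v", vv)
        if any(x <= 0.0 for x in vv):
            raise DomainError("all velocities must be > 0")
        if len(set(vv)) != len(vv):
            raise DomainError("velocities must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.v)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.v, dtype=float)


def diffusion_coefficient(medium: OpticalMedium) -> float:
    """Photon diffusion coefficient D = 1 / (3 μs (1 − g)) in mm.

    The scattering-only form is used, which is standard in the early-photon
    regime where absorption is weak (μa ≪ μs′); with the default phantom
    parameters the alternative 1/(3(μa + μs′)) differs by less than the
    precision at which FPDF values are quoted.
    """
    denom = 3.0 * medium.mus * (1.0 - medium.g)
    if denom <= 0.0:
        raise InvalidMediumError("degenerate medium: mus*(1-g) = 0")
    return 1.0 / denom


def light_speed(medium: OpticalMedium) -> float:
    """Light speed c = c₀ / n in the medium, mm/ps."""
    if medium.n < 1.0:
        raise InvalidMediumError(f"n must be >= 1, got {medium.n}")
    return C_VACUUM_MM_PS / medium.n


def average_velocity(sr_distance: float, gate: float) -> float:
    """Average photon migration velocity v = R / t (mm/ps) for a
    source–detector distance R (mm) and a time gate t (ps)."""
    if sr_distance <= 0.0:
        raise DomainError(f"sr_distance must be > 0, got {sr_distance}")
    if gate <= 0.0:
        raise DomainError(f"gate must be > 0, got {gate}")
    return sr_distance / gate


def fpdf_value(
    medium: OpticalMedium, fluor: FluorophoreProps, v: float
) -> float:
    """Closed-form FPDF value f = 4Dcγμ_af / (v²τ + 4Dc) in mm⁻¹.

    Monotonically decreasing in v for τ > 0; equals γ μ_af at v = 0 or
    τ = 0, which is its upper bound.
    """
    if v < 0.0:
        raise DomainError(f"velocity must be >= 0, got {v}")
    four_dc = 4.0 * diffusion_coefficient(medium) * light_speed(medium)
    return four_dc * fluor.gamma * fluor.muaf / (v * v * fluor.tau + four_dc)
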