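"""Minimal propagation-based imaging physics: Fresnel forward model and
Paganin single-distance phase retrieval.

A homogeneous object of projected thickness t imprints on a monochromatic
plane wave the amplitude sqrt(I0)·exp(-mu·t/2) and phase phi = -2*pi*delta*t
/lambda, where n = 1 - delta + i*beta is the refractive index and
mu = 4*pi*beta/lambda the linear attenuation coefficient.  Free-space
propagation over a distance z multiplies the angular spectrum by the Fresnel
transfer function exp(-i*pi*lambda*z*|f|^2) (f in cycles per metre), and the
detector records |wave|^2.

Paganin's retrieval inverts this in the near field for a single material:

    t = -(1/mu) * ln( F^-1[ F[I_z/I0] / (1 + (delta*z/mu)*k^2) ] ),

with k = 2*pi*|f| the angular spatial frequency.  At z = 0 the filter is the
identity and retrieval reduces to Beer–Lambert inversion.

Sign conventions for phase and transfer function are a matched pair; the
round-trip property (propagate then retrieve) is what fixes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .volume import VoxelVolume

__all__ = [
    "MaterialModel",
    "ProjectionImage",
    "ThicknessMap",
    "project_thickness",
    "fresnel_propagate",
    "paganin_retrieve",
]

# hc in keV·m: lambda[m] = HC_KEV_M / energy[keV]
HC_KEV_M = 1.2398419843320026e-9


@dataclass(frozen=True)
class MaterialModel:
    """Homogeneous single-material optical model.

    delta and beta are the real and imaginary refractive-index decrements of
    n = 1 - delta + i*beta; wavelength is in metres.  mu = 4*pi*beta/lambda is
    the linear attenuation coefficient (1/m).
    """

    delta: float
    beta: float
    wavelength: float

    def __post_init__(self) -> None:
        if not (self.delta > 0 and self.beta > 0 and self.wavelength > 0):
            raise ValueError("delta, beta and wavelength must all be > 0")

    @classmethod
    def from_energy(cls, delta: float, beta: float, energy_kev: float) -> "MaterialModel":
        return cls(delta=delta, beta=beta, wavelength=HC_KEV_M / energy_kev)

    @property
    def energy_kev(self) -> float:
        return HC_KEV_M / self.wavelength

    @property
    def mu(self) -> float:
        """Linear attenuation coefficient 4*pi*beta/lambda (1/m)."""
        return 4.0 * np.pi * self.beta / self.wavelength

    @property
    def delta_beta_ratio(self) -> float:
        return self.delta / self.beta


@dataclass
class ProjectionImage:
    """Recorded intensity at propagation distance z."""

    intensity: np.ndarray
    pixel_size_um: float
    distance_m: float
    flat_intensity: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("projection must be 2-D")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.distance_m < 0:
            raise ValueError("distance must be >= 0")
        if not self.flat_intensity > 0:
            raise ValueError("flat intensity I0 must be > 0")


@dataclass
class ThicknessMap:
    """Projected object thickness t(y, x) in metres."""

    thickness: np.ndarray
    pixel_size_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.ndim != 2:
            raise ValueError("thickness map must be 2-D")
        if not np.all(np.isfinite(self.thickness)):
            raise ValueError("thickness map contains non-finite values")


def project_thickness(
    volume: VoxelVolume, mask: np.ndarray, axis: int = 0
) -> ThicknessMap:
    """Line-integrate an object-support mask along one axis.

    t = (number of object voxels along the ray) × voxel_size, in metres.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape must match volume shape")
    counts = mask.sum(axis=axis)
    t_m = counts.astype(float) * volume.voxel_size * 1e-6
    return ThicknessMap(t_m, pixel_size_um=volume.voxel_size,
                        meta={"axis": axis, **volume.meta})


def _mirror_pad(a: np.ndarray) -> tuple[np.ndarray, tuple[slice, slice]]:
    ny, nx = a.shape
    padded = np.pad(a, ((0, ny), (0, nx)), mode="symmetric")
    return padded, (slice(0, ny), slice(0, nx))


def _freq_sq(shape: tuple[int, int], pixel_m: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0], d=pixel_m)
    fx = np.fft.fftfreq(shape[1], d=pixel_m)
    return fy[:, None] ** 2 + fx[None, :] ** 2


def check_near_field(pixel_size_um: float, wavelength: float, distance_m: float) -> float:
    """Single-pixel Fresnel number N_F = px^2 / (lambda z); warns below 0.1.

    Paganin's filter assumes near-field propagation; a Fresnel number much
    below 1 at the pixel scale means strong diffraction fringes the
    single-material model cannot describe.
    """
    if distance_m == 0:
        return np.inf
    px = pixel_size_um * 1e-6
    nf = px**2 / (wavelength * distance_m)
    if nf < 0.1:
        warnings.warn(
            f"near-field guard: Fresnel number per pixel {nf:.3g} < 0.1 "
            f"(pixel {pixel_size_um} um, z {distance_m} m); phase retrieval "
            "accuracy degrades outside the near field",
            stacklevel=3,
        )
    return nf


def fresnel_propagate(
    tmap: ThicknessMap,
    material: MaterialModel,
    distance_m: float,
    flat_intensity: float = 1.0,
    pad: bool = True,
) -> ProjectionImage:
    """Forward Fresnel propagation of a homogeneous object's exit wave.

    With ``pad=True`` the wave is mirror-padded to twice the size before the
    FFT filter and cropped afterwards, suppressing wrap-around from
    non-periodic fields; ``pad=False`` keeps periodic boundaries (useful for
    the energy-conservation property, which holds exactly only then).
    """
    check_near_field(tmap.pixel_size_um, material.wavelength, distance_m)
    t = tmap.thickness
    wave = np.sqrt(flat_intensity) * np.exp(
        -material.mu * t / 2.0 - 1j * 2.0 * np.pi * material.delta * t / material.wavelength
    )
    if distance_m > 0:
        if pad:
            wave, crop = _mirror_pad(wave)
        f2 = _freq_sq(wave.shape, tmap.pixel_size_um * 1e-6)
        h = np.exp(-1j * np.pi * material.wavelength * distance_m * f2)
        wave = np.fft.ifft2(np.fft.fft2(wave) * h)
        if pad:
            wave = wave[crop]
    intensity = np.abs(wave) ** 2
    return ProjectionImage(
        intensity=intensity,
        pixel_size_um=tmap.pixel_size_um,
        distance_m=float(distance_m),
        flat_intensity=float(flat_intensity),
        meta=dict(tmap.meta),
    )


def paganin_retrieve(
    projection: ProjectionImage,
    material: MaterialModel,
    eps: float = 1e-12,
    pad: bool = True,
) -> ThicknessMap:
    """Paganin single-distance phase retrieval to projected thickness.

    Nonpositive values entering the logarithm (a violation of the
    single-material near-field model, or noise) are clamped to ``eps`` and the
    clamp count is recorded in the output metadata.
    """
    check_near_field(projection.pixel_size_um, material.wavelength,
                     projection.distance_m)
    contrast = projection.intensity / projection.flat_intensity
    z = projection.distance_m
    if z > 0:
        a = contrast
        if pad:
            a, crop = _mirror_pad(a)
        f2 = _freq_sq(a.shape, projection.pixel_size_um * 1e-6)
        k2 = (2.0 * np.pi) ** 2 * f2
        denom = 1.0 + (material.delta * z / material.mu) * k2
        a = np.fft.ifft2(np.fft.fft2(a) / denom).real
        if pad:
            a = a[crop]
        filtered = a
    else:
        filtered = contrast
    n_clamped = int(np.count_nonzero(filtered <= 0))
    filtered = np.maximum(filtered, eps)
    t = -np.log(filtered) / material.mu
    meta = dict(projection.meta)
    meta["n_clamped"] = n_clamped
    if n_clamped:
        warnings.warn(
            f"paganin_retrieve: clamped {n_clamped} nonpositive pixels before log",
            stacklevel=2,
        )
    return ThicknessMap(t, pixel_size_um=projection.pixel_size_um, meta=meta)
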