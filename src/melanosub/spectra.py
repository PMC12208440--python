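"""Spectral data model and radiometric/colorimetric/alpha-opic transforms.

The unit of all optics here is the :class:`Spd` — a spectral radiance
distribution on a strictly increasing uniform wavelength grid, in
W·sr⁻¹·m⁻²·nm⁻¹.  Receptor excitations are discrete receptor-weighted sums

    E_p = Σ_λ S(λ) · R_p(λ) · Δλ ,      Y = 683 · Σ_λ S(λ) · V(λ) · Δλ

with Y the photopic luminance in cd/m².  Chromaticity uses the CIE 1931 2°
colour-matching functions; CIELAB uses the standard forward transform with a
configurable white point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensitivities import DEFAULT_GRID, SensitivitySet, cmf_xyz, standard_sensitivities

MAX_LUMINOUS_EFFICACY = 683.0  # lm/W at the V(λ) peak

__all__ = [
    "Spd",
    "Excitation",
    "photoreceptor_excitation",
    "xyz_from_spd",
    "xy_from_spd",
    "lab_from_xyz",
    "xyz_from_lab",
    "xy_from_xyz",
    "luminance_from_spd",
    "read_spd_csv",
    "write_spd_csv",
]


class GridError(ValueError):
    """Wavelength grids cannot be reconciled."""


class ChromaticityUndefinedError(ValueError):
    """Chromaticity of a zero spectrum is undefined."""


@dataclass(frozen=True)
class Spd:
    """Spectral power (radiance) distribution on a uniform wavelength grid."""

    wavelengths_nm: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "power", p)
        if lam.ndim != 1 or lam.shape != p.shape:
            raise ValueError("wavelengths and power must be 1-D and equal length")
        if lam.size < 2:
            raise ValueError("need at least two grid points")
        steps = np.diff(lam)
        if np.any(steps <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise GridError("wavelength grid must be uniform")
        if np.any(p < 0):
            raise ValueError("spectral power must be non-negative")
        if not np.all(np.isfinite(p)):
            raise ValueError("spectral power must be finite")

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def resample(self, grid: np.ndarray) -> "Spd":
        """Linear-interpolation resample onto ``grid`` (zero outside support)."""
        grid = np.asarray(grid, dtype=float)
        p = np.interp(grid, self.wavelengths_nm, self.power, left=0.0, right=0.0)
        return Spd(grid, p)

    def scaled(self, k: float) -> "Spd":
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return Spd(self.wavelengths_nm, self.power * k)

    def __add__(self, other: "Spd") -> "Spd":
        if not np.array_equal(self.wavelengths_nm, other.wavelengths_nm):
            raise GridError("cannot add SPDs on different grids")
        return Spd(self.wavelengths_nm, self.power + other.power)

    @classmethod
    def zero(cls, grid: np.ndarray | None = None) -> "Spd":
        g = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        return cls(g, np.zeros_like(g))


@dataclass(frozen=True)
class Excitation:
    """Relative receptor excitations plus absolute luminance Y (cd/m²)."""

    L: float
    M: float
    S: float
    mel: float
    Y: float
    rod: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.M, self.S, self.mel, self.Y])


def photoreceptor_excitation(spd: Spd, sens: SensitivitySet | None = None) -> Excitation:
    """Receptor-weighted integrals of ``spd`` against each sensitivity.

    If the grids differ the SPD is resampled (linear interpolation) onto the
    sensitivity grid first.
    """
    sens = standard_sensitivities() if sens is None else sens
    if not np.array_equal(spd.wavelengths_nm, sens.wavelengths_nm):
        spd = spd.resample(sens.wavelengths_nm)
    d = spd.step_nm
    p = spd.power
    rod = None if sens.rod is None else float(np.sum(p * sens.rod) * d)
    return Excitation(
        L=float(np.sum(p * sens.L) * d),
        M=float(np.sum(p * sens.M) * d),
        S=float(np.sum(p * sens.S) * d),
        mel=float(np.sum(p * sens.mel) * d),
        Y=float(MAX_LUMINOUS_EFFICACY * np.sum(p * sens.V) * d),
        rod=rod,
    )


def xyz_from_spd(spd: Spd) -> np.ndarray:
    """CIE 1931 tristimulus (X, Y, Z); Y on the absolute cd/m² scale."""
    xbar, ybar, zbar = cmf_xyz(spd.wavelengths_nm)
    d = spd.step_nm
    return MAX_LUMINOUS_EFFICACY * d * np.array(
        [np.sum(spd.power * xbar), np.sum(spd.power * ybar), np.sum(spd.power * zbar)]
    )


def xy_from_xyz(xyz: np.ndarray) -> tuple[float, float]:
    s = float(np.sum(xyz))
    if s <= 0:
        raise ChromaticityUndefinedError("chromaticity undefined for zero tristimulus")
    return float(xyz[0] / s), float(xyz[1] / s)


def xy_from_spd(spd: Spd) -> tuple[float, float]:
    """CIE 1931 chromaticity coordinates (x, y) of a non-zero SPD."""
    return xy_from_xyz(xyz_from_spd(spd))


def luminance_from_spd(spd: Spd, sens: SensitivitySet | None = None) -> float:
    """Photopic luminance Y = 683·ΣS(λ)V(λ)Δλ in cd/m²."""
    sens = standard_sensitivities() if sens is None else sens
    if not np.array_equal(spd.wavelengths_nm, sens.wavelengths_nm):
        spd = spd.resample(sens.wavelengths_nm)
    return float(MAX_LUMINOUS_EFFICACY * np.sum(spd.power * sens.V) * spd.step_nm)


_LAB_EPS = (6.0 / 29.0) ** 3


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _LAB_EPS, np.cbrt(t), t / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)


def _lab_finv(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(u > 6.0 / 29.0, u**3, 3 * (6.0 / 29.0) ** 2 * (u - 4.0 / 29.0))


def lab_from_xyz(xyz: np.ndarray, white: np.ndarray) -> tuple[float, float, float]:
    """Standard CIELAB forward transform relative to ``white`` (Xn, Yn, Zn)."""
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError("white point components must be positive")
    fx, fy, fz = _lab_f(np.asarray(xyz, dtype=float) / white)
    return float(116 * fy - 16), float(500 * (fx - fy)), float(200 * (fy - fz))


def xyz_from_lab(lab: tuple[float, float, float], white: np.ndarray) -> np.ndarray:
    """Inverse CIELAB transform (exact inverse of :func:`lab_from_xyz`)."""
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError("white point components must be positive")
    Lstar, astar, bstar = lab
    fy = (Lstar + 16) / 116.0
    fx = fy + astar / 500.0
    fz = fy - bstar / 200.0
    return white * _lab_finv(np.array([fx, fy, fz]))


def read_spd_csv(path) -> Spd:
    """Read a two-column ``wavelength_nm,power`` CSV (``#`` comments allowed)."""
    lam, power = [], []
    with open(path) as fh:
        header = None
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header != ["wavelength_nm", "power"]:
                    raise ValueError(f"bad SPD header: {header!r}")
                continue
            a, b = line.split(",")
            lam.append(float(a))
            power.append(float(b))
    return Spd(np.array(lam), np.array(power))


def write_spd_csv(path, spd: Spd) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm,power\n")
        for lam, p in zip(spd.wavelengths_nm, spd.power):
            fh.write(f"{lam:.1f},{float(p)!r}\n")
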