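"""Analytic photoreceptor sensitivity and colour-matching functions.

All spectral weighting functions used by the package are generated on a
uniform wavelength grid from closed-form components:

* Colour-matching functions x̄, ȳ, z̄ — the multi-lobe piecewise-Gaussian
  fits of Wyman, Sloan & Shirley (2013) to the CIE 1931 2° CMFs, clipped to
  be non-negative and renormalised so the three integrals are equal (an
  equal-energy spectrum maps to xy = (1/3, 1/3) exactly) and the ȳ peak is
  exactly 1 (so ȳ ≡ V(λ) and one luminance scale is shared everywhere).
* Cone fundamentals L, M, S — a fixed invertible linear transform of the
  CMFs (the Hunt–Pointer–Estévez matrix, with its negative entries shrunk
  just enough that each fundamental stays non-negative on the grid, then
  peak-normalised).  Because the transform is exact and invertible, two
  spectra with equal tristimulus values have *exactly* equal cone
  excitations — the algebraic backbone of the silent-substitution solver.
  This mirrors the classical Smith–Pokorny construction of fundamentals as
  CMF combinations.
* Melanopic (ipRGC) and rhodopic (rod) sensitivities — the Govardovskii
  et al. (2000) A1 opsin alpha-band template at the retinal pigment peak,
  multiplied by an analytic lens-transmission model (no macular pigment:
  ipRGCs and rods sit outside the fovea), converted to energy units and
  peak-normalised.  The melanopic curve peaks near 490 nm at the cornea.

These are analytic stand-ins for the tabulated standards — smooth,
non-negative, peak-normalised and accurate to a few percent, which is the
appropriate fidelity for a pipeline whose primaries are themselves
synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_GRID = np.arange(380.0, 781.0, 1.0)

#: Retinal photopigment peak wavelengths (nm) for the template receptors;
#: the corneal peaks emerge after lens screening (melanopsin ≈ 490 nm).
PEAK_NM = {"mel": 480.0, "rod": 496.3}

#: Hunt–Pointer–Estévez XYZ→LMS rows (before the non-negativity shrink).
_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22951, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)


def _lobe(lam: np.ndarray, mu: float, t1: float, t2: float) -> np.ndarray:
    """Piecewise Gaussian with separate left/right widths (Wyman et al.)."""
    t = np.where(lam < mu, t1, t2)
    return np.exp(-0.5 * (t * (lam - mu)) ** 2)


_CMF_SCALE: np.ndarray | None = None


def cmf_xyz(grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Colour-matching functions (x̄, ȳ, z̄) on ``grid`` (default 380–780/1).

    The normalisation constants are fixed once on the default grid, so the
    functions are identical regardless of the grid they are sampled on.
    """
    global _CMF_SCALE
    if _CMF_SCALE is None:
        raw = _raw_cmfs(DEFAULT_GRID)
        ypk = raw[1].max()
        sy = raw[1].sum()
        _CMF_SCALE = np.array([sy / raw[0].sum(), 1.0, sy / raw[2].sum()]) / ypk
    lam = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    xbar, ybar, zbar = _raw_cmfs(lam) * _CMF_SCALE[:, None]
    return xbar, ybar, zbar


def _raw_cmfs(lam: np.ndarray) -> np.ndarray:
    xbar = (
        0.362 * _lobe(lam, 442.0, 0.0624, 0.0374)
        + 1.056 * _lobe(lam, 599.8, 0.0264, 0.0323)
        - 0.065 * _lobe(lam, 501.1, 0.0490, 0.0382)
    )
    ybar = 0.821 * _lobe(lam, 568.8, 0.0213, 0.0247) + 0.286 * _lobe(
        lam, 530.9, 0.0613, 0.0322
    )
    zbar = 1.217 * _lobe(lam, 437.0, 0.0845, 0.0278) + 0.681 * _lobe(
        lam, 459.0, 0.0385, 0.0725
    )
    return np.stack([np.clip(xbar, 0.0, None), ybar, np.clip(zbar, 0.0, None)])


_LMS_MATRIX: np.ndarray | None = None


def lms_matrix() -> np.ndarray:
    """XYZ→LMS transform, adjusted for grid-wide non-negativity.

    Each negative HPE entry is shrunk (binary search) to the largest
    magnitude that keeps the corresponding fundamental non-negative on the
    default grid; rows are then scaled so each fundamental peaks at 1.
    """
    global _LMS_MATRIX
    if _LMS_MATRIX is None:
        cmf = np.stack(cmf_xyz(DEFAULT_GRID))
        m = _HPE.copy()
        for i in range(3):
            row = m[i]
            (neg,) = np.nonzero(row < 0)
            for j in neg:
                lo, hi = 0.0, -row[j]

                def ok(mag: float) -> bool:
                    r = row.copy()
                    r[j] = -mag
                    return bool(np.all(r @ cmf >= 0))

                if not ok(hi):
                    for _ in range(60):
                        mid = 0.5 * (lo + hi)
                        lo, hi = (mid, hi) if ok(mid) else (lo, mid)
                    row[j] = -lo
        fund = m @ cmf
        _LMS_MATRIX = m / fund.max(axis=1, keepdims=True)
    return _LMS_MATRIX


def pigment_template(lam_nm: np.ndarray, peak_nm: float) -> np.ndarray:
    """Govardovskii A1 opsin alpha-band absorbance template (quantal), peak ≈ 1.

    ``S(x) = 1 / (exp(A(a−x)) + exp(B(b−x)) + exp(C(c−x)) + D)`` with
    x = λmax/λ and the constants of Govardovskii et al. (2000).
    """
    lam = np.asarray(lam_nm, dtype=float)
    x = peak_nm / lam
    a = 0.8795 + 0.0459 * np.exp(-((peak_nm - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )


def lens_density(lam_nm: np.ndarray) -> np.ndarray:
    """Ocular-media (lens) optical density, exponential short-wave model.

    ``D(λ) = 1.7·exp(−(λ − 400)/32)``: ≈1.7 at 400 nm, ≈0.36 at 450 nm,
    ≈0.10 at 490 nm, negligible beyond 550 nm.  The scale and slope are set
    so the resulting corneal melanopic curve reproduces the standard
    alpha-opic values (melanopic sensitivity ≈ 0.41 at 450 nm relative to
    its ≈ 490 nm peak).
    """
    lam = np.asarray(lam_nm, dtype=float)
    return 1.7 * np.exp(-(lam - 400.0) / 32.0)


_TEMPLATE_NORM: dict[str, float] = {}


def corneal_template(lam: np.ndarray, key: str) -> np.ndarray:
    """Corneal sensitivity for ``key`` (mel/rod): template × lens, energy units.

    Peak-normalised against the default grid so the function is identical
    regardless of the grid it is sampled on.
    """

    def raw(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            pigment_template(x, PEAK_NM[key])
            * 10.0 ** (-lens_density(x))
            * (x / PEAK_NM[key])
        )

    if key not in _TEMPLATE_NORM:
        _TEMPLATE_NORM[key] = float(raw(DEFAULT_GRID).max())
    return raw(lam) / _TEMPLATE_NORM[key]


@dataclass(frozen=True)
class SensitivitySet:
    """L, M, S, melanopic and V(λ) response functions on a common grid.

    Every function is non-negative with global maximum 1 on the default
    grid (peak normalisation enforced at construction).
    """

    wavelengths_nm: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    mel: np.ndarray
    V: np.ndarray
    rod: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("L", "M", "S", "mel", "V"):
            f = getattr(self, name)
            if f.shape != self.wavelengths_nm.shape:
                raise ValueError(f"{name} not on the common grid")
            if np.any(f < 0) or f.max() > 1.0 + 1e-12:
                raise ValueError(f"{name} must be non-negative with peak ≤ 1")

    def as_matrix(self, order: tuple[str, ...] = ("L", "M", "S", "mel", "V")) -> np.ndarray:
        return np.stack([getattr(self, k) for k in order])


def standard_sensitivities(grid: np.ndarray | None = None) -> SensitivitySet:
    """Build the default sensitivity set on ``grid`` (default 380–780/1 nm)."""
    lam = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    cmf = np.stack(cmf_xyz(lam))
    L, M, S = np.clip(lms_matrix() @ cmf, 0.0, None)  # clip float-noise ~1e-20
    return SensitivitySet(
        wavelengths_nm=lam,
        L=L,
        M=M,
        S=S,
        mel=corneal_template(lam, "mel"),
        V=cmf[1],
        rod=corneal_template(lam, "rod"),
    )
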