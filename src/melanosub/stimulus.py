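"""Two-projector primary synthesis and silent-substitution metamer solving.

The rig modelled here superimposes two three-channel projectors on one
diffuser; a displayed light is therefore a non-negative combination of six
primaries.  One projector carries a narrow cyan band near the melanopsin
peak (488 nm bandpass in its blue path), the other is long-pass filtered at
435 nm with a conventional ~450 nm blue, so the two can trade melanopic
excitation against each other while their cone excitations are matched.

A metamer pair is solved as a single linear program over both members'
weights: both members are pinned to the same CIE 1931 tristimulus target
(chromaticity and luminance exact) and to equal L, M, S cone excitations
(silent substitution), and the melanopic difference between members is
maximised.  Feasible weights live in the box [0, 1]⁶ per member (fraction of
each channel's maximum output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, linprog

from .sensitivities import DEFAULT_GRID, SensitivitySet, standard_sensitivities
from .spectra import (
    Excitation,
    Spd,
    lab_from_xyz,
    luminance_from_spd,
    photoreceptor_excitation,
    xy_from_xyz,
    xyz_from_lab,
    xyz_from_spd,
)

PRIMARY_LABELS = ("projA.R", "projA.G", "projA.B", "projB.R", "projB.G", "projB.B")

#: Published channel chromaticities: projector A is the ipRGC-primary
#: (cyan-capable) projector, projector B the S-cone-primary projector.
DEFAULT_CHANNEL_XY = {
    "projA.R": (0.638, 0.357),
    "projA.G": (0.358, 0.613),
    "projA.B": (0.161, 0.065),
    "projB.R": (0.631, 0.366),
    "projB.G": (0.334, 0.613),
    "projB.B": (0.143, 0.138),
}

#: Post-filter maximum channel luminances, cd/m² on the diffuser.  Chosen as
#: typical 3LCD screen-luminance proportions; they only set the feasible box.
DEFAULT_CHANNEL_YMAX = {"R": 600.0, "G": 2000.0, "B": 300.0}

HIGH_LIGHT_XY = (0.412, 0.241)
HIGH_LIGHT_Y = 713.56


class GamutError(ValueError):
    """Requested chromaticity/luminance is outside the rig gamut."""


class ConvergenceError(RuntimeError):
    """A channel fit failed to reach its chromaticity tolerance."""


class UndefinedContrastError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Optical filter transmission model.

    kinds: ``bandpass`` (Gaussian band at ``center_nm`` with ``fwhm_nm``),
    ``notch`` (1 − bandpass), ``longpass`` (sigmoidal cut-on at ``cuton_nm``),
    ``none``.  ``floor`` is the out-of-band transmission fraction.
    """

    kind: str = "none"
    center_nm: float | None = None
    cuton_nm: float | None = None
    fwhm_nm: float | None = None
    floor: float = 0.0

    def transmission(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if self.kind == "none":
            return np.ones_like(lam)
        if self.kind in ("bandpass", "notch"):
            sigma = self.fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            band = np.exp(-0.5 * ((lam - self.center_nm) / sigma) ** 2)
            t = self.floor + (1.0 - self.floor) * band
            return t if self.kind == "bandpass" else 1.0 - (1.0 - self.floor) * band
        if self.kind == "longpass":
            # ~4 nm transition width around the cut-on
            t = 1.0 / (1.0 + np.exp(-(lam - self.cuton_nm) / 1.0))
            return self.floor + (1.0 - self.floor) * t
        raise ValueError(f"unknown filter kind {self.kind!r}")


#: Default optics: 488/10 bandpass in the ipRGC projector's blue path,
#: 435 nm long-pass across the S-cone projector.
DEFAULT_FILTERS = {
    "projA.B": FilterSpec(kind="bandpass", center_nm=488.0, fwhm_nm=10.0),
    "projB.R": FilterSpec(kind="longpass", cuton_nm=435.0),
    "projB.G": FilterSpec(kind="longpass", cuton_nm=435.0),
    "projB.B": FilterSpec(kind="longpass", cuton_nm=435.0),
}


@dataclass(frozen=True)
class PrimarySet:
    """Six channel SPDs at maximum output, with achieved xy and luminance."""

    labels: tuple[str, ...]
    spds: tuple[Spd, ...]
    chromaticities: tuple[tuple[float, float], ...]
    max_luminance: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.spds):
            raise ValueError("labels/spds length mismatch")

    @property
    def grid(self) -> np.ndarray:
        return self.spds[0].wavelengths_nm

    def spd_of_weights(self, w: np.ndarray) -> Spd:
        power = sum(wi * s.power for wi, s in zip(w, self.spds))
        return Spd(self.grid, np.asarray(power))


@dataclass(frozen=True)
class MetamerPair:
    weights_high: np.ndarray
    weights_low: np.ndarray
    excitations_high: Excitation
    excitations_low: Excitation
    mel_contrast_pct: float
    lms_residual: float
    xy_high: tuple[float, float]
    xy_low: tuple[float, float]


@dataclass(frozen=True)
class Candidate:
    cand_id: int
    ring: int
    radius: float
    a_offset: float
    b_offset: float
    x: float
    y: float
    Y: float
    weights: np.ndarray


@dataclass(frozen=True)
class CandidateSet:
    center_ab: tuple[float, float]
    candidates: tuple[Candidate, ...]
    center_xy: tuple[float, float] = HIGH_LIGHT_XY

    def __len__(self) -> int:
        return len(self.candidates)


def michelson_contrast(e_high: float, e_low: float) -> float:
    """Signed Michelson contrast 100·(E₁ − E₂)/(E₁ + E₂), in percent."""
    if e_high < 0 or e_low < 0:
        raise ValueError("excitations must be non-negative")
    if e_high + e_low == 0:
        raise UndefinedContrastError("contrast undefined for two zero excitations")
    return 100.0 * (e_high - e_low) / (e_high + e_low)


# ---------------------------------------------------------------------------
# Synthetic primary construction


def _channel_spd(params: np.ndarray, grid: np.ndarray, filt: FilterSpec) -> np.ndarray:
    """Gaussian emission bands with the channel's filter applied.

    A ``longpass``/``notch`` filter multiplies the emission; a ``bandpass``
    filter models a filtered beam-split path and contributes an *additive*
    line with the filter's own shape, whose relative amplitude is the last
    parameter.  (A purely multiplicative narrow bandpass would confine the
    channel to the line and contradict its published deep-blue chromaticity.)
    """
    c1, s1, c2, s2, frac2, frac_line = params
    band = np.exp(-0.5 * ((grid - c1) / s1) ** 2) + frac2 * np.exp(
        -0.5 * ((grid - c2) / s2) ** 2
    )
    if filt.kind == "bandpass":
        return band + frac_line * filt.transmission(grid)
    return band * filt.transmission(grid)


#: Per-channel fit setup: initial parameter vector for
#: (c1, s1, c2, s2, frac2, frac_line) and the indices left free in the
#: least-squares fit.  Blue channels are fitted with exactly two free
#: parameters against the two chromaticity targets, so the fit is fully
#: determined: the main-band centre plus either the 488 nm line fraction
#: (bandpass channel) or the broadband leak fraction (long-pass channel).
#: Fixed emission widths are typical 3LCD channel bandwidths.
_FIT_SETUP = {
    "R": ((610.0, 22.0, 560.0, 25.0, 0.05, 0.0), (0, 4)),
    "G": ((545.0, 28.0, 500.0, 20.0, 0.05, 0.0), (0, 4)),
    "B:bandpass": ((450.0, 13.0, 600.0, 60.0, 0.01, 0.5), (4, 5)),
    "B": ((455.0, 13.0, 600.0, 60.0, 0.01, 0.0), (0, 4)),
}
_PARAM_BOUNDS = np.array(
    [(385, 775), (3, 120), (385, 775), (3, 120), (0.0, 1.0), (0.0, 5.0)], dtype=float
)


def build_synthetic_primaries(
    channel_xy: dict[str, tuple[float, float]] | None = None,
    channel_ymax: dict[str, float] | None = None,
    filters: dict[str, FilterSpec] | None = None,
    grid: np.ndarray | None = None,
    seed: int = 0,
    xy_tol: float = 0.01,
) -> PrimarySet:
    """Fit Gaussian-band channel spectra to the published chromaticities.

    Each channel is 1–2 Gaussian emission bands multiplied by its filter
    transmission; band centres/widths are least-squares fitted so the
    filtered channel's CIE xy lands on its target, then the amplitude is
    scaled to the channel's maximum luminance.  Channels whose filter
    confines the spectrum to a narrow band (the ipRGC projector's 488 nm
    blue) cannot reach an arbitrary xy target; for those the achieved
    chromaticity is recorded but not enforced.
    """
    channel_xy = dict(DEFAULT_CHANNEL_XY if channel_xy is None else channel_xy)
    channel_ymax = dict(DEFAULT_CHANNEL_YMAX if channel_ymax is None else channel_ymax)
    filters = dict(DEFAULT_FILTERS if filters is None else filters)
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)

    labels, spds, xys, ymaxs = [], [], [], []
    for label in PRIMARY_LABELS:
        target = channel_xy[label]
        color = label.split(".")[1]
        filt = filters.get(label, FilterSpec())

        key = f"{color}:{filt.kind}" if f"{color}:{filt.kind}" in _FIT_SETUP else color
        p_init, free = np.array(_FIT_SETUP[key][0]), list(_FIT_SETUP[key][1])

        def assemble(pfree: np.ndarray, base: np.ndarray) -> np.ndarray:
            p = base.copy()
            p[free] = pfree
            return p

        def resid(pfree: np.ndarray, base: np.ndarray = p_init) -> np.ndarray:
            power = _channel_spd(assemble(pfree, base), grid, filt)
            if power.sum() <= 0 or not np.all(np.isfinite(power)):
                return np.array([10.0, 10.0])
            x, y = xy_from_xyz(xyz_from_spd(Spd(grid, power)))
            return np.array([x - target[0], y - target[1]])

        best, best_cost = None, np.inf
        for attempt in range(8):
            p0 = p_init.copy()
            if attempt:
                jitter = 1.0 + 0.08 * rng.standard_normal(6)
                p0[:4] *= jitter[:4]
                p0[4:] = np.abs(p0[4:] * jitter[4:])
                p0 = np.clip(p0, _PARAM_BOUNDS[:, 0], _PARAM_BOUNDS[:, 1])
            sol = least_squares(
                resid, p0[free], bounds=(_PARAM_BOUNDS[free, 0], _PARAM_BOUNDS[free, 1]),
                xtol=1e-14, ftol=1e-14,
            )
            if sol.cost < best_cost:
                best, best_cost = assemble(sol.x, p_init), sol.cost
            if np.linalg.norm(resid(best[free])) < xy_tol / 10:
                break
        err = float(np.linalg.norm(resid(best[free])))
        if err > xy_tol:
            raise ConvergenceError(
                f"channel {label}: achieved xy misses target {target} by {err:.4f}"
            )
        power = _channel_spd(best, grid, filt)
        spd = Spd(grid, power)
        ymax = channel_ymax[color]
        spd = spd.scaled(ymax / luminance_from_spd(spd))
        labels.append(label)
        spds.append(spd)
        xys.append(xy_from_xyz(xyz_from_spd(spd)))
        ymaxs.append(ymax)
    return PrimarySet(tuple(labels), tuple(spds), tuple(xys), tuple(ymaxs))


# ---------------------------------------------------------------------------
# Metamer solving


def _rig_matrices(
    primaries: PrimarySet, sens: SensitivitySet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-primary XYZ (3×n), LMS (3×n) and melanopic (n,) at max output."""
    xyz = np.stack([xyz_from_spd(s) for s in primaries.spds], axis=1)
    exc = [photoreceptor_excitation(s, sens) for s in primaries.spds]
    lms = np.array([[e.L for e in exc], [e.M for e in exc], [e.S for e in exc]])
    mel = np.array([e.mel for e in exc])
    return xyz, lms, mel


def _target_xyz(target_xy: tuple[float, float], target_Y: float) -> np.ndarray:
    x, y = target_xy
    if y <= 0:
        raise ValueError("target y must be positive")
    return np.array([x / y * target_Y, target_Y, (1 - x - y) / y * target_Y])


def metamer_constraints(
    primaries: PrimarySet,
    target_xy: tuple[float, float],
    target_Y: float,
    sens: SensitivitySet,
    member_mask: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equality system A·[w_high; w_low] = b plus the melanopic row pair.

    Rows: XYZ(high) = target, XYZ(low) = target, LMS(high) − LMS(low) = 0.
    Returns (A_eq, b_eq, mel_objective) with the objective being the
    melanopic difference mel·w_high − mel·w_low.
    """
    xyz, lms, mel = _rig_matrices(primaries, sens)
    n = xyz.shape[1]
    t = _target_xyz(target_xy, target_Y)
    A = np.zeros((9, 2 * n))
    b = np.zeros(9)
    A[0:3, :n] = xyz
    b[0:3] = t
    A[3:6, n:] = xyz
    b[3:6] = t
    A[6:9, :n] = lms
    A[6:9, n:] = -lms
    c = np.concatenate([mel, -mel])
    if member_mask is not None:
        keep = np.concatenate(member_mask).astype(bool)
        A = A[:, keep]
        c = c[keep]
    return A, b, c


def solve_metamer_pair(
    primaries: PrimarySet,
    target_xy: tuple[float, float] = HIGH_LIGHT_XY,
    target_Y: float = HIGH_LIGHT_Y,
    sens: SensitivitySet | None = None,
    assignment: tuple[np.ndarray, np.ndarray] | None = None,
) -> MetamerPair:
    """Solve the maximal-melanopic-contrast silent-substitution pair.

    ``assignment`` optionally restricts which primaries each member may use
    (boolean masks of length n for the high and low member); by default both
    members may use all primaries (the projectors superimpose).
    """
    sens = standard_sensitivities() if sens is None else sens
    n = len(primaries.spds)
    if assignment is None:
        assignment = (np.ones(n, bool), np.ones(n, bool))
    A, b, c = metamer_constraints(primaries, target_xy, target_Y, sens, assignment)
    # row scaling for conditioning
    scale = np.maximum(np.abs(A).max(axis=1), 1e-12)
    res = linprog(-c, A_eq=A / scale[:, None], b_eq=b / scale, bounds=(0.0, 1.0),
                  method="highs")
    if res.status == 2:
        lo, hi = _achievable_luminance(primaries, target_xy, sens)
        raise GamutError(
            f"target xy={target_xy} at Y={target_Y} cd/m² is outside the rig "
            f"gamut; achievable luminance range at that chromaticity is "
            f"[{lo:.1f}, {hi:.1f}] cd/m²"
        )
    if not res.success:
        raise np.linalg.LinAlgError(f"metamer LP failed: {res.message}")
    w = np.zeros(2 * n)
    keep = np.concatenate(assignment).astype(bool)
    w[keep] = res.x
    wh, wl = np.clip(w[:n], 0.0, 1.0), np.clip(w[n:], 0.0, 1.0)
    spd_h, spd_l = primaries.spd_of_weights(wh), primaries.spd_of_weights(wl)
    eh = photoreceptor_excitation(spd_h, sens)
    el = photoreceptor_excitation(spd_l, sens)
    lms_h = np.array([eh.L, eh.M, eh.S])
    lms_l = np.array([el.L, el.M, el.S])
    residual = float(np.max(np.abs(lms_h - lms_l) / np.maximum(np.abs(lms_h), 1e-300)))
    return MetamerPair(
        weights_high=wh,
        weights_low=wl,
        excitations_high=eh,
        excitations_low=el,
        mel_contrast_pct=michelson_contrast(eh.mel, el.mel),
        lms_residual=residual,
        xy_high=xy_from_xyz(xyz_from_spd(spd_h)),
        xy_low=xy_from_xyz(xyz_from_spd(spd_l)),
    )


def _achievable_luminance(
    primaries: PrimarySet, target_xy: tuple[float, float], sens: SensitivitySet
) -> tuple[float, float]:
    """Luminance range reachable at a fixed chromaticity (for error reports)."""
    xyz, _, _ = _rig_matrices(primaries, sens)
    u = _target_xyz(target_xy, 1.0)
    n = xyz.shape[1]
    # maximise s subject to xyz·w = s·u, 0 ≤ w ≤ 1
    A = np.hstack([xyz, -u[:, None]])
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(n + 1)
        c[-1] = sign
        r = linprog(c, A_eq=A, b_eq=np.zeros(3),
                    bounds=[(0.0, 1.0)] * n + [(0.0, None)], method="highs")
        out.append(float(r.x[-1]) if r.success else 0.0)
    return min(out), max(out)


def solve_min_mel_light(
    primaries: PrimarySet,
    target_xy: tuple[float, float],
    target_Y: float,
    sens: SensitivitySet | None = None,
) -> np.ndarray:
    """Weights of the minimal-melanopic light at a given chromaticity/luminance."""
    sens = standard_sensitivities() if sens is None else sens
    xyz, _, mel = _rig_matrices(primaries, sens)
    t = _target_xyz(target_xy, target_Y)
    scale = np.maximum(np.abs(xyz).max(axis=1), 1e-12)
    res = linprog(mel, A_eq=xyz / scale[:, None], b_eq=t / scale,
                  bounds=(0.0, 1.0), method="highs")
    if res.status == 2:
        lo, hi = _achievable_luminance(primaries, target_xy, sens)
        raise GamutError(
            f"candidate xy={target_xy} at Y={target_Y} out of gamut "
            f"(achievable [{lo:.1f}, {hi:.1f}] cd/m²)"
        )
    if not res.success:
        raise np.linalg.LinAlgError(f"candidate LP failed: {res.message}")
    return np.clip(res.x, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Low-ipRGC candidate geometry


def equal_energy_white_xyz(Y: float) -> np.ndarray:
    """Equal-energy-chromaticity white point scaled to luminance ``Y``."""
    return np.array([Y, Y, Y])


def generate_candidates(
    primaries: PrimarySet,
    rings: tuple[tuple[float, int], ...] = ((0.0, 1), (1.0, 4), (3.0, 7)),
    target_xy: tuple[float, float] = HIGH_LIGHT_XY,
    target_Y: float = HIGH_LIGHT_Y,
    sens: SensitivitySet | None = None,
    seed: int = 0,
) -> CandidateSet:
    """Low-ipRGC candidates on a*b* rings around the high light's colour.

    Ring points are equally spaced in angle starting at a seeded random
    phase, each at exact Euclidean distance ``radius`` from the centre in
    CIELAB a*b* (white: equal-energy chromaticity at the high light's
    luminance, so the centre sits at L* = 100).  Each candidate is converted
    back to a chromaticity target at fixed L* and solved as the
    minimal-melanopic light at that target.
    """
    sens = standard_sensitivities() if sens is None else sens
    rng = np.random.default_rng(seed)
    white = equal_energy_white_xyz(target_Y)
    center_xyz = _target_xyz(target_xy, target_Y)
    Lc, ac, bc = lab_from_xyz(center_xyz, white)

    cands = []
    cid = 0
    for ring_idx, (radius, count) in enumerate(rings):
        if count < 0 or radius < 0:
            raise ValueError("ring radius and count must be non-negative")
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for k in range(count):
            if radius == 0.0:
                da, db = 0.0, 0.0
            else:
                th = phase + 2.0 * np.pi * k / count
                da, db = radius * np.cos(th), radius * np.sin(th)
            xyz = xyz_from_lab((Lc, ac + da, bc + db), white)
            x, y = xy_from_xyz(xyz)
            Yc = float(xyz[1])
            w = solve_min_mel_light(primaries, (x, y), Yc, sens)
            cands.append(
                Candidate(cand_id=cid, ring=ring_idx, radius=radius, a_offset=da,
                          b_offset=db, x=x, y=y, Y=Yc, weights=w)
            )
            cid += 1
    return CandidateSet(center_ab=(ac, bc), candidates=tuple(cands), center_xy=target_xy)
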