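"""Simulated observers for the colour-tuning and brightness-matching tasks.

The tuning task is a yes/no colour-identity judgement: on each trial the
observer sees the high-melanopsin reference next to one of the candidate
lights (or the reference itself) and answers whether the two colours are
identical.  The observer model is deliberately minimal: the perceived
colour difference is the Euclidean a*b* distance plus Gaussian sensory
noise, compared against a fixed "identical" threshold.  The candidate with
the most "yes" answers is selected; ties go to the candidate whose CIE xy
chromaticity is closest to the reference (then to the lowest id).

Brightness matching models melanopsin's contribution to perceived
brightness as a multiplicative gain on luminance,

    B = Y · (1 + g · C_mel / 100),

where C_mel is the light's signed melanopic Michelson contrast relative to
the pair mean.  The observer raises/lowers the matching light's luminance
in fixed steps until the perceived brightnesses cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus import CandidateSet, MetamerPair

__all__ = [
    "ObserverModel",
    "TuningResult",
    "simulate_tuning_protocol",
    "simulate_brightness_matching",
    "predicted_brightness_ratio",
    "gain_for_enhancement",
]


@dataclass(frozen=True)
class ObserverModel:
    """Psychophysical observer parameters.

    noise_sd: sd of sensory noise on perceived a*b* distance (a*b* units).
    threshold: ΔE below which two lights are judged "identical".
    brightness_gain: melanopsin brightness gain g (dimensionless).
    adjust_step: luminance adjustment step, cd/m².
    """

    noise_sd: float = 0.75
    threshold: float = 1.5
    brightness_gain: float = 0.5
    adjust_step: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.threshold <= 0 or self.adjust_step <= 0:
            raise ValueError("threshold and adjustment step must be positive")


@dataclass(frozen=True)
class TuningResult:
    yes_counts: dict[int, int]
    selected_id: int
    tie_break_used: bool
    n_trials: int
    trial_order: tuple[int, ...] = field(repr=False, default=())


def simulate_tuning_protocol(
    observer: ObserverModel,
    candidates: CandidateSet,
    reps_per_reference: int = 12,
) -> TuningResult:
    """Run the 2AFC colour-tuning protocol against every candidate.

    Each of the candidates plus the high-light reference itself is shown
    ``reps_per_reference`` times in seeded random order (12 candidates + 1
    reference × 12 repetitions = 156 trials in the default layout).
    """
    if reps_per_reference <= 0:
        raise ValueError("reps_per_reference must be positive")
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    rng = np.random.default_rng(observer.seed)

    # reference id −1 denotes the high light itself (distance 0)
    ref_ids = [c.cand_id for c in candidates.candidates] + [-1]
    dist = {c.cand_id: float(np.hypot(c.a_offset, c.b_offset)) for c in candidates.candidates}
    dist[-1] = 0.0

    trials = np.repeat(ref_ids, reps_per_reference)
    rng.shuffle(trials)

    yes_counts = {cid: 0 for cid in ref_ids}
    for cid in trials:
        perceived = dist[cid] + rng.normal(0.0, observer.noise_sd)
        if perceived < observer.threshold:
            yes_counts[cid] += 1

    cand_yes = {c.cand_id: yes_counts[c.cand_id] for c in candidates.candidates}
    best = max(cand_yes.values())
    tied = [cid for cid, v in cand_yes.items() if v == best]
    tie_break = len(tied) > 1
    if tie_break:
        cx, cy = candidates.center_xy
        by_cand = {c.cand_id: c for c in candidates.candidates}
        tied.sort(key=lambda cid: (np.hypot(by_cand[cid].x - cx, by_cand[cid].y - cy), cid))
    selected = tied[0]
    return TuningResult(
        yes_counts=cand_yes,
        selected_id=int(selected),
        tie_break_used=tie_break,
        n_trials=int(trials.size),
        trial_order=tuple(int(t) for t in trials),
    )


def predicted_brightness_ratio(mel_contrast_pct: float, gain: float) -> float:
    """Closed-form matched-luminance ratio (adjusted low / fixed high).

    Solving B_low(Y) = B_high gives Y_low/Y_high =
    (1 + g·C/100)/(1 − g·C/100) with C the pair's Michelson contrast.
    """
    c = mel_contrast_pct / 100.0
    return (1.0 + gain * c) / (1.0 - gain * c)


def gain_for_enhancement(target_enhancement: float, mel_contrast_pct: float) -> float:
    """Gain g such that the predicted ratio is 1 + ``target_enhancement``."""
    r = 1.0 + target_enhancement
    c = mel_contrast_pct / 100.0
    return (r - 1.0) / (c * (r + 1.0))


def simulate_brightness_matching(
    pair: MetamerPair,
    observer: ObserverModel,
    n_trials: int = 20,
) -> float:
    """Mean adjusted-luminance ratio over ``n_trials`` staircase matches.

    The high light stays fixed; the low light's luminance starts at a
    seeded random offset and is stepped up/down until the perceived
    brightness ordering flips.  Returns mean(final low Y / high Y).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    y_high = pair.excitations_high.Y
    y_low0 = pair.excitations_low.Y
    if y_high <= 0 or y_low0 <= 0:
        raise ValueError("luminances must be positive")
    rng = np.random.default_rng(observer.seed + 1)
    g = observer.brightness_gain
    c = pair.mel_contrast_pct / 100.0
    b_high = y_high * (1.0 + g * c)

    def b_low(y: float) -> float:
        return y * (1.0 - g * c)

    finals = []
    for _ in range(n_trials):
        y = y_low0 * (1.0 + rng.uniform(-0.1, 0.1))
        direction = 1.0 if b_low(y) < b_high else -1.0
        for _ in range(10_000):
            if direction * (b_low(y) - b_high) >= 0.0:
                break
            y += direction * observer.adjust_step
        finals.append(y)
    return float(np.mean(finals) / y_high)
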