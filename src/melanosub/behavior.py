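"""Synthetic N-back experiment generator: sequences, responses, ratings, pupil.

The generator produces a complete two-block within-subject experiment with
known ground truth: each block runs under one light condition (low/high
melanopsin activation) and contains six runs of 50 one-back plus 50
two-back letter trials, per-run sleepiness/fatigue ratings with a
time-on-task drift, and a 1 kHz pupil trace with blink gaps, task-load
dilation and a melanopsin-driven constriction under the high light.

Injected effects (hit-rate boost, RT shift, rating reduction, pupil
constriction) are configurable so downstream analyses can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LETTERS = tuple("ABCDEJKOPRSUVXYZ")  # the 16-letter stimulus alphabet

LETTER_S = 0.5  # letter presentation, seconds
ISI_S = 1.5  # inter-stimulus interval, seconds
TRIAL_S = LETTER_S + ISI_S

__all__ = [
    "LETTERS",
    "SubjectParams",
    "CohortSpec",
    "generate_nback_sequence",
    "simulate_responses",
    "generate_ratings",
    "generate_pupil_trace",
    "generate_session",
    "cohort_hit_rates",
]


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth behavioural parameters for one simulated subject.

    Probabilities are per-trial; RT units are milliseconds; pupil units are
    millimetres.  ``light_effect_hit_2back`` is the additive boost to the
    2-back hit probability under the high-melanopsin light.
    """

    hit_prob_1back: float = 0.92
    hit_prob_2back: float = 0.78
    fa_prob: float = 0.05
    light_effect_hit_1back: float = 0.0
    light_effect_hit_2back: float = 0.06
    light_effect_fa_2back: float = -0.015
    rt_mean_1back: float = 520.0
    rt_mean_2back: float = 640.0
    rt_sd: float = 140.0
    light_effect_rt_1back: float = -18.0
    light_effect_rt_2back: float = -4.0
    sleepiness_intercept: float = 3.0
    fatigue_intercept: float = 2.0
    rating_slope_per_run: float = 0.35
    light_effect_sleepiness: float = -0.5
    light_effect_fatigue: float = -0.8
    rating_noise_sd: float = 1.0
    pupil_baseline_mm: float = 4.5
    pupil_task_dilation_mm: float = 0.2
    pupil_light_constriction_mm: float = 0.3
    pupil_noise_sd_mm: float = 0.05
    blink_rate_hz: float = 0.2
    blink_duration_ms: float = 150.0
    px_per_mm: float = 13.0

    def hit_prob(self, task: int, light: str) -> float:
        base = self.hit_prob_1back if task == 1 else self.hit_prob_2back
        eff = self.light_effect_hit_1back if task == 1 else self.light_effect_hit_2back
        p = base + (eff if light == "high" else 0.0)
        if not 0.0 <= p <= 1.0:
            raise ValueError("hit probability outside [0, 1] after light effect")
        return p

    def fa_prob_of(self, task: int, light: str) -> float:
        eff = self.light_effect_fa_2back if (task == 2 and light == "high") else 0.0
        p = self.fa_prob + eff
        if not 0.0 <= p <= 1.0:
            raise ValueError("false-alarm probability outside [0, 1]")
        return p

    def rt_mean(self, task: int, light: str) -> float:
        base = self.rt_mean_1back if task == 1 else self.rt_mean_2back
        eff = self.light_effect_rt_1back if task == 1 else self.light_effect_rt_2back
        return base + (eff if light == "high" else 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout and between-subject heterogeneity.

    The default cohort mirrors a 26-subject counterbalanced design: 13
    subjects start with the high light, 13 with the low light.
    """

    n_subjects: int = 26
    n_runs: int = 6
    trials_per_task: int = 50
    target_rate: float = 0.3
    base: SubjectParams = field(default_factory=SubjectParams)
    sd_hit: float = 0.05
    sd_rt: float = 40.0
    sd_rating: float = 0.8
    sd_pupil: float = 0.25
    sd_pupil_effect: float = 0.08

    def subject_params(self, rng: np.random.Generator) -> SubjectParams:
        b = self.base
        # keep headroom for additive light effects so probabilities stay valid
        slack = max(
            abs(b.light_effect_hit_1back), abs(b.light_effect_hit_2back),
            abs(b.light_effect_fa_2back),
        )
        clip = lambda p: float(np.clip(p, 0.02 + slack, 0.98 - slack))
        return replace(
            b,
            hit_prob_1back=clip(b.hit_prob_1back + rng.normal(0, self.sd_hit)),
            hit_prob_2back=clip(b.hit_prob_2back + rng.normal(0, self.sd_hit)),
            fa_prob=clip(b.fa_prob + rng.normal(0, self.sd_hit / 2)),
            rt_mean_1back=b.rt_mean_1back + rng.normal(0, self.sd_rt),
            rt_mean_2back=b.rt_mean_2back + rng.normal(0, self.sd_rt),
            sleepiness_intercept=b.sleepiness_intercept + rng.normal(0, self.sd_rating),
            fatigue_intercept=b.fatigue_intercept + rng.normal(0, self.sd_rating),
            pupil_baseline_mm=b.pupil_baseline_mm + rng.normal(0, self.sd_pupil),
            pupil_task_dilation_mm=max(
                0.0, b.pupil_task_dilation_mm + rng.normal(0, self.sd_pupil_effect)
            ),
            pupil_light_constriction_mm=max(
                0.0, b.pupil_light_constriction_mm + rng.normal(0, self.sd_pupil_effect)
            ),
        )


class GenerationError(RuntimeError):
    pass


def generate_nback_sequence(
    n: int,
    n_trials: int,
    target_rate: float = 0.3,
    letters: tuple[str, ...] = LETTERS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Letter sequence with exactly ``round(target_rate·(n_trials − n))`` targets.

    Trial i is a target iff letter(i) == letter(i − n); non-target letters
    are drawn avoiding accidental matches.
    """
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    if n_trials <= n:
        raise ValueError("n_trials must exceed n")
    if not 0.0 <= target_rate <= 1.0:
        raise ValueError("target_rate must be in [0, 1]")
    if len(letters) < 3:
        raise GenerationError("alphabet too small to avoid accidental targets")
    rng = np.random.default_rng(seed) if rng is None else rng

    n_targets = int(round(target_rate * (n_trials - n)))
    eligible = np.arange(n, n_trials)
    if n_targets > eligible.size:
        raise GenerationError("requested more targets than eligible positions")
    target_pos = set(rng.choice(eligible, size=n_targets, replace=False).tolist())

    seq: list[str] = []
    for i in range(n_trials):
        if i in target_pos:
            seq.append(seq[i - n])
        else:
            forbidden = {seq[i - n]} if i >= n else set()
            # avoid creating a future forced mismatch is unnecessary; only
            # the i-vs-(i-n) identity defines targets
            choices = [c for c in letters if c not in forbidden]
            seq.append(choices[rng.integers(len(choices))])
    is_target = np.zeros(n_trials, dtype=bool)
    is_target[list(target_pos)] = True
    return seq, is_target


def simulate_responses(
    is_target: np.ndarray,
    params: SubjectParams,
    task: int,
    light: str,
    rng: np.random.Generator,
    rt_bounds: tuple[float, float] = (150.0, 2000.0),
) -> pd.DataFrame:
    """Per-trial outcome (hit/miss/FA/CR) and RT for every key press."""
    is_target = np.asarray(is_target, dtype=bool)
    p_hit = params.hit_prob(task, light)
    p_fa = params.fa_prob_of(task, light)
    pressed = np.where(
        is_target,
        rng.random(is_target.size) < p_hit,
        rng.random(is_target.size) < p_fa,
    )
    outcome = np.where(
        is_target,
        np.where(pressed, "hit", "miss"),
        np.where(pressed, "fa", "cr"),
    )
    mu = params.rt_mean(task, light)
    rt = np.full(is_target.size, np.nan)
    need = np.flatnonzero(pressed)
    lo, hi = rt_bounds
    draws = mu + params.rt_sd * rng.standard_normal(need.size)
    bad = (draws < lo) | (draws > hi)
    while bad.any():  # redraw out-of-window RTs (truncated normal)
        draws[bad] = mu + params.rt_sd * rng.standard_normal(int(bad.sum()))
        bad = (draws < lo) | (draws > hi)
    rt[need] = draws
    return pd.DataFrame({"is_target": is_target, "response": outcome, "rt_ms": rt})


def generate_ratings(
    runs: int,
    params: SubjectParams,
    light: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sleepiness and fatigue (0–10 visual-analog) per run with drift."""
    if runs < 1:
        raise ValueError("runs must be ≥ 1")
    out = []
    is_high = light == "high"
    for run in range(1, runs + 1):
        for scale, icept, leff in (
            ("sleepiness", params.sleepiness_intercept, params.light_effect_sleepiness),
            ("fatigue", params.fatigue_intercept, params.light_effect_fatigue),
        ):
            val = (
                icept
                + params.rating_slope_per_run * run
                + (leff if is_high else 0.0)
                + rng.normal(0.0, params.rating_noise_sd)
            )
            out.append({"run": run, "scale": scale, "rating": float(np.clip(val, 0, 10))})
    return pd.DataFrame(out)


def generate_pupil_trace(
    duration_s: float,
    params: SubjectParams,
    task: int,
    light: str,
    rng: np.random.Generator,
    rate_hz: float = 1000.0,
) -> pd.DataFrame:
    """1 kHz pupil trace: baseline ± effects + AR(1) noise, blink zero-runs.

    Returns columns ``t_ms, pupil_raw, pupil_mm`` — the raw channel is the
    arbitrary-unit (pixel) signal the eye-tracker would log, zero during
    blinks.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * rate_hz))
    level = (
        params.pupil_baseline_mm
        + (params.pupil_task_dilation_mm if task == 2 else 0.0)
        - (params.pupil_light_constriction_mm if light == "high" else 0.0)
    )
    # AR(1) with lag-1 coefficient 0.995 scaled to the stationary sd
    phi = 0.995
    innov_sd = params.pupil_noise_sd_mm * np.sqrt(1 - phi**2)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, params.pupil_noise_sd_mm)
    eps = rng.normal(0.0, innov_sd, size=n)
    from scipy.signal import lfilter

    noise = lfilter([1.0], [1.0, -phi], eps, zi=[phi * noise[0]])[0]
    mm = level + noise

    blink_len = max(1, int(round(params.blink_duration_ms * rate_hz / 1000.0)))
    n_blinks = rng.poisson(params.blink_rate_hz * duration_s)
    starts = rng.integers(0, max(1, n - blink_len), size=n_blinks)
    raw = mm * params.px_per_mm
    for s in starts:
        raw[s : s + blink_len] = 0.0
    t_ms = np.arange(n) * (1000.0 / rate_hz)
    return pd.DataFrame({"t_ms": t_ms, "pupil_raw": raw, "pupil_mm": raw / params.px_per_mm})


def _block_lights(subject_idx: int) -> tuple[str, str]:
    """Counterbalanced block order: even-indexed subjects start with high."""
    return ("high", "low") if subject_idx % 2 == 0 else ("low", "high")


def generate_session(
    spec: CohortSpec,
    seed: int = 0,
    with_pupil: bool = False,
    pupil_rate_hz: float = 1000.0,
) -> dict:
    """Generate the full cohort: trial table, ratings, optional pupil traces.

    Returns ``{"session": DataFrame, "ratings": DataFrame, "pupil": dict}``;
    the session table has one row per trial with onset times so pupil
    windows can be carved out downstream.
    """
    rng = np.random.default_rng(seed)
    rows, rating_rows = [], []
    pupil: dict[tuple, pd.DataFrame] = {}
    for s in range(spec.n_subjects):
        sp = spec.subject_params(rng)
        for block, light in enumerate(_block_lights(s), start=1):
            t0 = 0.0
            for run in range(1, spec.n_runs + 1):
                for task in (1, 2):
                    seq, is_target = generate_nback_sequence(
                        task, spec.trials_per_task, spec.target_rate, rng=rng
                    )
                    resp = simulate_responses(is_target, sp, task, light, rng)
                    for i in range(spec.trials_per_task):
                        rows.append(
                            {
                                "subject": s,
                                "block": block,
                                "run": run,
                                "task": f"{task}-back",
                                "light": light,
                                "trial": i,
                                "letter": seq[i],
                                "is_target": bool(is_target[i]),
                                "response": resp.response.iloc[i],
                                "rt_ms": resp.rt_ms.iloc[i],
                                "t_onset_s": t0 + i * TRIAL_S,
                            }
                        )
                    if with_pupil:
                        tr = generate_pupil_trace(
                            spec.trials_per_task * TRIAL_S, sp, task, light, rng,
                            rate_hz=pupil_rate_hz,
                        )
                        pupil[(s, block, run, task)] = tr
                    t0 += spec.trials_per_task * TRIAL_S
            rat = generate_ratings(spec.n_runs, sp, light, rng)
            rat.insert(0, "subject", s)
            rat.insert(1, "block", block)
            rat.insert(2, "light", light)
            rating_rows.append(rat)
    session = pd.DataFrame(rows)
    ratings = pd.concat(rating_rows, ignore_index=True)
    return {"session": session, "ratings": ratings, "pupil": pupil}


def cohort_hit_rates(
    spec: CohortSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Fast binomial path to per-subject hit rates per task × light.

    Draws the per-cell hit counts directly from the binomial distribution
    implied by the trial-level model (distributionally identical to
    aggregating :func:`simulate_responses` over the same trials), for use
    in replication-heavy recovery studies.
    """
    rng = np.random.default_rng(seed)
    n_targets = int(round(spec.target_rate * (spec.trials_per_task - 1)))
    n2 = int(round(spec.target_rate * (spec.trials_per_task - 2)))
    rows = []
    for s in range(spec.n_subjects):
        sp = spec.subject_params(rng)
        for light in _block_lights(s):
            for task, nt in ((1, n_targets * spec.n_runs), (2, n2 * spec.n_runs)):
                p = sp.hit_prob(task, light)
                k = rng.binomial(nt, p)
                rows.append(
                    {
                        "subject": s,
                        "task": f"{task}-back",
                        "light": light,
                        "n_targets": nt,
                        "hits": int(k),
                        "hit_rate": k / nt,
                    }
                )
    return pd.DataFrame(rows)
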