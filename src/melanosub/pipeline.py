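"""End-to-end orchestration: design → simulate → preprocess → analyse.

One :class:`RunConfig` drives every stage; all stage randomness derives
deterministically from the master seed (stage seed = SHA-256 of
``"<seed>:<stage>"``), so an identical config and seed reproduce every
output file hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, observer, pupil, stats, stimulus
from .spectra import write_spd_csv

log = logging.getLogger("melanosub")

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2³¹."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Master configuration for a full synthetic study run."""

    seed: int = 0
    outdir: str = "melanosub_out"
    n_subjects: int = 26
    n_runs: int = 6
    trials_per_task: int = 50
    target_rate: float = 0.3
    target_xy: tuple[float, float] = stimulus.HIGH_LIGHT_XY
    target_Y: float = stimulus.HIGH_LIGHT_Y
    rings: tuple[tuple[float, int], ...] = ((0.0, 1), (1.0, 4), (3.0, 7))
    tuning_reps: int = 12
    brightness_trials: int = 20
    pupil_rate_hz: float = 1000.0
    write_pupil_example: bool = True
    n_boot: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rings" in raw:
            raw["rings"] = tuple((float(r), int(c)) for r, c in raw["rings"])
        if "target_xy" in raw:
            raw["target_xy"] = tuple(raw["target_xy"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["rings"] = [list(r) for r in self.rings]
        d["target_xy"] = list(self.target_xy)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; return (and write) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(asdict(config))), "stages": {}}
    produced: list[Path] = []

    def finish_stage(name: str, t0: float, files: list[Path]) -> None:
        produced.extend(files)
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 3),
            "files": [str(f.relative_to(out)) for f in files],
        }
        log.info("stage %s done in %.2fs", name, time.time() - t0)

    try:
        # ---- design -----------------------------------------------------
        t0 = time.time()
        seed_d = stage_seed(config.seed, "design")
        primaries = stimulus.build_synthetic_primaries(seed=seed_d)
        pair = stimulus.solve_metamer_pair(primaries, config.target_xy, config.target_Y)
        cands = stimulus.generate_candidates(
            primaries, config.rings, config.target_xy, config.target_Y, seed=seed_d
        )
        files = []
        spd_dir = out / "spd"
        spd_dir.mkdir(exist_ok=True)
        for label, spd in zip(primaries.labels, primaries.spds):
            f = spd_dir / f"{label}.csv"
            write_spd_csv(f, spd)
            files.append(f)
        mfile = out / "metamers.json"
        with open(mfile, "w") as fh:
            json.dump(
                {
                    "weights_high": pair.weights_high.tolist(),
                    "weights_low": pair.weights_low.tolist(),
                    "mel_contrast_pct": pair.mel_contrast_pct,
                    "lms_residual": pair.lms_residual,
                    "xy_high": pair.xy_high,
                    "xy_low": pair.xy_low,
                    "Y_high": pair.excitations_high.Y,
                    "Y_low": pair.excitations_low.Y,
                    "mel_high": pair.excitations_high.mel,
                    "mel_low": pair.excitations_low.mel,
                    "rod_high": pair.excitations_high.rod,
                    "rod_low": pair.excitations_low.rod,
                },
                fh,
                indent=1,
            )
        files.append(mfile)
        cfile = out / "candidates.csv"
        pd.DataFrame(
            [
                {
                    "id": c.cand_id,
                    "ring": c.ring,
                    "a_offset": c.a_offset,
                    "b_offset": c.b_offset,
                    "x": c.x,
                    "y": c.y,
                    "Y": c.Y,
                }
                for c in cands.candidates
            ]
        ).to_csv(cfile, index=False)
        files.append(cfile)
        finish_stage("design", t0, files)

        # ---- observer simulation ---------------------------------------
        t0 = time.time()
        seed_o = stage_seed(config.seed, "observer")
        tunings, bright = [], []
        for s in range(config.n_subjects):
            obs = observer.ObserverModel(seed=seed_o + s)
            tr = observer.simulate_tuning_protocol(obs, cands, config.tuning_reps)
            tunings.append(
                {"subject": s, "selected": tr.selected_id, "n_trials": tr.n_trials,
                 "tie_break": tr.tie_break_used, "yes_counts": tr.yes_counts}
            )
            ratio = observer.simulate_brightness_matching(pair, obs, config.brightness_trials)
            bright.append({"subject": s, "adjusted_ratio": ratio})
        tfile = out / "tuning_result.json"
        with open(tfile, "w") as fh:
            json.dump(tunings, fh, indent=1, default=_json_default)
        bfile = out / "brightness_result.csv"
        pd.DataFrame(bright).to_csv(bfile, index=False)
        finish_stage("observer", t0, [tfile, bfile])

        # ---- behaviour --------------------------------------------------
        t0 = time.time()
        seed_b = stage_seed(config.seed, "behavior")
        spec = behavior.CohortSpec(
            n_subjects=config.n_subjects,
            n_runs=config.n_runs,
            trials_per_task=config.trials_per_task,
            target_rate=config.target_rate,
        )
        data = behavior.generate_session(
            spec, seed=seed_b, with_pupil=True, pupil_rate_hz=config.pupil_rate_hz
        )
        sfile = out / "session.csv"
        data["session"].to_csv(sfile, index=False)
        rfile = out / "ratings.csv"
        data["ratings"].to_csv(rfile, index=False)
        files = [sfile, rfile]
        if config.write_pupil_example and data["pupil"]:
            pdir = out / "pupil"
            pdir.mkdir(exist_ok=True)
            key = min(data["pupil"])  # one example trace keeps output light
            f = pdir / ("sub%02d_block%d_run%d_task%d.csv" % key)
            data["pupil"][key].to_csv(f, index=False)
            files.append(f)
        finish_stage("behavior", t0, files)

        # ---- pupil preprocessing ----------------------------------------
        t0 = time.time()
        traces = {
            key: pupil.preprocess_pupil(pupil.PupilTrace.from_frame(df))
            for key, df in data["pupil"].items()
        }
        agg = pupil.aggregate_pupil(traces, data["session"])
        afile = out / "pupil_agg.csv"
        agg.to_csv(afile, index=False)
        finish_stage("pupil_prep", t0, [afile])

        # ---- statistics -------------------------------------------------
        t0 = time.time()
        seed_s = stage_seed(config.seed, "stats")
        report = analyze_session(
            data["session"], data["ratings"], agg, n_boot=config.n_boot, seed=seed_s
        )
        stfile = out / "stats_report.json"
        with open(stfile, "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)
        finish_stage("stats", t0, [stfile])
    except Exception as exc:  # partial manifest aids debugging failed stages
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise

    manifest["hashes"] = {str(f.relative_to(out)): _sha256(f) for f in produced}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _result_dict(r: stats.StatResult) -> dict:
    d = {
        "estimate": r.estimate,
        "df": r.df,
        "p": r.p,
        "effect_size": r.effect_size,
        "effect_size_name": r.effect_size_name,
        "bf10": r.bf10,
        "ci": r.ci,
        "correction": r.correction,
    }
    return {k: v for k, v in d.items() if v is not None}


def analyze_session(
    session: pd.DataFrame,
    ratings: pd.DataFrame,
    pupil_agg: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict:
    """The full inferential chain on a session table.

    Hit-rate 2×2 RM-ANOVA (light × N-back), Holm-corrected paired
    follow-ups with JZS Bayes factors, RT mixed models with cluster
    bootstrap CIs per task, rating time-on-task model, light → sleepiness
    → hit-rate mediation, and (when provided) the pupil 2×2 ANOVA.
    """
    report: dict = {}

    targets = session[session.is_target]
    hits = (
        targets.assign(hit=lambda d: d.response.eq("hit"))
        .groupby(["subject", "task", "light"], as_index=False)
        .hit.mean()
        .rename(columns={"hit": "value"})
    )
    report["hit_rate_anova"] = {
        k: _result_dict(v) for k, v in stats.rm_anova_2x2(hits, dv="value").items()
    }

    wide = hits.pivot_table(index="subject", columns=["task", "light"], values="value")
    followups: dict[str, stats.StatResult] = {}
    for task in ("1-back", "2-back"):
        followups[task] = stats.paired_t(
            wide[(task, "high")], wide[(task, "low")], compute_bf=True
        )
    adj = stats.holm_adjust([r.p for r in followups.values()])
    report["hit_rate_followups"] = {
        task: {**_result_dict(r), "p_holm": float(a), "correction": "holm"}
        for (task, r), a in zip(followups.items(), adj)
    }

    rts = session.dropna(subset=["rt_ms"])
    rt_lmm = {}
    for task in ("1-back", "2-back"):
        sub = rts[(rts.task == task) & rts.response.eq("hit")].copy()
        sub["light01"] = (sub.light == "high").astype(float)
        res = stats.fit_lmm_random_intercept(
            sub, "rt_ms", ["light01"], n_boot=n_boot, seed=seed
        )
        rt_lmm[task] = _result_dict(res["light01"])
    report["rt_lmm"] = rt_lmm

    rat = ratings.copy()
    rat["light01"] = (rat.light == "high").astype(float)
    rating_models = {}
    for scale in ("sleepiness", "fatigue"):
        sub = rat[rat.scale == scale]
        res = stats.fit_lmm_random_intercept(
            sub, "rating", ["light01", "run"], n_boot=n_boot, seed=seed + 1
        )
        rating_models[scale] = {k: _result_dict(v) for k, v in res.items()}
    report["rating_lmm"] = rating_models

    # subject × light aggregates for mediation (2-back hit rate as outcome)
    sleep = (
        rat[rat.scale == "sleepiness"]
        .groupby(["subject", "light"], as_index=False)
        .rating.mean()
    )
    hr2 = hits[hits.task == "2-back"][["subject", "light", "value"]]
    merged = sleep.merge(hr2, on=["subject", "light"])
    med = stats.mediate(
        (merged.light == "high").to_numpy(float),
        merged.rating.to_numpy(float),
        merged.value.to_numpy(float),
        n_boot=n_boot,
        seed=seed + 2,
    )
    report["mediation_light_sleepiness_hit2back"] = {
        k: _result_dict(v) for k, v in med.items()
    }

    if pupil_agg is not None and not pupil_agg.empty:
        report["pupil_anova"] = {
            k: _result_dict(v)
            for k, v in stats.rm_anova_2x2(pupil_agg, dv="mean_mm").items()
        }
    return report
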