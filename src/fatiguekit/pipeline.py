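"""Study-level orchestration: per-session metrics, group statistics and report.

A study is a complete set of subject x condition sessions (three fatiguing-
task force levels per subject).  Each session contributes a fatiguing-task
force slope, optional EMG slopes (FCR/ECR), an optional post-FT MVC and
optional assessment-task kinematics; the study report assembles the
within-subject ANOVAs, follow-up paired tests and (when occupancy maps are
available) the cluster-based permutation test on space covered.

Sessions can be supplied in memory (:class:`SessionData`) or as manifests
pointing at files in the package's on-disk formats; both paths produce
byte-identical reports for identical data and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .cluster import SpatialMapSet, permutation_test
from .emg import bandpass_emg, emg_envelope, emg_ft_slope
from .force import contraction_auc, fatigue_slope, fwhm_median, mvc_best_of_three, segment_contractions
from .io import (
    CONDITIONS,
    CueSchedule,
    SessionManifest,
    TaskLog,
    TimeSeries,
    build_cue_schedule,
    read_manifest,
    read_task_log,
    read_timeseries,
    write_manifest,
    write_task_log,
    write_timeseries,
)
from .kinematics import space_covered, summarize_hand
from .synth import ForceGenConfig, gen_force_session, gen_mvc_profile

__all__ = [
    "StudyConfig",
    "SessionData",
    "StudyReport",
    "analyze_session",
    "run_study",
    "load_session",
    "make_synthetic_study",
    "write_study",
]

EMG_CHANNELS = ("fcr", "ecr")


@dataclass(frozen=True)
class StudyConfig:
    """All analysis thresholds in one place (hashed into report provenance)."""

    n_cycles: int = 270
    on_s: float = 1.0
    off_s: float = 1.0
    discard_first: int = 10
    emg_band: tuple[float, float] = (10.0, 500.0)
    emg_envelope_method: str = "hilbert"
    cell_size_cm: float = 1.0
    n_perm: int = 5000
    cluster_threshold_p: float = 0.01
    cluster_min_cells: int = 2
    cluster_conditions: tuple[str, str] = ("pct5", "pct75")
    cluster_hand: str = "right"
    alpha: float = 0.05
    seed: int = 0

    def schedule(self) -> CueSchedule:
        return build_cue_schedule(self.n_cycles, self.on_s, self.off_s)

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class SessionData:
    """One subject-condition session, fully in memory."""

    subject_id: str
    condition: str
    round_index: int
    baseline_mvc: float
    force: TimeSeries | None = None
    schedule: CueSchedule | None = None
    mvc_post: list[TimeSeries] = field(default_factory=list)
    emg: dict[str, TimeSeries] = field(default_factory=dict)
    task_log: TaskLog | None = None


@dataclass
class StudyReport:
    """Nested-dict report with deterministic JSON serialisation."""

    data: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.data, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __getitem__(self, key: str):
        return self.data[key]


def load_session(manifest: SessionManifest | str | Path, config: StudyConfig) -> SessionData:
    """Materialise a session from its manifest; absent streams stay None."""
    if not isinstance(manifest, SessionManifest):
        manifest = read_manifest(manifest)
    files = manifest.files
    force = read_timeseries(files["force"]) if "force" in files else None
    emg = {ch: read_timeseries(files[f"emg_{ch}"]) for ch in EMG_CHANNELS if f"emg_{ch}" in files}
    mvc_post = [read_timeseries(files["mvc_post"])] if "mvc_post" in files else []
    task_log = read_task_log(files["task_log"]) if "task_log" in files else None
    return SessionData(
        subject_id=manifest.subject_id,
        condition=manifest.condition,
        round_index=manifest.round_index,
        baseline_mvc=manifest.baseline_mvc,
        force=force,
        schedule=config.schedule(),
        mvc_post=mvc_post,
        emg=emg,
        task_log=task_log,
    )


def analyze_session(session: SessionData, config: StudyConfig) -> dict:
    """Per-session metrics: FT slopes, post-FT MVC and AT kinematics."""
    out: dict = {
        "subject_id": session.subject_id,
        "condition": session.condition,
        "round_index": session.round_index,
        "baseline_mvc": session.baseline_mvc,
    }
    schedule = session.schedule or config.schedule()
    if session.force is not None:
        segments = segment_contractions(session.force, schedule)
        aucs = [contraction_auc(s) for s in segments]
        slope = fatigue_slope(aucs, discard_first=config.discard_first)
        out["force_slope"] = {
            "beta": slope.beta,
            "intercept": slope.intercept,
            "n_points": slope.n_points,
            "residual_se": slope.residual_se,
        }
    for ch, trace in sorted(session.emg.items()):
        filtered = bandpass_emg(trace, *config.emg_band)
        env = emg_envelope(filtered, method=config.emg_envelope_method)
        slope = emg_ft_slope(env, schedule, discard_first=config.discard_first)
        out[f"emg_{ch}_slope"] = {"beta": slope.beta, "n_points": slope.n_points}
    if session.mvc_post:
        est = (
            mvc_best_of_three(session.mvc_post)
            if len(session.mvc_post) >= 2
            else fwhm_median(session.mvc_post[0])
        )
        out["mvc_post"] = est.median_force
    if session.task_log is not None and session.task_log.trajectories:
        for hand in sorted(session.task_log.trajectories):
            s = summarize_hand(session.task_log, hand, cell_size=config.cell_size_cm)
            out[f"at_{hand}"] = {
                "hits_total": s.hits_total,
                "hits_per_bin": [int(c) for c in s.hits_per_bin],
                "mean_speed": s.mean_speed,
                "mean_abs_accel": s.mean_abs_accel,
                "space_covered": s.space_covered,
            }
    return out


def _check_complete(sessions: list[SessionData]) -> list[str]:
    subjects = sorted({s.subject_id for s in sessions})
    have = {(s.subject_id, s.condition) for s in sessions}
    missing = [
        f"{subj}:{cond}" for subj in subjects for cond in CONDITIONS if (subj, cond) not in have
    ]
    return missing


def _wide(records: list[dict], key: str) -> tuple[list[str], np.ndarray] | None:
    """Subjects x conditions matrix of a scalar metric; None if incomplete."""
    subjects = sorted({r["subject_id"] for r in records})
    table = np.full((len(subjects), len(CONDITIONS)), np.nan)
    for r in records:
        val = r.get(key)
        if isinstance(val, dict):
            val = val.get("beta")
        if val is None:
            continue
        i = subjects.index(r["subject_id"])
        j = CONDITIONS.index(r["condition"])
        table[i, j] = val
    if np.any(~np.isfinite(table)):
        return None
    return subjects, table


def _anova_block(table: np.ndarray, name: str, alpha: float) -> dict:
    from .stats import paired_tests, rm_anova_oneway

    res = rm_anova_oneway(table, effect_name=name)[name]
    tests = paired_tests(
        table,
        comparisons=[(str(i), str(j)) for i in range(3) for j in range(i + 1, 3)],
        m=3,
    )
    return {
        "F": res.F,
        "df": [res.df_num, res.df_den],
        "p": res.p,
        "partial_eta_sq": res.partial_eta_sq,
        "significant": bool(res.p < alpha),
        "pairwise": [
            {
                "pair": [CONDITIONS[int(t.pair[0])], CONDITIONS[int(t.pair[1])]],
                "t": t.t,
                "df": t.df,
                "p_bonf": t.p_bonf,
                "cohens_d": t.cohens_d,
            }
            for t in tests
        ],
    }


def run_study(
    sessions: list[SessionData] | list[SessionManifest] | list[str],
    config: StudyConfig = StudyConfig(),
) -> StudyReport:
    """Run the full study analysis over a complete subject x condition set.

    Raises ``ValueError`` listing the missing subject:condition cells if the
    design is incomplete.  The report is deterministic given the sessions and
    ``config.seed`` (which drives only the permutation test).
    """
    loaded = [
        s if isinstance(s, SessionData) else load_session(s, config) for s in sessions
    ]
    missing = _check_complete(loaded)
    if missing:
        raise ValueError(f"incomplete design; missing sessions: {', '.join(missing)}")

    records = [analyze_session(s, config) for s in loaded]
    report: dict = {
        "sessions": records,
        "group": {},
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "n_subjects": len({r["subject_id"] for r in records}),
            "version": __version__,
        },
    }

    for key, label in [
        ("force_slope", "force_slope"),
        ("mvc_post", "mvc_post"),
        ("emg_fcr_slope", "emg_fcr_slope"),
        ("emg_ecr_slope", "emg_ecr_slope"),
    ]:
        wide = _wide(records, key)
        if wide is not None:
            report["group"][label] = _anova_block(wide[1], "force_level", config.alpha)

    # two-way muscle x force-level ANOVA on EMG slopes when both muscles present
    fcr = _wide(records, "emg_fcr_slope")
    ecr = _wide(records, "emg_ecr_slope")
    if fcr is not None and ecr is not None:
        from .stats import rm_anova_twoway

        cube = np.stack([fcr[1], ecr[1]], axis=1)  # (n, muscle, force)
        res = rm_anova_twoway(cube, factor_names=("muscle", "force_level"))
        report["group"]["emg_muscle_by_force"] = {
            name: {"F": e.F, "df": [e.df_num, e.df_den], "p": e.p, "partial_eta_sq": e.partial_eta_sq}
            for name, e in res.effects.items()
        }

    report["group"]["cluster_space_covered"] = _cluster_block(loaded, config)
    return StudyReport(data=report)


def _cluster_block(sessions: list[SessionData], config: StudyConfig) -> dict | None:
    """Space-covered occupancy maps compared between two conditions."""
    cond_a, cond_b = config.cluster_conditions
    hand = config.cluster_hand
    maps, labels = [], []
    for cond in (cond_a, cond_b):
        for s in sorted(
            (s for s in sessions if s.condition == cond), key=lambda s: s.subject_id
        ):
            if s.task_log is None or hand not in s.task_log.trajectories:
                return None
            tx, ty = s.task_log.trajectories[hand]
            omap, _ = space_covered(tx, ty, cell_size=config.cell_size_cm)
            maps.append((omap.grid > 0).astype(float))
            labels.append(cond)
    if len(set(labels)) != 2 or min(labels.count(cond_a), labels.count(cond_b)) < 2:
        return None
    mset = SpatialMapSet(maps=np.array(maps), labels=np.array(labels))
    result = permutation_test(
        mset,
        n_perm=config.n_perm,
        seed=config.seed,
        threshold_p=config.cluster_threshold_p,
        min_cells=config.cluster_min_cells,
    )
    return {
        "conditions": [cond_a, cond_b],
        "hand": hand,
        "n_permutations": result.n_permutations,
        "n_clusters": len(result.clusters),
        "clusters": [
            {"size": c.size, "mass": c.mass, "sign": c.sign, "p": c.p_value}
            for c in result.clusters
        ],
        "any_significant": bool(result.significant(config.alpha)),
    }


# ---------------------------------------------------------------------------
# synthetic studies

#: per-condition fractional AUC drift per contraction: deterioration grows
#: with force level, none at the lightest level.  Fractions of the session's
#: baseline per-contraction AUC keep every force level feasible over the full
#: 270-contraction protocol (at -0.2%/contraction the 75% session ends near
#: half its initial output).
DEFAULT_DRIFTS = {"pct5": 0.0, "pct50": -0.001, "pct75": -0.002}

#: post-FT MVC attenuation per condition (fraction of baseline)
DEFAULT_MVC_DROP = {"pct5": 0.08, "pct50": 0.28, "pct75": 0.28}

_PCT = {"pct5": 5, "pct50": 50, "pct75": 75}


def make_synthetic_study(
    n_subjects: int = 6,
    drifts: dict[str, float] = DEFAULT_DRIFTS,
    subject_drift_sd: float = 0.0003,
    noise_sd: float = 0.5,
    n_cycles: int = 270,
    seed: int = 0,
) -> list[SessionData]:
    """Generate a complete in-memory study of cued force sessions.

    Each subject gets one session per force level; the injected drift is the
    condition's *fractional* AUC change per contraction (plus a subject-level
    Gaussian perturbation of SD ``subject_drift_sd``), converted to absolute
    AUC units against the session's baseline per-contraction AUC.  Condition
    order rotates across subjects (the counterbalancing is metadata only).
    Post-FT MVC profiles shrink with the condition's nominal fatigue.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    sessions: list[SessionData] = []
    conds = list(CONDITIONS)
    for i in range(n_subjects):
        subject = f"S{i + 1:02d}"
        mvc = float(rng.normal(57.0, 8.0))
        mvc = max(mvc, 20.0)
        order = conds[i % 3 :] + conds[: i % 3]
        for round_index, cond in enumerate(order, start=1):
            frac = drifts[cond] + float(rng.normal(0.0, subject_drift_sd))
            cfg = ForceGenConfig(
                mvc=mvc,
                target_pct=_PCT[cond],
                n_cycles=n_cycles,
                noise_sd=noise_sd,
            )
            cfg = replace(
                cfg, drift_beta=frac * cfg.target_force * cfg.pulse_area_per_unit
            )
            force, schedule = gen_force_session(cfg, seed=rng)
            post_amp = mvc * (1.0 - DEFAULT_MVC_DROP[cond]) + float(rng.normal(0.0, 1.0))
            mvc_post = gen_mvc_profile(max(post_amp, 5.0), noise_sd=noise_sd, seed=rng)
            sessions.append(
                SessionData(
                    subject_id=subject,
                    condition=cond,
                    round_index=round_index,
                    baseline_mvc=mvc,
                    force=force,
                    schedule=schedule,
                    mvc_post=[mvc_post],
                )
            )
    return sessions


def write_study(sessions: list[SessionData], out_dir: str | Path) -> list[Path]:
    """Write sessions to disk in the package formats; returns manifest paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_paths = []
    for s in sessions:
        stem = f"{s.subject_id}_{s.condition}"
        files: dict[str, str] = {}
        if s.force is not None:
            p = out_dir / f"{stem}_force.csv"
            write_timeseries(s.force, p)
            files["force"] = str(p)
        for ch, trace in s.emg.items():
            p = out_dir / f"{stem}_emg_{ch}.csv"
            write_timeseries(trace, p)
            files[f"emg_{ch}"] = str(p)
        if s.mvc_post:
            p = out_dir / f"{stem}_mvc_post.csv"
            write_timeseries(s.mvc_post[0], p)
            files["mvc_post"] = str(p)
        if s.task_log is not None:
            p = out_dir / f"{stem}_task.jsonl"
            write_task_log(s.task_log, p)
            files["task_log"] = str(p)
        manifest = SessionManifest(
            subject_id=s.subject_id,
            condition=s.condition,
            round_index=s.round_index,
            baseline_mvc=s.baseline_mvc,
            files=files,
        )
        mp = out_dir / f"{stem}_manifest.json"
        write_manifest(manifest, mp)
        manifest_paths.append(mp)
    return manifest_paths
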