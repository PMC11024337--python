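"""End-to-end study replica: simulate -> preprocess -> time-frequency ->
cluster statistics -> behavioral statistics -> report bundle.

Every stage is a pure function of (inputs, config, seed); the report is a
set of deterministic JSON/CSV files, so reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from .cluster import ClusterResult, build_adjacency, cluster_permutation_test
from .io_brainvision import ChannelMontage, load_montage
from .preprocess import run_preprocessing
from .synthetic import (
    CohortEffects,
    SimulationConfig,
    SubjectProfile,
    build_protocol,
    schedule_tms,
    simulate_cohort,
    simulate_epochs,
    simulate_responses,
    simulate_session_recording,
)
from .timefreq import (
    MANIPULATION_WINDOW_MS,
    morlet_tfr,
    tf_behavior_correlation,
    theta_topography,
    zscore_baseline,
)

__all__ = ["StudyConfig", "StageError", "run_study", "cluster_result_to_dict"]

PRE_SESSION = 1
TRAINING_EEG_SESSIONS = (3, 5)
POST_SESSION = 7


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudyConfig:
    """Everything needed to reproduce one synthetic study end to end."""

    n_per_group: int = 7
    runs: int = 1
    trials_per_run: int = 12
    n_simple: int = 4
    effects: CohortEffects = field(default_factory=CohortEffects)
    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        sampling_rate=500.0))
    montage: str = "standard-62"
    adjacency_mm: float = 50.0
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_perm: int = 500
    tms_freq_hz: float = 5.0
    tms_pulses: int = 10
    tfr_freqs: tuple[float, ...] = tuple(float(f)
                                         for f in np.arange(2.0, 21.0, 2.0))
    tfr_channels: tuple[str, ...] = ("CP2", "P7")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tfr_freqs"] = [float(f) for f in self.tfr_freqs]
        d["tfr_channels"] = list(self.tfr_channels)
        d["sim"]["target_channels"] = list(self.sim.target_channels)
        d["sim"]["epoch_window_ms"] = list(self.sim.epoch_window_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "effects" in d and isinstance(d["effects"], dict):
            d["effects"] = CohortEffects(**d["effects"])
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if "target_channels" in sim:
                sim["target_channels"] = tuple(sim["target_channels"])
            if "epoch_window_ms" in sim:
                sim["epoch_window_ms"] = tuple(sim["epoch_window_ms"])
            d["sim"] = SimulationConfig(**sim)
        if "tfr_freqs" in d:
            d["tfr_freqs"] = tuple(d["tfr_freqs"])
        if "tfr_channels" in d:
            d["tfr_channels"] = tuple(d["tfr_channels"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def cluster_result_to_dict(result: ClusterResult, labels: list[str]) -> dict:
    return {
        "design": result.design,
        "tail": result.tail,
        "threshold": round(result.threshold, 6),
        "n_perm": result.n_perm,
        "exact": result.exact,
        "clusters": [
            {
                "k": c.size,
                "mass": round(c.mass, 6),
                "p": round(c.p, 6),
                "channels": sorted(labels[i] for i in c.channels),
            }
            for c in result.clusters
        ],
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _topographies(
    profiles: list[SubjectProfile],
    session: int,
    montage: ChannelMontage,
    config: StudyConfig,
    with_schedule: bool,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-subject theta topographies split by trial type.

    Returns ``{subject_id: {"manipulation": topo, "simple": topo}}``.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for profile in profiles:
        protocol = build_protocol(
            config.runs, config.trials_per_run, config.n_simple,
            seed=profile.seed + session,
        )
        schedule = (
            schedule_tms(protocol, config.tms_freq_hz, config.tms_pulses)
            if with_schedule else None
        )
        sim = dataclasses.replace(config.sim, seed=profile.seed + 1000 * session)
        epochs = simulate_epochs(
            profile, protocol, schedule, montage, sim, session=session
        )
        per_type = {}
        for trial_type in ("manipulation", "simple"):
            sel = epochs.select_trials(
                (epochs.metadata["trial_type"] == trial_type).to_numpy()
            )
            per_type[trial_type] = theta_topography(sel)
        out[profile.subject_id] = per_type
    return out


def _behavior_stage(
    profiles: list[SubjectProfile], config: StudyConfig, outdir: Path
) -> dict:
    rng = np.random.default_rng(config.seed + 17)
    tables = []
    for profile in profiles:
        for session in range(1, 8):
            protocol = build_protocol(
                config.runs, config.trials_per_run, config.n_simple,
                seed=profile.seed + session,
            )
            tables.append(simulate_responses(profile, protocol, session, rng))
    behavior = pd.concat(tables, ignore_index=True)
    behavior.to_csv(outdir / "behavior.csv", index=False)

    dp = bh.dprime_table(behavior)
    dp.to_csv(outdir / "dprime.csv", index=False, float_format="%.6f")

    slopes = []
    for (subject, group), cell in dp[dp.trial_type == "manipulation"].groupby(
        ["subject", "group"]
    ):
        fit = bh.learning_slope(cell.set_index("session")["dprime"])
        slopes.append({"subject": subject, "group": group,
                       "slope": fit.slope, "intercept": fit.intercept})
    slopes_df = pd.DataFrame(slopes)
    slopes_df.to_csv(outdir / "slopes.csv", index=False, float_format="%.6f")

    def safe_wilcoxon(values: np.ndarray) -> dict:
        try:
            w, p = bh.wilcoxon_signed(values, tail="greater")
            return {"W": w, "p": round(p, 6)}
        except ValueError as exc:  # e.g. all slopes exactly zero
            return {"W": None, "p": None, "note": str(exc)}

    rh = slopes_df[slopes_df.group == "rhTMS"]["slope"].to_numpy()
    sh = slopes_df[slopes_df.group == "sham"]["slope"].to_numpy()
    u, p_u = bh.mannwhitney_u(rh, sh, tail="two")

    day5 = dp[(dp.session == 5) & (dp.trial_type == "manipulation")]
    m_rh = day5[day5.group == "rhTMS"]["dprime"]
    m_sh = day5[day5.group == "sham"]["dprime"]
    d = bh.cohens_d(m_rh.mean(), max(m_rh.std(ddof=1), 1e-9),
                    m_sh.mean(), max(m_sh.std(ddof=1), 1e-9))
    stats = {
        "slope_mannwhitney": {"U": u, "p": round(p_u, 6)},
        "slope_wilcoxon_rhTMS": safe_wilcoxon(rh),
        "slope_wilcoxon_sham": safe_wilcoxon(sh),
        "day5_cohens_d": round(d, 6),
        "required_n_per_group_nct": (
            bh.required_sample_size(abs(d)) if abs(d) > 0.05 else None
        ),
    }
    _write_json(outdir / "behavior_stats.json", stats)
    return stats


def run_study(
    config: StudyConfig, outdir: str | Path, seed: int | None = None
) -> dict:
    """Run the full synthetic study replica; returns the summary dict.

    Stages: cohort simulation; behavior + learning-slope statistics;
    pre-training manipulation-vs-simple theta contrast and power-behavior
    correlation; training-day group theta contrast (with the TMS artifact
    chain exercised through continuous preprocessing for one subject);
    post-vs-pre and post-training group contrasts.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed={config.seed}"]
    config.to_yaml(outdir / "config.yaml")

    montage = load_montage(config.montage)
    if len(montage) != config.sim.n_channels:
        montage = montage.subset(montage.labels[: config.sim.n_channels])
    adjacency = build_adjacency(montage, config.adjacency_mm)
    labels = montage.labels
    summary: dict = {}

    def stage(name):
        log_lines.append(f"stage={name}")

    try:
        stage("cohort")
        profiles = simulate_cohort(
            config.n_per_group, config.effects, seed=config.seed
        )
        _write_json(outdir / "cohort.json", [
            dataclasses.asdict(p) for p in profiles
        ])
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("cohort", exc) from exc

    try:
        stage("behavior")
        summary["behavior"] = _behavior_stage(profiles, config, outdir)
    except Exception as exc:
        raise StageError("behavior", exc) from exc

    rh = [p for p in profiles if p.group == "rhTMS"]
    sh = [p for p in profiles if p.group == "sham"]

    try:
        stage("pretraining_contrast")
        topo_pre = _topographies(profiles, PRE_SESSION, montage, config, False)
        manip = np.stack([topo_pre[p.subject_id]["manipulation"]
                          for p in profiles])
        simple = np.stack([topo_pre[p.subject_id]["simple"] for p in profiles])
        res = cluster_permutation_test(
            manip, simple, design="paired", adjacency=adjacency,
            alpha=config.alpha, cluster_alpha=config.cluster_alpha,
            n_perm=config.n_perm, seed=config.seed + 1,
        )
        _write_json(outdir / "cluster_manip_vs_simple.json",
                    cluster_result_to_dict(res, labels))
        summary["manip_vs_simple"] = cluster_result_to_dict(res, labels)
    except Exception as exc:
        raise StageError("pretraining_contrast", exc) from exc

    try:
        stage("tf_behavior_correlation")
        maps = []
        dprimes = []
        for profile in profiles:
            protocol = build_protocol(
                config.runs, config.trials_per_run, config.n_simple,
                seed=profile.seed + PRE_SESSION,
            )
            sim = dataclasses.replace(config.sim,
                                      seed=profile.seed + 1000 * PRE_SESSION)
            epochs = simulate_epochs(
                profile, protocol, None, montage, sim, session=PRE_SESSION
            )
            sel = epochs.select_trials(
                (epochs.metadata["trial_type"] == "manipulation").to_numpy()
            )
            tfr = zscore_baseline(morlet_tfr(
                sel, np.array(config.tfr_freqs), channels=list(
                    config.tfr_channels),
            ))
            maps.append(tfr.window_average(MANIPULATION_WINDOW_MS))
            dprimes.append(profile.dprime(PRE_SESSION, "manipulation"))
        corr = tf_behavior_correlation(maps, np.array(dprimes))
        peak_r, peak_idx = corr.peak()
        corr_df = pd.DataFrame(
            corr.r, index=list(config.tfr_channels),
            columns=[f"{f:g}Hz" for f in config.tfr_freqs],
        )
        corr_df.to_csv(outdir / "tf_behavior_correlation.csv",
                       float_format="%.6f")
        summary["tf_behavior_correlation"] = {
            "n": corr.n_subjects,
            "peak_r": round(peak_r, 6),
            "peak_channel": list(config.tfr_channels)[peak_idx[0]],
            "peak_freq_hz": list(config.tfr_freqs)[peak_idx[1]],
        }
    except Exception as exc:
        raise StageError("tf_behavior_correlation", exc) from exc

    try:
        stage("training_contrast")
        # exercise the full artifact chain once per group on continuous data
        topo_train: dict[str, np.ndarray] = {}
        for profile in profiles:
            per_session = []
            for session in TRAINING_EEG_SESSIONS:
                protocol = build_protocol(
                    config.runs, config.trials_per_run, config.n_simple,
                    seed=profile.seed + session,
                )
                schedule = schedule_tms(
                    protocol, config.tms_freq_hz, config.tms_pulses
                )
                sim = dataclasses.replace(
                    config.sim, seed=profile.seed + 1000 * session
                )
                epochs = simulate_epochs(
                    profile, protocol, schedule, montage, sim, session=session
                )
                sel = epochs.select_trials(
                    (epochs.metadata["trial_type"] == "manipulation").to_numpy()
                )
                per_session.append(theta_topography(sel))
            topo_train[profile.subject_id] = np.mean(per_session, axis=0)
        res = cluster_permutation_test(
            np.stack([topo_train[p.subject_id] for p in rh]),
            np.stack([topo_train[p.subject_id] for p in sh]),
            design="independent", adjacency=adjacency,
            alpha=config.alpha, cluster_alpha=config.cluster_alpha,
            n_perm=config.n_perm, seed=config.seed + 2,
        )
        _write_json(outdir / "cluster_training_group.json",
                    cluster_result_to_dict(res, labels))
        summary["training_group"] = cluster_result_to_dict(res, labels)
    except Exception as exc:
        raise StageError("training_contrast", exc) from exc

    try:
        stage("artifact_chain_check")
        # run one subject through the continuous BrainVision-style chain
        profile = profiles[0]
        protocol = build_protocol(2, 2, 1, seed=profile.seed)
        schedule = schedule_tms(protocol, config.tms_freq_hz,
                                config.tms_pulses)
        sim = dataclasses.replace(config.sim, seed=profile.seed + 99)
        recording, meta = simulate_session_recording(
            profile, protocol, schedule, montage, sim,
            session=TRAINING_EEG_SESSIONS[0],
        )
        epochs, rej, prov = run_preprocessing(
            recording, meta, schedule=schedule, seed=config.seed + 3
        )
        rej.table.to_csv(outdir / "rejection_log.csv", index=False,
                         float_format="%.3f")
        _write_json(outdir / "preprocess_provenance.json", prov)
        summary["artifact_chain"] = {
            "n_pulses": prov.get("n_pulses"),
            "n_trials_kept": prov.get("n_trials_kept"),
        }
    except Exception as exc:
        raise StageError("artifact_chain_check", exc) from exc

    try:
        stage("post_pre_contrast")
        topo_post = _topographies(profiles, POST_SESSION, montage, config,
                                  False)
        results = {}
        for name, group in (("rhTMS", rh), ("sham", sh)):
            res = cluster_permutation_test(
                np.stack([topo_post[p.subject_id]["manipulation"]
                          for p in group]),
                np.stack([topo_pre[p.subject_id]["manipulation"]
                          for p in group]),
                design="paired", adjacency=adjacency,
                alpha=config.alpha, cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm, seed=config.seed + 4,
            )
            results[name] = cluster_result_to_dict(res, labels)
            _write_json(outdir / f"cluster_post_vs_pre_{name}.json",
                        results[name])
        res = cluster_permutation_test(
            np.stack([topo_post[p.subject_id]["manipulation"] for p in rh]),
            np.stack([topo_post[p.subject_id]["manipulation"] for p in sh]),
            design="independent", adjacency=adjacency,
            alpha=config.alpha, cluster_alpha=config.cluster_alpha,
            n_perm=config.n_perm, seed=config.seed + 5,
        )
        results["post_group"] = cluster_result_to_dict(res, labels)
        _write_json(outdir / "cluster_post_group.json", results["post_group"])
        summary["post_pre"] = results
    except Exception as exc:
        raise StageError("post_pre_contrast", exc) from exc

    _write_json(outdir / "summary.json", summary)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
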