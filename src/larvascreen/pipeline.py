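"""Configuration-driven end-to-end runner.

Two input modes: ``simulate`` generates a plate of trajectories from
an arm list and effect library, then runs features -> profiles ->
synergy -> cluster/correlation; ``reanalyze`` starts from an existing
profile matrix on disk (delta table plus optional significance and
p-value companions) and runs only the downstream stages.  A run
writes its artifacts plus a manifest (config echo, seed, content
hashes); identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as _cluster
from . import features as _features
from . import presets
from . import profile_stats as _stats
from . import synergy as _synergy
from .errors import ConfigurationError
from .matrix import ProfileMatrix, read_profile_matrix, write_profile_matrix
from .protocol import StimulusSchedule, WellGeometry, default_schedule, schedule_from_dict
from .simulate import BehaviorParams, DrugEffect, simulate_plate
from .tracks import LarvaTrack, TreatmentArm, write_tracks

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    seed: int = 0
    mode: str = "simulate"  # or "reanalyze"
    schedule: StimulusSchedule = field(default_factory=default_schedule)
    well: WellGeometry = field(default_factory=WellGeometry)
    thresholds: _features.Thresholds = field(default_factory=_features.Thresholds)
    base: BehaviorParams = field(default_factory=BehaviorParams)
    arms: list[TreatmentArm] = field(default_factory=list)
    effects: dict[str, DrugEffect] = field(default_factory=dict)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    n_per_arm: int = 30
    m_comparisons: int | None = None
    tier_min: int = 1
    write_tracks: bool = False
    profile_path: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("out_dir", "seed", "mode", "n_per_arm", "m_comparisons",
                    "tier_min", "write_tracks", "profile_path"):
            if key in data:
                kwargs[key] = data[key]
        sched = data.get("schedule", "default")
        kwargs["schedule"] = (
            default_schedule() if sched == "default" else schedule_from_dict(sched)
        )
        if "well" in data:
            kwargs["well"] = WellGeometry(**data["well"])
        if "thresholds" in data:
            kwargs["thresholds"] = _features.Thresholds(**data["thresholds"])
        if "base" in data:
            kwargs["base"] = BehaviorParams(**data["base"])
        if "arms" in data:
            kwargs["arms"] = [
                TreatmentArm(
                    name=a["name"],
                    role=a["role"],
                    components=tuple(
                        (c["drug"], float(c["dose_uM"]))
                        for c in a.get("components", [])
                    ),
                    n_larvae=a.get("n_larvae"),
                )
                for a in data["arms"]
            ]
        if "effects" in data:
            kwargs["effects"] = {
                drug: DrugEffect(
                    drug,
                    dict(spec.get("offsets", {})),
                    reference_dose_uM=spec.get("reference_dose_uM"),
                )
                for drug, spec in data["effects"].items()
            }
        if "pairs" in data:
            kwargs["pairs"] = [tuple(p) for p in data["pairs"]]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def echo(self) -> dict:
        """JSON-serializable snapshot frozen into the run manifest."""
        from .protocol import schedule_to_dict

        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "mode": self.mode,
            "schedule": schedule_to_dict(self.schedule),
            "well": dataclasses.asdict(self.well),
            "thresholds": dataclasses.asdict(self.thresholds),
            "base": dataclasses.asdict(self.base),
            "arms": [
                {
                    "name": a.name,
                    "role": a.role,
                    "components": [
                        {"drug": d, "dose_uM": dose} for d, dose in a.components
                    ],
                    "n_larvae": a.n_larvae,
                }
                for a in self.arms
            ],
            "effects": {
                k: {"offsets": v.offsets, "reference_dose_uM": v.reference_dose_uM}
                for k, v in self.effects.items()
            },
            "pairs": [list(p) for p in self.pairs],
            "n_per_arm": self.n_per_arm,
            "m_comparisons": self.m_comparisons,
            "tier_min": self.tier_min,
            "write_tracks": self.write_tracks,
            "profile_path": self.profile_path,
        }


def demo_config(out_dir="out", seed: int = 0, n_per_arm: int = 30) -> PipelineConfig:
    """Small three-arm demonstration screen."""
    effects = presets.heart_screen_effects()
    arms = [
        TreatmentArm("DMSO", "vehicle_control", (), n_per_arm),
        TreatmentArm("simvastatin", "single", (("simvastatin", 10.0),), n_per_arm),
        TreatmentArm(
            "simvastatin+csa",
            "combination",
            (("simvastatin", 5.0), (presets.CSA, 5.0)),
            n_per_arm,
        ),
    ]
    return PipelineConfig(
        out_dir=str(out_dir),
        seed=seed,
        arms=arms,
        effects={k: effects[k] for k in ("simvastatin", presets.CSA)},
        pairs=[("simvastatin+csa", "simvastatin")],
        n_per_arm=n_per_arm,
    )


def study_config(out_dir="out", seed: int = 0,
                 n_per_arm: int = presets.N_PER_ARM) -> PipelineConfig:
    """The full 31-arm reference screen (see :mod:`larvascreen.presets`)."""
    return PipelineConfig(
        out_dir=str(out_dir),
        seed=seed,
        arms=presets.heart_screen_arms(n_per_arm),
        effects=presets.heart_screen_effects(),
        pairs=presets.heart_screen_pairs(),
        n_per_arm=n_per_arm,
    )


def validate(config: PipelineConfig) -> list[str]:
    """Schema and referential checks; empty list iff runnable."""
    findings: list[str] = []
    sim_inputs = bool(config.arms)
    re_inputs = config.profile_path is not None
    if config.mode not in ("simulate", "reanalyze"):
        findings.append(f"unknown mode {config.mode!r}")
    if sim_inputs and re_inputs:
        findings.append("both simulation arms and profile_path are set")
    if config.mode == "simulate":
        if not config.arms:
            findings.append("simulate mode needs arms")
        else:
            vehicles = [a for a in config.arms if a.role == "vehicle_control"]
            if len(vehicles) != 1:
                findings.append(
                    f"need exactly one vehicle_control arm, found {len(vehicles)}"
                )
            for arm in config.arms:
                for drug, _ in arm.components:
                    if drug not in config.effects:
                        findings.append(
                            f"arm {arm.name!r} references unknown drug {drug!r}"
                        )
        arm_names = {a.name for a in config.arms}
    else:
        if config.profile_path is None:
            findings.append("reanalyze mode needs profile_path")
        arm_names = None
    if arm_names is not None:
        for combo, single in config.pairs:
            for label in (combo, single):
                if label not in arm_names:
                    findings.append(f"synergy pair references unknown arm {label!r}")
    if config.tier_min not in (1, 2, 3):
        findings.append(f"tier_min must be 1, 2 or 3, got {config.tier_min}")
    return findings


# -- stages ---------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> list[LarvaTrack]:
    return simulate_plate(
        config.arms, config.effects, config.base, config.schedule,
        config.well, config.n_per_arm, config.seed,
    )


def stage_features(config: PipelineConfig, tracks: list[LarvaTrack]) -> pd.DataFrame:
    return _features.features_table(
        tracks, config.schedule, config.well, config.thresholds
    )


def stage_profiles(config: PipelineConfig, features: pd.DataFrame) -> ProfileMatrix:
    return _stats.build_profiles(features, config.arms, config.m_comparisons)


def stage_synergy(config: PipelineConfig, profiles: ProfileMatrix):
    return _synergy.synergy_table(profiles, config.pairs, config.tier_min)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the applicable stage chain; returns the run manifest."""
    findings = validate(config)
    if findings:
        raise ConfigurationError("; ".join(findings))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    artifacts: dict[str, str] = {}
    try:
        if config.mode == "simulate":
            stage = "simulate"
            tracks = stage_simulate(config)
            if config.write_tracks:
                artifacts["tracks"] = str(
                    emit("tracks.csv", lambda p: write_tracks(tracks, p))
                )
            stage = "features"
            feats = stage_features(config, tracks)
            artifacts["features"] = str(
                emit("features.csv", lambda p: _features.write_features(feats, p))
            )
            stage = "profiles"
            profiles = stage_profiles(config, feats)
            artifacts["profiles"] = str(
                emit("profiles.csv", lambda p: write_profile_matrix(profiles, p))
            )
            artifacts["profiles_sig"] = str(out / "profiles_sig.csv")
            artifacts["profiles_p"] = str(out / "profiles_p.csv")
            written.extend([out / "profiles_sig.csv", out / "profiles_p.csv"])
        else:
            stage = "read_profiles"
            profiles = read_profile_matrix(config.profile_path)

        stage = "synergy"
        if config.pairs:
            reports = stage_synergy(config, profiles)
            artifacts["synergy"] = str(
                emit("synergy.csv", lambda p: _synergy.write_synergy(reports, p))
            )
        stage = "cluster"
        dend = _cluster.hcluster(profiles)
        paths = _cluster.export_heatmap_tables(profiles, dend, out / "cluster")
        artifacts.update(paths)
        written.extend(Path(p) for p in paths.values())
        stage = "correlation"
        corr = _cluster.pearson_matrix(profiles)
        artifacts["correlation"] = str(
            emit("correlation.csv", lambda p: corr.to_csv(p, index_label="treatment"))
        )
    except Exception as exc:  # clean partial outputs, surface stage name
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "config": config.echo(),
        "artifacts": artifacts,
        "sha256": {
            name: _sha256(Path(path)) for name, path in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
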