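"""End-to-end pipeline driver: simulate → metrics → MD fit → compare.

One YAML config describes a set of synthetic cohorts (by preset name or
explicit model parameters), the metric thresholds, and the comparison to
run; :func:`run_pipeline` executes the stages in order, writes every
artifact under the output directory and returns a manifest with SHA-256
hashes.  The run seed is spawned into independent per-cohort seeds, so a
rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import displacement, metrics, stats
from .errors import ConfigError, PipelineError
from .presets import PRESETS, preset_regime
from .simulate import SimConfig, simulate_trackset
from .tracks import write_tracks

log = logging.getLogger("ivtrack.pipeline")

_RUN_KEYS = {
    "version", "seed", "output_dir", "cohorts", "metrics", "md_fit",
    "compare", "overwrite", "log_level",
}
_METRIC_KEYS = {"arrest_threshold", "immotile_threshold", "project_2d"}
_MD_KEYS = {"min_cells_per_point", "r2_threshold"}
_COMPARE_KEYS = {"metric", "adjust"}


@dataclass(frozen=True)
class CohortSpec:
    name: str
    preset: str | None = None
    config: SimConfig | None = None
    n_tracks: int | None = None

    def resolve(self, seed: int) -> SimConfig:
        if self.preset is not None:
            return preset_regime(self.preset, seed=seed, n_tracks=self.n_tracks)
        assert self.config is not None
        cfg = self.config.replace(seed=seed)
        if self.n_tracks is not None:
            cfg = cfg.replace(n_tracks=self.n_tracks)
        return cfg


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration; all defaults surfaced explicitly."""

    cohorts: tuple[CohortSpec, ...]
    output_dir: Path
    seed: int = 0
    arrest_threshold: float = metrics.DEFAULT_SPEED_THRESHOLD
    immotile_threshold: float = metrics.DEFAULT_SPEED_THRESHOLD
    project_2d: bool = True
    min_cells_per_point: int = 5
    r2_threshold: float = displacement.RANDOM_WALK_R2
    compare_metric: str = "mean_velocity_um_min"
    adjust: str = "bonferroni"
    overwrite: bool = False
    log_level: str = "INFO"


@dataclass(frozen=True)
class PipelineResult:
    manifest: dict[str, str]  # relative path -> sha256
    report_path: Path
    summaries: dict[str, dict] = field(default_factory=dict)


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a mapping")
    _check_keys(raw, _RUN_KEYS, "pipeline config")
    if raw.get("version", 1) != 1:
        raise ConfigError("unsupported config version (expected 1)")
    cohorts_raw = raw.get("cohorts")
    if not cohorts_raw:
        raise ConfigError("pipeline config needs a non-empty 'cohorts' list")
    cohorts = []
    for entry in cohorts_raw:
        if not isinstance(entry, dict):
            raise ConfigError("each cohort entry must be a mapping")
        if "preset" in entry:
            name = entry.get("name", entry["preset"])
            if entry["preset"] not in PRESETS:
                raise ConfigError(
                    f"unknown preset {entry['preset']!r}; "
                    f"available: {sorted(PRESETS)}"
                )
            cohorts.append(
                CohortSpec(
                    name=name,
                    preset=entry["preset"],
                    n_tracks=entry.get("n_tracks"),
                )
            )
        else:
            if "name" not in entry or "model" not in entry:
                raise ConfigError(
                    "explicit cohort entries need 'name' and 'model' keys"
                )
            cfg = SimConfig(
                model=entry["model"],
                params=entry.get("params", {}),
                n_tracks=int(entry.get("n_tracks", 100)),
                n_frames=int(entry.get("n_frames", 31)),
                frame_interval=float(entry.get("frame_interval", 0.5)),
                dim=int(entry.get("dim", 2)),
                labels=entry.get("labels", {}),
            )
            cohorts.append(CohortSpec(name=entry["name"], config=cfg))
    names = [c.name for c in cohorts]
    if len(set(names)) != len(names):
        raise ConfigError("cohort names must be unique")
    m = raw.get("metrics", {})
    _check_keys(m, _METRIC_KEYS, "metrics section")
    md = raw.get("md_fit", {})
    _check_keys(md, _MD_KEYS, "md_fit section")
    cmp_ = raw.get("compare", {})
    _check_keys(cmp_, _COMPARE_KEYS, "compare section")
    return RunConfig(
        cohorts=tuple(cohorts),
        output_dir=Path(raw.get("output_dir", "ivtrack_run")),
        seed=int(raw.get("seed", 0)),
        arrest_threshold=float(m.get("arrest_threshold", 2.0)),
        immotile_threshold=float(m.get("immotile_threshold", 2.0)),
        project_2d=bool(m.get("project_2d", True)),
        min_cells_per_point=int(md.get("min_cells_per_point", 5)),
        r2_threshold=float(md.get("r2_threshold", displacement.RANDOM_WALK_R2)),
        compare_metric=cmp_.get("metric", "mean_velocity_um_min"),
        adjust=cmp_.get("adjust", "bonferroni"),
        overwrite=bool(raw.get("overwrite", False)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _out_path(config: RunConfig, name: str) -> Path:
    path = config.output_dir / name
    if path.exists() and not config.overwrite:
        raise PipelineError(
            f"output {path} exists; pass overwrite: true to replace it"
        )
    return path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; any stage failure aborts naming the stage."""
    logging.basicConfig(level=config.log_level)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summaries: dict[str, dict] = {}
    report_lines: list[str] = []
    cohort_seeds = [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(config.seed).spawn(len(config.cohorts))
    ]
    group_values: dict[str, np.ndarray] = {}

    for spec, seed in zip(config.cohorts, cohort_seeds):
        stage = f"simulate[{spec.name}]"
        try:
            ts = simulate_trackset(spec.resolve(seed))
            tracks_path = _out_path(config, f"tracks_{spec.name}.csv")
            write_tracks(ts, tracks_path)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage wrapper
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        manifest[tracks_path.name] = _sha256(tracks_path)
        log.info("%s: %d tracks", stage, len(ts))

        stage = f"metrics[{spec.name}]"
        try:
            cm = metrics.cohort_metrics(
                ts,
                arrest_threshold=config.arrest_threshold,
                immotile_threshold=config.immotile_threshold,
                project_2d=config.project_2d,
            )
            metrics_path = _out_path(config, f"metrics_{spec.name}.csv")
            cm.per_track.to_csv(metrics_path, index=False)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        manifest[metrics_path.name] = _sha256(metrics_path)
        mv = cm.summary.loc["mean_velocity_um_min"]
        report_lines.append(
            f"cohort {spec.name}: mean velocity {mv['mean']:.2f} ± "
            f"{mv['sd']:.2f} um/min (n = {int(mv['n'])} cells)"
        )
        group_values[spec.name] = cm.per_track[
            config.compare_metric
        ].dropna().to_numpy()
        summaries[spec.name] = {
            "summary": cm.summary.to_dict(orient="index"),
            "n_excluded_short": cm.n_excluded_short,
            "n_confinement_undefined": cm.n_confinement_undefined,
        }

        stage = f"md-fit[{spec.name}]"
        try:
            curve = displacement.mean_displacement_curve(ts)
            fit = displacement.fit_md_sqrt_time(
                curve,
                min_cells_per_point=config.min_cells_per_point,
                r2_threshold=config.r2_threshold,
            )
            curve_path = _out_path(config, f"mdcurve_{spec.name}.csv")
            import pandas as pd

            pd.DataFrame(
                {
                    "t_min": curve.times,
                    "sqrt_t": curve.sqrt_times,
                    "md_um": curve.md,
                    "n_cells": curve.n_cells,
                }
            ).to_csv(curve_path, index=False)
            fit_path = _out_path(config, f"mdfit_{spec.name}.json")
            fit_path.write_text(json.dumps(fit.__dict__, indent=2))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        manifest[curve_path.name] = _sha256(curve_path)
        manifest[fit_path.name] = _sha256(fit_path)
        report_lines.append(
            f"cohort {spec.name}: MD-vs-sqrt(t) R^2 = {fit.r_squared:.4f} "
            f"({'random walk' if fit.is_random_walk else 'not random walk'})"
        )

    if len(group_values) >= 2:
        stage = "compare"
        try:
            result = stats.compare_groups(group_values, adjust=config.adjust)
            cmp_path = _out_path(config, "comparison.json")
            cmp_path.write_text(
                json.dumps(
                    {
                        "test_name": result.test_name,
                        "metric": config.compare_metric,
                        "statistic": result.statistic,
                        "pvalue": result.pvalue,
                        "pairwise": result.pairwise.to_dict(orient="records"),
                    },
                    indent=2,
                )
            )
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        manifest[cmp_path.name] = _sha256(cmp_path)
        report_lines.append(
            f"comparison ({config.compare_metric}): {result.test_name}, "
            f"p = {result.pvalue:.3g}"
        )

    report_path = _out_path(config, "report.txt")
    report_path.write_text("\n".join(report_lines) + "\n")
    manifest[report_path.name] = _sha256(report_path)
    manifest_path = config.output_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        manifest=manifest, report_path=report_path, summaries=summaries
    )
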