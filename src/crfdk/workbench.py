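"""Study orchestration: configuration, seeding, manifests, report assembly.

Two studies tie the modules together.  The *theoretical* study sweeps the
functional x condition grids through the Monte-Carlo simulator, profiles each
condition, and locates the per-scale error/time trade-off points.  The
*validation* study takes a rich spike table (synthetic or recorded), builds
per-unit reference CRFs, scores an explicit pattern list by subsampling,
ranks patterns, extracts cross-error consensus patterns, and runs the
growing-window dynamic analysis.

All randomness flows from one root seed through named sub-streams (``sweep``,
``subsample``, ``bootstrap``, ``cohort``), so partial reruns are stable, and
every run writes a manifest recording its seeds and counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design, validation
from .design import (
    TABLE1_CONDITIONS,
    TABLE1_FUNCTIONAL,
    Pattern,
    enumerate_patterns,
    find_tradeoff_point,
    functional_grid,
    recording_time,
    run_monte_carlo,
)
from .io import read_spike_table
from .validation import (
    ERROR_KINDS,
    build_ground_truth,
    consensus_patterns,
    dynamic_window_errors,
    rank_patterns,
    recordings_from_table,
    subsample_pattern_errors,
    unit_inclusion_filter,
)

__all__ = ["RunConfig", "run_theoretical_study", "run_validation_study", "substream"]

logger = logging.getLogger("crfdk")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random sub-stream derived from the root seed."""
    key = int.from_bytes(name.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def substream_seed(seed: int, name: str) -> int:
    """A small integer seed for APIs that take one (derived, stable, < 2**31)."""
    key = int.from_bytes(name.encode(), "little") % (2**31)
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,)).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Configuration of one study run; serializable to/from YAML."""

    study: str = "theoretical"  # theoretical | validation | dynamic
    seed: int = 0
    functional: dict = field(default_factory=lambda: {k: list(v) for k, v in TABLE1_FUNCTIONAL.items()})
    conditions: dict = field(default_factory=lambda: {k: list(v) for k, v in TABLE1_CONDITIONS.items()})
    scales: list = field(default_factory=lambda: list(range(1, 11)))
    n_replicates: int = 1
    n_restarts: int = 10
    n_iterations: int = 100
    patterns: list | None = None  # [[n_points, n_trials, trial_length], ...]
    windows: list = field(default_factory=lambda: [0.5, 1.0, 2.0, 3.0, 4.0])
    n_bootstrap: int = 1000
    trial_length: float = 4.0
    n_trials: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        errors = []
        if self.study not in ("theoretical", "validation", "dynamic"):
            errors.append(f"unknown study {self.study!r}")
        for key in ("n_points", "n_trials", "trial_length"):
            if not self.conditions.get(key):
                errors.append(f"empty condition grid: {key}")
        for key in ("r_max", "c50", "b", "n"):
            if not self.functional.get(key):
                errors.append(f"empty functional grid: {key}")
        if not self.scales:
            errors.append("no scales selected")
        if self.n_replicates < 1:
            errors.append("n_replicates must be >= 1")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def pattern_list(self) -> list[Pattern]:
        if self.patterns is not None:
            return [Pattern(int(p), int(t), float(L)) for p, t, L in self.patterns]
        return enumerate_patterns(self.conditions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(s)
        return s


def _write_manifest(out_dir: Path, manifest: dict) -> Path:
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def run_theoretical_study(config: RunConfig, out_dir) -> dict:
    """Sweep -> condition profiles -> per-scale trade-off points; write CSV/JSON."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    functional = functional_grid(config.functional)
    patterns = config.pattern_list()
    logger.info(
        "theoretical study: %d functional combos x %d patterns x %d scales x %d replicates",
        len(functional), len(patterns), len(config.scales), config.n_replicates,
    )
    mc = run_monte_carlo(
        functional=functional,
        patterns=patterns,
        scales=config.scales,
        n_replicates=config.n_replicates,
        seed=substream_seed(config.seed, "sweep"),
        n_restarts=config.n_restarts,
    )
    mc.table.to_csv(out / "sweep.csv", index=False)

    profiles = {}
    for condition in ("n_points", "n_trials", "trial_length"):
        if len(set(p_vals := [getattr(p, condition) for p in patterns])) >= 2:
            try:
                prof = design.condition_profiles(mc, condition)
                prof.to_csv(out / f"profile_{condition}.csv", index=False)
                profiles[condition] = str(out / f"profile_{condition}.csv")
            except ValueError:
                logger.info("profile for %s skipped (defaults not in sweep)", condition)

    tradeoffs = {}
    for sid in config.scales:
        pe = mc.pattern_errors(scale_id=sid)
        if len(pe) >= 2:
            pats = [
                Pattern(int(r.n_points), int(r.n_trials), float(r.trial_length))
                for r in pe.itertuples()
            ]
            tp = find_tradeoff_point(
                pe["error"].to_numpy(), pe["recording_time_s"].to_numpy(), pats
            )
            tradeoffs[sid] = {
                "pattern": list(tp.pattern.as_tuple()),
                "recording_time_s": tp.time_s,
                "index": tp.index,
                "crossed": tp.crossed,
            }
    (out / "tradeoffs.json").write_text(json.dumps(tradeoffs, indent=2))

    manifest = {
        "study": "theoretical",
        "seed": config.seed,
        "sweep_seed": substream_seed(config.seed, "sweep"),
        "n_functional": len(functional),
        "n_patterns": len(patterns),
        "scales": list(config.scales),
        "n_replicates": config.n_replicates,
        "n_failed_fits": mc.n_failed,
        "outputs": {
            "sweep": str(out / "sweep.csv"),
            "tradeoffs": str(out / "tradeoffs.json"),
            "profiles": profiles,
        },
        "config": asdict(config),
    }
    _write_manifest(out, manifest)
    return manifest


def run_validation_study(config: RunConfig, spike_table, out_dir) -> dict:
    """Ground-truth subsampling study on a spike table; writes scores + consensus."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if isinstance(spike_table, (str, Path)):
        spike_table = read_spike_table(spike_table)
    recordings = recordings_from_table(
        spike_table, trial_length=config.trial_length, n_trials=config.n_trials
    )
    included = [r for r in recordings if unit_inclusion_filter(r)]
    logger.info("cohort: %d units, %d pass the inclusion filter", len(recordings), len(included))
    if not included:
        raise ValueError("empty cohort: every unit is below the inclusion threshold")

    truths = {}
    for rec in included:
        gt = build_ground_truth(
            rec,
            n_restarts=config.n_restarts,
            seed=substream(config.seed, f"truth-{rec.unit_id}"),
        )
        truths[rec.unit_id] = gt
        logger.debug("unit %s ground truth: %s", rec.unit_id, gt.params)

    patterns = config.pattern_list()
    score_rows = []
    best_lists: dict[str, list] = {k: [] for k in ERROR_KINDS}
    for rec in included:
        gt = truths[rec.unit_id]
        for sid in config.scales:
            scores = []
            for pat in patterns:
                try:
                    score = subsample_pattern_errors(
                        rec,
                        gt.params,
                        pat,
                        sid,
                        n_iterations=config.n_iterations,
                        seed=substream(
                            config.seed, f"subsample-{rec.unit_id}-{sid}-{pat}"
                        ),
                        n_restarts=config.n_restarts,
                    )
                except validation.InfeasiblePatternError:
                    continue
                scores.append(score)
                m = score.mean
                score_rows.append(
                    {
                        "unit_id": rec.unit_id,
                        "scale_id": sid,
                        "n_points": pat.n_points,
                        "n_trials": pat.n_trials,
                        "trial_length": pat.trial_length,
                        "recording_time_s": recording_time(pat),
                        **m.as_dict(),
                    }
                )
            if len(scores) >= 1:
                for kind in ERROR_KINDS:
                    _, best = rank_patterns(scores, error_kind=kind)
                    best_lists[kind].append(best)
    scores_df = pd.DataFrame(score_rows)
    scores_df.to_csv(out / "pattern_scores.csv", index=False)

    report = consensus_patterns(best_lists)
    (out / "consensus.json").write_text(json.dumps(report.to_dict(), indent=2))

    dyn = dynamic_window_errors(
        included,
        [truths[r.unit_id].params for r in included],
        config.windows,
        n_bootstrap=config.n_bootstrap,
        seed=substream(config.seed, "bootstrap"),
        n_restarts=config.n_restarts,
    )
    dyn.to_csv(out / "dynamic_windows.csv", index=False)

    manifest = {
        "study": "validation",
        "seed": config.seed,
        "n_units": len(recordings),
        "n_included": len(included),
        "n_patterns": len(patterns),
        "scales": list(config.scales),
        "n_iterations": config.n_iterations,
        "outputs": {
            "pattern_scores": str(out / "pattern_scores.csv"),
            "consensus": str(out / "consensus.json"),
            "dynamic_windows": str(out / "dynamic_windows.csv"),
        },
        "config": asdict(config),
    }
    _write_manifest(out, manifest)
    return manifest
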