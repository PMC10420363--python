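"""End-to-end experiment orchestration.

simulate -> patient-stratified split -> train the two detectors (IC, FO)
-> detect on the test set with both the recurrent models and the
velocity-threshold baseline -> evaluate per pathology and compare methods.
Every stochastic stage takes an explicit seed, so a config reproduces its
report byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import evaluation, heuristic, postprocess
from .detector import ModelConfig, build_model, train
from .evaluation import EvaluationConfig, MatchResult
from .features import make_training_batches
from .gait_core import Dataset, EventType, Split, split_dataset
from .heuristic import HeuristicConfig
from .postprocess import PostprocessConfig, detect_events_for_trial
from .synthetic_gait import PRESET_PROFILES, CohortSpec, GaitProfile, simulate_cohort

__all__ = ["ExperimentConfig", "run_experiment", "cohort_spec_from_dict"]

REPORT_SCHEMA_VERSION = 1


def cohort_spec_from_dict(raw: dict) -> CohortSpec:
    """Build a CohortSpec from its JSON form.

    Each entry gives either a ``preset`` name (optionally with field
    overrides) or a full ``profile`` object, plus ``n_subjects`` and
    ``trials_per_subject``.
    """
    profiles = []
    for entry in raw["profiles"]:
        if "preset" in entry:
            profile = PRESET_PROFILES[entry["preset"]]
            overrides = entry.get("overrides", {})
            if overrides:
                profile = replace(profile, **overrides)
        else:
            profile = GaitProfile(**entry["profile"])
        profiles.append((profile, int(entry["n_subjects"]), int(entry["trials_per_subject"])))
    return CohortSpec(profiles=tuple(profiles), seed=int(raw.get("seed", 0)))


@dataclass
class ExperimentConfig:
    cohort: CohortSpec
    ic_model: ModelConfig = field(default_factory=lambda: ModelConfig(etype=EventType.IC))
    fo_model: ModelConfig = field(default_factory=lambda: ModelConfig(etype=EventType.FO))
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    heuristic: HeuristicConfig = field(default_factory=HeuristicConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    split_fractions: tuple[float, float, float] = (0.6, 0.1, 0.3)
    holdout_classes: tuple[str, ...] = ()
    split_seed: int = 0
    batch_seed: int = 0
    fit_heuristic: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        kw: dict = {"cohort": cohort_spec_from_dict(raw["cohort"])}
        if "ic_model" in raw:
            kw["ic_model"] = ModelConfig(etype="IC", **raw["ic_model"])
        if "fo_model" in raw:
            kw["fo_model"] = ModelConfig(etype="FO", **raw["fo_model"])
        for key, typ in (
            ("postprocess", PostprocessConfig),
            ("heuristic", HeuristicConfig),
            ("evaluation", EvaluationConfig),
        ):
            if key in raw:
                kw[key] = typ(**raw[key])
        for key in ("split_seed", "batch_seed", "fit_heuristic"):
            if key in raw:
                kw[key] = raw[key]
        if "split_fractions" in raw:
            kw["split_fractions"] = tuple(raw["split_fractions"])
        if "holdout_classes" in raw:
            kw["holdout_classes"] = tuple(raw["holdout_classes"])
        return cls(**kw)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"experiment stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def _evaluate_group(results: list[MatchResult]) -> dict:
    combined = MatchResult.combine(results)
    out = {
        "n_truth_events": len(combined.matches),
        "n_tp": combined.n_tp,
        "n_fp": combined.n_fp,
        "n_fn": combined.n_fn,
        "n_spurious": len(combined.spurious),
    }
    if combined.n_tp + combined.n_fp + combined.n_fn:
        out["detection_rate"] = evaluation.detection_rate(combined)
    if combined.n_matched:
        mae, lo, hi, n = evaluation.temporal_error_summary(combined, seed=0)
        out.update(mae_ms=mae, ci95=[lo, hi], n_matched=n)
        out["cumulative_detection"] = {
            str(w): v
            for w, v in evaluation.cumulative_detection_curve(combined).items()
        }
    return out


def run_experiment(config: ExperimentConfig, outdir=None) -> dict:
    """Run the full experiment; returns (and optionally writes) the report."""
    with _stage("simulate"):
        dataset = simulate_cohort(config.cohort)
    with _stage("split"):
        dataset = split_dataset(
            dataset,
            fractions=config.split_fractions,
            holdout_classes=config.holdout_classes,
            seed=config.split_seed,
        )
        train_trials = dataset.trials_in(Split.TRAIN)
        val_trials = dataset.trials_in(Split.VAL)
        test_trials = dataset.trials_in(Split.TEST)

    models = {}
    for etype, cfg in ((EventType.IC, config.ic_model), (EventType.FO, config.fo_model)):
        with _stage(f"train-{etype.value}"):
            rng = np.random.default_rng(config.batch_seed)
            batches = make_training_batches(
                train_trials, etype, cfg.weight_ratio, rng, cfg.batch_size
            )
            val_batches = make_training_batches(
                val_trials, etype, cfg.weight_ratio, rng, cfg.batch_size
            )
            models[etype] = train(build_model(cfg), batches, val_batches, cfg)

    with _stage("heuristic-fit"):
        heur_cfg = (
            heuristic.fit_thresholds(train_trials, base_config=config.heuristic)
            if config.fit_heuristic
            else config.heuristic
        )

    with _stage("detect"):
        per_method: dict[str, dict[EventType, dict[str, list[MatchResult]]]] = {
            "model": {e: {} for e in EventType},
            "heuristic": {e: {} for e in EventType},
        }
        for trial in test_trials:
            heur_events = heuristic.detect_events_heuristic(trial, heur_cfg)
            for etype in EventType:
                model_events = detect_events_for_trial(
                    models[etype], trial, config.postprocess
                )
                for method, events in (("model", model_events), ("heuristic", heur_events)):
                    preds = [e for e in events if e.etype == etype]
                    res = evaluation.match_trial(preds, trial, etype, config.evaluation)
                    per_method[method][etype].setdefault(trial.pathology, []).append(res)

    with _stage("evaluate"):
        report: dict = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seeds": {
                "cohort": config.cohort.seed,
                "split": config.split_seed,
                "batch": config.batch_seed,
                "ic_model": config.ic_model.seed,
                "fo_model": config.fo_model.seed,
            },
            "zero_shot_classes": sorted(config.holdout_classes),
            "n_trials": {
                "train": len(train_trials),
                "val": len(val_trials),
                "test": len(test_trials),
            },
            "heuristic_config": {
                "th_ic": heur_cfg.th_ic,
                "th_fo_factor": heur_cfg.th_fo_factor,
            },
            "methods": {},
        }
        for method, by_etype in per_method.items():
            report["methods"][method] = {}
            for etype, by_path in by_etype.items():
                all_results = [r for rs in by_path.values() for r in rs]
                report["methods"][method][etype.value] = {
                    "overall": _evaluate_group(all_results),
                    "by_pathology": {
                        p: _evaluate_group(rs) for p, rs in sorted(by_path.items())
                    },
                }

    with _stage("statistics"):
        report["statistics"] = {}
        for etype in EventType:
            paired_a, paired_b = _paired_errors(
                per_method["model"][etype], per_method["heuristic"][etype]
            )
            if len(paired_a) >= 5:
                report["statistics"][etype.value] = evaluation.compare_methods(
                    paired_a, paired_b, n_comparisons=3
                )

    if outdir is not None:
        _write_report(report, outdir)
    return report


def _paired_errors(model_groups, heur_groups):
    """Pair per-truth-event absolute errors of the two methods (events both matched)."""
    a, b = [], []
    for pathology in sorted(model_groups):
        if pathology not in heur_groups:
            continue
        for rm, rh in zip(model_groups[pathology], heur_groups[pathology]):
            em = {m.truth_frame: m.abs_error_ms for m in rm.matches if m.error_ms is not None}
            eh = {m.truth_frame: m.abs_error_ms for m in rh.matches if m.error_ms is not None}
            for frame in sorted(set(em) & set(eh)):
                a.append(em[frame])
                b.append(eh[frame])
    return np.array(a), np.array(b)


def _write_report(report: dict, outdir) -> None:
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    # CSV tables: method x pathology -> MAE (CI), detection rate; one per event type
    for etype in ("IC", "FO"):
        rows = []
        for method, per in report["methods"].items():
            for pathology, cell in per[etype]["by_pathology"].items():
                rows.append(
                    {
                        "method": method,
                        "pathology": pathology,
                        "mae_ms": cell.get("mae_ms"),
                        "ci95_low": cell.get("ci95", [None, None])[0],
                        "ci95_high": cell.get("ci95", [None, None])[1],
                        "detection_rate": cell.get("detection_rate"),
                        "n_truth_events": cell["n_truth_events"],
                    }
                )
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, f"temporal_error_{etype}.csv"), index=False
        )
    with open(os.path.join(outdir, "log.txt"), "w") as fh:
        import scipy

        fh.write(f"numpy {np.__version__}\nscipy {scipy.__version__}\n")
        fh.write(f"report schema {REPORT_SCHEMA_VERSION}\n")
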