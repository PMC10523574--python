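"""Config-driven orchestration of the full distillation experiment.

Stages: generate -> featurize/scale -> teachers -> federate -> students
-> evaluate. Each stage persists its artifacts under the run directory
keyed by the config hash, so re-running with the same config + seed
reproduces every CSV byte-for-byte and individual stages can be driven
from the command line. A manifest records the sha256 of every tabular
output; wall-clock stage logs live in a separate file so they never
perturb the comparable outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem_features as cf
from . import federation, student_models
from .evaluation import MetricsReport, ad_trend, class_ratio, evaluate_model
from .synthetic_data import Dataset, SyntheticWorld, WorldConfig, generate_world
from .teacher_models import (
    TrainedClassifier,
    load_bundle,
    optimize_hyperparameters,
    save_bundle,
    train_teacher,
)

__all__ = ["RunConfig", "RunContext", "run_experiment", "STAGES"]

STAGES = ("generate", "featurize", "teachers", "federate", "students", "evaluate")


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment end to end."""

    world: WorldConfig = field(default_factory=WorldConfig)
    teacher_architecture: str = "xgb"
    teacher_hyperparameters: dict = field(default_factory=dict)
    hpo_enabled: bool = False
    hpo_budget: int = 10
    hpo_k: int = 5
    hpo_repeats: int = 2
    oversample_ratio: float | None = None
    n_per_class: int = 500
    # Consolidated k-NN Tanimoto reliability separates chemistry no member
    # has trained on (~0.03-0.05) from chemistry at least one member knows
    # (>= ~0.15); the default filter excludes only the former — distilling
    # single-member knowledge to the others is the point of federation.
    # The platform-scale value 0.005 remains build_federated_set's own
    # default.
    reliability_min: float = 0.08
    decidability_min: float | None = None
    consolidation_rule: str = "decidability_weighted"
    reliability_k: int = 5
    student_variants: tuple[str, ...] = ("T", "HI", "HF", "PI", "RI", "F", "RF")
    student_base_architecture: str = "xgb"
    student_hyperparameters: dict = field(default_factory=dict)
    # AD evaluation mirrors the federation filter: reliability-thresholded
    # by default, decidability threshold off (0) unless an experiment
    # turns it on.
    eval_reliability_min: float = 0.2
    eval_decidability_min: float = 0.0
    scaling: str = "joint"  # "joint" (classic, mild leakage) or "train_only" (strict)
    write_world_csv: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scaling not in ("joint", "train_only"):
            raise ValueError("scaling must be 'joint' or 'train_only'")
        unknown = [v for v in self.student_variants if v not in student_models.VARIANT_TABLE]
        if unknown:
            raise ValueError(f"unknown student variants: {unknown}")
        self.world.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["student_variants"] = list(self.student_variants)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "world" in d and isinstance(d["world"], dict):
            d["world"] = WorldConfig(**d["world"])
        if "student_variants" in d:
            d["student_variants"] = tuple(d["student_variants"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunContext:
    """In-memory state + on-disk artifacts of one run directory."""

    def __init__(self, config: RunConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.world: SyntheticWorld | None = None
        self.features: dict[str, cf.FeatureMatrix] = {}
        self.teachers: dict[str, TrainedClassifier] = {}
        self.member_predictions: dict[str, pd.DataFrame] = {}
        self.consolidated: pd.DataFrame | None = None
        self.federated: federation.FederatedSet | None = None
        self.students: dict[tuple[str, str], TrainedClassifier] = {}
        self.reports: list[MetricsReport] = []
        self.stage_log: list[dict] = []
        self.warnings: list[str] = []
        (self.outdir / "config.yaml").write_text(
            yaml.safe_dump({"config_hash": config.config_hash, **config.to_dict()})
        )

    # -- helpers ----------------------------------------------------------

    def path(self, *parts) -> Path:
        p = self.outdir.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def write_csv(self, df: pd.DataFrame, *parts) -> Path:
        p = self.path(*parts)
        with open(p, "w") as fh:
            fh.write(f"# config_hash={self.config.config_hash}\n")
            df.to_csv(fh, index=False)
        return p

    def log_stage(self, stage: str, t0: float, outputs: list[str], warnings: list[str]):
        self.stage_log.append(
            {"stage": stage, "wall_time_s": round(time.time() - t0, 3),
             "outputs": outputs, "warnings": warnings}
        )
        self.warnings.extend(warnings)


def _dataset_items(world: SyntheticWorld) -> list[tuple[str, Dataset]]:
    items = [(f"{pid}-train", world.partner_train[pid]) for pid in world.partner_ids]
    items += [(f"{pid}-test", world.partner_test[pid]) for pid in world.partner_ids]
    items.append(("public", world.public))
    items.append(("pool", world.pool))
    if world.pool_eval is not None:
        items.append(("pool-eval", world.pool_eval))
    return items


# -- stages ----------------------------------------------------------------


def stage_generate(ctx: RunContext) -> None:
    t0 = time.time()
    ctx.world = generate_world(ctx.config.world)
    outputs = []
    if ctx.config.write_world_csv:
        for name, ds in _dataset_items(ctx.world):
            p = ctx.path("world", f"{name}.csv")
            cf.write_molecule_csv(ds.records, p)
            outputs.append(str(p))
        meta = ctx.path("world", "metadata.json")
        meta.write_text(json.dumps(ctx.world.generator_metadata, indent=2, default=str))
        outputs.append(str(meta))
    ctx.log_stage("generate", t0, outputs, list(ctx.world.warnings))


def stage_featurize(ctx: RunContext) -> None:
    """Featurize every dataset (or adopt generator features in abstract
    mode) and min-max scale the descriptor block.

    Classic scaling fits the scaler on all sets jointly, replicating the
    original protocol; strict mode fits on labeled training sources only
    and clips the rest, flagged in provenance.
    """
    t0 = time.time()
    cfgw = ctx.config.world
    raw: dict[str, cf.FeatureMatrix] = {}
    for name, ds in _dataset_items(ctx.world):
        if cfgw.mode == "abstract":
            raw[name] = ds.features
        else:
            std, rejected = cf.standardize_records(ds.records, on_error="drop")
            if rejected:
                ctx.warnings.append(f"{name}: dropped {len(rejected)} unparseable molecules")
            raw[name] = cf.featurize(std)
    if ctx.config.scaling == "joint":
        reference = cf.FeatureMatrix.concat(list(raw.values()))
    else:
        train_names = [f"{pid}-train" for pid in ctx.world.partner_ids] + ["public"]
        reference = cf.FeatureMatrix.concat([raw[n] for n in train_names])
    scaler = cf.fit_scaler(reference)
    ctx.features = {name: cf.apply_scaler(scaler, fm) for name, fm in raw.items()}
    ctx.scaler = scaler
    outputs = []
    for name, fm in ctx.features.items():
        p = ctx.path("features", f"{name}.npz")
        cf.save_feature_matrix(fm, p)
        outputs.append(str(p))
    ctx.log_stage("featurize", t0, outputs, [])


def stage_teachers(ctx: RunContext) -> None:
    t0 = time.time()
    cfg = ctx.config
    outputs = []
    for i, pid in enumerate(ctx.world.partner_ids):
        train = ctx.features[f"{pid}-train"]
        seed = cfg.seed + 101 * (i + 1)
        params = dict(cfg.teacher_hyperparameters)
        if cfg.hpo_enabled:
            hpo = optimize_hyperparameters(
                train, architecture=cfg.teacher_architecture, budget=cfg.hpo_budget,
                k=cfg.hpo_k, n_repeats=cfg.hpo_repeats, seed=seed,
            )
            params = hpo.best_params
        ctx.teachers[pid] = train_teacher(
            train, architecture=cfg.teacher_architecture, hyperparameters=params,
            seed=seed, oversample_ratio=cfg.oversample_ratio,
            scaler=getattr(ctx, "scaler", None), variant=f"teacher-{pid}",
        )
        outputs.append(str(save_bundle(ctx.teachers[pid], ctx.path("teachers", pid))))
    ctx.log_stage("teachers", t0, outputs, [])


def stage_federate(ctx: RunContext) -> None:
    t0 = time.time()
    cfg = ctx.config
    pool = ctx.features["pool"]
    outputs = []
    for pid, teacher in ctx.teachers.items():
        pred = federation.predict_pool(teacher, pool, member_id=pid,
                                       reliability_k=cfg.reliability_k)
        ctx.member_predictions[pid] = pred
        outputs.append(str(ctx.write_csv(pred, "predictions", f"member_{pid}.csv")))
    ctx.consolidated = federation.consolidate(
        [ctx.member_predictions[pid] for pid in sorted(ctx.member_predictions)],
        rule=cfg.consolidation_rule,
    )
    outputs.append(str(ctx.write_csv(ctx.consolidated, "predictions", "consolidated.csv")))
    ctx.federated = federation.build_federated_set(
        ctx.consolidated, n_per_class=cfg.n_per_class,
        reliability_min=cfg.reliability_min, decidability_min=cfg.decidability_min,
        provenance={"members": sorted(ctx.member_predictions),
                    "rule": cfg.consolidation_rule, "seed": cfg.seed,
                    "config_hash": cfg.config_hash},
    )
    fed_path = ctx.path("federated", "federated.csv")
    ctx.federated.to_csv(fed_path)
    outputs.append(str(fed_path))
    ctx.log_stage("federate", t0, outputs, list(ctx.federated.warnings))


def _student_sources(ctx: RunContext, pid: str) -> dict[str, cf.FeatureMatrix]:
    pool = ctx.features["pool"]
    fed_fm = federation.federated_feature_matrix(ctx.federated, pool)
    fluid_fm = pool.subset(np.arange(len(pool)))
    fluid_fm.labels = (
        ctx.consolidated.set_index("molecule_id")["consensus_label"]
        .reindex(pool.ids).to_numpy(dtype=np.int64)
    )
    sources = {
        "internal": ctx.features[f"{pid}-train"],
        "public": ctx.features["public"],
        "federated": fed_fm,
        "fluid_full": fluid_fm,
    }
    # single-channel run: both pseudo-label channels point at the same sets
    for chan in ("ft", "comp"):
        sources[f"federated@{chan}"] = fed_fm
        sources[f"fluid_full@{chan}"] = fluid_fm
    return sources


def stage_students(ctx: RunContext) -> None:
    t0 = time.time()
    cfg = ctx.config
    outputs = []
    for i, pid in enumerate(ctx.world.partner_ids):
        sources = _student_sources(ctx, pid)
        seed = cfg.seed + 7919 * (i + 1)
        for variant in cfg.student_variants:
            spec = student_models.VARIANT_TABLE[variant]
            if spec.path == "composition":
                clf = student_models.train_composition_path(
                    sources, variant, base_architecture=cfg.student_base_architecture,
                    hyperparameters=cfg.student_hyperparameters or None, seed=seed,
                )
            else:
                clf = student_models.train_finetune_path(sources, variant, seed=seed)
            ctx.students[(pid, variant)] = clf
            outputs.append(str(save_bundle(clf, ctx.path("students", f"{pid}_{variant}"))))
    ctx.log_stage("students", t0, outputs, [])


def stage_evaluate(ctx: RunContext) -> None:
    t0 = time.time()
    cfg = ctx.config
    rows = []
    warnings = []
    trend_paths = []
    for pid in ctx.world.partner_ids:
        test = ctx.features[f"{pid}-test"]
        per_partner: list[MetricsReport] = []
        for variant in cfg.student_variants:
            clf = ctx.students[(pid, variant)]
            for restricted in (False, True):
                rep = evaluate_model(
                    clf, test, ad_restricted=restricted,
                    reliability_min=cfg.eval_reliability_min,
                    decidability_min=cfg.eval_decidability_min,
                    reliability_k=cfg.reliability_k, variant=variant,
                )
                warnings.extend(rep.warnings)
                row = rep.to_dict()
                row["partner"] = pid
                rows.append(row)
                if restricted:
                    per_partner.append(rep)
        if len(per_partner) >= 2:
            trend = ad_trend(per_partner)
            trend_paths.append(str(ctx.write_csv(trend, "metrics", f"ad_trend_{pid}.csv")))
    metrics = pd.DataFrame(rows)
    outputs = [str(ctx.write_csv(metrics, "metrics", "variant_metrics.csv"))] + trend_paths

    audit_rows = []
    for name, ds in _dataset_items(ctx.world):
        labels = ds.labels
        if np.any(labels == 1):
            audit_rows.append({"dataset": name, "n": len(ds),
                               "inactive_active_ratio": round(class_ratio(labels), 2)})
    if ctx.federated is not None and ctx.federated.n_pos > 0:
        audit_rows.append({
            "dataset": "federated", "n": len(ctx.federated),
            "inactive_active_ratio": round(ctx.federated.n_neg / ctx.federated.n_pos, 2),
        })
    audit = pd.DataFrame(audit_rows)
    outputs.append(str(ctx.write_csv(audit, "metrics", "imbalance_audit.csv")))
    ctx.metrics = metrics
    ctx.imbalance_audit = audit
    ctx.log_stage("evaluate", t0, outputs, warnings)


_STAGE_FUNCS = {
    "generate": stage_generate,
    "featurize": stage_featurize,
    "teachers": stage_teachers,
    "federate": stage_federate,
    "students": stage_students,
    "evaluate": stage_evaluate,
}


def run_experiment(config: RunConfig, outdir, stages=STAGES) -> RunContext:
    """Execute the pipeline; any stage failure aborts with the stage name
    and persists the partial manifest. Returns the populated context."""
    ctx = RunContext(config, outdir)
    for stage in stages:
        try:
            _STAGE_FUNCS[stage](ctx)
        except Exception as exc:
            _write_manifest(ctx, failed_stage=stage)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    _write_manifest(ctx)
    return ctx


def _write_manifest(ctx: RunContext, failed_stage: str | None = None) -> None:
    files = sorted(
        p for p in ctx.outdir.rglob("*")
        if p.is_file() and p.suffix in (".csv", ".json", ".yaml")
        and p.name not in ("manifest.json", "run_log.json")
    )
    manifest = {
        "config_hash": ctx.config.config_hash,
        "seed": ctx.config.seed,
        "failed_stage": failed_stage,
        "files": {str(p.relative_to(ctx.outdir)): _sha256(p) for p in files},
    }
    (ctx.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (ctx.outdir / "run_log.json").write_text(
        json.dumps({"stages": ctx.stage_log, "warnings": ctx.warnings}, indent=2)
    )


def load_teachers(outdir) -> dict[str, TrainedClassifier]:
    out = {}
    for p in sorted(Path(outdir, "teachers").iterdir()):
        if p.is_dir():
            out[p.name] = load_bundle(p)
    return out
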