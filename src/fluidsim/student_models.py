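"""Federated "student" models along two training paths.

* Composition path — a configurable zoo classifier trained on a stated
  union of data sources. The named variants
  are T (internal only), HI (internal + public) and HF (internal +
  public + federated). Duplicate molecules across sources keep the
  internal label: experimental evidence outranks distilled labels.
* Pretrain/fine-tune path — a multilayer perceptron pretrained on one
  source and optionally refined on a partner's internal data with a
  reduced step size: PI (public only), RI (public, refined on internal),
  F (federated only), RF (federated, refined on internal). Refined
  models carry the union of pretraining and refinement fingerprints as
  their training-space reference, since both shaped the final weights.

The internal seven-way comparison variants are data compositions for the
composition path, with pseudo-label channels ``ft``/``comp`` naming which
student family produced the pool labels; in single-channel runs both
point at the same federated set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier

from .chem_features import MISSING_LABEL, FeatureMatrix
from .teacher_models import TrainedClassifier, make_classifier

__all__ = [
    "TrainingVariant",
    "VARIANT_TABLE",
    "COMPOSITION_VARIANTS",
    "FINETUNE_VARIANTS",
    "INTERNAL_COMPARISON_VARIANTS",
    "merge_sources",
    "train_composition_path",
    "train_finetune_path",
]


@dataclass(frozen=True)
class TrainingVariant:
    """Frozen definition of one named training-set composition."""

    name: str
    path: str  # "composition" or "finetune"
    composition: tuple[str, ...]  # ordered source tags, pretraining first
    refinement_source: str | None = None


# The frozen variant table. Source tags: internal (one partner's private
# training set), public (shared labeled set), federated (distilled
# 2N-molecule set), fluid_full (pseudo-labels for the entire pool).
# Channel suffixes @ft / @comp mark which student family's pool labels
# feed the internal comparison variants.
VARIANT_TABLE: dict[str, TrainingVariant] = {
    v.name: v
    for v in [
        # distillation-platform side
        TrainingVariant("T", "composition", ("internal",)),
        TrainingVariant("HI", "composition", ("internal", "public")),
        TrainingVariant("HF", "composition", ("internal", "public", "federated")),
        TrainingVariant("PI", "finetune", ("public",)),
        TrainingVariant("RI", "finetune", ("public",), refinement_source="internal"),
        TrainingVariant("F", "finetune", ("federated",)),
        TrainingVariant("RF", "finetune", ("federated",), refinement_source="internal"),
        # internal seven-way comparison
        TrainingVariant("internal_only", "composition", ("internal",)),
        TrainingVariant("fed_ft", "composition", ("federated@ft",)),
        TrainingVariant("fed_ft_plus_internal", "composition", ("internal", "federated@ft")),
        TrainingVariant("fluid_ft", "composition", ("fluid_full@ft",)),
        TrainingVariant("fed_comp", "composition", ("federated@comp",)),
        TrainingVariant("fed_comp_plus_internal", "composition", ("internal", "federated@comp")),
        TrainingVariant("fluid_comp", "composition", ("fluid_full@comp",)),
    ]
}

COMPOSITION_VARIANTS = ("T", "HI", "HF")
FINETUNE_VARIANTS = ("PI", "RI", "F", "RF")
INTERNAL_COMPARISON_VARIANTS = (
    "internal_only", "fed_ft", "fed_ft_plus_internal", "fluid_ft",
    "fed_comp", "fed_comp_plus_internal", "fluid_comp",
)

_SOURCE_PRIORITY = {"internal": 0, "public": 1, "federated": 2, "fluid_full": 3}


def _priority(tag: str) -> int:
    return _SOURCE_PRIORITY.get(tag.split("@")[0], 9)


def merge_sources(
    sources: dict[str, FeatureMatrix],
    composition: tuple[str, ...],
    dedup_keys: dict[str, list[str]] | None = None,
) -> FeatureMatrix:
    """Union the named sources in composition order with deduplication.

    Collisions (same molecule id, or same key from ``dedup_keys`` —
    e.g. canonical SMILES) keep the row from the highest-priority source:
    internal > public > federated > fluid_full.
    """
    missing = [tag for tag in composition if tag not in sources or sources[tag] is None]
    if missing:
        raise ValueError(f"variant requires absent source(s): {missing}")
    ordered = sorted(composition, key=_priority)
    seen: set[str] = set()
    parts: list[FeatureMatrix] = []
    for tag in ordered:
        fm = sources[tag]
        keys = dedup_keys[tag] if dedup_keys and tag in dedup_keys else fm.ids
        keep = []
        for i, k in enumerate(keys):
            if k not in seen:
                keep.append(i)
                seen.add(k)
        if keep:
            parts.append(fm.subset(np.array(keep)))
    if not parts:
        raise ValueError("merged composition is empty")
    merged = FeatureMatrix.concat(parts)
    if np.any(merged.labels == MISSING_LABEL):
        raise ValueError("merged training data contains unlabeled molecules")
    return merged


def train_composition_path(
    sources: dict[str, FeatureMatrix],
    variant: str,
    base_architecture: str = "xgb",
    hyperparameters: dict | None = None,
    seed: int = 0,
    dedup_keys: dict[str, list[str]] | None = None,
) -> TrainedClassifier:
    """Train a data-composition student (T / HI / HF or an internal
    comparison variant) with the configured base classifier."""
    spec = VARIANT_TABLE.get(variant)
    if spec is None or spec.path != "composition":
        raise ValueError(f"{variant!r} is not a composition-path variant")
    train = merge_sources(sources, spec.composition, dedup_keys)
    model = make_classifier(base_architecture, hyperparameters, seed)
    model.fit(train.X, train.labels)
    return TrainedClassifier(
        architecture=base_architecture,
        model=model,
        training_fingerprints=train.fingerprints.copy(),
        config_hash=train.config_hash,
        label_counts={c: int(np.sum(train.labels == c)) for c in (0, 1)},
        hyperparameters=dict(hyperparameters or {}),
        seed=seed,
        variant=variant,
        provenance={"path": "composition", "composition": list(spec.composition),
                    "n_train": len(train)},
    )


def _default_mlp(hyperparameters: dict | None, seed: int) -> MLPClassifier:
    p = dict(hyperparameters or {})
    return MLPClassifier(
        hidden_layer_sizes=p.get("hidden_layer_sizes", (64,)),
        alpha=p.get("alpha", 0.3),
        learning_rate_init=p.get("learning_rate_init", 1e-3),
        max_iter=p.get("max_iter", 400),
        random_state=seed,
    )


def train_finetune_path(
    sources: dict[str, FeatureMatrix],
    variant: str,
    hyperparameters: dict | None = None,
    seed: int = 0,
    refine_lr_factor: float = 0.1,
    refine_max_iter: int = 100,
) -> TrainedClassifier:
    """Train a pretrain/fine-tune student (PI / RI / F / RF).

    Refinement is warm-start continuation on the internal set at a
    reduced step size. If the refinement set is identical to the
    pretraining set (same molecule ids) it carries no new information and
    is skipped, recorded in provenance. The training-space reference of a
    refined model is the union of pretraining and refinement fingerprints.
    """
    spec = VARIANT_TABLE.get(variant)
    if spec is None or spec.path != "finetune":
        raise ValueError(f"{variant!r} is not a finetune-path variant")
    pre_tag = spec.composition[0]
    if pre_tag not in sources or sources[pre_tag] is None:
        raise ValueError(f"variant {variant} requires absent source {pre_tag!r}")
    pretrain = sources[pre_tag]
    if np.any(pretrain.labels == MISSING_LABEL):
        raise ValueError("pretraining data contains unlabeled molecules")

    model = _default_mlp(hyperparameters, seed)
    model.fit(pretrain.X, pretrain.labels)
    fingerprints = pretrain.fingerprints
    provenance = {"path": "finetune", "pretrain": pre_tag, "refinement": None,
                  "n_pretrain": len(pretrain)}

    if spec.refinement_source is not None:
        tag = spec.refinement_source
        if tag not in sources or sources[tag] is None:
            raise ValueError(f"variant {variant} requires absent source {tag!r}")
        refine = sources[tag]
        if len(np.unique(refine.labels)) < 2:
            raise ValueError("refinement set contains a single class")
        if sorted(refine.ids) == sorted(pretrain.ids):
            provenance["refinement"] = f"{tag} (skipped: identical to pretraining set)"
        else:
            model.set_params(
                warm_start=True,
                learning_rate_init=model.learning_rate_init * refine_lr_factor,
                max_iter=refine_max_iter,
            )
            model.fit(refine.X, refine.labels)
            fingerprints = np.vstack([pretrain.fingerprints, refine.fingerprints])
            provenance["refinement"] = tag
            provenance["refine_lr_factor"] = refine_lr_factor

    counts = {c: int(np.sum(pretrain.labels == c)) for c in (0, 1)}
    return TrainedClassifier(
        architecture="mlp",
        model=model,
        training_fingerprints=fingerprints.copy(),
        config_hash=pretrain.config_hash,
        label_counts=counts,
        hyperparameters=dict(hyperparameters or {}),
        seed=seed,
        variant=variant,
        provenance=provenance,
    )
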