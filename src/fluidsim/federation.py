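"""The distillation core: pool prediction, consolidation, federated set.

Each member's teacher labels the shared unlabeled pool; per-member
predictions are consolidated into one consensus call per molecule; the
federated training set is then built by (1) discarding consolidated
predictions whose reliability falls below a threshold, (2) ranking each
class by decreasing decidability, (3) taking up to N per class, and
(4) filling any shortfall in one class with further-ranked molecules of
the other, so the set reaches 2N whenever enough eligible molecules
exist.

Consolidation rules are registered by name; the default is a
decidability-weighted majority vote with exact ties resolved to the
inactive class (conservative for safety screening).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_features import FeatureMatrix
from .confidence_domain import decidability, reliability
from .teacher_models import TrainedClassifier

__all__ = [
    "PREDICTION_COLUMNS",
    "CONSOLIDATION_RULES",
    "FederatedSet",
    "predict_pool",
    "consolidate",
    "build_federated_set",
    "federated_feature_matrix",
]

PREDICTION_COLUMNS = [
    "molecule_id", "member_id", "predicted_label", "probability", "decidability", "reliability",
]

CONSOLIDATED_COLUMNS = [
    "molecule_id", "consensus_label", "consensus_decidability", "consensus_reliability",
    "n_members", "member_agreement",
]


def predict_pool(
    teacher: TrainedClassifier,
    pool: FeatureMatrix,
    member_id: str,
    reliability_k: int = 5,
) -> pd.DataFrame:
    """Run one teacher over the pool: label, probability, decidability,
    reliability per molecule. The pool must be featurized under the
    teacher's feature configuration."""
    if pool.config_hash != teacher.config_hash:
        raise ValueError(
            f"feature-config mismatch: teacher {teacher.config_hash!r} "
            f"vs pool {pool.config_hash!r}"
        )
    if len(pool) == 0:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    proba = teacher.predict_proba_positive(pool)
    rel = reliability(pool.fingerprints, teacher.training_fingerprints, k=reliability_k)
    return pd.DataFrame(
        {
            "molecule_id": pool.ids,
            "member_id": member_id,
            "predicted_label": (proba >= 0.5).astype(np.int64),
            "probability": proba,
            "decidability": decidability(proba),
            "reliability": rel,
        }
    )


def _rule_decidability_weighted(df: pd.DataFrame) -> pd.Series:
    w1 = df["decidability"].where(df["predicted_label"] == 1, 0.0).sum()
    w0 = df["decidability"].where(df["predicted_label"] == 0, 0.0).sum()
    return pd.Series({"consensus_label": int(w1 > w0)})


def _rule_majority(df: pd.DataFrame) -> pd.Series:
    n1 = int((df["predicted_label"] == 1).sum())
    n0 = len(df) - n1
    return pd.Series({"consensus_label": int(n1 > n0)})


def _rule_mean_probability(df: pd.DataFrame) -> pd.Series:
    return pd.Series({"consensus_label": int(df["probability"].mean() > 0.5)})


CONSOLIDATION_RULES: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "decidability_weighted": _rule_decidability_weighted,
    "majority": _rule_majority,
    "mean_probability": _rule_mean_probability,
}


def consolidate(
    member_predictions: Sequence[pd.DataFrame], rule: str = "decidability_weighted"
) -> pd.DataFrame:
    """Combine per-member pool predictions into one consensus per molecule.

    All members must have predicted the same id set. Consensus
    decidability/reliability are member means; ``member_agreement`` is
    the fraction of members voting the consensus label. Invariant under
    member order.
    """
    if not member_predictions:
        raise ValueError("no member predictions to consolidate")
    if rule not in CONSOLIDATION_RULES:
        raise ValueError(f"unknown consolidation rule {rule!r}")
    id_sets = [frozenset(df["molecule_id"]) for df in member_predictions]
    universe = id_sets[0]
    for i, ids in enumerate(id_sets[1:], start=1):
        if ids != universe:
            missing = sorted((universe ^ ids))[:10]
            raise ValueError(f"member {i} id set differs; examples: {missing}")

    allp = pd.concat(member_predictions, ignore_index=True)
    # vectorized default rules; groupby-apply reserved for custom callables
    g = allp.groupby("molecule_id", sort=True)
    if rule == "decidability_weighted":
        w1 = allp["decidability"].where(allp["predicted_label"] == 1, 0.0)
        w0 = allp["decidability"].where(allp["predicted_label"] == 0, 0.0)
        s1 = w1.groupby(allp["molecule_id"]).sum()
        s0 = w0.groupby(allp["molecule_id"]).sum()
        label = (s1 > s0).astype(np.int64)
    elif rule == "majority":
        votes = allp.groupby("molecule_id")["predicted_label"].sum()
        n = allp.groupby("molecule_id")["predicted_label"].count()
        label = (2 * votes > n).astype(np.int64)
    else:
        label = (g["probability"].mean() > 0.5).astype(np.int64)

    out = pd.DataFrame(
        {
            "consensus_label": label,
            "consensus_decidability": g["decidability"].mean(),
            "consensus_reliability": g["reliability"].mean(),
            "n_members": g["member_id"].count(),
        }
    )
    agree = (
        allp.assign(consensus=out["consensus_label"].reindex(allp["molecule_id"]).to_numpy())
        .assign(match=lambda d: (d["predicted_label"] == d["consensus"]).astype(float))
        .groupby("molecule_id")["match"]
        .mean()
    )
    out["member_agreement"] = agree
    return out.reset_index()[CONSOLIDATED_COLUMNS]


@dataclass
class FederatedSet:
    """The distilled training set selected by filter, rank and fill."""

    records: pd.DataFrame  # molecule_id, label, decidability, reliability
    n_per_class: int
    reliability_min: float
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_pos(self) -> int:
        return int((self.records["label"] == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.records["label"] == 0).sum())

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)
        sidecar = str(path) + ".provenance.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {"n_per_class": self.n_per_class, "reliability_min": self.reliability_min,
                 "n_pos": self.n_pos, "n_neg": self.n_neg, "warnings": self.warnings,
                 **self.provenance},
                fh, indent=2, default=str,
            )


def _rank(df: pd.DataFrame) -> pd.DataFrame:
    # decidability desc, then reliability desc, then id asc: fully deterministic
    return df.sort_values(
        ["consensus_decidability", "consensus_reliability", "molecule_id"],
        ascending=[False, False, True], kind="stable",
    )


def build_federated_set(
    consolidated: pd.DataFrame,
    n_per_class: int = 10000,
    reliability_min: float = 0.005,
    decidability_min: float | None = None,
    provenance: dict | None = None,
) -> FederatedSet:
    """Filter by reliability, rank each class by decidability, take up to
    N per class, and fill any shortfall from the other class's ranking.

    If both classes run out, everything eligible is returned with a
    shortfall warning; total = min(2N, eligible count).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    warnings: list[str] = []
    eligible = consolidated[consolidated["consensus_reliability"] >= reliability_min]
    if decidability_min is not None:
        eligible = eligible[eligible["consensus_decidability"] >= decidability_min]
    if eligible.empty:
        warnings.append("no consolidated predictions passed the reliability filter")
        records = pd.DataFrame(columns=["molecule_id", "label", "decidability", "reliability"])
        return FederatedSet(records, n_per_class, reliability_min, warnings, provenance or {})

    by_class = {
        lab: _rank(eligible[eligible["consensus_label"] == lab]) for lab in (1, 0)
    }
    take = {lab: min(n_per_class, len(by_class[lab])) for lab in (1, 0)}
    for lab in (1, 0):
        shortfall = n_per_class - take[lab]
        if shortfall > 0:
            donor = 1 - lab
            extra = min(shortfall, len(by_class[donor]) - take[donor])
            take[donor] += extra
            if extra < shortfall:
                warnings.append(
                    f"federated set short by {shortfall - extra} molecules: "
                    f"both classes exhausted"
                )
    parts = [by_class[lab].head(take[lab]) for lab in (1, 0)]
    sel = pd.concat(parts, ignore_index=True)
    records = pd.DataFrame(
        {
            "molecule_id": sel["molecule_id"],
            "label": sel["consensus_label"].astype(np.int64),
            "decidability": sel["consensus_decidability"],
            "reliability": sel["consensus_reliability"],
        }
    )
    return FederatedSet(records, n_per_class, reliability_min, warnings, provenance or {})


def federated_feature_matrix(fed: FederatedSet, pool: FeatureMatrix) -> FeatureMatrix:
    """Materialize the federated set as features + distilled labels."""
    index = {mid: i for i, mid in enumerate(pool.ids)}
    try:
        rows = np.array([index[mid] for mid in fed.records["molecule_id"]])
    except KeyError as exc:
        raise ValueError(f"federated molecule missing from pool: {exc}") from exc
    fm = pool.subset(rows)
    fm.labels = fed.records["label"].to_numpy(dtype=np.int64)
    return fm
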