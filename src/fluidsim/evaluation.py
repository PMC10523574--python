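"""Metrics, AD-restricted evaluation, trend tables and chemical-space maps.

Binary-classification metrics follow the screening conventions: active is
the positive class; balanced accuracy is the arithmetic mean of
sensitivity and specificity; MCC is the confusion-table correlation in
[-1, 1] with the zero-denominator convention MCC = 0. Undefined ratio
metrics (zero denominator) are reported as NaN and propagate into
balanced accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_features import FeatureMatrix
from .confidence_domain import decidability, in_applicability_domain, reliability

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "mcc",
    "classification_metrics",
    "evaluate_model",
    "class_ratio",
    "ad_trend",
    "chemspace_embed",
    "embedding_overlap",
]


@dataclass
class ConfusionCounts:
    """2x2 confusion table; active (label 1) is the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """One model x one test set. NaN marks metrics undefined on this table."""

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    precision: float
    mcc: float
    ad_coverage: float = 1.0
    n_evaluated: int = 0
    variant: str = ""
    ad_restricted: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "mcc": self.mcc,
            "ad_coverage": self.ad_coverage,
            "n_evaluated": self.n_evaluated,
            "ad_restricted": self.ad_restricted,
        }


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between labels and predictions")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); returns 0 when
    any denominator factor vanishes.
    """
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in denom_factors):
        return 0.0
    num = tp * tn - fp * fn
    return num / math.sqrt(math.prod(denom_factors))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity / specificity / precision / balanced accuracy / MCC.

    Balanced accuracy is the arithmetic mean of sensitivity and
    specificity and is NaN whenever either component is.
    """
    sens = _ratio(c.TP, c.TP + c.FN)
    spec = _ratio(c.TN, c.TN + c.FP)
    prec = _ratio(c.TP, c.TP + c.FP)
    ba = (sens + spec) / 2.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "balanced_accuracy": ba,
        "mcc": mcc(c),
    }


def evaluate_model(
    model,
    test: FeatureMatrix,
    ad_restricted: bool = False,
    reliability_min: float = 0.0,
    decidability_min: float = 0.0,
    reliability_k: int = 5,
    variant: str = "",
) -> MetricsReport:
    """Score a trained classifier on a labeled test set.

    With ``ad_restricted`` the confusion table is built only from the
    test molecules inside the applicability domain (reliability against
    the model's own training-space reference, decidability from its
    predicted probability), and ``ad_coverage`` reports the retained
    fraction; otherwise every molecule counts and coverage is 1.
    """
    if not test.has_labels:
        raise ValueError("test set carries unlabeled molecules")
    proba = model.predict_proba_positive(test)
    pred = (proba >= 0.5).astype(np.int64)
    warnings: list[str] = []

    if ad_restricted:
        rel = reliability(test.fingerprints, model.training_fingerprints, k=reliability_k)
        dec = decidability(proba)
        mask = in_applicability_domain(rel, dec, reliability_min, decidability_min)
        coverage = float(np.mean(mask)) if len(test) else 0.0
        if not np.any(mask):
            warnings.append("applicability domain retained no test molecules")
            return MetricsReport(
                sensitivity=float("nan"), specificity=float("nan"),
                balanced_accuracy=float("nan"), precision=float("nan"), mcc=float("nan"),
                ad_coverage=coverage, n_evaluated=0, variant=variant,
                ad_restricted=True, warnings=warnings,
            )
        y, p = test.labels[mask], pred[mask]
    else:
        coverage = 1.0
        y, p = test.labels, pred

    counts = confusion_counts(y, p)
    m = classification_metrics(counts)
    return MetricsReport(
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        balanced_accuracy=m["balanced_accuracy"], precision=m["precision"], mcc=m["mcc"],
        ad_coverage=coverage, n_evaluated=counts.n, variant=variant,
        ad_restricted=ad_restricted, warnings=warnings,
    )


def class_ratio(labels) -> float:
    """Inactive/active ratio (#label 0 / #label 1) of a labeled dataset.

    Accepts a label array or anything with a ``labels`` attribute. Zero
    actives is an error, not infinity: imbalance auditing needs both
    classes present.
    """
    y = np.asarray(getattr(labels, "labels", labels))
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0:
        raise ValueError("class_ratio undefined: no positive molecules")
    return n_neg / n_pos


def ad_trend(reports: list[MetricsReport]) -> pd.DataFrame:
    """Tabulate AD coverage against performance across model variants.

    Reports must share a test set (same-size comparison enforced by the
    caller passing reports from one evaluation round); row order is
    preserved and consecutive coverage deltas are added.
    """
    if len(reports) < 2:
        raise ValueError("ad_trend needs at least two reports")
    ns = {r.n_evaluated / r.ad_coverage for r in reports if r.ad_coverage > 0}
    if len({round(n) for n in ns}) > 1:
        raise ValueError("reports do not share a test set (mismatched sizes)")
    df = pd.DataFrame([r.to_dict() for r in reports])
    df["coverage_delta"] = df["ad_coverage"].diff().fillna(0.0)
    return df[
        ["variant", "ad_coverage", "coverage_delta", "sensitivity", "specificity",
         "balanced_accuracy", "mcc", "n_evaluated"]
    ]


def chemspace_embed(
    feature_sets: dict[str, np.ndarray], dims: int = 2, seed: int = 0, perplexity: float = 30.0
) -> dict[str, np.ndarray]:
    """Joint t-SNE embedding of several datasets sharing one feature space.

    All matrices are stacked and embedded together so coordinates are
    comparable across sets, then split back by set name. Deterministic
    given the seed.
    """
    from sklearn.manifold import TSNE

    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    names = list(feature_sets)
    mats = [np.asarray(feature_sets[n], dtype=np.float64) for n in names]
    widths = {m.shape[1] for m in mats}
    if len(widths) > 1:
        raise ValueError("feature sets do not share a feature space")
    X = np.vstack(mats)
    perp = min(perplexity, max(2.0, (X.shape[0] - 1) / 3.0))
    coords = TSNE(
        n_components=dims, random_state=seed, init="pca", perplexity=perp
    ).fit_transform(X)
    out, start = {}, 0
    for name, m in zip(names, mats):
        out[name] = coords[start : start + m.shape[0]]
        start += m.shape[0]
    return out


def embedding_overlap(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Fraction of set-B points whose nearest embedded neighbour lies in A.

    A scalar summary of how much B's chemical space is covered by A in
    the joint embedding (1 = fully interleaved, 0 = fully separated).
    """
    from sklearn.neighbors import NearestNeighbors

    both = np.vstack([coords_a, coords_b])
    nn = NearestNeighbors(n_neighbors=2).fit(both)
    _, idx = nn.kneighbors(coords_b)
    n_a = coords_a.shape[0]
    neighbours = np.where(
        idx[:, 0] == np.arange(n_a, n_a + coords_b.shape[0]), idx[:, 1], idx[:, 0]
    )
    return float(np.mean(neighbours < n_a))
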