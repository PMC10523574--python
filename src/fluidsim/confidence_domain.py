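"""Decidability, reliability and applicability-domain scoring.

A prediction is trusted along two axes:

* decidability — how far the predicted probability is from equivocal:
  ``|2p - 1|`` in [0, 1] (0 = coin flip, 1 = decisive);
* reliability — how close the query sits to the model's training
  chemistry: mean Tanimoto similarity between the query fingerprint and
  its k nearest training fingerprints, in [0, 1].

The applicability domain (AD) is the conjunction of thresholds on both.
Both scoring functions are registered by name so alternative definitions
can be plugged in per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "PredictionRecord",
    "decidability",
    "tanimoto_similarity_matrix",
    "reliability",
    "in_applicability_domain",
    "RELIABILITY_REGISTRY",
    "DECIDABILITY_REGISTRY",
]


@dataclass
class PredictionRecord:
    """One teacher's call on one pool molecule."""

    molecule_id: str
    member_id: str
    predicted_label: int
    probability: float
    decidability: float
    reliability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        if abs(self.decidability - abs(2 * self.probability - 1)) > 1e-12:
            raise ValueError("decidability inconsistent with probability")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError(f"reliability {self.reliability} outside [0, 1]")


def decidability(probability):
    """``|2p - 1|``: distance of a probability from the equivocal point 0.5.

    Symmetric about 0.5; accepts scalars or arrays; probabilities outside
    [0, 1] are rejected.
    """
    p = np.asarray(probability, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability outside [0, 1]")
    d = np.abs(2.0 * p - 1.0)
    return float(d) if np.isscalar(probability) else d


def tanimoto_similarity_matrix(query_fp: np.ndarray, ref_fp: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between two fingerprint blocks.

    Computed as intersection / union through a float32 matmul; a pair of
    all-zero fingerprints has similarity 0 by convention.
    """
    A = np.atleast_2d(np.asarray(query_fp)).astype(np.float32)
    B = np.atleast_2d(np.asarray(ref_fp)).astype(np.float32)
    # bit counts and their sums are small integers, exactly representable
    # in float32; only the final division needs double precision
    inter = (A @ B.T).astype(np.float64)
    pa = A.sum(axis=1, dtype=np.float64)[:, None]
    pb = B.sum(axis=1, dtype=np.float64)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def reliability(
    query_fp: np.ndarray,
    training_fp: np.ndarray,
    k: int = 5,
    chunk: int = 4096,
) -> np.ndarray | float:
    """Mean Tanimoto similarity to the k nearest training fingerprints.

    ``k`` is truncated to the reference size. Monotone in the training
    set: adding reference molecules can never lower any query's score.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref = np.atleast_2d(np.asarray(training_fp))
    if ref.shape[0] == 0:
        raise ValueError("empty training reference")
    single = np.asarray(query_fp).ndim == 1
    Q = np.atleast_2d(np.asarray(query_fp))
    k = min(k, ref.shape[0])
    out = np.empty(Q.shape[0], dtype=np.float64)
    for start in range(0, Q.shape[0], chunk):
        sim = tanimoto_similarity_matrix(Q[start : start + chunk], ref)
        if k == sim.shape[1]:
            topk = sim
        else:
            topk = np.partition(sim, sim.shape[1] - k, axis=1)[:, -k:]
        out[start : start + chunk] = topk.mean(axis=1)
    return float(out[0]) if single else out


def in_applicability_domain(
    reliability_values,
    decidability_values,
    reliability_min: float,
    decidability_min: float = 0.0,
):
    """AD membership: reliability >= r_min AND decidability >= d_min.

    Vectorized; thresholds are per-experiment configuration (the workflow
    platform-scale default for reliability filtering is 0.005).
    """
    for t in (reliability_min, decidability_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {t} outside [0, 1]")
    r = np.asarray(reliability_values, dtype=float)
    d = np.asarray(decidability_values, dtype=float)
    mask = (r >= reliability_min) & (d >= decidability_min)
    return bool(mask) if mask.ndim == 0 else mask


RELIABILITY_REGISTRY: dict[str, Callable] = {"knn_tanimoto": reliability}
DECIDABILITY_REGISTRY: dict[str, Callable] = {"abs_margin": decidability}
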