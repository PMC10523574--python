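"""Synthetic multi-partner world generator.

Emulates the data landscape of a multi-company federated-distillation
study: each partner holds a private labeled set split temporally into
train (pre-cutoff) and test (cutoff year onward), a public labeled set is
shared, and a large unlabeled pool is available for pseudo-labeling.
Chemical space is cluster-structured (Gaussian modes in a latent
coordinate, standing in for chemical series); each partner samples its
own cluster mixture, with ``partner_cluster_overlap`` controlling how much
chemistry partners share.

Activity is a smooth logistic function of a random linear projection of
the latent coordinate plus per-cluster offsets, expressed as a continuous
percent-response and thresholded at ``activity_threshold`` (default 50%,
the >=50% inhibition/binding at 10 uM convention). Per-cluster offsets
are calibrated analytically so every dataset realizes the requested
inactive/active ratio regardless of its cluster mixture. Observed labels
are flipped symmetrically with probability ``label_noise`` to mimic assay
variability; the pool's ground truth is kept noise-free and is reachable
only through an explicit oracle accessor.

Two emission modes:

* ``abstract`` — molecules carry precomputed feature matrices (latent
  coordinate as the descriptor block, cluster-structured random bits as
  the fingerprint block); no chemistry toolkit in the loop. This is the
  mode for statistically controlled experiments.
* ``smiles`` — concrete molecules assembled from a small scaffold +
  substituent grammar, for end-to-end runs through the featurization
  pipeline. Substituent choice is mildly biased by the true label so the
  real fingerprints also carry activity signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .chem_features import MISSING_LABEL, FeatureMatrix, MoleculeRecord

__all__ = [
    "WorldConfig",
    "Dataset",
    "SyntheticWorld",
    "generate_world",
    "label_activity",
    "temporal_split",
]


# Scaffold grammar for the ``smiles`` emission mode: each template has two
# substitution slots; every (template, substituent, substituent) combination
# below yields a valid molecule.
SCAFFOLD_TEMPLATES = [
    "c1cc({})ccc1{}",
    "c1cc({})cnc1{}",
    "c1cc({})sc1{}",
    "c1cc({})oc1{}",
    "c1cc({})[nH]c1{}",
    "C1CC({})CCC1{}",
    "C1CC({})CCN1{}",
    "c1ccc2ccc({})cc2c1{}",
    "C1CC({})OCC1{}",
    "C1CC({})CC1{}",
    "c1ccc({})nc1{}",
]

SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F", "C(=O)O", "C(=O)OC", "C(=O)N",
    "CO", "CN", "CCO", "S(C)(=O)=O", "CC(C)C", "C=C",
]


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    ``inactive_active_ratio`` is the requested #inactive / #active ratio,
    shared by all datasets so the ground-truth activity function is
    globally consistent. ``partner_cluster_overlap`` in [0, 1]: 1 means
    all partners draw from the same cluster mixture, 0 means disjoint
    private clusters. ``partner_threshold_jitter`` (percent-response
    units) emulates assay-condition drift between partners; default off.
    """

    n_partners: int = 3
    n_train_per_partner: int = 2000
    n_test_per_partner: int = 600
    n_public: int = 2000
    n_pool: int = 20000
    n_pool_eval: int = 0
    inactive_active_ratio: float = 2.0
    n_clusters: int = 8
    partner_cluster_overlap: float = 0.5
    label_noise: float = 0.05
    assay_noise: float = 0.4
    test_novelty: float = 0.3
    activity_threshold: float = 50.0
    temporal_cutoff_year: int = 2020
    partner_threshold_jitter: float = 0.0
    latent_dim: int = 16
    n_bits: int = 2048
    bits_per_cluster: int = 64
    cluster_bit_rate: float = 0.5
    background_bits: int = 8
    cluster_spread: float = 1.0
    cluster_separation: float = 4.0
    response_steepness: float = 1.5
    mode: str = "abstract"
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_partners, self.n_train_per_partner, self.n_test_per_partner,
            self.n_public, self.n_pool, self.n_pool_eval,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_partners < 1:
            raise ValueError("need at least one partner")
        if not 0.0 <= self.partner_cluster_overlap <= 1.0:
            raise ValueError("partner_cluster_overlap must be in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")
        if not 0.0 <= self.test_novelty <= 1.0:
            raise ValueError("test_novelty must be in [0, 1]")
        if self.inactive_active_ratio <= 0:
            raise ValueError("inactive_active_ratio must be positive")
        if self.mode not in ("abstract", "smiles"):
            raise ValueError(f"unknown emission mode {self.mode!r}")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")

    @property
    def active_fraction(self) -> float:
        return 1.0 / (1.0 + self.inactive_active_ratio)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        return cls(**d)

    @classmethod
    def low_noise(cls, **overrides) -> "WorldConfig":
        """Preset with both noise channels reduced (2% gross label errors,
        half the default assay measurement noise) — the regime for
        ground-truth-recovery experiments."""
        params = {"label_noise": 0.02, "assay_noise": 0.2}
        params.update(overrides)
        return cls(**params)


@dataclass
class Dataset:
    """A named set of molecules, with precomputed features in abstract mode."""

    name: str
    records: list[MoleculeRecord]
    features: FeatureMatrix | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array(
            [MISSING_LABEL if r.label is None else r.label for r in self.records], dtype=np.int64
        )


@dataclass
class SyntheticWorld:
    """Generated world: per-partner train/test, public set, unlabeled pool."""

    partner_train: dict[str, Dataset]
    partner_test: dict[str, Dataset]
    public: Dataset
    pool: Dataset
    pool_eval: Dataset | None
    config: WorldConfig
    warnings: list[str] = field(default_factory=list)
    _pool_truth: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def partner_ids(self) -> list[str]:
        return sorted(self.partner_train)

    def pool_ground_truth(self) -> np.ndarray:
        """Oracle accessor for the pool's hidden true labels (tests only)."""
        return self._pool_truth.copy()

    @property
    def generator_metadata(self) -> dict:
        return {"config": self.config.to_dict(), "seed": self.config.seed}


def label_activity(response_percent, threshold: float = 50.0):
    """Binary activity call: 1 iff percent response >= threshold.

    Accepts scalars or arrays; the boundary value itself counts as active.
    """
    arr = np.asarray(response_percent)
    out = (arr >= threshold).astype(np.int64)
    return int(out) if np.isscalar(response_percent) else out


def temporal_split(records, cutoff_year: int = 2020):
    """Partition records into (train, test) at an assay-year cutoff.

    Test = tested in ``cutoff_year`` or later; train = everything before.
    Returns (train, test, warnings); an empty side is a warning, not an
    error, because downstream stages decide whether they can proceed.
    """
    train = [r for r in records if r.assay_year < cutoff_year]
    test = [r for r in records if r.assay_year >= cutoff_year]
    warnings = []
    if records and not train:
        warnings.append(f"temporal split at {cutoff_year}: empty training side")
    if records and not test:
        warnings.append(f"temporal split at {cutoff_year}: empty test side")
    return train, test, warnings


# ---------------------------------------------------------------------------
# internals


class _LatentModel:
    """Cluster geometry + activity function shared by every dataset."""

    def __init__(self, cfg: WorldConfig, rng: np.random.Generator):
        self.cfg = cfg
        d, K = cfg.latent_dim, cfg.n_clusters
        self.means = rng.normal(size=(K, d)) * cfg.cluster_separation / np.sqrt(d)
        w = rng.normal(size=d)
        self.w = w / np.linalg.norm(w)
        # Per-cluster offsets calibrated so P(measured score >= q | cluster k)
        # equals the requested active fraction in every cluster: any cluster
        # mixture then realizes the requested inactive/active ratio. The
        # measured score is the latent score plus assay noise, so the
        # calibration uses the total sd; symmetric label flips pull the
        # observed active fraction toward 0.5, so the latent target is the
        # flip-corrected fraction — the requested ratio describes the
        # *observed* dataset composition.
        q = self._score_threshold()
        p = cfg.active_fraction
        if 0.0 < cfg.label_noise < 0.5:
            p = (p - cfg.label_noise) / (1.0 - 2.0 * cfg.label_noise)
        p = float(np.clip(p, 1e-6, 1.0 - 1e-6))
        z = norm.ppf(p)
        total_sd = float(np.hypot(cfg.cluster_spread, cfg.assay_noise))
        self.offsets = q + total_sd * z - self.means @ self.w
        self.cluster_bits = [
            rng.choice(cfg.n_bits, size=cfg.bits_per_cluster, replace=False) for _ in range(K)
        ]

    def _score_threshold(self, threshold: float | None = None) -> float:
        t = self.cfg.activity_threshold if threshold is None else threshold
        p = min(max(t / 100.0, 1e-9), 1 - 1e-9)
        return float(np.log(p / (1 - p)) / self.cfg.response_steepness)

    def sample_latent(self, clusters: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.normal(size=(len(clusters), self.cfg.latent_dim)) * self.cfg.cluster_spread
        return self.means[clusters] + eps

    def response_percent(
        self, x: np.ndarray, clusters: np.ndarray, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Measured percent response: logistic in the latent score plus
        assay measurement noise. Near-threshold molecules therefore flip
        between assays, so an ideal model's confidence varies smoothly —
        the spread that makes decidability ranking informative."""
        score = x @ self.w + self.offsets[clusters]
        if rng is not None and self.cfg.assay_noise > 0:
            score = score + rng.normal(0.0, self.cfg.assay_noise, size=len(score))
        return 100.0 / (1.0 + np.exp(-self.cfg.response_steepness * score))

    def fingerprints(self, clusters: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        cfg = self.cfg
        fp = np.zeros((len(clusters), cfg.n_bits), dtype=np.uint8)
        for i, k in enumerate(clusters):
            bits = self.cluster_bits[k]
            on = bits[rng.random(len(bits)) < cfg.cluster_bit_rate]
            fp[i, on] = 1
            fp[i, rng.choice(cfg.n_bits, size=cfg.background_bits, replace=False)] = 1
        return fp


def _partner_cluster_sets(cfg: WorldConfig) -> dict[str, np.ndarray]:
    """Assign each partner its cluster mixture.

    The first round(overlap * K) clusters are shared by everyone; the
    remainder are dealt round-robin as private clusters.
    """
    K = cfg.n_clusters
    n_shared = int(round(cfg.partner_cluster_overlap * K))
    shared = list(range(n_shared))
    private = list(range(n_shared, K))
    out: dict[str, np.ndarray] = {}
    for p in range(cfg.n_partners):
        mine = shared + [c for j, c in enumerate(private) if j % cfg.n_partners == p]
        if not mine:
            raise ValueError(
                f"partner {p} received no clusters "
                f"(n_clusters={K}, overlap={cfg.partner_cluster_overlap}, "
                f"n_partners={cfg.n_partners}); increase n_clusters or overlap"
            )
        out[f"P{p}"] = np.array(mine)
    return out


def _check_ratio_attainable(name: str, n: int, cfg: WorldConfig) -> None:
    if n == 0:
        return
    expected_active = n * cfg.active_fraction
    expected_inactive = n - expected_active
    if expected_active < 1 or expected_inactive < 1:
        raise ValueError(
            f"dataset {name!r}: requested ratio {cfg.inactive_active_ratio} is "
            f"unattainable at n={n} (< 1 expected molecule in one class)"
        )


def _emit_smiles(
    model: _LatentModel, clusters: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Assemble grammar SMILES; substituent pool choice leans on the label."""
    cfg = model.cfg
    out = []
    sub_sets = []
    for k in range(cfg.n_clusters):
        local = np.random.default_rng(cfg.seed * 1000003 + k)
        subs = local.permutation(len(SUBSTITUENTS))[:12]
        sub_sets.append((subs[:6], subs[6:]))
    for k, lab in zip(clusters, labels):
        template = SCAFFOLD_TEMPLATES[k % len(SCAFFOLD_TEMPLATES)]
        pool_a, pool_b = sub_sets[k]
        favoured = pool_a if lab == 1 else pool_b
        other = pool_b if lab == 1 else pool_a
        picks = []
        for _ in range(2):
            src = favoured if rng.random() < 0.8 else other
            picks.append(SUBSTITUENTS[src[rng.integers(len(src))]])
        out.append(template.format(*picks))
    return out


def _make_dataset(
    name: str,
    n: int,
    cluster_set: np.ndarray,
    years: tuple[int, int],
    model: _LatentModel,
    rng: np.random.Generator,
    cfg: WorldConfig,
    id_prefix: str,
    partner_id: str = "",
    hide_labels: bool = False,
    observe_noise: bool = True,
    threshold_shift: float = 0.0,
    novelty: float = 0.0,
) -> tuple[Dataset, np.ndarray]:
    """Draw one dataset from a cluster mixture; returns (dataset, true labels).

    ``novelty`` is the fraction of molecules drawn from the full cluster
    set instead of the dataset's own mixture — temporally newer test
    molecules explore chemistry outside a partner's historical series.
    """
    _check_ratio_attainable(name, n, cfg)
    clusters = cluster_set[rng.integers(len(cluster_set), size=n)]
    if novelty > 0 and n > 0:
        novel = rng.random(n) < novelty
        clusters[novel] = rng.integers(cfg.n_clusters, size=int(novel.sum()))
    x = model.sample_latent(clusters, rng)
    response = model.response_percent(x, clusters, rng)
    truth = label_activity(response, cfg.activity_threshold + threshold_shift)
    observed = truth.copy()
    if observe_noise and cfg.label_noise > 0:
        flip = rng.random(n) < cfg.label_noise
        observed[flip] = 1 - observed[flip]
    assay_years = rng.integers(years[0], years[1] + 1, size=n) if n else np.array([], dtype=int)

    smiles = [""] * n
    if cfg.mode == "smiles":
        smiles = _emit_smiles(model, clusters, truth, rng)

    records = [
        MoleculeRecord(
            id=f"{id_prefix}-{i:06d}",
            smiles=smiles[i],
            label=None if hide_labels else int(observed[i]),
            assay_year=int(assay_years[i]),
            partner_id=partner_id,
            target_id="T1",
        )
        for i in range(n)
    ]
    features = None
    if cfg.mode == "abstract":
        features = FeatureMatrix(
            ids=[r.id for r in records],
            physchem=x,
            fingerprints=model.fingerprints(clusters, rng),
            labels=np.full(n, MISSING_LABEL) if hide_labels else observed,
            config_hash=f"abstract-d{cfg.latent_dim}-b{cfg.n_bits}",
        )
    return Dataset(name=name, records=records, features=features), observed if not hide_labels else truth


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a full synthetic world; fully reproducible from config.seed."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    model = _LatentModel(cfg, rng)
    cluster_sets = _partner_cluster_sets(cfg)
    all_clusters = np.arange(cfg.n_clusters)
    cutoff = cfg.temporal_cutoff_year
    train_years = (cutoff - 5, cutoff - 1)
    test_years = (cutoff, cutoff + 2)

    partner_train: dict[str, Dataset] = {}
    partner_test: dict[str, Dataset] = {}
    warnings: list[str] = []
    for pid, cset in cluster_sets.items():
        shift = (
            float(rng.normal(0, cfg.partner_threshold_jitter))
            if cfg.partner_threshold_jitter > 0
            else 0.0
        )
        partner_train[pid], _ = _make_dataset(
            f"{pid}-train", cfg.n_train_per_partner, cset, train_years, model, rng, cfg,
            id_prefix=f"{pid}-TR", partner_id=pid, threshold_shift=shift,
        )
        partner_test[pid], _ = _make_dataset(
            f"{pid}-test", cfg.n_test_per_partner, cset, test_years, model, rng, cfg,
            id_prefix=f"{pid}-TE", partner_id=pid, threshold_shift=shift,
            novelty=cfg.test_novelty,
        )

    public, _ = _make_dataset(
        "public", cfg.n_public, all_clusters, train_years, model, rng, cfg, id_prefix="PUB"
    )
    pool, pool_truth = _make_dataset(
        "pool", cfg.n_pool, all_clusters, train_years, model, rng, cfg,
        id_prefix="POOL", hide_labels=True, observe_noise=False,
    )
    pool_eval = None
    if cfg.n_pool_eval > 0:
        pool_eval, _ = _make_dataset(
            "pool-eval", cfg.n_pool_eval, all_clusters, test_years, model, rng, cfg,
            id_prefix="PEV", observe_noise=False,
        )

    for pid in cluster_sets:
        for ds in (partner_train[pid], partner_test[pid]):
            if len(ds) == 0:
                warnings.append(f"dataset {ds.name} is empty")

    return SyntheticWorld(
        partner_train=partner_train,
        partner_test=partner_test,
        public=public,
        pool=pool,
        pool_eval=pool_eval,
        config=cfg,
        warnings=warnings,
        _pool_truth=pool_truth,
    )
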