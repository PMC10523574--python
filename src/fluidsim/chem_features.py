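"""Molecule standardization and featurization.

All models in the workflow operate on one feature space: a block of 2D
physicochemical descriptors scaled to [0, 1], concatenated with a 2048-bit
Morgan fingerprint (radius 3). This module owns SMILES standardization
(salt stripping + canonicalization), descriptor/fingerprint computation,
and the min-max scaler applied to the descriptor block.

The descriptor set is a frozen, named configuration shipped with the
package (``data/descriptors-rdkit2d.txt``); its length is asserted at load
rather than hard-coded, because the full 2D descriptor pool varies across
toolkit versions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

MISSING_LABEL = -1

__all__ = [
    "MoleculeRecord",
    "FeatureMatrix",
    "ScalerState",
    "DescriptorConfig",
    "StandardizationError",
    "FeaturizationError",
    "load_descriptor_config",
    "standardize_smiles",
    "standardize_records",
    "featurize",
    "fit_scaler",
    "apply_scaler",
    "read_molecule_csv",
    "write_molecule_csv",
]


class StandardizationError(ValueError):
    """Raised for SMILES that cannot be parsed; carries the offending string."""

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


class FeaturizationError(ValueError):
    """Raised when descriptor computation fails for a molecule; carries its id."""

    def __init__(self, molecule_id: str, reason: str):
        self.molecule_id = molecule_id
        super().__init__(f"featurization failed for {molecule_id!r}: {reason}")


@dataclass
class MoleculeRecord:
    """One compound: SMILES, optional binary activity label, assay era, tags.

    ``label`` is 1 (active), 0 (inactive) or None for unlabeled pool
    molecules. Activity follows the >=50% inhibition/binding at 10 uM
    convention used throughout the workflow.
    """

    id: str
    smiles: str = ""
    label: int | None = None
    assay_year: int = 0
    partner_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass
class FeatureMatrix:
    """Featurized dataset: ids + scaled-descriptor block + fingerprint block.

    ``physchem`` is (n, d) float64; after scaling every entry is in [0, 1].
    ``fingerprints`` is (n, n_bits) uint8 with entries in {0, 1}.
    ``labels`` is (n,) int64 with -1 marking missing labels.
    ``config_hash`` identifies the (descriptor config, radius, n_bits)
    used, so mismatched feature spaces are rejected instead of silently
    combined.
    """

    ids: list[str]
    physchem: np.ndarray
    fingerprints: np.ndarray
    labels: np.ndarray
    config_hash: str
    scaled: bool = False

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.physchem = np.asarray(self.physchem, dtype=np.float64)
        self.fingerprints = np.asarray(self.fingerprints, dtype=np.uint8)
        if self.labels is None:
            self.labels = np.full(n, MISSING_LABEL, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (self.physchem.shape[0] == self.fingerprints.shape[0] == self.labels.shape[0] == n):
            raise ValueError("inconsistent row counts in FeatureMatrix")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def X(self) -> np.ndarray:
        """Model input: descriptor block followed by fingerprint block."""
        return np.hstack([self.physchem, self.fingerprints.astype(np.float64)])

    @property
    def y(self) -> np.ndarray:
        return self.labels

    @property
    def has_labels(self) -> bool:
        return bool(np.all(self.labels != MISSING_LABEL))

    def subset(self, idx: np.ndarray | Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureMatrix(
            ids=[self.ids[i] for i in idx],
            physchem=self.physchem[idx],
            fingerprints=self.fingerprints[idx],
            labels=self.labels[idx],
            config_hash=self.config_hash,
            scaled=self.scaled,
        )

    @staticmethod
    def concat(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("cannot concatenate zero FeatureMatrix parts")
        hashes = {p.config_hash for p in parts}
        if len(hashes) > 1:
            raise ValueError(f"feature-config mismatch across parts: {sorted(hashes)}")
        scaled = {p.scaled for p in parts}
        if len(scaled) > 1:
            raise ValueError("cannot concatenate scaled with unscaled features")
        return FeatureMatrix(
            ids=[i for p in parts for i in p.ids],
            physchem=np.vstack([p.physchem for p in parts]),
            fingerprints=np.vstack([p.fingerprints for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            config_hash=parts[0].config_hash,
            scaled=parts[0].scaled,
        )


@dataclass
class DescriptorConfig:
    """Frozen descriptor configuration: name + ordered descriptor list."""

    name: str
    descriptor_names: list[str]
    radius: int = 3
    n_bits: int = 2048

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    @property
    def config_hash(self) -> str:
        payload = f"{self.name}|{','.join(self.descriptor_names)}|r{self.radius}|b{self.n_bits}"
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_DESCRIPTOR_CONFIG_CACHE: dict[tuple[int, int], DescriptorConfig] = {}


def load_descriptor_config(radius: int = 3, n_bits: int = 2048) -> DescriptorConfig:
    """Load the shipped 2D descriptor configuration and verify its length.

    The artifact records its own expected count on the first line
    (``# name=... n=...``); a mismatch between that count and the listed
    descriptors, or a descriptor missing from the installed toolkit,
    aborts the load.
    """
    key = (radius, n_bits)
    if key in _DESCRIPTOR_CONFIG_CACHE:
        return _DESCRIPTOR_CONFIG_CACHE[key]
    text = (resources.files("fluidsim") / "data" / "descriptors-rdkit2d.txt").read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    header = lines[0]
    if not header.startswith("#"):
        raise ValueError("descriptor config missing header line")
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    names = lines[1:]
    if len(names) != int(meta["n"]):
        raise ValueError(
            f"descriptor config corrupt: header declares {meta['n']} names, found {len(names)}"
        )
    available = {n for n, _ in Descriptors.descList}
    missing = [n for n in names if n not in available]
    if missing:
        raise ValueError(f"descriptors absent from installed toolkit: {missing[:5]}")
    cfg = DescriptorConfig(name=meta["name"], descriptor_names=names, radius=radius, n_bits=n_bits)
    _DESCRIPTOR_CONFIG_CACHE[key] = cfg
    return cfg


def standardize_smiles(smiles: str) -> str:
    """Strip salts (keep the largest fragment by heavy-atom count) and
    return the canonical SMILES.

    Idempotent: standardizing an output returns it unchanged. Ties on
    heavy-atom count are broken by lexicographically smallest canonical
    SMILES so the choice is deterministic.
    """
    if not smiles or not smiles.strip():
        raise StandardizationError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    best = min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return Chem.MolToSmiles(best)


def standardize_records(
    records: Iterable[MoleculeRecord], on_error: str = "raise"
) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Standardize SMILES in place on copies; return (kept, rejected).

    ``on_error='drop'`` collects rejects as (id, smiles) pairs instead of
    raising, leaving the caller to decide whether the loss is acceptable.
    """
    if on_error not in ("raise", "drop"):
        raise ValueError("on_error must be 'raise' or 'drop'")
    kept: list[MoleculeRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        try:
            smi = standardize_smiles(rec.smiles)
        except StandardizationError:
            if on_error == "raise":
                raise
            rejected.append((rec.id, rec.smiles))
            continue
        kept.append(
            MoleculeRecord(rec.id, smi, rec.label, rec.assay_year, rec.partner_id, rec.target_id)
        )
    return kept, rejected


def _label_array(records: Sequence[MoleculeRecord]) -> np.ndarray:
    return np.array(
        [MISSING_LABEL if r.label is None else int(r.label) for r in records], dtype=np.int64
    )


def featurize(
    records: Sequence[MoleculeRecord], radius: int = 3, n_bits: int = 2048
) -> FeatureMatrix:
    """Compute the descriptor + Morgan-fingerprint representation.

    One row per record in input order; identical SMILES give bitwise
    identical rows. Records must already be standardized (the function
    re-parses but does not strip salts).
    """
    cfg = load_descriptor_config(radius=radius, n_bits=n_bits)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    desc_fns = dict(Descriptors.descList)
    fns = [desc_fns[name] for name in cfg.descriptor_names]

    n = len(records)
    phys = np.empty((n, cfg.n_descriptors), dtype=np.float64)
    fps = np.empty((n, n_bits), dtype=np.uint8)
    for i, rec in enumerate(records):
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise FeaturizationError(rec.id, f"unparseable SMILES {rec.smiles!r}")
        try:
            row = [fn(mol) for fn in fns]
        except Exception as exc:  # descriptor implementations raise freely
            raise FeaturizationError(rec.id, str(exc)) from exc
        row = np.asarray(row, dtype=np.float64)
        if not np.all(np.isfinite(row)):
            bad = [cfg.descriptor_names[j] for j in np.flatnonzero(~np.isfinite(row))[:3]]
            raise FeaturizationError(rec.id, f"non-finite descriptors: {bad}")
        phys[i] = row
        fps[i] = np.frombuffer(
            gen.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
        ) - ord("0")
    return FeatureMatrix(
        ids=[r.id for r in records],
        physchem=phys,
        fingerprints=fps,
        labels=_label_array(records),
        config_hash=cfg.config_hash,
    )


@dataclass
class ScalerState:
    """Per-feature min/max for the descriptor block, fitted once then applied.

    Constant features (min == max) map to 0 to avoid division by zero.
    """

    min_: np.ndarray = field(default=None)  # type: ignore[assignment]
    max_: np.ndarray = field(default=None)  # type: ignore[assignment]
    fitted: bool = False

    def to_dict(self) -> dict:
        return {"min": self.min_.tolist(), "max": self.max_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(np.asarray(d["min"], float), np.asarray(d["max"], float), fitted=True)


def fit_scaler(features: FeatureMatrix) -> ScalerState:
    """Fit min-max bounds on the descriptor block of the reference matrix.

    By default the workflow fits on the designated reference (train+test
    jointly in classic mode, train only in strict mode — the caller picks
    the reference); fingerprint bits are never scaled.
    """
    phys = features.physchem
    if phys.shape[0] == 0:
        raise ValueError("cannot fit scaler on an empty matrix")
    return ScalerState(min_=phys.min(axis=0), max_=phys.max(axis=0), fitted=True)


def apply_scaler(state: ScalerState, features: FeatureMatrix, clip: bool = True) -> FeatureMatrix:
    """Map descriptors through (x - min) / (max - min), clipped to [0, 1].

    Fingerprint bits pass through unchanged. Applying an unfitted state is
    an error.
    """
    if not state.fitted or state.min_ is None:
        raise ValueError("scaler state is not fitted")
    span = state.max_ - state.min_
    safe = np.where(span > 0, span, 1.0)
    scaled = (features.physchem - state.min_) / safe
    scaled[:, span <= 0] = 0.0
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    return FeatureMatrix(
        ids=list(features.ids),
        physchem=scaled,
        fingerprints=features.fingerprints,
        labels=features.labels,
        config_hash=features.config_hash,
        scaled=True,
    )


def save_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Persist a FeatureMatrix as a compressed npz cache keyed by config hash."""
    np.savez_compressed(
        path,
        ids=np.array(fm.ids, dtype=object),
        physchem=fm.physchem,
        fingerprints=fm.fingerprints,
        labels=fm.labels,
        config_hash=np.array(fm.config_hash),
        scaled=np.array(fm.scaled),
    )


def load_feature_matrix(path) -> FeatureMatrix:
    with np.load(path, allow_pickle=True) as z:
        return FeatureMatrix(
            ids=[str(i) for i in z["ids"]],
            physchem=z["physchem"],
            fingerprints=z["fingerprints"],
            labels=z["labels"],
            config_hash=str(z["config_hash"]),
            scaled=bool(z["scaled"]),
        )


# ---------------------------------------------------------------------------
# CSV dialect: smiles,label,assay_year,partner_id,target_id (+ leading id)


def read_molecule_csv(path) -> list[MoleculeRecord]:
    """Read records from the package CSV dialect; blank label = unlabeled."""
    df = pd.read_csv(path, dtype={"smiles": str, "partner_id": str, "target_id": str})
    if "id" not in df.columns:
        df = df.reset_index().rename(columns={"index": "id"})
        df["id"] = df["id"].map(lambda i: f"row{i}")
    records = []
    for row in df.itertuples(index=False):
        label = None if pd.isna(row.label) else int(row.label)
        records.append(
            MoleculeRecord(
                id=str(row.id),
                smiles=row.smiles if isinstance(row.smiles, str) else "",
                label=label,
                assay_year=int(row.assay_year) if not pd.isna(row.assay_year) else 0,
                partner_id=str(row.partner_id) if not pd.isna(row.partner_id) else "",
                target_id=str(row.target_id) if not pd.isna(row.target_id) else "",
            )
        )
    return records


def write_molecule_csv(records: Sequence[MoleculeRecord], path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "label": [("" if r.label is None else r.label) for r in records],
            "assay_year": [r.assay_year for r in records],
            "partner_id": [r.partner_id for r in records],
            "target_id": [r.target_id for r in records],
        }
    )
    df.to_csv(path, index=False)
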