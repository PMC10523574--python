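"""Frozen micro-fixtures for regression tests.

Encodes the reported dataset-composition table of the five-target
secondary-pharmacology study (counts per target per dataset column), the
federated-set fill-rule worked examples, and hand MCC confusion tables.
Each fixture carries a ``provenance`` tag: "reported" (value printed in
the study), "derived" (computed from a closed form) or "trivial".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

__all__ = ["ReferenceFixture", "available_fixtures", "load_fixture"]


@dataclass
class ReferenceFixture:
    name: str
    description: str
    provenance: str
    data: dict

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "description": self.description,
             "provenance": self.provenance, "data": self.data},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceFixture":
        d = json.loads(text)
        return cls(**d)


def _registry() -> dict:
    text = (resources.files("fluidsim") / "data" / "reference_fixtures.json").read_text()
    return json.loads(text)


def available_fixtures() -> list[str]:
    return sorted(_registry())


def load_fixture(name: str) -> ReferenceFixture:
    """Load a registered fixture by name; unknown names list the registry."""
    reg = _registry()
    if name not in reg:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(reg)}")
    raw = dict(reg[name])
    return ReferenceFixture(
        name=name,
        description=raw.pop("description", ""),
        provenance=raw.pop("provenance", ""),
        data=raw,
    )
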