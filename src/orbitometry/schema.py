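"""Anatomical label schemas for orbital segmentation labelmaps.

A labelmap assigns one integer per voxel; the schema binds those integers to
anatomical roles.  The superior rectus and levator palpebrae are segmented as
a single complex (they are not separable on routine orbital CT), so the
schema carries one role for the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

ORBITAL_CAVITY = "orbital_cavity"
GLOBE = "globe"
MEDIAL_RECTUS = "medial_rectus"
LATERAL_RECTUS = "lateral_rectus"
INFERIOR_RECTUS = "inferior_rectus"
SUPERIOR_RECTUS_LEVATOR = "superior_rectus_levator_complex"
OPTIC_NERVE = "optic_nerve"
BONE = "bone"

#: The four extraocular straight muscles entering organ-volume accounting.
RECTUS_ROLES: tuple[str, ...] = (
    MEDIAL_RECTUS,
    LATERAL_RECTUS,
    INFERIOR_RECTUS,
    SUPERIOR_RECTUS_LEVATOR,
)

#: Soft-tissue roles counted as orbital content (see volumetry docs).
SOFT_TISSUE_ROLES: tuple[str, ...] = (GLOBE, *RECTUS_ROLES, OPTIC_NERVE)

MANDATORY_ROLES: tuple[str, ...] = (ORBITAL_CAVITY, GLOBE, *RECTUS_ROLES, BONE)
OPTIONAL_ROLES: tuple[str, ...] = (OPTIC_NERVE,)
ALL_ROLES: tuple[str, ...] = MANDATORY_ROLES + OPTIONAL_ROLES

_DEFAULT_LABELS = {
    ORBITAL_CAVITY: 1,
    GLOBE: 2,
    MEDIAL_RECTUS: 3,
    LATERAL_RECTUS: 4,
    INFERIOR_RECTUS: 5,
    SUPERIOR_RECTUS_LEVATOR: 6,
    OPTIC_NERVE: 7,
    BONE: 8,
}


class SchemaError(ValueError):
    """Invalid label schema."""


@dataclass(frozen=True)
class LabelSchema:
    """Mapping from anatomical role to integer label, plus orbit side.

    Parameters
    ----------
    labels
        role -> positive integer label; 0 is reserved for background.
        Mandatory roles: orbital_cavity, globe, the four rectus roles, bone.
    side
        ``"left"`` or ``"right"``; which orbit this labelmap describes.
    """

    labels: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_LABELS))
    side: str = "left"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise SchemaError(f"side must be 'left' or 'right', got {self.side!r}")
        for role in self.labels:
            if role not in ALL_ROLES:
                raise SchemaError(f"unknown anatomical role {role!r}")
        for role in MANDATORY_ROLES:
            if role not in self.labels:
                raise SchemaError(f"mandatory role {role!r} missing from schema")
        vals = list(self.labels.values())
        if any((not isinstance(v, (int,)) or isinstance(v, bool)) for v in vals):
            raise SchemaError("labels must be integers")
        if any(v <= 0 for v in vals):
            raise SchemaError("labels must be > 0 (0 is background)")
        if len(set(vals)) != len(vals):
            raise SchemaError("labels must be pairwise distinct")

    def label(self, role: str) -> int:
        try:
            return self.labels[role]
        except KeyError:
            raise SchemaError(f"role {role!r} not present in schema") from None

    def role_of(self, label: int) -> str:
        for role, lab in self.labels.items():
            if lab == label:
                return role
        raise SchemaError(f"label {label} not present in schema")

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.labels)

    def known_labels(self) -> set[int]:
        return set(self.labels.values())

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {"side": self.side, "labels": dict(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "LabelSchema":
        return cls(labels=dict(d["labels"]), side=d.get("side", "left"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "LabelSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_schema(side: str = "left") -> LabelSchema:
    """The package's default role->label assignment."""
    return LabelSchema(labels=dict(_DEFAULT_LABELS), side=side)
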