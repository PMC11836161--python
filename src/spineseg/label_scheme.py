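"""Semantic structure codes and instance-identifier conventions.

The 14 semantic structures are the ten vertebral substructures (corpus,
arcus, spinous process, the left/right articular processes inferior and
superior, the left/right costal processes, and the endplate) plus the
intervertebral disc (IVD), spinal canal, spinal cord and sacrum.  Code 0 is
reserved for background.  The numeric coding below is fixed here once and
serialized into a JSON sidecar next to every mask the CLI produces.

Instance identifiers: vertebrae are numbered 1..N from top (superior) to
bottom; each disc/endplate instance derives its id from the owning vertebra
via a disjoint offset block so vertebra and disc ids never collide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "SemanticScheme",
    "SCHEME",
    "CODES",
    "GROUPS",
    "GROUP_CODES",
    "BACKGROUND",
    "VERTEBRA_CODES",
    "anatomic_group",
    "DISC_OFFSET",
    "ENDPLATE_OFFSET",
    "MAX_VERTEBRAE",
    "disc_id",
    "endplate_id",
    "is_vertebra_id",
    "is_disc_id",
    "is_endplate_id",
    "owner_vertebra",
    "write_scheme_sidecar",
]

BACKGROUND = 0

_CODE_TABLE: dict[str, int] = {
    "corpus": 1,
    "arcus": 2,
    "spinous_process": 3,
    "articular_inferior_left": 4,
    "articular_inferior_right": 5,
    "articular_superior_left": 6,
    "articular_superior_right": 7,
    "costal_process_left": 8,
    "costal_process_right": 9,
    "endplate": 10,
    "ivd": 11,
    "spinal_canal": 12,
    "spinal_cord": 13,
    "sacrum": 14,
}

_GROUP_TABLE: dict[str, str] = {
    "corpus": "vertebra",
    "arcus": "vertebra",
    "spinous_process": "vertebra",
    "articular_inferior_left": "vertebra",
    "articular_inferior_right": "vertebra",
    "articular_superior_left": "vertebra",
    "articular_superior_right": "vertebra",
    "costal_process_left": "vertebra",
    "costal_process_right": "vertebra",
    "endplate": "endplate",
    "ivd": "ivd",
    "spinal_canal": "canal",
    "spinal_cord": "cord",
    "sacrum": "sacrum",
}

#: Integer codes for anatomic groups, used by masks derived per group.
GROUP_CODES: Mapping[str, int] = MappingProxyType(
    {"vertebra": 1, "ivd": 2, "endplate": 3, "canal": 4, "cord": 5, "sacrum": 6}
)


@dataclass(frozen=True)
class SemanticScheme:
    """The fixed 14-structure code set shared by all pipeline stages."""

    codes: Mapping[str, int] = field(default_factory=lambda: MappingProxyType(dict(_CODE_TABLE)))
    groups: Mapping[str, str] = field(default_factory=lambda: MappingProxyType(dict(_GROUP_TABLE)))

    def __post_init__(self) -> None:
        if set(self.codes) != set(self.groups):
            raise ValueError("group map must partition exactly the named structures")
        values = list(self.codes.values())
        if len(set(values)) != len(values) or any(v <= 0 for v in values):
            raise ValueError("codes must be unique positive integers (0 is background)")

    @property
    def names_by_code(self) -> dict[int, str]:
        return {v: k for k, v in self.codes.items()}

    @property
    def all_codes(self) -> frozenset[int]:
        return frozenset(self.codes.values())

    def group_of_code(self, code: int) -> str:
        if code == BACKGROUND:
            return "background"
        name = self.names_by_code.get(int(code))
        if name is None:
            raise KeyError(f"unknown semantic code {code}")
        return self.groups[name]

    def codes_in_group(self, group: str) -> frozenset[int]:
        return frozenset(c for n, c in self.codes.items() if self.groups[n] == group)


SCHEME = SemanticScheme()
CODES: Mapping[str, int] = SCHEME.codes
GROUPS: Mapping[str, str] = SCHEME.groups
#: The nine vertebral substructure codes forming the "vertebra" group.
VERTEBRA_CODES = SCHEME.codes_in_group("vertebra")


def anatomic_group(code: int, scheme: SemanticScheme = SCHEME) -> str:
    """Map a semantic code to its anatomic group (``"background"`` for 0)."""
    return scheme.group_of_code(code)


# --- instance identifier convention -------------------------------------------------

#: Disc instances occupy DISC_OFFSET + owning vertebra id.
DISC_OFFSET = 100
#: Endplate instances occupy ENDPLATE_OFFSET + owning vertebra id.
ENDPLATE_OFFSET = 200
#: Vertebra ids live in 1..MAX_VERTEBRAE, strictly below the disc block.
MAX_VERTEBRAE = DISC_OFFSET - 1


def disc_id(vertebra: int) -> int:
    if not is_vertebra_id(vertebra):
        raise ValueError(f"not a vertebra id: {vertebra}")
    return DISC_OFFSET + vertebra


def endplate_id(vertebra: int) -> int:
    if not is_vertebra_id(vertebra):
        raise ValueError(f"not a vertebra id: {vertebra}")
    return ENDPLATE_OFFSET + vertebra


def is_vertebra_id(i: int) -> bool:
    return 0 < i <= MAX_VERTEBRAE


def is_disc_id(i: int) -> bool:
    return DISC_OFFSET < i <= DISC_OFFSET + MAX_VERTEBRAE


def is_endplate_id(i: int) -> bool:
    return ENDPLATE_OFFSET < i <= ENDPLATE_OFFSET + MAX_VERTEBRAE


def owner_vertebra(i: int) -> int:
    """Owning vertebra id of any instance id."""
    if is_vertebra_id(i):
        return i
    if is_disc_id(i):
        return i - DISC_OFFSET
    if is_endplate_id(i):
        return i - ENDPLATE_OFFSET
    raise ValueError(f"instance id {i} outside all known ranges")


def write_scheme_sidecar(path: str | Path, scheme: SemanticScheme = SCHEME) -> Path:
    """Write the code → name → group table as a JSON sidecar."""
    path = Path(path)
    payload = {
        "background": BACKGROUND,
        "structures": [
            {"code": code, "name": name, "group": scheme.groups[name]}
            for name, code in sorted(scheme.codes.items(), key=lambda kv: kv[1])
        ],
        "instance_ranges": {
            "vertebra": [1, MAX_VERTEBRAE],
            "ivd": [DISC_OFFSET + 1, DISC_OFFSET + MAX_VERTEBRAE],
            "endplate": [ENDPLATE_OFFSET + 1, ENDPLATE_OFFSET + MAX_VERTEBRAE],
        },
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
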