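"""Tooth-type label schemes: 16 sided types, 8 anatomical types, 4 categories.

The canonical 16-label set covers the 8 maxillary tooth types × {Left,
Right}. Collapsing to 8 drops the side; collapsing to 4 groups anatomical
types into incisors / canines / premolars / molars. Integer class codes are
assigned alphabetically within each scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

__all__ = ["LabelScheme", "collapse_labels", "CANONICAL_16", "NAMES_8", "NAMES_4"]

_TYPES_8 = [
    "central incisor",
    "lateral incisor",
    "canine",
    "1st premolar",
    "2nd premolar",
    "1st molar",
    "2nd molar",
    "3rd molar",
]

_TITLE_8 = [
    "Central Incisor",
    "Lateral Incisor",
    "Canine",
    "1st Premolar",
    "2nd Premolar",
    "1st Molar",
    "2nd Molar",
    "3rd Molar",
]

CANONICAL_16: List[str] = [f"{t} (L)" for t in _TITLE_8] + [
    f"{t} (R)" for t in _TITLE_8
]

NAMES_8: List[str] = list(_TYPES_8)

NAMES_4: List[str] = ["incisors", "canines", "premolars", "molars"]

_TYPE_TO_4 = {
    "central incisor": "incisors",
    "lateral incisor": "incisors",
    "canine": "canines",
    "1st premolar": "premolars",
    "2nd premolar": "premolars",
    "1st molar": "molars",
    "2nd molar": "molars",
    "3rd molar": "molars",
}

MAP_16_TO_8: Dict[str, str] = {
    name: _TYPES_8[_TITLE_8.index(name[:-4])] for name in CANONICAL_16
}
MAP_16_TO_4: Dict[str, str] = {
    name: _TYPE_TO_4[MAP_16_TO_8[name]] for name in CANONICAL_16
}


@dataclass(frozen=True)
class LabelScheme:
    """A classification granularity: 16, 8 or 4 categories."""

    granularity: int = 16

    def __post_init__(self) -> None:
        if self.granularity not in (16, 8, 4):
            raise ValueError("granularity must be 16, 8 or 4")

    @property
    def names(self) -> List[str]:
        return {16: CANONICAL_16, 8: NAMES_8, 4: NAMES_4}[self.granularity]

    @property
    def classes(self) -> List[str]:
        """Class names in code order (alphabetical within the scheme)."""
        return sorted(self.names)

    def collapse(self, label16: str) -> str:
        if label16 not in CANONICAL_16:
            raise ValueError(
                f"unknown tooth label {label16!r}; canonical names are "
                f"{CANONICAL_16}"
            )
        if self.granularity == 16:
            return label16
        if self.granularity == 8:
            return MAP_16_TO_8[label16]
        return MAP_16_TO_4[label16]

    def code(self, name: str) -> int:
        """Integer class code (alphabetical order within the scheme)."""
        try:
            return self.classes.index(name)
        except ValueError:
            raise ValueError(
                f"{name!r} is not a class of the {self.granularity}-way scheme"
            ) from None

    def encode(self, labels16: Sequence[str]) -> List[int]:
        """Collapse a sequence of 16-way labels and map to integer codes."""
        return [self.code(self.collapse(l)) for l in labels16]


def collapse_labels(label16: str, scheme: LabelScheme) -> str:
    """Map a canonical 16-way label to its class under ``scheme``."""
    return scheme.collapse(label16)
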