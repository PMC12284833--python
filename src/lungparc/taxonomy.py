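"""The three-level lung anatomy: lungs -> lobes -> bronchopulmonary segments.

Human lungs divide into 5 lobes (3 right, 2 left) and, by the usual clinical
convention, 18 bronchopulmonary segments — the left lung fuses B1+B2
(apicoposterior) and B7+B8 (anteromedial basal) into single segments.  Each
segment is served by its own tertiary (segmental) bronchus, which is what the
parcellation modules key on.

Integer label codes are fixed at 1-18 (right B1..B10 = 1-10, then left
B1/2, B3, B4, B5, B6, B7/8, B9, B10 = 11-18); 0 is reserved for background.
These values are what appears in output NIfTI label volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from types import MappingProxyType

__all__ = [
    "SegmentTaxonomy",
    "build_taxonomy",
    "segments_for_lobe",
    "taxonomy_to_json",
    "LOBES",
    "RUL",
    "RML",
    "RLL",
    "LUL",
    "LLL",
]

RUL, RML, RLL, LUL, LLL = "RUL", "RML", "RLL", "LUL", "LLL"
LOBES: tuple[str, ...] = (RUL, RML, RLL, LUL, LLL)

# (code, short name, full anatomical name, lobe)
_SEGMENTS: tuple[tuple[int, str, str, str], ...] = (
    (1, "B1", "Apical segment (B1)", RUL),
    (2, "B2", "Posterior segment (B2)", RUL),
    (3, "B3", "Anterior segment (B3)", RUL),
    (4, "B4", "Lateral segment (B4)", RML),
    (5, "B5", "Medial segment (B5)", RML),
    (6, "B6", "Superior segment (B6)", RLL),
    (7, "B7", "Medial basal segment (B7)", RLL),
    (8, "B8", "Anterior basal segment (B8)", RLL),
    (9, "B9", "Lateral basal segment (B9)", RLL),
    (10, "B10", "Posterior basal segment (B10)", RLL),
    (11, "B1/2", "Apicoposterior segment (B1/2)", LUL),
    (12, "B3", "Anterior segment (B3)", LUL),
    (13, "B4", "Superior lingular segment (B4)", LUL),
    (14, "B5", "Inferior lingular segment (B5)", LUL),
    (15, "B6", "Superior segment (B6)", LLL),
    (16, "B7/8", "Anteromedial basal segment (B7/8)", LLL),
    (17, "B9", "Lateral basal segment (B9)", LLL),
    (18, "B10", "Posterior basal segment (B10)", LLL),
)


@dataclass(frozen=True)
class SegmentTaxonomy:
    """Queryable lobe/segment anatomy with fixed integer codes."""

    lobes: tuple[str, ...]
    segments: tuple[int, ...]
    lobe_of: MappingProxyType  # segment code -> lobe id
    name_of: MappingProxyType  # segment code -> full anatomical name
    short_name_of: MappingProxyType  # segment code -> bronchus shorthand
    side_of: MappingProxyType  # lobe id -> "right" | "left"
    _by_lobe: MappingProxyType = field(repr=False)

    def segments_for_lobe(self, lobe: str) -> tuple[int, ...]:
        if lobe not in self._by_lobe:
            raise KeyError(f"unknown lobe id {lobe!r}; expected one of {self.lobes}")
        return self._by_lobe[lobe]

    def lobe_code(self, lobe: str) -> int:
        """Integer code for a lobe (1-5 in RUL, RML, RLL, LUL, LLL order)."""
        if lobe not in self.lobes:
            raise KeyError(f"unknown lobe id {lobe!r}; expected one of {self.lobes}")
        return self.lobes.index(lobe) + 1

    def lobe_from_code(self, code: int) -> str:
        if not 1 <= code <= len(self.lobes):
            raise KeyError(f"unknown lobe code {code}")
        return self.lobes[code - 1]


def build_taxonomy() -> SegmentTaxonomy:
    """Return the fixed 18-segment / 5-lobe taxonomy.

    Deterministic and side-effect-free; repeated calls yield equal structures.
    """
    by_lobe: dict[str, tuple[int, ...]] = {
        lobe: tuple(c for c, _, _, lb in _SEGMENTS if lb == lobe) for lobe in LOBES
    }
    return SegmentTaxonomy(
        lobes=LOBES,
        segments=tuple(c for c, _, _, _ in _SEGMENTS),
        lobe_of=MappingProxyType({c: lb for c, _, _, lb in _SEGMENTS}),
        name_of=MappingProxyType({c: full for c, _, full, _ in _SEGMENTS}),
        short_name_of=MappingProxyType({c: s for c, s, _, _ in _SEGMENTS}),
        side_of=MappingProxyType(
            {RUL: "right", RML: "right", RLL: "right", LUL: "left", LLL: "left"}
        ),
        _by_lobe=MappingProxyType(by_lobe),
    )


def segments_for_lobe(tax: SegmentTaxonomy, lobe: str) -> tuple[int, ...]:
    """Segment codes belonging to ``lobe`` (3/2/5/4/4 for RUL/RML/RLL/LUL/LLL)."""
    return tax.segments_for_lobe(lobe)


def taxonomy_to_json(tax: SegmentTaxonomy, path=None) -> str:
    """Serialize the taxonomy (code, names, lobe, side) as JSON."""
    entries = [
        {
            "code": c,
            "short_name": tax.short_name_of[c],
            "full_name": tax.name_of[c],
            "lobe": tax.lobe_of[c],
            "side": tax.side_of[tax.lobe_of[c]],
        }
        for c in tax.segments
    ]
    text = json.dumps({"segments": entries, "lobes": list(tax.lobes)}, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
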