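"""Tequila category labels and their fixed ordering.

The three categories are defined by aging: Silver (unaged), Aged (at least
two months in oak), Extra-aged (at least one year in oak vessels of 600 L
or less).  Every module that needs an ordering of class labels — tie-breaks
in the discriminant classifier, confusion-matrix layout, report rows —
uses ``CATEGORY_ORDER`` so results are reproducible.
"""

from __future__ import annotations

CATEGORY_ORDER: tuple[str, str, str] = ("Silver", "Aged", "Extra-aged")

# Longest prefix first: "EA" must match before "A".
_TAG_PREFIXES: tuple[tuple[str, str], ...] = (
    ("EA", "Extra-aged"),
    ("A", "Aged"),
    ("S", "Silver"),
)


def category_from_tag(tag: str) -> str:
    """Infer the category from a sample tag such as ``"S1"``, ``"A7"`` or ``"EA5"``."""
    for prefix, category in _TAG_PREFIXES:
        if tag.startswith(prefix):
            return category
    raise ValueError(f"tag {tag!r} has no recognised category prefix (S/A/EA)")


def tag_sort_key(tag: str) -> tuple[int, int, str]:
    """Sort key giving category order first, then the numeric suffix (S1 < S2 < ... < A1)."""
    category = category_from_tag(tag)
    digits = "".join(ch for ch in tag if ch.isdigit())
    return (CATEGORY_ORDER.index(category), int(digits) if digits else 0, tag)
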