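"""Genus vocabulary and name normalisation.

16S genus labels in the SILVA taxonomy carry punctuation, spacing and
composite-group suffixes ("Ruminococcaceae UCG-005", "[Eubacterium]
xylanophilum group") that are written inconsistently across tools and
manuscripts.  All genus matching in this package goes through
:func:`normalize_genus`, which collapses case, punctuation, bracket and
common misspelling variants to a single canonical key.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence

#: Genera whose summed relative abundance forms the numerator of the
#: CAD-related dysbiosis index (enriched in obstructive disease).
NUMERATOR_GENERA: tuple[str, ...] = (
    "Veillonella",
    "Ruminococcus gnavus group",
    "Alistipes",
)

#: Genera whose summed relative abundance forms the denominator of the
#: index (depleted in obstructive disease; several are butyrate producers).
DENOMINATOR_GENERA: tuple[str, ...] = (
    "Prevotella 9",
    "Megasphaera",
    "Moryella",
    "Catenibacterium",
    "Fusicatenibacter",
    "Ruminococcaceae UCG-005",
    "Ruminococcaceae UCG-009",
    "Lachnospiraceae ND3007 group",
    "Eubacterium xylanophilum group",
)

INDEX_GENERA: tuple[str, ...] = NUMERATOR_GENERA + DENOMINATOR_GENERA

#: Genera treated as the main microbial producers of imidazole propionate.
PRODUCER_GENERA: tuple[str, ...] = (
    "Veillonella",
    "Ruminococcus gnavus group",
)

# frequent manuscript/tool spelling variants -> canonical token
_TOKEN_FIXES = {
    "megashpaera": "megasphaera",
    "ruminococcacea": "ruminococcaceae",
    "lachnospiracea": "lachnospiraceae",
    "veillonellacea": "veillonellaceae",
}


def normalize_genus(name: str) -> str:
    """Return the canonical matching key for a genus label.

    Lower-cases, strips brackets/underscores/hyphens/dots, collapses
    whitespace and repairs common truncated family-name misspellings, so
    that e.g. ``"[Ruminococcus] gnavus group"``, ``"Ruminococcus_gnavus
    group"`` and ``"Ruminococcus gnavus group"`` all map to one key, and
    ``"Ruminococcacea UCG 005"`` matches ``"Ruminococcaceae UCG-005"``.
    """
    if not isinstance(name, str) or not name.strip():
        raise ValueError(f"invalid genus label: {name!r}")
    key = name.lower()
    key = re.sub(r"[\[\]().]", "", key)
    key = re.sub(r"[-_/]", " ", key)
    key = re.sub(r"\s+", " ", key).strip()
    tokens = [_TOKEN_FIXES.get(tok, tok) for tok in key.split(" ")]
    return " ".join(tokens)


def match_genera(
    wanted: Iterable[str], available: Sequence[str]
) -> tuple[dict[str, str], list[str]]:
    """Match requested genus names against a table's columns.

    Returns ``(mapping, missing)`` where ``mapping`` maps each wanted name
    to the matching column label (via :func:`normalize_genus`) and
    ``missing`` lists wanted names with no match.
    """
    lookup: dict[str, str] = {}
    for col in available:
        lookup.setdefault(normalize_genus(col), col)
    mapping: dict[str, str] = {}
    missing: list[str] = []
    for name in wanted:
        col = lookup.get(normalize_genus(name))
        if col is None:
            missing.append(name)
        else:
            mapping[name] = col
    return mapping, missing
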