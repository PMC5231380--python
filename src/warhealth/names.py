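"""Canonical district spellings and alias resolution.

Sri Lankan district names have no official numeric codes in the source
material, so the district name is the join key throughout.  Published
spellings vary (Kilinochchi/Kilinochi, Kaluthara/Kalutara, ...); every
reader normalizes through this table and keeps the canonical form.
"""

from __future__ import annotations

CANONICAL_DISTRICTS: tuple[str, ...] = (
    "Ampara",
    "Anuradhapura",
    "Badulla",
    "Batticaloa",
    "Colombo",
    "Galle",
    "Gampaha",
    "Hambantota",
    "Jaffna",
    "Kaluthara",
    "Kandy",
    "Kegalle",
    "Kilinochchi",
    "Kurunegala",
    "Mannar",
    "Matale",
    "Matara",
    "Moneragala",
    "Mullaitivu",
    "Nuwara Eliya",
    "Polonnaruwa",
    "Puttalam",
    "Ratnapura",
    "Trincomalee",
    "Vavuniya",
)

# variant spelling -> canonical; keys are lowercase
ALIASES: dict[str, str] = {
    "kilinochi": "Kilinochchi",
    "killinochchi": "Kilinochchi",
    "kalutara": "Kaluthara",
    "batticoloa": "Batticaloa",
    "baticalloa": "Batticaloa",
    "trincomallee": "Trincomalee",
    "monaragala": "Moneragala",
    "nuwara-eliya": "Nuwara Eliya",
    "nuwaraeliya": "Nuwara Eliya",
    "vavuniy": "Vavuniya",
    "amparai": "Ampara",
}

_CANONICAL_LOWER = {name.lower(): name for name in CANONICAL_DISTRICTS}


def normalize_unit(name: str) -> str:
    """Resolve a district name (or the NATIONAL pseudo-unit) to canonical form.

    Unknown names are returned stripped but otherwise untouched, so synthetic
    unit ids pass through.
    """
    key = name.strip()
    low = key.lower()
    if low in ("national", "sri lanka"):
        return "NATIONAL"
    if low in _CANONICAL_LOWER:
        return _CANONICAL_LOWER[low]
    if low in ALIASES:
        return ALIASES[low]
    return key
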