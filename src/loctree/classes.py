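"""Localization class sets per domain of life, and class-merging maps.

Eukaryotes are predicted in 18 compartments (10 soluble/non-membrane plus 8
membrane classes), bacteria in 6 and archaea in 3.  For comparisons against
coarser methods some classes are conventionally merged: nuclear membrane with
nucleus, plastid with chloroplast, and bacterial fimbrium with extra-cellular
(secreted) proteins.
"""

from __future__ import annotations

import enum

__all__ = [
    "DomainOfLife",
    "class_set",
    "comparison_merge_map",
    "default_k",
    "identity_merge_map",
    "membrane_classes",
    "non_membrane_classes",
]


class DomainOfLife(enum.Enum):
    EUKARYOTA = "eukaryota"
    BACTERIA = "bacteria"
    ARCHAEA = "archaea"

    @classmethod
    def from_string(cls, s: str) -> "DomainOfLife":
        return cls(s.strip().lower())


_EUKARYOTA_NON_MEMBRANE = (
    "chloroplast",
    "cytosol",
    "endoplasmic reticulum",
    "extra-cellular",
    "golgi apparatus",
    "mitochondrion",
    "nucleus",
    "peroxisome",
    "plastid",
    "vacuole",
)

_EUKARYOTA_MEMBRANE = (
    "chloroplast membrane",
    "endoplasmic reticulum membrane",
    "golgi apparatus membrane",
    "mitochondrion membrane",
    "nucleus membrane",
    "peroxisome membrane",
    "plasma membrane",
    "vacuole membrane",
)

_CLASS_SETS: dict[DomainOfLife, tuple[str, ...]] = {
    DomainOfLife.EUKARYOTA: _EUKARYOTA_NON_MEMBRANE + _EUKARYOTA_MEMBRANE,
    DomainOfLife.BACTERIA: (
        "cytosol",
        "plasma membrane",
        "periplasmic space",
        "outer membrane",
        "fimbrium",
        "extra-cellular",
    ),
    DomainOfLife.ARCHAEA: ("cytosol", "plasma membrane", "extra-cellular"),
}

# k-mer length of the profile kernel per domain of life
_DEFAULT_K = {
    DomainOfLife.EUKARYOTA: 6,
    DomainOfLife.BACTERIA: 5,
    DomainOfLife.ARCHAEA: 3,
}


def class_set(domain: DomainOfLife) -> tuple[str, ...]:
    """Localization classes of *domain* (18 / 6 / 3), in canonical order."""
    return _CLASS_SETS[domain]


def non_membrane_classes() -> tuple[str, ...]:
    return _EUKARYOTA_NON_MEMBRANE


def membrane_classes() -> tuple[str, ...]:
    return _EUKARYOTA_MEMBRANE


def default_k(domain: DomainOfLife) -> int:
    """Default kernel k-mer length: 6 eukaryota, 5 bacteria, 3 archaea."""
    return _DEFAULT_K[domain]


def identity_merge_map(domain: DomainOfLife) -> dict[str, str]:
    """Total merge map sending every class to itself."""
    return {c: c for c in class_set(domain)}


def comparison_merge_map(domain: DomainOfLife) -> dict[str, str]:
    """Merge map used when comparing against coarser-grained methods.

    Eukaryota: nuclear membrane folds into nucleus and plastid into
    chloroplast (18 -> 16 effective classes).  Bacteria: fimbrium folds into
    extra-cellular (6 -> 5).  Archaea: identity.
    """
    merge = identity_merge_map(domain)
    if domain is DomainOfLife.EUKARYOTA:
        merge["nucleus membrane"] = "nucleus"
        merge["plastid"] = "chloroplast"
    elif domain is DomainOfLife.BACTERIA:
        merge["fimbrium"] = "extra-cellular"
    return merge
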