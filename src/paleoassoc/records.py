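"""Core record types for fossil occurrence data.

An *occurrence* is the presence of a particular taxon at a particular
locality at a particular time.  Each record carries the curation fields the
downstream tests depend on: a broad paleoenvironmental class, a broad
taphonomic completeness category, a dubious flag, and an optional
curator-assigned paralogy group linking records that may sample the same
ancient ecosystem (same stratigraphic unit, age and environment).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "Taxon",
    "Epoch",
    "Paleoenv",
    "TaphCategory",
    "OccurrenceRecord",
    "ValidationError",
    "validate_records",
]


class ValidationError(ValueError):
    """A record or record set violates the occurrence-data contract."""


class Taxon(enum.Enum):
    ABELISAURIDAE = "Abelisauridae"
    CARCHARODONTOSAURIDAE = "Carcharodontosauridae"
    SPINOSAURIDAE = "Spinosauridae"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Epoch(enum.Enum):
    JURASSIC = "Jurassic"
    EARLY_CRETACEOUS = "Early Cretaceous"
    LATE_CRETACEOUS = "Late Cretaceous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Paleoenv(enum.Enum):
    TERRESTRIAL = "terrestrial"
    COASTAL = "coastal"
    MARINE = "marine"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class TaphCategory(enum.Enum):
    """Broad completeness category of the fossil record behind an occurrence.

    CAT1: (semi)articulated or associated cranial/postcranial remains
    (low inferred transport).  CAT2: only isolated, fragmentary material
    (high inferred transport).  UNSPECIFIED: the source does not describe
    the nature of the material.
    """

    CAT1 = "1"
    CAT2 = "2"
    UNSPECIFIED = "unspecified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Merge precedence: the best-documented category wins when paralogous
#: occurrences are collapsed to one.
_CATEGORY_PRECEDENCE = {
    TaphCategory.CAT1: 0,
    TaphCategory.CAT2: 1,
    TaphCategory.UNSPECIFIED: 2,
}


def best_category(categories: Iterable[TaphCategory]) -> TaphCategory:
    """Return the highest-precedence category (CAT1 > CAT2 > UNSPECIFIED)."""
    cats = list(categories)
    if not cats:
        raise ValueError("empty category collection")
    return min(cats, key=_CATEGORY_PRECEDENCE.__getitem__)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One taxon-locality-time occurrence with its curation flags."""

    occurrence_id: str
    locality_id: str
    taxon: Taxon
    strat_unit: str
    epoch: Epoch
    paleoenv: Paleoenv
    taph_category: TaphCategory = TaphCategory.UNSPECIFIED
    dubious: bool = False
    paralogy_group: Optional[str] = None

    def replace(self, **kwargs) -> "OccurrenceRecord":
        return replace(self, **kwargs)


def validate_records(records: Iterable[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Check dataset-level invariants.

    * occurrence_id unique;
    * every paralogy group is homogeneous in taxon, paleoenvironment and
      epoch (the definition of possibly-paralogous occurrences).

    Returns the records as a list; raises :class:`ValidationError` on the
    first violation.
    """
    records = list(records)
    seen: set[str] = set()
    groups: dict[str, tuple[Taxon, Paleoenv, Epoch]] = {}
    for rec in records:
        if rec.occurrence_id in seen:
            raise ValidationError(f"duplicate occurrence_id {rec.occurrence_id!r}")
        seen.add(rec.occurrence_id)
        if rec.paralogy_group is not None:
            key = (rec.taxon, rec.paleoenv, rec.epoch)
            prev = groups.setdefault(rec.paralogy_group, key)
            if prev != key:
                raise ValidationError(
                    f"paralogy group {rec.paralogy_group!r} mixes "
                    f"taxon/paleoenv/epoch: {prev} vs {key}"
                )
    return records
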