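"""Curation of occurrence records into dataset variants and contingency
tables.

Four dataset variants express the sensitivity analysis to problematic
occurrences:

* **I** – all occurrences;
* **II** – possibly-paralogous occurrences synonymized (collapsed to one);
* **III** – dubious occurrences excluded;
* **IV** – synonymized first, then dubious merged records excluded.

Synonymization merges a paralogy group into a single occurrence.  The
merged record is dubious only when *every* member is dubious (a valid
member "rescues" the occurrence), and its taphonomic category is the best
one present (articulated/associated material beats fragments beats
unspecified).  Because of the rescue rule, |IV| is generally not
|I| − #paralogous − #dubious.

Eight test designs then map a variant onto a labelled count table; marine
occurrences are always excluded (too few), and the epoch design also drops
the few Jurassic records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .io import CountsFixture
from .records import (
    Epoch,
    OccurrenceRecord,
    Paleoenv,
    TaphCategory,
    Taxon,
    ValidationError,
    best_category,
    validate_records,
)

__all__ = [
    "DegenerateDesignError",
    "ContingencyTable",
    "TestSpec",
    "TEST_SPECS",
    "TEST_IDS",
    "DatasetVariant",
    "VARIANT_LABELS",
    "synonymize",
    "build_variant",
    "build_all_variants",
    "assemble_table",
    "table_from_fixture",
]

VARIANT_LABELS = ("I", "II", "III", "IV")

ENV_COLUMNS = (Paleoenv.COASTAL, Paleoenv.TERRESTRIAL)


class DegenerateDesignError(ValueError):
    """The requested design yields an empty table or a zero margin."""


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled non-negative integer count table (k rows, 1 or 2 columns)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match counts shape")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.row_labels) < 2 or not 1 <= len(self.col_labels) <= 2:
            raise DegenerateDesignError(
                f"need >=2 rows and 1-2 columns, got {counts.shape}"
            )
        if counts.sum() == 0:
            raise DegenerateDesignError("empty table")
        if (counts.sum(axis=0) == 0).any() or (
            counts.shape[1] > 1 and (counts.sum(axis=1) == 0).any()
        ):
            raise DegenerateDesignError("zero margin")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def cell_keys(self) -> list[tuple[str, str]]:
        """(row label, column label) pairs in row-major order."""
        return [(r, c) for r in self.row_labels for c in self.col_labels]


@dataclass(frozen=True)
class TestSpec:
    """One of the battery's test designs."""

    test_id: str
    row_scheme: str  # taxon | taxon_x_category | category_within_taxon | epoch
    env: Optional[Paleoenv]  # single-environment designs; None = both columns
    taxon_filter: Optional[Taxon] = None
    include_unspecified_taphonomy: bool = True
    pool_across_taxa: bool = False
    description: str = ""


TEST_SPECS: dict[str, TestSpec] = {
    s.test_id: s
    for s in [
        TestSpec("T1_C", "taxon", Paleoenv.COASTAL,
                 description="taxa vs coastal occurrences"),
        TestSpec("T1_T", "taxon", Paleoenv.TERRESTRIAL,
                 description="taxa vs terrestrial occurrences"),
        TestSpec("T2", "taxon", None,
                 description="taxa vs both environments"),
        TestSpec("T3_C", "taxon_x_category", Paleoenv.COASTAL,
                 include_unspecified_taphonomy=False,
                 description="taxon x taphonomy vs coastal"),
        TestSpec("T3_T", "taxon_x_category", Paleoenv.TERRESTRIAL,
                 include_unspecified_taphonomy=False,
                 description="taxon x taphonomy vs terrestrial"),
        TestSpec("T4", "taxon_x_category", None,
                 include_unspecified_taphonomy=False,
                 description="taxon x taphonomy vs both environments"),
        TestSpec("T5", "category_within_taxon", None,
                 taxon_filter=Taxon.ABELISAURIDAE,
                 include_unspecified_taphonomy=False,
                 description="abelisaurid taphonomy vs environments"),
        TestSpec("T6", "category_within_taxon", None,
                 taxon_filter=Taxon.CARCHARODONTOSAURIDAE,
                 include_unspecified_taphonomy=False,
                 description="carcharodontosaurid taphonomy vs environments"),
        TestSpec("T7", "category_within_taxon", None,
                 taxon_filter=Taxon.SPINOSAURIDAE,
                 include_unspecified_taphonomy=False,
                 description="spinosaurid taphonomy vs environments"),
        TestSpec("T8", "epoch", None, pool_across_taxa=True,
                 description="Cretaceous epochs vs environments"),
    ]
}

TEST_IDS = tuple(TEST_SPECS)

#: Designs whose table is 2x2 and therefore also gets Fisher's exact test.
FISHER_TESTS = ("T5", "T6", "T7", "T8")


@dataclass(frozen=True)
class DatasetVariant:
    label: str
    records: tuple[OccurrenceRecord, ...]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Synonymization and variant construction
# ---------------------------------------------------------------------------

def synonymize(records: Iterable[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Collapse each paralogy group to a single merged occurrence.

    Records without a ``paralogy_group`` pass through unchanged.  A merged
    record takes the first member's identifiers, is dubious only if all
    members are, and gets the best taphonomic category present.  Output
    order is deterministic: each merged record sits at its first member's
    position in the input order.
    """
    records = validate_records(records)
    out: list[OccurrenceRecord] = []
    members: dict[tuple[Taxon, str], list[OccurrenceRecord]] = {}
    slot: dict[tuple[Taxon, str], int] = {}
    for rec in records:
        if rec.paralogy_group is None:
            out.append(rec)
            continue
        key = (rec.taxon, rec.paralogy_group)
        if key not in members:
            members[key] = []
            out.append(rec)  # placeholder at first-member position
            slot[key] = len(out) - 1
        members[key].append(rec)
    for key, group in members.items():
        first = group[0]
        merged = first.replace(
            dubious=all(r.dubious for r in group),
            taph_category=best_category(r.taph_category for r in group),
        )
        out[slot[key]] = merged
    return out


def build_variant(
    records: Iterable[OccurrenceRecord], label: str
) -> DatasetVariant:
    """Apply the curation rules for one dataset variant (I, II, III or IV)."""
    records = list(records)
    if label == "I":
        kept = records
    elif label == "II":
        kept = synonymize(records)
    elif label == "III":
        kept = [r for r in records if not r.dubious]
    elif label == "IV":
        kept = [r for r in synonymize(records) if not r.dubious]
    else:
        raise ValueError(f"unknown dataset variant {label!r}")
    return DatasetVariant(label=label, records=tuple(kept))


def build_all_variants(
    records: Iterable[OccurrenceRecord],
) -> dict[str, DatasetVariant]:
    records = list(records)
    return {lab: build_variant(records, lab) for lab in VARIANT_LABELS}


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def _row_label(taxon: Taxon, category: Optional[TaphCategory] = None) -> str:
    if category is None:
        return taxon.value
    return f"{taxon.value} {category.value}"


def _columns(spec: TestSpec) -> tuple[Paleoenv, ...]:
    return (spec.env,) if spec.env is not None else ENV_COLUMNS


def assemble_table(
    variant: DatasetVariant, spec: Union[TestSpec, str]
) -> ContingencyTable:
    """Count a dataset variant into the contingency table of one design.

    Marine occurrences are always excluded.  Category-based designs drop
    records with unspecified taphonomy; the epoch design drops Jurassic
    records and counts each locality-time once even when several taxa
    occur there.
    """
    if isinstance(spec, str):
        spec = TEST_SPECS[spec]
    cols = _columns(spec)
    recs = [r for r in variant.records if r.paleoenv is not Paleoenv.MARINE]
    if not spec.include_unspecified_taphonomy:
        recs = [r for r in recs if r.taph_category is not TaphCategory.UNSPECIFIED]
    if spec.taxon_filter is not None:
        recs = [r for r in recs if r.taxon is spec.taxon_filter]
    recs = [r for r in recs if r.paleoenv in cols]

    if spec.row_scheme == "taxon":
        rows = [(t.value, lambda r, t=t: r.taxon is t) for t in Taxon]
    elif spec.row_scheme == "taxon_x_category":
        rows = [
            (
                _row_label(t, c),
                lambda r, t=t, c=c: r.taxon is t and r.taph_category is c,
            )
            for t in Taxon
            for c in (TaphCategory.CAT1, TaphCategory.CAT2)
        ]
    elif spec.row_scheme == "category_within_taxon":
        t = spec.taxon_filter
        if t is None:
            raise ValueError("category_within_taxon design needs a taxon filter")
        rows = [
            (_row_label(t, c), lambda r, c=c: r.taph_category is c)
            for c in (TaphCategory.CAT1, TaphCategory.CAT2)
        ]
    elif spec.row_scheme == "epoch":
        # One count per locality-time: drop duplicate records of the same
        # site and age contributed by different taxa.
        seen: set[tuple[str, str, Epoch]] = set()
        unique = []
        for r in recs:
            key = (r.locality_id, r.strat_unit, r.epoch)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        recs = [r for r in unique if r.epoch is not Epoch.JURASSIC]
        rows = [
            (e.value, lambda r, e=e: r.epoch is e)
            for e in (Epoch.EARLY_CRETACEOUS, Epoch.LATE_CRETACEOUS)
        ]
    else:
        raise ValueError(f"unknown row scheme {spec.row_scheme!r}")

    counts = np.zeros((len(rows), len(cols)), dtype=int)
    for i, (_, pred) in enumerate(rows):
        for j, env in enumerate(cols):
            counts[i, j] = sum(
                1 for r in recs if pred(r) and r.paleoenv is env
            )
    if counts.sum() != len(recs):
        raise ValidationError("records left unclassified by the design")
    return ContingencyTable(
        row_labels=tuple(lab for lab, _ in rows),
        col_labels=tuple(e.value for e in cols),
        counts=counts,
    )


def table_from_fixture(
    fixture: CountsFixture, test_id: str, variant: str
) -> ContingencyTable:
    """Build the contingency table of one design directly from published
    counts, bypassing record-level curation."""
    spec = TEST_SPECS[test_id]
    cols = _columns(spec)
    col_labels = tuple(e.value for e in cols)
    if spec.row_scheme == "taxon":
        counts = [
            [fixture.taxon_env_total(t, variant, e) for e in cols] for t in Taxon
        ]
        rows = tuple(t.value for t in Taxon)
    elif spec.row_scheme == "taxon_x_category":
        pairs = [
            (t, c) for t in Taxon for c in (TaphCategory.CAT1, TaphCategory.CAT2)
        ]
        counts = [[fixture.cell(t, c, variant, e) for e in cols] for t, c in pairs]
        rows = tuple(_row_label(t, c) for t, c in pairs)
    elif spec.row_scheme == "category_within_taxon":
        t = spec.taxon_filter
        cats = (TaphCategory.CAT1, TaphCategory.CAT2)
        counts = [[fixture.cell(t, c, variant, e) for e in cols] for c in cats]
        rows = tuple(_row_label(t, c) for c in cats)
    elif spec.row_scheme == "epoch":
        epochs = (Epoch.EARLY_CRETACEOUS, Epoch.LATE_CRETACEOUS)
        counts = [[fixture.epoch_cell(ep, variant, e) for e in cols] for ep in epochs]
        rows = tuple(ep.value for ep in epochs)
    else:  # pragma: no cover - exhaustive above
        raise ValueError(spec.row_scheme)
    return ContingencyTable(
        row_labels=rows, col_labels=col_labels, counts=np.array(counts)
    )
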