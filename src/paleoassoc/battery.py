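"""The 8-design x 4-variant test battery, residual-based association
signs, and cross-test concordance.

A design is *significant* when its operative p-value (Monte-Carlo when
triggered, asymptotic otherwise) is strictly below alpha.  Only then are
per-cell association signs assigned, by the sign of the Pearson residual;
non-significant designs carry ``n/a`` everywhere.  Fisher's exact test is
reported for the 2x2 designs but never gates sign assignment.

Concordance between two significant designs counts equal signs over the
(row label, environment) keys they share; designs with disjoint keys are
incomparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .curation import (
    FISHER_TESTS,
    TEST_IDS,
    TEST_SPECS,
    VARIANT_LABELS,
    ContingencyTable,
    DegenerateDesignError,
    assemble_table,
    build_all_variants,
    table_from_fixture,
)
from .engine import ChiSquareResult, EngineConfig, FisherResult, chi_square, fisher_exact_2x2
from .io import CountsFixture
from .records import OccurrenceRecord

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "NA",
    "TestResult",
    "ConcordanceEntry",
    "decide_p",
    "assign_signs",
    "run_battery",
    "concordance",
    "concordance_matrix",
    "display_label",
]

POSITIVE = "+"
NEGATIVE = "-"
NA = "n/a"

SignMap = dict[tuple[str, str], str]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one design on one dataset variant."""

    test_id: str
    dataset: str
    chi2: Optional[ChiSquareResult] = None
    fisher: Optional[FisherResult] = None
    significant: bool = False
    signs: SignMap = field(default_factory=dict)
    skipped: bool = False
    skip_reason: Optional[str] = None

    @property
    def p_operative(self) -> Optional[float]:
        return decide_p(self.chi2) if self.chi2 is not None else None

    def to_dict(self) -> dict:
        d: dict = {
            "test_id": self.test_id,
            "dataset": self.dataset,
            "skipped": self.skipped,
            "skip_reason": self.skip_reason,
        }
        if self.chi2 is not None:
            d.update(
                statistic=self.chi2.statistic,
                df=self.chi2.df,
                p_asymptotic=self.chi2.p_asymptotic,
                mc_used=self.chi2.mc_used,
                p_mc=self.chi2.p_mc,
                p_operative=self.p_operative,
                significant=self.significant,
                signs={f"{r}|{c}": s for (r, c), s in self.signs.items()},
            )
        if self.fisher is not None:
            d["fisher_or"] = self.fisher.or_cmle
            d["fisher_p"] = self.fisher.p_two_sided
        return d


@dataclass(frozen=True)
class ConcordanceEntry:
    test_a: str
    test_b: str
    matched: int
    total: int

    def __str__(self) -> str:
        return f"{self.matched}/{self.total}"


def decide_p(result: ChiSquareResult) -> float:
    """The operative p-value: Monte-Carlo when triggered, else asymptotic."""
    if result.mc_used:
        if result.p_mc is None:
            raise ValueError("Monte-Carlo was triggered but p_mc is missing")
        return result.p_mc
    return result.p_asymptotic


def assign_signs(
    result: ChiSquareResult, config: EngineConfig = EngineConfig()
) -> tuple[bool, SignMap]:
    """Significance-gated residual signs for every cell.

    Strict rule: significant iff operative p < alpha.  A residual of
    exactly zero stays ``n/a`` even in a significant design.
    """
    significant = decide_p(result) < config.alpha
    signs: SignMap = {}
    table = result.table
    for i, row in enumerate(table.row_labels):
        for j, col in enumerate(table.col_labels):
            if not significant or result.residuals[i, j] == 0:
                signs[(row, col)] = NA
            else:
                signs[(row, col)] = POSITIVE if result.residuals[i, j] > 0 else NEGATIVE
    return significant, signs


def run_battery(
    source: Union[Sequence[OccurrenceRecord], CountsFixture],
    config: EngineConfig = EngineConfig(),
) -> list[TestResult]:
    """Run every design on every dataset variant.

    ``source`` is either a list of occurrence records (curated into
    variants I-IV first) or a :class:`CountsFixture` of published counts
    (fed to the engine verbatim).  Results are ordered test id major,
    dataset variant minor; degenerate designs are reported as skipped.
    All Monte-Carlo randomness flows from one generator seeded by the
    config, consumed in that fixed order.
    """
    fixture = source if isinstance(source, CountsFixture) else None
    variants = None if fixture is not None else build_all_variants(list(source))
    rng = config.rng()
    results: list[TestResult] = []
    for test_id in TEST_IDS:
        for label in VARIANT_LABELS:
            try:
                if fixture is not None:
                    table = table_from_fixture(fixture, test_id, label)
                else:
                    table = assemble_table(variants[label], test_id)
            except DegenerateDesignError as exc:
                results.append(
                    TestResult(
                        test_id=test_id,
                        dataset=label,
                        skipped=True,
                        skip_reason=str(exc),
                    )
                )
                continue
            chi2 = chi_square(table, config, rng=rng)
            fisher = (
                fisher_exact_2x2(table)
                if test_id in FISHER_TESTS and table.shape == (2, 2)
                else None
            )
            significant, signs = assign_signs(chi2, config)
            results.append(
                TestResult(
                    test_id=test_id,
                    dataset=label,
                    chi2=chi2,
                    fisher=fisher,
                    significant=significant,
                    signs=signs,
                )
            )
    return results


def concordance(a: TestResult, b: TestResult) -> Optional[ConcordanceEntry]:
    """Sign agreement between two significant designs.

    Returns ``None`` (the incomparable marker) when the designs share no
    (row label, environment) keys with assigned signs in both.
    """
    if not (a.significant and b.significant):
        raise ValueError("concordance is defined only between significant tests")
    keys = [
        k
        for k in a.signs
        if k in b.signs and a.signs[k] != NA and b.signs[k] != NA
    ]
    if not keys:
        return None
    matched = sum(1 for k in keys if a.signs[k] == b.signs[k])
    return ConcordanceEntry(
        test_a=display_label(a),
        test_b=display_label(b),
        matched=matched,
        total=len(keys),
    )


_DISPLAY = {
    "T1_C": ("1", " (C)"),
    "T1_T": ("1", " (T)"),
    "T2": ("2", ""),
    "T3_C": ("3", " (C)"),
    "T3_T": ("3", " (T)"),
    "T4": ("4", ""),
    "T5": ("5", ""),
    "T6": ("6", ""),
    "T7": ("7", ""),
    "T8": ("8", ""),
}


def display_label(result: TestResult) -> str:
    """Human label like ``3-I (C)`` for one (design, variant) result."""
    num, suffix = _DISPLAY[result.test_id]
    return f"{num}-{result.dataset}{suffix}"


def concordance_matrix(results: Iterable[TestResult]) -> pd.DataFrame:
    """Pairwise concordance among all significant results.

    Cells hold ``matched/total`` strings, with ``x`` on the diagonal and
    for incomparable pairs.
    """
    sig = [r for r in results if r.significant]
    labels = [display_label(r) for r in sig]
    frame = pd.DataFrame("x", index=labels, columns=labels, dtype=object)
    for i, a in enumerate(sig):
        for j, b in enumerate(sig):
            if i == j:
                continue
            entry = concordance(a, b)
            if entry is not None:
                frame.iloc[i, j] = str(entry)
    return frame
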