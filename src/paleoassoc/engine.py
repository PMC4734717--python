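"""Contingency-table statistics: Pearson chi-square (asymptotic and
Monte-Carlo), fixed-margin null-table sampling, and Fisher's exact test
with the conditional-MLE odds ratio.

Conventions
-----------
* No continuity correction anywhere, including 2x2 tables.
* One-column designs are goodness-of-fit tests against a uniform
  expectation (total / number of rows); two-column designs use the usual
  independence expectation (row total x column total / n).
* The Monte-Carlo p-value uses the add-one estimator (1 + m) / (B + 1),
  where m counts null replicates with a statistic at least as large as the
  observed one.  Null replicates preserve both margins exactly for
  two-column tables (sequential multivariate-hypergeometric sampling, the
  conditional distribution under independence) and are uniform multinomial
  draws for one-column tables.
* Monte-Carlo is triggered when any expected cell count falls below the
  configured threshold (default 5, the classical rule of thumb behind the
  usual small-expected-count warning).  The asymptotic p-value is always
  retained alongside, so the trigger rule is auditable.
* Fisher's two-sided p sums central-hypergeometric probabilities of all
  tables no more probable than the observed one (relative tolerance 1e-7);
  the odds ratio is the conditional MLE under the noncentral
  hypergeometric likelihood, 0 or infinity when the observed cell sits at
  an edge of its conditional support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .curation import ContingencyTable

__all__ = [
    "EngineConfig",
    "ChiSquareResult",
    "FisherResult",
    "expected_counts",
    "pearson_residuals",
    "chi_square",
    "sample_fixed_margins",
    "monte_carlo_p",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class EngineConfig:
    """Tuning knobs of the test battery.

    alpha: significance level for the strict ``p < alpha`` rule.
    b: number of Monte-Carlo replicates.
    mc_trigger_threshold: minimum expected cell count below which the
        Monte-Carlo p-value is computed and used.
    seed: seed for the Monte-Carlo random number generator.
    """

    alpha: float = 0.05
    b: int = 2000
    mc_trigger_threshold: float = 5.0
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.mc_trigger_threshold <= 0:
            raise ValueError("mc_trigger_threshold must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    expected: np.ndarray
    residuals: np.ndarray
    p_asymptotic: float
    mc_used: bool
    p_mc: Optional[float]
    table: ContingencyTable


@dataclass(frozen=True)
class FisherResult:
    """Fisher's exact test on a 2x2 table.

    ``p_two_sided`` follows the probability-ordering rule; ``p_less`` and
    ``p_greater`` are the one-sided tail probabilities of the top-left
    cell; ``or_cmle`` is the conditional-MLE odds ratio.
    """

    p_two_sided: float
    or_cmle: float
    p_less: float
    p_greater: float


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under the design's null hypothesis."""
    counts = table.counts
    if counts.shape[1] == 1:
        return np.full_like(counts, counts.sum() / counts.shape[0], dtype=float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    return row * col / counts.sum()


def pearson_residuals(table: ContingencyTable) -> np.ndarray:
    expected = expected_counts(table)
    return (table.counts - expected) / np.sqrt(expected)


def _statistic(counts: np.ndarray, expected: np.ndarray) -> float:
    return float(((counts - expected) ** 2 / expected).sum())


def chi_square(
    table: ContingencyTable,
    config: EngineConfig = EngineConfig(),
    rng: Optional[np.random.Generator] = None,
) -> ChiSquareResult:
    """Pearson chi-square test without continuity correction.

    Degrees of freedom are rows − 1 for one-column (goodness-of-fit)
    designs and (rows − 1)(cols − 1) otherwise.  When the smallest
    expected count falls below the trigger threshold, a Monte-Carlo
    p-value is also computed (from ``rng``, or a generator seeded from the
    config when ``rng`` is omitted).
    """
    expected = expected_counts(table)
    stat = _statistic(table.counts, expected)
    r, c = table.shape
    df = (r - 1) * (c - 1) if c > 1 else r - 1
    p_asym = float(stats.chi2.sf(stat, df))
    mc_used = bool(expected.min() < config.mc_trigger_threshold)
    p_mc = None
    if mc_used:
        p_mc = monte_carlo_p(table, config, rng=rng)
    residuals = (table.counts - expected) / np.sqrt(expected)
    return ChiSquareResult(
        statistic=stat,
        df=df,
        expected=expected,
        residuals=residuals,
        p_asymptotic=p_asym,
        mc_used=mc_used,
        p_mc=p_mc,
        table=table,
    )


def sample_fixed_margins(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one random table with the given margins under independence.

    Rows are filled sequentially by multivariate-hypergeometric draws from
    the remaining column totals, which samples exactly from the
    conditional (Fisher-Yates) distribution of tables given both margins.
    """
    row_totals = np.asarray(row_totals, dtype=int)
    col_totals = np.asarray(col_totals, dtype=int)
    if row_totals.sum() != col_totals.sum():
        raise ValueError("margins are inconsistent")
    if (row_totals < 0).any() or (col_totals < 0).any():
        raise ValueError("margins must be non-negative")
    out = np.zeros((len(row_totals), len(col_totals)), dtype=int)
    remaining = col_totals.copy()
    for i, r in enumerate(row_totals[:-1]):
        draw = rng.multivariate_hypergeometric(remaining, int(r))
        out[i] = draw
        remaining -= draw
    out[-1] = remaining
    return out


def monte_carlo_p(
    table: ContingencyTable,
    config: EngineConfig = EngineConfig(),
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo p-value (1 + m) / (B + 1) for the chi-square statistic."""
    if rng is None:
        rng = config.rng()
    counts = table.counts
    expected = expected_counts(table)
    observed_stat = _statistic(counts, expected)
    b = config.b
    # Tolerance guards against float jitter when a replicate reproduces
    # the observed table exactly.
    threshold = observed_stat - 1e-9
    if counts.shape[1] == 1:
        n, k = counts.sum(), counts.shape[0]
        draws = rng.multinomial(n, np.full(k, 1.0 / k), size=b)
        stats_rep = ((draws - expected.T) ** 2 / expected.T).sum(axis=1)
        m = int((stats_rep >= threshold).sum())
    else:
        row = counts.sum(axis=1)
        col = counts.sum(axis=0)
        m = 0
        for _ in range(b):
            rep = sample_fixed_margins(row, col, rng)
            if _statistic(rep, expected) >= threshold:
                m += 1
    return (1 + m) / (b + 1)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def _support_and_logpmf(table: ContingencyTable):
    counts = table.counts
    r1, r2 = counts.sum(axis=1)
    c1 = counts[:, 0].sum()
    n = counts.sum()
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    support = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(support, n, c1, r1)
    return support, logpmf, int(counts[0, 0])


def _conditional_mean(log_psi: float, support: np.ndarray, logw: np.ndarray) -> float:
    lw = logw + support * log_psi
    lw -= lw.max()
    w = np.exp(lw)
    return float((support * w).sum() / w.sum())


def fisher_exact_2x2(table: ContingencyTable) -> FisherResult:
    """Fisher's exact test and conditional-MLE odds ratio for a 2x2 table."""
    if table.shape != (2, 2):
        raise ValueError(f"Fisher's exact test needs a 2x2 table, got {table.shape}")
    support, logpmf, x_obs = _support_and_logpmf(table)
    pmf = np.exp(logpmf)
    pmf = pmf / pmf.sum()
    log_obs = logpmf[support == x_obs][0]
    # Probability ordering with a relative tolerance, the convention under
    # which printed exact p-values from standard software reproduce.
    keep = logpmf <= log_obs + math.log1p(1e-7)
    p_two = 1.0 if keep.all() else float(min(1.0, pmf[keep].sum()))
    p_less = float(pmf[support <= x_obs].sum())
    p_greater = float(pmf[support >= x_obs].sum())

    if x_obs == support[0]:
        or_cmle = 0.0
    elif x_obs == support[-1]:
        or_cmle = math.inf
    else:
        counts = table.counts
        r1, r2 = counts.sum(axis=1)
        c1 = counts[:, 0].sum()
        # log central weights C(r1, x) C(r2, c1 - x)
        logw = special.gammaln(r1 + 1) - special.gammaln(support + 1) \
            - special.gammaln(r1 - support + 1) \
            + special.gammaln(r2 + 1) - special.gammaln(c1 - support + 1) \
            - special.gammaln(r2 - c1 + support + 1)

        def g(log_psi: float) -> float:
            return _conditional_mean(log_psi, support, logw) - x_obs

        lo_b, hi_b = -1.0, 1.0
        while g(lo_b) > 0:
            lo_b *= 2
        while g(hi_b) < 0:
            hi_b *= 2
        root = optimize.brentq(g, lo_b, hi_b, xtol=1e-10, rtol=1e-12)
        or_cmle = float(math.exp(root))
    return FisherResult(
        p_two_sided=p_two, or_cmle=or_cmle, p_less=p_less, p_greater=p_greater
    )
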