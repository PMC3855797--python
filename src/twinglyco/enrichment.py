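"""Heritability-stratified enrichment of array-wide EWAS hits.

Compares the rate of array-wide-significant (probe, trait) associations
between the low- and high-heritability trait classes with a 2x2 table whose
numerators count significant association rows and whose denominators are the
class sizes in traits, the counting convention of the study report.  The
primary test is the one-sided Fisher exact (hypergeometric tail) probability;
a Pearson chi-square and an odds ratio (Haldane-corrected at zero cells) are
reported alongside.  Group comparisons from printed summary statistics use
the Welch unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "build_contingency",
    "fisher_exact_one_sided",
    "compare_proportions",
    "welch_t_from_summary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Hit counts by heritability class.

    Row 1 is the low-heritability class, row 2 the high class; the first
    column counts array-wide significant association rows attributed to the
    class and the second column is the class size (number of traits) minus
    the hit count.  Because one trait can carry several hits, the hit count
    may exceed the trait count; the complementary cell then floors at 0
    (a documented quirk of the row-vs-trait counting convention).
    """

    low_hits: int
    low_rest: int
    high_hits: int
    high_rest: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.low_hits, self.low_rest], [self.high_hits, self.high_rest]]
        )

    def validate(self) -> None:
        cells = (self.low_hits, self.low_rest, self.high_hits, self.high_rest)
        if any(int(c) != c for c in cells):
            raise ValueError(f"non-integer cells: {cells}")
        if any(c < 0 for c in cells):
            raise ValueError(f"negative cells: {cells}")


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable2x2
    proportion_low: float
    proportion_high: float
    p_exact: float
    p_chi2: float
    odds_ratio: float

    def reported_percentages(self) -> tuple[float, float]:
        """Class hit percentages truncated to one decimal (report convention)."""
        return (
            np.floor(self.proportion_low * 1000) / 10,
            np.floor(self.proportion_high * 1000) / 10,
        )

    def summary(self) -> str:
        return (
            f"array-wide hits: {self.proportion_low * 100:.1f}% of low-heritability "
            f"traits vs {self.proportion_high * 100:.1f}% of high-heritability traits "
            f"(one-sided exact P = {self.p_exact:.4g}, chi-square P = {self.p_chi2:.4g}, "
            f"OR = {self.odds_ratio:.2f})"
        )


def build_contingency(
    classifications: pd.DataFrame | dict[str, str],
    association_table: pd.DataFrame,
    threshold: float | None = None,
) -> ContingencyTable2x2:
    """Count significant association rows per heritability class.

    ``classifications`` maps trait name to "low"/"high" (or is a DataFrame
    with ``trait`` and ``heritability_class`` columns).  Numerators count
    significant rows of ``association_table`` (probe x trait pairs, the
    ``significant`` flag or ``p < threshold``); denominators are the number
    of traits per class.  Every associated trait must be classified.
    """
    if isinstance(classifications, pd.DataFrame):
        classes = dict(
            zip(classifications["trait"], classifications["heritability_class"])
        )
    else:
        classes = dict(classifications)
    bad = set(classes.values()) - {"low", "high"}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")

    if threshold is not None:
        sig = association_table[association_table["p"] < threshold]
    else:
        sig = association_table[association_table["significant"].astype(bool)]
    unknown = sorted(set(sig["glycan"]) - set(classes))
    if unknown:
        raise ValueError(f"unclassified traits in association table: {unknown}")

    n_low = sum(1 for v in classes.values() if v == "low")
    n_high = len(classes) - n_low
    hits_low = int((sig["glycan"].map(classes) == "low").sum())
    hits_high = len(sig) - hits_low
    return ContingencyTable2x2(
        low_hits=hits_low,
        low_rest=max(n_low - hits_low, 0),
        high_hits=hits_high,
        high_rest=max(n_high - hits_high, 0),
    )


def fisher_exact_one_sided(table: ContingencyTable2x2 | np.ndarray) -> float:
    """One-sided Fisher exact p: probability of >= the observed first-row hits.

    Computed by direct hypergeometric enumeration with log-factorials: with
    margins fixed, P(X = k) = C(r1, k) C(r2, n1-k) / C(N, n1) where r1/r2 are
    the row sums and n1 the first-column sum, and the tail sums k from the
    observed count upward.
    """
    if isinstance(table, ContingencyTable2x2):
        table.validate()
        arr = table.as_array()
    else:
        arr = np.asarray(table)
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("non-integer cells")
        arr = arr.astype(int)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2, n1, N = a + b, c + d, a + c, a + b + c + d
    if N == 0:
        return 1.0

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    denom = log_comb(N, n1)
    kmax = min(r1, n1)
    terms = [
        log_comb(r1, k) + log_comb(r2, n1 - k) - denom
        for k in range(a, kmax + 1)
        if n1 - k <= r2
    ]
    if not terms:
        return 1.0
    m = max(terms)
    p = float(np.exp(m) * np.sum(np.exp(np.array(terms) - m)))
    return min(p, 1.0)


def compare_proportions(table: ContingencyTable2x2) -> EnrichmentResult:
    """Class-wise hit proportions with exact and chi-square p and odds ratio.

    Proportions use the class trait count (hits + remainder) as denominator.
    The odds ratio applies the Haldane 0.5 correction when any cell is 0.
    """
    table.validate()
    arr = table.as_array().astype(float)
    row_sums = arr.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("empty heritability class")
    p_low = table.low_hits / row_sums[0]
    p_high = table.high_hits / row_sums[1]
    p_exact = fisher_exact_one_sided(table)
    if arr.sum() > 0 and (arr.sum(axis=0) > 0).all():
        p_chi2 = float(stats.chi2_contingency(arr, correction=False)[1])
    else:
        p_chi2 = 1.0
    if (arr == 0).any():
        arr = arr + 0.5
    odds = (arr[0, 0] * arr[1, 1]) / (arr[0, 1] * arr[1, 0])
    return EnrichmentResult(
        table=table,
        proportion_low=float(p_low),
        proportion_high=float(p_high),
        p_exact=p_exact,
        p_chi2=p_chi2,
        odds_ratio=float(odds),
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sided Welch t-test from group summary statistics.

    Unequal-variance t with Welch-Satterthwaite degrees of freedom, suitable
    for comparing printed cohort tables (mean, SD, N per group).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(res.statistic), float(res.pvalue)
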