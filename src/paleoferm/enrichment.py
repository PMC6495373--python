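"""Exact isolation-frequency enrichment testing.

The headline question: is live yeast recovered from putative fermented-
beverage vessels more often than from matched non-beverage controls
(other vessel types, sediments, stones, off-site samples)?  With a handful
of positives among a hundred-odd samples, the 2x2 comparison calls for
Fisher's exact test; it is implemented here by complete enumeration of the
margin-preserving tables with log-factorial arithmetic, so totals in the
thousands stay exact without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma
from typing import Callable, Iterable

CATEGORIES = ("putative-beverage", "control-vessel", "sediment/stone", "off-site")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a/b = positives/negatives in group 1, c/d in group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError("cell counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("grand total must be >= 1")

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    site: str
    category: str
    yeast_recovered: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not in {CATEGORIES}"
            )


def _log_hypergeom_pmf(k: int, row1: int, col1: int, n: int) -> float:
    """log P(X = k) for the hypergeometric with fixed 2x2 margins."""
    return (
        lgamma(row1 + 1) - lgamma(k + 1) - lgamma(row1 - k + 1)
        + lgamma(n - row1 + 1) - lgamma(col1 - k + 1) - lgamma(n - row1 - col1 + k + 1)
        - (lgamma(n + 1) - lgamma(col1 + 1) - lgamma(n - col1 + 1))
    )


def fisher_exact_2x2(
    table: ContingencyTable2x2,
    sided: str = "two",
    two_sided_rule: str = "minlike",
) -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    ``sided="greater"`` is the upper tail on cell a (group-1 positives).
    The default two-sided rule sums the probabilities of every table with
    the observed margins whose point probability does not exceed the
    observed one (within 1e-7 relative slack, guarding against float ties),
    matching mainstream statistical software; ``two_sided_rule="double"``
    doubles the smaller one-sided tail instead, capped at 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    log_pmf = {k: _log_hypergeom_pmf(k, row1, col1, n) for k in range(lo, hi + 1)}
    p_obs = log_pmf[a]
    if sided == "greater":
        p = sum(exp(lp) for k, lp in log_pmf.items() if k >= a)
    elif sided == "two":
        if two_sided_rule == "minlike":
            p = sum(exp(lp) for lp in log_pmf.values() if lp <= p_obs + 1e-7)
        elif two_sided_rule == "double":
            lower = sum(exp(lp) for k, lp in log_pmf.items() if k <= a)
            upper = sum(exp(lp) for k, lp in log_pmf.items() if k >= a)
            p = 2 * min(lower, upper)
        else:
            raise ValueError(f"unknown two_sided_rule {two_sided_rule!r}")
    else:
        raise ValueError("sided must be 'two' or 'greater'")
    return min(1.0, p)


def isolation_enrichment(
    records: Iterable[SampleRecord],
    group_a: Callable[[SampleRecord], bool],
    group_b: Callable[[SampleRecord], bool],
    sided: str = "two",
) -> tuple[ContingencyTable2x2, float]:
    """Build the recovery 2x2 from two disjoint sample groups and test it.

    ``group_a``/``group_b`` are predicates over records (e.g. category
    filters).  Groups must be non-empty and disjoint.
    """
    records = list(records)
    in_a = [r for r in records if group_a(r)]
    in_b = [r for r in records if group_b(r)]
    if not in_a or not in_b:
        raise ValueError("both groups must be non-empty")
    overlap = {r.sample_id for r in in_a} & {r.sample_id for r in in_b}
    if overlap:
        raise ValueError(f"groups overlap on samples: {sorted(overlap)}")
    a = sum(r.yeast_recovered for r in in_a)
    c = sum(r.yeast_recovered for r in in_b)
    table = ContingencyTable2x2(a=a, b=len(in_a) - a, c=c, d=len(in_b) - c)
    return table, fisher_exact_2x2(table, sided=sided)
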