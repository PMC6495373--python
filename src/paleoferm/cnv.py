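"""Gene copy-number-variation signature scoring between isolate pairs.

Domesticated beverage yeasts carry a characteristic pattern of gene family
duplications and deletions (sugar transport and metabolism clusters).  Given
a copy-number table for a pair of closely related isolates and a signature
listing the expected direction per ortholog cluster, these routines count,
for each isolate, how many varying signature clusters changed in the
"beverage-adapted" direction, and test that split against neutrality.

Direction is evaluated relative to the other isolate of the pair: for an
expected duplication the isolate with the HIGHER copy number is concordant,
for an expected deletion the LOWER.  An absolute-baseline reading is also
defensible but the pairwise one matches how isolate pairs are compared here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DUPLICATION = "duplication"
DELETION = "deletion"


@dataclass
class ConcordanceResult:
    isolate_a: str
    isolate_b: str
    count_a: int  # signature-concordant clusters won by isolate a
    count_b: int
    total: int  # signature clusters showing CNV between the pair
    concordant_a: list[str]
    concordant_b: list[str]
    undefined: bool = False  # no signature cluster varied


def _check_isolates(table: pd.DataFrame, isolate_a: str, isolate_b: str) -> None:
    for iso in (isolate_a, isolate_b):
        if iso not in table.index:
            raise KeyError(f"isolate {iso!r} not in table")


def detect_cnv_clusters(table: pd.DataFrame, isolate_a: str, isolate_b: str) -> list[str]:
    """Ortholog clusters whose copy number differs between the two isolates."""
    _check_isolates(table, isolate_a, isolate_b)
    a, b = table.loc[isolate_a], table.loc[isolate_b]
    if a.isna().all() or b.isna().all():
        raise ValueError("isolates share no scored clusters")
    return sorted(table.columns[(a != b).to_numpy()])


def signature_concordance(
    table: pd.DataFrame,
    isolate_a: str,
    isolate_b: str,
    signature: dict[str, str],
) -> ConcordanceResult:
    """Count signature-direction-concordant CNV clusters per isolate.

    Only signature clusters where the pair actually differs are scored; each
    such cluster is awarded to exactly one isolate.
    """
    _check_isolates(table, isolate_a, isolate_b)
    missing = sorted(set(signature) - set(table.columns))
    if missing:
        raise ValueError(f"signature clusters absent from table: {missing}")
    bad = {c: d for c, d in signature.items() if d not in (DUPLICATION, DELETION)}
    if bad:
        raise ValueError(f"invalid signature directions: {bad}")
    conc_a, conc_b = [], []
    total = 0
    for cluster in sorted(signature):
        ca, cb = table.at[isolate_a, cluster], table.at[isolate_b, cluster]
        if ca == cb:
            continue
        total += 1
        higher_is_a = ca > cb
        expects_higher = signature[cluster] == DUPLICATION
        if higher_is_a == expects_higher:
            conc_a.append(cluster)
        else:
            conc_b.append(cluster)
    return ConcordanceResult(
        isolate_a=isolate_a,
        isolate_b=isolate_b,
        count_a=len(conc_a),
        count_b=len(conc_b),
        total=total,
        concordant_a=conc_a,
        concordant_b=conc_b,
        undefined=total == 0,
    )


def neutral_split_chisq(count_a: int, count_b: int) -> tuple[float, float]:
    """1-df goodness of fit of an observed split against equal expectation.

    chi2 = (a - n/2)^2/(n/2) + (b - n/2)^2/(n/2), no continuity correction;
    p is the upper tail of chi-square with 1 degree of freedom.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be nonnegative")
    n = count_a + count_b
    if n == 0:
        raise ValueError("counts sum to zero")
    expected = n / 2
    chi2 = (count_a - expected) ** 2 / expected + (count_b - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def signature_profile_ttest(
    table: pd.DataFrame,
    isolate_a: str,
    isolate_b: str,
    signature: dict[str, str],
    variant: str = "paired",
) -> tuple[float, float, str]:
    """t test of the two isolates' copy-number profiles over signature clusters.

    Default is a paired two-sided t test on per-cluster differences (a - b);
    ``variant="welch"`` runs the unequal-variance two-sample test instead.
    Returns (t, p, method).  All-zero differences report t=0, p=1 exactly;
    a constant nonzero difference makes the paired statistic undefined and
    raises with a pointer to the Welch variant.
    """
    _check_isolates(table, isolate_a, isolate_b)
    clusters = sorted(set(signature) & set(table.columns))
    if len(clusters) < 2:
        raise ValueError("need >= 2 signature clusters present for both isolates")
    a = table.loc[isolate_a, clusters].to_numpy(dtype=float)
    b = table.loc[isolate_b, clusters].to_numpy(dtype=float)
    if variant == "paired":
        diffs = a - b
        if np.all(diffs == 0):
            return 0.0, 1.0, "paired"
        if np.std(diffs, ddof=1) == 0:
            raise ValueError(
                "per-cluster differences have zero variance; the paired t is "
                "undefined — use variant='welch'"
            )
        t, p = stats.ttest_rel(a, b)
    elif variant == "welch":
        t, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(t), float(p), variant
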