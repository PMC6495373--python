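"""Alignment curation: dereplication, gap trimming, informativeness filters.

These are the deterministic bookkeeping steps between raw barcode/ortholog
sequences and the trees built from them: collapse near-identical reference
sequences to centroids, drop alignment columns dominated by gaps, and keep
only alignments/orthologs informative enough to support a gene tree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import Align

GAP = "-"


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions in a global pairwise alignment.

    Scoring: match +1, mismatch 0, linear gap cost, end gaps penalized.
    Denominator = aligned columns excluding gap-vs-gap pairs.  Sequences are
    uppercased and U folded to T first.
    """
    a, b = _normalize(a).replace(GAP, ""), _normalize(b).replace(GAP, "")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    cols = matches = 0
    for x, y in zip(sa, sb):
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y:
            matches += 1
    return matches / cols if cols else 0.0


def centroid_dereplicate(
    records: list[tuple[str, str]],
    identity_threshold: float = 0.99,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Greedy centroid clustering at a pairwise-identity threshold.

    Sequences are processed longest-first (ties by id); each joins the first
    centroid it matches at >= threshold, else founds a new cluster.  Returns
    (centroid records, member id -> centroid id map covering every input).
    """
    if not records:
        raise ValueError("no sequences to dereplicate")
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    order = sorted(records, key=lambda r: (-len(r[1].replace(GAP, "")), r[0]))
    centroids: list[tuple[str, str]] = []
    membership: dict[str, str] = {}
    for rid, seq in order:
        for cid, cseq in centroids:
            if pairwise_identity(seq, cseq) >= identity_threshold:
                membership[rid] = cid
                break
        else:
            centroids.append((rid, seq))
            membership[rid] = rid
    return centroids, membership


def trim_gappy_columns(
    alignment: list[tuple[str, str]],
    max_gap_prop: float = 0.8,
) -> tuple[list[tuple[str, str]], list[int]]:
    """Remove columns whose gap proportion strictly exceeds the threshold.

    The rule is strict ('over 0.8'): a column at exactly the threshold is
    kept.  Returns the trimmed alignment and the removed 0-based column
    indices; an alignment trimmed to zero length is returned as-is (empty
    sequences) rather than raising.
    """
    _check_alignment(alignment)
    nrows = len(alignment)
    ncols = len(alignment[0][1])
    removed = [
        c
        for c in range(ncols)
        if sum(1 for _, s in alignment if s[c] == GAP) / nrows > max_gap_prop
    ]
    removed_set = set(removed)
    kept = [
        (rid, "".join(ch for c, ch in enumerate(seq) if c not in removed_set))
        for rid, seq in alignment
    ]
    return kept, removed


def count_parsimony_informative(alignment: list[tuple[str, str]]) -> int:
    """Columns with >= 2 non-gap states each present in >= 2 sequences."""
    if not alignment:
        return 0
    _check_alignment(alignment)
    count = 0
    for col in zip(*(s.upper() for _, s in alignment)):
        tally: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                tally[ch] = tally.get(ch, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count


def filter_informative_alignments(
    alignments: dict[str, list[tuple[str, str]]],
    min_unique_seqs: int = 10,
    min_pi_columns: int = 10,
) -> list[str]:
    """Ids of alignments with enough distinct sequences and PI columns.

    Both bounds are inclusive ('at least').
    """
    kept = []
    for aid in sorted(alignments):
        aln = alignments[aid]
        uniques = len({s.upper() for _, s in aln})
        if uniques >= min_unique_seqs and count_parsimony_informative(aln) >= min_pi_columns:
            kept.append(aid)
    return kept


def filter_ortholog_occupancy(
    table: pd.DataFrame,
    reference_genomes: list[str],
    isolate_genomes: list[str],
    min_ref_fraction: float = 0.5,
    min_isolates: int = 3,
    one_to_one: bool = True,
) -> list[str]:
    """Ortholog clusters represented widely enough to enter the supermatrix.

    ``table`` is clusters x genomes with integer representative counts.  A
    cluster passes when it has the qualifying count (exactly 1 when
    ``one_to_one``, else >= 1) in at least ceil(min_ref_fraction * n_refs)
    reference genomes and in at least ``min_isolates`` isolates.
    """
    if not reference_genomes:
        raise ValueError("reference genome set is empty")
    refs = table[list(reference_genomes)]
    isos = table[list(isolate_genomes)]
    need_refs = int(np.ceil(min_ref_fraction * len(reference_genomes)))
    qualifies = (lambda block: block == 1) if one_to_one else (lambda block: block >= 1)
    ok = (qualifies(refs).sum(axis=1) >= need_refs) & (
        qualifies(isos).sum(axis=1) >= min_isolates
    )
    return sorted(table.index[ok])


def _check_alignment(alignment: list[tuple[str, str]]) -> None:
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for _, s in alignment}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
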