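"""APR conservation in homologue alignments.

A multiple sequence alignment is supplied with the structure-bearing parent
as its first row. Homologues are filtered by percent identity to the parent
(identity over mutually non-gap columns), optionally dropping rows identical
to the parent, and APR conservation is then measured: each parent APR is
located in every homologue via the parent's aligned columns, and the percent
conservation is

    100 * (nAPR_total - nAPR_uniq) / nAPR_total

where nAPR_total = (#APRs) x (#rows) and nAPR_uniq is the number of distinct
APR sequence variants summed over APRs. An APR instance is conserved between
two homologues when it has the same sequence in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import APRInterval, SequenceRecord

GAP = "-"


@dataclass(frozen=True)
class AlignmentSet:
    """Equal-length aligned rows; the first row is the designated parent."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def parent(self) -> SequenceRecord:
        return SequenceRecord(self.ids[0], self.rows[0].replace(GAP, ""))

    def parent_columns(self) -> np.ndarray:
        """For each parent residue (1-based order), its 0-based column index."""
        return np.nonzero(np.frombuffer(self.rows[0].encode(), np.uint8)
                          != ord(GAP))[0]


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two aligned rows over mutually non-gap columns."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    both = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not both:
        raise ValueError("no mutually non-gap columns to compare")
    same = sum(x == y for x, y in both)
    return 100.0 * same / len(both)


def filter_homologues(
    aln: AlignmentSet,
    min_identity: float = 80.0,
    drop_identical: bool = False,
) -> AlignmentSet:
    """Retain rows with identity to the parent >= ``min_identity`` (and
    < 100% when ``drop_identical``). The parent row is always kept."""
    keep_ids = [aln.ids[0]]
    keep_rows = [aln.rows[0]]
    for rid, row in zip(aln.ids[1:], aln.rows[1:]):
        ident = pairwise_identity(aln.rows[0], row)
        if ident >= min_identity and not (drop_identical and ident >= 100.0):
            keep_ids.append(rid)
            keep_rows.append(row)
    if len(keep_ids) == 1:
        warnings.warn(
            f"no homologue passed the {min_identity}% identity filter",
            stacklevel=2,
        )
    return AlignmentSet(tuple(keep_ids), tuple(keep_rows))


def mean_identity_to_parent(aln: AlignmentSet) -> float:
    """Mean percent identity of each homologue row to the parent."""
    if aln.n_rows < 2:
        raise ValueError("need at least one homologue")
    return float(np.mean([
        pairwise_identity(aln.rows[0], r) for r in aln.rows[1:]
    ]))


def mean_identity_all_pairs(aln: AlignmentSet) -> float:
    """Mean percent identity over all row pairs (parent included)."""
    if aln.n_rows < 2:
        raise ValueError("need at least two rows")
    vals = [
        pairwise_identity(aln.rows[i], aln.rows[j])
        for i in range(aln.n_rows)
        for j in range(i + 1, aln.n_rows)
    ]
    return float(np.mean(vals))


def extract_apr_variants(
    aln: AlignmentSet, apr: APRInterval
) -> list[str]:
    """The APR's sequence in every row, read at the parent's aligned columns
    with gaps removed."""
    cols = aln.parent_columns()
    apr.validate_on(len(cols))
    sel = cols[apr.start - 1 : apr.end]
    return [
        "".join(row[c] for c in sel).replace(GAP, "") for row in aln.rows
    ]


def apr_conservation(
    aln: AlignmentSet, parent_aprs: Sequence[APRInterval]
) -> tuple[float, pd.DataFrame]:
    """Percent APR conservation of a filtered alignment plus per-APR detail.

    Returns ``(percent, detail)`` where detail has one row per parent APR
    with its variant count and the parent variant. With M rows and perfectly
    conserved APRs the metric approaches 100*(M-1)/M.
    """
    if aln.n_rows < 2:
        raise ValueError("conservation is degenerate on a single-row alignment")
    if not parent_aprs:
        raise ValueError("no parent APRs supplied")
    n_total = len(parent_aprs) * aln.n_rows
    n_uniq = 0
    detail_rows = []
    for apr in parent_aprs:
        variants = extract_apr_variants(aln, apr)
        uniq = len(set(variants))
        n_uniq += uniq
        detail_rows.append({
            "seq_id": apr.seq_id, "start": apr.start, "end": apr.end,
            "source": apr.source, "parent_variant": variants[0],
            "n_variants": uniq, "n_rows": aln.n_rows,
            "pct_conserved": 100.0 * (aln.n_rows - uniq) / aln.n_rows,
        })
    pct = 100.0 * (n_total - n_uniq) / n_total
    return pct, pd.DataFrame(detail_rows)
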