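"""Order/disorder vs APR membership contingency analysis.

Residues of intrinsically disordered proteins are classified on two axes —
inside/outside an annotated APR and disordered/ordered (residues not
annotated as disordered are assumed ordered) — into a 2x2 table. The
association is summarized by an odds ratio,

    OR = (ordered_in / ordered_out) / (disordered_in / disordered_out),

read as "an ordered residue is OR times more likely to fall in an APR than a
disordered one", together with a Pearson chi-square test of independence and
a two-sided Fisher exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .records import APRInterval, SequenceRecord, coverage_mask, merge_intervals


@dataclass(frozen=True)
class DisorderAnnotation:
    """Disordered intervals (1-based inclusive) on one sequence."""

    seq_id: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if not (1 <= s <= e):
                raise ValueError(
                    f"invalid disorder interval [{s}, {e}] on {self.seq_id!r}"
                )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 residue counts: (in/out of APR) x (disordered/ordered)."""

    in_apr_disordered: int
    in_apr_ordered: int
    out_apr_disordered: int
    out_apr_ordered: int

    def __post_init__(self) -> None:
        for v in self.as_tuple():
            if v < 0:
                raise ValueError("contingency counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.in_apr_disordered, self.in_apr_ordered,
                self.out_apr_disordered, self.out_apr_ordered)

    def as_array(self) -> np.ndarray:
        """Rows: in/out of APR; columns: disordered/ordered."""
        return np.array([
            [self.in_apr_disordered, self.in_apr_ordered],
            [self.out_apr_disordered, self.out_apr_ordered],
        ])

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


def build_contingency(
    seqs: Sequence[SequenceRecord],
    aprs: Sequence[APRInterval],
    disorder: Sequence[DisorderAnnotation],
) -> ContingencyTable:
    """Count every residue of ``seqs`` into the four cells exactly once.

    Annotations referring to residues beyond a sequence's length raise (data
    integrity); overlapping disorder intervals are merged with a warning.
    """
    apr_by_seq: dict[str, list[APRInterval]] = {}
    for iv in aprs:
        apr_by_seq.setdefault(iv.seq_id, []).append(iv)
    dis_by_seq: dict[str, list[tuple[int, int]]] = {}
    for ann in disorder:
        dis_by_seq.setdefault(ann.seq_id, []).extend(ann.intervals)

    cells = np.zeros(4, dtype=np.int64)  # ad, ao, od, oo
    for seq in seqs:
        n = len(seq)
        in_apr = coverage_mask(n, apr_by_seq.get(seq.id, []))
        raw = dis_by_seq.get(seq.id, [])
        merged = merge_intervals(raw)
        if len(merged) < len(raw):
            warnings.warn(
                f"overlapping disorder intervals on {seq.id!r} were merged",
                stacklevel=2,
            )
        for s, e in merged:
            if e > n:
                raise ValueError(
                    f"disorder interval [{s}, {e}] exceeds sequence "
                    f"{seq.id!r} of length {n}"
                )
        dis = np.zeros(n, dtype=bool)
        for s, e in merged:
            dis[s - 1 : e] = True
        cells[0] += int(np.sum(in_apr & dis))
        cells[1] += int(np.sum(in_apr & ~dis))
        cells[2] += int(np.sum(~in_apr & dis))
        cells[3] += int(np.sum(~in_apr & ~dis))
    return ContingencyTable(*map(int, cells))


def odds_ratio(
    t: ContingencyTable,
    orientation: str = "ordered",
    continuity: bool = False,
) -> float:
    """Odds ratio of APR membership for ordered vs disordered residues.

    ``orientation='ordered'`` gives (ordered_in/ordered_out) /
    (disordered_in/disordered_out); ``'disordered'`` gives its reciprocal.
    With ``continuity`` 0.5 is added to every cell (use when a cell is 0).
    """
    ad, ao, od, oo = (float(v) for v in t.as_tuple())
    if continuity:
        ad, ao, od, oo = ad + 0.5, ao + 0.5, od + 0.5, oo + 0.5
    if min(ad, ao, od, oo) == 0:
        raise ZeroDivisionError(
            "a zero cell makes the odds ratio undefined; "
            "retry with continuity=True for a 0.5-corrected estimate"
        )
    or_ordered = (ao / oo) / (ad / od)
    if orientation == "ordered":
        return or_ordered
    if orientation == "disordered":
        return 1.0 / or_ordered
    raise ValueError(f"unknown orientation {orientation!r}")


def association_tests(t: ContingencyTable) -> dict:
    """Chi-square and two-sided Fisher exact tests of independence.

    Returns chi2 statistic, its p-value, the exact-test p-value and the
    method names used.
    """
    arr = t.as_array()
    if arr.sum() == 0:
        raise ValueError("empty contingency table")
    chi2, chi2_p, dof, _ = stats.chi2_contingency(arr, correction=False)
    _, fisher_p = stats.fisher_exact(arr, alternative="two-sided")
    return {
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
        "chi2_method": "pearson_no_correction",
        "exact_p": float(fisher_p),
        "exact_method": "fisher_two_sided",
        "dof": int(dof),
    }


def odds_ratio_confint(
    t: ContingencyTable, orientation: str = "ordered", alpha: float = 0.05
) -> tuple[float, float]:
    """Woolf (log) confidence interval for the odds ratio."""
    orv = odds_ratio(t, orientation)
    se = float(np.sqrt(np.sum(1.0 / np.array(t.as_tuple(), dtype=float))))
    z = stats.norm.ppf(1 - alpha / 2)
    return (orv * np.exp(-z * se), orv * np.exp(z * se))
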