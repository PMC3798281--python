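"""Core sequence and interval records shared across the toolkit.

All residue coordinates on sequences are 1-based and inclusive, matching the
numbering convention used throughout the aggregation literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The 20 standard amino acids, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_SET = frozenset(AMINO_ACIDS)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity / non-standard one-letter codes rejected (or optionally dropped)
#: on input: every formula here assumes the 20-letter alphabet.
AMBIGUOUS_CODES: frozenset = frozenset("BJOUXZ")

#: Charged and structure-breaking residues that oppose aggregation when they
#: flank an aggregation prone region.
GATEKEEPERS: frozenset = frozenset("DEKRP")


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence over the 20-letter amino-acid alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residues "
                f"{sorted(bad)}; only {AMINO_ACIDS} are accepted"
            )

    def __len__(self) -> int:
        return len(self.residues)


def clean_residues(raw: str, *, drop_ambiguous: bool = False) -> str:
    """Uppercase ``raw`` and handle ambiguity codes (B, J, O, U, X, Z).

    By default ambiguous codes raise; with ``drop_ambiguous`` they are removed.
    """
    seq = raw.upper().replace("-", "").replace("*", "")
    if drop_ambiguous:
        seq = "".join(c for c in seq if c in _AA_SET)
    return seq


@dataclass(frozen=True)
class APRInterval:
    """One aggregation prone region: a 1-based inclusive interval on a sequence.

    ``source`` tags the predictor of record (tango, waltz, amylseg, surrogate,
    user); intervals from different sources are never merged.
    """

    seq_id: str
    start: int
    end: int
    source: str = "user"
    score: float | None = None

    VALID_SOURCES = ("tango", "waltz", "amylseg", "surrogate", "user")

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] on {self.seq_id!r}"
            )
        if self.source not in self.VALID_SOURCES:
            raise ValueError(f"unknown APR source {self.source!r}")
        if self.score is not None and self.score < 0:
            raise ValueError("APR score must be non-negative")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def validate_on(self, seqlen: int, min_len: int = 1) -> None:
        if self.end > seqlen:
            raise ValueError(
                f"interval [{self.start}, {self.end}] exceeds sequence "
                f"{self.seq_id!r} of length {seqlen}"
            )
        if len(self) < min_len:
            raise ValueError(
                f"interval [{self.start}, {self.end}] shorter than the "
                f"minimum window of {min_len}"
            )


def check_non_overlapping(intervals: Sequence[APRInterval]) -> None:
    """Raise if any two intervals (same sequence) share a residue."""
    by_seq: dict[str, list[APRInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    for seq_id, ivs in by_seq.items():
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping intervals on {seq_id!r}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def coverage_mask(seqlen: int, intervals: Iterable[APRInterval]) -> np.ndarray:
    """Boolean mask of length ``seqlen``; True where covered by an interval."""
    mask = np.zeros(seqlen, dtype=bool)
    for iv in intervals:
        iv.validate_on(seqlen)
        mask[iv.start - 1 : iv.end] = True
    return mask


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching 1-based inclusive (start, end) pairs."""
    merged: list[list[int]] = []
    for s, e in sorted(pairs):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
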