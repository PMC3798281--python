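"""Sequence-level aggregation statistics over annotated APRs.

An APR (aggregation prone region) is an annotated interval on a protein
sequence, normally produced by an external predictor and supplied as a TSV
table. This module computes the per-sequence statistics reported for such
annotations — aggregation propensity (total score / length), the percentage
of residues inside APRs, and the frequency of gate-keeper residues
(D, E, K, R, P) at the three positions flanking each APR on either side —
plus a clearly-labelled surrogate sliding-window predictor used only for
synthetic closed-loop testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    APRInterval,
    GATEKEEPERS,
    SequenceRecord,
    check_non_overlapping,
)

#: Kyte–Doolittle hydropathy, the scale behind the surrogate predictor.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Flank offsets examined around each APR: three preceding, three succeeding.
FLANK_POSITIONS = ("PB-1", "PB-2", "PB-3", "PE+1", "PE+2", "PE+3")


def aggregation_propensity(total_score: float, seqlen: int) -> float:
    """Total aggregation score normalized by sequence length."""
    if seqlen < 1:
        raise ValueError("seqlen must be >= 1")
    if total_score < 0:
        raise ValueError("total score must be non-negative")
    return total_score / seqlen


def apr_proportion(seqlen: int, aprs: Sequence[APRInterval]) -> float:
    """Percentage of a sequence's residues that lie inside its APRs.

    Intervals must be non-overlapping: double-counting is undefined.
    """
    if seqlen < 1:
        raise ValueError("seqlen must be >= 1")
    check_non_overlapping(aprs)
    total = 0
    for iv in aprs:
        iv.validate_on(seqlen)
        total += len(iv)
    return 100.0 * total / seqlen


@dataclass(frozen=True)
class GateKeeperProfile:
    """Gate-keeper occupancy of the six positions flanking a set of APRs.

    ``counts[pos]`` is the number of APRs with a gate-keeper at that flank
    position; ``denominators[pos]`` is the number of APRs for which the
    position exists (not truncated by a sequence terminus) — the frequency
    denominator. ``mean_per_apr`` is the average number of gate-keepers among
    the up-to-six flanking residues of each APR.
    """

    counts: Mapping[str, int]
    denominators: Mapping[str, int]
    n_aprs: int
    mean_per_apr: float

    def frequency(self, pos: str) -> float:
        """Percent occupancy at one flank position (over existing positions)."""
        d = self.denominators[pos]
        return 100.0 * self.counts[pos] / d if d else math.nan


def gatekeeper_profile(
    seq: SequenceRecord, aprs: Sequence[APRInterval]
) -> GateKeeperProfile:
    """Count gate-keeper residues (D, E, K, R, P) at APR flank positions.

    Positions truncated by the sequence termini are excluded from both the
    numerator and denominator of the per-position frequencies.
    """
    n = len(seq)
    counts = {p: 0 for p in FLANK_POSITIONS}
    denoms = {p: 0 for p in FLANK_POSITIONS}
    total_gk = 0
    for iv in aprs:
        iv.validate_on(n)
        for off in (1, 2, 3):
            pos = iv.start - off  # 1-based
            if pos >= 1:
                denoms[f"PB-{off}"] += 1
                if seq.residues[pos - 1] in GATEKEEPERS:
                    counts[f"PB-{off}"] += 1
                    total_gk += 1
            pos = iv.end + off
            if pos <= n:
                denoms[f"PE+{off}"] += 1
                if seq.residues[pos - 1] in GATEKEEPERS:
                    counts[f"PE+{off}"] += 1
                    total_gk += 1
    n_aprs = len(aprs)
    mean = total_gk / n_aprs if n_aprs else math.nan
    return GateKeeperProfile(counts, denoms, n_aprs, mean)


def combine_gatekeeper_profiles(
    profiles: Sequence[GateKeeperProfile],
) -> GateKeeperProfile:
    """Pool per-sequence gate-keeper profiles into one dataset-level profile."""
    counts = {p: 0 for p in FLANK_POSITIONS}
    denoms = {p: 0 for p in FLANK_POSITIONS}
    n_aprs = 0
    total_gk = 0.0
    for pr in profiles:
        for p in FLANK_POSITIONS:
            counts[p] += pr.counts[p]
            denoms[p] += pr.denominators[p]
        n_aprs += pr.n_aprs
        if pr.n_aprs:
            total_gk += pr.mean_per_apr * pr.n_aprs
    mean = total_gk / n_aprs if n_aprs else math.nan
    return GateKeeperProfile(counts, denoms, n_aprs, mean)


@dataclass(frozen=True)
class PredictionResult:
    """Per-sequence output of an APR predictor: total score + intervals."""

    seq_id: str
    seqlen: int
    total_score: float
    intervals: tuple[APRInterval, ...]

    def __post_init__(self) -> None:
        if self.total_score < 0:
            raise ValueError("total score must be non-negative")
        check_non_overlapping(self.intervals)

    @property
    def propensity(self) -> float:
        return aggregation_propensity(self.total_score, self.seqlen)

    @property
    def proportion(self) -> float:
        return apr_proportion(self.seqlen, self.intervals)


def surrogate_predict_aprs(
    seq: SequenceRecord,
    window: int = 6,
    threshold: float = 2.0,
    scale: Mapping[str, float] = KYTE_DOOLITTLE,
) -> PredictionResult:
    """Hydropathy sliding-window APR surrogate (NOT a TANGO/WALTZ stand-in
    for real data — for synthetic closed-loop testing only).

    Every window of ``window`` residues whose mean scale value is at least
    ``threshold`` contributes its score to the total; overlapping qualifying
    windows merge into maximal intervals tagged ``source='surrogate'``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(seq)
    if window > n:
        return PredictionResult(seq.id, n, 0.0, ())
    vals = np.array([scale[c] for c in seq.residues])
    win_means = np.convolve(vals, np.ones(window) / window, mode="valid")
    hits = np.nonzero(win_means >= threshold)[0]
    total = float(win_means[hits].sum()) if hits.size else 0.0
    spans = [(int(i) + 1, int(i) + window) for i in hits]  # 1-based inclusive
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:  # overlapping windows only
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    ivs = tuple(
        APRInterval(seq.id, s, e, source="surrogate") for s, e in merged
    )
    return PredictionResult(seq.id, n, total, ivs)


def dataset_summary(predictions: Sequence[PredictionResult]) -> dict:
    """Average APR properties over a dataset of per-sequence predictions.

    Length and proportion statistics are computed only over sequences that
    contain at least one APR; when no sequence does, those fields are None.
    """
    if not predictions:
        raise ValueError("need at least one prediction")
    with_apr = [p for p in predictions if p.intervals]
    apr_lengths = [len(iv) for p in with_apr for iv in p.intervals]
    out = {
        "n_sequences": len(predictions),
        "pct_with_apr": 100.0 * len(with_apr) / len(predictions),
        "n_aprs": len(apr_lengths),
    }
    if with_apr:
        seqlens = np.array([p.seqlen for p in with_apr], dtype=float)
        props = np.array([p.proportion for p in with_apr])
        al = np.array(apr_lengths, dtype=float)
        out.update(
            mean_seqlen=float(seqlens.mean()),
            sd_seqlen=float(seqlens.std(ddof=1)) if len(seqlens) > 1 else 0.0,
            mean_apr_length=float(al.mean()),
            sd_apr_length=float(al.std(ddof=1)) if len(al) > 1 else 0.0,
            mean_apr_proportion=float(props.mean()),
            sd_apr_proportion=float(props.std(ddof=1)) if len(props) > 1 else 0.0,
        )
    else:
        out.update(
            mean_seqlen=None, sd_seqlen=None, mean_apr_length=None,
            sd_apr_length=None, mean_apr_proportion=None,
            sd_apr_proportion=None,
        )
    return out


def summary_frame(predictions: Sequence[PredictionResult]) -> pd.DataFrame:
    """One-row DataFrame form of :func:`dataset_summary`."""
    return pd.DataFrame([dataset_summary(predictions)])
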