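"""Randomized, scrambled and partitioned sequence datasets.

Null datasets used to separate the effects of amino-acid composition from
sequence patterning on aggregation propensity:

* uniform random sequences (5% per amino acid),
* composition-matched random sequences (i.i.d. draws from a stated profile,
  by default the composition of a curated set of small monomeric proteins),
* scrambles of a parent sequence that preserve its exact residue multiset,
* a k-means split of a sequence set into composition-contrasted halves.

Compositions are compared with a one-sample (goodness-of-fit) chi-square on
counts per 1000 residues, the convention under which the natural-vs-uniform
composition contrast evaluates to 160.84.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .records import AMINO_ACIDS, _AA_INDEX, SequenceRecord

#: Amino-acid composition of the 495-protein monomeric reference set
#: (fractions; sums to exactly 1).
F495_COMPOSITION: dict[str, float] = {
    "A": 0.075, "C": 0.018, "D": 0.058, "E": 0.075, "F": 0.038,
    "G": 0.071, "H": 0.028, "I": 0.054, "K": 0.065, "L": 0.087,
    "M": 0.023, "N": 0.043, "P": 0.044, "Q": 0.038, "R": 0.051,
    "S": 0.062, "T": 0.053, "V": 0.069, "W": 0.014, "Y": 0.034,
}

#: Uniform composition, 5% per amino acid.
UNIFORM_COMPOSITION: dict[str, float] = {aa: 0.05 for aa in AMINO_ACIDS}


def _as_probability_vector(composition: dict[str, float]) -> np.ndarray:
    p = np.zeros(20)
    for aa, f in composition.items():
        if aa not in _AA_INDEX:
            raise ValueError(f"unknown amino acid {aa!r} in composition")
        p[_AA_INDEX[aa]] = f
    if np.any(p < 0):
        raise ValueError("composition frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition must sum to 1 (got {p.sum():.12f})")
    return p


def generate_uniform_random(
    n: int, length: int, seed: int | np.random.Generator
) -> list[SequenceRecord]:
    """Generate ``n`` sequences of ``length`` residues, each drawn uniformly
    (5% per amino acid)."""
    return generate_composition_matched(n, length, UNIFORM_COMPOSITION, seed,
                                        id_prefix="R")


def generate_composition_matched(
    n: int,
    length: int,
    composition: dict[str, float],
    seed: int | np.random.Generator,
    id_prefix: str = "N",
) -> list[SequenceRecord]:
    """Generate ``n`` sequences of ``length`` residues drawn i.i.d. from
    ``composition``. Reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    p = _as_probability_vector(composition)
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    draws = rng.choice(20, size=(n, length), p=p)
    return [
        SequenceRecord(f"{id_prefix}{i + 1:06d}",
                       alphabet[row].tobytes().decode())
        for i, row in enumerate(draws)
    ]


def scramble_sequence(
    seq: SequenceRecord, copies: int, seed: int | np.random.Generator
) -> list[SequenceRecord]:
    """Scramble a parent sequence ``copies`` times.

    Implements the rejection procedure: a randomly selected residue of the
    parent is assigned to a randomly selected position of the scrambled
    sequence; if that position is occupied, new random positions are drawn
    until an unoccupied one is found. Every output preserves the parent's
    length and residue multiset exactly.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(seq)
    out = []
    for c in range(copies):
        source_order = rng.permutation(n)  # random order of parent residues
        placed = np.zeros(n, dtype=bool)
        new = [""] * n
        for src in source_order:
            pos = int(rng.integers(n))
            while placed[pos]:  # rejection on occupied targets
                pos = int(rng.integers(n))
            placed[pos] = True
            new[pos] = seq.residues[src]
        out.append(SequenceRecord(f"{seq.id}_scramble{c + 1}", "".join(new)))
    return out


def compute_composition(seqs: Sequence[SequenceRecord]) -> dict[str, float]:
    """Pooled amino-acid composition of a sequence set (fractions)."""
    counts = np.zeros(20)
    for s in seqs:
        idx = np.frombuffer(s.residues.encode(), dtype=np.uint8)
        counts += np.bincount(
            np.searchsorted(np.frombuffer(AMINO_ACIDS.encode(), np.uint8), idx),
            minlength=20,
        )
    total = counts.sum()
    if total == 0:
        raise ValueError("no residues in input")
    return {aa: counts[i] / total for i, aa in enumerate(AMINO_ACIDS)}


def composition_chi_square(
    observed: dict[str, float],
    expected: dict[str, float],
    scale: float = 1000.0,
) -> float:
    """One-sample chi-square between two compositions, counts per ``scale``.

    Both profiles are converted to counts per ``scale`` residues and the
    goodness-of-fit statistic Σ(O−E)²/E is returned over the 20 categories,
    with ``expected`` as the reference. Note the form is asymmetric in its
    arguments. 19 degrees of freedom apply when both profiles are fixed.
    """
    o = _as_probability_vector(observed) * scale
    e = _as_probability_vector(expected) * scale
    if np.any((e == 0) & (o > 0)):
        raise ValueError(
            "observed mass on a zero-expected category makes the "
            "goodness-of-fit statistic degenerate"
        )
    use = e > 0  # categories empty in both profiles contribute nothing
    return float(np.sum((o[use] - e[use]) ** 2 / e[use]))


def kmeans_composition_split(
    seqs: Sequence[SequenceRecord],
    k: int = 2,
    seed: int | None = 0,
) -> dict[int, list[str]]:
    """Partition sequences by k-means on per-sequence composition vectors.

    Returns ``{cluster_label: [sequence ids]}``. Deterministic for a fixed
    seed; identical sequences always share a cluster.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seqs) < k:
        raise ValueError(f"need at least k={k} sequences, got {len(seqs)}")
    X = np.array([
        _as_probability_vector(compute_composition([s])) for s in seqs
    ])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    out: dict[int, list[str]] = {c: [] for c in range(k)}
    for s, lab in zip(seqs, labels):
        out[int(lab)].append(s.id)
    return out


def compare_propensity_distributions(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test on aggregation-propensity values.

    Defaults to the unequal-variance (Welch) form; set ``equal_var`` for the
    pooled-variance variant. Two identical constant samples return (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    if np.var(a) == 0 and np.var(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0  # degenerate: no variance, no difference
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
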