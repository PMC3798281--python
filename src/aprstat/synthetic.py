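"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of the study corpora this
toolkit analyzes — natural-composition monomeric sequences with hydrophobic
APR windows and gate-keeper flanks, disordered-protein corpora with a
controlled order/APR odds ratio, analytic toy structures with provable
burial orderings, mutation-rate-controlled homologue families, and enzyme
scenarios with planted catalytic/APR proximity — and emits machine-readable
ground truth alongside the data. All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .datasets import F495_COMPOSITION, _as_probability_vector
from .disorder import ContingencyTable, DisorderAnnotation
from .proximity import CatalyticSite
from .records import AMINO_ACIDS, APRInterval, GATEKEEPERS, SequenceRecord
from .structure import StructureModel

#: Aggregation-promoting residues used to fill planted APR windows,
#: beta-branched and hydrophobic, weighted toward Val/Ile.
APR_RESIDUES = "VILF"
APR_WEIGHTS = np.array([0.35, 0.35, 0.20, 0.10])


@dataclass(frozen=True)
class SyntheticSpec:
    """Stated world for the generators.

    Sequence defaults mirror the curated monomeric set the analyses were
    designed around: 495 sequences of 52-200 residues (mean 152, sd 34) with
    the natural background composition; roughly 0.9 APRs per sequence of
    mean length 7.5 (minimum 6); ~0.43 gate-keeper occupancy per flank
    position (=> ~2.6 gate-keepers per APR over six positions); 26.1%
    disordered residues with a target ordered-vs-disordered odds ratio of
    3.0.
    """

    seed: int = 0
    n_sequences: int = 495
    length_mean: float = 152.0
    length_sd: float = 34.0
    length_min: int = 52
    length_max: int = 200
    background: dict = field(default_factory=lambda: dict(F495_COMPOSITION))
    aprs_per_sequence: float = 0.9
    apr_length_mean: float = 7.5
    apr_length_sd: float = 2.0
    apr_length_min: int = 6
    gatekeeper_rate: float = 0.43
    disorder_coverage: float = 0.261
    target_odds_ratio: float = 3.0
    mutation_rate_in_apr: float = 0.05
    mutation_rate_outside: float = 0.2
    n_homologues: int = 10
    helix_radius: float = 2.3
    helix_rise: float = 1.5
    helix_turn_deg: float = 100.0
    bundle_separation: float = 10.0
    tail_spacing: float = 3.5
    contact_proportion: float = 0.4

    def __post_init__(self) -> None:
        for name in ("aprs_per_sequence", "gatekeeper_rate",
                     "mutation_rate_in_apr", "mutation_rate_outside",
                     "contact_proportion"):
            v = getattr(self, name)
            if name == "aprs_per_sequence":
                if v < 0:
                    raise ValueError(f"{name} must be >= 0")
            elif not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.target_odds_ratio <= 0:
            raise ValueError("target odds ratio must be > 0")


def _draw_background(rng, p, size):
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    return alphabet[rng.choice(20, size=size, p=p)].tobytes().decode()


def _non_gatekeeper_profile(background: dict) -> np.ndarray:
    p = _as_probability_vector(background).copy()
    for i, aa in enumerate(AMINO_ACIDS):
        if aa in GATEKEEPERS:
            p[i] = 0.0
    return p / p.sum()


def make_sequences_with_aprs(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[APRInterval]]:
    """Background-composition sequences with planted hydrophobic APRs.

    APR windows are filled with beta-branched/aromatic hydrophobics and
    placed with at least 4 residues of clearance from the termini and from
    each other, so that flank positions always exist and planted intervals
    never merge. At each of the six flank positions a gate-keeper (D/E/K/R/P)
    is planted with probability ``gatekeeper_rate``; otherwise the flank is
    drawn from the background with gate-keepers excluded, so the planted
    rate is exactly the expected flank occupancy.
    """
    rng = np.random.default_rng(spec.seed)
    p_bg = _as_probability_vector(spec.background)
    p_flank = _non_gatekeeper_profile(spec.background)
    gk = sorted(GATEKEEPERS)
    seqs: list[SequenceRecord] = []
    truth: list[APRInterval] = []
    for i in range(spec.n_sequences):
        n = int(np.clip(round(rng.normal(spec.length_mean, spec.length_sd)),
                        spec.length_min, spec.length_max))
        residues = list(_draw_background(rng, p_bg, n))
        n_aprs = rng.poisson(spec.aprs_per_sequence)
        placed: list[tuple[int, int]] = []
        for _ in range(n_aprs):
            length = max(spec.apr_length_min,
                         int(round(rng.normal(spec.apr_length_mean,
                                              spec.apr_length_sd))))
            if length + 8 > n:
                raise ValueError(
                    f"planted APR of {length} exceeds capacity of a "
                    f"{n}-residue sequence"
                )
            for _attempt in range(200):
                start = int(rng.integers(4, n - length - 2))  # 1-based
                end = start + length - 1
                if all(start > e + 4 or end < s - 4 for s, e in placed):
                    placed.append((start, end))
                    break
            else:
                continue  # no room for this APR; skip it
        sid = f"S{i + 1:05d}"
        for start, end in sorted(placed):
            idx = rng.choice(len(APR_RESIDUES), size=end - start + 1,
                             p=APR_WEIGHTS)
            for off, j in enumerate(idx):
                residues[start - 1 + off] = APR_RESIDUES[j]
            for flank_pos in (start - 3, start - 2, start - 1,
                              end + 1, end + 2, end + 3):
                if 1 <= flank_pos <= n:
                    if rng.random() < spec.gatekeeper_rate:
                        residues[flank_pos - 1] = gk[rng.integers(len(gk))]
                    else:
                        residues[flank_pos - 1] = _draw_background(
                            rng, p_flank, 1
                        )
            truth.append(APRInterval(sid, start, end, source="user"))
        seqs.append(SequenceRecord(sid, "".join(residues)))
    return seqs, truth


def solve_disorder_rates(
    coverage: float, apr_fraction: float, odds_ratio: float
) -> tuple[float, float]:
    """Per-residue disorder probabilities (inside, outside APRs) whose
    expected 2x2 table has the target ordered-vs-disordered odds ratio and
    overall disorder ``coverage``."""
    if not (0.0 < coverage < 1.0):
        raise ValueError("disorder coverage must be in (0, 1)")
    if not (0.0 < apr_fraction < 1.0):
        raise ValueError("APR residue fraction must be in (0, 1)")

    def p_in(p_out: float) -> float:
        odds_in = (p_out / (1 - p_out)) / odds_ratio
        return odds_in / (1 + odds_in)

    def excess(p_out: float) -> float:
        return (apr_fraction * p_in(p_out)
                + (1 - apr_fraction) * p_out - coverage)

    try:
        p_out = brentq(excess, 1e-12, 1 - 1e-12)
    except ValueError as err:  # pragma: no cover - numeric corner
        raise ValueError(
            f"infeasible coverage {coverage} / odds ratio {odds_ratio} "
            f"combination: {err}"
        )
    return p_in(p_out), p_out


def make_disorder_corpus(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[APRInterval],
           list[DisorderAnnotation], ContingencyTable]:
    """Sequences + APRs + disorder intervals with a controlled odds ratio.

    Per-residue disorder is Bernoulli with separate rates inside and outside
    APRs, solved so the expected table attains ``target_odds_ratio`` at the
    stated overall coverage. The exact realized 2x2 bookkeeping is returned.
    """
    seqs, aprs = make_sequences_with_aprs(spec)
    total = sum(len(s) for s in seqs)
    in_apr = sum(a.end - a.start + 1 for a in aprs)
    p_in, p_out = solve_disorder_rates(
        spec.disorder_coverage, in_apr / total, spec.target_odds_ratio
    )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    apr_by_seq: dict[str, list[APRInterval]] = {}
    for a in aprs:
        apr_by_seq.setdefault(a.seq_id, []).append(a)
    annotations: list[DisorderAnnotation] = []
    cells = np.zeros(4, dtype=np.int64)  # ad, ao, od, oo
    for s in seqs:
        n = len(s)
        mask_apr = np.zeros(n, dtype=bool)
        for a in apr_by_seq.get(s.id, []):
            mask_apr[a.start - 1 : a.end] = True
        p = np.where(mask_apr, p_in, p_out)
        dis = rng.random(n) < p
        cells[0] += int(np.sum(mask_apr & dis))
        cells[1] += int(np.sum(mask_apr & ~dis))
        cells[2] += int(np.sum(~mask_apr & dis))
        cells[3] += int(np.sum(~mask_apr & ~dis))
        intervals = []
        i = 0
        while i < n:
            if dis[i]:
                j = i
                while j + 1 < n and dis[j + 1]:
                    j += 1
                intervals.append((i + 1, j + 1))
                i = j + 1
            else:
                i += 1
        if intervals:
            annotations.append(DisorderAnnotation(s.id, tuple(intervals)))
    return seqs, aprs, annotations, ContingencyTable(*map(int, cells))


def _helix_coords(
    n: int, radius: float, rise: float, turn_deg: float,
    axis_origin: np.ndarray, direction: int = 1, phase: float = 0.0,
) -> np.ndarray:
    """CA trace of an ideal helix along z through ``axis_origin``."""
    i = np.arange(n, dtype=float)
    theta = np.deg2rad(turn_deg) * i + phase
    z = direction * rise * i
    return np.column_stack([
        axis_origin[0] + radius * np.cos(theta),
        axis_origin[1] + radius * np.sin(theta),
        axis_origin[2] + z,
    ])


def make_toy_structure(
    spec: SyntheticSpec,
    helix_len: int = 16,
    tail_len: int = 14,
    res_name: str = "ALA",
) -> tuple[StructureModel, dict[str, APRInterval]]:
    """Deterministic CA-only three-helix bundle with an extended tail.

    The chain runs: helix 1 (up), helix 2 (down), helix 3 (up) on the
    vertices of an equilateral triangle of side ``bundle_separation``, then a
    straight tail marching away from the bundle at ``tail_spacing`` per
    residue. The designated ``core`` segment (middle of helix 2, occluded by
    both neighbouring helices) is strictly more buried than the ``tail``
    segment by construction. Residues are numbered consecutively so sliding
    windows traverse the whole chain.
    """
    s = spec.bundle_separation
    verts = [np.array([0.0, 0.0, 0.0]),
             np.array([s, 0.0, 0.0]),
             np.array([s / 2, s * np.sqrt(3) / 2, 0.0])]
    coords_list = [
        _helix_coords(helix_len, spec.helix_radius, spec.helix_rise,
                      spec.helix_turn_deg, verts[0], direction=1),
        _helix_coords(helix_len, spec.helix_radius, spec.helix_rise,
                      spec.helix_turn_deg, verts[1], direction=-1,
                      phase=np.pi) + np.array([0, 0, spec.helix_rise
                                               * (helix_len - 1)]),
        _helix_coords(helix_len, spec.helix_radius, spec.helix_rise,
                      spec.helix_turn_deg, verts[2], direction=1,
                      phase=np.pi / 2),
    ]
    tail_start = coords_list[-1][-1]
    tail_dir = np.array([0.5, np.sqrt(3) / 2, 0.0])  # away from the bundle
    tail = tail_start + spec.tail_spacing * tail_dir * \
        np.arange(1, tail_len + 1)[:, None]
    coords = np.vstack(coords_list + [tail])
    n = len(coords)
    from scipy.spatial.distance import pdist
    if pdist(coords).min() < 0.5:
        raise ValueError("degenerate toy geometry: near-coincident atoms")
    model = StructureModel(
        chain_ids=np.array(["A"] * n),
        res_ids=np.arange(1, n + 1),
        icodes=np.array([""] * n),
        res_names=np.array([res_name] * n),
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        coords=coords,
    )
    w = 6
    core_start = helix_len + (helix_len - w) // 2 + 1  # middle of helix 2
    tail_seg_start = 3 * helix_len + tail_len - w + 1  # tail tip
    segments = {
        "core": APRInterval("A", core_start, core_start + w - 1, "user"),
        "tail": APRInterval("A", tail_seg_start, tail_seg_start + w - 1,
                            "user"),
    }
    return model, segments


def make_alignment_family(
    spec: SyntheticSpec,
    parent: SequenceRecord | None = None,
    parent_aprs: Sequence[APRInterval] | None = None,
):
    """Homologue family with controlled mutation rates inside/outside APRs.

    Homologues substitute each parent column independently — with rate
    ``mutation_rate_in_apr`` inside APR columns, ``mutation_rate_outside``
    elsewhere — to a uniformly chosen *different* residue (no indels, so the
    alignment is the identity alignment). Returns ``(alignment, parent_aprs,
    expected)`` where ``expected`` holds the exact conservation implied by
    the generated rows, counted directly by the generator's own distinct-
    variant bookkeeping.
    """
    from .conservation import AlignmentSet

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    if parent is None:
        one = SyntheticSpec(
            seed=spec.seed, n_sequences=1, aprs_per_sequence=3.0,
            length_mean=spec.length_mean, length_sd=0.0,
            background=spec.background,
            gatekeeper_rate=spec.gatekeeper_rate,
        )
        seqs, aprs = make_sequences_with_aprs(one)
        import dataclasses

        while not aprs:  # Poisson(3) can still yield zero APRs
            one = dataclasses.replace(one, seed=one.seed + 1)
            seqs, aprs = make_sequences_with_aprs(one)
        parent, parent_aprs = seqs[0], aprs
    if not parent_aprs:
        raise ValueError("parent has no APRs")
    n = len(parent)
    in_apr = np.zeros(n, dtype=bool)
    for a in parent_aprs:
        in_apr[a.start - 1 : a.end] = True
    rates = np.where(in_apr, spec.mutation_rate_in_apr,
                     spec.mutation_rate_outside)
    ids = [parent.id]
    rows = [parent.residues]
    for h in range(spec.n_homologues - 1):
        res = list(parent.residues)
        hits = np.nonzero(rng.random(n) < rates)[0]
        for i in hits:
            choices = [c for c in AMINO_ACIDS if c != res[i]]
            res[i] = choices[rng.integers(len(choices))]
        ids.append(f"{parent.id}_h{h + 1}")
        rows.append("".join(res))
    aln = AlignmentSet(tuple(ids), tuple(rows))
    # generator-side bookkeeping: distinct APR variants counted directly
    m = len(rows)
    n_total = len(parent_aprs) * m
    n_uniq = sum(
        len({row[a.start - 1 : a.end] for row in rows}) for a in parent_aprs
    )
    expected = {
        "n_rows": m,
        "n_aprs": len(parent_aprs),
        "n_total": n_total,
        "n_uniq": n_uniq,
        "conservation_pct": 100.0 * (n_total - n_uniq) / n_total,
    }
    return aln, list(parent_aprs), expected


def make_catalytic_scenario(
    spec: SyntheticSpec,
    n_residues: int = 240,
    n_sites: int = 40,
    n_aprs: int = 4,
    apr_len: int = 8,
    res_name: str = "ALA",
):
    """Extended chain with planted catalytic-residue/APR proximity.

    A straight CA chain (3.8 Å spacing, so only sequence neighbours fall
    within a 4.5 Å cutoff) carries ``n_aprs`` evenly spaced APRs. A
    proportion ``contact_proportion`` of the catalytic sites is planted on
    contact-eligible residues (inside an APR or immediately adjacent); the
    rest sit far from every APR. Returns ``(model, sites, aprs, truth)``
    with per-site ground-truth contact flags.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    spacing = 3.8
    coords = np.column_stack([
        spacing * np.arange(n_residues, dtype=float),
        np.zeros(n_residues),
        np.zeros(n_residues),
    ])
    model = StructureModel(
        chain_ids=np.array(["A"] * n_residues),
        res_ids=np.arange(1, n_residues + 1),
        icodes=np.array([""] * n_residues),
        res_names=np.array([res_name] * n_residues),
        atom_names=np.array(["CA"] * n_residues),
        elements=np.array(["C"] * n_residues),
        coords=coords,
    )
    gap = n_residues // n_aprs
    aprs = []
    eligible: set[int] = set()  # 1-based positions in contact with an APR
    for k in range(n_aprs):
        start = k * gap + gap // 2
        end = start + apr_len - 1
        if end + 1 > n_residues:
            raise ValueError("APRs do not fit the chain")
        aprs.append(APRInterval("A", start, end, "user"))
        eligible.update(range(max(1, start - 1), min(n_residues, end + 1) + 1))
    far = [i for i in range(1, n_residues + 1)
           if all(i < a.start - 1 or i > a.end + 1 for a in aprs)]
    n_near = int(round(spec.contact_proportion * n_sites))
    if n_near > len(eligible) or n_sites - n_near > len(far):
        raise ValueError("infeasible site placement for this chain")
    near_pos = rng.choice(sorted(eligible), size=n_near, replace=False)
    far_pos = rng.choice(far, size=n_sites - n_near, replace=False)
    sites = []
    truth = {}
    for pos in list(near_pos) + list(far_pos):
        site = CatalyticSite("toy", "A", int(pos), "", res_name)
        sites.append(site)
        truth[site.key] = bool(pos in eligible)
    return model, sites, aprs, truth
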