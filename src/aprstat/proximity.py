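"""Catalytic-residue incidence in APRs and the decoy permutation null.

Two questions about enzyme active sites and aggregation prone regions:

* *Incidence* — how many catalytic residues are expected to fall inside APRs
  and their three-residue flanking regions if catalytic residues were spread
  uniformly: ``N_cata * N_apr_residues / N_total_residues``.

* *Structural contact* — a catalytic residue is in contact with an APR when
  at least one of its heavy atoms lies within a cutoff (default 4.5 Å) of a
  heavy atom of any APR residue other than itself. Significance is assessed
  against a permutation null: for each true site a decoy residue is drawn
  uniformly from the residues of the same chain (optionally restricted to
  decoys whose ASA is within a stated fraction of the true site's ASA), the
  per-list contact count is recorded over many decoy lists, and the observed
  count is expressed as a Z-score against the null mean and sd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .records import APRInterval, SequenceRecord, coverage_mask, merge_intervals
from .structure import ASATable, StructureModel


def estimate_incidence(
    n_cata: int, n_apr_residues: int, n_total_residues: int
) -> dict:
    """Expected number of catalytic residues inside APRs + flanks under a
    uniform spread: n_cata * n_apr_residues / n_total_residues.

    Returns the raw value, the headline count (rounded half away from zero)
    and the percentage of ``n_cata``.
    """
    if n_total_residues <= 0:
        raise ValueError("total residue count must be positive")
    if not (0 <= n_apr_residues <= n_total_residues):
        raise ValueError("need 0 <= n_apr_residues <= n_total_residues")
    raw = n_cata * n_apr_residues / n_total_residues
    rounded = int(math.floor(raw + 0.5))  # half away from zero (raw >= 0)
    return {
        "raw": raw,
        "rounded": rounded,
        "percent": 100.0 * raw / n_cata if n_cata else 0.0,
    }


def count_apr_flank_residues(
    seqs: Sequence[SequenceRecord],
    aprs: Sequence[APRInterval],
    flank: int = 3,
) -> int:
    """Union count of residues inside APRs plus up to ``flank`` residues on
    each side, truncated at the termini; overlaps counted once."""
    by_seq: dict[str, list[APRInterval]] = {}
    for iv in aprs:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    total = 0
    for seq in seqs:
        ivs = by_seq.get(seq.id, [])
        n = len(seq)
        spans = []
        for iv in ivs:
            iv.validate_on(n)
            spans.append((max(1, iv.start - flank), min(n, iv.end + flank)))
        total += sum(e - s + 1 for s, e in merge_intervals(spans))
    return total


@dataclass(frozen=True)
class CatalyticSite:
    """One annotated catalytic residue, addressed by author numbering."""

    structure_id: str
    chain_id: str
    res_id: int
    icode: str = ""
    res_type: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_id, self.icode)


def _apr_residue_keys(
    model: StructureModel,
    aprs: Sequence[APRInterval],
    chain_id: str | None = None,
) -> set[tuple[str, int, str]]:
    """Residue keys covered by APR intervals (1-based on the chain sequence)."""
    out: set[tuple[str, int, str]] = set()
    chains = {chain_id} if chain_id else set(str(c) for c in model.chain_ids)
    for ch in sorted(chains):
        _, keys = model.chain_sequence(ch)
        mask = coverage_mask(len(keys), [iv for iv in aprs if iv.seq_id == ch])
        out.update(k for k, m in zip(keys, mask) if m)
    return out


def contact_eligibility(
    model: StructureModel,
    apr_keys: set[tuple[str, int, str]],
    cutoff: float = 4.5,
) -> dict[tuple[str, int, str], bool]:
    """For every residue: is any of its heavy atoms within ``cutoff`` of a
    heavy atom of an APR residue *other than itself*?

    Self-pairs are ignored, so a residue inside a multi-residue APR normally
    still flags through its APR neighbours.
    """
    keys = model.residue_keys()
    idx = model.atom_residue_index()
    key_of_atom = [keys[i] for i in idx]
    apr_mask = np.array([k in apr_keys for k in key_of_atom])
    if not apr_mask.any():
        return {k: False for k in keys}
    apr_coords = model.coords[apr_mask]
    apr_atom_keys = [k for k, m in zip(key_of_atom, apr_mask) if m]
    tree = cKDTree(apr_coords)
    flags = {k: False for k in keys}
    neighbor_lists = tree.query_ball_point(model.coords, cutoff)
    for atom_i, neigh in enumerate(neighbor_lists):
        k = key_of_atom[atom_i]
        if flags[k]:
            continue
        for j in neigh:
            if apr_atom_keys[j] != k:  # ignore self-residue pairs
                flags[k] = True
                break
    return flags


def detect_contacts(
    model: StructureModel,
    sites: Sequence[CatalyticSite],
    aprs: Sequence[APRInterval],
    cutoff: float = 4.5,
) -> dict[tuple[str, int, str], bool]:
    """Contact flag for every catalytic site against the APRs of ``model``.

    ``aprs`` address chains by ``seq_id`` = chain id, 1-based on the chain's
    residue order. Unresolvable sites raise.
    """
    apr_keys = _apr_residue_keys(model, aprs)
    elig = contact_eligibility(model, apr_keys, cutoff)
    out = {}
    for s in sites:
        if s.key not in elig:
            raise KeyError(
                f"catalytic site {s.structure_id}/{s.chain_id}"
                f"{s.res_id}{s.icode} not found in structure"
            )
        out[s.key] = elig[s.key]
    return out


@dataclass(frozen=True)
class DecoyNullResult:
    """Observed contact count against the decoy-list null distribution."""

    observed: int
    null_mean: float
    null_sd: float
    z: float | None
    n_lists: int
    cutoff: float
    asa_match: float | None
    seed: int

    def __post_init__(self) -> None:
        if self.z is not None and self.null_sd > 0:
            expect = (self.observed - self.null_mean) / self.null_sd
            if abs(self.z - expect) > 1e-9:
                raise ValueError("inconsistent Z-score")


def decoy_null(
    models: Mapping[str, StructureModel],
    sites: Sequence[CatalyticSite],
    aprs: Mapping[str, Sequence[APRInterval]],
    n_lists: int = 10_000,
    cutoff: float = 4.5,
    asa_match: float | None = None,
    seed: int = 0,
    asa_tables: Mapping[str, ASATable] | None = None,
    exclude_self: bool = False,
) -> DecoyNullResult:
    """Permutation null for catalytic-residue/APR contact counts.

    For each true site a decoy residue is drawn uniformly (with replacement,
    independently per list) from the standard residues of the same chain of
    the same structure; the candidate pool includes the true residue itself
    and other catalytic residues unless ``exclude_self`` is set. With
    ``asa_match`` = f, candidates are restricted to residues whose ASA lies
    within ±f of the true site's ASA (``asa_tables`` required). The per-list
    contact count forms the null; the observed count is the number of true
    sites in contact.
    """
    if n_lists < 100:
        raise ValueError("n_lists must be >= 100")
    if asa_match is not None and asa_tables is None:
        raise ValueError("asa_match requires per-structure ASA tables")
    rng = np.random.default_rng(seed)

    observed = 0
    # per-site vector of candidate eligibility flags
    site_candidate_flags: list[np.ndarray] = []
    elig_cache: dict[tuple[str, float], dict] = {}
    for s in sites:
        if s.structure_id not in models:
            raise KeyError(f"structure {s.structure_id!r} not supplied")
        model = models[s.structure_id]
        cache_key = (s.structure_id, cutoff)
        if cache_key not in elig_cache:
            apr_keys = _apr_residue_keys(model, aprs.get(s.structure_id, []))
            elig_cache[cache_key] = contact_eligibility(model, apr_keys, cutoff)
        elig = elig_cache[cache_key]
        if s.key not in elig:
            raise KeyError(
                f"catalytic site {s.structure_id}/{s.chain_id}"
                f"{s.res_id}{s.icode} not found in structure"
            )
        observed += int(elig[s.key])

        _, chain_keys = model.chain_sequence(s.chain_id)
        candidates = list(chain_keys)
        if exclude_self:
            candidates = [k for k in candidates if k != s.key]
        if asa_match is not None:
            res_asa = asa_tables[s.structure_id].residue_asa()
            ref = res_asa[s.key]
            lo, hi = ref * (1 - asa_match), ref * (1 + asa_match)
            candidates = [k for k in candidates if lo <= res_asa[k] <= hi]
        if not candidates:
            raise ValueError(
                f"no decoy candidates for site {s.structure_id}/"
                f"{s.chain_id}{s.res_id}{s.icode} under the ASA constraint"
            )
        site_candidate_flags.append(
            np.array([elig[k] for k in candidates], dtype=bool)
        )

    counts = np.zeros(n_lists, dtype=np.int64)
    for flags in site_candidate_flags:
        draws = rng.integers(len(flags), size=n_lists)
        counts += flags[draws]
    mean = float(counts.mean())
    sd = float(counts.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else None
    return DecoyNullResult(
        observed=observed, null_mean=mean, null_sd=sd, z=z,
        n_lists=n_lists, cutoff=cutoff, asa_match=asa_match, seed=seed,
    )
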