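"""Solvent accessibility and burial metrics for sequence segments in 3D.

Per-residue solvent accessible surface areas (ASA) are computed with a
Shrake–Rupley engine: each heavy atom is covered with a deterministic
Fibonacci sphere of test points at radius (vdW + probe), a point counts as
accessible when it lies outside every neighbouring atom's probe-expanded
sphere, and the accessible fraction scales the sphere area. Defaults are a
1.4 Å water probe and 960 points per atom.

For a segment (e.g. an APR) of protein j the derived quantities are:

* ``SASAobs`` — sum of the segment residues' in-context ASA;
* ``SASAexp`` — sum of dataset-average ASA of the constituent residue types;
* ``TotSA``   — ASA of the segment's atoms alone, in the identical
  conformation, with the rest of the protein deleted;
* ``SolvAcc = 100 * SASAobs / TotSA`` (percent solvent accessibility);
* ``BurPref = SASAobs / SASAexp`` (< 1: more buried than composition predicts);
* ``ProtBurSA = TotSA - SASAobs`` (surface buried by the rest of the protein);
* ``Iso = ProtBurSA / TotSA`` (solvent isolatedness, 0–1).

Isolatedness of a segment is standardized against every equal-length sliding
window of the same protein: the Z-score uses the window mean and standard
deviation, and RIso is the ratio of the segment's Iso to the window mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .records import APRInterval

#: Van der Waals radii (Å), Bondi-style set used by the SASA engine.
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


@dataclass
class StructureModel:
    """Heavy atoms of a protein structure as parallel arrays.

    ``chain_ids``, ``res_ids`` (author numbering), ``icodes``, ``res_names``
    (3-letter), ``atom_names``, ``elements`` and ``coords`` (N x 3 Å) all
    have one entry per heavy atom. Hydrogens must be stripped before
    construction.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    icodes: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.coords)
        for name in ("chain_ids", "res_ids", "icodes", "res_names",
                     "atom_names", "elements"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if n == 0:
            raise ValueError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(np.char.upper(self.elements.astype(str)) == "H"):
            raise ValueError("hydrogens must be removed before construction")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain, resnum, icode) keys in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_ids, self.res_ids, self.icodes):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)

    def atom_residue_index(self) -> np.ndarray:
        """Per-atom index into :meth:`residue_keys`."""
        keys = {k: i for i, k in enumerate(self.residue_keys())}
        return np.array([
            keys[(str(c), int(r), str(i))]
            for c, r, i in zip(self.chain_ids, self.res_ids, self.icodes)
        ])

    def subset(self, atom_mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chain_ids[atom_mask], self.res_ids[atom_mask],
            self.icodes[atom_mask], self.res_names[atom_mask],
            self.atom_names[atom_mask], self.elements[atom_mask],
            self.coords[atom_mask],
        )

    def residue_subset(
        self, keys: Iterable[tuple[str, int, str]]
    ) -> "StructureModel":
        wanted = set(keys)
        idx = self.atom_residue_index()
        all_keys = self.residue_keys()
        mask = np.array([all_keys[i] in wanted for i in idx])
        if not mask.any():
            raise ValueError("no atoms matched the requested residues")
        return self.subset(mask)

    def chain_sequence(self, chain_id: str) -> tuple[str, list[tuple[str, int, str]]]:
        """One-letter sequence of a chain and the residue keys, file order."""
        keys = [k for k in self.residue_keys() if k[0] == chain_id]
        res_name: dict[tuple[str, int, str], str] = {}
        for c, r, i, rn in zip(self.chain_ids, self.res_ids, self.icodes,
                               self.res_names):
            res_name.setdefault((str(c), int(r), str(i)), str(rn))
        seq = "".join(THREE_TO_ONE.get(res_name[k], "X") for k in keys)
        return seq, keys


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors (deterministic golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(
    elements: np.ndarray, fallback_radius: float | None
) -> np.ndarray:
    radii = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = str(el).upper()
        if key in VDW_RADII:
            radii[i] = VDW_RADII[key]
        elif fallback_radius is not None:
            radii[i] = fallback_radius
        else:
            raise KeyError(
                f"no van der Waals radius for element {el!r}; "
                "pass fallback_radius to accept a default"
            )
    return radii


def atom_sasa(
    coords: np.ndarray,
    elements: np.ndarray,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
    fallback_radius: float | None = None,
) -> np.ndarray:
    """Shrake–Rupley SASA (Å²) per atom.

    An isolated atom evaluates exactly to 4*pi*(r + probe)^2 because every
    test point is accessible.
    """
    coords = np.asarray(coords, dtype=float)
    radii = _atom_radii(np.asarray(elements), fallback_radius) + probe
    n = len(coords)
    sphere = fibonacci_sphere(points)
    tree = cKDTree(coords)
    max_r = radii.max()
    out = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                 if j != i]
        if neigh:
            d2 = np.sum(
                (pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2
            )
            accessible = np.all(d2 > (radii[neigh] ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * math.pi * radii[i] ** 2
    return out


@dataclass(frozen=True)
class ASATable:
    """Per-residue solvent accessible surface areas for one structure."""

    frame: pd.DataFrame  # chain, res_id, icode, res_name, asa
    probe: float
    points: int

    def residue_asa(self) -> dict[tuple[str, int, str], float]:
        return {
            (str(r.chain), int(r.res_id), str(r.icode)): float(r.asa)
            for r in self.frame.itertuples()
        }


def compute_asa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
    fallback_radius: float | None = None,
) -> ASATable:
    """Per-residue SASA of a structure (atom SASA summed per residue)."""
    per_atom = atom_sasa(model.coords, model.elements, probe, points,
                         fallback_radius)
    idx = model.atom_residue_index()
    keys = model.residue_keys()
    res_name: dict[tuple[str, int, str], str] = {}
    for c, r, i, rn in zip(model.chain_ids, model.res_ids, model.icodes,
                           model.res_names):
        res_name.setdefault((str(c), int(r), str(i)), str(rn))
    sums = np.bincount(idx, weights=per_atom, minlength=len(keys))
    frame = pd.DataFrame({
        "chain": [k[0] for k in keys],
        "res_id": [k[1] for k in keys],
        "icode": [k[2] for k in keys],
        "res_name": [res_name[k] for k in keys],
        "asa": sums,
    })
    return ASATable(frame, probe, points)


def average_asa_by_type(tables: Sequence[ASATable]) -> dict[str, float]:
    """Dataset-average ASA per residue type: sum of ASA over all residues of
    a type divided by their count, pooled over all supplied structures."""
    if not tables:
        raise ValueError("need at least one ASA table")
    frames = pd.concat([t.frame for t in tables], ignore_index=True)
    frames["aa"] = frames["res_name"].map(THREE_TO_ONE)
    frames = frames.dropna(subset=["aa"])
    grouped = frames.groupby("aa")["asa"].mean()
    return {aa: float(v) for aa, v in grouped.items()}


@dataclass(frozen=True)
class SegmentMetrics:
    """Burial metrics of one segment within its parent structure."""

    sasa_obs: float
    sasa_exp: float
    tot_sa: float
    solv_acc: float
    bur_pref: float
    prot_bur_sa: float
    iso: float

    def __post_init__(self) -> None:
        if not (-1e-6 <= self.iso <= 1 + 1e-6):
            raise ValueError(f"Iso out of [0, 1]: {self.iso}")


def _segment_keys(
    model: StructureModel, chain_id: str, start: int, end: int
) -> list[tuple[str, int, str]]:
    """Residue keys of a chain's 1-based sequence interval [start, end]."""
    _, keys = model.chain_sequence(chain_id)
    if end > len(keys):
        raise ValueError(
            f"segment [{start}, {end}] exceeds chain {chain_id!r} "
            f"of {len(keys)} residues"
        )
    return keys[start - 1 : end]


def segment_metrics_from_keys(
    model: StructureModel,
    keys: Sequence[tuple[str, int, str]],
    avasa: Mapping[str, float],
    asa_table: ASATable | None = None,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
    fallback_radius: float | None = None,
) -> SegmentMetrics:
    """Burial metrics for an explicit set of residue keys.

    ``asa_table`` (the full-context per-residue ASA) may be passed to avoid
    recomputation; TotSA is always recomputed on the isolated segment atoms
    in their unchanged conformation.
    """
    if asa_table is None:
        asa_table = compute_asa(model, probe, points, fallback_radius)
    res_asa = asa_table.residue_asa()
    missing = [k for k in keys if k not in res_asa]
    if missing:
        raise ValueError(f"segment residues without coordinates: {missing}")
    sasa_obs = float(sum(res_asa[k] for k in keys))

    res_name: dict[tuple[str, int, str], str] = {}
    for c, r, i, rn in zip(model.chain_ids, model.res_ids, model.icodes,
                           model.res_names):
        res_name.setdefault((str(c), int(r), str(i)), str(rn))
    sasa_exp = 0.0
    for k in keys:
        aa = THREE_TO_ONE.get(res_name[k], None)
        if aa is None or aa not in avasa:
            raise KeyError(
                f"no average ASA for residue type {res_name[k]!r} at {k}"
            )
        sasa_exp += avasa[aa]

    segment = model.residue_subset(keys)
    seg_table = compute_asa(segment, asa_table.probe, asa_table.points,
                            fallback_radius)
    tot_sa = float(seg_table.frame["asa"].sum())
    # numerical guard: in-context ASA can exceed isolated ASA only via
    # point-sampling noise
    sasa_obs = min(sasa_obs, tot_sa)
    prot_bur = tot_sa - sasa_obs
    return SegmentMetrics(
        sasa_obs=sasa_obs,
        sasa_exp=sasa_exp,
        tot_sa=tot_sa,
        solv_acc=100.0 * sasa_obs / tot_sa,
        bur_pref=sasa_obs / sasa_exp if sasa_exp > 0 else math.nan,
        prot_bur_sa=prot_bur,
        iso=prot_bur / tot_sa,
    )


def segment_metrics(
    model: StructureModel,
    segment: APRInterval,
    avasa: Mapping[str, float],
    chain_id: str | None = None,
    asa_table: ASATable | None = None,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
    fallback_radius: float | None = None,
) -> SegmentMetrics:
    """Burial metrics of a sequence segment (1-based interval on a chain)."""
    if chain_id is None:
        chain_id = str(model.chain_ids[0])
    keys = _segment_keys(model, chain_id, segment.start, segment.end)
    return segment_metrics_from_keys(model, keys, avasa, asa_table,
                                     probe, points, fallback_radius)


def _consecutive_runs(keys: Sequence[tuple[str, int, str]]) -> list[list[int]]:
    """Indices of runs of consecutively numbered residues (same chain)."""
    runs: list[list[int]] = []
    for i, k in enumerate(keys):
        if runs and keys[i - 1][0] == k[0] and k[1] == keys[i - 1][1] + 1:
            runs[-1].append(i)
        elif runs and keys[i - 1][0] == k[0] and k[1] == keys[i - 1][1] \
                and k[2] != keys[i - 1][2]:
            runs[-1].append(i)  # insertion-code continuation
        else:
            runs.append([i])
    return runs


def sliding_window_iso(
    model: StructureModel,
    window: int,
    chain_id: str | None = None,
    avasa: Mapping[str, float] | None = None,
    asa_table: ASATable | None = None,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
    fallback_radius: float | None = None,
) -> list[tuple[int, float]]:
    """Iso of every ``window``-residue sliding window of a chain.

    Windows are restricted to runs of consecutively numbered residues with
    coordinates. Returns (1-based start position, Iso) pairs.
    """
    if chain_id is None:
        chain_id = str(model.chain_ids[0])
    if asa_table is None:
        asa_table = compute_asa(model, probe, points, fallback_radius)
    res_asa = asa_table.residue_asa()
    _, keys = model.chain_sequence(chain_id)
    out: list[tuple[int, float]] = []
    for run in _consecutive_runs(keys):
        for j in range(len(run) - window + 1):
            idxs = run[j : j + window]
            wkeys = [keys[i] for i in idxs]
            sasa_obs = sum(res_asa[k] for k in wkeys)
            seg = model.residue_subset(wkeys)
            tot = float(compute_asa(seg, asa_table.probe, asa_table.points,
                                    fallback_radius).frame["asa"].sum())
            sasa_obs = min(sasa_obs, tot)
            out.append((idxs[0] + 1, (tot - sasa_obs) / tot))
    return out


def iso_zscore_riso(
    model: StructureModel,
    segment: APRInterval,
    chain_id: str | None = None,
    asa_table: ASATable | None = None,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
    fallback_radius: float | None = None,
) -> dict:
    """Standardize a segment's Iso against same-length sliding windows.

    Returns the segment Iso, window mean/sd (the segment's own window
    included), Z = (Iso - mean)/sd (None when sd = 0) and RIso = Iso/mean.
    """
    if chain_id is None:
        chain_id = str(model.chain_ids[0])
    window = len(segment)
    windows = sliding_window_iso(model, window, chain_id, asa_table=asa_table,
                                 probe=probe, points=points,
                                 fallback_radius=fallback_radius)
    if len(windows) < 2:
        raise ValueError("need at least two sliding windows")
    iso_by_start = dict(windows)
    if segment.start not in iso_by_start:
        raise ValueError(
            f"segment start {segment.start} is not a valid window "
            "(chain break or missing coordinates)"
        )
    iso_seg = iso_by_start[segment.start]
    vals = np.array([v for _, v in windows])
    mean, sd = float(vals.mean()), float(vals.std(ddof=0))
    z = (iso_seg - mean) / sd if sd > 0 else None
    riso = iso_seg / mean if mean > 0 else math.nan
    return {
        "iso": iso_seg, "window_mean": mean, "window_sd": sd,
        "z": z, "riso": riso, "n_windows": len(windows),
    }


SS_BINS = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand", "b": "strand",
}


def bin_secondary_structure(
    assignments: Mapping[tuple[str, int], str],
    aprs: Sequence[APRInterval],
) -> dict[str, int]:
    """Bin per-residue secondary-structure codes of APR residues.

    ``assignments`` maps (seq_id, 1-based position) to a one-letter code;
    helix = {H, G, I}, strand = {E, B, b}, everything else = coil. APR
    residues without an assignment are excluded with a warning.
    """
    import warnings as _warnings

    out = {"helix": 0, "strand": 0, "coil": 0}
    for apr in aprs:
        for pos in range(apr.start, apr.end + 1):
            code = assignments.get((apr.seq_id, pos))
            if code is None:
                _warnings.warn(
                    f"no secondary-structure code for {apr.seq_id}:{pos}; "
                    "residue excluded", stacklevel=2,
                )
                continue
            out[SS_BINS.get(code, "coil")] += 1
    return out
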