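"""Readers and writers for the toolkit's interchange formats.

Sequences travel as FASTA (Biopython), alignments as aligned FASTA or
Clustal, structures as PDB (biotite; first model, ATOM records,
highest-occupancy altloc, hydrogens stripped). Tabular annotations use
normalized TSV dialects:

* APR tables:        seq_id, start, end, source, score
* disorder tables:   seq_id, start, end, state
* catalytic sites:   structure_id, chain, resnum, icode, restype
* compositions:      amino_acid, frequency (20 rows)

All sequence coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .conservation import AlignmentSet
from .disorder import DisorderAnnotation
from .proximity import CatalyticSite
from .records import AMINO_ACIDS, APRInterval, SequenceRecord, clean_residues
from .structure import StructureModel


# -- sequences ---------------------------------------------------------------

def read_fasta(path: str | Path, drop_ambiguous: bool = False) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = clean_residues(str(rec.seq), drop_ambiguous=drop_ambiguous)
        records.append(SequenceRecord(rec.id, residues))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(seqs: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


# -- alignments --------------------------------------------------------------

def read_alignment(path: str | Path, fmt: str = "fasta") -> AlignmentSet:
    """Read an alignment (``fasta`` or ``clustal``); first row = parent."""
    aln = AlignIO.read(str(path), fmt)
    return AlignmentSet(
        tuple(r.id for r in aln), tuple(str(r.seq).upper() for r in aln)
    )


def write_alignment(aln: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


# -- APR tables --------------------------------------------------------------

APR_COLUMNS = ["seq_id", "start", "end", "source", "score"]


def read_apr_table(path: str | Path) -> list[APRInterval]:
    df = pd.read_csv(path, sep="\t")
    missing = set(APR_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"APR table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        score = getattr(row, "score", None)
        if score is not None and (isinstance(score, float) and math.isnan(score)):
            score = None
        out.append(APRInterval(str(row.seq_id), int(row.start), int(row.end),
                               str(row.source), score))
    return out


def write_apr_table(aprs: Sequence[APRInterval], path: str | Path) -> None:
    pd.DataFrame(
        [{"seq_id": a.seq_id, "start": a.start, "end": a.end,
          "source": a.source, "score": a.score} for a in aprs],
        columns=APR_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def convert_predictor_output(path: str | Path) -> list[APRInterval]:
    """Converter stub for raw TANGO/WALTZ output files.

    Raw predictor formats are version-dependent and intentionally
    unsupported; convert them to the normalized APR TSV dialect
    (seq_id, start, end, source, score) and use :func:`read_apr_table`.
    """
    raise NotImplementedError(
        "raw predictor outputs are out of scope; supply a normalized APR TSV"
    )


# -- disorder tables ---------------------------------------------------------

def read_disorder_table(path: str | Path) -> list[DisorderAnnotation]:
    df = pd.read_csv(path, sep="\t")
    if "state" in df.columns:
        df = df[df["state"].str.lower() == "disordered"]
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples():
        by_seq.setdefault(str(row.seq_id), []).append(
            (int(row.start), int(row.end))
        )
    return [DisorderAnnotation(sid, tuple(ivs)) for sid, ivs in by_seq.items()]


def write_disorder_table(
    anns: Sequence[DisorderAnnotation], path: str | Path
) -> None:
    rows = [
        {"seq_id": a.seq_id, "start": s, "end": e, "state": "disordered"}
        for a in anns for s, e in a.intervals
    ]
    pd.DataFrame(rows, columns=["seq_id", "start", "end", "state"]).to_csv(
        path, sep="\t", index=False
    )


# -- catalytic-site tables ---------------------------------------------------

SITE_COLUMNS = ["structure_id", "chain", "resnum", "icode", "restype"]


def read_site_table(path: str | Path) -> list[CatalyticSite]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples():
        icode = str(row.icode) if str(row.icode) not in ("", "nan") else ""
        out.append(CatalyticSite(str(row.structure_id), str(row.chain),
                                 int(row.resnum), icode, str(row.restype)))
    return out


def write_site_table(sites: Sequence[CatalyticSite], path: str | Path) -> None:
    pd.DataFrame(
        [{"structure_id": s.structure_id, "chain": s.chain_id,
          "resnum": s.res_id, "icode": s.icode, "restype": s.res_type}
         for s in sites],
        columns=SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# -- compositions ------------------------------------------------------------

def read_composition(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    comp = {str(r.amino_acid): float(r.frequency) for r in df.itertuples()}
    if set(comp) != set(AMINO_ACIDS):
        raise ValueError("composition TSV must cover exactly the 20 amino acids")
    return comp


def write_composition(comp: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"amino_acid": list(AMINO_ACIDS),
         "frequency": [comp[a] for a in AMINO_ACIDS]}
    ).to_csv(path, sep="\t", index=False)


# -- secondary-structure codes ----------------------------------------------

def read_ss_table(path: str | Path) -> dict[tuple[str, int], str]:
    """STRIDE/DSSP-style per-residue codes: seq_id, position, code TSV."""
    df = pd.read_csv(path, sep="\t")
    return {(str(r.seq_id), int(r.position)): str(r.code)
            for r in df.itertuples()}


# -- PDB structures ----------------------------------------------------------

def read_pdb(path: str | Path, include_hetero: bool = False) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    First model of multi-model files; highest-occupancy altloc; hydrogens
    removed; hetero records (ligands, waters) dropped unless requested.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1, altloc="occupancy", extra_fields=[])
    mask = np.char.upper(arr.element.astype(str)) != "H"
    if not include_hetero:
        mask &= ~arr.hetero
    arr = arr[mask]
    if arr.array_length() == 0:
        raise ValueError(f"no heavy ATOM records in {path}")
    icodes = arr.ins_code if hasattr(arr, "ins_code") else \
        np.array([""] * arr.array_length())
    return StructureModel(
        chain_ids=arr.chain_id.astype(str),
        res_ids=arr.res_id.astype(int),
        icodes=icodes.astype(str),
        res_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        elements=arr.element.astype(str),
        coords=np.asarray(arr.coord, dtype=float),
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as a single-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = model.chain_ids.astype("U4")
    arr.res_id = model.res_ids.astype(int)
    arr.ins_code = model.icodes.astype("U1")
    arr.res_name = model.res_names.astype("U5")
    arr.atom_name = model.atom_names.astype("U6")
    arr.element = model.elements.astype("U2")
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.hetero = np.zeros(n, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))
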