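"""Disruption-candidate ranking and end-to-end orchestration.

The solubility-engineering decision rule evaluates, for each candidate APR,
three features: whether it is buried (its isolatedness Z-score against
equal-length sliding windows is positive), whether it contacts functional
residues, and whether it is more conserved than the mean sequence identity
of its homologue family. The verdicts:

* buried                                        -> do_not_disrupt
* exposed, contacts,     more conserved         -> do_not_disrupt
* exposed, no contact,   less conserved         -> priority_target
* exposed, no contact,   more conserved         -> conditional_disrupt_after_allostery_check
* exposed, contacts,     less conserved         -> conditional_disrupt_with_modeling

Any missing feature yields ``insufficient_evidence``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VERDICTS = (
    "do_not_disrupt",
    "priority_target",
    "conditional_disrupt_after_allostery_check",
    "conditional_disrupt_with_modeling",
    "insufficient_evidence",
)


@dataclass(frozen=True)
class APRDossier:
    """Feature flags gathered for one candidate APR."""

    seq_id: str
    start: int
    end: int
    buried: bool | None  # Iso Z-score > 0 against sliding windows
    functional_contact: bool | None
    more_conserved_than_identity: bool | None


def rank_disruption_candidate(d: APRDossier) -> tuple[str, str]:
    """Verdict and rationale for one dossier (total over the 2^3 flag cube)."""
    if d.buried is None or d.functional_contact is None \
            or d.more_conserved_than_identity is None:
        return "insufficient_evidence", "one or more feature flags missing"
    if d.buried:
        return ("do_not_disrupt",
                "buried in the core; contributes to stability")
    if d.functional_contact and d.more_conserved_than_identity:
        return ("do_not_disrupt",
                "contacts functional residues and is conserved beyond the "
                "family mean identity")
    if not d.functional_contact and not d.more_conserved_than_identity:
        return ("priority_target",
                "exposed, free of functional contacts, and less conserved "
                "than the family mean identity")
    if not d.functional_contact:
        return ("conditional_disrupt_after_allostery_check",
                "exposed and contact-free but conserved; verify the "
                "conservation is not structural/allosteric before disrupting")
    return ("conditional_disrupt_with_modeling",
            "exposed and weakly conserved but contacts functional residues; "
            "disrupt only at positions modeling shows are safe")


def rank_disruption_candidates(dossiers) -> pd.DataFrame:
    rows = []
    for d in dossiers:
        verdict, why = rank_disruption_candidate(d)
        rows.append({**asdict(d), "verdict": verdict, "rationale": why})
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the synthetic end-to-end analysis and write a report bundle.

    ``config`` keys (all optional): ``seed``, ``n_sequences``, ``n_lists``,
    ``cutoff``, ``surrogate_threshold``, plus any :class:`SyntheticSpec`
    field. Writes TSV tables, a JSON manifest with every resolved parameter,
    and returns the manifest dict. Identical config + seed reproduce
    byte-identical reports.
    """
    import dataclasses

    from . import io as aio
    from .annotation import dataset_summary, gatekeeper_profile, \
        combine_gatekeeper_profiles, surrogate_predict_aprs
    from .conservation import apr_conservation, mean_identity_to_parent
    from .disorder import association_tests, build_contingency, odds_ratio
    from .proximity import decoy_null
    from .structure import average_asa_by_type, compute_asa, \
        iso_zscore_riso, segment_metrics
    from .synthetic import (SyntheticSpec, make_alignment_family,
                            make_catalytic_scenario, make_disorder_corpus,
                            make_sequences_with_aprs, make_toy_structure)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    spec_fields = {f.name for f in dataclasses.fields(SyntheticSpec)}
    spec = SyntheticSpec(seed=seed, **{k: v for k, v in config.items()
                                       if k in spec_fields and k != "seed"})
    n_lists = int(config.get("n_lists", 2000))
    cutoff = float(config.get("cutoff", 4.5))
    threshold = float(config.get("surrogate_threshold", 2.0))

    manifest: dict = {"seed": seed, "n_lists": n_lists, "cutoff": cutoff,
                      "surrogate_threshold": threshold,
                      "spec": dataclasses.asdict(spec)}

    # 1. sequence world: planted APRs, gate-keepers, surrogate recovery
    seqs, truth = make_sequences_with_aprs(spec)
    aio.write_fasta(seqs, out / "sequences.fasta")
    aio.write_apr_table(truth, out / "aprs_truth.tsv")
    by_seq: dict[str, list] = {}
    for a in truth:
        by_seq.setdefault(a.seq_id, []).append(a)
    profiles = [gatekeeper_profile(s, by_seq.get(s.id, [])) for s in seqs]
    gk = combine_gatekeeper_profiles(profiles)
    preds = [surrogate_predict_aprs(s, threshold=threshold) for s in seqs]
    summary = dataset_summary(preds)
    manifest["sequences"] = {
        "n": len(seqs),
        "gatekeepers_per_apr": gk.mean_per_apr,
        "surrogate_summary": summary,
    }
    pd.DataFrame([summary]).to_csv(out / "surrogate_summary.tsv",
                                   sep="\t", index=False)

    # 2. disorder contingency
    dseqs, daprs, danns, table = make_disorder_corpus(spec)
    est = build_contingency(dseqs, daprs, danns)
    tests = association_tests(est)
    manifest["disorder"] = {
        "cells": est.as_tuple(),
        "odds_ratio_ordered": odds_ratio(est, "ordered"),
        "odds_ratio_disordered": odds_ratio(est, "disordered"),
        **tests,
    }

    # 3. structure burial on the toy bundle
    model, segments = make_toy_structure(spec)
    asa = compute_asa(model)
    avasa = average_asa_by_type([asa])
    burial = {}
    for name, seg in segments.items():
        m = segment_metrics(model, seg, avasa, asa_table=asa)
        zr = iso_zscore_riso(model, seg, asa_table=asa)
        burial[name] = {"iso": m.iso, "solv_acc": m.solv_acc,
                        "bur_pref": m.bur_pref, "z": zr["z"],
                        "riso": zr["riso"]}
    manifest["burial"] = burial

    # 4. conservation on a synthetic family
    aln, paprs, expected = make_alignment_family(spec)
    pct, detail = apr_conservation(aln, paprs)
    detail.to_csv(out / "conservation.tsv", sep="\t", index=False)
    manifest["conservation"] = {
        "measured_pct": pct,
        "expected_pct": expected["conservation_pct"],
        "mean_identity_pct": mean_identity_to_parent(aln),
    }

    # 5. catalytic proximity decoy null
    cmodel, sites, caprs, truth_flags = make_catalytic_scenario(spec)
    null = decoy_null({"toy": cmodel}, sites, {"toy": caprs},
                      n_lists=n_lists, cutoff=cutoff, seed=seed)
    manifest["catalytic"] = {
        "observed": null.observed, "null_mean": null.null_mean,
        "null_sd": null.null_sd, "z": null.z, "n_lists": null.n_lists,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
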