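"""Shrake-Rupley SASA engine and segment burial/isolatedness metrics."""

import math

import numpy as np
import pytest

from aprstat.records import APRInterval
from aprstat.structure import (
    StructureModel,
    atom_sasa,
    average_asa_by_type,
    bin_secondary_structure,
    compute_asa,
    iso_zscore_riso,
    segment_metrics,
    sliding_window_iso,
)

R_C = 1.70  # carbon vdW radius in the engine's radius set
PROBE = 1.4


def two_sphere_accessible_area(r1, r2, d):
    """Closed-form accessible area of sphere 1 (radius r1) occluded by
    sphere 2 (radius r2) at centre distance d — the spherical-cap formula,
    the independent oracle for pairwise occlusion."""
    if d >= r1 + r2:
        return 4 * math.pi * r1**2
    if d + r1 <= r2:
        return 0.0
    h = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    return 4 * math.pi * r1**2 - 2 * math.pi * r1 * h


def carbons(coords):
    coords = np.asarray(coords, dtype=float)
    return coords, np.array(["C"] * len(coords))


class TestAtomSASA:
    def test_isolated_atom_closed_form(self):
        coords, el = carbons([[0, 0, 0]])
        area = atom_sasa(coords, el)[0]
        assert area == pytest.approx(4 * math.pi * (R_C + PROBE) ** 2,
                                     rel=1e-9)

    def test_two_distant_atoms_no_occlusion(self):
        coords, el = carbons([[0, 0, 0], [100, 0, 0]])
        areas = atom_sasa(coords, el)
        single = 4 * math.pi * (R_C + PROBE) ** 2
        assert areas == pytest.approx([single, single], rel=1e-9)

    @pytest.mark.parametrize("d", [1.5, 2.5, 3.5, 4.5, 5.5])
    def test_two_sphere_oracle_within_1pct(self, d):
        coords, el = carbons([[0, 0, 0], [d, 0, 0]])
        areas = atom_sasa(coords, el)
        r = R_C + PROBE
        expected = two_sphere_accessible_area(r, r, d)
        total_single = 4 * math.pi * r**2
        # 1% of the full sphere area: point-sampling tolerance
        assert abs(areas[0] - expected) < 0.01 * total_single
        assert abs(areas[1] - expected) < 0.01 * total_single

    def test_three_atom_cluster_vs_biotite(self):
        # independent engine cross-check on a small toy
        import biotite.structure as struc

        coords = np.array([[0.0, 0, 0], [2.2, 0, 0], [1.1, 1.9, 0]])
        areas = atom_sasa(coords, np.array(["C", "C", "C"]), points=960)
        arr = struc.AtomArray(3)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 3)
        arr.res_id = np.array([1, 2, 3])
        arr.res_name = np.array(["ALA"] * 3)
        arr.atom_name = np.array(["CA"] * 3)
        arr.chain_id = np.array(["A"] * 3)
        arr.hetero = np.zeros(3, bool)
        ref = struc.sasa(arr, probe_radius=PROBE, point_number=1000,
                         vdw_radii="Single")
        # engines use different radius sets; compare at matched radii via
        # relative agreement only
        assert areas.sum() == pytest.approx(ref.sum(), rel=0.05)

    def test_point_count_convergence(self, toy_bundle):
        model, _ = toy_bundle
        a960 = compute_asa(model, points=960).frame["asa"].to_numpy()
        a1920 = compute_asa(model, points=1920).frame["asa"].to_numpy()
        rel = np.abs(a960 - a1920) / np.maximum(a1920, 1e-9)
        assert rel.max() < 0.02

    def test_occluder_monotonicity(self, rng):
        # adding an occluding atom never increases any existing atom's SASA
        base = rng.uniform(-3, 3, size=(6, 3))
        before = atom_sasa(*carbons(base))
        for _ in range(5):
            extra = np.vstack([base, rng.uniform(-3, 3, size=(1, 3))])
            after = atom_sasa(*carbons(extra))[:6]
            assert np.all(after <= before + 1e-9)

    def test_unknown_element_requires_fallback(self):
        with pytest.raises(KeyError):
            atom_sasa(np.array([[0.0, 0, 0]]), np.array(["ZZ"]))
        area = atom_sasa(np.array([[0.0, 0, 0]]), np.array(["ZZ"]),
                         fallback_radius=1.7)
        assert area[0] > 0


class TestStructureModel:
    def test_hydrogens_rejected(self):
        with pytest.raises(ValueError):
            StructureModel(
                chain_ids=np.array(["A"]), res_ids=np.array([1]),
                icodes=np.array([""]), res_names=np.array(["ALA"]),
                atom_names=np.array(["H"]), elements=np.array(["H"]),
                coords=np.zeros((1, 3)),
            )

    def test_non_finite_coords_rejected(self):
        with pytest.raises(ValueError):
            StructureModel(
                chain_ids=np.array(["A"]), res_ids=np.array([1]),
                icodes=np.array([""]), res_names=np.array(["ALA"]),
                atom_names=np.array(["CA"]), elements=np.array(["C"]),
                coords=np.array([[np.nan, 0, 0]]),
            )


class TestAverageASA:
    def test_single_residue_average(self, line_chain):
        asa = compute_asa(line_chain)
        av = average_asa_by_type([asa])
        assert av["A"] == pytest.approx(float(asa.frame["asa"].mean()))

    def test_two_residue_mean(self):
        import pandas as pd

        from aprstat.structure import ASATable

        frame = pd.DataFrame({
            "chain": ["A", "A"], "res_id": [1, 2], "icode": ["", ""],
            "res_name": ["ALA", "ALA"], "asa": [10.0, 30.0],
        })
        av = average_asa_by_type([ASATable(frame, 1.4, 960)])
        assert av["A"] == 20.0

    def test_pooled_over_structures(self):
        import pandas as pd

        from aprstat.structure import ASATable

        f1 = pd.DataFrame({"chain": ["A"], "res_id": [1], "icode": [""],
                           "res_name": ["GLY"], "asa": [12.0]})
        f2 = pd.DataFrame({"chain": ["A"], "res_id": [1], "icode": [""],
                           "res_name": ["GLY"], "asa": [24.0]})
        av = average_asa_by_type([ASATable(f1, 1.4, 960),
                                  ASATable(f2, 1.4, 960)])
        assert av["G"] == 18.0


class TestSegmentMetrics:
    def test_identity_iso_plus_solvacc(self, toy_bundle_asa):
        model, segments, asa = toy_bundle_asa
        av = average_asa_by_type([asa])
        for seg in segments.values():
            m = segment_metrics(model, seg, av, asa_table=asa)
            assert m.iso + m.solv_acc / 100.0 == pytest.approx(1.0, abs=1e-12)
            assert m.tot_sa >= m.sasa_obs
            assert 0.0 <= m.iso <= 1.0
            assert m.bur_pref >= 0.0

    def test_whole_structure_segment_iso_zero(self, line_chain):
        asa = compute_asa(line_chain)
        av = average_asa_by_type([asa])
        n = len(line_chain.residue_keys())
        m = segment_metrics(line_chain, APRInterval("A", 1, n), av,
                            asa_table=asa)
        assert m.iso == pytest.approx(0.0, abs=1e-12)
        assert m.solv_acc == pytest.approx(100.0)
        assert m.prot_bur_sa == pytest.approx(0.0, abs=1e-9)

    def test_equal_type_segments_share_sasaexp(self, toy_bundle_asa):
        model, segments, asa = toy_bundle_asa
        av = average_asa_by_type([asa])
        mc = segment_metrics(model, segments["core"], av, asa_table=asa)
        mt = segment_metrics(model, segments["tail"], av, asa_table=asa)
        assert mc.sasa_exp == pytest.approx(mt.sasa_exp)  # all-ALA chain

    def test_missing_residue_reported(self, line_chain):
        asa = compute_asa(line_chain)
        av = average_asa_by_type([asa])
        with pytest.raises(ValueError):
            segment_metrics(line_chain, APRInterval("A", 28, 40), av,
                            asa_table=asa)


class TestIsoZscore:
    def test_core_above_tail(self, toy_bundle_asa):
        model, segments, asa = toy_bundle_asa
        zc = iso_zscore_riso(model, segments["core"], asa_table=asa)
        zt = iso_zscore_riso(model, segments["tail"], asa_table=asa)
        assert zc["iso"] > zt["iso"]
        assert zc["z"] > 0 > zt["z"]
        assert zc["riso"] > 1 > zt["riso"]

    def test_direct_formula_consistency(self, toy_bundle_asa):
        model, segments, asa = toy_bundle_asa
        out = iso_zscore_riso(model, segments["core"], asa_table=asa)
        assert out["z"] == pytest.approx(
            (out["iso"] - out["window_mean"]) / out["window_sd"]
        )
        assert out["riso"] == pytest.approx(out["iso"] / out["window_mean"])

    def test_degenerate_sd_zero(self):
        # two identical far-apart residues, window 1: all windows Iso = 0
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        model = StructureModel(
            chain_ids=np.array(["A", "A"]), res_ids=np.array([1, 2]),
            icodes=np.array(["", ""]), res_names=np.array(["ALA", "ALA"]),
            atom_names=np.array(["CA", "CA"]), elements=np.array(["C", "C"]),
            coords=coords,
        )
        out = iso_zscore_riso(model, APRInterval("A", 1, 1))
        assert out["z"] is None
        assert out["window_sd"] == 0.0

    def test_windows_skip_chain_breaks(self):
        # residues numbered 1,2,3, 10,11,12: no window may span the gap
        n = 6
        coords = np.column_stack([4.0 * np.arange(n), np.zeros(n),
                                  np.zeros(n)])
        model = StructureModel(
            chain_ids=np.array(["A"] * n),
            res_ids=np.array([1, 2, 3, 10, 11, 12]),
            icodes=np.array([""] * n), res_names=np.array(["ALA"] * n),
            atom_names=np.array(["CA"] * n), elements=np.array(["C"] * n),
            coords=coords,
        )
        starts = [s for s, _ in sliding_window_iso(model, 3)]
        assert starts == [1, 4]  # one window per run of 3


class TestSecondaryStructureBins:
    def test_all_strand(self):
        codes = {("s", i): "E" for i in range(1, 11)}
        out = bin_secondary_structure(codes, [APRInterval("s", 2, 7)])
        assert out == {"helix": 0, "strand": 6, "coil": 0}

    def test_mixed_hand_binning(self):
        codes = {("s", 1): "H", ("s", 2): "G", ("s", 3): "I",
                 ("s", 4): "E", ("s", 5): "B", ("s", 6): "C",
                 ("s", 7): "T", ("s", 8): "b"}
        out = bin_secondary_structure(codes, [APRInterval("s", 1, 8)])
        assert out == {"helix": 3, "strand": 3, "coil": 2}

    def test_empty_apr_set(self):
        assert bin_secondary_structure({}, []) == \
            {"helix": 0, "strand": 0, "coil": 0}

    def test_missing_assignment_warns_and_excludes(self):
        codes = {("s", 1): "E"}
        with pytest.warns(UserWarning):
            out = bin_secondary_structure(codes, [APRInterval("s", 1, 6)])
        assert out["strand"] == 1 and sum(out.values()) == 1
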