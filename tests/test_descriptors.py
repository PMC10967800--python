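"""Descriptor math: pseudo-B-factors, hydrophobicity, charge, assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hacsurf.descriptors import (
    avg_surface_hydrophobicity,
    build_feature_table,
    charged_area_fractions,
    compute_descriptor_vector,
    net_surface_charge,
    normalized_surface_b,
    plddt_to_rmsd,
    rmsd_to_b,
)
from hacsurf.structure import Atom, ProteinStructure, Residue
from hacsurf.surface import SasaResult, SurfaceMask, shrake_rupley_sasa
from hacsurf.synthetic import make_ideal_helix

SIX_PI_SQ = 6.0 * np.pi**2


class TestPseudoBFactor:
    @pytest.mark.parametrize(
        "plddt, expected",
        [(50.0, 1.5), (100.0, 1.5 * np.exp(-2.0)), (70.0, 1.5 * np.exp(-0.8))],
    )
    def test_rmsd_values(self, plddt, expected):
        assert plddt_to_rmsd(plddt) == pytest.approx(expected, rel=1e-12)
        # spot values: 0.2030 A at full confidence, 0.6740 A at 70
        assert plddt_to_rmsd(100.0) == pytest.approx(0.2030, abs=5e-4)
        assert plddt_to_rmsd(70.0) == pytest.approx(0.6740, abs=5e-4)

    def test_b_values(self):
        assert rmsd_to_b(1.5) == pytest.approx(SIX_PI_SQ)
        assert rmsd_to_b(1.5) <= 60.0  # the "B <= 60" equivalence
        assert rmsd_to_b(0.0) == 0.0
        assert rmsd_to_b(plddt_to_rmsd(70.0)) == pytest.approx(11.96, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            plddt_to_rmsd(101.0)
        with pytest.raises(ValueError):
            plddt_to_rmsd(-1.0)
        with pytest.raises(ValueError):
            rmsd_to_b(-0.1)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_composition(self, p1, p2):
        # higher confidence -> smaller error -> smaller B
        d1, d2 = plddt_to_rmsd(p1), plddt_to_rmsd(p2)
        if p1 < p2:
            assert d1 > d2
            assert rmsd_to_b(d1) > rmsd_to_b(d2)

    @given(st.floats(0.0, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_confidence_threshold_maps_to_b_cut(self, p):
        assert (p >= 50.0) == (rmsd_to_b(plddt_to_rmsd(p)) <= SIX_PI_SQ + 1e-9)


def _structure_with_plddt(plddts, name="ALA"):
    residues = [
        Residue(name, i + 1, [Atom("CA", "C", np.array([3.8 * i, 0.0, 0.0]), p)])
        for i, p in enumerate(plddts)
    ]
    return ProteinStructure("toy", residues)


def _full_mask(n):
    return SurfaceMask(rel_acc=np.ones(n), surface_flag=np.ones(n, dtype=bool))


class TestNormalizedSurfaceB:
    def test_uniform_plddt_gives_zero(self):
        s = _structure_with_plddt([80.0] * 5)
        with pytest.warns(UserWarning, match="all pLDDT equal"):
            assert normalized_surface_b(s, _full_mask(5)) == 0.0

    def test_symmetric_b_set_has_zero_mean(self):
        # choose pLDDT values whose B are 10, 20, 30: z-scores average to 0
        plddts = [
            100.0 * (0.5 - np.log(np.sqrt(3.0 * b / (8 * np.pi**2)) / 1.5) / 4.0)
            for b in (10.0, 20.0, 30.0)
        ]
        s = _structure_with_plddt(plddts)
        assert normalized_surface_b(s, _full_mask(3)) == pytest.approx(0.0, abs=1e-10)

    def test_against_spreadsheet_oracle(self):
        rng = np.random.default_rng(3)
        plddts = rng.uniform(40.0, 98.0, 12)
        s = _structure_with_plddt(list(plddts))
        flags = np.zeros(12, dtype=bool)
        flags[[0, 3, 4, 7, 9]] = True
        mask = SurfaceMask(rel_acc=np.ones(12), surface_flag=flags)
        # independent recomputation
        delta = 1.5 * np.exp(4 * (0.5 - plddts / 100))
        b = 8 * np.pi**2 * delta**2 / 3
        bn = (b - b.mean()) / b.std()
        keep = flags & (delta <= 1.5)
        expected = bn[keep].mean()
        assert normalized_surface_b(s, mask) == pytest.approx(expected, rel=1e-12)

    def test_whole_structure_zscores_standardized(self):
        rng = np.random.default_rng(5)
        plddts = rng.uniform(30.0, 99.0, 50)
        b = rmsd_to_b(plddt_to_rmsd(plddts))
        bn = (b - b.mean()) / b.std()
        assert bn.mean() == pytest.approx(0.0, abs=1e-12)
        assert bn.std() == pytest.approx(1.0, abs=1e-12)

    def test_no_confident_surface_residue_flagged(self):
        s = _structure_with_plddt([40.0, 45.0, 42.0])  # all Delta > 1.5
        with pytest.warns(UserWarning, match="norm_s_b undefined"):
            assert np.isnan(normalized_surface_b(s, _full_mask(3)))


class TestHydrophobicity:
    def test_single_residue_extremes(self):
        for name, expected in [("ILE", 0.73), ("ARG", -1.76)]:
            s = _structure_with_plddt([90.0, 90.0], name=name)
            mask = SurfaceMask(
                rel_acc=np.ones(2), surface_flag=np.array([True, False])
            )
            assert avg_surface_hydrophobicity(s, mask) == pytest.approx(expected)

    def test_empty_surface_flagged(self):
        s = _structure_with_plddt([90.0] * 3)
        mask = SurfaceMask(rel_acc=np.ones(3), surface_flag=np.zeros(3, dtype=bool))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(avg_surface_hydrophobicity(s, mask))


class TestChargedAreas:
    def test_poly_ala_is_uncharged(self, helix15):
        sasa = shrake_rupley_sasa(helix15)
        assert charged_area_fractions(sasa, helix15) == (0.0, 0.0, 0.0)

    def test_symmetric_asp_lys_pair(self):
        s = ProteinStructure(
            "pair",
            [
                Residue("ASP", 1, [Atom("CA", "C", np.zeros(3), 90.0)]),
                Residue("LYS", 2, [Atom("CA", "C", np.array([10.0, 0, 0]), 90.0)]),
            ],
        )
        sasa = SasaResult(1.4, np.array([50.0, 50.0]), np.array([50.0, 50.0]))
        pos, neg, tot = charged_area_fractions(sasa, s)
        assert (pos, neg, tot) == pytest.approx((0.5, 0.5, 1.0))

    def test_fractions_match_per_residue_oracle(self, helix_mixed):
        sasa = shrake_rupley_sasa(helix_mixed)
        pos, neg, tot = charged_area_fractions(sasa, helix_mixed)
        areas = pd.Series(
            sasa.per_residue_area, index=[r.name for r in helix_mixed.residues]
        )
        total = areas.sum()
        exp_pos = areas[areas.index.isin(["LYS", "ARG"])].sum() / total
        exp_neg = areas[areas.index.isin(["ASP", "GLU"])].sum() / total
        assert pos == pytest.approx(exp_pos, rel=1e-12)
        assert neg == pytest.approx(exp_neg, rel=1e-12)
        assert tot == pytest.approx(pos + neg, rel=1e-12)


class TestNetCharge:
    def test_single_asp_near_minus_one(self):
        s = _structure_with_plddt([90.0], name="ASP")
        q = net_surface_charge(s, _full_mask(1), pH=7.0)
        assert q == pytest.approx(-1.0 / (1.0 + 10 ** (3.65 - 7.0)), rel=1e-12)
        assert q == pytest.approx(-0.99955, abs=1e-5)

    def test_histidine_half_protonated_at_its_pka(self):
        s = _structure_with_plddt([90.0], name="HIS")
        assert net_surface_charge(s, _full_mask(1), pH=6.0) == pytest.approx(0.5)

    def test_asp_lys_pair_nearly_cancels(self):
        s = ProteinStructure(
            "zwitter",
            [
                Residue("ASP", 1, [Atom("CA", "C", np.zeros(3), 90.0)]),
                Residue("LYS", 2, [Atom("CA", "C", np.array([8.0, 0, 0]), 90.0)]),
            ],
        )
        assert abs(net_surface_charge(s, _full_mask(2), pH=7.0)) < 0.01

    def test_missing_pka_raises(self):
        s = _structure_with_plddt([90.0], name="HIS")
        with pytest.raises(KeyError):
            net_surface_charge(s, _full_mask(1), pka_table={"ASP": (3.65, -1)})


@pytest.fixture(scope="module")
def helix_vec(helix_mixed):
    return compute_descriptor_vector(helix_mixed, enforce_filters=False, voxel=0.5)


class TestDescriptorVector:
    def test_helix_is_helical_on_surface(self, helix_vec):
        assert helix_vec.s_ah > 0.8
        assert helix_vec.s_bs == 0.0

    def test_charge_identity_and_bounds(self, helix_vec):
        v = helix_vec
        assert v.s_charge_avg == pytest.approx(v.s_pos_area + v.s_neg_area)
        for name in ("s_pos_area", "s_neg_area", "s_charge_avg", "s_ah", "s_bs", "s_do"):
            assert 0.0 <= getattr(v, name) <= 1.0
        assert 2.0 <= v.fd <= 3.0

    def test_too_short_structure_rejected(self, single_sphere):
        with pytest.raises(ValueError, match="inclusion"):
            compute_descriptor_vector(single_sphere)

    def test_assembly_is_deterministic(self, helix_mixed):
        kwargs = dict(enforce_filters=False, voxel=0.8)
        v1 = compute_descriptor_vector(helix_mixed, **kwargs)
        v2 = compute_descriptor_vector(helix_mixed, **kwargs)
        assert v1.as_dict() == v2.as_dict()


def test_build_feature_table_excludes_short_structures():
    rng = np.random.default_rng(1)
    seqs = {
        "P100": 100,
        "P050": 50,  # fails the length filter
        "P110": 110,
    }
    structures = []
    for pid, n in seqs.items():
        seq = list(rng.choice(["ALA", "LYS", "GLU", "SER", "VAL"], size=n))
        structures.append(
            make_ideal_helix(n, sequence=seq, plddt=85.0, structure_id=pid)
        )
    table, excluded = build_feature_table(
        structures, labels={"P100": 1, "P050": 0, "P110": 0}, voxel=0.8
    )
    assert list(table.index) == ["P100", "P110"]
    assert "P050" in excluded and "length" in excluded["P050"]
    assert table.loc["P100", "label"] == 1
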