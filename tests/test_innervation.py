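"""Contact graphs, poly-innervation ratios, swelling counts and typing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import calyxmorph as cm
from calyxmorph import innervation as inn
from calyxmorph.model import SegmentClass, derive_segment_table


def _toy_volume(gap: int):
    """One 5^3 PN block and a 3^3 partner separated by `gap` voxels."""
    labels = np.zeros((20, 12, 12), np.int32)
    labels[2:7, 4:9, 4:9] = 1
    labels[7 + gap: 10 + gap, 4:7, 4:7] = 1001
    v = cm.AnnotatedVolume(labels, (500.0, 500.0, 500.0))
    t = derive_segment_table(
        v, {1: SegmentClass.PN_SOMA, 1001: SegmentClass.CALYX})
    return v, t


class TestContactGraph:
    def test_touching_calyx_yields_edge_mono(self):
        v, t = _toy_volume(gap=0)
        g = inn.build_contact_graph(v, t)
        row = g.pn_row(1)
        assert row["n_calyces"] == 1 and not row["poly"]
        area = g.edges["contact_area_um2"].iloc[0]
        assert area == pytest.approx(9 * 0.25)   # 3x3 faces of 0.5um pixels

    def test_two_voxel_gap_yields_no_edge(self):
        v, t = _toy_volume(gap=2)
        g = inn.build_contact_graph(v, t)
        assert len(g.edges) == 0
        assert g.pn_row(1)["n_calyces"] == 0

    def test_minimum_contact_suppresses_single_voxel_touch(self):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[2:5, 2:5, 2:5] = 1
        labels[5, 4, 4] = 1001           # one face pair only
        v = cm.AnnotatedVolume(labels, (500.0, 500.0, 500.0))
        t = derive_segment_table(
            v, {1: SegmentClass.PN_SOMA, 1001: SegmentClass.CALYX})
        assert len(inn.build_contact_graph(v, t, min_contact_voxels=5).edges) == 0
        assert len(inn.build_contact_graph(v, t, min_contact_voxels=1).edges) == 1

    def test_generator_counts_recovered_exactly(self, morpho_bundle, morpho_graph):
        """Calyx counts, poly flags and bouton counts match the manifest
        with no tolerance."""
        _, _, _, manifest = morpho_bundle
        for pn in manifest.pns:
            row = morpho_graph.pn_row(pn.pn_id)
            assert row["n_calyces"] == pn.n_calyces
            assert bool(row["poly"]) == (pn.n_calyces >= 2)
            assert row["n_noncalyceal"] == pn.n_boutons


class TestPolyStatistics:
    @pytest.mark.parametrize("k,n,expected", [
        (20, 163, 12), (17, 118, 14), (11, 126, 9), (12, 107, 11),
        (0, 10, 0),
    ])
    def test_published_poly_percentages(self, k, n, expected):
        assert inn.poly_fraction((k, n)) == (k, n, expected)

    def test_empty_subset_errors(self, morpho_graph):
        with pytest.raises(ValueError):
            inn.poly_fraction(morpho_graph, subset=[])

    @pytest.mark.parametrize("lf,hf,p_lf,p_hf", [
        (4, 2, 67, 33),      # 4/6 vs 2/6
        (6, 2, 75, 25),      # 6/8 vs 2/8
    ])
    def test_published_regional_splits(self, lf, hf, p_lf, p_hf):
        regions = {i: "lateral" for i in range(lf)}
        regions.update({100 + i: "medial" for i in range(hf)})
        per_pn = [dict(pn_id=i, poly=True, n_calyces=2, n_noncalyceal=0,
                       calyx_ids=[]) for i in regions]
        import pandas as pd

        g = inn.InnervationGraph(edges=pd.DataFrame(),
                                 per_pn=pd.DataFrame(per_pn),
                                 min_contact_voxels=5)
        split = inn.regional_poly_split(g, regions)
        assert split["LF"] == (lf, lf + hf, p_lf)
        assert split["HF"] == (hf, lf + hf, p_hf)

    def test_all_medial_poly_split(self):
        import pandas as pd

        regions = {1: "medial", 2: "medial"}
        g = inn.InnervationGraph(
            edges=pd.DataFrame(),
            per_pn=pd.DataFrame([dict(pn_id=i, poly=True, n_calyces=2,
                                      n_noncalyceal=0, calyx_ids=[])
                                 for i in regions]),
            min_contact_voxels=5)
        split = inn.regional_poly_split(g, regions)
        assert split["LF"][2] == 0 and split["HF"][2] == 100

    def test_regional_split_recovers_manifest(self, morpho_bundle, morpho_graph):
        _, _, _, manifest = morpho_bundle
        regions = {p.pn_id: p.region for p in manifest.pns}
        split = inn.regional_poly_split(morpho_graph, regions)
        truth_lf = sum(1 for p in manifest.pns
                       if p.n_calyces >= 2 and p.region == "lateral")
        truth_hf = sum(1 for p in manifest.pns
                       if p.n_calyces >= 2 and p.region == "medial")
        assert split["LF"][0] == truth_lf
        assert split["HF"][0] == truth_hf


class TestSwellings:
    def test_smooth_sector_counts_zero(self):
        v, _, m = cm.generate_dataset(
            cm.SimulationConfig.single_pn(0.30, seed=6, voxel_pitch_nm=300.0,
                                          n_swellings=0))
        assert cm.count_swellings(v, m.pns[0].calyces[0].calyx_id) == 0

    def test_ten_lobes_recovered(self):
        v, _, m = cm.generate_dataset(
            cm.SimulationConfig.single_pn(0.45, seed=6, voxel_pitch_nm=300.0,
                                          n_swellings=10))
        assert cm.count_swellings(v, m.pns[0].calyces[0].calyx_id) == 10

    def test_generator_swellings_recovered_exactly(self, morpho_bundle):
        _, volume, _, manifest = morpho_bundle
        for pn in manifest.pns:
            for c in pn.calyces:
                assert cm.count_swellings(volume, c.calyx_id) == c.n_swellings


class TestTyping:
    @pytest.mark.parametrize("n,expected", [
        (0, 1), (7, 1), (8, 2), (14, 2), (15, 3), (16, 3), (40, 3),
    ])
    def test_threshold_mapping(self, n, expected):
        assert inn.classify_calyx_type(n) == expected

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            inn.classify_calyx_type(-1)

    @given(a=st.integers(0, 60), b=st.integers(0, 60))
    @settings(max_examples=60, deadline=None)
    def test_type_is_monotone_step_function(self, a, b):
        if a <= b:
            assert inn.classify_calyx_type(a) <= inn.classify_calyx_type(b)

    def test_type_proportions_table(self):
        types = [1, 1, 2, 3, 3, 3]
        groups = ["young", "young", "young", "old", "old", "old"]
        tab = inn.type_proportions(types, groups)
        assert tab.loc["young", 1] == 2 and tab.loc["old", 3] == 3
        assert not tab.attrs["degenerate"]
        # statistic matches the closed form sum (O-E)^2/E on the same table
        from calyxmorph.stats import chi_square

        obs = tab.values.astype(float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = float(((obs - expected) ** 2 / expected).sum())
        assert chi_square(obs).statistic == pytest.approx(by_hand, rel=1e-12)

    def test_single_class_table_flagged_degenerate(self):
        tab = inn.type_proportions([1, 1, 1], ["a", "a", "a"])
        assert tab.attrs["degenerate"]

    def test_balanced_table_chi_square_zero(self):
        from calyxmorph.stats import chi_square

        tab = inn.type_proportions([1, 2, 3, 1, 2, 3],
                                   ["a", "a", "a", "b", "b", "b"])
        res = chi_square(tab.values)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
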