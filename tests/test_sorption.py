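import numpy as np
import pytest
from dataclasses import replace

import networkx as nx

from conftest import make_system
from maomtools.aggregation import ContactParams, contact_graph, find_clusters
from maomtools.errors import SurfaceError
from maomtools.model import Box, Role
from maomtools.scenes import CounterIon, MineralKind, build_scene, small_scene_spec
from maomtools.sorption import (
    SorptionMode,
    SorptionParams,
    adsorbed_percentage,
    classify_sorption,
    detect_ligand_exchange,
    locate_liquid_surface,
    tag_bridging,
)


def water_slab_frame(z_extent=40.0, n=4000, seed=0, z_offset=0.0, box=None):
    rng = np.random.default_rng(seed)
    box = box or Box(30, 30, 100)
    pos = rng.uniform(0, 1, size=(n, 3)) * [box.lx, box.ly, z_extent]
    pos[:, 2] += z_offset
    mols = [{"positions": [p], "elements": ["O"], "role": Role.WATER,
             "species_id": "WAT"} for p in pos]
    frame, topo = make_system(mols, box)
    return frame, topo


class TestLocateLiquidSurface:
    def test_uniform_slab_edge(self):
        frame, _ = water_slab_frame(z_extent=40.0)
        z = locate_liquid_surface(frame)
        assert z == pytest.approx(40.0, abs=0.5)

    def test_bin_refinement_stability(self):
        frame, _ = water_slab_frame(z_extent=40.0, seed=3)
        coarse = locate_liquid_surface(frame, SorptionParams(density_bin=0.4))
        fine = locate_liquid_surface(frame, SorptionParams(density_bin=0.2))
        assert abs(coarse - fine) < 0.4

    def test_translation_equivariance(self):
        a, _ = water_slab_frame(z_extent=40.0, seed=7)
        b, _ = water_slab_frame(z_extent=40.0, seed=7, z_offset=5.0)
        za = locate_liquid_surface(a)
        zb = locate_liquid_surface(b)
        assert zb - za == pytest.approx(5.0, abs=0.4)

    def test_too_few_waters(self):
        frame, _ = water_slab_frame(n=30)
        with pytest.raises(SurfaceError):
            locate_liquid_surface(frame)


def _slab_row(z=1.0, box=Box(30, 30, 60)):
    xs = np.arange(1.0, box.lx, 2.0)
    pts = [[x, y, z] for x in xs for y in xs]
    return {"positions": pts, "elements": ["Si"] * len(pts), "role": Role.MINERAL,
            "species_id": "MIN"}


def _classify(frame, topo, params=SorptionParams(), z_star=50.0):
    g = contact_graph(frame, topo, ContactParams())
    cl = find_clusters(g)
    return classify_sorption(frame, topo, cl, g, params, z_star=z_star), g, cl


class TestClassifySorption:
    def test_direct_beats_cation_bridge(self):
        # molecule touching the slab AND coordinated to a surface cation
        frame, topo = make_system(
            [
                _slab_row(),
                {"positions": [[5.0, 5.0, 3.5]], "elements": ["O"]},
                {"positions": [[5.0, 7.0, 3.0]], "elements": ["Na"],
                 "role": Role.CATION, "charge": 1, "species_id": "NA"},
            ],
            Box(30, 30, 60),
        )
        labels, _, _ = _classify(frame, topo)
        assert labels[1] == SorptionMode.DIRECT

    def test_cation_bridged(self):
        frame, topo = make_system(
            [
                _slab_row(),
                {"positions": [[5.0, 5.0, 5.5]], "elements": ["O"]},
                {"positions": [[5.0, 5.0, 3.4]], "elements": ["Na"],
                 "role": Role.CATION, "charge": 1, "species_id": "NA"},
            ],
            Box(30, 30, 60),
        )
        labels, _, _ = _classify(frame, topo)
        assert labels[1] == SorptionMode.CATION_BRIDGED

    def test_som_bridged_two_hops_from_anchor(self):
        frame, topo = make_system(
            [
                _slab_row(),
                {"positions": [[5.0, 5.0, 3.5]]},   # DIRECT anchor
                {"positions": [[5.0, 5.0, 6.5]]},   # contact with anchor
                {"positions": [[5.0, 5.0, 9.5]]},   # contact with middle only
            ],
            Box(30, 30, 60),
        )
        labels, _, _ = _classify(frame, topo)
        assert labels[1] == SorptionMode.DIRECT
        assert labels[2] == SorptionMode.SOM_BRIDGED
        assert labels[3] == SorptionMode.SOM_BRIDGED

    def test_vapor_and_interface_and_free(self):
        frame, topo = make_system(
            [
                _slab_row(),
                {"positions": [[5.0, 5.0, 58.0]]},   # above z*+2*shell
                {"positions": [[15.0, 15.0, 51.0]]},  # within shell of z*=50
                {"positions": [[25.0, 25.0, 30.0]]},  # bulk
            ],
            Box(30, 30, 80),
        )
        labels, _, _ = _classify(frame, topo)
        assert labels[1] == SorptionMode.VAPOR
        assert labels[2] == SorptionMode.INTERFACE
        assert labels[3] == SorptionMode.FREE

    def test_exactly_one_label_each(self, small_scene):
        _, frame, topology, _ = small_scene
        g = contact_graph(frame, topology)
        labels = classify_sorption(frame, topology, find_clusters(g), g)
        assert sorted(labels) == topology.som_molecule_ids

    def test_direct_count_monotone_in_cutoff(self, small_scene):
        _, frame, topology, _ = small_scene
        g = contact_graph(frame, topology)
        cl = find_clusters(g)
        prev = -1
        for d in (2.0, 3.5, 5.0, 8.0, 12.0):
            labels = classify_sorption(
                frame, topology, cl, g, SorptionParams(d_direct=d)
            )
            n_direct = sum(1 for v in labels.values() if v == SorptionMode.DIRECT)
            assert n_direct >= prev
            prev = n_direct

    def test_missing_surface_is_error(self):
        frame, topo = make_system(
            [_slab_row(), {"positions": [[5.0, 5.0, 30.0]]}], Box(30, 30, 60)
        )
        g = contact_graph(frame, topo)
        with pytest.raises(SurfaceError):
            classify_sorption(frame, topo, find_clusters(g), g)


class TestTagBridging:
    def _labels_graph(self, labels, edges):
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from(edges)
        return labels, g

    def test_direct_with_unbound_neighbor_tagged(self):
        labels, g = self._labels_graph(
            {0: SorptionMode.DIRECT, 1: SorptionMode.SOM_BRIDGED}, [(0, 1)]
        )
        assert tag_bridging(labels, g) == {0}

    def test_direct_monomer_not_tagged(self):
        labels, g = self._labels_graph({0: SorptionMode.DIRECT, 1: SorptionMode.FREE}, [])
        assert tag_bridging(labels, g) == set()

    def test_direct_pair_not_tagged(self):
        labels, g = self._labels_graph(
            {0: SorptionMode.DIRECT, 1: SorptionMode.CATION_BRIDGED}, [(0, 1)]
        )
        assert tag_bridging(labels, g) == set()

    def test_planted_scene_anchors(self, small_scene):
        _, frame, topology, gt = small_scene
        g = contact_graph(frame, topology)
        labels = classify_sorption(frame, topology, find_clusters(g), g)
        assert tag_bridging(labels, g) == gt.bridging


class TestAdsorbedPercentage:
    def test_all_free(self):
        res = adsorbed_percentage([{i: SorptionMode.FREE for i in range(10)}])
        assert res.adsorbed_pct == 0.0
        assert res.desorbed_pct == 100.0

    def test_half_adsorbed(self):
        labels = {i: (SorptionMode.DIRECT if i < 42 else SorptionMode.FREE) for i in range(84)}
        res = adsorbed_percentage([labels] * 4)
        assert res.adsorbed_pct == pytest.approx(50.0)

    def test_multiframe_hand_count(self):
        f1 = {0: SorptionMode.DIRECT, 1: SorptionMode.FREE, 2: SorptionMode.VAPOR,
              3: SorptionMode.SOM_BRIDGED}
        f2 = {0: SorptionMode.FREE, 1: SorptionMode.FREE, 2: SorptionMode.INTERFACE,
              3: SorptionMode.CATION_BRIDGED}
        res = adsorbed_percentage([f1, f2])
        # frame 1: 2/4 adsorbed; frame 2: 1/4 -> mean 37.5%
        assert res.adsorbed_pct == pytest.approx(37.5)
        assert res.adsorbed_pct + res.desorbed_pct == pytest.approx(100.0, abs=1e-9)
        assert sum(res.mode_pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_interface_switch(self):
        labels = {0: SorptionMode.INTERFACE, 1: SorptionMode.FREE}
        assert adsorbed_percentage([labels]).adsorbed_pct == 0.0
        assert adsorbed_percentage([labels], interface_is_adsorbed=True).adsorbed_pct == 50.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            adsorbed_percentage([])


class TestLigandExchange:
    def _oxide_system(self, som_o_dist, ligand_dist):
        fe = [5.0, 5.0, 5.0]
        frame, topo = make_system(
            [
                {"positions": [fe, [5.0, 5.0, 5.0 + ligand_dist]],
                 "elements": ["Fe", "O"], "role": Role.MINERAL, "species_id": "MIN"},
                {"positions": [[5.0, 5.0 + som_o_dist, 5.0]], "elements": ["O"]},
            ],
            Box(30, 30, 60),
        )
        topo.metal_ligand_pairs = {0: 1}
        return frame, topo

    def test_event_detected(self):
        frame, topo = self._oxide_system(som_o_dist=2.1, ligand_dist=4.0)
        assert detect_ligand_exchange(frame, topo) == [(0, 2)]

    def test_intact_ligand_no_event(self):
        frame, topo = self._oxide_system(som_o_dist=5.0, ligand_dist=2.1)
        assert detect_ligand_exchange(frame, topo) == []

    def test_no_annotation_error(self):
        frame, topo = self._oxide_system(2.1, 4.0)
        topo.metal_ligand_pairs = {}
        with pytest.raises(ValueError):
            detect_ligand_exchange(frame, topo)

    @pytest.mark.parametrize("k", [1, 3])
    def test_planted_events_counted_exactly(self, k):
        spec = replace(
            small_scene_spec(MineralKind.OXIDE_LIKE, CounterIon.NA, seed=21),
            n_ligand_exchange=k,
        )
        frame, topology, gt = build_scene(spec)
        events = detect_ligand_exchange(frame, topology)
        assert len(events) == k
        assert events == sorted(gt.ligand_exchanges)


class TestGroundTruthRecovery:
    @pytest.mark.parametrize("mineral", list(MineralKind))
    @pytest.mark.parametrize("ion", list(CounterIon))
    def test_planted_labels_recovered(self, mineral, ion):
        spec = small_scene_spec(mineral, ion, seed=33)
        frame, topology, gt = build_scene(spec)
        g = contact_graph(frame, topology)
        cl = find_clusters(g)
        labels = classify_sorption(frame, topology, cl, g)
        assert labels == gt.labels
        assert cl.largest_members == gt.largest_cluster
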