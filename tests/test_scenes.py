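import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from maomtools import io as mio
from maomtools.aggregation import contact_graph
from maomtools.errors import PlacementError
from maomtools.model import Role
from maomtools.scenes import (
    CounterIon,
    MineralKind,
    SceneSpec,
    build_mineral_slab,
    build_scene,
    default_composition,
    default_species_library,
    jitter_trajectory,
    preset_spec,
    slab_top_z,
    small_scene_spec,
    temperature_ladder,
)
from maomtools.sorption import SorptionMode

# independent atomic weights for the recomputation oracle
WEIGHTS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


class TestSpeciesLibrary:
    def test_twenty_species(self, library):
        assert len(library) == 20
        assert len({sp.species_id for sp in library}) == 20

    def test_mass_range(self, library):
        masses = [sp.mass for sp in library]
        assert min(masses) >= 70
        assert max(masses) <= 300

    def test_mass_recomputation_oracle(self, library):
        for sp in library:
            expected = (
                sp.c * WEIGHTS["C"] + sp.h * WEIGHTS["H"] + sp.n * WEIGHTS["N"]
                + sp.o * WEIGHTS["O"] + sp.s * WEIGHTS["S"] + sp.p * WEIGHTS["P"]
            )
            assert sp.mass == pytest.approx(expected, abs=0.01)

    def test_exactly_one_peptide(self, library):
        peptides = [sp for sp in library if sp.is_peptide]
        assert len(peptides) == 1
        pep = peptides[0]
        assert pep.n >= 2 and pep.formal_charge == 0 and pep.n_amine_count >= 1

    def test_charges_in_allowed_set(self, library):
        assert all(sp.formal_charge in (-2, -1, 0) for sp in library)
        assert all(sp.c >= 1 for sp in library)

    def test_template_self_avoiding(self, library):
        for sp in library:
            heavy = [i for i, e in enumerate(sp.template_elements) if e != "H"]
            pts = sp.template_coords[heavy]
            if len(pts) > 1:
                assert pdist(pts).min() >= 1.2

    def test_template_element_counts_match_formula(self, library):
        for sp in library:
            els = list(sp.template_elements)
            for symbol, count in sp.element_counts.items():
                assert els.count(symbol) == count

    def test_templates_deterministic(self):
        a = default_species_library()
        b = default_species_library()
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.template_coords, sb.template_coords)


class TestComposition:
    def test_total_84(self, library):
        assert len(default_composition(library)) == 84

    def test_peptide_copies_8(self, library):
        seq = default_composition(library)
        pep = next(sp.species_id for sp in library if sp.is_peptide)
        assert seq.count(pep) == 8

    def test_four_copies_each_non_peptide(self, library):
        seq = default_composition(library)
        for sp in library:
            if not sp.is_peptide:
                assert seq.count(sp.species_id) == 4


class TestMineralSlab:
    def test_atom_count_matches_lattice(self):
        spec = small_scene_spec(MineralKind.SMECTITE_LIKE, CounterIon.NA)
        pos, elements, pairs = build_mineral_slab(spec, slab_charge_sites=0)
        nx = round(spec.lx / 2.6)
        ny = round(spec.ly / 2.6)
        assert len(pos) == nx * ny * 3
        assert pairs == {}

    def test_smectite_charge_sites(self):
        spec = small_scene_spec(MineralKind.SMECTITE_LIKE, CounterIon.NA)
        pos, elements, _ = build_mineral_slab(spec, slab_charge_sites=6)
        assert elements.count("Mg") == 6  # slab charge = -6 by construction

    def test_oxide_is_neutral_with_paired_ligands(self):
        spec = small_scene_spec(MineralKind.OXIDE_LIKE, CounterIon.NA)
        pos, elements, pairs = build_mineral_slab(spec)
        assert "Mg" not in elements
        assert len(pairs) == elements.count("Fe") > 0
        for metal, ligand in pairs.items():
            assert elements[ligand] == "O"
            d = np.linalg.norm(pos[metal] - pos[ligand])
            assert d == pytest.approx(2.0)

    def test_too_small_box(self):
        with pytest.raises(Exception):
            build_mineral_slab(
                SceneSpec(lx=6.0, ly=6.0, lz=50.0, n_free=1), slab_charge_sites=0
            )


class TestBuildScene:
    def test_counts_and_partition(self, small_scene):
        spec, frame, topology, gt = small_scene
        som = topology.som_molecule_ids
        assert len(som) == spec.n_som == 16
        assert sorted(gt.labels) == som
        from collections import Counter

        counts = Counter(gt.labels.values())
        assert counts[SorptionMode.DIRECT] == spec.n_direct
        assert counts[SorptionMode.VAPOR] == spec.n_vapor

    def test_full_composition_scene(self):
        frame, topology, gt = build_scene(preset_spec("na-smectite", seed=0))
        assert len(topology.som_molecule_ids) == 84
        assert len(gt.labels) == 84

    def test_charge_neutrality(self):
        for preset in ("na-smectite", "ca-smectite", "na-oxide", "ca-oxide"):
            _, topology, _ = build_scene(preset_spec(preset, seed=5))
            assert topology.total_charge() == 0

    def test_vapor_molecules_neutral(self, small_scene):
        _, _, topology, gt = small_scene
        for mid, label in gt.labels.items():
            if label == SorptionMode.VAPOR:
                assert topology.species_of(mid).formal_charge == 0

    def test_all_free_scene_has_no_edges(self):
        spec = SceneSpec(
            lx=48.0, ly=48.0, lz=76.0,
            mineral_kind=MineralKind.OXIDE_LIKE,
            n_free=6,
            n_water=0,
            species_sequence=("glucose", "phenol", "glycerol", "vanillin", "naphthol", "indole"),
        )
        frame, topology, _ = build_scene(spec)
        graph = contact_graph(frame, topology)
        assert graph.number_of_edges() == 0

    def test_min_heavy_spacing_across_molecules(self, small_scene):
        spec, frame, _, _ = small_scene
        heavy = frame.is_heavy
        pos = frame.positions[heavy]
        mols = frame.molecule_ids[heavy]
        wrapped = np.column_stack(
            [np.mod(pos[:, 0], spec.lx), np.mod(pos[:, 1], spec.ly), pos[:, 2] + 5.0]
        )
        tree = cKDTree(wrapped, boxsize=[spec.lx, spec.ly, 10 * spec.lz])
        bad = [(i, j) for i, j in tree.query_pairs(1.2) if mols[i] != mols[j]]
        assert bad == []

    def test_deterministic_serialization(self, tmp_path):
        spec = small_scene_spec(MineralKind.OXIDE_LIKE, CounterIon.CA, seed=9)
        for k in (0, 1):
            frame, topology, _ = build_scene(spec)
            mio.write_configuration(frame, topology, tmp_path / f"s{k}.gro")
            mio.write_topology(topology, tmp_path / f"t{k}.json")
        assert (tmp_path / "s0.gro").read_bytes() == (tmp_path / "s1.gro").read_bytes()
        assert (tmp_path / "t0.json").read_bytes() == (tmp_path / "t1.json").read_bytes()

    def test_ground_truth_largest_unique(self, small_scene):
        _, _, _, gt = small_scene
        from collections import Counter

        sizes = Counter(gt.cluster_of.values())
        largest_size = len(gt.largest_cluster)
        assert largest_size == max(sizes.values())
        assert sum(1 for s in sizes.values() if s == largest_size) == 1

    def test_infeasible_spec_raises(self):
        with pytest.raises(PlacementError):
            build_scene(
                SceneSpec(lx=14.0, ly=14.0, lz=76.0, n_direct=40, n_water=0)
            )

    def test_som_bridged_needs_anchor(self):
        with pytest.raises(PlacementError):
            build_scene(SceneSpec(lx=48.0, ly=48.0, lz=76.0, n_som_bridged=2, n_water=0))


class TestJitter:
    def test_sigma_zero_identity(self, small_scene):
        _, frame, _, _ = small_scene
        frames = jitter_trajectory(frame, 3, 0.0, seed=1)
        for f in frames:
            np.testing.assert_array_equal(f.positions, frame.wrapped().positions)

    def test_deterministic(self, small_scene):
        _, frame, _, _ = small_scene
        a = jitter_trajectory(frame, 4, 0.1, seed=7)
        b = jitter_trajectory(frame, 4, 0.1, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.positions, fb.positions)

    def test_sigma_too_large(self, small_scene):
        _, frame, _, _ = small_scene
        with pytest.raises(ValueError):
            jitter_trajectory(frame, 1, 0.2, seed=0, margin=0.5)

    def test_frame_indices(self, small_scene):
        _, frame, _, _ = small_scene
        frames = jitter_trajectory(frame, 3, 0.05, seed=0)
        assert [f.frame_index for f in frames] == [0, 1, 2]


class TestTemperatureLadder:
    def test_paper_ladder_has_8_replicas(self):
        assert len(temperature_ladder(300, 335, 5)) == 8

    def test_single(self):
        assert temperature_ladder(300, 300, 5) == [300]

    def test_three(self):
        assert temperature_ladder(300, 310, 5) == [300, 305, 310]

    def test_non_divisible(self):
        with pytest.raises(ValueError):
            temperature_ladder(300, 312, 5)

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            temperature_ladder(300, 310, 0)
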