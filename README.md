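# maomtools

Structural analysis of mineral-associated organic matter (MAOM) from
molecular configurations: aggregation clustering under periodic boundaries,
sorption-mode classification, polar/apolar solvent-accessible surface area
(SASA), per-layer Voronoi surface coverage, and descriptor–probability
correlation — plus a synthetic-scene generator that plants ground-truth
labels with geometric margins so every stage is testable exactly.

## What's in the box

| Module | Purpose |
| --- | --- |
| `maomtools.model` | Domain types (`Frame`, `Box`, `Topology`, `SpeciesRecord`), minimum-image geometry, system validation |
| `maomtools.io` | GRO / XYZ / PDB coordinate I/O (Å internally, nm at the GRO boundary) and the JSON topology sidecar |
| `maomtools.scenes` | Labeled synthetic scenes: mineral slab (charged smectite-like or neutral oxide-like), a 20-species organic library (~70–300 Da), Na⁺/Ca²⁺ counterions, gridded water, vapor gap, jittered trajectories, temperature ladders |
| `maomtools.aggregation` | Heavy-atom contact graph (periodic KD-tree), optional divalent-cation bridge edges, connected components, largest-cluster probabilities |
| `maomtools.sorption` | Per-molecule mode classification (DIRECT / CATION_BRIDGED / SOM_BRIDGED / FREE / INTERFACE / VAPOR), bridging tags, adsorbed percentages, ligand-exchange detection at annotated metal sites |
| `maomtools.surfaces` | First-N atomic layers above the slab; per-layer area coverage of water/ions/organics by periodic 2D Voronoi tessellation |
| `maomtools.descriptors` | Molecular mass, double-bond equivalents, van Krevelen ratios, Shrake–Rupley SASA split into polar (O/N) and apolar area |
| `maomtools.stats` / `report` | Spearman correlation with ties, segmented sub-200 Da mass fit, replica ensemble averaging, deterministic CSV/JSON reports |

## CLI

```bash
# generate a labeled scene (GRO frames + topology.json + ground_truth.csv)
maomtools generate --preset na-smectite --seed 1 --frames 3 --out scene/

# classify every frame; optional contact-edge dump
maomtools classify --frames-dir scene/ --out labels.csv --graph-out edges.csv

# per-layer Voronoi coverage
maomtools coverage --frames-dir scene/ --layers 4 --out coverage.csv

# species descriptor table (mass, DBE, O/C, H/C, polar/apolar SASA, logP)
maomtools descriptors --out descriptors.csv

# correlate descriptors with cluster/bridging probabilities and write a report
maomtools report --labels labels.csv --descriptors descriptors.csv --out report/

# or the whole thing at once on a bundled preset
maomtools pipeline --preset na-smectite --seed 1 --frames 3 --out report/
```

Presets: `na-smectite`, `ca-smectite`, `na-oxide`, `ca-oxide` (mineral kind ×
counterion), each with the default 84-molecule composition (4 copies of each
of 19 species + 8 copies of the peptide).

## Topology sidecar schema

```jsonc
{
  "species": [
    {"species_id": "glucose", "name": "...", "c": 6, "h": 12, "n": 0,
     "o": 6, "s": 0, "p": 0, "formal_charge": 0, "aromatic_ring_count": 0,
     "carboxylic_acid_count": 0, "n_amine_count": 0, "logp": -3.2,
     "is_peptide": false, "role": "SOM"}
  ],
  "molecules": [
    {"molecule_id": 0, "species_id": "glucose", "atom_ids": [12, 13, 14]}
  ],
  "metal_ligand_pairs": {"117": 118},   // metal-site atom -> ligand-water oxygen
  "radius_overrides": {"12": 1.62}      // per-atom vdW radius (Å)
}
```

## Conventions

- Lengths in Å everywhere; GRO nm values are converted at read/write.
- Orthorhombic boxes only; x and y are always periodic, z optionally.
- z is the surface normal; the mineral slab sits at low z.
- Hydrogens are excluded from contact detection, tessellation, and SASA.
- 0-based atom/molecule ids internally; 1-based only inside GRO/PDB records.
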