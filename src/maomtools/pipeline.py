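"""End-to-end analysis pipeline: frames -> labels -> coverage -> report.

This is the glue the CLI and the demo use; each stage is the corresponding
module's public API, so everything here stays thin and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import ClusterAssignment, ContactParams, contact_graph, find_clusters, largest_cluster_probability
from .descriptors import SasaParams, species_descriptor_table
from .model import Frame, Topology
from .report import write_report
from .scenes import SceneSpec, build_scene, jitter_trajectory, preset_spec, temperature_ladder
from .sorption import (
    SorptionMode,
    SorptionParams,
    adsorbed_percentage,
    classify_sorption,
    tag_bridging,
)
from .stats import ReplicaSummary, correlate_features, ensemble_average, segmented_mass_fit
from .surfaces import assign_layers, layer_coverage

__all__ = [
    "FrameAnalysis",
    "analyze_frame",
    "labels_table",
    "coverage_table",
    "run_replica",
    "run_demo_pipeline",
]


@dataclass
class FrameAnalysis:
    frame: Frame
    clusters: ClusterAssignment
    labels: dict[int, SorptionMode]
    bridging: set[int]
    graph: "object" = None
    coverage: pd.DataFrame | None = None


def analyze_frame(
    frame: Frame,
    topology: Topology,
    contact_params: ContactParams = ContactParams(),
    sorption_params: SorptionParams = SorptionParams(),
    n_layers: int = 4,
    with_coverage: bool = True,
    z_star: float | None = None,
) -> FrameAnalysis:
    graph = contact_graph(frame, topology, contact_params)
    clusters = find_clusters(graph)
    labels = classify_sorption(frame, topology, clusters, graph, sorption_params, z_star=z_star)
    bridging = tag_bridging(labels, graph)
    coverage = None
    if with_coverage:
        layers = assign_layers(frame, topology, n_layers=n_layers)
        rows = []
        for k in sorted(layers.layers):
            cov = layer_coverage(frame, topology, layers.layers[k])
            rows.append(
                {
                    "layer": k,
                    "fraction_water": cov.fraction_water,
                    "fraction_ion": cov.fraction_ion,
                    "fraction_som": cov.fraction_som,
                    "fallback_flag": layers.fallback,
                }
            )
        coverage = pd.DataFrame(rows)
    return FrameAnalysis(frame=frame, clusters=clusters, labels=labels,
                         bridging=bridging, graph=graph, coverage=coverage)


def labels_table(analyses: list[FrameAnalysis], topology: Topology) -> pd.DataFrame:
    """Per-frame per-molecule label CSV rows."""
    rows = []
    for a in analyses:
        for mid in topology.som_molecule_ids:
            rows.append(
                {
                    "frame": a.frame.frame_index,
                    "molecule_id": mid,
                    "species_id": topology.molecules[mid].species_id,
                    "label": a.labels[mid].value,
                    "bridging": mid in a.bridging,
                    "component": a.clusters.component_of[mid],
                    "in_largest": a.clusters.in_largest(mid),
                }
            )
    return pd.DataFrame(rows)


def coverage_table(analyses: list[FrameAnalysis]) -> pd.DataFrame:
    frames = []
    for a in analyses:
        if a.coverage is not None:
            df = a.coverage.copy()
            df.insert(0, "frame", a.frame.frame_index)
            frames.append(df)
    if not frames:
        raise ValueError("no coverage computed for any frame")
    return pd.concat(frames, ignore_index=True)


def _bridging_probability(analyses: list[FrameAnalysis], topology: Topology) -> dict[str, float]:
    hits: dict[str, int] = {}
    copies: dict[str, int] = {}
    for mid in topology.som_molecule_ids:
        sid = topology.molecules[mid].species_id
        copies[sid] = copies.get(sid, 0) + 1
        hits.setdefault(sid, 0)
        for a in analyses:
            if mid in a.bridging:
                hits[sid] += 1
    nf = len(analyses)
    return {sid: hits[sid] / (copies[sid] * nf) for sid in sorted(copies)}


def run_replica(
    spec: SceneSpec,
    temperature: float,
    n_frames: int = 3,
    jitter_sigma: float = 0.1,
    jitter_seed: int = 0,
    with_coverage: bool = True,
) -> tuple[ReplicaSummary, list[FrameAnalysis], Topology]:
    """Build one scene, jitter it into frames, and analyze each frame."""
    frame, topology, _ = build_scene(spec)
    frame.temperature = temperature
    frames = jitter_trajectory(frame, n_frames, jitter_sigma, jitter_seed, margin=spec.margin)
    analyses = [analyze_frame(f, topology, with_coverage=with_coverage) for f in frames]

    cluster_prob = largest_cluster_probability([a.clusters for a in analyses], topology)
    bridging_prob = _bridging_probability(analyses, topology)
    ads = adsorbed_percentage([a.labels for a in analyses])
    coverage = None
    if with_coverage:
        cov = coverage_table(analyses)
        coverage = (
            cov.groupby("layer")[["fraction_water", "fraction_ion", "fraction_som"]]
            .mean()
            .reset_index()
        )
    summary = ReplicaSummary(
        temperature=temperature,
        cluster_probability=cluster_prob,
        bridging_probability=bridging_prob,
        adsorbed_pct=ads.adsorbed_pct,
        desorbed_pct=ads.desorbed_pct,
        mode_pct={m.value: v for m, v in ads.mode_pct.items()},
        coverage=coverage,
    )
    return summary, analyses, topology


def run_demo_pipeline(
    preset: str = "na-smectite",
    seed: int = 0,
    n_frames: int = 3,
    out_dir=None,
    temperatures: tuple[float, ...] | None = None,
    with_coverage: bool = True,
):
    """Generate -> classify -> coverage -> descriptors -> correlate -> report.

    One replica per temperature (same planted scene, independent jitter),
    averaged into an ensemble summary, correlated against the species
    descriptor table, and written to ``out_dir`` when given.
    """
    if temperatures is None:
        temperatures = tuple(temperature_ladder(300.0, 305.0, 5.0))
    replicas = []
    topology = None
    for k, temp in enumerate(temperatures):
        spec = preset_spec(preset, seed=seed)
        summary, _, topology = run_replica(
            spec,
            temperature=temp,
            n_frames=n_frames,
            jitter_seed=seed * 1000 + k,
            with_coverage=with_coverage,
        )
        replicas.append(summary)
    ensemble = ensemble_average(replicas)

    from .scenes import default_species_library

    library = default_species_library()
    table = species_descriptor_table(library, SasaParams())
    table = table.join(ensemble.cluster_probability["mean"].rename("cluster_probability"))
    table = table.join(ensemble.bridging_probability["mean"].rename("bridging_probability"))
    correlations = correlate_features(table)

    masses = table["mass"].to_numpy()
    probs = table["cluster_probability"].to_numpy()
    try:
        slope, intercept = segmented_mass_fit(masses, probs)
        fit = {"slope_per_da": slope, "intercept": intercept}
    except ValueError:
        fit = None

    written = None
    if out_dir is not None:
        written = write_report(
            ensemble,
            correlations,
            out_dir,
            config={
                "preset": preset,
                "seed": seed,
                "n_frames": n_frames,
                "temperatures": list(temperatures),
                "sub_200da_fit": fit,
            },
        )
    return ensemble, correlations, table, written
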