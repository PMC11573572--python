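"""Correlation and ensemble statistics for the descriptor/response tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SchemaError

__all__ = [
    "spearman",
    "correlate_features",
    "segmented_mass_fit",
    "ReplicaSummary",
    "EnsembleSummary",
    "ensemble_average",
]

RESPONSE_COLUMNS = ("cluster_probability", "bridging_probability")


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (the documented undefined-result signal) when either input
    is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = sps.spearmanr(x, y)
    return float(rho)


def correlate_features(
    table: pd.DataFrame,
    descriptor_columns: list[str] | None = None,
    response_columns: tuple[str, ...] = RESPONSE_COLUMNS,
) -> pd.DataFrame:
    """One Spearman coefficient per (descriptor, response), pairwise-deleted.

    Rows with a missing descriptor (e.g. absent logP) are dropped per pair;
    the surviving n is reported. Fewer than 3 complete pairs yields NaN.
    """
    present_responses = [c for c in response_columns if c in table.columns]
    if not present_responses:
        raise SchemaError(f"table has none of the response columns {response_columns}")
    if descriptor_columns is None:
        descriptor_columns = [
            c for c in table.columns
            if c not in response_columns and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for resp in present_responses:
        for desc in descriptor_columns:
            pair = table[[desc, resp]].dropna()
            n = len(pair)
            rho = spearman(pair[desc], pair[resp]) if n >= 3 else float("nan")
            rows.append({"response": resp, "descriptor": desc, "spearman_rho": rho, "n": n})
    return pd.DataFrame(rows)


def segmented_mass_fit(
    masses, probabilities, threshold: float = 200.0
) -> tuple[float, float]:
    """OLS (slope, intercept) of probability vs mass on the sub-threshold subset."""
    masses = np.asarray(masses, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if masses.shape != probabilities.shape:
        raise ValueError("masses and probabilities must have equal length")
    sel = masses < threshold
    if sel.sum() < 2:
        raise ValueError(f"need >= 2 species below {threshold} Da (got {int(sel.sum())})")
    x, y = masses[sel], probabilities[sel]
    a = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(a, y, rcond=None)
    return float(slope), float(intercept)


@dataclass
class ReplicaSummary:
    """Frame-averaged results of one temperature replica."""

    temperature: float
    cluster_probability: dict[str, float]
    bridging_probability: dict[str, float]
    adsorbed_pct: float
    desorbed_pct: float
    mode_pct: dict[str, float] = field(default_factory=dict)
    coverage: pd.DataFrame | None = None  # columns: layer, fraction_water/ion/som


@dataclass
class EnsembleSummary:
    """Unweighted mean over replicas, with across-replica standard deviation."""

    n_replicas: int
    cluster_probability: pd.DataFrame  # index species_id, columns mean/sd
    bridging_probability: pd.DataFrame
    adsorbed_pct: float
    adsorbed_sd: float
    desorbed_pct: float
    mode_pct: pd.DataFrame  # index mode, columns mean/sd
    coverage: pd.DataFrame | None  # index layer, mean/sd per fraction


def _dict_stats(dicts: list[dict], what: str) -> pd.DataFrame:
    keys = sorted(dicts[0])
    for d in dicts[1:]:
        if sorted(d) != keys:
            raise SchemaError(f"replica {what} keys differ across replicas")
    data = np.array([[d[k] for k in keys] for d in dicts], dtype=float)
    return pd.DataFrame(
        {"mean": data.mean(axis=0), "sd": data.std(axis=0, ddof=0)},
        index=pd.Index(keys, name="key"),
    )


def ensemble_average(replicas: list[ReplicaSummary]) -> EnsembleSummary:
    """Pool replicas with equal weight (temperature differences are ignored)."""
    if not replicas:
        raise ValueError("need at least one replica")
    cluster = _dict_stats([r.cluster_probability for r in replicas], "cluster_probability")
    bridging = _dict_stats([r.bridging_probability for r in replicas], "bridging_probability")
    mode = _dict_stats([r.mode_pct for r in replicas], "mode_pct")
    ads = np.array([r.adsorbed_pct for r in replicas])

    coverage = None
    if replicas[0].coverage is not None:
        for r in replicas[1:]:
            if r.coverage is None or list(r.coverage.columns) != list(replicas[0].coverage.columns):
                raise SchemaError("replica coverage schemas differ")
            if list(r.coverage["layer"]) != list(replicas[0].coverage["layer"]):
                raise SchemaError("replica coverage layers differ")
        frames = [r.coverage.set_index("layer") for r in replicas]
        stacked = pd.concat(frames, keys=range(len(frames)))
        mean = stacked.groupby(level=1).mean()
        sd = stacked.groupby(level=1).std(ddof=0)
        coverage = mean.join(sd, lsuffix="_mean", rsuffix="_sd").sort_index()

    return EnsembleSummary(
        n_replicas=len(replicas),
        cluster_probability=cluster,
        bridging_probability=bridging,
        adsorbed_pct=float(ads.mean()),
        adsorbed_sd=float(ads.std(ddof=0)),
        desorbed_pct=float(100.0 - ads.mean()),
        mode_pct=mode,
        coverage=coverage,
    )
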