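"""End-to-end convenience driver: series + rainfall in, ASF table out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityTimeSeries
from .hydrology import (
    APISeries,
    KSchedule,
    asf_api_relation,
    classify_wetness,
    compute_api,
    summarize_api_by_cluster,
)
from .mrpp import pairwise_mrpp
from .psi import ASFEstimate, PSICurve, estimate_asf, psi_by_interval
from .som import (
    ClusterPartition,
    SOMModel,
    cluster_codebook,
    map_size_heuristic,
    smooth_contiguity,
    train_som,
)


@dataclass
class PipelineResult:
    model: SOMModel
    partition: ClusterPartition
    mrpp_table: pd.DataFrame
    psi_curves: list[PSICurve]
    asf_estimates: list[ASFEstimate]
    api: APISeries | None
    api_by_cluster: pd.DataFrame | None
    relation: dict | None

    def asf_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": [e.cluster_id for e in self.asf_estimates],
                "asf": [str(e) for e in self.asf_estimates],
                "censoring": [e.censoring for e in self.asf_estimates],
            }
        )


def run_pipeline(
    series: CommunityTimeSeries,
    precip_dates: pd.DatetimeIndex | None = None,
    precip: np.ndarray | None = None,
    k_schedule: KSchedule | None = None,
    k_range: range = range(2, 11),
    k: int | None = None,
    min_run: int = 5,
    max_interval: int = 30,
    threshold: float = 60.0,
    n_perm: int = 999,
    epochs: int = 30,
    seed: int = 0,
) -> PipelineResult:
    """Run the full sampling-frequency analysis on one year of data.

    Stages: profile conversion, SOM (map size from the 5*sqrt(n) heuristic),
    Ward cut chosen by Davies-Bouldin (or forced with ``k``), contiguity
    smoothing, MRPP validation, per-cluster PSI-decay curves thresholded into
    ASFs, and — when rainfall is supplied — API computation, wetness
    classification and the ASF-API relation.
    """
    profiles = series.profiles()
    grid = map_size_heuristic(series.n_samples)
    model = train_som(profiles, grid, epochs=epochs, seed=seed)
    raw = cluster_codebook(model, series.dates, data=profiles, k_range=k_range, k=k)
    partition = smooth_contiguity(raw, min_run=min_run)
    mrpp_table = pairwise_mrpp(
        profiles, partition.smoothed_labels, n_perm=n_perm, seed=seed
    )
    curves = psi_by_interval(series, partition, max_interval=max_interval)
    estimates = [estimate_asf(c, threshold=threshold) for c in curves]

    api = api_by_cluster = relation = None
    if precip is not None:
        api = compute_api(precip_dates, precip, k=k_schedule)
        api = classify_wetness(api)
        api_by_cluster = summarize_api_by_cluster(api, partition)
        relation = asf_api_relation(estimates, api_by_cluster)
    return PipelineResult(
        model=model,
        partition=partition,
        mrpp_table=mrpp_table,
        psi_curves=curves,
        asf_estimates=estimates,
        api=api,
        api_by_cluster=api_by_cluster,
        relation=relation,
    )
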