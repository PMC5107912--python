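"""Percentage similarity index (PSI), its decay over sampling intervals, and
the appropriate sampling frequency (ASF).

PSI (Renkonen similarity) between two relative-abundance profiles is
100 * sum_k min(P_ik, P_jk): 100 means identical composition, 0 means no
shared taxa.  Within each temporal cluster, PSI is averaged over all date
pairs separated by s calendar days for s = 1..max_interval; the ASF is the
longest interval at which the mean PSI still meets a similarity threshold
(60% by convention).  Clusters whose curve never crosses the threshold are
censored above the horizon ("> 30 days"); clusters already below it at a
one-day interval are censored below ("< 1 day").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityTimeSeries
from .som import ClusterPartition

__all__ = ["PSICurve", "ASFEstimate", "psi", "psi_matrix", "psi_by_interval", "estimate_asf"]


def psi(p: np.ndarray, q: np.ndarray) -> float:
    """Percentage similarity index between two profiles, in [0, 100].

    Profiles must be over the same taxon list (align with zeros beforehand
    if not).  Equals 100 - 50 * L1(p, q) for valid profiles.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(
            f"profiles have different taxon lists ({p.shape} vs {q.shape}); "
            "union-align with zeros first"
        )
    return float(100.0 * np.minimum(p, q).sum())


def psi_matrix(profiles: np.ndarray) -> np.ndarray:
    """All-pairs PSI for a stack of profiles (rows)."""
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        out[i] = 100.0 * np.minimum(profiles[i], profiles).sum(axis=1)
    return out


@dataclass
class PSICurve:
    """Mean PSI per sampling interval within one cluster.

    ``mean_psi`` is NaN at intervals with no evaluable date pair — absent,
    not zero.  ``se_psi`` = sd/sqrt(n_pairs) where n_pairs >= 2.
    """

    cluster_id: int | str
    intervals: np.ndarray
    mean_psi: np.ndarray
    sd_psi: np.ndarray
    se_psi: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval_days": self.intervals,
                "mean_psi": self.mean_psi,
                "sd_psi": self.sd_psi,
                "se_psi": self.se_psi,
                "n_pairs": self.n_pairs,
            }
        )


@dataclass(frozen=True)
class ASFEstimate:
    """Appropriate sampling frequency for one cluster, possibly censored.

    censoring:
        ``none``          — 1 <= asf_days <= horizon;
        ``above_horizon`` — mean PSI never drops below the threshold within
                            the horizon (report "> horizon days");
        ``below_one_day`` — mean PSI at a one-day interval is already below
                            the threshold (report "< 1 day").
    """

    cluster_id: int | str
    asf_days: int | None
    censoring: str
    threshold: float
    horizon: int

    def __str__(self) -> str:
        if self.censoring == "above_horizon":
            return f"> {self.horizon} days"
        if self.censoring == "below_one_day":
            return "< 1 day"
        return f"{self.asf_days} days"


def psi_by_interval(
    series: CommunityTimeSeries,
    partition: ClusterPartition,
    max_interval: int = 30,
) -> list[PSICurve]:
    """PSI decay curves: one per cluster, intervals 1..max_interval days.

    For each cluster and interval s, PSI is collected over every pair of
    sampled dates exactly s *calendar* days apart whose two endpoints both
    carry that cluster's smoothed label — missing dates lengthen gaps rather
    than re-indexing, and pairs spanning two clusters are dropped.
    """
    if max_interval < 1:
        raise ValueError("max_interval must be >= 1")
    labels = partition.labels_for(series.dates)
    profiles = series.profiles()
    day_index = {d: i for i, d in enumerate(series.dates)}
    curves = []
    for cluster in np.unique(labels):
        member = labels == cluster
        if member.sum() < 2:
            warnings.warn(
                f"cluster {cluster!r} has fewer than 2 sampled dates; empty curve",
                stacklevel=2,
            )
        values: list[list[float]] = [[] for _ in range(max_interval)]
        for i in np.flatnonzero(member):
            d = series.dates[i]
            for s in range(1, max_interval + 1):
                j = day_index.get(d + pd.Timedelta(days=s))
                if j is not None and member[j]:
                    values[s - 1].append(psi(profiles[i], profiles[j]))
        mean = np.full(max_interval, np.nan)
        sd = np.full(max_interval, np.nan)
        se = np.full(max_interval, np.nan)
        n = np.zeros(max_interval, dtype=int)
        for s, vals in enumerate(values):
            n[s] = len(vals)
            if vals:
                mean[s] = np.mean(vals)
            if len(vals) >= 2:
                sd[s] = np.std(vals, ddof=1)
                se[s] = sd[s] / np.sqrt(len(vals))
        curves.append(
            PSICurve(
                cluster_id=cluster,
                intervals=np.arange(1, max_interval + 1),
                mean_psi=mean,
                sd_psi=sd,
                se_psi=se,
                n_pairs=n,
            )
        )
    return curves


def estimate_asf(curve: PSICurve, threshold: float = 60.0) -> ASFEstimate:
    """Threshold the mean-PSI curve into an ASF, with censoring.

    First-crossing convention: the ASF is the largest interval s such that
    the mean PSI meets the threshold at *every* evaluable interval up to s
    (intervals with no pairs are skipped in the quantifier).  No crossing by
    the horizon censors above; a sub-threshold mean at one day censors below.
    """
    horizon = int(curve.intervals[-1])
    evaluable = ~np.isnan(curve.mean_psi)
    if not evaluable.any():
        raise ValueError(f"cluster {curve.cluster_id!r}: entirely empty PSI curve")
    if not evaluable[0]:
        raise ValueError(
            f"cluster {curve.cluster_id!r}: no pairs at a one-day interval; "
            "censoring cannot be determined"
        )
    if curve.mean_psi[0] < threshold:
        return ASFEstimate(curve.cluster_id, None, "below_one_day", threshold, horizon)
    asf = 0
    for s, ok in zip(curve.intervals, evaluable):
        if not ok:
            continue
        if curve.mean_psi[s - 1] >= threshold:
            asf = int(s)
        else:
            return ASFEstimate(curve.cluster_id, asf, "none", threshold, horizon)
    return ASFEstimate(curve.cluster_id, None, "above_horizon", threshold, horizon)
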