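"""Antecedent precipitation index (API), wetness classes and the ASF-API relation.

The API is an exponentially decayed running sum of daily rainfall used as a
proxy for catchment wetness:

    API_t = k(month of t) * API_{t-1} + P_{t-1}

with a monthly decay coefficient k (typically 0.85-0.98, low in summer when
evapotranspiration is high).  Days are classed low / moderate / high wetness
against the 25th and 75th percentiles of a long-term API record, and the
per-cluster mean API is related to the cluster's appropriate sampling
frequency (ASF) by a Pearson correlation and straight-line fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .psi import ASFEstimate
from .som import ClusterPartition

__all__ = [
    "KSchedule",
    "APISeries",
    "compute_api",
    "classify_wetness",
    "summarize_api_by_cluster",
    "asf_api_relation",
]

# winter-high / summer-low decay ramp (Jan..Dec): slow moisture loss in
# winter, fast in mid-summer
DEFAULT_K_BY_MONTH = (
    0.98, 0.97, 0.95, 0.93, 0.90, 0.87,
    0.85, 0.86, 0.89, 0.93, 0.96, 0.98,
)


@dataclass(frozen=True)
class KSchedule:
    """Twelve monthly decay coefficients, January..December."""

    k_by_month: tuple = DEFAULT_K_BY_MONTH
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        if len(self.k_by_month) != 12:
            raise ValueError("k schedule needs 12 monthly values")
        if not self.allow_out_of_range:
            for m, k in enumerate(self.k_by_month, start=1):
                if not (0.85 <= k <= 0.98):
                    raise ValueError(
                        f"k for month {m} is {k}, outside [0.85, 0.98] "
                        "(set allow_out_of_range=True to override)"
                    )

    def for_dates(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return np.asarray(self.k_by_month)[dates.month - 1]

    @classmethod
    def constant(cls, k: float) -> "KSchedule":
        return cls(tuple([k] * 12), allow_out_of_range=not (0.85 <= k <= 0.98))


@dataclass
class APISeries:
    """Daily API with optional wetness classification.

    ``burn_in`` flags the first spin-up days, which are excluded from
    quartile fitting because the recursion starts from an arbitrary state.
    """

    dates: pd.DatetimeIndex
    precipitation: np.ndarray
    api: np.ndarray
    burn_in: np.ndarray
    wetness: np.ndarray | None = None
    q1: float | None = None
    q3: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "precip_mm": self.precipitation,
                "api_mm": self.api,
                "burn_in": self.burn_in,
            },
            index=self.dates,
        )
        if self.wetness is not None:
            df["wetness"] = self.wetness
        return df

    def api_at(self, dates: pd.DatetimeIndex) -> np.ndarray:
        s = pd.Series(self.api, index=self.dates)
        return s.loc[dates].to_numpy()


def compute_api(
    dates: pd.DatetimeIndex,
    precip: np.ndarray,
    k: KSchedule | None = None,
    api_init: float = 0.0,
    spinup: int = 30,
    lumped: bool = False,
) -> APISeries:
    """Run the API recursion over a daily-contiguous precipitation series.

    Default form: API_t = k * API_{t-1} + P_{t-1}.  ``lumped=True`` switches
    to the variant API_t = k * (API_{t-1} + P_{t-1}).  The series must be
    daily with no gaps; missing days are an error, never imputed.
    """
    dates = pd.DatetimeIndex(dates)
    precip = np.asarray(precip, dtype=float)
    if len(dates) != len(precip):
        raise ValueError("dates and precipitation must align")
    if np.any(precip < 0):
        raise ValueError("negative precipitation")
    deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    if np.any(deltas != 1):
        gap = dates[int(np.argmax(deltas != 1))]
        raise ValueError(f"precipitation series has a gap after {gap.date()}")
    if k is None:
        k = KSchedule()
    kk = k.for_dates(dates)
    api = np.empty(len(dates))
    api[0] = api_init
    for t in range(1, len(dates)):
        if lumped:
            api[t] = kk[t] * (api[t - 1] + precip[t - 1])
        else:
            api[t] = kk[t] * api[t - 1] + precip[t - 1]
    burn = np.arange(len(dates)) < spinup
    return APISeries(dates=dates, precipitation=precip, api=api, burn_in=burn)


def classify_wetness(
    series: APISeries,
    reference: APISeries | None = None,
    thresholds: tuple[float, float] | None = None,
) -> APISeries:
    """Label each day low / moderate / high wetness by API quartiles.

    Thresholds are the 25th/75th percentiles of the non-burn-in reference
    record (which should span >= 365 days), of the series itself when no
    reference is given, or literal values (q1, q3) — e.g. (15.5, 63.4) mm.
    Boundary convention: low iff api <= q1; high iff api >= q3.
    """
    if thresholds is not None:
        q1, q3 = map(float, thresholds)
    else:
        ref = reference if reference is not None else series
        vals = ref.api[~ref.burn_in]
        if reference is not None and len(vals) < 365:
            raise ValueError(
                f"reference record has only {len(vals)} usable days; need >= 365"
            )
        q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
    wet = np.where(
        series.api <= q1, "low", np.where(series.api >= q3, "high", "moderate")
    )
    return APISeries(
        dates=series.dates,
        precipitation=series.precipitation,
        api=series.api,
        burn_in=series.burn_in,
        wetness=wet,
        q1=float(q1),
        q3=float(q3),
    )


def summarize_api_by_cluster(
    series: APISeries, partition: ClusterPartition
) -> pd.DataFrame:
    """Arithmetic mean of daily API over each cluster's sampled dates."""
    missing = partition.dates.difference(series.dates)
    if len(missing):
        raise ValueError(f"no API coverage for sampled date {missing[0].date()}")
    labels = partition.smoothed_labels
    api = series.api_at(partition.dates)
    df = pd.DataFrame({"cluster": labels, "api": api})
    out = df.groupby("cluster")["api"].agg(["mean", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_api", "count": "n_days"})


def asf_api_relation(
    asf_estimates: list[ASFEstimate],
    api_means: pd.DataFrame,
    censored_below_value: float = 0.5,
) -> dict:
    """Correlate per-cluster ASF with mean API over usable clusters.

    Below-censored ASFs enter as ``censored_below_value`` days (a community
    already dissimilar after one day needs sub-daily sampling); clusters
    censored above the horizon carry no usable number and are excluded from
    the fit but reported.  Returns Pearson r, slope, intercept and the point
    list; with fewer than 3 usable points the relation is reported as
    undetermined rather than raising.
    """
    api_by_cluster = dict(
        zip(api_means["cluster"].tolist(), api_means["mean_api"].tolist())
    )
    points, excluded = [], []
    for est in asf_estimates:
        api = api_by_cluster.get(est.cluster_id)
        if api is None:
            continue
        if est.censoring == "above_horizon":
            excluded.append({"cluster": est.cluster_id, "mean_api": api,
                             "asf": str(est)})
        else:
            asf = censored_below_value if est.censoring == "below_one_day" \
                else float(est.asf_days)
            points.append({"cluster": est.cluster_id, "mean_api": api, "asf": asf})
    result = {"points": points, "excluded_censored_above": excluded}
    if len(points) < 3:
        result.update(
            {"determined": False, "pearson_r": None, "slope": None, "intercept": None}
        )
        return result
    x = np.array([p["mean_api"] for p in points])
    y = np.array([p["asf"] for p in points])
    if np.ptp(x) == 0:
        r = float("nan")
        slope, intercept = 0.0, float(y.mean())
    else:
        r = float(stats.pearsonr(x, y)[0])
        slope, intercept, *_ = stats.linregress(x, y)
    result.update(
        {
            "determined": True,
            "pearson_r": r,
            "slope": float(slope),
            "intercept": float(intercept),
        }
    )
    return result
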