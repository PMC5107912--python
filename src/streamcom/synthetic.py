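"""Precipitation-driven synthetic community time series with known PSI decay.

The generator emulates a one-year daily monitoring record: the year is tiled
by temporal *regimes* (the ground truth the clustering stage should recover),
each with its own base composition, rainfall level and day-to-day species
replacement rate r.  Within a regime the latent profile evolves by a
replacement model — every day a fraction r of total proportion is removed
proportionally and handed to a "novel" taxon from a regime-specific pool
disjoint from the base support — so the expected percentage similarity
between days s apart is 100 * (1 - r)^s in closed form, and the true
appropriate sampling frequency is known analytically
(:func:`true_asf`).  Observed abundances are multinomial draws of a fixed
counting depth (microscope valve counts) from the latent profile, and a
seeded subset of days is removed to mimic sampler outages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityTimeSeries

__all__ = [
    "RegimeSpec",
    "SimulationConfig",
    "SimulationResult",
    "default_regimes",
    "default_config",
    "generate_precipitation",
    "generate_community",
    "true_asf",
]


@dataclass(frozen=True)
class RegimeSpec:
    """One temporal regime: a window with fixed composition dynamics.

    replacement_rate
        Fraction r of total proportion replaced by novel taxa per day,
        0 <= r < 1.  Expected PSI at lag s within the regime is
        100 * (1 - r)^s.
    precipitation_level
        Mean rainfall (mm/day) of the regime's rainfall generator.
    """

    regime_id: int
    start: str
    end: str
    replacement_rate: float
    precipitation_level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.replacement_rate < 1.0):
            raise ValueError("replacement rate must be in [0, 1)")
        if self.precipitation_level < 0:
            raise ValueError("precipitation level must be >= 0")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


def default_regimes() -> list[RegimeSpec]:
    """Five regimes tiling the default study year.

    Spring and late-summer regimes drift slowly (similarity holds past a
    30-day horizon), early summer crosses 60% similarity near 25 days, a wet
    winter regime is so dynamic that consecutive days already differ, and
    late winter/spring crosses near 13 days.  Rainfall levels put the winter
    regime in clearly high-wetness conditions, late winter/spring in
    moderate, and the remaining regimes in low.
    """
    return [
        RegimeSpec(1, "2013-04-25", "2013-05-31", 0.010, 1.6),
        RegimeSpec(2, "2013-06-01", "2013-07-31", 1.0 - 0.6 ** (1 / 25), 1.4),
        RegimeSpec(3, "2013-08-01", "2013-11-30", 0.008, 1.3),
        RegimeSpec(4, "2013-12-01", "2014-01-31", 0.45, 3.2),
        RegimeSpec(5, "2014-02-01", "2014-04-30", 1.0 - 0.6 ** (1 / 13), 1.8),
    ]


@dataclass
class SimulationConfig:
    """Study-scale defaults: ~1 year daily, 113 taxa, 23 missing days,
    300 counted valves per sample."""

    n_taxa: int = 113
    n_missing: int = 23
    counting_depth: int = 300
    regimes: list[RegimeSpec] = field(default_factory=default_regimes)
    seed: int = 0
    base_alpha: float = 0.25
    base_support_frac: float = 0.25
    disjoint_supports: bool = False
    winter_missing: bool = False
    wet_day_prob: float = 0.4
    gamma_shape: float = 0.7

    def __post_init__(self) -> None:
        if self.counting_depth < 50:
            raise ValueError("counting depth must be >= 50")
        regs = sorted(self.regimes, key=lambda r: pd.Timestamp(r.start))
        for a, b in zip(regs, regs[1:]):
            if pd.Timestamp(a.end) + pd.Timedelta(days=1) != pd.Timestamp(b.start):
                raise ValueError(
                    f"regimes {a.regime_id} and {b.regime_id} do not tile the window"
                )
        self.regimes = regs
        if self.n_missing >= len(self.window_dates):
            raise ValueError("n_missing must be smaller than the window length")

    @property
    def window_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.regimes[0].start, self.regimes[-1].end, freq="D")


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


@dataclass
class SimulationResult:
    """A simulated year: observed series, truth, and driving rainfall."""

    series: CommunityTimeSeries
    true_labels: np.ndarray  # regime id per sampled date
    precip_dates: pd.DatetimeIndex
    precip: np.ndarray
    latent: np.ndarray  # latent profile per sampled date (before counting noise)
    config: SimulationConfig

    def true_partition(self):
        from .som import ClusterPartition

        return ClusterPartition(
            dates=self.series.dates,
            raw_labels=self.true_labels,
            smoothed_labels=self.true_labels.copy(),
            n_clusters=len(np.unique(self.true_labels)),
        )


def generate_precipitation(
    config: SimulationConfig,
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Daily rainfall: per regime, Bernoulli wet days times Gamma amounts,
    scaled so the regime mean equals its precipitation_level."""
    rng = np.random.default_rng(config.seed)
    dates = config.window_dates
    out = np.zeros(len(dates))
    pos = 0
    for regime in config.regimes:
        n = len(regime.dates)
        if regime.precipitation_level > 0:
            wet = rng.random(n) < config.wet_day_prob
            scale = regime.precipitation_level / (
                config.wet_day_prob * config.gamma_shape
            )
            amounts = rng.gamma(config.gamma_shape, scale, size=n)
            out[pos : pos + n] = np.where(wet, amounts, 0.0)
        pos += n
    return dates, out


def _regime_supports(config: SimulationConfig, rng: np.random.Generator):
    """Pick per-regime base supports and disjoint novelty pools."""
    n = config.n_taxa
    n_base = max(2, int(round(config.base_support_frac * n)))
    supports = []
    if config.disjoint_supports:
        # well-separated mode: carve the taxon list into disjoint base supports
        perm = rng.permutation(n)
        block = n // len(config.regimes)
        n_base = block
        for i in range(len(config.regimes)):
            supports.append(np.sort(perm[i * block : (i + 1) * block]))
    else:
        for _ in config.regimes:
            supports.append(np.sort(rng.choice(n, size=n_base, replace=False)))
    pools = []
    for sup in supports:
        pool = np.setdiff1d(np.arange(n), sup)
        pools.append(rng.permutation(pool))
    return supports, pools


def generate_community(
    config: SimulationConfig,
    precip: np.ndarray | None = None,
) -> SimulationResult:
    """Simulate the observed community table for the configured year.

    The latent profile restarts from a Dirichlet base profile at every regime
    boundary and drifts by the replacement model within regimes; novelty mass
    cycles through the regime's pool (one taxon per day), so replaced
    proportion almost never returns to a recently vacated taxon before the
    pool wraps around.  Observations are multinomial counts at
    ``counting_depth``; ``n_missing`` days are dropped (uniformly at random,
    or concentrated in December-February with ``winter_missing``).
    """
    rng = np.random.default_rng(config.seed)
    if precip is None:
        _, precip = generate_precipitation(config)
    dates = config.window_dates
    supports, pools = _regime_supports(config, rng)

    latent_rows, labels = [], []
    for regime, sup, pool in zip(config.regimes, supports, pools):
        base = np.zeros(config.n_taxa)
        base[sup] = rng.dirichlet(np.full(len(sup), config.base_alpha))
        p = base.copy()
        r = regime.replacement_rate
        cursor = 0
        for _ in regime.dates:
            latent_rows.append(p.copy())
            labels.append(regime.regime_id)
            if r > 0 and len(pool):
                p = (1.0 - r) * p
                p[pool[cursor % len(pool)]] += r
                cursor += 1
    latent = np.vstack(latent_rows)
    labels = np.asarray(labels)

    # sampler outages
    if config.winter_missing:
        winter = np.flatnonzero(np.isin(dates.month, (12, 1, 2)))
        n_w = min(config.n_missing, len(winter))
        miss = rng.choice(winter, size=n_w, replace=False)
        rest = np.setdiff1d(np.arange(len(dates)), winter)
        extra = rng.choice(rest, size=config.n_missing - n_w, replace=False)
        missing_idx = np.concatenate([miss, extra])
    else:
        missing_idx = rng.choice(len(dates), size=config.n_missing, replace=False)
    sampled = np.setdiff1d(np.arange(len(dates)), missing_idx)

    counts = np.vstack(
        [rng.multinomial(config.counting_depth, latent[i]) for i in sampled]
    )
    series = CommunityTimeSeries(
        dates=dates[sampled],
        taxa=[f"taxon_{i:03d}" for i in range(config.n_taxa)],
        abundance=counts.astype(float),
        window=(dates[0], dates[-1]),
    )
    return SimulationResult(
        series=series,
        true_labels=labels[sampled],
        precip_dates=dates,
        precip=precip,
        latent=latent[sampled],
        config=config,
    )


def true_asf(r: float, threshold: float = 60.0) -> float:
    """Analytic crossing time of the replacement model's PSI decay.

    Solves 100 * (1 - r)^s = threshold for s.  r = 0 never crosses
    (returns +inf, i.e. censored above any horizon).
    """
    if not (0.0 <= r < 1.0):
        raise ValueError("r must be in [0, 1)")
    if not (0.0 < threshold <= 100.0):
        raise ValueError("threshold must be in (0, 100]")
    if threshold == 100.0:
        return 0.0
    if r == 0.0:
        return float("inf")
    return float(np.log(threshold / 100.0) / np.log(1.0 - r))
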