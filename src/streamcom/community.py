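"""Daily community matrices: data model, I/O, profiles and diversity indices.

The central container is :class:`CommunityTimeSeries`, a date-indexed taxon
abundance matrix over a fixed observation window in which some calendar days
may carry no sample (equipment outages, ice).  Downstream stages work on
relative-abundance *profiles*, so the matrix may hold either densities
(cells/L) or raw counts — units cancel on conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTimeSeries",
    "DiversitySummary",
    "CommunityParseError",
    "read_community_table",
    "to_profile",
    "diversity",
]


class CommunityParseError(ValueError):
    """Raised when a community table violates the data model.

    The message names the offending row/column where applicable.
    """


@dataclass(frozen=True)
class DiversitySummary:
    """The four standard diversity indices for one sample.

    richness
        Number of taxa with nonzero abundance.
    shannon
        Shannon–Wiener H' = −Σ p ln p (natural log by default).
    simpson
        Simpson diversity in its complement form 1 − Σ p², in [0, 1).
    evenness
        Pielou's J = H' / ln(richness); defined as 0 when richness = 1.
    """

    richness: int
    shannon: float
    simpson: float
    evenness: float


@dataclass
class CommunityTimeSeries:
    """Date-indexed taxon abundance matrix with an explicit missing-day mask.

    Parameters
    ----------
    dates
        Strictly increasing sampled dates (daily resolution, gaps allowed).
    taxa
        Taxon names, order preserved from the source table.
    abundance
        ``(n_dates, n_taxa)`` array of non-negative densities or counts.
    window
        Inclusive ``(start, end)`` observation window.  Defaults to the span
        of ``dates``.  Calendar days inside the window that carry no row are
        the missing days.
    """

    dates: pd.DatetimeIndex
    taxa: list[str]
    abundance: np.ndarray
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None
    missing_dates: pd.DatetimeIndex = field(init=False)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if len(self.taxa) < 1:
            raise CommunityParseError("at least one taxon is required")
        if len(self.dates) < 2:
            raise CommunityParseError("at least two sampled dates are required")
        if self.abundance.shape != (len(self.dates), len(self.taxa)):
            raise CommunityParseError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.dates)} dates x {len(self.taxa)} taxa"
            )
        if np.any(self.abundance < 0):
            i, j = np.argwhere(self.abundance < 0)[0]
            raise CommunityParseError(
                f"negative abundance at date {self.dates[i].date()}, "
                f"taxon {self.taxa[j]!r}"
            )
        if not np.isfinite(self.abundance).all():
            raise CommunityParseError("non-finite abundance values")
        dup = self.dates[self.dates.duplicated()]
        if len(dup):
            raise CommunityParseError(f"duplicate date {dup[0].date()}")
        if not self.dates.is_monotonic_increasing:
            raise CommunityParseError("dates must be strictly increasing")
        if self.window is None:
            self.window = (self.dates[0], self.dates[-1])
        start, end = self.window
        if self.dates[0] < start or self.dates[-1] > end:
            raise CommunityParseError("sampled dates fall outside the window")
        full = pd.date_range(start, end, freq="D")
        self.missing_dates = full.difference(self.dates)

    @property
    def n_samples(self) -> int:
        return len(self.dates)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def window_days(self) -> int:
        """Inclusive day count of the observation window."""
        start, end = self.window
        return int((end - start).days) + 1

    @property
    def n_missing(self) -> int:
        return len(self.missing_dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.dates, columns=self.taxa)

    def profiles(self) -> np.ndarray:
        """Relative-abundance matrix: every row converted with :func:`to_profile`."""
        return np.vstack([to_profile(row) for row in self.abundance])

    def diversity_table(self) -> pd.DataFrame:
        """One row of diversity indices per sampled date."""
        rows = [diversity(row) for row in self.abundance]
        return pd.DataFrame(
            {
                "richness": [r.richness for r in rows],
                "shannon": [r.shannon for r in rows],
                "simpson": [r.simpson for r in rows],
                "evenness": [r.evenness for r in rows],
            },
            index=self.dates,
        )


def read_community_table(
    path,
    sep: str = ",",
    date_column: str = "date",
    window: tuple[str, str] | None = None,
) -> CommunityTimeSeries:
    """Read a delimited community table into a :class:`CommunityTimeSeries`.

    The file must have a ``date`` column (ISO-8601) and one column per taxon;
    taxon order is preserved as in the header.  ``window`` widens the
    observation window beyond the sampled span so unsampled days at either
    end count as missing.
    """
    df = pd.read_csv(path, sep=sep)
    if date_column not in df.columns:
        raise CommunityParseError(f"missing required column {date_column!r}")
    dates = pd.to_datetime(df[date_column], errors="coerce", format="ISO8601")
    bad = df.index[dates.isna()]
    if len(bad):
        raise CommunityParseError(
            f"unparseable date {df[date_column].iloc[bad[0]]!r} at row {bad[0]}"
        )
    taxa = [c for c in df.columns if c != date_column]
    values = df[taxa].to_numpy(dtype=float)
    win = None
    if window is not None:
        win = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    return CommunityTimeSeries(
        dates=pd.DatetimeIndex(dates), taxa=taxa, abundance=values, window=win
    )


def to_profile(sample: np.ndarray) -> np.ndarray:
    """Convert an abundance vector to proportions summing to one.

    Zero taxa stay zero; an all-zero sample has no defined profile and raises
    ``ValueError``.
    """
    sample = np.asarray(sample, dtype=float)
    if np.any(sample < 0):
        raise ValueError("negative abundances have no profile")
    total = sample.sum()
    if total <= 0:
        raise ValueError("all-zero sample: profile undefined")
    return sample / total


def diversity(sample: np.ndarray, log_base: float | None = None) -> DiversitySummary:
    """Compute richness, Shannon, Simpson and Pielou evenness for one sample.

    ``log_base`` switches the Shannon logarithm (default natural log); the
    evenness denominator uses the same base so J stays in [0, 1].
    """
    p = to_profile(sample)
    p = p[p > 0]
    richness = int(p.size)
    shannon = float(-(p * np.log(p)).sum())
    if log_base is not None:
        shannon /= np.log(log_base)
    simpson = float(1.0 - (p**2).sum())
    if richness == 1:
        evenness = 0.0
    else:
        log_r = np.log(richness)
        if log_base is not None:
            log_r /= np.log(log_base)
        evenness = shannon / log_r
    return DiversitySummary(
        richness=richness, shannon=shannon, simpson=simpson, evenness=evenness
    )
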