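"""Temporal clustering of sampling dates with a batch self-organizing map.

A Kohonen SOM on a hexagonal lattice compresses the daily taxon profiles to a
small codebook; Ward agglomeration of the codebook vectors, scored by the
Davies-Bouldin index on the sample-level assignments, yields temporal
clusters; a contiguity rule then absorbs isolated misassignments into their
enclosing calendar run, replacing by an explicit algorithm what is often done
by eye on the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import davies_bouldin_score

__all__ = [
    "SOMGrid",
    "SOMModel",
    "ClusterPartition",
    "map_size_heuristic",
    "train_som",
    "u_matrix",
    "cluster_codebook",
    "smooth_contiguity",
]


@dataclass(frozen=True)
class SOMGrid:
    """Hexagonal SOM lattice of ``rows`` x ``cols`` units.

    Units are laid out in offset coordinates: odd rows are shifted half a
    step so every interior unit has six equidistant neighbours.
    """

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid needs rows, cols >= 2")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    @property
    def unit_coords(self) -> np.ndarray:
        """(n_units, 2) hex-layout positions, row-major unit order."""
        i, j = np.divmod(np.arange(self.n_units), self.cols)
        x = j + 0.5 * (i % 2)
        y = i * (np.sqrt(3.0) / 2.0)
        return np.column_stack([x, y]).astype(float)

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean (n_units, n_units) lattice adjacency (hex: <= 6 neighbours)."""
        c = self.unit_coords
        d = cdist(c, c)
        adj = (d > 1e-9) & (d < 1.0 + 1e-6)
        return adj


@dataclass
class SOMModel:
    """A trained SOM: codebook plus fit diagnostics.

    quantization_error
        Mean Euclidean distance of samples to their best-matching unit (BMU).
    topographic_error
        Fraction of samples whose two nearest units are not lattice-adjacent.
    qe_history
        Quantization error of the updated codebook at the end of each epoch.
    """

    grid: SOMGrid
    codebook: np.ndarray
    bmu: np.ndarray
    quantization_error: float
    topographic_error: float
    qe_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def map_size_heuristic(n_samples: int, max_aspect: float = 1.3) -> SOMGrid:
    """Choose the lattice size from the 5*sqrt(n) unit-count heuristic.

    Enumerates every rows x cols grid with aspect ratio at most ``max_aspect``
    and returns the one whose unit count is closest to 5*sqrt(n); ties go to
    the squarer grid, then to rows >= cols.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if max_aspect < 1:
        raise ValueError("max_aspect must be >= 1")
    target = 5.0 * np.sqrt(n_samples)
    limit = int(np.ceil(np.sqrt(target * max_aspect))) + 2
    best = None
    for rows in range(2, limit + 1):
        for cols in range(2, limit + 1):
            aspect = max(rows, cols) / min(rows, cols)
            if aspect > max_aspect + 1e-12:
                continue
            units = rows * cols
            key = (abs(units - target), aspect, 0 if rows >= cols else 1, rows)
            if best is None or key < best[0]:
                best = (key, SOMGrid(rows, cols))
    return best[1]


def _pca_init(data: np.ndarray, grid: SOMGrid) -> np.ndarray:
    """Spread the codebook along the first two principal components."""
    mean = data.mean(axis=0)
    centered = data - mean
    # deterministic SVD with a fixed sign convention
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    signs = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    vt = vt * signs[:, None]
    n_comp = min(2, vt.shape[0])
    coords = grid.unit_coords[:, :n_comp].copy()
    span = coords.max(axis=0) - coords.min(axis=0)
    span[span == 0] = 1.0
    # unit positions rescaled to +-2 std along each component
    coords = (coords - coords.mean(axis=0)) / (span / 2.0)
    stds = s[:n_comp] / np.sqrt(max(data.shape[0] - 1, 1))
    return mean + (coords * (stds * 2.0)) @ vt[:n_comp]


def train_som(
    data: np.ndarray,
    grid: SOMGrid,
    epochs: int = 30,
    seed: int = 0,
    init: str = "pca",
    finetune_epochs: int = 5,
) -> SOMModel:
    """Train a batch SOM with a Gaussian neighbourhood on a hex lattice.

    Each epoch assigns every sample to its best-matching unit by Euclidean
    distance, then replaces each codebook vector by the neighbourhood-weighted
    mean of the assigned samples.  The neighbourhood radius shrinks linearly
    from max(rows, cols)/2 to 1; ``finetune_epochs`` further epochs with the
    neighbourhood collapsed to the BMU alone (a Voronoi update) let the
    codebook converge onto the data.  Deterministic for a fixed seed and init.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D (samples x taxa) matrix")
    n, _ = data.shape
    if n < grid.n_units / 2:
        warnings.warn(
            f"only {n} samples for {grid.n_units} units; the map will be sparse",
            stacklevel=2,
        )
    if np.allclose(data, data[0]):
        warnings.warn("degenerate data: all samples identical", stacklevel=2)
    if init == "pca":
        codebook = _pca_init(data, grid)
    elif init == "random":
        rng = np.random.default_rng(seed)
        lo, hi = data.min(axis=0), data.max(axis=0)
        codebook = rng.uniform(lo, hi, size=(grid.n_units, data.shape[1]))
    else:
        raise ValueError(f"unknown init {init!r}")

    coords = grid.unit_coords
    lat2 = cdist(coords, coords) ** 2
    r0 = max(grid.rows, grid.cols) / 2.0
    total = epochs + finetune_epochs
    qe_history = np.empty(total)
    for epoch in range(total):
        d = cdist(data, codebook)
        bmu = d.argmin(axis=1)
        if epoch > 0:  # QE of the previous epoch's updated codebook
            qe_history[epoch - 1] = d[np.arange(n), bmu].mean()
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, data)
        counts = np.bincount(bmu, minlength=grid.n_units).astype(float)
        if epoch < epochs:
            radius = r0 + (1.0 - r0) * (epoch / max(epochs - 1, 1))
            h = np.exp(-lat2 / (2.0 * radius**2))  # unit x unit neighbourhood
            num = h @ sums
            den = h @ counts
        else:  # fine-tuning: neighbourhood collapsed to the BMU (Voronoi means)
            num, den = sums, counts
        ok = den > 1e-300
        codebook[ok] = num[ok] / den[ok, None]

    d = cdist(data, codebook)
    order = np.argsort(d, axis=1)
    bmu = order[:, 0]
    qe = float(d[np.arange(n), bmu].mean())
    qe_history[-1] = qe
    adj = grid.adjacency
    te = float(np.mean(~adj[order[:, 0], order[:, 1]]))
    return SOMModel(
        grid=grid,
        codebook=codebook,
        bmu=bmu,
        quantization_error=qe,
        topographic_error=te,
        qe_history=qe_history,
    )


def u_matrix(model: SOMModel) -> np.ndarray:
    """Unified distance matrix: per-unit mean distance to lattice neighbours.

    Returned as a (rows, cols) array; high values mark cluster boundaries on
    the map.
    """
    adj = model.grid.adjacency
    cb = model.codebook
    out = np.zeros(model.grid.n_units)
    for u in range(model.grid.n_units):
        nbrs = np.flatnonzero(adj[u])
        out[u] = np.linalg.norm(cb[nbrs] - cb[u], axis=1).mean()
    return out.reshape(model.grid.rows, model.grid.cols)


@dataclass
class ClusterPartition:
    """Date -> cluster-label map, before and after contiguity smoothing.

    ``raw_labels`` come straight from the Ward cut (via each sample's BMU);
    ``smoothed_labels`` are the contiguity-smoothed labels; ``exemptions``
    are the dates where the two differ.
    """

    dates: pd.DatetimeIndex
    raw_labels: np.ndarray
    smoothed_labels: np.ndarray
    n_clusters: int
    chosen_k: int | None = None
    db_scores: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.raw_labels = np.asarray(self.raw_labels)
        self.smoothed_labels = np.asarray(self.smoothed_labels)
        if not (len(self.dates) == len(self.raw_labels) == len(self.smoothed_labels)):
            raise ValueError("dates and labels must align")

    @property
    def exemptions(self) -> pd.DatetimeIndex:
        return self.dates[self.raw_labels != self.smoothed_labels]

    def labels_for(self, dates: pd.DatetimeIndex) -> np.ndarray:
        s = pd.Series(self.smoothed_labels, index=self.dates)
        return s.loc[dates].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "raw_label": self.raw_labels,
                "smoothed_label": self.smoothed_labels,
                "exemption": self.raw_labels != self.smoothed_labels,
            },
            index=self.dates,
        )


def _relabel_chronologically(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_codebook(
    model: SOMModel,
    dates: pd.DatetimeIndex,
    data: np.ndarray | None = None,
    k_range: range | None = None,
    k: int | None = None,
) -> ClusterPartition:
    """Ward-cluster the codebook and label samples through their BMUs.

    Candidate cuts over ``k_range`` are scored by the Davies-Bouldin index of
    the *sample-level* assignment (so empty units cannot distort the score);
    the k with the lowest index wins unless ``k`` forces a cut.  ``data`` is
    the sample matrix the SOM was trained on; without it the index falls back
    to each sample's BMU codebook vector.  Returns a raw partition (smoothed
    labels equal raw until :func:`smooth_contiguity`).
    """
    scoring = (
        np.asarray(data, dtype=float) if data is not None else model.codebook[model.bmu]
    )
    if k_range is None:
        k_range = range(2, max(3, model.grid.n_units // 2) + 1)
    link = linkage(model.codebook, method="ward", metric="euclidean")
    db_scores: dict[int, float] = {}
    unit_labels_by_k: dict[int, np.ndarray] = {}
    candidates = [k] if k is not None else list(k_range)
    for kk in candidates:
        unit_labels = fcluster(link, t=kk, criterion="maxclust")
        sample_labels = unit_labels[model.bmu]
        if len(np.unique(sample_labels)) < kk:
            if k is None:
                warnings.warn(
                    f"k={kk}: empty cluster at the sample level, skipped",
                    stacklevel=2,
                )
                continue
        unit_labels_by_k[kk] = unit_labels
        if len(np.unique(sample_labels)) >= 2:
            db_scores[kk] = float(davies_bouldin_score(scoring, sample_labels))
        else:
            db_scores[kk] = np.inf
    if not unit_labels_by_k:
        raise ValueError("no admissible k in k_range")
    chosen = k if k is not None else min(db_scores, key=lambda kk: (db_scores[kk], kk))
    sample_labels = unit_labels_by_k[chosen][model.bmu]
    sample_labels = _relabel_chronologically(sample_labels)
    return ClusterPartition(
        dates=dates,
        raw_labels=sample_labels,
        smoothed_labels=sample_labels.copy(),
        n_clusters=len(np.unique(sample_labels)),
        chosen_k=chosen,
        db_scores=db_scores,
    )


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of identical labels as (start, stop_exclusive, label)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, int(labels[start])))
            start = i
    return runs


def smooth_contiguity(
    partition: ClusterPartition, min_run: int = 5
) -> ClusterPartition:
    """Absorb short label runs into their temporally dominant neighbour.

    Any maximal run shorter than ``min_run`` is reassigned to the label of
    the longer adjacent run (tie: the earlier run), iterating to a fixpoint.
    Among several short runs the one with the longest dominant neighbour is
    merged first, so isolated one-day flips vanish into the season around
    them.  Dates whose label changes are recorded as exemptions.
    """
    labels = np.asarray(partition.smoothed_labels).copy()
    while True:
        runs = _runs(labels)
        if len(runs) <= 1:
            break
        short = [
            (i, r) for i, r in enumerate(runs) if (r[1] - r[0]) < min_run
        ]
        if not short:
            break
        # merge the short run whose dominant neighbour is longest (tie: earliest)
        def neighbour(i: int) -> tuple[int, int, int]:
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i < len(runs) - 1 else None
            if left is None:
                return right
            if right is None:
                return left
            return left if (left[1] - left[0]) >= (right[1] - right[0]) else right

        best_i, _ = max(
            short,
            key=lambda ir: (
                neighbour(ir[0])[1] - neighbour(ir[0])[0],
                -ir[0],
            ),
        )
        nb = neighbour(best_i)
        start, stop, _ = runs[best_i]
        labels[start:stop] = nb[2]
    return ClusterPartition(
        dates=partition.dates,
        raw_labels=partition.raw_labels,
        smoothed_labels=labels,
        n_clusters=len(np.unique(labels)),
        chosen_k=partition.chosen_k,
        db_scores=partition.db_scores,
    )
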