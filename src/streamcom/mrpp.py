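"""Multi-response permutation procedure (MRPP) for among-group composition tests.

MRPP asks whether a-priori groups of multivariate samples (here: temporal
clusters of daily community profiles) are more compositionally homogeneous
than random relabellings would be.  The test statistic is the weighted mean
within-group pairwise distance delta; significance comes from a Monte-Carlo
permutation null, and the chance-corrected within-group agreement
A = 1 - delta_obs / delta_exp summarises effect size (A = 1: all members of a
group identical; A ~ 0: no more structure than chance).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["MRPPResult", "mrpp_test", "pairwise_mrpp"]


@dataclass(frozen=True)
class MRPPResult:
    """Outcome of one MRPP test."""

    A: float
    delta_observed: float
    delta_expected: float
    p_value: float
    n_permutations: int
    seed: int
    groups: tuple


_WEIGHTS = ("size", "size_minus_one", "unweighted")


def _group_weights(sizes: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "size":
        return sizes / sizes.sum()
    if scheme == "size_minus_one":
        return (sizes - 1) / (sizes - 1).sum()
    if scheme == "unweighted":
        return np.full(len(sizes), 1.0 / len(sizes))
    raise ValueError(f"weight scheme must be one of {_WEIGHTS}")


def _delta_for_labels(dmat: np.ndarray, masks: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean within-group distance for one labelling.

    ``masks`` is a (n_groups, n) boolean membership matrix.
    """
    delta = 0.0
    for g, mask in enumerate(masks):
        sub = dmat[np.ix_(mask, mask)]
        n_g = mask.sum()
        delta += weights[g] * sub[np.triu_indices(n_g, k=1)].mean()
    return delta


def mrpp_test(
    data: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    distance: str = "euclidean",
    weight: str = "size",
) -> MRPPResult:
    """Run MRPP on a samples-by-taxa matrix with given group labels.

    delta = sum_i w_i * (mean pairwise distance within group i), with
    w_i = n_i / sum(n_j) by default.  The p-value uses the add-one rule
    p = (1 + #{permuted delta <= observed}) / (1 + n_perm), so the smallest
    attainable p is 1/(1+n_perm) — 0.001 at 999 permutations.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("MRPP needs at least two groups")
    small = groups[counts < 2]
    if len(small):
        raise ValueError(f"group {small[0]!r} has fewer than 2 members")
    dvec = pdist(data, metric=distance)
    if not np.isfinite(dvec).all():
        raise ValueError("non-finite distances in the data")
    dmat = squareform(dvec)
    weights = _group_weights(counts.astype(float), weight)

    masks = np.stack([labels == g for g in groups])
    observed = _delta_for_labels(dmat, masks, weights)

    rng = np.random.default_rng(seed)
    n = len(labels)
    perm_deltas = np.empty(n_perm)
    # group membership as index blocks of a permuted order; group sizes fixed
    bounds = np.concatenate([[0], np.cumsum(counts)])
    for b in range(n_perm):
        order = rng.permutation(n)
        delta = 0.0
        for g in range(len(groups)):
            idx = order[bounds[g] : bounds[g + 1]]
            sub = dmat[np.ix_(idx, idx)]
            delta += weights[g] * sub[np.triu_indices(len(idx), k=1)].mean()
        perm_deltas[b] = delta
    expected = float(perm_deltas.mean())
    p = float((1 + np.sum(perm_deltas <= observed + 1e-12)) / (1 + n_perm))
    A = float(1.0 - observed / expected) if expected > 0 else 0.0
    return MRPPResult(
        A=A,
        delta_observed=float(observed),
        delta_expected=expected,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        groups=tuple(groups.tolist()),
    )


def pairwise_mrpp(
    data: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    distance: str = "euclidean",
    weight: str = "size",
    holm: bool = False,
) -> pd.DataFrame:
    """MRPP for every unordered cluster pair plus the all-groups test.

    Returns a table with one row per pair (rows subset before testing) and a
    final ``overall`` row.  P-values are raw by default; ``holm=True`` adds a
    Holm-adjusted column for the pairwise rows.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    rows = []
    for i, (a, b) in enumerate(combinations(groups, 2)):
        mask = (labels == a) | (labels == b)
        res = mrpp_test(
            data[mask], labels[mask], n_perm=n_perm, seed=seed + i,
            distance=distance, weight=weight,
        )
        rows.append(
            {"group_a": a, "group_b": b, "A": res.A, "p_value": res.p_value}
        )
    overall = mrpp_test(
        data, labels, n_perm=n_perm, seed=seed + len(rows),
        distance=distance, weight=weight,
    )
    table = pd.DataFrame(rows)
    if holm and len(table):
        m = len(table)
        order = np.argsort(table["p_value"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_holm"] = adj
    overall_row = {
        "group_a": "overall", "group_b": "overall",
        "A": overall.A, "p_value": overall.p_value,
    }
    if holm and len(table):
        overall_row["p_holm"] = np.nan
    return pd.concat([table, pd.DataFrame([overall_row])], ignore_index=True)
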