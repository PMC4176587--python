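"""Fuzzy c-means clustering of expression profiles, with the parameter
selection heuristics used for time-course data.

The algorithm minimises the Bezdek objective

    J(U, V) = sum_g sum_j u_gj^m * ||x_g - v_j||^2

by alternating membership and centroid updates,

    u_gj = 1 / sum_k (d_gj / d_gk)^(2/(m-1)),
    v_j  = sum_g u_gj^m x_g / sum_g u_gj^m,

with Euclidean distance on profile vectors.  The fuzziness exponent m
controls sensitivity to noise (m -> 1 approaches hard k-means; large m
flattens memberships toward 1/c) and c is the number of clusters.

Parameter selection:

* ``select_m`` runs the algorithm on a row-randomized version of the data
  over a grid of m; m is chosen as the smallest value at which no
  clusters are detected in the randomized data (detection = more than a
  small fraction of genes reaching membership >= 0.5).
* ``select_c`` runs on the real data over a grid of c; a candidate passes
  if every cluster contains at least one gene with membership >= 0.5 and
  if repeated runs from different starts produce matching centroids
  (greedy best-match Pearson correlation above a stability threshold);
  the largest passing c is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .dataset import ProfileMatrix
from .simulate import permute_matrix

MEMBERSHIP_THRESHOLD = 0.5  # hard-assignment / cluster-detection cut-off
DEFAULT_M = 1.35


@dataclass
class FuzzyClustering:
    """Result of one fuzzy c-means fit."""

    centroids: np.ndarray        # c x T
    memberships: np.ndarray      # G x c, rows sum to 1
    m: float
    c: int
    objective_trace: list[float]
    seed: int
    converged: bool
    n_iter: int
    genes: list[str] | None = None

    def max_membership(self) -> np.ndarray:
        return self.memberships.max(axis=1)

    def hard_assignments(self, threshold: float = MEMBERSHIP_THRESHOLD) -> pd.Series:
        """Argmax cluster per gene where max membership >= threshold, else -1."""
        labels = self.memberships.argmax(axis=1)
        labels = np.where(self.max_membership() >= threshold, labels, -1)
        index = self.genes if self.genes is not None else range(len(labels))
        return pd.Series(labels, index=index, name="cluster")


@dataclass
class ClusterContingency:
    """Cross-tabulation of hard assignments from two clusterings."""

    counts: pd.DataFrame
    unassigned_a: int
    unassigned_b: int


def _extract(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, ProfileMatrix):
        return X.as_array(), X.genes
    if isinstance(X, pd.DataFrame):
        return np.asarray(X, dtype=float), list(X.index)
    return np.asarray(X, dtype=float), None


def memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix from squared distances, u_gj = 1/sum_k (d_gj/d_gk)^(2/(m-1)).

    Evaluated as a softmax of -log(d2)/(m-1) for numerical stability.  A
    gene at exactly zero distance from one or more centroids splits its
    membership equally over those centroids (the exact-hit limit of the
    update formula).
    """
    if m <= 1:
        raise ValueError("fuzziness exponent m must be > 1")
    d2 = np.asarray(d2, dtype=float)
    u = np.zeros_like(d2)
    zero = d2 <= 0.0
    hit = zero.any(axis=1)
    if hit.any():
        z = zero[hit]
        u[hit] = z / z.sum(axis=1, keepdims=True)
    rest = ~hit
    if rest.any():
        logits = -np.log(d2[rest]) / (m - 1.0)
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        u[rest] = w / w.sum(axis=1, keepdims=True)
    return u


def fcm_fit(
    X,
    c: int,
    m: float = DEFAULT_M,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FuzzyClustering:
    """Fit fuzzy c-means from a k-means++ seeded initialization.

    Initial centroids are spread over the data by k-means++ seeding
    (deterministic for a fixed seed) and initial memberships follow from
    the membership formula; duplicate initial centroids trigger a
    re-draw.  Convergence is declared when the maximum absolute
    membership change drops below ``tol``.
    """
    arr, genes = _extract(X)
    G, T = arr.shape
    if c < 2:
        raise ValueError("c must be >= 2")
    if G <= c:
        raise ValueError(f"need more genes ({G}) than clusters ({c})")
    if not np.isfinite(arr).all():
        raise ValueError("input matrix must be finite")

    for attempt in range(10):
        v0, _ = kmeans_plusplus(arr, n_clusters=c, random_state=seed + attempt)
        if cdist(v0, v0)[np.triu_indices(c, 1)].min() > 0:
            break
    else:
        raise RuntimeError(
            "could not initialize distinct centroids (too many duplicate profiles)"
        )
    u = memberships_from_distances(cdist(arr, v0, "sqeuclidean"), m)
    v = v0

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u ** m
        v = (um.T @ arr) / um.sum(axis=0)[:, None]
        d2 = cdist(arr, v, "sqeuclidean")
        u_new = memberships_from_distances(d2, m)
        trace.append(float((u_new ** m * d2).sum()))
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < tol:
            converged = True
            break

    return FuzzyClustering(
        centroids=v, memberships=u, m=m, c=c, objective_trace=trace,
        seed=seed, converged=converged, n_iter=it, genes=genes,
    )


def select_m(
    X,
    m_grid,
    c: int,
    n_seeds: int = 5,
    detection_frac: float = 0.01,
    threshold: float = MEMBERSHIP_THRESHOLD,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Choose m so that no clusters are detected in randomized data.

    For each m in the ascending grid the algorithm is run on row-permuted
    copies of X over ``n_seeds`` seeds; clusters are "detected" when the
    fraction of genes with max membership >= ``threshold`` exceeds
    ``detection_frac``.  Returns the smallest m with no detection at any
    seed, plus the full (m, seed, fraction) diagnostic table.
    """
    m_grid = list(m_grid)
    if any(m <= 1 for m in m_grid) or sorted(m_grid) != m_grid:
        raise ValueError("m_grid must be ascending with every value > 1")
    arr, _ = _extract(X)
    records = []
    chosen = None
    for m in m_grid:
        detected = False
        for s in range(n_seeds):
            Xp = permute_matrix(arr, seed=seed + 1000 * s)
            fit = fcm_fit(Xp, c=c, m=m, seed=seed + 1000 * s + 1)
            frac = float((fit.max_membership() >= threshold).mean())
            records.append({"m": m, "seed": s, "fraction_ge_threshold": frac})
            if frac > detection_frac:
                detected = True
        if not detected and chosen is None:
            chosen = m
    table = pd.DataFrame(records)
    if chosen is None:
        raise ValueError(
            "every m in the grid detects clusters in randomized data; "
            "extend the grid to larger m"
        )
    return chosen, table


def _greedy_match_correlation(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
    """Greedy best-match Pearson correlations between two centroid sets."""
    corr = np.corrcoef(va, vb)[: len(va), len(va):]
    corr = np.nan_to_num(corr, nan=-1.0)  # constant centroid: no usable shape
    matched = []
    rows, cols = set(range(len(va))), set(range(len(vb)))
    while rows and cols:
        best = max(((corr[i, j], i, j) for i in rows for j in cols))
        matched.append(best[0])
        rows.discard(best[1])
        cols.discard(best[2])
    return np.array(matched)


def select_c(
    X,
    c_grid,
    m: float = DEFAULT_M,
    n_repeats: int = 3,
    stability_r: float = 0.9,
    threshold: float = MEMBERSHIP_THRESHOLD,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters on the real data.

    A candidate c passes when (1) in every repeated run, every cluster
    contains at least one gene with membership >= ``threshold``, and
    (2) runs from different random starts are stable: greedily
    best-matched centroid pairs all correlate at >= ``stability_r``.
    The largest passing c is returned with a diagnostic table.
    """
    c_grid = list(c_grid)
    if any(c < 2 for c in c_grid) or sorted(c_grid) != c_grid:
        raise ValueError("c_grid must be ascending with every value >= 2")
    if n_repeats < 2:
        raise ValueError("stability assessment needs n_repeats >= 2")
    records = []
    chosen = None
    for c in c_grid:
        fits = [
            fcm_fit(X, c=c, m=m, seed=seed + 7919 * r) for r in range(n_repeats)
        ]
        occupied = all(
            bool(np.all((f.memberships >= threshold).any(axis=0))) for f in fits
        )
        min_match_r = min(
            float(_greedy_match_correlation(fits[0].centroids, f.centroids).min())
            for f in fits[1:]
        )
        stable = min_match_r >= stability_r
        records.append({
            "c": c, "all_clusters_occupied": occupied,
            "min_matched_centroid_r": min_match_r, "stable": stable,
            "passes": occupied and stable,
        })
        if occupied and stable:
            chosen = c
    table = pd.DataFrame(records)
    if chosen is None:
        raise ValueError(f"no candidate c passed both criteria; diagnostics:\n{table}")
    return chosen, table


def compare_clusterings(
    a: FuzzyClustering,
    b: FuzzyClustering,
    threshold: float = MEMBERSHIP_THRESHOLD,
) -> ClusterContingency:
    """Count genes each cluster of A shares with each cluster of B.

    Genes are hard-assigned to their argmax cluster when the max
    membership reaches ``threshold``; genes below threshold in either
    clustering are reported as unassigned and excluded from the counts.
    """
    if a.genes is None or b.genes is None:
        raise ValueError("both clusterings must carry gene identifiers")
    if set(a.genes) != set(b.genes):
        raise ValueError("gene universes differ between the two clusterings")
    ha = a.hard_assignments(threshold)
    hb = b.hard_assignments(threshold).loc[ha.index]
    counts = pd.DataFrame(
        0, index=[f"A{j}" for j in range(a.c)], columns=[f"B{j}" for j in range(b.c)]
    )
    both = (ha >= 0) & (hb >= 0)
    for i, j in zip(ha[both], hb[both]):
        counts.iloc[i, j] += 1
    return ClusterContingency(
        counts=counts,
        unassigned_a=int((ha < 0).sum()),
        unassigned_b=int((hb < 0).sum()),
    )
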