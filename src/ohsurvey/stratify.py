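"""Risk stratification: Z-scoring, K-means with seeded restarts, elbow
selection, and cluster profiling.

System scores are standardized with the population divisor (n), so the total
sum of squares of an n x p standardized matrix — and hence the within-cluster
sum of squares (WCSS) at k = 1 — is exactly n * p. K-means is Lloyd's
algorithm run from several random initializations drawn from one seeded
stream (default: seed 42, best of 10 restarts by WCSS). The elbow point is
automated as the k with the greatest curvature (maximal second difference of
the WCSS curve), reported alongside the full curve for manual override.
Clusters are renumbered in descending mean total-symptom-burden order, so
cluster 0 is always the highest-burden subgroup.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def standardize(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Column-wise Z-scores with population standard deviation (divisor n)."""
    columns = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    sd = values.std(axis=0, ddof=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [columns[j] if columns else j for j in constant]
        raise ValueError(
            f"constant column(s) cannot be standardized: {names}; drop them "
            f"explicitly before clustering"
        )
    return (values - values.mean(axis=0)) / sd


def _wcss(values: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((values - centers[labels]) ** 2).sum())


def kmeans(
    matrix: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 42,
    restarts: int = 10,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's K-means, best of ``restarts`` seeded random initializations.

    Each restart initializes centers at k distinct observations drawn from a
    single seeded stream and iterates assignment/update sweeps until the
    assignment is unchanged (or ``max_iter`` sweeps). A cluster emptied
    during a sweep is reseeded at the point farthest from its assigned
    center. Returns (labels, centers, wcss) of the restart with minimal WCSS;
    fixed (seed, restarts) is bitwise reproducible.
    """
    values = np.asarray(matrix, dtype=float)
    n = values.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        centers = values[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            d2 = ((values[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            for empty in range(k):
                if not np.any(new_labels == empty):
                    # reseed the empty cluster at the farthest point whose
                    # own cluster keeps at least one member
                    assigned = d2[np.arange(n), new_labels]
                    for farthest in np.argsort(-assigned):
                        donor = new_labels[farthest]
                        if donor != empty and np.sum(new_labels == donor) > 1:
                            centers[empty] = values[farthest]
                            new_labels[farthest] = empty
                            break
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                centers[c] = values[labels == c].mean(axis=0)
        wcss = _wcss(values, labels, centers)
        if best is None or wcss < best[2]:
            best = (labels.copy(), centers.copy(), wcss)
    assert best is not None
    return best


@dataclass
class ElbowResult:
    wcss_curve: dict[int, float]
    selected_k: int
    curvature: dict[int, float]
    weak: bool


def elbow(
    matrix: np.ndarray | pd.DataFrame,
    k_max: int = 8,
    seed: int = 42,
    restarts: int = 10,
    weak_threshold: float = 0.05,
) -> ElbowResult:
    """WCSS curve for k = 1..k_max and the automated elbow point.

    ``selected_k`` maximizes the second difference
    WCSS(k-1) - 2 WCSS(k) + WCSS(k+1); when the maximal curvature is below
    ``weak_threshold`` x WCSS(1) the curve has no clear elbow and a warning
    flags the selection for manual confirmation.
    """
    if k_max < 3:
        raise ValueError("k_max must be at least 3")
    values = np.asarray(matrix, dtype=float)
    curve = {}
    for k in range(1, k_max + 1):
        _, _, wcss = kmeans(values, k, seed=seed, restarts=restarts)
        curve[k] = wcss
    curvature = {
        k: curve[k - 1] - 2 * curve[k] + curve[k + 1]
        for k in range(2, k_max)
    }
    selected = max(curvature, key=lambda k: (curvature[k], -k))
    weak = max(curvature.values()) < weak_threshold * curve[1]
    if weak:
        warnings.warn(
            f"no pronounced elbow: max curvature {max(curvature.values()):.3g} "
            f"below {weak_threshold} x WCSS(1); confirm k={selected} manually",
            stacklevel=2,
        )
    return ElbowResult(wcss_curve=curve, selected_k=selected,
                       curvature=curvature, weak=weak)


@dataclass
class ClusterResult:
    standardized: np.ndarray
    k: int
    labels: np.ndarray
    centers: np.ndarray
    wcss: float
    wcss_curve: dict[int, float] = field(default_factory=dict)
    profiles: pd.DataFrame | None = None


def cluster_profiles(
    labels: np.ndarray,
    system_scores: pd.DataFrame,
    tsb: np.ndarray | pd.Series,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cluster size, share, mean burden, and mean raw system scores.

    Clusters are renumbered in descending mean-TSB order (0 = highest
    burden). Returns the profile table and the relabelled assignment.
    """
    labels = np.asarray(labels)
    tsb = np.asarray(tsb, dtype=float)
    if len(labels) != len(tsb) or len(labels) != len(system_scores):
        raise ValueError("labels, system scores, and burden must align")
    n = len(labels)
    old_ids = np.unique(labels)
    mean_tsb = {c: tsb[labels == c].mean() for c in old_ids}
    order = sorted(old_ids, key=lambda c: (-mean_tsb[c], c))
    remap = {old: new for new, old in enumerate(order)}
    relabelled = np.array([remap[c] for c in labels])
    rows = []
    for new_id, old in enumerate(order):
        mask = labels == old
        row = {
            "cluster": new_id,
            "size": int(mask.sum()),
            "share": mask.sum() / n,
            "share_pct": round(100 * mask.sum() / n, 2),
            "mean_tsb": float(tsb[mask].mean()),
        }
        for system in system_scores.columns:
            row[f"mean_{system}"] = float(system_scores.loc[mask, system].mean())
        rows.append(row)
    return pd.DataFrame(rows), relabelled


def stratify(
    system_scores: pd.DataFrame,
    tsb: np.ndarray | pd.Series,
    k: int | None = None,
    k_max: int = 8,
    seed: int = 42,
    restarts: int = 10,
) -> ClusterResult:
    """Standardize, pick k by the elbow method (unless given), cluster, and
    profile."""
    standardized = standardize(system_scores)
    elbow_result = elbow(standardized, k_max=k_max, seed=seed, restarts=restarts)
    chosen = k if k is not None else elbow_result.selected_k
    labels, centers, wcss = kmeans(standardized, chosen, seed=seed, restarts=restarts)
    profiles, relabelled = cluster_profiles(labels, system_scores, tsb)
    # reorder centers to match the burden-sorted labels
    order = []
    for new_id in range(chosen):
        old = np.unique(labels[relabelled == new_id])
        order.append(int(old[0]))
    return ClusterResult(
        standardized=standardized,
        k=chosen,
        labels=relabelled,
        centers=centers[order],
        wcss=wcss,
        wcss_curve=elbow_result.wcss_curve,
        profiles=profiles,
    )
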