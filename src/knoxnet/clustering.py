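"""K-means clustering of scaled temporal profiles.

k is chosen by the Calinski-Harabasz (CH) index, with the within-cluster
SSE trace reported alongside so the elbow can be checked for convergence
with the CH optimum.  Cluster membership quality is a "cluster score":
by default the Pearson correlation of a probe's scaled profile with its
assigned centroid (genes that closely match the cluster core score near 1);
``method="distance"`` gives 1 - normalized Euclidean distance instead.
Anticorrelated cluster pairs are read off the centroid correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from knoxnet.preprocess import ProfileMatrix

logger = logging.getLogger(__name__)


@dataclass
class KSelectionTrace:
    """SSE and CH index per candidate k, plus the chosen k (CH argmax)."""

    k_values: list[int]
    sse: list[float]
    ch_index: list[float]
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "sse": self.sse, "ch_index": self.ch_index}
        )


@dataclass
class ClusterModel:
    """A fitted k-means partition over a scaled profile matrix.

    ``assignments`` maps probe -> 1-based cluster index; ``scores`` maps
    probe -> similarity to its own centroid in [-1, 1].
    """

    k: int
    probe_ids: list[str]
    labels: np.ndarray  # 1-based, aligned with probe_ids
    centroids: np.ndarray  # k x n_conditions, scaled space
    sse: float
    seed: int
    restarts: int
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def assignments(self) -> dict[str, int]:
        return {p: int(c) for p, c in zip(self.probe_ids, self.labels)}

    def members(self, cluster: int) -> list[str]:
        return [p for p, c in zip(self.probe_ids, self.labels) if c == cluster]

    def cluster_sizes(self) -> dict[int, int]:
        return {
            c: int((self.labels == c).sum()) for c in range(1, self.k + 1)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "cluster": self.labels,
                "score": [self.scores.get(p, np.nan) for p in self.probe_ids],
            }
        )


def fit_kmeans(
    profile: ProfileMatrix,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterModel:
    """Lloyd's k-means with k-means++ init, best of ``restarts`` runs.

    Deterministic given (data, k, seed, restarts).  Cluster labels are
    relabelled to a canonical order (descending size, ties by smallest
    original label) so reruns and restarts are comparable.
    """
    if not profile.scaled:
        raise ValueError("fit_kmeans expects a scaled ProfileMatrix")
    n = len(profile.probe_ids)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} probes")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        algorithm="lloyd",
    ).fit(profile.values)
    labels0 = km.labels_
    # canonical relabel: big clusters first
    sizes = [( -(labels0 == c).sum(), c) for c in range(k)]
    order = [c for _, c in sorted(sizes)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in labels0], dtype=int)
    centroids = km.cluster_centers_[order]
    model = ClusterModel(
        k=k,
        probe_ids=list(profile.probe_ids),
        labels=labels,
        centroids=centroids,
        sse=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )
    model.scores = cluster_scores(model, profile)
    return model


def calinski_harabasz(
    values: np.ndarray, labels: np.ndarray, k: int
) -> float:
    """CH(k) = (B/(k-1)) / (W/(n-k)).

    B is the size-weighted squared distance of centroids to the grand
    centroid; W the within-cluster SSE.  Degenerate cases (k=1, k=n, or
    W=0) return inf when separation is perfect and nan when undefined.
    """
    n = values.shape[0]
    if k <= 1 or k >= n:
        return float("nan")
    grand = values.mean(axis=0)
    b = 0.0
    w = 0.0
    for c in np.unique(labels):
        pts = values[labels == c]
        cen = pts.mean(axis=0)
        b += len(pts) * float(((cen - grand) ** 2).sum())
        w += float(((pts - cen) ** 2).sum())
    if w == 0.0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def select_k(
    profile: ProfileMatrix,
    k_range,
    seed: int = 0,
    restarts: int = 50,
) -> KSelectionTrace:
    """Fit every k in ``k_range``; choose the CH-index argmax.

    The SSE trace is reported for the elbow convergence check but does not
    decide; CH ties break toward the smaller k.
    """
    k_values = sorted(set(int(k) for k in k_range))
    n = len(profile.probe_ids)
    if not k_values or k_values[0] < 2 or k_values[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    sse, ch = [], []
    for k in k_values:
        model = fit_kmeans(profile, k, seed=seed, restarts=restarts)
        sse.append(model.sse)
        ch.append(calinski_harabasz(profile.values, model.labels, k))
    finite = [(-c if np.isfinite(c) else np.inf, k) for c, k in zip(ch, k_values)]
    chosen = min(finite)[1] if finite else k_values[0]
    # inf CH (perfect separation) outranks all finite values
    for c, k in zip(ch, k_values):
        if np.isposinf(c):
            chosen = k
            break
    logger.info("select_k: chose k=%d (CH argmax) over %s", chosen, k_values)
    return KSelectionTrace(
        k_values=k_values, sse=sse, ch_index=ch, chosen_k=chosen
    )


def cluster_scores(
    model: ClusterModel, profile: ProfileMatrix, method: str = "pearson"
) -> dict[str, float]:
    """Score each probe against its own centroid.

    ``pearson``: correlation of the scaled profile with the centroid (the
    default membership filter semantics).  ``distance``: 1 - d/d_max with d
    the Euclidean distance to the centroid and d_max the largest distance
    in the cluster.  A constant centroid leaves the score NaN, which always
    fails a score filter.
    """
    if list(profile.probe_ids) != list(model.probe_ids):
        raise ValueError("model was not fitted on this profile")
    scores: dict[str, float] = {}
    if method == "pearson":
        cen_sd = model.centroids.std(axis=1)
        for p, row, lab in zip(profile.probe_ids, profile.values, model.labels):
            cen = model.centroids[lab - 1]
            if cen_sd[lab - 1] == 0 or row.std() == 0:
                scores[p] = float("nan")
            else:
                scores[p] = float(np.corrcoef(row, cen)[0, 1])
    elif method == "distance":
        dist = np.array(
            [
                float(np.linalg.norm(row - model.centroids[lab - 1]))
                for row, lab in zip(profile.values, model.labels)
            ]
        )
        for c in range(1, model.k + 1):
            mask = model.labels == c
            dmax = dist[mask].max()
            for p, d, m in zip(profile.probe_ids, dist, mask):
                if m:
                    scores[p] = 1.0 if dmax == 0 else float(1.0 - d / dmax)
    else:
        raise ValueError(f"unknown score method {method!r}")
    return scores


def filter_by_score(
    model: ClusterModel, cluster: int, score_min: float
) -> list[str]:
    """Members of ``cluster`` whose score meets ``score_min`` (NaN fails)."""
    return [
        p
        for p in model.members(cluster)
        if np.isfinite(model.scores.get(p, np.nan))
        and model.scores[p] >= score_min
    ]


def centroid_correlation(model: ClusterModel) -> np.ndarray:
    """k x k Pearson correlation matrix between centroid profiles."""
    cc = np.corrcoef(model.centroids)
    cc = np.atleast_2d(cc)
    np.fill_diagonal(cc, 1.0)
    return cc


def anticorrelated_pairs(
    cc: np.ndarray, threshold: float = -0.8
) -> list[tuple[int, int, float]]:
    """All unordered cluster pairs with centroid r <= threshold.

    Returned as (cluster_i, cluster_j, r) with 1-based indices, sorted by
    ascending r (most anticorrelated first).
    """
    if not (-1.0 <= threshold < 0.0):
        raise ValueError("threshold must lie in [-1, 0)")
    k = cc.shape[0]
    pairs = [
        (i + 1, j + 1, float(cc[i, j]))
        for i in range(k)
        for j in range(i + 1, k)
        if cc[i, j] <= threshold
    ]
    return sorted(pairs, key=lambda t: (t[2], t[0], t[1]))
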