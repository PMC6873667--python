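"""Clustering: species-count estimation, phase-1 k-medoids on long
contigs, and phase-2 L1 assignment of short contigs.

Long contigs carry the reliable k-mer statistics, so they are clustered
first (k-medoids with L2 distance on F = [Q H]); every cluster is then
summarized by a centroid in a simpler feature space (coverage profile
plus composition), and each short contig joins the centroid nearest in
L1 distance.  L1 is deliberately used in phase 2: it amplifies the
per-coordinate differences of the noisy short-contig profiles better
than the Euclidean distance.

The number of species C, when not supplied, is estimated by running
k-means for increasing k until fewer than 80% of the k clusters come out
non-empty; the last k that kept at least that occupancy is returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import cdist, squareform, pdist

from .config import RunConfig
from .errors import DimensionMismatchError, EmptyClusteringError
from .io import BinningResult, ContigSet, CoverageMatrix
from . import features as feat

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """State of a finished k-medoids run."""

    labels: np.ndarray
    medoid_indices: np.ndarray
    total_cost: float
    iterations: int
    cost_history: list[float]


@dataclass
class ClusterCentroids:
    """Per-cluster mean rows in the phase-2 feature space, with the
    original (pre-drop) cluster id kept for bookkeeping."""

    matrix: np.ndarray
    source_labels: np.ndarray  # original phase-1 cluster id of each row


def l1_distance(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionMismatchError(f"shape mismatch {u.shape} vs {v.shape}")
    return float(np.abs(u - v).sum())


def l2_distance(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionMismatchError(f"shape mismatch {u.shape} vs {v.shape}")
    return float(np.sqrt(((u - v) ** 2).sum()))


def _assign_to_medoids(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # medoids sorted ascending; argmin takes the first minimum, i.e. ties
    # resolve to the lowest medoid index
    return np.argmin(D[:, medoids], axis=1)


def kmedoids(
    X: np.ndarray,
    C: int,
    seed: int,
    max_iter: int = 100,
    restarts: int = 10,
) -> ClusterAssignment:
    """k-medoids (Voronoi iteration) with L2 distances.

    Each restart initializes with C distinct random rows as medoids, then
    alternates (a) assigning every row to its nearest medoid and (b)
    replacing each cluster's medoid by the member that minimizes the
    summed distance to the other members, until the medoid set is stable.
    The restart with the lowest total cost (sum of distances of rows to
    their medoid) wins.  Fully reproducible given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise EmptyClusteringError("empty input to kmedoids")
    N = X.shape[0]
    if not (1 <= C <= N):
        raise EmptyClusteringError(f"C={C} out of range for N={N}")
    D = squareform(pdist(X, metric="euclidean"))
    rng = np.random.default_rng(seed)
    best: Optional[ClusterAssignment] = None
    for _ in range(restarts):
        medoids = np.sort(rng.choice(N, size=C, replace=False))
        history: list[float] = []
        labels = _assign_to_medoids(D, medoids)
        for it in range(1, max_iter + 1):
            history.append(float(D[np.arange(N), medoids[labels]].sum()))
            new_medoids = medoids.copy()
            for ci in range(C):
                members = np.flatnonzero(labels == ci)
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[ci] = members[int(np.argmin(within))]
            new_medoids = np.sort(new_medoids)
            new_labels = _assign_to_medoids(D, new_medoids)
            if np.array_equal(new_medoids, medoids):
                break
            medoids, labels = new_medoids, new_labels
        total = float(D[np.arange(N), medoids[labels]].sum())
        history.append(total)
        cand = ClusterAssignment(
            labels=labels,
            medoid_indices=medoids,
            total_cost=total,
            iterations=len(history) - 1,
            cost_history=history,
        )
        if best is None or cand.total_cost < best.total_cost:
            best = cand
    assert best is not None
    return best


def _principal_plane(features: np.ndarray, n_components: int) -> np.ndarray:
    X = features - features.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    return X @ Vt[: min(n_components, X.shape[1])].T


def estimate_num_clusters(
    features: np.ndarray,
    k_min: int = 2,
    step: int = 1,
    occupancy: float = 0.8,
    seed: int = 0,
    restarts: int = 5,
    n_components: int = 2,
    iters: int = 100,
) -> int:
    """Estimate the number of species by iterated k-means with the
    cluster-occupancy stopping rule.

    k-means is run for k = k_min, k_min + step, ...; once fewer than
    ``occupancy * k`` of the k clusters come out non-empty the search
    stops and the previous candidate is returned (k_min if the very
    first iteration already trips).

    The occupancy signal only exists when clusters are allowed to die:
    a center that never captures points must stay where it is, which
    rules out k-means variants that relocate empty clusters.  Each run
    therefore uses Lloyd iteration (scipy's ``kmeans2``, which leaves
    empty clusters in place) started from centers drawn off the data —
    a diagonal Gaussian fitted to the feature cloud — so that a center
    survives only if the data claims it.  Two noise controls make the
    rule usable in practice: the features are projected onto their
    leading ``n_components`` principal directions (in the full,
    ~140-dimensional feature space every random center is roughly
    equidistant from everything and occupancy becomes uninformative),
    and per candidate k the median non-empty count over ``restarts``
    seeded restarts is used rather than a single run.  Deterministic
    given ``seed``.
    """
    features = np.asarray(features, dtype=float)
    N = features.shape[0]
    if N < k_min:
        raise EmptyClusteringError(f"need at least k_min={k_min} rows")
    P = _principal_plane(features, n_components)
    rng = np.random.default_rng(seed)
    mean = P.mean(axis=0)
    sd = P.std(axis=0)
    prev = k_min
    for k in range(k_min, N + 1, step):
        nonempty = []
        for _ in range(restarts):
            init = rng.normal(mean, sd, size=(k, P.shape[1]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, labels = kmeans2(P, init, minit="matrix", missing="warn", iter=iters)
            nonempty.append(np.unique(labels).size)
        med = float(np.median(nonempty))
        logger.debug("estimator k=%d -> median %.1f non-empty clusters", k, med)
        if med < occupancy * k:
            return k_min if k == k_min else prev
        prev = k
    warnings.warn(
        f"occupancy rule never tripped; returning the cap N={N}", RuntimeWarning
    )
    return prev


def compute_centroids(
    labels: np.ndarray, phase2_features_long: np.ndarray
) -> tuple[ClusterCentroids, np.ndarray]:
    """Mean phase-2 feature row of every non-empty cluster.

    Empty clusters are dropped and labels renumbered densely; returns the
    centroids plus the renumbered long-contig labels.
    """
    labels = np.asarray(labels)
    X = np.asarray(phase2_features_long, dtype=float)
    if labels.shape[0] != X.shape[0]:
        raise DimensionMismatchError("labels and feature rows differ in length")
    present = np.unique(labels)
    if present.size == 0:
        raise EmptyClusteringError("no non-empty clusters")
    rows = np.stack([X[labels == ci].mean(axis=0) for ci in present])
    remap = {int(ci): i for i, ci in enumerate(present)}
    new_labels = np.array([remap[int(l)] for l in labels])
    return ClusterCentroids(matrix=rows, source_labels=present), new_labels


def assign_short_contigs(
    short_features: np.ndarray,
    centroids: ClusterCentroids,
    metric: str = "l1",
) -> np.ndarray:
    """Label each short contig with its nearest centroid (ties break to
    the lowest cluster index)."""
    X = np.atleast_2d(np.asarray(short_features, dtype=float))
    if X.shape[0] == 0:
        return np.array([], dtype=int)
    if X.shape[1] != centroids.matrix.shape[1]:
        raise DimensionMismatchError(
            f"feature dimension {X.shape[1]} != centroid dimension "
            f"{centroids.matrix.shape[1]}"
        )
    scipy_metric = {"l1": "cityblock", "l2": "euclidean"}[metric]
    D = cdist(X, centroids.matrix, metric=scipy_metric)
    return np.argmin(D, axis=1)


def run_metacon(
    contigs: ContigSet,
    coverage: CoverageMatrix,
    config: Optional[RunConfig] = None,
) -> tuple[BinningResult, dict]:
    """Run the full two-phase binning pipeline.

    Steps: count canonical k-mers; add pseudo-counts; normalize coverage
    into Q; estimate C unless given; split contigs into long and short;
    standardize the long contigs' composition and assemble F = [Q H];
    cluster long contigs with k-medoids; build phase-2 centroids; assign
    short contigs by L1.  Returns the binning over all contigs plus a run
    report with every parameter needed to reproduce the run.
    """
    cfg = config or RunConfig()
    if coverage.contig_ids != contigs.ids:
        raise DimensionMismatchError("coverage rows are not aligned to the contig set")

    Z = feat.count_canonical_kmers(contigs, k=cfg.k)
    Zp, Yp = feat.add_pseudocounts(Z, coverage)
    Q = feat.normalize_coverage(Yp)

    if cfg.clusters is not None:
        C = int(cfg.clusters)
        c_source = "user-supplied"
    else:
        std_all = feat.standardize_composition(
            Z, contigs, mode=cfg.probability_mode, smooth=cfg.smooth,
            column_mode=cfg.column_mode,
        )
        F_all = feat.assemble_features(Q, std_all.normalized)
        C = estimate_num_clusters(
            F_all.values, occupancy=cfg.occupancy, seed=cfg.seed
        )
        c_source = "estimated"
    logger.info("number of bins C=%d (%s)", C, c_source)

    if cfg.two_phase:
        long_idx, short_idx = feat.split_by_length(
            contigs,
            threshold_bp=cfg.length_threshold_bp,
            mode=cfg.split_mode,
            short_fraction=cfg.short_fraction or 0.20,
        )
    else:
        long_idx = np.arange(contigs.N)
        short_idx = np.array([], dtype=int)

    long_contigs = contigs.subset(long_idx)
    Z_long = feat.CompositionMatrix(
        counts=Z.counts[long_idx], k=Z.k, kmer_index=Z.kmer_index
    )
    std_long = feat.standardize_composition(
        Z_long, long_contigs, mode=cfg.probability_mode, smooth=cfg.smooth,
        column_mode=cfg.column_mode,
    )
    F_long = feat.assemble_features(Q[long_idx], std_long.normalized)

    assignment = kmedoids(
        F_long.values, C, seed=cfg.seed, max_iter=cfg.max_iter, restarts=cfg.restarts
    )

    if cfg.phase2_composition == "relative":
        comp_phase2 = feat.relative_composition(Zp)
    else:
        comp_phase2 = Zp.counts.astype(float)
    phase2_space = np.hstack([Q, comp_phase2])

    centroids, long_labels = compute_centroids(
        assignment.labels, phase2_space[long_idx]
    )
    short_labels = assign_short_contigs(
        phase2_space[short_idx], centroids, metric=cfg.phase2_distance
    )

    all_labels = np.empty(contigs.N, dtype=int)
    all_labels[long_idx] = long_labels
    if short_idx.size:
        all_labels[short_idx] = short_labels
    num_bins = int(centroids.matrix.shape[0])

    result = BinningResult(
        contig_ids=list(contigs.ids),
        bin_labels=[int(l) for l in all_labels],
        num_bins=num_bins,
    )
    report = {
        "config": cfg.to_dict(),
        "clusters_used": C,
        "clusters_source": c_source,
        "num_bins": num_bins,
        "n_contigs": contigs.N,
        "n_long": int(long_idx.size),
        "n_short": int(short_idx.size),
        "kmedoids_total_cost": assignment.total_cost,
        "kmedoids_iterations": assignment.iterations,
    }
    return result, report
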