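"""Binning quality: precision/recall over the cluster x species
contingency matrix, per-bin metrics, and threshold filtering.

With A_ij the number of contigs from species j placed in cluster i,

    precision = sum_i max_j A_ij / sum_ij A_ij     (cluster purity)
    recall    = sum_j max_i A_ij / sum_ij A_ij     (species completeness)

Both are fractions of the total evaluated contig count, so a binning is
only perfect (1.0 on both) when every cluster is pure and every species
is gathered in a single cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptyClusteringError
from .io import BinningResult


@dataclass
class ContingencyMatrix:
    """C x n counts of contigs from species j (columns) in cluster i (rows)."""

    A: np.ndarray
    cluster_ids: list
    species_ids: list
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int64)
        if self.A.ndim != 2:
            raise ValueError("contingency matrix must be 2-D")
        if np.any(self.A < 0):
            raise ValueError("negative contingency count")

    @property
    def total(self) -> int:
        return int(self.A.sum())


@dataclass
class BinMetrics:
    """Per-bin purity and completeness against the bin's majority species."""

    cluster_id: object
    precision: float
    recall: float
    majority_species: object
    size: int


def contingency(pred: BinningResult, truth: Mapping[str, object]) -> ContingencyMatrix:
    """Cross-tabulate predicted bins against true species labels.

    Contigs absent from the truth map (e.g. ambiguous annotations) are
    excluded; their count is kept in ``n_excluded``.  Rows and columns
    are ordered by sorted cluster / species id, so the layout is
    deterministic.
    """
    pairs = [
        (bin_id, truth[cid])
        for cid, bin_id in zip(pred.contig_ids, pred.bin_labels)
        if cid in truth
    ]
    n_excluded = len(pred.contig_ids) - len(pairs)
    if not pairs:
        raise EmptyClusteringError("no contigs shared between prediction and truth")
    cluster_ids = sorted({p[0] for p in pairs})
    species_ids = sorted({p[1] for p in pairs})
    ci = {c: i for i, c in enumerate(cluster_ids)}
    sj = {s: j for j, s in enumerate(species_ids)}
    A = np.zeros((len(cluster_ids), len(species_ids)), dtype=np.int64)
    for b, s in pairs:
        A[ci[b], sj[s]] += 1
    return ContingencyMatrix(
        A=A, cluster_ids=cluster_ids, species_ids=species_ids, n_excluded=n_excluded
    )


def precision(A: ContingencyMatrix) -> float:
    """Fraction of contigs belonging to their cluster's majority species."""
    if A.total == 0:
        raise EmptyClusteringError("empty contingency matrix")
    return float(A.A.max(axis=1).sum() / A.total)


def recall(A: ContingencyMatrix) -> float:
    """Fraction of contigs sitting in their species' dominant cluster."""
    if A.total == 0:
        raise EmptyClusteringError("empty contingency matrix")
    return float(A.A.max(axis=0).sum() / A.total)


def per_bin_metrics(A: ContingencyMatrix) -> list[BinMetrics]:
    """Per-bin precision and recall.

    A bin's precision is the fraction of its contigs that belong to its
    majority species j* (ties to the lowest species index); its recall is
    the fraction of all contigs of j* that the bin holds.  Empty bins are
    dropped.
    """
    out: list[BinMetrics] = []
    col_totals = A.A.sum(axis=0)
    for i, cid in enumerate(A.cluster_ids):
        row = A.A[i]
        size = int(row.sum())
        if size == 0:
            continue
        j_star = int(np.argmax(row))  # argmax takes the first maximum
        out.append(
            BinMetrics(
                cluster_id=cid,
                precision=float(row[j_star] / size),
                recall=float(row[j_star] / col_totals[j_star]),
                majority_species=A.species_ids[j_star],
                size=size,
            )
        )
    return out


DEFAULT_BUCKETS = (0.95, 0.90, 0.80)


def filter_bins(
    metrics: Sequence[BinMetrics],
    metric: str = "precision",
    threshold: float = 0.8,
    bucket_edges: Sequence[float] = DEFAULT_BUCKETS,
) -> tuple[list[BinMetrics], list[int]]:
    """Drop bins whose chosen metric falls below ``threshold`` and
    histogram the survivors' complementary metric.

    With the default edges (0.95, 0.90, 0.80) the histogram counts bins
    with the complementary metric >= 95%, in [90%, 95%), in [80%, 90%),
    and below 80%.
    """
    if metric not in ("precision", "recall"):
        raise ValueError("metric must be 'precision' or 'recall'")
    other = "recall" if metric == "precision" else "precision"
    survivors = [m for m in metrics if getattr(m, metric) >= threshold]
    edges = sorted(bucket_edges, reverse=True)
    counts = [0] * (len(edges) + 1)
    for m in survivors:
        value = getattr(m, other)
        for b, edge in enumerate(edges):
            if value >= edge:
                counts[b] += 1
                break
        else:
            counts[-1] += 1
    return survivors, counts
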