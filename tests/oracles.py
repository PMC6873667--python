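"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity, not speed, and deliberately
avoids the code paths under test.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def canonical_classes(k: int) -> list[str]:
    reps = {min(("".join(p)), revcomp("".join(p)))
            for p in itertools.product("ACGT", repeat=k)}
    return sorted(reps)


def count_kmers_bruteforce(seq: str, k: int) -> dict[str, int]:
    """Slide every window, skip windows containing N, pool w with rc(w)."""
    counts = {rep: 0 for rep in canonical_classes(k)}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(b not in "ACGT" for b in w):
            continue
        counts[min(w, revcomp(w))] += 1
    return counts


def precision_bruteforce(A: np.ndarray) -> float:
    total = A.sum()
    s = 0
    for i in range(A.shape[0]):
        best = 0
        for j in range(A.shape[1]):
            if A[i, j] > best:
                best = A[i, j]
        s += best
    return s / total


def recall_bruteforce(A: np.ndarray) -> float:
    total = A.sum()
    s = 0
    for j in range(A.shape[1]):
        best = 0
        for i in range(A.shape[0]):
            if A[i, j] > best:
                best = A[i, j]
        s += best
    return s / total


def best_two_partition_cost(points: np.ndarray) -> float:
    """Exhaustive optimum over all 2-cluster partitions of the points,
    with each cluster represented by its best medoid (a member point
    minimizing the summed distance to the cluster)."""
    n = len(points)
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))

    def cluster_cost(members: list[int]) -> float:
        return min(sum(D[m, x] for x in members) for m in members)

    best = np.inf
    for mask in range(1, 2 ** (n - 1)):
        left = [i for i in range(n) if (mask >> i) & 1]
        right = [i for i in range(n) if not (mask >> i) & 1]
        if not left or not right:
            continue
        best = min(best, cluster_cost(left) + cluster_cost(right))
    return best


def assign_by_min_l1(rows: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    labels = []
    for r in rows:
        dists = [np.abs(r - c).sum() for c in centroids]
        best = 0
        for j, d in enumerate(dists):
            if d < dists[best]:
                best = j
        labels.append(best)
    return np.array(labels)
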