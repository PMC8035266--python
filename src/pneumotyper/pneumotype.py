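"""Community state discovery: k-medoids (PAM) with silhouette-based k.

Samples are partitioned around medoids on a precomputed dissimilarity
matrix (default Bray-Curtis on relative abundances).  The number of
clusters is chosen by maximizing the average silhouette width (ASW)
over a configurable k range, which on the study design yields four
states: one diverse "balanced" community, two single-taxon-dominated
communities, and a microbiota-depleted one.

The PAM implementation is the classic BUILD (greedy cost-minimizing
seeding) + SWAP (first-improvement descent) algorithm, made fully
deterministic by lexicographic tie-breaking, so a clustering is a pure
function of the dissimilarity matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountTable, ValidationError
from .diversity import DissimilarityMatrix


@dataclass
class ClusterSolution:
    k: int
    medoids: list[str]
    labels: pd.Series  # sample_id -> cluster index (0..k-1)
    silhouettes: pd.Series
    asw: float
    total_cost: float
    asw_trace: dict[int, float] = field(default_factory=dict)
    weak_structure: bool = False

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _assign(D: np.ndarray, medoid_idx: np.ndarray) -> tuple[np.ndarray, float]:
    cols = D[:, medoid_idx]
    nearest = cols.argmin(axis=1)
    return nearest, float(cols.min(axis=1).sum())


EXACT_SEARCH_LIMIT = 10_000  # max medoid subsets enumerated exactly


def pam_cluster(
    dm: DissimilarityMatrix, k: int, seed: int = 0, method: str = "auto"
) -> ClusterSolution:
    """Partition around medoids for a fixed k.

    Small instances (at most ``EXACT_SEARCH_LIMIT`` candidate medoid
    subsets) are solved exactly by enumeration, so tiny problems are
    provably optimal.  Larger instances use the classic heuristic:
    BUILD seeds medoids greedily by total-cost reduction, then SWAP
    applies the most cost-reducing (medoid, candidate) swap per pass
    (steepest descent, lexicographic tie-break) to a local optimum —
    the same strategy as the canonical PAM implementations.  ``seed``
    is accepted for interface uniformity; both paths are deterministic.
    """
    D = dm.D
    n = D.shape[0]
    if not 2 <= k < n:
        raise ValidationError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    if method not in ("auto", "exact", "build_swap"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and _comb(n, k) <= EXACT_SEARCH_LIMIT):
        best_cost, best_med = np.inf, None
        for cand in itertools.combinations(range(n), k):
            cost = D[:, cand].min(axis=1).sum()
            if cost < best_cost - 1e-15:
                best_cost, best_med = cost, cand
        med = np.array(best_med)
        return _finalize(dm, med)

    # BUILD
    medoids = [int(D.sum(axis=1).argmin())]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        best_gain, best_c = -np.inf, -1
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(current - D[:, c], 0.0).sum()
            if gain > best_gain + 1e-15:
                best_gain, best_c = gain, c
        medoids.append(best_c)
    medoids = sorted(medoids)

    # SWAP: steepest descent — apply the most cost-reducing
    # (medoid, candidate) swap each pass; ties broken by lexicographic
    # (medoid index, candidate index) order for determinism.
    med = np.array(medoids)
    while True:
        cols = D[:, med]
        order = cols.argsort(axis=1)
        d1 = cols[np.arange(n), order[:, 0]]
        d2 = cols[np.arange(n), order[:, 1]]
        nearest = order[:, 0]
        best_delta, best_swap = -1e-12, None
        for mi in range(len(med)):
            is_m = nearest == mi
            for h in range(n):
                if h in med:
                    continue
                dh = D[:, h]
                delta = np.where(
                    is_m,
                    np.minimum(dh, d2) - d1,
                    np.minimum(dh - d1, 0.0),
                ).sum()
                if delta < best_delta:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        med[best_swap[0]] = best_swap[1]
        med = np.sort(med)

    return _finalize(dm, med)


def _comb(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _finalize(dm: DissimilarityMatrix, med: np.ndarray) -> ClusterSolution:
    labels_idx, cost = _assign(dm.D, med)
    # clusters indexed by medoid order for determinism
    labels = pd.Series(labels_idx, index=dm.sample_ids, name="cluster")
    sil = silhouette_width(dm, labels)
    return ClusterSolution(
        k=len(med),
        medoids=[dm.sample_ids[m] for m in med],
        labels=labels,
        silhouettes=sil,
        asw=float(sil.mean()),
        total_cost=cost,
    )


def silhouette_width(dm: DissimilarityMatrix, labels: pd.Series) -> pd.Series:
    """Per-sample silhouette s(i) = (b - a) / max(a, b).

    a(i) is the mean distance to the sample's own cluster (excluding
    itself), b(i) the smallest mean distance to another cluster.
    Members of singleton clusters score 0 by convention.
    """
    lab = np.asarray(labels)
    D = dm.D
    n = len(lab)
    clusters = np.unique(lab)
    if len(clusters) < 2:
        raise ValidationError("silhouette needs at least two clusters")
    masks = {c: lab == c for c in clusters}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    s = np.zeros(n)
    for i in range(n):
        ci = lab[i]
        if sizes[ci] == 1:
            s[i] = 0.0
            continue
        a = D[i, masks[ci]].sum() / (sizes[ci] - 1)
        b = min(
            D[i, masks[c]].mean() for c in clusters if c != ci
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return pd.Series(s, index=labels.index, name="silhouette")


def select_k_and_assign(
    dm: DissimilarityMatrix,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    weak_asw_threshold: float = 0.3,
) -> ClusterSolution:
    """Run PAM across a k range and keep the max-ASW solution (ties -> smaller k).

    Solutions whose best ASW falls below ``weak_asw_threshold`` are
    flagged ``weak_structure`` — the partition is returned but should
    not be over-interpreted.
    """
    n = len(dm.sample_ids)
    kmin, kmax = k_range
    kmax = min(kmax, n - 1)
    if kmin > kmax:
        raise ValidationError(f"empty k range ({k_range}) for n={n}")
    trace: dict[int, float] = {}
    best: ClusterSolution | None = None
    for k in range(kmin, kmax + 1):
        sol = pam_cluster(dm, k, seed=seed)
        trace[k] = sol.asw
        if best is None or sol.asw > best.asw + 1e-12:
            best = sol
    assert best is not None
    best.asw_trace = trace
    best.weak_structure = best.asw < weak_asw_threshold
    return best


def aggregate_to_phylum(table: CountTable) -> CountTable:
    """Sum OTU counts into phylum-level bins (for phylum-level clustering)."""
    groups: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        phylum = table.taxonomy.get(otu, {}).get("phylum") or "unclassified"
        groups.setdefault(phylum, []).append(otu)
    data = {
        ph: table.counts[cols].sum(axis=1) for ph, cols in sorted(groups.items())
    }
    frame = pd.DataFrame(data, index=table.counts.index)
    tax = {ph: {"kingdom": "Bacteria", "phylum": ph} for ph in frame.columns}
    return CountTable(frame, tax)


__all__ = [
    "ClusterSolution",
    "aggregate_to_phylum",
    "pam_cluster",
    "select_k_and_assign",
    "silhouette_width",
]
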