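"""PAM partitioning on negated similarity and Fisher-exact cluster labels."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohort import CasePhenotype
from .ontology import Ontology
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterPartition",
    "ClusterSummary",
    "pam_partition",
    "pam_on_dissimilarity",
    "characterize_cluster",
    "cluster_variant_enrichment",
    "silhouette_scan",
]

LABEL_P_THRESHOLD = 1e-3


@dataclass
class ClusterPartition:
    k: int
    medoids: list[str]
    assignment: dict[str, int]
    total_cost: float

    def members(self, cluster: int) -> set[str]:
        return {c for c, g in self.assignment.items() if g == cluster}

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("case_id\tcluster\n")
            for case in sorted(self.assignment):
                fh.write(f"{case}\t{self.assignment[case]}\n")


def _assign(d: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    """Nearest-medoid assignment (ties to the lowest cluster index)."""
    sub = d[:, medoids]  # n x k
    labels = sub.argmin(axis=1)  # argmin takes the first of tied minima
    cost = float(sub[np.arange(d.shape[0]), labels].sum())
    return labels, cost


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    totals = d.sum(axis=1)
    medoids = [int(totals.argmin())]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        # gain of adding candidate c: sum over points of max(current - d[:, c], 0)
        gains = np.maximum(current[None, :] - d.T, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    n = d.shape[0]
    medoids = sorted(medoids)
    _, cost = _assign(d, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)  # (delta, medoid position, candidate)
        med_set = set(medoids)
        for pos, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                trial = medoids[:pos] + [h] + medoids[pos + 1 :]
                _, trial_cost = _assign(d, trial)
                delta = trial_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, pos, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            medoids = sorted(medoids)
            _, cost = _assign(d, medoids)
            improved = True
    return medoids, cost


def pam_on_dissimilarity(
    d: np.ndarray, k: int, seed: int = 0, n_restarts: int = 0
) -> tuple[list[int], np.ndarray, float]:
    """Classic BUILD+SWAP PAM on an arbitrary square dissimilarity matrix.

    Converged: no single medoid/non-medoid swap lowers the total cost.
    BUILD is deterministic; ``seed`` only drives optional random restarts.
    Returns (medoid indices, labels, total cost).
    """
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    best_medoids, best_cost = _pam_swap(d, _pam_build(d, k))
    if n_restarts:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            init = sorted(rng.choice(n, size=k, replace=False).tolist())
            medoids, cost = _pam_swap(d, init)
            if cost < best_cost - 1e-12:
                best_medoids, best_cost = medoids, cost
    labels, cost = _assign(d, best_medoids)
    return best_medoids, labels, cost


def pam_partition(
    simmat: SimilarityMatrix, k: int, seed: int = 0, n_restarts: int = 0
) -> ClusterPartition:
    """Partition cases by PAM on the negated similarity matrix.

    The dissimilarity between cases a and b is ``-sim(Da, Db)``.
    """
    n = len(simmat.case_ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    d = -simmat.values
    medoids, labels, cost = pam_on_dissimilarity(d, k, seed=seed, n_restarts=n_restarts)
    return ClusterPartition(
        k=k,
        medoids=[simmat.case_ids[m] for m in medoids],
        assignment={c: int(labels[i]) for i, c in enumerate(simmat.case_ids)},
        total_cost=cost,
    )


@dataclass
class ClusterSummary:
    cluster: int
    labels: list[tuple[str, float]]  # up to 3 (term, P), ascending P
    all_tested: dict[str, tuple[tuple[int, int, int, int], float]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "cluster": self.cluster,
                "labels": [{"term": t, "p": p} for t, p in self.labels],
                "tested": {
                    t: {"table": list(tab), "p": p}
                    for t, (tab, p) in sorted(self.all_tested.items())
                },
            },
            indent=2,
        )


def characterize_cluster(
    partition: ClusterPartition,
    cluster: int,
    cases: Sequence[CasePhenotype],
    onto: Ontology,
) -> ClusterSummary:
    """Label a cluster by its most discriminating ontology nodes.

    Every node present in at least one case's ancestor-propagated term set
    is tested with a two-sided Fisher exact test on the 2x2 table
    (inside/outside cluster) x (has/has-not node).  The first label is the
    globally smallest P; up to two further labels need P below 1e-3 and
    must not be ancestrally related to any earlier label (within a lineage
    only the most significant node is kept).
    """
    inside_ids = partition.members(cluster)
    if not inside_ids:
        raise ValueError(f"cluster {cluster} is empty")
    by_id = {c.case_id: c for c in cases}
    cohort_ids = [c.case_id for c in cases if c.case_id in partition.assignment]
    outside_ids = [c for c in cohort_ids if c not in inside_ids]
    if not outside_ids:
        raise ValueError("cluster covers the whole cohort; no outside group to compare")

    propagated = {
        cid: frozenset().union(*(onto.ancestors_of(t) for t in by_id[cid].terms))
        for cid in cohort_ids
    }
    nodes = sorted(set().union(*propagated.values()))

    tested: dict[str, tuple[tuple[int, int, int, int], float]] = {}
    for node in nodes:
        a = sum(node in propagated[c] for c in inside_ids)
        b = len(inside_ids) - a
        c_ = sum(node in propagated[c] for c in outside_ids)
        d = len(outside_ids) - c_
        _, p = stats.fisher_exact([[a, b], [c_, d]], alternative="two-sided")
        tested[node] = ((a, b, c_, d), float(p))

    ranked = sorted(tested.items(), key=lambda kv: (kv[1][1], kv[0]))
    labels: list[tuple[str, float]] = []
    for node, (_, p) in ranked:
        if labels and p >= LABEL_P_THRESHOLD:
            break
        related = any(
            node in onto.ancestors_of(prev) or prev in onto.ancestors_of(node)
            for prev, _ in labels
        )
        if related:
            continue
        labels.append((node, p))
        if len(labels) == 3:
            break
    return ClusterSummary(cluster=cluster, labels=labels, all_tested=tested)


def cluster_variant_enrichment(
    partition: ClusterPartition, cluster: int, carriers: Iterable[str]
) -> tuple[tuple[int, int, int, int], float]:
    """Fisher exact test for carrier enrichment inside a cluster.

    Returns the 2x2 table (inside-carrier, inside-non, outside-carrier,
    outside-non) and the two-sided P value.
    """
    carriers = set(carriers)
    cohort = set(partition.assignment)
    unknown = carriers - cohort
    if unknown:
        raise ValueError(f"carriers not in partition: {sorted(unknown)}")
    inside = partition.members(cluster)
    a = len(carriers & inside)
    b = len(inside) - a
    c = len(carriers - inside)
    d = len(cohort) - len(inside) - c
    if not carriers:
        logger.warning("empty carrier set: enrichment P = 1")
        return ((a, b, c, d), 1.0)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ((a, b, c, d), float(p))


def silhouette_scan(
    simmat: SimilarityMatrix, k_values: Iterable[int], seed: int = 0
) -> dict[int, float]:
    """Mean silhouette width of PAM partitions over a range of k.

    A convenience for choosing k; makes no claim about any particular
    published choice.  Works directly on the (possibly negative) negated
    similarity, since the silhouette formula only uses mean within/between
    dissimilarities.
    """
    d = -simmat.values
    n = d.shape[0]
    out: dict[int, float] = {}
    for k in k_values:
        _, labels, _ = pam_on_dissimilarity(d, k, seed=seed)
        widths = []
        for i in range(n):
            same = labels == labels[i]
            same[i] = False
            if not same.any():
                widths.append(0.0)
                continue
            a = d[i, same].mean()
            b = min(
                d[i, labels == g].mean() for g in set(labels) if g != labels[i]
            )
            denom = max(abs(a), abs(b))
            widths.append(0.0 if denom == 0 else (b - a) / denom)
        out[k] = float(np.mean(widths))
    return out
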