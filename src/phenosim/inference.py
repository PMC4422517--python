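"""Monte-Carlo group-similarity tests, Fisher's method, class association.

The one-tail Monte-Carlo P value for a case group Z asks whether the mean
rank distance among Z is smaller than expected for a random group of the
same size: P = #{W : dist(W) <= dist(Z)} / |W|, where the W are random
size-|Z| subsets of the eligible (index) cases.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import CasePhenotype
from .similarity import SimilarityMatrix, group_distance, rank_distance_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "monte_carlo_group_p",
    "fishers_method",
    "class_association_chisq",
    "ClassAssociationResult",
]

DEFAULT_N_SUBSETS = 250_000


@dataclass(frozen=True)
class GroupTestResult:
    group: frozenset[str]
    observed_distance: float
    p_value: float
    n_subsets: int
    seed: int
    n_below: int  # subsets with dist(W) <= dist(Z)

    @property
    def p_smoothed(self) -> float:
        """(k+1)/(n+1) add-one estimate, never exactly zero."""
        return (self.n_below + 1) / (self.n_subsets + 1)


def monte_carlo_group_p(
    group: Iterable[str],
    simmat: SimilarityMatrix,
    eligible: Sequence[str] | None = None,
    n_subsets: int = DEFAULT_N_SUBSETS,
    seed: int = 0,
    dist_matrix: np.ndarray | None = None,
) -> GroupTestResult:
    """One-tail Monte-Carlo P for the phenotypic closeness of a case group.

    Random subsets of size ``|group|`` are drawn (each without replacement
    within a subset, independently across subsets) from ``eligible``, which
    defaults to every case in the similarity matrix and should normally be
    the index cases.  The group itself may contain non-eligible cases
    (pedigree members).  Deterministic given ``seed``.
    """
    ids = sorted(set(group))
    if len(ids) < 2:
        raise ValueError("group test requires at least 2 cases")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if eligible is None:
        eligible = list(simmat.case_ids)
    elig_idx = np.array([simmat.index_of(c) for c in eligible])
    k = len(ids)
    if k > len(elig_idx):
        raise ValueError(
            f"group size {k} exceeds the {len(elig_idx)} eligible cases"
        )
    if dist_matrix is None:
        dist_matrix = rank_distance_matrix(simmat)
    observed = group_distance(ids, simmat, dist_matrix=dist_matrix)

    rng = np.random.default_rng(seed)
    pair_rows, pair_cols = zip(*itertools.combinations(range(k), 2))
    pair_rows, pair_cols = np.array(pair_rows), np.array(pair_cols)

    n_below = 0
    chunk = 20_000
    done = 0
    while done < n_subsets:
        m = min(chunk, n_subsets - done)
        # argpartition of uniform noise = m subsets of size k w/o replacement
        noise = rng.random((m, len(elig_idx)))
        subsets = elig_idx[np.argpartition(noise, k - 1, axis=1)[:, :k]]
        dists = dist_matrix[subsets[:, pair_rows], subsets[:, pair_cols]].mean(axis=1)
        n_below += int(np.count_nonzero(dists <= observed))
        done += m

    p = n_below / n_subsets
    return GroupTestResult(
        group=frozenset(ids),
        observed_distance=observed,
        p_value=p,
        n_subsets=n_subsets,
        seed=seed,
        n_below=n_below,
    )


def fishers_method(p_values: Sequence[float]) -> float:
    """Combine independent P values: X2 = -2 sum(ln p) ~ chi-squared(2k).

    A zero input P yields combined P 0 with a warning (below numerical
    resolution).
    """
    ps = list(p_values)
    if not ps:
        raise ValueError("fishers_method requires at least one P value")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"P value out of range: {p}")
    if any(p == 0.0 for p in ps):
        logger.warning("zero P value in Fisher's method: combined P reported as 0")
        return 0.0
    x2 = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(x2, df=2 * len(ps)))


@dataclass(frozen=True)
class ClassAssociationResult:
    stratum: str
    chi2: float
    p_value: float
    p_adjusted: float
    dof: int
    dropped_terms: tuple[str, ...]


def class_association_chisq(
    cases: Sequence[CasePhenotype],
    feature_terms: Sequence[str],
    strata: Mapping[str, str],
    onto,
    n_comparisons: int | None = None,
) -> list[ClassAssociationResult]:
    """Chi-squared comparison of feature-term distributions per stratum.

    For each stratum, counts how many cases carry each feature term (in the
    ancestor-propagated sense) inside the stratum versus in all other cases,
    and tests the two count vectors for homogeneity with a Pearson
    chi-squared test (no continuity correction, matching the plain
    contingency formula).  Terms whose expected count is zero in either
    margin are dropped with a warning.  Bonferroni adjustment multiplies
    raw P by ``n_comparisons`` (default: number of strata), capped at 1.
    """
    if not feature_terms:
        raise ValueError("feature_terms must be non-empty")
    labels = sorted(set(strata.values()))
    if n_comparisons is None:
        n_comparisons = len(labels)

    def has_term(case: CasePhenotype, term: str) -> bool:
        return any(term in onto.ancestors_of(t) for t in case.terms)

    results: list[ClassAssociationResult] = []
    for label in labels:
        inside = [c for c in cases if strata.get(c.case_id) == label]
        outside = [c for c in cases if strata.get(c.case_id) != label]
        if not inside:
            raise ValueError(f"stratum {label!r} has no cases")
        rows_in, rows_out, dropped = [], [], []
        for term in feature_terms:
            a = sum(has_term(c, term) for c in inside)
            b = sum(has_term(c, term) for c in outside)
            if a + b == 0:
                dropped.append(term)
                logger.warning(
                    "term %s dropped for stratum %s: zero expected count", term, label
                )
                continue
            rows_in.append(a)
            rows_out.append(b)
        table = np.array([rows_in, rows_out], dtype=float)
        # drop all-zero columns are handled above; guard degenerate margins
        if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
            results.append(
                ClassAssociationResult(label, 0.0, 1.0, 1.0, 0, tuple(dropped))
            )
            continue
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        results.append(
            ClassAssociationResult(
                stratum=label,
                chi2=float(chi2),
                p_value=float(p),
                p_adjusted=min(1.0, float(p) * n_comparisons),
                dof=int(dof),
                dropped_terms=tuple(dropped),
            )
        )
    return results
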