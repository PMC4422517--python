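"""Collection-relative information content and phenotype similarity.

The information content of a term is the negative natural log of its
ancestor-propagated frequency in the case collection.  Term similarity is
the IC of the most informative common ancestor (the ancestor closure is
reflexive, so a term's self-similarity equals its own IC).  Case similarity
is the symmetric best-match average over the two explicit term sets:

    sim(Da, Db) = 1/(2|Da|) sum_{s in Da} max_{t in Db} sim(s, t)
                + 1/(2|Db|) sum_{s in Db} max_{t in Da} sim(s, t)

Rank distance is a scale-free dissimilarity of a case pair measured
against the rest of the collection:

    dist(a, b) = 1/2 sum_{i in {a,b}} #{j not in {a,b} :
                                        sim(Di, Dj) >= sim(Da, Db)}

Ties are counted inclusively; small values mean the pair is unusually
similar relative to the collection.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CasePhenotype
from .ontology import Ontology

__all__ = [
    "TermFrequencyModel",
    "SimilarityMatrix",
    "fit_frequencies",
    "term_similarity",
    "case_similarity",
    "similarity_matrix",
    "rank_distance",
    "rank_distance_matrix",
    "group_distance",
]


@dataclass(frozen=True)
class TermFrequencyModel:
    """Propagated term frequencies and information content for one collection.

    ``freq[t]`` is the fraction of cases whose ancestor-propagated term set
    contains ``t``; ``ic[t] = -ln freq[t]`` (nats).  Terms annotated to no
    case are absent (IC undefined).
    """

    collection_size: int
    freq: dict[str, float]
    ic: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "collection_size": self.collection_size,
                "terms": {
                    t: {"p": self.freq[t], "ic": self.ic[t]} for t in sorted(self.freq)
                },
            },
            indent=2,
        )


@dataclass
class SimilarityMatrix:
    """Symmetric case-by-case best-match-average similarity matrix."""

    case_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.case_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match case_ids")
        self._index = {c: i for i, c in enumerate(self.case_ids)}

    def index_of(self, case_id: str) -> int:
        try:
            return self._index[case_id]
        except KeyError:
            raise KeyError(f"case {case_id!r} not in similarity matrix") from None

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.case_ids, columns=self.case_ids).to_csv(
            path, sep="\t", index_label="case_id"
        )

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(case_ids=[str(c) for c in df.index], values=df.to_numpy(dtype=float))


def fit_frequencies(cases: Sequence[CasePhenotype], onto: Ontology) -> TermFrequencyModel:
    """Estimate propagated term frequencies from a case collection.

    A case counts toward term ``t`` when ``t`` lies in the reflexive
    ancestor closure of any of its explicit terms, so frequency is
    monotone non-increasing (and IC non-decreasing) from root to leaf.
    """
    if not cases:
        raise ValueError("cannot fit term frequencies on an empty cohort")
    n = len(cases)
    counts: dict[str, int] = {}
    for case in cases:
        propagated: set[str] = set()
        for t in case.terms:
            propagated |= onto.ancestors_of(t)
        for t in propagated:
            counts[t] = counts.get(t, 0) + 1
    freq = {t: c / n for t, c in counts.items()}
    ic = {t: (0.0 if p == 1.0 else -math.log(p)) for t, p in freq.items()}
    return TermFrequencyModel(collection_size=n, freq=freq, ic=ic)


def term_similarity(
    s: str, t: str, model: TermFrequencyModel, onto: Ontology
) -> float:
    """IC of the most informative common ancestor of ``s`` and ``t``.

    Both terms must have defined IC.  Terms with disjoint ancestor sets
    (multi-root ontologies) get similarity 0 by convention.
    """
    s, t = onto.resolve(s), onto.resolve(t)
    for x in (s, t):
        if x not in model.ic:
            raise KeyError(f"term {x!r} has no IC (absent from the collection)")
    common = onto.ancestors_of(s) & onto.ancestors_of(t)
    if not common:
        return 0.0
    return max(model.ic[v] for v in common if v in model.ic)


def case_similarity(
    d_a: Iterable[str],
    d_b: Iterable[str],
    model: TermFrequencyModel,
    onto: Ontology,
) -> float:
    """Symmetric best-match-average similarity of two explicit term sets."""
    d_a, d_b = list(d_a), list(d_b)
    if not d_a or not d_b:
        raise ValueError("case similarity requires two non-empty term sets")
    fwd = sum(max(term_similarity(s, t, model, onto) for t in d_b) for s in d_a)
    rev = sum(max(term_similarity(s, t, model, onto) for t in d_a) for s in d_b)
    return fwd / (2 * len(d_a)) + rev / (2 * len(d_b))


def _term_sim_table(
    terms: list[str], model: TermFrequencyModel, onto: Ontology
) -> np.ndarray:
    """Dense MICA-IC table over ``terms``, via ancestor incidence bitmask."""
    universe = sorted({a for t in terms for a in onto.ancestors_of(t) if a in model.ic})
    uidx = {u: i for i, u in enumerate(universe)}
    ic = np.array([model.ic[u] for u in universe])
    inc = np.zeros((len(terms), len(universe)), dtype=bool)
    for i, t in enumerate(terms):
        for a in onto.ancestors_of(t):
            j = uidx.get(a)
            if j is not None:
                inc[i, j] = True
    table = np.zeros((len(terms), len(terms)))
    neg = np.full(len(universe), -np.inf)
    for i in range(len(terms)):
        masked = np.where(inc[i], ic, neg)  # IC over anc(i), -inf elsewhere
        vals = np.where(inc, masked, neg).max(axis=1)
        table[i] = np.where(np.isfinite(vals), vals, 0.0)
    return table


def similarity_matrix(
    cases: Sequence[CasePhenotype], model: TermFrequencyModel, onto: Ontology
) -> SimilarityMatrix:
    """All-pairs case similarity; diagonal entries equal each case's mean IC."""
    if len(cases) < 2:
        raise ValueError("similarity matrix requires at least two cases")
    terms = sorted({onto.resolve(t) for c in cases for t in c.terms})
    tidx = {t: i for i, t in enumerate(terms)}
    table = _term_sim_table(terms, model, onto)
    sets = [np.array([tidx[onto.resolve(t)] for t in c.terms]) for c in cases]

    n = len(cases)
    values = np.zeros((n, n))
    for a in range(n):
        ia = sets[a]
        for b in range(a, n):
            sub = table[np.ix_(ia, sets[b])]
            s = sub.max(axis=1).mean() / 2 + sub.max(axis=0).mean() / 2
            values[a, b] = values[b, a] = s
    return SimilarityMatrix(case_ids=[c.case_id for c in cases], values=values)


def rank_distance(a: str, b: str, simmat: SimilarityMatrix) -> float:
    """Scale-free dissimilarity of a case pair against the collection.

    Counts, for each member of the pair, how many outside cases are at
    least as similar to it as the pair is to each other (ties inclusive),
    then halves the sum.  Range [0, n-2]; 0 means no outside case matches
    either member as well as they match each other.
    """
    ia, ib = simmat.index_of(a), simmat.index_of(b)
    if ia == ib:
        raise ValueError("rank distance is undefined for a case with itself")
    n = len(simmat.case_ids)
    if n < 3:
        raise ValueError("rank distance requires a collection of at least 3 cases")
    s_ab = simmat.values[ia, ib]
    total = 0
    for i in (ia, ib):
        row = simmat.values[i]
        mask = np.ones(n, dtype=bool)
        mask[[ia, ib]] = False
        total += int(np.count_nonzero(row[mask] >= s_ab))
    return total / 2.0


def rank_distance_matrix(simmat: SimilarityMatrix) -> np.ndarray:
    """All-pairs rank distances, vectorised row-by-row.

    Equivalent to calling :func:`rank_distance` on every pair; used to make
    Monte-Carlo group tests cheap (group distance becomes a gather).
    The diagonal is set to 0 and is never meaningful.
    """
    s = simmat.values
    n = s.shape[0]
    c = np.zeros((n, n))
    for a in range(n):
        row = s[a]
        # ge[b, j] = 1 if sim(a, j) >= sim(a, b)
        ge = row[None, :] >= row[:, None]
        counts = ge.sum(axis=1).astype(float)
        counts -= (s[a, a] >= row)  # exclude j == a
        counts -= 1.0  # exclude j == b (always >=, equality)
        c[a] = counts
    d = (c + c.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def group_distance(
    group: Iterable[str],
    simmat: SimilarityMatrix,
    dist_matrix: np.ndarray | None = None,
) -> float:
    """Mean rank distance over all unordered pairs in a case group."""
    ids = list(group)
    if len(ids) < 2:
        raise ValueError("group distance requires at least 2 cases")
    if len(set(ids)) != len(ids):
        raise ValueError("group contains duplicate case ids")
    if dist_matrix is not None:
        idx = [simmat.index_of(c) for c in ids]
        pairs = list(itertools.combinations(idx, 2))
        rows, cols = zip(*pairs)
        return float(dist_matrix[list(rows), list(cols)].mean())
    dists = [
        rank_distance(x, y, simmat) for x, y in itertools.combinations(ids, 2)
    ]
    return float(np.mean(dists))
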