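"""Shared fixtures: the 6-term fixture ontology, the C4 cohort and its
similarity model, and brute-force oracles used across test modules."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from phenosim.cohort import CasePhenotype
from phenosim.ontology import Ontology, Term
from phenosim.similarity import SimilarityMatrix, fit_frequencies, similarity_matrix

FIXTURE_OBO = """\
format-version: 1.2

[Term]
id: T0
name: root

[Term]
id: T1
name: branch one
is_a: T0 ! root
alt_id: T1_OLD

[Term]
id: T2
name: branch two
is_a: T0 ! root

[Term]
id: T3
name: leaf three
is_a: T1 ! branch one

[Term]
id: T4
name: leaf four
is_a: T1 ! branch one

[Term]
id: T5
name: leaf five
is_a: T2 ! branch two

[Term]
id: T9
name: retired
is_obsolete: true
"""


@pytest.fixture()
def obo_path(tmp_path):
    p = tmp_path / "fixture.obo"
    p.write_text(FIXTURE_OBO)
    return p


@pytest.fixture()
def onto():
    """The 6-term fixture DAG: T1,T2 under T0; T3,T4 under T1; T5 under T2."""
    return Ontology(
        [
            Term("T0", "root"),
            Term("T1", "branch one", frozenset({"T0"})),
            Term("T2", "branch two", frozenset({"T0"})),
            Term("T3", "leaf three", frozenset({"T1"})),
            Term("T4", "leaf four", frozenset({"T1"})),
            Term("T5", "leaf five", frozenset({"T2"})),
        ],
        aliases={"T1_OLD": "T1"},
    )


@pytest.fixture()
def c4_cases():
    return [
        CasePhenotype("c1", {"T3"}),
        CasePhenotype("c2", {"T3", "T5"}),
        CasePhenotype("c3", {"T4"}),
        CasePhenotype("c4", {"T5"}),
    ]


@pytest.fixture()
def c4_model(c4_cases, onto):
    return fit_frequencies(c4_cases, onto)


@pytest.fixture()
def c4_simmat(c4_cases, c4_model, onto):
    return similarity_matrix(c4_cases, c4_model, onto)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)

def oracle_propagated(case: CasePhenotype, onto: Ontology) -> set[str]:
    out: set[str] = set()
    for t in case.terms:
        frontier = [t]
        while frontier:
            x = frontier.pop()
            if x in out:
                continue
            out.add(x)
            frontier.extend(onto.terms[x].parents)
    return out


def oracle_ic(cases, onto) -> dict[str, float]:
    n = len(cases)
    counts: dict[str, int] = {}
    for c in cases:
        for t in oracle_propagated(c, onto):
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(k / n) for t, k in counts.items()}


def oracle_term_sim(s, t, ic, onto) -> float:
    anc_s = oracle_propagated(CasePhenotype("x", {s}), onto)
    anc_t = oracle_propagated(CasePhenotype("x", {t}), onto)
    common = [v for v in anc_s & anc_t if v in ic]
    return max((ic[v] for v in common), default=0.0)


def oracle_case_sim(da, db, ic, onto) -> float:
    fwd = sum(max(oracle_term_sim(s, t, ic, onto) for t in db) for s in da)
    rev = sum(max(oracle_term_sim(s, t, ic, onto) for t in da) for s in db)
    return fwd / (2 * len(da)) + rev / (2 * len(db))


def oracle_rank_distance(a: int, b: int, values: np.ndarray) -> float:
    n = values.shape[0]
    thr = values[a, b]
    total = 0
    for i in (a, b):
        for j in range(n):
            if j in (a, b):
                continue
            if values[i, j] >= thr:
                total += 1
    return total / 2


def oracle_group_distance(idx, values: np.ndarray) -> float:
    pairs = list(itertools.combinations(idx, 2))
    return sum(oracle_rank_distance(a, b, values) for a, b in pairs) / len(pairs)


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c

    def table_prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(N=r1+r2, K=c1, n=r1)
        return (
            math.comb(c1, x)
            * math.comb(r1 + r2 - c1, r1 - x)
            / math.comb(r1 + r2, r1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = table_prob(a)
    return sum(
        p for x in range(lo, hi + 1) if (p := table_prob(x)) <= p_obs * (1 + 1e-9)
    )
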