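"""Synthetic ontologies, cohorts and variant tables with planted structure.

Everything is a pure function of (config, seed): generators never mutate
global state, and truth labels are returned beside the data but never
consumed by any analysis code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CasePhenotype
from .ontology import Ontology, Term
from .variants import VariantRecord

__all__ = [
    "PlantedGroup",
    "PlantedGene",
    "SimulationConfig",
    "simulate_ontology",
    "simulate_cohort",
    "simulate_variants",
    "write_obo",
    "write_cohort_tsv",
    "write_variants_tsv",
    "truth_to_json",
]


@dataclass(frozen=True)
class PlantedGroup:
    group_id: str
    size: int
    core_terms: tuple[str, ...]
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.size < 1:
            raise ValueError("planted group size must be positive")


@dataclass(frozen=True)
class PlantedGene:
    symbol: str
    carrier_group: str  # id of the planted group whose members carry it
    background_rate: float = 0.0  # extra carriers among background cases


@dataclass
class SimulationConfig:
    n_terms: int = 100
    n_roots: int = 1
    max_parents: int = 2
    n_cases: int = 200
    terms_per_case_mean: float = 7.0
    terms_per_case_max: int = 23
    planted_groups: list[PlantedGroup] = field(default_factory=list)
    planted_gene: PlantedGene | None = None
    n_background_genes: int = 20
    background_carrier_rate: float = 0.01
    violating_fraction: float = 0.2  # background records built to fail a filter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < self.n_roots or self.n_roots < 1:
            raise ValueError("need n_terms >= n_roots >= 1")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if sum(g.size for g in self.planted_groups) > self.n_cases:
            raise ValueError("planted group sizes exceed the cohort size")


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def simulate_ontology(config: SimulationConfig) -> Ontology:
    """Random DAG: terms are added in order; each non-root draws 1..max_parents
    parents among earlier terms, so insertion order is a topological order."""
    rng = np.random.default_rng(config.seed)
    terms: list[Term] = []
    for i in range(config.n_terms):
        if i < config.n_roots:
            parents: frozenset[str] = frozenset()
        else:
            k = int(rng.integers(1, config.max_parents + 1))
            k = min(k, i)
            picks = rng.choice(i, size=k, replace=False)
            parents = frozenset(_term_id(int(p)) for p in picks)
        terms.append(Term(id=_term_id(i), name=f"synthetic term {i}", parents=parents))
    return Ontology(terms)


def _leaf_weights(onto: Ontology) -> tuple[list[str], np.ndarray]:
    """Sampling weights proportional to 1/(1 + proper descendant count)."""
    ids = sorted(onto.terms)
    desc_counts = {t: 0 for t in ids}
    for t in ids:
        for anc in onto.ancestors_of(t):
            if anc != t:
                desc_counts[anc] += 1
    w = np.array([1.0 / (1 + desc_counts[t]) for t in ids])
    return ids, w / w.sum()


def simulate_cohort(
    onto: Ontology, config: SimulationConfig
) -> tuple[list[CasePhenotype], dict[str, str]]:
    """Generate a cohort with background noise and planted term-sharing groups.

    Background cases draw a truncated-Poisson number of terms, sampled
    leaf-weighted.  Planted-group members receive the group's core set
    (each core term independently dropped with the group's dropout
    probability) plus background noise terms.  Returns (cases, truth)
    where truth maps case_id -> group id or 'background'.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids, weights = _leaf_weights(onto)
    for g in config.planted_groups:
        missing = [t for t in g.core_terms if t not in onto]
        if missing:
            raise ValueError(f"core terms not in ontology: {missing}")

    def n_terms() -> int:
        while True:
            k = int(rng.poisson(config.terms_per_case_mean))
            if 1 <= k <= config.terms_per_case_max:
                return k

    def background_terms(k: int) -> set[str]:
        picks = rng.choice(len(ids), size=min(k, len(ids)), replace=False, p=weights)
        return {ids[int(i)] for i in picks}

    cases: list[CasePhenotype] = []
    truth: dict[str, str] = {}
    case_no = 0

    for g in config.planted_groups:
        for _ in range(g.size):
            cid = f"case{case_no:04d}"
            case_no += 1
            core = {t for t in g.core_terms if rng.random() >= g.dropout}
            noise = background_terms(n_terms())
            terms = core | noise or background_terms(1)
            cases.append(CasePhenotype(case_id=cid, terms=terms, pedigree_id=g.group_id))
            truth[cid] = g.group_id

    while case_no < config.n_cases:
        cid = f"case{case_no:04d}"
        case_no += 1
        cases.append(CasePhenotype(case_id=cid, terms=background_terms(n_terms())))
        truth[cid] = "background"
    return cases, truth


def simulate_variants(
    cases: Sequence[CasePhenotype],
    truth: dict[str, str],
    config: SimulationConfig,
) -> list[VariantRecord]:
    """Variant table with a planted causal gene and noisy background genes.

    Planted-gene carriers are exactly the planted group's members: het,
    protein-altering, zero reference frequency, ample alternate reads —
    passing all six filters.  Background genes scatter variants over random
    cases; a configurable fraction is built to violate one filter rule.
    """
    rng = np.random.default_rng(config.seed + 2)
    records: list[VariantRecord] = []

    def clean(case_id: str, gene: str, pos: int) -> VariantRecord:
        return VariantRecord(
            case_id=case_id,
            gene=gene,
            variant_id=f"chr1:{pos} A/G",
            genotype="het",
            protein_altering=True,
            ref_cohort_af={"ref1": 0.0},
            alt_reads=int(rng.integers(3, 60)),
            inhouse_control_ac=0,
            cross_project_ac=int(rng.integers(0, 5)),
        )

    pos = 1000
    if config.planted_gene is not None:
        gid = config.planted_gene.carrier_group
        members = [c for c in cases if truth.get(c.case_id) == gid]
        if not members:
            raise ValueError(f"planted gene carrier group {gid!r} not found in truth")
        pos += 1
        for c in members:
            rec = clean(c.case_id, config.planted_gene.symbol, pos)
            records.append(rec)
        for c in cases:
            if truth.get(c.case_id) != gid and rng.random() < config.planted_gene.background_rate:
                pos += 1
                records.append(clean(c.case_id, config.planted_gene.symbol, pos))

    case_ids = [c.case_id for c in cases]
    for g in range(config.n_background_genes):
        gene = f"GENE{g:03d}"
        n_carriers = 2 + int(rng.poisson(config.background_carrier_rate * len(case_ids)))
        n_carriers = min(n_carriers, len(case_ids))
        picks = rng.choice(len(case_ids), size=n_carriers, replace=False)
        for i in picks:
            pos += 1
            rec = clean(case_ids[int(i)], gene, pos)
            if rng.random() < config.violating_fraction:
                rule = int(rng.integers(1, 7))
                rec = _violate(rec, rule, rng)
            records.append(rec)
    return records


def _violate(rec: VariantRecord, rule: int, rng: np.random.Generator) -> VariantRecord:
    from dataclasses import replace

    if rule == 1:
        return replace(rec, ref_cohort_af={"ref1": float(rng.uniform(0.0011, 0.05))})
    if rule == 2:
        return replace(rec, protein_altering=False)
    if rule == 3:
        return replace(rec, pedigree_consistent=False)
    if rule == 4:
        return replace(rec, alt_reads=int(rng.integers(0, 3)))
    if rule == 5:
        return replace(rec, inhouse_control_ac=int(rng.integers(2, 6)))
    return replace(rec, cross_project_ac=int(rng.integers(21, 60)))


# ---------------------------------------------------------------------------
# writers (round-trip through the same flat formats the loaders read)

def write_obo(onto: Ontology, path) -> None:
    lines = ["format-version: 1.2", ""]
    for tid in sorted(onto.terms):
        t = onto.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.name}")
        for p in sorted(t.parents):
            lines.append(f"is_a: {p} ! {onto.terms[p].name}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def write_cohort_tsv(cases: Sequence[CasePhenotype], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("case_id\thpo_ids\tgender\tpedigree_id\tis_index\n")
        for c in cases:
            fh.write(
                f"{c.case_id}\t{';'.join(sorted(c.terms))}\t{c.gender}\t"
                f"{c.pedigree_id or ''}\t{'1' if c.is_index else '0'}\n"
            )


def write_variants_tsv(records: Sequence[VariantRecord], path) -> None:
    cols = (
        "case_id\tgene\tvariant_id\tgenotype\tprotein_altering\tref_cohort_af\t"
        "alt_reads\tinhouse_control_ac\tcross_project_ac\thgmd\tphenotype_match\t"
        "pedigree_consistent\tis_index\tgender\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(cols)
        for r in records:
            afs = ";".join(f"{k}={v}" for k, v in sorted(r.ref_cohort_af.items()))
            fh.write(
                f"{r.case_id}\t{r.gene}\t{r.variant_id}\t{r.genotype}\t"
                f"{int(r.protein_altering)}\t{afs}\t"
                f"{'' if r.alt_reads is None else r.alt_reads}\t"
                f"{r.inhouse_control_ac}\t{r.cross_project_ac}\t{int(r.hgmd)}\t"
                f"{r.phenotype_match}\t{int(r.pedigree_consistent)}\t"
                f"{int(r.is_index)}\t{r.gender}\n"
            )


def truth_to_json(truth: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
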