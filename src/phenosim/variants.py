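"""Rare-variant triage: exclusion filters, gene grouping, phenotype-driven
gene ranking and PV/LPV/VUS classification for known disease genes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import DEFAULT_N_SUBSETS, GroupTestResult, monte_carlo_group_p
from .similarity import SimilarityMatrix, rank_distance_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "ClassifiedVariant",
    "FilterResult",
    "GeneScanRow",
    "filter_variants",
    "group_cases_by_gene",
    "gene_similarity_scan",
    "classify_variants",
    "load_variants",
    "load_gene_list",
]

GENOTYPES = ("het", "hom", "hemi")
INHERITANCE_MODELS = ("autosomal_dominant", "autosomal_recessive", "x_linked")

# default thresholds for the six exclusion rules
MAX_REF_AF = 0.001
MIN_ALT_READS = 3
MAX_INHOUSE_AC = 1
MAX_OVERALL_AC = 20


@dataclass(frozen=True)
class VariantRecord:
    """One case-variant observation with every field the filters consume."""

    case_id: str
    gene: str
    variant_id: str  # chrom:pos ref/alt
    genotype: str  # het / hom / hemi
    protein_altering: bool
    ref_cohort_af: Mapping[str, float] = field(default_factory=dict)
    alt_reads: int | None = None
    inhouse_control_ac: int = 0
    cross_project_ac: int = 0
    hgmd: bool = False
    phenotype_match: str = "unknown"  # matched / unmatched / unknown
    pedigree_consistent: bool = True
    is_index: bool = True
    gender: str = "unknown"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.phenotype_match not in ("matched", "unmatched", "unknown"):
            raise ValueError(f"bad phenotype_match {self.phenotype_match!r}")
        for cohort, af in self.ref_cohort_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency out of range for {cohort}: {af}")


@dataclass(frozen=True)
class ClassifiedVariant:
    record: VariantRecord
    classification: str  # PV / LPV / VUS
    rationale: tuple[str, ...]


@dataclass
class FilterResult:
    retained: list[VariantRecord]
    excluded: list[tuple[VariantRecord, int, tuple[int, ...]]]  # (rec, first rule, all rules)

    def rule_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for _, first, _ in self.excluded:
            counts[first] = counts.get(first, 0) + 1
        return counts


def filter_variants(
    records: Sequence[VariantRecord],
    max_ref_af: float = MAX_REF_AF,
    min_alt_reads: int = MIN_ALT_READS,
    max_inhouse_ac: int = MAX_INHOUSE_AC,
    max_overall_ac: int = MAX_OVERALL_AC,
) -> FilterResult:
    """Apply the six exclusion criteria; a record failing any is excluded.

    1. allele frequency strictly above ``max_ref_af`` in ANY reference cohort
    2. not predicted protein-altering
    3. not present in the sequenced affected pedigree members
    4. fewer than ``min_alt_reads`` reads supporting the alternate allele
       (a missing read count is treated as failing)
    5. allele count above ``max_inhouse_ac`` in the in-house control panel
    6. overall cross-project allele count above ``max_overall_ac``

    Missing reference frequencies count as 0 (retain); each exclusion is
    tagged with the first triggering rule id and all triggering ids.
    """
    retained: list[VariantRecord] = []
    excluded: list[tuple[VariantRecord, int, tuple[int, ...]]] = []
    for rec in records:
        rules: list[int] = []
        if any(af > max_ref_af for af in rec.ref_cohort_af.values()):
            rules.append(1)
        if not rec.protein_altering:
            rules.append(2)
        if not rec.pedigree_consistent:
            rules.append(3)
        if rec.alt_reads is None or rec.alt_reads < min_alt_reads:
            rules.append(4)
        if rec.inhouse_control_ac > max_inhouse_ac:
            rules.append(5)
        if rec.cross_project_ac > max_overall_ac:
            rules.append(6)
        if rules:
            excluded.append((rec, rules[0], tuple(rules)))
        else:
            retained.append(rec)
    return FilterResult(retained=retained, excluded=excluded)


def group_cases_by_gene(
    retained: Sequence[VariantRecord], model: str = "autosomal_dominant"
) -> dict[str, set[str]]:
    """Group index cases by gene under an inheritance model.

    autosomal_dominant: any index case with >=1 retained het/hom variant;
    autosomal_recessive: hom, or >=2 distinct het variants in the gene
    (compound-het phase unverified); x_linked: hemizygous males or
    homozygous females.
    """
    if model not in INHERITANCE_MODELS:
        raise ValueError(f"unknown inheritance model {model!r}")
    per_gene_case: dict[tuple[str, str], list[VariantRecord]] = {}
    for rec in retained:
        if not rec.is_index:
            continue
        per_gene_case.setdefault((rec.gene, rec.case_id), []).append(rec)

    groups: dict[str, set[str]] = {}
    for (gene, case_id), recs in per_gene_case.items():
        if model == "autosomal_dominant":
            ok = any(r.genotype in ("het", "hom") for r in recs)
        elif model == "autosomal_recessive":
            distinct_hets = {r.variant_id for r in recs if r.genotype == "het"}
            ok = any(r.genotype == "hom" for r in recs) or len(distinct_hets) >= 2
        else:  # x_linked
            ok = any(
                (r.genotype == "hemi" and r.gender == "male")
                or (r.genotype == "hom" and r.gender == "female")
                for r in recs
            )
        if ok:
            groups.setdefault(gene, set()).add(case_id)
    return groups


@dataclass(frozen=True)
class GeneScanRow:
    gene: str
    group_size: int
    observed_distance: float | None
    p_value: float | None
    result: GroupTestResult | None


def gene_similarity_scan(
    gene_groups: Mapping[str, set[str]],
    simmat: SimilarityMatrix,
    eligible: Sequence[str] | None = None,
    n_subsets: int = DEFAULT_N_SUBSETS,
    seed: int = 0,
) -> list[GeneScanRow]:
    """Monte-Carlo phenotype-closeness P per gene carrier group.

    Output is sorted ascending by P, ties broken by group size descending
    then gene name.  Singleton groups are reported untested (P None) at the
    bottom.  Carriers missing from the similarity matrix are dropped from
    the group with a warning.
    """
    dist_matrix = rank_distance_matrix(simmat)
    known = set(simmat.case_ids)
    rows: list[GeneScanRow] = []
    for gene in sorted(gene_groups):
        carriers = set(gene_groups[gene])
        missing = carriers - known
        if missing:
            logger.warning("gene %s: carriers outside matrix dropped: %s", gene, sorted(missing))
            carriers -= missing
        if len(carriers) < 2:
            rows.append(GeneScanRow(gene, len(carriers), None, None, None))
            continue
        res = monte_carlo_group_p(
            carriers,
            simmat,
            eligible=eligible,
            n_subsets=n_subsets,
            seed=seed,
            dist_matrix=dist_matrix,
        )
        rows.append(
            GeneScanRow(gene, len(carriers), res.observed_distance, res.p_value, res)
        )
    tested = [r for r in rows if r.p_value is not None]
    untested = [r for r in rows if r.p_value is None]
    tested.sort(key=lambda r: (r.p_value, -r.group_size, r.gene))
    untested.sort(key=lambda r: (-r.group_size, r.gene))
    return tested + untested


def classify_variants(
    records: Sequence[VariantRecord], known_genes: Iterable[str]
) -> list[ClassifiedVariant]:
    """Assign PV / LPV / VUS to retained variants in known disease genes.

    PV: in HGMD with a matched phenotype.  LPV: not in HGMD, in a gene
    whose previously reported cases match the phenotype.  VUS: everything
    else.  A PV/LPV is demoted to VUS when another collection case carries
    the same variant with an unmatched phenotype (inconsistent relationship
    between genotype and phenotype).
    """
    known = set(known_genes)
    for rec in records:
        if rec.gene not in known:
            raise ValueError(
                f"gene {rec.gene!r} is not in the known-gene list; "
                "use gene_similarity_scan for discovery genes"
            )

    inconsistent_variants = {
        rec.variant_id for rec in records if rec.phenotype_match == "unmatched"
    }

    out: list[ClassifiedVariant] = []
    for rec in records:
        trace: list[str] = []
        if rec.hgmd and rec.phenotype_match == "matched":
            cls = "PV"
            trace.append("HGMD variant with matched phenotype")
        elif not rec.hgmd and rec.phenotype_match == "matched":
            cls = "LPV"
            trace.append("non-HGMD variant in gene with matched phenotype")
        else:
            cls = "VUS"
            trace.append("criteria for PV/LPV not met")
        if cls in ("PV", "LPV") and rec.variant_id in inconsistent_variants:
            trace.append(
                f"reclassified {cls} -> VUS: another carrier of "
                f"{rec.variant_id} has an unmatched phenotype"
            )
            cls = "VUS"
        out.append(ClassifiedVariant(record=rec, classification=cls, rationale=tuple(trace)))
    return out


_BOOL = {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False}


def _parse_bool(value, default: bool | None = None) -> bool:
    s = str(value).strip().lower()
    if s in _BOOL:
        return _BOOL[s]
    if default is not None and s in ("", "nan", "none"):
        return default
    raise ValueError(f"cannot parse boolean {value!r}")


def load_variants(path) -> list[VariantRecord]:
    """Read a variant TSV.

    Required columns: case_id, gene, variant_id, genotype, protein_altering,
    ref_cohort_af (semicolon-joined ``cohort=af`` pairs, may be empty),
    alt_reads, inhouse_control_ac, cross_project_ac, hgmd, phenotype_match,
    pedigree_consistent.  Optional: is_index, gender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        afs: dict[str, float] = {}
        for pair in str(row.ref_cohort_af).split(";"):
            pair = pair.strip()
            if not pair:
                continue
            cohort, af = pair.split("=")
            afs[cohort] = float(af)
        alt = row.alt_reads.strip()
        records.append(
            VariantRecord(
                case_id=row.case_id,
                gene=row.gene,
                variant_id=row.variant_id,
                genotype=row.genotype,
                protein_altering=_parse_bool(row.protein_altering),
                ref_cohort_af=afs,
                alt_reads=int(alt) if alt else None,
                inhouse_control_ac=int(row.inhouse_control_ac or 0),
                cross_project_ac=int(row.cross_project_ac or 0),
                hgmd=_parse_bool(row.hgmd, default=False),
                phenotype_match=row.phenotype_match or "unknown",
                pedigree_consistent=_parse_bool(row.pedigree_consistent, default=True),
                is_index=_parse_bool(getattr(row, "is_index", "true"), default=True),
                gender=getattr(row, "gender", "unknown") or "unknown",
            )
        )
    return records


def load_gene_list(path) -> list[str]:
    """Known-gene list: one symbol per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes
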