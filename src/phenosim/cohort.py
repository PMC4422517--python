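"""Case phenotypes: loading, automatic lab-driven annotation, term filtering."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .ontology import Ontology, OntologyError

logger = logging.getLogger(__name__)

__all__ = [
    "CasePhenotype",
    "ReferenceIntervalRule",
    "Suggestion",
    "DEFAULT_RULES",
    "load_cohort",
    "load_labs",
    "load_rules",
    "auto_annotate",
    "filter_terms",
]

GENDERS = ("male", "female", "unknown")


@dataclass
class CasePhenotype:
    """One case with its explicit ontology term set and metadata."""

    case_id: str
    terms: set[str] = field(default_factory=set)
    gender: str = "unknown"
    pedigree_id: str | None = None
    is_index: bool = True

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")


@dataclass(frozen=True)
class ReferenceIntervalRule:
    """Maps an out-of-interval lab value to an ontology term.

    ``mode='automatic'`` rules add the term directly; ``mode='suggested'``
    rules only emit a suggestion for manual confirmation.  Boundary values
    are strict: a value must fall strictly below ``lower`` or strictly
    above ``upper`` to trigger.
    """

    assay: str
    unit: str
    lower: float | None = None
    upper: float | None = None
    gender: str = "any"  # 'any', 'male' or 'female'
    term_below: str | None = None
    term_above: str | None = None
    mode: str = "automatic"

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"{self.assay}: lower must be < upper")
        if self.term_below is None and self.term_above is None:
            raise ValueError(f"{self.assay}: at least one of term_below/term_above required")
        if self.mode not in ("automatic", "suggested"):
            raise ValueError(f"{self.assay}: bad mode {self.mode!r}")


@dataclass(frozen=True)
class Suggestion:
    case_id: str
    term: str
    reason: str


# Platelet count 100-400 x10^9/L and mean platelet volume 6-12 fL are the
# only reference intervals recoverable from the source material; all other
# assays must be configured by the user.
DEFAULT_RULES: tuple[ReferenceIntervalRule, ...] = (
    ReferenceIntervalRule(
        assay="PLT",
        unit="10^9/L",
        lower=100.0,
        upper=400.0,
        term_below="HP:0001873",  # thrombocytopenia
        term_above="HP:0001894",  # thrombocytosis
    ),
    ReferenceIntervalRule(
        assay="MPV",
        unit="fL",
        lower=6.0,
        upper=12.0,
        term_below="HP:0005537",  # decreased mean platelet volume
        term_above="HP:0011877",  # increased mean platelet volume
    ),
)


def load_cohort(path, onto: Ontology) -> list[CasePhenotype]:
    """Read a tab-separated cohort table.

    Expected columns: ``case_id``, ``hpo_ids`` (semicolon-joined),
    ``gender``, ``pedigree_id``, ``is_index``.  Term ids are validated
    against the ontology with alias resolution; duplicates within a case
    are removed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"case_id", "hpo_ids", "gender", "pedigree_id", "is_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("cohort table %s contains no cases", path)
        return []
    if df["case_id"].duplicated().any():
        dups = sorted(df.loc[df["case_id"].duplicated(), "case_id"])
        raise ValueError(f"duplicate case ids: {dups}")

    cases: list[CasePhenotype] = []
    for row in df.itertuples(index=False):
        raw = [t.strip() for t in row.hpo_ids.split(";") if t.strip()]
        terms: set[str] = set()
        for t in raw:
            try:
                terms.add(onto.resolve(t))
            except OntologyError:
                raise ValueError(
                    f"case {row.case_id}: unknown term id {t!r}"
                ) from None
        cases.append(
            CasePhenotype(
                case_id=row.case_id,
                terms=terms,
                gender=row.gender or "unknown",
                pedigree_id=row.pedigree_id or None,
                is_index=str(row.is_index).strip().lower() in ("1", "true", "yes"),
            )
        )
    return cases


def load_labs(path) -> pd.DataFrame:
    """Read a tab-separated lab table (case_id, assay, value, unit)."""
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "assay": str, "unit": str})
    required = {"case_id", "assay", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lab table missing columns: {sorted(missing)}")
    df["value"] = df["value"].astype(float)
    return df


def load_rules(path) -> list[ReferenceIntervalRule]:
    """Load reference-interval rules from a YAML or JSON configuration file."""
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return [ReferenceIntervalRule(**entry) for entry in data]


def _rule_applies(rule: ReferenceIntervalRule, case: CasePhenotype) -> bool:
    return rule.gender == "any" or rule.gender == case.gender


def auto_annotate(
    cases: Sequence[CasePhenotype],
    labs: pd.DataFrame,
    rules: Sequence[ReferenceIntervalRule] = DEFAULT_RULES,
) -> tuple[list[CasePhenotype], list[Suggestion]]:
    """Annotate cases from lab values against reference intervals.

    Returns new case records (input untouched) plus the list of suggestions
    emitted by ``mode='suggested'`` rules and by gender-restricted rules
    applied to unknown-gender cases (which are never automatic).
    Idempotent: re-running on the output adds nothing new.
    """
    by_id = {c.case_id: replace(c, terms=set(c.terms)) for c in cases}
    suggestions: list[Suggestion] = []

    for row in labs.itertuples(index=False):
        case = by_id.get(str(row.case_id))
        if case is None:
            logger.warning("lab row for unknown case %s skipped", row.case_id)
            continue
        matching = [r for r in rules if r.assay == row.assay]
        for rule in matching:
            if rule.gender != "any" and case.gender not in (rule.gender, "unknown"):
                continue
            if rule.unit != row.unit:
                raise ValueError(
                    f"unit mismatch for {row.assay} on case {case.case_id}: "
                    f"rule expects {rule.unit!r}, lab row has {row.unit!r}"
                )
            term: str | None = None
            direction = ""
            if rule.lower is not None and row.value < rule.lower and rule.term_below:
                term, direction = rule.term_below, f"< {rule.lower}"
            elif rule.upper is not None and row.value > rule.upper and rule.term_above:
                term, direction = rule.term_above, f"> {rule.upper}"
            if term is None:
                continue
            reason = f"{row.assay} {row.value} {row.unit} {direction} {rule.unit}"
            gender_blocked = rule.gender != "any" and case.gender == "unknown"
            if rule.mode == "automatic" and not gender_blocked:
                case.terms.add(term)
            else:
                suggestions.append(Suggestion(case.case_id, term, reason))
    return list(by_id.values()), suggestions


def filter_terms(
    cases: Sequence[CasePhenotype],
    onto: Ontology,
    exclusion: Iterable[str] = (),
    reduce_redundancy: bool = True,
) -> list[CasePhenotype]:
    """Remove excluded terms and (optionally) redundant ancestors.

    A term is redundant within a case when it is a proper ancestor of
    another term in the same case.  Cases left with empty term sets are
    dropped (logged), since they cannot enter similarity analyses.
    """
    excl = {onto.resolve(t) for t in exclusion}
    out: list[CasePhenotype] = []
    for case in cases:
        terms = {onto.resolve(t) for t in case.terms} - excl
        if reduce_redundancy:
            terms = {
                t
                for t in terms
                if not any(t in (onto.ancestors_of(u) - {u}) for u in terms)
            }
        if not terms:
            logger.warning("case %s dropped: no terms after filtering", case.case_id)
            continue
        out.append(replace(case, terms=terms))
    return out
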