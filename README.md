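# phenosim

Ontology-based phenotype similarity for rare-disease gene discovery:
annotate cases with ontology terms, quantify pairwise phenotypic similarity
from collection-relative information content, test case groups for unusual
phenotypic closeness by Monte-Carlo resampling, partition a cohort with PAM
and characterise clusters by Fisher-exact term enrichment, and prioritise
genes by filtering rare variants and scoring the phenotype similarity of
variant-sharing case groups.

## Method sketch

- **Information content.** `IC(t) = -ln p_t`, where `p_t` is the fraction of
  cases whose ancestor-propagated term set contains `t` (reflexive is-a
  closure, so `sim(t, t) = IC(t)`).
- **Term similarity.** IC of the most informative common ancestor.
- **Case similarity.** Symmetric best-match average over the two explicit
  term sets.
- **Rank distance.** For a case pair, the (halved) count of other cases at
  least as similar to either member as the pair is to each other —
  scale-free; group distance is the mean over all pairs in the group.
- **Group test.** One-tail Monte-Carlo P: the fraction of random same-size
  subsets of the index cases whose group distance is ≤ the observed one.
- **Clustering.** Classic BUILD+SWAP PAM on `-sim`; clusters labelled by up
  to three ontology nodes from distinct lineages with the smallest
  Fisher-exact P (threshold 10⁻³ beyond the first).
- **Variants.** Six exclusion filters (reference AF > 0.1%, not
  protein-altering, not segregating in the pedigree, < 3 alt reads,
  in-house allele count > 1, cross-project allele count > 20), gene grouping
  under an inheritance model, Monte-Carlo gene ranking, and PV/LPV/VUS
  classification for known disease genes with demotion on inconsistent
  carriers.

A `simulate` module generates ontologies, cohorts with planted term-sharing
groups and variant tables with a planted causal gene, so the whole pipeline
is testable offline.

## CLI

One executable, `phenosim`, with subcommands:

```sh
# synthesise a full dataset (ontology, cohort, variants, truth labels)
phenosim simulate --n-cases 200 --seed 1 --out scratch/sim

# term-frequency model + case-similarity matrix
phenosim simmatrix --ontology scratch/sim/ontology.obo \
    --cohort scratch/sim/cohort.tsv --out scratch/mat

# Monte-Carlo closeness test for named case groups
phenosim grouptest --simmatrix scratch/mat/similarity.tsv \
    --groups groups.tsv --n-subsets 250000 --seed 1 --out scratch/gt

# PAM clustering + Fisher-exact cluster labels
phenosim cluster --ontology scratch/sim/ontology.obo \
    --cohort scratch/sim/cohort.tsv \
    --simmatrix scratch/mat/similarity.tsv -k 8 --out scratch/cl

# six-rule variant filtering (+ PV/LPV/VUS with --known-genes)
phenosim variants --variants scratch/sim/variants.tsv --out scratch/var

# rank genes by carrier-group phenotype similarity
phenosim genescan --variants scratch/sim/variants.tsv \
    --simmatrix scratch/mat/similarity.tsv --seed 1 --out scratch/scan

# lab-value driven automatic annotation
phenosim annotate --ontology o.obo --cohort c.tsv --labs labs.tsv --out out
```

Every command writes a `provenance.json` (version, config hash, seed);
reruns with identical inputs produce byte-identical data artefacts.

## File formats

All plain text: OBO 1.2/1.4 ontologies; TSV cohort
(`case_id, hpo_ids, gender, pedigree_id, is_index`), labs
(`case_id, assay, value, unit`), variant and similarity-matrix tables;
YAML/JSON reference-interval rules; JSON IC models, truth labels and
cluster summaries; DOT export for ontology summary subgraphs.
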