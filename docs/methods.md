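# Methods

## The matching model

A phenotype query is an ordered list of ontology term ids plus an optional
inheritance pattern. For gene *g* with annotated term set `ann(g)` (the union
over all of the gene's disease records), a query term *t* is satisfied iff

    ann(g) ∩ desc(t) ≠ ∅

with `desc(t)` the reflexive–transitive closure of *t* under reversed `is_a`
edges. This direction assumes the query is category-level and the annotation
specific (e.g. a query of "Puberty and gonadal disorders" satisfied by an
annotation of "Hypogonadotropic hypogonadism"). The converse situation — a
patient term more specific than the annotation — is handled by the opt-in
`bidirectional` flag, which additionally accepts `anc(t)` members. Default is
descendant-only; both directions are covered by tests.

Only `is_a` edges contribute to closures. `part_of` and other relationship
types are ignored, as is conventional in phenotype matching. The ontology is
a DAG (multiple parents allowed); cycles, dangling parents and duplicate ids
are load-time errors. Obsolete terms resolve through `replaced_by` when
present and are otherwise an error unless explicitly allowed, so dead ids in
annotation data surface instead of silently matching nothing.

The inheritance criterion counts as exactly one criterion. It is satisfied
when the query's mode set intersects the gene's recorded modes, or when the
gene is annotated beneath the corresponding mode-of-inheritance ontology term
(HP:0000006/7, HP:0001419/23, HP:0001427). A mismatch subtracts the
criterion but never removes the gene: panels deliberately retain partial
matches in lower tiers.

**Tie-break within a tier** (the score does not define a total order):
descending number of distinct annotated terms hit, then descending number of
supporting disease records, then gene symbol. The original system's
within-tier order is not documented and is not reproduced; determinism is
the contract here.

## Variant screening defaults

| parameter | default | rationale |
|---|---|---|
| `max_af_dominant` | 0.001 | common clinical cut-off for dominant candidates |
| `max_af_recessive` | 0.01 | recessive alleles tolerate higher carrier frequency |
| consequence whitelist | missense, nonsense, frameshift, splice_site, inframe_indel | protein-altering classes |
| missing `pop_af` | treated as 0 | absence from controls is evidence (PM2), not missing data |

A gene with any AR mode uses the recessive cut-off (most permissive mode
wins). Thresholds are config-overridable; the defaults are this package's
choice, not a property of the method. Indel normalization is out of scope:
sidecar keys must match the VCF representation exactly. VCF positions are
1-based; BED exports are 0-based half-open.

## Inheritance rules

Atomic modes are tried in a fixed order (AD, AR, XD, XR, MT, UNKNOWN)
restricted to the gene's permitted set; any success is consistency. Two
distinct heterozygous variants under AR are *provisionally* consistent
(`phase_confirmed = false`): compound heterozygosity is only confirmed when
parental genotypes assign one variant to each parent, and refuted (cis) when
all origins are known and identical. A variant absent from both parents
leaves phase open — possible de novo, flagged, never auto-confirmed.
Unknown-sex patients are evaluated under the stricter female XR rule.
UNKNOWN and MT modes are lenient (any variant is consistent): an
uncharacterized mode should never veto a finding, and heteroplasmy is not
modeled.

## ACMG combining

The 2015 guideline's combining table is shipped as packaged data
(`data/acmg_rules.tsv`: minimum counts per strength bucket). Pathogenic
clauses are evaluated before likely-pathogenic and benign before
likely-benign, so upper-bounded clauses ("1 strong + 1–2 moderate") emerge
from ordering. Conflict → VUS in two situations: clauses fire on both sides,
or evidence exists on both sides and no clause fires on either. Strength
overrides re-bucket a code (e.g. PVS1 used at moderate strength). Evidence
assignment is caller-supplied; only PM2 (absent/zero sidecar frequency) and
PM5 (different missense at the same codon of a user-supplied known-pathogenic
table) have helper functions.

## Cohort replay and reconstruction

The packaged 29-patient table transcribes the published cohort's sequencing
results verbatim. Two reconstructions were necessary because the source
prints neither zygosity nor per-patient sex:

- **Zygosity:** autosomal findings are heterozygous (the recessive diagnoses
  appear as two rows, forming compound hets); X-linked findings in males are
  hemizygous. An explicit `zygosity` column overrides this.
- **Sex:** chosen to respect the published aggregate (19 male / 10 female)
  and the X-linked verdicts (the XR finding must be in a male; XD carriers
  set female). These assignments are a reconstruction, marked as such in the
  data file header.

A patient is diagnostic if *any* gene group is consistent — patients are
counted, not variants — and the rate divides by cohort size, not by
candidate-positive count. Display rounding is half-up to two decimals
(19/29 → 65.52%); the raw fraction is preserved in data. One cohort patient
carries a gene of unknown inheritance alongside a dominant finding; either
the lenient UNKNOWN rule or the dominant gene alone makes the patient
diagnostic, so the verdict is insensitive to that choice.

## Synthetic generators: what they emulate, what they don't

`gen_ontology` emits single-rooted random DAGs (default 50 terms, ≤3 parents)
in which term *i* only points to earlier terms — acyclic by construction.
`gen_matching_instance` (default 20 genes, 1–6 annotated terms each,
optional spurious-annotation noise) can plant one full-match gene while
denying every other gene at least one criterion's closure, giving an exact
recovery target. `gen_cohort` plants per-patient truth (diagnostic patterns
drawn from AD/AR-hom/AR-comphet/XR-male/XD-female; excluded = single-het AR;
the rest negative). All generators are byte-deterministic per seed.

These fixtures exercise the logic, not the biology: term counts and gene
counts are far below a real ontology release, annotation noise is uniform,
variant coordinates (beyond the two printed case positions) are arbitrary,
and no sequence-level realism is attempted. Passing tests show the
implementation is faithful to its rules and recovers planted structure —
not that the rules themselves capture every real pedigree.

## Numerical and degenerate-input choices

- Closures are memoized per term; equality with a brute-force DFS oracle is
  the correctness contract (property-tested over seeded DAGs).
- Empty query → error; empty annotation store → empty panel with a warning;
  empty cohort → explicit error (rate undefined), never a division by zero.
- Duplicate annotation rows collapse; malformed rows warn-and-skip by
  default and raise in strict mode.
- Panel tier sizes at desk scale reproduce only the top two tiers of the
  reference panel (2 + 29 genes); lower tiers (hundreds to thousands of
  genes) depend on the annotation snapshot of the original analysis and are
  documented as not reproducible from fixtures.

## Known limitations

No semantic-similarity ranking (information-content methods rank genes more
smoothly than criterion counts); no imprinting, mosaicism, digenic models or
penetrance; no CNV/SV or mitochondrial-genome calling; no transcript-aware
consequence prediction (the sidecar carries the annotator's output); no live
database clients — annotation tables are inputs.
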