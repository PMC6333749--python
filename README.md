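# vpanel — phenotype-driven virtual gene panels for exome interpretation

Whole-exome sequencing of a rare-disease patient leaves tens of thousands of
variants, and an unguided review of them yields a molecular diagnosis in only
a quarter to a third of cases. `vpanel` implements the alternative that
clinical labs increasingly use: build a *virtual panel* from the patient's own
phenotypes, on demand, and interpret only the variants falling in it.

The pipeline, aimed at clinical bioinformaticians and method developers:

1. **Panel construction.** The patient's core phenotypes are ontology term
   ids (HPO-style). A gene *g* with annotated phenotype set `ann(g)` satisfies
   a query term *t* when `ann(g) ∩ desc(t) ≠ ∅`, where `desc(t)` is the
   reflexive–transitive descendant closure of *t* under `is_a`. An optional
   inheritance pattern (e.g. autosomal recessive) counts as one further
   criterion. Genes are ranked by their *consilient phenotype count* — the
   number of satisfied criteria — and grouped into descending tiers.
2. **Variant filtering.** Proband variants (VCF + annotation sidecar TSV) are
   screened on consequence and population frequency, then restricted to genes
   in panel tiers at or above a chosen count.
3. **Inheritance consistency.** Per gene, surviving zygosities must be able to
   realize one of the gene's inheritance modes (a single heterozygous variant
   in a strictly autosomal-recessive gene is excluded; two distinct
   heterozygotes are a provisional compound het until trio data confirm the
   trans configuration).
4. **ACMG classification.** Evidence codes (PVS/PS/PM/PP, BA/BS/BP) combine
   through the published clause table into pathogenic / likely pathogenic /
   VUS / likely benign / benign.
5. **Cohort yield.** Replaying a cohort results table gives per-patient
   verdicts and the diagnostic rate = diagnosed patients / cohort size.

## Worked example

The packaged index case is a proband with ataxia, seizures, esotropia,
puberty and gonadal disorders, global developmental delay, and suspected
autosomal-recessive inheritance — six criteria in all:

```bash
vpanel fixtures --case --out case/
vpanel run \
  --obo case/case.obo --annotations case/annotations.tsv \
  --vcf case/proband.vcf --sidecar case/sidecar.tsv --trio case/trio.tsv \
  --sample proband --sex male \
  --phenotype HP:0001251 --phenotype HP:0001250 --phenotype HP:0000565 \
  --phenotype HP:0008373 --phenotype HP:0001263 --inheritance AR \
  --out report/
# pipeline done; top consistent gene: PMM2 -> report
```

`report/panel.tsv` shows two genes satisfying all 6 criteria (PMM2, CEP290)
above a 29-gene tier at count 5. Both heterozygous PMM2 variants
(chr16:8905018 T>C, c.430T>C/p.F144L and chr16:8941581 G>C,
c.640G>C/p.G214R) survive filtering; with the trio table assigning one
variant to each parent the verdict in `report/report.json` is
`consistent / ar_compound_het_trans / phase_confirmed: true`. Note the codon
arithmetic: ceil(430/3) = 144 and ceil(640/3) = 214, matching the residue
numbers in the protein changes. Classifying the novel variant's evidence:

```bash
vpanel acmg --codes PM2,PM3,PM5
# likely_pathogenic	LP_iv
```

Replaying the packaged 29-patient cohort table:

```bash
vpanel cohort --table src/vpanel/data/cohort29.tsv --out yield.tsv
# 19/29 diagnostic (2 excluded by inheritance) -> yield.tsv
```

The aggregate line of `yield.tsv` reads
`candidate_positive=21 excluded=2 diagnostic=19 rate=19/29=65.52%`:
21 patients carried candidate variants, 2 were removed because a single
heterozygous variant in an autosomal-recessive gene cannot explain disease,
and the diagnostic rate over the cohort is 65.52%.

## Layout

- `src/vpanel/ontology.py` — OBO parsing, id resolution, closure queries
- `src/vpanel/annotations.py` — gene–disease–phenotype–inheritance store
- `src/vpanel/panel.py` — consilient-phenotype matching and tiering
- `src/vpanel/variants.py` — VCF intake, pre-filter, panel intersection
- `src/vpanel/inheritance.py` — mode-consistency rules, phase confirmation
- `src/vpanel/acmg.py` — evidence-code combining (rule table in `data/`)
- `src/vpanel/cohort.py` — cohort replay and diagnostic yield
- `src/vpanel/fixtures.py` — seeded generators + transcribed reference tables
- `src/vpanel/cli.py`, `config.py` — the `vpanel` command and run config

See `docs/methods.md` for the model, parameter defaults and limitations.
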