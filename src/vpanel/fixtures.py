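"""Synthetic data generators and packaged reference tables.

Every consuming module can be exercised offline from here: seeded random
ontologies/annotation stores for property tests, a fully worked index-case
bundle (ontology + annotations + query + VCF + sidecar + trio), seeded
synthetic cohorts with a planted truth table, and the transcribed reference
tables from the published study this package's method reproduces (the
29-patient cohort results and the top two tiers of the case's virtual
panel).

All generators are deterministic: a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .annotations import AnnotationStore, load_annotations
from .cohort import CohortRecord, load_cohort
from .ontology import Ontology, parse_obo
from .panel import PhenotypeQuery

__all__ = [
    "SimulationConfig",
    "gen_ontology",
    "gen_matching_instance",
    "gen_case_fixture",
    "gen_cohort",
    "CaseBundle",
    "reference_cohort",
    "reference_panel_tiers",
    "phenotype_label_map",
]


# --------------------------------------------------------------------------
# packaged reference tables


def _data_text(name: str) -> str:
    return resources.files("vpanel.data").joinpath(name).read_text()


def reference_cohort() -> list[CohortRecord]:
    """The transcribed 29-patient cohort sequencing-results table."""
    return load_cohort(_data_text("cohort29.tsv"))


def reference_cohort_text() -> str:
    return _data_text("cohort29.tsv")


def reference_panel_tiers() -> dict[int, list[str]]:
    """Top two tiers (criterion counts 6 and 5) of the index case's panel."""
    df = pd.read_csv(
        resources.files("vpanel.data").joinpath("panel_tiers.tsv").open(),
        sep="\t",
        comment="#",
    )
    out: dict[int, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(int(row.tier), []).append(str(row.gene))
    return out


def phenotype_label_map() -> dict[str, str]:
    df = pd.read_csv(
        resources.files("vpanel.data").joinpath("phenotype_labels.tsv").open(),
        sep="\t",
        comment="#",
    )
    return dict(zip(df["label"], df["term_id"]))


# --------------------------------------------------------------------------
# seeded random generators


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_terms: int = 50
    max_parents: int = 3
    n_genes: int = 20
    terms_per_gene: tuple[int, int] = (1, 6)
    planted_gene: Optional[str] = None
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_terms < 1 or self.n_genes < 0 or self.max_parents < 1:
            raise ValueError("n_terms >= 1, n_genes >= 0, max_parents >= 1")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise must be a probability")


def _term_id(i: int) -> str:
    return f"TT:{i:07d}"


def gen_ontology(cfg: SimulationConfig) -> str:
    """Random single-rooted DAG as OBO text.

    Term i's parents are sampled among terms < i, which guarantees
    acyclicity and connectivity to the root TT:0000001.
    """
    rng = random.Random(cfg.seed)
    stanzas = [
        "format-version: 1.2",
        "",
        "[Term]",
        f"id: {_term_id(1)}",
        "name: synthetic root",
    ]
    for i in range(2, cfg.n_terms + 1):
        n_parents = rng.randint(1, min(cfg.max_parents, i - 1))
        parents = rng.sample(range(1, i), n_parents)
        stanzas += ["", "[Term]", f"id: {_term_id(i)}", f"name: synthetic term {i}"]
        stanzas += [f"is_a: {_term_id(p)}" for p in sorted(parents)]
    return "\n".join(stanzas) + "\n"


def gen_matching_instance(
    cfg: SimulationConfig, n_query_terms: int = 4
) -> tuple[str, str, PhenotypeQuery]:
    """Random (ontology OBO, annotation TSV, query) triple for match tests.

    When ``cfg.planted_gene`` is set, that gene is annotated inside every
    query criterion's descendant closure (full match), and every other gene
    is denied at least one criterion, so the planted gene uniquely occupies
    the top tier under descendant-only matching.
    """
    obo = gen_ontology(cfg)
    onto = parse_obo(obo)
    rng = random.Random(cfg.seed + 1)
    term_ids = sorted(onto.terms)
    k = min(n_query_terms, len(term_ids))
    query_terms = rng.sample(term_ids, k)
    query = PhenotypeQuery(terms=tuple(query_terms))

    rows = ["gene_symbol\tdisease_id\thpo_id\tinheritance"]
    lo, hi = cfg.terms_per_gene
    for g in range(1, cfg.n_genes + 1):
        gene = f"GENE{g:03d}"
        disease = f"DIS:{g:05d}"
        if gene == cfg.planted_gene:
            pool = [
                rng.choice(sorted(onto.descendants_or_self(qt)))
                for qt in query_terms
            ]
        else:
            # deny one criterion: annotate only outside its closure
            denied = rng.choice(query_terms)
            allowed = [
                t for t in term_ids if t not in onto.descendants_or_self(denied)
            ]
            n = rng.randint(lo, min(hi, max(lo, len(allowed))))
            pool = rng.sample(allowed, min(n, len(allowed))) if allowed else []
        for t in pool:
            rows.append(f"{gene}\t{disease}\t{t}\t")
        if cfg.noise and rng.random() < cfg.noise:
            rows.append(f"{gene}\t{disease}\t{rng.choice(term_ids)}\t")
    return obo, "\n".join(rows) + "\n", query


# --------------------------------------------------------------------------
# the index-case bundle

_CASE_TERMS = [
    # (id, name, parents)
    ("HP:0000001", "All", []),
    ("HP:0000118", "Phenotypic abnormality", ["HP:0000001"]),
    ("HP:0000005", "Mode of inheritance", ["HP:0000001"]),
    ("HP:0000006", "Autosomal dominant inheritance", ["HP:0000005"]),
    ("HP:0000007", "Autosomal recessive inheritance", ["HP:0000005"]),
    ("HP:0001251", "Ataxia", ["HP:0000118"]),
    ("HP:0002066", "Gait ataxia", ["HP:0001251"]),
    ("HP:0001250", "Seizures", ["HP:0000118"]),
    ("HP:0002197", "Generalized-onset seizure", ["HP:0001250"]),
    ("HP:0000565", "Esotropia", ["HP:0000118"]),
    ("HP:0008373", "Puberty and gonadal disorders", ["HP:0000118"]),
    ("HP:0000044", "Hypogonadotropic hypogonadism", ["HP:0008373"]),
    ("HP:0001263", "Global developmental delay", ["HP:0000118"]),
    ("HP:0012736", "Profound global developmental delay", ["HP:0001263"]),
]

#: the six-criterion query of the index case: five core phenotypes plus the
#: autosomal-recessive inheritance pattern
CASE_QUERY_TERMS = (
    "HP:0001251",  # Ataxia
    "HP:0001250",  # Seizures
    "HP:0000565",  # Esotropia
    "HP:0008373",  # Puberty and gonadal disorders
    "HP:0001263",  # Global developmental delay
)

_CASE_VARIANTS = (
    # chrom, pos, ref, alt, cds, protein, parental origin
    ("chr16", 8905018, "T", "C", "c.430T>C", "p.F144L", "paternal"),
    ("chr16", 8941581, "G", "C", "c.640G>C", "p.G214R", "maternal"),
)


@dataclass
class CaseBundle:
    """All inputs of the worked index case, as in-memory text."""

    obo: str
    annotations: str
    query: PhenotypeQuery
    vcf: str
    sidecar: str
    trio: str
    sample: str = "proband"

    def ontology(self) -> Ontology:
        return parse_obo(self.obo)

    def store(self) -> AnnotationStore:
        return load_annotations(self.annotations)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in [
            ("case.obo", self.obo),
            ("annotations.tsv", self.annotations),
            ("proband.vcf", self.vcf),
            ("sidecar.tsv", self.sidecar),
            ("trio.tsv", self.trio),
        ]:
            p = out / name
            p.write_text(text)
            paths[name] = p
        return paths


def _case_obo() -> str:
    chunks = ["format-version: 1.2"]
    for tid, name, parents in _CASE_TERMS:
        chunks += ["", "[Term]", f"id: {tid}", f"name: {name}"]
        chunks += [f"is_a: {p}" for p in parents]
    return "\n".join(chunks) + "\n"


def _case_annotations() -> str:
    rows = ["gene_symbol\tdisease_id\thpo_id\tinheritance"]
    # the causal gene: annotated to specific descendants of each criterion
    for t in ("HP:0002066", "HP:0002197", "HP:0000565", "HP:0000044", "HP:0012736"):
        rows.append(f"PMM2\tOMIM:212065\t{t}\tAR")
    # the other full-match gene: annotated at category level
    for t in CASE_QUERY_TERMS:
        rows.append(f"CEP290\tOMIM:610188\t{t}\tAR")
    # the 29 genes matching the five phenotypes but not the AR criterion
    tier5 = reference_panel_tiers()[5]
    for i, gene in enumerate(tier5):
        for t in CASE_QUERY_TERMS:
            rows.append(f"{gene}\tDIS:{60001 + i}\t{t}\tAD")
    return "\n".join(rows) + "\n"


def _case_vcf() -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr16>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tproband",
    ]
    for chrom, pos, ref, alt, *_ in _CASE_VARIANTS:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t0/1")
    return "\n".join(lines) + "\n"


def _case_sidecar() -> str:
    rows = ["chrom\tpos\tref\talt\tgene\tconsequence\tpop_af\tcds_change\tprotein_change"]
    for chrom, pos, ref, alt, cds, prot, _ in _CASE_VARIANTS:
        rows.append(f"{chrom}\t{pos}\t{ref}\t{alt}\tPMM2\tmissense\t\t{cds}\t{prot}")
    return "\n".join(rows) + "\n"


def _case_trio() -> str:
    rows = ["chrom\tpos\tref\talt\torigin"]
    for chrom, pos, ref, alt, _, _, origin in _CASE_VARIANTS:
        rows.append(f"{chrom}\t{pos}\t{ref}\t{alt}\t{origin}")
    return "\n".join(rows) + "\n"


def gen_case_fixture() -> CaseBundle:
    """The worked index case: compound-heterozygous PMM2 in a six-criterion
    query (ataxia, seizures, esotropia, puberty and gonadal disorders,
    global developmental delay, AR inheritance)."""
    return CaseBundle(
        obo=_case_obo(),
        annotations=_case_annotations(),
        query=PhenotypeQuery.create(list(CASE_QUERY_TERMS), inheritance="AR"),
        vcf=_case_vcf(),
        sidecar=_case_sidecar(),
        trio=_case_trio(),
    )


# --------------------------------------------------------------------------
# synthetic cohorts with planted truth

_DIAG_PATTERNS = ("ad_het", "ar_hom", "ar_comphet", "xr_male", "xd_female")


def gen_cohort(
    cfg: SimulationConfig, n_patients: int, planted_rate: float
) -> tuple[str, dict[str, str]]:
    """Seeded cohort TSV plus a truth table of planted per-patient statuses.

    Planted diagnostic patients get a mode-consistent variant set (drawn
    from AD/AR/X-linked patterns), planted excluded patients get a single
    heterozygous variant in an AR gene, the rest are negative (``ND``).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not (0.0 <= planted_rate <= 1.0):
        raise ValueError("planted_rate must be in [0,1]")
    rng = random.Random(cfg.seed)
    header = (
        "patient_id\tsex\tgene\tposition\tnucleotide_change\t"
        "protein_change\tinheritance\tzygosity"
    )
    rows = [header]
    truth: dict[str, str] = {}
    n_diag = round(planted_rate * n_patients)
    statuses = ["diagnostic"] * n_diag
    for i in range(n_patients - n_diag):
        statuses.append("excluded" if i % 2 == 0 else "negative")
    rng.shuffle(statuses)

    for i, status in enumerate(statuses, start=1):
        pid = f"P{i:03d}"
        truth[pid] = status
        gene = f"GENE{i:03d}"
        if status == "negative":
            sex = rng.choice(("male", "female"))
            rows.append(f"{pid}\t{sex}\tND\tND\tND\tND\tND\t")
            continue
        if status == "excluded":
            sex = rng.choice(("male", "female"))
            pos = rng.randint(10_000, 5_000_000)
            rows.append(
                f"{pid}\t{sex}\tGENE{i:03d}\tchr{rng.randint(1, 22)}:{pos}"
                f"\tc.{rng.randint(1, 999)}A>G\tp.X{rng.randint(1, 333)}Y\tAR\thet"
            )
            continue
        pattern = rng.choice(_DIAG_PATTERNS)
        pos = rng.randint(10_000, 5_000_000)
        cds = rng.randint(1, 999)
        if pattern == "ad_het":
            sex = rng.choice(("male", "female"))
            rows.append(
                f"{pid}\t{sex}\t{gene}\tchr{rng.randint(1, 22)}:{pos}"
                f"\tc.{cds}A>G\tp.X{rng.randint(1, 333)}Y\tAD\thet"
            )
        elif pattern == "ar_hom":
            sex = rng.choice(("male", "female"))
            rows.append(
                f"{pid}\t{sex}\t{gene}\tchr{rng.randint(1, 22)}:{pos}"
                f"\tc.{cds}A>G\tp.X{rng.randint(1, 333)}Y\tAR\thom"
            )
        elif pattern == "ar_comphet":
            sex = rng.choice(("male", "female"))
            chrom = rng.randint(1, 22)
            for j in range(2):
                rows.append(
                    f"{pid}\t{sex}\t{gene}\tchr{chrom}:{pos + j * 1000}"
                    f"\tc.{cds + j}A>G\tp.X{rng.randint(1, 333)}Y\tAR\thet"
                )
        elif pattern == "xr_male":
            rows.append(
                f"{pid}\tmale\t{gene}\tchrX:{pos}"
                f"\tc.{cds}A>G\tp.X{rng.randint(1, 333)}Y\tXR\themi"
            )
        else:  # xd_female
            rows.append(
                f"{pid}\tfemale\t{gene}\tchrX:{pos}"
                f"\tc.{cds}A>G\tp.X{rng.randint(1, 333)}Y\tXD\thet"
            )
    return "\n".join(rows) + "\n", truth
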