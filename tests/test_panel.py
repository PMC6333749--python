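"""Virtual-panel matching, tiering and export."""

import pytest

from vpanel.annotations import Mode, load_annotations
from vpanel.fixtures import (
    SimulationConfig,
    gen_matching_instance,
    reference_panel_tiers,
)
from vpanel.ontology import parse_obo
from vpanel.panel import (
    PanelError,
    PhenotypeQuery,
    build_panel,
    export_panel,
    match_gene,
    parse_panel_json,
)


def reaches(onto, start, target):
    """Walk raw parent links: is *target* an ancestor-or-self of *start*?"""
    stack, seen = [start], set()
    while stack:
        cur = stack.pop()
        if cur == target:
            return True
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(onto.terms[cur].parents)
    return False


def oracle_count(gene, query, onto, store):
    """Brute-force double loop over (query term, annotated term) pairs."""
    count = 0
    for qt in query.terms:
        if any(reaches(onto, a, qt) for a in store.gene_terms(gene)):
            count += 1
    if query.inheritance and (query.inheritance & store.gene_modes(gene)):
        count += 1
    return count


class TestMatchGene:
    def test_full_match_counts_all_six_criteria(self, case_bundle, case_ontology, case_store):
        m = match_gene("PMM2", case_bundle.query, case_ontology, case_store)
        assert m.count == 6
        assert m.inheritance_matched
        assert set(m.matched_terms) == set(case_bundle.query.terms)

    def test_annotated_descendants_satisfy_broad_query_terms(
        self, case_bundle, case_ontology, case_store
    ):
        # PMM2 is annotated only to child terms, never the query terms
        m = match_gene("PMM2", case_bundle.query, case_ontology, case_store)
        assert "HP:0002066" in m.matched_terms["HP:0001251"]

    def test_unannotated_gene_counts_zero(self, case_bundle, case_ontology, case_store):
        m = match_gene("NOSUCH", case_bundle.query, case_ontology, case_store)
        assert m.count == 0 and not m.matched_terms

    def test_unresolvable_query_term_errors(self, case_ontology, case_store):
        q = PhenotypeQuery.create(["HP:0999999"])
        with pytest.raises(PanelError, match="HP:0999999"):
            match_gene("PMM2", q, case_ontology, case_store)

    def test_bidirectional_accepts_annotated_ancestor(self, case_ontology):
        # annotation at category level, query at the more specific child
        store = load_annotations(
            "gene_symbol\tdisease_id\thpo_id\tinheritance\nG1\tD1\tHP:0001251\tAR\n"
        )
        q = PhenotypeQuery.create(["HP:0002066"])  # Gait ataxia
        assert match_gene("G1", q, case_ontology, store).count == 0
        assert match_gene("G1", q, case_ontology, store, bidirectional=True).count == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_counts_equal_brute_force_oracle(self, seed):
        cfg = SimulationConfig(seed=seed, n_terms=50, n_genes=20, noise=0.3)
        obo, ann, query = gen_matching_instance(cfg, n_query_terms=4)
        onto, store = parse_obo(obo), load_annotations(ann)
        for gene in sorted(store.genes):
            m = match_gene(gene, query, onto, store)
            assert m.count == oracle_count(gene, query, onto, store)


class TestBuildPanel:
    def test_case_panel_reproduces_top_two_tiers(self, case_bundle, case_ontology, case_store):
        panel = build_panel(case_bundle.query, case_ontology, case_store)
        expected = reference_panel_tiers()
        assert {m.gene for m in panel.tiers[6]} == set(expected[6])
        assert {m.gene for m in panel.tiers[5]} == set(expected[5])
        assert len(panel.tiers[5]) == 29

    def test_single_partial_match_gets_one_tier(self, case_ontology):
        store = load_annotations(
            "gene_symbol\tdisease_id\thpo_id\tinheritance\n"
            "G1\tD1\tHP:0001251\tAD\nG1\tD1\tHP:0001250\tAD\nG1\tD1\tHP:0000565\tAD\n"
        )
        q = PhenotypeQuery.create(
            ["HP:0001251", "HP:0001250", "HP:0000565", "HP:0008373", "HP:0001263"],
            inheritance="AR",
        )
        panel = build_panel(q, case_ontology, store)
        assert list(panel.tiers) == [3]
        assert [m.gene for m in panel.tiers[3]] == ["G1"]

    def test_empty_query_errors(self, case_ontology, case_store):
        with pytest.raises(PanelError):
            build_panel(PhenotypeQuery(terms=()), case_ontology, case_store)

    def test_empty_store_gives_empty_panel(self, case_ontology, caplog):
        store = load_annotations("gene_symbol\tdisease_id\thpo_id\tinheritance\n")
        panel = build_panel(
            PhenotypeQuery.create(["HP:0001251"]), case_ontology, store
        )
        assert panel.tiers == {}

    def test_tier_partition_no_duplicates(self, case_bundle, case_ontology, case_store):
        panel = build_panel(case_bundle.query, case_ontology, case_store)
        genes = panel.genes
        assert len(genes) == len(set(genes))
        for count, matches in panel.tiers.items():
            assert all(m.count == count for m in matches)
        assert list(panel.tiers) == sorted(panel.tiers, reverse=True)

    @pytest.mark.parametrize("seed", range(20))
    def test_superset_query_never_lowers_counts(self, seed):
        cfg = SimulationConfig(seed=seed, n_terms=40, n_genes=15, noise=0.5)
        obo, ann, query = gen_matching_instance(cfg, n_query_terms=4)
        onto, store = parse_obo(obo), load_annotations(ann)
        smaller = PhenotypeQuery(terms=query.terms[:-1])
        for gene in store.genes:
            c_small = match_gene(gene, smaller, onto, store).count
            c_big = match_gene(gene, query, onto, store).count
            assert c_big >= c_small

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_gene_uniquely_tops_panel(self, seed):
        cfg = SimulationConfig(
            seed=seed, n_terms=50, n_genes=15, planted_gene="GENE007"
        )
        obo, ann, query = gen_matching_instance(cfg, n_query_terms=4)
        panel = build_panel(query, parse_obo(obo), load_annotations(ann))
        top = max(panel.tiers)
        assert top == len(query.terms)
        assert [m.gene for m in panel.tiers[top]] == ["GENE007"]

    def test_deterministic(self, case_bundle, case_ontology, case_store):
        p1 = build_panel(case_bundle.query, case_ontology, case_store)
        p2 = build_panel(case_bundle.query, case_ontology, case_store)
        assert export_panel(p1, "tsv") == export_panel(p2, "tsv")


class TestExport:
    def test_empty_panel_header_only_tsv(self, case_ontology):
        store = load_annotations("gene_symbol\tdisease_id\thpo_id\tinheritance\n")
        panel = build_panel(PhenotypeQuery.create(["HP:0001251"]), case_ontology, store)
        assert export_panel(panel, "tsv") == "tier\tgene\tmatched_criteria\n"

    def test_case_panel_tsv_has_31_rows(self, case_bundle, case_ontology, case_store):
        panel = build_panel(case_bundle.query, case_ontology, case_store)
        rows = export_panel(panel, "tsv").strip().splitlines()
        assert len(rows) == 1 + 31

    def test_json_round_trip(self, case_bundle, case_ontology, case_store):
        panel = build_panel(case_bundle.query, case_ontology, case_store)
        assert parse_panel_json(export_panel(panel, "json")) == panel

    def test_bed_requires_and_uses_coords(self, case_bundle, case_ontology, case_store):
        panel = build_panel(
            case_bundle.query, case_ontology, case_store, min_count=6
        )
        with pytest.raises(PanelError):
            export_panel(panel, "bed")
        coords = {
            "PMM2": ("chr16", 8891553, 8943194),
            "CEP290": ("chr12", 88049013, 88142216),
        }
        bed = export_panel(panel, "bed", gene_coords=coords)
        assert "chr16\t8891553\t8943194\tPMM2" in bed.splitlines()
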