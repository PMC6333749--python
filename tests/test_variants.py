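"""VCF intake, pre-filtering, panel intersection and codon arithmetic."""

import pytest

from vpanel.annotations import Mode
from vpanel.fixtures import gen_case_fixture
from vpanel.panel import build_panel
from vpanel.variants import (
    FilterConfig,
    Variant,
    VariantError,
    codon_from_cds,
    filter_by_panel,
    prefilter,
    read_variants,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr16>\n"
    "##contig=<ID=chr1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tproband\n"
)

SIDECAR_HEADER = (
    "chrom\tpos\tref\talt\tgene\tconsequence\tpop_af\tcds_change\tprotein_change\n"
)


def write_vcf(tmp_path, body, sidecar_rows=""):
    vcf = tmp_path / "v.vcf"
    vcf.write_text(VCF_HEADER + body)
    sc = tmp_path / "s.tsv"
    sc.write_text(SIDECAR_HEADER + sidecar_rows)
    return vcf, sc


class TestReadVariants:
    def test_case_variant_annotated_het(self, tmp_path):
        vcf, sc = write_vcf(
            tmp_path,
            "chr16\t8905018\t.\tT\tC\t.\tPASS\t.\tGT\t0/1\n",
            "chr16\t8905018\tT\tC\tPMM2\tmissense\t\tc.430T>C\tp.F144L\n",
        )
        (v,) = read_variants(vcf, sc, "proband")
        assert (v.chrom, v.pos, v.zygosity, v.gene) == ("chr16", 8905018, "het", "PMM2")
        assert v.protein_change == "p.F144L"

    def test_hom_ref_not_emitted(self, tmp_path):
        vcf, sc = write_vcf(tmp_path, "chr16\t100\t.\tT\tC\t.\tPASS\t.\tGT\t0/0\n")
        assert read_variants(vcf, sc, "proband") == []

    def test_multiallelic_1_2_gives_two_hets(self, tmp_path):
        vcf, sc = write_vcf(tmp_path, "chr1\t500\t.\tA\tC,T\t.\tPASS\t.\tGT\t1/2\n")
        vs = read_variants(vcf, sc, "proband")
        assert [(v.alt, v.zygosity) for v in vs] == [("C", "het"), ("T", "het")]

    def test_hom_alt_and_haploid(self, tmp_path):
        vcf, sc = write_vcf(
            tmp_path,
            "chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\nchr1\t600\t.\tG\tA\t.\tPASS\t.\tGT\t1\n",
        )
        vs = read_variants(vcf, sc, "proband")
        assert [v.zygosity for v in vs] == ["hom", "hemi"]

    def test_missing_sample_errors(self, tmp_path):
        vcf, sc = write_vcf(tmp_path, "")
        with pytest.raises(VariantError, match="nobody"):
            read_variants(vcf, sc, "nobody")

    def test_unannotated_variant_retained_without_gene(self, tmp_path):
        vcf, sc = write_vcf(tmp_path, "chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n")
        (v,) = read_variants(vcf, sc, "proband")
        assert v.gene is None and v.consequence is None

    def test_malformed_sidecar_row_strict(self, tmp_path):
        vcf, sc = write_vcf(
            tmp_path,
            "chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n",
            "chr1\tXXX\tA\tC\tG1\tmissense\t\t\t\n",
        )
        read_variants(vcf, sc, "proband")  # lenient: warn + skip
        with pytest.raises(VariantError):
            read_variants(vcf, sc, "proband", strict=True)

    def test_round_trips_case_bundle(self, case_paths):
        vs = read_variants(case_paths["proband.vcf"], case_paths["sidecar.tsv"], "proband")
        assert {(v.chrom, v.pos, v.ref, v.alt) for v in vs} == {
            ("chr16", 8905018, "T", "C"),
            ("chr16", 8941581, "G", "C"),
        }
        assert all(v.gene == "PMM2" and v.zygosity == "het" for v in vs)


def mkv(pos=100, consequence="missense", pop_af=None, gene="G1", zygosity="het"):
    return Variant(
        chrom="chr1", pos=pos, ref="A", alt="G",
        zygosity=zygosity, gene=gene, consequence=consequence, pop_af=pop_af,
    )


class TestPrefilter:
    def test_synonymous_removed_by_default_whitelist(self):
        assert prefilter([mkv(consequence="synonymous")], FilterConfig()) == []

    def test_missing_af_treated_as_novel_and_kept(self):
        assert prefilter([mkv(pop_af=None)], FilterConfig()) == [mkv()]

    def test_af_threshold_by_gene_mode(self):
        cfg = FilterConfig(max_af_dominant=0.001, max_af_recessive=0.01)
        v = mkv(pop_af=0.005)
        assert prefilter([v], cfg, {"G1": frozenset({Mode.AD})}) == []
        assert prefilter([v], cfg, {"G1": frozenset({Mode.AR})}) == [v]
        assert prefilter([v], cfg, {"G1": frozenset({Mode.AD, Mode.AR})}) == [v]

    def test_matches_independent_predicate_on_random_variants(self):
        import random

        rng = random.Random(7)
        cfg = FilterConfig()
        modes = {
            "G1": frozenset({Mode.AD}),
            "G2": frozenset({Mode.AR}),
            "G3": frozenset({Mode.UNKNOWN}),
        }
        conseqs = ["missense", "synonymous", "frameshift", "other", "splice_site"]
        vs = [
            mkv(
                pos=i + 1,
                consequence=rng.choice(conseqs),
                pop_af=rng.choice([None, 0.0, 0.0005, 0.005, 0.05]),
                gene=rng.choice(["G1", "G2", "G3"]),
            )
            for i in range(50)
        ]

        def keep(v):  # independently coded predicate
            if v.consequence not in (
                "missense", "nonsense", "frameshift", "splice_site", "inframe_indel",
            ):
                return False
            limit = 0.01 if Mode.AR in modes.get(v.gene, set()) else 0.001
            return (v.pop_af or 0.0) <= limit

        assert prefilter(vs, cfg, modes) == [v for v in vs if keep(v)]

    def test_subset_and_idempotent(self):
        vs = [mkv(pos=i, consequence=c) for i, c in enumerate(
            ["missense", "synonymous", "frameshift"], start=1)]
        out = prefilter(vs, FilterConfig())
        assert set(out) <= set(vs)
        assert prefilter(out, FilterConfig()) == out


@pytest.fixture(scope="module")
def case_panel():
    b = gen_case_fixture()
    return build_panel(b.query, b.ontology(), b.store())


class TestFilterByPanel:

    def test_causal_gene_variants_survive_top_tier_cut(self, case_panel):
        vs = [mkv(pos=8905018, gene="PMM2"), mkv(pos=8941581, gene="PMM2")]
        assert filter_by_panel(vs, case_panel, min_tier=6) == vs

    def test_geneless_variants_dropped(self, case_panel):
        vs = [mkv(gene=None), mkv(gene="PMM2")]
        assert filter_by_panel(vs, case_panel, min_tier=0) == [mkv(gene="PMM2")]

    def test_monotone_in_min_tier_and_idempotent(self, case_panel):
        vs = [mkv(gene=g) for g in ["PMM2", "GBA", "NOPE", None]]
        prev = filter_by_panel(vs, case_panel, min_tier=0)
        for t in (1, 5, 6, 7):
            cur = filter_by_panel(vs, case_panel, min_tier=t)
            assert set(cur) <= set(prev)
            assert filter_by_panel(cur, case_panel, min_tier=t) == cur
            prev = cur


class TestCodonArithmetic:
    @pytest.mark.parametrize(
        "cds,codon", [(430, 144), (640, 214), (1, 1), (3, 1), (4, 2)]
    )
    def test_printed_protein_positions(self, cds, codon):
        assert codon_from_cds(cds) == codon

    @pytest.mark.parametrize("k", [1, 2, 7, 100, 5000])
    def test_all_three_positions_of_codon_k(self, k):
        assert {codon_from_cds(3 * k - 2), codon_from_cds(3 * k - 1),
                codon_from_cds(3 * k)} == {k}

    def test_rejects_nonpositive(self):
        with pytest.raises(VariantError):
            codon_from_cds(0)
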