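"""SNP effect classification against a whole-protein translation oracle."""

import numpy as np
import pytest

from evilmap.effects import (
    CODON_TO_AA,
    COMPLEMENT,
    EffectCall,
    classify_snp,
    expected_mutation_load,
    extract_cds,
    summarize_effects,
    translate_cds,
)
from evilmap.model import GeneModel, GenomePosition, VariantCall


def snp(chrom, pos, ref, alt):
    return VariantCall(
        site=GenomePosition(chrom, pos), ref_allele=ref, alt_alleles=(alt,),
        qual=60, depth=30, genotype="hom_alt",
        ref_fwd=0, ref_rev=0, alt_fwd=15, alt_rev=15,
    )


def gene_from_codons(codons, strand="+", chrom="c1", offset=100):
    """Single-exon gene whose CDS is the given codon string."""
    cds = "".join(codons)
    length = len(cds)
    start, end = offset + 1, offset + length
    if strand == "-":
        body = "".join(COMPLEMENT[b] for b in reversed(cds))
    else:
        body = cds
    genome = {chrom: "T" * offset + body + "T" * 50}
    gene = GeneModel(
        gene_id="g1", chrom=chrom, start=start, end=end, strand=strand,
        cds_exons=((start, end),),
    )
    return gene, genome


def neutral_codons(n):
    return ["ATG"] + ["CTT"] * (n - 2) + ["TAA"]


class TestWorkedCodonExamples:
    """Six canonical EMS coding changes: codon strings, amino-acid labels
    and impact levels."""

    CASES = [
        # (codon, codon_number, pos_in_codon, expected codon_change,
        #  expected aa_change, category, impact)
        ("GCC", 100, 1, "gCc/gTc", "A100V", "missense", "MODERATE"),
        ("CGG", 138, 1, "cGg/cAg", "R138Q", "missense", "MODERATE"),
        ("GTG", 13, 0, "Gtg/Atg", "V13M", "missense", "MODERATE"),
        ("CCG", 28, 0, "Ccg/Tcg", "P28S", "missense", "MODERATE"),
        ("CGG", 346, 1, "cGg/cAg", "R346Q", "missense", "MODERATE"),
        ("CAG", 225, 0, "Cag/Tag", "Q225stop", "nonsense", "HIGH"),
    ]

    @pytest.mark.parametrize(
        "codon,number,pos_in_codon,codon_change,aa_change,category,impact",
        CASES,
    )
    def test_plus_strand_classification(
        self, codon, number, pos_in_codon, codon_change, aa_change, category, impact
    ):
        codons = neutral_codons(number + 10)
        codons[number - 1] = codon
        gene, genome = gene_from_codons(codons)
        ref = codon[pos_in_codon]
        alt = {"G": "A", "C": "T"}[ref]
        pos = gene.start + (number - 1) * 3 + pos_in_codon
        eff = classify_snp(snp("c1", pos, ref, alt), [gene], genome)
        assert eff.codon_change == codon_change
        assert eff.aa_change == aa_change
        assert eff.category == category
        assert eff.impact == impact

    @pytest.mark.parametrize(
        "codon,number,pos_in_codon,codon_change,aa_change,category,impact",
        CASES,
    )
    def test_minus_strand_mirror_gives_identical_effect(
        self, codon, number, pos_in_codon, codon_change, aa_change, category, impact
    ):
        codons = neutral_codons(number + 10)
        codons[number - 1] = codon
        gene, genome = gene_from_codons(codons, strand="-")
        ref_coding = codon[pos_in_codon]
        alt_coding = {"G": "A", "C": "T"}[ref_coding]
        # genomic position of this CDS offset on the minus strand
        pos = gene.end - ((number - 1) * 3 + pos_in_codon)
        eff = classify_snp(
            snp("c1", pos, COMPLEMENT[ref_coding], COMPLEMENT[alt_coding]),
            [gene],
            genome,
        )
        assert eff.codon_change == codon_change
        assert eff.aa_change == aa_change
        assert eff.category == category
        assert eff.impact == impact


class TestOtherCategories:
    def test_synonymous_third_position(self):
        codons = neutral_codons(12)
        codons[5] = "CTG"  # CTG -> CTA is Leu -> Leu
        gene, genome = gene_from_codons(codons)
        pos = gene.start + 5 * 3 + 2
        eff = classify_snp(snp("c1", pos, "G", "A"), [gene], genome)
        assert eff.category == "synonymous"
        assert eff.impact == "LOW"

    def test_start_codon_destruction(self):
        gene, genome = gene_from_codons(neutral_codons(12))
        eff = classify_snp(snp("c1", gene.start, "A", "T"), [gene], genome)
        assert eff.category == "start_loss"
        assert eff.impact == "HIGH"

    def test_stop_codon_loss(self):
        gene, genome = gene_from_codons(neutral_codons(12))
        # terminal TAA -> CAA removes the stop
        pos = gene.end - 2
        eff = classify_snp(snp("c1", pos, "T", "C"), [gene], genome)
        assert eff.category == "stop_loss"
        assert eff.impact == "HIGH"

    def test_intergenic_and_intronic_and_splice(self):
        chrom = "c1"
        genome = {chrom: "T" * 1000}
        seq = list(genome[chrom])
        # two-exon gene: CDS [101,130] + [201,230], intron (131..200)
        cds = "".join(neutral_codons(20))
        seq[100:130] = cds[:30]
        seq[200:230] = cds[30:]
        genome = {chrom: "".join(seq)}
        gene = GeneModel(
            gene_id="g1", chrom=chrom, start=101, end=230, strand="+",
            cds_exons=((101, 130), (201, 230)),
        )
        assert classify_snp(snp(chrom, 500, "T", "C"), [gene], genome).category == "intergenic"
        assert classify_snp(snp(chrom, 150, "T", "C"), [gene], genome).category == "intronic"
        assert classify_snp(snp(chrom, 131, "T", "C"), [gene], genome).category == "splice_site"
        assert classify_snp(snp(chrom, 132, "T", "C"), [gene], genome).category == "splice_site"
        assert classify_snp(snp(chrom, 199, "T", "C"), [gene], genome).category == "splice_site"
        assert classify_snp(snp(chrom, 133, "T", "C"), [gene], genome).category == "intronic"

    def test_reference_mismatch_is_error(self):
        gene, genome = gene_from_codons(neutral_codons(12))
        with pytest.raises(ValueError, match="mismatch"):
            classify_snp(snp("c1", gene.start, "G", "A"), [gene], genome)

    def test_untranslatable_gene_falls_back_with_warning(self):
        gene, genome = gene_from_codons(neutral_codons(12))
        broken = GeneModel(
            gene_id="g1", chrom="c1", start=gene.start, end=gene.end,
            strand="+", cds_exons=gene.cds_exons, translatable=False,
        )
        with pytest.warns(UserWarning, match="untranslatable"):
            eff = classify_snp(snp("c1", gene.start + 4, "T", "C"), [broken], genome)
        assert eff.category == "intronic"

    def test_impact_mapping_is_total_and_fixed(self):
        from evilmap.effects import IMPACT

        assert set(IMPACT) == {
            "intergenic", "intronic", "synonymous", "missense",
            "nonsense", "stop_loss", "splice_site", "start_loss",
        }
        with pytest.raises(ValueError):
            EffectCall(category="missense", impact="HIGH")


class TestWholeProteinOracle:
    def test_every_cds_ems_change_matches_translation_diff(self, small_dataset):
        """For one simulated gene per strand, classify every possible
        G:C->A:T CDS change and compare with a brute-force whole-protein
        translation diff."""
        genome = small_dataset.genome
        genes = {g.strand: g for g in small_dataset.genes if g.translatable}
        assert set(genes) == {"+", "-"}
        for gene in genes.values():
            cds = extract_cds(gene, genome)
            protein = translate_cds(cds)
            for offset in range(len(cds)):
                coding_ref = cds[offset]
                coding_alt = {"G": "A", "C": "T"}.get(coding_ref)
                if coding_alt is None:
                    continue
                pos = _genomic(gene, offset)
                if gene.strand == "+":
                    ref, alt = coding_ref, coding_alt
                else:
                    ref, alt = COMPLEMENT[coding_ref], COMPLEMENT[coding_alt]
                eff = classify_snp(snp(gene.chrom, pos, ref, alt), [gene], genome)
                mutant = translate_cds(cds[:offset] + coding_alt + cds[offset + 1 :])
                diffs = [
                    (i, a, b) for i, (a, b) in enumerate(zip(protein, mutant)) if a != b
                ]
                if offset < 3:
                    assert eff.category == ("synonymous" if not diffs else "start_loss")
                elif not diffs:
                    assert eff.category == "synonymous"
                else:
                    (i, a, b) = diffs[0]
                    assert eff.aa_change == (
                        f"{'stop' if a == '*' else a}{i + 1}{'stop' if b == '*' else b}"
                    )
                    expected = (
                        "nonsense" if b == "*" else
                        "stop_loss" if a == "*" else "missense"
                    )
                    assert eff.category == expected


def _genomic(gene, offset):
    remaining = offset
    for s, e in gene.cds_exons:
        length = e - s + 1
        if remaining < length:
            return s + remaining if gene.strand == "+" else e - remaining
        remaining -= length
    raise AssertionError


class TestSummaryAndLoad:
    def test_empty_summary_is_all_zero(self):
        out = summarize_effects([])
        assert all(v == 0 for v in out.values())

    def test_summary_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        cats = ["intergenic", "intronic", "synonymous", "missense", "nonsense"]
        from evilmap.effects import IMPACT

        effects = [
            EffectCall(category=c, impact=IMPACT[c])
            for c in rng.choice(cats, size=200)
        ]
        out = summarize_effects(effects)
        for c in cats:
            assert out[c] == sum(e.category == c for e in effects)
        assert out["protein_altering"] == out["missense"] + out["nonsense"]

    def test_expected_load_worked_example(self):
        genic, nonsyn = expected_mutation_load(30_000_000, 1.0 / 125_000.0)
        assert genic == pytest.approx(240.0)
        assert nonsyn == pytest.approx(160.0)

    def test_zero_rate_gives_zero_load(self):
        assert expected_mutation_load(1_000, 0.0) == (0.0, 0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_mutation_load(0, 1e-5)
        with pytest.raises(ValueError):
            expected_mutation_load(100, 1e-5, synonymous_fraction=2.0)
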