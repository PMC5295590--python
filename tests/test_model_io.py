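"""Domain types and lossless format round-trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evilmap import io as emio
from evilmap.model import (
    GeneModel,
    GenomePosition,
    PedigreeEntry,
    PedigreeManifest,
    PipelineParams,
    VariantCall,
)


class TestGenomePosition:
    def test_ordering_is_chrom_then_pos(self):
        a = GenomePosition("chr1", 500)
        b = GenomePosition("chr1", 9)
        c = GenomePosition("chr2", 1)
        assert sorted([c, a, b]) == [b, a, c]

    @pytest.mark.parametrize("chrom,pos", [("", 1), ("chr1", 0), ("chr1", -3)])
    def test_invalid_coordinates_rejected(self, chrom, pos):
        with pytest.raises(ValueError):
            GenomePosition(chrom, pos)


class TestVariantCallInvariants:
    def test_ref_among_alts_rejected(self):
        with pytest.raises(ValueError):
            VariantCall(
                site=GenomePosition("c", 1), ref_allele="G",
                alt_alleles=("G",), qual=10, depth=5, genotype="hom_alt",
            )

    def test_strand_counts_capped_by_depth(self):
        with pytest.raises(ValueError):
            VariantCall(
                site=GenomePosition("c", 1), ref_allele="G", alt_alleles=("A",),
                qual=10, depth=3, genotype="hom_alt",
                ref_fwd=2, ref_rev=2, alt_fwd=2, alt_rev=2,
            )

    def test_duplicate_alts_rejected(self):
        with pytest.raises(ValueError):
            VariantCall(
                site=GenomePosition("c", 1), ref_allele="G",
                alt_alleles=("A", "A"), qual=1, depth=2, genotype="het",
            )


class TestPipelineParams:
    def test_frequency_bounds_validated(self):
        with pytest.raises(ValueError):
            PipelineParams(wt_max_freq=1.5)
        with pytest.raises(ValueError):
            PipelineParams(min_depth=10, max_depth=2)


# ---------------------------------------------------------------------------
# VCF round-trip


@st.composite
def variant_calls(draw):
    n = draw(st.integers(1, 12))
    positions = sorted(
        draw(
            st.lists(st.integers(1, 10_000), min_size=n, max_size=n, unique=True)
        )
    )
    calls = []
    for pos in positions:
        ref = draw(st.sampled_from("ACGT"))
        alts = draw(
            st.lists(
                st.sampled_from([b for b in "ACGT" if b != ref]),
                min_size=1, max_size=2, unique=True,
            )
        )
        depth = draw(st.integers(1, 200))
        rf = draw(st.integers(0, depth))
        rr = draw(st.integers(0, depth - rf))
        af = draw(st.integers(0, depth - rf - rr))
        ar = draw(st.integers(0, depth - rf - rr - af))
        calls.append(
            VariantCall(
                site=GenomePosition("chr1", pos),
                ref_allele=ref,
                alt_alleles=tuple(alts),
                qual=draw(st.floats(0, 255, allow_nan=False)),
                depth=depth,
                genotype=draw(st.sampled_from(["het", "hom_alt"])),
                ref_fwd=rf, ref_rev=rr, alt_fwd=af, alt_rev=ar,
                rms_mapq=draw(st.floats(0, 100, allow_nan=False)),
                dist_to_gap=draw(st.one_of(st.none(), st.integers(0, 500))),
                line_id="lineA",
            )
        )
    return calls


@settings(max_examples=25, deadline=None, derandomize=True)
@given(calls=variant_calls())
def test_vcf_round_trip_preserves_all_consumed_fields(tmp_path_factory, calls):
    """Writing then reading a VCF reproduces every field the filters use."""
    path = tmp_path_factory.mktemp("vcf") / "rt.vcf"
    emio.write_variant_calls(calls, path, line_id="lineA")
    back = emio.read_variant_calls(path)
    assert len(back) == len(calls)
    for orig, rt in zip(calls, back):
        assert rt.site == orig.site
        assert rt.ref_allele == orig.ref_allele
        assert rt.alt_alleles == orig.alt_alleles
        assert rt.depth == orig.depth
        assert rt.genotype == orig.genotype
        assert (rt.ref_fwd, rt.ref_rev, rt.alt_fwd, rt.alt_rev) == (
            orig.ref_fwd, orig.ref_rev, orig.alt_fwd, orig.alt_rev,
        )
        assert rt.dist_to_gap == orig.dist_to_gap
        assert rt.line_id == "lineA"
        # qual/MQ survive to float32 precision (htslib storage)
        assert math.isclose(rt.qual, orig.qual, rel_tol=1e-5, abs_tol=1e-4)
        assert math.isclose(rt.rms_mapq, orig.rms_mapq, rel_tol=1e-5, abs_tol=1e-4)


def test_vcf_reader_counts_and_multiallelic(tmp_path):
    calls = [
        VariantCall(
            site=GenomePosition("chr1", p), ref_allele="G", alt_alleles=alts,
            qual=30, depth=10, genotype="het",
            ref_fwd=2, ref_rev=2, alt_fwd=3, alt_rev=3,
        )
        for p, alts in [(10, ("A",)), (20, ("A", "T")), (30, ("C",))]
    ]
    path = tmp_path / "three.vcf"
    emio.write_variant_calls(calls, path)
    back = emio.read_variant_calls(path)
    assert len(back) == 3
    assert [c.site.pos for c in back] == [10, 20, 30]
    assert back[1].alt_alleles == ("A", "T")


def test_strict_dialect_requires_strand_counts(tmp_path):
    call = VariantCall(
        site=GenomePosition("chr1", 5), ref_allele="G", alt_alleles=("A",),
        qual=30, depth=10, genotype="hom_alt",
    )
    path = tmp_path / "nostrand.vcf"
    emio.write_variant_calls([call], path)
    assert emio.read_variant_calls(path)[0].has_strand_counts is False
    with pytest.raises(ValueError, match="DP4"):
        emio.read_variant_calls(path, dialect=emio.VcfDialect(strict=True))


# ---------------------------------------------------------------------------
# GFF3


GFF_TWO_EXON = """##gff-version 3
c1\tsrc\tgene\t100\t400\t.\t{strand}\t.\tID=g1
c1\tsrc\tmRNA\t100\t400\t.\t{strand}\t.\tID=g1.1;Parent=g1
c1\tsrc\tCDS\t100\t199\t.\t{strand}\t0\tID=g1.1.c;Parent=g1.1
c1\tsrc\tCDS\t300\t400\t.\t{strand}\t0\tID=g1.1.c;Parent=g1.1
"""


def test_gff3_plus_strand_exons_in_file_order(tmp_path):
    p = tmp_path / "plus.gff3"
    p.write_text(GFF_TWO_EXON.format(strand="+"))
    (gene,) = emio.read_gene_models(p)
    assert gene.cds_exons == ((100, 199), (300, 400))
    assert gene.translatable  # 100 + 101 = 201 bases
    assert gene.cds_length == 201


def test_gff3_minus_strand_exons_reversed(tmp_path):
    p = tmp_path / "minus.gff3"
    p.write_text(GFF_TWO_EXON.format(strand="-"))
    (gene,) = emio.read_gene_models(p)
    assert gene.cds_exons == ((300, 400), (100, 199))


def test_gff3_untranslatable_cds_flagged(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tgene\t10\t20\t.\t+\t.\tID=g1\n"
        "c1\tsrc\tmRNA\t10\t20\t.\t+\t.\tID=g1.1;Parent=g1\n"
        "c1\tsrc\tCDS\t10\t19\t.\t+\t0\tID=g1.1.c;Parent=g1.1\n"
    )
    with pytest.warns(UserWarning, match="untranslatable"):
        (gene,) = emio.read_gene_models(p)
    assert not gene.translatable


def test_gff3_orphan_cds_is_error(tmp_path):
    p = tmp_path / "orphan.gff3"
    p.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tCDS\t10\t18\t.\t+\t0\tID=lonely\n"
    )
    with pytest.raises(ValueError, match="orphan"):
        emio.read_gene_models(p)


def test_gff3_round_trip_total_cds_length(small_dataset, tmp_path):
    """Writing then re-reading the simulated annotation preserves structure."""
    genes = small_dataset.genes
    p = tmp_path / "genes.gff3"
    emio.write_gene_models(genes, p)
    back = emio.read_gene_models(p)
    assert len(back) == len(genes)
    for orig, rt in zip(sorted(genes, key=lambda g: (g.chrom, g.start)), back):
        assert rt.gene_id == orig.gene_id
        assert rt.strand == orig.strand
        assert rt.cds_exons == orig.cds_exons
        assert rt.cds_length == sum(e - s + 1 for s, e in orig.cds_exons)


# ---------------------------------------------------------------------------
# FASTA and TSV


def test_fasta_uppercases_sequences(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">c1\nacgt\n")
    assert emio.read_fasta(p) == {"c1": "ACGT"}


def test_fasta_duplicate_header_is_error(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">c1\nACGT\n>c1\nGGCC\n")
    with pytest.raises(ValueError, match="duplicate"):
        emio.read_fasta(p)


def test_fasta_empty_sequence_is_error(tmp_path):
    p = tmp_path / "empty.fa"
    p.write_text(">c1\n\n>c2\nACGT\n")
    with pytest.raises(ValueError, match="empty"):
        emio.read_fasta(p)


def test_fasta_invalid_character_names_position(tmp_path):
    p = tmp_path / "bad.fa"
    p.write_text(">c1\nACGX\n")
    with pytest.raises(ValueError, match="c1:4"):
        emio.read_fasta(p)


def test_fasta_write_read_round_trip(tmp_path):
    genome = {"c1": "ACGT" * 40, "c2": "N" * 10 + "GATTACA"}
    p = tmp_path / "rt.fa"
    emio.write_fasta(genome, p, width=13)
    assert emio.read_fasta(p) == genome


def test_tsv_report_round_trip(tmp_path):
    import pandas as pd

    table = pd.DataFrame(
        {"line": ["a", "b"], "count": [3, 5], "frac": [0.25, 0.75]}
    )
    p = tmp_path / "r.tsv"
    emio.write_tsv_report(table, p)
    back = emio.read_tsv_report(p)
    pd.testing.assert_frame_equal(back, table)


def test_allele_counts_round_trip(small_dataset, tmp_path):
    p = tmp_path / "c.tsv"
    emio.write_allele_counts(small_dataset.counts, p)
    back = emio.read_allele_counts(p)
    assert sorted(back, key=lambda r: (r.line_id, r.site)) == sorted(
        small_dataset.counts, key=lambda r: (r.line_id, r.site)
    )


def test_manifest_round_trip(tmp_path):
    manifest = PedigreeManifest(
        entries=(
            PedigreeEntry("m", "L1", "mutant_pool", 13, 30.0),
            PedigreeEntry("w", "L1", "wt_sibling", 17, 45.0),
            PedigreeEntry("u", "L2", "unrelated", 1, 3.0),
        )
    )
    p = tmp_path / "ped.yaml"
    emio.write_manifest(manifest, p)
    assert emio.read_manifest(p) == manifest
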