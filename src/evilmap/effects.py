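"""Gene-model-based SNP effect classification and the expected-load calculator.

A SNP is located against the CDS structure of the gene containing it and
classified by translating the reference and mutated codons with the
standard genetic code.  Classes and their impact levels:

    intergenic, intronic        -> MODIFIER
    synonymous                  -> LOW
    missense                    -> MODERATE
    nonsense, splice_site,
    start_loss, stop_loss       -> HIGH

The codon-change string follows the "mutated base uppercase, rest
lowercase" convention (e.g. ``Cag/Tag``); amino-acid changes read
refAA + codon number + altAA, with ``stop`` for a termination codon
(``Q225stop``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .model import GeneModel, GenomePosition, VariantCall

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Intronic bases on each side of an exon junction treated as splice sites.
SPLICE_WINDOW = 2

IMPACT = {
    "intergenic": "MODIFIER",
    "intronic": "MODIFIER",
    "synonymous": "LOW",
    "missense": "MODERATE",
    "nonsense": "HIGH",
    "stop_loss": "HIGH",
    "splice_site": "HIGH",
    "start_loss": "HIGH",
}

PROTEIN_ALTERING = ("missense", "nonsense", "stop_loss", "splice_site", "start_loss")


@dataclass(frozen=True)
class EffectCall:
    category: str
    impact: str
    gene_id: Optional[str] = None
    codon_change: Optional[str] = None
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if IMPACT[self.category] != self.impact:
            raise ValueError(f"{self.category} must map to {IMPACT[self.category]}")


def _aa_label(aa: str) -> str:
    return "stop" if aa == "*" else aa


def _format_codon(codon: str, mutated_index: int) -> str:
    return "".join(
        b.upper() if i == mutated_index else b.lower() for i, b in enumerate(codon)
    )


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3) into a protein string."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def extract_cds(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Spliced CDS sequence, 5'->3' on the coding strand."""
    seq = genome[gene.chrom]
    parts = []
    for s, e in gene.cds_exons:
        exon = seq[s - 1 : e]
        if gene.strand == "-":
            exon = "".join(COMPLEMENT[b] for b in reversed(exon))
        parts.append(exon)
    return "".join(parts)


def _cds_offset(gene: GeneModel, pos: int) -> Optional[int]:
    """0-based position within the spliced CDS, or None when intronic."""
    offset = 0
    for s, e in gene.cds_exons:
        if s <= pos <= e:
            if gene.strand == "+":
                return offset + (pos - s)
            return offset + (e - pos)
        offset += e - s + 1
    return None


def _is_splice_proximal(gene: GeneModel, pos: int) -> bool:
    """Within SPLICE_WINDOW intronic bases of an internal exon junction."""
    if len(gene.cds_exons) < 2:
        return False
    genomic = sorted(gene.cds_exons)
    first, last = genomic[0], genomic[-1]
    for s, e in genomic:
        # donor/acceptor sides are internal boundaries only
        if (s, e) != first and s - SPLICE_WINDOW <= pos < s:
            return True
        if (s, e) != last and e < pos <= e + SPLICE_WINDOW:
            return True
    return False


def classify_snp(
    snp: VariantCall,
    gene_models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> EffectCall:
    """Classify a biallelic SNP against gene models and the genome.

    The genome's base at the SNP position must match the record's reference
    allele.  Genes flagged untranslatable fall back to intronic/intergenic
    classification with a warning.
    """
    if len(snp.alt_alleles) != 1:
        raise ValueError("classify_snp requires a biallelic SNP")
    site = snp.site
    ref_base = genome[site.chrom][site.pos - 1]
    if ref_base != snp.ref_allele:
        raise ValueError(
            f"reference mismatch at {site}: genome has {ref_base}, record has {snp.ref_allele}"
        )
    gene = next((g for g in gene_models if g.contains(site)), None)
    if gene is None:
        return EffectCall(category="intergenic", impact="MODIFIER")
    if not gene.translatable:
        import warnings

        warnings.warn(f"gene {gene.gene_id} untranslatable; intronic/intergenic fallback")
        cat = "intronic"
        return EffectCall(category=cat, impact=IMPACT[cat], gene_id=gene.gene_id)

    offset = _cds_offset(gene, site.pos)
    if offset is None:
        if _is_splice_proximal(gene, site.pos):
            return EffectCall(category="splice_site", impact="HIGH", gene_id=gene.gene_id)
        return EffectCall(category="intronic", impact="MODIFIER", gene_id=gene.gene_id)

    cds = extract_cds(gene, genome)
    codon_index = offset // 3
    pos_in_codon = offset % 3
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    alt_coding = (
        snp.alt_alleles[0] if gene.strand == "+" else COMPLEMENT[snp.alt_alleles[0]]
    )
    alt_codon = (
        ref_codon[:pos_in_codon] + alt_coding + ref_codon[pos_in_codon + 1 :]
    )
    ref_aa = CODON_TO_AA[ref_codon]
    alt_aa = CODON_TO_AA[alt_codon]

    if codon_index == 0 and alt_codon != "ATG":
        category = "start_loss"
    elif ref_aa == "*" and alt_aa != "*":
        category = "stop_loss"
    elif alt_aa == "*" and ref_aa != "*":
        category = "nonsense"
    elif ref_aa == alt_aa:
        category = "synonymous"
    else:
        category = "missense"

    return EffectCall(
        category=category,
        impact=IMPACT[category],
        gene_id=gene.gene_id,
        codon_change=f"{_format_codon(ref_codon, pos_in_codon)}/{_format_codon(alt_codon, pos_in_codon)}",
        aa_change=f"{_aa_label(ref_aa)}{codon_index + 1}{_aa_label(alt_aa)}",
    )


def summarize_effects(effects: Iterable[EffectCall]) -> dict[str, int]:
    """Per-category counts plus the protein-altering total."""
    counts = Counter(e.category for e in effects)
    summary = {cat: counts.get(cat, 0) for cat in IMPACT}
    summary["protein_altering"] = sum(counts.get(cat, 0) for cat in PROTEIN_ALTERING)
    return summary


def expected_mutation_load(
    coding_bp: float,
    per_bp_rate: float,
    synonymous_fraction: float = 1.0 / 3.0,
) -> tuple[float, float]:
    """Expected genic and nonsynonymous mutation counts per line.

    With ``coding_bp`` of protein-coding sequence mutated at ``per_bp_rate``,
    the expected genic load is their product; removing the synonymous
    fraction leaves the potentially causative nonsynonymous load.
    """
    if coding_bp <= 0:
        raise ValueError("coding_bp must be > 0")
    if not (0.0 <= per_bp_rate < 1.0):
        raise ValueError("per_bp_rate must lie in [0, 1)")
    if not (0.0 <= synonymous_fraction <= 1.0):
        raise ValueError("synonymous_fraction must lie in [0, 1]")
    genic = coding_bp * per_bp_rate
    return genic, genic * (1.0 - synonymous_fraction)
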