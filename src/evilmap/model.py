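"""Domain types shared by every stage of the pipeline.

All genomic coordinates in this package are 1-based and inclusive (the
VCF/GFF3 convention).  Conversions to other conventions happen only inside
format readers/writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

BASES = ("A", "C", "G", "T")

#: (ref, alt) pairs consistent with EMS alkylation of guanine, read on the
#: reference strand: G:C -> A:T transitions.
EMS_PAIRS = frozenset({("G", "A"), ("C", "T")})

Genotype = Literal["hom_ref", "het", "hom_alt", "no_call"]
Role = Literal["mutant_pool", "het_sibling", "wt_sibling", "unrelated"]


@dataclass(frozen=True, order=True)
class GenomePosition:
    """A 1-based genomic coordinate; orders by (chrom, pos)."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class VariantCall:
    """One putative SNP in one line, downstream of alignment.

    Strand-resolved read counts (``ref_fwd`` ...) are ``None`` when the
    source format did not carry them; ``dist_to_gap`` is ``None`` when the
    site is far from (or lacks) indel evidence.
    """

    site: GenomePosition
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float
    depth: int
    genotype: Genotype
    ref_fwd: Optional[int] = None
    ref_rev: Optional[int] = None
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None
    rms_mapq: Optional[float] = None
    dist_to_gap: Optional[int] = None
    line_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in BASES:
            raise ValueError(f"bad ref allele {self.ref_allele!r}")
        for a in self.alt_alleles:
            if a not in BASES:
                raise ValueError(f"bad alt allele {a!r}")
        if len(set(self.alt_alleles)) != len(self.alt_alleles):
            raise ValueError("duplicate alt alleles")
        if self.ref_allele in self.alt_alleles:
            raise ValueError("ref allele listed among alts")
        if self.genotype in ("het", "hom_alt") and not self.alt_alleles:
            raise ValueError("variant genotype requires >= 1 alt allele")
        if self.qual < 0 or self.depth < 0:
            raise ValueError("qual and depth must be >= 0")
        counts = [self.ref_fwd, self.ref_rev, self.alt_fwd, self.alt_rev]
        if any(c is not None and c < 0 for c in counts):
            raise ValueError("strand counts must be >= 0")
        if all(c is not None for c in counts) and sum(counts) > self.depth:
            raise ValueError("strand-resolved counts exceed depth")

    @property
    def alt(self) -> Optional[str]:
        """Primary alternate allele (first listed), or None."""
        return self.alt_alleles[0] if self.alt_alleles else None

    @property
    def has_strand_counts(self) -> bool:
        return all(
            c is not None
            for c in (self.ref_fwd, self.ref_rev, self.alt_fwd, self.alt_rev)
        )

    @property
    def ref_count(self) -> Optional[int]:
        if self.ref_fwd is None or self.ref_rev is None:
            return None
        return self.ref_fwd + self.ref_rev

    @property
    def alt_count(self) -> Optional[int]:
        if self.alt_fwd is None or self.alt_rev is None:
            return None
        return self.alt_fwd + self.alt_rev

    def with_(self, **kw) -> "VariantCall":
        return replace(self, **kw)


@dataclass(frozen=True)
class AlleleCountRecord:
    """Per-line, per-position reference/alternate read counts.

    This is the re-pileup surface used for allele-frequency queries: counts
    exist for variant and non-variant sites alike, independent of genotype
    calls.  ``alt_base`` is ``None`` when no alternate base was observed.
    """

    site: GenomePosition
    line_id: str
    ref_count: int
    alt_count: int
    alt_base: Optional[str] = None
    ref_fwd: Optional[int] = None
    ref_rev: Optional[int] = None
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("counts must be >= 0")
        if self.alt_count > 0 and self.alt_base is None:
            raise ValueError("alt_count > 0 requires alt_base")
        if self.alt_base is not None and self.alt_base not in BASES:
            raise ValueError(f"bad alt base {self.alt_base!r}")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def allele_frequency(self) -> Optional[float]:
        """Alternate allele frequency, or None when depth is zero."""
        if self.depth == 0:
            return None
        return self.alt_count / self.depth


@dataclass(frozen=True)
class GeneModel:
    """A stranded protein-coding gene with CDS structure.

    ``cds_exons`` are genomic (start, end) intervals, 1-based inclusive,
    ordered 5'->3' on the coding strand: ascending start for plus-strand
    genes, descending for minus-strand genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"]
    cds_exons: tuple[tuple[int, int], ...]
    description: str = ""
    translatable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.end < self.start:
            raise ValueError("gene end < start")
        ivs = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS exons in {self.gene_id}")
        for s, e in ivs:
            if e < s:
                raise ValueError("CDS exon end < start")
        coding_order = [x[0] for x in self.cds_exons]
        if self.strand == "+" and coding_order != sorted(coding_order):
            raise ValueError("plus-strand CDS exons must ascend")
        if self.strand == "-" and coding_order != sorted(coding_order, reverse=True):
            raise ValueError("minus-strand CDS exons must descend")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    def contains(self, site: GenomePosition) -> bool:
        return site.chrom == self.chrom and self.start <= site.pos <= self.end

    def cds_interval_of(self, pos: int) -> Optional[tuple[int, int]]:
        for s, e in self.cds_exons:
            if s <= pos <= e:
                return (s, e)
        return None


@dataclass(frozen=True)
class PedigreeEntry:
    line_id: str
    lineage_id: str
    role: Role
    pool_size: int = 1
    target_depth: float = 30.0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")


@dataclass(frozen=True)
class PedigreeManifest:
    """Sequenced lines, their mutagenesis lineage, and their mapping role."""

    entries: tuple[PedigreeEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.line_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate line_id in manifest")

    def line_ids(self) -> list[str]:
        return [e.line_id for e in self.entries]

    def entry(self, line_id: str) -> PedigreeEntry:
        for e in self.entries:
            if e.line_id == line_id:
                return e
        raise KeyError(f"line {line_id!r} not in manifest")

    def lineage_of(self, line_id: str) -> str:
        return self.entry(line_id).lineage_id

    def lines_of_lineage(self, lineage_id: str) -> list[str]:
        return [e.line_id for e in self.entries if e.lineage_id == lineage_id]

    def lineages(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.lineage_id not in seen:
                seen.append(e.lineage_id)
        return seen

    def line_with_role(self, role: Role) -> str:
        hits = [e.line_id for e in self.entries if e.role == role]
        if len(hits) != 1:
            raise ValueError(
                f"expected exactly one {role} line, found {len(hits)}"
            )
        return hits[0]

    def validate_mapping_roles(self) -> None:
        """A mapping run needs exactly one mutant pool and one of each sibling."""
        for role in ("mutant_pool", "het_sibling", "wt_sibling"):
            self.line_with_role(role)  # raises when missing/duplicated


@dataclass(frozen=True)
class PipelineParams:
    """Every numeric threshold used by the filtering and mapping stages.

    Defaults correspond to: depth in [2, 100], RMS mapping quality >= 10,
    no SNP within 3 bp of a gap, homozygous calls at Phred quality >= 20
    with zero reference reads and alternate support on both strands, and a
    G:C->A:T spectrum requirement.
    """

    min_depth: int = 2
    max_depth: int = 100
    min_rms_mapq: float = 10.0
    gap_window: int = 3
    min_hom_qual: float = 20.0
    require_zero_ref_reads: bool = True
    require_both_strands: bool = True
    ems_spectrum_only: bool = True
    strict_strand_counts: bool = True
    het_freq_window: tuple[float, float] = (0.2, 0.8)
    hom_alt_min_freq: float = 0.9
    wt_max_freq: float = 0.2
    min_interval_markers: int = 3
    # Below this many reads a frequency-window verdict is not trusted to
    # exclude a candidate; near-misses become "insufficient coverage".
    min_consistency_depth: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.min_depth <= self.max_depth):
            raise ValueError("need 0 <= min_depth <= max_depth")
        lo, hi = self.het_freq_window
        for f in (lo, hi, self.hom_alt_min_freq, self.wt_max_freq):
            if not (0.0 <= f <= 1.0):
                raise ValueError("frequency bounds must lie in [0, 1]")
        if lo > hi:
            raise ValueError("het_freq_window low > high")


def is_ems_pair(ref: str, alt: str) -> bool:
    """True when (ref, alt) is a G:C->A:T transition on the reference strand."""
    return (ref, alt) in EMS_PAIRS


def sort_calls(calls: Sequence[VariantCall]) -> list[VariantCall]:
    return sorted(calls, key=lambda c: c.site)
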