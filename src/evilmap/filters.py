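"""Sequential SNP quality-filter cascade with per-stage survivor accounting.

The cascade removes, in order: extreme-depth sites (repetitive or
under-covered), poorly mapped sites, gap-proximal sites, multi-allelic
positions, non-homozygous or low-quality calls, sites with reference-read
contamination or single-strand support, and finally every change outside
the EMS G:C->A:T spectrum.  Each filter retains records on the inclusive
side of its threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    GenomePosition,
    PipelineParams,
    VariantCall,
    is_ems_pair,
)

#: Stage names for the five reported checkpoints of the cascade.
STAGE_NAMES = (
    "Initial",
    "Q10 No Repeat",
    "Q20 Homozygous",
    "No Reference Calls",
    "G/A, C/T",
)


@dataclass(frozen=True)
class FilterReport:
    """Ordered (stage name, survivor count) accounting for one line."""

    line_id: str
    stages: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = [n for _, n in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("stage counts must be non-increasing")

    def count(self, stage: str) -> int:
        for name, n in self.stages:
            if name == stage:
                return n
        raise KeyError(stage)

    @property
    def initial(self) -> int:
        return self.stages[0][1]

    @property
    def final(self) -> int:
        return self.stages[-1][1]


def filter_depth(
    calls: Sequence[VariantCall], min_depth: int = 2, max_depth: int = 100
) -> list[VariantCall]:
    """Retain calls with min_depth <= depth <= max_depth (both inclusive)."""
    return [c for c in calls if min_depth <= c.depth <= max_depth]


def filter_rms_mapq(
    calls: Sequence[VariantCall], min_rms: float = 10.0
) -> list[VariantCall]:
    """Retain calls with RMS mapping quality >= min_rms.

    Records without an RMS mapping quality pass (their provenance predates
    this annotation); the condition is logged through the returned list
    only.
    """
    return [c for c in calls if c.rms_mapq is None or c.rms_mapq >= min_rms]


def filter_gap_proximity(
    calls: Sequence[VariantCall],
    indel_sites: Optional[Iterable[GenomePosition]] = None,
    window: int = 3,
) -> list[VariantCall]:
    """Remove calls within ``window`` bases of indel/gap evidence.

    Uses explicit indel positions when given, else each record's own
    ``dist_to_gap`` annotation (records lacking both are treated as far
    from any gap).
    """
    if indel_sites is not None:
        by_chrom: dict[str, list[int]] = {}
        for s in indel_sites:
            by_chrom.setdefault(s.chrom, []).append(s.pos)
        for v in by_chrom.values():
            v.sort()
        import bisect

        def near_gap(c: VariantCall) -> bool:
            positions = by_chrom.get(c.site.chrom)
            if not positions:
                return False
            i = bisect.bisect_left(positions, c.site.pos)
            for j in (i - 1, i):
                if 0 <= j < len(positions) and abs(positions[j] - c.site.pos) <= window:
                    return True
            return False

        return [c for c in calls if not near_gap(c)]
    return [c for c in calls if c.dist_to_gap is None or c.dist_to_gap > window]


def filter_biallelic(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Keep only biallelic positions.

    Removes records carrying more than one alternate allele and, when the
    same position appears in several records with different alternates,
    removes every record at that position.
    """
    single = [c for c in calls if len(c.alt_alleles) == 1]
    alts_at: dict[GenomePosition, set[str]] = {}
    for c in single:
        alts_at.setdefault(c.site, set()).add(c.alt_alleles[0])
    return [c for c in single if len(alts_at[c.site]) == 1]


def filter_hom_qual(
    calls: Sequence[VariantCall], min_qual: float = 20.0
) -> list[VariantCall]:
    """Retain homozygous-alternate calls with quality >= min_qual."""
    return [c for c in calls if c.genotype == "hom_alt" and c.qual >= min_qual]


def filter_strand_and_purity(
    calls: Sequence[VariantCall],
    require_zero_ref_reads: bool = True,
    require_both_strands: bool = True,
    strict_strand_counts: bool = True,
) -> list[VariantCall]:
    """Require no reference reads and alternate support on both strands.

    Records lacking strand-resolved counts fail when
    ``strict_strand_counts`` (the default); the escape hatch lets data from
    callers without allelic-depth annotations through unchecked.
    """
    out: list[VariantCall] = []
    for c in calls:
        if not c.has_strand_counts:
            if not strict_strand_counts:
                out.append(c)
            continue
        if require_zero_ref_reads and (c.ref_fwd + c.ref_rev) != 0:
            continue
        if require_both_strands and (c.alt_fwd < 1 or c.alt_rev < 1):
            continue
        out.append(c)
    return out


def filter_ems_spectrum(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Retain only G->A and C->T changes (reference strand)."""
    return [
        c
        for c in calls
        if len(c.alt_alleles) == 1 and is_ems_pair(c.ref_allele, c.alt_alleles[0])
    ]


def run_cascade(
    calls: Sequence[VariantCall],
    params: PipelineParams = PipelineParams(),
    indel_sites: Optional[Iterable[GenomePosition]] = None,
    line_id: Optional[str] = None,
) -> tuple[list[VariantCall], FilterReport]:
    """Apply the full filter cascade to one line's calls.

    Returns the survivors and a five-checkpoint report: the initial count;
    after depth/mapping-quality/gap/biallelic screening; after the
    homozygous Q20 requirement; after the zero-reference both-strand
    requirement; and after the EMS-spectrum restriction.
    """
    if line_id is None:
        line_id = next((c.line_id for c in calls if c.line_id), "unknown")
    stages: list[tuple[str, int]] = [(STAGE_NAMES[0], len(calls))]

    cur = filter_depth(list(calls), params.min_depth, params.max_depth)
    cur = filter_rms_mapq(cur, params.min_rms_mapq)
    cur = filter_gap_proximity(cur, indel_sites, params.gap_window)
    cur = filter_biallelic(cur)
    stages.append((STAGE_NAMES[1], len(cur)))

    cur = filter_hom_qual(cur, params.min_hom_qual)
    stages.append((STAGE_NAMES[2], len(cur)))

    cur = filter_strand_and_purity(
        cur,
        require_zero_ref_reads=params.require_zero_ref_reads,
        require_both_strands=params.require_both_strands,
        strict_strand_counts=params.strict_strand_counts,
    )
    stages.append((STAGE_NAMES[3], len(cur)))

    if params.ems_spectrum_only:
        cur = filter_ems_spectrum(cur)
    stages.append((STAGE_NAMES[4], len(cur)))

    return cur, FilterReport(line_id=line_id, stages=tuple(stages))
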