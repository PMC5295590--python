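"""Allele-frequency cosegregation mapping of a recessive mutant.

Markers are the mutant pool's filtered homozygous SNPs.  Reading their raw
allele frequencies in the wild-type sibling pool localizes the causal
region: only there does the wild-type sibling carry reference alleles at
positions the mutant pool fixed ("Hormigas" scatter, each marker one ant).
A candidate is pedigree-consistent when it is near-fixed in the mutant
pool, intermediate in the heterozygous sibling, and near-absent in the
wild-type sibling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .effects import EffectCall
from .model import (
    AlleleCountRecord,
    GenomePosition,
    PedigreeManifest,
    PipelineParams,
    VariantCall,
)


@dataclass(frozen=True)
class HormigasRow:
    """Alternate-allele frequency of one marker in one query line."""

    site: GenomePosition
    marker_line: str
    query_line: str
    frequency: Optional[float]  # None when the query line has no coverage
    depth: int


@dataclass(frozen=True)
class LinkedInterval:
    chrom: str
    start: int
    end: int
    n_supporting_markers: int
    mean_query_frequency: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("interval end < start")

    def contains(self, site: GenomePosition) -> bool:
        return site.chrom == self.chrom and self.start <= site.pos <= self.end


@dataclass(frozen=True)
class CandidateSNP:
    call: VariantCall
    effect: Optional[EffectCall]
    role_frequencies: Mapping[str, tuple[Optional[float], int]]
    verdict: str  # consistent | inconsistent | insufficient_coverage
    reasons: tuple[str, ...] = ()


CountsIndex = Mapping[tuple[str, str, int], AlleleCountRecord]


def index_counts(records: Iterable[AlleleCountRecord]) -> dict:
    """(line_id, chrom, pos) -> AlleleCountRecord lookup."""
    out: dict[tuple[str, str, int], AlleleCountRecord] = {}
    for r in records:
        out[(r.line_id, r.site.chrom, r.site.pos)] = r
    return out


def allele_frequencies_at(
    positions: Sequence[GenomePosition],
    counts: CountsIndex,
    query_line: str,
    marker_line: str = "",
) -> list[HormigasRow]:
    """Raw alternate-allele frequency of the query line at marker positions.

    Frequencies come straight from read counts, independent of any
    genotype call; positions missing from the count table (or with zero
    depth) yield a missing frequency.
    """
    rows: list[HormigasRow] = []
    for site in sorted(positions):
        rec = counts.get((query_line, site.chrom, site.pos))
        if rec is None:
            rows.append(HormigasRow(site, marker_line, query_line, None, 0))
        else:
            rows.append(
                HormigasRow(
                    site, marker_line, query_line, rec.allele_frequency, rec.depth
                )
            )
    return rows


def detect_linked_interval(
    rows: Sequence[HormigasRow],
    params: PipelineParams = PipelineParams(),
) -> list[LinkedInterval]:
    """Runs of consecutive markers whose query-line frequency stays low.

    Scans each chromosome's markers in positional order for maximal runs of
    at least ``min_interval_markers`` consecutive markers with frequency
    <= ``wt_max_freq`` (missing frequencies break a run).  Intervals span
    the first to last qualifying marker and rank by marker count
    descending, then lower mean frequency, then coordinate.
    """
    rows = sorted(rows, key=lambda r: r.site)
    intervals: list[LinkedInterval] = []
    run: list[HormigasRow] = []

    def flush() -> None:
        if len(run) >= params.min_interval_markers:
            freqs = [r.frequency for r in run]
            intervals.append(
                LinkedInterval(
                    chrom=run[0].site.chrom,
                    start=run[0].site.pos,
                    end=run[-1].site.pos,
                    n_supporting_markers=len(run),
                    mean_query_frequency=sum(freqs) / len(freqs),
                )
            )
        run.clear()

    prev_chrom: Optional[str] = None
    for r in rows:
        if r.site.chrom != prev_chrom:
            flush()
            prev_chrom = r.site.chrom
        qualifies = r.frequency is not None and r.frequency <= params.wt_max_freq
        if qualifies:
            run.append(r)
        else:
            flush()
    flush()
    intervals.sort(
        key=lambda iv: (
            -iv.n_supporting_markers,
            iv.mean_query_frequency,
            iv.chrom,
            iv.start,
        )
    )
    return intervals


def _role_frequency(
    counts: CountsIndex, line_id: str, site: GenomePosition
) -> tuple[Optional[float], int]:
    rec = counts.get((line_id, site.chrom, site.pos))
    if rec is None:
        return None, 0
    return rec.allele_frequency, rec.depth


def pedigree_consistency_filter(
    candidates: Sequence[VariantCall],
    counts: CountsIndex,
    manifest: PedigreeManifest,
    params: PipelineParams = PipelineParams(),
) -> list[CandidateSNP]:
    """Check each candidate against the three-role segregation pattern.

    consistent: mutant-pool frequency >= hom_alt_min_freq, heterozygous
    sibling inside het_freq_window, wild-type sibling <= wt_max_freq.
    A role whose frequency is missing, or which fails its condition on
    fewer than ``min_consistency_depth`` reads, yields the verdict
    ``insufficient_coverage`` instead of an exclusion: shallow data cannot
    confidently rule a candidate out.  Any condition failing at adequate
    depth yields ``inconsistent``.
    """
    mutant = manifest.line_with_role("mutant_pool")
    het_sib = manifest.line_with_role("het_sibling")
    wt_sib = manifest.line_with_role("wt_sibling")
    lo, hi = params.het_freq_window

    checks = (
        (mutant, lambda f: f >= params.hom_alt_min_freq, "mutant pool not fixed"),
        (het_sib, lambda f: lo <= f <= hi, "het sibling outside window"),
        (wt_sib, lambda f: f <= params.wt_max_freq, "wt sibling carries allele"),
    )
    out: list[CandidateSNP] = []
    for call in candidates:
        freqs: dict[str, tuple[Optional[float], int]] = {}
        reasons: list[str] = []
        shallow = False
        failed = False
        for line_id, ok, label in checks:
            f, depth = _role_frequency(counts, line_id, call.site)
            freqs[line_id] = (f, depth)
            if f is None:
                shallow = True
                reasons.append(f"insufficient coverage in {line_id}")
            elif not ok(f):
                if depth < params.min_consistency_depth:
                    shallow = True
                    reasons.append(
                        f"insufficient coverage in {line_id} ({depth} reads)"
                    )
                else:
                    failed = True
                    reasons.append(label)
        if failed:
            verdict = "inconsistent"
        elif shallow:
            verdict = "insufficient_coverage"
        else:
            verdict = "consistent"
        out.append(
            CandidateSNP(
                call=call,
                effect=None,
                role_frequencies=freqs,
                verdict=verdict,
                reasons=tuple(reasons),
            )
        )
    return out


@dataclass
class CandidateReport:
    """Ordered filter ledger and the final candidate list."""

    steps: list[tuple[str, int]]
    final: list[CandidateSNP]
    interval: Optional[LinkedInterval]
    interval_applied: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_candidates"])


def rank_candidates(
    survivors: Sequence[VariantCall],
    unique_sites: set[GenomePosition],
    sibling_called_sites: set[GenomePosition],
    effects: Mapping[GenomePosition, EffectCall],
    counts: CountsIndex,
    manifest: PedigreeManifest,
    intervals: Sequence[LinkedInterval],
    params: PipelineParams = PipelineParams(),
) -> CandidateReport:
    """Reduce the mutant pool's survivors to final causal candidates.

    Chain: cascade survivors -> lineage-unique -> not called in sibling
    lines -> protein-altering -> pedigree-consistent (or retained with
    insufficient coverage) -> inside the top linked interval.  When no
    interval was detected the last step is skipped and flagged.
    """
    steps: list[tuple[str, int]] = [("cascade_survivors", len(survivors))]

    cur = [c for c in survivors if c.site in unique_sites]
    steps.append(("lineage_unique", len(cur)))

    cur = [c for c in cur if c.site not in sibling_called_sites]
    steps.append(("not_in_siblings", len(cur)))

    cur = [
        c
        for c in cur
        if c.site in effects and effects[c.site].impact in ("MODERATE", "HIGH")
    ]
    steps.append(("protein_altering", len(cur)))

    verdicts = pedigree_consistency_filter(cur, counts, manifest, params)
    kept = [v for v in verdicts if v.verdict in ("consistent", "insufficient_coverage")]
    steps.append(("pedigree_consistent", len(kept)))

    top = intervals[0] if intervals else None
    if top is not None:
        kept = [v for v in kept if top.contains(v.call.site)]
        steps.append(("in_top_interval", len(kept)))
        applied = True
    else:
        applied = False

    final = [
        CandidateSNP(
            call=v.call,
            effect=effects.get(v.call.site),
            role_frequencies=v.role_frequencies,
            verdict=v.verdict,
            reasons=v.reasons,
        )
        for v in kept
    ]
    return CandidateReport(steps=steps, final=final, interval=top, interval_applied=applied)
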