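"""Cross-pedigree subtraction of reproducible false-positive positions.

Independently mutagenized lineages cannot share true EMS-induced SNPs
except by coincidence, so any position called in more than one lineage is
an error-prone position (reference error, sub-line drift, or paralogous
alignment).  Subtracting those positions from each line leaves
lineage-unique, likely-EMS variants; positions shared only within a
lineage are retained, since siblings really do share their founder's
mutations.

Position matching is allele-agnostic (chrom + pos), the BEDTools
intersect/subtract convention: an error-prone position may surface
different alleles in different lines.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import GeneModel, GenomePosition, PedigreeManifest, is_ems_pair
from .reports import percent

#: A SNP as carried through subtraction: (position, ref, alt).
Snp = tuple[GenomePosition, str, str]


def positions(snps: Iterable[Snp]) -> set[GenomePosition]:
    return {site for site, _, _ in snps}


def shared_positions(set_a: Iterable[Snp], set_b: Iterable[Snp]) -> set[GenomePosition]:
    """Positions present in both sets, matched by (chrom, pos) only."""
    return positions(set_a) & positions(set_b)


def subtract_other_lineages(
    target_line: str,
    manifest: PedigreeManifest,
    all_sets: Mapping[str, set[Snp]],
) -> set[Snp]:
    """The target line's SNPs at positions absent from every other lineage.

    Positions shared only within the target's own lineage are retained.
    """
    target_lineage = manifest.lineage_of(target_line)  # KeyError if absent
    other_positions: set[GenomePosition] = set()
    for line_id, snps in all_sets.items():
        if manifest.lineage_of(line_id) != target_lineage:
            other_positions |= positions(snps)
    return {s for s in all_sets[target_line] if s[0] not in other_positions}


def venn_counts(sets: Mapping[str, Iterable[Snp]]) -> dict[frozenset, int]:
    """Exclusive-region position counts for three SNP sets.

    Keys are frozensets of member names; values sum to the size of the
    position union.
    """
    if len(sets) != 3:
        raise ValueError("venn_counts expects exactly three sets")
    pos_sets = {name: positions(snps) for name, snps in sets.items()}
    union: set[GenomePosition] = set().union(*pos_sets.values())
    out: dict[frozenset, int] = {}
    names = list(pos_sets)
    for r in (1, 2, 3):
        for combo in combinations(names, r):
            out[frozenset(combo)] = 0
    for p in union:
        members = frozenset(n for n in names if p in pos_sets[n])
        out[members] += 1
    return out


def spectrum_fraction(snps: Iterable[Snp]) -> Optional[float]:
    """Fraction of SNPs that are G:C->A:T transitions; None for empty input."""
    snps = list(snps)
    if not snps:
        return None
    hits = sum(1 for _, ref, alt in snps if is_ems_pair(ref, alt))
    return hits / len(snps)


def coding_position_mask(genes: Sequence[GeneModel]):
    """Membership test for CDS positions, built from gene-model exons."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.cds_exons:
            tree.addi(s, e + 1)  # interval trees are half-open

    def in_coding(site: GenomePosition) -> bool:
        tree = trees.get(site.chrom)
        return bool(tree is not None and tree.overlaps(site.pos))

    return in_coding


def unique_summary(
    manifest: PedigreeManifest,
    all_sets: Mapping[str, set[Snp]],
    coding_mask=None,
) -> pd.DataFrame:
    """Per-line totals, lineage-unique counts and percent-unique.

    Reports all SNPs and, when a coding mask is supplied, the coding-only
    restriction; closes with a Total row of column sums whose percentages
    are recomputed from the summed counts.  One-decimal percentages round
    half up.
    """
    rows = []
    sums = {"total": 0, "unique": 0, "coding_total": 0, "coding_unique": 0}
    for line_id in manifest.line_ids():
        if line_id not in all_sets:
            continue
        snps = all_sets[line_id]
        uniq = subtract_other_lineages(line_id, manifest, all_sets)
        row = {
            "line": line_id,
            "total": len(snps),
            "unique": len(uniq),
            "pct_unique": percent(len(uniq), len(snps)) if snps else float("nan"),
        }
        sums["total"] += len(snps)
        sums["unique"] += len(uniq)
        if coding_mask is not None:
            csnps = {s for s in snps if coding_mask(s[0])}
            cuniq = {s for s in uniq if coding_mask(s[0])}
            row["coding_total"] = len(csnps)
            row["coding_unique"] = len(cuniq)
            row["pct_coding_unique"] = (
                percent(len(cuniq), len(csnps)) if csnps else float("nan")
            )
            sums["coding_total"] += len(csnps)
            sums["coding_unique"] += len(cuniq)
        rows.append(row)
    total_row = {
        "line": "Total",
        "total": sums["total"],
        "unique": sums["unique"],
        "pct_unique": percent(sums["unique"], sums["total"]) if sums["total"] else float("nan"),
    }
    if coding_mask is not None:
        total_row["coding_total"] = sums["coding_total"]
        total_row["coding_unique"] = sums["coding_unique"]
        total_row["pct_coding_unique"] = (
            percent(sums["coding_unique"], sums["coding_total"])
            if sums["coding_total"]
            else float("nan")
        )
    rows.append(total_row)
    return pd.DataFrame(rows)
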