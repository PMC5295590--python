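"""Binomial genotype caller over per-position allele counts.

A deliberately simple consensus model: given ``ref_count`` reference and
``alt_count`` alternate reads, the three diploid genotypes are scored with
binomial likelihoods for the alternate-read count,

    p(alt read | hom_ref) = e / 3        (alternate seen only by error)
    p(alt read | het)     = 1 / 2
    p(alt read | hom_alt) = 1 - e

with ``e`` the per-base error rate.  The call is the maximum-likelihood
genotype (ties resolved toward hom_ref, the conservative choice) and the
variant quality is the Phred-scaled posterior probability that the site is
non-variant under a uniform genotype prior, capped at 255.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.special import gammaln

from .model import AlleleCountRecord, VariantCall

QUAL_CAP = 255.0

_GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """Log-likelihoods of the three diploid genotypes at one site."""

    hom_ref: float
    het: float
    hom_alt: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.hom_ref, self.het, self.hom_alt)

    @property
    def argmax(self) -> str:
        # ties break toward hom_ref: fewer false variants
        vals = self.as_tuple()
        best = max(vals)
        return _GENOTYPES[vals.index(best)]


def _log_binom(k: int, n: int, p: float) -> float:
    if p <= 0.0:
        return 0.0 if k == 0 else -math.inf
    if p >= 1.0:
        return 0.0 if k == n else -math.inf
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * math.log(p) + (n - k) * math.log1p(-p)
    )


def genotype_likelihoods(ref_count: int, alt_count: int, e: float) -> GenotypeLikelihoods:
    if not (0.0 < e < 0.5):
        raise ValueError("error rate must lie in (0, 0.5)")
    n = ref_count + alt_count
    k = alt_count
    return GenotypeLikelihoods(
        hom_ref=_log_binom(k, n, e / 3.0),
        het=_log_binom(k, n, 0.5),
        hom_alt=_log_binom(k, n, 1.0 - e),
    )


def _phred_non_variant(ll: GenotypeLikelihoods) -> float:
    """-10 log10 P(hom_ref | data) under a uniform genotype prior."""
    m = max(ll.as_tuple())
    total = sum(math.exp(v - m) for v in ll.as_tuple())
    post_ref = math.exp(ll.hom_ref - m) / total
    if post_ref <= 0.0:
        return QUAL_CAP
    return min(QUAL_CAP, -10.0 * math.log10(post_ref))


def call_site(
    counts: AlleleCountRecord,
    e: float = 0.001,
    rms_mapq: Optional[float] = None,
    dist_to_gap: Optional[int] = None,
) -> VariantCall:
    """Genotype one site from its allele counts.

    Zero depth yields a no_call with quality 0.  Strand-resolved counts are
    propagated from the record when it carries them.
    """
    site_depth = counts.ref_count + counts.alt_count
    alts = (counts.alt_base,) if counts.alt_base is not None else ()
    common = dict(
        site=counts.site,
        ref_allele=_infer_ref(counts),
        alt_alleles=alts,
        depth=site_depth,
        ref_fwd=counts.ref_fwd,
        ref_rev=counts.ref_rev,
        alt_fwd=counts.alt_fwd,
        alt_rev=counts.alt_rev,
        rms_mapq=rms_mapq,
        dist_to_gap=dist_to_gap,
        line_id=counts.line_id,
    )
    if site_depth == 0:
        return VariantCall(qual=0.0, genotype="no_call", **common)
    ll = genotype_likelihoods(counts.ref_count, counts.alt_count, e)
    genotype = ll.argmax
    if genotype != "hom_ref" and not alts:  # cannot name the allele
        genotype = "hom_ref"
    return VariantCall(qual=_phred_non_variant(ll), genotype=genotype, **common)


def _infer_ref(counts: AlleleCountRecord) -> str:
    # AlleleCountRecord does not carry the reference base; the caller's VCF
    # surface gets it re-attached from the genome by the pipeline.  Use a
    # placeholder that can never collide with the alternate.
    for b in "ACGT":
        if b != counts.alt_base:
            return b
    raise AssertionError("unreachable")


def call_all(
    table: Iterable[AlleleCountRecord],
    e: float = 0.001,
    ref_lookup=None,
    rms_mapq: Optional[float] = None,
    gap_lookup=None,
) -> dict[str, list[VariantCall]]:
    """Genotype a whole allele-count table, grouped per line.

    Output order is deterministic: (chrom, pos) within each line.  Records
    called hom_ref or no_call are excluded from the variant lists (they stay
    available for allele-frequency queries through the count table itself).
    Duplicate (line, site) rows are an error.  ``ref_lookup(site)`` and
    ``gap_lookup(site)`` optionally supply the reference base and the
    distance to the nearest gap evidence.
    """
    seen: set[tuple[str, str, int]] = set()
    by_line: dict[str, list[VariantCall]] = {}
    for rec in table:
        key = (rec.line_id, rec.site.chrom, rec.site.pos)
        if key in seen:
            raise ValueError(f"duplicate allele-count row for {rec.line_id} {rec.site}")
        seen.add(key)
        call = call_site(
            rec,
            e,
            rms_mapq=rms_mapq,
            dist_to_gap=gap_lookup(rec.site) if gap_lookup else None,
        )
        if call.genotype in ("hom_ref", "no_call"):
            continue
        if ref_lookup is not None:
            ref = ref_lookup(rec.site)
            if ref != call.ref_allele:
                if ref in call.alt_alleles:
                    raise ValueError(
                        f"reference base {ref} at {rec.site} equals the alternate"
                    )
                call = call.with_(ref_allele=ref)
        by_line.setdefault(rec.line_id, []).append(call)
    for line in by_line:
        by_line[line].sort(key=lambda c: c.site)
    return by_line
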