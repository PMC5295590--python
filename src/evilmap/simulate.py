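"""Synthetic EMS-pedigree simulator with full ground truth.

Emulates the study design this pipeline exists for: three independent
mutagenesis events, one of which segregates a recessive causal mutation.
The focal lineage is carried through recurrent selfing with recombination
(heterozygotes selected at the causal site each generation), producing a
final segregating family from which a pooled mutant sample, a heterozygous
sibling and a selfed wild-type sibling pool are sequenced at unequal
depths.  Two unrelated lineages are propagated without selection.  Planted
alongside the true G:C->A:T heterozygous EMS mutations are: shared
non-EMS-spectrum background differences (sub-line drift relative to the
reference), error-prone positions that emit spurious alternate reads in
every line regardless of genotype (the read-level signature of paralogy
and misassembly), and indel positions providing gap evidence.

Everything is deterministic given the parameter set and seed.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import io as emio
from .caller import call_all
from .effects import CODON_TO_AA, COMPLEMENT
from .model import (
    AlleleCountRecord,
    GeneModel,
    GenomePosition,
    PedigreeEntry,
    PedigreeManifest,
    VariantCall,
)

BASES = np.array(list("ACGT"))

#: Coding-strand single-base changes in the EMS spectrum that convert a
#: non-stop codon into a stop codon (codon, position, new base).
_STOP_GAIN_CODONS = []
for _codon, _aa in CODON_TO_AA.items():
    if _aa == "*":
        continue
    for _i in range(3):
        _old = _codon[_i]
        _new = {"G": "A", "C": "T"}.get(_old)
        if _new is None:
            continue
        _mut = _codon[:_i] + _new + _codon[_i + 1 :]
        if CODON_TO_AA[_mut] == "*":
            _STOP_GAIN_CODONS.append((_codon, _i, _new))
del _codon, _aa, _i, _old, _new, _mut


@dataclass(frozen=True)
class SimParams:
    """Study-design parameters of the synthetic pedigree.

    Defaults are a desk-scale replica of the real design: a 5 Mb genome in
    two chromosomes carrying 100 genes; an EMS rate of 1/125,000 per bp;
    three generations of selfing after mutagenesis (M1 -> M4) before the
    segregating family; pool sizes 17 (wild-type siblings), 1
    (heterozygous sibling), 13 (mutant pool) and single individuals for the
    unrelated lineages; sequencing depths 45/7/30/3/43.  Crossovers per
    chromosome per meiosis are Poisson(0.1), which keeps the per-Mb
    crossover density at the few-percent-per-Mb scale of a real grass
    genome once the chromosomes are shrunk to 2.5 Mb.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 2_500_000
    n_genes: int = 100
    mean_cds_len: int = 1200
    ems_rate: float = 1.0 / 125_000.0
    generations_selfed: int = 3
    crossovers_per_meiosis: float = 0.1
    seq_error_rate: float = 0.001
    n_error_prone: int = 50
    error_prone_alt_prob: float = 0.9
    n_shared_background: int = 50
    n_indel_sites: int = 100
    end_margin: int = 1000
    max_retries: int = 2000

    def __post_init__(self) -> None:
        for r in (self.ems_rate, self.seq_error_rate, self.error_prone_alt_prob):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.ems_rate * self.genome_length < 1.0:
            raise ValueError("ems_rate too low: expect >= 1 mutation genome-wide")

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length_bp

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


#: The five sequenced lines of the default design and their roles.
DEFAULT_MANIFEST = PedigreeManifest(
    entries=(
        PedigreeEntry("fam1-wt", "fam1", "wt_sibling", pool_size=17, target_depth=45.0),
        PedigreeEntry("fam1-het", "fam1", "het_sibling", pool_size=1, target_depth=7.0),
        PedigreeEntry("fam1-mut", "fam1", "mutant_pool", pool_size=13, target_depth=30.0),
        PedigreeEntry("fam2-1", "fam2", "unrelated", pool_size=1, target_depth=3.0),
        PedigreeEntry("fam3-1", "fam3", "unrelated", pool_size=1, target_depth=43.0),
    )
)

FOCAL_LINEAGE = "fam1"


@dataclass
class Mutation:
    site: GenomePosition
    ref: str
    alt: str
    haplotype: int  # founder haplotype (0 or 1) carrying the change

    def key(self) -> tuple[str, int]:
        return (self.site.chrom, self.site.pos)


@dataclass
class CausalSite:
    site: GenomePosition
    ref: str
    alt: str
    gene_id: str
    codon_index: int  # 1-based
    codon_change: str
    aa_change: str


@dataclass
class SimTruth:
    """Ground truth: the oracle for every recovery test."""

    induced_mutations: dict[str, list[Mutation]]
    causal: CausalSite
    error_prone_sites: list[tuple[GenomePosition, str]]  # (site, spurious base)
    shared_background: list[Mutation]
    indel_sites: list[GenomePosition]
    crossover_log: list[list[int]]
    genotypes: dict[str, dict[tuple[str, int], list[int]]]

    def to_dict(self) -> dict:
        return {
            "induced_mutations": {
                lin: [
                    [m.site.chrom, m.site.pos, m.ref, m.alt, m.haplotype]
                    for m in muts
                ]
                for lin, muts in self.induced_mutations.items()
            },
            "causal": {
                "chrom": self.causal.site.chrom,
                "pos": self.causal.site.pos,
                "ref": self.causal.ref,
                "alt": self.causal.alt,
                "gene_id": self.causal.gene_id,
                "codon_index": self.causal.codon_index,
                "codon_change": self.causal.codon_change,
                "aa_change": self.causal.aa_change,
            },
            "error_prone_sites": [
                [s.chrom, s.pos, b] for s, b in self.error_prone_sites
            ],
            "shared_background": [
                [m.site.chrom, m.site.pos, m.ref, m.alt] for m in self.shared_background
            ],
            "indel_sites": [[s.chrom, s.pos] for s in self.indel_sites],
            "crossover_log": self.crossover_log,
            "genotypes": {
                line: {f"{c}:{p}": g for (c, p), g in sites.items()}
                for line, sites in self.genotypes.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            induced_mutations={
                lin: [
                    Mutation(GenomePosition(c, p), r, a, h)
                    for c, p, r, a, h in muts
                ]
                for lin, muts in d["induced_mutations"].items()
            },
            causal=CausalSite(
                site=GenomePosition(d["causal"]["chrom"], d["causal"]["pos"]),
                ref=d["causal"]["ref"],
                alt=d["causal"]["alt"],
                gene_id=d["causal"]["gene_id"],
                codon_index=d["causal"]["codon_index"],
                codon_change=d["causal"]["codon_change"],
                aa_change=d["causal"]["aa_change"],
            ),
            error_prone_sites=[
                (GenomePosition(c, p), b) for c, p, b in d["error_prone_sites"]
            ],
            shared_background=[
                Mutation(GenomePosition(c, p), r, a, 0)
                for c, p, r, a in d["shared_background"]
            ],
            indel_sites=[GenomePosition(c, p) for c, p in d["indel_sites"]],
            crossover_log=[list(x) for x in d["crossover_log"]],
            genotypes={
                line: {
                    (k.rsplit(":", 1)[0], int(k.rsplit(":", 1)[1])): list(g)
                    for k, g in sites.items()
                }
                for line, sites in d["genotypes"].items()
            },
        )


# ---------------------------------------------------------------------------
# Reference genome and gene models


def simulate_reference(
    params: SimParams, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random uniform-composition genome plus non-overlapping gene models.

    Each gene gets 1-4 CDS exons whose spliced sequence starts with ATG,
    contains no internal stop, ends in a stop codon, and has length
    divisible by three; roughly half the genes sit on each strand.  The
    gene's codons are written back into the genome sequence (reverse
    complemented for minus-strand genes).
    """
    genome_arr = {
        name: rng.choice(BASES, size=params.chrom_length_bp)
        for name in params.chrom_names
    }
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in params.chrom_names}
    non_stop = [c for c, aa in CODON_TO_AA.items() if aa != "*" and c != "ATG"]
    stops = sorted(c for c, aa in CODON_TO_AA.items() if aa == "*")
    for gi in range(params.n_genes):
        placed = False
        for _ in range(params.max_retries):
            chrom = params.chrom_names[int(rng.integers(params.n_chroms))]
            n_exons = int(rng.integers(1, 5))
            n_codons = max(
                100, int(rng.normal(params.mean_cds_len, params.mean_cds_len / 4)) // 3
            )
            cds_len = n_codons * 3
            # split the CDS into exons at codon-multiple boundaries
            if n_exons > 1:
                cuts = sorted(
                    rng.choice(np.arange(1, n_codons), size=n_exons - 1, replace=False)
                )
                exon_lens = np.diff([0, *cuts, n_codons]) * 3
            else:
                exon_lens = np.array([cds_len])
            intron_lens = rng.integers(100, 500, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            lo = params.end_margin
            hi = params.chrom_length_bp - params.end_margin - span
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + span - 1
            if any(s <= end and start <= e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            # genomic exon intervals, ascending
            exons = []
            pos = start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el) - 1))
                if i < n_exons - 1:
                    pos += int(el) + int(intron_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            codons = ["ATG"] + [
                non_stop[int(rng.integers(len(non_stop)))] for _ in range(n_codons - 2)
            ] + [stops[int(rng.integers(len(stops)))]]
            cds_seq = "".join(codons)
            # write CDS into the genome along the coding strand
            coding_exons = exons if strand == "+" else exons[::-1]
            offset = 0
            seq = genome_arr[chrom]
            for s, e in coding_exons:
                length = e - s + 1
                chunk = cds_seq[offset : offset + length]
                if strand == "-":
                    chunk = "".join(COMPLEMENT[b] for b in reversed(chunk))
                seq[s - 1 : e] = np.array(list(chunk))
                offset += length
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    cds_exons=tuple(coding_exons),
                    description="simulated gene",
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place all genes without overlap; enlarge the genome"
            )
    genome = {name: "".join(arr) for name, arr in genome_arr.items()}
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genome, genes


# ---------------------------------------------------------------------------
# Mutation induction


def induce_ems_mutations(
    genome: Mapping[str, str], rate: float, rng: np.random.Generator
) -> list[Mutation]:
    """Independent G->A / C->T mutations, heterozygous on a random founder haplotype.

    Each G or C base mutates with probability scaled so the expected
    genome-wide count equals rate x genome length.
    """
    total_len = sum(len(s) for s in genome.values())
    if rate == 0.0 or total_len == 0:
        return []
    gc_positions: list[tuple[str, np.ndarray, np.ndarray]] = []
    gc_count = 0
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        mask = (arr == b"G") | (arr == b"C")
        idx = np.nonzero(mask)[0]
        gc_positions.append((chrom, idx, arr))
        gc_count += len(idx)
    if gc_count == 0:
        return []
    per_gc = min(1.0, rate * total_len / gc_count)
    muts: list[Mutation] = []
    for chrom, idx, arr in gc_positions:
        hit = idx[rng.random(len(idx)) < per_gc]
        for i in hit:
            ref = arr[i].decode()
            alt = "A" if ref == "G" else "T"
            muts.append(
                Mutation(
                    site=GenomePosition(chrom, int(i) + 1),
                    ref=ref,
                    alt=alt,
                    haplotype=int(rng.integers(2)),
                )
            )
    muts.sort(key=lambda m: m.site)
    return muts


def choose_causal(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    mutations: list[Mutation],
    rng: np.random.Generator,
) -> CausalSite:
    """Plant a premature-stop EMS mutation in a random gene.

    Scans genes in random order for a mid-CDS codon where a single
    G:C->A:T change (on the coding strand) creates a stop codon, appends
    the corresponding mutation to the focal lineage's set, and returns the
    causal-site record.
    """
    from .effects import extract_cds

    order = rng.permutation(len(genes))
    for gidx in order:
        gene = genes[int(gidx)]
        cds = extract_cds(gene, genome)
        n_codons = len(cds) // 3
        candidates = []
        for ci in range(2, n_codons - 1):  # skip start and final codons
            codon = cds[ci * 3 : ci * 3 + 3]
            for tmpl, pos_in_codon, new in _STOP_GAIN_CODONS:
                if codon == tmpl:
                    candidates.append((ci, pos_in_codon, new))
        if not candidates:
            continue
        ci, pos_in_codon, new = candidates[int(rng.integers(len(candidates)))]
        cds_offset = ci * 3 + pos_in_codon
        gpos = _genomic_position(gene, cds_offset)
        codon = cds[ci * 3 : ci * 3 + 3]
        alt_codon = codon[:pos_in_codon] + new + codon[pos_in_codon + 1 :]
        if gene.strand == "+":
            ref, alt = codon[pos_in_codon], new
        else:
            ref, alt = COMPLEMENT[codon[pos_in_codon]], COMPLEMENT[new]
        site = GenomePosition(gene.chrom, gpos)
        if any(m.site == site for m in mutations):
            continue
        mut = Mutation(site=site, ref=ref, alt=alt, haplotype=int(rng.integers(2)))
        mutations.append(mut)
        mutations.sort(key=lambda m: m.site)

        def fmt(c: str, i: int) -> str:
            return "".join(b.upper() if j == i else b.lower() for j, b in enumerate(c))

        return CausalSite(
            site=site,
            ref=ref,
            alt=alt,
            gene_id=gene.gene_id,
            codon_index=ci + 1,
            codon_change=f"{fmt(codon, pos_in_codon)}/{fmt(alt_codon, pos_in_codon)}",
            aa_change=f"{CODON_TO_AA[codon]}{ci + 1}stop",
        )
    raise RuntimeError("no gene offers a premature-stop EMS change")


def _genomic_position(gene: GeneModel, cds_offset: int) -> int:
    """Map a 0-based spliced-CDS offset back to a genomic coordinate."""
    remaining = cds_offset
    for s, e in gene.cds_exons:
        length = e - s + 1
        if remaining < length:
            return s + remaining if gene.strand == "+" else e - remaining
        remaining -= length
    raise ValueError("cds_offset beyond CDS length")


# ---------------------------------------------------------------------------
# Pedigree propagation

# A haplotype mosaic is a list of (end_pos, founder_label) segments covering
# [1, L]; segment i spans (prev_end, end_pos].


def _label_at(mosaic: list[tuple[int, int]], pos: int) -> int:
    ends = [e for e, _ in mosaic]
    i = bisect.bisect_left(ends, pos)
    return mosaic[i][1]


def _slice(mosaic, a: int, b: int):
    """Segments of the mosaic restricted to positions (a, b]."""
    out = []
    prev = 0
    for end, lab in mosaic:
        lo, hi = max(prev, a), min(end, b)
        if lo < hi:
            out.append((hi, lab))
        prev = end
        if prev >= b:
            break
    return out


def meiosis(
    hap_a: list[tuple[int, int]],
    hap_b: list[tuple[int, int]],
    length: int,
    lam: float,
    rng: np.random.Generator,
    crossover_log: Optional[list[list[int]]] = None,
) -> list[tuple[int, int]]:
    """One gamete: Poisson(lam) crossovers at uniform positions, no interference."""
    k = int(rng.poisson(lam))
    xs = sorted(int(x) for x in rng.integers(1, length, size=k)) if k else []
    if crossover_log is not None:
        crossover_log.append(xs)
    cur = int(rng.integers(2))
    sources = (hap_a, hap_b)
    bounds = [0, *xs, length]
    segs: list[tuple[int, int]] = []
    for a, b in zip(bounds, bounds[1:]):
        if a < b:
            segs.extend(_slice(sources[cur], a, b))
        cur ^= 1
    merged: list[tuple[int, int]] = []
    for end, lab in segs:
        if merged and merged[-1][1] == lab:
            merged[-1] = (end, lab)
        else:
            merged.append((end, lab))
    return merged


@dataclass
class Individual:
    """Two haplotype mosaics per chromosome, all descending from one founder."""

    chroms: dict[str, tuple[list[tuple[int, int]], list[tuple[int, int]]]]

    @classmethod
    def founder(cls, chrom_names: Sequence[str], length: int) -> "Individual":
        return cls(
            chroms={n: ([(length, 0)], [(length, 1)]) for n in chrom_names}
        )

    def genotype(self, site: GenomePosition, mut_haplotype: int) -> int:
        """Copies (0/1/2) of a founder mutation carried at this site."""
        hap_a, hap_b = self.chroms[site.chrom]
        return int(_label_at(hap_a, site.pos) == mut_haplotype) + int(
            _label_at(hap_b, site.pos) == mut_haplotype
        )


def _self_offspring(
    parent: Individual,
    length: int,
    lam: float,
    rng: np.random.Generator,
    crossover_log: Optional[list[list[int]]] = None,
) -> Individual:
    return Individual(
        chroms={
            name: (
                meiosis(*parent.chroms[name], length, lam, rng, crossover_log),
                meiosis(*parent.chroms[name], length, lam, rng, crossover_log),
            )
            for name in parent.chroms
        }
    )


def propagate_pedigree(
    mutations_by_lineage: Mapping[str, list[Mutation]],
    causal: CausalSite,
    params: SimParams,
    rng: np.random.Generator,
    manifest: PedigreeManifest = DEFAULT_MANIFEST,
) -> tuple[dict[str, list[Individual]], list[list[int]]]:
    """Propagate every lineage and sample the sequenced individuals.

    The focal lineage is selfed ``generations_selfed`` times, selecting a
    causal-site heterozygote each generation; the final family yields the
    mutant pool (homozygous alternate at the causal site), the heterozygous
    sibling, and a homozygous-reference sibling that is selfed once more to
    form the wild-type pool.  Unrelated lineages are propagated without
    selection.
    """
    L = params.chrom_length_bp
    lam = params.crossovers_per_meiosis
    xlog: list[list[int]] = []
    causal_mut = next(
        m
        for m in mutations_by_lineage[FOCAL_LINEAGE]
        if m.site == causal.site
    )
    individuals: dict[str, list[Individual]] = {}

    for lineage in manifest.lineages():
        founder = Individual.founder(params.chrom_names, L)
        if lineage != FOCAL_LINEAGE:
            parent = founder
            for _ in range(params.generations_selfed):
                parent = _self_offspring(parent, L, lam, rng, xlog)
            for entry in manifest.entries:
                if entry.lineage_id != lineage:
                    continue
                individuals[entry.line_id] = [
                    _self_offspring(parent, L, lam, rng, xlog)
                    for _ in range(entry.pool_size)
                ]
            continue

        # focal lineage: recurrent selection of causal-site heterozygotes
        parent = founder
        for gen in range(params.generations_selfed):
            counts = [0, 0, 0]
            child = None
            for _ in range(params.max_retries):
                cand = _self_offspring(parent, L, lam, rng, xlog)
                g = cand.genotype(causal.site, causal_mut.haplotype)
                counts[g] += 1
                if g == 1:
                    child = cand
                    break
            if child is None:
                raise RuntimeError(
                    f"no causal heterozygote in generation {gen + 1}; "
                    f"segregation counts {counts}"
                )
            parent = child

        need = {
            "mutant_pool": manifest.entry(
                manifest.line_with_role("mutant_pool")
            ).pool_size,
            "het_sibling": 1,
            "wt_sibling": 1,
        }
        got: dict[str, list[Individual]] = {k: [] for k in need}
        counts = [0, 0, 0]
        for _ in range(params.max_retries):
            cand = _self_offspring(parent, L, lam, rng, xlog)
            g = cand.genotype(causal.site, causal_mut.haplotype)
            counts[g] += 1
            if g == 2 and len(got["mutant_pool"]) < need["mutant_pool"]:
                got["mutant_pool"].append(cand)
            elif g == 1 and len(got["het_sibling"]) < need["het_sibling"]:
                got["het_sibling"].append(cand)
            elif g == 0 and len(got["wt_sibling"]) < need["wt_sibling"]:
                got["wt_sibling"].append(cand)
            if all(len(got[k]) >= need[k] for k in need):
                break
        else:
            raise RuntimeError(
                f"required genotype classes missing after {params.max_retries} "
                f"draws; segregation counts {counts}"
            )
        individuals[manifest.line_with_role("mutant_pool")] = got["mutant_pool"]
        individuals[manifest.line_with_role("het_sibling")] = got["het_sibling"]
        wt_ancestor = got["wt_sibling"][0]
        wt_line = manifest.line_with_role("wt_sibling")
        individuals[wt_line] = [
            _self_offspring(wt_ancestor, L, lam, rng, xlog)
            for _ in range(manifest.entry(wt_line).pool_size)
        ]

    return individuals, xlog


# ---------------------------------------------------------------------------
# Read sampling


def sample_read_counts(
    individuals: Mapping[str, list[Individual]],
    mutations_by_lineage: Mapping[str, list[Mutation]],
    shared_background: Sequence[Mutation],
    error_prone_sites: Sequence[tuple[GenomePosition, str]],
    genome: Mapping[str, str],
    params: SimParams,
    rng: np.random.Generator,
    manifest: PedigreeManifest = DEFAULT_MANIFEST,
) -> tuple[list[AlleleCountRecord], dict[str, dict[tuple[str, int], list[int]]]]:
    """Poisson-depth, binomial-allele read counts for every line and site.

    At each site the per-read alternate probability mixes the pooled allele
    dosage with the sequencing error rate; error-prone sites additionally
    replace each read with their site-specific spurious base with
    probability ``error_prone_alt_prob``, in every line, regardless of
    genotype.  Reads split between strands as Binomial(n, 1/2).
    """
    e = params.seq_error_rate
    q = params.error_prone_alt_prob
    spurious: dict[tuple[str, int], str] = {
        (s.chrom, s.pos): b for s, b in error_prone_sites
    }
    site_index: dict[tuple[str, int], dict] = {}
    for lineage, muts in mutations_by_lineage.items():
        for m in muts:
            site_index.setdefault(
                m.key(), {"ref": m.ref, "muts": {}}
            )["muts"][lineage] = m
    for m in shared_background:
        site_index.setdefault(m.key(), {"ref": m.ref, "muts": {}})["background"] = m
    for key, b in spurious.items():
        site_index.setdefault(
            key, {"ref": genome[key[0]][key[1] - 1], "muts": {}}
        )

    base_idx = {b: i for i, b in enumerate("ACGT")}
    records: list[AlleleCountRecord] = []
    genotype_matrix: dict[str, dict[tuple[str, int], list[int]]] = {}

    for entry in manifest.entries:
        pool = individuals[entry.line_id]
        lineage = entry.lineage_id
        gm = genotype_matrix.setdefault(entry.line_id, {})
        for key in sorted(site_index):
            info = site_index[key]
            site = GenomePosition(*key)
            ref = info["ref"]
            mut = info["muts"].get(lineage)
            if mut is not None:
                genos = [ind.genotype(site, mut.haplotype) for ind in pool]
                dosage = sum(genos) / (2 * len(pool))
                alt_true: Optional[str] = mut.alt
                gm[key] = genos
            elif "background" in info:
                dosage, alt_true = 1.0, info["background"].alt
                gm[key] = [2] * len(pool)
            else:
                dosage, alt_true = 0.0, None
                gm[key] = [0] * len(pool)

            n = int(rng.poisson(entry.target_depth))
            if n == 0:
                records.append(
                    AlleleCountRecord(site=site, line_id=entry.line_id,
                                      ref_count=0, alt_count=0)
                )
                continue
            probs = np.zeros(4)
            probs[base_idx[ref]] = (1.0 - dosage) * (1.0 - e)
            for b in "ACGT":
                if b != ref:
                    probs[base_idx[b]] += (1.0 - dosage) * e / 3.0
            if alt_true is not None:
                probs[base_idx[alt_true]] += dosage * (1.0 - e)
                for b in "ACGT":
                    if b != alt_true:
                        probs[base_idx[b]] += dosage * e / 3.0
            elif dosage > 0.0:  # pragma: no cover - defensive
                raise AssertionError("dosage without an alternate allele")
            sp = spurious.get(key)
            if sp is not None:
                probs = (1.0 - q) * probs
                probs[base_idx[sp]] += q
            counts = rng.multinomial(n, probs / probs.sum())
            ref_count = int(counts[base_idx[ref]])
            non_ref = [(b, int(counts[base_idx[b]])) for b in "ACGT" if b != ref]
            non_ref.sort(key=lambda x: (-x[1], x[0]))
            alt_base, alt_count = non_ref[0]
            if alt_count == 0:
                alt_base = None
            ref_fwd = int(rng.binomial(ref_count, 0.5))
            alt_fwd = int(rng.binomial(alt_count, 0.5))
            records.append(
                AlleleCountRecord(
                    site=site,
                    line_id=entry.line_id,
                    ref_count=ref_count,
                    alt_count=alt_count,
                    alt_base=alt_base,
                    ref_fwd=ref_fwd,
                    ref_rev=ref_count - ref_fwd,
                    alt_fwd=alt_fwd,
                    alt_rev=alt_count - alt_fwd,
                )
            )
    return records, genotype_matrix


# ---------------------------------------------------------------------------
# Whole-dataset orchestration


@dataclass
class SimulatedDataset:
    params: SimParams
    manifest: PedigreeManifest
    genome: dict[str, str]
    genes: list[GeneModel]
    counts: list[AlleleCountRecord]
    calls: dict[str, list[VariantCall]]
    truth: SimTruth


def simulate_dataset(
    params: SimParams = SimParams(), seed: int = 1
) -> SimulatedDataset:
    """Run the full generator: reference, mutations, pedigree, reads, calls."""
    rng = np.random.default_rng(seed)
    manifest = DEFAULT_MANIFEST
    genome, genes = simulate_reference(params, rng)

    mutations_by_lineage = {
        lineage: induce_ems_mutations(genome, params.ems_rate, rng)
        for lineage in manifest.lineages()
    }
    causal = choose_causal(genome, genes, mutations_by_lineage[FOCAL_LINEAGE], rng)

    shared_background = _plant_shared_background(genome, params, rng)
    error_prone_sites = _plant_error_prone(genome, params, rng)
    indel_sites = _plant_indels(genome, params, rng)

    individuals, xlog = propagate_pedigree(
        mutations_by_lineage, causal, params, rng, manifest
    )
    counts, genotype_matrix = sample_read_counts(
        individuals,
        mutations_by_lineage,
        shared_background,
        error_prone_sites,
        genome,
        params,
        rng,
        manifest,
    )

    indel_by_chrom: dict[str, list[int]] = {}
    for s in indel_sites:
        indel_by_chrom.setdefault(s.chrom, []).append(s.pos)
    for v in indel_by_chrom.values():
        v.sort()

    def gap_lookup(site: GenomePosition) -> Optional[int]:
        pos_list = indel_by_chrom.get(site.chrom)
        if not pos_list:
            return None
        i = bisect.bisect_left(pos_list, site.pos)
        best = min(
            (abs(pos_list[j] - site.pos) for j in (i - 1, i) if 0 <= j < len(pos_list)),
            default=None,
        )
        return best if best is not None and best <= 1000 else None

    calls = call_all(
        counts,
        e=max(params.seq_error_rate, 1e-4),
        ref_lookup=lambda s: genome[s.chrom][s.pos - 1],
        rms_mapq=60.0,
        gap_lookup=gap_lookup,
    )
    for line_id in manifest.line_ids():
        calls.setdefault(line_id, [])

    truth = SimTruth(
        induced_mutations=mutations_by_lineage,
        causal=causal,
        error_prone_sites=error_prone_sites,
        shared_background=shared_background,
        indel_sites=indel_sites,
        crossover_log=xlog,
        genotypes=genotype_matrix,
    )
    return SimulatedDataset(
        params=params,
        manifest=manifest,
        genome=genome,
        genes=genes,
        counts=counts,
        calls=calls,
        truth=truth,
    )


def _random_sites(
    genome: Mapping[str, str],
    n: int,
    rng: np.random.Generator,
    margin: int,
) -> list[GenomePosition]:
    names = sorted(genome)
    out = []
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(margin + 1, len(genome[chrom]) - margin))
        out.append(GenomePosition(chrom, pos))
    return out


def _plant_shared_background(
    genome: Mapping[str, str], params: SimParams, rng: np.random.Generator
) -> list[Mutation]:
    """Homozygous non-EMS-spectrum differences shared by every lineage.

    These emulate drift between the sequenced material and the reference
    assembly's source line.
    """
    out: list[Mutation] = []
    for site in _random_sites(genome, params.n_shared_background, rng, params.end_margin):
        ref = genome[site.chrom][site.pos - 1]
        choices = [b for b in "ACGT" if b != ref and (ref, b) not in {("G", "A"), ("C", "T")}]
        alt = choices[int(rng.integers(len(choices)))]
        out.append(Mutation(site=site, ref=ref, alt=alt, haplotype=0))
    out.sort(key=lambda m: m.site)
    return out


def _plant_error_prone(
    genome: Mapping[str, str], params: SimParams, rng: np.random.Generator
) -> list[tuple[GenomePosition, str]]:
    """Positions that spuriously emit one fixed non-reference base in all lines."""
    out = []
    for site in _random_sites(genome, params.n_error_prone, rng, params.end_margin):
        ref = genome[site.chrom][site.pos - 1]
        choices = [b for b in "ACGT" if b != ref]
        out.append((site, choices[int(rng.integers(len(choices)))]))
    out.sort(key=lambda x: x[0])
    return out


def _plant_indels(
    genome: Mapping[str, str], params: SimParams, rng: np.random.Generator
) -> list[GenomePosition]:
    return sorted(_random_sites(genome, params.n_indel_sites, rng, 10))


def emit_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as files readable by the io module.

    Emits genome.fa, genes.gff3, per-line <line>.vcf and <line>.counts.tsv,
    pedigree.yaml, and truth.json; byte-identical across runs with the same
    parameters and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    emio.write_fasta(ds.genome, paths["genome"])
    paths["genes"] = outdir / "genes.gff3"
    emio.write_gene_models(ds.genes, paths["genes"])
    paths["manifest"] = outdir / "pedigree.yaml"
    emio.write_manifest(ds.manifest, paths["manifest"])
    by_line: dict[str, list[AlleleCountRecord]] = {}
    for rec in ds.counts:
        by_line.setdefault(rec.line_id, []).append(rec)
    for line_id in ds.manifest.line_ids():
        vcf = outdir / f"{line_id}.vcf"
        emio.write_variant_calls(ds.calls.get(line_id, []), vcf, line_id=line_id)
        paths[f"vcf:{line_id}"] = vcf
        tsv = outdir / f"{line_id}.counts.tsv"
        emio.write_allele_counts(by_line.get(line_id, []), tsv)
        paths[f"counts:{line_id}"] = tsv
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth.to_dict(), fh, indent=1, sort_keys=True)
    return paths
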