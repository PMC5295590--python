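"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 carries variant calls (INFO keys: DP, MQ, a 4-integer
strand-resolved allelic-depth key, and a gap-distance key; all key names
configurable through :class:`VcfDialect`).  GFF3 carries gene models, FASTA
the genome, TSV all tabular reports, YAML the pedigree manifest.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .model import (
    AlleleCountRecord,
    GeneModel,
    GenomePosition,
    PedigreeEntry,
    PedigreeManifest,
    VariantCall,
)

# ---------------------------------------------------------------------------
# VCF


@dataclass(frozen=True)
class VcfDialect:
    """Names of the INFO annotations a caller's VCF carries.

    ``strand_key`` points at a 4-integer ref-fwd, ref-rev, alt-fwd, alt-rev
    allelic depth field (the mpileup ``DP4`` convention).  With
    ``strict=True`` a record missing a required annotation is an error;
    otherwise the field is marked unavailable.
    """

    depth_key: str = "DP"
    mapq_key: str = "MQ"
    strand_key: str = "DP4"
    gap_key: str = "DGAP"
    strict: bool = False


_GT_STRINGS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "no_call": "./."}
_GT_TYPES = {0: "hom_ref", 1: "het", 2: "no_call", 3: "hom_alt"}


def write_variant_calls(
    calls: Sequence[VariantCall],
    path: str | Path,
    line_id: str = "sample",
    dialect: VcfDialect = VcfDialect(),
) -> None:
    """Write calls as a single-sample VCF, sorted by (chrom, pos)."""
    d = dialect
    rows = sorted(calls, key=lambda c: c.site)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({c.site.chrom for c in rows}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f'##INFO=<ID={d.depth_key},Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write(f'##INFO=<ID={d.mapq_key},Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write(
            f'##INFO=<ID={d.strand_key},Number=4,Type=Integer,'
            'Description="Strand-resolved allelic depths: ref-fwd,ref-rev,alt-fwd,alt-rev">\n'
        )
        fh.write(f'##INFO=<ID={d.gap_key},Number=1,Type=Integer,Description="Distance to nearest gap evidence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{line_id}\n")
        for c in rows:
            info = [f"{d.depth_key}={c.depth}"]
            if c.rms_mapq is not None:
                info.append(f"{d.mapq_key}={c.rms_mapq:g}")
            if c.has_strand_counts:
                info.append(
                    f"{d.strand_key}={c.ref_fwd},{c.ref_rev},{c.alt_fwd},{c.alt_rev}"
                )
            if c.dist_to_gap is not None:
                info.append(f"{d.gap_key}={c.dist_to_gap}")
            alt = ",".join(c.alt_alleles) if c.alt_alleles else "."
            fh.write(
                f"{c.site.chrom}\t{c.site.pos}\t.\t{c.ref_allele}\t{alt}\t"
                f"{c.qual:g}\t.\t{';'.join(info)}\tGT\t{_GT_STRINGS[c.genotype]}\n"
            )


def read_variant_calls(
    path: str | Path,
    dialect: VcfDialect = VcfDialect(),
    line_id: Optional[str] = None,
) -> list[VariantCall]:
    """Read a single-sample VCF into VariantCall records, sorted.

    Coordinates are kept 1-based.  Strand counts come from the dialect's
    4-integer allelic-depth key when present, else are marked unavailable
    (``None``); with a strict dialect their absence is an error.
    """
    d = dialect
    out: list[VariantCall] = []
    vcf = VCF(str(path))
    sample = line_id or (vcf.samples[0] if vcf.samples else None)
    for i, v in enumerate(_iter_records(vcf, path), start=1):
        depth = v.INFO.get(d.depth_key)
        if depth is None:
            if d.strict:
                raise ValueError(
                    f"{path}: record {i} missing required {d.depth_key}"
                )
            depth = 0
        dp4 = v.INFO.get(d.strand_key)
        if dp4 is None and d.strict:
            raise ValueError(f"{path}: record {i} missing required {d.strand_key}")
        if dp4 is not None and not isinstance(dp4, tuple):
            dp4 = tuple(dp4)
        mq = v.INFO.get(d.mapq_key)
        gap = v.INFO.get(d.gap_key)
        genotype = _GT_TYPES.get(v.gt_types[0], "no_call") if len(v.gt_types) else "no_call"
        out.append(
            VariantCall(
                site=GenomePosition(v.CHROM, v.POS),
                ref_allele=v.REF,
                alt_alleles=tuple(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                depth=int(depth),
                genotype=genotype,
                ref_fwd=int(dp4[0]) if dp4 else None,
                ref_rev=int(dp4[1]) if dp4 else None,
                alt_fwd=int(dp4[2]) if dp4 else None,
                alt_rev=int(dp4[3]) if dp4 else None,
                rms_mapq=float(mq) if mq is not None else None,
                dist_to_gap=int(gap) if gap is not None else None,
                line_id=sample,
            )
        )
    out.sort(key=lambda c: c.site)
    return out


def _iter_records(vcf: VCF, path):
    it = iter(vcf)
    n = 0
    while True:
        try:
            v = next(it)
        except StopIteration:
            return
        except Exception as exc:  # pragma: no cover - htslib-level failure
            raise ValueError(f"{path}: malformed record after data line {n}: {exc}")
        n += 1
        yield v


# ---------------------------------------------------------------------------
# GFF3


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/CDS features from GFF3 into GeneModel objects.

    CDS exons are grouped per gene and ordered 5'->3' on the coding strand
    (minus-strand genes get their file order reversed).  A gene whose total
    CDS length is not divisible by three is flagged untranslatable with a
    warning; a CDS without a gene ancestor is an error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=True,
    )
    for cds in db.features_of_type("CDS"):
        if not any(True for _ in db.parents(cds, featuretype="gene")):
            raise ValueError(f"orphan CDS {cds.id!r} has no gene ancestor")
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = [
            (c.start, c.end) for c in db.children(g, featuretype="CDS", order_by="start")
        ]
        if not exons:
            continue
        if g.strand == "-":
            exons = exons[::-1]
        translatable = True
        if sum(e - s + 1 for s, e in exons) % 3 != 0:
            warnings.warn(
                f"gene {g.id} CDS length not divisible by 3; flagged untranslatable"
            )
            translatable = False
        desc = ""
        for key in ("description", "Note", "product"):
            if key in g.attributes:
                desc = g.attributes[key][0]
                break
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand,
                cds_exons=tuple(exons),
                description=desc,
                translatable=translatable,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                f"{g.chrom}\tevilmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tevilmap\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in sorted(g.cds_exons):
                fh.write(
                    f"{g.chrom}\tevilmap\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

_VALID_FASTA = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a {chrom: uppercase sequence} map."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r}")
        for i, ch in enumerate(seq, start=1):
            if ch not in _VALID_FASTA:
                raise ValueError(
                    f"non-ACGTN character {ch!r} at {rec.id}:{i}"
                )
        genome[rec.id] = seq
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv_report(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Allele-count tables

_COUNT_COLUMNS = [
    "chrom", "pos", "line_id", "ref_count", "alt_count", "alt_base",
    "ref_fwd", "ref_rev", "alt_fwd", "alt_rev",
]


def write_allele_counts(records: Iterable[AlleleCountRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COUNT_COLUMNS)
        for r in sorted(records, key=lambda r: (r.line_id, r.site)):
            w.writerow(
                [
                    r.site.chrom, r.site.pos, r.line_id, r.ref_count, r.alt_count,
                    r.alt_base if r.alt_base is not None else "none",
                ]
                + ["." if c is None else c for c in (r.ref_fwd, r.ref_rev, r.alt_fwd, r.alt_rev)]
            )


def read_allele_counts(path: str | Path) -> list[AlleleCountRecord]:
    out: list[AlleleCountRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                AlleleCountRecord(
                    site=GenomePosition(row["chrom"], int(row["pos"])),
                    line_id=row["line_id"],
                    ref_count=int(row["ref_count"]),
                    alt_count=int(row["alt_count"]),
                    alt_base=None if row["alt_base"] == "none" else row["alt_base"],
                    **{
                        k: (None if row[k] == "." else int(row[k]))
                        for k in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev")
                    },
                )
            )
    return out


# ---------------------------------------------------------------------------
# Pedigree manifest (YAML)


def write_manifest(manifest: PedigreeManifest, path: str | Path) -> None:
    import yaml

    data = {
        "lines": [
            {
                "line_id": e.line_id,
                "lineage_id": e.lineage_id,
                "role": e.role,
                "pool_size": e.pool_size,
                "target_depth": e.target_depth,
            }
            for e in manifest.entries
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_manifest(path: str | Path) -> PedigreeManifest:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PedigreeManifest(
        entries=tuple(
            PedigreeEntry(
                line_id=d["line_id"],
                lineage_id=d["lineage_id"],
                role=d["role"],
                pool_size=int(d.get("pool_size", 1)),
                target_depth=float(d.get("target_depth", 30.0)),
            )
            for d in data["lines"]
        )
    )
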