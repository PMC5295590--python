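"""End-to-end orchestration: call -> filter -> subtract -> annotate -> map.

``run_end_to_end`` accepts either a self-contained demo configuration
(simulate a dataset, then map it) or paths to an existing dataset, runs
every stage in order, and persists all intermediates as TSV/VCF/JSON so
each number in the final report is recomputable from disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io as emio
from .effects import EffectCall, classify_snp
from .filters import FilterReport, run_cascade
from .mapping import (
    CandidateReport,
    HormigasRow,
    LinkedInterval,
    allele_frequencies_at,
    detect_linked_interval,
    index_counts,
    rank_candidates,
)
from .model import (
    AlleleCountRecord,
    GeneModel,
    GenomePosition,
    PedigreeManifest,
    PipelineParams,
    VariantCall,
)
from .reports import cascade_table
from .simulate import SimParams, SimulatedDataset, emit_dataset, simulate_dataset
from .subtract import (
    Snp,
    coding_position_mask,
    subtract_other_lineages,
    unique_summary,
    venn_counts,
)

log = logging.getLogger("evilmap")


@dataclass
class RunConfig:
    """Inputs for one mapping run.

    In demo mode only ``sim_params`` and ``seed`` are needed; otherwise the
    paths must point at an existing dataset (manifest, genome, annotation,
    per-line VCFs and count tables, and optionally a truth.json supplying
    indel positions).
    """

    outdir: Optional[Path] = None
    seed: int = 1
    params: PipelineParams = field(default_factory=PipelineParams)
    sim_params: Optional[SimParams] = None
    dataset_dir: Optional[Path] = None
    allow_empty: bool = False


@dataclass
class MappingReport:
    manifest: PedigreeManifest
    filter_reports: dict[str, FilterReport]
    survivor_sets: dict[str, set[Snp]]
    unique_sets: dict[str, set[Snp]]
    unique_table: pd.DataFrame
    venn: dict
    effects: dict[GenomePosition, EffectCall]
    hormigas: list[HormigasRow]
    intervals: list[LinkedInterval]
    candidates: CandidateReport

    @property
    def final_candidates(self):
        return self.candidates.final


def _snp_set(survivors: Sequence[VariantCall]) -> set[Snp]:
    return {(c.site, c.ref_allele, c.alt_alleles[0]) for c in survivors}


def load_dataset_dir(path: Path) -> SimulatedDataset:
    """Load an emitted dataset directory back into memory."""
    from .simulate import SimTruth

    manifest = emio.read_manifest(path / "pedigree.yaml")
    genome = emio.read_fasta(path / "genome.fa")
    genes = emio.read_gene_models(path / "genes.gff3")
    counts: list[AlleleCountRecord] = []
    calls: dict[str, list[VariantCall]] = {}
    for line_id in manifest.line_ids():
        counts.extend(emio.read_allele_counts(path / f"{line_id}.counts.tsv"))
        calls[line_id] = emio.read_variant_calls(
            path / f"{line_id}.vcf", line_id=line_id
        )
    truth = None
    truth_path = path / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = SimTruth.from_dict(json.load(fh))
    return SimulatedDataset(
        params=SimParams(),
        manifest=manifest,
        genome=genome,
        genes=genes,
        counts=counts,
        calls=calls,
        truth=truth,
    )


def map_dataset(
    manifest: PedigreeManifest,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    calls: Mapping[str, Sequence[VariantCall]],
    counts: Sequence[AlleleCountRecord],
    params: PipelineParams = PipelineParams(),
    indel_sites: Optional[Sequence[GenomePosition]] = None,
) -> MappingReport:
    """The full analysis on in-memory data."""
    manifest.validate_mapping_roles()
    mutant_line = manifest.line_with_role("mutant_pool")
    het_line = manifest.line_with_role("het_sibling")
    wt_line = manifest.line_with_role("wt_sibling")

    # 1. per-line filter cascade
    survivors: dict[str, list[VariantCall]] = {}
    reports: dict[str, FilterReport] = {}
    for line_id in manifest.line_ids():
        surv, rep = run_cascade(
            list(calls.get(line_id, [])), params, indel_sites, line_id=line_id
        )
        survivors[line_id] = surv
        reports[line_id] = rep
        log.info("cascade %s: %s", line_id, rep.stages)

    survivor_sets = {line: _snp_set(surv) for line, surv in survivors.items()}

    # 2. cross-lineage subtraction
    unique_sets = {
        line: subtract_other_lineages(line, manifest, survivor_sets)
        for line in survivor_sets
    }
    coding = coding_position_mask(genes)
    unique_table = unique_summary(manifest, survivor_sets, coding)
    other_lines = [
        l for l in manifest.line_ids()
        if manifest.lineage_of(l) != manifest.lineage_of(mutant_line)
    ]
    venn = venn_counts(
        {
            mutant_line: survivor_sets[mutant_line],
            **{l: survivor_sets[l] for l in other_lines[:2]},
        }
    )

    # 3. effect annotation of the mutant pool's lineage-unique SNPs
    effects: dict[GenomePosition, EffectCall] = {}
    unique_calls = [
        c for c in survivors[mutant_line]
        if (c.site, c.ref_allele, c.alt_alleles[0]) in unique_sets[mutant_line]
    ]
    for c in unique_calls:
        effects[c.site] = classify_snp(c, genes, genome)

    # 4. allele-frequency mapping at mutant markers
    cindex = index_counts(counts)
    marker_positions = sorted({c.site for c in unique_calls})
    wt_rows = allele_frequencies_at(marker_positions, cindex, wt_line, mutant_line)
    het_rows = allele_frequencies_at(marker_positions, cindex, het_line, mutant_line)
    intervals = detect_linked_interval(wt_rows, params)
    if not intervals:
        log.warning("no linked interval detected; interval step will be skipped")

    sibling_called = {s for s, _, _ in survivor_sets[wt_line]} | {
        s for s, _, _ in survivor_sets[het_line]
    }

    # 5. candidate reduction
    cand_report = rank_candidates(
        survivors[mutant_line],
        {s for s, _, _ in unique_sets[mutant_line]},
        sibling_called,
        effects,
        cindex,
        manifest,
        intervals,
        params,
    )
    return MappingReport(
        manifest=manifest,
        filter_reports=reports,
        survivor_sets=survivor_sets,
        unique_sets=unique_sets,
        unique_table=unique_table,
        venn=venn,
        effects=effects,
        hormigas=wt_rows + het_rows,
        intervals=intervals,
        candidates=cand_report,
    )


def write_report(report: MappingReport, outdir: Path, run_info: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emio.write_tsv_report(
        cascade_table(
            [report.filter_reports[l] for l in report.manifest.line_ids()]
        ),
        outdir / "filter_report.tsv",
    )
    emio.write_tsv_report(report.unique_table, outdir / "unique_summary.tsv")
    venn_df = pd.DataFrame(
        [
            {"members": "&".join(sorted(k)), "n_positions": v}
            for k, v in sorted(report.venn.items(), key=lambda kv: sorted(kv[0]))
        ]
    )
    emio.write_tsv_report(venn_df, outdir / "venn.tsv")
    emio.write_tsv_report(
        pd.DataFrame(
            [
                {
                    "chrom": r.site.chrom,
                    "pos": r.site.pos,
                    "marker_line": r.marker_line,
                    "query_line": r.query_line,
                    "frequency": "" if r.frequency is None else round(r.frequency, 6),
                    "depth": r.depth,
                }
                for r in report.hormigas
            ]
        ),
        outdir / "hormigas.tsv",
    )
    emio.write_tsv_report(
        pd.DataFrame(
            [
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "n_markers": iv.n_supporting_markers,
                    "mean_query_frequency": round(iv.mean_query_frequency, 6),
                }
                for iv in report.intervals
            ],
            columns=["chrom", "start", "end", "n_markers", "mean_query_frequency"],
        ),
        outdir / "intervals.tsv",
    )
    emio.write_tsv_report(report.candidates.to_frame(), outdir / "ledger.tsv")
    rows = []
    for cand in report.final_candidates:
        c = cand.call
        eff = cand.effect
        row = {
            "chrom": c.site.chrom,
            "pos": c.site.pos,
            "ref": c.ref_allele,
            "alt": c.alt_alleles[0],
            "gene_id": eff.gene_id if eff else "",
            "category": eff.category if eff else "",
            "codon_change": (eff.codon_change or "") if eff else "",
            "aa_change": (eff.aa_change or "") if eff else "",
            "impact": eff.impact if eff else "",
            "verdict": cand.verdict,
        }
        for role, (f, depth) in cand.role_frequencies.items():
            row[f"freq_{role}"] = "" if f is None else round(f, 6)
            row[f"depth_{role}"] = depth
        rows.append(row)
    emio.write_tsv_report(pd.DataFrame(rows), outdir / "candidates.tsv")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_info, fh, indent=1, sort_keys=True)


def run_end_to_end(config: RunConfig) -> MappingReport:
    """Execute all stages; write every intermediate when an outdir is set."""
    from . import __version__

    if config.sim_params is not None or config.dataset_dir is None:
        sim_params = config.sim_params or SimParams()
        ds = simulate_dataset(sim_params, seed=config.seed)
        if config.outdir is not None:
            emit_dataset(ds, Path(config.outdir) / "dataset")
    else:
        ds = load_dataset_dir(Path(config.dataset_dir))
    indels = ds.truth.indel_sites if ds.truth is not None else None
    report = map_dataset(
        ds.manifest, ds.genome, ds.genes, ds.calls, ds.counts,
        params=config.params, indel_sites=indels,
    )
    if config.outdir is not None:
        run_info = {
            "version": __version__,
            "seed": config.seed,
            "params": vars(config.params),
            "steps": report.candidates.steps,
            "interval_applied": report.candidates.interval_applied,
            "n_final_candidates": len(report.final_candidates),
        }
        write_report(report, Path(config.outdir), run_info)
    if not report.final_candidates and not config.allow_empty:
        log.warning("no candidate survived the full chain")
    return report
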