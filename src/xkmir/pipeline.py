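"""End-to-end orchestration: QC -> site search -> duplex -> annotate/dedup ->
enrichment -> mimicry/conservation, with every stage persisted as TSV.

Stage order is fixed and each stage consumes the previous stage's output, so
individual stages are re-runnable and inspectable.  All outputs are plain
text with deterministic formatting and ordering: rerunning on identical
inputs is byte-identical (the run log carries counts, never timestamps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, duplex, enrichment, homology, qc, sites
from .io_formats import (
    MatureMiRNA,
    TranscriptRecord,
    read_gmt,
    read_mirna_table,
    read_transcriptome,
    write_edges_tsv,
    write_interactions_tsv,
    write_mirna_table,
)


@dataclass
class PipelineConfig:
    """File paths and thresholds for one pipeline run."""

    mirna_table: str
    transcripts_fasta: str
    annotation: str
    out_dir: str
    gene_sets: list[str] = field(default_factory=list)
    host_mirnas: str | None = None
    multispecies_fasta: str | None = None
    energy_params: str | None = None
    min_reads: int = 1400
    min_len: int = 19
    max_len: int = 25
    require_read_counts: bool = True
    mfe_threshold: float = -25.0
    flank: int = 10
    enrich_top_k: int = 10
    enrich_fdr_cut: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mfe_threshold >= 0:
            raise ValueError("mfe_threshold must be negative (kcal/mol)")
        for p in [self.mirna_table, self.transcripts_fasta, self.annotation,
                  self.host_mirnas, self.multispecies_fasta, self.energy_params,
                  *self.gene_sets]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class PipelineResult:
    qc_report: qc.QcReport
    seed_matches: list[sites.SeedMatch]
    interactions: list[annotate.Interaction]
    summary: annotate.InteractionSummary
    gene_summaries: list[annotate.GeneSummary]
    enrichment_reports: dict[str, enrichment.EnrichmentReport]
    mimicry_pairs: list[homology.MimicryPair]
    mimic_hybrids: list[homology.MimicHybrid]
    conservation: list[homology.ConservationHit]
    log_lines: list[str]
    output_paths: dict[str, Path]


def hybridize_sites(
    matches: list[sites.SeedMatch],
    mirnas_by_id: dict[str, MatureMiRNA],
    transcripts_by_id: dict[str, TranscriptRecord],
    params: duplex.EnergyParameters,
    mfe_threshold: float | None,
    flank: int,
) -> list[annotate.Interaction]:
    """Fold each candidate site and keep those passing the selection criteria."""
    accepted = []
    for sm in matches:
        m = mirnas_by_id[sm.mirna_id]
        t = transcripts_by_id[sm.transcript_id]
        window = duplex.make_window(t, sm, len(m), flank=flank)
        structure = duplex.hybridize(
            m, window, params, require_seed_wc=True, forbid_seed_gu=True
        )
        if duplex.passes_criteria(structure, mfe_threshold):
            accepted.append(
                annotate.Interaction(
                    mirna_id=sm.mirna_id,
                    transcript_id=sm.transcript_id,
                    gene_symbol=t.gene_symbol,
                    region=annotate.classify_region(t, sm.site_start),
                    site_start=sm.site_start,
                    mfe=structure.mfe,
                )
            )
    return accepted


def run_all(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log: list[str] = []

    mirnas = read_mirna_table(config.mirna_table)
    report = qc.filter_mirnas(
        mirnas,
        min_reads=config.min_reads,
        min_len=config.min_len,
        max_len=config.max_len,
        require_read_counts=config.require_read_counts,
    )
    log.append(f"qc: {report.n_input} in, {len(report.kept)} kept, "
               f"{len(report.rejected)} rejected")
    paths["qc_kept"] = out / "qc_kept.tsv"
    write_mirna_table(report.kept, paths["qc_kept"])
    paths["qc_rejected"] = out / "qc_rejected.tsv"
    pd.DataFrame(
        [
            {"mirna_id": m.mirna_id, "reasons": ",".join(sorted(r))}
            for m, r in report.rejected
        ],
        columns=["mirna_id", "reasons"],
    ).to_csv(paths["qc_rejected"], sep="\t", index=False)

    transcripts = read_transcriptome(config.transcripts_fasta, config.annotation)
    log.append(f"transcriptome: {len(transcripts)} transcripts")

    matches = sites.find_sites(report.kept, transcripts)
    log.append(f"site search: {len(matches)} candidate sites")
    paths["sites"] = out / "sites.tsv"
    pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "site_start": s.site_start,
                "site_end": s.site_end,
                "site_sequence": s.site_sequence,
            }
            for s in matches
        ],
        columns=["mirna_id", "transcript_id", "site_start", "site_end", "site_sequence"],
    ).to_csv(paths["sites"], sep="\t", index=False)

    params = (
        duplex.load_params(config.energy_params)
        if config.energy_params
        else duplex.EnergyParameters()
    )
    mirnas_by_id = {m.mirna_id: m for m in report.kept}
    transcripts_by_id = {t.transcript_id: t for t in transcripts}
    interactions = hybridize_sites(
        matches, mirnas_by_id, transcripts_by_id, params,
        config.mfe_threshold, config.flank,
    )
    log.append(
        f"duplex: {len(interactions)} of {len(matches)} sites pass "
        f"(seed WC, no seed G-U, MFE < {config.mfe_threshold})"
    )
    paths["interactions"] = out / "interactions.tsv"
    write_interactions_tsv(interactions, paths["interactions"])
    paths["edges"] = out / "edges.tsv"
    write_edges_tsv(interactions, paths["edges"])

    summary = annotate.summarize(interactions)
    paths["summary"] = out / "summary.tsv"
    _write_summary(summary, paths["summary"])

    gene_summaries = annotate.dedup_genes(interactions)
    log.append(f"dedup: {len(gene_summaries)} unique protein-coding genes")
    paths["gene_summary"] = out / "gene_summary.tsv"
    pd.DataFrame(
        [
            {
                "gene_symbol": g.gene_symbol,
                "best_mirna": g.best_interaction.mirna_id,
                "best_transcript": g.best_interaction.transcript_id,
                "best_region": g.best_interaction.region,
                "best_mfe": f"{g.best_interaction.mfe:.4f}",
                "n_sites": g.n_sites,
                "mirna_ids": ",".join(sorted(g.mirna_ids)),
            }
            for g in gene_summaries
        ],
        columns=["gene_symbol", "best_mirna", "best_transcript", "best_region",
                 "best_mfe", "n_sites", "mirna_ids"],
    ).to_csv(paths["gene_summary"], sep="\t", index=False)

    background = sorted({t.gene_symbol for t in transcripts if t.biotype == "coding"})
    query = [g.gene_symbol for g in gene_summaries]
    enrichment_reports: dict[str, enrichment.EnrichmentReport] = {}
    for gmt_path in config.gene_sets:
        name = Path(gmt_path).stem
        collection = read_gmt(gmt_path)
        rep = enrichment.enrich(
            query, collection, background=background,
            top_k=config.enrich_top_k, fdr_cut=config.enrich_fdr_cut,
        )
        enrichment_reports[name] = rep
        log.append(
            f"enrichment[{name}]: {len(rep.significant)} significant of "
            f"{len(rep.rows)} sets; {rep.n_query_dropped} query genes outside background"
        )
        paths[f"enrichment_{name}"] = out / f"enrichment_{name}.tsv"
        _write_enrichment(rep, paths[f"enrichment_{name}"])

    mimicry_pairs: list[homology.MimicryPair] = []
    mimic_hybrids: list[homology.MimicHybrid] = []
    if config.host_mirnas:
        host = read_mirna_table(config.host_mirnas)
        hit_ids = {i.mirna_id for i in interactions}
        plant_with_hits = [m for m in report.kept if m.mirna_id in hit_ids]
        mimicry_pairs = homology.find_seed_mimics(plant_with_hits, host)
        coding_interactions = [i for i in interactions if i.region != annotate.NCRNA]
        mimic_hybrids = homology.mimic_hybridize(
            mimicry_pairs, coding_interactions, transcripts, host,
            params=params, flank=config.flank,
        )
        log.append(
            f"mimicry: {len(mimicry_pairs)} seed-identical pairs, "
            f"{len(mimic_hybrids)} re-scored hybrids (no MFE cutoff)"
        )
        paths["mimicry_pairs"] = out / "mimicry_pairs.tsv"
        pd.DataFrame(
            [
                {"plant_mirna_id": p.plant_mirna_id, "host_mirna_id": p.host_mirna_id,
                 "shared_seed": p.shared_seed}
                for p in mimicry_pairs
            ],
            columns=["plant_mirna_id", "host_mirna_id", "shared_seed"],
        ).to_csv(paths["mimicry_pairs"], sep="\t", index=False)
        paths["mimicry_hybrids"] = out / "mimicry_hybrids.tsv"
        pd.DataFrame(
            [
                {
                    "host_mirna_id": h.host_mirna_id,
                    "plant_mirna_id": h.plant_mirna_id,
                    "transcript_id": h.transcript_id,
                    "gene_symbol": h.gene_symbol,
                    "region": h.region,
                    "mfe": f"{h.mfe:.4f}",
                }
                for h in mimic_hybrids
            ],
            columns=["host_mirna_id", "plant_mirna_id", "transcript_id",
                     "gene_symbol", "region", "mfe"],
        ).to_csv(paths["mimicry_hybrids"], sep="\t", index=False)

    conservation: list[homology.ConservationHit] = []
    if config.multispecies_fasta:
        catalogue = homology.read_multispecies_fasta(config.multispecies_fasta)
        conservation = homology.find_conserved(report.kept, catalogue)
        n_detected = sum(1 for h in conservation if h.detected)
        log.append(
            f"conservation: {n_detected} of {len(conservation)} miRNAs found in other species"
        )
        paths["conservation"] = out / "conservation.tsv"
        pd.DataFrame(
            [
                {
                    "mirna_id": h.mirna_id,
                    "matching_species": ";".join(sorted(h.matching_species))
                    or "Not detected",
                    "matching_ids": ";".join(sorted(h.matching_ids)),
                }
                for h in conservation
            ],
            columns=["mirna_id", "matching_species", "matching_ids"],
        ).to_csv(paths["conservation"], sep="\t", index=False)

    paths["run_log"] = out / "run_log.txt"
    with open(paths["run_log"], "w") as fh:
        fh.write("\n".join(log) + "\n")
    paths["report"] = out / "report.txt"
    with open(paths["report"], "w") as fh:
        fh.write(report_text(interactions, gene_summaries))

    return PipelineResult(
        qc_report=report,
        seed_matches=matches,
        interactions=interactions,
        summary=summary,
        gene_summaries=gene_summaries,
        enrichment_reports=enrichment_reports,
        mimicry_pairs=mimicry_pairs,
        mimic_hybrids=mimic_hybrids,
        conservation=conservation,
        log_lines=log,
        output_paths=paths,
    )


def _write_summary(summary: annotate.InteractionSummary, path: Path) -> None:
    rows = []
    for region in annotate.REGIONS:
        rows.append({"kind": "region_count", "key": region,
                     "value": summary.region_counts[region]})
    for b in sorted(summary.mfe_histogram):
        rows.append({"kind": "mfe_bin", "key": b, "value": summary.mfe_histogram[b]})
    for region in annotate.REGIONS:
        for b in sorted(summary.per_region_histogram[region]):
            rows.append({
                "kind": f"mfe_bin_{region}", "key": b,
                "value": summary.per_region_histogram[region][b],
            })
    pd.DataFrame(rows, columns=["kind", "key", "value"]).to_csv(
        path, sep="\t", index=False
    )


def _write_enrichment(rep: enrichment.EnrichmentReport, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "term": r.term,
                "overlap": r.k,
                "set_size": r.K,
                "query_size": r.n,
                "background_size": r.N,
                "p_value": f"{r.p_value:.6g}",
                "fdr": f"{r.fdr:.6g}",
                "overlap_genes": ",".join(sorted(r.overlap_genes)),
            }
            for r in rep.rows
        ],
        columns=["term", "overlap", "set_size", "query_size", "background_size",
                 "p_value", "fdr", "overlap_genes"],
    ).to_csv(path, sep="\t", index=False)


def report_text(
    interactions: list[annotate.Interaction],
    gene_summaries: list[annotate.GeneSummary],
) -> str:
    """Human-readable run summary: region counts, MFE histogram per region,
    and per-miRNA target-gene counts."""
    summary = annotate.summarize(interactions)
    lines = [f"interactions: {summary.total}"]
    for region in annotate.REGIONS:
        lines.append(f"  {region}: {summary.region_counts[region]}")
    lines.append("MFE histogram (kcal/mol bins, left-closed toward more negative):")
    for b in sorted(summary.mfe_histogram):
        lines.append(f"  {b}: {summary.mfe_histogram[b]}")
    targets_per_mirna: dict[str, set[str]] = {}
    for g in gene_summaries:
        for mid in g.mirna_ids:
            targets_per_mirna.setdefault(mid, set()).add(g.gene_symbol)
    lines.append(f"unique protein-coding target genes: {len(gene_summaries)}")
    lines.append("target genes per miRNA:")
    for mid in sorted(targets_per_mirna, key=lambda m: (-len(targets_per_mirna[m]), m)):
        lines.append(f"  {mid}: {len(targets_per_mirna[mid])}")
    return "\n".join(lines) + "\n"
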