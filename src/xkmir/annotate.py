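"""Region annotation, interaction summaries and gene-level deduplication.

A site is assigned to the region containing its seed-match START position
(sites straddling a boundary take the start's region).  Transcript isoforms
collapse to one record per protein-coding gene, represented by the
minimum-MFE interaction — the most stable hybrid is the most plausible one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_formats import TranscriptRecord

FIVE_UTR = "FIVE_UTR"
CDS = "CDS"
THREE_UTR = "THREE_UTR"
NCRNA = "NCRNA"
REGIONS = (FIVE_UTR, CDS, THREE_UTR, NCRNA)


@dataclass(frozen=True)
class Interaction:
    """One accepted miRNA-transcript interaction at one site."""

    mirna_id: str
    transcript_id: str
    gene_symbol: str
    region: str
    site_start: int
    mfe: float


@dataclass(frozen=True)
class GeneSummary:
    """All interactions of one protein-coding gene, collapsed over isoforms."""

    gene_symbol: str
    best_interaction: Interaction
    n_sites: int
    mirna_ids: frozenset[str]


def classify_region(transcript: TranscriptRecord, site_start: int) -> str:
    """Region of a site by its start position (0-based, half-open CDS span)."""
    if not 0 <= site_start < len(transcript.sequence):
        raise ValueError(
            f"site_start {site_start} outside {transcript.transcript_id} "
            f"(length {len(transcript.sequence)})"
        )
    if transcript.biotype == "noncoding":
        return NCRNA
    if site_start < transcript.cds_start:
        return FIVE_UTR
    if site_start < transcript.cds_end:
        return CDS
    return THREE_UTR


# MFE histogram bins run from -25 downward in 5 kcal/mol steps; a value on an
# edge (e.g. -30.0) belongs to the more-negative bin [-30,-35).  Interactions
# with MFE above -25 (possible when the threshold is disabled) collect in a
# single ">-25" bin.
ABOVE_THRESHOLD_BIN = ">-25"


def mfe_bin(mfe: float) -> str:
    if mfe > -25.0:
        return ABOVE_THRESHOLD_BIN
    k = int((-mfe - 25.0) // 5.0)
    lo = -25 - 5 * k
    return f"[{lo},{lo - 5})"


@dataclass
class InteractionSummary:
    region_counts: dict[str, int]
    mfe_histogram: dict[str, int]
    per_region_histogram: dict[str, dict[str, int]]

    @property
    def total(self) -> int:
        return sum(self.region_counts.values())


def summarize(interactions: list[Interaction]) -> InteractionSummary:
    """Region counts plus MFE histograms (overall and per region)."""
    region_counts = {r: 0 for r in REGIONS}
    hist: Counter[str] = Counter()
    per_region: dict[str, Counter[str]] = {r: Counter() for r in REGIONS}
    for it in interactions:
        region_counts[it.region] += 1
        b = mfe_bin(it.mfe)
        hist[b] += 1
        per_region[it.region][b] += 1
    return InteractionSummary(
        region_counts=region_counts,
        mfe_histogram=dict(hist),
        per_region_histogram={r: dict(c) for r, c in per_region.items()},
    )


def dedup_genes(interactions: list[Interaction]) -> list[GeneSummary]:
    """Collapse to unique protein-coding genes.

    Non-coding interactions are dropped; each remaining gene symbol yields one
    summary whose representative is the minimum-MFE interaction, ties broken
    by (transcript_id, site_start).  Output sorted by gene symbol.
    """
    by_gene: dict[str, list[Interaction]] = {}
    for it in interactions:
        if it.region == NCRNA:
            continue
        by_gene.setdefault(it.gene_symbol, []).append(it)
    out = []
    for gene in sorted(by_gene):
        members = by_gene[gene]
        best = min(members, key=lambda i: (i.mfe, i.transcript_id, i.site_start))
        out.append(
            GeneSummary(
                gene_symbol=gene,
                best_interaction=best,
                n_sites=len(members),
                mirna_ids=frozenset(i.mirna_id for i in members),
            )
        )
    return out
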