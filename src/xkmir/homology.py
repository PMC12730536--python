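"""Seed mimicry against host miRNAs and cross-species mature-sequence conservation.

A host (e.g. human) miRNA whose nt 2-7 seed is identical to an exogenous plant
miRNA's seed can in principle engage the same target sites ("functional
mimicry").  Mimics are re-hybridized against the transcripts the plant miRNA
was predicted to hit, with the seed constraints enforced but no MFE cutoff,
since the question is what the endogenous mimic could achieve, however weak.

Conservation is exact full-length mature-sequence identity against a
multi-species catalogue (miRBase ``mature.fa`` dialect); T/U normalization is
applied before comparison and the query's own species is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .annotate import Interaction, classify_region
from .duplex import DuplexStructure, EnergyParameters, TargetWindow, hybridize
from .io_formats import MatureMiRNA, TranscriptRecord, species_from_id
from .sites import seed


@dataclass(frozen=True)
class MimicryPair:
    plant_mirna_id: str
    host_mirna_id: str
    shared_seed: str


@dataclass(frozen=True)
class ConservationHit:
    mirna_id: str
    sequence: str
    matching_species: frozenset[str]  # empty = "Not detected"
    matching_ids: frozenset[str]

    @property
    def detected(self) -> bool:
        return bool(self.matching_species)


@dataclass(frozen=True)
class MimicHybrid:
    """One re-scored host-miRNA duplex at a plant-miRNA target."""

    host_mirna_id: str
    plant_mirna_id: str
    transcript_id: str
    gene_symbol: str
    region: str
    mfe: float
    duplex: DuplexStructure


def find_seed_mimics(
    plant_mirnas: Sequence[MatureMiRNA], host_mirnas: Sequence[MatureMiRNA]
) -> list[MimicryPair]:
    """All cross pairs with identical nt 2-7 seeds, deterministically ordered."""
    by_seed: dict[str, list[str]] = {}
    for h in host_mirnas:
        by_seed.setdefault(seed(h), []).append(h.mirna_id)
    pairs = []
    for p in plant_mirnas:
        for host_id in by_seed.get(seed(p), []):
            pairs.append(
                MimicryPair(
                    plant_mirna_id=p.mirna_id,
                    host_mirna_id=host_id,
                    shared_seed=seed(p),
                )
            )
    pairs.sort(key=lambda x: (x.plant_mirna_id, x.host_mirna_id))
    return pairs


def mimic_hybridize(
    pairs: Sequence[MimicryPair],
    interactions: Sequence[Interaction],
    transcripts: Sequence[TranscriptRecord],
    host_mirnas: Sequence[MatureMiRNA],
    params: EnergyParameters | None = None,
    flank: int = 10,
) -> list[MimicHybrid]:
    """Re-hybridize each seed mimic at its plant partner's accepted sites.

    For every (plant, host) pair and every interaction of the plant miRNA, the
    host miRNA is folded against a window anchored at the shared-seed
    complement (target span ``[site_start+6, site_start+12)``), with perfect
    seed pairing required, seed G·U forbidden, and no MFE restriction.  A
    "no structure" outcome yields no row.
    """
    params = params or EnergyParameters()
    host_by_id = {h.mirna_id: h for h in host_mirnas}
    tr_by_id = {t.transcript_id: t for t in transcripts}
    sites_by_plant: dict[str, list[Interaction]] = {}
    for it in interactions:
        sites_by_plant.setdefault(it.mirna_id, []).append(it)
    out = []
    for pair in pairs:
        host = host_by_id[pair.host_mirna_id]
        for it in sites_by_plant.get(pair.plant_mirna_id, []):
            t = tr_by_id[it.transcript_id]
            # seed-complement hexamer sits at [site_start+6, site_start+12);
            # the host 3' arm extends 5'-ward of it on the target
            lo = max(0, it.site_start + 6 - (len(host) - 7) - flank)
            hi = min(len(t.sequence), it.site_start + 12 + 1 + flank)
            window = TargetWindow(
                transcript_id=t.transcript_id,
                window_start=lo,
                window_end=hi,
                sequence=t.sequence[lo:hi],
            )
            duplex = hybridize(
                host, window, params, require_seed_wc=True, forbid_seed_gu=True
            )
            if duplex is None:
                continue
            out.append(
                MimicHybrid(
                    host_mirna_id=host.mirna_id,
                    plant_mirna_id=pair.plant_mirna_id,
                    transcript_id=it.transcript_id,
                    gene_symbol=it.gene_symbol,
                    region=classify_region(t, it.site_start),
                    mfe=duplex.mfe,
                    duplex=duplex,
                )
            )
    out.sort(key=lambda h: (h.gene_symbol, h.host_mirna_id, h.transcript_id, h.mfe))
    return out


def read_multispecies_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read a miRBase ``mature.fa``-dialect multi-species FASTA.

    Species is taken from the id prefix (``zma-miR156a`` -> ``zma``) per the
    miRBase header convention.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            MatureMiRNA(
                mirna_id=rec.id,
                species=species_from_id(rec.id),
                sequence=str(rec.seq),
            )
        )
    return out


def find_conserved(
    query_mirnas: Sequence[MatureMiRNA],
    multispecies_mirnas: Sequence[MatureMiRNA],
) -> list[ConservationHit]:
    """Exact full-length identity of each query against other species.

    Every query gets a hit record; an empty ``matching_species`` set means the
    sequence was not detected outside the query's own species.
    """
    by_seq: dict[str, list[MatureMiRNA]] = {}
    for m in multispecies_mirnas:
        by_seq.setdefault(m.sequence, []).append(m)
    hits = []
    for q in query_mirnas:
        others = [m for m in by_seq.get(q.sequence, []) if m.species != q.species]
        hits.append(
            ConservationHit(
                mirna_id=q.mirna_id,
                sequence=q.sequence,
                matching_species=frozenset(m.species for m in others),
                matching_ids=frozenset(m.mirna_id for m in others),
            )
        )
    return hits
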