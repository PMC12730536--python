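"""Readers and writers for every external representation the pipeline touches.

All sequence data is held in RNA alphabet (``{A,C,G,U}``) regardless of the
source: miRBase-style inputs use U, RefSeq-style DNA inputs use T, and
:func:`normalize_sequence` reconciles the two at the boundary.  Coordinates are
0-based, half-open, transcript-local and 5'->3' everywhere.

TSV dialects (tab-delimited, UTF-8, one header line):

* miRNA table: ``mirna_id  species  sequence  read_count`` (read_count column
  optional; miRBase mature.fa carries no read counts, so they live in this
  sidecar column).
* transcript annotation: ``transcript_id  gene_symbol  biotype  cds_start
  cds_end`` with biotype in ``{coding, noncoding}`` and CDS columns blank for
  noncoding records.
* interactions / edge list: see :func:`write_interactions_tsv` and
  :func:`write_edges_tsv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
_INPUT_ALPHABET = frozenset("ACGTUacgtu")

COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


def normalize_sequence(raw: str) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U.

    Raises :class:`FormatError` naming the 1-based position of the first
    character outside ``{A,C,G,T,U}`` (case-insensitive).
    """
    if not raw:
        raise FormatError("empty sequence")
    for pos, ch in enumerate(raw, start=1):
        if ch not in _INPUT_ALPHABET:
            raise FormatError(
                f"invalid character {ch!r} at position {pos} (alphabet ACGTU)"
            )
    return raw.upper().replace("T", "U")


def reverse_complement(rna: str) -> str:
    """Watson-Crick reverse complement of an RNA string (A<->U, C<->G)."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(rna))
    except KeyError as exc:
        raise FormatError(f"invalid RNA character {exc.args[0]!r}") from None


@dataclass(frozen=True)
class MatureMiRNA:
    """One mature miRNA record.

    ``read_count`` is the deep-sequencing read support used by the abundance
    filter; it may be absent.  ``orientation`` models the 5'->3' alignment
    criterion and defaults to compliant.
    """

    mirna_id: str
    species: str
    sequence: str
    read_count: int | None = None
    orientation: str = "5p3p"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.read_count is not None and self.read_count < 0:
            raise ValueError(f"{self.mirna_id}: negative read_count")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with gene symbol, biotype and CDS span.

    ``cds_start``/``cds_end`` are 0-based half-open transcript coordinates,
    present iff ``biotype == "coding"``; the 5'UTR is ``[0, cds_start)`` and
    the 3'UTR is ``[cds_end, len)``.
    """

    transcript_id: str
    gene_symbol: str
    biotype: str
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(
                f"{self.transcript_id}: biotype must be coding/noncoding, "
                f"got {self.biotype!r}"
            )
        if self.biotype == "coding":
            if self.cds_start is None or self.cds_end is None:
                raise ValueError(f"{self.transcript_id}: coding record lacks CDS span")
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValueError(
                    f"{self.transcript_id}: invalid CDS span "
                    f"[{self.cds_start}, {self.cds_end}) for length {len(self.sequence)}"
                )
        elif self.cds_start is not None or self.cds_end is not None:
            raise ValueError(f"{self.transcript_id}: noncoding record carries a CDS span")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")
            if self.background is not None and not genes <= self.background:
                extra = sorted(genes - self.background)[:5]
                raise ValueError(
                    f"gene set {term!r} has members outside the background: {extra}"
                )


def _check_unique_ids(records: Sequence[MatureMiRNA]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.mirna_id in seen:
            raise FormatError(f"duplicate mirna_id {rec.mirna_id!r}")
        seen.add(rec.mirna_id)


def read_mirna_table(path: str | Path) -> list[MatureMiRNA]:
    """Read a miRNA table (TSV dialect, or FASTA as a convenience).

    The TSV dialect is authoritative: columns ``mirna_id``, ``species``,
    ``sequence`` and optionally ``read_count``.  A FASTA file (detected by a
    leading ``>``) is accepted with header fields ``>id species [read_count]``;
    when the species field is missing it is inferred from the id prefix
    (miRBase convention, e.g. ``zma-miR156a`` -> ``zma``).
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        records = list(_read_mirna_fasta(path))
    elif not text.strip():
        records = []
    else:
        records = _read_mirna_tsv(path)
    _check_unique_ids(records)
    return records


def species_from_id(mirna_id: str) -> str:
    """miRBase species code from an id like ``zma-miR156a`` -> ``zma``."""
    return mirna_id.split("-", 1)[0]


def _read_mirna_fasta(path: Path) -> Iterable[MatureMiRNA]:
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split()
        species = fields[1] if len(fields) > 1 and not fields[1].isdigit() else None
        count_field = next((f for f in fields[1:] if f.isdigit()), None)
        yield MatureMiRNA(
            mirna_id=rec.id,
            species=species or species_from_id(rec.id),
            sequence=str(rec.seq),
            read_count=int(count_field) if count_field is not None else None,
        )


def _read_mirna_tsv(path: Path) -> list[MatureMiRNA]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "species", "sequence"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: miRNA TSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for row in df.itertuples(index=False):
        count = getattr(row, "read_count", None)
        if count is not None and (pd.isna(count) or count == ""):
            count = None
        out.append(
            MatureMiRNA(
                mirna_id=row.mirna_id,
                species=row.species,
                sequence=row.sequence,
                read_count=int(float(count)) if count is not None else None,
                orientation=getattr(row, "orientation", "5p3p") or "5p3p",
            )
        )
    return out


def write_mirna_table(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    rows = [
        {
            "mirna_id": m.mirna_id,
            "species": m.species,
            "sequence": m.sequence,
            "read_count": "" if m.read_count is None else m.read_count,
            "orientation": m.orientation,
        }
        for m in mirnas
    ]
    pd.DataFrame(
        rows, columns=["mirna_id", "species", "sequence", "read_count", "orientation"]
    ).to_csv(path, sep="\t", index=False)


def read_transcriptome(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[TranscriptRecord]:
    """Join a transcript FASTA with its annotation TSV into records.

    Every FASTA record must have an annotation row and vice versa; orphans on
    either side raise :class:`FormatError` listing the ids.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"transcript_id", "gene_symbol", "biotype", "cds_start", "cds_end"}
    if not required <= set(ann.columns):
        raise FormatError(
            f"{annotation_path}: annotation TSV needs columns {sorted(required)}"
        )
    ann_ids = set(ann["transcript_id"])
    orphan_fa = sorted(set(seqs) - ann_ids)
    orphan_ann = sorted(ann_ids - set(seqs))
    if orphan_fa or orphan_ann:
        raise FormatError(
            f"FASTA/annotation mismatch: {len(orphan_fa)} sequences without "
            f"annotation {orphan_fa[:5]}, {len(orphan_ann)} annotations without "
            f"sequence {orphan_ann[:5]}"
        )
    records = []
    for row in ann.itertuples(index=False):
        coding = row.biotype == "coding"

        def _coord(v: object) -> int | None:
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return int(float(v))

        records.append(
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_symbol=row.gene_symbol,
                biotype=row.biotype,
                sequence=seqs[row.transcript_id],
                cds_start=_coord(row.cds_start) if coding else _coord(row.cds_start),
                cds_end=_coord(row.cds_end) if coding else _coord(row.cds_end),
            )
        )
    return records


def write_transcriptome(
    transcripts: Iterable[TranscriptRecord],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    transcripts = list(transcripts)
    with open(fasta_path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_symbol": t.gene_symbol,
            "biotype": t.biotype,
            "cds_start": "" if t.cds_start is None else t.cds_start,
            "cds_end": "" if t.cds_end is None else t.cds_end,
        }
        for t in transcripts
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "gene_symbol", "biotype", "cds_start", "cds_end"]
    ).to_csv(annotation_path, sep="\t", index=False)


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> GeneSetCollection:
    """Read gene sets in GMT format: ``term<TAB>description<TAB>gene...``."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
                )
            term = parts[0]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {term!r} is empty")
            sets[term] = genes
    return GeneSetCollection(
        sets=sets, background=frozenset(background) if background is not None else None
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\tna\t{genes}\n")


INTERACTION_COLUMNS = [
    "mirna_id",
    "transcript_id",
    "gene_symbol",
    "region",
    "site_start",
    "mfe",
]


def write_interactions_tsv(interactions: Iterable, path: str | Path) -> None:
    """Write accepted interactions; columns fixed so round-trips are exact."""
    rows = [
        {
            "mirna_id": i.mirna_id,
            "transcript_id": i.transcript_id,
            "gene_symbol": i.gene_symbol,
            "region": i.region,
            "site_start": i.site_start,
            "mfe": f"{i.mfe:.4f}",
        }
        for i in interactions
    ]
    pd.DataFrame(rows, columns=INTERACTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_interactions_tsv(path: str | Path) -> list:
    from .annotate import Interaction  # deferred: avoid a module cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != INTERACTION_COLUMNS:
        raise FormatError(f"{path}: unexpected columns {list(df.columns)}")
    return [
        Interaction(
            mirna_id=r.mirna_id,
            transcript_id=r.transcript_id,
            gene_symbol=r.gene_symbol,
            region=r.region,
            site_start=int(r.site_start),
            mfe=float(r.mfe),
        )
        for r in df.itertuples(index=False)
    ]


def write_edges_tsv(interactions: Iterable, path: str | Path) -> None:
    """Edge-list export (source miRNA, target gene, MFE, region) for network tools."""
    rows = [
        {
            "source": i.mirna_id,
            "target": i.gene_symbol,
            "mfe": f"{i.mfe:.4f}",
            "region": i.region,
        }
        for i in interactions
    ]
    pd.DataFrame(rows, columns=["source", "target", "mfe", "region"]).to_csv(
        path, sep="\t", index=False
    )
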