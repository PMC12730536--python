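"""Seed-anchored candidate target-site discovery.

A candidate site is an exact occurrence, in a transcript, of the reverse
complement of miRNA nucleotides 2-13 (the 12-nt "extended seed").  An exact
12-mer at 100% identity and full coverage is the retained-hit definition of a
short-word alignment search, so the scan here replaces that stage without an
external aligner, and it guarantees the 6-mer opposite the seed (nt 2-7) is a
perfect Watson-Crick complement with no G·U.

Only antisense (reverse-complement) occurrences are sites; a transcript
containing the miRNA's own sense sequence cannot hybridize with it and is
never reported.  Overlapping occurrences are all reported, and the output
order is deterministic: (transcript_id, site_start, mirna_id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import MatureMiRNA, TranscriptRecord, reverse_complement

EXTENDED_SEED_LEN = 12


@dataclass(frozen=True)
class SeedMatch:
    """One exact reverse-complement match of a miRNA extended seed."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    site_sequence: str


def seed(mirna: MatureMiRNA | str) -> str:
    """The 6-nt seed: miRNA nucleotides 2-7 (1-based, from the 5' end)."""
    seq = mirna if isinstance(mirna, str) else mirna.sequence
    if len(seq) < 7:
        raise ValueError(f"sequence of length {len(seq)} has no nt 2-7 seed")
    return seq[1:7]


def extended_seed(mirna: MatureMiRNA | str) -> str:
    """The 12-nt extended seed: miRNA nucleotides 2-13 (1-based)."""
    seq = mirna if isinstance(mirna, str) else mirna.sequence
    if len(seq) < 13:
        raise ValueError(f"sequence of length {len(seq)} has no nt 2-13 span")
    return seq[1:13]


def _occurrences(needle: str, haystack: str) -> Iterable[int]:
    """All (overlapping) start offsets of needle in haystack."""
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)


def find_sites(
    mirnas: Sequence[MatureMiRNA], transcripts: Sequence[TranscriptRecord]
) -> list[SeedMatch]:
    """All exact extended-seed reverse-complement sites, deterministically ordered."""
    probes = []
    for m in mirnas:
        probes.append((m.mirna_id, reverse_complement(extended_seed(m))))
    matches = []
    for t in transcripts:
        for mirna_id, probe in probes:
            for start in _occurrences(probe, t.sequence):
                matches.append(
                    SeedMatch(
                        mirna_id=mirna_id,
                        transcript_id=t.transcript_id,
                        site_start=start,
                        site_end=start + EXTENDED_SEED_LEN,
                        site_sequence=probe,
                    )
                )
    matches.sort(key=lambda s: (s.transcript_id, s.site_start, s.mirna_id))
    return matches
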