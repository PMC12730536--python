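"""Synthetic dataset generator with known ground truth.

Emulates the five external inputs of the pipeline — a plant miRNA table with
deep-sequencing read counts, a transcriptome (FASTA + annotation) with
UTR/CDS structure, a host miRNA table, a multi-species mature-sequence FASTA
and GMT gene sets — and plants verifiable signal in each:

* true target sites: exact reverse complements of miRNA nt 2-13 substituted
  into a chosen region, optionally extended by complements of the miRNA 3'
  arm (nt 14..L) to deepen the achievable MFE;
* decoy sites violating one criterion each (``SEED_GU``: a substitution in
  the 6-mer opposite the seed creating a wobble or mismatch; ``SEED_ONLY``:
  only the seed hexamer complement present; ``SHUFFLED``: a shuffle of the
  true 12-mer);
* host miRNAs with controlled seed sharing;
* exact cross-species duplicates of selected plant miRNAs;
* one gene set enriched among the genes that received true sites.

Everything is driven by one :class:`numpy.random.Generator`; identical config
and seed give byte-identical bundles.  Read counts are drawn log-normal and
forced to straddle the abundance threshold so the QC stage is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    COMPLEMENT,
    GeneSetCollection,
    MatureMiRNA,
    TranscriptRecord,
    write_gmt,
    write_mirna_table,
    write_transcriptome,
)
from .sites import extended_seed, reverse_complement, seed

DECOY_NONE = "NONE"
DECOY_SEED_GU = "SEED_GU"
DECOY_SEED_ONLY = "SEED_ONLY"
DECOY_SHUFFLED = "SHUFFLED"

_OTHER_SPECIES = ("sbi", "osa", "bdi", "ata", "mtr", "sof")
_BASES = "ACGU"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.  Counts are per bundle."""

    seed: int = 0
    # transcriptome
    n_genes: int = 200
    noncoding_fraction: float = 0.2
    p_extra_isoform: float = 0.3
    transcript_len_mean: int = 900
    transcript_len_sd: int = 150
    transcript_len_min: int = 400
    gc_fraction: float = 0.5
    utr5_fraction: float = 0.15
    cds_fraction: float = 0.55
    # plant miRNAs
    n_plant_mirnas: int = 12
    mirna_len_low: int = 19
    mirna_len_high: int = 25
    n_low_read_mirnas: int = 2  # forced to fail the abundance criterion
    n_bad_length_mirnas: int = 1  # forced outside the length window
    read_count_log_mean: float = 8.5
    read_count_log_sd: float = 1.0
    min_reads_threshold: int = 1400  # straddled by construction
    # planted signal
    sites_per_region: dict[str, int] = field(
        default_factory=lambda: {"FIVE_UTR": 4, "CDS": 6, "THREE_UTR": 6, "NCRNA": 3}
    )
    extend_prob: float = 0.9
    decoys_per_class: dict[str, int] = field(
        default_factory=lambda: {DECOY_SEED_GU: 4, DECOY_SEED_ONLY: 4, DECOY_SHUFFLED: 4}
    )
    # host miRNAs
    n_host_mirnas: int = 10
    host_seed_share_fraction: float = 0.4
    # conservation
    n_species: int = 4
    conservation_fraction: float = 0.4
    decoys_per_species: int = 5
    # gene sets
    n_gene_sets: int = 10
    gene_set_size_low: int = 15
    gene_set_size_high: int = 40
    planted_term: str = "PLANTED_TARGET_SET"
    planted_overlap_fraction: float = 0.8


@dataclass(frozen=True)
class TruthSite:
    mirna_id: str
    transcript_id: str
    site_start: int
    region: str
    decoy_class: str
    n_substituted: int


@dataclass
class TruthManifest:
    planted_sites: list[TruthSite]
    decoys: list[TruthSite]
    seed_pairs: list[tuple[str, str]]  # (plant_mirna_id, host_mirna_id)
    conserved: dict[str, frozenset[str]]  # mirna_id -> other-species codes
    enriched_term: str
    targeted_genes: frozenset[str]


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    plant_mirnas: list[MatureMiRNA]
    transcripts: list[TranscriptRecord]
    host_mirnas: list[MatureMiRNA]
    multispecies_mirnas: list[MatureMiRNA]
    gene_sets: GeneSetCollection
    truth: TruthManifest
    expected_background_matches: float
    log_lines: list[str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Persist the bundle as the pipeline's documented text formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirnas": out / "plant_mirnas.tsv",
            "transcripts_fasta": out / "transcripts.fa",
            "annotation": out / "annotation.tsv",
            "host_mirnas": out / "host_mirnas.tsv",
            "multispecies_fasta": out / "multispecies_mature.fa",
            "gene_sets": out / "gene_sets.gmt",
            "truth": out / "truth.tsv",
            "run_log": out / "simulate_log.txt",
        }
        write_mirna_table(self.plant_mirnas, paths["mirnas"])
        write_transcriptome(
            self.transcripts, paths["transcripts_fasta"], paths["annotation"]
        )
        write_mirna_table(self.host_mirnas, paths["host_mirnas"])
        with open(paths["multispecies_fasta"], "w") as fh:
            for m in self.multispecies_mirnas:
                fh.write(f">{m.mirna_id}\n{m.sequence}\n")
        write_gmt(self.gene_sets, paths["gene_sets"])
        with open(paths["truth"], "w") as fh:
            fh.write(
                "kind\tmirna_id\ttranscript_id\tsite_start\tregion\tdecoy_class\tn_substituted\n"
            )
            for s in self.truth.planted_sites + self.truth.decoys:
                kind = "site" if s.decoy_class == DECOY_NONE else "decoy"
                fh.write(
                    f"{kind}\t{s.mirna_id}\t{s.transcript_id}\t{s.site_start}\t"
                    f"{s.region}\t{s.decoy_class}\t{s.n_substituted}\n"
                )
            for plant, host in self.truth.seed_pairs:
                fh.write(f"seed_pair\t{plant}\t{host}\t\t\t\t\n")
            for mid, species in sorted(self.truth.conserved.items()):
                fh.write(f"conserved\t{mid}\t{','.join(sorted(species))}\t\t\t\t\n")
            fh.write(f"enriched_term\t{self.truth.enriched_term}\t\t\t\t\t\n")
        with open(paths["run_log"], "w") as fh:
            fh.write("\n".join(self.log_lines) + "\n")
        return paths


def _random_rna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def plant_site(
    sequence: str,
    mirna: MatureMiRNA,
    position: int,
    extend_prob: float,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Substitute a true binding site into ``sequence`` at ``position``.

    Writes the reverse complement of miRNA nt 2-13 at ``[position,
    position+12)``; then, with probability ``extend_prob`` per nucleotide and
    stopping at the first failure, substitutes the complement of miRNA nt
    14..L contiguously 5'-ward of the site (antiparallel geometry: nt 14 sits
    at ``position-1``).  Transcript length is preserved.  Returns the modified
    sequence and the number of substituted nucleotides.
    """
    if position < 0 or position + 12 > len(sequence):
        raise ValueError(
            f"site at {position} overflows sequence of length {len(sequence)}"
        )
    probe = reverse_complement(extended_seed(mirna))
    chars = list(sequence)
    chars[position : position + 12] = probe
    n_sub = 12
    mseq = mirna.sequence
    for k, mi in enumerate(range(13, len(mseq))):
        tpos = position - 1 - k
        if tpos < 0 or rng.random() >= extend_prob:
            break
        chars[tpos] = COMPLEMENT[mseq[mi]]
        n_sub += 1
    return "".join(chars), n_sub


def _region_span(t: TranscriptRecord, region: str) -> tuple[int, int]:
    if region == "NCRNA":
        return 0, len(t.sequence)
    if region == "FIVE_UTR":
        return 0, t.cds_start
    if region == "CDS":
        return t.cds_start, t.cds_end
    return t.cds_end, len(t.sequence)


def simulate(config: SimulationConfig) -> SimulatedBundle:
    """Generate one fully specified bundle with its truth manifest."""
    rng = np.random.default_rng(config.seed)
    log: list[str] = [f"simulate: seed={config.seed}"]

    plant = _make_plant_mirnas(config, rng)
    kept = [
        m
        for m in plant
        if m.read_count is not None
        and m.read_count > config.min_reads_threshold
        and config.mirna_len_low <= len(m) <= config.mirna_len_high
    ]
    log.append(f"plant miRNAs: {len(plant)} total, {len(kept)} pass QC by construction")

    transcripts = _make_transcripts(config, rng)
    log.append(f"transcripts: {len(transcripts)}")

    transcripts, planted, decoys = _plant_signal(config, rng, transcripts, kept)
    log.append(f"planted sites: {len(planted)}; decoys: {len(decoys)}")

    probes = {reverse_complement(extended_seed(m)) for m in kept}
    expected_bg = len(probes) * sum(
        max(0, len(t.sequence) - 11) for t in transcripts
    ) / 4**12
    log.append(f"expected spontaneous background matches: {expected_bg:.4f}")

    planted_mirna_ids = {s.mirna_id for s in planted}
    host, seed_pairs = _make_host_mirnas(config, rng, plant, planted_mirna_ids)
    log.append(f"host miRNAs: {len(host)}; expected seed pairs: {len(seed_pairs)}")

    multispecies, conserved = _make_multispecies(config, rng, plant, kept)
    n_detected = sum(1 for v in conserved.values() if v)
    log.append(
        f"multi-species records: {len(multispecies)}; conserved plant miRNAs: {n_detected}"
    )

    tr_by_id = {t.transcript_id: t for t in transcripts}
    targeted = frozenset(
        tr_by_id[s.transcript_id].gene_symbol
        for s in planted
        if s.region != "NCRNA"
    )
    universe = [t.gene_symbol for t in transcripts if t.biotype == "coding"]
    gene_sets = simulate_gene_sets(config, rng, universe, targeted)
    log.append(
        f"gene sets: {len(gene_sets.sets)}; planted term {config.planted_term!r} "
        f"over {len(targeted)} targeted genes"
    )

    truth = TruthManifest(
        planted_sites=planted,
        decoys=decoys,
        seed_pairs=seed_pairs,
        conserved=conserved,
        enriched_term=config.planted_term,
        targeted_genes=targeted,
    )
    return SimulatedBundle(
        config=config,
        plant_mirnas=plant,
        transcripts=transcripts,
        host_mirnas=host,
        multispecies_mirnas=multispecies,
        gene_sets=gene_sets,
        truth=truth,
        expected_background_matches=expected_bg,
        log_lines=log,
    )


def _make_plant_mirnas(
    config: SimulationConfig, rng: np.random.Generator
) -> list[MatureMiRNA]:
    n = config.n_plant_mirnas
    if config.n_low_read_mirnas + config.n_bad_length_mirnas >= n:
        raise ValueError("not enough miRNAs left after the designated QC failures")
    out = []
    for i in range(n):
        bad_length = i < config.n_bad_length_mirnas
        low_reads = (
            config.n_bad_length_mirnas
            <= i
            < config.n_bad_length_mirnas + config.n_low_read_mirnas
        )
        length = (
            config.mirna_len_high + 1
            if bad_length
            else int(rng.integers(config.mirna_len_low, config.mirna_len_high + 1))
        )
        count = int(np.exp(rng.normal(config.read_count_log_mean, config.read_count_log_sd)))
        if low_reads:
            count = int(rng.integers(0, config.min_reads_threshold + 1))
        elif count <= config.min_reads_threshold:
            count = config.min_reads_threshold + 1 + count
        out.append(
            MatureMiRNA(
                mirna_id=f"sim-miR{i + 1:03d}",
                species="sim",
                sequence=_random_rna(rng, length, config.gc_fraction),
                read_count=count,
            )
        )
    return out


def _make_transcripts(
    config: SimulationConfig, rng: np.random.Generator
) -> list[TranscriptRecord]:
    out = []
    n_noncoding = int(round(config.n_genes * config.noncoding_fraction))
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:04d}"
        noncoding = g >= config.n_genes - n_noncoding
        n_iso = 1 + (1 if rng.random() < config.p_extra_isoform else 0)
        for iso in range(n_iso):
            length = max(
                config.transcript_len_min,
                int(rng.normal(config.transcript_len_mean, config.transcript_len_sd)),
            )
            seq = _random_rna(rng, length, config.gc_fraction)
            tid = f"{gene}.t{iso + 1}"
            if noncoding:
                out.append(
                    TranscriptRecord(
                        transcript_id=tid, gene_symbol=gene, biotype="noncoding", sequence=seq
                    )
                )
            else:
                cds_start = int(round(length * config.utr5_fraction))
                cds_end = cds_start + int(round(length * config.cds_fraction))
                out.append(
                    TranscriptRecord(
                        transcript_id=tid,
                        gene_symbol=gene,
                        biotype="coding",
                        sequence=seq,
                        cds_start=cds_start,
                        cds_end=cds_end,
                    )
                )
    return out


def _choose_position(
    rng: np.random.Generator,
    span: tuple[int, int],
    occupied: list[tuple[int, int]],
    reserve_before: int,
    transcript_id: str,
) -> int:
    a, b = span
    lo = max(a, reserve_before)
    if b - 12 < lo:
        raise ValueError(f"region too short to host a site in {transcript_id}")
    for _ in range(80):
        p = int(rng.integers(lo, b - 12 + 1))
        block = (p - reserve_before - 1, p + 13)
        if all(block[1] <= s or block[0] >= e for s, e in occupied):
            occupied.append(block)
            return p
    raise ValueError(f"region too crowded to host a site in {transcript_id}")


def _plant_signal(
    config: SimulationConfig,
    rng: np.random.Generator,
    transcripts: list[TranscriptRecord],
    kept: list[MatureMiRNA],
) -> tuple[list[TranscriptRecord], list[TruthSite], list[TruthSite]]:
    if not kept:
        raise ValueError("no QC-passing miRNAs to plant sites for")
    seqs = {t.transcript_id: t.sequence for t in transcripts}
    meta = {t.transcript_id: t for t in transcripts}
    occupied: dict[str, list[tuple[int, int]]] = {t.transcript_id: [] for t in transcripts}
    coding_ids = [t.transcript_id for t in transcripts if t.biotype == "coding"]
    noncoding_ids = [t.transcript_id for t in transcripts if t.biotype == "noncoding"]

    planted: list[TruthSite] = []
    mirna_cycle = 0
    for region in ("FIVE_UTR", "CDS", "THREE_UTR", "NCRNA"):
        pool = noncoding_ids if region == "NCRNA" else coding_ids
        for _ in range(config.sites_per_region.get(region, 0)):
            m = kept[mirna_cycle % len(kept)]
            mirna_cycle += 1
            tid = pool[int(rng.integers(len(pool)))]
            t = meta[tid]
            span = _region_span(t, region)
            reserve = len(m) - 13  # room for the extended 3' arm 5'-ward
            pos = _choose_position(rng, span, occupied[tid], reserve, tid)
            new_seq, n_sub = plant_site(seqs[tid], m, pos, config.extend_prob, rng)
            seqs[tid] = new_seq
            planted.append(
                TruthSite(
                    mirna_id=m.mirna_id,
                    transcript_id=tid,
                    site_start=pos,
                    region=region,
                    decoy_class=DECOY_NONE,
                    n_substituted=n_sub,
                )
            )

    probes = {reverse_complement(extended_seed(m)) for m in kept}
    decoys: list[TruthSite] = []
    decoy_cycle = 0
    for decoy_class, count in config.decoys_per_class.items():
        for _ in range(count):
            m = kept[decoy_cycle % len(kept)]
            decoy_cycle += 1
            tid = coding_ids[int(rng.integers(len(coding_ids)))]
            t = meta[tid]
            span = _region_span(t, "CDS")
            pos = _choose_position(rng, span, occupied[tid], 0, tid)
            for _attempt in range(50):
                word = _decoy_word(decoy_class, m, rng)
                chars = list(seqs[tid])
                chars[pos : pos + 12] = word
                candidate = "".join(chars)
                lo, hi = max(0, pos - 12), min(len(candidate), pos + 24)
                neighborhood = candidate[lo:hi]
                if not any(p in neighborhood for p in probes):
                    seqs[tid] = candidate
                    break
            else:
                raise ValueError(f"could not place a {decoy_class} decoy in {tid}")
            decoys.append(
                TruthSite(
                    mirna_id=m.mirna_id,
                    transcript_id=tid,
                    site_start=pos,
                    region="CDS",
                    decoy_class=decoy_class,
                    n_substituted=12,
                )
            )

    rebuilt = []
    for t in transcripts:
        rebuilt.append(
            TranscriptRecord(
                transcript_id=t.transcript_id,
                gene_symbol=t.gene_symbol,
                biotype=t.biotype,
                sequence=seqs[t.transcript_id],
                cds_start=t.cds_start,
                cds_end=t.cds_end,
            )
        )
    return rebuilt, planted, decoys


def _decoy_word(decoy_class: str, m: MatureMiRNA, rng: np.random.Generator) -> str:
    """A 12-mer violating exactly one site criterion for miRNA ``m``.

    The probe is the reverse complement of nt 2-13; its last six characters
    (positions 6-11) oppose the seed (nt 2-7).
    """
    probe = reverse_complement(extended_seed(m))
    if decoy_class == DECOY_SHUFFLED:
        word = probe
        while word == probe:
            idx = rng.permutation(12)
            word = "".join(probe[i] for i in idx)
        return word
    if decoy_class == DECOY_SEED_ONLY:
        # keep the seed-complement hexamer, randomize the 3'-arm complement
        # half until it mismatches the true probe somewhere
        while True:
            head = _random_rna(rng, 6, 0.5)
            if head != probe[:6]:
                return head + probe[6:]
    if decoy_class == DECOY_SEED_GU:
        # one substitution inside the seed-complement hexamer; where the
        # miRNA base is G or U the substitution forms a G·U wobble, else a
        # plain mismatch
        pos = 6 + int(rng.integers(6))
        mirna_base = m.sequence[1:13][::-1][pos]  # miRNA base opposite probe[pos]
        if mirna_base == "G":
            repl = "U"
        elif mirna_base == "U":
            repl = "G"
        else:
            choices = [b for b in _BASES if b != probe[pos]]
            repl = choices[int(rng.integers(len(choices)))]
        return probe[:pos] + repl + probe[pos + 1 :]
    raise ValueError(f"unknown decoy class {decoy_class!r}")


def _make_host_mirnas(
    config: SimulationConfig,
    rng: np.random.Generator,
    plant: list[MatureMiRNA],
    planted_mirna_ids: set[str],
) -> tuple[list[MatureMiRNA], list[tuple[str, str]]]:
    plant_seeds = {seed(m) for m in plant}
    donors = [m for m in plant if m.mirna_id in planted_mirna_ids] or plant
    n_sharing = int(round(config.n_host_mirnas * config.host_seed_share_fraction))
    hosts = []
    for i in range(config.n_host_mirnas):
        length = int(rng.integers(20, 24))
        seq = _random_rna(rng, length, config.gc_fraction)
        if i < n_sharing:
            donor = donors[i % len(donors)]
            seq = seq[0] + seed(donor) + seq[7:]
        else:
            while seed(seq) in plant_seeds:
                seq = _random_rna(rng, length, config.gc_fraction)
        hosts.append(
            MatureMiRNA(mirna_id=f"hst-miR{i + 1:03d}", species="hst", sequence=seq)
        )
    pairs = sorted(
        (p.mirna_id, h.mirna_id)
        for p in plant
        for h in hosts
        if seed(p) == seed(h)
    )
    return hosts, pairs


def _make_multispecies(
    config: SimulationConfig,
    rng: np.random.Generator,
    plant: list[MatureMiRNA],
    kept: list[MatureMiRNA],
) -> tuple[list[MatureMiRNA], dict[str, frozenset[str]]]:
    """Cross-species duplicates are planted for QC-passing miRNAs only —
    those are the queries of the conservation stage downstream."""
    species = list(_OTHER_SPECIES[: config.n_species])
    records: list[MatureMiRNA] = []
    conserved: dict[str, frozenset[str]] = {}
    plant_seq_set = {m.sequence for m in plant}
    # queries themselves appear under their own species, as in a real catalogue
    for m in plant:
        records.append(
            MatureMiRNA(mirna_id=m.mirna_id, species=m.species, sequence=m.sequence)
        )
    for m in kept:
        if rng.random() < config.conservation_fraction:
            n_sp = 1 + int(rng.integers(min(2, len(species))))
            chosen = sorted(
                rng.choice(species, size=n_sp, replace=False).tolist()
            )
            for sp in chosen:
                name = m.mirna_id.split("-", 1)[1]
                records.append(
                    MatureMiRNA(
                        mirna_id=f"{sp}-{name}", species=sp, sequence=m.sequence
                    )
                )
            conserved[m.mirna_id] = frozenset(chosen)
        else:
            conserved[m.mirna_id] = frozenset()
    for sp in species:
        for i in range(config.decoys_per_species):
            while True:
                seq = _random_rna(rng, int(rng.integers(20, 23)), config.gc_fraction)
                if seq not in plant_seq_set:
                    break
            records.append(
                MatureMiRNA(mirna_id=f"{sp}-bg{i + 1:02d}", species=sp, sequence=seq)
            )
    return records, conserved


def simulate_gene_sets(
    config: SimulationConfig,
    rng: np.random.Generator,
    universe: list[str],
    targeted: frozenset[str],
) -> GeneSetCollection:
    """Gene sets over ``universe`` with one term enriched for ``targeted``.

    The planted term contains ``planted_overlap_fraction`` of the targeted
    genes padded with random fillers; the remaining sets are uniform draws.
    """
    universe = sorted(universe)
    sets: dict[str, frozenset[str]] = {}
    # with nothing targeted the "planted" term degenerates to a random set
    n_hit = (
        max(1, int(round(len(targeted) * config.planted_overlap_fraction)))
        if targeted
        else 0
    )
    hit = sorted(rng.choice(sorted(targeted), size=n_hit, replace=False).tolist()) if n_hit else []
    size = int(
        rng.integers(
            max(config.gene_set_size_low, n_hit), config.gene_set_size_high + 1
        )
    )
    fillers = [g for g in universe if g not in set(hit)]
    pad = rng.choice(fillers, size=size - n_hit, replace=False).tolist()
    sets[config.planted_term] = frozenset(hit + pad)
    for i in range(config.n_gene_sets - 1):
        size = int(rng.integers(config.gene_set_size_low, config.gene_set_size_high + 1))
        members = rng.choice(universe, size=size, replace=False).tolist()
        sets[f"RANDOM_SET_{i + 1:02d}"] = frozenset(members)
    return GeneSetCollection(sets=sets, background=frozenset(universe))
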