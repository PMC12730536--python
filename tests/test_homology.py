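from xkmir.annotate import Interaction
from xkmir.duplex import EnergyParameters, hybridize, make_window
from xkmir.fixtures import pca_mirnas
from xkmir.homology import (
    find_conserved,
    find_seed_mimics,
    mimic_hybridize,
    read_multispecies_fasta,
)
from xkmir.io_formats import MatureMiRNA, TranscriptRecord
from xkmir.sites import find_sites, reverse_complement, seed


def mirna(seq, mid, species=None):
    return MatureMiRNA(
        mirna_id=mid, species=species or mid.split("-")[0], sequence=seq
    )


class TestSeedMimics:
    def test_shared_seed_detected(self):
        plant = [mirna("UGGAAGGGGCAUGCAGAGGAG", "zma-miR528a-5p")]
        host = [mirna("AGGAAGGCCCCCCCCCCCCC", "hsa-miR-x")]  # nt 2-7 = GGAAGG
        (pair,) = find_seed_mimics(plant, host)
        assert pair.shared_seed == "GGAAGG"

    def test_identical_sequences_necessarily_pair(self):
        seq = "GCUCACUUCUCUCUCUGUCAGU"
        pairs = find_seed_mimics([mirna(seq, "zma-a")], [mirna(seq, "hsa-b")])
        assert len(pairs) == 1

    def test_disjoint_seeds_empty(self):
        plant = [mirna("AAAAAAAAAAAAAAAAAAAA", "zma-a")]
        host = [mirna("CCCCCCCCCCCCCCCCCCCC", "hsa-b")]
        assert find_seed_mimics(plant, host) == []

    def test_invariant_under_input_permutation(self):
        plants = [mirna(m.sequence, m.mirna_id) for m in pca_mirnas()[:6]]
        hosts = [
            mirna("A" + seed(p) + "CCCCCCCCCCCCC", f"hsa-miR-{i}")
            for i, p in enumerate(plants[:3])
        ]
        fwd = find_seed_mimics(plants, hosts)
        rev = find_seed_mimics(plants[::-1], hosts[::-1])
        assert fwd == rev


class TestConservation:
    def test_cross_species_duplicate_reported(self):
        seq = "UUCCACAGGCUUUCUUGAACUG"
        query = [mirna(seq, "zma-miR396c")]
        catalogue = [mirna(seq, "zma-miR396c"), mirna(seq, "sbi-miR396")]
        (hit,) = find_conserved(query, catalogue)
        assert hit.matching_species == {"sbi"}
        assert hit.detected

    def test_single_nucleotide_variant_not_a_hit(self):
        seq = "UUCCACAGGCUUUCUUGAACUG"
        variant = seq[:-1] + "A"
        (hit,) = find_conserved(
            [mirna(seq, "zma-miR396c")], [mirna(variant, "sbi-miR396")]
        )
        assert not hit.detected

    def test_identity_is_symmetric(self):
        a = mirna("GAUCAUGUUGCAGCUUCAC", "zma-miR167h-3p")
        b = mirna("GAUCAUGUUGCAGCUUCAC", "osa-miR167h")
        (ha,) = find_conserved([a], [a, b])
        (hb,) = find_conserved([b], [a, b])
        assert "osa" in ha.matching_species and "zma" in hb.matching_species

    def test_self_catalogue_with_unique_ids_finds_nothing(self):
        queries = [
            mirna(m.sequence, m.mirna_id) for m in pca_mirnas()
        ]
        hits = find_conserved(queries, queries)
        assert all(not h.detected for h in hits)

    def test_mature_fasta_dialect(self, tmp_path):
        p = tmp_path / "mature.fa"
        p.write_text(
            ">zma-miR396c MIMAT0000000 Zea mays miR396c\nUUCCACAGGCUUUCUUGAACUG\n"
            ">sbi-miR396x\nuuccacaggcuuucuugaacug\n"
        )
        records = read_multispecies_fasta(p)
        assert [r.species for r in records] == ["zma", "sbi"]
        # T/U and case normalization applies before identity comparison
        (hit,) = find_conserved([records[0]], records)
        assert hit.matching_species == {"sbi"}


class TestMimicHybridize:
    def setup_case(self):
        plant = mirna("GCUCACUUCUCUCUCUGUCAGU", "zma-miR156a-3p")
        probe = reverse_complement(plant.sequence[1:13])
        seq = "CAGC" * 10 + probe + "GACU" * 10
        t = TranscriptRecord(
            transcript_id="t1", gene_symbol="BCL2", biotype="coding",
            sequence=seq, cds_start=10, cds_end=30,
        )
        (sm,) = find_sites([plant], [t])
        params = EnergyParameters()
        d = hybridize(plant, make_window(t, sm, len(plant)), params,
                      require_seed_wc=True, forbid_seed_gu=True)
        interaction = Interaction(
            mirna_id=plant.mirna_id, transcript_id="t1", gene_symbol="BCL2",
            region="THREE_UTR", site_start=sm.site_start, mfe=d.mfe,
        )
        return plant, t, interaction, params, d

    def test_identical_host_reproduces_plant_mfe(self):
        plant, t, interaction, params, d = self.setup_case()
        host = mirna(plant.sequence, "hsa-miR-same")
        pairs = find_seed_mimics([plant], [host])
        (row,) = mimic_hybridize(pairs, [interaction], [t], [host], params)
        assert row.mfe == d.mfe

    def test_seed_only_host_reported_without_threshold(self):
        """A host sharing only the seed can produce a weak duplex (MFE above
        -25) which must still be reported — the mimicry stage has no cutoff."""
        plant, t, interaction, params, _ = self.setup_case()
        host = mirna("A" + seed(plant) + "AAAAAAAAAAAAAA", "hsa-miR-weak")
        pairs = find_seed_mimics([plant], [host])
        rows = mimic_hybridize(pairs, [interaction], [t], [host], params)
        assert len(rows) == 1
        assert rows[0].mfe > -25.0
        assert rows[0].duplex.seed_perfect and rows[0].duplex.seed_gu_free

    def test_empty_host_set(self):
        plant, t, interaction, params, _ = self.setup_case()
        assert mimic_hybridize([], [interaction], [t], [], params) == []
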