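import numpy as np
import pytest

from xkmir.io_formats import MatureMiRNA
from xkmir.qc import filter_mirnas
from xkmir.simulate import (
    DECOY_SEED_GU,
    SimulationConfig,
    plant_site,
    simulate,
    simulate_gene_sets,
)
from xkmir.sites import extended_seed, find_sites, reverse_complement


def mirna(seq, mid="sim-miR001"):
    return MatureMiRNA(mirna_id=mid, species="sim", sequence=seq)


class TestPlantSite:
    SEQ = "C" * 120

    def test_no_extension_substitutes_exactly_twelve(self):
        rng = np.random.default_rng(0)
        m = mirna("GCUCACUUCUCUCUCUGUCAGU")
        out, n_sub = plant_site(self.SEQ, m, 50, extend_prob=0.0, rng=rng)
        assert n_sub == 12
        assert out[50:62] == reverse_complement(extended_seed(m))
        assert out[:50] == self.SEQ[:50] and out[62:] == self.SEQ[62:]
        assert len(out) == len(self.SEQ)

    def test_full_extension_of_21mer_substitutes_twenty(self):
        rng = np.random.default_rng(0)
        m = mirna("UGGAAGGGGCAUGCAGAGGAG")  # 21 nt
        out, n_sub = plant_site(self.SEQ, m, 50, extend_prob=1.0, rng=rng)
        assert n_sub == 12 + 8

    def test_planted_site_found_exactly_once(self):
        rng = np.random.default_rng(1)
        m = mirna("GCUCACUUCUCUCUCUGUCAGU")
        out, _ = plant_site(self.SEQ, m, 30, extend_prob=0.5, rng=rng)
        from xkmir.io_formats import TranscriptRecord

        t = TranscriptRecord(
            transcript_id="t", gene_symbol="G", biotype="noncoding", sequence=out
        )
        hits = find_sites([m], [t])
        assert [h.site_start for h in hits] == [30]

    def test_overflow_rejected(self):
        rng = np.random.default_rng(0)
        m = mirna("GCUCACUUCUCUCUCUGUCAGU")
        with pytest.raises(ValueError):
            plant_site("C" * 20, m, 10, 0.0, rng)


class TestSimulate:
    def test_bundle_determinism(self, default_bundle, tmp_path):
        again = simulate(SimulationConfig(seed=1))
        d1 = default_bundle.write(tmp_path / "a")
        d2 = again.write(tmp_path / "b")
        for key in d1:
            assert d1[key].read_bytes() == d2[key].read_bytes(), key

    def test_read_counts_straddle_threshold(self, default_bundle):
        counts = [m.read_count for m in default_bundle.plant_mirnas]
        cfg = default_bundle.config
        assert any(c <= cfg.min_reads_threshold for c in counts)
        assert any(c > cfg.min_reads_threshold for c in counts)
        report = filter_mirnas(default_bundle.plant_mirnas)
        assert 0 < len(report.kept) < len(default_bundle.plant_mirnas)

    def test_planted_sites_lie_in_declared_regions(self, default_bundle):
        from xkmir.annotate import classify_region

        tr = {t.transcript_id: t for t in default_bundle.transcripts}
        for s in default_bundle.truth.planted_sites:
            assert classify_region(tr[s.transcript_id], s.site_start) == s.region

    def test_planted_words_match_truth(self, default_bundle):
        mir = {m.mirna_id: m for m in default_bundle.plant_mirnas}
        tr = {t.transcript_id: t for t in default_bundle.transcripts}
        for s in default_bundle.truth.planted_sites:
            probe = reverse_complement(extended_seed(mir[s.mirna_id]))
            assert tr[s.transcript_id].sequence[s.site_start : s.site_start + 12] == probe

    def test_decoy_words_differ_from_probe(self, default_bundle):
        mir = {m.mirna_id: m for m in default_bundle.plant_mirnas}
        tr = {t.transcript_id: t for t in default_bundle.transcripts}
        for d in default_bundle.truth.decoys:
            probe = reverse_complement(extended_seed(mir[d.mirna_id]))
            word = tr[d.transcript_id].sequence[d.site_start : d.site_start + 12]
            assert word != probe
            if d.decoy_class == DECOY_SEED_GU:
                # exactly one substitution, inside the seed-opposing hexamer
                diffs = [i for i in range(12) if word[i] != probe[i]]
                assert len(diffs) == 1 and 6 <= diffs[0] < 12

    def test_gu_only_decoys_yield_zero_interactions(self):
        """Seed-altered decoys can never match the exact scan; any chance
        background 12-mer match lacks 3' complementarity and fails the MFE
        cutoff, so the standard pipeline accepts nothing."""
        from xkmir.duplex import EnergyParameters
        from xkmir.pipeline import hybridize_sites

        cfg = SimulationConfig(
            seed=5,
            sites_per_region={},
            decoys_per_class={DECOY_SEED_GU: 6},
        )
        bundle = simulate(cfg)
        kept = filter_mirnas(bundle.plant_mirnas).kept
        hits = find_sites(kept, bundle.transcripts)
        decoy_pos = {(d.transcript_id, d.site_start) for d in bundle.truth.decoys}
        assert all((h.transcript_id, h.site_start) not in decoy_pos for h in hits)
        accepted = hybridize_sites(
            hits,
            {m.mirna_id: m for m in kept},
            {t.transcript_id: t for t in bundle.transcripts},
            EnergyParameters(),
            mfe_threshold=-25.0,
            flank=10,
        )
        assert accepted == []

    def test_conservation_truth_has_correct_species_sets(self, default_bundle):
        from xkmir.homology import find_conserved

        kept = filter_mirnas(default_bundle.plant_mirnas).kept
        hits = find_conserved(kept, default_bundle.multispecies_mirnas)
        got = {h.mirna_id: h.matching_species for h in hits}
        for mid, expected in default_bundle.truth.conserved.items():
            assert got[mid] == expected

    def test_region_too_short_raises(self):
        cfg = SimulationConfig(
            seed=2, transcript_len_mean=80, transcript_len_sd=1,
            transcript_len_min=80, utr5_fraction=0.05,
        )
        with pytest.raises(ValueError, match="region too"):
            simulate(cfg)


def test_gene_set_generator_plants_enrichable_term():
    cfg = SimulationConfig(seed=3)
    rng = np.random.default_rng(3)
    universe = [f"G{i}" for i in range(160)]
    targeted = frozenset(universe[:14])
    coll = simulate_gene_sets(cfg, rng, universe, targeted)
    assert cfg.planted_term in coll.sets
    planted = coll.sets[cfg.planted_term]
    assert len(planted & targeted) >= int(0.8 * 14)
    assert len(coll.sets) == cfg.n_gene_sets
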