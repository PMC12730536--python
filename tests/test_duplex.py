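import random

import pytest

from xkmir.duplex import (
    DuplexStructure,
    EnergyParameters,
    brute_force_mfe,
    hybridize,
    load_params,
    make_window,
    passes_criteria,
    write_params,
)
from xkmir.io_formats import TranscriptRecord
from xkmir.sites import SeedMatch, reverse_complement


def rand_rna(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


class TestToyModel:
    def test_perfect_helix_energy(self, toy_params):
        """8-mer against its exact reverse complement: 7 stacks of -2 plus
        +4 initiation gives -10.0."""
        m = "ACGUACGU"
        d = hybridize(m, reverse_complement(m), toy_params)
        assert d.mfe == -10.0
        assert len(d.pairs) == 8

    def test_unsatisfiable_seed_constraint_gives_no_structure(self, toy_params):
        # seed nt 2-7 = CCCCCC pairs only G; window has no G
        d = hybridize("ACCCCCCAAAAAA", "AUAUAUAUAU", toy_params, require_seed_wc=True)
        assert d is None

    def test_single_pair_costs_helix_init(self, toy_params):
        # exactly one admissible pair (A-U), no stack possible
        d = hybridize("AC", "CU", toy_params)
        assert d.mfe == toy_params.helix_init == 4.0
        assert not passes_criteria(d, mfe_threshold=-0.0001)

    def test_bulge_penalty_applied(self, toy_params):
        # miRNA ACGU vs target ACGAU: RC(ACGU)=ACGU, one extra A forces a
        # 1-nt target bulge between the GC and UA stacks if all 4 pairs form
        d = hybridize("ACGU", "ACGAU", toy_params)
        b = brute_force_mfe("ACGU", "ACGAU", toy_params)
        assert d.mfe == b.mfe and d.pairs == b.pairs


class TestOracleAgreement:
    def test_dp_matches_enumeration_on_random_instances(self, toy_params):
        """DP and exhaustive enumeration agree exactly (energy and pair list)
        over random sequences, parameter sets and constraint combinations."""
        rng = random.Random(42)
        default = EnergyParameters()
        for k in range(150):
            ml, wl = rng.randint(5, 10), rng.randint(6, 12)
            ms, ws = rand_rna(rng, ml), rand_rna(rng, wl)
            req = ml >= 7 and rng.random() < 0.3
            gu = rng.random() < 0.3
            params = toy_params if k % 2 else default
            d = hybridize(ms, ws, params, require_seed_wc=req, forbid_seed_gu=gu)
            b = brute_force_mfe(ms, ws, params, require_seed_wc=req, forbid_seed_gu=gu)
            if b is None:
                assert d is None
            else:
                assert d.mfe == b.mfe
                assert d.pairs == b.pairs

    def test_brute_force_size_bound_enforced(self):
        with pytest.raises(ValueError, match="bound"):
            brute_force_mfe("A" * 11, "U" * 5)


class TestInvariants:
    def test_translation_invariance(self, toy_params):
        """Embedding the window in a larger identical context never changes
        the optimum energy."""
        rng = random.Random(3)
        for _ in range(20):
            m = rand_rna(rng, 9)
            w = rand_rna(rng, 10)
            inner = hybridize(m, w, toy_params)
            padded = hybridize(m, rand_rna(rng, 4) + w + rand_rna(rng, 4), toy_params)
            if inner is not None:
                assert padded is not None and padded.mfe <= inner.mfe

    def test_constraint_relaxation_never_raises_optimum(self):
        rng = random.Random(7)
        params = EnergyParameters()
        for _ in range(30):
            m, w = rand_rna(rng, 9), rand_rna(rng, 11)
            strict = hybridize(m, w, params, require_seed_wc=True, forbid_seed_gu=True)
            loose = hybridize(m, w, params, require_seed_wc=True, forbid_seed_gu=False)
            free = hybridize(m, w, params)
            if strict is not None:
                assert loose is not None and loose.mfe <= strict.mfe
                assert free is not None and free.mfe <= loose.mfe

    def test_seed_flags_reflect_pairing(self):
        params = EnergyParameters()
        m = "AACGUACGUACGUA"
        d = hybridize(m, reverse_complement(m), params, require_seed_wc=True)
        assert d.seed_perfect and d.seed_gu_free


class TestWindow:
    def t(self, n=200):
        return TranscriptRecord(
            transcript_id="t1", gene_symbol="G", biotype="noncoding", sequence="A" * n
        )

    def sm(self, start):
        return SeedMatch("m", "t1", start, start + 12, "U" * 12)

    def test_window_formula(self):
        w = make_window(self.t(), self.sm(30), mirna_length=22, flank=10)
        assert (w.window_start, w.window_end) == (11, 53)

    def test_window_clipped_at_transcript_start(self):
        w = make_window(self.t(), self.sm(0), mirna_length=22, flank=10)
        assert w.window_start == 0

    def test_minimal_window(self):
        w = make_window(self.t(), self.sm(50), mirna_length=13, flank=0)
        assert (w.window_start, w.window_end) == (50, 63)

    def test_pairs_in_transcript_coordinates(self):
        """Folding against a TargetWindow reports transcript-local target
        positions covering the seed-match span."""
        probe_owner = "GCUCACUUCUCUCUCUGUCAGU"
        probe = reverse_complement(probe_owner[1:13])
        seq = "C" * 40 + probe + "C" * 40
        t = TranscriptRecord(
            transcript_id="t1", gene_symbol="G", biotype="noncoding", sequence=seq
        )
        smatch = SeedMatch("m", "t1", 40, 52, probe)
        w = make_window(t, smatch, len(probe_owner))
        d = hybridize(probe_owner, w, EnergyParameters(),
                      require_seed_wc=True, forbid_seed_gu=True)
        target_at = {i: j for i, j in d.pairs}
        # miRNA nt 2..13 sit antiparallel across the matched 12-mer
        for nt in range(2, 14):
            assert target_at[nt] == 52 - (nt - 1)


class TestCriteria:
    def mk(self, mfe, seed_perfect=True, seed_gu_free=True):
        return DuplexStructure(
            pairs=((2, 10),), mfe=mfe, seed_perfect=seed_perfect,
            seed_gu_free=seed_gu_free,
        )

    def test_threshold_is_strict(self):
        assert not passes_criteria(self.mk(-25.0))
        assert passes_criteria(self.mk(-25.7))

    def test_seed_gu_rejects_regardless_of_energy(self):
        assert not passes_criteria(self.mk(-40.0, seed_gu_free=False))

    def test_imperfect_seed_rejects(self):
        assert not passes_criteria(self.mk(-30.0, seed_perfect=False))

    def test_no_structure_never_passes(self):
        assert not passes_criteria(None)

    def test_threshold_disabled(self):
        assert passes_criteria(self.mk(-1.0), mfe_threshold=None)


def test_params_roundtrip(tmp_path):
    params = EnergyParameters(helix_init=3.0, max_bulge=7)
    p = tmp_path / "params.tsv"
    write_params(params, p)
    loaded = load_params(p)
    assert loaded.helix_init == 3.0
    assert loaded.max_bulge == 7
    assert loaded.stack_energy == params.stack_energy


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        EnergyParameters(bulge_open=-1.0)
    with pytest.raises(ValueError):
        EnergyParameters(stack_energy={**EnergyParameters().stack_energy, ("AU", "UA"): 1.0})
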