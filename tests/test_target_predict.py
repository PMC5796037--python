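import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from mirmint._errors import ConfigError, FormatError
from mirmint.data import MIR_204_5P_SEQUENCE
from mirmint.target_predict import (
    MatureMirna,
    PAIR_HALF_STACK,
    PredictorThresholds,
    STACK_ENERGIES,
    accessibility_ddg,
    align_score,
    consensus_predict,
    duplex_mfe,
    find_seed_sites,
    nussinov_pairs,
    reverse_complement,
    seed_of,
)

BASES = "ACGU"


def _random_seq(rng, lo, hi):
    return "".join(rng.choice(list(BASES), size=rng.integers(lo, hi + 1)))


class TestSeed:
    def test_printed_mimic_seed7_and_seed6(self):
        seed7, seed6 = seed_of(MIR_204_5P_SEQUENCE)
        assert seed7 == "UCCCUUU"
        assert seed6 == "UCCCUU"

    def test_short_sequence_rejected(self):
        with pytest.raises(ConfigError):
            seed_of("UUCCCUU")

    def test_mature_mirna_validation(self):
        with pytest.raises(FormatError, match="18-26"):
            MatureMirna("x", "ACGU")
        with pytest.raises(FormatError, match="non-RNA"):
            MatureMirna("x", "N" * 22)
        assert MatureMirna("x", "acgtacgtacgtacgtacgt").sequence == "ACGUACGUACGUACGUACGU"


class TestSeedScanner:
    def test_8mer_example(self):
        (site,) = find_seed_sites(MIR_204_5P_SEQUENCE, "GGAAAGGGAAGG")
        assert (site.start, site.end, site.seed_class) == (2, 10, "8mer")
        assert "GGAAAGGGAAGG"[site.start:site.end] == "AAAGGGAA"

    def test_poly_u_has_no_sites(self):
        assert find_seed_sites(MIR_204_5P_SEQUENCE, "U" * 40) == []

    def test_exact_rc_seed7_is_7mer_m8(self):
        mirna = "UGCACGAUCGAUCGAUCGAUCG"
        utr = reverse_complement(seed_of(mirna)[0])
        (site,) = find_seed_sites(mirna, utr)
        assert (site.start, site.end, site.seed_class) == (0, 7, "7mer-m8")

    def test_case_and_tu_representation_invariance(self, rng):
        mirna = _random_seq(rng, 20, 22)
        utr = reverse_complement(mirna[1:]) + "A" + _random_seq(rng, 30, 40)
        ref = [(s.start, s.end, s.seed_class) for s in find_seed_sites(mirna, utr)]
        for variant in (utr.lower(), utr.replace("U", "T"), utr.replace("U", "t")):
            got = [(s.start, s.end, s.seed_class)
                   for s in find_seed_sites(mirna, variant)]
            assert got == ref

    def test_matches_naive_pattern_oracle(self, rng):
        for _ in range(400):
            mirna = _random_seq(rng, 18, 26)
            # AU-biased UTRs raise the chance of seed hits
            utr = "".join(rng.choice(list("AAUUGC"), size=rng.integers(20, 120)))
            got = {(s.start, s.end, s.seed_class)
                   for s in find_seed_sites(mirna, utr)}
            assert got == oracles.naive_seed_sites(mirna, utr)


class TestDuplexMfe:
    def test_gc_duplex_is_hand_summed_stack_total(self):
        # 8 GC pairs -> 7 GC/GC stacks from the shipped table
        expected = 7 * STACK_ENERGIES[("GC", "GC")]
        assert duplex_mfe("G" * 8, "C" * 8) == pytest.approx(expected)
        assert expected == pytest.approx(-23.1)

    def test_no_complementarity_gives_sentinel(self):
        assert duplex_mfe("AAAA", "AAAA") is None

    def test_lone_pair_scores_zero(self):
        assert duplex_mfe("A", "U") == 0.0

    def test_window_cap_enforced(self):
        with pytest.raises(ConfigError):
            duplex_mfe("ACGU", "A" * 41)

    def test_half_stack_symmetry_of_table(self):
        for (p, q), e in STACK_ENERGIES.items():
            assert e == STACK_ENERGIES[(q, p)]
            assert e == -(PAIR_HALF_STACK[p] + PAIR_HALF_STACK[q])

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(250):
            u = _random_seq(rng, 1, 6)
            w = _random_seq(rng, 1, 6)
            assert duplex_mfe(u, w) == pytest.approx(
                oracles.enumerate_duplex_mfe(u, w), abs=1e-9
            ) or (duplex_mfe(u, w) is None
                  and oracles.enumerate_duplex_mfe(u, w) is None)


class TestAlignScore:
    def test_perfect_seed_site_scores_seventy(self):
        # 7 seed pairs x (+5) x seed weight 2, nothing else to pair
        mirna = MIR_204_5P_SEQUENCE
        window = reverse_complement(seed_of(mirna)[0])
        assert align_score(mirna, window) == 70.0

    def test_empty_window_scores_zero(self):
        assert align_score(MIR_204_5P_SEQUENCE, "") == 0.0

    def test_random_unrelated_20mers_stay_below_default_threshold(self, rng):
        n_hits = sum(
            align_score(_random_seq(rng, 20, 20), _random_seq(rng, 20, 20)) >= 80.0
            for _ in range(1000)
        )
        assert n_hits < 10  # < 1% by construction of the default cutoff

    def test_full_complement_beats_seed_only(self):
        mirna = MIR_204_5P_SEQUENCE
        full = reverse_complement(mirna[1:]) + "A"
        seed_only = reverse_complement(seed_of(mirna)[0])
        assert align_score(mirna, full) > align_score(mirna, seed_only)


class TestNussinov:
    def test_unpairable_sequence_has_zero_pairs(self):
        assert nussinov_pairs("AAAAAAAA") == 0

    def test_perfect_hairpin_counts_stem(self):
        assert nussinov_pairs("G" * 10 + "AAAA" + "C" * 10) == 10

    def test_min_loop_excludes_tight_hairpins(self):
        assert nussinov_pairs("GAAAC") == 1   # loop of exactly 3
        assert nussinov_pairs("GAAC") == 0    # loop of 2: forbidden

    def test_matches_enumeration(self, rng):
        for _ in range(120):
            s = _random_seq(rng, 1, 12)
            assert nussinov_pairs(s) == oracles.enumerate_max_pairs(s)


class TestAccessibility:
    def test_unstructured_context_equals_duplex_mfe(self):
        # site has no self-pairing and poly-A flanks: dG_open = 0
        mirna = "G" * 20
        utr = "A" * 17 + "C" * 10 + "A" * 17
        ddg = accessibility_ddg(mirna, utr, (17, 27))
        assert ddg == pytest.approx(duplex_mfe(mirna, utr[17:27]))

    def test_perfect_hairpin_costs_its_stem(self):
        # 10-bp GC hairpin inside the probed region, poly-A elsewhere
        mirna = "C" * 20  # pairs the G side of the stem
        region = "G" * 10 + "AAAA" + "C" * 10
        utr = "A" * 17 + region + "A" * 17
        site = (17, 17 + len(region))
        ddg = accessibility_ddg(mirna, utr, site)
        mfe = duplex_mfe(mirna, utr[site[0]:site[1]])
        assert ddg == pytest.approx(mfe + 10.0)

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ConfigError):
            accessibility_ddg("G" * 20, "ACGU" * 5, (10, 30))


class TestConsensusPredict:
    def _planted_case(self, rng):
        mirna_seq = _random_seq(rng, 22, 22)
        mirna = MatureMirna("m", mirna_seq)
        utr = (
            _random_seq(rng, 40, 60)
            + reverse_complement(mirna_seq[1:]) + "A"
            + _random_seq(rng, 40, 60)
        )
        return mirna, utr

    def test_planted_full_site_passes_all_three(self, rng):
        for _ in range(10):
            mirna, utr = self._planted_case(rng)
            sites = consensus_predict(mirna, utr, mrna_id="g")
            assert any(
                s.seed_class == "8mer" and len(s.predictors_passed) == 3
                for s in sites
            )

    def test_all_three_subset_of_union(self, rng):
        for _ in range(10):
            mirna, utr = self._planted_case(rng)
            strict = {(s.start, s.end)
                      for s in consensus_predict(mirna, utr, require_all_three=True)}
            union = {(s.start, s.end)
                     for s in consensus_predict(mirna, utr, require_all_three=False)}
            assert strict <= union

    def test_weak_6mer_fails_strict_but_can_pass_union(self):
        mirna = MatureMirna("m", MIR_204_5P_SEQUENCE)
        utr = "C" * 20 + reverse_complement(seed_of(mirna)[1]) + "C" * 21
        thresholds = PredictorThresholds()
        assert consensus_predict(mirna, utr, thresholds) == []
        union = consensus_predict(mirna, utr, thresholds, require_all_three=False)
        assert [s.seed_class for s in union] == ["6mer"]

    def test_seed_class_gate(self):
        mirna = MatureMirna("m", MIR_204_5P_SEQUENCE)
        utr = "C" * 20 + reverse_complement(seed_of(mirna)[1]) + "C" * 21
        gated = PredictorThresholds(min_seed_class="7mer-A1")
        assert consensus_predict(mirna, utr, gated, require_all_three=False) == []

    def test_empty_utr_set_empty_output(self):
        from mirmint.target_predict import predict_targets

        assert predict_targets([MatureMirna("m", MIR_204_5P_SEQUENCE)], {}) == []

    def test_sites_tsv_round_trip(self, tmp_path, rng):
        from mirmint.target_predict import sites_from_tsv, sites_to_tsv

        mirna, utr = self._planted_case(rng)
        sites = consensus_predict(mirna, utr, mrna_id="g1")
        p = tmp_path / "sites.tsv"
        sites_to_tsv(sites, p)
        back = sites_from_tsv(p)
        assert [(s.mirna_id, s.mrna_id, s.start, s.end, s.seed_class,
                 s.predictors_passed) for s in back] == [
            (s.mirna_id, s.mrna_id, s.start, s.end, s.seed_class,
             s.predictors_passed) for s in sites
        ]
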