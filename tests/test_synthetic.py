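import json
import hashlib
from pathlib import Path

import numpy as np
import pytest

from mirmint._errors import ConfigError
from mirmint.data import MIR_204_5P_SEQUENCE
from mirmint.diffexpr import LOG2_1P5, overexpression_filter
from mirmint.synthetic_cohort import (
    SimulationConfig,
    SyntheticTruth,
    evaluate_recovery,
    simulate_cohorts,
    simulate_overexpression,
    simulate_to_dir,
    simulate_utrs,
)
from mirmint.target_predict import find_seed_sites, reverse_complement, seed_of


def _dir_digest(d) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestConfigInvariants:
    def test_infeasible_planting_rejected(self):
        with pytest.raises(ConfigError, match="plant"):
            SimulationConfig(n_mirnas=10, frac_de_mirna=0.2, n_planted_pairs=50)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_mirnas=-1)

    def test_zero_noise_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(noise_sd=0.0)


class TestCohorts:
    def test_planted_pairs_oppose_and_anticorrelate(self):
        # strong effect, tiny noise: every planted pair must satisfy the
        # generative contract on the emitted matrices themselves
        cfg = SimulationConfig(
            n_mirnas=60, n_mrnas=120, de_shift=3.0, noise_sd=0.1,
            n_planted_pairs=10, samples_per_group=10, utr_length=300,
            rng_seed=7,
        )
        _, _, (mm, mg), truth = simulate_cohorts(cfg)
        tumor = mm.samples_in("tumor")
        for mirna_id, gene_id, _beta in truth.planted_pairs:
            assert truth.de_mirnas[mirna_id] == "down"
            assert truth.de_mrnas[gene_id] == "up"
            x = mm.values.loc[mirna_id, tumor]
            y = mg.values.loc[gene_id, tumor]
            assert np.corrcoef(x, y)[0, 1] < 0
            # opposite shifts visible in the matrices
            assert (mm.group_values("tumor").loc[mirna_id].mean()
                    < mm.group_values("normal").loc[mirna_id].mean())
            assert (mg.group_values("tumor").loc[gene_id].mean()
                    > mg.group_values("normal").loc[gene_id].mean())

    def test_matched_pair_shares_sample_list(self, small_study):
        _, _, (mm, mg), _, _ = small_study
        assert mm.sample_ids == mg.sample_ids

    def test_null_config_has_empty_truth(self):
        cfg = SimulationConfig(
            n_mirnas=20, n_mrnas=50, frac_de_mirna=0.0, frac_de_mrna=0.0,
            n_planted_pairs=0, samples_per_group=5, rng_seed=5,
        )
        _, _, _, truth = simulate_cohorts(cfg)
        assert truth.de_mirnas == {} and truth.de_mrnas == {}
        assert truth.planted_pairs == []

    def test_byte_identical_outputs_under_same_seed(self, tmp_path):
        cfg = dict(n_mirnas=30, n_mrnas=60, n_planted_pairs=4,
                   samples_per_group=5, utr_length=200, rng_seed=99)
        simulate_to_dir(SimulationConfig(**cfg), tmp_path / "a")
        simulate_to_dir(SimulationConfig(**cfg), tmp_path / "b")
        assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")

    def test_truth_json_round_trip(self, tmp_path, small_study):
        truth = small_study[3]
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = SyntheticTruth.from_json(p)
        assert back.planted_pairs == truth.planted_pairs
        assert back.de_mirnas == truth.de_mirnas
        assert back.planted_sites == truth.planted_sites


class TestUtrs:
    def test_planted_site_is_exactly_the_recorded_one(self, small_study):
        _, _, _, truth, utrs = small_study
        for gene_id, site in truth.planted_sites.items():
            mirna_seq = truth.mirna_sequences[site["mirna_id"]]
            found = find_seed_sites(mirna_seq, utrs[gene_id])
            assert [(s.start, s.end, s.seed_class) for s in found] == [
                (site["start"], site["end"], site["seed_class"])
            ]

    def test_mir204_embedding_contains_printed_8mer(self):
        cfg = SimulationConfig(
            n_mirnas=30, n_mrnas=60, n_planted_pairs=3, samples_per_group=5,
            utr_length=250, rng_seed=17,
        )
        _, _, _, truth = simulate_cohorts(cfg)
        focus = truth.planted_pairs[0][0]
        truth.mirna_sequences[focus] = MIR_204_5P_SEQUENCE
        utrs = simulate_utrs(cfg, truth)
        gene = truth.targets_of(focus)[0]
        site = truth.planted_sites[gene]
        assert utrs[gene][site["start"]:site["end"]] == "AAAGGGAA"
        assert reverse_complement(seed_of(MIR_204_5P_SEQUENCE)[0]) + "A" == "AAAGGGAA"

    def test_non_planted_utrs_free_of_de_seed_matches(self, small_study):
        _, _, _, truth, utrs = small_study
        cores = {
            reverse_complement(seed_of(truth.mirna_sequences[m])[1])
            for m in truth.de_mirnas
        }
        planted = set(truth.planted_sites)
        for gene_id, utr in utrs.items():
            if gene_id in planted:
                continue
            for i in range(len(utr) - 5):
                assert utr[i:i + 6] not in cores

    @pytest.mark.parametrize("seed_class", ["6mer", "7mer-A1", "7mer-m8", "8mer"])
    def test_every_seed_class_embeds_and_scans_back(self, seed_class):
        cfg = SimulationConfig(
            n_mirnas=30, n_mrnas=60, n_planted_pairs=3, samples_per_group=5,
            utr_length=250, seed_site_class=seed_class, rng_seed=23,
        )
        _, _, _, truth = simulate_cohorts(cfg)
        utrs = simulate_utrs(cfg, truth)
        for gene_id, site in truth.planted_sites.items():
            found = find_seed_sites(
                truth.mirna_sequences[site["mirna_id"]], utrs[gene_id]
            )
            assert [(s.start, s.end, s.seed_class) for s in found] == [
                (site["start"], site["end"], seed_class)
            ]


class TestOverexpression:
    def test_planted_targets_all_pass_down_filter(self, small_config, small_study):
        truth = small_study[3]
        focus = truth.planted_pairs[0][0]
        table = simulate_overexpression(truth, focus, small_config)
        _, down = overexpression_filter(table)
        assert set(truth.targets_of(focus)) <= set(down)
        lfc = table["mimic"] - table["scrambled"]
        for g in truth.targets_of(focus):
            assert lfc[g] <= -(LOG2_1P5 + small_config.oe_margin)

    def test_mirna_without_targets_yields_empty_intersection(
        self, small_config, small_study
    ):
        from mirmint.candidates import intersect_candidates

        truth = small_study[3]
        unplanted = next(
            m for m in truth.de_mirnas if not truth.targets_of(m)
        )
        table = simulate_overexpression(truth, unplanted, small_config)
        _, down = overexpression_filter(table)
        assert intersect_candidates(truth.targets_of(unplanted), down) == []

    def test_unknown_mirna_rejected(self, small_config, small_study):
        with pytest.raises(ConfigError):
            simulate_overexpression(small_study[3], "no-such-mirna", small_config)

    def test_deterministic_under_seed(self, small_config, small_study):
        truth = small_study[3]
        focus = truth.planted_pairs[0][0]
        a = simulate_overexpression(truth, focus, small_config)
        b = simulate_overexpression(truth, focus, small_config)
        assert a.equals(b)


class TestRecoveryScore:
    def test_perfect_report(self):
        truth = SyntheticTruth({}, {}, [("m", "g", 0.8)], {})
        assert evaluate_recovery([("m", "g")], truth) == (1.0, 1.0, 1.0)

    def test_empty_report_keeps_precision_convention(self):
        truth = SyntheticTruth({}, {}, [("m", "g", 0.8)], {})
        p, r, f1 = evaluate_recovery([], truth)
        assert (p, r) == (1.0, 0.0)
        assert f1 == 0.0

    def test_one_spurious_of_ten(self):
        pairs = [(f"m{i}", f"g{i}", 0.8) for i in range(10)]
        truth = SyntheticTruth({}, {}, pairs, {})
        reported = [(m, g) for m, g, _ in pairs] + [("mX", "gX")]
        p, r, _ = evaluate_recovery(reported, truth)
        assert p == pytest.approx(10 / 11)
        assert r == 1.0
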