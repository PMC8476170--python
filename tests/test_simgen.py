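"""Tests of the synthetic-evolution generator against closed forms and truth."""

import math

import numpy as np
import pytest

from genochron.divergence import STOP_CODONS
from genochron.simgen import (
    SimConfig,
    evolve_sequence_jc,
    random_sequence,
    simulate_karyotype_evolution,
    simulate_ortholog_triplets,
    simulate_paralog_family,
    simulate_te_history,
)


def expected_p(rt: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * rt / 3.0))


class TestEvolveSequenceJC:
    def test_zero_time_is_identity(self):
        seq = random_sequence(500, np.random.default_rng(0))
        assert evolve_sequence_jc(seq, 0.01, 0.0, seed=1) == seq

    def test_non_acgt_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 4"):
            evolve_sequence_jc("ACGN", 0.01, 1.0, seed=1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence_jc("", 0.01, 1.0, seed=1)

    def test_deterministic_given_seed(self):
        seq = random_sequence(1000, np.random.default_rng(3))
        a = evolve_sequence_jc(seq, 0.01, 5.0, seed=99)
        b = evolve_sequence_jc(seq, 0.01, 5.0, seed=99)
        assert a == b

    def test_marginal_matches_closed_form(self):
        # 1e5 sites at r*t = 0.05: observed mismatch fraction within
        # 4 binomial SD of p = 0.75*(1 - exp(-0.0667)) = 0.04837
        n = 100_000
        seq = random_sequence(n, np.random.default_rng(2))
        out = evolve_sequence_jc(seq, 0.01, 5.0, seed=1)
        p = expected_p(0.05)
        observed = sum(a != b for a, b in zip(seq, out)) / n
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 4 * sd


class TestTEHistory:
    def test_zero_age_burst_identical_to_consensus(self):
        cfg = SimConfig(seed=1, burst_times=[0.0], copies_per_burst=20,
                        copy_length=100)
        h = simulate_te_history(cfg)
        assert (h.truth.true_D == 0).all()
        consensus = h.consensi["FAM0"]
        assert all(s == consensus for s in h.copies.values())

    def test_mean_divergence_matches_jc_expectation(self):
        # burst at 10 Myr, r = 0.005: copy-vs-consensus K = 2rt = 0.10
        cfg = SimConfig(seed=7, rate_r=0.005, burst_times=[10.0],
                        copies_per_burst=300, copy_length=1000,
                        age_jitter_sd=0.0)
        h = simulate_te_history(cfg)
        p = expected_p(0.10)
        assert h.truth.true_D.mean() / 100.0 == pytest.approx(p, rel=0.03)

    def test_two_bursts_truth_bookkeeping(self):
        cfg = SimConfig(seed=5, burst_times=[4.0, 20.0], copies_per_burst=50,
                        copy_length=200)
        h = simulate_te_history(cfg)
        ages = h.truth.true_age_myr
        assert (ages == 4.0).sum() == 50
        assert (ages == 20.0).sum() == 50
        # bimodal divergences: modes separated
        young = h.truth.loc[ages == 4.0, "true_D"]
        old = h.truth.loc[ages == 20.0, "true_D"]
        assert young.max() < old.min()

    def test_truth_conservation(self):
        cfg = SimConfig(seed=2, burst_times=[3.0, 9.0], copies_per_burst=10,
                        copy_length=100)
        h = simulate_te_history(cfg)
        assert sorted(h.copies) == sorted(h.truth.copy_id)
        assert h.truth.copy_id.is_unique

    def test_short_copies_rejected(self):
        with pytest.raises(ValueError, match="50"):
            simulate_te_history(SimConfig(copy_length=49))

    def test_jitter_truncated_at_zero(self):
        cfg = SimConfig(seed=3, burst_times=[1.0], copies_per_burst=200,
                        copy_length=100, age_jitter_sd=2.0)
        h = simulate_te_history(cfg)
        assert (h.truth.true_age_myr >= 0).all()


class TestParalogFamily:
    def test_zero_age_duplication_identical(self):
        fam = simulate_paralog_family(SimConfig(seed=1, dup_times=[0.0],
                                                codon_count=100))
        seqs = list(fam.cds.values())
        assert len(seqs) == 2 and seqs[0] == seqs[1]

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            simulate_paralog_family(SimConfig(dup_times=[40.0, 5.0]))

    def test_no_internal_stops_ever(self):
        fam = simulate_paralog_family(
            SimConfig(seed=9, dup_times=[5.0, 40.0], codon_count=150,
                      rate_r=0.01)
        )
        for seq in fam.cds.values():
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOP_CODONS)

    def test_serial_duplication_truth_ordering(self):
        fam = simulate_paralog_family(
            SimConfig(seed=3, dup_times=[5.0, 40.0], codon_count=120)
        )
        assert len(fam.cds) == 3
        ages = fam.truth.set_index(["id_a", "id_b"]).true_age_myr
        assert ages.min() == 5.0 and ages.max() == 40.0
        # exactly one young pair, two old pairs
        assert (ages == 5.0).sum() == 1
        assert (ages == 40.0).sum() == 2


class TestOrthologTriplets:
    def test_outgroup_must_predate_ingroup(self):
        with pytest.raises(ValueError):
            simulate_ortholog_triplets(
                SimConfig(ingroup_time=50.0, outgroup_time=40.0)
            )

    def test_equal_rates_pairwise_divergence_additive(self):
        cfg = SimConfig(seed=1, rate_a=0.002, rate_b=0.002, rate_c=0.002,
                        ingroup_time=10.0, outgroup_time=100.0,
                        n_triplets=30, alignment_length=5000)
        ts = simulate_ortholog_triplets(cfg)
        p_obs = np.mean([
            sum(x != y for x, y in zip(a["A"], a["B"])) / len(a["A"])
            for a in ts.alignments
        ])
        assert p_obs == pytest.approx(expected_p(2 * 0.002 * 10.0), rel=0.05)

    def test_mutual_best_hits_match_truth_without_noise(self):
        from genochron.rates import reciprocal_best_hits

        ts = simulate_ortholog_triplets(SimConfig(seed=4, n_triplets=40))
        pairs = reciprocal_best_hits(ts.hits[("A", "B")], ts.hits[("B", "A")])
        expected = {(f"A_g{i}", f"B_g{i}") for i in range(40)}
        assert set(pairs) == expected

    def test_noise_fraction_of_pairs_disagree(self):
        from genochron.rates import reciprocal_best_hits

        ts = simulate_ortholog_triplets(
            SimConfig(seed=11, n_triplets=100, noise_frac=0.1)
        )
        pairs = reciprocal_best_hits(ts.hits[("A", "B")], ts.hits[("B", "A")])
        wrong = sum(1 for a, b in pairs if a.split("_g")[1] != b.split("_g")[1])
        assert wrong == 10


class TestKaryotypeSim:
    def test_empty_spec_identity(self):
        kar = simulate_karyotype_evolution(SimConfig(seed=1, genes_per_alg=10))
        assert kar.loci_b.chrom.nunique() == 17
        assert kar.truth_events.empty
        # every gene still on its ancestral chromosome
        merged = kar.truth_genes
        assert (
            merged.apply(lambda r: r.chrom == "B" + r.alg[3:], axis=1)
        ).all()

    def test_fusions_and_translocation_chromosome_count(self):
        cfg = SimConfig(
            seed=2,
            genes_per_alg=20,
            karyotype_spec=[
                "fuse(ALG3,ALG10)->C7",
                "fuse(ALG6,ALG15)->C12",
                "translocate(0.3,ALG2)->B5",
            ],
        )
        kar = simulate_karyotype_evolution(cfg)
        assert kar.loci_b.chrom.nunique() == 15
        assert len(kar.truth_events) == 3
        moved = kar.truth_genes.query("alg == 'ALG2' and chrom == 'B5'")
        assert len(moved) == 6  # 30% of 20

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            simulate_karyotype_evolution(
                SimConfig(karyotype_spec=["fuse(ALG3,ALG99)->C1"])
            )

    def test_noise_moves_expected_gene_count(self):
        cfg = SimConfig(seed=5, genes_per_alg=100, noise_frac=0.05)
        kar = simulate_karyotype_evolution(cfg)
        off = (
            kar.truth_genes.apply(
                lambda r: r.chrom != "B" + r.alg[3:], axis=1
            )
        ).sum()
        # 85 genes reassigned uniformly over 17 chromosomes: ~80 land off
        # their own; allow binomial slop
        assert 60 <= off <= 90

    def test_determinism(self):
        cfg = SimConfig(seed=8, genes_per_alg=15, noise_frac=0.1)
        a = simulate_karyotype_evolution(cfg)
        b = simulate_karyotype_evolution(cfg)
        assert a.loci_b.equals(b.loci_b)
        assert a.truth_genes.equals(b.truth_genes)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(noise_frac=1.0)
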