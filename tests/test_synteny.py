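"""Tests of ALG assignment, contingency, event calls, CI, and dot plots."""

import numpy as np
import pytest

from genochron.rates import reciprocal_best_hits
from genochron.simgen import SimConfig, simulate_karyotype_evolution
from genochron.synteny import (
    GeneLocus,
    assign_genes_to_algs,
    call_rearrangement_events,
    chromosome_alg_contingency,
    conservation_index,
    dotplot_coordinates,
)


def run_karyotype(cfg: SimConfig):
    kar = simulate_karyotype_evolution(cfg)
    pairs = reciprocal_best_hits(kar.hits[("B", "A")], kar.hits[("A", "B")])
    assignments, unassigned = assign_genes_to_algs(pairs, kar.alg_map)
    loci_b = {
        r.name: GeneLocus(r.name, r.chrom, int(r.start), int(r.end), r.strand)
        for r in kar.loci_b.itertuples(index=False)
    }
    table = chromosome_alg_contingency(assignments, loci_b)
    return kar, pairs, assignments, unassigned, loci_b, table


class TestAssignment:
    def test_partner_alg_inherited(self):
        asg, un = assign_genes_to_algs([("g1", "ref1")], {"ref1": "ALG5"})
        assert asg == {"g1": "ALG5"} and un == 0

    def test_partner_absent_from_map_unassigned(self):
        asg, un = assign_genes_to_algs([("g1", "refX")], {"ref1": "ALG5"})
        assert asg == {} and un == 1

    def test_duplicate_focal_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assign_genes_to_algs(
                [("g1", "r1"), ("g1", "r2")], {"r1": "ALG1", "r2": "ALG2"}
            )

    def test_noise_free_assignment_matches_truth(self):
        kar, _, assignments, un, _, _ = run_karyotype(
            SimConfig(seed=3, genes_per_alg=10)
        )
        truth = dict(zip(kar.truth_genes.gene_id, kar.truth_genes.alg))
        assert un == 0
        assert assignments == truth


class TestContingency:
    def test_identity_karyotype_diagonal_significant(self):
        _, _, _, _, _, table = run_karyotype(
            SimConfig(seed=1, genes_per_alg=100)
        )
        sig = table.significant.to_numpy()
        assert sig.sum() == 17
        for chrom in table.counts.index:
            alg = "ALG" + chrom[1:]
            assert table.significant.loc[chrom, alg]

    def test_counts_conserve_assigned_genes(self):
        _, _, assignments, _, _, table = run_karyotype(
            SimConfig(seed=2, genes_per_alg=30, noise_frac=0.1)
        )
        assert table.counts.to_numpy().sum() == len(assignments)
        assert table.n_assigned == len(assignments)

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError):
            chromosome_alg_contingency({}, {})

    def test_missing_locus_rejected_with_ids(self):
        with pytest.raises(ValueError, match="g1"):
            chromosome_alg_contingency({"g1": "ALG1"}, {})

    def test_uniform_random_assignment_controls_false_positives(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(1700)]
        assignments = {
            g: f"ALG{rng.integers(1, 18)}" for g in genes
        }
        loci = {
            g: GeneLocus(g, f"C{rng.integers(1, 18)}", 0, 1) for g in genes
        }
        table = chromosome_alg_contingency(assignments, loci)
        n_cells = table.significant.size
        assert table.significant.to_numpy().sum() <= 0.05 * n_cells


class TestEvents:
    def test_identity_karyotype_no_calls(self):
        _, _, _, _, _, table = run_karyotype(
            SimConfig(seed=1, genes_per_alg=100)
        )
        assert call_rearrangement_events(table) == []

    def test_fusion_called_with_both_algs(self):
        _, _, _, _, _, table = run_karyotype(
            SimConfig(seed=2, genes_per_alg=100,
                      karyotype_spec=["fuse(ALG3,ALG10)->C7"])
        )
        calls = call_rearrangement_events(table)
        fusions = [c for c in calls if c.type == "fusion"]
        assert len(fusions) == 1
        assert set(fusions[0].algs) == {"ALG10", "ALG3"}
        assert fusions[0].chromosomes == ("C7",)
        assert not [c for c in calls if c.type != "fusion"]

    def test_fission_called(self):
        _, _, _, _, _, table = run_karyotype(
            SimConfig(seed=4, genes_per_alg=100,
                      karyotype_spec=["fission(ALG4)->C8,C9"])
        )
        calls = call_rearrangement_events(table)
        fissions = [c for c in calls if c.type == "fission"]
        assert len(fissions) == 1
        assert fissions[0].algs == ("ALG4",)
        assert set(fissions[0].chromosomes) == {"C8", "C9"}

    def test_minority_translocation_called(self):
        _, _, _, _, _, table = run_karyotype(
            SimConfig(seed=5, genes_per_alg=100,
                      karyotype_spec=["translocate(0.12,ALG2)->B5"])
        )
        calls = call_rearrangement_events(table)
        trans = [c for c in calls if c.type == "translocation"]
        assert len(trans) == 1
        assert trans[0].algs == ("ALG2",)
        assert trans[0].chromosomes == ("B5",)

    def test_large_translocation_reported_as_fusion_like_split(self):
        # 30% exceeds the 20% translocation band, so the receiving
        # chromosome is called as a fusion and the donor ALG as a fission
        _, _, _, _, _, table = run_karyotype(
            SimConfig(seed=6, genes_per_alg=100,
                      karyotype_spec=["translocate(0.3,ALG2)->B5"])
        )
        calls = call_rearrangement_events(table)
        types = {c.type for c in calls}
        assert "fusion" in types or "fission" in types
        assert not [c for c in calls if c.type == "translocation"]


class TestConservationIndex:
    def test_identity_karyotype_ci_one(self):
        _, _, _, _, _, table = run_karyotype(
            SimConfig(seed=1, genes_per_alg=50)
        )
        assert conservation_index(table) == 1.0

    def test_even_split_ci_half(self):
        # every chromosome 50/50 between two ALGs
        assignments = {}
        loci = {}
        k = 0
        for c in range(4):
            for alg in (f"ALG{2*c+1}", f"ALG{2*c+2}"):
                for _ in range(10):
                    g = f"g{k}"; k += 1
                    assignments[g] = alg
                    loci[g] = GeneLocus(g, f"C{c}", 0, 1)
        table = chromosome_alg_contingency(assignments, loci)
        assert conservation_index(table) == 0.5

    def test_noisy_ci_matches_closed_form(self):
        cfg = SimConfig(seed=5, genes_per_alg=100, noise_frac=0.1)
        _, _, _, _, _, table = run_karyotype(cfg)
        # a noisy gene lands on its dominant-ALG chromosome with p=1/17
        expected = 0.9 + 0.1 / 17
        n = 1700
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(conservation_index(table) - expected) < 4 * sd

    def test_relabeling_invariance(self):
        cfg = SimConfig(seed=7, genes_per_alg=40, noise_frac=0.05)
        _, _, assignments, _, loci, table = run_karyotype(cfg)
        renamed_loci = {
            g: GeneLocus(g, "X" + l.chrom, l.start, l.end, l.strand)
            for g, l in loci.items()
        }
        table2 = chromosome_alg_contingency(assignments, renamed_loci)
        assert conservation_index(table2) == pytest.approx(
            conservation_index(table)
        )


class TestDotplot:
    def test_identity_karyotype_block_diagonal(self):
        kar, pairs, _, _, loci_b, _ = run_karyotype(
            SimConfig(seed=1, genes_per_alg=10)
        )
        loci_a = {
            r.name: GeneLocus(r.name, r.chrom, int(r.start), int(r.end))
            for r in kar.loci_a.itertuples(index=False)
        }
        df = dotplot_coordinates(pairs, loci_b, loci_a)
        assert len(df) == len(pairs)
        # within each chromosome pair block, points form a contiguous band
        for (cf, cr), block in df.groupby(["chrom_focal", "chrom_ref"]):
            assert cf[1:] == cr[1:]  # B7 pairs with A7 etc.

    def test_missing_locus_dropped_and_counted(self):
        pairs = [("f1", "r1"), ("f2", "r2")]
        loci_f = {"f1": GeneLocus("f1", "C1", 0, 1)}
        loci_r = {
            "r1": GeneLocus("r1", "A1", 0, 1),
            "r2": GeneLocus("r2", "A1", 5, 6),
        }
        df = dotplot_coordinates(pairs, loci_f, loci_r)
        assert len(df) == 1
        assert df.attrs["n_dropped"] == 1

    def test_empty_pairs_empty_output(self):
        df = dotplot_coordinates([], {}, {})
        assert df.empty
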