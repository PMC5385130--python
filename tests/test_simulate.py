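"""Generator tests: determinism, composition, calibration, reads."""

import numpy as np
import pytest

from paircomp import (
    AncestorSpec,
    DivergenceSpec,
    ReadMixSpec,
    diverge_pair,
    generate_ancestor,
    simulate_reads,
)
from paircomp.simulate import (
    lineage_substitution_prob,
    reverse_complement,
    translate,
)


class TestAncestor:
    def test_fixed_seed_is_byte_identical(self):
        spec = AncestorSpec(genome_length=30_000, gene_density=0.9, seed=1)
        g1, g2 = generate_ancestor(spec), generate_ancestor(spec)
        assert g1.contigs == g2.contigs
        assert [(g.gene_id, g.start, g.end, g.strand) for g in g1.genes] == [
            (g.gene_id, g.start, g.end, g.strand) for g in g2.genes
        ]

    def test_realized_gc_near_target(self):
        g = generate_ancestor(AncestorSpec(genome_length=50_000, gc_content=0.60, seed=3))
        assert 0.58 <= g.gc_content() <= 0.62

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(gene_density=1.2), "gene_density"),
            (dict(genome_length=5_000), "genome_length"),
            (dict(gc_content=1.5), "gc_content"),
            (dict(gene_length_mean=901), "gene_length_mean"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            generate_ancestor(AncestorSpec(**kwargs))

    def test_genes_non_overlapping_and_in_frame(self, small_ancestor):
        prev_end = 0
        for g in sorted(small_ancestor.genes, key=lambda g: g.start):
            assert g.start >= prev_end
            assert (g.end - g.start) % 3 == 0
            prev_end = g.end

    def test_gene_density_near_target(self, small_ancestor):
        coding = sum(g.length for g in small_ancestor.genes)
        assert 0.85 <= coding / small_ancestor.length <= 0.95

    def test_translations_are_stop_free(self, small_ancestor):
        for g in small_ancestor.genes:
            assert "*" not in small_ancestor.gene_protein(g)

    def test_both_strands_used(self, small_ancestor):
        strands = {g.strand for g in small_ancestor.genes}
        assert strands == {"+", "-"}


class TestDivergence:
    def test_zero_divergence_identity(self, small_ancestor):
        spec = DivergenceSpec(site_divergence=0.0, indel_rate=0.0,
                              gene_loss_fraction=0.0, seed=5)
        a, b, truth = diverge_pair(small_ancestor, spec)
        assert a.contigs[a.genes[0].contig] == small_ancestor.contigs[
            small_ancestor.genes[0].contig
        ]
        assert truth.programmed_ani == 100.0
        assert all(v == 100.0 for v in truth.per_gene_identity.values())

    def test_excessive_divergence_rejected(self, small_ancestor):
        with pytest.raises(ValueError, match="site_divergence"):
            diverge_pair(small_ancestor, DivergenceSpec(site_divergence=0.6))

    def test_substitution_prob_inversion(self):
        # expected pairwise mismatch from rate p must invert back to d
        for d in (0.02, 0.1, 0.3):
            for kappa in (0.5, 2.0, 10.0):
                p = lineage_substitution_prob(d, kappa)
                c = (kappa**2 + 0.5) / (kappa + 1) ** 2
                assert 2 * p - (1 + c) * p * p == pytest.approx(d, abs=1e-12)

    @pytest.mark.parametrize("d", [0.02, 0.05, 0.10, 0.231])
    def test_divergence_calibration(self, d):
        """Mean realized aligned-site mismatch within ±0.005 of the target."""
        realized = []
        for rep in range(10):
            anc = generate_ancestor(AncestorSpec(genome_length=50_000, seed=100 + rep))
            _, _, truth = diverge_pair(
                anc, DivergenceSpec(site_divergence=d, seed=200 + rep)
            )
            realized.append(truth.realized_site_divergence)
        assert abs(float(np.mean(realized)) - d) <= 0.005

    def test_gene_loss_binomial_range(self):
        # ~107 genes at p_keep=0.8: survivor count within wide binomial bounds
        anc = generate_ancestor(AncestorSpec(genome_length=100_000, seed=7))
        n = len(anc.genes)
        _, b, _ = diverge_pair(
            anc, DivergenceSpec(site_divergence=0.05, gene_loss_fraction=0.2, seed=8)
        )
        lo, hi = 0.8 * n - 3 * np.sqrt(n * 0.16), 0.8 * n + 3 * np.sqrt(n * 0.16)
        assert lo <= len(b.genes) <= hi

    def test_truth_orthologs_unique_and_consistent(self, small_pair):
        a, b, truth = small_pair
        ids_a = {g.gene_id for g in a.genes}
        ids_b = {g.gene_id for g in b.genes}
        seen = set()
        for ga, gb in truth.ortholog_pairs:
            assert ga in ids_a and gb in ids_b
            assert (ga, gb) not in seen
            seen.add((ga, gb))
        assert {p[0] for p in truth.ortholog_pairs} == ids_a & ids_b

    def test_translation_consistency(self, small_pair):
        """Every emitted protein equals the standard-code translation of its span."""
        for genome in small_pair[:2]:
            for g in genome.genes:
                cds = genome.gene_seq(g)
                assert genome.gene_protein(g) == translate(cds)
                assert "*" not in genome.gene_protein(g)

    def test_fixed_seed_is_byte_identical(self, small_ancestor):
        spec = DivergenceSpec(site_divergence=0.1, gene_loss_fraction=0.1, seed=42)
        a1, b1, _ = diverge_pair(small_ancestor, spec)
        a2, b2, _ = diverge_pair(small_ancestor, spec)
        assert a1.contigs == a2.contigs and b1.contigs == b2.contigs

    def test_nonsyn_forcing_lowers_protein_identity(self, small_ancestor):
        _, _, t_free = diverge_pair(
            small_ancestor, DivergenceSpec(site_divergence=0.1, seed=3)
        )
        _, _, t_forced = diverge_pair(
            small_ancestor,
            DivergenceSpec(site_divergence=0.1, nonsyn_fraction=1.0, seed=3),
        )
        assert t_forced.mean_protein_identity() < t_free.mean_protein_identity()


class TestReads:
    def test_degenerate_mixture_all_from_one_genome(self, small_pair):
        a, b, _ = small_pair
        reads = simulate_reads(
            [a, b], ReadMixSpec(n_reads=1000, weights={"A": 1, "B": 0}, seed=1)
        )
        assert len(reads) == 1000
        assert set(reads.labels().values()) == {"A"}

    def test_mixture_fraction_within_binomial_bounds(self, small_pair):
        a, b, _ = small_pair
        reads = simulate_reads(
            [a, b], ReadMixSpec(n_reads=10_000, weights={"A": 4, "B": 1}, seed=2)
        )
        frac_a = sum(1 for s in reads.labels().values() if s == "A") / 10_000
        assert 0.78 <= frac_a <= 0.82

    def test_error_free_reads_are_exact_substrings(self, small_pair):
        a, _, _ = small_pair
        reads = simulate_reads(
            [a], ReadMixSpec(n_reads=50, weights={"A": 1}, read_error_rate=0.0, seed=3)
        )
        contig = a.contigs[a.genes[0].contig]
        for r in reads.reads:
            assert r.seq in contig or reverse_complement(r.seq) in contig

    def test_read_length_exceeding_contig_rejected(self, small_pair):
        a, _, _ = small_pair
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(
                [a],
                ReadMixSpec(n_reads=10, read_length=10**6, weights={"A": 1}, seed=1),
            )

    def test_unknown_genome_weight_rejected(self, small_pair):
        a, _, _ = small_pair
        with pytest.raises(ValueError, match="weights"):
            simulate_reads([a], ReadMixSpec(n_reads=10, weights={"Z": 1}, seed=1))

    def test_determinism(self, small_pair):
        a, b, _ = small_pair
        spec = ReadMixSpec(n_reads=200, weights={"A": 1, "B": 1, "background": 0.2},
                           seed=9)
        r1 = simulate_reads([a, b], spec)
        r2 = simulate_reads([a, b], spec)
        assert r1.sequences() == r2.sequences()
        assert r1.labels() == r2.labels()
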