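"""Alignment engine tests, including the full-DP oracle cross-check."""

import math

import numpy as np
import pytest

from paircomp import (
    AncestorSpec,
    DivergenceSpec,
    HitFilters,
    ScoringScheme,
    align_pair,
    best_hits,
    diverge_pair,
    estimate_evalue,
    generate_ancestor,
    reciprocal_best_hits,
)

from conftest import mutate, random_seq
from oracle_align import all_pairs_best, nucleotide_lut, optimal_local_score

NT = ScoringScheme.nucleotide()
NT_LUT = nucleotide_lut()


def toy_family(rng, n_genes, min_len=150, max_len=300, divergence=0.03):
    """Two gene sets descended from common toy ancestors.

    Lengths and divergence keep every related pair within the seeded
    aligner's guarantee (a shared seed k-mer exists), so the heuristic must
    reproduce the full-DP optimum exactly.
    """
    queries, subjects = {}, {}
    for i in range(n_genes):
        anc = random_seq(rng, int(rng.integers(min_len, max_len + 1)))
        queries[f"q{i}"] = mutate(rng, anc, divergence)
        subjects[f"s{i}"] = mutate(rng, anc, divergence)
    return queries, subjects


class TestAlignPair:
    def test_self_alignment_is_perfect(self):
        s = random_seq(np.random.default_rng(0), 200)
        hit = align_pair(s, s, NT)
        assert hit.percent_identity == 100.0
        assert hit.query_coverage == 1.0 and hit.subject_coverage == 1.0
        assert hit.score == 200.0

    def test_identity_of_known_mismatch_count(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 100)
        # mutate exactly 10 interior positions (ends kept intact so the local
        # alignment spans the full sequence)
        pos = rng.choice(np.arange(10, 90), size=10, replace=False)
        t = list(s)
        for p in pos:
            t[p] = "ACGT"[("ACGT".index(t[p]) + 1) % 4]
        hit = align_pair(s, "".join(t), NT)
        assert hit.percent_identity == pytest.approx(90.0)
        assert hit.matches == 90 and hit.alignment_length == 100

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            align_pair("MKVLRR", "MKVLRR", NT)

    def test_no_shared_seed_returns_absent(self):
        assert align_pair("A" * 40, "C" * 40, NT) is None

    def test_ambiguity_never_matches(self):
        s = "ACGTACGTACGTNNNNACGTACGTACGT"
        hit = align_pair(s, s, NT)
        # N columns are either trimmed by the local alignment or counted as
        # mismatch, never as matches
        assert hit.matches <= len(s) - 4

    def test_hit_invariants(self, close_pair):
        a, b, _ = close_pair
        sa, sb = a.gene_seqs(), b.gene_seqs()
        for gid in list(sa)[:10]:
            if gid not in sb:
                continue
            hit = align_pair(sa[gid], sb[gid], NT)
            assert hit.matches <= hit.alignment_length
            assert hit.query_coverage <= 1.0 and hit.subject_coverage <= 1.0
            assert hit.percent_identity == pytest.approx(
                100.0 * hit.matches / hit.alignment_length, abs=0.01
            )


class TestOracleEquivalence:
    def test_align_pair_matches_full_dp_scores(self):
        """Seeded extension reaches the optimal local score on toy pairs."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            anc = random_seq(rng, int(rng.integers(150, 301)))
            q, s = mutate(rng, anc, 0.03), mutate(rng, anc, 0.03)
            expected = optimal_local_score(q, s, NT_LUT, NT.gap_open, NT.gap_extend)
            hit = align_pair(q, s, NT)
            got = hit.score if hit is not None else 0.0
            if expected >= NT.min_score:
                assert got == expected
            else:
                assert hit is None

    def test_best_hits_match_full_dp_all_pairs(self):
        """Heuristic best hits equal the DP oracle's on 50 toy gene sets."""
        rng = np.random.default_rng(1234)
        for _ in range(50):
            queries, subjects = toy_family(rng, int(rng.integers(3, 21)))
            hmap = best_hits(queries, subjects, NT, HitFilters())
            oracle = all_pairs_best(
                queries, subjects, NT_LUT, NT.gap_open, NT.gap_extend, NT.min_score
            )
            assert set(hmap.best_hit) == set(oracle)
            for qid, hit in hmap.best_hit.items():
                best_score, holders = oracle[qid]
                assert hit.score == best_score
                assert hit.subject_id in holders


class TestEvalue:
    def test_linear_in_database_length(self):
        e1 = estimate_evalue(30.0, 100, 1000, NT)
        e2 = estimate_evalue(30.0, 100, 2000, NT)
        assert e2 == pytest.approx(2 * e1)

    def test_monotone_decreasing_in_score(self):
        evs = [estimate_evalue(s, 100, 10_000, NT) for s in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert estimate_evalue(1e4, 100, 10_000, NT) == pytest.approx(0.0, abs=1e-300)

    def test_formula_at_stated_constants(self):
        # E = K * m * n * exp(-lambda * s) with nt defaults K=0.621, lambda=1.33
        e = estimate_evalue(30.0, 100, 1000, NT)
        assert e == pytest.approx(
            0.621 * 100 * 1000 * math.exp(-1.33 * 30.0), rel=1e-6
        )

    def test_nonpositive_score_rejected(self):
        with pytest.raises(ValueError):
            estimate_evalue(0.0, 100, 1000, NT)


class TestBestHits:
    def test_self_comparison_all_perfect(self):
        rng = np.random.default_rng(3)
        genes = {f"g{i}": random_seq(rng, 150) for i in range(8)}
        hmap = best_hits(genes, genes, NT)
        assert set(hmap.best_hit) == set(genes)
        for gid, hit in hmap.best_hit.items():
            assert hit.subject_id == gid
            assert hit.percent_identity == 100.0

    def test_identity_filter_drops_distant_pairs(self):
        rng = np.random.default_rng(4)
        anc = random_seq(rng, 200)
        queries = {"q": mutate(rng, anc, 0.4)}
        subjects = {"s": mutate(rng, anc, 0.4)}
        hmap = best_hits(queries, subjects, NT, HitFilters(min_identity=95.0))
        assert "q" not in hmap.best_hit

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            best_hits({}, {"s": "ACGT" * 10}, NT)


class TestReciprocalBestHits:
    def test_identical_gene_sets_pair_everything(self):
        rng = np.random.default_rng(5)
        genes = {f"g{i}": random_seq(rng, 120) for i in range(6)}
        ab = best_hits(genes, genes, NT, direction=("A", "B"))
        ba = best_hits(genes, genes, NT, direction=("B", "A"))
        rbh = reciprocal_best_hits(ab, ba)
        assert len(rbh) == len(genes)

    def test_non_mutual_best_excluded(self):
        # b's best is c, so (a, b) must not pair even though a's best is b
        from paircomp.align import AlignmentHit, HomologyMap

        def fake(q, s, score):
            return AlignmentHit(q, s, 100.0, 10, 10, 0, 0, 0, 0, 10, 0, 10,
                                1.0, 1.0, score)

        ab = HomologyMap(("A", "B"), {"a": fake("a", "b", 50)}, HitFilters())
        ba = HomologyMap(("B", "A"), {"b": fake("b", "c", 60)}, HitFilters())
        assert reciprocal_best_hits(ab, ba).pairs == []

    def test_direction_mismatch_rejected(self):
        from paircomp.align import HomologyMap

        ab = HomologyMap(("A", "B"), {}, HitFilters())
        also_ab = HomologyMap(("A", "B"), {}, HitFilters())
        with pytest.raises(ValueError, match="direction"):
            reciprocal_best_hits(ab, also_ab)

    def test_recovers_generator_truth(self, close_pair):
        """At 5% divergence, no paralogs: RBH pairs = true ortholog pairs."""
        a, b, truth = close_pair
        sa, sb = a.gene_seqs(), b.gene_seqs()
        ab = best_hits(sa, sb, NT, direction=("A", "B"))
        ba = best_hits(sb, sa, NT, direction=("B", "A"))
        rbh = reciprocal_best_hits(ab, ba)
        assert set(rbh.id_pairs()) == set(truth.ortholog_pairs)

    def test_symmetry(self, close_pair):
        a, b, _ = close_pair
        sa, sb = a.gene_seqs(), b.gene_seqs()
        ab = best_hits(sa, sb, NT, direction=("A", "B"))
        ba = best_hits(sb, sa, NT, direction=("B", "A"))
        fwd = {frozenset(p) for p in reciprocal_best_hits(ab, ba).id_pairs()}
        rev = {frozenset(p) for p in reciprocal_best_hits(ba, ab).id_pairs()}
        assert fwd == rev


class TestIdentityMonotonicity:
    def test_median_identity_never_increases_with_divergence(self):
        """More divergence never raises median best-hit identity (10 reps)."""
        for rep in range(10):
            anc = generate_ancestor(AncestorSpec(genome_length=15_000, seed=300 + rep))
            medians = []
            for d in (0.05, 0.10, 0.20):
                a, b, _ = diverge_pair(
                    anc, DivergenceSpec(site_divergence=d, seed=400 + rep)
                )
                hmap = best_hits(a.gene_seqs(), b.gene_seqs(), NT)
                medians.append(
                    float(np.median([h.percent_identity for h in hmap.best_hit.values()]))
                )
            assert medians[0] >= medians[1] >= medians[2]
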