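"""Local alignment scores, shuffle significance and pair classification."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import gumbel_r

from conftest import bruteforce_local_score
from intronmap.gene_models import Intron
from intronmap.hotspots import Thresholds
from intronmap.similarity import (
    IntronPair, ScoringScheme, SimilarityResult, _gumbel_mle,
    find_similar_pairs, format_percentage, shuffle_significance,
    smith_waterman, summarize_pairs,
)

S = ScoringScheme()


def _rand_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


class TestSmithWaterman:
    def test_perfect_self_match(self):
        assert smith_waterman("ACGTAC", "ACGTAC", S) == 6 * 5

    def test_all_mismatch_empty_alignment(self):
        assert smith_waterman("AAAA", "TTTT", S) == 0

    def test_n_scores_as_mismatch_even_vs_n(self):
        assert smith_waterman("NNNN", "NNNN", S) == 0
        assert smith_waterman("ACGN", "ACGT", S) == 3 * 5

    def test_empty_sequence_hard_error(self):
        with pytest.raises(ValueError, match="empty"):
            smith_waterman("", "ACGT", S)

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            smith_waterman("ACGU", "ACGT", S)

    def test_matches_bruteforce_on_short_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a = _rand_seq(rng, int(rng.integers(1, 9)))
            b = _rand_seq(rng, int(rng.integers(1, 9)))
            assert smith_waterman(a, b, S) == bruteforce_local_score(a, b, S)

    def test_matches_biopython_on_longer_sequences(self):
        # independent cross-check against an established aligner
        from Bio import Align
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = S.match
        al.mismatch_score = S.mismatch
        al.open_gap_score = S.gap_open
        al.extend_gap_score = S.gap_extend
        rng = np.random.default_rng(7)
        for _ in range(40):
            a = _rand_seq(rng, int(rng.integers(20, 120)))
            b = _rand_seq(rng, int(rng.integers(20, 120)))
            # seed similarity so nonzero scores are exercised
            b = b[:10] + a[5:40] + b[10:]
            assert smith_waterman(a, b, S) == int(al.score(a, b))

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = _rand_seq(rng, 30), _rand_seq(rng, 45)
            assert smith_waterman(a, b, S) == smith_waterman(b, a, S)

    def test_appending_shared_suffix_never_decreases(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = _rand_seq(rng, 25), _rand_seq(rng, 25)
            suffix = _rand_seq(rng, 12)
            assert smith_waterman(a + suffix, b + suffix, S) >= \
                smith_waterman(a, b, S)


class TestShuffleSignificance:
    def test_identical_sequences_minimal_p(self):
        rng = np.random.default_rng(11)
        a = _rand_seq(rng, 100)
        r = shuffle_significance(a, a, S, n_shuffles=200, seed=9)
        assert r.empirical_p == pytest.approx(1 / 201)
        assert r.evalue < 1e-6

    def test_unrelated_short_sequences_not_significant(self):
        r = shuffle_significance("ACGTTGCATG", "GGATCCTTAA", S,
                                 n_shuffles=200, seed=4)
        assert r.evalue > 0.02

    def test_single_shuffle_tie_gives_p_one(self):
        # a homopolymer is invariant under shuffling: the shuffle ties
        r = shuffle_significance("AAAAAAAA", "AAAAAAAA", S, n_shuffles=1, seed=0)
        assert r.empirical_p == 1.0

    def test_degenerate_null_falls_back_to_empirical_p(self):
        r = shuffle_significance("AAAAAAAA", "AAAAAAAA", S, n_shuffles=50, seed=0)
        assert r.empirical_p == 1.0
        assert r.evalue == r.empirical_p  # Gumbel fit impossible, zero spread

    def test_window_shuffle_mode_runs(self):
        rng = np.random.default_rng(13)
        a = _rand_seq(rng, 60)
        r = shuffle_significance(a, a, S, n_shuffles=50, seed=2,
                                 shuffle="window:10")
        assert r.empirical_p == pytest.approx(1 / 51)

    def test_gumbel_mle_agrees_with_scipy(self):
        x = gumbel_r.rvs(loc=35, scale=5, size=1000, random_state=8)
        mu, beta = _gumbel_mle(x)
        mu2, beta2 = gumbel_r.fit(x)
        assert mu == pytest.approx(mu2, rel=1e-3)
        assert beta == pytest.approx(beta2, rel=1e-3)


def _intron(iid, species, family, seq, anchor=3):
    return Intron(intron_id=iid, gene_id=f"{species}_{family}_1",
                  species=species, family=family, ordinal=1, genomic_start=0,
                  genomic_end=len(seq), length_nt=len(seq), cds_offset=3 * anchor,
                  phase=0, anchor_residue=anchor, seq=seq)


class TestFindPairs:
    def test_identical_introns_same_site_retained(self):
        rng = np.random.default_rng(21)
        seq = "GT" + _rand_seq(rng, 76) + "AG"
        a = _intron("a", "sp1", "H2A", seq)
        b = _intron("b", "sp2", "H2A", seq)
        site_of = {"a": (4,), "b": (4,)}
        (pair,) = find_similar_pairs([a, b], site_of, seed=1)
        assert pair.category == "same_site_same_gene"
        assert pair.result.evalue < 0.02
        assert not pair.same_species

    def test_categories_follow_family_and_site(self):
        rng = np.random.default_rng(22)
        seq = "GT" + _rand_seq(rng, 96) + "AG"
        introns = [
            _intron("a", "sp1", "H2A", seq), _intron("b", "sp2", "H2A", seq, anchor=9),
            _intron("c", "sp1", "H3", seq),
        ]
        site_of = {"a": (4,), "b": (10,), "c": (4,)}
        pairs = {(p.intron_a, p.intron_b): p.category
                 for p in find_similar_pairs(introns, site_of, seed=1)}
        assert pairs == {
            ("a", "b"): "diff_site_same_gene",
            ("a", "c"): "diff_gene",
            ("b", "c"): "diff_gene",
        }

    def test_single_intron_empty(self):
        a = _intron("a", "sp1", "H2A", "GT" + "ACGT" * 10 + "AG")
        assert find_similar_pairs([a], {"a": (4,)}, seed=1) == []

    def test_unprojectable_intron_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(23)
        seq = "GT" + _rand_seq(rng, 76) + "AG"
        a, b = _intron("a", "sp1", "H2A", seq), _intron("b", "sp2", "H2A", seq)
        assert find_similar_pairs([a, b], {"a": (4,)}, seed=1) == []
        assert "unclassifiable" in caplog.text

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(24)
        base = "GT" + _rand_seq(rng, 60) + "AG"
        introns = [
            _intron(f"i{k}", f"sp{k % 2}", "H2A", base) for k in range(4)
        ]
        site_of = {i.intron_id: (4,) for i in introns}
        first = find_similar_pairs(introns, site_of, seed=5)
        again = find_similar_pairs(introns, site_of, seed=5)
        reordered = find_similar_pairs(list(reversed(introns)), site_of, seed=5)
        assert first == again == reordered
        other_seed = find_similar_pairs(introns, site_of, seed=6)
        assert {(p.intron_a, p.intron_b) for p in other_seed} == \
            {(p.intron_a, p.intron_b) for p in first}


def _pair(i, cat, sp_a, sp_b):
    res = SimilarityResult(score=100, evalue=1e-5, empirical_p=1 / 201,
                           n_shuffles=200, seed=1)
    return IntronPair(intron_a=f"a{i}", intron_b=f"b{i}", species_a=sp_a,
                      species_b=sp_b, family_a="H2A", family_b="H2A",
                      result=res, category=cat)


class TestSummary:
    def test_reported_category_percentages(self):
        # the three-way split 113 / 13 / 8 out of 134
        pairs = ([_pair(i, "same_site_same_gene", "s", "s") for i in range(113)]
                 + [_pair(i + 200, "diff_site_same_gene", "s", "t") for i in range(13)]
                 + [_pair(i + 400, "diff_gene", "t", "u") for i in range(8)])
        summary = summarize_pairs(pairs)
        assert summary.n_pairs == 134
        assert format_percentage(summary.percentage("same_site_same_gene")) == "84%"
        assert format_percentage(summary.percentage("diff_site_same_gene")) == "9.7%"
        assert format_percentage(summary.percentage("diff_gene")) == "6.0%"

    def test_single_pair_percentages(self):
        summary = summarize_pairs([_pair(0, "same_site_same_gene", "s", "s")])
        assert summary.percentage("same_site_same_gene") == 100.0
        assert summary.percentage("diff_gene") == 0.0

    def test_within_species_tally(self):
        pairs = ([_pair(i, "same_site_same_gene", "L_bicolor", "L_bicolor")
                  for i in range(62)]
                 + [_pair(i + 100, "same_site_same_gene", "x", "y") for i in range(72)])
        summary = summarize_pairs(pairs)
        pct = summary.species_pair_percentage(("L_bicolor", "L_bicolor"))
        assert format_percentage(pct) == "46%"

    def test_empty_summary_valid(self):
        summary = summarize_pairs([])
        assert summary.n_pairs == 0
        assert summary.percentage("diff_gene") == 0.0
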