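import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import enhancerlm as elm
from enhancerlm import motifs as mot
from enhancerlm.motifs import (
    AhoCorasick,
    EnrichmentTest,
    MotifGroup,
    NucleotideAttentionProfile,
)

from conftest import min_hamming_to
from oracles import hypergeom_tail_exact, naive_containment


def make_attention(cls_row, n_layers=1, n_heads=1):
    """Build an attention tensor whose last-layer average CLS row over the
    k-mer tokens equals *cls_row* (rows renormalized to be stochastic)."""
    n = len(cls_row)
    T = n + 2
    A = np.full((n_layers, n_heads, T, T), 1.0 / T)
    rest = 1.0 - sum(cls_row)
    for h in range(n_heads):
        A[-1, h, 0, :] = 0.0
        A[-1, h, 0, 1 : n + 1] = cls_row
        A[-1, h, 0, -1] = max(rest, 0.0)
    return A


class TestNucleotideAttention:
    def test_hand_enumerated_example(self, vocab3):
        """k=3, 6 nt, CLS-row attentions (0.1, 0.2, 0.3, 0.4): position 1 is
        covered only by token 1, position 3 by tokens 1-3."""
        toks = elm.tokenize(elm.validate_sequence("ACGTAC"), vocab3)
        A = make_attention([0.1, 0.2, 0.3, 0.4])
        prof = mot.nucleotide_attention(A, toks)
        assert prof.weights[0] == pytest.approx(0.1 / 3)
        assert prof.weights[2] == pytest.approx((0.1 / 3 + 0.2 / 3 + 0.3 / 3) / 3)
        assert len(prof.weights) == 6

    def test_uniform_attention_gives_constant_profile(self, vocab3):
        toks = elm.tokenize(elm.validate_sequence("ACGTACGTAC"), vocab3)
        a = 1.0 / toks.n_kmers
        prof = mot.nucleotide_attention(make_attention([a] * toks.n_kmers), toks)
        assert np.allclose(prof.weights, a / 3)

    def test_single_head_average_is_identity(self, vocab3):
        toks = elm.tokenize(elm.validate_sequence("ACGTAC"), vocab3)
        row = [0.4, 0.3, 0.2, 0.1]
        one = mot.nucleotide_attention(make_attention(row, n_heads=1), toks)
        multi = mot.nucleotide_attention(make_attention(row, n_heads=3), toks)
        assert np.allclose(one.weights, multi.weights)

    def test_contribution_conservation(self, vocab3, desk_state):
        """Summed positional contributions equal the summed CLS-row attention
        over k-mer tokens (before the per-position averaging)."""
        toks = elm.tokenize(elm.validate_sequence("ACGTACGTACGTACGTACGT"), vocab3)
        _, A = elm.forward(desk_state, toks)
        prof = mot.nucleotide_attention(A, toks)
        k, n = toks.k, toks.n_kmers
        L = n + k - 1
        counts = np.array([min(i + 1, k, L - i, n) for i in range(L)])
        cls_total = A[-1].mean(axis=0)[0, 1 : n + 1].sum()
        assert (prof.weights * counts).sum() == pytest.approx(cls_total, abs=1e-9)


class TestFindCandidates:
    def run(self, w, bases=None, expand=10):
        w = np.array(w, dtype=float)
        bases = bases or "ACGTACGTAC"[: len(w)]
        seq = elm.DnaSequence("s", bases)
        prof = NucleotideAttentionProfile(seq_id="s", weights=w)
        return mot.find_candidates(prof, seq, expand=expand)

    def test_simple_core(self):
        cands = self.run([1, 1, 1, 9, 9, 9, 9, 9, 1, 1])
        assert len(cands) == 1
        c = cands[0]
        assert (c.core_start, c.core_end) == (3, 8)  # positions 4-8, 1-based
        assert c.core == "TACGT"

    def test_constant_profile_yields_nothing(self):
        assert self.run([2, 2, 2, 2, 2, 2, 2, 2, 2, 2]) == []

    def test_single_interior_gap_bridged(self):
        w = [9, 9, 1, 9, 9, 1, 1, 1, 1, 1]
        assert np.mean(w) == pytest.approx(4.2)
        cands = self.run(w)
        assert len(cands) == 1
        assert (cands[0].core_start, cands[0].core_end) == (0, 5)

    def test_runs_never_end_on_gap(self):
        # above-mean run of 4 then gap then nothing: too short, no candidate
        cands = self.run([9, 9, 9, 9, 1, 1, 1, 1, 1, 0])
        assert cands == []

    def test_expansion_clipped_to_sequence(self):
        cands = self.run([1, 1, 1, 9, 9, 9, 9, 9, 1, 1], expand=10)
        assert cands[0].start == 0 and cands[0].end == 10

    def test_coincident_expansions_deduplicated(self):
        # two runs whose clipped expansions give the identical interval
        w = [9] * 5 + [0, 0] + [9] * 5 + [0] * 8
        bases = "ACGTACGTACGTACGTACGT"
        cands = self.run(w, bases=bases, expand=20)  # both expand to [0, 20)
        assert len(cands) == 1
        # with a small expansion the two candidates stay separate
        cands = self.run(w, bases=bases, expand=1)
        assert len(cands) == 2
        assert [c.core for c in cands] == ["ACGTA", "TACGT"]


class TestContainmentCounting:
    def seqs(self, strings):
        return [elm.DnaSequence(f"s{i}", s) for i, s in enumerate(strings)]

    def test_saturated_pattern(self):
        seqs = self.seqs(["ACGTT", "TACGT", "AACGT"])
        out = mot.count_containing(["ACG"], seqs, [1, 1, 0])
        assert out["ACG"] == (3, 2)

    def test_absent_pattern(self):
        seqs = self.seqs(["AAAA", "CCCC"])
        assert mot.count_containing(["GGG"], seqs, [1, 0])["GGG"] == (0, 0)

    def test_overlapping_pattern_counted_once_per_sequence(self):
        seqs = self.seqs(["AAAAAA"])
        assert mot.count_containing(["AAA"], seqs, [1])["AAA"] == (1, 1)

    def test_matches_naive_scan_on_random_fixture(self):
        rng = np.random.default_rng(8)
        seqs = self.seqs(
            "".join("ACGT"[b] for b in rng.integers(0, 4, 40)) for _ in range(20)
        )
        labels = rng.integers(0, 2, 20).tolist()
        patterns = ["ACG", "TTT", "ACGTA", "GG", "CGTACG", "A"]
        assert mot.count_containing(patterns, seqs, labels) == naive_containment(
            patterns, seqs, labels
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_automaton_equals_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        seqs = self.seqs(
            "".join("ACGT"[b] for b in rng.integers(0, 4, rng.integers(5, 60)))
            for _ in range(n)
        )
        labels = rng.integers(0, 2, n).tolist()
        patterns = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, rng.integers(1, 8)))
            for _ in range(int(rng.integers(1, 12)))
        ]
        assert mot.count_containing(patterns, seqs, labels) == naive_containment(
            patterns, seqs, labels
        )

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            AhoCorasick([""])


class TestEnrichment:
    def test_zero_hits_full_tail(self):
        t = EnrichmentTest(pattern="X", K=5, k=0, N=10, n=4)
        assert mot.enrichment_pvalue(t) == pytest.approx(1.0)

    def test_exact_small_tail(self):
        # P(X >= 4) with N=10, K=5, n=4: only j=4 term, C(5,4)/C(10,4) = 5/210
        t = EnrichmentTest(pattern="X", K=5, k=4, N=10, n=4)
        assert mot.enrichment_pvalue(t) == pytest.approx(5 / 210, rel=1e-12)

    def test_literal_mode_single_pmf_term(self):
        t = EnrichmentTest(pattern="X", K=10, k=10, N=20, n=10)
        assert mot.enrichment_pvalue(t, mode="literal") == pytest.approx(
            1.0 - 1.0 / 184756, rel=1e-9
        )
        # the same fully-enriched pattern is maximally significant under the
        # survival statistic — the reason survival is the default
        assert mot.enrichment_pvalue(t) == pytest.approx(1.0 / 184756, rel=1e-9)

    def test_survival_matches_exact_rational_tail_on_grid(self):
        """Exhaustive check against big-rational tail sums for all N <= 30."""
        for N in range(1, 31):
            for K in range(0, N + 1, max(1, N // 5)):
                for n in range(0, N + 1, max(1, N // 5)):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        t = EnrichmentTest(pattern="X", K=K, k=k, N=N, n=n)
                        exact = float(hypergeom_tail_exact(k, N, K, n))
                        assert mot.enrichment_pvalue(t) == pytest.approx(
                            exact, rel=1e-9, abs=1e-12
                        ), (N, K, n, k)

    def test_survival_nonincreasing_in_k(self):
        ps = [
            mot.enrichment_pvalue(EnrichmentTest(pattern="X", K=15, k=k, N=40, n=20))
            for k in range(0, 16)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentTest(pattern="X", K=5, k=6, N=10, n=6)
        with pytest.raises(ValueError):
            EnrichmentTest(pattern="X", K=9, k=0, N=10, n=5)


class TestGrouping:
    def test_identical_members_plus_unrelated_shorts(self):
        cands = ["ACGTACGTAC"] * 12 + ["TTTTT", "GGGGG", "TTTTT"]
        groups = mot.group_and_align(cands)
        assert len(groups) == 1
        assert len(groups[0].members) == 12

    def test_near_identical_grouped(self):
        # 4 matches in overlap 5 > 2.5
        groups = mot.group_and_align(["ACGTT"] * 11 + ["ACGTA"], min_members=2)
        assert len(groups) == 1 and len(groups[0].members) == 12

    def test_member_floor_discards_small_groups(self):
        assert mot.group_and_align(["ACGTACGTAC"] * 10) == []

    def test_offsets_recorded(self):
        groups = mot.group_and_align(
            ["AAACGTACGTAA"] * 11 + ["ACGTACGT"], min_members=2
        )
        assert len(groups) == 1
        g = groups[0]
        assert g.offsets[g.members.index("ACGTACGT")] == 2


class TestPwm:
    def test_frequency_definition(self):
        g = MotifGroup(core="AC", members=["AC", "AC", "AT"], offsets=[0, 0, 0])
        pwm = mot.build_pwm(g)
        assert pwm.matrix[0, 0] == pytest.approx(1.0)  # col 1 all A
        assert pwm.matrix[1, 1] == pytest.approx(2 / 3)  # col 2: C 2/3
        assert pwm.matrix[3, 1] == pytest.approx(1 / 3)  # col 2: T 1/3

    def test_identical_members_one_hot(self):
        g = MotifGroup(core="ACGT", members=["ACGT"] * 11, offsets=[0] * 11)
        pwm = mot.build_pwm(g)
        assert np.array_equal(pwm.matrix.max(axis=0), np.ones(4))
        assert pwm.consensus == "ACGT"

    def test_columns_sum_to_one(self):
        g = MotifGroup(
            core="ACGTACGT",
            members=["ACGTACGT"] * 6 + ["GTACG"] * 5,
            offsets=[0] * 6 + [2] * 5,
        )
        pwm = mot.build_pwm(g)
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_low_coverage_ends_trimmed(self):
        # one long member sticking out left: its lone columns are trimmed
        g = MotifGroup(
            core="CGTAC",
            members=["CGTAC"] * 11 + ["AACGTAC"],
            offsets=[0] * 11 + [-2],
        )
        pwm = mot.build_pwm(g)
        assert pwm.width == 5


class TestMemeFormat:
    def make_pwms(self):
        g = MotifGroup(core="AC", members=["AC", "AC", "AT"], offsets=[0, 0, 0])
        return [mot.build_pwm(g)]

    def test_roundtrip_preserves_probabilities(self, tmp_path):
        p = tmp_path / "m.meme"
        pwms = self.make_pwms()
        mot.write_meme(pwms, p)
        back = mot.read_meme(p)
        assert len(back) == 1
        assert np.allclose(back[0].matrix, pwms[0].matrix, atol=5e-7)
        assert back[0].nsites == 3

    def test_minimal_grammar(self, tmp_path):
        p = tmp_path / "m.meme"
        mot.write_meme(self.make_pwms(), p)
        text = p.read_text()
        assert text.startswith("MEME version")
        assert "ALPHABET= ACGT" in text
        assert "letter-probability matrix: alength= 4 w= 2 nsites= 3" in text

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            mot.write_meme([], tmp_path / "x.meme")


class TestPlantedRecovery:
    def test_pipeline_recovers_planted_consensus(self, e2e_run):
        """The full attention pipeline on a fine-tuned desk-scale model
        returns at least one PWM whose consensus contains the planted
        width-10 consensus within Hamming distance 2."""
        result = e2e_run["motifs"]
        assert len(result.pwms) >= 1
        best = min(
            min_hamming_to(e2e_run["consensus"], p.consensus) for p in result.pwms
        )
        assert best <= 2
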