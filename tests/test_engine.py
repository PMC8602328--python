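import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from linmotif.background import BackgroundModel, build_background
from linmotif.engine import (
    DEFAULT_COMPOUND_GROUPS,
    EngineConfig,
    binomial_pvalue,
    classify_motif,
    classify_pairs,
    extract_motifs,
    motif_set_key,
    n_tests,
    partition,
    reverse_equivalence_check,
    scan_enrichment,
    select_maximal,
)
from linmotif.types import (
    STANDARD_AA,
    Motif,
    PositionalPair,
    SequenceSet,
    SequenceWindow,
)


def exact_binomial_tail(k, n, p0):
    """Independent oracle: exact rational summation of P(X >= k)."""
    p = Fraction(p0)
    q = 1 - p
    return float(
        sum(math.comb(n, i) * p**i * q ** (n - i) for i in range(k, n + 1))
    )


class TestBinomialPvalue:
    def test_zero_successes_gives_one(self):
        assert binomial_pvalue(0, 10, 0.3) == 1.0

    def test_all_successes_fair_coin(self):
        assert binomial_pvalue(3, 3, 0.5) == pytest.approx(0.125, rel=1e-15)

    def test_matches_brute_force_summation(self):
        expected = exact_binomial_tail(20, 39, 0.05)
        assert binomial_pvalue(20, 39, 0.05) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p0", [0.001, 0.05, 0.5, 0.95])
    @pytest.mark.parametrize("n", [1, 7, 33, 64, 200])
    def test_oracle_agreement_spot_grid(self, n, p0):
        for k in {0, 1, n // 2, n - 1, n}:
            expected = exact_binomial_tail(k, n, p0)
            assert binomial_pvalue(k, n, p0) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_probabilities(self):
        assert binomial_pvalue(5, 10, 1.0) == 1.0
        assert binomial_pvalue(5, 10, 0.0) == 0.0
        assert binomial_pvalue(0, 10, 0.0) == 1.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_pvalue(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_pvalue(1, 3, 1.5)


def uniform_background(width, n=2000, center="S", seed=5):
    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_AA))
    wins = []
    for _ in range(n):
        chars = aa[rng.integers(0, 20, size=width)]
        if center is not None:
            chars[(width - 1) // 2] = center
        wins.append("".join(chars))
    return BackgroundModel(wins, width)


def random_windows(n, width, seed, center=None):
    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_AA))
    out = []
    for _ in range(n):
        chars = aa[rng.integers(0, 20, size=width)]
        if center is not None:
            chars[(width - 1) // 2] = center
        out.append("".join(chars))
    return out


class TestScanEnrichment:
    def test_extreme_column_is_significant(self):
        bg = uniform_background(7, center=None, seed=1)
        wins = [s[:4] + "P" + s[5:] for s in random_windows(25, 7, seed=2)]
        fg = SequenceSet([SequenceWindow(w) for w in wins], width=7)
        cfg = EngineConfig()
        results = scan_enrichment(fg, bg, cfg)
        hit = [r for r in results if r.pair == PositionalPair(1, "P")]
        assert len(hit) == 1 and hit[0].significant
        assert hit[0].k == 25 and hit[0].m == n_tests(cfg, 7)

    def test_null_foreground_finds_nothing(self):
        bg = uniform_background(7, center=None, seed=3)
        idx = np.random.default_rng(4).choice(bg.n_sequences, 50, replace=False)
        fg = SequenceSet([SequenceWindow(bg.windows[i]) for i in idx], width=7)
        results = scan_enrichment(fg, bg, EngineConfig())
        assert not any(r.significant for r in results)

    def test_compound_group_significant_where_singles_are_not(self):
        """12 D + 12 E of 60 at +1: each single below the Bonferroni bar,
        the acidic group far above it."""
        base = random_windows(60, 15, seed=6, center="S")
        wins = []
        for i, s in enumerate(base):
            aa = "D" if i < 12 else ("E" if i < 24 else "A")
            wins.append(s[:8] + aa + s[9:])
        fg = SequenceSet([SequenceWindow(w) for w in wins], width=15)
        bg = uniform_background(15, center="S", seed=7)
        cfg = EngineConfig(compound_groups=DEFAULT_COMPOUND_GROUPS)
        results = scan_enrichment(fg, bg, cfg)
        by_pair = {r.pair: r for r in results}
        acidic = PositionalPair(1, "acidic", frozenset("DE"))
        assert by_pair[acidic].significant
        assert not by_pair[PositionalPair(1, "D")].significant
        assert not by_pair[PositionalPair(1, "E")].significant
        # cross-check the three p-values against the exact oracle
        for pair in (acidic, PositionalPair(1, "D"), PositionalPair(1, "E")):
            r = by_pair[pair]
            assert r.p == pytest.approx(exact_binomial_tail(r.k, r.n, r.p0), rel=1e-9)

    def test_results_in_canonical_order(self):
        bg = uniform_background(3, center=None, seed=8)
        fg = SequenceSet([SequenceWindow("ASD"), SequenceWindow("DSA")], width=3)
        results = scan_enrichment(fg, bg, EngineConfig())
        keys = [(r.pair.offset, r.pair.token) for r in results]
        assert keys == sorted(keys)


def _result(pair, k, p, significant=True, n=39, p0=0.05, m=300):
    from linmotif.types import EnrichmentResult

    return EnrichmentResult(pair=pair, k=k, n=n, p0=p0, p=p, m=m, significant=significant)


class TestSelectMaximal:
    def test_strict_minimum_selected_alone(self):
        rs = [
            _result(PositionalPair(-1, "D"), 20, 1e-16),
            _result(PositionalPair(1, "E"), 10, 1e-8),
        ]
        assert select_maximal(rs) == [PositionalPair(-1, "D")]

    def test_statistically_identical_pairs_both_selected(self):
        p = binomial_pvalue(20, 39, 0.05)
        rs = [
            _result(PositionalPair(-7, "D"), 20, p),
            _result(PositionalPair(7, "D"), 20, p),
        ]
        assert select_maximal(rs) == [PositionalPair(-7, "D"), PositionalPair(7, "D")]

    def test_tie_tolerance_covers_summation_order_noise(self):
        p = 1e-12
        rs = [
            _result(PositionalPair(-7, "D"), 20, p),
            _result(PositionalPair(7, "D"), 20, p * (1 + 1e-12)),
        ]
        assert len(select_maximal(rs)) == 2

    def test_no_significant_results_terminates(self):
        rs = [_result(PositionalPair(0, "S"), 5, 0.5, significant=False)]
        assert select_maximal(rs) == []

    def test_specific_residue_preferred_over_redundant_group(self):
        p = 1e-20
        single = PositionalPair(1, "D")
        group = PositionalPair(1, "acidic", frozenset("DE"))
        rs = [_result(single, 20, p), _result(group, 20, p)]
        assert select_maximal(rs) == [single]
        # the group genuinely adds sequences -> both kept
        rs = [_result(single, 20, p), _result(group, 24, p)]
        assert select_maximal(rs) == [single, group]

    def test_greedy_ablation_takes_first_only(self):
        p = binomial_pvalue(20, 39, 0.05)
        rs = [
            _result(PositionalPair(-7, "D"), 20, p),
            _result(PositionalPair(7, "D"), 20, p),
        ]
        cfg = EngineConfig(tie_strategy="first")
        assert select_maximal(rs, cfg) == [PositionalPair(-7, "D")]


class TestPartition:
    def test_bias_demo_partition_20_20_empty_remainder(self, bias_demo):
        fg, _ = bias_demo
        pairs = [PositionalPair(-7, "D"), PositionalPair(7, "D")]
        subsets, remainder = partition(fg, pairs)
        assert len(subsets[pairs[0]]) == 20
        assert len(subsets[pairs[1]]) == 20
        assert len(remainder) == 0

    def test_unmatched_pair_gives_empty_subset_full_remainder(self):
        fg = SequenceSet([SequenceWindow("ASD"), SequenceWindow("AKE")], width=3)
        subsets, remainder = partition(fg, [PositionalPair(0, "W")])
        assert len(subsets[PositionalPair(0, "W")]) == 0
        assert len(remainder) == 2

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_every_window_in_a_subset_xor_remainder(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = np.array(list("ASDE"))
        wins = ["".join(alphabet[rng.integers(0, 4, size=5)]) for _ in range(40)]
        fg = SequenceSet([SequenceWindow(w) for w in wins], width=5)
        pairs = [PositionalPair(-1, "S"), PositionalPair(1, "D"), PositionalPair(1, "E")]
        subsets, remainder = partition(fg, pairs)
        # brute-force matcher as the oracle
        h = 2
        for i, w in enumerate(wins):
            expect = {p for p in pairs if w[p.offset + h] in p.members}
            for p in pairs:
                assert (wins[i] in subsets[p].sequences()) == (p in expect)
            assert (w in remainder.sequences()) == (not expect)
        sum_sizes = sum(len(s) for s in subsets.values())
        assert sum_sizes >= len(fg) - len(remainder)


class TestExtractMotifs:
    def test_bias_demo_yields_both_anchors(self, bias_demo, bias_demo_bg):
        fg, _ = bias_demo
        motifs = extract_motifs(fg, bias_demo_bg)
        assert len(motifs) == 2
        anchors = sorted(p.offset for m in motifs for p in m.pairs)
        assert anchors == [-7, 7]
        assert all(m.support == 20 for m in motifs)
        assert all(p.token == "D" for m in motifs for p in m.pairs)

    def test_greedy_ablation_loses_one_anchor(self, bias_demo, bias_demo_bg):
        fg, _ = bias_demo
        motifs = extract_motifs(fg, bias_demo_bg, EngineConfig(tie_strategy="first"))
        assert len(motifs) == 1

    def test_null_foreground_yields_no_motifs(self):
        bg = uniform_background(15, center="S", n=5000, seed=9)
        for rep in range(5):
            idx = np.random.default_rng(rep).choice(bg.n_sequences, 100, replace=False)
            fg = SequenceSet(
                [SequenceWindow(bg.windows[i]) for i in idx], width=15
            )
            assert extract_motifs(fg, bg, EngineConfig()) == []

    def test_fully_determined_foreground_fixes_every_offset(self):
        # diffuse background with per-column 50% mass on the target letter,
        # so the recompiled background survives the full reduction chain
        rng = np.random.default_rng(10)
        aa = np.array(list(STANDARD_AA))
        target = "RRRSPPP"
        wins = []
        for _ in range(20000):
            chars = aa[rng.integers(0, 20, size=7)]
            mask = rng.random(7) < 0.5
            chars[mask] = np.array(list(target))[mask]
            wins.append("".join(chars))
        bg = BackgroundModel(wins, 7)
        fg = SequenceSet([SequenceWindow(target)] * 30, width=7)
        motifs = extract_motifs(fg, bg, EngineConfig())
        assert len(motifs) == 1
        assert motifs[0].offsets() == set(range(-3, 4))
        assert motifs[0].support == 30

    def test_compound_group_motif_only_when_enabled(self):
        base = random_windows(60, 15, seed=12, center="S")
        wins = []
        for i, s in enumerate(base):
            aa = "D" if i < 12 else ("E" if i < 24 else s[8])
            wins.append(s[:8] + aa + s[9:])
        fg = SequenceSet([SequenceWindow(w) for w in wins], width=15)
        bg = uniform_background(15, center="S", seed=13)
        plain = extract_motifs(fg, bg, EngineConfig())
        assert not any(p.offset == 1 for m in plain for p in m.pairs)
        grouped = extract_motifs(
            fg, bg, EngineConfig(compound_groups=DEFAULT_COMPOUND_GROUPS)
        )
        acidic = [
            m for m in grouped for p in m.pairs
            if p.offset == 1 and p.members == frozenset("DE")
        ]
        assert len(acidic) == 1

    def test_support_and_exact_match_invariants(self, bias_demo, bias_demo_bg):
        fg, _ = bias_demo
        cfg = EngineConfig()
        for m in extract_motifs(fg, bias_demo_bg, cfg):
            assert m.support == len(m.matched_ids) >= cfg.min_support
            h = fg.central_index
            for i in m.matched_ids:
                res = fg.windows[i].residues
                assert all(res[p.offset + h] in p.members for p in m.pairs)

    def test_significant_pairs_respect_bonferroni(self, bias_demo, bias_demo_bg):
        fg, _ = bias_demo
        cfg = EngineConfig()
        for m in extract_motifs(fg, bias_demo_bg, cfg):
            for r in m.trail:
                assert r.significant and r.p <= cfg.alpha / r.m

    def test_permutation_invariance(self, bias_demo, bias_demo_bg):
        """Output depends only on counts, never on input order."""
        fg, _ = bias_demo
        baseline = extract_motifs(fg, bias_demo_bg)
        for seed in range(3):
            perm = np.random.default_rng(seed).permutation(len(fg))
            shuffled = SequenceSet([fg.windows[i] for i in perm], width=fg.width)
            got = extract_motifs(shuffled, bias_demo_bg)
            assert motif_set_key(got) == motif_set_key(baseline)
            assert [m.pattern for m in got] == [m.pattern for m in baseline]

    def test_head_vs_tail_noise_symmetry(self, bias_demo, bias_demo_bg):
        fg, _ = bias_demo
        noise = SequenceWindow("KDCAIQQSQYNVPYY")
        head = SequenceSet([noise] + fg.windows, width=fg.width)
        tail = SequenceSet(fg.windows + [noise], width=fg.width)
        a = extract_motifs(head, bias_demo_bg)
        b = extract_motifs(tail, bias_demo_bg)
        assert motif_set_key(a) == motif_set_key(b)
        assert [(m.pattern, m.support) for m in a] == [(m.pattern, m.support) for m in b]

    def test_child_support_never_exceeds_parent(self):
        """Monotonicity: deeper fixation can only shrink the matched set."""
        bg = uniform_background(7, center="S", n=4000, seed=14)
        base = random_windows(40, 7, seed=15, center="S")
        wins = ["R" + s[1:4] + "P" + s[5:] if i < 30 else s for i, s in enumerate(base)]
        fg = SequenceSet([SequenceWindow(w) for w in wins], width=7)
        motifs = extract_motifs(fg, bg, EngineConfig())
        for m in motifs:
            assert m.support <= len(fg)
            assert len(m.trail) == len(m.pairs)
            ks = [r.k for r in m.trail]
            assert all(later <= earlier for earlier, later in zip(ks, ks[1:]))

    def test_central_residue_requirement_filters_windows(self):
        bg = uniform_background(7, center=None, n=3000, seed=16)
        fg = SequenceSet(
            [SequenceWindow("RRRSPPP")] * 25 + [SequenceWindow("RRRTPPP")] * 25,
            width=7,
        )
        all_motifs = extract_motifs(fg, bg, EngineConfig())
        assert sum(m.support for m in all_motifs) >= 50
        only_s = extract_motifs(
            fg, bg, EngineConfig(require_central_residue=frozenset("S"))
        )
        assert all(m.support == 25 for m in only_s)


class TestClassification:
    @pytest.mark.parametrize(
        "pairs,label",
        [
            ((PositionalPair(0, "S"), PositionalPair(1, "P")), "I"),
            ((PositionalPair(0, "S"),), "II"),
            ((PositionalPair(-7, "D"),), "III"),
            ((PositionalPair(-2, "R"), PositionalPair(3, "L")), "III"),
        ],
    )
    def test_classes(self, pairs, label):
        assert classify_pairs(pairs) == label

    def test_classify_motif_wrapper(self, bias_demo, bias_demo_bg):
        fg, _ = bias_demo
        for m in extract_motifs(fg, bias_demo_bg):
            assert classify_motif(m) == m.complexity_class == "III"


class TestReverseEquivalence:
    def test_bias_demo_is_reversal_equivariant(self, bias_demo, bias_demo_bg):
        fg, _ = bias_demo
        assert reverse_equivalence_check(fg, bias_demo_bg)

    def test_empty_motif_sets_are_trivially_equivalent(self):
        bg = uniform_background(7, center="S", n=3000, seed=17)
        idx = np.random.default_rng(18).choice(bg.n_sequences, 50, replace=False)
        fg = SequenceSet([SequenceWindow(bg.windows[i]) for i in idx], width=7)
        assert reverse_equivalence_check(fg, bg)

    def test_order_dependent_mock_extractor_is_caught(self, bias_demo, bias_demo_bg):
        """Negative control: a greedy first-pair extractor breaks the check."""
        fg, _ = bias_demo

        def greedy(fg_, bg_, cfg_):
            return extract_motifs(fg_, bg_, EngineConfig(tie_strategy="first"))

        assert reverse_equivalence_check(fg, bias_demo_bg, extractor=greedy) is False
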