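"""Codon-change classification, kappa-weighted site counting, kappa estimator."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from khscan import (
    CodonAlignment,
    classify_codon_change,
    count_sites,
    count_substitutions,
    estimate_kappa,
)
from khscan.counting import DEFAULT_KAPPA, KAPPA_CAP, k80_kappa, kappa_from_fourfold
from khscan.reference_data import STOP, codon_neighbors

import oracles
from conftest import random_codon_alignment


@pytest.mark.parametrize(
    "ca, cb, kind, n_diffs, pair, is_ts",
    [
        ("TTA", "TTA", "identical", 0, None, None),
        ("TTA", "CTA", "synonymous", 1, None, True),  # both Leu, C<->T transition
        ("AAA", "AGA", "elementary", 1, {"K", "R"}, True),
        ("AAA", "AGG", "nonelementary_aa_change", 2, {"K", "R"}, None),
        ("TGG", "TGA", "stop_involving", 1, None, None),  # TGA is a stop
        ("TTA", "CTG", "multihit_synonymous", 2, None, None),  # Leu<->Leu, 2 nt
        ("AAA", "ACC", "nonelementary_aa_change", 2, {"K", "T"}, None),
    ],
)
def test_classify_codon_change(code, ranking, ca, cb, kind, n_diffs, pair, is_ts):
    cls = classify_codon_change(ca, cb, code, ranking)
    assert cls.kind == kind
    assert cls.n_diffs == n_diffs
    assert cls.aa_pair == (frozenset(pair) if pair else None)
    assert cls.is_transition == is_ts
    assert (cls.class_rank is not None) == (kind == "elementary")
    if kind == "elementary":
        assert cls.class_rank == ranking.rank_of(*sorted(pair))


def test_classify_rejects_ambiguous(code, ranking):
    with pytest.raises(ValueError, match="triplet"):
        classify_codon_change("ANA", "AAA", code, ranking)


class TestCountSites:
    def test_phe_kappa1(self, code, ranking):
        """TTT with kappa=1: Ls=1/3; {F,L} collects CTT+TTA+TTG = 1 full site."""
        ls, li, stop_w = count_sites("TTT", 1.0, code, ranking)
        assert ls == Fraction(1, 3)
        assert li[ranking.rank_of("F", "L")] == 1
        for other in ("I", "V", "S", "Y", "C"):
            assert li[ranking.rank_of("F", other)] == Fraction(1, 3)
        assert stop_w == 0

    def test_phe_kappa2(self, code, ranking):
        """kappa=2: the position-3 transition TTC (synonymous) gets 2/4."""
        ls, li, stop_w = count_sites("TTT", 2.0, code, ranking)
        assert ls == Fraction(1, 2)
        assert sum(li.values()) == Fraction(5, 2)
        assert stop_w == 0

    def test_trp_stop_weight(self, code, ranking):
        """TGG: TGA and TAG are stops; their weights are excluded, not spread."""
        ls, li, stop_w = count_sites("TGG", 1.0, code, ranking)
        assert stop_w == Fraction(2, 3)
        assert ls + sum(li.values()) == Fraction(7, 3)

    def test_rejects_stop_codon(self, code, ranking):
        with pytest.raises(ValueError, match="stop codon TAA at codon position 1"):
            count_sites("AAATAA", 2.0, code, ranking)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 3.1415926, 50.0])
    def test_weights_sum_to_three_per_codon(self, code, ranking, kappa):
        """Exact partition of the 3 site units for every sense codon, any kappa."""
        for codon in code.sense_codons:
            ls, li, stop_w = count_sites(codon, kappa, code, ranking)
            assert ls + sum(li.values()) + stop_w == 3


class TestCountSubstitutions:
    def test_identical_pair(self, code, ranking):
        aln = CodonAlignment("g", "AAATTTGGG" * 10, "AAATTTGGG" * 10)
        c = count_substitutions(aln, code, ranking, kappa=2.0)
        assert float(c.ns) == 0 and c.na() == 0
        assert c.n_codons_used == 30

    def test_two_column_example(self, code, ranking):
        """AAA|TTT vs AGA|TTC: one Lys<->Arg change plus one synonymous."""
        aln = CodonAlignment("g", "AAATTT", "AGATTC")
        c = count_substitutions(aln, code, ranking, kappa=2.0)
        assert c.ns == 1
        assert c.ni[ranking.rank_of("K", "R")] == 1
        assert c.n_aa_changes_total == 1
        assert c.n_nonelementary == 0

    def test_site_partition_identity(self, code, ranking):
        """Ls + sum(Li) + stop_weight == 3 * usable codons, exactly."""
        rng = np.random.default_rng(3)
        aln = random_codon_alignment(rng, 80, code, p_sub=0.2, p_gap=0.02)
        c = count_substitutions(aln, code, ranking, kappa=2.7)
        assert c.ls + c.la() + c.stop_weight == 3 * c.n_codons_used

    def test_symmetry(self, code, ranking):
        rng = np.random.default_rng(11)
        for _ in range(20):
            aln = random_codon_alignment(rng, 40, code, p_sub=0.3, p_gap=0.02, p_n=0.02)
            fwd = count_substitutions(aln, code, ranking, kappa=1.7)
            rev = count_substitutions(
                CodonAlignment("g", aln.seq_b, aln.seq_a), code, ranking, kappa=1.7)
            assert fwd.ns == rev.ns and fwd.ni == rev.ni
            assert fwd.ls == rev.ls and fwd.li == rev.li

    def test_class_count_invariant(self, code, ranking):
        rng = np.random.default_rng(5)
        aln = random_codon_alignment(rng, 100, code, p_sub=0.3)
        c = count_substitutions(aln, code, ranking, kappa=2.0)
        assert sum(c.ni.values()) + c.n_nonelementary == c.n_aa_changes_total

    def test_all_gap_alignment_rejected(self, code, ranking):
        aln = CodonAlignment("g", "---", "AAA")
        with pytest.raises(ValueError, match="no usable codon"):
            count_substitutions(aln, code, ranking)

    def test_matches_brute_force_oracle(self, code, ranking):
        """Engine output is exactly the brute-force column classifier's."""
        rng = np.random.default_rng(99)
        for rep in range(60):
            aln = random_codon_alignment(
                rng, 50, code, p_sub=0.25, p_gap=0.01, p_n=0.01)
            kappa = float(rng.uniform(0.5, 5.0))
            c = count_substitutions(aln, code, ranking, kappa=kappa)
            ref = oracles.brute_force_counts(
                aln.seq_a, aln.seq_b, kappa, ranking.rank_of)
            assert c.ns == ref["ns"]
            assert c.ls == ref["ls"]
            assert c.ni == ref["ni"]
            assert c.li == ref["li"]
            assert c.stop_weight == ref["stop_weight"]
            assert c.n_nonelementary == ref["n_nonelementary"]
            assert c.n_codons_used == ref["n_codons_used"]


class TestKappa:
    def test_equal_rate_expectation(self):
        """P=0.1, Q=0.2 is the Q=2P equal-rates line: kappa == 1."""
        assert k80_kappa(0.1, 0.2) == pytest.approx(1.0, abs=1e-9)

    def test_transition_bias(self):
        assert k80_kappa(0.2, 0.1) == pytest.approx(5.2125676, abs=1e-6)

    def test_no_information_falls_back_to_default(self):
        est = kappa_from_fourfold(100, 0, 0)
        assert est.kappa == DEFAULT_KAPPA
        assert est.source == "default"
        assert est.n_4fold_sites == 100

    def test_no_transversions_capped(self):
        est = kappa_from_fourfold(100, 10, 0)
        assert est.kappa == KAPPA_CAP
        assert est.source == "capped"

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            k80_kappa(0.5, 0.3)

    def test_estimate_from_alignment(self, code):
        """Hand-built alignment: 4 fourfold sites, 1 transition difference."""
        # GGx columns are fourfold (Gly); GGA vs GGG is a third-position
        # transition; AAA columns are not fourfold and must be ignored
        aln = CodonAlignment("g", "GGAGGCGGTGGGAAA", "GGGGGCGGTGGGAAA")
        est = estimate_kappa(aln, code)
        assert est.n_4fold_sites == 4
        assert est.P == 0.25 and est.Q == 0.0
        assert est.source == "capped"

    def test_recovers_simulated_kappa(self, code, ranking):
        """Neutral 100k-codon simulation at kappa=2 estimates 2.0 +- 0.2."""
        from khscan import SimulationConfig, simulate_pair

        cfg = SimulationConfig(n_codons=100_000, kappa_true=2.0,
                               branch_length=0.02, seed=8)
        aln, _ = simulate_pair(cfg, code=code, table=ranking)
        est = estimate_kappa(aln, code)
        assert est.source == "k80"
        assert est.kappa == pytest.approx(2.0, abs=0.2)


@given(st.integers(min_value=0, max_value=60))
@settings(max_examples=30, deadline=None)
def test_single_diff_nonsyn_pairs_always_classify(code_idx):
    """Every one of the 61x9 neighbor pairs classifies into a unique kind."""
    from khscan import bundled_ranking, standard_code

    code = standard_code()
    ranking = bundled_ranking(code)
    codon = code.sense_codons[code_idx]
    aa = code.translate(codon)
    for nb in codon_neighbors(codon):
        cls = classify_codon_change(codon, nb, code, ranking)
        aa2 = code.translate(nb)
        if aa2 == STOP:
            assert cls.kind == "stop_involving"
        elif aa2 == aa:
            assert cls.kind == "synonymous"
        else:
            assert cls.kind == "elementary"
            assert 1 <= cls.class_rank <= 75
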