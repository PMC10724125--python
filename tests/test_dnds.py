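"""NG86 counting, F3x4 frequencies, GY-F3x4 ML estimation, group stats."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from araliome._codons import SENSE_CODONS
from araliome.dnds import (f3x4_frequencies, group_compare, ml_pair,
                           ng86_pair, ng86_sites, simulate_gy_pair)


def _translate(codon: str) -> str:
    """Independent translation oracle (Biopython, table 11)."""
    return str(Seq(codon).translate(table=11))


def _is_stop(codon: str) -> bool:
    return _translate(codon) == "*"


def brute_sites(codon):
    """Independent NG86 site oracle: enumerate the 9 single-base changes,
    drop changes to stops from the denominator."""
    syn = 0.0
    for pos in range(3):
        muts = [codon[:pos] + b + codon[pos + 1:]
                for b in "ACGT" if b != codon[pos]]
        counted = [m for m in muts if not _is_stop(m)]
        if counted:
            syn += sum(_translate(m) == _translate(codon)
                       for m in counted) / len(counted)
    return syn, 3.0 - syn


def brute_differences(ca, cb):
    """Independent pathway oracle: explicit stepwise enumeration."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if _is_stop(nxt):
                ok = False
                break
            if _translate(nxt) == _translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


class TestNG86Sites:
    @pytest.mark.parametrize("codon,syn", [
        ("TTT", 1 / 3),   # only TTC is synonymous
        ("TTA", 2 / 3),   # stop-blocked position 2 counts fully nonsyn
    ])
    def test_hand_enumerated(self, codon, syn):
        s, n = ng86_sites(codon)
        assert s == pytest.approx(syn)
        assert s + n == pytest.approx(3.0)

    def test_fourfold_third_position(self):
        # all third-position changes of GGG are synonymous
        s, _ = ng86_sites("GGG")
        assert s >= 1.0

    def test_sites_sum_to_three_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert (s, n) == pytest.approx(brute_sites(codon))


class TestNG86Pair:
    def test_identical_sequences(self):
        e = ng86_pair("ATGAAA", "ATGAAA")
        assert e.Sd == e.Nd == 0
        assert e.dS == e.dN == 0.0

    def test_single_codon_hand_computation(self):
        # TTT vs TTA: one nonsynonymous difference; S = (1/3 + 2/3)/2
        e = ng86_pair("TTT", "TTA")
        assert e.Nd == 1 and e.Sd == 0
        assert e.S == pytest.approx(0.5)
        assert e.N == pytest.approx(2.5)
        assert e.pN == pytest.approx(1 / 2.5)
        assert e.S + e.N == pytest.approx(3 * e.codons_used)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(8)
        pi = np.full(61, 1 / 61)
        for _ in range(5):
            a, b = simulate_gy_pair(0.4, 2.0, 0.5, pi, 200, rng)
            e1, e2 = ng86_pair(a, b), ng86_pair(b, a)
            assert e1.dS == pytest.approx(e2.dS)
            assert e1.dN == pytest.approx(e2.dN)

    def test_codon_order_permutation_invariance(self):
        rng = np.random.default_rng(12)
        pi = np.full(61, 1 / 61)
        a, b = simulate_gy_pair(0.3, 2.0, 0.4, pi, 100, rng)
        perm = rng.permutation(100)
        pa = "".join(a[3 * k:3 * k + 3] for k in perm)
        pb = "".join(b[3 * k:3 * k + 3] for k in perm)
        e1, e2 = ng86_pair(a, b), ng86_pair(pa, pb)
        assert e1.dS == pytest.approx(e2.dS)
        assert e1.dN == pytest.approx(e2.dN)

    def test_gap_and_ambiguous_codons_dropped_pairwise(self):
        e = ng86_pair("ATG---AAANNN", "ATGCCCAA-AAA")
        assert e.codons_used == 1  # only the ATG column survives

    def test_agrees_with_brute_force_on_all_near_pairs(self):
        """Exhaustive oracle check over sense-codon pairs within Hamming
        distance 2 (subset here; the full 61x61 sweep runs in the
        acceptance suite)."""
        for ca in SENSE_CODONS[::6]:
            for cb in SENSE_CODONS:
                if sum(x != y for x, y in zip(ca, cb)) > 2:
                    continue
                expected = brute_differences(ca, cb)
                e_sites_a = brute_sites(ca)
                est = ng86_pair(ca, cb) if expected is not None else None
                if expected is None:
                    continue
                assert est.Sd == pytest.approx(expected[0])
                assert est.Nd == pytest.approx(expected[1])
                assert est.S == pytest.approx(
                    (e_sites_a[0] + brute_sites(cb)[0]) / 2)


class TestF3x4:
    def test_uniform_composition_gives_1_over_61(self):
        pi = f3x4_frequencies(["ACGT" * 30])  # uniform at every position
        assert pi == pytest.approx(np.full(61, 1 / 61), abs=1e-12)

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert f3x4_frequencies([seq]).sum() == pytest.approx(1.0)

    def test_third_position_skew_raises_a_ending_codons(self):
        base = "ATGGCTACTGACAGGCCTTGGTTCATC" * 10
        skewed = base[:len(base) // 2] + "".join(
            c if (i % 3) != 2 else "A"
            for i, c in enumerate(base[len(base) // 2:]))
        pi_base = f3x4_frequencies([base])
        pi_skew = f3x4_frequencies([skewed])
        a_ending = [i for i, c in enumerate(SENSE_CODONS) if c[2] == "A"]
        assert pi_skew[a_ending].sum() > pi_base[a_ending].sum()

    def test_smoothing_warns_on_missing_base(self):
        with pytest.warns(UserWarning, match="smoothing"):
            f3x4_frequencies(["AAAAAA"])


class TestMLPair:
    def test_identical_sequences_zero_rates(self):
        seq = "ATGGCTACTGAAAGACCTTGGTTCATC" * 10
        e = ml_pair(seq, seq)
        assert e.params["t"] < 1e-3
        assert e.dS < 1e-3 and e.dN < 1e-3

    def test_swap_invariance(self):
        rng = np.random.default_rng(4)
        pi = np.full(61, 1 / 61)
        a, b = simulate_gy_pair(0.3, 2.0, 0.2, pi, 800, rng)
        e1, e2 = ml_pair(a, b), ml_pair(b, a)
        assert e1.params["loglik"] == pytest.approx(e2.params["loglik"],
                                                    rel=1e-6)
        assert e1.dS == pytest.approx(e2.dS, rel=1e-4)

    def test_parameter_recovery_moderate_divergence(self):
        """Single-replicate sanity recovery; the 20-replicate median-error
        check runs in the acceptance suite."""
        rng = np.random.default_rng(77)
        pi = f3x4_frequencies(["ATGGCTACTGAAAGACCTTGGTTCATC" * 20])
        a, b = simulate_gy_pair(0.3, 2.0, 0.1, pi, 5000, rng)
        e = ml_pair(a, b)
        assert e.params["t"] == pytest.approx(0.3, rel=0.15)
        assert e.params["kappa"] == pytest.approx(2.0, rel=0.2)
        assert e.params["omega"] == pytest.approx(0.1, rel=0.25)

    def test_agreement_with_ng86_at_low_divergence(self):
        rng = np.random.default_rng(31)
        pi = np.full(61, 1 / 61)
        a, b = simulate_gy_pair(0.08, 2.0, 0.3, pi, 4000, rng)
        ml, ng = ml_pair(a, b), ng86_pair(a, b)
        assert ml.dN == pytest.approx(ng.dN, rel=0.2)
        assert ml.dS == pytest.approx(ng.dS, rel=0.2)


class TestGroupCompare:
    def test_hand_anova(self):
        # groups {1,2,3} and {2,3,4}: F = 1.5 on (1, 4) df
        vals = {"a": 1, "b": 2, "c": 3, "d": 2, "e": 3, "f": 4}
        grouping = {k: ("g1" if k in "abc" else "g2") for k in vals}
        out = group_compare(vals, grouping)
        F, df1, df2, p = out.anova
        assert F == pytest.approx(1.5)
        assert (df1, df2) == (1, 4)

    def test_identical_groups_f_zero_p_one(self):
        vals = {"a": 1, "b": 2, "c": 1, "d": 2}
        grouping = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        out = group_compare(vals, grouping)
        assert out.anova[0] == pytest.approx(0.0)
        assert out.anova[3] == pytest.approx(1.0)
        assert out.pairwise.loc["g1", "g2"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        vals = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}
        grouping = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        out = group_compare(vals, grouping)
        assert "zero_variance" in out.flags
        assert math.isnan(out.anova[3])

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(1)
        vals = {f"s{i}": float(v) for i, v in
                enumerate(rng.normal(size=12))}
        grouping = {f"s{i}": f"g{i % 3}" for i in range(12)}
        out = group_compare(vals, grouping)
        for a in out.pairwise.index:
            for b in out.pairwise.columns:
                if a != b:
                    assert 0.0 <= out.pairwise.loc[a, b] <= 1.0

    def test_singletons_excluded_and_listed(self):
        vals = {"a": 1, "b": 2, "c": 2, "d": 3, "solo": 9}
        grouping = {"a": "g1", "b": "g1", "c": "g2", "d": "g2",
                    "solo": "lonely"}
        out = group_compare(vals, grouping)
        assert out.excluded_singletons == ["lonely"]
        assert "lonely" in out.group_stats  # mean still reported
        assert out.group_stats["lonely"][1] is None
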