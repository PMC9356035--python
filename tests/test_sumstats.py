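"""Summary-statistic tests against closed forms and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from danubesim.coalescent import HaplotypeSample
from danubesim.sumstats import (
    STAT_NAMES,
    GroupingPlan,
    K2PSaturationError,
    fst_permutation_p,
    gene_diversity,
    haplotype_count,
    k2p_distance,
    mean_pairwise_diff,
    pairwise_phist,
    stats_vector,
)


def sample(*seqs):
    return HaplotypeSample(group_id="s", sequences=list(seqs))


# ---------------------------------------------------------------------------
# Independent oracles (explicit loops, no shared code with the package)
# ---------------------------------------------------------------------------


def oracle_k2p(a, b):
    ts = tv = 0
    purines = {"A", "G"}
    for x, y in zip(a, b):
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    P, Q = ts / len(a), tv / len(a)
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


def oracle_phist(groups, distance):
    """AMOVA PhiST from first principles: SSD decomposition of the distance
    matrix (entries used as squared distances)."""
    seqs = [s for g in groups for s in g]
    sizes = [len(g) for g in groups]
    N, G = len(seqs), len(groups)
    ssd_total = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            ssd_total += distance(seqs[i], seqs[j])
    ssd_total /= N
    ssd_within = 0.0
    start = 0
    for g in groups:
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                ssd_within += distance(g[i], g[j]) / len(g)
        start += len(g)
    ssd_among = ssd_total - ssd_within
    msd_within = ssd_within / (N - G)
    msd_among = ssd_among / (G - 1)
    n_c = (N - sum(s * s for s in sizes) / N) / (G - 1)
    sigma_a = (msd_among - msd_within) / n_c
    if sigma_a + msd_within == 0:
        return 0.0
    return sigma_a / (sigma_a + msd_within)


def raw_diff(a, b):
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGT", "ACGT") == 0.0

    def test_single_transition(self):
        # L=10, one A<->G change: P=0.1, Q=0 -> -0.5 ln(0.8)
        a, b = "A" * 10, "G" + "A" * 9
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8))
        assert k2p_distance(a, b) == pytest.approx(0.11157, abs=1e-5)

    def test_saturation_raises(self):
        # Q=0.5 puts the formula outside its domain
        a, b = "A" * 10, "C" * 5 + "A" * 5
        with pytest.raises(K2PSaturationError):
            k2p_distance(a, b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            k2p_distance("AC", "ACG")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACGT"), st.sampled_from("ACGT")
            ),
            min_size=4,
            max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_oracle_when_defined(self, pairs):
        a = "".join(p[0] for p in pairs)
        b = "".join(p[1] for p in pairs)
        try:
            expect = oracle_k2p(a, b)
        except ValueError:
            with pytest.raises(K2PSaturationError):
                k2p_distance(a, b)
            return
        assert k2p_distance(a, b) == pytest.approx(expect)


# ---------------------------------------------------------------------------
# Within-sample diversity
# ---------------------------------------------------------------------------


class TestGeneDiversity:
    def test_all_distinct_is_one(self):
        s = sample("AAAA", "AAAC", "AACC", "ACCC")
        assert gene_diversity(s) == pytest.approx(1.0)

    def test_monomorphic_is_zero(self):
        assert gene_diversity(sample("AAAA", "AAAA", "AAAA")) == 0.0

    def test_two_haplotypes_half_half(self):
        s = sample("AAAA", "AAAA", "CCCC", "CCCC")
        assert gene_diversity(s) == pytest.approx(4 / 3 * 0.5)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            gene_diversity(sample("AAAA"))

    def test_invariant_under_haplotype_relabeling(self):
        s1 = sample("AAAA", "AAAA", "CCCC")
        s2 = sample("GGGG", "GGGG", "TTTT")
        assert gene_diversity(s1) == pytest.approx(gene_diversity(s2))


class TestPi:
    def test_monomorphic(self):
        assert mean_pairwise_diff(sample("AAA", "AAA")) == 0.0

    def test_raw_count_toy(self):
        # raw differences 1, 1, 2 -> mean 4/3
        s = sample("AAAAAAAAAA", "GAAAAAAAAA", "AGAAAAAAAA")
        assert mean_pairwise_diff(s, corrected=False) == pytest.approx(4 / 3)

    def test_corrected_is_mean_k2p(self):
        s = sample("AAAAAAAAAA", "GAAAAAAAAA", "AGAAAAAAAA")
        pairs = list(itertools.combinations(s.sequences, 2))
        expect = np.mean([oracle_k2p(a, b) for a, b in pairs])
        assert mean_pairwise_diff(s, corrected=True) == pytest.approx(expect)

    def test_invariant_under_site_permutation(self):
        rng = np.random.default_rng(0)
        seqs = ["ACGTAC", "ACGAAC", "TCGTAC", "ACGTGG"]
        perm = rng.permutation(6)
        permuted = ["".join(s[i] for i in perm) for s in seqs]
        for corrected in (True, False):
            assert mean_pairwise_diff(
                sample(*seqs), corrected=corrected
            ) == pytest.approx(
                mean_pairwise_diff(sample(*permuted), corrected=corrected)
            )


class TestHaplotypeCount:
    @pytest.mark.parametrize(
        "seqs, k",
        [
            (("AAA",) * 5, 1),
            (("AAA", "AAC", "ACC", "CCC", "CCA"), 5),
            (("AAA", "AAA", "AAC", "AAC", "ACC"), 3),
        ],
    )
    def test_counts(self, seqs, k):
        assert haplotype_count(sample(*seqs)) == k


# ---------------------------------------------------------------------------
# PhiST
# ---------------------------------------------------------------------------


class TestPhiST:
    def test_identical_samples_zero(self):
        a = sample("A" * 10, "AAGG" + "A" * 6, "GG" + "A" * 8)
        b = sample("A" * 10, "AAGG" + "A" * 6, "GG" + "A" * 8)
        assert pairwise_phist(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_monomorphic_samples(self):
        # two monomorphic samples two substitutions apart: all variance
        # is between groups
        a = sample(*["AAAAAAAAAA"] * 5)
        b = sample(*["GGAAAAAAAA"] * 5)
        expect = oracle_phist(
            [a.sequences, b.sequences], lambda x, y: oracle_k2p(x, y)
        )
        assert pairwise_phist(a, b) == pytest.approx(expect)
        assert pairwise_phist(a, b) == pytest.approx(1.0)

    def test_matches_oracle_on_small_instances(self):
        """Exhaustive check on all <=6-sequence two-group toys over a small
        haplotype pool."""
        pool = ["AAAA", "GAAA", "AGAA", "TTAA"]
        count = 0
        for na in (2, 3):
            for nb in (2, 3):
                for combo in itertools.combinations_with_replacement(
                    range(len(pool)), na + nb
                ):
                    seqs = [pool[i] for i in combo]
                    a, b = sample(*seqs[:na]), sample(*seqs[na:])
                    expect = oracle_phist(
                        [a.sequences, b.sequences], raw_diff
                    )
                    got = pairwise_phist(a, b, corrected=False, clamp=False)
                    assert got == pytest.approx(expect, abs=1e-12), seqs
                    count += 1
        assert count > 100

    def test_negative_estimates_clamped_for_reporting(self):
        a = sample("A" * 10, "G" + "A" * 9, "AG" + "A" * 8)
        b = sample("A" * 10, "G" + "A" * 9, "AG" + "A" * 8)
        raw = pairwise_phist(a, b, clamp=False)
        assert raw <= 0.0
        assert pairwise_phist(a, b, clamp=True) == 0.0

    def test_null_distribution_centred_at_zero(self):
        """Two samples drawn from one panmictic pool: the mean unclamped
        PhiST over replicates is near 0."""
        rng = np.random.default_rng(42)
        pool = ["AAAA", "GAAA", "AGAA", "AAGA", "TTAA", "AATT"]
        vals = []
        for _ in range(100):
            draws = rng.integers(0, len(pool), size=12)
            a = sample(*[pool[i] for i in draws[:6]])
            b = sample(*[pool[i] for i in draws[6:]])
            vals.append(pairwise_phist(a, b, corrected=False, clamp=False))
        assert abs(np.mean(vals)) < 0.05


class TestPermutationP:
    def test_identical_samples_high_p(self):
        a = sample("A" * 10, "G" + "A" * 9, "AG" + "A" * 8)
        b = sample("A" * 10, "G" + "A" * 9, "AG" + "A" * 8)
        assert fst_permutation_p(a, b, n_perm=200, seed=1) > 0.5

    def test_disjoint_haplotypes_significant(self):
        a = sample(*["A" * 20] * 10)
        b = sample(*["GGGG" + "A" * 16] * 10)
        assert fst_permutation_p(a, b, n_perm=1000, seed=1) <= 0.01

    def test_reproducible_under_seed(self):
        a = sample("A" * 10, "G" + "A" * 9, "AG" + "A" * 8, "A" * 10)
        b = sample("AAG" + "A" * 7, "A" * 10, "G" + "A" * 9, "TT" + "A" * 8)
        p1 = fst_permutation_p(a, b, n_perm=300, seed=7)
        p2 = fst_permutation_p(a, b, n_perm=300, seed=7)
        assert p1 == p2

    def test_minimum_permutations_enforced(self):
        a = sample("AAAA", "GAAA")
        with pytest.raises(ValueError):
            fst_permutation_p(a, a, n_perm=50)


# ---------------------------------------------------------------------------
# 14-statistic vector
# ---------------------------------------------------------------------------


def _seven_groups(builder):
    plan = GroupingPlan.danubian()
    return {g: builder(g) for g in plan.group_ids}, plan


class TestStatsVector:
    def test_degenerate_world_all_zero(self):
        groups, plan = _seven_groups(lambda g: sample("AAAA", "AAAA", "AAAA"))
        v = stats_vector(groups, plan)
        assert v.shape == (14,)
        assert v[0] == 1.0  # k mean
        assert np.allclose(v[1:], 0.0)

    def test_vector_length_and_names(self):
        assert len(STAT_NAMES) == 14

    def test_missing_group_is_an_error(self):
        groups, plan = _seven_groups(lambda g: sample("AAAA", "AAAA"))
        del groups["HG_CE"]
        with pytest.raises(ValueError, match="missing"):
            stats_vector(groups, plan)

    def test_aggregation_matches_hand_computation(self):
        """Means/SDs recomputed independently from per-group statistics."""
        rng = np.random.default_rng(3)
        pool = [
            "A" * 10,
            "G" + "A" * 9,
            "AG" + "A" * 8,
            "AAG" + "A" * 7,
            "TT" + "A" * 8,
        ]

        def builder(g):
            return sample(*[pool[i] for i in rng.integers(0, 5, size=6)])

        groups, plan = _seven_groups(builder)
        v = stats_vector(groups, plan)
        ordered = [groups[g] for g in plan.group_ids]
        ks = [haplotype_count(s) for s in ordered]
        Hs = [gene_diversity(s) for s in ordered]
        pis = [mean_pairwise_diff(s) for s in ordered]
        assert v[0] == pytest.approx(np.mean(ks))
        assert v[1] == pytest.approx(np.std(ks, ddof=1))
        assert v[2] == pytest.approx(np.mean(Hs))
        assert v[3] == pytest.approx(np.std(Hs, ddof=1))
        assert v[4] == pytest.approx(np.mean(pis))
        assert v[5] == pytest.approx(np.std(pis, ddof=1))
        # pair-group PhiST blocks, recomputed directly
        pg = plan.pair_groups()
        for block, (i_mean, i_sd) in zip(
            ("hg_cefarmers", "early", "late", "serial"), ((6, 7), (8, 9), (10, 11), (12, 13))
        ):
            fsts = [pairwise_phist(groups[a], groups[b]) for a, b in pg[block]]
            assert v[i_mean] == pytest.approx(np.mean(fsts))
            assert v[i_sd] == pytest.approx(np.std(fsts, ddof=1))

    def test_pair_group_sizes(self):
        plan = GroupingPlan.danubian()
        pg = plan.pair_groups()
        assert len(pg["hg_cefarmers"]) == 2
        assert len(pg["early"]) == 3
        assert len(pg["late"]) == 3
        assert len(pg["serial"]) == 3
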