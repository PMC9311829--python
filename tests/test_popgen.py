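"""Marker screening and inbreeding-index tests."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from asymlink.popgen import (
    GenotypeTable,
    compare_groups,
    compare_groups_batch,
    het_stats,
    holm_adjust,
    hwe_exact,
    inbreeding_indices,
    ld_test,
    read_genepop,
)


def table_from_arrays(a1, a2, loci=None):
    loci = loci or [f"L{j}" for j in range(np.asarray(a1).shape[1])]
    ids = [f"i{j}" for j in range(np.asarray(a1).shape[0])]
    return GenotypeTable(
        a1=pd.DataFrame(np.asarray(a1, dtype=float), index=ids, columns=loci),
        a2=pd.DataFrame(np.asarray(a2, dtype=float), index=ids, columns=loci),
    )


class TestHetStats:
    def test_monomorphic_locus(self):
        t = table_from_arrays([[5], [5], [5]], [[5], [5], [5]])
        assert het_stats(t, "L0") == (0.0, 0.0)

    def test_two_heterozygotes_closed_form(self):
        t = table_from_arrays([[1], [1]], [[2], [2]])
        ho, he = het_stats(t, "L0")
        assert ho == 1.0
        assert he == pytest.approx((4 / 3) * 0.5)

    def test_matches_direct_count_oracle(self, rng):
        a = rng.integers(8, 14, size=(40, 1)).astype(float)
        b = rng.integers(8, 14, size=(40, 1)).astype(float)
        t = table_from_arrays(a, b)
        ho, he = het_stats(t, "L0")
        het = sum(1 for x, y in zip(a[:, 0], b[:, 0]) if x != y)
        assert ho == pytest.approx(het / 40)
        counts = {}
        for allele in list(a[:, 0]) + list(b[:, 0]):
            counts[allele] = counts.get(allele, 0) + 1
        freq_sq = sum((v / 80) ** 2 for v in counts.values())
        assert he == pytest.approx((80 / 79) * (1 - freq_sq))

    def test_missing_calls_dropped(self, small_genotypes):
        ho, _ = het_stats(small_genotypes, "L3")
        assert ho == pytest.approx(3 / 5)  # 5 typed, 3 heterozygous


class TestHweExact:
    def test_all_heterozygotes_matches_longhand_enumeration(self):
        # 5 individuals, allele counts 5/5: arrays have h in {1,3,5}
        # heterozygotes; Levene probability computed longhand
        t = table_from_arrays([[1]] * 5, [[2]] * 5)

        def levene(n11, h, n22):
            n = n11 + h + n22
            return (
                math.factorial(n) * math.factorial(5) ** 2 * 2**h
                / (math.factorial(10) * math.factorial(n11) * math.factorial(h) * math.factorial(n22))
            )

        probs = {h: levene((5 - h) // 2, h, (5 - h) // 2) for h in (1, 3, 5)}
        assert sum(probs.values()) == pytest.approx(1.0)
        expected = sum(p for p in probs.values() if p <= probs[5] + 1e-12)
        assert hwe_exact(t, "L0", method="enumeration") == pytest.approx(expected)

    def test_monte_carlo_matches_enumeration_within_binomial_error(self):
        t = table_from_arrays([[1]] * 5, [[2]] * 5)
        p_enum = hwe_exact(t, "L0", method="enumeration")
        p_mc = hwe_exact(t, "L0", method="montecarlo", seed=11, n_perm=10_000)
        se = math.sqrt(p_enum * (1 - p_enum) / 10_000)
        assert abs(p_mc - p_enum) <= 3 * se + 2e-4

    def test_hw_proportions_give_large_p(self):
        # genotype counts built exactly at Hardy-Weinberg proportions
        # for p = (0.5, 0.3, 0.2), n = 200
        cells = {(1, 1): 50, (1, 2): 60, (1, 3): 40, (2, 2): 18, (2, 3): 24, (3, 3): 8}
        a1 = [[float(i)] for (i, j), c in cells.items() for _ in range(c)]
        a2 = [[float(j)] for (i, j), c in cells.items() for _ in range(c)]
        t = table_from_arrays(a1, a2)
        assert hwe_exact(t, "L0", seed=4) > 0.5

    def test_monomorphic_returns_one(self):
        t = table_from_arrays([[7]] * 4, [[7]] * 4)
        assert hwe_exact(t, "L0") == 1.0


class TestLdTest:
    def test_perfect_association_reaches_minimum_p(self, rng):
        g = rng.choice([1.0, 2.0, 3.0], size=(40, 2))
        t = table_from_arrays(np.column_stack([g[:, 0], g[:, 0]]),
                              np.column_stack([g[:, 1], g[:, 1]]))
        assert ld_test(t, "L0", "L1", n_perm=999, seed=0) == pytest.approx(1 / 1000)

    def test_degenerate_two_individuals_returns_large_p(self):
        t = table_from_arrays([[1, 1], [2, 2]], [[1, 1], [2, 2]])
        assert ld_test(t, "L0", "L1", n_perm=99, seed=1) > 0.2

    def test_null_p_values_are_uniform(self, rng):
        hits = 0
        reps = 500
        for _ in range(reps):
            a = rng.choice([1.0, 2.0], size=(30, 2))
            b = rng.choice([1.0, 2.0], size=(30, 2))
            t = table_from_arrays(np.column_stack([a[:, 0], b[:, 0]]),
                                  np.column_stack([a[:, 1], b[:, 1]]))
            if ld_test(t, "L0", "L1", n_perm=199, seed=int(rng.integers(2**31))) < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.08


class TestHolm:
    def test_closed_form_examples(self):
        assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])
        assert np.allclose(holm_adjust([0.003, 0.013, 0.2, 0.9]), [0.012, 0.039, 0.4, 0.9])
        assert np.allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_longhand_stepdown_oracle(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 12))
            adj = holm_adjust(p)
            order = sorted(range(len(p)), key=lambda i: p[i])
            running, expected = 0.0, [0.0] * len(p)
            for rank, i in enumerate(order):
                running = max(running, min(1.0, (len(p) - rank) * p[i]))
                expected[i] = running
            assert np.allclose(adj, expected)

    def test_matches_statsmodels_reference(self, rng):
        p = rng.random(20)
        assert np.allclose(holm_adjust(p), multipletests(p, method="holm")[1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=15))
    def test_never_decreases_and_idempotent(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        again = holm_adjust(adj)
        srt = np.sort(adj)
        # idempotence on already-monotone adjusted vectors holds when no
        # further multiplication can raise them, i.e. re-adjusting keeps order
        assert np.all(np.sort(again) >= srt - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestInbreedingIndices:
    def test_closed_form_examples(self, small_genotypes):
        idx = inbreeding_indices(small_genotypes)
        # i0: L1 het, L2 hom, L3 het -> mlh 2/3; d2 = (4 + 0 + 1)/3
        assert idx.loc["i0", "mlh"] == pytest.approx(2 / 3)
        assert idx.loc["i0", "d2"] == pytest.approx(5 / 3)
        # i3: fully homozygous at typed loci
        assert idx.loc["i3", "mlh"] == pytest.approx(1 / 3)

    def test_single_spread_locus_arithmetic(self):
        a1 = [[12, 5, 5, 5, 5, 5]]
        a2 = [[18, 5, 5, 5, 5, 5]]
        idx = inbreeding_indices(table_from_arrays(a1, a2))
        assert idx.loc["i0", "mlh"] == pytest.approx(1 / 6)
        assert idx.loc["i0", "d2"] == pytest.approx(36 / 6)

    def test_fully_homozygous_individual(self):
        idx = inbreeding_indices(table_from_arrays([[9, 9]], [[9, 9]]))
        assert idx.loc["i0", "mlh"] == 0.0
        assert idx.loc["i0", "d2"] == 0.0

    def test_matches_direct_count_oracle(self, rng):
        a = rng.integers(5, 12, size=(25, 6)).astype(float)
        b = rng.integers(5, 12, size=(25, 6)).astype(float)
        idx = inbreeding_indices(table_from_arrays(a, b))
        for i in range(25):
            het = sum(1 for j in range(6) if a[i, j] != b[i, j])
            d2 = sum((a[i, j] - b[i, j]) ** 2 for j in range(6)) / 6
            assert idx.iloc[i]["mlh"] == pytest.approx(het / 6)
            assert idx.iloc[i]["d2"] == pytest.approx(d2)

    def test_invariant_to_locus_order_and_allele_shift(self, rng):
        a = rng.integers(5, 12, size=(10, 4)).astype(float)
        b = rng.integers(5, 12, size=(10, 4)).astype(float)
        base = inbreeding_indices(table_from_arrays(a, b))
        perm = [2, 0, 3, 1]
        shuffled = inbreeding_indices(table_from_arrays(a[:, perm], b[:, perm]))
        shifted = inbreeding_indices(table_from_arrays(a + 7, b + 7))
        assert np.allclose(base["mlh"], shuffled["mlh"])
        assert np.allclose(base["d2"], shuffled["d2"])
        assert np.allclose(base["d2"], shifted["d2"])


class TestCompareGroups:
    def test_complete_separation_with_skewed_data_uses_mann_whitney(self):
        skewed = [0.1, 0.1, 0.12, 0.15, 0.2, 0.3, 0.9, 4.0, 9.0, 30.0]
        res = compare_groups({"a": skewed, "b": [v + 1000 for v in skewed]})
        assert res["test"] == "mann_whitney_u"
        assert res["statistic"] in (0.0, 100.0)
        assert res["p"] < 1e-3

    def test_normal_groups_use_welch_t(self, rng):
        res = compare_groups({"a": rng.normal(0, 1, 30), "b": rng.normal(0.2, 1, 30)})
        assert res["test"] == "welch_t"

    def test_null_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            res = compare_groups({"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30)})
            hits += res["p"] < 0.05
        assert 0.03 <= hits / reps <= 0.08

    def test_batch_holm_arithmetic(self, rng):
        comps = {f"c{j}": {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)} for j in range(4)}
        out = compare_groups_batch(comps)
        assert np.allclose(out["p_holm"], holm_adjust(out["p"].to_numpy()))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1, 2, 3]})


class TestGenepop:
    def test_round_trip_of_codes_and_missing(self, tmp_path):
        text = (
            "Title line\n"
            "LocA\nLocB\n"
            "Pop\n"
            "ind1 , 0102 010101\n"
            "ind2 , 0000 020202\n"
            "Pop\n"
            "ind3 , 0202 000000\n"
        )
        path = tmp_path / "g.gen"
        path.write_text(text)
        t = read_genepop(path)
        assert t.loci == ["LocA", "LocB"]
        assert t.groups["pop"].tolist() == ["pop1", "pop1", "pop2"]
        assert np.isnan(t.a1.loc["ind2", "LocA"])
        assert t.a1.loc["ind1", "LocB"] == 10.0 and t.a2.loc["ind1", "LocB"] == 101.0
        assert np.isnan(t.a1.loc["ind3", "LocB"])

    def test_wrong_genotype_count_rejected(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("T\nLocA\nLocB\nPop\nind1 , 0102\n")
        with pytest.raises(ValueError, match="ind1"):
            read_genepop(path)
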