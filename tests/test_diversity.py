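import numpy as np
import pytest
from scipy.special import comb

from msatabc import (
    allelic_richness,
    basic_diversity,
    fst_ena,
    group_permutation_test,
    null_allele_em,
    pairwise_fst_test,
    wc_fstats,
)
from msatabc.containers import MISSING

from conftest import make_dataset


def hwe_population(rng, freqs, n, n_loci=3):
    """Diploid genotypes drawn in exact HWE from given allele frequencies."""
    alleles = np.array(sorted(freqs))
    p = np.array([freqs[a] for a in alleles])
    g = rng.choice(alleles, size=(n, n_loci, 2), p=p)
    return g.astype(np.int16)


class TestBasicDiversity:
    def test_monomorphic_population(self):
        ds = make_dataset([np.full((8, 3, 2), 15)])
        rep = basic_diversity(ds)
        assert rep.A[0] == 1.0
        assert rep.Ho[0] == 0.0
        assert rep.uHe[0] == 0.0

    def test_ho_uhe_formula(self):
        # 10 diploids, 1 locus: 5 heterozygotes (15,17), 5 homozygotes (15,15)
        # p = (0.75, 0.25): Ho = 0.5, uHe = (20/19)(1 - 0.625)
        block = np.array([[(15, 17)]] * 5 + [[(15, 15)]] * 5, dtype=np.int16)
        rep = basic_diversity(make_dataset([block]))
        assert rep.Ho[0] == pytest.approx(0.5)
        assert rep.uHe[0] == pytest.approx(20 / 19 * (1 - 0.625), abs=1e-12)

    def test_private_alleles_attributed_to_single_population(self):
        a = np.array([[(10, 11)]] * 4, dtype=np.int16)
        b = np.array([[(10, 10)]] * 4, dtype=np.int16)
        rep = basic_diversity(make_dataset([a, b]))
        assert rep.Pa[0] == 1  # allele 11 only in population 1
        assert rep.Pa[1] == 0


class TestAllelicRichness:
    def test_full_sample_equals_observed_count(self):
        rng = np.random.default_rng(2)
        block = hwe_population(rng, {10: 0.5, 12: 0.3, 14: 0.2}, 12, 2)
        ds = make_dataset([block])
        n = 24  # gene copies
        ar = allelic_richness(ds, g=n)
        observed = basic_diversity(ds).A
        assert ar[0] == pytest.approx(observed[0], abs=1e-9)

    def test_hypergeometric_example(self):
        # counts {19, 1}, n = 20, g = 10 -> Ar = 2 - C(19,10)/C(20,10) = 1.5
        pairs = [(10, 10)] * 9 + [(10, 12)]
        block = np.array([[p] for p in pairs], dtype=np.int16)
        ar = allelic_richness(make_dataset([block]), g=10)
        expected = 2 - comb(19, 10) / comb(20, 10)
        assert expected == pytest.approx(1.5)
        assert ar[0] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_g(self):
        rng = np.random.default_rng(3)
        block = hwe_population(rng, {8: 0.4, 9: 0.3, 11: 0.2, 14: 0.1}, 20, 3)
        ds = make_dataset([block])
        values = [allelic_richness(ds, g=g)[0] for g in range(2, 40)]
        assert np.all(np.diff(values) >= -1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(4)
        block = hwe_population(rng, {8: 0.6, 9: 0.4}, 15, 2)
        ds = make_dataset([block])
        a_obs = basic_diversity(ds).A[0]
        for g in (2, 10, 20):
            ar = allelic_richness(ds, g=g)[0]
            assert 1.0 <= ar <= a_obs + 1e-9

    def test_small_g_rejected(self):
        ds = make_dataset([np.full((5, 2, 2), 9)])
        with pytest.raises(ValueError):
            allelic_richness(ds, g=1)


def brute_force_wc_fst(ds):
    """Independent direct implementation of the two-level Weir-Cockerham
    variance components (textbook formulas, no shortcuts)."""
    num = den = 0.0
    max_state = int(ds.genotypes.max())
    for l in range(ds.n_loci):
        per_pop = []
        for i in range(ds.n_populations):
            g = ds.pop_genotypes(i)[:, l, :]
            ok = (g[:, 0] != MISSING) & (g[:, 1] != MISSING)
            per_pop.append(g[ok])
        ns = np.array([len(g) for g in per_pop], dtype=float)
        r = (ns >= 1).sum()
        if r < 2:
            continue
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        alleles = set()
        for g in per_pop:
            alleles.update(np.unique(g))
        for allele in sorted(alleles):
            ps = np.array([np.mean(g == allele) if len(g) else 0.0 for g in per_pop])
            hs = np.array([
                np.mean((g[:, 0] != g[:, 1]) & ((g[:, 0] == allele) | (g[:, 1] == allele)))
                if len(g) else 0.0
                for g in per_pop
            ])
            pbar = (ns * ps).sum() / (r * nbar)
            s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns * hs).sum() / (r * nbar)
            a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
            b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestWcFst:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(5)
        block = hwe_population(rng, {10: 0.5, 13: 0.5}, 20, 3)
        _, gfst, pw = wc_fstats(make_dataset([block, block.copy()]))
        # duplicated samples leave only the negative O(1/n) correction term
        assert -1 / 19 < gfst <= 0.0
        assert pw[0, 1] == pytest.approx(gfst, abs=1e-12)

    def test_fixed_difference_is_one(self):
        a = np.full((10, 2, 2), 10, dtype=np.int16)
        b = np.full((10, 2, 2), 14, dtype=np.int16)
        _, gfst, _ = wc_fstats(make_dataset([a, b]))
        assert gfst == pytest.approx(1.0)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(6)
        pops = [
            hwe_population(rng, {10: 0.7, 12: 0.2, 15: 0.1}, 14, 4),
            hwe_population(rng, {10: 0.3, 12: 0.5, 16: 0.2}, 11, 4),
            hwe_population(rng, {10: 0.1, 12: 0.1, 15: 0.5, 16: 0.3}, 17, 4),
        ]
        ds = make_dataset(pops)
        _, gfst, _ = wc_fstats(ds)
        assert gfst == pytest.approx(brute_force_wc_fst(ds), abs=1e-10)


class TestNullAlleleEM:
    def test_hwe_data_without_nulls(self):
        rng = np.random.default_rng(7)
        block = hwe_population(rng, {10: 0.6, 12: 0.4}, 5000, 1)
        # enforce exact HWE genotype counts: use expected counts directly
        n = 5000
        counts = {(10, 10): 0.36, (10, 12): 0.48, (12, 12): 0.16}
        rows = []
        for (a1, a2), f in counts.items():
            rows += [[(a1, a2)]] * int(round(f * n))
        block = np.array(rows, dtype=np.int16)
        est = null_allele_em(make_dataset([block]))
        assert est.null_freq[0, 0] < 1e-6

    def test_recovers_simulated_null_frequency(self):
        rng = np.random.default_rng(8)
        r_true = 0.2
        n = 500
        freqs = {10: 0.3 * (1 - r_true), 12: 0.45 * (1 - r_true),
                 14: 0.25 * (1 - r_true), 0: r_true}
        alleles = np.array(sorted(freqs))
        p = np.array([freqs[a] for a in alleles])
        raw = rng.choice(alleles, size=(n, 1, 2), p=p).astype(np.int16)
        obs = raw.copy()
        # null homozygote -> blank; null heterozygote -> apparent homozygote
        for i in range(n):
            a1, a2 = raw[i, 0]
            if a1 == 0 and a2 == 0:
                obs[i, 0] = (MISSING, MISSING)
            elif a1 == 0:
                obs[i, 0] = (a2, a2)
            elif a2 == 0:
                obs[i, 0] = (a1, a1)
        est = null_allele_em(make_dataset([obs]))
        assert est.null_freq[0, 0] == pytest.approx(r_true, abs=0.03)

    def test_all_blank_locus(self):
        block = np.full((6, 1, 2), MISSING, dtype=np.int16)
        block2 = np.full((6, 1, 2), 10, dtype=np.int16)
        ds = make_dataset([np.concatenate([block, block2], axis=1)])
        est = null_allele_em(ds)
        assert est.null_freq[0, 0] == 1.0
        assert any("blank" in w for w in est.warnings)


class TestEnaFst:
    def test_zero_nulls_reduce_to_uncorrected_exactly(self, paper_dataset):
        _, gfst, pw = wc_fstats(paper_dataset)
        rep = fst_ena(
            paper_dataset,
            np.zeros((paper_dataset.n_populations, paper_dataset.n_loci)),
            n_boot=0,
        )
        assert rep.global_fst == gfst
        np.testing.assert_array_equal(
            np.nan_to_num(rep.pairwise_fst), np.nan_to_num(pw)
        )

    def test_bootstrap_ci_brackets_estimate(self, paper_dataset):
        rep = fst_ena(paper_dataset, None, n_boot=300, seed=4)
        lo, hi = rep.global_ci
        assert lo <= rep.global_fst <= hi

    def test_correction_reduces_null_bias(self):
        """The null is a segregating allele hidden from observation (the
        biological mechanism: one allelic variant fails to amplify, and its
        frequency drifts apart between populations). Hiding it inflates raw
        F_ST; the ENA estimate must land closer to the full-data F_ST in at
        least 80 % of replicates."""
        rng = np.random.default_rng(9)
        wins = 0
        reps = 60
        n, nl, k = 50, 9, 8
        null_mean = 0.15
        for _ in range(reps):
            pops = []
            for _ in range(2):
                blocks = []
                for _ in range(nl):
                    base = rng.dirichlet(np.ones(k) * 2.0)
                    f = 0.8 * base + 0.2 * rng.dirichlet(np.ones(k))
                    f[0] = null_mean * rng.uniform(0.5, 1.5)
                    f = f / f.sum()
                    blocks.append(rng.choice(np.arange(5, 5 + k), size=(n, 2), p=f))
                pops.append(np.stack(blocks, axis=1).astype(np.int16))
            A, B = pops
            clean = make_dataset([A, B])
            _, fst_true, _ = wc_fstats(clean)

            def hide(block):
                out = block.copy()
                isnull = block == 5  # allele 5 is the null variant
                one1 = isnull[..., 0] & ~isnull[..., 1]
                one2 = isnull[..., 1] & ~isnull[..., 0]
                both = isnull.all(axis=2)
                out[one1, 0] = out[one1, 1]
                out[one2, 1] = out[one2, 0]
                out[both] = MISSING
                return out

            noisy = make_dataset([hide(A), hide(B)])
            _, fst_raw, _ = wc_fstats(noisy)
            est = null_allele_em(noisy)
            fst_corr = fst_ena(noisy, est, n_boot=0).global_fst
            if abs(fst_corr - fst_true) < abs(fst_raw - fst_true):
                wins += 1
        assert wins / reps >= 0.8


class TestGroupPermutation:
    @staticmethod
    def _grouped_dataset(rng, n_per_group=6, ne_gap=False):
        from msatabc import DemographicEvent, LocusSpec
        from msatabc.coalescent import simulate_dataset
        from msatabc.scenarios import DemographicScenario, Lineage, ParameterDraw

        labels = [f"P{i}" for i in range(2 * n_per_group)]
        ne = {
            lab: (150.0 if ne_gap and i >= n_per_group else 4000.0)
            for i, lab in enumerate(labels)
        }
        sc = DemographicScenario(
            id=1,
            lineages=[Lineage(lab, f"Ne_{lab}", 12) for lab in labels],
            events=[
                DemographicEvent(
                    kind="split",
                    time_param="t",
                    derived=tuple(labels[1:]),
                    ancestor=labels[0],
                )
            ],
        )
        values = {f"Ne_{lab}": v for lab, v in ne.items()}
        values.update(t=8000.0, mu_mean=5e-4, p_mean=0.0)
        d = ParameterDraw(1, values, np.full(5, 5e-4), np.zeros(5))
        loci = [LocusSpec(f"L{i}", 20, 40) for i in range(5)]
        return simulate_dataset(sc, d, loci, rng)

    def test_p_floor(self, rng):
        ds = self._grouped_dataset(rng, n_per_group=2)
        _, p = group_permutation_test(ds, {"x": [0, 1], "y": [2, 3]}, "He", n_perm=9)
        assert p >= 1 / 10

    def test_identical_groups_not_significant(self, rng):
        ds = self._grouped_dataset(rng, ne_gap=False)
        _, p = group_permutation_test(
            ds, {"x": list(range(6)), "y": list(range(6, 12))}, "He",
            n_perm=199, seed=3,
        )
        assert p > 0.05

    def test_power_under_ne_gap(self):
        """Groups simulated with strongly different Ne separate on He."""
        rng = np.random.default_rng(12)
        ds = self._grouped_dataset(rng, ne_gap=True)
        obs, p = group_permutation_test(
            ds, {"big": list(range(6)), "small": list(range(6, 12))}, "He",
            n_perm=999, seed=3,
        )
        assert obs > 0
        assert p <= 0.01

    def test_pvalues_valid_under_null(self):
        """Label shuffling of a fixed dataset gives sub-uniform p-values."""
        rng = np.random.default_rng(13)
        ds = self._grouped_dataset(rng, n_per_group=2)
        outer = 200
        alpha = 0.2
        hits = 0
        for _ in range(outer):
            perm = rng.permutation(4)
            groups = {"x": list(perm[:2]), "y": list(perm[2:])}
            _, p = group_permutation_test(ds, groups, "He", n_perm=49,
                                          seed=int(rng.integers(2**31)))
            if p <= alpha:
                hits += 1
        assert hits / outer <= alpha + 2 / np.sqrt(outer)

    def test_bad_grouping_rejected(self, paper_dataset):
        with pytest.raises(ValueError):
            group_permutation_test(paper_dataset, {"x": [0, 1]}, "He")
        with pytest.raises(ValueError):
            group_permutation_test(paper_dataset, {"x": [0], "y": []}, "He")
        with pytest.raises(ValueError):
            group_permutation_test(paper_dataset, {"x": [0], "y": [1]}, "Het")


class TestPairwiseFstPermutation:
    def test_diverged_pair_significant(self):
        rng = np.random.default_rng(21)
        a = hwe_population(rng, {10: 0.9, 12: 0.1}, 40, 4)
        b = hwe_population(rng, {10: 0.1, 12: 0.9}, 40, 4)
        obs, p = pairwise_fst_test(make_dataset([a, b]), 0, 1, n_perm=199, seed=1)
        assert obs > 0.3
        assert p <= 1 / 100

    def test_same_source_not_significant(self):
        rng = np.random.default_rng(22)
        a = hwe_population(rng, {10: 0.5, 12: 0.5}, 30, 4)
        b = hwe_population(rng, {10: 0.5, 12: 0.5}, 30, 4)
        _, p = pairwise_fst_test(make_dataset([a, b]), 0, 1, n_perm=199, seed=1)
        assert p > 0.05

    def test_identical_indices_rejected(self, paper_dataset):
        with pytest.raises(ValueError):
            pairwise_fst_test(paper_dataset, 2, 2)
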