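import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from echinopop.diversity import (
    diversity_table,
    fis_bootstrap,
    haplotype_diversity,
    heterozygosities,
    hwe_permutation_test,
    multilocus_fis,
    nucleotide_diversity,
    rarefied_richness,
)
from echinopop.errors import UndefinedStatisticError
from echinopop.io import SequencePanel
from tests.conftest import make_genotype_panel


def panel_from(seqs):
    ids = [f"s{i}" for i in range(len(seqs))]
    return SequencePanel(ids, list(seqs), {i: "P" for i in ids}, {"P": "r"})


class TestHaplotypeDiversity:
    def test_two_singletons(self):
        assert haplotype_diversity([1, 1])[0] == pytest.approx(1.0)

    def test_monomorphic(self):
        assert haplotype_diversity([5])[0] == 0.0

    def test_livorno_like_split(self):
        # 11/12 split of n=23 gives Nei h = 0.5217
        h, sd = haplotype_diversity([11, 12])
        assert h == pytest.approx(0.5217, abs=1e-4)
        assert sd > 0

    def test_undefined_below_two(self):
        with pytest.raises(UndefinedStatisticError):
            haplotype_diversity([1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 30), min_size=2, max_size=8), st.integers(0, 10**6))
    def test_relabelling_invariance(self, counts, seed):
        perm = np.random.default_rng(seed).permutation(len(counts))
        h1, s1 = haplotype_diversity(counts)
        h2, s2 = haplotype_diversity(np.asarray(counts)[perm])
        assert h1 == pytest.approx(h2) and s1 == pytest.approx(s2)


class TestNucleotideDiversity:
    def test_identical_zero(self):
        assert nucleotide_diversity(panel_from(["AAAA"] * 3))[0] == 0.0

    def test_hand_enumeration(self):
        # pairs: (AAA,AAT)=1, (AAA,ATT)=2, (AAT,ATT)=1 -> 4/3 pairs /3 sites
        pi, _ = nucleotide_diversity(panel_from(["AAA", "AAT", "ATT"]))
        assert pi == pytest.approx(4.0 / 9.0)

    def test_matches_bruteforce_oracle(self, study_dataset):
        seq_panel, _, _, _ = study_dataset
        sub = seq_panel.subset(populations=seq_panel.populations()[:2])
        pi, _ = nucleotide_diversity(sub)
        # brute force all pairs
        vals = []
        seqs = sub.sequences
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                vals.append(d / sub.L)
        assert pi == pytest.approx(np.mean(vals))

    def test_reorder_invariance(self):
        seqs = ["AACT", "AAAT", "CACT", "AACT"]
        pi1 = nucleotide_diversity(panel_from(seqs))[0]
        pi2 = nucleotide_diversity(panel_from(seqs[::-1]))[0]
        assert pi1 == pytest.approx(pi2)


class TestRarefaction:
    def test_monomorphic_is_one(self):
        assert rarefied_richness([8], 8) == pytest.approx(1.0)

    def test_exact_hypergeometric_value(self):
        assert rarefied_richness([11, 12], 8) == pytest.approx(1.99865, abs=1e-5)

    def test_full_size_equals_richness(self):
        counts = [5, 3, 2, 1]
        assert rarefied_richness(counts, sum(counts)) == pytest.approx(4.0)

    def test_monte_carlo_agreement(self):
        counts = np.array([9, 5, 4, 2, 1, 1])
        g = 8
        exact = rarefied_richness(counts, g)
        rng = np.random.default_rng(1)
        pool = np.repeat(np.arange(len(counts)), counts)
        draws = np.array([
            len(np.unique(rng.choice(pool, size=g, replace=False)))
            for _ in range(100_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - exact) < 3 * se

    def test_monotone_in_g(self):
        counts = [7, 4, 2, 1]
        vals = [rarefied_richness(counts, g) for g in range(1, sum(counts) + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_g_too_large_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            rarefied_richness([3, 2], 6)


class TestHeterozygosity:
    def test_all_heterozygous(self, hetero_panel):
        ho, he = heterozygosities(hetero_panel, "P", "L0")
        assert ho == 1.0
        # two equifrequent alleles: He = (2n/(2n-1)) * 0.5 = 12/11 * 0.5
        assert he == pytest.approx(12.0 / 11.0 * 0.5)

    def test_two_individuals_formula(self):
        panel = make_genotype_panel({"P": [[(100, 102)], [(100, 102)]]})
        ho, he = heterozygosities(panel, "P", "L0")
        assert ho == 1.0 and he == pytest.approx(4.0 / 3.0 * 0.5)

    def test_monomorphic_zero(self):
        panel = make_genotype_panel({"P": [[(100, 100)], [(100, 100)]]})
        assert heterozygosities(panel, "P", "L0") == (0.0, 0.0)

    def test_hw_simulated_ho_near_he(self):
        rng = np.random.default_rng(3)
        n = 4000
        genos = [[tuple(100 + 2 * rng.integers(0, 4, size=2))] for _ in range(n)]
        panel = make_genotype_panel({"P": genos})
        ho, he = heterozygosities(panel, "P", "L0")
        assert abs(ho - he) < 3 * np.sqrt(he * (1 - he) / n)


class TestFis:
    def test_equilibrium_fis_zero_ci_spans(self):
        rng = np.random.default_rng(5)
        genos = [
            [tuple(100 + 2 * rng.integers(0, 5, size=2)) for _ in range(6)]
            for _ in range(200)
        ]
        panel = make_genotype_panel({"P": genos})
        res = fis_bootstrap(panel, "P", seed=0)
        assert res.ci_low < 0 < res.ci_high
        assert abs(res.fis) < 0.08

    def test_all_homozygous_fis_one(self):
        # two equifrequent alleles per locus, no heterozygotes
        genos = [[(100, 100), (200, 200)], [(102, 102), (204, 204)]] * 5
        panel = make_genotype_panel({"P": genos})
        assert multilocus_fis(panel, "P") == pytest.approx(1.0)

    def test_bootstrap_reproducible(self, study_dataset):
        _, gen_panel, _, _ = study_dataset
        pop = gen_panel.populations()[0]
        r1 = fis_bootstrap(gen_panel, pop, seed=42)
        r2 = fis_bootstrap(gen_panel, pop, seed=42)
        assert (r1.fis, r1.ci_low, r1.ci_high) == (r2.fis, r2.ci_low, r2.ci_high)


class TestHwePermutation:
    def test_monomorphic_skipped(self):
        panel = make_genotype_panel({"P": [[(100, 100)]] * 5})
        with pytest.raises(UndefinedStatisticError):
            hwe_permutation_test(panel, "P")

    def test_all_homozygote_panel_significant(self):
        genos = [[(100, 100), (200, 200)], [(102, 102), (204, 204)]] * 10
        panel = make_genotype_panel({"P": genos})
        p = hwe_permutation_test(panel, "P", n_perm=199, seed=1)
        assert p < 0.05

    def test_null_p_approximately_uniform(self):
        # HW-simulated panels: p-values should not deviate from uniform
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            genos = [
                [tuple(100 + 2 * rng.integers(0, 6, size=2)) for _ in range(4)]
                for _ in range(25)
            ]
            panel = make_genotype_panel({"P": genos})
            try:
                ps.append(hwe_permutation_test(
                    panel, "P", n_perm=199, seed=int(rng.integers(1, 2**31))
                ))
            except UndefinedStatisticError:
                continue
        assert kstest(ps, "uniform").pvalue > 0.01


class TestDiversityTable:
    def test_row_structure(self, study_dataset):
        seq_panel, gen_panel, _, _ = study_dataset
        df = diversity_table(seq_panel, gen_panel, n_boot=20, n_perm=49, seed=0)
        pops = seq_panel.populations()
        regions = set(seq_panel.region_of.values())
        assert set(pops) <= set(df.index)
        assert regions <= set(df.index)
        assert "Total" in df.index
        row = df.loc["Total"]
        assert row["N_seq"] == seq_panel.n
        assert 0 <= row["haplotype_diversity"] <= 1
        assert row["pi"] >= 0
        assert 0 <= row["Ho"] <= 1 and 0 <= row["He"] <= 1
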