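from itertools import product

import numpy as np
import pytest

from echinopop.demography import (
    bottleneck_test,
    critical_m,
    dating_table,
    expansion_expected,
    fit_expansion,
    growth_trajectory,
    m_ratio,
    m_ratio_with_critical,
    migrants_per_generation,
    mismatch_observed,
    tau_to_generations,
    theta_to_nf,
    wilcoxon_signed_rank,
)
from echinopop.errors import UndefinedStatisticError, ValidationError
from echinopop.io import SequencePanel
from tests.conftest import make_genotype_panel


def panel_from(seqs):
    ids = [f"s{i}" for i in range(len(seqs))]
    return SequencePanel(ids, list(seqs), {i: "P" for i in ids}, {"P": "r"})


class TestMismatchObserved:
    def test_identical_all_mass_at_zero(self):
        h = mismatch_observed(panel_from(["AAAA"] * 4))
        assert h[0] == 6 and h.sum() == 6

    def test_pair_enumeration(self):
        h = mismatch_observed(panel_from(["AAA", "AAT", "ATT"]))
        assert h.tolist() == [0, 2, 1]

    def test_total_is_n_choose_2(self, study_dataset):
        seq_panel, _, _, _ = study_dataset
        sub = seq_panel.subset(populations=seq_panel.populations()[:3])
        n = sub.n
        assert mismatch_observed(sub).sum() == n * (n - 1) // 2


class TestExpansionExpected:
    def test_geometric_equilibrium(self):
        F = expansion_expected(0.0, 1.0, 1.0, 8)
        np.testing.assert_allclose(F, [0.5 ** (i + 1) for i in range(9)])

    def test_normalisation(self):
        for tau, th0, th1 in product([0.5, 4, 20], [0, 0.3, 2], [1, 50]):
            F = expansion_expected(tau, th0, th1, 3000)
            assert abs(F.sum() - 1) < 1e-6

    def test_equilibrium_recovered_any_theta(self):
        # tau=0 equals closed-form equilibrium for any theta
        for theta in [0.1, 1.7, 42.0]:
            F = expansion_expected(0.0, theta, 12.3, 50)
            i = np.arange(51)
            eq = theta**i / (1 + theta) ** (i + 1)
            assert np.abs(F - eq).max() < 1e-12

    def test_mean_tracks_tau_against_simulation(self):
        # coalescent oracle: pair differences under sudden expansion
        tau, th0 = 6.0, 0.4
        rng = np.random.default_rng(0)
        n = 100_000
        # pair coalescence time: huge theta1 -> no coalescence before tau
        t = tau + rng.exponential(th0, size=n)
        sims = rng.poisson(t)
        F = expansion_expected(tau, th0, 1e9, 200)
        model_mean = float(np.sum(np.arange(201) * F))
        se = sims.std() / np.sqrt(n)
        assert abs(model_mean - sims.mean()) < 3 * se

    def test_mode_near_tau_for_large_tau(self):
        F = expansion_expected(15.0, 0.0, 1e8, 100)
        mean = np.sum(np.arange(101) * F)
        assert abs(mean - 15.0) / 15.0 < 0.05


class TestFitExpansion:
    def test_self_consistency_exact_recovery(self):
        F = expansion_expected(3.0, 0.2, 50.0, 80)
        counts = np.round(F * 1e7).astype(int)
        fit = fit_expansion(counts, i_max=80)
        assert fit.tau == pytest.approx(3.0, abs=1e-3)
        assert fit.theta0 == pytest.approx(0.2, abs=1e-3)
        assert fit.theta1 == pytest.approx(50.0, abs=2e-2)

    def test_degenerate_histogram_flagged(self):
        fit = fit_expansion(np.array([10]))
        assert fit.boundary

    def test_equilibrium_data_low_tau_or_boundary(self):
        rng = np.random.default_rng(5)
        theta = 3.0
        t = rng.exponential(theta, size=3000)
        sims = rng.poisson(t)
        fit = fit_expansion(np.bincount(sims))
        # no expansion signal: tau small or boundary flag
        assert fit.boundary or fit.tau < 1.5


class TestConversions:
    def test_tau_equals_2u_gives_one_generation(self):
        L, rate = 657, 2.3e-8
        u = L * rate
        assert tau_to_generations(2 * u, L, rate) == pytest.approx(1.0)

    def test_direct_formula_value(self):
        assert tau_to_generations(0.42, 657, 2.3e-8) == pytest.approx(13897, abs=1)

    def test_rate_ratio_identity(self):
        t1 = tau_to_generations(1.0, 657, 2.3e-8)
        t2 = tau_to_generations(1.0, 657, 3.6e-8)
        assert t1 / t2 == pytest.approx(3.6 / 2.3)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValidationError):
            tau_to_generations(1.0, 657, 0.0)
        with pytest.raises(ValidationError):
            theta_to_nf(1.0, 657, 0.0)

    def test_dating_table_years(self):
        df = dating_table(0.42, 657, [2.3e-8, 3.6e-8], generation_years=1.0)
        assert df["years"].tolist() == df["generations"].tolist()

    def test_migrants(self):
        assert migrants_per_generation(0.0, 1e-8) == 0.0
        assert migrants_per_generation(1e-8, 1e-8) == pytest.approx(1.0)
        assert migrants_per_generation(2e-8, 1e-8) == pytest.approx(
            2 * migrants_per_generation(1e-8, 1e-8)
        )

    def test_growth_trajectory(self):
        t = np.linspace(0, 5, 50)
        np.testing.assert_allclose(growth_trajectory(2.0, 0.0, t), 2.0)
        G = 1.3
        assert growth_trajectory(2.0, G, [np.log(2) / G])[0] == pytest.approx(1.0)
        vals = growth_trajectory(2.0, G, t)
        assert (np.diff(vals) < 0).all()


class TestWilcoxon:
    def test_matches_sign_enumeration(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.1, 1, size=9)
        res = wilcoxon_signed_rank(d)
        # independent oracle: enumerate all 2^n sign assignments
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        obs = ranks[d > 0].sum()
        n = len(d)
        stats = []
        for mask in range(2**n):
            signs = [(mask >> i) & 1 for i in range(n)]
            stats.append(sum(r for r, s in zip(ranks, signs) if s))
        stats = np.array(stats)
        assert res["p_greater"] == pytest.approx(np.mean(stats >= obs - 1e-12))
        assert res["p_less"] == pytest.approx(np.mean(stats <= obs + 1e-12))

    def test_all_ties_p_one(self):
        res = wilcoxon_signed_rank(np.zeros(6))
        assert res["p_two"] == 1.0 and res["zeros_dropped"] == 6

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1, size=24)
        exact = wilcoxon_signed_rank(d, exact_max_n=25)
        approx = wilcoxon_signed_rank(d, exact_max_n=10)
        assert approx["p_two"] == pytest.approx(exact["p_two"], abs=0.02)


class TestBottleneck:
    def test_monomorphic_locus_excluded(self):
        genos = {"P": [
            [(100, 100), (100, 102), (104, 110), (100, 108)] for _ in range(8)
        ]}
        panel = make_genotype_panel(genos)
        res = bottleneck_test(panel, "P", model="iam", n_reps=100, seed=1)
        per = res.per_locus.set_index("locus")
        assert not per.loc["L0", "informative"]

    def test_too_few_loci_flagged(self):
        panel = make_genotype_panel(
            {"P": [[(100, 102)], [(104, 100)], [(102, 102)], [(100, 104)]]}
        )
        res = bottleneck_test(panel, "P", model="smm", n_reps=60, seed=0)
        assert res.status == "too-few-informative-loci"

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        genos = {"P": [
            [tuple(100 + 2 * rng.integers(0, 5, size=2)) for _ in range(5)]
            for _ in range(12)
        ]}
        panel = make_genotype_panel(genos)
        r1 = bottleneck_test(panel, "P", model="smm", n_reps=80, seed=7)
        r2 = bottleneck_test(panel, "P", model="smm", n_reps=80, seed=7)
        assert r1.p_two == r2.p_two
        assert (r1.per_locus["Heq_mean"] == r2.per_locus["Heq_mean"]).all()


class TestMRatio:
    def test_no_gaps_is_one(self):
        panel = make_genotype_panel(
            {"P": [[(100, 102)], [(104, 100)], [(102, 104)]]}, motif=2
        )
        res = m_ratio(panel, "P")
        assert res.per_locus["M"].iloc[0] == pytest.approx(1.0)

    def test_one_missing_intermediate(self):
        panel = make_genotype_panel(
            {"P": [[(100, 104)], [(100, 100)]]}, motif=2
        )
        assert m_ratio(panel, "P").per_locus["M"].iloc[0] == pytest.approx(2 / 3)

    def test_direct_arithmetic(self):
        panel = make_genotype_panel(
            {"P": [[(100, 102)], [(104, 110)], [(100, 104)]]}, motif=2
        )
        assert m_ratio(panel, "P").per_locus["M"].iloc[0] == pytest.approx(4 / 6)

    def test_bad_binning_rejected(self):
        panel = make_genotype_panel({"P": [[(100, 103)]]}, motif=2)
        with pytest.raises(ValidationError):
            m_ratio(panel, "P")

    def test_critical_m_pure_smm_tiny_theta(self):
        mc = critical_m(40, theta=0.1, ps=1.0, n_sims=400, seed=3)
        assert mc > 0.8

    def test_critical_m_quantile_monotone(self):
        mc5 = critical_m(40, theta=5.0, n_sims=400, seed=3, percentile=5.0)
        mc1 = critical_m(40, theta=5.0, n_sims=400, seed=3, percentile=1.0)
        assert mc1 <= mc5

    def test_critical_m_deterministic(self):
        a = critical_m(30, theta=2.0, n_sims=300, seed=11)
        b = critical_m(30, theta=2.0, n_sims=300, seed=11)
        assert a == b

    def test_with_critical_wiring(self, study_dataset):
        _, gen_panel, _, _ = study_dataset
        pop = gen_panel.populations()[0]
        res = m_ratio_with_critical(gen_panel, pop, theta=5.0, n_sims=200, seed=2)
        assert 0 < res.mean_m <= max(res.per_locus["k"])
        assert 0 < res.mc <= 1
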