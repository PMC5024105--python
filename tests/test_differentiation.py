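from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echinopop.differentiation import (
    amova,
    bh_adjust,
    evanno_delta_k,
    jost_d,
    jost_d_from_counts,
    mantel_ibd,
    matrix_correlation,
    nested_amova_components,
    nmds,
    pairwise_fst_wc,
    pairwise_phist,
    phi_st_two_pop,
    sequence_sq_distances,
    wc_theta,
)
from echinopop.errors import ValidationError
from echinopop.io import SequencePanel
from echinopop.simulate import SimulationConfig, simulate_sequences
from tests.conftest import make_genotype_panel


def panel_from(seqs, pops, regions=None):
    ids = [f"s{i}" for i in range(len(seqs))]
    region_of = regions or {p: "r" for p in set(pops)}
    return SequencePanel(ids, list(seqs), dict(zip(ids, pops)), region_of)


class TestPhiST:
    def test_fixed_difference_is_one(self):
        panel = panel_from(["AAA", "AAA", "AAT", "AAT"], ["P1", "P1", "P2", "P2"])
        m = pairwise_phist(panel, n_perm=20, seed=0)
        assert m.values.loc["P1", "P2"] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # {X,X,Y} vs {Y,Y,Y}: SSD_T=8/6, SSD_W=2/3, sigma_a=sigma_w=1/6
        panel = panel_from(
            ["AAA", "AAA", "AAT", "AAT", "AAT", "AAT"],
            ["P1", "P1", "P1", "P2", "P2", "P2"],
        )
        d2 = sequence_sq_distances(panel)
        assert phi_st_two_pop(d2, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)

    def test_null_panmictic_mean_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(60):
            cfg = SimulationConfig(
                n_demes=1, samples_per_deme=12, theta=0.01, sequence_length=200,
                mutation_model="finite_sites_jc", seed=int(rng.integers(1, 2**31)),
            )
            panel, _ = simulate_sequences(cfg)
            pops = ["A"] * 6 + ["B"] * 6
            panel = SequencePanel(
                panel.sample_ids, panel.sequences,
                dict(zip(panel.sample_ids, pops)), {"A": "r", "B": "r"},
            )
            d2 = sequence_sq_distances(panel)
            v = phi_st_two_pop(d2, np.array([0] * 6 + [1] * 6))
            if np.isfinite(v):
                vals.append(v)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 0.02


class TestWcFst:
    def test_fixed_difference(self):
        g1 = np.array([[1, 1], [1, 1]])
        g2 = np.array([[2, 2], [2, 2]])
        assert wc_theta([g1, g2]) == pytest.approx(1.0)

    def test_hand_zero_case(self):
        g1 = np.array([[1, 1], [1, 1]])
        g2 = np.array([[1, 1], [2, 2]])
        assert wc_theta([g1, g2]) == pytest.approx(0.0)

    def test_identical_freqs_average_nonpositive(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(200):
            pool = rng.integers(1, 5, size=(40, 2))
            vals.append(wc_theta([pool[:20], pool[20:]]))
        vals = [v for v in vals if np.isfinite(v)]
        assert np.mean(vals) <= 0.01

    def test_pairwise_matrix_invariants(self):
        panel = make_genotype_panel({
            "P1": [[(100, 100)], [(100, 102)], [(102, 102)]],
            "P2": [[(104, 104)], [(104, 104)], [(104, 106)]],
        })
        m = pairwise_fst_wc(panel, n_perm=30, seed=0)
        v = m.values.to_numpy()
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
        assert (m.p_adj.to_numpy() >= m.p_raw.to_numpy() - 1e-12).all()


class TestJostD:
    def test_fixed_difference_is_one(self):
        counts = np.array([[4, 0], [0, 4]])
        assert jost_d_from_counts(counts, unbiased=False) == pytest.approx(1.0)

    def test_identical_pops_zero(self):
        counts = np.array([[3, 3], [3, 3]])
        assert jost_d_from_counts(counts, unbiased=False) == 0.0
        raw = jost_d_from_counts(counts, unbiased=True, clamp=False)
        assert raw <= 0.0

    def test_plugin_hand_value(self):
        # p1=(0.5,0.5), p2=(1,0): HS=0.25, HT=0.375, D = 1/3
        counts = np.array([[5, 5], [10, 0]])
        assert jost_d_from_counts(counts, unbiased=False) == pytest.approx(1 / 3)

    def test_sequence_pairwise(self):
        panel = panel_from(["AAA", "AAA", "TTT", "TTT"], ["P1", "P1", "P2", "P2"])
        m = jost_d(panel, "sequence", n_perm=30, seed=0)
        assert m.values.loc["P1", "P2"] > 0.9


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_geq_raw_and_order_preserving(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestAmova:
    def test_two_groups_of_one_pop_reproduces_toy(self):
        panel = panel_from(
            ["AAA", "AAA", "AAT", "AAT", "AAT", "AAT"],
            ["P1", "P1", "P1", "P2", "P2", "P2"],
            regions={"P1": "G1", "P2": "G2"},
        )
        res = amova(panel, "sequence", n_perm=0)
        assert res.indices["Phi_CT"] == pytest.approx(0.5)
        pct = res.table.set_index("source")["percent_variation"]
        assert pct["Among groups"] == pytest.approx(50.0, abs=1e-6)

    def test_degenerate_identical_sequences(self):
        panel = panel_from(["AAA"] * 6, ["P1"] * 3 + ["P2"] * 3,
                           regions={"P1": "G1", "P2": "G2"})
        res = amova(panel, "sequence", n_perm=0)
        assert res.status == "degenerate"

    @pytest.mark.parametrize("seed", range(6))
    def test_identity_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 30))
        pts = rng.normal(size=(n, 2))
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        n_pops, n_grp = int(rng.integers(4, 7)), int(rng.integers(2, 4))
        pops = rng.integers(0, n_pops, size=n)
        pops[:n_pops] = np.arange(n_pops)
        grp_of = rng.integers(0, n_grp, size=n_pops)
        grp_of[:n_grp] = np.arange(n_grp)
        _, _, s2 = nested_amova_components(d2, [grp_of[pops], pops])
        sa, sb, sw = s2
        lhs = (1 - sa / (sa + sb + sw)) * (1 - sb / (sb + sw))
        rhs = 1 - (sa + sb) / (sa + sb + sw)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_pairwise_equals_restricted_amova(self, study_dataset):
        seq_panel, _, _, _ = study_dataset
        pops = seq_panel.populations()[:2]
        sub = seq_panel.subset(populations=pops)
        m = pairwise_phist(sub, n_perm=0 + 5, seed=0)
        d2 = sequence_sq_distances(sub)
        assign = np.array(
            [0 if sub.population_of[s] == pops[0] else 1 for s in sub.sample_ids]
        )
        assert m.values.loc[pops[0], pops[1]] == pytest.approx(
            phi_st_two_pop(d2, assign)
        )

    def test_diploid_df_and_identity(self, study_dataset):
        _, gen_panel, _, _ = study_dataset
        sub = gen_panel.subset(gen_panel.populations()[:6])
        res = amova(sub, "microsatellite", n_perm=0)
        assert res.table["df"].sum() == 2 * sub.n - 1
        sa, sb, sc, sd = res.table["variance_component"]
        lhs = (1 - res.indices["F_CT"]) * (1 - res.indices["F_SC"])
        rhs = 1 - res.indices["F_ST"]
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_haploid_df_sum(self, study_dataset):
        seq_panel, _, _, _ = study_dataset
        res = amova(seq_panel, "sequence", n_perm=0)
        assert res.table["df"].sum() == seq_panel.n - 1

    def test_island_power_groups_are_demes(self):
        # each deme split into three pseudo-populations; groups = true demes
        # (4 demes x 3 pops gives the group permutation enough granularity)
        rng = np.random.default_rng(12)
        hits = total = 0
        for _ in range(15):
            cfg = SimulationConfig(
                n_demes=4, samples_per_deme=12, theta=0.02, sequence_length=300,
                migration=2.0,  # 2Nm=2 -> FST ~ 0.2 under the island model
                mutation_model="finite_sites_jc",
                seed=int(rng.integers(1, 2**31)),
            )
            panel, _ = simulate_sequences(cfg)
            pops, regions = {}, {}
            for d in range(4):
                members = panel.samples_of(f"pop_{d}")
                for i, s in enumerate(members):
                    pops[s] = f"d{d}_{i % 3}"
                for j in range(3):
                    regions[f"d{d}_{j}"] = f"deme{d}"
            panel = SequencePanel(panel.sample_ids, panel.sequences, pops, regions)
            res = amova(panel, "sequence", n_perm=99, seed=int(rng.integers(1, 2**31)))
            if "Phi_CT" in res.p_values:
                total += 1
                hits += res.p_values["Phi_CT"] <= 0.05
        assert total >= 12 and hits / total >= 0.8


class TestMatrixCorrelation:
    def test_self_correlation_one(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert matrix_correlation(m, m, n_perm=10, seed=0).r == pytest.approx(1.0)

    def test_affine_invariance(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert matrix_correlation(m, 2.5 * m + 1, n_perm=10, seed=0).r == pytest.approx(1.0)

    def test_exhaustive_enumeration_four_items(self):
        rng = np.random.default_rng(4)
        a = rng.random((4, 4)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = rng.random((4, 4)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        res = matrix_correlation(a, b, exhaustive=True)
        # independent enumeration of all 4! = 24 relabelings
        def r_of(perm):
            bp = b[np.ix_(perm, perm)]
            iu = np.triu_indices(4, 1)
            return np.corrcoef(a[iu], bp[iu])[0, 1]
        obs = r_of(list(range(4)))
        count = sum(
            r_of(list(p)) >= obs - 1e-12 for p in permutations(range(4))
        )
        assert res.p == pytest.approx(count / 24)


class TestMantel:
    def test_self_distance_r_one(self):
        d = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        res = mantel_ibd(d, d, n_perm=50, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_single_stratum_reduces_to_standard(self):
        rng = np.random.default_rng(7)
        a = rng.random((6, 6)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = rng.random((6, 6)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        pops = [f"p{i}" for i in range(6)]
        std = mantel_ibd(a, b, n_perm=300, seed=9)
        strat = mantel_ibd(a, b, n_perm=300, seed=9,
                           strata={p: "one" for p in pops},
                           populations=pops)
        assert std.r == strat.r
        assert std.p == strat.p  # same seed, same permutations

    def test_matches_scikit_bio_mantel(self):
        # independent implementation cross-check (standard path only;
        # skbio has no stratified variant)
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(17)
        pts = rng.normal(size=(8, 2))
        a = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        b = a + rng.normal(0, 0.3, size=a.shape)
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        b = np.abs(b)
        ours = mantel_ibd(a, b, n_perm=999, seed=5)
        ref_r, ref_p, _ = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(float(ref_r), abs=1e-12)
        assert ours.p == pytest.approx(float(ref_p), abs=0.05)

    def test_all_singleton_strata_rejected(self):
        d = np.abs(np.subtract.outer(np.arange(3.0), np.arange(3.0)))
        with pytest.raises(ValidationError):
            mantel_ibd(d, d, strata={"a": "x", "b": "y", "c": "z"},
                       populations=["a", "b", "c"], n_perm=10)


class TestNmds:
    def test_planar_points_low_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        _, stress = nmds(d, seed=3)
        assert stress < 0.01

    def test_equilateral_three_items(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, _ = nmds(d, seed=1)
        c = coords.to_numpy()
        dists = np.linalg.norm(c[:, None] - c[None], axis=-1)
        off = dists[np.triu_indices(3, 1)]
        assert np.ptp(off) < 1e-6

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        c1, s1 = nmds(d, seed=11)
        c2, s2 = nmds(d, seed=11)
        assert s1 == s2
        pd.testing.assert_frame_equal(c1, c2)


class TestEvanno:
    def test_linear_lnl_gives_zero(self):
        rows = [{"K": k, "run": r, "lnL": -100.0 + 10 * k}
                for k in range(1, 6) for r in range(3)]
        out = evanno_delta_k(pd.DataFrame(rows))
        # zero second difference, but sd is 0 too -> flagged
        assert out["flagged_zero_sd"].all()

    def test_direct_formula(self):
        # replicates mean +- sqrt(2) have sd 2; DeltaK(2) = |-78+160-100|/2 = 9
        df = pd.DataFrame([
            {"K": 1, "run": 0, "lnL": -100 - np.sqrt(2)},
            {"K": 1, "run": 1, "lnL": -100 + np.sqrt(2)},
            {"K": 2, "run": 0, "lnL": -80 - np.sqrt(2)},
            {"K": 2, "run": 1, "lnL": -80 + np.sqrt(2)},
            {"K": 3, "run": 0, "lnL": -78 - np.sqrt(2)},
            {"K": 3, "run": 1, "lnL": -78 + np.sqrt(2)},
        ])
        out = evanno_delta_k(df)
        assert out.loc[out["K"] == 2, "delta_K"].iloc[0] == pytest.approx(9.0)
        assert out.attrs["best_K"] == 2

    def test_replicate_permutation_invariance(self):
        rng = np.random.default_rng(0)
        rows = [{"K": k, "run": r, "lnL": float(-200 + 5 * k + rng.normal())}
                for k in range(1, 6) for r in range(4)]
        df = pd.DataFrame(rows)
        out1 = evanno_delta_k(df)
        out2 = evanno_delta_k(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(out1, out2)
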