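"""Population structure: hierarchical AMOVA and Phi/F statistics, pairwise
differentiation (PhiST, Weir-Cockerham FST, Jost's D) with permutation
p-values and Benjamini-Hochberg correction, Mantel / stratified-Mantel
isolation by distance, non-metric MDS ordination, and Evanno's DeltaK.

The AMOVA engine is a general method-of-moments nested random-effects
decomposition on a matrix of squared inter-unit distances, with Searle-type
coefficients for unbalanced designs.  It serves both the haploid 3-level
design (groups / populations / sequences) and the diploid 4-level design
(groups / populations / individuals / gene copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from echinopop.errors import UndefinedStatisticError, ValidationError
from echinopop.io import MISSING, GenotypePanel, SequencePanel

# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

_MISSING_CHARS = frozenset("-N")


def sequence_sq_distances(panel: SequencePanel) -> np.ndarray:
    """Squared molecular distances = pairwise difference counts
    (pairwise-complete over gap/N sites)."""
    mat = panel.matrix()
    n = mat.shape[0]
    ok = ~np.isin(mat, ["-", "N"])
    d = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok
        diff = (mat[i] != mat) & both
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return d


def genotype_copy_sq_distances(panel: GenotypePanel) -> np.ndarray:
    """Squared distances between gene copies: number of loci with different
    alleles, summed complete-case per locus.  Copy 2i and 2i+1 belong to
    individual i."""
    n, L, _ = panel.alleles.shape
    copies = panel.alleles.transpose(0, 2, 1).reshape(2 * n, L)
    present = copies != MISSING
    d = np.zeros((2 * n, 2 * n))
    for i in range(2 * n):
        both = present[i] & present
        diff = (copies[i] != copies) & both
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# general nested AMOVA engine
# ---------------------------------------------------------------------------

def _within_ssd(d2: np.ndarray, assign: np.ndarray) -> float:
    """Sum over clusters c of (1/n_c) * sum_{i<j in c} d2_ij."""
    total = 0.0
    for cl in np.unique(assign):
        idx = np.flatnonzero(assign == cl)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def nested_amova_components(d2: np.ndarray, levels: list[np.ndarray]):
    """Variance components for a fully nested design.

    ``levels`` are cluster assignments per unit, ordered top (coarsest) to
    bottom (finest); the unit level is implicit.  Returns (df, ssd, sigma2)
    arrays ordered top level first and the innermost (error) last.
    """
    n_units = d2.shape[0]
    all_levels = [np.zeros(n_units, dtype=int)] + [np.asarray(a) for a in levels]
    n_strata = len(levels) + 1  # among each declared level + error

    within = [_within_ssd(d2, a) for a in all_levels]
    total_ssd = within[0]
    ssd, df = [], []
    counts = [len(np.unique(a)) for a in all_levels]
    for ell in range(1, len(all_levels)):
        ssd.append(within[ell - 1] - within[ell])
        df.append(counts[ell] - counts[ell - 1])
    # error stratum: within the finest declared clusters
    ssd.append(within[-1])
    df.append(n_units - counts[-1])

    # Searle coefficients: k(ell, m) for E[SS_ell] = sum_m k * sigma2_m
    def T(assign_outer: np.ndarray, assign_inner: np.ndarray) -> np.ndarray:
        """For each outer cluster, sum of squared inner-cluster sizes."""
        out = {}
        for cl in np.unique(assign_outer):
            mask = assign_outer == cl
            _, c = np.unique(assign_inner[mask], return_counts=True)
            out[cl] = float(np.sum(c.astype(float) ** 2))
        return out

    sizes = [
        {cl: float(np.sum(a == cl)) for cl in np.unique(a)} for a in all_levels
    ]
    K = np.zeros((n_strata, n_strata))
    for ell in range(1, len(all_levels)):  # stratum index ell-1
        for m in range(ell, len(all_levels)):  # sigma2 of level m (stratum m-1)
            t_out = T(all_levels[ell], all_levels[m])
            t_par = T(all_levels[ell - 1], all_levels[m])
            term = sum(t_out[c] / sizes[ell][c] for c in t_out)
            term -= sum(t_par[c] / sizes[ell - 1][c] for c in t_par)
            K[ell - 1, m - 1] = term
        K[ell - 1, n_strata - 1] = df[ell - 1]
    K[n_strata - 1, n_strata - 1] = df[-1]

    ssd_arr = np.array(ssd)
    df_arr = np.array(df, dtype=float)
    # solve triangular system bottom-up on the SS scale
    sigma2 = np.zeros(n_strata)
    if df_arr[-1] > 0:
        sigma2[-1] = ssd_arr[-1] / df_arr[-1]
    for ell in range(n_strata - 2, -1, -1):
        if df_arr[ell] <= 0:
            sigma2[ell] = 0.0  # vacuous stratum (e.g. one pop per group)
            continue
        resid = ssd_arr[ell] - sum(
            K[ell, m] * sigma2[m] for m in range(ell + 1, n_strata)
        )
        sigma2[ell] = resid / K[ell, ell]
    return df_arr, ssd_arr, sigma2


@dataclass
class AmovaResult:
    """Hierarchical AMOVA table plus fixation indices and permutation p."""

    table: pd.DataFrame
    indices: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    status: str = "ok"

    def __repr__(self):
        return (
            f"AmovaResult(status={self.status!r}, indices={self.indices}, "
            f"p={self.p_values})\n{self.table}"
        )


def _haploid_indices(sigma2):
    sa, sb, sw = sigma2
    tot = sa + sb + sw
    if tot == 0 or not np.isfinite(tot):
        return None
    return {
        "Phi_ST": (sa + sb) / tot,
        "Phi_SC": sb / (sb + sw) if (sb + sw) != 0 else np.nan,
        "Phi_CT": sa / tot,
    }


def _diploid_indices(sigma2):
    sa, sb, sc, sd = sigma2
    tot = sa + sb + sc + sd
    if tot == 0 or not np.isfinite(tot):
        return None
    return {
        "F_IT": (sa + sb + sc) / tot,
        "F_IS": sc / (sc + sd) if (sc + sd) != 0 else np.nan,
        "F_SC": sb / (sb + sc + sd) if (sb + sc + sd) != 0 else np.nan,
        "F_CT": sa / tot,
        "F_ST": (sa + sb) / tot,
    }


def _percent(sigma2):
    clamped = np.clip(np.nan_to_num(sigma2, nan=0.0), 0.0, None)
    tot = clamped.sum()
    return 100.0 * clamped / tot if tot > 0 else np.full_like(clamped, np.nan)


def _amova_levels_sequence(panel: SequencePanel, grouping: dict[str, str]):
    pops = panel.populations()
    group_of = {p: grouping[p] for p in pops}
    group_ids = {g: i for i, g in enumerate(dict.fromkeys(group_of[p] for p in pops))}
    pop_ids = {p: i for i, p in enumerate(pops)}
    g_assign = np.array([group_ids[group_of[panel.population_of[s]]] for s in panel.sample_ids])
    p_assign = np.array([pop_ids[panel.population_of[s]] for s in panel.sample_ids])
    return g_assign, p_assign


def amova(
    data,
    marker_kind: str,
    grouping: dict[str, str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA: regions / populations / (individuals) / units.

    ``marker_kind`` is "sequence" (haploid, 3 levels) or "microsatellite"
    (diploid, 4 levels with a within-individual stratum).  ``grouping`` maps
    population -> group; defaults to the panel's region assignment.
    p-values: the top index by permuting whole populations among groups, the
    subdivision index by permuting individuals among populations within
    groups, and the total fixation index by permuting individuals among all
    populations.
    """
    if grouping is None:
        grouping = {p: data.region_of[p] for p in data.populations()}
    if marker_kind == "sequence":
        d2 = sequence_sq_distances(data)
        g_assign, p_assign = _amova_levels_sequence(data, grouping)
        unit_of_ind = None
        level_names = [
            "Among groups",
            "Among populations within groups",
            "Within populations",
        ]
        make_indices = _haploid_indices
        index_perm_map = {"Phi_ST": "st", "Phi_SC": "sc", "Phi_CT": "ct"}
    elif marker_kind == "microsatellite":
        d2 = genotype_copy_sq_distances(data)
        pops = data.populations()
        group_of = {p: grouping[p] for p in pops}
        group_ids = {g: i for i, g in enumerate(dict.fromkeys(group_of[p] for p in pops))}
        pop_ids = {p: i for i, p in enumerate(pops)}
        n = data.n
        ind_pop = np.array([pop_ids[data.population_of[s]] for s in data.sample_ids])
        ind_grp = np.array([group_ids[group_of[data.population_of[s]]] for s in data.sample_ids])
        g_assign = np.repeat(ind_grp, 2)
        p_assign = np.repeat(ind_pop, 2)
        unit_of_ind = np.repeat(np.arange(n), 2)
        level_names = [
            "Among groups",
            "Among populations within groups",
            "Among individuals within populations",
            "Within individuals",
        ]
        make_indices = _diploid_indices
        index_perm_map = {"F_ST": "st", "F_SC": "sc", "F_CT": "ct"}
    else:
        raise ValidationError(f"unknown marker_kind {marker_kind!r}")

    levels = [g_assign, p_assign]
    if unit_of_ind is not None:
        levels.append(unit_of_ind)
    df_arr, ssd_arr, sigma2 = nested_amova_components(d2, levels)
    indices = make_indices(sigma2)
    status = "ok"
    if indices is None:
        status = "degenerate"
        indices = {}
    pct = _percent(sigma2)
    table = pd.DataFrame(
        {
            "source": level_names,
            "df": df_arr.astype(int),
            "SSD": ssd_arr,
            "variance_component": sigma2,
            "percent_variation": pct,
        }
    )
    # flag single-population groups (Phi_SC contrast weakened)
    pops_per_group: dict = {}
    for p, g in grouping.items():
        pops_per_group.setdefault(g, set()).add(p)
    if any(len(v) == 1 for v in pops_per_group.values()) and status == "ok":
        status = "single-population-group"

    result = AmovaResult(table=table, indices=indices, status=status)
    if status == "degenerate" or n_perm <= 0:
        return result

    rng = np.random.default_rng(seed)
    n_units = d2.shape[0]

    def compute_indices(levs):
        _, _, s2 = nested_amova_components(d2, levs)
        idx = make_indices(s2)
        return idx or {}

    counts = {k: 0 for k in index_perm_map.values()}
    # precompute population -> group mapping for the ct permutation
    uniq_pops, pop_first = np.unique(p_assign, return_index=True)
    pop_group = {p: g_assign[i] for p, i in zip(uniq_pops, pop_first)}

    if unit_of_ind is None:
        ind_index = np.arange(n_units)
        ind_pop_arr = p_assign.copy()
        ind_grp_arr = g_assign.copy()
    else:
        ind_index = np.arange(len(ind_pop))
        ind_pop_arr = ind_pop.copy()
        ind_grp_arr = ind_grp.copy()

    def expand(arr):
        return arr if unit_of_ind is None else np.repeat(arr, 2)

    def levels_from_ind(pop_arr, grp_arr):
        levs = [expand(grp_arr), expand(pop_arr)]
        if unit_of_ind is not None:
            levs.append(unit_of_ind)
        return levs

    obs = {index_perm_map[k]: abs(indices[k]) for k in index_perm_map if k in indices}
    for _ in range(n_perm):
        # st: individuals among all populations
        perm = rng.permutation(len(ind_index))
        idx_st = compute_indices(levels_from_ind(ind_pop_arr[perm],
                                                 np.array([pop_group[p] for p in ind_pop_arr[perm]])))
        # sc: individuals among populations within groups
        pop_sc = ind_pop_arr.copy()
        for g in np.unique(ind_grp_arr):
            mask = np.flatnonzero(ind_grp_arr == g)
            pop_sc[mask] = pop_sc[mask[rng.permutation(len(mask))]]
        idx_sc = compute_indices(levels_from_ind(pop_sc, ind_grp_arr))
        # ct: whole populations among groups
        pop_list = list(pop_group)
        grp_list = [pop_group[p] for p in pop_list]
        shuffled = [grp_list[i] for i in rng.permutation(len(grp_list))]
        new_group = dict(zip(pop_list, shuffled))
        grp_ct = np.array([new_group[p] for p in ind_pop_arr])
        idx_ct = compute_indices(levels_from_ind(ind_pop_arr, grp_ct))

        for name, tag in index_perm_map.items():
            if tag not in obs:
                continue
            src = {"st": idx_st, "sc": idx_sc, "ct": idx_ct}[tag]
            if name in src and np.isfinite(src[name]) and abs(src[name]) >= obs[tag]:
                counts[tag] += 1

    p_values = {
        name: (counts[tag] + 1) / (n_perm + 1)
        for name, tag in index_perm_map.items()
        if tag in obs
    }
    result.p_values = p_values
    result.n_permutations = n_perm
    return result


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

@dataclass
class PairwiseStatMatrix:
    """Symmetric pairwise statistic matrix with raw and BH-adjusted p."""

    populations: list[str]
    statistic: str
    values: pd.DataFrame
    p_raw: pd.DataFrame | None = None
    p_adj: pd.DataFrame | None = None
    n_permutations: int = 0

    def condensed(self) -> np.ndarray:
        """Lower-triangle values in pair order (i<j)."""
        v = self.values.to_numpy()
        iu = np.triu_indices(len(self.populations), k=1)
        return v[iu]

    def clamped(self) -> pd.DataFrame:
        """Display variant with negative estimates clamped at zero."""
        return self.values.clip(lower=0.0)

    def to_csv(self, values_path, p_raw_path=None, p_adj_path=None) -> None:
        self.values.to_csv(values_path)
        if p_raw_path is not None and self.p_raw is not None:
            self.p_raw.to_csv(p_raw_path)
        if p_adj_path is not None and self.p_adj is not None:
            self.p_adj.to_csv(p_adj_path)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pairwise_matrix_from(pairs, pops, stat_name, n_perm):
    k = len(pops)
    vals = np.zeros((k, k))
    praw = np.ones((k, k))
    plist, ij = [], []
    for (i, j), (v, p) in pairs.items():
        vals[i, j] = vals[j, i] = v
        praw[i, j] = praw[j, i] = p
        plist.append(p)
        ij.append((i, j))
    padj_flat = bh_adjust(plist) if plist else np.array([])
    padj = np.ones((k, k))
    for (i, j), q in zip(ij, padj_flat):
        padj[i, j] = padj[j, i] = q
    idx = list(pops)
    return PairwiseStatMatrix(
        populations=idx,
        statistic=stat_name,
        values=pd.DataFrame(vals, index=idx, columns=idx),
        p_raw=pd.DataFrame(praw, index=idx, columns=idx),
        p_adj=pd.DataFrame(padj, index=idx, columns=idx),
        n_permutations=n_perm,
    )


def phi_st_two_pop(d2: np.ndarray, assign: np.ndarray) -> float:
    """Two-population AMOVA PhiST from a squared-distance matrix."""
    _, _, sigma2 = nested_amova_components(d2, [assign])
    sa, sw = sigma2
    tot = sa + sw
    if tot == 0:
        return np.nan
    return float(sa / tot)


def pairwise_phist(
    panel: SequencePanel, n_perm: int = 1000, seed: int | None = None
) -> PairwiseStatMatrix:
    """Pairwise PhiST between all populations with n >= 2, permutation p,
    BH adjustment across pairs."""
    pops = [p for p in panel.populations() if len(panel.samples_of(p)) >= 2]
    if len(pops) < 2:
        raise UndefinedStatisticError("need >= 2 populations with n >= 2")
    d2_full = sequence_sq_distances(panel)
    pop_idx = {
        p: [i for i, s in enumerate(panel.sample_ids) if panel.population_of[s] == p]
        for p in pops
    }
    rng = np.random.default_rng(seed)
    pairs = {}
    for i, j in combinations(range(len(pops)), 2):
        ia, ib = pop_idx[pops[i]], pop_idx[pops[j]]
        sel = ia + ib
        d2 = d2_full[np.ix_(sel, sel)]
        assign = np.array([0] * len(ia) + [1] * len(ib))
        obs = phi_st_two_pop(d2, assign)
        count = 0
        for _ in range(n_perm):
            perm = phi_st_two_pop(d2, rng.permutation(assign))
            if np.isfinite(perm) and np.isfinite(obs) and perm >= obs:
                count += 1
        p = (count + 1) / (n_perm + 1) if np.isfinite(obs) else 1.0
        pairs[(i, j)] = (obs if np.isfinite(obs) else 0.0, p)
    return _pairwise_matrix_from(pairs, pops, "PhiST", n_perm)


def wc_theta(genotypes_by_pop: list[np.ndarray]) -> float:
    """Weir & Cockerham (1984) theta for one locus from per-population
    complete genotype arrays (n_i, 2).  Returns the (a, a+b+c) sums via a
    single ratio; NaN if the locus is monomorphic across the populations."""
    a_sum, abc_sum = wc_components(genotypes_by_pop)
    if abc_sum == 0:
        return np.nan
    return a_sum / abc_sum


def wc_components(genotypes_by_pop: list[np.ndarray]) -> tuple[float, float]:
    """Sums of WC84 variance components (a, a+b+c) over alleles at one locus."""
    pops = [g for g in genotypes_by_pop if len(g) > 0]
    r = len(pops)
    if r < 2:
        return 0.0, 0.0
    n_i = np.array([len(g) for g in pops], dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1.0)
    alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
    if len(alleles) < 2:
        return 0.0, 0.0
    a_sum = abc_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean(g == al) for g in pops])
        h_i = np.array([np.mean((g[:, 0] != g[:, 1]) & ((g[:, 0] == al) | (g[:, 1] == al)))
                        for g in pops])
        pbar = np.sum(n_i * p_i) / (r * nbar)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def _multilocus_theta(panel: GenotypePanel, pop_a: str, pop_b: str,
                      sample_pops: dict[str, str] | None = None) -> float:
    a_tot = abc_tot = 0.0
    pop_of = sample_pops or panel.population_of
    idx_a = [i for i, s in enumerate(panel.sample_ids) if pop_of[s] == pop_a]
    idx_b = [i for i, s in enumerate(panel.sample_ids) if pop_of[s] == pop_b]
    for li in range(panel.n_loci):
        ga = panel.alleles[idx_a, li, :]
        gb = panel.alleles[idx_b, li, :]
        ga = ga[ga[:, 0] != MISSING]
        gb = gb[gb[:, 0] != MISSING]
        a, abc = wc_components([ga, gb])
        a_tot += a
        abc_tot += abc
    if abc_tot == 0:
        return np.nan
    return a_tot / abc_tot


def pairwise_fst_wc(
    panel: GenotypePanel, n_perm: int = 1000, seed: int | None = None
) -> PairwiseStatMatrix:
    """Pairwise multi-locus Weir-Cockerham theta with permutation p and BH
    adjustment; individuals are permuted between the two populations."""
    pops = [p for p in panel.populations() if len(panel.samples_of(p)) >= 2]
    if len(pops) < 2:
        raise UndefinedStatisticError("need >= 2 populations with n >= 2")
    rng = np.random.default_rng(seed)
    pairs = {}
    for i, j in combinations(range(len(pops)), 2):
        pa, pb = pops[i], pops[j]
        members = panel.samples_of(pa) + panel.samples_of(pb)
        labels = [pa] * len(panel.samples_of(pa)) + [pb] * len(panel.samples_of(pb))
        obs = _multilocus_theta(panel, pa, pb)
        count = 0
        for _ in range(n_perm):
            perm_labels = [labels[k] for k in rng.permutation(len(labels))]
            assign = dict(zip(members, perm_labels))
            perm = _multilocus_theta(panel, pa, pb, sample_pops={**panel.population_of, **assign})
            if np.isfinite(perm) and np.isfinite(obs) and perm >= obs:
                count += 1
        p = (count + 1) / (n_perm + 1) if np.isfinite(obs) else 1.0
        pairs[(i, j)] = (obs if np.isfinite(obs) else 0.0, p)
    return _pairwise_matrix_from(pairs, pops, "FST_WC", n_perm)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def jost_d_from_counts(
    counts_by_pop: np.ndarray,
    ho_by_pop: np.ndarray | None = None,
    n_ind: np.ndarray | None = None,
    unbiased: bool = True,
    clamp: bool = True,
) -> float:
    """Jost's D for one locus from an (s, n_alleles) count matrix.

    ``unbiased`` applies the Nei-Chesser small-sample corrections (with the
    heterozygote term when per-population observed heterozygosities and
    individual counts are supplied, i.e. diploid data); otherwise the plug-in
    estimator.  D = (HT - HS)/(1 - HS) * s/(s - 1).
    """
    counts = np.asarray(counts_by_pop, dtype=float)
    s = counts.shape[0]
    if s < 2:
        raise UndefinedStatisticError("Jost's D needs >= 2 populations")
    n_pop = counts.sum(axis=1)
    if (n_pop == 0).any():
        raise UndefinedStatisticError("empty population in Jost's D")
    freqs = counts / n_pop[:, None]
    hs_plug = float(np.mean(1.0 - np.sum(freqs**2, axis=1)))
    mean_freq = freqs.mean(axis=0)
    ht_plug = float(1.0 - np.sum(mean_freq**2))
    if not unbiased:
        hs, ht = hs_plug, ht_plug
    elif ho_by_pop is not None and n_ind is not None:
        ho = float(np.mean(ho_by_pop))
        ntil = len(n_ind) / np.sum(1.0 / np.asarray(n_ind, dtype=float))
        hs = ntil / (ntil - 1.0) * (hs_plug - ho / (2.0 * ntil))
        ht = ht_plug + hs / (2.0 * ntil * s) - ho / (2.0 * ntil * s)
    else:
        # haploid: harmonic mean of gene-copy counts
        ntil = s / np.sum(1.0 / n_pop)
        hs = ntil / (ntil - 1.0) * hs_plug
        ht = ht_plug + hs / (ntil * s)
    if hs >= 1.0:
        raise UndefinedStatisticError("HS = 1: Jost's D undefined")
    d = (ht - hs) / (1.0 - hs) * s / (s - 1.0)
    return float(max(d, 0.0)) if clamp else float(d)


def _seq_pair_jost(panel, pa, pb, unbiased):
    from echinopop.haplotypes import collapse_haplotypes

    sub = panel.subset(populations=[pa, pb])
    tab = collapse_haplotypes(sub)
    counts = tab.counts[[pa, pb]].to_numpy().T
    return jost_d_from_counts(counts, unbiased=unbiased)


def _msat_pair_jost(panel, pa, pb, unbiased):
    vals = []
    for locus in panel.loci_ids:
        ga = panel.genotypes(pa, locus)
        gb = panel.genotypes(pb, locus)
        if len(ga) == 0 or len(gb) == 0:
            continue
        alleles = np.unique(np.concatenate([ga.ravel(), gb.ravel()]))
        if len(alleles) < 2:
            continue
        counts = np.array([
            [np.sum(g.ravel() == al) for al in alleles] for g in (ga, gb)
        ], dtype=float)
        ho = np.array([np.mean(g[:, 0] != g[:, 1]) for g in (ga, gb)])
        n_ind = np.array([len(ga), len(gb)], dtype=float)
        try:
            vals.append(
                jost_d_from_counts(
                    counts,
                    ho_by_pop=ho if unbiased else None,
                    n_ind=n_ind if unbiased else None,
                    unbiased=unbiased,
                )
            )
        except UndefinedStatisticError:
            continue
    if not vals:
        return np.nan
    return float(np.mean(vals))


def jost_d(
    data,
    marker_kind: str,
    n_perm: int = 1000,
    seed: int | None = None,
    unbiased: bool = True,
) -> PairwiseStatMatrix:
    """Pairwise Jost's D with permutation p-values and BH adjustment.

    Sequence data treat haplotypes as alleles; microsatellite D is the mean
    over polymorphic loci of per-locus D with Nei-Chesser corrections.
    """
    if marker_kind == "sequence":
        stat = lambda pnl, pa, pb: _seq_pair_jost(pnl, pa, pb, unbiased)  # noqa: E731
        relabel = _relabel_sequence
    elif marker_kind == "microsatellite":
        stat = lambda pnl, pa, pb: _msat_pair_jost(pnl, pa, pb, unbiased)  # noqa: E731
        relabel = _relabel_genotype
    else:
        raise ValidationError(f"unknown marker_kind {marker_kind!r}")
    pops = [p for p in data.populations() if len(data.samples_of(p)) >= 2]
    if len(pops) < 2:
        raise UndefinedStatisticError("need >= 2 populations with n >= 2")
    rng = np.random.default_rng(seed)
    pairs = {}
    for i, j in combinations(range(len(pops)), 2):
        pa, pb = pops[i], pops[j]
        try:
            obs = stat(data, pa, pb)
        except UndefinedStatisticError:
            pairs[(i, j)] = (0.0, 1.0)
            continue
        count = 0
        members = data.samples_of(pa) + data.samples_of(pb)
        labels = [pa] * len(data.samples_of(pa)) + [pb] * len(data.samples_of(pb))
        for _ in range(n_perm):
            shuffled = [labels[k] for k in rng.permutation(len(labels))]
            perm_panel = relabel(data, dict(zip(members, shuffled)))
            try:
                perm = stat(perm_panel, pa, pb)
            except UndefinedStatisticError:
                continue
            if np.isfinite(perm) and np.isfinite(obs) and perm >= obs:
                count += 1
        p = (count + 1) / (n_perm + 1) if np.isfinite(obs) else 1.0
        pairs[(i, j)] = (obs if np.isfinite(obs) else 0.0, p)
    return _pairwise_matrix_from(pairs, pops, "JostD", n_perm)


def _relabel_sequence(panel: SequencePanel, new_labels: dict[str, str]) -> SequencePanel:
    pop_of = {**panel.population_of, **new_labels}
    return SequencePanel(panel.sample_ids, panel.sequences, pop_of, dict(panel.region_of))


def _relabel_genotype(panel: GenotypePanel, new_labels: dict[str, str]) -> GenotypePanel:
    pop_of = {**panel.population_of, **new_labels}
    return GenotypePanel(
        panel.sample_ids, panel.loci_ids, panel.alleles, pop_of,
        dict(panel.region_of), dict(panel.motif_length_of),
    )


# ---------------------------------------------------------------------------
# matrix correlation, Mantel, NMDS, Evanno
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    strata: dict[str, str] | None = None


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _mantel_r(m1: np.ndarray, m2: np.ndarray) -> float:
    x, y = _lower_triangle(m1), _lower_triangle(m2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("constant matrix: correlation undefined")
    return float(pearsonr(x, y)[0])


def matrix_correlation(
    m1: PairwiseStatMatrix | np.ndarray,
    m2: PairwiseStatMatrix | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Pearson correlation between two pairwise matrices over the lower
    triangle; significance by joint row/column (Mantel) permutation.  With
    ``exhaustive`` the full n! label permutations are enumerated (small n)."""
    a = m1.values.to_numpy() if isinstance(m1, PairwiseStatMatrix) else np.asarray(m1, float)
    b = m2.values.to_numpy() if isinstance(m2, PairwiseStatMatrix) else np.asarray(m2, float)
    if isinstance(m1, PairwiseStatMatrix) and isinstance(m2, PairwiseStatMatrix):
        if m1.populations != m2.populations:
            b = m2.values.loc[m1.populations, m1.populations].to_numpy()
    obs = _mantel_r(a, b)
    n = a.shape[0]
    if exhaustive:
        count = total = 0
        for perm in permutations(range(n)):
            perm = np.asarray(perm)
            r = _mantel_r(a, b[np.ix_(perm, perm)])
            total += 1
            if r >= obs - 1e-12:
                count += 1
        return MantelResult(r=obs, p=count / total, n_permutations=total)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _mantel_r(a, b[np.ix_(perm, perm)]) >= obs:
            count += 1
    return MantelResult(r=obs, p=(count + 1) / (n_perm + 1), n_permutations=n_perm)


def mantel_ibd(
    gen_dist,
    geo_dist,
    n_perm: int = 1000,
    strata: dict[str, str] | None = None,
    seed: int | None = None,
    populations: list[str] | None = None,
) -> MantelResult:
    """Mantel test of isolation by distance; one-tailed for positive r.

    With ``strata`` (population -> stratum), permutations shuffle population
    labels only within strata, removing between-stratum divergence from the
    null; single-member strata stay fixed.
    """
    if isinstance(gen_dist, PairwiseStatMatrix):
        populations = gen_dist.populations
        a = gen_dist.values.to_numpy()
    else:
        a = np.asarray(gen_dist, dtype=float)
    if hasattr(geo_dist, "submatrix") and populations is not None:
        b = geo_dist.submatrix(populations)
    elif hasattr(geo_dist, "distances"):
        b = geo_dist.distances
    else:
        b = np.asarray(geo_dist, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("matrices must match in shape")
    obs = _mantel_r(a, b)
    n = a.shape[0]
    rng = np.random.default_rng(seed)
    if strata is not None:
        if populations is None:
            raise ValidationError("strata require population labels")
        stratum_of = [strata[p] for p in populations]
        blocks = {}
        for i, st in enumerate(stratum_of):
            blocks.setdefault(st, []).append(i)
        if all(len(v) == 1 for v in blocks.values()):
            raise ValidationError("all strata of size 1: no permutations possible")

        def draw():
            perm = np.arange(n)
            for idx in blocks.values():
                if len(idx) > 1:
                    idx = np.asarray(idx)
                    perm[idx] = idx[rng.permutation(len(idx))]
            return perm
    else:
        def draw():
            return rng.permutation(n)

    count = 0
    for _ in range(n_perm):
        perm = draw()
        if _mantel_r(a, b[np.ix_(perm, perm)]) >= obs:
            count += 1
    return MantelResult(
        r=obs, p=(count + 1) / (n_perm + 1), n_permutations=n_perm, strata=strata
    )


def nmds(
    dissimilarity, n_dims: int = 2, seed: int | None = None, n_restarts: int = 20
):
    """Non-metric MDS (Kruskal stress-1) with seeded random restarts.

    Returns (coordinates, stress); coordinates are centred and deterministic
    for a fixed seed.
    """
    if isinstance(dissimilarity, PairwiseStatMatrix):
        labels = dissimilarity.populations
        d = dissimilarity.clamped().to_numpy()
    else:
        d = np.asarray(dissimilarity, dtype=float)
        labels = [str(i) for i in range(d.shape[0])]
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite dissimilarity")
    if d.shape[0] < 3:
        raise ValidationError("NMDS needs >= 3 items")
    model = MDS(
        n_components=n_dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=2000,
        eps=1e-12,
    )
    coords = model.fit_transform(d)
    coords = coords - coords.mean(axis=0)
    df = pd.DataFrame(
        coords, index=labels, columns=[f"dim{i + 1}" for i in range(n_dims)]
    )
    return df, float(model.stress_)


def evanno_delta_k(table: pd.DataFrame) -> pd.DataFrame:
    """Evanno's DeltaK from a table of clustering log-likelihoods.

    ``table`` has columns K, run, lnL (>= 2 replicates per K, >= 3
    consecutive K).  DeltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| /
    sd(L(K)); rows with zero sd get NaN and a flag.  The best K maximises
    DeltaK (exposed via ``df.attrs["best_K"]``).
    """
    req = {"K", "run", "lnL"}
    if not req.issubset(table.columns):
        raise ValidationError(f"need columns {sorted(req)}")
    grp = table.groupby("K")["lnL"]
    means, sds, reps = grp.mean(), grp.std(ddof=1), grp.count()
    ks = sorted(means.index)
    if len(ks) < 3 or any(ks[i + 1] - ks[i] != 1 for i in range(len(ks) - 1)):
        raise ValidationError("DeltaK needs >= 3 consecutive K values")
    if (reps < 2).any():
        raise ValidationError("DeltaK needs >= 2 replicates per K")
    rows = []
    for k in ks[1:-1]:
        second = abs(means[k + 1] - 2.0 * means[k] + means[k - 1])
        sd = sds[k]
        rows.append(
            {
                "K": k,
                "mean_lnL": means[k],
                "sd_lnL": sd,
                "delta_K": second / sd if sd > 0 else np.nan,
                "flagged_zero_sd": bool(sd == 0),
            }
        )
    out = pd.DataFrame(rows)
    valid = out.dropna(subset=["delta_K"])
    out.attrs["best_K"] = int(valid.loc[valid["delta_K"].idxmax(), "K"]) if len(valid) else None
    return out
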