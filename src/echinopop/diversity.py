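"""Per-population and pooled diversity statistics for both markers.

Sequence marker: haplotype number, Nei's haplotype diversity h with its
sampling SD, nucleotide diversity pi (pairwise-complete over sites), and
rarefied haplotype richness.  Microsatellites: allelic richness (rarefied),
observed/expected heterozygosity, multi-locus FIS with a bootstrap-over-loci
confidence interval, and a permutation test of Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from echinopop.errors import UndefinedStatisticError, ValidationError
from echinopop.haplotypes import collapse_haplotypes
from echinopop.io import GenotypePanel, SequencePanel

_MISSING_CHARS = frozenset("-N")


# ---------------------------------------------------------------------------
# sequence marker
# ---------------------------------------------------------------------------

def haplotype_diversity(counts) -> tuple[float, float]:
    """Nei's haplotype diversity h = n/(n-1) (1 - sum p_i^2) and its SD.

    The SD follows Nei (1987, eq. 8.12), the sampling variance of gene
    diversity.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2")
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - s2)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2
    )
    return h, float(np.sqrt(max(var, 0.0)))


def _pair_diff_and_sites(seq_a: str, seq_b: str) -> tuple[int, int]:
    diffs = sites = 0
    for a, b in zip(seq_a, seq_b):
        if a in _MISSING_CHARS or b in _MISSING_CHARS:
            continue
        sites += 1
        diffs += a != b
    return diffs, sites


def nucleotide_diversity(panel: SequencePanel) -> tuple[float, float]:
    """Mean pairwise difference per site, pairwise-complete over gap/N sites.

    Returns (pi, SD); the SD is the square root of Nei's (1987, eq. 10.7)
    total variance of pi.
    """
    n = panel.n
    if n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2")
    vals = []
    for sa, sb in combinations(panel.sequences, 2):
        diffs, sites = _pair_diff_and_sites(sa, sb)
        if sites == 0:
            raise ValidationError("a sequence pair shares no comparable sites")
        vals.append(diffs / sites)
    pi = float(np.mean(vals))
    L = panel.L
    var = (n + 1.0) / (3.0 * (n - 1.0)) * pi / L + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, float(np.sqrt(max(var, 0.0)))


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts, g: int) -> float:
    """Expected number of distinct types in a subsample of size g.

    Hurlbert's rarefaction / El Mousadik & Petit allelic richness:
    ``sum_i [1 - C(N - N_i, g) / C(N, g)]``.
    """
    counts = np.asarray(counts, dtype=int)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if g < 1:
        raise UndefinedStatisticError("rarefaction size g must be >= 1")
    if g > N:
        raise UndefinedStatisticError(f"rarefaction size g={g} exceeds N={N}")
    total = 0.0
    log_cng = _log_comb(N, g)
    for ni in counts:
        if N - ni < g:
            total += 1.0
        else:
            total += 1.0 - np.exp(_log_comb(N - ni, g) - log_cng)
    return float(total)


# ---------------------------------------------------------------------------
# microsatellite marker
# ---------------------------------------------------------------------------

def heterozygosities(
    panel: GenotypePanel, population: str, locus: str, unbiased: bool = True
) -> tuple[float, float]:
    """(Ho, He) at one locus in one population; complete genotypes only.

    He is Nei's gene diversity, by default with the unbiased 2n/(2n-1)
    small-sample correction.
    """
    g = panel.genotypes(population, locus)
    if len(g) == 0:
        raise UndefinedStatisticError(
            f"no complete genotypes for {population}/{locus}"
        )
    ho = float(np.mean(g[:, 0] != g[:, 1]))
    alleles = g.ravel()
    _, cnt = np.unique(alleles, return_counts=True)
    p = cnt / cnt.sum()
    he = 1.0 - float(np.sum(p**2))
    if unbiased:
        two_n = len(alleles)
        if two_n > 1:
            he *= two_n / (two_n - 1.0)
    return ho, he


def population_het_table(
    panel: GenotypePanel, population: str, unbiased: bool = True
) -> pd.DataFrame:
    """Per-locus Ho/He for one population (NaN where no data)."""
    rows = []
    for locus in panel.loci_ids:
        try:
            ho, he = heterozygosities(panel, population, locus, unbiased=unbiased)
        except UndefinedStatisticError:
            ho = he = np.nan
        rows.append({"locus": locus, "Ho": ho, "He": he})
    return pd.DataFrame(rows).set_index("locus")


def multilocus_fis(panel: GenotypePanel, population: str, loci=None) -> float:
    """Nei (1977) multi-locus FIS = 1 - sum(Ho) / sum(He) over loci."""
    loci = list(loci) if loci is not None else panel.loci_ids
    tab = population_het_table(panel, population).loc[loci].dropna()
    if len(tab) == 0 or tab["He"].sum() == 0:
        raise UndefinedStatisticError("FIS undefined: no heterozygosity at any locus")
    return float(1.0 - tab["Ho"].sum() / tab["He"].sum())


@dataclass
class FisResult:
    fis: float
    ci_low: float
    ci_high: float
    significant: bool
    n_boot: int
    per_locus: pd.DataFrame


def fis_bootstrap(
    panel: GenotypePanel,
    population: str,
    n_boot: int = 100,
    level: float = 0.05,
    seed: int | None = None,
) -> FisResult:
    """Multi-locus FIS with a percentile CI from resampling loci.

    Loci without data in the population are dropped before resampling; the
    CI is flagged significant when it excludes zero.
    """
    tab = population_het_table(panel, population).dropna()
    tab = tab[tab["He"] > 0]
    if len(tab) < 2:
        raise UndefinedStatisticError("FIS bootstrap needs >= 2 informative loci")
    ho, he = tab["Ho"].to_numpy(), tab["He"].to_numpy()
    fis = float(1.0 - ho.sum() / he.sum())
    rng = np.random.default_rng(seed)
    k = len(tab)
    idx = rng.integers(0, k, size=(n_boot, k))
    boots = 1.0 - ho[idx].sum(axis=1) / he[idx].sum(axis=1)
    lo, hi = np.quantile(boots, [level / 2.0, 1.0 - level / 2.0])
    per_locus = tab.assign(FIS=1.0 - tab["Ho"] / tab["He"])
    return FisResult(
        fis=fis,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        n_boot=n_boot,
        per_locus=per_locus,
    )


def hwe_permutation_test(
    panel: GenotypePanel,
    population: str,
    n_perm: int = 1001,
    seed: int | None = None,
) -> float:
    """Permutation test of Hardy-Weinberg equilibrium within one population.

    The statistic is |multi-locus FIS|; the null shuffles gene copies among
    individuals within the population independently at each locus.  Returns
    p = (#{|stat_perm| >= |stat_obs|} + 1) / (n_perm + 1).
    """
    genos = {loc: panel.genotypes(population, loc) for loc in panel.loci_ids}
    genos = {loc: g for loc, g in genos.items() if len(g) >= 2}
    informative = {
        loc: g for loc, g in genos.items() if len(np.unique(g.ravel())) >= 2
    }
    if not informative:
        raise UndefinedStatisticError(
            f"population {population!r} monomorphic at all loci; HWE test skipped"
        )

    def stat(geno_map) -> float:
        sum_ho = sum_he = 0.0
        for g in geno_map.values():
            sum_ho += float(np.mean(g[:, 0] != g[:, 1]))
            alleles = g.ravel()
            _, cnt = np.unique(alleles, return_counts=True)
            p = cnt / cnt.sum()
            he = (1.0 - float(np.sum(p**2))) * len(alleles) / (len(alleles) - 1.0)
            sum_he += he
        return 1.0 - sum_ho / sum_he

    obs = abs(stat(informative))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_map = {}
        for loc, g in informative.items():
            pool = g.ravel().copy()
            rng.shuffle(pool)
            perm_map[loc] = pool.reshape(-1, 2)
        if abs(stat(perm_map)) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# per-population summary table
# ---------------------------------------------------------------------------

def _seq_row(panel: SequencePanel, g_rarefy: int) -> dict:
    table = collapse_haplotypes(panel)
    counts = table.total_counts().to_numpy()
    h, h_sd = haplotype_diversity(counts)
    pi, pi_sd = nucleotide_diversity(panel)
    n = panel.n
    hr = rarefied_richness(counts, min(g_rarefy, n)) if n >= 1 else np.nan
    return {
        "N_seq": n,
        "Nh": len(counts),
        "haplotype_diversity": h,
        "haplotype_diversity_SD": h_sd,
        "rarefied_richness": hr,
        "pi": pi,
        "pi_SD": pi_sd,
    }


def _msat_row(
    panel: GenotypePanel, g_rarefy: int | None, n_boot: int, n_perm: int, seed
) -> dict:
    pops = panel.populations()
    assert len(pops) >= 1
    pop_label = pops[0] if len(pops) == 1 else None
    # pooled analyses treat the subset as one population
    merged = GenotypePanel(
        sample_ids=panel.sample_ids,
        loci_ids=panel.loci_ids,
        alleles=panel.alleles,
        population_of={s: "_pooled" for s in panel.sample_ids},
        region_of={"_pooled": "_pooled"},
        motif_length_of=panel.motif_length_of,
    ) if pop_label is None else panel
    pop = "_pooled" if pop_label is None else pop_label

    rs_vals, k_vals, ho_vals, he_vals = [], [], [], []
    min_2n = None
    for locus in merged.loci_ids:
        alleles = merged.population_alleles(pop, locus)
        if alleles.size == 0:
            continue
        if min_2n is None or alleles.size < min_2n:
            min_2n = alleles.size
    g_eff = g_rarefy if g_rarefy is not None else (min_2n or 2)
    for locus in merged.loci_ids:
        alleles = merged.population_alleles(pop, locus)
        if alleles.size == 0:
            continue
        _, cnt = np.unique(alleles, return_counts=True)
        k_vals.append(len(cnt))
        rs_vals.append(rarefied_richness(cnt, min(g_eff, int(cnt.sum()))))
        try:
            ho, he = heterozygosities(merged, pop, locus)
            ho_vals.append(ho)
            he_vals.append(he)
        except UndefinedStatisticError:
            pass
    row = {
        "N_msat": len(merged.sample_ids),
        "allele_count": int(np.sum(k_vals)) if k_vals else 0,
        "allelic_richness": float(np.mean(rs_vals)) if rs_vals else np.nan,
        "Ho": float(np.mean(ho_vals)) if ho_vals else np.nan,
        "He": float(np.mean(he_vals)) if he_vals else np.nan,
    }
    try:
        fr = fis_bootstrap(merged, pop, n_boot=n_boot, seed=seed)
        row.update(
            FIS=fr.fis, FIS_CI_low=fr.ci_low, FIS_CI_high=fr.ci_high,
            FIS_significant=fr.significant,
        )
    except UndefinedStatisticError:
        row.update(FIS=np.nan, FIS_CI_low=np.nan, FIS_CI_high=np.nan,
                   FIS_significant=False)
    try:
        row["HWE_p"] = hwe_permutation_test(merged, pop, n_perm=n_perm, seed=seed)
    except UndefinedStatisticError:
        row["HWE_p"] = np.nan
    return row


def private_allele_counts(panel: GenotypePanel) -> dict[str, int]:
    """Number of alleles found in exactly one population, per population."""
    pops = panel.populations()
    seen: dict[tuple[str, int], set[str]] = {}
    for pop in pops:
        for locus in panel.loci_ids:
            for a in np.unique(panel.population_alleles(pop, locus)):
                seen.setdefault((locus, int(a)), set()).add(pop)
    out = {p: 0 for p in pops}
    for (_, _), holders in seen.items():
        if len(holders) == 1:
            out[next(iter(holders))] += 1
    return out


def diversity_table(
    seq_panel: SequencePanel | None = None,
    genotype_panel: GenotypePanel | None = None,
    rarefaction_g: int = 8,
    rarefaction_g_msat: int | None = None,
    n_boot: int = 100,
    n_perm: int = 1001,
    seed: int | None = None,
) -> pd.DataFrame:
    """Diversity summary: one row per population, per region, and the total.

    Emits BOTH Nei's haplotype diversity (with SD) and rarefied haplotype
    richness; for microsatellites, rarefied allelic richness defaults to the
    smallest per-locus gene-copy count across the dataset when
    ``rarefaction_g_msat`` is None.
    """
    ref = seq_panel if seq_panel is not None else genotype_panel
    if ref is None:
        raise ValidationError("need at least one panel")
    pops = ref.populations()
    regions: dict[str, list[str]] = {}
    for p in pops:
        regions.setdefault(ref.region_of[p], []).append(p)

    rows = {}
    units = [("population", p, [p]) for p in pops]
    units += [("region", r, ps) for r, ps in regions.items()]
    units += [("total", "Total", pops)]
    for level, name, plist in units:
        row: dict = {"level": level}
        if seq_panel is not None:
            sub = seq_panel.subset(populations=plist)
            if sub.n >= 2:
                row.update(_seq_row(sub, rarefaction_g))
        if genotype_panel is not None:
            sub = genotype_panel.subset(plist)
            if sub.n >= 1:
                row.update(
                    _msat_row(sub, rarefaction_g_msat, n_boot, n_perm, seed)
                )
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    if genotype_panel is not None:
        priv = private_allele_counts(genotype_panel)
        df["private_alleles"] = pd.Series(priv)
    df.index.name = "unit"
    return df
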