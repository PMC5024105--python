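"""Demographic-history inference.

Sequence side: the mismatch distribution (pairwise-difference histogram),
its sudden-expansion model fit (tau, theta0, theta1), tau -> time dating via
tau = 2ut, and conversions from coalescent-scaled parameters (theta = 2 Nf
mu for the maternally inherited marker, Mt = m/mu migrants per generation,
exponential growth theta_t = theta1 * exp(-G t)).

Microsatellite side: heterozygosity excess/deficiency bottleneck tests under
IAM and SMM (Wilcoxon signed-rank, exact null), and the M-ratio with a
simulated critical value Mc under a two-phase mutation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.special import gammainc, gammaln
from scipy.stats import norm, rankdata

from echinopop.errors import UndefinedStatisticError, ValidationError
from echinopop.io import GenotypePanel, SequencePanel
from echinopop.simulate import sample_iam, sample_stepwise

_MISSING_CHARS = frozenset("-N")


# ---------------------------------------------------------------------------
# mismatch distribution
# ---------------------------------------------------------------------------

def mismatch_observed(panel: SequencePanel) -> np.ndarray:
    """Histogram of pairwise difference counts over all C(n,2) pairs
    (pairwise-complete over gap/N sites); index i = number of differences."""
    if panel.n < 2:
        raise UndefinedStatisticError("mismatch distribution needs n >= 2")
    diffs = []
    for sa, sb in combinations(panel.sequences, 2):
        d = sum(
            a != b
            for a, b in zip(sa, sb)
            if a not in _MISSING_CHARS and b not in _MISSING_CHARS
        )
        diffs.append(d)
    hist = np.bincount(diffs)
    return hist


def _equilibrium_mismatch(theta: float, i_max: int) -> np.ndarray:
    """F_i = theta^i / (1+theta)^(i+1); point mass at 0 when theta = 0."""
    i = np.arange(i_max + 1)
    if theta <= 0:
        out = np.zeros(i_max + 1)
        out[0] = 1.0
        return out
    return np.exp(i * np.log(theta) - (i + 1) * np.log1p(theta))


def expansion_expected(
    tau: float, theta0: float, theta1: float, i_max: int
) -> np.ndarray:
    """Sudden-expansion mismatch probabilities for i = 0..i_max.

    Exact transient distribution for a pair of lineages whose coalescence
    hazard is 1/theta1 during the last tau mutational units and whose
    residual time beyond tau is exponential with mean theta0:

        F_i = Fhat_i(theta1) * P(Gamma(i+1) <= tau (1+theta1)/theta1)
              + exp(-tau/theta1) * sum_j Pois_j(tau) Fhat_{i-j}(theta0)

    At tau = 0 this reduces to the equilibrium form for theta0, and for
    theta0 = theta1 it equals the equilibrium form at any tau.
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ValidationError("mismatch parameters must be non-negative")
    i = np.arange(i_max + 1)
    eq0 = _equilibrium_mismatch(theta0, i_max)
    if tau == 0:
        return eq0
    if theta1 <= 0:
        out = np.zeros(i_max + 1)
        out[0] = 1.0
        return out
    eq1 = _equilibrium_mismatch(theta1, i_max)
    recent = eq1 * gammainc(i + 1, tau * (1.0 + theta1) / theta1)
    log_pois = -tau + i * np.log(tau) - gammaln(i + 1) if tau > 0 else None
    pois = np.exp(log_pois)
    old = np.convolve(pois, eq0)[: i_max + 1] * np.exp(-tau / theta1)
    return recent + old


@dataclass
class MismatchFit:
    observed: np.ndarray
    expected: np.ndarray
    tau: float
    theta0: float
    theta1: float
    sse: float
    n_pairs: int
    boundary: bool = False


def fit_expansion(
    observed: np.ndarray, i_max: int | None = None
) -> MismatchFit:
    """Least-squares fit of the sudden-expansion model to an observed
    mismatch histogram.

    Minimises the SSE between observed pair frequencies and the model over
    i = 0..i_max from several moment-based starts; a fit pinned to the tau=0
    boundary (or a single-valued histogram) is flagged ``boundary``.
    """
    obs = np.asarray(observed, dtype=float)
    n_pairs = int(obs.sum())
    if n_pairs == 0:
        raise UndefinedStatisticError("empty mismatch histogram")
    if (obs > 0).sum() < 2:
        freq = obs / n_pairs
        i0 = int(np.argmax(obs))
        return MismatchFit(
            observed=obs.astype(int), expected=freq, tau=float(i0),
            theta0=0.0, theta1=0.0, sse=0.0, n_pairs=n_pairs, boundary=True,
        )
    if i_max is None:
        i_max = max(len(obs) - 1, 10)
    freq = np.zeros(i_max + 1)
    freq[: len(obs)] = obs / n_pairs
    mean = float(np.sum(np.arange(len(obs)) * obs) / n_pairs)

    def residuals(params):
        tau, th0, th1 = params
        return expansion_expected(tau, th0, th1, i_max) - freq

    starts = [
        (max(mean - 0.1, 0.05), 0.1, max(10.0 * mean, 10.0)),
        (max(mean, 0.1), 0.01, 100.0),
        (mean / 2.0 + 0.05, mean / 2.0 + 0.01, max(5.0 * mean, 5.0)),
        (0.05, max(mean, 0.05), max(mean, 1.0)),
    ]
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0=np.array(x0),
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise UndefinedStatisticError("expansion fit failed to converge")
    tau, th0, th1 = best.x
    expected = expansion_expected(tau, th0, th1, i_max)
    return MismatchFit(
        observed=obs.astype(int),
        expected=expected,
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th1),
        sse=float(2.0 * best.cost),
        n_pairs=n_pairs,
        boundary=bool(tau < 1e-3),
    )


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def tau_to_generations(tau: float, L: int, per_site_rate: float) -> float:
    """Expansion age in generations from tau = 2ut, u = L * per-site rate."""
    if tau <= 0 or L <= 0 or per_site_rate <= 0:
        raise ValidationError("tau, L and rate must be positive")
    u = L * per_site_rate
    return tau / (2.0 * u)


def dating_table(
    tau: float, L: int, rates, generation_years: float = 1.0
) -> pd.DataFrame:
    """Expansion dating across a range of per-site substitution rates."""
    rows = []
    for r in rates:
        t = tau_to_generations(tau, L, r)
        rows.append({"per_site_rate": r, "generations": t,
                     "years": t * generation_years})
    return pd.DataFrame(rows)


def theta_to_nf(theta: float, L: int, per_site_rate: float) -> float:
    """Female effective size from a per-sequence theta of the maternal
    marker: Nf = theta / (2 L r), with r the per-site per-generation rate."""
    if per_site_rate <= 0 or L <= 0:
        raise ValidationError("rate and L must be positive")
    if theta < 0:
        raise ValidationError("theta must be non-negative")
    return theta / (2.0 * L * per_site_rate)


def nf_table(thetas: dict[str, float], L: int, rates) -> pd.DataFrame:
    """Effective-size conversions per unit; Nf rounded for reporting, raw
    retained."""
    rows = []
    for unit, theta in thetas.items():
        for r in rates:
            nf = theta_to_nf(theta, L, r)
            rows.append({
                "unit": unit, "theta": theta, "per_site_rate": r,
                "Nf_raw": nf, "Nf": int(round(nf)),
            })
    return pd.DataFrame(rows)


def migrants_per_generation(m: float, mu: float, theta_receiver: float | None = None):
    """Mt = m/mu; if the receiving deme's theta is given, also the effective
    migrant count theta * Mt / 2."""
    if mu <= 0:
        raise ValidationError("mu must be positive")
    if m < 0:
        raise ValidationError("m must be non-negative")
    mt = m / mu
    if theta_receiver is None:
        return mt
    return mt, theta_receiver * mt / 2.0


def growth_trajectory(theta1: float, G: float, times) -> np.ndarray:
    """theta_t = theta1 * exp(-G t), t measured back in mutational units."""
    if theta1 <= 0:
        raise ValidationError("theta1 must be positive")
    t = np.asarray(times, dtype=float)
    return theta1 * np.exp(-G * t)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact null
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> dict:
    """Wilcoxon signed-rank test of median(diffs) = 0.

    Zero differences are dropped (flagged).  For <= ``exact_max_n``
    informative values the null distribution of W+ is computed exactly by
    enumeration over all sign assignments (dynamic programming on doubled
    midranks, valid under ties); beyond that, a normal approximation with
    continuity correction is used.  Returns one-tailed p in both directions
    and the two-tailed p.
    """
    d = np.asarray(diffs, dtype=float)
    ties_at_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return {"p_greater": 1.0, "p_less": 1.0, "p_two": 1.0,
                "n_informative": 0, "zeros_dropped": ties_at_zero,
                "W_plus": 0.0}
    ranks2 = np.rint(rankdata(np.abs(d)) * 2).astype(int)  # doubled midranks
    w_plus2 = int(ranks2[d > 0].sum())
    total2 = int(ranks2.sum())
    if n <= exact_max_n:
        # DP over achievable doubled-rank sums; counts of sign assignments
        dist = np.zeros(total2 + 1)
        dist[0] = 1.0
        for r in ranks2:
            nxt = dist.copy()
            nxt[r:] += dist[: total2 + 1 - r]
            dist = nxt
        dist /= dist.sum()
        p_greater = float(dist[w_plus2:].sum())
        p_less = float(dist[: w_plus2 + 1].sum())
    else:
        mean = total2 / 2.0
        # each rank contributes r_i^2/4 to Var(W+) under random signs
        var = float(np.sum((ranks2 / 2.0) ** 2)) / 4.0
        sd = np.sqrt(var)
        p_greater = float(norm.sf((w_plus2 / 2.0 - mean / 2.0 - 0.5) / sd))
        p_less = float(norm.cdf((w_plus2 / 2.0 - mean / 2.0 + 0.5) / sd))
    p_two = min(1.0, 2.0 * min(p_greater, p_less))
    return {
        "p_greater": min(p_greater, 1.0),
        "p_less": min(p_less, 1.0),
        "p_two": p_two,
        "n_informative": n,
        "zeros_dropped": ties_at_zero,
        "W_plus": w_plus2 / 2.0,
    }


# ---------------------------------------------------------------------------
# bottleneck heterozygosity test
# ---------------------------------------------------------------------------

def _unbiased_he(alleles: np.ndarray) -> float:
    n = len(alleles)
    _, cnt = np.unique(alleles, return_counts=True)
    p = cnt / n
    return (1.0 - float(np.sum(p**2))) * n / (n - 1.0)


def _ewens_expected_k(theta: float, n: int) -> float:
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


@lru_cache(maxsize=4096)
def _solve_theta_for_k(n_genes: int, k: int, model: str,
                       ps: float, dg: float) -> float:
    """theta such that the equilibrium expected allele count equals k.

    Closed-form (Ewens) for IAM; deterministic simulation bisection for
    stepwise models.  Internally seeded from (n, k, model) so results do not
    depend on call order.
    """
    if k <= 1:
        return 0.0
    if k >= n_genes:
        k = n_genes - 1e-9  # type: ignore[assignment]
    if model == "iam":
        lo, hi = 1e-6, 1e6
        f = lambda th: _ewens_expected_k(th, n_genes) - k  # noqa: E731
        return float(brentq(f, lo, hi, xtol=1e-10))

    def mean_k(log_theta: float, rng_seed: int, reps: int = 150) -> float:
        rng = np.random.default_rng(rng_seed)
        theta = float(np.exp(log_theta))
        ks = [
            len(np.unique(sample_stepwise(n_genes, theta, rng, ps=ps, dg=dg)))
            for _ in range(reps)
        ]
        return float(np.mean(ks))

    model_code = {"smm": 1, "tpm": 2}.get(model, 0)
    base_seed = (n_genes * 1_000_003 + int(k) * 7919 + model_code * 104_729
                 + int(ps * 1000) * 31 + int(dg * 100)) % (2**31 - 1) or 1
    lo, hi = np.log(1e-3), np.log(5e3)
    for it in range(18):
        mid = (lo + hi) / 2.0
        if mean_k(mid, base_seed + it) < k:
            lo = mid
        else:
            hi = mid
    return float(np.exp((lo + hi) / 2.0))


def equilibrium_heterozygosity(
    n_genes: int,
    k: int,
    model: str,
    n_reps: int = 1000,
    seed: int | None = None,
    ps: float = 1.0,
    dg: float = 3.5,
) -> tuple[float, float]:
    """(mean, sd) of expected heterozygosity in equilibrium samples of the
    same size conditioned on the observed allele count k.

    Simulates at the theta whose expected allele count is k and keeps
    replicates with exactly k alleles (rejection); falls back to all
    replicates if fewer than 20 match within the attempt budget.
    """
    if model not in ("iam", "smm", "tpm"):
        raise ValidationError(f"unknown model {model!r}")
    if k < 2:
        raise UndefinedStatisticError("monomorphic locus is uninformative")
    theta = _solve_theta_for_k(n_genes, k, model, ps, dg)
    rng = np.random.default_rng(seed)
    matched, fallback = [], []
    attempts = 0
    max_attempts = 25 * n_reps
    while len(matched) < n_reps and attempts < max_attempts:
        if model == "iam":
            sample = sample_iam(n_genes, theta, rng)
        else:
            sample = sample_stepwise(
                n_genes, theta, rng, ps=(1.0 if model == "smm" else ps), dg=dg
            )
        attempts += 1
        he = _unbiased_he(sample)
        fallback.append(he)
        if len(np.unique(sample)) == k:
            matched.append(he)
    vals = np.asarray(matched if len(matched) >= 20 else fallback)
    return float(vals.mean()), float(vals.std(ddof=1))


@dataclass
class BottleneckResult:
    population: str
    model: str
    per_locus: pd.DataFrame
    p_excess: float
    p_deficiency: float
    p_two: float
    n_replicates: int
    status: str = "ok"


def bottleneck_test(
    panel: GenotypePanel,
    population: str,
    model: str = "smm",
    n_reps: int = 1000,
    seed: int | None = None,
    tpm_ps: float = 0.9,
    tpm_dg: float = 3.5,
) -> BottleneckResult:
    """Heterozygosity excess/deficiency test for one population.

    Per polymorphic locus, the observed unbiased expected heterozygosity is
    compared with the equilibrium distribution of He conditioned on the
    observed allele count under the chosen mutation model; significance from
    a Wilcoxon signed-rank on the per-locus differences (exact null for
    <= 25 informative loci).  A heterozygosity DEFICIT (p_deficiency small)
    is the expansion signal; an EXCESS indicates a recent bottleneck.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus in panel.loci_ids:
        alleles = panel.population_alleles(population, locus)
        if alleles.size < 4:
            continue
        k = len(np.unique(alleles))
        if k < 2:
            rows.append({"locus": locus, "n_genes": int(alleles.size), "k": k,
                         "He_obs": 0.0, "Heq_mean": np.nan, "Heq_sd": np.nan,
                         "std_diff": np.nan, "informative": False})
            continue
        he_obs = _unbiased_he(alleles)
        heq_mean, heq_sd = equilibrium_heterozygosity(
            int(alleles.size), k, model, n_reps=n_reps,
            seed=int(rng.integers(1, 2**31 - 1)), ps=tpm_ps, dg=tpm_dg,
        )
        rows.append({
            "locus": locus, "n_genes": int(alleles.size), "k": k,
            "He_obs": he_obs, "Heq_mean": heq_mean, "Heq_sd": heq_sd,
            "std_diff": (he_obs - heq_mean) / heq_sd if heq_sd > 0 else np.nan,
            "informative": True,
        })
    per_locus = pd.DataFrame(rows)
    informative = per_locus[per_locus.get("informative", pd.Series(dtype=bool)) == True]  # noqa: E712
    status = "ok"
    if len(informative) < 4:
        status = "too-few-informative-loci"
    if len(informative) == 0:
        return BottleneckResult(population, model, per_locus, 1.0, 1.0, 1.0,
                                n_reps, status)
    d = (informative["He_obs"] - informative["Heq_mean"]).to_numpy()
    w = wilcoxon_signed_rank(d)
    return BottleneckResult(
        population=population,
        model=model,
        per_locus=per_locus,
        p_excess=w["p_greater"],
        p_deficiency=w["p_less"],
        p_two=w["p_two"],
        n_replicates=n_reps,
        status=status,
    )


# ---------------------------------------------------------------------------
# M-ratio
# ---------------------------------------------------------------------------

@dataclass
class MRatioResult:
    population: str
    per_locus: pd.DataFrame
    mean_m: float
    mc: float | None = None
    decline_inferred: bool | None = None
    sim_params: dict = field(default_factory=dict)


def m_ratio(panel: GenotypePanel, population: str) -> MRatioResult:
    """Per-locus M = k/(rho+1) with rho the allele-size range in repeat
    units, and the population mean over loci with data."""
    rows = []
    for locus in panel.loci_ids:
        alleles = panel.population_alleles(population, locus)
        if alleles.size == 0:
            continue
        motif = panel.motif_length_of.get(locus)
        if motif is None:
            raise ValidationError(f"no motif length for locus {locus!r}")
        k = len(np.unique(alleles))
        span = int(alleles.max() - alleles.min())
        if span % motif != 0:
            raise ValidationError(
                f"allele-size range {span} at {locus!r} not divisible by "
                f"motif {motif}: allele binning misconfigured"
            )
        rho = span // motif
        rows.append({"locus": locus, "k": k, "rho": rho, "M": k / (rho + 1.0)})
    if not rows:
        raise UndefinedStatisticError(f"no data for population {population!r}")
    per_locus = pd.DataFrame(rows)
    return MRatioResult(
        population=population,
        per_locus=per_locus,
        mean_m=float(per_locus["M"].mean()),
    )


def critical_m(
    n_genes: int,
    theta: float,
    ps: float = 0.9,
    dg: float = 3.5,
    n_sims: int = 10_000,
    seed: int | None = None,
    percentile: float = 5.0,
) -> float:
    """Critical M value: the given percentile (default 5th) of the
    equilibrium M distribution simulated under the two-phase model.

    ``theta`` must be supplied: it is not estimable from the ratio itself
    and dominates Mc.  A mean observed M below Mc indicates decline.
    """
    if theta <= 0:
        raise ValidationError("theta must be positive")
    if not 0 <= ps <= 1:
        raise ValidationError("ps must be in [0, 1]")
    if n_sims < 100:
        raise ValidationError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    ms = np.empty(n_sims)
    for s in range(n_sims):
        sample = sample_stepwise(n_genes, theta, rng, ps=ps, dg=dg)
        k = len(np.unique(sample))
        rho = int(sample.max() - sample.min())
        ms[s] = k / (rho + 1.0)
    return float(np.percentile(ms, percentile))


def m_ratio_with_critical(
    panel: GenotypePanel,
    population: str,
    theta: float,
    ps: float = 0.9,
    dg: float = 3.5,
    n_sims: int = 10_000,
    seed: int | None = None,
) -> MRatioResult:
    """M-ratio test: observed mean M against the simulated critical value
    at the population's median gene-copy count."""
    res = m_ratio(panel, population)
    n_genes = int(np.median([
        panel.population_alleles(population, loc).size
        for loc in panel.loci_ids
        if panel.population_alleles(population, loc).size > 0
    ]))
    mc = critical_m(n_genes, theta, ps=ps, dg=dg, n_sims=n_sims, seed=seed)
    res.mc = mc
    res.decline_inferred = bool(res.mean_m < mc)
    res.sim_params = {"theta": theta, "ps": ps, "dg": dg, "n_sims": n_sims,
                      "n_genes": n_genes}
    return res


# ---------------------------------------------------------------------------
# non-Bayesian theta estimate (pipeline convenience)
# ---------------------------------------------------------------------------

def theta_pi_per_sequence(panel: SequencePanel) -> float:
    """Per-sequence theta estimated as the mean pairwise difference count.

    A simple moment estimator provided so the conversion chain can run
    end-to-end on raw data; it is NOT a genealogy-aware (MCMC) estimate and
    is labelled as such in pipeline outputs.
    """
    hist = mismatch_observed(panel)
    n_pairs = hist.sum()
    return float(np.sum(np.arange(len(hist)) * hist) / n_pairs)
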