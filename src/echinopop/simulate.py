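"""Coalescent synthetic-data generator.

Generates aligned haploid sequence panels and diploid microsatellite panels
with known ground truth: Hudson-style coalescent genealogies (via msprime)
under constant size, exponential growth, sudden size changes and
island-model migration; mutations are placed on branches under
infinite-sites or finite-sites (Jukes-Cantor) models for sequences and
IAM / SMM / TPM models for microsatellites.

Time is handled in coalescent units at the interface (one unit = N
generations for the haploid marker, 2N for the diploid one), so that a
sudden expansion at time ``t`` with per-sequence theta produces a mismatch
expansion age of ``tau = theta * t`` directly.

Also exposes fast single-locus equilibrium samplers (Hoppe urn for the
infinite-allele model; an internal Kingman coalescent with stepwise/two-phase
mutation) used by the bottleneck and M-ratio machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from echinopop.errors import ValidationError
from echinopop.io import (
    GenotypePanel,
    GeoDistanceMatrix,
    SequencePanel,
    write_genotype_panel,
    write_geo_distances,
    write_sequence_panel,
)

_N_REF = 10_000  # reference population size; all rates are derived from theta
_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated dataset.

    ``theta`` is per site for sequences and per locus for microsatellites
    (both on the pairwise-difference scale: E[pair differences] = theta).
    ``growth`` is an exponential growth rate per coalescent time unit;
    ``bottleneck`` = (time in coalescent units, ancestral/current size ratio)
    encodes a sudden size change (ratio < 1 = expansion looking backwards);
    ``migration`` is the island-model 2Nm between each pair of demes.
    """

    n_demes: int = 1
    samples_per_deme: int | list[int] = 20
    theta: float = 0.001
    sequence_length: int = 657
    growth: float = 0.0
    bottleneck: tuple[float, float] | None = None
    migration: float = 0.0
    mutation_model: str = "finite_sites_jc"
    n_loci: int = 8
    tpm_ps: float = 0.9
    tpm_dg: float = 3.5
    inbreeding: float = 0.0
    basin_of_deme: list[int] | None = None
    migration_between: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory: no unseeded simulation")
        if self.theta < 0 or self.migration < 0:
            raise ValidationError("rates must be non-negative")

    def sample_sizes(self) -> list[int]:
        if isinstance(self.samples_per_deme, int):
            return [self.samples_per_deme] * self.n_demes
        if len(self.samples_per_deme) != self.n_demes:
            raise ValidationError("samples_per_deme length != n_demes")
        return list(self.samples_per_deme)


def _demography(config: SimulationConfig, ploidy: int) -> msprime.Demography:
    n_ref = _N_REF
    demo = msprime.Demography()
    # growth rate per generation; one coalescent unit = ploidy * n_ref gens
    g_per_gen = config.growth / (ploidy * n_ref)
    for d in range(config.n_demes):
        demo.add_population(
            name=f"pop_{d}", initial_size=n_ref, growth_rate=g_per_gen
        )
    if config.n_demes > 1 and config.migration > 0:
        # island model: 2Nm = migration  =>  m per generation, split over
        # the n-1 possible source demes
        m = config.migration / (2.0 * n_ref) / max(config.n_demes - 1, 1)
        if config.basin_of_deme is None:
            demo.set_symmetric_migration_rate(
                [f"pop_{d}" for d in range(config.n_demes)], m
            )
        else:
            # hierarchical: within-basin `migration`, between-basin
            # `migration_between` (both as 2Nm totals)
            basins = config.basin_of_deme
            mb = (config.migration_between or 0.0) / (2.0 * n_ref) \
                / max(config.n_demes - 1, 1)
            for a in range(config.n_demes):
                for b in range(config.n_demes):
                    if a == b:
                        continue
                    rate = m if basins[a] == basins[b] else mb
                    if rate > 0:
                        demo.set_migration_rate(f"pop_{a}", f"pop_{b}", rate)
    if config.bottleneck is not None:
        t_cau, ratio = config.bottleneck
        t_gen = t_cau * ploidy * n_ref
        for d in range(config.n_demes):
            demo.add_population_parameters_change(
                time=t_gen,
                population=f"pop_{d}",
                initial_size=max(n_ref * ratio, 1.0),
                growth_rate=0.0,
            )
    demo.sort_events()
    return demo


def _ancestry(config: SimulationConfig, ploidy: int, msp_seed: int,
              num_replicates: int | None = None):
    demo = _demography(config, ploidy)
    sizes = config.sample_sizes()
    samples = {f"pop_{d}": sizes[d] for d in range(config.n_demes)}
    return msprime.sim_ancestry(
        samples=samples,
        demography=demo,
        ploidy=ploidy,
        sequence_length=config.sequence_length if ploidy == 1 else 1,
        recombination_rate=0,
        random_seed=msp_seed,
        num_replicates=num_replicates,
    )


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def simulate_sequences(config: SimulationConfig):
    """Simulate an aligned haploid sequence panel.

    Returns (SequencePanel, truth) where truth records the genealogy-level
    quantities (segregating sites, TMRCA in coalescent units, total branch
    length) alongside the input parameters.
    """
    if config.mutation_model not in ("infinite_sites", "finite_sites_jc"):
        raise ValidationError(f"bad sequence model {config.mutation_model!r}")
    rng = np.random.default_rng(config.seed)
    msp_seed = int(rng.integers(1, 2**31 - 1))
    mut_seed = int(rng.integers(1, 2**31 - 1))
    ts = _ancestry(config, ploidy=1, msp_seed=msp_seed)
    L = config.sequence_length
    mu_site = config.theta / (2.0 * _N_REF)  # haploid: theta = 2 N mu
    reference = rng.choice(_BASES, size=L)
    seqs = np.tile(reference, (ts.num_samples, 1))

    if config.mutation_model == "finite_sites_jc":
        mts = msprime.sim_mutations(
            ts, rate=mu_site, model=msprime.JC69(), random_seed=mut_seed,
            discrete_genome=True,
        )
        for var in mts.variants():
            site = int(var.site.position)
            alleles = np.array(var.alleles, dtype="U1")
            seqs[:, site] = alleles[var.genotypes]
    else:
        mts = msprime.sim_mutations(
            ts, rate=mu_site, model=msprime.BinaryMutationModel(),
            random_seed=mut_seed, discrete_genome=False,
        )
        if mts.num_sites > L:
            raise ValidationError(
                f"{mts.num_sites} segregating sites do not fit in L={L} "
                "under the infinite-sites model"
            )
        used: set[int] = set()
        for var in mts.variants():
            site = int(var.site.position) % L
            while site in used:
                site = (site + 1) % L
            used.add(site)
            anc = seqs[0, site]
            derived = _BASES[(int(np.flatnonzero(_BASES == anc)[0]) + 1) % 4]
            derived_mask = var.genotypes != 0
            seqs[derived_mask, site] = derived

    sizes = config.sample_sizes()
    sample_ids, population_of = [], {}
    k = 0
    for d, n_d in enumerate(sizes):
        for _ in range(n_d):
            sid = f"s{k:04d}"
            sample_ids.append(sid)
            population_of[sid] = f"pop_{d}"
            k += 1
    region_of = {f"pop_{d}": "sim" for d in range(config.n_demes)}
    panel = SequencePanel(
        sample_ids=sample_ids,
        sequences=["".join(row) for row in seqs],
        population_of=population_of,
        region_of=region_of,
    )
    first = ts.first()
    truth = {
        "segregating_sites": int(mts.num_sites),
        "tmrca_coalescent_units": float(first.time(first.root)) / _N_REF,
        "total_branch_length_cau": float(first.total_branch_length) / _N_REF,
        "theta_site": config.theta,
        "theta_sequence": config.theta * L,
    }
    return panel, truth


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------

def _mutate_states_on_tree(tree, n_samples, mu, model, rng, ps, dg, root_state):
    """Evolve integer allele states from the root down one genealogy."""
    state = {}
    next_new = [root_state + 10_000]  # IAM novel-allele counter
    for root in tree.roots:
        state[root] = root_state
        stack = [root]
        while stack:
            parent = stack.pop()
            for child in tree.children(parent):
                bl = tree.branch_length(child)
                n_mut = rng.poisson(mu * bl)
                s = state[parent]
                if model == "iam":
                    if n_mut > 0:
                        s = next_new[0]
                        next_new[0] += 1
                else:
                    for _ in range(n_mut):
                        step = 1 if (model == "smm" or rng.random() < ps) \
                            else int(rng.geometric(1.0 / dg))
                        s += step if rng.random() < 0.5 else -step
                state[child] = s
                stack.append(child)
    return np.array([state[u] for u in range(n_samples)])


def simulate_microsatellites(config: SimulationConfig):
    """Simulate a diploid microsatellite genotype panel.

    Each locus gets an independent genealogy from the same demographic
    model; allele states evolve by IAM, SMM or TPM along branches.  Allele
    sizes are reported in bp with a 2-bp motif (state 100 repeat units ->
    200 bp).  ``config.inbreeding`` F makes an individual's two gene copies
    identical by descent with probability F, per locus.
    """
    if config.mutation_model not in ("iam", "smm", "tpm"):
        raise ValidationError(f"bad microsatellite model {config.mutation_model!r}")
    rng = np.random.default_rng(config.seed)
    msp_seed = int(rng.integers(1, 2**31 - 1))
    reps = _ancestry(config, ploidy=2, msp_seed=msp_seed,
                     num_replicates=config.n_loci)
    mu = config.theta / (4.0 * _N_REF)  # diploid: theta = 4 N mu
    root_units = 100
    motif = 2
    sizes = config.sample_sizes()
    n_ind = sum(sizes)
    alleles = np.zeros((n_ind, config.n_loci, 2), dtype=int)
    for li, ts in enumerate(reps):
        tree = ts.first()
        states = _mutate_states_on_tree(
            tree, ts.num_samples, mu, config.mutation_model, rng,
            config.tpm_ps, config.tpm_dg, root_units,
        )
        states = np.maximum(states, 1)
        bp = states * motif
        geno = bp.reshape(n_ind, 2)
        if config.inbreeding > 0:
            ibd = rng.random(n_ind) < config.inbreeding
            geno[ibd, 1] = geno[ibd, 0]
        alleles[:, li, :] = geno
    sample_ids, population_of = [], {}
    k = 0
    for d, n_d in enumerate(sizes):
        for _ in range(n_d):
            sid = f"i{k:04d}"
            sample_ids.append(sid)
            population_of[sid] = f"pop_{d}"
            k += 1
    region_of = {f"pop_{d}": "sim" for d in range(config.n_demes)}
    loci = [f"loc_{j + 1}" for j in range(config.n_loci)]
    panel = GenotypePanel(
        sample_ids=sample_ids,
        loci_ids=loci,
        alleles=alleles,
        population_of=population_of,
        region_of=region_of,
        motif_length_of={l: motif for l in loci},
    )
    truth = {"theta_locus": config.theta, "model": config.mutation_model}
    return panel, truth


# ---------------------------------------------------------------------------
# fast single-locus equilibrium samplers
# ---------------------------------------------------------------------------

def sample_iam(n_genes: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Equilibrium infinite-allele sample via the Hoppe urn (exact Ewens)."""
    alleles = np.empty(n_genes, dtype=int)
    next_allele = 0
    for i in range(n_genes):
        if rng.random() < theta / (theta + i):
            alleles[i] = next_allele
            next_allele += 1
        else:
            alleles[i] = alleles[rng.integers(0, i)]
    return alleles


def sample_stepwise(
    n_genes: int,
    theta: float,
    rng: np.random.Generator,
    ps: float = 1.0,
    dg: float = 3.5,
    root: int = 100,
) -> np.ndarray:
    """Equilibrium SMM/TPM sample from an internal Kingman coalescent.

    Times are in coalescent units (pair coalescence rate 1); mutations occur
    at rate theta/2 per lineage, so E[pair differences] = theta.  Returns
    allele sizes in repeat units.
    """
    n_nodes = 2 * n_genes - 1
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    times = np.zeros(n_nodes)
    active = list(range(n_genes))
    t = 0.0
    nxt = n_genes
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        times[nxt] = t
        blen[a] = t - times[a]
        blen[b] = t - times[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root_node = active[0]
    state = np.empty(n_nodes, dtype=int)
    state[root_node] = root
    children: dict[int, list[int]] = {}
    for u in range(n_nodes):
        if parent[u] >= 0:
            children.setdefault(parent[u], []).append(u)
    stack = [root_node]
    half_theta = theta / 2.0
    while stack:
        u = stack.pop()
        for c in children.get(u, []):
            n_mut = rng.poisson(half_theta * blen[c])
            s = state[u]
            for _ in range(n_mut):
                step = 1 if (ps >= 1.0 or rng.random() < ps) \
                    else int(rng.geometric(1.0 / dg))
                s += step if rng.random() < 0.5 else -step
            state[c] = s
            stack.append(c)
    return state[:n_genes]


# ---------------------------------------------------------------------------
# study-like dataset
# ---------------------------------------------------------------------------

_STUDY_REGIONS = [("atlantic", 2), ("west_mediterranean", 9), ("east_mediterranean", 4)]


def make_study_like_dataset(seed: int, out_dir=None):
    """A full synthetic survey: 15 populations in three regions (2 Atlantic,
    9 western Mediterranean, 4 eastern Mediterranean), 8-30 individuals per
    population, 657-bp low-diversity sequences with between-region divergence
    and a recent sudden expansion, 8 microsatellite loci, and a sea-distance
    matrix consistent with the regional layout.

    Returns (sequence_panel, genotype_panel, geo, truth); if ``out_dir`` is
    given, also writes FASTA + population map, GenePop + motif table, and the
    distance CSV there.
    """
    rng = np.random.default_rng(seed)
    n_demes = sum(k for _, k in _STUDY_REGIONS)
    sizes = [int(x) for x in rng.integers(8, 31, size=n_demes)]

    seq_cfg = SimulationConfig(
        n_demes=n_demes,
        samples_per_deme=sizes,
        theta=0.0009,          # per site: low-pi regime (pi ~ 1e-3)
        sequence_length=657,
        migration=8.0,         # within-survey connectivity
        bottleneck=(0.05, 0.02),  # recent sudden expansion
        mutation_model="finite_sites_jc",
        seed=int(rng.integers(1, 2**31 - 1)),
    )
    # regional divergence: overlay region-private substitutions after the
    # island-model panel, so between-region pairs differ by extra fixed sites
    seq_panel, seq_truth = simulate_sequences(seq_cfg)

    region_names = []
    for name, k in _STUDY_REGIONS:
        region_names += [name] * k
    pop_names = []
    counter = {r: 0 for r, _ in _STUDY_REGIONS}
    for r in region_names:
        counter[r] += 1
        pop_names.append(f"{r[:4]}_{counter[r]}")
    rename = {f"pop_{d}": pop_names[d] for d in range(n_demes)}
    population_of = {s: rename[seq_panel.population_of[s]] for s in seq_panel.sample_ids}
    region_of = {pop_names[d]: region_names[d] for d in range(n_demes)}

    # region-diagnostic substitutions (1 fixed site per non-reference region)
    L = seq_cfg.sequence_length
    marker_sites = rng.choice(L, size=2, replace=False)
    region_edit = {
        "west_mediterranean": marker_sites[:1],
        "east_mediterranean": marker_sites[1:],
    }
    seqs = []
    for sid, seq in zip(seq_panel.sample_ids, seq_panel.sequences):
        region = region_of[population_of[sid]]
        if region in region_edit:
            arr = list(seq)
            for site in region_edit[region]:
                arr[site] = {"A": "G", "C": "T", "G": "A", "T": "C"}[arr[site]]
            seq = "".join(arr)
        seqs.append(seq)
    seq_panel = SequencePanel(seq_panel.sample_ids, seqs, population_of, region_of)

    msat_cfg = SimulationConfig(
        n_demes=n_demes,
        samples_per_deme=sizes,
        theta=5.0,
        migration=2.0,
        bottleneck=(0.15, 0.05),
        mutation_model="smm",
        n_loci=8,
        seed=int(rng.integers(1, 2**31 - 1)),
    )
    gen_panel, msat_truth = simulate_microsatellites(msat_cfg)
    gen_ids = gen_panel.sample_ids
    gen_pop_of = {s: rename[gen_panel.population_of[s]] for s in gen_ids}
    gen_panel = GenotypePanel(
        sample_ids=gen_ids,
        loci_ids=gen_panel.loci_ids,
        alleles=gen_panel.alleles,
        population_of=gen_pop_of,
        region_of=region_of,
        motif_length_of=gen_panel.motif_length_of,
    )

    # sea distances: populations placed along a coastline axis by region
    anchors = {"atlantic": 0.0, "west_mediterranean": 2000.0,
               "east_mediterranean": 4200.0}
    xs = []
    for d in range(n_demes):
        xs.append(anchors[region_names[d]] + 120.0 * counter_index(pop_names[d]))
    xs = np.asarray(xs)
    dist = np.abs(xs[:, None] - xs[None, :])
    geo = GeoDistanceMatrix(populations=pop_names, distances=dist)

    truth = {
        "seed": seed,
        "sample_sizes": sizes,
        "regions": dict(zip(pop_names, region_names)),
        "sequence": seq_truth,
        "microsatellite": msat_truth,
    }
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sequence_panel(seq_panel, out / "sequences.fasta", out / "_seq_popmap.csv")
        write_genotype_panel(gen_panel, out / "genotypes.gen", out / "_gen_popmap.csv")
        # one shared population map covering both marker panels
        combined = pd.concat([
            pd.read_csv(out / "_seq_popmap.csv"),
            pd.read_csv(out / "_gen_popmap.csv"),
        ])
        combined.to_csv(out / "popmap.csv", index=False)
        (out / "_seq_popmap.csv").unlink()
        (out / "_gen_popmap.csv").unlink()
        pd.DataFrame(
            {"locus": gen_panel.loci_ids,
             "motif_length": [gen_panel.motif_length_of[l] for l in gen_panel.loci_ids]}
        ).to_csv(out / "motifs.csv", index=False)
        write_geo_distances(geo, out / "geo_distances.csv")
        pd.DataFrame([
            {"key": "seed", "value": seed},
            {"key": "theta_site_seq", "value": seq_cfg.theta},
            {"key": "theta_locus_msat", "value": msat_cfg.theta},
        ]).to_csv(out / "truth.csv", index=False)
    return seq_panel, gen_panel, geo, truth


def counter_index(pop_name: str) -> int:
    return int(pop_name.rsplit("_", 1)[1])
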