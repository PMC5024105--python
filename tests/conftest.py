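import numpy as np
import pytest

from echinopop.io import GenotypePanel, SequencePanel


@pytest.fixture
def toy_seq_panel():
    """Three populations, small alignment with known haplotype structure."""
    seqs = {
        "a1": "AAAAA", "a2": "AAAAA", "a3": "AAAAT",
        "b1": "AAATT", "b2": "AAATT",
        "c1": "AATTT", "c2": "AAAAA",
    }
    pop = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B",
           "c1": "C", "c2": "C"}
    return SequencePanel(
        sample_ids=list(seqs),
        sequences=list(seqs.values()),
        population_of=pop,
        region_of={"A": "west", "B": "west", "C": "east"},
    )


def make_genotype_panel(geno_by_pop, motif=2):
    """Build a GenotypePanel from {pop: [[(a,b) per locus] per individual]}."""
    sample_ids, alleles, pop_of = [], [], {}
    n_loci = len(next(iter(geno_by_pop.values()))[0])
    for pop, inds in geno_by_pop.items():
        for i, ind in enumerate(inds):
            sid = f"{pop}_{i}"
            sample_ids.append(sid)
            pop_of[sid] = pop
            alleles.append([list(pair) for pair in ind])
    loci = [f"L{j}" for j in range(n_loci)]
    return GenotypePanel(
        sample_ids=sample_ids,
        loci_ids=loci,
        alleles=np.array(alleles),
        population_of=pop_of,
        region_of={p: "r" for p in geno_by_pop},
        motif_length_of={l: motif for l in loci},
    )


@pytest.fixture
def hetero_panel():
    """One population, all individuals heterozygous A/B at two loci."""
    return make_genotype_panel(
        {"P": [[(100, 102), (200, 204)] for _ in range(6)]}
    )


@pytest.fixture(scope="session")
def study_dataset():
    from echinopop.simulate import make_study_like_dataset

    return make_study_like_dataset(11)
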