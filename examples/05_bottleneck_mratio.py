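"""Microsatellite demography: heterozygosity tests and the M-ratio.

Runs the IAM and SMM heterozygosity excess/deficiency tests (Wilcoxon
signed-rank over loci against equilibrium expectations conditioned on the
observed allele counts) and the M-ratio against a simulated critical value.
"""

from echinopop.demography import bottleneck_test, m_ratio_with_critical
from echinopop.simulate import make_study_like_dataset

_, gen, _, _ = make_study_like_dataset(seed=11)
pop = gen.populations()[0]

for model in ("iam", "smm"):
    res = bottleneck_test(gen, pop, model=model, n_reps=300, seed=5)
    print(f"{pop} {model.upper()}: p_excess = {res.p_excess:.3f}, "
          f"p_deficiency = {res.p_deficiency:.3f}  [{res.status}]")

m = m_ratio_with_critical(gen, pop, theta=5.0, n_sims=2000, seed=6)
verdict = "decline inferred" if m.decline_inferred else "no decline"
print(f"{pop} M-ratio: mean M = {m.mean_m:.2f} vs Mc = {m.mc:.2f} -> {verdict}")
# A significant heterozygosity DEFICIENCY is the footprint of expansion
# (allele numbers recover faster than He); an EXCESS would indicate a
# recent bottleneck; mean M above Mc means no size-reduction signal.
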