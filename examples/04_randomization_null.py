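"""Location-randomization null for developmental-gene containment.

Are pathogenic CNVs more likely to contain a developmental gene than
length- and chromosome-matched random intervals? Each permutation keeps
every CNV's length and chromosome and redraws its start uniformly; the
Z score measures how far the real calls sit above that null.
"""

from dosagescope import (
    Interpretation,
    SimulationConfig,
    fraction_with_flagged_gene,
    permutation_test,
    simulate_cnvs,
    simulate_genome,
)

config = SimulationConfig(seed=11)
build, genes = simulate_genome(config)
cnvs = simulate_cnvs(genes, build, config)
pathogenic = [c for c in cnvs if c.interpretation is Interpretation.PATHOGENIC]

statistic = fraction_with_flagged_gene(genes, "developmental")
result = permutation_test(statistic, pathogenic, build, n_reps=1000, seed=11)

print(f"observed: {100 * result.observed:.1f}% of {len(pathogenic)} pathogenic "
      "CNVs contain a developmental gene")
print(f"null:     mean {100 * result.null_mean:.1f}%, "
      f"max over {result.n_reps} randomizations {100 * result.null_max:.1f}%")
print(f"Z = {result.z:.1f}, empirical p = {result.p_empirical:.4g}")

# A Z well above 3 with the observed value beating every randomization
# says the excess of developmental genes in pathogenic CNVs is not a
# length artefact: the calls are anchored on dosage-sensitive loci.
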