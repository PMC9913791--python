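"""Generate a synthetic PDX cohort and inspect its structure.

The generator emulates a five-model PDX study with vehicle and decitabine
arms: EPIC-like beta values with a 1099-CpG CIMP panel, NB-distributed RNA
counts, four A/B compartment tracks over a 50 kb-binned toy genome, and
survival / flow-cytometry tables. Truth tables ride along for testing.
"""

from epidac import CohortConfig, generate_cohort

config = CohortConfig(seed=1)
cohort = generate_cohort(config)

print(f"models: {config.model_names} (sensitive: {config.sensitive_models})")
print(f"beta matrix: {cohort.beta.beta.shape[0]} probes x "
      f"{cohort.beta.beta.shape[1]} samples")
print(f"CIMP panel: {len(cohort.annotation.cimp_probes)} probes, "
      f"EpiTOC panel: {len(cohort.annotation.epitoc_probes)} probes")
print(f"counts: {cohort.counts.shape[0]} genes x {cohort.counts.shape[1]} samples")
print(f"compartment tracks: {len(cohort.tracks)} samples x "
      f"{len(cohort.tracks[0])} bins of {config.bin_size} bp")
affected = cohort.beta_truth["probes"]["is_affected"]
print(f"treatment shifts {affected.sum()} probes "
      f"({100 * affected.mean():.0f}% of the array) by {config.global_hypo_effect}")
# Each printed size mirrors one input of the analysis; the truth tables say
# which probes and genes actually carry a treatment effect.
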