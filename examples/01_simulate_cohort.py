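"""Generate the default synthetic tri-omics cohort and look inside it.

47 subjects carrying five latent factors; genus-level 16S counts (compositional),
fecal and plasma metabolite panels with realistic per-feature missingness, and
a 10-outcome cardiometabolic risk panel driven by the factors and covariates.
"""

from crosstalknet import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(seed=7))

print("block shapes (subjects x features):")
for label, block in cohort.blocks.items():
    print(f"  {label:>6}: {block.data.shape}")

fecal_missing = cohort.blocks["fecal"].missing_fraction()
plasma_missing = cohort.blocks["plasma"].missing_fraction()
print(f"fecal features with >20% missing cells:  {(fecal_missing > 0.20).sum()}")
print(f"plasma features with >20% missing cells: {(plasma_missing > 0.20).sum()}")

prevalence = (cohort.blocks["genus"].data > 0).mean(axis=0)
print(f"genera prevalent in >=10% of subjects:   {(prevalence >= 0.10).sum()}")

planted = {lab: len(t) for lab, t in cohort.truth.items()}
print(f"planted (factor-loading) features per block: {planted}")
print(
    "covariates: age %.1f +/- %.1f y, %.0f%% women, BMI %.1f +/- %.1f"
    % (
        cohort.covariates["age"].mean(),
        cohort.covariates["age"].std(),
        100 * cohort.covariates["sex"].mean(),
        cohort.covariates["BMI"].mean(),
        cohort.covariates["BMI"].std(),
    )
)
# The counts above are the panel sizes the preprocessing stage will filter:
# features above the missingness cut and genera below the prevalence cut drop.
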