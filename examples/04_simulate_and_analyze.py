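"""Simulate a PGT-SR cohort, classify every embryo from its CNV profile,
and run the risk-factor battery.

The generator uses the published cohort's structure: multinomial
segregation-mode model with female-sex, acrocentric-involvement and TAR1
effects, a per-carrier random intercept (SD 0.5), boundary jitter on CNV
calls and incidental aneuploidy. 600 carriers keep this example fast; the
full-scale run uses 2,253.
"""

from quadseg import (
    analyze_cohort,
    default_config_from_paper,
    load_chromosome_table,
    simulate_cohort,
    tabulate_modes,
)
from quadseg.pipeline import classified_table_from_simulation

chrom_table = load_chromosome_table()
cfg = default_config_from_paper(seed=42, n_carriers=600)
sim = simulate_cohort(cfg)
cohort = classified_table_from_simulation(sim, chrom_table)
print(f"{len(sim.carriers)} carriers, {len(cohort)} diagnosed embryos\n")

print(tabulate_modes(cohort).round(1), "\n")

res = analyze_cohort(cohort, candidates=("sex", "acr_involved", "tar1", "ts1", "age"))
print("univariate screen kept:", res["selected"])
fit = res["multivariable"]
if fit is not None:
    print("\nmultivariable random-intercept logistic (unbalanced vs alternate):")
    print(fit.coefficients[["or", "ci_low", "ci_high", "p"]].round(3))
    print(f"random-intercept SD: {fit.random_intercept_sd:.3f} "
          f"(generating value 0.5)")

cmh = res["cmh"]["sex_within_acr"]
print(f"\nCMH (female vs male within Acr-ch strata): "
      f"common OR {cmh.common_or:.3f}, p {cmh.p_value:.2g}, "
      f"homogeneity p {cmh.homogeneity_p:.2f}")
if res["roc"]:
    r = res["roc"]
    print(f"ROC of the fitted fixed effects: AUC {r.auc:.3f}, "
          f"sensitivity {r.sensitivity:.1%}, specificity {r.specificity:.1%}")
print("\nORs near their generating values (female 1.293, Acr-ch 1.208,")
print("TAR1 0.806) show the pipeline recovers the risk factors it assumes.")
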