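"""Phenotype-expression regression across a strain cohort.

Generates 8-strain cohorts whose heat-induced expression ratio follows the
thermotolerance phenotype (T_d ratio) with population R2 = 0.8 at 37°C and a
weaker 0.4 at 39°C, fits the per-temperature regressions, and shows how much
a single 8-strain R2 fluctuates around its population value.
"""

import numpy as np

import thermoscreen as ts

single = {}
for temp, planted_r2, seed in (("37C", 0.8, 11), ("39C", 0.4, 12)):
    cohort, _ = ts.simulate_phenotype_cohort(
        n_strains=8, slope=10.0, population_r2=planted_r2,
        temperature=temp, seed=seed,
    )
    res = ts.fit_phenotype_regression(cohort, gene="FMP21")
    single[temp] = res
    print(f"{temp}: one cohort -> slope = {res.slope:5.2f}, R2 = {res.r2:.3f} "
          f"(planted population R2 = {planted_r2}), n = {res.n} strains")

# with only 8 strains a single R2 is noisy; replicate cohorts show the
# planted separation between the two temperatures
print()
for temp, planted_r2 in (("37C", 0.8), ("39C", 0.4)):
    r2s = [
        ts.fit_phenotype_regression(
            ts.simulate_phenotype_cohort(
                n_strains=8, slope=10.0, population_r2=planted_r2,
                temperature=temp, seed=s,
            )[0]
        ).r2
        for s in range(100)
    ]
    print(f"{temp}: mean R2 over 100 cohorts = {np.mean(r2s):.3f} "
          f"(planted {planted_r2})")

report = ts.compare_temperatures(single)
print(f"\nthis draw's stronger association: {report.strongest[0]} — "
      "an 8-strain R2 can invert the true ordering, which is why the "
      "replicate-cohort averages above are the meaningful comparison")
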