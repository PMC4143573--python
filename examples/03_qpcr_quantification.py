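"""qPCR relative quantification through external standard curves.

Builds a 10-fold dilution standard series (1/10 .. 1/10000) for a target gene
and the ACT1 reference, fits standard curves, reads unknown samples off the
inverted curves, normalizes target by reference, and forms the heat/control
expression ratio.  A planted ratio of 8.5 must come back out.
"""

import thermoscreen as ts

EFFICIENCY = 0.95
PLANTED_RATIO = 8.5

# standard series + unknown Cq reads (zero noise: exact round trip)
target_series, cq_target_control = ts.simulate_qpcr(
    0.02, efficiency=EFFICIENCY, gene="FMP21"
)
_, cq_target_heat = ts.simulate_qpcr(0.02 * PLANTED_RATIO, efficiency=EFFICIENCY)
ref_series, cq_ref = ts.simulate_qpcr(0.5, efficiency=EFFICIENCY, gene="ACT1")

target_curve = ts.fit_standard_curve(target_series)
ref_curve = ts.fit_standard_curve(ref_series)
print(f"target curve: slope = {target_curve.slope:.4f} cycles/log10, "
      f"efficiency = {target_curve.efficiency:.3f}, R2 = {target_curve.r2:.4f}")
# slope near -3.32/-3.5 cycles per decade is the hallmark of a usable assay

ref_conc = ts.quantify(cq_ref, ref_curve)
heat = ts.normalized_rate(
    ts.quantify(cq_target_heat, target_curve), ref_conc, gene="FMP21", sample="heat"
)
control = ts.normalized_rate(
    ts.quantify(cq_target_control, target_curve), ref_conc,
    gene="FMP21", sample="control",
)
ratio = ts.expression_ratio(heat, control, strain="demo", temperature="39C")
print(f"heat/control expression ratio = {ratio.ratio:.3f} "
      f"(planted {PLANTED_RATIO})")

# reference-gene sanity check: ACT1 vs a second reference across conditions
report = ts.reference_stability(
    {"30C": 1.02, "39C": 0.97}, {"30C": 1.00, "39C": 1.01}
)
print(f"reference stability: max |log2 deviation| <= {report.tolerance}: "
      f"{'pass' if report.stable else 'FAIL'} "
      f"(mean log2 = {report.mean_log2:+.3f})")
# a stable reference pair sits within ~1.4-fold of each other everywhere
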