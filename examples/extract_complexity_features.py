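"""Compute plan-complexity metrics for a synthetic IMRT plan.

Builds a two-beam plan of moderate modulation, assembles the 91-entry
feature vector, and prints the headline geometric metrics.  These are the
inputs the passing-rate model consumes: larger small-aperture scores,
low-fluence fractions and penumbra fractions all signal a plan that is
harder to deliver and measure accurately.
"""

from virtualqa import DEFAULT_CONFIG, assemble_feature_vector
from virtualqa.synthetic import GeneratorConfig, generate_plan

plan = generate_plan(GeneratorConfig(seed=42, modulation=0.6),
                     plan_id="demo", n_beams=2)
fv = assemble_feature_vector(plan, DEFAULT_CONFIG)
vals = fv.as_dict()

print(f"plan {plan.plan_id}: {len(plan.beams)} beams, "
      f"{plan.total_mu:.0f} MU, feature vector length {len(fv)}")
for name in ["ciao_area_cm2", "perimeter_cm", "duty_cycle_mu_per_cgy",
             "small_aperture_lt_5mm", "small_aperture_lt_20mm",
             "fluence_lt_50pct", "irregularity_outside_5cm",
             "shape_irregularity", "penumbra_fraction", "mean_gap_mm"]:
    print(f"  {name:28s} {vals[name]:8.3f}")
print("A fraction near 1 for small_aperture_lt_5mm or penumbra_fraction "
      "marks a heavily modulated beam; CIAO area and perimeter describe "
      "the overall irradiated outline.")
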