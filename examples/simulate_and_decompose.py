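"""Simulate a mature wild-type granule population and decompose it.

Generates three seeded Coulter-style replicates (10⁵ granules each) from
the mature wild-type preset (A peak 19 μm, B volume-mean 6 μm, B content
40%), fits the normal + log-normal mixture to each, and prints the derived
phenotype metrics next to the generating truth.
"""

import numpy as np

from starchgran import (
    derive_metrics,
    make_preset,
    select_model,
    simulate_replicate_set,
)

spec = make_preset("WT_mature")
replicates = simulate_replicate_set(spec, n_reps=3, seed=1)

print("replicate  A diam (um)  B diam (um)  B content (%)")
rows = []
for dist in replicates:
    fit = select_model(dist)
    m = derive_metrics(fit)
    rows.append(m)
    print(f"{dist.replicate:>9d}  {m.a_mean_diameter:11.2f}  "
          f"{m.b_mean_diameter:11.2f}  {m.b_content_pct:13.2f}")

print(f"{'mean':>9s}  {np.mean([m.a_mean_diameter for m in rows]):11.2f}  "
      f"{np.mean([m.b_mean_diameter for m in rows]):11.2f}  "
      f"{np.mean([m.b_content_pct for m in rows]):13.2f}")
print(f"{'truth':>9s}  {spec.params.mu_A:11.2f}  "
      f"{spec.params.b_mean:11.2f}  {100 * spec.params.w_B:13.2f}")
print("\nEach row is one biological replicate; the fitted mixture recovers "
      "the generating A/B diameters and the B-type volume fraction.")
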