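"""Ca2+ dependence of the activation threshold with a modified Hill fit.

Simulates the six-concentration series (0, 1, 3, 9, 100, 240 uM) at the
study's per-group cell counts, detects per-cell thresholds and fits the
group means with y = base + (max - base) / (1 + (Ca/Ca_0.5)^h).
"""

from anophys.pipeline import CA_SERIES_N, CA_SERIES_UM, ca_series_run

means, hill, rows = ca_series_run(base_seed=42)

print(" [Ca2+] (uM)   n   mean V_threshold (mV)")
for ca, n in zip(CA_SERIES_UM, CA_SERIES_N):
    print(f"{ca:10.0f} {n:5d} {means[ca]:14.1f}")

print(f"\nHill fit: [Ca2+]_0.5 = {hill.ec50_um:.2f} uM, h = {hill.hill:.2f}")
print(f"plateaus: {hill.i_max:.1f} mV (zero Ca) -> {hill.i_base:.1f} mV (saturating)")

# A single series at these cell counts gives a noisy fit; replicating the
# experiment and taking medians stabilises the estimates.
import numpy as np

fits = [ca_series_run(base_seed=42 + 1_000_003 * r)[1] for r in range(10)]
print(f"median over 10 replicates: [Ca2+]_0.5 = "
      f"{np.median([f.ec50_um for f in fits]):.2f} uM, "
      f"h = {np.median([f.hill for f in fits]):.2f}")
# The threshold slides ~60 mV toward less depolarised potentials as
# cytosolic Ca2+ rises over ~2 decades, with half-maximal effect in the
# low-micromolar range -- the hallmark of a Ca2+-facilitated, strongly
# voltage-dependent activation.
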