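"""Simulate one cell's IV protocol and detect its activation threshold.

Runs the standard -100..+180 mV step protocol on a wild-type-like cell
at 3 uM intracellular Ca2+, extracts instantaneous/steady amplitudes and
applies the 2 x noise-SD threshold rule.
"""

from anophys import analysis, simulate
from anophys.pipeline import standard_protocol

g = simulate.get_gating("WT-HEK")
perm = simulate.get_permeation("nonselective")
protocol = standard_protocol()

rec = simulate.simulate_sweep_set(g, perm, protocol, ca_um=3.0, seed=7)
iv = analysis.extract_amplitudes(rec)
res = analysis.detect_threshold(iv)

print(" V (mV)   inst (pA)  steady (pA)  diff (pA)  noise SD  passes")
for v, i0, i1, d, sd, ok in zip(iv.voltages_mV, iv.instantaneous_pA,
                                iv.steady_pA, iv.difference_pA,
                                iv.noise_sd_pA, res.passed):
    print(f"{v:7.0f} {i0:10.1f} {i1:12.1f} {d:10.1f} {sd:9.1f}   {'x' if ok else ''}")
print(f"\ndetected V_threshold: {res.v_threshold_mV} mV")
# The time-dependent (difference) component first beats twice the
# end-of-pulse noise SD near +80..+100 mV: the cell's activation
# threshold, far below the gating midpoint where currents would saturate.

fit = analysis.fit_relaxation(rec, sweep=14)
print(f"activation tau at +180 mV: {fit.tau_ms:.1f} ms (rmse {fit.rmse_pA:.1f} pA)")
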