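"""Concentration-dependent inactivation of simulated TEVC traces.

Simulates 120 s concentration steps at -120 mV and extracts the percent
inactivation: currents persist at low micromolar K+ but collapse almost
completely at millimolar K+ — the transporter shuts down exactly where a
K+ channel could take over.
"""

import haksym as hx

print(f"{'[K+] step':>10} {'dI_peak (nA)':>13} {'dI_ss (nA)':>11} "
      f"{'inactivation':>13}")
for conc in (10e-6, 20e-6, 200e-6, 2e-3):
    protocol = hx.step_protocol(conc, pH=4.5)
    trace = hx.simulate_tevc_trace(hx.WT_PRESET, protocol,
                                   hx.NoiseModel(seed=7, cv=0.01))
    ft = hx.extract_trace_features(trace, protocol)
    print(f"{conc * 1e6:8.0f}uM {ft.dI_peak_A * 1e9:13.1f} "
          f"{ft.dI_ss_A * 1e9:11.1f} {ft.pct_inactivation:12.1f}%")

# Peaks are reached after ~2 s; at 2 mM the current then vanishes within
# the 120 s pulse (>90% inactivation) while at 10 uM it remains constant.
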