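"""Why couple K+ uptake to a proton?

Compares the lowest external K+ from which a channel and a 1H+:1K+
symporter can still accumulate potassium into a cell holding 150 mM K+ at
-180 mV, with the outside two pH units more acidic than the cytosol.
"""

import haksym as hx

channel = hx.ThermoScenario(K_in_M=0.15, V_mV=-180.0)
symport = hx.ThermoScenario(K_in_M=0.15, V_mV=-180.0, delta_pH=-2.0, n_H=1)

c = hx.channel_uptake_limit(channel)
s = hx.symport_uptake_limit(symport)

print(f"channel limit : {c * 1e6:8.3f} uM")
print(f"symport limit : {s * 1e9:8.3f} nM")
print(f"advantage     : {hx.accumulation_advantage(channel, symport):8.3g}x")

# Each coupled proton contributes its 2-decade chemical gradient plus one
# extra charge in the field (3 decades at -180 mV / 60 mV per decade), so
# the symporter works from 100,000-fold more dilute K+ than the channel.
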