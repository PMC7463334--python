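# Seawater total alkalinity polynomial, subtropical surface waters.
# AT [umol/kg] = c0 + c1*(SSS - s0) + c2*(SSS - s0)^2 + c3*(SST - t0) + c4*(SST - t0)^2
# EXTERNAL REFERENCE VALUES from Lee et al. (2006), GRL 33, L19605,
# (sub)tropical zone fit. Shipped as defaults; override per study region.
c0 = 2305.0
c1 = 58.66
c2 = 2.32
c3 = -1.41
c4 = 0.040
s0 = 35.0
t0 = 20.0
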