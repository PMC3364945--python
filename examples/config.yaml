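# puffsim configuration — fully commented example (these are the shipped
# defaults; any subset of keys may be given, the rest take defaults).
# Units: concentrations uM, times s, on-rates 1/(uM s), off-rates 1/s.

# ---- cluster / protocol ----------------------------------------------------
n_channels: 20        # channels per cluster
ip3: 0.07             # IP3 concentration (stimulation level)
dt: 1.0e-05           # stochastic step; max transition prob per step <= 0.05
record_dt: 0.001      # trace sampling interval (integer multiple of dt)
duration: 400.0       # recorded time after the burn-in
burn_in: 10.0         # discarded settling time from the all-unbound start
seed: 0               # RNG seed; identical config => byte-identical trace

# ---- DYK gating rates -------------------------------------------------------
# activating Ca2+ site (K_act = b_act/a_act = 0.25 uM)
a_act: 47.0
b_act: 11.75
# inhibiting Ca2+ site of IP3-bound subunits (K_inh_ip3 = 15 uM,
# de-inhibition b_inh_ip3 = 2 /s)
a_inh_ip3: 0.13333333333333333
b_inh_ip3: 2.0
# inhibiting Ca2+ site of IP3-free subunits (K_inh_noip3 = 0.111 uM)
a_inh_noip3: 1.25
b_inh_noip3: 0.13875
# IP3 site of non-inhibited subunits (K_ip3_noninh = 0.00518 uM, forced by
# the detailed-balance loop constraint
# K_ip3_noninh * K_inh_ip3 = K_ip3_inh * K_inh_noip3)
a_ip3_noninh: 1.25
b_ip3_noninh: 0.006475
# IP3 site of inhibited subunits (K_ip3_inh = 0.7 uM; slow unbinding here
# terminates long wave-like release)
a_ip3_inh: 0.2
b_ip3_inh: 0.13999999999999999

# ---- microdomain ------------------------------------------------------------
c0: 0.025             # resting Ca2+ level
c1: 2.8               # coupling concentration per open channel (closed channels)
c_high: 105.0         # pore concentration felt by open channels
k: 100.0              # residual-Ca2+ collapse rate; ~100 = EGTA-like buffering,
                      # ~10 = unbuffered (wave regime)
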