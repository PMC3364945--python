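# puffsim

Stochastic simulation of Ca²⁺ **puffs** and **wave-like bursts** released by a
cluster of inositol 1,4,5-trisphosphate receptor (IP₃R) channels, coupled to a
coarse-grained, *non-stationary* Ca²⁺ microdomain.

## Who this is for

Computational cell biologists and biophysicists studying Ca²⁺ signaling who
need a fast, reproducible model of a single release site: how long release
events last, how often they recur, and how slow mobile buffers (EGTA-like)
reshape them by accelerating the collapse of residual Ca²⁺ microdomains.

## The model

**Gating.** Each of the 20 channels in a cluster has four identical
DeYoung–Keizer (DYK) subunits. A subunit carries an IP₃ binding site, an
activating Ca²⁺ site, and an inhibiting Ca²⁺ site; its state is a triple
(i, a, h) on the corners of a cube. Binding transitions have rate a·[ligand],
unbinding transitions rate b; the inhibiting-site rate pair depends on the
IP₃ site and the IP₃-site pair on the inhibiting site, tied together by the
thermodynamic loop (detailed-balance) constraint

    K_ip3_noninh · K_inh_ip3 = K_ip3_inh · K_inh_noip3,   K_x = b_x / a_x.

A channel is **open** when at least three of its four subunits are in the open
substate (1, 1, 0); with per-subunit probability p the equilibrium open
probability is p⁴ + 4p³(1−p), a bell-shaped function of [Ca²⁺] whose peak
shifts right as [IP₃] grows.

**Microdomain.** Ca²⁺ feedback is split across two scales. An open channel
feels its own pore nanodomain at a fixed high concentration c_high. Closed
channels feel a shared microdomain concentration c with quasi-stationary value
c_stat(n) = c₀ + c₁·n for n open channels. On openings c equilibrates upward
instantaneously; after closings the residual Ca²⁺ collapses exponentially,

    dc/dt = k (c_stat − c),

with collapse rate k the proxy for slow mobile buffer: k ≈ 100 s⁻¹ mimics
EGTA-loaded cells (fast collapse → short puffs), k ≈ 10 s⁻¹ the unbuffered
case (persistent residual Ca²⁺ → long wave-like bursts, terminated by slow
IP₃ unbinding from inhibited subunits rather than by Ca²⁺ inhibition).

**Engine.** Fixed-time-step kinetic Monte Carlo (default dt = 10 µs): per step
each subunit makes at most one transition, drawn with probability rate·dt;
channel states and the microdomain are updated synchronously. Release events
are read from the open-channel-count trace with a 500 ms gap-closure rule: a
re-opening within 500 ms of the last closing belongs to the same event.

## Worked example

Simulate 60 s of the default puff regime (20 channels, [IP₃] = 0.07 µM,
k = 100 s⁻¹), then detect and summarize release events:

```sh
puffsim simulate --k 100 --ip3 0.07 --duration 60 --seed 1 --out trace.tsv
puffsim analyze trace.tsv --out-events events.tsv --out-summary summary.json
```

The `analyze` step prints (seed 1):

```json
{"mean_dormancy_s": 4.5805, "mean_ipi_end_to_onset_s": 4.5805,
 "mean_ipi_s": 4.8043, "mean_lifetime_s": 0.2144, "median_amplitude": 8.5,
 "median_lifetime_s": 0.1750, "n_events": 12}
```

i.e. 12 puffs in 60 s: the typical puff lasts ~175 ms (median), peaks at
~8–9 simultaneously open channels, and puffs recur every ~4–5 s, almost all
of which is dormancy (no channel open). Re-running the same command
reproduces the trace byte for byte; changing `--k` to 10 switches to the
wave regime with events an order of magnitude longer and longer dormancy.

Other subcommands: `puffsim popen` (equilibrium open-probability dose–response
table), `puffsim sweep` (event statistics over a k × IP₃ grid),
`puffsim validate-config` (checks a config file, prints the dissociation
constants). The same functionality is available as a library
(`puffsim.simulate`, `puffsim.detect_events`, `puffsim.sweep`, ...).

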