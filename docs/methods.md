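# Methods

`puffsim` simulates Ca²⁺ release from a single cluster of IP₃ receptor
(IP₃R) channels. It couples DeYoung–Keizer (DYK) subunit gating to a
coarse-grained, non-stationary description of the cluster's Ca²⁺
microdomain, and analyzes the resulting open-channel-count traces as trains
of release events. This note documents the model, its parameters and their
provenance, the numerical scheme, and the limits of what the shipped tests
demonstrate.

## Gating model

Each channel has four identical subunits; each subunit has three binding
sites — IP₃ (index i), activating Ca²⁺ (a), inhibiting Ca²⁺ (h) — giving
eight states (i, a, h) on a cube. Transitions flip one site at a time:
binding at rate a·[ligand], unbinding at rate b. Two rate pairs exist for
inhibition (with/without IP₃ bound) and two for IP₃ binding (with/without
the inhibiting site occupied); thermodynamic consistency around the cube's
faces forces the loop constraint

    K_ip3_noninh · K_inh_ip3 = K_ip3_inh · K_inh_noip3,

with K_x = b_x/a_x. The channel is open when ≥ 3 of its 4 subunits are in
(1, 1, 0); this gives the bell-shaped equilibrium open-probability curve
P_open(c) = p⁴ + 4p³(1−p) (p the equilibrium weight of (1,1,0)), whose
maximum shifts to larger Ca²⁺ as IP₃ increases because inhibition is much
weaker for IP₃-bound subunits (K_inh_ip3 ≫ K_inh_noip3).

The stationary subunit distribution is obtained by a direct linear solve of
the 8×8 generator with one balance row replaced by normalization; no product
form is assumed by the implementation (the product form, valid under the
loop constraint, is used as an independent oracle in the tests).

## Microdomain model

Reaction–diffusion studies of clustered IP₃Rs show strongly inhomogeneous
Ca²⁺ within a cluster: the pore concentration at an open channel is far
higher than the concentration at neighboring closed channels. The model
keeps exactly this two-scale structure and nothing more:

* subunits of an **open** channel feel the fixed pore concentration `c_high`;
* subunits of **closed** channels feel one shared microdomain concentration
  `c`, whose quasi-stationary value is linear in the number of open
  channels, `c_stat(n) = c0 + c1·n`;
* on an **increase** of n, `c` jumps instantaneously to `c_stat(n)` (upward
  equilibration is fast); if residual Ca²⁺ already exceeds the new plateau,
  `c` is left unchanged — an opening cannot remove released Ca²⁺
  (max rule; the source material specifies only upward equilibration);
* on a **decrease** of n (not only to zero), `c` is left in place at the
  transition and then relaxes toward the new, lower plateau as
  `dc/dt = k (c_stat − c)`.

The relaxation is integrated with its exact flow,
`c ← c_stat + (c − c_stat)·exp(−k·dt)`, so the concentration carries no
integrator error and composing half steps equals a full step to machine
precision.

The collapse rate `k` (s⁻¹) is the model's proxy for slow mobile buffer:
buffers such as EGTA bind residual Ca²⁺ and speed up microdomain collapse
after closings without affecting the peak, so large k (~100 s⁻¹) represents
EGTA-loaded conditions and small k (~10 s⁻¹) the unimpeded case. Explicit
buffer kinetics, spatial profiles, channel currents, and source geometry are
deliberately outside the model; they are all folded into (c0, c1, c_high, k).

## Stochastic engine

A fixed-time-step kinetic Monte Carlo scheme advances all 80 subunits
synchronously. Per step of length dt, each subunit draws a single uniform
and selects among its three candidate transitions with probability rate·dt
each (at most one transition per subunit per step); all rates are evaluated
at start-of-step concentrations and open/closed statuses, removing any
dependence on update order. This single-draw categorical step is equivalent
to independent per-transition Bernoulli draws to first order in dt, and is
exactly the discrete chain whose sojourn times are geometric with mean
1/(total rate) as dt → 0.

After the subunit sweep, channel open states are recomputed (3-of-4 rule),
the microdomain jump rule is applied if the open count changed, and `c` is
relaxed over dt.

Numerical choices:

* **dt = 10 µs** by default. The fastest transition is activating-site
  binding at the pore, a_act·c_high ≈ 4.9·10³ s⁻¹, giving a per-step
  probability of 0.049; configurations with max rate·dt > 0.05 are rejected.
  The time-step convergence test checks that halving dt leaves the long-run
  mean open count unchanged within Monte-Carlo error.
* **record_dt = 1 ms** resolves 100-ms puffs with ~100 samples and is 500×
  finer than the event-merging window.
* **Initial condition**: all sites unbound, c = c0, with a default 10 s
  burn-in discarded. Statistical runs in the tests and the acceptance script
  use a 20 s burn-in; the slowest relaxation (IP₃ re-equilibration) means
  long records (≥ 150 s) are preferred over short ones for stationary
  statistics.
* **Reproducibility**: one integer seed controls the whole run. The kernel
  executes in ~100 s blocks (for progress logging) whose sub-seeds derive
  deterministically from the run seed; identical configurations reproduce
  traces byte for byte.
* The compiled (numba) kernel and the pure-Python `step()` implement the
  same update; `step()` exists for inspection and unit tests, the kernel for
  production runs (~10⁷ steps/s on one core).

## Event analysis

A release event begins with the 0 → 1 transition of the open-channel count
and ends at the last 1 → 0 transition not followed by a re-opening within
the 500 ms gap window; shorter quiet gaps are merged into the event
(lifetime spans the merged extent). A trailing active period whose
termination cannot be certified within the trace is discarded. Interpuff
intervals (IPI) are onset-to-onset; dormancy is the open-channel-free span
between consecutive events; since the convention for IPIs is not uniquely
fixed by usage, the end-to-onset variant is also reported, with
onset-to-onset as the headline. Histogram resolutions: 100 ms for lifetimes,
0.5 s for IPI and dormancy, unit bins for amplitudes. With fewer than two
events, interval statistics are NaN (undefined), never zero.

Counters recorded along traces: N₁₁₁ (subunits Ca²⁺-inhibited while
IP₃-bound), N₀₁₁ (subunits that lost IP₃ while doubly Ca²⁺-bound), and
N_avail (channels with ≥ 3 IP₃-bound subunits, i.e. able to open). During
long events N₀₁₁ rises and N_avail falls — the signature of the slow
IP₃-unbinding mechanism that terminates wave-like release.

## Parameters

Printed anchors (units µM, s):

| quantity | value | role |
|---|---|---|
| K_act | 0.25 | half-activation of the activating Ca²⁺ site |
| K_inh_noip3 | 0.111 | half-inhibition, IP₃ site empty |
| K_ip3_inh | 0.7 | IP₃ affinity of inhibited subunits |
| b_inh_ip3 | 2 s⁻¹ | de-inhibition rate of IP₃-bound subunits |
| n_channels | 20 | cluster size |
| gap window | 0.5 s | event merging rule |
| k sweep | 10–100 s⁻¹ | buffer proxy range |
| ip3 | 0.07 µM | default stimulation (0.05–0.1 µM optimal band) |
| c_high | > 100 µM | pore concentration scale |

The remaining constants are not printed in the available source text and
were fixed by a single calibration against the printed dynamics (typical
peak of 5–10 open channels; 100–300 ms puffs with ~4 s IPIs at k = 100 s⁻¹;
wave-like events an order of magnitude longer with ~6 s IPIs at k = 10 s⁻¹),
performed once and frozen:

| quantity | value | constraint respected |
|---|---|---|
| K_inh_ip3 | 15 µM | ≫ K_inh_noip3; inhibition only at high Ca²⁺ |
| K_ip3_noninh | 0.00518 µM | forced by the loop constraint |
| a_act | 47 µM⁻¹s⁻¹ | max rate·dt ≤ 0.05 at the pore |
| a_inh_ip3 | 2/15 µM⁻¹s⁻¹ | fixed by b_inh_ip3 = 2 s⁻¹ and K_inh_ip3 |
| a_inh_noip3 | 1.25 µM⁻¹s⁻¹ | recovery kinetics of IP₃-free subunits |
| a_ip3_noninh | 1.25 µM⁻¹s⁻¹ | recovery kinetics of IP₃ rebinding |
| a_ip3_inh | 0.2 µM⁻¹s⁻¹ | IP₃ loss from inhibited subunits slowest process |
| c0 | 0.025 µM | physiological resting Ca²⁺ |
| c1 | 2.8 µM | closed-channel concentrations of order 10 µM during events |
| c_high | 105 µM | pore scale above 100 µM |

Affinities live in the dissociation constants; the on-rates encode pure
kinetics. Two kinetic scales matter. IP₃ **loss** happens from the inhibited
state (1,1,1) at b_ip3_inh = a_ip3_inh·K_ip3_inh ≈ 0.14 s⁻¹ — slow, so only
long (wave-like) events lose appreciable IP₃, which is what terminates them.
IP₃ **recovery** of a stranded (0,1,1) subunit runs through de-inhibition
(b_inh_noip3 = a_inh_noip3·K_inh_noip3 ≈ 0.14 s⁻¹) followed by IP₃ rebinding
(a_ip3_noninh·[IP₃] ≈ 0.09 s⁻¹ at 0.07 µM), i.e. tens of seconds — slow
enough to lengthen dormancy after waves, fast enough that release does not
die out. Every on-rate is an independent config key, so users can impose
shared on-rates per ligand if preferred.

Mechanistically, the calibrated set reproduces the intended division of
labor: at k = 100 s⁻¹ events are terminated by fast Ca²⁺ inhibition
(subunits accumulate transiently in 1,1,1 and recover at 2 s⁻¹), while at
k = 10 s⁻¹ persistent residual Ca²⁺ keeps re-opening de-inhibited channels
and release only ends as subunits in 1,1,1 gradually lose IP₃
(b_ip3_inh = a_ip3_inh·K_ip3_inh ≈ 0.14 s⁻¹), which also produces the longer
dormancy after waves.

## What the tests do and do not show

The statistical suite runs the full generative model at scaled-down problem
sizes (4–8 seeds per condition, 50–250 s of recording per seed, 15–30 s
burn-in; the acceptance script uses 4 × 150 s) and checks distributional
summaries — event counts, median/mean lifetimes, IPIs, dormancies,
amplitude medians, monotonic trends in k and IP₃, and the sign of counter
drifts during long events. These demonstrate internal consistency of the
model and reproduction of the study's simulated phenomenology. They do not
validate the model against raw experimental recordings: the synthetic traces
contain no fluorescence convolution, photon noise, dye–buffer competition,
or multi-cluster interactions, so quantitative agreement with measured puff
amplitudes or wave propagation is out of scope.

## Known limitations

* At slow collapse (k = 10 s⁻¹) the mean event lifetime rises steeply with
  IP₃ (≈1.1 s at 0.02 µM to ≈4.1 s at 0.1 µM), but the mean interpuff
  interval is U-shaped rather than monotonically increasing: the waiting
  time for a trigger opening falls with IP₃ (the IP₃ site is only ~80 %
  occupied at 0.02 µM, since the loop constraint pins K_ip3_noninh near
  5 nM once K_inh_ip3 is at tens of µM) and dominates the IPI at low IP₃,
  while the refractory and lifetime contributions dominate and rise at high
  IP₃. A monotone IPI would require near-saturated IP₃ binding at 0.02 µM,
  which the loop constraint, the pore inhibition speed needed for 100–300 ms
  puffs, and the step-size cap jointly exclude in this parameterization.
  The corresponding check in the statistical suite is expected to fail and
  documents this limitation.

* The microdomain is a single scalar; channel positions within the cluster
  are not resolved, so amplitude-distance correlations are absent.
* The fixed-step scheme has O(rate·dt) discretization bias (≤ 5 % for the
  fastest transition at defaults); an event-driven exact sampler is
  deliberately not provided.
* Whether the microdomain may jump downward when a channel re-opens onto a
  large residual is not specified by the underlying theory; the max rule
  used here never discards released Ca²⁺.
* Calibrated constants above are not experimental measurements; they are
  one consistent choice inside the printed constraint box.
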