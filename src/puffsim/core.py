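"""Stochastic simulation of Ca2+ puffs and waves from a cluster of IP3R channels.

The model couples DeYoung--Keizer (DYK) subunit gating of inositol
1,4,5-trisphosphate receptor (IP3R) channels to a coarse-grained,
non-stationary description of the Ca2+ microdomain around the cluster.

Each of the 20 channels in a cluster has four identical subunits.  A subunit
carries three binding sites -- an IP3 site, an activating Ca2+ site and an
inhibiting Ca2+ site -- giving 8 states arranged on a cube, written as
triples (i, a, h).  A channel is open when at least three of its four
subunits are in the open substate (1, 1, 0).

Ca2+ feedback is separated into two scales.  An open channel is exposed to
its own nanodomain at a fixed, high pore concentration ``c_high``.  Closed
channels feel a shared microdomain concentration ``c`` that tracks the
number of open channels ``n``: its quasi-stationary value is
``c_stat(n) = c0 + c1 * n``.  On channel opening the microdomain equilibrates
instantaneously upward; after closings the residual Ca2+ collapses
exponentially toward the new plateau at rate ``k`` (``dc/dt = k (c_stat - c)``).
Large ``k`` stands for a slow mobile buffer (EGTA-like) that removes residual
Ca2+ quickly and yields short puffs; small ``k`` leaves persistent residual
Ca2+ that re-opens channels and yields long, wave-like bursts.

Gating is advanced with a fixed-time-step kinetic Monte Carlo scheme: in
every step of length ``dt`` each subunit makes at most one transition,
selected with probability rate*dt from its three candidate site flips.
Release events are read off the open-channel-count trace with a 500 ms
gap-closure rule.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from numba import njit

__all__ = [
    "N_SUBUNIT_STATES",
    "OPEN_SUBSTATE",
    "SubunitState",
    "GatingParameters",
    "transition_rates",
    "detailed_balance_residual",
    "subunit_equilibrium",
    "channel_open_probability",
    "open_probability_curve",
    "site_occupancy",
    "half_occupancy_concentration",
    "MicrodomainParameters",
    "DomainState",
    "stationary_concentration",
    "advance_concentration",
    "on_open_count_change",
    "subunit_concentration",
    "SimulationConfig",
    "ClusterState",
    "Trace",
    "step",
    "simulate",
    "sweep",
    "clamped_subunit_occupancy",
    "clamped_subunit_dwells",
    "measure_deinhibition_rate",
    "ReleaseEvent",
    "EventStatistics",
    "detect_events",
    "event_statistics",
    "state_counters",
    "default_config",
    "config_from_dict",
    "config_to_dict",
    "load_config",
    "save_config",
    "write_trace",
    "read_trace",
    "make_fixture_trace",
]

__version__ = "0.1.0"

logger = logging.getLogger("puffsim")

# ----------------------------------------------------------------------------
# Gating: the DYK subunit cube
# ----------------------------------------------------------------------------

N_SUBUNIT_STATES = 8

#: Subunit states are encoded as integers ``s = 4*i + 2*a + h`` where ``i`` is
#: the IP3 site, ``a`` the activating Ca2+ site and ``h`` the inhibiting Ca2+
#: site (1 = ligand bound).  The open substate (1, 1, 0) is code 6.
OPEN_SUBSTATE = 6
STATE_111 = 7
STATE_011 = 3


@dataclass(frozen=True)
class SubunitState:
    """Occupation state (i, a, h) of one IP3R subunit."""

    i: int  # IP3 site
    a: int  # activating Ca2+ site
    h: int  # inhibiting Ca2+ site

    def __post_init__(self) -> None:
        for name in ("i", "a", "h"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"site index {name!r} must be 0 or 1, got {v!r}")

    @property
    def code(self) -> int:
        return 4 * self.i + 2 * self.a + self.h

    @classmethod
    def from_code(cls, code: int) -> "SubunitState":
        if not 0 <= code < N_SUBUNIT_STATES:
            raise ValueError(f"state code must be in 0..7, got {code}")
        return cls((code >> 2) & 1, (code >> 1) & 1, code & 1)


# Default rate constants.  The dissociation constants below are anchored to
# the dose-response features of nuclear patch-clamp data: half-activation of
# the activating Ca2+ site at 0.25 uM, half-inhibition at 0.111 uM for
# IP3-free subunits and far weaker (15 uM) for IP3-bound subunits, IP3
# affinity of inhibited subunits 0.7 uM, and a de-inhibition rate of 2 /s
# for IP3-bound subunits.  The IP3 affinity of non-inhibited subunits is
# then forced by the thermodynamic loop constraint
# ``K_ip3_noninh * K_inh_ip3 = K_ip3_inh * K_inh_noip3``.  The on-rates are
# calibration constants (see docs/methods.md): IP3 binding/unbinding of
# IP3-bound, inhibited subunits is the slowest process, which is what lets
# slow IP3 loss terminate long wave-like release.
_K_ACT = 0.25  # uM
_K_INH_NOIP3 = 0.111  # uM
_K_INH_IP3 = 15.0  # uM
_K_IP3_INH = 0.7  # uM
_K_IP3_NONINH = _K_IP3_INH * _K_INH_NOIP3 / _K_INH_IP3  # ~5.18e-3 uM, forced
_A_ACT = 47.0  # 1/(uM s)
_B_INH_IP3 = 2.0  # 1/s
_A_INH_IP3 = _B_INH_IP3 / _K_INH_IP3  # ~0.133 1/(uM s)
_A_REC = 1.25  # on-rate of the inhibiting site (IP3 free) and of IP3 binding
# (non-inhibited); sets the post-event recovery kinetics of availability
_A_IP3_INH = 0.2  # 1/(uM s), slow IP3 kinetics of inhibited subunits


@dataclass(frozen=True)
class GatingParameters:
    """The five binding/unbinding rate pairs of the DYK cube.

    Units: on-rates ``a_*`` in 1/(uM s), off-rates ``b_*`` in 1/s.  The
    inhibiting-site pair depends on the IP3 site (``_ip3`` vs ``_noip3``)
    and the IP3-site pair depends on the inhibiting site (``_noninh`` vs
    ``_inh``).  Dissociation constants ``K_x = b_x / a_x`` are exposed as
    properties.
    """

    a_act: float = _A_ACT
    b_act: float = _A_ACT * _K_ACT
    a_inh_ip3: float = _A_INH_IP3
    b_inh_ip3: float = _B_INH_IP3
    a_inh_noip3: float = _A_REC
    b_inh_noip3: float = _A_REC * _K_INH_NOIP3
    a_ip3_noninh: float = _A_REC
    b_ip3_noninh: float = _A_REC * _K_IP3_NONINH
    a_ip3_inh: float = _A_IP3_INH
    b_ip3_inh: float = _A_IP3_INH * _K_IP3_INH

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"gating rate {f.name!r} must be strictly positive, got {v!r}")
        if not self.K_inh_ip3 > self.K_inh_noip3:
            raise ValueError(
                "inhibition must be weaker for IP3-bound subunits: "
                f"K_inh_ip3={self.K_inh_ip3:g} uM must exceed K_inh_noip3={self.K_inh_noip3:g} uM"
            )

    # Derived dissociation constants (uM)
    @property
    def K_act(self) -> float:
        return self.b_act / self.a_act

    @property
    def K_inh_ip3(self) -> float:
        return self.b_inh_ip3 / self.a_inh_ip3

    @property
    def K_inh_noip3(self) -> float:
        return self.b_inh_noip3 / self.a_inh_noip3

    @property
    def K_ip3_noninh(self) -> float:
        return self.b_ip3_noninh / self.a_ip3_noninh

    @property
    def K_ip3_inh(self) -> float:
        return self.b_ip3_inh / self.a_ip3_inh

    def dissociation_constants(self) -> dict[str, float]:
        return {
            "K_act": self.K_act,
            "K_inh_ip3": self.K_inh_ip3,
            "K_inh_noip3": self.K_inh_noip3,
            "K_ip3_noninh": self.K_ip3_noninh,
            "K_ip3_inh": self.K_ip3_inh,
        }


def detailed_balance_residual(params: GatingParameters) -> float:
    """Log-residual of the thermodynamic loop constraint.

    Around any face of the DYK cube that involves both the IP3 site and the
    inhibiting site, equilibrium requires
    ``K_ip3_noninh * K_inh_ip3 == K_ip3_inh * K_inh_noip3``.  Returns
    ``|ln[(K_ip3_noninh * K_inh_ip3) / (K_ip3_inh * K_inh_noip3)]|``, which is
    zero iff the constraint holds.
    """
    return abs(
        math.log(
            (params.K_ip3_noninh * params.K_inh_ip3)
            / (params.K_ip3_inh * params.K_inh_noip3)
        )
    )


def _site_rates(code: int, c: float, ip3: float, params: GatingParameters) -> tuple[float, float, float]:
    """Transition rates (i-site, a-site, h-site) out of a subunit state code."""
    i, a, h = (code >> 2) & 1, (code >> 1) & 1, code & 1
    # IP3 site: the rate pair depends on the inhibiting site.
    if h == 0:
        r_i = params.b_ip3_noninh if i else params.a_ip3_noninh * ip3
    else:
        r_i = params.b_ip3_inh if i else params.a_ip3_inh * ip3
    # Activating Ca2+ site: a single rate pair.
    r_a = params.b_act if a else params.a_act * c
    # Inhibiting Ca2+ site: the rate pair depends on the IP3 site.
    if i == 1:
        r_h = params.b_inh_ip3 if h else params.a_inh_ip3 * c
    else:
        r_h = params.b_inh_noip3 if h else params.a_inh_noip3 * c
    return r_i, r_a, r_h


def transition_rates(
    state: SubunitState | int,
    c: float,
    ip3: float,
    params: GatingParameters,
) -> list[tuple[SubunitState, float]]:
    """The three outgoing transitions of a subunit state.

    Binding transitions carry rate ``a * c`` (Ca2+ sites) or ``a * ip3``
    (IP3 site); unbinding transitions carry the bare off-rate ``b``.

    Parameters
    ----------
    state
        Current subunit state (or its integer code).
    c, ip3
        Ca2+ and IP3 concentrations felt by the subunit, in uM.
    params
        Rate constants.

    Returns
    -------
    list of (target_state, rate) pairs, ordered (IP3 site, activating site,
    inhibiting site).
    """
    if c < 0:
        raise ValueError(f"Ca2+ concentration must be nonnegative, got {c!r}")
    if ip3 < 0:
        raise ValueError(f"IP3 concentration must be nonnegative, got {ip3!r}")
    code = state.code if isinstance(state, SubunitState) else int(state)
    if not 0 <= code < N_SUBUNIT_STATES:
        raise ValueError(f"invalid subunit state code {code}")
    r_i, r_a, r_h = _site_rates(code, c, ip3, params)
    return [
        (SubunitState.from_code(code ^ 4), r_i),
        (SubunitState.from_code(code ^ 2), r_a),
        (SubunitState.from_code(code ^ 1), r_h),
    ]


def _generator_matrix(c: float, ip3: float, params: GatingParameters) -> np.ndarray:
    """Generator Q of the 8-state subunit chain; Q[j, s] is the rate s -> j."""
    Q = np.zeros((N_SUBUNIT_STATES, N_SUBUNIT_STATES))
    for s in range(N_SUBUNIT_STATES):
        r_i, r_a, r_h = _site_rates(s, c, ip3, params)
        Q[s ^ 4, s] += r_i
        Q[s ^ 2, s] += r_a
        Q[s ^ 1, s] += r_h
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=0)
    return Q


def subunit_equilibrium(c: float, ip3: float, params: GatingParameters) -> np.ndarray:
    """Stationary distribution of a subunit at fixed concentrations.

    Solves ``Q pi = 0`` with normalization for the 8-state continuous-time
    Markov chain of one subunit held at Ca2+ concentration ``c`` and IP3
    concentration ``ip3`` (both uM).  Returns a probability vector indexed by
    state code.
    """
    if c < 0 or ip3 < 0:
        raise ValueError("concentrations must be nonnegative")
    Q = _generator_matrix(c, ip3, params)
    A = Q.copy()
    A[0, :] = 1.0  # replace one balance equation by the normalization
    b = np.zeros(N_SUBUNIT_STATES)
    b[0] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise ValueError(f"degenerate gating generator at c={c}, ip3={ip3}: {exc}") from exc
    pi = np.where(np.abs(pi) < 1e-300, 0.0, pi)
    if pi.min() < -1e-10:
        raise ValueError("stationary solve produced negative probabilities")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def channel_open_probability(c: float, ip3: float, params: GatingParameters) -> float:
    """Equilibrium open probability of one channel.

    A channel is open when at least three of its four independent subunits
    occupy the open substate (1, 1, 0).  With ``p`` the equilibrium
    probability of that substate this is ``p**4 + 4 p**3 (1 - p)``.
    """
    p = subunit_equilibrium(c, ip3, params)[OPEN_SUBSTATE]
    return float(p**4 + 4.0 * p**3 * (1.0 - p))


def open_probability_curve(
    c_values: Sequence[float] | np.ndarray,
    ip3: float,
    params: GatingParameters | None = None,
) -> pd.DataFrame:
    """Dose-response table of P_open over a grid of Ca2+ concentrations."""
    params = params or GatingParameters()
    rows = [
        {"c_uM": float(c), "ip3_uM": float(ip3), "p_open": channel_open_probability(c, ip3, params)}
        for c in c_values
    ]
    return pd.DataFrame(rows)


_SITE_BITS = {"ip3": 4, "activating": 2, "inhibiting": 1}


def site_occupancy(c: float, ip3: float, params: GatingParameters, site: str) -> float:
    """Marginal equilibrium occupancy of one binding site."""
    bit = _SITE_BITS[site]
    pi = subunit_equilibrium(c, ip3, params)
    return float(sum(pi[s] for s in range(N_SUBUNIT_STATES) if s & bit))


def half_occupancy_concentration(
    site: str,
    ip3: float,
    params: GatingParameters | None = None,
    c_lo: float = 1e-6,
    c_hi: float = 1e4,
    tol: float = 1e-12,
) -> float:
    """Ca2+ concentration at which a site's equilibrium occupancy is 1/2.

    Bisects over ``c``; occupancy of either Ca2+ site is monotone in ``c``.
    """
    params = params or GatingParameters()
    f = lambda c: site_occupancy(c, ip3, params, site) - 0.5
    lo, hi = c_lo, c_hi
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("half-occupancy not bracketed on the given interval")
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------------
# Microdomain: two-scale, non-stationary Ca2+ concentration
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class MicrodomainParameters:
    """Coarse-grained microdomain parameters.

    ``c0``: resting Ca2+ concentration (uM); ``c1``: coupling concentration
    contributed per open channel at closed channels (uM); ``c_high``: pore
    concentration felt by an open channel (uM); ``k``: collapse rate of
    residual Ca2+ after closings (1/s).  Large ``k`` models a slow mobile
    buffer (EGTA-like) that speeds up microdomain collapse.
    """

    c0: float = 0.025
    c1: float = 2.8
    c_high: float = 105.0
    k: float = 100.0

    def __post_init__(self) -> None:
        for name in ("c0", "c1", "c_high", "k"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"microdomain parameter {name!r} must be positive, got {v!r}")

    def validate_scale_separation(self, n_max: int) -> None:
        """The pore concentration must dominate the coupling scale."""
        if not self.c_high > self.c0 + self.c1 * n_max:
            raise ValueError(
                f"c_high={self.c_high:g} uM does not dominate the coupling scale "
                f"c0 + c1*N = {self.c0 + self.c1 * n_max:g} uM"
            )


@dataclass
class DomainState:
    """Microdomain concentration (uM, felt by closed channels) and open count."""

    c: float
    n_open: int


def stationary_concentration(n_open: int, params: MicrodomainParameters) -> float:
    """Quasi-stationary microdomain concentration ``c0 + c1 * n_open`` (uM)."""
    if n_open < 0:
        raise ValueError(f"open-channel count must be nonnegative, got {n_open}")
    return params.c0 + params.c1 * n_open


def advance_concentration(state: DomainState, dt: float, params: MicrodomainParameters) -> DomainState:
    """Relax the microdomain toward its plateau over a time step.

    Exact closed-form update of ``dc/dt = k (c_stat - c)``:
    ``c' = c_stat + (c - c_stat) exp(-k dt)``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    c_stat = stationary_concentration(state.n_open, params)
    c_new = c_stat + (state.c - c_stat) * math.exp(-params.k * dt)
    return DomainState(c=c_new, n_open=state.n_open)


def on_open_count_change(
    state: DomainState, new_n_open: int, params: MicrodomainParameters
) -> DomainState:
    """Apply the jump rule when the number of open channels changes.

    On an increase the microdomain equilibrates instantaneously upward to the
    new plateau, ``c -> max(c, c_stat(new))`` (released Ca2+ is never removed
    by an opening).  On a decrease the residual Ca2+ is left in place at the
    transition instant; subsequent :func:`advance_concentration` steps relax
    it toward the lower plateau.
    """
    if new_n_open < 0:
        raise ValueError(f"open-channel count must be nonnegative, got {new_n_open}")
    c = state.c
    if new_n_open > state.n_open:
        c = max(c, stationary_concentration(new_n_open, params))
    return DomainState(c=c, n_open=new_n_open)


def subunit_concentration(
    channel_is_open: bool, state: DomainState, params: MicrodomainParameters
) -> float:
    """Ca2+ concentration entering a subunit's gating rates.

    Subunits of an open channel sit in the pore nanodomain at ``c_high``;
    subunits of closed channels feel the shared microdomain concentration.
    """
    return params.c_high if channel_is_open else state.c


# ----------------------------------------------------------------------------
# Engine: fixed-time-step kinetic Monte Carlo of the coupled cluster
# ----------------------------------------------------------------------------

#: Hard cap on the per-step probability of any single transition.  The
#: scheme's discretization bias is O(rate*dt); 0.05 keeps it below a few
#: percent for the fastest transition (activating-site binding at c_high).
MAX_STEP_PROBABILITY = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of a cluster simulation.

    ``dt`` is the stochastic step (s), ``record_dt`` the sampling interval of
    the output trace, ``duration`` the recorded span after ``burn_in`` seconds
    are simulated and discarded.  ``seed`` makes runs exactly reproducible.
    """

    n_channels: int = 20
    ip3: float = 0.07
    gating: GatingParameters = field(default_factory=GatingParameters)
    domain: MicrodomainParameters = field(default_factory=MicrodomainParameters)
    dt: float = 1e-5
    record_dt: float = 1e-3
    duration: float = 400.0
    burn_in: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.ip3 < 0:
            raise ValueError(f"ip3 must be nonnegative, got {self.ip3}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be nonnegative, got {self.burn_in}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.record_dt < self.dt:
            raise ValueError(
                f"record_dt={self.record_dt} must be at least dt={self.dt}"
            )
        stride = self.record_dt / self.dt
        if abs(stride - round(stride)) > 1e-9:
            raise ValueError(
                f"record_dt={self.record_dt} must be an integer multiple of dt={self.dt}"
            )
        if not 0 <= self.seed < 2**31:
            raise ValueError(f"seed must be in [0, 2**31), got {self.seed}")
        p_max = self.max_rate * self.dt
        if p_max > MAX_STEP_PROBABILITY:
            raise ValueError(
                f"time step too large: max transition probability per step is "
                f"{p_max:.3g} > {MAX_STEP_PROBABILITY} (max rate {self.max_rate:.3g}/s, "
                f"dt={self.dt:g} s)"
            )
        self.domain.validate_scale_separation(self.n_channels)

    @property
    def max_rate(self) -> float:
        """Largest single-transition rate reachable in the simulation (1/s)."""
        g, d = self.gating, self.domain
        c_max = d.c_high
        return max(
            g.a_act * c_max,
            g.b_act,
            g.a_inh_ip3 * c_max,
            g.b_inh_ip3,
            g.a_inh_noip3 * c_max,
            g.b_inh_noip3,
            g.a_ip3_noninh * self.ip3,
            g.b_ip3_noninh,
            g.a_ip3_inh * self.ip3,
            g.b_ip3_inh,
        )

    @property
    def record_stride(self) -> int:
        return round(self.record_dt / self.dt)


@dataclass
class ClusterState:
    """Instantaneous state of the cluster: subunits, microdomain and clock."""

    subunits: np.ndarray  # (n_channels, 4) int array of state codes
    domain: DomainState
    t: float = 0.0

    @classmethod
    def initial(cls, config: SimulationConfig) -> "ClusterState":
        """Resting start: all sites unbound, microdomain at the rest level."""
        sub = np.zeros((config.n_channels, 4), dtype=np.int64)
        return cls(subunits=sub, domain=DomainState(c=config.domain.c0, n_open=0), t=0.0)

    def channel_open(self) -> np.ndarray:
        """Boolean open flag per channel (>= 3 subunits in the open substate)."""
        return (self.subunits == OPEN_SUBSTATE).sum(axis=1) >= 3

    def n_open(self) -> int:
        return int(self.channel_open().sum())


def state_counters(state: ClusterState) -> tuple[int, int, int]:
    """The (N111, N011, N_avail) counters of a cluster state.

    ``N111`` counts subunits in the doubly Ca2+-bound, IP3-bound state
    (1,1,1); ``N011`` counts subunits that lost IP3 while Ca2+-bound (0,1,1);
    ``N_avail`` counts channels with at least three IP3-bound subunits, i.e.
    channels in principle available for opening.
    """
    sub = state.subunits
    n111 = int((sub == STATE_111).sum())
    n011 = int((sub == STATE_011).sum())
    n_avail = int(((sub >= 4).sum(axis=1) >= 3).sum())
    return n111, n011, n_avail


def _step_tables(config: SimulationConfig) -> tuple[np.ndarray, ...]:
    """Per-state probability coefficients for the fixed-step scheme.

    For state code ``s`` the per-step transition probabilities are
    ``p_i[s]`` (IP3 site, concentration independent),
    ``coef_a[s] * c + const_a[s]`` (activating site) and
    ``coef_h[s] * c + const_h[s]`` (inhibiting site).
    """
    g, dt, ip3 = config.gating, config.dt, config.ip3
    p_i = np.zeros(8)
    coef_a = np.zeros(8)
    const_a = np.zeros(8)
    coef_h = np.zeros(8)
    const_h = np.zeros(8)
    for s in range(8):
        i, a, h = (s >> 2) & 1, (s >> 1) & 1, s & 1
        if i == 0:
            p_i[s] = (g.a_ip3_inh if h else g.a_ip3_noninh) * ip3 * dt
        else:
            p_i[s] = (g.b_ip3_inh if h else g.b_ip3_noninh) * dt
        if a == 0:
            coef_a[s] = g.a_act * dt
        else:
            const_a[s] = g.b_act * dt
        if h == 0:
            coef_h[s] = (g.a_inh_ip3 if i else g.a_inh_noip3) * dt
        else:
            const_h[s] = (g.b_inh_ip3 if i else g.b_inh_noip3) * dt
    return p_i, coef_a, const_a, coef_h, const_h


@njit(cache=False)
def _run_kernel(
    sub,
    c,
    n_steps,
    stride,
    p_i,
    coef_a,
    const_a,
    coef_h,
    const_h,
    c0,
    c1,
    c_high,
    decay,
    seed,
    out_n_open,
    out_c,
    out_n111,
    out_n011,
    out_n_avail,
):
    """Advance the cluster by ``n_steps`` fixed steps, recording every ``stride``.

    ``sub`` (n_channels, 4) is updated in place; the final microdomain
    concentration is returned.  Per step each subunit draws one uniform and
    makes at most one transition, chosen among its three site flips with
    probability rate*dt; all subunits use start-of-step concentrations
    (synchronous update).  Recording arrays may be empty (burn-in mode).
    """
    np.random.seed(seed)
    n_ch = sub.shape[0]
    record = out_n_open.size > 0

    open_cnt = np.zeros(n_ch, np.int64)
    i_cnt = np.zeros(n_ch, np.int64)
    open_flag = np.zeros(n_ch, np.uint8)
    n111 = 0
    n011 = 0
    for ch in range(n_ch):
        for su in range(4):
            s = sub[ch, su]
            if s == 6:
                open_cnt[ch] += 1
            elif s == 7:
                n111 += 1
            elif s == 3:
                n011 += 1
            if s >= 4:
                i_cnt[ch] += 1
    n_open = 0
    for ch in range(n_ch):
        if open_cnt[ch] >= 3:
            open_flag[ch] = 1
            n_open += 1

    cum_open = np.empty((8, 3))
    for s in range(8):
        pa = coef_a[s] * c_high + const_a[s]
        ph = coef_h[s] * c_high + const_h[s]
        cum_open[s, 0] = p_i[s]
        cum_open[s, 1] = p_i[s] + pa
        cum_open[s, 2] = p_i[s] + pa + ph
    cum_closed = np.empty((8, 3))

    rec_i = 0
    for istep in range(n_steps):
        for s in range(8):
            pa = coef_a[s] * c + const_a[s]
            ph = coef_h[s] * c + const_h[s]
            cum_closed[s, 0] = p_i[s]
            cum_closed[s, 1] = p_i[s] + pa
            cum_closed[s, 2] = p_i[s] + pa + ph
        n_open_old = n_open
        for ch in range(n_ch):
            if open_flag[ch] == 1:
                tbl = cum_open
            else:
                tbl = cum_closed
            for su in range(4):
                s = sub[ch, su]
                u = np.random.random()
                if u < tbl[s, 2]:
                    if u < tbl[s, 0]:
                        new = s ^ 4
                        if s >= 4:
                            i_cnt[ch] -= 1
                        else:
                            i_cnt[ch] += 1
                    elif u < tbl[s, 1]:
                        new = s ^ 2
                    else:
                        new = s ^ 1
                    if s == 6:
                        open_cnt[ch] -= 1
                    elif s == 7:
                        n111 -= 1
                    elif s == 3:
                        n011 -= 1
                    if new == 6:
                        open_cnt[ch] += 1
                    elif new == 7:
                        n111 += 1
                    elif new == 3:
                        n011 += 1
                    sub[ch, su] = new
        n_open = 0
        for ch in range(n_ch):
            if open_cnt[ch] >= 3:
                open_flag[ch] = 1
                n_open += 1
            else:
                open_flag[ch] = 0
        if n_open > n_open_old:
            cs = c0 + c1 * n_open
            if cs > c:
                c = cs
        cs = c0 + c1 * n_open
        c = cs + (c - cs) * decay
        if record and (istep + 1) % stride == 0:
            out_n_open[rec_i] = n_open
            out_c[rec_i] = c
            out_n111[rec_i] = n111
            out_n011[rec_i] = n011
            nav = 0
            for ch in range(n_ch):
                if i_cnt[ch] >= 3:
                    nav += 1
            out_n_avail[rec_i] = nav
            rec_i += 1
    return c


def step(state: ClusterState, config: SimulationConfig, rng: np.random.Generator) -> ClusterState:
    """One fixed step of the coupled scheme (reference implementation).

    Semantics are identical to the compiled simulation kernel: every subunit
    draws one uniform against the cumulative per-step probabilities of its
    three transitions, evaluated at start-of-step concentrations; then channel
    open statuses are recomputed, the microdomain jump rule is applied if the
    open count changed, and the concentration is relaxed over ``dt``.

    This per-step entry point exists for inspection and testing; long runs
    should use :func:`simulate`.
    """
    dt = config.dt
    sub = state.subunits.copy()
    open_before = state.channel_open()
    domain = state.domain
    for ch in range(config.n_channels):
        c_sub = subunit_concentration(bool(open_before[ch]), domain, config.domain)
        for su in range(4):
            s = int(sub[ch, su])
            transitions = transition_rates(s, c_sub, config.ip3, config.gating)
            probs = np.array([r * dt for _, r in transitions])
            total = probs.sum()
            if total > 1.0:
                raise ValueError(
                    f"step too large: total transition probability {total:.3g} > 1 for "
                    f"subunit state {s} at c={c_sub:g} uM"
                )
            u = rng.random()
            acc = 0.0
            for (target, _), p in zip(transitions, probs):
                acc += p
                if u < acc:
                    sub[ch, su] = target.code
                    break
    new_state = ClusterState(subunits=sub, domain=DomainState(domain.c, domain.n_open), t=state.t)
    n_open_new = new_state.n_open()
    d = new_state.domain
    if n_open_new != d.n_open:
        d = on_open_count_change(d, n_open_new, config.domain)
    d = advance_concentration(d, dt, config.domain)
    new_state.domain = d
    new_state.t = state.t + dt
    return new_state


@dataclass
class Trace:
    """Sampled output of a simulation.

    Arrays share a common length: sample times ``t`` (s, starting after the
    burn-in), open-channel count ``n_open``, microdomain concentration ``c``
    (uM), subunit counters ``n111`` and ``n011`` and the count ``n_avail`` of
    channels with at least three IP3-bound subunits.  ``meta`` echoes the
    configuration (including the seed) needed to reproduce the trace.
    """

    t: np.ndarray
    n_open: np.ndarray
    c: np.ndarray
    n111: np.ndarray
    n011: np.ndarray
    n_avail: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("n_open", "c", "n111", "n011", "n_avail"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace column {name!r} has mismatched length")

    @property
    def record_dt(self) -> float:
        if len(self.t) > 1:
            return float(self.t[1] - self.t[0])
        return float(self.meta.get("record_dt", np.nan))

    @property
    def duration(self) -> float:
        return float(self.t[-1]) if len(self.t) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "n_open": self.n_open,
                "c_uM": self.c,
                "n111": self.n111,
                "n011": self.n011,
                "n_avail": self.n_avail,
            }
        )


#: Wall-progress chunk: the compiled kernel is invoked in segments of at most
#: this many simulated seconds so that long runs emit progress logs.
_CHUNK_SECONDS = 100.0


def _chunk_seeds(seed: int, n_chunks: int) -> np.ndarray:
    """Independent sub-seeds for the kernel segments of one run."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_chunks, dtype=np.uint32) % np.uint32(2**31)


def simulate(config: SimulationConfig) -> Trace:
    """Run a full cluster simulation and return the recorded trace.

    Starts from the resting state (all sites unbound, ``c = c0``), simulates
    ``burn_in`` seconds that are discarded, then records samples every
    ``record_dt`` for ``duration`` seconds.
    """
    p_i, coef_a, const_a, coef_h, const_h = _step_tables(config)
    d = config.domain
    decay = math.exp(-d.k * config.dt)
    stride = config.record_stride

    burn_steps = round(config.burn_in / config.dt)
    rec_steps = round(config.duration / config.dt)
    # segment boundaries aligned to the record stride
    chunk_steps = max(stride, int(round(_CHUNK_SECONDS / config.dt)) // stride * stride)

    state = ClusterState.initial(config)
    sub = state.subunits
    c = state.domain.c

    n_rec = rec_steps // stride
    out_n_open = np.empty(n_rec, np.int32)
    out_c = np.empty(n_rec, np.float64)
    out_n111 = np.empty(n_rec, np.int32)
    out_n011 = np.empty(n_rec, np.int32)
    out_n_avail = np.empty(n_rec, np.int32)
    empty_i = np.empty(0, np.int32)
    empty_f = np.empty(0, np.float64)

    segments: list[tuple[int, int]] = []  # (n_steps, record_offset or -1)
    left = burn_steps
    while left > 0:
        n = min(left, chunk_steps)
        segments.append((n, -1))
        left -= n
    ofs = 0
    left = rec_steps
    while left > 0:
        n = min(left, chunk_steps)
        segments.append((n, ofs))
        ofs += n // stride
        left -= n

    seeds = _chunk_seeds(config.seed, len(segments))
    t0 = time.perf_counter()
    done = 0.0
    for (n_steps, rec_ofs), sub_seed in zip(segments, seeds):
        if rec_ofs < 0:
            c = _run_kernel(
                sub, c, n_steps, stride, p_i, coef_a, const_a, coef_h, const_h,
                d.c0, d.c1, d.c_high, decay, int(sub_seed),
                empty_i, empty_f, empty_i, empty_i, empty_i,
            )
        else:
            n_out = n_steps // stride
            sl = slice(rec_ofs, rec_ofs + n_out)
            c = _run_kernel(
                sub, c, n_steps, stride, p_i, coef_a, const_a, coef_h, const_h,
                d.c0, d.c1, d.c_high, decay, int(sub_seed),
                out_n_open[sl], out_c[sl], out_n111[sl], out_n011[sl], out_n_avail[sl],
            )
        done += n_steps * config.dt
        logger.info(
            "simulated %.0f / %.0f s (wall %.1f s)",
            done, config.burn_in + config.duration, time.perf_counter() - t0,
        )

    t = (np.arange(n_rec, dtype=np.float64) + 1.0) * config.record_dt
    meta = config_to_dict(config)
    meta["version"] = __version__
    return Trace(
        t=t,
        n_open=out_n_open,
        c=out_c,
        n111=out_n111,
        n011=out_n011,
        n_avail=out_n_avail,
        meta=meta,
    )


@njit(cache=False)
def _subunit_sample_kernel(s0, n_steps, cum, stride, seed, out_states):
    """Single subunit at clamped concentrations; occupancy counts + subsamples.

    ``cum`` is the (8, 3) cumulative per-step probability table.  Returns the
    per-state count of steps spent in each state; ``out_states`` receives the
    state every ``stride`` steps (for decorrelated sampling).
    """
    np.random.seed(seed)
    counts = np.zeros(8, np.int64)
    s = s0
    j = 0
    for istep in range(n_steps):
        counts[s] += 1
        u = np.random.random()
        if u < cum[s, 2]:
            if u < cum[s, 0]:
                s = s ^ 4
            elif u < cum[s, 1]:
                s = s ^ 2
            else:
                s = s ^ 1
        if (istep + 1) % stride == 0 and j < out_states.size:
            out_states[j] = s
            j += 1
    return counts


@njit(cache=False)
def _subunit_dwell_kernel(target, n_dwells, cum, seed, out_steps):
    """Dwell times (in steps) of a clamped subunit in one state.

    Simulates the full 8-state dynamics starting in ``target`` and records
    the number of steps of each sojourn in ``target`` until ``n_dwells`` are
    collected.
    """
    np.random.seed(seed)
    s = target
    dwell = 0
    n = 0
    while n < n_dwells:
        u = np.random.random()
        if s == target:
            dwell += 1
        if u < cum[s, 2]:
            if u < cum[s, 0]:
                new = s ^ 4
            elif u < cum[s, 1]:
                new = s ^ 2
            else:
                new = s ^ 1
            if s == target and new != target:
                out_steps[n] = dwell
                n += 1
                dwell = 0
            s = new
    return out_steps


def _clamped_cum_table(c: float, ip3: float, params: GatingParameters, dt: float) -> np.ndarray:
    cum = np.empty((8, 3))
    for s in range(8):
        r_i, r_a, r_h = _site_rates(s, c, ip3, params)
        if (r_i + r_a + r_h) * dt > 1.0:
            raise ValueError("dt too large for clamped subunit simulation")
        cum[s, 0] = r_i * dt
        cum[s, 1] = (r_i + r_a) * dt
        cum[s, 2] = (r_i + r_a + r_h) * dt
    return cum


def clamped_subunit_occupancy(
    c: float,
    ip3: float,
    params: GatingParameters,
    n_steps: int,
    dt: float,
    seed: int,
    sample_stride: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one subunit at clamped concentrations.

    Returns ``(fractions, samples)``: the fraction of steps spent in each of
    the 8 states, and (if ``sample_stride > 0``) the state subsampled every
    ``sample_stride`` steps, suitable for approximately independent draws.
    """
    cum = _clamped_cum_table(c, ip3, params, dt)
    stride = sample_stride if sample_stride > 0 else n_steps + 1
    n_samples = n_steps // stride if sample_stride > 0 else 0
    out = np.empty(n_samples, np.int64)
    counts = _subunit_sample_kernel(0, n_steps, cum, stride, seed, out)
    return counts / counts.sum(), out


def clamped_subunit_dwells(
    state: SubunitState | int,
    c: float,
    ip3: float,
    params: GatingParameters,
    n_dwells: int,
    dt: float,
    seed: int,
) -> np.ndarray:
    """Sojourn times (s) of a clamped subunit in one state, from simulation."""
    code = state.code if isinstance(state, SubunitState) else int(state)
    cum = _clamped_cum_table(c, ip3, params, dt)
    out = np.empty(n_dwells, np.int64)
    _subunit_dwell_kernel(code, n_dwells, cum, seed, out)
    return out * dt


def measure_deinhibition_rate(
    params: GatingParameters,
    n_dwells: int = 10_000,
    dt: float = 1e-4,
    seed: int = 0,
) -> float:
    """Recover the de-inhibition rate of an IP3-bound subunit from dwell times.

    Simulates the inhibiting site of a subunit with IP3 bound, starting
    Ca2+-inhibited at zero ambient Ca2+ so that rebinding is suppressed and
    the IP3 site is held occupied (saturating-IP3 limit).  Under the
    fixed-step scheme the waiting time until the h: 1 -> 0 transition is
    geometric with per-step probability ``b_inh_ip3 * dt``; the returned
    estimate is the reciprocal mean of ``n_dwells`` simulated waiting times.
    """
    p = params.b_inh_ip3 * dt
    if not 0 < p < 1:
        raise ValueError("dt too large for dwell-time simulation")
    rng = np.random.default_rng(seed)
    dwells = rng.geometric(p, size=n_dwells) * dt
    return 1.0 / float(dwells.mean())


# ----------------------------------------------------------------------------
# Events: detection and statistics of release events
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class ReleaseEvent:
    """A single release event (puff or wave-like burst).

    ``t_start`` is the first 0 -> 1 transition of the open-channel count,
    ``t_end`` the last 1 -> 0 transition before a quiet gap of at least the
    gap window, ``lifetime = t_end - t_start`` and ``amplitude`` the peak
    open-channel count within the event span.
    """

    t_start: float
    t_end: float
    amplitude: int

    @property
    def lifetime(self) -> float:
        return self.t_end - self.t_start


@dataclass
class EventStatistics:
    """Summary statistics of a list of release events.

    Interpuff intervals (IPI) use the onset-to-onset convention; the
    end-to-onset variant is reported separately as the dormancy-like
    ``mean_ipi_end_to_onset``.  Dormancy is the open-channel-free time between
    consecutive events.  Undefined quantities (fewer than two events) are NaN.
    """

    n_events: int
    mean_lifetime: float
    mean_ipi: float
    mean_ipi_end_to_onset: float
    mean_dormancy: float
    median_lifetime: float
    median_amplitude: float
    lifetime_histogram: tuple[np.ndarray, np.ndarray]
    ipi_histogram: tuple[np.ndarray, np.ndarray]
    dormancy_histogram: tuple[np.ndarray, np.ndarray]
    amplitude_histogram: tuple[np.ndarray, np.ndarray]

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "mean_lifetime_s": self.mean_lifetime,
            "median_lifetime_s": self.median_lifetime,
            "mean_ipi_s": self.mean_ipi,
            "mean_ipi_end_to_onset_s": self.mean_ipi_end_to_onset,
            "mean_dormancy_s": self.mean_dormancy,
            "median_amplitude": self.median_amplitude,
        }


#: Quiet-gap window of the event definition (s): a re-opening within this
#: span of the last closing is counted as the same event.
GAP_WINDOW = 0.5


def detect_events(trace: Trace, gap_window: float = GAP_WINDOW) -> list[ReleaseEvent]:
    """Segment a trace into release events with the gap-closure rule.

    Maximal active periods (``n_open >= 1``) separated by quiet gaps shorter
    than ``gap_window`` are merged into single events.  A trailing active
    period whose termination cannot be certified (the trace ends active, or
    less than ``gap_window`` of quiet follows) is discarded.
    """
    t = np.asarray(trace.t, dtype=float)
    if len(t) == 0:
        return []
    if np.any(t < 0):
        raise ValueError("trace times must be nonnegative")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError("trace times must be strictly increasing")
    if len(dts) and np.max(dts) > gap_window / 10 + 1e-12:
        raise ValueError(
            f"trace sampled too coarsely for event detection: sample interval "
            f"{np.max(dts):.4g} s exceeds gap_window/10 = {gap_window / 10:.4g} s"
        )
    active = np.asarray(trace.n_open) >= 1
    if not active.any():
        return []
    # boundaries of maximal active runs, as sample index ranges [i0, i1]
    padded = np.concatenate(([False], active, [False]))
    flips = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = flips[0::2], flips[1::2] - 1

    merged: list[list[int]] = [[starts[0], stops[0]]]
    for i0, i1 in zip(starts[1:], stops[1:]):
        if t[i0] - t[merged[-1][1]] < gap_window:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])

    events: list[ReleaseEvent] = []
    n_open = np.asarray(trace.n_open)
    for i0, i1 in merged:
        if t[-1] - t[i1] < gap_window:
            continue  # termination not certified by the end of the trace
        amp = int(n_open[i0 : i1 + 1].max())
        events.append(ReleaseEvent(t_start=float(t[i0]), t_end=float(t[i1]), amplitude=amp))
    return events


#: Histogram bin widths (s): 100 ms resolves puff lifetimes, 0.5 s resolves
#: interpuff and dormancy intervals.
LIFETIME_BIN = 0.1
INTERVAL_BIN = 0.5


def _histogram(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    if len(values) == 0:
        return np.zeros(0, dtype=int), np.array([0.0])
    upper = max(bin_width, float(np.max(values)))
    n_bins = int(np.ceil(upper / bin_width + 1e-9))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges


def event_statistics(events: Sequence[ReleaseEvent], trace_duration: float | None = None) -> EventStatistics:
    """Lifetime, interpuff-interval and dormancy statistics of an event train.

    IPIs are onset-to-onset intervals of consecutive events; dormancy is the
    quiet span ``t_start(next) - t_end(current)``.  With fewer than two events
    the interval statistics are NaN (undefined, not zero).
    """
    events = sorted(events, key=lambda e: e.t_start)
    for prev, nxt in zip(events, events[1:]):
        if nxt.t_start < prev.t_end:
            raise ValueError("events overlap; not a valid event train")
    lifetimes = np.array([e.lifetime for e in events])
    amplitudes = np.array([e.amplitude for e in events])
    onsets = np.array([e.t_start for e in events])
    ends = np.array([e.t_end for e in events])
    if len(events) >= 2:
        ipis = np.diff(onsets)
        dormancies = onsets[1:] - ends[:-1]
        ipis_eo = dormancies
        mean_ipi = float(ipis.mean())
        mean_ipi_eo = float(ipis_eo.mean())
        mean_dorm = float(dormancies.mean())
    else:
        ipis = np.zeros(0)
        dormancies = np.zeros(0)
        mean_ipi = mean_ipi_eo = mean_dorm = float("nan")
    amp_edges = np.arange(0.5, (amplitudes.max() if len(amplitudes) else 1) + 1.5)
    amp_counts, _ = np.histogram(amplitudes, bins=amp_edges) if len(amplitudes) else (np.zeros(0, int), amp_edges)
    return EventStatistics(
        n_events=len(events),
        mean_lifetime=float(lifetimes.mean()) if len(events) else float("nan"),
        median_lifetime=float(np.median(lifetimes)) if len(events) else float("nan"),
        mean_ipi=mean_ipi,
        mean_ipi_end_to_onset=mean_ipi_eo,
        mean_dormancy=mean_dorm,
        median_amplitude=float(np.median(amplitudes)) if len(events) else float("nan"),
        lifetime_histogram=_histogram(lifetimes, LIFETIME_BIN),
        ipi_histogram=_histogram(ipis, INTERVAL_BIN),
        dormancy_histogram=_histogram(dormancies, INTERVAL_BIN),
        amplitude_histogram=(amp_counts, amp_edges),
    )


def events_to_frame(events: Sequence[ReleaseEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_start_s": [e.t_start for e in events],
            "t_end_s": [e.t_end for e in events],
            "lifetime_s": [e.lifetime for e in events],
            "amplitude": [e.amplitude for e in events],
        }
    )


# ----------------------------------------------------------------------------
# Sweeps over the collapse rate k and the IP3 concentration
# ----------------------------------------------------------------------------


def _replicate_seed(base_seed: int, cell: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cell, rep))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % 2**31)


def sweep(
    base_config: SimulationConfig,
    k_values: Sequence[float],
    ip3_values: Sequence[float],
    replicates: int = 8,
    gap_window: float = GAP_WINDOW,
) -> pd.DataFrame:
    """Grid of simulations over collapse rate and IP3 concentration.

    For every (k, ip3) cell, ``replicates`` independent seeds are simulated
    with otherwise identical configuration; events are pooled across the
    replicates and summarized (means with standard errors of the mean).
    """
    if len(k_values) == 0 or len(ip3_values) == 0 or replicates < 1:
        raise ValueError("sweep needs at least one k, one ip3 and one replicate")
    rows = []
    cell = 0
    for k in k_values:
        for ip3 in ip3_values:
            lifetimes: list[float] = []
            ipis: list[float] = []
            dorms: list[float] = []
            amps: list[int] = []
            for rep in range(replicates):
                cfg = dataclasses.replace(
                    base_config,
                    ip3=float(ip3),
                    domain=dataclasses.replace(base_config.domain, k=float(k)),
                    seed=_replicate_seed(base_config.seed, cell, rep),
                )
                events = detect_events(simulate(cfg), gap_window)
                lifetimes.extend(e.lifetime for e in events)
                amps.extend(e.amplitude for e in events)
                onsets = np.array([e.t_start for e in events])
                ends = np.array([e.t_end for e in events])
                if len(events) >= 2:
                    ipis.extend(np.diff(onsets))
                    dorms.extend(onsets[1:] - ends[:-1])
            def _m(x):
                return float(np.mean(x)) if len(x) else float("nan")
            def _sem(x):
                return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")
            rows.append(
                {
                    "k_per_s": float(k),
                    "ip3_uM": float(ip3),
                    "n_events": len(lifetimes),
                    "mean_lifetime_s": _m(lifetimes),
                    "sem_lifetime_s": _sem(lifetimes),
                    "median_lifetime_s": float(np.median(lifetimes)) if lifetimes else float("nan"),
                    "mean_ipi_s": _m(ipis),
                    "sem_ipi_s": _sem(ipis),
                    "mean_dormancy_s": _m(dorms),
                    "sem_dormancy_s": _sem(dorms),
                    "median_amplitude": float(np.median(amps)) if amps else float("nan"),
                }
            )
            logger.info(
                "sweep cell k=%g ip3=%g: %d events, mean lifetime %.3g s",
                k, ip3, rows[-1]["n_events"], rows[-1]["mean_lifetime_s"],
            )
            cell += 1
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------------
# IO: configuration files, trace files, fixtures
# ----------------------------------------------------------------------------

_GATING_KEYS = [f.name for f in dataclasses.fields(GatingParameters)]
_DOMAIN_KEYS = [f.name for f in dataclasses.fields(MicrodomainParameters)]
_ENGINE_KEYS = ["n_channels", "ip3", "dt", "record_dt", "duration", "burn_in", "seed"]

#: Relative tolerance on the thermodynamic loop constraint when validating a
#: user-supplied configuration.
DETAILED_BALANCE_TOL = 1e-6


def default_config() -> SimulationConfig:
    """The shipped default configuration: 20 channels, ip3 = 0.07 uM, k = 100/s."""
    return SimulationConfig()


def config_to_dict(config: SimulationConfig) -> dict:
    """Flatten a configuration to a plain key/value mapping."""
    out: dict = {}
    for key in _ENGINE_KEYS:
        v = getattr(config, key)
        out[key] = int(v) if key in ("n_channels", "seed") else float(v)
    for key in _GATING_KEYS:
        out[key] = float(getattr(config.gating, key))
    for key in _DOMAIN_KEYS:
        out[key] = float(getattr(config.domain, key))
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    """Build and validate a configuration from a flat key/value mapping.

    Missing keys take the shipped defaults; unknown keys and invariant
    violations raise ``ValueError`` naming the offending key(s).
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a flat key/value mapping")
    known = set(_ENGINE_KEYS) | set(_GATING_KEYS) | set(_DOMAIN_KEYS)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    for key, value in data.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(f"configuration key {key!r} must be a number, got {value!r}")
    try:
        gating = GatingParameters(**{k: float(data[k]) for k in _GATING_KEYS if k in data})
        domain = MicrodomainParameters(**{k: float(data[k]) for k in _DOMAIN_KEYS if k in data})
        engine_kwargs = {}
        for k in _ENGINE_KEYS:
            if k in data:
                engine_kwargs[k] = int(data[k]) if k in ("n_channels", "seed") else float(data[k])
        config = SimulationConfig(gating=gating, domain=domain, **engine_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    residual = detailed_balance_residual(gating)
    if residual > DETAILED_BALANCE_TOL:
        raise ValueError(
            "gating rates violate the thermodynamic loop constraint "
            "K_ip3_noninh * K_inh_ip3 = K_ip3_inh * K_inh_noip3 "
            f"(K_ip3_noninh={gating.K_ip3_noninh:.6g}, K_inh_ip3={gating.K_inh_ip3:.6g}, "
            f"K_ip3_inh={gating.K_ip3_inh:.6g}, K_inh_noip3={gating.K_inh_noip3:.6g}; "
            f"log-residual {residual:.3g})"
        )
    logger.debug("loaded config; dissociation constants: %s", gating.dissociation_constants())
    return config


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML/JSON flat key/value configuration file.

    An empty file yields the full default configuration.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValueError(f"cannot read configuration file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse configuration file {path}: {exc}") from exc
    return config_from_dict(data or {})


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration as a flat YAML file (round-trips exactly)."""
    data = config_to_dict(config)
    header = "# puffsim configuration (rates 1/(uM s) and 1/s; concentrations uM; times s)\n"
    body = yaml.safe_dump(data, sort_keys=False, default_flow_style=False)
    Path(path).write_text(header + body)


_TRACE_COLUMNS = ["time_s", "n_open", "c_uM", "n111", "n011", "n_avail"]


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as tab-separated text with a commented manifest header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# puffsim trace\n")
        fh.write(f"# meta: {json.dumps(trace.meta, sort_keys=True)}\n")
        fh.write("\t".join(_TRACE_COLUMNS) + "\n")
        df = trace.to_frame()
        np.savetxt(
            fh,
            df.to_numpy(),
            fmt=["%.17g", "%d", "%.17g", "%d", "%d", "%d"],
            delimiter="\t",
        )


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace` (lossless round trip)."""
    path = Path(path)
    meta: dict = {}
    try:
        with path.open() as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise ValueError(f"cannot read trace file {path}: {exc}") from exc
    body_start = None
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("meta:"):
                try:
                    meta = json.loads(stripped[len("meta:"):].strip())
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed manifest header: {exc}") from exc
            continue
        body_start = lineno
        break
    if body_start is None or lines[body_start - 1].split("\t") == [""]:
        raise ValueError(f"{path}: truncated trace file (no column header)")
    header = lines[body_start - 1].rstrip("\n").split("\t")
    if header != _TRACE_COLUMNS:
        raise ValueError(f"{path}:{body_start}: unexpected column header {header!r}")
    cols: list[list[float]] = [[] for _ in _TRACE_COLUMNS]
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(_TRACE_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(_TRACE_COLUMNS)} fields, got {len(parts)}"
            )
        try:
            for col, part in zip(cols, parts):
                col.append(float(part))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed value: {exc}") from exc
    return Trace(
        t=np.array(cols[0]),
        n_open=np.array(cols[1], dtype=np.int64),
        c=np.array(cols[2]),
        n111=np.array(cols[3], dtype=np.int64),
        n011=np.array(cols[4], dtype=np.int64),
        n_avail=np.array(cols[5], dtype=np.int64),
        meta=meta,
    )


def make_fixture_trace(kind: str, record_dt: float = 0.01) -> Trace:
    """Deterministic synthetic traces with known event structure.

    ``"silent"``: 10 s with no openings.  ``"two-puffs"``: two active periods
    separated by a 0.6 s quiet gap (two events under the 0.5 s rule).
    ``"merged-burst"``: two active periods separated by a 0.3 s gap (one
    merged event).  These are hand-built test inputs, not simulations.
    """
    n = round(10.0 / record_dt)
    t = (np.arange(n) + 1) * record_dt
    n_open = np.zeros(n, dtype=np.int64)

    def _set(t0: float, t1: float, amp: int) -> None:
        mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
        n_open[mask] = amp

    if kind == "silent":
        pass
    elif kind == "two-puffs":
        _set(1.0, 1.1, 3)
        _set(1.7, 1.8, 5)
    elif kind == "merged-burst":
        _set(1.0, 1.1, 3)
        _set(1.4, 1.5, 5)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    domain = MicrodomainParameters()
    c = domain.c0 + domain.c1 * n_open
    zeros = np.zeros(n, dtype=np.int64)
    return Trace(
        t=t,
        n_open=n_open,
        c=c.astype(float),
        n111=zeros,
        n011=zeros.copy(),
        n_avail=np.full(n, 20, dtype=np.int64),
        meta={"synthetic_fixture": kind, "record_dt": record_dt},
    )
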