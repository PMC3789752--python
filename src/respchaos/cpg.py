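"""Map-based two-pacemaker model of respiratory rhythmogenesis.

Two discrete-time (map-based) pacemaker neurons — the pre-Bötzinger complex
(preBötC, inspiratory) and the parafacial respiratory group (pFRG, expiratory)
— are coupled through chemical synapses and iterated synchronously.  Each unit
is a discrete FitzHugh–Nagumo-type map (Courbage–Nekorkin form) with a
piecewise-linear cubic nullcline ``F(x)``, a Heaviside spike-reset term, and a
low-threshold calcium current ``I_T`` that produces post-inhibitory rebound
bursts:

    x[n+1] = x[n] + F(x[n]) - y[n] - beta * H(x[n] - d) + I_T[n] + I_syn[n]
    y[n+1] = y[n] + epsilon * (x[n] - J)

``x`` plays the role of the membrane potential, ``y`` aggregates the outward
(recovery) currents, and ``J`` sets the excitability of the unit.  The unit is
quiescent for ``J`` below the lower breakpoint of ``F``, fires chaotic
spike-bursting oscillations for ``J`` inside the window between the two
breakpoints, and sits at a depolarized rest above it.

The calcium current de-inactivates while the unit is hyperpolarized below
``x_th`` and produces a depolarizing rebound current upon release; ``tau1``
sets the rebound-burst duration and ``tau2`` the hyperpolarization duration
needed to recruit a maximal rebound.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PacemakerParams",
    "PacemakerState",
    "SynapseSpec",
    "NetworkConfig",
    "SimulationTrace",
    "DivergenceError",
    "piecewise_F",
    "heaviside",
    "calcium_current",
    "syn_current",
    "step",
    "simulate",
    "detect_spikes",
    "detect_bursts",
    "classify_regime",
    "load_preset",
    "PRESET_NAMES",
]

# |x| or |y| beyond this aborts the simulation; the nominal oscillation range
# of the map is about [-0.1, 0.7], so 10x that range signals bad parameters.
DIVERGENCE_BOUND = 7.0

REGIME_LABELS = (
    "no_handshake",
    "dominant_preBot_occasional_pfrg",
    "full_handshake",
    "half_handshake",
    "unclassified",
)


class DivergenceError(RuntimeError):
    """State left the admissible range during iteration."""


@dataclass(frozen=True)
class PacemakerParams:
    """Constants of one map-based pacemaker.

    epsilon : recovery time scale (>0, dimensionless)
    beta    : amplitude of the Heaviside reset term
    d       : Heaviside threshold on x
    a       : shape parameter of the piecewise-linear cubic F
    m0, m1  : outer / middle slopes of F (>0)
    J       : excitability level
    delta   : maximal conductance of the low-threshold calcium current
    x_th    : calcium activation/de-inactivation threshold on x
    tau1    : rebound-burst duration (steps)
    tau2    : hyperpolarization duration recruiting a maximal rebound (steps)
    """

    epsilon: float = 0.005
    beta: float = 0.4
    d: float = 0.4
    a: float = 0.2
    m0: float = 0.864
    m1: float = 0.65
    J: float = 0.25
    delta: float = 0.2
    x_th: float = -0.02
    tau1: int = 10
    tau2: int = 2

    def __post_init__(self) -> None:
        if not (self.m0 > 0 and self.m1 > 0):
            raise ValueError("slopes m0 and m1 must be positive")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.tau1 < 1 or self.tau2 < 1:
            raise ValueError("tau1 and tau2 must be >= 1 steps")
        for name in ("epsilon", "beta", "d", "a", "m0", "m1", "J", "delta", "x_th"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")

    @property
    def j_min(self) -> float:
        """Lower breakpoint of F; quiescent rest below, oscillations above."""
        return self.a * self.m1 / (self.m0 + self.m1)

    @property
    def j_max(self) -> float:
        """Upper breakpoint of F; depolarized rest above."""
        return (self.m0 + self.a * self.m1) / (self.m0 + self.m1)


@dataclass
class PacemakerState:
    """Dynamic variables of one unit.

    x : membrane-potential-like variable
    y : recovery variable (aggregate outward currents)
    k : calcium de-inactivation level in [0, 1]
    hyperpol_counter : consecutive steps spent below x_th
    """

    x: float
    y: float
    k: float = 0.0
    hyperpol_counter: int = 0


@dataclass
class SynapseSpec:
    """Rectangular-pulse chemical synapse.

    K > 0 is excitatory, K < 0 inhibitory.  Each presynaptic spike at step
    ``n_i`` injects the constant ``K`` into the target for the ``tau_syn``
    steps following the spike (steps ``n_i + 1 .. n_i + tau_syn``).
    """

    source: str
    target: str
    K: float
    tau_syn: int
    spike_steps: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tau_syn < 1:
            raise ValueError("tau_syn must be >= 1")
        steps = np.asarray(self.spike_steps, dtype=int)
        if steps.size > 1 and not np.all(np.diff(steps) > 0):
            raise ValueError("spike_steps must be strictly increasing")


@dataclass
class NetworkConfig:
    """Complete specification of a two-unit simulation."""

    pfrg_params: PacemakerParams
    prebot_params: PacemakerParams
    synapses: list[SynapseSpec] = field(default_factory=list)
    offswitch_enabled: bool = False
    n_steps: int = 60_000
    n_transient: int = 5_000
    init_state: Optional[tuple[PacemakerState, PacemakerState]] = None
    seed: Optional[int] = 0
    spike_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.n_transient >= self.n_steps:
            raise ValueError("n_transient must be smaller than n_steps")
        if self.init_state is None and self.seed is None:
            raise ValueError("either init_state or a seed is required")


@dataclass
class SimulationTrace:
    """Per-step states of both units plus spike/burst annotations.

    Arrays have length ``n_steps``; spike indices and burst intervals are
    restricted to the post-transient window ``[n_transient, n_steps)``.
    Burst intervals are (first-spike, last-spike) step pairs.
    """

    x: dict[str, np.ndarray]
    y: dict[str, np.ndarray]
    k: dict[str, np.ndarray]
    spikes: dict[str, np.ndarray]
    bursts: dict[str, list[tuple[int, int]]]
    n_transient: int
    regime: str = "unclassified"
    config: Optional[NetworkConfig] = None


def heaviside(u: float) -> int:
    """Heaviside step with the convention H(0) = 1."""
    return 1 if u >= 0 else 0


def piecewise_F(x, params: PacemakerParams):
    """Piecewise-linear cubic nullcline of the map.

    Three branches with slopes -m0, +m1, -m0 joined continuously at the
    breakpoints ``j_min = a*m1/(m0+m1)`` and ``j_max = (m0+a*m1)/(m0+m1)``.
    Accepts scalars or arrays.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    lo, hi = params.j_min, params.j_max
    out = np.where(
        arr <= lo,
        -params.m0 * arr,
        np.where(arr < hi, params.m1 * (arr - params.a), -params.m0 * (arr - 1.0)),
    )
    return float(out) if np.isscalar(x) else out


def calcium_current(state: PacemakerState, params: PacemakerParams) -> float:
    """Low-threshold calcium (rebound) current I_T = delta * G(k) * H(x - x_th).

    ``G(k) = k`` is the de-inactivation level: it charges toward 1 at rate
    1/tau2 per step while the unit is hyperpolarized below ``x_th`` and
    discharges at rate 1/tau1 while above, so a hyperpolarization of at least
    tau2 steps recruits a maximal rebound whose duration is set by tau1.
    """
    return params.delta * state.k * heaviside(state.x - params.x_th)


def _advance_gating(state: PacemakerState, params: PacemakerParams) -> tuple[float, int]:
    if state.x < params.x_th:
        return min(1.0, state.k + 1.0 / params.tau2), state.hyperpol_counter + 1
    return max(0.0, state.k - 1.0 / params.tau1), 0


def syn_current(syn: SynapseSpec, n: int) -> float:
    """Synaptic input at step ``n``: K within tau_syn steps after any spike."""
    if n < 0:
        raise ValueError("step index must be non-negative")
    for n_i in reversed(list(syn.spike_steps)):
        if n_i >= n:
            continue
        return syn.K if n - n_i <= syn.tau_syn else 0.0
    return 0.0


def _step_unit(
    state: PacemakerState, params: PacemakerParams, i_ext: float
) -> PacemakerState:
    i_t = calcium_current(state, params)
    x_new = (
        state.x
        + piecewise_F(state.x, params)
        - state.y
        - params.beta * heaviside(state.x - params.d)
        + i_t
        + i_ext
    )
    y_new = state.y + params.epsilon * (state.x - params.J)
    k_new, hyp = _advance_gating(state, params)
    if abs(x_new) > DIVERGENCE_BOUND or abs(y_new) > DIVERGENCE_BOUND:
        raise DivergenceError(
            f"state diverged (|x| or |y| > {DIVERGENCE_BOUND}) with "
            f"J={params.J}, epsilon={params.epsilon}, beta={params.beta}"
        )
    return PacemakerState(x_new, y_new, k_new, hyp)


def step(
    states: tuple[PacemakerState, PacemakerState],
    config: NetworkConfig,
    n: int,
) -> tuple[PacemakerState, PacemakerState]:
    """One synchronous update of (pFRG, preBötC) at step ``n``.

    Synaptic inputs are evaluated from the spike steps recorded in
    ``config.synapses``; when the inspiratory off-switch is enabled the pFRG
    rebound current is mirrored as an inhibitory pulse onto the preBötC (same
    amplitude and duration as the rebound burst).
    """
    pfrg, prebot = states
    inputs = {"pfrg": 0.0, "prebot": 0.0}
    for syn in config.synapses:
        inputs[syn.target] += syn_current(syn, n)
    if config.offswitch_enabled:
        inputs["prebot"] -= calcium_current(pfrg, config.pfrg_params)
    return (
        _step_unit(pfrg, config.pfrg_params, inputs["pfrg"]),
        _step_unit(prebot, config.prebot_params, inputs["prebot"]),
    )


def _default_init(config: NetworkConfig) -> tuple[PacemakerState, PacemakerState]:
    # Small uniform ranges around zero; the transient window absorbs the
    # approach to the attractor.
    rng = np.random.default_rng(config.seed)
    vals = rng.uniform(-0.05, 0.05, size=4)
    return (
        PacemakerState(vals[0], vals[1], 0.0, 0),
        PacemakerState(vals[2], vals[3], 0.0, 0),
    )


def simulate(config: NetworkConfig, classify: bool = True) -> SimulationTrace:
    """Iterate the coupled network for ``config.n_steps`` steps.

    Spikes are detected online as upward crossings of
    ``config.spike_threshold`` and drive the synaptic pulses; post-transient
    spikes and bursts are annotated on the returned trace and the
    synchronization regime is classified.
    """
    names = ("pfrg", "prebot")
    params = {"pfrg": config.pfrg_params, "prebot": config.prebot_params}
    n_steps = config.n_steps
    x = {u: np.empty(n_steps) for u in names}
    y = {u: np.empty(n_steps) for u in names}
    k = {u: np.empty(n_steps) for u in names}
    spikes_all: dict[str, list[int]] = {u: [] for u in names}

    init = config.init_state if config.init_state else _default_init(config)
    # Flat scalar state for the hot loop; constants hoisted per unit.
    state = {
        u: [float(s.x), float(s.y), float(s.k), int(s.hyperpol_counter)]
        for u, s in zip(names, init)
    }
    consts = {}
    for u in names:
        p = params[u]
        consts[u] = (
            p.epsilon, p.beta, p.d, p.m0, p.m1, p.a, p.J, p.delta, p.x_th,
            1.0 / p.tau1, 1.0 / p.tau2, p.j_min, p.j_max,
        )
    # Per-synapse pulse bookkeeping: step index until which the pulse is live.
    syn_info = [(s.source, s.target, s.K, s.tau_syn) for s in config.synapses]
    active_until = [-1] * len(syn_info)
    thr = config.spike_threshold
    offsw = config.offswitch_enabled
    pf_delta, pf_xth = consts["pfrg"][7], consts["pfrg"][8]
    xs = {u: x[u] for u in names}

    for n in range(n_steps):
        i_pf = 0.0
        i_pb = 0.0
        for j, (_, target, kk, _) in enumerate(syn_info):
            if n <= active_until[j]:
                if target == "pfrg":
                    i_pf += kk
                else:
                    i_pb += kk
        if offsw:
            spf = state["pfrg"]
            if spf[0] >= pf_xth:
                i_pb -= pf_delta * spf[2]

        for u in names:
            eps, beta, d, m0, m1, a, J, delta, x_th, inv_t1, inv_t2, lo, hi = consts[u]
            xv, yv, kv, hyp = state[u]
            i_ext = i_pf if u == "pfrg" else i_pb
            if xv <= lo:
                f = -m0 * xv
            elif xv < hi:
                f = m1 * (xv - a)
            else:
                f = -m0 * (xv - 1.0)
            i_t = delta * kv if xv >= x_th else 0.0
            x_new = xv + f - yv - (beta if xv >= d else 0.0) + i_t + i_ext
            y_new = yv + eps * (xv - J)
            if xv < x_th:
                kv = kv + inv_t2
                if kv > 1.0:
                    kv = 1.0
                hyp += 1
            else:
                kv = kv - inv_t1
                if kv < 0.0:
                    kv = 0.0
                hyp = 0
            if abs(x_new) > DIVERGENCE_BOUND or abs(y_new) > DIVERGENCE_BOUND:
                raise DivergenceError(
                    f"state diverged (|x| or |y| > {DIVERGENCE_BOUND}) with "
                    f"J={J}, epsilon={eps}, beta={beta}"
                )
            if xv < thr <= x_new:
                spikes_all[u].append(n)
                for j, (source, _, _, tau_s) in enumerate(syn_info):
                    if source == u:
                        active_until[j] = n + tau_s
            state[u] = [x_new, y_new, kv, hyp]
            xs[u][n] = x_new
            y[u][n] = y_new
            k[u][n] = kv

    spikes = {
        u: np.array([s for s in spikes_all[u] if s >= config.n_transient], dtype=int)
        for u in names
    }
    bursts = {u: detect_bursts(spikes[u]) for u in names}
    trace = SimulationTrace(
        x=x, y=y, k=k, spikes=spikes, bursts=bursts,
        n_transient=config.n_transient, config=config,
    )
    if classify:
        trace.regime = classify_regime(trace)
    return trace


def detect_spikes(x_series, threshold: Optional[float] = None) -> np.ndarray:
    """Indices of upward crossings of ``threshold`` in an x series.

    Default threshold is the midpoint of the series range.  A constant series
    has no crossings and yields an empty result.
    """
    xs = np.asarray(x_series, dtype=float)
    if xs.size < 2:
        raise ValueError("series must have at least 2 samples")
    if threshold is None:
        lo, hi = xs.min(), xs.max()
        if hi == lo:
            return np.array([], dtype=int)
        threshold = 0.5 * (lo + hi)
    return np.where((xs[:-1] < threshold) & (xs[1:] >= threshold))[0] + 1


def detect_bursts(spikes, gap: Optional[int] = None) -> list[tuple[int, int]]:
    """Group ordered spike indices into bursts.

    A burst is a maximal run of spikes whose inter-spike intervals are all
    <= ``gap``.  The default gap is 3x the median inter-spike interval of the
    input (intra-burst intervals dominate the median for bursting traces);
    it is configurable for non-bursting (tonic) traces.
    """
    sp = np.asarray(spikes, dtype=int)
    if sp.size == 0:
        return []
    if sp.size == 1:
        return [(int(sp[0]), int(sp[0]))]
    isi = np.diff(sp)
    if gap is None:
        gap = int(max(1, round(3 * float(np.median(isi)))))
    breaks = np.where(isi > gap)[0]
    onsets = np.concatenate(([0], breaks + 1))
    offsets = np.concatenate((breaks, [sp.size - 1]))
    return [(int(sp[i]), int(sp[j])) for i, j in zip(onsets, offsets)]


def classify_regime(
    trace: SimulationTrace,
    trigger_window: int = 60,
    rebound_window: int = 60,
    majority: float = 0.7,
) -> str:
    """Label the synchronization regime of an annotated trace.

    * ``no_handshake``       — the parafacial emits no spikes at all.
    * ``dominant_preBot_occasional_pfrg`` — the parafacial is active for only
      a minority of pre-Bötzinger cycles.
    * ``full_handshake``     — each preBötC burst onset is preceded (within
      ``trigger_window`` steps) by fresh pFRG pre-inspiratory activity and its
      offset is followed (within ``rebound_window`` steps) by a pFRG rebound.
    * ``half_handshake``     — the pFRG activity preceding preBötC onsets is
      itself a delayed rebound of the previous cycle, i.e. the rebound
      triggers the next pre-Bötzinger activation.

    The test works on spike times (handshake phases of a cycle can merge into
    a single detected burst): the pFRG spike immediately preceding a preBötC
    onset is rebound-like when it falls within ``rebound_window`` steps of
    the previous preBötC burst offset.  Traces with fewer than 5
    post-transient preBötC bursts are ``unclassified`` with a warning.
    """
    pf_spikes = trace.spikes["pfrg"]
    pb_bursts = trace.bursts["prebot"]

    if len(pf_spikes) == 0:
        return "no_handshake"
    if len(pb_bursts) < 5:
        warnings.warn("fewer than 5 pre-Bötzinger bursts; regime unclassified")
        return "unclassified"

    # Participation: fraction of preBötC cycles (onset-to-onset) in which the
    # parafacial spikes at all.  A minority marks the preBötC-dominant regime.
    pb_onsets = np.array([b[0] for b in pb_bursts])
    active = [
        np.any((pf_spikes >= lo) & (pf_spikes < hi))
        for lo, hi in zip(pb_onsets[:-1], pb_onsets[1:])
    ]
    if np.mean(active) < 0.5:
        return "dominant_preBot_occasional_pfrg"

    pb_offsets = np.array([b[1] for b in pb_bursts])
    n_pre = n_post = n_pre_rebound = 0
    for onset, offset in pb_bursts:
        before = pf_spikes[(pf_spikes < onset) & (pf_spikes >= onset - trigger_window)]
        if before.size:
            n_pre += 1
            last = int(before[-1])
            prior_off = pb_offsets[pb_offsets < last]
            if prior_off.size and last - prior_off[-1] <= rebound_window:
                n_pre_rebound += 1
        after = pf_spikes[(pf_spikes > offset) & (pf_spikes <= offset + rebound_window)]
        if after.size:
            n_post += 1

    n_cycles = len(pb_bursts)
    frac_pre = n_pre / n_cycles
    frac_post = n_post / n_cycles
    frac_rebound = n_pre_rebound / max(n_pre, 1)
    if frac_pre >= majority and frac_post >= majority:
        return "half_handshake" if frac_rebound >= 0.5 else "full_handshake"
    if frac_pre >= majority and frac_rebound >= 0.5:
        return "half_handshake"
    return "unclassified"


PRESET_NAMES = ("regime_A", "regime_B", "regime_C", "regime_D", "tonic")


def load_preset(
    name: str,
    n_steps: Optional[int] = None,
    n_transient: Optional[int] = None,
    seed: Optional[int] = 0,
) -> NetworkConfig:
    """Load a named network preset shipped with the package.

    ``regime_A`` … ``regime_D`` reproduce the four synchronization regimes
    (no-handshake, dominant-preBötC with occasional pFRG, full handshake,
    half handshake); ``tonic`` is a non-chaotic regular-spiking control.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("respchaos.presets").joinpath(f"{name}.json").read_text()
    raw = json.loads(text)
    cfg = NetworkConfig(
        pfrg_params=PacemakerParams(**raw["pfrg_params"]),
        prebot_params=PacemakerParams(**raw["prebot_params"]),
        synapses=[SynapseSpec(**s) for s in raw["synapses"]],
        offswitch_enabled=raw["offswitch_enabled"],
        n_steps=raw["n_steps"],
        n_transient=raw["n_transient"],
        seed=seed,
        spike_threshold=raw.get("spike_threshold", 0.3),
    )
    if n_steps is not None:
        cfg = replace(cfg, n_steps=n_steps)
    if n_transient is not None:
        cfg = replace(cfg, n_transient=n_transient)
    return cfg
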