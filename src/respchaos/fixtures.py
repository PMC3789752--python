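"""Seeded synthetic generators with known structure.

Every pipeline stage can be exercised without external recordings:

* ``gen_logistic`` / ``gen_henon`` — deterministic chaotic maps, the
  *alternative* for chaos-detection tests with known Lyapunov exponents and
  correlation dimensions.
* ``gen_ar_linear`` — linear-stochastic *null* series for type-I error tests.
* ``gen_sine_flow`` — sinusoidal flow traces for segmentation tests.
* ``gen_model_breaths`` — breath series driven by the map-based CPG, linking
  chaotic neuronal bursting to chaos in the simulated airflow.
* ``gen_covariates`` — physiological nuisance series (RVT, cardiac RR,
  end-tidal CO2, saturation) for regression-out tests.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from . import cpg
from .airflow import BreathSeries, FlowRecording
from .bold import CovariateSet

__all__ = [
    "gen_logistic",
    "gen_henon",
    "gen_ar_linear",
    "gen_sine_flow",
    "gen_model_breaths",
    "gen_covariates",
]


def gen_logistic(n: int, r: float = 4.0, x0: float = 0.3) -> np.ndarray:
    """Iterates of the logistic map x -> r x (1 - x).

    At r = 4 the map is fully chaotic with Lyapunov exponent ln 2 per step.
    Orbits through x = 0.5 collapse onto the fixed point 0 (degenerate); the
    generator warns when that happens.
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie strictly inside (0, 1)")
    out = np.empty(n)
    x = x0
    for i in range(n):
        x = r * x * (1.0 - x)
        out[i] = x
    if np.any(out == 0.0):
        warnings.warn("orbit hit the fixed point 0 (degenerate initial condition)")
    return out


def gen_henon(
    n: int, a: float = 1.4, b: float = 0.3, x0: float = 0.1, y0: float = 0.0,
    discard: int = 100,
) -> np.ndarray:
    """x-coordinate of the Hénon map; a benchmark strange attractor."""
    x, y = x0, y0
    out = np.empty(n)
    for i in range(n + discard):
        x, y = 1.0 - a * x * x + y, b * x
        if i >= discard:
            out[i - discard] = x
    return out


def gen_ar_linear(
    n: int, coefficients, noise_sd: float = 1.0, seed: int = 0, burn_in: int = 200
) -> np.ndarray:
    """Seeded Gaussian-driven autoregressive series (linear-stochastic null)."""
    coeffs = np.asarray(coefficients, dtype=float)
    p = coeffs.size
    if p:
        companion = np.zeros((p, p))
        companion[0] = coeffs
        if p > 1:
            companion[1:, :-1] = np.eye(p - 1)
        if np.any(np.abs(np.linalg.eigvals(companion)) >= 1.0):
            raise ValueError("explosive AR coefficients (non-stationary)")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, n + burn_in)
    out = np.zeros(n + burn_in)
    for i in range(n + burn_in):
        past = sum(
            coeffs[j] * out[i - 1 - j] for j in range(min(p, i))
        )
        out[i] = past + eps[i]
    return out[burn_in:]


def gen_sine_flow(
    n_breaths: int,
    period_s: float = 4.0,
    amplitude: float = 0.5,
    fs: float = 400.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FlowRecording:
    """Sinusoidal flow trace: ``n_breaths`` cycles, optional additive noise."""
    if fs * period_s < 10:
        raise ValueError("need at least 10 samples per breath period")
    n = int(round(n_breaths * period_s * fs))
    t = np.arange(n) / fs
    flow = amplitude * np.sin(2 * np.pi * t / period_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flow = flow + rng.normal(0.0, noise_sd, n)
    return FlowRecording(flow, fs)


def gen_model_breaths(
    scheme: str,
    n_breaths: int,
    seed: int = 0,
    target_period_s: float = 4.0,
    max_steps: int = 1_200_000,
) -> BreathSeries:
    """Breath series driven by the simulated CPG.

    Each post-transient burst of the driving (most bursting) unit becomes one
    breath: the burst spans inspiration (Ti), the following inter-burst
    interval expiration (Te), and the inspired volume integrates the
    membrane-variable excursion above its minimum over the burst.  Map steps
    are scaled so the mean cycle matches ``target_period_s`` seconds.  Errors
    if the scheme cannot produce ``n_breaths`` bursts within the step budget.
    """
    n_steps = min(max(60_000, 300 * n_breaths), max_steps)
    while True:
        cfg = cpg.load_preset(scheme, n_steps=n_steps, seed=seed)
        trace = cpg.simulate(cfg, classify=False)
        cycles = {u: _burst_cycles(trace, u) for u in ("pfrg", "prebot")}
        driver = max(cycles, key=lambda u: len(cycles[u][0]))
        if len(cycles[driver][0]) >= n_breaths + 1:
            break
        if n_steps >= max_steps:
            raise RuntimeError(
                f"scheme {scheme!r} produced only {len(cycles[driver][0])} "
                f"bursts within {max_steps} steps; cannot build {n_breaths} breaths"
            )
        n_steps = min(max_steps, n_steps * 2)

    all_bursts, tonic = cycles[driver]
    bursts = all_bursts[: n_breaths + 1]
    x = trace.x[driver]
    onsets = np.array([b[0] for b in bursts])
    dt = target_period_s / float(np.mean(np.diff(onsets)))
    base = float(x[trace.n_transient:].min())

    onset_t, ti, te, vi = [], [], [], []
    for b in range(n_breaths):
        on, off = bursts[b]
        nxt = bursts[b + 1][0]
        dur_i = max(off - on + 1, 1)
        dur_e = max(nxt - off - 1, 1)
        onset_t.append(on * dt)
        ti.append(dur_i * dt)
        te.append(dur_e * dt)
        vi.append(float(np.sum(x[on: off + 1] - base)) * dt)
    ti, te, vi = np.array(ti), np.array(te), np.array(vi)
    if tonic:
        ti = np.full_like(ti, ti.mean())
        te = np.full_like(te, te.mean())
        vi = np.full_like(vi, vi.mean())
    return BreathSeries(
        onset_times=np.array(onset_t),
        Ti=ti,
        Te=te,
        Vt_i=vi,
        Vt_e=vi.copy(),  # volume conservation over the cycle
    )


def _burst_cycles(trace, unit: str) -> tuple[list[tuple[int, int]], bool]:
    """Burst intervals of one unit plus a tonic flag.

    Tonic (non-bursting) traces fall back to one cycle per spike.  Regular
    spiking carries no breath-to-breath structure — the residual variation of
    per-cycle integrals is pure step-quantization jitter — so callers replace
    the per-cycle values by their means (a constant null series).
    """
    bursts = trace.bursts[unit]
    spikes = trace.spikes[unit]
    if len(bursts) < 3 and spikes.size >= 3:
        return [(int(s), int(s)) for s in spikes], True
    return bursts, False


def gen_covariates(n: int, TR: float = 2.0, seed: int = 0) -> CovariateSet:
    """Physiological covariate series interpolated to the imaging grid.

    Smooth AR(1) fluctuations around realistic set points: respiratory volume
    per time (L/min), cardiac RR interval (s), end-tidal CO2 (mmHg) and
    oxygen saturation (%).
    """
    rng = np.random.default_rng(seed)

    def smooth(level: float, sd: float, phi: float = 0.9) -> np.ndarray:
        eps = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n)
        out = np.empty(n)
        acc = 0.0
        for i in range(n):
            acc = phi * acc + eps[i]
            out[i] = level + acc
        return out

    return CovariateSet(
        rvt=smooth(7.0, 1.0),
        rr_interval=smooth(0.9, 0.05),
        petco2=smooth(40.0, 1.5),
        saturation=np.clip(smooth(97.5, 0.4), 90.0, 100.0),
    )
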