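"""Hemodynamic forward model and amplitude of low-frequency oscillations.

Simulated neural states are convolved with a canonical double-gamma
hemodynamic response function (HRF), sampled at the scanner repeat time and
corrupted with Gaussian measurement noise; the amplitude of low-frequency
oscillations (AlFO) of each regional signal — the mean square-root power
spectral density over 0.01–0.08 Hz after linear detrending — is normalized by
the mean across regions, mirroring the resting-state fMRI contrast between
the ventrolateral medulla (preBötC) and ventrolateral pons (pFRG) channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from . import cpg

__all__ = [
    "HRFParams",
    "NeuralStateSeries",
    "BoldSeries",
    "AlfoResult",
    "CovariateSet",
    "double_gamma_hrf",
    "convolve_neural",
    "compute_alfo",
    "normalize_alfo",
    "regress_out",
    "simulate_fmri_experiment",
]

ALFO_BAND = (0.01, 0.08)  # Hz


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (seconds)."""

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    onset: float = 0.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        if self.response_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.kernel_length <= self.response_delay:
            raise ValueError("kernel length must exceed the response delay")


@dataclass
class NeuralStateSeries:
    """Neural state s(t) on a uniform grid of ``dt`` seconds per map step."""

    s: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("neural states must be finite")


@dataclass
class BoldSeries:
    """BOLD-like signal sampled at repeat time TR."""

    m: np.ndarray
    TR: float = 2.0
    sigma: float = 0.25
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class AlfoResult:
    """Raw and reference-normalized AlFO per region."""

    raw: dict[str, float]
    normalized: dict[str, float]
    band: tuple[float, float] = ALFO_BAND
    dt: Optional[float] = None
    per_run: Optional[dict[str, list[float]]] = None


@dataclass
class CovariateSet:
    """Physiological covariates aligned with a BOLD series (any subset)."""

    rvt: Optional[np.ndarray] = None          # respiratory volume per time
    rr_interval: Optional[np.ndarray] = None  # cardiac RR interval
    petco2: Optional[np.ndarray] = None       # end-tidal CO2
    saturation: Optional[np.ndarray] = None   # oxygen saturation

    def matrix(self) -> np.ndarray:
        cols = [
            np.asarray(c, dtype=float)
            for c in (self.rvt, self.rr_interval, self.petco2, self.saturation)
            if c is not None
        ]
        if not cols:
            raise ValueError("covariate set is empty")
        lengths = {c.size for c in cols}
        if len(lengths) != 1:
            raise ValueError("covariates have mismatched lengths")
        return np.column_stack(cols)


def double_gamma_hrf(params: HRFParams = HRFParams(), dt: float = 0.1) -> np.ndarray:
    """Sample the double-gamma HRF kernel on a grid of ``dt`` seconds.

    The kernel is the difference of two gamma densities — a positive response
    lobe (shape = delay/dispersion, scale = dispersion) and an undershoot
    lobe scaled down by ``ratio`` — over ``[0, kernel_length]``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.kernel_length + dt / 2, dt) - params.onset
    a1 = params.response_delay / params.response_dispersion
    a2 = params.undershoot_delay / params.undershoot_dispersion
    main = stats.gamma.pdf(t, a1, scale=params.response_dispersion)
    under = stats.gamma.pdf(t, a2, scale=params.undershoot_dispersion)
    return main - under / params.ratio


def convolve_neural(
    series: NeuralStateSeries,
    params: HRFParams = HRFParams(),
    sigma: float = 0.25,
    seed: Optional[int] = None,
    TR: float = 2.0,
) -> BoldSeries:
    """Convolve neural states with the HRF, resample at TR, add noise.

    Linear convolution scaled by dt (a Riemann sum of the convolution
    integral), truncated to the support of the input, sampled every TR
    seconds, plus seeded Gaussian white measurement noise of SD ``sigma``.
    """
    kernel = double_gamma_hrf(params, series.dt)
    if series.s.size <= kernel.size:
        raise ValueError(
            f"neural series ({series.s.size * series.dt:.1f} s) shorter than "
            f"the {params.kernel_length:.0f} s kernel"
        )
    conv = np.convolve(series.s, kernel)[: series.s.size] * series.dt
    stride_idx = np.round(
        np.arange(0, series.s.size * series.dt, TR) / series.dt
    ).astype(int)
    stride_idx = stride_idx[stride_idx < conv.size]
    sampled = conv[stride_idx]
    if sigma > 0:
        rng = np.random.default_rng(seed)
        sampled = sampled + rng.normal(0.0, sigma, sampled.size)
    return BoldSeries(sampled, TR=TR, sigma=sigma, seed=seed)


def compute_alfo(series: BoldSeries, band: tuple[float, float] = ALFO_BAND) -> float:
    """Amplitude of low-frequency oscillations of one BOLD series.

    Linear detrend, plain (untapered) periodogram, then the mean square root
    of the power spectral density across the band.  The series must span at
    least two periods of the lower band edge.
    """
    lo, hi = band
    n = series.m.size
    duration = n * series.TR
    if duration < 2.0 / lo:
        raise ValueError(
            f"series of {duration:.0f} s too short for the {lo}-{hi} Hz band"
        )
    detrended = signal.detrend(series.m, type="linear")
    freqs, psd = signal.periodogram(detrended, fs=1.0 / series.TR, window="boxcar")
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError("no spectral estimate falls inside the band")
    return float(np.mean(np.sqrt(psd[mask])))


def normalize_alfo(
    raw: dict[str, float], reference: Optional[float] = None
) -> AlfoResult:
    """Divide each region's raw AlFO by a global reference.

    Default reference is the mean across the supplied regions (simulation
    convention); pass an external global mean for real recordings.
    """
    if not raw:
        raise ValueError("need at least one region")
    ref = float(np.mean(list(raw.values()))) if reference is None else float(reference)
    if ref <= 0:
        raise ValueError("normalization reference must be positive")
    normalized = {k: v / ref for k, v in raw.items()}
    return AlfoResult(raw=dict(raw), normalized=normalized)


def regress_out(series, covariates: CovariateSet | np.ndarray):
    """Residualize a series on covariates by OLS (intercept included)."""
    y = np.asarray(series, dtype=float)
    X = covariates.matrix() if isinstance(covariates, CovariateSet) else np.asarray(
        covariates, dtype=float
    )
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise ValueError("covariate length does not match the series")
    design = np.column_stack([np.ones(y.size), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


# --------------------------------------------------------------------------
# End-to-end simulated fMRI experiment
# --------------------------------------------------------------------------

REGION_OF = {"prebot": "medulla", "pfrg": "pons"}  # anatomical channel names


def _spike_train(trace: cpg.SimulationTrace, unit: str, stop: int) -> np.ndarray:
    s = np.zeros(stop - trace.n_transient)
    idx = trace.spikes[unit]
    idx = idx[idx < stop] - trace.n_transient
    s[idx] = 1.0
    return s


def simulate_fmri_experiment(
    scheme: str = "regime_B",
    runs: int = 5,
    n_action_potentials: int = 250,
    seed: int = 0,
    hrf: HRFParams = HRFParams(),
    sigma: float = 0.25,
    TR: float = 2.0,
    target_period_s: float = 4.0,
) -> AlfoResult:
    """Simulate the resting-state fMRI contrast for one network scheme.

    For each run the network preset is simulated until every spiking
    pacemaker has emitted ``n_action_potentials`` action potentials; map
    steps are mapped to seconds by calibrating the mean burst period of the
    driving unit to ``target_period_s`` (a physiological breath), the spike
    trains are convolved with the HRF, sampled at TR with Gaussian noise, and
    the AlFO of the medulla (preBötC) and pons (pFRG) channels is normalized
    by their mean.  Silent units (e.g. the pFRG in the no-handshake scheme)
    contribute a flat state series rather than an error.  Returned
    per-region values are means over runs.
    """
    master = np.random.SeedSequence(seed)
    run_seeds = master.spawn(runs)
    per_run: dict[str, list[float]] = {"medulla": [], "pons": []}
    per_run_raw: dict[str, list[float]] = {"medulla": [], "pons": []}
    dt_used = None
    for run_idx, ss in enumerate(run_seeds):
        child = np.random.default_rng(ss)
        sim_seed = int(child.integers(0, 2**31 - 1))
        noise_seed = int(child.integers(0, 2**31 - 1))
        trace, stop = _simulate_until(scheme, n_action_potentials, sim_seed)

        # Map-step duration: mean inter-burst-onset interval of the driving
        # (most bursting) unit calibrated to one breath.
        burst_counts = {u: len(trace.bursts[u]) for u in ("pfrg", "prebot")}
        driver = max(burst_counts, key=lambda u: burst_counts[u])
        onsets = np.array([b[0] for b in trace.bursts[driver]])
        if onsets.size < 2:
            raise RuntimeError(f"scheme {scheme}: driver emitted too few bursts")
        dt = target_period_s / float(np.mean(np.diff(onsets)))
        dt_used = dt
        # The analysis window must span >= 2 periods of the lower band edge;
        # extend past the n-th action potential when the calibrated clock
        # makes the spike-count window shorter than that.
        min_steps = int(np.ceil(2.0 / ALFO_BAND[0] / dt))
        stop = min(trace.x["pfrg"].size, max(stop, trace.n_transient + min_steps))

        trains = {
            u: NeuralStateSeries(_spike_train(trace, u, stop), dt)
            for u in ("pfrg", "prebot")
        }
        kernel = double_gamma_hrf(hrf, dt)
        convs = {
            u: np.convolve(t.s, kernel)[: t.s.size] * dt for u, t in trains.items()
        }
        # Common scaling so the mean channel SD matches the measurement-noise
        # SD (the paper's noise SD equals the SD of the measured BOLD mean
        # series); a common factor leaves the normalized AlFO unchanged.
        mean_sd = float(np.mean([np.std(c) for c in convs.values()]))
        scale = sigma / mean_sd if sigma > 0 and mean_sd > 0 else 1.0
        raw: dict[str, float] = {}
        rng = np.random.default_rng(noise_seed)
        for u in ("pfrg", "prebot"):
            n_samp = trains[u].s.size
            idx = np.round(np.arange(0, n_samp * dt, TR) / dt).astype(int)
            idx = idx[idx < n_samp]
            sampled = convs[u][idx] * scale
            if sigma > 0:
                sampled = sampled + rng.normal(0.0, sigma, sampled.size)
            raw[REGION_OF[u]] = compute_alfo(BoldSeries(sampled, TR=TR, sigma=sigma))
        norm = normalize_alfo(raw)
        for region in raw:
            per_run[region].append(norm.normalized[region])
            per_run_raw[region].append(raw[region])
    return AlfoResult(
        raw={k: float(np.mean(v)) for k, v in per_run_raw.items()},
        normalized={k: float(np.mean(v)) for k, v in per_run.items()},
        dt=dt_used,
        per_run=per_run,
    )


def _simulate_until(
    scheme: str, n_ap: int, seed: int, max_steps: int = 600_000
) -> tuple[cpg.SimulationTrace, int]:
    """Simulate a preset until every spiking unit has ``n_ap`` spikes.

    Returns the trace and the step index at which the slowest spiking unit
    reached its ``n_ap``-th post-transient spike (the analysis window end).
    """
    n_steps = 60_000
    while True:
        cfg = cpg.load_preset(scheme, n_steps=n_steps, seed=seed)
        trace = cpg.simulate(cfg, classify=False)
        counts = {u: trace.spikes[u].size for u in ("pfrg", "prebot")}
        spiking = [u for u, c in counts.items() if c > 0]
        if not spiking:
            raise RuntimeError(f"scheme {scheme}: no unit spiked")
        if all(counts[u] >= n_ap for u in spiking):
            stop = max(int(trace.spikes[u][n_ap - 1]) for u in spiking) + 1
            return trace, stop
        if n_steps >= max_steps:
            warnings.warn(
                f"scheme {scheme}: step budget reached with "
                f"{min(counts[u] for u in spiking)} spikes; using full trace"
            )
            return trace, n_steps
        n_steps = min(max_steps, n_steps * 2)
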