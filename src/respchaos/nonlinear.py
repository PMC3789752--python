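"""Nonlinear time-series pipeline for breath-by-breath airflow complexity.

The pipeline follows the classical chaos-detection workflow for short
physiological series:

1. **Noise titration** — fit competing linear and nonlinear polynomial
   autoregressive (Volterra–Wiener) models; if the nonlinear model fits
   significantly better (F-test), add white noise of increasing power until
   nonlinearity is no longer detected.  The noise limit NL (percent of signal
   power) is a relative measure of chaos intensity; NL > 0 indicates chaos.
2. **Largest Lyapunov exponent** — Rosenstein's nearest-neighbor divergence
   method, suited to short series.
3. **Correlation dimension** — Grassberger–Procaccia scaling of the
   correlation integral in a delay embedding.
4. **Surrogate testing** — phase-randomized surrogates preserve the power
   spectrum while destroying nonlinear structure; a Wilcoxon signed-rank test
   compares correlation dimensions of originals against surrogate averages.

Embedding parameters come from the autocorrelation drop (lag) and the false
nearest-neighbor fraction (dimension).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "TitrationConfig",
    "TitrationResult",
    "titration_config_for",
    "EmbeddingSpec",
    "LLEResult",
    "CDResult",
    "VolterraFit",
    "fit_volterra",
    "detect_nonlinearity",
    "titrate",
    "estimate_lag",
    "fnn_dimension",
    "lle_rosenstein",
    "correlation_integral",
    "correlation_dimension",
    "make_surrogates",
    "surrogate_test",
    "embed",
]


# --------------------------------------------------------------------------
# Volterra–Wiener noise titration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationConfig:
    """Settings of the noise-titration procedure.

    kappa      : maximal autoregressive memory (lags 1..kappa)
    degree     : maximal polynomial degree of the candidate terms
    alpha      : F-test significance level for nonlinearity (default 1%)
    noise_step : added-noise increment, percent of signal power
    max_noise  : titration ceiling, percent of signal power
    repeats    : number of titrations averaged into NL
    seed       : master seed; per-repeat seeds are split deterministically
    """

    kappa: int = 6
    degree: int = 3
    alpha: float = 0.01
    noise_step: float = 1.0
    max_noise: float = 300.0
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 1 or self.degree < 2:
            raise ValueError("require kappa >= 1 and degree >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def titration_config_for(n: int, **overrides) -> TitrationConfig:
    """A TitrationConfig whose model family fits a series of length ``n``.

    The candidate-term count (binomial(kappa+degree, degree)) is capped at a
    third of the usable observations so short breath series remain fittable;
    the default kappa=6/degree=3 family applies from n ≈ 260 up.
    """
    for kappa, degree in ((6, 3), (5, 3), (4, 3), (4, 2), (3, 2), (2, 2)):
        terms = math.comb(kappa + degree, degree)
        if (n - kappa) >= 3 * terms:
            return TitrationConfig(kappa=kappa, degree=degree, **overrides)
    return TitrationConfig(kappa=2, degree=2, **overrides)


@dataclass
class TitrationResult:
    """Noise limit of a series: NL > 0 indicates detected chaos."""

    NL: float
    nonlinear_detected: bool
    per_repeat: list[float]
    config: TitrationConfig


@dataclass
class VolterraFit:
    """Best linear and best nonlinear polynomial AR models of one series."""

    n_obs: int
    linear_terms: int          # model size (columns) of the best linear model
    nonlinear_terms: int       # model size of the best overall model
    sse_linear: float
    sse_nonlinear: float
    residuals_linear: np.ndarray
    residuals_nonlinear: np.ndarray


def _monomial_exponents(kappa: int, degree: int) -> list[tuple[int, ...]]:
    """Exponent tuples over lags 1..kappa, ordered by total degree then lex.

    The constant term (all zeros) comes first, then the kappa linear terms,
    then the quadratic products, and so on — the canonical search order of the
    fast orthogonal scheme.
    """
    terms: list[tuple[int, ...]] = []
    for total in range(degree + 1):
        def rec(prefix: tuple[int, ...], remaining: int, slots: int):
            if slots == 0:
                if remaining == 0:
                    terms.append(prefix)
                return
            for e in range(remaining, -1, -1):
                rec(prefix + (e,), remaining - e, slots - 1)
        rec((), total, kappa)
    return terms


def _design_matrix(series: np.ndarray, kappa: int, degree: int):
    n = series.size
    rows = n - kappa
    lags = np.column_stack([series[kappa - j: n - j] for j in range(1, kappa + 1)])
    exps = _monomial_exponents(kappa, degree)
    cols = np.empty((rows, len(exps)))
    for c, e in enumerate(exps):
        col = np.ones(rows)
        for j, p in enumerate(e):
            if p:
                col = col * lags[:, j] ** p
        cols[:, c] = col
    target = series[kappa:]
    n_linear = 1 + kappa  # constant + first-degree terms
    return cols, target, n_linear


def _nested_sse(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SSE of each nested prefix model via Gram–Schmidt orthogonalization.

    Returns (sse[r] for models using the first r columns, r = 1..M, and a
    boolean mask of columns kept).  Near-collinear columns are dropped with a
    warning, leaving the nesting order intact.
    """
    n, m = X.shape
    Q = np.empty((n, m))
    kept = np.ones(m, dtype=bool)
    sse = np.empty(m)
    resid = y.astype(float).copy()
    total = float(resid @ resid)
    n_kept = 0
    for j in range(m):
        v = X[:, j].copy()
        for i in range(n_kept):
            v -= (Q[:, i] @ v) * Q[:, i]
        norm = np.linalg.norm(v)
        if norm <= 1e-10 * max(1.0, np.linalg.norm(X[:, j])):
            kept[j] = False
            sse[j] = sse[j - 1] if j else total
            continue
        q = v / norm
        Q[:, n_kept] = q
        n_kept += 1
        total -= float(q @ y) ** 2
        sse[j] = max(total, 0.0)
    if not kept.all():
        warnings.warn("rank-deficient Volterra design: dropped collinear terms")
    return sse, kept


def fit_volterra(series, kappa: int = 6, degree: int = 3) -> VolterraFit:
    """Fit the best linear and best nonlinear polynomial AR models.

    Candidate monomials of lagged values up to memory ``kappa`` and total
    degree ``degree`` are orthogonalized in a fixed canonical order; nested
    prefix models are scored by the information criterion
    ``C(r) = ln eps(r) + r/N`` (normalized one-step error against model
    size).  The best linear model is the winner within the degree-1 family,
    the best nonlinear model the winner over the full family.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    X, target, n_linear = _design_matrix(y, kappa, degree)
    n, m = X.shape
    if n <= m:
        raise ValueError(
            f"series too short: {n} usable points for {m} candidate terms"
        )
    sse, kept = _nested_sse(X, target)
    ref = float(np.sum((target - target.mean()) ** 2))
    if ref <= 0:
        raise ValueError("series is constant")
    sizes = np.cumsum(kept)  # effective parameter count of each prefix
    # BIC-flavored complexity penalty: the plain r/N penalty admits enough
    # spurious nonlinear terms on short linear-stochastic series to inflate
    # the F-test's size; ln(N)/2N per term restores the nominal level.
    with np.errstate(divide="ignore"):
        crit = 0.5 * np.log(np.maximum(sse, 1e-300) / ref) + (
            math.log(n) / 2.0
        ) * sizes / n
    r_lin = int(np.argmin(crit[:n_linear]))
    r_nl = int(np.argmin(crit))
    if crit[r_nl] >= crit[r_lin]:
        r_nl = r_lin  # nonlinear family does not even win the criterion

    def prefix_residuals(r: int) -> np.ndarray:
        cols = np.where(kept[: r + 1])[0]
        beta, *_ = np.linalg.lstsq(X[:, cols], target, rcond=None)
        return target - X[:, cols] @ beta

    return VolterraFit(
        n_obs=n,
        linear_terms=int(sizes[r_lin]),
        nonlinear_terms=int(sizes[r_nl]),
        sse_linear=float(sse[r_lin]),
        sse_nonlinear=float(sse[r_nl]),
        residuals_linear=prefix_residuals(r_lin),
        residuals_nonlinear=prefix_residuals(r_nl),
    )


def detect_nonlinearity(series, config: TitrationConfig = TitrationConfig()) -> bool:
    """True iff the best nonlinear model beats the best linear one (F-test).

    The linear null (a stochastic series with linear dynamics) is rejected at
    ``config.alpha`` when the variance-ratio F-test on the one-step residuals
    of the two best models is significant.  Degenerate (constant) series are
    reported as linear with a warning.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 3 or np.ptp(y) == 0:
        warnings.warn("degenerate series; nonlinearity not detectable")
        return False
    try:
        fit = fit_volterra(y, config.kappa, config.degree)
    except ValueError as err:
        if "constant" in str(err):
            warnings.warn("degenerate series; nonlinearity not detectable")
            return False
        raise
    extra = fit.nonlinear_terms - fit.linear_terms
    if extra <= 0 or fit.sse_nonlinear >= fit.sse_linear:
        return False
    df2 = fit.n_obs - fit.nonlinear_terms
    if df2 <= 0:
        return False
    if fit.sse_nonlinear <= 1e-12 * fit.sse_linear:
        # numerically perfect nonlinear fit (e.g. a polynomial map)
        return True
    f_stat = ((fit.sse_linear - fit.sse_nonlinear) / extra) / (
        fit.sse_nonlinear / df2
    )
    p = stats.f.sf(f_stat, extra, df2)
    return bool(p < config.alpha)


def titrate(series, config: TitrationConfig = TitrationConfig()) -> TitrationResult:
    """Noise-titrate a series: NL = percent of signal power neutralizing it.

    Per repeat, Gaussian white noise whose variance increases in
    ``noise_step`` percent increments of the signal power (series variance)
    is added until nonlinearity is no longer detected; the repeat's NL is the
    last still-detected level.  Repeats that fail at zero added noise count
    as NL = 0.  The reported NL averages all repeats.
    """
    y = np.asarray(series, dtype=float)
    power = float(np.var(y))
    if not detect_nonlinearity(y, config):
        return TitrationResult(0.0, False, [0.0] * config.repeats, config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.repeats)
    per_repeat: list[float] = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        nl = 0.0
        level = config.noise_step
        while level <= config.max_noise:
            noisy = y + rng.normal(0.0, math.sqrt(level / 100.0 * power), y.size)
            if not detect_nonlinearity(noisy, config):
                break
            nl = level
            level += config.noise_step
        per_repeat.append(nl)
    nl_mean = float(np.mean(per_repeat))
    return TitrationResult(nl_mean, nl_mean > 0, per_repeat, config)


# --------------------------------------------------------------------------
# Delay embedding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: lag, dimension, Theiler exclusion window."""

    tau_embed: int = 1
    m: int = 2
    theiler: Optional[int] = None  # defaults to tau_embed

    def __post_init__(self) -> None:
        if self.tau_embed < 1 or self.m < 1:
            raise ValueError("tau_embed and m must be >= 1")
        if self.theiler is not None and self.theiler < 0:
            raise ValueError("theiler must be >= 0")

    @property
    def theiler_window(self) -> int:
        return self.tau_embed if self.theiler is None else self.theiler


def embed(series, tau: int, m: int) -> np.ndarray:
    """Delay-embed a series into m-dimensional vectors with lag tau."""
    y = np.asarray(series, dtype=float)
    n_vec = y.size - (m - 1) * tau
    if n_vec < 2:
        raise ValueError("series too short for this embedding")
    return np.column_stack([y[j * tau: j * tau + n_vec] for j in range(m)])


def estimate_lag(series, threshold: float = 1.0 / math.e) -> int:
    """Smallest lag at which the autocorrelation drops below ``threshold``."""
    y = np.asarray(series, dtype=float)
    if y.size < 10:
        raise ValueError("series too short to estimate a lag")
    y = y - y.mean()
    var = float(y @ y)
    if var <= 0:
        raise ValueError("series has zero variance")
    n = y.size
    acf = np.correlate(y, y, mode="full")[n - 1:] / var
    max_lag = n // 2
    below = np.where(acf[1: max_lag + 1] < threshold)[0]
    if below.size == 0:
        raise ValueError(
            "autocorrelation never drops below the threshold within half the "
            "series; supply the embedding lag manually"
        )
    return int(below[0] + 1)


def fnn_dimension(
    series,
    tau_embed: int,
    m_max: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.05,
) -> int:
    """Embedding dimension by the false-nearest-neighbor criterion.

    Returns the smallest m whose fraction of false neighbors falls below
    ``threshold``; a neighbor is false when unfolding into dimension m+1
    stretches it by more than ``rtol`` relative to its distance, or beyond
    ``atol`` attractor radii (loneliness criterion).  Returns ``m_max`` with
    a warning when no dimension eliminates the false neighbors (e.g. noise).
    """
    y = np.asarray(series, dtype=float)
    r_attr = float(np.std(y))
    if r_attr == 0:
        raise ValueError("series has zero variance")
    # Neighbors closer than float noise (exact recurrences of periodic
    # signals) carry no unfolding information and are skipped.
    tol = 1e-8 * r_attr
    for m in range(1, m_max):
        vecs = embed(y, tau_embed, m + 1)  # extra coordinate for the check
        n_vec = vecs.shape[0]
        base = vecs[:, :m]
        tree = cKDTree(base)
        k_query = min(25, n_vec)
        dist, idx = tree.query(base, k=k_query)
        d = np.full(n_vec, -1.0)
        j = np.zeros(n_vec, dtype=int)
        for col in range(1, k_query):
            take = (d < 0) & (dist[:, col] > tol)
            d[take] = dist[take, col]
            j[take] = idx[take, col]
        valid = d > 0
        if not valid.any():
            continue
        stretch = np.abs(vecs[valid, m] - vecs[j[valid], m])
        unfolded = np.sqrt(d[valid] ** 2 + stretch**2)
        false = (stretch / d[valid] > rtol) | (unfolded / r_attr > atol)
        if false.mean() < threshold:
            return m
    warnings.warn("false-neighbor fraction never fell below threshold")
    return m_max


# --------------------------------------------------------------------------
# Largest Lyapunov exponent (Rosenstein)
# --------------------------------------------------------------------------

@dataclass
class LLEResult:
    """Largest Lyapunov exponent with its mean log-divergence curve."""

    lambda_L: float
    steps: np.ndarray          # divergence horizon k (steps)
    divergence: np.ndarray     # mean ln d(k)
    fit_range: tuple[int, int]  # [start, end) slice of the fitted region
    spec: EmbeddingSpec


def lle_rosenstein(
    series,
    spec: EmbeddingSpec,
    k_max: int = 20,
    fit_range: Optional[tuple[int, int]] = None,
) -> LLEResult:
    """Largest Lyapunov exponent by nearest-neighbor divergence.

    For every delay vector the nearest neighbor outside the Theiler window is
    tracked forward; the mean of ln distance at each horizon forms the
    divergence curve, whose initial linear-region slope is the exponent (per
    step of the series).  The fitted region is selected automatically as the
    rise up to 80% of the curve's total span (flat curves — periodic signals
    — are fitted over the whole curve, giving a slope near zero); it can be
    overridden with ``fit_range``.
    """
    vecs = embed(series, spec.tau_embed, spec.m)
    n = vecs.shape[0]
    w = spec.theiler_window
    if n <= 2 * (w + 1):
        raise ValueError("not enough delay vectors for the Theiler exclusion")
    tree = cKDTree(vecs)
    k_query = min(n, 2 * w + 4)
    dist, idx = tree.query(vecs, k=k_query)
    neighbor = np.full(n, -1)
    for col in range(1, k_query):
        cand = idx[:, col]
        ok = (neighbor < 0) & (np.abs(cand - np.arange(n)) > w)
        neighbor[ok] = cand[ok]
    pairs = np.where(neighbor >= 0)[0]
    if pairs.size == 0:
        raise ValueError("no admissible nearest neighbors found")
    # Distance floor keeps exactly recurring orbits (periodic signals) finite
    # in log space; such pairs contribute zero divergence, as they should.
    floor = 1e-12 * max(float(np.std(series)), 1e-30)
    steps = np.arange(k_max + 1)
    curve = np.full(k_max + 1, np.nan)
    for k in steps:
        i = pairs[(pairs + k < n) & (neighbor[pairs] + k < n)]
        if i.size == 0:
            break
        d = np.linalg.norm(vecs[i + k] - vecs[neighbor[i] + k], axis=1)
        curve[k] = float(np.mean(np.log(np.maximum(d, floor))))
    valid = ~np.isnan(curve)
    steps, curve = steps[valid], curve[valid]

    if fit_range is None:
        span = curve.max() - curve[0]
        if span > 0.1:
            cutoff = curve[0] + 0.8 * span
            end = int(np.argmax(curve >= cutoff)) + 1
            end = max(end, 2)
        else:
            end = curve.size
        fit_range = (0, end)
    lo, hi = fit_range
    hi = min(hi, curve.size)
    slope = float(np.polyfit(steps[lo:hi], curve[lo:hi], 1)[0])
    return LLEResult(slope, steps, curve, (lo, hi), spec)


# --------------------------------------------------------------------------
# Correlation dimension (Grassberger–Procaccia)
# --------------------------------------------------------------------------

@dataclass
class CDResult:
    """Correlation dimension with the underlying correlation integrals."""

    D_corr: float
    radii: np.ndarray
    C: np.ndarray
    fit_range: tuple[int, int]
    spec: EmbeddingSpec


def correlation_integral(series, spec: EmbeddingSpec, radii) -> np.ndarray:
    """Correlation integrals C(r, m) of a delay-embedded series.

    C(r) is the fraction of admissible point pairs (time separation larger
    than the Theiler window) whose Chebyshev distance is <= r, normalized by
    the exact admissible pair count.
    """
    r = np.asarray(radii, dtype=float)
    if r.size == 0 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    vecs = embed(series, spec.tau_embed, spec.m)
    n = vecs.shape[0]
    w = spec.theiler_window
    counts = np.zeros(r.size, dtype=np.int64)
    n_pairs = 0
    block = max(1, int(2e6 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        # pairs (i, j) with j > i + w only, counted once
        diff = vecs[start:stop, None, :] - vecs[None, :, :]
        d = np.max(np.abs(diff), axis=2)
        i_idx = np.arange(start, stop)[:, None]
        j_idx = np.arange(n)[None, :]
        mask = j_idx > i_idx + w
        dm = d[mask]
        n_pairs += dm.size
        counts += np.searchsorted(np.sort(dm), r, side="right")
    if n_pairs == 0:
        raise ValueError("no admissible pairs under the Theiler exclusion")
    return counts / n_pairs


def correlation_dimension(
    series,
    spec: EmbeddingSpec,
    radii: Optional[np.ndarray] = None,
    n_radii: int = 24,
    slope_tol: float = 0.15,
    fit_range: Optional[tuple[int, int]] = None,
) -> CDResult:
    """Correlation dimension from the slope of ln C(r) vs ln r.

    The scaling region is selected automatically: the widest contiguous
    window of the ln–ln curve (at least 4 points) whose local slopes vary by
    less than ``slope_tol`` relative to their mean, preferring windows at
    least one decade wide in r.  Raises when no window qualifies.
    """
    y = np.asarray(series, dtype=float)
    if radii is None:
        vecs = embed(y, spec.tau_embed, spec.m)
        n = vecs.shape[0]
        rng = np.random.default_rng(0)
        ii = rng.integers(0, n, size=min(4000, n))
        jj = rng.integers(0, n, size=ii.size)
        keep = np.abs(ii - jj) > spec.theiler_window
        sample = np.max(np.abs(vecs[ii[keep]] - vecs[jj[keep]]), axis=1)
        sample = sample[sample > 0]
        r_lo = float(np.percentile(sample, 0.5))
        r_hi = float(sample.max())
        radii = np.geomspace(max(r_lo, 1e-12), r_hi, n_radii)
    C = correlation_integral(y, spec, radii)
    good = (C > 0) & (C < 1)
    ln_r = np.log(radii[good])
    ln_C = np.log(C[good])
    if fit_range is None:
        fit_range = _scaling_region(ln_r, ln_C, slope_tol)
    lo, hi = fit_range
    slope = float(np.polyfit(ln_r[lo:hi], ln_C[lo:hi], 1)[0])
    return CDResult(slope, radii[good], C[good], (lo, hi), spec)


def _scaling_region(ln_r: np.ndarray, ln_C: np.ndarray, tol: float) -> tuple[int, int]:
    if ln_r.size < 4:
        raise ValueError("too few usable radii for a scaling region")
    slopes = np.diff(ln_C) / np.diff(ln_r)
    decade = math.log(10.0)
    best: Optional[tuple[int, int]] = None
    best_key = (-1.0, -1.0)  # (reaches decade, width)
    n_s = slopes.size
    for i in range(n_s):
        for j in range(i + 3, n_s + 1):  # >= 3 slope segments = 4 points
            seg = slopes[i:j]
            mean = seg.mean()
            if mean <= 0:
                continue
            if np.max(np.abs(seg - mean)) / mean > tol:
                continue
            width = ln_r[j] - ln_r[i]
            key = (1.0 if width >= decade else 0.0, width)
            if key > best_key:
                best_key = key
                best = (i, j + 1)
    if best is None:
        raise ValueError(
            "no scaling region with stable local slopes; supply fit_range"
        )
    return best


# --------------------------------------------------------------------------
# Surrogates and the paired group test
# --------------------------------------------------------------------------

def make_surrogates(series, count: int = 5, seed: int = 0) -> np.ndarray:
    """Phase-randomized surrogates preserving the amplitude spectrum.

    The Fourier phases of all components except DC (and Nyquist, for even
    length) are replaced by uniform random phases with conjugate symmetry, so
    each surrogate is real with the exact power spectrum — and hence mean and
    autocorrelation — of the original, while any nonlinear structure is
    destroyed.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("series too short for surrogate generation")
    spec = np.fft.rfft(y)
    rng = np.random.default_rng(seed)
    out = np.empty((count, n))
    lo, hi = 1, spec.size - 1 if n % 2 == 0 else spec.size
    for s in range(count):
        phases = rng.uniform(0, 2 * math.pi, hi - lo)
        randomized = spec.copy()
        randomized[lo:hi] = np.abs(spec[lo:hi]) * np.exp(1j * phases)
        out[s] = np.fft.irfft(randomized, n=n)
    return out


def surrogate_test(original_cd_values, surrogate_mean_cd_values) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired correlation dimensions.

    Pairs each series' correlation dimension with the average dimension of
    its surrogates; a significant difference supports nonlinear dynamics in
    the originals.  The exact null distribution is enumerated for n <= 25
    without ties; the normal approximation with tie correction is used
    otherwise.  All-zero differences give p = 1 with a warning.
    """
    a = np.asarray(original_cd_values, dtype=float)
    b = np.asarray(surrogate_mean_cd_values, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired sequences of equal length >= 5")
    diff = a - b
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero")
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="auto")
    return float(res.statistic), float(res.pvalue)
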