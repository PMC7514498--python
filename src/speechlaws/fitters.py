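"""Estimation machinery for the linguistic-law analyses.

All estimators are deterministic given identical input arrays; the
nonlinear Menzerath fit uses a fixed internal seed for its jittered
restarts.  Logarithms are natural throughout; base-D conversions for the
optimality exponent live in :mod:`speechlaws.laws`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import DegenerateSampleError, FitError

__all__ = [
    "RescaledSample",
    "LognormalFit",
    "PowerLawFit",
    "YuleFit",
    "ExponentialFit",
    "MenzerathFit",
    "LoglogFit",
    "rescale_log",
    "fit_lognormal",
    "fit_power_law",
    "fit_yule",
    "fit_exponential",
    "fit_menzerath",
    "fit_loglog",
    "bin_log",
    "yule_rank_probs",
    "as_record",
]


def as_record(fit, **extra) -> dict:
    """Flatten a fit dataclass to a plain-JSON dict (law/level/unit tags via extra)."""
    rec = dict(extra)
    for k, v in dataclasses.asdict(fit).items():
        if isinstance(v, np.ndarray):
            continue
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        rec[k] = v
    return rec


# ---------------------------------------------------------------- rescaling


@dataclass
class RescaledSample:
    """Standardized log-durations: mean 0, sample sd 1 (dimensionless)."""

    values: np.ndarray
    source_level: str = ""


def rescale_log(sample, source_level: str = "") -> RescaledSample:
    """Map durations t to ``(log t - <log t>) / sd(log t)`` (sample sd, ddof=1)."""
    t = np.asarray(sample, dtype=float)
    if t.size < 2:
        raise DegenerateSampleError("need at least 2 values to rescale")
    if (t <= 0).any() or not np.isfinite(t).all():
        raise FitError("durations must be positive and finite")
    logs = np.log(t)
    sd = logs.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("zero variance in log-durations")
    return RescaledSample(values=(logs - logs.mean()) / sd, source_level=source_level)


# ---------------------------------------------------------------- lognormal


@dataclass
class LognormalFit:
    """Closed-form lognormal MLE plus the Gaussian-collapse diagnostic."""

    mu: float
    sigma: float
    n: int
    ks_to_gaussian: float


def fit_lognormal(sample) -> LognormalFit:
    """MLE of the lognormal: mu = mean of logs, sigma = sd of logs (ddof=0).

    ``ks_to_gaussian`` is the Kolmogorov-Smirnov distance between the
    rescaled log-sample and N(0,1) — the collapse diagnostic.
    """
    t = np.asarray(sample, dtype=float)
    if t.size < 10:
        raise FitError(f"need at least 10 durations, got {t.size}")
    resc = rescale_log(t)  # validates positivity and non-degeneracy
    logs = np.log(t)
    ks = stats.kstest(resc.values, "norm").statistic
    return LognormalFit(
        mu=float(logs.mean()), sigma=float(logs.std(ddof=0)), n=t.size, ks_to_gaussian=float(ks)
    )


# ---------------------------------------------------------------- power law


@dataclass
class PowerLawFit:
    """Discrete power-law MLE on a rank-frequency table with KS-selected xmin."""

    alpha: float
    xmin: int
    ks: float
    n_tail: int


def _rank_sample(freqs) -> tuple[np.ndarray, np.ndarray]:
    """Sort counts decreasing; return (ranks 1..V, counts per rank)."""
    f = np.asarray(freqs)
    if f.size == 0 or (f <= 0).any() or not np.issubdtype(f.dtype, np.number):
        raise FitError("frequencies must be positive counts")
    f = np.sort(f.astype(float))[::-1]
    return np.arange(1, f.size + 1), f


def _powerlaw_nll(alpha: float, ranks: np.ndarray, counts: np.ndarray) -> float:
    s = (ranks.astype(float) ** -alpha).sum()
    return alpha * float((counts * np.log(ranks)).sum()) + counts.sum() * np.log(s)


def _powerlaw_mle(ranks, counts, bounds=(1.001, 6.0)) -> float:
    res = optimize.minimize_scalar(
        _powerlaw_nll, args=(ranks, counts), bounds=bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise FitError(f"power-law MLE failed: {res.message}")
    return float(res.x)


def fit_power_law(freqs, max_xmin: int = 50) -> PowerLawFit:
    """Zipf fit: discrete power-law MLE on the rank-frequency relation.

    The likelihood treats the rank of each token's type as the random
    variable, with ``p(r) ∝ r^-alpha`` normalized over the finite rank
    support (rank is bounded by the vocabulary size; for heavy tails and
    large vocabularies this matches the zeta normalization).  ``xmin`` is
    selected by minimizing the KS distance over candidate cutoffs, after
    Clauset et al.; ``xmin = 1`` is reported when optimal.
    """
    ranks, f = _rank_sample(freqs)
    if ranks.size < 10:
        raise FitError(f"need at least 10 types, got {ranks.size}")
    if np.unique(f).size < 2:
        raise DegenerateSampleError("all type frequencies equal: no tail to fit")
    best = None
    for xmin in range(1, min(max_xmin, ranks.size - 9) + 1):
        tail = ranks >= xmin
        r_t, f_t = ranks[tail], f[tail]
        alpha = _powerlaw_mle(r_t, f_t)
        p = r_t.astype(float) ** -alpha
        mcdf = np.cumsum(p / p.sum())
        ecdf = np.cumsum(f_t) / f_t.sum()
        ks = float(np.abs(ecdf - mcdf).max())
        if best is None or ks < best[0]:
            best = (ks, xmin, alpha, int(f_t.sum()))
    ks, xmin, alpha, n_tail = best
    return PowerLawFit(alpha=alpha, xmin=xmin, ks=ks, n_tail=n_tail)


# ---------------------------------------------------------------- Yule


@dataclass
class YuleFit:
    """Two-parameter Yule rank-frequency fit, ``p(r) ∝ r^-a · b^r``.

    This geometric-damped power law over ranks r = 1, 2, ... (0 < b < 1)
    is the concrete family used for phoneme rank-frequency data; the
    report prints the formula alongside the parameters.
    """

    a: float
    b: float
    loglik: float
    n: int

    formula: str = "p(r) ∝ r^-a · b^r"


def yule_rank_probs(a: float, b: float, rmax: int) -> np.ndarray:
    """Normalized ``p(r) ∝ r^-a b^r`` over r = 1..rmax (tail mass beyond rmax folded in)."""
    r = np.arange(1, rmax + 1, dtype=float)
    w = r**-a * b**r
    return w / _yule_norm(a, b)


def _yule_norm(a: float, b: float, tol: float = 1e-14) -> float:
    """Sum of r^-a b^r for r >= 1 (converges geometrically for b < 1)."""
    total = 0.0
    r0 = 1
    while r0 < 2_000_000:
        r = np.arange(r0, r0 + 4096, dtype=float)
        terms = r**-a * np.exp(r * np.log(b))
        total += terms.sum()
        if terms[-1] < tol * max(total, 1e-300):
            break
        r0 += 4096
    return total


def fit_yule(freqs) -> YuleFit:
    """Numerical MLE of the Yule rank-frequency family ``p(r) ∝ r^-a b^r``."""
    ranks, f = _rank_sample(freqs)
    if ranks.size < 10:
        raise FitError(f"need at least 10 types, got {ranks.size}")
    if np.unique(f).size < 2:
        raise DegenerateSampleError("all type frequencies equal: degenerate sample")
    n = f.sum()
    slog = float((f * np.log(ranks)).sum())
    srank = float((f * ranks).sum())

    def nll(x):
        a, b = x
        return a * slog - np.log(b) * srank + n * np.log(_yule_norm(a, b))

    res = optimize.minimize(
        nll,
        x0=np.array([0.5, 0.9]),
        method="L-BFGS-B",
        bounds=[(-5.0, 10.0), (1e-6, 1.0 - 1e-9)],
    )
    if not res.success:
        raise FitError(f"Yule MLE did not converge: {res.message} (nit={res.nit})")
    a, b = res.x
    return YuleFit(a=float(a), b=float(b), loglik=float(-res.fun), n=int(n))


# ---------------------------------------------------------------- exponential (brevity)


@dataclass
class ExponentialFit:
    """Least-squares fit of ``f ∼ exp(-lambda · ell)`` on raw per-type data."""

    lambda_rate: float
    prefactor: float
    spearman_rho: float
    spearman_p: float
    n: int


def fit_exponential(sizes, freqs) -> ExponentialFit:
    """Regress log-frequency on size; Spearman rank correlation as a side check.

    Zero/negative frequencies are excluded with a warning; types with
    frequency 1 are retained.
    """
    ell = np.asarray(sizes, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if ell.shape != f.shape:
        raise FitError("sizes and freqs must align")
    if (ell < 0).any():
        raise FitError("sizes must be non-negative")
    usable = f > 0
    if (~usable).any():
        warnings.warn(f"excluding {int((~usable).sum())} non-positive frequencies")
    ell, f = ell[usable], f[usable]
    if ell.size < 3:
        raise FitError(f"need at least 3 usable points, got {ell.size}")
    slope, intercept = np.polyfit(ell, np.log(f), 1)
    rho, p = stats.spearmanr(f, ell)
    return ExponentialFit(
        lambda_rate=float(-slope),
        prefactor=float(np.exp(intercept)),
        spearman_rho=float(rho),
        spearman_p=float(p),
        n=ell.size,
    )


# ---------------------------------------------------------------- Menzerath-Altmann


@dataclass
class MenzerathFit:
    """Nonlinear LS fit of ``y(n) = a n^b exp(-c n)``; extremum at n = b/c."""

    a: float
    b: float
    c: float
    r2: float
    inversion_n: float
    n: int


def _mal(n, a, b, c):
    return a * n**b * np.exp(-c * n)


def fit_menzerath(n_values, y_values, max_restarts: int = 20) -> MenzerathFit:
    """Levenberg-Marquardt fit on raw (n, y) points.

    Starts at (median(y), -0.1, -0.01); on non-convergence, up to
    ``max_restarts`` jittered restarts (fixed internal seed).  R^2 is
    computed against the raw points used in the fit.
    """
    n = np.asarray(n_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if np.unique(n).size < 4:
        raise FitError("need at least 4 distinct construct sizes")
    if (y <= 0).any() or (n <= 0).any():
        raise FitError("construct sizes and constituent sizes must be positive")
    p0 = np.array([float(np.median(y)), -0.1, -0.01])
    rng = np.random.default_rng(0)
    last_err = None
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else p0 * rng.normal(1.0, 0.3, 3) + rng.normal(0, 0.05, 3)
        try:
            popt, _ = optimize.curve_fit(_mal, n, y, p0=start, method="lm", maxfev=20000)
            break
        except RuntimeError as exc:
            last_err = exc
    else:
        raise FitError(
            f"Menzerath fit did not converge from start {p0.tolist()} "
            f"after {max_restarts} restarts: {last_err}"
        )
    a, b, c = (float(v) for v in popt)
    resid = y - _mal(n, a, b, c)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-300:
        r2 = 1.0 if ss_res <= 1e-12 else 0.0  # constant data: exact fit → 1 by convention
    else:
        r2 = 1.0 - ss_res / ss_tot
    inversion = b / c if c != 0 else float("nan")
    return MenzerathFit(a=a, b=b, c=c, r2=r2, inversion_n=inversion, n=n.size)


# ---------------------------------------------------------------- log-log slope


@dataclass
class LoglogFit:
    """OLS of log y on log x (Heaps-type scaling exponents)."""

    slope: float
    intercept: float
    r2: float
    n: int


def fit_loglog(x, y) -> LoglogFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FitError("need at least 3 points")
    if (x <= 0).any() or (y <= 0).any():
        raise FitError("log-log fit requires positive values")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(ly) == 0:  # constant y: slope 0, exact fit
        return LoglogFit(slope=0.0, intercept=float(ly[0]), r2=1.0, n=x.size)
    res = stats.linregress(lx, ly)
    return LoglogFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), n=x.size,
    )


# ---------------------------------------------------------------- binning


def bin_log(x, y, n_bins: int):
    """Logarithmically spaced bins over x; per-bin means of y, empty bins dropped.

    Returns ``(centers, y_means, counts)`` where centers are the geometric
    midpoints of the occupied bins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bins < 2:
        raise FitError("n_bins must be >= 2")
    if (x <= 0).any():
        raise FitError("bin_log requires positive x")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return np.array([lo]), np.array([y.mean()]), np.array([x.size])
    edges = np.geomspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    centers = np.sqrt(edges[:-1] * edges[1:])
    return centers[occupied], sums[occupied] / counts[occupied], counts[occupied]
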