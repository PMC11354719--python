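"""Seasonal abundance models and the multi-device precision experiment.

Within-year mosquito abundance is modelled as an exponential cubic,
mu(t) = exp(b0 + b1 t + b2 t^2) on day-of-year t, with a negative
binomial error family for trap counts and a lognormal family for sensor
densities (log-transformed densities have homoscedastic errors).

The precision experiment asks how well a monitoring network of d devices
resolves a known 5% increase in overall abundance: simulate d baseline
years and d years with the seasonal function scaled by 1.05, sum annual
totals within each arm, and record the proportional difference
(S_1.05 - S_1) / S_1.  Repeating this many times gives a distribution
centred on 0.05 whose spread narrows as 1/sqrt(d); matching spreads
across two device types yields a device-equivalence factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "SeasonalModel",
    "fit_seasonal_nb",
    "fit_seasonal_lognormal",
    "simulate_year",
    "precision_experiment",
    "PowerSimResult",
    "device_equivalence",
    "interdecile_range",
]


@dataclass(frozen=True)
class SeasonalModel:
    """Exponential-cubic seasonal trend with an observation-error family.

    ``family`` is ``negative_binomial`` (counts; ``dispersion`` is the
    NB2 alpha, Var = mu + alpha mu^2) or ``lognormal`` (densities;
    ``dispersion`` is the log-scale residual variance sigma^2).
    """

    beta: tuple[float, float, float]
    family: str = "negative_binomial"
    dispersion: float = 0.1
    season: tuple[int, int] = (121, 304)  # day-of-year bounds (May-Oct)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")
        if self.family not in ("negative_binomial", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def mean(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        b0, b1, b2 = self.beta
        return np.exp(b0 + b1 * t + b2 * t * t)

    def draw(self, mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Sample from the error family with mean ``mu``."""
        mu = np.asarray(mu, dtype=float)
        if self.family == "negative_binomial":
            # gamma-Poisson mixture, Var = mu + alpha mu^2
            shape = 1.0 / self.dispersion
            lam = rng.gamma(shape, self.dispersion * mu)
            return rng.poisson(lam).astype(float)
        sigma = np.sqrt(self.dispersion)
        # median-parameterised lognormal: exp(log mu + N(0, sigma^2))
        return mu * np.exp(rng.normal(0.0, sigma, size=mu.shape))

    def to_json(self) -> str:
        return json.dumps({
            "beta": list(self.beta), "family": self.family,
            "dispersion": self.dispersion, "season": list(self.season),
        })

    @classmethod
    def from_json(cls, text: str) -> "SeasonalModel":
        d = json.loads(text)
        return cls(tuple(d["beta"]), d["family"], d["dispersion"],
                   tuple(d.get("season", (121, 304))))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _design(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.column_stack([np.ones_like(t), t, t * t])


def fit_seasonal_nb(
    counts: np.ndarray,
    t: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> SeasonalModel:
    """Negative binomial regression of daily counts on (t, t^2), log link.

    Alternates a GLM fit (iteratively reweighted least squares) at fixed
    dispersion with a method-of-moments update of the NB2 alpha from the
    Pearson residuals, until both stabilise.  Zero counts are retained
    (the NB supports zero).  Non-convergence raises rather than returning
    a silent partial fit.
    """
    counts = np.asarray(counts, dtype=float)
    t = np.asarray(t, dtype=float)
    if counts.size < 10:
        raise ValueError("need at least 10 observations")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    x = _design(t)
    alpha = 0.1
    beta = None
    for _ in range(max_iter):
        model = sm.GLM(counts, x, family=sm.families.NegativeBinomial(alpha=alpha))
        res = model.fit()
        mu = res.mu
        # method-of-moments: E[(y-mu)^2] = mu + alpha mu^2
        num = np.sum((counts - mu) ** 2 - mu)
        den = np.sum(mu**2)
        new_alpha = max(num / den, 1e-8)
        new_beta = np.asarray(res.params)
        if beta is not None and (
            abs(new_alpha - alpha) < tol * max(alpha, 1.0)
            and np.allclose(new_beta, beta, rtol=0, atol=tol)
        ):
            alpha, beta = new_alpha, new_beta
            break
        alpha, beta = new_alpha, new_beta
    else:
        raise RuntimeError("negative binomial fit did not converge")
    return SeasonalModel(tuple(beta), "negative_binomial", float(alpha))


def fit_seasonal_lognormal(
    densities: np.ndarray,
    t: np.ndarray,
    drop_zeros: bool = True,
) -> SeasonalModel:
    """OLS of log density on (t, t^2); residual variance becomes sigma^2.

    Zero densities carry no information on the log scale; by default
    they are dropped (set ``drop_zeros=False`` to add half the smallest
    positive density before the log instead).
    """
    densities = np.asarray(densities, dtype=float)
    t = np.asarray(t, dtype=float)
    pos = densities > 0
    if not pos.any():
        raise ValueError("all densities are zero")
    if drop_zeros:
        densities, t = densities[pos], t[pos]
    else:
        eps = densities[pos].min() / 2.0
        densities = densities + eps
    res = sm.OLS(np.log(densities), _design(t)).fit()
    sigma2 = float(np.var(res.resid, ddof=3)) if densities.size > 3 else 1e-8
    return SeasonalModel(tuple(res.params), "lognormal", max(sigma2, 1e-10))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_year(
    model: SeasonalModel,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    days: int | None = None,
) -> np.ndarray:
    """One simulated season of daily values located at scale * mu(t).

    For the negative binomial family the daily mean is scale * mu(t);
    for the lognormal family scale * mu(t) is the daily median (the
    mean carries the usual exp(sigma^2/2) factor, which cancels in the
    proportional-difference experiment).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = model.season
    if days is None:
        t = np.arange(lo, hi + 1, dtype=float)
    else:
        t = np.arange(1, days + 1, dtype=float)
    return model.draw(scale * model.mean(t), rng)


@dataclass
class PowerSimResult:
    """Distributions of proportional annual differences by device count."""

    device_counts: tuple[int, ...]
    differences: dict[int, np.ndarray] = field(default_factory=dict)
    true_effect: float = 0.05

    def center(self, d: int) -> float:
        return float(np.mean(self.differences[d]))

    def spread(self, d: int) -> float:
        return interdecile_range(self.differences[d])

    def spreads(self) -> dict[int, float]:
        return {d: self.spread(d) for d in self.device_counts}


def interdecile_range(x: np.ndarray) -> float:
    """90th minus 10th percentile — robust to the NB right skew."""
    q10, q90 = np.percentile(x, [10.0, 90.0])
    return float(q90 - q10)


def precision_experiment(
    model: SeasonalModel,
    device_counts: tuple[int, ...] = (1, 2, 4, 8, 16),
    n_comparisons: int = 10_000,
    effect: float = 1.05,
    seed: int = 0,
) -> PowerSimResult:
    """Proportional-difference distributions for each network size.

    For each device count d and each comparison: simulate d baseline
    seasons and d seasons from the ``effect``-scaled model, sum the
    annual totals within each arm, and record
    (S_scaled - S_baseline) / S_baseline.  The baseline-arm denominator
    makes the noise-free limit exactly ``effect - 1``.
    """
    if min(device_counts) < 1:
        raise ValueError("device counts must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = model.season
    t = np.arange(lo, hi + 1, dtype=float)
    mu = model.mean(t)
    result = PowerSimResult(tuple(device_counts), true_effect=effect - 1.0)
    for d in device_counts:
        diffs = np.empty(n_comparisons)
        for i in range(n_comparisons):
            base = sum(float(model.draw(mu, rng).sum()) for _ in range(d))
            scaled = sum(float(model.draw(effect * mu, rng).sum()) for _ in range(d))
            diffs[i] = (scaled - base) / base
        result.differences[d] = diffs
    return result


def device_equivalence(
    result_a: PowerSimResult, result_b: PowerSimResult
) -> float:
    """Number of B-devices matching the precision of one A-device.

    Interpolates log(spread) versus log(device count) for B and solves
    for the count at which B's spread equals A's single-device spread.
    Outside the simulated range the nearest bound is returned (a
    conservative bound rather than an extrapolation).
    """
    target = result_a.spread(min(result_a.device_counts))
    counts = np.array(sorted(result_b.device_counts), dtype=float)
    spreads = np.array([result_b.spread(int(d)) for d in counts])
    order = np.argsort(spreads)  # spread decreasing in d -> sort ascending
    log_s, log_d = np.log(spreads[order]), np.log(counts[order])
    if target <= spreads.min():
        return float(counts.max())
    if target >= spreads.max():
        return float(counts.min())
    return float(np.exp(np.interp(np.log(target), log_s, log_d)))
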