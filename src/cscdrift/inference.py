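"""Bayesian fitting of the ratio trajectory by adaptive Metropolis-Hastings.

The observable is the time course of the differentiated-to-stem ratio
r = D/S (equivalently the CSC percentage).  The likelihood is, by default,
independent Gaussian error on the observed ratio with a single unknown scale
sigma that is sampled together with the four rates; the sum of squared
deviations (SSD) between observed and model ratios is then the sufficient
data statistic.  A Gaussian-on-log-ratio option is available for data
spanning several orders of magnitude.

Priors are independent uniforms on configurable non-negative boxes.  The
sampler is an adaptive Metropolis algorithm in the Haario family: after an
initial non-adaptive phase the multivariate-normal proposal covariance is
replaced by the scaled empirical covariance of the chain history
(2.38^2/d * cov + jitter), which keeps the run seed-reproducible while
letting the proposal learn the posterior geometry -- in particular the flat
ridge along k1 + c, k2 + c that ratio-only data cannot resolve.  Because of
that ridge the summaries always report the identifiable combination
delta = k2 - k1 alongside the raw rates, and derived quantities (limiting
ratio, asymptotic CSC percentage) are computed per posterior sample, never
from summarized parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    RateParams,
    limiting_ratio_algebraic,
    percent_to_ratio,
    ratio_to_percent,
    ratio_trajectory,
)

__all__ = [
    "TimeCourse",
    "FitConfig",
    "PosteriorChain",
    "sum_squared_deviations",
    "log_posterior",
    "run_adaptive_mh",
    "summarize_chain",
]

# tolerance for declaring stated percent and ratio columns inconsistent;
# generous enough for values printed at 1 (percent) and 4 (ratio) decimals
_PERCENT_RATIO_TOL = 1e-3


@dataclass(frozen=True)
class TimeCourse:
    """Observed CSC time course: times (days) with percent and/or ratio."""

    times: np.ndarray
    ratio: np.ndarray
    percent: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "ratio", np.asarray(self.ratio, float))
        if self.percent is not None:
            object.__setattr__(self, "percent", np.asarray(self.percent, float))
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.ratio.shape != self.times.shape:
            raise ValueError("ratio and times must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be >= 0")
        if np.any(self.ratio < 0):
            raise ValueError("ratios must be >= 0")
        if self.percent is not None:
            if self.percent.shape != self.times.shape:
                raise ValueError("percent and times must have the same length")
            if np.any(self.percent <= 0) or np.any(self.percent > 100):
                raise ValueError("percent must lie in (0, 100]")
            implied = ratio_to_percent(self.ratio)
            if np.any(np.abs(implied - self.percent) > _PERCENT_RATIO_TOL * 100):
                bad = int(np.argmax(np.abs(implied - self.percent)))
                raise ValueError(
                    f"percent and ratio columns disagree at row {bad} "
                    f"(t={self.times[bad]}): {self.percent[bad]} vs "
                    f"implied {implied[bad]:.4f}"
                )

    @property
    def n(self) -> int:
        return self.times.size

    @classmethod
    def from_percent(cls, times, percent) -> "TimeCourse":
        percent = np.asarray(percent, float)
        return cls(times=np.asarray(times, float),
                   ratio=percent_to_ratio(percent), percent=percent)

    @classmethod
    def from_ratio(cls, times, ratio) -> "TimeCourse":
        ratio = np.asarray(ratio, float)
        return cls(times=np.asarray(times, float), ratio=ratio,
                   percent=ratio_to_percent(ratio))

    def to_frame(self) -> pd.DataFrame:
        percent = (self.percent if self.percent is not None
                   else ratio_to_percent(self.ratio))
        return pd.DataFrame({"time_days": self.times,
                             "csc_percent": percent,
                             "ratio": self.ratio})


def _default_bounds() -> dict[str, tuple[float, float]]:
    return {
        "k1": (0.0, 1.0),
        "k2": (0.0, 1.0),
        "a": (0.0, 0.5),
        "b": (0.0, 0.5),
        "sigma": (1e-6, 20.0),
        "r0": (1e-6, 1.0),
    }


@dataclass(frozen=True)
class FitConfig:
    """Sampler configuration.

    ``iterations`` / ``burn_in`` default to the 10,000 / 3,000 schedule of
    the mammosphere analysis.  ``bounds`` are the uniform-prior boxes (all
    non-negative).  ``likelihood`` selects Gaussian error on the ratio
    ("gaussian") or on its logarithm ("lognormal").  ``r0_mode`` fixes the
    initial ratio to the first observation ("fixed", matching a measured
    sorting purity) or samples it ("estimated").
    """

    iterations: int = 10_000
    burn_in: int = 3_000
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=_default_bounds)
    likelihood: str = "gaussian"
    r0_mode: str = "fixed"
    adapt_start_frac: float = 0.1
    adapt_interval: int = 25
    initial_step_frac: float = 0.02
    init: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.likelihood not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.r0_mode not in ("fixed", "estimated"):
            raise ValueError(f"unknown r0_mode {self.r0_mode!r}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 <= lo < hi):
                raise ValueError(f"bad bounds for {name!r}: ({lo}, {hi})")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ("k1", "k2", "a", "b", "sigma")
        return names + ("r0",) if self.r0_mode == "estimated" else names


@dataclass(frozen=True)
class PosteriorChain:
    """Retained MCMC samples with bookkeeping."""

    samples: np.ndarray  # (iterations - burn_in, d)
    param_names: tuple[str, ...]
    acceptance_rate: float
    seed: int
    config: FitConfig
    r0: float  # the fixed value, or the first observation when estimated

    def __post_init__(self) -> None:
        expected = self.config.iterations - self.config.burn_in
        if self.samples.shape != (expected, len(self.param_names)):
            raise ValueError("chain shape inconsistent with config")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(self.param_names))

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.param_names.index(name)]


def sum_squared_deviations(params: RateParams, r0: float,
                           data: TimeCourse) -> float:
    """SSD = sum over observations of (r_obs - r_model)^2.

    This is both the design function of the sensitivity analysis and (up to
    scaling by the noise variance) the Gaussian log-likelihood kernel.
    """
    if data.n == 0:
        return 0.0
    model_r = ratio_trajectory(params, r0)(data.times)
    return float(np.sum((data.ratio - model_r) ** 2))


def log_posterior(params: RateParams, noise_scale: float, data: TimeCourse,
                  config: FitConfig, r0: float | None = None) -> float:
    """Log posterior density (up to an additive constant).

    Uniform box priors contribute only through their support; outside the
    bounds the value is -inf.  ``r0`` defaults to the first observed ratio.
    """
    values = {"k1": params.k1, "k2": params.k2, "a": params.a, "b": params.b,
              "sigma": noise_scale}
    if r0 is None:
        r0 = float(data.ratio[0])
    if config.r0_mode == "estimated":
        values["r0"] = r0
    for name, value in values.items():
        lo, hi = config.bounds[name]
        if not (lo <= value <= hi):
            return -math.inf
    n = data.n
    if n == 0:
        return 0.0
    sigma = noise_scale
    if config.likelihood == "gaussian":
        ssd = sum_squared_deviations(params, r0, data)
        return -n * math.log(sigma) - ssd / (2.0 * sigma * sigma)
    # lognormal: Gaussian error on log r
    model_r = ratio_trajectory(params, r0)(data.times)
    if np.any(model_r <= 0) or np.any(data.ratio <= 0):
        return -math.inf
    resid = np.log(data.ratio) - np.log(model_r)
    return -n * math.log(sigma) - float(resid @ resid) / (2.0 * sigma * sigma)


def _vector_log_post(data: TimeCourse, config: FitConfig):
    estimated_r0 = config.r0_mode == "estimated"
    default_r0 = float(data.ratio[0]) if data.n else 0.0

    def logp(x: np.ndarray) -> float:
        k1, k2, a, b, sigma = x[:5]
        if min(k1, k2, a, b) < 0:
            return -math.inf
        r0 = x[5] if estimated_r0 else default_r0
        try:
            params = RateParams(k1=k1, k2=k2, a=a, b=b)
        except ValueError:
            return -math.inf
        return log_posterior(params, sigma, data, config, r0=r0)

    return logp


_INIT_DRAWS = 256


def _initial_point(data: TimeCourse, config: FitConfig, lo: np.ndarray,
                   span: np.ndarray, rng: np.random.Generator,
                   logp) -> np.ndarray:
    """Seeded coarse search for a starting point with non-trivial density.

    The ratio trajectory identifies only (a, b, delta = k2 - k1), so the
    search runs in (log a, log b, delta): a seeded coarse scan (log-uniform
    in the conversion rates) followed by a deterministic Nelder-Mead polish
    of the SSD.  The intrinsic rates are placed symmetrically about the
    middle of their prior boxes, the starting noise scale is the residual
    scale sqrt(SSD/n) of the polished point (clipped to the sigma bounds),
    and r0, when estimated, starts at the first observation.  With no data
    the prior midpoint is used.
    """
    from scipy.optimize import minimize

    names = config.param_names
    mid = lo + 0.5 * span
    if data.n == 0:
        return mid
    hi = lo + span
    b_ = {n: config.bounds[n] for n in names}
    r0_obs = float(data.ratio[0])
    log_a_box = (math.log(max(b_["a"][0], 1e-8)), math.log(b_["a"][1]))
    log_b_box = (math.log(max(b_["b"][0], 1e-8)), math.log(b_["b"][1]))
    delta_box = (b_["k1"][0] - b_["k2"][1], b_["k2"][1] - b_["k1"][0])

    def rates_of(z: np.ndarray) -> RateParams | None:
        la, lb, delta = z
        if not (log_a_box[0] <= la <= log_a_box[1]
                and log_b_box[0] <= lb <= log_b_box[1]):
            return None
        k1 = min(max(0.5 * (b_["k1"][0] + b_["k1"][1]) - 0.5 * delta,
                     b_["k1"][0]), b_["k1"][1])
        k2 = k1 + delta
        if not (b_["k2"][0] <= k2 <= b_["k2"][1]):
            return None
        return RateParams(k1=k1, k2=k2, a=math.exp(la), b=math.exp(lb))

    def ssd_z(z: np.ndarray) -> float:
        params = rates_of(z)
        if params is None:
            return 1e12
        return sum_squared_deviations(params, r0_obs, data)

    candidates = []
    for _ in range(_INIT_DRAWS):
        u = rng.random(3)
        z = np.array([log_a_box[0] + u[0] * (log_a_box[1] - log_a_box[0]),
                      log_b_box[0] + u[1] * (log_b_box[1] - log_b_box[0]),
                      delta_box[0] + u[2] * (delta_box[1] - delta_box[0])])
        candidates.append((ssd_z(z), z))
    candidates.sort(key=lambda c: c[0])
    best_ssd, best_z = candidates[0]
    # polish several starts: a single Nelder-Mead run can stall in a local
    # minimum of the SSD surface
    for start_ssd, start_z in candidates[:5]:
        result = minimize(ssd_z, start_z, method="Nelder-Mead",
                          options={"maxiter": 2000, "xatol": 1e-12,
                                   "fatol": 1e-12})
        if math.isfinite(result.fun) and result.fun < best_ssd:
            best_z, best_ssd = np.asarray(result.x), float(result.fun)

    params = rates_of(best_z)
    if params is None:
        return mid
    sigma = math.sqrt(max(best_ssd, 1e-300) / data.n)
    sigma = min(max(sigma, b_["sigma"][0]), b_["sigma"][1])
    x = mid.copy()
    values = {"k1": params.k1, "k2": params.k2, "a": params.a,
              "b": params.b, "sigma": sigma}
    if "r0" in names:
        values["r0"] = min(max(r0_obs, b_["r0"][0]), b_["r0"][1])
    for i, name in enumerate(names):
        x[i] = min(max(values[name], lo[i]), hi[i])
    if math.isfinite(logp(x)):
        return x
    return mid


def run_adaptive_mh(data: TimeCourse, config: FitConfig) -> PosteriorChain:
    """Run the adaptive Metropolis sampler and return the retained chain.

    The first ``adapt_start_frac`` of iterations use a fixed diagonal
    proposal (``initial_step_frac`` of each prior range); afterwards the
    proposal covariance is refreshed every ``adapt_interval`` iterations
    from the chain history as 2.38^2/d * cov + small diagonal jitter.
    Bit-for-bit reproducible for a fixed seed.

    Raises
    ------
    RuntimeError
        If no proposal at all is accepted, which indicates a proposal scale
        grossly mismatched to the posterior; decrease ``initial_step_frac``.
    """
    rng = np.random.default_rng(config.seed)
    names = config.param_names
    d = len(names)
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])
    span = hi - lo

    logp = _vector_log_post(data, config)
    if config.init is not None:
        x = np.asarray(config.init, float)
    else:
        x = _initial_point(data, config, lo, span, rng, logp)
    lp = logp(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")

    n_iter = config.iterations
    history = np.empty((n_iter, d))
    scale = (2.38 ** 2) / d
    jitter = scale * 1e-8 * np.diag(span ** 2)
    chol = np.diag(config.initial_step_frac * span)
    adapt_start = max(int(config.adapt_start_frac * n_iter), 2 * d)
    accepted = 0

    for i in range(n_iter):
        if i >= adapt_start and i % config.adapt_interval == 0:
            # adapt from the most recent half of the history so the early
            # transient does not inflate the proposal covariance
            cov = scale * np.cov(history[i // 2:i].T) + jitter
            chol = np.linalg.cholesky(cov)
        proposal = x + chol @ rng.standard_normal(d)
        lp_prop = logp(proposal)
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = proposal, lp_prop
            accepted += 1
        history[i] = x

    if accepted == 0:
        raise RuntimeError(
            "adaptive M-H accepted no proposals; the proposal scale is "
            "mismatched to the posterior -- try a smaller initial_step_frac"
        )

    return PosteriorChain(
        samples=history[config.burn_in:].copy(),
        param_names=names,
        acceptance_rate=accepted / n_iter,
        seed=config.seed,
        config=config,
        r0=(float(data.ratio[0]) if data.n else 0.0),
    )


def _limiting_ratio_samples(chain: PosteriorChain) -> np.ndarray:
    """Riccati-fixed-point limiting ratio for every retained sample."""
    k1 = chain.column("k1")
    k2 = chain.column("k2")
    a = chain.column("a")
    b = chain.column("b")
    m = k2 - b - k1 + a
    disc = np.sqrt(m * m + 4.0 * a * b)
    with np.errstate(divide="ignore", invalid="ignore"):
        root_hi = (m + disc) / (2.0 * b)      # stable for m > 0
        root_lo = 2.0 * a / (disc - m)        # stable for m <= 0
    out = np.where(m > 0, root_hi, root_lo)
    out = np.where((a == 0) & (m <= 0) & (b > 0), 0.0, out)
    # b == 0 (prior boundary; measure zero but be exact anyway)
    zero_b = b == 0
    if np.any(zero_b):
        out = out.copy()
        fin = zero_b & (m < 0)
        out[fin] = (a[fin] / -m[fin]) if np.any(fin) else out[fin]
        out[zero_b & (m >= 0) & (a > 0)] = np.inf
        out[zero_b & (a == 0)] = np.where(m[zero_b & (a == 0)] > 0, np.inf, 0.0)
    return out


def _quantiles(x: np.ndarray) -> dict[str, float]:
    q2, q50, q97 = np.quantile(x, [0.025, 0.5, 0.975])
    return {"median": float(q50), "q2.5": float(q2), "q97.5": float(q97),
            "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))
            if x.size > 1 else 0.0}


def summarize_chain(chain: PosteriorChain,
                    time_grid: np.ndarray | None = None) -> dict:
    """Posterior point estimates, 95% credible intervals and derived output.

    Point estimates are posterior medians.  The limiting ratio and the
    asymptotic CSC percentage 100/(1 + r_inf) are computed per sample and
    then summarized.  ``curve`` is the ratio trajectory at the posterior
    medians of the identifiable parameters (a, b, delta), evaluated on
    ``time_grid`` (default 0..300 days).
    """
    if chain.samples.shape[0] == 0:
        raise ValueError("empty chain")
    summary: dict = {"parameters": {}, "derived": {}}
    for name in chain.param_names:
        summary["parameters"][name] = _quantiles(chain.column(name))

    delta = chain.column("k2") - chain.column("k1")
    summary["derived"]["delta"] = _quantiles(delta)
    r_inf = _limiting_ratio_samples(chain)
    finite = np.isfinite(r_inf)
    summary["derived"]["r_inf"] = _quantiles(r_inf[finite])
    summary["derived"]["asymptotic_percent"] = _quantiles(
        100.0 / (1.0 + r_inf))  # fine under inf: percent -> 0

    med = {n: summary["parameters"][n]["median"] for n in chain.param_names}
    med_params = RateParams(k1=med["k1"], k2=med["k2"], a=med["a"], b=med["b"])
    r0 = med.get("r0", chain.r0)
    if time_grid is None:
        time_grid = np.linspace(0.0, 300.0, 301)
    curve = ratio_trajectory(med_params, r0)(time_grid)
    summary["curve"] = {"time_days": np.asarray(time_grid, float).tolist(),
                        "ratio": np.asarray(curve, float).tolist()}
    summary["acceptance_rate"] = chain.acceptance_rate
    summary["seed"] = chain.seed
    summary["r0"] = r0
    summary["n_retained"] = int(chain.samples.shape[0])
    return summary


def with_seed(config: FitConfig, seed: int) -> FitConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
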