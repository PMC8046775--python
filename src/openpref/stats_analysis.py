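"""Descriptive and Bayesian statistical layer for preference-strength data.

Covers the analyses run on the behavioural data: preference strength
(absolute distance of a signed rating from the scale midpoint), standardized
fifth-order Bayesian polynomial regression of strength on elicitation time,
Bayesian t-tests at individual delays, Gaussian-process regression over the
time->mean-strength function with 95% credible bands and the divergence
windows / effect sizes derived from it, and the +/-3 s running average used
to display continuously-sampled delays.

The Bayesian linear models use a conjugate Normal-Inverse-Gamma prior
(zero-mean, weakly-informative coefficient scale proportional to the outcome
spread, vague Inverse-Gamma on the residual variance), so exact posterior
draws are generated with a seeded generator and all HDIs are reproducible
bit-for-bit.  HDIs are narrowest-interval (true highest-density) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .model_predict import MeanTrajectory

DEFAULT_DRAWS = 8000
#: prior scale multiplier for standardized regression coefficients
COEF_PRIOR_SCALE = 10.0


# ---------------------------------------------------------------------------
# strength observations
# ---------------------------------------------------------------------------

def preference_strength(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial preference strength: |signed rating|, validated against the
    scale bound carried in ``scale_max``.

    Expects columns ``participant, condition, delay_s, rating, scale_max``;
    returns the same frame plus a ``strength`` column.
    """
    req = {"participant", "condition", "delay_s", "rating", "scale_max"}
    if not req.issubset(trials.columns):
        raise ValueError(f"trials must have columns {sorted(req)}")
    bad = trials[np.abs(trials["rating"]) > trials["scale_max"]]
    if len(bad):
        raise ValueError(
            f"{len(bad)} ratings exceed the scale bound "
            f"(first at index {bad.index[0]})")
    out = trials.copy()
    out["strength"] = np.abs(out["rating"].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------------------
# conjugate Bayesian linear regression
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Posterior draws plus means and 95% HDIs for named quantities."""

    names: list[str]
    draws: np.ndarray               # (n_draws, n_quantities)
    mean: np.ndarray
    hdi95: np.ndarray               # (n_quantities, 2)

    @classmethod
    def from_draws(cls, names: Sequence[str],
                   draws: np.ndarray) -> "PosteriorSummary":
        draws = np.atleast_2d(draws)
        if draws.shape[1] != len(names):
            draws = draws.T
        hdi = np.array([az.hdi(np.ascontiguousarray(draws[:, k]),
                               hdi_prob=0.95) for k in range(draws.shape[1])])
        return cls(names=list(names), draws=draws,
                   mean=draws.mean(axis=0), hdi95=hdi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "quantity": self.names,
            "mean": self.mean,
            "hdi95_lower": self.hdi95[:, 0],
            "hdi95_upper": self.hdi95[:, 1],
        })

    def __getitem__(self, name: str) -> dict:
        k = self.names.index(name)
        return {"mean": float(self.mean[k]),
                "hdi95": (float(self.hdi95[k, 0]), float(self.hdi95[k, 1]))}


def _nig_posterior_draws(X: np.ndarray, y: np.ndarray, prior_scale: float,
                         n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Exact draws from the conjugate NIG posterior of a linear model.

    Prior: beta | sigma^2 ~ N(0, sigma^2 * prior_scale^2 I),
    sigma^2 ~ InvGamma(a0, b0) with vague a0 = b0 = 1e-3.
    """
    n, k = X.shape
    lam0 = np.eye(k) / prior_scale ** 2
    lam_n = X.T @ X + lam0
    lam_n_inv = np.linalg.inv(lam_n)
    mu_n = lam_n_inv @ (X.T @ y)
    a_n = 1e-3 + 0.5 * n
    b_n = 1e-3 + 0.5 * float(y @ y - mu_n @ lam_n @ mu_n)
    sigma2 = b_n / rng.gamma(a_n, 1.0, size=n_draws)
    L = np.linalg.cholesky(lam_n_inv)
    z = rng.standard_normal((n_draws, k))
    return mu_n + np.sqrt(sigma2)[:, None] * (z @ L.T)


@dataclass(frozen=True)
class PolynomialDesign:
    """Standardized polynomial design: column ``m`` is ``t^m / SD(t^m)``.

    Dividing each elementwise power of the time vector by its standard
    deviation puts the coefficients on comparable scales; a raw coefficient
    is recovered by dividing the standardized one by ``SD(t^m)``.
    """

    time_points: np.ndarray
    order: int = 5

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def column_sds(self) -> np.ndarray:
        t = np.asarray(self.time_points, dtype=float)
        return np.array([np.std(t ** m) for m in range(1, self.order + 1)])

    def matrix(self) -> np.ndarray:
        t = np.asarray(self.time_points, dtype=float)
        cols = [np.ones_like(t)]
        for m, sd in zip(range(1, self.order + 1), self.column_sds()):
            if sd == 0:
                raise ValueError(f"degenerate time column t^{m}")
            cols.append(t ** m / sd)
        return np.column_stack(cols)


def fit_polynomial(data: pd.DataFrame, condition: str | None = None,
                   order: int = 5, n_draws: int = DEFAULT_DRAWS,
                   seed: int = 0) -> PosteriorSummary:
    """Bayesian polynomial regression of strength on elicitation delay.

    With ``condition`` given, fits that condition's observations and returns
    posteriors for the standardized coefficients ``b0..b{order}``.  With
    ``condition=None``, fits both conditions separately (same prior, seeded
    independently) and returns the no-choice-minus-choice coefficient
    difference posterior as quantities ``diff_b0..``.
    """
    if "strength" not in data.columns:
        data = preference_strength(data)
    if condition is None:
        nc = fit_polynomial(data, "no_choice", order, n_draws, seed)
        ch = fit_polynomial(data, "choice", order, n_draws, seed + 1)
        diff = nc.draws - ch.draws
        return PosteriorSummary.from_draws(
            [f"diff_{n}" for n in nc.names], diff)
    sub = data[data["condition"] == condition]
    t = sub["delay_s"].to_numpy(dtype=float)
    y = sub["strength"].to_numpy(dtype=float)
    n_delays = len(np.unique(t))
    if n_delays < order + 1:
        raise ValueError(
            f"need at least {order + 1} distinct delays, got {n_delays}")
    X = PolynomialDesign(time_points=t, order=order).matrix()
    rng = np.random.default_rng(seed)
    draws = _nig_posterior_draws(
        X, y, prior_scale=COEF_PRIOR_SCALE * max(np.std(y), 1e-9),
        n_draws=n_draws, rng=rng)
    return PosteriorSummary.from_draws(
        [f"b{m}" for m in range(order + 1)], draws)


def bayesian_ttest(x: np.ndarray, y: np.ndarray, n_draws: int = DEFAULT_DRAWS,
                   seed: int = 0) -> PosteriorSummary:
    """Posterior of the mean difference ``mean(x) - mean(y)``.

    Each group gets an independent conjugate Normal-Inverse-Gamma model
    (vague priors); the returned quantity ``mean_diff`` is the difference of
    the posterior mean draws.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    rng = np.random.default_rng(seed)

    def group_mean_draws(v):
        X = np.ones((len(v), 1))
        return _nig_posterior_draws(
            X, v, prior_scale=COEF_PRIOR_SCALE * max(np.std(v), 1e-9),
            n_draws=n_draws, rng=rng)[:, 0]

    diff = group_mean_draws(x) - group_mean_draws(y)
    return PosteriorSummary.from_draws(["mean_diff"], diff[:, None])


# ---------------------------------------------------------------------------
# Gaussian-process regression
# ---------------------------------------------------------------------------

@dataclass
class GPRResult:
    """GP posterior over the time -> mean-strength function."""

    grid: np.ndarray
    mean_fn: np.ndarray
    band95: np.ndarray              # (len(grid), 2)
    lengthscale: float
    amplitude: float
    noise_sd: float
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "time_s": self.grid,
            "mean_strength": self.mean_fn,
            "band95_lower": self.band95[:, 0],
            "band95_upper": self.band95[:, 1],
        })


def _per_delay_means(sub: pd.DataFrame, bin_width: float | None):
    t = sub["delay_s"].to_numpy(dtype=float)
    if bin_width:
        t = np.round(t / bin_width) * bin_width
    g = sub.assign(_t=t).groupby("_t")["strength"]
    means = g.mean()
    sems = g.sem().fillna(0.0)
    counts = g.size()
    return (means.index.to_numpy(), means.to_numpy(), sems.to_numpy(),
            counts.to_numpy())


def _noise_sd(sub: pd.DataFrame, rule: str, bin_width: float | None) -> float:
    if rule == "per_delay_max_sem":
        _, _, sems, counts = _per_delay_means(sub, bin_width)
        return float(np.max(sems[counts >= 2]))
    if rule == "window10s_max_sem":
        t = sub["delay_s"].to_numpy(dtype=float)
        s = sub["strength"].to_numpy(dtype=float)
        lo, hi = t.min(), t.max()
        best = 0.0
        for start in np.arange(lo, max(hi - 10.0, lo) + 1e-9, 1.0):
            m = (t >= start) & (t <= start + 10.0)
            if m.sum() >= 2:
                best = max(best, float(np.std(s[m], ddof=1) / np.sqrt(m.sum())))
        if best == 0.0:
            raise ValueError("no 10 s window holds two observations")
        return best
    raise ValueError(f"unknown noise rule {rule!r}")


def _lengthscale_from_covariance(sub: pd.DataFrame,
                                 bin_width: float | None) -> float:
    """Fit the squared-exponential decay to within-subject correlations.

    Correlations of per-participant mean strength between delay pairs are
    computed across participants, then ``exp(-dt^2 / (2 l^2))`` is fit to
    (correlation, |dt|) by least squares.
    """
    t = sub["delay_s"].to_numpy(dtype=float)
    if bin_width:
        t = np.round(t / bin_width) * bin_width
    pivot = (sub.assign(_t=t)
             .pivot_table(index="participant", columns="_t",
                          values="strength", aggfunc="mean"))
    cols = pivot.columns.to_numpy(dtype=float)
    dts, corrs = [], []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair = pivot.iloc[:, [i, j]].dropna()
            if len(pair) >= 3 and pair.iloc[:, 0].std() > 0 \
                    and pair.iloc[:, 1].std() > 0:
                corrs.append(float(pair.corr().iloc[0, 1]))
                dts.append(abs(cols[j] - cols[i]))
    if not corrs:
        # no repeated measures: fall back to half the median delay gap
        return float(max(np.median(np.diff(np.unique(cols))), 1.0))
    dts = np.asarray(dts)
    corrs = np.asarray(corrs)

    def loss(log_l):
        l = np.exp(log_l)
        return float(np.sum((corrs - np.exp(-dts ** 2 / (2 * l ** 2))) ** 2))

    res = minimize_scalar(loss, bounds=(np.log(0.5), np.log(200.0)),
                          method="bounded")
    return float(np.exp(res.x))


def fit_gpr(data: pd.DataFrame, condition: str,
            noise_rule: str = "per_delay_max_sem",
            lengthscale: float | None = None,
            bin_width: float | None = None,
            grid_step: float = 0.5) -> GPRResult:
    """Gaussian-process regression of mean strength on elicitation delay.

    A squared-exponential kernel with amplitude equal to the variance of the
    per-delay means and lengthscale estimated from the within-subject
    covariance (or supplied) is conditioned on the per-delay condition means;
    the observation noise is fixed by the stated SEM rule, never optimised.
    ``band95`` is the pointwise 95% credible band of the latent function.
    """
    if "strength" not in data.columns:
        data = preference_strength(data)
    sub = data[data["condition"] == condition]
    if len(sub) < 5:
        raise ValueError("need at least 5 observations")
    noise = _noise_sd(sub, noise_rule, bin_width)
    if lengthscale is None:
        lengthscale = _lengthscale_from_covariance(sub, bin_width)
    tt, means, _, _ = _per_delay_means(sub, bin_width)
    grand = float(np.mean(means))
    amp = float(max(np.var(means), 1e-12))
    kernel = ConstantKernel(amp, constant_value_bounds="fixed") * \
        RBF(lengthscale, length_scale_bounds="fixed")
    gpr = GaussianProcessRegressor(kernel=kernel, alpha=max(noise, 1e-9) ** 2,
                                   optimizer=None, normalize_y=False)
    gpr.fit(tt[:, None], means - grand)
    grid = np.arange(tt.min(), tt.max() + 1e-9, grid_step)
    mu, sd = gpr.predict(grid[:, None], return_std=True)
    mu = mu + grand
    band = np.column_stack([mu - 1.96 * sd, mu + 1.96 * sd])
    return GPRResult(grid=grid, mean_fn=mu, band95=band,
                     lengthscale=float(lengthscale), amplitude=amp,
                     noise_sd=float(noise), condition=condition)


# ---------------------------------------------------------------------------
# divergence windows, effect sizes, running average
# ---------------------------------------------------------------------------

def divergence_windows(choice: GPRResult, no_choice: GPRResult
                       ) -> list[dict]:
    """Maximal grid intervals where one condition's mean exits the other's
    95% band.

    ``bolstering``: choice strength credibly above no-choice;
    ``suppression``: no-choice credibly above choice.
    """
    if len(choice.grid) != len(no_choice.grid) or \
            not np.allclose(choice.grid, no_choice.grid):
        raise ValueError("GPR results must share a grid")
    bol = (choice.mean_fn > no_choice.band95[:, 1]) | \
          (no_choice.mean_fn < choice.band95[:, 0])
    sup = (no_choice.mean_fn > choice.band95[:, 1]) | \
          (choice.mean_fn < no_choice.band95[:, 0])
    out = []
    for mask, label in ((bol & ~sup, "bolstering"), (sup & ~bol, "suppression")):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            out.append({"start_s": float(choice.grid[run[0]]),
                        "end_s": float(choice.grid[run[-1]]),
                        "direction": label})
    return sorted(out, key=lambda w: w["start_s"])


def effect_sizes(choice: GPRResult, no_choice: GPRResult,
                 sd_ratings: float) -> dict:
    """Cohen's-d style effect sizes from the GPR mean functions.

    ``between_max_d``: largest between-condition difference of the mean
    functions divided by the rating SD; ``within_range_d``: per-condition
    (max - min) of the mean function divided by the rating SD.
    """
    if sd_ratings <= 0:
        raise ValueError("sd_ratings must be positive")
    if not np.allclose(choice.grid, no_choice.grid):
        raise ValueError("GPR results must share a grid")
    dmax = float(np.max(np.abs(choice.mean_fn - no_choice.mean_fn)))
    out = {
        "between_max_points": dmax,
        "between_max_d": dmax / sd_ratings,
    }
    for res, name in ((choice, "choice"), (no_choice, "no_choice")):
        rng_pts = float(res.mean_fn.max() - res.mean_fn.min())
        out[f"within_range_points_{name}"] = rng_pts
        out[f"within_range_d_{name}"] = rng_pts / sd_ratings
    return out


def running_average(data: pd.DataFrame, condition: str | None = None,
                    half_window: float = 3.0,
                    grid: np.ndarray | None = None) -> MeanTrajectory:
    """Mean strength of all observations within +/- ``half_window`` seconds
    of each grid point; empty windows yield NaN."""
    if "strength" not in data.columns:
        data = preference_strength(data)
    if condition is not None:
        data = data[data["condition"] == condition]
    t = data["delay_s"].to_numpy(dtype=float)
    s = data["strength"].to_numpy(dtype=float)
    if grid is None:
        grid = np.arange(np.floor(t.min()), np.ceil(t.max()) + 1e-9, 1.0)
    vals = np.full(len(grid), np.nan)
    for i, g in enumerate(grid):
        m = np.abs(t - g) <= half_window
        if m.any():
            vals[i] = s[m].mean()
    return MeanTrajectory(delay=np.asarray(grid), strength=vals,
                          condition=condition or "all")
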