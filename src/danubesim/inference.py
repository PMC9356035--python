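"""Approximate Bayesian computation: reference tables, rejection + GLM
posteriors, model choice and calibration diagnostics.

The estimation follows the ABC-GLM scheme: a small fraction delta of the
reference simulations closest to the observed statistics (Euclidean
distance on standardised statistics) is retained; a general linear model
``s = a + B theta + eps``, ``eps ~ N(0, Sigma)``, is fitted to the
retained simulations; and the posterior is proportional to the truncated
prior times the GLM likelihood evaluated at the observed statistics.
Posteriors are represented on a regular grid per parameter (1,024 points
for the marginals), from which mode, mean and highest-density intervals
are read off deterministically.

Model choice reports, per scenario, the GLM marginal density of the
observed statistics, posterior probabilities proportional to those
densities under equal model priors, Bayes factors of each scenario against
the pooled others, and the acceptance-fraction method (share of each model
among the globally closest simulations, at several tolerance levels).
Validation utilities implement relative bias, relative RMSE, the Factor2
score, and posterior quantile / HDI uniformity diagnostics with
Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.special import logsumexp

__all__ = [
    "PriorSpec",
    "SimulationFailure",
    "build_reference_table",
    "param_names",
    "stat_names",
    "retain",
    "ParamPosterior",
    "PosteriorResult",
    "abc_glm_posterior",
    "marginal_density_pvalue",
    "ModelChoiceResult",
    "model_choice",
    "cross_validate_recovery",
    "bias_rmse_factor2",
    "hdi",
    "posterior_quantile",
    "hdi_level_of",
    "ValidationReport",
    "calibration_diagnostics",
    "DEFAULT_PRIORS",
]

PARAM_PREFIX = "param_"
STAT_PREFIX = "stat_"

#: Default tolerance levels for the acceptance-fraction model choice.
PRITCHARD_EPSILONS = (0.0025, 0.01, 0.025)

MARGINAL_GRID = 1024


class SimulationFailure(RuntimeError):
    """Raised by a simulator to request a resampled parameter draw."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one per parameter."""

    bounds: dict

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: lower bound must be < upper")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def sample(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        cols = {
            name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in self.bounds.items()
        }
        return pd.DataFrame(cols)

    def contains(self, params: dict) -> bool:
        return all(lo <= params[k] <= hi for k, (lo, hi) in self.bounds.items())

    def log_volume(self) -> float:
        return float(sum(np.log(hi - lo) for lo, hi in self.bounds.values()))


#: Table-1 priors of the Danubian-expansion analysis.
DEFAULT_PRIORS = PriorSpec(
    bounds={"gamma": (0.0, 0.4), "K_FA": (500.0, 1000.0), "Mdec": (1.0, 20.0)}
)


def param_names(table: pd.DataFrame) -> list[str]:
    return [c[len(PARAM_PREFIX):] for c in table.columns if c.startswith(PARAM_PREFIX)]


def stat_names(table: pd.DataFrame) -> list[str]:
    return [c[len(STAT_PREFIX):] for c in table.columns if c.startswith(STAT_PREFIX)]


def build_reference_table(
    simulator: Callable[[dict, int], Sequence[float]],
    priors: PriorSpec,
    n_sims: int,
    seed: int,
    scenario_id: str = "M0",
    stat_labels: Optional[Sequence[str]] = None,
    max_failures: int = 1000,
) -> pd.DataFrame:
    """Draw parameters from the priors and simulate the reference table.

    ``simulator(params, seed)`` returns the statistic vector of one
    simulation, or raises :class:`SimulationFailure` to have the draw
    resampled (failures are counted and reported in ``table.attrs``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    failures = 0
    while len(rows) < n_sims:
        draw = {k: float(v) for k, v in priors.sample(rng, 1).iloc[0].items()}
        sim_seed = int(rng.integers(0, 2**31 - 1))
        try:
            stats_vec = np.asarray(simulator(draw, sim_seed), dtype=float)
        except SimulationFailure:
            failures += 1
            if failures > max_failures:
                raise RuntimeError("too many simulation failures")
            continue
        if not np.all(np.isfinite(stats_vec)):
            failures += 1
            if failures > max_failures:
                raise RuntimeError("too many non-finite simulations")
            continue
        labels = (
            list(stat_labels)
            if stat_labels is not None
            else [f"s{i}" for i in range(stats_vec.shape[0])]
        )
        row = {"scenario": scenario_id, "seed": sim_seed}
        row.update({PARAM_PREFIX + k: v for k, v in draw.items()})
        row.update({STAT_PREFIX + l: v for l, v in zip(labels, stats_vec)})
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["n_failures"] = failures
    return table


# ---------------------------------------------------------------------------
# Rejection step
# ---------------------------------------------------------------------------


@dataclass
class _Scaler:
    mean: np.ndarray
    sd: np.ndarray
    stat_cols: list

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _make_scaler(table: pd.DataFrame) -> _Scaler:
    stat_cols = [c for c in table.columns if c.startswith(STAT_PREFIX)]
    X = table[stat_cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant statistics carry no signal
    return _Scaler(mean=mean, sd=sd, stat_cols=stat_cols)


def retain(
    observed: Sequence[float],
    table: pd.DataFrame,
    delta: float,
    scaler: Optional[_Scaler] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Retain the ``ceil(delta * N)`` simulations closest to the observed
    statistics (Euclidean distance on statistics standardised by the
    reference-table mean and SD).

    Returns ``(retained_rows, all_distances)``; the retained frame carries
    the distances in column ``abc_distance``.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    N = len(table)
    n_keep = int(np.ceil(delta * N))
    if n_keep < 1:
        raise ValueError("delta * N < 1: nothing would be retained")
    if n_keep < 10:
        warnings.warn(f"only {n_keep} simulations retained; estimates will be noisy")
    scaler = scaler or _make_scaler(table)
    X = scaler.transform(table[scaler.stat_cols].to_numpy(dtype=float))
    obs = scaler.transform(np.asarray(observed, dtype=float))
    dist = np.sqrt(((X - obs) ** 2).sum(axis=1))
    idx = np.argsort(dist, kind="stable")[:n_keep]
    out = table.iloc[idx].copy()
    out["abc_distance"] = dist[idx]
    return out, dist


# ---------------------------------------------------------------------------
# ABC-GLM posterior
# ---------------------------------------------------------------------------


@dataclass
class _GLMFit:
    a: np.ndarray  # (k,)
    B: np.ndarray  # (k, p)
    Sigma_inv: np.ndarray  # (k, k)
    log_det_term: float
    scaler: _Scaler
    params: list
    theta: np.ndarray  # retained parameter draws (n, p)


def _fit_glm(
    retained: pd.DataFrame,
    scaler: Optional[_Scaler] = None,
    params: Optional[list] = None,
) -> _GLMFit:
    scaler = scaler or _make_scaler(retained)
    params = params if params is not None else param_names(retained)
    theta = retained[[PARAM_PREFIX + p for p in params]].to_numpy(dtype=float)
    S = scaler.transform(retained[scaler.stat_cols].to_numpy(dtype=float))
    n, p = theta.shape
    X = np.column_stack([np.ones(n), theta])
    coef, *_ = np.linalg.lstsq(X, S, rcond=None)
    a = coef[0]
    B = coef[1:].T  # (k, p)
    resid = S - X @ coef
    k = S.shape[1]
    Sigma = resid.T @ resid / max(n - p - 1, 1)
    Sigma += 1e-8 * np.eye(k) * max(np.trace(Sigma) / k, 1e-12)
    Sigma_inv = np.linalg.inv(Sigma)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("residual covariance not positive definite")
    log_det_term = -0.5 * (k * np.log(2 * np.pi) + logdet)
    return _GLMFit(
        a=a,
        B=B,
        Sigma_inv=Sigma_inv,
        log_det_term=log_det_term,
        scaler=scaler,
        params=params,
        theta=theta,
    )


def _glm_loglik(fit: _GLMFit, s_std: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """log N(s_std; a + B theta, Sigma) for an (m, p) array of theta."""
    resid = s_std[None, :] - fit.a[None, :] - theta @ fit.B.T
    quad = np.einsum("mk,kl,ml->m", resid, fit.Sigma_inv, resid)
    return fit.log_det_term - 0.5 * quad


@dataclass
class ParamPosterior:
    """Marginal posterior of one parameter on a regular grid."""

    name: str
    grid: np.ndarray
    density: np.ndarray
    mode: float
    mean: float
    hdi50: tuple[float, float]
    hdi90: tuple[float, float]


@dataclass
class PosteriorResult:
    params: dict  # name -> ParamPosterior
    retained_index: np.ndarray
    method: str  # 'glm' or 'rejection'
    marginal_p: Optional[float] = None

    def point_estimate(self, name: str, estimator: str = "mode") -> float:
        pp = self.params[name]
        return pp.mode if estimator == "mode" else pp.mean


def _joint_grid(priors: PriorSpec, n_per_dim: int) -> tuple[np.ndarray, list[np.ndarray]]:
    axes = [
        np.linspace(lo, hi, n_per_dim) for lo, hi in priors.bounds.values()
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    theta = np.column_stack([m.ravel() for m in mesh])
    return theta, axes


def _marginals_from_joint(
    log_dens: np.ndarray, axes: list[np.ndarray], priors: PriorSpec
) -> dict:
    shape = tuple(len(ax) for ax in axes)
    dens = np.exp(log_dens - log_dens.max()).reshape(shape)
    out = {}
    for i, (name, ax) in enumerate(zip(priors.names, axes)):
        other = tuple(j for j in range(len(axes)) if j != i)
        marg = dens.sum(axis=other) if other else dens
        out[name] = _finish_marginal(name, ax, marg)
    return out


def _finish_marginal(name: str, ax: np.ndarray, marg: np.ndarray) -> ParamPosterior:
    grid = np.linspace(ax[0], ax[-1], MARGINAL_GRID)
    density = np.interp(grid, ax, marg)
    density = np.clip(density, 0.0, None)
    area = np.trapezoid(density, grid)
    if area <= 0:
        density = np.full_like(grid, 1.0 / (grid[-1] - grid[0]))
    else:
        density = density / area
    mode = float(grid[np.argmax(density)])
    mean = float(np.trapezoid(grid * density, grid))
    return ParamPosterior(
        name=name,
        grid=grid,
        density=density,
        mode=mode,
        mean=mean,
        hdi50=hdi(grid, density, 0.5),
        hdi90=hdi(grid, density, 0.9),
    )


def abc_glm_posterior(
    retained: pd.DataFrame,
    priors: PriorSpec,
    observed: Sequence[float],
    scaler: Optional[_Scaler] = None,
    min_retained: int = 50,
) -> PosteriorResult:
    """ABC-GLM posterior of the parameters given the observed statistics.

    The posterior is the truncated uniform prior times the fitted GLM
    likelihood at the observed statistics, evaluated on a joint parameter
    grid and marginalised per parameter.  Falls back to the plain rejection
    posterior (density of the retained draws) if the regression is
    degenerate.
    """
    if len(retained) < min_retained:
        raise ValueError(f"need >= {min_retained} retained simulations")
    p = len(priors.names)
    n_per_dim = {1: MARGINAL_GRID, 2: 257, 3: 81, 4: 41}.get(p)
    if n_per_dim is None:
        raise ValueError("grid posterior supports at most 4 parameters")
    try:
        fit = _fit_glm(retained, scaler=scaler, params=priors.names)
        s_std = fit.scaler.transform(np.asarray(observed, dtype=float))
        theta, axes = _joint_grid(priors, n_per_dim)
        log_dens = _glm_loglik(fit, s_std, theta)
        marginals = _marginals_from_joint(log_dens, axes, priors)
        method = "glm"
    except np.linalg.LinAlgError:
        warnings.warn("singular GLM regression; falling back to rejection posterior")
        marginals = {}
        for name in priors.names:
            lo, hi = priors.bounds[name]
            draws = retained[PARAM_PREFIX + name].to_numpy(dtype=float)
            ax = np.linspace(lo, hi, 256)
            if np.std(draws) > 0:
                kde = sp_stats.gaussian_kde(draws)
                marg = kde(ax)
            else:
                marg = np.exp(-0.5 * ((ax - draws[0]) / ((hi - lo) / 100)) ** 2)
            marginals[name] = _finish_marginal(name, ax, marg)
        method = "rejection"
    return PosteriorResult(
        params=marginals,
        retained_index=retained.index.to_numpy(),
        method=method,
    )


# ---------------------------------------------------------------------------
# Goodness of fit and model choice
# ---------------------------------------------------------------------------


def _log_marginal_density(fit: _GLMFit, s_std: np.ndarray) -> float:
    """GLM marginal density of a statistics vector: the likelihood averaged
    over the retained parameter draws (truncated-prior Monte Carlo)."""
    ll = _glm_loglik(fit, s_std, fit.theta)
    return float(logsumexp(ll) - np.log(ll.shape[0]))


def marginal_density_pvalue(
    retained: pd.DataFrame,
    observed: Sequence[float],
    scaler: Optional[_Scaler] = None,
) -> float:
    """Goodness-of-fit P-value in [0, 1]: the fraction of retained
    simulations whose own statistics have a smaller GLM marginal density
    than the observed statistics (0 = no fit, 1 = good fit)."""
    if len(retained) == 0:
        raise ValueError("retained set is empty")
    fit = _fit_glm(retained, scaler=scaler)
    S = fit.scaler.transform(
        retained[fit.scaler.stat_cols].to_numpy(dtype=float)
    )
    dens_obs = _log_marginal_density(fit, fit.scaler.transform(np.asarray(observed, float)))
    dens_sims = np.array([_log_marginal_density(fit, s) for s in S])
    return float(np.mean(dens_sims < dens_obs))


@dataclass
class ModelChoiceResult:
    marginal_density: dict  # scenario -> density of observed stats
    posterior_prob: dict  # scenario -> probability (equal model priors)
    bayes_factor: dict  # scenario -> density / mean density of the others
    fit_pvalue: dict  # scenario -> marginal density P-value
    pritchard: dict  # epsilon -> {scenario: acceptance fraction}

    @property
    def best(self) -> str:
        return max(self.posterior_prob, key=self.posterior_prob.get)


def model_choice(
    observed: Sequence[float],
    tables: dict,
    delta: float = 0.01,
    epsilons: Sequence[float] = PRITCHARD_EPSILONS,
    seed: int = 0,
    fit_pvalues: bool = True,
) -> ModelChoiceResult:
    """Compare demographic scenarios against the observed statistics.

    ``tables`` maps scenario id to its reference table (equal sizes).
    Statistics are standardised with the pooled mean/SD so that marginal
    densities are comparable across scenarios.
    """
    if len(tables) < 2:
        raise ValueError("model choice requires at least 2 scenarios")
    sizes = {k: len(t) for k, t in tables.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"reference tables must have equal sizes, got {sizes}")
    pooled = pd.concat(tables.values(), ignore_index=True)
    scaler = _make_scaler(pooled)
    obs = np.asarray(observed, dtype=float)

    log_dens = {}
    fit_p = {}
    for scen, table in tables.items():
        retained, _ = retain(obs, table, delta, scaler=scaler)
        fit = _fit_glm(retained, scaler=scaler)
        log_dens[scen] = _log_marginal_density(fit, scaler.transform(obs))
        if fit_pvalues:
            fit_p[scen] = marginal_density_pvalue(retained, obs, scaler=scaler)
    scens = list(tables)
    ld = np.array([log_dens[s] for s in scens])
    post = np.exp(ld - logsumexp(ld))
    posterior_prob = {s: float(p) for s, p in zip(scens, post)}
    bayes = {}
    for i, s in enumerate(scens):
        others = np.delete(ld, i)
        log_bf = ld[i] - (logsumexp(others) - np.log(others.size))
        bayes[s] = float(np.exp(np.clip(log_bf, -700, 700)))

    # acceptance-fraction model choice on the pooled simulations
    X = scaler.transform(pooled[scaler.stat_cols].to_numpy(dtype=float))
    dist = np.sqrt(((X - scaler.transform(obs)) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")
    labels = pooled["scenario"].to_numpy()
    pritchard = {}
    for eps in epsilons:
        n_keep = max(int(np.ceil(eps * len(pooled))), 1)
        kept = labels[order[:n_keep]]
        pritchard[eps] = {
            s: float(np.mean(kept == tab["scenario"].iloc[0]))
            for s, tab in tables.items()
        }
    return ModelChoiceResult(
        marginal_density={s: float(np.exp(v)) for s, v in log_dens.items()},
        posterior_prob=posterior_prob,
        bayes_factor=bayes,
        fit_pvalue=fit_p,
        pritchard=pritchard,
    )


def cross_validate_recovery(
    tables: dict,
    delta: float = 0.01,
    n_pseudo: int = 50,
    seed: int = 0,
) -> dict:
    """Probability of recovering the correct model (PR) per scenario.

    Rows of each scenario's table are held out in turn as pseudo-observed
    datasets; model choice runs on the remaining simulations; PR is the
    fraction of pseudo-observations for which the true scenario attains the
    highest posterior probability.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = pd.concat(tables.values(), ignore_index=True)
    scaler = _make_scaler(pooled)
    out = {}
    scens = list(tables)
    for true_scen in scens:
        table = tables[true_scen]
        picks = rng.choice(len(table), size=min(n_pseudo, len(table)), replace=False)
        stat_cols = scaler.stat_cols
        hits = 0
        for i in picks:
            obs = table.iloc[int(i)][stat_cols].to_numpy(dtype=float)
            log_dens = {}
            for scen in scens:
                t = tables[scen]
                if scen == true_scen:
                    t = t.drop(t.index[int(i)])
                retained, _ = retain(obs, t, delta, scaler=scaler)
                fit = _fit_glm(retained, scaler=scaler)
                log_dens[scen] = _log_marginal_density(fit, scaler.transform(obs))
            if max(log_dens, key=log_dens.get) == true_scen:
                hits += 1
        out[true_scen] = hits / len(picks)
    return out


# ---------------------------------------------------------------------------
# Estimator accuracy and calibration
# ---------------------------------------------------------------------------


def bias_rmse_factor2(
    true: Sequence[float], est: Sequence[float]
) -> tuple[float, float, float]:
    """Relative bias, relative RMSE and the Factor2 score of an estimator.

    BIAS = mean(|est_i - true_i| / true_i); RMSE = sqrt(mean((est_i -
    true_i)^2)) / mean(true); Factor2 = proportion of estimates within
    [0.5 true_i, 2 true_i] (bounds inclusive).
    """
    t = np.asarray(true, dtype=float)
    e = np.asarray(est, dtype=float)
    if t.shape != e.shape:
        raise ValueError("true and est must have equal length")
    if np.any(t == 0):
        raise ValueError("relative bias undefined for true values of 0")
    bias = float(np.mean(np.abs(e - t) / t))
    rmse = float(np.sqrt(np.mean((e - t) ** 2)) / np.mean(t))
    factor2 = float(np.mean((e >= 0.5 * t) & (e <= 2.0 * t)))
    return bias, rmse, factor2


def hdi(grid: np.ndarray, density: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest single interval holding ``level`` of the posterior mass.

    Computed on the gridded density; a multimodal density still yields one
    interval (the shortest window whose integral reaches the level), with a
    warning when the highest-density region is visibly split.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    grid = np.asarray(grid, dtype=float)
    dens = np.clip(np.asarray(density, dtype=float), 0, None)
    dx = grid[1] - grid[0]
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * dx)])
    cdf = cdf / cdf[-1]
    n = grid.shape[0]
    best = (grid[0], grid[-1])
    best_w = grid[-1] - grid[0] + dx
    best_mass = 0.0
    j = 0
    for i in range(n):
        j = max(j, i)
        while j < n - 1 and cdf[j] - cdf[i] < level:
            j += 1
        mass = cdf[j] - cdf[i]
        if mass < level:
            continue
        w = grid[j] - grid[i]
        # ties within one grid step: prefer the window holding more mass
        # (recentres the interval of a symmetric density)
        if w < best_w - 0.5 * dx or (w < best_w + 0.5 * dx and mass > best_mass):
            best_w, best_mass = w, mass
            best = (float(grid[i]), float(grid[j]))
    # warn when the included region's density dips well below its edges
    lo_i = np.searchsorted(grid, best[0])
    hi_i = np.searchsorted(grid, best[1])
    inside = dens[lo_i : hi_i + 1]
    if inside.size > 2 and inside.min() < 0.1 * min(inside[0], inside[-1]):
        warnings.warn("multimodal density: HDI reported as shortest single interval")
    return best


def posterior_quantile(grid: np.ndarray, density: np.ndarray, x: float) -> float:
    """Posterior CDF evaluated at x (the 'posterior quantile' of a true
    value)."""
    dens = np.clip(np.asarray(density, dtype=float), 0, None)
    dx = grid[1] - grid[0]
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * dx)])
    cdf = cdf / cdf[-1]
    return float(np.interp(x, grid, cdf))


def hdi_level_of(grid: np.ndarray, density: np.ndarray, x: float) -> float:
    """Mass of the smallest highest-density region containing x."""
    dens = np.clip(np.asarray(density, dtype=float), 0, None)
    dx = grid[1] - grid[0]
    d_x = float(np.interp(x, grid, dens))
    mass = dens[dens >= d_x].sum() * dx
    total = dens.sum() * dx
    return float(min(mass / total, 1.0))


@dataclass
class ValidationReport:
    """Calibration and accuracy diagnostics over pseudo-observed datasets."""

    quantiles: dict  # param -> array of posterior quantiles of the truth
    hdi_levels: dict  # param -> array of smallest-HDI levels containing it
    ks_quantile_p: dict  # param -> KS P-value vs uniform
    ks_hdi_p: dict
    accuracy: pd.DataFrame  # rows: (param, estimator) -> BIAS, RMSE, Factor2


def calibration_diagnostics(
    posteriors: Sequence[PosteriorResult],
    truths: pd.DataFrame,
) -> ValidationReport:
    """Posterior quantile / HDI uniformity and point-estimator accuracy.

    ``truths`` has one row per pseudo-observed dataset and one column per
    parameter.  If the posteriors are unbiased, the quantiles of the true
    values and the smallest-HDI levels containing them are uniform;
    deviations are flagged by Kolmogorov-Smirnov tests.
    """
    if len(posteriors) != len(truths):
        raise ValueError("one posterior per pseudo-observed dataset required")
    params = list(truths.columns)
    quantiles = {p: [] for p in params}
    hdi_levels = {p: [] for p in params}
    acc_rows = []
    for p in params:
        modes, means = [], []
        for post, (_, row) in zip(posteriors, truths.iterrows()):
            pp = post.params[p]
            quantiles[p].append(posterior_quantile(pp.grid, pp.density, row[p]))
            hdi_levels[p].append(hdi_level_of(pp.grid, pp.density, row[p]))
            modes.append(pp.mode)
            means.append(pp.mean)
        t = truths[p].to_numpy(dtype=float)
        for est_name, est in (("mode", modes), ("mean", means)):
            b, r, f2 = bias_rmse_factor2(t, est)
            acc_rows.append(
                dict(param=p, estimator=est_name, BIAS=b, RMSE=r, Factor2=f2)
            )
    ks_q = {
        p: float(sp_stats.kstest(quantiles[p], "uniform").pvalue) for p in params
    }
    ks_h = {
        p: float(sp_stats.kstest(hdi_levels[p], "uniform").pvalue) for p in params
    }
    return ValidationReport(
        quantiles={p: np.asarray(v) for p, v in quantiles.items()},
        hdi_levels={p: np.asarray(v) for p, v in hdi_levels.items()},
        ks_quantile_p=ks_q,
        ks_hdi_p=ks_h,
        accuracy=pd.DataFrame(acc_rows),
    )
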