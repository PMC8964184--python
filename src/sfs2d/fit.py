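"""Poisson composite-likelihood fitting and AIC model comparison.

Spectrum cells are treated as independent Poisson counts with mean
``theta * model_sfs[i, j]`` where the model spectrum is computed at
theta = 1; theta is profiled analytically (its MLE is the ratio of observed
to model total mass), so it never counts as a free parameter.  Models are
ranked by ``AIC = 2k - 2 logL`` and summarised with delta-AIC and Akaike
weights over the full candidate set.

Optimization follows the multi-round perturbation style of published SFS
pipelines: each round launches several Nelder-Mead searches (in log
parameter space) from random draws or from log-uniform perturbations of the
incumbent best, with the expected spectrum evaluated under common random
numbers so the surface is deterministic for a given seed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .coalescent import expected_jsfs
from .containers import JointSFS
from .models import DemographicModel, ParamSet

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult", "ModelComparison", "OptimizationError",
    "profile_theta", "poisson_loglik", "aic", "delta_aic", "akaike_weights",
    "optimize_model", "compare_models", "residuals", "DEFAULT_ROUNDS",
]

#: default multi-round schema: (replicates, perturbation fold, max NM iterations)
DEFAULT_ROUNDS = ((10, 3.0, 30), (20, 2.0, 40), (30, 2.0, 50), (40, 1.0, 60))

_MU_FLOOR = 1e-300


class OptimizationError(RuntimeError):
    pass


def _joint_unmasked(obs: JointSFS, model_sfs: JointSFS):
    if obs.shape != model_sfs.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {model_sfs.shape}")
    if obs.folded != model_sfs.folded:
        raise ValueError("fold-state mismatch between observed and model SFS")
    return ~(obs.mask | model_sfs.mask)


def profile_theta(obs: JointSFS, model_sfs: JointSFS) -> float:
    """MLE of theta: ratio of observed to model unmasked totals."""
    ok = _joint_unmasked(obs, model_sfs)
    denom = float(model_sfs.counts[ok].sum())
    if denom <= 0:
        raise OptimizationError("model spectrum has zero unmasked mass")
    return float(obs.counts[ok].sum()) / denom


def poisson_loglik(obs: JointSFS, model_sfs: JointSFS, theta: float) -> float:
    """Composite log-likelihood: sum over unmasked cells of the Poisson
    log-mass at mean ``theta * model``."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ok = _joint_unmasked(obs, model_sfs)
    o = obs.counts[ok]
    mu = np.maximum(theta * model_sfs.counts[ok], _MU_FLOOR)
    return float(np.sum(o * np.log(mu) - mu - gammaln(o + 1.0)))


def aic(loglik: float, k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * loglik


def delta_aic(aics) -> list:
    aics = list(aics)
    if not aics:
        raise ValueError("empty AIC list")
    best = min(aics)
    return [a - best for a in aics]


def akaike_weights(aics) -> list:
    deltas = np.array(delta_aic(aics))
    raw = np.exp(-deltas / 2.0)
    return list(raw / raw.sum())


@dataclass
class FitResult:
    """Best fit of one model: optimum, likelihood, AIC, profiled theta."""

    model: str
    params: ParamSet
    loglik: float
    k: int
    theta_hat: float
    trajectory: list = field(default_factory=list)  # (round, replicate, loglik)
    seed: int = 0

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)


@dataclass
class ModelComparison:
    """Ranked fits with delta-AIC and Akaike weights (best model first)."""

    results: list
    delta_aic: list
    weights: list

    @property
    def best(self) -> FitResult:
        return self.results[0]


def _search_bounds(model: DemographicModel):
    """Log10 search box; zero lower bounds are lifted for log-space search."""
    lo, hi = [], []
    for name, a, b in model.free_params:
        a = max(a, 1e-3)
        lo.append(np.log10(a))
        hi.append(np.log10(b))
    return np.array(lo), np.array(hi)


def _params_at(model: DemographicModel, xlog, lo, hi):
    """Decode a log-space point into an in-bounds ParamSet (float-safe)."""
    x = 10.0 ** np.clip(xlog, lo, hi)
    x = np.minimum(np.maximum(x, 10.0 ** lo), 10.0 ** hi)
    # guard against log/exp round-off pushing a value past its linear bound
    for idx, (_, a, b) in enumerate(model.free_params):
        x[idx] = min(max(x[idx], max(a, 1e-3)), b)
    return model.paramset(x)


def optimize_model(model: DemographicModel, obs: JointSFS,
                   nreps: int = 50_000, seed: int = 0,
                   rounds=DEFAULT_ROUNDS, start: ParamSet = None,
                   n_scan: int = 100) -> FitResult:
    """Multi-round Nelder-Mead fit of one model to an observed folded SFS.

    A cheap global scan of ``n_scan`` random log-uniform in-bounds draws
    seeds the search (skipped when ``start`` is given); round 1 then
    launches local Nelder-Mead replicates from fold-perturbations of the
    scan winner (or of ``start``, the standard way to benchmark local
    identifiability), and later rounds perturb the incumbent best.  Every
    likelihood evaluation recomputes the expected spectrum with the same
    engine seed (common random numbers), making the search surface
    deterministic and the whole fit reproducible given ``seed``.
    """
    if not obs.folded:
        raise ValueError("observed spectrum must be folded before fitting")
    n1, n2 = obs.n1, obs.n2
    lo, hi = _search_bounds(model)
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2 ** 31))

    def objective(xlog):
        xc = np.clip(xlog, lo, hi)
        penalty = 1e3 * float(np.sum((xlog - xc) ** 2))
        p = _params_at(model, xlog, lo, hi)
        exp_sfs = expected_jsfs(model, p, n1, n2, nreps=nreps, seed=crn_seed)
        fexp = exp_sfs.fold()
        try:
            theta = profile_theta(obs, fexp)
            ll = poisson_loglik(obs, fexp, theta)
        except (OptimizationError, ValueError):
            return np.inf
        return -ll + penalty

    def loglik_at(xlog):
        p = _params_at(model, xlog, lo, hi)
        fexp = expected_jsfs(model, p, n1, n2, nreps=nreps, seed=crn_seed).fold()
        theta = profile_theta(obs, fexp)
        return p, theta, poisson_loglik(obs, fexp, theta)

    if start is not None:
        x_start = np.clip(np.log10([start[n] for n in model.param_names]),
                          lo, hi)
    else:
        x_start = None

    best_x, best_f = None, np.inf
    trajectory = []
    scan_ranked = []
    if x_start is None and n_scan > 0:
        scanned = []
        for _ in range(n_scan):
            x0 = rng.uniform(lo, hi)
            f0 = objective(x0)
            if np.isfinite(f0):
                scanned.append((float(f0), x0))
        scanned.sort(key=lambda t: t[0])
        scan_ranked = [x for _, x in scanned]
        if scanned:
            best_f, best_x = scanned[0][0], scanned[0][1]
            trajectory.append((0, 0, -best_f))
    for rnd, (n_rep, fold, maxiter) in enumerate(rounds, start=1):
        for rep in range(n_rep):
            if rnd == 1 and scan_ranked:
                # first round explores the best distinct scan basins
                centre = scan_ranked[rep % len(scan_ranked)]
            elif best_x is None and x_start is None:
                centre = rng.uniform(lo, hi)
            else:
                centre = best_x if best_x is not None else x_start
            x0 = centre + rng.uniform(-1, 1, size=len(lo)) * np.log10(max(fold, 1.0 + 1e-9))
            x0 = np.clip(x0, lo, hi)
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 1e-3,
                                    "fatol": 1e-3})
            trajectory.append((rnd, rep, -float(res.fun)))
            if np.isfinite(res.fun) and res.fun < best_f:
                best_f, best_x = float(res.fun), np.asarray(res.x)
        logger.info("%s round %d best loglik %.3f", model.name, rnd,
                    -best_f if np.isfinite(best_f) else float("nan"))
    if best_x is None or not np.isfinite(best_f):
        raise OptimizationError(f"all replicates non-finite for {model.name}")

    p_best, theta_hat, ll = loglik_at(best_x)
    return FitResult(model=model.name, params=p_best, loglik=ll, k=model.k,
                     theta_hat=theta_hat, trajectory=trajectory, seed=seed)


def compare_models(obs: JointSFS, registry, nreps: int = 50_000,
                   seed: int = 0, rounds=DEFAULT_ROUNDS,
                   starts: dict = None, n_scan: int = 100) -> ModelComparison:
    """Fit every registry model and rank by AIC.

    Each model gets its own deterministic seed substream.  A model whose
    optimization fails outright is excluded with a warning, never silently.
    Ranking ties break by smaller ``k``, then name; Akaike weights are
    normalised over all successfully fitted models.
    """
    if not registry:
        raise ValueError("empty model registry")
    fits = []
    for model in registry:
        sub = (int(seed) + zlib.crc32(model.name.encode())) % (2 ** 31)
        start = (starts or {}).get(model.name)
        try:
            fits.append(optimize_model(model, obs, nreps=nreps, seed=sub,
                                       rounds=rounds, start=start,
                                       n_scan=n_scan))
        except OptimizationError as exc:
            logger.warning("model %s excluded from comparison: %s",
                           model.name, exc)
    if not fits:
        raise OptimizationError("no model could be fitted")
    fits.sort(key=lambda f: (f.aic, f.k, f.model))
    aics = [f.aic for f in fits]
    return ModelComparison(results=fits, delta_aic=delta_aic(aics),
                           weights=akaike_weights(aics))


def residuals(obs: JointSFS, model_sfs: JointSFS, theta_hat: float) -> np.ndarray:
    """Pearson-style Poisson residuals ``(obs - mu) / sqrt(mu)`` per cell.

    Masked cells (including the fixed corners) hold NaN.
    """
    ok = _joint_unmasked(obs, model_sfs)
    mu = theta_hat * model_sfs.counts
    grid = np.full(obs.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        grid[ok] = (obs.counts[ok] - mu[ok]) / np.sqrt(np.maximum(mu[ok], _MU_FLOOR))
    return grid
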