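"""Mass-constrained fitting of the reversible-aggregation size distribution.

The model density curve c_n(dG_bulk, A0) is fit to one or more measured
cluster-size distributions subject to the mass constraint
Σ_{n=1..nmax} n·c_n = ctot for each dataset (ctot is measured, so for any
candidate (dG_bulk, A0) the monomer density is not free: it is resolved by
inverting the constraint).  Global fits share a single dG_bulk across
datasets while each dataset's A0 is profiled out under its own constraint.

The outer problem is one-dimensional in dG_bulk: a deterministic coarse grid
is scanned and the best point refined with a bounded scalar minimizer.  The
inner problem (per-dataset A0 at fixed dG_bulk) is a bounded scalar
minimization over log10(A0) in which every objective evaluation first solves
the mass constraint for cmon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .theory import (
    AggregationParams,
    SizeDistribution,
    nmer_density,
    solve_monomer_from_total,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "UnderdeterminedError",
    "fit_single",
    "fit_global",
    "fit_shared_A0",
    "predict_curve",
]


class UnderdeterminedError(ValueError):
    """Too few occupied size bins to constrain the two-parameter model."""


@dataclass(frozen=True)
class FitConfig:
    """Fitting options.

    loss: 'auto' uses inverse-SE weighted least squares on densities when the
    dataset carries standard errors, else unweighted least squares on
    densities ('lin'); 'lin', 'wls' and 'log' (least squares on
    log(density + log_floor)) can be forced.  Zero-density bins inside
    1..nmax are retained.  nmax=None uses each dataset's largest observed
    size.
    """

    dG_bounds: tuple[float, float] = (-8.0, -1e-3)
    A0_bounds: tuple[float, float] = (1e-4, 10.0)
    loss: str = "auto"
    log_floor: float = 1e-6
    nmax: int | None = None
    alpha: float = 0.5
    n_grid: int = 48
    n_bootstrap: int = 0
    seed: int = 0


@dataclass
class FitResult:
    """Fitted global cohesion energy and per-dataset configurational areas."""

    dG_bulk: float
    A0_per_dataset: list[float]
    cmon_per_dataset: list[float]
    ctot_per_dataset: list[float]
    nmax_per_dataset: list[int]
    objective: float
    residuals: list[np.ndarray]
    converged: bool
    alpha: float = 0.5
    dG_ci: tuple[float, float] | None = None
    bootstrap_dG: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _prepare(dist: SizeDistribution, config: FitConfig):
    """Pad to the fitting nmax and pull out (n, density, se, ctot)."""
    if dist.ctot is None:
        ctot = dist.total()
    else:
        ctot = dist.ctot
    if ctot <= 0:
        raise ValueError("dataset has zero total density")
    nmax = config.nmax or dist.nmax
    padded = dist.padded(nmax)
    se = padded.se if (dist.se is not None) else None
    return padded.n, padded.density, se, ctot, nmax


def _loss(model: np.ndarray, density: np.ndarray, se, config: FitConfig) -> float:
    mode = config.loss
    if mode == "auto":
        mode = "wls" if (se is not None and np.all(se > 0)) else "lin"
    if mode == "lin":
        return float(np.sum((model - density) ** 2))
    if mode == "wls":
        if se is None or np.any(se <= 0):
            raise ValueError("wls loss requires positive standard errors")
        return float(np.sum(((model - density) / se) ** 2))
    if mode == "log":
        f = config.log_floor
        return float(np.sum((np.log(model + f) - np.log(density + f)) ** 2))
    raise ValueError(f"unknown loss {config.loss!r}")


def _dataset_objective(dG: float, A0: float, prep, config: FitConfig):
    n, density, se, ctot, nmax = prep
    params = AggregationParams(dG, A0, config.alpha)
    cmon = solve_monomer_from_total(params, ctot, nmax)
    model = nmer_density(params, cmon, n)
    return _loss(model, density, se, config), cmon, model


def _profile_A0(dG: float, prep, config: FitConfig):
    """Best A0 (and its loss/cmon) for this dataset at fixed dG."""
    lo, hi = np.log10(config.A0_bounds)

    def obj(u):
        return _dataset_objective(dG, 10.0**u, prep, config)[0]

    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    A0 = float(10.0 ** res.x)
    loss, cmon, model = _dataset_objective(dG, A0, prep, config)
    return A0, loss, cmon, model


def fit_global(dists: list[SizeDistribution], config: FitConfig | None = None) -> FitResult:
    """Fit one shared dG_bulk across datasets, profiling each dataset's A0
    under its own mass constraint; the objective is the summed loss."""
    config = config or FitConfig()
    if not dists:
        raise ValueError("no datasets")
    preps = []
    for dist in dists:
        prep = _prepare(dist, config)
        if np.count_nonzero(prep[1]) < 3:
            raise UnderdeterminedError(
                "need at least 3 occupied size bins to fit (dG_bulk, A0)"
            )
        preps.append(prep)

    def objective(dG: float) -> float:
        return sum(_profile_A0(dG, p, config)[1] for p in preps)

    lo, hi = config.dG_bounds
    grid = np.linspace(lo, hi, config.n_grid)
    vals = np.array([objective(g) for g in grid])
    k = int(np.argmin(vals))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(objective, bounds=(blo, bhi), method="bounded",
                          options={"xatol": 1e-6})
    dG = float(res.x) if res.fun <= vals[k] else float(grid[k])
    converged = bool(res.success) or res.fun > vals[k]
    if min(abs(dG - lo), abs(dG - hi)) < 1e-5:
        warnings.warn("fitted dG_bulk at bound; fit flagged as not converged")
        converged = False

    A0s, cmons, residuals, total_loss = [], [], [], 0.0
    for prep in preps:
        A0, loss, cmon, model = _profile_A0(dG, prep, config)
        A0s.append(A0)
        cmons.append(cmon)
        residuals.append(model - prep[1])
        total_loss += loss

    result = FitResult(
        dG_bulk=dG,
        A0_per_dataset=A0s,
        cmon_per_dataset=cmons,
        ctot_per_dataset=[p[3] for p in preps],
        nmax_per_dataset=[p[4] for p in preps],
        objective=total_loss,
        residuals=residuals,
        converged=converged,
        alpha=config.alpha,
        meta={"loss": config.loss, "n_datasets": len(dists)},
    )
    if config.n_bootstrap > 0:
        result.bootstrap_dG = _bootstrap_dG(dists, config)
        result.dG_ci = (
            float(np.percentile(result.bootstrap_dG, 2.5)),
            float(np.percentile(result.bootstrap_dG, 97.5)),
        )
    return result


def fit_single(dist: SizeDistribution, config: FitConfig | None = None) -> FitResult:
    """Fit (dG_bulk, A0) to one measured distribution under its mass constraint."""
    return fit_global([dist], config)


def _bootstrap_dG(dists: list[SizeDistribution], config: FitConfig) -> np.ndarray:
    """Nonparametric bootstrap over clusters: resample each dataset's cluster
    counts (multinomial over sizes, total cluster count fixed) and refit."""
    rng = np.random.default_rng(config.seed)
    refit_cfg = FitConfig(**{**config.__dict__, "n_bootstrap": 0})
    out = []
    for _ in range(config.n_bootstrap):
        resampled = []
        for dist in dists:
            if dist.counts is None or dist.area is None:
                raise ValueError("bootstrap requires counts and area")
            total = int(round(dist.counts.sum()))
            p = dist.counts / dist.counts.sum()
            counts = rng.multinomial(total, p).astype(float)
            se = (
                np.sqrt(np.maximum(counts, 1.0)) / dist.area
                if dist.se is not None
                else None
            )
            d = SizeDistribution(
                n=dist.n, density=counts / dist.area, counts=counts, se=se,
                area=dist.area,
            )
            d.ctot = d.total()
            resampled.append(d)
        try:
            out.append(fit_global(resampled, refit_cfg).dG_bulk)
        except (ValueError, UnderdeterminedError):  # degenerate resample
            continue
    return np.asarray(out)


def fit_shared_A0(
    dists: list[SizeDistribution],
    dG_bulk: float,
    config: FitConfig | None = None,
    n_match: int = 6,
) -> float:
    """Refit with dG_bulk fixed and a single A0 shared across all datasets,
    matching only the small-cluster densities n = 1..n_match; each dataset's
    cmon is still resolved from its own ctot at its full fitting nmax."""
    config = config or FitConfig()
    preps = [_prepare(d, config) for d in dists]

    def obj(u: float) -> float:
        A0 = 10.0**u
        total = 0.0
        for n, density, se, ctot, nmax in preps:
            params = AggregationParams(dG_bulk, A0, config.alpha)
            cmon = solve_monomer_from_total(params, ctot, nmax)
            m = min(n_match, len(n))
            model = nmer_density(params, cmon, n[:m])
            total += _loss(model, density[:m], None if se is None else se[:m], config)
        return total

    lo, hi = np.log10(config.A0_bounds)
    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    return float(10.0**res.x)


def predict_curve(result: FitResult, dataset_index: int, nmax: int) -> SizeDistribution:
    """Model densities n = 1..nmax at the fitted parameters for one dataset."""
    if not 0 <= dataset_index < len(result.A0_per_dataset):
        raise IndexError(f"dataset index {dataset_index} out of range")
    params = AggregationParams(
        result.dG_bulk, result.A0_per_dataset[dataset_index], result.alpha
    )
    n = np.arange(1, nmax + 1)
    density = nmer_density(params, result.cmon_per_dataset[dataset_index], n)
    dist = SizeDistribution(n=n, density=density)
    dist.ctot = dist.total()
    return dist
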