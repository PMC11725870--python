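"""Closed-form reversible-aggregation theory for 2D membrane-protein clusters.

Small clusters ("higher-order transient structures", HOTS) of a single
membrane-protein species are modeled as nmers in reversible equilibrium with
monomers on a two-dimensional surface.  The model has two parameters: the
cohesion free energy ``dG_bulk`` (standard free energy, in RT units, of
transferring one monomer into an infinite close-packed "bulk phase" sheet;
negative means cohesive) and the configurational unit area ``A0`` (μm²),
which sets the standard-state concentration ``1/A0`` of the oligomerization
reaction.  An nmer pays a boundary energy proportional to the number of
proteins on its perimeter, taken as ``n**alpha`` with ``alpha = 0.5`` for
compact two-dimensional clusters, giving the nmer density

    c_n = A0**-1 * (A0 * c_mon)**n * exp((n**alpha - n) * dG_bulk)

with all densities in μm⁻² and energies in RT.  A critical monomer
concentration ``c_mon_crit = exp(dG_bulk)/A0`` marks saturation: above the
corresponding (finite, for dG_bulk < 0 and alpha > 0) critical total
concentration, excess protein partitions into the bulk phase while the HOTS
distribution stays pinned at its critical form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "ParameterError",
    "DivergenceError",
    "BracketingError",
    "AggregationParams",
    "SizeDistribution",
    "nmer_density",
    "critical_monomer_concentration",
    "critical_distribution",
    "critical_total_concentration",
    "delta_g_nmer",
    "total_concentration",
    "solve_monomer_from_total",
]


class ParameterError(ValueError):
    """Invalid model parameter (e.g. nonpositive A0)."""


class DivergenceError(ValueError):
    """The critical series does not converge: no finite critical total concentration."""


class BracketingError(RuntimeError):
    """Root bracketing failed in the mass-constraint solve."""


@dataclass(frozen=True)
class AggregationParams:
    """Parameters of the reversible-aggregation model.

    Parameters
    ----------
    dG_bulk : float
        Monomer-to-bulk transfer free energy in RT units (dimensionless).
        Negative values are cohesive.
    A0 : float
        Configurational unit area in μm²; ``1/A0`` is the standard-state
        concentration of the oligomerization reaction.
    alpha : float, default 0.5
        Boundary-energy exponent: an nmer's bonding deficit relative to bulk
        scales as ``n**alpha``.  ``0.5`` is the compact two-dimensional
        cluster case; ``0`` is the linear-aggregate (polymer chain) variant
        whose boundary energy is independent of n and which therefore has no
        phase transition.
    """

    dG_bulk: float
    A0: float
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A0) and self.A0 > 0):
            raise ParameterError(f"A0 must be positive and finite, got {self.A0}")
        if not math.isfinite(self.dG_bulk):
            raise ParameterError(f"dG_bulk must be finite, got {self.dG_bulk}")
        if not (0.0 <= self.alpha < 1.0):
            raise ParameterError(
                f"boundary exponent alpha must lie in [0, 1), got {self.alpha}"
            )

    @property
    def phase_transition_capable(self) -> bool:
        """True if the model supports a 2D phase transition (finite critical
        total concentration): cohesive (dG_bulk < 0) with a size-dependent
        boundary energy (alpha > 0).  The alpha = 0 linear-aggregate variant
        is flagged non-critical."""
        return self.dG_bulk < 0 and self.alpha > 0


@dataclass
class SizeDistribution:
    """Per-size cluster densities over a membrane area.

    ``n`` are positive cluster sizes (ascending), ``density`` the density of
    clusters of each size in μm⁻².  ``counts`` (raw cluster counts) and ``se``
    (per-size standard errors, μm⁻²) are optional, as are the membrane
    ``area`` (μm²) and the declared total protein density ``ctot``
    (μm⁻², equal to Σ n·density).
    """

    n: np.ndarray
    density: np.ndarray
    counts: np.ndarray | None = None
    se: np.ndarray | None = None
    area: float | None = None
    ctot: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.density = np.asarray(self.density, dtype=float)
        if self.n.ndim != 1 or self.n.shape != self.density.shape:
            raise ValueError("n and density must be 1D arrays of equal length")
        if self.n.size and (np.any(self.n < 1) or np.any(np.diff(self.n) <= 0)):
            raise ValueError("cluster sizes must be positive and strictly increasing")
        if np.any(self.density < -1e-12):
            raise ValueError("densities must be nonnegative")
        self.density = np.clip(self.density, 0.0, None)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative")
            if self.area is not None and self.counts.size:
                expected = self.counts / self.area
                if not np.allclose(self.density, expected, rtol=1e-9, atol=1e-12):
                    raise ValueError("density must equal counts/area when both are given")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        if self.ctot is not None:
            total = self.total()
            if total > 0 and abs(self.ctot - total) > 1e-9 * max(total, 1e-300):
                raise ValueError(
                    f"declared ctot={self.ctot} inconsistent with sum n*density={total}"
                )

    def total(self) -> float:
        """Total protein density Σ n·density (μm⁻²)."""
        return float(np.sum(self.n * self.density))

    @property
    def nmax(self) -> int:
        return int(self.n[-1]) if self.n.size else 0

    @classmethod
    def from_sizes(cls, sizes: Sequence[int], area: float, **kw) -> "SizeDistribution":
        """Build from a list of observed cluster sizes over ``area`` μm²."""
        sizes = np.asarray(sizes, dtype=int)
        if sizes.size == 0:
            return cls(n=np.array([], dtype=int), density=np.array([]), area=area, **kw)
        nmax = int(sizes.max())
        counts = np.bincount(sizes, minlength=nmax + 1)[1:]
        n = np.arange(1, nmax + 1)
        dist = cls(n=n, density=counts / area, counts=counts, area=area, **kw)
        dist.ctot = dist.total()
        return dist

    def padded(self, nmax: int) -> "SizeDistribution":
        """Return a copy covering n = 1..nmax, zero-filling missing sizes."""
        n = np.arange(1, nmax + 1)
        density = np.zeros(nmax)
        idx = self.n[self.n <= nmax] - 1
        density[idx] = self.density[self.n <= nmax]
        counts = se = None
        if self.counts is not None:
            counts = np.zeros(nmax)
            counts[idx] = self.counts[self.n <= nmax]
        if self.se is not None:
            se = np.zeros(nmax)
            se[idx] = self.se[self.n <= nmax]
        return SizeDistribution(
            n=n, density=density, counts=counts, se=se, area=self.area,
            ctot=None, meta=dict(self.meta),
        )


def nmer_density(
    params: AggregationParams, cmon: float, n: int | np.ndarray
) -> float | np.ndarray:
    """Density (μm⁻²) of clusters of size n at monomer density ``cmon``.

    Evaluates ``A0**-1 (A0*cmon)**n exp((n**alpha - n) dG_bulk)``; for n = 1
    this returns ``cmon`` exactly.
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("cluster size n must be >= 1")
    if cmon < 0:
        raise ValueError("cmon must be nonnegative")
    if cmon == 0.0:
        out = np.zeros_like(n_arr)
        return float(out) if np.isscalar(n) else out
    # log-space evaluation: stable for large n where (A0*cmon)**n under/overflows
    log_c = (
        -math.log(params.A0)
        + n_arr * math.log(params.A0 * cmon)
        + (n_arr**params.alpha - n_arr) * params.dG_bulk
    )
    out = np.exp(log_c)
    return float(out) if np.isscalar(n) else out


def critical_monomer_concentration(params: AggregationParams) -> float:
    """Monomer density (μm⁻²) at equilibrium with bulk phase: exp(dG_bulk)/A0."""
    return math.exp(params.dG_bulk) / params.A0


def delta_g_nmer(params: AggregationParams, n: int | np.ndarray) -> float | np.ndarray:
    """Standard free energy (RT) of n monomers forming one nmer:
    (n - n**alpha)·dG_bulk; zero at n = 1."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("cluster size n must be >= 1")
    out = (n_arr - n_arr**params.alpha) * params.dG_bulk
    return float(out) if np.isscalar(n) else out


def critical_distribution(params: AggregationParams, nmax: int) -> SizeDistribution:
    """HOTS size distribution at saturation (cmon = cmon_crit):
    density[n] = A0**-1 exp(n**alpha · dG_bulk)."""
    if nmax < 1:
        raise ValueError("nmax must be >= 1")
    n = np.arange(1, nmax + 1)
    density = np.exp(n.astype(float) ** params.alpha * params.dG_bulk) / params.A0
    return SizeDistribution(n=n, density=density)


def _critical_term_log(params: AggregationParams, n: np.ndarray) -> np.ndarray:
    return np.log(n) + n**params.alpha * params.dG_bulk - math.log(params.A0)


def critical_total_concentration(
    params: AggregationParams, rel_tol: float = 1e-9
) -> float:
    """Total protein density (μm⁻²) held by the critical HOTS distribution:
    A0**-1 Σ_{n>=1} n·exp(n**alpha · dG_bulk).

    Converges only for cohesive parameters (dG_bulk < 0) with a
    size-dependent boundary energy (alpha > 0).  The series is summed in
    blocks until an integral tail bound falls below ``rel_tol`` of the
    partial sum.
    """
    if not params.phase_transition_capable:
        raise DivergenceError(
            "no finite critical total concentration: requires dG_bulk < 0 and "
            "alpha > 0 (linear aggregates have no phase transition)"
        )
    g, a = params.dG_bulk, params.alpha
    total = 0.0
    start = 1
    block = 4096
    while True:
        n = np.arange(start, start + block, dtype=float)
        total += float(np.sum(np.exp(_critical_term_log(params, n))))
        start += block
        # x*exp(g*x^a) is decreasing once x^a > 1/(a*|g|); only then does the
        # integral from N bound the remaining sum.
        n_dec = (1.0 / (a * abs(g))) ** (1.0 / a)
        if start > n_dec:
            tail, _ = quad(
                lambda x: x * math.exp(g * x**a) / params.A0,
                start - 1,
                np.inf,
                limit=200,
            )
            if tail <= rel_tol * total:
                return total
        if start > 10**8:  # pragma: no cover - safety valve
            raise DivergenceError("critical series failed to converge numerically")


def total_concentration(dist: SizeDistribution) -> float:
    """Total protein density Σ n·density[n] (μm⁻²)."""
    return dist.total()


def _total_at(params: AggregationParams, cmon: float, nmax: int) -> float:
    """Σ_{n=1..nmax} n·c_n(cmon), evaluated stably in log space."""
    if cmon == 0.0:
        return 0.0
    n = np.arange(1, nmax + 1, dtype=float)
    log_terms = (
        np.log(n)
        - math.log(params.A0)
        + n * math.log(params.A0 * cmon)
        + (n**params.alpha - n) * params.dG_bulk
    )
    val = logsumexp(log_terms)
    if val > 690:  # exp would overflow; return a large finite sentinel
        return 1e300
    return float(np.exp(val))


def solve_monomer_from_total(
    params: AggregationParams, ctot: float, nmax: int, rtol: float = 1e-12
) -> float:
    """Invert the mass constraint: find cmon with Σ_{n<=nmax} n·c_n = ctot.

    Σ n·c_n is strictly increasing in cmon and bounded below by its n = 1
    term, so the root is unique and lies in (0, ctot].
    """
    if ctot <= 0:
        raise ValueError("ctot must be positive")
    if nmax < 1:
        raise ValueError("nmax must be >= 1")
    f = lambda c: _total_at(params, c, nmax) - ctot
    hi = ctot
    if f(hi) < 0:  # pragma: no cover - total(c) >= c makes this unreachable
        raise BracketingError(
            f"ctot={ctot} not attainable below bracket; maximum attainable "
            f"total at cmon={hi} is {_total_at(params, hi, nmax)}"
        )
    return float(brentq(f, 0.0, hi, rtol=rtol, maxiter=200))
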