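"""Synthetic point patterns and distribution tables with known ground truth.

Emulates immunogold-style data from membrane sheets: cluster-size counts are
drawn per size as independent Poissons (clusters are independent of, but in
equilibrium with, each other in the grand-canonical picture), cluster
centroids are placed uniformly (CSR) in the membrane region, and each
size-n cluster is laid out as a compact hexagonal packing with
nearest-neighbor spacing ``packing_distance`` (default 5.2 nm, the scale of
a closely packed GPCR cluster).  An observation model composes binomial
thinning (labeling efficiency) with a uniform nonspecific background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from . import spatial
from .attractor import AttractorParams, attractor_distribution
from .spatial import PointPattern, rectangle_region
from .theory import (
    AggregationParams,
    SizeDistribution,
    critical_total_concentration,
    nmer_density,
    solve_monomer_from_total,
)

__all__ = [
    "SynthConfig",
    "SupercriticalError",
    "sample_sizes",
    "place_clusters",
    "apply_observation_model",
    "make_distribution_panel",
    "generate_pattern",
]


class SupercriticalError(ValueError):
    """Requested total density exceeds the model's critical total concentration."""


def _default_region() -> Polygon:
    return rectangle_region(50_000.0, 50_000.0)  # 50 × 50 μm


@dataclass
class SynthConfig:
    model: str = "hots"                      # 'hots' | 'attractor' | 'monomers'
    params: AggregationParams | AttractorParams | None = None
    ctot: float = 4.0                        # μm⁻²
    region: Polygon = field(default_factory=_default_region)
    packing_distance: float = 5.2            # nm
    packing_jitter: float = 0.4              # nm (sd of isotropic jitter)
    labeling_efficiency: float = 1.0
    background_density: float = 0.0          # μm⁻²
    seed: int = 0
    nmax: int = 400

    def __post_init__(self) -> None:
        if self.ctot < 0:
            raise ValueError("ctot must be nonnegative")
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling efficiency must be in (0, 1]")
        if self.packing_distance <= 0:
            raise ValueError("packing distance must be positive")
        if self.model not in ("hots", "attractor", "monomers"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def area_um2(self) -> float:
        return self.region.area / spatial.NM2_PER_UM2


def model_distribution(config: SynthConfig) -> SizeDistribution:
    """Exact per-size cluster densities implied by the configured model."""
    n = np.arange(1, config.nmax + 1)
    if config.model == "monomers":
        return SizeDistribution(n=np.array([1]), density=np.array([config.ctot]))
    if config.model == "attractor":
        if not isinstance(config.params, AttractorParams):
            raise TypeError("attractor model requires AttractorParams")
        return attractor_distribution(config.params, config.ctot, config.nmax)
    params = config.params
    if not isinstance(params, AggregationParams):
        raise TypeError("hots model requires AggregationParams")
    if params.dG_bulk >= 0:
        raise ValueError("hots sampling requires cohesive parameters (dG_bulk < 0)")
    if params.phase_transition_capable:
        ctot_crit = critical_total_concentration(params)
        if config.ctot > ctot_crit * (1 + 1e-9):
            raise SupercriticalError(
                f"ctot={config.ctot} μm⁻² exceeds the critical total "
                f"concentration {ctot_crit:.6g} μm⁻² for these parameters"
            )
    cmon = solve_monomer_from_total(params, config.ctot, config.nmax)
    return SizeDistribution(n=n, density=nmer_density(params, cmon, n))


def sample_sizes(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluster sizes drawn as independent Poisson counts per size with mean
    density[n]·area; expected Σ n·counts / area equals ctot."""
    dist = model_distribution(config)
    mean_counts = dist.density * config.area_um2
    counts = rng.poisson(mean_counts)
    return np.repeat(dist.n, counts)


def _hex_layout(size: int, spacing: float) -> np.ndarray:
    """First ``size`` sites of a hexagonal spiral (center, then rings),
    centered on its centroid; nearest-neighbor spacing = ``spacing``."""
    pts = [(0.0, 0.0)]
    ring = 1
    while len(pts) < size:
        # walk the ring: start at axial (ring, 0), take 6 sides of length ring
        q, r = ring, 0
        steps = [(-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)]
        for dq, dr in steps:
            for _ in range(ring):
                x = spacing * (q + r / 2.0)
                y = spacing * (math.sqrt(3) / 2.0) * r
                pts.append((x, y))
                q, r = q + dq, r + dr
        ring += 1
    out = np.asarray(pts[:size])
    return out - out.mean(axis=0)


def place_clusters(
    sizes: np.ndarray, config: SynthConfig, rng: np.random.Generator
) -> PointPattern:
    """CSR centroids; each size-n cluster is a randomly rotated, jittered
    hexagonal packing.  Placement is rejected and retried until every point
    of the cluster lies inside the region."""
    coords = []
    labels = []
    region = config.region
    for ci, s in enumerate(np.asarray(sizes, dtype=int)):
        layout = _hex_layout(int(s), config.packing_distance)
        for _ in range(1000):
            theta = rng.uniform(0, 2 * math.pi)
            c, sn = math.cos(theta), math.sin(theta)
            rot = layout @ np.array([[c, sn], [-sn, c]])
            jitter = rng.normal(0.0, config.packing_jitter, rot.shape)
            centroid = spatial._uniform_in_polygon(region, 1, rng)[0]
            pts = rot + jitter + centroid
            if np.all(shapely.intersects_xy(region, pts[:, 0], pts[:, 1])):
                coords.append(pts)
                labels.extend([ci] * int(s))
                break
        else:
            raise ValueError("region too small to place a cluster after 1000 tries")
    points = np.vstack(coords) if coords else np.zeros((0, 2))
    return PointPattern(
        points=points,
        region=region,
        channel=np.array(["signal"] * len(points)),
        meta={"seed": config.seed, "model": config.model},
    )


def apply_observation_model(
    pattern: PointPattern,
    config: SynthConfig,
    rng: np.random.Generator,
    blind: bool = False,
) -> PointPattern:
    """Binomial thinning at the labeling efficiency, then superposition of a
    uniform nonspecific background at ``background_density`` (μm⁻²).
    Channels annotate signal vs background unless ``blind``."""
    thinned = (
        spatial.thin_labels(pattern, config.labeling_efficiency, rng)
        if config.labeling_efficiency < 1.0
        else pattern
    )
    pts = thinned.points
    channel = (
        thinned.channel
        if thinned.channel is not None
        else np.array(["signal"] * len(pts))
    )
    if config.background_density > 0:
        n_bg = rng.poisson(config.background_density * config.area_um2)
        bg = spatial._uniform_in_polygon(config.region, n_bg, rng)
        pts = np.vstack([pts, bg])
        channel = np.concatenate([channel, np.array(["background"] * n_bg)])
    return PointPattern(
        points=pts,
        region=pattern.region,
        channel=None if blind else channel,
        meta={**pattern.meta, "labeling_efficiency": config.labeling_efficiency,
              "background_density": config.background_density},
    )


def generate_pattern(
    config: SynthConfig, rng: np.random.Generator | None = None, blind: bool = False
) -> PointPattern:
    """sample_sizes → place_clusters → apply_observation_model."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sizes = sample_sizes(config, rng)
    pattern = place_clusters(sizes, config, rng)
    return apply_observation_model(pattern, config, rng, blind=blind)


def make_distribution_panel(
    dG: float,
    ctots: list[float],
    area: float,
    rng: np.random.Generator,
    A0: float = 0.08,
    alpha: float = 0.5,
    nmax: int = 400,
) -> list[SizeDistribution]:
    """Noisy (Poisson-count) cluster-size tables sharing one cohesion energy
    at several total densities, emulating an expression-series panel."""
    params = AggregationParams(dG, A0, alpha)
    panel = []
    for ctot in ctots:
        cfg = SynthConfig(model="hots", params=params, ctot=ctot,
                          region=rectangle_region(1.0, 1.0), nmax=nmax)
        # region is irrelevant here; counts are drawn directly on `area`
        exact = model_distribution(cfg)
        counts = rng.poisson(exact.density * area).astype(float)
        occupied = np.nonzero(counts)[0]
        nmax_obs = int(occupied[-1]) + 1 if occupied.size else 1
        n = np.arange(1, nmax_obs + 1)
        c = counts[:nmax_obs]
        dist = SizeDistribution(
            n=n, density=c / area, counts=c,
            se=np.sqrt(np.maximum(c, 1.0)) / area, area=area,
        )
        dist.ctot = dist.total()
        dist.meta.update({"true_dG": dG, "true_A0": A0, "requested_ctot": ctot})
        panel.append(dist)
    return panel
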