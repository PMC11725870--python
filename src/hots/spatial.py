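"""Point-pattern analytics for labeled proteins on membrane sheets.

Coordinates are in nm, membrane areas in μm², densities in μm⁻².  Clusters
are single-linkage connected components under a distance cutoff (a
configurable stand-in for the label-dependent linking rule used with
immunogold data; all outputs record the cutoff).  Downstream statistics:
cluster-size distributions with background subtraction, centroid
nearest-neighbor distances against a complete-spatial-randomness (CSR)
null, within-window pairwise-distance histograms with a Gaussian peak fit,
and binomial thinning to model sub-unity labeling efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.optimize import curve_fit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box

from .theory import SizeDistribution

__all__ = [
    "PointPattern",
    "ClusterSet",
    "Histogram",
    "PeakFit",
    "NoPeakError",
    "link_clusters",
    "size_distribution",
    "subtract_background",
    "nnd_centroids",
    "csr_null",
    "pairwise_distance_histogram",
    "fit_gaussian_peak",
    "thin_labels",
]

NM2_PER_UM2 = 1e6


class NoPeakError(ValueError):
    """Histogram has no interior maximum to fit."""


@dataclass
class PointPattern:
    """Labeled point coordinates (nm) inside a membrane-region polygon."""

    points: np.ndarray                     # (N, 2) nm
    region: Polygon                        # nm coordinates
    channel: np.ndarray | None = None      # label identity per point
    precision: np.ndarray | None = None    # localization precision, nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if self.region.area <= 0:
            raise ValueError("region must have positive area")
        if self.channel is not None:
            self.channel = np.asarray(self.channel)
        if self.precision is not None:
            self.precision = np.asarray(self.precision, dtype=float)
        if self.points.shape[0]:
            # boundary points count as inside (even-odd rule + boundary)
            inside = shapely.intersects_xy(self.region, self.points[:, 0], self.points[:, 1])
            if not np.all(inside):
                bad = int(np.count_nonzero(~inside))
                raise ValueError(f"{bad} point(s) fall outside the region polygon")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def area_um2(self) -> float:
        return self.region.area / NM2_PER_UM2


@dataclass
class ClusterSet:
    """Exhaustive disjoint partition of point indices into clusters."""

    labels: np.ndarray       # cluster id per point, 0..K-1
    sizes: np.ndarray        # per-cluster point counts
    centroids: np.ndarray    # (K, 2) mean coordinates, nm
    cutoff: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.sizes.size

    @property
    def n_points(self) -> int:
        return int(self.sizes.sum())


def link_clusters(pattern: PointPattern, cutoff: float) -> ClusterSet:
    """Single-linkage clustering: connected components of the graph joining
    point pairs at Euclidean distance <= cutoff (ties link)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pts = pattern.points
    n = pts.shape[0]
    if n == 0:
        return ClusterSet(
            labels=np.array([], dtype=int),
            sizes=np.array([], dtype=int),
            centroids=np.zeros((0, 2)),
            cutoff=cutoff,
        )
    pairs = cKDTree(pts).query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    # relabel in order of first appearance for determinism
    _, labels = np.unique(labels, return_inverse=True)
    k = labels.max() + 1
    sizes = np.bincount(labels, minlength=k)
    cx = np.bincount(labels, weights=pts[:, 0], minlength=k) / sizes
    cy = np.bincount(labels, weights=pts[:, 1], minlength=k) / sizes
    return ClusterSet(
        labels=labels, sizes=sizes, centroids=np.column_stack([cx, cy]), cutoff=cutoff
    )


def size_distribution(clusters: ClusterSet, area_um2: float) -> SizeDistribution:
    """Cluster-size distribution in μm⁻²: density[n] = (#size-n clusters)/area."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    dist = SizeDistribution.from_sizes(clusters.sizes, area_um2)
    if clusters.cutoff is not None:
        dist.meta["cutoff_nm"] = clusters.cutoff
    return dist


def subtract_background(
    dist: SizeDistribution, background: SizeDistribution
) -> SizeDistribution:
    """Per-size density subtraction (both μm⁻²), clamped at zero; bins where
    the background exceeded the signal are recorded in meta['clamped_n']."""
    nmax = max(dist.nmax, background.nmax)
    a = dist.padded(nmax)
    b = background.padded(nmax)
    diff = a.density - b.density
    clamped = a.n[diff < 0]
    if clamped.size:
        warnings.warn(
            f"background exceeds signal in {clamped.size} bin(s); clamped to 0"
        )
    out = SizeDistribution(n=a.n, density=np.clip(diff, 0.0, None), area=dist.area)
    out.ctot = out.total()
    out.meta = dict(dist.meta)
    out.meta["clamped_n"] = clamped.tolist()
    return out


def nnd_centroids(clusters: ClusterSet, min_size: int = 3) -> np.ndarray:
    """Nearest-neighbor distances (nm) between centroids of clusters with at
    least ``min_size`` points."""
    cent = clusters.centroids[clusters.sizes >= min_size]
    if cent.shape[0] < 2:
        warnings.warn("fewer than 2 qualifying clusters; no distances")
        return np.array([])
    d, _ = cKDTree(cent).query(cent, k=2)
    return d[:, 1]


def _uniform_in_polygon(region: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = region.bounds
    out = np.empty((0, 2))
    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 16)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        keep = shapely.intersects_xy(region, x, y)
        out = np.vstack([out, np.column_stack([x, y])[keep]])
    return out[:n]


def csr_null(
    region: Polygon, n_clusters: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Pooled nearest-neighbor distances from ``n_reps`` independent uniform
    (CSR) placements of ``n_clusters`` points in the region."""
    if region.area <= 0:
        raise ValueError("degenerate polygon")
    if n_clusters < 2:
        raise ValueError("need at least 2 points per replicate")
    out = []
    for _ in range(n_reps):
        pts = _uniform_in_polygon(region, n_clusters, rng)
        d, _ = cKDTree(pts).query(pts, k=2)
        out.append(d[:, 1])
    return np.concatenate(out)


@dataclass
class Histogram:
    edges: np.ndarray
    counts: np.ndarray
    distances: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def pairwise_distance_histogram(
    pattern: PointPattern,
    max_distance: float,
    precision_filter: float | None = None,
    bin_width: float = 0.5,
) -> Histogram:
    """Histogram of all pairwise distances <= max_distance (nm), optionally
    restricted to points with localization precision <= precision_filter."""
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    pts = pattern.points
    if precision_filter is not None:
        if pattern.precision is None:
            raise ValueError("pattern has no precision column to filter on")
        pts = pts[pattern.precision <= precision_filter]
    if pts.shape[0] >= 2:
        pairs = cKDTree(pts).query_pairs(r=max_distance, output_type="ndarray")
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1) if pairs.size else np.array([])
    else:
        d = np.array([])
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return Histogram(edges=edges, counts=counts, distances=d)


@dataclass
class PeakFit:
    mean: float
    sd: float
    amplitude: float
    secondary_peak: bool = False


def fit_gaussian_peak(hist: Histogram) -> PeakFit:
    """Least-squares single-Gaussian fit around the histogram's main peak.

    Raises NoPeakError for monotone histograms (maximum at the first bin with
    no interior mode).  If another local maximum of comparable height lies
    outside the fitted window, the result is flagged (``secondary_peak``).
    """
    counts = hist.counts.astype(float)
    centers = hist.centers
    if counts.size < 4 or np.all(counts == 0):
        raise NoPeakError("histogram too small or empty")
    k = int(np.argmax(counts))
    if k == 0 or k == counts.size - 1:
        raise NoPeakError("no interior maximum; histogram is monotone at its peak")
    # fitting window: expand from the peak while counts stay above half max
    half = counts[k] / 2.0
    lo = k
    while lo > 0 and counts[lo - 1] >= half:
        lo -= 1
    hi = k
    while hi < counts.size - 1 and counts[hi + 1] >= half:
        hi += 1
    lo = max(0, lo - 2)
    hi = min(counts.size - 1, hi + 2)
    x, y = centers[lo : hi + 1], counts[lo : hi + 1]

    def gauss(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    sd0 = max((centers[hi] - centers[lo]) / 4.0, (centers[1] - centers[0]) / 2.0)
    popt, _ = curve_fit(
        gauss, x, y, p0=[counts[k], centers[k], sd0],
        bounds=([0, centers[lo], 1e-6], [np.inf, centers[hi], np.inf]),
        maxfev=10000,
    )
    # secondary-peak flag: local maxima outside the window above half the main peak
    secondary = False
    for j in range(1, counts.size - 1):
        if (lo <= j <= hi):
            continue
        if counts[j] >= half and counts[j] >= counts[j - 1] and counts[j] >= counts[j + 1]:
            secondary = True
            break
    return PeakFit(mean=float(popt[1]), sd=float(abs(popt[2])),
                   amplitude=float(popt[0]), secondary_peak=secondary)


def thin_labels(
    pattern: PointPattern, efficiency: float, rng: np.random.Generator
) -> PointPattern:
    """Independent binomial thinning: each point kept with probability
    ``efficiency`` (models sub-unity labeling efficiency)."""
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    keep = rng.random(pattern.n_points) < efficiency
    return PointPattern(
        points=pattern.points[keep],
        region=pattern.region,
        channel=None if pattern.channel is None else pattern.channel[keep],
        precision=None if pattern.precision is None else pattern.precision[keep],
        meta={**pattern.meta, "labeling_efficiency": efficiency},
    )


def rectangle_region(width_nm: float, height_nm: float) -> Polygon:
    """Convenience axis-aligned rectangular membrane region (nm)."""
    return box(0.0, 0.0, width_nm, height_nm)
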