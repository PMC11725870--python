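"""Toy lattice Monte Carlo of self-binding diffusing particles.

Excluded-volume random walkers on a square grid: per sweep, each particle
(visited in random order) draws one of {stay, up, down, left, right} with
weights {w, 1, 1, 1, 1}, where w = ``pwait_bound`` if the particle has at
least one occupied 4-neighbor and ``pwait_free`` otherwise.  A drawn move
into an occupied or out-of-bounds site becomes a stay.  Reversible
self-binding (pwait_bound > pwait_free) produces emergent transient
clusters; 4-connected components of occupied sites are binned into
cluster-size histograms.  The grid maps to physical units through ``rpg``
(μm per grid unit; default 0.1, so unit site area is 0.01 μm²) and,
optionally, a diffusion coefficient D giving a time per sweep of rpg²/4D.

This is an illustrative kinetic toy, not a Boltzmann lattice gas: waiting
weights are not derived from an nmer energy function.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .theory import SizeDistribution

__all__ = [
    "LatticeConfig",
    "LatticeState",
    "initial_state",
    "step",
    "run",
    "extract_clusters",
    "cluster_size_distribution",
    "density_sweep",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class LatticeConfig:
    width: int = 100
    height: int = 100
    n_particles: int = 200
    pwait_bound: float = 50.0    # stay weight with >=1 occupied 4-neighbor
    pwait_free: float = 1.0      # stay weight with no occupied neighbor
    rpg: float = 0.1             # μm per grid unit
    D: float | None = None       # μm²/s, for optional time mapping
    seed: int = 0
    boundary: str = "reflecting"  # or "periodic"

    def __post_init__(self) -> None:
        if self.n_particles > self.width * self.height:
            raise ValueError("more particles than grid sites")
        if self.pwait_bound < 1 or self.pwait_free < 1:
            raise ValueError("waiting weights must be >= 1")
        if self.rpg <= 0:
            raise ValueError("rpg must be positive")
        if self.boundary not in ("reflecting", "periodic"):
            raise ValueError("boundary must be 'reflecting' or 'periodic'")

    @property
    def area_um2(self) -> float:
        return self.width * self.height * self.rpg**2

    @property
    def time_per_sweep(self) -> float | None:
        return None if self.D is None else self.rpg**2 / (4.0 * self.D)


@dataclass
class LatticeState:
    """Particle positions (rows, cols) on the grid; exclusion holds: no two
    particles share a site and the particle count is constant."""

    rows: np.ndarray
    cols: np.ndarray
    step_index: int = 0
    meta: dict = field(default_factory=dict)

    def occupancy(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))

    def grid(self, config: LatticeConfig) -> np.ndarray:
        g = np.zeros((config.height, config.width), dtype=bool)
        g[self.rows, self.cols] = True
        return g


def initial_state(config: LatticeConfig, rng: random.Random) -> LatticeState:
    """Uniformly random distinct sites."""
    sites = rng.sample(range(config.width * config.height), config.n_particles)
    sites = np.asarray(sites)
    return LatticeState(rows=sites // config.width, cols=sites % config.width)


def _sweep(rows, cols, occ, config: LatticeConfig, rng: random.Random) -> None:
    """One Monte-Carlo sweep, in place.  rows/cols are Python lists, occ a
    set of (row, col) tuples."""
    W, H = config.width, config.height
    wb, wf = config.pwait_bound, config.pwait_free
    periodic = config.boundary == "periodic"
    order = list(range(len(rows)))
    rng.shuffle(order)
    for i in order:
        r, c = rows[i], cols[i]
        if periodic:
            up, dn = ((r - 1) % H, c), ((r + 1) % H, c)
            lf, rt = (r, (c - 1) % W), (r, (c + 1) % W)
        else:
            up, dn, lf, rt = (r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)
        bound = up in occ or dn in occ or lf in occ or rt in occ
        w = wb if bound else wf
        u = rng.random() * (w + 4.0)
        if u < w:
            continue  # stay
        k = int(u - w)  # direction index in 0..3
        nr, nc = (up, dn, lf, rt)[k]
        if not periodic and not (0 <= nr < H and 0 <= nc < W):
            continue  # off-grid draw becomes a stay
        if (nr, nc) in occ:
            continue  # blocked draw becomes a stay
        occ.discard((r, c))
        occ.add((nr, nc))
        rows[i], cols[i] = nr, nc


def step(state: LatticeState, config: LatticeConfig, rng: random.Random) -> LatticeState:
    """Advance one sweep; returns a new state (input unchanged)."""
    rows = state.rows.tolist()
    cols = state.cols.tolist()
    occ = set(zip(rows, cols))
    _sweep(rows, cols, occ, config, rng)
    return LatticeState(
        rows=np.asarray(rows), cols=np.asarray(cols), step_index=state.step_index + 1
    )


def run(
    config: LatticeConfig,
    n_steps: int = 5000,
    burn_in: int = 1500,
    sample_every: int = 10,
) -> list[LatticeState]:
    """Seeded trajectory: random initial placement, ``burn_in`` discarded
    sweeps, then snapshots every ``sample_every`` sweeps up to ``n_steps``."""
    if n_steps <= burn_in:
        raise ValueError("n_steps must exceed burn_in")
    rng = random.Random(config.seed)
    state = initial_state(config, rng)
    rows = state.rows.tolist()
    cols = state.cols.tolist()
    occ = set(zip(rows, cols))
    samples: list[LatticeState] = []
    for t in range(1, n_steps + 1):
        _sweep(rows, cols, occ, config, rng)
        if t > burn_in and (t - burn_in) % sample_every == 0:
            samples.append(
                LatticeState(rows=np.asarray(rows), cols=np.asarray(cols), step_index=t)
            )
    return samples


def extract_clusters(state: LatticeState, config: LatticeConfig) -> np.ndarray:
    """Sizes of 4-connected components of occupied sites.  Σ sizes equals the
    particle count.  With periodic boundaries, components touching opposite
    edges are merged."""
    grid = state.grid(config)
    labels, n_lab = ndimage.label(grid, structure=_STRUCT4)
    if n_lab == 0:
        return np.array([], dtype=int)
    if config.boundary == "periodic":
        parent = list(range(n_lab + 1))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for a, b in zip(labels[0, :], labels[-1, :]):
            if a and b:
                union(a, b)
        for a, b in zip(labels[:, 0], labels[:, -1]):
            if a and b:
                union(a, b)
        roots = np.array([find(l) for l in range(n_lab + 1)])
        labels = roots[labels]
    sizes = np.bincount(labels.ravel())[1:]
    return sizes[sizes > 0]


def cluster_size_distribution(
    samples: list[LatticeState], config: LatticeConfig
) -> SizeDistribution:
    """Time-averaged cluster-size histogram over snapshots, in μm⁻²."""
    if not samples:
        raise ValueError("no samples")
    area = config.area_um2
    acc = np.zeros(1)
    for s in samples:
        sizes = extract_clusters(s, config)
        if sizes.size:
            counts = np.bincount(sizes)
            if counts.size > acc.size:
                acc = np.pad(acc, (0, counts.size - acc.size))
            acc[: counts.size] += counts
    mean_counts = acc[1:] / len(samples)
    nmax = int(np.max(np.nonzero(mean_counts)[0])) + 1 if mean_counts.any() else 0
    n = np.arange(1, nmax + 1)
    dist = SizeDistribution(n=n, density=mean_counts[:nmax] / area, area=None)
    dist.ctot = dist.total()
    dist.meta.update(
        {"n_particles": config.n_particles, "n_samples": len(samples), "seed": config.seed}
    )
    return dist


def density_sweep(
    base: LatticeConfig,
    densities: list[float],
    n_steps: int = 5000,
    burn_in: int = 1500,
    sample_every: int = 10,
) -> list[SizeDistribution]:
    """One time-averaged SizeDistribution per requested total density
    (μm⁻²); the particle count is density × grid area."""
    out = []
    for i, dens in enumerate(densities):
        exact = dens * base.area_um2
        n_part = int(round(exact))
        if abs(exact - n_part) > 1e-9:
            warnings.warn(
                f"density {dens} μm⁻² needs {exact} particles; rounded to {n_part}"
            )
        config = replace(base, n_particles=n_part, seed=base.seed + 7919 * i)
        samples = run(config, n_steps=n_steps, burn_in=burn_in, sample_every=sample_every)
        out.append(cluster_size_distribution(samples, config))
    return out
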