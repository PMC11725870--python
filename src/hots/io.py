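"""File formats: point tables, size-distribution tables, parameters, results.

Conventions: CSV, comma-separated, header row required, UTF-8, '.' decimal.
Coordinates in nm, areas in μm², densities in μm⁻².  Region polygons are WKT
(nm coordinates) in a sidecar file, or an explicit --area rectangle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.wkt
import yaml
from shapely.geometry import Polygon

from .fitting import FitResult
from .spatial import NM2_PER_UM2, PointPattern, rectangle_region
from .theory import AggregationParams, SizeDistribution

__all__ = [
    "read_point_table",
    "write_point_table",
    "read_distribution",
    "write_distribution",
    "read_region",
    "write_region",
    "read_params",
    "write_params",
    "write_trajectory",
    "write_fit_result",
    "load_config",
]


def read_region(path: str | Path) -> Polygon:
    """Region polygon from a WKT file or a CSV vertex list (columns x_nm,
    y_nm), in nm coordinates."""
    path = Path(path)
    text = path.read_text().strip()
    if text.upper().startswith(("POLYGON", "MULTIPOLYGON")):
        region = shapely.wkt.loads(text)
    else:
        df = pd.read_csv(path)
        for col in ("x_nm", "y_nm"):
            if col not in df.columns:
                raise ValueError(f"{path}: region CSV needs columns x_nm, y_nm")
        region = Polygon(df[["x_nm", "y_nm"]].to_numpy(dtype=float))
    if region.area <= 0:
        raise ValueError(f"degenerate region polygon in {path}")
    return region


def write_region(region: Polygon, path: str | Path) -> None:
    Path(path).write_text(region.wkt + "\n")


def read_point_table(
    path: str | Path,
    region: Polygon | None = None,
    area_um2: float | None = None,
) -> PointPattern:
    """Point pattern from CSV with columns x_nm, y_nm [, channel,
    precision_nm].  Supply either a region polygon or an area (interpreted
    as a square region of that area)."""
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in ("x_nm", "y_nm"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: malformed value in column {col!r} at line {bad[0] + 2}")
    if region is None:
        if area_um2 is None:
            raise ValueError("supply a region polygon or an area")
        side = float(np.sqrt(area_um2 * NM2_PER_UM2))
        region = rectangle_region(side, side)
    return PointPattern(
        points=df[["x_nm", "y_nm"]].to_numpy(dtype=float),
        region=region,
        channel=df["channel"].to_numpy() if "channel" in df.columns else None,
        precision=(
            df["precision_nm"].to_numpy(dtype=float)
            if "precision_nm" in df.columns
            else None
        ),
    )


def write_point_table(pattern: PointPattern, path: str | Path) -> None:
    df = pd.DataFrame({"x_nm": pattern.points[:, 0], "y_nm": pattern.points[:, 1]})
    if pattern.channel is not None:
        df["channel"] = pattern.channel
    if pattern.precision is not None:
        df["precision_nm"] = pattern.precision
    df.to_csv(path, index=False)


def read_distribution(path: str | Path) -> SizeDistribution:
    """Size distribution from CSV (n, density_per_um2 [, count, se]).
    Missing n rows are treated as zero density; ctot is recomputed."""
    df = pd.read_csv(path)
    for col in ("n", "density_per_um2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if (df["density_per_um2"] < 0).any():
        line = int(df.index[df["density_per_um2"] < 0][0]) + 2
        raise ValueError(f"{path}: negative density at line {line}")
    df = df.sort_values("n")
    nmax = int(df["n"].max())
    density = np.zeros(nmax)
    density[df["n"].to_numpy(dtype=int) - 1] = df["density_per_um2"].to_numpy()
    counts = se = None
    if "count" in df.columns and df["count"].notna().all():
        counts = np.zeros(nmax)
        counts[df["n"].to_numpy(dtype=int) - 1] = df["count"].to_numpy()
    if "se" in df.columns and df["se"].notna().all():
        se = np.zeros(nmax)
        se[df["n"].to_numpy(dtype=int) - 1] = df["se"].to_numpy()
    area = None
    if counts is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = counts / density
        finite = np.isfinite(ratio) & (density > 0)
        if finite.any() and np.allclose(ratio[finite], ratio[finite][0], rtol=1e-6):
            area = float(ratio[finite][0])
    dist = SizeDistribution(
        n=np.arange(1, nmax + 1), density=density, counts=counts, se=se, area=area
    )
    dist.ctot = dist.total()
    return dist


def write_distribution(dist: SizeDistribution, path: str | Path) -> None:
    df = pd.DataFrame({"n": dist.n, "density_per_um2": dist.density})
    if dist.counts is not None:
        df["count"] = dist.counts
    if dist.se is not None:
        df["se"] = dist.se
    df.to_csv(path, index=False)


def write_trajectory(samples, path: str | Path) -> None:
    """Lattice snapshots as CSV of (step, row, col)."""
    rows = [
        {"step": s.step_index, "row": int(r), "col": int(c)}
        for s in samples
        for r, c in zip(s.rows, s.cols)
    ]
    pd.DataFrame(rows, columns=["step", "row", "col"]).to_csv(path, index=False)


def read_params(path: str | Path) -> AggregationParams:
    """Aggregation parameters from JSON {dG_bulk_RT, A0_um2, alpha}."""
    d = json.loads(Path(path).read_text())
    return AggregationParams(
        dG_bulk=d["dG_bulk_RT"], A0=d["A0_um2"], alpha=d.get("alpha", 0.5)
    )


def write_params(params: AggregationParams, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"dG_bulk_RT": params.dG_bulk, "A0_um2": params.A0, "alpha": params.alpha},
            indent=2,
        )
        + "\n"
    )


def write_fit_result(result: FitResult, path: str | Path, extra: dict | None = None) -> None:
    payload = {
        "dG_bulk_RT": result.dG_bulk,
        "alpha": result.alpha,
        "A0_per_dataset_um2": result.A0_per_dataset,
        "cmon_per_dataset_um2": result.cmon_per_dataset,
        "ctot_per_dataset_um2": result.ctot_per_dataset,
        "nmax_per_dataset": result.nmax_per_dataset,
        "objective": result.objective,
        "converged": result.converged,
        "dG_ci_RT": result.dG_ci,
        "meta": result.meta,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_config(path: str | Path) -> dict:
    """YAML-style key-value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
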