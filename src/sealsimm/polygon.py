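"""Monte Carlo mixing-polygon simulation for TEF evaluation.

A consumer's isotope values can only be explained as a mixture of sources if
they fall inside the convex hull (mixing polygon) of the TEF-adjusted source
means.  Because both source means and TEFs are uncertain, the polygon is
itself random: each iteration draws source means and a TEF realization,
builds the hull, and records which consumers fall inside.  The per-consumer
inside-probability measures how plausibly a TEF candidate places the
consumers inside the mixing space, and candidates are ranked by how many
consumers sit inside the 95% mixing region (probability ≥ 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon

from .grouping import SourceGroup
from .isotopes import IsotopeRecord, TEFSpec


class DegenerateGeometryError(ValueError):
    """Fewer than 3 distinct points, or all points collinear."""


def convex_hull(points: Sequence[Sequence[float]]) -> np.ndarray:
    """Counter-clockwise convex hull vertices of a 2-D point set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(np.unique(pts, axis=0)) < 3:
        raise DegenerateGeometryError("need at least 3 distinct 2-D points")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise DegenerateGeometryError(f"degenerate point set: {e}") from e
    return pts[hull.vertices]  # scipy returns CCW order in 2-D


def point_in_polygon(point: Sequence[float], polygon: Sequence[Sequence[float]]) -> bool:
    """Whether a point lies in a simple polygon; boundary counts as inside."""
    poly = Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise DegenerateGeometryError("invalid or degenerate polygon")
    return bool(poly.covers(Point(float(point[0]), float(point[1]))))


@dataclass
class MixingRegionResult:
    """Inside-probabilities for one TEF candidate.

    ``contour_grid`` is ``(x_nodes, y_nodes, prob)`` with ``prob`` of shape
    ``(len(y_nodes), len(x_nodes))``, or None when no grid was requested.
    """

    tef_provenance: str
    n_iter: int
    per_consumer_probability: dict[str, float]
    contour_grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    level: float = 0.05

    def __post_init__(self) -> None:
        for cid, p in self.per_consumer_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {cid!r} outside [0, 1]")

    @property
    def n_inside_95(self) -> int:
        """Consumers inside the 95% mixing region (probability ≥ level)."""
        return sum(p >= self.level for p in self.per_consumer_probability.values())

    @property
    def mean_probability(self) -> float:
        probs = list(self.per_consumer_probability.values())
        return float(np.mean(probs)) if probs else float("nan")


def _inside_hull(points: np.ndarray, hull: ConvexHull, atol: float = 1e-9) -> np.ndarray:
    """Vectorized membership against hull facet equations (boundary inside)."""
    A = hull.equations[:, :2]
    b = hull.equations[:, 2]
    return (points @ A.T + b <= atol).all(axis=1)


def simulate_mixing_region(
    groups: Sequence[SourceGroup],
    tef: TEFSpec,
    consumers: Sequence[IsotopeRecord],
    n_iter: int = 1500,
    seed: int | np.random.SeedSequence | None = None,
    grid: tuple[int, int] | None = None,
    pad: float = 2.0,
    source_spread: str = "sd",
) -> MixingRegionResult:
    """Monte Carlo mixing polygons: per-consumer inside-probabilities.

    Each iteration draws one TEF realization (shared across groups: TEF
    uncertainty belongs to the consumer, not to each source) and, per group
    and isotope, a source mean from Normal(group mean, group SD); the TEF-
    adjusted draws define a convex hull and consumers are tested for
    membership.  ``source_spread='se'`` scales source SDs by 1/sqrt(n).
    ``grid=(nx, ny)`` additionally rasterizes the inside-probability over the
    data extent padded by ``pad`` ‰.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 source groups to form a mixing polygon")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if source_spread not in ("sd", "se"):
        raise ValueError("source_spread must be 'sd' or 'se'")
    rng = np.random.default_rng(seed)

    mu = np.array([[g.d13C_mean, g.d15N_mean] for g in groups])
    sd = np.array([[g.d13C_sd, g.d15N_sd] for g in groups])
    if np.isnan(sd).any():
        raise ValueError("all source groups need defined SDs")
    if source_spread == "se":
        sd = sd / np.sqrt(np.array([[g.n] for g in groups], dtype=float))
    tef_mu = np.array([tef.d13C_mean, tef.d15N_mean])
    tef_sd = np.array([tef.d13C_sd, tef.d15N_sd])

    cons_ids = [c.record_id for c in consumers]
    cons_xy = np.array([c.xy for c in consumers], dtype=float).reshape(len(consumers), 2)

    source_draws = rng.normal(mu, sd, size=(n_iter, *mu.shape))
    tef_draws = rng.normal(tef_mu, tef_sd, size=(n_iter, 2))
    points = source_draws + tef_draws[:, None, :]

    grid_xy = None
    grid_counts = None
    if grid is not None:
        nx, ny = grid
        all_pts = np.vstack([points.reshape(-1, 2), cons_xy]) if len(cons_xy) else points.reshape(-1, 2)
        xs = np.linspace(all_pts[:, 0].min() - pad, all_pts[:, 0].max() + pad, nx)
        ys = np.linspace(all_pts[:, 1].min() - pad, all_pts[:, 1].max() + pad, ny)
        gx, gy = np.meshgrid(xs, ys)
        grid_xy = np.column_stack([gx.ravel(), gy.ravel()])
        grid_counts = np.zeros(len(grid_xy))

    counts = np.zeros(len(consumers))
    for it in range(n_iter):
        hull = ConvexHull(points[it])
        if len(cons_xy):
            counts += _inside_hull(cons_xy, hull)
        if grid_xy is not None:
            grid_counts += _inside_hull(grid_xy, hull)

    contour = None
    if grid_xy is not None:
        contour = (xs, ys, (grid_counts / n_iter).reshape(ny, nx))
    return MixingRegionResult(
        tef_provenance=tef.provenance,
        n_iter=n_iter,
        per_consumer_probability={
            cid: float(c / n_iter) for cid, c in zip(cons_ids, counts)
        },
        contour_grid=contour,
    )


def rank_tefs(results: Sequence[MixingRegionResult]) -> list[MixingRegionResult]:
    """Rank TEF candidates: most consumers inside the 95% region first,
    ties broken by higher mean inside-probability, then by provenance."""
    if not results:
        raise ValueError("no results to rank")
    consumer_sets = {frozenset(r.per_consumer_probability) for r in results}
    if len(consumer_sets) > 1:
        raise ValueError("results cover different consumer sets")
    return sorted(
        results,
        key=lambda r: (-r.n_inside_95, -r.mean_probability, r.tef_provenance),
    )


def export_contour_csv(result: MixingRegionResult, path) -> None:
    """Write the probability raster as long-format CSV (d13C,d15N,probability)."""
    if result.contour_grid is None:
        raise ValueError("result has no contour grid")
    import pandas as pd

    xs, ys, prob = result.contour_grid
    gx, gy = np.meshgrid(xs, ys)
    pd.DataFrame(
        {"d13C": gx.ravel(), "d15N": gy.ravel(), "probability": prob.ravel()}
    ).to_csv(path, index=False)


def plot_mixing_region(
    result: MixingRegionResult,
    groups: Sequence[SourceGroup],
    tef: TEFSpec,
    consumers: Sequence[IsotopeRecord],
    path,
) -> None:
    """Diagnostic biplot: probability contours (5% steps), TEF-adjusted source
    means, and consumer points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if result.contour_grid is not None:
        xs, ys, prob = result.contour_grid
        levels = np.arange(0.05, 1.0, 0.05)
        cf = ax.contourf(xs, ys, prob, levels=levels, cmap="viridis", alpha=0.7)
        fig.colorbar(cf, ax=ax, label="inside-probability")
    for g in groups:
        ax.plot(g.d13C_mean + tef.d13C_mean, g.d15N_mean + tef.d15N_mean, "P",
                color="white", mec="black", ms=10)
    if consumers:
        xy = np.array([c.xy for c in consumers])
        ax.plot(xy[:, 0], xy[:, 1], "ko", ms=4)
    ax.set_xlabel("δ13C (‰)")
    ax.set_ylabel("δ15N (‰)")
    ax.set_title(f"Mixing region — TEF: {result.tef_provenance}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
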