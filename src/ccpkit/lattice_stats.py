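"""Triskelion angle and population statistics on lattice skeletons.

A triskelion hub is a degree-3 vertex of the lattice skeleton; its three
arms are straight 3D chords to the neighbouring hubs.  The three inter-arm
angles (alpha, beta, gamma) sum to 360 deg for a flat hub and to less for a
pyramidal (convex) hub — e.g. 348/336/324 deg for hubs joining regular
6-6-5 / 6-5-5 / 5-5-5 polygon configurations — so the angle sum classifies
each hub as convex, flat, or concave.  Interior angles pooled per polygon
class (pentagon/hexagon/heptagon) are summarized by a maximum-likelihood
normal fit, and angle sums binned against pit radius expose the coupling
between global pit curvature and local triskelion distortion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import regular_polygon_interior_angle
from .morphometry import CCPRecord, LatticeSkeleton

__all__ = [
    "TriskelionHub",
    "AngleFit",
    "hub_angles",
    "all_hub_angles",
    "classify_conformation",
    "fit_angle_distribution",
    "polygon_angle_histogram",
    "anglesum_vs_radius",
    "area_radius_distribution",
    "ARDistribution",
]

#: Angle-sum tolerance band (degrees) separating flat from curved hubs;
#: matches the AFM angular noise scale.
FLAT_TOLERANCE_DEG = 5.0


@dataclass(frozen=True)
class TriskelionHub:
    """One triskelion hub: position, arm vectors, inter-arm angles.

    ``alpha``, ``beta``, ``gamma_angle`` are the three pairwise angles
    (degrees) between arm chords; ``gamma_angle`` is named to avoid clashing
    with the membrane tension gamma.  ``conformation`` is convex/flat/concave
    by the angle sum vs 360 deg; ``adjacent_faces`` are the sizes of the
    polygons meeting at the hub (None where the face is not resolved).
    """

    position: Tuple[float, float, float]
    arms: Tuple[Tuple[float, float, float], ...]
    alpha: float
    beta: float
    gamma_angle: float
    conformation: str
    adjacent_faces: Tuple[Optional[int], Optional[int], Optional[int]]

    @property
    def angle_sum(self) -> float:
        return self.alpha + self.beta + self.gamma_angle


def classify_conformation(angle_sum: float, tolerance: float = FLAT_TOLERANCE_DEG) -> str:
    """convex (< 360 - tol), flat (within tol of 360), or concave (> 360 + tol)."""
    if not angle_sum > 0:
        raise ValueError("angle_sum must be positive")
    if angle_sum < 360.0 - tolerance:
        return "convex"
    if angle_sum > 360.0 + tolerance:
        return "concave"
    return "flat"


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def hub_angles(skel: LatticeSkeleton, vertex: int,
               tolerance: float = FLAT_TOLERANCE_DEG) -> TriskelionHub:
    """Inter-arm angles of the degree-3 hub at ``vertex``.

    The arms are the straight 3D chords to the three neighbouring vertices;
    the angles are arc-cosines of normalized dot products, invariant under
    rigid motion of the skeleton.  Raises ``ValueError`` for vertices that
    are not degree-3 hubs.
    """
    nbrs = sorted({j if i == vertex else i for i, j in skel.edges if vertex in (i, j)})
    if len(nbrs) != 3:
        raise ValueError(f"vertex {vertex} has degree {len(nbrs)}, not a triskelion hub")
    pos = skel.vertices[vertex]
    arms = [skel.vertices[j] - pos for j in nbrs]
    a = _angle_deg(arms[0], arms[1])
    b = _angle_deg(arms[0], arms[2])
    g = _angle_deg(arms[1], arms[2])
    sizes: List[Optional[int]] = [len(f) for f in skel.faces if vertex in f]
    sizes = sorted(sizes, reverse=True)[:3]
    while len(sizes) < 3:
        sizes.append(None)
    return TriskelionHub(
        position=tuple(map(float, pos)),
        arms=tuple(tuple(map(float, v)) for v in arms),
        alpha=a, beta=b, gamma_angle=g,
        conformation=classify_conformation(a + b + g, tolerance),
        adjacent_faces=tuple(sizes),
    )


def all_hub_angles(skel: LatticeSkeleton,
                   tolerance: float = FLAT_TOLERANCE_DEG) -> List[TriskelionHub]:
    """:func:`hub_angles` for every degree-3 vertex; others are skipped."""
    return [hub_angles(skel, v, tolerance) for v in skel.hubs()]


@dataclass(frozen=True)
class AngleFit:
    """Normal fit to the interior angles of one polygon class."""

    polygon: int  # 5, 6 or 7
    n: int
    mean: float  # degrees
    sd: float  # degrees
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def reference_angle(self) -> float:
        """Interior angle of the regular polygon of this class."""
        return regular_polygon_interior_angle(self.polygon)


def _face_interior_angles(skel: LatticeSkeleton, size: int) -> List[float]:
    out = []
    for f in skel.faces:
        if len(f) != size:
            continue
        for k, v in enumerate(f):
            prev = skel.vertices[f[k - 1]] - skel.vertices[v]
            nxt = skel.vertices[f[(k + 1) % len(f)]] - skel.vertices[v]
            out.append(_angle_deg(prev, nxt))
    return out


def fit_angle_distribution(angles: Sequence[float], polygon: int,
                           bin_width: float = 2.0) -> AngleFit:
    """Maximum-likelihood normal fit (sample mean/sd) with attached histogram."""
    angles = np.asarray(angles, dtype=float)
    lo = bin_width * math.floor(angles.min() / bin_width)
    hi = bin_width * math.ceil(angles.max() / bin_width)
    nbins = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(angles, bins=nbins, range=(lo, hi))
    return AngleFit(polygon=polygon, n=len(angles),
                    mean=float(np.mean(angles)), sd=float(np.std(angles)),
                    bin_edges=edges, counts=counts)


def polygon_angle_histogram(
    skels: Iterable[LatticeSkeleton],
    polygon: int,
    bin_width: float = 2.0,
    min_samples: int = 10,
) -> Optional[AngleFit]:
    """Normal fit to all interior angles of ``polygon``-sized faces.

    The fit is the maximum-likelihood sample mean and standard deviation
    (bin-width independent); the 2-degree histogram is attached for
    plotting.  Returns None when fewer than ``min_samples`` angles exist.
    """
    angles = []
    for s in skels:
        angles.extend(_face_interior_angles(s, polygon))
    if len(angles) < min_samples:
        return None
    return fit_angle_distribution(angles, polygon, bin_width)


def anglesum_vs_radius(
    table: pd.DataFrame,
    n_bins: int = 4,
    bin_edges: Optional[Sequence[float]] = None,
) -> Tuple[pd.DataFrame, float]:
    """Bin hub angle sums by pit radius and measure the monotone trend.

    ``table`` needs columns ``R_nm`` (pit radius of the hub's parent pit) and
    ``angle_sum_deg``.  Default bins are radius quartiles.  Returns the
    per-bin summary (mean radius, mean and sd of the angle sum, count) and
    the Spearman rank correlation between bin radius and mean angle sum —
    positive when flatter (larger-R) pits carry flatter triskelia.
    """
    if bin_edges is None:
        if n_bins < 2:
            raise ValueError("need at least 2 radius bins")
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(table["R_nm"], qs))
        if len(bin_edges) < 3:
            # discrete radius populations: one bin per distinct radius
            u = np.unique(table["R_nm"])
            mids = (u[:-1] + u[1:]) / 2.0
            bin_edges = np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])
    cats = pd.cut(table["R_nm"], bins=bin_edges, include_lowest=True)
    grouped = table.groupby(cats, observed=True)
    summary = grouped.agg(
        R_mean=("R_nm", "mean"),
        angle_sum_mean=("angle_sum_deg", "mean"),
        angle_sum_sd=("angle_sum_deg", "std"),
        n=("angle_sum_deg", "size"),
    ).reset_index(drop=True)
    if len(summary) >= 2 and summary["angle_sum_mean"].nunique() > 1:
        rho = float(stats.spearmanr(summary["R_mean"], summary["angle_sum_mean"]).statistic)
    elif len(summary) >= 2:
        rho = 0.0  # constant angle sums: no trend
    else:
        rho = math.nan
    return summary, rho


@dataclass
class ARDistribution:
    """Area-radius population summary with model reference lines."""

    table: pd.DataFrame  # columns A_nm2, R_nm
    mean_A: float
    mean_R: float
    density: Optional[object] = None  # gaussian_kde in (log10 A, log10 R)

    def sphere_curve_A(self, R: np.ndarray) -> np.ndarray:
        """Closed-vesicle locus A = 4*pi*R^2."""
        return 4.0 * math.pi * np.square(np.asarray(R, dtype=float))

    def plot(self, ax=None, grid=None):
        """Scatter on log axes with constant-area/curvature lines and the
        closed-sphere curve; ``grid`` optionally overlays an
        :class:`~ccpkit.energy.EnergyLandscapeGrid` heatmap."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if grid is not None:
            ax.pcolormesh(grid.R, grid.A, grid.E, shading="auto", cmap="viridis")
        ax.scatter(self.table["R_nm"], self.table["A_nm2"], s=12, c="k", zorder=3)
        ax.axhline(self.mean_A, color="r", lw=1, label="constant area")
        ax.axvline(self.mean_R, color="r", lw=1, ls="--", label="constant curvature")
        rr = np.logspace(math.log10(max(self.table["R_nm"].min() * 0.5, 1.0)),
                         math.log10(self.table["R_nm"].max() * 2.0), 100)
        ax.plot(rr, self.sphere_curve_A(rr), "k--", lw=1, label="A = 4πR²")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("radius of curvature R (nm)")
        ax.set_ylabel("surface area A (nm²)")
        ax.legend(fontsize=7)
        return ax


def area_radius_distribution(records: Sequence[CCPRecord]) -> ARDistribution:
    """Population (A, R) table with mean reference lines and log-space density.

    The horizontal mean-area and vertical mean-radius lines are the
    constant-area and constant-curvature model predictions computed from the
    population means; a Gaussian kernel density in (log10 A, log10 R) is
    attached when there are enough distinct points.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    A = np.array([r.cap.A for r in records])
    R = np.array([r.cap.R for r in records])
    table = pd.DataFrame({"A_nm2": A, "R_nm": R})
    density = None
    pts = np.vstack([np.log10(A), np.log10(R)])
    if len(records) >= 5 and np.linalg.matrix_rank(np.cov(pts)) == 2:
        density = stats.gaussian_kde(pts)
    return ARDistribution(table=table, mean_A=float(A.mean()), mean_R=float(R.mean()),
                          density=density)
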