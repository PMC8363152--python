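"""HS-AFM topograph morphometry: sphere fits, ridge detection, skeletons.

Turns a height map (a :class:`Topograph`) into fitted coated-pit records and
a 3D clathrin-lattice skeleton:

* :func:`level_background` sets the zero level from the surrounding membrane;
* :func:`fit_sphere` fits a sphere to a protrusion — a linear algebraic fit
  followed by refits restricted to the top +/-45 deg of the cap, which keeps
  tip-dilated flanks out of the fit;
* :func:`detect_lattice` extracts the ridge network by multiscale high-pass
  filtering and directional peak detection;
* :func:`build_skeleton` thins the ridge mask and assembles the triskelion
  hub/arm graph with polygon faces;
* :func:`section_profile` samples a height profile along a line and measures
  its local circle-fit curvature.

Coordinates: pixel centres, 0-based indices, ``x = column * pixel_size``,
``y = row * pixel_size``; heights are nm above the zero level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, transform
from skimage.registration import phase_cross_correlation

from .energy import EnergyBreakdown, ModelParams, total_energy
from .geometry import SphericalCap

__all__ = [
    "Topograph",
    "LatticeSkeleton",
    "CCPRecord",
    "SphereFitError",
    "SectionProfile",
    "level_background",
    "register_frames",
    "estimate_shift",
    "fit_sphere",
    "detect_lattice",
    "build_skeleton",
    "section_profile",
    "detect_seeds",
    "analyze_topograph",
]


@dataclass
class Topograph:
    """Height grid with physical pixel size and zero level.

    ``heights`` in nm, row-major 2D; ``pixel_size`` in nm/pixel;
    ``zero_level`` is the background membrane height in nm.
    """

    heights: np.ndarray
    pixel_size: float
    zero_level: float = 0.0
    image_id: str = ""

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 16:
            raise ValueError("topograph must be a 2D grid of at least 16x16 pixels")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("topograph heights must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.heights.shape

    def relative_heights(self) -> np.ndarray:
        """Heights in nm above the zero level."""
        return self.heights - self.zero_level


def level_background(t: Topograph) -> Topograph:
    """Set the zero level to the robust mode of the membrane background.

    The background estimate is the median of the lowest quartile of heights —
    insensitive to the protruding pits, which occupy the upper tail.  Heights
    themselves are unchanged.
    """
    vals = t.heights.ravel()
    q25 = np.quantile(vals, 0.25)
    low = vals[vals <= q25]
    zl = float(np.median(low)) if low.size else float(q25)
    return replace(t, heights=t.heights, zero_level=zl)


def estimate_shift(ref: Topograph, moving: Topograph) -> Tuple[int, int]:
    """Integer-pixel (row, col) drift of ``moving`` relative to ``ref``.

    Positive values mean the content moved down/right; applying the negated
    drift registers the frame back onto the reference.
    """
    if np.ptp(moving.heights) < 1e-12 or np.ptp(ref.heights) < 1e-12:
        warnings.warn("featureless frame: assuming identity shift")
        return (0, 0)
    shift, _, _ = phase_cross_correlation(ref.heights, moving.heights, upsample_factor=1)
    return (-int(round(shift[0])), -int(round(shift[1])))


def register_frames(frames: Sequence[Topograph]) -> List[Topograph]:
    """Align a stack of frames to the first by integer-pixel translation.

    Drift between consecutive HS-AFM frames is dominated by in-plane
    translation; the shift maximizing the cross-correlation with the first
    frame is applied (nearest-neighbour, edge values extended).
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    ref = frames[0]
    out = [ref]
    for f in frames[1:]:
        dy, dx = estimate_shift(ref, f)
        shifted = ndi.shift(f.heights, (-dy, -dx), order=0, mode="nearest")
        out.append(replace(f, heights=shifted))
    return out


# ---------------------------------------------------------------------------
# Sphere fitting


class SphereFitError(RuntimeError):
    """Raised when a protrusion cannot be fitted by a sphere."""


@dataclass
class CCPRecord:
    """One fitted coated pit: cap geometry, fit quality, energies, provenance."""

    cap: SphericalCap
    residual: float  # nm RMS distance of fitted points from the sphere
    energies: Optional[EnergyBreakdown] = None
    hubs: Optional[list] = None  # TriskelionHub list, filled by lattice_stats
    image_id: str = ""
    seed: Optional[Tuple[int, int]] = None  # (row, col) seed pixel

    def __post_init__(self):
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def _algebraic_sphere_fit(P: np.ndarray) -> Tuple[np.ndarray, float]:
    """Least-squares sphere through 3D points via the linearized equation.

    Solves ``x^2+y^2+z^2 + D x + E y + F z + G = 0`` for (D, E, F, G);
    centre = -(D,E,F)/2, radius = sqrt(|c|^2 - G).
    """
    M = np.column_stack([P, np.ones(len(P))])
    b = -np.sum(P**2, axis=1)
    coef, *_ = np.linalg.lstsq(M, b, rcond=None)
    c = -coef[:3] / 2.0
    r2 = float(np.dot(c, c) - coef[3])
    if r2 <= 0:
        raise SphereFitError("degenerate algebraic sphere fit")
    return c, math.sqrt(r2)


def fit_sphere(
    t: Topograph,
    seed_point: Tuple[int, int],
    min_height: float = 0.5,
    angle_cut_deg: float = 45.0,
    refit_iterations: int = 2,
    min_points: int = 12,
    radius_bounds: Tuple[float, float] = (5.0, 2000.0),
    params: Optional[ModelParams] = None,
) -> CCPRecord:
    """Fit a spherical cap to the protrusion containing ``seed_point``.

    Two-stage procedure: (1) algebraic least-squares sphere over the
    connected above-background region containing the seed; (2) refit using
    only points whose polar angle from the current apex is at most
    ``angle_cut_deg`` (default 45 deg), iterated ``refit_iterations`` times.
    The apex-restricted refit avoids the bias from tip-dilated cap flanks.

    Cap height is the fitted apex height above the zero level and the cap
    area follows as ``A = 2*pi*R*h``.

    Raises :class:`SphereFitError` if the seed is not on a protrusion, fewer
    than ``min_points`` usable points exist, or the fitted radius falls
    outside ``radius_bounds``.
    """
    r0, c0 = int(seed_point[0]), int(seed_point[1])
    if not (0 <= r0 < t.shape[0] and 0 <= c0 < t.shape[1]):
        raise SphereFitError("seed point outside the image")
    z = t.relative_heights()
    mask = z > min_height
    if not mask[r0, c0]:
        raise SphereFitError("seed point is not on a protrusion above the background")
    labels, _ = ndi.label(mask)
    comp = labels == labels[r0, c0]
    rows, cols = np.nonzero(comp)
    if rows.size < min_points:
        raise SphereFitError(f"only {rows.size} usable points (need {min_points})")
    ps = t.pixel_size
    P = np.column_stack([cols * ps, rows * ps, z[rows, cols]])

    center, R = _algebraic_sphere_fit(P)
    cos_cut = math.cos(math.radians(angle_cut_deg))
    used = P
    for _ in range(refit_iterations):
        d = P - center
        norm = np.linalg.norm(d, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_polar = d[:, 2] / norm
        sel = cos_polar >= cos_cut
        if np.count_nonzero(sel) < min_points:
            break
        used = P[sel]
        center, R = _algebraic_sphere_fit(used)

    if not (radius_bounds[0] <= R <= radius_bounds[1]):
        raise SphereFitError(f"fitted radius {R:.1f} nm outside {radius_bounds}")
    h = center[2] + R  # apex height above the zero level
    if not h > 0:
        raise SphereFitError("fitted apex below the zero level")
    h = min(h, 2.0 * R)
    dist = np.linalg.norm(used - center, axis=1)
    residual = float(np.sqrt(np.mean((dist - R) ** 2)))
    cap = SphericalCap(R=float(R), h=float(h), center=tuple(map(float, center)))
    energies = total_energy(cap.A, cap.R, params) if params is not None else None
    return CCPRecord(cap=cap, residual=residual, energies=energies,
                     image_id=t.image_id, seed=(r0, c0))


def detect_seeds(
    t: Topograph,
    min_height: float = 3.0,
    smooth_sigma: float = 4.0,
    min_distance: int = 10,
) -> List[Tuple[int, int]]:
    """Candidate pit apices: local maxima of the smoothed height map.

    Convenience driver for batch analysis of crowded membranes; each seed is
    meant to be passed to :func:`fit_sphere`.
    """
    from skimage.feature import peak_local_max

    sm = ndi.gaussian_filter(t.relative_heights(), smooth_sigma)
    peaks = peak_local_max(sm, min_distance=min_distance, threshold_abs=min_height)
    return [tuple(p) for p in peaks]


# ---------------------------------------------------------------------------
# Lattice ridge detection


def _peak_mask(hp: np.ndarray, min_prominence: float) -> np.ndarray:
    """Strict 1D local maxima of ``hp`` along either image axis."""
    m = np.zeros_like(hp, dtype=bool)
    m[1:-1, :] |= (hp[1:-1, :] > hp[:-2, :]) & (hp[1:-1, :] > hp[2:, :])
    m[:, 1:-1] |= (hp[:, 1:-1] > hp[:, :-2]) & (hp[:, 1:-1] > hp[:, 2:])
    return m & (hp > min_prominence)


def detect_lattice(
    t: Topograph,
    sigma_hp: float = 6.0,
    min_prominence: float = 0.3,
    samplings: Sequence[float] = (1.0, 0.5, 0.25),
    closing_rounds: int = 2,
) -> np.ndarray:
    """Binary mask of clathrin-lattice ridges.

    At each sampling the image is high-pass filtered (subtracting a
    Gaussian-smoothed copy with ``sigma_hp`` pixels at full sampling, scaled
    with the sampling) so the overall pit topography drops out while the
    ridge texture remains; pixels that are strict local maxima along either
    image axis and exceed ``min_prominence`` (nm, rejects pixel noise) are
    marked.  Down-sampled passes (0.5x, 0.25x) catch the tops of flat, wide
    ridges.  Masks are upsampled, OR-combined, and closed
    (``closing_rounds`` rounds of 3x3 dilation then erosion) to bridge
    single-pixel gaps.
    """
    masks = []
    shape = t.shape
    for s in samplings:
        if s == 1.0:
            img = t.heights
        else:
            img = transform.rescale(t.heights, s, anti_aliasing=True, order=1)
        hp = img - ndi.gaussian_filter(img, max(sigma_hp * s, 1.0))
        m = _peak_mask(hp, min_prominence)
        if s != 1.0:
            m = transform.resize(m.astype(float), shape, order=0) > 0.5
        masks.append(m)
    mask = np.logical_or.reduce(masks)
    selem = np.ones((3, 3), dtype=bool)
    mask = ndi.binary_dilation(mask, structure=selem, iterations=closing_rounds)
    mask = ndi.binary_erosion(mask, structure=selem, iterations=closing_rounds)
    return mask


# ---------------------------------------------------------------------------
# Skeleton graph


@dataclass
class LatticeSkeleton:
    """3D graph of triskelion hubs and arms with polygon faces.

    ``vertices`` are (N, 3) positions in nm; ``edges`` index pairs;
    ``faces`` are simple cycles (vertex index lists) of the minimal polygons.
    A triskelion hub is a degree-3 vertex.  Arm counts: ``n_total`` arms
    (edges), ``n_open_arms`` arms with a free (degree-1) end, and
    ``n_poly_arms = n_total - n_open_arms`` polymerized arms.
    """

    vertices: np.ndarray
    edges: List[Tuple[int, int]]
    faces: List[List[int]] = field(default_factory=list)
    pentagon_count: Optional[int] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.edges = [tuple(sorted((int(i), int(j)))) for i, j in self.edges]
        if self.pentagon_count is None:
            self.pentagon_count = sum(1 for f in self.faces if len(f) == 5)

    @property
    def n_total(self) -> int:
        return len(self.edges)

    @property
    def n_open_arms(self) -> int:
        deg = self.degrees()
        return sum(1 for i, j in self.edges if deg[i] == 1 or deg[j] == 1)

    @property
    def n_poly_arms(self) -> int:
        return self.n_total - self.n_open_arms

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.vertices), dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def hubs(self) -> List[int]:
        """Indices of triskelion hubs (degree-3 vertices)."""
        deg = self.degrees()
        return [i for i in range(len(self.vertices)) if deg[i] == 3]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.vertices)))
        g.add_edges_from(self.edges)
        return g

    def face_sizes(self) -> List[int]:
        return [len(f) for f in self.faces]


def planar_faces(positions: np.ndarray, edges: Sequence[Tuple[int, int]]) -> List[List[int]]:
    """Minimal polygon faces of a geometrically embedded planar graph.

    Traverses directed half-edges, at each vertex continuing with the next
    neighbour in clockwise order after the incoming direction — the standard
    face-tracing rule for a planar subdivision.  Bounded (interior) faces are
    returned as simple cycles; the unbounded outer walk and walks around
    dangling trees are discarded.
    """
    xy = positions[:, :2]
    adj = {i: [] for i in range(len(positions))}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    for v, nbrs in adj.items():
        nbrs.sort(key=lambda u: math.atan2(xy[u][1] - xy[v][1], xy[u][0] - xy[v][0]))
    visited = set()
    faces = []
    for i, j in edges:
        for tail, head in ((i, j), (j, i)):
            if (tail, head) in visited:
                continue
            walk = [tail]
            u, v = tail, head
            while True:
                visited.add((u, v))
                walk.append(v)
                nbrs = adj[v]
                k = nbrs.index(u)
                u, v = v, nbrs[(k - 1) % len(nbrs)]  # next edge clockwise
                if (u, v) == (tail, head):
                    break
            cycle = walk[:-1]
            if len(cycle) < 3 or len(set(cycle)) != len(cycle):
                continue
            # signed area: interior faces come out counter-clockwise (+)
            pts = xy[cycle]
            area = 0.5 * float(np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                                      - np.roll(pts[:, 0], -1) * pts[:, 1]))
            if area > 0:
                faces.append([int(c) for c in cycle])
    return faces


def _trace_paths(skel: np.ndarray, node_label: np.ndarray):
    """Walk skeleton pixels between labelled node clusters.

    ``node_label`` > 0 marks junction/endpoint clusters.  Returns a list of
    (label_a, label_b, path_pixels) arcs; isolated cycles (no nodes) are
    returned separately as ordered pixel loops.
    """
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    H, W = skel.shape

    def neighbours(p):
        r, c = p
        out = []
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and skel[rr, cc]:
                out.append((rr, cc))
        return out

    arcs = []
    used = set()
    node_pixels = list(zip(*np.nonzero(node_label > 0)))
    for p in node_pixels:
        for q in neighbours(p):
            if node_label[q] == node_label[p] and node_label[q] > 0:
                continue
            if (p, q) in used:
                continue
            path = [p]
            prev, cur = p, q
            used.add((p, q))
            used.add((q, p))
            while node_label[cur] == 0:
                path.append(cur)
                nxts = [n for n in neighbours(cur)
                        if n != prev and (cur, n) not in used]
                if not nxts:
                    cur = None
                    break
                prev, cur = cur, nxts[0]
                used.add((prev, cur))
                used.add((cur, prev))
            if cur is None:
                continue
            path.append(cur)
            arcs.append((int(node_label[p]), int(node_label[cur]), path))
    # isolated cycles: skeleton pixels never reached from any node
    reached = set()
    for _, _, path in arcs:
        reached.update(path)
    loops = []
    remaining = set(zip(*np.nonzero(skel))) - reached - set(node_pixels)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        remaining.discard(start)
        prev, cur = None, start
        while True:
            nbrs = [n for n in neighbours(cur) if n != prev and n in remaining]
            if not nbrs:
                break
            prev, cur = cur, nbrs[0]
            loop.append(cur)
            remaining.discard(cur)
        if len(loop) >= 3:
            loops.append(loop)
    return arcs, loops


def _prune_collinear(ring: np.ndarray, tol: float) -> np.ndarray:
    """Drop ring points closer than ``tol`` to the chord of their neighbours.

    Cleans up the arbitrary seam point and rasterization doublets that
    polygon simplification leaves on closed loops.
    """
    pts = list(map(tuple, ring))
    changed = True
    while changed and len(pts) > 3:
        changed = False
        for i in range(len(pts)):
            a = np.array(pts[i - 1])
            c = np.array(pts[i])
            b = np.array(pts[(i + 1) % len(pts)])
            ab = b - a
            denom = np.linalg.norm(ab)
            ac = c - a
            d = (np.linalg.norm(ac) if denom < 1e-9
                 else abs(ab[0] * ac[1] - ab[1] * ac[0]) / denom)
            if d < tol:
                pts.pop(i)
                changed = True
                break
    return np.array(pts)


def _vertex_height(t: Topograph, r: int, c: int, win: int = 2) -> float:
    r0, r1 = max(0, r - win), min(t.shape[0], r + win + 1)
    c0, c1 = max(0, c - win), min(t.shape[1], c + win + 1)
    return float(np.max(t.relative_heights()[r0:r1, c0:c1]))


def build_skeleton(mask: np.ndarray, t: Topograph, merge_radius: int = 2,
                   simplify_tol: float = 2.0, min_spur_px: int = 4) -> LatticeSkeleton:
    """Thin a ridge mask to a 1-pixel skeleton and build the hub/arm graph.

    Junction pixels (>= 3 skeleton neighbours) within ``merge_radius`` pixels
    are merged into single hub nodes, since AFM hub blobs span more than one
    pixel; endpoints become open-arm terminals, except spurs shorter than
    ``min_spur_px`` pixels, which are thinning artifacts and are pruned.
    Arcs between nodes are simplified to their corner points
    (Douglas-Peucker, ``simplify_tol`` pixels), so bends along boundary
    ridges become degree-2 vertices rather than being cut off.  Vertex 3D
    positions are (x, y, local max height) in nm; faces are the minimal
    polygons of the planar-embedded graph.
    """
    skel = morphology.skeletonize(mask.astype(bool))
    if not skel.any():
        return LatticeSkeleton(vertices=np.zeros((0, 3)), edges=[], faces=[])
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nb = ndi.convolve(skel.astype(int), kernel, mode="constant")
    junctions = skel & (nb >= 3)
    endpoints = skel & (nb == 1)

    # cluster junction pixels within merge_radius into hub nodes
    merged = ndi.binary_dilation(junctions, structure=morphology.disk(merge_radius))
    jlab, njunc = ndi.label(merged)
    jlab = np.where(junctions, jlab, 0)
    node_label = np.zeros_like(jlab)
    node_label[junctions] = jlab[junctions]
    next_label = njunc + 1
    endpoint_labels = set()
    for r, c in zip(*np.nonzero(endpoints)):
        if node_label[r, c] == 0:
            node_label[r, c] = next_label
            endpoint_labels.add(next_label)
            next_label += 1

    arcs, loops = _trace_paths(skel, node_label)
    arcs = [(la, lb, path) for la, lb, path in arcs
            if not ((la in endpoint_labels or lb in endpoint_labels)
                    and (la in endpoint_labels) != (lb in endpoint_labels)
                    and len(path) <= min_spur_px)]

    ps = t.pixel_size
    verts: List[Tuple[float, float, float]] = []
    label2idx = {}

    def add_vertex(rr: float, cc: float) -> int:
        verts.append((cc * ps, rr * ps, _vertex_height(t, int(round(rr)), int(round(cc)))))
        return len(verts) - 1

    label_pixels = {}
    for r, c in zip(*np.nonzero(node_label > 0)):
        label_pixels.setdefault(int(node_label[r, c]), []).append((int(r), int(c)))

    def node_index(label: int) -> int:
        if label not in label2idx:
            pixels = label_pixels[label]
            rr = float(np.mean([p[0] for p in pixels]))
            cc = float(np.mean([p[1] for p in pixels]))
            label2idx[label] = add_vertex(rr, cc)
        return label2idx[label]

    edges = set()
    for la, lb, path in arcs:
        ia = node_index(la)
        ib = node_index(lb)
        pts = np.asarray(path, dtype=float)
        chain = [ia]
        if len(pts) > 2:
            poly = measure.approximate_polygon(pts, tolerance=simplify_tol)
            for r, c in poly[1:-1]:  # interior corner points become vertices
                chain.append(add_vertex(r, c))
        chain.append(ib)
        for k in range(len(chain) - 1):
            if chain[k] != chain[k + 1]:
                edges.add(tuple(sorted((chain[k], chain[k + 1]))))
    # polyline loops without junctions: corner vertices via polygon simplification
    for loop in loops:
        pts = np.array(loop, dtype=float)
        poly = measure.approximate_polygon(np.vstack([pts, pts[:1]]), tolerance=simplify_tol)
        corners = poly[:-1] if np.allclose(poly[0], poly[-1]) else poly
        corners = _prune_collinear(corners, simplify_tol)
        if len(corners) < 3:
            corners = pts[:: max(1, len(pts) // 3)][:3]
        idxs = []
        for r, c in corners:
            verts.append((c * ps, r * ps, _vertex_height(t, int(round(r)), int(round(c)))))
            idxs.append(len(verts) - 1)
        for k in range(len(idxs)):
            edges.add(tuple(sorted((idxs[k], idxs[(k + 1) % len(idxs)]))))

    vertices = np.array(verts, dtype=float).reshape(-1, 3)
    edge_list = sorted(edges)
    faces = planar_faces(vertices, edge_list) if len(edge_list) >= 3 else []
    return LatticeSkeleton(vertices=vertices, edges=edge_list, faces=faces)


# ---------------------------------------------------------------------------
# Section profiles


@dataclass
class SectionProfile:
    """Height profile along a line with local circle-fit curvature."""

    distance: np.ndarray  # nm along the section
    height: np.ndarray  # nm above zero level
    curvature: np.ndarray  # 1/nm, signed (+ = convex protrusion), NaN at ends

    def apex_radius(self, rel_height: float = 0.3) -> float:
        """Circle-fit radius (nm) of the contiguous apex region.

        Fits a circle to the profile points around the highest point whose
        height exceeds ``rel_height`` times the apex height.
        """
        imax = int(np.argmax(self.height))
        thr = rel_height * self.height[imax]
        lo = imax
        while lo > 0 and self.height[lo - 1] >= thr:
            lo -= 1
        hi = imax
        while hi < len(self.height) - 1 and self.height[hi + 1] >= thr:
            hi += 1
        if hi - lo < 4:
            return math.inf
        _, _, r = _circle_fit(self.distance[lo:hi + 1], self.height[lo:hi + 1])
        return r


def _circle_fit(s: np.ndarray, z: np.ndarray) -> Tuple[float, float, float]:
    """Algebraic (Kasa) circle fit in the (s, z) plane -> (cs, cz, R)."""
    M = np.column_stack([s, z, np.ones_like(s)])
    b = s**2 + z**2
    coef, *_ = np.linalg.lstsq(M, b, rcond=None)
    cs, cz = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + cs**2 + cz**2
    if r2 <= 0:
        return cs, cz, math.inf
    return float(cs), float(cz), math.sqrt(float(r2))


def section_profile(
    t: Topograph,
    start: Tuple[float, float],
    end: Tuple[float, float],
    curvature_window: int = 11,
) -> SectionProfile:
    """Bilinear height profile along a segment given in nm coordinates.

    ``start``/``end`` are (x, y) points in nm; samples are spaced one pixel
    apart.  Local curvature at each sample is the inverse radius of a circle
    fitted over a ``curvature_window``-sample window, signed positive where
    the profile bulges upward.
    """
    (x0, y0), (x1, y1) = start, end
    ps = t.pixel_size
    length = math.hypot(x1 - x0, y1 - y0)
    if length <= 0:
        raise ValueError("zero-length section line")
    n = int(math.ceil(length / ps)) + 1
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    rows = ys / ps
    cols = xs / ps
    if (rows.min() < -0.5 or cols.min() < -0.5 or
            rows.max() > t.shape[0] - 0.5 or cols.max() > t.shape[1] - 0.5):
        raise ValueError("section line endpoints out of bounds")
    z = ndi.map_coordinates(t.relative_heights(), [rows, cols], order=1, mode="nearest")
    s = np.linspace(0.0, length, n)
    half = curvature_window // 2
    curv = np.full(n, np.nan)
    for i in range(half, n - half):
        ss = s[i - half:i + half + 1]
        zz = z[i - half:i + half + 1]
        if np.ptp(zz) < 1e-9:
            curv[i] = 0.0
            continue
        _, cz, r = _circle_fit(ss, zz)
        if math.isinf(r):
            curv[i] = 0.0
        else:
            sign = 1.0 if cz < np.mean(zz) else -1.0
            curv[i] = sign / r
    return SectionProfile(distance=s, height=z, curvature=curv)


def analyze_topograph(
    t: Topograph,
    params: Optional[ModelParams] = None,
    seeds: Optional[Sequence[Tuple[int, int]]] = None,
    **seed_kw,
) -> Tuple[List[CCPRecord], LatticeSkeleton]:
    """Level, fit all detectable pits, and skeletonize the lattice of one image."""
    t = level_background(t)
    if seeds is None:
        seeds = detect_seeds(t, **seed_kw)
    records = []
    for s in seeds:
        try:
            records.append(fit_sphere(t, s, params=params))
        except SphereFitError:
            continue
    mask = detect_lattice(t)
    skel = build_skeleton(mask, t)
    return records, skel
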