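"""Synthetic AFM-like topographs of clathrin-coated pits with known truth.

Every input the analysis pipeline consumes can be generated here with its
ground truth attached:

* :func:`sample_population` draws (A, R) cap populations from a
  Boltzmann-style distribution over the energy landscape (an effective-
  temperature device for producing realistic-looking clouds, not a physical
  claim);
* :func:`build_cap_lattice` tiles a spherical cap with a hexagon-dominant
  polygonal mesh (pentagonal insertions appear in proportion to the
  subtended solid angle, 12 for a closed sphere by Euler's formula);
* :func:`render_topograph` rasterizes membrane + cap + lattice ridges,
  applies tip dilation with a spherical tip, and adds pixel noise —
  emulating unroofed-membrane HS-AFM imaging geometry (300 x 300 pixels,
  2 nm pixels by default);
* :func:`simulate_nanodissection` removes lattice edges and relaxes the
  resulting fragments at constant area, reproducing the energetics of
  nanodissection-induced curvature increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import SphericalVoronoi

from .energy import (
    ModelParams,
    clath_bend_energy,
    landscape,
    memb_bend_energy,
    memb_tension_energy,
    relax_at_constant_area,
)
from .geometry import SphericalCap
from .morphometry import LatticeSkeleton, Topograph

__all__ = [
    "SyntheticTruth",
    "DissectionRecord",
    "sample_population",
    "build_cap_lattice",
    "build_flat_honeycomb",
    "render_topograph",
    "simulate_nanodissection",
    "generate_benchmark",
]

#: Hexagon area for a given edge length: (3*sqrt(3)/2) * e^2
_HEX_AREA = 1.5 * math.sqrt(3.0)


@dataclass
class SyntheticTruth:
    """Ground truth of one rendered pit: cap, lattice mesh, render settings."""

    cap: Optional[SphericalCap]  # None renders a flat membrane (lattice only)
    mesh: Optional[LatticeSkeleton] = None
    pentagon_count: int = 0
    ridge_height: float = 2.0  # nm above the local surface
    tip_radius: float = 2.0  # nm
    noise_sd: float = 0.1  # nm
    pixel_size: float = 2.0  # nm/pixel
    shape: Tuple[int, int] = (300, 300)
    seed: int = 0


def sample_population(
    p: ModelParams,
    n: int,
    T_eff: float = 300.0,
    seed: int = 0,
    grid_resolution: Tuple[int, int] = (300, 300),
    A_range: Tuple[float, float] = (1e2, 1e5),
    R_range: Tuple[float, float] = (10.0, 400.0),
) -> List[SphericalCap]:
    """Draw ``n`` caps with probability proportional to exp(-E_total/T_eff).

    ``T_eff`` is an effective temperature in kBT controlling how far the
    population spreads above the landscape minimum; it is a sampling device
    for generating test populations that occupy the observed low-energy
    region, not a physical temperature.  Deterministic per ``seed``.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if not T_eff > 0:
        raise ValueError("effective temperature must be positive")
    grid = landscape(p, A_range=A_range, R_range=R_range, resolution=grid_resolution)
    E = grid.E[grid.valid]
    idx_valid = np.argwhere(grid.valid)
    w = np.exp(-(E - np.min(E)) / T_eff)
    w /= w.sum()
    rng = np.random.default_rng(seed)
    choice = rng.choice(len(w), size=n, p=w)
    logA = np.log10(grid.A)
    logR = np.log10(grid.R)
    dA = logA[1] - logA[0]
    dR = logR[1] - logR[0]
    caps = []
    for k in choice:
        i, j = idx_valid[k]
        a = 10 ** (logA[i] + rng.uniform(-0.5, 0.5) * dA)
        r = 10 ** (logR[j] + rng.uniform(-0.5, 0.5) * dR)
        a = min(a, 4.0 * math.pi * r**2)
        caps.append(SphericalCap.from_R_A(R=r, A=a))
    return caps


def _geodesic_sphere(n_target: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform unit-sphere points from a subdivided icosahedron.

    Returns the ``10*f**2 + 2`` vertices of the frequency-``f`` geodesic
    icosahedron with ``f`` chosen so the count is closest to ``n_target``,
    randomly rotated.  The Voronoi dual of this point set is a
    Goldberg-type mesh: exactly 12 pentagonal cells, all others hexagonal —
    the defect structure of real clathrin cages and soccer-ball vesicles.
    """
    f = max(int(round(math.sqrt(max(n_target - 2, 10) / 10.0))), 1)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    base = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    base /= np.linalg.norm(base[0])
    tris = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    pts = {}
    for a, b, c in tris:
        va, vb, vc = base[a], base[b], base[c]
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                v = (i * va + j * vb + k * vc) / f
                v /= np.linalg.norm(v)
                pts[tuple(np.round(v, 9))] = v
    arr = np.array(list(pts.values()))
    # random rotation so different seeds orient the pentagon sites differently
    q = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(q)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return arr @ Q.T


def _lloyd_relax(points: np.ndarray, iterations: int) -> SphericalVoronoi:
    """Centroidal Voronoi relaxation on the unit sphere."""
    sv = None
    for _ in range(max(iterations, 0)):
        sv = SphericalVoronoi(points, radius=1.0)
        sv.sort_vertices_of_regions()
        new_pts = np.empty_like(points)
        for i, reg in enumerate(sv.regions):
            c = sv.vertices[reg].mean(axis=0)
            nrm = np.linalg.norm(c)
            new_pts[i] = c / nrm if nrm > 0 else points[i]
        points = new_pts
    sv = SphericalVoronoi(points, radius=1.0)
    sv.sort_vertices_of_regions()
    return sv


def build_cap_lattice(
    cap: SphericalCap,
    edge_length: float = 18.0,
    seed: int = 0,
    lloyd_iterations: int = 20,
) -> Tuple[LatticeSkeleton, int]:
    """Hexagon-dominant polygonal mesh draped on a spherical cap.

    Generator points are placed quasi-uniformly over the full support sphere
    (geodesic-icosahedral seeding followed by Lloyd relaxation, which keeps
    the Goldberg combinatorics: exactly 12 pentagonal cells on the closed
    sphere, all others hexagonal), then dualized on the sphere: the Voronoi
    cells are the lattice polygons, their vertices the degree-3 triskelion
    hubs.  Cells whose generator lies on the cap are kept, so the pentagon
    count scales with the subtended solid angle.

    ``edge_length`` is the arm (polygon edge) length in nm, clathrin scale
    10..30 nm.  The mesh is returned in cap coordinates (base plane z = 0,
    apex at z = h) together with its pentagon count.
    """
    if not (10.0 <= edge_length <= 30.0):
        raise ValueError("edge_length must be in [10, 30] nm (clathrin scale)")
    cell_area = _HEX_AREA * edge_length**2
    if cap.A < cell_area:
        raise ValueError("cap too small to carry a single lattice cell")
    R = cap.R
    n_target = max(int(round(4.0 * math.pi * R**2 / cell_area)), 12)
    rng = np.random.default_rng(seed)
    pts = _geodesic_sphere(n_target, rng)
    n_pts = len(pts)
    sv = _lloyd_relax(pts, lloyd_iterations)

    z_cut = 1.0 - cap.h / R  # generators with z >= z_cut lie on the cap
    keep = [i for i in range(n_pts) if sv.points[i, 2] >= z_cut]
    if not keep:
        raise ValueError("cap too small to carry a single lattice cell")
    used_vertices = sorted({v for i in keep for v in sv.regions[i]})
    vmap = {v: k for k, v in enumerate(used_vertices)}
    verts = sv.vertices[used_vertices] * R
    verts[:, 2] -= R - cap.h  # base plane to z = 0
    edges = set()
    faces = []
    for i in keep:
        reg = sv.regions[i]
        faces.append([vmap[v] for v in reg])
        for k in range(len(reg)):
            edges.add(tuple(sorted((vmap[reg[k]], vmap[reg[(k + 1) % len(reg)]]))))
    pentagons = sum(1 for i in keep if len(sv.regions[i]) == 5)
    mesh = LatticeSkeleton(vertices=verts, edges=sorted(edges), faces=faces,
                           pentagon_count=pentagons)
    return mesh, pentagons


def build_flat_honeycomb(n_rings: int = 2, edge_length: float = 18.0) -> LatticeSkeleton:
    """Planar honeycomb patch of ``1 + 3*n_rings*(n_rings+1)`` hexagonal cells.

    ``n_rings = 2`` gives the canonical 19-hexagon patch.  Vertices are 3D
    points at z = 0 centred on the origin; all interior hubs have degree 3.
    """
    e = edge_length
    centers = []
    for q in range(-n_rings, n_rings + 1):
        for r in range(-n_rings, n_rings + 1):
            if abs(q + r) > n_rings:
                continue
            cx = e * math.sqrt(3.0) * (q + r / 2.0)
            cy = e * 1.5 * r
            centers.append((cx, cy))
    verts: List[Tuple[float, float, float]] = []
    vindex = {}

    def vid(x, y):
        key = (round(x, 6), round(y, 6))
        if key not in vindex:
            verts.append((x, y, 0.0))
            vindex[key] = len(verts) - 1
        return vindex[key]

    edges = set()
    faces = []
    for cx, cy in centers:
        ids = []
        for k in range(6):
            ang = math.pi / 6.0 + k * math.pi / 3.0  # pointy-top hexagon
            ids.append(vid(cx + e * math.cos(ang), cy + e * math.sin(ang)))
        faces.append(ids)
        for k in range(6):
            edges.add(tuple(sorted((ids[k], ids[(k + 1) % 6]))))
    return LatticeSkeleton(vertices=np.array(verts), edges=sorted(edges), faces=faces)


# ---------------------------------------------------------------------------
# Rendering


def _cap_height_field(cap: SphericalCap, X: np.ndarray, Y: np.ndarray,
                      cx: float, cy: float) -> np.ndarray:
    """Top-surface height of the cap over the base plane (AFM sees the max z)."""
    R, h = cap.R, cap.h
    zc = h - R  # sphere centre height
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    top = zc + np.sqrt(np.maximum(R**2 - r2, 0.0))
    footprint = cap.footprint_radius
    return np.where(r2 <= footprint**2 + 1e-12, np.maximum(top, 0.0), 0.0)


def _tip_structure(tip_radius: float, pixel_size: float):
    """Spherical-tip structuring function for grayscale dilation."""
    rad_px = int(math.floor(tip_radius / pixel_size))
    if rad_px < 1:
        return None, None
    ax = np.arange(-rad_px, rad_px + 1) * pixel_size
    DX, DY = np.meshgrid(ax, ax)
    d2 = DX**2 + DY**2
    fp = d2 <= tip_radius**2
    struct = np.where(fp, np.sqrt(np.maximum(tip_radius**2 - d2, 0.0)) - tip_radius, 0.0)
    return fp, struct


def render_topograph(truth: SyntheticTruth, center: Optional[Tuple[float, float]] = None) -> Topograph:
    """Rasterize a synthetic pit into an AFM-like height map.

    The height at each pixel is the maximum of the flat membrane (z = 0),
    the cap top surface, and the lattice ridges raised ``ridge_height`` above
    the local surface; the map is then grayscale-dilated with a spherical
    tip of radius ``tip_radius`` (the standard tip-convolution model, which
    widens but never narrows features) and Gaussian pixel noise of sd
    ``noise_sd`` is added.  Raises if the cap footprint does not fit in the
    frame.
    """
    ny, nx = truth.shape
    ps = truth.pixel_size
    # default centre on a pixel centre so the apex is sampled exactly
    cx = (nx // 2) * ps if center is None else center[0]
    cy = (ny // 2) * ps if center is None else center[1]
    xs = np.arange(nx) * ps
    ys = np.arange(ny) * ps
    X, Y = np.meshgrid(xs, ys)
    if truth.cap is not None:
        foot = truth.cap.footprint_radius
        if (cx - foot < 0 or cy - foot < 0
                or cx + foot > (nx - 1) * ps or cy + foot > (ny - 1) * ps):
            raise ValueError("cap footprint exceeds the frame")
        H = _cap_height_field(truth.cap, X, Y, cx, cy)
    else:
        H = np.zeros((ny, nx))

    if truth.mesh is not None and len(truth.mesh.edges):
        surf = H
        verts = truth.mesh.vertices
        for i, j in truth.mesh.edges:
            p0, p1 = verts[i], verts[j]
            npts = max(int(math.ceil(np.linalg.norm(p1[:2] - p0[:2]) / (0.5 * ps))), 2)
            ts = np.linspace(0.0, 1.0, npts)
            px = p0[0] + ts * (p1[0] - p0[0]) + cx
            py = p0[1] + ts * (p1[1] - p0[1]) + cy
            cc = np.clip(np.round(px / ps).astype(int), 0, nx - 1)
            rr = np.clip(np.round(py / ps).astype(int), 0, ny - 1)
            zr = surf[rr, cc] + truth.ridge_height
            np.maximum.at(H, (rr, cc), zr)

    if truth.tip_radius > 0:
        fp, struct = _tip_structure(truth.tip_radius, ps)
        if fp is not None:
            H = ndi.grey_dilation(H, footprint=fp, structure=struct)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        H = H + rng.normal(0.0, truth.noise_sd, size=H.shape)
    return Topograph(heights=H, pixel_size=ps, zero_level=0.0,
                     image_id=f"synthetic-seed{truth.seed}")


# ---------------------------------------------------------------------------
# Nanodissection


@dataclass(frozen=True)
class DissectionRecord:
    """Before/after state of one lattice fragment produced by edge cuts."""

    component: int
    n_faces: int
    A: float  # nm^2, from the face count (3 arm-arm interactions per cell)
    R_before: float
    R_after: float
    E_elastic_before: float
    E_elastic_after: float

    @property
    def dE_elastic(self) -> float:
        return self.E_elastic_after - self.E_elastic_before


def _elastic_energy(A: float, R: float, p: ModelParams) -> float:
    """Bending + tension energy (kBT); R may be inf for a flat lattice."""
    if math.isinf(R):
        e = A * (p.kappa_clath / 2.0) * (2.0 / p.R_clath) ** 2
        if not math.isinf(p.R_memb):
            e += A * (p.kappa_memb / 2.0) * (2.0 / p.R_memb) ** 2
        return e
    return float(memb_bend_energy(A, R, p) + memb_tension_energy(A, R, p)
                 + clath_bend_energy(A, R, p))


def simulate_nanodissection(
    truth: SyntheticTruth,
    cut_edges: Sequence[Tuple[int, int]],
    p: ModelParams,
    R_before: Optional[float] = None,
) -> List[DissectionRecord]:
    """Cut lattice arms and relax each resulting fragment at constant area.

    ``cut_edges`` must be edges of ``truth.mesh``.  After removal, each
    connected component keeps the faces all of whose corners it retains; the
    component coat area is ``n_faces * 3 * A_clath`` (three arm-arm
    interactions per lattice unit cell).  Each fragment then relaxes to the
    constant-area optimal radius, which can only lower the elastic
    (bending + tension) energy; fragments with no complete face are dropped.
    ``R_before`` defaults to the truth cap radius; pass ``inf`` for an
    initially flat lattice.
    """
    if truth.mesh is None:
        raise ValueError("truth carries no lattice mesh")
    mesh = truth.mesh
    edge_set = set(mesh.edges)
    cuts = [tuple(sorted((int(i), int(j)))) for i, j in cut_edges]
    for e in cuts:
        if e not in edge_set:
            raise ValueError(f"cut edge {e} is not a mesh edge")
    g = nx.Graph()
    g.add_nodes_from(range(len(mesh.vertices)))
    g.add_edges_from(e for e in mesh.edges if e not in set(cuts))
    r_before = truth.cap.R if R_before is None else float(R_before)
    records = []
    for ci, comp in enumerate(nx.connected_components(g)):
        n_faces = sum(1 for f in mesh.faces if set(f) <= comp)
        if n_faces == 0:
            continue
        A = n_faces * 3.0 * p.A_clath
        r_after = relax_at_constant_area(A, p)
        e_before = _elastic_energy(A, max(r_before, math.sqrt(A / (4 * math.pi))), p)
        e_after = _elastic_energy(A, r_after, p)
        records.append(DissectionRecord(
            component=ci, n_faces=n_faces, A=A,
            R_before=r_before, R_after=r_after,
            E_elastic_before=e_before, E_elastic_after=e_after,
        ))
    return records


# ---------------------------------------------------------------------------
# Benchmark batch


def generate_benchmark(
    n: int = 50,
    R_range: Tuple[float, float] = (40.0, 300.0),
    seed: int = 0,
    with_mesh: bool = True,
    shape: Tuple[int, int] = (300, 300),
    pixel_size: float = 2.0,
    ridge_height: float = 2.0,
    tip_radius: float = 2.0,
    noise_sd: float = 0.1,
    margin: float = 40.0,
) -> List[SyntheticTruth]:
    """Seeded batch of synthetic pits spanning a radius range.

    Radii are log-uniform over ``R_range``; aspect ratios h/R are uniform in
    [0.25, 0.9], capped so the cap footprint stays ``margin`` nm inside the
    frame.  Each pit gets its own derived seed, so the batch is reproducible
    as a whole and per item.
    """
    rng = np.random.default_rng(seed)
    half_field = (min(shape) - 1) / 2.0 * pixel_size - margin
    truths = []
    for k in range(n):
        R = 10 ** rng.uniform(math.log10(R_range[0]), math.log10(R_range[1]))
        # max h with footprint <= half_field: h*(2R-h) <= half_field^2
        if R <= half_field:
            h_max = 0.95 * R
        else:
            h_max = R - math.sqrt(R**2 - half_field**2)
        aspect = rng.uniform(0.25, 0.9)
        h = min(aspect * R, 0.95 * h_max)
        cap = SphericalCap(R=R, h=h)
        mesh = None
        pent = 0
        if with_mesh:
            mesh, pent = build_cap_lattice(cap, seed=int(rng.integers(2**31 - 1)))
        truths.append(SyntheticTruth(
            cap=cap, mesh=mesh, pentagon_count=pent,
            ridge_height=ridge_height, tip_radius=tip_radius, noise_sd=noise_sd,
            pixel_size=pixel_size, shape=shape, seed=int(rng.integers(2**31 - 1)),
        ))
    return truths
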