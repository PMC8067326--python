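"""Simplicial discretizations of mitochondrial model domains.

Supported outer shapes are the 2D disk and ellipse and the 3D sphere and
ellipsoid; calcium phosphate granules are circular/spherical holes cut out
of the domain (volume exclusion), whose internal boundary is tagged
separately so the solver can pin the order parameter there.

Meshes are produced by a force-equilibrium mesher in the style of
Persson & Strang's distmesh: points seeded on a lattice inside a signed
distance function, relaxed by edge "spring" forces, retriangulated with
scipy's Delaunay, and projected back onto the zero level set of the
distance function when they escape.  Axis convention for the ellipse and
ellipsoid: ``size_params`` are FULL axis lengths (an ellipse "10 by 8" has
semi-axes 5 and 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from math import factorial, pi

import numpy as np
from scipy.spatial import Delaunay

from ._fem import FemOps, boundary_facet_array

OUTER = -1  # tag value for the outer boundary Γ; granules are tagged 0, 1, ...

_SHAPE_DIMS = {"disk": 2, "ellipse": 2, "sphere": 3, "ellipsoid": 3}

DEFAULT_H = 0.15


class MeshError(RuntimeError):
    """Mesh generation failed or produced an unusable mesh."""


class ResolutionError(ValueError):
    """Target edge length too coarse for the requested features."""


class GranuleValidationError(ValueError):
    """Granules overlap each other or leave the outer shape."""

    def __init__(self, report: "GranuleValidationReport"):
        self.report = report
        super().__init__("invalid granule layout:\n" + "\n".join(report.violations))


@dataclass(frozen=True)
class GranuleSpec:
    """A calcium phosphate granule: excluded ball with a pinned boundary value.

    ``pinned_value`` is the constant C imposed on the order parameter on the
    granule surface (C = +1 surrounds the granule with matrix fluid).
    """

    center: tuple
    radius: float
    pinned_value: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.radius <= 0:
            raise ValueError("granule radius must be positive")
        if not -1.0 <= self.pinned_value <= 1.0:
            raise ValueError("pinned value must lie in [-1, 1]")


@dataclass
class GranuleCheck:
    index: int
    inside: bool
    boundary_clearance: float


@dataclass
class GranuleValidationReport:
    """Report-only validation of a granule layout (no mutation, no raise)."""

    checks: list
    pair_clearances: list  # (i, j, clearance)
    min_clearance: float
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass(eq=False)
class Domain:
    """A conforming simplicial mesh with tagged boundary facets.

    ``outer_facets`` carry the zero-flux outer boundary Γ; ``granule_facets``
    maps granule index -> facet array for the pinned internal boundaries Γ′.
    ``element_coords`` may differ from ``nodes[elements]`` only for periodic
    1D meshes, where the wrapped element stores the periodic image.
    """

    dimension: int
    nodes: np.ndarray
    elements: np.ndarray
    outer_facets: np.ndarray
    granule_facets: dict
    granules: list
    h_target: float
    shape_descriptor: dict
    element_coords: np.ndarray = None
    periodic: bool = False

    def __post_init__(self):
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        if self.nodes.shape[1] != self.dimension:
            self.nodes = self.nodes.reshape(-1, self.dimension)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.size == 0:
            raise MeshError("domain has no elements")
        if self.element_coords is None:
            self.element_coords = self.nodes[self.elements]

    @cached_property
    def fem(self) -> FemOps:
        return FemOps(self.element_coords, self.elements, len(self.nodes))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def granule_nodes(self, index: int) -> np.ndarray:
        facets = self.granule_facets.get(index)
        if facets is None or facets.size == 0:
            return np.empty(0, dtype=np.int64)
        return np.unique(facets)

    @cached_property
    def pinned(self) -> tuple:
        """(node indices, pinned values) over all granule boundaries."""
        idx, val = [], []
        for i, g in enumerate(self.granules):
            nodes = self.granule_nodes(i)
            idx.append(nodes)
            val.append(np.full(len(nodes), g.pinned_value))
        if not idx:
            return np.empty(0, dtype=np.int64), np.empty(0)
        return np.concatenate(idx), np.concatenate(val)

    def measure(self) -> float:
        return self.fem.total_measure


# ---------------------------------------------------------------------------
# signed distance functions
# ---------------------------------------------------------------------------

def _semi_axes(shape: str, size_params) -> np.ndarray:
    size = np.asarray(size_params, dtype=float)
    dim = _SHAPE_DIMS[shape]
    if shape in ("disk", "sphere"):
        if size.shape != (1,) or size[0] <= 0:
            raise ValueError(f"{shape} takes one positive radius, got {size_params}")
        return np.full(dim, size[0])
    if size.shape != (dim,) or np.any(size <= 0):
        raise ValueError(f"{shape} takes {dim} positive full-axis lengths, got {size_params}")
    return size / 2.0  # full axis lengths -> semi-axes


def _outer_distance(shape: str, semi: np.ndarray):
    if np.allclose(semi, semi[0]):
        r = float(semi[0])

        def fd(p):
            return np.linalg.norm(p, axis=-1) - r
    else:
        scale = float(semi.min())

        def fd(p):
            q = np.sqrt(np.sum((p / semi) ** 2, axis=-1))
            return (q - 1.0) * scale  # approximate signed distance

    return fd


def _combined_distance(fd_outer, granules):
    centers = np.array([g.center for g in granules], dtype=float) if granules else None
    radii = np.array([g.radius for g in granules], dtype=float) if granules else None

    def fd(p):
        d = fd_outer(p)
        if centers is not None:
            for c, r in zip(centers, radii):
                d = np.maximum(d, r - np.linalg.norm(p - c, axis=-1))
        return d

    return fd


# ---------------------------------------------------------------------------
# distmesh-style relaxation
# ---------------------------------------------------------------------------

def _seed_points(bbox_lo, bbox_hi, h: float, dim: int) -> np.ndarray:
    if dim == 1:
        return np.arange(bbox_lo[0], bbox_hi[0] + h / 2, h)[:, None]
    if dim == 2:
        dy = h * np.sqrt(3.0) / 2.0
        xs = np.arange(bbox_lo[0] - h, bbox_hi[0] + h, h)
        ys = np.arange(bbox_lo[1] - h, bbox_hi[1] + h, dy)
        X, Y = np.meshgrid(xs, ys)
        X[1::2] += h / 2.0  # hex lattice
        return np.column_stack([X.ravel(), Y.ravel()])
    axes = [np.arange(bbox_lo[i] - h, bbox_hi[i] + h, h) for i in range(3)]
    G = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([g.ravel() for g in G])


def _project_to_boundary(fd, pts: np.ndarray, deps: float, n_iter: int = 4) -> np.ndarray:
    pts = pts.copy()
    for _ in range(n_iter):
        d = fd(pts)
        grad = np.empty_like(pts)
        for ax in range(pts.shape[1]):
            shift = np.zeros(pts.shape[1])
            shift[ax] = deps
            grad[:, ax] = (fd(pts + shift) - d) / deps
        g2 = np.sum(grad**2, axis=1)
        g2 = np.where(g2 > 1e-30, g2, 1.0)
        pts -= (d / g2)[:, None] * grad
    return pts


def _unique_edges(simplices: np.ndarray) -> np.ndarray:
    n = simplices.shape[1]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    edges = np.vstack([simplices[:, [i, j]] for i, j in pairs])
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)


def _distmesh(fd, h: float, bbox_lo, bbox_hi, dim: int, max_iter: int = 150):
    geps = 1e-3 * h
    deps = np.sqrt(np.finfo(float).eps) * h
    if dim == 2:
        fscale, deltat = 1.2, 0.2
    else:
        fscale, deltat = 1.1, 0.1
    dptol, ttol = 1e-3, 0.1

    p = _seed_points(np.asarray(bbox_lo), np.asarray(bbox_hi), h, dim)
    p = p[fd(p) < geps]
    if len(p) <= dim + 1:
        raise MeshError("too few seed points; reduce h_target")

    pold = np.full_like(p, np.inf)
    simp = None
    bars = None
    for _ in range(max_iter):
        if np.max(np.linalg.norm(p - pold, axis=1)) > ttol * h:
            pold = p.copy()
            tri = Delaunay(p)
            simp = tri.simplices
            cent = p[simp].mean(axis=1)
            simp = simp[fd(cent) < -geps]
            if len(simp) == 0:
                raise MeshError("empty triangulation; reduce h_target")
            bars = _unique_edges(simp)

        barvec = p[bars[:, 0]] - p[bars[:, 1]]
        L = np.linalg.norm(barvec, axis=1)
        L0 = fscale * (np.sum(L**dim) / len(L)) ** (1.0 / dim)
        Fmag = np.maximum(L0 - L, 0.0)
        Fvec = (Fmag / np.maximum(L, 1e-30))[:, None] * barvec
        Ftot = np.zeros_like(p)
        np.add.at(Ftot, bars[:, 0], Fvec)
        np.add.at(Ftot, bars[:, 1], -Fvec)
        p = p + deltat * Ftot

        d = fd(p)
        out = d > 0
        if np.any(out):
            p[out] = _project_to_boundary(fd, p[out], deps)
        interior = d < -geps
        if interior.any():
            move = deltat * np.linalg.norm(Ftot[interior], axis=1).max()
            if move < dptol * h:
                break

    tri = Delaunay(p)
    simp = tri.simplices
    cent = p[simp].mean(axis=1)
    simp = simp[fd(cent) < -geps]

    # Drop degenerate slivers that would break the P1 operators.
    ec = p[simp]
    J = ec[:, 1:, :] - ec[:, :1, :]
    meas = np.abs(np.linalg.det(J)) / factorial(dim)
    simp = simp[meas > 1e-9 * h**dim]

    used = np.unique(simp)
    remap = -np.ones(len(p), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return p[used], remap[simp]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def validate_granules(shape: str, size_params, granules, h_target: float = DEFAULT_H
                      ) -> GranuleValidationReport:
    """Check granule placement; reports problems instead of raising."""
    semi = _semi_axes(shape, size_params)
    fd_outer = _outer_distance(shape, semi)
    granules = list(granules)
    checks, pairs, violations = [], [], []
    min_clear = np.inf
    for i, g in enumerate(granules):
        c = np.asarray(g.center, dtype=float)
        if c.shape != semi.shape:
            raise ValueError(f"granule {i} center has dimension {c.size}, expected {semi.size}")
        clearance = float(-fd_outer(c[None, :])[0] - g.radius)
        inside = clearance > 0
        checks.append(GranuleCheck(index=i, inside=inside, boundary_clearance=clearance))
        min_clear = min(min_clear, clearance)
        if clearance < h_target:
            violations.append(
                f"granule {i}: clearance to outer boundary {clearance:.4g} < h_target {h_target:g}")
    for i in range(len(granules)):
        for j in range(i + 1, len(granules)):
            ci = np.asarray(granules[i].center)
            cj = np.asarray(granules[j].center)
            clearance = float(np.linalg.norm(ci - cj) - granules[i].radius - granules[j].radius)
            pairs.append((i, j, clearance))
            min_clear = min(min_clear, clearance)
            if clearance < h_target:
                violations.append(
                    f"granules {i},{j}: pairwise clearance {clearance:.4g} < h_target {h_target:g}")
    if not granules:
        min_clear = np.inf
    return GranuleValidationReport(checks=checks, pair_clearances=pairs,
                                   min_clearance=float(min_clear), violations=violations)


def _tag_boundary(nodes, elements, granules, h):
    facets = boundary_facet_array(elements)
    if facets.size == 0:
        return facets.reshape(0, elements.shape[1] - 1), {}
    granule_facets = {}
    assigned = np.zeros(len(facets), dtype=bool)
    tol = 0.25 * h
    for i, g in enumerate(granules):
        c = np.asarray(g.center)
        dev = np.abs(np.linalg.norm(nodes[facets] - c, axis=-1) - g.radius)
        on_g = np.all(dev < tol, axis=-1) & ~assigned
        granule_facets[i] = facets[on_g]
        assigned |= on_g
    outer = facets[~assigned]
    return outer, granule_facets


def build_domain(shape: str, size_params, granules=(), h_target: float = DEFAULT_H) -> Domain:
    """Mesh one of the model's outer shapes, with granules cut out as holes."""
    if shape not in _SHAPE_DIMS:
        raise ValueError(f"unknown shape {shape!r}; expected one of {sorted(_SHAPE_DIMS)}")
    if h_target <= 0:
        raise ValueError("h_target must be positive")
    granules = list(granules)
    semi = _semi_axes(shape, size_params)
    dim = _SHAPE_DIMS[shape]

    report = validate_granules(shape, size_params, granules, h_target)
    if not report.ok:
        raise GranuleValidationError(report)
    if granules and h_target > min(g.radius for g in granules):
        raise ResolutionError(
            f"h_target {h_target:g} exceeds smallest granule radius "
            f"{min(g.radius for g in granules):g}; granule boundary would be unresolved")

    fd = _combined_distance(_outer_distance(shape, semi), granules)
    nodes, elements = _distmesh(fd, h_target, -semi, semi, dim)
    outer, granule_facets = _tag_boundary(nodes, elements, granules, h_target)

    descriptor = {
        "shape": shape,
        "size_params": [float(s) for s in np.atleast_1d(size_params)],
        "h_target": float(h_target),
        "axis_convention": "full" if shape in ("ellipse", "ellipsoid") else "radius",
    }
    return Domain(dimension=dim, nodes=nodes, elements=elements,
                  outer_facets=outer, granule_facets=granule_facets,
                  granules=granules, h_target=h_target, shape_descriptor=descriptor)


def domain_measure(d: Domain) -> float:
    """Total discretized area (2D) or volume (3D) of the domain."""
    return d.measure()


def analytic_measure(shape: str, size_params, granules=()) -> float:
    """Exact measure of the continuum shape minus its granule balls."""
    semi = _semi_axes(shape, size_params)
    dim = _SHAPE_DIMS[shape]
    if dim == 2:
        outer = pi * semi[0] * semi[1]
        holes = sum(pi * g.radius**2 for g in granules)
    else:
        outer = 4.0 / 3.0 * pi * semi[0] * semi[1] * semi[2]
        holes = sum(4.0 / 3.0 * pi * g.radius**3 for g in granules)
    return float(outer - holes)


# ---------------------------------------------------------------------------
# structured auxiliary meshes (1D intervals, rectangles) used by the linear
# analysis, the fixtures, and the solver's periodic test discretization
# ---------------------------------------------------------------------------

def interval_domain(length: float, h: float, periodic: bool = False,
                    x0: float = None) -> Domain:
    """Uniform 1D mesh, optionally periodic (used for dispersion tests)."""
    if length <= 0 or h <= 0:
        raise ValueError("length and h must be positive")
    if periodic:
        n = max(int(round(length / h)), 4)
        dx = length / n
        start = 0.0 if x0 is None else x0
        nodes = (start + dx * np.arange(n))[:, None]
        elements = np.column_stack([np.arange(n), (np.arange(n) + 1) % n])
        ec = nodes[elements].copy()
        ec[-1, 1, 0] = start + length  # periodic image of node 0
        descriptor = {"shape": "interval", "length": float(length), "periodic": True}
        return Domain(dimension=1, nodes=nodes, elements=elements,
                      outer_facets=np.empty((0, 1), dtype=np.int64), granule_facets={},
                      granules=[], h_target=dx, shape_descriptor=descriptor,
                      element_coords=ec, periodic=True)
    n = max(int(round(length / h)), 2)
    start = -length / 2.0 if x0 is None else x0
    nodes = np.linspace(start, start + length, n + 1)[:, None]
    elements = np.column_stack([np.arange(n), np.arange(n) + 1])
    outer = np.array([[0], [n]], dtype=np.int64)
    descriptor = {"shape": "interval", "length": float(length), "periodic": False}
    return Domain(dimension=1, nodes=nodes, elements=elements,
                  outer_facets=outer, granule_facets={}, granules=[],
                  h_target=length / n, shape_descriptor=descriptor)


def rectangle_domain(width: float, height: float, h: float) -> Domain:
    """Structured crossed-triangle mesh of [-w/2, w/2] x [-h/2, h/2]."""
    if width <= 0 or height <= 0 or h <= 0:
        raise ValueError("width, height and h must be positive")
    nx = max(int(round(width / h)), 1)
    ny = max(int(round(height / h)), 1)
    xs = np.linspace(-width / 2.0, width / 2.0, nx + 1)
    ys = np.linspace(-height / 2.0, height / 2.0, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [(a, b, c), (a, c, d)]
            else:
                tris += [(a, b, d), (b, c, d)]
    elements = np.array(tris, dtype=np.int64)
    outer = boundary_facet_array(elements)
    descriptor = {"shape": "rectangle", "size_params": [float(width), float(height)],
                  "h_target": float(h)}
    return Domain(dimension=2, nodes=nodes, elements=elements,
                  outer_facets=outer, granule_facets={}, granules=[],
                  h_target=h, shape_descriptor=descriptor)
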