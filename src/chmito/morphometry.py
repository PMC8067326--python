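"""Morphometrics of simulated ultrastructure.

Quantitative counterparts of the qualitative remodeling vocabulary: phase
fractions (matrix expansion), interface length/area (transition-region
extent), connected components of the membrane phase (fragmentation), a
spectral characteristic pattern length (coarsening), and the composition
of the shell around each granule (matrix halo formation).

Convention: Ψ = 0 is the phase boundary (midpoint of the double well);
Ψ > 0 is matrix, Ψ < 0 is membrane, and nodes exactly at 0 fall in the
interface band.  Sub-element fractions and the Ψ = 0 level set are
computed from the linear interpolant on each simplex, so the fractions
partition the domain measure exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

from .energetics import _values
from .geometry import Domain, GranuleSpec


class SpectrumUndefinedError(RuntimeError):
    """Spectrally flat field: characteristic length is undefined."""


class EmptyShellError(ValueError):
    """No element centroid falls inside the requested granule shell."""


@dataclass
class MorphometryReport:
    matrix_fraction: float
    membrane_fraction: float
    interface_band_residual: float
    interface_measure: float
    n_membrane_components: int
    characteristic_length: float
    granule_halo_means: tuple


# ---------------------------------------------------------------------------
# phase fractions: exact sub-element clipping of the linear interpolant
# ---------------------------------------------------------------------------

def _positive_fraction(vals: np.ndarray, dim: int) -> np.ndarray:
    """Measure fraction of each simplex where the linear interpolant is > 0.

    Uses the divided-difference identity: for distinct nodal values v_i,
    frac = Σ_{v_i>0} v_i^d / Π_{j≠i}(v_i − v_j).  Near-ties are broken by a
    deterministic jitter (the identity cancels catastrophically for equal
    values, which only occur in uniform elements handled by the fast path).
    """
    E, n = vals.shape
    frac = np.zeros(E)
    pos = vals > 0
    all_pos = pos.all(axis=1)
    none_pos = (~pos).all(axis=1)
    frac[all_pos] = 1.0
    mixed = ~(all_pos | none_pos)
    if not mixed.any():
        return frac
    v = vals[mixed].astype(float).copy()
    scale = np.max(np.abs(v), axis=1, keepdims=True)
    v += scale * 1e-12 * np.arange(1, n + 1)  # deterministic tie-break
    f = np.zeros(v.shape[0])
    for i in range(n):
        vi = v[:, i]
        contrib = np.where(vi > 0, vi**dim, 0.0)
        denom = np.ones_like(vi)
        for j in range(n):
            if j != i:
                denom *= vi - v[:, j]
        f += contrib / denom
    frac[mixed] = np.clip(f, 0.0, 1.0)
    return frac


def phase_fractions(d: Domain, psi, threshold: float = 0.0) -> tuple:
    """(matrix_fraction, membrane_fraction): measure of {Ψ>t} and {Ψ<t} over Ω.

    Mixed elements are split by the linear interpolant and partition exactly
    (the Ψ = t set has measure zero there); only elements identically at the
    threshold contribute to the interface-band residual.
    """
    v = _values(psi, d)[d.elements] - threshold
    meas = d.fem.measures
    total = d.fem.total_measure
    pos = _positive_fraction(v, d.dimension)
    neg = np.where((v < 0).any(axis=1) | (v > 0).any(axis=1), 1.0 - pos, 0.0)
    neg[(v >= 0).all(axis=1)] = 0.0
    neg[(v < 0).all(axis=1)] = 1.0
    matrix = float(np.sum(meas * pos) / total)
    membrane = float(np.sum(meas * neg) / total)
    return matrix, membrane


# ---------------------------------------------------------------------------
# interface measure: marching segments / marching tetrahedra
# ---------------------------------------------------------------------------

def _triangle_area(p0, p1, p2) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(p1 - p0, p2 - p0)))


def interface_measure(d: Domain, psi) -> float:
    """Length (2D) or area (3D) of the Ψ = 0 level set of the interpolant."""
    if d.dimension < 2:
        raise ValueError("interface measure is defined for 2D/3D domains")
    vals = _values(psi, d)[d.elements]
    pos = vals > 0
    mixed = np.where(~(pos.all(axis=1) | (~pos).all(axis=1)))[0]
    if len(mixed) == 0:
        return 0.0
    coords = d.element_coords
    n = d.dimension + 1
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    total = 0.0
    for e in mixed:
        v = vals[e].astype(float).copy()
        v[v == 0.0] = 1e-30  # nudge exact zeros off the level set
        pts = []
        for i, j in edges:
            if (v[i] > 0) != (v[j] > 0):
                t = v[i] / (v[i] - v[j])
                pts.append(coords[e, i] + t * (coords[e, j] - coords[e, i]))
        if d.dimension == 2:
            if len(pts) == 2:
                total += float(np.linalg.norm(pts[1] - pts[0]))
        else:
            if len(pts) == 3:
                total += _triangle_area(*pts)
            elif len(pts) == 4:
                # order crossings around the planar quad: edges sorted by
                # (positive vertex, negative vertex) give the cycle
                # (p0n0, p0n1, p1n1, p1n0)
                pidx = [i for i in range(n) if v[i] > 0]
                nidx = [i for i in range(n) if v[i] <= 0]
                def cross(i, j):
                    t = v[i] / (v[i] - v[j])
                    return coords[e, i] + t * (coords[e, j] - coords[e, i])
                q = [cross(pidx[0], nidx[0]), cross(pidx[0], nidx[1]),
                     cross(pidx[1], nidx[1]), cross(pidx[1], nidx[0])]
                total += _triangle_area(q[0], q[1], q[2]) + _triangle_area(q[0], q[2], q[3])
    return float(total)


# ---------------------------------------------------------------------------
# connected components of a phase
# ---------------------------------------------------------------------------

def _element_adjacency(d: Domain) -> tuple:
    """Pairs of elements sharing a facet (edge in 2D, face in 3D)."""
    elements = d.elements
    E, n = elements.shape
    parts = [np.sort(np.delete(elements, i, axis=1), axis=1) for i in range(n)]
    allf = np.vstack(parts)
    owner = np.tile(np.arange(E), n)
    order = np.lexsort(allf.T[::-1])
    allf = allf[order]
    owner = owner[order]
    same = np.all(allf[1:] == allf[:-1], axis=1)
    return owner[:-1][same], owner[1:][same]


def count_phase_components(d: Domain, psi, phase: str = "membrane") -> int:
    """Connected components (facet adjacency) of one phase's element set."""
    if phase not in ("membrane", "matrix"):
        raise ValueError("phase must be 'membrane' or 'matrix'")
    v = _values(psi, d)[d.elements].mean(axis=1)  # centroid value of interpolant
    in_phase = v < 0 if phase == "membrane" else v > 0
    n_sel = int(in_phase.sum())
    if n_sel == 0:
        return 0
    cache = getattr(d, "_adjacency_cache", None)
    if cache is None:
        cache = _element_adjacency(d)
        d._adjacency_cache = cache
    a, b = cache
    keep = in_phase[a] & in_phase[b]
    idx = np.cumsum(in_phase) - 1  # renumber selected elements
    g = sp.coo_matrix((np.ones(int(keep.sum())), (idx[a[keep]], idx[b[keep]])),
                      shape=(n_sel, n_sel))
    n_comp, _ = connected_components(g, directed=False)
    return int(n_comp)


# ---------------------------------------------------------------------------
# characteristic pattern length from the radially averaged power spectrum
# ---------------------------------------------------------------------------

class GridSampler:
    """Resamples nodal fields onto a uniform grid over the bounding box.

    Grid points outside the meshed region (beyond the outer shape or inside
    a granule hole) are masked and later filled with the field mean, so the
    exterior does not leak power into the spectrum.  The Delaunay
    triangulation and barycentric weights are computed once per domain.
    """

    def __init__(self, d: Domain, shape: tuple):
        self.shape = tuple(shape)
        lo = d.nodes.min(axis=0)
        hi = d.nodes.max(axis=0)
        axes = [np.linspace(lo[i], hi[i], self.shape[i]) for i in range(d.dimension)]
        self.spacings = [float(ax[1] - ax[0]) for ax in axes]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])

        tri = Delaunay(d.nodes)
        simplex = tri.find_simplex(pts)
        inside = simplex >= 0
        # exclude grid points in granule holes or outside the outer shape
        inside &= self._analytic_mask(d, pts)
        self.inside = inside
        sim = simplex[inside]
        X = tri.transform[sim]
        bc = np.einsum("nij,nj->ni", X[:, :-1], pts[inside] - X[:, -1])
        self.weights = np.column_stack([bc, 1.0 - bc.sum(axis=1)])
        self.vertices = tri.simplices[sim]

    @staticmethod
    def _analytic_mask(d: Domain, pts: np.ndarray) -> np.ndarray:
        desc = d.shape_descriptor
        mask = np.ones(len(pts), dtype=bool)
        shape = desc.get("shape")
        if shape in ("disk", "sphere"):
            mask &= np.linalg.norm(pts, axis=1) <= desc["size_params"][0]
        elif shape in ("ellipse", "ellipsoid"):
            semi = np.asarray(desc["size_params"]) / 2.0
            mask &= np.sum((pts / semi) ** 2, axis=1) <= 1.0
        for g in d.granules:
            mask &= np.linalg.norm(pts - np.asarray(g.center), axis=1) >= g.radius
        return mask

    def sample(self, values: np.ndarray) -> np.ndarray:
        fill = float(values.mean())
        out = np.full(int(np.prod(self.shape)), fill)
        out[self.inside] = np.einsum("ni,ni->n", self.weights, values[self.vertices])
        return out.reshape(self.shape)


def resample_to_grid(d: Domain, psi, shape: tuple = None):
    """(grid, spacings): uniform-grid resampling of a nodal field."""
    if shape is None:
        shape = (128, 128) if d.dimension == 2 else (64, 64, 64)
    key = ("grid_sampler", tuple(shape))
    cache = getattr(d, "_sampler_cache", {})
    sampler = cache.get(key)
    if sampler is None:
        sampler = GridSampler(d, shape)
        cache[key] = sampler
        d._sampler_cache = cache
    return sampler.sample(_values(psi, d)), sampler.spacings


def characteristic_length(grid: np.ndarray, spacings) -> float:
    """2π/⟨k⟩ with ⟨k⟩ the first moment of the radially averaged spectrum."""
    grid = np.asarray(grid, dtype=float)
    fluct = grid - grid.mean()
    power = np.abs(np.fft.fftn(fluct)) ** 2
    if power.sum() <= 1e-16 * grid.size:
        raise SpectrumUndefinedError("field is spectrally flat; no pattern length")
    freqs = [2.0 * np.pi * np.fft.fftfreq(n, d=dx)
             for n, dx in zip(grid.shape, spacings)]
    mesh = np.meshgrid(*freqs, indexing="ij")
    kmag = np.sqrt(sum(m**2 for m in mesh))
    kmag.flat[0] = 0.0
    power.flat[0] = 0.0  # drop the mean mode
    total = power.sum()
    if total <= 0:
        raise SpectrumUndefinedError("field is spectrally flat; no pattern length")
    kmean = float((power * kmag).sum() / total)
    return 2.0 * np.pi / kmean


def characteristic_length_of_field(d: Domain, psi, shape: tuple = None) -> float:
    grid, spacings = resample_to_grid(d, psi, shape)
    return characteristic_length(grid, spacings)


# ---------------------------------------------------------------------------
# granule halo composition
# ---------------------------------------------------------------------------

def _shell_elements(d: Domain, g: GranuleSpec, shell_width: float) -> np.ndarray:
    if shell_width <= 0:
        raise ValueError("shell_width must be positive")
    centroids = d.element_coords.mean(axis=1)
    dist = np.linalg.norm(centroids - np.asarray(g.center), axis=1) - g.radius
    sel = (dist >= 0.0) & (dist <= shell_width)
    if not sel.any():
        raise EmptyShellError(
            f"no element centroids within {shell_width:g} of the granule surface")
    return sel


def granule_halo_mean(d: Domain, psi, g: GranuleSpec, shell_width: float = 0.5) -> float:
    """Measure-weighted mean of Ψ in the shell around a granule surface."""
    sel = _shell_elements(d, g, shell_width)
    v = _values(psi, d)[d.elements].mean(axis=1)
    meas = d.fem.measures
    return float(np.sum(meas[sel] * v[sel]) / np.sum(meas[sel]))


def granule_halo_membrane_fraction(d: Domain, psi, g: GranuleSpec,
                                   shell_width: float = 0.5) -> float:
    """Membrane (Ψ<0) measure fraction inside the granule shell."""
    sel = _shell_elements(d, g, shell_width)
    v = _values(psi, d)[d.elements]
    frac = _positive_fraction(-v[sel], d.dimension)
    meas = d.fem.measures[sel]
    return float(np.sum(meas * frac) / np.sum(meas))


def morphometry_report(d: Domain, psi, shell_width: float = 0.5,
                       grid_shape: tuple = None) -> MorphometryReport:
    """All morphometrics of one field in a single report."""
    mf, bf = phase_fractions(d, psi)
    try:
        clen = characteristic_length_of_field(d, psi, grid_shape)
    except SpectrumUndefinedError:
        clen = float("nan")
    halo = tuple(granule_halo_mean(d, psi, g, shell_width) for g in d.granules)
    return MorphometryReport(
        matrix_fraction=mf, membrane_fraction=bf,
        interface_band_residual=1.0 - mf - bf,
        interface_measure=interface_measure(d, psi),
        n_membrane_components=count_phase_components(d, psi, "membrane"),
        characteristic_length=clen, granule_halo_means=halo)
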