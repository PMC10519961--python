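"""Reconstruction of Cartesian images from continuously streamed scan data.

The acquisition records every detector sample in a continuous stream (no
per-pulse triggering), together with A-quad-B encoder states of the fast
(voice-coil, sinusoidal) and slow (linear) stage axes.  Reconstruction
proceeds in three steps:

1. decode the quadrature encoder states into stage positions,
2. associate the per-pulse maxima of the PARS and peak-held scattering
   traces with the decoded position of each excitation event,
3. map the resulting scattered sample points onto a pixelated Cartesian
   grid with natural-neighbor (Sibson) interpolation on a Delaunay
   triangulation.

Sibson interpolation reproduces values exactly at the data sites and is
exact for affine fields inside the convex hull, which makes scan
trajectories with strongly non-uniform point densities (dense at the
sinusoid turnarounds) reconstruct without directional bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay

__all__ = [
    "ScanStream",
    "SamplePoints",
    "GridSpec",
    "EncoderGlitchError",
    "DegenerateGeometryError",
    "decode_encoder",
    "extract_samples",
    "grid_interpolate",
    "sibson_weights",
]

# forward quadrature order of (A, B) states; one full cycle = 4 counts
_QUAD_ORDER = ((0, 0), (0, 1), (1, 1), (1, 0))
_STATE_TO_PHASE = {2 * a + b: p for p, (a, b) in enumerate(_QUAD_ORDER)}


class EncoderGlitchError(ValueError):
    """Both quadrature bits flipped in one sample: direction is ambiguous."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"illegal quadrature transition (both bits flip) at sample {index}")


class DegenerateGeometryError(ValueError):
    """Scattered points are collinear/degenerate; no triangulation exists."""


@dataclass
class ScanStream:
    """Continuously streamed acquisition data.

    pulse_markers are sample indices of excitation events (strictly
    increasing).  pars_trace is the AC-coupled interrogation signal,
    scatter_trace the peak-held UV back-scatter signal.  encoder_*_a/b are
    quadrature bit sequences for the fast (x) and slow (y) axes, sampled at
    ``sample_rate``.  counts_per_um converts encoder counts to micrometres.
    """

    pulse_markers: np.ndarray
    pars_trace: np.ndarray
    scatter_trace: np.ndarray
    encoder_x_a: np.ndarray
    encoder_x_b: np.ndarray
    encoder_y_a: np.ndarray
    encoder_y_b: np.ndarray
    sample_rate: float
    counts_per_um: float = 10.0
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pulse_markers = np.asarray(self.pulse_markers, dtype=int)
        for name in ("pars_trace", "scatter_trace", "encoder_x_a", "encoder_x_b",
                     "encoder_y_a", "encoder_y_b"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n = len(self.pars_trace)
        for name in ("scatter_trace", "encoder_x_a", "encoder_x_b",
                     "encoder_y_a", "encoder_y_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from pars_trace")
        if np.any(np.diff(self.pulse_markers) <= 0):
            raise ValueError("pulse_markers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.pars_trace)


@dataclass
class SamplePoints:
    """One (x, y, pars, scatter) record per accepted pulse event (x, y in μm)."""

    x: np.ndarray
    y: np.ndarray
    pars_value: np.ndarray
    scatter_value: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pars_value = np.asarray(self.pars_value, dtype=float)
        self.scatter_value = np.asarray(self.scatter_value, dtype=float)
        n = len(self.x)
        if not (len(self.y) == len(self.pars_value) == len(self.scatter_value) == n):
            raise ValueError("SamplePoints sequences must have equal length")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class GridSpec:
    """Target Cartesian grid: origin (μm), size (px) and pixel spacing (μm/px).

    Pixel centers sit at ``x0 + i * spacing`` (0-based indices).
    """

    x0: float
    y0: float
    nx: int
    ny: int
    spacing: float

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid size must be positive")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + np.arange(self.nx) * self.spacing
        ys = self.y0 + np.arange(self.ny) * self.spacing
        return xs, ys


def decode_encoder(
    encoder_a: np.ndarray,
    encoder_b: np.ndarray,
    counts_per_um: float | None = None,
) -> np.ndarray:
    """Decode quadrature bit streams into cumulative displacement.

    Returns displacement per sample in counts, or in micrometres when
    ``counts_per_um`` is given.  The forward phase order is
    00 -> 01 -> 11 -> 10 -> 00 (+4 counts per full cycle).  A transition in
    which both bits flip is physically impossible at an adequate sample rate
    and raises :class:`EncoderGlitchError` with the offending index.
    """
    a = np.asarray(encoder_a).astype(int)
    b = np.asarray(encoder_b).astype(int)
    if a.shape != b.shape:
        raise ValueError("encoder state sequences must have equal length")
    if a.size == 0:
        return np.zeros(0)
    phase = np.array([_STATE_TO_PHASE[s] for s in (2 * a + b)], dtype=int)
    delta = (np.diff(phase) + 1) % 4 - 1  # in {-1, 0, 1, 2}; 2 == glitch
    bad = np.nonzero(delta == 2)[0]
    if bad.size:
        raise EncoderGlitchError(int(bad[0]) + 1)
    counts = np.concatenate([[0], np.cumsum(delta)]).astype(float)
    if counts_per_um is not None:
        return counts / counts_per_um
    return counts


def extract_samples(stream: ScanStream, window: int) -> SamplePoints:
    """Associate per-pulse trace maxima with a single decoded stage position.

    For each pulse marker the PARS value is the maximum of the AC-coupled
    trace over the ``window`` samples following the pulse, and the scattering
    value is the held peak over the same window.  The (x, y) position is the
    decoded encoder position at the pulse sample.  Events whose window
    overruns the end of the stream are dropped with a warning.
    """
    if window < 1:
        raise ValueError("window must be at least one sample")
    x_pos = decode_encoder(stream.encoder_x_a, stream.encoder_x_b,
                           stream.counts_per_um) + stream.origin_um[0]
    y_pos = decode_encoder(stream.encoder_y_a, stream.encoder_y_b,
                           stream.counts_per_um) + stream.origin_um[1]
    n = len(stream)
    keep = stream.pulse_markers + window <= n
    if not np.all(keep):
        warnings.warn(
            f"{int(np.sum(~keep))} pulse event(s) truncated at stream end; dropped",
            stacklevel=2,
        )
    markers = stream.pulse_markers[keep]
    pars_vals = np.empty(len(markers))
    scat_vals = np.empty(len(markers))
    for i, m in enumerate(markers):
        pars_vals[i] = stream.pars_trace[m:m + window].max()
        scat_vals[i] = stream.scatter_trace[m:m + window].max()
    return SamplePoints(x_pos[markers], y_pos[markers], pars_vals, scat_vals)


# ---------------------------------------------------------------------------
# natural-neighbor (Sibson) interpolation
# ---------------------------------------------------------------------------

def _circumcenters(points: np.ndarray, simplices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circumcenters and squared circumradii of 2-D triangles."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    ab = b - a
    ac = c - a
    d = 2.0 * (ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = (ac[:, 1] * (ab ** 2).sum(1) - ab[:, 1] * (ac ** 2).sum(1)) / d
        uy = (ab[:, 0] * (ac ** 2).sum(1) - ac[:, 0] * (ab ** 2).sum(1)) / d
    centers = a + np.stack([ux, uy], axis=1)
    r2 = ((centers - a) ** 2).sum(1)
    return centers, r2


def _circumcenter_one(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    ab = p1 - p0
    ac = p2 - p0
    d = 2.0 * (ab[0] * ac[1] - ab[1] * ac[0])
    if d == 0:
        raise DegenerateGeometryError("degenerate triangle while inserting query point")
    ux = (ac[1] * (ab @ ab) - ab[1] * (ac @ ac)) / d
    uy = (ab[0] * (ac @ ac) - ac[0] * (ab @ ab)) / d
    return p0 + np.array([ux, uy])


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a convex polygon given in arbitrary vertex order."""
    if len(vertices) < 3:
        return 0.0
    centroid = vertices.mean(axis=0)
    ang = np.arctan2(vertices[:, 1] - centroid[1], vertices[:, 0] - centroid[0])
    v = vertices[np.argsort(ang)]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def sibson_weights(
    tri: Delaunay,
    centers: np.ndarray,
    r2: np.ndarray,
    q: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sibson natural-neighbor weights of query point ``q``.

    Uses Watson's local-retriangulation construction: the triangles whose
    circumcircle contains ``q`` form the insertion cavity; the area each
    natural neighbor's Voronoi cell cedes to ``q`` is the polygon bounded by
    the cavity triangles' circumcenters and the circumcenters of the new
    triangles formed between ``q`` and the cavity boundary edges.

    Returns (neighbor_indices, weights) with weights summing to 1.  ``q``
    must lie strictly inside the convex hull (caller's responsibility).
    """
    pts = tri.points
    d2 = ((centers - q) ** 2).sum(1)
    cavity = np.nonzero(d2 < r2 * (1 + 1e-12) + 1e-12)[0]
    if cavity.size == 0:
        raise DegenerateGeometryError("query point has an empty insertion cavity")
    cavity_set = set(cavity.tolist())

    # old Voronoi vertices (cavity circumcenters) incident to each neighbor
    vert_lists: dict[int, list[np.ndarray]] = {}
    for t in cavity:
        for v in tri.simplices[t]:
            vert_lists.setdefault(int(v), []).append(centers[t])

    # cavity boundary edges -> circumcenters of the new triangles (q, a, b)
    for t in cavity:
        for i in range(3):
            nb = tri.neighbors[t, i]
            if nb == -1 or int(nb) not in cavity_set:
                edge = [int(v) for j, v in enumerate(tri.simplices[t]) if j != i]
                cnew = _circumcenter_one(q, pts[edge[0]], pts[edge[1]])
                vert_lists[edge[0]].append(cnew)
                vert_lists[edge[1]].append(cnew)

    neighbors = np.array(sorted(vert_lists.keys()), dtype=int)
    areas = np.array([_polygon_area(np.array(vert_lists[int(v)])) for v in neighbors])
    total = areas.sum()
    if total <= 0:
        raise DegenerateGeometryError("degenerate stolen-area computation")
    return neighbors, areas / total


def _dedupe_points(xy: np.ndarray, values: np.ndarray, tol: float = 1e-9):
    """Average values of samples falling on the same position (within tol)."""
    key = np.round(xy / tol).astype(np.int64)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    xy_out = np.zeros((counts.size, 2))
    v_out = np.zeros(counts.size)
    np.add.at(xy_out, inv, xy)
    np.add.at(v_out, inv, values)
    return xy_out / counts[:, None], v_out / counts


def grid_interpolate(
    points: SamplePoints,
    grid: GridSpec,
    channel: str = "pars",
    method: str = "sibson",
    fill: float = 0.0,
) -> np.ndarray:
    """Interpolate scattered samples onto a Cartesian grid.

    ``method='sibson'`` performs natural-neighbor interpolation (exact at
    data sites and for affine fields inside the convex hull);
    ``method='linear'`` is a faster barycentric fallback on the same
    triangulation.  Pixels outside the convex hull are set to ``fill``.
    Multiple samples recorded at one position are averaged before
    triangulation.  Returns a (ny, nx) raster.
    """
    if channel not in ("pars", "scatter"):
        raise ValueError("channel must be 'pars' or 'scatter'")
    values = points.pars_value if channel == "pars" else points.scatter_value
    xy = np.stack([points.x, points.y], axis=1)
    xy, values = _dedupe_points(xy, values)
    if len(xy) < 3:
        raise DegenerateGeometryError("need at least 3 non-collinear points")
    try:
        tri = Delaunay(xy)
    except Exception as exc:  # qhull failure on collinear input
        raise DegenerateGeometryError(str(exc)) from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("all points are collinear")

    xs, ys = grid.node_coords()
    out = np.full((grid.ny, grid.nx), float(fill))

    if method == "linear":
        interp = LinearNDInterpolator(tri, values, fill_value=fill)
        gx, gy = np.meshgrid(xs, ys)
        out[:] = interp(np.stack([gx.ravel(), gy.ravel()], axis=1)).reshape(out.shape)
        return out
    if method != "sibson":
        raise ValueError("method must be 'sibson' or 'linear'")

    centers, r2 = _circumcenters(xy, tri.simplices)
    # site coincidence tolerance relative to grid spacing
    site_tol2 = (1e-7 * grid.spacing) ** 2
    gx, gy = np.meshgrid(xs, ys)
    qpts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    inside = tri.find_simplex(qpts) >= 0
    lin = None  # lazy barycentric fallback for hull-boundary queries,
    # where Sibson degenerates to linear interpolation along the edge
    for idx in np.nonzero(inside)[0]:
        q = qpts[idx]
        d2site = ((xy - q) ** 2).sum(1)
        jmin = int(np.argmin(d2site))
        if d2site[jmin] <= site_tol2:
            out.ravel()[idx] = values[jmin]
            continue
        try:
            nbrs, w = sibson_weights(tri, centers, r2, q)
            out.ravel()[idx] = float(w @ values[nbrs])
        except DegenerateGeometryError:
            if lin is None:
                lin = LinearNDInterpolator(tri, values, fill_value=fill)
            out.ravel()[idx] = float(np.asarray(lin(q[None, :])).ravel()[0])
    return out
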