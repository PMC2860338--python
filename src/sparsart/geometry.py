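"""Fan-beam acquisition geometry and the area-weighted system matrix.

The scanner model: an X-ray source on a circle of radius ``source_radius``
around the rotation axis, and a flat equispatial virtual detector of length
``detector_length`` passing through the origin, perpendicular to the
source-origin direction.  For view angle theta the source sits at
``(-R sin(theta), R cos(theta))`` and the detector axis points along
``(cos(theta), sin(theta))``; views are equiangular over a full scan.

Each measurement corresponds to a finite-width beam: the wedge spanned by
the two rays joining the source to the endpoints of one detector element.
The system-matrix entry ``a[m, n]`` is the exact area (cm^2) of the
intersection of that wedge with pixel ``n``'s square, computed by convex
polygon clipping, so the forward model ``g = A f`` integrates attenuation
over beam/pixel interaction areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import sparse

from .phantom import Image, pixel_centers

__all__ = [
    "FanBeamGeometry",
    "SystemMatrix",
    "Sinogram",
    "build_system_matrix",
    "forward_project",
    "back_project",
    "add_noise",
    "save_sinogram_csv",
    "load_sinogram_csv",
    "geometry_to_text",
    "geometry_from_text",
]


@dataclass(frozen=True)
class FanBeamGeometry:
    """Full-scan equiangular fan-beam geometry.

    Parameters
    ----------
    source_radius : float
        Distance source to rotation axis, cm.
    detector_length : float
        Physical length of the flat detector array, cm.
    n_detectors : int
        Number of equispatial detector elements.
    n_views : int
        Number of view angles, equiangular over [0, 2*pi).
    """

    source_radius: float = 57.0
    detector_length: float = 20.0
    n_detectors: int = 128
    n_views: int = 55
    view_angles: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source_radius <= 0 or self.detector_length <= 0:
            raise ValueError("source_radius and detector_length must be positive")
        if self.n_detectors < 1 or self.n_views < 1:
            raise ValueError("n_detectors and n_views must be >= 1")
        if self.view_angles is None:
            angles = 2 * np.pi * np.arange(self.n_views) / self.n_views
        else:
            angles = np.asarray(self.view_angles, dtype=float)
            if angles.shape != (self.n_views,):
                raise ValueError("view_angles must have length n_views")
        object.__setattr__(self, "view_angles", angles)

    @property
    def n_measurements(self) -> int:
        return self.n_views * self.n_detectors

    def source_position(self, theta: float) -> np.ndarray:
        R = self.source_radius
        return np.array([-R * np.sin(theta), R * np.cos(theta)])

    def detector_axis(self, theta: float) -> np.ndarray:
        return np.array([np.cos(theta), np.sin(theta)])

    def detector_edges(self) -> np.ndarray:
        """Signed positions of the n_detectors+1 element edges along the
        detector axis, cm, centered on the origin."""
        L = self.detector_length
        return np.linspace(-L / 2, L / 2, self.n_detectors + 1)


@dataclass(frozen=True)
class Sinogram:
    """Measurement vector g: area-weighted line integrals (cm^2 * attenuation)."""

    values: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.geometry.n_measurements:
            raise ValueError("sinogram length must equal n_views * n_detectors")
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram values must be finite")
        object.__setattr__(self, "values", v)

    def as_grid(self) -> np.ndarray:
        """(n_views, n_detectors) view of the measurements."""
        g = self.geometry
        return self.values.reshape(g.n_views, g.n_detectors)


@dataclass(frozen=True)
class SystemMatrix:
    """Sparse area-weight matrix plus the SART normalization diagonals.

    ``lam_row`` holds 1/a_{m+} (zero where a beam misses the grid) and
    ``lam_col`` holds 1/a_{+n} (zero for pixels no beam touches), so
    multiplying by them applies the SART diagonal scalers while excluding
    degenerate rows/pixels from the update.
    """

    weights: sparse.csr_matrix
    geometry: FanBeamGeometry | None
    grid_n: int
    pixel_size: float
    row_sums: np.ndarray
    col_sums: np.ndarray
    lam_row: np.ndarray
    lam_col: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @classmethod
    def from_matrix(
        cls,
        W,
        grid_n: int | None = None,
        pixel_size: float = 1.0,
        geometry: FanBeamGeometry | None = None,
    ) -> "SystemMatrix":
        """Wrap an arbitrary nonnegative measurement matrix.

        Useful for generic linear systems (e.g. random compressed-sensing
        matrices) and for dense oracles in tests; row/column sums and the
        SART diagonals are computed the same way as for a built projector.
        """
        W = sparse.csr_matrix(W)
        if (W.data < 0).any():
            raise ValueError("SART weighting requires nonnegative entries")
        if grid_n is None:
            grid_n = int(np.sqrt(W.shape[1]))
        row_sums = np.asarray(W.sum(axis=1)).ravel()
        col_sums = np.asarray(W.sum(axis=0)).ravel()
        lam_row = np.where(row_sums > 0, 1.0 / np.where(row_sums > 0, row_sums, 1.0), 0.0)
        lam_col = np.where(col_sums > 0, 1.0 / np.where(col_sums > 0, col_sums, 1.0), 0.0)
        return cls(
            weights=W,
            geometry=geometry,
            grid_n=grid_n,
            pixel_size=pixel_size,
            row_sums=row_sums,
            col_sums=col_sums,
            lam_row=lam_row,
            lam_col=lam_col,
        )


def _beam_wedges(geom: FanBeamGeometry, view: int, reach: float) -> np.ndarray:
    """Vertex arrays (n_detectors, 3, 2) of the extended beam triangles for
    one view.  Detector-element endpoints are pushed away from the source far
    enough (``reach``) that the wedge covers the whole image square."""
    theta = geom.view_angles[view]
    src = geom.source_position(theta)
    axis = geom.detector_axis(theta)
    edges = geom.detector_edges()
    pts = edges[:, None] * axis[None, :]  # (n_det+1, 2) on the detector line
    vec = pts - src
    scale = reach / np.linalg.norm(vec, axis=1)
    far = src + vec * np.maximum(scale, 1.0)[:, None]
    tris = np.empty((geom.n_detectors, 3, 2))
    tris[:, 0] = src
    tris[:, 1] = far[:-1]
    tris[:, 2] = far[1:]
    return tris


def build_system_matrix(
    geom: FanBeamGeometry,
    grid_n: int,
    fov: float = 20.0,
    drop_tol: float = 1e-12,
) -> SystemMatrix:
    """Compute the exact beam/pixel interaction areas for a pixel grid.

    For every measurement the beam wedge is clipped against each candidate
    pixel square and the polygon intersection area is recorded; entries
    below ``drop_tol`` cm^2 are dropped.  Candidates are pre-filtered by the
    signed distance of pixel centers to the wedge's two bounding rays, so
    only pixels within half a diagonal of the strip are clipped exactly.
    """
    h = fov / grid_n
    half_diag = h * np.sqrt(2) / 2
    if np.hypot(fov / 2, fov / 2) >= geom.source_radius:
        raise ValueError("source lies inside the image square: degenerate geometry")

    xc, yc = pixel_centers(grid_n, fov)
    X, Y = np.meshgrid(xc, yc)
    centers = np.column_stack([X.ravel(), Y.ravel()])
    boxes = shapely.box(
        centers[:, 0] - h / 2, centers[:, 1] - h / 2,
        centers[:, 0] + h / 2, centers[:, 1] + h / 2,
    )

    # far enough that the wedge's chord lies beyond the image even for wide fans
    reach = 3.0 * (geom.source_radius + fov)
    N = grid_n * grid_n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for v in range(geom.n_views):
        tris = _beam_wedges(geom, v, reach)
        src = tris[0, 0]
        rel = centers - src  # (N, 2)
        for d in range(geom.n_detectors):
            a, b = tris[d, 1] - src, tris[d, 2] - src
            # inward normals of the two bounding rays (wedge interior between them)
            cross_ab = a[0] * b[1] - a[1] * b[0]
            sgn = np.sign(cross_ab) or 1.0
            d1 = sgn * (a[0] * rel[:, 1] - a[1] * rel[:, 0]) / np.hypot(*a)
            d2 = -sgn * (b[0] * rel[:, 1] - b[1] * rel[:, 0]) / np.hypot(*b)
            cand = np.flatnonzero((d1 >= -half_diag) & (d2 >= -half_diag))
            if cand.size == 0:
                continue
            tri = shapely.polygons(tris[d])
            areas = shapely.area(shapely.intersection(boxes[cand], tri))
            keep = areas > drop_tol
            if np.any(keep):
                m = v * geom.n_detectors + d
                rows.append(np.full(int(keep.sum()), m, dtype=np.int64))
                cols.append(cand[keep].astype(np.int64))
                vals.append(areas[keep])

    M = geom.n_measurements
    if rows:
        A = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(M, N),
        )
    else:
        A = sparse.csr_matrix((M, N))
    row_sums = np.asarray(A.sum(axis=1)).ravel()
    col_sums = np.asarray(A.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        lam_row = np.where(row_sums > 0, 1.0 / np.where(row_sums > 0, row_sums, 1.0), 0.0)
        lam_col = np.where(col_sums > 0, 1.0 / np.where(col_sums > 0, col_sums, 1.0), 0.0)
    return SystemMatrix(
        weights=A,
        geometry=geom,
        grid_n=grid_n,
        pixel_size=h,
        row_sums=row_sums,
        col_sums=col_sums,
        lam_row=lam_row,
        lam_col=lam_col,
    )


def forward_project(A: SystemMatrix, f: Image | np.ndarray) -> Sinogram:
    """g = A f: area-weighted projection of an image onto the detector."""
    vec = f.ravel() if isinstance(f, Image) else np.asarray(f, dtype=float).ravel()
    if vec.size != A.shape[1]:
        raise ValueError("image size does not match system matrix")
    return Sinogram(values=A.weights @ vec, geometry=A.geometry)


def back_project(A: SystemMatrix, r: Sinogram | np.ndarray) -> np.ndarray:
    """A^T r: smear a sinogram-shaped vector back over the pixel grid."""
    vec = r.values if isinstance(r, Sinogram) else np.asarray(r, dtype=float).ravel()
    if vec.size != A.shape[0]:
        raise ValueError("vector size does not match system matrix")
    return A.weights.T @ vec


def save_sinogram_csv(g: Sinogram, path) -> None:
    """Write measurements as CSV, one row per view, one column per detector."""
    np.savetxt(path, g.as_grid(), delimiter=",")


def load_sinogram_csv(path, geom: FanBeamGeometry) -> Sinogram:
    """Read a view-by-detector CSV written by :func:`save_sinogram_csv`."""
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    if values.shape != (geom.n_views, geom.n_detectors):
        raise ValueError("CSV shape does not match the geometry")
    return Sinogram(values=values.ravel(), geometry=geom)


_GEOM_FIELDS = ("source_radius_cm", "detector_length_cm", "n_detectors", "n_views")


def geometry_to_text(geom: FanBeamGeometry) -> str:
    """Serialize a geometry as a `key = value` text block."""
    vals = (geom.source_radius, geom.detector_length, geom.n_detectors, geom.n_views)
    return "".join(f"{k} = {v}\n" for k, v in zip(_GEOM_FIELDS, vals))


def geometry_from_text(text: str) -> FanBeamGeometry:
    """Parse the `key = value` block written by :func:`geometry_to_text`."""
    fields: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = float(value)
    missing = [k for k in _GEOM_FIELDS if k not in fields]
    if missing:
        raise ValueError(f"geometry config is missing {missing}")
    return FanBeamGeometry(
        source_radius=fields["source_radius_cm"],
        detector_length=fields["detector_length_cm"],
        n_detectors=int(fields["n_detectors"]),
        n_views=int(fields["n_views"]),
    )


def add_noise(g: Sinogram, level: float, seed: int) -> Sinogram:
    """Add zero-mean Gaussian noise with sigma = level * max(g).

    ``level`` is the relative noise amplitude (0.001 for "0.1% noise");
    the reference scale is the maximum measurement.  Deterministic for a
    fixed seed.
    """
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    if level == 0:
        return g
    rng = np.random.default_rng(seed)
    sigma = level * np.max(g.values)
    e = rng.normal(0.0, sigma, size=g.values.shape)
    return Sinogram(values=g.values + e, geometry=g.geometry)
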