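"""Modified Shepp-Logan head phantom on a centimetre grid.

The phantom is the standard ten-ellipse "modified" (high-contrast) variant:
a skull ellipse of intensity 1.0, brain tissue at -0.8, two ventricles at
-0.2 and six small high-intensity features at +0.1.  The attenuation value
at a pixel is the sum of the intensities of every ellipse containing the
pixel *center* (point sampling, no anti-aliasing), so pixels outside all
ellipses are exactly zero.  This rasterization keeps the image extremely
sparse under a Haar decomposition, which is what the reconstruction
experiments rely on.

Grid convention (shared by all modules): the image square is
``[-fov/2, fov/2]^2`` centimetres, pixel (0, 0) is the top-left raster
element, its center sits at ``(-fov/2 + h/2, +fov/2 - h/2)`` with
``h = fov / n`` the pixel side; x grows rightward, y upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Image", "ELLIPSES", "generate_phantom", "pixel_centers"]

#: Ellipse table (intensity, semi-axis a, semi-axis b, x0, y0, angle degrees)
#: in coordinates normalized to the unit disc (multiply by fov/2 for cm).
ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
)


@dataclass(frozen=True)
class Image:
    """A square pixel grid centered on the rotation axis.

    Attributes
    ----------
    values : ndarray of shape (n, n)
        Attenuation values (dimensionless), row 0 at the top.
    pixel_size : float
        Side length of one pixel in cm.
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] < 2:
            raise ValueError("image must be a square grid with n >= 2")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("image values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def fov(self) -> float:
        """Field-of-view side length in cm."""
        return self.n * self.pixel_size

    def ravel(self) -> np.ndarray:
        return self.values.ravel()


def pixel_centers(n: int, fov: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (x increasing, y decreasing) in cm.

    Returns ``(x, y)`` 1-D arrays such that pixel ``(i, j)`` of the raster
    has center ``(x[j], y[i])``.
    """
    h = fov / n
    x = -fov / 2 + h * (np.arange(n) + 0.5)
    y = fov / 2 - h * (np.arange(n) + 0.5)
    return x, y


def generate_phantom(n: int, fov: float = 20.0) -> Image:
    """Rasterize the modified Shepp-Logan phantom at ``n x n`` pixels.

    Parameters
    ----------
    n : int
        Grid side; the image covers the ``fov x fov`` cm square.
    fov : float
        Field of view in cm; the ellipse table is scaled so the unit disc
        maps onto the disc of radius ``fov/2`` (compact support radius
        10 cm at the default).

    Returns
    -------
    Image
        Pixel-center point-sampled phantom; exterior pixels are exactly 0.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise ValueError("n must be an integer")
    if n < 2:
        raise ValueError("n must be >= 2")
    x, y = pixel_centers(n, fov)
    # work in normalized coordinates where the support is the unit disc
    X, Y = np.meshgrid(x / (fov / 2), y / (fov / 2))
    img = np.zeros((n, n))
    for inten, a, b, x0, y0, phi in ELLIPSES:
        t = np.deg2rad(phi)
        xr = (X - x0) * np.cos(t) + (Y - y0) * np.sin(t)
        yr = -(X - x0) * np.sin(t) + (Y - y0) * np.cos(t)
        img += inten * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return Image(values=img, pixel_size=fov / n)
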