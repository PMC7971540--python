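"""Rasterized cell-shape masks on regular grids.

Cell outlines mimic the micropattern confinement geometries used in cell
polarization experiments: "symmetric" outlines with two mirror axes
(circle, ellipse, square, rectangle) and "asymmetric" outlines with a
single horizontal mirror axis and a blunt end at +x (teardrop, narrow
drop, wide drop, triangle).  Masks are rasterized at cell centers on a
square grid; the finite-volume solver operates on the interior cells.

Coordinate convention: x rightward, y upward, origin at the left/bottom
corner of the shape's bounding box.  Cell centers sit at ``(i + 1/2) h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "GeometryMask",
    "SHAPE_NAMES",
    "SYMMETRIC_SHAPES",
    "ASYMMETRIC_SHAPES",
    "make_shape",
    "import_mask",
    "export_mask",
]

SYMMETRIC_SHAPES = ("circle", "ellipse", "square", "rectangle")
ASYMMETRIC_SHAPES = ("teardrop", "narrow_drop", "wide_drop", "triangle")
SHAPE_NAMES = SYMMETRIC_SHAPES + ASYMMETRIC_SHAPES

# 4-connectivity structuring element (no diagonals)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class GeometryMask:
    """A rasterized cell interior on a regular square grid.

    Attributes
    ----------
    nx, ny : int
        Grid cells along x and y.
    h : float
        Grid spacing in μm (equal in both directions).
    inside : ndarray of bool, shape (ny, nx)
        True for interior (cytosolic) cells; row index is y, column x.
    shape_name : str
        Label of the generating outline ("imported" for raster imports).
    length, width : float
        Physical x- and y-extent of the outline in μm.
    """

    nx: int
    ny: int
    h: float
    inside: np.ndarray
    shape_name: str
    length: float
    width: float
    # bounding-box offset of the shape's left/bottom corner in grid μm
    x0: float = 0.0
    y0: float = 0.0
    _interior: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != (self.ny, self.nx):
            raise ValueError("inside must have shape (ny, nx)")
        if not self.inside.any():
            raise ValueError("mask has no interior cells")
        n_comp = ndimage.label(self.inside, structure=_STRUCT4)[1]
        if n_comp != 1:
            raise ValueError(f"mask must be a single 4-connected component, got {n_comp}")
        self._interior = np.flatnonzero(self.inside.ravel())

    # -- derived quantities -------------------------------------------------

    @property
    def n_interior(self) -> int:
        return self._interior.size

    @property
    def interior_indices(self) -> np.ndarray:
        """Flat (row-major) indices of interior cells."""
        return self._interior

    @property
    def area(self) -> float:
        """Rasterized area in μm² (pixel count × h²)."""
        return float(self.n_interior) * self.h**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of interior cell centers, in μm measured
        from the left/bottom edge of the shape's bounding box."""
        iy, ix = np.unravel_index(self._interior, (self.ny, self.nx))
        x = (ix + 0.5) * self.h - self.x0
        y = (iy + 0.5) * self.h - self.y0
        return x, y

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a vector over interior cells back onto the (ny, nx) grid."""
        grid = np.full(self.ny * self.nx, fill, dtype=float)
        grid[self._interior] = values
        return grid.reshape(self.ny, self.nx)

    def mirrored(self, axis: str = "x") -> "GeometryMask":
        """Mirror image of the mask (axis='x' flips left-right)."""
        flip = np.fliplr if axis == "x" else np.flipud
        m = GeometryMask(
            nx=self.nx, ny=self.ny, h=self.h, inside=flip(self.inside).copy(),
            shape_name=self.shape_name, length=self.length, width=self.width,
        )
        # recompute bounding-box offsets from the flipped raster
        iy, ix = np.nonzero(m.inside)
        m.x0 = ix.min() * self.h
        m.y0 = iy.min() * self.h
        return m


def _outline_predicate(shape_name: str, length: float, width: float, h: float):
    """Return f(dx, dy) -> bool for points inside the outline.

    Coordinates are centered: dx from the shape center along x, dy from
    the horizontal midline; using |dy| (and |dx| where applicable) keeps
    rasterization exactly mirror-symmetric.
    """
    L, W = length, width

    if shape_name in ("circle", "ellipse"):
        a, b = L / 2.0, W / 2.0
        return lambda dx, dy: (dx / a) ** 2 + (dy / b) ** 2 <= 1.0

    if shape_name in ("square", "rectangle"):
        return lambda dx, dy: (np.abs(dx) <= L / 2.0) & (np.abs(dy) <= W / 2.0)

    if shape_name == "triangle":
        # isoceles, apex at -x, blunt vertical edge at +x
        def inside(dx, dy):
            x = dx + L / 2.0
            # a pointed apex keeps at least a one-cell spine when the
            # analytic taper falls below the grid resolution
            half = np.maximum((W / 2.0) * x / L, 0.55 * h)
            return (x >= 0) & (x <= L) & (np.abs(dy) <= half)
        return inside

    if shape_name in ("teardrop", "narrow_drop", "wide_drop"):
        # blunt half-ellipse at +x joined to a triangular tail tapering to
        # a point at x = 0.  The blunt cap's x semi-axis sets how stubby
        # the drop looks; outlines are import-overridable approximations.
        cap_frac = {"teardrop": 0.5, "narrow_drop": 1.0 / 3.0, "wide_drop": 2.0 / 3.0}[shape_name]
        ax = min(W / 2.0, cap_frac * L)
        xc = L - ax  # cap center, bounding-box coordinates

        def inside(dx, dy):
            x = dx + L / 2.0
            cap = (((x - xc) / ax) ** 2 + (dy / (W / 2.0)) ** 2 <= 1.0) & (x >= xc)
            half = np.maximum((W / 2.0) * x / xc, 0.55 * h)
            tail = (x >= 0) & (x < xc) & (np.abs(dy) <= half)
            return cap | tail

        return inside

    raise ValueError(f"unknown shape_name {shape_name!r}; expected one of {SHAPE_NAMES}")


def make_shape(shape_name: str, length: float, width: float, n_mesh: int = 110) -> GeometryMask:
    """Rasterize a parametric cell outline on an ``n_mesh`` × ``n_mesh`` grid.

    The grid spacing is chosen so the longest shape extent plus a two-cell
    margin spans ``n_mesh`` cells; the shape is centered.

    Parameters
    ----------
    shape_name : one of ``SHAPE_NAMES``
    length, width : float
        x- and y-extent of the outline in μm.
    n_mesh : int
        Cells per grid axis (≥ 20).
    """
    if shape_name not in SHAPE_NAMES:
        raise ValueError(f"unknown shape_name {shape_name!r}; expected one of {SHAPE_NAMES}")
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    if n_mesh < 20:
        raise ValueError("n_mesh must be at least 20")
    if shape_name == "circle" and not np.isclose(length, width):
        raise ValueError("a circle needs length == width; use 'ellipse' otherwise")
    if shape_name == "square" and not np.isclose(length, width):
        raise ValueError("a square needs length == width; use 'rectangle' otherwise")

    # h solves max_extent + 2h = n_mesh * h
    h = max(length, width) / (n_mesh - 2)
    if length < 3 * h or width < 3 * h:
        raise ValueError(
            f"degenerate dimensions: length and width must each be >= 3h = {3 * h:.3g} μm"
        )
    nx = ny = n_mesh
    # center the bounding box on the grid
    x0 = (nx * h - length) / 2.0
    y0 = (ny * h - width) / 2.0

    # centered coordinates, rounded so mirror-paired cells are bitwise equal
    dx = np.round((np.arange(nx) + 0.5) * h - x0 - length / 2.0, 9)
    dy = np.round((np.arange(ny) + 0.5) * h - y0 - width / 2.0, 9)
    DX, DY = np.meshgrid(dx, dy)
    inside = _outline_predicate(shape_name, length, width, h)(DX, DY)

    # drop stray diagonal-only pixels (thin tails can rasterize to
    # disconnected specks); keep the largest 4-connected component
    labels, n_comp = ndimage.label(inside, structure=_STRUCT4)
    if n_comp > 1:
        sizes = ndimage.sum_labels(inside, labels, index=np.arange(1, n_comp + 1))
        inside = labels == (1 + int(np.argmax(sizes)))

    return GeometryMask(
        nx=nx, ny=ny, h=h, inside=inside,
        shape_name=shape_name, length=float(length), width=float(width),
        x0=x0, y0=y0,
    )


def export_mask(geom: GeometryMask, path) -> None:
    """Write the mask as an 8-bit image (foreground 255, background 0).

    The format follows the file suffix (PNG or PGM).  Image row 0 is the
    top of the picture, so the grid is flipped vertically on write.
    """
    img = np.where(np.flipud(geom.inside), 255, 0).astype(np.uint8)
    Image.fromarray(img).save(path)


def import_mask(image, pixel_size: float, shape_name: str = "imported") -> GeometryMask:
    """Build a GeometryMask from a binary raster image.

    Parameters
    ----------
    image : path or ndarray
        8-bit image (or boolean array); pixels > 127 (or True) are
        foreground.  Must contain exactly one 4-connected component.
    pixel_size : float
        Physical size of one pixel in μm.
    """
    if isinstance(image, np.ndarray):
        arr = image
    else:
        arr = np.asarray(Image.open(image).convert("L"))
        arr = np.flipud(arr)  # image rows top-down -> grid rows bottom-up
    inside = arr > 127 if arr.dtype != bool else arr
    if not inside.any():
        raise ValueError("image has empty foreground")
    n_comp = ndimage.label(inside, structure=_STRUCT4)[1]
    if n_comp != 1:
        raise ValueError(f"image must have exactly one foreground component, got {n_comp}")

    ny, nx = inside.shape
    iy, ix = np.nonzero(inside)
    h = float(pixel_size)
    length = (ix.max() - ix.min() + 1) * h
    width = (iy.max() - iy.min() + 1) * h
    return GeometryMask(
        nx=nx, ny=ny, h=h, inside=inside.copy(),
        shape_name=shape_name, length=length, width=width,
        x0=ix.min() * h, y0=iy.min() * h,
    )
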