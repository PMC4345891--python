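"""Regions of interest, hierarchical grid tilings, and DMD pattern masks.

A DMD (digital micromirror device) projects binary illumination patterns
onto the sample: each micromirror is either ON or OFF.  Stimulation
targets are defined in *camera* pixel coordinates on a background image
of the field of view, then rasterized to the DMD pixel grid through a
calibration transform.

Coordinate conventions used throughout:

* 0-based pixel indices, origin at the top-left, row-major arrays;
* a point is ``(x, y)`` with ``x`` along columns and ``y`` along rows;
* pixel ``(r, c)`` has its center at ``(c + 0.5, r + 0.5)``;
* rectangular bounds ``(x0, y0, x1, y1)`` are half-open: the region
  covers ``x0 <= x < x1`` and ``y0 <= y < y1``.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "DEFAULT_DMD_SHAPE",
    "ROI",
    "CalibrationTransform",
    "PatternMask",
    "GridCell",
    "SmartGrid",
    "ValidationError",
    "EmptyMaskWarning",
    "make_roi",
    "rasterize",
    "grid_create",
    "grid_subdivide",
    "grid_merge",
    "grid_export",
    "cell_dimensions_um",
    "group_masks",
    "save_masks",
    "load_masks",
    "load_image",
]

#: Default DMD resolution (rows, cols); a configuration parameter.
DEFAULT_DMD_SHAPE = (684, 608)

_roi_counter = itertools.count()


class ValidationError(ValueError):
    """Raised when a geometric object violates its invariants."""


class EmptyMaskWarning(UserWarning):
    """Issued when a rasterized ROI contains no ON pixels (e.g. it lies
    entirely outside the DMD extent)."""


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass
class ROI:
    """A stimulation region defined on the camera image.

    ``kind`` is one of ``rectangle``, ``ellipse`` or ``polygon``;
    ``params`` are camera-pixel coordinates:

    * rectangle: ``(x0, y0, x1, y1)`` with ``x1 > x0`` and ``y1 > y0``;
    * ellipse: ``(cx, cy, rx, ry)`` with positive radii;
    * polygon: an ordered vertex list ``[(x, y), ...]`` with at least
      three vertices and nonzero area.
    """

    id: str
    kind: str
    params: tuple
    label: str = ""


def _polygon_area(vertices) -> float:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def make_roi(kind: str, params, label: str = "") -> ROI:
    """Validate geometry and return an :class:`ROI` with a fresh id.

    Raises :class:`ValidationError` naming the offending field for
    degenerate geometry (zero area, fewer than three polygon vertices,
    non-positive ellipse radii).
    """
    if kind == "rectangle":
        x0, y0, x1, y1 = map(float, params)
        if not x1 > x0:
            raise ValidationError(f"rectangle requires x1 > x0, got x0={x0}, x1={x1}")
        if not y1 > y0:
            raise ValidationError(f"rectangle requires y1 > y0, got y0={y0}, y1={y1}")
        clean = (x0, y0, x1, y1)
    elif kind == "ellipse":
        cx, cy, rx, ry = map(float, params)
        if not rx > 0:
            raise ValidationError(f"ellipse requires rx > 0, got rx={rx}")
        if not ry > 0:
            raise ValidationError(f"ellipse requires ry > 0, got ry={ry}")
        clean = (cx, cy, rx, ry)
    elif kind == "polygon":
        verts = [(float(x), float(y)) for x, y in params]
        if len(verts) < 3:
            raise ValidationError(
                f"polygon requires >= 3 vertices, got {len(verts)}"
            )
        if _polygon_area(verts) == 0.0:
            raise ValidationError("polygon has zero area")
        clean = tuple(verts)
    else:
        raise ValidationError(f"unknown ROI kind {kind!r}")
    return ROI(id=f"roi-{next(_roi_counter)}", kind=kind, params=clean, label=label)


# ---------------------------------------------------------------------------
# Calibration transform
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTransform:
    """Affine registration of camera pixels onto DMD pixels.

    ``matrix`` is a 2x3 array ``[A | b]`` mapping a camera point ``p``
    to the DMD point ``A p + b``.  ``um_per_camera_px`` gives the
    physical scale of the camera image.
    """

    matrix: np.ndarray
    um_per_camera_px: float = 1.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValidationError(f"transform matrix must be 2x3, got {self.matrix.shape}")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValidationError("transform is singular (non-invertible linear part)")
        if not self.um_per_camera_px > 0:
            raise ValidationError("um_per_camera_px must be positive")

    @classmethod
    def identity(cls, um_per_camera_px: float = 1.0) -> "CalibrationTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), um_per_camera_px)

    @classmethod
    def uniform_scale(cls, camera_bounds, dmd_shape=DEFAULT_DMD_SHAPE,
                      um_per_camera_px: float = 1.0) -> "CalibrationTransform":
        """Map the camera bounds ``(x0, y0, x1, y1)`` onto the full DMD."""
        x0, y0, x1, y1 = camera_bounds
        rows, cols = dmd_shape
        sx = cols / (x1 - x0)
        sy = rows / (y1 - y0)
        m = np.array([[sx, 0.0, -sx * x0], [0.0, sy, -sy * y0]])
        return cls(m, um_per_camera_px)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Camera -> DMD for an (N, 2) array of points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return p @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        """DMD -> camera for an (N, 2) array of points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a_inv = np.linalg.inv(self.matrix[:, :2])
        return (p - self.matrix[:, 2]) @ a_inv.T

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(),
                "um_per_camera_px": self.um_per_camera_px}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTransform":
        return cls(np.asarray(d["matrix"], dtype=float), d["um_per_camera_px"])


# ---------------------------------------------------------------------------
# Pattern masks
# ---------------------------------------------------------------------------

@dataclass
class PatternMask:
    """Boolean DMD-pixel grid naming which micromirrors are ON."""

    id: str
    grid: np.ndarray
    member_roi_ids: list = field(default_factory=list)

    @property
    def n_on(self) -> int:
        return int(self.grid.sum())


def _dmd_pixel_centers_in_camera(transform: CalibrationTransform, dmd_shape):
    rows, cols = dmd_shape
    cx = np.arange(cols) + 0.5
    cy = np.arange(rows) + 0.5
    gx, gy = np.meshgrid(cx, cy)                      # (rows, cols)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    cam = transform.inverse_apply(pts)
    return cam[:, 0].reshape(rows, cols), cam[:, 1].reshape(rows, cols)


def _points_in_polygon(x: np.ndarray, y: np.ndarray, vertices) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized.

    Points exactly on an edge are not guaranteed a consistent answer;
    membership is intended for pixel centers at half-integer positions.
    """
    inside = np.zeros(x.shape, dtype=bool)
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    j = n - 1
    for i in range(n):
        xi, yi = v[i]
        xj, yj = v[j]
        crosses = (yi > y) != (yj > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_edge = (xj - xi) * (y - yi) / (yj - yi) + xi
        inside ^= crosses & (x < x_edge)
        j = i
    return inside


def _roi_membership(roi: ROI, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if roi.kind == "rectangle":
        x0, y0, x1, y1 = roi.params
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if roi.kind == "ellipse":
        cx, cy, rx, ry = roi.params
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    if roi.kind == "polygon":
        return _points_in_polygon(x, y, roi.params)
    raise ValidationError(f"unknown ROI kind {roi.kind!r}")


def rasterize(roi: ROI, transform: CalibrationTransform,
              dmd_shape=DEFAULT_DMD_SHAPE) -> PatternMask:
    """Rasterize an ROI to a DMD pattern mask.

    DMD pixel ``(r, c)`` is ON iff its center, mapped back to camera
    coordinates through the inverse calibration transform, lies inside
    the ROI.  Boundary rule: inside-or-on for rectangles and ellipses;
    strict interior under the even-odd rule for polygons.

    An ROI entirely outside the DMD extent yields an empty mask and an
    :class:`EmptyMaskWarning` (not an error).
    """
    rows, cols = dmd_shape
    if rows < 1 or cols < 1:
        raise ValidationError(f"dmd_shape must be positive, got {dmd_shape}")
    x, y = _dmd_pixel_centers_in_camera(transform, dmd_shape)
    grid = _roi_membership(roi, x, y)
    mask = PatternMask(id=roi.id, grid=grid, member_roi_ids=[roi.id])
    if mask.n_on == 0:
        warnings.warn(f"ROI {roi.id!r} rasterizes to an empty mask",
                      EmptyMaskWarning, stacklevel=2)
    return mask


def group_masks(masks, id: str | None = None) -> PatternMask:
    """Pixelwise OR of several masks into one grouped pattern."""
    masks = list(masks)
    if not masks:
        raise ValueError("cannot group an empty mask list")
    grid = np.zeros_like(masks[0].grid, dtype=bool)
    members = []
    for m in masks:
        if m.grid.shape != grid.shape:
            raise ValueError("all masks in a group must share the DMD shape")
        grid |= m.grid
        members.extend(m.member_roi_ids)
    return PatternMask(id=id or "+".join(m.id for m in masks),
                       grid=grid, member_roi_ids=members)


# ---------------------------------------------------------------------------
# SmartGrid
# ---------------------------------------------------------------------------

def _split_edges(lo: int, hi: int, n: int) -> list[int]:
    """Split [lo, hi) into n integer spans; remainder pixels go to the
    lowest-index spans (left-to-right / top-to-bottom)."""
    span = hi - lo
    base, rem = divmod(span, n)
    edges = [lo]
    for i in range(n):
        edges.append(edges[-1] + base + (1 if i < rem else 0))
    return edges


@dataclass
class GridCell:
    """One rectangular cell of a :class:`SmartGrid`.

    ``bounds`` are integer camera pixels (half-open) and drive
    rasterization; ``nominal_bounds`` carry the exact fractional
    subdivision and drive physical-dimension reporting, so a cell from
    a 3-way split of 724 px reports 724/3 = 241.3 um even though its
    pixel footprint is 241 or 242 px.
    """

    id: str
    bounds: tuple[int, int, int, int]
    nominal_bounds: tuple[float, float, float, float]
    children: list["GridCell"] = field(default_factory=list)
    selected: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def px_size(self) -> tuple[int, int]:
        x0, y0, x1, y1 = self.bounds
        return (x1 - x0, y1 - y0)


class SmartGrid:
    """Hierarchical rectangular tiling of the field of view.

    The root covers the full bounds; any leaf can be subdivided into an
    r x c grid of children (down to the pixel limit of the DMD), and
    sibling leaves whose union is a rectangle can be merged back.  Leaf
    cells carry a selection flag used for pattern export.
    """

    def __init__(self, bounds: tuple[int, int, int, int]):
        x0, y0, x1, y1 = (int(v) for v in bounds)
        if not (x1 > x0 and y1 > y0):
            raise ValidationError(f"degenerate grid bounds {bounds}")
        self.bounds = (x0, y0, x1, y1)
        self.root = GridCell(id="0", bounds=self.bounds,
                             nominal_bounds=tuple(float(v) for v in self.bounds))
        self._index: dict[str, GridCell] = {"0": self.root}
        self._merge_counter = itertools.count()

    # -- lookup -----------------------------------------------------------
    def cell(self, cell_id: str) -> GridCell:
        try:
            return self._index[cell_id]
        except KeyError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None

    def parent_of(self, cell_id: str) -> GridCell | None:
        for cell in self._index.values():
            if any(child.id == cell_id for child in cell.children):
                return cell
        return None

    def leaves(self) -> list[GridCell]:
        out = []

        def walk(cell):
            if cell.is_leaf:
                out.append(cell)
            else:
                for ch in cell.children:
                    walk(ch)

        walk(self.root)
        return out

    # -- mutation ---------------------------------------------------------
    def subdivide(self, cell_id: str, rows: int, cols: int) -> None:
        cell = self.cell(cell_id)
        if not cell.is_leaf:
            raise ValueError(f"cell {cell_id!r} is not a leaf and cannot be subdivided")
        if rows < 1 or cols < 1:
            raise ValueError(f"rows and cols must be >= 1, got {rows}x{cols}")
        w, h = cell.px_size
        if cols > w or rows > h:
            raise ValueError(
                f"cannot subdivide a {w}x{h} px cell into {rows}x{cols}: "
                "below the pixel limit of the DMD"
            )
        x0, y0, x1, y1 = cell.bounds
        xe = _split_edges(x0, x1, cols)
        ye = _split_edges(y0, y1, rows)
        nx0, ny0, nx1, ny1 = cell.nominal_bounds
        nxw = (nx1 - nx0) / cols
        nyh = (ny1 - ny0) / rows
        cell.children = []
        for r in range(rows):
            for c in range(cols):
                k = r * cols + c
                child = GridCell(
                    id=f"{cell.id}.{k}",
                    bounds=(xe[c], ye[r], xe[c + 1], ye[r + 1]),
                    nominal_bounds=(nx0 + c * nxw, ny0 + r * nyh,
                                    nx0 + (c + 1) * nxw, ny0 + (r + 1) * nyh),
                )
                cell.children.append(child)
                self._index[child.id] = child
        cell.selected = False

    def merge(self, cell_ids) -> GridCell:
        cell_ids = list(cell_ids)
        if not cell_ids:
            raise ValueError("merge requires at least one cell id")
        cells = [self.cell(cid) for cid in cell_ids]
        for c in cells:
            if not c.is_leaf:
                raise ValueError(f"cell {c.id!r} is not a leaf and cannot be merged")
        parents = {id(self.parent_of(cid)) for cid in cell_ids}
        parent = self.parent_of(cell_ids[0])
        if parent is None:
            raise ValueError("the root cell cannot be merged")
        if len(parents) != 1:
            raise ValueError("cells to merge must share a parent")
        bx0 = min(c.bounds[0] for c in cells)
        by0 = min(c.bounds[1] for c in cells)
        bx1 = max(c.bounds[2] for c in cells)
        by1 = max(c.bounds[3] for c in cells)
        area = sum((c.bounds[2] - c.bounds[0]) * (c.bounds[3] - c.bounds[1])
                   for c in cells)
        if area != (bx1 - bx0) * (by1 - by0):
            raise ValueError("cells to merge must form an exact rectangle")
        nx0 = min(c.nominal_bounds[0] for c in cells)
        ny0 = min(c.nominal_bounds[1] for c in cells)
        nx1 = max(c.nominal_bounds[2] for c in cells)
        ny1 = max(c.nominal_bounds[3] for c in cells)
        merged = GridCell(id=f"{parent.id}.m{next(self._merge_counter)}",
                          bounds=(bx0, by0, bx1, by1),
                          nominal_bounds=(nx0, ny0, nx1, ny1))
        keep = [ch for ch in parent.children if ch.id not in set(cell_ids)]
        for cid in cell_ids:
            del self._index[cid]
        if not keep and merged.bounds == parent.bounds:
            # merging every child restores the parent as a leaf
            parent.children = []
            return parent
        parent.children = keep + [merged]
        self._index[merged.id] = merged
        return merged

    def select(self, cell_ids, selected: bool = True) -> None:
        for cid in cell_ids:
            cell = self.cell(cid)
            if not cell.is_leaf:
                raise ValueError(f"only leaf cells may be selected, {cid!r} has children")
            cell.selected = selected

    def selected_ids(self) -> list[str]:
        return [c.id for c in self.leaves() if c.selected]

    # -- queries ----------------------------------------------------------
    def cell_dimensions_um(self, cell_id: str, um_per_camera_px: float) -> tuple[int, int]:
        """Physical cell size, rounded to the nearest micrometre
        (ties away from zero).  Uses the exact fractional span."""
        cell = self.cell(cell_id)
        nx0, ny0, nx1, ny1 = cell.nominal_bounds
        w = (nx1 - nx0) * um_per_camera_px
        h = (ny1 - ny0) * um_per_camera_px
        return (int(math.floor(w + 0.5)), int(math.floor(h + 0.5)))

    def rasterize_cell(self, cell_id: str, transform: CalibrationTransform,
                       dmd_shape=DEFAULT_DMD_SHAPE) -> PatternMask:
        """Rasterize a cell with half-open membership so that sibling
        cells never share DMD pixels."""
        cell = self.cell(cell_id)
        x, y = _dmd_pixel_centers_in_camera(transform, dmd_shape)
        x0, y0, x1, y1 = cell.bounds
        grid = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        return PatternMask(id=cell.id, grid=grid, member_roi_ids=[cell.id])

    def export(self, selected_ids=None, grouped: bool = False,
               transform: CalibrationTransform | None = None,
               dmd_shape=DEFAULT_DMD_SHAPE) -> list[PatternMask]:
        """Export selected cells as DMD pattern masks.

        ``grouped=False`` returns one mask per cell; ``grouped=True``
        returns a single mask that is the pixelwise OR of the per-cell
        masks (simultaneous stimulation of possibly non-adjacent areas).
        """
        if selected_ids is None:
            selected_ids = self.selected_ids()
        selected_ids = list(selected_ids)
        if not selected_ids:
            raise ValueError("empty selection: nothing to export")
        if transform is None:
            transform = CalibrationTransform.identity()
        masks = [self.rasterize_cell(cid, transform, dmd_shape)
                 for cid in selected_ids]
        if grouped:
            return [group_masks(masks)]
        return masks

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def encode(cell):
            return {
                "id": cell.id,
                "bounds": list(cell.bounds),
                "nominal_bounds": list(cell.nominal_bounds),
                "selected": cell.selected,
                "children": [encode(ch) for ch in cell.children],
            }

        return {"bounds": list(self.bounds), "root": encode(self.root)}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SmartGrid":
        grid = cls(tuple(d["bounds"]))

        def decode(node) -> GridCell:
            cell = GridCell(id=node["id"],
                            bounds=tuple(node["bounds"]),
                            nominal_bounds=tuple(node["nominal_bounds"]),
                            selected=node["selected"])
            cell.children = [decode(ch) for ch in node["children"]]
            return cell

        grid.root = decode(d["root"])
        grid._index = {}

        def index(cell):
            grid._index[cell.id] = cell
            for ch in cell.children:
                index(ch)

        index(grid.root)
        return grid

    @classmethod
    def from_json(cls, source) -> "SmartGrid":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Functional front-ends
# ---------------------------------------------------------------------------

def grid_create(bounds, rows: int, cols: int) -> SmartGrid:
    """Create a grid whose root is subdivided into ``rows x cols`` leaves.

    Column pixel widths differ by at most one; remainder pixels are
    assigned left-to-right (and top-to-bottom for rows).
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"rows and cols must be >= 1, got {rows}x{cols}")
    grid = SmartGrid(bounds)
    if (rows, cols) != (1, 1):
        grid.subdivide("0", rows, cols)
    return grid


def grid_subdivide(grid: SmartGrid, cell_id: str, rows: int, cols: int) -> SmartGrid:
    grid.subdivide(cell_id, rows, cols)
    return grid


def grid_merge(grid: SmartGrid, cell_ids) -> SmartGrid:
    grid.merge(cell_ids)
    return grid


def grid_export(grid: SmartGrid, selected_ids=None, grouped: bool = False,
                transform: CalibrationTransform | None = None,
                dmd_shape=DEFAULT_DMD_SHAPE) -> list[PatternMask]:
    return grid.export(selected_ids, grouped, transform, dmd_shape)


def cell_dimensions_um(grid: SmartGrid, cell_id: str,
                       um_per_camera_px: float) -> tuple[int, int]:
    return grid.cell_dimensions_um(cell_id, um_per_camera_px)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_masks(masks, tiff_path, sidecar_path=None,
               transform: CalibrationTransform | None = None) -> None:
    """Persist masks as a multi-page TIFF (one 0/255 page per pattern)
    plus a JSON sidecar recording ids, provenance and calibration."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to save")
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    stack = np.stack([m.grid.astype(np.uint8) * 255 for m in masks])
    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    sidecar = {
        "dmd_shape": list(masks[0].grid.shape),
        "patterns": [{"id": m.id, "member_roi_ids": m.member_roi_ids}
                     for m in masks],
        "transform": transform.to_dict() if transform is not None else None,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def load_masks(tiff_path, sidecar_path=None):
    """Inverse of :func:`save_masks`; returns ``(masks, transform_or_None)``."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    if not tiff_path.exists():
        raise FileNotFoundError(f"mask stack not found: {tiff_path}")
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None, ...]
    sidecar = json.loads(Path(sidecar_path).read_text())
    masks = [PatternMask(id=rec["id"], grid=page > 0,
                         member_roi_ids=list(rec["member_roi_ids"]))
             for rec, page in zip(sidecar["patterns"], stack)]
    t = sidecar.get("transform")
    transform = CalibrationTransform.from_dict(t) if t else None
    return masks, transform


def load_image(path) -> np.ndarray:
    """Load a background field-of-view image (8/16-bit gray TIFF, or PNG)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)
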