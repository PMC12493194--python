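"""Midsagittal corpus callosum morphometry from 2D binary masks.

Given a binary mask of the callosal cross-section with known in-plane pixel
spacing, this module measures

* the total midsagittal area (foreground pixel count times pixel area), and
* a regional thickness profile: the callosal outline is traced, split at two
  anatomical landmarks (tip of the rostrum, base of the splenium) into a
  dorsal and a ventral arc, both arcs are resampled to ``n`` equidistant
  points, a midline is formed as the pointwise mean of the two arcs, and the
  local thickness is the distance between the two outlines measured along
  the line orthogonal to the (smoothed) midline at each of the ``n``
  sampling points, ordered anterior to posterior.

Coordinate conventions
----------------------
The canonical grid orientation maps columns to the anterior->posterior axis
(anterior at low column index) and rows to the dorsal->ventral axis (dorsal
at low row index).  Masks declared in another orientation are flipped into
canonical form before processing.  Pixel ``(i, j)`` has its centre at
``x = (j + 0.5) * col_mm``, ``y = (i + 0.5) * row_mm``; larger ``y`` is more
ventral.

Contours are traced over the border pixels (foreground pixels with at least
one 4-connected background neighbour) with Moore neighbour tracing, and the
vertices are then pushed half a pixel outward along the local normal so that
the polygon approximates the boundary of the pixel union rather than the
chain of pixel centres (``boundary_offset=0`` restores raw centres).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "AreaMeasure",
    "BinaryMask",
    "Contour",
    "Landmarks",
    "MaskError",
    "LandmarkError",
    "MorphometryResult",
    "Orientation",
    "ThicknessProfile",
    "clean_mask",
    "compute_area",
    "compute_midline",
    "detect_landmarks",
    "extract_outline",
    "measure_thickness",
    "profile_pipeline",
    "resample_contour",
    "split_contour",
]

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class MaskError(ValueError):
    """Raised for masks that cannot be measured (empty, fragmented, holed)."""


class LandmarkError(ValueError):
    """Raised when automatic landmark detection finds no plausible anatomy."""


@dataclass(frozen=True)
class Orientation:
    """Declared mapping of grid axes onto anatomical axes.

    ``transpose``: the anterior-posterior axis runs along grid rows instead
    of columns (applied first during canonicalization).  After any
    transposition, ``anterior_low_col`` says the anterior end sits at low
    column indices and ``dorsal_low_row`` that the dorsal side sits at low
    row indices.  The canonical orientation is ``(False, True, True)``.
    """

    anterior_low_col: bool = True
    dorsal_low_row: bool = True
    transpose: bool = False


@dataclass
class BinaryMask:
    """A 2D binary mask with physical pixel spacing.

    ``spacing`` is ``(row_mm, col_mm)``, the pixel edge lengths in mm (the
    source study used 0.7 x 0.7 mm).
    """

    grid: np.ndarray
    spacing: tuple[float, float] = (0.7, 0.7)
    orientation: Orientation = field(default_factory=Orientation)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise MaskError(f"mask grid must be 2D, got shape {grid.shape}")
        if not np.isin(grid, (0, 1)).all():
            raise MaskError("mask grid must contain only 0/1 values")
        if min(self.spacing) <= 0:
            raise MaskError(f"pixel spacing must be positive, got {self.spacing}")
        self.grid = grid.astype(bool)

    def canonical(self) -> "BinaryMask":
        """Return a copy flipped into the canonical orientation."""
        grid = self.grid
        spacing = self.spacing
        if self.orientation.transpose:
            grid = grid.T
            spacing = (spacing[1], spacing[0])
        if not self.orientation.anterior_low_col:
            grid = grid[:, ::-1]
        if not self.orientation.dorsal_low_row:
            grid = grid[::-1, :]
        return BinaryMask(grid=grid.copy(), spacing=spacing)

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())


@dataclass
class Contour:
    """An ordered boundary polyline in mm coordinates.

    ``points`` has shape (N, 2) with columns (x, y); ``pixels`` holds the
    traced border-pixel indices (row, col) of the same length (empty for
    contours that were not traced from a grid).  A closed contour ends
    adjacent to its start (the first point is not repeated).
    """

    points: np.ndarray
    closed: bool
    pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must have shape (N, 2)")
        if len(self.points) > 1 and np.any(
            np.all(np.diff(self.points, axis=0) == 0, axis=1)
        ):
            raise ValueError("contour contains repeated consecutive points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Landmarks:
    """Indices into a closed contour of the two split landmarks."""

    rostrum_tip: int
    splenium_base: int

    def __post_init__(self) -> None:
        if self.rostrum_tip == self.splenium_base:
            raise LandmarkError("landmarks must be two distinct contour points")


@dataclass(frozen=True)
class AreaMeasure:
    """Total midsagittal area as pixel count times pixel area."""

    voxel_count: int
    pixel_area_mm2: float

    @property
    def area_mm2(self) -> float:
        return self.voxel_count * self.pixel_area_mm2


@dataclass
class ThicknessProfile:
    """Regional thickness sampled along the callosal midline.

    ``thickness`` holds ``n`` values (mm) ordered anterior to posterior;
    ``midline`` is the pointwise mean of ``dorsal_pts`` and ``ventral_pts``
    (the paired equidistant sampling coordinates on the two outlines).
    ``fallback`` flags segments where the orthogonal line failed to cross an
    outline and a nearest-point distance was substituted; ``terminal`` flags
    the first and last segment, whose tangents use one-sided differences.
    """

    thickness: np.ndarray
    midline: np.ndarray
    dorsal_pts: np.ndarray
    ventral_pts: np.ndarray
    fallback: np.ndarray
    terminal: np.ndarray
    dorsal_hits: np.ndarray | None = None
    ventral_hits: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.thickness)
        for name in ("midline", "dorsal_pts", "ventral_pts", "fallback", "terminal"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match thickness length {n}")
        if not np.all(np.isfinite(self.thickness)) or np.any(self.thickness < 0):
            raise ValueError("thickness values must be finite and non-negative")

    @property
    def n_points(self) -> int:
        return len(self.thickness)


@dataclass
class MorphometryResult:
    """Bundle returned by :func:`profile_pipeline`."""

    area: AreaMeasure
    profile: ThicknessProfile
    landmarks: Landmarks
    contour: Contour
    provenance: dict


# ---------------------------------------------------------------------------
# mask cleanup and area
# ---------------------------------------------------------------------------


def clean_mask(mask: BinaryMask) -> tuple[BinaryMask, dict]:
    """Deterministic stand-in for manual mask editing: keep the largest
    4-connected component and fill interior holes.  Returns the cleaned
    mask and a report of what was removed/filled."""
    grid = mask.canonical().grid
    if not grid.any():
        raise MaskError("mask is empty: corpus callosum extraction failed")
    labels, n_comp = ndimage.label(grid, structure=_FOUR_CONNECTED)
    if n_comp > 1:
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        grid = labels == keep
        removed = int(sizes.sum() - sizes[keep - 1])
    else:
        removed = 0
    filled = ndimage.binary_fill_holes(grid)
    n_filled = int(filled.sum() - grid.sum())
    report = {
        "components_removed": n_comp - 1,
        "pixels_removed": removed,
        "holes_filled_pixels": n_filled,
    }
    return BinaryMask(grid=filled, spacing=mask.spacing), report


def compute_area(mask: BinaryMask) -> AreaMeasure:
    """Foreground pixel count times pixel area (exact by construction)."""
    count = mask.foreground_count
    if count == 0:
        raise MaskError("mask is empty: corpus callosum extraction failed")
    row_mm, col_mm = mask.spacing
    return AreaMeasure(voxel_count=count, pixel_area_mm2=row_mm * col_mm)


# ---------------------------------------------------------------------------
# outline extraction
# ---------------------------------------------------------------------------

# Moore neighbourhood in clockwise order starting West (row, col offsets;
# rows grow downward so "clockwise" here is clockwise in image coordinates).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_INDEX = {off: k for k, off in enumerate(_MOORE)}


def border_pixels(grid: np.ndarray) -> np.ndarray:
    """Boolean map of foreground pixels with >=1 background 4-neighbour."""
    eroded = ndimage.binary_erosion(grid, structure=_FOUR_CONNECTED, border_value=0)
    return grid & ~eroded


def _moore_trace(grid: np.ndarray) -> list[tuple[int, int]]:
    """Trace the outer boundary of a single 4-connected component.

    Returns the ordered list of border pixels (row, col).  Uses Jacob's
    stopping criterion (stop on re-entering the start pixel from the same
    backtrack direction).
    """
    padded = np.zeros((grid.shape[0] + 2, grid.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = grid
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    if len(rows) == 1:
        return [(start[0] - 1, start[1] - 1)]
    backtrack = (start[0], start[1] - 1)  # west neighbour, background
    path: list[tuple[int, int]] = []
    cur, prev_bg = start, backtrack
    seen: dict[tuple, int] = {}
    limit = 8 * int(padded.sum()) + 8
    while (cur, prev_bg) not in seen:
        seen[(cur, prev_bg)] = len(path)
        path.append(cur)
        if len(path) > limit:  # safety net, unreachable for valid masks
            raise MaskError("boundary tracing failed to terminate")
        k = _MOORE_INDEX[(prev_bg[0] - cur[0], prev_bg[1] - cur[1])]
        bg = prev_bg
        for step in range(1, 9):
            off = _MOORE[(k + step) % 8]
            cand = (cur[0] + off[0], cur[1] + off[1])
            if padded[cand]:
                cur, prev_bg = cand, bg
                break
            bg = cand
    # the tracer is a deterministic map on (pixel, backtrack) states; the
    # closed boundary is the cycle of that map, extracted at first recurrence
    path = path[seen[(cur, prev_bg)] :]
    return [(r - 1, c - 1) for r, c in path]


def _pixel_centers(pixels: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    row_mm, col_mm = spacing
    xy = np.empty((len(pixels), 2), dtype=float)
    xy[:, 0] = (pixels[:, 1] + 0.5) * col_mm
    xy[:, 1] = (pixels[:, 0] + 0.5) * row_mm
    return xy


def _offset_outward(
    points: np.ndarray, spacing: tuple[float, float], amount: float
) -> np.ndarray:
    """Push closed-contour vertices outward along the local normal by
    ``amount`` pixels (per-axis, so axis-aligned edges move exactly
    ``amount * spacing``)."""
    if amount == 0 or len(points) < 3:
        return points
    row_mm, col_mm = spacing
    tangent = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    norm[norm == 0] = 1.0
    tangent = tangent / norm[:, None]
    # signed area > 0 => counter-clockwise in (x, y); outward normal is then
    # (t_y, -t_x), otherwise (-t_y, t_x)
    x, y = points[:, 0], points[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 > 0:
        normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    else:
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    shift = np.column_stack([normal[:, 0] * amount * col_mm, normal[:, 1] * amount * row_mm])
    return points + shift


def extract_outline(
    mask: BinaryMask, boundary_offset: float = 0.5, validate: bool = True
) -> Contour:
    """Trace the closed outline of a single-component, hole-free mask.

    Every border pixel (foreground pixel with a background 4-neighbour) is
    represented in the traced path.  ``boundary_offset`` (pixels) pushes the
    vertices outward along the local normal; 0 keeps raw pixel centres.
    """
    mask = mask.canonical()
    grid = mask.grid
    if not grid.any():
        raise MaskError("mask is empty")
    if validate:
        _, n_comp = ndimage.label(grid, structure=_FOUR_CONNECTED)
        if n_comp != 1:
            raise MaskError(
                f"mask has {n_comp} 4-connected components; run clean_mask first"
            )
        if ndimage.binary_fill_holes(grid).sum() != grid.sum():
            raise MaskError("mask has interior holes; run clean_mask first")
    traced = _moore_trace(grid)
    border = border_pixels(grid)
    traced_set = set(traced)
    missing = set(zip(*np.nonzero(border))) - traced_set
    if missing:
        raise MaskError(
            f"{len(missing)} border pixels unreachable by outer-boundary "
            "tracing (shape too thin or degenerate)"
        )
    pixels = np.asarray(traced, dtype=int)
    points = _pixel_centers(pixels, mask.spacing)
    # drop consecutive duplicates that 1-px-wide necks can produce
    if len(points) > 1:
        keep = np.ones(len(points), dtype=bool)
        keep[1:] = np.any(np.diff(points, axis=0) != 0, axis=1)
        points, pixels = points[keep], pixels[keep]
    points = _offset_outward(points, mask.spacing, boundary_offset)
    return Contour(points=points, closed=True, pixels=pixels)


# ---------------------------------------------------------------------------
# landmarks and contour splitting
# ---------------------------------------------------------------------------


def detect_landmarks(
    contour: Contour,
    anterior_fraction: float = 0.5,
    override: tuple[Sequence[float] | None, Sequence[float] | None] | None = None,
    min_hook_margin_mm: float = 1.0,
) -> Landmarks:
    """Locate the rostrum tip and the splenium base on a closed outline.

    The rostrum tip is the posterior-most contour point within the anterior,
    ventral quadrant of the bounding box (the in-bent hook of the rostrum
    points posteriorly underneath the genu); the splenium base is the
    ventral-most point of the posterior half.  ``override`` supplies manual
    (x, y) coordinates for either landmark (mapped to the nearest contour
    vertex), mirroring the manual correction step of the source protocol.
    """
    pts = contour.points
    x, y = pts[:, 0], pts[:, 1]
    x_min, x_max = x.min(), x.max()
    y_min, y_max = y.min(), y.max()
    x_cut = x_min + anterior_fraction * (x_max - x_min)
    y_mid = 0.5 * (y_min + y_max)

    def nearest(coord: Sequence[float]) -> int:
        d = np.hypot(x - coord[0], y - coord[1])
        return int(np.argmin(d))

    rostrum = splenium = None
    if override is not None:
        if override[0] is not None:
            rostrum = nearest(override[0])
        if override[1] is not None:
            splenium = nearest(override[1])

    if rostrum is None:
        sel = (x <= x_cut) & (y >= y_mid)
        if not sel.any():
            raise LandmarkError("no contour points in the anterior-ventral quadrant")
        cand = np.nonzero(sel)[0]
        rostrum = int(cand[np.argmax(x[cand])])
        if x_cut - x[rostrum] < min_hook_margin_mm:
            raise LandmarkError(
                "no anterior in-bend found (rostrum candidate hugs the "
                "anterior-half cutoff); supply a manual override"
            )
    if splenium is None:
        sel = x >= x_cut
        if not sel.any():
            raise LandmarkError("no contour points in the posterior half")
        cand = np.nonzero(sel)[0]
        splenium = int(cand[np.argmax(y[cand])])
    return Landmarks(rostrum_tip=rostrum, splenium_base=splenium)


def split_contour(
    contour: Contour, landmarks: Landmarks
) -> tuple[Contour, Contour]:
    """Split a closed contour at the two landmarks into the dorsal and the
    ventral arc, both ordered rostrum tip -> splenium base and sharing the
    two landmark endpoints.  The dorsal arc is the one containing the
    topmost (most dorsal) contour point."""
    if not contour.closed:
        raise ValueError("split_contour requires a closed contour")
    n = len(contour)
    i, j = landmarks.rostrum_tip, landmarks.splenium_base
    idx_a = np.arange(i, i + (j - i) % n + 1) % n  # i -> j forward
    idx_b = np.arange(j, j + (i - j) % n + 1) % n  # j -> i forward
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("landmarks split the contour into a zero-length arc")
    idx_b = idx_b[::-1]  # reorder to run i -> j as well
    arc_a = contour.points[idx_a]
    arc_b = contour.points[idx_b]
    top = int(np.argmin(contour.points[:, 1]))
    if top in set(idx_a[1:-1].tolist()):
        dorsal_idx, ventral_idx = idx_a, idx_b
    elif top in set(idx_b[1:-1].tolist()):
        dorsal_idx, ventral_idx = idx_b, idx_a
    else:  # topmost point is a landmark: fall back to mean height
        if arc_a[:, 1].mean() <= arc_b[:, 1].mean():
            dorsal_idx, ventral_idx = idx_a, idx_b
        else:
            dorsal_idx, ventral_idx = idx_b, idx_a

    def as_arc(idx: np.ndarray) -> Contour:
        pix = contour.pixels[idx] if len(contour.pixels) == n else np.empty((0, 2), int)
        return Contour(points=contour.points[idx], closed=False, pixels=pix)

    return as_arc(dorsal_idx), as_arc(ventral_idx)


# ---------------------------------------------------------------------------
# resampling, midline, thickness
# ---------------------------------------------------------------------------


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_contour(arc: Contour | np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` points at equal arc-length spacing
    (linear interpolation between vertices; endpoints preserved)."""
    points = arc.points if isinstance(arc, Contour) else np.asarray(arc, float)
    if len(points) < 2:
        raise ValueError("resampling requires an arc with at least 2 points")
    if n < 2:
        raise ValueError("n must be at least 2")
    cum = _arc_lengths(points)
    if cum[-1] == 0:
        raise ValueError("zero-length arc cannot be resampled")
    target = np.linspace(0.0, cum[-1], n)
    out = np.column_stack(
        [np.interp(target, cum, points[:, 0]), np.interp(target, cum, points[:, 1])]
    )
    return out


def compute_midline(dorsal_pts: np.ndarray, ventral_pts: np.ndarray) -> np.ndarray:
    """Pointwise mean of paired dorsal/ventral sampling points.

    Both sequences must run in the same direction; a gross endpoint mismatch
    (start of one arc pairing with the end of the other) raises an error
    suggesting reversal.
    """
    dorsal_pts = np.asarray(dorsal_pts, float)
    ventral_pts = np.asarray(ventral_pts, float)
    if dorsal_pts.shape != ventral_pts.shape:
        raise ValueError("dorsal and ventral point sequences must match in shape")
    direct = np.hypot(*(dorsal_pts[0] - ventral_pts[0])) + np.hypot(
        *(dorsal_pts[-1] - ventral_pts[-1])
    )
    crossed = np.hypot(*(dorsal_pts[0] - ventral_pts[-1])) + np.hypot(
        *(dorsal_pts[-1] - ventral_pts[0])
    )
    if crossed < direct:
        raise ValueError(
            "dorsal and ventral arcs appear to run in opposite directions; "
            "reverse one of them"
        )
    return 0.5 * (dorsal_pts + ventral_pts)


def _smooth_polyline(points: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return points
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.vstack(
        [np.repeat(points[:1], half, axis=0), points, np.repeat(points[-1:], half, axis=0)]
    )
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in range(2)]
    )
    return out


def _line_polyline_intersections(
    origin: np.ndarray, direction: np.ndarray, polyline: np.ndarray
) -> np.ndarray:
    """Signed parameters t of all intersections of the infinite line
    ``origin + t * direction`` with the polyline's segments."""
    a = polyline[:-1]
    d = polyline[1:] - a
    rel = a - origin
    denom = direction[0] * d[:, 1] - direction[1] * d[:, 0]
    ok = np.abs(denom) > 1e-12
    t = np.where(ok, (rel[:, 0] * d[:, 1] - rel[:, 1] * d[:, 0]) / np.where(ok, denom, 1.0), np.nan)
    u = np.where(ok, (rel[:, 0] * direction[1] - rel[:, 1] * direction[0]) / np.where(ok, denom, 1.0), np.nan)
    hit = ok & (u >= -1e-9) & (u <= 1 + 1e-9)
    return t[hit]


def _nearest_on_polyline(point: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    a = polyline[:-1]
    d = polyline[1:] - a
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2[seg_len2 == 0] = 1.0
    u = np.clip(np.einsum("ij,ij->i", point - a, d) / seg_len2, 0.0, 1.0)
    proj = a + u[:, None] * d
    dist = np.hypot(*(proj - point).T)
    return proj[np.argmin(dist)]


def measure_thickness(
    midline: np.ndarray,
    dorsal: Contour | np.ndarray,
    ventral: Contour | np.ndarray,
    smooth_window: int = 5,
    degenerate_factor: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Distance between the two outlines orthogonal to the midline.

    For each midline point, the local tangent is estimated by centred finite
    differences on a moving-average-smoothed copy of the midline (one-sided
    at the two termini); the line through the point normal to that tangent
    is intersected with each outline polyline and the intersection nearest
    the midline point on each side is kept.

    An orthogonal cut is accepted only if the midline point actually lies
    between the two outlines (the two intersections sit on opposite sides)
    and the cut length is consistent with the nearest-outline distances on
    both sides (at most ``degenerate_factor`` times their sum); this rejects
    the degenerate near-parallel geometry that arises where the two arcs
    share an end cap.  Rejected segments — and segments whose normal misses
    an outline altogether — fall back to the distance between the two
    nearest outline points and are flagged.

    Returns ``(thickness, dorsal_hits, ventral_hits, fallback)``.
    """
    midline = np.asarray(midline, float)
    d_poly = dorsal.points if isinstance(dorsal, Contour) else np.asarray(dorsal, float)
    v_poly = ventral.points if isinstance(ventral, Contour) else np.asarray(ventral, float)
    smoothed = _smooth_polyline(midline, smooth_window)
    tangents = np.gradient(smoothed, axis=0)
    n = len(midline)
    thickness = np.zeros(n)
    d_hits = np.zeros((n, 2))
    v_hits = np.zeros((n, 2))
    fallback = np.zeros(n, dtype=bool)
    for i in range(n):
        point = midline[i]
        near_d = _nearest_on_polyline(point, d_poly)
        near_v = _nearest_on_polyline(point, v_poly)
        accepted = False
        t_vec = tangents[i]
        norm = np.hypot(*t_vec)
        if norm > 0:
            normal = np.array([-t_vec[1], t_vec[0]]) / norm
            td = _line_polyline_intersections(point, normal, d_poly)
            tv = _line_polyline_intersections(point, normal, v_poly)
            if len(td) and len(tv):
                t_d = td[np.argmin(np.abs(td))]
                t_v = tv[np.argmin(np.abs(tv))]
                cut = abs(t_d - t_v)
                side_sum = np.hypot(*(near_d - point)) + np.hypot(*(near_v - point))
                opposite = t_d * t_v <= 0
                if opposite and cut <= degenerate_factor * max(side_sum, 1e-12):
                    d_hits[i] = point + t_d * normal
                    v_hits[i] = point + t_v * normal
                    thickness[i] = cut
                    accepted = True
        if not accepted:
            fallback[i] = True
            d_hits[i] = near_d
            v_hits[i] = near_v
            thickness[i] = np.hypot(*(near_d - near_v))
    return thickness, d_hits, v_hits, fallback


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def profile_pipeline(
    mask: BinaryMask,
    n_points: int = 100,
    landmark_override: tuple | None = None,
    cleanup: bool = True,
    anterior_fraction: float = 0.5,
    smooth_window: int = 5,
    boundary_offset: float = 0.5,
    use_full_resolution: bool = True,
) -> MorphometryResult:
    """Run the full morphometry chain on one mask.

    cleanup -> area -> outline -> landmarks -> split -> resample(n) ->
    midline -> orthogonal thickness.  Deterministic for a fixed mask; the
    provenance dict records cleanup actions, landmark overrides and flagged
    segments.
    """
    provenance: dict = {"n_points": n_points, "boundary_offset": boundary_offset}
    mask = mask.canonical()
    if cleanup:
        mask, report = clean_mask(mask)
        provenance["cleanup"] = report
    area = compute_area(mask)
    contour = extract_outline(mask, boundary_offset=boundary_offset, validate=not cleanup)
    landmarks = detect_landmarks(
        contour, anterior_fraction=anterior_fraction, override=landmark_override
    )
    provenance["landmark_override"] = landmark_override is not None
    dorsal, ventral = split_contour(contour, landmarks)
    dorsal_pts = resample_contour(dorsal, n_points)
    ventral_pts = resample_contour(ventral, n_points)
    midline = compute_midline(dorsal_pts, ventral_pts)
    d_arc = dorsal if use_full_resolution else dorsal_pts
    v_arc = ventral if use_full_resolution else ventral_pts
    thickness, d_hits, v_hits, fallback = measure_thickness(
        midline, d_arc, v_arc, smooth_window=smooth_window
    )
    terminal = np.zeros(n_points, dtype=bool)
    terminal[0] = terminal[-1] = True
    profile = ThicknessProfile(
        thickness=thickness,
        midline=midline,
        dorsal_pts=dorsal_pts,
        ventral_pts=ventral_pts,
        fallback=fallback,
        terminal=terminal,
        dorsal_hits=d_hits,
        ventral_hits=v_hits,
    )
    provenance["fallback_segments"] = np.nonzero(fallback)[0].tolist()
    return MorphometryResult(
        area=area,
        profile=profile,
        landmarks=landmarks,
        contour=contour,
        provenance=provenance,
    )
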