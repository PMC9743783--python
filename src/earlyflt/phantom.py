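"""Digital phantom, probe and scan geometry.

Coordinates are right-handed with the scan surface at z = 0 and z positive
into the medium.  Scan rows run along the x axis (the cylinder axis of the
default fluorophore inclusion is parallel to a scan row); successive rows
are offset along y and traversed in alternating (zigzag) x order, matching
a translator-driven probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import FluorophoreProps, OpticalMedium


class GeometryError(ValueError):
    """Inconsistent phantom / scan geometry."""


@dataclass(frozen=True)
class VoxelGrid:
    """Uniform voxel grid.

    ``shape`` is the voxel count along (x, y, z); ``voxel_size`` the cubic
    edge length in mm; ``origin`` the corner of voxel (0, 0, 0).  Voxel
    ``(i, j, k)`` spans the half-open box
    ``[origin + idx*h, origin + (idx+1)*h)``.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shp = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(s < 1 for s in shp):
            raise GeometryError(f"all voxel counts must be >= 1, got {shp}")
        if not (self.voxel_size > 0.0):
            raise GeometryError("voxel_size must be > 0")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def extent(self) -> np.ndarray:
        """Physical size along each axis, mm."""
        return np.asarray(self.shape, float) * self.voxel_size

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin, float) + self.extent

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        o = self.origin[axis]
        h = self.voxel_size
        return o + (np.arange(n) + 0.5) * h

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates broadcast to the grid shape."""
        cx = self.axis_centers(0)[:, None, None]
        cy = self.axis_centers(1)[None, :, None]
        cz = self.axis_centers(2)[None, None, :]
        return cx, cy, cz

    def contains_point(self, p) -> bool:
        p = np.asarray(p, float)
        lo = np.asarray(self.origin, float)
        return bool(np.all(p >= lo - 1e-12) and np.all(p <= self.upper + 1e-12))


@dataclass
class Phantom:
    """Voxelized scattering object with a fluorophore inclusion.

    ``muaf_map`` is zero and ``tau_map`` NaN (undefined) outside
    ``fluoro_mask``.
    """

    grid: VoxelGrid
    medium: OpticalMedium
    fluor: FluorophoreProps
    fluoro_mask: np.ndarray
    muaf_map: np.ndarray
    tau_map: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fluoro_mask", "muaf_map", "tau_map"):
            arr = getattr(self, name)
            if tuple(arr.shape) != self.grid.shape:
                raise GeometryError(f"{name} shape {arr.shape} != grid shape")
        out = ~self.fluoro_mask
        if np.any(self.muaf_map[out] != 0.0):
            raise GeometryError("muaf_map must be zero outside fluoro_mask")


@dataclass(frozen=True)
class ProbeGeometry:
    """Fiber-probe optics: fiber diameter (mm), numerical aperture, the
    corresponding critical angle (deg, inside the medium) and the list of
    source–detector center distances (mm)."""

    fiber_diameter: float = 0.4
    numerical_aperture: float = 0.2
    critical_angle: float = 8.2
    sr_offsets: tuple[float, ...] = (3.3, 2.2, 1.1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sr_offsets",
                           tuple(float(r) for r in self.sr_offsets))
        if not (self.fiber_diameter >= 0.0):
            raise GeometryError("fiber_diameter must be >= 0")
        if not (0.0 < self.numerical_aperture < 1.0):
            raise GeometryError("numerical aperture must be in (0, 1)")
        if any(r <= 0.0 for r in self.sr_offsets):
            raise GeometryError("sr_offsets must be positive")
        if len(set(self.sr_offsets)) != len(self.sr_offsets):
            raise GeometryError("sr_offsets must be distinct")

    @property
    def critical_angle_rad(self) -> float:
        return float(np.deg2rad(self.critical_angle))


@dataclass(frozen=True)
class ScanPattern:
    """Raster scan of the probe over the surface plane z = 0.

    ``origin`` is the (x, y) of the first source position; columns advance
    along ``scan_axis`` ('x') by ``step`` and rows along ``row_axis`` ('y').
    """

    n_rows: int = 19
    n_cols: int = 19
    step: float = 0.5
    origin: tuple[float, float] = (-4.5, -4.5)
    scan_axis: str = "x"
    row_axis: str = "y"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("scan pattern must have >= 1 rows and cols")
        if not (self.step > 0.0):
            raise GeometryError("step must be > 0")
        if {self.scan_axis, self.row_axis} != {"x", "y"}:
            raise GeometryError("scan_axis and row_axis must be 'x' and 'y'")


@dataclass(frozen=True)
class SRLink:
    """One source–detector pair at a fixed probe position."""

    source_center: tuple[float, float, float]
    detector_center: tuple[float, float, float]
    sr_distance: float
    row_index: int
    col_index: int

    def __post_init__(self) -> None:
        s = np.asarray(self.source_center, float)
        d = np.asarray(self.detector_center, float)
        if abs(float(np.linalg.norm(d - s)) - self.sr_distance) > 1e-9:
            raise GeometryError("|source - detector| != sr_distance")

    @property
    def key(self) -> tuple[int, int, float]:
        return (self.row_index, self.col_index, round(self.sr_distance, 6))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and parameters for :func:`make_phantom`.

    The inclusion is one of the primitive shapes 'cylinder' (axis parallel
    to x, i.e. to a scan row), 'sphere' or 'box'.  ``center`` is the shape
    center in mm; for the cylinder, ``length`` is its extent along x
    (``inf`` means through the whole grid, emulating a filled hole drilled
    along the phantom).
    """

    grid_shape: tuple[int, int, int] = (200, 200, 150)
    voxel_size: float = 0.1
    grid_origin: tuple[float, float, float] = (-10.0, -10.0, 0.0)
    medium: OpticalMedium = field(
        default_factory=lambda: OpticalMedium(mua=0.01, mus=2.63, g=0.62, n=1.521))
    fluor: FluorophoreProps = field(
        default_factory=lambda: FluorophoreProps(muaf=0.01, gamma=0.2, tau=900.0))
    shape: str = "cylinder"
    center: tuple[float, float, float] = (0.0, 0.0, 4.2)
    radius: float = 1.0
    length: float = float("inf")
    box_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_shape, self.voxel_size, self.grid_origin)


def _inclusion_mask(cfg: PhantomConfig, grid: VoxelGrid) -> np.ndarray:
    cx, cy, cz = grid.center_mesh()
    x0, y0, z0 = cfg.center
    if cfg.shape == "cylinder":
        # axis along x
        mask = (cy - y0) ** 2 + (cz - z0) ** 2 <= cfg.radius ** 2
        if np.isfinite(cfg.length):
            mask = mask & (np.abs(cx - x0) <= cfg.length / 2.0)
        else:
            mask = mask & np.ones_like(cx, dtype=bool)
        return np.broadcast_to(mask, grid.shape).copy()
    if cfg.shape == "sphere":
        r2 = (cx - x0) ** 2 + (cy - y0) ** 2 + (cz - z0) ** 2
        return np.broadcast_to(r2 <= cfg.radius ** 2, grid.shape).copy()
    if cfg.shape == "box":
        sx, sy, sz = cfg.box_size
        m = ((np.abs(cx - x0) <= sx / 2.0) & (np.abs(cy - y0) <= sy / 2.0)
             & (np.abs(cz - z0) <= sz / 2.0))
        return np.broadcast_to(m, grid.shape).copy()
    raise GeometryError(f"unknown inclusion shape {cfg.shape!r}")


def make_phantom(cfg: PhantomConfig) -> Phantom:
    """Build the voxelized phantom from a configuration.

    Voxel membership is decided by the voxel *center* lying inside the
    inclusion shape.  Raises :class:`GeometryError` if the inclusion does
    not fit inside the grid (a zero-radius inclusion is allowed and yields
    an empty mask).
    """
    grid = cfg.grid
    lo = np.asarray(grid.origin, float)
    hi = grid.upper
    c = np.asarray(cfg.center, float)
    if cfg.shape == "cylinder":
        r = cfg.radius
        span_lo = np.array([lo[0], c[1] - r, c[2] - r])
        span_hi = np.array([hi[0], c[1] + r, c[2] + r])
    elif cfg.shape == "sphere":
        span_lo, span_hi = c - cfg.radius, c + cfg.radius
    else:
        half = np.asarray(cfg.box_size, float) / 2.0
        span_lo, span_hi = c - half, c + half
    if np.any(span_lo < lo - 1e-9) or np.any(span_hi > hi + 1e-9):
        raise GeometryError("inclusion does not fit inside the grid")

    mask = _inclusion_mask(cfg, grid)
    muaf_map = np.where(mask, cfg.fluor.muaf, 0.0)
    tau_map = np.where(mask, cfg.fluor.tau, np.nan)
    return Phantom(grid=grid, medium=cfg.medium, fluor=cfg.fluor,
                   fluoro_mask=mask, muaf_map=muaf_map, tau_map=tau_map)


def scan_links(pattern: ScanPattern, probe: ProbeGeometry) -> list[SRLink]:
    """Enumerate all source–detector links of a raster scan.

    Returns ``n_rows * n_cols * len(sr_offsets)`` links in zigzag order:
    row-major, with the column direction alternating between consecutive
    rows; within a probe position, one link per offset in probe order.
    The detector sits at ``source + (R, 0, 0)``.
    """
    links: list[SRLink] = []
    ox, oy = pattern.origin
    for r in range(pattern.n_rows):
        cols = range(pattern.n_cols)
        if r % 2 == 1:
            cols = reversed(cols)
        y = oy + r * pattern.step
        for cidx in cols:
            x = ox + cidx * pattern.step
            for R in probe.sr_offsets:
                links.append(SRLink(
                    source_center=(x, y, 0.0),
                    detector_center=(x + R, y, 0.0),
                    sr_distance=R, row_index=r, col_index=cidx))
    return links


def links_to_table(links: list[SRLink]) -> "np.ndarray":
    """Scan links as a structured record table (row, col, sr_distance,
    sx, sy, dx, dy), exportable as TSV."""
    dtype = [("row", int), ("col", int), ("sr_distance", float),
             ("sx", float), ("sy", float), ("dx", float), ("dy", float)]
    out = np.empty(len(links), dtype=dtype)
    for i, ln in enumerate(links):
        out[i] = (ln.row_index, ln.col_index, ln.sr_distance,
                  ln.source_center[0], ln.source_center[1],
                  ln.detector_center[0], ln.detector_center[1])
    return out
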