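"""Density maps on regular orthogonal grids, MRC/CCP4 I/O, and atom masks.

The grid is stored (z, y, x) internally; every public interface speaks Å
positions.  Origin handling follows the MRC-2014 convention: the Å position
of grid point (i, j, k) along (z, y, x) is ``origin + voxel * (k, j, i)``
with ``origin`` the (x, y, z) ORIGIN header.  Voxels are isotropic — the
analysis assumes a single spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["DensityMap", "GridMask", "read_map", "write_map", "mask_within",
           "sigma_contour_stats"]


class DensityMap:
    """A 3-D scalar field with isotropic voxel size and an Å origin."""

    def __init__(self, values: np.ndarray, voxel: float,
                 origin: tuple[float, float, float] = (0.0, 0.0, 0.0)):
        values = np.asarray(values, float)
        if values.ndim != 3 or min(values.shape) < 2:
            raise ValueError("map grid must be 3-D with each dimension >= 2")
        if not voxel > 0:
            raise ValueError("voxel size must be positive")
        self.values = values
        self.voxel = float(voxel)
        self.origin = np.asarray(origin, float)  # (x, y, z) Å

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (nz, ny, nx)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        """Standard deviation over all voxels (the σ of 'σ contour')."""
        return float(self.values.std())

    def copy(self, values: np.ndarray | None = None) -> "DensityMap":
        return DensityMap(self.values.copy() if values is None else values,
                          self.voxel, tuple(self.origin))

    def grid_coords(self, xyz: np.ndarray) -> np.ndarray:
        """Å positions (n, 3) (x, y, z) → fractional grid indices (n, 3) (z, y, x)."""
        xyz = np.atleast_2d(np.asarray(xyz, float))
        rel = (xyz - self.origin) / self.voxel
        return rel[:, ::-1]

    def position_of(self, zyx: np.ndarray) -> np.ndarray:
        """Grid indices (z, y, x) → Å positions (x, y, z)."""
        zyx = np.atleast_2d(np.asarray(zyx, float))
        return zyx[:, ::-1] * self.voxel + self.origin

    def congruent(self, other: "DensityMap") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.voxel, other.voxel, rtol=1e-6)
                and np.allclose(self.origin, other.origin, atol=1e-4))


@dataclass
class GridMask:
    """Boolean grid congruent with a map, from an atom selection at a radius."""

    values: np.ndarray
    radius: float
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, bool)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def __and__(self, other: "GridMask") -> "GridMask":
        return GridMask(self.values & other.values, self.radius,
                        f"({self.source}) & ({other.source})")


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4-2014 map (gzip transparent).

    Rejects non-isotropic voxels and non-float modes: the resolution and
    correlation machinery assumes one spacing and real values.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    m = gemmi.read_ccp4_map(str(path))
    grid = m.grid
    nx, ny, nz = grid.nu, grid.nv, grid.nw
    cell = grid.unit_cell
    vx, vy, vz = cell.a / nx, cell.b / ny, cell.c / nz
    if not (np.isclose(vx, vy, rtol=1e-4) and np.isclose(vx, vz, rtol=1e-4)):
        raise ValueError(f"non-isotropic voxel ({vx:.4f}, {vy:.4f}, {vz:.4f}) Å not supported")
    mode = int(m.header_i32(4))
    if mode != 2:
        raise ValueError(f"MRC mode {mode} not supported (need float32 mode 2)")
    arr = np.array(grid, copy=True)          # (nx, ny, nz) in gemmi order
    values = np.ascontiguousarray(arr.T)     # → (nz, ny, nx)
    ox = m.header_float(50)
    oy = m.header_float(51)
    oz = m.header_float(52)
    if ox == oy == oz == 0.0:
        # fall back to NXSTART-style origin
        ox = m.header_i32(5) * vx
        oy = m.header_i32(6) * vy
        oz = m.header_i32(7) * vz
    return DensityMap(values, vx, (ox, oy, oz))


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write MRC/CCP4-2014 with the ORIGIN header carrying the Å origin."""
    import gemmi

    nz, ny, nx = dmap.shape
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values.T, dtype=np.float32))
    grid.set_unit_cell(gemmi.UnitCell(nx * dmap.voxel, ny * dmap.voxel, nz * dmap.voxel,
                                      90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2)
    m.set_header_float(50, float(dmap.origin[0]))
    m.set_header_float(51, float(dmap.origin[1]))
    m.set_header_float(52, float(dmap.origin[2]))
    m.write_ccp4_map(str(path))


def mask_within(dmap: DensityMap, model, selection: np.ndarray | None = None,
                radius: float = 2.0, source: str = "") -> GridMask:
    """Voxels whose centers lie within ``radius`` Å of any selected atom.

    ``selection`` is a boolean mask over the model's atoms (default: all).
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    xyz = model.xyz if not isinstance(model, np.ndarray) else np.atleast_2d(model)
    if selection is not None:
        xyz = xyz[np.asarray(selection, bool)]
    if len(xyz) == 0:
        raise ValueError("empty atom selection")
    nz, ny, nx = dmap.shape
    out = np.zeros(dmap.shape, bool)
    rv = radius / dmap.voxel
    gpos = dmap.grid_coords(xyz)  # (n, 3) fractional (z, y, x)
    any_inside = False
    for gz, gy, gx in gpos:
        z0, z1 = int(np.floor(gz - rv)), int(np.ceil(gz + rv))
        y0, y1 = int(np.floor(gy - rv)), int(np.ceil(gy + rv))
        x0, x1 = int(np.floor(gx - rv)), int(np.ceil(gx + rv))
        z0c, y0c, x0c = max(z0, 0), max(y0, 0), max(x0, 0)
        z1c, y1c, x1c = min(z1, nz - 1), min(y1, ny - 1), min(x1, nx - 1)
        if z1c < z0c or y1c < y0c or x1c < x0c:
            continue
        any_inside = True
        zz = np.arange(z0c, z1c + 1)[:, None, None] - gz
        yy = np.arange(y0c, y1c + 1)[None, :, None] - gy
        xx = np.arange(x0c, x1c + 1)[None, None, :] - gx
        d2 = zz * zz + yy * yy + xx * xx
        out[z0c:z1c + 1, y0c:y1c + 1, x0c:x1c + 1] |= d2 <= rv * rv + 1e-12
    if not any_inside or not out.any():
        warnings.warn("atom selection lies outside the grid: empty mask")
    return GridMask(out, radius, source)


def sigma_contour_stats(dmap: DensityMap, mask: GridMask | None = None,
                        quantiles: tuple[float, ...] = (0.5, 0.9, 0.99)) -> dict:
    """Mean, σ and value-at-quantiles used to express thresholds in σ units."""
    v = dmap.values if mask is None else dmap.values[mask.values]
    return {
        "mean": float(np.mean(v)),
        "sigma": float(np.std(v)),
        "quantiles": {q: float(np.quantile(v, q)) for q in quantiles},
    }
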