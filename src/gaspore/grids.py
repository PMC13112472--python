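"""Scalar-field containers: 3D free-energy grids and 1D axial profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import RT, T_DEFAULT

__all__ = ["GridSpec", "FreeEnergyGrid", "Profile1D"]


@dataclass(frozen=True)
class GridSpec:
    """Regular orthorhombic analysis grid.

    ``origin`` is the corner of the grid region; cells of edge
    ``cell_spacing`` tile ``extent``; cell centers sit at
    origin + (i + 1/2)·spacing.  ``subsites_per_cell`` insertion points are
    placed uniformly inside each cell for free-energy mapping and
    ``n_orientations`` probe orientations are evaluated at each.
    """

    origin: tuple[float, float, float]
    extent: tuple[float, float, float]
    cell_spacing: float = 1.0
    subsites_per_cell: tuple[int, int, int] = (3, 3, 3)
    n_orientations: int = 10

    def __post_init__(self) -> None:
        if self.cell_spacing <= 0:
            raise ValueError("cell_spacing must be positive")
        if any(e < self.cell_spacing for e in self.extent):
            raise ValueError("extent must cover at least one cell per axis")
        if any(s < 1 for s in self.subsites_per_cell):
            raise ValueError("subsites_per_cell must be >= 1 per axis")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(e / self.cell_spacing)) for e in self.extent
        )  # type: ignore[return-value]

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.cell_spacing

    def cell_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of cell-center coordinates."""
        xs, ys, zs = (self.axis_centers(i) for i in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def subsite_offsets(self) -> np.ndarray:
        """(n_sub, 3) offsets of subsites from a cell center, spanning the cell."""
        offs = []
        for n in self.subsites_per_cell:
            # uniform lattice inside the cell, symmetric about the center
            offs.append((np.arange(n) + 0.5) / n * self.cell_spacing - self.cell_spacing / 2)
        ox, oy, oz = np.meshgrid(*offs, indexing="ij")
        return np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=-1)


@dataclass
class FreeEnergyGrid:
    """3D map of insertion free energies ΔG(x, y, z), kcal/mol.

    ``values`` has shape ``spec.shape``.  ``capped`` marks cells clamped at
    the energy cap (all Boltzmann factors vanished).  ``segments`` optionally
    holds per-segment maps (n_seg, nx, ny, nz) for block-error analysis;
    ``reference`` is a bulk solvation free energy already subtracted from
    ``values`` (None if the map is unreferenced).
    """

    spec: GridSpec
    values: np.ndarray
    capped: np.ndarray | None = None
    segments: np.ndarray | None = None
    reference: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.capped is None:
            self.capped = np.zeros(self.values.shape, dtype=bool)

    def shifted(self, offset: float) -> "FreeEnergyGrid":
        return FreeEnergyGrid(
            spec=self.spec,
            values=self.values + offset,
            capped=self.capped.copy(),
            segments=None if self.segments is None else self.segments + offset,
            reference=self.reference,
        )


@dataclass
class Profile1D:
    """A z-binned scalar profile with optional per-bin uncertainty and flags."""

    z: np.ndarray  # bin centers, Å
    values: np.ndarray  # kcal/mol (or counts, densities...)
    errors: np.ndarray | None = None
    flags: np.ndarray | None = None  # True where the value is a bound/capped
    label: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z.shape != self.values.shape:
            raise ValueError("z and values must have the same shape")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.z.shape, dtype=bool)

    @property
    def valid(self) -> np.ndarray:
        """Mask of bins holding actual estimates (finite and unflagged)."""
        return np.isfinite(self.values) & ~self.flags

    def barrier(self) -> tuple[float, float]:
        """(z, ΔG) of the highest valid point."""
        m = self.valid
        if not m.any():
            raise ValueError("profile has no valid bins")
        i = int(np.argmax(np.where(m, self.values, -np.inf)))
        return float(self.z[i]), float(self.values[i])

    def boltzmann_reference(self, z_range: tuple[float, float], temperature: float = T_DEFAULT) -> float:
        """−RT ln⟨e^(−G/RT)⟩ over valid bins inside z_range."""
        lo, hi = z_range
        m = self.valid & (self.z >= lo) & (self.z <= hi)
        if not m.any():
            raise ValueError(f"no valid bins in reference range {z_range}")
        rt = RT(temperature)
        g = self.values[m]
        gmin = g.min()
        return float(gmin - rt * np.log(np.mean(np.exp(-(g - gmin) / rt))))
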