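"""Lattice construction and probe-interaction field evaluation.

The descriptor matrix holds, per compound, a truncated Lennard-Jones
(steric) and a distance-dependent-dielectric Coulomb (electrostatic)
energy at every lattice point. Column order is normative: the full steric
block first, then the full electrostatic block, each in (i, j, k) raster
order with k fastest.

Conventions (all configurable where noted):

* steric:        E = sum eps_ij * [(R_ij/r)^12 - 2 (R_ij/r)^6], truncated
                 at +cutoff; R_ij = r_atom + r_probe, eps_ij = sqrt(eps_atom
                 * eps_probe) (arithmetic/geometric combination);
* electrostatic: E = sum K q_atom q_probe / r^2 (the dielectric eps = r
                 folds a second r into the denominator), K = 332.0, the sum
                 clipped to [-cutoff, +cutoff];
* at sterically excluded points (steric at the truncation value) the
  electrostatic entry is replaced by the column mean over non-excluded
  compounds (classic CoMFA convention; pass ``excluded_electrostatic="raw"``
  to keep raw values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .conformer_alignment import Molecule3D
from .params import COULOMB_CONSTANT, ENERGY_CUTOFF, PROBE_CHARGE, PROBE_RADIUS, PROBE_WELL_DEPTH

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldTable",
    "ScalingParams",
    "FieldEngineError",
    "build_grid",
    "steric_energy_at",
    "electrostatic_energy_at",
    "compute_field_table",
    "filter_columns",
    "scale_comfa_std",
]

STERIC = "steric"
ELECTROSTATIC = "electrostatic"


class FieldEngineError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice: point(i,j,k) = origin + (i,j,k) * spacing."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise FieldEngineError("grid spacing must be positive")
        if any(c < 1 for c in self.counts):
            raise FieldEngineError("grid counts must be >= 1 per axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, raster order (i, j, k) with k fastest."""
        nx, ny, nz = self.counts
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
        return np.asarray(self.origin) + idx * self.spacing

    def upper_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.counts) - 1) * self.spacing


@dataclass(frozen=True)
class ProbeSpec:
    """The fictitious sp3-carbon probe evaluated at each lattice point."""

    charge: float = PROBE_CHARGE
    radius: float = PROBE_RADIUS
    well_depth: float = PROBE_WELL_DEPTH

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.well_depth <= 0:
            raise FieldEngineError("probe radius and well depth must be positive")


@dataclass(frozen=True)
class ScalingParams:
    """Column centering + per-block variance equalization (invertible)."""

    column_means: np.ndarray  # over unmasked columns
    block_factors: dict  # field name -> multiplicative factor


@dataclass
class FieldTable:
    """Compounds x (lattice point x field type) energy matrix."""

    ids: list[str]
    data: np.ndarray  # (n, 2 * n_points), raw truncated energies, kcal/mol
    grid: GridSpec
    probe: ProbeSpec
    cutoff: float = ENERGY_CUTOFF
    mask: np.ndarray | None = None  # True = column kept
    scaled: np.ndarray | None = field(default=None, repr=False)
    scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1], dtype=bool)
        if self.data.shape[1] != 2 * self.grid.n_points:
            raise FieldEngineError("data width must be 2 * grid points")
        if len(self.mask) != self.data.shape[1]:
            raise FieldEngineError("mask length must equal column count")

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    @property
    def field_labels(self) -> np.ndarray:
        return np.array([STERIC] * self.n_points + [ELECTROSTATIC] * self.n_points)

    def block(self, name: str) -> np.ndarray:
        p = self.n_points
        if name == STERIC:
            return self.data[:, :p]
        if name == ELECTROSTATIC:
            return self.data[:, p:]
        raise FieldEngineError(f"unknown field {name!r}")

    def masked_data(self) -> np.ndarray:
        return self.data[:, self.mask]

    def masked_scaled(self) -> np.ndarray:
        if self.scaled is None:
            raise FieldEngineError("table is not scaled; call scale_comfa_std first")
        return self.scaled

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        """Recover raw (unmasked-column) values from scaled values."""
        if self.scaling is None:
            raise FieldEngineError("no scaling parameters stored")
        labels = self.field_labels[self.mask]
        factors = np.ones(scaled.shape[1])
        for name, factor in self.scaling.block_factors.items():
            factors[labels == name] = factor
        return scaled / factors + self.scaling.column_means


def build_grid(
    aligned: list[Molecule3D], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Axis-aligned lattice box: per-axis [min - margin, max + margin]."""
    if not aligned:
        raise FieldEngineError("empty aligned set")
    coords = np.vstack([m.coords for m in aligned])
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    counts = tuple(int(np.floor((hi[a] - lo[a]) / spacing + 1e-9)) + 1 for a in range(3))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing), counts=counts)


def _steric_matrix(
    points: np.ndarray, mol: Molecule3D, probe: ProbeSpec, cutoff: float
) -> np.ndarray:
    r = cdist(points, mol.coords)
    r = np.maximum(r, 1e-12)  # r = 0 collapses to the truncation value below
    rij = mol.vdw_radius + probe.radius
    eps = np.sqrt(mol.well_depth * probe.well_depth)
    s6 = (rij / r) ** 6
    energy = (eps * (s6 * s6 - 2.0 * s6)).sum(axis=1)
    return np.minimum(energy, cutoff)


def _electrostatic_matrix(
    points: np.ndarray, mol: Molecule3D, probe: ProbeSpec, cutoff: float
) -> np.ndarray:
    if mol.charges is None:
        raise FieldEngineError(f"no partial charges on {mol.compound_id!r}")
    r = cdist(points, mol.coords)
    r = np.maximum(r, 1e-12)
    energy = (COULOMB_CONSTANT * probe.charge * mol.charges / r**2).sum(axis=1)
    return np.clip(energy, -cutoff, cutoff)


def steric_energy_at(
    point, mol: Molecule3D, probe: ProbeSpec, cutoff: float = ENERGY_CUTOFF
) -> float:
    """Truncated Lennard-Jones probe energy at one point, kcal/mol."""
    if mol.vdw_radius is None or mol.well_depth is None:
        raise FieldEngineError(f"no force-field parameters on {mol.compound_id!r}")
    return float(_steric_matrix(np.atleast_2d(point).astype(float), mol, probe, cutoff)[0])


def electrostatic_energy_at(
    point, mol: Molecule3D, probe: ProbeSpec, cutoff: float = ENERGY_CUTOFF
) -> float:
    """Clipped distance-dependent-dielectric Coulomb energy, kcal/mol."""
    return float(_electrostatic_matrix(np.atleast_2d(point).astype(float), mol, probe, cutoff)[0])


def compute_field_table(
    aligned: list[Molecule3D],
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    cutoff: float = ENERGY_CUTOFF,
    excluded_electrostatic: str = "mean",
) -> FieldTable:
    """Evaluate both fields for every compound at every lattice point."""
    if probe is None:
        probe = ProbeSpec()
    if excluded_electrostatic not in ("mean", "raw"):
        raise FieldEngineError("excluded_electrostatic must be 'mean' or 'raw'")
    lo = np.asarray(grid.origin)
    hi = grid.upper_corner()
    for mol in aligned:
        if np.any(mol.coords < lo - 1e-9) or np.any(mol.coords > hi + 1e-9):
            raise FieldEngineError(f"atoms of {mol.compound_id!r} lie outside the grid hull")
    points = grid.points()
    steric = np.vstack([_steric_matrix(points, m, probe, cutoff) for m in aligned])
    elec = np.vstack([_electrostatic_matrix(points, m, probe, cutoff) for m in aligned])
    if excluded_electrostatic == "mean":
        excluded = steric >= cutoff - 1e-12
        n_kept = (~excluded).sum(axis=0)
        col_sum = np.where(excluded, 0.0, elec).sum(axis=0)
        col_mean = np.divide(col_sum, n_kept, out=np.zeros_like(col_sum), where=n_kept > 0)
        elec = np.where(excluded, col_mean[None, :], elec)
    return FieldTable(
        ids=[m.compound_id for m in aligned],
        data=np.hstack([steric, elec]),
        grid=grid,
        probe=probe,
        cutoff=cutoff,
    )


def filter_columns(table: FieldTable, min_sigma: float = 2.0) -> FieldTable:
    """Mask out columns whose standard deviation falls below ``min_sigma``."""
    sd = table.data.std(axis=0, ddof=1) if table.data.shape[0] > 1 else np.zeros(table.data.shape[1])
    mask = table.mask & (sd >= min_sigma)
    if not mask.any():
        raise FieldEngineError("no variance above threshold")
    return replace(table, mask=mask, scaled=None, scaling=None)


def scale_comfa_std(table: FieldTable) -> FieldTable:
    """CoMFA-standard block scaling: center, then equalize block variances.

    Each unmasked column is centered; all columns of one field block are
    multiplied by a common factor chosen so both blocks carry unit total
    variance. Parameters are stored for the inverse transform.
    """
    x = table.masked_data()
    means = x.mean(axis=0)
    centered = x - means
    labels = table.field_labels[table.mask]
    factors: dict[str, float] = {}
    scaled = centered.copy()
    for name in (STERIC, ELECTROSTATIC):
        cols = labels == name
        if not cols.any():
            continue
        block_var = float(centered[:, cols].var(axis=0, ddof=1).sum())
        if block_var <= 0:
            raise FieldEngineError(f"zero-variance {name} block")
        factors[name] = 1.0 / np.sqrt(block_var)
        scaled[:, cols] = centered[:, cols] * factors[name]
    return replace(table, scaled=scaled, scaling=ScalingParams(column_means=means, block_factors=factors))


def apply_scaling(table: FieldTable, raw_rows: np.ndarray) -> np.ndarray:
    """Project new raw full-width rows into the table's masked, scaled space."""
    if table.scaling is None:
        raise FieldEngineError("table has no stored scaling")
    if raw_rows.shape[1] != table.data.shape[1]:
        raise FieldEngineError(
            f"row width {raw_rows.shape[1]} does not match table width {table.data.shape[1]}"
        )
    x = raw_rows[:, table.mask] - table.scaling.column_means
    labels = table.field_labels[table.mask]
    for name, factor in table.scaling.block_factors.items():
        x[:, labels == name] *= factor
    return x
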