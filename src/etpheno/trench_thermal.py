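"""2-D steady-state heat conduction across the chip cross-section.

A thermal isolation trench (an air-filled cavity etched 350 um into the
silicon around the microheater) limits lateral heat spread through the
substrate.  This module reproduces that effect with a finite-difference
solve of the variable-coefficient steady conduction (Poisson) problem

    div( k(x, z) grad T ) + s = 0

on a uniform node-centred grid: interface conductances use the harmonic
mean of the two adjacent node conductivities, Dirichlet edges carry the
ambient temperature, all other boundary faces are adiabatic, and the
heater injects a fixed total power spread over its source nodes.  The
discrete system is solved directly (sparse LU), so the residual and the
energy balance close to machine precision.

Being 2-D with a configurable out-of-plane depth, the model is a
qualitative desk-scale analogue of a full 3-D finite-element study: it is
used for direction checks (power demand and temperature uniformity with
vs without the trench), not for quantitative chip temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .errors import ConvergenceError, IllPosedError, InputError, InvalidParametersError

__all__ = [
    "DEFAULT_CONDUCTIVITY",
    "CrossSectionGrid",
    "chip_cross_section",
    "solve_steady",
    "energy_balance",
    "uniformity_metric",
    "power_for_target",
    "heater_vicinity_mask",
]

#: Material conductivities, W m^-1 K^-1.  Oxide is the 1 um thermal SiO2
#: film (only resolved on grids fine enough to carry it); "tissue" is a
#: generic fixed-tissue value and is configurable per grid.
DEFAULT_CONDUCTIVITY: dict[str, float] = {
    "silicon": 150.0,
    "oxide": 1.3,
    "air": 0.026,
    "tissue": 0.4,
}


@dataclass(frozen=True)
class CrossSectionGrid:
    """One 2-D cross-section problem.

    ``material[i, j]`` names the material of node (row i, column j); rows
    index the vertical (z) direction with row 0 at the bottom.  The heater
    injects ``source_power`` watts split evenly over ``source_mask``;
    ``fixed_mask`` nodes are pinned to ``fixed_temperature``.
    """

    spacing: float
    material: np.ndarray
    source_mask: np.ndarray
    source_power: float
    fixed_mask: np.ndarray
    #: Dirichlet value(s): a scalar, or an array giving each fixed node its
    #: own temperature (e.g. hot and cold edges).
    fixed_temperature: float | np.ndarray = 25.0
    conductivity: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CONDUCTIVITY))
    out_of_plane_depth: float = 1.0e-3

    def __post_init__(self) -> None:
        mat = np.asarray(self.material)
        if mat.ndim != 2 or min(mat.shape) < 3:
            raise InvalidParametersError("grid must be 2-D and at least 3x3")
        if self.spacing <= 0.0 or self.out_of_plane_depth <= 0.0:
            raise InvalidParametersError("spacing and out-of-plane depth must be > 0")
        for name in np.unique(mat):
            kval = self.conductivity.get(str(name))
            if kval is None or kval <= 0.0:
                raise InvalidParametersError(f"material {name!r} needs a positive conductivity")
        if self.source_mask.shape != mat.shape or self.fixed_mask.shape != mat.shape:
            raise InvalidParametersError("masks must match the material grid shape")
        if not self.source_mask.any():
            raise InvalidParametersError("heater (source) region is empty")

    @property
    def k_field(self) -> np.ndarray:
        """Node conductivities as a float array."""
        k = np.empty(self.material.shape, dtype=float)
        for name, val in self.conductivity.items():
            k[self.material == name] = val
        return k

    @property
    def dirichlet_values(self) -> np.ndarray:
        """Fixed temperatures broadcast to the grid shape."""
        return np.broadcast_to(
            np.asarray(self.fixed_temperature, dtype=float), self.material.shape
        )


def _face_conductances(grid: CrossSectionGrid) -> tuple[np.ndarray, np.ndarray]:
    """(vertical, horizontal) face conductances, W/K, harmonic-mean interfaces.

    ``gv[i, j]`` couples nodes (i, j) and (i+1, j); ``gh[i, j]`` couples
    (i, j) and (i, j+1).  For a uniform grid the face area / distance ratio
    is just the out-of-plane depth.
    """
    k = grid.k_field
    d = grid.out_of_plane_depth
    gv = 2.0 * k[:-1, :] * k[1:, :] / (k[:-1, :] + k[1:, :]) * d
    gh = 2.0 * k[:, :-1] * k[:, 1:] / (k[:, :-1] + k[:, 1:]) * d
    return gv, gh


def solve_steady(grid: CrossSectionGrid, tolerance: float = 1e-8) -> np.ndarray:
    """Solve the steady conduction problem; returns the temperature field (deg C).

    Raises :class:`IllPosedError` without at least one fixed-temperature
    node and :class:`ConvergenceError` if the direct solve leaves a
    residual above ``tolerance`` (relative to the injected power scale).
    """
    fixed = np.asarray(grid.fixed_mask, dtype=bool)
    if not fixed.any():
        raise IllPosedError("no fixed-temperature node: steady problem is singular")
    nrow, ncol = grid.material.shape
    gv, gh = _face_conductances(grid)
    dirichlet = grid.dirichlet_values

    source = np.zeros((nrow, ncol))
    nsrc = int(grid.source_mask.sum())
    source[grid.source_mask] = grid.source_power / nsrc

    idx = -np.ones((nrow, ncol), dtype=int)
    free = ~fixed
    idx[free] = np.arange(int(free.sum()))

    rows_a: list[int] = []
    cols_a: list[int] = []
    vals_a: list[float] = []
    b = np.zeros(int(free.sum()))

    def couple(i1, j1, i2, j2, g):
        # add face between node1 (free) and node2
        a1 = idx[i1, j1]
        rows_a.append(a1); cols_a.append(a1); vals_a.append(g)
        if free[i2, j2]:
            rows_a.append(a1); cols_a.append(idx[i2, j2]); vals_a.append(-g)
        else:
            b[a1] += g * dirichlet[i2, j2]

    for i in range(nrow):
        for j in range(ncol):
            if not free[i, j]:
                continue
            b[idx[i, j]] += source[i, j]
            if i > 0:
                couple(i, j, i - 1, j, gv[i - 1, j])
            if i < nrow - 1:
                couple(i, j, i + 1, j, gv[i, j])
            if j > 0:
                couple(i, j, i, j - 1, gh[i, j - 1])
            if j < ncol - 1:
                couple(i, j, i, j + 1, gh[i, j])

    a_mat = sparse.csr_matrix(
        (vals_a, (rows_a, cols_a)), shape=(int(free.sum()), int(free.sum()))
    )
    sol = spsolve(a_mat.tocsc(), b)
    field_out = dirichlet.copy()
    field_out[free] = sol

    scale = max(abs(grid.source_power), float(np.abs(b).max()), 1.0)
    residual = float(np.abs(a_mat @ sol - b).max()) / scale
    if residual > tolerance:
        raise ConvergenceError(f"direct solve residual {residual:.3e} exceeds {tolerance:.1e}")
    return field_out


def energy_balance(grid: CrossSectionGrid, field: np.ndarray) -> tuple[float, float]:
    """(injected power, power absorbed at fixed-temperature nodes), watts.

    At steady state the two agree; the discrete conservation check used by
    the tests requires closure within 0.1%.
    """
    fixed = np.asarray(grid.fixed_mask, dtype=bool)
    gv, gh = _face_conductances(grid)
    nrow, ncol = grid.material.shape
    absorbed = 0.0
    for i in range(nrow):
        for j in range(ncol):
            if not fixed[i, j]:
                continue
            for i2, j2, g in (
                (i - 1, j, gv[i - 1, j] if i > 0 else 0.0),
                (i + 1, j, gv[i, j] if i < nrow - 1 else 0.0),
                (i, j - 1, gh[i, j - 1] if j > 0 else 0.0),
                (i, j + 1, gh[i, j] if j < ncol - 1 else 0.0),
            ):
                if g and not fixed[i2, j2]:
                    absorbed += g * (field[i2, j2] - field[i, j])
    return float(grid.source_power), float(absorbed)


def uniformity_metric(field: np.ndarray, region: np.ndarray) -> float:
    """Temperature SD (kelvin, population SD) over a region of nodes."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise InputError("uniformity region is empty")
    return float(np.std(field[region]))


def power_for_target(
    grid: CrossSectionGrid,
    heater_target: float,
    tolerance: float = 1e-4,
    power_cap: float = 10.0,
) -> float:
    """Source power (W) that brings the mean heater-node temperature to target.

    Bisection on the injected power; the discrete problem is linear in the
    source, so the bracket always tightens monotonically.  Raises
    :class:`ConvergenceError` if the target is unreachable under
    ``power_cap`` and :class:`InputError` if it lies below the zero-power
    temperature.
    """
    def heater_mean(power: float) -> float:
        fld = solve_steady(replace(grid, source_power=power))
        return float(fld[grid.source_mask].mean())

    base = heater_mean(0.0)
    if abs(heater_target - base) <= tolerance:
        return 0.0
    if heater_target < base:
        raise InputError(
            f"target {heater_target} below the zero-power heater temperature {base:.3f}"
        )
    lo, hi = 0.0, 1e-3
    while heater_mean(hi) < heater_target:
        hi *= 2.0
        if hi > power_cap:
            raise ConvergenceError(f"target {heater_target} unreachable under {power_cap} W")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        t_mid = heater_mean(mid)
        if abs(t_mid - heater_target) <= tolerance:
            return mid
        if t_mid < heater_target:
            lo = mid
        else:
            hi = mid
    raise ConvergenceError("bisection failed to reach the temperature tolerance")


def chip_cross_section(
    trench: bool = True,
    spacing: float = 25e-6,
    width: float = 4.0e-3,
    silicon_thickness: float = 500e-6,
    tissue_thickness: float = 1.0e-3,
    tissue_k: float = 0.4,
    heater_width: float = 0.5e-3,
    trench_width: float = 100e-6,
    trench_offset: float = 0.4e-3,
    trench_depth: float = 350e-6,
    source_power: float = 10e-3,
    boundary_temp: float = 25.0,
) -> CrossSectionGrid:
    """Default chip cross-section: silicon substrate, tissue on top, heater
    at the silicon surface centre, optional air trenches flanking it.

    The trench pair sits at +/- ``trench_offset`` from the heater centre,
    ``trench_depth`` (350 um by default) deep from the silicon surface.
    Bottom and side edges are pinned to ambient; the tissue top surface is
    adiabatic.
    """
    ncol = int(round(width / spacing))
    n_si = int(round(silicon_thickness / spacing))
    n_ti = int(round(tissue_thickness / spacing))
    nrow = n_si + n_ti
    material = np.full((nrow, ncol), "silicon", dtype="<U8")
    material[n_si:, :] = "tissue"

    x = (np.arange(ncol) + 0.5) * spacing - width / 2.0
    if trench:
        n_tr = int(round(trench_depth / spacing))
        for sign in (-1.0, 1.0):
            cols = np.abs(x - sign * trench_offset) <= trench_width / 2.0
            material[n_si - n_tr : n_si, cols] = "air"

    source_mask = np.zeros((nrow, ncol), dtype=bool)
    source_mask[n_si - 1, np.abs(x) <= heater_width / 2.0] = True

    fixed_mask = np.zeros((nrow, ncol), dtype=bool)
    fixed_mask[0, :] = True
    fixed_mask[:, 0] = True
    fixed_mask[:, -1] = True

    conductivity = dict(DEFAULT_CONDUCTIVITY)
    conductivity["tissue"] = tissue_k
    return CrossSectionGrid(
        spacing=spacing,
        material=material,
        source_mask=source_mask,
        source_power=source_power,
        fixed_mask=fixed_mask,
        fixed_temperature=boundary_temp,
        conductivity=conductivity,
    )


def heater_vicinity_mask(grid: CrossSectionGrid, half_width: float = 0.35e-3) -> np.ndarray:
    """Surface nodes within ``half_width`` of the heater centre (its own row).

    This is the isothermal island the trench is meant to protect; the
    uniformity metric is evaluated over it.
    """
    rows, cols = np.nonzero(grid.source_mask)
    row = rows[0]
    ncol = grid.material.shape[1]
    x = (np.arange(ncol) + 0.5) * grid.spacing
    center = x[cols].mean()
    mask = np.zeros_like(grid.source_mask)
    mask[row, np.abs(x - center) <= half_width] = True
    return mask
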