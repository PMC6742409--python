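"""Ensemble averaging of activation probability over cell placements.

A reconstruction never sits at one exact spot: the estimate for "a cell of
type T at planar distance R from the electrode" averages over rotations of
the arbor about the vertical axis through the soma and over vertical shifts
of the soma inside its layer.  The soma depth Z is sampled from
``[Z_min, Z_min + c * L_s]``, where ``L_s`` is the layer size, ``c`` a
type-specific coefficient (0.1, basket cells 0.4) and ``Z_min`` either the
top of the home layer (compact arbors) or the vertical reach of the arbor
above the soma (large cells — the arbor must not protrude above the pial
surface at Z = 0).

The averaging order is fixed: probability per reconstruction first (over its
own placements), then the mean across reconstructions of the same type.

Current sweeps exploit linearity: the activating function at current I > 0
is I times the function at +1 μA (and |I| times the -1 μA profile for
cathodal I), so each placement is evaluated once per polarity and rescaled
across the whole current grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .activation import (ActivationParams, FStencil, activating_function,
                         spike_probability, tangent_directions, trigger_region)
from .field import FieldSource
from .morphology import CellTypeSpec, Morphology


@dataclass(frozen=True)
class PlacementSampler:
    """Placement randomization settings for one estimate.

    ``planar_distance_R``: horizontal distance (μm) from the electrode
    center to the soma.  Rotation angles are uniform on [0, 2π); depths are
    uniform on the type's depth range.  ``n_rotations * n_depth_shifts``
    placements are evaluated per reconstruction.
    """

    planar_distance_R: float = 0.0
    n_rotations: int = 12
    n_depth_shifts: int = 10

    def __post_init__(self) -> None:
        if self.n_rotations < 1 or self.n_depth_shifts < 1:
            raise ValueError("sampler counts must be >= 1")


@dataclass
class ActivationCurve:
    """Mean activation probability vs distance R or current I for one type."""

    cell_type: str
    abscissa: np.ndarray              # R grid (μm) or signed I grid (μA)
    mean_probability: np.ndarray      # in [0, 1]
    dispersion: np.ndarray            # sd across reconstructions
    kind: str = "distance"            # "distance" | "current"


@dataclass(frozen=True)
class DensityGridSpec:
    """Axis-aligned volume around the soma origin, binned 100 x 100 x 50."""

    x_range: tuple[float, float] = (-500.0, 500.0)
    y_range: tuple[float, float] = (-500.0, 500.0)
    z_range: tuple[float, float] = (-1000.0, 400.0)
    shape: tuple[int, int, int] = (100, 100, 50)


@dataclass
class DensityGrid:
    """Normalized axonal occupancy density for a pool of reconstructions."""

    spec: DensityGridSpec
    density: np.ndarray               # (nx, ny, nz), values in [0, 1]
    n_cells: int

    @property
    def z_projection(self) -> np.ndarray:
        """Mean over the z axis (depth of the slice): an (nx, ny) map."""
        return self.density.mean(axis=2)

    def log_display(self, floor: float = 1e-3) -> np.ndarray:
        """Log-scaled z-projection for visualization (not for analysis)."""
        return np.log10(np.maximum(self.z_projection, floor))


# ---------------------------------------------------------------------------
# Depth rule
# ---------------------------------------------------------------------------

def z_min(morph: Morphology, spec: CellTypeSpec) -> float:
    """Minimal allowed soma depth for a placed reconstruction.

    ``layer_boundary``: the top of the home layer.  ``arbor_reach``: the
    vertical extent from the soma to the highest point of the arbor (axonal
    or dendritic), so that no part of the cell rises above the surface.
    """
    if spec.z_min_rule == "layer_boundary":
        return spec.layer_top
    soma_z = morph.soma_position[2]
    reach = float(soma_z - morph.xyz[:, 2].min())   # Z grows downward
    return max(reach, 0.0)


# ---------------------------------------------------------------------------
# Placement evaluation
# ---------------------------------------------------------------------------

def _placement_poses(stencil: FStencil, spec: CellTypeSpec,
                     sampler: PlacementSampler, rng: np.random.Generator):
    """Sampled (angle, soma position) placements with rejection.

    Placements whose arbor would protrude above the surface (any Z < 0) are
    rejected; with the arbor-reach depth rule this cannot happen, with the
    layer-boundary rule it can for atypically tall reconstructions.
    Rotation about the vertical axis preserves every z coordinate, so the
    protrusion test only needs the arbor's vertical reach above the soma.
    """
    zmin = z_min(stencil.morph, spec)
    zmax = zmin + spec.depth_coefficient_c * spec.layer_size
    angles = rng.uniform(0.0, 2.0 * np.pi, size=sampler.n_rotations)
    depths = rng.uniform(zmin, zmax, size=sampler.n_depth_shifts)
    poses = []
    for theta in angles:
        for z in depths:
            if z + stencil.min_dz < 0.0:
                continue
            poses.append((theta, (sampler.planar_distance_R, 0.0, z)))
    return poses


def placement_probability(morph: Morphology | FStencil, spec: CellTypeSpec,
                          source: FieldSource,
                          params: ActivationParams | None = None,
                          sampler: PlacementSampler | None = None,
                          seed: int | np.random.Generator = 0) -> float:
    """Mean spike probability of one reconstruction over placements.

    Myelinated types average the closed-form node-occurrence probability per
    placement; unmyelinated types average the binary any-trigger outcome.
    Zero current (or an all-rejected sampler) gives probability 0.  Passing
    a prebuilt :class:`FStencil` skips the per-call stencil construction.
    """
    params = params or ActivationParams()
    sampler = sampler or PlacementSampler()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if source.current_ua == 0.0:
        return 0.0
    stencil = (morph if isinstance(morph, FStencil)
               else FStencil(morph, params))
    thr = params.threshold(spec.myelinated)
    seg, ax = stencil.segment_lengths, stencil.axon_mask
    probs = []
    for theta, pos in _placement_poses(stencil, spec, sampler, rng):
        f = stencil.evaluate(source, theta, pos)
        L = float(seg[ax & (f >= thr)].sum())
        probs.append(spike_probability(L, params, spec.myelinated))
    return float(np.mean(probs)) if probs else 0.0


def _placement_unit_profiles(stencil: FStencil, spec: CellTypeSpec,
                             source: FieldSource,
                             params: ActivationParams,
                             sampler: PlacementSampler,
                             rng: np.random.Generator):
    """Per-placement (f at +1 μA, f at -1 μA) profiles."""
    out = []
    for theta, pos in _placement_poses(stencil, spec, sampler, rng):
        f_plus = stencil.evaluate(source.with_current(1.0), theta, pos)
        f_minus = stencil.evaluate(source.with_current(-1.0), theta, pos)
        out.append((f_plus, f_minus))
    return out


def _probability_at_current(profiles, current_ua: float,
                            params: ActivationParams,
                            myelinated: bool) -> float:
    """Mean probability over cached placements at a given signed current."""
    profiles, seg, ax = profiles
    if current_ua == 0.0 or not profiles:
        return 0.0
    thr = params.threshold(myelinated)
    probs = []
    for f_plus, f_minus in profiles:
        f = (abs(current_ua) * f_plus if current_ua > 0
             else abs(current_ua) * f_minus)
        L = float(seg[ax & (f >= thr)].sum())
        probs.append(spike_probability(L, params, myelinated))
    return float(np.mean(probs))


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

def probability_vs_distance(cells: Sequence[Morphology], spec: CellTypeSpec,
                            source: FieldSource,
                            params: ActivationParams | None = None,
                            r_grid: Sequence[float] = (0, 100, 200, 400),
                            sampler: PlacementSampler | None = None,
                            seed: int = 0) -> ActivationCurve:
    """Mean activation probability vs planar distance R at fixed current."""
    if len(cells) == 0:
        raise ValueError("cell pool must be non-empty")
    params = params or ActivationParams()
    base = sampler or PlacementSampler()
    r_grid = np.asarray(r_grid, dtype=float)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(len(cells))
    per_cell = np.zeros((len(cells), len(r_grid)))
    for ci, (morph, cs) in enumerate(zip(cells, cell_seeds)):
        stencil = FStencil(morph, params)
        for rj, r in enumerate(r_grid):
            s = PlacementSampler(planar_distance_R=float(r),
                                 n_rotations=base.n_rotations,
                                 n_depth_shifts=base.n_depth_shifts)
            rng = np.random.default_rng(cs)
            per_cell[ci, rj] = placement_probability(
                stencil, spec, source, params, s, rng)
    return ActivationCurve(spec.name, r_grid, per_cell.mean(axis=0),
                           per_cell.std(axis=0), kind="distance")


def probability_vs_current(cells: Sequence[Morphology], spec: CellTypeSpec,
                           source: FieldSource,
                           params: ActivationParams | None = None,
                           i_grid: Sequence[float] = (-150, -75, 75, 150),
                           sampler: PlacementSampler | None = None,
                           seed: int = 0) -> ActivationCurve:
    """Mean activation probability vs signed electrode current I.

    Evaluates each placement once per polarity at unit current and rescales
    across the grid (the activating function is linear in I).
    """
    if len(cells) == 0:
        raise ValueError("cell pool must be non-empty")
    params = params or ActivationParams()
    base = sampler or PlacementSampler()
    i_grid = np.asarray(i_grid, dtype=float)
    ss = np.random.SeedSequence(seed)
    per_cell = np.zeros((len(cells), len(i_grid)))
    for ci, (morph, cs) in enumerate(zip(cells, ss.spawn(len(cells)))):
        rng = np.random.default_rng(cs)
        stencil = FStencil(morph, params)
        profiles = (_placement_unit_profiles(stencil, spec, source, params,
                                             base, rng),
                    stencil.segment_lengths, stencil.axon_mask)
        for ij, cur in enumerate(i_grid):
            per_cell[ci, ij] = _probability_at_current(
                profiles, float(cur), params, spec.myelinated)
    return ActivationCurve(spec.name, i_grid, per_cell.mean(axis=0),
                           per_cell.std(axis=0), kind="current")


def classify_polarity(curve: ActivationCurve,
                      weak_band: float = 0.25) -> str:
    """Label a current curve anodal-preferring / weak-preference / cathodal.

    Compares areas under the anodal (I > 0) and cathodal (I < 0) branches;
    an asymmetry index within ``weak_band`` of zero is a weak preference.
    """
    if curve.kind != "current":
        raise ValueError("polarity classification needs a current curve")
    i = curve.abscissa
    p = curve.mean_probability
    a = np.trapezoid(p[i > 0], i[i > 0]) if np.sum(i > 0) > 1 else \
        float(np.sum(p[i > 0]))
    c = np.trapezoid(p[i < 0][::-1], -i[i < 0][::-1]) if np.sum(i < 0) > 1 \
        else float(np.sum(p[i < 0]))
    if a + c == 0:
        return "weak_preference"
    asym = (a - c) / (a + c)
    if asym > weak_band:
        return "anodal_preferring"
    if asym < -weak_band:
        return "cathodal_preferring"
    return "weak_preference"


# ---------------------------------------------------------------------------
# Axonal density maps
# ---------------------------------------------------------------------------

def axonal_density(cells: Sequence[Morphology],
                   spec: DensityGridSpec | None = None) -> DensityGrid:
    """Average binary axonal occupancy over soma-centred reconstructions.

    Each cell marks a grid voxel once if any axonal sample point falls in
    it; summing the binary per-cell grids and dividing by the number of
    cells yields a density in [0, 1], comparable across cell types whatever
    the pool size.
    """
    if len(cells) == 0:
        raise ValueError("cell pool must be non-empty")
    spec = spec or DensityGridSpec()
    nx, ny, nz = spec.shape
    edges = [np.linspace(*spec.x_range, nx + 1),
             np.linspace(*spec.y_range, ny + 1),
             np.linspace(*spec.z_range, nz + 1)]
    acc = np.zeros(spec.shape)
    for morph in cells:
        m = morph.translated(-morph.soma_position)
        pts = m.xyz[m.axon_mask]
        occ, _ = np.histogramdd(pts, bins=edges)
        acc += (occ > 0)
    return DensityGrid(spec, acc / len(cells), n_cells=len(cells))
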