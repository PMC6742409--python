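"""End-to-end orchestration: synthetic column pool -> curves -> network.

The column model's populations map onto morphological archetypes and
cell-type specs:

* excitatory cells (``exc23``, ``exc4``, ``exc5``) — vertically dominated
  arbors (pyramidal-like), myelinated;
* basket cells (``BC23``, ``BC4``, ``BC5``) — compact isotropic arbors,
  myelinated, confined near the soma;
* Martinotti cells (``MC23``, ``MC4``, ``MC5``) — an ascending trunk with a
  dense horizontal layer-I plexus, unmyelinated.

``population_current_curves`` runs the ensemble analysis for each population
at its layer depth and returns interpolable probability-vs-current curves,
which :func:`cortexstim.network.response_vs_current` consumes.
"""

from __future__ import annotations

import zlib
from typing import Callable, Mapping, Sequence

import numpy as np

from .activation import ActivationParams
from .ensemble import ActivationCurve, PlacementSampler, probability_vs_current
from .field import FieldSource
from .morphology import (ArborParams, CellTypeSpec, DEFAULT_CELL_TYPES,
                         Morphology, resample, synthesize_arbor)

#: population -> (archetype, cell-type spec name)
POPULATION_ARCHETYPES: dict[str, tuple[str, str]] = {
    "exc23": ("vertical_dominant", "PY23"),
    "exc4": ("vertical_dominant", "PY4"),
    "exc5": ("vertical_dominant", "PY5a"),
    "BC23": ("isotropic_local", "BC23"),
    "BC4": ("isotropic_local", "BC4"),
    "BC5": ("isotropic_local", "BC5"),
    "MC23": ("horizontal_layer1", "MC23"),
    "MC4": ("horizontal_layer1", "MC4"),
    "MC5": ("horizontal_layer1", "MC5"),
}


def archetype_params(archetype: str, spec: CellTypeSpec) -> ArborParams:
    """Default arbor geometry per archetype, adapted to the home layer.

    Ascending trunks stop short of the surface for shallow layers; the
    Martinotti trunk reaches just above the home-layer top so the
    horizontal plexus lands in layer I once the soma is placed at its
    minimal depth.  Basket arbors are compact (soma-confined).
    """
    if archetype == "horizontal_layer1":
        return ArborParams(trunk_height=spec.layer_top + 60.0,
                           branch_length=350.0)
    if archetype == "vertical_dominant":
        return ArborParams(trunk_height=min(400.0, spec.layer_top + 100.0))
    return ArborParams(n_branches=24, branch_length=250.0, local_radius=160.0)


def population_pool(population: str, n_cells: int = 3, seed: int = 0,
                    dx: float = 2.0) -> tuple[list[Morphology], CellTypeSpec]:
    """Synthetic reconstruction pool for one column population."""
    archetype, type_name = POPULATION_ARCHETYPES[population]
    spec = DEFAULT_CELL_TYPES[type_name]
    ap = archetype_params(archetype, spec)
    # stable per-population stream (str hash() is salted per process)
    pop_key = zlib.crc32(population.encode()) % (2**31)
    ss = np.random.SeedSequence([seed, pop_key])
    seeds = [int(s) for s in ss.generate_state(n_cells)]
    cells = [resample(synthesize_arbor(archetype, ap, seed=s % (2**31)),
                      dx) for s in seeds]
    return cells, spec


def population_current_curves(
        i_grid: Sequence[float],
        source: FieldSource | None = None,
        params: ActivationParams | None = None,
        sampler: PlacementSampler | None = None,
        n_cells: int = 3,
        seed: int = 0,
        populations: Sequence[str] | None = None,
) -> dict[str, ActivationCurve]:
    """Probability-vs-current curve per column population (R = 0 column)."""
    source = source or FieldSource()
    params = params or ActivationParams()
    sampler = sampler or PlacementSampler(planar_distance_R=0.0,
                                          n_rotations=8, n_depth_shifts=6)
    pops = populations or list(POPULATION_ARCHETYPES)
    out: dict[str, ActivationCurve] = {}
    for pop in pops:
        cells, spec = population_pool(pop, n_cells, seed)
        out[pop] = probability_vs_current(cells, spec, source, params,
                                          i_grid, sampler, seed=seed)
    return out


def curve_interpolators(curves: Mapping[str, ActivationCurve]
                        ) -> dict[str, Callable[[float], float]]:
    """Linear interpolators (clamped at the grid ends) for network seeding."""
    out = {}
    for name, c in curves.items():
        grid = np.asarray(c.abscissa, dtype=float)
        vals = np.asarray(c.mean_probability, dtype=float)
        order = np.argsort(grid)
        g, v = grid[order], vals[order]

        def fn(i, g=g, v=v):
            return float(np.interp(i, g, v))
        out[name] = fn
    return out
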