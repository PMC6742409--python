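"""Neuronal morphologies as compartmentalized 3D trees.

A morphology is an ordered collection of compartments (SWC-style sample
points): each has an integer id, a parent id (-1 for the root), a 3D position
in micrometres, a radius and a structure label.  The coordinate frame is
right-handed with Z increasing *downward* from the cortical surface at Z = 0,
matching the surface-electrode geometry used throughout the package; SWC
files are taken verbatim and placed in this frame by the caller (soma
translation / rotation helpers below).

Only the axonal sub-tree participates in the activating-function analysis;
dendrites are carried along for layer-placement rules (the highest point of
the ascending arbor, axonal or dendritic, constrains the minimal soma depth).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class Structure(enum.IntEnum):
    """SWC structure codes (de-facto standard)."""

    OTHER = 0
    SOMA = 1
    AXON = 2
    BASAL_DENDRITE = 3
    APICAL_DENDRITE = 4


#: SWC type codes outside 1..4 collapse to OTHER.
_KNOWN_CODES = {int(s) for s in (Structure.SOMA, Structure.AXON,
                                 Structure.BASAL_DENDRITE,
                                 Structure.APICAL_DENDRITE)}


class SWCParseError(ValueError):
    """Malformed SWC content; message names the offending line."""


class SWCStructureError(ValueError):
    """Topology violation: cycles, multiple roots, parent after child."""


@dataclass(frozen=True)
class CellTypeSpec:
    """Layer placement and excitability attributes of a cortical cell type.

    Parameters
    ----------
    name
        Type label, e.g. ``"PY23"`` (layer II/III pyramidal cell).
    layer_top, layer_bottom
        Depth of the type's home layer boundaries, micrometres below the
        cortical surface (``layer_top < layer_bottom``).
    myelinated
        Whether the axon is myelinated.  Myelinated axons spike when the
        triggered region contains a node of Ranvier; unmyelinated axons
        follow the binary any-trigger rule with a 20-fold higher threshold.
    depth_coefficient_c
        Fraction ``c`` of the layer size over which the soma depth is
        shuffled during placement sampling: Z in [Z_min, Z_min + c*L_s].
        0.1 for all types except basket cells (0.4).
    z_min_rule
        ``"layer_boundary"``: minimal soma depth is the layer top (compact
        arbors).  ``"arbor_reach"``: minimal depth is the vertical reach of
        the arbor above the soma, so the arbor never protrudes above the
        surface (large cells whose arbor can reach layer I).
    """

    name: str
    layer_top: float
    layer_bottom: float
    myelinated: bool
    depth_coefficient_c: float = 0.1
    z_min_rule: str = "arbor_reach"

    def __post_init__(self) -> None:
        if not self.layer_top < self.layer_bottom:
            raise ValueError("layer_top must be < layer_bottom")
        if not 0.0 < self.depth_coefficient_c <= 1.0:
            raise ValueError("depth_coefficient_c must be in (0, 1]")
        if self.z_min_rule not in ("layer_boundary", "arbor_reach"):
            raise ValueError(f"unknown z_min_rule {self.z_min_rule!r}")

    @property
    def layer_size(self) -> float:
        return self.layer_bottom - self.layer_top


# Default laminar geometry (rat sensory cortex scale, micrometres depth).
LAYER_BOUNDS = {
    "I": (0.0, 150.0),
    "II/III": (150.0, 600.0),
    "IV": (600.0, 900.0),
    "Va": (900.0, 1100.0),
    "Vb": (1100.0, 1400.0),
    "V": (900.0, 1400.0),
}


def _spec(name, layer, myel, c=0.1, rule="arbor_reach"):
    top, bot = LAYER_BOUNDS[layer]
    return CellTypeSpec(name, top, bot, myel, c, rule)


#: Built-in cell-type registry.  Pyramidal/spiny-stellate and basket axons are
#: treated as myelinated; Martinotti, bitufted and layer-I interneuron axons
#: as unmyelinated.  Basket cells are compact (layer-boundary depth rule,
#: c = 0.4); the rest can reach the surface (arbor-reach rule, c = 0.1).
DEFAULT_CELL_TYPES = {
    s.name: s
    for s in [
        _spec("L1", "I", False, rule="layer_boundary"),
        _spec("PY23", "II/III", True),
        _spec("PY4", "IV", True),
        _spec("SC4", "IV", True),
        _spec("PY5a", "Va", True),
        _spec("PY5b", "Vb", True),
        _spec("BC23", "II/III", True, c=0.4, rule="layer_boundary"),
        _spec("BC4", "IV", True, c=0.4, rule="layer_boundary"),
        _spec("BC5", "V", True, c=0.4, rule="layer_boundary"),
        _spec("MC23", "II/III", False),
        _spec("MC4", "IV", False),
        _spec("MC5", "V", False),
        _spec("bitufted", "II/III", False),
    ]
}


@dataclass
class Morphology:
    """A connected, acyclic tree of compartments (vectorized storage).

    Attributes
    ----------
    ids : (n,) int array — SWC sample ids (unique).
    parents : (n,) int array — parent id per compartment; -1 marks the root.
    xyz : (n, 3) float array — positions, micrometres.
    radius : (n,) float array — compartment radii, micrometres (> 0).
    structure : (n,) int array — :class:`Structure` codes.
    cell_type : optional :class:`CellTypeSpec`.
    """

    ids: np.ndarray
    parents: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    structure: np.ndarray
    cell_type: CellTypeSpec | None = None

    # id -> row index, built lazily
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.structure = np.asarray(self.structure, dtype=np.int64)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self._validate()

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, comp_id: int) -> int:
        return self._index[int(comp_id)]

    @property
    def parent_rows(self) -> np.ndarray:
        """Row index of each compartment's parent; -1 for the root."""
        out = np.full(len(self), -1, dtype=np.int64)
        for k, p in enumerate(self.parents):
            if p != -1:
                out[k] = self._index[int(p)]
        return out

    @property
    def soma_position(self) -> np.ndarray:
        soma = self.structure == Structure.SOMA
        if soma.any():
            return self.xyz[soma].mean(axis=0)
        return self.xyz[self.parents == -1][0]

    def mask(self, *structures: Structure) -> np.ndarray:
        m = np.zeros(len(self), dtype=bool)
        for s in structures:
            m |= self.structure == int(s)
        return m

    @property
    def axon_mask(self) -> np.ndarray:
        return self.mask(Structure.AXON)

    def segment_lengths(self) -> np.ndarray:
        """Length of the edge joining each compartment to its parent (root: 0)."""
        pr = self.parent_rows
        out = np.zeros(len(self))
        has = pr >= 0
        out[has] = np.linalg.norm(self.xyz[has] - self.xyz[pr[has]], axis=1)
        return out

    def total_length(self, structure: Structure = Structure.AXON) -> float:
        """Total cable length of edges whose child lies in ``structure``."""
        seg = self.segment_lengths()
        return float(seg[self.structure == int(structure)].sum())

    def children_rows(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(len(self))]
        pr = self.parent_rows
        for k, p in enumerate(pr):
            if p >= 0:
                out[p].append(k)
        return out

    # -- transforms --------------------------------------------------------

    def translated(self, offset: Sequence[float]) -> "Morphology":
        return replace(self, xyz=self.xyz + np.asarray(offset, dtype=float),
                       _index=None)

    def rotated_z(self, angle: float, about: Sequence[float] | None = None) -> "Morphology":
        """Rotate about the vertical (Z) axis through ``about`` (default soma)."""
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        pivot = self.soma_position if about is None else np.asarray(about, float)
        xyz = (self.xyz - pivot) @ rot.T + pivot
        return replace(self, xyz=xyz, _index=None)

    def placed(self, soma_at: Sequence[float], angle: float = 0.0) -> "Morphology":
        """Soma-centred copy rotated about the vertical axis, soma at ``soma_at``."""
        m = self.translated(-self.soma_position)
        if angle:
            m = m.rotated_z(angle, about=(0.0, 0.0, 0.0))
        return m.translated(soma_at)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.ids)
        if not (len(self.parents) == len(self.radius) == len(self.structure) == n
                and self.xyz.shape == (n, 3)):
            raise SWCStructureError("inconsistent array lengths")
        if len(self._index) != n:
            raise SWCStructureError("duplicate compartment ids")
        if np.any(self.radius <= 0):
            raise SWCStructureError("all radii must be positive")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise SWCStructureError(f"expected exactly one root, found {len(roots)}")
        seen: set[int] = set()
        for k in range(n):
            p = int(self.parents[k])
            if p != -1:
                if p not in self._index:
                    raise SWCStructureError(
                        f"compartment {int(self.ids[k])} references unknown parent {p}")
                if p not in seen:
                    raise SWCStructureError(
                        f"parent {p} listed after child {int(self.ids[k])}")
            seen.add(int(self.ids[k]))
        # parent-before-child ordering on a single root guarantees a connected
        # acyclic tree, so no separate traversal is needed.


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path, cell_type: CellTypeSpec | None = None) -> Morphology:
    """Read a 7-column SWC file.

    Columns: id, type, x, y, z, radius, parent.  Comment lines start with
    ``#``.  Unknown type codes map to :class:`Structure.OTHER`.

    Raises
    ------
    SWCParseError
        On a malformed row (names the line number).
    SWCStructureError
        On duplicate ids, multiple roots, unknown parents, or a parent
        listed after its child.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                i, t = int(parts[0]), int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                p = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}: line {lineno}: {exc}") from exc
            ids.append(i)
            types.append(t if t in _KNOWN_CODES else int(Structure.OTHER))
            xyz.append((x, y, z))
            radii.append(r)
            parents.append(p)
    if not ids:
        raise SWCParseError(f"{path}: no samples")
    return Morphology(np.array(ids), np.array(parents), np.array(xyz),
                      np.array(radii), np.array(types), cell_type=cell_type)


def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write a morphology as 7-column whitespace-delimited SWC."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(len(morph)):
            x, y, z = morph.xyz[k]
            fh.write(f"{int(morph.ids[k])} {int(morph.structure[k])} "
                     f"{x:.6f} {y:.6f} {z:.6f} {morph.radius[k]:.6f} "
                     f"{int(morph.parents[k])}\n")


# ---------------------------------------------------------------------------
# Resampling and fixtures
# ---------------------------------------------------------------------------

def resample(morph: Morphology, dx: float) -> Morphology:
    """Subdivide edges so that no segment exceeds ``dx`` micrometres.

    Each parent-child edge longer than ``dx`` is split into equal straight
    sub-segments, so branch points and terminals keep their coordinates and
    total cable length is conserved exactly.  Inserted compartments inherit
    the child's structure label and linearly interpolated radii.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    pr = morph.parent_rows
    new_ids: list[int] = []
    new_parents: list[int] = []
    new_xyz: list[np.ndarray] = []
    new_rad: list[float] = []
    new_struct: list[int] = []
    # original row -> new id (compartments keep their place, ids renumbered)
    assigned: dict[int, int] = {}
    next_id = 1

    for k in range(len(morph)):
        p = pr[k]
        if p < 0:
            assigned[k] = next_id
            new_ids.append(next_id)
            new_parents.append(-1)
            new_xyz.append(morph.xyz[k])
            new_rad.append(float(morph.radius[k]))
            new_struct.append(int(morph.structure[k]))
            next_id += 1
            continue
        a, b = morph.xyz[p], morph.xyz[k]
        ra, rb = float(morph.radius[p]), float(morph.radius[k])
        length = float(np.linalg.norm(b - a))
        nseg = max(1, int(np.ceil(length / dx - 1e-9)))
        parent_id = assigned[p]
        for j in range(1, nseg + 1):
            t = j / nseg
            new_ids.append(next_id)
            new_parents.append(parent_id)
            new_xyz.append(a + t * (b - a))
            new_rad.append(ra + t * (rb - ra))
            new_struct.append(int(morph.structure[k]))
            parent_id = next_id
            next_id += 1
        assigned[k] = parent_id
    return Morphology(np.array(new_ids), np.array(new_parents),
                      np.array(new_xyz), np.array(new_rad),
                      np.array(new_struct), cell_type=morph.cell_type)


def make_fiber(start: Sequence[float], direction: Sequence[float],
               length: float, dx: float, radius: float = 1.0,
               structure: Structure = Structure.AXON) -> Morphology:
    """Straight poly-line axon: ``round(length/dx) + 1`` equally spaced points.

    The default radius of 1 μm gives the 2 μm fiber diameter used for
    synthetic fixtures throughout the package.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if dx <= 0:
        raise ValueError("dx must be positive")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction vector must be non-zero")
    d = d / norm
    n = max(1, int(round(length / dx)))
    ts = np.linspace(0.0, length, n + 1)
    xyz = np.asarray(start, dtype=float)[None, :] + ts[:, None] * d[None, :]
    ids = np.arange(1, n + 2)
    parents = np.concatenate([[-1], ids[:-1]])
    return Morphology(ids, parents, xyz,
                      np.full(n + 1, float(radius)),
                      np.full(n + 1, int(structure)))


# ---------------------------------------------------------------------------
# Synthetic arborization archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArborParams:
    """Size/branching settings for :func:`synthesize_arbor`.

    All lengths in micrometres.  ``step`` is the polyline sampling step of
    generated branches; resample to the analysis spacing afterwards.
    """

    n_branches: int = 10
    branch_length: float = 300.0
    trunk_height: float = 400.0      # vertical_dominant / horizontal_layer1
    local_radius: float = 150.0      # isotropic_local confinement radius
    step: float = 5.0
    jitter: float = 0.1              # direction wobble per step (radians, sd)
    radius: float = 1.0


ARCHETYPES = ("vertical_dominant", "isotropic_local", "horizontal_layer1")


class _Builder:
    """Incremental compartment-list builder for synthetic arbors."""

    def __init__(self) -> None:
        self.ids: list[int] = []
        self.parents: list[int] = []
        self.xyz: list[np.ndarray] = []
        self.radius: list[float] = []
        self.struct: list[int] = []

    def add(self, pos, parent_id, radius, structure) -> int:
        cid = len(self.ids) + 1
        self.ids.append(cid)
        self.parents.append(parent_id)
        self.xyz.append(np.asarray(pos, dtype=float))
        self.radius.append(float(radius))
        self.struct.append(int(structure))
        return cid

    def run(self, start_pos, parent_id, direction, length, step, jitter, rng,
            radius, clamp=None) -> int:
        """Append a wobbly straight run; returns the id of its last point."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        pos = np.asarray(start_pos, dtype=float)
        n = max(1, int(round(length / step)))
        pid = parent_id
        for _ in range(n):
            if jitter > 0:
                d = d + jitter * rng.standard_normal(3)
                d = d / np.linalg.norm(d)
            nxt = pos + step * d
            if clamp is not None:
                nxt = clamp(pos, nxt)
                if nxt is None:
                    break
            pos = nxt
            pid = self.add(pos, pid, radius, Structure.AXON)
        return pid

    def build(self, cell_type=None) -> Morphology:
        return Morphology(np.array(self.ids), np.array(self.parents),
                          np.array(self.xyz), np.array(self.radius),
                          np.array(self.struct), cell_type=cell_type)


def synthesize_arbor(archetype: str, params: ArborParams | None = None,
                     seed: int = 0,
                     cell_type: CellTypeSpec | None = None) -> Morphology:
    """Generate a reproducible synthetic axonal arbor of a given archetype.

    Soma sits at the origin; Z increases downward, so "up" (toward the
    cortical surface) is the -Z direction.

    Archetypes
    ----------
    ``vertical_dominant``
        Pyramidal-like: a dominant ascending trunk plus vertical side
        branches; well over half the cable lies within 30° of vertical.
    ``isotropic_local``
        Basket-like: wobbly branches radiating in uniformly random
        directions, confined within ``params.local_radius`` of the soma.
    ``horizontal_layer1``
        Martinotti-like: an ascending trunk to ``trunk_height`` above the
        soma, then long horizontal collaterals fanning out at that height
        (placing the soma so that this height falls in layer I reproduces
        the dense layer-I horizontal plexus).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}")
    p = params or ArborParams()
    if p.n_branches < 1 or p.branch_length <= 0 or p.step <= 0:
        raise ValueError("n_branches, branch_length and step must be positive")
    rng = np.random.default_rng(seed)
    b = _Builder()
    soma = b.add((0.0, 0.0, 0.0), -1, max(p.radius, 5.0), Structure.SOMA)
    up = np.array([0.0, 0.0, -1.0])

    if archetype == "vertical_dominant":
        # ascending trunk
        trunk_end = b.run((0, 0, 0), soma, up, p.trunk_height, p.step,
                          p.jitter * 0.3, rng, p.radius)
        trunk_ids = list(range(2, len(b.ids) + 1))
        # vertical side branches from random trunk points (short horizontal
        # offset then a vertical run), plus a descending branch
        for _ in range(p.n_branches):
            src = int(rng.choice(trunk_ids))
            ang = rng.uniform(0, 2 * np.pi)
            horiz = np.array([np.cos(ang), np.sin(ang), 0.0])
            elbow = b.run(b.xyz[src - 1], src, horiz,
                          0.12 * p.branch_length, p.step, p.jitter, rng, p.radius)
            # mostly ascending, occasionally descending, always vertical
            sign = 1.0 if rng.random() < 0.8 else -1.0
            b.run(b.xyz[elbow - 1], elbow, sign * up,
                  0.88 * p.branch_length, p.step, p.jitter * 0.3, rng, p.radius)
    elif archetype == "isotropic_local":
        lim = p.local_radius

        def clamp(pos, nxt):
            # stop a run at the confinement sphere
            return nxt if np.linalg.norm(nxt) <= lim else None

        for _ in range(p.n_branches):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            b.run((0, 0, 0), soma, v, min(p.branch_length, 0.95 * lim),
                  p.step, p.jitter, rng, p.radius, clamp=clamp)
    else:  # horizontal_layer1
        trunk_end = b.run((0, 0, 0), soma, up, p.trunk_height, p.step,
                          p.jitter * 0.2, rng, p.radius)
        top = b.xyz[trunk_end - 1]
        for _ in range(p.n_branches):
            ang = rng.uniform(0, 2 * np.pi)
            horiz = np.array([np.cos(ang), np.sin(ang), 0.0])

            def clamp_z(pos, nxt, z0=top[2]):
                out = nxt.copy()
                out[2] = z0 + 0.3 * (nxt[2] - z0)  # keep collaterals planar
                return out

            b.run(top, trunk_end, horiz, p.branch_length, p.step,
                  p.jitter, rng, p.radius, clamp=clamp_z)
        # a couple of short local branches near the soma
        for _ in range(2):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            b.run((0, 0, 0), soma, v, 0.2 * p.branch_length, p.step,
                  p.jitter, rng, p.radius)

    return b.build(cell_type=cell_type)


# ---------------------------------------------------------------------------
# Orientation / extent statistics (used by archetype tests and docs)
# ---------------------------------------------------------------------------

def cable_orientation_fractions(morph: Morphology, cone_deg: float = 30.0
                                ) -> tuple[float, float]:
    """(vertical_fraction, horizontal_fraction) of axonal cable length.

    A segment counts as vertical when its direction lies within ``cone_deg``
    of the Z axis, horizontal when within ``cone_deg`` of the XY plane.
    """
    pr = morph.parent_rows
    ax = morph.axon_mask & (pr >= 0)
    vec = morph.xyz[ax] - morph.xyz[pr[ax]]
    seg = np.linalg.norm(vec, axis=1)
    ok = seg > 0
    vec, seg = vec[ok], seg[ok]
    cosz = np.abs(vec[:, 2]) / seg
    ang_from_z = np.degrees(np.arccos(np.clip(cosz, -1, 1)))
    vert = seg[ang_from_z <= cone_deg].sum()
    horiz = seg[ang_from_z >= 90.0 - cone_deg].sum()
    total = seg.sum()
    return float(vert / total), float(horiz / total)


def cable_within_radius(morph: Morphology, radius: float) -> float:
    """Fraction of axonal cable within ``radius`` μm of the soma."""
    pr = morph.parent_rows
    ax = morph.axon_mask & (pr >= 0)
    seg = np.linalg.norm(morph.xyz[ax] - morph.xyz[pr[ax]], axis=1)
    mid = 0.5 * (morph.xyz[ax] + morph.xyz[pr[ax]])
    dist = np.linalg.norm(mid - morph.soma_position, axis=1)
    total = seg.sum()
    return float(seg[dist <= radius].sum() / total) if total > 0 else 0.0


def cable_above_height(morph: Morphology, height: float,
                       horizontal_only: bool = False,
                       cone_deg: float = 30.0) -> float:
    """Fraction of axonal cable at least ``height`` μm above the soma.

    With ``horizontal_only`` the numerator keeps only segments oriented
    within ``cone_deg`` of the horizontal plane.
    """
    pr = morph.parent_rows
    ax = morph.axon_mask & (pr >= 0)
    vec = morph.xyz[ax] - morph.xyz[pr[ax]]
    seg = np.linalg.norm(vec, axis=1)
    ok = seg > 0
    vec, seg = vec[ok], seg[ok]
    mid = 0.5 * (morph.xyz[ax] + morph.xyz[pr[ax]])[ok]
    soma_z = morph.soma_position[2]
    above = (soma_z - mid[:, 2]) >= height   # Z grows downward
    if horizontal_only:
        cosz = np.abs(vec[:, 2]) / seg
        ang_from_z = np.degrees(np.arccos(np.clip(cosz, -1, 1)))
        above &= ang_from_z >= 90.0 - cone_deg
    total = seg.sum()
    return float(seg[above].sum() / total) if total > 0 else 0.0
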