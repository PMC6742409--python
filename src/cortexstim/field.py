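"""Extracellular potential of surface-plate and point current sources.

The tissue is an infinite homogeneous ohmic volume conductor with
resistivity ``rho_e``.  A square surface electrode of edge ``A`` carrying net
current ``I`` (uniform current density) produces

    Phi(X, Y, Z) = rho_e * I / (4 pi A^2) *
                   integral over the plate of dx dy / sqrt((X-x)^2 + (Y-y)^2 + Z^2)

and a point source produces ``Phi = rho_e * I / (4 pi r)``.  Positive current
is anodal.  The double integral has an exact antiderivative

    F(u, v) = u*log(v + r) + v*log(u + r) - |Z|*atan(u*v / (|Z|*r)),
    r = sqrt(u^2 + v^2 + Z^2),

evaluated at the four plate corners, which this module uses instead of
numerical quadrature; the quadrature route survives in the test suite as an
independent oracle.

Units: distances in μm, current in μA, resistivity in Ω·cm, potential in mV.
(Ω·cm → Ω·μm is 1e4 and Ω·μm·μA/μm = μV, so the net conversion is a factor
of 10.)  An optional ``medium_factor`` rescales the field, e.g. 2 for a
hemi-infinite medium with an insulating boundary above the plate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .morphology import Morphology

#: (Ω·cm → Ω·μm) * (μV → mV)
_UNIT_FACTOR = 1.0e4 * 1.0e-3


class SingularFieldError(ValueError):
    """Potential requested on the singular surface of a source."""


@dataclass(frozen=True)
class FieldSource:
    """A current source: square surface plate or ideal point.

    Parameters
    ----------
    kind : ``"square_plate"`` or ``"point"``.
    center : 3-vector, μm.  Plates lie in the Z = ``center[2]`` plane
        (normally the cortical surface Z = 0).
    edge_a : plate edge length, μm (default 150).
    current_ua : net current, μA; positive = anodal, negative = cathodal.
    rho_e_ohm_cm : extracellular resistivity, Ω·cm.
    medium_factor : overall field scale (1 = infinite medium, 2 = hemi-space).
    """

    kind: str = "square_plate"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    edge_a: float = 150.0
    current_ua: float = 100.0
    rho_e_ohm_cm: float = 300.0
    medium_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("square_plate", "point"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.kind == "square_plate" and self.edge_a <= 0:
            raise ValueError("edge_a must be positive for a plate source")
        if self.rho_e_ohm_cm <= 0:
            raise ValueError("rho_e_ohm_cm must be positive")

    def with_current(self, current_ua: float) -> "FieldSource":
        return replace(self, current_ua=float(current_ua))


def _plate_integral(u1, u2, v1, v2, z):
    """Exact value of the plate double integral of 1/r (lengths in μm)."""
    zabs = np.abs(z)

    def F(u, v):
        r = np.sqrt(u * u + v * v + z * z)
        # log arguments vanish only on measure-zero edge rays; clip keeps
        # those from producing -inf before the singularity check catches them
        t1 = u * np.log(np.maximum(v + r, 1e-300))
        t2 = v * np.log(np.maximum(u + r, 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            t3 = np.where(zabs > 0,
                          zabs * np.arctan(u * v / np.maximum(zabs * r, 1e-300)),
                          0.0)
        return t1 + t2 - t3

    return F(u2, v2) - F(u2, v1) - F(u1, v2) + F(u1, v1)


def potential(source: FieldSource, points: np.ndarray) -> np.ndarray:
    """Extracellular potential, mV, at an ``(n, 3)`` array of points (μm).

    Raises :class:`SingularFieldError` for points on the plate surface
    (``Z = center_z`` inside or on the plate rectangle) or at a point
    source's own location.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 3:
        raise ValueError("points must have shape (n, 3)")
    rel = pts - np.asarray(source.center, dtype=float)
    amp = _UNIT_FACTOR * source.medium_factor * source.rho_e_ohm_cm \
        * source.current_ua / (4.0 * np.pi)

    if source.kind == "point":
        r = np.linalg.norm(rel, axis=1)
        if np.any(r < 1e-9):
            raise SingularFieldError("potential requested at the point source")
        return amp / r

    half = source.edge_a / 2.0
    on_plane = np.abs(rel[:, 2]) < 1e-9
    inside = (np.abs(rel[:, 0]) <= half + 1e-9) & (np.abs(rel[:, 1]) <= half + 1e-9)
    if np.any(on_plane & inside):
        raise SingularFieldError(
            "potential requested on the electrode plate surface")
    integral = _plate_integral(-half - rel[:, 0], half - rel[:, 0],
                               -half - rel[:, 1], half - rel[:, 1],
                               rel[:, 2])
    return amp / source.edge_a**2 * integral


def potential_profile_along_fiber(source: FieldSource,
                                  morph: Morphology) -> np.ndarray:
    """Potential (mV) at every compartment position of a morphology."""
    return potential(source, morph.xyz)


def point_source_potential(rho_e_ohm_cm: float, current_ua: float,
                           r_um: np.ndarray | float,
                           medium_factor: float = 1.0) -> np.ndarray | float:
    """Closed-form monopole potential ``rho_e I / (4 pi r)`` in mV."""
    r = np.asarray(r_um, dtype=float)
    return _UNIT_FACTOR * medium_factor * rho_e_ohm_cm * current_ua / (4.0 * np.pi * r)
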