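"""Magnetic fields from neural currents (Biot-Savart, quasistatic).

Far field: the magnetostatic dipole form B = mu0/(4 pi) p x R / R^3, valid
for any spherically symmetric head model because the magnetic permeability
is that of free space throughout.  Near field: the sum over intracellular
axial current elements B = mu0/(4 pi) sum_m I_m d_m x (r - r_m)/|r - r_m|^3
(extracellular volume-current contributions are neglected).  Output in
tesla; internally the field is assembled as H and multiplied by mu = mu0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axial import AxialCurrentSet
from .dipole import DipoleMoment
from .headmodels import SurfaceGrid, decompose_field

__all__ = ["FieldSample", "dipole_field", "field_from_axial",
           "surface_field_components"]

MU0 = 4.0 * np.pi * 1e-7  # T*m/A


@dataclass
class FieldSample:
    """Magnetic field vectors (T) per position and time step."""

    positions: np.ndarray  # (N, 3)
    B: np.ndarray          # (N, 3, n_t) tesla


def dipole_field(p: DipoleMoment, points) -> FieldSample:
    """B = mu0/(4 pi) p x R / R^3 from a current dipole.

    ``points`` in mm relative to the same origin as ``p.location`` (mm);
    p in nAm.  On the dipole axis p x R vanishes and so does B.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    loc = p.location if p.location is not None else np.zeros(3)
    R = (points - loc) * 1e-3                       # mm -> m
    R3 = np.linalg.norm(R, axis=1) ** 3
    if np.any(R3 == 0):
        raise ValueError("field point coincides with the dipole location")
    # H = (p x R)/(4 pi R^3); B = mu0 H
    pxR = np.cross(p.p.T[None, :, :] * 1e-9, R[:, None, :])  # (N, n_t, 3)
    B = MU0 / (4.0 * np.pi) * pxR / R3[:, None, None]
    return FieldSample(points, np.swapaxes(B, 1, 2))


def field_from_axial(ax: AxialCurrentSet, points) -> FieldSample:
    """Near-field Biot-Savart sum over axial current elements.

    ``points`` in um in the cell's coordinate frame; currents in nA, line
    elements in um.  Volume currents in the extracellular medium are
    neglected.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    R = (points[:, None, :] - ax.r_mid[None, :, :]) * 1e-6  # um -> m, (N, m, 3)
    R3 = np.linalg.norm(R, axis=-1) ** 3
    if np.any(R3 == 0):
        raise ValueError("field point coincides with an axial current midpoint")
    dxR = np.cross(ax.d_vectors[None, :, :] * 1e-6, R)      # (N, m, 3)
    geom = MU0 / (4.0 * np.pi) * dxR / R3[..., None]        # (N, m, 3)
    # sum_m I_m(t) * geom_m ; currents nA -> A
    B = np.einsum("nmk,mt->nkt", geom, ax.i_axial * 1e-9)
    return FieldSample(points, B)


def surface_field_components(p: DipoleMoment, grid: SurfaceGrid):
    """Dipole field at the grid points decomposed into (r, theta, phi).

    Grid points in mm on the measurement sphere; returns three (N, n_t)
    arrays.  For a radial dipole only the azimuthal component survives; a
    tangential dipole produces the characteristic butterfly pattern with a
    radial component antisymmetric about the apex.
    """
    sample = dipole_field(p, grid.points)
    return decompose_field(sample.B, grid)
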