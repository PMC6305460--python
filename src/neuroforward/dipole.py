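"""Current dipole moments from transmembrane and from axial currents.

p(t) = sum_n r_n I_n(t) over segment midpoints (computed as a matrix
product), or equivalently p(t) = sum_m I_a,m(t) d_m over axial-current line
elements -- the two agree exactly when virtual currents at mid-section
attachments are included.  Units: positions um, currents nA, moments nAm
(1 um * 1 nA = 1e-6 nAm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .axial import AxialCurrentSet

__all__ = ["DipoleMoment", "dipole_from_transmembrane", "dipoles_from_axial",
           "population_dipole"]

_UM_NA_TO_NAM = 1e-6


@dataclass
class DipoleMoment:
    """3 x n_t current dipole moment time series (nAm) with source location."""

    p: np.ndarray                 # (3, n_t) nAm
    location: np.ndarray = None   # (3,) um (or mm inside head models)
    location_rule: str = ""

    def __post_init__(self):
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        if self.p.shape[0] != 3:
            raise ValueError("dipole moment must have 3 spatial rows")
        if self.location is not None:
            self.location = np.asarray(self.location, dtype=float)

    @property
    def n_t(self) -> int:
        return self.p.shape[1]


def dipole_from_transmembrane(i_m, midpoints, location=None,
                              monopole_warn=1e-6) -> DipoleMoment:
    """Dipole moment from transmembrane currents: p(t) = sum_n r_n I_n(t).

    ``i_m`` is (n_seg, n_t) in nA and ``midpoints`` (n_seg, 3) in um.  A
    warning is issued if currents fail to sum to ~zero (monopole residue),
    in which case p depends on the coordinate origin.
    """
    i_m = np.atleast_2d(np.asarray(i_m, dtype=float))
    midpoints = np.atleast_2d(np.asarray(midpoints, dtype=float))
    if i_m.shape[0] != midpoints.shape[0]:
        raise ValueError("i_m rows must match number of midpoints")
    residue = np.max(np.abs(i_m.sum(axis=0)))
    if residue > monopole_warn:
        warnings.warn(
            f"transmembrane currents sum to {residue:.3g} nA (monopole "
            "residue); the dipole moment is origin-dependent")
    p = (midpoints.T @ i_m) * _UM_NA_TO_NAM
    return DipoleMoment(p, location=location)


def dipoles_from_axial(ax: AxialCurrentSet):
    """Per-element dipoles p_m(t) = I_a,m(t) d_m and their sum.

    Returns (per_element, total): per_element is (m_a, 3, n_t) in nAm.
    """
    per = ax.i_axial[:, None, :] * ax.d_vectors[:, :, None] * _UM_NA_TO_NAM
    total = per.sum(axis=0)
    return per, DipoleMoment(total)


def population_dipole(cell_dipoles, location=None,
                      location_rule="population placement") -> DipoleMoment:
    """Elementwise sum of per-cell dipole moments on a common time axis."""
    cell_dipoles = list(cell_dipoles)
    if not cell_dipoles:
        raise ValueError("no dipoles to sum")
    n_t = cell_dipoles[0].n_t
    for d in cell_dipoles:
        if d.n_t != n_t:
            raise ValueError("dipole time axes do not match")
    p = np.sum([d.p for d in cell_dipoles], axis=0)
    return DipoleMoment(p, location=location, location_rule=location_rule)
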