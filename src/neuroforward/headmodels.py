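"""EEG/ECoG forward models from current dipoles.

Contains the infinite homogeneous-medium dipole potential, the corrected
four-concentric-sphere head model (brain / CSF / skull / scalp with
individual conductivities, air outside), the multi-dipole variant used for
ECoG (one dipole per axial current, summed by linearity), and spherical
surface utilities (measurement grids with local r/theta/phi unit vectors,
dipole rotation).

The four-sphere solution is a Legendre series.  For each harmonic order n
the free dipole field inside the brain is corrected by shell terms
A_s (r/r_s)^n + B_s (r_(s-1)/r)^(n+1); the coefficients follow from
potential and radial-current continuity at the three interfaces and zero
radial current at the scalp-air boundary, a 7x7 linear solve per n (done
batched).  Radial and tangential dipole components share the same radial
profiles; they differ only in the angular basis (P_n vs P_n^1 cos/sin phi)
and source coefficient (n vs 1), which is validated against the infinite
medium limit, shell continuity and azimuthal symmetry.

Units: radii and measurement points in mm, dipole moments in nAm,
conductivities in S/m; potentials are returned in uV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dipole import DipoleMoment

__all__ = [
    "FourSphereModel", "SurfaceGrid", "infinite_medium_dipole_potential",
    "four_sphere_potential", "four_sphere_multi_dipole", "rotate_dipole",
    "decompose_field", "multi_dipoles_from_axial",
]

#: default head parameters: brain, CSF, skull, scalp
DEFAULT_RADII = (79.0, 80.0, 85.0, 90.0)        # mm
DEFAULT_SIGMAS = (0.3, 1.5, 0.015, 0.3)         # S/m


@dataclass
class FourSphereModel:
    """Concentric brain/CSF/skull/scalp shells with piecewise conductivity."""

    radii: tuple = DEFAULT_RADII      # outer radii r_1 < r_2 < r_3 < r_4, mm
    sigmas: tuple = DEFAULT_SIGMAS    # S/m
    n_max: int = 300

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        s = np.asarray(self.sigmas, dtype=float)
        if r.shape != (4,) or s.shape != (4,):
            raise ValueError("need four radii and four conductivities")
        if not (0 < r[0] < r[1] < r[2] < r[3]):
            raise ValueError("radii must be strictly increasing and positive")
        if np.any(s <= 0):
            raise ValueError("conductivities must be positive")
        self.radii = tuple(r)
        self.sigmas = tuple(s)

    # -- per-order shell coefficients -------------------------------------
    def _shell_coefficients(self, r_z):
        """Solve the interface conditions for harmonic orders 1..n_max.

        Returns u of shape (n_max, 7): columns A1, A2, B2, A3, B3, A4, B4
        for a unit source coefficient (the tangential normalization); the
        radial solution is n times this by linearity.
        """
        r1, r2, r3, r4 = self.radii
        s1, s2, s3, s4 = self.sigmas
        ns = np.arange(1, self.n_max + 1, dtype=float)
        k = len(ns)
        t1 = (r_z / r1) ** (ns + 1)
        f12 = (r1 / r2) ** ns
        f23 = (r2 / r3) ** ns
        f34 = (r3 / r4) ** ns
        g12 = (r1 / r2) ** (ns + 1)
        g23 = (r2 / r3) ** (ns + 1)
        g34 = (r3 / r4) ** (ns + 1)

        A = np.zeros((k, 7, 7))
        b = np.zeros((k, 7))
        n = ns
        # continuity at r1: A1 - A2 f12 - B2 = -t1
        A[:, 0, 0] = 1.0
        A[:, 0, 1] = -f12
        A[:, 0, 2] = -1.0
        b[:, 0] = -t1
        # flux at r1: s1 n A1 - s2 (n f12 A2 - (n+1) B2) = s1 (n+1) t1
        A[:, 1, 0] = s1 * n
        A[:, 1, 1] = -s2 * n * f12
        A[:, 1, 2] = s2 * (n + 1)
        b[:, 1] = s1 * (n + 1) * t1
        # continuity at r2: A2 + B2 g12 - A3 f23 - B3 = 0
        A[:, 2, 1] = 1.0
        A[:, 2, 2] = g12
        A[:, 2, 3] = -f23
        A[:, 2, 4] = -1.0
        # flux at r2
        A[:, 3, 1] = s2 * n
        A[:, 3, 2] = -s2 * (n + 1) * g12
        A[:, 3, 3] = -s3 * n * f23
        A[:, 3, 4] = s3 * (n + 1)
        # continuity at r3
        A[:, 4, 3] = 1.0
        A[:, 4, 4] = g23
        A[:, 4, 5] = -f34
        A[:, 4, 6] = -1.0
        # flux at r3
        A[:, 5, 3] = s3 * n
        A[:, 5, 4] = -s3 * (n + 1) * g23
        A[:, 5, 5] = -s4 * n * f34
        A[:, 5, 6] = s4 * (n + 1)
        # zero radial current at r4
        A[:, 6, 5] = n
        A[:, 6, 6] = -(n + 1) * g34
        return np.linalg.solve(A, b[:, :, None])[:, :, 0]

    def _radial_profiles(self, r_z, r_points):
        """G_n(r) for every measurement radius: source term (shell 1 only)
        plus the shell correction, shape (n_points, n_max)."""
        r1, r2, r3, r4 = self.radii
        u = self._shell_coefficients(r_z)
        ns = np.arange(1, self.n_max + 1, dtype=float)
        out = np.empty((len(r_points), self.n_max))
        for i, r in enumerate(r_points):
            if r <= r_z:
                raise ValueError(
                    "measurement radius must exceed the dipole radius")
            if r > r4 * (1 + 1e-9):
                raise ValueError("measurement point outside the scalp sphere")
            if r <= r1:
                prof = (r_z / r) ** (ns + 1) + u[:, 0] * (r / r1) ** ns
            elif r <= r2:
                prof = u[:, 1] * (r / r2) ** ns + u[:, 2] * (r1 / r) ** (ns + 1)
            elif r <= r3:
                prof = u[:, 3] * (r / r3) ** ns + u[:, 4] * (r2 / r) ** (ns + 1)
            else:
                prof = u[:, 5] * (r / r4) ** ns + u[:, 6] * (r3 / r) ** (ns + 1)
            out[i] = prof
        return out


@dataclass
class SurfaceGrid:
    """Measurement points on a sphere with local orthonormal unit vectors."""

    points: np.ndarray     # (N, 3) mm
    r_hat: np.ndarray      # (N, 3)
    theta_hat: np.ndarray  # (N, 3)
    phi_hat: np.ndarray    # (N, 3)
    angles: np.ndarray = None

    @classmethod
    def from_angles(cls, radius, theta, phi):
        """Grid from polar angles theta (from +z) and azimuths phi."""
        theta = np.atleast_1d(np.asarray(theta, float))
        phi = np.atleast_1d(np.asarray(phi, float))
        if phi.size == 1:
            phi = np.full_like(theta, phi[0])
        st, ct = np.sin(theta), np.cos(theta)
        sp, cp = np.sin(phi), np.cos(phi)
        r_hat = np.column_stack([st * cp, st * sp, ct])
        theta_hat = np.column_stack([ct * cp, ct * sp, -st])
        phi_hat = np.column_stack([-sp, cp, np.zeros_like(sp)])
        return cls(radius * r_hat, r_hat, theta_hat, phi_hat,
                   angles=np.column_stack([theta, phi]))

    @classmethod
    def arc_xz(cls, radius, angles=None):
        """Arc of sites in the xz-plane at signed angles from the +z apex.

        Default: the nine-site layout theta in [-pi/4, pi/4], step pi/16.
        phi_hat is +y at every site (in particular at the apex).
        """
        if angles is None:
            angles = np.arange(-4, 5) * np.pi / 16.0
        a = np.atleast_1d(np.asarray(angles, float))
        r_hat = np.column_stack([np.sin(a), np.zeros_like(a), np.cos(a)])
        theta_hat = np.column_stack([np.cos(a), np.zeros_like(a), -np.sin(a)])
        phi_hat = np.tile([0.0, 1.0, 0.0], (len(a), 1))
        return cls(radius * r_hat, r_hat, theta_hat, phi_hat, angles=a)

    def __len__(self):
        return len(self.points)


def infinite_medium_dipole_potential(p: DipoleMoment, points, sigma=0.3):
    """phi = p.R / (4 pi sigma R^3) in an infinite homogeneous medium.

    ``points`` in um relative to the same origin as the dipole location
    (um); output in mV, shape (n_points, n_t).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    loc = p.location if p.location is not None else np.zeros(3)
    R = (points - loc) * 1e-3  # um -> mm
    R3 = np.linalg.norm(R, axis=1) ** 3
    if np.any(R3 == 0):
        raise ValueError("measurement point coincides with the dipole")
    return (R @ p.p) / (4.0 * np.pi * sigma * R3[:, None])


def _legendre_pair(n_max, x):
    """(P_n(x), P_n^1(x)) for n = 1..n_max at scalar x.

    P_n^1 carries the Condon-Shortley phase: P_1^1(x) = -sqrt(1-x^2).
    """
    P = np.empty(n_max + 1)
    P[0], P[1] = 1.0, x
    for k in range(1, n_max):
        P[k + 1] = ((2 * k + 1) * x * P[k] - k * P[k - 1]) / (k + 1)
    s = np.sqrt(max(1.0 - x * x, 0.0))
    P1 = np.empty(n_max + 1)
    P1[0] = 0.0
    if s == 0.0:
        P1[1:] = 0.0
    else:
        # P_n^1 = -(1-x^2)^(1/2) dP_n/dx;  (x^2-1) P_n' = n (x P_n - P_(n-1))
        ns = np.arange(1, n_max + 1)
        dP = ns * (x * P[1:] - P[:-1]) / (x * x - 1.0) if abs(x) != 1.0 else None
        P1[1:] = -s * dP
    return P[1:], P1[1:]


def four_sphere_potential(model: FourSphereModel, dip: DipoleMoment, points):
    """Electric potential (uV) of a current dipole in the four-sphere model.

    ``dip.location`` (mm) must lie strictly inside the brain sphere and at
    nonzero radius; ``points`` (N, 3) in mm must lie outside the dipole
    radius and inside (or on) the scalp sphere.  Returns (N, n_t).
    """
    loc = np.asarray(dip.location, dtype=float)
    r_z = np.linalg.norm(loc)
    r1 = model.radii[0]
    if r_z >= r1:
        raise ValueError("dipole location must lie strictly inside the brain sphere")
    if r_z <= 0:
        raise ValueError("dipole must sit at nonzero radius (radial axis undefined at the center)")
    points = np.atleast_2d(np.asarray(points, dtype=float))

    z_hat = loc / r_z
    helper = np.array([1.0, 0.0, 0.0])
    if abs(z_hat @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1_hat = np.cross(z_hat, helper)
    t1_hat /= np.linalg.norm(t1_hat)
    t2_hat = np.cross(z_hat, t1_hat)

    p_r = z_hat @ dip.p          # (n_t,)
    p_t1 = t1_hat @ dip.p
    p_t2 = t2_hat @ dip.p

    r_pts = np.linalg.norm(points, axis=1)
    G = model._radial_profiles(r_z, r_pts)   # (N, n_max)
    ns = np.arange(1, model.n_max + 1, dtype=float)

    out = np.empty((len(points), dip.p.shape[1]))
    K = 1.0 / (4.0 * np.pi * model.sigmas[0] * r_z**2)  # mV for nAm, mm
    for i, (x, r) in enumerate(zip(points, r_pts)):
        cos_t = np.clip((x @ z_hat) / r, -1.0, 1.0)
        sin_t = np.sqrt(max(1.0 - cos_t**2, 0.0))
        if sin_t < 1e-14:
            cphi = sphi = 0.0
        else:
            xy1, xy2 = x @ t1_hat, x @ t2_hat
            norm = np.hypot(xy1, xy2)
            cphi, sphi = xy1 / norm, xy2 / norm
        Pn, Pn1 = _legendre_pair(model.n_max, cos_t)
        S_rad = np.sum(ns * G[i] * Pn)
        S_tan = np.sum(G[i] * Pn1)
        out[i] = K * (p_r * S_rad - (p_t1 * cphi + p_t2 * sphi) * S_tan)
    return out * 1e3  # mV -> uV


def four_sphere_multi_dipole(model: FourSphereModel, dipoles, points):
    """Sum of four-sphere potentials over a set of dipoles (linearity).

    ``dipoles`` is an iterable of DipoleMoment, each with its own location
    in mm.  Used for ECoG where a single whole-cell dipole is inaccurate:
    one small dipole per axial current keeps the dipole approximation valid.
    """
    dipoles = list(dipoles)
    if not dipoles:
        raise ValueError("no dipoles given")
    total = None
    for d in dipoles:
        phi = four_sphere_potential(model, d, points)
        total = phi if total is None else total + phi
    return total


def multi_dipoles_from_axial(ax, cell_origin_mm):
    """Per-axial-current dipoles positioned in head coordinates.

    ``ax`` is an AxialCurrentSet in cell coordinates (um); the cell origin
    is given in mm.  Returns a list of DipoleMoment (nAm, locations mm).
    """
    origin = np.asarray(cell_origin_mm, dtype=float)
    out = []
    for i in range(ax.n_currents):
        p = ax.i_axial[i][None, :] * ax.d_vectors[i][:, None] * 1e-6
        out.append(DipoleMoment(p, location=origin + ax.r_mid[i] * 1e-3,
                                location_rule="axial-current midpoint"))
    return out


def rotation_matrix(axis, angle):
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError("axis must be 'x', 'y' or 'z'")


def rotate_dipole(p: DipoleMoment, axis="x", angle=np.pi / 2) -> DipoleMoment:
    """Rotate the dipole moment vector about a coordinate axis.

    The source location is kept fixed (the standard construction for
    comparing radial vs tangential dipoles at the same site).
    """
    R = rotation_matrix(axis, angle)
    return DipoleMoment(R @ p.p, location=p.location,
                        location_rule=p.location_rule)


def decompose_field(vectors, grid: SurfaceGrid):
    """Project vectors at the grid points onto (r_hat, theta_hat, phi_hat).

    ``vectors`` is (N, 3) or (N, 3, n_t); returns the three components with
    the leading N axis preserved.
    """
    v = np.asarray(vectors, dtype=float)
    if v.shape[0] != len(grid):
        raise ValueError("vectors must match the number of grid points")
    ein = "nk,nk->n" if v.ndim == 2 else "nk,nkt->nt"
    return (np.einsum(ein, grid.r_hat, v),
            np.einsum(ein, grid.theta_hat, v),
            np.einsum(ein, grid.phi_hat, v))
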