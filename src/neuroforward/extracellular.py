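"""Volume-conductor kernels mapping current sources to electrode potentials.

All kernels return a :class:`KernelMatrix` M (mV per nA): the potential at
the contacts is the linear map phi = M @ I with I the per-source currents in
nA.  Geometry is in micrometers and conductivities in S/m, which makes
1/(4*pi*sigma*d) come out directly in mV/nA.

Supported media: infinite homogeneous isotropic, homogeneous anisotropic
(diagonal conductivity tensor), planar layered media via the method of
images (slice-on-MEA three-layer and cortical-surface two-layer models), and
a sphere of one conductivity embedded in another (monopole sources).
Singularities are prevented by clamping the source-contact distance (point
sources) or the perpendicular distance (line sources) to the segment radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import SegmentTree

__all__ = [
    "Homogeneous", "Anisotropic", "MoILayers", "OneSphere", "ProbeSpec",
    "KernelMatrix", "point_source_kernel", "line_source_kernel",
    "soma_as_point_kernel", "disc_average", "anisotropic_point_kernel",
    "moi_surface_kernel", "moi_three_layer_kernel", "one_sphere_potential",
    "kernel_matrix",
]


@dataclass
class Homogeneous:
    """Infinite homogeneous isotropic medium; sigma in S/m."""
    sigma: float = 0.3

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class Anisotropic:
    """Homogeneous medium with diagonal conductivity tensor (S/m)."""
    sigma_x: float
    sigma_y: float
    sigma_z: float

    def __post_init__(self):
        if min(self.sigma_x, self.sigma_y, self.sigma_z) <= 0:
            raise ValueError("all conductivities must be > 0")


@dataclass
class MoILayers:
    """Three planar layers: electrode plane (z<0, sigma_g), tissue slab
    z in [0, h) (sigma_t) and saline above (z>=h, sigma_s)."""
    sigma_g: float
    sigma_t: float
    sigma_s: float
    h: float = 300.0
    n_images: int = 20

    def __post_init__(self):
        if self.sigma_t <= 0:
            raise ValueError("tissue conductivity must be > 0")
        if self.sigma_g < 0 or self.sigma_s < 0:
            raise ValueError("conductivities must be >= 0")
        if self.h <= 0:
            raise ValueError("slab thickness must be > 0")


@dataclass
class OneSphere:
    """Sphere of radius R (um) centered at the origin with conductivity
    sigma_in, embedded in an infinite medium of sigma_out."""
    sigma_in: float
    sigma_out: float
    R: float
    n_terms: int = 100

    def __post_init__(self):
        if self.sigma_in <= 0 or self.sigma_out <= 0 or self.R <= 0:
            raise ValueError("require positive conductivities and radius")


@dataclass
class ProbeSpec:
    """Electrode geometry plus medium and source model.

    positions: (n, 3) contact positions (um); normals: unit surface normals;
    r_contact: disc radius (um) for surface averaging with m random points;
    medium: one of the medium dataclasses above; source_model: one of
    "pointsource", "linesource", "soma_as_point".
    """

    positions: np.ndarray
    normals: np.ndarray = None
    r_contact: float = 0.0
    m: int = 50
    medium: object = field(default_factory=Homogeneous)
    source_model: str = "linesource"

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.normals is None:
            self.normals = np.tile([0.0, 1.0, 0.0], (len(self.positions), 1))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if self.normals.shape != self.positions.shape:
            raise ValueError("normals must match positions in shape")
        if self.r_contact < 0 or self.m < 1:
            raise ValueError("require r_contact >= 0 and m >= 1")
        if self.source_model not in ("pointsource", "linesource", "soma_as_point"):
            raise ValueError(f"unknown source model {self.source_model!r}")


@dataclass
class KernelMatrix:
    """Linear map from source currents (nA) to contact potentials (mV)."""

    M: np.ndarray
    medium: object = None
    source_model: str = ""
    meta: dict = field(default_factory=dict)

    def __matmul__(self, currents):
        return self.M @ currents

    @property
    def shape(self):
        return self.M.shape


def _sigma_of(probe):
    if not isinstance(probe.medium, Homogeneous):
        raise ValueError("this kernel requires a homogeneous isotropic medium")
    return probe.medium.sigma


def _point_rows(contacts, sources, sigma, radii):
    diff = contacts[:, None, :] - sources[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    if radii is not None:
        dist = np.maximum(dist, np.asarray(radii)[None, :])
    if np.any(dist <= 0):
        raise ValueError("contact coincides with a zero-radius source")
    return 1.0 / (4.0 * np.pi * sigma * dist)


def point_source_kernel(sources, probe: ProbeSpec, radii=None) -> KernelMatrix:
    """Point-current-source kernel, 1/(4 pi sigma |r - r_n|).

    ``radii`` (um, per source) clamps the distance from below to prevent
    singular potentials inside the source.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    M = _point_rows(probe.positions, sources, _sigma_of(probe), radii)
    return KernelMatrix(M, probe.medium, "pointsource")


def _line_rows(contacts, starts, ends, sigma, radii):
    starts = np.atleast_2d(starts)
    ends = np.atleast_2d(ends)
    d = ends - starts
    ds = np.linalg.norm(d, axis=-1)
    if np.any(ds <= 0):
        raise ValueError("degenerate (zero-length) line source")
    u = d / ds[:, None]
    a = contacts[:, None, :] - starts[None, :, :]
    proj = np.einsum("cnk,nk->cn", a, u)
    rp2 = np.maximum(np.einsum("cnk,cnk->cn", a, a) - proj**2, 0.0)
    rp = np.sqrt(rp2)
    if radii is not None:
        rp = np.maximum(rp, np.asarray(radii)[None, :])
    if np.any((rp <= 0) & (proj >= 0) & (proj <= ds[None, :])):
        raise ValueError("contact lies on a zero-radius line source")
    rp = np.maximum(rp, 1e-12)
    # int_0^ds ds'/|r - x(s')| = asinh((ds - proj)/rp) + asinh(proj/rp)
    integral = np.arcsinh((ds[None, :] - proj) / rp) + np.arcsinh(proj / rp)
    return integral / (4.0 * np.pi * sigma * ds[None, :])


def line_source_kernel(starts, ends, probe: ProbeSpec, radii=None) -> KernelMatrix:
    """Line-source kernel: the point kernel integrated along each segment axis.

    The perpendicular distance is clamped to the segment radius when given.
    """
    M = _line_rows(probe.positions, np.asarray(starts, float),
                   np.asarray(ends, float), _sigma_of(probe), radii)
    return KernelMatrix(M, probe.medium, "linesource")


def soma_as_point_kernel(tree: SegmentTree, probe: ProbeSpec) -> KernelMatrix:
    """Line sources for neurites combined with a spherical (point) soma."""
    labels = tree.label
    soma_mask = labels == "soma"
    if not soma_mask.any():
        raise ValueError("tree has no soma-labeled segment")
    sigma = _sigma_of(probe)
    M = _line_rows(probe.positions, tree.start, tree.end, sigma, tree.radius)
    Mp = _point_rows(probe.positions, tree.mid, sigma, tree.radius)
    M[:, soma_mask] = Mp[:, soma_mask]
    return KernelMatrix(M, probe.medium, "soma_as_point")


def _disc_points(center, normal, r_contact, m, rng):
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("zero-length contact normal")
    normal = normal / nn
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rad = r_contact * np.sqrt(rng.uniform(size=m))
    ang = rng.uniform(0.0, 2.0 * np.pi, size=m)
    return center + rad[:, None] * (np.cos(ang)[:, None] * e1
                                    + np.sin(ang)[:, None] * e2)


def disc_average(kernel_fn, probe: ProbeSpec, seed=0) -> KernelMatrix:
    """Average a kernel over each contact's disc surface.

    ``kernel_fn`` maps an (n, 3) array of evaluation positions to a kernel
    matrix (rows = positions).  Each contact's row becomes the mean over
    probe.m points drawn uniformly on the disc of radius probe.r_contact
    oriented by the contact normal; the draw is seeded and recorded.
    """
    rng = np.random.default_rng(seed)
    if probe.r_contact == 0.0:
        return kernel_fn(probe.positions)
    rows = []
    for c, nvec in zip(probe.positions, probe.normals):
        pts = _disc_points(c, nvec, probe.r_contact, probe.m, rng)
        rows.append(kernel_fn(pts).M.mean(axis=0))
    out = KernelMatrix(np.vstack(rows), probe.medium, "disc_average")
    out.meta.update(seed=seed, m=probe.m, r_contact=probe.r_contact)
    return out


def anisotropic_point_kernel(sources, probe: ProbeSpec, radii=None) -> KernelMatrix:
    """Point-source kernel in a homogeneous anisotropic medium.

    phi = I / (4 pi sqrt(sy*sz*dx^2 + sx*sz*dy^2 + sx*sy*dz^2)); reduces to
    the isotropic kernel when all three conductivities coincide.
    """
    med = probe.medium
    if not isinstance(med, Anisotropic):
        raise ValueError("probe.medium must be Anisotropic")
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    diff = probe.positions[:, None, :] - sources[None, :, :]
    if radii is not None:
        dist = np.linalg.norm(diff, axis=-1)
        r = np.asarray(radii)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(dist < r, r / np.maximum(dist, 1e-300), 1.0)
        diff = diff * scale[..., None]
    sx, sy, sz = med.sigma_x, med.sigma_y, med.sigma_z
    q = (sy * sz * diff[..., 0]**2 + sx * sz * diff[..., 1]**2
         + sx * sy * diff[..., 2]**2)
    if np.any(q <= 0):
        raise ValueError("contact coincides with a zero-radius source")
    return KernelMatrix(1.0 / (4.0 * np.pi * np.sqrt(q)), med, "pointsource")


def anisotropic_line_kernel(starts, ends, probe: ProbeSpec, radii=None,
                            order=64) -> KernelMatrix:
    """Anisotropic line sources by Gauss-Legendre quadrature of the point
    kernel along each segment (no closed form is attempted)."""
    starts = np.atleast_2d(np.asarray(starts, float))
    ends = np.atleast_2d(np.asarray(ends, float))
    x, w = np.polynomial.legendre.leggauss(order)
    ts = 0.5 * (x + 1.0)
    M = 0.0
    for t, wt in zip(ts, w):
        pts = starts + t * (ends - starts)
        M = M + 0.5 * wt * anisotropic_point_kernel(pts, probe, radii).M
    return KernelMatrix(M, probe.medium, "linesource")


def moi_surface_kernel(sources, probe: ProbeSpec, radii=None) -> KernelMatrix:
    """Two-layer method-of-images kernel for a planar cortical surface.

    Tissue of conductivity sigma_t fills z <= h with a medium sigma_s above;
    the potential at or below the surface is the direct term plus one image
    about z = h weighted by W = (sigma_t - sigma_s)/(sigma_t + sigma_s).
    The probe's medium must be MoILayers with sigma_g == sigma_t (the lower
    boundary is ignored).
    """
    med = probe.medium
    if not isinstance(med, MoILayers):
        raise ValueError("probe.medium must be MoILayers")
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if np.any(sources[:, 2] > med.h) or np.any(probe.positions[:, 2] > med.h):
        raise ValueError("sources and contacts must lie at or below z = h")
    W = (med.sigma_t - med.sigma_s) / (med.sigma_t + med.sigma_s)
    direct = _point_rows(probe.positions, sources, med.sigma_t, radii)
    image = sources.copy()
    image[:, 2] = 2.0 * med.h - image[:, 2]
    mirrored = _point_rows(probe.positions, image, med.sigma_t, None)
    out = KernelMatrix(direct + W * mirrored, med, "pointsource")
    out.meta["W_TS"] = W
    return out


def _moi_image_terms(med: MoILayers):
    """Image z-maps and weights for the doubly-mirrored three-layer expansion.

    Returns a list of (weight, sign, shift) describing images at
    z_img = sign * z' + shift with the given weight.  Derived by repeated
    reflection about the tissue-saline plane z = h (coefficient W_TS) and
    the tissue-electrode plane z = 0 (coefficient W_TG): one family sits at
    z' + 2nh with weight (W_TS*W_TG)^|n| and one at -z' + 2nh with weight
    W_TS^n * W_TG^(n-1) for n >= 1 and W_TS^|n| * W_TG^(|n|+1) for n <= 0.
    """
    W_ts = (med.sigma_t - med.sigma_s) / (med.sigma_t + med.sigma_s)
    W_tg = (med.sigma_t - med.sigma_g) / (med.sigma_t + med.sigma_g)
    terms = [(1.0, 1.0, 0.0)]
    N = med.n_images
    for n in range(1, N + 1):
        w = (W_ts * W_tg) ** n
        terms.append((w, 1.0, 2.0 * n * med.h))
        terms.append((w, 1.0, -2.0 * n * med.h))
    for n in range(1, N + 1):
        terms.append((W_ts**n * W_tg**(n - 1), -1.0, 2.0 * n * med.h))
    for n in range(0, N + 1):
        terms.append((W_ts**n * W_tg**(n + 1), -1.0, -2.0 * n * med.h))
    return [(w, s, z) for w, s, z in terms if w != 0.0]


def moi_three_layer_kernel(sources, probe: ProbeSpec, radii=None,
                           starts=None, ends=None) -> KernelMatrix:
    """Three-layer (electrode/tissue/saline) method-of-images kernel.

    Point sources anywhere in the slab z in [0, h); the line-source variant
    (pass ``starts``/``ends``) is only valid in the special case sigma_g = 0
    with all contacts at z = 0, mirroring the source segments.
    """
    med = probe.medium
    if not isinstance(med, MoILayers):
        raise ValueError("probe.medium must be MoILayers")
    line = starts is not None
    if line:
        starts = np.atleast_2d(np.asarray(starts, float))
        ends = np.atleast_2d(np.asarray(ends, float))
        zcoords = np.concatenate([starts[:, 2], ends[:, 2]])
        if med.sigma_g != 0.0 or np.any(np.abs(probe.positions[:, 2]) > 1e-9):
            raise ValueError("line sources require sigma_g = 0 and contacts at z = 0")
    else:
        sources = np.atleast_2d(np.asarray(sources, dtype=float))
        zcoords = sources[:, 2]
    if np.any(zcoords < 0) or np.any(zcoords >= med.h):
        raise ValueError("all sources must lie inside the slab z in [0, h)")

    M = 0.0
    first = True
    for w, s, shift in _moi_image_terms(med):
        if line:
            ist = starts.copy()
            ien = ends.copy()
            ist[:, 2] = s * starts[:, 2] + shift
            ien[:, 2] = s * ends[:, 2] + shift
            rows = _line_rows(probe.positions, ist, ien, med.sigma_t,
                              radii if first else None)
        else:
            img = sources.copy()
            img[:, 2] = s * sources[:, 2] + shift
            rows = _point_rows(probe.positions, img, med.sigma_t,
                               radii if first else None)
        M = M + w * rows
        first = False
    out = KernelMatrix(M, med, "linesource" if line else "pointsource")
    out.meta["n_images"] = med.n_images
    return out


def one_sphere_potential(sources, probe: ProbeSpec, radii=None) -> KernelMatrix:
    """Monopole sources inside a conducting sphere in a different outer medium.

    Legendre-series solution, continuous across the surface: inside,
    phi = I/(4 pi s_in) * (1/d + sum_n a_n r^n P_n) with
    a_n = (n+1)(s_in - s_out) r_s^n / (R^(2n+1) (n s_in + (n+1) s_out));
    outside the n=0 term reduces to the monopole I/(4 pi s_out r).
    """
    med = probe.medium
    if not isinstance(med, OneSphere):
        raise ValueError("probe.medium must be OneSphere")
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    rs = np.linalg.norm(sources, axis=1)
    if np.any(rs >= med.R):
        raise ValueError("all sources must lie strictly inside the sphere")
    contacts = probe.positions
    rc = np.linalg.norm(contacts, axis=1)
    n = np.arange(med.n_terms + 1)
    s_in, s_out, R = med.sigma_in, med.sigma_out, med.R

    M = np.zeros((len(contacts), len(sources)))
    for j, (src, r_s) in enumerate(zip(sources, rs)):
        # boundary-correction coefficients, fully expressed in radius ratios
        c_n = ((n + 1) * (s_in - s_out) * (r_s / R) ** n
               / (R * (n * s_in + (n + 1) * s_out)))
        e_n = (r_s / R) ** n + c_n * R
        for i, (c, r_c) in enumerate(zip(contacts, rc)):
            cosg = 1.0 if (r_c == 0 or r_s == 0) else \
                float(np.dot(c, src) / (r_c * r_s))
            cosg = np.clip(cosg, -1.0, 1.0)
            Pn = _legendre_all(med.n_terms, cosg)
            if r_c < R:
                d = np.linalg.norm(c - src)
                if radii is not None:
                    d = max(d, radii[j])
                if d <= 0:
                    raise ValueError("contact coincides with a source")
                series = np.sum(c_n * (r_c / R) ** n * Pn)
                M[i, j] = (1.0 / d + series) / (4.0 * np.pi * s_in)
            else:
                series = np.sum(e_n * (R / r_c) ** (n + 1) * Pn) / R
                M[i, j] = series / (4.0 * np.pi * s_in)
    return KernelMatrix(M, med, "pointsource")


def _legendre_all(n_max, x):
    """P_0..P_n_max at scalar x by upward recurrence."""
    P = np.empty(n_max + 1)
    P[0] = 1.0
    if n_max >= 1:
        P[1] = x
    for k in range(1, n_max):
        P[k + 1] = ((2 * k + 1) * x * P[k] - k * P[k - 1]) / (k + 1)
    return P


def kernel_matrix(tree: SegmentTree, probe: ProbeSpec, seed=0) -> KernelMatrix:
    """Build the probe's kernel matrix for a segment tree.

    Dispatches on probe.medium and probe.source_model and applies disc
    averaging when r_contact > 0.
    """
    med = probe.medium
    radii = tree.radius

    def at_positions(positions):
        p = ProbeSpec(positions, r_contact=0.0, m=1, medium=med,
                      source_model=probe.source_model)
        if isinstance(med, Homogeneous):
            if probe.source_model == "pointsource":
                return point_source_kernel(tree.mid, p, radii)
            if probe.source_model == "linesource":
                return line_source_kernel(tree.start, tree.end, p, radii)
            return soma_as_point_kernel(tree, p)
        if isinstance(med, Anisotropic):
            if probe.source_model == "pointsource":
                return anisotropic_point_kernel(tree.mid, p, radii)
            return anisotropic_line_kernel(tree.start, tree.end, p, radii)
        if isinstance(med, MoILayers):
            if probe.source_model == "linesource":
                return moi_three_layer_kernel(None, p, radii,
                                              starts=tree.start, ends=tree.end)
            return moi_three_layer_kernel(tree.mid, p, radii)
        if isinstance(med, OneSphere):
            return one_sphere_potential(tree.mid, p, radii)
        raise ValueError(f"unsupported medium {type(med).__name__}")

    if probe.r_contact > 0:
        return disc_average(at_positions, probe, seed=seed)
    return at_positions(probe.positions)
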