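"""Neuron morphologies: sections, discretization into segment trees, SWC I/O, fixtures.

A morphology is described as a rooted tree of *sections* (continuous pieces of
cable given as 3D polylines with per-point diameters).  For simulation and
forward modeling each section is split into ``nseg`` equal-arc-length
*segments* (compartments).  The resulting :class:`SegmentTree` carries, per
segment, start/mid/end coordinates, frustum membrane area, and the axial
half-resistances from the segment midpoint toward each end, plus the explicit
list of electrical connection nodes between segments (including mid-section
child attachments at a relative position chi on the parent).

Coordinate convention: z is the vertical/cortical-depth axis with the cortical
surface at z = 0 and depths negative.  Geometry is in micrometers, axial
resistivity in ohm*cm, lumped resistances in megaohm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Section",
    "SegmentTree",
    "discretize",
    "load_swc",
    "write_swc",
    "make_ball_and_stick",
    "make_stylized_pyramidal",
]

LABELS = ("soma", "dend", "apic", "axon")

_SWC_TYPE_TO_LABEL = {1: "soma", 2: "axon", 3: "dend", 4: "apic"}
_LABEL_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_LABEL.items()}


@dataclass
class Section:
    """A continuous, unbranched piece of neural cable.

    ``points`` is an (k, 3) polyline in micrometers, ``diams`` the matching
    per-point diameters.  ``parent`` refers to another section id (None for
    the root) and ``chi`` is the relative arc position on the parent where
    this section attaches (0 = start, 1 = end).
    """

    id: int
    label: str
    points: np.ndarray
    diams: np.ndarray
    parent: int | None = None
    chi: float = 1.0
    nseg: int = 1

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.diams = np.atleast_1d(np.asarray(self.diams, dtype=float))
        if self.diams.size == 1:
            self.diams = np.full(len(self.points), float(self.diams[0]))
        if self.label not in LABELS:
            raise ValueError(f"unknown section label {self.label!r}")
        if len(self.points) < 2:
            raise ValueError("a section needs at least two polyline points")
        if len(self.diams) != len(self.points):
            raise ValueError("diams and points length mismatch")
        if np.any(self.diams <= 0):
            raise ValueError("diameters must be positive")
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")
        if self.nseg < 1:
            raise ValueError("nseg must be >= 1")

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each polyline point (starts at 0)."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])


@dataclass
class _Node:
    """Electrical connection node between segments.

    ``kind`` is "boundary" for true nodes located at a segment boundary
    (parent reached through its half resistance, Kirchhoff applies) or
    "clamped" for mid-segment child attachments where the node potential
    equals the parent segment potential and the parent resistance does not
    enter.  ``children`` holds (segment index, resistance to child midpoint
    in megaohm, child-side start point).
    """

    kind: str
    pos: np.ndarray
    parent_seg: int
    parent_res: float
    children: list = field(default_factory=list)


@dataclass
class SegmentTree:
    """Discretized morphology: flat arrays over segments plus connection nodes."""

    start: np.ndarray        # (n, 3) um
    mid: np.ndarray          # (n, 3) um
    end: np.ndarray          # (n, 3) um
    length: np.ndarray       # (n,) um
    diam: np.ndarray         # (n,) um, arc-averaged
    area: np.ndarray         # (n,) um^2, frustum lateral surface
    label: np.ndarray        # (n,) str
    section_id: np.ndarray   # (n,) int
    parent: np.ndarray       # (n,) int, -1 for the root segment
    r_half_start: np.ndarray  # (n,) Mohm, midpoint -> segment start
    r_half_end: np.ndarray    # (n,) Mohm, midpoint -> segment end
    rho_a: float             # ohm*cm used to build the resistances
    nodes: list = field(default_factory=list)
    sections: list = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.length)

    @property
    def radius(self) -> np.ndarray:
        return self.diam / 2.0

    def soma_index(self) -> int:
        idx = np.flatnonzero(self.label == "soma")
        if idx.size == 0:
            raise ValueError("morphology has no soma-labeled segment")
        return int(idx[0])

    def axial_laplacian(self, rho_a: float | None = None) -> np.ndarray:
        """Axial conductance Laplacian L (uS), n x n.

        Row n of L @ V is the total axial current (nA) flowing *out* of
        segment n through all its connection nodes.  Branch nodes are
        eliminated analytically (their potential is a conductance-weighted
        mean of the neighbors), which yields pairwise effective couplings
        g_i g_j / sum(g) between all segments meeting at the node.  Clamped
        (mid-attachment) nodes couple each child to the parent through the
        child resistance only.
        """
        scale = 1.0 if rho_a is None else rho_a / self.rho_a
        n = self.n_segments
        L = np.zeros((n, n))

        def couple(i, j, g):
            L[i, i] += g
            L[j, j] += g
            L[i, j] -= g
            L[j, i] -= g

        for node in self.nodes:
            if node.kind == "clamped":
                for seg, res, _pos in node.children:
                    couple(node.parent_seg, seg, 1.0 / (res * scale))
            else:
                members = [(node.parent_seg, node.parent_res)]
                members += [(seg, res) for seg, res, _pos in node.children]
                g = np.array([1.0 / (r * scale) for _s, r in members])
                gtot = g.sum()
                for a in range(len(members)):
                    for b in range(a + 1, len(members)):
                        couple(members[a][0], members[b][0], g[a] * g[b] / gtot)
        return L


def _interp_on_polyline(arcs, points, diams, s):
    """Point and diameter at arc position s along a polyline."""
    s = np.clip(s, 0.0, arcs[-1])
    i = np.searchsorted(arcs, s, side="right") - 1
    i = min(max(i, 0), len(arcs) - 2)
    ds = arcs[i + 1] - arcs[i]
    t = 0.0 if ds == 0 else (s - arcs[i]) / ds
    return points[i] + t * (points[i + 1] - points[i]), diams[i] + t * (diams[i + 1] - diams[i])


def _piece_integrals(arcs, points, diams, s0, s1, rho_a):
    """Frustum lateral area (um^2) and axial resistance (Mohm) over [s0, s1].

    The sub-interval is cut at every polyline vertex so each piece has a
    linear taper: area uses the slant surface pi*(d0+d1)/2*slant and the
    resistance the exact linear-taper form rho*l/(pi r0 r1).
    """
    cuts = [s0] + [a for a in arcs if s0 < a < s1] + [s1]
    area = 0.0
    res = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a <= 0:
            continue
        _, d0 = _interp_on_polyline(arcs, points, diams, a)
        _, d1 = _interp_on_polyline(arcs, points, diams, b)
        dl = b - a
        slant = np.hypot(dl, (d0 - d1) / 2.0)
        area += np.pi * (d0 + d1) / 2.0 * slant
        # rho [ohm*cm] * l [um] / (pi r0 r1 [um^2]) * 1e4 -> ohm, *1e-6 -> Mohm
        res += rho_a * dl / (np.pi * (d0 / 2.0) * (d1 / 2.0)) * 1e-2
    return area, res


def discretize(sections, nseg=None, max_seg_length=None, rho_a=150.0) -> SegmentTree:
    """Split sections into equal-arc-length segments and wire the tree.

    ``nseg`` overrides the per-section segment count (an int applies to all
    sections); alternatively ``max_seg_length`` (um) imposes a ceiling on
    segment length.  ``rho_a`` is the axial resistivity (ohm*cm) used for the
    stored half resistances.
    """
    sections = list(sections)
    ids = [s.id for s in sections]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate section ids")
    by_id = {s.id: s for s in sections}
    roots = [s for s in sections if s.parent is None]
    if len(roots) != 1:
        raise ValueError(f"section graph must have exactly one root, got {len(roots)}")
    for s in sections:
        if s.parent is not None and s.parent not in by_id:
            raise ValueError(f"section {s.id} references unknown parent {s.parent}")
    # cycle check via rootedness
    for s in sections:
        seen = set()
        cur = s
        while cur.parent is not None:
            if cur.id in seen:
                raise ValueError("cycle in section parent links")
            seen.add(cur.id)
            cur = by_id[cur.parent]

    seg_start, seg_mid, seg_end = [], [], []
    seg_len, seg_diam, seg_area = [], [], []
    seg_label, seg_secid = [], []
    seg_rhs, seg_rhe = [], []
    first_seg = {}
    seg_count = {}
    nodes: list[_Node] = []

    for sec in sections:
        L = sec.length
        if L <= 0:
            raise ValueError(f"section {sec.id} has zero length")
        if isinstance(nseg, dict):
            ns = int(nseg.get(sec.id, sec.nseg))
        elif nseg is not None:
            ns = int(nseg)
        elif max_seg_length is not None:
            ns = max(1, int(np.ceil(L / float(max_seg_length))))
        else:
            ns = sec.nseg
        arcs = sec.arc_lengths
        first_seg[sec.id] = len(seg_len)
        seg_count[sec.id] = ns
        bounds = np.linspace(0.0, L, ns + 1)
        for i in range(ns):
            s0, s1 = bounds[i], bounds[i + 1]
            smid = 0.5 * (s0 + s1)
            p0, d0 = _interp_on_polyline(arcs, sec.points, sec.diams, s0)
            p1, d1 = _interp_on_polyline(arcs, sec.points, sec.diams, s1)
            pm, _dm = _interp_on_polyline(arcs, sec.points, sec.diams, smid)
            a_lo, r_lo = _piece_integrals(arcs, sec.points, sec.diams, s0, smid, rho_a)
            a_hi, r_hi = _piece_integrals(arcs, sec.points, sec.diams, smid, s1, rho_a)
            seg_start.append(p0)
            seg_mid.append(pm)
            seg_end.append(p1)
            seg_len.append(s1 - s0)
            seg_diam.append(0.5 * (d0 + d1))
            seg_area.append(a_lo + a_hi)
            seg_label.append(sec.label)
            seg_secid.append(sec.id)
            seg_rhs.append(r_lo)
            seg_rhe.append(r_hi)

    n = len(seg_len)
    start = np.array(seg_start)
    mid = np.array(seg_mid)
    end = np.array(seg_end)
    rhs = np.array(seg_rhs)
    rhe = np.array(seg_rhe)
    parent = np.full(n, -1, dtype=int)

    # internal boundary nodes between consecutive segments of a section
    for sec in sections:
        f0, ns = first_seg[sec.id], seg_count[sec.id]
        for i in range(1, ns):
            a, b = f0 + i - 1, f0 + i
            nodes.append(_Node("boundary", end[a].copy(), a, rhe[a],
                               [(b, rhs[b], start[b].copy())]))
            parent[b] = a

    # attachment nodes for child sections
    end_nodes = {}      # parent section id -> _Node at its far end
    start_nodes = {}    # root section id -> _Node at its near end
    clamped_nodes = {}  # (parent section id, containing segment) -> _Node
    for sec in sections:
        if sec.parent is None:
            continue
        psec = by_id[sec.parent]
        pf, pns = first_seg[psec.id], seg_count[psec.id]
        cf = first_seg[sec.id]
        child_entry = (cf, rhs[cf], start[cf].copy())
        if sec.chi >= 1.0 - 1e-9:
            key = psec.id
            if key not in end_nodes:
                plast = pf + pns - 1
                end_nodes[key] = _Node("boundary", end[plast].copy(), plast, rhe[plast])
                nodes.append(end_nodes[key])
            node = end_nodes[key]
        elif sec.chi <= 1e-9 and psec.parent is None:
            key = psec.id
            if key not in start_nodes:
                start_nodes[key] = _Node("boundary", start[pf].copy(), pf, rhs[pf])
                nodes.append(start_nodes[key])
            node = start_nodes[key]
        else:
            # mid-section attachment: node potential clamped to the segment
            # of the parent section that contains arc position chi
            arc = sec.chi * psec.length
            k = min(int(arc / (psec.length / pns)), pns - 1)
            key = (psec.id, k)
            if key not in clamped_nodes:
                clamped_nodes[key] = _Node("clamped", start[cf].copy(), pf + k, np.inf)
                nodes.append(clamped_nodes[key])
            node = clamped_nodes[key]
        node.children.append(child_entry)
        parent[cf] = node.parent_seg

    tree = SegmentTree(
        start=start, mid=mid, end=end,
        length=np.array(seg_len), diam=np.array(seg_diam), area=np.array(seg_area),
        label=np.array(seg_label), section_id=np.array(seg_secid, dtype=int),
        parent=parent, r_half_start=rhs, r_half_end=rhe,
        rho_a=float(rho_a), nodes=nodes, sections=sections,
    )
    if np.count_nonzero(tree.parent < 0) != 1:
        raise ValueError("segment tree must have exactly one root segment")
    return tree


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column dialect, 1-based ids)

def _soma_equivalent_section(sec_id, center, radius):
    """Spherical soma as a z-aligned cylinder of length = diameter.

    The lateral cylinder area pi*d^2 equals the sphere surface area.
    """
    c = np.asarray(center, dtype=float)
    d = 2.0 * radius
    pts = np.array([c + [0, 0, -radius], c + [0, 0, radius]])
    return Section(sec_id, "soma", pts, np.full(2, d), parent=None, chi=1.0)


def load_swc(path, nseg=None, max_seg_length=None, rho_a=150.0) -> SegmentTree:
    """Read a 7-column SWC file into a discretized segment tree.

    One section is built per contiguous run of same-type samples between
    branch points; the root must be the soma.  A 1-point or standard 3-point
    soma is collapsed to a single spherical-equivalent section (radius taken
    from the root sample).  Parent ids must reference earlier rows (or -1).
    """
    rows = {}
    order = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC row: {line!r}")
            rid = int(parts[0])
            typ = int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            r = float(parts[5])
            par = int(parts[6])
            if rid in rows:
                raise ValueError(f"duplicate SWC id {rid}")
            if par != -1 and par not in rows:
                raise ValueError(
                    f"SWC row {rid} references parent {par} that does not precede it")
            if par == rid:
                raise ValueError(f"SWC row {rid} is its own parent")
            rows[rid] = (typ, xyz, r, par)
            order.append(rid)
    if not rows:
        raise ValueError("empty SWC file")
    roots = [rid for rid in order if rows[rid][3] == -1]
    if len(roots) != 1:
        raise ValueError(f"SWC file must have exactly one root, got {len(roots)}")
    root = roots[0]
    if rows[root][0] != 1:
        raise ValueError("SWC root sample must be a soma (type 1)")

    children = {rid: [] for rid in order}
    for rid in order:
        par = rows[rid][3]
        if par != -1:
            children[par].append(rid)

    def label_of(rid):
        typ = rows[rid][0]
        if typ not in _SWC_TYPE_TO_LABEL:
            warnings.warn(f"unknown SWC type code {typ}; mapping to dend")
            return "dend"
        return _SWC_TYPE_TO_LABEL[typ]

    # soma: collapse 1- or 3-point somata to a spherical-equivalent section
    soma_ids = [rid for rid in order if rows[rid][0] == 1]
    sections = []
    sec_counter = 0
    soma_collapsed = len(soma_ids) in (1, 3) and root in soma_ids
    soma_center = rows[root][1]
    soma_radius = rows[root][2]
    if soma_collapsed:
        sections.append(_soma_equivalent_section(sec_counter, soma_center, soma_radius))
        soma_sec_id = sec_counter
        sec_counter += 1
        branch_starts = []
        for sid in soma_ids:
            for ch in children[sid]:
                if rows[ch][0] != 1:
                    branch_starts.append((ch, soma_sec_id, "soma"))
    else:
        raise ValueError(
            "only 1-point or 3-point somata are supported by this SWC dialect")

    # sample -> (section id, arc position within section) for chi recovery
    sample_loc = {}
    soma_sec = sections[0]

    stack = list(branch_starts)
    while stack:
        start_id, parent_sec, parent_kind = stack.pop()
        lab = label_of(start_id)
        pts = []
        sample_ids = []
        if parent_kind == "soma":
            pass  # soma children: polyline is the branch's own samples
        else:
            # prepend the parent sample so the cable starts at the branch point
            par_sample = rows[start_id][3]
            pts.append((rows[par_sample][1], 2.0 * rows[par_sample][2]))
        cur = start_id
        while True:
            pts.append((rows[cur][1], 2.0 * rows[cur][2]))
            sample_ids.append(cur)
            ch = children[cur]
            same = [c for c in ch if label_of(c) == lab and rows[c][0] != 1]
            if len(ch) == 1 and len(same) == 1:
                cur = same[0]
            else:
                break
        points = np.array([p for p, _d in pts])
        diams = np.array([d for _p, d in pts])
        if parent_kind == "soma":
            # recover attachment end from proximity to the soma poles
            p0 = points[0]
            d_lo = np.linalg.norm(p0 - soma_sec.points[0])
            d_hi = np.linalg.norm(p0 - soma_sec.points[-1])
            d_c = np.linalg.norm(p0 - soma_center)
            chi = [0.0, 1.0, 0.5][int(np.argmin([d_lo, d_hi, d_c]))]
        else:
            chi = sample_loc[rows[start_id][3]][1]
        sec = Section(sec_counter, lab, points, diams,
                      parent=parent_sec, chi=chi)
        sections.append(sec)
        arcs = sec.arc_lengths
        offset = len(pts) - len(sample_ids)
        for k, sid in enumerate(sample_ids):
            sample_loc[sid] = (sec.id, float(arcs[k + offset] / sec.length))
        sec_counter += 1
        # queue children that start new sections (any sample's child not
        # already consumed into this section's polyline)
        consumed = set(sample_ids)
        for sid in sample_ids:
            for c in children[sid]:
                if rows[c][0] == 1 or c in consumed:
                    continue
                stack.append((c, sec.id, "branch"))

    return discretize(sections, nseg=nseg, max_seg_length=max_seg_length, rho_a=rho_a)


def write_swc(tree: SegmentTree, path) -> None:
    """Write a segment tree's sections to standard 7-column SWC.

    The soma is emitted as a single spherical sample at its center; other
    sections as their polyline samples, with the first sample dropped when it
    coincides with a sample already written for the parent section.
    """
    sections = tree.sections
    if not sections:
        raise ValueError("tree carries no section polylines (not SWC-serializable)")
    by_id = {s.id: s for s in sections}
    lines = []
    next_id = 1
    sample_ids = {}  # (section id, point index) -> SWC id
    soma_swc = {}

    def fmt(v):
        return f"{v:.9g}"

    for sec in sections:
        if sec.parent is None:
            if sec.label != "soma":
                raise ValueError("root section must be the soma")
            center = 0.5 * (sec.points[0] + sec.points[-1])
            radius = float(sec.diams[0]) / 2.0
            lines.append(
                f"{next_id} 1 {fmt(center[0])} {fmt(center[1])} {fmt(center[2])} "
                f"{fmt(radius)} -1")
            soma_swc[sec.id] = next_id
            next_id += 1
            continue
        psec = by_id[sec.parent]
        if psec.parent is None:
            par_id = soma_swc[psec.id]
            start_k = 0
        else:
            # locate the parent sample coinciding with our first point
            par_id = None
            for k in range(len(psec.points)):
                if (psec.id, k) in sample_ids and \
                        np.linalg.norm(psec.points[k] - sec.points[0]) < 1e-6:
                    par_id = sample_ids[(psec.id, k)]
                    break
            if par_id is None:
                # fall back: nearest written parent sample, keep own first point
                cand = [(np.linalg.norm(psec.points[k] - sec.points[0]), k)
                        for k in range(len(psec.points)) if (psec.id, k) in sample_ids]
                par_id = sample_ids[(psec.id, min(cand)[1])]
                start_k = 0
            else:
                start_k = 1
        typ = _LABEL_TO_SWC_TYPE[sec.label]
        prev = par_id
        for k in range(start_k, len(sec.points)):
            p = sec.points[k]
            r = sec.diams[k] / 2.0
            lines.append(
                f"{next_id} {typ} {fmt(p[0])} {fmt(p[1])} {fmt(p[2])} {fmt(r)} {prev}")
            sample_ids[(sec.id, k)] = next_id
            prev = next_id
            next_id += 1
        if start_k == 1:
            sample_ids[(sec.id, 0)] = par_id

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fixtures

def make_ball_and_stick(soma_diam=20.0, stick_length=400.0, stick_diam=2.0,
                        nseg=8, rho_a=150.0) -> SegmentTree:
    """Spherical-equivalent soma with a single straight apical stick along +z."""
    if min(soma_diam, stick_length, stick_diam) <= 0:
        raise ValueError("dimensions must be positive")
    r = soma_diam / 2.0
    soma = Section(0, "soma",
                   np.array([[0.0, 0.0, -r], [0.0, 0.0, r]]),
                   np.full(2, soma_diam), parent=None, nseg=1)
    stick = Section(1, "apic",
                    np.array([[0.0, 0.0, r], [0.0, 0.0, r + stick_length]]),
                    np.full(2, stick_diam), parent=0, chi=1.0, nseg=int(nseg))
    return discretize([soma, stick], rho_a=rho_a)


def make_stylized_pyramidal(seed=0, rho_a=150.0) -> SegmentTree:
    """Stylized passive pyramidal cell fixture, entirely in the xz-plane.

    Soma at the origin, a 1000 um apical trunk with a bifurcating tuft, an
    oblique branch attached mid-trunk (chi = 0.5, exercising virtual axial
    currents), and two basal dendrites below the soma.  Branch angles carry a
    small seeded jitter; the same seed reproduces the identical morphology.
    """
    rng = np.random.default_rng(seed)
    jit = lambda: np.deg2rad(rng.uniform(-5.0, 5.0))

    def ray(origin, angle, length, n_pts=3):
        """Polyline from origin at `angle` (from +z toward +x) in the xz-plane."""
        direction = np.array([np.sin(angle), 0.0, np.cos(angle)])
        ts = np.linspace(0.0, length, n_pts)
        return origin + np.outer(ts, direction)

    soma = Section(0, "soma", np.array([[0, 0, -10.0], [0, 0, 10.0]]),
                   np.full(2, 20.0), parent=None, nseg=1)
    trunk = Section(1, "apic",
                    np.array([[0, 0, 10.0], [0, 0, 510.0], [0, 0, 1010.0]]),
                    np.full(3, 4.0), parent=0, chi=1.0, nseg=10)
    top = trunk.points[-1]
    tuft1 = Section(2, "apic", ray(top, np.deg2rad(40.0) + jit(), 250.0),
                    np.full(3, 2.0), parent=1, chi=1.0, nseg=5)
    tuft2 = Section(3, "apic", ray(top, np.deg2rad(-40.0) + jit(), 250.0),
                    np.full(3, 2.0), parent=1, chi=1.0, nseg=5)
    oblique = Section(4, "apic", ray(np.array([0, 0, 510.0]),
                                     np.deg2rad(95.0) + jit(), 200.0),
                      np.full(3, 2.0), parent=1, chi=0.5, nseg=4)
    basal1 = Section(5, "dend", ray(np.array([0, 0, -10.0]),
                                    np.deg2rad(140.0) + jit(), 300.0),
                     np.full(3, 2.5), parent=0, chi=0.0, nseg=5)
    basal2 = Section(6, "dend", ray(np.array([0, 0, -10.0]),
                                    np.deg2rad(-140.0) + jit(), 300.0),
                     np.full(3, 2.5), parent=0, chi=0.0, nseg=5)
    return discretize([soma, trunk, tuft1, tuft2, oblique, basal1, basal2],
                      rho_a=rho_a)
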