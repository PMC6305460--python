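"""Axial currents from membrane potentials.

Every electrical connection node of the segment tree generates one axial
current entry per half-path: the within-parent element (parent midpoint to
node) and one within-child element (node to child midpoint) per attached
child.  At branch nodes the node potential V_x is obtained from Kirchhoff's
current law over the parent and all children, sum_k (V_k - V_x)/R_k = 0.
For mid-section (chi) attachments the node potential is the parent segment
potential; the straight *virtual* element from the parent midpoint to the
child start point carries the child current, which makes the summed dipole
moment of the axial currents identical to the transmembrane-current dipole
moment.

Sign convention: positive I_a flows along the line element d_m, which points
from the electrically upstream node toward the downstream midpoint, so the
dipole of element m is simply I_a,m * d_m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import SegmentTree

__all__ = ["AxialCurrentSet", "axial_currents", "center_of_areas"]


@dataclass
class AxialCurrentSet:
    """Axial current magnitudes with their line elements and midpoints."""

    i_axial: np.ndarray    # (m_a, n_t) nA
    d_vectors: np.ndarray  # (m_a, 3) um
    r_mid: np.ndarray      # (m_a, 3) um

    @property
    def n_currents(self) -> int:
        return len(self.d_vectors)


def axial_currents(tree: SegmentTree, v_m: np.ndarray) -> AxialCurrentSet:
    """Compute all axial currents (including virtual ones) from V_m.

    ``v_m`` is (n_seg, n_t) in mV; currents come out in nA (resistances are
    in megaohm).  Gap elements are emitted when a child's start point does
    not coincide with the node position, so the summed dipole is exact for
    arbitrary geometry.
    """
    v_m = np.atleast_2d(np.asarray(v_m, dtype=float))
    if v_m.shape[0] != tree.n_segments:
        raise ValueError(
            f"v_m has {v_m.shape[0]} rows for {tree.n_segments} segments")

    currents, dvecs, rmids = [], [], []

    def emit(i_t, p0, p1):
        d = np.asarray(p1, float) - np.asarray(p0, float)
        if np.linalg.norm(d) <= 1e-12:
            return
        currents.append(i_t)
        dvecs.append(d)
        rmids.append(0.5 * (np.asarray(p0, float) + np.asarray(p1, float)))

    for node in tree.nodes:
        f = node.parent_seg
        if node.kind == "clamped":
            # node potential equals the parent segment potential; the
            # virtual element runs from the parent midpoint to child start
            for seg, res, cstart in node.children:
                if res <= 0:
                    raise ValueError("zero axial resistance")
                i = (v_m[f] - v_m[seg]) / res
                emit(i, tree.mid[f], cstart)          # virtual current
                emit(i, cstart, tree.mid[seg])        # within-child half
        else:
            if node.parent_res <= 0:
                raise ValueError("zero axial resistance")
            g = [1.0 / node.parent_res] + [1.0 / res for _s, res, _p in node.children]
            for _s, res, _p in node.children:
                if res <= 0:
                    raise ValueError("zero axial resistance")
            g = np.asarray(g)
            vstack = np.vstack([v_m[f]] + [v_m[seg] for seg, _r, _p in node.children])
            v_x = (g[:, None] * vstack).sum(axis=0) / g.sum()
            emit((v_m[f] - v_x) / node.parent_res, tree.mid[f], node.pos)
            for seg, res, cstart in node.children:
                i = (v_x - v_m[seg]) / res
                if np.linalg.norm(cstart - node.pos) > 1e-9:
                    emit(i, node.pos, cstart)         # geometric gap element
                emit(i, cstart, tree.mid[seg])

    if not currents:
        return AxialCurrentSet(np.zeros((0, v_m.shape[1])),
                               np.zeros((0, 3)), np.zeros((0, 3)))
    return AxialCurrentSet(np.vstack([np.atleast_2d(c) for c in currents]),
                           np.vstack(dvecs), np.vstack(rmids))


def center_of_areas(tree: SegmentTree) -> np.ndarray:
    """Membrane-area-weighted mean of segment midpoints (um)."""
    if np.any(tree.area <= 0):
        raise ValueError("segment areas must be positive")
    w = tree.area / tree.area.sum()
    return w @ tree.mid
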