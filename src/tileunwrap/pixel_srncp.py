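"""Pixel-based SRNCP phase unwrapper (Herráez-style), the comparison baseline.

SRNCP — "sorting by reliability following a non-continuous path" — unwraps at
pixel granularity.  Each interior pixel gets a reliability that is the
inverse of its wrapped second-difference magnitude

    mag = sqrt(H² + V² + D1² + D2²)

over the horizontal, vertical and two diagonal directions of its 3×3
neighborhood (each first difference wrapped before subtracting).  An edge
between adjacent pixels has reliability equal to the sum of its two pixels'
reliabilities.  Edges are processed in descending reliability; each edge
merges the two pixel groups it connects by adding the appropriate 2π multiple
to every pixel of the smaller group (weighted union-find).  Because the
processing order follows quality rather than spatial continuity, unreliable
regions are stitched in last and errors do not propagate along a scan path.

Border pixels lack a full 3×3 neighborhood and are assigned the minimal
reliability, so their edges are processed last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .phase_core import TWO_PI, PhaseMap, _values_of, _wrap

#: Guard for reliability inversion; border pixels get exactly this value.
RELIABILITY_EPS = 1e-12


def _pixel_reliability_values(v: np.ndarray) -> np.ndarray:
    """Per-pixel reliabilities; borders (and maps thinner than 3 pixels)
    receive the minimal guard value."""
    rel = np.full(v.shape, RELIABILITY_EPS)
    if v.shape[0] < 3 or v.shape[1] < 3:
        return rel
    c = v[1:-1, 1:-1]
    h = _wrap(v[1:-1, :-2] - c) - _wrap(c - v[1:-1, 2:])
    vv = _wrap(v[:-2, 1:-1] - c) - _wrap(c - v[2:, 1:-1])
    d1 = _wrap(v[:-2, :-2] - c) - _wrap(c - v[2:, 2:])
    d2 = _wrap(v[:-2, 2:] - c) - _wrap(c - v[2:, :-2])
    mag = np.sqrt(h * h + vv * vv + d1 * d1 + d2 * d2)
    rel[1:-1, 1:-1] = 1.0 / (mag + RELIABILITY_EPS)
    return rel


@dataclass(eq=False)
class PixelReliabilityMap:
    """Per-pixel and per-edge reliabilities of a wrapped map.

    ``horizontal_edges[i, j]`` joins pixels (i, j)–(i, j+1);
    ``vertical_edges[i, j]`` joins (i, j)–(i+1, j).  Edge reliability is the
    sum of the two pixel reliabilities.
    """

    pixel: np.ndarray
    horizontal_edges: np.ndarray
    vertical_edges: np.ndarray


def pixel_reliability(phase_map) -> PixelReliabilityMap:
    """Second-difference reliability map of a wrapped phase map (≥ 3×3)."""
    if isinstance(phase_map, PhaseMap) and not phase_map.wrapped:
        raise ValueError("pixel_reliability requires a wrapped phase map")
    v = _values_of(phase_map)
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise ValueError("pixel_reliability requires a map of at least 3x3 pixels")
    rel = _pixel_reliability_values(v)
    return PixelReliabilityMap(
        pixel=rel,
        horizontal_edges=rel[:, :-1] + rel[:, 1:],
        vertical_edges=rel[:-1, :] + rel[1:, :],
    )


@njit(cache=False)
def _find(parent, offset, x):
    root = x
    total = np.int64(0)
    while parent[root] != root:
        total += offset[root]
        root = parent[root]
    # path compression: point every node on the path at the root, storing its
    # full offset-to-root
    cur = x
    t = total
    while parent[cur] != root:
        nxt = parent[cur]
        step = offset[cur]
        parent[cur] = root
        offset[cur] = t
        t -= step
        cur = nxt
    return root, total


@njit(cache=False)
def _process_edges(vflat, edge_p, edge_q, order):
    n = vflat.size
    parent = np.arange(n)
    offset = np.zeros(n, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    two_pi = 2.0 * np.pi
    for ii in range(order.size):
        e = order[ii]
        p = edge_p[e]
        q = edge_q[e]
        rp, op = _find(parent, offset, p)
        rq, oq = _find(parent, offset, q)
        if rp == rq:
            continue
        d = (vflat[q] + two_pi * oq) - (vflat[p] + two_pi * op)
        x = d / two_pi
        k = np.int64(np.floor(abs(x) + 0.5))
        if x < 0.0:
            k = -k
        if size[rq] >= size[rp]:
            # shift p's group onto q's
            parent[rp] = rq
            offset[rp] = k
            size[rq] += size[rp]
        else:
            parent[rq] = rp
            offset[rq] = -k
            size[rp] += size[rq]
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        _, o = _find(parent, offset, i)
        out[i] = o
    return out


def srncp_unwrap(phase_map) -> np.ndarray:
    """Unwrap a wrapped phase map with the pixel-based SRNCP algorithm.

    Returns the unwrapped values; output − input is a pixelwise integer
    multiple of 2π.  Maps thinner than 3 pixels in either dimension are
    handled with all-border reliabilities, in which case the processing
    order degenerates to plain sequential (Itoh-like) merging.
    """
    if isinstance(phase_map, PhaseMap) and not phase_map.wrapped:
        raise ValueError("srncp_unwrap requires a wrapped phase map")
    v = _values_of(phase_map)
    h, w = v.shape
    rel = _pixel_reliability_values(v)

    idx = np.arange(h * w, dtype=np.int64).reshape(h, w)
    edge_p = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    edge_q = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    edge_rel = np.concatenate(
        [(rel[:, :-1] + rel[:, 1:]).ravel(), (rel[:-1, :] + rel[1:, :]).ravel()]
    )
    if edge_p.size == 0:
        return v.copy()
    order = np.argsort(-edge_rel, kind="stable")
    offsets = _process_edges(v.ravel(), edge_p, edge_q, order)
    return v + TWO_PI * offsets.reshape(h, w)
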