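"""Merging of individually unwrapped tiles into a continuous surface.

After tile unwrapping, adjacent tiles can differ by integer multiples of 2π.
A merger removes those jumps by adding 2π multiples to whole tiles, guided by
*junction* statistics: for edge-adjacent tiles τ_A, τ_B the junction J_AB is
the set of neighbor pixel pairs on their shared border, with differences
D(J_AB) = {P_B − P_A}, mean Δ and (population) variance V_J.  The 2π multiple
that aligns A to B is round(Δ / 2π).

Two mergers are implemented: a unidirectional column-wise pass (Strand), and
a reliability-guided merger (τSRNCP) that processes junctions in descending
reliability with group bookkeeping, so unreliable junctions — noise, failed
tile unwraps, residues — are resolved last and their errors stay contained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phase_core import TWO_PI, PhaseMap, Tessellation, Tile, add_tile_offset

#: Guard added to junction-variance means before inversion so that perfectly
#: continuous junctions get a large, finite reliability.
RELIABILITY_EPS = 1e-12


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (deterministic)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def junction_differences(tile_a: Tile, tile_b: Tile) -> np.ndarray:
    """Border differences D(J_AB), oriented B minus A, ordered along the border."""
    wa, ha = tile_a.grid_pos
    wb, hb = tile_b.grid_pos
    dw, dh = wb - wa, hb - ha
    if abs(dw) + abs(dh) != 1:
        raise ValueError(
            f"tiles {tile_a.grid_pos} and {tile_b.grid_pos} are not edge-adjacent"
        )
    a, b = tile_a.values, tile_b.values
    if dw == 1:  # B right of A
        return b[:, 0] - a[:, -1]
    if dw == -1:  # B left of A
        return b[:, -1] - a[:, 0]
    if dh == 1:  # B below A
        return b[0, :] - a[-1, :]
    return b[-1, :] - a[0, :]  # B above A


def junction_stats(differences) -> tuple[float, float]:
    """Mean Δ and population variance V_J of a junction difference set.

    Population variance (divide by |D|) keeps single-pixel junctions
    well-defined (V_J = 0); only the ordering of reliabilities matters.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("junction difference set must be non-empty")
    return float(d.mean()), float(d.var())


@dataclass(eq=False)
class Junction:
    """A junction between two adjacent tiles with its statistics."""

    tile_a: Tile
    tile_b: Tile
    differences: np.ndarray
    delta: float
    variance: float
    reliability: float = math.nan
    index: int = -1


def build_junction(tile_a: Tile, tile_b: Tile) -> Junction:
    d = junction_differences(tile_a, tile_b)
    delta, var = junction_stats(d)
    return Junction(tile_a, tile_b, d, delta, var)


def merge_pair(tile_a: Tile, tile_b: Tile) -> int:
    """Merge τ_A onto τ_B: add 2π·round(Δ/2π) to all pixels of τ_A.

    Returns the applied integer k; afterwards the recomputed |Δ| ≤ π.
    """
    delta, _ = junction_stats(junction_differences(tile_a, tile_b))
    k = _round_half_away(delta / TWO_PI)
    if k != 0:
        add_tile_offset(tile_a, k)
    return k


def _neighbors(tess: Tessellation, w: int, h: int):
    for dw, dh in ((0, -1), (0, 1), (-1, 0), (1, 0)):
        nw, nh = w + dw, h + dh
        if 0 <= nw < tess.n_tiles_w and 0 <= nh < tess.n_tiles_h:
            yield tess.tile(nw, nh)


def unidirectional_merge(tess: Tessellation) -> PhaseMap:
    """Column-wise merger: visit tiles left→right, top→bottom per column.

    Each tile's jump value is the nearest 2π multiple of the pooled mean of
    junction differences to its already-visited top and left neighbors (the
    pool concatenates both junctions' difference sets, weighting junctions by
    border length).
    """
    for w in range(tess.n_tiles_w):
        for h in range(tess.n_tiles_h):
            current = tess.tile(w, h)
            pooled = []
            if w > 0:
                pooled.append(junction_differences(current, tess.tile(w - 1, h)))
            if h > 0:
                pooled.append(junction_differences(current, tess.tile(w, h - 1)))
            if not pooled:
                continue
            delta = float(np.concatenate(pooled).mean())
            k = _round_half_away(delta / TWO_PI)
            if k != 0:
                add_tile_offset(current, k)
    tess.parent.wrapped = False
    return tess.parent


def tile_reliability(tile: Tile, tess: Tessellation) -> float:
    """R = 1 / (V + ε) with V the mean junction variance over the tile's
    2–4 existing junctions.  High R means the tile segues continuously into
    its neighbors (a constant 2π offset does not reduce R: the variance is
    offset-invariant)."""
    w, h = tile.grid_pos
    variances = [
        junction_stats(junction_differences(tile, nb))[1]
        for nb in _neighbors(tess, w, h)
    ]
    if not variances:
        raise ValueError("tile_reliability requires at least one junction")
    v = float(np.mean(variances))
    return 1.0 / (v + RELIABILITY_EPS)


def junction_reliability(junction: Junction, tess: Tessellation) -> float:
    """Product of the two adjoining tiles' reliabilities."""
    return tile_reliability(junction.tile_a, tess) * tile_reliability(junction.tile_b, tess)


def _enumerate_junctions(tess: Tessellation) -> list[Junction]:
    """All junctions in row-major tile order, right before down, indexed."""
    junctions = []
    for h in range(tess.n_tiles_h):
        for w in range(tess.n_tiles_w):
            tile = tess.tile(w, h)
            if w + 1 < tess.n_tiles_w:
                j = build_junction(tile, tess.tile(w + 1, h))
                j.index = len(junctions)
                junctions.append(j)
            if h + 1 < tess.n_tiles_h:
                j = build_junction(tile, tess.tile(w, h + 1))
                j.index = len(junctions)
                junctions.append(j)
    return junctions


def tsrncp_merge(tess: Tessellation) -> PhaseMap:
    """Reliability-guided tile merger (τSRNCP).

    All tile and junction reliabilities are computed once, up front (junction
    variances are invariant under the 2π offsets applied while merging).
    Junctions are then processed in descending reliability (ties broken by
    row-major junction index) with group bookkeeping:

    * neither tile grouped → merge A onto B, open a new group;
    * only B grouped → merge A onto B, A joins B's group;
    * only A grouped → merge B onto A, B joins A's group;
    * distinct groups → shift the smaller group wholesale by the 2π multiple
      from this junction and absorb it into the larger (tie: A's group is
      shifted);
    * same group → no action.
    """
    if tess.n_tiles == 1:
        tess.parent.wrapped = False
        return tess.parent

    tile_rel = {
        tile.grid_pos: tile_reliability(tile, tess) for tile in tess
    }
    junctions = _enumerate_junctions(tess)
    for j in junctions:
        j.reliability = tile_rel[j.tile_a.grid_pos] * tile_rel[j.tile_b.grid_pos]
    ordered = sorted(junctions, key=lambda j: (-j.reliability, j.index))

    group_of: dict = {}
    members: dict = {}
    next_gid = 0
    for j in ordered:
        a, b = j.tile_a, j.tile_b
        ga = group_of.get(a.grid_pos)
        gb = group_of.get(b.grid_pos)
        if ga is None and gb is None:
            merge_pair(a, b)
            group_of[a.grid_pos] = group_of[b.grid_pos] = next_gid
            members[next_gid] = [a, b]
            next_gid += 1
        elif ga is None:
            merge_pair(a, b)
            group_of[a.grid_pos] = gb
            members[gb].append(a)
        elif gb is None:
            merge_pair(b, a)
            group_of[b.grid_pos] = ga
            members[ga].append(b)
        elif ga != gb:
            delta, _ = junction_stats(junction_differences(a, b))
            k = _round_half_away(delta / TWO_PI)
            if len(members[ga]) <= len(members[gb]):
                shifted, absorbed_into, shift = ga, gb, k
            else:
                shifted, absorbed_into, shift = gb, ga, -k
            if shift != 0:
                for tile in members[shifted]:
                    add_tile_offset(tile, shift)
            for tile in members[shifted]:
                group_of[tile.grid_pos] = absorbed_into
            members[absorbed_into].extend(members.pop(shifted))
        # same group: junction already consistent by the group invariant

    tess.parent.wrapped = False
    return tess.parent


MERGERS = {
    "unidirectional": unidirectional_merge,
    "tsrncp": tsrncp_merge,
}
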