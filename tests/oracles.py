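"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: alignment
scores come from exhaustive enumeration of alignment paths, site matchings
from exhaustive search over injective assignments, and geometric quantities
from direct vector arithmetic.
"""

from __future__ import annotations

import math

import numpy as np


def affine_align_score_bruteforce(a, b, matrix, gap_open=10.0, gap_extend=0.5):
    """Optimal global affine-gap score by exhaustive path enumeration.

    A gap of length L costs gap_open + (L - 1) * gap_extend; switching gap
    strands opens a new gap. Only feasible for short sequences.
    """
    best = -math.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + float(matrix[a[i], b[j]]))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, "X", score - cost)
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, "Y", score - cost)

    rec(0, 0, None, 0.0)
    return best


def optimal_site_matching(q_pts, r_pts, cutoff):
    """Best injective pairing: max #pairs under cutoff, then min total distance.

    Exhaustive recursion; returns a frozenset of (query_index, ref_index).
    """
    q_pts = np.asarray(q_pts, float)
    r_pts = np.asarray(r_pts, float)
    nq = len(q_pts)
    best: dict = {"count": -1, "total": math.inf, "pairs": frozenset()}

    def rec(qi, used_r, pairs, total):
        if qi == nq:
            count = len(pairs)
            if count > best["count"] or (
                count == best["count"] and total < best["total"]
            ):
                best.update(count=count, total=total, pairs=frozenset(pairs))
            return
        rec(qi + 1, used_r, pairs, total)  # leave qi unmatched
        for ri in range(len(r_pts)):
            if ri in used_r:
                continue
            d = float(np.linalg.norm(q_pts[qi] - r_pts[ri]))
            if d <= cutoff:
                rec(qi + 1, used_r | {ri}, pairs + [(qi, ri)], total + d)

    rec(0, set(), [], 0.0)
    return best["pairs"]


def point_plane_rms(coords, normal, centroid):
    """Direct evaluation of rms point-plane distance."""
    coords = np.asarray(coords, float)
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    d = (coords - np.asarray(centroid, float)) @ n
    return float(np.sqrt(np.mean(d**2)))


def rotation_about_axis(axis, angle_deg):
    """Rodrigues rotation matrix (proper) about a unit axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(th) * k + (1 - math.cos(th)) * (k @ k)


def random_rotation(rng):
    """Uniform-ish random proper rotation via QR."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q
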