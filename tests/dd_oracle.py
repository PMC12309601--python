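"""Exact double-description enumeration of flux-cone extreme rays.

Independent oracle for the basic-pathway construction: enumerates the
extreme rays of {v ≥ 0 : S v = 0} in exact rational arithmetic by the
classical double-description method (impose one equality at a time on
the nonnegative orthant, combining positive/negative ray pairs and
keeping only rays whose active constraints have rank n − 1).
Deliberately brute force — correctness over speed.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import sympy


def _dot(row, v):
    return sum(a * b for a, b in zip(row, v))


def _normalize(ray: tuple[Fraction, ...]) -> tuple[Fraction, ...]:
    nz = [abs(x) for x in ray if x != 0]
    if not nz:
        return ray
    m = max(nz)
    return tuple(x / m for x in ray)


def _is_extreme(ray, processed_rows, n) -> bool:
    active = [list(r) for r in processed_rows]
    for i, x in enumerate(ray):
        if x == 0:
            e = [0] * n
            e[i] = 1
            active.append(e)
    return sympy.Matrix(active).rank() == n - 1


def extreme_rays(S) -> list[tuple[Fraction, ...]]:
    """All extreme rays of {v >= 0 : S v = 0}, max-normalized."""
    S = [[Fraction(int(x)) for x in row] for row in np.asarray(S, dtype=int)]
    n = len(S[0])
    rays: list[tuple[Fraction, ...]] = []
    for i in range(n):
        e = [Fraction(0)] * n
        e[i] = Fraction(1)
        rays.append(tuple(e))
    processed: list[list[Fraction]] = []
    for row in S:
        vals = [_dot(row, r) for r in rays]
        keep = [r for r, v in zip(rays, vals) if v == 0]
        pos = [(r, v) for r, v in zip(rays, vals) if v > 0]
        neg = [(r, v) for r, v in zip(rays, vals) if v < 0]
        processed.append(row)
        candidates = {_normalize(r) for r in keep}
        for rp, vp in pos:
            for rm, vm in neg:
                comb = tuple(vp * b - vm * a for a, b in zip(rp, rm))
                if _is_extreme(comb, processed, n):
                    candidates.add(_normalize(comb))
        rays = sorted(candidates)
    return rays


def in_cone(v, rays, tol: float = 1e-8) -> bool:
    """Is v a nonnegative combination of the given rays? (NNLS check)"""
    from scipy.optimize import nnls

    A = np.array(rays, dtype=float).T
    b = np.asarray(v, dtype=float)
    scale = max(np.abs(b).max(), 1.0)
    _, resid = nnls(A, b)
    return resid <= tol * scale
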