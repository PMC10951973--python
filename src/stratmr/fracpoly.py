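"""Fractional-polynomial basis utilities.

The standard FP power family is {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, with 0
denoting the natural log.  A repeated power p contributes x^p and
x^p * ln(x).  Powers other than positive integers require x > 0, so an
additive offset (default 1 g/day) is applied before transformation to
accommodate zero exposure; the offset is part of the fitted model and is
recorded with it.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np

FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def _xp(x: np.ndarray, p: float) -> np.ndarray:
    if p == 0.0:
        return np.log(x)
    return x ** p


def fp_basis(x: np.ndarray, powers: tuple[float, ...], offset: float = 1.0
             ) -> np.ndarray:
    """Columns of the FP basis evaluated at ``x`` (no intercept).

    ``x + offset`` must be strictly positive.
    """
    u = np.asarray(x, float) + offset
    if np.any(u <= 0.0):
        raise ValueError(f"x + offset must be > 0 (offset={offset})")
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        k = seen.get(p, 0)
        base = _xp(u, p)
        if k == 0:
            cols.append(base)
        else:
            cols.append(base * np.log(u) ** k)
        seen[p] = k + 1
    return np.column_stack(cols)


def candidate_powers(degree: int,
                     family: tuple[float, ...] = FP_POWERS
                     ) -> list[tuple[float, ...]]:
    """All power multisets of the given degree from the family."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    return [tuple(c) for c in combinations_with_replacement(sorted(family), degree)]


def fp_antiderivative(u: np.ndarray, p: float) -> np.ndarray:
    """Antiderivative of the basis term u^p (u = x + offset), with 0 = ln u."""
    u = np.asarray(u, float)
    if p == 0.0:
        return u * np.log(u) - u
    if p == -1.0:
        return np.log(u)
    return u ** (p + 1.0) / (p + 1.0)
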