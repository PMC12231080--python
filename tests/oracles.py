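"""Independent brute-force oracles used to cross-check the implementation."""

from math import comb

import numpy as np


def brute_force_max_spread(patch_pixels, boundary_pixels, pixel_size,
                           seed_point=None, origin_x=0.0, origin_y=0.0):
    """All-pairs maximum of per-pixel minimum distance to the seed set.

    Continuous patches: seed set = shared-boundary pixel centers.
    Discontinuous patches: a single seed point.
    """
    rows, cols = patch_pixels
    px = origin_x + (np.asarray(cols) + 0.5) * pixel_size
    py = origin_y - (np.asarray(rows) + 0.5) * pixel_size
    if seed_point is not None:
        d = np.hypot(px - seed_point[0], py - seed_point[1])
        return float(d.max())
    brows, bcols = boundary_pixels
    bx = origin_x + (np.asarray(bcols) + 0.5) * pixel_size
    by = origin_y - (np.asarray(brows) + 0.5) * pixel_size
    best = np.full(px.size, np.inf)
    for x0, y0 in zip(bx, by):
        best = np.minimum(best, np.hypot(px - x0, py - y0))
    return float(best.max())


def exact_two_sided_binomial_p(k, n):
    """Minimum-likelihood two-sided exact binomial p at p0 = 0.5.

    Computed with integer arithmetic (all pmf values are c / 2^n with
    integer c), so the result is exact to float rounding.
    """
    c_obs = comb(n, k)
    total = sum(comb(n, i) for i in range(n + 1) if comb(n, i) <= c_obs)
    return min(1.0, total / 2 ** n)
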