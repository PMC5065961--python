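"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the forward plume
simulator works on a flat meter plane with its own stepping loop, and the
rank-sum oracle enumerates the exact null distribution by brute force.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def forward_residence_at_receptor(rng, n_particles, source_cell_center_m,
                                  cell_m, receptor_m, kh, dt, n_steps,
                                  domain_m):
    """Forward Monte-Carlo estimate of a backward run's source sensitivity.

    Releases particles uniformly inside the source cell at time zero on a
    flat 2-D plane, random-walks them with reflecting walls, and accumulates
    ``dt`` whenever a particle sits inside the receptor's grid cell. Returns
    expected seconds of receptor-cell occupancy per released particle, which
    (for equal source/receptor cell areas, zero wind) equals the backward
    model's expected residence time in the source cell per particle.
    """
    sx, sy = source_cell_center_m
    rx, ry = receptor_m
    (x_lo, x_hi), (y_lo, y_hi) = domain_m
    x = sx + rng.uniform(-cell_m / 2, cell_m / 2, size=n_particles)
    y = sy + rng.uniform(-cell_m / 2, cell_m / 2, size=n_particles)
    sig = np.sqrt(2.0 * kh * dt)
    occupancy = 0.0

    def reflect(p, lo, hi):
        span = hi - lo
        q = np.mod(p - lo, 2 * span)
        return lo + np.where(q > span, 2 * span - q, q)

    for _ in range(n_steps):
        x = reflect(x + rng.normal(0, sig, n_particles), x_lo, x_hi)
        y = reflect(y + rng.normal(0, sig, n_particles), y_lo, y_hi)
        inside = (np.abs(x - rx) <= cell_m / 2) & (np.abs(y - ry) <= cell_m / 2)
        occupancy += inside.sum() * dt
    return occupancy / n_particles


def exact_ranksum_two_sided_p(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = np.sort(np.concatenate([x, y]))
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    mean = n1 * (len(pooled) + 1) / 2.0
    obs_dev = abs(obs - mean)
    count = 0
    total = comb(len(pooled), n1)
    all_ranks = list(range(1, len(pooled) + 1))
    for c in combinations(all_ranks, n1):
        if abs(sum(c) - mean) >= obs_dev - 1e-12:
            count += 1
    return count / total
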