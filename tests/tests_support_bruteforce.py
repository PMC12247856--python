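"""Shared brute-force oracles used by the test suite (not package code)."""

import numpy as np


def brute_force_depths(agg, nuc, spacing):
    """Direct per-voxel nearest-outside search; oracle for inside_depths."""
    dz, dy, dx = spacing
    inside = agg & nuc
    if not inside.any():
        return 0.0, 0.0
    out = ~nuc
    lat_best = ax_best = 0.0
    for z, y, x in np.argwhere(inside):
        oy, ox = np.nonzero(out[z])
        lat = np.sqrt(((oy - y) * dy) ** 2 + ((ox - x) * dx) ** 2).min()
        oz = np.nonzero(out[:, y, x])[0]
        ax = (np.abs(oz - z) * dz).min()
        lat_best = max(lat_best, lat)
        ax_best = max(ax_best, ax)
    return float(lat_best), float(ax_best)
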