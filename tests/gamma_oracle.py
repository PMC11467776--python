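"""Exhaustive brute-force γ oracle, independent of the package route.

Searches every candidate point of the interpolation lattice within the
radius using scipy's RegularGridInterpolator, one reference voxel at a time.
Shared by the unit and acceptance suites.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def brute_force_gamma(reference, evaluated, spacing, criteria, radius, step):
    ny, nx = reference.shape
    d_max = reference.max()
    tol = criteria.dose_tolerance / 100.0 * d_max
    interp = RegularGridInterpolator(
        (np.arange(ny) * spacing[0], np.arange(nx) * spacing[1]),
        evaluated, bounds_error=False, fill_value=np.nan,
    )
    k = int(np.floor(radius / step + 1e-9))
    offs = np.arange(-k, k + 1) * step
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    r2 = dy**2 + dx**2
    keep = r2 <= radius**2 + 1e-12
    dy, dx, r2 = dy[keep], dx[keep], r2[keep]
    gamma = np.full(reference.shape, np.nan)
    for iy in range(ny):
        for ix in range(nx):
            if reference[iy, ix] < criteria.threshold / 100.0 * d_max:
                continue
            ev = interp(
                np.column_stack([iy * spacing[0] + dy, ix * spacing[1] + dx])
            )
            g2 = (reference[iy, ix] - ev) ** 2 / tol**2 + r2 / criteria.dta**2
            gamma[iy, ix] = np.sqrt(np.nanmin(g2))
    return gamma
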