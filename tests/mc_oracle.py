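"""Isotropic random-walk Monte Carlo oracle for layered diffuse reflectance.

Independent cross-check of the layered diffusion solution: photons take
exponentially distributed steps of mean 1/musp (similarity-scaled
isotropic scattering), absorption is scored continuously via path-length
weights per layer, and photons crossing the surface (z < 0, matched
boundary: no internal reflection) are binned by exit radius and total
time of flight.  Used only by the test suite.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _run(n_photons, mua1, mua2, musp, L, v, rho_min, rho_max,
         bin_width, n_bins, seed):
    np.random.seed(seed)
    counts = np.zeros(n_bins)
    sq = np.zeros(n_bins)  # sum of squared weights, for the variance
    t_max = bin_width * n_bins
    path_max = v * t_max
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 1e-9  # just below the surface, heading down
        ux, uy, uz = 0.0, 0.0, 1.0
        l1 = 0.0  # path length in layer 1
        l2 = 0.0
        alive = True
        while alive:
            step = -np.log(np.random.random()) / musp
            nx = x + ux * step
            ny = y + uy * step
            nz = z + uz * step
            # split the segment at the interface z = L
            if (z - L) * (nz - L) < 0.0:
                frac = (L - z) / (nz - z)
                seg1 = step * frac if z < L else step * (1.0 - frac)
                seg2 = step - seg1
                if z < L:
                    d1, d2 = seg1, seg2
                else:
                    d1, d2 = seg2, seg1
            elif z < L:
                d1, d2 = step, 0.0
            else:
                d1, d2 = 0.0, step
            if nz < 0.0:
                # escaped: clip the segment at the surface
                frac = z / (z - nz)
                cut = step * frac
                # the escaping segment starts in layer 1 (z < L always here)
                d1 = d1 - (step - cut)
                if d1 < 0.0:
                    d1 = 0.0
                ex = x + ux * cut
                ey = y + uy * cut
                r = np.sqrt(ex * ex + ey * ey)
                t = (l1 + d1 + l2) / v
                if rho_min <= r <= rho_max and t < t_max:
                    w = np.exp(-mua1 * (l1 + d1) - mua2 * l2)
                    idx = int(t / bin_width)
                    counts[idx] += w
                    sq[idx] += w * w
                alive = False
            else:
                l1 += d1
                l2 += d2
                if (l1 + l2) > path_max:
                    alive = False
                else:
                    x, y, z = nx, ny, nz
                    # isotropic re-direction
                    uz = 2.0 * np.random.random() - 1.0
                    phi = 2.0 * np.pi * np.random.random()
                    sin_t = np.sqrt(1.0 - uz * uz)
                    ux = sin_t * np.cos(phi)
                    uy = sin_t * np.sin(phi)
    return counts, sq


def mc_reflectance(
    n_photons: int,
    mua_sup: float,
    mua_deep: float,
    musp: float,
    L: float,
    v: float,
    rho_band: tuple[float, float],
    bin_width: float,
    n_bins: int,
    seed: int = 12345,
):
    """Binned time-resolved reflectance in an annular detector.

    Returns (R, sigma): photons per mm^2 per ps escaping with exit radius
    inside ``rho_band``, normalized per launched photon, and the
    per-bin statistical standard error.
    """
    counts, sq = _run(
        int(n_photons), mua_sup, mua_deep, musp, L, v,
        rho_band[0], rho_band[1], bin_width, int(n_bins), seed,
    )
    area = np.pi * (rho_band[1] ** 2 - rho_band[0] ** 2)
    norm = n_photons * area * bin_width
    return counts / norm, np.sqrt(sq) / norm
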