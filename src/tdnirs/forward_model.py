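"""Time-domain diffuse reflectance of homogeneous and layered media.

Implements the diffusion-equation Green's function for a semi-infinite
turbid medium under extrapolated boundary conditions, both for a
homogeneous medium (closed form in the time domain) and for an N-layered
medium (frequency-domain solution over radial spatial frequency, inverted
to the time domain with an FFT).  Model curves can be convolved with a
measured or synthetic instrument response function (IRF).

Conventions
-----------
* z = 0 at the surface, z increasing with depth; the last layer is
  semi-infinite.
* Diffusion coefficient D = 1/(3 mu_s') (absorption-independent).
* Isotropic point source at depth z0 = 1/mu_s' of the top layer; the
  extrapolated ("zero fluence") plane sits at z = -zb with zb = 2 A D,
  where A accounts for internal reflection at the refractive-index
  mismatch.
* Reflectance is the outward diffuse flux D dPhi/dz at z = 0.
* Internal units: mm and ps; optical coefficients in mm^-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.fft import irfft, next_fast_len
from scipy.special import j0

from .exceptions import (
    IncompatibleGridError,
    InvalidParameterError,
    NumericalFailureError,
)
from .units import speed_in_medium

logger = logging.getLogger(__name__)

__all__ = [
    "TimeGrid",
    "OpticalLayer",
    "LayeredMedium",
    "ModelCurve",
    "boundary_factor",
    "homogeneous_reflectance",
    "layered_reflectance",
    "convolve_irf",
    "TwoLayerEngine",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis of a TCSPC histogram.

    Parameters
    ----------
    bin_width : float
        Channel width in ps.
    n_bins : int
        Number of channels.
    t0 : float
        Time of the first bin center relative to the source pulse (ps).
    """

    bin_width: float
    n_bins: int
    t0: float = 0.0

    def __post_init__(self):
        if not (self.bin_width > 0):
            raise InvalidParameterError("bin_width must be positive")
        if self.n_bins < 1:
            raise InvalidParameterError("n_bins must be >= 1")

    @property
    def times(self) -> np.ndarray:
        """Bin-center times (ps)."""
        return self.t0 + self.bin_width * np.arange(self.n_bins)

    @property
    def span(self) -> float:
        return self.bin_width * self.n_bins

    def compatible_with(self, other: "TimeGrid", rtol: float = 1e-9) -> bool:
        return abs(self.bin_width - other.bin_width) <= rtol * self.bin_width


@dataclass(frozen=True)
class OpticalLayer:
    """One layer of a turbid medium.

    mua, musp in mm^-1; thickness in mm (``None`` for the semi-infinite
    last layer); n is the refractive index.
    """

    mua: float
    musp: float
    thickness: float | None = None
    n: float = 1.33

    def __post_init__(self):
        if not np.isfinite(self.mua) or self.mua < 0:
            raise InvalidParameterError(f"mua must be finite and >= 0, got {self.mua}")
        if not np.isfinite(self.musp) or self.musp <= 0:
            raise InvalidParameterError(f"musp must be finite and > 0, got {self.musp}")
        if self.thickness is not None and not self.thickness > 0:
            raise InvalidParameterError("layer thickness must be > 0")
        if self.n < 1:
            raise InvalidParameterError("refractive index must be >= 1")


@dataclass(frozen=True)
class LayeredMedium:
    """Ordered stack of :class:`OpticalLayer` from the surface downward."""

    layers: tuple[OpticalLayer, ...]
    n_exterior: float = 1.0

    def __post_init__(self):
        if len(self.layers) < 1:
            raise InvalidParameterError("a medium needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        for lay in self.layers[:-1]:
            if lay.thickness is None:
                raise InvalidParameterError(
                    "all layers above the last need a finite thickness"
                )
        ns = {lay.n for lay in self.layers}
        if len(ns) > 1:
            warnings.warn(
                "layers have different refractive indices; the solver assumes "
                "a single n and uses the top layer's value",
                stacklevel=2,
            )

    @property
    def n(self) -> float:
        return self.layers[0].n


@dataclass(frozen=True)
class ModelCurve:
    """Model reflectance sampled at the bin centers of ``grid``."""

    values: np.ndarray
    grid: TimeGrid
    rho: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise NumericalFailureError("model curve contains non-finite values")
        if np.any(v < 0):
            raise NumericalFailureError("model curve contains negative values")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# Boundary reflection
# ---------------------------------------------------------------------------

def boundary_factor(n: float, n_exterior: float = 1.0) -> float:
    """Internal-reflection factor A for the extrapolated boundary.

    Uses the polynomial fit of the diffuse reflection coefficient r_d as a
    function of the relative refractive index (Groenhuis et al.),
    A = (1 + r_d)/(1 - r_d).  For a matched boundary A is close to 1.
    """
    n_rel = n / n_exterior
    if n_rel < 1:
        # index-matched or inverted mismatch: fall back to the matched value
        return 1.0
    r_d = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_d) / (1.0 - r_d)


# ---------------------------------------------------------------------------
# Homogeneous semi-infinite medium, closed form
# ---------------------------------------------------------------------------

def homogeneous_reflectance(
    mua: float,
    musp: float,
    n: float,
    n_exterior: float,
    rho: float,
    grid: TimeGrid,
) -> ModelCurve:
    """Time-domain reflectance of a homogeneous semi-infinite medium.

    Image-source solution with extrapolated boundary: a positive source at
    z0 = 1/musp and a negative image mirrored about z = -zb.  The outward
    flux at the surface is

        R(rho, t) = (4 pi D v)^(-3/2) t^(-5/2)
                    exp(-mua v t - rho^2/(4 D v t)) * 1/2 *
                    [ z0 exp(-z0^2/(4Dvt)) + (z0+2zb) exp(-(z0+2zb)^2/(4Dvt)) ]

    Zero for t <= 0.  Amplitude units are arbitrary but consistent.
    """
    if not np.isfinite(mua) or mua < 0:
        raise InvalidParameterError(f"mua must be finite and >= 0, got {mua}")
    if not np.isfinite(musp) or musp <= 0:
        raise InvalidParameterError(f"musp must be finite and > 0, got {musp}")
    if not rho > 0:
        raise InvalidParameterError("rho must be > 0")

    v = speed_in_medium(n)
    D = 1.0 / (3.0 * musp)
    z0 = 1.0 / musp
    zb = 2.0 * boundary_factor(n, n_exterior) * D

    t = grid.times
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    four_dvt = 4.0 * D * v * tp
    pref = (4.0 * np.pi * D * v) ** -1.5 * tp**-2.5
    common = np.exp(-mua * v * tp - rho**2 / four_dvt)
    z1 = z0
    z2 = z0 + 2.0 * zb
    bracket = 0.5 * (
        z1 * np.exp(-(z1**2) / four_dvt) + z2 * np.exp(-(z2**2) / four_dvt)
    )
    out[pos] = pref * common * bracket
    return ModelCurve(values=out, grid=grid, rho=rho)


# ---------------------------------------------------------------------------
# Layered medium: frequency-domain solution + FFT inversion
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _quadrature(s_max: float, n_nodes: int, rho: float):
    """Gauss-Legendre nodes on [0, s_max] and combined Hankel weights
    w_i s_i J0(s_i rho) / (2 pi)."""
    x, w = leggauss(n_nodes)
    s = 0.5 * s_max * (x + 1.0)
    w = 0.5 * s_max * w
    return s, (w * s * j0(s * rho)) / (2.0 * np.pi)


class TwoLayerEngine:
    """Fast evaluator of layered time-domain reflectance for varying mua.

    Geometry (musp per layer, thicknesses, n, rho, grid) is fixed at
    construction; per-layer absorption varies per call.  The top layer's
    transcendental terms are cached so that sweeps over the deep layer's
    mua (chi^2 landscapes, LM iterations) reuse them.

    Numerical route: the layered flux in the (radial spatial frequency,
    temporal frequency) domain is split as

        flux = flux_top + front * (1 - beta) * (EC - E2b) / Dm

    where ``flux_top`` is the flux of a homogeneous medium with the top
    layer's properties (known in closed form in the time domain) and the
    remainder -- the influence of the deeper layers -- decays like
    exp(-s (2 L - z0)), i.e. much faster than the full integrand's
    exp(-s z0).  Only the remainder goes through Gauss-Legendre Hankel
    quadrature and an inverse real FFT (on a grid at least ``pad_factor``
    times the requested window); this avoids the heavy oscillatory
    cancellation of the direct integral, and the equal-layer limit is
    exact by construction.
    """

    #: spectrum truncated where its magnitude falls below this fraction of peak
    SPECTRUM_FLOOR = 1e-12
    #: negative FFT ringing beyond this fraction of peak raises an error
    RINGING_LIMIT = 1e-4

    def __init__(
        self,
        musps: tuple[float, ...],
        thicknesses: tuple[float, ...],
        n: float,
        n_exterior: float,
        rho: float,
        grid: TimeGrid,
        pad_factor: int = 4,
        n_quad: int | None = None,
    ):
        if not rho > 0:
            raise InvalidParameterError("rho must be > 0")
        if len(musps) < 2:
            raise InvalidParameterError("engine requires at least two layers")
        if len(thicknesses) != len(musps) - 1:
            raise InvalidParameterError(
                "need one thickness per layer above the semi-infinite one"
            )
        self.musps = tuple(float(m) for m in musps)
        self.thicknesses = tuple(float(t) for t in thicknesses)
        self.n = float(n)
        self.rho = float(rho)
        self.grid = grid
        self.v = speed_in_medium(n)
        self.D = tuple(1.0 / (3.0 * m) for m in self.musps)
        self.z0 = 1.0 / self.musps[0]
        if self.z0 >= self.thicknesses[0]:
            raise InvalidParameterError(
                "top layer thinner than one transport mean free path; the "
                "diffusion dipole source would sit below the first interface"
            )
        self._n_exterior = float(n_exterior)
        self.zb = 2.0 * boundary_factor(n, n_exterior) * self.D[0]

        # temporal-frequency grid: window >= pad_factor x requested span
        self.n_t = next_fast_len(pad_factor * grid.n_bins)
        self.dt = grid.bin_width
        T = self.n_t * self.dt
        d_omega = 2.0 * np.pi / T
        n_rfft = self.n_t // 2 + 1
        # The perturbation spectrum decays like exp(-rho sqrt(omega/(2 D v)));
        # keep frequencies down to ~1e-13 of DC and zero the rest.
        omega_cut = 2.0 * self.D[0] * self.v * (32.0 / rho) ** 2
        self.m_cut = int(min(n_rfft, max(64, np.ceil(omega_cut / d_omega))))
        self.n_rfft = n_rfft
        omega = d_omega * np.arange(self.m_cut)

        # radial spatial frequency: the perturbation integrand decays like
        # exp(-s (2 L - z0)), set by the shortest path to depth L and back
        decay_scale = 2.0 * self.thicknesses[0] - self.z0
        s_max = 35.0 / decay_scale
        if n_quad is None:
            n_quad = max(128, int(0.75 * s_max * rho) + 32)
        self.s, self.w_hankel = _quadrature(s_max, n_quad, rho)

        # mua-independent part of alpha_k^2 = s^2 + (mua_k + i omega/v)/D_k
        i_omega_v = 1j * omega / self.v
        self._P = [
            self.s[None, :] ** 2 + i_omega_v[:, None] / Dk for Dk in self.D
        ]
        self._phase = (
            np.exp(1j * omega * grid.t0) if grid.t0 != 0.0 else None
        )
        self._top_cache: tuple[float, tuple] | None = None

    # -- layer-1 terms ------------------------------------------------------

    def _top_terms(self, mua_sup: float):
        if self._top_cache is not None and self._top_cache[0] == mua_sup:
            return self._top_cache[1]
        a1 = np.sqrt(self._P[0] + mua_sup / self.D[0])
        L = self.thicknesses[0]
        ea = np.exp(-a1 * self.z0)        # e^{-a1 z0}
        eh = np.exp(-a1 * self.zb)        # e^{-a1 zb}
        ec = np.exp(-2.0 * a1 * (L - self.z0))
        front = 0.5 * ea * (1.0 + eh * eh)
        e2b = ec * (ea * eh) ** 2         # e^{-2 a1 (L + zb)}
        d1a1 = self.D[0] * a1
        terms = (d1a1, front, ec, e2b)
        self._top_cache = (mua_sup, terms)
        return terms

    # -- admittance of the stack below the first interface ------------------

    def _lower_admittance(self, muas_below: tuple[float, ...]):
        """Effective D*alpha looking down from the bottom of layer 1."""
        k_last = len(self.musps) - 1
        a = np.sqrt(self._P[k_last] + muas_below[-1] / self.D[k_last])
        Z = self.D[k_last] * a
        for k in range(k_last - 1, 0, -1):
            ak = np.sqrt(self._P[k] + muas_below[k - 1] / self.D[k])
            Dk_ak = self.D[k] * ak
            th = np.tanh(ak * self.thicknesses[k])
            Z = Dk_ak * (Z + Dk_ak * th) / (Dk_ak + Z * th)
        return Z

    # -- public evaluation --------------------------------------------------

    def perturbation_spectrum(self, muas: tuple[float, ...]) -> np.ndarray:
        """Spectrum of (layered - top-layer-homogeneous) reflectance."""
        if len(muas) != len(self.musps):
            raise InvalidParameterError("one mua per layer required")
        for m in muas:
            if not np.isfinite(m) or m < 0:
                raise InvalidParameterError(f"mua must be finite and >= 0, got {m}")
        d1a1, front, ec, e2b = self._top_terms(muas[0])
        beta = self._lower_admittance(tuple(muas[1:])) / d1a1
        one_m = 1.0 - beta
        flux_delta = front * one_m * (ec - e2b) / ((1.0 + beta) + e2b * one_m)
        return flux_delta @ self.w_hankel

    def curve(self, muas: tuple[float, ...]) -> ModelCurve:
        """Time-domain reflectance at the grid's bin centers."""
        delta = self._to_time(self.perturbation_spectrum(muas))
        top = homogeneous_reflectance(
            muas[0], self.musps[0], self.n, self._n_exterior, self.rho, self.grid
        )
        values = top.values + delta
        if not np.all(np.isfinite(values)):
            raise NumericalFailureError(
                "FFT inversion of the layered solution returned non-finite values"
            )
        peak = values.max()
        if peak <= 0:
            raise NumericalFailureError("layered solution is non-positive everywhere")
        worst = -min(values.min(), 0.0)
        if worst > self.RINGING_LIMIT * peak:
            raise NumericalFailureError(
                f"negative ringing {worst / peak:.2e} of peak exceeds "
                f"{self.RINGING_LIMIT:.0e}"
            )
        if worst > 0:
            logger.debug("clipped negative ringing of %.2e of peak", worst / peak)
        return ModelCurve(
            values=np.clip(values, 0.0, None), grid=self.grid, rho=self.rho
        )

    def _to_time(self, spec: np.ndarray) -> np.ndarray:
        """Invert a truncated rfft spectrum to bin-center time samples."""
        spec = spec.copy()
        floor = self.SPECTRUM_FLOOR * np.max(np.abs(spec), initial=0.0)
        spec[np.abs(spec) < floor] = 0.0
        if self._phase is not None:
            spec = spec * self._phase
        full = np.zeros(self.n_rfft, dtype=complex)
        full[: self.m_cut] = spec
        return irfft(full, n=self.n_t)[: self.grid.n_bins] / self.dt


@lru_cache(maxsize=16)
def _cached_engine(musps, thicknesses, n, n_exterior, rho, grid):
    return TwoLayerEngine(musps, thicknesses, n, n_exterior, rho, grid)


def layered_reflectance(medium: LayeredMedium, rho: float, grid: TimeGrid) -> ModelCurve:
    """Time-domain reflectance of an N-layered semi-infinite medium.

    N = 1 routes to :func:`homogeneous_reflectance`.  For N >= 2 the
    frequency-domain layered Green's function is inverted with an FFT;
    see :class:`TwoLayerEngine` for the numerical route.
    """
    layers = medium.layers
    if len(layers) == 1:
        return homogeneous_reflectance(
            layers[0].mua, layers[0].musp, medium.n, medium.n_exterior, rho, grid
        )
    engine = _cached_engine(
        tuple(l.musp for l in layers),
        tuple(l.thickness for l in layers[:-1]),
        medium.n,
        medium.n_exterior,
        float(rho),
        grid,
    )
    return engine.curve(tuple(l.mua for l in layers))


# ---------------------------------------------------------------------------
# IRF convolution
# ---------------------------------------------------------------------------

def convolve_irf(model: ModelCurve, irf) -> "DTOF":  # noqa: F821
    """Convolve a model curve with an instrument response function.

    The IRF is normalized to unit area, the discrete linear convolution is
    truncated to the model grid length, so the output total counts are
    proportional to the model curve's area.
    """
    from .moments import DTOF  # local import to avoid a cycle

    if not model.grid.compatible_with(irf.grid):
        raise IncompatibleGridError(
            f"model bin width {model.grid.bin_width} ps != "
            f"IRF bin width {irf.grid.bin_width} ps"
        )
    irf_counts = np.asarray(irf.counts, dtype=float)
    total = irf_counts.sum()
    if total <= 0:
        raise InvalidParameterError("IRF has non-positive total counts")
    out = np.convolve(model.values, irf_counts / total)[: model.grid.n_bins]
    return DTOF(counts=out, grid=model.grid)
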