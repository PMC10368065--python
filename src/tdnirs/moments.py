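"""Statistical moments of photon time-of-flight distributions (DTOFs).

A DTOF is a histogram of photon counts per TCSPC time channel.  Its first
statistical moments -- total counts N_tot (and attenuation A = -ln N_tot),
mean time of flight m1, variance V, and the higher central moments m3C and
m4C -- are the measurands of the moments-based layered-absorption method:
changes of A, m1 and V between a baseline and a perturbed state carry
depth-resolved information about absorption changes, and the photon-noise
(Poisson) uncertainties of those changes follow from higher-order moments
of the baseline histogram.

All moments are computed over a fixed channel range selected on the
baseline DTOF (by default from 25% of the peak on the rising edge to 3% on
the tail) and the same range is reused for every subsequent measured or
simulated DTOF, which makes changes in moments insensitive to the exact
range choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyInputError, InvalidParameterError
from .forward_model import TimeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "DTOF",
    "ChannelRange",
    "MomentSet",
    "MomentChanges",
    "MomentNoise",
    "select_range",
    "compute_moments",
    "deconvolve_irf_moments",
    "moment_changes",
    "photon_noise",
]


@dataclass(frozen=True)
class DTOF:
    """Histogram of photon counts per time channel.

    ``counts`` may be real-valued (after background subtraction);
    ``background`` records the per-bin offset already removed.
    """

    counts: np.ndarray
    grid: TimeGrid
    background: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1:
            raise InvalidParameterError("counts must be one-dimensional")
        if len(c) != self.grid.n_bins:
            raise InvalidParameterError(
                f"counts length {len(c)} != grid n_bins {self.grid.n_bins}"
            )
        if not np.all(np.isfinite(c)):
            raise InvalidParameterError("counts contain non-finite values")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class ChannelRange:
    """Inclusive [first, last] bin range plus the fractions that defined it."""

    first: int
    last: int
    rise_fraction: float = 0.25
    tail_fraction: float = 0.03

    def __post_init__(self):
        if not (0 <= self.first <= self.last):
            raise InvalidParameterError("need 0 <= first <= last")

    @property
    def slice(self) -> slice:
        return slice(self.first, self.last + 1)

    def __len__(self) -> int:
        return self.last - self.first + 1


@dataclass(frozen=True)
class MomentSet:
    """Moments of one DTOF over one channel range.

    Ntot : total counts;  A = -ln(Ntot) up to an additive constant;
    m1 : mean time of flight (ps);  V : variance (ps^2);
    m3C, m4C : third and fourth central moments (ps^3, ps^4).
    """

    Ntot: float
    m1: float
    V: float
    m3C: float
    m4C: float

    @property
    def A(self) -> float:
        return -np.log(self.Ntot)


@dataclass(frozen=True)
class MomentChanges:
    """Baseline-to-state changes in attenuation, mean time and variance.

    Sign convention: the starred (after) state enters as
    dA = -ln(Ntot_after / Ntot_baseline), dm1 = m1 - m1*, dV = V - V*,
    so an absorption increase gives positive dA, dm1 and dV.
    """

    dA: float
    dm1: float
    dV: float

    def as_array(self, moments_used=("dm1", "dV")) -> np.ndarray:
        return np.array([getattr(self, k) for k in moments_used])


@dataclass(frozen=True)
class MomentNoise:
    """Photon-noise standard deviations of the moment *changes*.

    Evaluated from the baseline MomentSet under the simplifying assumption
    that both DTOFs (baseline and after the absorption change) carry the
    same noise:  sA = sqrt(2/Ntot), sm1 = sqrt(2 V / Ntot),
    sV = sqrt(2 (m4C - V^2) / Ntot).
    """

    sA: float
    sm1: float
    sV: float

    def as_array(self, moments_used=("dm1", "dV")) -> np.ndarray:
        key = {"dA": "sA", "dm1": "sm1", "dV": "sV"}
        return np.array([getattr(self, key[k]) for k in moments_used])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_range(
    dtof: DTOF, rise_fraction: float = 0.25, tail_fraction: float = 0.03
) -> ChannelRange:
    """Channel range from ``rise_fraction`` of the peak on the rising edge
    to ``tail_fraction`` of the peak on the tail.

    ``first`` is the earliest bin at or before the peak with counts >=
    rise_fraction * peak; ``last`` is the latest bin at or after the peak
    with counts >= tail_fraction * peak.  Whole-bin resolution, no
    interpolation; peak ties break toward the earlier bin (argmax).
    """
    if not (0 < rise_fraction < 1 and 0 < tail_fraction < 1):
        raise InvalidParameterError("fractions must lie strictly in (0, 1)")
    c = dtof.counts
    peak_idx = int(np.argmax(c))
    peak = c[peak_idx]
    if peak <= 0:
        raise EmptyInputError("all-zero histogram: no peak to threshold against")
    above_rise = np.nonzero(c[: peak_idx + 1] >= rise_fraction * peak)[0]
    first = int(above_rise[0])
    above_tail = np.nonzero(c[peak_idx:] >= tail_fraction * peak)[0]
    last = peak_idx + int(above_tail[-1])
    return ChannelRange(first, last, rise_fraction, tail_fraction)


def compute_moments(dtof: DTOF, rng: ChannelRange) -> MomentSet:
    """Moments of ``dtof`` over the inclusive channel range ``rng``.

    Central moments are taken about the mean of the same range.  Small
    negative counts (background-subtraction residue) are kept as is; a
    warning is logged if the negative mass exceeds 0.1% of the total.
    """
    if rng.last >= dtof.grid.n_bins:
        raise InvalidParameterError("channel range exceeds histogram length")
    c = dtof.counts[rng.slice]
    t = dtof.grid.times[rng.slice]
    ntot = c.sum()
    if ntot <= 0:
        raise EmptyInputError("non-positive total counts in range")
    neg = -c[c < 0].sum()
    if neg > 1e-3 * ntot:
        logger.warning(
            "negative counts amount to %.2e of Ntot in the analysis range", neg / ntot
        )
    m1 = float(t @ c / ntot)
    dt_c = t - m1
    V = float((dt_c**2) @ c / ntot)
    m3C = float((dt_c**3) @ c / ntot)
    m4C = float((dt_c**4) @ c / ntot)
    return MomentSet(Ntot=float(ntot), m1=m1, V=V, m3C=m3C, m4C=m4C)


def deconvolve_irf_moments(dtof_moments: MomentSet, irf_moments: MomentSet) -> MomentSet:
    """Remove the IRF contribution from m1, V and m3C by moment subtraction.

    Cumulants of orders 1-3 are additive under convolution, so subtracting
    the IRF's m1, V and m3C deconvolves them exactly.  Ntot and m4C are
    passed through unchanged (m4C is used only for noise weighting of the
    raw histogram).
    """
    return MomentSet(
        Ntot=dtof_moments.Ntot,
        m1=dtof_moments.m1 - irf_moments.m1,
        V=dtof_moments.V - irf_moments.V,
        m3C=dtof_moments.m3C - irf_moments.m3C,
        m4C=dtof_moments.m4C,
    )


def moment_changes(baseline: MomentSet, after: MomentSet) -> MomentChanges:
    """Changes in moments from ``baseline`` to ``after``.

    dA = -ln(Ntot_after/Ntot_baseline); dm1 = m1 - m1*; dV = V - V*
    (star = after).  An absorption increase yields positive changes.
    """
    if baseline.Ntot <= 0 or after.Ntot <= 0:
        raise InvalidParameterError("both MomentSets need Ntot > 0")
    return MomentChanges(
        dA=float(-np.log(after.Ntot / baseline.Ntot)),
        dm1=baseline.m1 - after.m1,
        dV=baseline.V - after.V,
    )


def photon_noise(baseline: MomentSet) -> MomentNoise:
    """Photon-noise uncertainties of moment changes, from the baseline DTOF.

    Poisson counting statistics give, for the difference of two equally
    noisy DTOFs: sA = sqrt(2/Ntot), sm1 = sqrt(2 V/Ntot),
    sV = sqrt(2 (m4C - V^2)/Ntot).
    """
    if baseline.Ntot <= 0:
        raise InvalidParameterError("Ntot must be > 0")
    excess = baseline.m4C - baseline.V**2
    if excess < 0:
        warnings.warn(
            f"m4C - V^2 = {excess:.3e} < 0 (numerical); clamping to zero",
            stacklevel=2,
        )
        excess = 0.0
    n = baseline.Ntot
    return MomentNoise(
        sA=float(np.sqrt(2.0 / n)),
        sm1=float(np.sqrt(2.0 * baseline.V / n)),
        sV=float(np.sqrt(2.0 * excess / n)),
    )
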