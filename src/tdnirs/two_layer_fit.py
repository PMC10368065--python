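"""Absorption changes in two layers from changes in DTOF moments.

The central method of the package.  Given two DTOFs -- at baseline and
after an absorption change -- and the full set of baseline parameters
(mua, musp per layer, superficial thickness L, refractive index n,
source-detector distance rho), the changes in the statistical moments
(dA, dm1, dV) are compared with the changes predicted by the layered
diffusion forward model, and the pair (dmua_sup, dmua_deep) minimizing
the photon-noise-weighted error norm

    chi2 = (dA_sim - dA)^2 + (dm1_sim - dm1)^2 / V + (dV_sim - dV)^2 / (m4C - V^2)

is found by damped (Levenberg-Marquardt-type) iterative least squares.
The denominators are the baseline DTOF's variance and excess fourth
moment, i.e. the squared photon-noise uncertainties up to the common
factor 2/Ntot.  Because the forward model is evaluated through the same
moment pipeline (IRF convolution, fixed channel range) as the
measurement, the method is largely insensitive to the chosen range.

By default the intensity term dA is excluded (it is the moment most
exposed to source-power drifts and attenuator changes); the pair
{dm1, dV} identifies the two unknowns.  Adding the fitted changes to the
baseline absorption gives absolute mua per layer.

A linearized solution using sensitivity factors (the derivative of each
moment change with respect to each layer's absorption change at baseline)
provides the initial guess; unlike the linearized method, the iterative
fit stays accurate for large absorption changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError, InvalidParameterError
from .forward_model import (
    LayeredMedium,
    OpticalLayer,
    TimeGrid,
    TwoLayerEngine,
    convolve_irf,
)
from .moments import (
    ChannelRange,
    DTOF,
    MomentChanges,
    MomentNoise,
    MomentSet,
    compute_moments,
    moment_changes,
    photon_noise,
    select_range,
)

__all__ = [
    "BaselineState",
    "SensitivityFactors",
    "TwoLayerFitResult",
    "TwoLayerScenario",
    "simulate_dtof_pair",
    "sensitivity_factors",
    "linear_initial_guess",
    "chi2",
    "fit_two_layer",
    "chi2_landscape",
    "baseline_error_study",
]

MOMENT_ORDER = ("dA", "dm1", "dV")
DEFAULT_MOMENTS = ("dm1", "dV")
#: parameter box for the fitted changes: |dmua| <= 0.5 cm^-1 = 0.05 mm^-1
DMUA_BOX = 0.05


@dataclass(frozen=True)
class BaselineState:
    """Known baseline of the two-layered medium (mm^-1, mm)."""

    mua_sup: float
    mua_deep: float
    musp_sup: float
    musp_deep: float
    L: float
    n: float = 1.33
    rho: float = 30.0

    def __post_init__(self):
        for name in ("mua_sup", "mua_deep", "musp_sup", "musp_deep", "L", "n", "rho"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")

    def medium(self, dmua_sup: float = 0.0, dmua_deep: float = 0.0) -> LayeredMedium:
        mua_s = self.mua_sup + dmua_sup
        mua_d = self.mua_deep + dmua_deep
        if mua_s < 0 or mua_d < 0:
            warnings.warn(
                "absorption change drives a layer's mua below zero; "
                "constraining at mua = 0",
                stacklevel=2,
            )
            mua_s = max(mua_s, 0.0)
            mua_d = max(mua_d, 0.0)
        return LayeredMedium(
            layers=(
                OpticalLayer(mua=mua_s, musp=self.musp_sup, thickness=self.L, n=self.n),
                OpticalLayer(mua=mua_d, musp=self.musp_deep, n=self.n),
            )
        )


@dataclass(frozen=True)
class SensitivityFactors:
    """Partial derivatives of moment changes w.r.t. layer absorption changes.

    ``matrix`` has rows (dA, dm1, dV) and columns (superficial, deep),
    in (ln, ps, ps^2) per mm^-1.
    """

    matrix: np.ndarray
    baseline: BaselineState

    def rows(self, moments_used=DEFAULT_MOMENTS) -> np.ndarray:
        idx = [MOMENT_ORDER.index(k) for k in moments_used]
        return self.matrix[idx, :]


@dataclass(frozen=True)
class TwoLayerFitResult:
    """Recovered absorption changes and diagnostics (mm^-1)."""

    dmua_sup: float
    dmua_deep: float
    mua_sup_abs: float
    mua_deep_abs: float
    chi2: float
    initial_guess: tuple[float, float]
    moments_used: tuple[str, ...]
    converged: bool


@dataclass(frozen=True)
class TwoLayerScenario:
    """A ground-truth configuration for in-silico studies."""

    baseline: BaselineState
    dmua_sup: float
    dmua_deep: float
    irf: DTOF
    grid: TimeGrid


# ---------------------------------------------------------------------------
# Forward pipeline: candidate (dmua_sup, dmua_deep) -> simulated changes
# ---------------------------------------------------------------------------

class MomentsForward:
    """Simulated moment changes of a two-layered medium versus baseline.

    Builds the layered engine once for a fixed baseline geometry and
    caches the simulated baseline moments, so repeated candidate
    evaluations (LM iterations, landscape cells) cost one forward curve
    each.
    """

    def __init__(
        self,
        baseline: BaselineState,
        irf: DTOF,
        grid: TimeGrid,
        rng: ChannelRange,
    ):
        self.baseline = baseline
        self.irf = irf
        self.grid = grid
        self.rng = rng
        self.engine = TwoLayerEngine(
            musps=(baseline.musp_sup, baseline.musp_deep),
            thicknesses=(baseline.L,),
            n=baseline.n,
            n_exterior=1.0,
            rho=baseline.rho,
            grid=grid,
        )
        self._base_sim = self._moments(baseline.mua_sup, baseline.mua_deep)

    def _moments(self, mua_sup: float, mua_deep: float) -> MomentSet:
        curve = self.engine.curve((max(mua_sup, 0.0), max(mua_deep, 0.0)))
        return compute_moments(convolve_irf(curve, self.irf), self.rng)

    def changes(self, dmua_sup: float, dmua_deep: float) -> MomentChanges:
        after = self._moments(
            self.baseline.mua_sup + dmua_sup, self.baseline.mua_deep + dmua_deep
        )
        return moment_changes(self._base_sim, after)


def simulate_dtof_pair(
    scenario: TwoLayerScenario, ntot_baseline: float = 1e6
) -> tuple[DTOF, DTOF]:
    """Noiseless baseline/after DTOF pair for a ground-truth scenario.

    Both curves come from the layered forward model convolved with the
    scenario's IRF; the baseline is scaled to ``ntot_baseline`` total
    counts and the after-curve keeps the physical intensity ratio.
    """
    from .forward_model import layered_reflectance

    b = scenario.baseline
    base_curve = layered_reflectance(b.medium(), b.rho, scenario.grid)
    after_curve = layered_reflectance(
        b.medium(scenario.dmua_sup, scenario.dmua_deep), b.rho, scenario.grid
    )
    base = convolve_irf(base_curve, scenario.irf)
    after = convolve_irf(after_curve, scenario.irf)
    scale = ntot_baseline / base.total
    return (
        DTOF(counts=base.counts * scale, grid=scenario.grid),
        DTOF(counts=after.counts * scale, grid=scenario.grid),
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sensitivity_factors(
    baseline: BaselineState,
    irf: DTOF,
    grid: TimeGrid,
    rng: ChannelRange,
    rel_perturbation: float = 0.02,
) -> SensitivityFactors:
    """Sensitivity factors by central differences at +/- 2% of baseline mua.

    Each layer's absorption is perturbed by ``rel_perturbation`` of its
    baseline value in both directions; the resulting moment changes give
    the local derivative d(dA, dm1, dV)/d(dmua) per layer.
    """
    fw = MomentsForward(baseline, irf, grid, rng)
    cols = []
    for layer in ("sup", "deep"):
        mua0 = getattr(baseline, f"mua_{layer}")
        delta = rel_perturbation * mua0
        kw_p = {"dmua_sup": delta if layer == "sup" else 0.0,
                "dmua_deep": delta if layer == "deep" else 0.0}
        kw_m = {k: -v for k, v in kw_p.items()}
        ch_p = fw.changes(**kw_p)
        ch_m = fw.changes(**kw_m)
        cols.append(
            (ch_p.as_array(MOMENT_ORDER) - ch_m.as_array(MOMENT_ORDER)) / (2 * delta)
        )
    return SensitivityFactors(matrix=np.column_stack(cols), baseline=baseline)


def linear_initial_guess(
    sf: SensitivityFactors,
    measured: MomentChanges,
    moments_used: tuple[str, ...] = DEFAULT_MOMENTS,
    noise: MomentNoise | None = None,
) -> tuple[float, float]:
    """Linearized solution SF . dmua = measured changes (least squares).

    With all three moments selected and a noise estimate available, rows
    are weighted by their inverse photon-noise uncertainty.  Valid for
    small changes only; serves as the initial guess of the iterative fit.
    """
    if len(moments_used) < 2:
        raise InvalidParameterError("need at least two moments for two unknowns")
    A = sf.rows(moments_used)
    b = measured.as_array(moments_used)
    if noise is not None and len(moments_used) == 3:
        w = 1.0 / noise.as_array(moments_used)
        A = A * w[:, None]
        b = b * w
    if np.linalg.cond(A) > 1e8:
        raise DegenerateGeometryError(
            "sensitivity matrix is ill-conditioned; the geometry does not "
            "separate the two layers (e.g. L too large)"
        )
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(sol[0]), float(sol[1])


def _weights(baseline_moments: MomentSet, moments_used) -> np.ndarray:
    """Inverse of the error-norm denominators: 1, sqrt(V), sqrt(m4C - V^2)."""
    denom = {
        "dA": 1.0,
        "dm1": np.sqrt(baseline_moments.V),
        "dV": np.sqrt(max(baseline_moments.m4C - baseline_moments.V**2, 0.0)),
    }
    return np.array([1.0 / denom[k] for k in moments_used])


def chi2(
    candidate: tuple[float, float],
    measured: MomentChanges,
    baseline: BaselineState,
    baseline_moments: MomentSet,
    irf: DTOF,
    rng: ChannelRange,
    moments_used: tuple[str, ...] = DEFAULT_MOMENTS,
    forward: MomentsForward | None = None,
) -> float:
    """Scaled error norm (the 2 Ntot chi^2 form) of one candidate pair.

    Simulates the moment changes for ``candidate`` through the layered
    model + IRF pipeline and sums the squared weighted differences to the
    measured changes, restricted to ``moments_used``.  Denominators come
    from the measured baseline MomentSet.
    """
    fw = forward or MomentsForward(baseline, irf, irf.grid, rng)
    sim = fw.changes(*candidate)
    w = _weights(baseline_moments, moments_used)
    diff = (sim.as_array(moments_used) - measured.as_array(moments_used)) * w
    return float(diff @ diff)


def fit_two_layer(
    dtof_baseline: DTOF,
    dtof_after: DTOF,
    baseline: BaselineState,
    irf: DTOF,
    moments_used: tuple[str, ...] = DEFAULT_MOMENTS,
    init: tuple[float, float] | None = None,
    rise_fraction: float = 0.25,
    tail_fraction: float = 0.03,
    rng: ChannelRange | None = None,
) -> TwoLayerFitResult:
    """Determine (dmua_sup, dmua_deep) from a baseline/after DTOF pair.

    The channel range is selected on the baseline DTOF (25%/3% by
    default) and reused everywhere.  The initial guess defaults to the
    linearized sensitivity-factor solution.  Returns changes and absolute
    mua per layer in mm^-1.
    """
    if not dtof_baseline.grid.compatible_with(dtof_after.grid):
        raise InvalidParameterError("baseline and after DTOFs must share a grid")
    if len(moments_used) < 2:
        raise InvalidParameterError("need at least two moments for two unknowns")
    if rng is None:
        rng = select_range(dtof_baseline, rise_fraction, tail_fraction)
    base_m = compute_moments(dtof_baseline, rng)
    after_m = compute_moments(dtof_after, rng)
    measured = moment_changes(base_m, after_m)
    fw = MomentsForward(baseline, irf, dtof_baseline.grid, rng)

    if init is None:
        sf = sensitivity_factors(baseline, irf, dtof_baseline.grid, rng)
        init = linear_initial_guess(sf, measured, moments_used, photon_noise(base_m))

    w = _weights(base_m, moments_used)
    meas_vec = measured.as_array(moments_used)

    lo = (max(-DMUA_BOX, -baseline.mua_sup), max(-DMUA_BOX, -baseline.mua_deep))
    hi = (DMUA_BOX, DMUA_BOX)
    x0 = np.clip(init, lo, hi)

    def residuals(x):
        sim = fw.changes(x[0], x[1])
        return (sim.as_array(moments_used) - meas_vec) * w

    res = least_squares(
        residuals,
        x0=x0,
        bounds=(lo, hi),
        ftol=1e-10,
        xtol=1e-8,
        gtol=1e-12,
        max_nfev=400,
        method="trf",
        x_scale=0.001,
        diff_step=1e-3,
    )
    dsup, ddeep = res.x
    return TwoLayerFitResult(
        dmua_sup=float(dsup),
        dmua_deep=float(ddeep),
        mua_sup_abs=float(baseline.mua_sup + dsup),
        mua_deep_abs=float(baseline.mua_deep + ddeep),
        chi2=float(2.0 * res.cost),
        initial_guess=(float(x0[0]), float(x0[1])),
        moments_used=tuple(moments_used),
        converged=bool(res.status > 0),
    )


def chi2_landscape(
    measured: MomentChanges,
    baseline: BaselineState,
    baseline_moments: MomentSet,
    irf: DTOF,
    rng: ChannelRange,
    grid_spec: tuple[np.ndarray, np.ndarray] | None = None,
    moments_used: tuple[str, ...] = DEFAULT_MOMENTS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled error norm over a Cartesian grid of (dmua_sup, dmua_deep).

    ``grid_spec`` is a pair of 1-D arrays of candidate changes in mm^-1;
    the default covers -0.05 ... +0.15 cm^-1 in 61 steps on both axes.
    Returns (sup_values, deep_values, chi2_matrix) with
    ``chi2_matrix[i, j]`` for ``sup_values[i]``, ``deep_values[j]``.
    The superficial axis is the outer loop so the engine reuses the top
    layer's transcendental terms along each column.
    """
    if grid_spec is None:
        axis = np.linspace(-0.005, 0.015, 61)
        grid_spec = (axis, axis.copy())
    sup_values, deep_values = (np.asarray(a, dtype=float) for a in grid_spec)
    fw = MomentsForward(baseline, irf, irf.grid, rng)
    w = _weights(baseline_moments, moments_used)
    meas_vec = measured.as_array(moments_used)
    out = np.empty((len(sup_values), len(deep_values)))
    for i, dsup in enumerate(sup_values):
        for j, ddeep in enumerate(deep_values):
            sim = fw.changes(dsup, ddeep)
            diff = (sim.as_array(moments_used) - meas_vec) * w
            out[i, j] = diff @ diff
    return sup_values, deep_values, out


def baseline_error_study(
    truth: TwoLayerScenario,
    perturbed_parameter: str,
    values,
    moments_used: tuple[str, ...] = DEFAULT_MOMENTS,
) -> pd.DataFrame:
    """Effect of a wrong assumed baseline parameter on the recovered pair.

    Simulates a noiseless DTOF pair from the ground-truth scenario, then
    refits it repeatedly, each time replacing one baseline parameter
    (``mua_sup``, ``mua_deep``, ``musp_sup``, ``musp_deep``, ``n`` or
    ``L``) by an assumed value while the data stay fixed.  Returns a
    table of assumed value and recovered (dmua_sup, dmua_deep).
    """
    allowed = {"mua_sup", "mua_deep", "musp_sup", "musp_deep", "n", "L"}
    if perturbed_parameter not in allowed:
        raise InvalidParameterError(
            f"perturbed_parameter must be one of {sorted(allowed)}"
        )
    dtof_base, dtof_after = simulate_dtof_pair(truth)
    rows = []
    for value in values:
        assumed = replace(truth.baseline, **{perturbed_parameter: float(value)})
        fit = fit_two_layer(
            dtof_base, dtof_after, assumed, truth.irf, moments_used=moments_used
        )
        rows.append(
            {
                "assumed_value": float(value),
                "dmua_sup": fit.dmua_sup,
                "dmua_deep": fit.dmua_deep,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
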