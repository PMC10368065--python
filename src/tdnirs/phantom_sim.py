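"""Digital twin of the two-layered blood-lipid phantom.

The physical phantom holds two liquid compartments (superficial and deep,
separated by a thin film; superficial-layer thickness L adjustable) whose
optical properties are controlled by adding calibrated amounts of
scatterer (SMOFlipid), absorber (India ink) or whole blood whose oxygen
saturation is driven down with yeast and up by bubbling oxygen.  This
module reproduces those experiments in silico:

* nominal-property calculators: reduced scattering from the lipid volume
  fraction and absorption from the diluted-ink volume fraction and the
  ink's effective absorption and single-scattering albedo;
* an ink protocol (20 absorption steps in one compartment, the other
  fixed) and a blood protocol (six deoxygenation cycles driven by yeast
  and oxygen events) producing DTOF time series through the layered
  forward model;
* a synthetic IRF (Gaussian main peak plus a delayed after-pulse replica)
  and Poisson counting noise.

All simulator outputs are deterministic given the protocol and seed.
Internal units mm/ps; masses in grams with density 1 g/ml assumed for the
volume fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromophores import ExtinctionTable, hemoglobin_mua
from .exceptions import InvalidParameterError
from .forward_model import (
    TimeGrid,
    TwoLayerEngine,
    convolve_irf,
    homogeneous_reflectance,
)
from .moments import DTOF
from .two_layer_fit import BaselineState

__all__ = [
    "InkCharacterization",
    "MixtureRecipe",
    "CompartmentRecipe",
    "DEEP_BLOOD_RECIPE",
    "SUP_BLOOD_RECIPE",
    "InkProtocol",
    "BloodProtocol",
    "IRFModel",
    "InkStepFrame",
    "BloodFrame",
    "nominal_musp",
    "characterize_ink",
    "nominal_mua",
    "stock_mass_for_step",
    "synth_irf",
    "add_poisson_noise",
    "simulate_ink_experiment",
    "simulate_blood_experiment",
    "calibrate_total_hemoglobin",
]

#: specific reduced scattering of the lipid emulsion at 750 nm (mm^-1)
EPS_S_SL_750 = 21.5
#: default single-scattering albedo of the ink
INK_ALBEDO = 0.15
#: volume fraction of water (+ lipid) used for the water background
WATER_FRACTION = 0.985


# ---------------------------------------------------------------------------
# Nominal-property calculators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InkCharacterization:
    """Spectrophotometric characterization of the ink stock.

    eps_eff_ink: effective absorption of pure ink (1/mm);
    albedo: single-scattering albedo Lambda, so the true absorption is
    eps_a_ink = eps_eff_ink * (1 - Lambda).
    """

    eps_eff_ink: float
    albedo: float = INK_ALBEDO
    d_ink: float | None = None
    A_p: float | None = None

    def __post_init__(self):
        if not self.eps_eff_ink > 0:
            raise InvalidParameterError("eps_eff_ink must be positive")
        if not (0 <= self.albedo < 1):
            raise InvalidParameterError("albedo must lie in [0, 1)")

    @property
    def eps_a_ink(self) -> float:
        return self.eps_eff_ink * (1.0 - self.albedo)


@dataclass(frozen=True)
class MixtureRecipe:
    """Ingredient masses in grams (density 1 g/ml assumed for volumes)."""

    mass_water: float
    mass_SL: float
    mass_diluted_ink: float = 0.0

    def __post_init__(self):
        if min(self.mass_water, self.mass_SL, self.mass_diluted_ink) < 0:
            raise InvalidParameterError("masses must be non-negative")
        if self.total <= 0:
            raise InvalidParameterError("total mass must be positive")

    @property
    def total(self) -> float:
        return self.mass_water + self.mass_SL + self.mass_diluted_ink


def nominal_musp(recipe: MixtureRecipe, eps_s_SL: float = EPS_S_SL_750) -> float:
    """Nominal reduced scattering (mm^-1) from the lipid volume fraction:
    eps_s_SL * V_SL / (V_diluted_ink + V_SL + V_water)."""
    return eps_s_SL * recipe.mass_SL / recipe.total


def characterize_ink(
    A_p: float, d_ink: float, albedo: float = INK_ALBEDO
) -> InkCharacterization:
    """Ink characterization from a cuvette absorbance measurement.

    ``A_p`` is the absorbance of a dilution ``d_ink`` (ink weight / total
    weight) measured in a 1 cm cuvette, already expressed on the natural
    per-mm scale; the effective absorption of the pure ink is
    eps_eff_ink = A_p / d_ink.
    """
    if not d_ink > 0:
        raise InvalidParameterError("d_ink must be positive")
    return InkCharacterization(eps_eff_ink=A_p / d_ink, albedo=albedo, d_ink=d_ink, A_p=A_p)


def nominal_mua(
    recipe: MixtureRecipe, ink: InkCharacterization, mua_water: float
) -> float:
    """Nominal absorption (mm^-1) from the diluted-ink volume fraction:

        mua_water + (V_diluted_ink * d_ink / V_total) * eps_eff_ink * (1 - Lambda)

    The lipid is assumed to absorb like water (its own absorption is
    similar and the mixture is mostly water).
    """
    if ink.d_ink is None:
        raise InvalidParameterError("ink characterization lacks the dilution d_ink")
    frac = recipe.mass_diluted_ink * ink.d_ink / recipe.total
    return mua_water + frac * ink.eps_eff_ink * (1.0 - ink.albedo)


def stock_mass_for_step(
    total_mass: float, mua_current: float, mua_target: float, mua_stock: float
) -> float:
    """Mass of a high-absorption stock mixture needed to raise a
    compartment of ``total_mass`` grams from ``mua_current`` to
    ``mua_target`` (all coefficients in the same units).

    Mass balance: m = M (mua_target - mua_current) / (mua_stock - mua_target).
    """
    if mua_stock <= mua_target:
        raise InvalidParameterError("stock must be more absorbing than the target")
    return total_mass * (mua_target - mua_current) / (mua_stock - mua_target)


# ---------------------------------------------------------------------------
# Synthetic IRF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IRFModel:
    """Gaussian main peak plus a delayed after-pulse replica.

    The after-pulse sits ``afterpulse_delay`` ps after the main peak with
    ``afterpulse_fraction`` of its height (about 1% at +1 ns for the
    modelled detector).
    """

    fwhm: float = 400.0
    peak_time: float = 1200.0
    afterpulse_delay: float = 1000.0
    afterpulse_fraction: float = 0.01
    total_counts: float = 1e7

    def __post_init__(self):
        if self.afterpulse_fraction < 0:
            raise InvalidParameterError("afterpulse_fraction must be >= 0")
        if not self.afterpulse_delay > 0:
            raise InvalidParameterError("afterpulse_delay must be > 0")
        if not self.fwhm > 0:
            raise InvalidParameterError("fwhm must be > 0")


def synth_irf(model: IRFModel, grid: TimeGrid, seed: int | None = None) -> DTOF:
    """Synthetic IRF histogram on ``grid``.

    Deterministic shape (Gaussian mixture sampled at bin centers,
    normalized to ``total_counts``); with ``seed`` given, Poisson counts
    are drawn instead.
    """
    t = grid.times
    if not (t[0] <= model.peak_time <= t[-1]):
        raise InvalidParameterError("IRF peak time falls outside the grid")
    sigma = model.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    main = np.exp(-0.5 * ((t - model.peak_time) / sigma) ** 2)
    after = model.afterpulse_fraction * np.exp(
        -0.5 * ((t - model.peak_time - model.afterpulse_delay) / sigma) ** 2
    )
    shape = main + after
    counts = shape * (model.total_counts / shape.sum())
    if seed is not None:
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
    return DTOF(counts=counts, grid=grid)


def add_poisson_noise(
    dtof: DTOF,
    target_ntot: float,
    seed: int | np.random.Generator | None = None,
    negative: str = "error",
) -> DTOF:
    """Rescale to ``target_ntot`` expected counts and draw Poisson counts.

    ``negative`` chooses how negative input values are handled ("clip"
    or "error").
    """
    c = dtof.counts
    if np.any(c < 0):
        if negative == "clip":
            c = np.clip(c, 0.0, None)
        else:
            raise InvalidParameterError(
                "negative counts present; pass negative='clip' to zero them"
            )
    if target_ntot < 0:
        raise InvalidParameterError("target_ntot must be >= 0")
    total = c.sum()
    lam = c * (target_ntot / total) if total > 0 else np.zeros_like(c)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return DTOF(counts=rng.poisson(lam).astype(float), grid=dtof.grid)


# ---------------------------------------------------------------------------
# Ink protocol
# ---------------------------------------------------------------------------

def _default_ink_steps() -> tuple[float, ...]:
    # targeted mua 0.05 -> 0.25 cm^-1 (at 750 nm) in 20 steps, in mm^-1
    return tuple(np.linspace(0.005, 0.025, 20))


@dataclass(frozen=True)
class InkProtocol:
    """One ink experiment: 20 absorption steps in one compartment.

    ``stepped_compartment`` is "deep" (Exp. #1) or "sup" (Exp. #2); the
    other compartment stays at ``fixed_mua``.  Coefficients in mm^-1 (at
    the working wavelength, 750 nm); L in mm.
    """

    stepped_compartment: str = "deep"
    stepped_mua: tuple[float, ...] = field(default_factory=_default_ink_steps)
    fixed_mua: float = 0.010
    musp: float = 0.107 * 10.0  # 10.7 cm^-1 nominal at 750 nm -> 1.07 mm^-1
    L: float = 14.5
    n: float = 1.33
    rho: float = 30.0

    def __post_init__(self):
        if self.stepped_compartment not in ("deep", "sup"):
            raise InvalidParameterError("stepped_compartment must be 'deep' or 'sup'")
        if len(self.stepped_mua) == 0:
            raise InvalidParameterError("protocol needs at least one step")

    def step_muas(self, i: int) -> tuple[float, float]:
        """(mua_sup, mua_deep) of step ``i``."""
        if self.stepped_compartment == "deep":
            return self.fixed_mua, self.stepped_mua[i]
        return self.stepped_mua[i], self.fixed_mua

    def baseline_state(self, baseline_step: int = 9) -> BaselineState:
        """Baseline parameters with the stepped compartment at
        ``baseline_step`` (default the 10th step)."""
        mua_sup, mua_deep = self.step_muas(baseline_step)
        return BaselineState(
            mua_sup=mua_sup,
            mua_deep=mua_deep,
            musp_sup=self.musp,
            musp_deep=self.musp,
            L=self.L,
            n=self.n,
            rho=self.rho,
        )


@dataclass(frozen=True)
class InkStepFrame:
    """Simulated measurements of one ink step."""

    step: int
    mua_sup: float
    mua_deep: float
    dtof_two_layer: DTOF
    dtof_stepped: DTOF


def simulate_ink_experiment(
    protocol: InkProtocol,
    irf: DTOF,
    grid: TimeGrid | None = None,
    ntot: float | None = None,
    seed: int | None = None,
) -> list[InkStepFrame]:
    """Simulate one ink experiment step by step.

    For every step, the two-layer measurement window sees the layered
    medium (superficial thickness L) and a second window sees the stepped
    compartment alone (homogeneous).  Both curves are convolved with the
    IRF; with ``ntot`` given, Poisson noise at that expected total count
    is added (seeded).
    """
    grid = grid or irf.grid
    engine = TwoLayerEngine(
        musps=(protocol.musp, protocol.musp),
        thicknesses=(protocol.L,),
        n=protocol.n,
        n_exterior=1.0,
        rho=protocol.rho,
        grid=grid,
    )
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(len(protocol.stepped_mua)):
        mua_sup, mua_deep = protocol.step_muas(i)
        two_layer = convolve_irf(engine.curve((mua_sup, mua_deep)), irf)
        stepped_mua = mua_deep if protocol.stepped_compartment == "deep" else mua_sup
        homog = convolve_irf(
            homogeneous_reflectance(
                stepped_mua, protocol.musp, protocol.n, 1.0, protocol.rho, grid
            ),
            irf,
        )
        if ntot is not None:
            two_layer = add_poisson_noise(two_layer, ntot, rng)
            homog = add_poisson_noise(homog, ntot, rng)
        frames.append(
            InkStepFrame(
                step=i,
                mua_sup=mua_sup,
                mua_deep=mua_deep,
                dtof_two_layer=two_layer,
                dtof_stepped=homog,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Blood protocol
# ---------------------------------------------------------------------------

def calibrate_total_hemoglobin(
    table: ExtinctionTable, target_mua_705: float = 0.017
) -> float:
    """Total hemoglobin (uM) such that the fully deoxygenated mixture has
    mua = ``target_mua_705`` mm^-1 at 705 nm (a calibration constant of
    the twin, matching the absorption maxima observed on the phantom)."""
    wl = np.array([705.0])
    per_uM = hemoglobin_mua(table, wl, 0.0, 1.0, water_fraction=0.0)[0]
    water = WATER_FRACTION * table._interp("mua_water", wl)[0]
    return (target_mua_705 - water) / per_uM


@dataclass(frozen=True)
class CompartmentRecipe:
    """Ingredient masses (grams) of one blood-lipid compartment."""

    mass_pbs_water: float
    mass_SL: float
    mass_blood: float
    mass_yeast: float

    @property
    def total(self) -> float:
        """Total excluding yeast (added later)."""
        return self.mass_pbs_water + self.mass_SL + self.mass_blood

    def fraction(self, ingredient: str) -> float:
        return getattr(self, f"mass_{ingredient}") / self.total


#: deep compartment: 3600 g total at 93.5% PBS-water, 5% lipid, 1.5% blood
DEEP_BLOOD_RECIPE = CompartmentRecipe(3366.0, 180.0, 54.0, 5.4)
#: superficial compartment: half the volume, same fractions
SUP_BLOOD_RECIPE = CompartmentRecipe(1683.0, 90.0, 27.0, 2.7)


@dataclass(frozen=True)
class BloodProtocol:
    """Event schedule of one blood experiment (times in minutes).

    Yeast events start a first-order desaturation (time constant ``tau``)
    in their compartment; each oxygenation window drives the deep
    compartment's StO2 linearly back to 100% and desaturation resumes
    when it closes.  Yeast also bumps the reduced scattering of its
    compartment.  The six resulting deoxygenation cycles are: one in the
    superficial compartment (after its single yeast addition) and five in
    the deep compartment.
    """

    yeast_deep_time: float = 0.0
    yeast_sup_time: float = 31.0
    oxygenation_windows: tuple[tuple[float, float], ...] = (
        (13.0, 15.0),
        (45.0, 47.0),
        (60.0, 62.0),
        (77.0, 79.0),
    )
    duration: float = 92.0
    tau: float = 3.0
    frame_interval: float = 0.05  # minutes (3 s sampling)
    musp_base: float = 1.07
    musp_bump_deep: float = 0.03
    musp_bump_sup: float = 0.02
    musp_drift_per_min: float = 0.0  # optional late drift of the deep musp
    drift_start: float = 45.0
    c_tot_uM: float | None = None  # calibrated from the table if None
    deep_recipe: CompartmentRecipe = DEEP_BLOOD_RECIPE
    sup_recipe: CompartmentRecipe = SUP_BLOOD_RECIPE

    def __post_init__(self):
        times = [a for a, _ in self.oxygenation_windows]
        if sorted(times) != list(times):
            raise InvalidParameterError("oxygenation windows must be time-ordered")
        for a, b in self.oxygenation_windows:
            if not b > a:
                raise InvalidParameterError("oxygenation window must have b > a")

    # -- trajectories -------------------------------------------------------

    def _sto2_deep_scalar(self, ti: float) -> float:
        if ti < self.yeast_deep_time:
            return 100.0
        s, t_mark = 100.0, self.yeast_deep_time
        for a, b in self.oxygenation_windows:
            if ti < a:
                return s * float(np.exp(-(ti - t_mark) / self.tau))
            s_at_a = s * float(np.exp(-(a - t_mark) / self.tau))
            if ti <= b:
                return s_at_a + (100.0 - s_at_a) * (ti - a) / (b - a)
            s, t_mark = 100.0, b
        return s * float(np.exp(-(ti - t_mark) / self.tau))

    def sto2_deep(self, t) -> np.ndarray:
        """Deep-compartment StO2 (%) at times ``t`` (min): first-order
        decay after the yeast event, linear recovery to 100% inside each
        oxygenation window, decay resuming when it closes."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.array([self._sto2_deep_scalar(ti) for ti in t])

    def sto2_sup(self, t: np.ndarray) -> np.ndarray:
        """Superficial-compartment StO2 (%): 100 until its yeast event,
        then first-order decay to 0 (never reoxygenated)."""
        t = np.asarray(t, dtype=float)
        dt_c = np.clip(t - self.yeast_sup_time, 0.0, None)
        return np.where(
            t < self.yeast_sup_time, 100.0, 100.0 * np.exp(-dt_c / self.tau)
        )

    def musp_deep_at(self, t: float) -> float:
        m = self.musp_base + (self.musp_bump_deep if t >= self.yeast_deep_time else 0.0)
        if self.musp_drift_per_min and t > self.drift_start:
            m -= self.musp_drift_per_min * (t - self.drift_start)
        return m

    def musp_sup_at(self, t: float) -> float:
        return self.musp_base + (
            self.musp_bump_sup if t >= self.yeast_sup_time else 0.0
        )


@dataclass(frozen=True)
class BloodFrame:
    """One multi-wavelength frame of a simulated blood experiment."""

    time_min: float
    sto2_sup: float
    sto2_deep: float
    musp_sup: float
    musp_deep: float
    wavelengths: np.ndarray
    mua_sup: np.ndarray
    mua_deep: np.ndarray
    dtofs_two_layer: dict
    dtofs_deep: dict


def simulate_blood_experiment(
    protocol: BloodProtocol,
    baseline: BaselineState,
    table: ExtinctionTable,
    irf: DTOF,
    grid: TimeGrid | None = None,
    seed: int | None = None,
    wavelengths: np.ndarray | None = None,
    times_min: np.ndarray | None = None,
    ntot: float | None = None,
) -> list[BloodFrame]:
    """Simulate the blood experiment as a multi-wavelength DTOF time series.

    Per frame and wavelength the compartment absorption follows the
    hemoglobin mixture at the protocol's StO2 trajectories (plus the
    water background), the reduced scattering includes the yeast bumps,
    and DTOFs are produced for the two-layer window (layered model, with
    the superficial thickness from ``baseline``) and the deep window
    (homogeneous).  ``times_min`` defaults to the full protocol at the
    frame interval; with ``ntot`` given, Poisson noise is added (seeded).
    """
    from .chromophores import channel_wavelengths

    grid = grid or irf.grid
    if wavelengths is None:
        wavelengths = channel_wavelengths(3, 11)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if times_min is None:
        times_min = np.arange(0.0, protocol.duration, protocol.frame_interval)
    c_tot = (
        protocol.c_tot_uM
        if protocol.c_tot_uM is not None
        else calibrate_total_hemoglobin(table)
    )
    rng = np.random.default_rng(seed)
    engines: dict[tuple[float, float], TwoLayerEngine] = {}
    frames = []
    for t in np.asarray(times_min, dtype=float):
        s_sup = float(protocol.sto2_sup(t))
        s_deep = float(protocol.sto2_deep(np.array([t]))[0])
        musp_sup = protocol.musp_sup_at(t)
        musp_deep = protocol.musp_deep_at(t)
        mua_sup = hemoglobin_mua(
            table, wavelengths, c_tot * s_sup / 100.0, c_tot * (1 - s_sup / 100.0)
        )
        mua_deep = hemoglobin_mua(
            table, wavelengths, c_tot * s_deep / 100.0, c_tot * (1 - s_deep / 100.0)
        )
        key = (musp_sup, musp_deep)
        if key not in engines:
            engines[key] = TwoLayerEngine(
                musps=key,
                thicknesses=(baseline.L,),
                n=baseline.n,
                n_exterior=1.0,
                rho=baseline.rho,
                grid=grid,
            )
        engine = engines[key]
        d2l, ddeep = {}, {}
        for k, wl in enumerate(wavelengths):
            two_layer = convolve_irf(engine.curve((mua_sup[k], mua_deep[k])), irf)
            deep = convolve_irf(
                homogeneous_reflectance(
                    mua_deep[k], musp_deep, baseline.n, 1.0, baseline.rho, grid
                ),
                irf,
            )
            if ntot is not None:
                two_layer = add_poisson_noise(two_layer, ntot, rng)
                deep = add_poisson_noise(deep, ntot, rng)
            d2l[float(wl)] = two_layer
            ddeep[float(wl)] = deep
        frames.append(
            BloodFrame(
                time_min=float(t),
                sto2_sup=s_sup,
                sto2_deep=s_deep,
                musp_sup=musp_sup,
                musp_deep=musp_deep,
                wavelengths=wavelengths,
                mua_sup=mua_sup,
                mua_deep=mua_deep,
                dtofs_two_layer=d2l,
                dtofs_deep=ddeep,
            )
        )
    return frames
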