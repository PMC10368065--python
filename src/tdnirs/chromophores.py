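"""Hemoglobin concentrations and oxygen saturation from mua spectra.

Given absolute absorption coefficients determined at several wavelengths,
this module subtracts the water background, solves the linear spectral
unmixing problem for the oxy- and deoxyhemoglobin concentrations, and
forms the oxygen saturation StO2 = 100 * C_HbO2 / (C_HbO2 + C_Hb).

The unmixing is deliberately *unconstrained*: when the input spectra are
biased (e.g. by an unmodelled scattering change), negative concentrations
-- and hence StO2 outside [0, 100]% -- are possible and are reported as
such rather than clipped.

Spectral channels follow the 16-channel spectrometer layout from 680 to
867.5 nm with 12.5 nm spacing: channel k is centered at
680 + 12.5 (k - 1) nm, so channels 3-11 span 705-805 nm.  A packaged
extinction table sampled at these centers ships with the module; it is a
synthetic rendition of published hemoglobin and water spectra (see the
data file header) suitable for simulation and self-consistent analysis.

Units: molar absorption coefficients are stored as decadic 1/(mM cm);
internally mua(lambda) [mm^-1] = ln(10) * eps * C[uM] * 1e-4 plus the
water term.  Concentrations are reported in uM.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .exceptions import DegenerateGeometryError, InvalidParameterError
from .units import LN10

__all__ = [
    "ExtinctionTable",
    "MuaSpectrum",
    "HemoglobinState",
    "channel_wavelengths",
    "load_extinction_table",
    "subtract_water",
    "fit_concentrations",
    "compute_sto2",
    "hemoglobin_mua",
]

#: conversion: eps[1/(mM cm)] * C[uM] -> natural absorption in mm^-1
_EPS_UM_TO_PER_MM = LN10 * 1e-4

#: default water volume fraction of the blood-lipid mixtures
WATER_FRACTION = 0.985


def channel_wavelengths(first: int = 1, last: int = 16) -> np.ndarray:
    """Center wavelengths (nm) of spectrometer channels ``first``..``last``
    (1-based, inclusive): 680 + 12.5 (k - 1)."""
    if not (1 <= first <= last <= 16):
        raise InvalidParameterError("channels must satisfy 1 <= first <= last <= 16")
    return 680.0 + 12.5 * (np.arange(first, last + 1) - 1)


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar absorption of HbO2/Hb and water absorption per wavelength.

    eps_* in decadic 1/(mM cm); mua_water in natural mm^-1.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    mua_water: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        for name in ("eps_hbo2", "eps_hb", "mua_water"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise InvalidParameterError(f"{name} misaligned with wavelengths")
            if np.any(arr < 0):
                raise InvalidParameterError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "wavelengths", wl)

    def _interp(self, what: str, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise InvalidParameterError(
                f"wavelength outside table support "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        return np.interp(wl, self.wavelengths, getattr(self, what))


@dataclass(frozen=True)
class MuaSpectrum:
    """Absorption coefficients (mm^-1) at a set of wavelengths (nm)."""

    wavelengths: np.ndarray
    mua: np.ndarray
    uncertainties: np.ndarray | None = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        mua = np.asarray(self.mua, dtype=float)
        if wl.shape != mua.shape:
            raise InvalidParameterError("wavelengths and mua misaligned")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mua", mua)


@dataclass(frozen=True)
class HemoglobinState:
    """Concentrations (uM) and oxygen saturation (%).

    Concentrations may be negative (unconstrained unmixing); StO2 then
    falls outside [0, 100]%.
    """

    C_HbO2: float
    C_Hb: float

    @property
    def StO2(self) -> float:
        return compute_sto2(self)


def load_extinction_table() -> ExtinctionTable:
    """The packaged 16-channel extinction table."""
    path = resources.files("tdnirs.data") / "extinction_16ch_synthetic.tsv"
    raw = np.loadtxt(str(path), comments="#")
    return ExtinctionTable(
        wavelengths=raw[:, 0],
        eps_hbo2=raw[:, 1],
        eps_hb=raw[:, 2],
        mua_water=raw[:, 3] * 0.1,  # file stores 1/cm
    )


def subtract_water(
    spectrum: MuaSpectrum,
    table: ExtinctionTable,
    water_fraction: float = WATER_FRACTION,
) -> MuaSpectrum:
    """Remove the water contribution water_fraction * mua_water per channel."""
    water = table._interp("mua_water", spectrum.wavelengths)
    return MuaSpectrum(
        wavelengths=spectrum.wavelengths,
        mua=spectrum.mua - water_fraction * water,
        uncertainties=spectrum.uncertainties,
    )


def hemoglobin_mua(
    table: ExtinctionTable,
    wavelengths: np.ndarray,
    c_hbo2_uM: float,
    c_hb_uM: float,
    water_fraction: float = WATER_FRACTION,
) -> np.ndarray:
    """Forward model: mua (mm^-1) of a hemoglobin + water mixture."""
    wl = np.asarray(wavelengths, dtype=float)
    return (
        _EPS_UM_TO_PER_MM
        * (c_hbo2_uM * table._interp("eps_hbo2", wl) + c_hb_uM * table._interp("eps_hb", wl))
        + water_fraction * table._interp("mua_water", wl)
    )


def fit_concentrations(
    spectrum: MuaSpectrum,
    table: ExtinctionTable,
    channels: tuple[int, int] = (3, 11),
    water_fraction: float = WATER_FRACTION,
) -> HemoglobinState:
    """Unconstrained least-squares unmixing of HbO2 and Hb (uM).

    ``channels`` selects the spectrometer channels used (1-based,
    inclusive); the default 3-11 spans 705-805 nm.  The water background
    is subtracted before solving.  Negative solutions are permitted.
    """
    use = channel_wavelengths(*channels)
    wl = spectrum.wavelengths
    mask = np.isin(np.round(wl, 4), np.round(use, 4))
    if mask.sum() < 2:
        # fall back: use every channel of the spectrum inside the window
        mask = (wl >= use.min() - 1e-9) & (wl <= use.max() + 1e-9)
    if mask.sum() < 2:
        raise InvalidParameterError("need at least two wavelengths for unmixing")
    wl_used = wl[mask]
    clean = subtract_water(
        MuaSpectrum(wl_used, spectrum.mua[mask]), table, water_fraction
    )
    design = _EPS_UM_TO_PER_MM * np.column_stack(
        [table._interp("eps_hbo2", wl_used), table._interp("eps_hb", wl_used)]
    )
    if np.linalg.cond(design) > 1e8:
        raise DegenerateGeometryError(
            "extinction design matrix is rank-deficient at these wavelengths"
        )
    sol, *_ = np.linalg.lstsq(design, clean.mua, rcond=None)
    return HemoglobinState(C_HbO2=float(sol[0]), C_Hb=float(sol[1]))


def compute_sto2(state: HemoglobinState) -> float:
    """StO2 = 100 * C_HbO2 / (C_HbO2 + C_Hb), in percent.

    May leave [0, 100] when a concentration is negative.  A zero total is
    undefined and raises.
    """
    total = state.C_HbO2 + state.C_Hb
    if total == 0:
        raise InvalidParameterError("StO2 undefined: C_HbO2 + C_Hb = 0")
    return 100.0 * state.C_HbO2 / total
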