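"""Wavelength grids, extinction libraries, Beer-law absorption and scattering.

The analysis works on calibrated diffuse reflectance in the 450-600 nm band,
where the dominant breast absorbers are oxy-/deoxy-hemoglobin, beta-carotene
and (when sentinel-node mapping was performed) patent blue dye.  Absorption is
composed by Beer's law from molar extinction tables; reduced scattering is a
wavelength power law whose band average <mus'> is the scalar scattering
endpoint used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

LN10 = float(np.log(10.0))

#: species names recognized by the packaged extinction library
SPECIES = ("hbo2", "hbh", "beta_carotene", "patent_blue_dye")

#: reference wavelength (nm) anchoring the scattering power law
LAMBDA0_NM = 500.0


def default_grid(step_nm: float = 5.0) -> "WavelengthGrid":
    """Default analysis grid: 450-600 nm, 5 nm steps (31 points)."""
    return WavelengthGrid(np.arange(450.0, 600.0 + 0.5 * step_nm, step_nm))


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm, restricted to 450-600 nm."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(v) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if v[0] < 450.0 - 1e-9 or v[-1] > 600.0 + 1e-9:
            raise ValueError("analysis band is 450-600 nm")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ChromophoreConcentrations:
    """Absorber concentrations in uM; all non-negative."""

    c_hbo2: float = 0.0
    c_hbh: float = 0.0
    c_beta_carotene: float = 0.0
    c_dye: float = 0.0

    def __post_init__(self):
        for name in ("c_hbo2", "c_hbh", "c_beta_carotene", "c_dye"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return {
            "hbo2": self.c_hbo2,
            "hbh": self.c_hbh,
            "beta_carotene": self.c_beta_carotene,
            "patent_blue_dye": self.c_dye,
        }

    @property
    def thb(self) -> float:
        return self.c_hbo2 + self.c_hbh


@dataclass(frozen=True)
class ScatteringParams:
    """Reduced scattering power law mus'(lam) = a * (lam/lam0)^(-b).

    ``a`` is the reduced scattering coefficient (cm^-1) at the reference
    wavelength ``lambda0_nm``; ``b`` is the dimensionless scattering power.
    """

    a: float
    b: float
    lambda0_nm: float = LAMBDA0_NM

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be > 0")
        if self.b < 0:
            raise ValueError("scattering power b must be >= 0")


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering spectra on a shared grid (cm^-1)."""

    grid: WavelengthGrid
    mua: np.ndarray
    musp: np.ndarray

    def __post_init__(self):
        mua = np.asarray(self.mua, dtype=float)
        musp = np.asarray(self.musp, dtype=float)
        if mua.shape != (len(self.grid),) or musp.shape != (len(self.grid),):
            raise ValueError("mua/musp must match the grid length")
        if np.any(mua < 0):
            raise ValueError("mua must be non-negative")
        if np.any(musp <= 0):
            raise ValueError("musp must be strictly positive")
        object.__setattr__(self, "mua", mua)
        object.__setattr__(self, "musp", musp)


class ExtinctionLibrary:
    """Per-species molar extinction curves on a reference grid.

    Curves are stored internally as natural-log extinction in cm^-1 uM^-1, so
    Beer's law reads mua = sum_i eps_i(lam) * c_i directly.  Decadic sources
    are converted on load (``log_base='decadic'``).
    """

    def __init__(self, wavelengths_nm: np.ndarray, curves: dict,
                 log_base: str = "natural"):
        lam = np.asarray(wavelengths_nm, dtype=float)
        if np.any(np.diff(lam) <= 0):
            raise ValueError("library grid must be strictly increasing")
        factor = {"natural": 1.0, "decadic": LN10}[log_base]
        self.wavelengths_nm = lam
        self.curves = {}
        for name, eps in curves.items():
            eps = np.asarray(eps, dtype=float) * factor
            if eps.shape != lam.shape:
                raise ValueError(f"curve {name!r} does not match the grid")
            if np.any(eps < 0):
                raise ValueError(f"curve {name!r} has negative extinction")
            self.curves[name] = eps

    @property
    def species(self):
        return tuple(self.curves)

    def covers(self, grid: WavelengthGrid) -> bool:
        return (self.wavelengths_nm[0] <= grid.values[0] + 1e-9
                and self.wavelengths_nm[-1] >= grid.values[-1] - 1e-9)

    def epsilon(self, species: str, grid: WavelengthGrid) -> np.ndarray:
        """Extinction of one species interpolated onto ``grid`` (linear)."""
        if species not in self.curves:
            raise KeyError(f"species {species!r} not in library")
        if not self.covers(grid):
            raise ValueError("grid extends outside library support")
        return np.interp(grid.values, self.wavelengths_nm, self.curves[species])


def load_default_library() -> ExtinctionLibrary:
    """Load the packaged extinction tables (see their JSON sidecar).

    The shipped curves are synthetic Gaussian band models with the
    characteristic band structure of each absorber; the analysis is
    forward/inverse self-consistent so only their consistent use matters.
    """
    root = resources.files("margindrs").joinpath("data/extinction")
    meta = json.loads(root.joinpath("extinction_meta.json").read_text())
    curves = {}
    lam = None
    for name, fname in meta["files"].items():
        arr = np.loadtxt(str(root.joinpath(fname)), comments="#")
        if lam is None:
            lam = arr[:, 0]
        elif not np.array_equal(lam, arr[:, 0]):
            raise ValueError("packaged tables disagree on the reference grid")
        curves[name] = arr[:, 1]
    log_base = {"natural": "natural", "decadic": "decadic"}[meta["log_base"]]
    return ExtinctionLibrary(lam, curves, log_base=log_base)


def compose_mua(concs: ChromophoreConcentrations, lib: ExtinctionLibrary,
                grid: WavelengthGrid) -> np.ndarray:
    """Beer's-law absorption mua(lam) = sum_i eps_i(lam) c_i in cm^-1."""
    mua = np.zeros(len(grid))
    for name, c in concs.as_dict().items():
        if c == 0.0:
            continue
        mua += lib.epsilon(name, grid) * c
    return mua


def musp_power_law(params: ScatteringParams, grid: WavelengthGrid) -> np.ndarray:
    """Reduced scattering spectrum mus'(lam) = a (lam/lam0)^(-b) in cm^-1."""
    return params.a * (grid.values / params.lambda0_nm) ** (-params.b)


def mean_musp(params: ScatteringParams, grid: WavelengthGrid) -> float:
    """Band average <mus'> over the grid, the scalar scattering endpoint."""
    return float(np.mean(musp_power_law(params, grid)))


def calibrate_amplitude(target_mean_musp: float, b: float,
                        grid: WavelengthGrid) -> ScatteringParams:
    """Scattering params whose band average <mus'> equals ``target_mean_musp``.

    Closed form: the mean is linear in the amplitude ``a``.
    """
    if target_mean_musp <= 0:
        raise ValueError("target <mus'> must be > 0")
    shape_mean = float(np.mean((grid.values / LAMBDA0_NM) ** (-b)))
    return ScatteringParams(a=target_mean_musp / shape_mean, b=b)
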