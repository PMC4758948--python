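"""Single-cell light-transmission estimate from a suspension spectrum.

The thylakoid membrane system of a cyanobacterial cell is approximated as
a hollow sphere (default inner diameter 1 µm, outer 2 µm) in which the
photosynthetic pigments are evenly distributed.  A narrow beam through
the cell centre then crosses a 1 µm total path of pigmented material, and
Beer–Lambert absorbance along that chord converts pigment content into a
single-cell transmission spectrum:

    A = sum_p  eps_p(lambda) * c_p * L,      T = 10^(-A).

Pipeline: subtract the scattering baseline (OD at 750 nm) from the
suspension spectrum, estimate per-cell pigment counts (supplied, or by
non-negative least squares onto extinction basis spectra), convert counts
to effective concentrations in the shell volume, compute the central-chord
peak absorbance, scale the suspension spectrum to that peak, and convert
to transmission / absorbed fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "AVOGADRO",
    "Spectrum",
    "CellGeometry",
    "PigmentModel",
    "subtract_scatter_baseline",
    "shell_volume_um3",
    "effective_concentration_mM",
    "beer_lambert",
    "scale_to_single_cell",
    "to_transmission",
    "absorbed_fraction",
    "decompose_pigments",
]

log = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # 1/mol


@dataclass
class Spectrum:
    """Wavelength-indexed absorbance or transmission values."""

    wavelength_nm: np.ndarray
    value: np.ndarray
    kind: str = "absorbance"  # or "transmission"

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.wavelength_nm.shape != self.value.shape:
            raise ValueError("wavelength and value grids differ in shape")
        if len(self.wavelength_nm) and np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if self.kind == "transmission" and (
            np.any(self.value < 0) or np.any(self.value > 1 + 1e-12)
        ):
            raise ValueError("transmission values must lie in [0, 1]")

    def at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value; errors outside the grid."""
        w = self.wavelength_nm
        if not w[0] <= wavelength_nm <= w[-1]:
            raise ValueError(f"{wavelength_nm} nm outside the spectral grid")
        return float(np.interp(wavelength_nm, w, self.value))


@dataclass
class CellGeometry:
    """Hollow-sphere model of the pigmented thylakoid region."""

    cell_diameter_um: float = 3.0
    shell_inner_diameter_um: float = 1.0
    shell_outer_diameter_um: float = 2.0
    central_path_length_um: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.shell_inner_diameter_um
                <= self.shell_outer_diameter_um
                <= self.cell_diameter_um):
            raise ValueError("need inner <= outer <= cell diameter")
        if self.central_path_length_um <= 0:
            raise ValueError("central path length must be > 0")


@dataclass
class Pigment:
    name: str
    molecules_per_cell: float
    extinction: Spectrum  # molar extinction, M^-1 cm^-1, vs wavelength

    def __post_init__(self) -> None:
        if self.molecules_per_cell < 0:
            raise ValueError("molecule count must be >= 0")
        if np.any(self.extinction.value < 0):
            raise ValueError("extinction coefficients must be >= 0")


@dataclass
class PigmentModel:
    pigments: list[Pigment] = field(default_factory=list)


def subtract_scatter_baseline(
    suspension: Spectrum, ref_wavelength_nm: float = 750.0
) -> Spectrum:
    """Remove the scattering offset: OD(lambda) - OD(ref), clipped at zero.

    Suspension optical density includes a wavelength-flat scattering
    contribution estimated at a wavelength where pigments do not absorb
    (750 nm by default).  Negative results after subtraction are clipped
    to zero and counted in the log.
    """
    offset = suspension.at(ref_wavelength_nm)
    v = suspension.value - offset
    n_neg = int(np.sum(v < 0))
    if n_neg:
        log.info("baseline subtraction clipped %d negative values to 0", n_neg)
    return Spectrum(suspension.wavelength_nm, np.clip(v, 0.0, None), "absorbance")


def shell_volume_um3(geom: CellGeometry) -> float:
    """Volume of the hollow spherical shell, µm³."""
    ro = geom.shell_outer_diameter_um / 2.0
    ri = geom.shell_inner_diameter_um / 2.0
    return float(4.0 / 3.0 * np.pi * (ro**3 - ri**3))


def effective_concentration_mM(molecules: float, volume_um3: float) -> float:
    """Molar concentration (in mM) of N molecules in a volume in µm³."""
    if volume_um3 <= 0:
        raise ValueError("volume must be > 0")
    litres = volume_um3 * 1e-15  # 1 um^3 = 1e-15 L
    molar = molecules / AVOGADRO / litres
    return float(molar * 1e3)


def beer_lambert(extinction_M_cm, concentration_mM: float,
                 path_um: float) -> float | np.ndarray:
    """Absorbance A = eps * c * L with eps in 1/(M cm), c in mM, L in µm."""
    if concentration_mM < 0 or path_um < 0:
        raise ValueError("inputs must be non-negative")
    return np.asarray(extinction_M_cm) * (concentration_mM * 1e-3) * (path_um * 1e-4)


def pigment_absorbance(model: PigmentModel, geom: CellGeometry,
                       wavelength_nm) -> np.ndarray:
    """Central-chord absorbance spectrum summed over pigments."""
    w = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
    vol = shell_volume_um3(geom)
    total = np.zeros_like(w)
    for p in model.pigments:
        c = effective_concentration_mM(p.molecules_per_cell, vol)
        eps = np.interp(w, p.extinction.wavelength_nm, p.extinction.value)
        total = total + beer_lambert(eps, c, geom.central_path_length_um)
    return total


def scale_to_single_cell(
    suspension_baselined: Spectrum,
    target_peak_absorbance: float,
    peak_wavelength_nm: float = 620.0,
) -> Spectrum:
    """Rescale a suspension spectrum so it equals a target at the peak.

    The suspension absorbance spectrum has the right shape but arbitrary
    magnitude (it depends on cell density); the single-cell absorbance at
    the reference peak, computed independently from pigment content and
    geometry, fixes the scale.
    """
    cur = suspension_baselined.at(peak_wavelength_nm)
    if cur <= 0:
        raise ValueError("suspension spectrum is zero at the scaling wavelength")
    k = target_peak_absorbance / cur
    return Spectrum(suspension_baselined.wavelength_nm,
                    suspension_baselined.value * k, "absorbance")


def to_transmission(cell_abs: Spectrum) -> Spectrum:
    """T(lambda) = 10^(-A(lambda))."""
    if np.any(cell_abs.value < 0):
        raise ValueError("absorbance must be >= 0")
    return Spectrum(cell_abs.wavelength_nm, 10.0 ** (-cell_abs.value),
                    "transmission")


def absorbed_fraction(absorbance) -> float | np.ndarray:
    """Fraction of photons absorbed: 1 - 10^(-A)."""
    a = np.asarray(absorbance, dtype=float)
    out = 1.0 - 10.0 ** (-a)
    return float(out) if np.ndim(absorbance) == 0 else out


def decompose_pigments(
    baselined: Spectrum, bases: list[Spectrum]
) -> np.ndarray:
    """Non-negative least-squares weights of basis spectra in a spectrum.

    Each basis is interpolated onto the target grid; returns one
    non-negative coefficient per basis (concentration x path, in whatever
    units the bases carry).
    """
    if not bases:
        raise ValueError("need at least one basis spectrum")
    w = baselined.wavelength_nm
    A = np.column_stack([
        np.interp(w, b.wavelength_nm, b.value) for b in bases
    ])
    coef, _ = nnls(A, baselined.value)
    return coef
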