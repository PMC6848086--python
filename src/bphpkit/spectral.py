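"""Two-state photochrome spectra: basis sets, mixtures, peaks, and unmixing.

A bacteriophytochrome interconverts between a red-absorbing state (Pr) and a
far-red-absorbing state (Pfr).  Any measured absorption spectrum of a sample
is, by Beer-Lambert linearity, a non-negative combination of the two pure
state spectra:

    A(lambda) = c * l * (f_pr * eps_pr(lambda) + f_pfr * eps_pfr(lambda))

with ``c*l`` the concentration-pathlength product (M cm), ``eps`` the molar
extinction coefficients (M^-1 cm^-1, possibly on a relative scale) and
``f_pr + f_pfr = 1`` the state fractions.  This module holds the basis
container and the forward (mixing, difference spectra) and inverse
(peak/isosbestic location, non-negative least-squares unmixing) operations
built on that linearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "GRID_MIN_NM",
    "GRID_MAX_NM",
    "GRID_STEP_NM",
    "default_grid",
    "GroundState",
    "State",
    "ChromophoreBasis",
    "SpectrumMeasurement",
    "StateFractions",
    "IsosbesticResult",
    "UnmixResult",
    "mixture_spectrum",
    "difference_spectrum",
    "find_peak",
    "find_isosbestic",
    "unmix",
]

# Standard wavelength grid covering the Soret (~400 nm) and Q (600-800 nm)
# bands of biliverdin-binding phytochromes.
GRID_MIN_NM = 250.0
GRID_MAX_NM = 850.0
GRID_STEP_NM = 1.0

# Unmixing is restricted to the Q-band region by default: the Soret band is
# state-insensitive in these proteins and carries no mixture information.
DEFAULT_UNMIX_WINDOW = (600.0, 850.0)


def default_grid() -> np.ndarray:
    """The standard 1-nm wavelength grid, 250-850 nm inclusive."""
    return np.arange(GRID_MIN_NM, GRID_MAX_NM + 0.5 * GRID_STEP_NM, GRID_STEP_NM)


class GroundState(Enum):
    """Which state the protein thermally reverts to in darkness."""

    PR_GROUND = "pr_ground"
    PFR_GROUND = "pfr_ground"


class State(Enum):
    PR = "pr"
    PFR = "pfr"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ChromophoreBasis:
    """Pure Pr and Pfr extinction-coefficient spectra on a common grid.

    Parameters
    ----------
    protein_id : str
        Label for the protein the basis describes.
    wavelengths : array
        Strictly increasing wavelength grid, nm.
    eps_pr, eps_pfr : array
        Extinction coefficients of the pure Pr / Pfr states per grid point,
        M^-1 cm^-1 (a relative scale is permitted; only ratios enter most of
        the downstream algebra).
    ground_state : GroundState
        The dark-adapted (thermal ground) state.
    """

    protein_id: str
    wavelengths: np.ndarray
    eps_pr: np.ndarray
    eps_pfr: np.ndarray
    ground_state: GroundState

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelengths, "wavelengths")
        pr = _as_float_array(self.eps_pr, "eps_pr")
        pfr = _as_float_array(self.eps_pfr, "eps_pfr")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing with >= 2 points")
        if pr.shape != wl.shape or pfr.shape != wl.shape:
            raise ValueError("eps arrays must match the wavelength grid length")
        if np.any(pr < 0) or np.any(pfr < 0):
            raise ValueError("extinction coefficients must be non-negative")
        if not isinstance(self.ground_state, GroundState):
            raise TypeError("ground_state must be a GroundState enum member")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "eps_pr", pr)
        object.__setattr__(self, "eps_pfr", pfr)

    def eps(self, state: State, wavelength_nm) -> np.ndarray | float:
        """Extinction coefficient of a pure state at given wavelength(s).

        Off-grid wavelengths are linearly interpolated; wavelengths outside
        the grid raise ``ValueError``.
        """
        wl = np.asarray(wavelength_nm, dtype=float)
        if np.any(wl < self.wavelengths[0]) or np.any(wl > self.wavelengths[-1]):
            raise ValueError(
                f"wavelength outside basis grid "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        eps = self.eps_pr if state is State.PR else self.eps_pfr
        out = np.interp(wl, self.wavelengths, eps)
        return float(out) if np.isscalar(wavelength_nm) else out

    def ground_eps(self) -> np.ndarray:
        return self.eps_pr if self.ground_state is GroundState.PR_GROUND else self.eps_pfr

    def photoproduct_state(self) -> State:
        return State.PFR if self.ground_state is GroundState.PR_GROUND else State.PR


@dataclass
class SpectrumMeasurement:
    """An absorbance spectrum: wavelength grid plus dimensionless absorbance."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.absorbance = _as_float_array(self.absorbance, "absorbance")
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must have the same length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class StateFractions:
    """Population fractions of the two states; must sum to one."""

    f_pr: float
    f_pfr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_pr <= 1.0 and 0.0 <= self.f_pfr <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(self.f_pr + self.f_pfr - 1.0) > 1e-9:
            raise ValueError("f_pr + f_pfr must equal 1 within 1e-9")

    @classmethod
    def from_pfr(cls, f_pfr: float) -> "StateFractions":
        return cls(f_pr=1.0 - f_pfr, f_pfr=f_pfr)


@dataclass(frozen=True)
class IsosbesticResult:
    """Location of an isosbestic (equal-extinction) crossing."""

    wavelength_nm: float
    n_crossings: int


@dataclass(frozen=True)
class UnmixResult:
    fractions: StateFractions
    scale: float  # fitted concentration-pathlength product, M cm
    residual_norm: float
    collinear: bool


def mixture_spectrum(
    basis: ChromophoreBasis,
    fractions: StateFractions,
    concentration_pathlength: float,
) -> SpectrumMeasurement:
    """Noiseless Beer-Lambert spectrum of a Pr/Pfr mixture.

    ``A(lambda) = c*l * (f_pr eps_pr + f_pfr eps_pfr)``.
    """
    if concentration_pathlength < 0:
        raise ValueError("concentration_pathlength must be >= 0")
    absorbance = concentration_pathlength * (
        fractions.f_pr * basis.eps_pr + fractions.f_pfr * basis.eps_pfr
    )
    return SpectrumMeasurement(basis.wavelengths.copy(), absorbance, noise_sigma=0.0)


def difference_spectrum(
    light: SpectrumMeasurement, dark: SpectrumMeasurement
) -> SpectrumMeasurement:
    """Pointwise light-minus-dark spectrum on the overlapping grid.

    If the grids differ, the dark spectrum is linearly interpolated onto the
    light grid restricted to the common wavelength range.  Disjoint ranges
    raise ``ValueError``.
    """
    lo = max(light.wavelengths[0], dark.wavelengths[0])
    hi = min(light.wavelengths[-1], dark.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectra have disjoint wavelength ranges")
    mask = (light.wavelengths >= lo) & (light.wavelengths <= hi)
    wl = light.wavelengths[mask]
    if wl.size < 2:
        raise ValueError("fewer than two overlapping wavelengths")
    dark_interp = np.interp(wl, dark.wavelengths, dark.absorbance)
    sigma = float(np.hypot(light.noise_sigma, dark.noise_sigma))
    return SpectrumMeasurement(wl, light.absorbance[mask] - dark_interp, sigma)


def find_peak(
    spectrum: SpectrumMeasurement, search_window: tuple[float, float]
) -> float:
    """Wavelength of the absorbance maximum within a window, in nm.

    The discrete maximum (ties broken toward the lowest wavelength) is
    refined by parabolic interpolation through the three surrounding grid
    points, so sub-grid peak positions are resolved; a maximum at the window
    edge is returned unrefined.
    """
    lo, hi = float(search_window[0]), float(search_window[1])
    if lo >= hi:
        raise ValueError("search window must satisfy lo < hi")
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not mask.any():
        raise ValueError("search window contains no grid points")
    wl = spectrum.wavelengths[mask]
    y = spectrum.absorbance[mask]
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(wl[i])
    # Parabola through (i-1, i, i+1); assumes locally uniform spacing.
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0 or abs(denom) < 1e-300:
        return float(wl[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = 0.5 * (wl[i + 1] - wl[i - 1])
    return float(wl[i] + np.clip(delta, -1.0, 1.0) * step)


def find_isosbestic(
    basis: ChromophoreBasis, search_window: tuple[float, float]
) -> IsosbesticResult:
    """Locate the wavelength where eps_pr - eps_pfr changes sign.

    Crossings are bracketed on the grid and refined by linear interpolation.
    If several crossings fall inside the window, the one nearest the window
    center is returned and the total count is reported.
    """
    lo, hi = float(search_window[0]), float(search_window[1])
    mask = (basis.wavelengths >= lo) & (basis.wavelengths <= hi)
    if mask.sum() < 2:
        raise ValueError("search window contains fewer than two grid points")
    wl = basis.wavelengths[mask]
    d = (basis.eps_pr - basis.eps_pfr)[mask]
    scale = max(basis.eps_pr.max(), basis.eps_pfr.max())
    if np.all(np.abs(d) <= 1e-12 * scale):
        raise ValueError("eps_pr and eps_pfr coincide in window: no isolated crossing")
    crossings: list[float] = []
    sign = np.sign(d)
    for i in range(d.size - 1):
        if sign[i] == 0.0:
            if 0 < i and sign[i - 1] * sign[i + 1] < 0:
                crossings.append(float(wl[i]))
            continue
        if sign[i] * sign[i + 1] < 0:
            # linear interpolation between bracketing grid points
            t = d[i] / (d[i] - d[i + 1])
            crossings.append(float(wl[i] + t * (wl[i + 1] - wl[i])))
    if not crossings:
        raise ValueError("eps_pr - eps_pfr does not change sign in window")
    center = 0.5 * (lo + hi)
    best = min(crossings, key=lambda x: abs(x - center))
    return IsosbesticResult(wavelength_nm=best, n_crossings=len(crossings))


def unmix(
    spectrum: SpectrumMeasurement,
    basis: ChromophoreBasis,
    window: tuple[float, float] = DEFAULT_UNMIX_WINDOW,
) -> UnmixResult:
    """Estimate state fractions from a measured spectrum.

    Non-negative least squares for the coefficients ``a_pr, a_pfr`` in
    ``A = a_pr eps_pr + a_pfr eps_pfr``; fractions are ``a_i / (a_pr+a_pfr)``
    and the coefficient sum is the fitted concentration-pathlength product.
    Fractions are physical populations, hence the non-negativity constraint.

    A nearly collinear basis (condition number > 1e8 on the window) is
    flagged: the fitted fractions are then unreliable.
    """
    lo = max(window[0], basis.wavelengths[0], spectrum.wavelengths[0])
    hi = min(window[1], basis.wavelengths[-1], spectrum.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectrum, basis and window do not overlap")
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    wl = spectrum.wavelengths[mask]
    if wl.size < 10:
        raise ValueError("need >= 10 wavelengths overlapping the basis window")
    y = spectrum.absorbance[mask]
    if np.allclose(y, 0.0):
        raise ValueError("all-zero spectrum cannot be unmixed")
    design = np.column_stack(
        [
            np.interp(wl, basis.wavelengths, basis.eps_pr),
            np.interp(wl, basis.wavelengths, basis.eps_pfr),
        ]
    )
    collinear = bool(np.linalg.cond(design) > 1e8)
    if collinear:
        warnings.warn(
            "basis spectra are nearly collinear on the unmixing window; "
            "fractions are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    coef, residual = nnls(design, y)
    total = float(coef.sum())
    if total <= 0:
        raise ValueError("unmixing produced zero total amplitude")
    fractions = StateFractions(f_pr=float(coef[0] / total), f_pfr=float(coef[1] / total))
    return UnmixResult(
        fractions=fractions,
        scale=total,
        residual_norm=float(residual),
        collinear=collinear,
    )
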