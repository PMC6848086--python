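"""Two-state Pr/Pfr population kinetics under illumination and darkness.

The population dynamics are a single linear ODE in the Pfr fraction f:

    df/dt = A_fwd * (1 - f) - A_rev * f  [+ dark-reversion terms]

where ``A_fwd = sum_j k_Pr,j * phi_fwd`` is the total Pr->Pfr photoconversion
rate summed over light sources (and symmetrically for ``A_rev``).  The
per-molecule excitation rate under a source of irradiance E (umol photons
m^-2 s^-1) at wavelength lambda is

    k = ln(10) * 1e-7 * eps(lambda) * E      [s^-1]

with eps in M^-1 cm^-1.  The constant converts the decadic molar extinction
coefficient into an absorption cross-section (sigma_cm2 = 1000 ln(10) eps /
N_A) and the irradiance into a photon flux per cm^2 (1 umol m^-2 s^-1 =
1e-6 N_A * 1e-4 photons cm^-2 s^-1); Avogadro's number cancels.

Thermal (dark) reversion drives the photoproduct back to the ground state,
possibly as a sum of exponentials (parallel subpopulations with fixed
amplitude fractions).  Within each protocol segment the coefficients are
constant, so the trajectory has a closed-form solution; a generic stiff ODE
integration of the same piecewise model is provided as an independent path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .spectral import (
    ChromophoreBasis,
    GroundState,
    SpectrumMeasurement,
    State,
    StateFractions,
)

__all__ = [
    "PHOTON_RATE_CONSTANT",
    "DarkComponent",
    "PhotochromeParams",
    "LightSource",
    "ProtocolSegment",
    "IlluminationProtocol",
    "StateTrajectory",
    "excitation_rate",
    "photostationary_fraction",
    "relaxation_rate",
    "simulate_protocol",
]

#: s^-1 per (M^-1 cm^-1 of extinction x umol photons m^-2 s^-1 of irradiance).
PHOTON_RATE_CONSTANT = math.log(10.0) * 1e-7  # ~2.3026e-7


@dataclass(frozen=True)
class DarkComponent:
    """One exponential component of thermal reversion toward the ground state."""

    amplitude_fraction: float
    rate: float  # s^-1

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude_fraction <= 1.0:
            raise ValueError("amplitude_fraction must lie in (0, 1]")
        if self.rate <= 0:
            raise ValueError("dark-reversion rate must be > 0")

    @property
    def half_time_s(self) -> float:
        return math.log(2.0) / self.rate


@dataclass(frozen=True)
class PhotochromeParams:
    """Photochemical parameters of a two-state photochrome.

    ``phi_fwd`` is the quantum yield of Pr -> Pfr, ``phi_rev`` of Pfr -> Pr,
    regardless of which state is the thermal ground state.
    """

    phi_fwd: float
    phi_rev: float
    ground_state: GroundState
    dark_components: tuple[DarkComponent, ...] = ()

    def __post_init__(self) -> None:
        for name, phi in (("phi_fwd", self.phi_fwd), ("phi_rev", self.phi_rev)):
            if not 0.0 < phi <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        comps = tuple(self.dark_components)
        if comps:
            total = sum(c.amplitude_fraction for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("dark amplitude fractions must sum to 1")
        object.__setattr__(self, "dark_components", comps)

    @property
    def mean_dark_rate(self) -> float:
        """Amplitude-weighted mean reversion rate (0 with no components), s^-1."""
        return sum(c.amplitude_fraction * c.rate for c in self.dark_components)

    @property
    def yield_ratio_to_photoproduct(self) -> float:
        """Quantum yield toward the photoproduct over the reverse yield."""
        if self.ground_state is GroundState.PR_GROUND:
            return self.phi_fwd / self.phi_rev
        return self.phi_rev / self.phi_fwd


@dataclass(frozen=True)
class LightSource:
    wavelength: float  # nm
    irradiance: float  # umol photons m^-2 s^-1

    def __post_init__(self) -> None:
        if self.irradiance < 0:
            raise ValueError("irradiance must be >= 0")


@dataclass(frozen=True)
class ProtocolSegment:
    sources: tuple[LightSource, ...]
    duration: float  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        object.__setattr__(self, "sources", tuple(self.sources))

    @property
    def is_dark(self) -> bool:
        return len(self.sources) == 0


@dataclass(frozen=True)
class IlluminationProtocol:
    """Ordered illumination segments plus the wavelengths to observe."""

    segments: tuple[ProtocolSegment, ...]
    observation_wavelengths: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(
            self, "observation_wavelengths", tuple(float(w) for w in self.observation_wavelengths)
        )

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])


@dataclass
class StateTrajectory:
    """Time course of the Pfr fraction with derived absorbance traces."""

    times: np.ndarray  # s, strictly increasing
    f_pfr: np.ndarray
    wavelengths: tuple[float, ...] = ()
    absorbance: np.ndarray | None = None  # shape (n_wavelengths, n_times)
    segment_boundaries: np.ndarray | None = None  # s
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f_pfr = np.asarray(self.f_pfr, dtype=float)
        if self.times.shape != self.f_pfr.shape:
            raise ValueError("times and f_pfr must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def f_pr(self) -> np.ndarray:
        return 1.0 - self.f_pfr

    def trace(self, wavelength_nm: float) -> np.ndarray:
        """Absorbance trace at one of the observation wavelengths."""
        if self.absorbance is None:
            raise ValueError("trajectory carries no absorbance traces")
        for i, w in enumerate(self.wavelengths):
            if abs(w - wavelength_nm) < 1e-9:
                return self.absorbance[i]
        raise KeyError(f"{wavelength_nm} nm is not an observation wavelength")


def excitation_rate(
    basis: ChromophoreBasis, state: State, source: LightSource
) -> float:
    """Per-molecule photon-absorption rate of a pure state under a source, s^-1.

    ``k = ln(10)*1e-7 * eps_state(lambda) * E``; e.g. eps = 80 000 M^-1 cm^-1
    at E = 60 umol m^-2 s^-1 gives k ~ 1.1 s^-1.  Off-grid wavelengths inside
    the basis range are interpolated; outside the range is an error.
    """
    eps = basis.eps(state, source.wavelength)
    return PHOTON_RATE_CONSTANT * float(eps) * source.irradiance


def _conversion_rates(
    basis: ChromophoreBasis,
    params: PhotochromeParams,
    sources: tuple[LightSource, ...] | list[LightSource],
) -> tuple[float, float]:
    """Total photoconversion rates (A_fwd: Pr->Pfr, A_rev: Pfr->Pr), s^-1."""
    a_fwd = sum(params.phi_fwd * excitation_rate(basis, State.PR, s) for s in sources)
    a_rev = sum(params.phi_rev * excitation_rate(basis, State.PFR, s) for s in sources)
    return float(a_fwd), float(a_rev)


def _stationary_pfr(
    a_fwd: float, a_rev: float, k_dark: float, ground_state: GroundState
) -> float:
    denom = a_fwd + a_rev + k_dark
    if denom <= 0:
        raise ValueError("all rates are zero: no stationary state is defined")
    if ground_state is GroundState.PR_GROUND:
        return a_fwd / denom
    return (a_fwd + k_dark) / denom


def photostationary_fraction(
    basis: ChromophoreBasis,
    params: PhotochromeParams,
    sources: list[LightSource] | tuple[LightSource, ...],
    include_dark_reversion: bool = False,
) -> StateFractions:
    """Closed-form steady state of the two-state system under the sources.

    With dark reversion off this is the strong-light photostationary state,
    ``f_pfr = A_fwd / (A_fwd + A_rev)``, the balance the quantum-yield
    deductions rest on.  With the flag on, the amplitude-weighted mean dark
    rate adds to the flow toward the ground state.
    """
    a_fwd, a_rev = _conversion_rates(basis, params, sources)
    k = params.mean_dark_rate if include_dark_reversion else 0.0
    f_pfr = _stationary_pfr(a_fwd, a_rev, k, params.ground_state)
    return StateFractions.from_pfr(f_pfr)


def relaxation_rate(
    basis: ChromophoreBasis,
    params: PhotochromeParams,
    sources: list[LightSource] | tuple[LightSource, ...],
) -> float:
    """Mono-exponential rate of approach to the stationary state, s^-1.

    ``A_fwd + A_rev + k_dark`` with ``k_dark`` the amplitude-weighted mean
    reversion rate.
    """
    a_fwd, a_rev = _conversion_rates(basis, params, sources)
    return a_fwd + a_rev + params.mean_dark_rate


def _segment_grid(duration: float, dt: float) -> np.ndarray:
    n = max(2, int(math.ceil(duration / dt)) + 1)
    return np.linspace(0.0, duration, n)


def _dark_decay_analytic(
    f_nonground0: float, params: PhotochromeParams, local_t: np.ndarray
) -> np.ndarray:
    """Multi-exponential non-ground fraction during a dark segment.

    The non-ground population is partitioned into the fixed amplitude
    fractions at segment start (parallel subpopulations), each decaying with
    its own rate.
    """
    if not params.dark_components:
        return np.full_like(local_t, f_nonground0)
    out = np.zeros_like(local_t)
    for comp in params.dark_components:
        out += comp.amplitude_fraction * np.exp(-comp.rate * local_t)
    return f_nonground0 * out


def _nonground(f_pfr: float, ground_state: GroundState) -> float:
    return f_pfr if ground_state is GroundState.PR_GROUND else 1.0 - f_pfr


def _to_pfr(f_nonground: np.ndarray | float, ground_state: GroundState):
    return f_nonground if ground_state is GroundState.PR_GROUND else 1.0 - f_nonground


def simulate_protocol(
    basis: ChromophoreBasis,
    params: PhotochromeParams,
    protocol: IlluminationProtocol,
    initial: StateFractions,
    dt: float | None = None,
    method: str = "analytic",
    concentration_pathlength: float | None = None,
) -> StateTrajectory:
    """Simulate the Pfr fraction through an illumination protocol.

    Per segment the model has constant coefficients: illuminated segments
    follow the single-exponential relaxation toward the photostationary
    state (multiphasic dark reversion entering through its mean rate, since
    illumination rates dominate there); dark segments follow the
    multi-exponential reversion with amplitude fractions re-equilibrated at
    segment start.  ``method="ode"`` integrates the same piecewise model
    with a stiff solver as an independent numerical path.

    ``dt`` defaults to 1/1000 of each segment duration; if given it must not
    exceed a tenth of the shortest segment.  Absorbance traces at the
    protocol's observation wavelengths are computed by Beer-Lambert mixing;
    ``concentration_pathlength`` defaults to ``1 / max(eps)`` so the
    strongest pure-state band has unit absorbance.
    """
    if method not in ("analytic", "ode"):
        raise ValueError("method must be 'analytic' or 'ode'")
    shortest = min(s.duration for s in protocol.segments)
    if dt is not None:
        if dt <= 0:
            raise ValueError("dt must be > 0")
        if dt > shortest / 10.0:
            raise ValueError("dt must be <= shortest segment duration / 10")
    if concentration_pathlength is None:
        concentration_pathlength = 1.0 / max(basis.eps_pr.max(), basis.eps_pfr.max())

    gs = params.ground_state
    times: list[np.ndarray] = []
    fs: list[np.ndarray] = []
    t0 = 0.0
    f = float(initial.f_pfr)
    for seg in protocol.segments:
        local_t = _segment_grid(seg.duration, dt if dt is not None else seg.duration / 1000.0)
        if seg.is_dark:
            ng0 = _nonground(f, gs)
            if method == "analytic":
                ng = _dark_decay_analytic(ng0, params, local_t)
            else:
                ng = _ode_dark(ng0, params, local_t)
            seg_f = np.asarray(_to_pfr(ng, gs), dtype=float)
        else:
            a_fwd, a_rev = _conversion_rates(basis, params, seg.sources)
            k = params.mean_dark_rate
            lam = a_fwd + a_rev + k
            if lam <= 0:
                seg_f = np.full_like(local_t, f)
            elif method == "analytic":
                f_ss = _stationary_pfr(a_fwd, a_rev, k, gs)
                seg_f = f_ss + (f - f_ss) * np.exp(-lam * local_t)
            else:
                seg_f = _ode_light(f, a_fwd, a_rev, k, gs, local_t)
        times.append(t0 + local_t)
        fs.append(seg_f)
        t0 += seg.duration
        f = float(seg_f[-1])

    # concatenate, dropping duplicated segment-boundary points
    all_t = [times[0]]
    all_f = [fs[0]]
    for t_arr, f_arr in zip(times[1:], fs[1:]):
        all_t.append(t_arr[1:])
        all_f.append(f_arr[1:])
    t_full = np.concatenate(all_t)
    f_full = np.clip(np.concatenate(all_f), 0.0, 1.0)

    wavelengths = protocol.observation_wavelengths
    absorbance = None
    if wavelengths:
        eps_pr = np.array([basis.eps(State.PR, w) for w in wavelengths])
        eps_pfr = np.array([basis.eps(State.PFR, w) for w in wavelengths])
        absorbance = concentration_pathlength * (
            np.outer(eps_pr, 1.0 - f_full) + np.outer(eps_pfr, f_full)
        )
    return StateTrajectory(
        times=t_full,
        f_pfr=f_full,
        wavelengths=wavelengths,
        absorbance=absorbance,
        segment_boundaries=protocol.boundaries(),
    )


def _ode_light(
    f0: float,
    a_fwd: float,
    a_rev: float,
    k_dark: float,
    gs: GroundState,
    local_t: np.ndarray,
) -> np.ndarray:
    sign = -1.0 if gs is GroundState.PR_GROUND else 1.0

    def rhs(_t, y):
        f = y[0]
        dark = sign * k_dark * (_nonground(f, gs))
        return [a_fwd * (1.0 - f) - a_rev * f + dark]

    sol = solve_ivp(
        rhs,
        (local_t[0], local_t[-1]),
        [f0],
        method="Radau",
        t_eval=local_t,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


def _ode_dark(
    ng0: float, params: PhotochromeParams, local_t: np.ndarray
) -> np.ndarray:
    if not params.dark_components:
        return np.full_like(local_t, ng0)
    rates = np.array([c.rate for c in params.dark_components])
    y0 = ng0 * np.array([c.amplitude_fraction for c in params.dark_components])

    def rhs(_t, y):
        return -rates * y

    sol = solve_ivp(
        rhs,
        (local_t[0], local_t[-1]),
        y0,
        method="Radau",
        t_eval=local_t,
        rtol=1e-10,
        atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.sum(axis=0)
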