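"""Inverse problems on the two-state photocycle.

Three estimators:

* ``qy_ratio_from_stationary`` — the photostationary-state deduction: at a
  single effective wavelength the steady-state balance
  ``phi_prod * eps_ground * f_ground = phi_rev * eps_prod * f_prod`` inverts
  to a quantum-yield ratio given the observed remaining ground-state
  fraction and the extinction ratio at the excitation wavelength.
* ``fit_dark_reversion`` — mono/bi-exponential fits of thermal reversion
  traces with small-sample-corrected AIC model selection.
* ``recover_params_from_protocol`` — joint recovery of quantum yields and
  an effective dark rate from stationary levels and relaxation rates of a
  simulated (or measured) multi-wavelength protocol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    DarkComponent,
    IlluminationProtocol,
    LightSource,
    PhotochromeParams,
    StateTrajectory,
    excitation_rate,
)
from .spectral import ChromophoreBasis, GroundState, State

__all__ = [
    "PhotostationaryObservation",
    "DecayFit",
    "ParamRecovery",
    "qy_ratio_from_stationary",
    "fit_dark_reversion",
    "recover_params_from_protocol",
]


@dataclass(frozen=True)
class PhotostationaryObservation:
    """A steady-state observation under a single effective wavelength.

    ``f_ground_remaining`` is the fraction of the dark-adapted (ground)
    state left at the photostationary state; ``sigma_ratio`` is
    eps_photoproduct / eps_ground at the excitation wavelength.
    """

    sources: tuple[LightSource, ...]
    f_ground_remaining: float
    sigma_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_ground_remaining <= 1.0:
            raise ValueError("f_ground_remaining must lie in [0, 1]")
        if self.sigma_ratio <= 0:
            raise ValueError("sigma_ratio must be > 0")
        object.__setattr__(self, "sources", tuple(self.sources))


def qy_ratio_from_stationary(obs: PhotostationaryObservation) -> float:
    """Quantum-yield ratio (toward photoproduct / reverse) from a steady state.

    ``ratio = [f_prod / (1 - f_prod)] * sigma_ratio`` with
    ``f_prod = 1 - f_ground_remaining``; the exact inverse of the
    strong-light photostationary fraction.  An observation at exactly 0 or 1
    leaves the ratio unidentifiable.
    """
    f_prod = 1.0 - obs.f_ground_remaining
    if f_prod <= 0.0 or f_prod >= 1.0:
        raise ValueError("ratio is unidentifiable at f_product of exactly 0 or 1")
    return f_prod / (1.0 - f_prod) * obs.sigma_ratio


@dataclass(frozen=True)
class DecayFit:
    """Result of an exponential decay fit.

    ``amplitudes`` are normalized component weights (sum to 1), ``rates``
    the corresponding rate constants in inverse time units of the input.
    ``half_time`` is ln2 / rate of the dominant (largest-amplitude)
    component, in the time units of the input.
    """

    n_components: int
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    baseline: float
    total_amplitude: float
    half_time: float
    criterion_scores: dict[int, float]

    @property
    def dominant_rate(self) -> float:
        return self.rates[int(np.argmax(self.amplitudes))]


def _exp_model(theta: np.ndarray, t: np.ndarray, n: int) -> np.ndarray:
    c = theta[0]
    out = np.full_like(t, c)
    for i in range(n):
        out = out + theta[1 + i] * np.exp(-np.exp(theta[1 + n + i]) * t)
    return out


def _aicc(rss: float, n_obs: int, n_params: int) -> float:
    rss = max(rss, 1e-300 * n_obs)
    score = n_obs * math.log(rss / n_obs) + 2 * n_params
    if n_obs - n_params - 1 > 0:
        score += 2 * n_params * (n_params + 1) / (n_obs - n_params - 1)
    return score


def _initial_rate_guess(t: np.ndarray, y: np.ndarray, baseline: float) -> float:
    """Rate guess from log-linear regression of the relaxing tail."""
    dev = np.abs(y - baseline)
    top = dev[0] if dev[0] > 0 else dev.max()
    mask = (dev > 0.02 * top) & (dev < 0.9 * top)
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(dev[mask]), 1)[0]
        if slope < 0:
            return -slope
    span = t[-1] - t[0]
    return 3.0 / span if span > 0 else 1.0


def fit_dark_reversion(
    trace,
    signal=None,
    max_components: int = 2,
) -> DecayFit:
    """Fit a (multi)exponential relaxation toward a baseline.

    Accepts a :class:`~bphpkit.kinetics.StateTrajectory` (its Pfr-fraction
    time course is fitted) or a pair of arrays ``(t, signal)``.  Models with
    1..``max_components`` exponentials are fitted by bounded nonlinear least
    squares (initialized from a log-linear regression of the tail) and
    compared by small-sample-corrected AIC; the more complex model must win
    by at least 2 to be selected, since visual multiphasicity alone does not
    justify extra components.  Relaxations in either direction (decay or
    recovery toward the baseline) are handled.
    """
    if isinstance(trace, StateTrajectory):
        t = trace.times
        y = trace.f_pfr
    else:
        if signal is None:
            raise ValueError("provide a StateTrajectory or both time and signal arrays")
        t = np.asarray(trace, dtype=float)
        y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and signal must be 1-d arrays of equal length")
    if t.size < 20:
        raise ValueError("need >= 20 samples to fit a relaxation")
    if not (1 <= max_components <= 3):
        raise ValueError("max_components must be 1, 2 or 3")

    order = np.argsort(t)
    t = t[order] - t[order][0]
    y = y[order]
    scale = float(np.max(np.abs(y))) or 1.0
    n_tail = max(3, t.size // 20)
    baseline0 = float(np.mean(y[-n_tail:]))
    amp0 = float(np.mean(y[:3])) - baseline0
    if abs(amp0) <= 1e-8 * scale:
        raise ValueError("trace does not relax: no decaying component to fit")

    k0 = _initial_rate_guess(t, y, baseline0)
    fits: dict[int, tuple[float, np.ndarray]] = {}
    scores: dict[int, float] = {}
    for n in range(1, max_components + 1):
        if n == 1:
            theta0 = np.array([baseline0, amp0, math.log(k0)])
        else:
            split = np.linspace(0.6, 0.4, 2) if n == 2 else np.full(n, 1.0 / n)
            spread = np.geomspace(3.0, 1.0 / 3.0, n)
            theta0 = np.concatenate(
                [[baseline0], amp0 * split, np.log(k0 * spread)]
            )
        lo = np.concatenate(
            [[-np.inf], np.full(n, -np.inf), np.full(n, math.log(k0) - 14.0)]
        )
        hi = np.concatenate(
            [[np.inf], np.full(n, np.inf), np.full(n, math.log(k0) + 14.0)]
        )
        try:
            res = least_squares(
                lambda th: _exp_model(th, t, n) - y,
                theta0,
                bounds=(lo, hi),
                method="trf",
                max_nfev=20000,
            )
        except Exception:  # numerically degenerate fit for this n
            continue
        rss = float(np.sum(res.fun**2))
        p = 1 + 2 * n
        scores[n] = _aicc(rss, t.size, p)
        fits[n] = (rss, res.x)

    if 1 not in fits:
        raise ValueError("mono-exponential fit failed; trace may not relax")

    best_n = 1
    for n in sorted(fits):
        if n == 1:
            continue
        amps = fits[n][1][1 : 1 + n]
        rates = np.exp(fits[n][1][1 + n : 1 + 2 * n])
        same_sign = np.all(amps > 0) or np.all(amps < 0)
        distinct = rates.max() / max(rates.min(), 1e-300) > 1.2
        well_posed = same_sign and distinct and np.all(np.isfinite(rates))
        if well_posed and scores[n] <= scores[best_n] - 2.0:
            best_n = n
        elif not well_posed and scores.get(n, np.inf) < scores[best_n] - 2.0:
            warnings.warn(
                f"{n}-component fit is ill-conditioned; keeping {best_n} component(s)",
                RuntimeWarning,
                stacklevel=2,
            )

    _, theta = fits[best_n]
    n = best_n
    amps = theta[1 : 1 + n]
    rates = np.exp(theta[1 + n : 1 + 2 * n])
    total = float(np.sum(amps))
    weights = np.abs(amps) / np.sum(np.abs(amps))
    order = np.argsort(-weights)
    weights = weights[order]
    rates = rates[order]
    half_time = math.log(2.0) / float(rates[0])
    return DecayFit(
        n_components=n,
        amplitudes=tuple(float(w) for w in weights),
        rates=tuple(float(r) for r in rates),
        baseline=float(theta[0]),
        total_amplitude=total,
        half_time=half_time,
        criterion_scores=scores,
    )


@dataclass(frozen=True)
class ParamRecovery:
    """Recovered photochemical parameters with an identifiability report."""

    params: PhotochromeParams
    yield_ratio: float
    n_wavelengths: int
    absolute_yields_identifiable: bool
    dark_rate: float
    residual_norm: float
    message: str


def _segment_slices(
    protocol: IlluminationProtocol, times: np.ndarray
) -> list[tuple[int, int]]:
    bounds = protocol.boundaries()
    out = []
    for i in range(len(protocol.segments)):
        i0 = int(np.searchsorted(times, bounds[i], side="left"))
        i1 = int(np.searchsorted(times, bounds[i + 1], side="right"))
        out.append((i0, i1))
    return out


def recover_params_from_protocol(
    basis: ChromophoreBasis,
    protocol: IlluminationProtocol,
    trajectory: StateTrajectory,
    ground_state: GroundState,
    n_starts: int = 5,
    seed: int = 1234,
) -> ParamRecovery:
    """Estimate (phi_fwd, phi_rev, effective dark rate) from a protocol run.

    For each illuminated segment the stationary level (tail mean) and the
    mono-exponential approach rate are extracted; dark segments contribute a
    directly fitted reversion rate.  The three parameters are then fitted
    jointly by bounded least squares with multistart (quantum yields
    constrained to (0, 1]).  With a single distinct illumination wavelength
    only the yield ratio is identifiable; this is reported.
    """
    per_segment: list[dict] = []
    dark_rate_obs: float | None = None
    slices = _segment_slices(protocol, trajectory.times)
    for seg, (i0, i1) in zip(protocol.segments, slices):
        t_seg = trajectory.times[i0:i1]
        f_seg = trajectory.f_pfr[i0:i1]
        if t_seg.size < 25:
            continue
        if seg.is_dark:
            try:
                fit = fit_dark_reversion(t_seg, f_seg, max_components=2)
            except ValueError:
                continue
            mean_rate = float(
                np.dot(fit.amplitudes, fit.rates)
            )
            dark_rate_obs = mean_rate
            continue
        s_pr = sum(excitation_rate(basis, State.PR, s) for s in seg.sources)
        s_pfr = sum(excitation_rate(basis, State.PFR, s) for s in seg.sources)
        n_tail = max(5, t_seg.size // 10)
        f_ss_obs = float(np.mean(f_seg[-n_tail:]))
        rate_obs = None
        try:
            fit = fit_dark_reversion(t_seg, f_seg, max_components=1)
            rate_obs = fit.rates[0]
        except ValueError:
            pass  # segment started at its stationary level; no rate information
        wavelengths = tuple(sorted({s.wavelength for s in seg.sources}))
        per_segment.append(
            dict(s_pr=s_pr, s_pfr=s_pfr, f_ss=f_ss_obs, rate=rate_obs, wl=wavelengths)
        )
    if not per_segment:
        raise ValueError("protocol/trajectory contain no usable illuminated segments")

    wavelength_set = sorted({w for seg in per_segment for w in seg["wl"]})
    n_wavelengths = len(wavelength_set)

    def residuals(x: np.ndarray) -> np.ndarray:
        phi_f, phi_r, k = x
        out = []
        for seg in per_segment:
            a_f = phi_f * seg["s_pr"]
            a_r = phi_r * seg["s_pfr"]
            lam = a_f + a_r + k
            if ground_state is GroundState.PR_GROUND:
                f_pred = a_f / lam
            else:
                f_pred = (a_f + k) / lam
            out.append(f_pred - seg["f_ss"])
            if seg["rate"] is not None:
                out.append(0.5 * (math.log(lam) - math.log(seg["rate"])))
        if dark_rate_obs is not None:
            out.append(math.log(max(k, 1e-12)) - math.log(dark_rate_obs))
        return np.asarray(out)

    rng = np.random.default_rng(seed)
    lo = np.array([1e-5, 1e-5, 1e-9])
    hi = np.array([1.0, 1.0, 10.0])
    best = None
    k_guess = dark_rate_obs if dark_rate_obs is not None else 1e-4
    starts = [np.array([0.1, 0.1, k_guess])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.array(
                [
                    10 ** rng.uniform(-3, 0),
                    10 ** rng.uniform(-3, 0),
                    k_guess * 10 ** rng.uniform(-1, 1),
                ]
            )
        )
    for x0 in starts:
        res = least_squares(
            residuals, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf", max_nfev=5000
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    phi_f, phi_r, k = best.x
    params = PhotochromeParams(
        phi_fwd=float(phi_f),
        phi_rev=float(phi_r),
        ground_state=ground_state,
        dark_components=(DarkComponent(1.0, float(k)),),
    )
    ratio = params.yield_ratio_to_photoproduct
    absolute = n_wavelengths >= 2
    message = (
        "absolute yields identified from >=2 wavelengths"
        if absolute
        else "single illumination wavelength: only the yield ratio is identifiable"
    )
    if not absolute:
        warnings.warn(message, RuntimeWarning, stacklevel=2)
    return ParamRecovery(
        params=params,
        yield_ratio=float(ratio),
        n_wavelengths=n_wavelengths,
        absolute_yields_identifiable=absolute,
        dark_rate=float(k),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        message=message,
    )
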