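"""Thermal-unfolding analysis: sigmoidal melt fits and DSC deconvolution.

Melting curves (e.g. temperature-resolved circular dichroism at 208 nm) are
fitted with one or two logistic transitions on a linear baseline. DSC
thermograms are deconvoluted with a non-two-state equilibrium model in which
each transition i contributes

    Cp_i(T) = dH_vH,i * dH_cal,i * K_i / ((1 + K_i)^2 * R * T^2)
    K_i     = exp[(dH_vH,i / R) * (1/Tm_i - 1/T)]

with T in kelvin, R = 1.987e-3 kcal mol^-1 K^-1, so that the van 't Hoff
enthalpy sets the transition sharpness and the calorimetric enthalpy the
integrated peak area. This is an effective equilibrium description; for
irreversibly unfolding proteins (as here) the fitted parameters are apparent
quantities, which is the standard practice for these instruments.

Inputs and outputs are in degrees Celsius; kelvin is used internally for all
exponentials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL

__all__ = [
    "MeltCurve",
    "Thermogram",
    "TransitionFit",
    "fit_melt_sigmoid",
    "dsc_model_cp",
    "fit_dsc_transitions",
    "melt_model",
]

_T0 = 273.15


class FitError(RuntimeError):
    pass


def _check_trace(temperature, signal, min_points: int):
    t = np.asarray(temperature, float)
    y = np.asarray(signal, float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("temperature and signal must be 1-D and equal length")
    if len(t) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(t)}")
    if not np.all(np.diff(t) > 0):
        raise ValueError("temperature must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in trace")
    return t, y


@dataclass(frozen=True)
class MeltCurve:
    """An optical melting trace: temperature (deg C) vs signal."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t, y = _check_trace(self.temperature, self.signal, 20)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class Thermogram:
    """A DSC trace: temperature (deg C) vs excess heat capacity
    (kcal mol^-1 K^-1)."""

    temperature: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        t, y = _check_trace(self.temperature, self.cp, 50)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "cp", y)


@dataclass(frozen=True)
class TransitionFit:
    """One fitted unfolding transition.

    ``tm`` in deg C; enthalpies in kcal/mol. For melt fits ``amplitude`` is
    the signal step and ``width`` the logistic width in deg C (dh fields are
    NaN); for DSC fits amplitude equals dh_cal.
    """

    tm: float
    dh_vh: float = float("nan")
    dh_cal: float = float("nan")
    amplitude: float = float("nan")
    width: float = float("nan")
    baseline: tuple = ()
    rms_residual: float = float("nan")
    covariance: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Sigmoidal melt fitting


def melt_model(t: np.ndarray, baseline: Sequence[float], tms: Sequence[float],
               widths: Sequence[float], amps: Sequence[float],
               post_slope: float = 0.0) -> np.ndarray:
    """Linear pre-baseline plus logistic steps plus a post-transition slope.

    signal(T) = a0 + a1*T + sum_i amp_i / (1 + exp((Tm_i - T)/w_i))
                + post_slope * T * fbar(T)

    where fbar is the mean of the logistic terms, so the post-baseline slope
    a1 + post_slope takes over once all transitions are complete.
    """
    t = np.asarray(t, float)
    a0, a1 = baseline
    y = a0 + a1 * t
    fsum = np.zeros_like(t)
    for tm, w, amp in zip(tms, widths, amps):
        f = 1.0 / (1.0 + np.exp(np.clip((tm - t) / w, -500, 500)))
        y = y + amp * f
        fsum += f
    if post_slope:
        y = y + post_slope * t * fsum / max(len(list(tms)), 1)
    return y


def fit_melt_sigmoid(curve: MeltCurve, n_transitions: int = 1,
                     init: Sequence[float] | None = None,
                     fit_post_slope: bool = False) -> list[TransitionFit]:
    """Least-squares fit of ``n_transitions`` (1 or 2) logistic transitions.

    ``init`` optionally gives starting Tm values; otherwise a deterministic
    grid of starting Tm values across the data range is tried and the best
    RMS wins. Transitions are returned sorted by Tm.
    """
    if n_transitions not in (1, 2):
        raise ValueError("n_transitions must be 1 or 2")
    t, y = curve.temperature, curve.signal
    span = t[-1] - t[0]
    amp_guess = (y[-1] - y[0]) / n_transitions

    def pack(tms):
        p = [y[0], 0.0]
        for tm in tms:
            p += [tm, max(span / 20, 1.0), amp_guess]
        if fit_post_slope:
            p.append(0.0)
        return np.array(p, float)

    def unpack(p):
        base = p[:2]
        rest = p[2:2 + 3 * n_transitions]
        tms = rest[0::3]
        widths = rest[1::3]
        amps = rest[2::3]
        post = p[-1] if fit_post_slope else 0.0
        return base, tms, widths, amps, post

    def resid(p):
        base, tms, widths, amps, post = unpack(p)
        return melt_model(t, base, tms, np.abs(widths), amps, post) - y

    if init is not None:
        starts = [list(init)]
    elif n_transitions == 1:
        starts = [[t[0] + f * span] for f in (0.25, 0.4, 0.5, 0.6, 0.75)]
    else:
        grid = [t[0] + f * span for f in (0.2, 0.35, 0.5, 0.65, 0.8)]
        starts = [[x1, x2] for x1, x2 in itertools.combinations(grid, 2)]

    # physically motivated bounds: Tm inside the data range, widths between
    # one grid step and a third of the range (excludes spike-like
    # degenerate solutions of two cancelling transitions), amplitudes within
    # three times the observed signal range
    step = float(np.median(np.diff(t)))
    y_range = max(float(y.max() - y.min()), 1e-9)
    lo = [-np.inf, -np.inf]
    hi = [np.inf, np.inf]
    for _ in range(n_transitions):
        lo += [t[0], step, -3 * y_range]
        hi += [t[-1], span / 3, 3 * y_range]
    if fit_post_slope:
        lo.append(-np.inf)
        hi.append(np.inf)
    x_scale = np.array([max(abs(y).max(), 1e-9), 0.1]
                       + [10.0, 1.0, y_range] * n_transitions
                       + ([0.1] if fit_post_slope else []))

    best = None
    for tms0 in starts:
        p0 = np.minimum(np.maximum(pack(tms0), lo), hi)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                x_scale=x_scale, max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("melt fit did not converge"
                       + ("" if best is None else f"; final cost {best.cost:.3g}"))

    base, tms, widths, amps, post = unpack(best.x)
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    cov = _covariance(best)
    fits = [TransitionFit(tm=float(tm), amplitude=float(amp), width=float(abs(w)),
                          baseline=(float(base[0]), float(base[1]), float(post)),
                          rms_residual=rms, covariance=cov)
            for tm, w, amp in zip(tms, widths, amps)]
    fits.sort(key=lambda f: f.tm)
    return fits


def _covariance(sol) -> np.ndarray | None:
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(len(sol.fun) - len(sol.x), 1)
        return np.linalg.pinv(jtj) * 2 * sol.cost / dof
    except Exception:
        return None


# ---------------------------------------------------------------------------
# DSC non-two-state model


def dsc_model_cp(transitions: Sequence[TransitionFit], temperature) -> np.ndarray:
    """Excess heat capacity of a sum of independent non-two-state transitions.

    Implements Cp(T) = sum_i dH_vH,i dH_cal,i K_i / ((1+K_i)^2 R T^2) with
    K_i the van 't Hoff equilibrium constant; T in deg C on input, kelvin
    internally. At T = Tm each transition contributes dH_vH dH_cal/(4 R T^2).
    """
    t_k = np.asarray(temperature, float) + _T0
    cp = np.zeros_like(t_k)
    for tr in transitions:
        tm_k = tr.tm + _T0
        # clip ln K to +-60: K/(1+K)^2 ~ e^-|lnK| is already ~1e-27 there,
        # and the clipped range cannot overflow in double precision
        ln_k = np.clip((tr.dh_vh / R_KCAL) * (1.0 / tm_k - 1.0 / t_k), -60, 60)
        k = np.exp(ln_k)
        cp = cp + tr.dh_vh * tr.dh_cal * k / ((1.0 + k) ** 2 * R_KCAL * t_k ** 2)
    return cp


def fit_dsc_transitions(thermogram: Thermogram, n_transitions: int = 2,
                        init: Sequence[float] | None = None,
                        baseline: str = "linear") -> list[TransitionFit]:
    """Deconvolute a thermogram into ``n_transitions`` non-two-state
    transitions plus a co-fitted linear baseline.

    Initialization is multi-start over a deterministic grid of 5 Tm values
    across the data range (all ascending combinations for n > 1); the
    lowest-RMS solution wins. Transitions are returned sorted by Tm. A
    transition whose parameters are not identifiable (singular curvature)
    is flagged by a non-finite covariance.
    """
    if n_transitions < 1:
        raise ValueError("n_transitions must be >= 1")
    if baseline != "linear":
        raise ValueError("only the linear baseline is implemented")
    t, y = thermogram.temperature, thermogram.cp
    span = t[-1] - t[0]
    area = np.trapezoid(np.clip(y - np.median(y), 0, None), t)
    dh_cal0 = max(area / n_transitions, 10.0)

    def model(p):
        a0, a1 = p[0], p[1]
        trs = [TransitionFit(tm=p[2 + 3 * i], dh_vh=abs(p[3 + 3 * i]),
                             dh_cal=abs(p[4 + 3 * i]))
               for i in range(n_transitions)]
        return a0 + a1 * t + dsc_model_cp(trs, t)

    def resid(p):
        return model(p) - y

    def pack(tms):
        p = [float(np.median(y)), 0.0]
        for tm in tms:
            p += [tm, 100.0, dh_cal0]
        return np.array(p, float)

    if init is not None:
        starts = [list(init)]
    else:
        # anchor the grid on the endotherm maximum plus a coarse span grid
        t_peak = float(t[int(np.argmax(y))])
        if n_transitions == 1:
            starts = [[t_peak], [t[0] + 0.35 * span], [t[0] + 0.65 * span]]
        elif n_transitions == 2:
            starts = [[t_peak - 3.0, t_peak + 1.0], [t_peak - 1.0, t_peak + 3.0],
                      [t_peak - 8.0, t_peak], [t_peak, t_peak + 8.0],
                      [t[0] + 0.35 * span, t[0] + 0.65 * span]]
        else:
            grid = [t[0] + f * span for f in (0.2, 0.35, 0.5, 0.65, 0.8)]
            starts = [list(c) for c in itertools.combinations(grid, n_transitions)]

    y_scale = max(float(np.max(np.abs(y))), 1e-6)
    x_scale = np.array([y_scale, y_scale / span]
                       + [10.0, 100.0, 100.0] * n_transitions)
    best = None
    for tms0 in starts:
        try:
            sol = least_squares(resid, pack(tms0), method="lm",
                                x_scale=x_scale, max_nfev=40000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("DSC fit did not converge from any start")

    p = best.x
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    cov = _covariance(best)
    fits = []
    for i in range(n_transitions):
        fits.append(TransitionFit(
            tm=float(p[2 + 3 * i]), dh_vh=float(abs(p[3 + 3 * i])),
            dh_cal=float(abs(p[4 + 3 * i])), amplitude=float(abs(p[4 + 3 * i])),
            baseline=(float(p[0]), float(p[1])), rms_residual=rms, covariance=cov))
    fits.sort(key=lambda f: f.tm)
    return fits
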