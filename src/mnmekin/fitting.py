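"""Exponential and hyperbolic fits for single-turnover kinetic traces.

Conventions: time in seconds, all reported rate constants in min^-1.
Nonlinear fits are initialized from a log-spaced rate grid search
(1e-1 to 1e5 min^-1) with the linear parameters profiled out, then
refined with lmfit least squares; this makes the fits insensitive to
starting values over the four decades of rates in the GTPase cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .synthetic import KobsTitration
from .trace import Trace

__all__ = [
    "FitResult",
    "NoTransitionError",
    "fit_single_exponential",
    "fit_double_exponential",
    "fit_one_phase_decay",
    "fit_hyperbolic",
    "detect_lag",
    "amplitude_retention",
    "BINDING_WINDOW",
    "DISSOCIATION_WINDOW",
]

#: Default fitting windows (s): binding/dimerization on the biphasic rise,
#: dissociation on the slow decay.
BINDING_WINDOW = (0.0, 0.5)
DISSOCIATION_WINDOW = (0.5, 17.0)

_RATE_GRID = np.geomspace(1e-1, 1e5, 49)  # min^-1
_S = 1.0 / 60.0  # min^-1 * s -> dimensionless exponent


class NoTransitionError(ValueError):
    """Raised when a trace shows no amplitude above the noise floor."""


@dataclass
class FitResult:
    """Parameter estimates and diagnostics from one trace-level fit.

    ``params``/``stderr`` are keyed by parameter name; rates are min^-1,
    amplitudes and offsets in signal units.  ``converged`` False marks the
    estimates unusable.
    """

    model: str
    params: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    residual_sd: float = np.nan
    converged: bool = False
    message: str = ""
    lag_s: float | None = None
    nobs: int = 0

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def se(self, name: str) -> float:
        return self.stderr.get(name, np.nan)


def _finish(result: lmfit.minimizer.MinimizerResult | lmfit.model.ModelResult,
            model: str, n: int, message: str = "") -> FitResult:
    params = {p: result.params[p].value for p in result.params}
    stderr = {p: (result.params[p].stderr if result.params[p].stderr
                  is not None else np.nan) for p in result.params}
    resid_sd = float(np.std(result.residual, ddof=len(params)) \
        if result.residual.size > len(params) else np.nan)
    return FitResult(model, params, stderr, resid_sd,
                     converged=bool(result.success), message=message, nobs=n)


def _noise_floor(trace: Trace) -> float:
    return trace.noise_sd if trace.noise_sd > 0 else 0.0


def _window(trace: Trace, window) -> Trace:
    return trace.window(*window) if window is not None else trace


def fit_single_exponential(trace: Trace, direction: str = "decay",
                           window=None) -> FitResult:
    """Fit y = y_inf + A exp(-k t) to one transition; k reported in min^-1.

    ``direction`` fixes the sign convention of the amplitude ('decay':
    A > 0, 'rise': A < 0).  Raises :class:`NoTransitionError` when the
    signal range is below 3x the trace noise.
    """
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    tr = _window(trace, window)
    t, y = tr.time, tr.signal
    if t.size < 20:
        raise ValueError("need >= 20 points after dead-time trim")
    if np.ptp(y) <= 3.0 * _noise_floor(tr) or np.ptp(y) == 0.0:
        raise NoTransitionError(
            "no transition detected: signal range below 3x noise floor")

    # profile (offset, amp) linearly at each grid rate
    best = None
    for k in _RATE_GRID:
        e = np.exp(-k * _S * t)
        X = np.column_stack([np.ones_like(t), e])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssr = float(res[0]) if res.size else float(np.sum((y - X @ coef) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, k, coef)
    _, k0, (off0, amp0) = best

    model = lmfit.Model(lambda t, k, amp, offset:
                        offset + amp * np.exp(-k * _S * t))
    pars = model.make_params(k=k0, amp=amp0, offset=off0)
    pars["k"].min = 0.0
    out = model.fit(tr.signal, pars, t=t, method="leastsq",
                    fit_kws={"xtol": 1e-13, "ftol": 1e-13})
    fr = _finish(out, "single_exponential", t.size)
    sign_ok = (fr.params["amp"] > 0) == (direction == "decay")
    if not sign_ok:
        fr.message = (fr.message + " amplitude sign opposite to requested "
                      f"direction {direction!r}").strip()
    if abs(fr.params["amp"]) < 3.0 * _noise_floor(tr):
        raise NoTransitionError(
            "no transition detected: fitted amplitude below 3x noise floor")
    return fr


def _double_model(t, k_fast, k_slow, amp_fast, amp_slow, offset):
    return (offset + amp_fast * (1.0 - np.exp(-k_fast * _S * t))
            + amp_slow * (1.0 - np.exp(-k_slow * _S * t)))


def fit_double_exponential(trace: Trace, window=BINDING_WINDOW) -> FitResult:
    """Fit the biphasic rise y = y0 + A1(1-e^{-k1 t}) + A2(1-e^{-k2 t}).

    Phases are labelled by rate magnitude (k_fast >= k_slow).  When the
    fitted rates separate by less than 3x, the fit is compared against a
    single exponential by AIC and the simpler model returned if preferred,
    with a 'phases poorly separable' note.
    """
    tr = _window(trace, window)
    t, y = tr.time, tr.signal
    if t.size < 40:
        raise ValueError("need >= 40 points over the rise window")

    best = None
    grid = np.geomspace(1e0, 1e5, 26)
    for ia, ka in enumerate(grid):
        ea = 1.0 - np.exp(-ka * _S * t)
        for kb in grid[:ia]:
            eb = 1.0 - np.exp(-kb * _S * t)
            X = np.column_stack([np.ones_like(t), ea, eb])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            ssr = float(res[0]) if res.size else float(np.sum((y - X @ coef) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, ka, kb, coef)
    _, ka, kb, (off0, a0, b0) = best

    model = lmfit.Model(_double_model)
    pars = model.make_params(k_fast=ka, k_slow=kb, amp_fast=a0,
                             amp_slow=b0, offset=off0)
    pars["k_fast"].min = 0.0
    pars["k_slow"].min = 0.0
    out = model.fit(y, pars, t=t, method="leastsq",
                    fit_kws={"xtol": 1e-13, "ftol": 1e-13})
    fr = _finish(out, "double_exponential", t.size)

    # enforce k_fast >= k_slow labelling
    if fr.params["k_fast"] < fr.params["k_slow"]:
        p, s = fr.params, fr.stderr
        p["k_fast"], p["k_slow"] = p["k_slow"], p["k_fast"]
        p["amp_fast"], p["amp_slow"] = p["amp_slow"], p["amp_fast"]
        s["k_fast"], s["k_slow"] = s.get("k_slow", np.nan), s.get("k_fast", np.nan)
        s["amp_fast"], s["amp_slow"] = (s.get("amp_slow", np.nan),
                                        s.get("amp_fast", np.nan))

    ratio = fr.params["k_fast"] / max(fr.params["k_slow"], 1e-300)
    if ratio < 3.0:
        warnings.warn("phases poorly separable (rate ratio < 3); comparing "
                      "against a single exponential", stacklevel=2)
        single = lmfit.Model(lambda t, k, amp, offset:
                             offset + amp * (1.0 - np.exp(-k * _S * t)))
        spars = single.make_params(k=fr.params["k_fast"],
                                   amp=fr.params["amp_fast"] + fr.params["amp_slow"],
                                   offset=fr.params["offset"])
        sout = single.fit(y, spars, t=t, method="leastsq")
        if sout.aic <= out.aic:
            sfr = _finish(sout, "single_exponential", t.size,
                          message="phases poorly separable; single "
                                  "exponential preferred by AIC")
            return sfr
        fr.message = "phases poorly separable (rate ratio < 3)"
    return fr


def fit_one_phase_decay(points: Trace) -> FitResult:
    """Fit a one-phase exponential decay to quench-flow %-uncleaved-GTP data.

    The model is %GTP = plateau + (y0 - plateau) exp(-k t) with the
    initial value y0 free, the standard instrument-software convention.
    The t=0 point is the 100% normalization control and is excluded from
    the least squares: when upstream binding/dimerization leave a short
    lag, the decay's back-extrapolated intercept legitimately exceeds
    100% and pinning it would bias the rate.
    """
    t, y = points.time, points.signal
    if t.size < 5:
        raise ValueError("need >= 5 quench time points")
    if t[0] != 0.0:
        raise ValueError("quench data must include the t=0 control point")
    slope = np.polyfit(t, y, 1)[0]
    if slope > 0 and y[-1] > y[0]:
        return FitResult("one_phase_decay", converged=False,
                         message="increasing data: not a decay", nobs=t.size)
    floor = 3.0 * points.noise_sd * 100.0 if points.noise_sd > 0 else 0.0
    if np.ptp(y) <= max(floor, 1e-9):
        raise NoTransitionError("no transition detected: quench signal flat")

    tf, yf = t[1:], y[1:]  # drop the normalization control
    best = None
    for k in _RATE_GRID:
        e = np.exp(-k * _S * tf)
        X = np.column_stack([np.ones_like(tf), e])
        coef, res, *_ = np.linalg.lstsq(X, yf, rcond=None)
        ssr = float(res[0]) if res.size else float(np.sum((yf - X @ coef) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, k, coef)
    _, k0, (p0, a0) = best

    model = lmfit.Model(lambda t, k, y0, plateau:
                        plateau + (y0 - plateau) * np.exp(-k * _S * t))
    pars = model.make_params(k=k0, y0=p0 + a0, plateau=p0)
    pars["k"].min = 0.0
    out = model.fit(yf, pars, t=tf, method="leastsq",
                    fit_kws={"xtol": 1e-13, "ftol": 1e-13})
    return _finish(out, "one_phase_decay", tf.size)


def fit_hyperbolic(titration: KobsTitration) -> FitResult:
    """Fit k_obs = k_max [E] / (K_D + [E]) to a rate-vs-concentration titration.

    Observed rates carry roughly proportional errors, so residuals are
    weighted by 1/k_obs (relative least squares).
    """
    e, k = titration.e_concs, titration.k_obs
    model = lmfit.Model(lambda e, k_max, K_D: k_max * e / (K_D + e))
    pars = model.make_params(k_max=float(np.max(k) * 1.2),
                             K_D=float(np.median(e)))
    pars["k_max"].min = 0.0
    pars["K_D"].min = 1e-12
    out = model.fit(k, pars, e=e, weights=1.0 / np.abs(k), method="leastsq",
                    fit_kws={"xtol": 1e-13, "ftol": 1e-13})
    fr = _finish(out, "hyperbolic", e.size)
    if np.min(e) > 10.0 * fr.params["K_D"]:
        warnings.warn("K_D poorly constrained: all concentrations far above "
                      "the fitted K_D", stacklevel=2)
        fr.message = "K_D poorly constrained"
    return fr


def detect_lag(trace: Trace, plateau_window: float = 0.25,
               noise_sd: float | None = None) -> float:
    """Duration (s) the signal dwells at its peak plateau before decaying.

    The plateau mean is taken over ``plateau_window`` seconds after the
    signal maximum; the lag ends when the signal first drops more than
    3x the noise SD below that mean.  ``noise_sd`` defaults to the
    trace's own value, falling back to 0.003 relative-fluorescence units
    (the default instrument noise) for noiseless traces.  Raises
    ``ValueError('no decay')`` if no such drop occurs.
    """
    t, y = trace.time, trace.signal
    sd = noise_sd if noise_sd is not None else trace.noise_sd
    if sd <= 0:
        sd = 0.003
    i_peak = int(np.argmax(y))
    t_peak = t[i_peak]
    plate = y[(t >= t_peak) & (t <= t_peak + plateau_window)]
    plateau_mean = float(np.mean(plate))
    threshold = plateau_mean - 3.0 * sd
    below = (t > t_peak) & (y < threshold)
    # require 3 consecutive samples below threshold so a single noise
    # excursion does not end the lag early
    run = 0
    for idx, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run == 3:
            return float(max(t[idx - 2] - t_peak, 0.0))
    raise ValueError("no decay: signal never drops below the plateau")


def amplitude_retention(amp_variant: float, amp_reference: float) -> float:
    """% of molecules retaining product, from relative signal amplitudes.

    100 * (1 - amp_variant / amp_reference); e.g. a variant whose Pi-release
    amplitude is 77% of wild type retains Pi in 23% of molecules.
    """
    if amp_reference <= 0:
        raise ValueError("amp_reference must be > 0")
    if amp_variant < 0:
        raise ValueError("amplitudes must be >= 0")
    return 100.0 * (1.0 - amp_variant / amp_reference)
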