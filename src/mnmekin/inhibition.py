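"""Product-inhibition inference: Michaelis-Menten fits under inhibitor,
Dixon and Cornish-Bowden ([S]/v) inhibition constants, inhibition-type
classification, IC50 and fraction inhibited at cellular concentrations.

The Dixon plot draws 1/v versus [I] lines at fixed substrate; for
competitive or mixed inhibition they share a common point at [I] = -K_IE.
The Cornish-Bowden plot draws [S]/v versus [I]; for mixed or
uncompetitive inhibition those lines intersect at [I] = -K_IES.  Both
intersections are estimated here as the least-squares common point of
the fitted lines (the graphical reading made algebraic), with a global
nonlinear fit of the corresponding rate law reported alongside as a
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .cycle import steady_state_rate
from .synthetic import InhibitionGrid

__all__ = [
    "MMFit",
    "InhibitionResult",
    "ParallelLinesError",
    "fit_michaelis_menten",
    "dixon_fit",
    "cornish_bowden_fit",
    "classify_inhibition",
    "ic50_competitive",
    "ic50_mixed",
    "fraction_inhibited",
    "rate_percentages",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


class ParallelLinesError(ValueError):
    """Raised when Dixon/Cornish-Bowden lines are parallel (no intersection)."""


@dataclass
class MMFit:
    """Michaelis-Menten parameters at one inhibitor level."""

    kcat: float                # min^-1
    Km: float                  # uM (apparent)
    Vmax: float                # uM min^-1
    kcat_se: float = np.nan
    Km_se: float = np.nan
    inhibitor_name: str = ""
    inhibitor_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.kcat <= 0 or self.Km <= 0:
            raise ValueError("kcat and Km must be > 0")


@dataclass
class InhibitionResult:
    """Inhibition model with its constants and cellular-scale summaries."""

    model: str                       # competitive|mixed|uncompetitive|none
    K_IE: float | None = None        # uM
    K_IES: float | None = None       # uM; absent for competitive
    IC50: float | None = None        # uM
    fraction_inhibited_at_cellular: float | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("K_IE", "K_IES", "IC50"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when present")
        if self.model == "competitive" and self.K_IES is not None:
            raise ValueError("competitive inhibition has no K_IES")


def fit_michaelis_menten(s, v, e0: float, inhibitor_name: str = "",
                         inhibitor_conc: float = 0.0) -> MMFit:
    """Nonlinear fit of v = Vmax s / (Km_app + s); kcat = Vmax / e0."""
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.size < 3:
        raise ValueError("need >= 3 substrate levels")
    model = lmfit.Model(lambda s, Vmax, Km: Vmax * s / (Km + s))
    pars = model.make_params(Vmax=float(np.max(v) * 1.2),
                             Km=float(np.median(s)))
    pars["Vmax"].min = 1e-12
    pars["Km"].min = 1e-12
    out = model.fit(v, pars, s=s, method="leastsq",
                    fit_kws={"xtol": 1e-13, "ftol": 1e-13})
    Vmax = out.params["Vmax"].value
    Km = out.params["Km"].value
    if np.max(s) < Km:
        warnings.warn("non-saturating design: max substrate below the "
                      "apparent Km", stacklevel=2)
    vse = out.params["Vmax"].stderr
    kse = out.params["Km"].stderr
    return MMFit(kcat=Vmax / e0, Km=Km, Vmax=Vmax,
                 kcat_se=(vse / e0 if vse is not None else np.nan),
                 Km_se=(kse if kse is not None else np.nan),
                 inhibitor_name=inhibitor_name, inhibitor_conc=inhibitor_conc)


def _weighted_lines(x, Y):
    """Per-line weighted OLS (weights 1/y^2, matching relative rate noise)."""
    A, B = [], []
    X = np.column_stack([np.ones_like(x), x])
    for row in Y:
        w = 1.0 / row ** 2
        coef = np.linalg.solve((X.T * w) @ X, (X.T * w) @ row)
        A.append(coef[0])
        B.append(coef[1])
    return np.array(A), np.array(B)


def _check_parallel(slopes, what: str) -> None:
    slopes = np.asarray(slopes, float)
    spread = (np.max(slopes) - np.min(slopes)) / np.mean(np.abs(slopes))
    if spread < 0.05:
        raise ParallelLinesError(what)


def _common_point(x, Y):
    """Weighted least-squares common intersection of near-concurrent lines.

    Fits all lines simultaneously under the constraint that they pass
    through one point: y_ij = y0 + b_i (x_j - x0), minimizing the
    inverse-variance-weighted squared residuals (weights 1/y^2 for
    relative noise).  For a fixed abscissa x0 the problem is linear, so
    x0 is found by profiling; the curvature of the profiled objective
    gives the standard error.  Returns (x0, y0, weighted SSR, se(x0)).
    """
    from scipy.optimize import minimize_scalar

    W = 1.0 / Y ** 2
    n = Y.shape[0]

    def profile(x0):
        dx = x - x0
        A = np.zeros((n + 1, n + 1))
        rhs = np.zeros(n + 1)
        A[0, 0] = W.sum()
        rhs[0] = (W * Y).sum()
        for i in range(n):
            A[0, i + 1] = A[i + 1, 0] = (W[i] * dx).sum()
            A[i + 1, i + 1] = (W[i] * dx * dx).sum()
            rhs[i + 1] = (W[i] * dx * Y[i]).sum()
        sol = np.linalg.solve(A, rhs)
        resid = Y - (sol[0] + sol[1:][:, None] * dx[None, :])
        return float((W * resid * resid).sum()), float(sol[0])

    scale = float(np.max(np.abs(x))) or 1.0
    res = minimize_scalar(lambda z: profile(z)[0],
                          bounds=(-1e3 * scale, -1e-9 * scale),
                          method="bounded",
                          options={"xatol": 1e-10 * scale})
    x0 = float(res.x)
    ssr, y0 = profile(x0)
    # SE from the curvature of the profiled objective
    h = max(1e-4 * abs(x0), 1e-9 * scale)
    curv = (profile(x0 + h)[0] - 2.0 * ssr + profile(x0 - h)[0]) / h ** 2
    dof = Y.size - (n + 2)
    sigma2 = ssr / dof if dof > 0 else np.nan
    se = float(np.sqrt(2.0 * sigma2 / curv)) if curv > 0 else np.nan
    return x0, y0, ssr, se


def _global_law_fit(grid: InhibitionGrid, model: str) -> dict:
    """Log-residual nonlinear fit of the full inhibited rate law (cross-check).

    Residuals are taken on log(v), the maximum-likelihood choice for
    multiplicative rate noise.
    """
    from scipy.optimize import least_squares

    s, i = np.meshgrid(grid.substrate, grid.inhibitor, indexing="ij")
    s, i, v = s.ravel(), i.ravel(), grid.rates.ravel()
    competitive = model == "competitive"

    def resid(theta):
        Vmax, Km, ki_e = np.exp(theta[:3])
        ki_es = np.inf if competitive else np.exp(theta[3])
        denom = Km * (1.0 + i / ki_e) + s * (1.0 + i / ki_es)
        return np.log(Vmax * s / denom) - np.log(v)

    th0 = [np.log(np.max(v) * 1.5), np.log(np.median(grid.substrate)),
           np.log(np.median(grid.inhibitor[grid.inhibitor > 0]))]
    if not competitive:
        th0.append(np.log(np.max(grid.inhibitor)))
    out = least_squares(resid, th0, method="lm", xtol=1e-14, ftol=1e-14)
    names = ["Vmax", "Km", "ki_e"] + ([] if competitive else ["ki_es"])
    return dict(zip(names, np.exp(out.x)))


def dixon_fit(grid: InhibitionGrid) -> dict:
    """Competitive/mixed K_IE (uM) from the Dixon (1/v vs [I]) plot.

    Returns a dict with ``K_IE`` (least-squares common intersection),
    ``intersection_residual``, the per-line coefficients, and
    ``K_IE_global`` from a nonlinear fit of the full rate law.
    Near-parallel lines (slope spread < 5%) raise
    :class:`ParallelLinesError` (uncompetitive-like pattern).
    """
    if grid.substrate.size < 2 or grid.inhibitor.size < 3:
        raise ValueError("need >= 2 substrate and >= 3 inhibitor levels")
    recip = 1.0 / grid.rates
    a, b = _weighted_lines(grid.inhibitor, recip)
    _check_parallel(b, "no intersection: uncompetitive-like pattern")
    x, y, resid, se = _common_point(grid.inhibitor, recip)
    model = "competitive" if grid.inhibitor_name.upper() == "GDP" else "mixed"
    out = {"K_IE": -x, "K_IE_se": se, "intersection_y": y,
           "intersection_residual": resid, "intercepts": a, "slopes": b}
    try:
        out["K_IE_global"] = _global_law_fit(grid, model)["ki_e"]
    except Exception:  # cross-check only; never blocks the primary estimate
        out["K_IE_global"] = np.nan
    return out


def cornish_bowden_fit(grid: InhibitionGrid) -> dict:
    """Mixed/uncompetitive K_IES (uM) from the [S]/v versus [I] plot.

    Parallel [S]/v lines mean a purely competitive pattern with K_IES
    unbounded and raise :class:`ParallelLinesError`.
    """
    if grid.substrate.size < 2 or grid.inhibitor.size < 3:
        raise ValueError("need >= 2 substrate and >= 3 inhibitor levels")
    sv = grid.substrate[:, None] / grid.rates
    a, b = _weighted_lines(grid.inhibitor, sv)
    _check_parallel(b, "competitive pattern: K_IES unbounded")
    x, y, resid, se = _common_point(grid.inhibitor, sv)
    out = {"K_IES": -x, "K_IES_se": se, "intersection_y": y,
           "intersection_residual": resid, "intercepts": a, "slopes": b}
    try:
        out["K_IES_global"] = _global_law_fit(grid, "mixed")["ki_es"]
    except Exception:
        out["K_IES_global"] = np.nan
    return out


def classify_inhibition(mm_fits: list[MMFit]) -> str:
    """Label the inhibition pattern from MM fits across inhibitor levels.

    Requires >= 3 levels including 0, in increasing inhibitor order.
    Apparent Km rising (Spearman rank correlation >= 0.7, tolerating one
    noise-induced rank swap, and a > 1.3-fold overall increase) with kcat
    dropping by more than 25% is 'mixed'; Km rising with kcat held (or
    drifting up) is 'competitive'; kcat dropping alone is
    'uncompetitive'; neither trend is 'none'.
    """
    from scipy.stats import spearmanr

    if len(mm_fits) < 3:
        raise ValueError("need >= 3 inhibitor levels")
    levels = np.array([f.inhibitor_conc for f in mm_fits])
    if levels[0] != 0.0:
        raise ValueError("the zero-inhibitor reference level is required")
    if not np.all(np.diff(levels) > 0):
        raise ValueError("inhibitor levels must be strictly increasing")
    km = np.array([f.Km for f in mm_fits])
    kcat = np.array([f.kcat for f in mm_fits])
    km_rho = spearmanr(levels, km).statistic
    km_up = km_rho >= 0.7 and km[-1] > 1.3 * km[0]
    kcat_drop = (kcat[0] - np.min(kcat[1:])) / kcat[0] > 0.25
    if km_up and kcat_drop:
        return "mixed"
    if km_up:
        return "competitive"
    if kcat_drop:
        return "uncompetitive"
    return "none"


def ic50_competitive(k_ie: float, Km: float, s_cell: float) -> float:
    """IC50 (uM) for a competitive inhibitor at substrate s_cell:
    IC50 = K_IE (1 + s_cell / Km)."""
    if k_ie <= 0 or Km <= 0 or s_cell < 0:
        raise ValueError("k_ie, Km must be > 0 and s_cell >= 0")
    return k_ie * (1.0 + s_cell / Km)


def ic50_mixed(k_ie: float, k_ies: float, Km: float, s_cell: float) -> dict:
    """IC50 (uM) for a mixed inhibitor at substrate s_cell.

    Primary value: K_IE / ((Km / s_cell) + (K_IE / K_IES)) — the bracketed
    reading of the conventional shorthand.  The textbook Cheng-Prusoff
    style form (s_cell + Km) / (Km/K_IE + s_cell/K_IES) is returned
    alongside for comparison.
    """
    if min(k_ie, k_ies, Km, s_cell) <= 0:
        raise ValueError("all arguments must be > 0")
    primary = k_ie / ((Km / s_cell) + (k_ie / k_ies))
    textbook = (s_cell + Km) / (Km / k_ie + s_cell / k_ies)
    return {"IC50": primary, "IC50_textbook": textbook}


def fraction_inhibited(model: str, i: float, s: float, Km: float,
                       k_ie: float, k_ies: float | None = None) -> float:
    """Fraction of enzyme activity suppressed at inhibitor level i.

    competitive: the equilibrium fraction of free enzyme sequestered by
    inhibitor, (i/K_IE) / (1 + i/K_IE + s/Km).  mixed: the steady-state
    rate reduction 1 - v(i)/v(0).
    """
    if i < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    if model == "competitive":
        x = i / k_ie
        return x / (1.0 + x + s / Km)
    if model == "mixed":
        if k_ies is None:
            raise ValueError("mixed model requires k_ies")
        v0 = steady_state_rate(1.0, 1.0, Km, s, 0.0, "mixed", k_ie, k_ies)
        vi = steady_state_rate(1.0, 1.0, Km, s, i, "mixed", k_ie, k_ies)
        return 1.0 - vi / v0
    raise ValueError(f"unknown inhibition model {model!r}")


def rate_percentages(k_test: float, k_ref: float) -> dict:
    """Integer percent-of-reference and percent-inhibition for a rate pair.

    Rounding is half away from zero, matching the printed-table convention.
    """
    if k_ref <= 0:
        raise ValueError("k_ref must be > 0")
    if k_test < 0:
        raise ValueError("rates must be >= 0")
    frac = k_test / k_ref
    return {"percent_of_reference": round_half_away(100.0 * frac),
            "percent_inhibition": round_half_away(100.0 * (1.0 - frac))}
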