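"""Mechanistic model of the five-step MnmE GTPase cycle.

The cycle is modelled as one cooperative G-domain pair per MnmE dimer
traversing

    E_apo + T  -->  E_T  -->  D_T  -->  D_P  -->  (E_DP  -->)  E_D + Pi

i.e. nucleotide binding, G-domain dimerization, GTP hydrolysis inside the
closed dimer, dimer dissociation, and Pi release (concerted with
dissociation by default; a finite release rate inserts the transient
open-state E_DP seen in release-retarded variants).  GDP remains enzyme
bound under single-turnover conditions; its chase-induced exchange is
handled analytically by :func:`simulate_chase`.

Product inhibition: GDP forms a dead-end complex with the open apo enzyme
(competitive, K_IE_gdp); Pi binds both the free enzyme (K_IE_pi, slows
binding) and the substrate complex (K_IES_pi, slows hydrolysis).

Units: rate constants are min^-1 throughout the API; time grids are in
seconds.  The single conversion between the two lives in ``_PER_MIN``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import CycleParameters, InhibitorContext
from .trace import Trace

__all__ = [
    "SpeciesTimeseries",
    "ObservableMap",
    "DEFAULT_MAPS",
    "simulate_cycle",
    "bateman_chain",
    "project_observable",
    "effective_binding_rate",
    "steady_state_rate",
    "simulate_chase",
]

# min^-1 -> s^-1; the one place the unit boundary is crossed.
_PER_MIN = 1.0 / 60.0

SPECIES = ("T_free", "E_apo", "E_I", "E_T", "D_T", "D_P", "E_DP",
           "E_D", "Pi_free", "GDP_free")

#: Species whose concentration counts toward total enzyme.
ENZYME_SPECIES = ("E_apo", "E_I", "E_T", "D_T", "D_P", "E_DP", "E_D")


@dataclass
class SpeciesTimeseries:
    """Concentrations (uM) of the mechanistic species on a time grid (s)."""

    time: np.ndarray
    conc: pd.DataFrame  # columns = SPECIES
    e0: float
    t0: float
    params: CycleParameters
    inhibitors: InhibitorContext

    def enzyme_total(self) -> np.ndarray:
        return self.conc[list(ENZYME_SPECIES)].sum(axis=1).to_numpy()

    def gamma_phosphate_total(self) -> np.ndarray:
        """Total gamma-phosphate equivalents (should equal t0 at all times)."""
        cols = ["T_free", "E_T", "D_T", "D_P", "E_DP", "Pi_free"]
        return self.conc[cols].sum(axis=1).to_numpy()

    def nucleotide_total(self) -> np.ndarray:
        cols = ["T_free", "E_T", "D_T", "D_P", "E_DP", "E_D", "GDP_free"]
        return self.conc[cols].sum(axis=1).to_numpy()


@dataclass(frozen=True)
class ObservableMap:
    """Linear projection of species fractions onto one instrument channel.

    Coefficients are relative-signal units per unit nucleotide fraction
    (species concentration / t0).  Any species not listed contributes 0.
    """

    channel: str
    coefficients: dict = field(default_factory=dict)
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for k, v in self.coefficients.items():
            if k not in SPECIES:
                raise ValueError(f"unknown species {k!r} in ObservableMap")
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient for {k!r}")


# Default channel maps.  The mant coefficients encode the observation that
# hydrolysis itself (D_T -> D_P) produces no fluorescence change: binding
# raises the signal to ~0.095, dimerization to ~0.15, and only dimer
# dissociation drops it to ~0.10, so the decay phase reports dissociation.
DEFAULT_MAPS = {
    "mant": ObservableMap("mant", {
        "E_T": 0.095, "D_T": 0.15, "D_P": 0.15, "E_DP": 0.10, "E_D": 0.10,
    }),
    "fret": ObservableMap("fret", {
        "E_T": 1.0, "D_T": 1.0, "D_P": 1.0, "E_DP": 1.0, "E_D": 1.0,
    }),
    "pbp": ObservableMap("pbp", {"Pi_free": 1.0}),
    "quench": ObservableMap("quench", {
        "T_free": 100.0, "E_T": 100.0, "D_T": 100.0,
    }),
}


def _free_fraction(gdp: float, pi: float, ctx: InhibitorContext) -> float:
    """Fraction of the open apo pool not sequestered in dead-end complexes."""
    return 1.0 / (1.0 + gdp / ctx.K_IE_gdp) / (1.0 + pi / ctx.K_IE_pi)


def simulate_cycle(
    params: CycleParameters,
    e0: float,
    t0: float,
    inhibitors: InhibitorContext | None = None,
    t_grid: np.ndarray | None = None,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> SpeciesTimeseries:
    """Integrate the cycle from rapid 1:1 mixing of enzyme (e0) and GTP (t0).

    Binding is integrated as a saturating second-order step: the flux onto
    the nucleotide is k_max * E_avail/(K_D + E_avail) * [T] with the free
    enzyme co-consumed, which reduces exactly to the hyperbolic k_obs law
    under pseudo-first-order conditions and remains valid for equimolar
    mixing.  With ``params.pseudo_first_order_binding`` the flux is simply
    k_max * [T] (apparent-rate mode).

    Parameters are in uM / min^-1; ``t_grid`` in seconds, starting at 0.
    """
    ctx = inhibitors if inhibitors is not None else InhibitorContext.none()
    if e0 <= 0 or t0 <= 0:
        raise ValueError("e0 and t0 must be > 0")
    if t_grid is None:
        t_grid = np.arange(0.0, 17.0 + 1e-12, 0.01)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if t_grid.size >= 2 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if ctx.pi_conc > 2000.0:
        warnings.warn(
            "Pi above 2 mM: dissociation of GTP-containing dimers can add an "
            "atypical fluorescence contribution that this model ignores",
            stacklevel=2)

    kb = params.k_max_bind * _PER_MIN
    kdim = params.k_dim * _PER_MIN
    khyd = params.k_hyd * _PER_MIN
    kdiss = params.k_diss * _PER_MIN
    instant_pi = params.instantaneous_pi_release
    krel = 0.0 if instant_pi else params.k_pi_rel * _PER_MIN
    KD = params.K_D_bind

    # state: [T, A, E_T, D_T, D_P, E_DP, Pi]; A = apo pool incl. dead-end.
    def rhs(t, y):
        T, A, ET, DT, DP, EDP, Pi = y
        pi_tot = ctx.pi_conc + max(Pi, 0.0)
        if params.pseudo_first_order_binding:
            jb = kb * T
        else:
            e_avail = max(A, 0.0) * _free_fraction(ctx.gdp_conc, pi_tot, ctx)
            jb = kb * e_avail / (KD + e_avail) * T
        jdim = kdim * ET
        jhyd = khyd * DT / (1.0 + pi_tot / ctx.K_IES_pi)
        jdiss = kdiss * DP
        if instant_pi:
            jrel = jdiss
            dEDP = 0.0
        else:
            jrel = krel * EDP
            dEDP = jdiss - jrel
        return [
            -jb,
            -jb,
            jb - jdim,
            jdim - jhyd,
            jhyd - jdiss,
            dEDP,
            jrel,
        ]

    y0 = [t0, e0, 0.0, 0.0, 0.0, 0.0, 0.0]
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"cycle integration failed: {sol.message}")

    T, A, ET, DT, DP, EDP, Pi = sol.y
    pi_tot = ctx.pi_conc + np.clip(Pi, 0.0, None)
    f = 1.0 / (1.0 + ctx.gdp_conc / ctx.K_IE_gdp) / (1.0 + pi_tot / ctx.K_IE_pi)
    if instant_pi:
        ED = Pi.copy()
    else:
        ED = t0 - (T + ET + DT + DP + EDP)  # nucleotide balance
    conc = pd.DataFrame({
        "T_free": np.clip(T, 0.0, None),
        "E_apo": np.clip(A, 0.0, None) * f,
        "E_I": np.clip(A, 0.0, None) * (1.0 - f),
        "E_T": np.clip(ET, 0.0, None),
        "D_T": np.clip(DT, 0.0, None),
        "D_P": np.clip(DP, 0.0, None),
        "E_DP": np.clip(EDP, 0.0, None),
        "E_D": np.clip(ED, 0.0, None),
        "Pi_free": np.clip(Pi, 0.0, None),
        "GDP_free": np.zeros_like(T),
    })
    ts = SpeciesTimeseries(t_grid, conc, e0, t0, params, ctx)

    etot = ts.enzyme_total()
    if np.max(np.abs(etot - e0)) > 1e-6 * e0:
        raise RuntimeError(
            "enzyme mass not conserved: max relative drift "
            f"{np.max(np.abs(etot - e0)) / e0:.2e}")
    ptot = ts.gamma_phosphate_total()
    if np.max(np.abs(ptot - t0)) > 1e-6 * t0:
        raise RuntimeError(
            "phosphate mass not conserved: max relative drift "
            f"{np.max(np.abs(ptot - t0)) / t0:.2e}")
    return ts


def bateman_chain(rates, t, *, perturb: bool = False):
    """Closed-form occupancies of the linear chain S0 -> S1 -> ... -> Sn.

    ``rates`` (min^-1) are the n forward rate constants; ``t`` is in
    seconds.  Returns an array of shape (len(t), n+1) with state
    occupancies starting from S0 = 1; rows sum to 1.

    Rates must be pairwise distinct (relative separation > 1e-9).  Pass
    ``perturb=True`` to resolve near-degenerate rates by a 1e-6 relative
    perturbation (emits a warning).
    """
    k = np.asarray(rates, dtype=float) * _PER_MIN
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(k <= 0):
        raise ValueError("all rates must be > 0")
    n = k.size
    scale = np.max(k)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(k[i] - k[j]) <= 1e-9 * scale:
                if not perturb:
                    raise ValueError(
                        f"rates {i} and {j} are (near-)degenerate; the "
                        "closed form is singular — perturb the rates or "
                        "call with perturb=True")
                warnings.warn(
                    "degenerate Bateman rates perturbed by 1e-6 relative",
                    stacklevel=2)
                k[j] *= 1.0 + 1e-6 * (j + 1)

    occ = np.zeros((t.size, n + 1))
    exp_kt = np.exp(-np.outer(t, k))  # (nt, n)
    for i in range(n):
        # occupancy of intermediate state i (Bateman coefficients)
        pref = np.prod(k[:i]) if i > 0 else 1.0
        ci = np.empty(i + 1)
        for j in range(i + 1):
            denom = np.prod([k[l] - k[j] for l in range(i + 1) if l != j])
            ci[j] = pref / denom if i > 0 else 1.0
        occ[:, i] = exp_kt[:, :i + 1] @ ci
    occ[:, n] = 1.0 - occ[:, :n].sum(axis=1)
    return occ


def project_observable(states: SpeciesTimeseries,
                       obs_map: ObservableMap | str) -> Trace:
    """Project a species timeseries onto one instrument channel (noiseless).

    Signals are linear combinations of nucleotide fractions
    (concentration / t0); the quench channel yields % uncleaved GTP and the
    pbp channel the released-Pi fraction (sensor binding treated as
    instantaneous and non-depleting).
    """
    if isinstance(obs_map, str):
        try:
            obs_map = DEFAULT_MAPS[obs_map]
        except KeyError:
            raise ValueError(
                f"unknown channel {obs_map!r}; expected one of "
                f"{tuple(DEFAULT_MAPS)}") from None
    sig = np.full(states.time.shape, obs_map.baseline, dtype=float)
    for sp, coef in obs_map.coefficients.items():
        sig = sig + coef * states.conc[sp].to_numpy() / states.t0
    return Trace(obs_map.channel, states.time, sig,
                 construct_label=states.params.label,
                 meta={"e0": states.e0, "t0": states.t0})


def effective_binding_rate(params: CycleParameters, e_conc: float,
                           gdp_conc: float = 0.0,
                           ctx: InhibitorContext | None = None) -> float:
    """Apparent first-order binding rate (min^-1) at enzyme excess.

    k_obs = k_max [E] / (K_D + [E]), scaled by the GDP dead-end factor
    1/(1 + [GDP]/K_IE_gdp).
    """
    if e_conc < 0:
        raise ValueError("e_conc must be >= 0")
    ctx = ctx if ctx is not None else InhibitorContext.none()
    hyper = params.k_max_bind * e_conc / (params.K_D_bind + e_conc)
    return hyper / (1.0 + gdp_conc / ctx.K_IE_gdp)


def steady_state_rate(kcat: float, e0: float, Km: float, s: float,
                      i: float = 0.0, model: str = "competitive",
                      ki_e: float = np.inf, ki_es: float = np.inf) -> float:
    """Steady-state initial rate (uM min^-1) under product inhibition.

    competitive:  v = kcat e0 s / (Km (1 + i/ki_e) + s)
    mixed:        v = kcat e0 s / (Km (1 + i/ki_e) + s (1 + i/ki_es))
    """
    if Km <= 0 or ki_e <= 0 or ki_es <= 0:
        raise ValueError("Km and inhibition constants must be > 0")
    vmax = kcat * e0
    if model == "competitive":
        return vmax * s / (Km * (1.0 + i / ki_e) + s)
    if model == "mixed":
        return vmax * s / (Km * (1.0 + i / ki_e) + s * (1.0 + i / ki_es))
    raise ValueError(f"unknown inhibition model {model!r}")


def simulate_chase(params: CycleParameters, competitor_conc: float,
                   t_add: float, t_grid: np.ndarray,
                   rebind_weight: float | None = None,
                   e0: float = 2.5) -> Trace:
    """FRET chase: excess unlabelled GTP displaces enzyme-bound mGDP.

    Before ``t_add`` the signal sits at the mGDP-bound plateau (1.0
    relative units).  After competitor addition the signal decays single
    exponentially at the exchange-limited off-rate k_gdp_off; the
    amplitude is the partition fraction comp/(comp + w), where the
    rebinding weight w (default: the released-mGDP pool, e0, at equal
    competitor/mGDP affinity) captures recapture of the labelled
    nucleotide, so the rate is competitor independent while the amplitude
    saturates with competitor.
    """
    if competitor_conc < 0:
        raise ValueError("competitor concentration must be >= 0")
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid[0] <= t_add <= t_grid[-1]):
        raise ValueError("t_add must lie within t_grid")
    w = e0 if rebind_weight is None else rebind_weight
    amp = 0.0 if competitor_conc == 0 else competitor_conc / (competitor_conc + w)
    k = params.k_gdp_off * _PER_MIN
    sig = np.ones_like(t_grid)
    post = t_grid >= t_add
    sig[post] = 1.0 - amp * (1.0 - np.exp(-k * (t_grid[post] - t_add)))
    return Trace("fret", t_grid, sig, construct_label=params.label,
                 meta={"competitor_uM": competitor_conc, "t_add_s": t_add,
                       "amplitude": amp})
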