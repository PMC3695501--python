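"""Seeded synthetic-data generators emulating the single-turnover experiments.

Each generator produces the noiseless model output from
:mod:`mnmekin.cycle` plus additive i.i.d. Gaussian noise; replicate ``r``
of a call with seed ``s`` uses ``numpy.random.default_rng(s + r)``, so a
repeated call is bit-identical.  Defaults follow the experimental design:
optical traces sampled at 10 ms and averaged over six mixing replicates,
quench-flow sampled at 12 points over 12 s, initial rates carrying a few
percent relative error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cycle as _cycle
from .panels import MutantKineticProfile, get_profile, mutant_panel
from .params import CycleParameters, InhibitorContext
from .trace import Trace

__all__ = [
    "Trace",
    "KobsTitration",
    "InhibitionGrid",
    "MutantKineticProfile",
    "mutant_panel",
    "get_profile",
    "generate_traces",
    "generate_quench_flow",
    "generate_kobs_titration",
    "generate_inhibition_grid",
    "DEAD_TIME_S",
]

#: Stopped-flow dead time discarded from the start of optical traces.
DEAD_TIME_S = 0.002


@dataclass
class KobsTitration:
    """Observed step rates versus enzyme concentration for hyperbolic fitting."""

    e_concs: np.ndarray        # uM
    k_obs: np.ndarray          # min^-1
    step: str                  # binding | dimerization | dissociation
    seed: int | None = None

    def __post_init__(self) -> None:
        self.e_concs = np.asarray(self.e_concs, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.step not in ("binding", "dimerization", "dissociation"):
            raise ValueError(f"unknown step {self.step!r}")
        if self.e_concs.size < 4:
            raise ValueError("need >= 4 concentrations for hyperbolic fitting")
        if np.any(self.e_concs <= 0):
            raise ValueError("enzyme concentrations must be > 0")
        if np.unique(self.e_concs).size != self.e_concs.size:
            raise ValueError("degenerate design: duplicate enzyme concentrations")


@dataclass
class InhibitionGrid:
    """Initial rates on a rectangular [substrate] x [inhibitor] grid.

    ``rates`` has shape (len(substrate), len(inhibitor)); units are
    uM min^-1 (initial velocities) or min^-1 (step rate constants) —
    the inhibition analyses are invariant to which.
    """

    substrate: np.ndarray
    inhibitor: np.ndarray
    rates: np.ndarray
    inhibitor_name: str = "GDP"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.inhibitor = np.asarray(self.inhibitor, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (self.substrate.size, self.inhibitor.size):
            raise ValueError("rates must be rectangular: (n_substrate, n_inhibitor)")
        if self.substrate.size < 2 or self.inhibitor.size < 2:
            raise ValueError("need >= 2 substrate and inhibitor levels")
        if np.any(self.rates <= 0):
            raise ValueError("all rates must be > 0")

    def to_frame(self) -> pd.DataFrame:
        s, i = np.meshgrid(self.substrate, self.inhibitor, indexing="ij")
        return pd.DataFrame({"substrate_uM": s.ravel(),
                             "inhibitor_uM": i.ravel(),
                             "rate": self.rates.ravel()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, inhibitor_name: str = "GDP"
                   ) -> "InhibitionGrid":
        required = {"substrate_uM", "inhibitor_uM", "rate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"grid CSV missing columns: {sorted(missing)}")
        piv = df.pivot_table(index="substrate_uM", columns="inhibitor_uM",
                             values="rate")
        if piv.isna().any().any():
            raise ValueError("grid is not rectangular (missing cells)")
        return cls(piv.index.to_numpy(), piv.columns.to_numpy(),
                   piv.to_numpy(), inhibitor_name)


def generate_traces(
    params: CycleParameters,
    channel: str = "mant",
    e0: float = 2.5,
    t0: float = 2.5,
    duration: float = 17.0,
    dt: float = 0.01,
    noise_sd: float = 0.003,
    n_replicates: int = 6,
    seed: int = 0,
    inhibitors: InhibitorContext | None = None,
    dead_time: float = DEAD_TIME_S,
) -> tuple[list[Trace], Trace]:
    """Simulate one optical single-turnover experiment with replicates.

    Returns ``(replicates, average)``.  Each replicate is the noiseless
    channel projection plus N(0, noise_sd) per point; the average trace
    carries ``noise_sd / sqrt(n_replicates)``.  The instrument dead time
    (default 2 ms) is trimmed from the front of the grid.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration < 10 * dt:
        raise ValueError("grid too coarse: duration must cover >= 10 samples")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    n = int(round(duration / dt))
    grid = np.linspace(0.0, n * dt, n + 1)
    states = _cycle.simulate_cycle(params, e0, t0, inhibitors, grid)
    clean = _cycle.project_observable(states, channel)
    keep = clean.time >= dead_time
    t, y = clean.time[keep], clean.signal[keep]

    reps = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        noisy = y + rng.normal(0.0, noise_sd, size=y.size) if noise_sd > 0 else y.copy()
        reps.append(Trace(channel, t, noisy, noise_sd=noise_sd,
                          n_replicates=1, seed=seed + r,
                          construct_label=params.label,
                          meta={"e0": e0, "t0": t0}))
    avg = Trace(channel, t, np.mean([tr.signal for tr in reps], axis=0),
                noise_sd=noise_sd / np.sqrt(n_replicates),
                n_replicates=n_replicates, seed=seed,
                construct_label=params.label, meta={"e0": e0, "t0": t0})
    return reps, avg


def generate_quench_flow(
    params: CycleParameters,
    e0: float = 50.0,
    t0: float = 50.0,
    timepoints: np.ndarray | None = None,
    noise_frac: float = 0.02,
    seed: int = 0,
    n_replicates: int = 1,
    inhibitors: InhibitorContext | None = None,
) -> Trace:
    """Quench-flow % uncleaved GTP over ~12 s at 1:1 enzyme:GTP (50 uM post-mix).

    Default grid: the t = 0 normalization control plus 11 log-spaced
    points from 0.4 to 12 s — the first quenched point is placed past the
    binding/dimerization transient (complete within ~0.3 s at these
    concentrations) so the sampled decay isolates the hydrolysis step.
    Noise is relative (``noise_frac`` of the signal), averaged over
    ``n_replicates`` quenched reactions, and the result is clipped at 0.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if timepoints is None:
        timepoints = np.concatenate(
            [[0.0], np.geomspace(0.4, 12.0, 11)])
    timepoints = np.asarray(timepoints, dtype=float)
    grid = timepoints if timepoints[0] == 0.0 else np.concatenate([[0.0], timepoints])
    states = _cycle.simulate_cycle(params, e0, t0, inhibitors, grid)
    clean = _cycle.project_observable(states, "quench")
    y = np.interp(timepoints, clean.time, clean.signal)
    if noise_frac > 0:
        draws = []
        for r in range(n_replicates):
            rng = np.random.default_rng(seed + r)
            draws.append(y + rng.normal(0.0, noise_frac * np.abs(y)))
        y = np.clip(np.mean(draws, axis=0), 0.0, None)
    return Trace("quench", timepoints, y, noise_sd=noise_frac,
                 n_replicates=n_replicates, seed=seed,
                 construct_label=params.label, meta={"e0": e0, "t0": t0})


def generate_kobs_titration(
    params: CycleParameters,
    step: str = "binding",
    e_concs: np.ndarray | None = None,
    noise_frac: float = 0.05,
    seed: int = 0,
) -> KobsTitration:
    """Observed-rate titration over enzyme concentration for one cycle step.

    Rates follow the saturating law k_max [E]/(K_D + [E]) with the step's
    maximum rate (k_max_bind, k_dim or k_diss) and the binding K_D as the
    half-saturation point, times (1 + Gaussian relative noise).
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if e_concs is None:
        e_concs = np.geomspace(0.5, 50.0, 8)
    e_concs = np.asarray(e_concs, dtype=float)
    k_max = {"binding": params.k_max_bind,
             "dimerization": params.k_dim,
             "dissociation": params.k_diss}.get(step)
    if k_max is None:
        raise ValueError(f"unknown step {step!r}")
    k = k_max * e_concs / (params.K_D_bind + e_concs)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        k = k * (1.0 + rng.normal(0.0, noise_frac, size=k.size))
    return KobsTitration(e_concs, k, step, seed=seed)


def generate_inhibition_grid(
    kcat: float,
    e0: float,
    Km: float,
    inhibitor: str = "GDP",
    ki_e: float = 41.2,
    ki_es: float | None = None,
    s_list: np.ndarray | None = None,
    i_list: np.ndarray | None = None,
    noise_frac: float = 0.03,
    seed: int = 0,
    model: str | None = None,
) -> InhibitionGrid:
    """Initial-rate grid over [substrate] x [inhibitor] from the steady-state law.

    The inhibition model is implied by the inhibitor identity (GDP ->
    competitive, Pi -> mixed) unless ``model`` overrides it.  Rates are
    v0 * (1 + Gaussian relative noise).
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if model is None:
        model = "competitive" if inhibitor.upper() == "GDP" else "mixed"
    if model == "mixed" and ki_es is None:
        raise ValueError("mixed model requires ki_es")
    if s_list is None:
        s_list = np.array([5.0, 20.0, 50.0])
    if i_list is None:
        i_list = np.linspace(0.0, 100.0, 5)
    s_list = np.asarray(s_list, dtype=float)
    i_list = np.asarray(i_list, dtype=float)
    if s_list.size < 3 or i_list.size < 3:
        raise ValueError("need >= 3 substrate and >= 3 inhibitor levels")
    v = np.empty((s_list.size, i_list.size))
    for a, s in enumerate(s_list):
        for b, i in enumerate(i_list):
            v[a, b] = _cycle.steady_state_rate(
                kcat, e0, Km, s, i, model=model, ki_e=ki_e,
                ki_es=np.inf if ki_es is None else ki_es)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, noise_frac, size=v.shape))
    return InhibitionGrid(s_list, i_list, v, inhibitor_name=inhibitor,
                          meta={"model": model, "kcat": kcat, "Km": Km,
                                "e0": e0, "ki_e": ki_e, "ki_es": ki_es,
                                "seed": seed, "noise_frac": noise_frac})
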