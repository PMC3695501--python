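"""Parameter containers for the five-step MnmE GTPase cycle.

All rate constants are stored in min^-1 (the field's reporting convention);
time grids everywhere else in the package are in seconds.  The single
min->s conversion lives in :mod:`mnmekin.cycle`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CycleParameters",
    "InhibitorContext",
    "CellularContext",
    "INSTANTANEOUS",
]

#: Sentinel for "Pi release occurs instantaneously upon G-domain dissociation".
INSTANTANEOUS = math.inf


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CycleParameters:
    """Rate and affinity constants of one MnmE construct.

    The cycle is: GTP binding (saturating, k_max_bind / K_D_bind) ->
    G-domain dimerization (k_dim) -> GTP hydrolysis (k_hyd) ->
    G-domain dissociation (k_diss) -> Pi release (k_pi_rel; infinite
    means release is concerted with dissociation).  GDP stays bound
    under single-turnover conditions; k_gdp_off is the exchange-limited
    off-rate seen only when a chase competitor is present.

    Rates in min^-1, concentrations in uM.
    """

    k_max_bind: float = 3896.0
    K_D_bind: float = 0.60
    k_dim: float = 717.0
    k_hyd: float = 201.0
    k_diss: float = 12.4
    k_pi_rel: float = INSTANTANEOUS
    k_gdp_off: float = 300.0
    K_D_gdp: float = 0.5
    label: str = "wt"
    #: When True the binding step is applied as a pure first-order rate
    #: k_max_bind on the nucleotide (apparent-rate mode for panel fits).
    pseudo_first_order_binding: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("k_max_bind", "k_dim", "k_hyd", "k_diss",
                     "k_pi_rel", "k_gdp_off"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.K_D_bind > 0, "K_D_bind must be > 0")
        _require(self.K_D_gdp > 0, "K_D_gdp must be > 0")

    @property
    def instantaneous_pi_release(self) -> bool:
        return math.isinf(self.k_pi_rel)

    def with_(self, **changes) -> "CycleParameters":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class InhibitorContext:
    """Product concentrations present at mixing plus their inhibition constants.

    GDP acts as a dead-end competitive inhibitor on the free enzyme
    (K_IE_gdp); inorganic phosphate binds both the free enzyme (K_IE_pi)
    and the enzyme-substrate complex (K_IES_pi), slowing hydrolysis.
    Concentrations and constants in uM.
    """

    gdp_conc: float = 0.0
    pi_conc: float = 0.0
    K_IE_gdp: float = 41.2
    K_IE_pi: float = 670.0
    K_IES_pi: float = 5800.0

    def __post_init__(self) -> None:
        _require(self.gdp_conc >= 0 and self.pi_conc >= 0,
                 "inhibitor concentrations must be >= 0")
        for name in ("K_IE_gdp", "K_IE_pi", "K_IES_pi"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    @classmethod
    def none(cls) -> "InhibitorContext":
        return cls()


@dataclass(frozen=True)
class CellularContext:
    """Estimated steady-state nucleotide/phosphate pools in E. coli (uM)."""

    gtp_cellular: float = 5000.0
    gdp_cellular: float = 700.0
    pi_cellular: float = 10000.0

    def __post_init__(self) -> None:
        for name in ("gtp_cellular", "gdp_cellular", "pi_cellular"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
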