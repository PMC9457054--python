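"""Closed-form limits on maintaining and accumulating genetic information.

Asymptotics for the single-locus mutation-selection-drift balance, derived in
the diffusion limit, and the back-of-envelope accumulation-capacity
arithmetic.  Two regimes matter:

* Weak selection (Ns << 1): selection perturbs each allele-frequency
  distribution only slightly, and information is maintained at an efficiency
  of up to ``N / (mu (1 + 4 N mu))`` bits per unit cost -- approaching
  ``N / mu`` when mutation is also weak and ``1 / (4 mu^2)`` when N mu >> 1.
* Strong selection (Ns >> 1): deleterious mutations are purged as they
  arise, each purge costing about ``1/(N ln 2)`` bits, so efficiency falls
  to about ``ln(2) / mu`` bits per unit cost, independent of N.

These are the dotted asymptotes of the stationary single-locus scan
(:func:`evoinfo.single_locus_wf.maintenance_scan` is the exact counterpart).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegimeParams",
    "efficiency_weak",
    "efficiency_strong",
    "weak_selection_stationary",
    "accumulation_capacity",
    "efficiency_table",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class RegimeParams:
    """Scaled single-locus parameters: N, mu, s and the derived Ns, N mu."""

    N: int
    mu: float
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N={self.N!r} must be >= 2")
        if self.mu <= 0:
            raise ValueError(f"mu={self.mu!r} must be positive")

    @property
    def Ns(self) -> float:
        return self.N * self.s

    @property
    def Nmu(self) -> float:
        return self.N * self.mu


def efficiency_weak(params: RegimeParams) -> float:
    """Weak-selection maintenance efficiency N / (mu (1 + 4 N mu)).

    Bits of genotype-level information maintained per unit cost of selection
    in the limit Ns << 1.  A warning is issued when called outside that
    regime; the formula itself is the object of study and is always returned.
    """
    if params.s != 0.0 and params.Ns >= 1.0:
        warnings.warn(
            f"Ns = {params.Ns:g} is not << 1; the weak-selection efficiency "
            "is an extrapolation here", stacklevel=2)
    return params.N / (params.mu * (1.0 + 4.0 * params.Nmu))


def efficiency_strong(mu: float) -> float:
    """Strong-selection maintenance efficiency ln(2) / mu bits per unit cost."""
    if mu <= 0:
        raise ValueError(f"mu={mu!r} must be positive")
    return _LN2 / mu


def weak_selection_stationary(params: RegimeParams) -> tuple[float, float]:
    """Diffusion approximations (D_G, <C>) at weak mutation-selection balance.

    For Ns << 1 and N mu << 1 the stationary genotype-level information is
    approximately ``N^2 s^2 / (2 ln 2)`` bits and the mean cost of selection
    ``N mu s^2 / (2 ln 2)`` bits per generation (their ratio is exactly
    N / mu).  Warns outside the stated regime.
    """
    if params.Ns >= 1.0 or params.Nmu >= 1.0:
        warnings.warn(
            f"(Ns, Nmu) = ({params.Ns:g}, {params.Nmu:g}) outside the weak "
            "regime; approximations may be poor", stacklevel=2)
    D_G = params.N ** 2 * params.s ** 2 / (2.0 * _LN2)
    C = params.N * params.mu * params.s ** 2 / (2.0 * _LN2)
    return D_G, C


def accumulation_capacity(k: int, N: float, C_bar: float, T: float) -> float:
    """Upper bound k * N * <C> * T on information accumulated over T
    generations at mean per-generation cost <C> (bits)."""
    if min(k, N, C_bar, T) < 0:
        raise ValueError("all arguments must be nonnegative")
    return float(k * N * C_bar * T)


def efficiency_table(N_values, mu_values) -> pd.DataFrame:
    """Tidy table of weak- and strong-selection efficiencies over a grid."""
    rows = []
    for N in N_values:
        for mu in mu_values:
            p = RegimeParams(N=int(N), mu=float(mu))
            rows.append({
                "N": int(N), "mu": float(mu), "Nmu": p.Nmu,
                "efficiency_weak": efficiency_weak(p),
                "efficiency_strong": efficiency_strong(mu),
            })
    return pd.DataFrame(rows)
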