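"""Cost-of-selection measures for a single population state.

When parents are sampled for the next generation, a genotype ``g`` present at
frequency ``x_g`` is picked with probability ``x_g`` under neutrality and
``x_g * w_hat_g`` under selection, where ``w_hat_g = w_g / w_bar`` is relative
fitness.  Three measures quantify how hard selection is working in state x:

* ``C(x) = sum_g x_g w_hat_g log2(w_hat_g)`` -- the KL divergence, in bits,
  between the selection-weighted and neutral parental sampling distributions
  (the per-individual KL cost of control);
* ``V(x) = sum_g x_g (w_hat_g - 1)^2``      -- relative fitness variance;
* ``L(x) = 1 - 1 / w_hat_max(x)``           -- genetic load, with
  ``w_hat_max`` the largest relative fitness among genotypes actually present.

They obey C <= V/ln2, C <= log2(1/(1-L)) and V <= L/(1-L); under weak
selection C ~= V/(2 ln 2).  Only relative fitness matters: rescaling all
``w_g`` by a positive constant leaves every measure unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable
import json

import numpy as np

__all__ = [
    "PopulationState",
    "CostSummary",
    "InequalityReport",
    "cost_summary",
    "truncation_cost",
    "check_cost_inequalities",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class PopulationState:
    """Genotype frequencies and their (already evaluated) absolute fitnesses.

    Frequency-dependent fitness is the caller's responsibility: ``fitnesses``
    are the values ``w_g(x)`` at this particular ``x``.  Fitness 0 is allowed
    for genotypes excluded from reproduction (truncation selection); negative
    fitness is not.
    """

    labels: tuple
    freqs: np.ndarray
    fitnesses: np.ndarray

    def __init__(self, labels: Iterable, freqs, fitnesses) -> None:
        labels = tuple(labels)
        freqs = np.asarray(freqs, dtype=float)
        fitnesses = np.asarray(fitnesses, dtype=float)
        if not (len(labels) == freqs.size == fitnesses.size):
            raise ValueError("labels, freqs and fitnesses must align")
        if np.any(freqs < 0):
            raise ValueError("negative genotype frequency")
        total = freqs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total!r}, not 1")
        if np.any(fitnesses < 0):
            raise ValueError("negative fitness")
        if np.all(fitnesses[freqs > 0] == 0):
            raise ValueError("no present genotype has positive fitness")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "freqs", freqs / total)
        object.__setattr__(self, "fitnesses", fitnesses)
        self.freqs.setflags(write=False)
        self.fitnesses.setflags(write=False)


@dataclass(frozen=True)
class CostSummary:
    """C (bits), V (dimensionless), L in [0, 1), and the max relative fitness."""

    C: float
    V: float
    L: float
    w_max_rel: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def cost_summary(state: PopulationState) -> CostSummary:
    """Evaluate C(x), V(x), L(x) and w_hat_max for one population state.

    Genotypes with ``x_g * w_hat_g = 0`` contribute 0 to C (the ``0 log 0``
    convention); ``w_hat_max`` is taken over genotypes with ``x_g > 0``.
    """
    x = state.freqs
    w = state.fitnesses
    w_bar = float(np.dot(x, w))
    w_hat = w / w_bar
    present = x > 0
    xw = x * w_hat
    pos = xw > 0
    C = float(np.sum(xw[pos] * np.log2(w_hat[pos])))
    V = float(np.dot(x, (w_hat - 1.0) ** 2))
    w_max_rel = float(np.max(w_hat[present]))
    L = 1.0 - 1.0 / w_max_rel
    return CostSummary(C=C, V=V, L=L, w_max_rel=w_max_rel)


def truncation_cost(N: int) -> tuple[float, float]:
    """Cost of purging one deleterious individual by truncation selection.

    Models the state where the top fraction ``alpha = 1 - 1/N`` of the
    population reproduces with equal fitness and the remaining individual
    (frequency ``1/N``) does not reproduce at all.  Returns ``(exact,
    approx)``: the exact ``C`` of that two-class state,
    ``-log2(1 - 1/N)``, and the large-N approximation ``1/(N ln 2)``.
    """
    if N < 2:
        raise ValueError(f"N={N!r} must be >= 2")
    alpha = 1.0 - 1.0 / N
    state = PopulationState(
        labels=("reproducing", "purged"),
        freqs=(alpha, 1.0 - alpha),
        fitnesses=(1.0, 0.0),
    )
    exact = cost_summary(state).C
    approx = 1.0 / (N * _LN2)
    return exact, approx


@dataclass(frozen=True)
class InequalityReport:
    """Slack of each cost inequality for one state (all slacks >= 0 if valid).

    ``weak_selection_ratio`` is C / (V / (2 ln 2)), which approaches 1 as
    fitness differences shrink.
    """

    summary: CostSummary
    slack_C_le_V: float       # V/ln2 - C
    slack_C_le_load: float    # log2(1/(1-L)) - C
    slack_V_le_load: float    # L/(1-L) - V
    weak_selection_ratio: float

    @property
    def all_hold(self) -> bool:
        tol = 1e-12
        return (self.slack_C_le_V >= -tol and self.slack_C_le_load >= -tol
                and self.slack_V_le_load >= -tol)


def check_cost_inequalities(state: PopulationState) -> InequalityReport:
    """Evaluate C <= V/ln2, C <= log2(1/(1-L)), V <= L/(1-L) and the
    weak-selection ratio C / (V / 2 ln 2) for one state."""
    s = cost_summary(state)
    load_bound = np.log2(1.0 / (1.0 - s.L)) if s.L < 1.0 else np.inf
    v_load_bound = s.L / (1.0 - s.L) if s.L < 1.0 else np.inf
    ratio = s.C / (s.V / (2.0 * _LN2)) if s.V > 0 else 1.0
    return InequalityReport(
        summary=s,
        slack_C_le_V=s.V / _LN2 - s.C,
        slack_C_le_load=float(load_bound - s.C),
        slack_V_le_load=float(v_load_bound - s.V),
        weak_selection_ratio=float(ratio),
    )
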