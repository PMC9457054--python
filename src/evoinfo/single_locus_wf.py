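"""Exact haploid single-locus two-allele Wright-Fisher machinery.

The population carries ``i`` copies of allele A (``0 <= i <= N``), and one
generation consists of, in order:

1. selection -- parents are drawn with probability proportional to fitness,
   so the allele-A sampling probability becomes
   ``p_sel = x w_A / (x w_A + (1 - x) w_a)`` with ``x = i/N``;
2. symmetric mutation -- ``p'' = p_sel (1 - mu) + (1 - p_sel) mu``;
3. binomial resampling of N offspring, ``i' ~ Binomial(N, p'')``.

Everything downstream is exact linear algebra on the (N+1)-state Markov
chain: distribution propagation under selection and neutrality side by side,
stationary distributions, genotype (allele) marginals, and the two in-silico
experiments -- information accumulation during the fixation or loss of a
single beneficial copy, and accumulation from a neutral stationary start when
selection is switched on.  Each experiment verifies the per-generation
accumulation bound ``dD(X^t) <= k N <C>_t`` and its cumulative form as it
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .info_measures import ProbVector, PairedEnsemble, kl_divergence, fixation_information
from .selection_cost import PopulationState, cost_summary

__all__ = [
    "WFModel",
    "TrajectorySummary",
    "transition_matrix",
    "propagate",
    "stationary_distribution",
    "genotype_marginal",
    "information_levels",
    "state_costs",
    "absorption_probability",
    "fixation_experiment",
    "accumulation_experiment",
    "maintenance_scan",
    "kimura_fixation_probability",
]

#: Propagation stops once this much probability mass is absorbed at {0, N}.
ABSORPTION_TOL = 1e-10

#: Per-generation slack allowed when asserting the accumulation bound.
BOUND_TOL = 1e-9

FitnessRule = Callable[[float], tuple[float, float]]


def constant_selection(s: float) -> FitnessRule:
    """Frequency-independent fitnesses w_a = 1, w_A = 1 + s."""
    def rule(x: float) -> tuple[float, float]:
        return 1.0, 1.0 + s
    return rule


@dataclass(frozen=True)
class WFModel:
    """Haploid single-locus two-allele Wright-Fisher specification.

    Parameters
    ----------
    N
        Population size (haploid individuals), >= 2.
    mu
        Symmetric per-copy per-generation mutation probability in [0, 1/2].
    s
        Selection coefficient of allele A under the default constant-fitness
        rule (w_a, w_A) = (1, 1 + s).  Ignored if ``fitness_rule`` is given.
    fitness_rule
        Optional map from the allele-A frequency ``x`` to the fitness pair
        ``(w_a, w_A)``; enables arbitrary frequency-dependent selection.
    """

    N: int
    mu: float
    s: float = 0.0
    fitness_rule: FitnessRule | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N={self.N!r} must be >= 2")
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError(f"mu={self.mu!r} outside [0, 1/2]")
        if self.s <= -1.0:
            raise ValueError(f"s={self.s!r} must exceed -1")

    def fitnesses(self, x: float) -> tuple[float, float]:
        """(w_a, w_A) at allele-A frequency x."""
        if self.fitness_rule is not None:
            w_a, w_A = self.fitness_rule(x)
        else:
            w_a, w_A = 1.0, 1.0 + self.s
        if w_a <= 0 or w_A <= 0:
            raise ValueError(f"nonpositive fitness at x={x!r}: ({w_a}, {w_A})")
        return w_a, w_A

    @property
    def counts(self) -> np.ndarray:
        return np.arange(self.N + 1)


def transition_matrix(model: WFModel, selected: bool = True) -> np.ndarray:
    """Row-stochastic (N+1)x(N+1) matrix over allele-A counts.

    Rows index the current count, columns the next; ``selected=False``
    replaces the fitness rule by w_a = w_A (pure drift plus mutation).
    """
    N, mu = model.N, model.mu
    i = model.counts
    x = i / N
    if selected:
        pairs = np.array([model.fitnesses(xi) for xi in x])
        w_a, w_A = pairs[:, 0], pairs[:, 1]
        denom = x * w_A + (1.0 - x) * w_a
        p_sel = x * w_A / denom
    else:
        p_sel = x
    p = p_sel * (1.0 - mu) + (1.0 - p_sel) * mu
    # rows of binomial pmfs: entry [i, j] = P(Binom(N, p[i]) = j)
    return stats.binom.pmf(i[None, :], N, p[:, None])


def propagate(
    model: WFModel,
    initial: np.ndarray,
    generations: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate one initial distribution under selection and neutrality.

    Returns ``(psi, phi)``, each of shape ``(generations + 1, N + 1)``, with
    ``psi[0] == phi[0] == initial``: the selected and neutral ensembles at
    every generation, obtained by repeated vector-matrix products.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (model.N + 1,):
        raise ValueError(f"initial distribution must have length {model.N + 1}")
    M_sel = transition_matrix(model, selected=True)
    M_neu = transition_matrix(model, selected=False)
    psi = np.empty((generations + 1, model.N + 1))
    phi = np.empty_like(psi)
    psi[0] = phi[0] = initial / initial.sum()
    for t in range(generations):
        psi[t + 1] = psi[t] @ M_sel
        phi[t + 1] = phi[t] @ M_neu
    return psi, phi


def stationary_distribution(
    model: WFModel,
    selected: bool = True,
    method: str = "direct",
    tol: float = 1e-13,
    max_iter: int = 10_000_000,
) -> np.ndarray:
    """Unique stationary distribution of the mutation-selection-drift chain.

    Requires ``mu > 0`` (irreducibility).  ``method='direct'`` solves the
    linear system ``v (M - I) = 0`` with the normalisation constraint
    appended; ``method='power'`` iterates ``v <- v M`` until the L1 change
    drops below ``tol``.
    """
    if model.mu <= 0.0:
        raise ValueError(
            "mu = 0 makes the boundary states absorbing; use "
            "absorption_probability for fixation analysis instead"
        )
    M = transition_matrix(model, selected=selected)
    n = model.N + 1
    if method == "direct":
        A = M.T - np.eye(n)
        A[-1, :] = 1.0          # replace one redundant equation by sum(v) = 1
        b = np.zeros(n)
        b[-1] = 1.0
        v = np.linalg.solve(A, b)
        v = np.clip(v, 0.0, None)
        return v / v.sum()
    if method == "power":
        v = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            nxt = v @ M
            if np.abs(nxt - v).sum() < tol:
                return nxt / nxt.sum()
            v = nxt
        raise RuntimeError(f"power iteration did not converge within {max_iter}")
    raise ValueError(f"unknown method {method!r}")


def genotype_marginal(probs: np.ndarray, N: int) -> ProbVector:
    """Allele distribution of one genotype sampled from a random population.

    P(A) = sum_i P(count = i) * i / N; returns a two-point distribution over
    labels ('a', 'A').
    """
    probs = np.asarray(probs, dtype=float)
    p_A = float(np.dot(probs, np.arange(N + 1))) / N
    return ProbVector(("a", "A"), (1.0 - p_A, p_A))


def information_levels(
    psi: np.ndarray, phi: np.ndarray, N: int
) -> tuple[float, float]:
    """(D_X, D_G) in bits for one selected/neutral state-distribution pair."""
    counts = tuple(range(N + 1))
    D_X = kl_divergence(PairedEnsemble.from_arrays(counts, psi, phi))
    D_G = kl_divergence(
        PairedEnsemble(genotype_marginal(psi, N), genotype_marginal(phi, N))
    )
    return D_X, D_G


def state_costs(model: WFModel) -> np.ndarray:
    """Cost of selection C(x_i) in bits for every allele count i = 0..N."""
    N = model.N
    out = np.empty(N + 1)
    for i in range(N + 1):
        x = i / N
        w_a, w_A = model.fitnesses(x)
        if i == 0 or i == N:
            out[i] = 0.0       # monomorphic: no fitness variation
            continue
        state = PopulationState(("a", "A"), (1.0 - x, x), (w_a, w_A))
        out[i] = cost_summary(state).C
    return out


def absorption_probability(model: WFModel, start_count: int = 1) -> float:
    """Fixation probability of allele A by linear solve, mu = 0 only.

    Solves ``(I - Q) h = r`` on the transient states 1..N-1, where Q is the
    transient block of the selected transition matrix and r the one-step
    probabilities of hitting the absorbing state N.
    """
    if model.mu != 0.0:
        raise ValueError("absorption analysis requires mu = 0")
    M = transition_matrix(model, selected=True)
    Q = M[1:-1, 1:-1]
    r = M[1:-1, -1]
    h = np.linalg.solve(np.eye(model.N - 1) - Q, r)
    if start_count == 0:
        return 0.0
    if start_count == model.N:
        return 1.0
    return float(h[start_count - 1])


@dataclass
class TrajectorySummary:
    """Per-generation information and cost series for one experiment.

    All series are in bits.  ``cost_rate[t] = k N <C>_t`` is the accumulation
    bound on ``dD_X[t] = D_X[t+1] - D_X[t]``; ``cost_cum`` is its running sum
    (nondecreasing), bounding ``D_X[t] - D_X[0]`` cumulatively.
    """

    k: int
    D_X: np.ndarray
    D_G: np.ndarray
    dD_X: np.ndarray
    dD_G: np.ndarray
    cost_rate: np.ndarray
    cost_cum: np.ndarray
    extras: dict = field(default_factory=dict)

    @property
    def generations(self) -> int:
        return len(self.D_X) - 1

    def max_bound_violation(self) -> float:
        """Largest excess of dD_X over the per-generation bound (<= 0 if the
        bound holds everywhere)."""
        return float(np.max(self.dD_X - self.cost_rate))

    def to_frame(self) -> pd.DataFrame:
        T = self.generations
        return pd.DataFrame({
            "generation": np.arange(T + 1),
            "D_X": self.D_X,
            "D_G": self.D_G,
            "dD_X": np.append(self.dD_X, np.nan),
            "dD_G": np.append(self.dD_G, np.nan),
            "cost_rate": np.append(self.cost_rate, np.nan),
            "cost_cum": np.concatenate(([0.0], self.cost_cum)),
        })


def _summarise(
    model: WFModel, psi: np.ndarray, phi: np.ndarray, k: int
) -> TrajectorySummary:
    """Build the information/cost series from propagated ensembles and check
    the accumulation bound generation by generation."""
    N = model.N
    T = psi.shape[0] - 1
    D_X = np.empty(T + 1)
    D_G = np.empty(T + 1)
    for t in range(T + 1):
        D_X[t], D_G[t] = information_levels(psi[t], phi[t], N)
    C_i = state_costs(model)
    cost_rate = k * N * (psi[:-1] @ C_i)
    cost_cum = np.cumsum(cost_rate)
    summary = TrajectorySummary(
        k=k,
        D_X=D_X, D_G=D_G,
        dD_X=np.diff(D_X), dD_G=np.diff(D_G),
        cost_rate=cost_rate, cost_cum=cost_cum,
    )
    violation = summary.max_bound_violation()
    if violation > BOUND_TOL:
        raise RuntimeError(
            f"accumulation bound violated by {violation:.3e} bits -- "
            "this indicates an implementation bug"
        )
    if D_X[-1] - D_X[0] > cost_cum[-1] + BOUND_TOL:
        raise RuntimeError("cumulative accumulation bound violated")
    return summary


def fixation_experiment(
    N: int,
    s: float,
    k: int = 1,
    fitness_rule: FitnessRule | None = None,
    max_generations: int = 1_000_000,
) -> TrajectorySummary:
    """Information accumulated by the fixation or loss of one beneficial copy.

    A single copy of allele A appears at t = 0 and evolves under drift and
    selection with no mutation until all but ``ABSORPTION_TOL`` of the
    probability mass is absorbed at counts {0, N} in both ensembles.  The
    ultimate information ``D(X_inf) = D(G_inf)`` is computed from the closed
    form in terms of the fixation probability, not from the truncated series.

    ``extras`` carries ``psi_fix`` (selected-chain fixation probability from
    the propagated mass, renormalised by the absorbed mass), ``psi_fix_exact``
    (independent linear solve) and ``D_X_inf``.
    """
    model = WFModel(N=N, mu=0.0, s=s, fitness_rule=fitness_rule)
    M_sel = transition_matrix(model, selected=True)
    M_neu = transition_matrix(model, selected=False)
    v_sel = np.zeros(N + 1)
    v_sel[1] = 1.0
    v_neu = v_sel.copy()
    psi_rows = [v_sel.copy()]
    phi_rows = [v_neu.copy()]
    for _ in range(max_generations):
        absorbed_sel = v_sel[0] + v_sel[-1]
        absorbed_neu = v_neu[0] + v_neu[-1]
        if min(absorbed_sel, absorbed_neu) > 1.0 - ABSORPTION_TOL:
            break
        v_sel = v_sel @ M_sel
        v_neu = v_neu @ M_neu
        psi_rows.append(v_sel.copy())
        phi_rows.append(v_neu.copy())
    else:
        raise RuntimeError(f"not absorbed within {max_generations} generations")
    psi = np.array(psi_rows)
    phi = np.array(phi_rows)
    summary = _summarise(model, psi, phi, k)
    psi_fix = float(v_sel[-1] / (v_sel[0] + v_sel[-1]))
    summary.extras = {
        "psi_fix": psi_fix,
        "psi_fix_exact": absorption_probability(model, start_count=1),
        "D_X_inf": fixation_information(psi_fix, N),
        "total_cost": float(summary.cost_cum[-1]),
    }
    return summary


def accumulation_experiment(
    model: WFModel, generations: int, k: int = 1
) -> TrajectorySummary:
    """Information accumulation when selection is switched on at t = 0.

    Both ensembles start from the *neutral* stationary distribution
    (D(X^0) = 0); the selected ensemble then evolves under the model's
    fitness rule while the neutral ensemble stays at its stationary state.
    Requires ``mu > 0``.  ``extras`` carries the final (D_X, D_G).
    """
    if model.mu <= 0.0:
        raise ValueError("accumulation_experiment requires mu > 0")
    phi0 = stationary_distribution(model, selected=False)
    M_sel = transition_matrix(model, selected=True)
    M_neu = transition_matrix(model, selected=False)
    psi = np.empty((generations + 1, model.N + 1))
    phi = np.empty_like(psi)
    psi[0] = phi[0] = phi0
    for t in range(generations):
        psi[t + 1] = psi[t] @ M_sel
        phi[t + 1] = phi[t] @ M_neu
    summary = _summarise(model, psi, phi, k)
    summary.extras = {"D_X_final": summary.D_X[-1], "D_G_final": summary.D_G[-1]}
    return summary


def maintenance_scan(
    N: int, mu: float, Ns_grid, k: int = 1
) -> pd.DataFrame:
    """Stationary information and cost across selection strengths.

    For each scaled selection strength Ns on the grid, computes the exact
    selected and neutral stationary distributions, the information maintained
    at the population (D_X) and genotype (D_G) levels, the mean cost of
    selection ``<C> = sum_x psi(x) C(x)``, and the maintenance efficiencies
    ``D_X/<C>`` and ``D_G/<C>`` in bits per unit cost.
    """
    rows = []
    for Ns in Ns_grid:
        s = Ns / N
        model = WFModel(N=N, mu=mu, s=s)
        psi = stationary_distribution(model, selected=True)
        phi = stationary_distribution(model, selected=False)
        D_X, D_G = information_levels(psi, phi, N)
        C_mean = float(psi @ state_costs(model))
        rows.append({
            "Ns": Ns, "s": s, "D_X": D_X, "D_G": D_G, "C_mean": C_mean,
            "eff_X": D_X / C_mean if C_mean > 0 else np.nan,
            "eff_G": D_G / C_mean if C_mean > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def kimura_fixation_probability(N: int, s: float) -> float:
    """Diffusion approximation (1 - e^{-2s}) / (1 - e^{-2Ns}) for a single
    new copy of an allele with advantage s in a haploid population."""
    if s == 0.0:
        return 1.0 / N
    return float(np.expm1(-2.0 * s) / np.expm1(-2.0 * N * s))
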