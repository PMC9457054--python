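"""Forward individual-based simulation of polygenic directional selection.

A population of N haploid individuals carries l biallelic loci.  The trait is
fully heritable and additive with equal effects -- ``z_g`` is the number of
beneficial alleles in genotype g -- and fitness is multiplicative across
loci, ``w_g = (1 + s)^{z_g}``.  One generation:

1. free recombination: each offspring draws two parents with probability
   proportional to fitness and inherits, at every locus, the allele of either
   parent with probability 1/2 (two parents sampled with selection per
   offspring, so k = 2 in the accumulation bound);
   no recombination: each offspring is a copy of a single selected parent
   (k = 1);
2. mutation: every allele flips independently with probability mu.

At mutation-selection-drift stationarity the simulator estimates, by pooling
over generations, the phenotype-level information D(Z) against the exact
neutral Binomial(l, 1/2) trait distribution, the single-locus population- and
genotype-level information against the exact neutral Wright-Fisher
references, and the mean cost of selection <C> and relative fitness variance
<V> per generation.  All estimators are plug-in (empirical histogram)
estimators with no smoothing; their positive bias shrinks as the number of
pooled generations grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import json

import numpy as np
import pandas as pd
from scipy import stats

from .diffusion_limits import RegimeParams, efficiency_weak
from .single_locus_wf import WFModel, stationary_distribution, state_costs, information_levels

__all__ = [
    "IBMConfig",
    "StationaryEstimates",
    "init_population",
    "step",
    "run_stationary",
    "efficiency_sweep",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class IBMConfig:
    """Parameters of one individual-based run.

    ``mu`` is the per-locus per-generation flip probability, ``s`` the
    per-allele selective advantage (fitness ``(1+s)^z``).  ``init``:
    ``random_half`` seeds every allele independently with probability 1/2
    (the neutral stationary genotype distribution), ``all_zero`` starts
    without any beneficial alleles.
    """

    N: int
    l: int
    mu: float
    s: float
    recombination: str = "free"      # "free" | "none"
    burn_in: int = 5_000
    sample_generations: int = 200_000
    seed: int = 0
    init: str = "random_half"        # "random_half" | "all_zero"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N={self.N!r} must be >= 2")
        if self.l < 1:
            raise ValueError(f"l={self.l!r} must be >= 1")
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError(f"mu={self.mu!r} outside [0, 1/2]")
        if self.s <= -1.0:
            raise ValueError(f"s={self.s!r} must exceed -1")
        if self.recombination not in ("free", "none"):
            raise ValueError(f"unknown recombination mode {self.recombination!r}")
        if self.init not in ("random_half", "all_zero"):
            raise ValueError(f"unknown init {self.init!r}")

    @property
    def k(self) -> int:
        """Parents sampled with selection per offspring (2 sexual, 1 asexual)."""
        return 2 if self.recombination == "free" else 1


@dataclass
class StationaryEstimates:
    """Pooled stationary estimates from one individual-based run.

    Divergences are plug-in KL estimates in bits against exact neutral
    references; ``C_mean`` (bits/generation) and ``V_mean`` are averages of
    the per-generation cost of selection and relative fitness variance.
    ``bound_rate_k1``/``bound_rate_k2`` give the per-generation accumulation
    bound ``k N <C>`` under both parent-sampling conventions, since the
    asexual mode admits k = 1 while the sexual mode requires k = 2.
    """

    config: IBMConfig
    D_Z: float
    D_X_single: float
    D_G_single: float
    C_mean: float
    V_mean: float
    efficiency: float
    p_mean: float
    phenotype_hist: np.ndarray = field(repr=False)
    allele_count_hist: np.ndarray = field(repr=False)
    bound_rate_k1: float = 0.0
    bound_rate_k2: float = 0.0
    blocks: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, include_histograms: bool = False) -> str:
        out = {
            "config": asdict(self.config),
            "D_Z": self.D_Z,
            "D_X_single": self.D_X_single,
            "D_G_single": self.D_G_single,
            "C_mean": self.C_mean,
            "V_mean": self.V_mean,
            "efficiency": self.efficiency,
            "p_mean": self.p_mean,
            "bound_rate_k1": self.bound_rate_k1,
            "bound_rate_k2": self.bound_rate_k2,
        }
        if include_histograms:
            out["phenotype_hist"] = self.phenotype_hist.tolist()
            out["allele_count_hist"] = self.allele_count_hist.tolist()
        if self.blocks is not None:
            out["blocks"] = self.blocks.to_dict(orient="list")
        return json.dumps(out)


def init_population(config: IBMConfig, rng: np.random.Generator) -> np.ndarray:
    """N x l boolean genotype matrix (True = beneficial allele)."""
    if config.init == "random_half":
        return rng.random((config.N, config.l)) < 0.5
    return np.zeros((config.N, config.l), dtype=bool)


def _selection_probs(z: np.ndarray, s: float) -> np.ndarray:
    """Parent-sampling probabilities proportional to (1+s)^z, computed in
    log space so large trait values cannot overflow."""
    logw = z * np.log1p(s)
    w = np.exp(logw - logw.max())
    return w / w.sum()


def step(
    genotypes: np.ndarray, config: IBMConfig, rng: np.random.Generator
) -> np.ndarray:
    """Advance the population one generation; returns the offspring matrix."""
    N, l = genotypes.shape
    p = _selection_probs(genotypes.sum(axis=1), config.s)
    if config.recombination == "free":
        parents = rng.choice(N, size=2 * N, p=p)
        a = genotypes[parents[:N]]
        b = genotypes[parents[N:]]
        offspring = np.where(rng.random((N, l)) < 0.5, a, b)
    else:
        parents = rng.choice(N, size=N, p=p)
        offspring = genotypes[parents].copy()
    if config.mu > 0.0:
        offspring ^= rng.random((N, l)) < config.mu
    return offspring


def _plugin_kl(counts: np.ndarray, log2_ref: np.ndarray) -> float:
    """Plug-in KL (bits) of an empirical histogram against an exact reference
    given as log2 probabilities (finite on the whole support)."""
    total = counts.sum()
    pos = counts > 0
    f = counts[pos] / total
    return float(np.sum(f * (np.log2(f) - log2_ref[pos])))


def _two_point_kl(p: float) -> float:
    """KL of (p, 1-p) against the symmetric (1/2, 1/2), in bits."""
    out = 0.0
    if p > 0:
        out += p * np.log2(2.0 * p)
    if p < 1:
        out += (1.0 - p) * np.log2(2.0 * (1.0 - p))
    return out


def run_stationary(config: IBMConfig, n_blocks: int = 0) -> StationaryEstimates:
    """Simulate to stationarity and estimate information and cost.

    After ``burn_in`` generations, pools over ``sample_generations``:

    * trait values of all individuals -> phenotype histogram on {0..l};
      D(Z) against the exact neutral Binomial(l, 1/2) pmf;
    * per-locus beneficial-allele counts over all loci -> count histogram on
      {0..N}; D(X_single) against the exact neutral single-locus
      Wright-Fisher stationary distribution at (N, mu, s=0);
    * pooled mean allele frequency p -> D(G_single) = KL((p,1-p) || (1/2,1/2));
    * per-generation C and V from the realised trait-class frequencies with
      fitness (1+s)^z (valid because fitness depends on the genotype only
      through z), averaged over generations.

    ``n_blocks > 0`` additionally splits the sampling phase into that many
    contiguous blocks and reports per-block estimates (for block-bootstrap
    confidence intervals).
    """
    rng = np.random.default_rng(config.seed)
    genotypes = init_population(config, rng)
    for _ in range(config.burn_in):
        genotypes = step(genotypes, config, rng)

    N, l = config.N, config.l
    z_support = np.arange(l + 1)
    pheno_hist = np.zeros(l + 1, dtype=np.int64)
    count_hist = np.zeros(N + 1, dtype=np.int64)
    C_sum = 0.0
    V_sum = 0.0
    log1ps = np.log1p(config.s)

    n_blocks = int(n_blocks)
    block_edges = (
        np.linspace(0, config.sample_generations, n_blocks + 1).astype(int)
        if n_blocks > 0 else None
    )
    block_rows: list[dict] = []
    blk_pheno = np.zeros(l + 1, dtype=np.int64)
    blk_C = 0.0
    blk = 0

    for t in range(config.sample_generations):
        z = genotypes.sum(axis=1)
        zc = np.bincount(z, minlength=l + 1)
        pheno_hist += zc
        count_hist += np.bincount(genotypes.sum(axis=0), minlength=N + 1)
        # cost of selection from trait classes: w_hat = (1+s)^z / w_bar
        logw = z * log1ps
        w = np.exp(logw - logw.max())
        w_hat = w / w.mean()
        C_sum += np.mean(w_hat * np.log2(w_hat))
        V_sum += np.mean((w_hat - 1.0) ** 2)
        if block_edges is not None:
            blk_pheno += zc
            blk_C += np.mean(w_hat * np.log2(w_hat))
            if t + 1 == block_edges[blk + 1]:
                block_rows.append({"pheno": blk_pheno.copy(), "C_sum": blk_C,
                                   "n_gen": int(block_edges[blk + 1] - block_edges[blk])})
                blk_pheno[:] = 0
                blk_C = 0.0
                blk += 1
        genotypes = step(genotypes, config, rng)

    # exact neutral references
    log2_binom = stats.binom.logpmf(z_support, l, 0.5) / _LN2
    neutral_wf = stationary_distribution(
        WFModel(N=N, mu=config.mu, s=0.0), selected=False
    )
    D_Z = _plugin_kl(pheno_hist, log2_binom)
    D_X_single = _plugin_kl(count_hist, np.log2(neutral_wf))
    total_alleles = count_hist.sum()
    p_mean = float(np.dot(count_hist, np.arange(N + 1))) / (N * total_alleles)
    D_G_single = _two_point_kl(p_mean)
    C_mean = C_sum / config.sample_generations
    V_mean = V_sum / config.sample_generations

    blocks = None
    if block_rows:
        blocks = pd.DataFrame({
            "D_Z": [_plugin_kl(r["pheno"], log2_binom) for r in block_rows],
            "C_mean": [r["C_sum"] / r["n_gen"] for r in block_rows],
        })
        blocks["efficiency"] = blocks["D_Z"] / blocks["C_mean"]

    return StationaryEstimates(
        config=config,
        D_Z=D_Z,
        D_X_single=D_X_single,
        D_G_single=D_G_single,
        C_mean=C_mean,
        V_mean=V_mean,
        efficiency=D_Z / C_mean if C_mean > 0 else np.nan,
        p_mean=p_mean,
        phenotype_hist=pheno_hist,
        allele_count_hist=count_hist,
        bound_rate_k1=1 * N * C_mean,
        bound_rate_k2=2 * N * C_mean,
        blocks=blocks,
    )


def efficiency_sweep(
    template: IBMConfig, Ns_grid, modes=("free", "none")
) -> pd.DataFrame:
    """Maintained D(Z) against cost <C> across selection strengths and
    recombination modes.

    One row per (Ns, mode) with the simulated ``C_mean`` and ``D_Z``, the
    independent-loci prediction (l times the exact single-locus stationary
    D(G) and <C> at the same N, mu, s), and the weak-selection linear
    prediction ``efficiency_weak * C_mean``.
    """
    rows = []
    for Ns in Ns_grid:
        s = Ns / template.N
        for i, mode in enumerate(modes):
            config = replace(template, s=s, recombination=mode,
                             seed=template.seed + 1000 * i + hash(float(Ns)) % 997)
            est = run_stationary(config)
            model = WFModel(N=template.N, mu=template.mu, s=s)
            psi = stationary_distribution(model, selected=True)
            phi = stationary_distribution(model, selected=False)
            _, D_G_single = information_levels(psi, phi, template.N)
            C_single = float(psi @ state_costs(model))
            eff_weak = efficiency_weak(RegimeParams(N=template.N, mu=template.mu))
            rows.append({
                "Ns": Ns, "s": s, "mode": mode,
                "C_mean": est.C_mean, "D_Z": est.D_Z,
                "D_Z_independent": template.l * D_G_single,
                "C_independent": template.l * C_single,
                "D_Z_linear_weak": eff_weak * est.C_mean,
            })
    return pd.DataFrame(rows)
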