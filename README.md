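# evoinfo

Tools for quantifying the information that natural selection accumulates and
maintains in evolving populations, and what that information costs in fitness
variation.

Evolution is stochastic: drift and mutation alone would leave population
composition, genotypes and phenotypes broadly random. Selection narrows that
randomness. `evoinfo` measures the narrowing in bits as the Kullback–Leibler
divergence between the distribution of a variable under selection (ψ) and its
matched neutral distribution (φ),

```
D(U) = Σ_u ψ(u) log2( ψ(u) / φ(u) ),
```

applied at three nested levels — population states X (genotype frequencies),
genotypes G, and phenotypes Z — which obey D(X) ≥ D(G) ≥ D(Z). The rate at
which D(X) can grow is bounded by the cost of selection,

```
ΔD(X^t) ≤ k N ⟨C⟩_t ,    C(x) = Σ_g x_g ŵ_g(x) log2 ŵ_g(x),
```

where N is the population size, k the number of parents sampled with
selection per offspring (1 asexual, 2 sexual), and C(x) — the KL divergence
between selection-weighted and neutral parental sampling — is itself bounded
by the relative fitness variance V(x)/ln2 and the genetic load via
log2(1/(1−L)). At mutation–selection–drift stationarity, maintenance is most
efficient under weak selection: up to N/(μ(1+4Nμ)) bits per unit cost,
falling toward ln(2)/μ when selection is strong.

The package is aimed at population geneticists and theorists who want to
compute these quantities exactly for single-locus Wright–Fisher systems,
estimate them by forward simulation for polygenic systems, and check the
accumulation bounds and efficiency limits on concrete models.

## What's inside

| module | contents |
| --- | --- |
| `evoinfo.info_measures` | probability containers, KL/joint/conditional divergence, chain rule, fixation information |
| `evoinfo.single_locus_wf` | exact haploid two-allele Wright–Fisher: transition matrices, propagation, stationary solves, fixation & accumulation experiments, maintenance scans |
| `evoinfo.selection_cost` | C(x), V(x), L(x), their inequalities, truncation-selection cost |
| `evoinfo.diffusion_limits` | weak/strong-selection efficiency limits, accumulation capacity |
| `evoinfo.multilocus_ibm` | individual-based simulator of N haploids × l loci with free or zero recombination; stationary estimators of D(Z), D(X_single), D(G_single), ⟨C⟩, ⟨V⟩ |
| `evoinfo.phenotype_info` | phenotype-level D(Z) for Gaussian trait maps; hierarchy reports |
| `evoinfo.cli_io` | `evoinfo` CLI, config parsing, seeded experiment recipes |

## Worked example

Information maintained by weak polygenic selection — 40 haploids, 1000
unlinked loci of equal effect, per-locus mutation rate μ = 5×10⁻⁴ (Nμ = 0.02)
and per-allele advantage s = 0.01 (Ns = 0.4), fitness (1+s)^z on the additive
trait z:

```python
from evoinfo import IBMConfig, run_stationary

config = IBMConfig(N=40, l=1000, mu=5e-4, s=0.01, recombination="free",
                   burn_in=5_000, sample_generations=200_000, seed=1)
est = run_stationary(config)
print(f"D(Z)        = {est.D_Z:.1f} bits")
print(f"D(X_single) = {est.D_X_single:.4f} bits")
print(f"D(G_single) = {est.D_G_single:.4f} bits")
print(f"<C>         = {est.C_mean:.5f} bits/generation")
print(f"D(Z)/<C>    = {est.efficiency:.3g} bits per unit cost")
```

Output (a few minutes on one core):

```
D(Z)        = 87.6 bits
D(X_single) = 0.0945 bits
D(G_single) = 0.0876 bits
<C>         = 0.00123 bits/generation
D(Z)/<C>    = 7.12e+04 bits per unit cost
```

Read: each locus is only weakly perturbed from neutrality (≈0.09 bits), but a
thousand loci together shift the trait distribution ≈88 bits away from the
neutral Binomial(1000, ½) — roughly l·D(G_single), since unlinked equal-effect
loci contribute additively. The cost is about 0.0012 bits per generation, so
some 7×10⁴ bits are maintained per unit cost, close to the single-locus
weak-selection limit N/(μ(1+4Nμ)) ≈ 7.4×10⁴:

```python
from evoinfo import RegimeParams, efficiency_weak
efficiency_weak(RegimeParams(N=40, mu=5e-4))   # 74074.07...
```

The same experiment from the shell:

```bash
evoinfo ibm --n 40 --l 1000 --nmu 0.02 --ns 0.4 --seed 1 --out out/
evoinfo recipe fig6 --seed 1 --out out/   # same run plus block CIs
```

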