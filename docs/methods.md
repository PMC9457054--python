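# Methods

This note documents the models, estimators and numerical choices behind
`evoinfo`, in the order a user meets them.

## Information measures

All information quantities are Kullback–Leibler divergences in bits between a
distribution under selection, ψ, and a matched neutral distribution, φ, over
the same finite state space. Three conventions are fixed package-wide:

* logarithms are base 2; where closed forms are naturally stated in nats, a
  single ln 2 constant converts;
* `0·log(0/q) = 0` — states selection never produces cost nothing;
* `p·log(p/0)` with p > 0 raises `AbsoluteContinuityError` rather than
  returning +∞. An absolute-continuity violation means the neutral process
  cannot reach a state the selected process occupies, which in every model
  here indicates a construction bug; failing loudly (with the offending state
  named) is more useful than propagating infinities.

Probability vectors whose entries sum to within 1e-9 of 1 are renormalised on
construction; larger deviations raise. The window tolerates float
accumulation over long matrix-product chains while still catching logic
errors.

Conditional divergence D(V|U) averages the per-state conditional KL over the
*selected* marginal of the conditioning variable; conditioning states with
zero selected mass are skipped. Together with the joint divergence this
satisfies the chain rule D(U,V) = D(U) + D(V|U) = D(V) + D(U|V), which the
test suite verifies on random joints to 1e-10.

The closed form for the information generated by the fixation or loss of a
single new allele,

```
D_inf(p, N) = p log2(N p) + (1-p) log2( N (1-p) / (N-1) ),
```

is exactly the two-point KL of the fate distribution (p, 1−p) against the
neutral (1/N, 1−1/N); the tests tie the two routes together for random
(p, N).

## Single-locus Wright–Fisher model

The exact engine is a haploid two-allele Wright–Fisher chain on allele counts
i ∈ {0..N}. The per-generation event order is: selection reweighting of the
parental pool, then symmetric mutation, then binomial resampling:

```
p_sel = x w_A / (x w_A + (1-x) w_a),   x = i/N
p''   = p_sel (1 - μ) + (1 - p_sel) μ
i'    ~ Binomial(N, p'')
```

This is the standard construction of Wright–Fisher with selection; other
orders (mutation before selection) differ at O(μs) and are
indistinguishable at the parameter ranges used here. Fitness may be an
arbitrary positive callable of the allele frequency (frequency-dependent
selection); the default is the constant rule (w_a, w_A) = (1, 1+s). No
optimisation over frequency-dependent rules is performed — the hook only
evaluates a user-supplied rule.

**Stationary distributions.** The default solver is a direct null-space
solve of v(M − I) = 0 with the normalisation constraint replacing one
redundant equation. For the ≤ 101-state chains used throughout, this is
exact to machine precision and fast, and in particular it is reliable for
stiff matrices (large Ns), where power iteration converges slowly because
the relevant relaxation time scales like 1/μ. A power-iteration solver
(L1 tolerance 1e-13) is kept as an alternative method and the tests require
the two to agree to 1e-10.

**Experiments.** Two canonical experiments produce per-generation series of
D(X^t), D(G^t), their increments, the bound rate kN⟨C⟩_t (with ⟨C⟩_t averaged
over the selected ensemble ψ^X_t) and its running sum:

* *Fixation*: a single copy of the beneficial allele at t = 0, μ = 0,
  propagated until all but 1e-10 of the mass in both ensembles is absorbed at
  {0, N}. The ultimate information D(X_∞) = D(G_∞) is then computed from the
  closed form above using the fixation probability — exact and independent of
  where the series is truncated. The propagated fixation probability is
  cross-checked against the absorption linear solve (I−Q)h = r to 1e-8.
* *Accumulation*: both ensembles start at the neutral stationary
  distribution and selection is switched on; requires μ > 0.

Both experiments assert the per-generation bound ΔD(X^t) ≤ kN⟨C⟩_t and its
cumulative form as they run (slack 1e-9 bits) and raise if violated: the
bound is a theorem for this model class, so a violation can only be an
implementation bug. k = 1 is the default for all single-locus experiments
(asexual sampling) and remains an explicit parameter.

## Cost of selection

For a population state x with already-evaluated fitnesses w_g,

```
C(x) = Σ_g x_g ŵ_g log2 ŵ_g,   V(x) = Σ_g x_g (ŵ_g − 1)²,
L(x) = 1 − 1/ŵ_max(x),         ŵ_g = w_g / Σ_h x_h w_h,
```

with ŵ_max over genotypes actually present (x_g > 0). Zero fitness is
allowed (excluded-from-reproduction classes); such classes drop out of C via
the 0·log 0 convention. Frequency dependence is the caller's problem by
design: the functions consume w_g(x) already evaluated at x, which keeps the
definitions pure and testable. C is invariant under rescaling all fitnesses
by a positive constant, equals the KL divergence between selection-weighted
and neutral parental sampling (tested via the generic KL machinery), and
satisfies C ≤ V/ln2, C ≤ log2(1/(1−L)), V ≤ L/(1−L), with C → V/(2 ln 2)
under weak selection.

Truncation selection is modelled as two fitness classes — the top fraction
α = 1 − 1/N reproduces with equal fitness, the remaining individual not at
all — giving the exact purge cost −log2(1 − 1/N), within O(1/N²) of the
1/(N ln 2) approximation.

## Diffusion-limit formulas

The weak-selection maintenance efficiency N/(μ(1+4Nμ)), its limits N/μ
(Nμ → 0) and 1/(4μ²) (Nμ ≫ 1), the strong-selection efficiency ln(2)/μ, and
the weak-regime stationary approximations D(G) ≈ N²s²/(2 ln 2),
⟨C⟩ ≈ Nμs²/(2 ln 2) are implemented as literal formulas. Calls outside their
regimes of validity warn rather than raise — the asymptotics are themselves
the object of study, and comparing them against the exact scan outside their
regime is legitimate use.

A caution established by the exact machinery: the strong-selection asymptote
ln(2)/μ presumes the cost of purging a deleterious mutant equals the
truncation cost ≈ 1/(N ln 2), which holds only when relative fitness
differences are large in absolute terms (s ≳ O(10)). With constant selection
at N = 100, μ = 10⁻⁴ the exact stationary efficiency is still ≈ 11× above
ln(2)/μ at Ns = 20 and approaches the asymptote only around Ns ~ 10³. The
weak-selection formula, by contrast, is accurate to ~1% already at Ns = 0.1.

## Multilocus individual-based model

N haploid individuals × l biallelic loci (boolean matrix), additive
equal-effect trait z = number of beneficial alleles, multiplicative fitness
(1+s)^z evaluated in log space so large l cannot overflow. Per generation:

* free recombination — each offspring draws two parents (with replacement,
  independently; a pair may coincide) with probability ∝ fitness, and
  inherits each locus from either parent with probability ½. Two parents are
  sampled with selection per offspring, so k = 2 in the accumulation bound.
* no recombination — one selected parent, copied. k = 1.
* mutation — every allele flips independently with probability μ.

Initialisation `random_half` (each allele Bernoulli(½)) starts the population
at the neutral stationary genotype distribution, so burn-in only needs to
reach the *selected* stationary state; `all_zero` is available for
adaptation-from-scratch runs.

**Estimators.** After burn-in, the run pools over generations:

* trait values of all individuals → histogram on {0..l}; D(Z) is the plug-in
  KL against the exact neutral Binomial(l, ½) pmf (by allele-exchange
  symmetry the neutral trait distribution is exactly binomial). The
  reference pmf is evaluated via `binom.logpmf`, which is finite on the full
  support, so no empirical bin can meet a zero reference.
* per-locus allele counts over all loci → histogram on {0..N}, treating loci
  as exchangeable replicates; D(X_single) is the plug-in KL against the
  exact neutral single-locus Wright–Fisher stationary distribution at
  (N, μ, s=0), which has full support for μ > 0.
* the pooled mean allele frequency p → D(G_single) = KL((p,1−p) ‖ (½,½)).
* C and V are computed each generation from the realised trait-class
  frequencies with fitness (1+s)^z — valid because fitness depends on the
  genotype only through z, reducing the computation from 2^l genotype
  classes to at most N trait classes — and averaged over generations.

The plug-in estimators use no smoothing; their positive bias decays as more
generations are pooled (tested at three sampling efforts) and is negligible
at the reference sampling effort of 2×10⁵ generations. Pooled samples are
autocorrelated with decorrelation time ~ 1/(2μ) generations, which matters
for significance tests (the neutral Kolmogorov–Smirnov check uses an
effective sample size of N·(sampled generations)·2μ) but not for the point
estimates.

Because the no-recombination mode arguably admits either parent-sampling
convention in the accumulation bound, stationary outputs report the bound
rate kN⟨C⟩ under both k = 1 and k = 2 rather than choosing silently.

## Phenotype-level information

D(Z) for a Gaussian trait map ζ(z|g) = Normal(μ_g, σ) is the KL divergence
between the selected and neutral genotype-weighted mixtures, computed by
adaptive quadrature on [min μ_g − 8σ, max μ_g + 8σ] to an absolute tolerance
of 1e-8 bits; the ±8σ truncation discards < 1e-14 of either mixture's mass.
Binning is unnecessary for the mixtures used here; the multilocus module's
histogram route covers discrete phenotypes. Failure to reach the tolerance
raises with the achieved error. D(Z) is invariant under shifting all means
and under jointly rescaling (means, σ).

## Reference study conditions and problem sizes

The canonical experiment recipes are: single-copy adaptation at N = 40,
μ = 0.005, s = 0.05 with trait means (−1, +1), σ = 1; fixation and
accumulation at N = 100 (Ns ∈ {1,2,3}, k = 1; accumulation at Nμ = 0.01 for
2×10⁴ generations); the stationary maintenance scan at N = 100, μ = 10⁻⁴;
and the polygenic run at N = 40, l = 1000, Nμ = 0.02, Ns = 0.4 with free
recombination, 5×10³ burn-in and 2×10⁵ sampled generations. The stationary
scan recipe for two mutation regimes uses Nμ = 0.1 and 5 as representative
weak and strong mutation strengths.

The test suite exercises the same machinery at reduced problem sizes chosen
so the full suite runs in well under a minute of simulation per test: the
polygenic check uses 2×10⁴ sampled generations (estimates at this effort sit
within a few percent of the full-length run, so the test tolerance is widened
to ±20%), and stochastic invariants (chi-square against exact transition
rows, KS against the neutral binomial, bias decay) run at fixed seeds with
sample sizes stated in each test.

## Known limitations

* All genetics is haploid; no diploid load theory, dominance or multiple
  alleles per locus.
* The multilocus model has only the two recombination extremes (free/none);
  no linkage maps, unequal effects or epistasis.
* The simulator emulates idealised unlinked equal-effect architectures with
  symmetric mutation; real genomes have linkage blocks, effect-size spectra
  and mutational biases, so passing tests demonstrate correctness of the
  model, not quantitative transfer to real data.
* Fitness-flux bounds and free-fitness decompositions are out of scope, as is
  any optimisation of frequency-dependent selection rules.
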