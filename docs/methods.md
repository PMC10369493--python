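# Methods

This note records what `finitek` computes, how each estimator is defined, and
why the main design choices were made.

## 1. Definitions

Consider N identical particles in a closed volume V at temperature T, able to
associate into clusters ("m-mers") of any size. A frame of data is the vector
of cluster counts (n₁, …, n_N) with Σ m·n_m = N. Concentrations are c_m =
n_m / V, and c⌀ is the standard concentration (default 1 M =
0.602214076 molecules/nm³).

**Elementary association** of an a-mer and a b-mer, a + b → s (s = a + b):

```
K = ⟨c_s⟩ c⌀ / M[a, b]
```

where M[a, b] is the correlated reactant moment. For distinct sizes it is
⟨c_a c_b⟩; repeated sizes contribute falling-factorial self-correlation
corrections, e.g. M[a, a] = ⟨c_a (c_a − 1/V)⟩ and in general, for k reactants
of one size, ⟨c(c − 1/V)(c − 2/V)⋯(c − (k−1)/V)⟩. In count space this is the
falling factorial ⟨n^(k)⟩ = ⟨n(n−1)⋯(n−k+1)⟩ / V^k: the number of ordered ways
to pick k *distinct* reactant clusters from a frame. This is the whole
finite-system correction — a reacting pair cannot contain the same cluster
twice, and in a system of a few particles that distinction is numerically
dominant.

Defined this way K is a state function. The package exposes the consequences
as testable identities:

- **Path independence.** Any mechanism — gradual monomer addition
  `K[1+1]*K[1+2]*…`, dimer-of-dimers `K[1+1]*K[1+1]*K[2+2]`, mixed orders,
  or the concerted `K[1+1+…+1]` — yields the same K_m.
  `enumerate_mechanisms` generates every distinct mechanism so the property
  can be checked exhaustively.
- **Probability-ratio form.** When N = m, K_m can also be computed from the
  fraction of frames that are fully clustered versus fully monomeric:
  K_m = (f_clu / f_mono) (c⌀ V)^(m−1) / m!. This is algebraically identical
  to the concerted form frame-by-frame and serves as an independent check.
- **Uncorrelated comparison.** K′_m = ⟨c_m⟩ c⌀^(m−1) / ⟨c₁⟩^m is the bulk
  expression evaluated on small-system means. It is *not* a constant: it
  depends on V and N. For N = 2 its bias has the closed form
  K′₂/K₂ = (1 + b₂/V)/2, which the tests verify.
- **Transfer reactions** such as A + A₃ ⇌ 2A₂ have association and
  dissociation on both sides, so c⌀ cancels. Three forms are provided: the
  direct correlated ratio (`Ktrans`), the equivalent ratio of two binding
  constants K_{1+1}/K_{1+(b−1)} (`KtransRatio`), and the uncorrelated form
  (`KtransPrime`). Direct and ratio forms are identical on exact moments;
  the uncorrelated transfer bias is strictly smaller than the uncorrelated
  association bias on the same model, because correlation errors partially
  cancel between the two sides.
- **Fluctuation identities.** With the relative fluctuation
  l(ζ, η) = ⟨ζη⟩/(⟨ζ⟩⟨η⟩) − 1, the mean product count obeys
  ⟨N_{i+j}⟩ = K ⟨N_i (N_j − δ_ij)⟩ / (c⌀ V), and the two partitions of a
  tetramer satisfy an exact l-equality linking (1,3) and (2,2) correlations.

Free energies are ΔG = −RT ln K with R = 0.0083144626 kJ/(mol·K); cycle
closures are signed sums of ΔG around a closed reaction loop and vanish in
exact equilibrium.

## 2. The exact oracle

`ClusterModel` implements an ideal-cluster ensemble: clusters are internally
equilibrated, non-interacting objects, and a composition with n_m m-mers has
weight

```
W = N! / Π_m [(m!)^{n_m} n_m!] · Π_m (V b_m)^{n_m}
```

over all integer partitions of N (enumerated with sympy). b_m is the
per-cluster internal configuration integral (b₁ ≡ 1); it is the only physics
input. All moments are exact finite sums, and K_m has the closed form
c⌀^(m−1) b_m / m!, independent of V and N.

This oracle is the package's certification instrument: every estimator is
tested against it to relative 1e-10, which pins down the combinatorial
factors (the m! symmetry numbers, the falling factorials, the (c⌀V)^(m−1)
prefactors) far more sharply than any stochastic test could. Its limitation
is equally important to state: it contains no inter-cluster interactions and
no cluster geometry, so it validates *estimators*, not the physics of any
particular fluid.

## 3. The Monte Carlo sampler

Instead of molecular dynamics, cluster statistics are generated by Metropolis
Monte Carlo of Lennard-Jones particles (default σ = 0.2 nm, truncated
unshifted at r_cut = 2 nm) in a periodic cubic box, T = 300 K. Two particles
are bonded when their minimum-image distance is below r_bond = 0.35 nm;
clusters are connected components of the bond graph (union-find, compiled
with numba along with the energy and move kernels).

Only equilibrium populations enter the estimators, so any Markov chain with
the correct stationary distribution is as good as dynamics, and the move set
is chosen purely for mixing:

- **Local displacements**, step tuned toward ~40 % acceptance during
  equilibration only (tuning during production would break detailed balance).
- **Reinsertion jumps** (probability 0.2): a particle is redrawn uniformly in
  the box. Symmetric, so standard Metropolis acceptance.
- **Aggregation-volume-biased swaps** (probability 0.5): a particle is moved
  between the bonding shell of a random partner and the bulk, with the
  generation-probability ratio V_in/V_out entering the acceptance rule.
  These are essential at deep wells: with displacements alone, breaking an
  ε = 16 kJ/mol bond costs e^(−2βε) per attempt and composition
  autocorrelation times reach thousands of sweeps; with swaps the
  composition decorrelates in tens of sweeps, an order-of-magnitude error
  reduction at fixed cost.

The first 10 % of sweeps are discarded as equilibration. Determinism: one
seed fixes the whole chain.

**Independent validation.** For N = 2 the binding constant has a quadrature
oracle: K = c⌀ V I_b / (2 I_u) with I_b = ∫₀^{r_bond} e^{−βu(r)} 4πr² dr and
I_u the corresponding unbound integral, evaluated with adaptive quadrature to
1e-11. The MC estimate must agree within 3 stderr; at ε = 0 the bonded-pair
frequency must match the geometric ratio (4/3)πr_bond³ / V.

## 4. Error estimation

All stochastic estimates carry block-averaging standard errors: the series is
cut into n contiguous blocks (default 20), the full statistic is re-evaluated
on each block, and the stderr is the block standard deviation over √n. Whole-
statistic re-evaluation (rather than error propagation through the ratio)
keeps the estimate honest for strongly correlated numerators and
denominators. Blocks in which a statistic is undefined (a species never
observed) are dropped; estimates that are undefined on the full series are
returned as NaN with `defined=False`, never raised, so scans over harsh
conditions degrade gracefully.

Sampling lengths in the tests are set by error budgets, not by the answers:
e.g. the cycle-closure criterion (≤ 0.2 kJ/mol) is run at 4 × 10⁷ sweeps,
where the observed seed-to-seed closure spread is ≈ 0.05 kJ/mol, a 4×
margin.

## 5. Experiment designs

`run_scan` supports two designs and their exact-ensemble analogues:

- **R1 (volume scan):** fixed N, grid of box lengths — how each expression
  behaves as concentration changes. Correlated K is flat; K′ is not.
- **R2 (size scan):** grid of N at fixed concentration, box length derived
  as (N/c)^{1/3} — invariance of K with system size. At 0.01954 nm⁻³
  (0.03245 M) this gives L = 4.678 nm for N = 2 up to 8.500 nm for N = 12.

One caveat: with periodic minimum-image conventions, box lengths below
2·r_cut let a pair interact with its own image. The sampler permits
L ≥ 2 r_cut exactly (L = 4 nm with the default cutoff) because small-system
conditions demand small boxes; shrink r_cut if you need smaller L.
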