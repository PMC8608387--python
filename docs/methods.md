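# Methods

## The problem

Single-cell snapshot measurements mix two sources of copy-number
variability: the stochastic kinetics of expression inside each cell
(*intrinsic* noise) and cell-to-cell differences in kinetic parameters
(*extrinsic* noise).  `txnoise` implements (i) the distribution theory
showing the two are not separable from a single species' copy-number
distribution, and (ii) estimators that separate them using two species
measured jointly per cell.

## Copy-number laws

The Telegraph model — promoter switching at on-rate λ and off-rate μ,
transcription at rate K while active, degradation at rate δ — has the
stationary law (all rates in units of δ):

    p(n) = K^n (λ)_n / (n! (λ+μ)_n) · 1F1(λ+n; λ+μ+n; −K)

with `(x)_n` the rising factorial.  Limits: μ=0 gives Poisson(K)
(constitutive); μ→∞ at fixed burst size β=K/μ gives NegBin(λ, β/(β+1)).
Negative binomials are parameterised throughout by `(r, β)` with β the mean
burst size (mean rβ).

**Numerical evaluation.** 1F1(λ+n; λ+μ+n; −K) alternates in sign, so we use
Kummer's transformation to `exp(−K)·1F1(μ; λ+μ+n; K)`, whose series terms
are all positive, and accumulate term logs with a log-sum-exp.  The series
needs ≈ K + 12√K terms; evaluation is stable to K ≈ 10³ and n well past ten
times the mean.  The pmf is vectorised over n by sharing one log-gamma
evaluation on the integer grid λ+μ+{0,1,…}.  Pmf tables are truncated at
mean + 10 sd, extended until the tail mass is below 1e-8.

## Compound distributions and non-identifiability

Extrinsic noise is modelled by compounding: q(n) = ∫ p(n; θ) f(θ) dθ with a
hyper-distribution f on one kinetic parameter (families: point, scaled beta,
gamma, scaled beta-prime, normal truncated at 0).  Five integral identities
make non-identifiability exact — each fixed-parameter law below is *equal*
to a mixture of a less bursty law:

| target | base | mixing law |
|---|---|---|
| Tele(λ, μ′, K′) | Tele(λ, μ, K), μ<μ′ | K ~ K′·Beta(λ+μ, μ′−μ) |
| Tele(λ, μ′, K′) | Pois(K) | K ~ K′·Beta(λ, μ′) |
| NegBin(λ, β) | Tele(λ, μ, K) | K ~ Gamma(λ+μ, β) |
| NegBin(λ, β) | Pois(K) | K ~ Gamma(λ, β) |
| NegBin(λ′, b) | NegBin(λ, θ), λ>λ′ | b/θ − 1 ~ BetaPrime(λ−λ′, λ′) |

The last row deserves a note: the mixing variable is most naturally stated
on the burst *rate* 1/θ ∈ (1/b, ∞); equivalently θ ~ b·Beta(λ′, λ−λ′) on
(0, b), which is the form implemented (it follows from the Laplace-transform
identity ∫_{1/b}^∞ (s−1/b)^{c−1} e^{−ks} ds = Γ(c) k^{−c} e^{−k/b} applied
to the gamma mixture underlying both negative binomials).  The
`scaled-beta-prime` noise family encodes exactly this law.

**Quadrature.** Mixtures are integrated by Gauss–Legendre with node
doubling (48 → 768 nodes) until two refinements agree within the requested
absolute tolerance (default 1e-8) uniformly over the whole support —
bounded families on their exact support, unbounded families to the
1 − 1e-10 quantile.  All ten certification cases (five rows, two parameter
sets each) reproduce their targets to better than 1e-11 in the uniform
norm; the certification itself runs in under a second.

A sampling demonstration (`apparent_burstiness_demo`) shows the effect is
not tied to the special mixing laws: generic unimodal noise (truncated
normal) on the transcription rate produces samples close in total-variation
distance to a burstier fixed-parameter law.  No pass threshold is attached;
the distance is reported.

## Simulators

Five reaction networks are simulated with the exact SSA (numba-compiled
direct method): M1 (nascent → mature maturation, constitutive), M2
(mRNA → protein two-stage), M3 (M2 + two-state promoter), M4 (M3 + nascent
maturation), MS3 (multiscale three-state promoter S0 → S10 → S11 with
transcription only from the polymerase-paused state S11, which resets to
S10 on firing; shut-off μ acts from both S10 and S11).

* **Units.** δM = 1 sets the clock; every other rate is relative to the
  mature-mRNA lifetime.
* **Initial state and relaxation.** Cells start empty and inactive and are
  observed at t_end = max(15, 10/δP) when the network makes protein, else
  15.  The protein autocorrelation time 1/δP dominates convergence; ten
  protein lifetimes leave a relative stationarity bias below ~5e-5.  (For
  0.1 < δP < 2/3 this is more conservative than a flat 15; the extension
  removes a ~1% protein-mean bias at δP = 0.3.)
* **Maturation delays.** Fixed or Erlang maturation is exact: each nascent
  synthesis schedules a completion time (Erlang drawn as a gamma variate —
  equivalent to chaining exponential stages), kept in an event queue
  interleaved with SSA steps; the first-order maturation channel is removed.
* **Static extrinsic noise.** Populations draw one parameter vector per
  cell (independent draws per parameter) and keep it fixed — the compound
  model's ensemble-heterogeneity assumption.  Correlated parameter draws
  are out of scope.
* **Dual reporters.** Two SSA runs share the cell's parameter draw:
  conditionally independent, identically distributed copies by
  construction.
* **Cell cycle (MS3).** Time to replication and replication to division are
  each Erlang(12, rate) (total cycle Erlang(24, rate); rate defaults to the
  cell's activation rate λ1).  Replication instantaneously doubles the gene
  copy (the new copy inherits the promoter state) and multiplies λ1 by the
  dosage-compensation factor 0.7; at division every molecule survives
  independently with probability 1/2 and one daughter is followed (copy 1's
  promoter state is kept).  Snapshots are taken at a uniform time in a
  post-burn-in cycle, emulating an unsynchronised population.  In dual
  mode the two copies share the cycle schedule and snapshot time — both
  reporters live in the same cell — while reaction noise and partitioning
  stay independent.
* **Seeding.** One root seed spawns a `numpy` `SeedSequence` tree: one
  child for parameter draws, one 32-bit stream seed per SSA run.  Identical
  seeds give bit-identical populations, including delay and cell-cycle
  variants.

## Estimators

Total noise is η² = Var(X)/E(X)² (unbiased variance).  Conditioning on the
cell's parameter vector Z splits it as η² = E(Var(X|Z))/E(X)² +
Var(E(X|Z))/E(X)² — intrinsic plus extrinsic.

* **Dual reporter:** η²_ext = Cov(X₁, X₂)/(E X₁ E X₂) for two conditionally
  independent identical copies.  The total is the average of the two
  copies' η² (symmetric choice), so total = int + ext holds exactly as
  computed.
* **Pathway reporter:** the same normalised covariance applied to two
  *different* species of one gene's pathway.  When the conditional means
  factor across shared parameters and the conditional covariance is
  negligible, it identifies the extrinsic noise on the shared
  transcriptional factor (K_N for constitutive maturation; K_N·λ/(λ+μ) for
  the bursty gene).  The total noise reported with the decomposition is the
  upstream species' η² — the method decomposes noise at the transcriptional
  level — and the intrinsic part is left unclipped (it can be negative when
  the estimator overshoots).
* **Overshoot:** for downstream pairs of a bursty gene the conditional
  covariance is not zero; its normalised value at fixed parameters —
  computable by simulation (`intrinsic_overshoot`) — is the estimator's
  positive bias and can be subtracted.  For the two-stage model it has the
  closed form δp/((1+δp)Km); the general factor α = E(1/(δp+1)) / E(1/δp)
  is implemented as that *ratio*: re-deriving the normalised intrinsic term
  under independent noise yields the ratio, and only the ratio satisfies
  α ≪ 1 for δp ≪ 1.

## Benchmark studies (stated worlds)

* **Constitutive maturation (M1).**  KM ~ Gamma(8, 1.25) (mean 10,
  cv² = 0.125); transcription-noise ladder on KN: point 50, 133.3·Beta(6,
  10.5) (cv² 0.1), Gamma(5, 10) (cv² 0.2), 300·Beta(1.5, 7.5) (cv² 0.5);
  mean nascent ≈ 5, mean mature ≈ 50.
* **Two-stage (M2).**  Kp ~ Gamma(5, 0.4) (mean 2, cv² 0.2),
  δp ~ Gamma(8, 0.0125) (mean 0.1, cv² 0.125), same Km ladder; mRNA ≈ 50,
  protein ≈ 1000.  (A gamma scale of 0.125 for δp would put the protein
  mean at 100, contradicting the stated means; 0.0125 is the consistent
  choice.)
* **Bursty (M4).**  Six mean-parameter rows (λ, μ, KN, KP, δP) with KM = 10
  fixed — pathway and dual reporters only measure the same quantity when
  the maturation rate carries no noise — and scaled Beta(5, 6) noise
  (cv² 0.1) on λ, μ, KP, δP, scaled Beta(3, 6) (cv² 0.2) on KN, each scaled
  to the row's mean.  Means: nascent 5, mature 50, protein 1000.
* **Overshoot maps.**  M4 at fixed parameters, KM = 20, KN and KP chosen
  for nascent mean 5 and protein mean 1000 (these two pins imply a mature
  mean of 100 = 5·KM/δM); λ ∈ [0.5, 5], δP ∈ [0.01, 0.5], off-rate
  μ ∈ {2, 10, 20}.  The shipped profile is a reduced 8×8 grid at 1000
  samples per pixel; full-fidelity maps (3000+ samples) take hours per μ.
* **Replicate profile.**  The published protocol is 100 replicates × 500
  cells; the default here is 20 × 500 (runtime), with `replicates=100`
  restoring full fidelity.  With 20 replicates the replicate-mean standard
  error is √5 ≈ 2.2× larger.
* **Structural variants.**  Case 1: constitutive maturation with a fixed
  (or Erlang) delay of 0.1.  Cases 2–4: the multiscale promoter at λ1 = 4,
  μ1 = 2, λ2 = 50, KN = 300 — an *active* regime chosen because the pathway
  method's premise (negligible conditional correlation) targets active
  genes; case 3 adds a fixed maturation delay, case 4 the full cell cycle
  with Erlang(3, 30) maturation and cycle rate 1 (cycle length 24 mRNA
  lifetimes, slow enough that protein tracks the phase quasi-statically).
  Extrinsic noise: scaled Beta(5, 6) on λ1.  The dual-reporter value is the
  in-run reference.

## What a green test establishes — and what it does not

The synthetic populations realise exactly the modelling assumptions the
estimators are built on: static per-cell parameters, independent noise
sources, a single gene copy (outside the cell-cycle model), perfect
single-molecule counting.  Green tests therefore establish correctness of
the distribution theory, the simulators and the estimator algebra — not
robustness to features real data have and these worlds do not: measurement
noise and capture efficiency (the estimators are provably scale-invariant,
which covers *uniform* efficiency only), correlated parameter fluctuations,
dynamic extrinsic noise faster than the cell cycle, or multiple
distinguishable gene copies.

## Numerical choices and tie-breaks

* Variances/covariances use the unbiased (n−1) divisor so the dual-reporter
  identity is exact in finite samples.
* Quadrature node doubling stops at 768 nodes; near-degenerate mixing laws
  (e.g. Beta shape → 0) should be expressed as `point` specs instead.
* Zero total propensity with an empty delay queue is absorbing: the
  simulator returns the current state at t_end.
* Truncated-normal noise uses the exact truncated distribution
  (inverse-CDF sampling), not resampling.
* The maturation event queue holds up to 16384 pending molecules; overflow
  raises rather than silently dropping events.
* Statistical test tolerances are 3 standard errors (or 3 published
  replicate sds for table reproductions, with printed "0.00" sds read as
  the printing precision 0.005).

## Known limitations

* The leaky Telegraph variant (basal transcription in the off state) is not
  implemented; all laws assume the off state is silent.
* No parameter inference from data — the identifiability results are the
  reason — and no extraction of the full extrinsic-noise distribution from
  compound-Poisson data.
* The cell-cycle machinery is wired to the multiscale (MS3) network only.
* Pure-Python pmf evaluation beyond K ≈ 10³ becomes slow (series length
  grows linearly in K).
* The three-stage model M3 is simulated and tested structurally but no
  benchmark table targets it.
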