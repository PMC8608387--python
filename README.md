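# txnoise

Tools for separating the two sources of cell-to-cell variability in gene
expression — *intrinsic* noise from stochastic reaction kinetics and
*extrinsic* noise from cell-to-cell parameter differences — from single-cell
snapshot data, for computational biologists studying transcriptional noise.

The package has three layers:

1. **Distribution theory.**  The Telegraph model's stationary copy-number
   law

   p(n) = Kⁿ (λ)ₙ / (n! (λ+μ)ₙ) · ₁F₁(λ+n; λ+μ+n; −K)

   (promoter on-rate λ, off-rate μ, transcription rate K, rates in units of
   the mRNA decay rate), its Poisson and negative-binomial limits, and
   compound (mixture) distributions over hyper-distributions of the kinetic
   parameters.  Five exact integral identities are certified numerically:
   every Telegraph or negative-binomial law is *identical* to a mixture of
   a less bursty law — so the sources of variability cannot be identified
   from one species' copy-number distribution, and extrinsic noise always
   inflates apparent burstiness.

2. **Exact stochastic simulators** (numba-accelerated SSA) for five
   networks — constitutive maturation (M1), the two-stage mRNA–protein
   model (M2), its promoter-switching extension (M3), the four-stage bursty
   model with maturation (M4), and a multiscale three-state promoter (MS3)
   — with optional fixed/Erlang maturation delays and cell-cycle features
   (gene replication, 70% dosage compensation, binomial partitioning at
   division, Erlang(24) cycle lengths).

3. **Noise-decomposition estimators.**  The dual-reporter split
   η²_ext = Cov(X₁, X₂)/(E X₁ · E X₂) for two identically regulated reporter
   copies, and the *pathway-reporter* alternative: the same normalised
   covariance computed from two different species of one gene's pathway
   (nascent mRNA, mature mRNA, protein), which identifies the extrinsic
   noise at the transcriptional level without engineered dual reporters.
   A simulation diagnostic quantifies the estimator's bias ("overshoot")
   for bursty genes.

## Worked example

Estimate the extrinsic noise of a constitutively expressed gene whose
transcription rate varies across cells as Gamma(5, 10) (squared CV 0.2) and
whose maturation rate varies as Gamma(8, 1.25) (squared CV 0.125):

```python
import numpy as np
from txnoise import (ModelSpec, GeneParams, NoiseSpec, simulate_population,
                     pathway_reporter_estimate, dual_reporter_decompose)

pop = simulate_population(
    ModelSpec("M1"), GeneParams.of(KN=50, KM=10, deltaM=1),
    noise={"KN": NoiseSpec.gamma(5, 10), "KM": NoiseSpec.gamma(8, 1.25)},
    n_cells=500, dual_reporter=True, seed=1)

pr = pathway_reporter_estimate(pop.counts("nascent"), pop.counts("mature"),
                               ("nascent", "mature"))
dr = dual_reporter_decompose(pop.counts("mature"), pop.counts("mature", 2))
print(f"pathway : eta2_ext = {pr.eta2_ext:.3f}")
print(f"dual    : eta2_ext = {dr.eta2_ext:.3f}")
```

prints

```
pathway : eta2_ext = 0.192
dual    : eta2_ext = 0.195
```

Both estimators recover the imposed transcription-rate noise of 0.2 (up to
sampling error at 500 cells): the nascent–mature covariance of a *single*
gene replaces the dual-reporter construct.  The theory says the pathway
estimate targets exactly the noise on K_N here, because the conditional
means of both species factor into K_N times independent parameters.

The same study at the benchmark scale, from the shell:

```
txnoise table2 --seed 1 --out table2.csv           # 4-row noise ladder
txnoise verify-representations --out report.csv    # certify the 5 identities
txnoise decompose --input counts.csv --columns nascent,mature
```

Each command writes its result table plus a JSON manifest (command, config,
seed, package version) so runs can be replayed.

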