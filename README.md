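# paleoclock

Bayesian relaxed-clock analysis of protein evolution around ancient gene
duplications.

Several of the oldest events in molecular evolution — the duplication of
the ATP-synthase catalytic subunit into Alpha and Beta, the duplications
behind the photosystem II core antenna (CP43/CP47) and reaction centre
(D1/D2) — predate the crown group of Cyanobacteria that inherited both
copies.  Because the sequence distance between two paralogs is fixed by the
data, the span of time ΔT assumed between the duplication and the crown
ancestor dictates how fast the protein must have evolved near the
duplication.  `paleoclock` implements that analysis end to end for
synthetic, fully controlled datasets:

* **ΔT rate extraction** — a relaxed molecular clock (autocorrelated
  lognormal rates; empirical amino-acid matrices with discrete-gamma site
  rates; hard or soft node calibrations) sampled by Metropolis-within-Gibbs
  MCMC on a fixed rooted topology, from which ν_max (the rate at the point
  of duplication) and ν_min (the mean rate through the Proterozoic,
  branches with midpoint younger than 2.5 Ga) are extracted with standard
  errors, plus power-law and exponential-decay fits of rate against time.
* **Corrected distances** — p-distances with pairwise gap deletion,
  Poisson and gamma-Poisson corrections, matrix maximum-likelihood
  distances (JTT/WAG/LG + Γ), and within-group means with a column
  bootstrap.
* **Marginal ancestral sequence reconstruction** — per-site posterior
  residue distributions at any internal node, with ML or Fitch-parsimony
  indel placement and reconstruction-agreement statistics.
* **A synthetic-data generator** — species chronograms mirrored into
  duplication-anchored paralog trees, branch rates from an autocorrelated
  lognormal walk or a decaying exponential envelope, and forward-simulated
  alignments, each dataset carrying its exactly known ν_max/ν_min truth.

The model in brief: node ages t on a fixed rooted topology (leaves at 0,
Ga before present), node log-rates following Brownian motion with variance
σ² per Ga, branch rate r_b = exp((log r_parent + log r_child)/2), branch
length r_b·Δt in expected substitutions/site, likelihood by Felsenstein
pruning under an empirical rate matrix with K = 4 gamma categories, soft
calibrations holding 95% of their mass in a uniform core with exponential
tails (2.5% per side two-sided, 5% one-sided), and a conditional-uniform
(or birth–death) prior on the remaining node ages.

## Worked example

Simulate a duplication-anchored dataset with a known rate ratio, run the
clock under its calibration scaffold, and compare:

```python
from paleoclock import run_recovery_replicate

out = run_recovery_replicate(target_ratio=5.0, seed=42, n_iterations=350)
print(f"true nu_max/nu_min : {out['true_ratio']:.2f}")
print(f"estimated          : {out['estimated_ratio']:.2f}")
print(f"nu_max {out['nu_max']:.2f}  nu_min {out['nu_min']:.3f}")
```

```
true nu_max/nu_min : 5.00
estimated          : 3.81
nu_max 1.01  nu_min 0.265
```

The simulated truth places the duplication at 2.9 Ga, the paralog crowns at
2.3 Ga, and a decaying rate profile whose realised ν_max/ν_min is exactly
5; the MCMC (two chains, short schedule) recovers the ratio within the
factor-1.5 band the recovery benchmark checks.  The reporting convention
truncates ratios toward zero, so a published pair like (ν_max, ν_min) =
(7.32, 0.28) δ Ga⁻¹ is reported as 26:

```python
from paleoclock import rate_ratio, compute_delta_t
rate_ratio(7.32, 0.28)   # -> (26.142857142857142, 26)
compute_delta_t(3.5, 1.7)  # -> 1.8 (Ga)
```

A configuration-driven pipeline covers the same stages from the shell:

```bash
paleoclock run config.yaml     # stages: simulate, distances, clock, scenarios, asr
paleoclock validate config.yaml
```

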