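# Methods

`paleoclock` implements a desk-scale version of a comparative
molecular-evolution analysis built around ancient gene duplications: how
fast must a protein have evolved between a pre-divergence duplication event
and the crown group that inherited both copies, and how does that rate
compare with the rate observed through the rest of the protein's history?
This note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## The ΔT framework

A gene duplication older than a clade's crown ancestor leaves both paralogs
in every descendant.  Rooting the paralog tree at the duplication and
calibrating both the duplication age and the crown age turns the paralog
alignment into a rate meter: the phylogenetic distance between the copies
is fixed by the data, so the assumed span ΔT = age(duplication) −
age(crown MRCA) dictates the rate of evolution near the duplication.  We
quantify:

* **ν_max** — the rate at the point of duplication, operationalised as the
  mean posterior rate of the two branches incident to the duplication node
  (an option selects the single fastest incident branch instead; the mean
  is the default because both copies contribute symmetrically to the
  distance across the duplication).
* **ν_min** — the average rate through the Proterozoic, operationalised as
  the unweighted mean posterior rate over branches whose posterior-mean
  midpoint age is younger than 2.5 Ga (the Archean/Proterozoic boundary;
  the cutoff is a parameter).
* their ratio, reported both as a float and as the integer truncation
  toward zero — the only convention that reproduces all published integer
  ratios from their published rate pairs (26 from 26.14, 21 from 21.5,
  40 from 40.88).

ΔT arithmetic is literal subtraction.  One published scenario prints a ΔT
of 1.1 Ga for a 3.5 Ga duplication and a 2.6 Ga crown; 3.5 − 2.6 = 0.9, and
`compute_delta_t` returns 0.9.  The discrepancy is documented here rather
than reconciled, as the printed value cannot be recovered from its stated
inputs.

## Relaxed clock model

The clock operates on a fixed rooted topology with:

* **Node ages** in Ga before present, leaves at 0, parent strictly older
  than child.  The age prior is "conditional uniform": a proper calibration
  density on the root, and the other internal ages i.i.d. uniform below the
  root age.  This makes the root calibration exactly the prior marginal of
  the root age, which the prior-predictive test exploits.  A birth–death
  alternative (Rannala–Yang kernel with speciation λ, extinction μ and
  sampling fraction ρ, conditioned on the root age) is available; the
  critical case λ = μ is not supported.
* **Branch rates** from an autocorrelated lognormal process: each node
  carries a log-rate, log r_child ~ Normal(log r_parent, σ²·Δt), and the
  rate of a branch is exp of the mean of its endpoint log-rates.  The same
  endpoint-average convention is used by the simulator, so simulation and
  inference are exactly conjugate.  No drift correction is applied to the
  Brownian walk (geometric-median parameterisation).  An uncorrelated
  alternative draws i.i.d. Gamma(shape, scale) branch rates.
* **Substitution model**: empirical exchangeabilities (POISSON, JTT, WAG,
  LG; transcribed constants of the published matrices) with model or
  observed equilibrium frequencies and K = 4 discrete-gamma rate categories
  (equal-probability categories at their conditional means).  Site-profile
  mixture models are out of scope; fixed empirical matrices keep the
  likelihood analytic and testable while exercising the same ΔT machinery.
* **Calibrations**: hard bounds are indicators.  Soft bounds keep 95% of
  the mass in a uniform core and place exactly 2.5% beyond each bound
  (two-sided) or 5% beyond the single bound (one-sided) in exponential
  tails whose density is continuous at the bound.  The tail family is a
  design choice — only the tail masses are prescribed — and the one-sided
  core width (`span`, default 1 Ga) is a parameter.  Tail masses are
  verified by quadrature to 1e-6.

### Hyperpriors (defaults)

| parameter | prior | default rationale |
|---|---|---|
| root log-rate | Normal(log 1.0, 1.5²) | weakly informative around 1 δ Ga⁻¹, the scale of moderately conserved proteins |
| σ² (log-rate diffusion) | Exponential(mean 1 Ga⁻¹) | permits strong rate decay while shrinking gently toward clock-like behaviour |
| gamma shape α | LogNormal(0, 1) | centred on α = 1, the value used for the distance work |
| branch rates (uncorrelated) | Gamma(2, 0.5) | mean 1 δ Ga⁻¹, fixed (not sampled) |

## MCMC

Metropolis-within-Gibbs with a fixed scan order per sweep: a reflected
uniform slide on each internal node age (window a fraction of the
parent–child gap; a fixed window with lower reflection for the root), a
Gaussian walk on each node log-rate, multiplier moves on σ² and α, and a
whole-tree age-scale move with the appropriate Jacobian.  Defaults are
4 chains × 20 000 sweeps, 25% burn-in, thinning 10; every benchmark in the
test-suite states its own (much shorter) schedule.  All randomness derives
from one integer seed through `numpy.random.SeedSequence` spawning, so
identical settings give bit-identical chains.

The pruning likelihood is evaluated incrementally: identical site patterns
are collapsed with weights; transition matrices come from one spectral
decomposition of the reversible rate matrix; each single-parameter proposal
recomputes only the changed branches and the partial-likelihood arrays on
the path to the root, into double-buffered storage, so a rejection costs no
copying.  Buffers are float64; per-site scaling is omitted, which bounds
the usable tree size to roughly 60 tips at amino-acid state space — ample
here, and far before underflow the likelihood of saturated branches loses
signal anyway.  An engine-level stress test checks that arbitrary
accept/reject sequences leave the cache bit-consistent with a fresh
computation.

Convergence is advisory: split-R̂ and bulk ESS (via ArviZ) are reported for
headline scalars, with a warning at R̂ > 1.1; small scripted runs are never
blocked.  Posterior SEs of branch rates divide the posterior standard
deviation by √ESS.

## Synthetic data

The generator produces the structures the analysis assumes:

* **Chronograms** by random pairwise merging, with either rescaled
  coalescent waiting times (merges concentrated near the tips) or i.i.d.
  uniform internal ages.  The uniform mode matches the clock's age prior
  and is used for parameter-recovery and coverage benchmarks, which
  therefore test the well-specified case; the coalescent mode produces the
  tip-heavy shapes typical of real species samples.
* **Duplication datasets**: two mirrored copies of a species chronogram
  joined at a duplication root, leaf names suffixed `_A`/`_B`, with a truth
  record (ΔT, ν_max, ν_min) recomputable from the stored tree.
* **Rates** either from the autocorrelated process above or from a
  deterministic exponential envelope r(t) = plateau + (r0 − plateau)
  e^(−λ(t_root − t)), with branch rates the exact time-average of r(t)
  over the branch.  The envelope amplitude can be solved (bisection) so the
  realised ν_max/ν_min hits a requested value exactly.
* **Alignments** by forward simulation under the chosen matrix + Γ4, no
  indels.  Indel-handling operations are tested on hand-built gapped
  fixtures instead.

What passing recovery tests show: the full pipeline (simulate → clock →
profile → ratio) recovers a known rate ratio under matched model
assumptions and a strong calibration scaffold.  What they do not show:
robustness to alignment error, model misspecification (e.g. site-profile
heterogeneity), indel processes, or calibration misplacement — none of
which the generator emulates.

## Benchmark problem sizes

The recovery benchmark uses 16 species × 2 paralogs (32 sequences), 500
columns, crown age 2.3 Ga, duplication at 2.9 Ga (ΔT = 0.6 Ga), decay rate
8 Ga⁻¹, plateau 0.25 δ Ga⁻¹.  Calibrations: hard ±0.05 Ga anchors on the
duplication root and both crowns (these ages are the scenario's
assumptions, not estimates) and soft ±0.08 Ga intervals on the two largest
internal clades of each paralog copy — the cross-calibration layout a
duplication-anchored design affords.  Geometry rationale: the decay must
be essentially complete at the crown (λ·ΔT ≈ 5) or the "Proterozoic"
window itself contains fast branches and the target ratio becomes
unmeasurable by construction; and ΔT must be short enough that the
duplication-incident branches stay near or below ~2.5 expected
substitutions/site even at a 20-fold ratio — beyond that the amino-acid
likelihood is flat in branch length and no method can measure ν_max from
500 columns — yet long enough that the log-rate jump at the crown is not
crushed by the autocorrelated prior's small per-Ga variance.  A ~25–30%
downward bias in ν_max remains at these settings: the Brownian rate prior
smooths the sharp rate drop across the crown, trading duplication-branch
length into the crown-adjacent branches (the total cross-paralog path
length is checked to match its pairwise ML estimate).  This is the known
smoothing behaviour of autocorrelated clocks under abrupt rate shifts and
is well inside the factor-1.5 band the benchmark checks.  Chains for
benchmark batteries are 2 × 450–550 sweeps (30% burn-in, thinning 2) with
distance-informed initial rates and a wide σ² prior (Exponential, mean
5 Ga⁻¹) — sized for factor-level accuracy of posterior means, not
publication-grade ESS.  The ΔT scenario sweep uses 8 species × 2 paralogs
and a crown-age grid {2.3, 2.0, 1.7, 1.4} Ga below a 2.7 Ga duplication.

## Distances

Observed p-distances use pairwise deletion (columns gapped in either
sequence are dropped for that pair), the behaviour of the standard distance
software the analysis mirrors.  Corrections: Poisson d = −ln(1 − p);
gamma-rates Poisson d = α[(1 − p)^(−1/α) − 1]; and a 1-D
maximum-likelihood distance under a full empirical matrix (+Γ), maximised
by bounded scalar search on [0, 20] substitutions/site, which reduces to
the analytic inversion of the 20-state equal-rates chain under the POISSON
matrix.  Within-group means bootstrap alignment columns (500 replicates by
default, one seed per result); the SE is the standard deviation of the
group mean over replicates.  `dedup_by_identity` compares equal-length
(pre-aligned) sequences, counting gap-versus-residue columns as mismatches
(global-identity behaviour); unequal-length ungapped inputs are only
checked for exact equality — no alignment is attempted.

## Ancestral reconstruction

Only marginal reconstruction is implemented: the published per-site support
values are marginal posteriors, and the joint path adds machinery without
adding testable quantities.  For a target node the inside (pruning) partial
is combined with an outside pass per gamma category; posteriors are
renormalised per site.  MAP ties break alphabetically for determinism.
Indels are reconstructed as a separate binary presence/absence character:
Fitch parsimony (target ties resolve to "present") or maximum likelihood
under a symmetric 2-state chain using the tree's branch lengths times a
scale factor (default 1 — no indel rate is prescribed, so the substitution
branch lengths serve as the time axis), with a present-posterior cutoff of
0.7.  Multi-method consensus is emulated by reconstructing under several
substitution matrices and comparing MAP sequences on mutually unmasked
sites.

## Column filtering and baselines

Block-selection tools are replaced by a per-column gap-occupancy filter
(default: keep columns with ≤ 50% gaps); the analysis only needs
clade-specific indels stripped, not a specific block algorithm, and the
filter is idempotent and coordinate-transparent (0-based internally,
1-based in reports).  Random-sequence identity baselines draw i.i.d.
residues (10 × 350 and 10 × 750 by default in the worked examples), whose
expected pairwise identity is Σfᵢ² — 5% under uniform frequencies.

## Known limitations

* No per-site likelihood scaling (tree size bound above); no codon or
  nucleotide models; no topology inference or model selection.
* The uncorrelated-gamma clock fixes its rate-prior hyperparameters rather
  than sampling them.
* The birth–death age prior requires λ ≠ μ.
* Saturated pairs (p ≥ 1 after bootstrap resampling) raise rather than
  return infinity; group tables should be computed within clades, as the
  defaults do.
* Convergence diagnostics are advisory; very short runs report unreliable
  ESS-based standard errors.
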