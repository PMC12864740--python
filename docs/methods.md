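# Methods

## Population model

The simulator is a Wright–Fisher model extended to "multiploid" cells: a
constant population of `N` bacteria with discrete, non-overlapping
generations, where each cell's genotype is the pair `(x_m, x_wt)` of
mutated and wild-type plasmid copies. Every generation applies, to every
cell: (1) mutation, (2) replication, (3) partitioning into two daughters,
(4) uniform selection of half of the `2N` daughters.

Assumptions, and what they imply:

- **Neutrality.** Mutant and wild-type cells and plasmids have identical
  fitness; selection is uniform. Consequences of burden or benefit are out
  of scope.
- **One-way mutation.** Wild-type copies convert to mutant with
  per-copy, per-generation probability `μ`; there is no reversion. The
  "Poisson process" of rare editing events is implemented as a
  `Binomial(x_wt, μ)` draw, which is bounded by the available copies and
  indistinguishable from Poisson at `μ ≪ 1`. An editing window of `w`
  nucleotides with a per-nucleotide rate can be expressed through the
  `site_multiplier` knob (default 1, i.e. `μ` is per plasmid).
- **Replication.** Each cell synthesises `P' ~ Poisson(P)` new copies per
  generation, an abstraction of RepA-initiated, negatively autoregulated
  copy-number control; each new copy is mutant with probability equal to
  the mutated proportion `x_m/(x_m+x_wt)` in the cell. (The proportion is
  the only reading that is a valid probability and matches the stated
  intent of proportional assignment.)
- **No segregational loss.** The pooled `P + P'` copies are divided
  exhaustively: daughter A receives `floor(T/2)` or `ceil(T/2)` copies (a
  fair coin decides the extra copy when `T` is odd) and its mutated count
  is hypergeometric in the pool composition. A cell that ever reaches zero
  total copies (possible only at `T = 1`) is retained as a permanently
  plasmid-free, non-mutant cell.
- **Lineage bookkeeping.** `first_mutation_gen` marks when a lineage first
  acquired a mutant copy and is inherited by both daughters, even by one
  that receives zero mutant copies; summaries still count only cells with
  `x_m ≥ 1` as mutant.

A useful exact property used throughout the tests: replication,
partitioning and selection are all unbiased in the mutant-copy proportion,
so the expected population-wide mutant-plasmid frequency after `g`
generations is `1 − (1 − μ)^g` independently of PCN. Mutant-*cell*
fractions, by contrast, depend on PCN both through the mutational supply
(`P` targets per cell) and through segregational dilution of mutant copies
across daughter lineages.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `μ` | 2.5e-6 | per-plasmid mutation probability per generation |
| `N` | 1e5 | constant population size (cells) |
| `G` | 15 | generations (22 h at a 90 min doubling time) |
| PCN list | 3, 5, 9, 17, 25, 39, 79 | average copy numbers of the pSC101 variants studied |
| replicates | 50 | independent seeded runs |

Replicate `r` draws from a stream seeded by `(seed, r)`; identically
seeded runs are byte-identical.

## Circuit models

All expression levels are steady states in arbitrary units; degradation
and dilution rates are absorbed into the synthesis-rate units, so only
ratios and trends are meaningful. The functional forms are dosage-weighted
Hill-repression steady states built to encode four qualitative facts:
IFFL control keeps *total* output constant across PCN (per-copy rate
`α_tot/P`); a mutated repressor protein is fully non-functional; intact
repressor copies compensate coding-sequence mutations; and a mutated
promoter/operator expresses its copy unrepressed, unmaskable by intact
copies. Defaults `a = α_tot = β = K = 1`, `n = 2` put the wild-type
repressor level at the half-saturation point scale, where compensation and
masking are both visible; the parameters are exposed and any positive
values may be used.

- constitutive target: `F = a·x_m`
- IFFL gain: `F = α_tot·x_m/P`
- IFFL loss: `L = α_tot(P−x_m)/P`, `F = β/(1+(L/K)^n)`
- constitutive repressor, coding target: `L = a(P−x_m)`,
  `F = P·β/(1+(L/K)^n)`; promoter target: `L = aP`,
  `F = x_m·β + (P−x_m)·β/(1+(L/K)^n)`
- autoregulated repressor: the same two forms with `L` replaced by the
  fixed point of `L = (P−x_m)·a/(1+(L/K)^n)` (coding) or
  `L = x_m·a + (P−x_m)·a/(1+(L/K)^n)` (promoter).

The fixed point is unique because `L − rhs(L)` is strictly increasing; it
is bracketed on `[0, rhs(0)]` and solved by Brent's method to ~1e-12
relative tolerance, which matches the `n = 1` quadratic closed form to
better than 1e-10. Gene-expression noise is not modelled: the only
stochasticity is the genotype distribution produced by the simulator.
Leaky transcription is set to zero.

## Phenotype detection

Simulated cells carry fluctuating total copy numbers (`x_m + x_wt` varies
around the average `P`), so expression is evaluated at each cell's *own*
total, and detection gates each cell against the wild-type level **at that
same total**: the detected signal is the mutation-attributable expression
shift, with strict-inequality comparison. Gating against a fixed
nominal-`P` baseline instead lets pure dosage noise cross the gate in the
repressor circuits and swamp the mutant signal; gating against the
same-dosage baseline corresponds to a cytometry gate set on the wild-type
distribution, which already contains copy-number noise.

Thresholds are specified in relative units — fractions of `α_tot` for the
gain circuit, of `β` for repressor-based circuits — so sweeps are
comparable across copy numbers. Two threshold regimes matter:

- **Gain circuits.** At threshold 0 any mutated copy is detected and the
  detected ratio equals the genotypic mutant fraction, increasing with
  PCN. At a gate of half the single-copy expression of the lowest-PCN
  strain (`0.5·α_tot/3`), detection requires `x_m > P/6` copies, and the
  detected ratio rises then falls across the PCN range.
- **Loss circuits.** The dynamic range of the reporter is `β/2` between
  fully repressed and fully derepressed. Detection of a recessive loss
  phenotype requires a mutated-*majority* cell (with `n = 2` and a gate at
  `0.3β`, derepression needs `x_m/T > 0.5`). The threshold grid used for
  the loss-circuit trend checks, {0.30, 0.35, 0.40, 0.45}·β, spans that
  regime. Below it (gates within a few per cent of baseline) a single
  mutated copy is detectable, the detected ratio tracks the genotypic
  fraction, and the trend with PCN inverts — the same mechanism that makes
  the gain circuit's low gate monotone increasing.
- **Repressor circuits (coding vs promoter).** A single gate at `0.3β` is
  used for the dominance comparison: at `P = 3` one coding-mutant copy at
  nominal dosage shifts expression by `0.30β` (constitutive) or `0.286β`
  (autoregulated) — at or below the gate — while one promoter-mutant copy
  shifts it by at least `0.34β` at every copy number in both
  architectures. The gate therefore encodes "coding maskable, promoter
  unmaskable" without being saturated.

Optional log-normal measurement noise (`noise_sigma`) is off by default.

## Fluctuation analysis

The classical model: mutational events per culture `~ Poisson(m)`, each
event founds a clone whose final size has `P(size ≥ s) = 1/s` (relative
mutant fitness 1, no phenotypic delay, no plating losses; the final
population size `N_t` is a user input). The pmf follows the Panjer
(Ma–Sandri–Sarkar) recursion `p_0 = e^{−m}`,
`p_k = (m/k) Σ_{j<k} p_j/(k−j+1)`, whose low orders match direct
enumeration of event/clone combinations and whose whole shape matches the
Monte-Carlo sampler (total-variation distance < 0.01 at `m = 1` with 1e5
cultures, tail classes lumped).

Estimators of `m`:

- **p0 method**: `m = −ln(z/R)` from the zero-count fraction;
  Clopper–Pearson binomial CI propagated through `−ln`. Requires at least
  one zero culture.
- **MSS MLE**: maximises `Σ log p_{k_i}(m)` by bounded scalar
  optimisation; 95% CI from a profile log-likelihood drop of 1.92
  (χ², 1 df). Counts at or above a censoring ceiling (default 1000) enter
  the likelihood through the exact tail probability, keeping the recursion
  depth bounded for jackpot cultures without biasing the estimate. The
  all-zero boundary returns `m = 0` with a one-sided interval. Profile CIs
  were chosen over bootstrap for determinism.

The phenotypic rate is `m/N_t` per cell per growth cycle. When the input
is simulator output, each replicate run is treated as one parallel culture
and its detected-mutant count feeds the estimator; note the simulator's
constant-`N` demography is not literal exponential growth, so these rates
are comparative statistics across conditions rather than literal per-
division probabilities.

## Problem sizes used in the test suite

Trend and oracle checks run at reduced scale — `N = 1e4`, `μ` inflated to
1e-4 (trends) or 1e-3 (neutral-frequency oracle), 20 replicates,
PCN {3, 9, 25, 79} or the full seven-value list — which gives the same
qualitative behaviour as the experimental regime with enough mutants per
run for stable means. The rarity check runs at the full experimental
parameters. Estimator calibration uses 200 simulated datasets of 50
cultures at `m ∈ {0.5, 2, 5}`.

## What the synthetic conditions do not capture

- No fitness effects of mutations or plasmid burden, no two-level
  (intracellular vs. population) selection, no horizontal transfer.
- Replication is a Poisson abstraction; real iteron/RepA kinetics regulate
  copy number more tightly than Poisson.
- Expression is deterministic given genotype; real cytometry distributions
  overlap because of intrinsic/extrinsic noise, autofluorescence and
  gating artefacts. Passing the threshold-trend tests shows the
  genotype-driven component of those trends, not instrument-level
  quantitation.
- The Luria–Delbrück estimators assume pure exponential growth; applying
  them to constant-`N` simulator output yields comparative, not absolute,
  rates.
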