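# Methods

## Model

Let *G* be the genome, *R = {r_1, …, r_N}* the reads (length *L*
assumed fixed; variable lengths are handled by per-read decomposition),
and *R^k* the set of distinct observed kmers with counts *Y_l*. Each
kmer *x_l* has an unobserved genomic occurrence count α_l; the quantity
estimated is *T_l*, the expected number of attempts to read *x_l*
(error-free plus misread), which equals α_l times the coverage constant
*c = N(L−k+1)/(|G|−k+1)* in expectation.

Counts are modeled as Multinomial(N(L−k+1), **p**) where the cell
probability of *x_l* mixes over its misread neighborhood 𝒩_l — the
observed kmers within Hamming distance `d_max` — with weights
*p_e(x_m → x_l)* from the substitution model. The log likelihood
(up to an additive constant when written in *T* rather than in cell
probabilities)

  l(T | Y) = Σ_l Y_l log( Σ_{m∈𝒩_l} T_m · w(m→l) )

is maximized by EM: the E-step splits each observed count *Y_l* across
its candidate sources in proportion to *T_m · w(m→l)*, and the M-step
sums each source's responsibilities. Initialization is *T = Y*; total
mass Σ T = Σ Y is conserved exactly by every M-step, and the likelihood
trace is non-decreasing. Iteration stops when the relative likelihood
change falls below `tol` (default 1e−6) or after `max_iter` (default
100) iterations. All arithmetic is plain double precision in linear
space — neighborhood sums are short and well scaled — and a zero
denominator under a positive count raises a degeneracy error instead of
being smoothed over. A *T_m* that reaches exactly 0 stays 0 (the updates
make 0 absorbing); detection treats *T = 0* as the strongest evidence of
an erroneous kmer. The EM is fully deterministic for a fixed kmer sort
order.

### Substitution models

* **Uniform**: constant per-base rate *p_e* ∈ [0, 0.75), each wrong base
  equally likely; misread probabilities are symmetric.
* **Positional**: per-kmer-position stochastic tables *q_i(α, β)*,
  multiplied along the kmer; not symmetric. Trained from alignment
  pairs by the ML ratio estimator (a base at read position *j*
  contributes to up to *k* kmer windows, hence up to *k* kmer
  positions); zero-denominator rows default to identity, and a
  pseudocount flag exists for degenerate inputs. The kmer-position
  model is a deliberate approximation of the read-position error
  process; even a model trained on the exact reads being analyzed does
  not match their errors perfectly, which is what the wrong-model
  robustness experiment quantifies.

Insertions and deletions are out of scope throughout: on the
Illumina-style substrates this package targets they are rare relative
to substitutions.

### Neighborhoods

The full 4^k × 4^k misread matrix is restricted to *observed* kmers
within `d_max` and renormalized so that each **source** kmer's outgoing
weights over its observed targets sum to 1. Excluding unobserved kmers
from the normalization as well is a deliberate choice: a kmer that is
genuinely frequent in the genome would have been observed, so the mass
truncated away is small. The structure is stored as a COO/CSR-by-target
sparse triplet; it is recomputed rather than serialized.

Defaults **k = 13** and **d_max = 1**: 4^13 ≈ 6.7·10^7 dwarfs any
desk-scale spectrum so chance kmer collisions are negligible, while
d_max = 1 keeps every neighborhood at most 3k+1 = 40 wide; both are
exposed as flags. At the benchmark scale below (~1.5–3·10^5 observed
kmers) a full run fits comfortably in a few hundred MB.

## Detection

A kmer is called erroneous when its statistic is strictly below the
threshold *M*; the statistic is *T* (repeat-aware) or *Y* (the
classical baseline, available for comparison). Against simulator truth
a kmer **type** is erroneous iff α_l = 0 — i.e. every observation of it
contains at least one misread base. Sweeps use the integer grid
0…⌈max⌉+1 (comparable across Y and T; finer grids via flag), counting
FP (clean kmer called), FN (erroneous kmer missed) and WP = FP + FN at
each threshold; ties in the minimum go to the smaller threshold.

## Correction

For observed kmer *x_l* and kmer position *t*, the posterior that the
true base was *b* follows from Bayes' rule over candidate sources, with
*T_m* standing in for the unknown genomic frequencies:

  p_t(b | x_l) ∝ Σ_{m∈𝒩_l, x_m[t]=b} T_m · w(m→l)

Window posteriors covering a read position are averaged (they carry
non-independent information), and the base is rewritten to the argmax
when it differs from the observed base; ties retain the observed base
(conservative). Correction is a single pass computed from the original
read's windows — corrections are not fed back into posteriors within a
read, avoiding order dependence — and *T* is not re-estimated
afterwards. Reads enter correction only if they contain at least one
kmer with *T* below a liberal threshold; the pipeline default is 3× the
detection threshold in use (or the mixture-derived threshold when one
was fitted). A neighborhood with zero attempt mass falls back to a
point mass on the observed base, logged.

## Threshold mixture

The histogram of *T* is multi-modal: erroneous kmers pile up near 0 and
occurrence classes *g* = 1, 2, … peak near *g·c*. The fitted mixture
has G + 2 components: Gamma(shape, rate) for the erroneous bulk; G
Normals with means *g·m* and variances *g·v*, the moments of a sum of
*g* iid Negative Binomial deviates (*m = μp/(1−p)*, *v = μp/(1−p)²* — a
Poisson read count with Gamma-distributed rate); and a Uniform over the
observed range absorbing the few kmers beyond class G. On a
non-repetitive simulation the fitted first-class mean *m* estimates the
coverage constant *c*.

Fitting is EM with deterministic initialization (no randomness
anywhere): gamma shape 1 with rate 1/median of the lowest decile; class
spacing *m* from a histogram peak and *v = 2m*. Three refinements were
needed beyond the plain recipe, all visible in the code:

* the **uniform component starts at weight 0.02** (its role is the few
  very-high-occurrence kmers; starting it as an equal partner lets it
  swallow the other components' tails and traps EM);
* the **peak search for m ignores mass below the overall mean** when
  enough points remain above it (otherwise the gamma tail masquerades
  as the first peak on error-dominated histograms);
* EM is **restarted from three deterministic spacing candidates**
  (peak, half-peak, median-above-mean) and the best final likelihood
  wins — the likelihood surface has local optima when the initial
  spacing falls between histogram peaks.

The (m, v) M-step has closed-form weighted-ML updates; the gamma shape
solves the usual digamma equation with a bracketed root finder, with
the gamma **mean capped at m/2** (erroneous kmers sit below the
single-occurrence peak — without this identifiability constraint a
high-shape gamma can impersonate a normal component; the cap is solved
on the boundary, so the M-step remains a constrained maximizer and the
likelihood stays monotone). The number of classes G minimizes
BIC = −2·loglik + (G+5)·log n. A kmer is classified erroneous when its
posterior membership in the gamma component exceeds 0.5; *T* = 0 is
assigned to the gamma component deterministically.

## Simulator

Genomes are iid sequence at a chosen composition (default maize-like
A 28 / C 23 / G 22 / T 27) with repeat families — one random unit per
family, drawn from the same composition, copied `multiplicity` times —
placed by interleaving all copies in random order and distributing the
free space multinomially among the gaps, so any feasible recipe packs
without rejection sampling. Reads are uniform-start substrings passed
through the substitution model (constant rate, or per-read-position
matrices sampled column-wise); forward strand only by default, since
both detection and correction are strand-agnostic given reads as they
come. Ground truth: per-read start and per-base misread flags, plus
exhaustive genomic kmer counts α. One seeded generator drives all
randomness; identical seeds give bit-identical output.

### Presets and the scaling rationale

The full benchmark recipes (1 Mb, 80×, 36 bp; 20%/50%/80% repeat span
with repeat families up to 400 copies) are shipped as presets D1–D3.
The `-small` presets scale the genome to 100 kb with proportional read
counts, **scaling repeat unit lengths by 1/10 while keeping copy
numbers** (e.g. D3-small: families (50, 400), (150, 200), (300, 100) =
80% span). Copy number is what matters: a satellite of an α-copy repeat
is observed ≈ α·c·(p_e/3)(1−p_e)^(k−1) times (≈ 40 for α = 400 at 80×,
p_e = 0.006), squarely inside the honest single-copy range (≈ 49) —
this overlap is the regime the method exists for. Scaling copy numbers
down by 10 would push satellite counts to ≈ 4 and make frequency
thresholding trivially adequate, leaving nothing to measure.

## Evaluation

Base-level correction scoring: TP = erroneous base restored to truth;
FP = true base changed at all; TN = true base untouched; FN = erroneous
base still erroneous — including an erroneous base rewritten to a
*different* wrong base, which harms no true base (not FP) but removes
no error (FN). Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
gain = (TP−FP)/(TP+FN) — the net fraction of erroneous bases removed;
gain ≤ sensitivity, and negative gain means correction did net damage.

## What the tests do and do not show

The simulator emulates uniform coverage, iid substitution errors
(optionally position-dependent), exact repeat copies, and single-contig
genomes. Real data add coverage bias, correlated and quality-dependent
errors, diverged repeat copies, indels and strand effects — none of
which are modeled, so passing benchmarks here demonstrate the
statistical machinery under its stated assumptions, not field
performance. The wrong-model experiment (t2) probes one specific
robustness axis: a mis-specified positional error pattern at matched
overall rate.

Problem sizes used by the shipped checks — 100 kb genomes at 80×
(≈ 2.2·10^5 reads, ≈ 5.3·10^6 kmer windows) for the detection
experiments, 10^7 bases for simulator re-calibration, 2·10^4 draws for
mixture recovery — were chosen so a full run completes in minutes on
one CPU while keeping every estimate's sampling error well inside the
asserted tolerances.

## Known limitations

* Quality scores are read and passed through but never used.
* Single-pass correction: no correct→recount→re-correct loop.
* Plain EM (no acceleration); d_max ≤ 2, and d_max = 2 neighborhoods
  are quadratically more expensive to build.
* The kmer-position error model cannot express how a kmer's errors
  depend on where the kmer sits in the read.
* Threshold choice via the mixture is available but the benchmark
  numbers use full sweeps against simulated truth.
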