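# Methods

## Model

Each editable genomic site is analysed independently. For site-level data
`D = {(x_j, n_j)}_{j=1..J}` from `J` single cells plus a bulk pair `(x, n)`:

* `x_j | p_j ~ Binomial(n_j, p_j)` — read sampling within a cell;
* `p_j | v ~ Beta(mean p̂, variance v)` — variation of the latent per-cell
  editing rate across cells, with the beta distribution in its
  mean/variance parametrization (`α = p̂·s`, `β = (1−p̂)·s`,
  `s = p̂(1−p̂)/v − 1`);
* `p̂ = x/n`, the bulk plug-in estimate, held fixed throughout. The bulk
  sample pools a large number of cells (≥ 1e5 under the modelling
  assumption), so resampling `p̂` would add nothing but noise. Bulk
  estimates of exactly 0 or 1 cannot serve as a beta mean and are clamped
  to `1/(2n)` resp. `1 − 1/(2n)` — half a read at the observed depth, i.e.
  the resolution limit of the data. This situation does not arise in the
  shipped scenarios; the clamp is a package-level convention for real
  tables.

The variance `v ∈ [0, p̂(1−p̂)]` is the quantity of interest: 0 means
identical rates in every cell, and the upper bound is the two-point mixture
of fully-unedited and fully-edited cells. `v = 0` is handled everywhere as
an explicit degenerate branch (point mass at `p̂`, binomial marginal),
never as limiting shape parameters, because `α, β → ∞` as `v → 0` and
silent conversion would hide the failure mode.

The beta-binomial marginal is computed in log space via log-gamma
functions; coverages of hundreds of reads are exact. Below `v/v_max ≈
1e−10` the log-gamma differences lose precision against shapes of order
1e10 and the marginal switches to its binomial limit, whose error `O(n²v)`
is far below that noise floor.

## Penalized-complexity prior on v

The base model is `v = 0`. Complexity is the distance
`d(v) = sqrt(2·KL(v))`, with the KL divergence evaluated between the
*marginal* read-count distributions — beta-binomial vs binomial — at a
reference coverage `n_ref` (exact finite sum over `x = 0..n_ref`). At the
latent level the divergence (beta density against a point mass) is
infinite, so the marginal level is the natural observable-scale choice;
`n_ref = 20` by default, matching the recommended per-cell coverage, and
settable per site (e.g. the median observed `n_j`). At the boundary
`v = v_max` the flexible marginal degenerates to the two-point mixture with
mass `1−p` at 0 and `p` at `n_ref`, and the KL sum has a closed form
(`(n−1)·ln 2` at `p = 1/2`), used both in the implementation and as a test
oracle.

An exponential `λe^{−λd}` is placed on `d`. Because `v` lives on a bounded
interval, `d` is bounded by `d_max = d(v_max)` and the exponential is
truncated and renormalized to `[0, d_max]`; otherwise the induced prior on
`v` would not integrate to one. The rate `λ` solves the tail condition

    (e^{−λ·d(v_L)} − e^{−λ·d_max}) / (1 − e^{−λ·d_max}) = α

by Brent root finding (reducing to `λ = −ln α / d(v_L)` when truncation is
negligible); calibration fails loudly, reporting `d(v_L)` and `d_max`, if
no rate in `(0, ∞)` satisfies it (possible only when `v_L` is nearly
`v_max`). Defaults `v_L = 0.142`, `α = 0.01`: the conservative
little-variability prior. The induced density on `v` is
`λ e^{−λ d(v)} d'(v)` (normalized for truncation) with `d'` by central
finite differences, step `min(1e−5, v/10, (v_max − v)/10)` so the stencil
never leaves the support; there is no closed form for `d'`. The density has
an integrable `1/sqrt(v)` singularity at 0 (KL grows linearly in `v` at the
boundary of its parameter space), which quadrature handles.

## Sampler

Metropolis-within-Gibbs, per site:

1. `p_j | v, x_j ~ Beta(α(v)+x_j, β(v)+n_j−x_j)` exactly, vectorized over
   cells. Cells with `n_j = 0` stay in the dataset — their rate is drawn
   from the beta layer itself and contributes no binomial term — keeping
   cell indexing stable. Draws are clipped to `[1e−12, 1−1e−12]` before
   entering the `v` target's log-density.
2. `v | {p_j}`: Gaussian random-walk Metropolis on `u = logit(v/v_max)`,
   target `Π_j Beta(p_j; p̂, v) · prior(v) · |dv/du|`. The transform
   respects the bounded support without boundary rejections. The step size
   starts at 0.8 and is multiplied by 0.75/1.35 every 50 burn-in iterations
   when the windowed acceptance rate leaves [0.25, 0.45], then frozen so
   the post-burn-in chain is a valid fixed-kernel Markov chain.

Defaults: 20 000 iterations, 5 000 burn-in, thinning 1, `v` initialized at
`v_max/10`; one default-length site fit takes a few seconds. A mandatory
seed drives a single `numpy` Generator, so identical settings give
bitwise-identical draws. Reported diagnostics are the post-burn-in
acceptance rate of the `v` step and seed-replicate agreement; the tests'
shorter chains (4 000–8 000 iterations) are their own problem-size choice
for replicate sweeps.

Summaries: the 95% HPD interval is the shortest window of
`⌈0.95·N⌉` consecutive sorted draws (exact for unimodal posteriors; checked
against `arviz.hdi` in tests). "Variance excludes zero" means the HPD lower
bound clears `δ = 1e−3`, since a sample-based interval never literally
contains 0. The posterior-predictive marginal editing rate draws one
`p_new ~ Beta(p̂, v)` per retained `v` draw. Posterior modes (for `v` and
for rates) come from the maximum of a beta-kernel density estimate on a
512-point grid: each draw `t` contributes a `Beta(t·κ+1, (1−t)·κ+1)`
kernel — support exactly `[0, 1]`, shapes ≥ 1 so the estimate stays finite
when draws pile at the endpoints, kernel mean within `O(1/κ)` of `t` — with
concentration `κ = N^{2/5}` balancing kernel width against Monte-Carlo
noise at the usual nonparametric rate.

## Scenario generator

The generator reproduces the artificial study designs, and its defaults are
those designs, not tuning knobs: per-cell rates are drawn by choosing a
rate region by weight and then uniformly within it (uniform-within-region
is the minimal reading of "rates sampled from the region"); counts are the
deterministic rounding `x_j = round(p_j·n_j)`, nudged by ±1 back inside the
drawn region when rounding left it and an attainable integer ratio exists.
Rounding is deliberate rather than binomial sampling — the designs fix
*effective* rates inside a region, and the binomial layer belongs to the
model during inference, not to the data generator. The bulk sample is a
separate large population (1e5 cells) from the same region mixture, read at
depth 1e4 so estimator noise (~0.005) is negligible against region widths;
`bulk_from_cells=True` instead aggregates the J simulated cells, covering
the other reading of how an artificial bulk might be formed.

Presets: high variance (0–5% ∪ 95–100%), low variance (45–55%), coverage
sweep {100, 50, 20, 10}×(J=20), cell sweep J∈{50, 20, 10, 5}×(coverage 20),
physiological uniform 0–20% (bulk mean 10%) and 20–50% (bulk mean 35%), and
two bimodal 5–15% ∪ 40–50% variants. The stated bulk means of the bimodal
designs cannot both come from one equal-weight mixture (no positive weight
on the 40–50% region yields a 10% mean), so `phys_bimodal_mid` weights the
regions (2/7, 5/7) putting the shared mixture mean exactly between them at
35%, while `phys_bimodal_low` keeps equal-weight cells and draws its bulk
from the 5–15% region alone (mean 10%, inside the low region) via the
`bulk_regions` override.

What the generator does *not* emulate: capture-efficiency dropout beyond
what low `n_j` encodes, expression-correlated coverage, alignment artefacts
or sequencing error, and cross-site correlation. Passing tests therefore
demonstrate correct inference under the model's own sampling assumptions
and the stated scenario geometry — not robustness to the technical noise of
real single-cell libraries.

## Detection pipeline

Sites are summarized per sample as A/T/G/C base-count vectors (1-based
coordinates; BED exclusion tracks are 0-based half-open with conversion
centralized in `ExclusionTracks`). The edited base is C→T on the transcript
strand; minus-strand sites are read as genomic G→A and handled by one
strand-axis helper so plus/minus calls are exactly mirror images. QC per
site: wild-type coverage ≥ 5, edit support ≥ 2 reads, no second
non-reference base with ≥ 2 supporting reads ("multiple transitions",
operationalized with the same support cutoff as the edit itself), and no
edited-base reads at all in the knockout. Retained sites must then have
wild-type vector magnitude ≥ 15 and wild-type/knockout angle ≥ 0.11 rad
(arccos of the normalized dot product, computed in an atan2 form that is
exact for identical vectors), lie outside SNP and repeat tracks, and be
more than 4 bp from every splice junction.

The magnitude is the vector's total read count (L1 norm). Under the
Euclidean norm, a site edited at ~50% of 20 reads would have magnitude
`sqrt(10² + 10²) ≈ 14.1` and be rejected while weakly edited sites pass —
inverting the intent of a coverage floor. The L1 reading makes the
admissible edited-read counts at coverage 20 exactly {2..20} and, combined
with the 2-read support minimum, reproduces the threshold's characterized
equivalence: minimum coverage 20 with a 10% editing rate.

Read-level filtering (indel-containing reads; edits within 2 bp of either
read end) applies both to the abstract `ReadObs` filter and to the optional
pysam adapter that builds count tables from MD-tagged alignments;
deduplication is assumed upstream, with a `(start, CIGAR)` collapse flag as
a convenience. Transcript classification: one called site → site-specific,
two or more → hyperedited.

## Problem sizes and limitations

Test and acceptance runs use the study geometries (J = 5–50 cells, coverage
10–100, bulk populations 1e4–1e5); replicate sweeps use 25 seeded
replicates for HPD coverage (≥ 80% observed at J = 20, a small-J effect,
not a sampler defect) and 10 for the extreme-scenario contrasts. Known
limitations: single-site independence (no joint model across sites), the
fixed-`p̂` approximation (poor if the bulk is shallow), no convergence
diagnostics beyond acceptance rate and seed agreement, and a caller that
consumes count tables — alignment, expression quantification and ambiguity
re-checks (e.g. BLAT) are out of scope.
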