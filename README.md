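# editvar

Bulk RNA-seq reports a single editing rate per site — the fraction of reads
carrying, say, a C-to-U change. That number is a population average: a site
edited at 25% in bulk could mean every cell edits a quarter of its
transcripts, or that a quarter of the cells edit almost all of theirs.
`editvar` is a toolkit for telling these apart from single-cell RNA-seq
counts, for researchers studying APOBEC1-mediated C-to-U editing (or any
per-site binary modification) in cell populations.

## The model

For one editable site observed in `J` single cells plus a cognate bulk
sample, with `x_j` edited of `n_j` mapped reads in cell `j`:

    x_j | p_j ~ Binomial(n_j, p_j)
    p_j | v   ~ Beta(mean = p̂, variance = v),  i.i.d. over cells
    v         ~ PC(v_L, α)  on  [0, p̂(1 − p̂)]

The beta layer is parametrized by its mean and variance; the mean is fixed
at the bulk estimate `p̂ = x/n` (the bulk pools ≥ 1e5 cells, so the plug-in
estimator is accurate), leaving the between-cell variance `v` as the
inferential target. `v = 0` means all cells share one editing rate;
`v = p̂(1 − p̂)` is the extreme two-point mixture of never- and
always-editing cells.

The prior on `v` is a penalized-complexity (PC) prior: an exponential
distribution on the complexity distance `d(v) = sqrt(2·KL(v))` from the
base model `v = 0`, where the KL divergence is taken between the
beta-binomial and binomial read-count marginals at a reference coverage
(20 reads by default). The exponential rate is calibrated so that
`P[v > v_L] = α`, with the conservative default `v_L = 0.142`, `α = 0.01`.
Posterior sampling is Metropolis-within-Gibbs: exact conjugate
`Beta(α(v)+x_j, β(v)+n_j−x_j)` updates per cell, a random-walk Metropolis
step for `v` on the logit-transformed scale. Heterogeneity is declared when
the 95% highest-posterior-density (HPD) interval for `v` excludes zero.

The package also includes:

* **`simulate`** — the artificial study scenarios (per-cell rates drawn
  from uniform rate regions, fixed coverage, bulk aggregated from a large
  emulated population), including coverage/cell-number sweeps and
  physiological ranges.
* **`detect`** — the bulk wild-type vs knockout C-to-U site caller:
  per-site A/T/G/C base-count vectors, QC filters (≥ 5 reads, ≥ 2 edit
  supports, single transition, no knockout signal), a wild-type vector
  magnitude ≥ 15 and wild-type/knockout angle ≥ 0.11 rad, and BED-based
  SNP/repeat/splice-junction exclusions.
* a thin CLI (`editvar simulate | infer | detect | report`) over the
  library, and narrative scripts in `examples/`.

## Worked example

```python
from editvar import (get_preset, simulate_site, infer_site,
                     hpd_interval, excludes_zero, marginal_rate_draws)

data = simulate_site(get_preset("fig4_high", seed=1)[0])   # rates in 0-5% & 95-100%
post = infer_site(data, seed=2)
iv = hpd_interval(post.v, 0.95)
print(iv.lo, iv.hi, excludes_zero(iv))
```

Running `python examples/quantify_editing_variance.py` prints:

```
fig4_high: J=20 cells, bulk mean p^ = 0.506
  posterior v: mean=0.1783 mode=0.1800
  95% HPD: (0.1467, 0.2067)  excludes zero: True
  marginal editing rate of a new cell: mean=0.496 sd=0.421

fig4_low: J=20 cells, bulk mean p^ = 0.506
  posterior v: mean=0.0013 mode=0.0010
  95% HPD: (0.0000, 0.0042)  excludes zero: False
  marginal editing rate of a new cell: mean=0.506 sd=0.037
```

Both sites are ~50% edited in bulk, but only the first is heterogeneous:
its variance posterior sits far from zero and the predicted editing rate of
an unobserved cell is bimodal (sd 0.42), while the second collapses to
near-identical rates across cells. The other examples demonstrate prior
calibration, the site caller, and the coverage/cell-number requirements
(variance remains detectable down to 10 reads per cell and 5 cells).

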