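"""Quantify cell-to-cell editing-rate variance on two simulated sites.

Generates the two extreme artificial scenarios — one where per-cell editing
rates sit only in 0-5% and 95-100% (maximal heterogeneity), one where they
sit in 45-55% (near-uniform editing) — fits the hierarchical beta-binomial
model to each, and prints the posterior summary of the variance v.
"""

from editvar import (
    excludes_zero,
    get_preset,
    hpd_interval,
    infer_site,
    kde_mode,
    marginal_rate_draws,
    simulate_site,
)

for preset in ("fig4_high", "fig4_low"):
    data = simulate_site(get_preset(preset, seed=1)[0])
    post = infer_site(data, seed=2)
    interval = hpd_interval(post.v, 0.95)
    marginal = marginal_rate_draws(post)
    print(f"\n{preset}: J={data.n_cells} cells, bulk mean p^ = {post.bulk_rate:.3f}")
    print(f"  posterior v: mean={post.v.mean():.4f} "
          f"mode={kde_mode(post.v, (0, post.v_max)):.4f}")
    print(f"  95% HPD: ({interval.lo:.4f}, {interval.hi:.4f})  "
          f"excludes zero: {excludes_zero(interval)}")
    print(f"  marginal editing rate of a new cell: mean={marginal.mean():.3f} "
          f"sd={marginal.std():.3f}")

print(
    "\nThe high-variance site is flagged (v's HPD clears zero: cells genuinely"
    "\ndiffer in editing), while the low-variance site collapses towards v=0"
    "\nand a marginal rate concentrated at the bulk mean of 0.5."
)
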