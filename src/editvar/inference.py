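"""Posterior sampling for per-site editing-rate variance.

The model for one site with J cells is

    x_j | p_j        ~ Binomial(n_j, p_j)
    p_j | v          ~ Beta(mean = p_hat, variance = v)     (i.i.d. over cells)
    v                ~ PC prior on [0, p_hat(1 - p_hat)]

with the mean of the beta layer fixed at the bulk estimate p_hat.  Sampling
alternates exact conjugate draws of each p_j given v with a random-walk
Metropolis update of v given {p_j} (Metropolis-within-Gibbs).  The v-update
walks on the unconstrained scale u = logit(v / v_max) so the bounded support
is respected without rejection at the boundary; the proposal step size is
adapted during burn-in towards a 25-45% acceptance rate and frozen after.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, expit, logit

from .model import (
    BetaMeanVar,
    SiteDataset,
    beta_params_from_mean_var,
    effective_bulk_mean,
)
from .prior import PCPrior

_P_CLIP = 1e-12
_V_EDGE = 1e-9  # keep v away from {0, v_max} on the logit scale


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration; the seed is mandatory for reproducibility."""

    seed: int
    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 1
    step_init: float = 0.8
    adapt_window: int = 50
    target_accept: tuple[float, float] = (0.25, 0.45)
    excludes_zero_delta: float = 1e-3

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class HPDInterval:
    """Highest-posterior-density credible interval [lo, hi] of given mass."""

    lo: float
    hi: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("HPD interval needs lo <= hi")

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class PosteriorSamples:
    """Retained MCMC draws for one site.

    ``v`` holds the variance draws, ``p`` the per-cell rate draws with shape
    (n_draws, J); ``bulk_rate`` is the fixed beta-layer mean p_hat.
    """

    v: np.ndarray
    p: np.ndarray
    cell_ids: tuple[str, ...]
    bulk_rate: float
    v_max: float
    acceptance_rate: float
    settings: SamplerSettings

    @property
    def n_draws(self) -> int:
        return self.v.shape[0]


def _beta_layer_loglik(p_cells: np.ndarray, p_hat: float, v: float) -> float:
    """Sum of log Beta(p_j; mean p_hat, var v) over cells."""
    a, b = beta_params_from_mean_var(BetaMeanVar(p_hat, v))
    return float(
        np.sum((a - 1.0) * np.log(p_cells) + (b - 1.0) * np.log1p(-p_cells))
        - len(p_cells) * betaln(a, b)
    )


def run_sampler(
    data: SiteDataset,
    prior: PCPrior,
    settings: SamplerSettings,
    *,
    update_v: bool = True,
    v_init: float | None = None,
) -> PosteriorSamples:
    """Metropolis-within-Gibbs sampler for (v, p_1..p_J) at one site.

    The prior must be calibrated at p = the bulk mean of ``data`` (the model
    fixes the beta-layer mean there).  Cells with zero coverage are retained:
    their rate is drawn from the beta layer itself and they contribute no
    binomial likelihood.  Identical seed and settings give identical draws.

    Setting ``update_v=False`` freezes v at ``v_init`` (conjugate-only Gibbs),
    which is useful for validation against closed-form beta posteriors.
    """
    p_hat = effective_bulk_mean(data.bulk)
    if not prior.calibrated:
        prior = PCPrior(p=p_hat, n_ref=prior.n_ref, v_l=prior.v_l, tail_alpha=prior.tail_alpha).calibrate()
    if abs(prior.p - p_hat) > 1e-9:
        raise ValueError(
            f"prior calibrated at p = {prior.p} but the bulk mean is {p_hat}"
        )
    x = np.array([c.edited for c in data.cells], dtype=float)
    n = np.array([c.total for c in data.cells], dtype=float)
    if np.all(n == 0):
        raise ValueError(f"site {data.label}: no cell has any mapped reads")

    v_max = prior.v_max
    v = float(v_init) if v_init is not None else 0.1 * v_max
    if not 0.0 < v < v_max:
        raise ValueError(f"initial v = {v} outside (0, {v_max})")

    rng = np.random.default_rng(settings.seed)
    step = settings.step_init
    lo_acc, hi_acc = settings.target_accept

    n_draws = settings.n_draws
    v_out = np.empty(n_draws)
    p_out = np.empty((n_draws, len(x)))

    log_post_v = -np.inf  # log target for current v given current p_cells
    accepted_post = 0
    kept = 0
    window_accepts = 0

    for it in range(settings.iterations):
        # (i) conjugate per-cell updates p_j | v, x_j
        a, b = beta_params_from_mean_var(BetaMeanVar(p_hat, v))
        p_cells = rng.beta(a + x, b + n - x)
        np.clip(p_cells, _P_CLIP, 1.0 - _P_CLIP, out=p_cells)

        if update_v:
            # (ii) Metropolis step for v | {p_j} on u = logit(v / v_max)
            log_post_v = (
                _beta_layer_loglik(p_cells, p_hat, v)
                + prior.log_density(v)
                + math.log(v * (v_max - v) / v_max)  # |dv/du| Jacobian
            )
            u = logit(v / v_max)
            u_new = u + step * rng.standard_normal()
            v_new = float(v_max * expit(u_new))
            v_new = min(max(v_new, v_max * _V_EDGE), v_max * (1.0 - _V_EDGE))
            log_post_new = (
                _beta_layer_loglik(p_cells, p_hat, v_new)
                + prior.log_density(v_new)
                + math.log(v_new * (v_max - v_new) / v_max)
            )
            if math.log(rng.uniform()) < log_post_new - log_post_v:
                v = v_new
                log_post_v = log_post_new
                window_accepts += 1
                if it >= settings.burn_in:
                    accepted_post += 1
            # step-size adaptation, burn-in only
            if it < settings.burn_in and (it + 1) % settings.adapt_window == 0:
                rate = window_accepts / settings.adapt_window
                if rate < lo_acc:
                    step *= 0.75
                elif rate > hi_acc:
                    step *= 1.35
                window_accepts = 0
            elif it == settings.burn_in - 1:
                window_accepts = 0

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            v_out[kept] = v
            p_out[kept] = p_cells
            kept += 1

    n_post = settings.iterations - settings.burn_in
    return PosteriorSamples(
        v=v_out[:kept],
        p=p_out[:kept],
        cell_ids=tuple(c.cell_id for c in data.cells),
        bulk_rate=p_hat,
        v_max=v_max,
        acceptance_rate=accepted_post / n_post if update_v else float("nan"),
        settings=settings,
    )


def infer_site(
    data: SiteDataset,
    *,
    seed: int,
    v_l: float = 0.142,
    tail_alpha: float = 0.01,
    n_ref: int = 20,
    settings: SamplerSettings | None = None,
) -> PosteriorSamples:
    """Convenience wrapper: build and calibrate the PC prior at the site's
    bulk mean, then run the sampler."""
    p_hat = effective_bulk_mean(data.bulk)
    prior = PCPrior(p=p_hat, n_ref=n_ref, v_l=v_l, tail_alpha=tail_alpha).calibrate()
    if settings is None:
        settings = SamplerSettings(seed=seed)
    elif settings.seed != seed:
        raise ValueError("seed argument disagrees with settings.seed")
    return run_sampler(data, prior, settings)


# ---------------------------------------------------------------------------
# interval and density summaries


def hpd_interval(draws, mass: float = 0.95) -> HPDInterval:
    """Shortest contiguous interval containing ceil(mass * N) sorted draws.

    For a unimodal posterior this sliding-window minimum-width interval is
    the highest-posterior-density credible interval; its contained empirical
    mass is at least ``mass`` by construction.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("cannot form an HPD interval from no draws")
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    s = np.sort(draws)
    k = int(np.ceil(mass * s.size))
    k = min(max(k, 1), s.size)
    widths = s[k - 1 :] - s[: s.size - k + 1]
    i = int(np.argmin(widths))
    return HPDInterval(float(s[i]), float(s[i + k - 1]), mass)


def excludes_zero(interval: HPDInterval, delta: float = 1e-3) -> bool:
    """Whether an HPD interval on v excludes the no-variability model v = 0.

    Sample-based intervals never literally contain 0, so "excludes zero" is
    operationalized as the lower bound clearing a small delta.
    """
    return interval.lo > delta


def marginal_rate_draws(
    post: PosteriorSamples, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Posterior-predictive editing rate of an unobserved cell.

    For each retained variance draw v, one draw p_new ~ Beta(mean p_hat,
    var v).  The histogram of these draws is the model's predicted
    distribution of editing rates among cells.
    """
    if post.n_draws == 0:
        raise ValueError("empty posterior")
    if rng is None:
        rng = np.random.default_rng((post.settings.seed + 1_000_003) % 2**31)
    p_hat = post.bulk_rate
    out = np.full(post.n_draws, p_hat)
    s = p_hat * (1.0 - p_hat) / np.maximum(post.v, 1e-300) - 1.0
    ok = (post.v > 0.0) & (s > 0.0)
    a = p_hat * s[ok]
    b = (1.0 - p_hat) * s[ok]
    out[ok] = rng.beta(a, b)
    return out


def beta_kernel_density(
    draws, grid, concentration: float | None = None
) -> np.ndarray:
    """Beta-kernel density estimate on [0, 1].

    Each draw t contributes a Beta(t*kappa + 1, (1-t)*kappa + 1) kernel with
    mean (t*kappa + 1)/(kappa + 2), i.e. centred on t up to an O(1/kappa)
    shrink towards 1/2, so the estimate has support exactly [0, 1] and
    respects the bounded domain of editing rates (no spill-over beyond the
    endpoints, in contrast to Gaussian kernels).  The +1 offset keeps both
    kernel shapes >= 1 so the estimate stays finite at the endpoints even
    when draws pile up there.  The concentration kappa plays the role of an
    inverse bandwidth; the default N**(2/5) balances kernel variance
    (~1/kappa) against Monte-Carlo noise at the usual nonparametric rate.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("cannot estimate a density from no draws")
    if np.any((draws < 0.0) | (draws > 1.0)):
        raise ValueError("draws must lie in [0, 1]")
    grid = np.asarray(grid, dtype=float)
    kappa = float(concentration) if concentration is not None else draws.size ** 0.4
    a = draws * kappa + 1.0  # (N,)
    b = (1.0 - draws) * kappa + 1.0
    g = np.clip(grid, 1e-12, 1.0 - 1e-12)
    # log kernel matrix (N, G), mean over draws in probability space
    log_k = (
        (a[:, None] - 1.0) * np.log(g[None, :])
        + (b[:, None] - 1.0) * np.log1p(-g[None, :])
        - betaln(a, b)[:, None]
    )
    dens = np.exp(log_k).mean(axis=0)
    dens[(grid < 0.0) | (grid > 1.0)] = 0.0
    return dens


def kde_mode(draws, support: tuple[float, float] = (0.0, 1.0), n_grid: int = 512) -> float:
    """Mode of a bounded sample, via the beta-kernel KDE maximum on a grid.

    The sample is affinely mapped to [0, 1], smoothed with beta kernels and
    the grid argmax mapped back; used e.g. for the posterior mode of v on
    [0, v_max].
    """
    lo, hi = support
    if hi <= lo:
        raise ValueError("support must have positive width")
    scaled = (np.asarray(draws, dtype=float) - lo) / (hi - lo)
    grid = np.linspace(0.0, 1.0, n_grid)
    dens = beta_kernel_density(np.clip(scaled, 0.0, 1.0), grid)
    return float(lo + grid[int(np.argmax(dens))] * (hi - lo))
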