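"""Sampler correctness, HPD intervals, posterior-predictive draws, KDE."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from editvar.inference import (
    HPDInterval,
    SamplerSettings,
    beta_kernel_density,
    excludes_zero,
    hpd_interval,
    infer_site,
    kde_mode,
    marginal_rate_draws,
    run_sampler,
)
from editvar.model import (
    BetaMeanVar,
    BulkSiteCounts,
    CellSiteCounts,
    GenomicSite,
    SiteDataset,
    beta_params_from_mean_var,
)
from editvar.prior import PCPrior
from editvar.simulate import get_preset, simulate_site

SHORT = dict(iterations=4000, burn_in=1000)


def site_from_counts(xs, ns, bulk_edited, bulk_total):
    cells = tuple(
        CellSiteCounts(f"c{j}", int(x), int(n)) for j, (x, n) in enumerate(zip(xs, ns))
    )
    return SiteDataset(GenomicSite("chr1", 100), cells, BulkSiteCounts(bulk_edited, bulk_total))


def model_simulated_site(v_true, m=0.35, n_cells=20, coverage=20, seed=0):
    """Data drawn from the hierarchy itself (not the scenario generator)."""
    rng = np.random.default_rng(seed)
    a, b = beta_params_from_mean_var(BetaMeanVar(m, v_true))
    p_cells = rng.beta(a, b, size=n_cells)
    xs = rng.binomial(coverage, p_cells)
    return site_from_counts(xs, np.full(n_cells, coverage), int(m * 10000), 10000)


class TestConjugateUpdates:
    def test_frozen_variance_recovers_closed_form_beta(self):
        # v = 1/12 at mean 1/2 is a flat Beta(1,1) layer, so a single cell
        # with 5 of 10 edited has posterior rate Beta(6, 6)
        data = site_from_counts([5], [10], 50, 100)
        prior = PCPrior(p=0.5, n_ref=20, v_l=0.142).calibrate()
        post = run_sampler(
            data, prior, SamplerSettings(seed=3, iterations=30_000, burn_in=2000),
            update_v=False, v_init=1 / 12,
        )
        assert np.all(post.v == 1 / 12)
        assert post.p[:, 0].mean() == pytest.approx(0.5, abs=0.01)
        assert post.p[:, 0].var() == pytest.approx(1 / 52, rel=0.1)

    def test_frozen_variance_oracle_random_configurations(self):
        rng = np.random.default_rng(42)
        prior = PCPrior(p=0.5, n_ref=20, v_l=0.142).calibrate()
        for trial in range(10):
            n = int(rng.integers(5, 60))
            x = int(rng.integers(0, n + 1))
            v = float(rng.uniform(0.01, 0.2))
            data = site_from_counts([x], [n], 50, 100)
            post = run_sampler(
                data, prior, SamplerSettings(seed=trial, iterations=20_000, burn_in=1000),
                update_v=False, v_init=v,
            )
            a, b = beta_params_from_mean_var(BetaMeanVar(0.5, v))
            ref = stats.beta(a + x, b + n - x)
            n_draws = post.p.shape[0]
            se_mean = ref.std() / np.sqrt(n_draws)
            assert post.p[:, 0].mean() == pytest.approx(ref.mean(), abs=5 * se_mean)
            assert post.p[:, 0].var() == pytest.approx(ref.var(), rel=0.15)

    def test_zero_coverage_cells_draw_from_the_beta_layer(self):
        data = site_from_counts([5, 0], [10, 0], 50, 100)
        prior = PCPrior(p=0.5, n_ref=20, v_l=0.142).calibrate()
        post = run_sampler(
            data, prior, SamplerSettings(seed=1, iterations=20_000, burn_in=1000),
            update_v=False, v_init=1 / 12,
        )
        # Beta(1,1) layer: the uncovered cell's rate is uniform on (0,1)
        assert post.p[:, 1].mean() == pytest.approx(0.5, abs=0.02)
        assert post.p[:, 1].var() == pytest.approx(1 / 12, rel=0.1)

    def test_all_cells_uncovered_is_an_error(self):
        data = site_from_counts([0, 0], [0, 0], 50, 100)
        prior = PCPrior(p=0.5, n_ref=20, v_l=0.142).calibrate()
        with pytest.raises(ValueError, match="mapped reads"):
            run_sampler(data, prior, SamplerSettings(seed=1, **SHORT))


class TestSamplerBehaviour:
    def test_identical_seed_gives_identical_draws(self):
        data = simulate_site(get_preset("fig4_high", seed=5)[0])
        a = infer_site(data, seed=7, settings=SamplerSettings(seed=7, **SHORT))
        b = infer_site(data, seed=7, settings=SamplerSettings(seed=7, **SHORT))
        np.testing.assert_array_equal(a.v, b.v)
        np.testing.assert_array_equal(a.p, b.p)
        assert a.acceptance_rate == b.acceptance_rate

    def test_prior_bulk_mean_mismatch_rejected(self):
        data = site_from_counts([5], [10], 23, 100)
        prior = PCPrior(p=0.5, n_ref=20, v_l=0.142).calibrate()
        with pytest.raises(ValueError, match="bulk mean"):
            run_sampler(data, prior, SamplerSettings(seed=1, **SHORT))

    def test_high_variance_data_shift_posterior_away_from_zero(self):
        data = simulate_site(get_preset("fig4_high", seed=2)[0])
        post = infer_site(data, seed=4, settings=SamplerSettings(seed=4, **SHORT))
        assert excludes_zero(hpd_interval(post.v))
        assert post.v.mean() > 0.05

    def test_low_variance_data_accumulate_towards_zero(self):
        data = simulate_site(get_preset("fig4_low", seed=2)[0])
        post = infer_site(data, seed=4, settings=SamplerSettings(seed=4, **SHORT))
        assert not excludes_zero(hpd_interval(post.v))
        assert kde_mode(post.v, (0.0, post.v_max)) < 0.02

    @pytest.mark.parametrize("coverage", [10, 20, 50, 100])
    def test_high_variance_detected_across_coverage_sweep(self, coverage):
        cfg = next(c for c in get_preset("fig2", seed=3) if c.coverage == coverage)
        post = infer_site(simulate_site(cfg), seed=9, settings=SamplerSettings(seed=9, **SHORT))
        assert excludes_zero(hpd_interval(post.v))

    @pytest.mark.parametrize("n_cells", [5, 10, 20, 50])
    def test_high_variance_detected_across_cell_sweep(self, n_cells):
        cfg = next(c for c in get_preset("fig3", seed=3) if c.n_cells == n_cells)
        post = infer_site(simulate_site(cfg), seed=9, settings=SamplerSettings(seed=9, **SHORT))
        assert excludes_zero(hpd_interval(post.v))

    @pytest.mark.parametrize("v_true", [0.005, 0.05, 0.12])
    def test_hpd_covers_true_variance_in_most_replicates(self, v_true):
        # data from the model itself; 95% HPD should cover v_true in >= 80%
        # of replicates (small J keeps this below nominal coverage)
        covered = 0
        for rep in range(25):
            data = model_simulated_site(v_true, seed=1000 + rep)
            post = infer_site(data, seed=rep, settings=SamplerSettings(seed=rep, **SHORT))
            interval = hpd_interval(post.v)
            covered += interval.lo <= v_true <= interval.hi
        assert covered >= 20

    def test_excludes_zero_flag_replicates_on_extreme_scenarios(self):
        high = get_preset("fig4_high")[0]
        low = get_preset("fig4_low")[0]
        hits_high, hits_low = 0, 0
        for rep in range(10):
            post = infer_site(
                simulate_site(replace(high, seed=rep)), seed=rep + 50,
                settings=SamplerSettings(seed=rep + 50, **SHORT),
            )
            hits_high += excludes_zero(hpd_interval(post.v))
            post = infer_site(
                simulate_site(replace(low, seed=rep)), seed=rep + 50,
                settings=SamplerSettings(seed=rep + 50, **SHORT),
            )
            hits_low += kde_mode(post.v, (0.0, post.v_max)) < 0.02
        assert hits_high >= 9
        assert hits_low >= 9


class TestHPD:
    def test_uniform_interval_width(self):
        rng = np.random.default_rng(0)
        interval = hpd_interval(rng.uniform(size=100_000), 0.95)
        assert interval.width == pytest.approx(0.95, abs=0.01)

    def test_normal_interval_matches_central_quantiles(self):
        rng = np.random.default_rng(1)
        interval = hpd_interval(rng.standard_normal(100_000), 0.95)
        assert interval.lo == pytest.approx(-1.96, abs=0.05)
        assert interval.hi == pytest.approx(1.96, abs=0.05)

    def test_contains_at_least_nominal_mass(self):
        rng = np.random.default_rng(2)
        draws = rng.beta(2, 5, size=100_000)
        interval = hpd_interval(draws, 0.95)
        inside = np.mean((draws >= interval.lo) & (draws <= interval.hi))
        assert inside >= 0.95

    def test_matches_arviz_oracle(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        draws = rng.gamma(3.0, 1.0, size=50_000)
        mine = hpd_interval(draws, 0.95)
        ref_lo, ref_hi = az.hdi(draws, hdi_prob=0.95)
        assert mine.lo == pytest.approx(ref_lo, abs=0.02)
        assert mine.hi == pytest.approx(ref_hi, abs=0.02)

    def test_degenerate_draws_give_zero_width(self):
        interval = hpd_interval(np.full(100, 0.07), 0.95)
        assert interval.lo == interval.hi == 0.07

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([], 0.95)

    @pytest.mark.parametrize(
        "lo, delta, expected", [(0.01, 1e-3, True), (5e-4, 1e-3, False)]
    )
    def test_excludes_zero_thresholding(self, lo, delta, expected):
        assert excludes_zero(HPDInterval(lo, 0.2), delta) is expected


@pytest.fixture(scope="module")
def high_post():
    data = simulate_site(get_preset("fig4_high", seed=8)[0])
    return infer_site(data, seed=13, settings=SamplerSettings(seed=13, **SHORT))


@pytest.fixture(scope="module")
def low_post():
    data = simulate_site(get_preset("fig4_low", seed=8)[0])
    return infer_site(data, seed=13, settings=SamplerSettings(seed=13, **SHORT))


class TestMarginalRates:
    def test_mean_matches_bulk_rate(self, high_post, low_post):
        for post in (high_post, low_post):
            draws = marginal_rate_draws(post)
            assert draws.mean() == pytest.approx(post.bulk_rate, abs=0.02)

    def test_near_zero_variance_collapses_to_bulk_mean(self, low_post):
        draws = marginal_rate_draws(low_post)
        assert draws.std() < 0.1

    def test_high_variance_posterior_gives_fat_tails(self, high_post):
        draws = marginal_rate_draws(high_post)
        assert draws.std() > 0.3
        assert np.mean((draws < 0.1) | (draws > 0.9)) > 0.3

    def test_draws_are_seeded_by_the_sampler_settings(self, high_post):
        np.testing.assert_array_equal(
            marginal_rate_draws(high_post), marginal_rate_draws(high_post)
        )


class TestBetaKernelDensity:
    def test_normalization_on_grid(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 1, 201)
        dens = beta_kernel_density(rng.beta(3, 2, 20_000), grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.02)

    def test_support_is_the_unit_interval(self):
        grid = np.array([-0.2, -0.01, 0.5, 1.01, 1.2])
        dens = beta_kernel_density(np.array([0.4, 0.6]), grid)
        assert np.all(dens[[0, 1, 3, 4]] == 0.0)
        assert dens[2] > 0.0

    def test_consistency_against_known_density(self):
        rng = np.random.default_rng(6)
        grid = np.linspace(0, 1, 101)
        dens = beta_kernel_density(rng.beta(2, 2, 100_000), grid)
        assert np.abs(dens - stats.beta(2, 2).pdf(grid)).max() < 0.05

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            beta_kernel_density([], np.linspace(0, 1, 11))

    def test_mode_of_bounded_sample(self):
        rng = np.random.default_rng(7)
        mode = kde_mode(rng.beta(5, 2, 50_000))
        assert mode == pytest.approx(4 / 5, abs=0.05)  # Beta(5,2) mode
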