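"""Synthetic per-site editing data: the artificial study scenarios.

A scenario draws one editing rate per cell from a mixture of uniform rate
regions (e.g. the very-high-variance design with rates only in 0-5% and
95-100%, or the low-variance design with rates in 45-55%), converts each
rate to an edited-read count at fixed coverage, and builds a cognate bulk
sample by averaging a large emulated cell population (>= 1e5 cells by
default, matching the assumption under which the bulk mean estimator is
accurate).

Counts are the deterministic rounding of rate x coverage (nudged back inside
the drawn region when rounding left it): the scenarios fix *effective*
editing rates inside a region, and the binomial read-sampling layer is
supplied by the model during inference, not by the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import BulkSiteCounts, CellSiteCounts, GenomicSite, SiteDataset

Region = tuple[float, float]


@dataclass(frozen=True)
class ScenarioConfig:
    """Recipe for one simulated site.

    ``rate_regions`` are (lo, hi) intervals on [0, 1]; a cell's rate is drawn
    by picking a region with probability ``region_weights`` (uniform over
    regions when omitted) and then uniformly inside it.  ``bulk_regions``
    overrides the mixture the bulk population is drawn from; by default the
    bulk is a separate large population (``bulk_population`` cells) from the
    same mixture as the single cells, read to depth ``bulk_reads``.  With
    ``bulk_from_cells`` the bulk instead aggregates the J simulated cells.
    """

    name: str
    n_cells: int
    coverage: int | tuple[int, ...]
    rate_regions: tuple[Region, ...]
    region_weights: tuple[float, ...] | None = None
    bulk_regions: tuple[Region, ...] | None = None
    bulk_population: int = 100_000
    bulk_reads: int = 10_000
    bulk_from_cells: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.rate_regions:
            raise ValueError("at least one rate region is required")
        for lo, hi in self.rate_regions:
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError(f"malformed rate region ({lo}, {hi})")
        w = self.weights
        if len(w) != len(self.rate_regions):
            raise ValueError("one weight per rate region required")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("region weights must sum to 1")
        cov = self.coverage if isinstance(self.coverage, tuple) else (self.coverage,)
        if any(c < 1 for c in cov):
            raise ValueError("coverage must be >= 1 read per cell")

    @property
    def weights(self) -> tuple[float, ...]:
        if self.region_weights is None:
            k = len(self.rate_regions)
            return tuple(1.0 / k for _ in range(k))
        return self.region_weights

    def per_cell_coverage(self) -> np.ndarray:
        if isinstance(self.coverage, tuple):
            if len(self.coverage) != self.n_cells:
                raise ValueError("per-cell coverage list must have length n_cells")
            return np.asarray(self.coverage, dtype=int)
        return np.full(self.n_cells, self.coverage, dtype=int)


def _draw_region_rates(
    regions: tuple[Region, ...],
    weights: tuple[float, ...],
    size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.choice(len(regions), size=size, p=weights)
    los = np.array([r[0] for r in regions])
    his = np.array([r[1] for r in regions])
    rates = rng.uniform(los[idx], his[idx])
    return rates, idx


def sample_cell_rates(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one editing rate per cell; returns (rates, region indices)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _draw_region_rates(config.rate_regions, config.weights, config.n_cells, rng)


def counts_from_rates(
    rates,
    coverage,
    regions: list[Region] | None = None,
) -> list[CellSiteCounts]:
    """Deterministically convert per-cell rates to (edited, total) counts.

    x_j = round(p_j * n_j); if an integer ratio inside the cell's drawn
    region exists but rounding fell outside it, x_j is nudged by +-1 back in.
    """
    rates = np.asarray(rates, dtype=float)
    cov = np.broadcast_to(np.asarray(coverage, dtype=int), rates.shape)
    cells = []
    for j, (p, n) in enumerate(zip(rates, cov)):
        x = int(round(p * n))
        if regions is not None:
            lo, hi = regions[j]
            k_lo, k_hi = int(np.ceil(lo * n - 1e-9)), int(np.floor(hi * n + 1e-9))
            if k_lo <= k_hi:  # an integer ratio inside the region exists
                x = min(max(x, k_lo), k_hi)
        x = min(max(x, 0), int(n))
        cells.append(CellSiteCounts(cell_id=f"cell{j + 1}", edited=x, total=int(n)))
    return cells


def make_bulk(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    cell_rates: np.ndarray | None = None,
) -> BulkSiteCounts:
    """Bulk counts emulating a pooled large population of cells.

    Draws ``bulk_population`` rates from the bulk mixture, forms their mean,
    and reads it at depth ``bulk_reads`` through a binomial draw.  With
    ``bulk_from_cells`` the population mean is replaced by the mean of the J
    simulated cell rates (which must be supplied).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.bulk_from_cells:
        if cell_rates is None:
            raise ValueError("bulk_from_cells requires the simulated cell rates")
        mean_rate = float(np.mean(cell_rates))
    else:
        regions = config.bulk_regions or config.rate_regions
        weights = (
            config.weights
            if config.bulk_regions is None
            else tuple(1.0 / len(regions) for _ in regions)
        )
        pop_rates, _ = _draw_region_rates(regions, weights, config.bulk_population, rng)
        mean_rate = float(np.mean(pop_rates))
    x = int(rng.binomial(config.bulk_reads, mean_rate))
    return BulkSiteCounts(edited=x, total=config.bulk_reads)


def simulate_site(config: ScenarioConfig, seed: int | None = None) -> SiteDataset:
    """Generate one complete SiteDataset (cells + bulk) from a scenario."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    rates, region_idx = sample_cell_rates(config, rng)
    regions = [config.rate_regions[i] for i in region_idx]
    cells = counts_from_rates(rates, config.per_cell_coverage(), regions)
    bulk = make_bulk(config, rng, cell_rates=rates)
    return SiteDataset(
        site=GenomicSite(chrom="sim", pos=1, strand="+"),
        cells=tuple(cells),
        bulk=bulk,
        site_id=config.name,
    )


# ---------------------------------------------------------------------------
# preset catalogue

_HIGH_VAR: tuple[Region, ...] = ((0.0, 0.05), (0.95, 1.0))
_LOW_VAR: tuple[Region, ...] = ((0.45, 0.55),)


def preset_scenarios() -> dict[str, ScenarioConfig | list[ScenarioConfig]]:
    """Named catalogue of the study's simulation designs.

    * ``fig2``: coverage sweep {100, 50, 20, 10} reads/cell at J = 20 cells,
      high-variance rates (0-5% and 95-100%).
    * ``fig3``: cell-number sweep J in {50, 20, 10, 5} at 20 reads/cell,
      high-variance rates.
    * ``fig4_high`` / ``fig4_low``: very high variance vs very low variance
      (rates in 45-55%) at J = 20, coverage 20.
    * ``phys_low`` / ``phys_mid``: physiological uniform ranges 0-20% (bulk
      mean 10%) and 20-50% (bulk mean 35%).
    * ``phys_bimodal_mid``: rates from 5-15% and 40-50% weighted (2/7, 5/7)
      so the mixture (and bulk) mean sits between the regions at 35%.
    * ``phys_bimodal_low``: equal-weight bimodal cells with the bulk drawn
      from the 5-15% region alone, bulk mean 10% (inside the low region).
    """
    base = dict(n_cells=20, coverage=20)
    presets: dict[str, ScenarioConfig | list[ScenarioConfig]] = {
        "fig2": [
            ScenarioConfig(
                name=f"fig2_cov{c}", n_cells=20, coverage=c, rate_regions=_HIGH_VAR
            )
            for c in (100, 50, 20, 10)
        ],
        "fig3": [
            ScenarioConfig(
                name=f"fig3_J{j}", n_cells=j, coverage=20, rate_regions=_HIGH_VAR
            )
            for j in (50, 20, 10, 5)
        ],
        "fig4_high": ScenarioConfig(name="fig4_high", rate_regions=_HIGH_VAR, **base),
        "fig4_low": ScenarioConfig(name="fig4_low", rate_regions=_LOW_VAR, **base),
        "phys_low": ScenarioConfig(
            name="phys_low", rate_regions=((0.0, 0.20),), **base
        ),
        "phys_mid": ScenarioConfig(
            name="phys_mid", rate_regions=((0.20, 0.50),), **base
        ),
        "phys_bimodal_mid": ScenarioConfig(
            name="phys_bimodal_mid",
            rate_regions=((0.05, 0.15), (0.40, 0.50)),
            region_weights=(2.0 / 7.0, 5.0 / 7.0),
            **base,
        ),
        "phys_bimodal_low": ScenarioConfig(
            name="phys_bimodal_low",
            rate_regions=((0.05, 0.15), (0.40, 0.50)),
            bulk_regions=((0.05, 0.15),),
            **base,
        ),
    }
    presets["phys_bimodal"] = presets["phys_bimodal_mid"]
    return presets


def get_preset(name: str, seed: int | None = None) -> list[ScenarioConfig]:
    """Look up a preset by name (hyphens and underscores interchangeable);
    always returns a list of configs, reseeded if ``seed`` is given."""
    key = name.replace("-", "_")
    presets = preset_scenarios()
    if key not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    entry = presets[key]
    configs = entry if isinstance(entry, list) else [entry]
    if seed is not None:
        configs = [replace(c, seed=seed + i) for i, c in enumerate(configs)]
    return configs
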