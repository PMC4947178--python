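"""Count containers and the binomial-beta hierarchy for per-site editing rates.

The unit of inference is a single editable genomic site observed in J single
cells plus one cognate bulk sample.  Each cell j contributes an edited-read
count and a total mapped-read count; the latent per-cell editing rate p_j is
modelled as beta-distributed across cells with mean fixed at the bulk
estimate and unknown variance v.  The beta layer is parametrized by its mean
and variance (not by shape parameters) because the variance v in
[0, m(1-m)] is the scientifically interpretable quantity: v = 0 means every
cell edits at the same rate, v = m(1-m) is the maximal two-point mixture of
never- and always-edited cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import betaln, gammaln


class DegenerateBetaError(ValueError):
    """Raised when v = 0: the beta layer collapses to a point mass at the mean.

    Shape parameters diverge in this limit, so callers must branch explicitly
    instead of receiving (alpha, beta).
    """


@dataclass(frozen=True)
class CellSiteCounts:
    """Edited / total read counts for one cell at one site."""

    cell_id: str
    edited: int
    total: int

    def __post_init__(self) -> None:
        if not (isinstance(self.edited, (int, np.integer)) and isinstance(self.total, (int, np.integer))):
            raise TypeError("read counts must be integers")
        if self.total < 0:
            raise ValueError(f"cell {self.cell_id}: total reads {self.total} < 0")
        if not 0 <= self.edited <= self.total:
            raise ValueError(
                f"cell {self.cell_id}: edited reads {self.edited} outside [0, {self.total}]"
            )


@dataclass(frozen=True)
class BulkSiteCounts:
    """Edited / total read counts for the bulk sample at one site."""

    edited: int
    total: int

    def __post_init__(self) -> None:
        if not (isinstance(self.edited, (int, np.integer)) and isinstance(self.total, (int, np.integer))):
            raise TypeError("read counts must be integers")
        if self.total < 1:
            raise ValueError("bulk total reads must be >= 1")
        if not 0 <= self.edited <= self.total:
            raise ValueError(f"bulk edited reads {self.edited} outside [0, {self.total}]")


@dataclass(frozen=True)
class GenomicSite:
    chrom: str
    pos: int  # 1-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("site position is 1-based and must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class SiteDataset:
    """All observations for one site: J per-cell count pairs plus the bulk pair."""

    site: GenomicSite
    cells: tuple[CellSiteCounts, ...]
    bulk: BulkSiteCounts
    site_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        if len(self.cells) < 1:
            raise ValueError("a SiteDataset needs at least one cell (J >= 1)")
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique within a site")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def label(self) -> str:
        return self.site_id if self.site_id is not None else self.site.label


@dataclass(frozen=True)
class BetaMeanVar:
    """Beta distribution in the mean/variance parametrization.

    Valid for 0 < mean < 1 and 0 <= var <= mean*(1-mean).  The upper bound is
    a formal boundary (the two-point mixture); it is constructible here so
    that e.g. KL computations can reference it, but it is not a usable beta
    density and shape conversion rejects it.
    """

    mean: float
    var: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError(f"beta mean must lie strictly in (0, 1), got {self.mean}")
        bound = self.mean * (1.0 - self.mean)
        if not 0.0 <= self.var <= bound:
            raise ValueError(
                f"beta variance {self.var} outside [0, m(1-m)] = [0, {bound}]"
            )

    @property
    def var_max(self) -> float:
        return self.mean * (1.0 - self.mean)

    @property
    def is_degenerate(self) -> bool:
        return self.var == 0.0


class BulkRate(NamedTuple):
    """Bulk editing-rate estimate with a flag for boundary (0 or 1) results."""

    value: float
    degenerate: bool

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


def bulk_mean(bulk: BulkSiteCounts) -> BulkRate:
    """Standard mean estimator x/n of the bulk editing rate.

    The bulk sample pools at least ~1e5 cells, so its empirical rate is an
    accurate estimate of the population mean editing rate.  Results of
    exactly 0 or 1 are flagged degenerate: they cannot serve directly as a
    beta mean (see :func:`effective_bulk_mean`).
    """
    if bulk.total == 0:
        raise ValueError("bulk mean undefined for zero total reads")
    rate = bulk.edited / bulk.total
    return BulkRate(rate, degenerate=(bulk.edited == 0 or bulk.edited == bulk.total))


def effective_bulk_mean(bulk: BulkSiteCounts) -> float:
    """Bulk mean clamped into (0, 1) for use as a beta-layer mean.

    Degenerate estimates 0 and 1 are moved to eps and 1-eps with
    eps = 1/(2n): half a read at the observed depth, i.e. the resolution of
    the data itself.
    """
    rate, degenerate = bulk_mean(bulk)
    if not degenerate:
        return rate
    eps = 1.0 / (2.0 * bulk.total)
    return min(max(rate, eps), 1.0 - eps)


def beta_params_from_mean_var(mv: BetaMeanVar) -> tuple[float, float]:
    """Convert (mean, variance) to beta shape parameters (alpha, beta).

    With s = m(1-m)/v - 1: alpha = m*s, beta = (1-m)*s.  Requires
    0 < v < m(1-m); v = 0 signals the degenerate point mass instead.
    """
    if mv.var == 0.0:
        raise DegenerateBetaError("v = 0 is a point mass at the mean; no beta shapes exist")
    # reject the formal boundary up to float rounding of m(1-m)
    if mv.var >= mv.var_max * (1.0 - 1e-12):
        raise ValueError(
            f"variance {mv.var} must be strictly below m(1-m) = {mv.var_max}"
        )
    s = mv.mean * (1.0 - mv.mean) / mv.var - 1.0
    return mv.mean * s, (1.0 - mv.mean) * s


def beta_binomial_logpmf(
    x: int | np.ndarray, n: int, mv: BetaMeanVar
) -> float | np.ndarray:
    """Log-pmf of x edited reads out of n when the rate is Beta(mean m, var v).

    Computed in log space through log-gamma functions so that coverages of
    hundreds of reads do not underflow.  v = 0 falls back to Binomial(n, m).
    """
    xs = np.asarray(x)
    if np.any((xs < 0) | (xs > n)):
        raise ValueError("x must lie in 0..n")
    choose = gammaln(n + 1) - gammaln(xs + 1) - gammaln(n - xs + 1)
    # below ~1e-10 of the admissible range the beta shapes are so large that
    # log-gamma differences lose precision; the binomial limit is exact to
    # O(n^2 v), far below that noise floor
    if mv.var < mv.var_max * 1e-10:
        mv = BetaMeanVar(mv.mean, 0.0)
    if mv.is_degenerate:
        out = choose + xs * np.log(mv.mean) + (n - xs) * np.log1p(-mv.mean)
    else:
        a, b = beta_params_from_mean_var(mv)
        out = choose + betaln(xs + a, n - xs + b) - betaln(a, b)
    return out if out.shape else float(out)


def beta_binomial_pmf(
    x: int | np.ndarray, n: int, mv: BetaMeanVar
) -> float | np.ndarray:
    """Probability of x edited reads out of n under the beta-binomial marginal."""
    return np.exp(beta_binomial_logpmf(x, n, mv))
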