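"""Penalized-complexity (PC) prior on the between-cell editing-rate variance v.

The base model is v = 0 (all cells edit at the same rate); the flexible
model has v > 0.  Complexity is measured as the distance
d(v) = sqrt(2 * KL(flexible(v) || base)) and an exponential distribution is
placed on d, shrinking towards the base model.  The single interpretable
tuning knob is the tail condition P[v > v_L] = tail_alpha, which fixes the
exponential rate lambda.

Two numerical choices matter here:

* The KL divergence is evaluated between the *marginal* read-count
  distributions at a reference coverage ``n_ref`` (beta-binomial vs
  binomial), as an exact finite sum over x = 0..n_ref.  At the latent level
  (beta density vs point mass) the divergence is infinite, so the marginal
  level is the natural observable-scale choice; n_ref defaults to 20 reads,
  the recommended per-cell coverage, and can be set per site (e.g. to the
  median observed coverage).
* Because v lives on the bounded interval [0, p(1-p)], d is bounded by
  d_max = d(v_max) and the exponential on d is truncated and renormalized to
  [0, d_max]; otherwise the induced prior on v would not integrate to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from scipy.special import betaln, gammaln

from .model import BetaMeanVar, beta_binomial_logpmf

_BOUNDARY_FRAC = 1.0 - 1e-12


def kl_flexible_vs_base(v: float, p: float, n_ref: int) -> float:
    """KL divergence (nats) of BetaBinomial(n_ref, p, v) from Binomial(n_ref, p).

    Exact finite sum over x = 0..n_ref.  KL(0) = 0.  At the boundary
    v = p(1-p) the beta layer degenerates to the two-point mixture
    (1-p) at x=0 and p at x=n_ref, for which the sum has a closed form.
    """
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    v_max = p * (1.0 - p)
    if not 0.0 <= v <= v_max:
        raise ValueError(f"v = {v} outside [0, v_max = {v_max}]")
    if v == 0.0:
        return 0.0
    xs = np.arange(n_ref + 1)
    base_lp = beta_binomial_logpmf(xs, n_ref, BetaMeanVar(p, 0.0))
    if v >= v_max * _BOUNDARY_FRAC:
        # two-point mixture: mass 1-p at x=0, p at x=n_ref
        return float(
            (1.0 - p) * (np.log1p(-p) - base_lp[0]) + p * (np.log(p) - base_lp[-1])
        )
    flex_lp = beta_binomial_logpmf(xs, n_ref, BetaMeanVar(p, v))
    return float(np.sum(np.exp(flex_lp) * (flex_lp - base_lp)))


@dataclass
class PCPrior:
    """PC prior spec for the editing-rate variance at one site.

    Parameters
    ----------
    p : bulk mean editing rate (fixed at the bulk estimator).
    n_ref : reference coverage (reads) at which the KL is evaluated.
    v_l : calibration threshold on the variance scale; the default 0.142 is
        the conservative little-variability prior used throughout.
    tail_alpha : prior mass allowed above v_l (default 0.01).
    """

    p: float = 0.5
    n_ref: int = 20
    v_l: float = 0.142
    tail_alpha: float = 0.01
    lam: float | None = field(default=None, repr=False)
    _xs: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)
    _choose: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)
    _base_lp: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)
    _d_max: float | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.tail_alpha < 1.0:
            raise ValueError("tail_alpha must lie in (0, 1)")
        if not 0.0 < self.v_l < self.v_max:
            raise ValueError(
                f"v_l = {self.v_l} must lie strictly inside (0, v_max = {self.v_max})"
            )

    @property
    def v_max(self) -> float:
        return self.p * (1.0 - self.p)

    @property
    def d_max(self) -> float:
        if self._d_max is None:
            self._d_max = self.distance(self.v_max)
        return self._d_max

    @property
    def calibrated(self) -> bool:
        return self.lam is not None

    # -- distance ---------------------------------------------------------

    def _tables(self):
        # cached per-prior: support, binomial coefficients, base log-pmf
        if self._xs is None:
            self._xs = np.arange(self.n_ref + 1, dtype=float)
            self._choose = (
                gammaln(self.n_ref + 1)
                - gammaln(self._xs + 1)
                - gammaln(self.n_ref - self._xs + 1)
            )
            self._base_lp = (
                self._choose
                + self._xs * np.log(self.p)
                + (self.n_ref - self._xs) * np.log1p(-self.p)
            )
        return self._xs, self._choose, self._base_lp

    def kl(self, v: float) -> float:
        """As :func:`kl_flexible_vs_base` with per-prior cached tables (the
        sampler evaluates this in its innermost loop)."""
        v_max = self.v_max
        if not 0.0 <= v <= v_max:
            raise ValueError(f"v = {v} outside [0, v_max = {v_max}]")
        if v == 0.0:
            return 0.0
        xs, choose, base_lp = self._tables()
        p, n = self.p, self.n_ref
        if v >= v_max * _BOUNDARY_FRAC:
            return float(
                (1.0 - p) * (np.log1p(-p) - base_lp[0]) + p * (np.log(p) - base_lp[-1])
            )
        s = v_max / v - 1.0
        a, b = p * s, (1.0 - p) * s
        flex_lp = choose + betaln(xs + a, n - xs + b) - betaln(a, b)
        w = np.exp(flex_lp)
        return float(np.dot(w, flex_lp - base_lp))

    def distance(self, v: float) -> float:
        """d(v) = sqrt(2 KL(v)); zero at the base model, nondecreasing in v."""
        return float(np.sqrt(2.0 * max(self.kl(v), 0.0)))

    def _distance_slope(self, v: float) -> float:
        # central finite difference; step shrinks near either boundary
        h = min(1e-5, v / 10.0, (self.v_max - v) / 10.0)
        if h <= 0.0:
            raise ValueError("cannot differentiate d at the boundary of [0, v_max]")
        slope = (self.distance(v + h) - self.distance(v - h)) / (2.0 * h)
        return max(slope, 1e-300)

    # -- calibration ------------------------------------------------------

    def calibrate(self) -> "PCPrior":
        """Solve for lambda such that P[v > v_l] = tail_alpha.

        Under the exponential truncated to d in [0, d_max] the tail mass is
        (exp(-lam*d_l) - exp(-lam*d_max)) / (1 - exp(-lam*d_max)); solved by
        1-D root finding.  Reduces to lam = -ln(alpha)/d(v_l) when the
        truncation mass is negligible.
        """
        d_l = self.distance(self.v_l)
        d_hi = self.d_max
        if d_l <= 0.0 or d_hi <= d_l:
            raise RuntimeError(
                f"PC-prior calibration failed: d(v_l) = {d_l}, d_max = {d_hi}"
            )
        # lam -> 0 limit of the tail mass is (d_max - d_l)/d_max
        if self.tail_alpha >= (d_hi - d_l) / d_hi:
            raise RuntimeError(
                "PC-prior calibration failed: no exponential rate can push the "
                f"tail mass down to {self.tail_alpha} (d(v_l) = {d_l}, d_max = {d_hi})"
            )

        def tail(lam: float) -> float:
            e_l = np.exp(-lam * d_l)
            e_m = np.exp(-lam * d_hi)
            return (e_l - e_m) / (1.0 - e_m) - self.tail_alpha

        lo, hi = 1e-10, 1.0
        while tail(hi) > 0.0:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - defensive
                raise RuntimeError("PC-prior calibration failed: no root below 1e12")
        self.lam = float(brentq(tail, lo, hi, xtol=1e-12, rtol=1e-12))
        return self

    # -- induced density on v ---------------------------------------------

    def log_density(self, v: float) -> float:
        """Log of the induced prior density at v (per unit variance)."""
        if not self.calibrated:
            raise RuntimeError("PCPrior must be calibrated before evaluating its density")
        if not 0.0 < v < self.v_max:
            return -np.inf
        lam = self.lam
        log_norm = np.log1p(-np.exp(-lam * self.d_max))
        return float(
            np.log(lam)
            - lam * self.distance(v)
            + np.log(self._distance_slope(v))
            - log_norm
        )

    def density(self, v: float) -> float:
        """Induced prior density f(v) = lam*exp(-lam*d(v))*d'(v) / normalizer."""
        return float(np.exp(self.log_density(v)))

    def tail_mass(self, v_from: float | None = None) -> float:
        """Numerically integrated prior mass above ``v_from`` (default v_l)."""
        lo = self.v_l if v_from is None else v_from
        mass, _ = quad(self.density, lo, self.v_max, limit=200)
        return float(mass)
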