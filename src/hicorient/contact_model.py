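"""Estimation of the Hi-C contact probability vs distance curve p(d).

The contact frequency between two loci decays with their one-dimensional
separation d.  Because the decay differs between samples, p(d) is estimated
de novo from the intra-contig contacts of the longest contig:

1. kernel density estimation of log10(d) (Gaussian kernel, Silverman
   bandwidth by default; log scale handles the heavy tail);
2. least-squares fit of the base function ``p(d) = c1 * d^(-c2)`` (i.e.
   ``log p = log c1 - c2 log d``) on [short_cutoff, K];
3. below ``short_cutoff`` (default 3 kb) a low-order polynomial in log d
   captures the non-monotone rise-and-fall observed at short range;
4. beyond the tail threshold K the curve is the constant p(K), modelling
   random contacts whose frequency no longer carries distance information;
5. the curve is renormalized to integrate to 1 over [d_min, d_cap].

K is chosen automatically as the third quantile of the observed contact
separation distances unless overridden.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import integrate, stats

from .core import ContactStore, ScaffoldLayout

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DistributionConfig:
    """Tunables of the p(d) estimation pipeline.

    bandwidth: KDE bandwidth rule or scalar factor (passed to
        ``scipy.stats.gaussian_kde``); 'silverman' by default.
    short_cutoff: boundary (bp) between the polynomial short-range segment
        and the power-law segment.
    poly_degree: degree of the short-range polynomial in log d.
    min_contacts: below this many source distances a warning is logged.
    n_grid: number of (log-spaced) grid points stored on [d_min, d_cap].
    d_cap_factor: d_cap = d_cap_factor * K; evaluation beyond d_cap returns
        the constant tail, so unbounded support is unnecessary.
    """

    bandwidth: str | float = "silverman"
    short_cutoff: float = 3_000.0
    poly_degree: int = 3
    min_contacts: int = 1_000
    n_grid: int = 512
    d_cap_factor: float = 10.0


def select_K(distances: Sequence[float] | np.ndarray, quantile: float = 0.75) -> float:
    """Tail threshold K: an empirical quantile of contact separation distances.

    Uses the linear-interpolation quantile definition (numpy's default).
    The third quantile of the separation-distance histogram is the
    automatic rule; an explicit K from configuration takes precedence at
    the pipeline level.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("cannot select K from an empty distance set")
    return float(np.quantile(distances, quantile))


@dataclasses.dataclass
class ContactDistribution:
    """The estimated log p(d) curve.

    Piecewise form: polynomial in ln d below ``short_cutoff``, the power-law
    fit ``log c1 - c2 ln d`` on [short_cutoff, K], and the constant
    ``log_p_tail = log p(K)`` for d > K.  Continuity at the junctions is
    enforced by vertical offset matching.  ``grid``/``log_p`` store the
    final curve on a log-spaced grid for dumping and interpolation-based
    fallback evaluation.
    """

    grid: np.ndarray
    log_p: np.ndarray
    K: float
    log_p_tail: float
    c1: float
    c2: float
    short_range_poly: np.ndarray  # ascending coefficients in ln d
    short_cutoff: float
    d_min: float
    d_cap: float
    n_source_contacts: int
    used_fallback: bool = False

    @property
    def log_c1(self) -> float:
        return math.log(self.c1)

    @property
    def breakpoints(self) -> list[float]:
        """Junction points of the piecewise curve (for quadrature)."""
        pts = [self.d_min, self.short_cutoff, self.K, self.d_cap]
        return sorted({p for p in pts if self.d_min <= p <= self.d_cap})

    def logp(self, d):
        """Vectorized log-density evaluation; d below d_min is clamped."""
        scalar = np.isscalar(d)
        d = np.atleast_1d(np.asarray(d, dtype=float))
        d = np.clip(d, self.d_min, None)
        out = np.empty_like(d)
        if self.used_fallback:
            ln_d = np.log(d)
            ln_grid = np.log(self.grid)
            out = np.interp(ln_d, ln_grid, self.log_p)
            out[d > self.K] = self.log_p_tail
        else:
            ln_d = np.log(d)
            short = d < self.short_cutoff
            tail = d > self.K
            mid = ~(short | tail)
            if short.any():
                out[short] = npoly.polyval(ln_d[short], self.short_range_poly)
            out[mid] = self.log_c1 - self.c2 * ln_d[mid]
            out[tail] = self.log_p_tail
        return float(out[0]) if scalar else out


def evaluate_logp(dist: ContactDistribution, d) -> np.ndarray | float:
    """Evaluate the fitted log p(d) curve (piecewise, constant beyond K)."""
    return dist.logp(d)


def estimate_distribution(
    intra_distances: Sequence[float] | np.ndarray,
    K: float,
    config: DistributionConfig | None = None,
) -> ContactDistribution:
    """Fit the contact distance-decay curve from intra-contig distances.

    The caller selects which contig the distances come from (the longest
    contig is the standard choice: it observes the decay over the widest
    distance range).
    """
    cfg = config or DistributionConfig()
    d = np.asarray(intra_distances, dtype=float)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("no positive intra-contig distances")
    if float(d.min()) == float(d.max()):
        raise ValueError("degenerate distances: all values identical")
    if d.size < cfg.min_contacts:
        logger.warning(
            "only %d intra-contig distances (< %d); the fitted curve may be noisy",
            d.size, cfg.min_contacts,
        )

    d_min = max(1.0, float(d.min()))
    d_cap = cfg.d_cap_factor * K
    if d_cap <= d_min:
        raise ValueError(f"d_cap={d_cap} <= d_min={d_min}; K too small for the data")
    grid = np.geomspace(d_min, d_cap, cfg.n_grid)

    # KDE in log10-distance; back-transform to a density in d:
    # p_d(d) = p_u(log10 d) / (d ln 10).
    kde = stats.gaussian_kde(np.log10(d), bw_method=cfg.bandwidth)

    def kde_logp(dd: np.ndarray) -> np.ndarray:
        dens = np.maximum(kde(np.log10(dd)), 1e-300)
        return np.log(dens) - np.log(dd) - math.log(math.log(10.0))

    # power-law fit log p = log c1 - c2 log d on [short_cutoff, K]
    fit_lo = max(d_min, cfg.short_cutoff)
    fit_hi = min(K, d_cap)
    if fit_hi <= fit_lo:
        raise ValueError(
            f"empty power-law fit range [{fit_lo}, {fit_hi}]; "
            "check short_cutoff and K"
        )
    fit_d = np.geomspace(fit_lo, fit_hi, 200)
    fit_y = kde_logp(fit_d)
    slope, intercept = np.polyfit(np.log(fit_d), fit_y, 1)
    c2 = -float(slope)
    log_c1 = float(intercept)

    if c2 <= 0:
        logger.warning(
            "fitted decay exponent c2=%.3f <= 0; falling back to the raw KDE curve",
            c2,
        )
        return _fallback_distribution(kde_logp, grid, K, d_min, d_cap, c2, d.size,
                                      cfg)

    # short-range polynomial in ln d, shifted to join the power law at the
    # cutoff
    if d_min < cfg.short_cutoff:
        sr_d = np.geomspace(d_min, cfg.short_cutoff, 100)
        sr_y = kde_logp(sr_d)
        deg = min(cfg.poly_degree, max(1, sr_d.size - 1))
        poly = np.polynomial.Polynomial.fit(np.log(sr_d), sr_y, deg).convert().coef
        shift = (log_c1 - c2 * math.log(cfg.short_cutoff)) - npoly.polyval(
            math.log(cfg.short_cutoff), poly
        )
        poly = poly.copy()
        poly[0] += shift
        short_cutoff = float(cfg.short_cutoff)
    else:
        # all data above the cutoff: extend the power law downward
        poly = np.array([log_c1 - c2 * math.log(d_min)])
        short_cutoff = d_min

    log_p_tail = log_c1 - c2 * math.log(K)

    dist = ContactDistribution(
        grid=grid,
        log_p=np.zeros_like(grid),
        K=float(K),
        log_p_tail=log_p_tail,
        c1=math.exp(log_c1),
        c2=c2,
        short_range_poly=poly,
        short_cutoff=short_cutoff,
        d_min=d_min,
        d_cap=d_cap,
        n_source_contacts=int(d.size),
    )
    _normalize(dist)
    return dist


def _fallback_distribution(kde_logp, grid, K, d_min, d_cap, c2, n_source, cfg):
    log_p = kde_logp(np.minimum(grid, K))
    tail_val = float(kde_logp(np.array([min(K, grid[-1])]))[0])
    log_p[grid > K] = tail_val
    dist = ContactDistribution(
        grid=grid,
        log_p=log_p,
        K=float(K),
        log_p_tail=tail_val,
        c1=1.0,
        c2=c2,
        short_range_poly=np.array([0.0]),
        short_cutoff=float(min(cfg.short_cutoff, K)),
        d_min=d_min,
        d_cap=d_cap,
        n_source_contacts=int(n_source),
        used_fallback=True,
    )
    _normalize(dist)
    return dist


def _normalize(dist: ContactDistribution) -> None:
    """Shift the curve so exp(log_p) integrates to 1 over [d_min, d_cap].

    The pairwise normalization factor Z_ij is identical across orientation
    cases, so a global constant cancels in every likelihood-ratio decision;
    normalizing anyway makes reported absolute log-likelihoods reproducible.
    """
    log_shift = math.log(_integral(dist))
    dist.log_p_tail -= log_shift
    if dist.used_fallback:
        dist.log_p -= log_shift
    else:
        dist.c1 = math.exp(dist.log_c1 - log_shift)
        dist.short_range_poly = dist.short_range_poly.copy()
        dist.short_range_poly[0] -= log_shift
        dist.log_p = dist.logp(dist.grid)


def _integral(dist: ContactDistribution) -> float:
    if dist.used_fallback:
        fine = np.geomspace(dist.d_min, dist.d_cap, 20_000)
        return float(np.trapezoid(np.exp(dist.logp(fine)), fine))
    total = 0.0
    # short-range segment by quadrature
    if dist.d_min < dist.short_cutoff:
        val, _ = integrate.quad(
            lambda u: math.exp(npoly.polyval(math.log(u), dist.short_range_poly)),
            dist.d_min, dist.short_cutoff, limit=200,
        )
        total += val
    # power-law segment analytically
    lo, hi = max(dist.d_min, dist.short_cutoff), min(dist.K, dist.d_cap)
    if hi > lo:
        if abs(dist.c2 - 1.0) < 1e-12:
            total += dist.c1 * math.log(hi / lo)
        else:
            e = 1.0 - dist.c2
            total += dist.c1 / e * (hi**e - lo**e)
    # constant tail
    if dist.d_cap > dist.K:
        total += math.exp(dist.log_p_tail) * (dist.d_cap - dist.K)
    return total


def power_law_distribution(
    c2: float,
    K: float,
    d_min: float = 1_000.0,
    d_cap: float | None = None,
) -> ContactDistribution:
    """An analytic pure power-law curve with constant tail beyond K.

    Useful as a known-truth scoring distribution in simulations and small
    worked examples; it has no short-range polynomial segment.
    """
    if c2 <= 0:
        raise ValueError("c2 must be positive")
    d_cap = 10.0 * K if d_cap is None else d_cap
    grid = np.geomspace(d_min, d_cap, 256)
    dist = ContactDistribution(
        grid=grid,
        log_p=np.zeros_like(grid),
        K=float(K),
        log_p_tail=-c2 * math.log(K),
        c1=1.0,
        c2=float(c2),
        short_range_poly=np.array([-c2 * math.log(d_min)]),
        short_cutoff=float(d_min),
        d_min=float(d_min),
        d_cap=float(d_cap),
        n_source_contacts=0,
    )
    _normalize(dist)
    return dist


def fit_contact_model(
    store: ContactStore,
    layout: ScaffoldLayout,
    K: float | None = None,
    config: DistributionConfig | None = None,
) -> ContactDistribution:
    """Standard pipeline step: K from pooled separations, p(d) from the
    longest contig's intra-contig contacts.

    Precedence for K: an explicit argument overrides the automatic
    third-quantile rule.
    """
    pooled = store.pooled_intra()
    if pooled.size == 0:
        raise ValueError("no intra-contig contacts; cannot estimate p(d)")
    if K is None:
        K = select_K(pooled)
    candidates = [
        (layout.contig(name).length, name)
        for name in store.intra
        if layout.locate(name) is not None
    ]
    if not candidates:
        raise ValueError("no intra-contig contacts on contigs present in the layout")
    _, best = max(candidates)
    logger.info("estimating p(d) from contig %s with K=%.0f", best, K)
    return estimate_distribution(store.intra[best], K, config)


def compare_top_contigs(
    store: ContactStore,
    layout: ScaffoldLayout,
    top_n: int = 3,
    K: float | None = None,
    config: DistributionConfig | None = None,
) -> tuple[list[tuple[str, ContactDistribution]], float]:
    """Consistency diagnostic: fit p(d) per contig for the longest contigs.

    Returns the per-contig curves and the maximum absolute difference
    between their renormalized log-curves on a common grid over
    [short_cutoff, K].  A small statistic indicates that the single-contig
    estimate is representative.
    """
    cfg = config or DistributionConfig()
    pooled = store.pooled_intra()
    if K is None:
        K = select_K(pooled)
    eligible = sorted(
        (
            (layout.contig(name).length, name)
            for name in store.intra
            if layout.locate(name) is not None
            and store.intra[name].size >= cfg.min_contacts
        ),
        reverse=True,
    )
    if len(eligible) < top_n:
        logger.warning(
            "only %d contigs have >= %d intra contacts (requested %d)",
            len(eligible), cfg.min_contacts, top_n,
        )
    chosen = eligible[:top_n]
    fits = [(name, estimate_distribution(store.intra[name], K, cfg)) for _, name in chosen]
    if len(fits) < 2:
        return fits, 0.0

    lo = max(max(f.d_min, f.short_cutoff) for _, f in fits)
    hi = min(f.K for _, f in fits)
    common = np.geomspace(lo, hi, 200)
    curves = []
    for _, f in fits:
        vals = f.logp(common)
        # renormalize over the comparison range so only shape is compared
        norm = np.log(np.trapezoid(np.exp(vals), common))
        curves.append(vals - norm)
    stat = 0.0
    for a in range(len(curves)):
        for b in range(a + 1, len(curves)):
            stat = max(stat, float(np.max(np.abs(curves[a] - curves[b]))))
    return fits, stat


def dump_distribution_tsv(dist: ContactDistribution, path) -> None:
    """Write the fitted (grid, log_p) curve as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("distance_bp\tlog_p\n")
        for d, lp in zip(dist.grid, dist.log_p):
            fh.write(f"{d:.3f}\t{lp:.8f}\n")
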