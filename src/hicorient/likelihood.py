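"""Orientation-conditional likelihood of Hi-C contacts between two contigs.

For a contact r = (x, y) between the i-th and j-th contigs of a scaffold
(native offsets), the separation distance implied by orientations
(theta_i, theta_j) is

    d = (x if theta_i == '-' else L_i - x) + D + (y if theta_j == '+' else L_j - y)

where D is the total length of contigs strictly between i and j (no-gap
assumption).  Geometrically: with theta_i = '+' the contig's native end L_i
faces contig j, and with theta_j = '+' contig j's native start 0 faces
contig i.  The contact probability is p(d) / Z_ij with a normalization
integral Z_ij over the two contigs' coordinate rectangle; Z_ij is
*identical* across the four orientation cases (substituting x -> L_i - x
and/or y -> L_j - y leaves the integral unchanged), so Z cancels in every
orientation decision.  Contacts are conditionally independent given the
orientations, so set log-likelihoods are sums; all arithmetic is carried
out in natural-log space because contact sets can hold thousands of reads.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import integrate

from .core import FORWARD, REVERSE, ContactStore, ScaffoldLayout
from .contact_model import ContactDistribution

LOG_HALF = math.log(0.5)


@dataclasses.dataclass(frozen=True)
class PairGeometry:
    """Lengths of two contigs and the intervening length D between them."""

    Li: int
    Lj: int
    D: int

    def __post_init__(self) -> None:
        if self.Li < 1 or self.Lj < 1:
            raise ValueError("contig lengths must be >= 1")
        if self.D < 0:
            raise ValueError("intervening length D must be >= 0")


@dataclasses.dataclass
class PairLikelihood:
    """Four-case summed log-likelihood of a contact set R_ij.

    ``log_like[a, b]`` is the value for (theta_i, theta_j) = (a, b) with
    0 = '+' and 1 = '-'.  ``logZ`` is the (orientation-invariant)
    normalization constant, computed only when requested.
    """

    log_like: np.ndarray
    n_contacts: int
    logZ: float | None = None


def contact_distance(x, y, theta_i: int, theta_j: int, geom: PairGeometry):
    """Separation distance of contact offsets under an orientation case.

    Vectorized over ``x``/``y``; accepts scalars too.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    left = x if theta_i == REVERSE else geom.Li - x
    right = y if theta_j == FORWARD else geom.Lj - y
    return left + geom.D + right


def normalization_Z(geom: PairGeometry, dist) -> float:
    """log of the pair normalization integral Z_ij.

    The double integral of p over the coordinate rectangle reduces to the
    1-D form  ``Z = \\int p(u) * overlap(u) du``  over u in
    [D, D + Li + Lj], where ``overlap(u) = min(u - D, Li, Lj, Li+Lj+D-u)``
    counts the (x, y) combinations at total separation u.  The same value
    holds for all four orientation cases.  ``dist`` needs a scalar-capable
    ``logp`` method and a ``breakpoints`` sequence for quadrature splitting.
    """
    D, Li, Lj = float(geom.D), float(geom.Li), float(geom.Lj)
    lo, hi = D, D + Li + Lj
    pts = {D + min(Li, Lj), D + max(Li, Lj)}
    for b in getattr(dist, "breakpoints", []):
        if lo < b < hi:
            pts.add(float(b))
    points = sorted(p for p in pts if lo < p < hi)

    def integrand(u: float) -> float:
        ov = min(u - D, Li, Lj, Li + Lj + D - u)
        if ov <= 0:
            return 0.0
        return math.exp(dist.logp(u)) * ov

    val, _ = integrate.quad(integrand, lo, hi, points=points or None, limit=500)
    if not np.isfinite(val) or val <= 0:
        raise ValueError(f"non-finite or non-positive normalization integral: {val}")
    return math.log(val)


def normalization_Z_four_cases(
    geom: PairGeometry, dist, n_nodes: int = 96
) -> np.ndarray:
    """The four orientation-case Z integrals, each by direct 2-D quadrature.

    A diagnostic/validation companion to :func:`normalization_Z`: each case
    integrates its own integrand expression from the four-case contact
    probability over the (x, y) rectangle with a tensor Gauss-Legendre rule,
    so their numerical agreement checks the orientation-invariance of Z
    rather than assuming it.  Returns the four Z values (linear scale) in
    case order [(-,+), (-,-), (+,+), (+,-)].
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    x = 0.5 * geom.Li * (nodes + 1.0)
    wx = 0.5 * geom.Li * weights
    y = 0.5 * geom.Lj * (nodes + 1.0)
    wy = 0.5 * geom.Lj * weights
    X = x[:, None]
    Y = y[None, :]
    W = wx[:, None] * wy[None, :]
    out = []
    for ti, tj in ((REVERSE, FORWARD), (REVERSE, REVERSE), (FORWARD, FORWARD), (FORWARD, REVERSE)):
        d = contact_distance(X, Y, ti, tj, geom)
        out.append(float(np.sum(np.exp(dist.logp(d.ravel())).reshape(d.shape) * W)))
    return np.array(out)


def pair_log_likelihood(
    contacts: np.ndarray,
    geom: PairGeometry,
    dist,
    include_Z: bool = False,
) -> PairLikelihood:
    """Summed log-likelihood of a contact set for all four orientation cases.

    ``contacts`` is an (m, 2) array of (x, y) offsets; an empty set yields
    zeros for every case (the empty product).  With ``include_Z`` the
    orientation-invariant term ``m * logZ`` is subtracted from every case;
    because it is constant across cases it cannot change any decision, and
    it defaults off for decoding.
    """
    contacts = np.asarray(contacts, dtype=np.int64).reshape(-1, 2)
    m = contacts.shape[0]
    table = np.zeros((2, 2))
    logZ = None
    if m > 0:
        x = contacts[:, 0]
        y = contacts[:, 1]
        for ti in (FORWARD, REVERSE):
            for tj in (FORWARD, REVERSE):
                d = contact_distance(x, y, ti, tj, geom)
                table[ti, tj] = float(np.sum(dist.logp(d)))
        if include_Z:
            logZ = normalization_Z(geom, dist)
            table -= m * logZ
    elif include_Z:
        logZ = normalization_Z(geom, dist)
    return PairLikelihood(log_like=table, n_contacts=m, logZ=logZ)


def in_range_pairs(layout: ScaffoldLayout, K: float):
    """Yield ``(scaffold_index, i, j, PairGeometry)`` for pairs with
    intervening length < K (the orientation-informative pairs)."""
    for si, scaf in enumerate(layout.scaffolds):
        lengths = scaf.lengths
        prefix = np.concatenate([[0], np.cumsum(lengths)])
        n = scaf.n
        for i in range(n):
            for j in range(i + 1, n):
                D = int(prefix[j] - prefix[i + 1])
                if D >= K:
                    break
                yield si, i, j, PairGeometry(int(lengths[i]), int(lengths[j]), D)


def joint_log_probability(
    layout: ScaffoldLayout,
    store: ContactStore,
    dist,
    orientations: np.ndarray | Sequence[int],
    K: float | None = None,
    include_Z: bool = False,
) -> float:
    """log P(R, Theta): summed pair log-likelihoods over pairs with
    intervening length < K, plus the uniform prior n * log(1/2).

    Used for diagnostics and as the objective of the brute-force decoder;
    the HMM decoder maximizes exactly this quantity.
    """
    K = dist.K if K is None else K
    theta = layout.split_vector(np.asarray(orientations, dtype=np.uint8))
    terms = []
    for si, i, j, geom in in_range_pairs(layout, K):
        contacts = store.pair(si, i, j)
        if contacts.shape[0] == 0 and not include_Z:
            continue
        pl = pair_log_likelihood(contacts, geom, dist, include_Z=include_Z)
        terms.append(pl.log_like[theta[si][i], theta[si][j]])
    return math.fsum(terms) + layout.n_contigs * LOG_HALF
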