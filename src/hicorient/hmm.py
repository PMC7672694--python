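"""Orientation decoding with a hidden Markov model over contig windows.

Hidden state S_t assigns orientations to a window of neighboring contigs;
consecutive windows overlap in all shared contigs and each new window
introduces exactly one new contig.  The observation attached to a window is
the set of contact sets R_ij it newly covers, and the emission probability
is the product of the orientation-conditional pair likelihoods.  Transitions
carry probability 1/2 when the overlapping orientations are consistent and
0 otherwise, so together with the uniform orientation prior the score of a
complete path equals log P(R, Theta) and the Viterbi path is the global
maximum-probability orientation vector.

Window arity is either a fixed k (contacts between contigs with |i-j| < k)
or adaptive: the window ending at contig j reaches back just far enough to
cover every earlier contig whose intervening length to j is below the tail
threshold K — beyond K the contact density is constant, so more distant
pairs carry no orientation information.  Adaptive windows grow over runs of
short contigs (where single-pair evidence is weak) and collapse to arity 2
between long contigs.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math

import numpy as np

from .core import ContactStore, Scaffold, ScaffoldLayout
from .likelihood import (
    LOG_HALF,
    PairGeometry,
    in_range_pairs,
    pair_log_likelihood,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class HMMConfig:
    """Decoder settings.

    K: tail threshold (bp); taken from the fitted distribution when None.
    mode: 'adaptive' (window arity k(j) from K) or 'fixed' (constant k).
    k: window arity for fixed mode (>= 2).
    k_max: hard cap on window arity; adaptive windows over runs of tiny
        contigs are truncated to this with a logged warning, bounding the
        2^k state blow-up.
    tie_break: 'min-flips-lex' — among equal-likelihood decodes prefer the
        one with fewest flips relative to the input, then the
        lexicographically smallest ('+' < '-').
    """

    K: float | None = None
    mode: str = "adaptive"
    k: int | None = None
    k_max: int = 10
    tie_break: str = "min-flips-lex"

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fixed":
            if self.k is None or self.k < 2:
                raise ValueError("fixed mode requires k >= 2")
            if self.k > self.k_max:
                raise ValueError(f"k={self.k} exceeds k_max={self.k_max}")
        if not 2 <= self.k_max <= 16:
            raise ValueError("k_max must be in [2, 16]")


@dataclasses.dataclass
class StateSpace:
    """Windows, observation partition and bookkeeping for one scaffold.

    ``windows[t] = (a, b)`` are inclusive 0-based contig positions;
    ``observations[t]`` lists the contact-set pairs (i, j) scored at t.
    Every orientation-informative pair (intervening length < K) is assigned
    to exactly one observation; pairs dropped by the k_max cap are recorded
    in ``dropped_pairs``.
    """

    n: int
    windows: list[tuple[int, int]]
    observations: list[list[tuple[int, int]]]
    k0: int
    mode: str
    K: float
    dropped_pairs: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    @property
    def arities(self) -> list[int]:
        return [b - a + 1 for a, b in self.windows]

    def arity_of_contig(self, c: int) -> int:
        """Window arity in effect where contig c is decided."""
        a0, b0 = self.windows[0]
        if c <= b0:
            return self.k0
        for (a, b) in self.windows:
            if b == c:
                return b - a + 1
        raise IndexError(c)


def build_state_space(scaffold: Scaffold, config: HMMConfig) -> StateSpace:
    """Construct windows and the observation partition for one scaffold."""
    n = scaffold.n
    if n == 0:
        raise ValueError("scaffold has no contigs")
    lengths = scaffold.lengths
    prefix = np.concatenate([[0], np.cumsum(lengths)])
    K = config.K
    if K is None:
        raise ValueError("HMMConfig.K must be set to build the state space")

    def gap(i: int, j: int) -> int:
        return int(prefix[j] - prefix[i + 1])

    dropped: list[tuple[int, int]] = []

    if n == 1:
        return StateSpace(1, [(0, 0)], [[]], 1, config.mode, K)

    if config.mode == "fixed":
        k = min(config.k, n)
        windows = [(t, t + k - 1) for t in range(n - k + 1)]
        observations: list[list[tuple[int, int]]] = [
            [(i, j) for i in range(k) for j in range(i + 1, k)]
        ]
        for t in range(1, n - k + 1):
            end = t + k - 1
            observations.append([(i, end) for i in range(t, end)])
        return StateSpace(n, windows, observations, k, config.mode, K)

    # adaptive: the window ending at j spans exactly the contigs whose
    # intervening length to j is < K (capped at k_max)
    def window_start(j: int) -> tuple[int, list[tuple[int, int]]]:
        start = 0
        for i in range(j - 1, -1, -1):
            if gap(i, j) >= K:
                start = i + 1
                break
        lost = []
        if j - start + 1 > config.k_max:
            capped = j - config.k_max + 1
            lost = [(i, j) for i in range(start, capped) if gap(i, j) < K]
            start = capped
        return start, lost

    # first window: all contigs still in range of contig 0
    e0 = n - 1
    for e in range(1, n):
        if gap(0, e) >= K:
            e0 = e - 1
            break
    if e0 + 1 > config.k_max:
        e0 = config.k_max - 1
        logger.warning("first adaptive window truncated to k_max=%d", config.k_max)
    windows = [(0, e0)]
    observations = [
        [(i, j) for i in range(e0 + 1) for j in range(i + 1, e0 + 1) if gap(i, j) < K]
    ]
    for j in range(e0 + 1, n):
        start, lost = window_start(j)
        if lost:
            logger.warning(
                "adaptive window at contig %d truncated to k_max=%d; "
                "%d in-range pairs dropped", j, config.k_max, len(lost),
            )
            dropped.extend(lost)
        start = max(start, windows[-1][0])  # keep window starts monotone
        windows.append((start, j))
        observations.append([(i, j) for i in range(start, j) if gap(i, j) < K])
    return StateSpace(n, windows, observations, e0 + 1, config.mode, K, dropped)


def compute_emissions(
    state_space: StateSpace,
    store: ContactStore,
    dist,
    scaffold: Scaffold,
    scaffold_index: int = 0,
    include_Z: bool = False,
) -> list[np.ndarray]:
    """Per-window log-emission tables.

    Table t has 2^arity entries; bit q of the state index is the
    orientation of contig ``a + q`` (0 = '+').  Pairs without contacts
    contribute nothing (the empty product), so a scaffold with no contacts
    has all-zero emissions.
    """
    lengths = scaffold.lengths
    prefix = np.concatenate([[0], np.cumsum(lengths)])
    tables: list[np.ndarray] = []
    for (a, b), obs in zip(state_space.windows, state_space.observations):
        m = b - a + 1
        states = np.arange(2**m)
        table = np.zeros(2**m)
        for i, j in obs:
            contacts = store.pair(scaffold_index, i, j)
            if contacts.shape[0] == 0:
                continue
            geom = PairGeometry(int(lengths[i]), int(lengths[j]),
                                int(prefix[j] - prefix[i + 1]))
            pl = pair_log_likelihood(contacts, geom, dist, include_Z=include_Z)
            bi = (states >> (i - a)) & 1
            bj = (states >> (j - a)) & 1
            table += pl.log_like[bi, bj]
        tables.append(table)
    return tables


@dataclasses.dataclass
class OrientationVector:
    """A decoded orientation assignment for one scaffold."""

    orientations: np.ndarray  # uint8 codes
    flip_mask: np.ndarray  # True where the decode differs from the input
    score: float  # log P(R, Theta) over the scored pairs
    confidence: np.ndarray | None = None
    window_arity: np.ndarray | None = None
    n_contacts: np.ndarray | None = None


def viterbi(
    state_space: StateSpace,
    emissions: list[np.ndarray],
    config: HMMConfig,
    input_orientations: np.ndarray,
) -> OrientationVector:
    """Decode the maximum-probability orientation vector.

    The score of a path is the sum of its emissions plus the constant
    n * log(1/2) from the transition/prior structure (argmax-neutral but
    reported for fidelity to the joint probability).  Ties are resolved by
    the configured policy: fewest flips relative to the input, then
    lexicographic with '+' < '-'; the result is deterministic.
    """
    input_bits = np.asarray(input_orientations, dtype=np.uint8)
    n = state_space.n
    if input_bits.shape[0] != n:
        raise ValueError("input orientation vector length mismatch")
    windows = state_space.windows
    T = len(windows)

    a0, b0 = windows[0]
    m0 = b0 - a0 + 1
    states0 = np.arange(2**m0)
    in0 = 0
    for q in range(m0):
        in0 |= int(input_bits[a0 + q]) << q
    scores = emissions[0] + m0 * LOG_HALF
    flips = np.array([bin(s ^ in0).count("1") for s in states0], dtype=np.int64)
    backptrs: list[np.ndarray | None] = [None]

    def reconstruct(t: int, state: int) -> np.ndarray:
        """Orientations of contigs [0 .. windows[t][1]] along the best path."""
        out = np.zeros(windows[t][1] + 1, dtype=np.uint8)
        cur = state
        for tt in range(t, 0, -1):
            a, b = windows[tt]
            out[b] = (cur >> (b - a)) & 1
            cur = int(backptrs[tt][cur])
        a, b = windows[0]
        for q in range(b + 1):
            out[q] = (cur >> q) & 1
        return out

    def lex_less(t: int, s1: int, s2: int) -> bool:
        v1, v2 = reconstruct(t, s1), reconstruct(t, s2)
        for x1, x2 in zip(v1, v2):
            if x1 != x2:
                return x1 < x2
        return False

    for t in range(1, T):
        a, b = windows[t]
        ap = windows[t - 1][0]
        shift = a - ap
        m = b - a + 1
        n_groups = 2 ** (m - 1)
        best_state = np.full(n_groups, -1, dtype=np.int64)
        best_score = np.full(n_groups, -np.inf)
        best_flips = np.zeros(n_groups, dtype=np.int64)
        for sp in range(scores.shape[0]):
            g = sp >> shift
            sc = scores[sp]
            if best_state[g] < 0 or sc > best_score[g]:
                better = True
            elif sc == best_score[g]:
                if flips[sp] != best_flips[g]:
                    better = flips[sp] < best_flips[g]
                else:
                    better = lex_less(t - 1, sp, int(best_state[g]))
            else:
                better = False
            if better:
                best_state[g] = sp
                best_score[g] = sc
                best_flips[g] = flips[sp]
        new_bit = input_bits[b]
        n_states = 2**m
        new_scores = np.empty(n_states)
        new_flips = np.empty(n_states, dtype=np.int64)
        new_back = np.empty(n_states, dtype=np.int64)
        for s in range(n_states):
            g = s & (n_groups - 1)
            hi = s >> (m - 1)
            new_scores[s] = best_score[g] + emissions[t][s] + LOG_HALF
            new_flips[s] = best_flips[g] + (hi != new_bit)
            new_back[s] = best_state[g]
        scores, flips = new_scores, new_flips
        backptrs.append(new_back)

    best = 0
    for s in range(1, scores.shape[0]):
        if scores[s] > scores[best]:
            best = s
        elif scores[s] == scores[best]:
            if flips[s] != flips[best]:
                if flips[s] < flips[best]:
                    best = s
            elif lex_less(T - 1, s, best):
                best = s

    decoded = reconstruct(T - 1, best)
    return OrientationVector(
        orientations=decoded,
        flip_mask=decoded != input_bits,
        score=float(scores[best]),
    )


def exhaustive_decode(
    layout: ScaffoldLayout,
    store: ContactStore,
    dist,
    K: float | None = None,
    input_orientations: np.ndarray | None = None,
) -> np.ndarray:
    """Brute-force reference decoder for small scaffolds.

    Enumerates all 2^n orientation vectors per scaffold, scores each by the
    joint log-probability over in-range pairs, and applies the same
    fewest-flips-then-lexicographic tie policy as the Viterbi decoder.
    Exponential in n: intended for n <= ~12 validation instances only.
    """
    K = dist.K if K is None else K
    if input_orientations is None:
        input_orientations = layout.all_orientations()
    input_parts = layout.split_vector(np.asarray(input_orientations, dtype=np.uint8))
    decoded_parts = []
    for si, scaf in enumerate(layout.scaffolds):
        n = scaf.n
        tables = []
        for ssi, i, j, geom in in_range_pairs(layout, K):
            if ssi != si:
                continue
            contacts = store.pair(si, i, j)
            if contacts.shape[0] == 0:
                continue
            pl = pair_log_likelihood(contacts, geom, dist)
            tables.append((i, j, pl.log_like))
        inp = input_parts[si]
        best_vec = None
        best_score = -np.inf
        best_flips = -1
        for theta in itertools.product((0, 1), repeat=n):  # lexicographic order
            score = math.fsum(tab[theta[i], theta[j]] for i, j, tab in tables)
            nflips = sum(int(t != o) for t, o in zip(theta, inp))
            if (
                best_vec is None
                or score > best_score
                or (score == best_score and nflips < best_flips)
            ):
                best_vec, best_score, best_flips = theta, score, nflips
        decoded_parts.append(np.array(best_vec, dtype=np.uint8))
    return np.concatenate(decoded_parts)


def refine(
    layout: ScaffoldLayout,
    store: ContactStore,
    dist,
    config: HMMConfig | None = None,
):
    """Decode every super-scaffold and assemble the corrected layout.

    Super-scaffolds are independent decoding problems (no cross-scaffold
    contacts are used).  Contigs with no in-range contacts keep their input
    orientation and are flagged in the report.  Returns
    ``(new_layout, [OrientationVector per scaffold], report DataFrame)``.
    """
    import pandas as pd

    config = config or HMMConfig()
    if config.K is None:
        config = dataclasses.replace(config, K=float(dist.K))

    vectors: list[OrientationVector] = []
    rows = []
    for si, scaf in enumerate(layout.scaffolds):
        space = build_state_space(scaf, config)
        emissions = compute_emissions(space, store, dist, scaf, si)
        ov = viterbi(space, emissions, config, scaf.orientations)

        lengths = scaf.lengths
        prefix = np.concatenate([[0], np.cumsum(lengths)])
        n_contacts = np.zeros(scaf.n, dtype=np.int64)
        pair_tables: dict[tuple[int, int], np.ndarray] = {}
        for obs in space.observations:
            for i, j in obs:
                contacts = store.pair(si, i, j)
                if contacts.shape[0] == 0:
                    continue
                n_contacts[i] += contacts.shape[0]
                n_contacts[j] += contacts.shape[0]
                geom = PairGeometry(int(lengths[i]), int(lengths[j]),
                                    int(prefix[j] - prefix[i + 1]))
                pair_tables[(i, j)] = pair_log_likelihood(contacts, geom, dist).log_like

        ov.confidence = _conditional_confidence(scaf.n, pair_tables, ov.orientations)
        ov.window_arity = np.array(
            [space.arity_of_contig(c) for c in range(scaf.n)], dtype=np.int64
        )
        ov.n_contacts = n_contacts
        vectors.append(ov)

        for c in range(scaf.n):
            rows.append(
                {
                    "scaffold": scaf.name,
                    "contig": scaf.contigs[c].name,
                    "length": int(lengths[c]),
                    "input_orientation": "+-"[scaf.orientations[c]],
                    "output_orientation": "+-"[ov.orientations[c]],
                    "flipped": bool(ov.flip_mask[c]),
                    "window_arity": int(ov.window_arity[c]),
                    "n_contacts": int(n_contacts[c]),
                    "no_contacts": bool(n_contacts[c] == 0),
                    "confidence": float(ov.confidence[c]),
                }
            )

    decoded_all = np.concatenate([v.orientations for v in vectors])
    report = pd.DataFrame(rows)
    return layout.with_orientations(decoded_all), vectors, report


def _conditional_confidence(
    n: int,
    pair_tables: dict[tuple[int, int], np.ndarray],
    decoded: np.ndarray,
) -> np.ndarray:
    """Posterior probability of each decoded orientation, conditioning the
    other contigs on their decoded values.  Contact-free contigs get 0.5."""
    conf = np.full(n, 0.5)
    delta = np.zeros(n)  # log-likelihood margin decoded vs flipped
    touched = np.zeros(n, dtype=bool)
    for (i, j), tab in pair_tables.items():
        ti, tj = int(decoded[i]), int(decoded[j])
        delta[i] += tab[ti, tj] - tab[1 - ti, tj]
        delta[j] += tab[ti, tj] - tab[ti, 1 - tj]
        touched[i] = touched[j] = True
    with np.errstate(over="ignore"):
        conf[touched] = 1.0 / (1.0 + np.exp(-delta[touched]))
    return conf
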