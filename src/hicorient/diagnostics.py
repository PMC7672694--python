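"""Confidence diagnostics and orientation-error metrics.

Two kinds of output:

* the relative orientation probability matrix M, whose entry M_ij is the
  posterior-like fraction of pair-likelihood mass that supports contig i's
  reference orientation given only its contacts with contig j (0.5 = no
  information; M is asymmetric by construction);
* global/local orientation error rates against a supplied truth table
  (contig -> reference rank and orientation).  A contig is *globally*
  erroneous when its orientation disagrees with the reference outright, and
  *locally* erroneous when it is a single misoriented contig between two
  correctly oriented, order-consistent neighbors — the error class this
  method targets, as opposed to large block inversions that are corrected
  upstream by manual curation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import ContactStore, ScaffoldLayout, orientation_char, parse_orientation
from .likelihood import PairGeometry, in_range_pairs, pair_log_likelihood


@dataclasses.dataclass
class ConfidenceMatrix:
    """Relative orientation probabilities for in-range contig pairs.

    ``entries[(scaffold, i, j)]`` is M_ij: how strongly contacts with
    contig j support contig i's reference orientation.  Both (i, j) and
    (j, i) are stored; the matrix is generally asymmetric.  Pairs with no
    contacts, or beyond the tail threshold, are 0.5 exactly.
    """

    entries: dict[tuple[int, int, int], float]
    reference: np.ndarray  # concatenated reference orientation codes
    K: float

    def to_dataframe(self, layout: ScaffoldLayout) -> pd.DataFrame:
        rows = []
        for (si, i, j), m in sorted(self.entries.items()):
            scaf = layout.scaffolds[si]
            rows.append(
                {
                    "scaffold": scaf.name,
                    "contig_i": scaf.contigs[i].name,
                    "contig_j": scaf.contigs[j].name,
                    "M": m,
                }
            )
        return pd.DataFrame(rows, columns=["scaffold", "contig_i", "contig_j", "M"])


def confidence_matrix(
    layout: ScaffoldLayout,
    store: ContactStore,
    dist,
    reference_orientations: np.ndarray,
    K: float | None = None,
) -> ConfidenceMatrix:
    """Compute M_ij for every pair with intervening length < K.

    M_ij = sum_{theta_j} P(R_ij | theta_i = ref_i, theta_j)
         / sum_{theta_i, theta_j} P(R_ij | theta_i, theta_j),
    evaluated in log space via log-sum-exp; the normalization Z cancels
    because it is identical across the four cases.
    """
    K = dist.K if K is None else K
    ref = layout.split_vector(np.asarray(reference_orientations, dtype=np.uint8))
    entries: dict[tuple[int, int, int], float] = {}
    for si, i, j, geom in in_range_pairs(layout, K):
        contacts = store.pair(si, i, j)
        if contacts.shape[0] == 0:
            entries[(si, i, j)] = 0.5
            entries[(si, j, i)] = 0.5
            continue
        tab = pair_log_likelihood(contacts, geom, dist).log_like
        if np.all(tab == tab[0, 0]):  # no orientation information
            entries[(si, i, j)] = 0.5
            entries[(si, j, i)] = 0.5
            continue
        total = logsumexp(tab)
        entries[(si, i, j)] = float(np.exp(logsumexp(tab[ref[si][i], :]) - total))
        entries[(si, j, i)] = float(np.exp(logsumexp(tab[:, ref[si][j]]) - total))
    return ConfidenceMatrix(entries=entries, reference=np.asarray(reference_orientations, dtype=np.uint8), K=K)


@dataclasses.dataclass
class ErrorReport:
    """Orientation-error summary against a truth table.

    Rates use all evaluated contigs (those present in the truth table) as
    the denominator.  The flip confusion block treats a flip performed by
    the decoder as a positive: TP = flip of a truly misoriented input,
    FP = flip of a correct input, FN = missed flip, TN = correctly left
    alone.
    """

    n_evaluated: int
    n_excluded: int
    n_global_errors: int
    global_error_rate: float
    n_local_errors: int
    local_error_rate: float
    n_local_eligible: int
    n_local_excluded: int
    tp: int
    fp: int
    fn: int
    tn: int


def _truth_maps(truth_table: pd.DataFrame) -> tuple[dict, dict]:
    required = {"contig", "rank", "orientation"}
    if not required.issubset(truth_table.columns):
        raise ValueError(f"truth table needs columns {sorted(required)}")
    orient = {
        str(row.contig): parse_orientation(str(row.orientation))
        for row in truth_table.itertuples()
    }
    rank = {str(row.contig): int(row.rank) for row in truth_table.itertuples()}
    return orient, rank


def _local_error_flags(
    layout: ScaffoldLayout,
    predicted_parts: list[np.ndarray],
    truth_orient: dict,
    truth_rank: dict,
) -> tuple[dict[str, bool], dict[str, bool]]:
    """Per-contig (eligible, local_error) flags.

    A contig is eligible when it is the middle of a scaffold-adjacent triple
    whose members are all in the truth table with strictly monotone
    reference ranks (order-consistent up to whole-block reversal).  It is a
    local error when it is globally erroneous while both neighbors are
    globally correct — the single-contig misorientation pattern.
    Scaffold-end contigs have one neighbor only and are not eligible.
    """
    eligible: dict[str, bool] = {}
    local_err: dict[str, bool] = {}
    for si, scaf in enumerate(layout.scaffolds):
        names = [c.name for c in scaf.contigs]
        errs = {}
        for pi, name in enumerate(names):
            if name in truth_orient:
                errs[pi] = int(predicted_parts[si][pi]) != truth_orient[name]
        for pi, name in enumerate(names):
            if pi not in errs:
                continue
            eligible[name] = False
            local_err[name] = False
            if pi == 0 or pi == scaf.n - 1:
                continue
            if (pi - 1) not in errs or (pi + 1) not in errs:
                continue
            r = [truth_rank[names[pi - 1]], truth_rank[name], truth_rank[names[pi + 1]]]
            if not (r[0] < r[1] < r[2] or r[0] > r[1] > r[2]):
                continue
            eligible[name] = True
            local_err[name] = errs[pi] and not errs[pi - 1] and not errs[pi + 1]
    return eligible, local_err


def orientation_errors(
    predicted: np.ndarray | ScaffoldLayout,
    truth_table: pd.DataFrame,
    layout: ScaffoldLayout,
) -> ErrorReport:
    """Global/local error rates and the flip confusion block.

    ``predicted`` is the decoded orientation vector (concatenated codes, or
    a layout carrying them); ``layout`` supplies the *input* orientations
    against which flips are counted.  Contigs absent from the truth table
    are excluded from all counts and reported in ``n_excluded``.
    """
    if isinstance(predicted, ScaffoldLayout):
        predicted = predicted.all_orientations()
    predicted = np.asarray(predicted, dtype=np.uint8)
    truth_orient, truth_rank = _truth_maps(truth_table)
    pred_parts = layout.split_vector(predicted)

    n_eval = n_excl = n_glob = 0
    tp = fp = fn = tn = 0
    for si, scaf in enumerate(layout.scaffolds):
        for pi, contig in enumerate(scaf.contigs):
            if contig.name not in truth_orient:
                n_excl += 1
                continue
            n_eval += 1
            truth = truth_orient[contig.name]
            pred = int(pred_parts[si][pi])
            inp = int(scaf.orientations[pi])
            if pred != truth:
                n_glob += 1
            flipped = pred != inp
            wrong_in = inp != truth
            if flipped and wrong_in:
                tp += 1
            elif flipped:
                fp += 1
            elif wrong_in:
                fn += 1
            else:
                tn += 1

    eligible, local_err = _local_error_flags(layout, pred_parts, truth_orient, truth_rank)
    n_eligible = sum(eligible.values())
    n_local = sum(local_err.values())
    return ErrorReport(
        n_evaluated=n_eval,
        n_excluded=n_excl,
        n_global_errors=n_glob,
        global_error_rate=n_glob / n_eval if n_eval else math.nan,
        n_local_errors=n_local,
        local_error_rate=n_local / n_eval if n_eval else math.nan,
        n_local_eligible=n_eligible,
        n_local_excluded=n_eval - n_eligible,
        tp=tp, fp=fp, fn=fn, tn=tn,
    )


def error_by_length(
    predicted: np.ndarray | ScaffoldLayout,
    truth_table: pd.DataFrame,
    layout: ScaffoldLayout,
    bin_edges,
) -> pd.DataFrame:
    """Local error rate binned by contig length.

    Each bin spans ``[bin_edges[b], bin_edges[b+1])`` (the last bin is
    closed); the rate denominator is every evaluated contig in the bin, so
    a single whole-range bin reproduces the overall local error rate.
    Empty bins report a missing (NaN) rate.
    """
    if isinstance(predicted, ScaffoldLayout):
        predicted = predicted.all_orientations()
    predicted = np.asarray(predicted, dtype=np.uint8)
    truth_orient, truth_rank = _truth_maps(truth_table)
    pred_parts = layout.split_vector(predicted)
    _, local_err = _local_error_flags(layout, pred_parts, truth_orient, truth_rank)

    edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    errors = np.zeros(len(edges) - 1, dtype=np.int64)
    for _, _, contig, _ in layout.iter_contigs():
        if contig.name not in local_err:
            continue
        b = int(np.searchsorted(edges, contig.length, side="right")) - 1
        if b == len(counts):  # closed last bin
            b -= 1
        if not 0 <= b < len(counts):
            continue
        counts[b] += 1
        errors[b] += int(local_err[contig.name])
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(counts > 0, errors / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "n": counts,
            "n_local_errors": errors,
            "local_error_rate": rates,
        }
    )


def write_truth_table(truth_table: pd.DataFrame, path) -> None:
    """Write a truth table as TSV with columns contig/rank/orientation."""
    truth_table.to_csv(path, sep="\t", index=False, columns=["contig", "rank", "orientation"])


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "orientation": str})
    df["rank"] = df["rank"].astype(int)
    return df
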