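"""Target-decoy FDR estimation and q-values.

The estimator follows the decoy-doubling convention used with
reversed-sequence decoy databases: if the search space contains one decoy
sequence per target, a decoy match betrays one false target match on
average, so the estimated false-discovery proportion of an accepted set is

    FDR = 2 * n_decoy / (n_target + n_decoy)

clipped to [0, 1].  An accepted set in which 1% of matches are reversed
decoys therefore carries an estimated 2% PSM FDR.  The convention is
isolated here so that D/T variants can be swapped if a different decoy
construction is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FdrEstimate:
    """Decoy-doubling FDR of the set of records scoring at or above a threshold."""

    threshold: float
    n_target: int
    n_decoy: int
    fdr: float


def decoy_doubling(n_target: int, n_decoy: int) -> float:
    """FDR = 2*D/(T+D), clipped to [0, 1]. Raises on an empty accepted set."""
    total = n_target + n_decoy
    if total == 0:
        raise ValueError("FDR is undefined for an empty accepted set")
    return min(1.0, 2.0 * n_decoy / total)


def estimate_fdr(scores, is_decoy, threshold: float) -> FdrEstimate:
    """Decoy-doubling FDR over records with ``score >= threshold``.

    Higher scores are better.  Raises ``ValueError`` when no record passes
    the threshold (the FDR of an empty set is undefined, not zero).
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.shape != is_decoy.shape:
        raise ValueError("scores and is_decoy must have equal length")
    accepted = scores >= threshold
    n_decoy = int(np.count_nonzero(is_decoy & accepted))
    n_target = int(np.count_nonzero(~is_decoy & accepted))
    return FdrEstimate(
        threshold=float(threshold),
        n_target=n_target,
        n_decoy=n_decoy,
        fdr=decoy_doubling(n_target, n_decoy),
    )


def qvalues(scores, is_decoy) -> np.ndarray:
    """Per-record q-values: the minimum decoy-doubling FDR at which the
    record is accepted, scanning thresholds from high to low scores.

    Records tied on score enter the accepted set together.  Monotonicity is
    enforced (q is non-increasing in score) by a reverse running minimum.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    n = scores.size
    if n == 0:
        return np.empty(0, dtype=float)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    cum_decoy = np.cumsum(is_decoy[order])
    totals = np.arange(1, n + 1)
    raw = np.minimum(1.0, 2.0 * cum_decoy / totals)

    # tie blocks share the FDR at the last tied index (all-in threshold semantics)
    is_last_of_tie = np.empty(n, dtype=bool)
    is_last_of_tie[:-1] = sorted_scores[:-1] != sorted_scores[1:]
    is_last_of_tie[-1] = True
    ends = np.flatnonzero(is_last_of_tie)
    block_end = ends[np.searchsorted(ends, np.arange(n))]
    raw = raw[block_end]

    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q
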