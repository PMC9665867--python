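"""PWM construction from crawl alignments, and PWM-based k-mer alignment.

Two directions of travel between alignments and position weight matrices:

* :func:`pwm_from_alignment` summarizes a crawl alignment as a PWM whose
  counts are weighted by each k-mer's binding metric (e.g., relative
  enrichment) — the logo-style summary of the alignment.
* :func:`pwm_align_kmers` goes the other way: given any PWM (e.g., from a
  motif-discovery tool), it pads the matrix with neutral (background)
  columns and slides each k-mer across every window, assigning the k-mer
  the shift of its best log-odds score.  This makes PWM-producing methods
  directly comparable with the crawl via :func:`shift_agreement`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .io_formats import ALPHABET, AlignedTable, FormatError, KmerTable

log = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_UNIFORM = np.full(4, 0.25)

#: Probability floor applied per cell before taking log-odds, so that a
#: zero-probability base scores very unfavourably instead of -inf.
PROB_FLOOR = 1e-4


@dataclass(frozen=True)
class PWM:
    """Position x base probability matrix (columns ordered A, C, G, T).

    ``anchor`` records which matrix position corresponds to shift 0 when the
    PWM is used as an aligner; PWMs built from a crawl alignment carry the
    alignment's own origin there, while PWMs read from a MEME file default
    to anchor 0 (shift 0 = k-mer start at the first matrix position).
    """

    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())
    anchor: int = 0

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] < 1:
            raise FormatError(
                f"PWM matrix must be (width >= 1, 4), got {matrix.shape}"
            )
        if np.any(matrix < 0):
            raise FormatError("PWM probabilities must be non-negative")
        sums = matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise FormatError("PWM positions must sum to 1 within 1e-9")
        background = np.asarray(self.background, dtype=float)
        if background.shape != (4,) or np.any(background <= 0):
            raise FormatError("background must be 4 positive probabilities")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "background", background)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PWM):
            return NotImplemented
        return (
            self.matrix.shape == other.matrix.shape
            and np.allclose(self.matrix, other.matrix, atol=1e-6)
            and np.allclose(self.background, other.background, atol=1e-6)
        )


def pwm_from_alignment(
    aligned: AlignedTable,
    max_abs_shift: int = 5,
    pseudoweight: float = 0.0,
) -> PWM:
    """Metric-weighted PWM over the window of shifts within ±``max_abs_shift``.

    Each k-mer contributes its metric as a weight to the base it carries at
    every window position it covers; gap positions contribute nothing, and
    each position is normalized over the sequences covering it.  Metrics
    must be non-negative — exponentiate log enrichments first.  Returns a
    PWM of width ``2 * max_abs_shift + k`` anchored so that a shift-0 k-mer
    starts at matrix position ``max_abs_shift``.
    """
    if max_abs_shift < 0:
        raise FormatError("max_abs_shift must be >= 0")
    if pseudoweight < 0:
        raise FormatError("pseudoweight must be >= 0")
    if np.any(aligned.metrics < 0):
        raise FormatError(
            "negative metric: PWM weights must be non-negative — if your "
            "metrics are log enrichments, exponentiate them first"
        )
    k = aligned.k
    width = 2 * max_abs_shift + k
    counts = np.zeros((width, 4))
    covered = np.zeros(width, dtype=bool)
    shift_of = zip(aligned.kmers(), aligned.shifts, aligned.metrics)
    n_used = 0
    for seq, shift, metric in shift_of:
        if abs(shift) > max_abs_shift:
            continue
        n_used += 1
        start = shift + max_abs_shift
        for i, base in enumerate(seq):
            counts[start + i, _BASE_INDEX[base]] += metric
        covered[start: start + k] = True
    if n_used == 0:
        raise FormatError(
            f"no aligned k-mer falls within ±{max_abs_shift} bp of the origin"
        )
    counts += pseudoweight
    matrix = np.empty_like(counts)
    for j in range(width):
        total = counts[j].sum()
        if total > 0:
            matrix[j] = counts[j] / total
        else:
            matrix[j] = _UNIFORM
            if not covered[j]:
                log.warning(
                    "PWM position %d covered by no sequence; set to background",
                    j,
                )
    return PWM(matrix, anchor=max_abs_shift)


def pad_pwm(pwm: PWM, pad: int) -> PWM:
    """Add ``pad`` neutral (background-distribution) positions to each end.

    Neutral positions score 0 in log-odds against the same background, so
    padding never changes which window of the original matrix a k-mer
    prefers — it only widens the set of placements.
    """
    if pad < 0:
        raise FormatError("pad must be >= 0")
    if pad == 0:
        return pwm
    neutral = np.tile(pwm.background, (pad, 1))
    return PWM(
        np.vstack([neutral, pwm.matrix, neutral]),
        pwm.background,
        anchor=pwm.anchor + pad,
    )


def _log_odds(pwm: PWM, floor: float) -> np.ndarray:
    return np.log2(np.maximum(pwm.matrix, floor) / pwm.background)


def pwm_align_kmers(
    pwm: PWM, table: KmerTable, floor: float = PROB_FLOOR
) -> dict[str, int]:
    """Assign each k-mer the shift of its best-scoring PWM placement.

    The PWM is padded internally with k-1 neutral positions per side so
    every offset places the whole k-mer on defined columns.  Score of a
    placement is the summed log2 odds of each base against the background,
    with probabilities floored at ``floor``.  Ties go to the smaller
    |shift|, 5' (negative) first.  Shift 0 means the k-mer starts at the
    PWM's anchor position.
    """
    seqs = table.sequences if isinstance(table, KmerTable) else tuple(table)
    k = len(seqs[0])
    padded = pad_pwm(pwm, k - 1)
    if k > padded.width:
        raise FormatError(f"k={k} exceeds padded PWM width {padded.width}")
    lo_matrix = _log_odds(padded, floor)
    n_offsets = padded.width - k + 1
    shifts = np.arange(n_offsets) - padded.anchor

    base_idx = np.array(
        [[_BASE_INDEX[b] for b in s] for s in seqs], dtype=np.intp
    )
    scores = np.zeros((len(seqs), n_offsets))
    for j in range(n_offsets):
        for i in range(k):
            scores[:, j] += lo_matrix[j + i, base_idx[:, i]]

    # evaluate offsets in tie-precedence order: |shift| ascending, 5' first
    order = sorted(range(n_offsets), key=lambda j: (abs(shifts[j]), shifts[j]))
    ordered = scores[:, order]
    best = ordered.max(axis=1, keepdims=True)
    pick = np.argmax(ordered >= best - 1e-9, axis=1)
    return {
        s: int(shifts[order[p]]) for s, p in zip(seqs, pick)
    }


def shift_agreement(
    reference_shifts: dict[str, int],
    other_shifts: dict[str, int],
    eligible: set[str] | None = None,
    return_offset: bool = False,
):
    """Fraction of k-mers assigned the same shift by two aligners.

    Different aligners anchor their origin differently, so agreement is
    computed after reconciling origins: the single constant offset c that
    maximizes the number of matches (the mode of the per-k-mer shift
    differences) is applied globally before counting.
    """
    if eligible is None:
        eligible = set(reference_shifts) & set(other_shifts)
    eligible = set(eligible)
    if not eligible:
        raise FormatError("no eligible k-mers shared by both alignments")
    missing = [s for s in eligible if s not in reference_shifts
               or s not in other_shifts]
    if missing:
        raise FormatError(
            f"eligible k-mer(s) missing from an alignment: {missing[:5]}"
        )
    diffs: dict[int, int] = {}
    for s in eligible:
        d = other_shifts[s] - reference_shifts[s]
        diffs[d] = diffs.get(d, 0) + 1
    best_c, n_match = min(diffs.items(), key=lambda kv: (-kv[1], kv[0]))
    frac = n_match / len(eligible)
    if return_offset:
        return frac, best_c
    return frac


class PWMAligner(BaseEstimator):
    """Scikit-learn style wrapper around :func:`pwm_align_kmers`.

    Parameters
    ----------
    pwm : PWM
        The matrix to slide k-mers along.
    floor : float, default 1e-4
        Per-cell probability floor before log-odds.
    """

    def __init__(self, pwm: PWM | None = None, floor: float = PROB_FLOOR):
        self.pwm = pwm
        self.floor = floor

    def fit(self, X=None, y=None) -> "PWMAligner":
        if self.pwm is None:
            raise FormatError("PWMAligner requires a pwm")
        self.pwm_ = self.pwm
        return self

    def predict(self, X) -> np.ndarray:
        """Best-placement shift for each k-mer in ``X`` (table or strings)."""
        if not hasattr(self, "pwm_"):
            self.fit()
        seqs = X.sequences if isinstance(X, KmerTable) else tuple(X)
        table = KmerTable(seqs, np.zeros(len(seqs)))
        shift_of = pwm_align_kmers(self.pwm_, table, floor=self.floor)
        return np.array([shift_of[s] for s in seqs])

    def align(self, X) -> dict[str, int]:
        if not hasattr(self, "pwm_"):
            self.fit()
        seqs = X.sequences if isinstance(X, KmerTable) else tuple(X)
        table = KmerTable(seqs, np.zeros(len(seqs)))
        return pwm_align_kmers(self.pwm_, table, floor=self.floor)
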