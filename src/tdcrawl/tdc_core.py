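"""The Top-Down Crawl: rank-dependent, PWM-free alignment of scored k-mers.

The crawl starts from the k-mer with the largest binding metric (shift 0)
and repeatedly recruits, from the current reference, (a) every unaligned
k-mer one base substitution away (same shift) and (b) every unaligned k-mer
overlapping the reference by k-1 or k-2 bp (reference shift minus 1 or 2 for
5'-overlaps, plus 1 or 2 for 3'-overlaps).  Each round's reference is the
highest-metric aligned k-mer not yet used as a reference; the crawl stops
when every aligned k-mer has served as a reference.  Shifts, once assigned,
are never revised, so the alignment is driven purely by the rank order of
the metrics — no PWM, no experiment-specific parameters.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .io_formats import (
    ALPHABET,
    AlignedTable,
    FormatError,
    KmerTable,
    build_aligned_table,
    revcomp,
)

log = logging.getLogger(__name__)

_DNA = frozenset(ALPHABET)


@dataclass
class Alignment:
    """Shift assignments produced by the crawl.

    ``shift_of`` maps each aligned k-mer to its integer shift (bp) relative
    to the first reference (which always sits at shift 0); negative shifts
    point toward the 5' end.  ``completed`` is the subset of aligned k-mers
    that have already served as a reference.
    """

    k: int
    shift_of: dict[str, int] = field(default_factory=dict)
    completed: set[str] = field(default_factory=set)
    orientation_of: dict[str, str] | None = None

    @property
    def aligned(self) -> set[str]:
        return set(self.shift_of)

    def __len__(self) -> int:
        return len(self.shift_of)


@dataclass
class CrawlTrace:
    """Per-round diagnostics: (reference k-mer, k-mers newly aligned)."""

    rounds: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rounds)

    @property
    def references(self) -> list[str]:
        return [r for r, _ in self.rounds]


def single_bp_neighbors(seq: str) -> set[str]:
    """All 3k strings at Hamming distance exactly 1 from ``seq``."""
    if not seq or not _DNA.issuperset(seq):
        raise FormatError(f"not an A/C/G/T k-mer: {seq!r}")
    return {
        seq[:i] + b + seq[i + 1:]
        for i in range(len(seq))
        for b in ALPHABET
        if b != seq[i]
    }


def _iter_single_bp_neighbors(seq: str):
    """Deterministically ordered variant of :func:`single_bp_neighbors`."""
    for i in range(len(seq)):
        for b in ALPHABET:
            if b != seq[i]:
                yield seq[:i] + b + seq[i + 1:]


# Overlap recruitment order: smaller |shift| first, 5' before 3'.  A k-mer
# satisfying several overlap offsets is reported once, at the first match.
_OVERLAP_ORDER = (-1, +1, -2, +2)


def _iter_overlap_candidates(reference: str):
    """Yield (candidate, relative shift) pairs in precedence order.

    Candidates are constructed, not searched: a 5'-overlap at -d is
    ``x + reference[:k-d]`` and a 3'-overlap at +d is ``reference[d:] + x``
    for every d-mer x, which enumerates exactly the strings sharing the
    required (k-d)-length prefix/suffix.
    """
    k = len(reference)
    for shift in _OVERLAP_ORDER:
        d = abs(shift)
        for x in itertools.product(ALPHABET, repeat=d):
            ext = "".join(x)
            if shift < 0:
                cand = ext + reference[: k - d]
            else:
                cand = reference[d:] + ext
            yield cand, shift


def overlap_candidates(
    reference: str, universe: set[str]
) -> list[tuple[str, int]]:
    """k-mers of ``universe`` overlapping ``reference`` by k-1 or k-2 bp.

    Returns (k-mer, relative shift) pairs with shift -d for a 5'-extension
    (candidate suffix equals reference prefix) and +d for a 3'-extension,
    d in {1, 2}.  A candidate matching several offsets appears once, at the
    smallest |shift| (5' first on ties); the reference itself is excluded.
    """
    k = len(reference)
    if not _DNA.issuperset(reference):
        raise FormatError(f"not an A/C/G/T k-mer: {reference!r}")
    if k < 3:
        raise FormatError(f"overlap rule undefined for k={k} < 3")
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    for cand, shift in _iter_overlap_candidates(reference):
        if cand == reference or cand in seen:
            continue
        if cand in universe:
            seen.add(cand)
            out.append((cand, shift))
    return out


def _merge_revcomp(table: KmerTable) -> tuple[KmerTable, dict[str, str]]:
    """Collapse each k-mer with its reverse complement onto a canonical strand.

    The lexicographically smaller of (seq, revcomp) is kept.  If both
    orientations occur in the input their metrics must agree exactly, since
    they are the same molecular species read from opposite strands.
    """
    metric = table.metric_of()
    canon_metric: dict[str, float] = {}
    orientation: dict[str, str] = {}
    for s, m in metric.items():
        rc = revcomp(s)
        canon = min(s, rc)
        orientation[s] = "+" if s == canon else "-"
        if canon in canon_metric:
            if canon_metric[canon] != m:
                raise FormatError(
                    f"reverse-complement pair {canon}/{revcomp(canon)} has "
                    f"conflicting metrics {canon_metric[canon]} vs {m}"
                )
        else:
            canon_metric[canon] = m
    seqs = tuple(sorted(canon_metric))
    return (
        KmerTable(seqs, np.array([canon_metric[s] for s in seqs])),
        orientation,
    )


def crawl(
    table: KmerTable, revcomp_merge: bool = False
) -> tuple[Alignment, CrawlTrace]:
    """Run the Top-Down Crawl on a k-mer table.

    Returns the alignment (max-metric k-mer at shift 0) and a per-round
    trace.  k-mers unreachable from the seed through mutation/overlap
    relations remain unaligned; callers can recover them as
    ``set(table.sequences) - alignment.aligned``.

    With ``revcomp_merge`` each k-mer is first collapsed with its reverse
    complement onto the lexicographically smaller strand;
    ``alignment.orientation_of`` then records each input k-mer's strand.
    """
    orientation = None
    if revcomp_merge:
        table, orientation = _merge_revcomp(table)
    metric = table.metric_of()
    k = table.k

    seed = min(table.sequences, key=lambda s: (-metric[s], s))
    alignment = Alignment(k=k, shift_of={seed: 0}, orientation_of=orientation)
    trace = CrawlTrace()
    unaligned = set(table.sequences)
    unaligned.discard(seed)

    # aligned-but-not-complete k-mers, highest metric first (ties: lexicographic)
    frontier: list[tuple[float, str]] = [(-metric[seed], seed)]
    while frontier:
        _, ref = heapq.heappop(frontier)
        ref_shift = alignment.shift_of[ref]
        n_new = 0
        for q in _iter_single_bp_neighbors(ref):
            if q in unaligned:
                alignment.shift_of[q] = ref_shift
                unaligned.discard(q)
                heapq.heappush(frontier, (-metric[q], q))
                n_new += 1
        if k >= 3:
            for q, rel in _iter_overlap_candidates(ref):
                if q in unaligned:
                    alignment.shift_of[q] = ref_shift + rel
                    unaligned.discard(q)
                    heapq.heappush(frontier, (-metric[q], q))
                    n_new += 1
        alignment.completed.add(ref)
        trace.rounds.append((ref, n_new))
        log.debug("round %d: ref=%s shift=%d newly aligned=%d",
                  len(trace), ref, ref_shift, n_new)
    return alignment, trace


class TopDownCrawlAligner(BaseEstimator):
    """Scikit-learn style wrapper around :func:`crawl`.

    Parameters
    ----------
    revcomp_merge : bool, default False
        Collapse reverse-complement pairs onto a canonical strand before
        aligning.  Off by default: each input row is treated as an
        independent species.

    Attributes
    ----------
    shift_of_ : dict mapping each aligned k-mer to its shift (bp)
    trace_ : CrawlTrace of per-round references and recruitment counts
    unaligned_ : tuple of k-mers unreachable from the seed
    k_ : k-mer length of the fitted table
    """

    def __init__(self, revcomp_merge: bool = False):
        self.revcomp_merge = revcomp_merge

    def fit(self, X, y=None) -> "TopDownCrawlAligner":
        """Align a k-mer table.

        ``X`` may be a :class:`KmerTable`, or a sequence of k-mer strings
        with their metrics in ``y``.
        """
        table = X if isinstance(X, KmerTable) else KmerTable(tuple(X), y)
        alignment, trace = crawl(table, revcomp_merge=self.revcomp_merge)
        self.table_ = table
        self.alignment_ = alignment
        self.shift_of_ = alignment.shift_of
        self.trace_ = trace
        aligned = alignment.aligned
        self.unaligned_ = tuple(
            s for s in table.sequences if s not in aligned
        )
        self.k_ = table.k
        return self

    def transform(self, X) -> np.ndarray:
        """Shifts for the given k-mers (NaN where unaligned)."""
        seqs = X.sequences if isinstance(X, KmerTable) else X
        return np.array(
            [self.shift_of_.get(s, np.nan) for s in seqs], dtype=float
        )

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def to_aligned_table(self) -> AlignedTable:
        """The fitted alignment as a gap-padded table (aligned k-mers only)."""
        table = self.table_
        if self.revcomp_merge:
            table, _ = _merge_revcomp(table)
        return build_aligned_table(table, self.shift_of_)
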