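"""Readers, writers and in-memory containers for k-mer tables, alignments and PWMs.

The external surface is deliberately small and plain-text:

* input k-mer tables: 2+-column TSV ``sequence<TAB>metric`` with an optional
  header row (auto-detected);
* alignment output: 3-column TSV ``padded_seq<TAB>shift<TAB>metric`` where
  gaps are written as ``_``;
* PWMs: minimal MEME motif format (letter-probability matrix over ACGT).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_DNA = frozenset(ALPHABET)
GAP = "_"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for any malformed external input or invalid container state."""


@dataclass(frozen=True)
class KmerTable:
    """Fixed-length k-mers with one quantitative binding metric each.

    The metric is unitless; larger means higher affinity.  Sequences must be
    unique, all of the same length, over the A/C/G/T alphabet.
    """

    sequences: tuple[str, ...]
    metrics: np.ndarray

    def __post_init__(self) -> None:
        seqs = tuple(self.sequences)
        object.__setattr__(self, "sequences", seqs)
        metrics = np.asarray(self.metrics, dtype=float)
        object.__setattr__(self, "metrics", metrics)
        if len(seqs) < 1:
            raise FormatError("k-mer table is empty")
        if metrics.shape != (len(seqs),):
            raise FormatError(
                f"{len(seqs)} sequences but {metrics.size} metrics"
            )
        k = len(seqs[0])
        for i, s in enumerate(seqs):
            if len(s) != k:
                raise FormatError(
                    f"mixed k-mer lengths: row {i + 1} ({s!r}) has length "
                    f"{len(s)}, expected {k}"
                )
            if not _DNA.issuperset(s):
                bad = sorted(set(s) - _DNA)
                raise FormatError(
                    f"non-ACGT character(s) {bad} in row {i + 1} ({s!r})"
                )
        if len(set(seqs)) != len(seqs):
            seen: set[str] = set()
            for i, s in enumerate(seqs):
                if s in seen:
                    raise FormatError(f"duplicate k-mer {s!r} at row {i + 1}")
                seen.add(s)
        if not np.all(np.isfinite(metrics)):
            i = int(np.flatnonzero(~np.isfinite(metrics))[0])
            raise FormatError(f"non-finite metric at row {i + 1}")

    @property
    def k(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def metric_of(self) -> dict[str, float]:
        return dict(zip(self.sequences, self.metrics.tolist()))

    def subset(self, keep: np.ndarray) -> "KmerTable":
        keep = np.asarray(keep)
        return KmerTable(
            tuple(s for s, f in zip(self.sequences, keep) if f),
            self.metrics[keep.astype(bool)],
        )


@dataclass(frozen=True)
class AlignedTable:
    """Gap-padded k-mers with integer shifts relative to the alignment origin.

    Padded width is ``(max shift - min shift) + k``; a row with shift ``s``
    carries ``s - min(shift)`` leading gaps, so shifts are recoverable from
    the gap counts alone.  Negative shifts point toward the 5' end.
    """

    sequences: tuple[str, ...]
    shifts: tuple[int, ...]
    metrics: np.ndarray
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        object.__setattr__(self, "shifts", tuple(int(s) for s in self.shifts))
        object.__setattr__(
            self, "metrics", np.asarray(self.metrics, dtype=float)
        )
        n = len(self.sequences)
        if n < 1:
            raise FormatError("aligned table is empty")
        if len(self.shifts) != n or self.metrics.shape != (n,):
            raise FormatError("sequences, shifts and metrics disagree in length")
        lo, hi = min(self.shifts), max(self.shifts)
        width = (hi - lo) + self.k
        for seq, shift in zip(self.sequences, self.shifts):
            if len(seq) != width:
                raise FormatError(
                    f"padded row {seq!r} has width {len(seq)}, expected {width}"
                )
            core = seq.strip(GAP)
            if len(core) != self.k or GAP in core or not _DNA.issuperset(core):
                raise FormatError(
                    f"padded row {seq!r} does not contain one contiguous "
                    f"{self.k}-mer"
                )
            lead = len(seq) - len(seq.lstrip(GAP))
            if lead != shift - lo:
                raise FormatError(
                    f"row {seq!r}: {lead} leading gaps inconsistent with "
                    f"shift {shift} (min shift {lo})"
                )

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    @property
    def min_shift(self) -> int:
        return min(self.shifts)

    def kmers(self) -> tuple[str, ...]:
        """The unpadded k-mers, in row order."""
        return tuple(s.strip(GAP) for s in self.sequences)

    def shift_of(self) -> dict[str, int]:
        return dict(zip(self.kmers(), self.shifts))

    def to_kmer_table(self) -> KmerTable:
        return KmerTable(self.kmers(), self.metrics)


def build_aligned_table(
    table: KmerTable, shift_of: Mapping[str, int]
) -> AlignedTable:
    """Pad every aligned k-mer of ``table`` into a fixed-width block.

    Rows are ordered by descending metric (ties broken by sequence) and only
    k-mers present in ``shift_of`` are included.
    """
    metric = table.metric_of()
    rows = [(s, shift_of[s]) for s in table.sequences if s in shift_of]
    if not rows:
        raise FormatError("no k-mer in the table has an assigned shift")
    rows.sort(key=lambda r: (-metric[r[0]], r[0]))
    lo = min(sh for _, sh in rows)
    hi = max(sh for _, sh in rows)
    width = (hi - lo) + table.k
    padded = tuple(
        GAP * (sh - lo) + s + GAP * (width - table.k - (sh - lo))
        for s, sh in rows
    )
    return AlignedTable(
        padded,
        tuple(sh for _, sh in rows),
        np.array([metric[s] for s, _ in rows]),
        table.k,
    )


def _detect_header(first_metric_field: str) -> bool:
    try:
        float(first_metric_field)
        return False
    except (TypeError, ValueError):
        return True


def read_kmer_table(
    path,
    metric_column: str | int | None = None,
    header: bool | None = None,
    permissive: bool = False,
) -> KmerTable:
    """Read a tab-delimited k-mer table: sequence in column 1, metric elsewhere.

    Parameters
    ----------
    metric_column
        Column holding the binding metric, as a 0-based index or, when a
        header row is present, a column name.  Defaults to column 1.
    header
        ``None`` auto-detects a header row (first row whose metric field is
        non-numeric); ``True``/``False`` force the decision.
    permissive
        If set, rows containing non-ACGT characters are skipped with a
        warning instead of aborting.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: fewer than 2 entries (file is empty)")
    df = df.dropna(how="all")

    if isinstance(metric_column, str):
        names = [str(v) for v in df.iloc[0]]
        if metric_column not in names:
            raise FormatError(
                f"{path}: no column named {metric_column!r} in header {names}"
            )
        col = names.index(metric_column)
        if header is False:
            raise FormatError("a named metric_column requires a header row")
        df = df.iloc[1:]
    else:
        col = 1 if metric_column is None else int(metric_column)
        if col >= df.shape[1]:
            raise FormatError(
                f"{path}: metric column {col} out of range "
                f"({df.shape[1]} columns found)"
            )
        if header is None:
            header = _detect_header(df.iloc[0, col])
        if header:
            df = df.iloc[1:]

    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least 2 tab-delimited columns")

    seqs: list[str] = []
    metrics: list[float] = []
    for row_no, (raw_seq, raw_metric) in enumerate(
        zip(df.iloc[:, 0], df.iloc[:, col]), start=1
    ):
        seq = str(raw_seq).strip().upper()
        try:
            metric = float(raw_metric)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-numeric metric {raw_metric!r} at data row {row_no}"
            )
        if not math.isfinite(metric):
            raise FormatError(
                f"{path}: non-finite metric at data row {row_no}"
            )
        if not _DNA.issuperset(seq):
            if permissive:
                log.warning(
                    "%s: skipping row %d (%r): non-ACGT character",
                    path, row_no, seq,
                )
                continue
            raise FormatError(
                f"{path}: non-ACGT character in {seq!r} at data row {row_no} "
                "(use permissive mode to skip such rows)"
            )
        seqs.append(seq)
        metrics.append(metric)

    if len(seqs) < 2:
        raise FormatError(f"{path}: fewer than 2 entries")
    if seqs:
        k = len(seqs[0])
        for row_no, s in enumerate(seqs, start=1):
            if len(s) != k:
                raise FormatError(
                    f"{path}: mixed k-mer lengths: {s!r} at data row {row_no} "
                    f"has length {len(s)}, expected {k}"
                )
    return KmerTable(tuple(seqs), np.array(metrics))


def write_alignment(aligned: AlignedTable, path) -> None:
    """Write a 3-column TSV: padded sequence, shift, metric (descending metric).

    Metrics are written with ``repr`` (shortest exact round-trip form), so a
    read-back recovers them bit-for-bit.
    """
    order = sorted(
        range(len(aligned.sequences)),
        key=lambda i: (-aligned.metrics[i], aligned.sequences[i]),
    )
    with open(path, "w") as fh:
        for i in order:
            fh.write(
                f"{aligned.sequences[i]}\t{aligned.shifts[i]}\t"
                f"{float(aligned.metrics[i])!r}\n"
            )


def read_alignment(path) -> AlignedTable:
    """Read an alignment TSV written by :func:`write_alignment`.

    Shifts are cross-checked against the leading-gap counts, so a file whose
    gap padding disagrees with its shift column is rejected.
    """
    seqs: list[str] = []
    shifts: list[int] = []
    metrics: list[float] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}: expected 3 columns at row {row_no}, "
                    f"got {len(parts)}"
                )
            seqs.append(parts[0])
            try:
                shifts.append(int(parts[1]))
                metrics.append(float(parts[2]))
            except ValueError:
                raise FormatError(
                    f"{path}: malformed shift/metric at row {row_no}"
                )
    if not seqs:
        raise FormatError(f"{path}: empty alignment file")
    k = len(seqs[0].strip(GAP))
    # AlignedTable.__post_init__ re-validates gap counts against shifts.
    return AlignedTable(tuple(seqs), tuple(shifts), np.array(metrics), k)


# --- minimal MEME motif format -------------------------------------------

_MEME_HEADER = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A {bg[0]:.6g} C {bg[1]:.6g} G {bg[2]:.6g} T {bg[3]:.6g}

MOTIF {name}
letter-probability matrix: alength= 4 w= {w} nsites= 1 E= 0
"""


def write_pwm(pwm, path, name: str = "motif") -> None:
    """Write a PWM as a minimal MEME motif file (letter-probability matrix)."""
    sums = pwm.matrix.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise FormatError("PWM columns must sum to 1 within 1e-6 before writing")
    with open(path, "w") as fh:
        fh.write(
            _MEME_HEADER.format(bg=list(pwm.background), name=name, w=pwm.width)
        )
        for row in pwm.matrix:
            fh.write(" " + " ".join(f"{p:.12g}" for p in row) + "\n")


def read_pwm(path):
    """Read the first motif of a minimal MEME file into a PWM.

    Matrix rows whose probabilities deviate from sum 1 by more than 1e-3 are
    fatal; smaller deviations are renormalized.
    """
    from .pwm_tools import PWM  # local import: pwm_tools imports this module

    background = np.full(4, 0.25)
    rows: list[list[float]] = []
    in_matrix = False
    read_background_next = False
    expected_w = None
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("Background letter frequencies"):
                read_background_next = True
                continue
            if read_background_next and stripped:
                read_background_next = False
                fields = stripped.split()
                try:
                    freq = {
                        fields[i]: float(fields[i + 1])
                        for i in range(0, len(fields) - 1, 2)
                    }
                    background = np.array(
                        [freq[b] for b in ALPHABET], dtype=float
                    )
                except (KeyError, ValueError, IndexError):
                    raise FormatError(
                        f"{path}: malformed background line {stripped!r}"
                    )
                continue
            if stripped.startswith("letter-probability matrix"):
                in_matrix = True
                fields = stripped.split()
                if "w=" in fields:
                    try:
                        expected_w = int(fields[fields.index("w=") + 1])
                    except (ValueError, IndexError):
                        expected_w = None
                continue
            if in_matrix:
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                try:
                    vals = [float(x) for x in stripped.split()]
                except ValueError:
                    raise FormatError(
                        f"{path}: malformed matrix line {stripped!r}"
                    )
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: matrix line has {len(vals)} fields, expected 4"
                    )
                rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no letter-probability matrix found")
    if expected_w is not None and len(rows) != expected_w:
        raise FormatError(
            f"{path}: matrix has {len(rows)} positions but header says "
            f"w= {expected_w}"
        )
    matrix = np.array(rows, dtype=float)
    if np.any(matrix < -1e-12):
        raise FormatError(f"{path}: negative probability in matrix")
    matrix = np.clip(matrix, 0.0, None)
    sums = matrix.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-3)
    if bad.size:
        raise FormatError(
            f"{path}: matrix position(s) {bad.tolist()} deviate from sum 1 "
            "by more than 1e-3"
        )
    matrix /= sums[:, None]
    bg_sum = background.sum()
    if abs(bg_sum - 1.0) > 1e-3 or np.any(background <= 0):
        raise FormatError(f"{path}: invalid background frequencies")
    return PWM(matrix, background / bg_sum)
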