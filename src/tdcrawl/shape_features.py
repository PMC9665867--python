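"""Pentamer-based DNA shape features for aligned k-mers.

Minor groove width (MGW, Angstrom) and electrostatic potential (EP, kT/e)
are structural readouts of local base-pair geometry; both are well
approximated by a lookup over the pentamer centred on each position, and
both are reverse-complement symmetric (the double helix has no idea which
strand you wrote down).  This module loads such lookup tables, validates
their completeness and symmetry, and slides them along k-mers.

No literature table is bundled; :func:`synthetic_shape_table` produces a
deterministic, RC-symmetric stand-in spanning realistic value ranges, and
any user-supplied table in the same TSV format plugs in unchanged.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import ALPHABET, FormatError, revcomp

log = logging.getLogger(__name__)

FEATURES = ("MGW", "EP")

_ALL_PENTAMERS = tuple(
    "".join(p) for p in itertools.product(ALPHABET, repeat=5)
)

#: Plausible value ranges for the synthetic table (MGW in Angstrom, EP in kT/e).
_SYNTHETIC_RANGES = {"MGW": (2.85, 6.20), "EP": (-12.0, -2.0)}


@dataclass(frozen=True)
class ShapeTable:
    """Per-feature pentamer lookup: feature name -> {pentamer -> value}."""

    values: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for feature, table in self.values.items():
            missing = [p for p in _ALL_PENTAMERS if p not in table]
            if missing:
                raise FormatError(
                    f"{feature}: missing pentamer(s), e.g. {missing[:5]} "
                    f"({len(missing)} of 1024 absent)"
                )
            if len(table) != 1024:
                extra = sorted(set(table) - set(_ALL_PENTAMERS))
                raise FormatError(
                    f"{feature}: unexpected key(s) {extra[:5]}"
                )
            bad = [p for p, v in table.items() if not np.isfinite(v)]
            if bad:
                raise FormatError(
                    f"{feature}: non-finite value(s) at {bad[:5]}"
                )
            asym = [
                p for p in _ALL_PENTAMERS
                if abs(table[p] - table[revcomp(p)]) > 0.01
            ]
            if asym:
                raise FormatError(
                    f"{feature}: reverse-complement asymmetry beyond 0.01 at "
                    f"{asym[:5]} ({len(asym)} pentamer(s))"
                )

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.values)


def load_shape_table(path) -> ShapeTable:
    """Read a header-required TSV with columns pentamer, MGW, EP."""
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if len(header) < 3 or header[0].upper() in _ALL_PENTAMERS:
            raise FormatError(
                f"{path}: expected a header row 'pentamer\\tMGW\\tEP'"
            )
        features = header[1:]
        values: dict[str, dict[str, float]] = {f: {} for f in features}
        for row_no, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}: row {row_no} has {len(parts)} fields, "
                    f"expected {len(header)}"
                )
            penta = parts[0].upper()
            for feature, raw in zip(features, parts[1:]):
                try:
                    values[feature][penta] = float(raw)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric {feature} value at row {row_no}"
                    )
    return ShapeTable(values)


def write_shape_table(table: ShapeTable, path) -> None:
    features = table.features
    with open(path, "w") as fh:
        fh.write("pentamer\t" + "\t".join(features) + "\n")
        for p in _ALL_PENTAMERS:
            vals = "\t".join(f"{table.values[f][p]:.6g}" for f in features)
            fh.write(f"{p}\t{vals}\n")


def _hash_unit(feature: str, seed: int, pentamer: str) -> float:
    digest = hashlib.blake2b(
        f"{feature}:{seed}:{pentamer}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") / 2**64


def synthetic_shape_table(seed: int = 0) -> ShapeTable:
    """Deterministic RC-symmetric stand-in shape table (synthetic values).

    Each reverse-complement pentamer pair gets one value per feature,
    derived by hashing the lexicographically smaller member, mapped into a
    realistic range (MGW 2.85-6.20 Angstrom, EP -12 to -2 kT/e).  Not a
    physical prediction — a structurally valid table for testing pipelines.
    """
    values: dict[str, dict[str, float]] = {f: {} for f in FEATURES}
    for p in _ALL_PENTAMERS:
        canon = min(p, revcomp(p))
        for feature in FEATURES:
            lo, hi = _SYNTHETIC_RANGES[feature]
            u = _hash_unit(feature, seed, canon)
            values[feature][p] = lo + u * (hi - lo)
    return ShapeTable(values)


def shape_profile(seq: str, table: ShapeTable) -> dict[str, np.ndarray]:
    """Per-feature shape values along ``seq``, one per interior position.

    Position i (0-based, 2 <= i <= k-3) takes the table value of the
    pentamer centred on it; the two positions at each end lack full
    pentamer context and are dropped, so each profile has length k-4.
    """
    k = len(seq)
    if k < 5:
        raise FormatError(f"shape profile requires k >= 5, got k={k}")
    pentamers = [seq[i - 2: i + 3] for i in range(2, k - 2)]
    return {
        feature: np.array([table.values[feature][p] for p in pentamers])
        for feature in table.features
    }
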