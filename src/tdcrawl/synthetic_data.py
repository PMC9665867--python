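"""SELEX-like synthetic k-mer enrichment tables with known true offsets.

The generator emulates what a k-mer enrichment table from an in vitro
binding experiment looks like: a transcription factor with an additive
per-position binding-energy matrix over a core site of width w, observed
through k-mers that window the site at every offset.  A k-mer's log
enrichment is the score of its best placement against the core (positions
off the core contribute nothing, as flanking DNA is unbiased), plus
Gaussian noise; unenriched library content appears as random k-mers at
score zero plus noise.  Because each k-mer's best placement is known, the
generator yields ground-truth offsets against which any aligner can be
scored.

Signal k-mers are constructed so the set is realistically dense: for every
strong placement of the core, all consensus-core windows over every flank
base combination, plus sampled single-base core mutants.  Dense coverage is
what makes real enrichment tables alignable at all — enriched k-mers are
connected through single-base substitutions and 1-2 bp overlaps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ALPHABET, FormatError, KmerTable

log = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class GroundTruthModel:
    """Additive binding-energy model: core width w x 4 contributions.

    Higher contributions mean stronger binding; the consensus is the
    per-column argmax (required unique).  ``noise_sd`` is the standard
    deviation of the Gaussian noise added to each k-mer's log enrichment,
    in the same arbitrary units as the energies.
    """

    energy: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        energy = np.asarray(self.energy, dtype=float)
        if energy.ndim != 2 or energy.shape[1] != 4 or energy.shape[0] < 4:
            raise FormatError(
                f"energy matrix must be (w >= 4, 4), got {energy.shape}"
            )
        if not np.all(np.isfinite(energy)):
            raise FormatError("energy matrix must be finite")
        for j in range(energy.shape[0]):
            top = energy[j].max()
            if (energy[j] == top).sum() != 1:
                raise FormatError(
                    f"energy column {j} has a tied maximum; perturb the ties"
                )
        if self.noise_sd < 0:
            raise FormatError("noise_sd must be >= 0")
        object.__setattr__(self, "energy", energy)

    @property
    def w(self) -> int:
        return self.energy.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.energy.argmax(axis=1))

    @property
    def consensus_score(self) -> float:
        return float(self.energy.max(axis=1).sum())

    @classmethod
    def random(
        cls, w: int, noise_sd: float = 0.0, seed: int = 0
    ) -> "GroundTruthModel":
        """A random model with a clear consensus at every position.

        The preferred base contributes U(1.0, 2.0) energy units and the
        other three U(0.0, 0.5), giving realistic specificity (the best
        single-base mutation costs at least half a unit on average).
        """
        rng = np.random.default_rng(seed)
        energy = rng.uniform(0.0, 0.5, size=(w, 4))
        best = rng.integers(0, 4, size=w)
        energy[np.arange(w), best] = rng.uniform(1.0, 2.0, size=w)
        return cls(energy, noise_sd=noise_sd, seed=seed)

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        match: float = 2.0,
        mismatch: float = 0.0,
        noise_sd: float = 0.0,
        seed: int = 0,
    ) -> "GroundTruthModel":
        """Uniform match/mismatch model for a given consensus core."""
        w = len(consensus)
        energy = np.full((w, 4), mismatch)
        # break exact ties among non-consensus bases deterministically
        energy += np.arange(4) * 1e-9
        for j, base in enumerate(consensus):
            energy[j, _BASE_INDEX[base]] = match
        return cls(energy, noise_sd=noise_sd, seed=seed)


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated k-mer table plus its ground truth.

    ``true_offset`` maps each signal k-mer to the start of its best
    placement relative to the core start (bp; negative = 5' of the core),
    recorded only for k-mers whose best placement overlaps the core by at
    least min(w, k) - 2 bp.
    """

    table: KmerTable
    true_offset: dict[str, int]
    model: GroundTruthModel
    k: int

    def __post_init__(self) -> None:
        present = set(self.table.sequences)
        stray = [s for s in self.true_offset if s not in present]
        if stray:
            raise FormatError(
                f"true_offset contains k-mer(s) absent from the table: "
                f"{stray[:5]}"
            )


def _placement_offsets(w: int, k: int) -> np.ndarray:
    return np.arange(-(k - 1), w)


def _core_overlap(t: int, w: int, k: int) -> int:
    return max(0, min(t + k, w) - max(t, 0))


def score_placements(model: GroundTruthModel, seqs: list[str]) -> tuple[
    np.ndarray, np.ndarray
]:
    """Best additive score and best offset for each k-mer.

    A placement at offset t scores the sum of energy contributions over the
    core positions it covers; off-core positions contribute 0.  Ties go to
    the smaller |offset|, then the more 5' one.
    """
    w = model.w
    k = len(seqs[0])
    offsets = _placement_offsets(w, k)
    base_idx = np.array(
        [[_BASE_INDEX[b] for b in s] for s in seqs], dtype=np.intp
    )
    scores = np.zeros((len(seqs), offsets.size))
    for j, t in enumerate(offsets):
        i = np.arange(k)
        valid = (t + i >= 0) & (t + i < w)
        if not valid.any():
            continue
        cols = (t + i)[valid]
        scores[:, j] = model.energy[cols[None, :], base_idx[:, valid]].sum(
            axis=1
        )
    order = sorted(range(offsets.size), key=lambda j: (abs(offsets[j]),
                                                       offsets[j]))
    ordered = scores[:, order]
    best = ordered.max(axis=1)
    pick = np.argmax(ordered >= best[:, None] - 1e-12, axis=1)
    best_offsets = np.array([offsets[order[p]] for p in pick])
    return best, best_offsets


def generate(
    model: GroundTruthModel,
    k: int,
    n_background: int = 2000,
    flank_samples_per_mutation: int = 8,
) -> SyntheticDataset:
    """Generate a SELEX-like enrichment table from the model.

    Parameters
    ----------
    k
        Observation k-mer length (>= 5 so shape features are defined).
    n_background
        Number of unenriched random k-mers added at score 0 + noise.
    flank_samples_per_mutation
        How many random flank contexts accompany each single-base core
        mutant; consensus-core windows get *all* flank combinations, so
        the signal cloud stays connected under substitutions and overlaps.
    """
    if k < 5:
        raise FormatError(f"k must be >= 5, got {k}")
    if n_background < 0:
        raise FormatError("n_background must be >= 0")
    rng = np.random.default_rng(model.seed)
    w = model.w
    consensus = model.consensus
    eligible_overlap = min(w, k) - 2
    offsets = [
        int(t)
        for t in _placement_offsets(w, k)
        if _core_overlap(int(t), w, k) >= eligible_overlap
    ]

    candidates: set[str] = set()
    for t in offsets:
        core_pos = [i for i in range(k) if 0 <= t + i < w]
        flank_pos = [i for i in range(k) if not 0 <= t + i < w]
        template = list("N" * k)
        for i in core_pos:
            template[i] = consensus[t + i]
        # consensus window over every flank combination (keeps the cloud
        # Hamming-connected: any mutant differs from some ideal by 1 bp)
        for combo in itertools.product(ALPHABET, repeat=len(flank_pos)):
            seq = template[:]
            for i, b in zip(flank_pos, combo):
                seq[i] = b
            candidates.add("".join(seq))
        # sampled single-base core mutants
        for i in core_pos:
            for b in ALPHABET:
                if b == consensus[t + i]:
                    continue
                for _ in range(flank_samples_per_mutation):
                    seq = template[:]
                    seq[i] = b
                    for j in flank_pos:
                        seq[j] = ALPHABET[rng.integers(4)]
                    candidates.add("".join(seq))

    signal = sorted(candidates)
    scores, best_offsets = score_placements(model, signal)
    noise = rng.normal(0.0, model.noise_sd, size=len(signal)) \
        if model.noise_sd > 0 else np.zeros(len(signal))

    metric_of: dict[str, float] = {}
    true_offset: dict[str, int] = {}
    for seq, score, t, eps in zip(signal, scores, best_offsets, noise):
        metric_of[seq] = float(score + eps)
        if _core_overlap(int(t), w, k) >= eligible_overlap:
            true_offset[seq] = int(t)

    added = 0
    attempts = 0
    while added < n_background and attempts < 50 * max(n_background, 1):
        attempts += 1
        seq = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=k))
        if seq in metric_of:
            continue  # duplicate of a signal k-mer: keep the signal metric
        eps = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
        metric_of[seq] = float(eps)
        added += 1

    seqs = tuple(sorted(metric_of))
    table = KmerTable(seqs, np.array([metric_of[s] for s in seqs]))
    log.info(
        "generated %d signal + %d background k-mers (%d with true offsets)",
        len(signal), added, len(true_offset),
    )
    return SyntheticDataset(table, true_offset, model, k)
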