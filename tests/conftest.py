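import itertools

import numpy as np
import pytest

from tdcrawl import GroundTruthModel, KmerTable, generate


@pytest.fixture
def worked_table() -> KmerTable:
    """Two-row table whose crawl is fully checkable by hand."""
    return KmerTable(("GTAAACA", "AGTAAAC"), np.array([9.0, 5.0]))


def random_kmer_table(rng: np.random.Generator, k: int, n: int) -> KmerTable:
    """n distinct random k-mers with standard-normal metrics."""
    if n >= 4**k:
        seqs = tuple(
            "".join(p) for p in itertools.product("ACGT", repeat=k)
        )
    else:
        seqs_set: set[str] = set()
        while len(seqs_set) < n:
            seqs_set.add(
                "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
            )
        seqs = tuple(sorted(seqs_set))
    return KmerTable(seqs, rng.normal(size=len(seqs)))


def noisy_dataset(seed: int, w: int, noise_frac: float, k: int = 10,
                  n_background: int = 2000):
    """Synthetic dataset with noise scaled to the consensus score."""
    base = GroundTruthModel.random(w, seed=seed)
    model = GroundTruthModel(
        base.energy, noise_sd=noise_frac * base.consensus_score, seed=seed
    )
    return generate(model, k=k, n_background=n_background)
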