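"""Independent reference implementation of the crawl for oracle tests.

Deliberately naive: every round rescans the full k-mer list for mutation
and overlap neighbours of the current reference, with no neighbour
construction, no priority structure and no shared code with the package's
implementation.  Same round semantics: reference = highest-metric aligned
k-mer not yet used as a reference (ties lexicographic), mutants first,
then overlaps at -1, +1, -2, +2.
"""


def _hamming_is_one(a: str, b: str) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > 1:
                return False
    return d == 1


def naive_crawl(sequences, metrics) -> dict[str, int]:
    m = dict(zip(sequences, metrics))
    k = len(sequences[0])
    shift_of: dict[str, int] = {}
    completed: set[str] = set()
    seed = min(sequences, key=lambda s: (-m[s], s))
    shift_of[seed] = 0
    while True:
        frontier = [s for s in shift_of if s not in completed]
        if not frontier:
            return shift_of
        ref = min(frontier, key=lambda s: (-m[s], s))
        base = shift_of[ref]
        for q in sequences:
            if q not in shift_of and _hamming_is_one(q, ref):
                shift_of[q] = base
        if k >= 3:
            for shift in (-1, +1, -2, +2):
                d = abs(shift)
                for q in sequences:
                    if q in shift_of or q == ref:
                        continue
                    if shift < 0 and q[d:] == ref[: k - d]:
                        shift_of[q] = base + shift
                    elif shift > 0 and q[: k - d] == ref[d:]:
                        shift_of[q] = base + shift
        completed.add(ref)
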