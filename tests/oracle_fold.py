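"""Brute-force folding oracle: enumerate every valid secondary structure of
a short sequence under the package's energy-model contract and score each by
direct loop decomposition. Independent of the DP scanner — only the
model constants (pair strengths, loop-penalty tables, MAXLOOP, minimum
hairpin) are shared, since they define the model being checked.
"""

from __future__ import annotations

from srnascan._fold import (
    MAXLOOP,
    MIN_HAIRPIN,
    _CAN_PAIR,
    encode,
    hairpin_energy,
    loop_energy,
)


def _pairable(enc, i, j):
    return bool(_CAN_PAIR[enc[i], enc[j]])


def enumerate_structures(seq: str, max_span: int) -> list[list[tuple[int, int]]]:
    """All multiloop-free structures: disjoint stem-loops at the external
    level, each a chain of nested pairs with interior loops of at most
    MAXLOOP unpaired nt and a terminal hairpin loop of >= MIN_HAIRPIN nt."""
    enc = encode(seq.upper().replace("U", "T"))
    n = len(enc)

    def stemloops(i, j):
        # all pair-chains closed by (i, j)
        out = []
        if j - i - 1 >= MIN_HAIRPIN:
            out.append([(i, j)])
        for k in range(i + 1, min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 1) + 1):
            l1 = k - i - 1
            for l in range(max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1)), j):
                if l - k > max_span or not _pairable(enc, k, l):
                    continue
                for sub in stemloops(k, l):
                    out.append([(i, j)] + sub)
        return out

    def ext(i):
        if i >= n:
            return [[]]
        out = [s for s in ext(i + 1)]  # position i unpaired
        for j in range(i + MIN_HAIRPIN + 1, min(n, i + max_span + 1)):
            if not _pairable(enc, i, j):
                continue
            for stem in stemloops(i, j):
                for rest in ext(j + 1):
                    out.append(stem + rest)
        return out

    return ext(0)


def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Score one structure by loop decomposition."""
    enc = encode(seq.upper().replace("U", "T"))
    if not pairs:
        return 0.0
    pairs = sorted(pairs)
    total = 0.0
    for idx, (i, j) in enumerate(pairs):
        nested = [(k, l) for (k, l) in pairs if i < k and l < j]
        if not nested:
            total += hairpin_energy(j - i - 1)
        else:
            k, l = min(nested)  # directly nested pair (single chain)
            total += loop_energy(
                k - i - 1, j - l - 1, (enc[i], enc[j]), (enc[k], enc[l])
            )
    return total


def mfe_oracle(seq: str, max_span: int) -> float:
    """Minimum energy over the exhaustive enumeration (0 if nothing helps)."""
    best = 0.0
    for pairs in enumerate_structures(seq, max_span):
        e = structure_energy(seq, pairs)
        if e < best:
            best = e
    return best
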