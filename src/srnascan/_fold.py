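"""Minimum-free-energy folding kernel.

A deliberately compact nearest-neighbour energy model for pseudoknot-free,
multiloop-free secondary structures:

* pair types AU, UA, GC, CG, GU, UG;
* helix stacking energy for two adjacent pairs = -(s1 + s2)/2 where the pair
  strengths are s(GC) = 3.3, s(AU) = 2.1, s(GU) = 1.4 kcal/mol;
* hairpin loops (>= 3 unpaired nt): 5.0 + 1.3 ln(l/3);
* bulge loops: 3.6 + 1.3 ln(l);
* internal loops (total unpaired l = l1 + l2): 2.0 + 1.3 ln(l/2);
* interior loops bounded at MAXLOOP = 8 total unpaired nt;
* no multibranch loops: every closed substructure is a single (possibly
  interrupted) stem-loop, but disjoint stem-loops may sit side by side at
  the external level;
* no dangling-end or terminal-mismatch terms;
* base pair (i, j) allowed only when j - i <= max_span.

The unpaired structure scores 0, so the MFE is always <= 0.

The same constants are the contract for the exhaustive-enumeration oracle in
the test suite; they are intentionally module-level so both sides read one
definition.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e9
MAXLOOP = 8
MIN_HAIRPIN = 3

# base encoding A=0 C=1 G=2 T/U=3
_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair strength matrix (kcal/mol); 0 where the two bases cannot pair
_PS = np.zeros((4, 4), dtype=np.float64)
_PS[0, 3] = _PS[3, 0] = 2.1  # A:U
_PS[2, 1] = _PS[1, 2] = 3.3  # G:C
_PS[2, 3] = _PS[3, 2] = 1.4  # G:U

_CAN_PAIR = _PS > 0

# loop penalty lookup tables, index = unpaired length (precomputed so the
# jitted kernel does no transcendental calls)
_MAXTAB = 512
_HAIRPIN = np.full(_MAXTAB, INF)
for _l in range(MIN_HAIRPIN, _MAXTAB):
    _HAIRPIN[_l] = 5.0 + 1.3 * np.log(_l / 3.0)
_BULGE = np.full(_MAXTAB, INF)
for _l in range(1, _MAXTAB):
    _BULGE[_l] = 3.6 + 1.3 * np.log(float(_l))
_INTERNAL = np.full(_MAXTAB, INF)
for _l in range(2, _MAXTAB):
    _INTERNAL[_l] = 2.0 + 1.3 * np.log(_l / 2.0)


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string to the kernel's integer alphabet."""
    try:
        return np.array([_ENCODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unfoldable residue {exc.args[0]!r} in sequence") from None


def loop_energy(n_unpaired_5p: int, n_unpaired_3p: int,
                outer: tuple[int, int], inner: tuple[int, int]) -> float:
    """Energy of the loop closed by ``outer`` with ``inner`` nested directly
    inside, given the unpaired counts on each side. Shared contract with the
    enumeration oracle."""
    l1, l2 = n_unpaired_5p, n_unpaired_3p
    if l1 == 0 and l2 == 0:
        return -(_PS[outer] + _PS[inner]) / 2.0
    if l1 + l2 > MAXLOOP:
        return INF
    if l1 == 0 or l2 == 0:
        return float(_BULGE[l1 + l2])
    return float(_INTERNAL[l1 + l2])


def hairpin_energy(n_unpaired: int) -> float:
    if n_unpaired < MIN_HAIRPIN or n_unpaired >= _MAXTAB:
        return INF
    return float(_HAIRPIN[n_unpaired])


@njit(cache=True)
def _fill_v(enc, max_span, ps, can_pair, hairpin_tab, bulge_tab, internal_tab):
    n = enc.shape[0]
    v = np.full((n, n), INF)
    top = min(max_span, n - 1)
    for span in range(MIN_HAIRPIN + 1, top + 1):
        for i in range(n - span):
            j = i + span
            if not can_pair[enc[i], enc[j]]:
                continue
            # hairpin closing (i, j)
            best = hairpin_tab[span - 1] if span - 1 < _MAXTAB else INF
            # interior pair (k, l)
            kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 1)
            for k in range(i + 1, kmax + 1):
                l1 = k - i - 1
                lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1))
                for l in range(lmin, j):
                    if v[k, l] >= INF:
                        continue
                    l2 = j - l - 1
                    if l1 == 0 and l2 == 0:
                        e = -(ps[enc[i], enc[j]] + ps[enc[k], enc[l]]) / 2.0
                    elif l1 == 0 or l2 == 0:
                        e = bulge_tab[l1 + l2]
                    else:
                        e = internal_tab[l1 + l2]
                    tot = e + v[k, l]
                    if tot < best:
                        best = tot
            v[i, j] = best
    return v


@njit(cache=True)
def _fill_w(v):
    n = v.shape[0]
    w = np.zeros(n + 1)
    for j in range(1, n + 1):
        best = w[j - 1]
        for i in range(0, j - MIN_HAIRPIN - 1):
            vij = v[i, j - 1]
            if vij < 0.0 and w[i] + vij < best:
                best = w[i] + vij
        w[j] = best
    return w


def fold_energy_encoded(enc: np.ndarray, max_span: int) -> float:
    """MFE only (no traceback); fast path for the shuffle null."""
    if enc.shape[0] < MIN_HAIRPIN + 2:
        return 0.0
    v = _fill_v(enc, max_span, _PS, _CAN_PAIR, _HAIRPIN, _BULGE, _INTERNAL)
    w = _fill_w(v)
    return float(w[enc.shape[0]])


def fold_encoded(enc: np.ndarray, max_span: int) -> tuple[float, str]:
    """MFE plus dot-bracket structure."""
    n = enc.shape[0]
    if n < MIN_HAIRPIN + 2:
        return 0.0, "." * n
    v = _fill_v(enc, max_span, _PS, _CAN_PAIR, _HAIRPIN, _BULGE, _INTERNAL)
    w = _fill_w(v)
    pairs: list[tuple[int, int]] = []
    _trace_w(enc, v, w, n, pairs)
    struct = ["."] * n
    for i, j in pairs:
        struct[i], struct[j] = "(", ")"
    return float(w[n]), "".join(struct)


def _trace_w(enc, v, w, j, pairs):
    eps = 1e-9
    while j > 0:
        if abs(w[j] - w[j - 1]) < eps:
            j -= 1
            continue
        found = False
        for i in range(0, j - MIN_HAIRPIN - 1):
            vij = v[i, j - 1]
            if vij < 0.0 and abs(w[i] + vij - w[j]) < eps:
                _trace_v(enc, v, i, j - 1, pairs)
                j = i
                found = True
                break
        if not found:  # numerical safety net; cannot normally trigger
            j -= 1


def _trace_v(enc, v, i, j, pairs):
    eps = 1e-9
    while True:
        pairs.append((i, j))
        span = j - i
        hp = hairpin_energy(span - 1)
        if abs(v[i, j] - hp) < eps:
            return
        kmax = min(i + MAXLOOP + 1, j - MIN_HAIRPIN - 1)
        nxt = None
        for k in range(i + 1, kmax + 1):
            l1 = k - i - 1
            lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1))
            for l in range(lmin, j):
                if v[k, l] >= INF:
                    continue
                e = loop_energy(l1, j - l - 1, (enc[i], enc[j]), (enc[k], enc[l]))
                if abs(e + v[k, l] - v[i, j]) < eps:
                    nxt = (k, l)
                    break
            if nxt:
                break
        if nxt is None:
            return
        i, j = nxt
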