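"""Compiled depth-first search kernel for exclusive-motif enumeration.

Sequences are represented as per-token position bitmasks: bit ``p`` of
``tok_masks[t, s]`` is set iff token ``t`` matches residue ``p`` of sequence
``s`` (so sequences must be at most 64 residues long, which covers the
peptide range this package mines). A candidate motif is carried as the
bitmask of *end positions* at which it matches each sequence; appending a
token is a shift-and against that token's mask.

The search enumerates candidates level-wise along a DFS path with two exact
prunes:

* positive coverage is anti-monotone under extension, so a candidate whose
  coverage drops below the minimum is abandoned;
* a candidate that is already exclusive (zero negative coverage) and does
  not end in a wildcard is emitted and never extended — every extension
  covers a subset of its positives and would be removed by the
  non-redundancy filter anyway. A candidate that is exclusive but ends in a
  wildcard is not a legal motif and is extended instead.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _dfs(pos_tok, neg_tok, wild, min_cov, max_len, gap, out):  # pragma: no cover
    cap = out.shape[0]
    n_out = 0
    n_tok, n_pos = pos_tok.shape
    n_neg = neg_tok.shape[1]
    P = np.zeros((max_len, n_pos), dtype=np.uint64)
    N = np.zeros((max_len, n_neg), dtype=np.uint64)
    path = np.zeros(max_len, dtype=np.int64)
    titer = np.zeros(max_len, dtype=np.int64)
    wcnt = np.zeros(max_len + 1, dtype=np.int64)
    zero = np.uint64(0)
    one = np.uint64(1)
    depth = 0
    titer[0] = 0
    wcnt[0] = 0
    while depth >= 0:
        if titer[depth] >= n_tok:
            depth -= 1
            continue
        t = titer[depth]
        titer[depth] += 1
        iswild = t == wild
        if iswild and (depth == 0 or wcnt[depth] >= gap or depth == max_len - 1):
            continue
        # positive end-position masks for the extended candidate
        pcov = 0
        if depth == 0:
            for i in range(n_pos):
                v = pos_tok[t, i]
                P[0, i] = v
                if v != zero:
                    pcov += 1
        else:
            for i in range(n_pos):
                v = (P[depth - 1, i] << one) & pos_tok[t, i]
                P[depth, i] = v
                if v != zero:
                    pcov += 1
        if pcov < min_cov:
            continue
        neg_any = False
        if depth == 0:
            for i in range(n_neg):
                v = neg_tok[t, i]
                N[0, i] = v
                if v != zero:
                    neg_any = True
        else:
            for i in range(n_neg):
                v = (N[depth - 1, i] << one) & neg_tok[t, i]
                N[depth, i] = v
                if v != zero:
                    neg_any = True
        if not neg_any and not iswild:
            if n_out + depth + 2 > cap:
                return n_out, True  # overflow: caller retries with more room
            for d in range(depth):
                out[n_out] = path[d]
                n_out += 1
            out[n_out] = t
            n_out += 1
            out[n_out] = -1
            n_out += 1
            continue
        if depth + 1 < max_len:
            path[depth] = t
            wcnt[depth + 1] = wcnt[depth] + (1 if iswild else 0)
            depth += 1
            titer[depth] = 0
    return n_out, False


def enumerate_exclusive(
    pos_tok: np.ndarray,
    neg_tok: np.ndarray,
    wild: int,
    min_cov: int,
    max_len: int,
    gap: int,
) -> list[tuple[int, ...]]:
    """Run the DFS kernel and decode the flat output into token-id tuples."""
    cap = 1 << 16
    while True:
        out = np.empty(cap, dtype=np.int64)
        n_out, overflow = _dfs(
            np.ascontiguousarray(pos_tok),
            np.ascontiguousarray(neg_tok),
            wild,
            min_cov,
            max_len,
            gap,
            out,
        )
        if not overflow:
            break
        cap *= 4
    motifs: list[tuple[int, ...]] = []
    cur: list[int] = []
    for v in out[:n_out]:
        if v == -1:
            motifs.append(tuple(cur))
            cur = []
        else:
            cur.append(int(v))
    return motifs
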