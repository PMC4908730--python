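"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force / textbook formulas,
sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

from proinflam.motifs import WILDCARD, ResidueClassScheme
from proinflam.sequence_io import PeptideRecord


def window_matches(tokens, scheme: ResidueClassScheme, seq: str) -> bool:
    k = len(tokens)
    for start in range(len(seq) - k + 1):
        ok = True
        for j, tok in enumerate(tokens):
            ch = seq[start + j]
            if tok == WILDCARD:
                continue
            if len(tok) == 1:
                if ch != tok:
                    ok = False
                    break
            elif ch not in scheme.classes[tok]:
                ok = False
                break
        if ok:
            return True
    return False


def brute_force_exclusive(
    positives: list[PeptideRecord],
    negatives: list[PeptideRecord],
    scheme: ResidueClassScheme,
    max_len: int,
    gap: int,
    min_cov: int,
) -> list[tuple[tuple[str, ...], frozenset[str]]]:
    """Exhaustive enumeration of non-redundant exclusive motifs.

    Returns (tokens, covered positive ids) sorted like the miner: coverage
    descending, ties by the joined token string.
    """
    observed = sorted({ch for r in positives + negatives for ch in r.sequence})
    tokens = observed + sorted(scheme.classes) + [WILDCARD]
    candidates = []
    for k in range(1, max_len + 1):
        for combo in itertools.product(tokens, repeat=k):
            if combo[0] == WILDCARD or combo[-1] == WILDCARD:
                continue
            if sum(1 for t in combo if t == WILDCARD) > gap:
                continue
            covered = frozenset(
                r.id for r in positives if window_matches(combo, scheme, r.sequence)
            )
            if len(covered) < min_cov:
                continue
            if any(window_matches(combo, scheme, r.sequence) for r in negatives):
                continue
            candidates.append((combo, covered))

    def degeneracy(combo):
        return sum(1 for t in combo if len(t) > 1 or t == WILDCARD)

    retained: list[tuple[tuple[str, ...], frozenset[str]]] = []
    for combo, covered in sorted(
        candidates, key=lambda c: (len(c[0]), degeneracy(c[0]), c[0])
    ):
        if not any(
            len(rc) <= len(combo) and covered <= rcov for rc, rcov in retained
        ):
            retained.append((combo, covered))
    retained.sort(key=lambda c: (-len(c[1]), "-".join(c[0])))
    return retained


def welch_t(a, b) -> tuple[float, float]:
    """Textbook Welch statistic and two-sided p with Welch-Satterthwaite df."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * t_dist.sf(abs(t), df)
    return t, p


def auc_pair_counting(scores, labels) -> float:
    """AUC as concordant-pair probability with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l in (1, "positive")]
    neg = [s for s, l in zip(scores, labels) if l not in (1, "positive")]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def sw_score_dp(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Quadratic Smith-Waterman-Gotoh best local score.

    A gap of length g costs gap_open + (g - 1) * gap_extend, matching the
    affine convention used by the implementation.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + float(sub[a[i - 1], b[j - 1]])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def confusion_metrics_formulas(tp, fp, tn, fn):
    """Direct evaluation of the four printed confusion-matrix equations."""
    sen = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + fn + fp + tn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return sen, spec, acc, mcc
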